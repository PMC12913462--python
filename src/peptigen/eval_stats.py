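"""Evaluation metrics, dataset characterization, ELISpot classification.

* Top-N capture: immunogenic records found in the first N of a ranking.
* ROC AUC via the Mann-Whitney U normalization (ties counted half).
* Chi-square characterization of peptide length and per-position residue
  composition between immunogenic and non-immunogenic peptides.
* Feature statistics: Spearman correlation, Shapiro-Wilk normality,
  Mann-Whitney group comparison, random-forest importance.
* ELISpot response classification at the weak (>= 8) and strong (>= 81)
  background-subtracted spot-count thresholds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .ensemble import ConsensusResult, RankedList
from .records_io import AMINO_ACIDS, LABEL_IMMUNOGENIC, LABEL_NON_IMMUNOGENIC, Dataset


class UndefinedMetricError(ValueError):
    pass


# --- Top-N --------------------------------------------------------------

@dataclass
class TopNReport:
    n_values: list[int]
    captured: dict[int, int]
    total_positives: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"n": n, "captured": self.captured[n]} for n in self.n_values]
        )


def top_n_capture(
    ranking: ConsensusResult | RankedList | list[str],
    truth: dict[str, str],
    n_values: list[int] = (10, 20, 50),
) -> TopNReport:
    """Count truly immunogenic records within each ranking prefix."""
    if isinstance(ranking, ConsensusResult):
        order = ranking.final_order
    elif isinstance(ranking, RankedList):
        order = ranking.record_ids
    else:
        order = list(ranking)
    missing = [rid for rid in order if rid not in truth]
    if missing:
        raise KeyError(f"ranked ids missing from truth map: {missing[:5]}")
    captured = {}
    for n in n_values:
        captured[n] = sum(truth[rid] == LABEL_IMMUNOGENIC for rid in order[:n])
    positives = sum(v == LABEL_IMMUNOGENIC for v in truth.values())
    return TopNReport(n_values=list(n_values), captured=captured, total_positives=positives)


# --- AUC ----------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney U) identity.

    ``labels`` are binary (1 = positive).  Tied scores contribute half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined with a single class")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# --- Dataset characterization ------------------------------------------

@dataclass
class CharacterizationReport:
    length_chi2: float
    length_chi2_p: float
    length_table: pd.DataFrame
    positional_chi2_p: dict[int, float]
    positional_chi2: dict[int, float]
    residue_frequencies: dict[str, pd.DataFrame]  # per class, position x residue


def _length_table(dataset: Dataset) -> pd.DataFrame:
    rows = {
        lab: Counter(len(r.mutant_peptide) for r in dataset if r.label == lab)
        for lab in (LABEL_IMMUNOGENIC, LABEL_NON_IMMUNOGENIC)
    }
    lengths = sorted(set().union(*[set(c) for c in rows.values()]))
    return pd.DataFrame(
        {lab: [rows[lab].get(L, 0) for L in lengths] for lab in rows}, index=lengths
    )


def _position_counts(dataset: Dataset, position: int) -> pd.DataFrame:
    """20 x 2 residue count table at a 1-based position (peptides long enough)."""
    counts = {
        lab: Counter(
            r.mutant_peptide[position - 1]
            for r in dataset
            if r.label == lab and len(r.mutant_peptide) >= position
        )
        for lab in (LABEL_IMMUNOGENIC, LABEL_NON_IMMUNOGENIC)
    }
    return pd.DataFrame(
        {lab: [counts[lab].get(a, 0) for a in AMINO_ACIDS] for lab in counts},
        index=list(AMINO_ACIDS),
    )


def _pool_sparse(table: pd.DataFrame, min_expected: float = 5.0) -> pd.DataFrame:
    """Pool residue rows with expected count < min_expected into 'other'."""
    total = table.values.sum()
    if total == 0:
        return table
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    expected = np.outer(row_sums, col_sums) / total
    sparse = (expected < min_expected).any(axis=1)
    if sparse.sum() <= 1:
        return table
    keep = table.loc[~sparse]
    other = table.loc[sparse].sum(axis=0).to_frame().T
    other.index = ["other"]
    return pd.concat([keep, other])


def characterize_dataset(
    dataset: Dataset,
    max_position: int = 11,
    min_expected: float = 5.0,
) -> CharacterizationReport:
    """Compare length and positional residue composition between classes.

    The length test is a chi-square on the 8-11 contingency table; each
    position gets a residue x class chi-square after pooling sparse rows
    (expected count < ``min_expected``) into an 'other' row.  Residue
    frequencies are normalized to sum to 1 per position within each class.
    """
    counts = dataset.label_counts()
    for lab in (LABEL_IMMUNOGENIC, LABEL_NON_IMMUNOGENIC):
        if counts.get(lab, 0) == 0:
            raise UndefinedMetricError(f"no records with label {lab!r}")
    length_table = _length_table(dataset)
    nonzero = length_table.loc[(length_table.sum(axis=1) > 0)]
    if len(nonzero) > 1 and (nonzero.sum(axis=0) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(nonzero.values)
    else:
        chi2, p = 0.0, 1.0
    positional_p: dict[int, float] = {}
    positional_stat: dict[int, float] = {}
    freq: dict[str, pd.DataFrame] = {
        LABEL_IMMUNOGENIC: pd.DataFrame(index=list(AMINO_ACIDS)),
        LABEL_NON_IMMUNOGENIC: pd.DataFrame(index=list(AMINO_ACIDS)),
    }
    for pos in range(1, max_position + 1):
        table = _position_counts(dataset, pos)
        for lab in freq:
            col_total = table[lab].sum()
            freq[lab][pos] = table[lab] / col_total if col_total else 0.0
        if (table.sum(axis=0) == 0).any():
            continue
        pooled = _pool_sparse(table, min_expected=min_expected)
        pooled = pooled.loc[pooled.sum(axis=1) > 0]
        if len(pooled) < 2:
            continue
        s, p_pos, _, _ = stats.chi2_contingency(pooled.values)
        positional_stat[pos] = float(s)
        positional_p[pos] = float(p_pos)
    return CharacterizationReport(
        length_chi2=float(chi2),
        length_chi2_p=float(p),
        length_table=length_table,
        positional_chi2_p=positional_p,
        positional_chi2=positional_stat,
        residue_frequencies=freq,
    )


# --- Feature statistics -------------------------------------------------

@dataclass
class FeatureStatsReport:
    spearman: pd.DataFrame
    shapiro_p: dict[str, float]
    mannwhitney_p: dict[str, float]
    rf_importance: pd.Series
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)


def feature_stats(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    n_trees: int = 500,
) -> FeatureStatsReport:
    """Feature independence, normality, group separation and RF importance.

    Constant features make Spearman undefined for their pairs; those cells
    are reported as NaN and the pairs listed, never silently zeroed.
    """
    labels = np.asarray(labels).astype(int)
    if min((labels == 1).sum(), (labels == 0).sum()) < 3:
        raise UndefinedMetricError("need >= 3 records per class")
    names = list(features.columns)
    X = features.values.astype(float)
    constant = [n for n, col in zip(names, X.T) if np.ptp(col) == 0]
    spearman = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    undefined: list[tuple[str, str]] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if names[i] in constant or names[j] in constant:
                spearman.iloc[i, j] = spearman.iloc[j, i] = np.nan
                undefined.append((names[i], names[j]))
            else:
                rho, _ = stats.spearmanr(X[:, i], X[:, j])
                spearman.iloc[i, j] = spearman.iloc[j, i] = rho
    shapiro_p = {}
    mw_p = {}
    for n, col in zip(names, X.T):
        shapiro_p[n] = float(stats.shapiro(col).pvalue) if np.ptp(col) > 0 else float("nan")
        if np.ptp(col) > 0:
            mw_p[n] = float(
                stats.mannwhitneyu(col[labels == 1], col[labels == 0]).pvalue
            )
        else:
            mw_p[n] = float("nan")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(X, labels)
    importance = pd.Series(rf.feature_importances_, index=names).sort_values(
        ascending=False
    )
    return FeatureStatsReport(
        spearman=spearman,
        shapiro_p=shapiro_p,
        mannwhitney_p=mw_p,
        rf_importance=importance,
        undefined_pairs=undefined,
    )


# --- ELISpot ------------------------------------------------------------

@dataclass(frozen=True)
class ElispotThresholds:
    """Background-subtracted spot-count cutoffs: weak = [8, 81), strong >= 81."""

    weak_min: float = 8.0
    strong_min: float = 81.0

    def __post_init__(self) -> None:
        if not 0 < self.weak_min < self.strong_min:
            raise ValueError("require 0 < weak_min < strong_min")


@dataclass
class ElispotResult:
    peptide_id: str
    replicate_counts: list[float]
    background_mean: float
    adjusted_count: float = 0.0
    response: str = "negative"
    dropped_replicates: int = 0


def _drop_outliers(counts: np.ndarray, n_sd: float = 2.0) -> np.ndarray:
    """Leave-one-out outlier rule for replicate wells (>= 3 replicates).

    A replicate is dropped when it deviates from the mean of the other
    replicates by more than ``n_sd`` times their SD.  The SD is floored at
    a counting-noise scale (0.1 x mean + 1) so near-identical replicates
    do not flag trivial jitter.  An all-of-the-mean rule (z against the
    full-sample SD) cannot fire at all for <= 5 replicates, hence the
    leave-one-out form.
    """
    if len(counts) < 3:
        return counts
    keep = np.ones(len(counts), dtype=bool)
    for i in range(len(counts)):
        others = np.delete(counts, i)
        floor = 0.1 * others.mean() + 1.0
        sd = max(others.std(), floor)
        if abs(counts[i] - others.mean()) > n_sd * sd:
            keep[i] = False
    return counts[keep] if keep.any() else counts


@dataclass
class ElispotSummary:
    n_total: int
    n_weak: int
    n_strong: int

    @property
    def n_positive(self) -> int:
        return self.n_weak + self.n_strong

    @property
    def positive_rate(self) -> float:
        return 100.0 * self.n_positive / self.n_total

    @property
    def weak_rate(self) -> float:
        return 100.0 * self.n_weak / self.n_total

    @property
    def strong_rate(self) -> float:
        return 100.0 * self.n_strong / self.n_total


def classify_elispot(
    raw: list[ElispotResult] | pd.DataFrame,
    thresholds: ElispotThresholds = ElispotThresholds(),
    outlier_sd: float | None = 2.0,
) -> tuple[list[ElispotResult], ElispotSummary]:
    """Classify per-peptide ELISpot responses and summarize positivity.

    The adjusted count is the replicate mean after outlier removal minus
    the background mean, floored at 0.  Strong takes precedence at the
    shared boundary: strong = adjusted >= strong_min, weak = [weak_min,
    strong_min), else negative.
    """
    if isinstance(raw, pd.DataFrame):
        results = []
        rep_cols = [c for c in raw.columns if c.startswith("replicate")]
        for row in raw.itertuples(index=False):
            d = row._asdict()
            reps = [float(d[c]) for c in rep_cols if str(d[c]).strip() != ""]
            results.append(
                ElispotResult(
                    peptide_id=str(d["peptide_id"]),
                    replicate_counts=reps,
                    background_mean=float(d["background_mean"]),
                )
            )
    else:
        results = raw
    n_weak = n_strong = 0
    for res in results:
        counts = np.asarray(res.replicate_counts, dtype=float)
        if len(counts) == 0:
            raise ValueError(f"peptide {res.peptide_id}: no replicates")
        if (counts < 0).any():
            raise ValueError(f"peptide {res.peptide_id}: negative spot count")
        kept = _drop_outliers(counts, outlier_sd) if outlier_sd is not None else counts
        res.dropped_replicates = len(counts) - len(kept)
        res.adjusted_count = max(0.0, float(kept.mean()) - res.background_mean)
        if res.adjusted_count >= thresholds.strong_min:
            res.response = "strong"
            n_strong += 1
        elif res.adjusted_count >= thresholds.weak_min:
            res.response = "weak"
            n_weak += 1
        else:
            res.response = "negative"
    return results, ElispotSummary(n_total=len(results), n_weak=n_weak, n_strong=n_strong)
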