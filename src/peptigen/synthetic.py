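"""Synthetic fixtures emulating the curated training data, plus read mixing.

The training-set generator reproduces the structural signatures of the
curated peptide-HLA corpus: 8-11-mer peptides with class-dependent length
skew (9-mers dominate the immunogenic class), positional residue
enrichment in immunogenic peptides (K/R at P1, E/D at P2-P4), a broader
HLA-allele usage in the immunogenic class, class imbalance, and eleven
class-conditionally Gaussian structured features of which seven carry a
mean shift.  Ground-truth sampling parameters are returned with every
dataset so parameter-recovery tests can close the loop.

``insilico_mix`` emulates constructing a diluted tumor cell-free DNA
sample by mixing tumor-derived reads with non-cancer reads at a fixed
tumor fraction (default 15:85), sampling without replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .eval_stats import ElispotResult
from .records_io import (
    AMINO_ACIDS,
    FEATURE_NAMES,
    LABEL_IMMUNOGENIC,
    LABEL_NON_IMMUNOGENIC,
    Dataset,
    PeptideHlaRecord,
)

# Background amino-acid frequencies (approximate vertebrate proteome usage)
BACKGROUND_AA_FREQ = {
    "A": 0.074, "R": 0.042, "N": 0.044, "D": 0.059, "C": 0.033,
    "Q": 0.037, "E": 0.058, "G": 0.074, "H": 0.029, "I": 0.038,
    "L": 0.076, "K": 0.072, "M": 0.018, "F": 0.040, "P": 0.050,
    "S": 0.081, "T": 0.062, "W": 0.013, "Y": 0.033, "V": 0.068,
}

DEFAULT_HLA_POOL = (
    "HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01", "HLA-A*11:01",
    "HLA-A*24:02", "HLA-B*07:02", "HLA-B*08:01", "HLA-B*15:01",
    "HLA-B*44:02", "HLA-C*04:01", "HLA-C*07:01", "HLA-C*07:02",
)

# Negative-class allele usage is concentrated in a few common alleles
# (immunogenic peptides span a more diverse allele range).
_NEG_HLA_WEIGHTS_DEFAULT = (1, 6, 1, 1, 6, 1, 1, 1, 6, 1, 1, 1)
_NEG_HLA_WEIGHTS_STRONG = (0.3, 10, 0.3, 0.3, 10, 0.3, 0.3, 0.3, 10, 0.3, 0.3, 0.3)


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorSpec:
    """Sampling parameters for the synthetic peptide-HLA training set."""

    n_records: int = 2000
    positive_fraction: float = 0.30
    # class-conditional length probabilities over 8..11
    length_probs_positive: tuple[float, float, float, float] = (0.06, 0.59, 0.28, 0.07)
    length_probs_negative: tuple[float, float, float, float] = (0.03, 0.49, 0.46, 0.02)
    # position (1-based) -> (residues, enrichment odds in the positive class)
    enriched_positions: tuple[tuple[int, str, float], ...] = (
        (1, "KR", 3.0),
        (2, "ED", 3.0),
        (3, "ED", 3.0),
        (4, "ED", 3.0),
    )
    hla_pool: tuple[str, ...] = DEFAULT_HLA_POOL
    hla_weights_positive: tuple[float, ...] = tuple([1.0] * len(DEFAULT_HLA_POOL))
    hla_weights_negative: tuple[float, ...] = _NEG_HLA_WEIGHTS_DEFAULT
    # feature name -> mean shift (in SD units) of the positive class
    feature_effect_sizes: tuple[tuple[str, float], ...] = tuple(
        (f, 0.8) for f in FEATURE_NAMES[:7]
    )
    # when set, each class draws peptides as 1-residue variants of a finite
    # repertoire of prototype epitopes (shared/public epitope families), so
    # the class signal recurs in k-mer space instead of being carried by
    # near-unique positional draws
    family_repertoire: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for probs in (self.length_probs_positive, self.length_probs_negative):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise SpecError(f"length probabilities must sum to 1, got {probs}")
        if not 0 < self.positive_fraction < 1:
            raise SpecError("positive_fraction must be in (0, 1)")
        if self.n_records * self.positive_fraction < 1 or self.n_records * (
            1 - self.positive_fraction
        ) < 1:
            raise SpecError("spec expects zero records of one class")

    @classmethod
    def strong_signal(cls, n_records: int = 2000, seed: int = 0) -> "GeneratorSpec":
        """Planted-signal condition for parameter-recovery experiments:
        high positional enrichment odds, strongly tilted allele usage and
        seven features shifted by 1.5 SD."""
        return cls(
            n_records=n_records,
            enriched_positions=(
                (1, "KR", 25.0),
                (2, "ED", 25.0),
                (3, "ED", 25.0),
                (4, "ED", 25.0),
            ),
            hla_weights_negative=_NEG_HLA_WEIGHTS_STRONG,
            feature_effect_sizes=tuple((f, 1.5) for f in FEATURE_NAMES[:7]),
            family_repertoire=25,
            seed=seed,
        )

    @classmethod
    def null(cls, n_records: int = 400, seed: int = 0) -> "GeneratorSpec":
        """No planted signal anywhere: identical length, residue, allele
        and feature distributions in both classes (calibration checks)."""
        uniform = tuple([1.0] * len(DEFAULT_HLA_POOL))
        probs = (0.05, 0.55, 0.35, 0.05)
        return cls(
            n_records=n_records,
            positive_fraction=0.5,
            length_probs_positive=probs,
            length_probs_negative=probs,
            enriched_positions=(),
            hla_weights_positive=uniform,
            hla_weights_negative=uniform,
            feature_effect_sizes=(),
            seed=seed,
        )


@dataclass
class GroundTruth:
    """Sampling distributions actually used, for parameter-recovery tests."""

    spec: GeneratorSpec
    position_distributions: dict[str, dict[int, np.ndarray]]
    hla_frequencies: dict[str, np.ndarray]
    feature_means: dict[str, np.ndarray]


def _background_vector() -> np.ndarray:
    base = np.array([BACKGROUND_AA_FREQ[a] for a in AMINO_ACIDS])
    return base / base.sum()


def _position_distribution(
    enriched: dict[int, tuple[str, float]], position: int, positive: bool
) -> np.ndarray:
    base = np.array([BACKGROUND_AA_FREQ[a] for a in AMINO_ACIDS])
    base = base / base.sum()
    if positive and position in enriched:
        residues, odds = enriched[position]
        weights = base.copy()
        for a in residues:
            weights[AMINO_ACIDS.index(a)] *= odds
        return weights / weights.sum()
    return base


def generate_training_set(spec: GeneratorSpec) -> tuple[Dataset, GroundTruth]:
    """Draw a labeled synthetic peptide-HLA dataset; seeded and deterministic."""
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_records * spec.positive_fraction))
    n_neg = spec.n_records - n_pos
    enriched = {p: (res, odds) for p, res, odds in spec.enriched_positions}
    aa = np.array(list(AMINO_ACIDS))
    lengths_all = np.array([8, 9, 10, 11])

    pos_dists = {
        LABEL_IMMUNOGENIC: {
            p: _position_distribution(enriched, p, True) for p in range(1, 12)
        },
        LABEL_NON_IMMUNOGENIC: {
            p: _position_distribution(enriched, p, False) for p in range(1, 12)
        },
    }
    hla_freqs = {}
    for lab, weights in (
        (LABEL_IMMUNOGENIC, spec.hla_weights_positive),
        (LABEL_NON_IMMUNOGENIC, spec.hla_weights_negative),
    ):
        w = np.asarray(weights, dtype=float)
        hla_freqs[lab] = w / w.sum()
    effects = dict(spec.feature_effect_sizes)
    feat_means = {
        LABEL_IMMUNOGENIC: np.array([effects.get(f, 0.0) for f in FEATURE_NAMES]),
        LABEL_NON_IMMUNOGENIC: np.zeros(len(FEATURE_NAMES)),
    }

    records: list[PeptideHlaRecord] = []
    counter = 0
    for lab, n_class, length_probs in (
        (LABEL_IMMUNOGENIC, n_pos, spec.length_probs_positive),
        (LABEL_NON_IMMUNOGENIC, n_neg, spec.length_probs_negative),
    ):
        if spec.family_repertoire:
            # draw a finite repertoire of prototype epitopes per class, then
            # emit each record as a 1-residue variant of a random prototype
            n_proto = spec.family_repertoire
            proto_lengths = rng.choice(lengths_all, size=n_proto, p=np.asarray(length_probs))
            proto_matrix = np.empty((n_proto, 11), dtype="<U1")
            for p in range(1, 12):
                proto_matrix[:, p - 1] = rng.choice(aa, size=n_proto, p=pos_dists[lab][p])
            pick = rng.integers(0, n_proto, size=n_class)
            lengths = proto_lengths[pick]
            residue_matrix = proto_matrix[pick].copy()
            var_pos = rng.integers(0, lengths)
            var_res = rng.choice(aa, size=n_class, p=_background_vector())
            residue_matrix[np.arange(n_class), var_pos] = var_res
        else:
            lengths = rng.choice(lengths_all, size=n_class, p=np.asarray(length_probs))
            # residues drawn position-wise for the full 11-mer frame, then cut
            residue_matrix = np.empty((n_class, 11), dtype="<U1")
            for p in range(1, 12):
                residue_matrix[:, p - 1] = rng.choice(aa, size=n_class, p=pos_dists[lab][p])
        alleles = rng.choice(spec.hla_pool, size=n_class, p=hla_freqs[lab])
        feats = rng.standard_normal((n_class, len(FEATURE_NAMES))) + feat_means[lab]
        wt_pos = rng.integers(0, lengths)  # mutated position per record
        wt_sub = rng.choice(aa, size=n_class)
        for i in range(n_class):
            L = int(lengths[i])
            pep = "".join(residue_matrix[i, :L])
            wt = list(pep)
            # wild-type differs from mutant in exactly one residue
            alt = wt_sub[i] if wt_sub[i] != wt[wt_pos[i]] else aa[(AMINO_ACIDS.index(wt[wt_pos[i]]) + 1) % 20]
            wt[wt_pos[i]] = alt
            records.append(
                PeptideHlaRecord(
                    record_id=f"syn{counter:05d}",
                    mutant_peptide=pep,
                    wildtype_peptide="".join(wt),
                    hla_allele=str(alleles[i]),
                    label=lab,
                    features={f: float(v) for f, v in zip(FEATURE_NAMES, feats[i])},
                    source="synthetic",
                )
            )
            counter += 1
    perm = rng.permutation(len(records))
    records = [records[i] for i in perm]
    for i, rec in enumerate(records):
        rec.record_id = f"syn{i:05d}"
    truth = GroundTruth(
        spec=spec,
        position_distributions=pos_dists,
        hla_frequencies=hla_freqs,
        feature_means=feat_means,
    )
    return Dataset(records=records, role="train"), truth


# --- ELISpot fixtures ---------------------------------------------------

def generate_elispot_counts(
    n_peptides: int,
    response_mix: dict[str, float] | None = None,
    background_mean: float = 10.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[list[ElispotResult], list[str]]:
    """Draw replicate spot counts with planted response classes.

    Replicates are Poisson around background + a class-dependent signal
    (negative +2, weak +40, strong +150), so at default noise the planted
    class is recovered by threshold classification with probability
    >= 0.95.  Returns the inputs and the planted class labels.
    """
    response_mix = response_mix or {"weak": 0.3, "strong": 0.1}
    if sum(response_mix.values()) > 1 + 1e-9:
        raise ValueError("response_mix fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    n_weak = int(round(n_peptides * response_mix.get("weak", 0.0)))
    n_strong = int(round(n_peptides * response_mix.get("strong", 0.0)))
    planted = (
        ["strong"] * n_strong + ["weak"] * n_weak + ["negative"] * (n_peptides - n_weak - n_strong)
    )
    signal = {"negative": 2.0, "weak": 40.0, "strong": 150.0}
    results = []
    for i, cls in enumerate(planted):
        lam = background_mean + signal[cls]
        counts = rng.poisson(lam, size=n_replicates).astype(float)
        results.append(
            ElispotResult(
                peptide_id=f"pep{i:03d}",
                replicate_counts=list(counts),
                background_mean=background_mean,
            )
        )
    return results, planted


# --- In-silico read mixing ----------------------------------------------

@dataclass(frozen=True)
class MixSpec:
    tumor_fraction: float = 0.15
    depth_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tumor_fraction <= 1:
            raise SpecError("tumor_fraction must be in (0, 1]")
        if self.depth_scale <= 0:
            raise SpecError("depth_scale must be > 0")


class DepthError(ValueError):
    pass


def make_toy_reads(
    n_reads: int,
    read_length: int = 100,
    seed: int = 0,
    prefix: str = "read",
    reference_length: int = 10_000,
) -> list[SeqRecord]:
    """Random reads drawn from a random toy reference (Phred+33 quality)."""
    rng = np.random.default_rng(seed)
    ref = "".join(rng.choice(list("ACGT"), size=reference_length))
    records = []
    for i in range(n_reads):
        start = int(rng.integers(0, reference_length - read_length))
        seq = ref[start : start + read_length]
        rec = SeqRecord(Seq(seq), id=f"{prefix}_{i}", description="")
        rec.letter_annotations["phred_quality"] = [30] * read_length
        records.append(rec)
    return records


def insilico_mix(
    tumor_reads: list[SeqRecord],
    normal_reads: list[SeqRecord],
    spec: MixSpec = MixSpec(),
    n_total: int | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Mix tumor and normal reads at a fixed tumor fraction.

    Samples ``floor(tumor_fraction * n_total)`` reads without replacement
    from the tumor pool and the complement from the normal pool, shuffles
    with the seed, and returns the mixed reads plus a manifest tracing
    every output read to its source stream.
    """
    if not tumor_reads or not normal_reads:
        raise ValueError("both read streams must be non-empty")
    if n_total is None:
        # largest feasible total at the requested fraction and depth scale
        f = spec.tumor_fraction
        n_total = min(
            math.floor(len(tumor_reads) / f) if f > 0 else 0,
            math.floor(len(normal_reads) / (1 - f)) if f < 1 else 10**18,
        )
        n_total = int(n_total * spec.depth_scale)
    n_tumor = math.floor(spec.tumor_fraction * n_total)
    n_normal = n_total - n_tumor
    if n_tumor > len(tumor_reads):
        raise DepthError(f"requested {n_tumor} tumor reads, only {len(tumor_reads)} available")
    if n_normal > len(normal_reads):
        raise DepthError(f"requested {n_normal} normal reads, only {len(normal_reads)} available")
    rng = np.random.default_rng(spec.seed)
    t_idx = rng.choice(len(tumor_reads), size=n_tumor, replace=False)
    n_idx = rng.choice(len(normal_reads), size=n_normal, replace=False)
    mixed = [(tumor_reads[i], "tumor") for i in t_idx] + [
        (normal_reads[i], "normal") for i in n_idx
    ]
    order = rng.permutation(len(mixed))
    mixed = [mixed[i] for i in order]
    manifest = pd.DataFrame(
        [{"read_id": rec.id, "origin": origin} for rec, origin in mixed]
    )
    return [rec for rec, _ in mixed], manifest


def write_fastq(records: list[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fastq"))
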