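"""Rank-level late-fusion consensus over 2-3 submodel rankings.

Each submodel emits a full ranking of the candidate peptide-HLA pairs.
The ensemble takes the top-n (default 50) of each list, calls every
candidate that appears in at least two of those top-n sets a *consensus*
peptide, puts the consensus block first, and appends the remaining
candidates by their model-specific scores.

Two sub-rules are underdetermined by a pure rank-fusion description and
are fixed (and config-switchable) here:

* order *within* the consensus block: support count descending, then mean
  per-model rank ascending, then record_id;
* the remainder block compares scores across models after per-model
  min-max normalization, taking each record's maximum normalized score
  (descending, record_id tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RankedList:
    """Ordered (record_id, score, rank) triples from one model."""

    entries: list[tuple[str, float, int]]
    model_tag: str = ""

    @classmethod
    def from_scores(cls, record_ids, scores, model_tag: str = "") -> "RankedList":
        """Rank by descending score with lexicographic record_id tie-break."""
        order = sorted(range(len(record_ids)), key=lambda i: (-scores[i], record_ids[i]))
        entries = [
            (record_ids[i], float(scores[i]), rank + 1) for rank, i in enumerate(order)
        ]
        return cls(entries=entries, model_tag=model_tag)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def record_ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def scores(self) -> dict[str, float]:
        return {rid: s for rid, s, _ in self.entries}

    def ranks(self) -> dict[str, int]:
        return {rid: r for rid, _, r in self.entries}

    def top(self, n: int) -> list[str]:
        return [e[0] for e in self.entries[:n]]

    def validate(self) -> None:
        ids = self.record_ids
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in ranking: {dups}")
        ranks = [e[2] for e in self.entries]
        if ranks != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be 1..n in order")


@dataclass
class ConsensusResult:
    final_order: list[str]
    consensus_ids: set[str]
    support_count: dict[str, int]
    top_n: int
    per_model_ranks: dict[str, dict[str, int]] = field(default_factory=dict)
    per_model_scores: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, rid in enumerate(self.final_order, start=1):
            row = {
                "rank": rank,
                "record_id": rid,
                "consensus_flag": rid in self.consensus_ids,
                "support_count": self.support_count.get(rid, 0),
            }
            for tag, ranks in self.per_model_ranks.items():
                row[f"rank_{tag}"] = ranks[rid]
            for tag, scores in self.per_model_scores.items():
                row[f"score_{tag}"] = scores[rid]
            rows.append(row)
        return pd.DataFrame(rows)


def _minmax(scores: dict[str, float]) -> dict[str, float]:
    vals = np.array(list(scores.values()))
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return {k: 0.0 for k in scores}
    return {k: (v - lo) / (hi - lo) for k, v in scores.items()}


def fuse_rankings(lists: list[RankedList], top_n: int = 50) -> ConsensusResult:
    """Fuse 2-3 full rankings of the same candidate set into one ordering.

    Consensus block = candidates in >= 2 of the per-model top-n sets,
    ordered by (support desc, mean per-model rank asc, record_id);
    remainder ordered by max per-model min-max-normalized score
    (desc, record_id tie-break).
    """
    if not 2 <= len(lists) <= 3:
        raise ValueError(f"expected 2-3 ranked lists, got {len(lists)}")
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    for rl in lists:
        rl.validate()
    candidate_sets = [set(rl.record_ids) for rl in lists]
    universe = candidate_sets[0]
    for i, s in enumerate(candidate_sets[1:], start=2):
        if s != universe:
            diff = sorted(universe.symmetric_difference(s))
            raise ValueError(f"candidate sets differ (list 1 vs {i}): {diff}")

    support: dict[str, int] = {rid: 0 for rid in universe}
    for rl in lists:
        for rid in rl.top(top_n):
            support[rid] += 1
    consensus = {rid for rid, c in support.items() if c >= 2}

    ranks_by_model = {rl.model_tag or f"m{i}": rl.ranks() for i, rl in enumerate(lists)}
    scores_by_model = {rl.model_tag or f"m{i}": rl.scores() for i, rl in enumerate(lists)}
    mean_rank = {
        rid: float(np.mean([r[rid] for r in ranks_by_model.values()])) for rid in universe
    }
    norm_scores = [_minmax(s) for s in scores_by_model.values()]
    best_norm = {rid: max(ns[rid] for ns in norm_scores) for rid in universe}

    consensus_sorted = sorted(
        consensus, key=lambda rid: (-support[rid], mean_rank[rid], rid)
    )
    remainder_sorted = sorted(
        universe - consensus, key=lambda rid: (-best_norm[rid], rid)
    )
    return ConsensusResult(
        final_order=consensus_sorted + remainder_sorted,
        consensus_ids=consensus,
        support_count=support,
        top_n=top_n,
        per_model_ranks=ranks_by_model,
        per_model_scores=scores_by_model,
    )
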