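"""Mutant-peptide enumeration from missense variants and feature assembly.

A missense variant at protein position p yields, for each length L in
8-11, every window of length L that lies fully inside the protein and
covers p, with the reference residue replaced by the alternate.  The
eleven structured immunogenicity features attached to each candidate are
split into locally computable sequence descriptors and externally supplied
predictor scores (binding affinity, stability, TAP transport, processing,
expression); the model layer treats all eleven identically, so swapping a
proxy for an external tool's score changes no interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import pandas as pd
from Bio.Align import substitution_matrices

from .records_io import VariantRecord

# Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
_POLAR = set("STNQYCHKRDE")
_AROMATIC = set("FWY")
_POSITIVE = set("KRH")
_NEGATIVE = set("DE")
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class RefMismatchError(ValueError):
    """Protein sequence disagrees with the variant's reference residue."""


class CoordinateError(ValueError):
    pass


class MissingFeatureError(KeyError):
    pass


@dataclass(frozen=True)
class EpitopeCandidate:
    """One mutant peptide window derived from a missense variant."""

    peptide: str
    source_variant: VariantRecord
    mutant_position_in_peptide: int  # 1-based
    window_start: int  # 1-based protein coordinate

    def __post_init__(self) -> None:
        if self.peptide[self.mutant_position_in_peptide - 1] != self.source_variant.alt_aa:
            raise ValueError(
                f"peptide {self.peptide} does not carry alt residue "
                f"{self.source_variant.alt_aa} at position "
                f"{self.mutant_position_in_peptide}"
            )


def enumerate_mutant_peptides(
    protein: str,
    variant: VariantRecord,
    lengths: frozenset[int] | set[int] = frozenset({8, 9, 10, 11}),
) -> list[EpitopeCandidate]:
    """Enumerate all 8-11-mer mutant windows covering a missense variant.

    For a variant at interior distance >= L-1 from both protein ends there
    are exactly L windows of length L; windows are clipped at the protein
    boundaries.  Identical peptide strings arising from different windows
    collapse to the first (leftmost) occurrence.
    """
    if not lengths <= {8, 9, 10, 11}:
        raise ValueError(f"lengths must be within 8..11, got {sorted(lengths)}")
    pos = variant.position
    if not 1 <= pos <= len(protein):
        raise CoordinateError(
            f"variant position {pos} outside protein of length {len(protein)}"
        )
    if protein[pos - 1] != variant.ref_aa:
        raise RefMismatchError(
            f"protein {variant.protein_id} position {pos}: expected "
            f"{variant.ref_aa}, found {protein[pos - 1]}"
        )
    mutated = protein[: pos - 1] + variant.alt_aa + protein[pos:]
    seen: dict[str, EpitopeCandidate] = {}
    for L in sorted(lengths):
        start_lo = max(1, pos - L + 1)
        start_hi = min(pos, len(protein) - L + 1)
        for start in range(start_lo, start_hi + 1):
            pep = mutated[start - 1 : start - 1 + L]
            if pep not in seen:
                seen[pep] = EpitopeCandidate(
                    peptide=pep,
                    source_variant=variant,
                    mutant_position_in_peptide=pos - start + 1,
                    window_start=start,
                )
    return list(seen.values())


# --- Feature registry ---------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    name: str
    category: str  # processing_presentation | tcr_recognition | expression
    provenance: str  # local_proxy | external_column
    compute: Callable[[EpitopeCandidate], float] | None = None
    description: str = ""


def _tcr_contact_hydrophobicity(c: EpitopeCandidate) -> float:
    """Mean Kyte-Doolittle hydropathy over positions 4..L-1 (TCR-facing)."""
    segment = c.peptide[3 : len(c.peptide) - 1]
    return sum(KYTE_DOOLITTLE[a] for a in segment) / len(segment)


def _net_charge(c: EpitopeCandidate) -> float:
    return float(
        sum(a in _POSITIVE for a in c.peptide) - sum(a in _NEGATIVE for a in c.peptide)
    )


def _polar_fraction(c: EpitopeCandidate) -> float:
    return sum(a in _POLAR for a in c.peptide) / len(c.peptide)


def _aromatic_fraction(c: EpitopeCandidate) -> float:
    return sum(a in _AROMATIC for a in c.peptide) / len(c.peptide)


def _peptide_hydrophobicity(c: EpitopeCandidate) -> float:
    return sum(KYTE_DOOLITTLE[a] for a in c.peptide) / len(c.peptide)


def _wt_dissimilarity(c: EpitopeCandidate) -> float:
    """Negated BLOSUM62 score of the ref->alt substitution (higher = more
    dissimilar to self, i.e. more foreign-looking to the immune system)."""
    v = c.source_variant
    return -float(_BLOSUM62[v.ref_aa][v.alt_aa])


DEFAULT_REGISTRY: tuple[FeatureSpec, ...] = (
    FeatureSpec("F1", "processing_presentation", "external_column",
                description="peptide-HLA binding affinity (external predictor)"),
    FeatureSpec("F2", "processing_presentation", "external_column",
                description="peptide-HLA complex stability (external predictor)"),
    FeatureSpec("F3", "processing_presentation", "external_column",
                description="TAP transport efficiency (external predictor)"),
    FeatureSpec("F4", "processing_presentation", "external_column",
                description="NetCTLpan combined processing score (external predictor)"),
    FeatureSpec("F5", "expression", "external_column",
                description="source gene expression level (external quantification)"),
    FeatureSpec("F6", "tcr_recognition", "local_proxy", _tcr_contact_hydrophobicity,
                "hydrophobicity of TCR contact residues (mean Kyte-Doolittle, positions 4..L-1)"),
    FeatureSpec("F7", "tcr_recognition", "local_proxy", _peptide_hydrophobicity,
                "mean Kyte-Doolittle hydropathy of the full peptide"),
    FeatureSpec("F8", "tcr_recognition", "local_proxy", _net_charge,
                "net charge: count(K,R,H) - count(D,E)"),
    FeatureSpec("F9", "tcr_recognition", "local_proxy", _polar_fraction,
                "fraction of polar residues"),
    FeatureSpec("F10", "tcr_recognition", "local_proxy", _aromatic_fraction,
                "fraction of aromatic residues"),
    FeatureSpec("F11", "tcr_recognition", "local_proxy", _wt_dissimilarity,
                "mutant-vs-wild-type dissimilarity (negated BLOSUM62 substitution score)"),
)


def registry_frame(registry: tuple[FeatureSpec, ...] = DEFAULT_REGISTRY) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": s.name,
                "category": s.category,
                "provenance": s.provenance,
                "description": s.description,
            }
            for s in registry
        ]
    )


@dataclass
class FeatureVector:
    values: dict[str, float]
    provenance: dict[str, str]

    @property
    def complete(self) -> bool:
        return len(self.values) == len(DEFAULT_REGISTRY)


def assemble_features(
    candidate: EpitopeCandidate,
    hla: str,
    external: Mapping[str, float] | None = None,
    registry: tuple[FeatureSpec, ...] = DEFAULT_REGISTRY,
    allow_missing: bool = False,
) -> FeatureVector:
    """Fill the 11-slot feature vector for one candidate.

    Local proxies are computed from the sequence; features declared
    external must be present in ``external`` (keyed by feature name) or a
    :class:`MissingFeatureError` is raised — there is no silent imputation.
    """
    external = external or {}
    values: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for spec in registry:
        if spec.provenance == "local_proxy":
            values[spec.name] = float(spec.compute(candidate))
            provenance[spec.name] = "local_proxy"
        elif spec.name in external:
            values[spec.name] = float(external[spec.name])
            provenance[spec.name] = "external_column"
        elif not allow_missing:
            raise MissingFeatureError(
                f"external feature {spec.name} ({spec.description}) not supplied "
                f"for peptide {candidate.peptide} / {hla}"
            )
    return FeatureVector(values=values, provenance=provenance)


def candidates_frame(
    candidates: list[EpitopeCandidate],
    hla: str,
    features: list[FeatureVector] | None = None,
) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(candidates):
        row = {
            "peptide": c.peptide,
            "hla_allele": hla,
            "protein_id": c.source_variant.protein_id,
            "window_start": c.window_start,
            "mutant_position": c.mutant_position_in_peptide,
        }
        if features is not None:
            row.update(features[i].values)
        rows.append(row)
    return pd.DataFrame(rows)
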