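"""Domain records, table/FASTA/VCF readers and dataset curation.

The unit of analysis is a labeled peptide-HLA pair: a mutant peptide of
8-11 amino acids together with the HLA class-I allele presenting it, an
immunogenicity label, and optionally the wild-type peptide plus eleven
structured immunogenicity features (F1-F11).  Curation enforces the length
window, the amino-acid alphabet, completeness of the mandatory fields, and
uniqueness of each (peptide, allele) pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

FEATURE_NAMES = tuple(f"F{i}" for i in range(1, 12))

LABEL_IMMUNOGENIC = "immunogenic"
LABEL_NON_IMMUNOGENIC = "non_immunogenic"
LABEL_UNKNOWN = "unknown"
VALID_LABELS = frozenset({LABEL_IMMUNOGENIC, LABEL_NON_IMMUNOGENIC, LABEL_UNKNOWN})


class SchemaError(ValueError):
    """A table is missing a mandatory column."""


class NormalizationError(ValueError):
    """An HLA allele string could not be parsed."""


class FastaError(ValueError):
    """Malformed FASTA input (e.g. duplicate identifiers)."""


@dataclass
class PeptideHlaRecord:
    """One labeled peptide-HLA pair with optional structured features."""

    record_id: str
    mutant_peptide: str
    hla_allele: str
    label: str = LABEL_UNKNOWN
    wildtype_peptide: str | None = None
    hla_pseudosequence: str | None = None
    features: dict[str, float] = field(default_factory=dict)
    source: str = ""

    def copy(self) -> "PeptideHlaRecord":
        return replace(self, features=dict(self.features))


@dataclass
class Dataset:
    """Ordered collection of peptide-HLA records with a partition role."""

    records: list[PeptideHlaRecord]
    role: str = "train"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideHlaRecord]:
        return iter(self.records)

    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.label] = counts.get(rec.label, 0) + 1
        return counts

    def labels(self) -> list[str]:
        return [rec.label for rec in self.records]

    def record_ids(self) -> list[str]:
        return [rec.record_id for rec in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row: dict[str, object] = {
                "record_id": rec.record_id,
                "mutant_peptide": rec.mutant_peptide,
                "wildtype_peptide": rec.wildtype_peptide,
                "hla_allele": rec.hla_allele,
                "hla_pseudosequence": rec.hla_pseudosequence,
                "label": rec.label,
                "source": rec.source,
            }
            for name in FEATURE_NAMES:
                if name in rec.features:
                    row[name] = rec.features[name]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class VariantRecord:
    """A protein-level missense variant (1-based coordinates)."""

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    gene: str = ""
    expression: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"ref and alt amino acid are both {self.ref_aa!r}")


MANDATORY_COLUMNS = ("mutant_peptide", "hla_allele", "label")
OPTIONAL_COLUMNS = ("record_id", "wildtype_peptide", "hla_pseudosequence", "source")


def read_peptide_table(path: str | Path, dialect: str = "tsv") -> Dataset:
    """Read a peptide-HLA table (TSV or CSV) into a Dataset.

    Mandatory columns: mutant_peptide, hla_allele, label.  Optional columns
    (record_id, wildtype_peptide, hla_pseudosequence, source, F1..F11)
    become absent fields when missing.  Row order is preserved.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return dataset_from_frame(df, source=str(path))


def dataset_from_frame(df: pd.DataFrame, source: str = "", role: str = "train") -> Dataset:
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        features: dict[str, float] = {}
        for name in FEATURE_NAMES:
            if name in row_d and str(row_d[name]).strip() != "":
                try:
                    features[name] = float(row_d[name])
                except (TypeError, ValueError) as exc:
                    raise ValueError(
                        f"unparseable value for feature {name} at row {i}: "
                        f"{row_d[name]!r}"
                    ) from exc
        rec = PeptideHlaRecord(
            record_id=str(row_d.get("record_id") or f"rec{i}"),
            mutant_peptide=str(row_d["mutant_peptide"]).strip().upper(),
            wildtype_peptide=(str(row_d["wildtype_peptide"]).strip().upper() or None)
            if "wildtype_peptide" in row_d
            else None,
            hla_allele=str(row_d["hla_allele"]).strip(),
            hla_pseudosequence=(str(row_d["hla_pseudosequence"]).strip() or None)
            if "hla_pseudosequence" in row_d
            else None,
            label=str(row_d["label"]).strip(),
            source=str(row_d.get("source", source)),
            features=features,
        )
        records.append(rec)
    return Dataset(records=records, role=role)


def write_peptide_table(dataset: Dataset, path: str | Path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = dataset.to_frame()
    df.to_csv(path, sep=sep, index=False)


# --- HLA normalization --------------------------------------------------

# Accepts e.g. "HLA-A*01:01", "A*01:01", "A0101", "hla-b4402", "B44:02".
# Colon-delimited form: a locus digit (DRB1 etc.) is only a locus digit when
# a '*' follows, so "B44:02" parses as locus B, group 44.
_HLA_RE = re.compile(
    r"^(?:HLA-?)?([A-Z]+(?:[0-9](?=\*))?)\s*\*?\s*([0-9]{1,3}):([0-9]{1,3})$",
    re.IGNORECASE,
)


def normalize_hla(raw: str) -> str:
    """Canonicalize an HLA class-I allele string to HLA-<locus>*<gg>:<pp>.

    Handles common alias spellings (missing prefix, missing separators,
    lowercase).  Idempotent on already-canonical names.
    """
    if raw is None or not str(raw).strip():
        raise NormalizationError("empty HLA allele string")
    s = str(raw).strip().replace(" ", "")
    m = _HLA_RE.match(s)
    if m is None:
        # Undelimited digit runs like "A0101" or "B44021" need a split point.
        m2 = re.match(r"^(?:HLA-?)?([A-Z]+[0-9]?)\*?([0-9]{4,6})$", s, re.IGNORECASE)
        if m2 is None:
            raise NormalizationError(f"cannot parse HLA allele {raw!r}")
        locus, digits = m2.group(1), m2.group(2)
        split = 2 if len(digits) in (4, 5) else 3
        group, protein = digits[:split], digits[split:]
    else:
        locus, group, protein = m.group(1), m.group(2), m.group(3)
    locus = locus.upper()
    return f"HLA-{locus}*{int(group):02d}:{int(protein):02d}"


# --- Curation -----------------------------------------------------------

@dataclass
class CurationReport:
    """Per-rule removal counts from one curation pass."""

    n_input: int = 0
    n_output: int = 0
    removed_incomplete: int = 0
    removed_bad_alphabet: int = 0
    removed_bad_length: int = 0
    removed_duplicate: int = 0
    label_conflicts: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("input", self.n_input),
                ("output", self.n_output),
                ("incomplete", self.removed_incomplete),
                ("bad_alphabet", self.removed_bad_alphabet),
                ("bad_length", self.removed_bad_length),
                ("duplicate", self.removed_duplicate),
                ("label_conflict", self.label_conflicts),
            ],
            columns=["rule", "count"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def curate(
    dataset: Dataset,
    min_length: int = 8,
    max_length: int = 11,
) -> tuple[Dataset, CurationReport]:
    """Filter a dataset down to valid, unique peptide-HLA pairs.

    Rules, applied in order per record: completeness of
    mutant_peptide/hla_allele/label; amino-acid alphabet; length in
    [min_length, max_length]; first occurrence of each
    (mutant_peptide, canonical hla_allele) pair wins.  Relative order is
    preserved and curation never raises on record content.
    """
    report = CurationReport(n_input=len(dataset))
    seen: dict[tuple[str, str], str] = {}
    kept: list[PeptideHlaRecord] = []
    for rec in dataset:
        pep = (rec.mutant_peptide or "").strip().upper()
        if not pep or not (rec.hla_allele or "").strip() or rec.label not in (
            LABEL_IMMUNOGENIC,
            LABEL_NON_IMMUNOGENIC,
        ):
            report.removed_incomplete += 1
            continue
        if not set(pep) <= _AA_SET:
            report.removed_bad_alphabet += 1
            continue
        if not (min_length <= len(pep) <= max_length):
            report.removed_bad_length += 1
            continue
        try:
            allele = normalize_hla(rec.hla_allele)
        except NormalizationError:
            report.removed_incomplete += 1
            continue
        key = (pep, allele)
        if key in seen:
            report.removed_duplicate += 1
            if seen[key] != rec.label:
                report.label_conflicts += 1
            continue
        seen[key] = rec.label
        out = rec.copy()
        out.mutant_peptide = pep
        out.hla_allele = allele
        kept.append(out)
    report.n_output = len(kept)
    return Dataset(records=kept, role=dataset.role), report


# --- FASTA / variants ---------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into {id: uppercase sequence}.

    The ID is the first whitespace-delimited token of the header.
    Duplicate IDs are an error.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FastaError(f"duplicate FASTA identifier {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return sequences


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read protein-level missense variants from a TSV/CSV table.

    Mandatory columns: protein_id, position, ref_aa, alt_aa.  Optional:
    gene, expression.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("protein_id", "position", "ref_aa", "alt_aa"):
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    variants = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        expr = d.get("expression", "")
        variants.append(
            VariantRecord(
                protein_id=d["protein_id"],
                position=int(d["position"]),
                ref_aa=d["ref_aa"].upper(),
                alt_aa=d["alt_aa"].upper(),
                gene=d.get("gene", ""),
                expression=float(expr) if str(expr).strip() else None,
            )
        )
    return variants


_CSQ_RE = re.compile(r"([A-Za-z0-9_.\-]+)\|(\d+)\|([A-Z])\|([A-Z])")


def read_vcf_variants(path: str | Path, csq_tag: str = "PCSQ") -> list[VariantRecord]:
    """Minimal VCF reader for protein-consequence-annotated SNVs.

    Expects the fixed columns CHROM/POS/ID/REF/ALT/QUAL/FILTER/INFO and a
    required INFO tag (default ``PCSQ``) of the form
    ``protein_id|protein_pos|ref_aa|alt_aa``.  Rows lacking the tag are
    skipped; this is deliberately a plumbing-grade reader, not an annotator.
    """
    variants: list[VariantRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                continue
            info = fields[7]
            for entry in info.split(";"):
                if "=" not in entry:
                    continue
                tag, value = entry.split("=", 1)
                if tag != csq_tag:
                    continue
                m = _CSQ_RE.match(value)
                if m is None:
                    raise ValueError(
                        f"malformed {csq_tag} tag {value!r}; expected "
                        "protein_id|pos|ref|alt"
                    )
                variants.append(
                    VariantRecord(
                        protein_id=m.group(1),
                        position=int(m.group(2)),
                        ref_aa=m.group(3),
                        alt_aa=m.group(4),
                    )
                )
    return variants
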