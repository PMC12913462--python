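"""Sequence encoders: k-mer slicing, TF-IDF, one-hot, contextual embeddings.

Every encoder turns peptide-HLA records into a numeric design matrix
(`EncodedMatrix`) or a list of per-record token-level matrices
(`TokenMatrixBatch`), aligned to record order.  The peptide and the HLA
representation are merged with an explicit separator so that k-mers
spanning the boundary stay distinct tokens rather than chimeric
amino-acid words.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .records_io import PeptideHlaRecord

DEFAULT_SEPARATOR = "|"


class TokenizationError(ValueError):
    pass


class EncodingError(ValueError):
    pass


@dataclass
class KmerTokenization:
    """Stride-1 k-mer decomposition of one merged peptide-HLA string."""

    k: int
    merge_separator: str
    tokens: list[str]
    record_id: str = ""

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class EncodedMatrix:
    """Design matrix (n_records x n_dims) aligned to record order.

    ``values`` may be a dense ndarray or a scipy sparse matrix; both expose
    shape and matrix products.  ``role`` carries the dataset partition tag
    so downstream steps can enforce train-only fitting.
    """

    values: object
    row_ids: list[str]
    encoder_tag: str
    role: str | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if hasattr(v, "toarray") else np.asarray(v)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.dense(), index=self.row_ids).to_csv(
            path, sep="\t", header=False
        )


@dataclass
class TokenMatrixBatch:
    """Per-record token-level embedding matrices (variable token counts)."""

    matrices: list[np.ndarray]
    row_ids: list[str]
    encoder_tag: str
    dimension: int
    role: str | None = None

    def __len__(self) -> int:
        return len(self.matrices)

    def padded(self, max_tokens: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Zero-pad to (n, T, d); returns (tensor, lengths)."""
        lengths = np.array([m.shape[0] for m in self.matrices], dtype=int)
        T = int(max_tokens if max_tokens is not None else lengths.max())
        out = np.zeros((len(self.matrices), T, self.dimension), dtype=np.float64)
        for i, m in enumerate(self.matrices):
            t = min(m.shape[0], T)
            out[i, :t] = m[:t]
        return out, np.minimum(lengths, T)


def merged_string(
    record: PeptideHlaRecord,
    hla_repr: str = "allele_name",
    separator: str = DEFAULT_SEPARATOR,
) -> str:
    if hla_repr == "allele_name":
        hla = record.hla_allele
    elif hla_repr == "pseudosequence":
        if not record.hla_pseudosequence:
            raise EncodingError(
                f"record {record.record_id!r} has no HLA pseudo-sequence"
            )
        hla = record.hla_pseudosequence
    else:
        raise ValueError(f"unknown hla_repr {hla_repr!r}")
    return f"{record.mutant_peptide}{separator}{hla}"


def merge_and_slice(
    record: PeptideHlaRecord,
    k: int,
    hla_repr: str = "allele_name",
    separator: str = DEFAULT_SEPARATOR,
) -> KmerTokenization:
    """Merge peptide + HLA and slice into all stride-1 windows of length k."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    merged = merged_string(record, hla_repr=hla_repr, separator=separator)
    if len(merged) < k:
        raise TokenizationError(
            f"merged string of length {len(merged)} is shorter than k={k}"
        )
    tokens = [merged[i : i + k] for i in range(len(merged) - k + 1)]
    return KmerTokenization(
        k=k, merge_separator=separator, tokens=tokens, record_id=record.record_id
    )


def tokenize_dataset(
    records: Iterable[PeptideHlaRecord],
    k: int,
    hla_repr: str = "allele_name",
    separator: str = DEFAULT_SEPARATOR,
) -> list[KmerTokenization]:
    return [merge_and_slice(r, k, hla_repr=hla_repr, separator=separator) for r in records]


# --- TF-IDF -------------------------------------------------------------

@dataclass
class TfidfModel:
    """Fitted TF-IDF weighting over a k-mer vocabulary.

    Dialect: raw term counts, smoothed idf ln((1+N)/(1+df)) + 1, row-wise
    l2 normalization.  Out-of-vocabulary tokens are ignored at transform
    time.
    """

    vectorizer: TfidfVectorizer
    norm: str = "l2"

    @property
    def vocabulary(self) -> dict[str, int]:
        return dict(self.vectorizer.vocabulary_)

    @property
    def idf(self) -> np.ndarray:
        return np.asarray(self.vectorizer.idf_)

    @property
    def n_dims(self) -> int:
        return len(self.vectorizer.vocabulary_)


def fit_tfidf(corpus: Sequence[KmerTokenization], norm: str = "l2") -> TfidfModel:
    if len(corpus) == 0:
        raise ValueError("cannot fit TF-IDF on an empty corpus")
    vec = TfidfVectorizer(
        analyzer=lambda doc: doc.tokens,
        lowercase=False,
        norm=None if norm == "none" else norm,
        smooth_idf=True,
        sublinear_tf=False,
    )
    vec.fit(list(corpus))
    return TfidfModel(vectorizer=vec, norm=norm)


def transform_tfidf(
    model: TfidfModel,
    docs: Sequence[KmerTokenization],
    role: str | None = None,
) -> EncodedMatrix:
    X = model.vectorizer.transform(list(docs))
    return EncodedMatrix(
        values=X,
        row_ids=[d.record_id for d in docs],
        encoder_tag=f"tfidf-{docs[0].k if docs else '?'}mer",
        role=role,
    )


# --- One-hot ------------------------------------------------------------

def one_hot(
    seq: str,
    alphabet: Sequence[str] = tuple("ACDEFGHIKLMNPQRSTVWY"),
) -> EncodedMatrix:
    """One-hot encode a sequence: (L x |alphabet|), one 1 per row."""
    index = {sym: i for i, sym in enumerate(alphabet)}
    out = np.zeros((len(seq), len(alphabet)), dtype=np.float64)
    for pos, sym in enumerate(seq):
        if sym not in index:
            raise EncodingError(f"unknown symbol {sym!r} at position {pos + 1}")
        out[pos, index[sym]] = 1.0
    return EncodedMatrix(values=out, row_ids=[seq], encoder_tag="one_hot")


# --- Contextual embeddings ---------------------------------------------

class ContextualEmbedder(Protocol):
    """A fixed (non-trainable) token embedder.

    Contract: deterministic — the same token sequence must always map to
    the identical embedding matrix of shape (n_tokens, dimension).
    """

    name: str
    dimension: int

    def embed_tokens(self, tokens: Sequence[str]) -> np.ndarray: ...


@dataclass
class DeterministicStubEmbedder:
    """Hash-seeded stand-in for a pre-trained contextual embedder.

    Each distinct token string maps to a fixed pseudo-random unit-variance
    vector derived from a BLAKE2 digest of the token, so embeddings are
    bitwise-reproducible across processes with no model download.  Useful
    as the default offline embedder; a real transformer checkpoint can be
    plugged in through the same interface.
    """

    dimension: int = 32
    name: str = "stub"
    _cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def embed_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        out = np.empty((len(tokens), self.dimension), dtype=np.float64)
        for i, tok in enumerate(tokens):
            vec = self._cache.get(tok)
            if vec is None:
                digest = hashlib.blake2b(
                    tok.encode(), digest_size=8, person=b"peptigen"
                ).digest()
                rng = np.random.default_rng(int.from_bytes(digest, "little"))
                vec = rng.standard_normal(self.dimension)
                self._cache[tok] = vec
            out[i] = vec
        return out


def get_embedder(spec: str = "stub", dimension: int = 32) -> ContextualEmbedder:
    """Resolve an embedder config key (``stub`` | ``pretrained:<path>``)."""
    if spec == "stub":
        return DeterministicStubEmbedder(dimension=dimension)
    if spec.startswith("pretrained:"):
        raise NotImplementedError(
            "pretrained transformer adapters require an external checkpoint "
            "and the transformers runtime; plug in any object satisfying the "
            "ContextualEmbedder protocol instead"
        )
    raise ValueError(f"unknown embedder spec {spec!r}")


def embed(
    tokenizations: Sequence[KmerTokenization],
    embedder: ContextualEmbedder,
    pooling: str = "none",
    max_tokens: int | None = None,
    role: str | None = None,
) -> EncodedMatrix | TokenMatrixBatch:
    """Embed token sequences; pool to one row per record or keep token level.

    ``pooling='none'`` returns a TokenMatrixBatch for convolutional models;
    ``'mean'``/``'cls'`` return an EncodedMatrix with one row per record.
    Sequences longer than ``max_tokens`` are truncated (reported via the
    returned object's lengths, never silently mid-token).
    """
    matrices: list[np.ndarray] = []
    for tk in tokenizations:
        tokens = tk.tokens
        if max_tokens is not None and len(tokens) > max_tokens:
            tokens = tokens[:max_tokens]
        matrices.append(embedder.embed_tokens(tokens))
    row_ids = [tk.record_id for tk in tokenizations]
    tag = f"{embedder.name}-{tokenizations[0].k if tokenizations else '?'}mer"
    if pooling == "none":
        return TokenMatrixBatch(
            matrices=matrices,
            row_ids=row_ids,
            encoder_tag=tag,
            dimension=embedder.dimension,
            role=role,
        )
    if pooling == "mean":
        pooled = np.vstack([m.mean(axis=0) for m in matrices])
    elif pooling == "cls":
        pooled = np.vstack([m[0] for m in matrices])
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return EncodedMatrix(
        values=pooled, row_ids=row_ids, encoder_tag=f"{tag}-{pooling}", role=role
    )
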