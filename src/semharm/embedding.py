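"""Pluggable sentence-embedding backends and similarity matrices.

Two backends implement one contract:

* :class:`ReferenceBackend` wraps the published ``all-mpnet-base-v2``
  sentence-transformer (768-dimensional).  Its absence is a hard
  :class:`BackendUnavailableError` — never a silent fallback — so that
  offline runs are explicit about what they computed.
* :class:`MockEmbeddingBackend` is a fully deterministic, dependency-free
  stand-in: texts are reduced to hashed token-count vectors and pushed
  through a seeded random projection, so texts sharing more tokens have
  higher expected cosine.  It makes every pipeline stage testable offline
  with known ground truth.

Similarity matrices are dense (a hundred items is tiny); sparsification is
a separate, explicit step in :mod:`semharm.backbone`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .item_bank import ItemBank

__all__ = [
    "EmbeddingError",
    "BackendUnavailableError",
    "EmbeddingBackend",
    "MockEmbeddingBackend",
    "ReferenceBackend",
    "EmbeddingMatrix",
    "SimilarityMatrix",
    "embed_texts",
    "embed_bank",
    "mock_embed",
    "cosine",
    "item_similarity_matrix",
    "scale_centroid_matrix",
    "write_similarity_tsv",
    "read_similarity_tsv",
]

NORMALIZATIONS = ("raw_cosine", "clip01", "affine01")

REFERENCE_MODEL_ID = "sentence-transformers/all-mpnet-base-v2"


class EmbeddingError(ValueError):
    pass


class BackendUnavailableError(EmbeddingError):
    """The requested embedding backend cannot run in this environment."""


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Contract: a deterministic map from text to a fixed-width vector."""

    backend_id: str
    dimension: int
    deterministic: bool

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover
        ...


def _token_slot(token: str, n_slots: int) -> int:
    # stable across processes and platforms (unlike builtin hash())
    digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big") % n_slots


class MockEmbeddingBackend:
    """Seeded random-projection bag-of-words embedder.

    Tokens (lowercased, split on non-alphanumerics) are hashed into a fixed
    slot space; the count vector is projected by an ``n_slots x dimension``
    Gaussian matrix generated from ``seed`` only, then L2-normalized.  Same
    seed + dimension + text => bitwise-identical vector in any process.
    """

    def __init__(self, seed: int = 0, dimension: int = 256, n_slots: int = 4096):
        if dimension < 8:
            raise EmbeddingError("mock backend requires dimension >= 8")
        self.seed = int(seed)
        self.dimension = int(dimension)
        self.n_slots = int(n_slots)
        self.deterministic = True
        self.backend_id = f"mock(seed={self.seed},d={self.dimension})"
        rng = np.random.default_rng(self.seed)
        self._projection = rng.standard_normal((self.n_slots, self.dimension)) / np.sqrt(
            self.dimension
        )

    @staticmethod
    def tokenize(text: str) -> list[str]:
        out, cur = [], []
        for ch in text.lower():
            if ch.isalnum():
                cur.append(ch)
            elif cur:
                out.append("".join(cur))
                cur = []
        if cur:
            out.append("".join(cur))
        return out

    def _counts(self, text: str) -> np.ndarray:
        v = np.zeros(self.n_slots)
        for tok in self.tokenize(text):
            v[_token_slot(tok, self.n_slots)] += 1.0
        return v

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        counts = np.stack([self._counts(t) for t in texts])
        vecs = counts @ self._projection
        norms = np.linalg.norm(vecs, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise EmbeddingError(
                f"text at position {bad[0]} has no tokens to embed"
            )
        return vecs / norms[:, None]


def mock_embed(text: str, seed: int, dimension: int) -> np.ndarray:
    """One-shot convenience wrapper around :class:`MockEmbeddingBackend`."""
    return MockEmbeddingBackend(seed=seed, dimension=dimension).embed([text])[0]


class ReferenceBackend:
    """The published 768-d sentence-transformer, pinned by model id.

    Requires the ``sentence-transformers`` package and the downloaded model
    weights; constructing the backend without them raises
    :class:`BackendUnavailableError`.
    """

    def __init__(self, model_id: str = REFERENCE_MODEL_ID, revision: str | None = None):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # explicit, never a silent mock substitution
            raise BackendUnavailableError(
                f"reference backend {model_id!r} needs the sentence-transformers "
                "package, which is not installed; use MockEmbeddingBackend for "
                "offline runs"
            ) from exc
        self._model = SentenceTransformer(model_id, revision=revision)
        self.backend_id = model_id if revision is None else f"{model_id}@{revision}"
        self.dimension = int(self._model.get_sentence_embedding_dimension())
        self.deterministic = True

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        return np.asarray(self._model.encode(list(texts), convert_to_numpy=True), float)


@dataclass(frozen=True)
class EmbeddingMatrix:
    """n x d embedding rows keyed by item (or construct) ids, in input order."""

    ids: tuple[str, ...]
    vectors: np.ndarray
    backend_id: str

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise EmbeddingError("vectors must be one row per id")
        if not np.all(np.isfinite(self.vectors)):
            raise EmbeddingError("embedding contains non-finite values")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity table over items or scales.

    ``normalization`` records the map applied to raw cosines:
    ``raw_cosine`` (identity, range [-1, 1]), ``clip01`` (max(0, cos)) or
    ``affine01`` ((cos + 1) / 2).  Diagonal entries may be NaN only for
    scale-level matrices where within-scale consistency is undefined
    (single-item scales).
    """

    ids: tuple[str, ...]
    values: np.ndarray
    normalization: str = "clip01"

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise EmbeddingError("similarity matrix must be square over ids")
        offdiag = ~np.eye(n, dtype=bool)
        if not np.allclose(self.values, self.values.T, atol=1e-9, equal_nan=True):
            raise EmbeddingError("similarity matrix must be symmetric")
        vals = self.values[offdiag]
        if self.normalization == "raw_cosine":
            lo, hi = -1.0, 1.0
        elif self.normalization in ("clip01", "affine01"):
            lo, hi = 0.0, 1.0
        else:
            raise EmbeddingError(f"unknown normalization {self.normalization!r}")
        if vals.size and (np.nanmin(vals) < lo - 1e-9 or np.nanmax(vals) > hi + 1e-9):
            raise EmbeddingError(
                f"values out of range for normalization {self.normalization!r}"
            )

    def loc(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


def embed_texts(texts: Sequence[str], backend: EmbeddingBackend,
                ids: Sequence[str] | None = None) -> EmbeddingMatrix:
    """Embed texts in order; empty texts are rejected by position."""
    for i, t in enumerate(texts):
        if not t or not t.strip():
            raise EmbeddingError(f"text at position {i} is empty")
    vectors = backend.embed(list(texts))
    if ids is None:
        ids = tuple(str(i) for i in range(len(texts)))
    return EmbeddingMatrix(ids=tuple(ids), vectors=vectors, backend_id=backend.backend_id)


def embed_bank(bank: ItemBank, backend: EmbeddingBackend) -> EmbeddingMatrix:
    """Embed every item's ``clean_text`` (bank must be preprocessed first)."""
    texts = [it.clean_text for it in bank]
    for it, t in zip(bank, texts):
        if not t:
            raise EmbeddingError(f"{it.item_id}: clean_text is empty; "
                                 "run preprocess_bank first")
    return embed_texts(texts, backend, ids=bank.item_ids)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise EmbeddingError("cosine undefined for zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))


def _apply_normalization(raw: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "raw_cosine":
        return raw
    if normalization == "clip01":
        return np.maximum(raw, 0.0)
    if normalization == "affine01":
        return (raw + 1.0) / 2.0
    raise EmbeddingError(f"unknown normalization {normalization!r}")


def _raw_cosine_matrix(vectors: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise EmbeddingError(f"zero-norm vector for id {ids[bad[0]]!r}")
    unit = vectors / norms[:, None]
    raw = unit @ unit.T
    raw = (raw + raw.T) / 2.0  # exact symmetry
    return np.clip(raw, -1.0, 1.0)


def item_similarity_matrix(emb: EmbeddingMatrix,
                           normalization: str = "clip01") -> SimilarityMatrix:
    """Pairwise cosine similarity of all items, mapped to the stated range."""
    raw = _raw_cosine_matrix(emb.vectors, emb.ids)
    values = _apply_normalization(raw, normalization)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=emb.ids, values=values, normalization=normalization)


def scale_centroid_matrix(emb: EmbeddingMatrix, bank: ItemBank,
                          normalization: str = "clip01") -> SimilarityMatrix:
    """Scale-level similarity: centroid cosines off-diagonal, within-scale
    consistency on the diagonal.

    The diagonal entry for scale *s* is the mean cosine over all unordered
    item pairs inside *s* (self-pairs excluded) — a coherence measure that
    is generally below 1.  Scales with a single item get a NaN diagonal.
    """
    if emb.ids != bank.item_ids:
        raise EmbeddingError("embedding ids do not match bank item ids")
    scales = bank.scales
    idx = {s: [i for i, it in enumerate(bank) if it.scale_id == s] for s in scales}
    for s, rows in idx.items():
        if not rows:
            raise EmbeddingError(f"scale {s!r} has zero items")
    raw_items = _raw_cosine_matrix(emb.vectors, emb.ids)
    centroids = np.stack([emb.vectors[idx[s]].mean(axis=0) for s in scales])
    raw = _raw_cosine_matrix(centroids, scales)
    for d, s in enumerate(scales):
        rows = idx[s]
        if len(rows) < 2:
            raw[d, d] = np.nan
            continue
        block = raw_items[np.ix_(rows, rows)]
        iu = np.triu_indices(len(rows), k=1)
        raw[d, d] = block[iu].mean()
    values = _apply_normalization(raw, normalization)
    return SimilarityMatrix(ids=scales, values=values, normalization=normalization)


def write_similarity_tsv(sim: SimilarityMatrix, path: str | Path) -> None:
    """TSV with an id header row and a leading id column."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(sim.ids) + "\n")
        for i, rid in enumerate(sim.ids):
            row = "\t".join(repr(float(v)) for v in sim.values[i])
            fh.write(f"{rid}\t{row}\n")


def read_similarity_tsv(path: str | Path,
                        normalization: str = "clip01") -> SimilarityMatrix:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    ids = tuple(lines[0].split("\t")[1:])
    values = np.array(
        [[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]]
    )
    return SimilarityMatrix(ids=ids, values=values, normalization=normalization)
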