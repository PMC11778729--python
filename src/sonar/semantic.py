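"""Semantic embeddings of variable descriptions via pluggable backends.

The method consumes fixed-dimension vector representations of cleaned variable
descriptions.  In production these come from pretrained biomedical language
models (CODER, SapBERT, with BioBERT as a benchmark); here a backend is any
object satisfying :class:`EmbeddingBackend` — a name, a fixed output dimension
and a deterministic ``embed``.  The package ships
:class:`HashedLexicalBackend`, a deterministic character n-gram embedder with
no model weights, so the full pipeline (and its tests) runs self-contained;
transformer-based adapters can be plugged in wherever their weights are
available.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .errors import BackendError, ValidationError


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Deterministic text -> vector contract.

    Same input string must always yield the same vector, and the output
    dimension is constant.
    """

    name: str
    dimension: int

    def embed(self, texts: Sequence[str]) -> np.ndarray: ...


class HashedLexicalBackend:
    """Deterministic lexical embedder: hashed character n-grams, TF weights,
    seeded random-sign projection, L2 normalization.

    Character 3-5-grams of the lower-cased, whitespace-collapsed text are
    hashed (CRC32) into a fixed feature space, weighted by term frequency,
    projected to ``dimension`` by a seeded +/-1 matrix and L2-normalized.
    Empty text maps to the zero vector.  Deterministic given
    ``(texts, dimension, seed)``; two backends with different seeds give
    unrelated projections and serve as distinct "models".
    """

    N_FEATURES = 1 << 16

    def __init__(
        self,
        name: str = "lexical",
        dimension: int = 256,
        seed: int = 0,
        ngram_range: tuple[int, int] = (3, 5),
    ):
        if dimension < 8:
            raise ValidationError("embedding dimension must be at least 8")
        self.name = name
        self.dimension = int(dimension)
        self.seed = int(seed)
        self.ngram_range = ngram_range
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x53]))
        # int8 keeps the projection table small; slices are cast on use
        self._signs = (
            rng.integers(0, 2, size=(self.N_FEATURES, self.dimension)).astype(np.int8)
            * 2
            - 1
        )
        self._cache: dict[str, np.ndarray] = {}

    def _vector(self, text: str) -> np.ndarray:
        canonical = re.sub(r"\s+", " ", text.lower()).strip()
        if canonical in self._cache:
            return self._cache[canonical]
        if not canonical:
            vector = np.zeros(self.dimension)
            self._cache[canonical] = vector
            return vector
        padded = f" {canonical} "
        counts: dict[int, float] = {}
        total = 0
        lo, hi = self.ngram_range
        for n in range(lo, hi + 1):
            for i in range(len(padded) - n + 1):
                idx = zlib.crc32(padded[i : i + n].encode("utf-8")) % self.N_FEATURES
                counts[idx] = counts.get(idx, 0.0) + 1.0
                total += 1
        indices = np.fromiter(counts.keys(), dtype=np.int64, count=len(counts))
        weights = np.fromiter(counts.values(), dtype=np.float64, count=len(counts))
        weights /= total
        vector = self._signs[indices].astype(np.float64).T @ weights
        norm = np.linalg.norm(vector)
        if norm > 0:
            vector = vector / norm
        self._cache[canonical] = vector
        return vector

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        return np.stack([self._vector(t) for t in texts]) if len(texts) else (
            np.empty((0, self.dimension))
        )


def fallback_lexical_embed(
    texts: Sequence[str], dimension: int, seed: int
) -> np.ndarray:
    """One-shot lexical embedding of ``texts`` (see :class:`HashedLexicalBackend`)."""
    return HashedLexicalBackend(
        name=f"lexical-{dimension}", dimension=dimension, seed=seed
    ).embed(texts)


@dataclass
class EmbeddingSet:
    """Per-variable vectors from one backend."""

    backend_name: str
    dimension: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def matrix(self, accessions: Sequence[str]) -> np.ndarray:
        return np.stack([self.vectors[a] for a in accessions])


def embed_descriptions(records, backend: EmbeddingBackend) -> EmbeddingSet:
    """Embed every record's cleaned description with one backend.

    Identical cleaned descriptions are embedded once and share a vector
    (the backend's determinism contract makes this a pure cache).
    """
    texts = sorted({r.description_clean for r in records})
    try:
        matrix = np.asarray(backend.embed(texts), dtype=float)
    except Exception as exc:  # pragma: no cover - exercised via error contract test
        raise BackendError(
            f"backend {backend.name!r} failed on a batch of {len(texts)} texts"
        ) from exc
    if matrix.shape != (len(texts), backend.dimension):
        raise BackendError(
            f"backend {backend.name!r} returned shape {matrix.shape}, "
            f"expected {(len(texts), backend.dimension)}"
        )
    by_text = {text: matrix[i] for i, text in enumerate(texts)}
    return EmbeddingSet(
        backend_name=backend.name,
        dimension=backend.dimension,
        vectors={
            r.variable_accession: by_text[r.description_clean] for r in records
        },
    )


def default_backends(dimension: int = 256) -> dict[str, HashedLexicalBackend]:
    """The three deterministic stand-in backends used throughout the package.

    Distinct seeds give independent projections, playing the roles of the two
    fused semantic models ("coder", "sapbert") and the benchmark ("biobert").
    """
    return {
        "coder": HashedLexicalBackend("coder", dimension, seed=101),
        "sapbert": HashedLexicalBackend("sapbert", dimension, seed=202),
        "biobert": HashedLexicalBackend("biobert", dimension, seed=303),
    }


def write_embeddings(embeddings: EmbeddingSet, path) -> None:
    """Export to delimited text; the comment header carries name and dimension."""
    accessions = sorted(embeddings.vectors)
    frame = pd.DataFrame(
        [embeddings.vectors[a] for a in accessions],
        index=pd.Index(accessions, name="variable_accession"),
        columns=[f"c{i}" for i in range(embeddings.dimension)],
    )
    with open(path, "w") as handle:
        handle.write(
            f"#backend={embeddings.backend_name} dimension={embeddings.dimension}\n"
        )
        frame.to_csv(handle, float_format="%.12g")


def read_embeddings(path) -> EmbeddingSet:
    with open(path) as handle:
        header = handle.readline().strip()
        match = re.match(r"#backend=(\S+) dimension=(\d+)", header)
        if not match:
            raise ValidationError(
                f"embedding file {path} lacks the '#backend=... dimension=...' header"
            )
        frame = pd.read_csv(handle, index_col="variable_accession")
    name, dimension = match.group(1), int(match.group(2))
    if frame.shape[1] != dimension:
        raise ValidationError(
            f"embedding file {path} has {frame.shape[1]} components, "
            f"header says {dimension}"
        )
    return EmbeddingSet(
        backend_name=name,
        dimension=dimension,
        vectors={str(a): row.to_numpy(dtype=float) for a, row in frame.iterrows()},
    )
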