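"""Embedded, ID-addressable record store with integrity validation.

Each record's ``record_text`` is embedded once (in batches) and stored
under its unique id. Retrieval is *exact*: a lookup returns the payload
for that id or fails — there is deliberately no similarity fallback, so a
screening call can never be fed a near-duplicate of the intended record.
Validation compares the id sets of a dataset and an index and reports any
missing or extra documents.

The default embedder is a deterministic hash-based pseudo-embedding
(fixed dimension 64, no network), which makes the whole pipeline testable
offline; live embedding services plug in behind the same two-method
contract (``dim`` attribute + ``embed_batch``).
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import EmbeddingError, RecordNotFoundError
from .records import ReviewDataset

__all__ = [
    "Embedder",
    "HashEmbedder",
    "IndexConfig",
    "ValidationReport",
    "EmbeddedIndex",
    "embed_corpus",
    "fetch_by_id",
    "validate_index",
]


@runtime_checkable
class Embedder(Protocol):
    """Anything that maps a batch of texts to fixed-dimension vectors."""

    dim: int

    def embed_batch(self, texts: Sequence[str]) -> np.ndarray:  # (n, dim)
        ...


class HashEmbedder:
    """Deterministic offline pseudo-embedder.

    Vectors are derived from a SHAKE-128 digest of the text, scaled to
    [0, 1). Not semantically meaningful — it exists so that indexing,
    persistence and exact-ID retrieval are exercisable with no network.
    """

    name = "hash64"

    def __init__(self, dim: int = 64) -> None:
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim

    def embed_batch(self, texts: Sequence[str]) -> np.ndarray:
        out = np.empty((len(texts), self.dim), dtype=np.float64)
        for i, text in enumerate(texts):
            digest = hashlib.shake_128(text.encode("utf-8")).digest(4 * self.dim)
            words = np.frombuffer(digest, dtype="<u4").astype(np.float64)
            out[i] = words / 2.0**32
        return out


@dataclass
class IndexConfig:
    """Indexing knobs; batch_size 100 matches typical embedding-API batching."""

    batch_size: int = 100
    embedder_name: str = "hash64"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class ValidationReport:
    missing_ids: set[str] = field(default_factory=set)
    extra_ids: set[str] = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return not self.missing_ids and not self.extra_ids


class EmbeddedIndex:
    """In-memory exact-ID index with lossless directory persistence."""

    def __init__(self, dim: int, embedder_name: str = "hash64") -> None:
        self.dim = dim
        self.embedder_name = embedder_name
        self._payloads: dict[str, str] = {}
        self._metadata: dict[str, dict] = {}
        self._vectors: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self._payloads)

    def ids(self) -> set[str]:
        return set(self._payloads)

    def add(self, record_id: str, vector: np.ndarray, payload: str, metadata: dict | None = None) -> None:
        vector = np.asarray(vector, dtype=np.float64)
        if vector.shape != (self.dim,):
            raise ValueError(f"vector shape {vector.shape} != ({self.dim},)")
        self._vectors[record_id] = vector
        self._payloads[record_id] = payload
        self._metadata[record_id] = dict(metadata or {})

    def fetch(self, record_id: str) -> str:
        """Exact payload for ``record_id``; unknown ids raise, never fall back."""
        try:
            return self._payloads[record_id]
        except KeyError:
            raise RecordNotFoundError(record_id) from None

    def vector(self, record_id: str) -> np.ndarray:
        try:
            return self._vectors[record_id]
        except KeyError:
            raise RecordNotFoundError(record_id) from None

    # -- persistence: vectors file + JSON manifest, atomic via tmp+rename --

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ids = sorted(self._payloads)
        vectors = np.stack([self._vectors[i] for i in ids]) if ids else np.empty((0, self.dim))
        manifest = {
            "dim": self.dim,
            "embedder_name": self.embedder_name,
            "ids": ids,
            "payloads": {i: self._payloads[i] for i in ids},
            "metadata": {i: self._metadata[i] for i in ids},
        }
        def _write_vectors(p: str) -> None:
            with open(p, "wb") as fh:  # np.save appends .npy to bare paths
                np.save(fh, vectors)

        for name, writer in (
            ("vectors.npy", _write_vectors),
            ("manifest.json", lambda p: Path(p).write_text(json.dumps(manifest), encoding="utf-8")),
        ):
            fd, tmp = tempfile.mkstemp(dir=directory, prefix=name, suffix=".tmp")
            os.close(fd)
            try:
                writer(tmp)
                os.replace(tmp, directory / name)
            finally:
                if os.path.exists(tmp):
                    os.unlink(tmp)

    @classmethod
    def load(cls, directory: str | Path) -> "EmbeddedIndex":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
        vectors = np.load(directory / "vectors.npy")
        index = cls(dim=manifest["dim"], embedder_name=manifest["embedder_name"])
        for row, record_id in enumerate(manifest["ids"]):
            index.add(
                record_id,
                vectors[row],
                manifest["payloads"][record_id],
                manifest["metadata"].get(record_id),
            )
        return index


def embed_corpus(
    dataset: ReviewDataset,
    embedder: Embedder | None = None,
    config: IndexConfig | None = None,
) -> EmbeddedIndex:
    """Embed every record's text in batches and build an exact-ID index.

    A failing embedding batch raises
    :class:`~abscreen.errors.EmbeddingError` carrying the record ids of the
    affected batch, so a caller can retry just that batch.
    """
    embedder = embedder or HashEmbedder()
    config = config or IndexConfig(embedder_name=getattr(embedder, "name", "custom"))
    index = EmbeddedIndex(dim=embedder.dim, embedder_name=config.embedder_name)
    records = dataset.records
    for start in range(0, len(records), config.batch_size):
        batch = records[start : start + config.batch_size]
        texts = [r.record_text for r in batch]
        try:
            vectors = embedder.embed_batch(texts)
        except Exception as exc:  # noqa: BLE001 — re-raised with batch context
            raise EmbeddingError(
                f"embedding batch starting at {start} failed: {exc}",
                record_ids=[r.record_id for r in batch],
            ) from exc
        for record, vector in zip(batch, np.asarray(vectors)):
            index.add(
                record.record_id,
                vector,
                record.record_text,
                {"title": record.title},
            )
    return index


def fetch_by_id(index: EmbeddedIndex, record_id: str) -> str:
    """Exact-ID retrieval of a record's text."""
    return index.fetch(record_id)


def validate_index(dataset: ReviewDataset, index: EmbeddedIndex) -> ValidationReport:
    """Report ids present in the dataset but not the index, and vice versa."""
    dataset_ids = set(dataset.ids())
    index_ids = index.ids()
    return ValidationReport(
        missing_ids=dataset_ids - index_ids,
        extra_ids=index_ids - dataset_ids,
    )
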