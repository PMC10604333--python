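"""Offline feature indexing and online Euclidean top-K patch search.

The search space is the dictionary of embeddings extracted from the training
and validation patches; test patches act as queries.  Search is an exhaustive
Euclidean scan over the raw (un-normalised) embedding vectors — exact by
construction, with ties broken by insertion order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cae import CAE, encode
from .types import FeatureVector, PatchImage


@dataclass
class RetrievalHit:
    patch_id: str
    distance: float
    label: int | None
    magnification: int | None


@dataclass
class RetrievalResult:
    """Ranked hit list for one query, ascending by distance."""

    query_id: str
    k: int
    hits: list[RetrievalHit]

    @property
    def labels(self) -> list[int | None]:
        return [h.label for h in self.hits]

    @property
    def distances(self) -> np.ndarray:
        return np.array([h.distance for h in self.hits])


class FeatureIndex:
    """Ordered store of (patch_id, label, magnification, embedding)."""

    def __init__(self, features: Sequence[FeatureVector]):
        if not features:
            raise ValueError("cannot build an index from zero features")
        dims = {len(f) for f in features}
        if len(dims) != 1:
            raise ValueError(f"inconsistent feature lengths in index: {sorted(dims)}")
        ids = [f.patch_id for f in features]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patch_ids in index")
        self.patch_ids: list[str] = ids
        self.labels: list[int | None] = [f.label for f in features]
        self.magnifications: list[int | None] = [f.magnification for f in features]
        self.vectors: np.ndarray = np.stack([f.values for f in features])

    @property
    def latent_dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return self.vectors.shape[0]

    def subset(self, keep: np.ndarray) -> "FeatureIndex":
        idx = np.flatnonzero(keep)
        feats = [
            FeatureVector(self.vectors[i], self.patch_ids[i], self.labels[i],
                          self.magnifications[i])
            for i in idx
        ]
        return FeatureIndex(feats)

    def split_by_magnification(self) -> dict[int | None, "FeatureIndex"]:
        mags = []
        for m in self.magnifications:
            if m not in mags:
                mags.append(m)
        out = {}
        for m in mags:
            keep = np.array([mm == m for mm in self.magnifications])
            out[m] = self.subset(keep)
        return out


def build_index(model: CAE, patches: Sequence[PatchImage]) -> FeatureIndex:
    """Embed every patch with the trained encoder and store in order."""
    if not patches:
        raise ValueError("cannot index an empty patch set")
    return FeatureIndex(encode(model, patches))


def euclidean_distances(index: FeatureIndex, query: np.ndarray) -> np.ndarray:
    q = np.asarray(query, dtype=np.float64).ravel()
    if q.size != index.latent_dim:
        raise ValueError(
            f"query has {q.size} features but index stores {index.latent_dim}"
        )
    d = index.vectors - q
    return np.sqrt(np.einsum("ij,ij->i", d, d))


def query_features(index: FeatureIndex, query: np.ndarray, k: int,
                   query_id: str = "query") -> RetrievalResult:
    """Top-K Euclidean neighbours of an embedding; stable on ties."""
    if k < 1:
        raise ValueError("k must be >= 1")
    dist = euclidean_distances(index, query)
    order = np.argsort(dist, kind="stable")[: min(k, len(index))]
    hits = [
        RetrievalHit(index.patch_ids[i], float(dist[i]), index.labels[i],
                     index.magnifications[i])
        for i in order
    ]
    return RetrievalResult(query_id=query_id, k=k, hits=hits)


def query(index: FeatureIndex, model: CAE, q: PatchImage, k: int) -> RetrievalResult:
    """Embed a query patch and return its K nearest indexed patches."""
    fq = model.encode_batch(q.pixels[None])[0]
    return query_features(index, fq, k, query_id=q.patch_id)


def query_cross_magnification(
    indexes: Mapping[int | None, FeatureIndex], model: CAE, q: PatchImage, k: int
) -> dict[int | None, RetrievalResult]:
    """Independent top-K search in each per-magnification index.

    This realises the cross-magnification scenario: a query captured at one
    magnification retrieves the most similar patches separately at each
    available magnification.
    """
    if not indexes:
        raise ValueError("need at least one per-magnification index")
    fq = model.encode_batch(q.pixels[None])[0]
    return {
        mag: query_features(idx, fq, k, query_id=q.patch_id)
        for mag, idx in indexes.items()
    }
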