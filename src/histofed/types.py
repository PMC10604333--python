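"""Core value types shared across the pipeline.

A :class:`PatchImage` is one RGB tissue patch with its provenance; a
:class:`FeatureVector` is the embedding the encoder produced for it; a
:class:`ModelWeights` is the named tensor collection that crosses the
client/server boundary during federated training.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

BENIGN = 0
MALIGNANT = 1

#: magnifications used for breast-histology patches, in objective power
MAGNIFICATIONS = (40, 100, 200, 400)


@dataclass
class PatchImage:
    """One RGB patch in [0, 1] with label, magnification and provenance.

    ``label`` follows the two-class convention 0 = benign / non-cancerous,
    1 = malignant / cancerous; ``magnification`` is the objective power
    (40, 100, 200, 400) or ``None`` when unknown.
    """

    pixels: np.ndarray
    patch_id: str
    label: int | None = None
    magnification: int | None = None
    client_id: str = ""
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"patch {self.patch_id!r}: expected H x W x 3 pixels, "
                f"got shape {self.pixels.shape}"
            )
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(
                f"patch {self.patch_id!r}: pixel values must lie in [0, 1], "
                f"observed range [{lo:.4g}, {hi:.4g}]"
            )

    @property
    def size(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class FeatureVector:
    """Embedding of one patch, with the patch metadata carried along."""

    values: np.ndarray
    patch_id: str
    label: int | None = None
    magnification: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"feature vector for {self.patch_id!r} is not finite")

    def __len__(self) -> int:
        return self.values.size


class ModelWeights:
    """Named collection of real tensors, addressed uniformly for aggregation.

    Two weight sets are aggregable iff their ``schema_id`` (a digest of the
    sorted parameter names and shapes) matches.  Only these objects ever
    cross the client/server boundary in a federation; raw images never do.
    """

    def __init__(self, entries: Mapping[str, np.ndarray]):
        self.entries: dict[str, np.ndarray] = {
            name: np.asarray(t, dtype=np.float64) for name, t in entries.items()
        }
        for name, t in self.entries.items():
            if not np.all(np.isfinite(t)):
                raise ValueError(f"non-finite values in weight tensor {name!r}")

    @property
    def schema_id(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.entries):
            h.update(name.encode())
            h.update(str(self.entries[name].shape).encode())
        return h.hexdigest()[:16]

    def content_digest(self) -> str:
        """Digest of the tensor *values* (schema_id covers only names/shapes)."""
        h = hashlib.sha256()
        for name in sorted(self.entries):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.entries[name]).tobytes())
        return h.hexdigest()[:16]

    def copy(self) -> "ModelWeights":
        return ModelWeights({k: v.copy() for k, v in self.entries.items()})

    def names(self) -> list[str]:
        return sorted(self.entries)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_parameters(self) -> int:
        return int(sum(t.size for t in self.entries.values()))

    def norm(self) -> float:
        """Global L2 norm over all tensors (used in round logs)."""
        return float(
            np.sqrt(sum(float(np.sum(t * t)) for t in self.entries.values()))
        )

    def allclose(self, other: "ModelWeights", rtol: float = 0.0, atol: float = 0.0) -> bool:
        if self.schema_id != other.schema_id:
            return False
        return all(
            np.allclose(self.entries[k], other.entries[k], rtol=rtol, atol=atol)
            for k in self.entries
        )
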