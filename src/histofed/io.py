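"""Persistence: HDF5 weight/index stores, PNG patches, CSV manifests, reports.

Weight checkpoints are HDF5 files mapping parameter names to arrays with the
schema digest stored as an attribute; feature indexes are HDF5 vector blocks
with a CSV sidecar carrying (patch_id, label, magnification).  Missing labels
and magnifications are stored as -1.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .evaluation import EvalReport
from .retrieval import FeatureIndex
from .types import FeatureVector, ModelWeights, PatchImage


def config_hash(config: dict) -> str:
    """Stable short digest of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# -- weights ----------------------------------------------------------------

def save_weights(path: str | Path, weights: ModelWeights, attrs: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["schema_id"] = weights.schema_id
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
        for name in weights.names():
            f.create_dataset(name, data=weights[name])


def load_weights(path: str | Path) -> ModelWeights:
    entries: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        stored = f.attrs.get("schema_id")

        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                entries[name] = obj[()]

        f.visititems(visit)
    w = ModelWeights(entries)
    if stored is not None and stored != w.schema_id:
        raise ValueError(f"weight file {path} schema mismatch: {stored} vs {w.schema_id}")
    return w


def weights_attrs(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        return dict(f.attrs)


# -- feature index ----------------------------------------------------------

def _opt(v: int | None) -> int:
    return -1 if v is None else int(v)


def _unopt(v: int) -> int | None:
    return None if v == -1 else int(v)


def save_index(path: str | Path, index: FeatureIndex, attrs: dict | None = None) -> None:
    """HDF5 vectors plus a CSV sidecar of (patch_id, label, magnification)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("vectors", data=index.vectors)
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
    pd.DataFrame(
        {
            "patch_id": index.patch_ids,
            "label": [_opt(v) for v in index.labels],
            "magnification": [_opt(v) for v in index.magnifications],
        }
    ).to_csv(path.with_suffix(path.suffix + ".csv"), index=False)


def load_index(path: str | Path) -> FeatureIndex:
    path = Path(path)
    with h5py.File(path, "r") as f:
        vectors = f["vectors"][()]
    meta = pd.read_csv(path.with_suffix(path.suffix + ".csv"))
    feats = [
        FeatureVector(
            vectors[i],
            patch_id=str(meta.patch_id[i]),
            label=_unopt(int(meta.label[i])),
            magnification=_unopt(int(meta.magnification[i])),
        )
        for i in range(len(meta))
    ]
    return FeatureIndex(feats)


def index_attrs(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        return dict(f.attrs)


# -- patches ----------------------------------------------------------------

def write_patch_dataset(directory: str | Path, patches: Sequence[PatchImage]) -> Path:
    """Write patches as 8-bit PNGs plus a manifest CSV; returns the manifest path."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patches:
        fname = p.patch_id.replace("/", "_") + ".png"
        iio.imwrite(directory / fname, (p.pixels * 255).round().astype(np.uint8))
        rows.append(
            {
                "patch_id": p.patch_id,
                "path": fname,
                "label": _opt(p.label),
                "magnification": _opt(p.magnification),
                "client_id": p.client_id,
                "slide_id": p.slide_id,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_patch_dataset(manifest: str | Path) -> list[PatchImage]:
    import imageio.v3 as iio

    manifest = Path(manifest)
    base = manifest.parent
    meta = pd.read_csv(manifest, keep_default_na=False)
    patches = []
    for row in meta.itertuples():
        pixels = np.asarray(iio.imread(base / row.path), dtype=np.float64) / 255.0
        patches.append(
            PatchImage(
                pixels=pixels,
                patch_id=str(row.patch_id),
                label=_unopt(int(row.label)),
                magnification=_unopt(int(row.magnification)),
                client_id=str(row.client_id),
                slide_id=str(row.slide_id),
            )
        )
    return patches


# -- reports ----------------------------------------------------------------

def save_report(path: str | Path, report: EvalReport, extra: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict()
    payload.update(extra or {})
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def round_logs_to_csv(path: str | Path, logs) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for log in logs:
        for cid, loss in log.client_losses.items():
            rows.append(
                {
                    "round": log.round_index,
                    "client_id": cid,
                    "final_local_loss": loss,
                    "aggregate_weight_norm": log.weight_norm,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
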