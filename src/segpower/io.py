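"""Mask ingestion and tabular I/O.

Binary masks are read from NIfTI (via nibabel) or MetaImage (via
SimpleITK) volumes; any nonzero voxel binarizes to 1 at ingestion.
Label tables are long-format CSV with columns ``image_id, voxel_id, a, b,
l[, h]``.  Reports serialize estimates and sample-size results to JSON and
CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import PilotDataset, SampleSizeResult
from .estimation import PilotEstimates

__all__ = [
    "read_mask",
    "read_mask_set",
    "write_mask",
    "write_mask_set",
    "read_label_table",
    "write_label_table",
    "write_report",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mhd", ".mha")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_mask(path: str | Path) -> np.ndarray:
    """Read one volume and binarize (nonzero -> 1); returns the full array."""
    path = Path(path)
    suffix = _suffix(path)
    if suffix in _NIFTI_SUFFIXES:
        import nibabel as nib

        data = np.asanyarray(nib.load(path).dataobj)
    elif suffix in _META_SUFFIXES:
        import SimpleITK as sitk

        data = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
    else:
        raise ValueError(
            f"unsupported mask format {suffix!r} for {path}; "
            "expected .nii, .nii.gz, .mhd or .mha"
        )
    return (data != 0).astype(np.int8)


def write_mask(data: np.ndarray, path: str | Path) -> None:
    """Write a binary volume as NIfTI or MetaImage, by extension."""
    path = Path(path)
    suffix = _suffix(path)
    arr = np.asarray(data, dtype=np.uint8)
    if suffix in _NIFTI_SUFFIXES:
        import nibabel as nib

        nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), path)
    elif suffix in _META_SUFFIXES:
        import SimpleITK as sitk

        sitk.WriteImage(sitk.GetImageFromArray(arr), str(path))
    else:
        raise ValueError(f"unsupported mask format {suffix!r} for {path}")


def read_mask_set(
    images: Sequence[Mapping[str, str | Path]],
) -> PilotDataset:
    """Read co-registered mask volumes into a pilot dataset.

    ``images`` is a sequence of per-image mappings with keys ``a, b, l``
    and optionally ``h``, each a volume path.  All volumes of one image
    must share dimensions; all images must list the same sources.
    """
    if not images:
        raise ValueError("no images given")
    has_h = "h" in images[0]
    sources = ("a", "b", "l") + (("h",) if has_h else ())
    per_source: dict[str, list[np.ndarray]] = {s: [] for s in sources}
    grid_shape: tuple[int, ...] | None = None
    for k, entry in enumerate(images):
        if set(map(str.lower, entry.keys())) != set(sources):
            raise ValueError(
                f"image {k} lists sources {sorted(entry)} but expected {sorted(sources)}"
            )
        shapes = {}
        for s in sources:
            vol = read_mask(entry[s])
            shapes[s] = vol.shape
            per_source[s].append(vol.ravel(order="C"))
        if len(set(shapes.values())) != 1:
            raise ValueError(f"volumes for image {k} have mismatched dimensions: {shapes}")
        shape = next(iter(shapes.values()))
        if grid_shape is None:
            grid_shape = shape
        elif shape != grid_shape:
            grid_shape = None  # mixed geometries: no common lattice
    return PilotDataset(
        labels_A=tuple(per_source["a"]),
        labels_B=tuple(per_source["b"]),
        labels_L=tuple(per_source["l"]),
        labels_H=tuple(per_source["h"]) if has_h else None,
        grid_shape=grid_shape,
    )


def write_mask_set(pilot: PilotDataset, directory: str | Path, fmt: str = ".nii.gz") -> list[dict]:
    """Write a pilot dataset as one volume per source per image.

    Volumes are reshaped to ``pilot.grid_shape`` when known, else written
    as 1-D.  Returns the per-image path mappings accepted by
    :func:`read_mask_set`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    shape = pilot.grid_shape
    entries = []
    sources = {"a": pilot.labels_A, "b": pilot.labels_B, "l": pilot.labels_L}
    if pilot.has_H:
        sources["h"] = pilot.labels_H
    for k in range(pilot.n_images):
        entry = {}
        for s, labels in sources.items():
            vol = labels[k].reshape(shape) if shape is not None else labels[k]
            path = directory / f"image{k:03d}_{s}{fmt}"
            write_mask(vol, path)
            entry[s] = path
        entries.append(entry)
    return entries


def read_label_table(path: str | Path) -> PilotDataset:
    """Read a long-format CSV of per-voxel labels into a pilot dataset."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"image_id", "voxel_id", "a", "b", "l"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label table is missing columns: {sorted(missing)}")
    has_h = "h" in df.columns
    label_cols = ["a", "b", "l"] + (["h"] if has_h else [])
    bad = df[label_cols].apply(lambda c: ~c.isin((0, 1)))
    if bad.any().any():
        row = int(np.argwhere(bad.values.any(axis=1))[0][0])
        raise ValueError(f"non-binary label value at table row {row}")
    A, B, L, H = [], [], [], []
    for _, group in df.sort_values(["image_id", "voxel_id"]).groupby("image_id", sort=True):
        A.append(group["a"].to_numpy())
        B.append(group["b"].to_numpy())
        L.append(group["l"].to_numpy())
        if has_h:
            H.append(group["h"].to_numpy())
    return PilotDataset(
        labels_A=tuple(A),
        labels_B=tuple(B),
        labels_L=tuple(L),
        labels_H=tuple(H) if has_h else None,
    )


def write_label_table(pilot: PilotDataset, path: str | Path) -> None:
    """Write a pilot dataset as a long-format CSV."""
    rows = []
    for k in range(pilot.n_images):
        rec = {
            "image_id": k,
            "voxel_id": np.arange(len(pilot.labels_A[k])),
            "a": pilot.labels_A[k],
            "b": pilot.labels_B[k],
            "l": pilot.labels_L[k],
        }
        if pilot.has_H:
            rec["h"] = pilot.labels_H[k]
        rows.append(pd.DataFrame(rec))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    return obj


def write_report(
    results: PilotEstimates | SampleSizeResult | Mapping[str, object],
    path: str | Path,
    csv_path: str | Path | None = None,
) -> dict:
    """Serialize estimates or sample-size results to JSON (and optional CSV).

    Returns the JSON-ready payload (also usable for round-trip checks).
    """
    payload = _to_jsonable(results)
    if not isinstance(payload, dict):
        raise TypeError(f"cannot serialize object of type {type(results)!r}")
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if csv_path is not None:
        flat = {
            k: (v if np.isscalar(v) or v is None else json.dumps(v))
            for k, v in payload.items()
        }
        pd.DataFrame([flat]).to_csv(csv_path, index=False)
    return payload
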