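"""File formats: multi-page TIFF volumes, mask images, manifests, reports.

Volumes are stored as multi-page grayscale TIFF, one page per spectral band
in wavelength-ascending page order (a flag reverses); masks as single-page
8-bit images (0/255); cohorts as a manifest CSV with columns
``sample_id, label, volume_path, mask_path``.  Feature tables are CSV with
a JSON provenance sidecar; reports are pretty-printed, key-sorted JSON so
reruns diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .features import FEATURE_NAMES
from .synthetic import CLASS_LABELS, LabeledSample

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_manifest",
    "write_cohort",
    "write_feature_table",
    "read_feature_table",
    "write_json_report",
    "config_hash",
]


def read_volume(path, *, reverse_bands: bool = False) -> np.ndarray:
    """Read a multi-page TIFF stack as an (x, y, band) float volume.

    Pages are stacked along the spectral axis in page order (wavelength
    ascending unless ``reverse_bands``); all pages must share dimensions and
    there must be at least two.
    """
    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
    if len(pages) < 2:
        raise ValueError(f"{path}: not a multispectral stack (needs >= 2 pages)")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"{path}: mixed page dimensions {shapes}")
    if pages[0].ndim != 2:
        raise ValueError(f"{path}: pages must be single-channel grayscale")
    if reverse_bands:
        pages = pages[::-1]
    return np.stack(pages, axis=2).astype(float)


def write_volume(path, volume: np.ndarray) -> None:
    """Write an (x, y, band) volume as 16-bit multi-page TIFF.

    Float volumes are min-max scaled to the full uint16 range; integer
    volumes are written as-is.
    """
    v = np.asarray(volume)
    if v.ndim != 3:
        raise ValueError("volume must be 3D (x, y, band)")
    if np.issubdtype(v.dtype, np.integer):
        data = v.astype(np.uint16)
    else:
        lo, hi = float(v.min()), float(v.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 0.0
        data = np.round((v - lo) * scale).astype(np.uint16)
    pages = np.moveaxis(data, 2, 0)  # one page per band
    tifffile.imwrite(str(path), pages, photometric="minisblack")


def read_mask(path) -> np.ndarray:
    """Read a single-channel mask image; nonzero pixels are in the region."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be single-channel 2D")
    return arr > 0


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit TIFF with values 0/255."""
    m = np.asarray(mask).astype(bool)
    tifffile.imwrite(str(path), (m * np.uint8(255)), photometric="minisblack")


def write_cohort(samples: list[LabeledSample], out_dir) -> Path:
    """Write volumes, masks and the manifest CSV of a cohort; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        vol_path = out / f"{s.sample_id}_volume.tif"
        mask_path = out / f"{s.sample_id}_mask.tif"
        write_volume(vol_path, s.volume)
        write_mask(mask_path, s.mask)
        rows.append(
            {"sample_id": s.sample_id, "label": s.label,
             "volume_path": vol_path.name, "mask_path": mask_path.name}
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(path) -> pd.DataFrame:
    """Load and validate a manifest CSV; paths are resolved relative to it."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"sample_id", "label", "volume_path", "mask_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_ids in manifest: {dupes}")
    bad = set(df["label"]) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown labels in manifest: {sorted(bad)}")
    base = path.parent
    for col in ("volume_path", "mask_path"):
        resolved = []
        for p in df[col]:
            if not isinstance(p, str) or not p:  # absent mask (NaN/empty) allowed
                resolved.append("")
                continue
            resolved.append(p if Path(p).is_absolute() else str((base / p).resolve()))
        df[col] = resolved
        if col == "volume_path" and (df[col] == "").any():
            raise ValueError("manifest has rows without a volume_path")
        for p in df[col]:
            if p and not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
    return df


def write_feature_table(table: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a feature table CSV plus a JSON provenance sidecar."""
    path = Path(path)
    cols = ["sample_id", "label", *FEATURE_NAMES]
    table.loc[:, cols].to_csv(path, index=False, float_format="%.12g")
    side = dict(provenance or {})
    side.setdefault("normalization", table.attrs.get("normalization", "raw"))
    write_json_report(side, path.with_suffix(".provenance.json"))


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table CSV (normalization state from the sidecar if present)."""
    path = Path(path)
    table = pd.read_csv(path)
    sidecar = path.with_suffix(".provenance.json")
    state = "raw"
    if sidecar.exists():
        state = json.loads(sidecar.read_text()).get("normalization", "raw")
    table.attrs["normalization"] = state
    return table


def write_json_report(obj, path) -> None:
    """Pretty-printed, key-sorted JSON for diffable reruns."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
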