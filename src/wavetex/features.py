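"""Texture quantifiers over octant sub-bands and the 24-feature vector.

Each octant sub-band is summarized inside the region of interest by three
quantifier functions:

* **variance** — mean squared deviation from the mean of the sub-band values
  (population, 1/N convention); sensitive to the amplitude of texture at the
  sub-band's scale/orientation.
* **entropy** — Shannon entropy (bits) of the sub-band value histogram with
  256 equal-width bins spanning the ROI min-max; 0 for a regular (constant)
  texture, 8 bits for a completely uniform 256-bin histogram.
* **energy** — sum of squared histogram bin probabilities (uniformity) over
  the same histogram; 1 for a constant texture, 1/256 for a uniform one.

Three quantifiers x eight octants give the 24-feature vector per sample.
Feature tables are plain pandas DataFrames with columns
``sample_id, label, <quantifier>_<octant> ...`` and a ``normalization``
entry in ``DataFrame.attrs`` (``"raw"`` or ``"zscored"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .wavelet import OCTANT_KEYS, FilterBank, db2_filters, decimate_mask, dwt3d_single_level

logger = logging.getLogger(__name__)

__all__ = [
    "QUANTIFIERS",
    "FEATURE_NAMES",
    "HistogramSpec",
    "normalize_volume",
    "variance_feature",
    "entropy_feature",
    "energy_feature",
    "extract_feature_vector",
    "extract_feature_table",
    "zscore_table",
]

QUANTIFIERS = ("variance", "entropy", "energy")

#: The 24 canonical feature column names, quantifier-major, octants in
#: LLL, HLL, LHL, HHL, LLH, HLH, LHH, HHH order.
FEATURE_NAMES = tuple(f"{q}_{o}" for q in QUANTIFIERS for o in OCTANT_KEYS)


@dataclass(frozen=True)
class HistogramSpec:
    """Histogram discretization used by entropy and energy.

    Values are binned into ``n_bins`` equal-width intervals spanning the ROI
    min-max of the sub-band; a degenerate range (min == max) collapses to a
    single occupied bin.
    """

    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def probabilities(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float).ravel()
        if v.size == 0:
            raise ValueError("empty ROI: no sub-band values to histogram")
        lo, hi = v.min(), v.max()
        if lo == hi:
            return np.array([1.0])
        counts, _ = np.histogram(v, bins=self.n_bins, range=(lo, hi))
        return counts / v.size


def normalize_volume(volume: np.ndarray) -> np.ndarray:
    """Divide voxel intensities by the standard deviation of the whole volume.

    Raises on a constant (zero-SD) volume.
    """
    v = np.asarray(volume, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("constant volume: standard deviation is zero")
    return v / sd


def variance_feature(values: np.ndarray, *, raw_sum: bool = False) -> float:
    """Population variance (1/N) of the ROI sub-band values.

    ``raw_sum=True`` returns the un-normalized sum of squared deviations
    instead (legacy convention kept behind a flag).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty ROI: no sub-band values")
    sq = np.sum((v - v.mean()) ** 2)
    return float(sq if raw_sum else sq / v.size)


def entropy_feature(values: np.ndarray, spec: HistogramSpec | None = None) -> float:
    """Shannon entropy (bits) of the histogrammed ROI sub-band values."""
    spec = spec or HistogramSpec()
    p = spec.probabilities(values)
    p = p[p > 0]  # 0 * log 0 := 0
    return float(-np.sum(p * np.log2(p))) + 0.0  # normalize -0.0


def energy_feature(values: np.ndarray, spec: HistogramSpec | None = None) -> float:
    """Sum of squared histogram probabilities (uniformity) of ROI values."""
    spec = spec or HistogramSpec()
    p = spec.probabilities(values)
    return float(np.sum(p ** 2))


def _pad_to_even(arr: np.ndarray) -> np.ndarray:
    """Edge-pad each odd-length axis by one element at its far end."""
    pads = [(0, dim % 2) for dim in arr.shape]
    if not any(p[1] for p in pads):
        return arr
    return np.pad(arr, pads, mode="edge")


def extract_feature_vector(
    volume: np.ndarray,
    mask: np.ndarray,
    *,
    bank: FilterBank | None = None,
    spec: HistogramSpec | None = None,
    raw_sum_variance: bool = False,
) -> dict[str, float]:
    """Compute the 24 named texture features of one sample.

    Pipeline: global SD normalization -> crop the volume to the ROI bounding
    box and zero voxels outside the ROI -> pad odd dims to even -> single
    level 3D DWT -> each octant quantified by variance/entropy/energy over
    the voxels whose 2x2x2 parent cell intersects the ROI.

    Parameters
    ----------
    volume : (X, Y, Z) array, spectral bands along z.
    mask : (X, Y) binary region-of-interest membership.
    """
    v = np.asarray(volume, dtype=float)
    m = np.asarray(mask).astype(bool)
    if v.ndim != 3:
        raise ValueError("volume must be 3D (x, y, band)")
    if m.shape != v.shape[:2]:
        raise ValueError(f"mask shape {m.shape} != volume spatial dims {v.shape[:2]}")
    if not m.any():
        raise ValueError("empty ROI mask")

    v = normalize_volume(v)

    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    v = v[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1, :]
    m = m[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    v = v * m[:, :, None]  # confine texture to lesion tissue

    v = _pad_to_even(v)
    m = _pad_to_even(m)

    subbands = dwt3d_single_level(v, bank or db2_filters())
    support = decimate_mask(m, v.shape[2])
    if not support.any():
        raise ValueError("empty decimated ROI support")

    spec = spec or HistogramSpec()
    features: dict[str, float] = {}
    for key in OCTANT_KEYS:
        vals = subbands[key][support]
        features[f"variance_{key}"] = variance_feature(vals, raw_sum=raw_sum_variance)
        features[f"entropy_{key}"] = entropy_feature(vals, spec)
        features[f"energy_{key}"] = energy_feature(vals, spec)
    return {name: features[name] for name in FEATURE_NAMES}


def extract_feature_table(samples, **kwargs) -> pd.DataFrame:
    """Extract the feature table of a cohort of labelled samples.

    ``samples`` is an iterable of objects with ``volume``, ``mask``,
    ``label`` and ``sample_id`` attributes (e.g.
    :class:`wavetex.synthetic.LabeledSample`).
    """
    records = []
    for s in samples:
        rec = {"sample_id": s.sample_id, "label": s.label}
        rec.update(extract_feature_vector(s.volume, s.mask, **kwargs))
        records.append(rec)
    table = pd.DataFrame.from_records(records)
    table.attrs["normalization"] = "raw"
    return table


def zscore_table(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column to zero mean and unit (population) SD.

    Constant columns are set to all-zeros with a logged warning.  Requires at
    least two rows.
    """
    if len(table) < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    out = table.copy()
    for name in FEATURE_NAMES:
        col = out[name].to_numpy(dtype=float)
        sd = col.std()  # population (1/n) SD
        if sd == 0:
            logger.warning("feature %s is constant across samples; zscored to 0", name)
            out[name] = 0.0
        else:
            out[name] = (col - col.mean()) / sd
    out.attrs["normalization"] = "zscored"
    return out
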