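"""Single-level separable 3D discrete wavelet transform into octant sub-bands.

A multispectral pathology volume (x, y spatial; z spectral) is decomposed by
the 2D + 1D scheme: a 1D analysis filter pair is applied with dyadic
decimation along x, then y, then z, yielding eight octant sub-bands labelled
by the filter (L = low pass, H = high pass) applied on each axis in (x, y, z)
order: LLL, HLL, LHL, HHL, LLH, HLH, LHH, HHH.

The transform uses periodized boundaries, under which the analysis operator
is exactly orthogonal for an orthonormal filter bank: sub-band lengths are
exactly N/2, energy is conserved (Parseval) and the inverse is the adjoint,
giving perfect reconstruction to machine precision.

Filter convention
-----------------
``dec_low`` is stored in the classical Daubechies order
``[(1+sqrt(3)), (3+sqrt(3)), (3-sqrt(3)), (1-sqrt(3))]/(4*sqrt(2))`` and the
analysis step is ``a[n] = sum_k g[k] * x[(2n - 1 + k) mod N]``, which
coincides coefficient-for-coefficient with PyWavelets' ``periodization``
mode (asserted by a cross-check test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OCTANT_KEYS",
    "FilterBank",
    "SubbandSet",
    "db2_filters",
    "dwt1d",
    "idwt1d",
    "dwt3d_single_level",
    "idwt3d",
    "decimate_mask",
]

#: Octant sub-band keys; letter i is the filter applied on axis i in (x, y, z) order.
OCTANT_KEYS = ("LLL", "HLL", "LHL", "HHL", "LLH", "HLH", "LHH", "HHH")


@dataclass(frozen=True)
class FilterBank:
    """Analysis/synthesis filter pair of an orthonormal two-channel bank.

    For an orthonormal bank with periodized boundaries the synthesis filters
    are determined by the analysis pair (the transform is orthogonal), so
    ``rec_low``/``rec_high`` simply mirror the decomposition filters.
    """

    name: str
    dec_low: np.ndarray
    dec_high: np.ndarray
    rec_low: np.ndarray = field(default=None)  # type: ignore[assignment]
    rec_high: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dec_low", np.asarray(self.dec_low, dtype=float))
        object.__setattr__(self, "dec_high", np.asarray(self.dec_high, dtype=float))
        if self.rec_low is None:
            object.__setattr__(self, "rec_low", self.dec_low.copy())
        if self.rec_high is None:
            object.__setattr__(self, "rec_high", self.dec_high.copy())

    def __len__(self) -> int:
        return len(self.dec_low)


def db2_filters() -> FilterBank:
    """Return the 4-tap Daubechies-2 orthonormal analysis/synthesis pair.

    ``dec_low`` sums to sqrt(2) (unit DC gain after the sqrt(2) analysis
    normalization), ``dec_high`` has a vanishing zeroth moment (sums to 0),
    and both have unit l2 norm.
    """
    s3 = np.sqrt(3.0)
    g = np.array([1.0 + s3, 3.0 + s3, 3.0 - s3, 1.0 - s3]) / (4.0 * np.sqrt(2.0))
    # quadrature mirror: h[k] = (-1)^k g[L-1-k]
    h = np.array([g[3], -g[2], g[1], -g[0]])
    return FilterBank(name="db2", dec_low=g, dec_high=h)


def _check_length(n: int, bank: FilterBank) -> None:
    if n < len(bank):
        raise ValueError(
            f"signal length {n} shorter than filter length {len(bank)}"
        )
    if n % 2 != 0:
        raise ValueError(f"signal length {n} must be even (periodized transform)")


def _analysis_axis(x: np.ndarray, filt: np.ndarray, axis: int) -> np.ndarray:
    """Periodized convolve-and-decimate along ``axis``: y[n] = sum_k f[k] x[2n-1+k]."""
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    half = n // 2
    out = np.zeros(x.shape[:-1] + (half,), dtype=float)
    starts = 2 * np.arange(half) - 1
    for k, fk in enumerate(filt):
        out += fk * x[..., (starts + k) % n]
    return np.moveaxis(out, -1, axis)


def _synthesis_axis(
    approx: np.ndarray, detail: np.ndarray, bank: FilterBank, axis: int
) -> np.ndarray:
    """Adjoint of :func:`_analysis_axis` for both channels (exact inverse)."""
    a = np.moveaxis(approx, axis, -1)
    d = np.moveaxis(detail, axis, -1)
    half = a.shape[-1]
    n = 2 * half
    out = np.zeros(a.shape[:-1] + (n,), dtype=float)
    starts = 2 * np.arange(half) - 1
    for k in range(len(bank)):
        idx = (starts + k) % n
        np.add.at(out, (..., idx), bank.rec_low[k] * a + bank.rec_high[k] * d)
    return np.moveaxis(out, -1, axis)


def dwt1d(
    signal: np.ndarray, bank: FilterBank | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Single-level periodized 1D DWT: returns (approximation, detail).

    The input length must be even and at least the filter length; each output
    has exactly half the input length.
    """
    bank = bank or db2_filters()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("dwt1d expects a 1D signal")
    _check_length(x.shape[0], bank)
    approx = _analysis_axis(x, bank.dec_low, 0)
    detail = _analysis_axis(x, bank.dec_high, 0)
    return approx, detail


def idwt1d(
    approx: np.ndarray, detail: np.ndarray, bank: FilterBank | None = None
) -> np.ndarray:
    """Inverse of :func:`dwt1d` (exact for the orthonormal periodized bank)."""
    bank = bank or db2_filters()
    a = np.asarray(approx, dtype=float)
    d = np.asarray(detail, dtype=float)
    if a.shape != d.shape or a.ndim != 1:
        raise ValueError("approx/detail must be 1D with equal shapes")
    return _synthesis_axis(a, d, bank, 0)


@dataclass
class SubbandSet:
    """The eight octant sub-volumes of a single-level 3D DWT.

    Each octant has shape ``(X/2, Y/2, Z/2)`` of the (even-dimension) input.
    ``provenance`` records the filter name and boundary mode.
    """

    octants: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.octants) != set(OCTANT_KEYS):
            raise ValueError(f"octant keys must be exactly {OCTANT_KEYS}")
        shapes = {o.shape for o in self.octants.values()}
        if len(shapes) != 1:
            raise ValueError(f"octant shapes inconsistent: {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.octants["LLL"].shape

    def __getitem__(self, key: str) -> np.ndarray:
        return self.octants[key]

    def keys(self):
        return OCTANT_KEYS

    def energy(self) -> float:
        """Total squared-coefficient energy over all eight octants."""
        return float(sum(np.sum(o ** 2) for o in self.octants.values()))


def dwt3d_single_level(
    volume: np.ndarray, bank: FilterBank | None = None
) -> SubbandSet:
    """Single-level separable 3D DWT of a volume into eight octant sub-bands.

    The 1D analysis pair is applied with decimation independently along the
    x and y image axes (the 2D stage) and then along the spectral z axis.
    Octant key letter i names the filter applied on axis i in (x, y, z)
    order; separability makes the result independent of the axis ordering.
    """
    bank = bank or db2_filters()
    v = np.asarray(volume, dtype=float)
    if v.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={v.ndim}")
    for ax in range(3):
        _check_length(v.shape[ax], bank)

    octants: dict[str, np.ndarray] = {}
    for key in OCTANT_KEYS:
        sub = v
        for axis, letter in enumerate(key):
            filt = bank.dec_low if letter == "L" else bank.dec_high
            sub = _analysis_axis(sub, filt, axis)
        octants[key] = sub
    return SubbandSet(
        octants=octants,
        provenance={"filter": bank.name, "boundary": "periodization", "level": 1},
    )


def idwt3d(subbands: SubbandSet, bank: FilterBank | None = None) -> np.ndarray:
    """Reconstruct the volume from its eight octant sub-bands (exact inverse)."""
    bank = bank or db2_filters()
    oc = subbands.octants
    # collapse z, then y, then x
    merged_z = {
        xy: _synthesis_axis(oc[xy + "L"], oc[xy + "H"], bank, 2)
        for xy in ("LL", "HL", "LH", "HH")
    }
    merged_y = {
        x: _synthesis_axis(merged_z[x + "L"], merged_z[x + "H"], bank, 1)
        for x in ("L", "H")
    }
    return _synthesis_axis(merged_y["L"], merged_y["H"], bank, 0)


def decimate_mask(mask: np.ndarray, z_extent: int) -> np.ndarray:
    """Map a 2D ROI mask onto the octant sub-band grid of a z_extent-band volume.

    The mask is replicated across all z planes, then each 2x2x2 parent cell
    maps to one sub-band voxel, included iff ANY parent voxel lies in the
    ROI.  Output shape is ``(X/2, Y/2, z_extent/2)`` — the octant shape.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2D")
    if m.shape[0] % 2 or m.shape[1] % 2 or z_extent % 2:
        raise ValueError(
            f"mask dims {m.shape} and z_extent {z_extent} must all be even"
        )
    coarse2d = (
        m.reshape(m.shape[0] // 2, 2, m.shape[1] // 2, 2).any(axis=(1, 3))
    )
    return np.repeat(coarse2d[:, :, None], z_extent // 2, axis=2)
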