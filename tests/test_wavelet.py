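"""Wavelet core: filter identities, perfect reconstruction, Parseval,
separability, the brute-force matrix-operator oracle and the PyWavelets
cross-check."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from wavetex.wavelet import (
    OCTANT_KEYS,
    SubbandSet,
    db2_filters,
    decimate_mask,
    dwt1d,
    dwt3d_single_level,
    idwt1d,
    idwt3d,
)
from wavetex.wavelet import _analysis_axis  # noqa: PLC2701 - separability check


class TestFilterBank:
    def test_db2_closed_form_identities(self):
        bank = db2_filters()
        s3 = np.sqrt(3.0)
        expected = np.array([1 + s3, 3 + s3, 3 - s3, 1 - s3]) / (4 * np.sqrt(2))
        np.testing.assert_allclose(bank.dec_low, expected, atol=1e-15)
        assert bank.dec_low.sum() == pytest.approx(np.sqrt(2), abs=1e-12)
        assert bank.dec_high.sum() == pytest.approx(0.0, abs=1e-12)
        assert (bank.dec_low**2).sum() == pytest.approx(1.0, abs=1e-12)

    def test_quadrature_mirror_orthogonality(self):
        bank = db2_filters()
        g, h = bank.dec_low, bank.dec_high
        # even-shift orthonormality and cross-orthogonality (CQF conditions)
        n = 8
        G = np.zeros((n // 2, n))
        H = np.zeros((n // 2, n))
        for row in range(n // 2):
            for k in range(4):
                G[row, (2 * row - 1 + k) % n] += g[k]
                H[row, (2 * row - 1 + k) % n] += h[k]
        W = np.vstack([G, H])
        np.testing.assert_allclose(W @ W.T, np.eye(n), atol=1e-12)


class TestDwt1d:
    def test_zero_signal_gives_zero_subbands(self):
        a, d = dwt1d(np.zeros(16))
        assert not a.any() and not d.any()

    def test_constant_signal_detail_vanishes_approx_gains_sqrt2(self):
        c = 3.7
        a, d = dwt1d(np.full(12, c))
        np.testing.assert_allclose(d, 0.0, atol=1e-12)
        np.testing.assert_allclose(a, c * np.sqrt(2), atol=1e-12)

    def test_perfect_reconstruction_random(self, rng):
        x = rng.standard_normal(16)
        a, d = dwt1d(x)
        np.testing.assert_allclose(idwt1d(a, d), x, atol=1e-10)

    @pytest.mark.parametrize("bad", [np.zeros(3), np.zeros(7)])
    def test_rejects_short_or_odd_signals(self, bad):
        with pytest.raises(ValueError):
            dwt1d(bad)

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=4, max_size=64
        ).filter(lambda v: len(v) % 2 == 0)
    )
    def test_perfect_reconstruction_property(self, values):
        x = np.asarray(values)
        a, d = dwt1d(x)
        scale = max(1.0, np.abs(x).max())
        np.testing.assert_allclose(idwt1d(a, d), x, atol=1e-10 * scale)

    def test_matches_pywt_periodization_exactly(self, rng):
        for n in (8, 16, 64):
            x = rng.standard_normal(n)
            a, d = dwt1d(x)
            ca, cd = pywt.dwt(x, "db2", mode="periodization")
            np.testing.assert_allclose(a, ca, atol=1e-12)
            np.testing.assert_allclose(d, cd, atol=1e-12)


class TestDwt3d:
    def test_zero_volume(self):
        sb = dwt3d_single_level(np.zeros((8, 8, 8)))
        assert all(not sb[k].any() for k in OCTANT_KEYS)

    def test_constant_volume_energy_in_lll(self):
        c = 2.0
        sb = dwt3d_single_level(np.full((8, 8, 8), c))
        np.testing.assert_allclose(sb["LLL"], c * 2**1.5, atol=1e-12)
        for key in OCTANT_KEYS[1:]:
            np.testing.assert_allclose(sb[key], 0.0, atol=1e-12)

    def test_octant_count_and_shapes(self, rng):
        v = rng.standard_normal((16, 12, 8))
        sb = dwt3d_single_level(v)
        assert tuple(sb.keys()) == OCTANT_KEYS
        assert len(OCTANT_KEYS) == 8
        assert all(sb[k].shape == (8, 6, 4) for k in OCTANT_KEYS)

    def test_parseval_and_reconstruction(self, rng):
        for _ in range(20):
            v = rng.standard_normal((16, 16, 16))
            sb = dwt3d_single_level(v)
            energy_in = float(np.sum(v**2))
            assert abs(sb.energy() - energy_in) / energy_in < 1e-8
            np.testing.assert_allclose(idwt3d(sb), v, atol=1e-10)

    def test_separability_axis_order(self, rng):
        """x->y->z pass order equals z->y->x order exactly."""
        bank = db2_filters()
        v = rng.standard_normal((8, 8, 8))
        for key in OCTANT_KEYS:
            filters = [bank.dec_low if ch == "L" else bank.dec_high for ch in key]
            fwd = _analysis_axis(
                _analysis_axis(_analysis_axis(v, filters[0], 0), filters[1], 1),
                filters[2],
                2,
            )
            rev = _analysis_axis(
                _analysis_axis(_analysis_axis(v, filters[2], 2), filters[1], 1),
                filters[0],
                0,
            )
            np.testing.assert_allclose(fwd, rev, atol=1e-12)
            np.testing.assert_allclose(dwt3d_single_level(v)[key], fwd, atol=1e-14)

    def test_matrix_operator_oracle_8cubed(self, rng):
        """Brute-force periodized analysis operator reproduces every octant."""
        n = 8
        bank = db2_filters()
        W = np.zeros((n, n))
        for row in range(n // 2):
            for k in range(4):
                W[row, (2 * row - 1 + k) % n] += bank.dec_low[k]
                W[n // 2 + row, (2 * row - 1 + k) % n] += bank.dec_high[k]
        v = rng.standard_normal((n, n, n))
        t = np.einsum("ia,jb,kc,abc->ijk", W, W, W, v)
        half = n // 2
        sl = {"L": slice(0, half), "H": slice(half, n)}
        sb = dwt3d_single_level(v)
        for key in OCTANT_KEYS:
            np.testing.assert_allclose(
                sb[key], t[sl[key[0]], sl[key[1]], sl[key[2]]], atol=1e-10
            )

    def test_matches_pywt_dwtn(self, rng):
        v = rng.standard_normal((16, 8, 8))
        ref = pywt.dwtn(v, "db2", mode="periodization")
        sb = dwt3d_single_level(v)
        for key in OCTANT_KEYS:
            pywt_key = key.replace("L", "a").replace("H", "d").lower()
            np.testing.assert_allclose(sb[key], ref[pywt_key], atol=1e-12)

    def test_lll_only_reconstruction_is_orthogonal_projection(self, rng):
        v = rng.standard_normal((8, 8, 8))
        sb = dwt3d_single_level(v)
        detail_energy = sum(
            float(np.sum(sb[k] ** 2)) for k in OCTANT_KEYS if k != "LLL"
        )
        smoothed = idwt3d(
            SubbandSet(
                octants={
                    k: (sb[k] if k == "LLL" else np.zeros_like(sb[k]))
                    for k in OCTANT_KEYS
                }
            )
        )
        assert float(np.sum((v - smoothed) ** 2)) == pytest.approx(
            detail_energy, rel=1e-8
        )

    def test_rejects_non_3d(self):
        with pytest.raises(ValueError):
            dwt3d_single_level(np.zeros((8, 8)))

    def test_subbandset_rejects_inconsistent_shapes(self):
        octants = {k: np.zeros((2, 2, 2)) for k in OCTANT_KEYS}
        octants["HHH"] = np.zeros((2, 2, 3))
        with pytest.raises(ValueError):
            SubbandSet(octants=octants)


class TestDecimateMask:
    def test_full_and_empty_masks(self):
        full = decimate_mask(np.ones((8, 8), dtype=bool), 16)
        assert full.shape == (4, 4, 8) and full.all()
        empty = decimate_mask(np.zeros((8, 8), dtype=bool), 16)
        assert not empty.any()

    def test_single_block_maps_to_one_inplane_column(self):
        m = np.zeros((8, 8), dtype=bool)
        m[:2, :2] = True
        out = decimate_mask(m, 16)
        assert out.sum() == 8  # one in-plane position across all 8 z cells
        assert out[0, 0].all() and not out[1:, :, :].any() and not out[0, 1:, :].any()

    def test_any_parent_voxel_rule(self):
        m = np.zeros((4, 4), dtype=bool)
        m[1, 1] = True  # a single parent pixel inside the (0,0) cell
        out = decimate_mask(m, 2)
        assert out[0, 0, 0] and out.sum() == 1

    def test_rejects_odd_dims(self):
        with pytest.raises(ValueError):
            decimate_mask(np.ones((7, 8), dtype=bool), 16)
        with pytest.raises(ValueError):
            decimate_mask(np.ones((8, 8), dtype=bool), 15)
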