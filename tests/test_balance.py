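"""Balance, DCM, mirror symmetry, and homogeneity against brute-force oracles."""

from itertools import product

import numpy as np
import pytest

from qipbox.balance import (
    DegenerateImageWarning,
    area_pair_masses,
    balance_score,
    dcm_score,
    homogeneity,
    mass_image,
    mirror_symmetry,
)
from qipbox.io import GrayImage

# ---------------------------------------------------------------- oracles
# Pure-python loop implementations, independent of the vectorized code path.


def _oracle_band_weight(ds, lo, hi):
    n = len(ds)
    sds = sorted(ds)
    out = []
    for d in ds:
        start = sum(1 for v in sds if v < d)
        end = start + sum(1 for v in sds if v == d)
        ov = max(0.0, min(end, hi * n) - max(start, lo * n))
        out.append(ov / (end - start))
    return out


def oracle_balance(g, polarity="dark_heavy"):
    h, w = g.shape
    mass = [(255.0 - g[y][x]) if polarity == "dark_heavy" else float(g[y][x])
            for y in range(h) for x in range(w)]
    if sum(mass) <= 0:
        return float("nan")
    coords = {
        "v": [float(x) for y in range(h) for x in range(w)],
        "h": [float(y) for y in range(h) for x in range(w)],
        "d1": [h * (x + 0.5) - w * (y + 0.5) for y in range(h) for x in range(w)],
        "d2": [h * (x + 0.5) + w * (y + 0.5) - h * w
               for y in range(h) for x in range(w)],
    }
    scores = []
    for d in coords.values():
        for (lo1, hi1), (lo2, hi2) in (((0, .5), (.5, 1)), ((0, .25), (.75, 1))):
            w1 = _oracle_band_weight(d, lo1, hi1)
            w2 = _oracle_band_weight(d, lo2, hi2)
            m1 = sum(a * b for a, b in zip(mass, w1))
            m2 = sum(a * b for a, b in zip(mass, w2))
            scores.append(0.0 if m1 + m2 <= 0 else 100 * abs(m1 - m2) / (m1 + m2))
    return sum(scores) / 8


def oracle_dcm(g, polarity="dark_heavy"):
    h, w = g.shape
    tot = cx = cy = 0.0
    for y in range(h):
        for x in range(w):
            m = (255.0 - g[y][x]) if polarity == "dark_heavy" else float(g[y][x])
            tot += m
            cx += m * x
            cy += m * y
    if tot <= 0:
        return float("nan")
    gx, gy = (w - 1) / 2, (h - 1) / 2
    dist = ((cx / tot - gx) ** 2 + (cy / tot - gy) ** 2) ** 0.5
    mx = (gx ** 2 + gy ** 2) ** 0.5
    return 100 * dist / mx if mx else 0.0


def oracle_mirror(g):
    h, w = g.shape

    def axis_score(mirror):
        tot = sum(abs(float(g[y][x]) - float(mirror(y, x)))
                  for y in range(h) for x in range(w))
        return 100 * (1 - tot / (h * w * 255))

    scores = [axis_score(lambda y, x: g[y][w - 1 - x]),
              axis_score(lambda y, x: g[h - 1 - y][x])]
    if h == w:
        scores.append(axis_score(lambda y, x: g[x][y]))
        scores.append(axis_score(lambda y, x: g[w - 1 - x][h - 1 - y]))
    return sum(scores) / len(scores)


# ----------------------------------------------------------------- tests


class TestOracleEquivalence:
    def test_all_3x3_binary_images(self):
        """Balance/DCM/mirror agree with loop oracles on all 2^9 binaries."""
        for bits in product([0, 255], repeat=9):
            g = np.array(bits, dtype=float).reshape(3, 3)
            gi = GrayImage(g)
            if g.min() == 255.0:  # blank under dark_heavy: both NaN
                with pytest.warns(DegenerateImageWarning):
                    assert np.isnan(balance_score(gi))
                continue
            assert balance_score(gi) == pytest.approx(oracle_balance(g), abs=1e-9)
            assert dcm_score(gi) == pytest.approx(oracle_dcm(g), abs=1e-9)
            assert mirror_symmetry(gi) == pytest.approx(oracle_mirror(g), abs=1e-9)

    def test_random_grays_match_oracle(self, rng):
        for h, w in [(5, 5), (4, 7), (8, 3)]:
            g = rng.integers(0, 256, (h, w)).astype(float)
            gi = GrayImage(g)
            assert balance_score(gi) == pytest.approx(oracle_balance(g), abs=1e-8)
            assert dcm_score(gi) == pytest.approx(oracle_dcm(g), abs=1e-8)
            assert mirror_symmetry(gi) == pytest.approx(oracle_mirror(g), abs=1e-8)


class TestBalance:
    def test_four_axis_symmetric_image_is_perfectly_balanced(self):
        g = np.full((8, 8), 255.0)
        g[3:5, 3:5] = 0
        g[0, 0] = g[0, 7] = g[7, 0] = g[7, 7] = 100
        assert balance_score(GrayImage(g)) == 0.0

    def test_single_corner_pixel_4x4_hand_enumeration(self):
        g = np.full((4, 4), 255.0)
        g[0, 0] = 0.0
        # all mass in one pixel: every half/outer pair is fully one-sided
        # except pairs whose regions share the pixel fractionally
        assert balance_score(GrayImage(g)) == pytest.approx(
            oracle_balance(g), abs=1e-12)

    def test_area_pairs_have_equal_areas(self, rng):
        for h, w in [(10, 10), (7, 13), (16, 9)]:
            ones = GrayImage(np.zeros((h, w)))  # uniform mass 255
            for name, (m1, m2) in area_pair_masses(
                    mass_image(ones, "dark_heavy")).items():
                assert m1 == pytest.approx(m2, rel=1e-12), name

    def test_mirroring_input_preserves_score(self, rng):
        g = rng.integers(0, 256, (12, 17)).astype(float)
        a = balance_score(GrayImage(g))
        b = balance_score(GrayImage(g[:, ::-1].copy()))
        assert a == pytest.approx(b, abs=1e-9)

    def test_blank_image_nan_with_warning(self):
        with pytest.warns(DegenerateImageWarning):
            assert np.isnan(balance_score(GrayImage(np.full((4, 4), 255.0))))


class TestDCM:
    def test_symmetric_image_zero(self):
        g = np.full((6, 6), 255.0)
        g[2:4, 2:4] = 0
        assert dcm_score(GrayImage(g)) == 0.0

    def test_corner_pixel_is_100(self):
        g = np.full((100, 100), 255.0)
        g[0, 0] = 0.0
        assert dcm_score(GrayImage(g)) == 100.0

    def test_bright_heavy_polarity(self):
        g = np.zeros((10, 10))
        g[9, 9] = 255.0  # single bright pixel in a corner
        assert dcm_score(GrayImage(g), "bright_heavy") == 100.0


class TestMirrorSymmetry:
    def test_fully_symmetric_is_100(self):
        g = np.full((6, 6), 10.0)
        g[2:4, 2:4] = 200.0
        assert mirror_symmetry(GrayImage(g)) == 100.0

    def test_half_black_4x4_axis_decomposition(self):
        g = np.full((4, 4), 255.0)
        g[:, :2] = 0.0
        # per-axis scores (0, 100, 50, 50) -> mean 50
        assert mirror_symmetry(GrayImage(g)) == 50.0

    def test_rectangular_uses_two_axes_only(self):
        g = np.zeros((4, 8))
        g[:, :4] = 255.0  # lr-antisymmetric, ud-symmetric
        assert mirror_symmetry(GrayImage(g)) == pytest.approx(50.0)


class TestHomogeneity:
    def test_uniform_distribution_scores_100(self):
        g = np.full((100, 100), 255.0)
        g[::10, ::10] = 0.0  # one black pixel per cell
        res = homogeneity(GrayImage(g))
        assert res.cells_pct == pytest.approx(100.0)
        assert res.final_pct == pytest.approx(100.0)

    def test_single_cell_concentration_scores_0(self):
        g = np.full((100, 100), 255.0)
        g[:10, :10] = 0.0
        res = homogeneity(GrayImage(g))
        assert res.cells_pct == pytest.approx(0.0)
        assert res.final_pct == pytest.approx(0.0)

    def test_final_is_row_col_mean_and_transpose_invariant(self, rng):
        g = rng.integers(0, 256, (50, 80)).astype(float)
        a = homogeneity(GrayImage(g))
        assert a.final_pct == pytest.approx((a.rows_pct + a.cols_pct) / 2)
        b = homogeneity(GrayImage(g.T.copy()))
        assert a.final_pct == pytest.approx(b.final_pct, abs=1e-9)
        for v in (a.cells_pct, a.rows_pct, a.cols_pct, a.final_pct):
            assert -1e-9 <= v <= 100.0 + 1e-9

    def test_constant_image_nan_with_warning(self):
        with pytest.warns(DegenerateImageWarning):
            res = homogeneity(GrayImage(np.full((20, 20), 7.0)))
        assert np.isnan(res.final_pct)
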