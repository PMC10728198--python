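import numpy as np
import pytest

import pace2 as p2
from pace2.exceptions import InsufficientExtremaError


def _brute_extrema(arr):
    """Independent 3x3 scan: strict comparison against existing neighbors."""
    h, w = arr.shape
    maxima = np.zeros((h, w), dtype=bool)
    minima = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            neigh = [
                arr[yy, xx]
                for yy in range(max(0, y - 1), min(h, y + 2))
                for xx in range(max(0, x - 1), min(w, x + 2))
                if (yy, xx) != (y, x)
            ]
            maxima[y, x] = all(arr[y, x] > v for v in neigh)
            minima[y, x] = all(arr[y, x] < v for v in neigh)
    return maxima, minima


class TestDetectExtrema:
    def test_single_bright_pixel(self):
        arr = np.zeros((9, 9))
        arr[4, 4] = 1.0
        maxima, _ = p2.detect_extrema(arr)
        assert maxima.sum() == 1 and maxima[4, 4]

    def test_constant_image_has_no_extrema(self):
        maxima, minima = p2.detect_extrema(np.full((8, 8), 0.3))
        assert maxima.sum() == 0 and minima.sum() == 0

    def test_checkerboard_matches_brute_force(self):
        board = np.indices((6, 6)).sum(axis=0) % 2
        maxima, minima = p2.detect_extrema(board.astype(float))
        bm, bn = _brute_extrema(board.astype(float))
        assert np.array_equal(maxima, bm) and np.array_equal(minima, bn)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_grids_match_brute_force(self, seed):
        arr = np.random.default_rng(seed).random((12, 12))
        maxima, minima = p2.detect_extrema(arr)
        bm, bn = _brute_extrema(arr)
        assert np.array_equal(maxima, bm) and np.array_equal(minima, bn)

    def test_plateaus_are_not_extrema(self):
        arr = np.zeros((8, 8))
        arr[3:5, 3:5] = 1.0  # 2x2 plateau
        maxima, _ = p2.detect_extrema(arr)
        assert maxima.sum() == 0


class TestEnvelopeWindowSize:
    def _mask(self, shape, points):
        m = np.zeros(shape, dtype=bool)
        for y, x in points:
            m[y, x] = True
        return m

    def test_two_pairs_five_apart(self):
        maxima = self._mask((16, 16), [(0, 0), (0, 5)])
        minima = self._mask((16, 16), [(10, 0), (10, 5)])
        assert p2.envelope_window_size(maxima, minima) == 5

    def test_mixed_nearest_distances(self):
        # nearest-neighbor distances {2, 3, 4}; max 4 -> next odd is 5
        maxima = self._mask((32, 32), [(0, 0), (0, 2), (10, 0), (10, 3), (20, 0), (20, 4)])
        minima = self._mask((32, 32), [(30, 0), (30, 2)])
        assert p2.envelope_window_size(maxima, minima) == 5

    def test_lattice_spacing_two_gives_minimum_window(self):
        pts = [(y, x) for y in range(0, 8, 2) for x in range(0, 8, 2)]
        maxima = self._mask((16, 16), pts)
        minima = self._mask((16, 16), [(y + 1, x + 1) for y, x in pts])
        assert p2.envelope_window_size(maxima, minima) == 3

    def test_insufficient_extrema_raises(self):
        maxima = self._mask((16, 16), [(0, 0)])
        minima = self._mask((16, 16), [(5, 5), (9, 9)])
        with pytest.raises(InsufficientExtremaError):
            p2.envelope_window_size(maxima, minima)

    def test_lowest_rule_takes_minimum(self):
        maxima = self._mask((32, 32), [(0, 0), (0, 6)])
        minima = self._mask((32, 32), [(20, 0), (20, 2)])
        assert p2.envelope_window_size(maxima, minima, "lowest_min_distance") == 3
        assert p2.envelope_window_size(maxima, minima, "highest_min_distance") == 7


class TestDecompose:
    def test_constant_image_is_pure_residue(self):
        img = p2.Image2D(np.full((32, 32), 0.4))
        stack = p2.decompose(img)
        assert stack.K == 10
        assert all(np.all(b == 0) for b in stack.bimfs)
        assert np.array_equal(stack.residue, img.pixels)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_perfect_reconstruction(self, seed):
        img, _ = p2.generate_phantom(p2.PhantomSpec(seed=seed, size=(128, 128)))
        stack = p2.decompose(img)
        assert np.abs(stack.reconstruct() - img.pixels).max() <= 1e-9

    def test_deterministic_bitwise(self, default_phantom):
        img, _ = default_phantom
        a = p2.decompose(img)
        b = p2.decompose(img)
        assert all(np.array_equal(x, y) for x, y in zip(a.bimfs, b.bimfs))
        assert np.array_equal(a.residue, b.residue)

    def test_early_stop_pads_to_constant_k(self):
        # smooth hill: a single maximum, decomposition stops immediately
        yy, xx = np.mgrid[0:64, 0:64]
        hill = np.exp(-(((yy - 32) / 15.0) ** 2 + ((xx - 32) / 15.0) ** 2))
        stack = p2.decompose(p2.Image2D(hill), p2.FabemdConfig(K=5))
        assert stack.K == 5
        assert all(np.all(b == 0) for b in stack.bimfs)

    def test_mode_separation_sinusoid_vs_hill(self):
        # planted high-frequency sinusoid should land in the leading modes,
        # the broad hill in the residue
        yy, xx = np.mgrid[0:128, 0:128]
        hill = 0.5 * np.exp(-(((yy - 64) / 30.0) ** 2 + ((xx - 64) / 30.0) ** 2))
        sin2d = 0.05 * np.sin(2 * np.pi * xx / 8.0) * np.sin(2 * np.pi * yy / 8.0)
        img = p2.Image2D.from_array(np.clip(hill + sin2d + 0.2, 0, 1))
        stack = p2.decompose(img)
        b12 = stack.bimfs[0] + stack.bimfs[1]
        e_sin = float((sin2d**2).sum())
        captured = float((b12 * sin2d).sum()) ** 2 / (e_sin * float((b12**2).sum()) + 1e-30)
        proj_coef = float((b12 * sin2d).sum()) / e_sin
        assert proj_coef >= 0.8  # >= 80% of the sinusoid amplitude is in modes 1-2
        energies = p2.component_energies(stack)
        assert float((stack.residue**2).sum()) > sum(energies)
        flat_hill = (hill + 0.2).ravel()
        # order-statistics envelopes move some hill amplitude into mode 2,
        # but the residue remains dominated by the hill's shape
        corr = np.corrcoef(stack.residue.ravel(), flat_hill)[0, 1]
        assert corr > 0.8

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            p2.FabemdConfig(K=0)
        with pytest.raises(ValueError):
            p2.FabemdConfig(min_extrema=1)
        with pytest.raises(ValueError):
            p2.FabemdConfig(window_rule="median")
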