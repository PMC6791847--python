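import numpy as np
import pytest

from lincquant import (
    Filament,
    ValidationError,
    count_modes,
    density_curve,
    global_minimum_shift,
    min_pair_distance,
    nn_filament_distances,
    nn_origin_distances,
)

from conftest import random_polyline, random_rotation


def _fil(points, fid="f"):
    return Filament(fid, points)


class TestMinPairDistance:
    def test_parallel_offset(self):
        a = _fil([[0, 0, 0], [0, 0, 10], [0, 0, 20]])
        b = _fil([[2, 0, 0], [2, 0, 10], [2, 0, 20]])
        assert min_pair_distance(a, b) == pytest.approx(2.0)

    def test_shared_point_is_zero(self):
        a = _fil([[0, 0, 0], [0, 0, 10]])
        b = _fil([[0, 0, 10], [5, 0, 10]])
        assert min_pair_distance(a, b) == pytest.approx(0.0)

    def test_symmetry_and_loop_oracle(self, rng):
        for _ in range(20):
            a, b = random_polyline(rng, 15), random_polyline(rng, 9) + [30, 0, 0]
            fa, fb = _fil(a), _fil(b)
            best = min(
                float(np.sqrt(((p - q) ** 2).sum())) for p in a for q in b
            )  # exhaustive double loop
            assert min_pair_distance(fa, fb) == pytest.approx(best)
            assert min_pair_distance(fb, fa) == pytest.approx(best)

    def test_segment_variant_bounded_by_point_variant(self, rng):
        # segment-to-segment distance can only be smaller than vertex-to-vertex
        for _ in range(10):
            a, b = random_polyline(rng, 8), random_polyline(rng, 8) + [40, 0, 0]
            dp = min_pair_distance(_fil(a), _fil(b), method="points")
            ds = min_pair_distance(_fil(a), _fil(b), method="segments")
            assert ds <= dp + 1e-9

    def test_segment_variant_crossing_is_zero(self):
        a = _fil([[-1, 0, 0], [1, 0, 0]])
        b = _fil([[0, -1, 0], [0, 1, 0]])
        assert min_pair_distance(a, b, method="segments") == pytest.approx(0.0)
        assert min_pair_distance(a, b, method="points") == pytest.approx(np.sqrt(2))


class TestNearestNeighborSamples:
    def test_collinear_origins(self):
        origins = np.array([[0.0, 0, 0], [5, 0, 0], [12, 0, 0]])
        df = nn_origin_distances(origins, ["a", "b", "c"])
        assert df["distance"].tolist() == pytest.approx([5.0, 5.0, 7.0])
        assert df["neighbor_id"].tolist() == ["b", "a", "b"]

    def test_duplicate_origins_give_zero(self):
        origins = np.array([[1.0, 1, 1], [1, 1, 1]])
        df = nn_origin_distances(origins, ["a", "b"])
        assert df["distance"].tolist() == pytest.approx([0.0, 0.0])

    def test_singleton_site_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            df = nn_origin_distances(np.array([[0.0, 0, 0]]), ["a"])
        assert df.empty

    def test_whole_length_closer_than_origins(self):
        # origins 6 nm apart but tips approach to 1 nm
        a = _fil([[0, 0, 0], [0, 0, 50]], "a")
        b = _fil([[6, 0, 0], [1, 0, 50]], "b")
        df = nn_filament_distances([a, b])
        assert df["distance"].tolist() == pytest.approx([1.0, 1.0])

    def test_filament_nn_matches_brute_force(self, rng):
        fils = [
            _fil(random_polyline(rng, 10) + [80 * k, 0, 0], f"f{k}") for k in range(4)
        ]
        df = nn_filament_distances(fils)
        for i, fil in enumerate(fils):
            expected = min(
                min_pair_distance(fil, other)
                for j, other in enumerate(fils)
                if j != i
            )
            assert df["distance"].iloc[i] == pytest.approx(expected)

    def test_global_min_filament_le_origin(self, rng):
        """Origins are member points, so the site-wide minimum whole-filament
        distance cannot exceed the site-wide minimum origin distance."""
        fils = [_fil(random_polyline(rng, 12) + [30 * k, 0, 0], f"f{k}") for k in range(5)]
        origins = np.vstack([f.points[0] for f in fils])
        d_orig = nn_origin_distances(origins, [f.filament_id for f in fils])
        d_fil = nn_filament_distances(fils)
        assert d_fil["distance"].min() <= d_orig["distance"].min() + 1e-9

    def test_rigid_motion_invariance(self, rng):
        fils = [_fil(random_polyline(rng, 10) + [50 * k, 0, 0], f"f{k}") for k in range(3)]
        rot, shift = random_rotation(rng), rng.uniform(-20, 20, 3)
        moved = [_fil(f.points @ rot.T + shift, f.filament_id) for f in fils]
        d0 = nn_filament_distances(fils)["distance"].to_numpy()
        d1 = nn_filament_distances(moved)["distance"].to_numpy()
        np.testing.assert_allclose(d0, d1, rtol=1e-9)


class TestGlobalMinimumShift:
    def test_sample_minimum_is_headline(self):
        fit = global_minimum_shift([5.1, 6.0, 9.7])
        assert fit.shift == pytest.approx(5.1)
        assert not fit.degenerate

    def test_parametric_recovery(self, rng):
        x = 5.0 + rng.exponential(scale=1 / 0.2, size=800)
        fit = global_minimum_shift(x)
        assert abs(fit.shift - 5.0) < 0.2
        assert abs(fit.rate - 0.2) / 0.2 < 0.10

    def test_degenerate_all_equal_flagged(self):
        fit = global_minimum_shift([3.0, 3.0, 3.0])
        assert fit.shift == pytest.approx(3.0)
        assert fit.degenerate and np.isnan(fit.rate)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            global_minimum_shift([])


class TestDensityCurve:
    def test_unimodal_lengths(self, rng):
        x = rng.normal(91, 18, size=800)
        grid, dens = density_curve(x)
        assert count_modes(grid, dens) == 1
        assert abs(grid[np.argmax(dens)] - 91) < 3.0

    def test_integrates_to_one(self, rng):
        grid, dens = density_curve(rng.normal(0, 1, 500))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)

    def test_bimodal_mixture_detected(self, rng):
        x = np.concatenate([rng.normal(60, 5, 400), rng.normal(120, 5, 400)])
        grid, dens = density_curve(x)
        assert count_modes(grid, dens) == 2

    def test_two_points_small_bandwidth(self):
        grid, dens = density_curve([0.0, 100.0], bandwidth=5.0)
        assert count_modes(grid, dens) == 2

    def test_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            density_curve([1.0, 1.0, 1.0])
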