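import numpy as np
import pytest

from lincquant import (
    Filament,
    ValidationError,
    classify_by_cutoff,
    cutoff_scan,
    distance_to_microtubule,
    rippled_polyline,
    stretch_cohort_compare,
)

from conftest import random_polyline


def straight_axis(y=0.0, z=0.0, length=400.0):
    xs = np.linspace(-length / 2, length / 2, 9)
    return np.column_stack([xs, np.full_like(xs, y), np.full_like(xs, z)])


class TestDistanceToMicrotubule:
    def test_parallel_straight_filament(self):
        fil = Filament("f", [[0, 30, 0], [50, 30, 0]])
        assert distance_to_microtubule(fil, straight_axis()) == pytest.approx(30.0)

    def test_touching_filament(self):
        fil = Filament("f", [[0, 0, 0], [0, 50, 0]])
        assert distance_to_microtubule(fil, straight_axis()) == pytest.approx(0.0)

    def test_between_axis_vertices(self):
        # the closest approach lies mid-segment, so vertex-only distances overshoot
        fil = Filament("f", [[10.0, 20, 0], [10.0, 40, 0]])
        axis = np.array([[0.0, 0, 0], [20.0, 0, 0]])
        assert distance_to_microtubule(fil, axis) == pytest.approx(20.0)

    def test_no_microtubule_returns_absent(self):
        fil = Filament("f", [[0, 0, 0], [1, 1, 1]])
        assert distance_to_microtubule(fil, None) is None

    def test_matches_dense_resampling_oracle(self, rng):
        """Axis resampled at 0.1 nm: point-to-point distance converges to the
        point-to-segment result."""
        for _ in range(10):
            fil = random_polyline(rng, 10) + [0, 60, 0]
            axis = np.cumsum(rng.normal(size=(6, 3)) * 20, axis=0)
            dense = []
            for a, b in zip(axis[:-1], axis[1:]):
                seg_len = np.linalg.norm(b - a)
                ts = np.linspace(0, 1, max(2, int(seg_len / 0.1)))
                dense.append(a + np.outer(ts, b - a))
            dense = np.vstack(dense)
            oracle = min(
                np.linalg.norm(dense - p, axis=1).min() for p in fil
            )
            got = distance_to_microtubule(Filament("f", fil), axis)
            assert got == pytest.approx(oracle, abs=0.1)


class TestClassifyByCutoff:
    def test_boundary_is_exclusive(self):
        close = classify_by_cutoff([50, 99.9, 100, 140], cutoff=100)
        assert close.tolist() == [True, True, False, False]

    def test_cutoff_below_all_warns(self):
        with pytest.warns(UserWarning):
            close = classify_by_cutoff([50, 60], cutoff=10)
        assert not close.any()

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValidationError):
            classify_by_cutoff([1.0], cutoff=0)


class TestCutoffScan:
    def test_all_equal_distances_all_rows_undefined(self):
        scan = cutoff_scan([50.0] * 6, np.arange(6.0), cutoffs=[20, 50, 80])
        assert scan["mean_difference"].isna().all()

    def test_known_effect_recovered(self, rng):
        """Constructed cohort: +4 nm boost on linear distance inside 100 nm."""
        n = 400
        d = rng.uniform(0, 300, n)
        lin = 70 + 4.0 * (d < 100) + rng.normal(0, 8, n)
        scan = cutoff_scan(d, lin, cutoffs=[100.0, 250.0])
        at100 = scan[scan.cutoff == 100.0].iloc[0]
        assert at100["mean_difference"] == pytest.approx(4.0, abs=1.0)
        assert at100["wilcoxon_p"] < 0.01
        # far beyond the boost radius the contrast is diluted
        at250 = scan[scan.cutoff == 250.0].iloc[0]
        assert at250["mean_difference"] < at100["mean_difference"]

    def test_mean_difference_antisymmetric(self, rng):
        d = rng.uniform(0, 200, 100)
        lin = rng.normal(70, 10, 100)
        scan = cutoff_scan(d, lin, cutoffs=[100.0])
        swapped = cutoff_scan(200.0 - d, lin, cutoffs=[100.0])
        # swapping close/far (reflecting distances) negates the difference
        assert scan["mean_difference"].iloc[0] == pytest.approx(
            -swapped["mean_difference"].iloc[0], abs=1e-9
        )

    def test_empty_cutoff_list_rejected(self):
        with pytest.raises(ValidationError):
            cutoff_scan([1.0], [1.0], cutoffs=[])

    def test_null_centered_without_boost(self, rng):
        """With no generating effect, scan differences centre on zero."""
        diffs = []
        for _ in range(20):
            d = rng.uniform(0, 300, 200)
            lin = rng.normal(70, 10, 200)
            scan = cutoff_scan(d, lin, cutoffs=[100.0])
            diffs.append(scan["mean_difference"].iloc[0])
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 2 * se + 0.5


class TestStretchCohortCompare:
    def test_identical_cohorts_zero_difference(self, rng):
        x = rng.uniform(0.6, 0.9, 50)
        cmp = stretch_cohort_compare(x, x.copy())
        assert cmp.mean_difference == pytest.approx(0.0)
        assert cmp.test.p_value == pytest.approx(1.0)

    def test_generator_cohort_difference_recovered(self, rng):
        """Rippled filaments at stretch targets 0.80 vs 0.77 (n = 380 each)."""
        def cohort(target, n=380):
            vals = []
            for _ in range(n):
                fil = rippled_polyline(
                    np.zeros(3), [0, 0, 1.0], 90.0, target, 4.0, rng
                )
                from lincquant import stretch_factor

                vals.append(stretch_factor(fil))
            return np.array(vals)

        cmp = stretch_cohort_compare(cohort(0.80), cohort(0.77))
        assert cmp.mean_difference == pytest.approx(0.03, abs=0.01)
        assert cmp.test.p_value < 1e-6

    def test_single_filament_cohort_warns_but_reports_means(self):
        with pytest.warns(UserWarning):
            cmp = stretch_cohort_compare([0.8], [0.7])
        assert cmp.mean_with_mt == pytest.approx(0.8)
        assert cmp.density_with_mt is None

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            stretch_cohort_compare([], [0.5])
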