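import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from hypothesis.extra.numpy import arrays

from lincquant import (
    Filament,
    StructurePointSet,
    ValidationError,
    assign_plates,
    find_origin,
    linear_distance,
    path_length,
    stretch_factor,
)
from lincquant.synthetic import SyntheticConfig, generate_cohort

from conftest import random_polyline, random_rotation


def _le(points):
    return StructurePointSet("lateral_element", points)


class TestPathAndLinearDistance:
    def test_single_segment(self):
        f = Filament("f", [[0, 0, 0], [0, 0, 90]])
        assert path_length(f) == pytest.approx(90.0)
        assert linear_distance(f) == pytest.approx(90.0)
        assert stretch_factor(f) == pytest.approx(1.0)

    def test_right_angle_path(self):
        f = Filament("f", [[0, 0, 0], [3, 4, 0], [3, 4, 12]])
        assert path_length(f) == pytest.approx(17.0)  # 5 + 12

    def test_closed_path_has_zero_linear_distance(self):
        f = Filament("f", [[0, 0, 0], [10, 0, 0], [0, 0, 0]])
        assert linear_distance(f) == pytest.approx(0.0)
        assert stretch_factor(f) == pytest.approx(0.0)

    def test_stretch_right_angle(self):
        f = Filament("f", [[0, 0, 0], [10, 0, 0], [10, 10, 0]])
        assert stretch_factor(f) == pytest.approx(np.sqrt(200) / 20)

    def test_path_length_matches_loop_oracle(self, rng):
        for _ in range(20):
            pts = random_polyline(rng)
            total = 0.0
            for i in range(len(pts) - 1):  # independent brute-force summation
                total += float(np.sqrt(((pts[i + 1] - pts[i]) ** 2).sum()))
            assert path_length(Filament("f", pts)) == pytest.approx(total, rel=1e-12)
            assert linear_distance(Filament("f", pts)) == pytest.approx(
                float(np.sqrt(((pts[-1] - pts[0]) ** 2).sum()))
            )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            path_length(np.array([[0.0, 0.0, 0.0]]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            hst.tuples(hst.integers(2, 15), hst.just(3)),
            elements=hst.floats(-1e3, 1e3),
        )
    )
    def test_linear_never_exceeds_path(self, pts):
        """Triangle inequality: end-to-end <= arc length, so stretch <= 1."""
        if not np.linalg.norm(np.diff(pts, axis=0), axis=1).sum() > 0:
            return
        f = Filament("f", pts)
        assert linear_distance(f) <= path_length(f) + 1e-9
        assert 0.0 <= stretch_factor(f) <= 1.0 + 1e-12

    def test_rigid_motion_invariance(self, rng):
        pts = random_polyline(rng)
        f = Filament("f", pts)
        rot, shift = random_rotation(rng), rng.uniform(-100, 100, 3)
        g = Filament("g", pts @ rot.T + shift)
        assert path_length(g) == pytest.approx(path_length(f))
        assert linear_distance(g) == pytest.approx(linear_distance(f))
        assert stretch_factor(g) == pytest.approx(stretch_factor(f))


class TestFindOrigin:
    def test_endpoint_nearest_lateral_element(self):
        f = Filament("f", [[0, 0, 0], [0, 0, 50]])
        res = find_origin(f, _le([[0, 0, -10]]))
        np.testing.assert_allclose(res.origin, [0, 0, 0])
        assert res.origin_index == 0

    def test_reversed_storage_same_origin(self):
        pts = np.array([[0.0, 0, 0], [0, 0, 25], [0, 0, 50]])
        le = _le([[0, 0, -10]])
        fwd = find_origin(Filament("f", pts), le)
        rev = find_origin(Filament("r", pts[::-1]), le)
        np.testing.assert_allclose(rev.origin, fwd.origin)
        # after re-orientation the origin leads in both cases
        np.testing.assert_allclose(rev.filament.points[0], fwd.filament.points[0])

    def test_tie_breaks_to_lowest_index(self):
        # both endpoints equidistant to the single reference point
        f = Filament("f", [[-5.0, 0, 0], [0, 0, 7], [5, 0, 0]])
        res = find_origin(f, _le([[0.0, 0, 0]]))
        assert res.origin_index == 0

    def test_matches_exhaustive_search(self, rng):
        """Brute-force double loop over all (filament, reference) point pairs."""
        for _ in range(30):
            pts = random_polyline(rng, n_points=12)
            le_pts = rng.uniform(-60, 60, size=(40, 3))
            best_idx, best_d = None, np.inf
            for i, p in enumerate(pts):
                for q in le_pts:
                    d = float(np.sqrt(((p - q) ** 2).sum()))
                    if d < best_d - 1e-12:
                        best_d, best_idx = d, i
            res = find_origin(Filament("f", pts), _le(le_pts))
            assert res.origin_index == best_idx
            assert res.distance == pytest.approx(best_d)

    def test_empty_reference_rejected(self):
        f = Filament("f", [[0, 0, 0], [0, 0, 1]])
        with pytest.raises(ValidationError):
            find_origin(f, None)


class TestAssignPlates:
    def test_well_separated_clusters_recovered(self, rng):
        a = rng.normal(scale=3.0, size=(20, 3))
        b = rng.normal(scale=3.0, size=(25, 3)) + [200, 0, 0]
        labels = assign_plates(np.vstack([a, b]))
        assert (labels[:20] == 0).all() and (labels[20:] == 1).all()

    def test_origins_on_plate_centroids(self):
        plates = StructurePointSet(
            "attachment_plate",
            np.array([[0.0, 0, 0], [1, 0, 0], [250, 0, 0], [251, 0, 0]]),
        )
        labels = assign_plates(np.array([[0.5, 0, 0], [250.5, 0, 0]]), plates)
        assert labels.tolist() == [0, 1]

    def test_single_origin_warns(self):
        with pytest.warns(UserWarning):
            labels = assign_plates(np.array([[0.0, 0, 0]]))
        assert labels.tolist() == [0]

    def test_generator_ground_truth_agreement(self):
        """>= 95% agreement with the generating plate labels across seeds."""
        total, agree = 0, 0
        for seed in range(5):
            cfg = SyntheticConfig(
                n_sites=2, filament_counts="normal", count_mean=40, seed=seed
            )
            cohort = generate_cohort(cfg)
            from lincquant import quantify_sites

            metrics, _ = quantify_sites(cohort.models)
            merged = metrics.merge(
                cohort.ground_truth, on=["site_id", "filament_id"],
                suffixes=("_measured", "_truth"),
            )
            total += len(merged)
            agree += (merged["plate_id_measured"] == merged["plate_id_truth"]).sum()
        assert agree / total >= 0.95
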