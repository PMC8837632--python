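import numpy as np
import pandas as pd
import pytest

from tlomap import (
    aggregate_cells_to_spots,
    annotation_overlap,
    density_score,
    interpolate_grid,
    interpolate_volume,
    register_sections,
)
from tlomap.errors import EmptyResultError, ParameterError, SchemaError, ValidationError
from tlomap.spatial3d import _fit_similarity


def spot_frame(x, y, section="s0", z=0.0):
    return pd.DataFrame(
        {
            "barcode": [f"{section}_b{i}" for i in range(len(x))],
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
            "section_id": section,
            "z": z,
        }
    )


class TestAggregate:
    def test_cell_at_spot_center_counted(self):
        spots = spot_frame([100.0], [100.0])
        cells = pd.DataFrame({"x": [100.0], "y": [100.0], "area": [30.0],
                              "section_id": ["s0"]})
        out = aggregate_cells_to_spots(cells, spots, window_px=200)
        assert out.loc[0, "cell_count"] == 1
        assert out.loc[0, "mean_area"] == 30.0

    def test_empty_cell_table_flags_all_spots(self):
        spots = spot_frame([0, 200], [0, 0])
        cells = pd.DataFrame(columns=["x", "y", "area", "section_id"])
        out = aggregate_cells_to_spots(cells, spots)
        assert not out["keep"].any()

    def test_counts_match_bruteforce_point_in_square(self):
        rng = np.random.default_rng(0)
        spots = spot_frame([100, 300, 100, 300], [100, 100, 300, 300])
        cx, cy = rng.uniform(0, 400, 20), rng.uniform(0, 400, 20)
        cells = pd.DataFrame({"x": cx, "y": cy, "area": 50.0, "section_id": "s0"})
        out = aggregate_cells_to_spots(cells, spots, window_px=200)
        for i, row in spots.iterrows():
            inside = (np.abs(cx - row.x) <= 100) & (np.abs(cy - row.y) <= 100)
            assert out.loc[i, "cell_count"] == inside.sum()

    def test_unknown_section_rejected(self):
        spots = spot_frame([0.0], [0.0])
        cells = pd.DataFrame({"x": [0.0], "y": [0.0], "area": [1.0],
                              "section_id": ["elsewhere"]})
        with pytest.raises(SchemaError):
            aggregate_cells_to_spots(cells, spots)


class TestDensityScore:
    def _frame(self, counts, section="s0"):
        return pd.DataFrame({"section_id": section, "cell_count": counts})

    def test_hand_ranked_percentiles_and_threshold(self):
        out = density_score(self._frame([1, 2, 3, 4, 5]))
        np.testing.assert_allclose(out["density_score"], [0, 25, 50, 75, 100])
        assert out["is_tlo"].sum() == 2  # strictly above 70

    def test_all_ties_score_fifty_none_flagged(self):
        out = density_score(self._frame([7, 7, 7, 7]))
        np.testing.assert_allclose(out["density_score"], 50.0)
        assert not out["is_tlo"].any()

    def test_single_spot_scores_fifty(self):
        out = density_score(self._frame([42]))
        assert out["density_score"].iloc[0] == 50.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 100, 30)
        base = density_score(self._frame(counts))
        squashed = density_score(self._frame(np.sqrt(counts + 1.0)))
        np.testing.assert_allclose(base["density_score"], squashed["density_score"])

    def test_percentile_properties_hold_for_arbitrary_counts(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(st.lists(st.integers(min_value=0, max_value=10**6),
                        min_size=2, max_size=40))
        def check(counts):
            out = density_score(self._frame(counts))
            scores = out["density_score"].to_numpy()
            counts = np.asarray(counts)
            assert scores.min() >= 0.0 and scores.max() <= 100.0
            # monotone: a strictly larger count never scores lower
            order = np.argsort(counts)
            assert (np.diff(scores[order]) >= -1e-9).all()

        check()

    def test_sections_ranked_independently(self):
        frame = pd.concat(
            [self._frame([1, 2, 3]), self._frame([100, 200, 300], section="s1")],
            ignore_index=True,
        )
        out = density_score(frame)
        np.testing.assert_allclose(out["density_score"], [0, 50, 100, 0, 50, 100])


class TestAnnotationOverlap:
    def test_trivial_fractions(self):
        d = density_score(pd.DataFrame({"section_id": "s0",
                                        "cell_count": [1, 2, 3, 4, 5]}))
        ann_all = np.array(["infiltrate"] * 2 + ["other"] * 3)
        # two annotated spots are the two lowest-density ones -> none flagged
        assert annotation_overlap(d, ann_all) == 0.0
        ann_top = np.array(["other"] * 3 + ["infiltrate"] * 2)
        assert annotation_overlap(d, ann_top) == 1.0

    def test_no_annotations_raises(self):
        d = density_score(pd.DataFrame({"section_id": "s0", "cell_count": [1, 2]}))
        with pytest.raises(EmptyResultError):
            annotation_overlap(d, np.array(["other", "other"]))


def _similarity(pts, theta_deg, scale, tx, ty):
    th = np.deg2rad(theta_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return scale * pts @ R.T + np.array([tx, ty])


class TestRegistration:
    def _two_sections(self, theta=10.0, scale=1.05, t=(3.0, -2.0), n=200, seed=0):
        rng = np.random.default_rng(seed)
        P = rng.uniform(0, 4000, (n, 2))
        Q = _similarity(P, theta, scale, *t)
        return pd.concat(
            [spot_frame(P[:, 0], P[:, 1], "s0", 0.0),
             spot_frame(Q[:, 0], Q[:, 1], "s1", 7.0)],
            ignore_index=True,
        )

    def test_identical_section_gets_identity(self):
        spots = self._two_sections(theta=0.0, scale=1.0, t=(0.0, 0.0))
        vol = register_sections(spots, "rigid")
        tf = vol.transforms["s1"]
        assert abs(tf.theta) < 1e-9 and abs(tf.tx) < 1e-9 and abs(tf.ty) < 1e-9
        assert tf.scale == 1.0
        assert vol.transforms["s0"].theta == 0.0  # reference stays identity

    def test_known_similarity_recovered(self):
        spots = self._two_sections()
        vol = register_sections(spots, "scaled_rotation")
        tf = vol.transforms["s1"]  # maps s1 back onto s0: the inverse map
        assert abs(tf.theta - np.deg2rad(-10.0)) < 1e-6
        assert abs(tf.scale - 1 / 1.05) < 1e-6
        assert tf.rmsd < 1e-6
        # forward parameters from inverting the recovered transform
        R = np.array([[np.cos(tf.theta), -np.sin(tf.theta)],
                      [np.sin(tf.theta), np.cos(tf.theta)]])
        t_fwd = -np.linalg.inv(tf.scale * R) @ np.array([tf.tx, tf.ty])
        np.testing.assert_allclose(t_fwd, [3.0, -2.0], atol=1e-6)

    def test_rigid_mode_forces_unit_scale(self):
        spots = self._two_sections()
        vol = register_sections(spots, "rigid")
        tf = vol.transforms["s1"]
        assert tf.scale == 1.0
        assert tf.rmsd > 1.0  # the 5% scale mismatch cannot be absorbed

    def test_icp_matches_closed_form_procrustes(self):
        rng = np.random.default_rng(3)
        P = rng.uniform(0, 1000, (80, 2))
        Q = _similarity(P, -25.0, 0.9, 50.0, 10.0)
        direct = _fit_similarity(Q, P, with_scale=True)  # known correspondence
        spots = pd.concat(
            [spot_frame(P[:, 0], P[:, 1], "s0"), spot_frame(Q[:, 0], Q[:, 1], "s1")],
            ignore_index=True,
        )
        vol = register_sections(spots, "scaled_rotation")
        tf = vol.transforms["s1"]
        assert tf.theta == pytest.approx(direct.theta, abs=1e-9)
        assert tf.scale == pytest.approx(direct.scale, abs=1e-9)
        assert tf.rmsd == pytest.approx(direct.rmsd, abs=1e-9)

    def test_collinear_landmarks_rejected(self):
        x = np.arange(10.0)
        spots = pd.concat(
            [spot_frame(x, 2 * x, "s0"), spot_frame(x, 2 * x + 1, "s1")],
            ignore_index=True,
        )
        with pytest.raises(ValidationError, match="collinear"):
            register_sections(spots, "rigid")

    def test_single_section_rejected(self):
        with pytest.raises(ParameterError):
            register_sections(spot_frame([0, 1, 2], [0, 1, 0]), "rigid")


class TestInterpolation:
    def _points(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(0, 100, (n, 2))

    def test_constant_field_reproduced(self):
        pts = self._points()
        out = interpolate_grid(np.full(len(pts), 3.5), pts, grid_step=5.0)
        grid = out["grid"]
        assert np.allclose(grid.compressed(), 3.5)
        assert grid.mask.any()  # corners outside the hull are masked

    def test_linear_field_reproduced_exactly(self):
        pts = self._points()
        values = 2 * pts[:, 0] + pts[:, 1]
        out = interpolate_grid(values, pts, grid_step=4.0)
        XX, YY = np.meshgrid(out["x"], out["y"])
        expected = 2 * XX + YY
        diff = np.abs(out["grid"] - expected)
        assert diff.max() < 1e-9

    def test_exact_at_spot_locations(self):
        from scipy.interpolate import LinearNDInterpolator

        pts = self._points(seed=4)
        values = np.random.default_rng(4).normal(size=len(pts))
        interp = LinearNDInterpolator(pts, values)
        np.testing.assert_allclose(interp(pts), values, atol=1e-12)

    def test_collinear_spots_rejected(self):
        x = np.arange(6.0)
        with pytest.raises(ValidationError):
            interpolate_grid(x, np.column_stack([x, 2 * x]), grid_step=1.0)

    def test_volume_slices_match_single_section_result(self):
        rng = np.random.default_rng(5)
        frames = []
        for s, z in (("s0", 0.0), ("s1", 7.0)):
            pts = rng.uniform(0, 500, (40, 2))
            frames.append(spot_frame(pts[:, 0], pts[:, 1], s, z))
        spots = pd.concat(frames, ignore_index=True)
        vol = register_sections(spots, "rigid")
        values = pd.Series(rng.normal(size=len(spots)))
        vol = interpolate_volume(vol, values, grid_step=25.0, name="score")
        assert set(vol.grids["score"]) == {"s0", "s1"}
        for sec in ("s0", "s1"):
            idx = vol.spots.index[vol.spots.section_id == sec]
            pts = vol.spots.loc[idx, ["x_reg", "y_reg"]].to_numpy()
            single = interpolate_grid(values[idx].to_numpy(), pts, 25.0)
            np.testing.assert_allclose(
                vol.grids["score"][sec]["grid"].filled(np.nan),
                single["grid"].filled(np.nan),
            )
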