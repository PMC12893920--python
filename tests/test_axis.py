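"""Axis construction: relative-distance assignment, stitching, rescaling,
binning and their invariances."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare, spearmanr

from axistk.axis import (
    AffineTransform2D,
    AxisAssignment,
    assign_axis_relative_distance,
    bin_axis,
    rescale_axis,
    stitch_sections,
)
from axistk.errors import (
    InvalidAnchorError,
    InvalidTransformError,
    LandmarkNotFoundError,
)
from axistk.synthetic import split_into_sections


def _line_dataset(xs, landmarks):
    n = len(xs)
    adata = ad.AnnData(
        X=np.ones((n, 2)),
        obs=pd.DataFrame(
            {"landmark_label": landmarks, "section_id": ["S0"] * n},
            index=[f"u{i}" for i in range(n)],
        ),
    )
    adata.obsm["spatial"] = np.column_stack([np.asarray(xs, float), np.zeros(n)])
    return adata


class TestAssignAxis:
    def test_landmark_units_at_bounds(self):
        ds = _line_dataset([0.0, 1.0, 4.0], ["R", None, "C"])
        a = assign_axis_relative_distance(ds, "R", "C", method="euclidean")
        assert a.value[0] == 0.0
        assert a.value[2] == 1.0

    def test_collinear_quarter_point(self):
        """d_R = 1, d_C = 3 gives 1 / (1 + 3) = 0.25."""
        ds = _line_dataset([0.0, 1.0, 4.0], ["R", None, "C"])
        a = assign_axis_relative_distance(ds, "R", "C", method="euclidean")
        assert a.value[1] == pytest.approx(0.25)

    def test_missing_landmark_error(self):
        ds = _line_dataset([0.0, 1.0], ["R", None])
        with pytest.raises(LandmarkNotFoundError):
            assign_axis_relative_distance(ds, "R", "C")

    def test_recovers_arclength_on_curved_tube(self, tube_bundle):
        adata, truth = tube_bundle
        a = assign_axis_relative_distance(adata, "rostral_tip", "caudal_tip")
        rho = spearmanr(a.value, truth.true_axis.to_numpy()).statistic
        assert rho >= 0.95  # small fixture; the full-scale bound is checked at n=2000

    def test_rigid_transform_invariance(self, tube_bundle):
        adata, _ = tube_bundle
        a = assign_axis_relative_distance(adata, "rostral_tip", "caudal_tip")
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = adata.copy()
        moved.obsm["spatial"] = adata.obsm["spatial"] @ R.T + np.array([50.0, -20.0])
        b = assign_axis_relative_distance(moved, "rostral_tip", "caudal_tip")
        np.testing.assert_allclose(a.value, b.value, atol=1e-9)

    def test_unit_order_independence(self, tube_bundle):
        adata, _ = tube_bundle
        a = assign_axis_relative_distance(adata, "rostral_tip", "caudal_tip")
        perm = np.random.default_rng(3).permutation(adata.n_obs)
        b = assign_axis_relative_distance(adata[perm].copy(), "rostral_tip", "caudal_tip")
        np.testing.assert_allclose(
            a.to_series().loc[adata.obs_names[perm]].to_numpy(), b.value, atol=1e-9
        )

    def test_mask_marks_units_missing(self, tube_bundle):
        adata, _ = tube_bundle
        mask = np.ones(adata.n_obs, dtype=bool)
        mask[:10] = False
        a = assign_axis_relative_distance(
            adata, "rostral_tip", "caudal_tip", mask=mask
        )
        assert np.isnan(a.value[:10]).all()
        assert not np.isnan(a.value[10:]).any()


class TestStitchSections:
    def test_identity_transforms_concatenate(self, tube_bundle):
        adata, truth = tube_bundle
        import copy

        truth = copy.deepcopy(truth)
        secs = split_into_sections(adata, truth, [], seed=1)
        out = stitch_sections(secs, [AffineTransform2D.identity()])
        assert out.n_obs == adata.n_obs
        np.testing.assert_allclose(
            out[adata.obs_names].obsm["spatial"], adata.obsm["spatial"]
        )

    def test_pure_translation_shifts_x(self):
        ds1 = _line_dataset([0.0, 1.0], [None, None])
        ds2 = _line_dataset([0.0, 2.0], [None, None])
        ds2.obs_names = ["v0", "v1"]
        tr = AffineTransform2D(np.array([[1.0, 0, 100.0], [0, 1.0, 0]]))
        out = stitch_sections([ds1, ds2], [AffineTransform2D.identity(), tr])
        np.testing.assert_allclose(
            out[["v0", "v1"]].obsm["spatial"][:, 0], [100.0, 102.0]
        )

    def test_round_trip_matches_never_split(self, tube_bundle):
        import copy

        adata, truth = tube_bundle
        truth = copy.deepcopy(truth)
        direct = assign_axis_relative_distance(adata, "rostral_tip", "caudal_tip")
        secs = split_into_sections(adata, truth, [0.4, 0.8], seed=13)
        stitched = stitch_sections(
            secs,
            [truth.section_transforms[f"S{k}"] for k in range(3)],
        )
        stitched = stitched[adata.obs_names]
        np.testing.assert_allclose(
            stitched.obsm["spatial"], adata.obsm["spatial"], atol=1e-9
        )
        redone = assign_axis_relative_distance(
            stitched.copy(), "rostral_tip", "caudal_tip"
        )
        np.testing.assert_allclose(redone.value, direct.value, atol=1e-9)

    def test_singular_transform_rejected(self):
        with pytest.raises(InvalidTransformError):
            AffineTransform2D(np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0]]))


class TestRescaleAxis:
    def _assignment(self, values):
        return AxisAssignment(
            unit_ids=np.array([f"u{i}" for i in range(len(values))]),
            value=np.asarray(values, dtype=float),
        )

    def test_no_anchors_identity(self):
        a = self._assignment([0.0, 0.3, 1.0])
        out = rescale_axis(a, [])
        np.testing.assert_allclose(out.value, a.value)

    def test_single_anchor_piecewise_linear(self):
        a = self._assignment([0.5, 0.75])
        out = rescale_axis(a, [(0.5, 0.4)])
        assert out.value[0] == pytest.approx(0.4)
        assert out.value[1] == pytest.approx(0.7)

    def test_non_monotone_anchors_rejected(self):
        a = self._assignment([0.5])
        with pytest.raises(InvalidAnchorError):
            rescale_axis(a, [(0.3, 0.6), (0.6, 0.5)])

    @settings(max_examples=50, deadline=None)
    @given(
        anchors=st.lists(
            st.tuples(
                st.floats(0.05, 0.95), st.floats(0.05, 0.95)
            ),
            max_size=3,
        ),
        pair=st.tuples(st.floats(0, 1), st.floats(0, 1)),
    )
    def test_monotonicity_preserved(self, anchors, pair):
        anchors = sorted(set(anchors))
        xs = [p[0] for p in anchors]
        ys = [p[1] for p in anchors]
        if sorted(set(xs)) != xs or sorted(set(ys)) != ys:
            return  # invalid anchor set, covered by the rejection test
        a, b = min(pair), max(pair)
        out = rescale_axis(self._assignment([a, b]), anchors)
        assert out.value[0] <= out.value[1] + 1e-12
        assert 0.0 <= out.value.min() and out.value.max() <= 1.0

    def test_endpoints_fixed(self):
        out = rescale_axis(self._assignment([0.0, 1.0]), [(0.5, 0.2)])
        assert out.value[0] == 0.0 and out.value[1] == 1.0


class TestBinAxis:
    def _assignment(self, values):
        return AxisAssignment(
            unit_ids=np.array([f"u{i}" for i in range(len(values))]),
            value=np.asarray(values, dtype=float),
        )

    def test_boundaries(self):
        bins = bin_axis(self._assignment([0.0, 1.0, 0.5]), n_bins=20)
        assert bins.iloc[0] == 0
        assert bins.iloc[1] == 19
        assert bins.iloc[2] == 10

    def test_missing_stays_missing(self):
        bins = bin_axis(self._assignment([0.2, np.nan]), n_bins=10)
        assert bins.iloc[0] == 2
        assert pd.isna(bins.iloc[1])

    def test_uniform_values_fill_bins_evenly(self, rng):
        v = rng.uniform(0, 1, 4000)
        bins = bin_axis(self._assignment(v), n_bins=20)
        counts = bins.value_counts().sort_index().to_numpy()
        assert chisquare(counts).pvalue > 0.01

    def test_invalid_bin_count(self):
        with pytest.raises(ValueError):
            bin_axis(self._assignment([0.5]), n_bins=1)
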