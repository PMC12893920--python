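"""Negative-binomial spline models of expression along the axis."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from axistk.axis import AxisAssignment, assign_axis_relative_distance
from axistk.svg import (
    GeneAxisModel,
    association_test,
    binned_minmax_profiles,
    bspline_basis,
    classify_pattern,
    detect_spatially_variable_genes,
    fit_gene_axis_model,
)


@pytest.fixture(scope="module")
def strong_bundle():
    """Tube with strong (1.5 log2) gradients for recovery checks."""
    from axistk.synthetic import generate_tube_organ

    return generate_tube_organ(500, 100, 0.3, amplitude=1.5, seed=19)


@pytest.fixture(scope="module")
def design(rng_seed=17):
    rng = np.random.default_rng(rng_seed)
    n = 500
    s = rng.uniform(0, 1, n)
    sf = np.exp(rng.normal(0, 0.3, n))
    return rng, n, s, sf


def _nb_draw(rng, mu, dispersion):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def test_basis_shape_and_partition(design):
    _, n, s, _ = design
    B, _ = bspline_basis(s, 5)
    assert B.shape == (n, 5)
    B1, _ = bspline_basis(s, 1)
    np.testing.assert_allclose(B1.ravel(), s, atol=1e-12)


def test_all_zero_gene_flat_model(design):
    _, n, s, sf = design
    m = fit_gene_axis_model(np.zeros(n), s, sf, 5)
    assert m.lrt_stat == 0.0 and m.p_value == 1.0 and m.log2_amplitude == 0.0


def test_linear_basis_matches_direct_glm_slope_test(design):
    """With spline_df = 1 the LRT equals an NB-GLM slope test computed by
    the generic statsmodels route directly."""
    rng, n, s, sf = design
    mu = sf * 5.0 * 2 ** (1.2 * s)
    y = _nb_draw(rng, mu, 0.5)
    m = fit_gene_axis_model(y, s, sf, 1, dispersion=0.5)
    fam = sm.families.NegativeBinomial(alpha=0.5)
    X = np.column_stack([np.ones(n), s])
    full = sm.GLM(y, X, family=fam, offset=np.log(sf)).fit()
    null = sm.GLM(y, np.ones((n, 1)), family=fam, offset=np.log(sf)).fit()
    assert m.lrt_stat == pytest.approx(2 * (full.llf - null.llf), abs=1e-6)


def test_amplitude_recovery_log_linear_gradient(design):
    """Genes with a 1 log2-fold gradient recover amplitude near 1."""
    rng, n, s, sf = design
    amps = []
    for _ in range(30):
        mu = sf * 8.0 * 2 ** (1.0 * (1 - s))
        y = _nb_draw(rng, mu, 0.3)
        amps.append(fit_gene_axis_model(y, s, sf, 5).log2_amplitude)
    assert 0.8 <= np.mean(amps) <= 1.2


def test_null_amplitude_small_on_average(design):
    rng, n, s, sf = design
    amps = []
    for _ in range(30):
        y = rng.poisson(sf * 20.0)
        amps.append(fit_gene_axis_model(y, s, sf, 5).log2_amplitude)
    assert np.mean(amps) < 0.2


def test_strong_gradient_extreme_p(design):
    rng, n, s, sf = design
    hits = 0
    for _ in range(20):
        mu = sf * 20.0 * 2 ** (2.0 * s)
        y = _nb_draw(rng, mu, 0.5)
        if fit_gene_axis_model(y, s, sf, 5).p_value < 1e-6:
            hits += 1
    assert hits >= 19


def test_lrt_invariant_to_size_factor_scale(design):
    rng, n, s, sf = design
    mu = sf * 5.0 * 2 ** (1.0 * s)
    y = _nb_draw(rng, mu, 0.5)
    m1 = fit_gene_axis_model(y, s, sf, 5, dispersion=0.5)
    m2 = fit_gene_axis_model(y, s, sf * 7.5, 5, dispersion=0.5)
    assert m1.lrt_stat == pytest.approx(m2.lrt_stat, abs=1e-6)


def test_association_test_identical_fits_null(design):
    rng, n, s, sf = design
    y = _nb_draw(rng, sf * 5.0, 0.5)
    m = fit_gene_axis_model(y, s, sf, 5)
    stat, p = association_test(m, m)  # same loglik on both sides
    assert stat == 0.0 and p == 1.0


class TestClassifyPattern:
    def _model(self, profile):
        grid = np.linspace(0, 1, len(profile))
        prof = np.asarray(profile, dtype=float)
        return GeneAxisModel(
            gene_id="g", spline_df=5, coefficients=np.zeros(6), dispersion=0.1,
            grid=grid, fitted_log_mean=prof, loglik=0.0, null_loglik=0.0,
            lrt_stat=1.0, p_value=0.5,
            log2_amplitude=float((prof.max() - prof.min()) / np.log(2)),
            converged=True, n_units=100,
        )

    def test_decreasing_is_rostral(self):
        assert classify_pattern(self._model(np.linspace(2, 0, 50))) == "rostral"

    def test_bump_is_middle(self):
        g = np.linspace(0, 1, 50)
        assert classify_pattern(self._model(2 * np.exp(-((g - 0.5) ** 2) / 0.02))) == "middle"

    def test_increasing_is_caudal(self):
        assert classify_pattern(self._model(np.linspace(0, 2, 50))) == "caudal"

    def test_small_amplitude_is_flat(self):
        assert classify_pattern(self._model(np.linspace(0, 0.1, 50))) == "flat"


@pytest.fixture(scope="module")
def svg_run(strong_bundle):
    adata, truth = strong_bundle
    axis = assign_axis_relative_distance(adata, "rostral_tip", "caudal_tip")
    table = detect_spatially_variable_genes(adata, axis)
    return adata, truth, axis, table


class TestDetectSVG:

    def test_planted_gradient_genes_recovered(self, svg_run):
        _, truth, _, table = svg_run
        truth_patterns = {g.gene_id: g.pattern for g in truth.gradient_table}
        planted = [g for g, p in truth_patterns.items() if p != "flat"]
        recall = table.loc[planted, "pass"].mean()
        assert recall >= 0.9

    def test_all_flat_dataset_nothing_passes(self):
        """With no gradient genes at all, (almost) nothing is called."""
        from axistk.synthetic import generate_tube_organ

        adata, _ = generate_tube_organ(300, 100, 0.0, seed=23)
        axis = assign_axis_relative_distance(adata, "rostral_tip", "caudal_tip")
        table = detect_spatially_variable_genes(adata, axis)
        assert table["pass"].sum() <= max(1, int(0.001 * len(table)) + 1)

    def test_pattern_classification_against_truth(self, svg_run):
        _, truth, _, table = svg_run
        mapping = {
            "rostral_decreasing": "rostral",
            "middle_peak": "middle",
            "caudal_increasing": "caudal",
        }
        planted = {
            g.gene_id: mapping[g.pattern]
            for g in truth.gradient_table
            if g.pattern != "flat"
        }
        found = table.loc[list(planted), "pattern"]
        acc = np.mean([found[g] == p for g, p in planted.items()])
        assert acc >= 0.9

    def test_sorted_by_statistic_and_q_monotone_in_p(self, svg_run):
        _, _, _, table = svg_run
        stats = table["lrt_stat"].to_numpy()
        assert np.all(np.diff(stats) <= 1e-9)
        conv = table[table["converged"]].sort_values("p_value")
        assert np.all(np.diff(conv["q_value"].to_numpy()) >= -1e-12)

    def test_unit_permutation_invariance(self, svg_run):
        adata, _, axis, table = svg_run
        perm = np.random.default_rng(5).permutation(adata.n_obs)
        sub = adata[perm].copy()
        table_p = detect_spatially_variable_genes(sub, axis)
        joined = table[["lrt_stat"]].join(
            table_p[["lrt_stat"]], rsuffix="_perm"
        )
        np.testing.assert_allclose(
            joined["lrt_stat"], joined["lrt_stat_perm"], rtol=1e-6, atol=1e-6
        )


class TestBinnedProfiles:
    def test_rows_span_unit_interval_and_monotone_gene_decreases(self, strong_bundle):
        from scipy.stats import spearmanr

        adata, truth = strong_bundle
        axis = assign_axis_relative_distance(adata, "rostral_tip", "caudal_tip")
        genes = [g.gene_id for g in truth.gradient_table if g.pattern == "rostral_decreasing"]
        prof = binned_minmax_profiles(adata, axis, genes, n_bins=10)
        vals = prof.to_numpy()
        assert np.nanmin(vals, axis=1) == pytest.approx(0.0)
        assert np.nanmax(vals, axis=1) == pytest.approx(1.0)
        rhos = [
            spearmanr(np.arange(10), row).statistic
            for row in vals
            if not np.isnan(row).any()
        ]
        assert np.mean(np.asarray(rhos) <= -0.9) >= 0.8

    def test_constant_gene_all_zero_row(self):
        import anndata as ad
        import scipy.sparse as sp

        n = 50
        X = np.column_stack([np.full(n, 5), np.arange(1, n + 1)])
        adata = ad.AnnData(
            X=sp.csr_matrix(X),
            obs=pd.DataFrame(index=[f"u{i}" for i in range(n)]),
            var=pd.DataFrame(index=["const", "other"]),
        )
        axis = AxisAssignment(
            unit_ids=np.array(adata.obs_names), value=np.linspace(0, 1, n)
        )
        # "const" has equal counts but depth scaling varies; use equal totals
        adata.X = sp.csr_matrix(np.column_stack([np.full(n, 5), np.full(n, 7)]))
        prof = binned_minmax_profiles(adata, axis, ["const"], n_bins=5)
        np.testing.assert_array_equal(prof.to_numpy(), 0.0)
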