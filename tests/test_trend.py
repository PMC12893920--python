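"""Signature scoring, Jonckheere-Terpstra trend tests and target-set
enrichment."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from axistk.errors import (
    EmptySignatureError,
    InvalidGroupsError,
    LabelNotFoundError,
    TooLargeForEnumerationError,
)
from axistk.trend import (
    exact_jonckheere_p,
    jonckheere_test,
    score_signature,
    target_set_enrichment,
)


class TestJonckheere:
    def test_worked_two_group_instance(self):
        """g1=[1,2], g2=[3,4]: all 4 cross pairs concordant, and only 1 of
        the 6 label assignments reaches JT=4, so exact p = 1/6."""
        stat, p = exact_jonckheere_p(
            [1, 2, 3, 4], ["g1", "g1", "g2", "g2"], "increasing",
            group_order=["g1", "g2"],
        )
        assert stat == 4.0
        assert p == pytest.approx(1 / 6)

    def test_reversed_alternative_is_one(self):
        _, p = exact_jonckheere_p(
            [1, 2, 3, 4], ["g1", "g1", "g2", "g2"], "decreasing",
            group_order=["g1", "g2"],
        )
        assert p == 1.0

    def test_three_singletons_give_one_over_factorial(self):
        _, p = exact_jonckheere_p(
            [1, 2, 3], ["a", "b", "c"], "increasing", group_order=["a", "b", "c"]
        )
        assert p == pytest.approx(1 / 6)

    def test_all_values_equal(self):
        res = jonckheere_test(
            [5.0] * 6, ["a", "a", "b", "b", "c", "c"], "increasing",
            group_order=["a", "b", "c"], seed=0,
        )
        assert res.jt_stat == 6.0  # 12 cross-group pairs, all ties at 0.5
        assert res.p_value == 1.0

    def test_permutation_close_to_exact_on_random_instances(self):
        """Permutation p agrees with exhaustive enumeration within
        binomial Monte-Carlo error on >= 19/20 small instances."""
        rng = np.random.default_rng(99)
        ok = 0
        for trial in range(20):
            sizes = rng.integers(2, 5, size=rng.integers(2, 4))
            values = rng.normal(size=sizes.sum()) + 0.5 * np.repeat(
                np.arange(len(sizes)), sizes
            )
            groups = np.repeat([f"g{i}" for i in range(len(sizes))], sizes)
            order = [f"g{i}" for i in range(len(sizes))]
            _, p_exact = exact_jonckheere_p(values, groups, "increasing", group_order=order)
            res = jonckheere_test(
                values, groups, "increasing", n_perm=2000, group_order=order,
                seed=1000 + trial,
            )
            tol = 3 * np.sqrt(p_exact * (1 - p_exact) / 2000) + 1 / 2001
            if abs(res.p_value - p_exact) <= tol:
                ok += 1
        assert ok >= 19

    def test_p_floor_is_add_one(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)])
        groups = ["lo"] * 30 + ["hi"] * 30
        res = jonckheere_test(values, groups, "increasing",
                              group_order=["lo", "hi"], n_perm=500, seed=2)
        assert res.p_value == pytest.approx(1 / 501)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=12))
    def test_statistic_invariant_under_monotone_transform(self, values):
        n = len(values)
        groups = np.array(["a", "b", "c"])[np.arange(n) % 3]
        order = ["a", "b", "c"]
        from scipy.stats import rankdata

        v = np.asarray(values)
        s1, _ = exact_jonckheere_p(v, groups, "increasing", group_order=order)
        # doubling and rank transforms are strictly monotone and exact in
        # floating point (no tie collapse)
        s2, _ = exact_jonckheere_p(2.0 * v, groups, "increasing", group_order=order)
        s3, _ = exact_jonckheere_p(rankdata(v), groups, "increasing", group_order=order)
        assert s1 == s2 == s3

    def test_null_pvalues_superuniform(self):
        """Under shuffled labels the test is valid (not anticonservative)."""
        rng = np.random.default_rng(5)
        hits = 0
        n_trials = 200
        for _ in range(n_trials):
            values = rng.normal(size=18)
            groups = rng.permutation(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
            res = jonckheere_test(values, groups, "increasing",
                                  group_order=["a", "b", "c"], n_perm=200,
                                  seed=int(rng.integers(2**31)))
            hits += res.p_value <= 0.05
        # binomial(200, 0.05): observing > 20 would be a gross violation
        assert hits <= 20

    def test_errors(self):
        with pytest.raises(InvalidGroupsError):
            jonckheere_test([1, 2], ["a", "a"], "increasing", group_order=["a", "b"])
        with pytest.raises(TooLargeForEnumerationError):
            exact_jonckheere_p(
                np.arange(30), ["a"] * 10 + ["b"] * 10 + ["c"] * 10, "increasing",
                group_order=["a", "b", "c"],
            )


def _uniform_adata(n_units=30, n_genes=40):
    X = np.full((n_units, n_genes), 3)
    return ad.AnnData(
        X=sp.csr_matrix(X),
        obs=pd.DataFrame(index=[f"u{i}" for i in range(n_units)]),
        var=pd.DataFrame(index=[f"g{i}" for i in range(n_genes)]),
    )


class TestScoreSignature:
    def test_uniform_expression_scores_zero(self):
        adata = _uniform_adata()
        sc = score_signature(adata, ["g0", "g1"], n_ctrl_bins=4, ctrl_size=5, seed=0)
        np.testing.assert_allclose(sc.score, 0.0, atol=1e-12)

    def test_identical_units_identical_scores(self, tube_bundle):
        adata, _ = tube_bundle
        two = adata[[0, 0]].copy()
        two.obs_names = ["a", "b"]
        sc = score_signature(two, list(adata.var_names[:5]), n_ctrl_bins=5,
                             ctrl_size=5, seed=0)
        assert sc.score[0] == pytest.approx(sc.score[1], abs=1e-12)

    def test_deterministic_given_seed(self, tube_bundle):
        adata, _ = tube_bundle
        genes = list(adata.var_names[:8])
        a = score_signature(adata, genes, seed=3).score
        b = score_signature(adata, genes, seed=3).score
        np.testing.assert_array_equal(a, b)

    def test_gene_order_invariance(self, tube_bundle):
        adata, _ = tube_bundle
        genes = list(adata.var_names[:8])
        a = score_signature(adata, genes, seed=3).score
        perm = adata[:, np.random.default_rng(0).permutation(adata.n_vars)].copy()
        b = score_signature(perm, genes, seed=3).score
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_planted_rostral_signature_decreases(self, tube_bundle):
        from axistk.synthetic import gradient_gene_ids

        adata, truth = tube_bundle
        genes = gradient_gene_ids(truth, ["rostral_decreasing"])
        s = truth.true_axis.to_numpy()
        hits = 0
        for seed in range(20):
            sc = score_signature(adata, genes, seed=seed).score
            hits += sc[s < 1 / 3].mean() > sc[s > 2 / 3].mean()
        assert hits >= 19

    def test_all_absent_error_and_partial_warning(self, tube_bundle):
        adata, _ = tube_bundle
        with pytest.raises(EmptySignatureError):
            score_signature(adata, ["NOPE1", "NOPE2"])
        with pytest.warns(UserWarning, match="absent"):
            score_signature(adata, [adata.var_names[0], "NOPE"])


class TestTargetSetEnrichment:
    def _planted(self, rng):
        n_focus, n_other, n_genes = 60, 140, 50
        X = rng.poisson(1.0, size=(n_focus + n_other, n_genes))
        X[:n_focus, :3] += rng.poisson(30.0, size=(n_focus, 3))  # drugA targets
        adata = ad.AnnData(
            X=sp.csr_matrix(X),
            obs=pd.DataFrame(
                {"cell_type": ["focus"] * n_focus + ["other"] * n_other},
                index=[f"u{i}" for i in range(n_focus + n_other)],
            ),
            var=pd.DataFrame(index=[f"g{i}" for i in range(n_genes)]),
        )
        return adata

    def test_planted_specific_targets_pass(self, rng):
        adata = self._planted(rng)
        table = target_set_enrichment(
            adata,
            {"drugA": ["g0", "g1", "g2"], "drugB": ["g10", "g11"]},
            "focus",
        )
        assert bool(table.loc["drugA", "pass"])
        assert not bool(table.loc["drugB", "pass"])

    def test_uniform_expression_fails(self):
        adata = _uniform_adata(60, 30)
        adata.obs["cell_type"] = ["focus"] * 20 + ["other"] * 40
        table = target_set_enrichment(adata, {"drugA": ["g0", "g1"]}, "focus")
        assert not bool(table.loc["drugA", "pass"])
        assert table.loc["drugA", "p_adj"] > 0.5

    def test_unknown_focus_label(self):
        adata = _uniform_adata()
        adata.obs["cell_type"] = "x"
        with pytest.raises(LabelNotFoundError):
            target_set_enrichment(adata, {"d": ["g0"]}, "missing")
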