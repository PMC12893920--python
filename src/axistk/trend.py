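"""Signature scoring, Jonckheere-Terpstra trend testing and target-set
enrichment.

``score_signature`` scores units for the average expression of a gene
set relative to an expression-matched control pool, as used to test
whether a fetal gene signature persists along an adult organ.
``jonckheere_test`` assesses a monotone trend of those scores across
ordered anatomical regions with a permutation null (2000 permutations by
default), with ``exact_jonckheere_p`` as a complete-enumeration oracle
for small instances. ``target_set_enrichment`` applies the same per-cell
mean-expression scoring to drug target sets and filters by rank-sum
significance, fold change and target detection in the focus cell type.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import (
    EmptySignatureError,
    InvalidGroupsError,
    LabelNotFoundError,
    TooLargeForEnumerationError,
)
from .io import normalize_log_cpm100


@dataclass
class SignatureScore:
    """Per-unit control-adjusted signature scores."""

    unit_ids: np.ndarray
    score: np.ndarray
    gene_set_id: str
    n_ctrl_bins: int
    ctrl_size: int
    seed: int

    def to_series(self) -> pd.Series:
        return pd.Series(self.score, index=self.unit_ids, name=self.gene_set_id)


@dataclass
class TrendTestResult:
    """Jonckheere-Terpstra permutation test outcome."""

    jt_stat: float
    alternative: str
    p_value: float
    n_perm: int
    seed: int
    group_sizes: np.ndarray


def score_signature(
    adata: ad.AnnData,
    gene_set: list[str],
    n_ctrl_bins: int = 25,
    ctrl_size: int = 50,
    *,
    gene_set_id: str = "signature",
    seed: int = 0,
    layer: str | None = None,
) -> SignatureScore:
    """Score units for a gene signature against expression-matched controls.

    Genes are ranked by dataset-mean normalized expression and cut into
    ``n_ctrl_bins`` equal-size bins; for each signature gene,
    ``ctrl_size`` control genes are sampled without replacement from its
    bin (signature genes excluded). The score of a unit is the mean
    normalized expression over the signature genes minus the mean over
    the pooled control genes. Signature genes absent from the dataset are
    dropped with a warning; if all are absent an
    :class:`EmptySignatureError` is raised.
    """
    present = [g for g in gene_set if g in set(adata.var_names)]
    absent = sorted(set(gene_set) - set(present))
    if not present:
        raise EmptySignatureError("no signature gene present in the dataset")
    if absent:
        warnings.warn(f"{len(absent)} signature genes absent and dropped: {absent[:5]}")

    if layer is not None:
        X = sp.csr_matrix(adata.layers[layer], dtype=float)
    else:
        X = normalize_log_cpm100(adata)
    gene_means = np.asarray(X.mean(axis=0)).ravel()
    order = pd.Series(gene_means, index=adata.var_names)
    bins = pd.qcut(order.rank(method="first"), q=min(n_ctrl_bins, adata.n_vars),
                   labels=False)
    sig_set = set(present)
    rng = np.random.default_rng(seed)
    controls: list[str] = []
    for g in present:
        pool = bins.index[(bins == bins[g]) & ~bins.index.isin(sig_set)]
        take = min(ctrl_size, len(pool))
        if take:
            controls.extend(rng.choice(pool, size=take, replace=False))
    controls = sorted(set(controls))
    var_index = pd.Index(adata.var_names)
    sig_idx = var_index.get_indexer(present)
    ctrl_idx = var_index.get_indexer(controls)
    sig_mean = np.asarray(X[:, sig_idx].mean(axis=1)).ravel()
    ctrl_mean = (
        np.asarray(X[:, ctrl_idx].mean(axis=1)).ravel()
        if len(controls)
        else np.zeros(adata.n_obs)
    )
    return SignatureScore(
        unit_ids=adata.obs_names.to_numpy(),
        score=sig_mean - ctrl_mean,
        gene_set_id=gene_set_id,
        n_ctrl_bins=n_ctrl_bins,
        ctrl_size=ctrl_size,
        seed=seed,
    )


def _jt_statistic(values: np.ndarray, group_slices: list[np.ndarray]) -> float:
    """JT = sum over ordered group pairs of Mann-Whitney counts, ties 0.5."""
    stat = 0.0
    sorted_groups = [np.sort(g) for g in group_slices]
    for i in range(len(sorted_groups)):
        gi = sorted_groups[i]
        for j in range(i + 1, len(sorted_groups)):
            gj = sorted_groups[j]
            # for each b in gj: #(a < b) + 0.5 * #(a == b), a in gi
            lo = np.searchsorted(gi, gj, side="left")
            hi = np.searchsorted(gi, gj, side="right")
            stat += lo.sum() + 0.5 * (hi - lo).sum()
    return float(stat)


def _split_groups(values: np.ndarray, sizes: np.ndarray) -> list[np.ndarray]:
    out = []
    start = 0
    for n in sizes:
        out.append(values[start : start + n])
        start += n
    return out


def _check_groups(values, groups, group_order):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if group_order is None:
        group_order = list(pd.unique(groups))
    if len(group_order) < 2:
        raise InvalidGroupsError("need at least two ordered groups")
    pooled = []
    sizes = []
    for g in group_order:
        v = values[groups == g]
        if v.size == 0:
            raise InvalidGroupsError(f"group {g!r} is empty")
        pooled.append(v)
        sizes.append(v.size)
    return np.concatenate(pooled), np.array(sizes)


def jonckheere_test(
    values,
    groups,
    alternative: str = "two_sided",
    n_perm: int = 2000,
    *,
    group_order: list | None = None,
    seed: int = 0,
) -> TrendTestResult:
    """Permutation Jonckheere-Terpstra test for an ordered monotone trend.

    The statistic counts concordant cross-group pairs (ties 0.5) over
    groups taken in ``group_order`` (or first-appearance order). The
    null is built by permuting group labels ``n_perm`` times; the
    p-value uses the add-one estimator
    p = (1 + #{permuted as-or-more-extreme}) / (n_perm + 1), so it is
    never below 1/(n_perm + 1). ``two_sided`` doubles the smaller tail,
    capped at 1.
    """
    if alternative not in ("increasing", "decreasing", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled, sizes = _check_groups(values, groups, group_order)
    obs = _jt_statistic(pooled, _split_groups(pooled, sizes))
    rng = np.random.default_rng(seed)
    ge = le = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = _jt_statistic(perm, _split_groups(perm, sizes))
        if stat >= obs:
            ge += 1
        if stat <= obs:
            le += 1
    p_inc = (1 + ge) / (n_perm + 1)
    p_dec = (1 + le) / (n_perm + 1)
    if alternative == "increasing":
        p = p_inc
    elif alternative == "decreasing":
        p = p_dec
    else:
        p = min(1.0, 2.0 * min(p_inc, p_dec))
    return TrendTestResult(
        jt_stat=obs,
        alternative=alternative,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        group_sizes=sizes,
    )


def exact_jonckheere_p(
    values, groups, alternative: str = "two_sided", *,
    group_order: list | None = None, max_assignments: int = 100_000
) -> tuple[float, float]:
    """Exact JT tail probability by complete enumeration.

    Enumerates every distinct assignment of the observed values to the
    group sizes and computes the exact tail probability of the observed
    statistic under the permutation null. Serves as the independent
    oracle for :func:`jonckheere_test`. Returns (jt_stat, p_value).

    Raises
    ------
    TooLargeForEnumerationError
        When the multinomial coefficient of the group sizes exceeds
        ``max_assignments``.
    """
    if alternative not in ("increasing", "decreasing", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled, sizes = _check_groups(values, groups, group_order)
    n = pooled.size
    n_assign = math.factorial(n)
    for k in sizes:
        n_assign //= math.factorial(int(k))
    if n_assign > max_assignments:
        raise TooLargeForEnumerationError(
            f"{n_assign} assignments exceed the cap of {max_assignments}"
        )
    obs = _jt_statistic(pooled, _split_groups(pooled, sizes))

    idx_all = tuple(range(n))
    ge = le = total = 0

    def recurse(remaining: tuple, g: int, chosen: list):
        nonlocal ge, le, total
        if g == len(sizes) - 1:
            arrangement = chosen + [remaining]
            stat = _jt_statistic(
                pooled, [pooled[np.array(ix)] for ix in arrangement]
            )
            total += 1
            if stat >= obs:
                ge += 1
            if stat <= obs:
                le += 1
            return
        for comb in combinations(remaining, int(sizes[g])):
            rest = tuple(i for i in remaining if i not in set(comb))
            recurse(rest, g + 1, chosen + [comb])

    recurse(idx_all, 0, [])
    p_inc = ge / total
    p_dec = le / total
    if alternative == "increasing":
        p = p_inc
    elif alternative == "decreasing":
        p = p_dec
    else:
        p = min(1.0, 2.0 * min(p_inc, p_dec))
    return obs, float(p)


def target_set_enrichment(
    adata: ad.AnnData,
    target_sets: dict[str, list[str]],
    focus_label: str,
    *,
    cell_type_col: str = "cell_type",
    p_adj_max: float = 0.01,
    min_log2fc: float = 2.0,
    min_expr_frac: float = 0.10,
) -> pd.DataFrame:
    """Score cells for drug target sets and rank focus-cell enrichment.

    Each drug's per-cell score is the mean normalized expression of its
    target genes. Scores of the focus cell type are compared with all
    other cells by Wilcoxon rank-sum; p-values are BH-adjusted across
    drugs. A drug passes when adjusted p < ``p_adj_max``, log2 fold
    change of mean scores > ``min_log2fc`` and at least
    ``min_expr_frac`` of focus cells express >= 1 target. The table is
    ordered by the rank-sum statistic, descending.
    """
    if cell_type_col not in adata.obs:
        raise LabelNotFoundError(f"obs column {cell_type_col!r} missing")
    cell_types = adata.obs[cell_type_col].astype(str).to_numpy()
    focus = cell_types == str(focus_label)
    if not focus.any():
        raise LabelNotFoundError(f"no cell labelled {focus_label!r}")
    Xn = normalize_log_cpm100(adata)
    Xc = sp.csr_matrix(adata.X)
    var_index = pd.Index(adata.var_names)
    eps = 1e-9
    rows = []
    for drug, targets in target_sets.items():
        idx = var_index.get_indexer([t for t in targets if t in var_index])
        idx = idx[idx >= 0]
        if idx.size == 0:
            continue
        score = np.asarray(Xn[:, idx].mean(axis=1)).ravel()
        u, p = mannwhitneyu(score[focus], score[~focus], alternative="greater")
        m_f, m_o = score[focus].mean(), score[~focus].mean()
        # fold change on the linear expression scale (scores are log1p-like)
        log2fc = float(np.log2((np.expm1(m_f) + eps) / (np.expm1(m_o) + eps)))
        expr_frac = float(
            (np.asarray((Xc[:, idx] > 0).sum(axis=1)).ravel()[focus] > 0).mean()
        )
        rows.append(
            {
                "drug": drug,
                "rank_sum_stat": float(u),
                "p_value": float(p),
                "log2_fc": log2fc,
                "focus_expr_frac": expr_frac,
                "n_targets_present": int(idx.size),
            }
        )
    table = pd.DataFrame(rows).set_index("drug")
    if len(table):
        table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["pass"] = (
            (table["p_adj"] < p_adj_max)
            & (table["log2_fc"] > min_log2fc)
            & (table["focus_expr_frac"] >= min_expr_frac)
        )
        table = table.sort_values("rank_sum_stat", ascending=False)
    return table
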