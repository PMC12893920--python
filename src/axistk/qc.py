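"""Integration-quality and annotation statistics.

After integrating libraries, clusters are evaluated by the Shannon
entropy of their per-sample labels (a donor-entropy of 0 marks a
donor-specific cluster for removal) and annotated by threshold majority
voting (>= 40% of member cells sharing a label). Cluster markers are
scored with TF-IDF: a gene is a good marker when it is detected in most
cells of the cluster (high term frequency) but few cells overall (high
inverse document frequency). Cell-type abundances are summarized as
z-score enrichment across anatomical regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import anndata as ad

from .errors import AxisTkError, LabelNotFoundError


def _check_aligned(clusters, labels) -> tuple[pd.Series, pd.Series]:
    clusters = pd.Series(clusters).reset_index(drop=True)
    labels = pd.Series(labels).reset_index(drop=True)
    if len(clusters) != len(labels):
        raise AxisTkError("clusters and labels have different lengths")
    if clusters.isna().any() or labels.isna().any():
        raise AxisTkError("clusters and labels must not contain missing values")
    return clusters.astype(str), labels.astype(str)


def cluster_label_entropy(clusters, labels, base: float = 2.0) -> pd.DataFrame:
    """Shannon entropy of label fractions within each cluster.

    H(c) = -sum_l f_l log_base(f_l) over labels present in the cluster.
    The ``flag_removal`` column marks zero-entropy clusters (when the
    labels are donors, these are donor-specific clusters to drop).
    Returns a frame indexed by cluster with columns ``entropy_bits``,
    ``majority_label``, ``majority_fraction``, ``n_units``,
    ``flag_removal``.
    """
    clusters, labels = _check_aligned(clusters, labels)
    rows = []
    for c, sub in labels.groupby(clusters, observed=True):
        f = sub.value_counts(normalize=True).to_numpy()
        H = float(-(f * np.log(f)).sum() / np.log(base))
        if abs(H) <= 1e-12:
            H = 0.0
        vc = sub.value_counts()
        rows.append(
            {
                "cluster_id": c,
                "entropy_bits": max(H, 0.0),
                "majority_label": vc.index[0],
                "majority_fraction": float(vc.iloc[0] / len(sub)),
                "n_units": len(sub),
                "flag_removal": H <= 1e-12,
            }
        )
    return pd.DataFrame(rows).set_index("cluster_id")


def majority_vote_annotation(
    clusters, labels, threshold: float = 0.40
) -> pd.DataFrame:
    """Annotate each cluster with its modal label if frequent enough.

    The modal label is assigned iff its fraction is >= ``threshold``
    (inclusive); otherwise, and on modal ties at or above the
    threshold, the cluster is "unresolved" (ties additionally flagged).
    """
    clusters, labels = _check_aligned(clusters, labels)
    rows = []
    for c, sub in labels.groupby(clusters, observed=True):
        vc = sub.value_counts()
        top = vc.iloc[0]
        winners = sorted(vc.index[vc == top])
        frac = float(top / len(sub))
        tie = len(winners) > 1
        if frac >= threshold and not tie:
            label = winners[0]
        else:
            label = "unresolved"
        rows.append(
            {
                "cluster_id": c,
                "label": label,
                "fraction": frac,
                "tie": tie,
            }
        )
    return pd.DataFrame(rows).set_index("cluster_id")


def tfidf_markers(
    adata_or_counts, clusters, top_n: int = 20
) -> pd.DataFrame:
    """TF-IDF cluster markers.

    tf(g, c) = fraction of cluster-c units detecting g (count > 0);
    idf(g) = ln(N / n_detecting(g)); score = tf * idf. Never-expressed
    genes are dropped. The top ``top_n`` genes per cluster are returned,
    ties broken by higher tf then gene id; ``rank`` is 1-based within
    each cluster.
    """
    if isinstance(adata_or_counts, ad.AnnData):
        X = sp.csc_matrix(adata_or_counts.X)
        genes = np.asarray(adata_or_counts.var_names)
    else:
        X = sp.csc_matrix(adata_or_counts)
        genes = np.array([f"g{j}" for j in range(X.shape[1])])
    clusters = pd.Series(np.asarray(clusters)).astype(str)
    if clusters.nunique() < 2:
        raise AxisTkError("TF-IDF markers need at least two clusters")
    detected = (X > 0).astype(np.int64)
    n_total = X.shape[0]
    n_expr = np.asarray(detected.sum(axis=0)).ravel()
    keep = n_expr > 0
    detected = detected[:, keep]
    genes = genes[keep]
    idf = np.log(n_total / n_expr[keep])
    rows = []
    for c in sorted(clusters.unique()):
        mask = (clusters == c).to_numpy()
        tf = np.asarray(detected[mask].sum(axis=0)).ravel() / mask.sum()
        score = tf * idf
        df = pd.DataFrame(
            {"cluster": c, "gene": genes, "tf": tf, "idf": idf, "score": score}
        )
        df = df.sort_values(
            ["score", "tf", "gene"], ascending=[False, False, True]
        ).head(top_n)
        df["rank"] = np.arange(1, len(df) + 1)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def celltype_region_enrichment(
    abundance: pd.DataFrame, regions, ddof: int = 1
) -> pd.DataFrame:
    """z-score enrichment of cell types across anatomical regions.

    Abundances (units x cell types) are averaged per region; each cell
    type's region means are then z-scored across regions with sample
    standard deviation (``ddof``). Cell types with zero variance across
    regions get an all-zero row. Returns cell types x regions.
    """
    regions = pd.Series(np.asarray(regions), index=abundance.index).astype(str)
    if regions.nunique() < 2:
        raise AxisTkError("need at least two regions")
    counts = regions.value_counts()
    if (counts == 0).any():
        raise AxisTkError("region with zero units")
    means = abundance.groupby(regions, observed=True).mean().T  # cell types x regions
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=ddof)
    z = means.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
    z = z.fillna(0.0)
    z.index.name = "cell_type"
    z.columns.name = "region"
    return z
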