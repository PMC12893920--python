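"""Cross-species matching of kNN-graph neighbourhoods.

Two datasets from different species are placed in a shared feature space
(one-to-one orthologues expressed in at least ten cells in both species,
intersected top highly-variable genes); each dataset is summarized as
neighbourhoods (a sampled index cell plus its k nearest neighbours in an
embedding), and neighbourhoods are paired across species by mutual
nearest neighbours of their mean expression profiles. Matched pairs are
annotated by majority voting of member cell labels, and the unique
(label_A, label_B) combinations form harmonized annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import (
    InvalidProfileError,
    InvalidProportionError,
    MissingLabelError,
    NoSharedFeaturesError,
)
from .io import normalize_log_cpm100


@dataclass
class Neighbourhoods:
    """kNN-graph neighbourhoods of one dataset on a shared feature list."""

    dataset_id: str
    index_units: np.ndarray
    membership: list[np.ndarray]
    profile: np.ndarray  # n_neighbourhoods x n_shared_features
    features: list[str]
    majority_label: np.ndarray | None = None
    majority_fraction: np.ndarray | None = None
    label_tie: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.index_units)


@dataclass
class NeighbourhoodMatch:
    """Mutual nearest pairs of neighbourhoods between two datasets."""

    pairs: list[tuple[int, int]]
    distances: np.ndarray
    k_match: int


def shared_hvg_space(
    dsA: ad.AnnData,
    dsB: ad.AnnData,
    orth_map: pd.DataFrame,
    min_cells: int = 10,
    n_hvg: int = 4000,
) -> pd.DataFrame:
    """Shared feature list: orthologues expressed in both species whose
    highly-variable rankings intersect.

    Candidate genes are orthologue pairs detected (count > 0) in at
    least ``min_cells`` cells in *both* datasets. Each species ranks the
    candidates by normalized dispersion of log-normalized expression
    within mean bins and keeps its top ``n_hvg``; the returned feature
    list is the intersection, as a frame with columns gene_a / gene_b.
    """
    if orth_map["gene_a"].duplicated().any() or orth_map["gene_b"].duplicated().any():
        raise ValueError("orthologue map must be one-to-one")
    om = orth_map[
        orth_map["gene_a"].isin(dsA.var_names) & orth_map["gene_b"].isin(dsB.var_names)
    ]
    if not len(om):
        raise NoSharedFeaturesError("orthologue map shares no genes with the datasets")

    def n_expressing(ds, genes):
        X = sp.csc_matrix(ds[:, genes].X)
        return np.asarray((X > 0).sum(axis=0)).ravel()

    nA = n_expressing(dsA, om["gene_a"].tolist())
    nB = n_expressing(dsB, om["gene_b"].tolist())
    om = om[(nA >= min_cells) & (nB >= min_cells)]
    if not len(om):
        raise NoSharedFeaturesError(
            f"no orthologue expressed in >= {min_cells} cells in both species"
        )

    def hvg_set(ds, genes):
        sub = ds[:, genes].copy()
        sub.X = normalize_log_cpm100(sub)
        n_top = min(n_hvg, len(genes))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.highly_variable_genes(sub, flavor="seurat", n_top_genes=n_top)
        return set(sub.var_names[sub.var["highly_variable"]])

    hvgA = hvg_set(dsA, om["gene_a"].tolist())
    hvgB = hvg_set(dsB, om["gene_b"].tolist())
    shared = om[om["gene_a"].isin(hvgA) & om["gene_b"].isin(hvgB)]
    if not len(shared):
        raise NoSharedFeaturesError("highly-variable gene sets do not intersect")
    return shared.reset_index(drop=True)


def _normalized_feature_matrix(ds: ad.AnnData, features: list[str]) -> np.ndarray:
    """Depth-normalize over the full gene universe, then subset columns."""
    Xn = normalize_log_cpm100(ds)
    idx = pd.Index(ds.var_names).get_indexer(features)
    return np.asarray(Xn[:, idx].todense())


def default_embedding(
    ds: ad.AnnData, features: list[str], n_pcs: int = 30, seed: int = 0
) -> np.ndarray:
    """Per-dataset PCA embedding on log-normalized shared features.

    A stand-in for an externally supplied batch-corrected embedding;
    pass your own embedding to :func:`build_neighbourhoods` to use one.
    """
    X = _normalized_feature_matrix(ds, features)
    X = X - X.mean(axis=0)
    n_pcs = min(n_pcs, X.shape[1], X.shape[0] - 1)
    return PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(X)


def build_neighbourhoods(
    ds: ad.AnnData,
    features: list[str],
    embedding: np.ndarray | None = None,
    k_graph: int = 30,
    sample_prop: float = 0.1,
    *,
    feature_key: list[str] | None = None,
    label_col: str | None = None,
    dataset_id: str = "",
    seed: int = 0,
) -> Neighbourhoods:
    """Sample index cells and form their kNN neighbourhoods.

    ceil(sample_prop * n) index cells are drawn uniformly without
    replacement; each neighbourhood is the index cell plus its
    ``k_graph`` nearest neighbours in the embedding (so k_graph + 1
    members), profiled as the mean log-normalized expression of its
    members over ``features``. With ``label_col``, the majority member
    label and its fraction are recorded (ties broken lexicographically
    and flagged).

    ``feature_key`` names the features in a dataset-independent way (for
    cross-species use, the orthologue key shared by both datasets);
    it defaults to the dataset's own gene identifiers.
    """
    n = ds.n_obs
    if k_graph >= n:
        raise ValueError("k_graph must be smaller than the number of units")
    n_index = int(np.ceil(sample_prop * n))
    if n_index < 1:
        raise InvalidProportionError("sample_prop selects fewer than one index cell")
    rng = np.random.default_rng(seed)
    index_pos = np.sort(rng.choice(n, size=n_index, replace=False))

    if embedding is None:
        embedding = default_embedding(ds, features, seed=seed)
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape[0] != n:
        raise ValueError("embedding rows must align with dataset units")

    nn = NearestNeighbors(n_neighbors=k_graph + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding[index_pos])
    membership = []
    for row, centre in zip(idx, index_pos):
        members = list(dict.fromkeys([centre] + list(row)))[: k_graph + 1]
        membership.append(np.array(members))

    dense = _normalized_feature_matrix(ds, features)
    profile = np.stack([dense[m].mean(axis=0) for m in membership])

    maj = frac = tie = None
    if label_col is not None:
        labels = ds.obs[label_col]
        if labels.isna().any():
            bad = list(ds.obs_names[labels.isna()][:5])
            raise MissingLabelError(f"unlabelled units: {bad}")
        labels = labels.astype(str).to_numpy()
        maj, frac, tie = _majority(labels, membership)
    return Neighbourhoods(
        dataset_id=dataset_id,
        index_units=ds.obs_names.to_numpy()[index_pos],
        membership=membership,
        profile=profile,
        features=list(feature_key) if feature_key is not None else list(features),
        majority_label=maj,
        majority_fraction=frac,
        label_tie=tie,
    )


def _majority(labels: np.ndarray, membership: list[np.ndarray]):
    maj, frac, tie = [], [], []
    for m in membership:
        counts = pd.Series(labels[m]).value_counts()
        top = counts.max()
        winners = sorted(counts.index[counts == top])
        maj.append(winners[0])
        frac.append(top / len(m))
        tie.append(len(winners) > 1)
    return np.array(maj, dtype=object), np.array(frac), np.array(tie)


def match_neighbourhoods(
    nbA: Neighbourhoods, nbB: Neighbourhoods, k_match: int = 30
) -> NeighbourhoodMatch:
    """Mutual-nearest pairing of neighbourhoods across datasets.

    Profiles are standardized per feature with statistics pooled across
    both datasets; each neighbourhood's ``k_match`` nearest counterparts
    are found in both directions and pairs present in both directions
    are retained.
    """
    if nbA.features != nbB.features:
        raise InvalidProfileError("neighbourhood profiles are on different features")
    pooled = np.vstack([nbA.profile, nbB.profile])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    A = (nbA.profile - mu) / sd
    B = (nbB.profile - mu) / sd
    kA = min(k_match, B.shape[0])
    kB = min(k_match, A.shape[0])
    nnB = NearestNeighbors(n_neighbors=kA).fit(B)
    _, idxAB = nnB.kneighbors(A)  # for each A nbhd, nearest B nbhds
    nnA = NearestNeighbors(n_neighbors=kB).fit(A)
    _, idxBA = nnA.kneighbors(B)
    edges_ab = {(i, int(j)) for i in range(A.shape[0]) for j in idxAB[i]}
    edges_ba = {(int(j), i) for i in range(B.shape[0]) for j in idxBA[i]}
    mutual = sorted(edges_ab & edges_ba)
    # recompute pair distances exactly from the profiles (the kNN search
    # reports float32-rounded values; identical profiles must be at 0)
    distances = np.array(
        [float(np.linalg.norm(A[i] - B[j])) for i, j in mutual]
    )
    return NeighbourhoodMatch(pairs=mutual, distances=distances, k_match=k_match)


def harmonize_annotations(
    match: NeighbourhoodMatch, nbA: Neighbourhoods, nbB: Neighbourhoods
) -> pd.DataFrame:
    """Aggregate mutual pairs into a (label_A, label_B, n_pairs) table.

    Requires both neighbourhood sets to carry majority labels (built
    with ``label_col``). Rows are sorted by pair count, descending.
    """
    if nbA.majority_label is None or nbB.majority_label is None:
        raise MissingLabelError("neighbourhoods carry no majority labels")
    rows = [
        {
            "label_a": nbA.majority_label[i],
            "label_b": nbB.majority_label[j],
            "tie": bool(nbA.label_tie[i] or nbB.label_tie[j]),
        }
        for i, j in match.pairs
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["label_a", "label_b", "n_pairs", "n_ties"])
    out = (
        df.groupby(["label_a", "label_b"], as_index=False)
        .agg(n_pairs=("tie", "size"), n_ties=("tie", "sum"))
        .sort_values("n_pairs", ascending=False, ignore_index=True)
    )
    return out
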