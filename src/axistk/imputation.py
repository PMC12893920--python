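"""kNN transfer of axis coordinates and labels from a spatial reference.

Dissociated cells carry no coordinates; an ISS-like spatial reference
with a limited gene panel does. Both datasets are restricted to their
shared genes, depth-normalized, scaled with the reference's per-gene
statistics and projected onto the reference's principal components;
each query cell then inherits the mean axis value (or majority label)
of its k nearest reference units in that space.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .axis import AxisAssignment
from .errors import InsufficientPanelError, InvalidKError, MissingLabelError
from .io import normalize_log_cpm100

#: maximum possible standard deviation of values confined to [0, 1]
_MAX_SD = 0.5


@dataclass
class TransferResult:
    """Outcome of a kNN transfer onto query units.

    ``confidence`` is the majority-label fraction for label transfer, or
    1 minus the normalized neighbour-value dispersion for axis transfer.
    """

    unit_ids: np.ndarray
    imputed_value: np.ndarray
    confidence: np.ndarray
    k: int
    n_shared_genes: int
    low_confidence: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "unit_id": self.unit_ids,
                "imputed_value": self.imputed_value,
                "confidence": self.confidence,
            }
        ).set_index("unit_id")
        if self.low_confidence is not None:
            df["low_confidence_flag"] = self.low_confidence
        return df


def _shared_joint_pcs(
    reference: ad.AnnData, query: ad.AnnData, n_pcs: int, seed: int
):
    shared = [g for g in reference.var_names if g in set(query.var_names)]
    if len(shared) < 10:
        raise InsufficientPanelError(
            f"only {len(shared)} shared genes between reference and query (need >= 10)"
        )
    ref = normalize_log_cpm100(reference[:, shared]).toarray()
    qry = normalize_log_cpm100(query[:, shared]).toarray()
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0)
    sd = np.where(sd < 1e-8, 1.0, sd)
    ref = (ref - mu) / sd
    qry = (qry - mu) / sd
    n_pcs = min(n_pcs, ref.shape[1], ref.shape[0] - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    ref_pcs = pca.fit_transform(ref)
    qry_pcs = pca.transform(qry)
    return ref_pcs, qry_pcs, len(shared)


def impute_axis_knn(
    reference: ad.AnnData,
    ref_axis: AxisAssignment | pd.Series,
    query: ad.AnnData,
    k: int = 50,
    n_pcs: int = 30,
    *,
    weighted: bool = False,
    seed: int = 0,
) -> TransferResult:
    """Impute a per-cell axis coordinate from the spatial reference.

    Reference units with missing axis values are excluded before the
    neighbour search. The imputed value is the unweighted mean of the k
    nearest reference axis values (inverse-distance weighted with
    ``weighted=True``). Confidence is 1 - sd(neighbour values) / 0.5,
    clipped to [0, 1]: 1 when all neighbours agree.
    """
    axis_values = (
        ref_axis.to_series() if isinstance(ref_axis, AxisAssignment) else ref_axis
    )
    axis_values = axis_values.reindex(reference.obs_names)
    usable = ~axis_values.isna().to_numpy()
    if k < 1:
        raise InvalidKError("k must be >= 1")
    if usable.sum() < k:
        raise InvalidKError(
            f"k={k} exceeds the {int(usable.sum())} reference units with an axis value"
        )
    ref_pcs, qry_pcs, n_shared = _shared_joint_pcs(
        reference[usable], query, n_pcs, seed
    )
    vals = axis_values.to_numpy(dtype=float)[usable]
    nn = NearestNeighbors(n_neighbors=k).fit(ref_pcs)
    dist, idx = nn.kneighbors(qry_pcs)
    neigh = vals[idx]
    if weighted:
        w = 1.0 / np.maximum(dist, 1e-12)
        imputed = (neigh * w).sum(axis=1) / w.sum(axis=1)
    else:
        imputed = neigh.mean(axis=1)
    sd = neigh.std(axis=1)
    confidence = np.clip(1.0 - sd / _MAX_SD, 0.0, 1.0)
    return TransferResult(
        unit_ids=query.obs_names.to_numpy(),
        imputed_value=imputed,
        confidence=confidence,
        k=k,
        n_shared_genes=n_shared,
    )


def transfer_labels_knn(
    reference: ad.AnnData,
    query: ad.AnnData,
    label_col: str = "cell_type",
    k: int = 50,
    min_fraction: float = 0.8,
    n_pcs: int = 30,
    *,
    seed: int = 0,
) -> TransferResult:
    """Transfer categorical labels by kNN majority vote.

    Query units whose majority fraction falls below ``min_fraction``
    (default 0.8, i.e. fewer than 80% of neighbours agreeing) are
    flagged low-confidence but retained. Majority ties are broken by
    lexicographic label order.
    """
    labels = reference.obs[label_col]
    if labels.isna().any():
        raise MissingLabelError(
            f"reference has {int(labels.isna().sum())} unlabelled units"
        )
    if k < 1 or k > reference.n_obs:
        raise InvalidKError(f"k={k} outside [1, {reference.n_obs}]")
    ref_pcs, qry_pcs, n_shared = _shared_joint_pcs(reference, query, n_pcs, seed)
    codes, uniques = pd.factorize(labels.astype(str), sort=True)
    nn = NearestNeighbors(n_neighbors=k).fit(ref_pcs)
    _, idx = nn.kneighbors(qry_pcs)
    neigh_codes = codes[idx]
    n_lab = len(uniques)
    counts = np.zeros((qry_pcs.shape[0], n_lab), dtype=np.int64)
    for j in range(n_lab):
        counts[:, j] = (neigh_codes == j).sum(axis=1)
    # argmax takes the first (lexicographically smallest) label on ties
    best = counts.argmax(axis=1)
    frac = counts[np.arange(counts.shape[0]), best] / k
    out_labels = uniques.to_numpy()[best]
    return TransferResult(
        unit_ids=query.obs_names.to_numpy(),
        imputed_value=out_labels,
        confidence=frac,
        k=k,
        n_shared_genes=n_shared,
        low_confidence=frac < min_fraction,
    )
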