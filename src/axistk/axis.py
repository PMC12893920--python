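"""Normalized organ-axis construction from landmark annotations.

Each spatial unit receives a scalar coordinate in [0, 1] along an organ's
rostrocaudal axis, computed as the relative distance to two annotated
landmark regions: value = d_R / (d_R + d_C), where d_R and d_C are the
distances to the nearest rostral- and caudal-landmark unit. Distances are
geodesic by default (shortest path over a Delaunay adjacency graph of the
units, which tracks the tissue through bends where straight-line distance
does not), with a Euclidean fallback. Sections recorded in different
coordinate frames are stitched with user-supplied affine transforms before
axis assignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import Delaunay, cKDTree

from .errors import (
    AmbiguousLandmarkError,
    InvalidAnchorError,
    InvalidTransformError,
    LandmarkNotFoundError,
)

logger = logging.getLogger(__name__)


@dataclass
class AxisAssignment:
    """Per-unit axis coordinate in [0, 1]; NaN marks out-of-mask units."""

    unit_ids: np.ndarray
    value: np.ndarray
    method: str = "relative_distance"
    rostral_landmark: str = ""
    caudal_landmark: str = ""

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids)
        self.value = np.asarray(self.value, dtype=float)
        if self.unit_ids.shape[0] != self.value.shape[0]:
            raise ValueError("unit_ids and value lengths differ")
        ok = self.value[~np.isnan(self.value)]
        if ok.size and (ok.min() < -1e-12 or ok.max() > 1 + 1e-12):
            raise ValueError("axis values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit_id": self.unit_ids, "axis_value": self.value}
        ).set_index("unit_id")

    def to_series(self) -> pd.Series:
        return pd.Series(self.value, index=self.unit_ids, name="axis_value")


@dataclass
class AffineTransform2D:
    """2-D affine map y = A x + b stored as a 2x3 matrix [A | b] (micrometres)."""

    matrix: np.ndarray = field(
        default_factory=lambda: np.hstack([np.eye(2), np.zeros((2, 1))])
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise InvalidTransformError("linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.matrix[:, :2].T + self.matrix[:, 2]


def _euclidean_landmark_distances(coords, rostral_idx, caudal_idx):
    tree_r = cKDTree(coords[rostral_idx])
    tree_c = cKDTree(coords[caudal_idx])
    d_r, _ = tree_r.query(coords)
    d_c, _ = tree_c.query(coords)
    return d_r, d_c


def _delaunay_graph(coords: np.ndarray, cutoff_factor: float = 3.0) -> sp.csr_matrix:
    """Symmetric weighted adjacency: Delaunay edges shorter than
    cutoff_factor x median nearest-neighbour spacing (long edges bridging
    folds of the organ are removed)."""
    tri = Delaunay(coords)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = simplex[a], simplex[(a + 1) % 3]
            edges.add((min(i, j), max(i, j)))
    ii, jj = np.array(sorted(edges)).T
    lengths = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    tree = cKDTree(coords)
    nn_dist, _ = tree.query(coords, k=2)
    cutoff = cutoff_factor * np.median(nn_dist[:, 1])
    keep = lengths <= cutoff
    ii, jj, lengths = ii[keep], jj[keep], lengths[keep]
    n = coords.shape[0]
    # reconnect isolated components (jitter outliers) through their
    # closest pair to the largest component, so the cutoff cannot
    # disconnect the organ
    from scipy.sparse.csgraph import connected_components

    def as_graph(ii, jj, lengths):
        return sp.coo_matrix(
            (
                np.concatenate([lengths, lengths]),
                (np.concatenate([ii, jj]), np.concatenate([jj, ii])),
            ),
            shape=(n, n),
        ).tocsr()

    n_comp, comp = connected_components(as_graph(ii, jj, lengths), directed=False)
    while n_comp > 1:
        sizes = np.bincount(comp)
        main = np.flatnonzero(comp == np.argmax(sizes))
        other = np.flatnonzero(comp != np.argmax(sizes))
        tree_main = cKDTree(coords[main])
        d, nearest = tree_main.query(coords[other])
        pick = int(np.argmin(d))
        a, b = other[pick], main[nearest[pick]]
        ii = np.append(ii, a)
        jj = np.append(jj, b)
        lengths = np.append(lengths, d[pick])
        n_comp, comp = connected_components(as_graph(ii, jj, lengths), directed=False)
    return as_graph(ii, jj, lengths)


def _geodesic_landmark_distances(coords, rostral_idx, caudal_idx, cutoff_factor):
    G = _delaunay_graph(coords, cutoff_factor)
    d_r = dijkstra(G, directed=False, indices=rostral_idx, min_only=True)
    d_c = dijkstra(G, directed=False, indices=caudal_idx, min_only=True)
    return d_r, d_c


def assign_axis_relative_distance(
    spatial: ad.AnnData,
    rostral_label: str,
    caudal_label: str,
    *,
    mask: np.ndarray | str | None = None,
    method: str = "geodesic",
    landmark_col: str = "landmark_label",
    cutoff_factor: float = 3.0,
) -> AxisAssignment:
    """Assign each unit a normalized rostrocaudal coordinate.

    Parameters
    ----------
    spatial
        Dataset with coordinates in ``.obsm["spatial"]`` and landmark
        annotations in ``.obs[landmark_col]``.
    rostral_label, caudal_label
        Landmark labels anchoring axis value 0 and 1.
    mask
        Optional boolean array (or name of a boolean obs column); units
        outside the mask get NaN. Landmark units are always used as
        anchors regardless of the mask.
    method
        ``"geodesic"`` (default; graph-shortest-path over Delaunay
        adjacency, falling back to Euclidean if the graph is
        disconnected) or ``"euclidean"``.
    cutoff_factor
        Delaunay edges longer than this multiple of the median
        nearest-neighbour spacing are dropped.
    """
    if "spatial" not in spatial.obsm:
        raise ValueError("dataset has no .obsm['spatial'] coordinates")
    coords = np.asarray(spatial.obsm["spatial"], dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    labels = spatial.obs[landmark_col].astype(object)
    rostral_idx = np.flatnonzero(labels.to_numpy() == rostral_label)
    caudal_idx = np.flatnonzero(labels.to_numpy() == caudal_label)
    if rostral_idx.size == 0:
        raise LandmarkNotFoundError(f"no unit carries landmark {rostral_label!r}")
    if caudal_idx.size == 0:
        raise LandmarkNotFoundError(f"no unit carries landmark {caudal_label!r}")

    used_method = method
    if method == "geodesic":
        d_r, d_c = _geodesic_landmark_distances(
            coords, rostral_idx, caudal_idx, cutoff_factor
        )
        if not (np.isfinite(d_r).all() and np.isfinite(d_c).all()):
            warnings.warn(
                "adjacency graph disconnected; falling back to Euclidean distances"
            )
            d_r, d_c = _euclidean_landmark_distances(coords, rostral_idx, caudal_idx)
            used_method = "euclidean_fallback"
    elif method == "euclidean":
        d_r, d_c = _euclidean_landmark_distances(coords, rostral_idx, caudal_idx)
    else:
        raise ValueError(f"unknown method {method!r}")

    denom = d_r + d_c
    both_zero = denom == 0
    if both_zero.any():
        raise AmbiguousLandmarkError(
            f"{int(both_zero.sum())} unit(s) at zero distance from both landmarks"
        )
    value = d_r / denom
    if mask is not None:
        if isinstance(mask, str):
            mask = spatial.obs[mask].to_numpy(dtype=bool)
        value = np.where(np.asarray(mask, dtype=bool), value, np.nan)
    return AxisAssignment(
        unit_ids=spatial.obs_names.to_numpy(),
        value=value,
        method=f"relative_distance[{used_method}]",
        rostral_landmark=rostral_label,
        caudal_landmark=caudal_label,
    )


def stitch_sections(
    sections: list[ad.AnnData],
    transforms: list[AffineTransform2D | np.ndarray],
) -> ad.AnnData:
    """Map each section into a common frame and concatenate.

    Gene universes are unified by union with zero-fill; non-shared genes
    are reported in the log. Unit ids must be disjoint across sections;
    colliding ids are prefixed with the section index.
    """
    if len(transforms) != len(sections):
        raise ValueError("need one transform per section")
    transforms = [
        t if isinstance(t, AffineTransform2D) else AffineTransform2D(np.asarray(t))
        for t in transforms
    ]
    mapped = []
    seen: set[str] = set()
    for k, (sec, tr) in enumerate(zip(sections, transforms)):
        sec = sec.copy()
        sec.obsm["spatial"] = tr.apply(sec.obsm["spatial"])
        if seen & set(sec.obs_names):
            sec.obs_names = [f"sec{k}:{u}" for u in sec.obs_names]
        seen |= set(sec.obs_names)
        mapped.append(sec)
    gene_sets = [set(s.var_names) for s in mapped]
    union = set().union(*gene_sets)
    shared = set.intersection(*gene_sets)
    if union - shared:
        logger.info(
            "stitching: %d genes not shared by all sections (zero-filled)",
            len(union - shared),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        out = ad.concat(mapped, join="outer", fill_value=0, merge="first")
    out.X = sp.csr_matrix(out.X)
    return out


def rescale_axis(
    assignment: AxisAssignment, anchors: list[tuple[float, float]]
) -> AxisAssignment:
    """Apply a piecewise-linear monotone map through the given anchors.

    Anchors are (raw_value, target_value) pairs strictly increasing in
    both coordinates; (0, 0) and (1, 1) are included implicitly. Used to
    bring axes from different samples onto a consistent scale.
    """
    pts = [(0.0, 0.0)] + [tuple(map(float, a)) for a in anchors] + [(1.0, 1.0)]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.any(np.diff(xs) <= 0) or np.any(np.diff(ys) <= 0):
        raise InvalidAnchorError(
            "anchors must be strictly increasing in both coordinates within (0,1)"
        )
    value = np.interp(assignment.value, xs, ys)
    value = np.where(np.isnan(assignment.value), np.nan, value)
    return AxisAssignment(
        unit_ids=assignment.unit_ids,
        value=value,
        method=assignment.method + "+rescaled",
        rostral_landmark=assignment.rostral_landmark,
        caudal_landmark=assignment.caudal_landmark,
    )


def bin_axis(assignment: AxisAssignment, n_bins: int = 20) -> pd.Series:
    """Discretize axis values: bin = floor(value * n_bins), value 1 ->
    n_bins - 1. Missing values stay missing (nullable integer dtype)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    v = assignment.value
    bins = np.floor(v * n_bins)
    bins = np.minimum(bins, n_bins - 1)
    missing = np.isnan(bins)
    arr = pd.array(np.where(missing, 0, bins).astype(np.int64), dtype="Int64")
    arr[missing] = pd.NA
    return pd.Series(arr, index=assignment.unit_ids, name="bin")
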