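"""Synthetic tubular-organ data generator with known ground truth.

Emulates the inputs of a landmark-based organ-axis study: spot/cell units
positioned along a curved tube in 2-D, negative-binomial counts whose log
mean varies along the normalized arc-length axis, an ISS-like panel-limited
spatial reference, dissociated cells without coordinates, multi-section
splits that must be re-stitched, and a two-species pair sharing cell
populations through a one-to-one orthologue map.

Every generator is a pure function of its arguments: the same seed and
configuration yield byte-identical output.

Count model
-----------
For gene *g* at unit *u* with axis position ``s`` and size factor ``c_u``::

    log2 mu(u, g) = log2(c_u * base_mean_g) + amplitude_g * f_pattern(s)

with counts drawn NB(mu, dispersion) under the NB2 parameterization
``var = mu + mu^2 * dispersion`` (dispersion -> 0 is the Poisson limit).
``f_pattern`` is ``1 - s`` (rostral_decreasing), ``s`` (caudal_increasing),
a Gaussian bump centred at 0.5 with sigma 0.15 (middle_peak), or 0 (flat).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import (
    DegenerateSectionError,
    MissingGeneError,
    NoSharedFeaturesError,
)

Pattern = Literal["flat", "rostral_decreasing", "caudal_increasing", "middle_peak"]

#: width of the middle_peak Gaussian bump on the [0, 1] axis
MIDDLE_PEAK_SIGMA = 0.15

#: log-normal sigma of the per-unit library-size factor
SIZE_FACTOR_SDLOG = 0.3

#: fraction of units nearest each tube endpoint annotated as landmarks
LANDMARK_FRAC = 0.02

ROSTRAL_LANDMARK = "rostral_tip"
CAUDAL_LANDMARK = "caudal_tip"


@dataclass(frozen=True)
class GradientSpec:
    """Per-gene expression gradient specification along the axis."""

    gene_id: str
    pattern: Pattern
    base_mean: float
    amplitude: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.base_mean <= 0:
            raise ValueError(f"{self.gene_id}: base_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError(f"{self.gene_id}: dispersion must be positive")
        if self.amplitude < 0:
            raise ValueError(f"{self.gene_id}: amplitude must be non-negative")
        if (self.amplitude == 0) != (self.pattern == "flat"):
            raise ValueError(
                f"{self.gene_id}: amplitude must be 0 iff pattern is 'flat'"
            )

    def log2_mean(self, s: np.ndarray) -> np.ndarray:
        """log2 expected counts at unit scale for axis positions ``s``."""
        return np.log2(self.base_mean) + self.amplitude * pattern_profile(
            self.pattern, np.asarray(s, dtype=float)
        )


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators, for parameter-recovery tests."""

    true_axis: pd.Series
    gradient_table: list[GradientSpec]
    population_labels: pd.Series
    section_transforms: dict[str, np.ndarray] = field(default_factory=dict)
    size_factors: pd.Series | None = None

    def gradient_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(g) for g in self.gradient_table])


def pattern_profile(pattern: Pattern, s: np.ndarray) -> np.ndarray:
    """Axis response f(s) in [0, 1] for each gradient pattern."""
    if pattern == "flat":
        return np.zeros_like(s)
    if pattern == "rostral_decreasing":
        return 1.0 - s
    if pattern == "caudal_increasing":
        return s
    if pattern == "middle_peak":
        return np.exp(-0.5 * ((s - 0.5) / MIDDLE_PEAK_SIGMA) ** 2)
    raise ValueError(f"unknown pattern {pattern!r}")


def _sample_nb(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Draw NB2 counts with variance mu + mu^2 * dispersion (Poisson limit)."""
    if dispersion < 1e-12:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _draw_counts(
    rng: np.random.Generator,
    specs: Sequence[GradientSpec],
    s: np.ndarray,
    size_factors: np.ndarray,
) -> sp.csr_matrix:
    """units x genes count matrix under the gradient NB model."""
    n_units = s.shape[0]
    X = np.empty((n_units, len(specs)), dtype=np.int64)
    for j, spec in enumerate(specs):
        mu = size_factors * np.exp2(spec.log2_mean(s))
        X[:, j] = _sample_nb(rng, mu, spec.dispersion)
    return sp.csr_matrix(X)


def _bezier(t: np.ndarray, p0, p1, p2) -> np.ndarray:
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _tube_centerline(tube_length: float):
    """Quadratic Bezier centerline scaled so its arc-length is tube_length.

    Returns (point_at_s, endpoints, actual length) where point_at_s maps
    normalized arc-length s in [0, 1] to 2-D coordinates.
    """
    p0 = np.array([0.0, 0.0])
    p1 = np.array([0.5, 0.6])
    p2 = np.array([1.0, 0.0])
    tt = np.linspace(0.0, 1.0, 4001)
    pts = _bezier(tt, p0, p1, p2)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    scale = tube_length / arc[-1]
    pts = pts * scale
    arc = arc * scale

    def point_at_s(s: np.ndarray) -> np.ndarray:
        t_of_s = np.interp(np.asarray(s, dtype=float) * arc[-1], arc, tt)
        return _bezier(t_of_s, p0, p1, p2) * scale

    return point_at_s, (pts[0], pts[-1]), arc[-1]


def _default_gradient_table(
    rng: np.random.Generator,
    n_genes: int,
    frac_gradient: float,
    base_mean: float,
    amplitude: float,
    dispersion: float,
) -> list[GradientSpec]:
    n_gradient = int(round(frac_gradient * n_genes))
    patterns = ["rostral_decreasing", "caudal_increasing", "middle_peak"]
    gradient_idx = rng.choice(n_genes, size=n_gradient, replace=False)
    is_gradient = np.zeros(n_genes, dtype=bool)
    is_gradient[gradient_idx] = True
    # per-gene baseline spread around the requested median
    base = base_mean * np.exp(rng.normal(0.0, 0.5, size=n_genes))
    specs = []
    for j in range(n_genes):
        if is_gradient[j]:
            pat = patterns[rng.integers(len(patterns))]
            amp = amplitude
        else:
            pat, amp = "flat", 0.0
        specs.append(
            GradientSpec(
                gene_id=f"G{j:04d}",
                pattern=pat,  # type: ignore[arg-type]
                base_mean=float(base[j]),
                amplitude=amp,
                dispersion=dispersion,
            )
        )
    return specs


def generate_tube_organ(
    n_units: int = 2000,
    n_genes: int = 500,
    frac_gradient: float = 0.3,
    *,
    base_mean: float = 5.0,
    amplitude: float = 1.0,
    dispersion: float = 0.5,
    tube_length: float = 1000.0,
    lateral_sd_frac: float = 0.05,
    gradient_table: Sequence[GradientSpec] | None = None,
    seed: int = 0,
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate a landmark-annotated curved tubular organ.

    Units are placed along a quadratic Bezier tube with Gaussian lateral
    jitter (sigma = ``lateral_sd_frac`` of the tube length), so Euclidean
    distance between units is not proportional to arc-length. The true
    axis is the normalized arc-length position at which each unit was
    sampled. The 2% of units nearest each tube endpoint carry the
    landmark labels ``rostral_tip`` and ``caudal_tip``.

    Parameters
    ----------
    n_units
        Number of spatial units (spots/cells); must be >= 50.
    n_genes
        Number of genes.
    frac_gradient
        Fraction of genes given a non-flat axis pattern (ignored when an
        explicit ``gradient_table`` is supplied).
    base_mean, amplitude, dispersion
        Defaults for the generated :class:`GradientSpec` table: median
        baseline expected count, log2 amplitude of gradient genes and NB
        dispersion shared by all genes.
    gradient_table
        Explicit per-gene specs overriding the generated table; its length
        must equal ``n_genes``.
    seed
        Seed for all randomness.

    Returns
    -------
    (AnnData, SyntheticTruth)
        AnnData with integer counts in ``.X`` (units x genes), coordinates
        in ``.obsm["spatial"]`` (micrometres), ``section_id`` and
        ``landmark_label`` in ``.obs``.
    """
    if n_units < 50:
        raise ValueError("n_units must be >= 50")
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    if not 0.0 <= frac_gradient <= 1.0:
        raise ValueError("frac_gradient must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    if gradient_table is None:
        specs = _default_gradient_table(
            rng, n_genes, frac_gradient, base_mean, amplitude, dispersion
        )
    else:
        if len(gradient_table) != n_genes:
            raise ValueError("gradient_table length must equal n_genes")
        specs = list(gradient_table)

    s = rng.uniform(0.0, 1.0, size=n_units)
    point_at_s, (end_r, end_c), _length = _tube_centerline(tube_length)
    centers = point_at_s(s)
    jitter = rng.normal(0.0, lateral_sd_frac * tube_length, size=(n_units, 2))
    coords = centers + jitter

    size_factors = np.exp(rng.normal(0.0, SIZE_FACTOR_SDLOG, size=n_units))
    X = _draw_counts(rng, specs, s, size_factors)

    unit_ids = [f"u{i:05d}" for i in range(n_units)]
    n_land = max(1, int(round(LANDMARK_FRAC * n_units)))
    d_rost = np.linalg.norm(coords - end_r, axis=1)
    d_caud = np.linalg.norm(coords - end_c, axis=1)
    landmark = np.array([""] * n_units, dtype=object)
    landmark[np.argsort(d_rost)[:n_land]] = ROSTRAL_LANDMARK
    landmark[np.argsort(d_caud)[:n_land]] = CAUDAL_LANDMARK
    landmark[landmark == ""] = None

    obs = pd.DataFrame(
        {
            "section_id": pd.Categorical(["S0"] * n_units),
            "landmark_label": landmark,
        },
        index=pd.Index(unit_ids, name="unit_id"),
    )
    var = pd.DataFrame(
        {"pattern": [g.pattern for g in specs]},
        index=pd.Index([g.gene_id for g in specs], name="gene_id"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.obsm["spatial"] = coords

    truth = SyntheticTruth(
        true_axis=pd.Series(s, index=obs.index, name="true_axis"),
        gradient_table=specs,
        population_labels=pd.Series(["tube"] * n_units, index=obs.index),
        size_factors=pd.Series(size_factors, index=obs.index),
    )
    return adata, truth


def generate_dissociated(
    bundle: tuple[ad.AnnData, SyntheticTruth],
    n_cells: int = 2000,
    panel: Sequence[str] | None = None,
    *,
    axis_positions: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[ad.AnnData, pd.Series]:
    """Sample dissociated cells from the tube's expression model.

    Cells take uniform-random axis positions (or the pinned
    ``axis_positions``) and draw counts from the same NB gradient model as
    the spatial bundle; they carry no coordinates. With ``panel`` set the
    output is restricted to those genes, emulating an ISS-like
    panel-limited reference.

    Returns the cell dataset and the per-cell true axis position.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    spatial, truth = bundle
    rng = np.random.default_rng(seed)
    if axis_positions is None:
        s = rng.uniform(0.0, 1.0, size=n_cells)
    else:
        s = np.asarray(axis_positions, dtype=float)
        if s.shape[0] != n_cells:
            raise ValueError("axis_positions length must equal n_cells")

    specs = truth.gradient_table
    if panel is not None:
        panel = list(panel)
        known = set(g.gene_id for g in specs)
        missing = [g for g in panel if g not in known]
        if missing:
            raise MissingGeneError(f"panel genes absent from bundle: {missing}")

    size_factors = np.exp(rng.normal(0.0, SIZE_FACTOR_SDLOG, size=n_cells))
    X = _draw_counts(rng, specs, s, size_factors)

    cell_ids = [f"c{i:05d}" for i in range(n_cells)]
    obs = pd.DataFrame(index=pd.Index(cell_ids, name="unit_id"))
    var = pd.DataFrame(index=pd.Index([g.gene_id for g in specs], name="gene_id"))
    adata = ad.AnnData(X=X, obs=obs, var=var)
    if panel is not None:
        adata = adata[:, panel].copy()
    true_axis = pd.Series(s, index=obs.index, name="true_axis")
    return adata, true_axis


def split_into_sections(
    spatial: ad.AnnData,
    truth: SyntheticTruth,
    cut_positions: Sequence[float],
    *,
    seed: int = 0,
) -> list[ad.AnnData]:
    """Cut the organ into consecutive sections with scrambled frames.

    Sections are defined by cutting the true axis at ``cut_positions``
    (strictly increasing, in (0, 1)). Each section's coordinates are
    re-expressed in a section-local frame through a random rigid transform
    (rotation + translation); the inverse transforms, which restore the
    original frame when applied by the stitcher, are recorded in
    ``truth.section_transforms`` as 2x3 matrices ``[A | b]``.
    """
    cuts = list(cut_positions)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cut_positions must be strictly increasing")
    if any(not 0.0 < c < 1.0 for c in cuts):
        raise ValueError("cut_positions must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    s = truth.true_axis.loc[spatial.obs_names].to_numpy()
    edges = np.array([-np.inf] + cuts + [np.inf])
    section_of = np.digitize(s, edges[1:-1])

    sections: list[ad.AnnData] = []
    truth.section_transforms = {}
    for k in range(len(cuts) + 1):
        mask = section_of == k
        if not mask.any():
            raise DegenerateSectionError(
                f"section {k} is empty for cut_positions {cuts}"
            )
        sec = spatial[mask].copy()
        sec_id = f"S{k}"
        sec.obs["section_id"] = pd.Categorical([sec_id] * sec.n_obs)
        if len(cuts) == 0:
            theta, t = 0.0, np.zeros(2)  # single section keeps its frame
        else:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            t = rng.uniform(-500.0, 500.0, size=2)
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        sec.obsm["spatial"] = sec.obsm["spatial"] @ R.T + t
        # inverse: x_orig = R^T (y - t)
        inv = np.hstack([R.T, (-R.T @ t)[:, None]])
        truth.section_transforms[sec_id] = inv
        sections.append(sec)
    return sections


def generate_species_pair(
    n_cells_per_species: int = 3000,
    n_populations: int = 5,
    orth_frac: float = 0.8,
    species_shift: float = 0.0,
    *,
    n_genes: int = 600,
    marker_log2fc: float = 3.0,
    base_mean: float = 2.0,
    dispersion: float = 0.5,
    seed: int = 0,
) -> tuple[ad.AnnData, ad.AnnData, pd.DataFrame, SyntheticTruth]:
    """Generate two "species" datasets sharing cell populations.

    Both species draw from the same population-specific NB mean profiles:
    each population upregulates its own marker-gene module by
    ``marker_log2fc``. Gene identifiers differ between species; a fraction
    ``orth_frac`` of genes appear in a one-to-one orthologue map.
    ``species_shift`` adds a species-wide log2 offset to a random half of
    species B's genes, emulating systematic cross-species expression
    divergence.

    Returns (A, B, orthologue map with columns gene_a/gene_b, truth); each
    dataset carries the true population in ``.obs["population"]``.
    """
    if orth_frac <= 0.0:
        raise NoSharedFeaturesError("orth_frac must be positive")
    if not orth_frac <= 1.0:
        raise ValueError("orth_frac must lie in (0, 1]")
    if n_populations < 2:
        raise ValueError("n_populations must be >= 2")
    if n_populations > n_cells_per_species / 20:
        raise ValueError("need >= 20 cells per population")
    rng = np.random.default_rng(seed)

    base = base_mean * np.exp(rng.normal(0.0, 0.8, size=n_genes))
    markers_per_pop = max(5, n_genes // (2 * n_populations))
    perm = rng.permutation(n_genes)
    log2_mean = np.tile(np.log2(base), (n_populations, 1))
    for p in range(n_populations):
        mod = perm[p * markers_per_pop : (p + 1) * markers_per_pop]
        log2_mean[p, mod] += marker_log2fc

    shift = np.zeros(n_genes)
    if species_shift > 0:
        shifted = rng.choice(n_genes, size=n_genes // 2, replace=False)
        shift[shifted] = species_shift

    def make_species(tag: str, extra_log2: np.ndarray, rng_s: np.random.Generator):
        pops = rng_s.integers(n_populations, size=n_cells_per_species)
        mu = np.exp2(log2_mean[pops] + extra_log2)
        sf = np.exp(rng_s.normal(0.0, SIZE_FACTOR_SDLOG, size=n_cells_per_species))
        mu = mu * sf[:, None]
        X = sp.csr_matrix(_sample_nb(rng_s, mu, dispersion))
        ids = [f"{tag.lower()}{i:05d}" for i in range(n_cells_per_species)]
        obs = pd.DataFrame(
            {"population": pd.Categorical([f"pop{p}" for p in pops])},
            index=pd.Index(ids, name="unit_id"),
        )
        var = pd.DataFrame(
            index=pd.Index([f"G{tag}{j:04d}" for j in range(n_genes)], name="gene_id")
        )
        adata = ad.AnnData(X=X, obs=obs, var=var)
        return adata

    seeds = rng.integers(2**31 - 1, size=2)
    A = make_species("A", np.zeros(n_genes), np.random.default_rng(seeds[0]))
    B = make_species("B", shift, np.random.default_rng(seeds[1]))

    n_orth = int(round(orth_frac * n_genes))
    if n_orth == 0:
        raise NoSharedFeaturesError("orth_frac too small: empty orthologue map")
    orth_idx = np.sort(rng.choice(n_genes, size=n_orth, replace=False))
    orth_map = pd.DataFrame(
        {
            "gene_a": [f"GA{j:04d}" for j in orth_idx],
            "gene_b": [f"GB{j:04d}" for j in orth_idx],
        }
    )

    pop_labels = pd.concat([A.obs["population"], B.obs["population"]]).astype(str)
    truth = SyntheticTruth(
        true_axis=pd.Series(dtype=float),
        gradient_table=[],
        population_labels=pop_labels,
    )
    return A, B, orth_map, truth


def gradient_gene_ids(truth: SyntheticTruth, patterns: Sequence[str] | None = None):
    """Gene ids with a non-flat (or specified) pattern, in table order."""
    wanted = set(patterns) if patterns is not None else None
    out = []
    for g in truth.gradient_table:
        if g.pattern == "flat":
            continue
        if wanted is None or g.pattern in wanted:
            out.append(g.gene_id)
    return out


def expected_log2_mean(truth: SyntheticTruth, gene_id: str, s) -> np.ndarray:
    """Closed-form log2 expected count (unit size factor) for one gene."""
    for g in truth.gradient_table:
        if g.gene_id == gene_id:
            return g.log2_mean(np.asarray(s, dtype=float))
    raise MissingGeneError(gene_id)
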