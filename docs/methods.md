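# Methods

## The axis model

A tubular organ is represented as a set of spatial units (Visium-style
spots or ISS-style cells) with 2-D coordinates in micrometres and two
annotated landmark *regions* — rostral and caudal — rather than single
points, mirroring how anatomical landmarks (fimbriae, duct junctions)
are annotated in practice. The axis coordinate of unit *u* is the
relative distance

    s(u) = d_R(u) / (d_R(u) + d_C(u)),

where `d_R` and `d_C` are the distances to the nearest rostral- and
caudal-landmark unit. Units coincident with a landmark get exactly 0
or 1; a unit at distance zero from both is an error.

**Distance definition.** Two metrics are implemented behind a switch.
`euclidean` is the simplest reading of a normalized between-landmark
distance. The default, `geodesic`, is the shortest path over a unit
adjacency graph (Delaunay triangulation, edges longer than 3× the
median nearest-neighbour spacing removed, edge weight = Euclidean
length); in a curved organ the Euclidean ratio is generally
non-monotone in arc-length while the graph distance tracks the tissue.
If edge pruning disconnects the graph, isolated components are
re-attached through their closest point pair to the main component, so
outlying units never silently lose their coordinate; if the graph is
still unusable the implementation falls back to Euclidean with a
warning. Axis values are invariant under rigid motions of the whole
sample and under unit reordering.

**Stitching.** Samples captured as several sections arrive in
section-local frames. The stitcher applies user-supplied 2×3 affine
transforms (estimated elsewhere, e.g. by interactive image alignment —
estimation is out of scope), concatenates the sections and unifies gene
universes by union with zero fill. Transforms must have an invertible
linear part.

**Rescaling and binning.** Axes from different samples are aligned by a
piecewise-linear monotone map through user anchors (with (0,0) and
(1,1) implicit); monotonicity in both coordinates is enforced. For
display, values are binned as `floor(s·n_bins)` with `s = 1` assigned
to the last bin; the default of 20 bins keeps bin occupancy stable at
spot-level unit counts.

## Axis imputation onto dissociated cells

Dissociated cells share no coordinates with the spatial reference, but
share genes. Reference and query are restricted to shared genes
(≥ 10 required), depth-normalized to `ln(CPM/100 + 1)`, standardized
per gene with the *reference's* statistics, and projected onto the
reference's top principal components (default 30). Projecting the
query into the reference space avoids batch-dominated joint embeddings
without implementing integration. Each query cell's axis value is the
unweighted mean of its k = 50 nearest reference units' values
(inverse-distance weighting is available); the imputed value is
therefore always inside the reference's value range, and as k
approaches the reference size every imputation converges to the
reference mean. Confidence is `1 − sd(neighbour values)/0.5`, clipped
to [0, 1] (0.5 is the largest possible standard deviation of values
confined to [0, 1]). Label transfer uses the same space with majority
vote; cells whose majority fraction falls below 0.8 are flagged
low-confidence but kept.

## Axis-variable genes

Counts of gene *g* are modelled as negative binomial (NB2,
`var = μ + αμ²`) with

    log μ_u = β₀ + B(s_u)·β + log c_u,

where `B` is a cubic B-spline basis with `spline_df` functions (default
5; for `spline_df = 1` the basis degenerates to the linear ramp, making
the model an ordinary log-linear NB regression — used as an equivalence
oracle in tests), knots at axis quantiles so sparse axis regions do not
destabilize the fit, and `c_u` the unit's size factor (total counts
scaled to mean 1). The dispersion α is estimated once per gene by a
Pearson moment estimator on a Poisson fit of the full model
(`α = (X² − (n − p)) / Σμ`, floored at 1e-8) and held fixed; no
empirical-Bayes shrinkage is applied. Full and intercept-only models
are then fitted by IRLS (statsmodels GLM, 100-iteration cap;
non-converged fits are flagged and excluded from FDR computation) and
compared by likelihood ratio against χ² with `spline_df` degrees of
freedom. All-zero genes return a flat model with statistic 0 and p = 1
rather than an error.

**Effect size.** The fold change of a smooth curve is taken as the
amplitude of the fitted profile: `(max − min)` of the fitted log mean
over a 100-point grid, divided by ln 2 to give a log2 amplitude. The
detection criterion is `p < 0.001` and log2 amplitude > 0.5 (the
threshold interpreted on the log2 scale, the convention for
fold-change cutoffs in this literature; both the base and the p/q
choice are configurable, and BH q-values are reported alongside the raw
p used for calling). Genes detected in fewer than 1% of units are not
tested. Pattern classes are assigned from the fitted peak position:
flat if the amplitude is at or below the threshold, else rostral /
middle / caudal for a peak in [0, ⅓), [⅓, ⅔], (⅔, 1].

On simulated data the test is calibrated but mildly anticonservative
(type-I error ≈ 0.05–0.06 at α = 0.05 with 500 units), the known cost
of a plug-in dispersion; the p < 0.001 calling threshold leaves this
immaterial in practice. Note also that size factors estimated from
totals induce compositional coupling: when a large fraction of the
transcriptome is strongly axis-dependent, genes that are flat in
absolute counts acquire a small apparent axis effect in relative terms,
exactly as in real depth-normalized data.

## Signature scoring and trend testing

A unit's signature score is the mean log-normalized expression of the
signature genes minus the mean over an expression-matched control pool:
genes are ranked by dataset-mean expression and cut into 25 equal-size
bins, and 50 control genes are drawn (seeded, without replacement,
signature genes excluded) from each signature gene's bin. These pool
parameters follow the common scoring convention and are exposed as
flags.

Monotone trends of scores across ordered groups (e.g. anatomical
regions sampled along the organ) are tested with the
Jonckheere–Terpstra statistic: the sum over ordered group pairs of
Mann–Whitney counts, ties counted 0.5. The null is permutational
(default 2,000 label permutations) with the add-one estimator
`p = (1 + #extreme)/(n_perm + 1)`, so p is valid and never below
1/(n_perm+1); two-sided doubles the smaller tail, capped at 1. A
complete-enumeration oracle (`exact_jonckheere_p`, capped at 100,000
distinct assignments) computes the exact tail probability with the same
tie convention and anchors the permutation test in tests.

The same per-cell mean-expression scoring is applied to drug target
sets: per drug, focus cells are compared with all other cells by
Wilcoxon rank-sum, p-values BH-adjusted across drugs, and a drug passes
at adjusted p < 0.01, log2 fold change > 2 (computed on the linear
expression scale, i.e. after `expm1` of mean log scores — the
convention of the surrounding ecosystem) and ≥ 10% of focus cells
detecting at least one target. The under-specified "rank score" filter
is realized as ordering by the rank-sum statistic, not as an extra
cutoff.

## Cross-species neighbourhood matching

The shared feature space is built from a one-to-one orthologue map:
candidates are pairs detected in ≥ 10 cells of both species; each
species ranks candidates by normalized dispersion within mean bins
(scanpy's seurat flavour) and keeps its top 4,000; the feature list is
the intersection. Each species is summarized as neighbourhoods — index
cells sampled uniformly (10% of cells), each with its 30 nearest
neighbours in an embedding (by default a 30-PC embedding on the shared
features; a user-supplied batch-corrected embedding can replace it) —
profiled as mean log-normalized expression over the shared features.
Cross-species distances are Euclidean between per-feature standardized
profiles (statistics pooled over both datasets): expression-profile
distance is the only space common to both datasets without
re-implementing integration. Each neighbourhood's 30 nearest in the
other species are candidate edges in both directions, and pairs present
in both directions are kept (mutual nearest). Pair distances are
recomputed exactly from the profiles, so identical datasets recover the
identity pairing at distance exactly 0. Matched neighbourhoods are
annotated by majority vote of member labels (lexicographic tie-break,
flagged) and aggregated into a (label_A, label_B, n_pairs) table.

## Integration QC

Per-cluster Shannon entropy of label fractions is reported in bits
(base 2 — the base is cosmetic for the two rules actually applied:
H = 0 flags donor-specific clusters for removal, and the annotation
rule assigns a cluster its modal label iff its fraction is ≥ 0.40,
ties and sub-threshold modes giving "unresolved"). TF-IDF markers
follow the quickMarkers convention: tf = in-cluster detection rate,
idf = ln(N / n detecting overall), score = tf·idf — a function of the
detection pattern only, invariant to count magnitude. Cell-type ×
region enrichment averages abundances per region and z-scores each cell
type across regions with sample standard deviation (ddof = 1);
zero-variance cell types get an all-zero row.

## The synthetic generator

The generator emulates the study's data modalities with analytic ground
truth. Units lie on a quadratic Bézier tube (arc-length-normalized, so
Euclidean distance ≠ arc-length and the geodesic/Euclidean choice is
actually exercised) with isotropic Gaussian jitter of σ = 5% of tube
length; the true axis is the arc-length position at which a unit was
sampled, and the 2% of units nearest each endpoint carry landmark
labels. Counts are NB2 with
`log2 μ = log2(base_mean) + amplitude·f(s)` and a log-normal(0, 0.3)
per-unit size factor (forcing offsets to matter in the regression
model); `f` is `1 − s`, `s`, or a Gaussian bump (σ = 0.15) at `s = 0.5`
for the three gradient patterns, 0 for flat genes. Dissociated cells
draw from the same model at uniform (or pinned) axis positions without
coordinates; ISS-like references are panel subsets. Sections are cut by
true axis position and scrambled by random rigid transforms whose
inverses are recorded. The species pair shares population-specific mean
profiles (each population up-regulating its own marker module by 3
log2-fold) with species-specific gene identifiers, a partial one-to-one
orthologue map, and an optional species-wide log offset on half the
genes. ISS counts and spot counts are treated as the same NB family at
different unit granularity — the generator does not model segmentation,
probe efficiency, images or 3-D geometry.

**What passing tests show, and don't.** Recovery results on this
generator demonstrate internal correctness (the statistics recover
planted truth under the stated noise model), not robustness to
segmentation errors, ambient contamination, batch effects between
reference and query, or anisotropic tissue deformation, none of which
are simulated.

## Numerical and scale choices

- Natural log everywhere except thresholds stated in log2 (SVG
  amplitude, drug fold change).
- Default problem sizes in the analysis scripts and end-to-end checks:
  2,000-unit tubes, 500-gene panels, 500-unit × 2,000-gene null
  calibration, 3,000-cell species pairs — large enough for stable
  recovery statistics while keeping a full run in tens of seconds.
- Seeds: every stochastic routine takes an explicit seed; workflows fan
  one global seed out by fixed offsets so stages are individually
  reproducible, and manifests record SHA-256 checksums of all tables.
- kNN ties resolve by stable index order; majority-vote ties break
  lexicographically and are flagged.
- The jitter σ of 5% of tube length bounds achievable axis recovery at
  Spearman ρ ≈ 0.98 at 2,000 units — the residual is along-axis
  displacement of the units themselves, not estimation error.

## Known limitations

- The doublet-score QC filter is out of scope (the report schema
  reserves a `doublet_score` column for external scores).
- No batch correction, trajectory inference, deconvolution or
  differential-abundance GLM; embeddings and abundances are accepted as
  inputs where relevant.
- The geodesic graph assumes units sample the organ densely enough that
  the Delaunay graph follows the tissue; sparse or fragmented sections
  degrade toward the Euclidean ratio.
- Dispersion is per-gene moment-based without shrinkage; for very low
  counts the LRT is slightly anticonservative at loose α (calibration
  measured in the acceptance run).
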