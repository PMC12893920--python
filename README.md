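# axistk

Landmark-based organ-axis analysis for spatial transcriptomics.

Developing tubular organs — the embryonic Müllerian and Wolffian ducts and
their derivatives (fallopian tube, uterus, epididymis, vas deferens) — are
patterned along their rostrocaudal axis. `axistk` turns landmark-annotated
spatial transcriptomics of such an organ into a quantitative axis
coordinate and provides the downstream statistics that go with it:

1. **Axis construction** — every spatial unit *u* gets a normalized
   coordinate `s(u) = d_R(u) / (d_R(u) + d_C(u)) ∈ [0, 1]`, where `d_R`
   and `d_C` are distances to the nearest unit of the annotated rostral
   and caudal landmark regions. Distances are geodesic by default
   (shortest path over a pruned Delaunay graph of the units), so the
   coordinate follows the tissue through bends. Multi-section samples
   are stitched with user-supplied affine transforms first; axes from
   different samples are aligned with piecewise-linear rescaling.
2. **Axis imputation** — dissociated scRNA-seq cells, which have no
   coordinates, inherit the axis from a panel-limited in-situ reference
   by k-nearest-neighbour transfer in the reference's PC space (k = 50
   by default); categorical labels transfer the same way with a 0.8
   majority-fraction confidence rule.
3. **Axis-variable genes** — counts are modelled as NB(μ, α) with
   `log μ = β₀ + B(s)β + log(size factor)`, B a cubic B-spline basis
   (default 5 df, knots at axis quantiles), the axis treated analogously
   to pseudotime. Association is a likelihood-ratio χ² test of the
   spline terms; a gene is called when `p < 0.001` and the fitted
   curve's log2 amplitude exceeds 0.5, and classified rostral / middle /
   caudal / flat by its fitted peak.
4. **Signature trends** — units are scored for a gene set against an
   expression-matched control pool, and a monotone trend across ordered
   regions is tested with a permutation Jonckheere–Terpstra test
   (2,000 permutations; an exact-enumeration oracle is included). The
   same per-cell scoring drives a drug-target enrichment filter
   (rank-sum adjusted p < 0.01, log2 FC > 2, targets detected in ≥ 10%
   of focus cells).
5. **Cross-species matching** — two datasets are placed on shared
   orthologues (expressed in ≥ 10 cells of both species, intersected
   top-4,000 HVGs), summarized as kNN-graph neighbourhoods, and paired
   by mutual nearest neighbours (k = 30 both directions); matched pairs
   are annotated by majority vote.
6. **Integration QC** — per-cluster Shannon label entropy (zero donor
   entropy flags donor-specific clusters), ≥ 40% threshold majority-vote
   annotation, TF-IDF cluster markers, and cell-type × region z-score
   enrichment.

A synthetic tubular-organ generator (`axistk.synthetic`) provides every
input with known ground truth — a curved tube with NB gradient genes,
an ISS-like panel reference, dissociated cells, multi-section splits and
a two-species pair — so the whole pipeline is testable without any
download.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from axistk.synthetic import generate_tube_organ, generate_dissociated, gradient_gene_ids
from axistk.axis import assign_axis_relative_distance
from axistk.imputation import impute_axis_knn
from axistk.svg import detect_spatially_variable_genes

spatial, truth = generate_tube_organ(n_units=2000, n_genes=500,
                                     frac_gradient=0.4, seed=20260919)
axis = assign_axis_relative_distance(spatial, "rostral_tip", "caudal_tip")
print(spearmanr(axis.value, truth.true_axis).statistic)   # 0.9824

panel = gradient_gene_ids(truth)[:150]
query, q_truth = generate_dissociated((spatial, truth), 2000, seed=20260921)
res = impute_axis_knn(spatial[:, panel].copy(), axis, query, k=50)
print(np.corrcoef(res.imputed_value, q_truth)[0, 1])      # 0.9245

table = detect_spatially_variable_genes(spatial, axis)
print(int(table["pass"].sum()))                           # 203
```

The Spearman ρ of 0.98 says the landmark-distance coordinate reproduces
the true arc-length ordering of the tube; the Pearson r of 0.92 says a
150-gene panel suffices to place dissociated cells on that axis; and the
203 calls at `p < 0.001`, log2 amplitude > 0.5 recover all 200 planted
gradient genes with 3 false calls among the 300 flat ones.

The same analyses, with commentary and output tables under `results/`,
are available as numbered scripts:

```bash
python analysis/01_simulate_tube.py
python analysis/02_build_axis.py
...
python analysis/07_integration_qc.py
```

and as a CLI over config files or individual stages:

```bash
axistk run --config configs/demo_axis_svg.yaml
axistk simulate --preset tube --out sim/ --seed 7
axistk axis --in sim/ --rostral rostral_tip --caudal caudal_tip --out axis.csv
```

## Layout

- `src/axistk/` — the library: `synthetic`, `io`, `axis`, `imputation`,
  `svg`, `trend`, `crossspecies`, `qc`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers over the library
- `tests/` — unit, property and end-to-end recovery tests
- `docs/methods.md` — models, assumptions, parameter choices, limitations
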