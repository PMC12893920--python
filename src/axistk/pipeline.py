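"""Config-driven end-to-end workflows with a run manifest.

A workflow is described by a single YAML mapping with a ``workflow`` key
(axis_svg, trend, match or qc), a ``seed``, an ``outdir`` and
per-workflow parameters. Unknown keys are rejected before any
computation. Each run writes a ``manifest.json`` recording the resolved
parameters, the package version and SHA-256 checksums of every written
table, so reruns can be verified byte-for-byte. The global seed is
fanned out to per-stage seeds by fixed offsets, keeping each stage
reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .axis import assign_axis_relative_distance, bin_axis
from .crossspecies import (
    build_neighbourhoods,
    harmonize_annotations,
    match_neighbourhoods,
    shared_hvg_space,
)
from .errors import ConfigError
from .imputation import impute_axis_knn
from .io import write_bundle
from .qc import cluster_label_entropy, majority_vote_annotation, tfidf_markers
from .svg import binned_minmax_profiles, detect_spatially_variable_genes
from .synthetic import (
    CAUDAL_LANDMARK,
    ROSTRAL_LANDMARK,
    generate_dissociated,
    generate_species_pair,
    generate_tube_organ,
    gradient_gene_ids,
)
from .trend import jonckheere_test, score_signature

logger = logging.getLogger(__name__)

_COMMON = {"workflow", "seed", "outdir"}

SCHEMAS: dict[str, dict] = {
    "axis_svg": {
        "n_units": 1000,
        "n_genes": 300,
        "frac_gradient": 0.2,
        "amplitude": 1.0,
        "dispersion": 0.5,
        "n_query_cells": 1000,
        "panel_size": 150,
        "k": 50,
        "n_pcs": 30,
        "spline_df": 5,
        "p_max": 0.001,
        "min_log2fc": 0.5,
        "n_bins": 20,
    },
    "trend": {
        "n_units": 1000,
        "n_genes": 300,
        "frac_gradient": 0.2,
        "amplitude": 1.0,
        "dispersion": 0.5,
        "signature_size": 15,
        "n_groups": 3,
        "alternative": "decreasing",
        "n_perm": 2000,
    },
    "match": {
        "n_cells_per_species": 1500,
        "n_populations": 5,
        "n_genes": 400,
        "orth_frac": 0.8,
        "species_shift": 0.0,
        "n_hvg": 4000,
        "k_graph": 30,
        "k_match": 30,
        "sample_prop": 0.1,
    },
    "qc": {
        "n_cells_per_species": 1000,
        "n_populations": 4,
        "n_genes": 300,
        "n_donors": 3,
        "top_n_markers": 10,
    },
}


def load_config(path_or_dict) -> dict:
    """Load and validate a run configuration."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    wf = cfg.get("workflow")
    if wf not in SCHEMAS:
        raise ConfigError(
            f"unknown workflow {wf!r}; expected one of {sorted(SCHEMAS)}"
        )
    allowed = _COMMON | set(SCHEMAS[wf])
    unknown = set(cfg) - allowed
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    if "outdir" not in cfg:
        raise ConfigError("configuration must set 'outdir'")
    resolved = {**SCHEMAS[wf], "seed": 0, **cfg}
    return resolved


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, cfg: dict, outputs: list[Path]) -> dict:
    manifest = {
        "workflow": cfg["workflow"],
        "package_version": __version__,
        "parameters": {k: v for k, v in cfg.items() if k != "outdir"},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_workflow(config) -> dict:
    """Execute a workflow from a config mapping or YAML path.

    Returns the run manifest. Rerunning with an identical configuration
    and seed reproduces byte-identical tabular outputs.
    """
    cfg = load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    runner = {
        "axis_svg": _run_axis_svg,
        "trend": _run_trend,
        "match": _run_match,
        "qc": _run_qc,
    }[cfg["workflow"]]
    try:
        outputs = runner(cfg, outdir)
    except Exception:
        (outdir / ".failed").write_text("workflow failed; partial artifacts retained\n")
        raise
    return _write_manifest(outdir, cfg, outputs)


def _run_axis_svg(cfg: dict, outdir: Path) -> list[Path]:
    seed = int(cfg["seed"])
    logger.info("stage simulate: tube organ n_units=%d", cfg["n_units"])
    spatial, truth = generate_tube_organ(
        n_units=cfg["n_units"],
        n_genes=cfg["n_genes"],
        frac_gradient=cfg["frac_gradient"],
        amplitude=cfg["amplitude"],
        dispersion=cfg["dispersion"],
        seed=seed,
    )
    write_bundle(spatial, outdir / "sim", truth=truth)

    logger.info("stage axis: landmark relative distance")
    axis = assign_axis_relative_distance(spatial, ROSTRAL_LANDMARK, CAUDAL_LANDMARK)
    axis_df = axis.to_frame()
    axis_df["bin"] = bin_axis(axis, n_bins=cfg["n_bins"]).to_numpy()
    axis_path = outdir / "axis.csv"
    axis_df.to_csv(axis_path)

    logger.info("stage impute: kNN transfer onto %d cells", cfg["n_query_cells"])
    panel = gradient_gene_ids(truth)[: cfg["panel_size"]]
    reference = spatial[:, panel] if panel else spatial
    query, q_truth = generate_dissociated(
        (spatial, truth), n_cells=cfg["n_query_cells"], seed=seed + 1
    )
    imputed = impute_axis_knn(
        reference.copy(), axis, query, k=cfg["k"], n_pcs=cfg["n_pcs"], seed=seed + 2
    )
    imp_df = imputed.to_frame()
    imp_df["true_axis"] = q_truth.reindex(imp_df.index).to_numpy()
    imputed_path = outdir / "imputed_axis.csv"
    imp_df.to_csv(imputed_path)

    logger.info("stage svg: spline models for %d genes", spatial.n_vars)
    table = detect_spatially_variable_genes(
        spatial,
        axis,
        p_max=cfg["p_max"],
        min_log2fc=cfg["min_log2fc"],
        spline_df=cfg["spline_df"],
    )
    svg_path = outdir / "svg_results.tsv"
    table.to_csv(svg_path, sep="\t")
    top = table.index[table["pass"]][:50].tolist()
    outputs = [axis_path, imputed_path, svg_path]
    if top:
        prof = binned_minmax_profiles(spatial, axis, top, n_bins=cfg["n_bins"])
        prof_path = outdir / "profiles.tsv"
        prof.to_csv(prof_path, sep="\t")
        outputs.append(prof_path)
    return outputs


def _run_trend(cfg: dict, outdir: Path) -> list[Path]:
    seed = int(cfg["seed"])
    logger.info("stage simulate: tube organ for trend testing")
    spatial, truth = generate_tube_organ(
        n_units=cfg["n_units"],
        n_genes=cfg["n_genes"],
        frac_gradient=cfg["frac_gradient"],
        amplitude=cfg["amplitude"],
        dispersion=cfg["dispersion"],
        seed=seed,
    )
    axis = assign_axis_relative_distance(spatial, ROSTRAL_LANDMARK, CAUDAL_LANDMARK)
    signature = gradient_gene_ids(truth, ["rostral_decreasing"])[: cfg["signature_size"]]

    logger.info("stage score: %d-gene signature", len(signature))
    scores = score_signature(spatial, signature, seed=seed + 1)
    score_series = scores.to_series()
    n_groups = int(cfg["n_groups"])
    group_idx = np.minimum((axis.value * n_groups).astype(int), n_groups - 1)
    groups = np.array([f"region{k}" for k in group_idx])
    df = pd.DataFrame(
        {"unit_id": spatial.obs_names, "score": score_series.to_numpy(), "group": groups}
    ).set_index("unit_id")
    scores_path = outdir / "signature_scores.csv"
    df.to_csv(scores_path)

    logger.info("stage trend: Jonckheere-Terpstra, %s", cfg["alternative"])
    res = jonckheere_test(
        df["score"].to_numpy(),
        df["group"].to_numpy(),
        alternative=cfg["alternative"],
        n_perm=cfg["n_perm"],
        group_order=[f"region{k}" for k in range(n_groups)],
        seed=seed + 2,
    )
    trend_path = outdir / "trend.json"
    trend_path.write_text(
        json.dumps(
            {
                "jt_stat": res.jt_stat,
                "alternative": res.alternative,
                "p_value": res.p_value,
                "n_perm": res.n_perm,
                "group_sizes": res.group_sizes.tolist(),
            },
            indent=2,
        )
    )
    return [scores_path, trend_path]


def _run_match(cfg: dict, outdir: Path) -> list[Path]:
    seed = int(cfg["seed"])
    logger.info("stage simulate: species pair")
    A, B, orth, _truth = generate_species_pair(
        n_cells_per_species=cfg["n_cells_per_species"],
        n_populations=cfg["n_populations"],
        orth_frac=cfg["orth_frac"],
        species_shift=cfg["species_shift"],
        n_genes=cfg["n_genes"],
        seed=seed,
    )
    logger.info("stage features: shared orthologue HVG space")
    shared = shared_hvg_space(A, B, orth, n_hvg=cfg["n_hvg"])
    logger.info("stage neighbourhoods: %d shared features", len(shared))
    key = shared["gene_a"].tolist()
    nbA = build_neighbourhoods(
        A, shared["gene_a"].tolist(), k_graph=cfg["k_graph"],
        sample_prop=cfg["sample_prop"], label_col="population",
        dataset_id="A", seed=seed + 1, feature_key=key,
    )
    nbB = build_neighbourhoods(
        B, shared["gene_b"].tolist(), k_graph=cfg["k_graph"],
        sample_prop=cfg["sample_prop"], label_col="population",
        dataset_id="B", seed=seed + 2, feature_key=key,
    )
    logger.info("stage match: mutual nearest neighbourhoods")
    match = match_neighbourhoods(nbA, nbB, k_match=cfg["k_match"])
    matches = pd.DataFrame(
        {
            "nbhd_a": [nbA.index_units[i] for i, _ in match.pairs],
            "nbhd_b": [nbB.index_units[j] for _, j in match.pairs],
            "label_a": [nbA.majority_label[i] for i, _ in match.pairs],
            "label_b": [nbB.majority_label[j] for _, j in match.pairs],
            "distance": match.distances,
        }
    )
    matches_path = outdir / "matches.tsv"
    matches.to_csv(matches_path, sep="\t", index=False)
    combos = harmonize_annotations(match, nbA, nbB)
    combos_path = outdir / "combinations.tsv"
    combos.to_csv(combos_path, sep="\t", index=False)
    return [matches_path, combos_path]


def _run_qc(cfg: dict, outdir: Path) -> list[Path]:
    seed = int(cfg["seed"])
    logger.info("stage simulate: clustered cells with donors")
    A, _B, _orth, _truth = generate_species_pair(
        n_cells_per_species=cfg["n_cells_per_species"],
        n_populations=cfg["n_populations"],
        n_genes=cfg["n_genes"],
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    donors = np.array([f"donor{d}" for d in rng.integers(cfg["n_donors"], size=A.n_obs)])
    clusters = A.obs["population"].astype(str).to_numpy()

    logger.info("stage entropy: per-cluster donor entropy and majority vote")
    stats = cluster_label_entropy(clusters, donors)
    vote = majority_vote_annotation(clusters, A.obs["population"].astype(str).to_numpy())
    stats = stats.join(vote.add_prefix("vote_"))
    stats_path = outdir / "cluster_stats.tsv"
    stats.to_csv(stats_path, sep="\t")

    logger.info("stage markers: TF-IDF per cluster")
    markers = tfidf_markers(A, clusters, top_n=cfg["top_n_markers"])
    markers_path = outdir / "markers.tsv"
    markers.to_csv(markers_path, sep="\t", index=False)
    return [stats_path, markers_path]
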