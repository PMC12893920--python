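"""Reading/writing 10x-style count bundles, depth normalization and cell QC.

On-disk layout is the Cell Ranger / Space Ranger triplet dialect: a
MatrixMarket ``matrix.mtx`` with genes as rows and units as columns
(1-based indices), headerless tab-separated ``features.tsv`` and
``barcodes.tsv``, plus CSVs with headers for spatial coordinates
(``coords.csv``: unit_id, x_um, y_um, section_id) and landmark
annotations (``landmarks.csv``: unit_id, landmark_label). Gzipped
variants of the triplet files are read transparently.

In memory, datasets are AnnData objects: integer counts in ``.X``
(units x genes, CSR), coordinates in ``.obsm["spatial"]``, section and
landmark labels in ``.obs``. All log transforms are natural log.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ZeroLibraryError

logger = logging.getLogger(__name__)


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_tsv_column(path, column: int = 0) -> list[str]:
    with _open_maybe_gzip(path) as fh:
        return [line.rstrip("\n").split("\t")[column] for line in fh if line.strip()]


def _deduplicate(ids: list[str], what: str) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        if g in seen:
            seen[g] += 1
            new = f"{g}-{seen[g]}"
            warnings.warn(f"duplicated {what} identifier {g!r} renamed to {new!r}")
            out.append(new)
        else:
            seen[g] = 0
            out.append(g)
    return out


def read_expression_matrix(
    matrix_path, features_path, barcodes_path, *, truncate_non_integer: bool = False
) -> ad.AnnData:
    """Read a Cell Ranger-style MTX triplet into an AnnData (units x genes).

    The on-disk matrix stores genes as rows; it is transposed so units
    are observations. 1-based MatrixMarket indices become 0-based
    internally. Duplicate gene identifiers are disambiguated with a
    numeric suffix and a warning.

    Raises
    ------
    FormatError
        If the MTX dimensions disagree with the TSV lengths, or values
        are non-integer (unless ``truncate_non_integer``).
    """
    try:
        M = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # noqa: BLE001 - scipy raises bare ValueError
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}")
    genes = _read_tsv_column(features_path)
    barcodes = _read_tsv_column(barcodes_path)
    if M.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix is {M.shape[0]} x {M.shape[1]} but features.tsv has "
            f"{len(genes)} rows and barcodes.tsv {len(barcodes)}"
        )
    X = sp.csr_matrix(M.T)
    if not np.allclose(X.data, np.round(X.data)):
        if truncate_non_integer:
            X.data = np.trunc(X.data)
        else:
            raise FormatError("matrix contains non-integer values")
    X = X.astype(np.int64)
    if X.nnz and X.data.min() < 0:
        raise FormatError("matrix contains negative values")
    genes = _deduplicate(genes, "gene")
    obs = pd.DataFrame(index=pd.Index(barcodes, name="unit_id"))
    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    return ad.AnnData(X=X, obs=obs, var=var)


def read_bundle(directory) -> ad.AnnData:
    """Read a full bundle directory (triplet + optional coords/landmarks)."""
    d = Path(directory)

    def pick(stem):
        for name in (stem, stem + ".gz"):
            if (d / name).exists():
                return d / name
        raise FileNotFoundError(d / stem)

    adata = read_expression_matrix(
        pick("matrix.mtx"), pick("features.tsv"), pick("barcodes.tsv")
    )
    coords_path = d / "coords.csv"
    if coords_path.exists():
        coords = pd.read_csv(coords_path).set_index("unit_id")
        coords = coords.loc[adata.obs_names]
        adata.obsm["spatial"] = coords[["x_um", "y_um"]].to_numpy(dtype=float)
        adata.obs["section_id"] = pd.Categorical(coords["section_id"].astype(str))
    lm_path = d / "landmarks.csv"
    if lm_path.exists():
        lm = pd.read_csv(lm_path).set_index("unit_id")["landmark_label"]
        adata.obs["landmark_label"] = lm.reindex(adata.obs_names)
    return adata


def write_bundle(adata: ad.AnnData, directory, truth=None) -> None:
    """Write an AnnData as an MTX triplet bundle (plus coords/landmarks).

    ``truth`` (a SyntheticTruth) is serialized to ``truth.json`` when given.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X).T  # genes x units on disk
    scipy.io.mmwrite(str(d / "matrix.mtx"), X, field="integer")
    (d / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in adata.var_names)
    )
    (d / "barcodes.tsv").write_text("".join(f"{b}\n" for b in adata.obs_names))
    if "spatial" in adata.obsm:
        coords = pd.DataFrame(
            {
                "unit_id": adata.obs_names,
                "x_um": adata.obsm["spatial"][:, 0],
                "y_um": adata.obsm["spatial"][:, 1],
                "section_id": adata.obs.get(
                    "section_id", pd.Series("S0", index=adata.obs_names)
                ).astype(str).to_numpy(),
            }
        )
        coords.to_csv(d / "coords.csv", index=False)
    if "landmark_label" in adata.obs:
        lm = adata.obs["landmark_label"]
        lm = lm[lm.notna()]
        pd.DataFrame(
            {"unit_id": lm.index, "landmark_label": lm.to_numpy()}
        ).to_csv(d / "landmarks.csv", index=False)
    if truth is not None:
        payload = {
            "true_axis": {
                k: float(v) for k, v in truth.true_axis.to_dict().items()
            },
            "gradient_table": [
                {
                    "gene_id": g.gene_id,
                    "pattern": g.pattern,
                    "base_mean": g.base_mean,
                    "amplitude": g.amplitude,
                    "dispersion": g.dispersion,
                }
                for g in truth.gradient_table
            ],
            "population_labels": {
                k: str(v) for k, v in truth.population_labels.to_dict().items()
            },
            "section_transforms": {
                k: np.asarray(v).tolist()
                for k, v in truth.section_transforms.items()
            },
        }
        (d / "truth.json").write_text(json.dumps(payload))


def normalize_log_cpm100(adata_or_counts) -> sp.csr_matrix:
    """Depth-normalize counts to ln(CPM/100 + 1).

    value(u, g) = ln(count(u, g) / total(u) * 1e6 / 100 + 1); zeros stay
    zero, so sparsity is preserved. The input counts are not modified.

    Raises
    ------
    ZeroLibraryError
        Naming the first units whose total count is zero.
    """
    X = adata_or_counts.X if isinstance(adata_or_counts, ad.AnnData) else adata_or_counts
    X = sp.csr_matrix(X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        if isinstance(adata_or_counts, ad.AnnData):
            names = list(adata_or_counts.obs_names[zero[:5]])
        else:
            names = list(zero[:5])
        raise ZeroLibraryError(f"units with zero total counts: {names}")
    out = X.copy()
    scale = 1e4 / totals  # 1e6 / 100
    out.data *= np.repeat(scale, np.diff(out.indptr))
    np.log1p(out.data, out=out.data)
    return out


def qc_filter_cells(
    adata: ad.AnnData,
    min_genes: int = 1500,
    max_mito_frac: float = 0.20,
    mito_prefix: str = "MT-",
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove low-complexity and high-mitochondrial units.

    A unit is kept when it detects at least ``min_genes`` genes
    (count > 0) and its mitochondrial count fraction is at most
    ``max_mito_frac``; mitochondrial genes are identified by the id
    prefix. Retained units keep their input order.

    Returns the filtered dataset and a per-unit report with columns
    ``n_genes``, ``mito_frac``, ``doublet_score`` (reserved for external
    scores, NaN here), ``kept`` and ``reason``.
    """
    X = sp.csr_matrix(adata.X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = np.array(
        [g.startswith(mito_prefix) for g in adata.var_names], dtype=bool
    )
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    low_genes = n_genes < min_genes
    high_mito = mito_frac > max_mito_frac
    kept = ~(low_genes | high_mito)
    reason = np.where(
        kept,
        "",
        np.where(
            low_genes & high_mito,
            "low_genes;high_mito",
            np.where(low_genes, "low_genes", "high_mito"),
        ),
    )
    report = pd.DataFrame(
        {
            "n_genes": n_genes,
            "mito_frac": mito_frac,
            "doublet_score": np.nan,
            "kept": kept,
            "reason": reason,
        },
        index=adata.obs_names,
    )
    if not kept.any():
        logger.warning("qc_filter_cells removed every unit")
    return adata[kept].copy(), report
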