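"""Readers and writers for the pipeline's plain-text formats.

Tabular data travels as TSV/CSV with explicit headers; sparse single-cell
counts as MatrixMarket (genes x cells, 10x-style) with line-aligned gene
and cell label files; signatures and scenario configurations as YAML.
Every writer has a matching reader and round-trips exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData
from scipy import io as scipy_io
from scipy import sparse

from .synthetic import ModelPanel

log = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sparse_counts",
    "write_sparse_counts",
    "read_growth_csv",
    "write_growth_csv",
    "read_panel",
    "write_panel",
    "load_scenario",
]

TPM_TOTAL = 1e6


def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    """Write a genes x samples TPM matrix as TSV (gene ids in column 1)."""
    expression.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path, renormalize: bool = False) -> pd.DataFrame:
    """Read a genes x samples TPM matrix from TSV.

    Columns whose sum deviates from 1e6 by more than 1% raise a warning
    (or are rescaled to 1e6 when ``renormalize`` is set).  Duplicate gene
    ids and non-numeric cells are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {path}: {dupes}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric value at gene {gene!r}, sample {col!r}"
                ) from exc
        raise
    sums = df.sum(axis=0)
    off = (sums - TPM_TOTAL).abs() > 0.01 * TPM_TOTAL
    if off.any():
        if renormalize:
            df = df / sums * TPM_TOTAL
            log.info("renormalized %d column(s) to TPM", int(off.sum()))
        else:
            log.warning(
                "%d column(s) deviate from a 1e6 TPM total by >1%%: %s",
                int(off.sum()),
                sums[off].index.tolist(),
            )
    return df


def write_sparse_counts(adata: AnnData, prefix) -> None:
    """Write counts as MTX (genes x cells) + gene and cell label TSVs.

    Produces ``<prefix>.mtx``, ``<prefix>.genes.tsv`` (one id per line) and
    ``<prefix>.cells.tsv`` (cell_id, cluster).
    """
    prefix = str(prefix)
    X = adata.X
    mat = sparse.csr_matrix(X).T.astype(np.int64)  # genes x cells
    scipy_io.mmwrite(prefix + ".mtx", mat)
    Path(prefix + ".genes.tsv").write_text(
        "".join(f"{g}\n" for g in adata.var_names)
    )
    cells = pd.DataFrame(
        {"cell_id": adata.obs_names, "cluster": adata.obs["cluster"].astype(str)}
    )
    cells.to_csv(prefix + ".cells.tsv", sep="\t", index=False)


def read_sparse_counts(path_mtx, path_genes, path_cells) -> AnnData:
    """Read MTX counts plus gene/cell label files into an AnnData.

    The matrix is genes x cells on disk; dimension mismatches against the
    label files are rejected with the expected and found counts.
    """
    mat = scipy_io.mmread(str(path_mtx)).tocsr()
    genes = [line.strip() for line in Path(path_genes).read_text().splitlines() if line.strip()]
    cells = pd.read_csv(path_cells, sep="\t")
    if "cell_id" not in cells.columns or "cluster" not in cells.columns:
        raise ValueError("cell label file must have columns cell_id, cluster")
    n_genes, n_cells = mat.shape
    if len(genes) != n_genes:
        raise ValueError(
            f"gene label mismatch: matrix has {n_genes} genes, file has {len(genes)}"
        )
    if len(cells) != n_cells:
        raise ValueError(
            f"cell label mismatch: matrix has {n_cells} cells, file has {len(cells)}"
        )
    if mat.nnz == 0:
        log.warning("count matrix has no nonzero entries")
    counts = np.asarray(mat.T.todense()).astype(np.int32)
    obs = pd.DataFrame(
        {"cluster": pd.Categorical(cells["cluster"])},
        index=cells["cell_id"].astype(str).tolist(),
    )
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    return AnnData(X=counts, obs=obs, var=var)


def write_growth_csv(growth: pd.DataFrame, path) -> None:
    """Write a long-format growth table (model,arm,animal,day,volume_mm3)."""
    growth.to_csv(path, index=False)


def read_growth_csv(path) -> pd.DataFrame:
    """Read a long-format growth table; accepts length/width columns.

    If the file carries ``length_mm``/``width_mm`` instead of
    ``volume_mm3``, volumes are computed with the caliper formula.
    """
    df = pd.read_csv(path)
    required = {"model", "arm", "animal", "day"}
    if not required.issubset(df.columns):
        raise ValueError(f"growth table must have columns {sorted(required)}")
    if "volume_mm3" not in df.columns:
        if {"length_mm", "width_mm"}.issubset(df.columns):
            from .efficacy import tumor_volume

            df["volume_mm3"] = tumor_volume(
                df["length_mm"].to_numpy(), df["width_mm"].to_numpy()
            )
        else:
            raise ValueError(
                "growth table needs volume_mm3 or length_mm/width_mm columns"
            )
    return df


def write_panel(panel: ModelPanel, outdir, prefix: str = "panel") -> None:
    """Write a model panel: expression TSV plus sample/model metadata CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(panel.expression, outdir / f"{prefix}.expression.tsv")
    panel.samples.to_csv(outdir / f"{prefix}.samples.csv")
    if panel.models is not None:
        panel.models.to_csv(outdir / f"{prefix}.models.csv")


def read_panel(outdir, prefix: str = "panel") -> ModelPanel:
    """Read a model panel written by :func:`write_panel`."""
    outdir = Path(outdir)
    expression = read_expression_tsv(outdir / f"{prefix}.expression.tsv")
    samples = pd.read_csv(outdir / f"{prefix}.samples.csv", index_col=0)
    models_path = outdir / f"{prefix}.models.csv"
    models = pd.read_csv(models_path, index_col=0) if models_path.exists() else None
    return ModelPanel(expression=expression, samples=samples, models=models)


def load_scenario(path_or_name) -> dict:
    """Load a simulation scenario YAML (bundled name or explicit path).

    Bundled scenarios live in ``mvdsig/scenarios``; ``load_scenario("panel12")``
    resolves the default panel scenario.
    """
    p = Path(path_or_name)
    if not p.exists():
        bundled = Path(__file__).parent / "scenarios" / f"{path_or_name}.yaml"
        if bundled.exists():
            p = bundled
        else:
            raise FileNotFoundError(f"no scenario file or bundled scenario {path_or_name!r}")
    with open(p) as fh:
        return yaml.safe_load(fh)
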