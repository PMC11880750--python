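"""Endothelial-cell marker selection from labeled single-cell data.

Given library-size-normalized expression and per-cell cluster labels, genes
enriched in a target cluster are found with a two-sided Mann-Whitney U test
(midranks for ties, normal approximation with continuity correction),
Benjamini-Hochberg adjusted across all tested genes, and filtered by the
standard cluster-marker rule: adjusted P < alpha and log2 fold change above
a threshold (strictly; a gene at exactly the threshold is excluded).

The fold change is computed on normalized means with a pseudocount:
``log2((mean_target + pc) / (mean_rest + pc))``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "normalize_cells",
    "cluster_log2fc",
    "ec_marker_test",
    "bh_adjust",
    "marker_table",
    "select_ec_genes",
]


def _as_dense(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def normalize_cells(
    counts, target_sum: float = 10_000.0, drop_empty: bool = False
) -> np.ndarray:
    """Scale every cell (row) to a common library size.

    ``normalized = counts * target_sum / cell_total``.  Cells with zero
    total are an error unless ``drop_empty`` is set, in which case they are
    removed and the count of dropped cells logged.
    """
    X = _as_dense(counts)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    totals = X.sum(axis=1)
    empty = totals == 0
    if empty.any():
        if not drop_empty:
            raise ValueError(
                f"{int(empty.sum())} cell(s) have zero total counts; "
                "pass drop_empty=True to remove them"
            )
        log.warning("dropping %d empty cell(s)", int(empty.sum()))
        X, totals = X[~empty], totals[~empty]
    return X * (target_sum / totals[:, None])


def _split(X, labels, target_cluster):
    labels = np.asarray(labels)
    mask = labels == target_cluster
    if not mask.any():
        available = sorted(set(labels.tolist()))
        raise ValueError(
            f"cluster {target_cluster!r} not found; available: {available}"
        )
    return mask


def cluster_log2fc(
    normalized, labels, target_cluster, pseudocount: float = 1.0
) -> np.ndarray:
    """Per-gene log2 fold change of the target cluster vs all other cells."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    X = _as_dense(normalized)
    mask = _split(X, labels, target_cluster)
    mean_t = X[mask].mean(axis=0)
    mean_r = X[~mask].mean(axis=0)
    return np.log2((mean_t + pseudocount) / (mean_r + pseudocount))


def ec_marker_test(normalized, labels, target_cluster) -> np.ndarray:
    """Two-sided Mann-Whitney U p-value per gene, target vs rest.

    Ties are handled by midranks with the normal approximation and
    continuity correction; a gene with a single tied value across all cells
    gets p = 1.
    """
    X = _as_dense(normalized)
    mask = _split(X, labels, target_cluster)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("need at least 2 cells in the target cluster and in the rest")
    res = stats.mannwhitneyu(
        X[mask],
        X[~mask],
        axis=0,
        alternative="two-sided",
        method="asymptotic",
        use_continuity=True,
    )
    return np.asarray(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def marker_table(
    normalized,
    labels,
    target_cluster,
    gene_ids,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full per-gene marker statistics for one target cluster.

    Columns: gene, mean_target, mean_rest, log2fc, p, adj_p, passes, with
    ``passes = (adj_p < alpha) & (log2fc > lfc_threshold)``.
    """
    X = _as_dense(normalized)
    mask = _split(X, labels, target_cluster)
    lfc = cluster_log2fc(X, labels, target_cluster, pseudocount)
    p = ec_marker_test(X, labels, target_cluster)
    adj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "gene": np.asarray(gene_ids, dtype=str),
            "mean_target": X[mask].mean(axis=0),
            "mean_rest": X[~mask].mean(axis=0),
            "log2fc": lfc,
            "p": p,
            "adj_p": adj,
        }
    )
    table["passes"] = (table["adj_p"] < alpha) & (table["log2fc"] > lfc_threshold)
    return table


def select_ec_genes(
    table: pd.DataFrame, alpha: float = 0.05, lfc_threshold: float = 1.0
) -> list[str]:
    """Marker genes passing BH-adjusted P < alpha and log2FC > threshold.

    BH is (re)applied across all genes in the table, so the adjustment
    family is every tested gene regardless of how the table was filtered
    upstream.  The result is sorted by descending log2 fold change, ties
    broken lexicographically by gene id.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    required = {"gene", "p", "log2fc"}
    if not required.issubset(table.columns):
        raise ValueError(f"marker table must have columns {sorted(required)}")
    adj = bh_adjust(table["p"].to_numpy())
    keep = (adj < alpha) & (table["log2fc"].to_numpy() > lfc_threshold)
    selected = table.loc[keep, ["gene", "log2fc"]].copy()
    selected = selected.sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="mergesort"
    )
    return selected["gene"].tolist()
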