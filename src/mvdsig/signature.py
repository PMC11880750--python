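"""Building an MVD gene signature from a model panel and single-cell data.

The derivation mirrors how vessel-density surrogates are built in practice:
candidate EC-enriched genes are ranked by the Pearson correlation of their
per-model mean log2(TPM+1) expression with the paired MVD(IHC) measurement
across a panel of tumor models; the top-correlated genes (plus any
well-known EC markers supplied by the caller, e.g. Kdr/Cdh5/Tek) are then
filtered by a single-cell specificity index and truncated to the requested
signature size.

Correlation is computed on per-model means (replicates averaged) so the
sample size of the correlation is the number of models.  Ranking uses
signed r, not |r|: only genes whose abundance tracks vessel density
positively are vessel surrogates.  The specificity index replaces manual
inspection of embedding plots with a numeric criterion: the share of a
gene's total normalized expression that falls in the target cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .synthetic import ModelPanel

log = logging.getLogger(__name__)

__all__ = [
    "SignatureDefinition",
    "model_mean_log_expression",
    "correlate_with_mvd",
    "top_correlated",
    "specificity_index",
    "specificity_indices",
    "build_signature",
]

#: Log-transform convention shared by signature building and scoring.
DEFAULT_TRANSFORM: dict = {"log_base": 2, "pseudocount": 1, "unit": "TPM"}


@dataclass(frozen=True)
class SignatureDefinition:
    """An ordered gene list plus the transform that makes scores meaningful.

    A signature score is the (weighted) mean over the genes of
    ``log(expr + pseudocount)`` in the recorded unit and base; the
    transform is stored with the gene list because a score without it is
    not portable.
    """

    name: str
    genes: tuple[str, ...]
    transform: Mapping = field(default_factory=lambda: dict(DEFAULT_TRANSFORM))

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            # an empty signature can come out of a vacuous specificity
            # filter; it is unusable for scoring and flagged here
            log.warning("signature %r has no genes; it cannot be scored", self.name)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")

    def to_yaml(self, path) -> None:
        payload = {
            "name": self.name,
            "genes": list(self.genes),
            "transform": dict(self.transform),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SignatureDefinition":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            name=payload["name"],
            genes=tuple(payload["genes"]),
            transform=payload.get("transform", dict(DEFAULT_TRANSFORM)),
        )


def model_mean_log_expression(panel: ModelPanel, genes: Sequence[str]) -> pd.DataFrame:
    """Per-model mean over replicates of log2(TPM+1), models x genes."""
    genes = list(genes)
    missing = [g for g in genes if g not in panel.expression.index]
    if missing:
        raise KeyError(f"genes absent from panel expression: {missing}")
    logexpr = np.log2(panel.expression.loc[genes].T + 1.0)
    logexpr["model"] = panel.samples["model"].to_numpy()
    return logexpr.groupby("model", sort=False).mean()


def correlate_with_mvd(
    model_means: pd.DataFrame, model_mvd: pd.Series
) -> pd.DataFrame:
    """Pearson correlation of each gene's model-level expression with MVD.

    ``model_means`` is models x genes (e.g. from
    :func:`model_mean_log_expression`); ``model_mvd`` holds one MVD(IHC)
    value per model (replicates already averaged).  Genes with zero
    variance across models have no defined correlation: they are reported
    as NaN with a warning and excluded from any downstream ranking.
    """
    aligned = model_mvd.reindex(model_means.index)
    if aligned.isna().any():
        raise ValueError("model_mvd must provide a value for every model")
    n = len(aligned)
    if n < 3:
        raise ValueError("need at least 3 models for a correlation p-value")
    mvd = aligned.to_numpy(dtype=float)
    rows = []
    for gene in model_means.columns:
        x = model_means[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(mvd) == 0:
            rows.append((gene, np.nan, np.nan, n))
            continue
        r, p = stats.pearsonr(x, mvd)
        rows.append((gene, r, p, n))
    table = pd.DataFrame(rows, columns=["gene", "pearson_r", "p_value", "n_models"])
    n_bad = int(table["pearson_r"].isna().sum())
    if n_bad:
        log.warning("%d gene(s) with zero variance: correlation undefined", n_bad)
    return table


def top_correlated(correlation_table: pd.DataFrame, k: int = 20) -> list[str]:
    """Top ``k`` genes by descending signed r; ties broken by gene id.

    Genes with undefined correlation are excluded.  If fewer than ``k``
    genes remain, all are returned and the shortfall is logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    valid = correlation_table.dropna(subset=["pearson_r"])
    ranked = valid.sort_values(
        ["pearson_r", "gene"], ascending=[False, True], kind="mergesort"
    )
    if len(ranked) < k:
        log.warning("only %d gene(s) with defined correlation (k=%d)", len(ranked), k)
    return ranked["gene"].head(k).tolist()


def specificity_indices(
    normalized, labels, gene_ids, target_cluster
) -> pd.Series:
    """Share of each gene's total normalized expression in the target cluster.

    1 means exclusively expressed in the target cluster; a gene expressed
    uniformly across k equally sized clusters scores 1/k.  An all-zero gene
    scores 0 by convention (flagged in the log).
    """
    X = np.asarray(normalized, dtype=float)
    labels = np.asarray(labels)
    mask = labels == target_cluster
    if not mask.any():
        raise ValueError(f"cluster {target_cluster!r} not found")
    total = X.sum(axis=0)
    in_target = X[mask].sum(axis=0)
    zero = total == 0
    if zero.any():
        log.warning("%d all-zero gene(s): specificity set to 0", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(zero, 0.0, in_target / np.where(zero, 1.0, total))
    return pd.Series(idx, index=pd.Index(np.asarray(gene_ids, dtype=str), name="gene"))


def specificity_index(normalized, labels, gene_ids, gene, target_cluster) -> float:
    """Specificity of one gene's expression for the target cluster."""
    series = specificity_indices(normalized, labels, gene_ids, target_cluster)
    if gene not in series.index:
        raise KeyError(f"gene {gene!r} not present")
    return float(series[gene])


def build_signature(
    candidates: Sequence[str],
    extra_markers: Sequence[str],
    normalized,
    labels,
    gene_ids,
    target_cluster,
    specificity_threshold: float = 0.5,
    size: int = 6,
    name: str = "MVD",
) -> SignatureDefinition:
    """Assemble a signature from ranked candidates plus known markers.

    The pool is the ranked candidate list (typically :func:`top_correlated`
    output) followed by any ``extra_markers`` not already present, which
    rank after the correlated genes because they carry no r of their own.
    Genes whose single-cell specificity index falls below the threshold are
    dropped, and the survivors are truncated to ``size``.  If fewer than
    ``size`` genes survive, all survivors are returned with a warning.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    pool = list(dict.fromkeys(list(candidates) + list(extra_markers)))
    if not pool:
        raise ValueError("candidate pool is empty")
    spec = specificity_indices(normalized, labels, gene_ids, target_cluster)
    survivors = [
        g for g in pool if g in spec.index and spec[g] >= specificity_threshold
    ]
    if len(survivors) < size:
        log.warning(
            "only %d gene(s) pass the specificity filter (requested %d)",
            len(survivors),
            size,
        )
    return SignatureDefinition(name=name, genes=tuple(survivors[:size]))
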