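"""Signature scoring on bulk expression and TME quadrant classification.

A signature score is the mean over the signature's genes of log2(TPM+1) in
a sample (optionally a weighted mean, for externally defined signatures
such as the T cell-inflamed GEP whose published form carries per-gene
weights).  Samples are classified into four tumor-microenvironment
subgroups by thresholding the MVD gene score and the Tcell_inf_GEP:
cohort-median thresholds for sample-level quadrants, a top-quartile
threshold for the model-level MVD-high/low split.

Conventions, fixed so results are bit-reproducible across tools:

* "high" means strictly above the threshold on each quadrant axis; a
  sample exactly at a threshold is low (logged);
* the model-level top-quartile split uses the inclusive linear-interpolated
  75th percentile and labels values >= the threshold as high, so a panel
  of 12 models yields exactly 3 high models.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signature import SignatureDefinition

log = logging.getLogger(__name__)

__all__ = [
    "signature_score",
    "threshold_median",
    "threshold_top_quartile",
    "high_by_top_quartile",
    "classify_quadrants",
    "subgroup_proportions",
    "compare_signatures",
]


def signature_score(
    expression_tpm: pd.DataFrame,
    signature: SignatureDefinition,
    weights: Mapping[str, float] | None = None,
    max_missing_frac: float = 1 / 3,
) -> pd.Series:
    """Score every sample (column) of a TPM matrix with a signature.

    The score is the mean of ``log2(TPM + 1)`` over the signature genes
    present in the matrix (a weighted mean when ``weights`` is given).
    Missing genes are tolerated up to ``max_missing_frac`` of the
    signature, logged, and recorded in ``result.attrs["n_genes_used"]``.
    """
    genes = list(signature.genes)
    if not genes:
        raise ValueError(f"signature {signature.name!r} has no genes")
    present = [g for g in genes if g in expression_tpm.index]
    n_missing = len(genes) - len(present)
    if not present:
        raise ValueError(
            f"no gene of signature {signature.name!r} is present in the matrix"
        )
    if n_missing / len(genes) > max_missing_frac:
        raise ValueError(
            f"{n_missing}/{len(genes)} signature genes missing "
            f"(limit {max_missing_frac:.0%})"
        )
    if n_missing:
        log.warning(
            "signature %s: %d/%d genes missing from matrix",
            signature.name,
            n_missing,
            len(genes),
        )
    base = signature.transform.get("log_base", 2)
    pc = signature.transform.get("pseudocount", 1)
    logexpr = np.log(expression_tpm.loc[present] + pc) / np.log(base)
    if weights is None:
        scores = logexpr.mean(axis=0)
    else:
        w = np.array([weights[g] for g in present], dtype=float)
        scores = pd.Series(
            (logexpr.to_numpy() * w[:, None]).sum(axis=0) / w.sum(),
            index=logexpr.columns,
        )
    scores.name = signature.name
    scores.attrs["signature"] = signature.name
    scores.attrs["transform"] = dict(signature.transform)
    scores.attrs["n_genes_used"] = len(present)
    scores.attrs["n_genes_missing"] = n_missing
    return scores


def threshold_median(scores) -> float:
    """Sample median (midpoint of the central pair for even n)."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take the median of an empty score vector")
    return float(np.median(arr))


def threshold_top_quartile(model_means) -> float:
    """75th percentile by inclusive linear interpolation (numpy 'linear').

    The high/low rule attached to this threshold is "high iff value >=
    threshold": on 12 distinct model means it labels exactly 3 models high.
    """
    arr = np.asarray(model_means, dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 values for a top-quartile split")
    thr = float(np.percentile(arr, 75, method="linear"))
    if np.ptp(arr) == 0:
        log.warning("all values equal: every model labeled high")
    return thr


def high_by_top_quartile(model_means: pd.Series) -> pd.Series:
    """Boolean high/low labels from the top-quartile threshold (high = >=)."""
    thr = threshold_top_quartile(model_means)
    labels = model_means >= thr
    labels.attrs["threshold"] = thr
    return labels


def classify_quadrants(
    mvd_scores: pd.Series,
    tgep_scores: pd.Series,
    mvd_threshold: float,
    tgep_threshold: float,
) -> pd.Series:
    """Assign each sample one of the four MVD x Tcell_inf_GEP quadrants.

    High means strictly above the threshold on that axis; samples exactly
    at a threshold are classified low (counted in the log).  The thresholds
    are recorded in ``result.attrs``.
    """
    if set(mvd_scores.index) != set(tgep_scores.index):
        raise ValueError("MVD and Tcell_inf_GEP score vectors must cover the same samples")
    tgep_scores = tgep_scores.reindex(mvd_scores.index)
    at_boundary = int(
        ((mvd_scores == mvd_threshold) | (tgep_scores == tgep_threshold)).sum()
    )
    if at_boundary:
        log.info("%d sample(s) exactly at a threshold classified low", at_boundary)
    mvd = np.where(mvd_scores > mvd_threshold, "MVD-high", "MVD-low")
    gep = np.where(
        tgep_scores > tgep_threshold, "Tcell_inf_GEP-high", "Tcell_inf_GEP-low"
    )
    labels = pd.Series(
        [f"{m}/{g}" for m, g in zip(mvd, gep)],
        index=mvd_scores.index,
        name="quadrant",
    )
    labels.attrs["mvd_threshold"] = float(mvd_threshold)
    labels.attrs["tgep_threshold"] = float(tgep_threshold)
    return labels


def subgroup_proportions(labels: pd.Series, group_by: pd.Series) -> pd.DataFrame:
    """Per-group fraction of samples in each quadrant (rows sum to 1)."""
    group_by = group_by.reindex(labels.index)
    if group_by.isna().any():
        n = int(group_by.isna().sum())
        log.warning("%d sample(s) without a group omitted", n)
        keep = group_by.notna()
        labels, group_by = labels[keep], group_by[keep]
    counts = (
        pd.crosstab(group_by, labels)
        .reindex(columns=sorted(labels.unique()), fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def compare_signatures(
    expression_tpm: pd.DataFrame,
    signatures: Sequence[SignatureDefinition],
    reference_values: pd.Series,
) -> pd.DataFrame:
    """Rank signatures by Pearson r of their scores against a reference.

    The reference is typically a measured quantity such as MVD(IHC); a
    vessel-density surrogate should out-correlate generic angiogenic
    signatures.  Returns one row per signature (r, p, n), sorted by
    descending r.
    """
    samples = reference_values.dropna().index
    if len(samples) < 3:
        raise ValueError("need at least 3 samples with reference values")
    ref = reference_values.loc[samples].to_numpy(dtype=float)
    rows = []
    for sig in signatures:
        scores = signature_score(expression_tpm[list(samples)], sig)
        r, p = stats.pearsonr(scores.to_numpy(), ref)
        rows.append((sig.name, r, p, len(samples)))
    table = pd.DataFrame(rows, columns=["signature", "pearson_r", "p_value", "n"])
    return table.sort_values("pearson_r", ascending=False, ignore_index=True)
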