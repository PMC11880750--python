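"""Synthetic data with planted ground truth.

Four generators emulate the inputs of an MVD-signature study so every
downstream stage can be tested without animal or patient data:

* :func:`make_cluster_profiles` — per-cluster mean expression profiles with
  disjoint marker sets, including an endothelial-cell (EC) cluster and an
  immune cluster;
* :func:`simulate_scrnaseq` — negative-binomial single-cell counts with
  per-cell cluster labels;
* :func:`simulate_panel` — a panel of tumor models with replicate bulk TPM
  profiles built as convex mixtures of the cluster profiles, where each
  model's EC mixture weight co-drives a simulated microvessel density
  MVD(IHC) readout (vessels per mm²);
* :func:`simulate_growth` — per-animal exponential tumor-growth curves whose
  treatment effects depend on a planted tumor-microenvironment quadrant.

The bulk model is a pseudo-bulk mixture of cluster mean profiles rather than
an aggregation of simulated cells: it is fast and isolates the EC-fraction
signal the signature pipeline must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData

from ._seeds import stage_rng

__all__ = [
    "ARMS",
    "QUADRANTS",
    "ClusterProfileSet",
    "ModelPanel",
    "make_cluster_profiles",
    "simulate_scrnaseq",
    "simulate_panel",
    "simulate_growth",
    "assign_quadrant_truth",
]

#: Treatment arms of an efficacy study: untreated control, antiangiogenic
#: monotherapy, checkpoint-inhibitor monotherapy, and their combination.
ARMS = ("NT", "drugA", "drugB", "combo")

#: The four tumor-microenvironment subgroups from thresholding the MVD axis
#: and the T cell-inflamed GEP axis.
QUADRANTS = (
    "MVD-high/Tcell_inf_GEP-high",
    "MVD-high/Tcell_inf_GEP-low",
    "MVD-low/Tcell_inf_GEP-high",
    "MVD-low/Tcell_inf_GEP-low",
)


@dataclass(frozen=True)
class ClusterProfileSet:
    """Mean expression profiles for a set of cell clusters.

    ``profiles[c, g]`` is the expected count of gene ``g`` in one cell of
    cluster ``c``.  Marker genes of cluster ``c`` sit at
    ``baseline_mean * 2**marker_log2fc`` in that cluster and at
    ``baseline_mean`` everywhere else; marker sets are disjoint.
    """

    profiles: np.ndarray
    gene_ids: np.ndarray
    cluster_ids: tuple[str, ...]
    marker_assignment: Mapping[str, np.ndarray]
    marker_log2fc: float
    baseline_mean: float
    ec_cluster_id: str = "EC"
    immune_cluster_id: str = "Immune"

    def __post_init__(self) -> None:
        if self.marker_log2fc < 0:
            raise ValueError("marker_log2fc must be >= 0")
        seen: set[int] = set()
        for cluster, idx in self.marker_assignment.items():
            idx = np.asarray(idx)
            if idx.size and idx.max() >= self.n_genes:
                raise ValueError(f"marker index out of range for cluster {cluster}")
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise ValueError(f"marker sets overlap at gene indices {sorted(overlap)}")
            seen.update(idx.tolist())

    @property
    def n_clusters(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_genes(self) -> int:
        return self.profiles.shape[1]

    def marker_genes(self, cluster: str) -> list[str]:
        """Gene identifiers of the planted markers of ``cluster``."""
        return [str(g) for g in self.gene_ids[self.marker_assignment[cluster]]]


@dataclass
class ModelPanel:
    """Bulk TPM expression for a panel of tumor models with paired MVD(IHC).

    ``expression`` is genes x samples (TPM, columns sum to 1e6);
    ``samples`` maps each sample to its model and carries the per-replicate
    MVD(IHC) measurement; ``models`` records the planted EC and immune
    mixture fractions (simulation truth; absent for real data).
    """

    expression: pd.DataFrame
    samples: pd.DataFrame
    models: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.expression.columns.equals(self.samples.index):
            raise ValueError("expression columns and sample table index must match")
        if (self.samples["mvd_ihc"] < 0).any():
            raise ValueError("mvd_ihc must be non-negative")
        sums = self.expression.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1e6, rtol=1e-6):
            raise ValueError("TPM columns must sum to 1e6")

    @property
    def model_ids(self) -> list[str]:
        return list(dict.fromkeys(self.samples["model"]))

    def model_mvd(self) -> pd.Series:
        """Mean MVD(IHC) per model over its replicate measurements."""
        return self.samples.groupby("model", sort=False)["mvd_ihc"].mean()


def make_cluster_profiles(
    n_genes: int,
    n_clusters: int,
    markers_per_cluster: int,
    marker_log2fc: float,
    seed: int,
    baseline_mean: float = 0.5,
) -> ClusterProfileSet:
    """Build cluster mean profiles with disjoint planted marker sets.

    Marker indices are drawn without replacement from all genes, so the
    planted structure is random but reproducible given ``seed``.  Cluster 0
    is the EC cluster and cluster 1 the immune cluster (requires
    ``n_clusters >= 2``).
    """
    if n_genes < 1 or n_clusters < 2:
        raise ValueError("need n_genes >= 1 and n_clusters >= 2")
    if markers_per_cluster < 0:
        raise ValueError("markers_per_cluster must be >= 0")
    if markers_per_cluster > 0 and marker_log2fc <= 0:
        raise ValueError("marker_log2fc must be > 0")
    if markers_per_cluster * n_clusters > n_genes:
        raise ValueError(
            f"cannot allocate {markers_per_cluster} disjoint markers to "
            f"{n_clusters} clusters with only {n_genes} genes"
        )
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be > 0")

    rng = stage_rng(seed, "cluster_profiles")
    gene_ids = np.array([f"G{i:04d}" for i in range(n_genes)])
    cluster_ids = tuple(
        ["EC", "Immune"] + [f"C{i:02d}" for i in range(2, n_clusters)]
    )
    order = rng.permutation(n_genes)
    assignment = {
        cluster_ids[c]: np.sort(
            order[c * markers_per_cluster : (c + 1) * markers_per_cluster]
        )
        for c in range(n_clusters)
    }
    profiles = np.full((n_clusters, n_genes), baseline_mean, dtype=float)
    for c, cid in enumerate(cluster_ids):
        profiles[c, assignment[cid]] = baseline_mean * 2.0**marker_log2fc
    return ClusterProfileSet(
        profiles=profiles,
        gene_ids=gene_ids,
        cluster_ids=cluster_ids,
        marker_assignment=assignment,
        marker_log2fc=marker_log2fc,
        baseline_mean=baseline_mean,
    )


def simulate_scrnaseq(
    profiles: ClusterProfileSet,
    cells_per_cluster: int | Mapping[str, int],
    dispersion: float,
    seed: int,
) -> AnnData:
    """Draw negative-binomial single-cell counts from cluster profiles.

    Counts for a cell of cluster ``c`` are NB with mean ``profiles[c, g]``
    and a single shared dispersion ``theta`` (variance ``mu + mu**2/theta``),
    sampled as a gamma-Poisson mixture.  Large ``theta`` approaches the
    Poisson limit.  Returns an AnnData (cells x genes) with the cluster
    label in ``obs["cluster"]``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if isinstance(cells_per_cluster, int):
        cells_per_cluster = {c: cells_per_cluster for c in profiles.cluster_ids}
    for c, n in cells_per_cluster.items():
        if n < 1:
            raise ValueError(f"cells_per_cluster must be >= 1 (cluster {c})")

    rng = stage_rng(seed, "scrnaseq")
    blocks, labels = [], []
    for c, cid in enumerate(profiles.cluster_ids):
        n_cells = cells_per_cluster[cid]
        mu = np.broadcast_to(profiles.profiles[c], (n_cells, profiles.n_genes))
        lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
        blocks.append(rng.poisson(lam))
        labels.extend([cid] * n_cells)
    counts = np.concatenate(blocks, axis=0).astype(np.int32)
    obs = pd.DataFrame(
        {"cluster": pd.Categorical(labels, categories=list(profiles.cluster_ids))},
        index=[f"cell{i:05d}" for i in range(counts.shape[0])],
    )
    var = pd.DataFrame(index=pd.Index(profiles.gene_ids, name="gene"))
    return AnnData(X=counts, obs=obs, var=var)


def simulate_panel(
    profiles: ClusterProfileSet,
    n_models: int,
    ec_fraction_range: tuple[float, float],
    mvd_slope: float,
    mvd_noise_sd: float,
    bulk_noise_sd: float,
    replicates_per_model: int,
    seed: int,
    immune_fraction_range: tuple[float, float] | None = None,
) -> ModelPanel:
    """Simulate replicate bulk TPM plus paired MVD(IHC) for a model panel.

    Per model ``m`` an EC fraction ``f_m`` is drawn uniformly on
    ``ec_fraction_range`` (and an immune fraction on
    ``immune_fraction_range``, defaulting to the same range).  Bulk
    expression is the convex mixture of cluster TPM profiles with EC weight
    ``f_m``, immune weight ``g_m`` and the remaining weight spread evenly
    over the other clusters, multiplied per gene and replicate by lognormal
    noise (log-sd ``bulk_noise_sd``) and renormalized to TPM.  MVD(IHC) is
    drawn per replicate as ``mvd_slope * f_m + N(0, mvd_noise_sd)``
    truncated at zero.
    """
    lo, hi = ec_fraction_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("ec_fraction_range must satisfy 0 <= lo <= hi <= 1")
    if n_models < 2:
        raise ValueError("need at least 2 models")
    if replicates_per_model < 1:
        raise ValueError("need at least 1 replicate per model")
    if immune_fraction_range is None:
        immune_fraction_range = ec_fraction_range
    ilo, ihi = immune_fraction_range
    if not (0 <= ilo <= ihi <= 1) or hi + ihi > 1:
        raise ValueError("fraction ranges must fit inside the simplex")

    rng = stage_rng(seed, "panel")
    # per-cluster TPM profiles
    cluster_tpm = profiles.profiles / profiles.profiles.sum(axis=1, keepdims=True) * 1e6
    ec_idx = profiles.cluster_ids.index(profiles.ec_cluster_id)
    imm_idx = profiles.cluster_ids.index(profiles.immune_cluster_id)
    other = [i for i in range(profiles.n_clusters) if i not in (ec_idx, imm_idx)]

    model_ids = [f"M{m + 1:02d}" for m in range(n_models)]
    f_ec = rng.uniform(lo, hi, size=n_models)
    f_imm = rng.uniform(ilo, ihi, size=n_models)

    columns, sample_rows = [], []
    expr = np.empty((profiles.n_genes, n_models * replicates_per_model))
    j = 0
    for m, mid in enumerate(model_ids):
        w = np.zeros(profiles.n_clusters)
        w[ec_idx], w[imm_idx] = f_ec[m], f_imm[m]
        w[other] = (1.0 - f_ec[m] - f_imm[m]) / len(other)
        base = w @ cluster_tpm
        for r in range(replicates_per_model):
            noisy = base * np.exp(rng.normal(0.0, bulk_noise_sd, size=profiles.n_genes))
            expr[:, j] = noisy / noisy.sum() * 1e6
            mvd = mvd_slope * f_ec[m] + rng.normal(0.0, mvd_noise_sd)
            sample = f"{mid}_r{r + 1}"
            columns.append(sample)
            sample_rows.append((sample, mid, r + 1, max(mvd, 0.0)))
            j += 1

    expression = pd.DataFrame(
        expr, index=pd.Index(profiles.gene_ids, name="gene"), columns=columns
    )
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "model", "replicate", "mvd_ihc"]
    ).set_index("sample")
    models = pd.DataFrame(
        {"ec_fraction": f_ec, "immune_fraction": f_imm},
        index=pd.Index(model_ids, name="model"),
    )
    return ModelPanel(expression=expression, samples=samples, models=models)


def assign_quadrant_truth(
    panel: ModelPanel,
    mvd_quantile: float = 0.75,
    gep_quantile: float = 0.5,
) -> dict[str, str]:
    """Ground-truth quadrant per model from the planted mixture fractions.

    A model is MVD-high when its planted EC fraction is at or above the
    panel's ``mvd_quantile`` (top quartile by default, mirroring the
    high/low split used on measured MVD), and GEP-high when its planted
    immune fraction is strictly above the ``gep_quantile`` (median).
    """
    if panel.models is None:
        raise ValueError("panel carries no planted truth")
    ec = panel.models["ec_fraction"]
    imm = panel.models["immune_fraction"]
    ec_thr = float(np.percentile(ec, 100 * mvd_quantile))
    imm_thr = float(np.percentile(imm, 100 * gep_quantile))
    out = {}
    for mid in panel.models.index:
        mvd = "MVD-high" if ec[mid] >= ec_thr else "MVD-low"
        gep = "Tcell_inf_GEP-high" if imm[mid] > imm_thr else "Tcell_inf_GEP-low"
        out[mid] = f"{mvd}/{gep}"
    return out


def simulate_growth(
    panel: ModelPanel | Sequence[str],
    quadrant_truth: Mapping[str, str],
    effect_map: Mapping[str, Mapping[str, float]],
    growth_rate: float,
    days: int,
    n_animals: int,
    noise_sd: float,
    seed: int,
    start_volume: float = 100.0,
) -> pd.DataFrame:
    """Simulate per-animal tumor-volume curves for a four-arm efficacy study.

    Each animal follows ``V(t) = V1 * exp(r_eff * (t - 1))`` with
    multiplicative lognormal measurement noise (log-sd ``noise_sd``) and
    ``V1 = start_volume`` (treatment starts at roughly 100 mm³).  The
    effective rate is ``growth_rate * (1 - effect)`` where ``effect`` comes
    from ``effect_map[arm][quadrant_truth[model]]`` (0 when missing; the NT
    arm is always untreated).  ``effect > 1`` produces regression.

    Returns a long-format frame (model, arm, animal, day, volume_mm3).
    """
    if days < 2:
        raise ValueError("need days >= 2")
    if n_animals < 1:
        raise ValueError("need n_animals >= 1")
    model_ids = panel.model_ids if isinstance(panel, ModelPanel) else list(panel)
    for arm, by_quadrant in effect_map.items():
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
        for q in by_quadrant:
            if q not in QUADRANTS:
                raise ValueError(f"unknown quadrant {q!r} in effect_map[{arm!r}]")

    rng = stage_rng(seed, "growth")
    t = np.arange(1, days + 1)
    rows = []
    for mid in model_ids:
        quadrant = quadrant_truth[mid]
        for arm in ARMS:
            effect = 0.0 if arm == "NT" else effect_map.get(arm, {}).get(quadrant, 0.0)
            r_eff = growth_rate * (1.0 - effect)
            mean = start_volume * np.exp(r_eff * (t - 1))
            noise = np.exp(rng.normal(0.0, noise_sd, size=(n_animals, days)))
            volumes = mean[None, :] * noise
            for a in range(n_animals):
                for d in range(days):
                    rows.append((mid, arm, f"{mid}-{arm}-{a + 1}", t[d], volumes[a, d]))
    return pd.DataFrame(rows, columns=["model", "arm", "animal", "day", "volume_mm3"])
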