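"""End-to-end orchestration: simulate → markers → signature → score →
classify → efficacy, with every intermediate written to a run directory
and a machine-readable manifest recording parameters, seed, versions and
input checksums.

The pipeline is hermetic: every file a stage reads or writes is listed in
the manifest, and all randomness derives from the single run seed via
per-stage seed splitting, so identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as mio
from ._seeds import derive_seed
from .efficacy import compare_high_low, delta_t_c_table
from .markers import marker_table, normalize_cells, select_ec_genes
from .scoring import (
    classify_quadrants,
    high_by_top_quartile,
    signature_score,
    threshold_median,
)
from .signature import (
    SignatureDefinition,
    build_signature,
    correlate_with_mvd,
    model_mean_log_expression,
    top_correlated,
)
from .synthetic import (
    assign_quadrant_truth,
    make_cluster_profiles,
    simulate_growth,
    simulate_panel,
    simulate_scrnaseq,
)

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_scenario", "derive_signature"]


def derive_signature(
    adata,
    panel,
    target_cluster: str = "EC",
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    k: int = 20,
    size: int = 6,
    specificity_threshold: float = 0.5,
    extra_markers=(),
    name: str = "MVD",
):
    """Full signature derivation from labeled single-cell data and a panel.

    Runs the stepwise selection: cluster-marker test with BH and the
    adjusted-P/log2FC filter, correlation of per-model mean log expression
    with MVD(IHC), top-k ranking, specificity filter, truncation to
    ``size``.  Returns ``(signature, marker_table, correlation_table)``.
    """
    normalized = normalize_cells(adata.X, drop_empty=True)
    kept = np.asarray(adata.X).sum(axis=1) > 0
    labels = adata.obs["cluster"].to_numpy()[kept]
    table = marker_table(
        normalized,
        labels,
        target_cluster,
        gene_ids=adata.var_names,
        alpha=alpha,
        lfc_threshold=lfc_threshold,
    )
    ec_genes = select_ec_genes(table, alpha=alpha, lfc_threshold=lfc_threshold)
    means = model_mean_log_expression(panel, ec_genes)
    corr = correlate_with_mvd(means, panel.model_mvd())
    candidates = top_correlated(corr, k=k)
    sig = build_signature(
        candidates,
        extra_markers=list(extra_markers),
        normalized=normalized,
        labels=labels,
        gene_ids=adata.var_names,
        target_cluster=target_cluster,
        specificity_threshold=specificity_threshold,
        size=size,
        name=name,
    )
    return sig, table, corr


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_scenario(scenario: dict, seed: int | None = None):
    """Materialize a scenario: profiles, single-cell data, panel, truth, growth.

    ``seed`` overrides the scenario's own seed; per-generator seeds are
    derived from it so each stage has an independent stream.
    """
    seed = int(scenario.get("seed", 0)) if seed is None else int(seed)
    prof_cfg = scenario["profiles"]
    profiles = make_cluster_profiles(
        n_genes=prof_cfg["n_genes"],
        n_clusters=prof_cfg["n_clusters"],
        markers_per_cluster=prof_cfg["markers_per_cluster"],
        marker_log2fc=prof_cfg["marker_log2fc"],
        baseline_mean=prof_cfg.get("baseline_mean", 0.5),
        seed=derive_seed(seed, "profiles"),
    )
    sc_cfg = scenario["scrnaseq"]
    adata = simulate_scrnaseq(
        profiles,
        cells_per_cluster=sc_cfg["cells_per_cluster"],
        dispersion=sc_cfg["dispersion"],
        seed=derive_seed(seed, "scrnaseq"),
    )
    p_cfg = scenario["panel"]
    panel = simulate_panel(
        profiles,
        n_models=p_cfg["n_models"],
        ec_fraction_range=tuple(p_cfg["ec_fraction_range"]),
        immune_fraction_range=tuple(p_cfg.get("immune_fraction_range") or p_cfg["ec_fraction_range"]),
        mvd_slope=p_cfg["mvd_slope"],
        mvd_noise_sd=p_cfg["mvd_noise_sd"],
        bulk_noise_sd=p_cfg["bulk_noise_sd"],
        replicates_per_model=p_cfg["replicates_per_model"],
        seed=derive_seed(seed, "panel"),
    )
    truth = assign_quadrant_truth(panel)
    g_cfg = scenario.get("growth")
    growth = None
    if g_cfg is not None:
        effect_map = g_cfg.get("effect_map", {})
        growth = simulate_growth(
            panel,
            quadrant_truth=truth,
            effect_map=effect_map,
            growth_rate=g_cfg["growth_rate"],
            days=g_cfg["days"],
            n_animals=g_cfg["n_animals"],
            noise_sd=g_cfg["noise_sd"],
            seed=derive_seed(seed, "growth"),
        )
    return profiles, adata, panel, truth, growth


def run_pipeline(config: dict, outdir) -> Path:
    """Run the full derivation workflow on a scenario configuration.

    Stages: simulate, markers, build-signature, score, classify, efficacy.
    Returns the run directory; ``manifest.json`` inside it lists completed
    stages, parameters, the seed, package versions, and output checksums.
    """
    for key in ("profiles", "scrnaseq", "panel", "markers", "signature"):
        if key not in config:
            raise KeyError(f"configuration missing required section {key!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages: list[str] = []
    outputs: dict[str, str] = {}

    def _done(stage: str, *paths: Path) -> None:
        stages.append(stage)
        for p in paths:
            outputs[str(p.relative_to(outdir))] = _sha256(p)

    # --- simulate -------------------------------------------------------
    profiles, adata, panel, truth, growth = simulate_scenario(config, seed=seed)
    mio.write_sparse_counts(adata, outdir / "sc_counts")
    mio.write_panel(panel, outdir)
    truth_path = outdir / "quadrant_truth.csv"
    pd.Series(truth, name="quadrant").rename_axis("model").to_csv(truth_path)
    sim_paths = [
        outdir / "sc_counts.mtx",
        outdir / "sc_counts.genes.tsv",
        outdir / "sc_counts.cells.tsv",
        outdir / "panel.expression.tsv",
        outdir / "panel.samples.csv",
        outdir / "panel.models.csv",
        truth_path,
    ]
    if growth is not None:
        mio.write_growth_csv(growth, outdir / "growth.csv")
        sim_paths.append(outdir / "growth.csv")
    _done("simulate", *sim_paths)

    # --- markers + build-signature --------------------------------------
    m_cfg = config["markers"]
    s_cfg = config["signature"]
    target = m_cfg.get("target_cluster", "EC")
    mvd_sig, table, corr = derive_signature(
        adata,
        panel,
        target_cluster=target,
        alpha=m_cfg.get("alpha", 0.05),
        lfc_threshold=m_cfg.get("lfc_threshold", 1.0),
        k=s_cfg.get("k", 20),
        size=s_cfg.get("size", 6),
        specificity_threshold=s_cfg.get("specificity_threshold", 0.5),
        extra_markers=s_cfg.get("extra_markers") or [],
    )
    table_path = outdir / "marker_table.tsv"
    table.to_csv(table_path, sep="\t", index=False)
    ec_genes = select_ec_genes(
        table, alpha=m_cfg.get("alpha", 0.05), lfc_threshold=m_cfg.get("lfc_threshold", 1.0)
    )
    genes_path = outdir / "ec_genes.txt"
    genes_path.write_text("".join(f"{g}\n" for g in ec_genes))
    _done("markers", table_path, genes_path)

    corr_path = outdir / "mvd_correlations.tsv"
    corr.to_csv(corr_path, sep="\t", index=False)
    sig_path = outdir / "mvd_signature.yaml"
    mvd_sig.to_yaml(sig_path)

    # T cell-inflamed GEP analogue: same marker machinery on the immune
    # cluster; in real use the published gene set is supplied instead.
    gep_cfg = config.get("gep", {})
    gep_cluster = gep_cfg.get("target_cluster", "Immune")
    normalized = normalize_cells(adata.X, drop_empty=True)
    kept = np.asarray(adata.X).sum(axis=1) > 0
    labels = adata.obs["cluster"].to_numpy()[kept]
    gep_table = marker_table(normalized, labels, gep_cluster, gene_ids=adata.var_names)
    gep_genes = select_ec_genes(gep_table)[: gep_cfg.get("size", 6)]
    gep_sig = SignatureDefinition(name="Tcell_inf_GEP", genes=tuple(gep_genes))
    gep_path = outdir / "gep_signature.yaml"
    gep_sig.to_yaml(gep_path)
    _done("build-signature", corr_path, sig_path, gep_path)

    # --- score ----------------------------------------------------------
    mvd_scores = signature_score(panel.expression, mvd_sig)
    gep_scores = signature_score(panel.expression, gep_sig)
    scores = pd.DataFrame({"MVD": mvd_scores, "Tcell_inf_GEP": gep_scores})
    scores_path = outdir / "scores.tsv"
    scores.rename_axis("sample").to_csv(scores_path, sep="\t")
    _done("score", scores_path)

    # --- classify -------------------------------------------------------
    labels_q = classify_quadrants(
        mvd_scores,
        gep_scores,
        mvd_threshold=threshold_median(mvd_scores),
        tgep_threshold=threshold_median(gep_scores),
    )
    quad_path = outdir / "quadrants.tsv"
    out = labels_q.rename_axis("sample").to_frame()
    out["mvd_threshold"] = labels_q.attrs["mvd_threshold"]
    out["tgep_threshold"] = labels_q.attrs["tgep_threshold"]
    out.to_csv(quad_path, sep="\t")

    model_scores = mvd_scores.groupby(panel.samples["model"]).mean()
    high = high_by_top_quartile(model_scores)
    high_path = outdir / "model_high_low.tsv"
    high.rename("mvd_high").rename_axis("model").to_frame().to_csv(high_path, sep="\t")
    _done("classify", quad_path, high_path)

    # --- efficacy -------------------------------------------------------
    if growth is not None:
        e_cfg = config.get("efficacy", {})
        day = e_cfg.get("day", 15)
        dtc = delta_t_c_table(growth, day=day)
        dtc_path = outdir / "delta_t_c.tsv"
        dtc.to_csv(dtc_path, sep="\t", index=False)
        eff_paths = [dtc_path]
        drug_a = dtc[dtc["arm"] == "drugA"].set_index("model")["delta_t_c"]
        if len(drug_a) and high.astype(bool).sum() >= 2 and (~high.astype(bool)).sum() >= 2:
            cmp = compare_high_low(drug_a, high)
            cmp_path = outdir / "high_vs_low.json"
            cmp_path.write_text(
                json.dumps(
                    {
                        "test": cmp.statistic_name,
                        "t": cmp.t,
                        "df": cmp.df,
                        "p": cmp.p,
                        "mean_high": cmp.mean_x,
                        "mean_low": cmp.mean_y,
                        "day": day,
                    },
                    indent=2,
                )
            )
            eff_paths.append(cmp_path)
        _done("efficacy", *eff_paths)

    manifest = {
        "package": "mvdsig",
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "parameters": config,
        "outputs": outputs,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (outdir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    return outdir
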