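import numpy as np
import pandas as pd
import pytest

from mvdsig._seeds import derive_seed
from mvdsig.io import load_scenario
from mvdsig.synthetic import (
    make_cluster_profiles,
    simulate_panel,
    simulate_scrnaseq,
)


@pytest.fixture(scope="session")
def panel12_config() -> dict:
    return load_scenario("panel12")


@pytest.fixture(scope="session")
def small_profiles():
    """A small planted-marker profile set: 200 genes, 4 clusters, 10 markers."""
    return make_cluster_profiles(
        n_genes=200, n_clusters=4, markers_per_cluster=10, marker_log2fc=2.0, seed=11
    )


@pytest.fixture(scope="session")
def small_adata(small_profiles):
    return simulate_scrnaseq(
        small_profiles, cells_per_cluster=100, dispersion=2.0, seed=12
    )


@pytest.fixture(scope="session")
def small_panel(small_profiles):
    return simulate_panel(
        small_profiles,
        n_models=8,
        ec_fraction_range=(0.05, 0.4),
        immune_fraction_range=(0.05, 0.4),
        mvd_slope=500.0,
        mvd_noise_sd=10.0,
        bulk_noise_sd=0.2,
        replicates_per_model=3,
        seed=13,
    )


@pytest.fixture(scope="session")
def panel12_realization(panel12_config):
    """One full realization of the default scenario (shared, read-only)."""
    cfg = panel12_config
    seed = 0
    profiles = make_cluster_profiles(
        n_genes=cfg["profiles"]["n_genes"],
        n_clusters=cfg["profiles"]["n_clusters"],
        markers_per_cluster=cfg["profiles"]["markers_per_cluster"],
        marker_log2fc=cfg["profiles"]["marker_log2fc"],
        baseline_mean=cfg["profiles"]["baseline_mean"],
        seed=derive_seed(seed, "profiles"),
    )
    adata = simulate_scrnaseq(
        profiles,
        cells_per_cluster=cfg["scrnaseq"]["cells_per_cluster"],
        dispersion=cfg["scrnaseq"]["dispersion"],
        seed=derive_seed(seed, "scrnaseq"),
    )
    p = cfg["panel"]
    panel = simulate_panel(
        profiles,
        n_models=p["n_models"],
        ec_fraction_range=tuple(p["ec_fraction_range"]),
        immune_fraction_range=tuple(p["immune_fraction_range"]),
        mvd_slope=p["mvd_slope"],
        mvd_noise_sd=p["mvd_noise_sd"],
        bulk_noise_sd=p["bulk_noise_sd"],
        replicates_per_model=p["replicates_per_model"],
        seed=derive_seed(seed, "panel"),
    )
    return profiles, adata, panel
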