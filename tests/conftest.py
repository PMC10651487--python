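"""Shared fixtures: small synthetic cohorts reused across test modules."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ctap import default_config, generate_cohort
from ctap.simulate import PhenotypeSpec, SimConfig, StateSpec


@pytest.fixture(scope="session")
def preset_cohort():
    """Default six-phenotype preset at a small size (session-cached)."""
    cfg = default_config(n_samples=60, cells_per_sample=(400, 600), seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def naming_cohort():
    """Larger preset cohort used where phenotype naming must be stable."""
    cfg = default_config(n_samples=120, cells_per_sample=(400, 600), seed=5)
    return generate_cohort(cfg)


def two_state_config(theta_expanded: float,
                     theta_other: float = 0.2,
                     n_samples: int = 40,
                     cells_per_sample: tuple[int, int] = (80, 120),
                     centroid_distance: float = 4.0,
                     seed: int = 0) -> SimConfig:
    """Single-type cohort with one state expanded in the first phenotype.

    The first phenotype mixes the two T states at
    ``(theta_expanded, 1 - theta_expanded)``; the second at
    ``(theta_other, 1 - theta_other)``. Compositions are degenerate (all T),
    so the association signal lives purely in the state mixture.
    """
    states = (
        StateSpec("T-x", "T", (0.0, 0.0), emb_sd=1.0, marker_genes=(0, 1),
                  marker_fold=8.0),
        StateSpec("T-y", "T", (centroid_distance, 0.0), emb_sd=1.0,
                  marker_genes=(2, 3), marker_fold=8.0),
    )
    pi = (1.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    phenotypes = (
        PhenotypeSpec("G1", pi, float("inf"),
                      {"T": (theta_expanded, 1.0 - theta_expanded)}),
        PhenotypeSpec("G2", pi, float("inf"),
                      {"T": (theta_other, 1.0 - theta_other)}),
    )
    return SimConfig(n_samples=n_samples, phenotypes=phenotypes,
                     states=states, cells_per_sample=cells_per_sample,
                     n_genes=8, seed=seed)


def homogeneous_state_config(n_samples: int = 30,
                             cells_per_sample: tuple[int, int] = (1500, 2000),
                             seed: int = 0) -> SimConfig:
    """Preset compositions but identical state mixtures in every phenotype.

    With state mixtures held fixed, per-type expression profiles are
    consistent across samples, which isolates the identifiability of
    signature deconvolution from state-mix heterogeneity.
    """
    from ctap.simulate import PhenotypeSpec as PS

    cfg = default_config(n_samples=n_samples,
                         cells_per_sample=cells_per_sample, seed=seed)
    shared = cfg.phenotypes[0].state_props
    phenotypes = tuple(
        PS(p.name, p.composition, p.alpha, shared) for p in cfg.phenotypes)
    from dataclasses import replace
    return replace(cfg, phenotypes=phenotypes)


@pytest.fixture(scope="session")
def planted_expansion_cohort():
    """Two-state cohort where T-x is expanded two-fold in phenotype G1."""
    return generate_cohort(two_state_config(0.4, 0.2, seed=1))


def association_inputs(cohort):
    """Graph/NAM inputs for :func:`ctap.associate` from a cohort."""
    from ctap import build_graph, compute_nam

    emb_cols = [c for c in cohort.cells.columns if c.startswith("emb_")]
    graph = build_graph(cohort.cells[emb_cols].to_numpy(), k=15)
    nam = compute_nam(graph, cohort.cells["sample_id"].tolist(), steps=3)
    meta = cohort.sample_meta.loc[nam.sample_ids]
    covars = pd.DataFrame({
        "age": meta["age"].to_numpy(float),
        "sex": (meta["sex"] == "M").to_numpy(float),
        "log_n_cells": np.log(meta["n_cells"].to_numpy(float)),
    })
    pheno = (cohort.truth.phenotype.loc[nam.sample_ids] == "G1"
             ).to_numpy(float)
    return nam, pheno, covars
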