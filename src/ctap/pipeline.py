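"""End-to-end pipeline runner with manifest and reproducible seeding.

Stages run in dependency order (simulate -> stratify -> associate ->
classify -> downstream); every artifact is listed in ``manifest.json`` with
a sha256 checksum, and each stochastic stage derives its own seed from the
single run seed, so a rerun with identical config produces identical
checksums.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, downstream, io as cio, neighbourhood, simulate, stratify
from .core import child_seed

log = logging.getLogger("ctap")


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    n_samples: int = 60
    cells_per_sample: tuple[int, int] = (300, 500)
    n_genes: int = 120
    alpha: float = 200.0
    k_range: range = range(2, 9)
    n_boot: int = 100
    min_size: int = 3
    min_cells: int = 100
    k_neighbors: int = 30
    steps: int = 3
    n_perm: int = 200
    q: float = 0.05
    associate_cell_type: str = "T"
    z_threshold: float = 0.5

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data or data["seed"] is None:
            raise ValueError("seed is mandatory")
        if "out_dir" not in data:
            raise ValueError("out_dir is mandatory")
        data = dict(data)
        if "k_range" in data and isinstance(data["k_range"], str):
            data["k_range"] = parse_k_range(data["k_range"])
        if "cells_per_sample" in data:
            lo, hi = data["cells_per_sample"]
            data["cells_per_sample"] = (int(lo), int(hi))
        return cls(**data)


def parse_k_range(text: str) -> range:
    """Parse ``"2:8"`` into ``range(2, 9)``; reject empty or inverted spans."""
    try:
        lo, hi = (int(x) for x in text.split(":"))
    except Exception as exc:
        raise ValueError(f"k_range: cannot parse {text!r} (expected LO:HI)"
                         ) from exc
    if lo < 1 or hi < lo:
        raise ValueError(f"k_range: invalid span {text!r} (need 1 <= LO <= HI)")
    return range(lo, hi + 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; return the artifact manifest (also written to disk).

    On failure every file created so far is removed and the exception
    propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def register(path: Path) -> Path:
        created.append(path)
        return path

    try:
        log.info("pipeline start: seed=%d out=%s", config.seed, out)
        # --- simulate -----------------------------------------------------
        sim_cfg = simulate.default_config(
            n_samples=config.n_samples,
            cells_per_sample=config.cells_per_sample,
            n_genes=config.n_genes,
            alpha=config.alpha,
            seed=child_seed(config.seed, "simulate"),
        )
        cohort = simulate.generate_cohort(sim_cfg)
        cohort_dir = out / "cohort"
        cio.write_cohort(cohort, cohort_dir)
        for p in sorted(cohort_dir.iterdir()):
            register(p)

        # --- stratify -----------------------------------------------------
        comp = stratify.compute_composition(cohort.cells,
                                            min_cells=config.min_cells)
        model = stratify.cluster_samples(
            comp, k_range=config.k_range, n_boot=config.n_boot,
            min_size=config.min_size,
            seed=child_seed(config.seed, "stratify"))
        stratify.name_ctaps(model, comp, z_threshold=config.z_threshold)
        labels = pd.DataFrame({
            "sample_id": model.sample_ids,
            "ctap": model.labels,
            "ctap_name": model.label_names(),
        })
        labels_path = register(out / "ctap_labels.tsv")
        labels.to_csv(labels_path, sep="\t", index=False)
        model_path = register(out / "ctap_model.json")
        model_path.write_text(model.to_json())

        # --- associate ----------------------------------------------------
        sub = cohort.subset_cell_type(config.associate_cell_type)
        emb_cols = [c for c in sub.cells.columns if c.startswith("emb_")]
        graph = neighbourhood.build_graph(
            sub.cells[emb_cols].to_numpy(),
            k=min(config.k_neighbors, len(sub.cells) - 1),
            cell_ids=sub.cells["cell_id"].tolist())
        nam = neighbourhood.compute_nam(
            graph, sub.cells["sample_id"].tolist(), steps=config.steps)
        by_sample = labels.set_index("sample_id")
        target = by_sample["ctap_name"].value_counts().index[0]
        pheno = np.array([
            1.0 if by_sample.loc[s, "ctap_name"] == target else 0.0
            for s in nam.sample_ids])
        meta = cohort.sample_meta.loc[nam.sample_ids]
        covars = pd.DataFrame({
            "age": meta["age"].to_numpy(float),
            "sex": (meta["sex"] == "M").to_numpy(float),
            "log_n_cells": np.log(meta["n_cells"].to_numpy(float)),
        })
        result = neighbourhood.associate(
            nam, pheno, covariates=covars, n_perm=config.n_perm, q=config.q,
            seed=child_seed(config.seed, "associate"))
        ncorr_path = register(out / "ncorr.tsv")
        pd.DataFrame({
            "cell_id": nam.cell_ids,
            "ncorr": result.ncorr,
            "significant": result.mask,
        }).to_csv(ncorr_path, sep="\t", index=False)
        summary = neighbourhood.summarize_by_state(result,
                                                   sub.cells["state"])
        summary_path = register(out / "state_summary.tsv")
        summary.to_csv(summary_path, sep="\t")
        global_path = register(out / "association.json")
        global_path.write_text(json.dumps({
            "phenotype": f"one-vs-rest:{target}",
            "cell_type": config.associate_cell_type,
            "global_p": result.global_p,
            "n_perm": result.n_perm,
            "m_star": result.m_star,
        }, indent=1))

        # --- classify -----------------------------------------------------
        flow = simulate.simulate_flow_panel(
            cohort, sim_cfg.flow_noise_sd,
            seed=child_seed(config.seed, "flow"))
        flow_sub = flow.subset(model.sample_ids)
        names = np.asarray(model.label_names())
        loo = classify.loo_accuracy(flow_sub, names)
        sigs = classify.derive_signatures(cohort.counts, cohort.cells,
                                          cohort.gene_ids)
        bulk = simulate.mix_pseudobulk(
            cohort, sim_cfg.bulk_noise_sd,
            seed=child_seed(config.seed, "bulk"))
        proj = classify.bulk_classify(bulk[model.sample_ids], sigs, model)
        bulk_agree = float(np.mean(np.asarray(proj.names) == names))
        classify_path = register(out / "classification.json")
        classify_path.write_text(json.dumps({
            "flow_loo_accuracy": loo,
            "bulk_agreement_with_sc_labels": bulk_agree,
        }, indent=1))

        # --- downstream ---------------------------------------------------
        meta_all = cohort.sample_meta.loc[model.sample_ids]
        var = downstream.variance_explained(
            meta_all["density_score"], names,
            covariates=meta_all[["age"]].assign(
                sex=(meta_all["sex"] == "M").astype(float)))
        comp_mat = comp.subset(model.sample_ids)
        half = comp_mat.n_samples // 2
        stab = downstream.paired_stability_test(
            comp_mat.proportions[:half], comp_mat.proportions[:half],
            n_perm=199, seed=child_seed(config.seed, "stability"))
        downstream_path = register(out / "downstream.json")
        downstream_path.write_text(json.dumps({
            "density_variance_fraction": var.fraction,
            "density_variance_p": None if np.isnan(var.p_value)
            else var.p_value,
            "self_paired_stability_p": stab.p_value,
        }, indent=1))

        manifest = {
            "seed": config.seed,
            "artifacts": [
                {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
                for p in created
            ],
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1))
        log.info("pipeline done: %d artifacts", len(created))
        return manifest
    except Exception:
        for p in created:
            try:
                p.unlink()
            except OSError:
                pass
        raise
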