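"""Cell-type abundance phenotyping of multi-sample cohorts.

Samples are stratified by hierarchically clustering their cell-type
proportion vectors (Ward linkage, Euclidean distance), the number of groups
is chosen by bootstrap stability (adjusted Rand index between the reference
partition and partitions of cell-resampled cohorts), and the resulting
groups are named after their relatively enriched lineages.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from .core import CELL_TYPES, TYPE_LETTERS, CompositionMatrix


@dataclass
class CTAPModel:
    """Fitted abundance-phenotype stratification."""

    linkage: np.ndarray
    stability: dict[int, float]
    k: int
    labels: np.ndarray                  # per-sample labels in 1..k
    sample_ids: list[str]
    centroids: np.ndarray               # (k, n_types) mean proportions
    cell_types: tuple[str, ...]
    names: list[str] | None = None
    z_threshold: float | None = None
    min_size: int = 3

    def label_names(self) -> list[str]:
        """Per-sample phenotype names (requires ``name_ctaps`` to have run)."""
        if self.names is None:
            raise ValueError("model has no names; run name_ctaps first")
        return [self.names[lab - 1] for lab in self.labels]

    def to_json(self) -> str:
        payload = {
            "linkage": self.linkage.tolist(),
            "stability": {str(k): v for k, v in self.stability.items()},
            "k": int(self.k),
            "labels": [int(x) for x in self.labels],
            "sample_ids": list(self.sample_ids),
            "centroids": self.centroids.tolist(),
            "cell_types": list(self.cell_types),
            "names": self.names,
            "z_threshold": self.z_threshold,
            "min_size": int(self.min_size),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CTAPModel":
        d = json.loads(text)
        return cls(
            linkage=np.asarray(d["linkage"], dtype=float),
            stability={int(k): float(v) for k, v in d["stability"].items()},
            k=int(d["k"]),
            labels=np.asarray(d["labels"], dtype=int),
            sample_ids=list(d["sample_ids"]),
            centroids=np.asarray(d["centroids"], dtype=float),
            cell_types=tuple(d["cell_types"]),
            names=d.get("names"),
            z_threshold=d.get("z_threshold"),
            min_size=int(d.get("min_size", 3)),
        )


@dataclass
class ProjectionResult:
    labels: np.ndarray                  # assigned cluster index, 1..k
    names: list[str] | None
    distances: np.ndarray               # (n_new, k) distance to each centroid
    ties: np.ndarray                    # boolean flags for equidistant samples


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray


def compute_composition(cell_table: pd.DataFrame, min_cells: int = 1,
                        cell_types: tuple[str, ...] = CELL_TYPES,
                        ) -> CompositionMatrix:
    """Per-sample cell-type proportions from a per-cell table.

    Samples with fewer than ``min_cells`` cells are excluded with a warning;
    unknown cell-type strings raise.
    """
    required = {"sample_id", "cell_type"}
    if not required.issubset(cell_table.columns):
        raise ValueError(f"cell table must have columns {sorted(required)}")
    unknown = set(cell_table["cell_type"].unique()) - set(cell_types)
    if unknown:
        raise ValueError(f"unknown cell types: {sorted(unknown)}")
    tab = pd.crosstab(cell_table["sample_id"], cell_table["cell_type"])
    tab = tab.reindex(columns=list(cell_types), fill_value=0)
    totals = tab.sum(axis=1)
    keep = totals >= max(min_cells, 1)
    if (~keep).any():
        dropped = list(tab.index[~keep].astype(str))
        warnings.warn(f"excluding {len(dropped)} samples with <{min_cells} "
                      f"cells: {dropped}")
        tab = tab.loc[keep]
    if tab.empty:
        raise ValueError("no samples left after cell-count filtering")
    return CompositionMatrix.from_counts(
        tab.to_numpy(), list(tab.index.astype(str)), tuple(cell_types))


def _partition(Z: np.ndarray, k: int) -> np.ndarray:
    return fcluster(Z, t=k, criterion="maxclust")


def cluster_samples(comp: CompositionMatrix,
                    k_range: range = range(2, 9),
                    n_boot: int = 200,
                    min_size: int = 3,
                    seed: int = 0,
                    force_k: int | None = None,
                    k_tol: float | None = 0.015) -> CTAPModel:
    """Ward/Euclidean stratification with bootstrap-stability model selection.

    For every candidate ``k``, stability(k) is the mean adjusted Rand index
    between the reference partition at ``k`` and partitions of ``n_boot``
    bootstrap cohorts (cells resampled with replacement within each sample,
    compositions recomputed and re-clustered).

    Model selection: on cleanly separated data every cut at or below the true
    number of groups is perfectly stable, so a plain argmax (ties to smaller
    k) collapses to the smallest candidate. The chosen k is therefore the
    **largest** feasible k whose stability is within ``k_tol`` of the
    maximum ("most granular stable partition"); pass ``k_tol=None`` for the
    plain argmax with ties broken toward smaller k. ``force_k`` overrides
    selection entirely.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain positive integers")
    if comp.n_samples <= max(ks):
        raise ValueError("need more samples than the largest candidate k")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if comp.counts is None:
        raise ValueError("composition matrix must carry per-sample cell "
                         "counts for the bootstrap (use from_counts or "
                         "compute_composition)")

    X = comp.proportions
    Z = linkage(X, method="ward")
    ref = {k: _partition(Z, k) for k in ks}
    feasible = [
        k for k in ks
        if len(np.unique(ref[k])) == k
        and np.bincount(ref[k])[1:].min() >= min_size
    ]
    if not feasible and force_k is None:
        raise ValueError(f"k_range {ks} infeasible given min_size={min_size}")

    rng = np.random.default_rng(seed)
    ari_sums = {k: 0.0 for k in ks}
    totals = comp.counts.sum(axis=1)
    probs = comp.counts / totals[:, None]
    # resampling n_s cells with replacement within a sample is exactly a
    # multinomial(n_s, observed proportions) draw on the type counts
    for _ in range(n_boot):
        boot = np.empty_like(probs)
        for i in range(comp.n_samples):
            boot[i] = rng.multinomial(totals[i], probs[i]) / totals[i]
        Zb = linkage(boot, method="ward")
        for k in ks:
            ari_sums[k] += adjusted_rand_score(ref[k], _partition(Zb, k))
    stability = {k: ari_sums[k] / n_boot for k in ks}

    if force_k is not None:
        chosen = int(force_k)
        if chosen not in ref:
            ref[chosen] = _partition(Z, chosen)
    else:
        best = max(stability[k] for k in feasible)
        if k_tol is None:
            chosen = min(k for k in feasible if stability[k] == best)
        else:
            chosen = max(k for k in feasible if stability[k] >= best - k_tol)

    labels = ref[chosen]
    k_eff = int(labels.max())
    centroids = np.vstack([X[labels == c].mean(axis=0)
                           for c in range(1, k_eff + 1)])
    model = CTAPModel(
        linkage=Z, stability=stability, k=k_eff, labels=labels,
        sample_ids=list(comp.sample_ids), centroids=centroids,
        cell_types=comp.cell_types, min_size=min_size,
    )
    name_ctaps(model, comp)
    return model


def name_ctaps(model: CTAPModel, comp: CompositionMatrix,
               z_threshold: float = 0.5) -> list[str]:
    """Name each cluster by its relatively enriched lineages.

    For cluster c and type t, ``z = (cluster mean - cohort mean) / cohort
    sd``; the name concatenates the letters of types with ``z > z_threshold``
    in decreasing-z order (E=endothelial, F=stromal, M=myeloid, T=T,
    B=B/plasma; NK has no letter). If no type passes, the single max-z
    lettered type is used.
    """
    if comp.cell_types != model.cell_types:
        raise ValueError("composition cell types do not match the model")
    X = comp.proportions
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    names: list[str] = []
    for c in range(1, model.k + 1):
        cm = X[model.labels == c].mean(axis=0)
        scored: list[tuple[float, str]] = []
        for j, t in enumerate(model.cell_types):
            letter = TYPE_LETTERS.get(t)
            if letter is None:
                continue
            if sd[j] == 0:
                warnings.warn(f"cell type {t!r} has zero cohort sd; skipped "
                              f"in naming")
                continue
            scored.append(((cm[j] - mean[j]) / sd[j], letter))
        if not scored:
            raise ValueError("no cell type usable for naming")
        passing = sorted([s for s in scored if s[0] > z_threshold],
                         reverse=True)
        if passing:
            names.append("".join(letter for _, letter in passing))
        else:
            names.append(max(scored)[1])
    model.names = names
    model.z_threshold = z_threshold
    return names


def project_samples(model: CTAPModel,
                    comp_new: CompositionMatrix) -> ProjectionResult:
    """Assign new samples to the nearest cluster centroid (Euclidean)."""
    if comp_new.cell_types != model.cell_types:
        raise ValueError(
            f"cell-type column mismatch: model has {model.cell_types}, "
            f"input has {comp_new.cell_types}")
    dists = cdist(comp_new.proportions, model.centroids)
    labels = dists.argmin(axis=1) + 1
    mins = dists.min(axis=1, keepdims=True)
    ties = (dists == mins).sum(axis=1) > 1
    names = None
    if model.names is not None:
        names = [model.names[lab - 1] for lab in labels]
    return ProjectionResult(labels=labels, names=names, distances=dists,
                            ties=ties)


def composition_pca(comp: CompositionMatrix) -> PCAResult:
    """PCA of the column-centred proportion matrix (all components kept)."""
    if comp.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = comp.proportions - comp.proportions.mean(axis=0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    total = (s ** 2).sum()
    if total == 0:
        raise ValueError("no variance across samples")
    return PCAResult(scores=u * s, loadings=vt,
                     variance_fractions=s ** 2 / total)


def cytokine_categorize(pseudobulk: pd.DataFrame,
                        cytokine_gene_ids: list[str],
                        k: int,
                        ctap_labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Cluster samples by effector-gene pseudobulk; compare to CTAP labels.

    Restricts to the listed genes, log1p-CPM transforms, z-scores per gene,
    Ward-clusters samples at ``k`` and returns the partition plus its
    adjusted Rand index against ``ctap_labels``.
    """
    present = [g for g in cytokine_gene_ids if g in pseudobulk.index]
    if len(present) < 2:
        raise ValueError("fewer than 2 listed genes present in the pseudobulk")
    if len(ctap_labels) != pseudobulk.shape[1]:
        raise ValueError("ctap_labels length must match pseudobulk samples")
    cpm = pseudobulk / pseudobulk.sum(axis=0) * 1e6
    expr = np.log1p(cpm.loc[present].to_numpy())
    sd = expr.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} zero-variance genes")
    expr = expr[keep]
    if expr.shape[0] < 2:
        raise ValueError("fewer than 2 informative genes after filtering")
    zs = (expr - expr.mean(axis=1, keepdims=True)) / expr.std(axis=1, keepdims=True)
    Z = linkage(zs.T, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    ari = adjusted_rand_score(np.asarray(ctap_labels), labels)
    return labels, float(ari)
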