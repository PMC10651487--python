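"""Label transfer to flow-style compositions and bulk RNA-seq, and
longitudinal phenotype-transition summaries.

The bulk route derives per-type mean-CPM signature profiles with one-vs-rest
marker genes from single-cell counts, estimates mixing proportions per bulk
sample by non-negative least squares on the marker genes, and assigns the
nearest stratification centroid. This is a transparent, testable realization
of bulk classification; details of any published variant are not reproduced.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import nnls
from scipy.spatial.distance import cdist

from .core import CompositionMatrix, round_half_up_percent
from .stratify import CTAPModel, ProjectionResult, project_samples


@dataclass
class SignatureProfiles:
    """Per-cell-type mean CPM expression profiles plus marker subsets.

    ``profiles`` columns are the CPM-scaled summed counts of each type
    (library-size-weighted mean CPM; columns sum to 1e6);
    ``mean_library_size`` records each type's mean per-cell total count so
    deconvolved count-mass weights can be converted to cell fractions.
    """

    genes: list[str]
    cell_types: tuple[str, ...]
    profiles: pd.DataFrame            # genes x cell types, mean CPM
    markers: dict[str, list[str]]     # cell type -> marker gene ids
    mean_library_size: dict[str, float] | None = None

    def marker_union(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.cell_types:
            for g in self.markers.get(t, []):
                seen.setdefault(g, None)
        return list(seen)


@dataclass
class TransitionSummary:
    """Baseline -> follow-up phenotype transition counts for paired samples."""

    labels: tuple[str, ...]
    matrix: pd.DataFrame              # baseline x follow-up counts
    n_pairs: int
    n_changed: int
    percent_changed: int
    modal_followup: str | None        # most common follow-up among changed
    modal_followup_percent: int | None
    per_arm: dict[str, "TransitionSummary"] | None = None


def flow_nn_classify(train_comp: CompositionMatrix,
                     train_labels: np.ndarray,
                     test_comp: CompositionMatrix,
                     n_neighbors: int = 1,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour classification in proportion space.

    Returns predicted labels and a boolean tie flag per test sample (ties in
    nearest distance resolve to the smaller training-sample index).
    """
    if train_comp.n_samples == 0:
        raise ValueError("empty training set")
    if train_comp.cell_types != test_comp.cell_types:
        raise ValueError("train and test must share cell-type columns")
    train_labels = np.asarray(train_labels)
    if train_labels.size != train_comp.n_samples:
        raise ValueError("train_labels length must match training samples")
    d = cdist(test_comp.proportions, train_comp.proportions)
    if n_neighbors == 1:
        nearest = d.argmin(axis=1)
        mins = d.min(axis=1, keepdims=True)
        ties = (d == mins).sum(axis=1) > 1
        return train_labels[nearest], ties
    order = np.argsort(d, kind="stable", axis=1)[:, :n_neighbors]
    preds, ties = [], []
    for row in order:
        votes = pd.Series(train_labels[row]).value_counts()
        top = votes.max()
        winners = sorted(votes.index[votes == top])
        preds.append(winners[0])
        ties.append(len(winners) > 1)
    return np.asarray(preds), np.asarray(ties)


def loo_accuracy(train_comp: CompositionMatrix,
                 train_labels: np.ndarray) -> float:
    """Leave-one-out accuracy of the 1-NN flow classifier."""
    n = train_comp.n_samples
    if n < 2:
        raise ValueError("leave-one-out requires at least 2 samples")
    train_labels = np.asarray(train_labels)
    d = cdist(train_comp.proportions, train_comp.proportions)
    np.fill_diagonal(d, np.inf)
    nearest = d.argmin(axis=1)
    return float(np.mean(train_labels[nearest] == train_labels))


def derive_signatures(counts: sparse.spmatrix,
                      cell_table: pd.DataFrame,
                      gene_ids: list[str],
                      n_markers: int = 50,
                      expression_floor: float = 10.0,
                      pseudocount: float = 1.0) -> SignatureProfiles:
    """Per-type mean-CPM profiles and one-vs-rest marker genes.

    Markers are the top ``n_markers`` genes per type by one-vs-rest
    log-fold-change among genes whose in-type mean CPM is at least
    ``expression_floor``.
    """
    counts = sparse.csr_matrix(counts)
    if counts.shape[1] != len(cell_table):
        raise ValueError("counts columns must match cell table rows")
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if np.any(totals == 0):
        warnings.warn(f"dropping {(totals == 0).sum()} cells with zero counts")
    types = [t for t in dict.fromkeys(cell_table["cell_type"])]
    profile_cols = {}
    mean_lib = {}
    for t in types:
        mask = ((cell_table["cell_type"] == t).to_numpy()) & (totals > 0)
        n_t = int(mask.sum())
        if n_t == 0:
            raise ValueError(f"cell type {t!r} has no usable cells")
        if n_t < 20:
            warnings.warn(f"cell type {t!r} has only {n_t} cells; profile "
                          f"computed anyway")
        summed = np.asarray(counts[:, mask].sum(axis=1)).ravel()
        profile_cols[t] = summed / summed.sum() * 1e6
        mean_lib[t] = float(totals[mask].mean())
    profiles = pd.DataFrame(profile_cols, index=list(gene_ids))

    markers: dict[str, list[str]] = {}
    for t in types:
        own = profiles[t].to_numpy()
        rest = profiles.drop(columns=t).to_numpy().mean(axis=1)
        lfc = np.log2(own + pseudocount) - np.log2(rest + pseudocount)
        eligible = own >= expression_floor
        idx = np.where(eligible)[0]
        top = idx[np.argsort(lfc[idx], kind="stable")[::-1][:n_markers]]
        markers[t] = [gene_ids[j] for j in top]
    return SignatureProfiles(list(gene_ids), tuple(types), profiles,
                             markers, mean_lib)


def bulk_deconvolve(bulk: pd.DataFrame,
                    signatures: SignatureProfiles,
                    min_shared_markers: int = 50) -> CompositionMatrix:
    """NNLS mixing-proportion estimates from marker-gene CPM vectors.

    Each bulk column is CPM-normalized, restricted to the marker-gene union
    shared with the signatures, regressed (non-negatively) on the per-type
    profiles, and the coefficients are closed to sum 1.
    """
    shared = [g for g in signatures.marker_union() if g in bulk.index]
    if len(shared) < min_shared_markers:
        raise ValueError(
            f"only {len(shared)} marker genes shared between bulk and "
            f"signatures (need >= {min_shared_markers})")
    col_sums = bulk.sum(axis=0)
    zero = list(col_sums.index[col_sums == 0].astype(str))
    if zero:
        raise ValueError(f"all-zero bulk columns for samples: {zero}")
    cpm = bulk / col_sums * 1e6
    A = signatures.profiles.loc[shared].to_numpy()
    libs = np.ones(len(signatures.cell_types))
    if signatures.mean_library_size is not None:
        libs = np.asarray([signatures.mean_library_size[t]
                           for t in signatures.cell_types])
    rows = []
    for s in cpm.columns:
        coef, _ = nnls(A, cpm[s].loc[shared].to_numpy())
        if coef.sum() == 0:
            raise ValueError(f"NNLS returned all-zero coefficients for "
                             f"sample {s!r}")
        cells = coef / libs  # count-mass weights -> cell fractions
        rows.append(cells / cells.sum())
    return CompositionMatrix(np.vstack(rows), list(map(str, cpm.columns)),
                             signatures.cell_types)


def bulk_classify(bulk: pd.DataFrame,
                  signatures: SignatureProfiles,
                  ctap_model: CTAPModel) -> ProjectionResult:
    """Deconvolve bulk samples then assign nearest stratification centroids."""
    comp = bulk_deconvolve(bulk, signatures)
    if comp.cell_types != ctap_model.cell_types:
        order = [comp.cell_types.index(t) for t in ctap_model.cell_types]
        comp = CompositionMatrix(comp.proportions[:, order], comp.sample_ids,
                                 ctap_model.cell_types)
    return project_samples(ctap_model, comp)


def _summary(t0: pd.Series, t1: pd.Series,
             labels: tuple[str, ...]) -> TransitionSummary:
    matrix = pd.crosstab(t0, t1).reindex(index=list(labels),
                                         columns=list(labels), fill_value=0)
    matrix.index.name = "baseline"
    matrix.columns.name = "followup"
    changed = t0.to_numpy() != t1.to_numpy()
    n_pairs = len(t0)
    n_changed = int(changed.sum())
    modal = None
    modal_pct = None
    if n_changed:
        counts = t1[changed].value_counts()
        top = counts.max()
        modal = sorted(counts.index[counts == top])[0]
        modal_pct = round_half_up_percent(top / n_changed)
    return TransitionSummary(
        labels=labels, matrix=matrix, n_pairs=n_pairs, n_changed=n_changed,
        percent_changed=round_half_up_percent(n_changed / n_pairs)
        if n_pairs else 0,
        modal_followup=modal, modal_followup_percent=modal_pct,
    )


def transition_summary(labels_t0: pd.Series,
                       labels_t1: pd.Series,
                       arm: pd.Series | None = None) -> TransitionSummary:
    """Transition counts between baseline and follow-up phenotype labels.

    Inputs are Series indexed by patient/sample id; ids present at only one
    timepoint are excluded with a warning. ``percent_changed`` is rounded to
    the nearest integer (halves up). When ``arm`` is given, per-arm
    summaries are attached.
    """
    t0 = pd.Series(labels_t0).astype(str)
    t1 = pd.Series(labels_t1).astype(str)
    common = t0.index.intersection(t1.index)
    unmatched = sorted(set(t0.index.symmetric_difference(t1.index)).union())
    if unmatched:
        warnings.warn(f"excluding {len(unmatched)} unmatched ids: "
                      f"{[str(u) for u in unmatched]}")
    if len(common) == 0:
        raise ValueError("no paired ids present at both timepoints")
    t0, t1 = t0.loc[common], t1.loc[common]
    labels = tuple(sorted(set(t0) | set(t1)))
    out = _summary(t0, t1, labels)
    if arm is not None:
        arm = pd.Series(arm).astype(str).reindex(common)
        if arm.isna().any():
            raise ValueError("arm labels missing for some paired ids")
        out.per_arm = {
            a: _summary(t0[arm == a], t1[arm == a], labels)
            for a in sorted(arm.unique())
        }
    return out
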