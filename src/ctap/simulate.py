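"""Synthetic multi-sample single-cell cohorts.

Generates cohorts with the statistical structure the abundance-phenotype
analyses assume: per-sample cell-type compositions drawn from phenotype-
specific Dirichlet distributions, within-type state mixtures, Gaussian
embeddings per state, negative-binomial counts with planted marker /
cytokine / risk genes, plus pseudobulk and flow-style derivatives.

All randomness flows from ``SimConfig.seed``; no global state is touched.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .core import CELL_TYPES, CompositionMatrix


@dataclass(frozen=True)
class StateSpec:
    """A fine cell state within one major cell type.

    ``marker_genes`` are 0-based gene indices whose mean expression is
    multiplied by ``marker_fold`` in cells of this state.
    """

    name: str
    cell_type: str
    centroid: tuple[float, ...]
    emb_sd: float = 0.5
    marker_genes: tuple[int, ...] = ()
    marker_fold: float = 8.0


@dataclass(frozen=True)
class PhenotypeSpec:
    """A latent sample-level phenotype.

    ``composition`` is the mean proportion vector over the 6 canonical types;
    per-sample compositions are drawn from Dirichlet(alpha * composition).
    ``state_props`` gives, per cell type, the mixing proportions over that
    type's states (ordered as in ``SimConfig.states``).
    """

    name: str
    composition: tuple[float, ...]
    alpha: float
    state_props: dict[str, tuple[float, ...]]


@dataclass(frozen=True)
class SimConfig:
    n_samples: int
    phenotypes: tuple[PhenotypeSpec, ...]
    states: tuple[StateSpec, ...]
    cells_per_sample: tuple[int, int]
    n_genes: int
    nb_dispersion: float = 2.0
    base_mean: float = 3.0
    flow_noise_sd: float = 0.1
    bulk_noise_sd: float = 0.2
    embedding_dim: int = 2
    cytokine_genes: dict[str, tuple[int, ...]] = field(default_factory=dict)
    cytokine_fold: float = 6.0
    risk_genes: dict[str, tuple[int, ...]] = field(default_factory=dict)
    risk_fold: float = 4.0
    seed: int = 0

    def states_of(self, cell_type: str) -> list[StateSpec]:
        return [s for s in self.states if s.cell_type == cell_type]

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        lo, hi = self.cells_per_sample
        if lo < 1 or hi < lo:
            raise ValueError("cells_per_sample range must satisfy 1 <= lo <= hi")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.nb_dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("nb_dispersion and base_mean must be positive")
        if self.flow_noise_sd < 0 or self.bulk_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")
        if not self.phenotypes:
            raise ValueError("at least one phenotype is required")
        for state in self.states:
            if state.cell_type not in CELL_TYPES:
                raise ValueError(f"state {state.name!r}: unknown cell type "
                                 f"{state.cell_type!r}")
            if state.emb_sd <= 0:
                raise ValueError(f"state {state.name!r}: emb_sd must be positive")
            if len(state.centroid) != self.embedding_dim:
                raise ValueError(f"state {state.name!r}: centroid dimension "
                                 f"!= embedding_dim")
            for g in state.marker_genes:
                if not 0 <= g < self.n_genes:
                    raise ValueError(f"state {state.name!r}: marker gene {g} "
                                     f"out of range")
        planted = dict(self.cytokine_genes) | dict(self.risk_genes)
        state_names = {s.name for s in self.states}
        for name, genes in planted.items():
            if name not in state_names:
                raise ValueError(f"planted genes reference unknown state {name!r}")
            for g in genes:
                if not 0 <= g < self.n_genes:
                    raise ValueError(f"planted gene {g} out of range")
        for ph in self.phenotypes:
            pi = np.asarray(ph.composition, dtype=float)
            if pi.shape != (len(CELL_TYPES),):
                raise ValueError(f"phenotype {ph.name!r}: composition must have "
                                 f"{len(CELL_TYPES)} entries")
            if np.any(pi < 0) or pi.sum() == 0:
                raise ValueError(f"phenotype {ph.name!r}: empty or negative "
                                 f"composition")
            if abs(pi.sum() - 1.0) > 1e-9:
                raise ValueError(f"phenotype {ph.name!r}: composition must sum "
                                 f"to 1 within 1e-9")
            if not (ph.alpha > 0):
                raise ValueError(f"phenotype {ph.name!r}: alpha must be > 0")
            for t, pi_t in zip(CELL_TYPES, pi):
                if pi_t > 0:
                    states_t = self.states_of(t)
                    if not states_t:
                        raise ValueError(f"phenotype {ph.name!r}: no states "
                                         f"defined for cell type {t!r}")
                    theta = np.asarray(ph.state_props.get(t, ()), dtype=float)
                    if theta.shape != (len(states_t),):
                        raise ValueError(
                            f"phenotype {ph.name!r}: state_props[{t!r}] must "
                            f"have {len(states_t)} entries")
                    if np.any(theta < 0) or abs(theta.sum() - 1.0) > 1e-9:
                        raise ValueError(
                            f"phenotype {ph.name!r}: state_props[{t!r}] must "
                            f"be non-negative and sum to 1 within 1e-9")


@dataclass
class Truth:
    """Generating ground truth attached to a synthetic cohort."""

    phenotype: pd.Series          # per-sample phenotype label
    composition: pd.DataFrame     # per-sample true (drawn) composition
    state: pd.Series              # per-cell state label
    gene_base_mean: np.ndarray | None = None
    state_means: dict[str, np.ndarray] | None = None

    def __eq__(self, other: object) -> bool:  # generator internals excluded
        if not isinstance(other, Truth):
            return NotImplemented
        return (self.phenotype.equals(other.phenotype)
                and np.allclose(self.composition.to_numpy(),
                                other.composition.to_numpy(), atol=1e-12)
                and list(self.composition.index) == list(other.composition.index)
                and self.state.equals(other.state))


@dataclass
class SyntheticCohort:
    """Cells + counts + metadata + ground truth for one simulated cohort."""

    cells: pd.DataFrame           # cell_id, sample_id, cell_type, state, emb_*
    counts: sparse.csr_matrix     # genes x cells, non-negative integers
    gene_ids: list[str]
    sample_meta: pd.DataFrame     # indexed by sample_id
    truth: Truth
    config: SimConfig | None = None

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_meta.index)

    def subset_cell_type(self, cell_type: str) -> "SyntheticCohort":
        """Restrict to cells of one major type (counts columns included)."""
        mask = (self.cells["cell_type"] == cell_type).to_numpy()
        cells = self.cells.loc[mask].reset_index(drop=True)
        truth = Truth(
            phenotype=self.truth.phenotype,
            composition=self.truth.composition,
            state=self.truth.state[mask].reset_index(drop=True),
            gene_base_mean=self.truth.gene_base_mean,
            state_means=self.truth.state_means,
        )
        return SyntheticCohort(cells, self.counts[:, mask], list(self.gene_ids),
                               self.sample_meta, truth, self.config)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticCohort):
            return NotImplemented
        if self.gene_ids != other.gene_ids:
            return False
        if not self.cells.equals(other.cells):
            return False
        if self.counts.shape != other.counts.shape:
            return False
        if (self.counts != other.counts).nnz != 0:
            return False
        if not self.sample_meta.equals(other.sample_meta):
            return False
        return self.truth == other.truth


def _state_mean_matrix(config: SimConfig, base: np.ndarray) -> dict[str, np.ndarray]:
    """Per-state mean expression vectors with planted elevations applied."""
    means: dict[str, np.ndarray] = {}
    for state in config.states:
        mu = base.copy()
        if state.marker_genes:
            mu[list(state.marker_genes)] *= state.marker_fold
        for g in config.cytokine_genes.get(state.name, ()):
            mu[g] *= config.cytokine_fold
        for g in config.risk_genes.get(state.name, ()):
            mu[g] *= config.risk_fold
        means[state.name] = mu
    return means


def _draw_dirichlet(rng: np.random.Generator, alpha: float,
                    pi: np.ndarray) -> np.ndarray:
    """Dirichlet(alpha * pi) supporting zero entries and alpha = inf."""
    if math.isinf(alpha):
        return pi.copy()
    out = np.zeros_like(pi)
    support = pi > 0
    if support.sum() == 1:
        out[support] = 1.0
        return out
    out[support] = rng.dirichlet(alpha * pi[support])
    return out


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float,
             n_cells: int) -> np.ndarray:
    """NB(mean=mu, size=dispersion) draws, shape (len(mu), n_cells)."""
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p[:, None],
                                 size=(mu.size, n_cells))


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a cohort from ``config``; fully reproducible from its seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_types = len(CELL_TYPES)
    g = config.n_genes
    base = rng.lognormal(mean=np.log(config.base_mean), sigma=0.4, size=g)
    state_means = _state_mean_matrix(config, base)
    states_by_type = {t: config.states_of(t) for t in CELL_TYPES}

    lo, hi = config.cells_per_sample
    n_ph = len(config.phenotypes)
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    phen_labels = [config.phenotypes[i % n_ph].name for i in range(config.n_samples)]

    comp_rows = np.zeros((config.n_samples, n_types))
    sample_col: list[np.ndarray] = []
    type_col: list[str] = []
    state_col: list[str] = []
    for i, sid in enumerate(sample_ids):
        ph = config.phenotypes[i % n_ph]
        pi = np.asarray(ph.composition, dtype=float)
        n_cells = int(rng.integers(lo, hi + 1))
        p_s = _draw_dirichlet(rng, ph.alpha, pi)
        comp_rows[i] = p_s
        type_counts = rng.multinomial(n_cells, p_s)
        for t, n_t in zip(CELL_TYPES, type_counts):
            if n_t == 0:
                continue
            states_t = states_by_type[t]
            theta = np.asarray(ph.state_props[t], dtype=float)
            state_counts = rng.multinomial(n_t, theta)
            for spec, n_st in zip(states_t, state_counts):
                if n_st == 0:
                    continue
                sample_col.append(np.full(n_st, i, dtype=np.int64))
                type_col.extend([t] * n_st)
                state_col.extend([spec.name] * n_st)

    sample_idx = (np.concatenate(sample_col) if sample_col
                  else np.empty(0, dtype=np.int64))
    n_total = sample_idx.size
    state_arr = np.asarray(state_col, dtype=object)

    # Embeddings and counts are drawn per state block (cells of the same
    # state are contiguous within a sample, but blocks are gathered across
    # samples by boolean masks to keep the draws vectorized).
    emb = np.empty((n_total, config.embedding_dim))
    counts_blocks: list[sparse.csr_matrix] = []
    col_order: list[np.ndarray] = []
    for spec in config.states:
        mask = state_arr == spec.name
        n_st = int(mask.sum())
        if n_st == 0:
            continue
        idx = np.where(mask)[0]
        emb[idx] = rng.normal(loc=np.asarray(spec.centroid),
                              scale=spec.emb_sd,
                              size=(n_st, config.embedding_dim))
        block = _nb_draw(rng, state_means[spec.name], config.nb_dispersion, n_st)
        counts_blocks.append(sparse.csr_matrix(block.astype(np.int64)))
        col_order.append(idx)
    if counts_blocks:
        stacked = sparse.hstack(counts_blocks, format="csc")
        perm = np.argsort(np.concatenate(col_order), kind="stable")
        counts = stacked[:, perm].tocsr()
    else:
        counts = sparse.csr_matrix((g, 0), dtype=np.int64)

    cell_ids = [f"C{j:06d}" for j in range(n_total)]
    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "sample_id": [sample_ids[j] for j in sample_idx],
        "cell_type": type_col,
        "state": state_col,
    })
    for d in range(config.embedding_dim):
        cells[f"emb_{d + 1}"] = emb[:, d]

    n_cells_per_sample = np.bincount(sample_idx, minlength=config.n_samples)
    sample_meta = pd.DataFrame({
        "sample_id": sample_ids,
        "age": np.round(rng.normal(55.0, 12.0, config.n_samples), 1),
        "sex": rng.choice(["F", "M"], size=config.n_samples),
        "site": rng.choice(["site_A", "site_B", "site_C"], size=config.n_samples),
        "timepoint": np.zeros(config.n_samples, dtype=np.int64),
        "n_cells": n_cells_per_sample.astype(np.int64),
        "CDAI": np.round(np.clip(rng.normal(28.0, 8.0, config.n_samples), 10, None), 1),
        "DAS28_CRP": np.round(rng.normal(5.0, 1.0, config.n_samples), 2),
        "CCP_titre": np.round(rng.lognormal(3.0, 1.0, config.n_samples), 1),
        "krenn_inflammation": rng.integers(0, 4, config.n_samples).astype(np.int64),
        "krenn_lining": rng.integers(0, 4, config.n_samples).astype(np.int64),
        "density_score": np.round(rng.uniform(0, 3, config.n_samples), 2),
        "aggregate_score": np.round(rng.uniform(0, 3, config.n_samples), 2),
        "treatment_arm": rng.choice(["arm_1", "arm_2"], size=config.n_samples),
    }).set_index("sample_id")

    truth = Truth(
        phenotype=pd.Series(phen_labels, index=sample_meta.index, name="phenotype"),
        composition=pd.DataFrame(comp_rows, index=sample_meta.index,
                                 columns=list(CELL_TYPES)),
        state=cells["state"].copy(),
        gene_base_mean=base,
        state_means=state_means,
    )
    gene_ids = [f"g{j:05d}" for j in range(g)]
    return SyntheticCohort(cells, counts, gene_ids, sample_meta, truth, config)


def pseudobulk_counts(cohort: SyntheticCohort) -> pd.DataFrame:
    """Raw per-sample count sums (genes x samples), before normalization."""
    sample_ids = cohort.sample_ids
    n_cells = cohort.cells["sample_id"].value_counts()
    empty = [s for s in sample_ids if n_cells.get(s, 0) == 0]
    if empty:
        raise ValueError(f"samples with zero cells: {empty}")
    pos = {s: j for j, s in enumerate(sample_ids)}
    col = cohort.cells["sample_id"].map(pos).to_numpy()
    ind = sparse.csr_matrix(
        (np.ones(len(col)), (np.arange(len(col)), col)),
        shape=(len(col), len(sample_ids)),
    )
    sums = np.asarray((cohort.counts @ ind).todense())
    return pd.DataFrame(sums, index=cohort.gene_ids, columns=sample_ids)


def mix_pseudobulk(cohort: SyntheticCohort, noise_sd: float,
                   seed: int = 0) -> pd.DataFrame:
    """Library-size-normalized pseudobulk with lognormal gene-wise noise.

    Per-sample counts are summed, scaled to counts-per-million and, when
    ``noise_sd > 0``, multiplied entry-wise by lognormal(0, noise_sd**2)
    factors. ``noise_sd=0`` returns the exact CPM pseudobulk.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    bulk = pseudobulk_counts(cohort)
    totals = bulk.sum(axis=0)
    cpm = bulk / totals * 1e6
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cpm = cpm * rng.lognormal(0.0, noise_sd, size=cpm.shape)
    return cpm


def simulate_flow_panel(cohort: SyntheticCohort, noise_sd: float,
                        seed: int = 0) -> CompositionMatrix:
    """Noisy flow-style composition: log-space jitter closed onto the simplex.

    With ``noise_sd=0`` the true composition is returned exactly; zero
    proportions remain exactly zero (log 0 = -inf is preserved).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    truth = cohort.truth.composition.to_numpy(float)
    with np.errstate(divide="ignore"):
        logp = np.log(truth)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        logp = logp + rng.normal(0.0, noise_sd, size=logp.shape)
    shifted = logp - logp.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    closed = expd / expd.sum(axis=1, keepdims=True)
    return CompositionMatrix(closed, cohort.sample_ids, CELL_TYPES)


# ---------------------------------------------------------------------------
# Default preset: six phenotypes named by their enriched lineages. The
# composition means are package defaults chosen so that the naming rule
# recovers {EFM, F, TF, TB, TM, M}; they are illustrative, not measured.
# ---------------------------------------------------------------------------

_PRESET_COMPOSITIONS: dict[str, tuple[float, ...]] = {
    #            T      B/pl   NK     mye    str    endo
    "EFM": (0.066, 0.032, 0.019, 0.322, 0.301, 0.260),
    "F":   (0.031, 0.251, 0.230, 0.131, 0.323, 0.034),
    "TF":  (0.374, 0.251, 0.014, 0.062, 0.259, 0.040),
    "TB":  (0.428, 0.314, 0.048, 0.078, 0.056, 0.076),
    "TM":  (0.376, 0.253, 0.015, 0.304, 0.036, 0.016),
    "M":   (0.074, 0.250, 0.104, 0.389, 0.072, 0.111),
}


def _preset_states(n_genes: int) -> tuple[StateSpec, ...]:
    layout = [
        ("T-naive", "T", (0.0, 0.0)),
        ("T-ph", "T", (0.0, 4.0)),
        ("T-gzmb", "T", (4.0, 0.0)),
        ("B-mem", "B/plasma", (8.0, 0.0)),
        ("B-abc", "B/plasma", (8.0, 4.0)),
        ("B-plasma", "B/plasma", (12.0, 0.0)),
        ("NK-gzmk", "NK", (0.0, 8.0)),
        ("NK-gzmb", "NK", (4.0, 8.0)),
        ("M-mertk", "myeloid", (8.0, 8.0)),
        ("M-il1b", "myeloid", (12.0, 8.0)),
        ("M-spp1", "myeloid", (8.0, 12.0)),
        ("F-lining", "stromal", (0.0, 12.0)),
        ("F-sublining", "stromal", (0.0, 16.0)),
        ("F-cxcl12", "stromal", (4.0, 16.0)),
        ("E-cap", "endothelial", (12.0, 16.0)),
        ("E-ven", "endothelial", (16.0, 16.0)),
    ]
    specs = []
    for j, (name, cell_type, centroid) in enumerate(layout):
        markers = tuple(range(4 * j, 4 * j + 4))
        markers = tuple(m for m in markers if m < n_genes)
        specs.append(StateSpec(name, cell_type, centroid, emb_sd=0.6,
                               marker_genes=markers, marker_fold=8.0))
    return tuple(specs)


_PRESET_STATE_PROPS: dict[str, dict[str, tuple[float, ...]]] = {
    # state order follows _preset_states within each type:
    # T: (naive, ph, gzmb); B: (mem, abc, plasma); NK: (gzmk, gzmb);
    # myeloid: (mertk, il1b, spp1); stromal: (lining, sublining, cxcl12);
    # endothelial: (cap, ven)
    "EFM": {"T": (0.70, 0.15, 0.15), "B/plasma": (0.50, 0.10, 0.40),
            "NK": (0.60, 0.40), "myeloid": (0.55, 0.35, 0.10),
            "stromal": (0.55, 0.35, 0.10), "endothelial": (0.60, 0.40)},
    "F":   {"T": (0.70, 0.15, 0.15), "B/plasma": (0.50, 0.10, 0.40),
            "NK": (0.60, 0.40), "myeloid": (0.60, 0.30, 0.10),
            "stromal": (0.60, 0.30, 0.10), "endothelial": (0.45, 0.55)},
    "TF":  {"T": (0.35, 0.15, 0.50), "B/plasma": (0.50, 0.10, 0.40),
            "NK": (0.30, 0.70), "myeloid": (0.50, 0.40, 0.10),
            "stromal": (0.35, 0.25, 0.40), "endothelial": (0.50, 0.50)},
    "TB":  {"T": (0.30, 0.55, 0.15), "B/plasma": (0.30, 0.50, 0.20),
            "NK": (0.60, 0.40), "myeloid": (0.50, 0.40, 0.10),
            "stromal": (0.50, 0.40, 0.10), "endothelial": (0.50, 0.50)},
    "TM":  {"T": (0.55, 0.25, 0.20), "B/plasma": (0.50, 0.10, 0.40),
            "NK": (0.50, 0.50), "myeloid": (0.30, 0.60, 0.10),
            "stromal": (0.50, 0.40, 0.10), "endothelial": (0.50, 0.50)},
    "M":   {"T": (0.70, 0.15, 0.15), "B/plasma": (0.50, 0.10, 0.40),
            "NK": (0.50, 0.50), "myeloid": (0.25, 0.25, 0.50),
            "stromal": (0.40, 0.30, 0.30), "endothelial": (0.70, 0.30)},
}


def default_config(
    n_samples: int = 60,
    cells_per_sample: tuple[int, int] = (400, 600),
    n_genes: int = 120,
    alpha: float = 200.0,
    seed: int = 0,
) -> SimConfig:
    """Default six-phenotype preset (names EFM/F/TF/TB/TM/M)."""
    phenotypes = tuple(
        PhenotypeSpec(name, comp, alpha, _PRESET_STATE_PROPS[name])
        for name, comp in _PRESET_COMPOSITIONS.items()
    )
    cytokine = {
        "T-ph": (100, 101), "T-gzmb": (102,), "NK-gzmb": (103,),
        "M-il1b": (104, 105), "M-spp1": (106,), "F-cxcl12": (107,),
        "E-ven": (108,), "B-abc": (109,),
    }
    risk = {
        "T-ph": (110, 111), "T-naive": (112,), "B-abc": (113,),
        "M-spp1": (114,), "F-cxcl12": (115,), "E-cap": (116,),
        "NK-gzmk": (117,),
    }
    if n_genes < 118:
        cytokine = {k: tuple(g for g in v if g < n_genes)
                    for k, v in cytokine.items()}
        cytokine = {k: v for k, v in cytokine.items() if v}
        risk = {k: tuple(g for g in v if g < n_genes) for k, v in risk.items()}
        risk = {k: v for k, v in risk.items() if v}
    return SimConfig(
        n_samples=n_samples,
        phenotypes=phenotypes,
        states=_preset_states(n_genes),
        cells_per_sample=cells_per_sample,
        n_genes=n_genes,
        cytokine_genes=cytokine,
        risk_genes=risk,
        seed=seed,
    )
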