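"""Phenotype-level association statistics.

Variance explained by the abundance phenotype over clinical covariates,
cross-lineage proportion correlations, expression-matched permutation tests
for risk-gene / neighbourhood-score correlation, treatment-response odds
ratios, and a permutation test for repeat-biopsy composition stability.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .core import CompositionMatrix


@dataclass
class VarianceResult:
    fraction: float                   # incremental R^2 of the phenotype term
    p_value: float                    # nested F-test p (nan when degenerate)
    degenerate: bool
    n_used: int
    n_dropped: int


@dataclass
class RiskGeneResult:
    gene: str
    r: float
    p_value: float
    tier: str                         # "p<0.01", "0.01<=p<0.05" or "ns"
    expression_bin: int
    bin_mean_expression: float
    n_null: int


@dataclass
class EnrichmentResult:
    observed_count: int
    null_median: float
    p_value: float
    null_counts: np.ndarray
    n_perm: int


@dataclass
class ResponseResult:
    table: pd.DataFrame               # per-phenotype OR, CI and Wald p
    overall_p: float                  # likelihood-ratio test of the term
    reference: str
    quasi_separation: bool
    n_used: int
    n_dropped: int


@dataclass
class StabilityResult:
    observed_mean_distance: float
    p_value: float
    n_perm: int
    n_pairs: int


def _design(frame: pd.DataFrame | None, n: int) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix (no intercept) from a possibly mixed frame."""
    if frame is None or frame.shape[1] == 0:
        return np.empty((n, 0)), []
    enc = pd.get_dummies(frame, drop_first=True, dtype=float)
    return enc.to_numpy(dtype=float), [str(c) for c in enc.columns]


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns linearly dependent on the preceding ones."""
    aliased, kept = [], np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.hstack([kept, X[:, [j]]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            kept = cand
        else:
            aliased.append(name)
    return aliased


def variance_explained(outcome: pd.Series | np.ndarray,
                       ctap_labels: pd.Series | np.ndarray,
                       covariates: pd.DataFrame | None = None,
                       ) -> VarianceResult:
    """Incremental R^2 of the phenotype factor over a covariate-only model.

    Fits ``outcome ~ covariates`` and ``outcome ~ covariates + phenotype``
    by least squares; the fraction is the R^2 increase and the p-value comes
    from the nested F-test. Missing values are handled by complete-case
    analysis with the dropped count reported.
    """
    y = pd.Series(np.asarray(outcome, dtype=float))
    labs = pd.Series(np.asarray(ctap_labels)).astype(str)
    if len(y) != len(labs):
        raise ValueError("outcome and ctap_labels must have equal length")
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        if len(cov) != len(y):
            raise ValueError("covariates must match outcome length")
    ok = y.notna().to_numpy()
    if cov is not None:
        ok &= cov.notna().all(axis=1).to_numpy()
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} samples with missing values")
    y = y[ok].to_numpy()
    labs = labs[ok.nonzero()[0]] if isinstance(labs.index, pd.RangeIndex) \
        else labs[ok]
    labs = pd.Series(np.asarray(labs))
    cov = cov.loc[ok] if cov is not None else None
    n = y.size

    sizes = labs.value_counts()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need at least 2 phenotypes with >= 2 samples each")

    Xc, cov_names = _design(cov, n)
    ctap_dum = pd.get_dummies(labs, drop_first=True, dtype=float)
    names = (["intercept"] + cov_names
             + [f"ctap[{c}]" for c in ctap_dum.columns])
    X0 = np.hstack([np.ones((n, 1)), Xc])
    X1 = np.hstack([X0, ctap_dum.to_numpy()])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError(f"rank-deficient design; aliased terms: "
                         f"{_aliased_columns(X1, names)}")

    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("outcome has no variance")

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum())

    rss0, rss1 = rss(X0), rss(X1)
    fraction = (rss0 - rss1) / tss
    df_extra = X1.shape[1] - X0.shape[1]
    df_resid = n - X1.shape[1]
    degenerate = rss1 <= 1e-10 * tss or df_resid < 1
    if degenerate:
        warnings.warn("saturated or zero-residual fit; nested F degenerate")
        p = float("nan")
    else:
        f = ((rss0 - rss1) / df_extra) / (rss1 / df_resid)
        p = float(stats.f.sf(f, df_extra, df_resid))
    return VarianceResult(float(fraction), p, degenerate, n, n_dropped)


def proportion_correlation(prop_a: np.ndarray,
                           prop_b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-test p on n-2 df."""
    a = np.asarray(prop_a, dtype=float)
    b = np.asarray(prop_b, dtype=float)
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def filter_low_count_genes(counts: sparse.spmatrix,
                           cell_mask: np.ndarray,
                           min_frac: float = 0.05) -> np.ndarray:
    """Keep genes detected above 1 UMI in at least ``min_frac`` of the cells.

    A gene is analyzable in a cell type iff the fraction of that type's
    cells with a count of more than one UMI is at least ``min_frac``
    (boundary included). Returns a boolean array over genes.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.sum() == 0:
        raise ValueError("empty cell mask")
    sub = sparse.csr_matrix(counts)[:, cell_mask]
    n_cells = sub.shape[1]
    detected = np.asarray((sub > 1).sum(axis=1)).ravel()
    return detected / n_cells >= min_frac


def _tier(p: float) -> str:
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "0.01<=p<0.05"
    return "ns"


def gene_score_correlation(gene: str,
                           expression: pd.DataFrame,
                           ncorr: np.ndarray,
                           expression_bins: int = 10,
                           n_perm: int = 200,
                           seed: int = 0) -> RiskGeneResult:
    """Expression-matched permutation test for positive gene/score correlation.

    ``expression`` is a normalized genes x cells matrix containing the test
    gene. The observed statistic is the Pearson correlation of the gene's
    per-cell expression with the per-cell neighbourhood correlation. The
    null draws ``n_perm`` other genes from the same mean-expression bin
    (equal-occupancy bins; widened if too small) and the one-sided p counts
    null correlations at least as positive.
    """
    if gene not in expression.index:
        raise ValueError(f"gene {gene!r} not present in the expression matrix")
    ncorr = np.asarray(ncorr, dtype=float)
    if ncorr.size != expression.shape[1]:
        raise ValueError("ncorr length must match the number of cells")
    x = expression.loc[gene].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"gene {gene!r} has zero expression variance")
    if np.ptp(ncorr) == 0:
        raise ValueError("neighbourhood scores have zero variance")
    r_obs = float(stats.pearsonr(x, ncorr).statistic)

    means = expression.mean(axis=1)
    ranks = means.rank(method="first")
    bins = np.ceil(ranks / (len(means) / expression_bins)).astype(int)
    bins = bins.clip(1, expression_bins)
    my_bin = int(bins.loc[gene])
    width = 0
    while True:
        in_bin = bins.index[(bins >= my_bin - width)
                            & (bins <= my_bin + width)]
        candidates = [g for g in in_bin if g != gene
                      and np.ptp(expression.loc[g].to_numpy()) > 0]
        if len(candidates) >= n_perm or width >= expression_bins:
            break
        width += 1
        warnings.warn(f"expression bin widened to +/-{width} for {gene!r}")

    rng = np.random.default_rng(seed)
    replace = len(candidates) < n_perm
    chosen = rng.choice(len(candidates), size=n_perm, replace=replace)
    E = expression.loc[[candidates[j] for j in chosen]].to_numpy(dtype=float)
    Ec = E - E.mean(axis=1, keepdims=True)
    yc = ncorr - ncorr.mean()
    denom = np.linalg.norm(Ec, axis=1) * np.linalg.norm(yc)
    r_null = (Ec @ yc) / denom
    p = float((1 + np.sum(r_null >= r_obs)) / (n_perm + 1))
    return RiskGeneResult(
        gene=gene, r=r_obs, p_value=p, tier=_tier(p), expression_bin=my_bin,
        bin_mean_expression=float(means.loc[in_bin].mean()), n_null=n_perm,
    )


def risk_gene_enrichment_count(run_grid: Callable[[np.ndarray], np.ndarray],
                               labels: np.ndarray,
                               n_perm: int = 100,
                               seed: int = 0,
                               alpha: float = 0.05) -> EnrichmentResult:
    """Count significant tests on a gene x type x phenotype grid vs null.

    ``run_grid(labels)`` must return the grid of one-sided p-values given a
    per-sample phenotype labelling. The null re-runs the same pipeline with
    labels permuted; the permutation p is the fraction of null counts at
    least as large as the observed one.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse p resolution")
    labels = np.asarray(labels)
    obs_p = np.asarray(run_grid(labels), dtype=float).ravel()
    if obs_p.size == 0:
        raise ValueError("empty results grid")
    observed = int((obs_p < alpha).sum())
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(labels)
        null_counts[b] = int(
            (np.asarray(run_grid(perm), dtype=float).ravel() < alpha).sum())
    p = float((1 + np.sum(null_counts >= observed)) / (n_perm + 1))
    return EnrichmentResult(observed, float(np.median(null_counts)), p,
                            null_counts, n_perm)


def response_association(ctap_labels: pd.Series | np.ndarray,
                         responder: pd.Series | np.ndarray,
                         covariates: pd.DataFrame | None = None,
                         reference: str | None = None) -> ResponseResult:
    """Logistic model of treatment response on phenotype plus covariates.

    Phenotypes are reference-coded; the overall p is the likelihood-ratio
    test of the phenotype term against the covariate-only model and per-
    phenotype odds ratios carry Wald confidence intervals. Quasi-separation
    triggers an L2-penalized fallback for the estimates (flagged).
    """
    import statsmodels.api as sm

    labs = pd.Series(np.asarray(ctap_labels)).astype(str)
    y = pd.Series(np.asarray(responder, dtype=float))
    if len(labs) != len(y):
        raise ValueError("ctap_labels and responder must have equal length")
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        if len(cov) != len(y):
            raise ValueError("covariates must match responder length")
    ok = y.notna().to_numpy()
    if cov is not None:
        ok &= cov.notna().all(axis=1).to_numpy()
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} samples with missing values")
    labs, y = labs[ok].reset_index(drop=True), y[ok].reset_index(drop=True)
    cov = cov.loc[ok].reset_index(drop=True) if cov is not None else None
    n = len(y)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("responder must be binary (0/1)")

    levels = sorted(labs.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 phenotypes")
    ref = reference if reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference {ref!r} not among labels")
    others = [lv for lv in levels if lv != ref]
    D = np.column_stack([(labs == lv).to_numpy(float) for lv in others])
    Xc, _ = _design(cov, n)
    X0 = np.hstack([np.ones((n, 1)), Xc])
    X1 = np.hstack([X0, D])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("rank-deficient design for the logistic model")

    quasi = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit1 = sm.Logit(y, X1).fit(disp=0, maxiter=200)
            fit0 = sm.Logit(y, X0).fit(disp=0, maxiter=200)
        if (not fit1.mle_retvals.get("converged", True)
                or np.max(np.abs(fit1.params)) > 15):
            quasi = True
    except Exception:
        quasi = True
        fit1 = fit0 = None

    if fit1 is not None and fit0 is not None:
        lr = 2 * (fit1.llf - fit0.llf)
        overall_p = float(stats.chi2.sf(max(lr, 0.0), len(others)))
    else:
        overall_p = float("nan")

    if quasi:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit1 = sm.GLM(
                y, X1, family=sm.families.Binomial()
            ).fit_regularized(alpha=1.0 / n, L1_wt=0.0)
        params = np.asarray(fit1.params)
        se = np.full_like(params, np.nan)
        pvals = np.full_like(params, np.nan)
    else:
        params = np.asarray(fit1.params)
        se = np.asarray(fit1.bse)
        pvals = np.asarray(fit1.pvalues)

    off = X0.shape[1]
    rows = []
    for j, lv in enumerate(others):
        b = params[off + j]
        s = se[off + j]
        rows.append({
            "ctap": lv,
            "odds_ratio": float(np.exp(b)),
            "ci_low": float(np.exp(b - 1.96 * s)),
            "ci_high": float(np.exp(b + 1.96 * s)),
            "p_value": float(pvals[off + j]),
        })
    table = pd.DataFrame(rows).set_index("ctap")
    return ResponseResult(table, overall_p, ref, quasi, n, n_dropped)


def paired_stability_test(comp_t0: CompositionMatrix | np.ndarray,
                          comp_t1: CompositionMatrix | np.ndarray,
                          n_perm: int = 999,
                          seed: int = 0) -> StabilityResult:
    """Permutation test for composition similarity of repeat biopsies.

    The statistic is the mean Euclidean distance between paired composition
    rows; the null re-pairs rows at random, and the p-value is the fraction
    of null means at most as small as the observed one.
    """
    A = comp_t0.proportions if isinstance(comp_t0, CompositionMatrix) \
        else np.asarray(comp_t0, dtype=float)
    B = comp_t1.proportions if isinstance(comp_t1, CompositionMatrix) \
        else np.asarray(comp_t1, dtype=float)
    if A.shape != B.shape:
        raise ValueError("paired composition matrices must share shape")
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    observed = float(np.linalg.norm(A - B, axis=1).mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = np.linalg.norm(A - B[perm], axis=1).mean()
    p = float((1 + np.sum(null <= observed + 1e-15)) / (n_perm + 1))
    return StabilityResult(observed, p, n_perm, n)
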