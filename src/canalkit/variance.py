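"""Variance-dynamics ("canalization") statistics.

Quantifies how inter-individual variation in gene expression changes
across differentiation days, per species: global shift tests on the
distribution of log2 per-gene variances, gene-wise one-sided F tests
between two days, Storey-style estimation of the fraction of genes with a
true variance change (pi1 = 1 - pi0), the conditional-sharing estimator
(pi1 of one species restricted to genes significant in the other), a
permutation null for that estimator, and a purity-adjusted variant of the
variance computation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, validate_design
from .de import ContrastResult

DEFAULT_LAMBDA = np.round(np.arange(0.05, 0.96, 0.05), 2)


# ---------------------------------------------------------------------------
# variance tables


def variance_table(expr_combined: ExpressionMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene unbiased sample variance across individuals, by species/day.

    Returns a frame with MultiIndex columns ``(statistic, species, day)``
    where statistic is ``var``, ``log2_var`` (NaN where the variance is 0)
    or ``n``. Cells with fewer than two individuals are NaN.
    """
    design = validate_design(design)
    if design["tech_rep"].max() > 1:
        raise ValueError("combine technical replicates before variance analysis")
    out = {}
    for (sp, day), grp in design.groupby(["species", "day"]):
        cols = [c for c in grp["sample_id"] if c in expr_combined.values.columns]
        n = len(cols)
        if n < 2:
            v = pd.Series(np.nan, index=expr_combined.gene_ids)
        else:
            v = expr_combined.values[cols].var(axis=1, ddof=1)
        out[("var", sp, day)] = v
        with np.errstate(divide="ignore"):
            out[("log2_var", sp, day)] = np.where(v > 0, np.log2(v), np.nan)
        out[("n", sp, day)] = n
    return pd.DataFrame(out, index=expr_combined.gene_ids)


def global_variance_shift_test(
    vt: pd.DataFrame, species: str, day_a: int, day_b: int, paired: bool = False
) -> tuple[float, float]:
    """One-sided test that mean log2 variance is greater at ``day_a``.

    Welch two-sample by default; ``paired`` switches to a per-gene paired t.
    """
    a = vt[("log2_var", species, day_a)].to_numpy(float)
    b = vt[("log2_var", species, day_b)].to_numpy(float)
    if paired:
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2:
            raise ValueError("fewer than two genes with finite variances")
        res = stats.ttest_rel(a[ok], b[ok], alternative="greater")
    else:
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if min(len(a), len(b)) < 2:
            raise ValueError("fewer than two genes with finite variances")
        res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def divergence_shift_test(
    res_a: ContrastResult, res_b: ContrastResult, fdr: float = 0.05
) -> tuple[float, float]:
    """One-sided Mann-Whitney U: are |log2 FC| of DE genes larger in A?"""
    if not res_a.table.index.equals(res_b.table.index):
        raise ValueError("results must share the same gene universe")
    mag_a = res_a.table.loc[res_a.table["q"] < fdr, "logFC"].abs().to_numpy()
    mag_b = res_b.table.loc[res_b.table["q"] < fdr, "logFC"].abs().to_numpy()
    if len(mag_a) == 0 or len(mag_b) == 0:
        raise ValueError("empty DE set at the stated FDR")
    res = stats.mannwhitneyu(mag_a, mag_b, alternative="greater")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# gene-wise F tests


def variance_f_tests(
    expr_combined: ExpressionMatrix,
    design: pd.DataFrame,
    species: str,
    day_a: int,
    day_b: int,
    alternative: str = "reduction",
) -> pd.DataFrame:
    """One-sided F tests of equal variances at two days, per gene.

    F = var(day_a)/var(day_b) on (n_a-1, n_b-1) df. ``reduction`` puts the
    alternative "variance smaller at day_b" in the upper tail of F;
    ``increase`` uses the lower tail. Zero denominator variance yields
    p = 0 under ``reduction`` with ``degenerate`` flagged.
    """
    if alternative not in ("reduction", "increase"):
        raise ValueError("alternative must be 'reduction' or 'increase'")
    design = validate_design(design)
    sub = design[design["species"] == species]
    cols_a = list(sub.loc[sub["day"] == day_a, "sample_id"])
    cols_b = list(sub.loc[sub["day"] == day_b, "sample_id"])
    if min(len(cols_a), len(cols_b)) < 2:
        raise ValueError("need at least two individuals at each day")
    va = expr_combined.values[cols_a].var(axis=1, ddof=1).to_numpy()
    vb = expr_combined.values[cols_b].var(axis=1, ddof=1).to_numpy()
    dfn, dfd = len(cols_a) - 1, len(cols_b) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        F = va / vb
    degenerate = vb == 0
    F = np.where(degenerate, np.inf, F)
    if alternative == "reduction":
        p = np.where(degenerate, 0.0, stats.f.sf(F, dfn, dfd))
    else:
        p = np.where(degenerate, 1.0, stats.f.cdf(F, dfn, dfd))
    return pd.DataFrame(
        {"F": F, "p": p, "degenerate": degenerate},
        index=expr_combined.gene_ids,
    )


# ---------------------------------------------------------------------------
# pi0 estimation


def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (intercept + df columns) at points x."""
    kmax = knots[-1]

    def d(k):
        num = np.clip(x - k, 0, None) ** 3 - np.clip(x - kmax, 0, None) ** 3
        return num / (kmax - k)

    cols = [np.ones_like(x), x]
    dKm1 = d(knots[-2])
    for k in knots[:-2]:
        cols.append(d(k) - dKm1)
    return np.column_stack(cols)


def _pi0_smoother(pi0_grid: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Natural-cubic-spline (3 df) smooth of pi0(lambda), evaluated at the
    largest lambda. ``pi0_grid`` may be (n_lam,) or (B, n_lam)."""
    knots = np.quantile(lam, [0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
    X = _natural_spline_basis(lam, knots)
    x_eval = _natural_spline_basis(np.array([lam[-1]]), knots)
    grid = np.atleast_2d(pi0_grid)
    beta, *_ = np.linalg.lstsq(X, grid.T, rcond=None)
    out = (x_eval @ beta).ravel()
    return out if np.ndim(pi0_grid) > 1 else float(out[0])


def estimate_pi0(
    pvalues,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA,
    method: str = "smoother",
    n_boot: int = 100,
    seed: int = 0,
) -> float:
    """Storey's estimate of the proportion of null hypotheses.

    ``smoother``: pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the
    grid, smoothed by a natural cubic spline (3 df) and read off at the
    largest lambda. ``bootstrap``: choose the lambda minimizing the
    bootstrap mean-squared error. The result is clipped to [0, 1].
    """
    p = np.asarray(pvalues, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    lam = np.asarray(lambda_grid, float)
    m = p.size
    pi0_grid = np.array([(p > l).mean() / (1.0 - l) for l in lam])
    if method == "smoother":
        pi0 = float(_pi0_smoother(pi0_grid, lam))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        target = pi0_grid.min()
        mse = np.zeros(lam.size)
        for _ in range(n_boot):
            pb = rng.choice(p, size=m, replace=True)
            grid_b = np.array([(pb > l).mean() / (1.0 - l) for l in lam])
            mse += (grid_b - target) ** 2
        pi0 = float(pi0_grid[np.argmin(mse)])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(np.clip(pi0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# conditional sharing and its permutation null


@dataclass
class SharingEstimate:
    """Conditional cross-species sharing of a variance change."""

    transition: tuple
    direction: str
    cutoff: float
    n_conditioned: int
    pi1_unconditional: float
    pi1_conditional: float
    null_draws: np.ndarray | None = None
    null_mean: float = float("nan")
    empirical_p: float = float("nan")
    n_permutations: int = 0
    seed: int | None = None
    lambda_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA.copy())


def conditional_pi1(
    p_species1,
    p_species2,
    cutoff: float = 0.05,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA,
    method: str = "smoother",
    transition: tuple = (),
    direction: str = "reduction",
) -> SharingEstimate:
    """pi1 of species 2 restricted to genes significant in species 1.

    ``cutoff = 1`` reduces to the unconditional estimate.
    """
    p1 = np.asarray(p_species1, float)
    p2 = np.asarray(p_species2, float)
    if p1.shape != p2.shape:
        raise ValueError("p-value vectors must be aligned over the same genes")
    sel = p1 < cutoff if cutoff < 1.0 else np.ones_like(p1, bool)
    if sel.sum() < 50:
        warnings.warn(f"conditioning subset has only {int(sel.sum())} genes")
    if sel.sum() == 0:
        raise ValueError("conditioning subset is empty")
    pi1_c = 1.0 - estimate_pi0(p2[sel], lambda_grid, method=method)
    pi1_u = 1.0 - estimate_pi0(p2, lambda_grid, method=method)
    return SharingEstimate(
        transition=tuple(transition),
        direction=direction,
        cutoff=cutoff,
        n_conditioned=int(sel.sum()),
        pi1_unconditional=pi1_u,
        pi1_conditional=pi1_c,
        lambda_grid=np.asarray(lambda_grid, float),
    )


def top_n_conditional_pi1(
    p_species1, p_species2, n_values, lambda_grid: np.ndarray = DEFAULT_LAMBDA
) -> pd.DataFrame:
    """Robustness scan: condition on the N smallest species-1 p-values."""
    p1 = np.asarray(p_species1, float)
    p2 = np.asarray(p_species2, float)
    order = np.argsort(p1, kind="stable")
    rows = []
    for n in n_values:
        n = int(min(n, p1.size))
        pi1 = 1.0 - estimate_pi0(p2[order[:n]], lambda_grid)
        rows.append({"n": n, "pi1_conditional": pi1})
    return pd.DataFrame(rows)


def permutation_null_pi1(
    p_species1,
    p_species2,
    cutoff: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA,
    chunk: int = 1000,
) -> SharingEstimate:
    """Permutation null for the conditional-sharing estimator.

    Each draw permutes species-1 p-values across genes (equivalently,
    conditions species-2 p-values on a random subset of the same size) and
    recomputes the conditional pi1. The null value is the mean draw and the
    one-sided empirical p uses the add-one rule.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations; empirical p is coarse")
    obs = conditional_pi1(p_species1, p_species2, cutoff, lambda_grid)
    p2 = np.asarray(p_species2, float)
    g = p2.size
    n_cut = obs.n_conditioned
    lam = np.asarray(lambda_grid, float)
    knots = np.quantile(lam, [0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
    X = _natural_spline_basis(lam, knots)
    x_eval = _natural_spline_basis(np.array([lam[-1]]), knots)
    proj = x_eval @ np.linalg.pinv(X)  # 1 x n_lam: spline-smooth + evaluate

    rng = np.random.default_rng(seed)
    draws = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, g))
        idx = np.argpartition(keys, n_cut - 1, axis=1)[:, :n_cut]
        sub = p2[idx]  # b x n_cut
        grid = np.empty((b, lam.size))
        for j, l in enumerate(lam):
            grid[:, j] = (sub > l).mean(axis=1) / (1.0 - l)
        pi0_draws = np.clip((proj @ grid.T).ravel(), 0.0, 1.0)
        draws[done : done + b] = 1.0 - pi0_draws
        done += b
    emp_p = (1.0 + np.sum(draws >= obs.pi1_conditional)) / (n_perm + 1.0)
    return SharingEstimate(
        transition=obs.transition,
        direction=obs.direction,
        cutoff=cutoff,
        n_conditioned=n_cut,
        pi1_unconditional=obs.pi1_unconditional,
        pi1_conditional=obs.pi1_conditional,
        null_draws=draws,
        null_mean=float(draws.mean()),
        empirical_p=float(emp_p),
        n_permutations=n_perm,
        seed=seed,
        lambda_grid=lam,
    )


def two_cutoff_variance_overlap(
    p_species1, p_species2, strict: float = 0.05, loose: float = 0.10, index=None
) -> pd.Index:
    """Genes with a variance change called in both species under the
    asymmetric two-cutoff rule (for gene-list export)."""
    p1 = np.asarray(p_species1, float)
    p2 = np.asarray(p_species2, float)
    hit = ((p1 < strict) & (p2 < loose)) | ((p2 < strict) & (p1 < loose))
    idx = pd.Index(range(len(p1))) if index is None else pd.Index(index)
    return idx[hit]


# ---------------------------------------------------------------------------
# purity adjustment


def purity_adjusted_variance(
    expr_combined: ExpressionMatrix, design: pd.DataFrame, purity: pd.Series
) -> pd.DataFrame:
    """Purity-regressed, median-anchored log2 variances.

    Samples with a purity value contribute residual variances from a
    per-gene, per-species regression of expression on purity; samples
    without contribute plain variances. Each track's log2 variances are
    shifted so its per-species day-0 median equals 1, then the tracks are
    averaged per gene/species/day.
    """
    design = validate_design(design)
    purity = pd.Series(purity)
    have = design["sample_id"].isin(purity.dropna().index)
    tracks = []
    for with_purity, track_design in ((True, design[have]), (False, design[~have])):
        if track_design.empty:
            continue
        vals = expr_combined.values[list(track_design["sample_id"])].copy()
        if with_purity:
            # regress expression on purity within species, keep residuals
            for sp in track_design["species"].unique():
                cols = list(track_design.loc[track_design["species"] == sp, "sample_id"])
                x = purity[cols].to_numpy(float)
                y = vals[cols].to_numpy(float)
                if np.ptp(x) == 0:
                    warnings.warn(f"constant purity in {sp}; residuals are centered values")
                    vals[cols] = y - y.mean(axis=1, keepdims=True)
                    continue
                xc = x - x.mean()
                slope = (y * xc).sum(axis=1) / (xc ** 2).sum()
                fitted = y.mean(axis=1, keepdims=True) + np.outer(slope, xc)
                vals[cols] = y - fitted
        sub_expr = ExpressionMatrix(vals, unit="residual")
        vt = variance_table(sub_expr, track_design.reset_index(drop=True))
        log2v = vt["log2_var"]
        day0 = sorted(track_design["day"].unique())[0]
        shifted = {}
        for sp in track_design["species"].unique():
            med = np.nanmedian(log2v[(sp, day0)])
            for day in track_design.loc[track_design["species"] == sp, "day"].unique():
                shifted[(sp, day)] = log2v[(sp, day)] - med + 1.0
        tracks.append(pd.DataFrame(shifted, index=expr_combined.gene_ids))
    if not tracks:
        raise ValueError("no samples available")
    combined = tracks[0] if len(tracks) == 1 else (tracks[0] + tracks[1]) / 2.0
    combined.columns = pd.MultiIndex.from_tuples(combined.columns, names=["species", "day"])
    return combined
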