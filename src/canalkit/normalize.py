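"""Filtering, scaling and loess normalization of count matrices.

The pipeline follows the standard bulk RNA-seq recipe: low-expression
filtering on log2 counts-per-million, trimmed-mean-of-M-values (TMM)
scaling factors, log-CPM with a depth-adjusted prior count, optional
cyclic loess to straighten residual intensity-dependent trends between
samples, per-observation precision weights from the empirical
mean-variance trend, and combination of technical replicates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import CountMatrix, ExpressionMatrix, validate_design


# ---------------------------------------------------------------------------
# log-CPM / log-RPKM


def _effective_lib(counts: pd.DataFrame, factors: pd.Series | None) -> np.ndarray:
    lib = counts.sum(axis=0).to_numpy(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    if factors is not None:
        f = pd.Series(factors).reindex(counts.columns).to_numpy(float)
        if (f <= 0).any() or np.isnan(f).any():
            raise ValueError("scaling factors must be positive for all samples")
        lib = lib * f
    return lib


def log2_cpm(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> ExpressionMatrix:
    """log2 counts per million with a depth-adjusted prior count.

    The prior for sample *k* is ``prior_count * L_k / 1e6`` (i.e.
    ``prior_count`` on the CPM scale), and the effective library grows by
    twice that, so log-CPM is exactly invariant to rescaling a sample's
    counts and depth together:

        value = log2((x + p*L/1e6) / (L + 2*p*L/1e6) * 1e6)
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    lib = _effective_lib(counts.counts, factors)
    prior = prior_count * lib / 1e6
    vals = np.log2((counts.counts.to_numpy(float) + prior[None, :])
                   / (lib + 2 * prior)[None, :] * 1e6)
    state = {"tmm": factors is not None}
    return ExpressionMatrix(pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
                            unit="log2cpm", norm_state=state)


def log2_rpkm(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> ExpressionMatrix:
    """log2 reads per kilobase per million: log-CPM minus log2(length/1000)."""
    if counts.gene_length_bp is None:
        raise ValueError("gene lengths required for RPKM")
    cpm = log2_cpm(counts, factors, prior_count)
    vals = cpm.values.sub(np.log2(counts.gene_length_bp / 1000.0), axis=0)
    return ExpressionMatrix(vals, unit="log2rpkm", norm_state=dict(cpm.norm_state))


# ---------------------------------------------------------------------------
# filtering


def filter_low_expression(
    expr: ExpressionMatrix,
    design: pd.DataFrame,
    threshold: float = 1.5,
    min_per_species: dict | None = None,
) -> pd.Index:
    """Genes detected above ``threshold`` in enough samples of *every* species.

    A gene is kept iff, for each species, strictly more than ``threshold``
    log2-CPM is reached in at least ``min_per_species[species]`` samples.
    """
    design = validate_design(design)
    if min_per_species is None:
        min_per_species = {sp: 16 for sp in design["species"].unique()}
    keep = np.ones(len(expr.gene_ids), bool)
    for sp, need in min_per_species.items():
        cols = design.loc[design["species"] == sp, "sample_id"]
        cols = [c for c in cols if c in expr.values.columns]
        if need > len(cols):
            raise ValueError(f"min_per_species[{sp!r}]={need} exceeds {len(cols)} samples")
        n_above = (expr.values[cols].to_numpy() > threshold).sum(axis=1)
        keep &= n_above >= need
    return expr.gene_ids[keep]


# ---------------------------------------------------------------------------
# TMM


@dataclass
class TMMDiagnostics:
    ref_sample: str
    factors: pd.Series
    trimmed_gene_count: pd.Series
    M: pd.DataFrame  # per-gene log ratio vs reference (NaN where undefined)
    A: pd.DataFrame
    weights: pd.DataFrame


def tmm_factors(
    counts: CountMatrix, trim_M: float = 0.30, trim_A: float = 0.05
) -> TMMDiagnostics:
    """Weighted trimmed-mean-of-M-values scaling factors.

    Reference: the sample whose upper-quartile count fraction is closest to
    the mean upper quartile (ties broken by column order). Per sample, gene
    log-ratios M and abundances A versus the reference are doubly trimmed
    (``trim_M`` on each M tail, ``trim_A`` on each A tail) and combined with
    inverse asymptotic-variance weights; factors are rescaled to have zero
    mean log.
    """
    x = counts.counts.to_numpy(float)
    if x.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = x.sum(axis=0)
    if (x.max(axis=0) <= 0).any():
        raise ValueError("each sample needs at least one positive count")
    q75 = np.quantile(x / lib[None, :], 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    nz_ref = x[:, ref] > 0
    n_samples = x.shape[1]
    logf = np.zeros(n_samples)
    trimmed_n = np.zeros(n_samples, int)
    M_all = np.full_like(x, np.nan)
    A_all = np.full_like(x, np.nan)
    W_all = np.full_like(x, np.nan)
    for k in range(n_samples):
        if k == ref:
            continue
        use = (x[:, k] > 0) & nz_ref
        if not use.any():
            raise ValueError("no genes positive in both sample and reference")
        xk, xr = x[use, k], x[use, ref]
        m = np.log2((xk / lib[k]) / (xr / lib[ref]))
        a = 0.5 * np.log2((xk / lib[k]) * (xr / lib[ref]))
        w = (lib[k] - xk) / (lib[k] * xk) + (lib[ref] - xr) / (lib[ref] * xr)
        M_all[use, k], A_all[use, k], W_all[use, k] = m, a, 1.0 / w
        n = len(m)
        lo_m = int(np.floor(n * trim_M)) + 1
        hi_m = n - lo_m + 1
        lo_a = int(np.floor(n * trim_A)) + 1
        hi_a = n - lo_a + 1
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        trimmed_n[k] = int(keep.sum())
        if keep.sum() == 0:
            logf[k] = 0.0
        else:
            logf[k] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        if not np.isfinite(logf[k]):
            logf[k] = 0.0
    logf = logf - logf.mean()
    cols = counts.sample_ids
    gi = counts.gene_ids
    return TMMDiagnostics(
        ref_sample=str(cols[ref]),
        factors=pd.Series(2.0 ** logf, index=cols, name="tmm_factor"),
        trimmed_gene_count=pd.Series(trimmed_n, index=cols),
        M=pd.DataFrame(M_all, index=gi, columns=cols),
        A=pd.DataFrame(A_all, index=gi, columns=cols),
        weights=pd.DataFrame(W_all, index=gi, columns=cols),
    )


# ---------------------------------------------------------------------------
# cyclic loess


def _lowess_fit(y: np.ndarray, x: np.ndarray, span: float) -> np.ndarray:
    delta = 0.01 * (x.max() - x.min())
    return lowess(y, x, frac=span, delta=delta, return_sorted=False)


def cyclic_loess(
    expr: ExpressionMatrix, iterations: int = 3, span: float = 0.5
) -> ExpressionMatrix:
    """Pairwise M-A loess normalization cycled over all sample pairs.

    For each pair (i, j): fit a loess of M = x_i - x_j on A = (x_i + x_j)/2
    and move each sample half the fitted trend toward the other, preserving
    the pair's A values. Already-straight pairs are left unchanged.
    """
    vals = expr.values.to_numpy(float).copy()
    n = vals.shape[1]
    if n < 2:
        raise ValueError("cyclic loess requires at least two samples")
    for _ in range(iterations):
        for i in range(n):
            for j in range(i + 1, n):
                m = vals[:, i] - vals[:, j]
                a = 0.5 * (vals[:, i] + vals[:, j])
                fit = _lowess_fit(m, a, span)
                vals[:, i] -= fit / 2.0
                vals[:, j] += fit / 2.0
    out = pd.DataFrame(vals, index=expr.gene_ids, columns=expr.sample_ids)
    return expr.copy_with(out, norm_state={"cyclic_loess": True})


# ---------------------------------------------------------------------------
# voom-style precision weights


def voom_weights(
    counts: CountMatrix,
    design_matrix: np.ndarray,
    factors: pd.Series | None = None,
    span: float = 0.5,
    prior_count: float = 0.5,
) -> ExpressionMatrix:
    """Precision weights from the empirical mean-variance trend of counts.

    Per gene, an OLS fit of log-CPM on the design yields a residual SD; a
    lowess of sqrt(SD) against average log2 count gives the trend, which is
    evaluated at each observation's fitted log2 count to predict its
    sqrt-SD. Weights are predicted sqrt-SD to the -4 (inverse variance).
    """
    X = np.asarray(design_matrix, float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if n <= p:
        raise ValueError("more coefficients than samples")
    expr = log2_cpm(counts, factors, prior_count)
    y = expr.values.to_numpy()
    lib = _effective_lib(counts.counts, factors)

    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    fitted = (X @ beta).T
    resid = y - fitted
    df_resid = n - p
    s = np.sqrt((resid ** 2).sum(axis=1) / df_resid)
    sqrt_s = np.sqrt(s)
    # average log2 count: mean log-CPM mapped back to the count scale
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    order = np.argsort(sx)
    trend = _lowess_fit(sqrt_s[order], sx[order], span)
    # monotone-safe interpolation of the trend at each observation's fitted count
    xs, idx = np.unique(sx[order], return_index=True)
    ys = trend[idx]
    fitted_count = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_count, xs, ys)
    pred = np.clip(pred, 1e-4, None)
    w = pred ** -4.0
    wdf = pd.DataFrame(w, index=expr.gene_ids, columns=expr.sample_ids)
    return ExpressionMatrix(expr.values, unit="log2cpm",
                            norm_state=dict(expr.norm_state), weights=wdf)


# ---------------------------------------------------------------------------
# technical replicates and depth anomalies


def _reduced_design(design: pd.DataFrame) -> pd.DataFrame:
    agg = (
        design.sort_values(["individual", "day", "tech_rep"])
        .groupby(["individual", "day"], as_index=False)
        .agg(
            species=("species", "first"),
            batch=("batch", "first"),
            sex=("sex", "first"),
            purity=("purity", "mean"),
            lib_size=("lib_size", "sum"),
        )
    )
    agg["sample_id"] = agg["individual"] + "_d" + agg["day"].astype(str)
    agg["tech_rep"] = 1
    return validate_design(agg)


def combine_replicates(
    expr: ExpressionMatrix | None,
    design: pd.DataFrame,
    method: str = "post_average",
    counts: CountMatrix | None = None,
    **norm_kw,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Collapse technical replicates to one column per (individual, day).

    ``post_average`` takes the arithmetic mean of already-normalized values;
    ``pre_sum`` sums the raw counts and re-runs the normalization pipeline
    (requires ``counts``).
    """
    design = validate_design(design)
    red = _reduced_design(design)
    if method == "post_average":
        if expr is None:
            raise ValueError("post_average requires a normalized matrix")
        cols = {}
        for row in red.itertuples(index=False):
            members = design.loc[
                (design["individual"] == row.individual) & (design["day"] == row.day),
                "sample_id",
            ]
            cols[row.sample_id] = expr.values[list(members)].mean(axis=1)
        out = pd.DataFrame(cols, index=expr.gene_ids)[red["sample_id"]]
        return expr.copy_with(out, weights=None), red
    if method == "pre_sum":
        if counts is None:
            raise ValueError("pre_sum requires raw counts")
        summed = {}
        for row in red.itertuples(index=False):
            members = design.loc[
                (design["individual"] == row.individual) & (design["day"] == row.day),
                "sample_id",
            ]
            summed[row.sample_id] = counts.counts[list(members)].sum(axis=1)
        cm = CountMatrix(pd.DataFrame(summed)[red["sample_id"]], counts.gene_length_bp)
        expr_out, _, _ = normalize_pipeline(cm, red, filter_genes=False, **norm_kw)
        return expr_out, red
    raise ValueError(f"unknown method {method!r}")


def subsample_depth(
    counts: CountMatrix, ratio: float = 1.8, seed: int = 0
) -> tuple[CountMatrix, str | None]:
    """Binomially thin an anomalously deep library.

    If the largest library exceeds the second largest by at least ``ratio``,
    its counts are thinned to approximately the second-largest depth.
    Returns the (possibly) thinned matrix and the thinned sample id.
    """
    lib = counts.counts.sum(axis=0)
    order = lib.sort_values(ascending=False)
    if len(order) < 2 or order.iloc[0] < ratio * order.iloc[1]:
        return counts, None
    target = order.index[0]
    p = order.iloc[1] / order.iloc[0]
    rng = np.random.default_rng(seed)
    new = counts.counts.copy()
    new[target] = rng.binomial(new[target].to_numpy(), p)
    return CountMatrix(new, counts.gene_length_bp), str(target)


# ---------------------------------------------------------------------------
# pipeline


def normalize_pipeline(
    counts: CountMatrix,
    design: pd.DataFrame,
    threshold: float = 1.5,
    min_per_species: dict | None = None,
    loess: bool = True,
    span: float = 0.5,
    iterations: int = 3,
    exclude_samples: tuple = (),
    filter_genes: bool = True,
    prior_count: float = 0.5,
):
    """Filter, TMM-normalize and (optionally) cyclic-loess a count matrix.

    Returns ``(expr, kept_design, diagnostics)``. Listed ``exclude_samples``
    are dropped before any computation (outlier handling is an explicit
    configuration choice, not automated).
    """
    design = validate_design(design)
    if exclude_samples:
        missing = set(exclude_samples) - set(design["sample_id"])
        if missing:
            warnings.warn(f"exclude_samples not found: {sorted(missing)}")
        design = design[~design["sample_id"].isin(exclude_samples)].reset_index(drop=True)
        counts = CountMatrix(counts.counts[list(design["sample_id"])], counts.gene_length_bp)
    if filter_genes:
        raw = log2_cpm(counts, prior_count=prior_count)
        kept = filter_low_expression(raw, design, threshold, min_per_species)
        counts = counts.subset_genes(kept)
    diag = tmm_factors(counts)
    expr = log2_cpm(counts, diag.factors, prior_count)
    if loess:
        expr = cyclic_loess(expr, iterations=iterations, span=span)
    return expr, design, diag
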