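"""PCA-based data QC and the technical-factor confounding screen.

Stage 1 asks which recorded technical factors predict any of the leading
expression PCs; stage 2 asks whether the surviving factors are associated
with the biological variables (day, species). A separate partition test
compares a reduced model (species + day) against a full model adding the
species-by-day interaction for each factor, with the test family chosen
by the factor's type (nested ANOVA, binomial deviance, or multinomial
likelihood ratio).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import ExpressionMatrix, validate_design
from .de import bh_adjust


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x PCs
    var_explained: np.ndarray
    assoc: pd.DataFrame  # (PC, covariate) -> r, p


def pca_qc(expr: ExpressionMatrix, design: pd.DataFrame, n_pcs: int = 5) -> PCAResult:
    """Sample-space PCA of gene-centered expression plus day/species associations.

    Day enters the association regressions numerically (a trend over the
    time course); species as a binary indicator.
    """
    design = validate_design(design)
    y = expr.values[list(design["sample_id"])].to_numpy(float)
    if y.shape[1] < 2:
        raise ValueError("PCA requires at least two samples")
    yc = y - y.mean(axis=1, keepdims=True)
    if not yc.any():
        raise ValueError("constant expression matrix")
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    scores = pd.DataFrame(
        (vt[:n_pcs].T * s[:n_pcs]),
        index=design["sample_id"],
        columns=[f"PC{i + 1}" for i in range(n_pcs)],
    )
    ve = s ** 2 / (s ** 2).sum()
    rows = []
    day = design["day"].to_numpy(float)
    sp_ind = (design["species"] == "chimpanzee").to_numpy(float)
    for pc in scores.columns:
        for cov_name, cov in (("day", day), ("species", sp_ind)):
            r, p = stats.pearsonr(scores[pc].to_numpy(), cov)
            rows.append({"PC": pc, "covariate": cov_name, "r": r, "p": p})
    return PCAResult(scores=scores, var_explained=ve[:n_pcs], assoc=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# stage 1: factors vs PCs


def _is_numeric(x: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(x) and x.nunique() > 2


def _factor_pc_pvalue(pc: np.ndarray, factor: pd.Series) -> float:
    """Overall p for one (PC, factor) model: regression F for numeric
    factors, one-way ANOVA across levels otherwise."""
    if _is_numeric(factor):
        x = factor.to_numpy(float)
        return float(stats.pearsonr(pc, x).pvalue)
    groups = [pc[(factor == lv).to_numpy()] for lv in factor.unique()]
    return float(stats.f_oneway(*groups).pvalue)


def factor_screen(
    pca: PCAResult, factors: pd.DataFrame, fdr: float = 0.10
) -> pd.DataFrame:
    """BH screen of every (PC, factor) pair; survivors feed stage 2.

    Returns the full long table with q-values and a ``significant`` flag;
    constant factors are skipped with a note.
    """
    rows = []
    for fname in factors.columns:
        fac = factors[fname].reindex(pca.scores.index)
        if fac.nunique(dropna=True) < 2:
            warnings.warn(f"factor {fname!r} is constant; skipped")
            continue
        for pc in pca.scores.columns:
            p = _factor_pc_pvalue(pca.scores[pc].to_numpy(), fac)
            rows.append({"factor": fname, "PC": pc, "p": p})
    tab = pd.DataFrame(rows)
    if tab.empty:
        tab["q"] = tab["significant"] = []
        return tab
    tab["q"] = bh_adjust(tab["p"].to_numpy())
    tab["significant"] = tab["q"] < fdr
    return tab


# ---------------------------------------------------------------------------
# stage 2: factors vs biology


def factor_design_association(
    factor: pd.Series,
    design: pd.DataFrame,
    target: str = "day",
    n_mc: int = 10000,
    seed: int = 0,
) -> float:
    """p-value for association of a technical factor with day or species.

    Numeric factors: one-way ANOVA across target levels. Categorical
    factors: chi-square independence with a Monte-Carlo p (tables resampled
    at fixed margins). BH adjustment across the stage-2 matrix is the
    caller's responsibility.
    """
    design = validate_design(design)
    if target not in ("day", "species"):
        raise ValueError("target must be 'day' or 'species'")
    t = design[target]
    factor = factor.reindex(design["sample_id"]).reset_index(drop=True)
    if _is_numeric(factor):
        groups = [factor[(t == lv).to_numpy()].to_numpy(float) for lv in t.unique()]
        return float(stats.f_oneway(*groups).pvalue)
    if factor.nunique() < 2:
        raise ValueError("categorical factor has a single level")
    table = pd.crosstab(factor, t).to_numpy()
    chi2_obs = stats.chi2_contingency(table, correction=False).statistic
    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    sims = dist.rvs(n_mc, random_state=rng)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_sim = np.nansum((sims - expected) ** 2 / expected, axis=(1, 2))
    return float((1.0 + np.sum(chi2_sim >= chi2_obs)) / (n_mc + 1.0))


# ---------------------------------------------------------------------------
# interaction partition test


def _partition_design(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cross = pd.crosstab(design["species"], design["day"])
    empty = [(sp, d) for sp in cross.index for d in cross.columns if cross.loc[sp, d] == 0]
    if empty:
        raise ValueError(f"interaction inestimable; empty species x day cells: {empty}")
    days = np.sort(design["day"].unique())
    chimp = (design["species"] == "chimpanzee").to_numpy(float)
    reduced = [np.ones(len(design)), chimp]
    inter = []
    for d in days[1:]:
        ind = (design["day"].to_numpy() == d).astype(float)
        reduced.append(ind)
        inter.append(chimp * ind)
    if not inter:
        raise ValueError("full model adds zero extra degrees of freedom")
    Xr = np.column_stack(reduced)
    Xf = np.column_stack(reduced + inter)
    return Xr, Xf


def interaction_partition_test(factor: pd.Series, design: pd.DataFrame) -> float:
    """p-value for the species-by-day term in explaining a technical factor.

    Numeric factor: nested-ANOVA F test. Two-level categorical: binomial
    GLM deviance difference against chi-square. More levels: multinomial
    logistic likelihood-ratio test.
    """
    design = validate_design(design)
    factor = factor.reindex(design["sample_id"]).reset_index(drop=True)
    Xr, Xf = _partition_design(design)
    df_extra = Xf.shape[1] - Xr.shape[1]
    if _is_numeric(factor):
        y = factor.to_numpy(float)
        rss_r = sm.OLS(y, Xr).fit().ssr
        fit_f = sm.OLS(y, Xf).fit()
        f_stat = ((rss_r - fit_f.ssr) / df_extra) / (fit_f.ssr / fit_f.df_resid)
        return float(stats.f.sf(f_stat, df_extra, fit_f.df_resid))
    levels = pd.unique(factor.dropna())
    if len(levels) < 2:
        raise ValueError("categorical factor has a single level")
    if len(levels) == 2:
        y = (factor == levels[1]).to_numpy(float)
        dev_r = sm.GLM(y, Xr, family=sm.families.Binomial()).fit().deviance
        dev_f = sm.GLM(y, Xf, family=sm.families.Binomial()).fit().deviance
        return float(stats.chi2.sf(dev_r - dev_f, df_extra))
    codes = pd.Categorical(factor).codes
    # bfgs: Newton is fragile on sparse multinomial cells
    llf_r = sm.MNLogit(codes, Xr).fit(disp=False, maxiter=500, method="bfgs").llf
    llf_f = sm.MNLogit(codes, Xf).fit(disp=False, maxiter=500, method="bfgs").llf
    lr = 2.0 * (llf_f - llf_r)
    return float(stats.chi2.sf(max(lr, 0.0), df_extra * (len(levels) - 1)))
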