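"""Per-gene species x day linear models with empirical-Bayes moderation.

Each gene's log expression is modelled with species, day (categorical) and
their interaction as fixed effects. Repeated samples from the same cell
line are handled through a single consensus within-individual correlation
(estimated per gene on an atanh scale, then trimmed-mean pooled), which
enters a generalized least squares fit with an equicorrelated block
covariance. Residual variances are shrunk toward a common prior by
matching the first two moments of log s^2 to a scaled F distribution, and
contrasts are tested with moderated t statistics under
Benjamini-Hochberg FDR control.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, validate_design


# ---------------------------------------------------------------------------
# design matrix


def build_design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Full-rank species + day + species:day encoding (treatment coding).

    The reference level is (human, day 0). Individuals are not fixed
    effects; they enter the fit later as a correlated block.
    """
    design = validate_design(design)
    species = design["species"].to_numpy()
    days = np.sort(design["day"].unique())
    if len(set(species)) < 2:
        raise ValueError("both species must be present")
    if len(days) < 2:
        raise ValueError("at least two days required")
    cols = {"Intercept": np.ones(len(design))}
    chimp = (species == "chimpanzee").astype(float)
    cols["species[chimpanzee]"] = chimp
    for d in days[1:]:
        cols[f"day[{d}]"] = (design["day"].to_numpy() == d).astype(float)
    for d in days[1:]:
        cols[f"species[chimpanzee]:day[{d}]"] = chimp * cols[f"day[{d}]"]
    X = np.column_stack(list(cols.values()))
    names = list(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the first aliased column by incremental rank
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                raise ValueError(f"design is confounded: coefficient {names[j]!r} inestimable")
            r = rj
    return X, names


def standard_contrasts(coef_names: list[str], days: list[int]) -> dict[str, np.ndarray]:
    """The study's pairwise contrasts over the interaction parameterization.

    species@day d   : species difference at day d
    human/chimp d-1:d : consecutive-day change within one species
    interaction@day d : species difference-of-differences relative to day 0
    """
    idx = {n: i for i, n in enumerate(coef_names)}
    p = len(coef_names)
    out: dict[str, np.ndarray] = {}
    d0 = days[0]
    for d in days:
        c = np.zeros(p)
        c[idx["species[chimpanzee]"]] = 1.0
        if d != d0:
            c[idx[f"species[chimpanzee]:day[{d}]"]] = 1.0
        out[f"species@day{d}"] = c
    for prev, d in zip(days[:-1], days[1:]):
        c = np.zeros(p)
        c[idx[f"day[{d}]"]] = 1.0
        if prev != d0:
            c[idx[f"day[{prev}]"]] = -1.0
        out[f"human:day{prev}-{d}"] = c
        c2 = c.copy()
        c2[idx[f"species[chimpanzee]:day[{d}]"]] = 1.0
        if prev != d0:
            c2[idx[f"species[chimpanzee]:day[{prev}]"]] = -1.0
        out[f"chimpanzee:day{prev}-{d}"] = c2
    for d in days[1:]:
        c = np.zeros(p)
        c[idx[f"species[chimpanzee]:day[{d}]"]] = 1.0
        out[f"interaction@day{d}"] = c
    return out


# ---------------------------------------------------------------------------
# consensus within-individual correlation


def _consensus_correlation(
    resid: np.ndarray, blocks: np.ndarray, X: np.ndarray, trim: float = 0.15
) -> float:
    """Consensus within-block correlation from OLS residuals.

    Per gene, a bias-corrected moment estimate: with M = I - H the OLS
    residual projector and C the within-block (off-diagonal) adjacency,
    E[sum_pairs e_i e_j] = sigma^2 (a + rho b) and
    E[RSS] = sigma^2 (n - p + rho c) with a, b, c computable from M and C,
    so rho solves a linear equation gene by gene. Estimates are pooled by
    a trimmed mean on the atanh scale.
    """
    n, p = X.shape
    labels, inv = np.unique(blocks, return_inverse=True)
    sizes = np.bincount(inv)
    if (sizes * (sizes - 1)).sum() == 0:
        return 0.0
    C = (inv[:, None] == inv[None, :]).astype(float)
    np.fill_diagonal(C, 0.0)
    Q, _ = np.linalg.qr(X)
    M = np.eye(n) - Q @ Q.T
    MCM = M @ C @ M
    pairmask = C > 0
    a = float(M[pairmask].sum())
    b = float(MCM[pairmask].sum())
    c = float(np.trace(MCM))

    # per-gene S = sum over within-block ordered pairs of e_i e_j
    bsum = np.zeros((resid.shape[0], len(labels)))
    bsq = np.zeros_like(bsum)
    np.add.at(bsum.T, inv, resid.T)
    np.add.at(bsq.T, inv, (resid ** 2).T)
    S = (bsum ** 2 - bsq).sum(axis=1)
    rss = (resid ** 2).sum(axis=1)
    denom = b * rss - c * S
    ok = (rss > 0) & (np.abs(denom) > 1e-12 * np.maximum(rss, 1.0))
    rho_g = np.clip(((n - p) * S[ok] - a * rss[ok]) / denom[ok], -0.99, 0.99)
    if rho_g.size == 0:
        return 0.0
    z = np.arctanh(rho_g)
    rho = float(np.tanh(stats.trim_mean(z, trim)))
    lower = -1.0 / (sizes.max() - 1) + 1e-3 if sizes.max() > 1 else -0.99
    if rho <= lower or rho >= 0.999:
        warnings.warn("consensus correlation outside admissible range; clipped")
        rho = float(np.clip(rho, lower, 0.999))
    return rho


# ---------------------------------------------------------------------------
# moderation helpers


def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Estimate prior df ``d0`` and prior variance ``s0^2`` from the spread
    of log residual variances, and return the posterior variances.

    Matches the first two moments of log s^2 to a scaled F: the excess of
    var(log s^2) over trigamma(df/2) identifies trigamma(d0/2).
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    z = np.log(np.where(ok, s2, np.nan))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = np.nanmean(e)
    evar = np.nanvar(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    if np.isfinite(d0):
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        post = np.full_like(s2, s0_2)
    return d0, s0_2, post


# ---------------------------------------------------------------------------
# moderated fit


@dataclass
class ModeratedFit:
    coefficients: pd.DataFrame  # genes x coefficients
    stdev_unscaled: pd.DataFrame
    cov_unscaled: np.ndarray  # genes x p x p
    sigma2: pd.Series  # residual variances s_g^2
    df_resid: float
    rho_block: float
    d0: float
    s0_2: float
    s2_post: pd.Series
    coef_names: list[str]

    @property
    def df_total(self) -> float:
        return self.df_resid + self.d0 if np.isfinite(self.d0) else np.inf


def fit_moderated(
    expr: ExpressionMatrix,
    design_matrix: np.ndarray,
    blocks=None,
    coef_names: list[str] | None = None,
) -> ModeratedFit:
    """GLS fit with consensus block correlation plus variance moderation.

    ``blocks`` labels the correlated groups (one label per sample, e.g. the
    cell line); ``None`` reduces to (weighted) ordinary least squares.
    Observation weights, if present on ``expr``, scale the residual
    covariance as diag(1/w).
    """
    X = np.asarray(design_matrix, float)
    y = expr.values.to_numpy(float)
    g, n = y.shape
    p = X.shape[1]
    if X.shape[0] != n:
        raise ValueError("design matrix rows must match samples")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    w = None if expr.weights is None else expr.weights.to_numpy(float)
    names = coef_names or [f"b{i}" for i in range(p)]

    # 1. consensus correlation from OLS residuals
    rho = 0.0
    if blocks is not None:
        blocks = np.asarray(blocks)
        if len(blocks) != n:
            raise ValueError("blocks must align with samples")
        beta0, *_ = np.linalg.lstsq(X, y.T, rcond=None)
        resid0 = y - (X @ beta0).T
        rho = _consensus_correlation(resid0, blocks, X)

    # 2. whitening transform for the block-equicorrelation structure
    if blocks is not None and rho != 0.0:
        _, inv = np.unique(blocks, return_inverse=True)
        R = np.where(inv[:, None] == inv[None, :], rho, 0.0)
        np.fill_diagonal(R, 1.0)
        Rinv_half = linalg.fractional_matrix_power(np.linalg.inv(R), 0.5).real
    else:
        Rinv_half = None

    df_resid = float(n - p)
    coefs = np.empty((g, p))
    cov = np.empty((g, p, p))
    s2 = np.empty(g)
    if w is None:
        Xt = X if Rinv_half is None else Rinv_half @ X
        yt = y if Rinv_half is None else (Rinv_half @ y.T).T
        XtX_inv = np.linalg.inv(Xt.T @ Xt)
        B = XtX_inv @ Xt.T
        coefs = (B @ yt.T).T
        resid = yt - (Xt @ coefs.T).T
        s2 = (resid ** 2).sum(axis=1) / df_resid
        cov[:] = XtX_inv[None, :, :]
    else:
        sw = np.sqrt(w)
        for i in range(g):
            Xi = X * sw[i][:, None]
            yi = y[i] * sw[i]
            if Rinv_half is not None:
                Xi = Rinv_half @ Xi
                yi = Rinv_half @ yi
            q, r = np.linalg.qr(Xi)
            coefs[i] = linalg.solve_triangular(r, q.T @ yi)
            ri = yi - Xi @ coefs[i]
            s2[i] = ri @ ri / df_resid
            rinv = linalg.solve_triangular(r, np.eye(p))
            cov[i] = rinv @ rinv.T

    d0, s0_2, post = squeeze_var(s2, df_resid)
    gi = expr.gene_ids
    return ModeratedFit(
        coefficients=pd.DataFrame(coefs, index=gi, columns=names),
        stdev_unscaled=pd.DataFrame(
            np.sqrt(np.stack([np.diag(c) for c in cov])), index=gi, columns=names
        ),
        cov_unscaled=cov,
        sigma2=pd.Series(s2, index=gi),
        df_resid=df_resid,
        rho_block=rho,
        d0=d0,
        s0_2=s0_2,
        s2_post=pd.Series(post, index=gi),
        coef_names=names,
    )


# ---------------------------------------------------------------------------
# contrasts


@dataclass
class ContrastResult:
    name: str
    contrast: np.ndarray
    table: pd.DataFrame  # logFC, t, p, q, de
    fdr: float
    df_total: float


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def contrast_tests(
    fit: ModeratedFit, contrasts: dict[str, np.ndarray], fdr: float = 0.05
) -> dict[str, ContrastResult]:
    """Moderated t tests for each contrast with BH FDR control."""
    out = {}
    p_coef = len(fit.coef_names)
    s_tilde = np.sqrt(fit.s2_post.to_numpy())
    df_t = fit.df_total
    for name, c in contrasts.items():
        c = np.asarray(c, float)
        if c.shape != (p_coef,):
            raise ValueError(f"contrast {name!r} does not conform to coefficient space")
        if not c.any():
            raise ValueError(f"contrast {name!r} is identically zero")
        eff = fit.coefficients.to_numpy() @ c
        var_u = np.einsum("i,gij,j->g", c, fit.cov_unscaled, c)
        se = np.sqrt(var_u) * s_tilde
        t = eff / se
        if np.isfinite(df_t):
            pval = 2.0 * stats.t.sf(np.abs(t), df_t)
        else:
            pval = 2.0 * stats.norm.sf(np.abs(t))
        q = bh_adjust(pval)
        tab = pd.DataFrame(
            {"logFC": eff, "t": t, "p": pval, "q": q, "de": q < fdr},
            index=fit.coefficients.index,
        )
        out[name] = ContrastResult(name, c, tab, fdr, df_t)
    return out


# ---------------------------------------------------------------------------
# cross-species sharing of DE calls


@dataclass
class TwoCutoffSharing:
    shared_genes: pd.Index
    a_specific: pd.Index
    b_specific: pd.Index
    fraction_b_given_a: float
    fraction_a_given_b: float


def two_cutoff_sharing(
    res_a: ContrastResult,
    res_b: ContrastResult,
    q_strict: float = 0.01,
    q_loose: float = 0.05,
) -> TwoCutoffSharing:
    """Shared DE calls under the asymmetric two-cutoff rule.

    A gene is shared when it passes the strict FDR in one result and the
    loose FDR in the other (mitigating winner's-curse asymmetry). The
    conditional fraction "B given A" divides the strict-B calls among
    loose-A calls by the number of loose-A calls.
    """
    if not res_a.table.index.equals(res_b.table.index):
        raise ValueError("results must share the same gene universe")
    qa = res_a.table["q"]
    qb = res_b.table["q"]
    shared = ((qa < q_strict) & (qb < q_loose)) | ((qb < q_strict) & (qa < q_loose))
    denom_a = int((qa < q_loose).sum())
    denom_b = int((qb < q_loose).sum())
    num_b = int(((qb < q_strict) & (qa < q_loose)).sum())
    num_a = int(((qa < q_strict) & (qb < q_loose)).sum())
    return TwoCutoffSharing(
        shared_genes=qa.index[shared],
        a_specific=qa.index[(qa < q_strict) & ~shared],
        b_specific=qa.index[(qb < q_strict) & ~shared],
        fraction_b_given_a=num_b / denom_a if denom_a else 0.0,
        fraction_a_given_b=num_a / denom_b if denom_b else 0.0,
    )
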