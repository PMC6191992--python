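"""Joint modelling of pairwise DE tests with correlation motifs.

Each gene contributes one moderated t statistic per "study" (a pairwise
day comparison within one species). Genes are modelled as draws from a
K-component mixture: component k carries a probability q_kd of being DE
in study d, and the observed t in study d comes from a central t density
f0 when null or a scale-inflated t density f1 when DE. The mixture is fit
by EM over many random restarts; genes are then assigned to motifs and
classified as having the same temporal trajectory in both species when
their per-study posterior DE probabilities agree across the paired
transitions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .datatypes import ExpressionMatrix, validate_design
from .de import build_design_matrix  # noqa: F401  (re-exported convenience)
from . import de as _de


# ---------------------------------------------------------------------------
# study statistics


@dataclass
class StudyStatistics:
    t: pd.DataFrame  # genes x studies
    df: pd.Series  # per study total df of the moderated t
    v0: pd.Series  # per study effect-variance inflation of f1
    studies: list[str]
    scheme: str

    def log_densities(self) -> tuple[np.ndarray, np.ndarray]:
        """(log f0, log f1) evaluated at every (gene, study) statistic."""
        t = self.t.to_numpy()
        lf0 = np.empty_like(t)
        lf1 = np.empty_like(t)
        for d, st_name in enumerate(self.studies):
            df = self.df[st_name]
            scale = np.sqrt(1.0 + self.v0[st_name])
            lf0[:, d] = stats.t.logpdf(t[:, d], df)
            lf1[:, d] = stats.t.logpdf(t[:, d] / scale, df) - np.log(scale)
        return lf0, lf1


def _estimate_v0(t: np.ndarray, df: float, n_iter: int = 100) -> float:
    """Effect-variance inflation of the alternative density by moment
    matching within a two-group EM: the responsibility-weighted second
    moment of t identifies (1 + v0) * df / (df - 2)."""
    null_m2 = df / (df - 2.0) if df > 2 else 1.5
    pi1, v0 = 0.2, 4.0
    for _ in range(n_iter):
        scale = np.sqrt(1.0 + v0)
        lf0 = stats.t.logpdf(t, df)
        lf1 = stats.t.logpdf(t / scale, df) - np.log(scale)
        r = 1.0 / (1.0 + (1.0 - pi1) / pi1 * np.exp(np.clip(lf0 - lf1, -700, 700)))
        pi1_new = float(np.clip(r.mean(), 1e-4, 1 - 1e-4))
        m2 = float((r * t ** 2).sum() / max(r.sum(), 1e-12))
        v0_new = max(m2 / null_m2 - 1.0, 0.05)
        if abs(pi1_new - pi1) < 1e-8 and abs(v0_new - v0) < 1e-6:
            pi1, v0 = pi1_new, v0_new
            break
        pi1, v0 = pi1_new, v0_new
    return v0


def compute_study_statistics(
    expr_combined: ExpressionMatrix,
    design: pd.DataFrame,
    scheme: str = "consecutive",
    max_day: int | None = None,
) -> StudyStatistics:
    """Moderated t per gene per (species, day-pair) study.

    ``consecutive`` compares each day with the previous one; ``vs_day0``
    compares every later day with day 0. ``max_day`` drops transitions past
    that day (e.g. 2 excludes the final-stage studies).
    """
    design = validate_design(design)
    if design["tech_rep"].max() > 1:
        raise ValueError("combine technical replicates before computing study statistics")
    days = sorted(design["day"].unique())
    if max_day is not None:
        days = [d for d in days if d <= max_day]
    if scheme == "consecutive":
        pairs = list(zip(days[:-1], days[1:]))
    elif scheme == "vs_day0":
        pairs = [(days[0], d) for d in days[1:]]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    cols = {}
    dfs = {}
    v0s = {}
    names = []
    for sp in ("human", "chimpanzee"):
        for a, b in pairs:
            sub = design[(design["species"] == sp) & (design["day"].isin([a, b]))]
            for d in (a, b):
                if (sub["day"] == d).sum() < 2:
                    raise ValueError(f"fewer than 2 individuals for {sp} day {d}")
            name = f"{sp}:d{a}-d{b}"
            names.append(name)
            X = np.column_stack(
                [np.ones(len(sub)), (sub["day"] == b).to_numpy(float)]
            )
            sub_expr = ExpressionMatrix(
                expr_combined.values[list(sub["sample_id"])],
                unit=expr_combined.unit,
                norm_state=dict(expr_combined.norm_state),
            )
            fit = _de.fit_moderated(sub_expr, X, blocks=sub["individual"].to_numpy(),
                                    coef_names=["Intercept", "day"])
            res = _de.contrast_tests(fit, {"day": np.array([0.0, 1.0])})["day"]
            t = res.table["t"].to_numpy()
            df_tot = min(res.df_total, 200.0)  # guard the d0 -> inf limit
            cols[name] = t
            dfs[name] = df_tot
            v0s[name] = _estimate_v0(t, df_tot)
    return StudyStatistics(
        t=pd.DataFrame(cols, index=expr_combined.gene_ids),
        df=pd.Series(dfs),
        v0=pd.Series(v0s),
        studies=names,
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# the EM mixture


@dataclass
class MotifModel:
    K: int
    pi: np.ndarray  # (K,)
    q: pd.DataFrame  # K x D, q_kd = P(DE in study d | motif k)
    posterior: pd.DataFrame  # genes x K, rows sum to 1
    post_de: pd.DataFrame  # genes x D, posterior DE probability
    loglik: float
    bic: float
    aic: float
    seed: int
    studies: list[str]
    n_iter: int


def _em_once(lf0, lf1, K, rng, tol=1e-6, max_iter=500):
    g, d = lf0.shape
    q = rng.uniform(0.05, 0.95, (K, d))
    pi = rng.dirichlet(np.ones(K))
    # density ratio f1/f0 is bounded (t tails), so work with it directly
    A = np.exp(lf1 - lf0)  # g x d
    const = lf0.sum()
    prev = -np.inf
    n_it = 0
    for n_it in range(1, max_iter + 1):
        q = np.clip(q, 1e-6, 1 - 1e-6)
        # log P(t_g | k) - sum_d lf0 = sum_d log(1 + q_kd (A - 1))
        mix = 1.0 + q[None, :, :] * (A[:, None, :] - 1.0)  # g x K x d
        lgk = np.log(mix).sum(axis=2) + np.log(np.clip(pi, 1e-300, None))[None, :]
        lse = logsumexp(lgk, axis=1)
        ll = float(lse.sum() + const)
        p_gk = np.exp(lgk - lse[:, None])
        # per-gene per-study DE responsibility within each component
        b = q[None, :, :] * A[:, None, :] / mix
        denom = p_gk.sum(axis=0)
        q = np.einsum("gk,gkd->kd", p_gk, b) / np.clip(denom, 1e-300, None)[:, None]
        pi = denom / g
        if ll < prev - 1e-6:
            raise RuntimeError("EM log-likelihood decreased")
        if ll - prev < tol:
            prev = ll
            break
        prev = ll
    post_de = np.einsum("gk,gkd->gd", p_gk, b)
    return pi, q, p_gk, post_de, prev, n_it


def fit_motifs(
    stats_: StudyStatistics,
    K: int,
    n_starts: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MotifModel:
    """Best-of-``n_starts`` EM fit of the K-motif mixture."""
    g, d = stats_.t.shape
    if K < 1 or K > g:
        raise ValueError("K must be between 1 and the number of genes")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    lf0, lf1 = stats_.log_densities()
    best = None
    root = np.random.default_rng(seed)
    for _ in range(n_starts):
        rng = np.random.default_rng(root.integers(2 ** 31))
        out = _em_once(lf0, lf1, K, rng, tol, max_iter)
        if best is None or out[4] > best[4]:
            best = out
    pi, q, p_gk, post_de, ll, n_it = best
    if (pi < 1e-8).any():
        warnings.warn("empty motif component (pi < 1e-8) in the selected fit")
    n_par = (K - 1) + K * d
    return MotifModel(
        K=K,
        pi=pi,
        q=pd.DataFrame(q, columns=stats_.studies),
        posterior=pd.DataFrame(p_gk, index=stats_.t.index,
                               columns=[f"motif{k}" for k in range(K)]),
        post_de=pd.DataFrame(post_de, index=stats_.t.index, columns=stats_.studies),
        loglik=ll,
        bic=-2.0 * ll + n_par * np.log(g),
        aic=-2.0 * ll + 2.0 * n_par,
        seed=seed,
        studies=stats_.studies,
        n_iter=n_it,
    )


def select_k(
    stats_: StudyStatistics,
    K_range,
    n_starts: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Best restart per K with BIC and AIC; rows ordered by K."""
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    rows = []
    for K in K_range:
        m = fit_motifs(stats_, K, n_starts=n_starts, seed=seed)
        rows.append({"K": K, "loglik": m.loglik, "bic": m.bic, "aic": m.aic})
    tab = pd.DataFrame(rows)
    tab["best_bic"] = tab["bic"] == tab["bic"].min()
    tab["best_aic"] = tab["aic"] == tab["aic"].min()
    return tab


# ---------------------------------------------------------------------------
# assignment and trajectory sharing


@dataclass
class MotifAssignment:
    motif_id: pd.Series  # -1 for unassigned
    shared: pd.Series  # per-gene same-trajectory flag (NaN if unpaired)
    shared_fraction: float
    n_assigned: int


def assign_and_classify(
    model: MotifModel,
    de_threshold: float = 0.5,
    share_delta: float = 0.20,
) -> MotifAssignment:
    """Conservative motif assignment plus cross-species trajectory sharing.

    A gene joins its maximum-posterior motif only when its own per-study
    DE calls (posterior >= ``de_threshold``; the boundary counts as DE)
    reproduce that motif's rounded pattern. A trajectory is shared when the
    human and chimpanzee posterior DE probabilities differ by at most
    ``share_delta`` in every paired transition.
    """
    studies = model.studies
    human = [s for s in studies if s.startswith("human:")]
    chimp = [s for s in studies if s.startswith("chimpanzee:")]
    if len(human) != len(chimp) or [h.split(":")[1] for h in human] != [
        c.split(":")[1] for c in chimp
    ]:
        raise ValueError("studies are not paired across species")

    p_gk = model.posterior.to_numpy()
    best_k = p_gk.argmax(axis=1)
    gene_calls = model.post_de.to_numpy() >= de_threshold
    motif_calls = model.q.to_numpy() >= de_threshold
    consistent = (gene_calls == motif_calls[best_k]).all(axis=1)
    motif_id = np.where(consistent, best_k, -1)

    dh = model.post_de[human].to_numpy()
    dc = model.post_de[chimp].to_numpy()
    shared = (np.abs(dh - dc) <= share_delta).all(axis=1)
    assigned = motif_id >= 0
    n_assigned = int(assigned.sum())
    frac = float((shared & assigned).sum() / n_assigned) if n_assigned else float("nan")
    idx = model.posterior.index
    return MotifAssignment(
        motif_id=pd.Series(motif_id, index=idx),
        shared=pd.Series(shared, index=idx),
        shared_fraction=frac,
        n_assigned=n_assigned,
    )
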