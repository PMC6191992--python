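"""Synthetic study generator.

Emulates a two-species iPSC-to-endoderm differentiation time course: a
panel of human and chimpanzee cell lines sampled over consecutive days,
with technical replicates, motif-structured differential expression
between consecutive days, a day-specific shrink of inter-individual
variability ("canalization" signal) with tunable cross-species sharing,
negative-binomial sequencing counts, and flow-cytometry-like per-cell
marker fluorescence for purity estimation. Every draw is controlled by an
explicit seed, and the ground truth behind each gene and cell is returned
alongside the data so recovery can be scored.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, validate_design

#: study names, ordered: per species, consecutive-day transitions
def study_names(days: int = 4) -> list[str]:
    out = []
    for sp in ("human", "chimpanzee"):
        for d in range(1, days):
            out.append(f"{sp}:d{d - 1}-d{d}")
    return out


# ---------------------------------------------------------------------------
# design


def generate_design(
    n_human: int,
    n_chimp: int,
    days: int = 4,
    rep_scheme: dict | None = None,
    seed: int = 0,
    mean_lib_size: float = 2.0e7,
    lib_size_sdlog2: float = 0.25,
    deep_sample: str | None = None,
    deep_factor: float = 2.0,
) -> pd.DataFrame:
    """Build a per-sample design table for a two-species time course.

    ``rep_scheme`` maps species to the number of individuals carrying a
    second technical replicate. The default mirrors the study layout: every
    chimpanzee line replicated, two human lines replicated, so that
    (6, 4, 4) yields 64 sequencing samples. ``deep_sample`` optionally
    inflates one library by ``deep_factor`` to emulate an anomalously deep
    library (exercises the depth-subsampling rule downstream).
    """
    if n_human <= 0 or n_chimp <= 0 or min(n_human, n_chimp) < 2:
        raise ValueError("need at least two individuals per species")
    if days < 2:
        raise ValueError("need at least two days")
    if rep_scheme is None:
        rep_scheme = {"human": min(2, n_human), "chimpanzee": n_chimp}
    rng = np.random.default_rng(seed)

    rows = []
    for sp, n_ind, prefix in (("human", n_human, "H"), ("chimpanzee", n_chimp, "C")):
        n_rep = int(rep_scheme.get(sp, 0))
        if n_rep > n_ind:
            raise ValueError(f"rep_scheme[{sp!r}] exceeds individual count")
        for i in range(n_ind):
            ind = f"{prefix}{i + 1}"
            sex = "M" if i % 2 == 0 else "F"
            n_tech = 2 if i < n_rep else 1
            for day in range(days):
                for rep in range(1, n_tech + 1):
                    # replicate r goes to batch r; singletons alternate so each
                    # batch carries both species on every day
                    batch = rep if n_tech == 2 else (i % 2) + 1
                    rows.append(
                        {
                            "sample_id": f"{ind}{'ABC'[rep - 1]}_d{day}",
                            "species": sp,
                            "individual": ind,
                            "day": day,
                            "tech_rep": rep,
                            "batch": batch,
                            "sex": sex,
                            "purity": np.nan,
                        }
                    )
    design = pd.DataFrame(rows)
    lib = mean_lib_size * 2.0 ** rng.normal(0.0, lib_size_sdlog2, len(design))
    design["lib_size"] = np.round(lib).astype(np.int64)
    if deep_sample is not None:
        if deep_sample not in set(design["sample_id"]):
            raise ValueError(f"unknown deep_sample {deep_sample!r}")
        sel = design["sample_id"] == deep_sample
        design.loc[sel, "lib_size"] = (design.loc[sel, "lib_size"] * deep_factor).astype(np.int64)
    return validate_design(design)


# ---------------------------------------------------------------------------
# counts


@dataclass
class Motif:
    """A temporal DE pattern: which consecutive-day transitions move, per species."""

    proportion: float
    human: tuple
    chimp: tuple


def default_motifs(n_transitions: int = 3) -> list[Motif]:
    """A realistic motif mix: mostly flat genes, a core of conserved early
    responders, and small species-specific late classes."""
    z = (0,) * n_transitions
    early = (1,) + (0,) * (n_transitions - 1)
    allt = (1,) * n_transitions
    late = (0,) * (n_transitions - 1) + (1,)
    mid = tuple(1 if t < 2 else 0 for t in range(n_transitions))
    return [
        Motif(0.40, z, z),
        Motif(0.15, early, early),
        Motif(0.15, allt, allt),
        Motif(0.10, mid, mid),
        Motif(0.10, late, late),
        Motif(0.05, late, z),
        Motif(0.05, z, late),
    ]


@dataclass
class SimParams:
    """Generator settings for the count simulator.

    Effects are on the log2 scale. ``ind_sd`` is the SD of the per-gene,
    per-individual random intercept, redrawn each day; on genes flagged for
    variance reduction it is multiplied by ``var_shrink`` at
    ``var_shrink_day``. ``f_human``/``f_chimp`` are the flagged fractions and
    ``shared_fraction`` controls their overlap (see ``_shared_count``).
    """

    n_genes: int = 5000
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    dispersion: float = 0.1
    motifs: list = field(default_factory=default_motifs)
    day_effect_sd: float = 1.5
    species_de_fraction: float = 0.4
    species_effect_sd: float = 0.75
    ind_sd: float = 1.5
    ind_persist_sd: float = 0.0
    var_shrink: float = 0.5
    var_shrink_day: int = 1
    f_human: float = 0.0
    f_chimp: float = 0.0
    shared_fraction: float = 0.5
    tech_rep_sd: float = 0.1

    def validate(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in ("f_human", "f_chimp", "shared_fraction", "species_de_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(m.proportion for m in self.motifs) - 1.0) > 1e-8:
            raise ValueError("motif proportions must sum to 1")


@dataclass
class SimTruth:
    """Ground truth behind a simulated count matrix."""

    de_indicator: pd.DataFrame  # genes x studies, 0/1
    motif_id: pd.Series
    species_de: pd.Series
    var_reduced_human: pd.Series
    var_reduced_chimp: pd.Series
    shared: pd.Series
    shared_fraction: float
    true_purity: pd.Series | None = None


def _shared_count(g: int, f_h: float, f_c: float, s: float) -> int:
    """Number of genes flagged in both species.

    ``s`` interpolates between the smallest overlap the marginals allow
    (``f_h + f_c - 1`` when they sum past one, else zero) and complete
    nesting of the rarer set; ``s * min(f_h, f_c)`` below that floor is
    clipped up to keep the construction feasible.
    """
    lo = max(0.0, f_h + f_c - 1.0)
    return int(round(g * min(min(f_h, f_c), max(s * min(f_h, f_c), lo))))


def simulate_counts(
    design: pd.DataFrame, params: SimParams | None = None, seed: int = 0
) -> tuple[CountMatrix, SimTruth]:
    """Draw a negative-binomial count matrix with the study's structure.

    Expected counts are ``lib_size * 2**eta / sum_g 2**eta`` where ``eta``
    stacks baseline, species shift, cumulative day effects, a per-day
    individual intercept, and technical-replicate noise; NB dispersion is
    constant across genes (0 gives the deterministic mean, the noiseless
    limit).
    """
    params = params or SimParams()
    params.validate()
    design = validate_design(design)
    rng = np.random.default_rng(seed)

    g = params.n_genes
    days = int(design["day"].max()) + 1
    n_tr = days - 1
    genes = pd.Index([f"gene{i:05d}" for i in range(g)], name="gene")
    studies = study_names(days)

    # motif assignment and per-transition effects (shared draw across species)
    props = np.array([m.proportion for m in params.motifs])
    motif_id = rng.choice(len(params.motifs), size=g, p=props / props.sum())
    eff = rng.normal(0.0, params.day_effect_sd, (g, n_tr))
    pat = {
        "human": np.array([np.resize(m.human, n_tr) for m in params.motifs]),
        "chimpanzee": np.array([np.resize(m.chimp, n_tr) for m in params.motifs]),
    }
    de = np.concatenate([pat["human"][motif_id], pat["chimpanzee"][motif_id]], axis=1)
    de_indicator = pd.DataFrame(de, index=genes, columns=studies)

    # day-level means: cumulative sums of transition effects where active
    day_mean = {}
    for sp in ("human", "chimpanzee"):
        delta = eff * pat[sp][motif_id]
        day_mean[sp] = np.concatenate(
            [np.zeros((g, 1)), np.cumsum(delta, axis=1)], axis=1
        )

    species_de = rng.random(g) < params.species_de_fraction
    species_shift = np.where(species_de, rng.normal(0.0, params.species_effect_sd, g), 0.0)

    # variance-reduction flags with controlled overlap
    n_h = int(round(g * params.f_human))
    n_c = int(round(g * params.f_chimp))
    n_both = _shared_count(g, params.f_human, params.f_chimp, params.shared_fraction)
    order = rng.permutation(g)
    vr_h = np.zeros(g, bool)
    vr_c = np.zeros(g, bool)
    vr_h[order[:n_both]] = vr_c[order[:n_both]] = True
    vr_h[order[n_both : n_h]] = True
    vr_c[order[n_h : n_h + (n_c - n_both)]] = True

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, g)

    individuals = design[["individual", "species"]].drop_duplicates()
    ind_index = {ind: j for j, ind in enumerate(individuals["individual"])}
    ind_species = dict(zip(individuals["individual"], individuals["species"]))
    vr = {"human": vr_h, "chimpanzee": vr_c}
    # per gene x individual x day intercept, redrawn each day with a
    # day-specific SD (this makes a day-specific variance change expressible
    # and keeps the per-day variances independent, so two-day F tests have
    # their nominal null). An optional persistent line component
    # (ind_persist_sd) adds correlation across the time course.
    n_ind = len(ind_index)
    ind_eff = rng.normal(0.0, 1.0, (g, n_ind, days))
    for ind, j in ind_index.items():
        sp = ind_species[ind]
        sd = np.full((g, days), params.ind_sd)
        if 0 <= params.var_shrink_day < days:
            sd[vr[sp], params.var_shrink_day] *= params.var_shrink
        ind_eff[:, j, :] *= sd
    if params.ind_persist_sd > 0:
        ind_eff += rng.normal(0.0, params.ind_persist_sd, (g, n_ind))[:, :, None]

    n_s = len(design)
    eta = np.empty((g, n_s))
    for k, row in enumerate(design.itertuples(index=False)):
        sp = row.species
        eta[:, k] = (
            baseline
            + (species_shift if sp == "chimpanzee" else 0.0)
            + day_mean[sp][:, row.day]
            + ind_eff[:, ind_index[row.individual], row.day]
        )
    if params.tech_rep_sd > 0:
        eta += rng.normal(0.0, params.tech_rep_sd, (g, n_s))

    rel = 2.0 ** (eta - eta.max(axis=0))
    mu = design["lib_size"].to_numpy()[None, :] * rel / rel.sum(axis=0)[None, :]
    if params.dispersion == 0:
        counts = np.round(mu).astype(np.int64)
    else:
        r = 1.0 / params.dispersion
        counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)

    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=design["sample_id"].to_numpy()),
        gene_length_bp=pd.Series(
            np.round(2.0 ** rng.normal(11.0, 1.0, g)).astype(np.int64).clip(min=200),
            index=genes,
        ),
    )
    truth = SimTruth(
        de_indicator=de_indicator,
        motif_id=pd.Series(motif_id, index=genes),
        species_de=pd.Series(species_de, index=genes),
        var_reduced_human=pd.Series(vr_h, index=genes),
        var_reduced_chimp=pd.Series(vr_c, index=genes),
        shared=pd.Series(vr_h & vr_c, index=genes),
        shared_fraction=params.shared_fraction,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# flow cytometry


MARKERS = ["OCT3_4", "SOX2", "SOX17", "EOMES", "CKIT", "CXCR4"]

#: per-day marker mean profiles (fluorescence, arbitrary units); rows are
#: days 0..3, separation between rows is >= 6 unit SDs
DEFAULT_MARKER_MEANS = np.array(
    [
        [8.0, 8.0, 0.0, 0.0, 0.0, 0.0],  # iPSC: OCT3/4+, SOX2+
        [2.0, 2.0, 0.0, 8.0, 0.0, 0.0],  # primitive streak: EOMES+
        [0.0, 0.0, 8.0, 2.0, 8.0, 0.0],  # endoderm progenitor: SOX17+, CKIT+
        [0.0, 0.0, 8.0, 0.0, 8.0, 8.0],  # definitive endoderm: CKIT+, CXCR4+
    ]
)


@dataclass
class FlowParams:
    """Mixture settings for the per-cell fluorescence simulator."""

    component_means: np.ndarray = field(default_factory=lambda: DEFAULT_MARKER_MEANS.copy())
    component_cov: np.ndarray = field(default_factory=lambda: np.eye(6))
    cells_per_sample: int = 2000
    day_purity: dict = field(
        default_factory=lambda: {0: 0.90, 1: 0.85, 2: 0.75, 3: 0.70}
    )
    purity_jitter_sd: float = 0.03


def simulate_flow(
    design: pd.DataFrame, purity_params: FlowParams | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-cell marker fluorescence from day-component Gaussians.

    One flow sample per (individual, day) in the design. Each cell comes
    from its sample's day component with probability equal to the sample's
    true purity; contaminating cells come from the other days, weighted
    toward adjacent stages. Returns ``(cells, composition)`` where ``cells``
    has one row per cell (with its true component under ``true_day``) and
    ``composition`` one row per sample with the true mixing fractions.
    """
    p = purity_params or FlowParams()
    design = validate_design(design)
    days = sorted(design["day"].unique())
    means = np.asarray(p.component_means, float)
    cov = np.asarray(p.component_cov, float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("component covariance must be positive definite") from exc
    if means.shape != (len(days), len(MARKERS)):
        raise ValueError("component_means must be n_days x 6")

    rng = np.random.default_rng(seed)
    units = design[design["tech_rep"] == 1][["individual", "species", "day"]].drop_duplicates()
    cells = []
    comp_rows = []
    for row in units.itertuples(index=False):
        purity = float(
            np.clip(
                p.day_purity.get(row.day, 0.8) + rng.normal(0.0, p.purity_jitter_sd),
                0.05,
                1.0,
            )
        )
        w = np.array([1.0 / (1.0 + abs(row.day - d)) if d != row.day else 0.0 for d in days])
        mix = np.where(np.arange(len(days)) == days.index(row.day), purity,
                       (1.0 - purity) * w / w.sum() if w.sum() > 0 else 0.0)
        comp = rng.choice(len(days), size=p.cells_per_sample, p=mix / mix.sum())
        z = rng.standard_normal((p.cells_per_sample, len(MARKERS)))
        x = means[comp] + z @ chol.T
        df = pd.DataFrame(x, columns=MARKERS)
        df.insert(0, "sample_id", f"{row.individual}_d{row.day}")
        df.insert(1, "individual", row.individual)
        df.insert(2, "day", row.day)
        df["true_day"] = np.asarray(days)[comp]
        cells.append(df)
        frac = np.bincount(comp, minlength=len(days)) / p.cells_per_sample
        comp_rows.append(
            {"sample_id": f"{row.individual}_d{row.day}", "individual": row.individual,
             "day": row.day, "true_purity": frac[days.index(row.day)],
             **{f"frac_day{d}": frac[i] for i, d in enumerate(days)}}
        )
    cells = pd.concat(cells, ignore_index=True)
    cells.insert(0, "cell_id", [f"cell{i:06d}" for i in range(len(cells))])
    return cells, pd.DataFrame(comp_rows)
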