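"""Unsupervised purity estimation from per-cell marker fluorescence.

Cells carry six compensated fluorescence values (pluripotency and
endoderm-lineage markers). After per-sample subsampling, cells are
clustered by k-means on the rows of the cell-cell Pearson correlation
matrix; clusters are mapped to differentiation days and each sample's
purity is the fraction of its cells landing in its own day's cluster.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .simulate import MARKERS


def subsample_cells(
    flow: pd.DataFrame, per_sample: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Uniform without-replacement subsample of cells per sample.

    Samples with fewer than ``per_sample`` cells are kept whole (with a
    warning); empty samples are an error.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for sid, grp in flow.groupby("sample_id", sort=True):
        if len(grp) == 0:
            raise ValueError(f"sample {sid!r} has no cells")
        if len(grp) < per_sample:
            warnings.warn(f"sample {sid!r} has only {len(grp)} cells; keeping all")
            parts.append(grp)
        else:
            idx = rng.choice(len(grp), size=per_sample, replace=False)
            parts.append(grp.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def _correlation_rows(x: np.ndarray, block: int = 20000) -> np.ndarray:
    """Cell x cell Pearson correlation matrix, computed blockwise above
    ``block`` cells to bound peak memory (identical values either way)."""
    sd = x.std(axis=1)
    if (sd == 0).any():
        raise ValueError("zero-variance cell vectors present")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    n, m = z.shape
    if n <= block:
        return (z @ z.T) / m
    out = np.empty((n, n))
    for i in range(0, n, block):
        out[i : i + block] = (z[i : i + block] @ z.T) / m
    return out


def cluster_cells(
    flow_sub: pd.DataFrame, K: int = 4, seed: int = 0, markers=MARKERS
) -> pd.Series:
    """Hard k-means assignments on rows of the cell-cell correlation matrix.

    Zero-variance cells (undefined correlation) are dropped with a warning;
    their assignment is reported as -1.
    """
    x = flow_sub[list(markers)].to_numpy(float)
    if len(x) < K:
        raise ValueError("fewer cells than clusters")
    sd = x.std(axis=1)
    ok = sd > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} zero-variance cells")
    corr = _correlation_rows(x[ok])
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    labels = km.fit_predict(corr)
    out = np.full(len(x), -1)
    out[ok] = labels
    return pd.Series(out, index=flow_sub.index, name="cluster")


@dataclass
class CompositionEstimate:
    composition: pd.DataFrame  # samples x clusters, fractions sum to 1
    cluster_to_day: dict
    purity: pd.Series  # per sample: fraction in own-day cluster
    pc_scores: pd.DataFrame  # first 3 PCs of the correlation rows (audit)


def match_and_compose(
    assignments: pd.Series,
    flow_sub: pd.DataFrame,
    design: pd.DataFrame | None = None,
    markers=MARKERS,
) -> CompositionEstimate:
    """Map clusters to days and summarize per-sample composition.

    Each cluster is assigned the day whose cells dominate it (majority
    rule, ties to the lower day); a day can claim several clusters. PCA
    scores of the correlation rows are returned for visual audit.
    """
    ok = assignments >= 0
    sub = flow_sub[ok]
    labels = assignments[ok].to_numpy()
    day = sub["day"].to_numpy()
    clusters = np.unique(labels)
    mapping = {}
    for c in clusters:
        days_c, counts = np.unique(day[labels == c], return_counts=True)
        mapping[int(c)] = int(days_c[np.argmax(counts)])  # ties: first = lowest day

    comp = (
        pd.crosstab(sub["sample_id"], labels)
        .reindex(columns=clusters, fill_value=0)
        .pipe(lambda t: t.div(t.sum(axis=1), axis=0))
    )
    comp.columns = [f"cluster{c}" for c in clusters]
    sample_day = sub.groupby("sample_id")["day"].first()
    own = {}
    for sid, d in sample_day.items():
        own_clusters = [f"cluster{c}" for c, md in mapping.items() if md == d]
        own[sid] = float(comp.loc[sid, own_clusters].sum()) if own_clusters else float("nan")

    x = sub[list(markers)].to_numpy(float)
    corr = _correlation_rows(x)
    pcs = PCA(n_components=3, random_state=0).fit_transform(corr)
    return CompositionEstimate(
        composition=comp,
        cluster_to_day=mapping,
        purity=pd.Series(own, name="purity"),
        pc_scores=pd.DataFrame(pcs, index=sub.index, columns=["PC1", "PC2", "PC3"]),
    )


def estimate_purity(
    flow: pd.DataFrame, K: int = 4, per_sample: int = 1000, seed: int = 0
) -> CompositionEstimate:
    """Subsample, cluster and compose in one call."""
    sub = subsample_cells(flow, per_sample, seed)
    labels = cluster_cells(sub, K=K, seed=seed)
    return match_and_compose(labels, sub)
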