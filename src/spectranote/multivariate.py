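"""PCA of NSAF profiles and k-means clustering of treatment profiles.

PCA treats samples as observations and retained proteins as variables,
mean-centered but not variance-scaled by default (unit-variance scaling
and a log transform are available as flags).  Component signs are fixed so
that each loading vector's largest-magnitude entry is positive, making
decompositions reproducible across library versions.

For clustering, each protein's per-treatment mean NSAF values are first
rescaled to sum to one ("treatment profiles": the protein's proportional
distribution of abundance across conditions), so clusters group proteins
by the *shape* of their response, not by absolute abundance.  Clustering
is Euclidean k-means with k-means++ seeding and a best-of-``n_restarts``
inertia criterion; k = 30 is the conventional choice for this workflow.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io import NSAFMatrix
from .quantify import treatment_means

__all__ = [
    "PCAModel",
    "ClusterModel",
    "pca_fit",
    "loading_sum_profile",
    "profile_normalize",
    "kmeans_fit",
    "cluster_profile_plot_data",
]


@dataclasses.dataclass
class PCAModel:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # proteins x components
    explained_variance: pd.Series
    explained_variance_ratio: pd.Series
    mean: pd.Series               # per-protein center removed before fit
    scaled: bool
    log_transformed: bool

    @property
    def components(self) -> list[str]:
        return list(self.scores.columns)


def pca_fit(
    nsafm: NSAFMatrix,
    retained: list[str] | set[str] | None = None,
    n_components: int | None = None,
    scale: bool = False,
    log: bool = False,
) -> PCAModel:
    """Principal-component decomposition of samples over retained proteins.

    ``log`` applies log2(1 + x) to the (reporting-scale) NSAF values before
    centering; ``scale`` divides each protein by its standard deviation
    (proteins with zero variance are left centered only).
    """
    accs = nsafm.accessions if retained is None else [
        a for a in nsafm.accessions if a in set(retained)
    ]
    X = nsafm.values.loc[accs].T.to_numpy(float)  # samples x proteins
    n_samples, n_proteins = X.shape
    max_comp = min(n_samples, n_proteins)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(
            f"{n_components} components requested, at most {max_comp} available"
        )
    if log:
        X = np.log2(1.0 + X)
    mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - mean) / sd + mean  # recentered below by sklearn

    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # proteins x components

    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    pcs = [f"PC{i + 1}" for i in range(n_components)]
    samples = list(nsafm.values.columns)
    return PCAModel(
        scores=pd.DataFrame(scores, index=samples, columns=pcs),
        loadings=pd.DataFrame(loadings, index=accs, columns=pcs),
        explained_variance=pd.Series(model.explained_variance_, index=pcs),
        explained_variance_ratio=pd.Series(model.explained_variance_ratio_, index=pcs),
        mean=pd.Series(mean, index=accs),
        scaled=scale,
        log_transformed=log,
    )


def loading_sum_profile(
    pca: PCAModel,
    nsafm: NSAFMatrix,
    component: str | int = "PC1",
    n: int = 100,
    side: str = "high",
) -> pd.Series:
    """Per-treatment summed mean NSAF of the n most extreme-loading proteins.

    ``side`` "high" takes the n largest loadings on the component, "low"
    the n most negative; ties break by accession order.  The returned
    Series (indexed by treatment) is the summed treatment-mean NSAF of the
    selected proteins — the quantity plotted as per-treatment bars when
    interpreting which conditions drive a component.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if isinstance(component, int):
        component = f"PC{component}"
    load = pca.loadings[component]
    if n > len(load):
        raise ValueError(f"n={n} exceeds protein count {len(load)}")
    accs = np.asarray(load.index)
    vals = load.to_numpy()
    if side == "high":
        order = np.lexsort((accs, -vals))
    elif side == "low":
        order = np.lexsort((accs, vals))
    else:
        raise ValueError("side must be 'high' or 'low'")
    chosen = accs[order[:n]]
    means = treatment_means(nsafm)
    return means.loc[chosen].sum(axis=0)


def profile_normalize(means: pd.DataFrame) -> pd.DataFrame:
    """Rescale each protein's treatment means to proportions summing to 1.

    All-zero rows cannot be profiled; they are dropped with a warning.
    """
    rowsum = means.sum(axis=1)
    zero = rowsum == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} all-zero profile row(s)", stacklevel=2
        )
    means = means.loc[~zero]
    return means.div(means.sum(axis=1), axis=0)


@dataclasses.dataclass
class ClusterModel:
    profiles: pd.DataFrame      # proteins x treatments, rows sum to 1
    k: int
    assignments: pd.Series      # accession -> cluster id (0..k-1)
    centroids: pd.DataFrame     # k x treatments
    seed: int
    n_restarts: int
    inertia: float

    def members(self, cluster_id: int) -> list[str]:
        if cluster_id not in set(range(self.k)):
            raise KeyError(f"unknown cluster id {cluster_id}")
        return list(self.assignments.index[self.assignments == cluster_id])


def kmeans_fit(
    profiles: pd.DataFrame, k: int = 30, seed: int = 0, n_restarts: int = 50
) -> ClusterModel:
    """Euclidean k-means on treatment profiles, best of ``n_restarts`` runs.

    Rows are canonicalized by sorting on accession before seeding, so the
    result is invariant to input row order for a given seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds protein count {len(profiles)}")
    profiles = profiles.sort_index(kind="stable")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy(float))
    return ClusterModel(
        profiles=profiles,
        k=k,
        assignments=pd.Series(labels, index=profiles.index),
        centroids=pd.DataFrame(km.cluster_centers_, columns=profiles.columns),
        seed=seed,
        n_restarts=n_restarts,
        inertia=float(km.inertia_),
    )


def cluster_profile_plot_data(
    model: ClusterModel, clusters: list[int] | None = None
) -> pd.DataFrame:
    """Mean normalized profile and size per cluster, for plotting/reporting.

    ``clusters`` defaults to all non-empty clusters.  Columns: cluster id,
    size, semicolon-joined member accessions, then one mean-proportion
    column per treatment.
    """
    if clusters is None:
        clusters = sorted(set(model.assignments))
    rows = []
    for cid in clusters:
        members = model.members(int(cid))
        if not members:
            raise KeyError(f"cluster {cid} is empty")
        sub = model.profiles.loc[members]
        row = {"cluster": int(cid), "size": len(members), "members": ";".join(members)}
        row.update(sub.mean(axis=0).to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
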