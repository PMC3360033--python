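"""Community state type (CST) assignment by clustering composition vectors.

Vaginal communities fall into a handful of recurring states: CST I, II
and III dominated by *L. crispatus*, *L. gasseri* and *L. iners*
respectively, and CST IV, a diverse state rich in strict and facultative
anaerobes with few lactobacilli. Samples are clustered with Ward linkage
on the Jensen-Shannon divergence matrix and each cluster is labeled from
its centroid: if the centroid's total *Lactobacillus* proportion is
below 0.5 the cluster is CST IV, otherwise the dominant *Lactobacillus*
species decides (crispatus -> I, gasseri -> II, iners -> III).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .distance import pairwise_distances
from .types import CSTAssignment, LACTOBACILLUS_TAXA, TaxonProfile, profiles_to_frame

_SPECIES_TO_CST = {"L. crispatus": "I", "L. gasseri": "II", "L. iners": "III"}


class CSTClusterer(ClusterMixin, BaseEstimator):
    """Hierarchical CST typing of taxon composition vectors.

    Parameters
    ----------
    n_clusters : int, default 4
        Number of clusters the dendrogram is cut into. Four matches the
        states present in this cohort; prior vaginal microbiome surveys
        describe five.
    linkage_method : str, default "ward"
        Linkage passed to scipy; Ward is applied to the JSD matrix
        treated as a plain dissimilarity (no square-root correction).
    dominance_threshold : float, default 0.5
        Minimum centroid *Lactobacillus* fraction for a cluster to be
        labeled by its dominant species rather than CST IV.

    Attributes
    ----------
    labels_ : ndarray of cluster indices (0-based).
    cst_labels_ : list of "I"/"II"/"III"/"IV" per sample.
    cluster_cst_ : dict cluster index -> CST label.
    centroids_ : DataFrame, cluster centroids in taxon space.
    """

    def __init__(self, n_clusters: int = 4, linkage_method: str = "ward",
                 dominance_threshold: float = 0.5):
        self.n_clusters = n_clusters
        self.linkage_method = linkage_method
        self.dominance_threshold = dominance_threshold

    def fit(self, X, y=None):
        """Cluster samples given as a samples x taxa DataFrame."""
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x taxa DataFrame")
        n = X.shape[0]
        if self.n_clusters < 2 or self.n_clusters > n:
            raise ValueError(f"n_clusters must be in [2, {n}]")
        # sort rows for an input-order-independent merge sequence
        order = np.argsort(X.index.to_numpy())
        Xs = X.iloc[order]
        profiles = _frame_to_profiles(Xs)
        dm = pairwise_distances(profiles, metric="jsd")
        Z = linkage(squareform(dm.data, checks=False), method=self.linkage_method)
        flat = fcluster(Z, t=self.n_clusters, criterion="maxclust")
        labels_sorted = np.asarray(flat) - 1
        labels = np.empty(n, dtype=int)
        labels[order] = labels_sorted
        self.linkage_ = Z
        self.labels_ = labels
        centroids = {}
        cluster_cst = {}
        for c in np.unique(labels):
            centroid = X.iloc[labels == c].mean(axis=0)
            centroids[c] = centroid
            cluster_cst[c] = _label_centroid(centroid, self.dominance_threshold)
        self.centroids_ = pd.DataFrame(centroids).T
        self.cluster_cst_ = cluster_cst
        self.cst_labels_ = [cluster_cst[c] for c in labels]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _label_centroid(centroid: pd.Series, threshold: float) -> str:
    lacto = sum(centroid.get(t, 0.0) for t in LACTOBACILLUS_TAXA)
    if lacto < threshold:
        return "IV"
    dominant = _dominant_taxon(centroid)
    if dominant in _SPECIES_TO_CST:
        return _SPECIES_TO_CST[dominant]
    # Lactobacillus-dominated but led by an unmapped taxon (e.g. a
    # jensenii-heavy mixture): fall back to the strongest mapped species.
    mapped = {t: centroid.get(t, 0.0) for t in _SPECIES_TO_CST}
    return _SPECIES_TO_CST[max(sorted(mapped), key=lambda t: mapped[t])]


def _dominant_taxon(centroid: pd.Series) -> str:
    best = centroid.max()
    candidates = sorted(centroid.index[centroid >= best - 1e-12])
    return candidates[0]


def _frame_to_profiles(frame: pd.DataFrame) -> list[TaxonProfile]:
    profiles = []
    for sid, row in frame.iterrows():
        vec = row.to_numpy(dtype=float)
        props = {t: v / vec.sum() for t, v in row.items() if v > 0}
        profiles.append(
            TaxonProfile(sample_id=str(sid), subject_id=str(sid), condition="C1",
                         total_reads=1, proportions=props)
        )
    return profiles


def assign_cst(profiles: Sequence[TaxonProfile], k: int = 4) -> list[CSTAssignment]:
    """Cluster profiles into ``k`` community state types.

    Returns one :class:`CSTAssignment` per profile, in input order.
    """
    frame = profiles_to_frame(profiles)
    est = CSTClusterer(n_clusters=k).fit(frame)
    out = []
    for prof, cluster in zip(profiles, est.labels_):
        centroid = est.centroids_.loc[cluster]
        dominant = _dominant_taxon(centroid)
        out.append(
            CSTAssignment(
                sample_id=prof.sample_id,
                cst_label=est.cluster_cst_[cluster],
                cluster_index=int(cluster),
                dominant_taxon=dominant,
                dominant_fraction=float(centroid.max()),
            )
        )
    return out
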