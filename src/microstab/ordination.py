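"""Phylogeny-aware distances and principal coordinates analysis.

Weighted UniFrac weighs every branch of a rooted tree by its length
times the absolute difference in the fraction of community mass found
below it, so communities differing in deeply diverged taxa are farther
apart than communities differing in close relatives. PCoA (classical
metric multidimensional scaling) embeds any distance matrix into
Euclidean axes ordered by explained variation. The subject clustering
score summarizes whether within-subject distances sit below
between-subject distances.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence, Union

import numpy as np
import skbio
from scipy.linalg import eigh
from sklearn.base import BaseEstimator

from .types import TaxonProfile


def weighted_unifrac(tree: Union[skbio.TreeNode, str], p: dict, q: dict,
                     normalized: bool = True) -> float:
    """Weighted UniFrac distance between two compositions on a tree.

    ``p`` and ``q`` map leaf names to proportions (each summing to 1).
    Raw form: sum over branches of b_i * |A_i - B_i| where A_i/B_i are
    the fractions of each community's mass below branch i. The
    normalized form divides by sum of b_i * (A_i + B_i), bounding the
    distance by 1. Zero-length and unlengthed branches contribute
    nothing; multifurcations are fine.
    """
    if isinstance(tree, str):
        tree = skbio.TreeNode.read([tree])
    leaf_names = {leaf.name for leaf in tree.tips()}
    missing = (set(p) | set(q)) - leaf_names
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    for name, v in (("p", p), ("q", q)):
        total = sum(v.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{name} sums to {total:.8f}, expected 1")
    raw = 0.0
    denom = 0.0
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            a = p.get(node.name, 0.0)
            b = q.get(node.name, 0.0)
        else:
            a = sum(p.get(t.name, 0.0) for t in node.tips())
            b = sum(q.get(t.name, 0.0) for t in node.tips())
        length = node.length or 0.0
        raw += length * abs(a - b)
        denom += length * (a + b)
    if not normalized:
        return raw
    return raw / denom if denom > 0 else 0.0


def unifrac_distance_matrix(tree, profiles: Sequence[TaxonProfile],
                            normalized: bool = True) -> skbio.DistanceMatrix:
    """Pairwise weighted UniFrac matrix over profiles (taxa = tree leaves)."""
    if isinstance(tree, str):
        tree = skbio.TreeNode.read([tree])
    n = len(profiles)
    out = np.zeros((n, n))
    # zero-abundance taxa contribute no branch mass; drop them so an
    # all-zero remainder taxon needs no tree leaf
    comps = [{t: v for t, v in p.proportions.items() if v > 0}
             for p in profiles]
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = weighted_unifrac(tree, comps[i], comps[j],
                                                     normalized)
    return skbio.DistanceMatrix(out, ids=[p.sample_id for p in profiles])


class PCoA(BaseEstimator):
    """Classical (Gower) principal coordinates analysis.

    ``fit_transform`` double-centers -D**2/2, eigendecomposes it, and
    returns coordinates on the axes with positive eigenvalues (up to
    ``n_components``). Negative eigenvalues — which arise when D is not
    Euclidean-embeddable — are dropped from both the coordinates and the
    explained-variation denominator; their total magnitude is kept in
    ``negative_eigenvalue_mass_`` for inspection.

    Attributes
    ----------
    eigenvalues_ : positive eigenvalues, descending.
    explained_fraction_ : eigenvalue / sum of positive eigenvalues.
    coordinates_ : samples x axes array.
    sample_ids_ : ids when a skbio DistanceMatrix was supplied.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, D, y=None):
        self.fit_transform(D)
        return self

    def fit_transform(self, D, y=None) -> np.ndarray:
        if isinstance(D, skbio.DistanceMatrix):
            ids = list(D.ids)
            D = D.data
        else:
            D = np.asarray(D, dtype=float)
            ids = list(range(D.shape[0]))
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be square")
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("D must be symmetric")
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D ** 2) @ J
        vals, vecs = eigh((B + B.T) / 2)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        tol = 1e-10 * max(1.0, abs(vals[0]))
        pos = vals > tol
        self.negative_eigenvalue_mass_ = float(-vals[vals < -tol].sum())
        vals_pos, vecs_pos = vals[pos], vecs[:, pos]
        k = vals_pos.size
        if self.n_components is not None:
            k = min(k, self.n_components)
        self.eigenvalues_ = vals_pos
        self.explained_fraction_ = (
            vals_pos / vals_pos.sum() if vals_pos.size else vals_pos
        )
        self.coordinates_ = vecs_pos[:, :k] * np.sqrt(vals_pos[:k])
        self.sample_ids_ = ids
        return self.coordinates_


def pcoa(D, n_axes: int | None = None) -> PCoA:
    """Fit a :class:`PCoA` on a distance matrix and return the estimator."""
    est = PCoA(n_components=n_axes)
    est.fit_transform(D)
    return est


def subject_clustering_score(D: skbio.DistanceMatrix,
                             subject_labels: Sequence[str]) -> tuple[float, float, float]:
    """(median within, median between, score) for subject-wise clustering.

    The score is the fraction of within-subject pairs whose distance
    falls below the median between-subject distance; 1 means perfect
    subject separation, ~0.5 means none.
    """
    labels = list(subject_labels)
    n = len(labels)
    if D.shape[0] != n:
        raise ValueError("label count must match matrix size")
    within, between = [], []
    for i, j in combinations(range(n), 2):
        (within if labels[i] == labels[j] else between).append(D.data[i, j])
    counts = {s: labels.count(s) for s in set(labels)}
    if sum(c >= 2 for c in counts.values()) < 2 or not between:
        raise ValueError("need >= 2 subjects with >= 2 samples each")
    med_between = float(np.median(between))
    score = float(np.mean([d < med_between for d in within]))
    return float(np.median(within)), med_between, score
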