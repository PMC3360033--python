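"""Dissimilarity measures between community composition vectors.

All metrics operate on proportion vectors (compositions summing to 1).
The Jensen-Shannon divergence is computed in natural log, so it is
bounded by ln 2. The relative-entropy ("kl") and log-Euclidean metrics
need a pseudocount for zero proportions; the default is a small relative
offset of 1e-6.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import skbio

from .types import TaxonProfile, profiles_to_frame

METRICS = ("jsd", "kl", "euclidean", "log_euclidean", "bray_curtis")

DEFAULT_PSEUDOCOUNT = 1e-6


def _validate_pair(p, q) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1-D vectors of equal length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("proportions must be non-negative")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} sums to {v.sum():.8f}, expected 1 (tol 1e-6)")
    return p, q


def _entropy_nats(v: np.ndarray) -> float:
    nz = v[v > 0]
    return float(-(nz * np.log(nz)).sum())


def jensen_shannon(p, q) -> float:
    """Jensen-Shannon divergence in nats: H(m) - [H(p)+H(q)]/2, m=(p+q)/2.

    Symmetric, zero iff p == q, and bounded above by ln 2 (attained on
    disjoint supports). ``0 log 0`` is taken as 0.
    """
    p, q = _validate_pair(p, q)
    m = 0.5 * (p + q)
    return max(0.0, _entropy_nats(m) - 0.5 * (_entropy_nats(p) + _entropy_nats(q)))


def dissimilarity(p, q, metric: str = "jsd",
                  pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Evaluate one of the supported dissimilarities between two compositions.

    Metrics: ``jsd``; ``kl`` (directed relative entropy of p from q —
    asymmetric, so matrix-building code symmetrizes it); ``euclidean``;
    ``log_euclidean`` (Euclidean on log-transformed proportions);
    ``bray_curtis``.
    """
    if metric == "jsd":
        return jensen_shannon(p, q)
    p, q = _validate_pair(p, q)
    if metric == "kl":
        return kl_divergence(p, q, pseudocount)
    if metric == "euclidean":
        return float(np.linalg.norm(p - q))
    if metric == "log_euclidean":
        if pseudocount <= 0:
            raise ValueError("log_euclidean requires a positive pseudocount")
        return float(np.linalg.norm(np.log(p + pseudocount) - np.log(q + pseudocount)))
    if metric == "bray_curtis":
        denom = (p + q).sum()
        return float(np.abs(p - q).sum() / denom)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def kl_divergence(p, q, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Directed relative entropy sum p_i ln((p_i+eps)/(q_i+eps)) in nats."""
    p, q = _validate_pair(p, q)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    eps = pseudocount
    if eps == 0:
        nz = p > 0
        if (q[nz] == 0).any():
            raise ValueError("KL undefined: q has zeros where p > 0 and pseudocount=0")
        return float((p[nz] * np.log(p[nz] / q[nz])).sum())
    return float((p * np.log((p + eps) / (q + eps))).sum())


def pairwise_distances(profiles: Sequence[TaxonProfile], metric: str = "jsd",
                       pseudocount: float = DEFAULT_PSEUDOCOUNT) -> skbio.DistanceMatrix:
    """Symmetric distance matrix between all profiles under one metric.

    Profiles are placed in a common taxon space (union, zero-filled)
    before the pairwise calls. The asymmetric ``kl`` metric is
    symmetrized as [KL(p,q)+KL(q,p)]/2 so the result is a valid
    dissimilarity matrix.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    frame = profiles_to_frame(profiles)
    X = frame.to_numpy()
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pair_dissimilarity(X[i], X[j], metric, pseudocount)
    return skbio.DistanceMatrix(out, ids=list(frame.index))


def pair_dissimilarity(p, q, metric: str = "jsd",
                       pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Symmetric dissimilarity between two compositions (kl symmetrized)."""
    if metric == "kl":
        return 0.5 * (kl_divergence(p, q, pseudocount) + kl_divergence(q, p, pseudocount))
    return dissimilarity(p, q, metric, pseudocount)


def rarefy(counts: Mapping[str, int], depth: int, seed) -> dict[str, int]:
    """Subsample a taxon count table without replacement to a fixed depth.

    Draws from the multivariate hypergeometric distribution, i.e. picks
    ``depth`` reads uniformly at random from the observed reads.
    """
    taxa = list(counts)
    vals = np.array([counts[t] for t in taxa], dtype=np.int64)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(vals.sum())
    if depth <= 0:
        raise ValueError("depth must be positive")
    if total < depth:
        raise ValueError(
            f"sample has only {total} reads, cannot rarefy to depth {depth}"
        )
    rng = np.random.default_rng(seed)
    sub = rng.multivariate_hypergeometric(vals, depth)
    return {t: int(c) for t, c in zip(taxa, sub)}
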