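"""Storage-condition equivalence testing against a replicate-derived null.

The question: do communities from the same subject stored under two
different cold-chain conditions differ more than technical replicates
handled identically? For each unordered condition pair the
within-subject between-condition dissimilarities form the test sample;
all within-subject pairwise dissimilarities among replicate triplets
form the null sample; a two-sample Kolmogorov-Smirnov test compares the
two distributions. Failing to reject at 0.05 supports storage
equivalence under that metric.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb
from typing import Sequence

from scipy import stats

from .distance import DEFAULT_PSEUDOCOUNT, pair_dissimilarity
from .types import EquivalenceResult, TaxonProfile, profiles_to_frame

logger = logging.getLogger(__name__)

#: Largest number of distinct orderings C(n+m, n) for which the exact
#: (distribution-free) KS p-value is used; beyond it the asymptotic
#: Kolmogorov distribution with effective size nm/(n+m) takes over.
EXACT_KS_LIMIT = 10 ** 5

DEFAULT_METRICS = ("jsd", "kl", "euclidean", "log_euclidean", "bray_curtis")


def between_condition_distances(profiles: Sequence[TaxonProfile], cond_a: str,
                                cond_b: str, metric: str = "jsd",
                                pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[float]:
    """Within-subject dissimilarity between two storage conditions.

    One distance per subject that has both conditions; subjects missing
    either are skipped with a logged notice.
    """
    frame = profiles_to_frame(profiles)
    by_subject: dict[str, dict[str, str]] = {}
    for p in profiles:
        by_subject.setdefault(p.subject_id, {})[p.condition] = p.sample_id
    out = []
    for subject, conds in by_subject.items():
        if cond_a not in conds or cond_b not in conds:
            logger.info("subject %s lacks condition %s or %s; skipped",
                        subject, cond_a, cond_b)
            continue
        p = frame.loc[conds[cond_a]].to_numpy()
        q = frame.loc[conds[cond_b]].to_numpy()
        out.append(pair_dissimilarity(p, q, metric, pseudocount))
    if not out:
        raise ValueError(f"no subject has both conditions {cond_a} and {cond_b}")
    return out


def null_distances(replicate_profiles: Sequence[TaxonProfile], metric: str = "jsd",
                   pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[float]:
    """Pooled within-subject pairwise distances among technical replicates.

    A triplet contributes its three pairwise distances. Groups with a
    single sample are skipped with a notice.
    """
    frame = profiles_to_frame(replicate_profiles)
    by_subject: dict[str, list[str]] = {}
    for p in replicate_profiles:
        by_subject.setdefault(p.subject_id, []).append(p.sample_id)
    out = []
    for subject, ids in by_subject.items():
        if len(ids) < 2:
            logger.info("replicate group %s has one sample; skipped", subject)
            continue
        for a, b in combinations(ids, 2):
            out.append(
                pair_dissimilarity(frame.loc[a].to_numpy(), frame.loc[b].to_numpy(),
                                   metric, pseudocount)
            )
    if not out:
        raise ValueError("no replicate group with >= 2 samples")
    return out


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D is the supremum gap between the two right-continuous empirical
    CDFs, evaluated at all pooled data points. The p-value is exact
    (distribution-free permutation distribution) while C(n+m, n) stays
    at or below :data:`EXACT_KS_LIMIT`, and asymptotic with effective
    size nm/(n+m) beyond that.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if comb(len(x) + len(y), len(x)) <= EXACT_KS_LIMIT else "asymp"
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def equivalence_report(profiles: Sequence[TaxonProfile],
                       replicate_profiles: Sequence[TaxonProfile],
                       metrics: Sequence[str] = DEFAULT_METRICS,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[EquivalenceResult]:
    """KS equivalence results for every metric x unordered condition pair."""
    conditions = sorted({p.condition for p in profiles})
    if len(conditions) < 2:
        raise ValueError("need at least two storage conditions")
    results = []
    for metric in metrics:
        null = null_distances(replicate_profiles, metric, pseudocount)
        for cond_a, cond_b in combinations(conditions, 2):
            test = between_condition_distances(profiles, cond_a, cond_b,
                                               metric, pseudocount)
            d, p = ks_two_sample(test, null)
            results.append(
                EquivalenceResult(
                    metric=metric, condition_pair=(cond_a, cond_b),
                    ks_statistic=d, p_value=p,
                    n_test=len(test), n_null=len(null),
                )
            )
    return results
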