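from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from scipy.stats import rankdata

import microstab as ms


def wilcoxon_sign_enumeration_oracle(x, y):
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxonSignedRank:
    def test_identical_pairs_degenerate(self):
        res = ms.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.degenerate

    def test_three_positive_differences_exact_quarter(self):
        """n=3, all signs positive: one-sided 1/8, two-sided 1/4."""
        res = ms.wilcoxon_signed_rank([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert res.p_value == pytest.approx(0.25)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=9)
        y = rng.normal(loc=0.5, size=9)
        assert ms.wilcoxon_signed_rank(x, y).p_value == pytest.approx(
            ms.wilcoxon_signed_rank(y, x).p_value
        )

    @pytest.mark.parametrize("seed,n", [(0, 4), (1, 6), (2, 8), (3, 10), (4, 7)])
    def test_matches_sign_enumeration_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = x + rng.normal(loc=0.3, scale=1.0, size=n)
        # force a tie in |differences| occasionally
        if seed % 2:
            y[1] = x[1] + (x[0] - y[0])
        res = ms.wilcoxon_signed_rank(x, y)
        w_or, p_or = wilcoxon_sign_enumeration_oracle(x, y)
        assert res.statistic == pytest.approx(w_or)
        assert res.p_value == pytest.approx(p_or, abs=1e-12)

    def test_large_n_normal_approximation_close_to_exact_shape(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        y = x + rng.normal(loc=0.4, scale=1.0, size=40)
        res = ms.wilcoxon_signed_rank(x, y)
        assert 0.0 <= res.p_value <= 1.0


class TestFdrBH:
    def test_single_p_unchanged(self):
        assert ms.fdr_bh([0.03]) == pytest.approx([0.03])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(ms.fdr_bh([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_step_up_hand_oracle(self):
        """Worked step-up case: q_(i) = min_{j>=i} p_(j) m / j."""
        got = ms.fdr_bh([0.01, 0.02, 0.04, 0.05])
        np.testing.assert_allclose(got, [0.04, 0.04, 0.05, 0.05])

    def test_permutation_equivariance_and_monotonicity(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        q = ms.fdr_bh(p)
        perm = rng.permutation(20)
        np.testing.assert_allclose(ms.fdr_bh(p[perm]), q[perm])
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ms.fdr_bh([0.5, 1.2])


def _cohort_bucket_table(seed=0, lactate_scale=None):
    params = ms.StudyParams(seed=seed)
    study = ms.generate_study(params)
    spectra = ms.generate_nmr_spectra(study, seed=seed,
                                      condition_lactate_scale=lactate_scale)
    table = ms.IntelligentBucketer().fit(spectra).transform(spectra)
    meta = pd.DataFrame(
        {"subject_id": [p.subject_id for p in study],
         "condition": [p.condition for p in study]},
        index=[p.sample_id for p in study],
    )
    return table, meta


class TestBucketConditionReport:
    def test_result_count_is_buckets_times_pairs(self):
        table, meta = _cohort_bucket_table(seed=5)
        results = ms.bucket_condition_report(table, meta)
        assert len(results) == table.shape[1] * 3
        assert all(0 <= r.p_value <= 1 and 0 <= r.q_value <= 1 for r in results)
        assert all(r.q_value >= r.p_value - 1e-12 for r in results)

    def test_no_effect_cohort_rarely_discovers(self):
        """Without a storage effect the discovery fraction stays near zero.

        Not exactly zero: with 8 paired subjects an all-same-sign pattern
        has probability 2/2^8 per condition pair, and total-sum
        normalization couples the buckets, so such a flip produces a
        correlated block of spurious discoveries in a small share of
        cohorts.
        """
        hits = total = 0
        for seed in range(5):
            table, meta = _cohort_bucket_table(seed=seed)
            results = ms.bucket_condition_report(table, meta)
            hits += sum(r.q_value < 0.05 for r in results)
            total += len(results)
        assert hits / total < 0.05

    def test_insufficient_pairing_raises(self):
        table, meta = _cohort_bucket_table(seed=1)
        solo = meta.iloc[:1]
        with pytest.raises(ValueError):
            ms.bucket_condition_report(table.loc[solo.index], solo)


class TestHierarchicalCluster:
    def test_identical_rows_merge_first(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0], [9.0, 1.0]])
        Z = ms.hierarchical_cluster(X)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 2}
        assert Z[0, 2] == pytest.approx(0.0)

    def test_two_blobs_join_last(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.3, size=(6, 3))
        b = rng.normal(8, 0.3, size=(6, 3))
        Z = ms.hierarchical_cluster(np.vstack([a, b]))
        flat = fcluster(Z, t=2, criterion="maxclust")
        assert len(set(flat[:6])) == 1
        assert len(set(flat[6:])) == 1
        assert flat[0] != flat[6]

    def test_four_point_lance_williams_trace(self):
        """Merge heights equal a direct Lance-Williams Ward recursion."""
        X = np.array([[0.0, 0.0], [1.0, 0.0], [4.0, 1.0], [5.0, 3.0]])
        Z = ms.hierarchical_cluster(X)

        clusters = {i: [i] for i in range(4)}
        d2 = {
            (i, j): float(np.sum((X[i] - X[j]) ** 2))
            for i in range(4) for j in range(i + 1, 4)
        }
        heights = []
        next_id = 4
        while len(clusters) > 1:
            (i, j), dij2 = min(d2.items(), key=lambda kv: kv[1])
            heights.append(np.sqrt(dij2))
            ni, nj = len(clusters[i]), len(clusters[j])
            merged = clusters.pop(i) + clusters.pop(j)
            updates = {}
            for k in clusters:
                nk = len(clusters[k])
                dik2 = d2[tuple(sorted((i, k)))]
                djk2 = d2[tuple(sorted((j, k)))]
                updates[(k, next_id)] = (
                    (ni + nk) * dik2 + (nj + nk) * djk2 - nk * dij2
                ) / (ni + nj + nk)
            d2 = {
                key: v for key, v in d2.items()
                if i not in key and j not in key
            }
            d2.update(updates)
            clusters[next_id] = merged
            next_id += 1
        np.testing.assert_allclose(Z[:, 2], heights, rtol=1e-10)

    def test_fixture_metabolites_cocluster_by_subject(self, table3_records):
        """At the 5-cluster cut, most subjects' samples stay together."""
        X = np.array([[r.lactic_pct, r.acetic_pct, r.succinic_pct]
                      for r in table3_records])
        Z = ms.hierarchical_cluster(X)
        flat = fcluster(Z, t=5, criterion="maxclust")
        subjects = [r.subject_id for r in table3_records]
        together = sum(
            len({flat[i] for i, s in enumerate(subjects) if s == subj}) == 1
            for subj in set(subjects)
        )
        assert together >= 6

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            ms.hierarchical_cluster(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestNewickExport:
    def test_linkage_to_newick_parses_with_skbio(self):
        import skbio

        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        Z = ms.hierarchical_cluster(X)
        nwk = ms.linkage_to_newick(Z, ["a", "b", "c", "d"])
        tree = skbio.TreeNode.read([nwk])
        assert {t.name for t in tree.tips()} == {"a", "b", "c", "d"}
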