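import math

import numpy as np
import pandas as pd
import pytest

from est454.diffexpr import (
    CountMatrix,
    DECall,
    classify_de,
    cross_tissue_categories,
    null_threshold,
    r_statistic,
    r_statistics,
)

from .conftest import r_direct


def _cm(counts: dict, totals: dict) -> CountMatrix:
    df = pd.DataFrame(counts)
    return CountMatrix(df, pd.Series(totals)[df.columns])


class TestRStatistic:
    def test_equal_proportions_give_zero(self):
        assert r_statistic([5, 5], [100, 100]) == 0.0
        assert r_statistic([3, 6, 9], [100, 200, 300]) == 0.0

    def test_worked_two_library_value(self):
        assert r_statistic([10, 0], [100, 100]) == pytest.approx(
            10 * math.log(2), abs=1e-12
        )

    def test_worked_skewed_value(self):
        expected = 30 * math.log(1.5) + 10 * math.log(0.5)
        assert r_statistic([30, 10], [1000, 1000]) == pytest.approx(
            expected, abs=1e-12
        )

    def test_all_zero_cluster_rejected(self):
        with pytest.raises(ValueError):
            r_statistic([0, 0], [100, 100])

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            r_statistic([101, 0], [100, 100])

    def test_matches_direct_formula_on_random_vectors(self, rng):
        for _ in range(500):
            m = int(rng.choice([2, 4]))
            N = rng.integers(50, 5000, size=m)
            x = np.minimum(rng.integers(0, 50, size=m), N)
            if x.sum() == 0:
                x[0] = 1
            assert r_statistic(x, N) == pytest.approx(
                max(r_direct(x, N), 0.0), abs=1e-10
            )

    def test_permutation_invariance(self, rng):
        x, N = [7, 1, 19, 3], [500, 700, 900, 400]
        base = r_statistic(x, N)
        for _ in range(5):
            perm = rng.permutation(4)
            assert r_statistic(np.array(x)[perm], np.array(N)[perm]) == (
                pytest.approx(base, abs=1e-12)
            )

    def test_homogeneity_in_counts(self):
        assert r_statistic([20, 6], [2000, 2000]) == pytest.approx(
            2 * r_statistic([10, 3], [1000, 1000]), abs=1e-12
        )

    def test_vectorised_agrees_with_scalar(self, rng):
        N = np.array([3000, 2500, 4000, 3500])
        X = rng.integers(0, 60, size=(200, 4))
        X[X.sum(axis=1) == 0, 0] = 1
        vec = r_statistics(X, N)
        for j in range(200):
            assert vec[j] == pytest.approx(r_statistic(X[j], N), abs=1e-10)


class TestNullThreshold:
    def test_proportional_counts_give_inf_and_zero_significant(self):
        cm = _cm({"t": [5] * 20, "u": [5] * 20}, {"t": 1000, "u": 1000})
        cutoff = null_threshold(cm, fdr=0.05, n_perm=200, seed=1)
        assert cutoff == math.inf
        calls = classify_de(cm, cutoff, "t", "u")
        assert not any(c.significant for c in calls)

    def test_monotone_in_fdr(self, rng):
        t = rng.integers(0, 60, size=150)
        u = rng.integers(0, 60, size=150)
        keep = (t + u) > 0
        cm = _cm({"t": t[keep], "u": u[keep]}, {"t": 5000, "u": 5000})
        cuts = [null_threshold(cm, fdr=f, n_perm=300, seed=7)
                for f in (0.01, 0.05, 0.1)]
        assert cuts[0] >= cuts[1] >= cuts[2]

    def test_deterministic_for_fixed_seed(self, rng):
        t = rng.integers(0, 40, size=100) + 1
        cm = _cm({"t": t, "u": t[::-1]}, {"t": 3000, "u": 3000})
        assert null_threshold(cm, 0.05, 300, seed=3) == null_threshold(
            cm, 0.05, 300, seed=3
        )

    def test_planted_skew_detected_across_seeds(self):
        """10 strongly skewed clusters among 200 balanced ones at depth
        5,000 exceed the fdr=0.05 cutoff in >= 95% of 20 seeds."""
        hits = 0
        total = 0
        for seed in range(1, 21):
            rng = np.random.default_rng(seed)
            tot = rng.poisson(30, size=200) + 2
            t = rng.binomial(tot, 0.5)
            counts = {"t": list(t) + [40] * 10, "u": list(tot - t) + [5] * 10}
            cm = _cm(counts, {"t": 5000, "u": 5000})
            cutoff = null_threshold(cm, fdr=0.05, n_perm=500, seed=seed)
            R = r_statistics(cm.counts.to_numpy(int),
                             cm.totals.to_numpy(float))
            hits += int((R[-10:] >= cutoff).sum())
            total += 10
        assert hits / total >= 0.95


class TestClassifyDE:
    def test_one_sided_count_called_up(self):
        cm = _cm({"t": [10], "u": [0]}, {"t": 100, "u": 100})
        (call,) = classify_de(cm, cutoff=3.0, treated="t", untreated="u")
        assert call.significant and call.direction == "up"

    def test_balanced_counts_not_significant(self):
        cm = _cm({"t": [5], "u": [5]}, {"t": 100, "u": 100})
        (call,) = classify_de(cm, cutoff=0.5, treated="t", untreated="u")
        assert not call.significant and call.direction == "ns"
        assert call.raw_direction == "tie"

    def test_swapping_labels_flips_direction(self):
        cm = _cm({"t": [30], "u": [5]}, {"t": 1000, "u": 1000})
        (up,) = classify_de(cm, 2.0, "t", "u")
        (down,) = classify_de(cm, 2.0, "u", "t")
        assert up.direction == "up" and down.direction == "down"

    def test_missing_label_rejected(self):
        cm = _cm({"t": [5], "u": [5]}, {"t": 100, "u": 100})
        with pytest.raises(ValueError, match="nope"):
            classify_de(cm, 1.0, "nope", "u")

    def test_min_total_excludes_tiny_clusters(self):
        cm = _cm({"t": [1, 10], "u": [0, 0]}, {"t": 100, "u": 100})
        calls = classify_de(cm, 1.0, "t", "u", min_total=2)
        assert [c.cluster_id for c in calls] == [1]


class TestCrossTissueCategories:
    @staticmethod
    def _call(cid, sig, direction, total, raw=None):
        return DECall(cluster_id=cid, R=5.0 if sig else 0.5, significant=sig,
                      direction=direction if sig else "ns", total_reads=total,
                      raw_direction=raw or (direction if direction != "ns"
                                            else "tie"))

    def test_up_in_both_tissues(self):
        t = cross_tissue_categories(
            [self._call(1, True, "up", 20)], [self._call(1, True, "up", 30)]
        )
        assert t.counts["up_both"] == 1 and t.total == 1

    def test_leaf_specific_up(self):
        t = cross_tissue_categories(
            [self._call(1, False, "ns", 0)], [self._call(1, True, "up", 30)]
        )
        assert t.counts["leaf_only_up"] == 1 and t.total == 1

    def test_opposite_directions(self):
        t = cross_tissue_categories(
            [self._call(1, True, "down", 20)], [self._call(1, True, "up", 30)]
        )
        assert t.counts["up_leaf_down_root"] == 1

    def test_non_significant_side_uses_raw_direction(self):
        t = cross_tissue_categories(
            [self._call(1, True, "down", 20)],
            [self._call(1, False, "ns", 15, raw="down")],
        )
        assert t.counts["down_both"] == 1

    def test_duplicate_cluster_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cross_tissue_categories(
                [self._call(1, True, "up", 5), self._call(1, True, "up", 5)], []
            )

    def test_conservation_on_random_call_sets(self, rng):
        n = 60
        root, leaf = [], []
        n_sig_any = 0
        for cid in range(n):
            rsig, lsig = bool(rng.random() < 0.3), bool(rng.random() < 0.3)
            rtot = int(rng.integers(0, 20))
            ltot = int(rng.integers(0, 20))
            if rtot == 0:
                rsig = False
            if ltot == 0:
                lsig = False
            rdir = str(rng.choice(["up", "down"]))
            ldir = str(rng.choice(["up", "down"]))
            if rtot > 0:
                root.append(self._call(cid, rsig, rdir if rsig else "ns",
                                       rtot, raw=rdir))
            if ltot > 0:
                leaf.append(self._call(cid, lsig, ldir if lsig else "ns",
                                       ltot, raw=ldir))
            if rsig or lsig:
                n_sig_any += 1
        t = cross_tissue_categories(root, leaf)
        assert t.total == n_sig_any
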