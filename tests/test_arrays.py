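"""Array statistics: normalization, EB moderated t, FDR, DE calls, Venn, clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import polygamma
from scipy.stats import t as t_dist

from seedage.errors import (
    DegenerateArrayError,
    DegenerateScaleError,
    InvalidInputError,
    InvalidParameterError,
)
from seedage.arrays import (
    EBHyperparameters,
    adjust_fdr,
    call_de,
    cluster_profiles,
    estimate_eb_hyperparameters,
    loess_smooth,
    moderated_t,
    normalize_within_array,
    scale_between_arrays,
    venn_partition,
)

# --------------------------------------------------------------------------
# independent oracles


def brute_force_loess(x, y, span):
    """Pointwise tricube local-linear regression via explicit normal equations."""
    n = len(x)
    k = max(2, math.ceil(span * n))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        dmax = np.sort(d)[k - 1]
        w = np.clip(1 - (d / dmax) ** 3, 0, None) ** 3 if dmax > 0 else (d <= 0).astype(float)
        W = np.diag(w)
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.pinv(X.T @ W @ X) @ (X.T @ W @ y)
        out[i] = beta[0] + beta[1] * x[i]
    return out


def brute_force_bh(p):
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        val = min(p[idx] * n / rank, prev)
        q[idx] = val
        prev = val
    return q


def brute_force_complete_linkage(X, K):
    """Naive agglomeration: merge the closest pair of clusters under
    complete (maximum) Euclidean linkage until K clusters remain."""
    clusters = [[i] for i in range(len(X))]
    while len(clusters) > K:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(
                np.linalg.norm(X[i] - X[j])
                for i in clusters[a]
                for j in clusters[b]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(X), dtype=int)
    for cid, members in enumerate(clusters):
        for i in members:
            labels[i] = cid
    return labels


def same_partition(labels_a, labels_b):
    from collections import defaultdict

    def groups(labels):
        g = defaultdict(frozenset)
        d = defaultdict(list)
        for i, l in enumerate(labels):
            d[l].append(i)
        return {frozenset(v) for v in d.values()}

    return groups(labels_a) == groups(labels_b)


# --------------------------------------------------------------------------


class TestLoessNormalization:
    def test_matches_brute_force_oracle(self, rng):
        x = rng.uniform(6, 16, 200)
        y = 0.3 * np.sin(x) + rng.normal(0, 0.1, 200)
        ours = loess_smooth(x, y, span=0.3)
        oracle = brute_force_loess(x, y, 0.3)
        assert np.max(np.abs(ours - oracle)) < 1e-8

    def test_injected_block_bias_removed(self, rng):
        n = 1200
        A = rng.uniform(6, 16, n)
        blocks = np.arange(n) % 4
        M = 0.5 * np.sin(2 * np.pi * (A - 6) / 10)
        df = pd.DataFrame({"M": M, "A": A, "print_tip_block": blocks})
        out = normalize_within_array(df)
        med = out.groupby("print_tip_block")["M"].apply(lambda s: np.median(np.abs(s)))
        assert (med < 0.05).all()

    def test_bias_free_array_nearly_unchanged(self, rng):
        # the smoother's own variance shrinks with block size, so a large null
        # block shows the no-op limit
        n = 2000
        A = rng.uniform(6, 16, n)
        M = rng.normal(0, 0.3, n)
        df = pd.DataFrame({"M": M, "A": A, "print_tip_block": np.zeros(n, dtype=int)})
        out = normalize_within_array(df)
        assert np.median(np.abs(out["M"].to_numpy() - M)) < 0.02

    def test_small_block_falls_back_to_median_centering(self, rng):
        df = pd.DataFrame(
            {
                "M": np.r_[rng.normal(1.0, 0.1, 10), rng.normal(0, 0.1, 100)],
                "A": rng.uniform(6, 16, 110),
                "print_tip_block": np.r_[np.zeros(10), np.ones(100)],
            }
        )
        out = normalize_within_array(df)
        small = out[out["print_tip_block"] == 0]["M"]
        assert np.median(small) == pytest.approx(0.0, abs=1e-12)

    def test_single_small_block_degenerate(self, rng):
        df = pd.DataFrame({"M": rng.normal(0, 1, 10), "A": rng.uniform(6, 16, 10),
                           "print_tip_block": np.zeros(10)})
        with pytest.raises(DegenerateArrayError):
            normalize_within_array(df)


class TestBetweenArrayScaling:
    def test_geometric_mean_target(self, rng):
        a = rng.normal(0, 0.6, 501)
        b = rng.normal(0, 1.2, 501)
        scaled = scale_between_arrays({"a": a, "b": b})
        mad_a = np.median(np.abs(scaled["a"]))
        mad_b = np.median(np.abs(scaled["b"]))
        assert mad_a == pytest.approx(mad_b, rel=1e-9)
        target = math.sqrt(np.median(np.abs(a)) * np.median(np.abs(b)))
        assert mad_a == pytest.approx(target, rel=1e-9)

    def test_worked_example_mads(self):
        # arrays with median |M| exactly 0.4 and 0.8 -> both rescaled to 0.56569
        a = np.array([0.4, -0.4, 0.4, -0.4, 0.2])
        b = 2 * a
        scaled = scale_between_arrays({"a": a, "b": b})
        assert np.median(np.abs(scaled["a"])) == pytest.approx(0.56569, abs=1e-5)
        assert np.median(np.abs(scaled["b"])) == pytest.approx(0.56569, abs=1e-5)

    def test_identical_arrays_unchanged(self, rng):
        a = rng.normal(0, 1, 101)
        scaled = scale_between_arrays({"x": a, "y": a.copy()})
        assert np.allclose(scaled["x"], a)
        assert np.allclose(scaled["y"], a)

    def test_median_sign_preserved(self, rng):
        a = rng.normal(0.5, 1, 101)
        b = rng.normal(-0.5, 2, 101)
        scaled = scale_between_arrays({"a": a, "b": b})
        assert np.sign(np.median(scaled["a"])) == np.sign(np.median(a))
        assert np.sign(np.median(scaled["b"])) == np.sign(np.median(b))

    def test_zero_mad_rejected(self):
        with pytest.raises(DegenerateScaleError):
            scale_between_arrays({"a": np.zeros(10), "b": np.ones(10)})


class TestEBHyperparameters:
    def test_recovery_from_simulated_variances(self):
        rng = np.random.default_rng(42)
        sigma2 = 0.09 * 4 / rng.chisquare(4, size=5000)
        s2 = sigma2 * rng.chisquare(2, size=5000) / 2
        h = estimate_eb_hyperparameters(s2, d_g=2)
        assert 3.0 <= h.d0 <= 5.0
        assert 0.08 <= h.s0_sq <= 0.10

    def test_identical_variances_give_infinite_d0(self):
        h = estimate_eb_hyperparameters(np.full(100, 0.05), d_g=2)
        assert math.isinf(h.d0)
        assert h.s0_sq == pytest.approx(0.05)

    def test_underdispersed_variances_hit_sentinel(self):
        rng = np.random.default_rng(0)
        # spread of log s2 far below the chi^2_2 sampling floor
        s2 = 0.09 * np.exp(rng.normal(0, 0.05, 1000))
        h = estimate_eb_hyperparameters(s2, d_g=2)
        assert math.isinf(h.d0)


class TestModeratedT:
    def test_hand_computed_fixture(self):
        h = EBHyperparameters(d0=4.0, s0_sq=0.09)
        r = moderated_t(np.array([1.0, 1.2, 0.8]), h)
        assert r["s2"] == pytest.approx(0.04, abs=1e-12)
        assert r["s2_post"] == pytest.approx(0.07333, abs=1e-4)
        assert r["t_mod"] == pytest.approx(6.396, abs=1e-3)
        assert r["df_total"] == 6

    def test_infinite_d0_pins_posterior_variance(self, rng):
        h = EBHyperparameters(d0=float("inf"), s0_sq=0.09)
        for _ in range(5):
            m = rng.normal(0, 1, 4)
            assert moderated_t(m, h)["s2_post"] == 0.09

    def test_d0_limits_recover_t_and_z(self, rng):
        m = rng.normal(0.5, 0.3, 5)
        n = m.size
        s2 = np.var(m, ddof=1)
        t_ord = np.mean(m) / math.sqrt(s2 / n)
        # d0 -> 0: ordinary t
        r_small = moderated_t(m, EBHyperparameters(d0=1e-6, s0_sq=0.09))
        assert r_small["t_mod"] == pytest.approx(t_ord, rel=1e-4)
        p_ord = 2 * t_dist.sf(abs(t_ord), n - 1)
        assert r_small["p_value"] == pytest.approx(p_ord, rel=1e-3)
        # d0 -> infinity: fixed-variance z
        r_big = moderated_t(m, EBHyperparameters(d0=1e6, s0_sq=0.09))
        z = np.mean(m) / math.sqrt(0.09 / n)
        assert r_big["t_mod"] == pytest.approx(z, rel=1e-4)

    def test_posterior_between_prior_and_sample(self, rng):
        h = EBHyperparameters(d0=4.0, s0_sq=0.09)
        for _ in range(20):
            m = rng.normal(0, 0.5, 3)
            r = moderated_t(m, h)
            lo, hi = sorted((r["s2"], h.s0_sq))
            assert lo - 1e-12 <= r["s2_post"] <= hi + 1e-12


class TestFDR:
    def test_hand_oracle(self):
        np.testing.assert_allclose(adjust_fdr(np.array([0.01, 0.02, 0.04])), [0.03, 0.03, 0.04])

    def test_all_ones(self):
        assert (adjust_fdr(np.ones(7)) == 1.0).all()

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            np.testing.assert_allclose(adjust_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidInputError):
            adjust_fdr(np.array([0.5, 1.5]))


class TestCallDE:
    def fixture_table(self):
        # 10 probes: exactly probes p0, p2, p5, p9 satisfy n>=2, q<0.05, |M|>=1
        rows = [
            ("p0", 3, 0.01, 1.5),   # called up
            ("p1", 1, 1e-9, 3.0),   # n too small
            ("p2", 2, 0.04, -1.0),  # called down
            ("p3", 3, 0.04, 0.8),   # fold too small
            ("p4", 3, 0.20, 2.0),   # q too large
            ("p5", 3, 0.001, 1.0),  # called up (boundary fold)
            ("p6", 2, 0.06, -2.0),  # q boundary fail
            ("p7", 1, 0.01, -1.5),  # n too small
            ("p8", 3, 0.049, 0.0),  # no fold
            ("p9", 2, 0.02, -2.5),  # called down
        ]
        return pd.DataFrame(
            [
                {"probe_id": p, "time_days": 8.0, "n_reps_present": n, "q_value": q, "mean_M": m}
                for p, n, q, m in rows
            ]
        )

    def test_enumerated_fixture(self):
        calls, counts = call_de(self.fixture_table())
        called = set(calls[calls["direction"] != "none"]["probe_id"])
        assert called == {"p0", "p2", "p5", "p9"}
        assert counts.iloc[0]["up"] == 2 and counts.iloc[0]["down"] == 2

    def test_single_replicate_probe_never_called(self):
        calls, _ = call_de(self.fixture_table())
        p1 = calls[calls["probe_id"] == "p1"].iloc[0]
        assert not p1["passed_filter"] and p1["direction"] == "none"

    def test_fold_threshold_separates_filter_from_direction(self):
        calls, _ = call_de(self.fixture_table())
        p3 = calls[calls["probe_id"] == "p3"].iloc[0]
        assert p3["passed_filter"] and p3["direction"] == "none"


class TestVennPartition:
    def test_worked_example(self):
        v = venn_partition({"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3, 5}})
        assert v[("A",)] == 1 and v[("B",)] == 1 and v[("C",)] == 1
        assert v[("A", "B")] == 1 and v[("A", "C")] == 0 and v[("B", "C")] == 0
        assert v[("A", "B", "C")] == 1
        assert v["union"] == 5

    def test_identical_sets_all_central(self):
        v = venn_partition({"a": {1, 2}, "b": {1, 2}, "c": {1, 2}})
        assert v[("a", "b", "c")] == 2
        assert sum(c for k, c in v.items() if k != "union") == v["union"] == 2

    def test_disjoint_sets(self):
        v = venn_partition({"a": {1}, "b": {2}, "c": {3}})
        assert v[("a",)] == v[("b",)] == v[("c",)] == 1
        assert v[("a", "b", "c")] == 0

    def test_regions_sum_to_union(self, rng):
        for _ in range(20):
            sets = {i: set(rng.integers(0, 30, rng.integers(0, 15))) for i in range(3)}
            v = venn_partition(sets)
            assert sum(c for k, c in v.items() if k != "union") == v["union"]


class TestClustering:
    def test_two_separated_groups(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (3, 3)), rng.normal(3, 0.05, (3, 3))])
        prof = pd.DataFrame(X, index=[f"p{i}" for i in range(6)])
        model = cluster_profiles(prof, K=2)
        labels = [model.assignments[f"p{i}"] for i in range(6)]
        oracle = brute_force_complete_linkage(X, 2)
        assert same_partition(labels, oracle)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 12))
            K = int(rng.integers(1, n))
            X = rng.normal(0, 1, (n, 3))
            prof = pd.DataFrame(X, index=[f"p{i}" for i in range(n)])
            model = cluster_profiles(prof, K=K)
            labels = [model.assignments[f"p{i}"] for i in range(n)]
            oracle = brute_force_complete_linkage(X, K)
            assert same_partition(labels, oracle)

    def test_identical_profiles_collapse_to_one_cluster(self):
        prof = pd.DataFrame(np.zeros((5, 3)), index=list("abcde"))
        model = cluster_profiles(prof, K=1)
        assert set(model.assignments.values()) == {1}
        assert np.allclose(model.linkage_heights, 0.0)

    def test_k_equals_n_gives_singletons(self, rng):
        prof = pd.DataFrame(rng.normal(0, 1, (6, 3)), index=[f"p{i}" for i in range(6)])
        model = cluster_profiles(prof, K=6)
        assert sorted(model.assignments.values()) == [1, 2, 3, 4, 5, 6]

    def test_k_too_large_rejected(self, rng):
        prof = pd.DataFrame(rng.normal(0, 1, (4, 3)))
        with pytest.raises(InvalidParameterError):
            cluster_profiles(prof, K=5)

    def test_missing_profiles_excluded_and_reported(self, rng):
        X = rng.normal(0, 1, (5, 3))
        prof = pd.DataFrame(X, index=[f"p{i}" for i in range(5)])
        prof.iloc[2, 1] = np.nan
        model = cluster_profiles(prof, K=2)
        assert model.excluded == ["p2"]
        assert "p2" not in model.assignments
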