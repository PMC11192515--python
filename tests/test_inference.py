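"""Inference layer: adjacency, paired t, cluster permutation engines
(checked against brute force, hand enumeration, and the mne ecosystem
implementation), Hedges g, JZS Bayes factors, evidence tabulation."""

import itertools

import numpy as np
import pytest
import scipy.sparse
import scipy.stats

import fpvstag as f


# ---------------------------------------------------------------------------
# adjacency

class TestBuildAdjacency:
    def test_two_nodes_within_threshold(self):
        coords = np.array([[0, 0, 0.1], [0.004, 0, 0.1]])
        g = f.build_adjacency(coords, 0.006)
        assert len(g.edges) == 1

    def test_regular_grid_coarser_than_threshold(self):
        xs = np.arange(5) * 0.01
        coords = np.array([[x, y, 0] for x in xs for y in xs])
        g = f.build_adjacency(coords, 0.006)
        assert len(g.edges) == 0

    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(-0.1, 0.1, (50, 3))
        g = f.build_adjacency(coords, 0.05)
        brute = set()
        for i in range(50):
            for j in range(i + 1, 50):
                if np.linalg.norm(coords[i] - coords[j]) <= 0.05:
                    brute.add(frozenset((f"v{i}", f"v{j}")))
        assert set(g.edges) == brute

    def test_layout_kinds_kept_separate(self, tiny_layout):
        gm = f.build_adjacency(tiny_layout, 0.08, kind="mag")
        gp = f.build_adjacency(tiny_layout, 0.08, kind="grad_pairs")
        assert len(gm) == 8 and len(gp) == 8
        assert all(n.startswith("MAG") for n in gm.nodes)
        assert all(n.startswith("P") for n in gp.nodes)

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError, match="max_dist"):
            f.build_adjacency(np.zeros((2, 3)), 0.0)
        with pytest.raises(ValueError, match="finite"):
            f.build_adjacency(np.array([[np.nan, 0, 0]]), 0.01)


# ---------------------------------------------------------------------------
# paired t

class TestPairedTMap:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(21)
        exp = rng.normal(0.3, 1.0, (21, 6))
        base = rng.normal(0.0, 1.0, (21, 6))
        t, df, valid = f.paired_t_map(exp, base)
        assert df == 20 and valid.all()
        d = exp - base
        expect = d.mean(0) / (d.std(0, ddof=1) / np.sqrt(21))
        np.testing.assert_allclose(t, expect, rtol=1e-12)
        # and scipy's paired t as a second, independent route
        np.testing.assert_allclose(
            t, scipy.stats.ttest_rel(exp, base, axis=0).statistic, rtol=1e-10)

    def test_zero_mean_differences_give_zero_t(self):
        d = np.array([[1.0], [-1.0], [2.0], [-2.0]])
        t, _, _ = f.paired_t_map(d, np.zeros_like(d))
        assert t[0] == pytest.approx(0.0, abs=1e-15)

    def test_zero_variance_node_flagged(self):
        exp = np.ones((5, 2))
        base = np.zeros((5, 2))
        base[:, 1] = np.arange(5)
        with pytest.warns(UserWarning, match="zero variance"):
            t, _, valid = f.paired_t_map(exp, base)
        assert not valid[0] and valid[1]
        assert np.isnan(t[0])


# ---------------------------------------------------------------------------
# cluster permutation engines

def line_graph(n: int) -> f.AdjacencyGraph:
    nodes = tuple(f"v{i}" for i in range(n))
    edges = frozenset(frozenset((nodes[i], nodes[i + 1])) for i in range(n - 1))
    return f.AdjacencyGraph(nodes=nodes, edges=edges)


class TestClusterPermutation:
    def test_identical_conditions_yield_no_clusters(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 6))
        g = line_graph(6)
        with pytest.warns(UserWarning, match="zero variance"):
            res = f.cluster_permutation_test(x, x.copy(), g,
                                             f.ClusterConfig(n_permutations=100))
        assert res.clusters == ()

    @pytest.mark.parametrize("seed", range(20))
    def test_large_effect_detected_at_p_floor(self, seed):
        """A 10-SD effect on a 5-node connected patch, n=12: the significant
        cluster covers the patch and p sits at the 1/(n_perm+1) floor, up
        to chance re-draws of the identity sign assignment (each adds one
        exceedance)."""
        rng = np.random.default_rng(1000 + seed)
        n, m = 12, 12
        g = line_graph(m)
        base = rng.normal(0, 1, (n, m))
        exp = base + rng.normal(0, 0.1, (n, m))
        patch = [3, 4, 5, 6, 7]
        exp[:, patch] += 10 * 0.1
        cfg = f.ClusterConfig(n_permutations=500, seed=seed)
        res = f.cluster_permutation_test(exp, base, g, cfg)
        assert res.method == "montecarlo"
        top = res.clusters[0]
        assert set(f"v{i}" for i in patch) <= set(top.members)
        assert 1 / 501 <= top.p <= 4 / 501

    def test_montecarlo_fallback_equals_exhaustive_n8(self):
        rng = np.random.default_rng(5)
        exp = rng.normal(0.8, 1, (8, 10))
        base = rng.normal(0, 1, (8, 10))
        g = line_graph(10)
        cfg = f.ClusterConfig(n_permutations=5000, seed=1)
        mc = f.cluster_permutation_test(exp, base, g, cfg)
        ex = f.exhaustive_signflip_test(exp, base, g, cfg)
        assert mc.method == "exhaustive"
        assert [(c.members, c.mass, c.p) for c in mc.clusters] == \
               [(c.members, c.mass, c.p) for c in ex.clusters]

    def test_exhaustive_matches_hand_enumeration_n3(self):
        """n=3 subjects, 2 connected nodes: p recomputed by explicitly
        enumerating all 8 sign assignments with scipy's one-sample t."""
        diff = np.array([[1.0, 0.8], [0.6, 1.2], [0.9, 0.3]])
        g = line_graph(2)
        cfg = f.ClusterConfig(cluster_forming_alpha=0.2)
        res = f.exhaustive_signflip_test(diff, np.zeros_like(diff), g, cfg)
        thr = scipy.stats.t.ppf(0.8, 2)
        null = []
        for signs in itertools.product([-1, 1], repeat=3):
            d = diff * np.array(signs)[:, None]
            t = scipy.stats.ttest_1samp(d, 0.0, axis=0).statistic
            supra = t > thr
            if supra.all():
                null.append(t.sum())       # both nodes form one cluster
            elif supra.any():
                null.append(t[supra].max())
            else:
                null.append(0.0)
        null = np.array(null)
        assert len(res.clusters) == 1
        obs = res.clusters[0].mass
        assert res.clusters[0].p == pytest.approx(np.mean(null >= obs - 1e-12))

    def test_exhaustive_p_bounded_below(self):
        rng = np.random.default_rng(3)
        exp = rng.normal(2, 1, (6, 4))
        res = f.exhaustive_signflip_test(exp, np.zeros_like(exp), line_graph(4),
                                         f.ClusterConfig())
        for c in res.clusters:
            assert c.p >= 1 / 2**6

    def test_exhaustive_refuses_large_n(self):
        x = np.random.default_rng(0).normal(size=(21, 3))
        with pytest.raises(ValueError, match="not enumerable"):
            f.exhaustive_signflip_test(x, np.zeros_like(x), line_graph(3),
                                       f.ClusterConfig())

    def test_observed_clusters_match_mne(self):
        """Cluster membership and mass agree with the ecosystem reference
        implementation on the same threshold and adjacency."""
        mne_stats = pytest.importorskip("mne.stats")
        rng = np.random.default_rng(7)
        n, m = 15, 20
        diff = rng.normal(0.4, 1, (n, m))
        g = line_graph(m)
        thr = scipy.stats.t.ppf(0.95, n - 1)
        adj = scipy.sparse.coo_matrix(
            ([1] * (2 * (m - 1)),
             ([i for i in range(m - 1)] + [i + 1 for i in range(m - 1)],
              [i + 1 for i in range(m - 1)] + [i for i in range(m - 1)])),
            shape=(m, m))
        t_obs, clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
            diff, threshold=thr, adjacency=adj, tail=1, n_permutations=50,
            seed=0, out_type="indices", verbose="error")
        mne_clusters = {
            frozenset(int(i) for i in c[0]): float(t_obs[c[0]].sum())
            for c in clusters}
        res = f.cluster_permutation_test(diff, np.zeros_like(diff), g,
                                         f.ClusterConfig(n_permutations=100))
        ours = {frozenset(int(mm[1:]) for mm in c.members): c.mass
                for c in res.clusters}
        assert set(ours) == set(mne_clusters)
        for k in ours:
            assert ours[k] == pytest.approx(mne_clusters[k], rel=1e-9)


# ---------------------------------------------------------------------------
# effect size

class TestHedgesG:
    def test_symmetric_differences(self):
        es = f.hedges_g([-2.0, -1.0, 1.0, 2.0])
        assert es.g == pytest.approx(0.0, abs=1e-15)
        assert es.ci_low < 0 < es.ci_high

    def test_scale_invariance(self):
        d = np.array([0.3, 0.5, 0.9, 1.4, 0.2, 0.7])
        a, b = f.hedges_g(d), f.hedges_g(5.0 * d)
        assert a.g == pytest.approx(b.g, rel=1e-12)
        assert a.ci_low == pytest.approx(b.ci_low, rel=1e-9)

    def test_formula_oracle(self):
        d = np.array([0.1, 0.4, -0.2, 0.9, 0.3, 0.6, -0.1, 0.5, 0.8, 0.2])
        es = f.hedges_g(d)
        j = 1 - 3 / (4 * 9 - 1)
        assert es.g == pytest.approx(d.mean() / d.std(ddof=1) * j, rel=1e-12)

    def test_noncentral_ci_covers_and_brackets(self):
        d = np.random.default_rng(2).normal(0.8, 1, 21)
        es = f.hedges_g(d)
        assert es.ci_low < es.g < es.ci_high
        # CI endpoints invert the noncentral t cdf at 2.5% / 97.5%
        t = d.mean() / (d.std(ddof=1) / np.sqrt(21))
        j = 1 - 3 / (4 * 20 - 1)
        for bound, prob in ((es.ci_low, 0.975), (es.ci_high, 0.025)):
            ncp = bound / j * np.sqrt(21)
            assert scipy.stats.nct.cdf(t, 20, ncp) == pytest.approx(prob, abs=1e-6)

    def test_bootstrap_ci_close_to_noncentral(self):
        d = np.random.default_rng(3).normal(0.8, 1, 40)
        a = f.hedges_g(d)
        b = f.hedges_g(d, ci="bootstrap", seed=0)
        assert a.g == b.g
        assert b.ci_low == pytest.approx(a.ci_low, abs=0.25)
        assert b.ci_high == pytest.approx(a.ci_high, abs=0.25)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            f.hedges_g([1.0, 1.0, 1.0])


# ---------------------------------------------------------------------------
# Bayes factors

def rouder_grid_bf10(t: float, n: int, r: float = 0.707,
                     n_grid: int = 200_001) -> float:
    """Independent dense-grid evaluation of the JZS Bayes factor via the
    g-mixture integral (log-spaced trapezoid over the prior on g)."""
    nu = n - 1
    u = np.linspace(-25, 25, n_grid)    # g = e^u
    g = np.exp(u)
    term = ((1 + n * g) ** -0.5
            * (1 + t**2 / ((1 + n * g) * nu)) ** (-(nu + 1) / 2)
            * r / np.sqrt(2 * np.pi) * g ** -1.5 * np.exp(-r**2 / (2 * g)))
    num = np.trapezoid(term * g, u)     # d(g) = g du
    den = (1 + t**2 / nu) ** (-(nu + 1) / 2)
    return num / den


class TestJZSBayesFactor:
    def test_null_data_favor_null(self):
        for n in (2, 5, 21, 100):
            assert f.jzs_bf10(0.0, n).bf10 < 1

    def test_monotone_in_abs_t(self):
        ts = np.linspace(0, 6, 13)
        bfs = [f.jzs_bf10(t, 21).bf10 for t in ts]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize("t, n", [(0.0, 5), (1.0, 10), (2.5, 21),
                                      (-2.5, 21), (4.0, 12), (6.0, 30)])
    def test_agrees_with_dense_grid_oracle(self, t, n):
        assert f.jzs_bf10(t, n).bf10 == pytest.approx(
            rouder_grid_bf10(t, n), rel=1e-6)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n in [(2.5, 21), (0.5, 10), (3.8, 15)]:
            expect = float(pingouin.bayesfactor_ttest(t, n, paired=True,
                                                      r=0.707))
            assert f.jzs_bf10(t, n).bf10 == pytest.approx(expect, rel=1e-6)

    def test_vanishing_prior_scale_gives_unit_bf(self):
        assert f.jzs_bf10(2.0, 21, r_scale=1e-6).bf10 == pytest.approx(
            1.0, abs=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            f.jzs_bf10(np.nan, 10)
        with pytest.raises(ValueError):
            f.jzs_bf10(1.0, 1)
        with pytest.raises(ValueError):
            f.jzs_bf10(1.0, 10, r_scale=0.0)


class TestEvidence:
    @pytest.mark.parametrize("bf, expect", [
        (0.2, "supports_null"), (1.0, "inconclusive"), (5.0, "supports_alternative"),
        (3.0, "inconclusive"), (1 / 3, "inconclusive")])
    def test_classification(self, bf, expect):
        assert f.classify_evidence(bf) == expect

    def test_reciprocal_symmetry(self):
        for bf in (3.5, 10.0, 100.0):
            assert f.classify_evidence(bf) == "supports_alternative"
            assert f.classify_evidence(1 / bf) == "supports_null"

    def test_tabulation_single_roi(self):
        bf = {f"v{i}": 0.1 for i in range(10)}
        roi = {f"v{i}": "fusiform" for i in range(10)}
        tab = f.tabulate_evidence(bf, roi)
        row = tab.iloc[0]
        assert (row.n_vertices, row.n_bf_below_third, row.pct_bf_below_third,
                row.n_bf_above_three) == (10, 10, 100, 0)

    def test_tabulation_matches_brute_tally(self):
        rng = np.random.default_rng(13)
        nodes = [f"v{i}" for i in range(300)]
        bf = {v: float(10 ** rng.uniform(-2, 2)) for v in nodes}
        roi = {v: ["A", "B", "C"][i % 3] for i, v in enumerate(nodes)}
        tab = f.tabulate_evidence(bf, roi).set_index("roi")
        for r in "ABC":
            vals = [bf[v] for v in nodes if roi[v] == r]
            assert tab.loc[r, "n_vertices"] == len(vals)
            assert tab.loc[r, "n_bf_below_third"] == sum(v < 1 / 3 for v in vals)
            assert tab.loc[r, "n_bf_above_three"] == sum(v > 3 for v in vals)
            assert tab.loc[r, "pct_bf_above_three"] == int(
                round(100 * sum(v > 3 for v in vals) / len(vals)))

    def test_missing_labels_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            f.tabulate_evidence({"a": 1.0}, {"b": "roi"})
        with pytest.raises(ValueError, match="Bayes"):
            f.tabulate_evidence({"a": 1.0}, {"a": "r", "b": "r"})


# ---------------------------------------------------------------------------
# model / results objects

class TestContrastModel:
    def make_fit(self, effect=1.0, n=10, seed=0):
        rng = np.random.default_rng(seed)
        g = line_graph(6)
        base = rng.normal(0, 1, (n, 6))
        exp = base + rng.normal(0, 0.3, (n, 6))
        exp[:, 2:5] += effect
        model = f.FPVSContrast(exp, base, g,
                               cluster_config=f.ClusterConfig(
                                   n_permutations=200, seed=1),
                               name="demo")
        return model, model.fit()

    def test_fit_reports_clusters_effects_and_summary(self):
        model, res = self.make_fit(effect=2.0)
        assert len(res.clusters) == len(res.effect_sizes)
        assert res.significant()
        text = res.summary()
        assert "demo" in text and "cluster 0" in text
        frame = res.cluster_frame()
        assert {"mass", "p", "g"} <= set(frame.columns)

    def test_bayes_map_covers_nodes(self):
        _, res = self.make_fit()
        bf = res.bayes_map()
        assert set(bf) == set(res.cluster_result.nodes)
        assert all(v > 0 for v in bf.values())

    def test_from_response_maps_pairs_subjects(self):
        rng = np.random.default_rng(4)
        g = line_graph(3)
        maps = []
        for s in range(5):
            for cond in ("exp", "base"):
                maps.append(f.ResponseMap(
                    values=rng.normal(size=3), f_target=3.0,
                    subject_id=f"sub{s}", condition=cond,
                    node_id=g.nodes))
        model = f.FPVSContrast.from_response_maps(maps, "exp", "base", g)
        assert model.n_subjects == 5
        assert model.name == "exp vs base"


# ---------------------------------------------------------------------------
# calibration properties (share the session H0 batch)

def test_h0_cluster_p_values_super_uniform(h0_batch):
    """Under the null, min cluster p values are super-uniform: the empirical
    CDF does not exceed the uniform CDF beyond one-sided KS noise at 0.01."""
    _, min_p = h0_batch
    n = len(min_p)
    p_sorted = np.sort(min_p)
    ecdf_hi = np.arange(1, n + 1) / n
    d_plus = np.max(ecdf_hi - p_sorted)
    crit = np.sqrt(np.log(1 / 0.01) / (2 * n))
    assert d_plus < crit


def test_power_monotone_in_injected_amplitude(tiny_layout, h0_batch):
    """Detection rate is non-decreasing across oddball amplitudes
    {0, 0.5, 1, 2} x noise scale."""
    from conftest import run_h0_batch
    rates = [h0_batch[0].mean()]
    for amp in (0.5, 1.0, 2.0):
        sig, _ = run_h0_batch(100, tiny_layout, seed=777, odd_amp=amp)
        rates.append(sig.mean())
    assert all(r2 >= r1 for r1, r2 in zip(rates, rates[1:])), rates
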