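"""Statistical assessment of frequency-tagged discrimination responses.

The central question is whether the oddball response in an experimental
(alternating-category) condition exceeds that of its single-category
baseline across subjects. The tools here are:

* a paired cluster-based permutation test on a sensor/vertex adjacency
  graph, with per-subject sign flips of difference maps as the
  exchangeability scheme and maximum cluster mass (sum of member t values)
  as the family-wise statistic;
* an exhaustive sign-flip enumeration of the same test, usable both as a
  small-n exact test and as an oracle for the Monte Carlo engine;
* Hedges g (bias-corrected standardized mean difference) with a
  noncentral-t or bootstrap confidence interval;
* the JZS (Jeffreys-Zellner-Siow) Bayes factor for a one-sample/paired t
  design — Cauchy prior of scale r on the standardized effect — with the
  conventional moderate-evidence classification (BF10 < 1/3 supports the
  null, BF10 > 3 the alternative) and per-region tabulation.

`FPVSContrast` wraps these in a model object built from per-subject
response maps; `fit()` returns a `ContrastResults` with the clusters,
effect sizes, Bayes factor map and a text `summary()`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.optimize
import scipy.stats

from .layout import SensorLayout
from .spectral import ResponseMap

__all__ = [
    "AdjacencyGraph", "ClusterConfig", "Cluster", "ClusterResult",
    "EffectSize", "BayesResult", "build_adjacency", "paired_t_map",
    "cluster_permutation_test", "exhaustive_signflip_test", "hedges_g",
    "jzs_bf10", "classify_evidence", "tabulate_evidence",
    "FPVSContrast", "ContrastResults",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# adjacency

@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected graph over sensor/vertex ids."""

    nodes: tuple[str, ...]
    edges: frozenset[frozenset]        # frozenset of 2-node frozensets
    max_dist: float | None = None

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        if len(nodeset) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"edge {set(e)} is not a 2-node pair")
            if not e <= nodeset:
                raise ValueError(f"edge {set(e)} references unknown nodes")

    def __len__(self) -> int:
        return len(self.nodes)

    def neighbor_lists(self) -> list[list[int]]:
        """Adjacency as index lists aligned with ``nodes`` order."""
        index = {n: i for i, n in enumerate(self.nodes)}
        out: list[list[int]] = [[] for _ in self.nodes]
        for e in self.edges:
            a, b = (index[n] for n in e)
            out[a].append(b)
            out[b].append(a)
        return out


def build_adjacency(source, max_dist: float, kind: str | None = None,
                    node_id: tuple[str, ...] | None = None) -> AdjacencyGraph:
    """Neighborhood graph: edge iff Euclidean distance <= max_dist (meters).

    ``source`` is a :class:`SensorLayout` or an (n, 3) coordinate array.
    For a layout, ``kind`` restricts to one sensor kind (``"mag"`` or
    ``"grad"``) — adjacency is only meaningful within a kind — or
    ``"grad_pairs"`` builds one node per planar pair at the site position.
    """
    if isinstance(source, SensorLayout):
        if kind == "grad_pairs":
            pairs = source.pairs()
            ids = tuple(sorted(pairs))
            coords = np.array([source.positions[pairs[p][0]] for p in ids])
        elif kind in ("mag", "grad"):
            sel = source.select(kind)
            ids = tuple(source.sensor_id[i] for i in sel)
            coords = source.positions[sel]
        elif kind is None:
            raise ValueError("building from a layout requires `kind`")
        else:
            raise ValueError(f"unknown kind {kind!r}")
    else:
        coords = np.asarray(source, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3)")
        ids = node_id or tuple(f"v{i}" for i in range(len(coords)))
    if len(ids) == 0:
        raise ValueError("empty node set")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    ii, jj = np.where(np.triu(d <= max_dist, k=1))
    edges = frozenset(frozenset((ids[i], ids[j])) for i, j in zip(ii, jj))
    return AdjacencyGraph(nodes=ids, edges=edges, max_dist=max_dist)


# ---------------------------------------------------------------------------
# paired t and clusters

def _as_matrix(maps) -> tuple[np.ndarray, tuple[str, ...] | None]:
    """Stack per-subject ResponseMaps (or a 2-D array) to (subjects, nodes)."""
    if isinstance(maps, np.ndarray):
        return np.atleast_2d(np.asarray(maps, float)), None
    rows = [np.asarray(m.values, float) for m in maps]
    ids = maps[0].node_id
    if any(r.size != rows[0].size for r in rows):
        raise ValueError("response maps disagree on node count")
    return np.vstack(rows), ids


def paired_t_map(resp_exp, resp_base) -> tuple[np.ndarray, int, np.ndarray]:
    """Node-wise paired t statistic.

    Returns ``(t, df, valid)``: ``t`` holds NaN at zero-variance nodes,
    which are flagged invalid (with a warning) and excluded downstream.
    """
    exp, _ = _as_matrix(resp_exp)
    base, _ = _as_matrix(resp_base)
    if exp.shape != base.shape:
        raise ValueError("experimental and baseline shapes differ")
    n = exp.shape[0]
    if n < 2:
        raise ValueError("paired t needs >= 2 subjects")
    diff = exp - base
    sd = diff.std(axis=0, ddof=1)
    valid = sd > 0
    t = np.full(diff.shape[1], np.nan)
    t[valid] = diff.mean(axis=0)[valid] / (sd[valid] / np.sqrt(n))
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} node(s) with zero variance excluded from t map",
            UserWarning, stacklevel=2)
    return t, n - 1, valid


@dataclass(frozen=True)
class ClusterConfig:
    """Cluster permutation test parameters (paired, one-tailed greater)."""

    n_permutations: int = 5000
    alpha: float = 0.05
    cluster_forming_alpha: float = 0.05
    tail: str = "greater"
    statistic: str = "cluster_mass"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.tail != "greater":
            raise ValueError("only the one-tailed 'greater' test is implemented")
        if self.statistic not in ("cluster_mass", "cluster_size"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass(frozen=True)
class Cluster:
    members: tuple[str, ...]
    mass: float
    p: float


@dataclass(frozen=True)
class ClusterResult:
    clusters: tuple[Cluster, ...]
    t_map: np.ndarray
    df: int
    threshold: float
    null_distribution: np.ndarray
    nodes: tuple[str, ...]
    method: str = "montecarlo"

    def significant(self, alpha: float = 0.05) -> tuple[Cluster, ...]:
        return tuple(c for c in self.clusters if c.p < alpha)


def _components(supra: np.ndarray, neighbors: list[list[int]]) -> list[list[int]]:
    """Connected components restricted to suprathreshold node indices."""
    seen = np.zeros(len(neighbors), dtype=bool)
    comps = []
    for start in np.flatnonzero(supra):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in neighbors[u]:
                if supra[v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(comp)
    return comps


def _stat_of(comp: list[int], t: np.ndarray, statistic: str) -> float:
    if statistic == "cluster_size":
        return float(len(comp))
    return float(t[comp].sum())


def _t_maps_for_signs(diff: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Paired-t maps for many sign assignments at once.

    ``diff`` is (subjects, nodes); ``signs`` is (n_assign, subjects) of +-1.
    Uses the identity that flipping signs leaves per-node sums of squares
    unchanged, so only the mean moves.
    """
    n = diff.shape[0]
    sumsq = np.einsum("ij,ij->j", diff, diff)
    mean = signs @ diff / n                       # (n_assign, nodes)
    var = (sumsq[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return t


def _max_null_stats(diff: np.ndarray, signs: np.ndarray, threshold: float,
                    neighbors: list[list[int]], valid: np.ndarray,
                    statistic: str, block: int = 256) -> np.ndarray:
    """Max cluster statistic for each sign assignment (0 when none)."""
    out = np.zeros(len(signs))
    for lo in range(0, len(signs), block):
        tmaps = _t_maps_for_signs(diff, signs[lo:lo + block])
        supra_block = (tmaps > threshold) & valid[None, :]
        for j in range(tmaps.shape[0]):
            supra = supra_block[j]
            if not supra.any():
                continue
            comps = _components(supra, neighbors)
            out[lo + j] = max(_stat_of(c, tmaps[j], statistic) for c in comps)
    return out


def _prepare(exp: np.ndarray, base: np.ndarray):
    """Shared setup for both permutation engines.

    The observed t map used for clustering is computed through the same
    vectorized kernel as the permutation null (identity sign assignment),
    so the identity permutation compares bit-exactly against the observed
    cluster masses.
    """
    if exp.shape != base.shape:
        raise ValueError("experimental and baseline shapes differ")
    n = exp.shape[0]
    if n < 2:
        raise ValueError("paired t needs >= 2 subjects")
    diff = exp - base
    valid = diff.std(axis=0, ddof=1) > 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} node(s) with zero variance excluded from t map",
            UserWarning, stacklevel=3)
    t_obs = _t_maps_for_signs(diff, np.ones((1, n)))[0]
    t_obs = np.where(valid, t_obs, -np.inf)
    t = np.where(valid, t_obs, np.nan)
    return t, n - 1, valid, diff, t_obs


def _pin_identity(null: np.ndarray, signs: np.ndarray,
                  observed: list[tuple[tuple[str, ...], float]]) -> None:
    """Set null entries for identity (all +1) assignments to the observed
    maximum cluster statistic, which they equal by definition; avoids
    losing the tie to a different float summation path."""
    ident = np.all(signs == 1.0, axis=1)
    if ident.any():
        null[ident] = max((s for _, s in observed), default=0.0)


def _observed_clusters(t: np.ndarray, valid: np.ndarray, threshold: float,
                       neighbors: list[list[int]], nodes: tuple[str, ...],
                       statistic: str) -> list[tuple[tuple[str, ...], float]]:
    supra = np.zeros_like(valid)
    supra[valid] = t[valid] > threshold
    comps = _components(supra, neighbors)
    out = [(tuple(nodes[i] for i in sorted(c)), _stat_of(c, t, statistic))
           for c in comps]
    return sorted(out, key=lambda c: -c[1])


def _align_graph(graph: AdjacencyGraph, node_id: tuple[str, ...] | None,
                 n_nodes: int) -> tuple[tuple[str, ...], list[list[int]]]:
    if len(graph) != n_nodes:
        raise ValueError(
            f"graph has {len(graph)} nodes but response maps have {n_nodes}")
    if node_id is not None and tuple(node_id) != graph.nodes:
        order = {n: i for i, n in enumerate(node_id)}
        missing = [n for n in graph.nodes if n not in order]
        if missing:
            raise ValueError(f"graph nodes missing from response maps: {missing[:5]}")
        raise ValueError("graph node order differs from response map order; "
                         "reorder one of them")
    return graph.nodes, graph.neighbor_lists()


def cluster_permutation_test(resp_exp, resp_base, graph: AdjacencyGraph,
                             cfg: ClusterConfig | None = None) -> ClusterResult:
    """Paired cluster permutation test via Monte Carlo sign flips.

    Observed node-wise paired t values above the one-tailed critical value
    at ``cluster_forming_alpha`` are grouped into graph-connected clusters;
    each cluster's mass (sum of member t values) is referred to the null
    distribution of the maximum cluster mass under random per-subject sign
    flips of the difference maps. Cluster p values use the
    (1 + exceedances) / (1 + n_permutations) estimator. When
    ``n_permutations`` is at least the number of distinct sign assignments
    (2^n), the test falls back to exhaustive enumeration.
    """
    cfg = cfg or ClusterConfig()
    exp, ids = _as_matrix(resp_exp)
    base, _ = _as_matrix(resp_base)
    n = exp.shape[0]
    if n <= 62 and cfg.n_permutations >= 2 ** n:
        logger.info("n_permutations=%d >= 2^%d: exhaustive enumeration",
                    cfg.n_permutations, n)
        return exhaustive_signflip_test(resp_exp, resp_base, graph, cfg)
    t, df, valid, diff, t_obs = _prepare(exp, base)
    nodes, neighbors = _align_graph(graph, ids, exp.shape[1])
    threshold = float(scipy.stats.t.ppf(1 - cfg.cluster_forming_alpha, df))
    rng = np.random.default_rng(cfg.seed)
    signs = rng.choice([-1.0, 1.0], size=(cfg.n_permutations, n))
    null = _max_null_stats(diff, signs, threshold, neighbors, valid,
                           cfg.statistic)
    observed = _observed_clusters(t_obs, valid, threshold, neighbors, nodes,
                                  cfg.statistic)
    _pin_identity(null, signs, observed)
    clusters = tuple(
        Cluster(members=m, mass=s,
                p=float((1 + np.sum(null >= s)) / (1 + cfg.n_permutations)))
        for m, s in observed)
    return ClusterResult(clusters=clusters, t_map=t, df=df, threshold=threshold,
                         null_distribution=null, nodes=nodes,
                         method="montecarlo")


def exhaustive_signflip_test(resp_exp, resp_base, graph: AdjacencyGraph,
                             cfg: ClusterConfig | None = None) -> ClusterResult:
    """Exact paired cluster test: all 2^n sign assignments.

    p = #{null >= observed} / 2^n. Requires n <= 20 subjects.
    """
    cfg = cfg or ClusterConfig()
    exp, ids = _as_matrix(resp_exp)
    base, _ = _as_matrix(resp_base)
    n = exp.shape[0]
    if n > 20:
        raise ValueError(
            f"n={n}: 2^n assignments not enumerable; use cluster_permutation_test")
    t, df, valid, diff, t_obs = _prepare(exp, base)
    nodes, neighbors = _align_graph(graph, ids, exp.shape[1])
    threshold = float(scipy.stats.t.ppf(1 - cfg.cluster_forming_alpha, df))
    bits = (np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1
    signs = bits * 2.0 - 1.0
    null = _max_null_stats(diff, signs, threshold, neighbors, valid,
                           cfg.statistic)
    observed = _observed_clusters(t_obs, valid, threshold, neighbors, nodes,
                                  cfg.statistic)
    _pin_identity(null, signs, observed)
    clusters = tuple(
        Cluster(members=m, mass=s, p=float(np.sum(null >= s) / 2 ** n))
        for m, s in observed)
    return ClusterResult(clusters=clusters, t_map=t, df=df, threshold=threshold,
                         null_distribution=null, nodes=nodes,
                         method="exhaustive")


# ---------------------------------------------------------------------------
# effect size

@dataclass(frozen=True)
class EffectSize:
    g: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.g <= self.ci_high:
            raise ValueError("effect size outside its own confidence interval")

    def __str__(self) -> str:
        return f"{self.g:.2f} [{self.ci_low:.2f}, {self.ci_high:.2f}]"


def _J(nu: int) -> float:
    """Small-sample bias correction for the standardized mean difference."""
    return 1 - 3 / (4 * nu - 1)


def hedges_g(differences, ci: str = "noncentral", level: float = 0.95,
             n_boot: int = 10_000, seed: int = 0) -> EffectSize:
    """Hedges g for paired differences, with a 95% confidence interval.

    g = (mean / SD) * J(n-1), J(nu) = 1 - 3/(4 nu - 1). The default CI
    inverts the noncentral t distribution of the one-sample t statistic;
    ``ci="bootstrap"`` uses a seeded percentile bootstrap instead.
    """
    d = np.asarray(differences, dtype=float).ravel()
    n = d.size
    if n < 2:
        raise ValueError("need >= 2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: effect size undefined")
    nu = n - 1
    j = _J(nu)
    g = d.mean() / sd * j
    alpha = 1 - level
    if ci == "noncentral":
        tstat = d.mean() / (sd / np.sqrt(n))
        lo = _invert_ncp(tstat, nu, 1 - alpha / 2) / np.sqrt(n) * j
        hi = _invert_ncp(tstat, nu, alpha / 2) / np.sqrt(n) * j
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        samples = d[idx]
        sds = samples.std(axis=1, ddof=1)
        ok = sds > 0
        gs = samples.mean(axis=1)[ok] / sds[ok] * j
        lo, hi = np.quantile(gs, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    lo, hi = min(lo, g), max(hi, g)
    return EffectSize(g=float(g), ci_low=float(lo), ci_high=float(hi), n=n)


def _invert_ncp(t: float, df: int, prob: float) -> float:
    """Noncentrality delta with P(T_df(delta) <= t) = prob."""
    f = lambda ncp: scipy.stats.nct.cdf(t, df, ncp) - prob
    lo, hi = t - 1.0, t + 1.0
    width = 1.0
    while f(lo) < 0:            # cdf decreasing in ncp
        width *= 2
        lo -= width
    while f(hi) > 0:
        width *= 2
        hi += width
    return float(scipy.optimize.brentq(f, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# Bayes factors

@dataclass(frozen=True)
class BayesResult:
    bf10: float
    r_scale: float
    n: int
    t: float

    @property
    def evidence(self) -> str:
        return classify_evidence(self.bf10)


def jzs_bf10(t: float, n: int, r_scale: float = 0.707) -> BayesResult:
    """JZS Bayes factor BF10 for a one-sample / paired t statistic.

    The alternative places a Cauchy(0, r_scale) prior on the standardized
    effect delta; BF10 is the ratio of the marginal likelihood of t under
    that prior (noncentral t mixed over delta, noncentrality delta*sqrt(n))
    to the central-t likelihood under the point null. Evaluated by adaptive
    quadrature; integration failure raises rather than falling back.
    """
    if not np.isfinite(t):
        raise ValueError("non-finite t statistic")
    if n < 2:
        raise ValueError("n must be >= 2")
    if r_scale <= 0:
        raise ValueError("r_scale must be > 0")
    df = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta: float) -> float:
        return (scipy.stats.nct.pdf(t, df, delta * sqrt_n)
                * scipy.stats.cauchy.pdf(delta, scale=r_scale))

    like_h0 = scipy.stats.t.pdf(t, df)
    # split at 0 and near the MLE of delta so quad sees the mass
    center = t / sqrt_n
    pts = sorted({0.0, center})
    like_h1, abserr = scipy.integrate.quad(
        integrand, -np.inf, np.inf, points=None, limit=200,
        epsabs=1e-14, epsrel=1e-10)
    if not np.isfinite(like_h1) or like_h1 <= 0:
        raise RuntimeError("JZS marginal likelihood integration failed")
    if abserr > max(1e-12, 1e-6 * like_h1):
        # refine by integrating piecewise around the mass
        parts = []
        knots = [-np.inf] + pts + [np.inf]
        total = 0.0
        for a, b in zip(knots[:-1], knots[1:]):
            val, err = scipy.integrate.quad(integrand, a, b, limit=200)
            parts.append(err)
            total += val
        if not np.isfinite(total) or total <= 0 or sum(parts) > 1e-6 * total:
            raise RuntimeError("JZS marginal likelihood integration failed")
        like_h1 = total
    return BayesResult(bf10=float(like_h1 / like_h0), r_scale=r_scale,
                       n=n, t=float(t))


def classify_evidence(bf10: float) -> str:
    """Moderate-evidence classification: BF10 < 1/3 supports the null,
    BF10 > 3 the alternative; boundary values are inconclusive."""
    if bf10 <= 0:
        raise ValueError("bf10 must be > 0")
    if bf10 < 1 / 3:
        return "supports_null"
    if bf10 > 3:
        return "supports_alternative"
    return "inconclusive"


def tabulate_evidence(bf_per_node: dict[str, float],
                      roi_membership: dict[str, str]) -> pd.DataFrame:
    """Per-region counts of nodes in each evidence class.

    Returns a DataFrame with one row per region: total vertices, count and
    integer-rounded percentage with BF10 < 1/3, and with BF10 > 3. Regions
    present in ``roi_membership`` with no nodes yield zero rows.
    """
    missing = set(bf_per_node) - set(roi_membership)
    if missing:
        raise ValueError(f"nodes missing an ROI label: {sorted(missing)[:5]}")
    rois: dict[str, list[float]] = {r: [] for r in roi_membership.values()}
    for node, roi in roi_membership.items():
        if node not in bf_per_node:
            raise ValueError(f"node {node!r} has no Bayes factor")
        rois[roi].append(bf_per_node[node])
    rows = []
    for roi in sorted(rois):
        bfs = np.array(rois[roi])
        n = bfs.size
        below = int(np.sum(bfs < 1 / 3))
        above = int(np.sum(bfs > 3))
        rows.append({
            "roi": roi, "n_vertices": n,
            "n_bf_below_third": below,
            "pct_bf_below_third": int(round(100 * below / n)) if n else 0,
            "n_bf_above_three": above,
            "pct_bf_above_three": int(round(100 * above / n)) if n else 0,
        })
    return pd.DataFrame(rows, columns=[
        "roi", "n_vertices", "n_bf_below_third", "pct_bf_below_third",
        "n_bf_above_three", "pct_bf_above_three"])


# ---------------------------------------------------------------------------
# model / results objects

class FPVSContrast:
    """Paired contrast between an experimental and a baseline condition.

    Built from per-subject oddball ResponseMaps (or plain
    (subjects x nodes) arrays) and the adjacency graph of the sensor or
    vertex set they live on. ``fit()`` runs the cluster permutation test,
    computes Hedges g for each cluster (on per-subject responses averaged
    over cluster members) and the per-node JZS Bayes factor map.
    """

    def __init__(self, resp_exp, resp_base, graph: AdjacencyGraph,
                 cluster_config: ClusterConfig | None = None,
                 r_scale: float = 0.707, name: str = ""):
        self.exp, ids = _as_matrix(resp_exp)
        self.base, _ = _as_matrix(resp_base)
        if self.exp.shape != self.base.shape:
            raise ValueError("experimental and baseline shapes differ")
        self.nodes, _ = _align_graph(graph, ids, self.exp.shape[1])
        self.graph = graph
        self.cluster_config = cluster_config or ClusterConfig()
        self.r_scale = r_scale
        self.name = name

    @classmethod
    def from_response_maps(cls, maps: list[ResponseMap], exp_label: str,
                           base_label: str, graph: AdjacencyGraph,
                           **kwargs) -> "FPVSContrast":
        """Pair up maps by subject for the two condition labels."""
        by = {}
        for m in maps:
            by.setdefault(m.subject_id, {})[m.condition] = m
        subjects = sorted(s for s, d in by.items()
                          if exp_label in d and base_label in d)
        if len(subjects) < 2:
            raise ValueError(
                f"need >= 2 subjects with both {exp_label!r} and {base_label!r}")
        exp = [by[s][exp_label] for s in subjects]
        base = [by[s][base_label] for s in subjects]
        return cls(exp, base, graph, name=f"{exp_label} vs {base_label}",
                   **kwargs)

    @property
    def n_subjects(self) -> int:
        return self.exp.shape[0]

    def fit(self, method: str = "montecarlo") -> "ContrastResults":
        if method == "montecarlo":
            cres = cluster_permutation_test(self.exp, self.base, self.graph,
                                            self.cluster_config)
        elif method == "exhaustive":
            cres = exhaustive_signflip_test(self.exp, self.base, self.graph,
                                            self.cluster_config)
        else:
            raise ValueError(f"unknown method {method!r}")
        diff = self.exp - self.base
        index = {nd: i for i, nd in enumerate(self.nodes)}
        effects = []
        for c in cres.clusters:
            cols = [index[m] for m in c.members]
            effects.append(hedges_g(diff[:, cols].mean(axis=1)))
        return ContrastResults(model=self, cluster_result=cres,
                               effect_sizes=tuple(effects))


@dataclass(frozen=True)
class ContrastResults:
    """Fit results for one FPVS contrast."""

    model: FPVSContrast = field(repr=False)
    cluster_result: ClusterResult
    effect_sizes: tuple[EffectSize, ...]

    @property
    def clusters(self) -> tuple[Cluster, ...]:
        return self.cluster_result.clusters

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def significant(self, alpha: float | None = None) -> tuple[Cluster, ...]:
        alpha = alpha if alpha is not None else self.model.cluster_config.alpha
        return self.cluster_result.significant(alpha)

    def bayes_map(self) -> dict[str, float]:
        """Per-node JZS BF10 from the node-wise paired t map."""
        t = self.cluster_result.t_map
        n = self.model.n_subjects
        out = {}
        for node, ti in zip(self.cluster_result.nodes, t):
            if np.isfinite(ti):
                out[node] = jzs_bf10(float(ti), n, self.model.r_scale).bf10
        return out

    def evidence_table(self, roi_membership: dict[str, str]) -> pd.DataFrame:
        return tabulate_evidence(self.bayes_map(), roi_membership)

    def cluster_frame(self) -> pd.DataFrame:
        rows = [{
            "cluster": i, "n_members": len(c.members), "mass": c.mass,
            "p": c.p, "g": e.g, "g_ci_low": e.ci_low, "g_ci_high": e.ci_high,
            "members": ",".join(c.members),
        } for i, (c, e) in enumerate(zip(self.clusters, self.effect_sizes))]
        return pd.DataFrame(rows, columns=[
            "cluster", "n_members", "mass", "p", "g", "g_ci_low",
            "g_ci_high", "members"])

    def summary(self) -> str:
        cr = self.cluster_result
        lines = [
            f"FPVS contrast: {self.model.name or '(unnamed)'}",
            f"  subjects: {self.model.n_subjects}   nodes: {len(cr.nodes)}   "
            f"df: {cr.df}",
            f"  method: {cr.method}   permutations: "
            f"{len(cr.null_distribution)}   cluster-forming t > {cr.threshold:.3f}",
        ]
        if not self.clusters:
            lines.append("  no suprathreshold clusters")
        for i, (c, e) in enumerate(zip(self.clusters, self.effect_sizes)):
            star = " *" if c.p < self.model.cluster_config.alpha else ""
            lines.append(
                f"  cluster {i}: {len(c.members)} nodes, mass = {c.mass:.2f}, "
                f"p = {c.p:.4f}, g = {e}{star}")
        return "\n".join(lines)
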