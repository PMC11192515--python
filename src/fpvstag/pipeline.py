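"""End-to-end desk-scale experiment: simulate, quantify, test, report.

`run_experiment` replays the full oddball analysis for a set of named
contrasts (default: the five linguistic properties — alphabetic,
readability, familiarity, meaningfulness, lexicality — represented
abstractly as experimental/baseline condition pairs). For each contrast it
simulates a cohort, extracts per-subject oddball responses, runs the
cluster permutation test with effect sizes and Bayes factors, and writes
tidy tables plus a reproducibility manifest. Identical master seeds yield
byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import (AdjacencyGraph, ClusterConfig, ContrastResults,
                        FPVSContrast, build_adjacency)
from .io import save_epochs, save_json, save_responses_tsv
from .layout import SensorLayout, hemisphere_layout, make_sensor_layout
from .simulate import SimulationConfig, Topography, simulate_cohort
from .spectral import BaselineCorrectionConfig, epochs_to_response

__all__ = ["ExperimentConfig", "run_experiment", "report_tables"]

logger = logging.getLogger(__name__)

DEFAULT_CONTRASTS = ("alphabetic", "readability", "familiarity",
                     "meaningfulness", "lexicality")


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete description of one synthetic replica experiment."""

    sim: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(fs=300.0))
    n_subjects: int = 21
    trials_per_condition: int = 6
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS
    effect_scales: dict = field(default_factory=dict)  # contrast -> odd scale
    layout_sites: int = 102
    layout_csv: str | None = None
    sensor_set: str = "mag"
    f_target: float = 3.0
    adjacency_max_dist: float = 0.03
    correction: BaselineCorrectionConfig = field(
        default_factory=BaselineCorrectionConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    r_scale: float = 0.707
    seed: int = 0
    save_epochs: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.effect_scales) - set(self.contrasts)
        if unknown:
            raise ValueError(f"effect_scales for undefined contrasts: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["base_amplitudes"] = {
            str(k): v for k, v in self.sim.base_amplitudes.items()}
        d["sim"]["odd_amplitudes"] = {
            str(k): v for k, v in self.sim.odd_amplitudes.items()}
        d["contrasts"] = list(self.contrasts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "sim" in d:
            sim = dict(d["sim"])
            for key in ("base_amplitudes", "odd_amplitudes"):
                if key in sim:
                    sim[key] = {int(k): float(v) for k, v in sim[key].items()}
            for key in ("base_topography", "odd_topography"):
                if sim.get(key) is not None:
                    sim[key] = Topography(**sim[key])
            d["sim"] = SimulationConfig(**sim)
        if "correction" in d and not isinstance(d["correction"], BaselineCorrectionConfig):
            d["correction"] = BaselineCorrectionConfig(**d["correction"])
        if "cluster" in d and not isinstance(d["cluster"], ClusterConfig):
            d["cluster"] = ClusterConfig(**d["cluster"])
        if "contrasts" in d:
            d["contrasts"] = tuple(d["contrasts"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _layout(config: ExperimentConfig) -> SensorLayout:
    if config.layout_csv:
        return make_sensor_layout(config.layout_csv)
    return hemisphere_layout(n_sites=config.layout_sites)


def _graph(config: ExperimentConfig, layout: SensorLayout) -> AdjacencyGraph:
    kind = "grad_pairs" if config.sensor_set == "grad" else config.sensor_set
    return build_adjacency(layout, config.adjacency_max_dist, kind=kind)


def run_experiment(config: ExperimentConfig, out_dir) -> dict:
    """Run every contrast and write the report directory.

    Returns ``{"results": {contrast: ContrastResults}, "manifest": dict,
    "out_dir": Path}``. Outputs per contrast: responses TSV, clusters
    JSON, Bayes factor TSV; plus summary tables and a run manifest with
    config hash, per-stage seeds and file checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = _layout(config)
    graph = _graph(config, layout)
    master = np.random.SeedSequence(config.seed)
    contrast_seeds = master.spawn(len(config.contrasts))
    results: dict[str, ContrastResults] = {}
    stage_seeds: dict[str, dict] = {}
    written: list[Path] = []

    for name, css in zip(config.contrasts, contrast_seeds):
        sim_ss, perm_ss = css.spawn(2)
        perm_seed = int(perm_ss.generate_state(1)[0] % (2**31))
        stage_seeds[name] = {"simulate": str(sim_ss.spawn_key),
                             "permutation_seed": perm_seed}
        exp_label, base_label = f"{name}_exp", f"{name}_base"
        scale = float(config.effect_scales.get(name, 1.0))
        logger.info("contrast %s: simulating cohort (oddball scale %.3g)",
                    name, scale)
        epoch_sets, manifest = simulate_cohort(
            config.sim, layout,
            n_subjects=config.n_subjects,
            trials_per_condition=config.trials_per_condition,
            conditions=((exp_label, "experimental"), (base_label, "baseline")),
            seed=sim_ss, odd_scale={exp_label: scale})
        maps = []
        for es in epoch_sets:
            maps.append(epochs_to_response(
                es, f_target=config.f_target, cfg=config.correction,
                layout=layout, sensor_set=config.sensor_set))
            if config.save_epochs:
                p = out / f"epochs_{name}_{es.subject_id}_{es.condition}.h5"
                save_epochs(es, p, sensor_id=layout.sensor_id)
                written.append(p)
        del epoch_sets
        p = out / f"responses_{name}.tsv"
        save_responses_tsv(maps, p)
        written.append(p)

        cluster_cfg = dataclasses.replace(config.cluster, seed=perm_seed)
        model = FPVSContrast(
            [m for m in maps if m.condition == exp_label],
            [m for m in maps if m.condition == base_label],
            graph, cluster_config=cluster_cfg, r_scale=config.r_scale,
            name=f"{exp_label} vs {base_label}")
        res = model.fit()
        results[name] = res

        save_json({"contrast": name,
                   "threshold": res.cluster_result.threshold,
                   "df": res.cluster_result.df,
                   "method": res.cluster_result.method,
                   "clusters": [
                       {"members": list(c.members), "mass": c.mass, "p": c.p}
                       for c in res.clusters]},
                  out / f"clusters_{name}.json")
        written.append(out / f"clusters_{name}.json")
        bf = res.bayes_map()
        bf_df = pd.DataFrame(sorted(bf.items()), columns=["sensor", "bf10"])
        bf_df.to_csv(out / f"bayes_{name}.tsv", sep="\t", index=False,
                     float_format="%.17g")
        written.append(out / f"bayes_{name}.tsv")

    summary, evidence, md = report_tables(results, alpha=config.cluster.alpha)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False,
                   float_format="%.17g")
    evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)
    (out / "report.md").write_text(md)
    written += [out / "summary.tsv", out / "evidence.tsv", out / "report.md"]

    run_manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": stage_seeds,
        "n_nodes": len(graph),
        "n_edges": len(graph.edges),
        "checksums": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    save_json(run_manifest, out / "manifest.json")
    return {"results": results, "manifest": run_manifest, "out_dir": out}


def report_tables(results: dict[str, ContrastResults], alpha: float = 0.05,
                  roi_membership: dict[str, str] | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Summary and evidence tables across contrasts.

    Returns ``(summary, evidence, markdown)``. The summary has one row per
    contrast (largest cluster's mass, p and Hedges g with CI); the
    evidence table counts nodes per evidence class per contrast — grouped
    by region when ``roi_membership`` is given, otherwise over all nodes.
    """
    srows, erows = [], []
    for name, res in results.items():
        if res.clusters:
            c, e = res.clusters[0], res.effect_sizes[0]
            srows.append({
                "contrast": name, "significant": bool(c.p < alpha),
                "min_p": res.min_p, "mass": c.mass, "n_members": len(c.members),
                "g": e.g, "g_ci_low": e.ci_low, "g_ci_high": e.ci_high})
        else:
            srows.append({"contrast": name, "significant": False,
                          "min_p": 1.0, "mass": np.nan, "n_members": 0,
                          "g": np.nan, "g_ci_low": np.nan, "g_ci_high": np.nan})
        bf = res.bayes_map()
        membership = roi_membership or {n: "all" for n in bf}
        ev = res.evidence_table({n: membership[n] for n in bf})
        ev.insert(0, "contrast", name)
        erows.append(ev)
    cols = ["contrast", "significant", "min_p", "mass", "n_members",
            "g", "g_ci_low", "g_ci_high"]
    summary = pd.DataFrame(srows, columns=cols)
    evidence = (pd.concat(erows, ignore_index=True) if erows
                else pd.DataFrame(columns=[
                    "contrast", "roi", "n_vertices", "n_bf_below_third",
                    "pct_bf_below_third", "n_bf_above_three",
                    "pct_bf_above_three"]))
    md_lines = ["# FPVS oddball contrast report", "",
                "## Cluster summary", "",
                _df_to_md(summary), "",
                "## Bayes factor evidence counts", "",
                _df_to_md(evidence), ""]
    return summary, evidence, "\n".join(md_lines)


def _df_to_md(df: pd.DataFrame) -> str:
    header = "| " + " | ".join(df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    rows = ["| " + " | ".join(
        f"{v:.4g}" if isinstance(v, float) else str(v) for v in rec) + " |"
        for rec in df.itertuples(index=False)]
    return "\n".join([header, sep] + rows)
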