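"""Shared fixtures: small layouts, simulation configs, and a session-wide
null-hypothesis simulation batch reused by the calibration tests."""

from __future__ import annotations

import numpy as np
import pytest

import fpvstag as f


@pytest.fixture(scope="session")
def tiny_layout() -> f.SensorLayout:
    """8-site helmet: 8 mags + 16 paired grads."""
    return f.hemisphere_layout(n_sites=8)


@pytest.fixture(scope="session")
def small_layout() -> f.SensorLayout:
    return f.hemisphere_layout(n_sites=24)


def h0_sim_config(noise_sigma: float = 1.0, odd_amp: float = 0.0,
                  fs: float = 60.0) -> f.SimulationConfig:
    """Trial-length config with base-rate content only; oddball optional."""
    return f.SimulationConfig(
        fs=fs, base_amplitudes={1: 1.0}, odd_amplitudes={1: odd_amp},
        noise_sigma=noise_sigma, subject_cv=0.2)


def run_h0_batch(n_sims: int, layout: f.SensorLayout, seed: int = 12345,
                 n_subjects: int = 12, n_permutations: int = 500,
                 odd_amp: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Simulate -> quantify -> cluster-test `n_sims` independent cohorts.

    Returns (any_significant flags, min cluster p per simulation); the
    min p is 1.0 when no cluster forms.
    """
    cfg = h0_sim_config(odd_amp=odd_amp)
    graph = f.build_adjacency(layout, 0.08, kind="mag")
    master = np.random.SeedSequence(seed)
    any_sig = np.zeros(n_sims, dtype=bool)
    min_p = np.ones(n_sims)
    for i, child in enumerate(master.spawn(n_sims)):
        sim_ss, perm_ss = child.spawn(2)
        epoch_sets, _ = f.simulate_cohort(
            cfg, layout, n_subjects=n_subjects, trials_per_condition=1,
            seed=sim_ss)
        maps = [f.epochs_to_response(es, 3.0, layout=layout, sensor_set="mag")
                for es in epoch_sets]
        model = f.FPVSContrast.from_response_maps(
            maps, "experimental", "baseline", graph,
            cluster_config=f.ClusterConfig(
                n_permutations=n_permutations,
                seed=int(perm_ss.generate_state(1)[0] % 2**31)))
        res = model.fit()
        any_sig[i] = len(res.significant(0.05)) > 0
        min_p[i] = res.min_p
    return any_sig, min_p


@pytest.fixture(scope="session")
def h0_batch(tiny_layout):
    """500 independent null cohorts at 500 permutations each."""
    return run_h0_batch(500, tiny_layout)
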