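"""Synthetic frequency-tagged MEG epochs.

The generative model mirrors the statistical structure an FPVS oddball
analysis assumes. Every epoch is a sum of

* a steady-state base response: sinusoids at the base stimulation rate and
  its configured harmonics, shared by all conditions;
* an oddball discrimination response, present only in ``experimental``
  sequences: sinusoids at the oddball rate and those of its harmonics that
  do not coincide with base harmonics (coincident terms are unidentifiable
  and are dropped with a warning);
* Gaussian 1/f^beta background noise, the canonical resting MEG spectrum.

Both responses are spatially weighted by unit-peak Gaussian topographies
over great-circle distance from a center sensor, so injected effects are
spatially smooth and contiguous — the regime cluster-based tests address.
Epoch duration is exactly ``n_cycles / f_base`` seconds, which places the
base and oddball frequencies on exact FFT bins.

Every random draw (phases, subject gains, noise) descends deterministically
from the run seed, and :func:`simulate_cohort` returns a manifest recording
each drawn parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .layout import SensorLayout

__all__ = [
    "Topography", "SimulationConfig", "EpochSet",
    "pink_noise", "simulate_epoch", "simulate_cohort",
]


@dataclass(frozen=True)
class Topography:
    """Gaussian spatial profile: exp(-d^2 / 2 width^2), d = great-circle
    distance (meters) from the center sensor; unit peak at the center."""

    center_sensor: str
    width: float = 0.04

    def weights(self, layout: SensorLayout) -> np.ndarray:
        try:
            c = layout.sensor_id.index(self.center_sensor)
        except ValueError:
            raise ValueError(f"center sensor {self.center_sensor!r} not in layout")
        pos = layout.positions
        radii = np.linalg.norm(pos, axis=1)
        center = pos[c] / radii[c]
        cosang = np.clip(pos @ center / radii, -1.0, 1.0)
        dist = radii * np.arccos(cosang)   # arc length on each sensor's shell
        return np.exp(-dist**2 / (2 * self.width**2))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic FPVS recording.

    ``base_amplitudes`` / ``odd_amplitudes`` map harmonic number to
    amplitude, in the same (arbitrary but consistent) field units as the
    emitted epochs; harmonic ``h`` of the base lies at ``h * f_base`` Hz,
    harmonic ``k`` of the oddball at ``k * f_odd`` Hz.
    """

    f_base: float = 6.0
    f_odd: float = 3.0
    n_cycles: int = 160
    fs: float = 1200.0
    base_amplitudes: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.0})
    odd_amplitudes: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.5})
    base_topography: Topography | None = None
    odd_topography: Topography | None = None
    noise_sigma: float = 1.0
    noise_beta: float = 1.0
    subject_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        ratio = self.f_base / self.f_odd
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 2:
            raise ValueError("f_base must be an integer multiple (>= 2) of f_odd")
        dur_odd_cycles = self.duration * self.f_odd
        if abs(dur_odd_cycles - round(dur_odd_cycles)) > 1e-9:
            raise ValueError("epoch duration must hold an integer number of oddball cycles")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration must be an integer sample count")
        fmax = max(
            [h * self.f_base for h in self.base_amplitudes] +
            [k * self.f_odd for k in self.odd_amplitudes], default=0.0)
        if self.fs <= 2 * fmax:
            raise ValueError(f"fs={self.fs} too low for max frequency {fmax} Hz")
        if any(a < 0 for a in self.base_amplitudes.values()):
            raise ValueError("base amplitudes must be >= 0")
        if any(a < 0 for a in self.odd_amplitudes.values()):
            raise ValueError("oddball amplitudes must be >= 0")
        if self.noise_sigma < 0 or self.subject_cv < 0:
            raise ValueError("noise_sigma and subject_cv must be >= 0")

    @property
    def duration(self) -> float:
        """Epoch length in seconds (exactly n_cycles / f_base)."""
        return self.n_cycles / self.f_base

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def valid_odd_harmonics(self, warn: bool = False) -> list[int]:
        """Oddball harmonics whose frequency is not a base harmonic."""
        ratio = int(round(self.f_base / self.f_odd))
        keep, dropped = [], []
        for k in sorted(self.odd_amplitudes):
            (dropped if k % ratio == 0 else keep).append(k)
        if dropped and warn:
            warnings.warn(
                f"oddball harmonics {dropped} coincide with base harmonics "
                "and were dropped", UserWarning, stacklevel=2)
        return keep


@dataclass
class EpochSet:
    """Per-subject, per-condition stack of epochs (trial x sensor x time)."""

    subject_id: str
    condition: str
    data: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, sensors, samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in epoch data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def pink_noise(shape: tuple[int, ...], fs: float, beta: float = 1.0,
               sigma: float = 1.0, rng: np.random.Generator | None = None
               ) -> np.ndarray:
    """Gaussian 1/f^beta noise along the last axis, std ``sigma``.

    White Gaussian noise is shaped in the frequency domain by
    ``|H(f)| = f^(-beta/2)`` (DC removed) and rescaled so the expected
    time-domain variance equals ``sigma**2`` exactly.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1 / fs)
    h = np.zeros_like(freqs)
    h[1:] = freqs[1:] ** (-beta / 2)
    # Parseval: E[var] = (1/n) * sum over full spectrum of |H_k|^2
    mult = np.full_like(h, 2.0)
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0
    expected_var = float(np.sum(mult * h**2)) / n
    white = rng.standard_normal(shape)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * h, n=n, axis=-1)
    if expected_var == 0:
        return np.zeros(shape)
    return shaped * (sigma / np.sqrt(expected_var))


def _default_topographies(config: SimulationConfig, layout: SensorLayout
                          ) -> tuple[Topography, Topography]:
    """Fall back to posterior centers (max x site) if none configured."""
    base = config.base_topography
    odd = config.odd_topography
    if base is None or odd is None:
        order = np.argsort(layout.positions[:, 0])
        fallback = Topography(center_sensor=layout.sensor_id[order[-1]])
        base = base or fallback
        odd = odd or fallback
    return base, odd


def _draw_phases(config: SimulationConfig, rng: np.random.Generator
                 ) -> tuple[dict[int, float], dict[int, float]]:
    phi = {h: float(rng.uniform(0, 2 * np.pi)) for h in sorted(config.base_amplitudes)}
    psi = {k: float(rng.uniform(0, 2 * np.pi)) for k in config.valid_odd_harmonics()}
    return phi, psi


def _signal(config: SimulationConfig, layout: SensorLayout, condition: str,
            phases_base: Mapping[int, float], phases_odd: Mapping[int, float],
            gain: float = 1.0) -> np.ndarray:
    """Noise-free (sensor x time) epoch for one condition."""
    t = np.arange(config.n_samples) / config.fs
    base_topo, odd_topo = _default_topographies(config, layout)
    w = base_topo.weights(layout)
    v = odd_topo.weights(layout)
    out = np.zeros((len(layout), config.n_samples))
    for h, amp in config.base_amplitudes.items():
        out += gain * amp * np.outer(
            w, np.sin(2 * np.pi * h * config.f_base * t + phases_base[h]))
    if condition == "experimental":
        for k in config.valid_odd_harmonics(warn=True):
            amp = config.odd_amplitudes[k]
            out += gain * amp * np.outer(
                v, np.sin(2 * np.pi * k * config.f_odd * t + phases_odd[k]))
    elif condition != "baseline":
        raise ValueError(f"condition must be 'experimental' or 'baseline', got {condition!r}")
    return out


def simulate_epoch(config: SimulationConfig, layout: SensorLayout,
                   condition: str = "experimental",
                   seed: int | np.random.SeedSequence | None = None
                   ) -> np.ndarray:
    """One synthetic (sensor x time) epoch. Deterministic given the seed."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    phi, psi = _draw_phases(config, rng)
    epoch = _signal(config, layout, condition, phi, psi)
    if config.noise_sigma > 0:
        epoch = epoch + pink_noise(epoch.shape, config.fs, config.noise_beta,
                                   config.noise_sigma, rng)
    return epoch


def simulate_cohort(config: SimulationConfig, layout: SensorLayout,
                    n_subjects: int = 21, trials_per_condition: int = 6,
                    conditions: Sequence[tuple[str, str]] = (
                        ("experimental", "experimental"),
                        ("baseline", "baseline")),
                    seed: int | np.random.SeedSequence | None = None,
                    odd_scale: Mapping[str, float] | None = None,
                    ) -> tuple[list[EpochSet], dict]:
    """Simulate a full cohort and return (epoch sets, ground-truth manifest).

    Parameters
    ----------
    conditions
        Sequence of ``(label, kind)`` pairs; kind is ``"experimental"``
        (oddball present) or ``"baseline"`` (oddball absent).
    odd_scale
        Optional per-condition-label multiplier on the oddball amplitudes,
        used to inject effects of different sizes under one config.
    seed
        Master seed; phases are drawn once per run, then every subject,
        condition and trial receives an independent child noise stream.

    Per-subject gains are lognormal with mean 1 and coefficient of
    variation ``config.subject_cv``, applied to all signal amplitudes.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    labels = [lab for lab, _ in conditions]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels")
    if seed is None:
        seed = config.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    phase_ss, gain_ss, noise_ss = ss.spawn(3)
    phi, psi = _draw_phases(config, np.random.default_rng(phase_ss))

    cv = config.subject_cv
    if cv > 0:
        s2 = np.log1p(cv**2)
        gains = np.random.default_rng(gain_ss).lognormal(
            mean=-s2 / 2, sigma=np.sqrt(s2), size=n_subjects)
    else:
        gains = np.ones(n_subjects)

    odd_scale = dict(odd_scale or {})
    epoch_sets: list[EpochSet] = []
    noise_children = iter(noise_ss.spawn(n_subjects * len(conditions)))
    for s in range(n_subjects):
        subject_id = f"sub{s:02d}"
        for label, kind in conditions:
            scale = odd_scale.get(label, 1.0)
            cfg = config if scale == 1.0 else _scaled(config, scale)
            clean = _signal(cfg, layout, kind, phi, psi, gain=gains[s])
            child = next(noise_children)
            rng = np.random.default_rng(child)
            trials = np.broadcast_to(
                clean, (trials_per_condition, *clean.shape)).copy()
            if config.noise_sigma > 0:
                trials += pink_noise(trials.shape, config.fs,
                                     config.noise_beta, config.noise_sigma, rng)
            epoch_sets.append(EpochSet(subject_id=subject_id, condition=label,
                                       data=trials, fs=config.fs))
    manifest = {
        "seed": str(ss.entropy),
        "n_subjects": n_subjects,
        "trials_per_condition": trials_per_condition,
        "conditions": [list(c) for c in conditions],
        "duration_s": config.duration,
        "n_samples": config.n_samples,
        "subject_gains": {f"sub{s:02d}": float(g) for s, g in enumerate(gains)},
        "phases_base": {str(h): p for h, p in phi.items()},
        "phases_odd": {str(k): p for k, p in psi.items()},
        "odd_scale": {k: float(v) for k, v in odd_scale.items()},
        "config": {
            "f_base": config.f_base, "f_odd": config.f_odd,
            "n_cycles": config.n_cycles, "fs": config.fs,
            "base_amplitudes": {str(h): a for h, a in config.base_amplitudes.items()},
            "odd_amplitudes": {str(k): a for k, a in config.odd_amplitudes.items()},
            "noise_sigma": config.noise_sigma, "noise_beta": config.noise_beta,
            "subject_cv": config.subject_cv,
        },
    }
    return epoch_sets, manifest


def _scaled(config: SimulationConfig, odd_scale: float) -> SimulationConfig:
    from dataclasses import replace
    return replace(config, odd_amplitudes={
        k: a * odd_scale for k, a in config.odd_amplitudes.items()})
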