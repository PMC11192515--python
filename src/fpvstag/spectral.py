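"""From epochs to baseline-corrected amplitude spectra and oddball responses.

The quantification chain is: band-pass filter and downsample (optional),
average trials within a condition (coherent averaging), Fourier-transform
the average, baseline-correct each frequency bin against its surrounding
bins, and read off the corrected amplitude at the oddball frequency.

Amplitude normalization is ``2|X_k|/N`` for k > 0 (``|X_0|/N`` at DC), so a
bin-aligned sinusoid of amplitude A reads A at its bin and simulator
amplitudes are directly recoverable from spectra.

The baseline correction subtracts, from each bin, the mean of 20
surrounding bins: per side the 12 next bins are taken, the bin immediately
adjacent is skipped, the 22 pooled candidates lose their single largest and
single smallest value, and the remaining 20 are averaged. This local
detrending removes the smooth 1/f noise floor while being robust to a
nearby spectral peak landing in the candidate window. All counts are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from .layout import SensorLayout
from .simulate import EpochSet

__all__ = [
    "AmplitudeSpectrum", "BaselineCorrectionConfig", "ResponseMap",
    "filter_and_downsample", "average_epochs", "compute_spectrum",
    "combine_planar", "baseline_correct", "extract_response",
    "epochs_to_response",
]


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """One-sided amplitude spectrum per sensor.

    ``defined`` marks bins with a valid value; after baseline correction,
    edge bins whose surrounding-bin window would leave the spectrum are
    undefined (value 0, flag False) rather than estimated asymmetrically.
    """

    amplitudes: np.ndarray            # (n_sensors, n_bins)
    freqs: np.ndarray                 # (n_bins,) Hz
    resolution: float                 # Hz, = 1/epoch duration
    corrected: bool = False
    sensor_id: tuple[str, ...] | None = None
    defined: np.ndarray | None = None  # (n_bins,) bool

    def __post_init__(self) -> None:
        amp = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        object.__setattr__(self, "amplitudes", amp)
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        if amp.shape[1] != freqs.size:
            raise ValueError("amplitudes and freqs disagree on bin count")
        df = np.diff(freqs)
        if freqs.size > 1 and not np.allclose(df, self.resolution, rtol=1e-9):
            raise ValueError("freqs must be uniformly spaced at `resolution`")
        if not np.all(np.isfinite(amp)):
            raise ValueError("non-finite spectrum values")
        if self.defined is None:
            object.__setattr__(self, "defined", np.ones(freqs.size, dtype=bool))

    @property
    def n_sensors(self) -> int:
        return self.amplitudes.shape[0]

    def bin_of(self, f: float) -> int:
        """Index of the bin nearest to frequency f (Hz)."""
        return int(np.argmin(np.abs(self.freqs - f)))


@dataclass(frozen=True)
class BaselineCorrectionConfig:
    """Surrounding-bin baseline correction parameters.

    Defaults implement the 20-contributing-bins rule: 10 used bins per
    side after skipping 1 adjacent bin per side and dropping the pooled
    maximum and minimum candidate.
    """

    n_used_per_side: int = 10
    n_adjacent_excluded: int = 1
    exclude_extremes: bool = True

    def __post_init__(self) -> None:
        if self.n_used_per_side < 1:
            raise ValueError("n_used_per_side must be >= 1")
        if self.n_adjacent_excluded < 0:
            raise ValueError("n_adjacent_excluded must be >= 0")

    @property
    def window_per_side(self) -> int:
        """Candidate bins consumed on each side of the corrected bin."""
        return (self.n_used_per_side + self.n_adjacent_excluded
                + (1 if self.exclude_extremes else 0))


@dataclass(frozen=True)
class ResponseMap:
    """Per-node scalar response at the target frequency."""

    values: np.ndarray
    f_target: float
    subject_id: str = ""
    condition: str = ""
    node_id: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite response values")
        object.__setattr__(self, "values", v)
        if self.node_id is not None and len(self.node_id) != v.size:
            raise ValueError("node_id length mismatch")


def filter_and_downsample(data: np.ndarray, fs: float,
                          band: tuple[float, float] = (0.1, 100.0),
                          fs_new: float = 250.0,
                          order: int = 8) -> np.ndarray:
    """Zero-phase Butterworth band-pass, then integer-factor decimation.

    ``data`` has time on the last axis. The decimation factor ``fs/fs_new``
    must be an integer; decimation uses a zero-phase FIR anti-alias filter.
    """
    low, high = band
    if not low < high:
        raise ValueError(f"band limits inverted: {band}")
    if fs_new > fs:
        raise ValueError("fs_new must not exceed fs")
    if high >= fs_new / 2:
        raise ValueError("band upper edge must be below the new Nyquist")
    q = fs / fs_new
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"fs/fs_new = {q} is not an integer decimation factor")
    q = int(round(q))
    sos = scipy.signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, np.asarray(data, float), axis=-1)
    if q == 1:
        return filtered
    return scipy.signal.decimate(filtered, q, ftype="fir", zero_phase=True, axis=-1)


def average_epochs(trials: np.ndarray) -> np.ndarray:
    """Arithmetic mean over the trial axis (coherent averaging)."""
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3 or trials.shape[0] < 1:
        raise ValueError("trials must be a non-empty (trials, sensors, samples) array")
    return trials.mean(axis=0)


def compute_spectrum(epoch: np.ndarray, fs: float,
                     sensor_id: tuple[str, ...] | None = None
                     ) -> AmplitudeSpectrum:
    """One-sided amplitude spectrum of a (sensor x time) epoch."""
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    n = epoch.shape[-1]
    if n < 2:
        raise ValueError("epoch must have at least 2 samples")
    if not np.all(np.isfinite(epoch)):
        raise ValueError("non-finite input")
    x = np.fft.rfft(epoch, axis=-1)
    amp = np.abs(x) / n
    amp[:, 1:] *= 2.0
    if n % 2 == 0:
        amp[:, -1] /= 2.0          # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, 1 / fs)
    return AmplitudeSpectrum(amplitudes=amp, freqs=freqs, resolution=fs / n,
                             corrected=False, sensor_id=sensor_id)


def combine_planar(spectrum: AmplitudeSpectrum, layout: SensorLayout
                   ) -> AmplitudeSpectrum:
    """Root-sum-of-squares combination of planar gradiometer pairs.

    The spectrum's sensor axis must match ``layout``. Returns one row per
    complete pair, labelled by pair_id.
    """
    if spectrum.n_sensors != len(layout):
        raise ValueError("spectrum sensor axis does not match layout")
    pairs = layout.pairs()
    grads = set(layout.select("grad").tolist())
    paired = {i for members in pairs.values() for i in members}
    unpaired = sorted(grads - paired)
    if unpaired:
        ids = [layout.sensor_id[i] for i in unpaired]
        raise ValueError(f"gradiometers without a complete pair: {ids}")
    pair_ids = sorted(pairs)
    rows = np.array([
        np.sqrt(spectrum.amplitudes[pairs[p][0]] ** 2
                + spectrum.amplitudes[pairs[p][1]] ** 2)
        for p in pair_ids])
    return replace(spectrum, amplitudes=rows, sensor_id=tuple(pair_ids))


def _candidate_offsets(cfg: BaselineCorrectionConfig) -> np.ndarray:
    """Signed offsets of candidate bins relative to the corrected bin."""
    per_side = np.arange(cfg.n_adjacent_excluded + 1,
                         cfg.window_per_side + 1)
    return np.concatenate([-per_side[::-1], per_side])


def baseline_correct(spectrum: AmplitudeSpectrum,
                     cfg: BaselineCorrectionConfig | None = None
                     ) -> AmplitudeSpectrum:
    """Subtract the local noise floor estimated from surrounding bins.

    For each bin: pool the candidate bins from both sides (skipping the
    immediately adjacent ones), optionally drop the single largest and
    single smallest pooled value, and subtract the mean of the remainder.
    Bins whose candidate window leaves the spectrum are marked undefined.
    """
    if spectrum.corrected:
        raise ValueError("spectrum is already baseline-corrected")
    cfg = cfg or BaselineCorrectionConfig()
    amp = spectrum.amplitudes
    n_bins = amp.shape[1]
    offsets = _candidate_offsets(cfg)
    w = cfg.window_per_side
    defined = np.zeros(n_bins, dtype=bool)
    interior = np.arange(w, n_bins - w)
    defined[interior] = True
    corrected = np.zeros_like(amp)
    if interior.size:
        idx = interior[:, None] + offsets[None, :]      # (n_interior, n_cand)
        cand = amp[:, idx]                              # (sensors, interior, cand)
        total = cand.sum(axis=-1)
        count = offsets.size
        if cfg.exclude_extremes:
            total = total - cand.max(axis=-1) - cand.min(axis=-1)
            count -= 2
        corrected[:, interior] = amp[:, interior] - total / count
    return replace(spectrum, amplitudes=corrected, corrected=True,
                   defined=defined)


def extract_response(spectrum: AmplitudeSpectrum, f_target: float,
                     subject_id: str = "", condition: str = "") -> ResponseMap:
    """Read the corrected amplitude at the bin nearest ``f_target``.

    Errors if the nearest bin lies more than half a bin away (target
    outside the spectrum grid) or is undefined after edge handling.
    """
    if not spectrum.corrected:
        raise ValueError("extract_response requires a baseline-corrected spectrum")
    b = spectrum.bin_of(f_target)
    miss = abs(spectrum.freqs[b] - f_target)
    if miss > spectrum.resolution / 2 + 1e-9:
        raise ValueError(
            f"target {f_target} Hz is {miss:.6g} Hz from the nearest bin "
            f"({spectrum.freqs[b]:.6g} Hz); beyond half the {spectrum.resolution:.6g} Hz resolution")
    if not spectrum.defined[b]:
        raise ValueError(
            f"bin at {spectrum.freqs[b]:.6g} Hz is undefined after edge handling")
    return ResponseMap(values=spectrum.amplitudes[:, b].copy(),
                       f_target=f_target, subject_id=subject_id,
                       condition=condition, node_id=spectrum.sensor_id)


def epochs_to_response(epochs: EpochSet, f_target: float = 3.0,
                       cfg: BaselineCorrectionConfig | None = None,
                       layout: SensorLayout | None = None,
                       sensor_set: str = "all",
                       coherent: bool = True) -> ResponseMap:
    """Full quantification of one EpochSet: average, FFT, correct, extract.

    ``sensor_set`` selects ``"all"`` sensors, ``"mag"`` only, or
    ``"grad"`` (planar pairs combined by root-sum-of-squares; requires
    ``layout``). ``coherent=False`` averages per-trial amplitude spectra
    instead of Fourier-transforming the trial average.
    """
    data = epochs.data
    ids = layout.sensor_id if layout is not None else None
    if coherent:
        spec = compute_spectrum(average_epochs(data), epochs.fs, sensor_id=ids)
    else:
        per_trial = [compute_spectrum(tr, epochs.fs, sensor_id=ids)
                     for tr in data]
        spec = replace(per_trial[0], amplitudes=np.mean(
            [s.amplitudes for s in per_trial], axis=0))
    if sensor_set == "grad":
        if layout is None:
            raise ValueError("sensor_set='grad' requires a layout")
        spec = combine_planar(spec, layout)
    elif sensor_set == "mag":
        if layout is None:
            raise ValueError("sensor_set='mag' requires a layout")
        sel = layout.select("mag")
        spec = replace(spec, amplitudes=spec.amplitudes[sel],
                       sensor_id=tuple(layout.sensor_id[i] for i in sel))
    elif sensor_set != "all":
        raise ValueError(f"unknown sensor_set {sensor_set!r}")
    corrected = baseline_correct(spec, cfg)
    return extract_response(corrected, f_target,
                            subject_id=epochs.subject_id,
                            condition=epochs.condition)
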