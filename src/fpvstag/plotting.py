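"""Basic spectrum plots (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .spectral import AmplitudeSpectrum


def plot_spectrum(spectrum: AmplitudeSpectrum, sensors=None, fmax: float = 20.0,
                  mark: tuple[float, ...] = (3.0, 6.0), ax=None):
    """Amplitude vs frequency, averaged over selected sensors.

    ``mark`` frequencies get dashed vertical guides (the tagged rates by
    default). Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    sel = np.arange(spectrum.n_sensors) if sensors is None else np.asarray(sensors)
    keep = spectrum.freqs <= fmax
    mean_amp = spectrum.amplitudes[sel].mean(axis=0)
    ax.plot(spectrum.freqs[keep], mean_amp[keep], lw=0.8, color="k")
    for f in mark:
        ax.axvline(f, ls="--", lw=0.6, color="tab:red", alpha=0.6)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("amplitude" + (" (corrected)" if spectrum.corrected else ""))
    ax.set_xlim(0, fmax)
    return ax
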