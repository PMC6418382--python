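"""Stimulus-evoked ECoG characterization: triggered averaging, Morlet
time–frequency transform, and peak (time, frequency, amplitude) extraction.

The per-animal average ECoG trace is passed through a bank of complex Morlet
wavelets; the evoked wave is summarized by the coordinates of the maximum of
the coefficient magnitude inside a frequency band and a post-anchor time
window (default 15–40 Hz within 100 ms after stimulation offset).  The
magnitude is scaled so a sustained unit-amplitude sinusoid at frequency f
yields peak magnitude 1 at f, making the reported amplitude directly
comparable to the µV amplitude of a sustained oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .io import ContinuousSignal, EventSeries
from .kinematics import StimAverage, stim_triggered_average

__all__ = [
    "TFPeak",
    "triggered_ecog_average",
    "morlet_tf",
    "find_tf_peak",
    "evoked_tf_peak",
]

DEFAULT_BAND = (15.0, 40.0)
DEFAULT_WINDOW = (0.0, 0.1)


@dataclass
class TFPeak:
    """Dominant time–frequency peak inside a band/window."""

    time: float        # s relative to the window anchor
    frequency: float   # Hz
    amplitude: float   # coefficient magnitude, µV-equivalent
    band: tuple[float, float]
    window: tuple[float, float]
    at_boundary: bool = False  # peak sits on the window/band edge
    degenerate: bool = False   # flat input; time/frequency arbitrary


def triggered_ecog_average(
    sig: ContinuousSignal,
    events: EventSeries,
    window: tuple[float, float],
    anchor: str = "offset",
    trial_mask: np.ndarray | None = None,
) -> StimAverage:
    """Mean ECoG trace across trials, optionally restricted (e.g. rest-only) by a mask."""
    return stim_triggered_average(
        sig.samples, sig.fs, events, window, anchor=anchor, t0=sig.t0,
        trial_mask=trial_mask,
    )


def _morlet_kernel(f: float, fs: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet kernel normalized so a unit sinusoid at f gives magnitude 1."""
    sigma_t = n_cycles / (2 * np.pi * f)
    half = int(np.ceil(3 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    g = np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    kernel = g * np.exp(2j * np.pi * f * t)
    # a unit cosine contributes g/2 per sample at the analytic frequency
    return kernel / (g.sum() / 2.0)


def morlet_tf(
    samples: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    n_cycles: float = 7.0,
) -> np.ndarray:
    """Complex Morlet coefficients, shape (n_freqs, n_times).

    Raises on frequencies at or above Nyquist.  Edges of the input are
    zero-padded by the kernel half-width; callers analysing a window should
    provide a margin of ~3 wavelet widths around it (see ``evoked_tf_peak``).
    """
    x = np.asarray(samples, dtype=float)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs >= fs / 2):
        raise ValueError("frequencies must be below Nyquist")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    out = np.empty((freqs.size, x.size), dtype=complex)
    for i, f in enumerate(freqs):
        k = _morlet_kernel(f, fs, n_cycles)
        out[i] = fftconvolve(x, k, mode="same")
    return out


def find_tf_peak(
    tfmap: np.ndarray,
    times: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> TFPeak:
    """Argmax of |coefficient| restricted to ``band`` × ``window``."""
    times = np.asarray(times, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    fi = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    ti = np.flatnonzero((times >= window[0]) & (times <= window[1]))
    if fi.size == 0 or ti.size == 0:
        raise ValueError("band/window selects no time–frequency points")
    mag = np.abs(tfmap[np.ix_(fi, ti)])
    j = np.unravel_index(int(np.argmax(mag)), mag.shape)
    amp = float(mag[j])
    at_boundary = j[0] in (0, fi.size - 1) or j[1] in (0, ti.size - 1)
    return TFPeak(
        time=float(times[ti[j[1]]]),
        frequency=float(freqs[fi[j[0]]]),
        amplitude=amp,
        band=band,
        window=window,
        at_boundary=bool(at_boundary and amp > 0),
        degenerate=amp == 0.0,
    )


def evoked_tf_peak(
    sig: ContinuousSignal,
    events: EventSeries,
    band: tuple[float, float] = DEFAULT_BAND,
    window: tuple[float, float] = DEFAULT_WINDOW,
    anchor: str = "offset",
    n_cycles: float = 7.0,
    freq_step: float = 1.0,
    trial_mask: np.ndarray | None = None,
) -> TFPeak:
    """Average across trials, Morlet-transform, and locate the band/window peak.

    The average is epoched with a margin of 3 wavelet widths at the lowest
    band frequency on both sides, so the analysed window is free of edge
    artifacts; the margin is cropped before the peak search.
    """
    pad = 3 * n_cycles / (2 * np.pi * band[0])
    avg = triggered_ecog_average(
        sig, events, (window[0] - pad, window[1] + pad), anchor=anchor,
        trial_mask=trial_mask,
    )
    freqs = np.arange(band[0], band[1] + freq_step / 2, freq_step)
    tfmap = morlet_tf(avg.mean, sig.fs, freqs, n_cycles=n_cycles)
    return find_tf_peak(tfmap, avg.t, freqs, band=band, window=window)
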