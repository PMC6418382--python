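"""Synthetic recordings with known ground truth for every analysis stage.

The generators emulate the study conditions of a head-fixed-free mouse
optogenetics experiment: 1 s stimulation pulses delivered at 0.25 Hz; a
head-mounted IMU sampled at 200 Hz (5 ms resolution) carrying, per trial, a
Gaussian-profile rotational-speed bump whose axis is drawn around a mean axis
with von Mises–Fisher dispersion; a 1/f-background ECoG carrying a Gaussian-
envelope oscillatory wave packet after each stimulation offset; gamma-renewal
spike trains (with Poisson-burst injection, and Purkinje simple/complex-spike
mixtures including slow, down-state-riddled firing); correlated-random-walk
open-field trajectories with pauses; and elliptical body contours of
controlled elongation.

Every generator returns the artifact together with the ground-truth record
used to build it, sufficient to predict the expected analysis output without
re-reading the signal.  Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .behavior import Contour, Trajectory
from .io import ContinuousSignal, EventSeries
from .kinematics import InertialRecord
from .spiketrains import SpikeTrain, Waveform

__all__ = [
    "SimConfig",
    "gen_spike_train",
    "inject_bursts",
    "gen_purkinje_train",
    "sample_axes_vmf",
    "gen_inertial",
    "gen_ecog",
    "gen_trajectory",
    "gen_contour",
    "default_templates",
    "gen_raw_trace",
]


@dataclass(frozen=True)
class SimConfig:
    """Global simulation parameters mirroring the experimental protocol."""

    seed: int = 0
    duration_s: float = 120.0
    fs_signal: float = 1000.0   # ECoG / raw-trace sampling (Hz)
    fs_imu: float = 200.0       # inertial sampling: 5 ms resolution
    stim_period_s: float = 4.0  # 0.25 Hz stimulation
    stim_duration_s: float = 1.0

    def __post_init__(self) -> None:
        if min(self.duration_s, self.fs_signal, self.fs_imu,
               self.stim_period_s, self.stim_duration_s) <= 0:
            raise ValueError("all durations and rates must be positive")
        if self.stim_duration_s >= self.stim_period_s:
            raise ValueError("stim_duration_s must be below stim_period_s")

    def events(self, post_margin_s: float = 1.0) -> EventSeries:
        """Stimulation onsets/offsets; first onset after one full period,
        last offset leaving ``post_margin_s`` of recording."""
        onsets = np.arange(
            self.stim_period_s,
            self.duration_s - self.stim_duration_s - post_margin_s,
            self.stim_period_s,
        )
        if onsets.size == 0:
            raise ValueError("recording too short for a single stimulation")
        return EventSeries(onsets, onsets + self.stim_duration_s)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ----------------------------------------------------------------- spikes


def gen_spike_train(
    rate: float,
    duration: float,
    shape: float = 1.0,
    seed=0,
    t_start: float = 0.0,
    unit_id: str = "unit0",
) -> SpikeTrain:
    """Gamma-renewal spike train: ISIs ~ Gamma(shape, 1/(rate*shape)).

    shape=1 is Poisson; large shape approaches a regular (clock-like) train.
    Expected count is rate * duration.
    """
    if rate < 0 or duration <= 0:
        raise ValueError("rate must be >= 0 and duration > 0")
    if shape < 1:
        raise ValueError("gamma order must be >= 1")
    span = (t_start, t_start + duration)
    if rate == 0:
        return SpikeTrain(np.array([]), span, unit_id=unit_id)
    rng = _rng(seed)
    n_draw = int(rate * duration + 10 * np.sqrt(rate * duration) + 20)
    times = t_start + np.cumsum(rng.gamma(shape, 1.0 / (rate * shape), size=n_draw))
    while times.size and times[-1] < span[1]:
        extra = t_start if not times.size else times[-1]
        times = np.concatenate(
            [times, extra + np.cumsum(rng.gamma(shape, 1.0 / (rate * shape), size=n_draw))]
        )
    times = times[times < span[1]]
    return SpikeTrain(times, span, unit_id=unit_id)


def inject_bursts(
    train: SpikeTrain,
    burst_rate: float,
    spikes_per_burst: int = 5,
    intra_isi: float = 0.003,
    seed=0,
) -> tuple[SpikeTrain, list[tuple[float, float]]]:
    """Superimpose Poisson-timed bursts of regular high-frequency spikes.

    Returns the merged sorted train plus the truth windows (start, end) that
    cover exactly the injected spikes; overlapping injected windows are merged.
    """
    if burst_rate < 0:
        raise ValueError("burst_rate must be >= 0")
    if burst_rate == 0:
        return train, []
    rng = _rng(seed)
    t0, t1 = train.span
    burst_len = (spikes_per_burst - 1) * intra_isi
    n_bursts = rng.poisson(burst_rate * (t1 - t0 - burst_len))
    starts = np.sort(rng.uniform(t0, t1 - burst_len, size=n_bursts))
    new_spikes = (starts[:, None] + np.arange(spikes_per_burst) * intra_isi).ravel()
    merged = np.unique(np.concatenate([train.times, new_spikes]))
    # strictly increasing: nudge exact duplicates is handled by unique; enforce
    windows: list[list[float]] = []
    for s in starts:
        w = [s, s + burst_len]
        if windows and w[0] <= windows[-1][1]:
            windows[-1][1] = max(windows[-1][1], w[1])
        else:
            windows.append(w)
    out = SpikeTrain(merged, train.span, unit_id=train.unit_id)
    return out, [tuple(w) for w in windows]


def gen_purkinje_train(
    mode: str,
    duration: float = 60.0,
    seed=0,
    unit_id: str = "pc0",
) -> SpikeTrain:
    """Purkinje-cell train with per-spike simple/complex labels.

    ``normal``: ~55 Hz simple spikes plus ~1 Hz complex spikes (overall within
    the 40–80 Hz tonic range).  ``slow``: sparse simple firing interrupted by
    silent down-states, overall rate below 10 Hz.  ``cs_only``: complex spikes
    only, ~1 Hz.
    """
    rng = _rng(seed)
    span = (0.0, duration)
    if mode == "normal":
        ss = gen_spike_train(55.0, duration, shape=4.0, seed=rng).times
        cs = gen_spike_train(1.0, duration, shape=1.0, seed=rng).times
    elif mode == "slow":
        # alternating up (mean 1.5 s) / down (mean 3 s) states; simple spikes
        # at 8 Hz only during up states
        edges, up = [0.0], []
        state_up = bool(rng.integers(2))
        t = 0.0
        while t < duration:
            dur = rng.exponential(1.5 if state_up else 3.0)
            t = min(t + dur, duration)
            edges.append(t)
            up.append(state_up)
            state_up = not state_up
        raw = gen_spike_train(8.0, duration, shape=2.0, seed=rng).times
        keep = np.zeros(raw.size, dtype=bool)
        for (a, b), is_up in zip(zip(edges[:-1], edges[1:]), up):
            if is_up:
                keep |= (raw >= a) & (raw < b)
        ss = raw[keep]
        cs = gen_spike_train(1.0, duration, shape=1.0, seed=rng).times
    elif mode == "cs_only":
        ss = np.array([])
        cs = gen_spike_train(1.0, duration, shape=1.0, seed=rng).times
    else:
        raise ValueError(f"unknown Purkinje mode {mode!r}")
    times = np.concatenate([ss, cs])
    labels = np.concatenate([np.repeat("simple", ss.size), np.repeat("complex", cs.size)])
    order = np.argsort(times)
    times, labels = times[order], labels[order]
    # drop pathological coincidences to keep times strictly increasing
    if times.size:
        keep = np.concatenate([[True], np.diff(times) > 0])
        times, labels = times[keep], labels[keep]
    return SpikeTrain(times, span, labels=labels, unit_id=unit_id)


# ----------------------------------------------------------------- inertial


def sample_axes_vmf(axis: np.ndarray, kappa: float, n: int, rng) -> np.ndarray:
    """n unit vectors with von Mises–Fisher dispersion kappa around ``axis``.

    kappa = 0 is isotropic; kappa >= 1e6 returns the mean axis exactly.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa >= 1e6:
        return np.tile(axis, (n, 1))
    if kappa == 0:
        v = rng.standard_normal((n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    return stats.vonmises_fisher(mu=axis, kappa=kappa).rvs(n, random_state=rng)


def gen_inertial(
    config: SimConfig,
    events: EventSeries,
    axis=(0.0, 0.0, 1.0),
    kappa: float = 50.0,
    peak_speed: float = 38.0,
    latency: float = 0.2,
    width: float = 0.05,
    baseline_speed: float = 5.0,
    seed=0,
    gravity_axis=(0.0, 0.0, -1.0),
    accel_noise_sd: float = 0.02,
    active_prob: float = 0.0,
) -> tuple[InertialRecord, dict]:
    """IMU record with a stimulus-locked rotation bump per trial.

    Each trial's angular-velocity channels carry a Gaussian speed profile of
    amplitude ``peak_speed`` (deg/s) peaking at offset + ``latency`` along an
    axis drawn around ``axis`` with vMF dispersion ``kappa``.  The baseline is
    white gyro noise scaled so the resting rotational speed is about
    ``baseline_speed``; acceleration channels carry constant 1 g gravity along
    ``gravity_axis`` plus noise.  With ``active_prob`` > 0 a random subset of
    trials also receives a pre-onset bump, making them *active* trials.

    Truth dict: per-event ``axes``, ``latency``, ``peak_speed``, ``width``,
    and boolean ``active`` flags.
    """
    rng = _rng(seed)
    n = int(round(config.duration_s * config.fs_imu))
    t = np.arange(n) / config.fs_imu
    n_ev = len(events)
    axes = sample_axes_vmf(axis, kappa, n_ev, rng)

    gyro = (
        rng.standard_normal((n, 3)) * (baseline_speed / np.sqrt(3.0))
        if baseline_speed > 0
        else np.zeros((n, 3))
    )
    active = rng.random(n_ev) < active_prob
    for k in range(n_ev):
        t_pk = events.offsets[k] + latency
        prof = peak_speed * np.exp(-((t - t_pk) ** 2) / (2 * width ** 2))
        gyro += prof[:, None] * axes[k]
        if active[k]:
            pre_axis = sample_axes_vmf(axis, 0.0, 1, rng)[0]
            prof = 40.0 * np.exp(-((t - (events.onsets[k] - 0.5)) ** 2) / (2 * 0.05 ** 2))
            gyro += prof[:, None] * pre_axis

    g = np.asarray(gravity_axis, dtype=float)
    g = g / np.linalg.norm(g)
    accel = g[None, :] + rng.standard_normal((n, 3)) * accel_noise_sd
    truth = {
        "axes": axes,
        "latency": latency,
        "peak_speed": peak_speed,
        "width": width,
        "active": active,
        "gravity_axis": g,
        "mean_axis": np.asarray(axis, dtype=float) / np.linalg.norm(axis),
        "kappa": kappa,
    }
    return InertialRecord(accel, gyro, config.fs_imu), truth


# ----------------------------------------------------------------- ECoG


def one_over_f_noise(
    n: int, fs: float, exponent: float = 1.0, rms: float = 50.0, rng=None
) -> np.ndarray:
    """Gaussian 1/f^exponent background scaled to the requested RMS (µV)."""
    rng = _rng(rng)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    # flatten below 1 Hz to keep finite low-frequency power
    amp[nz] = np.maximum(freqs[nz], 1.0) ** (-exponent / 2)
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    x *= rms / np.sqrt(np.mean(x ** 2))
    return x


def gen_ecog(
    config: SimConfig,
    events: EventSeries,
    wave_amp: float = 40.0,
    wave_freq: float = 25.0,
    wave_latency: float = 0.04,
    wave_decay: float = 0.04,
    noise_exponent: float = 1.0,
    noise_rms: float = 50.0,
    seed=0,
) -> tuple[ContinuousSignal, dict]:
    """1/f-background ECoG plus a stimulus-offset-locked oscillatory wave.

    The evoked wave is a Gaussian-envelope packet
    ``amp * cos(2π f (t - tc)) * exp(-(t - tc)² / (2 decay²))`` centered at
    ``tc = offset + latency``, so the injected latency is the time of the
    largest oscillation — the quantity the time–frequency peak reports.
    """
    if wave_freq >= config.fs_signal / 2:
        raise ValueError("wave frequency at or above Nyquist")
    rng = _rng(seed)
    n = int(round(config.duration_s * config.fs_signal))
    t = np.arange(n) / config.fs_signal
    x = (
        one_over_f_noise(n, config.fs_signal, noise_exponent, noise_rms, rng)
        if noise_rms > 0
        else np.zeros(n)
    )
    for off in events.offsets:
        tc = off + wave_latency
        sel = np.abs(t - tc) < 5 * wave_decay
        x[sel] += (
            wave_amp
            * np.cos(2 * np.pi * wave_freq * (t[sel] - tc))
            * np.exp(-((t[sel] - tc) ** 2) / (2 * wave_decay ** 2))
        )
    truth = {
        "wave_amp": wave_amp,
        "wave_freq": wave_freq,
        "wave_latency": wave_latency,
        "wave_decay": wave_decay,
        "noise_rms": noise_rms,
    }
    return ContinuousSignal(x, config.fs_signal, name="ecog"), truth


# ----------------------------------------------------------------- behavior


def gen_trajectory(
    duration: float = 300.0,
    fs: float = 25.0,
    arena_radius: float = 19.0,
    mean_speed: float = 9.0,
    pause_prob: float = 0.0,
    seed=0,
    mean_pause_s: float = 2.0,
) -> tuple[Trajectory, dict]:
    """Correlated random walk in a circular arena with pauses.

    The animal alternates between moving and paused states; the stationary
    pause probability equals ``pause_prob``.  While moving, per-step speed is
    ``mean_speed`` with mild gamma variability and the heading performs a
    random walk; the walk reflects at the arena wall.  Truth holds the pause
    intervals (zero displacement) and a video-style frame-change percent
    series coupled to them (moving ≈ 2%, paused ≈ 0.3%).
    """
    if arena_radius <= 0:
        raise ValueError("arena_radius must be positive")
    if not 0 <= pause_prob <= 1:
        raise ValueError("pause_prob must be within [0, 1]")
    rng = _rng(seed)
    n = int(round(duration * fs))
    # two-state Markov chain with stationary P(paused) = pause_prob
    paused = np.zeros(n, dtype=bool)
    if pause_prob >= 1.0:
        paused[:] = True
    elif pause_prob > 0:
        p_leave_pause = 1.0 / (mean_pause_s * fs)
        p_enter_pause = p_leave_pause * pause_prob / (1 - pause_prob)
        state = rng.random() < pause_prob
        for i in range(n):
            paused[i] = state
            if state:
                state = not (rng.random() < p_leave_pause)
            else:
                state = rng.random() < p_enter_pause
    x = np.empty(n)
    y = np.empty(n)
    x[0] = y[0] = 0.0
    heading = rng.uniform(0, 2 * np.pi)
    for i in range(1, n):
        if paused[i]:
            x[i], y[i] = x[i - 1], y[i - 1]
            continue
        heading += rng.normal(0, 0.4)
        speed = mean_speed * rng.gamma(25.0, 1 / 25.0)
        nx = x[i - 1] + speed / fs * np.cos(heading)
        ny = y[i - 1] + speed / fs * np.sin(heading)
        r = np.hypot(nx, ny)
        if r > arena_radius:  # reflect at the wall
            nx, ny = nx * arena_radius / r, ny * arena_radius / r
            heading += np.pi / 2 + rng.normal(0, 0.2)
        x[i], y[i] = nx, ny
    pauses = []
    d = np.diff(np.concatenate([[0], paused.astype(int), [0]]))
    for i0, i1 in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        pauses.append((i0 / fs, i1 / fs))
    frame_change = np.where(paused, 0.3, 2.0) + rng.normal(0, 0.05, size=n)
    truth = {"pauses": pauses, "paused": paused, "frame_change": frame_change,
             "mean_speed": mean_speed, "pause_prob": pause_prob}
    return Trajectory(x, y, fs), truth


def gen_contour(
    aspect_ratio: float,
    n_points: int = 64,
    seed=0,
    rotate: bool = True,
    center=(0.0, 0.0),
    scale: float = 1.0,
) -> tuple[Contour, dict]:
    """Points on an ellipse with semi-axes (a, b) = (aspect_ratio, 1) * scale,
    uniform in parameter angle, optionally rotated and translated.

    The closed-form elongation of such a contour is
    ``100 * (a² - b²) / (a² + b²)``.
    """
    if aspect_ratio < 1:
        raise ValueError("aspect_ratio must be >= 1")
    if n_points < 8:
        raise ValueError("need at least 8 contour points")
    rng = _rng(seed)
    theta = np.arange(n_points) * 2 * np.pi / n_points
    a, b = aspect_ratio * scale, 1.0 * scale
    pts = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
    if rotate:
        phi = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        pts = pts @ rot.T
    pts += np.asarray(center, dtype=float)
    expected = 100.0 * (a ** 2 - b ** 2) / (a ** 2 + b ** 2)
    return Contour(pts), {"aspect_ratio": aspect_ratio, "expected_elongation": expected}


# ----------------------------------------------------------------- raw traces


def default_templates(fs: float = 25_000.0) -> list[np.ndarray]:
    """Three distinct biphasic extracellular spike templates (µV at ``fs``)."""
    t = np.arange(int(0.002 * fs)) / fs * 1000.0  # 2 ms in ms
    shapes = []
    for trough_ms, trough_amp, width_ms, peak_amp, peak_lag in (
        (0.6, -100.0, 0.10, 35.0, 0.30),
        (0.6, -80.0, 0.18, 50.0, 0.55),
        (0.6, -120.0, 0.14, 20.0, 0.80),
    ):
        w = trough_amp * np.exp(-((t - trough_ms) ** 2) / (2 * width_ms ** 2))
        w += peak_amp * np.exp(-((t - trough_ms - peak_lag) ** 2) / (2 * (2 * width_ms) ** 2))
        shapes.append(w)
    return shapes


def gen_raw_trace(
    templates: list[np.ndarray],
    unit_rates,
    noise_sd: float,
    fs: float = 25_000.0,
    duration: float = 20.0,
    seed=0,
) -> tuple[ContinuousSignal, dict]:
    """Noise plus spike templates inserted at Poisson times (1 ms refractory).

    Truth: per-spike ``times`` (template-trough-aligned, s) and ``labels``
    (template indices).
    """
    unit_rates = np.atleast_1d(np.asarray(unit_rates, dtype=float))
    if len(templates) != unit_rates.size:
        raise ValueError("one rate per template")
    lengths = {len(tp) for tp in templates}
    if len(lengths) != 1:
        raise ValueError("templates must share a length")
    n = int(round(duration * fs))
    tpl_len = lengths.pop()
    if tpl_len > n:
        raise ValueError("template longer than the trace")
    rng = _rng(seed)
    x = rng.standard_normal(n) * noise_sd if noise_sd > 0 else np.zeros(n)
    all_times, all_labels = [], []
    margin = tpl_len / fs
    for u, (tpl, rate) in enumerate(zip(templates, unit_rates)):
        if rate <= 0:
            continue
        tr = gen_spike_train(rate, duration - 2 * margin, shape=1.0, seed=rng,
                             t_start=margin)
        # enforce the 1 ms refractory within the unit
        times = tr.times
        if times.size:
            keep = np.concatenate([[True], np.diff(times) >= 0.001])
            times = times[keep]
        i_trough = int(np.argmin(tpl))
        for s in times:
            i0 = int(round(s * fs)) - i_trough
            x[i0 : i0 + tpl_len] += tpl
        all_times.append(times)
        all_labels.append(np.full(times.size, u))
    if all_times:
        times = np.concatenate(all_times)
        labels = np.concatenate(all_labels)
        order = np.argsort(times)
        times, labels = times[order], labels[order]
    else:
        times, labels = np.array([]), np.array([], dtype=int)
    truth = {"times": times, "labels": labels, "templates": templates}
    return ContinuousSignal(x, fs, name="raw"), truth
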