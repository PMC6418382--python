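"""Head-movement kinematics from a head-mounted inertial sensor.

The analysis chain mirrors how stimulation-evoked head rotations are
quantified in freely moving mice: the instantaneous rotational speed is the
Euclidean norm of the 3-axis angular velocity; head immobility is any run of
at least 1 s spent strictly below 20 deg/s; trials are classified *rest* or
*active* from the second preceding stimulation onset; per-trial peak
rotations are located inside a *during*- or *post*-stimulation window; and
the consistency of the evoked rotation axes is summarised by the resultant
vector

    v = (1/N) * sum_i  omega_i_peak / |omega_i_peak|      over |omega_i_peak| > 10 deg/s,

whose length is 1 for perfectly aligned axes and tends to 0 for random ones.
A session is called directionally *biased* when its resultant length falls
outside the 2.5–97.5% band of resultant lengths obtained from 10 000 Monte
Carlo draws of N uniformly random unit vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import EventSeries

logger = logging.getLogger(__name__)

__all__ = [
    "InertialRecord",
    "RotationEvent",
    "ResultantSummary",
    "MonteCarloNull",
    "ImmobilitySegments",
    "StimAverage",
    "rotational_speed",
    "segment_immobility",
    "classify_trials",
    "stim_triggered_average",
    "detect_peak_rotation",
    "resultant_vector",
    "mc_null_resultant",
    "alignment_test",
    "estimate_gravity",
    "orientation_vs_vertical",
]

#: default immobility / rest threshold on rotational speed (deg/s)
IMMOBILITY_THRESHOLD = 20.0
#: default trial-inclusion threshold on the peak rotational speed (deg/s)
RESULTANT_MIN_SPEED = 10.0
#: reporting filter on resultant length used when plotting orientation summaries
GOOD_ALIGNMENT_LENGTH = 0.4


@dataclass
class InertialRecord:
    """Synchronized 3-axis acceleration (g) and 3-axis angular velocity (deg/s)."""

    accel: np.ndarray  # (n, 3) in g: Ax, Ay, Az
    gyro: np.ndarray   # (n, 3) in deg/s: wx, wy, wz
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel must be (n, 3)")
        if self.gyro.shape != self.accel.shape:
            raise ValueError("gyro and accel must have the same shape")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def to_file(self, prefix) -> None:
        from .io import write_signal

        data = np.hstack([self.accel, self.gyro])
        write_signal(
            prefix, data, self.fs,
            ["Ax", "Ay", "Az", "wx", "wy", "wz"],
            units="g,g,g,deg/s,deg/s,deg/s", t0=self.t0,
        )

    @classmethod
    def from_file(cls, prefix) -> "InertialRecord":
        from .io import read_signal

        data, meta = read_signal(prefix)
        if data.shape[1] != 6:
            raise ValueError("inertial records need 6 channels (Ax..Az, wx..wz)")
        return cls(data[:, :3], data[:, 3:], meta["fs"], meta.get("t0", 0.0))


@dataclass
class RotationEvent:
    """Per-trial peak rotation: speed, latency from the phase anchor, and axis."""

    trial_index: int
    phase: str  # "during" | "post"
    peak_speed: float
    latency: float
    axis: np.ndarray
    flagged: bool = False  # True when the gyro was all-zero and the axis is undefined

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if self.peak_speed < 0:
            raise ValueError("peak_speed must be nonnegative")


@dataclass
class ResultantSummary:
    length: float
    direction: np.ndarray
    n_trials_used: int
    inclusion_threshold: float = RESULTANT_MIN_SPEED
    angle_to_vertical: float | None = None


@dataclass
class MonteCarloNull:
    """Null distribution of resultant lengths for N uniform random unit vectors."""

    n: np.ndarray            # N = 1..n_max
    mean_length: np.ndarray
    lo: np.ndarray           # 2.5th percentile
    hi: np.ndarray           # 97.5th percentile
    n_samples: int
    seed: int

    @property
    def n_max(self) -> int:
        return int(self.n[-1])


@dataclass
class ImmobilitySegments:
    segments: list  # list of (start_s, end_s)
    threshold: float = IMMOBILITY_THRESHOLD
    min_duration: float = 1.0

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def total_duration(self) -> float:
        return float(sum(e - s for s, e in self.segments))


@dataclass
class StimAverage:
    t: np.ndarray      # time relative to the anchor
    mean: np.ndarray
    sd: np.ndarray
    n_trials: int


def rotational_speed(rec: InertialRecord) -> np.ndarray:
    """Per-sample Euclidean norm of the angular-velocity vector, in deg/s."""
    gyro = np.asarray(rec.gyro, dtype=float) if isinstance(rec, InertialRecord) else np.asarray(rec, dtype=float)
    if gyro.ndim != 2 or gyro.shape[1] != 3:
        raise ValueError("need three gyroscope channels")
    return np.linalg.norm(gyro, axis=1)


def _runs_below(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as half-open index pairs (i0, i1)."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def segment_immobility(
    speed: np.ndarray,
    fs: float,
    threshold: float = IMMOBILITY_THRESHOLD,
    min_duration: float = 1.0,
    t0: float = 0.0,
) -> ImmobilitySegments:
    """Maximal runs of speed strictly below ``threshold`` lasting at least ``min_duration``.

    Samples exactly at the threshold are excluded (strict comparison).
    """
    speed = np.asarray(speed, dtype=float)
    segments = []
    for i0, i1 in _runs_below(speed < threshold):
        dur = (i1 - i0) / fs
        if dur >= min_duration:
            segments.append((t0 + i0 / fs, t0 + i1 / fs))
    return ImmobilitySegments(segments, threshold, min_duration)


def classify_trials(
    events: EventSeries,
    speed: np.ndarray,
    fs: float,
    pre_window: float = 1.0,
    threshold: float = IMMOBILITY_THRESHOLD,
    t0: float = 0.0,
) -> list[str | None]:
    """Label each trial ``"rest"`` or ``"active"`` from the pre-onset second.

    A trial is *rest* iff the rotational speed stays strictly below
    ``threshold`` throughout [onset − pre_window, onset).  Trials without a
    full pre-window of history are excluded (``None``) and logged.
    """
    speed = np.asarray(speed, dtype=float)
    labels: list[str | None] = []
    for k, onset in enumerate(events.onsets):
        i1 = int(np.floor((onset - t0) * fs))
        i0 = i1 - int(round(pre_window * fs))
        if i0 < 0 or i1 > speed.size:
            logger.warning("trial %d lacks pre-stimulus history; excluded", k)
            labels.append(None)
            continue
        labels.append("rest" if np.all(speed[i0:i1] < threshold) else "active")
    return labels


def _epoch(
    signal: np.ndarray,
    fs: float,
    anchors: np.ndarray,
    window: tuple[float, float],
    t0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract sample-aligned trials; returns (trials (k, m), t_rel, kept mask)."""
    signal = np.asarray(signal, dtype=float)
    i_pre = int(round(window[0] * fs))
    i_post = int(round(window[1] * fs))
    if i_post <= i_pre:
        raise ValueError("window must have positive span")
    rows, kept = [], []
    for k, a in enumerate(anchors):
        c = int(round((a - t0) * fs))
        if c + i_pre < 0 or c + i_post > signal.size:
            logger.warning("trial %d window exceeds the recording; dropped", k)
            kept.append(False)
            continue
        rows.append(signal[c + i_pre : c + i_post])
        kept.append(True)
    t_rel = (np.arange(i_pre, i_post)) / fs
    trials = np.array(rows) if rows else np.empty((0, i_post - i_pre))
    return trials, t_rel, np.asarray(kept, dtype=bool)


def stim_triggered_average(
    signal: np.ndarray,
    fs: float,
    events: EventSeries,
    window: tuple[float, float],
    anchor: str = "onset",
    t0: float = 0.0,
    trial_mask: np.ndarray | None = None,
) -> StimAverage:
    """Stimulation-triggered mean ± sd of a series across trials."""
    anchors = events.anchors(anchor)
    if trial_mask is not None:
        anchors = anchors[np.asarray(trial_mask, dtype=bool)]
    trials, t_rel, _ = _epoch(signal, fs, anchors, window, t0)
    if trials.shape[0] == 0:
        raise ValueError("no usable trials")
    return StimAverage(
        t=t_rel,
        mean=trials.mean(axis=0),
        sd=trials.std(axis=0, ddof=0),
        n_trials=trials.shape[0],
    )


# Default peak-search windows: "during" spans the stimulation itself,
# "post" covers 600 ms after its end (the evoked rotations peak ~200 ms post-offset).
POST_WINDOW_S = 0.6


def detect_peak_rotation(
    rec: InertialRecord,
    events: EventSeries,
    phase: str = "post",
    window: tuple[float, float] | None = None,
) -> list[RotationEvent]:
    """Per trial, the peak of the rotational speed inside the phase window.

    The rotation axis is the gyro vector at the peak sample, normalized.
    ``window`` is relative to the phase anchor (onset for "during", offset for
    "post"); defaults: during = [0, stim duration], post = [0, 0.6 s].
    """
    if phase not in ("during", "post"):
        raise ValueError("phase must be 'during' or 'post'")
    speed = rotational_speed(rec)
    out: list[RotationEvent] = []
    for k in range(len(events)):
        if phase == "during":
            anchor = events.onsets[k]
            w = window if window is not None else (0.0, events.offsets[k] - events.onsets[k])
        else:
            anchor = events.offsets[k]
            w = window if window is not None else (0.0, POST_WINDOW_S)
        i0 = int(round((anchor + w[0] - rec.t0) * rec.fs))
        i1 = int(round((anchor + w[1] - rec.t0) * rec.fs))
        if i0 < 0 or i1 > rec.n_samples or i1 <= i0:
            raise ValueError(f"trial {k}: peak-search window outside the recording")
        seg = speed[i0:i1]
        j = int(np.argmax(seg))
        peak = float(seg[j])
        vec = rec.gyro[i0 + j]
        if peak > 0:
            axis = vec / np.linalg.norm(vec)
            flagged = False
        else:
            axis = np.full(3, np.nan)
            flagged = True
        out.append(RotationEvent(k, phase, peak, (i0 + j) / rec.fs + rec.t0 - anchor, axis, flagged))
    return out


def resultant_vector(
    events: list[RotationEvent],
    min_speed: float = RESULTANT_MIN_SPEED,
) -> ResultantSummary:
    """Resultant of per-trial unit rotation axes, over trials strictly above ``min_speed``."""
    axes = [e.axis for e in events if e.peak_speed > min_speed and not e.flagged]
    if not axes:
        raise ValueError("no qualifying trials above the inclusion threshold")
    v = np.mean(axes, axis=0)
    length = float(np.linalg.norm(v))
    direction = v / length if length > 0 else np.full(3, np.nan)
    return ResultantSummary(length, direction, len(axes), min_speed)


def mc_null_resultant(
    n_max: int = 100,
    n_samples: int = 10_000,
    seed: int = 0,
) -> MonteCarloNull:
    """Monte-Carlo null of resultant lengths for N ∈ [1, n_max] uniform unit vectors.

    For each N, ``n_samples`` sets of N isotropic unit 3-vectors are summed and
    the mean, 2.5th and 97.5th percentile of the resultant length recorded.
    Common random numbers (cumulative sums over one sample block) are used
    across N.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_samples, n_max, 3))
    g /= np.linalg.norm(g, axis=2, keepdims=True)
    sums = np.cumsum(g, axis=1)
    lengths = np.linalg.norm(sums, axis=2) / np.arange(1, n_max + 1)
    return MonteCarloNull(
        n=np.arange(1, n_max + 1),
        mean_length=lengths.mean(axis=0),
        lo=np.percentile(lengths, 2.5, axis=0),
        hi=np.percentile(lengths, 97.5, axis=0),
        n_samples=n_samples,
        seed=seed,
    )


def alignment_test(summary: ResultantSummary, null: MonteCarloNull) -> str:
    """``"biased"`` iff the resultant length falls outside the null 2.5–97.5% band at N."""
    n = summary.n_trials_used
    if n < 1 or n > null.n_max:
        raise ValueError(f"N={n} outside the null table (1..{null.n_max}); extend the null")
    i = n - 1
    if summary.length > null.hi[i] or summary.length < null.lo[i]:
        return "biased"
    return "unbiased"


def estimate_gravity(rec: InertialRecord, segments: ImmobilitySegments) -> np.ndarray:
    """Unit gravity direction: normalized mean acceleration over immobility samples."""
    if len(segments) == 0:
        raise ValueError("no immobility segments; cannot estimate gravity")
    idx = np.zeros(rec.n_samples, dtype=bool)
    for s, e in segments.segments:
        i0 = max(0, int(np.ceil((s - rec.t0) * rec.fs)))
        i1 = min(rec.n_samples, int(np.floor((e - rec.t0) * rec.fs)))
        idx[i0:i1] = True
    mean_acc = rec.accel[idx].mean(axis=0)
    norm = np.linalg.norm(mean_acc)
    if norm == 0:
        raise ValueError("zero mean acceleration during immobility")
    return mean_acc / norm


def orientation_vs_vertical(axis: np.ndarray, gravity: np.ndarray) -> float:
    """Angle (degrees) between a rotation axis and the gravity direction."""
    axis = np.asarray(axis, dtype=float)
    gravity = np.asarray(gravity, dtype=float)
    c = float(np.dot(axis, gravity) / (np.linalg.norm(axis) * np.linalg.norm(gravity)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
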