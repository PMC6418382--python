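"""Single-unit spike-train statistics, Poisson-surprise burst detection,
threshold-based waveform extraction and PCA + k-means spike sorting.

Firing rate uses the recording span as denominator (robust to sparse units).
Discharge irregularity is the coefficient of variation of the interspike
intervals.  Bursts are sequences of short interspike intervals that would be
very rare if the intervals were randomly (Poisson) distributed, scored by the
Legendy–Salcman surprise

    S = -ln P( >= n spikes in T | Poisson at the train's mean rate ),

and kept when S exceeds a threshold (default 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "TrainStats",
    "Burst",
    "BurstSet",
    "Waveform",
    "train_stats",
    "poisson_surprise",
    "detect_bursts",
    "extract_waveforms",
    "sort_spikes",
    "classify_width",
]


@dataclass
class SpikeTrain:
    """Ordered spike times with optional per-spike labels and a recording span."""

    times: np.ndarray
    span: tuple[float, float]
    labels: np.ndarray | None = None  # per-spike: "simple" | "complex" | "unlabeled"
    unit_id: str = "unit0"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        t0, t1 = self.span
        if not t1 > t0:
            raise ValueError("span must have positive length")
        if self.times.size and (self.times[0] < t0 or self.times[-1] > t1):
            raise ValueError("spike times outside the recording span")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.times.shape:
                raise ValueError("labels must match times")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    @property
    def span_length(self) -> float:
        return self.span[1] - self.span[0]

    def shifted(self, dt: float) -> "SpikeTrain":
        return SpikeTrain(self.times + dt, (self.span[0] + dt, self.span[1] + dt),
                          self.labels, self.unit_id)


@dataclass
class TrainStats:
    rate: float            # Hz over the recording span
    median_isi: float      # s (nan if < 2 spikes)
    cv_isi: float          # unitless (nan if < 3 spikes)
    log_rate: float        # ln(rate), nan if rate == 0
    log_median_isi: float  # ln(median ISI)
    n_spikes: int
    isi_defined: bool      # False when too few spikes for ISI statistics


@dataclass
class Burst:
    start_s: float
    end_s: float
    n_spikes: int
    surprise: float


@dataclass
class BurstSet:
    bursts: list
    burst_rate: float           # bursts per second of recording span
    fraction_in_bursts: float   # spikes inside bursts / total spikes
    surprise_threshold: float


@dataclass
class Waveform:
    """An aligned spike snippet in µV at sampling rate ``fs``."""

    samples: np.ndarray
    fs: float

    def trough_to_peak_ms(self) -> float | None:
        """Trough-to-subsequent-peak duration in ms; None when no post-trough peak."""
        x = np.asarray(self.samples, dtype=float)
        i_trough = int(np.argmin(x))
        if i_trough >= x.size - 1:
            return None
        i_peak = i_trough + int(np.argmax(x[i_trough + 1:])) + 1
        return (i_peak - i_trough) / self.fs * 1000.0


def train_stats(train: SpikeTrain) -> TrainStats:
    """Rate, median ISI, ISI CV and their natural-log transforms."""
    n = train.n_spikes
    rate = n / train.span_length
    if n >= 2:
        isi = np.diff(train.times)
        median_isi = float(np.median(isi))
    else:
        median_isi = float("nan")
    if n >= 3:
        isi = np.diff(train.times)
        cv = float(isi.std(ddof=0) / isi.mean())
        isi_defined = True
    else:
        cv = float("nan")
        isi_defined = False
    return TrainStats(
        rate=rate,
        median_isi=median_isi,
        cv_isi=cv,
        log_rate=float(np.log(rate)) if rate > 0 else float("nan"),
        log_median_isi=float(np.log(median_isi)) if median_isi > 0 else float("nan"),
        n_spikes=n,
        isi_defined=isi_defined,
    )


def poisson_surprise(n: int, duration: float, rate: float) -> float:
    """S = -ln P(>= n events in ``duration`` | Poisson at ``rate``)."""
    if rate <= 0 or duration <= 0:
        return float("inf")
    # P(X >= n) = sf(n - 1)
    return float(-stats.poisson.logsf(n - 1, rate * duration))


def _surprise_of(times: np.ndarray, i: int, j: int, rate: float) -> float:
    """Surprise of the spike run times[i..j] inclusive."""
    return poisson_surprise(j - i + 1, times[j] - times[i], rate)


def detect_bursts(
    train: SpikeTrain,
    surprise_threshold: float = 10.0,
    min_spikes: int = 3,
    max_extend: int = 10,
) -> BurstSet:
    """Legendy–Salcman Poisson-surprise burst detection.

    Seeds are runs of >= ``min_spikes`` spikes whose interspike intervals are
    all below half the train's mean ISI; each seed is greedily extended
    forward (up to ``max_extend`` look-ahead spikes) and then trimmed at its
    start to maximize the surprise.  Bursts with S >= ``surprise_threshold``
    are kept; overlapping bursts are merged.
    """
    times = train.times
    n = times.size
    rate = n / train.span_length
    if n < 3 or rate <= 0:
        return BurstSet([], 0.0, 0.0, surprise_threshold)
    isi = np.diff(times)
    mean_isi = 1.0 / rate
    fast = isi < 0.5 * mean_isi

    candidates: list[tuple[int, int]] = []
    for i0, i1 in _fast_runs(fast):
        if i1 - i0 + 1 < min_spikes - 1:  # run of ISIs; spikes = ISIs + 1
            continue
        a, b = i0, i1 + 1  # spike indices [a, b]
        # forward extension: accept the look-ahead end that maximizes S
        best_s = _surprise_of(times, a, b, rate)
        improved = True
        while improved:
            improved = False
            limit = min(n - 1, b + max_extend)
            for j in range(b + 1, limit + 1):
                s = _surprise_of(times, a, j, rate)
                if s > best_s:
                    best_s, b = s, j
                    improved = True
        # trim from the start
        improved = True
        while improved and b - a + 1 > min_spikes:
            improved = False
            s = _surprise_of(times, a + 1, b, rate)
            if s > best_s:
                best_s, a = s, a + 1
                improved = True
        if b - a + 1 >= min_spikes and best_s >= surprise_threshold:
            candidates.append((a, b))

    # merge overlapping spike-index ranges
    merged: list[list[int]] = []
    for a, b in sorted(candidates):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])

    bursts = [
        Burst(times[a], times[b], b - a + 1, _surprise_of(times, a, b, rate))
        for a, b in merged
    ]
    in_bursts = sum(b.n_spikes for b in bursts)
    return BurstSet(
        bursts,
        burst_rate=len(bursts) / train.span_length,
        fraction_in_bursts=in_bursts / n,
        surprise_threshold=surprise_threshold,
    )


def _fast_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive index pairs."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, mask.size - 1))
    return runs


def extract_waveforms(
    samples: np.ndarray,
    fs: float,
    threshold: float,
    pre_ms: float = 0.5,
    post_ms: float = 1.0,
    refractory_ms: float = 1.0,
) -> tuple[np.ndarray, list[Waveform]]:
    """Negative-going threshold crossings with refractory censoring.

    ``threshold`` is a (negative) µV level; a crossing is the first sample at
    or below it after a sample above it.  Snippets are aligned on the local
    minimum within 0.3 ms of the crossing.  Returns (times_s, waveforms).
    """
    if fs < 10_000:
        raise ValueError("raw traces must be sampled at >= 10 kHz")
    x = np.asarray(samples, dtype=float)
    below = x <= threshold
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    noise_sd = np.median(np.abs(x)) / 0.6745  # robust MAD estimate
    if abs(threshold) < 3 * noise_sd:
        logger.warning(
            "threshold %.1f µV is inside the noise floor (sd≈%.1f µV); "
            "crossing rate %.1f Hz", threshold, noise_sd, crossings.size / (x.size / fs)
        )
    i_pre = int(round(pre_ms / 1000 * fs))
    i_post = int(round(post_ms / 1000 * fs))
    i_align = int(round(0.3 / 1000 * fs))
    refr = int(round(refractory_ms / 1000 * fs))
    times, waves = [], []
    last = -np.inf
    for c in crossings:
        if c - last < refr:
            continue
        j = c + int(np.argmin(x[c : c + i_align + 1]))  # align to trough
        if j - i_pre < 0 or j + i_post > x.size:
            continue
        times.append(j / fs)
        waves.append(Waveform(x[j - i_pre : j + i_post].copy(), fs))
        last = c
    return np.asarray(times), waves


def sort_spikes(
    waveforms: list[Waveform] | np.ndarray,
    n_components: int = 3,
    k: int | None = None,
    seed: int = 0,
    k_range: tuple[int, int] = (2, 5),
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """k-means clustering on PCA of the spike waveforms.

    When ``k`` is None it is chosen by the maximum silhouette score over
    ``k_range``.  Returns (labels, centroids in PC space, silhouette or None
    for k=1).  Fully seeded and deterministic.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    X = np.array([w.samples for w in waveforms]) if not isinstance(waveforms, np.ndarray) else np.asarray(waveforms, dtype=float)
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    if X.shape[0] < (k or 1):
        raise ValueError("need at least k waveforms")
    n_components = min(n_components, X.shape[0], X.shape[1])
    pcs = PCA(n_components=n_components, random_state=seed).fit_transform(X)

    def fit(kk: int):
        km = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(pcs)
        sil = silhouette_score(pcs, km.labels_) if kk > 1 and len(set(km.labels_)) > 1 else None
        return km, sil

    if k is None:
        best = None
        for kk in range(k_range[0], k_range[1] + 1):
            if kk >= X.shape[0]:
                break
            km, sil = fit(kk)
            if best is None or (sil is not None and sil > best[1]):
                best = (km, sil)
        km, sil = best
    else:
        if k == 1:
            return np.zeros(X.shape[0], dtype=int), pcs.mean(axis=0, keepdims=True), None
        km, sil = fit(k)
    return km.labels_, km.cluster_centers_, sil


def classify_width(w: Waveform, cutoff_ms: float = 0.35) -> str | None:
    """``"narrow"`` iff trough-to-peak < cutoff (strict); None when unclassifiable."""
    t2p = w.trough_to_peak_ms()
    if t2p is None:
        logger.warning("waveform has no post-trough peak; unclassifiable")
        return None
    return "narrow" if t2p < cutoff_ms else "broad"
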