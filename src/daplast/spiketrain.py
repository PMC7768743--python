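"""Spike-train statistics, burst detection, and firing-pattern classification.

Substantia nigra dopaminergic neurons recorded extracellularly in vivo fire
tonically at 1-8 Hz, with or without interspersed bursts.  This module holds
the standard single-unit descriptors used to characterise such trains:

* interspike intervals (ISIs), mean discharge rate, and the coefficient of
  variation (CV) of the ISIs as an irregularity index;
* burst detection by the Grace-Bunney 80/160-ms ISI criterion and the
  resulting fraction of spikes fired in bursts (SFB; > 20 % => "bursty");
* ISI histograms (10-ms bins) and the spike autocorrelation histogram
  (ACH; 1-ms bins, Gaussian-smoothed with a 20-ms kernel);
* an ACH-shape decision tree assigning each train one of four firing-pattern
  labels: regular (pacemaker), irregular, bursty, or irregular-bursty.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "SpikeTrain",
    "BurstAnnotation",
    "PatternLabel",
    "Histogram",
    "ClassifierConfig",
    "UnclassifiableError",
    "compute_isis",
    "mean_rate",
    "coefficient_of_variation",
    "detect_bursts",
    "isi_histogram",
    "autocorrelogram",
    "classify_pattern",
]

#: Burst onset threshold: an ISI of at most 80 ms opens a burst.
BURST_ONSET_ISI = 0.080
#: Burst offset threshold: an ISI of at least 160 ms closes the burst.
BURST_OFFSET_ISI = 0.160
#: A train is "bursty" when the fraction of spikes in bursts exceeds 20 %.
SFB_THRESHOLD = 0.20


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) over a recording of known duration (s).

    Default duration is 600 s, the standard 10-min single-unit recording.
    Times must be strictly increasing and lie inside [0, duration].
    """

    times: np.ndarray
    duration: float = 600.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if t.size:
            if not np.all(np.isfinite(t)):
                raise ValueError("spike times must be finite")
            if np.any(np.diff(t) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class BurstAnnotation:
    """Bursts as (first, last) spike-index pairs plus the SFB summary."""

    bursts: tuple[tuple[int, int], ...]
    sfb: float
    is_bursty: bool

    @property
    def n_burst_spikes(self) -> int:
        return sum(last - first + 1 for first, last in self.bursts)


@dataclass(frozen=True)
class PatternLabel:
    """One of the four firing-pattern labels with the classifier evidence.

    ``evidence`` records the smoothed-ACH peak lags, prominences and widths
    the decision tree actually used, for audit and plotting.
    """

    label: str  # regular | irregular | bursty | irregular_bursty
    evidence: dict = field(default_factory=dict)

    LABELS = ("regular", "irregular", "bursty", "irregular_bursty")

    def __post_init__(self) -> None:
        if self.label not in self.LABELS:
            raise ValueError(f"unknown pattern label {self.label!r}")


@dataclass(frozen=True)
class Histogram:
    """Counts over half-open bins [edge[i], edge[i+1]); optionally smoothed."""

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if counts.size != edges.size - 1:
            raise ValueError("counts must have one fewer element than bin_edges")
        if np.any(counts < 0):
            raise ValueError("histogram counts must be non-negative")
        if self.smoothed is not None:
            sm = np.asarray(self.smoothed, dtype=float)
            if sm.size != counts.size:
                raise ValueError("smoothed must match counts length")
            object.__setattr__(self, "smoothed", sm)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


class UnclassifiableError(ValueError):
    """Raised when the ACH carries no structure to classify (e.g. all zeros)."""


def compute_isis(train: SpikeTrain) -> np.ndarray:
    """Interspike intervals (s); empty for trains with fewer than two spikes."""
    return np.diff(train.times)


def mean_rate(train: SpikeTrain) -> float:
    """Mean discharge rate in Hz: spike count over recording duration."""
    return train.n_spikes / train.duration


def coefficient_of_variation(isis: Sequence[float]) -> float:
    """CV of the ISIs: sample SD (n-1 denominator) over the mean.

    Dimensionless irregularity index; 0 for a perfect pacemaker, 1 for a
    Poisson process. Requires at least two ISIs and a positive mean.
    """
    x = np.asarray(isis, dtype=float)
    if x.size < 2:
        raise ValueError("CV requires at least two ISIs")
    m = x.mean()
    if m <= 0:
        raise ValueError("CV requires a positive mean ISI")
    return float(x.std(ddof=1) / m)


def detect_bursts(
    train: SpikeTrain,
    onset_isi: float = BURST_ONSET_ISI,
    offset_isi: float = BURST_OFFSET_ISI,
    sfb_threshold: float = SFB_THRESHOLD,
) -> BurstAnnotation:
    """Grace-Bunney burst detection over the ISI sequence.

    An ISI <= ``onset_isi`` opens a burst containing both flanking spikes;
    the burst then absorbs subsequent spikes until an ISI >= ``offset_isi``
    is met (the spike after that ISI is excluded) or the train ends.  An ISI
    strictly between the thresholds continues an open burst but never opens
    one.  SFB is the fraction of all spikes inside bursts; the train is
    bursty when SFB strictly exceeds ``sfb_threshold``.
    """
    if not (0 < onset_isi <= offset_isi):
        raise ValueError("need 0 < onset_isi <= offset_isi")
    isis = compute_isis(train)
    bursts: list[tuple[int, int]] = []
    open_start: int | None = None
    for i, isi in enumerate(isis):
        if open_start is None:
            if isi <= onset_isi:
                open_start = i
        else:
            if isi >= offset_isi:
                bursts.append((open_start, i))
                open_start = None
    if open_start is not None:
        bursts.append((open_start, len(isis)))

    n = train.n_spikes
    n_in = sum(last - first + 1 for first, last in bursts)
    sfb = n_in / n if n else 0.0
    return BurstAnnotation(tuple(bursts), sfb, sfb > sfb_threshold)


def isi_histogram(isis: Sequence[float], bin_width: float = 0.010) -> Histogram:
    """ISI histogram with half-open ``bin_width`` bins starting at zero."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(isis, dtype=float)
    if x.size == 0:
        return Histogram(np.array([0.0, bin_width]), np.array([0]))
    n_bins = int(np.floor(x.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    # np.histogram closes the last bin; pad one empty bin so all bins are
    # effectively half-open for the data range.
    counts, _ = np.histogram(x, bins=np.append(edges, edges[-1] + bin_width))
    return Histogram(edges, counts[:-1])


def autocorrelogram(
    train: SpikeTrain,
    bin_width: float = 0.001,
    max_lag: float = 2.0,
    smooth_sd: float = 0.020,
) -> Histogram:
    """Spike autocorrelation histogram over lags (0, max_lag].

    Counts every ordered spike pair (i < j) whose lag falls in (0, max_lag]
    into 1-ms bins, then smooths with a Gaussian kernel (SD 20 ms).  Zero-lag
    self-pairs are excluded.  Returns both raw counts and the smoothed ACH.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if max_lag <= bin_width:
        raise ValueError("max_lag must exceed bin_width")
    t = train.times
    n_bins = int(round(max_lag / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins, dtype=float)
    if t.size >= 2:
        hi = np.searchsorted(t, t + max_lag, side="right")
        for i in range(t.size - 1):
            lags = t[i + 1 : hi[i]] - t[i]
            if lags.size:
                idx = np.minimum((lags / bin_width).astype(int), n_bins - 1)
                # lags exactly on a bin edge belong to the lower (left-closed
                # seen from the lag side) bin so that lag == max_lag is kept
                on_edge = lags % bin_width == 0
                idx[on_edge] -= 1
                np.add.at(counts, idx[idx >= 0], 1.0)
    smoothed = gaussian_filter1d(counts, sigma=smooth_sd / bin_width, mode="nearest")
    return Histogram(edges, counts, smoothed)


@dataclass(frozen=True)
class ClassifierConfig:
    """Quantitative surrogates for the qualitative ACH-shape criteria.

    The published criteria are verbal ("three consecutive oscillations with
    decreasing amplitude", "plateau", "narrow initial peak ... broader peak");
    these thresholds operationalise them and are deliberately exposed:

    prominence_frac    peak prominence floor, as a fraction of the ACH
                       asymptote (mean of the last ``asymptote_frac`` lags)
    oscillation_tol    relative window (+-) around integer multiples of the
                       mean ISI where pacemaker oscillation peaks must fall
    narrow_max_lag     latest lag (s) of the "narrow initial peak" of bursts
    narrow_max_width   maximum width at half prominence (s) of that peak
    broad_width_ratio  minimum width ratio (later peak / initial peak) for the
                       "broader peak (pause)" of the bursty pattern
    """

    prominence_frac: float = 0.15
    asymptote_frac: float = 0.25
    oscillation_tol: float = 0.30
    n_oscillations: int = 3
    narrow_max_lag: float = 0.100
    narrow_max_width: float = 0.080
    broad_width_ratio: float = 2.0
    plateau_min_lag: float = 0.050


def _ach_peaks(ach: Histogram, cfg: ClassifierConfig):
    """Peaks of the smoothed ACH above the prominence floor."""
    sm = ach.smoothed if ach.smoothed is not None else ach.counts
    lags = ach.bin_centers
    n_tail = max(1, int(len(sm) * cfg.asymptote_frac))
    asymptote = float(np.mean(sm[-n_tail:]))
    floor = cfg.prominence_frac * asymptote
    idx, props = find_peaks(sm, prominence=max(floor, 1e-12), width=1)
    bin_w = ach.bin_edges[1] - ach.bin_edges[0]
    return (
        lags[idx],
        props["prominences"],
        props["widths"] * bin_w,  # width at half prominence, in seconds
        asymptote,
    )


def classify_pattern(
    ach: Histogram,
    burst: BurstAnnotation,
    mean_isi: float,
    config: ClassifierConfig | None = None,
) -> PatternLabel:
    """Assign regular / irregular / bursty / irregular_bursty from ACH shape.

    Decision tree:

    1. Bursty trains (SFB > 20 %): a narrow initial ACH peak followed by a
       clearly broader later peak (the post-burst pause) => ``bursty``; a
       narrow initial peak that decays into a plateau => ``irregular_bursty``.
    2. Non-bursty trains: ``regular`` when the smoothed ACH shows at least
       three successive oscillation peaks near integer multiples of the mean
       ISI with strictly decreasing prominence; otherwise ``irregular``
       (plateau-shaped ACH).
    """
    cfg = config or ClassifierConfig()
    if mean_isi <= 0:
        raise ValueError("mean_isi must be positive")
    sm = ach.smoothed if ach.smoothed is not None else ach.counts
    if not np.any(sm > 0):
        raise UnclassifiableError("ACH is degenerate (all zeros)")

    lags, proms, widths, asymptote = _ach_peaks(ach, cfg)
    evidence = {
        "peak_lags_s": lags.tolist(),
        "peak_prominences": proms.tolist(),
        "peak_widths_s": widths.tolist(),
        "asymptote": asymptote,
        "sfb": burst.sfb,
        "mean_isi_s": mean_isi,
    }

    if burst.is_bursty:
        narrow = (lags < cfg.narrow_max_lag) & (widths < cfg.narrow_max_width)
        if np.any(narrow):
            k = int(np.flatnonzero(narrow)[0])
            later = np.flatnonzero(
                (np.arange(lags.size) > k)
                & (widths >= cfg.broad_width_ratio * widths[k])
            )
            if later.size:
                evidence["initial_peak_lag_s"] = float(lags[k])
                evidence["pause_peak_lag_s"] = float(lags[later[0]])
                return PatternLabel("bursty", evidence)
        return PatternLabel("irregular_bursty", evidence)

    # tonic branch: look for pacemaker oscillations at m, 2m, 3m ...
    n_req = cfg.n_oscillations
    if lags.size >= n_req:
        first = lags[:n_req]
        target = mean_isi * np.arange(1, n_req + 1)
        in_window = np.all(np.abs(first - target) <= cfg.oscillation_tol * target)
        decreasing = np.all(np.diff(proms[:n_req]) < 0)
        if in_window and decreasing:
            return PatternLabel("regular", evidence)
    return PatternLabel("irregular", evidence)


def summarize(train: SpikeTrain, config: ClassifierConfig | None = None) -> dict:
    """One-stop per-train record: rate, CV, SFB, burst count, pattern label."""
    isis = compute_isis(train)
    burst = detect_bursts(train)
    rec = {
        "n_spikes": train.n_spikes,
        "duration_s": train.duration,
        "rate_hz": mean_rate(train),
        "sfb": burst.sfb,
        "is_bursty": burst.is_bursty,
        "n_bursts": len(burst.bursts),
        "cv": None,
        "label": None,
    }
    if isis.size >= 2:
        rec["cv"] = coefficient_of_variation(isis)
        ach = autocorrelogram(train)
        try:
            rec["label"] = classify_pattern(ach, burst, float(isis.mean()), config).label
        except UnclassifiableError:
            rec["label"] = None
    return rec
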