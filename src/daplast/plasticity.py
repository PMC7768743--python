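"""Stimulus protocols, stimulus-response fits, and short-term plasticity metrics.

The experiment paradigm: each *sweep* is one single burst (30 pulses at
50 Hz, i.e. 0.6 s), a 2-min recovery, then a *repeated-burst train* of six
such bursts at 5-s intervals; six sweeps are run with 6-min rests between
them.  Single-burst peaks across sweeps quantify slow, minutes-scale
depression; burst peaks within a train quantify seconds-scale facilitation
or depression.

Stimulus-response characterisation uses two fits:

* frequency response at fixed pulse count — allosteric sigmoidal (Hill)
  curve  y = Vmax * x**h / (K_half**h + x**h);
* pulse-number response at fixed frequency — ordinary least squares line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .voltammetry import ConcentrationTrace, TransientMetrics, transient_metrics

__all__ = [
    "StimulusProtocol",
    "SweepResult",
    "FitResult",
    "protocol_timeline",
    "burst_onsets",
    "hill",
    "fit_frequency_response",
    "fit_pulse_response",
    "normalize_train",
    "facilitation_index",
    "sweep_depression",
    "analyze_sweeps",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Parameters of the single-burst / repeated-burst sweep paradigm.

    Defaults encode the standard protocol: 30 pulses at 50 Hz per burst,
    six bursts per train at 5-s intervals, a 2-min gap between the single
    burst and the train, six sweeps separated by 6-min rests.  Burst
    duration follows the pulses x period convention (30 x 20 ms = 0.6 s).
    """

    pulses_per_burst: int = 30
    intra_burst_hz: float = 50.0
    bursts_per_train: int = 6
    inter_burst_interval: float = 5.0  # s, onset to onset within the train
    single_to_train_gap: float = 120.0  # s, single-burst onset to train onset
    n_sweeps: int = 6
    inter_sweep_interval: float = 360.0  # s, train end to next sweep start
    pulse_amplitude_ua: float = 400.0  # metadata only

    def __post_init__(self) -> None:
        if min(self.pulses_per_burst, self.bursts_per_train, self.n_sweeps) < 1:
            raise ValueError("counts must be at least 1")
        if self.intra_burst_hz <= 0:
            raise ValueError("intra_burst_hz must be positive")
        if self.inter_burst_interval <= self.burst_duration and self.bursts_per_train > 1:
            raise ValueError("inter-burst interval must exceed the burst duration")
        if self.single_to_train_gap <= self.burst_duration:
            raise ValueError("single-to-train gap must exceed the burst duration")

    @property
    def burst_duration(self) -> float:
        """Pulses x period; 30 pulses at 50 Hz -> 0.6 s."""
        return self.pulses_per_burst / self.intra_burst_hz

    @property
    def sweep_period(self) -> float:
        """Start-to-start interval between consecutive sweeps."""
        train_span = (self.bursts_per_train - 1) * self.inter_burst_interval + self.burst_duration
        return self.single_to_train_gap + train_span + self.inter_sweep_interval

    @property
    def total_duration(self) -> float:
        return self.n_sweeps * self.sweep_period


def burst_onsets(p: StimulusProtocol) -> list[dict]:
    """Absolute onset (s) of every burst with sweep/role bookkeeping.

    Roles: ``single`` for the lone burst opening each sweep; ``train`` with
    ``burst`` 1..bursts_per_train for the repeated-burst train.
    """
    out = []
    for s in range(p.n_sweeps):
        t0 = s * p.sweep_period
        out.append({"sweep": s + 1, "role": "single", "burst": 0, "onset": t0})
        for b in range(p.bursts_per_train):
            out.append(
                {
                    "sweep": s + 1,
                    "role": "train",
                    "burst": b + 1,
                    "onset": t0 + p.single_to_train_gap + b * p.inter_burst_interval,
                }
            )
    return out


def protocol_timeline(p: StimulusProtocol) -> np.ndarray:
    """Absolute time (s) of every stimulus pulse across all sweeps."""
    period = 1.0 / p.intra_burst_hz
    within = np.arange(p.pulses_per_burst) * period
    return np.concatenate([b["onset"] + within for b in burst_onsets(p)])


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters with RSS and a convergence flag.

    ``params`` holds either (Vmax, K_half, h) for the sigmoidal fit or
    (slope, intercept) for the linear fit, keyed by name.
    """

    params: dict
    rss: float
    converged: bool
    model: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "hill":
            return hill(x, self.params["vmax"], self.params["k_half"], self.params["h"])
        if self.model == "linear":
            return self.params["slope"] * x + self.params["intercept"]
        raise ValueError(f"unknown model {self.model!r}")


def hill(x, vmax, k_half, h):
    """Allosteric sigmoidal curve y = Vmax * x^h / (K_half^h + x^h)."""
    x = np.asarray(x, dtype=float)
    return vmax * x**h / (k_half**h + x**h)


def fit_frequency_response(
    freqs: Sequence[float], responses: Sequence[float], n_starts: int = 3, seed: int = 0
) -> FitResult:
    """Least-squares Hill fit of evoked response vs stimulus frequency.

    Multi-start (the given start plus ``n_starts`` perturbed restarts) to
    avoid the local-minimum trap of Hill fits.  Non-convergence is reported
    through the ``converged`` flag, never raised.
    """
    x = np.asarray(freqs, dtype=float)
    y = np.asarray(responses, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("sigmoidal fit needs at least 4 distinct frequencies")
    if np.any(x <= 0):
        raise ValueError("frequencies must be positive")

    ymax = max(y.max(), 1e-12)
    p0 = np.array([ymax, float(np.median(x)), 2.0])
    lower = np.array([1e-9, 1e-9, 0.2])
    upper = np.array([10.0 * ymax, 10.0 * x.max(), 10.0])

    def resid(p):
        return hill(x, *p) - y

    rng = np.random.default_rng(seed)
    best = None
    any_ok = False
    starts = [p0] + [
        np.clip(p0 * rng.uniform(0.5, 2.0, size=3), lower, upper) for _ in range(n_starts)
    ]
    for start in starts:
        try:
            sol = least_squares(resid, start, bounds=(lower, upper))
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        any_ok = any_ok or sol.success
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return FitResult(
            {"vmax": np.nan, "k_half": np.nan, "h": np.nan}, np.inf, False, "hill"
        )
    rss, sol = best
    params = {"vmax": float(sol.x[0]), "k_half": float(sol.x[1]), "h": float(sol.x[2])}
    return FitResult(params, rss, bool(sol.success), "hill")


def fit_pulse_response(pulses: Sequence[float], responses: Sequence[float]) -> FitResult:
    """OLS line for evoked response vs pulse number: slope (µM/pulse), intercept."""
    x = np.asarray(pulses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("linear fit needs at least 2 distinct pulse counts")
    slope, intercept = np.polyfit(x, y, 1)
    rss = float(np.sum((slope * x + intercept - y) ** 2))
    return FitResult(
        {"slope": float(slope), "intercept": float(intercept)}, rss, True, "linear"
    )


def normalize_train(peaks: Sequence[float]) -> np.ndarray:
    """Divide each within-train peak by the first; element 0 is exactly 1."""
    p = np.asarray(peaks, dtype=float)
    if p.size == 0 or not np.isfinite(p[0]) or p[0] <= 0:
        raise ValueError("first peak must be detected and positive")
    return p / p[0]


def facilitation_index(peaks: Sequence[float]) -> float:
    """Last normalized within-train peak: > 1 facilitation, < 1 depression."""
    p = np.asarray(peaks, dtype=float)
    if np.sum(np.isfinite(p)) < 2:
        raise ValueError("facilitation index needs at least two detected peaks")
    return float(normalize_train(p)[-1])


def sweep_depression(first_peaks_by_sweep: Sequence[float]) -> np.ndarray:
    """Per-sweep peaks relative to sweep 1; element n-1 = peak(n)/peak(1).

    The final element is the usual summary ("released x% of initial levels
    by the last sweep").
    """
    p = np.asarray(first_peaks_by_sweep, dtype=float)
    if p.size < 2:
        raise ValueError("sweep depression needs at least two sweeps")
    if not np.isfinite(p[0]) or p[0] <= 0:
        raise ValueError("sweep-1 peak must be detected and positive")
    return p / p[0]


@dataclass(frozen=True)
class SweepResult:
    """Transient metrics of one sweep: the single burst + the train bursts."""

    sweep: int
    single_burst: TransientMetrics
    train_peaks: tuple[TransientMetrics, ...]
    train_auc: float


def analyze_sweeps(
    trace: ConcentrationTrace,
    protocol: StimulusProtocol,
    search_window: float | None = None,
    baseline_window: float = 2.0,
    train_auc_tail: float = 5.0,
    detection_floor: float = 0.05,
) -> list[SweepResult]:
    """Slice a full-protocol concentration trace into per-sweep metrics.

    Single-burst and per-train-burst transients are measured with
    :func:`daplast.voltammetry.transient_metrics`; the train AUC integrates
    baseline-subtracted (clipped) concentration from the first train burst
    onset to ``train_auc_tail`` s after the last burst ends.
    """
    if search_window is None:
        # cover the burst plus clearance, but stay inside the inter-burst gap
        search_window = min(protocol.inter_burst_interval, protocol.burst_duration + 4.4)
    events = burst_onsets(protocol)
    results: list[SweepResult] = []
    for s in range(1, protocol.n_sweeps + 1):
        ev = [e for e in events if e["sweep"] == s]
        single = next(e for e in ev if e["role"] == "single")
        train = sorted((e for e in ev if e["role"] == "train"), key=lambda e: e["burst"])

        sm = transient_metrics(
            trace,
            single["onset"],
            search_window=search_window,
            baseline_window=baseline_window,
            detection_floor=detection_floor,
        )
        tp = tuple(
            transient_metrics(
                trace,
                e["onset"],
                search_window=search_window,
                baseline_window=baseline_window,
                detection_floor=detection_floor,
            )
            for e in train
        )
        if not sm.detected:
            warnings.warn(f"sweep {s}: single-burst peak below detection floor")

        # train AUC over the shaded analysis region
        t0 = train[0]["onset"]
        t1 = train[-1]["onset"] + protocol.burst_duration + train_auc_tail
        base_mask = (trace.t >= t0 - baseline_window) & (trace.t < t0)
        auc_mask = (trace.t >= t0) & (trace.t <= t1)
        baseline = float(trace.c[base_mask].mean())
        y = np.clip(trace.c[auc_mask] - baseline, 0.0, None)
        train_auc = float(np.trapezoid(y, trace.t[auc_mask]))

        results.append(SweepResult(s, sm, tp, train_auc))
    return results


def sweep_table(results: list[SweepResult], animal_id: str = "", genotype: str = ""):
    """Tidy per-burst metric table (one row per transient) as a DataFrame."""
    import pandas as pd

    rows = []
    for r in results:
        for burst, m in [(0, r.single_burst)] + [
            (i + 1, m) for i, m in enumerate(r.train_peaks)
        ]:
            rows.append(
                {
                    "animal_id": animal_id,
                    "genotype": genotype,
                    "sweep": r.sweep,
                    "burst": burst,
                    "role": "single" if burst == 0 else "train",
                    "peak_uM": m.peak_amplitude,
                    "t_half_s": m.t_half,
                    "auc": m.auc,
                    "detected": m.detected,
                    "train_auc": r.train_auc if burst == 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
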