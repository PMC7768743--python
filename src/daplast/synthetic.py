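"""Synthetic-data generators with ground truth for every pipeline input.

Every generator is deterministic given its seed and returns ground truth
alongside the data (labels, underlying concentration, kernel parameters),
so the analysis modules can be validated end to end without any recorded
data.  What is emulated, and what is not, is documented in the methods
note; the kinetic constants are artifact choices in the range of the
dorsal-striatum literature, not measured values.

Generators
----------
gen_spike_train       pacemaker / irregular / bursty / irregular-bursty
                      trains with tonic rates in the 1-8 Hz range
gen_population        a population with an exact number of bursty members
gen_da_concentration  evoked DA concentration: impulsive per-pulse release
                      plus saturable Michaelis-Menten reuptake, 1-ms grid
gen_fscv_movie        renders a concentration trace into an FSCV current
                      movie (background + DA voltammogram template + noise)
gen_photometry        dual-channel GCaMP6f-like traces with shared drift
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .plasticity import StimulusProtocol, protocol_timeline
from .spiketrain import SpikeTrain, detect_bursts
from .voltammetry import (
    ConcentrationTrace,
    ScanConfig,
    VoltammetryRecording,
    anodic_index,
    cathodic_index,
    scan_potentials,
)
from .photometry import PhotometryTrace

__all__ = [
    "GeneratorSpec",
    "DaKineticsParams",
    "gen_spike_train",
    "gen_population",
    "gen_da_concentration",
    "gen_fscv_movie",
    "gen_photometry",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic spike train.

    kind         pacemaker | irregular | bursty | irregular_bursty
    rate         tonic firing rate, Hz (dopaminergic range 1-8 Hz)
    cv_target    ISI coefficient of variation of the tonic process
    burst_rate   bursts per second of recording (bursty kinds)
    burst_len    (min, max) spikes per burst, inclusive
    intra_burst_isi  (min, max) ISI inside bursts, s (<= 80 ms so bursts
                 satisfy the onset criterion)
    sfb_target   approximate fraction of spikes in bursts to aim for; the
                 burst rate is adjusted to match it when given
    """

    kind: str = "pacemaker"
    rate: float = 5.0
    cv_target: float = 0.05
    burst_rate: float = 0.25
    burst_len: tuple[int, int] = (3, 6)
    intra_burst_isi: tuple[float, float] = (0.020, 0.060)
    sfb_target: float | None = None
    seed: int = 0

    KINDS = ("pacemaker", "irregular", "bursty", "irregular_bursty")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if not (0 < self.rate):
            raise ValueError("rate must be positive")
        if self.intra_burst_isi[1] > 0.080:
            raise ValueError("intra-burst ISIs must satisfy the 80-ms onset criterion")


def _tonic_isis(rng, n, rate, cv, kind) -> np.ndarray:
    """ISIs of the tonic background process."""
    mean = 1.0 / rate
    if kind == "pacemaker":
        isis = rng.normal(mean, cv * mean, size=n)
        return np.clip(isis, 0.05 * mean, None)
    # irregular: gamma ISIs on top of a 90-ms refractory offset, so that the
    # background never satisfies the burst-onset criterion by itself
    refractory = 0.090
    gmean = mean - refractory
    shape = 1.0 / cv**2 if cv > 0 else 100.0
    return refractory + rng.gamma(shape, gmean / shape, size=n)


def gen_spike_train(spec: GeneratorSpec, duration: float = 600.0) -> tuple[SpikeTrain, str]:
    """Generate one spike train and its ground-truth pattern label.

    Pacemaker: Gaussian-jittered regular ISIs (CV ~ cv_target).
    Irregular: gamma ISIs (CV ~ cv_target, default 0.5) over a 90-ms
    refractory floor.  Bursty kinds superimpose bursts of
    ``burst_len`` spikes at intra-burst ISIs of 20-60 ms on the tonic
    (pacemaker or irregular) background, replacing the background spike
    that triggers each burst.
    """
    if duration <= 0:
        return SpikeTrain(np.empty(0), duration=max(duration, 1e-9)), spec.kind
    rng = np.random.default_rng(spec.seed)
    bursty = spec.kind in ("bursty", "irregular_bursty")
    base_kind = "pacemaker" if spec.kind in ("pacemaker", "bursty") else "irregular"
    # bursty backgrounds are noisier than a pure pacemaker (their pause peak
    # is broad), and irregular-bursty backgrounds noisier still (plateau ACH)
    base_cv = spec.cv_target if spec.kind in ("pacemaker", "irregular") else (
        0.22 if base_kind == "pacemaker" else 0.7
    )

    n_guess = int(np.ceil(duration * spec.rate * 1.5)) + 10
    isis = _tonic_isis(rng, n_guess, spec.rate, base_cv, base_kind)
    times = np.cumsum(isis)
    times = times[times < duration]

    if not bursty:
        return SpikeTrain(times, duration), spec.kind

    # choose burst frequency from the SFB target when given
    mean_len = 0.5 * (spec.burst_len[0] + spec.burst_len[1])
    if spec.sfb_target is not None:
        if not (0 < spec.sfb_target < 1):
            raise ValueError("sfb_target must lie in (0, 1)")
        # sfb ~ n_burst_spikes / (n_tonic + n_extra); each burst converts one
        # tonic spike and adds (mean_len - 1) new ones
        n_tonic = times.size
        n_bursts = spec.sfb_target * n_tonic / (mean_len * (1 - spec.sfb_target) + 1)
        burst_rate = n_bursts / duration
        if burst_rate * (mean_len + 2) > spec.rate + burst_rate * mean_len:
            raise ValueError("sfb_target infeasible at this tonic rate")
    else:
        burst_rate = spec.burst_rate

    n_bursts = rng.poisson(burst_rate * duration)
    if n_bursts == 0 or times.size == 0:
        return SpikeTrain(times, duration), spec.kind
    anchors = np.sort(rng.choice(times.size, size=min(n_bursts, times.size), replace=False))
    keep = np.ones(times.size, dtype=bool)
    burst_spikes = []
    for a in anchors:
        t0 = times[a]
        n_len = int(rng.integers(spec.burst_len[0], spec.burst_len[1] + 1))
        isis_b = rng.uniform(*spec.intra_burst_isi, size=n_len - 1)
        burst = t0 + np.concatenate([[0.0], np.cumsum(isis_b)])
        burst_spikes.append(burst)
        # post-burst pause before tonic firing resumes (depolarisation-block
        # -like); also guarantees the closing ISI satisfies the 160-ms offset
        pause = rng.uniform(0.25, 0.60)
        too_close = (times > t0) & (times < burst[-1] + pause)
        keep &= ~too_close
    merged = np.unique(np.concatenate([times[keep]] + burst_spikes))
    merged = merged[merged < duration]
    return SpikeTrain(merged, duration), spec.kind


def gen_population(
    n: int, n_bursty: int, seed: int = 0, duration: float = 600.0
) -> list[tuple[SpikeTrain, str]]:
    """A population with exactly ``n_bursty`` trains satisfying SFB > 20 %.

    Non-bursty members are pacemakers; bursty members target SFB 0.30 and
    are regenerated (fresh substream) until the 80/160-ms detector confirms
    SFB > 0.20 and non-bursty members confirm SFB <= 0.20.
    """
    if n_bursty > n:
        raise ValueError("n_bursty cannot exceed n")
    root = np.random.default_rng(seed)
    out: list[tuple[SpikeTrain, str]] = []
    for i in range(n):
        want_bursty = i < n_bursty
        for attempt in range(50):
            sub_seed = int(root.integers(0, 2**31 - 1))
            spec = GeneratorSpec(
                kind="bursty" if want_bursty else "pacemaker",
                rate=float(root.uniform(3.0, 6.0)),
                sfb_target=0.30 if want_bursty else None,
                seed=sub_seed,
            )
            train, label = gen_spike_train(spec, duration)
            ann = detect_bursts(train)
            if ann.is_bursty == want_bursty:
                out.append((train, label))
                break
        else:
            raise RuntimeError("could not realise the requested burstiness")
    return out


@dataclass(frozen=True)
class DaKineticsParams:
    """Release/uptake/rendering constants for the FSCV generator.

    release_per_pulse   µM DA added per stimulus pulse (when no pool-model
                        release sequence is supplied).  The default is
                        calibrated so that a 30-pulse 50-Hz burst peaks near
                        0.9 µM while the per-pulse release rate exceeds the
                        saturated uptake rate, keeping peak vs pulse number
                        linear over 5-80 pulses.
    vmax_uptake/km_uptake   Michaelis-Menten DAT reuptake constants
    noise_sd            white current noise per sample, nA
    drift               slow linear current drift, nA/s
    calibration_factor  electrode sensitivity, nA per µM
    """

    release_per_pulse: float = 0.098
    vmax_uptake: float = 4.0  # µM/s
    km_uptake: float = 0.05  # µM
    noise_sd: float = 0.2  # nA
    drift: float = 0.05  # nA/s
    calibration_factor: float = 10.0  # nA/µM

    def __post_init__(self) -> None:
        for name in (
            "release_per_pulse",
            "vmax_uptake",
            "km_uptake",
            "calibration_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.drift < 0:
            raise ValueError("noise_sd and drift must be non-negative")


def gen_da_concentration(
    protocol: StimulusProtocol,
    kinetics: DaKineticsParams | None = None,
    pool_release: np.ndarray | None = None,
    dt: float = 0.001,
    tail: float = 10.0,
    pre: float = 10.0,
) -> ConcentrationTrace:
    """Evoked extracellular DA on a fine (1-ms) grid.

    d[DA]/dt = sum_i release_i * delta(t - pulse_i)
               - vmax_uptake * [DA] / (km_uptake + [DA])

    integrated by forward Euler; per-pulse release is either the constant
    ``release_per_pulse`` or the supplied pool-model output (already µM).
    The grid runs from ``-pre`` (quiet lead-in for baseline estimation) to
    ``tail`` seconds past the last pulse.
    """
    k = kinetics or DaKineticsParams()
    pulses = protocol_timeline(protocol)
    if pool_release is not None:
        pool_release = np.asarray(pool_release, dtype=float)
        if pool_release.size != pulses.size:
            raise ValueError("pool_release length must match the pulse count")
    t_end = (pulses[-1] if pulses.size else 0.0) + tail
    n = int(np.ceil((t_end + pre) / dt)) + 1
    c = np.zeros(n)
    t = -pre + np.arange(n) * dt
    pulse_bins = np.round((pulses + pre) / dt).astype(int)
    release = pool_release if pool_release is not None else np.full(
        pulses.size, k.release_per_pulse
    )
    impulse = np.zeros(n)
    np.add.at(impulse, pulse_bins, release)
    for i in range(1, n):
        prev = c[i - 1] + impulse[i - 1]
        nxt = prev - dt * k.vmax_uptake * prev / (k.km_uptake + prev)
        if nxt < 0:
            raise RuntimeError("integration became unstable (negative concentration)")
        c[i] = nxt
    return ConcentrationTrace(t, c)


def da_voltammogram_template(config: ScanConfig) -> np.ndarray:
    """Per-sample DA current template, unit amplitude at the 300-mV anodic sample.

    Gaussian oxidation peak centred at +300 mV on the anodic ramp (SD
    150 mV) and a smaller inverted reduction peak at -200 mV on the
    cathodic ramp, mimicking the characteristic background-subtracted DA
    voltammogram.
    """
    pots = scan_potentials(config)
    n = pots.size
    half = n // 2
    template = np.zeros(n)
    anodic = np.arange(n) <= half
    template[anodic] = np.exp(-0.5 * ((pots[anodic] - 300.0) / 150.0) ** 2)
    template[~anodic] = -0.5 * np.exp(-0.5 * ((pots[~anodic] + 200.0) / 150.0) ** 2)
    template /= template[anodic_index(config, 300.0)]
    return template


def gen_fscv_movie(
    c_trace: ConcentrationTrace,
    config: ScanConfig | None = None,
    kinetics: DaKineticsParams | None = None,
    seed: int = 0,
    t0: float | None = None,
) -> VoltammetryRecording:
    """Render a concentration trace into a synthetic FSCV current movie.

    currents = static background + c(scan time) * calibration * template
               + white noise + linear drift

    The background is a large capacitive-like profile (scaled triangular
    charging current) that background subtraction removes exactly.
    """
    cfg = config or ScanConfig()
    k = kinetics or DaKineticsParams()
    rng = np.random.default_rng(seed)

    if t0 is None:
        t0 = float(c_trace.t[0])
    t_end = float(c_trace.t[-1])
    n_scans = int(np.floor((t_end - t0) / cfg.repetition_interval)) + 1
    scan_t = t0 + np.arange(n_scans) * cfg.repetition_interval
    c_at_scan = np.interp(scan_t, c_trace.t, c_trace.c)

    pots = scan_potentials(cfg)
    n_samp = pots.size
    half = n_samp // 2
    # capacitive background: +/- charging current plus a broad surface wave
    background = np.where(np.arange(n_samp) <= half, 180.0, -180.0) + 40.0 * np.exp(
        -0.5 * ((pots - 100.0) / 400.0) ** 2
    )

    template = da_voltammogram_template(cfg)
    currents = (
        background[:, None]
        + k.calibration_factor * template[:, None] * c_at_scan[None, :]
        + k.drift * scan_t[None, :]
        + rng.normal(0.0, k.noise_sd, size=(n_samp, n_scans))
    )
    return VoltammetryRecording(
        currents=currents, config=cfg, t0=t0, calibration_factor=k.calibration_factor
    )


@dataclass(frozen=True)
class GcampKernelParams:
    """Double-exponential GCaMP6f-like impulse response and channel layout."""

    rise: float = 0.050  # s
    decay: float = 0.400  # s
    amplitude: float = 0.004  # ΔF/F-equivalent per pulse at the signal baseline
    baseline_465: float = 100.0  # a.u.
    baseline_405: float = 60.0  # a.u.
    drift_amplitude: float = 3.0  # a.u., slow shared drift
    noise_sd: float = 0.1  # a.u. per channel


def gen_photometry(
    protocol: StimulusProtocol,
    kernel: GcampKernelParams | None = None,
    seed: int = 0,
    fs: float = 100.0,
    tail: float = 10.0,
    pre: float = 5.0,
) -> tuple[PhotometryTrace, dict]:
    """Dual-wavelength photometry traces for a stimulus protocol.

    465-nm channel: baseline + per-pulse kernel responses + shared slow
    drift + noise; 405-nm channel: scaled baseline + the same drift
    (scaled by the channel gain) + noise.  Returns the trace and a ground
    truth dict (kernel, pulse times, noiseless ΔF/F).
    """
    k = kernel or GcampKernelParams()
    rng = np.random.default_rng(seed)
    pulses = protocol_timeline(protocol)
    t_end = (pulses[-1] if pulses.size else 0.0) + tail
    n = int(np.ceil((t_end + pre) * fs)) + 1
    t = -pre + np.arange(n) / fs

    # double-exponential kernel, unit peak
    tk = np.arange(0.0, k.decay * 8, 1.0 / fs)
    kern = np.exp(-tk / k.decay) - np.exp(-tk / k.rise)
    kern /= kern.max()

    impulse = np.zeros(n)
    np.add.at(impulse, np.round((pulses + pre) * fs).astype(int), 1.0)
    response = np.convolve(impulse, kern)[:n] * k.amplitude * k.baseline_465

    drift = k.drift_amplitude * np.sin(2 * np.pi * t / (t[-1] + 1.0) * 0.5)
    gain = k.baseline_405 / k.baseline_465
    f465 = k.baseline_465 + response + drift + rng.normal(0, k.noise_sd, n)
    f405 = k.baseline_405 + gain * drift + rng.normal(0, k.noise_sd, n)
    truth = {
        "kernel": kern,
        "pulse_times": pulses,
        "dff_true": response / k.baseline_465,
        "params": k,
    }
    return PhotometryTrace(t, np.clip(f465, 0, None), np.clip(f405, 0, None), fs), truth
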