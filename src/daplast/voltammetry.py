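"""Fast-scan cyclic voltammetry (FSCV) data model and DA-trace extraction.

A carbon-fiber microelectrode is driven with a triangular potential wave
(-450 to +800 mV vs Ag/AgCl at 294 mV/ms) every 100 ms; the current during
each sweep is sampled at 25 kHz.  Dopamine concentration is read out as the
background-subtracted oxidation current at ~300 mV on the anodic (rising)
ramp, converted to µM with a single-point calibration factor (nA per µM).

The module provides:

* :class:`ScanConfig` — waveform geometry and derived quantities;
* :class:`VoltammetryRecording` — current matrix (sample x scan) + metadata;
* background subtraction, oxidation-trace extraction, single-scan
  voltammograms, and evoked-transient metrics (peak, t1/2, AUC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ScanConfig",
    "VoltammetryRecording",
    "ConcentrationTrace",
    "TransientMetrics",
    "scan_potentials",
    "background_subtract",
    "extract_trace",
    "voltammogram_at",
    "transient_metrics",
]

#: Electrochemical detection floor for DA, µM (~50 nM in vivo).
DETECTION_FLOOR_UM = 0.05


@dataclass(frozen=True)
class ScanConfig:
    """Triangular-wave scan geometry.

    Defaults follow the standard in vivo DA waveform: -450 -> +800 mV at
    294 mV/ms, repeated every 100 ms, digitised at 25 kHz.
    """

    v_min: float = -450.0  # mV
    v_max: float = 800.0  # mV
    scan_rate: float = 294.0  # mV/ms
    repetition_interval: float = 0.100  # s
    adc_rate: float = 25_000.0  # Hz

    def __post_init__(self) -> None:
        if self.v_max <= self.v_min:
            raise ValueError("v_max must exceed v_min")
        if self.scan_rate <= 0 or self.adc_rate <= 0:
            raise ValueError("scan_rate and adc_rate must be positive")
        if self.scan_duration >= self.repetition_interval:
            raise ValueError("scan must finish within the repetition interval")
        if self.samples_per_scan < 2:
            raise ValueError("scan too short for the ADC rate")

    @property
    def scan_duration(self) -> float:
        """Up-plus-down ramp time in seconds."""
        return 2.0 * (self.v_max - self.v_min) / self.scan_rate / 1000.0

    @property
    def samples_per_scan(self) -> int:
        return int(np.floor(self.scan_duration * self.adc_rate))


def scan_potentials(config: ScanConfig) -> np.ndarray:
    """Applied potential (mV) at each ADC sample of one triangular scan."""
    t = np.arange(config.samples_per_scan) / config.adc_rate  # s
    half = (config.v_max - config.v_min) / config.scan_rate / 1000.0
    rate_mv_s = config.scan_rate * 1000.0
    up = config.v_min + rate_mv_s * t
    down = config.v_max - rate_mv_s * (t - half)
    return np.where(t <= half, up, down)


def anodic_index(config: ScanConfig, potential_mv: float) -> int:
    """Sample index on the rising ramp nearest ``potential_mv``."""
    if not (config.v_min < potential_mv < config.v_max):
        raise ValueError("potential outside the scan range")
    t = np.arange(config.samples_per_scan) / config.adc_rate
    half = (config.v_max - config.v_min) / config.scan_rate / 1000.0
    pots = scan_potentials(config)
    rising = t <= half
    idx = np.flatnonzero(rising)
    return int(idx[np.argmin(np.abs(pots[idx] - potential_mv))])


def cathodic_index(config: ScanConfig, potential_mv: float) -> int:
    """Sample index on the falling ramp nearest ``potential_mv``."""
    if not (config.v_min < potential_mv < config.v_max):
        raise ValueError("potential outside the scan range")
    t = np.arange(config.samples_per_scan) / config.adc_rate
    half = (config.v_max - config.v_min) / config.scan_rate / 1000.0
    pots = scan_potentials(config)
    idx = np.flatnonzero(t > half)
    return int(idx[np.argmin(np.abs(pots[idx] - potential_mv))])


@dataclass(frozen=True)
class VoltammetryRecording:
    """FSCV movie: currents (samples_per_scan x n_scans, nA) + metadata."""

    currents: np.ndarray
    config: ScanConfig
    t0: float = 0.0
    calibration_factor: float = 10.0  # nA per µM

    def __post_init__(self) -> None:
        c = np.asarray(self.currents, dtype=float)
        object.__setattr__(self, "currents", c)
        if c.ndim != 2:
            raise ValueError("currents must be a 2-D (samples x scans) matrix")
        if c.shape[0] != self.config.samples_per_scan:
            raise ValueError(
                f"expected {self.config.samples_per_scan} samples per scan, "
                f"got {c.shape[0]}"
            )
        if c.shape[1] < 1:
            raise ValueError("recording needs at least one scan")
        if not np.all(np.isfinite(c)):
            raise ValueError("currents must be finite")
        if self.calibration_factor <= 0:
            raise ValueError("calibration_factor must be positive")

    @property
    def n_scans(self) -> int:
        return self.currents.shape[1]

    @property
    def scan_times(self) -> np.ndarray:
        """Start time (s) of each scan."""
        return self.t0 + np.arange(self.n_scans) * self.config.repetition_interval

    # -- plain-text container (matrix CSV + JSON sidecar) ------------------

    def save_csv(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        np.savetxt(matrix_path, self.currents, delimiter=",")
        meta = {
            "config": asdict(self.config),
            "t0": self.t0,
            "calibration_factor": self.calibration_factor,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def load_csv(cls, matrix_path: str | Path, meta_path: str | Path) -> "VoltammetryRecording":
        meta = json.loads(Path(meta_path).read_text())
        return cls(
            currents=np.loadtxt(matrix_path, delimiter=",", ndmin=2),
            config=ScanConfig(**meta["config"]),
            t0=meta["t0"],
            calibration_factor=meta["calibration_factor"],
        )

    def save_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("currents", data=self.currents)
            f.attrs["t0"] = self.t0
            f.attrs["calibration_factor"] = self.calibration_factor
            for k, v in asdict(self.config).items():
                f.attrs[f"config_{k}"] = v

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "VoltammetryRecording":
        import h5py

        with h5py.File(path, "r") as f:
            cfg = ScanConfig(
                **{
                    k[len("config_"):]: float(v)
                    for k, v in f.attrs.items()
                    if k.startswith("config_")
                }
            )
            return cls(
                currents=f["currents"][()],
                config=cfg,
                t0=float(f.attrs["t0"]),
                calibration_factor=float(f.attrs["calibration_factor"]),
            )


@dataclass(frozen=True)
class ConcentrationTrace:
    """Extracellular DA concentration (µM) sampled at the scan times."""

    t: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "c", c)
        if t.size != c.size:
            raise ValueError("t and c must have equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size >= 2 else np.nan


@dataclass(frozen=True)
class TransientMetrics:
    """Peak amplitude, peak time, FWHM (t1/2) and AUC of one evoked transient.

    Units are µM and µM*s for FSCV traces, or ΔF/F and ΔF/F*s when reused by
    the photometry module.  ``detected`` is False when the peak falls below
    the detection floor; the remaining fields are then NaN.
    """

    peak_amplitude: float
    peak_time: float
    t_half: float
    auc: float
    baseline: float
    detected: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def _resolve_baseline(n_scans: int, baseline_scans) -> np.ndarray:
    idx = np.arange(n_scans)[baseline_scans]
    if np.size(idx) == 0:
        raise ValueError("baseline range selects no scans")
    return np.atleast_1d(idx)


def background_subtract(rec: VoltammetryRecording, baseline_scans) -> np.ndarray:
    """Subtract the mean of the baseline scans from every scan.

    ``baseline_scans`` is any index expression over scans (slice, array of
    indices, boolean mask).  Returns a matrix of the same shape (nA).
    """
    idx = _resolve_baseline(rec.n_scans, baseline_scans)
    background = rec.currents[:, idx].mean(axis=1, keepdims=True)
    return rec.currents - background


def default_baseline_scans(
    rec: VoltammetryRecording, stim_onset: float, n_scans: int = 10, margin: float = 0.5
) -> slice:
    """Default baseline: ``n_scans`` scans ending ``margin`` s before stimulus."""
    end = int(np.floor((stim_onset - margin - rec.t0) / rec.config.repetition_interval))
    start = end - n_scans
    if start < 0:
        raise ValueError("not enough pre-stimulus scans for the baseline window")
    return slice(start, end)


def extract_trace(
    rec: VoltammetryRecording,
    baseline_scans,
    oxidation_potential: float = 300.0,
) -> ConcentrationTrace:
    """Oxidation-current time course at ``oxidation_potential`` (anodic ramp),
    background-subtracted and converted to µM via the calibration factor."""
    row = anodic_index(rec.config, oxidation_potential)
    sub = background_subtract(rec, baseline_scans)
    c = sub[row, :] / rec.calibration_factor
    return ConcentrationTrace(rec.scan_times, c)


def voltammogram_at(
    rec: VoltammetryRecording, scan_index: int, baseline_scans
) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtracted (potential mV, current nA) pair for one scan."""
    if not (0 <= scan_index < rec.n_scans):
        raise IndexError("scan_index out of range")
    sub = background_subtract(rec, baseline_scans)
    return scan_potentials(rec.config), sub[:, scan_index]


def _fwhm(t: np.ndarray, y: np.ndarray, i_peak: int, half: float) -> float:
    """Full width of y around sample i_peak at level ``half``, interpolated."""

    def cross(lo_side: bool) -> float:
        rng = range(i_peak, 0, -1) if lo_side else range(i_peak, len(y) - 1)
        step = -1 if lo_side else 1
        for i in rng:
            j = i + step
            if y[j] <= half < y[i] or y[j] <= half <= y[i]:
                frac = (y[i] - half) / (y[i] - y[j])
                return float(t[i] + frac * (t[j] - t[i]))
        # transient never falls to half within the trace: clamp to the edge
        return float(t[0] if lo_side else t[-1])

    return cross(False) - cross(True)


def transient_metrics(
    trace: ConcentrationTrace,
    stim_onset: float,
    search_window: float = 5.0,
    baseline_window: float = 2.0,
    detection_floor: float = DETECTION_FLOOR_UM,
    clip_negative_auc: bool = True,
    interpolate_t_half: bool = True,
) -> TransientMetrics:
    """Peak / t1/2 / AUC of the evoked transient after ``stim_onset``.

    baseline  mean concentration over [onset - baseline_window, onset)
    peak      max of (c - baseline) within [onset, onset + search_window]
    t_half    full width at half the peak amplitude, linearly interpolated
              between samples (or nearest-sample if ``interpolate_t_half``
              is False)
    auc       trapezoidal integral of (c - baseline) over the search window,
              negative excursions clipped to zero by default

    Transients whose peak falls below ``detection_floor`` are flagged
    not-detected and carry NaN metrics.
    """
    t, c = trace.t, trace.c
    base_mask = (t >= stim_onset - baseline_window) & (t < stim_onset)
    search_mask = (t >= stim_onset) & (t <= stim_onset + search_window)
    if not base_mask.any() or not search_mask.any():
        raise ValueError("baseline/search windows fall outside the trace")

    baseline = float(c[base_mask].mean())
    y = c - baseline
    sidx = np.flatnonzero(search_mask)
    i_peak = int(sidx[np.argmax(y[sidx])])
    peak = float(y[i_peak])

    if peak < detection_floor:
        return TransientMetrics(peak, np.nan, np.nan, np.nan, baseline, detected=False)

    if interpolate_t_half:
        t_half = _fwhm(t, y, i_peak, peak / 2.0)
    else:
        # nearest-sample convention: span of contiguous samples >= half max
        lo = i_peak
        while lo > 0 and y[lo - 1] >= peak / 2.0:
            lo -= 1
        hi = i_peak
        while hi < len(y) - 1 and y[hi + 1] >= peak / 2.0:
            hi += 1
        t_half = float(t[hi] - t[lo])

    y_auc = np.clip(y[sidx], 0.0, None) if clip_negative_auc else y[sidx]
    auc = float(np.trapezoid(y_auc, t[sidx]))
    return TransientMetrics(peak, float(t[i_peak]), float(t_half), auc, baseline)
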