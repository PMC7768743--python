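"""Dual-wavelength fiber-photometry ΔF/F and stimulus-locked transient analysis.

GCaMP6f fluorescence is excited at 465 nm; a 405-nm channel measures
calcium-independent background (movement, bleaching, autofluorescence).
The background channel is regressed onto the signal channel over the whole
recording; the fitted baseline F̂ gives ΔF/F = (F465 - F̂)/F̂.  Transient
metrics (peak, t1/2, AUC) reuse the voltammetry contract with ΔF/F units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .voltammetry import ConcentrationTrace, TransientMetrics, transient_metrics

__all__ = [
    "PhotometryTrace",
    "DffTrace",
    "compute_dff",
    "transient_metrics_photometry",
]


@dataclass(frozen=True)
class PhotometryTrace:
    """Raw two-channel recording: 465-nm signal and 405-nm background (a.u.)."""

    t: np.ndarray
    f_signal: np.ndarray
    f_background: np.ndarray
    fs: float = 100.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        fs_ = np.asarray(self.f_signal, dtype=float)
        fb = np.asarray(self.f_background, dtype=float)
        for name, arr in (("t", t), ("f_signal", fs_), ("f_background", fb)):
            object.__setattr__(self, name, arr)
        if not (t.size == fs_.size == fb.size):
            raise ValueError("channels must share the time base")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.any(fs_ < 0) or np.any(fb < 0):
            raise ValueError("fluorescence must be non-negative")


@dataclass(frozen=True)
class DffTrace:
    """Normalized fluorescence ΔF/F on the recording time base."""

    t: np.ndarray
    dff: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        d = np.asarray(self.dff, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "dff", d)
        if t.size != d.size:
            raise ValueError("t and dff must have equal length")
        if not np.all(np.isfinite(d)):
            raise ValueError("dff must be finite")


def compute_dff(trace: PhotometryTrace) -> DffTrace:
    """Isosbestic-corrected ΔF/F via linear regression of 405 onto 465.

    F̂ = a*F405 + b fitted by least squares over the whole recording;
    ΔF/F = (F465 - F̂) / F̂.  A non-positive fitted baseline anywhere, or a
    variance-free background channel, is an error: the correction would be
    meaningless.
    """
    fb = trace.f_background
    fs = trace.f_signal
    if np.var(fb) <= 0:
        raise ValueError("background channel has no variance; cannot fit baseline")
    a, b = np.polyfit(fb, fs, 1)
    fitted = a * fb + b
    if np.any(fitted <= 0):
        raise ValueError("fitted baseline is non-positive; check channels")
    return DffTrace(trace.t, (fs - fitted) / fitted)


def transient_metrics_photometry(
    dff: DffTrace,
    stim_onset: float,
    search_window: float = 5.0,
    baseline_window: float = 2.0,
    detection_floor: float = 0.005,
) -> TransientMetrics:
    """Peak / t1/2 / AUC of a stimulus-locked ΔF/F transient.

    Identical contract to :func:`daplast.voltammetry.transient_metrics`;
    amplitudes are ΔF/F and AUC is ΔF/F * s.  The default detection floor is
    0.5 % ΔF/F.
    """
    return transient_metrics(
        ConcentrationTrace(dff.t, dff.dff),
        stim_onset,
        search_window=search_window,
        baseline_window=baseline_window,
        detection_floor=detection_floor,
    )
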