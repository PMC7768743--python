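"""FSCV scan geometry, background subtraction, extraction, transient metrics."""

import numpy as np
import pytest

from daplast.plasticity import StimulusProtocol
from daplast.synthetic import (
    DaKineticsParams,
    da_voltammogram_template,
    gen_da_concentration,
    gen_fscv_movie,
)
from daplast.voltammetry import (
    ConcentrationTrace,
    ScanConfig,
    VoltammetryRecording,
    anodic_index,
    background_subtract,
    extract_trace,
    scan_potentials,
    transient_metrics,
    voltammogram_at,
)


@pytest.fixture(scope="module")
def config():
    return ScanConfig()


def _single_burst_trace(n_pulses=30, **kin):
    proto = StimulusProtocol(pulses_per_burst=n_pulses, bursts_per_train=1, n_sweeps=1)
    return proto, gen_da_concentration(proto, DaKineticsParams(**kin), tail=8.0)


# ------------------------------------------------------------- scan geometry


def test_scan_ramp_endpoints(config):
    pots = scan_potentials(config)
    mv_per_sample = config.scan_rate * 1000.0 / config.adc_rate
    assert pots[0] == pytest.approx(-450.0)
    assert pots.max() == pytest.approx(800.0, abs=mv_per_sample)
    # apex at the scan midpoint
    assert abs(np.argmax(pots) - pots.size / 2) <= 1


def test_scan_duration_from_waveform(config):
    assert config.scan_duration == pytest.approx(2 * 1250 / 294 / 1000, rel=1e-6)
    assert config.samples_per_scan == int(config.scan_duration * 25000)


def test_degenerate_waveform_rejected():
    with pytest.raises(ValueError):
        ScanConfig(v_min=300.0, v_max=300.0)
    with pytest.raises(ValueError):
        ScanConfig(repetition_interval=0.005)  # scan longer than repetition


# ------------------------------------------------------- background handling


def _flat_recording(config, n_scans=40, value=5.0):
    cur = np.full((config.samples_per_scan, n_scans), value)
    return VoltammetryRecording(cur, config)


def test_background_subtract_identical_scans(config):
    rec = _flat_recording(config)
    assert np.allclose(background_subtract(rec, slice(0, 10)), 0.0)


def test_background_subtract_empty_baseline(config):
    rec = _flat_recording(config)
    with pytest.raises(ValueError):
        background_subtract(rec, slice(5, 5))


def test_background_subtract_idempotent(config, rng):
    cur = rng.normal(0, 1, size=(config.samples_per_scan, 30))
    rec = VoltammetryRecording(cur, config)
    once = background_subtract(rec, slice(0, 5))
    twice = background_subtract(VoltammetryRecording(once, config), slice(0, 5))
    assert np.allclose(once, twice)


def test_background_subtract_recovers_template(config):
    """Background + known DA template at scans 50-80 -> residual ~ template."""
    template = da_voltammogram_template(config)
    n_scans = 100
    cur = np.tile(np.linspace(-100, 100, config.samples_per_scan)[:, None], (1, n_scans))
    amp = np.zeros(n_scans)
    amp[50:80] = 7.0
    cur = cur + template[:, None] * amp[None, :]
    rec = VoltammetryRecording(cur, config)
    sub = background_subtract(rec, slice(0, 20))
    assert np.allclose(sub, template[:, None] * amp[None, :], atol=1e-9)


# ------------------------------------------------------------- extraction


def test_extract_zero_matrix(config):
    rec = _flat_recording(config, value=0.0)
    trace = extract_trace(rec, slice(0, 10))
    assert np.allclose(trace.c, 0.0)
    assert np.allclose(np.diff(trace.t), config.repetition_interval)


def test_extract_potential_out_of_range(config):
    rec = _flat_recording(config)
    with pytest.raises(ValueError):
        extract_trace(rec, slice(0, 10), oxidation_potential=900.0)


def test_extraction_round_trip():
    """c(t) -> movie -> extract recovers c within 2 % for SNR >= 10.

    Baseline scans are taken just before the stimulus, as in practice —
    a distant baseline would fold electrode drift into the trace.
    """
    from daplast.voltammetry import default_baseline_scans

    kin = DaKineticsParams(noise_sd=0.05, drift=0.01)
    proto, trace = _single_burst_trace(noise_sd=0.05, drift=0.01)
    movie = gen_fscv_movie(trace, kinetics=kin, seed=11)
    got = extract_trace(movie, default_baseline_scans(movie, stim_onset=0.0))
    true_at_scan = np.interp(got.t, trace.t, trace.c)
    first = got.t < 6.0
    i = np.flatnonzero(first)[np.argmax(true_at_scan[first])]
    assert got.c[i] == pytest.approx(true_at_scan[i], rel=0.02)


def test_extraction_error_bounded_at_default_noise():
    """At default noise/drift, per-scan error stays within ~4 sigma."""
    from daplast.voltammetry import default_baseline_scans

    proto, trace = _single_burst_trace()
    kin = DaKineticsParams()
    movie = gen_fscv_movie(trace, kinetics=kin, seed=11)
    got = extract_trace(movie, default_baseline_scans(movie, stim_onset=0.0))
    true_at_scan = np.interp(got.t, trace.t, trace.c)
    first = got.t < 6.0
    sigma = kin.noise_sd / kin.calibration_factor
    err = got.c[first] - true_at_scan[first]
    assert np.abs(err).max() < 4.5 * sigma + kin.drift * 8.0 / kin.calibration_factor
    assert abs(err.mean()) < 2.0 * sigma


def test_calibration_linearity(config, rng):
    cur = rng.normal(0, 1, size=(config.samples_per_scan, 30)) + 50.0
    rec1 = VoltammetryRecording(cur, config, calibration_factor=10.0)
    rec2 = VoltammetryRecording(3.0 * cur, config, calibration_factor=10.0)
    t1 = extract_trace(rec1, slice(0, 5))
    t2 = extract_trace(rec2, slice(0, 5))
    assert np.allclose(t2.c, 3.0 * t1.c)


def test_voltammogram_at_template_argmax(config):
    proto, trace = _single_burst_trace()
    movie = gen_fscv_movie(trace, kinetics=DaKineticsParams(noise_sd=0.0, drift=0.0), seed=0)
    c_at_scan = np.interp(movie.scan_times, trace.t, trace.c)
    first = movie.scan_times < 6.0
    i_peak = int(np.flatnonzero(first)[np.argmax(c_at_scan[first])])
    pots, cur = voltammogram_at(movie, i_peak, slice(0, 50))
    ox_sample = anodic_index(config, 300.0)
    assert np.argmax(cur) == ox_sample
    assert pots[ox_sample] == pytest.approx(300.0, abs=3.0)


def test_voltammogram_baseline_scan_near_zero(config):
    proto, trace = _single_burst_trace()
    kin = DaKineticsParams()
    movie = gen_fscv_movie(trace, kinetics=kin, seed=1)
    _, cur = voltammogram_at(movie, 10, slice(0, 50))  # pre-stimulus scan
    assert np.abs(cur).max() < 4.0 * kin.noise_sd + 1.0  # drift allowance


def test_voltammogram_bad_index(config):
    rec = _flat_recording(config)
    with pytest.raises(IndexError):
        voltammogram_at(rec, 1000, slice(0, 5))


# --------------------------------------------------------- transient metrics


def _triangle_trace(height=1.0, base=4.0, dt=0.1, onset=10.0):
    t = np.arange(0, 30, dt)
    c = np.interp(t, [onset, onset + base / 2, onset + base], [0, height, 0])
    return ConcentrationTrace(t, c)


def test_triangle_metrics_closed_form():
    m = transient_metrics(_triangle_trace(), stim_onset=10.0, search_window=6.0)
    assert m.detected
    assert m.peak_amplitude == pytest.approx(1.0, rel=1e-6)
    assert m.t_half == pytest.approx(2.0, rel=1e-6)
    assert m.auc == pytest.approx(2.0, rel=1e-3)


def test_flat_trace_not_detected():
    t = np.arange(0, 30, 0.1)
    m = transient_metrics(ConcentrationTrace(t, np.zeros_like(t)), stim_onset=10.0)
    assert not m.detected
    assert np.isnan(m.t_half)


def test_metrics_invariant_under_baseline_offset():
    m0 = transient_metrics(_triangle_trace(), 10.0, search_window=6.0)
    tr = _triangle_trace()
    shifted = ConcentrationTrace(tr.t, tr.c + 0.7)
    m1 = transient_metrics(shifted, 10.0, search_window=6.0)
    assert m1.peak_amplitude == pytest.approx(m0.peak_amplitude)
    assert m1.t_half == pytest.approx(m0.t_half)
    assert m1.auc == pytest.approx(m0.auc)
    assert m1.baseline == pytest.approx(m0.baseline + 0.7)


def test_metrics_against_fine_grid_oracle():
    """Scan-rate metrics match a 1-ms-grid numerical oracle within 5 %.

    Uses a slow-clearance transient: the 10-Hz scan grid can only hit a
    sharp peak to within (clearance rate x 50 ms), so the 5 % contract is
    meaningful for transients whose clearance is slow against the scan
    interval (as for the several-second evoked transients analysed here).
    """
    proto, fine = _single_burst_trace(vmax_uptake=0.6, release_per_pulse=0.035)
    # oracle on the fine grid
    m_fine = transient_metrics(fine, 0.0, search_window=6.0)
    # decimate to the 100-ms scan grid
    idx = slice(None, None, 100)
    coarse = ConcentrationTrace(fine.t[idx], fine.c[idx])
    m_coarse = transient_metrics(coarse, 0.0, search_window=6.0)
    assert m_coarse.peak_amplitude == pytest.approx(m_fine.peak_amplitude, rel=0.05)
    assert m_coarse.t_half == pytest.approx(m_fine.t_half, rel=0.05)
    assert m_coarse.auc == pytest.approx(m_fine.auc, rel=0.05)


def test_csv_round_trip(tmp_path, config, rng):
    cur = rng.normal(0, 1, size=(config.samples_per_scan, 12))
    rec = VoltammetryRecording(cur, config, t0=-1.0, calibration_factor=8.0)
    rec.save_csv(tmp_path / "m.csv", tmp_path / "meta.json")
    back = VoltammetryRecording.load_csv(tmp_path / "m.csv", tmp_path / "meta.json")
    assert np.allclose(back.currents, rec.currents)
    assert back.config == rec.config
    assert back.calibration_factor == 8.0


def test_hdf5_round_trip(tmp_path, config, rng):
    cur = rng.normal(0, 1, size=(config.samples_per_scan, 12))
    rec = VoltammetryRecording(cur, config)
    rec.save_hdf5(tmp_path / "rec.h5")
    back = VoltammetryRecording.load_hdf5(tmp_path / "rec.h5")
    assert np.allclose(back.currents, rec.currents)
    assert back.config.v_max == config.v_max
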