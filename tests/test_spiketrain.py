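"""Spike-train statistics, burst detection, and pattern classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from daplast.spiketrain import (
    BurstAnnotation,
    Histogram,
    SpikeTrain,
    UnclassifiableError,
    autocorrelogram,
    classify_pattern,
    coefficient_of_variation,
    compute_isis,
    detect_bursts,
    isi_histogram,
    mean_rate,
    summarize,
)
from daplast.synthetic import GeneratorSpec, gen_spike_train


# ---------------------------------------------------------------- SpikeTrain


def test_spike_train_validation():
    with pytest.raises(ValueError):
        SpikeTrain(np.array([0.1, 0.1, 0.2]))  # duplicated times
    with pytest.raises(ValueError):
        SpikeTrain(np.array([0.3, 0.2]))  # not increasing
    with pytest.raises(ValueError):
        SpikeTrain(np.array([1.0]), duration=0.5)  # outside span
    with pytest.raises(ValueError):
        SpikeTrain(np.array([1.0]), duration=0.0)


@pytest.mark.parametrize(
    "times, expected",
    [
        ([0.0, 0.2, 0.4], [0.2, 0.2]),
        ([0.7], []),
        ([0.0, 0.05, 0.10, 0.30], [0.05, 0.05, 0.20]),
    ],
)
def test_compute_isis(times, expected):
    isis = compute_isis(SpikeTrain(np.array(times), duration=1.0))
    assert np.allclose(isis, expected)


def test_mean_rate():
    t = np.arange(3000) * 0.2
    assert mean_rate(SpikeTrain(t, duration=600.0)) == pytest.approx(5.0)
    assert mean_rate(SpikeTrain(np.empty(0), duration=600.0)) == 0.0


def test_mean_rate_poisson_sampling_error(rng):
    isis = rng.exponential(0.25, size=4000)
    times = np.cumsum(isis)
    times = times[times < 600.0]
    rate = mean_rate(SpikeTrain(times, duration=600.0))
    assert rate == pytest.approx(4.0, abs=0.2)


# ------------------------------------------------------------------------ CV


def test_cv_examples():
    assert coefficient_of_variation([0.2] * 10) == 0.0
    assert coefficient_of_variation([0.1, 0.2, 0.3]) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        coefficient_of_variation([0.2])


def test_cv_exponential_is_one(rng):
    isis = rng.exponential(0.2, size=10_000)
    assert coefficient_of_variation(isis) == pytest.approx(1.0, abs=0.05)


@given(scale=st.floats(0.01, 100.0))
def test_cv_invariant_under_time_rescaling(scale):
    isis = np.array([0.05, 0.21, 0.13, 0.34, 0.08, 0.19])
    assert coefficient_of_variation(isis * scale) == pytest.approx(
        coefficient_of_variation(isis)
    )


# ------------------------------------------------------------ burst detection


def _burst_oracle(isis, onset, offset):
    """Independent state machine over the ISI sequence."""
    bursts, state, start = [], "closed", None
    for i, isi in enumerate(isis):
        if state == "closed" and isi <= onset:
            state, start = "open", i
        elif state == "open" and isi >= offset:
            bursts.append((start, i))
            state = "closed"
    if state == "open":
        bursts.append((start, len(isis)))
    return bursts


@pytest.mark.parametrize(
    "times, n_bursts, burst_spikes, sfb",
    [
        # ISIs 50,50,20,280,300 ms: one burst spanning spikes 0-3
        ([0, 0.05, 0.10, 0.12, 0.40, 0.70], 1, 4, 4 / 6),
        # regular 200-ms train: nothing
        (list(np.arange(0, 2.0, 0.2)), 0, 0, 0.0),
        # ISIs 50,120,50,200: 120 ms is between thresholds and continues
        ([0, 0.05, 0.17, 0.22, 0.42], 1, 4, 4 / 5),
    ],
)
def test_detect_bursts_rule(times, n_bursts, burst_spikes, sfb):
    ann = detect_bursts(SpikeTrain(np.array(times), duration=5.0))
    assert len(ann.bursts) == n_bursts
    assert ann.n_burst_spikes == burst_spikes
    assert ann.sfb == pytest.approx(sfb)
    assert ann.is_bursty == (sfb > 0.20)


def test_detect_bursts_open_at_end():
    # final ISI opens a burst that is closed at the last spike
    ann = detect_bursts(SpikeTrain(np.array([0.0, 0.5, 0.55]), duration=1.0))
    assert ann.bursts == ((1, 2),)


def test_detect_bursts_invalid_thresholds():
    train = SpikeTrain(np.array([0.0, 0.1]), duration=1.0)
    with pytest.raises(ValueError):
        detect_bursts(train, onset_isi=0.2, offset_isi=0.1)


def test_detect_bursts_matches_oracle_on_random_trains(rng):
    """Detector == brute-force ISI state machine on 1000 random trains."""
    for _ in range(1000):
        n = int(rng.integers(2, 120))
        isis = rng.choice([0.02, 0.05, 0.09, 0.12, 0.2, 0.5], size=n)
        times = np.cumsum(isis)
        train = SpikeTrain(times, duration=float(times[-1]) + 0.1)
        got = detect_bursts(train)
        want = _burst_oracle(np.diff(times), 0.080, 0.160)
        assert list(got.bursts) == want
        n_in = sum(b - a + 1 for a, b in want)
        assert got.sfb == pytest.approx(n_in / train.n_spikes)
        assert 0.0 <= got.sfb <= 1.0


def test_sfb_zero_without_short_isis(rng):
    isis = rng.uniform(0.081, 0.5, size=200)
    train = SpikeTrain(np.cumsum(isis), duration=100.0)
    assert detect_bursts(train).sfb == 0.0


# ----------------------------------------------------------------- histograms


def test_isi_histogram_single_bin():
    h = isi_histogram(np.full(7, 0.205))
    nz = np.flatnonzero(h.counts)
    assert nz.size == 1
    assert h.bin_edges[nz[0]] == pytest.approx(0.20)
    assert h.counts[nz[0]] == 7


def test_isi_histogram_empty():
    h = isi_histogram([])
    assert h.counts.sum() == 0


def test_isi_histogram_matches_direct_counting(rng):
    isis = rng.uniform(0.0, 0.8, size=500)
    h = isi_histogram(isis, bin_width=0.01)
    for lo, hi, c in zip(h.bin_edges[:-1], h.bin_edges[1:], h.counts):
        assert c == np.sum((isis >= lo) & (isis < hi))
    assert h.counts.sum() == isis.size


# -------------------------------------------------------------- autocorrelogram


def test_ach_single_spike_is_zero():
    ach = autocorrelogram(SpikeTrain(np.array([1.0]), duration=2.0))
    assert ach.counts.sum() == 0


def test_ach_total_mass_equals_pair_count(rng):
    times = np.sort(rng.uniform(0, 30, size=150))
    train = SpikeTrain(times, duration=30.0)
    ach = autocorrelogram(train, max_lag=2.0)
    diffs = times[None, :] - times[:, None]
    n_pairs = np.sum((diffs > 0) & (diffs <= 2.0))
    assert ach.counts.sum() == n_pairs


def test_ach_regular_train_peaks_at_period_multiples():
    train = SpikeTrain(np.arange(0, 600, 0.2), duration=600.0)
    ach = autocorrelogram(train)
    sm = ach.smoothed
    lags = ach.bin_centers
    for k in (1, 2, 3):
        window = (lags > 0.2 * k - 0.05) & (lags < 0.2 * k + 0.05)
        peak_lag = lags[window][np.argmax(sm[window])]
        assert abs(peak_lag - 0.2 * k) < 0.01


def test_ach_poisson_flat(rng):
    times = np.cumsum(rng.exponential(0.25, size=3000))
    train = SpikeTrain(times, duration=float(times[-1]) + 1)
    ach = autocorrelogram(train)
    sm = ach.smoothed[50:]  # skip the zero-lag edge
    assert np.abs(sm - sm.mean()).max() < 3.0 * np.sqrt(ach.counts[50:].mean()) + 1


# ------------------------------------------------------------- classification


def _classify_train(train):
    isis = compute_isis(train)
    return classify_pattern(
        autocorrelogram(train), detect_bursts(train), float(isis.mean())
    )


def test_classify_pacemaker_regular():
    train, _ = gen_spike_train(GeneratorSpec(kind="pacemaker", rate=5.0, cv_target=0.05, seed=1))
    assert _classify_train(train).label == "regular"


def test_classify_poisson_irregular(rng):
    # slow Poisson train: SFB stays under the bursty gate, ACH is flat
    times = np.cumsum(rng.exponential(1.0, size=800))
    times = times[times < 600.0]
    train = SpikeTrain(times, duration=600.0)
    assert _classify_train(train).label == "irregular"


def test_classify_bursty():
    train, _ = gen_spike_train(GeneratorSpec(kind="bursty", rate=4.5, sfb_target=0.3, seed=7))
    assert _classify_train(train).label == "bursty"


def test_classify_degenerate_ach_raises():
    h = Histogram(np.arange(0, 2.001, 0.001), np.zeros(2000), np.zeros(2000))
    ann = BurstAnnotation((), 0.0, False)
    with pytest.raises(UnclassifiableError):
        classify_pattern(h, ann, 0.2)


def test_classifier_recovers_generator_labels():
    """>= 90 % agreement with ground truth over a 100-train population."""
    name_map = {"pacemaker": "regular"}
    rng = np.random.default_rng(42)
    confusion = {}
    correct = total = 0
    for kind in GeneratorSpec.KINDS:
        for _ in range(25):
            spec = GeneratorSpec(
                kind=kind,
                rate=float(rng.uniform(3, 6)),
                cv_target=0.05 if kind == "pacemaker" else 0.5,
                sfb_target=0.30 if "bursty" in kind else None,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            train, label = gen_spike_train(spec)
            got = summarize(train)["label"]
            want = name_map.get(label, label)
            confusion[(want, got)] = confusion.get((want, got), 0) + 1
            correct += got == want
            total += 1
    assert total == 100
    assert correct / total >= 0.90, f"confusion: {confusion}"
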