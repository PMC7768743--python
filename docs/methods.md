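# Methods

This note records the models, conventions, and numerical choices behind
`daplast`, and what the synthetic-data validation does and does not
demonstrate about real recordings.

## Spike-train analysis

A `SpikeTrain` is a strictly increasing time series over a known recording
span (default 600 s, the standard 10-min single-unit recording). Ties are
rejected: two spikes cannot share a timestamp at the rates and sampling
considered here, so duplicates indicate an upstream sorting error.

**CV.** Sample standard deviation (n−1) over the mean ISI. The population
formula differs by < 1 % at the spike counts involved; the sample form is
the standard finite-sample choice.

**Burst detection.** The 80/160-ms two-threshold rule is implemented as a
left-to-right scan over ISIs: an ISI ≤ 80 ms opens a burst containing both
flanking spikes; while open, spikes are appended until an ISI ≥ 160 ms
occurs (its right spike excluded) or the train ends (the burst closes at
the last spike). An ISI strictly between the thresholds extends an open
burst but never opens one. Minimum burst size is two spikes. SFB is the
fraction of all spikes inside bursts; "bursty" means SFB strictly greater
than 0.20. The detector is verified against an independent brute-force
state machine on 1000 random trains.

**Autocorrelogram.** One-sided ordered-pair lag counts in (0, 2 s], 1-ms
bins, smoothed with a 20-ms-SD Gaussian kernel (`scipy.ndimage`). The 2-s
maximum lag covers pause peaks for tonic rates down to ~1 Hz.

**Pattern classifier.** The published criteria are verbal; the quantitative
surrogates (all exposed in `ClassifierConfig`) are:

- peak candidates: smoothed-ACH maxima with prominence ≥ 15 % of the ACH
  asymptote (mean over the last 25 % of lags);
- *regular*: the first three peaks fall within ±30 % of successive integer
  multiples of the mean ISI with strictly decreasing prominences;
- *bursty*: SFB > 20 % plus a narrow initial peak (lag < 100 ms, width at
  half prominence < 80 ms) followed by a later peak at least twice as wide
  (the post-burst pause);
- *irregular-bursty*: SFB > 20 % without such a broad later peak (plateau);
- *irregular*: everything else; an all-zero ACH raises an
  "unclassifiable" error instead of guessing.

These thresholds are surrogates chosen to operationalise the shape
descriptions, not a claim about the original authors' exact procedure. On
the synthetic population at generator defaults the classifier agrees with
ground truth on 91/100 trains; the residual confusion is bursty vs
irregular-bursty, whose ACH shapes genuinely blend into each other as the
tonic background roughens.

## FSCV

Scan geometry follows the standard in vivo DA waveform (−450 → +800 mV at
294 mV/ms, 100-ms repetition, 25-kHz ADC; 212 samples per 8.50-ms scan).
The DA concentration readout is the background-subtracted current at the
anodic-ramp sample nearest +300 mV divided by the single-point calibration
factor (default 10 nA/µM). The cathodic sample selection is available for
reduction-trace work but unused by default. Background subtraction uses the
mean of an explicit baseline scan range; the recommended default is ten
scans ending 0.5 s before stimulus onset — with a slowly drifting
electrode a *distant* baseline folds drift into the trace, which is why
`analyze_sweeps` re-baselines locally for every transient.

Transient metrics: baseline = mean concentration over the pre-stimulus
window (default 2 s); peak = max of the baseline-subtracted trace within
the search window; t½ = full width at half maximum with linear
interpolation between samples (a nearest-sample variant is exposed);
AUC = trapezoidal integral with negative excursions clipped (clipping is
switchable; it suppresses drift artifacts). Peaks below 0.05 µM — the
~50-nM electrochemical detection floor — are flagged not-detected and all
derived metrics become NaN rather than propagating noise.

At the 10-Hz scan rate a sharp concentration cusp is undersampled by up to
(clearance rate × 50 ms); the metric contract (5 % against a 1-ms-grid
oracle) therefore applies to transients whose clearance is slow against
the scan interval, which the several-second evoked transients analysed
here satisfy.

## Stimulus protocol and fits

`StimulusProtocol` defaults encode the sweep paradigm: 30 pulses at 50 Hz
per burst (duration = pulses × period = 0.6 s), six bursts per train at
5-s onset intervals, a 120-s gap between the opening single burst and the
train, and 360-s rests between the six sweeps.

The frequency response is fitted with the Hill form y = Vmax·x^h/(K½^h+x^h)
by bounded least squares (`scipy.optimize.least_squares`) with Vmax₀ =
max(y), K½₀ = median(x), h₀ = 2, bounds Vmax ∈ (0, 10·max y],
K½ ∈ (0, 10·max x], h ∈ [0.2, 10], and three perturbed restarts — Hill
fits have a well-known local-minimum trap at large h. Non-convergence is
reported in the result, never raised. Negative measured responses (noise
around zero at sub-threshold frequencies) are deliberately not clipped
before fitting: truncation at zero biases Vmax upward and h downward.
The pulse response is ordinary least squares.

Facilitation and depression are ratio metrics: within-train peaks
normalised to the first burst of the same train (the facilitation index is
the last normalised peak; > 1 facilitation, < 1 depression), and
single-burst peaks per sweep normalised to sweep 1. Transients whose
sweep-1 anchor is below the detection floor are excluded with a logged
warning, not imputed.

## Photometry

ΔF/F uses the whole-recording linear regression of the 405-nm background
channel onto the 465-nm signal channel: F̂ = a·F405 + b, ΔF/F =
(F465 − F̂)/F̂. This removes shared gain, drift, and movement components;
a non-positive fitted baseline or a variance-free background channel is an
error. A low-pass baseline-division alternative is a possible extension;
the regression convention is the package's documented choice. Transient
metrics are the FSCV contract in ΔF/F units with a 0.5 % detection floor.

## Vesicle pool model

The pool model is deliberately artifact-defined: the biological model it
implements is qualitative (pool cartoons, no rate equations), so the
update rules below are this package's own minimal formalisation, and every
numeric preset is a calibration artifact — not a measured quantity.

State: RRP (docked vesicles, capacity `rrp_cap`), RP (a mobilised staging
pool), reserve (deep pool), active-zone occupancy, and an in-transit queue
of released vesicles. Per stimulus pulse

    released = p_release · min(RRP, n_az − occupied)

vesicles fuse; their collapsing membrane occupies active zones, which
clear exponentially at `k_clear`. A calcium gate is open during each burst
and for 1 s after it. While open, reserve vesicles are mobilised into the
RP at `k_reserve` and RP vesicles dock into the RRP at `k_refill` (capped
at the RRP capacity); while closed, unused RP vesicles re-sequester into
the reserve at `k_demob`, and a constitutive trickle `k_rest` re-docks
reserve vesicles directly. Released vesicles return to the reserve after a
fixed `recycle_delay`. All relaxations use exact exponential factors, so
the integration is insensitive to step size (the simulator steps at 1 ms
inside gated windows and coarsens in the long rests); vesicle number is
conserved to machine precision. A stochastic variant draws binomial fusion
counts behind a seed; all validation uses the mean-field core so results
are deterministic.

Why this topology: within-train facilitation requires a state variable
with multi-cycle memory that sits *below* its cycling equilibrium when a
train begins. With full per-burst RRP drainage (p_release = 0.6 over 30
pulses empties any realistic RRP), the RRP itself has one-cycle memory;
the gated staging pool provides the slow variable — it builds over
successive gate windows, so refill per cycle grows across the train. The
across-sweep depression is reserve exhaustion: with slow recycling
(`recycle_delay` longer than the session) and near-zero resting
remobilisation, each sweep works from a smaller mobilisable reserve.

Genotype presets encode the proposed synuclein actions:

| parameter | WT | KO | reading |
| --- | --- | --- | --- |
| `k_clear` (1/s) | 5.0 | 0.5 | α-syn speeds active-zone clearance |
| `k_reserve` (1/s, gated) | 0.01 | 0.002 | activity-driven mobilisation, α-syn-enhanced |
| `k_rest` (1/s) | 2·10⁻⁵ | 2·10⁻³ | resting remobilisation, α-syn-inhibited |
| `recycle_delay` (s) | 1800 | 90 | α-syn slows re-entry of used vesicles |

Shared: n_az = 100, RRP₀ = capacity = 100, RP₀ = 0, reserve₀ = 5000,
p_release = 0.6, k_refill = 0.35 /s, k_demob = 0.02 /s, q = 0.0145 µM per
released vesicle unit. These values were calibrated once against the
package's stated phenotype targets — WT within-train facilitation, WT
first-train-burst decline across sweeps, WT sweep-6/sweep-1 single-burst
peak ≈ 50 % through the full FSCV pipeline, KO within-train depression
with flat sweeps, and 5–80-pulse release linearity (affine residual < 2 %
of maximum) — and are re-tunable via `PoolParams`.

Monotonicity sanity checks follow the model levers: raising `k_clear`
never reduces the within-train burst-6/burst-1 ratio, and raising `k_rest`
never deepens the sweep-6/sweep-1 ratio (checked over parameter grids).

## Synthetic data generators

The generators emulate the *statistical structure* the analysis code must
handle, with ground truth attached; they do not emulate electrode fouling,
pH drift, adsorption kinetics, photon shot noise, hemodynamics, or
movement artifacts, so green tests certify the analysis conventions and
their numerical implementation — not robustness to every failure mode of
real recordings.

**Spike trains.** Pacemaker: Gaussian-jittered ISIs (CV ≈ 0.05 by
default). Irregular: gamma ISIs over a 90-ms refractory floor (CV ≈ 0.5);
the floor keeps ground-truth irregular trains below the SFB criterion,
which a memoryless process at tonic rates above ~1.5 Hz would frequently
violate. Bursty kinds superimpose 3–6-spike bursts (intra-burst ISIs
20–60 ms) on a pacemaker (CV 0.22) or irregular (CV 0.7) background, with
a 0.25–0.6-s post-burst pause before tonic firing resumes; the pause both
produces the classic broad ACH pause peak and guarantees the closing ISI
meets the 160-ms offset. Burst frequency is solved from the target SFB.
`gen_population` regenerates members until the detector confirms the
requested bursty count, so population-level splits are exact by
construction.

**DA kinetics.** d[DA]/dt = Σᵢ rᵢ·δ(t−tᵢ) − Vmax·[DA]/(Km+[DA]), forward
Euler at 1 ms. Defaults: Vmax = 4 µM/s (dorsal-striatum range),
Km = 0.05 µM, release 0.098 µM/pulse. The three were calibrated jointly so
that a 30-pulse 50-Hz burst peaks at 0.9 µM *and* peak vs pulse number is
linear over 5–80 pulses (r² > 0.99): both require the per-pulse release
rate (≈ 4.9 µM/s at 50 Hz) to exceed the saturated uptake rate, i.e.
effectively zero-order reuptake during bursts — a small Km relative to
evoked concentrations. A larger Km (0.2 µM) leaves uptake only partially
saturated and visibly curves the pulse–response relation.

**FSCV rendering.** currents = static capacitive-like background +
c(scan time) × calibration × DA voltammogram template + white noise
(0.2 nA SD) + linear drift (0.05 nA/s). The template is a Gaussian
oxidation peak centred at +300 mV on the anodic ramp (SD 150 mV,
normalised to 1 at the extraction sample) minus a smaller reduction peak
at −200 mV on the cathodic ramp. Noise and drift give SNR ≈ 45 at 0.9 µM
with a 10-nA/µM electrode.

**Photometry.** Per-pulse impulses convolved with a 50-ms-rise /
400-ms-decay double exponential (unit peak), scaled to 0.4 % ΔF/F per
pulse on a 465-channel baseline of 100 a.u.; both channels share a slow
sinusoidal drift (scaled by the channel gain) plus 0.1-a.u. white noise.
The decay constant makes single-burst transients return below 10 % of
peak within 2 s, and linearity of AUC in pulse count is inherited from
the LTI convolution.

## Validation protocol

Parameter-recovery checks (sigmoid and line) regenerate data from the
printed model values with Gaussian noise (SD 0.05 µM, 5 replicates per
level) and refit; because the Vmax/K½/h estimator has a few-percent
sampling SD at this design, the recovery experiment is replicated five
times with independent noise and the median fitted parameters are
reported. The full-pipeline depression check simulates the complete
six-sweep paradigm (≈ 50 min of simulated recording, ~27,000 scans) and
runs in a few seconds; test problem sizes throughout were chosen to keep
the whole suite under half a minute while leaving every contract
non-trivially exercised.

## Known limitations

- The pool model is mean-field and phenomenological; its parameters are
  calibration artifacts and should not be read as physical rates.
- The ACH classifier thresholds are surrogates for verbal criteria;
  borderline bursty / irregular-bursty trains are genuinely ambiguous.
- t½ and AUC depend on window placement for overlapping transients; the
  defaults assume ≥ 5-s inter-burst spacing.
- No chemometric (principal-component) voltammogram correction: the
  single-point calibration assumes a DA-dominated signal.
- Group-level inferential statistics are out of scope by design; the tidy
  per-animal tables are the hand-off point to any statistics package.
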