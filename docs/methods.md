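# Methods

This note documents the models, estimators, parameter choices, and
numerical conventions implemented in `synscale`, and what the
synthetic-data validation does and does not establish about real
recordings.

## Units and containers

All internal quantities are in pA (voltage-clamp current), mV
(voltage), s, Hz, and MΩ; integrated neurograms carry arbitrary units.
A `Trace` is a uniformly sampled single channel with a declared role;
uniformity of two-column time files is enforced to 1 ppm at the I/O
boundary, and no resampling is ever performed internally.

## Synthetic mEPSC recordings

A recording is `baseline + Gaussian noise − Σ events`. Each event is a
difference of exponentials `e^(−t/τ_decay) − e^(−t/τ_rise)` normalized
to unit peak and scaled by a drawn amplitude, so an isolated event's
extremum sits exactly one amplitude below baseline (inward current at a
−80 mV holding potential; amplitudes are reported as positive
magnitudes throughout). Event times are Poisson; overlaps summate.

Defaults, with reasons:

| parameter | default | why |
|---|---|---|
| τ_rise / τ_decay | 1 ms / 8 ms | typical AMPA-receptor mEPSC kinetics; the analyses use only rise time, which is reported, not a kinetics model |
| amplitude law | lognormal, median 18 pA, σ = 0.40 | right-skewed, as universally observed for quantal amplitudes; σ chosen so < 2% of mass lies below the 7.5 pA detection floor (1.4%), keeping truncation bias in scaling recovery negligible. σ = 0.40 corresponds to CV ≈ 0.42 |
| event rate | 1.5 /s | mid-range for mEPSC recordings; guarantees ≥ 50 events in a one-minute trace with overwhelming probability, as the first-50 sampling design requires |
| noise SD | 2 pA | puts the 7.5 pA rejection threshold at ≈ 4× the noise, the regime the detector is specified for; exposed in config |
| seed policy | one master seed; per-neuron streams via `SeedSequence.spawn` | bit-identical cohorts under a fixed master seed |

A treated cohort is generated by multiplying every drawn amplitude by
the scaling factor before trace synthesis (implemented as scaling the
lognormal median, which is the same operation draw-for-draw), with
event times independent of the control cohort.

**Problem sizes.** Minute-long cohort simulations in the test suite and
the acceptance script run at 5 kHz sampling rather than the 100 kHz
hardware default: the 1 ms-rise kernel is fully resolved at 5 kHz, and
the detector's ground-truth certification is unchanged. Burst-recovery
simulations use 120-s epochs at 50 Hz; the pipeline default remains
10-minute epochs.

## mEPSC detection

The detector is deliberately minimal so its behavior can be certified
against ground truth: 4th-order Butterworth low-pass at 1 kHz
(zero-phase), running-median baseline over 200 ms (evaluated on a
50 ms grid and interpolated), peak finding on the baseline-subtracted
inward deflection with a 7.5 pA height threshold and 5 ms minimum peak
separation. The onset is the last baseline crossing before the peak;
when no crossing exists within 50 ms (an event riding the decay of the
previous one) the onset is the inter-event minimum, the amplitude is
measured from that local level, and the event is flagged `overlapped`.

Conventions that differ between laboratories, pinned down here:

* **Rise time is onset-to-peak**, not 10–90%.
* **Charge** integrates the baseline-subtracted current from onset
  until it first returns within 2.5% of the event amplitude of the
  local baseline (0.5 pA for a 20 pA event), capped at 100 ms. The
  tolerance is relative so that charge, like amplitude, scales exactly
  linearly with the deflection.
* **Frequency counts post-threshold events** per minute.

Recording QC follows standard slice-physiology practice: resting
potential more negative than −45 mV, action potentials taller than
50 mV, series resistance at most 25 MΩ and drifting less than 20%;
failures are enumerated per criterion, and missing fields yield an
explicit `incomplete` status rather than a silent pass or fail.

## Rank-order scaling analysis

Equal pooled counts are enforced (the caller samples the first n per
neuron; nothing is subsampled silently). Treated amplitudes are
regressed on control (OLS, free intercept), so a slope above 1 means
up-scaling and the intercept's closeness to zero is itself a check of
pure multiplicativity. The exponential alternative `y = a·e^(bx)` is
fitted by nonlinear least squares initialized from the log-linear fit,
with r² computed on the original scale so the two models are
comparable. Down-scaling divides by the fitted slope and removes
values below the 7.5 pA floor (they cannot appear in the control
distribution); only the down-scaled distribution is filtered — the
control side is left intact, with symmetric truncation of the control
distribution available in config as an alternative convention.
Kolmogorov–Smirnov comparisons use the exact null when
`n_a·n_b ≤ 10⁴` and the asymptotic approximation otherwise; the mode
used is always recorded.

The `multiplicative` verdict requires all three of: linear r² above
exponential r², raw KS p < α, down-scaled KS p ≥ α (α defaults
to 0.05).

Two properties of this estimator surfaced by the validation suite are
worth knowing:

* **Truncation bias.** Detection censors the control distribution at
  7.5 pA more than the (larger-amplitude) treated distribution, biasing
  the recovered slope up by ≈ +0.015 at the default amplitude law.
  The median recovered factor over 100 simulated studies is ≈ 1.52 for
  a generative factor of 1.51.
* **r² fluctuation.** The median rank-order r² under true scaling is
  ≈ 0.993, but because the two pooled n = 800 samples are independent,
  their extreme order statistics fluctuate independently, and r² falls
  below 0.99 in roughly a third of realizations — for any right-skewed
  amplitude law with a realistic CV. A single observed r² of 0.99 is
  therefore typical of multiplicative scaling, but it is not a
  near-certain event per realization, and the suite documents this
  honestly rather than asserting it.
* **Fit comparison does not separate LTP by itself.** For an LTP-like
  mixture (a random 30% of synapses potentiated 3×) OLS r² on ranked
  data is dominated by the upper ranks, which both two-parameter models
  track, so the linear r² typically stays higher; it is the down-scaled
  KS test that correctly refuses to certify such data as multiplicative.

## Intrinsic excitability

The step protocol is 24 sweeps, −150 pA to 1000 pA in 50 pA increments,
0.5 s per step. Input resistance is the OLS slope of steady-state
deflection (mean of the last 100 ms of the step, ≥ 5 membrane time
constants for plausible cells) versus current over the non-positive
steps. Firing rate is spike count divided by step duration (not
inverse-ISI), and the F-I gain is the OLS slope of rate versus current
over 0–1000 pA, with a suprathreshold-only option. Spikes are upward
0 mV crossings with a 2 ms refractory; spike amplitude is measured from
the take-off point (last pre-peak sample with dV/dt below 20 mV/ms), and
spikes below the 50 mV QC criterion are flagged, not discarded. Resting
potential is the pre-step baseline plus a single −12 mV liquid-junction
correction; traces marked as already corrected are refused.

The synthetic neuron is a leaky integrate-and-fire cell with an
absolute refractory period — the simplest spiking model with a closed
form, `f(I) = 1/(t_ref + τ_m·ln(ΔV∞/(ΔV∞ − ΔV_th)))`, which serves as
an independent oracle: simulated families recover input resistance
within 2% and gain within 5% of the analytic values at 0.1 ms steps.

Group comparison uses the homogeneity-of-slopes ANCOVA — the F test of
the `current × group` interaction in `rate ~ current * group` — plus an
unpaired t test on per-neuron gains. The ANCOVA's type-I calibration is
verified on a null that satisfies the model's assumptions (shared line,
iid noise); real step families with per-neuron random slopes would
require a mixed model, which is out of scope.

## Burst analysis

Raw nerve signals are conditioned as in standard rhythm-recording
chains: causal 100–1000 Hz band-pass, full-wave rectification, leaky
integration with a 60 ms time constant. Burst detection runs on
integrated traces: rolling-median baseline (60 s window), entry
threshold at baseline + 4×MAD with hysteresis exit at +2×MAD, duration
gate 0.3–3 s (operationalizing "about one second"). A vagal burst
counts as respiratory only when a hypoglossal burst onset lies within
±0.5 s — coactivation of both outflows is the signature of the
respiratory pattern generator. Burst amplitude is the within-burst
maximum minus the mean of the preceding second; area integrates the
baseline-subtracted trace over the burst, clipped at zero.

Because suction-electrode amplitudes are not comparable across
preparations, epoch summaries report percent-of-baseline only; there is
deliberately no API for absolute cross-preparation amplitude
comparison. The synthetic neurogram paints half-sine bursts at renewal
times whose mean interval equals the configured rate exactly (a
refractory gap plus an exponential tail), so configured per-epoch
amplitude and frequency multipliers are recovered without bias; chance
coincidences between an injected cnx-only burst and an unrelated
hypoglossal burst are possible by construction, exactly as in real
recordings.

## Statistics

Two-tailed throughout; Welch's correction is an explicit per-call
choice (an F-test-based `auto` exists but is never a default, to keep
analyses reproducible); Mann–Whitney is exact up to 8 per group without
ties and normal-approximated with tie and continuity corrections
otherwise; paired t on differences; no multiple-testing correction
anywhere, with the number of tests run noted in report output. Exact
KS and Mann–Whitney p-values are certified in the test suite against
brute-force enumeration over all rank arrangements.

## Degenerate inputs and tie-breaks

Zero detected events yield a flagged record, not an exception; a
zero-variance t test reports the p = 1 convention (equal means) or a
flagged infinite statistic (paired, constant nonzero difference);
all-silent step families report gain 0 with a zero-activity flag; an
empty baseline epoch leaves percent-of-baseline undefined and flagged.
Rank pairing uses a stable sort, ties keeping input order (irrelevant
to any fit, fixed for reproducibility). Down-scaling then re-scaling is
exact in real arithmetic and to one ulp in floats (exact for
power-of-two factors).

## What the synthetic validation does not show

The generator emulates the statistical structure the analyses assume —
Poisson event times, a stationary right-skewed amplitude law, Gaussian
noise, stereotyped kinetics, half-sine burst envelopes. Real recordings
add dendritic filtering (amplitude-dependent kernel shapes),
non-stationary noise and baseline drift, series-resistance changes,
correlated event timing, and buccal-type fast bursts, none of which are
modeled. Passing the recovery suites certifies the estimators under
the stated assumptions; it does not certify the detector's behavior
under heavy space-clamp error, nor the burst classifier against
non-respiratory discharge patterns beyond simple solo-channel events.
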