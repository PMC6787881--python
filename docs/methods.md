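# Methods

`dintest` implements a free-field digits-in-noise (DIN) speech test as a
simulation and analysis engine. This note documents the model, the
parameters that matter, the synthetic-data assumptions, and the numerical
and design choices, so results produced with the package can be
interpreted correctly.

## The test procedure

A trial presents a triplet of spoken digits against multitalker babble.
Only the nine monosyllabic digits are used ("oh"=0, 1–6, 8, 9; 7 is
disyllabic and excluded). Within a triplet no digit repeats; within one
test run no ordered triplet is presented twice (504 ordered sequences
exist, so a ~25-trial run never approaches exhaustion). A trial is scored
correct only if all three digits are reported correctly *and in order*.

Digit onsets are isochronous: the inter-onset interval is the duration of
the longer of the first two digits plus 140 ms, the same between digits
1→2 and 2→3. Babble runs from 600 ms before the first digit to 600 ms
after the third digit's offset. The target is fixed at 62 dB(A); SNR is
varied by moving the masker level (masker = 62 − SNR), and a 400 ms cue
light marks the first-digit onset in the hardware version (a constant
here; no audio playback is performed).

## The adaptive staircase

The SNR track has three phases:

1. **Descent (1-up/1-down, 6 dB).** From +14 dB SNR (colocated) or
   +11 dB (separated), each correct response lowers SNR by 6 dB. The
   first incorrect response is the first reversal of the track and drops
   the step to 3 dB.
2. **Recovery (3 dB up).** SNR rises 3 dB per incorrect response until a
   correct response occurs (the second reversal). That correct response
   counts as the first of a down-pair and does not itself move SNR.
3. **Tracking (2-down/1-up, 3 dB).** Two consecutive correct responses
   lower SNR 3 dB; one incorrect raises it 3 dB. This rule converges on
   the SNR where P(triplet correct) = √0.5 ≈ 70.7%. A reversal is
   recorded whenever movement direction flips, at the SNR presented on
   the flipping trial (the track extremum — the standard transformed
   up-down convention). The track stops at the sixth tracking-phase
   reversal, and **SRT = mean of those six reversal SNRs**. The two
   phase-transition reversals are not among the six.

No SNR ceiling or floor is imposed; a `max_trials` bound (default 60)
marks runaway tracks unconverged. The engine is exactly reproducible
under a fixed seed, and a property test checks it trial-for-trial against
an independent straight-line restatement of the rules.

### Known bias of the reversal-mean estimator

The nominal 70.7% target is the fixed point of the 2-down/1-up rule, but
the *mean of reversal extrema* with a fixed 3 dB step is not an unbiased
estimate of that point: upward excursions (one error per 3 dB step) are
faster than downward ones (two corrects per step), so peaks overshoot
more than valleys undershoot. Simulation — both with this engine and with
an independent bare random-walk implementation — puts the bias near
+0.1 dB, essentially independent of slope and persisting asymptotically.
Evaluated on the psychometric function this corresponds to ≈ 71–73%
rather than 70.7% at realistic slopes. This is a property of the
procedure itself, shared by any faithful implementation, and is reported
as measured by `dintest.validation.staircase_convergence`.

## The simulated listener

Per-digit recognition follows a guessing-corrected Boltzmann function

  P_c(SNR) = γ + (1 − γ) / (1 + exp(−β (SNR − SRT₅₀)))

with γ = 0.11 (chance for nine alternatives), slope β (per dB) and
midpoint SRT₅₀ (where P_c = 0.555). Digits within a triplet are
recognized independently, so P(triplet) is the product of the three
per-digit probabilities; the 70.7% triplet point corresponds to per-digit
p = 0.5^(1/6) ≈ 0.891. A missed digit is reported as a uniform draw from
the other eight (confusion structure is not modelled). The spatially
separated condition is modelled as a fixed per-listener SNR advantage
(spatial release from masking, SRM) added to the effective SNR.

Simulation defaults: adult per-digit slope β = 0.7/dB; children 0.75×
that (0.525/dB), reflecting shallower child psychometric functions. These
are simulation defaults exposed in configuration, not measured constants.
The listener is an *ideal* observer apart from its sensory noise: it has
no attentional lapses, no fatigue, and no response-set errors. This is
the main reason simulated tracks finish in ≈ 21 trials on average where
child participants need ≈ 23–24; passing trial-count checks should be
read with that idealization in mind.

## Psychometric fitting and homogenization

Each digit's intelligibility is estimated by pooling every presentation
of that digit — across runs, spatial conditions and triplet positions —
at the SNR *relative to the SRT of its own track*. Fitting is Bernoulli
maximum likelihood on raw trials with γ fixed at 0.11 (the original
analysis fitted binned percent-correct without stating a criterion;
trial-level likelihood is the statistically cleaner equivalent, and 1 dB
binning is kept for plotting only). Optimization is L-BFGS-B from three
starts with β bounded in [10⁻³, 5] per dB.

A digit is flagged *ill-defined* when its data cannot constrain the
slope: fewer than 10 observations in 1 dB bins with empirical accuracy
below 0.70, or β pinned at its upper bound. Ill-defined digits are
refitted with the slope fixed to the unweighted mean slope of the
well-defined digits, leaving the midpoint as the only free parameter.
The homogenization table is adjustment(d) = mean(SRT₅₀) − SRT₅₀(d),
which sums to zero by construction; its min/max is the reported
adjustment range.

## Norms, z-scores, SRM, maturation

Child norms are linear regressions of first-run SRT on age with a
residual SD; adult norms are a mean and SD:

  0°: SRT = 4.5 − 0.69·age, SD 1.85 dB 90°: SRT = −0.9 − 0.77·age, SD 2.31 dB
  adults: 0° −5.7 (SD 2.00) dB, 90° −12.5 (SD 1.69) dB

z = −(SRT − age-expected SRT)/SD, so better-than-average (lower) SRTs get
positive z. Ages are real-valued years; no norms exist for (13, 18) y or
below 4 y, and the module refuses those ages unless an explicit
extrapolation flag is set (used for the maturation analysis, which solves
the child regression against the adult mean: ≈ 14.8 y at 0°, ≈ 15.1 y at
90°). SRM = SRT(0°) − SRT(90°); the child norm difference at age 8 is
6.04 dB. Norm refitting uses ordinary least squares with residual
SD = √(SSR/(n−2)).

Test–retest agreement is Bland–Altman: mean, SD, and mean ± 1.96·SD of
paired Run 1 − Run 2 differences (normal-theory multiplier).

## Synthetic cohort

The generator emulates the normative sample: 100 children uniform in age
4.08–13.0 y and 23 adults, each measured twice per spatial condition.
The printed norm SDs describe *observed* first-run scatter, which already
contains measurement error; the generator therefore decomposes each norm
SD into a between-subject component √(SD² − s²) plus per-run noise of
SD s = 1.6 dB. That value is a tuning choice placing the test–retest
difference SD (s·√2 ≈ 2.26 dB) mid-range of the observed 2.05–2.91 dB
band; it is not a measured constant. Practice improvements between runs
are 0.6 dB (children) and 1.0 dB (adults) in the colocated condition and
0 at 90°. SRM is age-constant by construction, N(6.0, 1.4²) dB for
children — the SD chosen so observed 90° scatter ≈ the printed 2.31 dB —
and N(6.8, 0.8²) dB for adults; an `srm_age_slope_db_per_yr` knob
(default 0) exposes the age-growing alternative. Because SRM is additive
and independent, the generator slightly inflates adult 90° scatter
relative to the printed 1.69 dB; no analysis in this package depends on
that quantity.

What the synthetic cohort does *not* emulate: non-Gaussian residuals,
age-dependent reliability, incomplete sessions of the youngest children,
head-orientation effects, and any correlation between SRM and SRT.
Passing tests on synthetic cohorts therefore validate the analysis code
and the internal consistency of the normative model, not the field
behavior of real listeners.

## Stimulus preparation (synthetic audio)

The acoustic pipeline operates at 44.1 kHz (16-bit PCM on disk, via
`scipy.io.wavfile`): LTASS estimation by Welch averaging (1024-sample
Hann windows, 50% overlap, one-third-octave smoothing — analysis
parameters are package choices, normalized to 0 dB overall level);
correction filtering by a 513-tap linear-phase FIR whose magnitude is the
reference-minus-talker spectrum in dB, with per-band gain capped at
±20 dB so empty bands are not amplified into noise; exemplar selection
retaining tokens within ±1 SD of their digit's mean RMS level *and* mean
duration ("level" is interpreted as RMS; the source procedure does not
say); and level equalization to the pre-equalization mean RMS. The final
same-voice-quality choice, subjective in the original corpus work, is
replaced by an automated stand-in: the six retained exemplars whose
autocorrelation-estimated f0 is closest to the per-digit median. Test
fixtures are synthetic digit-like tokens (speech-shaped noise with
f0-periodic structure), generated at test time.

## Problem sizes and numerics

Validation studies default to 2,000 adaptive tracks for the convergence
study and 2,000 norm-sampled listeners per trial-count study (Monte
Carlo SE < 0.1 trials); the test suite uses 1,000 and 500. All dB values
are serialized to two decimals; internal computation keeps full
precision. Every random path flows from one `numpy.random.Generator`
seed, recorded in the session log, and regeneration under the same seed
is bit-identical.

## Known limitations

- No lapse/attention model in the simulated listener (see trial counts).
- The reversal-mean SRT inherits the +0.1 dB extremum bias above.
- Homogenization offsets in simulation recover whatever per-digit
  offsets the listener profile was given; the package does not claim to
  reproduce any particular corpus's adjustment range.
- The stimulus pipeline is validated on synthetic tokens only; no speech
  recordings ship with the package.
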