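# Methods

This note documents the models, the generator design, the numerical
choices, and the limits of what the synthetic-cohort tests demonstrate.

## The decay model and its fitting

All three paradigms reduce to a measure `y` observed at four intervals
`t` and modeled as `y(t) = α + β·exp(−t/τ)`.  Fits minimize squared error
under box bounds: `α, β ∈ [0, 100]` for d′ measures; `α ∈ [0, 15000]`,
`β ∈ [−15000, 0]` for the (positive) P2 area in µV·ms; the mirrored
convention `α ∈ [−15000, 0]`, `β ∈ [0, 15000]` for the (negative) N1 —
the sign convention for N1 is an interpretation: a negative component
recovers toward a more negative asymptote.  `τ ∈ [0, 100]` s everywhere.

With only four time points the τ profile of the squared error is often
nearly flat, so single-start optimizers are unreliable.  `fit_decay` runs
a multi-start search: 40 log-spaced τ values (0.1–100 s), an exact bounded
linear solve for (α, β) at each, and a bounded trust-region polish of the
best start.  Noise-free curves are recovered to ~1e−12 and `R² = 1`
(tested).  Degenerate inputs: constant `y` returns `α = mean(y)`, `β = 0`,
τ flagged non-identifiable; a fit is also flagged when `|β|` is below
twice the residual SD or τ lands on a search bound.

Per-subject fits on noisy four-point curves are heavy-tailed: a noise
realization that flattens the curve sends τ̂ up the flat profile toward the
bound, one that exaggerates the first point sends it toward zero.  The
pipeline's group-level τ is therefore a 10% trimmed mean of the
per-subject estimates; for tightly identified cohorts (all ERP settings
here) this coincides with the plain mean, which is also reported.

Block intervals enter the fit at their nominal values: active-condition
ITIs 1.4/2.9/5.9/8.9 s, passive ISIs 2/3.5/6.5/9.5 s.  Tone durations
(50 ms in the emulated design) are neglected on the session clock — this
is the only convention under which the nominal ITIs, the 600 ms inter-tone
interval and the 2/3.5/6.5/9.5 s onset asynchronies are mutually
consistent.

## Contraction-bias observer

The observer holds an implicit prior over the first-tone frequency,

```
prior(t) = γ·f1(t−1) + (1−γ)·mean(f1(1..t−1)),
```

mixing a recency component with the running mean (γ = 0.6 by default,
which reproduces both a Recent and a Global context contribution in the
choice GLM).  Its percept of the first tone is pulled toward the prior
with a weight that decays with the inter-trial interval,

```
w(t) = w_floor + (w0 − w_floor)·exp(−iti/τ_mem),
f1* = (1 − w)·f1 + w·prior,
```

and it answers "first higher" when `f1* + ε > f2`, `ε ~ N(0, (σ·f1)²)`.
The decay acts on the *weight*, not on the prior's value, matching the
observation that the magnitude of the bias (not its direction) fades with
time.  Trial 1 has no prior (w = 0).  With σ = 0 the observer is the
deterministic sign comparison (tested).

**Calibration.**  Planting a target Δd′ decay curve requires inverting the
map from weight to *measured* context effect.  That map is estimated by
Monte-Carlo with a fixed internal seed — simulating finite 100-trial
blocks and applying the exact analysis pipeline (running-mean labeling,
1/(2N) rate clipping) — because the finite-sample estimator is
substantially attenuated relative to the asymptotic expectation, and it
saturates near Δd′ ≈ 3: trials with large frequency differences are
immune to contraction, so no weight w ≤ 1 can push the measured effect
much higher.  (w0, w_floor, τ_mem) are then chosen by least squares so the
expected measured Δd′ matches the target at the four block ITIs.  Decay
cohorts use γ = 0 so the generative prior coincides with the analysis
labeling prior; σ = 0.055 keeps response rates away from the
variance-inflating extremes of Φ⁻¹ while leaving the needed dynamic range.

Because of the saturation, the dyslexic reference curve — whose
extrapolated Δd′(0) = α + β = 4.5 exceeds the measurable range — is
planted scaled by 0.70.  Scaling a decay curve changes α and β but not τ
(a tested invariance), and τ is the quantity the recovery exercises.

**What recovery does and does not show.**  The behavioral Δd′ point noise
at 100 trials per block is ≈ 0.5–0.6 d′ (binomial rates through Φ⁻¹),
which is irreducible given binary choices; per-subject τ̂ therefore
scatters over an order of magnitude, and 23–25-subject group means move by
±1–1.5 s between master seeds.  Behavioral τ recovery should be read as
"unbiased to within the estimator's own sampling noise", not as a
precise measurement — the same caveat applies to any real cohort of this
size and trial count.

## Synthetic EEG and the ERP pipeline

Recordings are single virtual vertex-channel traces at 256 Hz in µV.
Each stimulus event contributes two fixed raised-cosine kernels: N1
(negative, centered 100 ms, half-width 30 ms) and P2 (positive, centered
200 ms, half-width 50 ms), each inside its analysis window (70–130 /
150–250 ms).  The planted area of each component follows
`α + β·exp(−Δt/τ)` with Δt the time since the previous event; the first
event of a block is fully recovered (Δt = ∞ → area α).  In the active
condition the second tone of a trial follows at 600 ms; there the curve
extrapolates past zero, and since adaptation cannot invert a component's
polarity, second-tone target areas are clipped at zero (second-tone
responses are never analyzed).

Kernel amplitudes are solved through a 2×2 transmission matrix measured by
passing unit kernels through the package's own band-pass, baseline and
windowed-area code: the 1–30 Hz filter removes a noticeable fraction of a
kernel's windowed area and leaks a little across windows, and the matrix
pre-compensation makes planted areas exact after the full pipeline
(noise-free round trip agrees to ≪1%, tested at every block interval in
both conditions).

The analysis chain follows standard practice: zero-phase Butterworth
band-pass (order 2 per pass; 5 Hz attenuated <5%, 60 Hz >90%, DC
removed — tested), artifact rejection on the continuous signal as the
union of three rules (|x| > 100 µV → ±300 ms; 50 ms max–min range >
100 µV → ±200 ms; adjacent-sample step > 50 µV → ±300 ms; each verified
sample-exactly against brute-force oracles), 2000 ms epochs from −500 ms,
baseline −500..−150 ms, exclusion of epochs touching rejected samples, and
component areas as the integral of the block-average waveform over the
exact closed window (fractional-sample endpoints are interpolated, so a
constant 1 µV across 150–250 ms is exactly 100 µV·ms).

Generator noise defaults are `noise_sd = 3 µV` white noise (per-subject
windowed-area standard error ≈ 5 µV·ms at 100 epochs/block) plus sham
ocular/movement artifacts at 0.5/min (400 µV, 80 ms), and 10%
between-subject CV on planted (α, β, τ).  These defaults are deliberately
clean: they make every planted recovery curve identifiable from four
interval points, so recovery failures indicate pipeline bias rather than
noise.  Real cohorts are several-fold more variable between subjects;
passing recovery here demonstrates correctness of the measurement chain,
not that real data of this size would constrain τ equally well.

## Reading sessions

Sessions are self-paced: each non-word appears 500 ms after the voice
offset of its predecessor; response time is visual onset → voice onset.
Non-words are unique disyllables (CV+CVC or CVC+CV) except for planned
within-block repetitions with at least one intervening item.  The lag plan
places 40 repeated tokens per 120-word block: 12 at the minimum legal lag
(one intervening item, giving intervals just under 2 s at control reading
rates) and 28 at long log-normal lags (mean interval ≈ 40 s, max ≈ 160 s).
A repeated item's second reading time is its own first reading time
reduced by the planted benefit, evaluated at the actual first-voice-offset
→ second-visual-onset interval:

```
benefit(Δt) = floor + (b0 − floor)·exp(−Δt/τ_read)   [percent]
```

Published group values are per-bin mean benefits, not curve parameters,
so the generator's (b0, floor) are solved from the two bin means via the
linear relation `bin_mean = floor·(1−Ē) + b0·Ē`, `Ē = E[exp(−Δt/τ)|bin]`,
with Ē estimated from a short timing-only simulation (fixed internal
seed) and τ_read fixed a priori (7 s control, 5 s dyslexic).  Percent
benefit is invariant to a uniform slowing of all reading times (tested),
which is what makes the slower dyslexic-like group comparable to
controls.  Pairs with a reading error at either presentation are dropped
(switchable); the interval definition is switchable to onset→onset.

## Group statistics

Between-group, paired and repeated-measures comparisons use Mann-Whitney
U, Wilcoxon signed-rank and Friedman tests (scipy), with the U convention
"number of (x, y) pairs with x > y, ties counting ½" verified against
exhaustive enumeration.  Null calibration (rejection rate 0.05 ± 0.02
under identical generative parameters) and power for the planted
control/dyslexic τ difference are covered by tests.

## Known limitations

* The observer has no lapse/attention model, so its overall d′ at the
  planted bias levels exceeds typical human performance; only the context
  *difference* is calibrated.
* The measured Δd′ saturates near 3 d′ units under the stated stimulus
  statistics; extrapolated curve values above that are representable only
  scaled (see above).
* Synthetic EEG has a single channel, fixed component latencies and
  white noise — no alpha rhythm, drifts, or ocular topography; the
  rejection rules are exercised by injected square artifacts only.
* The reading generator does not model articulation–orthography
  interactions; non-words are ASCII stand-ins with the right
  combinatorial structure, not Hebrew phonology.
* Hierarchical seeding makes every cohort reproducible from one master
  seed, but behavioral τ recovery remains seed-sensitive at realistic
  trial counts (see calibration section).
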