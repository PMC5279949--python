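# memtrace

Decay of implicit memory traces in auditory perception: simulation and
analysis pipelines for two-tone frequency discrimination with contraction
bias, N1/P2 auditory ERP adaptation, and repetition priming of oral
non-word reading.

## The scientific problem

In a two-tone frequency discrimination trial the listener hears two tones
(`f1`, then `f2` after 600 ms) and reports which was higher.  Responses are
not driven by the current trial alone: the remembered `f1` is *contracted*
toward the statistics of previous stimuli (an implicit prior).  When this
contraction widens the within-trial difference it helps (**Bias+** trials),
when it shrinks it it hurts (**Bias−**).  Sensitivity is measured as

```
d' = Φ⁻¹(HR) − Φ⁻¹(FA)
```

with HR/FA the "first tone higher" response rates given `f1 > f2` /
`f1 < f2`, and the behavioral **context effect** is
`Δd' = d'(Bias+) − d'(Bias−)`.  The central quantity throughout the package
is the bounded exponential decay of such context measures with the time
`t` since the previous stimulus:

```
y(t) = α + β·exp(−t/τ)
```

where `α` is the asymptote after recovery, `β` the magnitude of adaptation
at `t = 0`, and `τ` the time constant of the implicit memory trace.  The
same model is fitted to three measures: the Δd' context effect across
inter-trial intervals (1.4/2.9/5.9/8.9 s), the windowed areas of the N1
(70–130 ms) and P2 (150–250 ms) auditory ERP components as they recover
from adaptation, and the percent reading-time benefit from re-reading a
recently seen non-word.  A population with faster trace decay — the
hypothesis for dyslexia — shows a smaller `τ` on all three measures.

Since no raw study data are distributed, the package is built around
*planted-parameter recovery*: synthetic cohorts are generated with
published control/dyslexic group estimates as generative ground truth, and
the full analysis pipeline (preprocessing included) must recover them.

## Modules

| module           | contents |
|------------------|----------|
| `synthetic_data` | trial-sequence generators (random and decorrelated), the contraction-bias observer, synthetic single-channel EEG with planted N1/P2 recovery curves, self-paced reading sessions with planted repetition-benefit decay |
| `behavior`       | d′, Bias± labeling, Δd′ context effect per ITI, three-predictor choice GLM (trial Δf, global-context congruence, recent-context congruence) |
| `erp`            | 1–30 Hz zero-phase band-pass, three-rule amplitude/gradient artifact rejection, epoching with −500..−150 ms baseline, windowed component areas |
| `decay`          | bounded multi-start least-squares fit of `α + β·exp(−t/τ)` with measure-specific bounds |
| `reading`        | repetition pairing, per-interval-bin benefit summaries |
| `pipeline`       | cohort simulation, experiment orchestration, nonparametric group tests, planted-parameter recovery entry points |

## Worked example

Plant a decaying contraction bias in a simulated cohort and recover its
time constant:

```python
import numpy as np
from memtrace import (generate_random_sequence, simulate_observer,
                      context_effect, fit_decay, ObserverParams)

observer = ObserverParams(sigma=0.055, w0=0.85, w_floor=0.20,
                          tau_mem=4.6, gamma=0.0)
rng = np.random.default_rng(0)
itis, ddprime = [], []
for iti in (1.4, 2.9, 5.9, 8.9):
    vals = []
    for _ in range(30):                      # 30 simulated listeners
        seq = generate_random_sequence(100, iti=iti, seed=rng)
        choices = simulate_observer(seq, observer, seed=rng)
        vals.append(context_effect(seq, choices).delta_dprime)
    itis.append(iti); ddprime.append(float(np.mean(vals)))
    print(f"ITI {iti:>4} s   mean delta-d' = {np.mean(vals):.2f}")
fit = fit_decay(itis, ddprime, kind="dprime")
print(f"decay fit: alpha={fit.alpha:.2f} d', beta={fit.beta:.2f} d', "
      f"tau={fit.tau:.1f} s, R^2={fit.r_squared:.3f}")
```

prints

```
ITI  1.4 s   mean delta-d' = 2.64
ITI  2.9 s   mean delta-d' = 2.06
ITI  5.9 s   mean delta-d' = 1.55
ITI  8.9 s   mean delta-d' = 1.22
decay fit: alpha=1.01 d', beta=2.33 d', tau=3.8 s, R^2=0.996
```

The context effect is large right after the previous trial (Δd' ≈ 2.6 at
1.4 s) and decays toward its asymptote within a few seconds; the fitted
`τ` estimates how long the implicit trace of the previous trials keeps
shaping perception.  Note that the observer's weight-decay constant
(`tau_mem`) and the fitted Δd′-decay constant agree only through the
calibrated weight→Δd′ mapping; `memtrace.pipeline` handles that
calibration when planting published group curves.

A command-line interface exposes the same machinery
(`memtrace simulate / analyze / fit / report`); see `memtrace --help`.

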