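"""Synthetic cohorts for serial two-tone psychophysics, ERP adaptation and
oral-reading repetition priming.

Every downstream analysis in this package can be exercised without any real
data: this module generates

* two-tone trial sequences (random, or decorrelated so that the global and
  recent context directions are statistically independent),
* choices of a contraction-bias observer whose reliance on the stimulus
  prior decays exponentially with the inter-trial interval,
* single-channel EEG whose N1/P2 areas recover from adaptation along a
  planted ``alpha + beta*exp(-dt/tau)`` curve,
* self-paced non-word reading sessions whose repetition benefit decays with
  the interval since the previous encounter of the same item.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm

from . import erp as erp_mod

__all__ = [
    "ConfigurationError", "GenerationError",
    "ToneTrial", "TrialSequence", "ObserverParams",
    "ErpComponentGen", "ErpGenParams", "ReadingGenParams", "LagPlanConfig",
    "generate_random_sequence", "generate_decorrelated_sequence",
    "phi_coefficient", "simulate_observer", "calibrate_observer",
    "make_event_schedule", "generate_eeg",
    "generate_nonwords", "make_lag_plan", "generate_reading_session",
    "calibrate_reading_benefit",
    "write_trial_table", "read_trial_table",
]

INTER_TONE_INTERVAL = 0.6          # s between the two tones of a trial
DEFAULT_F_BAND = (800.0, 1250.0)   # Hz
DEFAULT_DF_BAND = (1.0, 30.0)      # percent


class ConfigurationError(ValueError):
    """Invalid generator configuration (e.g. degenerate bands)."""


class GenerationError(RuntimeError):
    """Constrained generation failed within the attempt budget."""


# ---------------------------------------------------------------------------
# trial sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToneTrial:
    """One two-tone trial.  ``iti`` is the interval from the previous
    trial's second tone to this trial's first tone (None for trial 1).
    Tone durations (50 ms in the emulated design) are neglected on the
    session clock, so offsets coincide with onsets."""

    index: int          # 1-based
    f1: float           # Hz, first tone
    f2: float           # Hz, second tone
    onset1: float       # s
    onset2: float       # s
    iti: float | None

    def __post_init__(self):
        if self.f1 == self.f2:
            raise ValueError("f1 and f2 must differ")
        if self.iti is not None and self.iti <= 0:
            raise ValueError("iti must be positive")


@dataclass
class TrialSequence:
    """Ordered two-tone trials plus the design they were drawn from."""

    trials: list[ToneTrial]
    design_tag: str = "random"

    def __post_init__(self):
        onsets = [t.onset1 for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trials must be sorted by onset")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def f1(self) -> np.ndarray:
        return np.array([t.f1 for t in self.trials])

    @property
    def f2(self) -> np.ndarray:
        return np.array([t.f2 for t in self.trials])

    @property
    def itis(self) -> np.ndarray:
        return np.array([np.nan if t.iti is None else t.iti
                         for t in self.trials])

    @property
    def global_mean_f1(self) -> float:
        return float(self.f1.mean())


def _check_band(name, band):
    lo, hi = band
    if not lo < hi:
        raise ConfigurationError(f"{name} must satisfy min < max, got {band}")


def _draw_trials(rng, n, f_band, df_band):
    f1 = rng.uniform(f_band[0], f_band[1], n)
    dfrac = rng.uniform(df_band[0], df_band[1], n) / 100.0
    sign = rng.choice([-1.0, 1.0], n)
    f2 = f1 * (1.0 + sign * dfrac)
    return f1, f2


def _assemble(f1, f2, iti, design_tag):
    iti = np.broadcast_to(np.asarray(iti, dtype=float), f1.shape)
    trials = []
    clock = 0.0
    for i in range(len(f1)):
        if i > 0:
            clock = trials[-1].onset2 + iti[i]
        trials.append(ToneTrial(index=i + 1, f1=float(f1[i]), f2=float(f2[i]),
                                onset1=clock, onset2=clock + INTER_TONE_INTERVAL,
                                iti=None if i == 0 else float(iti[i])))
    return TrialSequence(trials, design_tag=design_tag)


def generate_random_sequence(
    n: int,
    f_band: tuple[float, float] = DEFAULT_F_BAND,
    df_band: tuple[float, float] = DEFAULT_DF_BAND,
    iti: float = 1.4,
    seed: int | np.random.Generator | None = None,
) -> TrialSequence:
    """Random two-tone sequence: the base tone is uniform on ``f_band`` and
    the comparison differs by a uniform ``df_band`` percentage of either
    sign; which tone comes first is random (the percentage is defined
    relative to the first tone)."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    _check_band("f_band", f_band)
    _check_band("df_band", df_band)
    rng = np.random.default_rng(seed)
    f1, f2 = _draw_trials(rng, n, f_band, df_band)
    return _assemble(f1, f2, iti, "random")


def phi_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Phi (Matthews) correlation of two sign/boolean series via the 2x2
    contingency table.  Raises if a margin is empty (phi undefined)."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        raise ValueError("phi undefined: a contingency margin is empty")
    return (n11 * n00 - n10 * n01) / np.sqrt(denom)


def _context_signs(f1: np.ndarray):
    """G(t) = sign(f1(t) - <f1>) and R(t) = sign(f1(t) - f1(t-1)) for
    trials 2..n (the first trial has no recent context)."""
    g = np.sign(f1[1:] - f1.mean())
    r = np.sign(f1[1:] - f1[:-1])
    return g, r


def generate_decorrelated_sequence(
    n: int,
    max_phi: float = 0.05,
    f_band: tuple[float, float] = DEFAULT_F_BAND,
    df_band: tuple[float, float] = DEFAULT_DF_BAND,
    iti: float = 1.4,
    seed: int | np.random.Generator | None = None,
    max_attempts: int = 500,
) -> TrialSequence:
    """Sequence whose global-context and recent-context directions are
    uncorrelated: |phi(sign G, sign R)| < ``max_phi`` over trials 2..n.

    In an i.i.d. random sequence the two directions are strongly positively
    correlated (a tone above the session mean is usually also above its
    predecessor), so the sequence must be constructed: a fixed multiset of
    base frequencies is drawn once (leaving the marginal stimulus statistics
    untouched) and its order is optimized by pairwise-swap hill climbing on
    |phi|, with random restarts within the attempt budget.
    """
    if n < 10:
        raise ConfigurationError("n must be >= 10 for a decorrelated design")
    if not 0 < max_phi < 1:
        raise ConfigurationError("max_phi must be in (0, 1)")
    _check_band("f_band", f_band)
    _check_band("df_band", df_band)
    rng = np.random.default_rng(seed)
    f1, f2 = _draw_trials(rng, n, f_band, df_band)

    def abs_phi(order):
        g, r = _context_signs(f1[order])
        try:
            return abs(phi_coefficient(g, r))
        except ValueError:
            return np.inf        # degenerate ordering: never acceptable

    best = np.inf
    n_restarts = max(max_attempts // 100, 1)
    for _ in range(n_restarts):
        order = rng.permutation(n)
        phi = abs_phi(order)
        stall = 0
        while phi >= max_phi and stall < 40 * n:
            i, j = rng.integers(0, n, 2)
            if i == j:
                continue
            order[i], order[j] = order[j], order[i]
            phi_new = abs_phi(order)
            if phi_new < phi:
                phi, stall = phi_new, 0
            else:
                order[i], order[j] = order[j], order[i]
                stall += 1
        best = min(best, phi)
        if phi < max_phi:
            return _assemble(f1[order], f2[order], iti, "decorrelated")
    raise GenerationError(
        f"could not reach |phi| < {max_phi} within the attempt budget "
        f"(best |phi| = {best:.3f})")


# ---------------------------------------------------------------------------
# contraction-bias observer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of the contraction-bias decision model.

    The observer's percept of the first tone is pulled toward an implicit
    prior built from stimulus history,

        prior(t) = gamma * f1(t-1) + (1 - gamma) * mean(f1(1..t-1)),

    with a pull whose weight decays with the time since the previous trial:

        w(t)  = w_floor + (w0 - w_floor) * exp(-iti(t) / tau_mem)
        f1*(t) = (1 - w(t)) * f1(t) + w(t) * prior(t)

    The response ("first tone higher") is ``f1* + eps > f2`` with
    ``eps ~ N(0, (sigma * f1)^2)``.  Trial 1 has no prior (w = 0).
    """

    sigma: float = 0.055      # decision noise, fraction of f1
    w0: float = 0.6           # prior weight at iti -> 0
    tau_mem: float = 6.0      # s, memory decay time constant
    gamma: float = 0.6        # recent-vs-running-mean mix in the prior
    w_floor: float = 0.1      # prior weight at iti -> inf

    def __post_init__(self):
        for name in ("w0", "gamma", "w_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tau_mem <= 0:
            raise ValueError("tau_mem must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def weight_at(self, iti: float) -> float:
        return self.w_floor + (self.w0 - self.w_floor) * np.exp(-iti / self.tau_mem)


def _prior_series(f1: np.ndarray, gamma: float) -> np.ndarray:
    """gamma * recent + (1-gamma) * running mean; NaN for trial 1."""
    n = len(f1)
    prior = np.full(n, np.nan)
    if n > 1:
        runmean = np.cumsum(f1)[:-1] / np.arange(1, n)
        prior[1:] = gamma * f1[:-1] + (1 - gamma) * runmean
    return prior


def simulate_observer(
    seq: TrialSequence,
    p: ObserverParams,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate choices for a trial sequence.

    Returns a boolean array, True where the observer responded "first tone
    higher".  With ``sigma = 0`` the response is the deterministic sign of
    the biased comparison.
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 trials to involve a prior")
    rng = np.random.default_rng(seed)
    f1, f2 = seq.f1, seq.f2
    prior = _prior_series(f1, p.gamma)
    itis = seq.itis
    w = p.w_floor + (p.w0 - p.w_floor) * np.exp(-itis / p.tau_mem)
    w[0] = 0.0
    prior[0] = f1[0]          # inert: weight is zero on trial 1
    f1_star = (1 - w) * f1 + w * prior
    eps = rng.standard_normal(len(f1)) * p.sigma * f1 if p.sigma > 0 else 0.0
    return f1_star + eps > f2


# -- calibration of the observer against a target decay curve --------------

def _measured_ddprime_blocks(rng, w, sigma, gamma, n_trials, n_blocks):
    """Measured Bias+/Bias- d-prime difference for ``n_blocks`` independent
    blocks simulated at a fixed prior weight ``w`` (vectorized).

    The measurement matches the behavior module's convention: labels from
    the running-mean prior, trial 1 excluded, hit/false-alarm rates clipped
    to [1/(2N), 1 - 1/(2N)] per condition cell.
    """
    shape = (n_blocks, n_trials)
    f1 = rng.uniform(*DEFAULT_F_BAND, shape)
    dfrac = rng.uniform(*DEFAULT_DF_BAND, shape) / 100.0
    f2 = f1 * (1.0 + rng.choice([-1.0, 1.0], shape) * dfrac)
    runmean = np.full(shape, np.nan)
    runmean[:, 1:] = np.cumsum(f1, axis=1)[:, :-1] / np.arange(1, n_trials)
    recent = np.full(shape, np.nan)
    recent[:, 1:] = f1[:, :-1]
    prior = gamma * recent + (1 - gamma) * runmean
    f1_star = f1.copy()
    f1_star[:, 1:] = (1 - w) * f1[:, 1:] + w * prior[:, 1:]
    resp = f1_star + rng.standard_normal(shape) * sigma * f1 > f2

    s = np.sign(f1 - f2)
    label = np.sign(runmean - f1) * s          # +1 Bias+, -1 Bias-
    valid = np.zeros(shape, dtype=bool)
    valid[:, 1:] = True

    def rate(cell):
        n = cell.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(n > 0, (resp & cell).sum(axis=1) / np.maximum(n, 1),
                         np.nan)
            r = np.clip(r, 1 / (2 * np.maximum(n, 1)),
                        1 - 1 / (2 * np.maximum(n, 1)))
        return norm.ppf(r)

    out = np.zeros(n_blocks)
    for lab_sign, coef in ((1, 1.0), (-1, -1.0)):
        m = valid & (label == lab_sign)
        d = rate(m & (s > 0)) - rate(m & (s < 0))
        out = out + coef * d
    return out


def calibrate_observer(
    alpha: float,
    beta: float,
    tau: float,
    itis: tuple[float, ...] = (1.4, 2.9, 5.9, 8.9),
    sigma: float = 0.055,
    gamma: float = 0.0,
    n_trials: int = 100,
    scale: float = 1.0,
    n_sims: int = 400,
    w_max: float = 0.95,
    calibration_seed: int = 20240,
) -> tuple[ObserverParams, float]:
    """Observer parameters that plant a target decay of the measured bias.

    Finds (w0, w_floor, tau_mem) such that the *expected measured*
    Bias+/Bias- d-prime difference (with finite blocks of ``n_trials`` and
    clipped rates, i.e. including the estimator's small-sample attenuation)
    matches ``scale * (alpha + beta*exp(-t/tau))`` at the given block
    intervals.  Returns the parameters and the largest absolute curve
    mismatch (d-prime units) at those intervals.

    The map from weight to measured bias saturates near ~3 d-prime units
    because trials with large frequency differences are immune to
    contraction; curves exceeding that range must be planted scaled down
    (``scale`` < 1), which leaves the time constant untouched.
    """
    itis = np.asarray(itis, dtype=float)
    target = scale * (alpha + beta * np.exp(-itis / tau))

    ws = np.linspace(0.0, w_max, 24)
    cn = np.empty_like(ws)
    for i, w in enumerate(ws):
        rng = np.random.default_rng(calibration_seed)
        cn[i] = np.nanmean(
            _measured_ddprime_blocks(rng, w, sigma, gamma, n_trials, n_sims))

    def curve(p):
        w0, wf, tm = p
        w_t = wf + (w0 - wf) * np.exp(-itis / tm)
        return np.interp(w_t, ws, cn)

    x0 = [min(float(np.interp(target[0], cn, ws)) * 1.2, w_max),
          float(np.interp(target[-1], cn, ws)), tau]
    sol = least_squares(lambda p: curve(p) - target, x0,
                        bounds=([0, 0, 0.1], [w_max, w_max, 100.0]))
    w0, wf, tm = sol.x
    params = ObserverParams(sigma=sigma, w0=float(w0), tau_mem=float(tm),
                            gamma=gamma, w_floor=float(wf))
    return params, float(np.abs(sol.fun).max())


# ---------------------------------------------------------------------------
# synthetic EEG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErpComponentGen:
    """Planted recovery-from-adaptation curve for one component, in uV*ms:
    expected windowed area after an inter-event interval dt is
    ``alpha + beta * exp(-dt / tau)`` (first event of a block: dt = inf,
    i.e. area = alpha)."""

    alpha: float
    beta: float
    tau: float

    def area_at(self, dt: float | None) -> float:
        if dt is None or np.isinf(dt):
            return self.alpha
        return self.alpha + self.beta * np.exp(-dt / self.tau)


@dataclass(frozen=True)
class ErpGenParams:
    """Generator settings for synthetic single-channel EEG."""

    n1: ErpComponentGen
    p2: ErpComponentGen
    noise_sd: float = 3.0        # uV, white noise on the raw (cleaned) trace
    artifact_rate: float = 0.5   # events / minute, Poisson
    sampling_rate: float = 256.0

    def __post_init__(self):
        if not (self.p2.alpha >= 0 and self.p2.beta <= 0):
            raise ValueError("P2 requires alpha >= 0 and beta <= 0")
        if not (self.n1.alpha <= 0 and self.n1.beta >= 0):
            raise ValueError("N1 requires alpha <= 0 and beta >= 0")
        if self.n1.tau <= 0 or self.p2.tau <= 0:
            raise ValueError("tau must be positive")
        if self.noise_sd < 0 or self.artifact_rate < 0:
            raise ValueError("noise_sd and artifact_rate must be >= 0")


# Fixed unimodal kernels: raised cosines centered on the canonical N1/P2
# latencies, chosen narrow enough to sit inside the analysis windows.
_KERNELS = {
    "n1": {"center": 0.100, "half_width": 0.030, "sign": -1.0},
    "p2": {"center": 0.200, "half_width": 0.050, "sign": +1.0},
}


def _unit_kernel(name: str, fs: float, n: int, onset: float) -> np.ndarray:
    kern = _KERNELS[name]
    t = np.arange(n) / fs - onset - kern["center"]
    h = kern["half_width"]
    out = np.zeros(n)
    m = np.abs(t) <= h
    out[m] = kern["sign"] * 0.5 * (1 + np.cos(np.pi * t[m] / h))
    return out


@lru_cache(maxsize=8)
def _kernel_transmission(fs: float) -> np.ndarray:
    """2x2 matrix M[window, kernel]: windowed area (uV*ms) measured by the
    full ERP pipeline (band-pass, epoch, baseline) for each unit-amplitude
    kernel in isolation.  Used to pre-compensate kernel amplitudes so that
    planted areas survive filtering exactly (linearity)."""
    onset = 4.0
    n = int(round(8.0 * fs))
    M = np.zeros((2, 2))
    for j, name in enumerate(("n1", "p2")):
        rec = erp_mod.Recording(_unit_kernel(name, fs, n, onset), fs,
                                events=[(onset, "tone1")])
        filt = erp_mod.bandpass_filter(rec)
        epochs = erp_mod.epoch_and_baseline(filt)
        for i, comp in enumerate(("n1", "p2")):
            M[i, j] = erp_mod.average_and_area(epochs, comp).area_uv_ms
    return M


def make_event_schedule(
    n_events: int,
    soa: float,
    paired: bool = False,
    inter_tone: float = INTER_TONE_INTERVAL,
    lead_in: float = 1.0,
) -> list[tuple[float, str]]:
    """Event onsets for one block: ``n_events`` trials at a fixed stimulus
    onset asynchrony.  ``paired`` adds a second tone ``inter_tone`` seconds
    after each first tone (active two-tone condition)."""
    schedule = []
    for i in range(n_events):
        t0 = lead_in + i * soa
        schedule.append((t0, "tone1"))
        if paired:
            schedule.append((t0 + inter_tone, "tone2"))
    return schedule


def generate_eeg(
    schedule: list[tuple[float, str]],
    p: ErpGenParams,
    seed: int | np.random.Generator | None = None,
    lead_out: float = 2.0,
) -> erp_mod.Recording:
    """Synthesize a recording whose measured N1/P2 areas follow the planted
    recovery curves.

    For each event the target areas are evaluated at dt = time since the
    previous event (dt = inf for the first event of the block).  Kernel
    amplitudes are solved through the filter/baseline transmission matrix so
    that, with ``noise_sd = 0`` and ``artifact_rate = 0``, the areas
    measured by the ERP pipeline reproduce the planted curve.
    Artifacts are injected as >100 uV excursions at Poisson times.
    """
    onsets = [t for t, _k in schedule]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("schedule must be strictly increasing")
    if any(b - a < 0.5 for a, b in zip(onsets, onsets[1:])):
        warnings.warn("events closer than 500 ms: component kernels overlap",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    fs = p.sampling_rate
    n = int(round((onsets[-1] + lead_out) * fs))
    x = np.zeros(n)

    Minv = np.linalg.inv(_kernel_transmission(fs))
    prev = None
    for onset, kind in schedule:
        dt = None if prev is None else onset - prev
        target = np.array([p.n1.area_at(dt), p.p2.area_at(dt)])
        if kind == "tone2":
            # the recovery curve is defined for the measured first-tone
            # response; at the 0.6 s within-trial interval it extrapolates
            # past zero, and adaptation cannot invert a component's
            # polarity, so second-tone responses are clipped at zero
            target[0] = min(target[0], 0.0)   # N1 stays non-positive
            target[1] = max(target[1], 0.0)   # P2 stays non-negative
        amps = Minv @ target
        for amp, name in zip(amps, ("n1", "p2")):
            kern = _KERNELS[name]
            i0 = int(np.floor((onset + kern["center"] - kern["half_width"]) * fs))
            i1 = int(np.ceil((onset + kern["center"] + kern["half_width"]) * fs)) + 1
            i0c, i1c = max(i0, 0), min(i1, n)
            t = np.arange(i0c, i1c) / fs - onset - kern["center"]
            m = np.abs(t) <= kern["half_width"]
            x[i0c:i1c][m] += (amp * kern["sign"] * 0.5
                              * (1 + np.cos(np.pi * t[m] / kern["half_width"])))
        prev = onset

    if p.noise_sd > 0:
        x += rng.normal(0.0, p.noise_sd, n)
    if p.artifact_rate > 0:
        duration_min = n / fs / 60.0
        n_art = rng.poisson(p.artifact_rate * duration_min)
        width = int(round(0.080 * fs))
        for _ in range(n_art):
            i0 = rng.integers(0, max(n - width, 1))
            x[i0:i0 + width] += rng.choice([-1.0, 1.0]) * 400.0
    return erp_mod.Recording(x, fs, events=list(schedule))


# ---------------------------------------------------------------------------
# reading sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadingGenParams:
    """Generator settings for a self-paced non-word reading session.

    The repetition benefit (percent RT reduction at the second presentation
    of an item) decays with the interval since its first presentation:
    ``benefit(dt) = benefit_floor + (benefit0 - benefit_floor)*exp(-dt/tau_read)``
    with dt measured from first voice offset to second visual onset.
    """

    n_blocks: int = 6
    words_per_block: int = 120
    rt_base_mean: float = 660.0     # ms, first-presentation RT
    rt_base_sd: float = 100.0
    articulation_mean: float = 240.0  # ms voice duration
    articulation_sd: float = 40.0
    rt2_sd: float = 60.0            # ms extra noise on repeated items
    benefit0: float = 26.0          # % at zero lag
    tau_read: float = 7.0           # s
    benefit_floor: float = 12.0     # % as dt -> inf
    inter_word_gap: float = 500.0   # ms, voice offset to next visual onset
    error_rate: float = 0.014

    def __post_init__(self):
        if not 0 <= self.benefit_floor <= self.benefit0 <= 100:
            raise ValueError("need 0 <= benefit_floor <= benefit0 <= 100")
        if self.tau_read <= 0:
            raise ValueError("tau_read must be positive")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")

    def benefit_at(self, dt_s: float) -> float:
        return (self.benefit_floor
                + (self.benefit0 - self.benefit_floor) * np.exp(-dt_s / self.tau_read))


@dataclass(frozen=True)
class LagPlanConfig:
    """How repeated non-words are spaced within each block.

    ``n_pairs`` tokens per block appear twice; ``n_short`` of them at the
    minimum legal lag (one intervening item) and the rest at long lags with
    log-normally distributed intervening counts (clipped to
    [min_long, max_long]), giving a long-interval bin with a mean interval
    of roughly 40 s at typical reading rates.
    """

    n_pairs: int = 40
    n_short: int = 12
    long_log_mean: float = 2.96
    long_log_sd: float = 0.9
    min_long: int = 2
    max_long: int = 100


def generate_nonwords(
    k: int,
    consonants: tuple[str, ...] = tuple("bdgklmnprstvz"),
    vowels: tuple[str, ...] = tuple("aeiou"),
    seed: int | np.random.Generator | None = None,
) -> list[str]:
    """Unique disyllabic non-words: CV+CVC or CVC+CV syllable conjunctions."""
    if not consonants or not vowels:
        raise ConfigurationError("consonant and vowel inventories must be non-empty")
    c, v = len(consonants), len(vowels)
    capacity = 2 * (c * v) * (c * v * c)
    if k > capacity:
        raise ConfigurationError(
            f"requested {k} tokens but the inventory supports only {capacity}")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < k:
        cv = rng.choice(consonants) + rng.choice(vowels)
        cvc = rng.choice(consonants) + rng.choice(vowels) + rng.choice(consonants)
        token = cv + cvc if rng.random() < 0.5 else cvc + cv
        if token not in seen:
            seen.add(token)
            out.append(token)
    return out


def make_lag_plan(
    n_blocks: int = 6,
    words_per_block: int = 120,
    config: LagPlanConfig = LagPlanConfig(),
    seed: int | np.random.Generator | None = None,
) -> list[list[str]]:
    """Token order for each block, with planned repetitions.

    Tokens are unique across the whole session except that ``n_pairs``
    tokens per block occur exactly twice within their block, never
    consecutively (>= 1 intervening item).
    """
    rng = np.random.default_rng(seed)
    cfg = config
    if 2 * cfg.n_pairs > words_per_block:
        raise ConfigurationError("pairs do not fit in the block")
    n_single = words_per_block - 2 * cfg.n_pairs
    n_tokens = n_blocks * (cfg.n_pairs + n_single)
    tokens = generate_nonwords(n_tokens, seed=rng)
    it = iter(tokens)

    plan: list[list[str]] = []
    for _b in range(n_blocks):
        lags = [1] * cfg.n_short
        n_long = cfg.n_pairs - cfg.n_short
        draw = np.exp(rng.normal(cfg.long_log_mean, cfg.long_log_sd, n_long))
        lags += list(np.clip(np.round(draw).astype(int),
                             cfg.min_long, cfg.max_long))
        if any(l < 1 for l in lags):
            raise ConfigurationError("a repetition lag below 1 (consecutive) "
                                     "is not allowed")
        slots: list[str | None] = [None] * words_per_block
        # place longest lags first; find a feasible random position for each
        for lag in sorted(lags, reverse=True):
            tok = next(it)
            placed = False
            for lag_eff in range(lag, 0, -1):
                feasible = [pos for pos in range(words_per_block - lag_eff - 1)
                            if slots[pos] is None and slots[pos + lag_eff + 1] is None]
                if feasible:
                    pos = int(rng.choice(feasible))
                    slots[pos] = tok
                    slots[pos + lag_eff + 1] = tok
                    placed = True
                    break
            if not placed:
                raise GenerationError("could not place a repetition pair")
        for i in range(words_per_block):
            if slots[i] is None:
                slots[i] = next(it)
        plan.append(slots)  # type: ignore[arg-type]
    return plan


def generate_reading_session(
    p: ReadingGenParams,
    lag_plan: list[list[str]] | None = None,
    seed: int | np.random.Generator | None = None,
    block_pause: float = 20_000.0,
):
    """Simulate one self-paced oral-reading session.

    Each non-word appears 500 ms (``inter_word_gap``) after the voice offset
    of the preceding one.  Second presentations are faster by the planted
    benefit evaluated at the actual first-voice-offset to second-visual-
    onset interval.  Returns a :class:`memtrace.reading.ReadingSession`.
    """
    from .reading import ReadingSession

    rng = np.random.default_rng(seed)
    if lag_plan is None:
        lag_plan = make_lag_plan(p.n_blocks, p.words_per_block, seed=rng)
    _validate_lag_plan(lag_plan)

    rows = []
    clock = 0.0  # ms
    for b, block in enumerate(lag_plan):
        first_seen: dict[str, tuple[float, float]] = {}  # token -> (rt, voice_off)
        for i, tok in enumerate(block):
            visual_onset = clock if i > 0 or b > 0 else 0.0
            if tok in first_seen:
                rt1, off1 = first_seen[tok]
                dt_s = (visual_onset - off1) / 1000.0
                benefit = p.benefit_at(max(dt_s, 0.0))
                rt = rt1 * (1 - benefit / 100.0) + rng.normal(0, p.rt2_sd)
                rt = max(rt, 100.0)
            else:
                rt = max(rng.normal(p.rt_base_mean, p.rt_base_sd), 200.0)
            dur = max(rng.normal(p.articulation_mean, p.articulation_sd), 80.0)
            voice_onset = visual_onset + rt
            voice_offset = voice_onset + dur
            correct = bool(rng.random() >= p.error_rate)
            rows.append(dict(token=tok, block=b, visual_onset_ms=visual_onset,
                             voice_onset_ms=voice_onset,
                             voice_offset_ms=voice_offset, correct=correct))
            if tok not in first_seen:
                first_seen[tok] = (rt, voice_offset)
            clock = voice_offset + p.inter_word_gap
        clock += block_pause
    return ReadingSession(pd.DataFrame(rows))


def _validate_lag_plan(plan: list[list[str]]) -> None:
    for block in plan:
        for a, b in zip(block, block[1:]):
            if a == b:
                raise ConfigurationError(
                    "lag plan contains a consecutive repetition")
        counts = pd.Series(block).value_counts()
        if (counts > 2).any():
            raise ConfigurationError("a token occurs more than twice in a block")


def calibrate_reading_benefit(
    bin_short_pct: float,
    bin_long_pct: float,
    base: ReadingGenParams,
    tau_read: float,
    lag_config: LagPlanConfig = LagPlanConfig(),
    bin_edge_s: float = 2.0,
    n_sessions: int = 6,
    calibration_seed: int = 20241,
) -> ReadingGenParams:
    """Solve (benefit0, benefit_floor) so that the expected per-bin mean
    benefits match the targets under the configured lag plan and timing.

    The bin mean is linear in (benefit0, floor):
    ``m_bin = floor * (1 - E[e^(-dt/tau)|bin]) + benefit0 * E[e^(-dt/tau)|bin]``,
    so two bins give an exact 2x2 solve.  E[.] is estimated from a short
    forward simulation with a fixed internal seed (provisional parameters
    only perturb pair intervals at second order).
    """
    from .reading import pair_repetitions

    provisional = replace(base, benefit0=min(bin_short_pct + 5, 100.0),
                          benefit_floor=min(bin_long_pct, bin_short_pct),
                          tau_read=tau_read, error_rate=0.0)
    rng = np.random.default_rng(calibration_seed)
    dts = []
    for _ in range(n_sessions):
        session = generate_reading_session(provisional, seed=rng)
        pairs = pair_repetitions(session)
        dts.extend(p.delta_t for p in pairs)
    dts = np.asarray(dts)
    e = np.exp(-dts / tau_read)
    targets = np.array([bin_short_pct, bin_long_pct])
    ebar = np.array([e[dts < bin_edge_s].mean(), e[dts >= bin_edge_s].mean()])
    A = np.column_stack([ebar, 1 - ebar])      # [b0, floor]
    b0, floor = np.linalg.solve(A, targets)
    b0 = float(np.clip(b0, 0, 100))
    floor = float(np.clip(floor, 0, b0))
    return replace(base, benefit0=b0, benefit_floor=floor, tau_read=tau_read)


# ---------------------------------------------------------------------------
# trial-table interchange
# ---------------------------------------------------------------------------

def write_trial_table(seq: TrialSequence, path, choices=None,
                      block_id: str | None = None) -> None:
    """Trial table CSV: index,f1_hz,f2_hz,onset1_s,onset2_s,iti_s[,response][,block_id]."""
    df = pd.DataFrame({
        "index": [t.index for t in seq.trials],
        "f1_hz": seq.f1, "f2_hz": seq.f2,
        "onset1_s": [t.onset1 for t in seq.trials],
        "onset2_s": [t.onset2 for t in seq.trials],
        "iti_s": seq.itis,
    })
    if choices is not None:
        df["response"] = np.asarray(choices).astype(int)
    if block_id is not None:
        df["block_id"] = block_id
    df.to_csv(path, index=False)


def read_trial_table(path) -> tuple[TrialSequence, np.ndarray | None]:
    df = pd.read_csv(path)
    trials = [
        ToneTrial(index=int(r["index"]), f1=r["f1_hz"], f2=r["f2_hz"],
                  onset1=r["onset1_s"], onset2=r["onset2_s"],
                  iti=None if pd.isna(r["iti_s"]) else r["iti_s"])
        for r in df.to_dict("records")
    ]
    choices = df["response"].to_numpy(dtype=bool) if "response" in df else None
    return TrialSequence(trials), choices
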