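"""Behavioral analysis of two-tone discrimination with context effects.

Two complementary quantifications of the contraction bias are provided:

* the **Bias+/Bias- d-prime difference** (context effect): trials are
  labeled by whether contraction of the first tone toward the prior widens
  (Bias+) or shrinks (Bias-) the perceived within-trial difference, and the
  context effect is d'(Bias+) - d'(Bias-) per inter-trial-interval block;

* a **three-predictor choice GLM** per participant: trial difficulty
  (percent frequency difference), congruence of the global context with the
  correct response, and congruence of the recent context, regressed on
  trial correctness (binomial family, logit link).

Sensitivity is ``d' = Phi^-1(HR) - Phi^-1(FA)`` with HR/FA the rates of
"first tone higher" responses given f1 > f2 / f1 < f2; empirical rates of 0
or 1 are corrected to 1/(2N) and 1 - 1/(2N).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .synthetic_data import TrialSequence

__all__ = [
    "BiasLabel", "ContextEffect", "GlmFit", "UndefinedMeasureError",
    "compute_dprime", "prior_estimates", "label_bias", "context_effect",
    "build_design_matrix", "fit_choice_glm",
]

PRIOR_MODES = ("running", "full", "exclude_recent")


class UndefinedMeasureError(ValueError):
    """A rate or measure is undefined (e.g. zero trials in a condition)."""


class BiasLabel(enum.Enum):
    BIAS_PLUS = 1
    BIAS_MINUS = -1
    NEUTRAL = 0


@dataclass(frozen=True)
class ContextEffect:
    """Bias+/Bias- d-prime difference for one ITI block."""

    iti: float
    dprime_plus: float
    dprime_minus: float
    n_plus: int
    n_minus: int
    valid: bool = True

    @property
    def delta_dprime(self) -> float:
        return self.dprime_plus - self.dprime_minus


@dataclass(frozen=True)
class GlmFit:
    """Coefficients of the three-predictor choice GLM."""

    beta_df: float
    beta_global: float
    beta_recent: float
    se_df: float
    se_global: float
    se_recent: float
    intercept: float
    n_trials: int
    ridge_fallback: bool = False


def compute_dprime(responded_first_higher, first_is_higher) -> float:
    """Signal-detection sensitivity from "first higher" responses.

    HR is the "first higher" response rate on trials where the first tone
    really is higher; FA the same rate where it is lower.  Both conditions
    must be non-empty.  Extreme rates are corrected to 1/(2N), 1 - 1/(2N).
    """
    resp = np.asarray(responded_first_higher, dtype=bool)
    truth = np.asarray(first_is_higher, dtype=bool)
    if resp.shape != truth.shape:
        raise ValueError("response and condition arrays must align")
    zs = []
    for cond in (truth, ~truth):
        n = int(cond.sum())
        if n == 0:
            raise UndefinedMeasureError("a response condition has zero trials")
        rate = resp[cond].mean()
        rate = min(max(rate, 1 / (2 * n)), 1 - 1 / (2 * n))
        zs.append(norm.ppf(rate))
    return float(zs[0] - zs[1])


def prior_estimates(seq: TrialSequence, mode: str = "running") -> pd.DataFrame:
    """Per-trial global and recent prior frequencies (Hz).

    ``recent_prior(t) = f1(t-1)``.  The global prior depends on ``mode``:
    ``running`` = mean of all previous f1; ``exclude_recent`` = mean of all
    previous except the immediately preceding one; ``full`` = mean of every
    other trial in the sequence (leave-one-out).  Undefined entries are NaN
    and must be excluded downstream.
    """
    if mode not in PRIOR_MODES:
        raise ValueError(f"mode must be one of {PRIOR_MODES}")
    f1 = seq.f1
    n = len(f1)
    if n < 3:
        raise ValueError("need at least 3 trials for prior estimates")
    recent = np.full(n, np.nan)
    recent[1:] = f1[:-1]
    glob = np.full(n, np.nan)
    if mode == "running":
        glob[1:] = np.cumsum(f1)[:-1] / np.arange(1, n)
    elif mode == "exclude_recent":
        glob[2:] = np.cumsum(f1)[:-2] / np.arange(1, n - 1)
    else:  # full: leave-one-out mean of the whole sequence
        total = f1.sum()
        glob = (total - f1) / (n - 1)
    return pd.DataFrame({"global_prior": glob, "recent_prior": recent})


def label_bias(f1: float, f2: float, prior: float) -> BiasLabel:
    """Bias+ when contraction toward the prior widens the perceived
    difference (sign(prior - f1) == sign(f1 - f2)); Bias- when it shrinks
    it; Neutral only when prior == f1 exactly."""
    if f1 == f2:
        raise ValueError("invalid trial: f1 == f2")
    s = np.sign(prior - f1) * np.sign(f1 - f2)
    if s > 0:
        return BiasLabel.BIAS_PLUS
    if s < 0:
        return BiasLabel.BIAS_MINUS
    return BiasLabel.NEUTRAL


def _label_signs(f1, f2, prior):
    """Vectorized bias labels as +1 / -1 / 0 (NaN prior -> NaN)."""
    return np.sign(prior - f1) * np.sign(f1 - f2)


def context_effect(
    seq: TrialSequence,
    choices,
    prior_mode: str = "running",
    min_per_label: int = 10,
) -> ContextEffect:
    """Bias+/Bias- d-prime difference for one constant-ITI block.

    Trials with undefined priors and Neutral trials are excluded.  If either
    label has fewer than ``min_per_label`` usable trials, or a d' condition
    is empty, the block is returned flagged (``valid=False``) and must be
    excluded from decay fitting.
    """
    choices = np.asarray(choices, dtype=bool)
    f1, f2 = seq.f1, seq.f2
    prior = prior_estimates(seq, prior_mode)["global_prior"].to_numpy()
    labels = _label_signs(f1, f2, prior)
    truth = f1 > f2
    itis = seq.itis
    iti = float(np.nanmedian(itis))

    usable = ~np.isnan(labels) & (labels != 0)
    dps = {}
    counts = {}
    ok = True
    for sign in (1, -1):
        m = usable & (labels == sign)
        counts[sign] = int(m.sum())
        if counts[sign] < min_per_label:
            ok = False
            dps[sign] = np.nan
            continue
        try:
            dps[sign] = compute_dprime(choices[m], truth[m])
        except UndefinedMeasureError:
            ok = False
            dps[sign] = np.nan
    return ContextEffect(iti=iti, dprime_plus=dps[1], dprime_minus=dps[-1],
                         n_plus=counts[1], n_minus=counts[-1], valid=ok)


def build_design_matrix(
    seq: TrialSequence,
    choices,
    prior_mode: str = "exclude_recent",
) -> pd.DataFrame:
    """Per-trial predictors for the choice GLM.

    * ``x_df``: |f1 - f2| as a percentage of the lower tone;
    * ``c_global``: +1 when contraction toward the global mean favors the
      correct response (``-G(t) * sign(f1 - f2)``), -1 otherwise;
    * ``c_recent``: same for contraction toward the previous first tone;
    * ``correct``: 1 when the choice matched the true sign.

    Trials with undefined priors are dropped.
    """
    choices = np.asarray(choices, dtype=bool)
    f1, f2 = seq.f1, seq.f2
    pri = prior_estimates(seq, prior_mode)
    g_sign = np.sign(f1 - pri["global_prior"].to_numpy())
    r_sign = np.sign(f1 - pri["recent_prior"].to_numpy())
    s_df = np.sign(f1 - f2)
    df = pd.DataFrame({
        "x_df": np.abs(f1 - f2) / np.minimum(f1, f2) * 100.0,
        "c_global": -g_sign * s_df,
        "c_recent": -r_sign * s_df,
        "correct": (choices == (f1 > f2)).astype(int),
    })
    return df.dropna().reset_index(drop=True)


def fit_choice_glm(design: pd.DataFrame, ridge_alpha: float = 1e-3) -> GlmFit:
    """Binomial(logit) GLM of trial correctness on the three predictors.

    Falls back to a small-ridge penalized fit (flagged) when the likelihood
    is separated or fails to converge; standard errors then come from the
    penalized Fisher information.
    """
    if len(design) < 30:
        raise ValueError("need at least 30 usable trials for the GLM")
    X = sm.add_constant(design[["x_df", "c_global", "c_recent"]].to_numpy())
    y = design["correct"].to_numpy()

    def finite(res_params, res_bse):
        return (np.all(np.isfinite(res_params)) and np.all(np.isfinite(res_bse))
                and np.max(np.abs(res_params)) < 15)

    model = sm.GLM(y, X, family=sm.families.Binomial())
    ridge = False
    try:
        res = model.fit()
        params, bse = res.params, res.bse
        if not finite(params, bse):
            raise ValueError("separation suspected")
    except Exception:
        ridge = True
        res = model.fit_regularized(alpha=ridge_alpha, L1_wt=0.0)
        params = np.asarray(res.params)
        mu = model.predict(params, X)
        W = mu * (1 - mu)
        info = X.T @ (W[:, None] * X) + 2 * ridge_alpha * len(y) * np.eye(X.shape[1])
        bse = np.sqrt(np.diag(np.linalg.inv(info)))

    return GlmFit(beta_df=float(params[1]), beta_global=float(params[2]),
                  beta_recent=float(params[3]), se_df=float(bse[1]),
                  se_global=float(bse[2]), se_recent=float(bse[3]),
                  intercept=float(params[0]), n_trials=len(design),
                  ridge_fallback=ridge)
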