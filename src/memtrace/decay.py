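"""Bounded three-parameter exponential decay/recovery fitting.

The model is ``y(t) = alpha + beta * exp(-t / tau)`` where ``alpha`` is the
asymptote after full recovery (value as t -> inf), ``beta`` is the magnitude
of adaptation (value at t = 0 minus ``alpha``) and ``tau`` is the time
constant: the time for the t = 0 excess to fall to 1/e of its initial value.
A small ``tau`` means fast decay.

Fits are bounded least squares.  The bounds depend on the measure being
fitted (``kind``):

=========  ===================  ===================
kind       alpha bounds         beta bounds
=========  ===================  ===================
dprime     [0, 100]             [0, 100]
erp_p2     [0, 15000]           [-15000, 0]
erp_n1     [-15000, 0]          [0, 15000]
=========  ===================  ===================

``tau`` is bounded to [0, 100] s for every kind.  The P2 component is
positive and adapted responses are smaller, hence beta <= 0; N1 is negative
with the mirrored convention.

Because the tau likelihood is often nearly flat when only a handful of
intervals were sampled, the fit is a multi-start search: for each tau on a
log-spaced grid the conditionally-linear (alpha, beta) subproblem is solved
exactly under its box bounds, and the best start is polished with a bounded
trust-region least-squares step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, lsq_linear

__all__ = ["DecayModel", "DecayFit", "eval_decay", "fit_decay", "KIND_BOUNDS"]

TAU_BOUNDS = (0.0, 100.0)

#: (alpha_lo, alpha_hi), (beta_lo, beta_hi) per measure kind.
KIND_BOUNDS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "dprime": ((0.0, 100.0), (0.0, 100.0)),
    "erp_p2": ((0.0, 15000.0), (-15000.0, 0.0)),
    "erp_n1": ((-15000.0, 0.0), (0.0, 15000.0)),
}


@dataclass(frozen=True)
class DecayModel:
    """Parameters of the exponential decay/recovery curve."""

    alpha: float
    beta: float
    tau: float

    def __call__(self, t):
        return eval_decay(self, t)


@dataclass(frozen=True)
class DecayFit:
    """A fitted :class:`DecayModel` plus goodness of fit and flags.

    ``tau_identifiable`` is False when the data carry essentially no
    information about the time constant: all y equal, |beta| smaller than
    twice the residual standard deviation, or tau pinned at a search bound.
    """

    model: DecayModel
    r_squared: float
    sse: float
    n_points: int
    converged: bool
    tau_identifiable: bool

    @property
    def alpha(self) -> float:
        return self.model.alpha

    @property
    def beta(self) -> float:
        return self.model.beta

    @property
    def tau(self) -> float:
        return self.model.tau


def eval_decay(m: DecayModel, t):
    """Evaluate ``alpha + beta * exp(-t/tau)`` at times ``t`` (seconds).

    ``tau == 0`` is taken as the instant-decay limit: ``alpha + beta`` at
    t = 0 and ``alpha`` for t > 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("decay model is defined for t >= 0")
    if m.tau == 0.0:
        out = np.where(t == 0.0, m.alpha + m.beta, m.alpha)
    else:
        out = m.alpha + m.beta * np.exp(-t / m.tau)
    return out if out.ndim else float(out)


def _solve_linear(t, y, tau, ab_bounds):
    """Exact bounded least squares for (alpha, beta) at fixed tau."""
    e = np.exp(-t / tau)
    A = np.column_stack([np.ones_like(t), e])
    lo = [ab_bounds[0][0], ab_bounds[1][0]]
    hi = [ab_bounds[0][1], ab_bounds[1][1]]
    res = lsq_linear(A, y, bounds=(lo, hi))
    alpha, beta = res.x
    sse = float(np.sum((A @ res.x - y) ** 2))
    return alpha, beta, sse


def fit_decay(
    t_points,
    y_points,
    kind: str = "dprime",
    n_starts: int = 40,
) -> DecayFit:
    """Fit the bounded exponential decay model to (t, y) samples.

    Parameters
    ----------
    t_points, y_points
        Sample times (s) and measure values.  At least three pairs with
        distinct times are required.
    kind
        Selects the (alpha, beta) box bounds, see :data:`KIND_BOUNDS`.
    n_starts
        Number of log-spaced tau starting values (0.1-100 s); each start
        solves the conditionally-linear subproblem exactly and the best is
        polished with a bounded least-squares step.
    """
    t = np.asarray(t_points, dtype=float)
    y = np.asarray(y_points, dtype=float)
    if kind not in KIND_BOUNDS:
        raise ValueError(f"unknown kind {kind!r}; choose from {sorted(KIND_BOUNDS)}")
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t_points and y_points must be 1-D and equally long")
    if len(t) < 3:
        raise ValueError("need at least 3 (t, y) pairs to fit three parameters")
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct time points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("t and y must be finite")

    ab_bounds = KIND_BOUNDS[kind]
    sst = float(np.sum((y - y.mean()) ** 2))

    if sst == 0.0:
        # Degenerate: constant data.  beta goes to its nearest-to-zero bound
        # (zero for every kind) and tau is meaningless.
        alpha = float(np.clip(y[0], *ab_bounds[0]))
        model = DecayModel(alpha=alpha, beta=0.0, tau=TAU_BOUNDS[1])
        sse = float(np.sum((alpha - y) ** 2))
        return DecayFit(model, r_squared=1.0 if sse == 0 else 0.0, sse=sse,
                        n_points=len(t), converged=True, tau_identifiable=False)

    best = None
    for tau0 in np.geomspace(0.1, 100.0, n_starts):
        alpha, beta, sse = _solve_linear(t, y, tau0, ab_bounds)
        if best is None or sse < best[0]:
            best = (sse, alpha, beta, tau0)

    _, a0, b0, tau0 = best
    lo = [ab_bounds[0][0], ab_bounds[1][0], max(TAU_BOUNDS[0], 1e-6)]
    hi = [ab_bounds[0][1], ab_bounds[1][1], TAU_BOUNDS[1]]
    x0 = np.clip([a0, b0, tau0], lo, hi)

    def resid(p):
        return p[0] + p[1] * np.exp(-t / p[2]) - y

    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12,
                        gtol=1e-12)
    alpha, beta, tau = sol.x
    sse = float(2.0 * sol.cost)
    # keep the grid solution if the polish wandered (should not happen)
    if sse > best[0] + 1e-12:
        sse, alpha, beta, tau = best

    dof = max(len(t) - 3, 1)
    resid_sd = np.sqrt(sse / dof)
    at_bound = tau >= TAU_BOUNDS[1] * (1 - 1e-9) or tau <= 1e-5
    identifiable = (abs(beta) >= 2.0 * resid_sd) and not at_bound

    r2 = 1.0 - sse / sst
    model = DecayModel(alpha=float(alpha), beta=float(beta), tau=float(tau))
    return DecayFit(model, r_squared=float(r2), sse=sse, n_points=len(t),
                    converged=bool(sol.success), tau_identifiable=identifiable)
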