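"""Logistic growth and Luedeking-Piret lipid-production kinetics.

The batch fermentation is modelled by the logistic growth equation

    dX/dt = mu_max * (1 - X/X_m) * X

with closed-form solution X(t) = X_m / (1 + C * exp(-mu_max * t)),
C = (X_m - X_0)/X_0, and by the Luedeking-Piret product equation

    dP/dt = alpha * dX/dt + beta * X

whose integral against the logistic biomass is also closed-form:

    P(t) = P_0 + alpha*(X(t) - X_0)
               + (beta*X_m/mu_max) * ln((C + exp(mu_max*t)) / (C + 1)).

X is dry cell weight (g/L), P lipid (g/L), t time in days. alpha is the
growth-associated coefficient (g lipid per g biomass), beta the
non-growth-associated coefficient (g lipid per g biomass per day).

Fitting goes the route practitioners use for this pair of models:
nonlinear least squares on the biomass closed form, then *linear* least
squares for (alpha, beta) on the integrated product form — which avoids
differentiating noisy measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LogisticParams",
    "LuedekingPiretParams",
    "TimeCourse",
    "FitResult",
    "RateTable",
    "biomass",
    "growth_rate",
    "biomass_from_rate",
    "anchor_trajectory",
    "lipid",
    "lipid_rate",
    "cumulative_biomass",
    "fit_logistic",
    "fit_luedeking_piret",
    "rate_table",
]


@dataclass(frozen=True)
class LogisticParams:
    """Logistic growth parameters.

    mu_max : maximum specific growth rate (1/day), > 0
    x_m    : carrying capacity / maximum biomass (g/L DCW), > 0
    x_0    : initial biomass (g/L), 0 < x_0 <= x_m
    """

    mu_max: float
    x_m: float
    x_0: float

    def __post_init__(self) -> None:
        if not self.mu_max > 0:
            raise ValueError(f"mu_max must be > 0, got {self.mu_max}")
        if not self.x_m > 0:
            raise ValueError(f"x_m must be > 0, got {self.x_m}")
        if not 0 < self.x_0 <= self.x_m:
            raise ValueError(
                f"x_0 must satisfy 0 < x_0 <= x_m, got x_0={self.x_0}, x_m={self.x_m}"
            )

    @property
    def c(self) -> float:
        """Integration constant C = (x_m - x_0)/x_0 of the closed form."""
        return (self.x_m - self.x_0) / self.x_0

    @property
    def max_rate(self) -> float:
        """Continuous maximum of dX/dt, attained at X = x_m/2."""
        return self.mu_max * self.x_m / 4.0


@dataclass(frozen=True)
class LuedekingPiretParams:
    """Luedeking-Piret product-formation parameters.

    alpha : growth-associated coefficient (g lipid / g biomass), >= 0
    beta  : non-growth-associated coefficient (g lipid / g biomass / day), >= 0
    p_0   : initial product concentration (g/L)
    """

    alpha: float
    beta: float
    p_0: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError(
                f"alpha and beta must be >= 0, got alpha={self.alpha}, beta={self.beta}"
            )


@dataclass
class TimeCourse:
    """A sampled fermentation trajectory.

    t in days (strictly increasing), x biomass g/L, p lipid g/L,
    s optional residual glucose g/L.
    """

    t: np.ndarray
    x: np.ndarray
    p: np.ndarray | None = None
    s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.ndim != 1 or self.t.size == 0:
            raise ValueError("t must be a non-empty 1-D sequence")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.x.shape != self.t.shape:
            raise ValueError("x must have the same length as t")
        for name in ("p", "s"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.t.shape:
                    raise ValueError(f"{name} must have the same length as t")
                setattr(self, name, v)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_d": self.t, "dcw_g_l": self.x}
        if self.p is not None:
            cols["lipid_g_l"] = self.p
        if self.s is not None:
            cols["glucose_g_l"] = self.s
        return pd.DataFrame(cols)


@dataclass
class FitResult:
    """Outcome of a model fit: parameter bundle plus goodness-of-fit."""

    params: LogisticParams | LuedekingPiretParams
    rss: float
    r_squared: float
    converged: bool
    n_obs: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        p = self.params
        if isinstance(p, LogisticParams):
            model, pd_ = "logistic", {"mu_max": p.mu_max, "x_m": p.x_m, "x_0": p.x_0}
        else:
            model, pd_ = "luedeking_piret", {"alpha": p.alpha, "beta": p.beta, "p_0": p.p_0}
        return {
            "model": model,
            "params": pd_,
            "rss": self.rss,
            "r_squared": self.r_squared,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "flags": list(self.flags),
        }


@dataclass
class RateTable:
    """Daily growth and lipid-accumulation rates on an integer-day grid.

    q_x_max / q_l_max are maxima over the tabulated days (the grid maximum,
    not the continuous maximum mu_max*x_m/4).
    """

    day: np.ndarray
    q_x: np.ndarray
    q_l: np.ndarray
    q_x_max: float
    q_l_max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day, "q_x_g_l_d": self.q_x, "q_l_g_l_d": self.q_l}
        )


# ---------------------------------------------------------------------------
# closed forms


def biomass(t, p: LogisticParams):
    """Biomass X(t) (g/L) from the closed-form logistic solution.

    Accepts scalar or array t (days); X(0) = x_0, X -> x_m as t -> inf.
    """
    t = np.asarray(t, dtype=float)
    c = p.c
    out = p.x_m / (1.0 + c * np.exp(-p.mu_max * t))
    return out if out.ndim else float(out)


def growth_rate(x, p: LogisticParams):
    """Instantaneous growth rate dX/dt = mu_max*X*(1 - X/x_m) at biomass x.

    x must lie in [0, x_m] (a 1e-9 relative overshoot is tolerated and
    clipped, so that x = biomass(t) round-trips at large t).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-9 * p.x_m) or np.any(x > p.x_m * (1 + 1e-9)):
        raise ValueError(f"biomass outside [0, x_m={p.x_m}]: {x}")
    x = np.clip(x, 0.0, p.x_m)
    out = p.mu_max * x * (1.0 - x / p.x_m)
    return out if out.ndim else float(out)


def biomass_from_rate(
    q: float,
    p: LogisticParams,
    branch: Literal["pre_inflection", "post_inflection"] = "pre_inflection",
) -> float:
    """Invert the logistic rate law: solve mu_max*X*(1 - X/x_m) = q for X.

    The rate law is a downward parabola in X with two roots; ``branch``
    selects the smaller (pre-inflection, X < x_m/2) or larger
    (post-inflection) root. q must lie in [0, mu_max*x_m/4].
    """
    if q < 0:
        raise ValueError(f"rate must be >= 0, got {q}")
    qmax = p.max_rate
    if q > qmax * (1 + 1e-12):
        raise ValueError(
            f"rate {q} exceeds logistic maximum mu_max*x_m/4 = {qmax:.6g}"
        )
    disc = max(p.x_m * p.x_m - 4.0 * q * p.x_m / p.mu_max, 0.0)
    half = np.sqrt(disc) / 2.0
    if branch == "pre_inflection":
        return p.x_m / 2.0 - half
    if branch == "post_inflection":
        return p.x_m / 2.0 + half
    raise ValueError(f"unknown branch {branch!r}")


def anchor_trajectory(day1_rate: float, mu_max: float, x_m: float) -> LogisticParams:
    """Pin a logistic trajectory through an observed day-1 growth rate.

    Published kinetic tables report mu_max and x_m but not the inoculum
    biomass x_0; the day-1 rate determines it. The day-1 biomass is the
    pre-inflection root of the rate law, and the closed form is then run
    backwards one day to x_0 = x_m / (1 + C) with
    C = (x_m/X(1) - 1)*exp(mu_max).
    """
    shape = LogisticParams(mu_max=mu_max, x_m=x_m, x_0=x_m / 2.0)
    x1 = biomass_from_rate(day1_rate, shape, "pre_inflection")
    if x1 <= 0:
        raise ValueError("day-1 rate of 0 cannot anchor a growing trajectory")
    c = (x_m / x1 - 1.0) * np.exp(mu_max)
    return LogisticParams(mu_max=mu_max, x_m=x_m, x_0=x_m / (1.0 + c))


def cumulative_biomass(t, p: LogisticParams):
    """Closed-form integral of biomass from 0 to t (g*day/L).

    ∫0^t X dτ = (x_m/mu_max) * ln((C + e^{mu_max t}) / (C + 1)),
    evaluated in log space so large mu_max*t cannot overflow.
    """
    t = np.asarray(t, dtype=float)
    c = p.c
    if c == 0.0:  # x_0 == x_m: constant biomass
        out = p.x_m * t
    else:
        log_num = np.logaddexp(np.log(c), p.mu_max * t)
        out = (p.x_m / p.mu_max) * (log_num - np.log(c + 1.0))
    return out if np.ndim(out) else float(out)


def lipid(t, p: LogisticParams, lp: LuedekingPiretParams):
    """Lipid P(t) (g/L) from the closed-form Luedeking-Piret integral."""
    t = np.asarray(t, dtype=float)
    out = lp.p_0 + lp.alpha * (biomass(t, p) - p.x_0) + lp.beta * cumulative_biomass(t, p)
    return out if np.ndim(out) else float(out)


def lipid_rate(x, dxdt, lp: LuedekingPiretParams):
    """Instantaneous lipid accumulation rate dP/dt = alpha*dX/dt + beta*X."""
    x = np.asarray(x, dtype=float)
    dxdt = np.asarray(dxdt, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(dxdt))):
        raise ValueError("x and dxdt must be finite")
    if np.any(x < 0):
        raise ValueError("biomass must be >= 0")
    out = lp.alpha * dxdt + lp.beta * x
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fitting


def _r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_logistic(tc: TimeCourse, fix_x_0: float | None = None) -> FitResult:
    """Nonlinear least squares of the logistic closed form to biomass data.

    Fits (mu_max, x_m, x_0) jointly, or (mu_max, x_m) with x_0 held at
    ``fix_x_0``. Starting values come from the data: x_m from 1.05*max(X),
    x_0 from the first positive observation, mu_max from the early log-slope.
    Requires >= 4 observations. Non-convergence and boundary-pinned
    solutions are flagged, never silently returned.
    """
    t, x = tc.t, tc.x
    if len(t) < 4:
        raise ValueError(f"need >= 4 observations to fit the logistic, got {len(t)}")
    xmax = float(np.max(x))
    flags: list[str] = []
    if xmax <= 0 or np.ptp(x) == 0:
        # flat or non-positive series: carrying capacity and rate unidentifiable
        x0c = max(xmax, 1e-12)
        params = LogisticParams(mu_max=1e-6, x_m=x0c, x_0=x0c)
        return FitResult(params, rss=float(np.sum((x - x0c) ** 2)),
                         r_squared=0.0, converged=False, n_obs=len(t),
                         flags=["degenerate_series"])

    x_m0 = 1.05 * xmax
    pos = x[x > 0]
    x_00 = float(pos[0]) if len(pos) else 0.1 * xmax
    # early-phase log-slope as mu_max guess
    k = max(3, len(t) // 3)
    tt, xx = t[:k], x[:k]
    good = xx > 0
    if good.sum() >= 2:
        slope = np.polyfit(tt[good], np.log(xx[good]), 1)[0]
        mu0 = float(np.clip(slope, 0.05, 5.0))
    else:
        mu0 = 0.5

    if fix_x_0 is None:
        theta0 = [mu0, x_m0, min(x_00, x_m0)]
        lo = [1e-6, xmax, 1e-9]
        hi = [10.0, 10.0 * xmax, x_m0]

        def resid(th):
            mu, xm, x0 = th
            x0 = min(x0, xm)
            return biomass(t, LogisticParams(mu, xm, x0)) - x
    else:
        if not 0 < fix_x_0:
            raise ValueError("fix_x_0 must be > 0")
        theta0 = [mu0, max(x_m0, fix_x_0)]
        lo = [1e-6, max(xmax, fix_x_0)]
        hi = [10.0, 10.0 * max(xmax, fix_x_0)]

        def resid(th):
            mu, xm = th
            return biomass(t, LogisticParams(mu, xm, fix_x_0)) - x

    sol = optimize.least_squares(
        resid, theta0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    if fix_x_0 is None:
        mu, xm, x0 = sol.x
        params = LogisticParams(mu, xm, min(x0, xm))
    else:
        mu, xm = sol.x
        params = LogisticParams(mu, xm, fix_x_0)

    pred = biomass(t, params)
    rss = float(np.sum((pred - x) ** 2))
    converged = bool(sol.success)
    if not converged:
        flags.append("optimizer_did_not_converge")
    if mu >= hi[0] * (1 - 1e-6) or xm >= hi[1] * (1 - 1e-6):
        flags.append("parameter_at_bound")
        converged = False
    return FitResult(params, rss=rss, r_squared=_r_squared(x, pred),
                     converged=converged, n_obs=len(t), flags=flags)


def fit_luedeking_piret(tc: TimeCourse, p: LogisticParams) -> FitResult:
    """Linear least squares for (alpha, beta) on the integrated product form.

    With the logistic parameters known, Luedeking-Piret integrates to

        P(t_i) - P(t_1) = alpha*(X(t_i) - X(t_1))
                          + beta * ∫_{t_1}^{t_i} X dτ,

    a regression that is linear in (alpha, beta) with the integral evaluated
    from the closed form — no numerical differentiation of noisy data.
    The trajectory is anchored at the first observation, so the unknown
    initial lipid level never enters the fitted coefficients. Negative
    estimates are clipped to 0 and flagged.
    """
    if tc.p is None:
        raise ValueError("time course has no lipid column")
    t, pobs = tc.t, tc.p
    if len(t) < 3:
        raise ValueError(f"need >= 3 lipid observations, got {len(t)}")

    xfit = biomass(t, p)
    integ = cumulative_biomass(t, p)
    dx = xfit - xfit[0]
    di = integ - integ[0]
    dpv = pobs - pobs[0]
    design = np.column_stack([dx, di])
    if np.linalg.matrix_rank(design) < 2:
        raise ValueError("singular design: biomass and its integral are collinear "
                         "over the sampled times (too few distinct time points?)")
    coef, *_ = np.linalg.lstsq(design, dpv, rcond=None)
    alpha, beta = (float(c) for c in coef)

    flags: list[str] = []
    if alpha < 0 or beta < 0:
        flags.append("negative_coefficient_clipped")
        # refit the remaining coefficient with the negative one pinned at 0
        if alpha < 0 and beta < 0:
            alpha = beta = 0.0
        elif alpha < 0:
            alpha = 0.0
            beta = float(np.dot(di, dpv) / np.dot(di, di))
            beta = max(beta, 0.0)
        else:
            beta = 0.0
            alpha = float(np.dot(dx, dpv) / np.dot(dx, dx))
            alpha = max(alpha, 0.0)

    p_0 = float(pobs[0] - alpha * (xfit[0] - p.x_0) - beta * integ[0])
    params = LuedekingPiretParams(alpha=alpha, beta=beta, p_0=p_0)
    pred = pobs[0] + alpha * dx + beta * di
    rss = float(np.sum((pred - pobs) ** 2))
    return FitResult(params, rss=rss, r_squared=_r_squared(pobs, pred),
                     converged=True, n_obs=len(t), flags=flags)


def rate_table(
    p: LogisticParams,
    lp: LuedekingPiretParams,
    days: Sequence[int] = range(1, 9),
) -> RateTable:
    """Daily growth and lipid rates Q_X(d), Q_L(d) on an integer-day grid.

    Q_X(d) = dX/dt at the day-d biomass, Q_L(d) = alpha*Q_X(d) + beta*X(d);
    the reported maxima are taken over the listed days.
    """
    day = np.asarray(list(days), dtype=int)
    if day.size == 0:
        raise ValueError("days must be non-empty")
    x = biomass(day.astype(float), p)
    q_x = growth_rate(x, p)
    q_l = lipid_rate(x, q_x, lp)
    return RateTable(day=day, q_x=q_x, q_l=q_l,
                     q_x_max=float(np.max(q_x)), q_l_max=float(np.max(q_l)))
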