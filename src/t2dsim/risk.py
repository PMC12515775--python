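"""Outcome risk equations: parametric time-to-event families, logistic annual
mortality, flexible parametric (spline-on-log-time) survival, maximum-likelihood
fitting with right censoring, and AIC-based family selection.

Parameterisations
-----------------
Let ``lp = intercept + sum(beta_i * x_i)`` be the linear predictor.

Proportional-hazards action (covariates scale the cumulative hazard):

* ``exponential``:   H(t) = exp(lp) * t
* ``weibull``:       H(t) = exp(lp) * t**shape,                shape > 0
* ``gompertz``:      H(t) = exp(lp) * expm1(shape*t)/shape     (shape -> 0
  recovers the exponential; any real shape is accepted)
* ``flexible_parametric``: log H(t) = s(log t) + lp with ``s`` a natural cubic
  spline (restricted cubic basis, linear beyond the boundary knots).

Accelerated-failure-time action (covariates shift log event time):

* ``loglogistic``:   S(t) = 1 / (1 + (t * exp(-lp))**(1/shape)), shape > 0
* ``lognormal``:     S(t) = 1 - Phi((log t - lp) / shape),       shape > 0

``logistic`` is not a survival family here: it gives the annual probability
``expit(lp)`` and is used for mortality only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

OUTCOMES: tuple[str, ...] = (
    "mortality",
    "haemodialysis",
    "myocardial_infarction",
    "ischaemic_heart_disease",
    "heart_failure",
    "cerebrovascular_disease",
    "peripheral_vascular_disease",
    "neuropathy",
    "lower_limb_amputation",
    "skin_ulcer",
    "chronic_kidney_disease",
    "retinopathy",
    "cataract",
)

COMPLICATIONS: tuple[str, ...] = tuple(o for o in OUTCOMES if o != "mortality")

SURVIVAL_FAMILIES = (
    "exponential",
    "weibull",
    "gompertz",
    "loglogistic",
    "lognormal",
    "flexible_parametric",
)
FAMILIES = SURVIVAL_FAMILIES + ("logistic",)

_SHAPED = {"weibull", "gompertz", "loglogistic", "lognormal"}


class RiskModelError(ValueError):
    pass


class FitRejectedError(RiskModelError):
    """Raised when a fitted model violates a structural requirement
    (e.g. non-monotone fitted cumulative hazard for the spline family)."""


@dataclass(frozen=True)
class RiskEquation:
    """A fitted risk model for one outcome.

    ``coefficients`` must contain an ``"intercept"`` entry; the remaining keys
    define the covariates the equation consumes (``covariate_spec`` fixes
    their order). ``shape`` is the ancillary parameter for the shaped
    families; ``spline_gamma``/``knots`` parameterise the flexible parametric
    family (knots on the log-time scale, ascending, first/last are boundary
    knots).
    """

    outcome: str
    family: str
    coefficients: Mapping[str, float]
    shape: float | None = None
    spline_gamma: tuple[float, ...] | None = None
    knots: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise RiskModelError(f"unknown family {self.family!r}")
        if "intercept" not in self.coefficients:
            raise RiskModelError(f"{self.outcome}: coefficients must include 'intercept'")
        if self.family in _SHAPED:
            if self.shape is None:
                raise RiskModelError(f"{self.family} requires a shape parameter")
            if self.family != "gompertz" and self.shape <= 0:
                raise RiskModelError(f"{self.family} shape must be > 0, got {self.shape}")
        if self.family == "flexible_parametric":
            if self.spline_gamma is None or self.knots is None:
                raise RiskModelError("flexible_parametric requires spline_gamma and knots")
            if len(self.knots) < 2 or any(
                b <= a for a, b in zip(self.knots, self.knots[1:])
            ):
                raise RiskModelError("knots must be >= 2 strictly increasing values")
            if len(self.spline_gamma) != len(self.knots):
                raise RiskModelError(
                    "spline_gamma must have length len(knots) "
                    "(2 base terms + one per internal knot)"
                )

    @property
    def covariate_spec(self) -> tuple[str, ...]:
        return tuple(k for k in self.coefficients if k != "intercept")

    @property
    def n_parameters(self) -> int:
        k = len(self.coefficients)
        if self.family in _SHAPED:
            k += 1
        if self.family == "flexible_parametric":
            k += len(self.spline_gamma) - 1  # intercept already counted
        return k

    def to_dict(self) -> dict:
        d = {
            "outcome": self.outcome,
            "family": self.family,
            "coefficients": dict(self.coefficients),
        }
        if self.shape is not None:
            d["shape"] = float(self.shape)
        if self.spline_gamma is not None:
            d["spline_gamma"] = [float(g) for g in self.spline_gamma]
            d["knots"] = [float(k) for k in self.knots]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskEquation":
        return cls(
            outcome=d["outcome"],
            family=d["family"],
            coefficients=dict(d["coefficients"]),
            shape=d.get("shape"),
            spline_gamma=tuple(d["spline_gamma"]) if "spline_gamma" in d else None,
            knots=tuple(d["knots"]) if "knots" in d else None,
        )


@dataclass
class FitResult:
    equation: RiskEquation
    log_likelihood: float
    aic: float
    n_events: int
    n_observations: int
    converged: bool
    standard_errors: dict[str, float] = field(default_factory=dict)
    optimizer: dict = field(default_factory=dict)
    aic_table: list[tuple[str, float, bool]] | None = None


# ---------------------------------------------------------------------------
# linear predictor


def linear_predictor(eq: RiskEquation, covariates: Mapping[str, object]):
    """``intercept + sum(beta_i * x_i)``; scalar or vectorised over arrays.

    Every covariate named in the equation must be present — a missing
    covariate is an error, never silently zero. Extra keys are ignored.
    """
    missing = [k for k in eq.covariate_spec if k not in covariates]
    if missing:
        raise RiskModelError(
            f"{eq.outcome}: missing covariate(s) {missing} for linear predictor"
        )
    lp = eq.coefficients["intercept"]
    for name in eq.covariate_spec:
        lp = lp + eq.coefficients[name] * np.asarray(covariates[name], dtype=float)
    return lp


# ---------------------------------------------------------------------------
# restricted cubic spline basis (natural cubic, linear beyond boundary knots)


def _rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Basis columns [1, x, v_1(x), ..., v_m(x)] for internal knots k_1..k_m."""
    x = np.asarray(x, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.ones_like(x), x]
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        v = (
            np.maximum(x - kj, 0.0) ** 3
            - lam * np.maximum(x - kmin, 0.0) ** 3
            - (1 - lam) * np.maximum(x - kmax, 0.0) ** 3
        )
        cols.append(v)
    return np.stack(cols, axis=-1)


def _rcs_deriv(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Derivative columns matching :func:`_rcs_basis`."""
    x = np.asarray(x, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.zeros_like(x), np.ones_like(x)]
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        dv = 3 * (
            np.maximum(x - kj, 0.0) ** 2
            - lam * np.maximum(x - kmin, 0.0) ** 2
            - (1 - lam) * np.maximum(x - kmax, 0.0) ** 2
        )
        cols.append(dv)
    return np.stack(cols, axis=-1)


def _spline_log_chaz(eq: RiskEquation, t):
    x = np.log(np.asarray(t, dtype=float))
    gamma = np.asarray(eq.spline_gamma, dtype=float)
    return _rcs_basis(x, eq.knots) @ gamma


def _spline_dlogchaz_dx(eq: RiskEquation, t):
    x = np.log(np.asarray(t, dtype=float))
    gamma = np.asarray(eq.spline_gamma, dtype=float)
    return _rcs_deriv(x, eq.knots) @ gamma


# ---------------------------------------------------------------------------
# family math


def cumulative_hazard(eq: RiskEquation, lp, t):
    """H(t) for a survival family; vectorised over ``lp`` and ``t``."""
    t = np.asarray(t, dtype=float)
    lp = np.asarray(lp, dtype=float)
    if np.any(t < 0):
        raise RiskModelError("time must be >= 0")
    fam = eq.family
    if fam == "exponential":
        return np.exp(lp) * t
    if fam == "weibull":
        return np.exp(lp) * t**eq.shape
    if fam == "gompertz":
        g = eq.shape
        if abs(g) < 1e-12:
            return np.exp(lp) * t
        return np.exp(lp) * np.expm1(g * t) / g
    if fam == "loglogistic":
        with np.errstate(divide="ignore"):
            w = (np.log(t) - lp) / eq.shape
        return np.where(t > 0, np.log1p(np.exp(np.minimum(w, 700.0))), 0.0)
    if fam == "lognormal":
        with np.errstate(divide="ignore"):
            z = (np.log(t) - lp) / eq.shape
        return np.where(t > 0, -sps.norm.logsf(z), 0.0)
    if fam == "flexible_parametric":
        out = np.zeros(np.broadcast_shapes(t.shape, lp.shape))
        pos = np.broadcast_to(t > 0, out.shape)
        tb = np.broadcast_to(t, out.shape)
        lpb = np.broadcast_to(lp, out.shape)
        out[pos] = np.exp(
            np.minimum(_spline_log_chaz(eq, tb[pos]) + lpb[pos], 700.0)
        )
        return out
    raise RiskModelError(f"{fam} is not a survival family")


def survival(eq: RiskEquation, lp, t):
    """S(t) in [0, 1]; S(0) = 1 by construction for every family."""
    if eq.family == "logistic":
        raise RiskModelError("logistic is not a survival family; use mortality_probability")
    H = cumulative_hazard(eq, lp, t)
    return np.clip(np.exp(-H), 0.0, 1.0)


def log_hazard(eq: RiskEquation, lp, t):
    """log h(t); requires t > 0."""
    t = np.asarray(t, dtype=float)
    lp = np.asarray(lp, dtype=float)
    if np.any(t <= 0):
        raise RiskModelError("log_hazard requires t > 0")
    fam = eq.family
    if fam == "exponential":
        return lp + np.zeros_like(t)
    if fam == "weibull":
        return lp + np.log(eq.shape) + (eq.shape - 1) * np.log(t)
    if fam == "gompertz":
        return lp + eq.shape * t
    if fam == "loglogistic":
        w = (np.log(t) - lp) / eq.shape
        return -np.log(eq.shape) - np.log(t) + w - np.log1p(np.exp(np.minimum(w, 700.0)))
    if fam == "lognormal":
        z = (np.log(t) - lp) / eq.shape
        return sps.norm.logpdf(z) - np.log(eq.shape * t) - sps.norm.logsf(z)
    if fam == "flexible_parametric":
        x = np.log(t)
        ds = _spline_dlogchaz_dx(eq, t)
        if np.any(ds <= 0):
            raise RiskModelError("non-positive spline slope: hazard undefined")
        return _spline_log_chaz(eq, t) + lp + np.log(ds) - x
    raise RiskModelError(f"{fam} is not a survival family")


def density(eq: RiskEquation, lp, t):
    """Event-time density f(t) = h(t) * S(t)."""
    return np.exp(log_hazard(eq, lp, t)) * survival(eq, lp, t)


def inverse_survival(eq: RiskEquation, lp, u):
    """Solve S(T) = u for T (inverse-CDF sampling with U = S(T)).

    Returns ``inf`` where the cumulative hazard is bounded below ``-log u``
    (e.g. negative-shape Gompertz), i.e. the event never happens.
    """
    lp = np.asarray(lp, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u > 1)):
        raise RiskModelError("u must be in (0, 1]")
    H = -np.log(u)
    fam = eq.family
    if fam == "exponential":
        with np.errstate(divide="ignore", over="ignore"):
            return H / np.exp(lp)
    if fam == "weibull":
        with np.errstate(divide="ignore", over="ignore"):
            return (H / np.exp(lp)) ** (1.0 / eq.shape)
    if fam == "gompertz":
        g = eq.shape
        if abs(g) < 1e-12:
            return H / np.exp(lp)
        arg = g * H / np.exp(lp)
        with np.errstate(invalid="ignore"):
            out = np.log1p(arg) / g
        if g < 0:
            out = np.where(arg <= -1.0, np.inf, out)
        return out
    if fam == "loglogistic":
        return np.exp(lp) * np.expm1(H) ** eq.shape
    if fam == "lognormal":
        return np.exp(lp + eq.shape * sps.norm.isf(np.exp(-H)))
    if fam == "flexible_parametric":
        # log H is monotone in x = log t; bisect on x with linear tails.
        target = np.log(H) - lp
        lo = np.full(target.shape, eq.knots[0] - 40.0)
        hi = np.full(target.shape, eq.knots[-1] + 40.0)
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            val = _rcs_basis(mid, eq.knots) @ np.asarray(eq.spline_gamma)
            lo = np.where(val < target, mid, lo)
            hi = np.where(val < target, hi, mid)
        return np.exp(0.5 * (lo + hi))
    raise RiskModelError(f"{fam} is not a survival family")


def mortality_probability(eq: RiskEquation, covariates: Mapping):
    """Annual death probability ``expit(lp)`` for the logistic mortality model."""
    if eq.family != "logistic":
        raise RiskModelError(
            f"mortality_probability requires a logistic equation, got {eq.family}"
        )
    return special.expit(linear_predictor(eq, covariates))


def annual_event_probability(eq: RiskEquation, covariates: Mapping, t):
    """Probability of the event in cycle ``[t, t+1)`` conditional on being
    event-free at ``t``: ``1 - S(t+1)/S(t)``, clamped to [0, 1].

    The logistic mortality equation has no time dimension and delegates to
    :func:`mortality_probability`.
    """
    if eq.family == "logistic":
        return mortality_probability(eq, covariates)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise RiskModelError("cycle index must be >= 0")
    lp = linear_predictor(eq, covariates)
    Ht = cumulative_hazard(eq, lp, t)
    Ht1 = cumulative_hazard(eq, lp, t + 1.0)
    st = np.exp(-Ht)
    if np.any(st == 0.0):
        warnings.warn(
            f"{eq.outcome}: S(t)=0 encountered; annual probability set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        p = -np.expm1(-(Ht1 - Ht))
    p = np.where(st == 0.0, 1.0, p)
    return np.clip(p, 0.0, 1.0)


def retinopathy_survival(eq: RiskEquation, lp, t):
    """Survival for the flexible parametric (spline) family, S(0)=1.

    Thin validated wrapper over :func:`survival` for the one outcome that
    uses this family in the default catalog.
    """
    if eq.family != "flexible_parametric":
        raise RiskModelError("retinopathy_survival requires a flexible_parametric equation")
    return survival(eq, lp, t)


# ---------------------------------------------------------------------------
# fitting

_OPTIMIZER_SETTINGS = {"method": "L-BFGS-B", "maxiter": 500, "gtol": 1e-8}


def _design(panel: pd.DataFrame, covariate_spec: Sequence[str]) -> np.ndarray:
    missing = [c for c in covariate_spec if c not in panel.columns]
    if missing:
        raise RiskModelError(f"panel lacks covariate column(s) {missing}")
    X = np.column_stack(
        [np.ones(len(panel))] + [panel[c].to_numpy(dtype=float) for c in covariate_spec]
    )
    return X


def _unpack(theta, n_beta, family, knots=None):
    beta = theta[:n_beta]
    shape = None
    gamma = None
    if family in _SHAPED:
        shape = np.exp(theta[n_beta]) if family != "gompertz" else theta[n_beta]
    if family == "flexible_parametric":
        gamma = theta[n_beta:]
    return beta, shape, gamma


def _negloglik(theta, X, time, event, family, knots):
    n_beta = X.shape[1]
    beta, shape, gamma = _unpack(theta, n_beta, family, knots)
    lp = X @ beta
    if family == "logistic":
        # each row is one Bernoulli trial
        ll = np.sum(event * lp - np.logaddexp(0.0, lp))
        return -ll
    eq = RiskEquation(
        outcome="_fit",
        family=family,
        coefficients={"intercept": 0.0},
        shape=shape,
        spline_gamma=tuple(gamma) if gamma is not None else None,
        knots=knots,
    )
    if family == "flexible_parametric":
        # reject slopes that make the hazard negative at observed times
        ds = _rcs_deriv(np.log(time), knots) @ np.asarray(gamma)
        if np.any(ds <= 1e-10):
            return 1e10 + np.sum(np.minimum(ds, 0.0) ** 2)
    H = cumulative_hazard(eq, lp, time)
    with np.errstate(over="ignore"):
        ll = -np.sum(H)
    ev = event.astype(bool)
    if ev.any():
        ll += np.sum(log_hazard(eq, lp[ev], time[ev]))
    if not np.isfinite(ll):
        return 1e10
    return -ll


def _numeric_hessian(f, theta, eps=1e-5):
    k = len(theta)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * eps * eps)
    return H


def default_knots(time: np.ndarray, event: np.ndarray, n_internal: int = 1) -> tuple[float, ...]:
    """Knots on log time: boundaries at min/max event times, internal knots at
    event-time quantiles (median for the default single internal knot)."""
    et = np.log(time[event.astype(bool)])
    qs = np.linspace(0, 1, n_internal + 2)
    ks = np.quantile(et, qs)
    # guard against duplicate knots in small samples
    for i in range(1, len(ks)):
        if ks[i] <= ks[i - 1]:
            ks[i] = ks[i - 1] + 1e-6
    return tuple(float(k) for k in ks)


def fit_risk_equation(
    panel: pd.DataFrame,
    family: str,
    covariate_spec: Sequence[str],
    outcome: str = "outcome",
    n_internal_knots: int = 1,
    knots: Sequence[float] | None = None,
) -> FitResult:
    """Maximum-likelihood fit with right censoring.

    ``panel`` needs columns ``time`` (>0; ignored by the logistic family),
    ``event`` (0/1) and one column per covariate. Deterministic given the
    data and the fixed optimizer settings. Zero events is an error;
    non-convergence is flagged on the result, never silent.
    """
    if family not in FAMILIES:
        raise RiskModelError(f"unknown family {family!r}")
    event = panel["event"].to_numpy(dtype=float)
    n_events = int(event.sum())
    if n_events == 0:
        raise RiskModelError("cannot fit a risk equation to a panel with zero events")
    X = _design(panel, covariate_spec)
    n_beta = X.shape[1]

    if family == "logistic":
        time = np.ones(len(panel))
    else:
        time = panel["time"].to_numpy(dtype=float)
        if np.any(time <= 0):
            raise RiskModelError("survival times must be > 0")

    # starting values
    theta0 = np.zeros(n_beta)
    person_time = float(time.sum())
    if family in ("exponential", "weibull", "gompertz"):
        theta0[0] = np.log(n_events / person_time)
    elif family in ("loglogistic", "lognormal"):
        theta0[0] = float(np.mean(np.log(time[event.astype(bool)])))
    elif family == "logistic":
        p0 = np.clip(n_events / len(panel), 1e-6, 1 - 1e-6)
        theta0[0] = float(special.logit(p0))

    fit_knots = None
    if family in _SHAPED:
        theta0 = np.append(theta0, 0.0 if family != "gompertz" else 0.01)
    elif family == "flexible_parametric":
        fit_knots = tuple(knots) if knots is not None else default_knots(
            time, event, n_internal_knots
        )
        gamma0 = np.zeros(len(fit_knots))
        gamma0[0] = np.log(n_events / person_time)
        gamma0[1] = 1.0
        theta0 = np.concatenate([theta0, gamma0])
        theta0[0] = 0.0  # constant lives in gamma[0]

    nll = lambda th: _negloglik(th, X, time, event, family, fit_knots)  # noqa: E731
    res = optimize.minimize(
        nll,
        theta0,
        method=_OPTIMIZER_SETTINGS["method"],
        options={
            "maxiter": _OPTIMIZER_SETTINGS["maxiter"],
            "gtol": _OPTIMIZER_SETTINGS["gtol"],
        },
    )
    theta = res.x
    beta, shape, gamma = _unpack(theta, n_beta, family, fit_knots)
    coefficients = {"intercept": float(beta[0])}
    coefficients.update({c: float(b) for c, b in zip(covariate_spec, beta[1:])})

    eq = RiskEquation(
        outcome=outcome,
        family=family,
        coefficients=coefficients,
        shape=float(shape) if shape is not None else None,
        spline_gamma=tuple(float(g) for g in gamma) if gamma is not None else None,
        knots=fit_knots,
    )

    if family == "flexible_parametric":
        grid = np.exp(np.linspace(fit_knots[0] - 2, fit_knots[-1] + 2, 200))
        if np.any(_spline_dlogchaz_dx(eq, grid) <= 0):
            raise FitRejectedError(
                "fitted flexible parametric cumulative hazard is non-monotone"
            )

    ll = -res.fun
    k = eq.n_parameters
    aic = 2 * k - 2 * ll

    ses: dict[str, float] = {}
    try:
        H = _numeric_hessian(nll, theta)
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        names = ["intercept", *covariate_spec]
        ses = {n: float(s) for n, s in zip(names, se[:n_beta])}
        if family in _SHAPED:
            # delta method for shape = exp(theta) families
            s = se[n_beta]
            ses["shape"] = float(s * shape) if family != "gompertz" else float(s)
        if family == "flexible_parametric":
            for i, s in enumerate(se[n_beta:]):
                ses[f"gamma{i}"] = float(s)
    except np.linalg.LinAlgError:
        pass

    return FitResult(
        equation=eq,
        log_likelihood=float(ll),
        aic=float(aic),
        n_events=n_events,
        n_observations=len(panel),
        converged=bool(res.success),
        standard_errors=ses,
        optimizer={**_OPTIMIZER_SETTINGS, "n_iter": int(res.nit), "message": str(res.message)},
    )


def select_model(
    panel: pd.DataFrame,
    families: Iterable[str],
    covariate_spec: Sequence[str],
    outcome: str = "outcome",
) -> FitResult:
    """Fit each candidate family and return the minimum-AIC converged fit.

    Ties within 1e-9 go to the earlier family in the caller's order. The full
    per-family AIC table (family, aic, converged) is attached to the result
    for audit. Raises if no candidate converges.
    """
    families = list(families)
    if not families:
        raise RiskModelError("need at least one candidate family")
    fits: list[FitResult | None] = []
    table: list[tuple[str, float, bool]] = []
    for fam in families:
        try:
            fr = fit_risk_equation(panel, fam, covariate_spec, outcome=outcome)
        except RiskModelError:
            fits.append(None)
            table.append((fam, float("nan"), False))
            continue
        fits.append(fr)
        table.append((fam, fr.aic, fr.converged))
    candidates = [(i, f) for i, f in enumerate(fits) if f is not None and f.converged]
    if not candidates:
        raise RiskModelError("no candidate family converged")
    best_aic = min(f.aic for _, f in candidates)
    for i, f in candidates:
        if f.aic <= best_aic + 1e-9:
            best = f
            break
    best.aic_table = table
    return best
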