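"""Time-varying progression of BMI, HbA1c, systolic BP and LDL-cholesterol —
the uncontrolled (comparator) biomarker trajectory.

Each biomarker has a one-step regression on its previous-year value plus
demographic covariates, either on the natural scale (``linear``) or on a
logit-rescaled bounded range (``logistic_transform``). The default policy for
the main analysis is deterministic conditional-mean paths (events stay
stochastic); Gaussian residuals are available for sensitivity runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import special

PROGRESSED = ("bmi", "hba1c", "sbp", "ldl")

_EPS = 1e-9


class BiomarkerError(ValueError):
    pass


@dataclass(frozen=True)
class BiomarkerEquation:
    """One-step-ahead model for a single biomarker.

    ``coefficients`` must include ``intercept`` and ``prev``; any other keys
    name state covariates (age, female, duration, year). ``bounds`` is the
    physiological clamp applied to predictions.
    """

    biomarker: str
    model_type: str  # "linear" | "logistic_transform"
    coefficients: Mapping[str, float]
    residual_sd: float
    bounds: tuple[float, float]

    def __post_init__(self):
        if self.model_type not in ("linear", "logistic_transform"):
            raise BiomarkerError(f"unknown model_type {self.model_type!r}")
        if self.residual_sd < 0:
            raise BiomarkerError("residual_sd must be >= 0")
        lo, hi = self.bounds
        if not lo < hi:
            raise BiomarkerError("bounds must satisfy lo < hi")
        for key in ("intercept", "prev"):
            if key not in self.coefficients:
                raise BiomarkerError(f"coefficients must include {key!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coefficients"] = dict(self.coefficients)
        d["bounds"] = list(self.bounds)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "BiomarkerEquation":
        d = dict(d)
        d["bounds"] = tuple(d["bounds"])
        d["coefficients"] = dict(d["coefficients"])
        return cls(**d)


def _to_model_scale(eq: BiomarkerEquation, value):
    if eq.model_type == "linear":
        return np.asarray(value, dtype=float)
    lo, hi = eq.bounds
    frac = np.clip((np.asarray(value, dtype=float) - lo) / (hi - lo), _EPS, 1 - _EPS)
    return special.logit(frac)


def _from_model_scale(eq: BiomarkerEquation, z):
    if eq.model_type == "linear":
        return np.asarray(z, dtype=float)
    lo, hi = eq.bounds
    return lo + (hi - lo) * special.expit(np.asarray(z, dtype=float))


def predict_biomarker(
    eq: BiomarkerEquation,
    covariates: Mapping[str, object],
    rng: np.random.Generator | None = None,
):
    """Next-year value: conditional mean when ``rng`` is None, mean plus a
    Gaussian residual (on the model scale) otherwise. Clamped to bounds."""
    if "prev" not in covariates:
        raise BiomarkerError("covariates must include 'prev' (previous value)")
    z = eq.coefficients["intercept"] + eq.coefficients["prev"] * _to_model_scale(
        eq, covariates["prev"]
    )
    for name, beta in eq.coefficients.items():
        if name in ("intercept", "prev"):
            continue
        if name not in covariates:
            raise BiomarkerError(f"{eq.biomarker}: missing covariate {name!r}")
        z = z + beta * np.asarray(covariates[name], dtype=float)
    if rng is not None and eq.residual_sd > 0:
        z = z + rng.normal(0.0, eq.residual_sd, size=np.shape(z))
    value = _from_model_scale(eq, z)
    lo, hi = eq.bounds
    return np.clip(value, lo, hi)


def fit_biomarker_model(
    panel,
    biomarker: str,
    model_type: str = "linear",
    covariates: tuple[str, ...] = (),
    bounds: tuple[float, float] | None = None,
) -> BiomarkerEquation:
    """Least-squares fit of the one-step model from consecutive-year pairs.

    ``panel`` needs columns ``year``, ``value`` (this year), ``prev``
    (last year) plus any requested covariates. The logistic_transform variant
    fits by least squares on the logit-rescaled scale.
    """
    if panel["year"].nunique() < 2:
        raise BiomarkerError("panel must span at least 2 distinct years")
    lo, hi = bounds if bounds is not None else (
        float(panel[["value", "prev"]].min().min()) - 1.0,
        float(panel[["value", "prev"]].max().max()) + 1.0,
    )
    eq_stub = BiomarkerEquation(
        biomarker=biomarker,
        model_type=model_type,
        coefficients={"intercept": 0.0, "prev": 1.0},
        residual_sd=0.0,
        bounds=(lo, hi),
    )
    y = _to_model_scale(eq_stub, panel["value"].to_numpy(dtype=float))
    prev = _to_model_scale(eq_stub, panel["prev"].to_numpy(dtype=float))
    X = np.column_stack(
        [np.ones(len(panel)), prev]
        + [panel[c].to_numpy(dtype=float) for c in covariates]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(panel) - X.shape[1], 1)
    sd = float(np.sqrt(resid @ resid / dof))
    coefs = {"intercept": float(beta[0]), "prev": float(beta[1])}
    coefs.update({c: float(b) for c, b in zip(covariates, beta[2:])})
    return BiomarkerEquation(
        biomarker=biomarker,
        model_type=model_type,
        coefficients=coefs,
        residual_sd=sd,
        bounds=(lo, hi),
    )


def progress_biomarkers(
    state: Mapping[str, object],
    catalog: Mapping[str, BiomarkerEquation],
    rng: np.random.Generator | str = "mean",
) -> dict[str, np.ndarray]:
    """Advance all four progressed biomarkers by one cycle.

    Every equation reads the *previous* cycle's values from ``state``, so the
    update is order-independent. ``rng="mean"`` gives the deterministic
    conditional-mean path.
    """
    missing = [b for b in PROGRESSED if b not in catalog]
    if missing:
        raise BiomarkerError(f"biomarker catalog missing equations for {missing}")
    gen = None if isinstance(rng, str) else rng
    if isinstance(rng, str) and rng != "mean":
        raise BiomarkerError(f"unknown rng policy {rng!r}")
    out: dict[str, np.ndarray] = {}
    for b in PROGRESSED:
        eq = catalog[b]
        cov = dict(state)
        cov["prev"] = state[b]
        out[b] = predict_biomarker(eq, cov, rng=gen)
    return out
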