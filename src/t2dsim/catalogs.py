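"""Default coefficient catalogs and YAML/JSON (de)serialisation.

Every number in the default catalogs is SYNTHETIC: a plausible,
internally-consistent placeholder chosen so the pipeline runs end to end
with protective risk equations (hazards increase with HbA1c, SBP and LDL).
Fidelity runs should load externally supplied catalogs via the loaders here;
the file layout round-trips through ``to_dict``/``from_dict`` of each type.

Intercepts in the risk catalog are not hand-tuned constants: each equation
states a target annual event rate at a reference covariate vector and the
intercept is solved from it, so the synthetic population starts at sensible
absolute risks.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import yaml
from scipy import special
from scipy import stats as sps

from .biomarkers import BiomarkerEquation
from .economics import CostCatalog, UtilityCatalog
from .risk import RiskEquation

#: covariate values the synthetic base rates refer to
REFERENCE_COVARIATES: dict[str, float] = {
    "age": 68.2,
    "female": 0.503,
    "duration": 6.7,
    "bmi": 25.8,
    "hba1c": 7.3,
    "sbp": 135.0,
    "ldl": 2.2,
    "smoker": 0.15,
    "prior_cvd": 0.20,
}

# outcome -> (family, shape, base annual rate at reference, effects)
# AFT families (loglogistic/lognormal) take effects on log time, so harmful
# covariates carry negative signs there.
_RISK_SPEC: dict[str, tuple[str, float | None, float, dict[str, float]]] = {
    "mortality": (
        "logistic",
        None,
        0.030,
        {
            "age": 0.080, "female": -0.15, "duration": 0.020, "bmi": -0.010,
            "hba1c": 0.100, "sbp": 0.008, "ldl": 0.050, "smoker": 0.35,
            "prior_cvd": 0.50,
        },
    ),
    "myocardial_infarction": (
        "weibull",
        1.10,
        0.006,
        {
            "age": 0.050, "female": -0.30, "duration": 0.010, "hba1c": 0.120,
            "sbp": 0.015, "ldl": 0.300, "smoker": 0.40, "prior_cvd": 0.60,
        },
    ),
    "ischaemic_heart_disease": (
        "exponential",
        None,
        0.008,
        {
            "age": 0.045, "female": -0.20, "hba1c": 0.100, "sbp": 0.012,
            "ldl": 0.250, "smoker": 0.35, "prior_cvd": 0.50,
        },
    ),
    "heart_failure": (
        "gompertz",
        0.030,
        0.005,
        {
            "age": 0.070, "female": -0.10, "duration": 0.015, "hba1c": 0.080,
            "sbp": 0.020, "bmi": 0.030, "prior_cvd": 0.50,
            "prior_myocardial_infarction": 0.70,
        },
    ),
    "cerebrovascular_disease": (
        "weibull",
        1.05,
        0.007,
        {
            "age": 0.060, "female": -0.10, "hba1c": 0.080, "sbp": 0.025,
            "ldl": 0.150, "smoker": 0.30, "prior_cvd": 0.40,
        },
    ),
    "peripheral_vascular_disease": (
        "exponential",
        None,
        0.004,
        {
            "age": 0.040, "duration": 0.020, "hba1c": 0.150, "ldl": 0.200,
            "smoker": 0.50,
        },
    ),
    "neuropathy": (
        "weibull",
        1.20,
        0.010,
        {"age": 0.020, "duration": 0.030, "hba1c": 0.200, "bmi": 0.020},
    ),
    "lower_limb_amputation": (
        "exponential",
        None,
        0.001,
        {
            "duration": 0.030, "hba1c": 0.180, "smoker": 0.30,
            "prior_peripheral_vascular_disease": 0.90,
        },
    ),
    "skin_ulcer": (
        "exponential",
        None,
        0.004,
        {"age": 0.020, "duration": 0.020, "hba1c": 0.120},
    ),
    "chronic_kidney_disease": (
        "gompertz",
        0.050,
        0.012,
        {
            "age": 0.050, "duration": 0.020, "hba1c": 0.120, "sbp": 0.015,
        },
    ),
    "haemodialysis": (
        "exponential",
        None,
        0.002,
        {
            "duration": 0.025, "hba1c": 0.100, "sbp": 0.010, "ldl": 0.080,
            "prior_chronic_kidney_disease": 1.20,
        },
    ),
    "retinopathy": (
        "flexible_parametric",
        None,
        0.015,
        {"age": 0.010, "duration": 0.040, "hba1c": 0.250, "sbp": 0.005},
    ),
    # AFT family: negative log-time effects = earlier events = higher risk
    "cataract": (
        "loglogistic",
        0.80,
        0.012,
        {"age": -0.060, "female": 0.05, "hba1c": -0.050, "duration": -0.010},
    ),
}

_RETINOPATHY_KNOTS = (np.log(0.5), np.log(20.0))
_RETINOPATHY_G1 = 1.15  # log-cumulative-hazard slope in log time (Weibull-like)


def _reference_lp(effects: Mapping[str, float]) -> float:
    # prior-complication flags reference a no-history person (value 0)
    return sum(
        beta * REFERENCE_COVARIATES.get(name, 0.0) for name, beta in effects.items()
    )


def _solve_intercept(family: str, shape: float | None, rate: float, effects: Mapping[str, float]) -> float:
    """Intercept so that the annual event probability at the reference
    covariates over the first cycle equals ``rate``."""
    ref = _reference_lp(effects)
    p = rate
    if family == "logistic":
        return float(special.logit(p)) - ref
    H1 = -np.log1p(-p)  # cumulative hazard over [0, 1] matching probability p
    if family == "exponential" or family == "weibull":
        return float(np.log(H1)) - ref  # H(1) = exp(lp) for both
    if family == "gompertz":
        return float(np.log(H1 * shape / np.expm1(shape))) - ref
    if family == "loglogistic":
        # S(1) = 1/(1+exp(-lp/shape)) -> lp = -shape * logit(H->p)
        return float(-shape * np.log(np.expm1(H1))) - ref
    if family == "lognormal":
        return float(-shape * sps.norm.isf(np.exp(-H1))) - ref
    if family == "flexible_parametric":
        # constant lives in gamma[0]; covariate intercept stays 0
        return float(np.log(H1)) - ref
    raise ValueError(family)


def default_risk_catalog() -> dict[str, RiskEquation]:
    """SYNTHETIC 13-equation catalog (see module docstring)."""
    catalog: dict[str, RiskEquation] = {}
    for outcome, (family, shape, rate, effects) in _RISK_SPEC.items():
        intercept = _solve_intercept(family, shape, rate, effects)
        if family == "flexible_parametric":
            coefficients = {"intercept": 0.0, **effects}
            eq = RiskEquation(
                outcome=outcome,
                family=family,
                coefficients=coefficients,
                spline_gamma=(intercept, _RETINOPATHY_G1),
                knots=_RETINOPATHY_KNOTS,
            )
        else:
            eq = RiskEquation(
                outcome=outcome,
                family=family,
                coefficients={"intercept": intercept, **effects},
                shape=shape,
            )
        catalog[outcome] = eq
    return catalog


def default_biomarker_catalog() -> dict[str, BiomarkerEquation]:
    """SYNTHETIC progression catalog: slow mean-reverting upward drift."""

    def drift(name, prev_coef, annual_drift, anchor, sd, bounds):
        return BiomarkerEquation(
            biomarker=name,
            model_type="linear",
            coefficients={"intercept": anchor * (1 - prev_coef) + annual_drift, "prev": prev_coef},
            residual_sd=sd,
            bounds=bounds,
        )

    return {
        "hba1c": drift("hba1c", 0.98, 0.05, 7.3, 0.30, (4.0, 20.0)),
        "sbp": drift("sbp", 0.97, 0.50, 135.0, 8.0, (70.0, 250.0)),
        "ldl": drift("ldl", 0.97, 0.01, 2.2, 0.25, (0.3, 10.0)),
        "bmi": drift("bmi", 0.995, -0.02, 25.8, 0.50, (12.0, 60.0)),
    }


def default_utility_catalog() -> UtilityCatalog:
    """SYNTHETIC utilities: baseline for uncomplicated disease plus additive
    event-year/subsequent-year decrements."""
    return UtilityCatalog(
        baseline_utility=0.85,
        decrements={
            "myocardial_infarction": (0.055, 0.035),
            "ischaemic_heart_disease": (0.040, 0.020),
            "heart_failure": (0.080, 0.050),
            "cerebrovascular_disease": (0.100, 0.060),
            "peripheral_vascular_disease": (0.040, 0.020),
            "neuropathy": (0.035, 0.020),
            "lower_limb_amputation": (0.120, 0.080),
            "skin_ulcer": (0.030, 0.015),
            "chronic_kidney_disease": (0.050, 0.030),
            "retinopathy": (0.040, 0.030),
            "cataract": (0.020, 0.010),
            "haemodialysis": (0.150, 0.100),
        },
        excess_weight_decrement=0.006,
        bmi_threshold=25.0,
    )


def default_cost_catalog() -> CostCatalog:
    """SYNTHETIC unit costs (USD): event-year / subsequent-year pairs."""
    return CostCatalog(
        costs={
            "myocardial_infarction": (12000.0, 1500.0),
            "ischaemic_heart_disease": (6000.0, 900.0),
            "heart_failure": (9000.0, 1800.0),
            "cerebrovascular_disease": (14000.0, 2500.0),
            "peripheral_vascular_disease": (5000.0, 800.0),
            "neuropathy": (2500.0, 600.0),
            "lower_limb_amputation": (18000.0, 2200.0),
            "skin_ulcer": (3000.0, 700.0),
            "chronic_kidney_disease": (4000.0, 1200.0),
            "retinopathy": (3500.0, 900.0),
            "cataract": (2800.0, 300.0),
            "haemodialysis": (30000.0, 25000.0),
        },
        management_annual=450.0,
        inflation_factor=1.0,
        discount_rate=0.03,
    )


# ---------------------------------------------------------------------------
# YAML IO


def save_risk_catalog(catalog: Mapping[str, RiskEquation], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: v.to_dict() for k, v in catalog.items()}, fh, sort_keys=True)


def load_risk_catalog(path) -> dict[str, RiskEquation]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: RiskEquation.from_dict(v) for k, v in raw.items()}


def save_biomarker_catalog(catalog: Mapping[str, BiomarkerEquation], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: v.to_dict() for k, v in catalog.items()}, fh, sort_keys=True)


def load_biomarker_catalog(path) -> dict[str, BiomarkerEquation]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: BiomarkerEquation.from_dict(v) for k, v in raw.items()}


def save_utility_catalog(catalog: UtilityCatalog, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(catalog.to_dict(), fh, sort_keys=True)


def load_utility_catalog(path) -> UtilityCatalog:
    with open(path) as fh:
        return UtilityCatalog.from_dict(yaml.safe_load(fh))


def save_cost_catalog(catalog: CostCatalog, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(catalog.to_dict(), fh, sort_keys=True)


def load_cost_catalog(path) -> CostCatalog:
    with open(path) as fh:
        return CostCatalog.from_dict(yaml.safe_load(fh))
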