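"""Synthetic baseline cohorts and longitudinal event panels.

The generator emulates the marginal structure of a 2021 Hong Kong-style
type 2 diabetes population: configurable mean age/duration/BMI, sex split,
and — crucially — the marginal and joint "target failure" fractions for
HbA1c (>= 7%), blood pressure (>= 130/80) and LDL-cholesterol
(>= 2.6 mmol/L, >= 1.8 with prior cardiovascular disease). Failure flags are
always *derived from the generated biomarker values*, never sampled
independently, so tabulating target attainment on a generated cohort
reproduces the profile fractions up to binomial sampling error.

Mechanism: HbA1c, SBP and LDL share a latent equicorrelated Gaussian.
Marginal locations are calibrated analytically (HbA1c, LDL) or by 1-D root
finding (BP, whose failure rule involves the diastolic gap). The common
latent correlation is then calibrated by bisection against a fixed internal
Monte-Carlo sample so the joint any-of-three failure fraction matches the
profile. Physiological truncation is applied by clipping at bounds that do
not cross the targets, so the calibrated fractions survive truncation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .risk import COMPLICATIONS, RiskEquation, RiskModelError
from .risk import inverse_survival, linear_predictor, mortality_probability

BIOMARKERS = ("bmi", "hba1c", "sbp", "dbp", "ldl")

#: physiological clip bounds applied at generation
PHYSIO_BOUNDS = {
    "hba1c": (4.0, 20.0),
    "sbp": (70.0, 250.0),
    "dbp": (30.0, 150.0),
    "ldl": (0.3, 10.0),
    "bmi": (12.0, 60.0),
}

_CALIBRATION_SEED = 20211231  # fixed: calibration is a pure function of targets
_CALIBRATION_N = 120_000


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class CohortProfile:
    """Targets and dispersion parameters for synthetic cohort generation.

    Means for HbA1c/SBP/LDL are derived from the failure fractions given the
    standard deviations (set the ``*_mean`` fields to override — the failure
    fractions are then no longer guaranteed). Standard deviations and
    correlations are assumptions surfaced here, not published values.
    """

    n: int = 10_000
    seed: int = 0
    prop_female: float = 0.503
    age_mean: float = 68.2
    age_sd: float = 11.5
    duration_mean: float = 6.7
    duration_sd: float = 5.5
    bmi_mean: float = 25.8
    bmi_sd: float = 4.3
    hba1c_sd: float = 1.4
    sbp_sd: float = 18.0
    ldl_sd: float = 0.85
    fail_hba1c: float = 0.476
    fail_bp: float = 0.683
    fail_ldl: float = 0.189
    fail_any: float = 0.849
    prior_cvd_prev: float = 0.20
    smoker_prev: float = 0.15
    history_prev: float = 0.0
    dbp_gap_mean: float = 54.0
    dbp_gap_cv: float = 0.15
    bmi_corr: float = 0.10
    latent_corr: float | None = None  # None -> calibrated to fail_any
    hba1c_mean: float | None = None
    sbp_mean: float | None = None
    ldl_mean: float | None = None
    missing_rates: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        fracs = {
            "prop_female": self.prop_female,
            "fail_hba1c": self.fail_hba1c,
            "fail_bp": self.fail_bp,
            "fail_ldl": self.fail_ldl,
            "fail_any": self.fail_any,
            "prior_cvd_prev": self.prior_cvd_prev,
            "smoker_prev": self.smoker_prev,
            "history_prev": self.history_prev,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ProfileError(f"{name}={v} outside [0, 1]")
        for name in ("age_sd", "duration_sd", "bmi_sd", "hba1c_sd", "sbp_sd", "ldl_sd"):
            if getattr(self, name) < 0:
                raise ProfileError(f"{name} must be >= 0")
        if self.n < 0:
            raise ProfileError("n must be >= 0")
        marg_max = max(self.fail_hba1c, self.fail_bp, self.fail_ldl)
        if self.fail_any < marg_max - 1e-12:
            raise ProfileError(
                f"joint failure fraction {self.fail_any} below largest marginal {marg_max}"
            )
        marg_sum = self.fail_hba1c + self.fail_bp + self.fail_ldl
        if self.fail_any > min(1.0, marg_sum) + 1e-12:
            raise ProfileError(
                f"joint failure fraction {self.fail_any} exceeds sum of marginals"
            )
        for k, r in self.missing_rates.items():
            if k not in BIOMARKERS:
                raise ProfileError(f"unknown biomarker {k!r} in missing_rates")
            if not 0.0 <= r < 1.0:
                raise ProfileError(f"missing rate for {k} must be in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["missing_rates"] = dict(self.missing_rates)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortProfile":
        return cls(**d)


# ---------------------------------------------------------------------------
# calibration helpers


def _gap_params(profile: CohortProfile) -> tuple[float, float]:
    """Lognormal (mu, sigma) for the positive SBP-DBP gap."""
    sigma = float(np.sqrt(np.log1p(profile.dbp_gap_cv**2)))
    mu = float(np.log(profile.dbp_gap_mean) - 0.5 * sigma**2)
    return mu, sigma


def _bp_fail_prob(mean_sbp: float, profile: CohortProfile) -> float:
    """P(SBP >= 130 or DBP >= 80) with DBP = SBP - lognormal gap.

    Integrates the diastolic branch only over SBP in (80, 130), where the
    integrand is smooth; the systolic branch is a closed-form tail.
    """
    mu, sigma = _gap_params(profile)
    sd = profile.sbp_sd
    p_sys = float(sps.norm.sf((130.0 - mean_sbp) / sd))
    z_lo = max((80.0 - mean_sbp) / sd, -8.0)
    z_hi = min((130.0 - mean_sbp) / sd, 8.0)
    if z_hi <= z_lo:
        return p_sys
    nodes, weights = np.polynomial.legendre.leggauss(120)
    z = 0.5 * (z_hi - z_lo) * nodes + 0.5 * (z_hi + z_lo)
    w = 0.5 * (z_hi - z_lo) * weights * sps.norm.pdf(z)
    s = mean_sbp + sd * z
    p_dbp = sps.norm.cdf((np.log(np.maximum(s - 80.0, 1e-12)) - mu) / sigma)
    return p_sys + float(np.sum(w * p_dbp))


def _ldl_fail_prob(mean_ldl: float, profile: CohortProfile) -> float:
    p_cvd = profile.prior_cvd_prev
    sd = profile.ldl_sd
    return float(
        p_cvd * sps.norm.sf((1.8 - mean_ldl) / sd)
        + (1 - p_cvd) * sps.norm.sf((2.6 - mean_ldl) / sd)
    )


def _calibrate_means(profile: CohortProfile) -> dict[str, float]:
    means: dict[str, float] = {}
    means["hba1c"] = (
        profile.hba1c_mean
        if profile.hba1c_mean is not None
        else 7.0 - profile.hba1c_sd * sps.norm.isf(profile.fail_hba1c)
    )
    if profile.ldl_mean is not None:
        means["ldl"] = profile.ldl_mean
    else:
        means["ldl"] = float(
            optimize.brentq(
                lambda m: _ldl_fail_prob(m, profile) - profile.fail_ldl, 0.3, 6.0
            )
        )
    if profile.sbp_mean is not None:
        means["sbp"] = profile.sbp_mean
    else:
        means["sbp"] = float(
            optimize.brentq(
                lambda m: _bp_fail_prob(m, profile) - profile.fail_bp, 90.0, 200.0
            )
        )
    return means


def _fail_flags(
    hba1c: np.ndarray,
    sbp: np.ndarray,
    dbp: np.ndarray,
    ldl: np.ndarray,
    prior_cvd: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    fail_h = hba1c >= 7.0
    fail_b = (sbp >= 130.0) | (dbp >= 80.0)
    thresh = np.where(prior_cvd, 1.8, 2.6)
    fail_l = ldl >= thresh
    return fail_h, fail_b, fail_l


def _calibrate_latent_corr(profile: CohortProfile, means: dict[str, float]) -> float:
    """Bisection on the common latent correlation so the any-of-three failure
    fraction matches ``fail_any`` on a fixed internal Monte-Carlo sample."""
    rng = np.random.default_rng(_CALIBRATION_SEED)
    m = _CALIBRATION_N
    z = rng.standard_normal((m, 3))
    gap_z = rng.standard_normal(m)
    cvd = rng.random(m) < profile.prior_cvd_prev
    mu_g, sig_g = _gap_params(profile)
    gap = np.exp(mu_g + sig_g * gap_z)

    def any_fail(rho: float) -> float:
        R = np.full((3, 3), rho)
        np.fill_diagonal(R, 1.0)
        L = np.linalg.cholesky(R)
        zc = z @ L.T
        hba1c = means["hba1c"] + profile.hba1c_sd * zc[:, 0]
        sbp = means["sbp"] + profile.sbp_sd * zc[:, 1]
        ldl = means["ldl"] + profile.ldl_sd * zc[:, 2]
        dbp = sbp - gap
        fh, fb, fl = _fail_flags(hba1c, sbp, dbp, ldl, cvd)
        return float(np.mean(fh | fb | fl))

    lo, hi = -0.45, 0.95  # keep the equicorrelation matrix positive definite
    f_lo, f_hi = any_fail(lo), any_fail(hi)
    target = profile.fail_any
    # any-fail decreases as rho increases
    if not (f_hi - 5e-3 <= target <= f_lo + 5e-3):
        raise ProfileError(
            f"fail_any={target} unreachable with latent correlation in "
            f"[{lo}, {hi}] (achievable range ~[{f_hi:.3f}, {f_lo:.3f}])"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if any_fail(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# generation


def generate_cohort(profile: CohortProfile) -> pd.DataFrame:
    """Generate a baseline cohort as one row per person.

    Deterministic given ``profile.seed``. Realized means and target-failure
    fractions converge to the profile values as ``n`` grows.
    """
    profile.validate()
    n = profile.n
    cols = _column_dictionary()
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in cols.items()})

    means = _calibrate_means(profile)
    rho = (
        profile.latent_corr
        if profile.latent_corr is not None
        else _calibrate_latent_corr(profile, means)
    )

    rng = np.random.default_rng(profile.seed)
    z = rng.standard_normal((n, 3))
    R = np.full((3, 3), rho)
    np.fill_diagonal(R, 1.0)
    zc = z @ np.linalg.cholesky(R).T

    hba1c = means["hba1c"] + profile.hba1c_sd * zc[:, 0]
    sbp = means["sbp"] + profile.sbp_sd * zc[:, 1]
    ldl = means["ldl"] + profile.ldl_sd * zc[:, 2]

    mu_g, sig_g = _gap_params(profile)
    gap = np.exp(mu_g + sig_g * rng.standard_normal(n))
    dbp = sbp - gap

    # BMI modestly correlated with the HbA1c latent
    zb = profile.bmi_corr * zc[:, 0] + np.sqrt(1 - profile.bmi_corr**2) * rng.standard_normal(n)
    bmi = profile.bmi_mean + profile.bmi_sd * zb

    for name, arr in (("hba1c", hba1c), ("sbp", sbp), ("dbp", dbp), ("ldl", ldl), ("bmi", bmi)):
        lo, hi = PHYSIO_BOUNDS[name]
        np.clip(arr, lo, hi, out=arr)
    np.minimum(dbp, sbp - 5.0, out=dbp)  # diastolic strictly below systolic

    age = np.clip(rng.normal(profile.age_mean, profile.age_sd, n), 30.0, 100.0)
    # gamma keeps duration >= 0 with the requested mean/sd
    if profile.duration_sd > 0:
        k = (profile.duration_mean / profile.duration_sd) ** 2
        duration = rng.gamma(k, profile.duration_mean / k, n)
    else:
        duration = np.full(n, profile.duration_mean)
    duration = np.minimum(duration, age - 20.0)

    female = rng.random(n) < profile.prop_female
    smoker = rng.random(n) < profile.smoker_prev
    prior_cvd = rng.random(n) < profile.prior_cvd_prev

    df = pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(n)],
            "age": age,
            "sex": np.where(female, "female", "male"),
            "diabetes_duration": duration,
            "bmi": bmi,
            "hba1c": hba1c,
            "sbp": sbp,
            "dbp": dbp,
            "ldl": ldl,
            "smoker": smoker,
            "prior_cvd": prior_cvd,
        }
    )
    for comp in COMPLICATIONS:
        df[f"hist_{comp}"] = (
            rng.random(n) < profile.history_prev if profile.history_prev > 0 else False
        )
    for b in BIOMARKERS:
        rate = float(profile.missing_rates.get(b, 0.0))
        mask = rng.random(n) < rate if rate > 0 else np.zeros(n, dtype=bool)
        df[f"{b}_missing"] = mask
        if mask.any():
            df.loc[mask, b] = np.nan
    validate_cohort(df, allow_missing=True)
    return df


def _column_dictionary() -> dict[str, str]:
    cols: dict[str, str] = {
        "person_id": "object",
        "age": "float64",
        "sex": "object",
        "diabetes_duration": "float64",
        "bmi": "float64",
        "hba1c": "float64",
        "sbp": "float64",
        "dbp": "float64",
        "ldl": "float64",
        "smoker": "bool",
        "prior_cvd": "bool",
    }
    for comp in COMPLICATIONS:
        cols[f"hist_{comp}"] = "bool"
    for b in BIOMARKERS:
        cols[f"{b}_missing"] = "bool"
    return cols


def validate_cohort(df: pd.DataFrame, allow_missing: bool = False) -> None:
    """Check baseline invariants; raises ``ProfileError`` on violation."""
    if df["person_id"].duplicated().any():
        raise ProfileError("duplicate person_id in cohort")
    if (df["age"] <= 0).any():
        raise ProfileError("age must be > 0")
    if (df["diabetes_duration"] < 0).any() or (df["diabetes_duration"] > df["age"]).any():
        raise ProfileError("diabetes_duration must be in [0, age]")
    for b in BIOMARKERS:
        v = df[b]
        bad = v.notna() & (v <= 0)
        if bad.any():
            raise ProfileError(f"{b} must be strictly positive when observed")
        if not allow_missing and v.isna().any():
            raise ProfileError(f"{b} has missing values; impute first")
    both = df["sbp"].notna() & df["dbp"].notna()
    if (df.loc[both, "dbp"] >= df.loc[both, "sbp"]).any():
        raise ProfileError("dbp must be below sbp")


# ---------------------------------------------------------------------------
# imputation


def impute_missing(cohort: pd.DataFrame) -> pd.DataFrame:
    """Fill missing biomarkers with the sex-specific mean of observed values.

    Observed values are untouched and the ``*_missing`` audit masks are
    preserved, which also makes the operation idempotent. An empty
    (sex, biomarker) stratum with something to fill is a hard error.
    """
    out = cohort.copy()
    for b in BIOMARKERS:
        if not out[b].isna().any():
            continue
        for sex, grp in out.groupby("sex", observed=True):
            idx = grp.index[grp[b].isna()]
            if len(idx) == 0:
                continue
            observed = grp[b].dropna()
            if observed.empty:
                raise ProfileError(
                    f"cannot impute {b} for sex={sex}: no observed values in stratum"
                )
            out.loc[idx, b] = observed.mean()
    return out


# ---------------------------------------------------------------------------
# event-panel fixtures


def generate_event_panel(
    cohort: pd.DataFrame,
    equation: RiskEquation,
    horizon: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate a right-censored time-to-event panel from a known equation.

    Event times are drawn by inverse-CDF sampling (``T = S^{-1}(U)``) with
    administrative censoring at ``horizon``. For the logistic (annual
    Bernoulli) family the panel is person-year rows with a 0/1 event column.
    Primarily a fixture generator for fitting tests.
    """
    if horizon < 1:
        raise RiskModelError("horizon must be >= 1")
    rng = np.random.default_rng(seed)
    cov = cohort_covariates(cohort)

    if equation.family == "logistic":
        p = np.asarray(mortality_probability(equation, cov), dtype=float)
        p = np.broadcast_to(p, (len(cohort),))
        rows = []
        alive = np.ones(len(cohort), dtype=bool)
        for year in range(1, int(horizon) + 1):
            u = rng.random(len(cohort))
            event = alive & (u < p)
            for i in np.flatnonzero(alive):
                rows.append((cohort["person_id"].iloc[i], year, bool(event[i])))
            alive &= ~event
        panel = pd.DataFrame(rows, columns=["person_id", "year", "event"])
        panel["event"] = panel["event"].astype(int)
        return panel.merge(_covariate_frame(cohort), on="person_id")

    lp = linear_predictor(equation, cov)
    u = rng.random(len(cohort))
    with np.errstate(over="ignore"):
        T = np.asarray(inverse_survival(equation, lp, u), dtype=float)
    T = np.broadcast_to(T, (len(cohort),))
    time = np.minimum(T, float(horizon))
    event = (T <= horizon).astype(int)
    panel = _covariate_frame(cohort)
    panel["time"] = np.maximum(time, 1e-9)
    panel["event"] = event
    return panel


def cohort_covariates(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    """Named covariate arrays for risk-equation evaluation at baseline."""
    cov = {
        "age": cohort["age"].to_numpy(dtype=float),
        "female": (cohort["sex"] == "female").to_numpy(dtype=float),
        "duration": cohort["diabetes_duration"].to_numpy(dtype=float),
        "bmi": cohort["bmi"].to_numpy(dtype=float),
        "hba1c": cohort["hba1c"].to_numpy(dtype=float),
        "sbp": cohort["sbp"].to_numpy(dtype=float),
        "ldl": cohort["ldl"].to_numpy(dtype=float),
        "smoker": cohort["smoker"].to_numpy(dtype=float),
        "prior_cvd": cohort["prior_cvd"].to_numpy(dtype=float),
    }
    for comp in COMPLICATIONS:
        col = f"hist_{comp}"
        if col in cohort.columns:
            cov[f"prior_{comp}"] = cohort[col].to_numpy(dtype=float)
    return cov


def _covariate_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    d = {"person_id": cohort["person_id"].to_numpy()}
    d.update(cohort_covariates(cohort))
    return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# delimited-text IO


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c, t in _column_dictionary().items():
        if c in df.columns and t == "bool":
            df[c] = df[c].astype(bool)
    return df
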