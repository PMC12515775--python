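"""Risk-factor targets, baseline attainment classification, and control
scenarios (immediate, ramped, partial coverage) imposed on biomarker paths.

Targets are strict inequalities: HbA1c < 7.0%, SBP < 130 and DBP < 80 mmHg,
LDL-cholesterol < 2.6 mmol/L (< 1.8 mmol/L with prior cardiovascular
disease). A value sitting exactly on the threshold fails, matching the
">= threshold did not meet target" tabulation convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

FACTORS = ("hba1c", "bp", "ldl")

HBA1C_TARGET = 7.0
SBP_TARGET = 130.0
DBP_TARGET = 80.0
LDL_TARGET = 2.6
LDL_TARGET_CVD = 1.8


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class AttainmentValues:
    """Concrete values a controlled biomarker is set to when it would fail.

    The targets are strict inequalities, so "meeting the target" needs a
    just-inside level; these defaults sit slightly below each threshold and
    are configuration, not published values.
    """

    hba1c: float = 6.9
    sbp: float = 125.0
    dbp: float = 75.0
    ldl: float = 2.5
    ldl_cvd: float = 1.7


@dataclass(frozen=True)
class Scenario:
    name: str
    controlled_factors: frozenset = frozenset()
    time_to_target: int = 1
    coverage: float = 1.0
    horizon: int = 10
    attainment: AttainmentValues = field(default_factory=AttainmentValues)

    def __post_init__(self):
        unknown = set(self.controlled_factors) - set(FACTORS)
        if unknown:
            raise ScenarioError(f"unknown controlled factor(s) {sorted(unknown)}")
        if not 0.0 < self.coverage <= 1.0:
            raise ScenarioError("coverage must be in (0, 1]")
        if self.time_to_target < 1:
            raise ScenarioError("time_to_target must be >= 1")
        if self.horizon < self.time_to_target:
            raise ScenarioError("horizon must be >= time_to_target")
        object.__setattr__(self, "controlled_factors", frozenset(self.controlled_factors))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "controlled_factors": sorted(self.controlled_factors),
            "time_to_target": self.time_to_target,
            "coverage": self.coverage,
            "horizon": self.horizon,
            "attainment": dataclasses.asdict(self.attainment),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        d = dict(d)
        d["controlled_factors"] = frozenset(d.get("controlled_factors", ()))
        if "attainment" in d:
            d["attainment"] = AttainmentValues(**d["attainment"])
        return cls(**d)


def preset_scenarios(horizon: int = 10) -> dict[str, Scenario]:
    """The four analysis scenarios plus the natural-progression comparator."""
    return {
        "natural": Scenario("natural", frozenset(), horizon=horizon),
        "hba1c_only": Scenario("hba1c_only", frozenset({"hba1c"}), horizon=horizon),
        "bp_only": Scenario("bp_only", frozenset({"bp"}), horizon=horizon),
        "ldl_only": Scenario("ldl_only", frozenset({"ldl"}), horizon=horizon),
        "combined": Scenario("combined", frozenset({"hba1c", "bp", "ldl"}), horizon=horizon),
    }


# ---------------------------------------------------------------------------
# attainment classification


def target_attainment(patients: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Flags ``hba1c_met, bp_met, ldl_met, all_met`` under strict-inequality
    targets. Requires imputed biomarkers — missing values are an error."""
    single = isinstance(patients, pd.Series)
    df = patients.to_frame().T if single else patients
    for col in ("hba1c", "sbp", "dbp", "ldl"):
        if df[col].isna().any():
            raise ScenarioError(f"missing {col} values: impute before classification")
    hba1c_met = df["hba1c"] < HBA1C_TARGET
    bp_met = (df["sbp"] < SBP_TARGET) & (df["dbp"] < DBP_TARGET)
    ldl_thresh = np.where(df["prior_cvd"].astype(bool), LDL_TARGET_CVD, LDL_TARGET)
    ldl_met = df["ldl"] < ldl_thresh
    out = pd.DataFrame(
        {
            "hba1c_met": hba1c_met,
            "bp_met": bp_met,
            "ldl_met": ldl_met,
            "all_met": hba1c_met & bp_met & ldl_met,
        },
        index=df.index,
    )
    return out.iloc[0] if single else out


def fails_scenario_targets(cohort: pd.DataFrame, scenario: Scenario) -> pd.Series:
    """True for persons not meeting *all* of the scenario's controlled
    factors at baseline — the per-person outcome denominator."""
    if not scenario.controlled_factors:
        return pd.Series(False, index=cohort.index)
    met = target_attainment(cohort)
    ok = pd.Series(True, index=cohort.index)
    for f in scenario.controlled_factors:
        ok &= met[f"{f}_met"]
    return ~ok


# ---------------------------------------------------------------------------
# control application


def _ramp(baseline, attain, cycle, k):
    frac = min(cycle, k) / k
    return baseline + (attain - baseline) * frac


def apply_control(
    biomarkers: Mapping[str, np.ndarray],
    baseline_biomarkers: Mapping[str, np.ndarray],
    scenario: Scenario,
    cycle: int,
    prior_cvd: np.ndarray,
    covered: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Impose the scenario on natural-path biomarker values at ``cycle``.

    For each controlled factor: covered persons whose natural-path value
    fails the target are moved to the attainment value (immediately when
    ``time_to_target`` is 1, else linearly from baseline, reaching the
    attainment value at cycle ``time_to_target``). Values already meeting
    the target, uncontrolled factors and uncovered persons follow the
    natural path unchanged.
    """
    if cycle < 1:
        raise ScenarioError("cycle must be >= 1")
    out = {k: np.array(v, dtype=float, copy=True) for k, v in biomarkers.items()}
    if not scenario.controlled_factors:
        return out
    n = len(np.asarray(prior_cvd))
    covered = np.ones(n, dtype=bool) if covered is None else np.asarray(covered, dtype=bool)
    att = scenario.attainment
    k = scenario.time_to_target

    if "hba1c" in scenario.controlled_factors:
        fail = covered & (out["hba1c"] >= HBA1C_TARGET)
        out["hba1c"][fail] = _ramp(
            np.asarray(baseline_biomarkers["hba1c"], dtype=float)[fail], att.hba1c, cycle, k
        )
    if "bp" in scenario.controlled_factors:
        fail = covered & ((out["sbp"] >= SBP_TARGET) | (out["dbp"] >= DBP_TARGET))
        out["sbp"][fail] = _ramp(
            np.asarray(baseline_biomarkers["sbp"], dtype=float)[fail], att.sbp, cycle, k
        )
        out["dbp"][fail] = _ramp(
            np.asarray(baseline_biomarkers["dbp"], dtype=float)[fail], att.dbp, cycle, k
        )
    if "ldl" in scenario.controlled_factors:
        thresh = np.where(np.asarray(prior_cvd, dtype=bool), LDL_TARGET_CVD, LDL_TARGET)
        attain = np.where(np.asarray(prior_cvd, dtype=bool), att.ldl_cvd, att.ldl)
        fail = covered & (out["ldl"] >= thresh)
        out["ldl"][fail] = _ramp(
            np.asarray(baseline_biomarkers["ldl"], dtype=float)[fail], attain[fail], cycle, k
        )
    return out


def coverage_mask(cohort: pd.DataFrame, coverage: float, seed: int) -> np.ndarray:
    """Simple random sample without replacement flagging
    ``round(coverage * n)`` persons as controlled; reproducible given seed."""
    if not 0.0 < coverage <= 1.0:
        raise ScenarioError("coverage must be in (0, 1]")
    n = len(cohort)
    m = int(np.floor(coverage * n + 0.5))
    mask = np.zeros(n, dtype=bool)
    if m > 0:
        idx = np.random.default_rng(seed).choice(n, size=m, replace=False)
        mask[idx] = True
    return mask
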