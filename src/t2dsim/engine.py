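"""Annual-cycle patient-level Monte Carlo.

Composes the risk equations, biomarker progression and a control scenario
into a per-person per-cycle run ledger. Within each cycle the fixed order is:

1. mortality draw (logistic annual probability);
2. for survivors, one independent draw per not-yet-occurred complication
   from its annual conditional probability at model time ``t = cycle - 1``;
3. biomarker progression for the next cycle, scenario-adjusted;
4. attained age and diabetes duration advance with the cycle index.

Death contributes a half year of exposure in the death cycle (no half-cycle
correction elsewhere). Random numbers are pre-drawn per person, indexed by
(cycle, outcome slot), and depend only on ``(master_seed, person_id)`` — so
the same person sees the same draws under every scenario (common random
numbers) and results are independent of cohort ordering.

Ledger columns record the state that generated the cycle's draws
(``alive_frac``, incident ``inc_*`` and prevalent ``prev_*`` complication
flags, baseline-history included) and the *end-of-cycle* biomarker values
(the values attained during the cycle under the scenario).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import config_hash, person_uniform_block
from .biomarkers import PROGRESSED, BiomarkerEquation, progress_biomarkers
from .cohort import validate_cohort
from .risk import (
    COMPLICATIONS,
    OUTCOMES,
    RiskEquation,
    annual_event_probability,
    mortality_probability,
)
from .scenarios import Scenario, apply_control, coverage_mask

#: outcomes whose occurrence sets the dynamic prior-CVD flag
CVD_OUTCOMES = (
    "myocardial_infarction",
    "ischaemic_heart_disease",
    "heart_failure",
    "cerebrovascular_disease",
    "peripheral_vascular_disease",
)

_N_SLOTS = 1 + len(COMPLICATIONS) + len(PROGRESSED)  # mortality, events, residuals


class SimulationError(ValueError):
    pass


def _check_equations(equations: dict[str, RiskEquation]) -> None:
    missing = [o for o in OUTCOMES if o not in equations]
    if missing:
        raise SimulationError(f"missing risk equation(s) for {missing}")
    if equations["mortality"].family != "logistic":
        raise SimulationError("mortality equation must be logistic")
    for o in COMPLICATIONS:
        if equations[o].family == "logistic":
            raise SimulationError(f"{o}: logistic family is reserved for mortality")


def simulate_cohort(
    cohort: pd.DataFrame,
    equations: dict[str, RiskEquation],
    biomarker_catalog: dict[str, BiomarkerEquation],
    scenario: Scenario,
    horizon: int,
    master_seed: int,
    rng_policy: str = "mean",
) -> pd.DataFrame:
    """Simulate every person and return the run ledger (tidy DataFrame).

    Rows exist for each person for cycles ``1..death_cycle`` (or ``horizon``).
    Metadata (seed, scenario, horizon, catalog hash) is attached in
    ``ledger.attrs``.
    """
    if cohort["person_id"].duplicated().any():
        raise SimulationError("duplicate person_id in cohort")
    validate_cohort(cohort, allow_missing=False)
    _check_equations(equations)
    if horizon < 1:
        raise SimulationError("horizon must be >= 1")

    n = len(cohort)
    ids = cohort["person_id"].to_numpy()

    # pre-drawn uniforms: CRN across scenarios by construction
    U = np.empty((n, horizon, _N_SLOTS))
    for i, pid in enumerate(ids):
        U[i] = person_uniform_block(master_seed, pid, horizon, _N_SLOTS)

    covered = coverage_mask(cohort, scenario.coverage, seed=master_seed ^ 0x5EED)

    age0 = cohort["age"].to_numpy(dtype=float)
    dur0 = cohort["diabetes_duration"].to_numpy(dtype=float)
    female = (cohort["sex"] == "female").to_numpy(dtype=float)
    smoker = cohort["smoker"].to_numpy(dtype=float)
    cvd0 = cohort["prior_cvd"].to_numpy(dtype=bool)

    bio = {b: cohort[b].to_numpy(dtype=float) for b in ("bmi", "hba1c", "sbp", "dbp", "ldl")}
    baseline_bio = {k: v.copy() for k, v in bio.items()}

    had = {c: cohort[f"hist_{c}"].to_numpy(dtype=bool).copy() for c in COMPLICATIONS}
    onset = {c: np.where(had[c], 0, -1) for c in COMPLICATIONS}  # cycle of onset, -1 = never
    prior_cvd = cvd0.copy()

    alive = np.ones(n, dtype=bool)
    death_cycle = np.full(n, -1)

    records: list[dict[str, np.ndarray]] = []
    bio_rng = (
        None
        if rng_policy == "mean"
        else np.random.default_rng(np.random.SeedSequence([master_seed, 0xB10]))
    )

    for cycle in range(1, horizon + 1):
        at_risk = alive.copy()
        if not at_risk.any():
            break
        t = float(cycle - 1)
        cov = {
            "age": age0 + t,
            "female": female,
            "duration": dur0 + t,
            "bmi": bio["bmi"],
            "hba1c": bio["hba1c"],
            "sbp": bio["sbp"],
            "ldl": bio["ldl"],
            "smoker": smoker,
            "prior_cvd": prior_cvd.astype(float),
        }
        for c in COMPLICATIONS:
            cov[f"prior_{c}"] = had[c].astype(float)

        # (1) mortality
        p_death = np.asarray(mortality_probability(equations["mortality"], cov), dtype=float)
        died = at_risk & (U[:, cycle - 1, 0] < p_death)
        death_cycle[died] = cycle
        survivors = at_risk & ~died

        # (2) complications for survivors, independent draws, entering-state flags
        incident: dict[str, np.ndarray] = {}
        for j, c in enumerate(COMPLICATIONS):
            p = np.asarray(
                annual_event_probability(equations[c], cov, t), dtype=float
            )
            ev = survivors & ~had[c] & (U[:, cycle - 1, 1 + j] < p)
            incident[c] = ev
        prevalent = {c: at_risk & had[c] for c in COMPLICATIONS}
        for c in COMPLICATIONS:
            onset[c][incident[c]] = cycle
            had[c] |= incident[c]
        prior_cvd |= np.any([incident[c] for c in CVD_OUTCOMES], axis=0)

        # (3) biomarker progression, scenario-adjusted
        state = {
            "bmi": bio["bmi"],
            "hba1c": bio["hba1c"],
            "sbp": bio["sbp"],
            "ldl": bio["ldl"],
            "age": age0 + t,
            "female": female,
            "duration": dur0 + t,
            "year": np.full(n, float(cycle)),
        }
        natural = progress_biomarkers(
            state, biomarker_catalog, rng=bio_rng if bio_rng is not None else "mean"
        )
        natural["dbp"] = bio["dbp"]  # diastolic held at baseline on the natural path
        controlled = apply_control(
            natural, baseline_bio, scenario, cycle, cvd0, covered=covered
        )
        for k in bio:
            bio[k] = np.where(at_risk, controlled[k], bio[k])

        rec = {
            "person_id": ids[at_risk],
            "cycle": np.full(at_risk.sum(), cycle),
            "female": female[at_risk].astype(bool),
            "alive_frac": np.where(died[at_risk], 0.5, 1.0),
            "died": died[at_risk],
        }
        for b in ("bmi", "hba1c", "sbp", "dbp", "ldl"):
            rec[b] = bio[b][at_risk]
        for c in COMPLICATIONS:
            rec[f"inc_{c}"] = incident[c][at_risk]
            rec[f"prev_{c}"] = prevalent[c][at_risk]
        records.append(rec)

        alive = survivors

    ledger = pd.concat([pd.DataFrame(r) for r in records], ignore_index=True)
    ledger.attrs.update(
        {
            "master_seed": int(master_seed),
            "scenario": scenario.to_dict(),
            "horizon": int(horizon),
            "n_persons": int(n),
            "rng_policy": rng_policy,
            "catalog_hash": config_hash(
                {
                    "risk": {k: v.to_dict() for k, v in sorted(equations.items())},
                    "biomarkers": {k: v.to_dict() for k, v in sorted(biomarker_catalog.items())},
                }
            ),
        }
    )
    return ledger


def simulate_patient(
    record: pd.Series,
    equations: dict[str, RiskEquation],
    biomarker_catalog: dict[str, BiomarkerEquation],
    scenario: Scenario,
    horizon: int,
    master_seed: int,
) -> pd.DataFrame:
    """Ledger rows for a single person (wrapper over :func:`simulate_cohort`,
    so a person's trajectory is identical inside any cohort)."""
    cohort = record.to_frame().T
    cohort = cohort.astype({c: bool for c in cohort.columns if c.startswith(("hist_", "smoker", "prior_cvd"))})
    for c in ("age", "diabetes_duration", "bmi", "hba1c", "sbp", "dbp", "ldl"):
        cohort[c] = cohort[c].astype(float)
    for b in ("bmi", "hba1c", "sbp", "dbp", "ldl"):
        col = f"{b}_missing"
        if col not in cohort.columns:
            cohort[col] = False
    return simulate_cohort(cohort, equations, biomarker_catalog, scenario, horizon, master_seed)
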