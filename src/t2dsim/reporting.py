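"""Pipeline orchestration and rendering of baseline/outcome tables.

Number formatting mirrors the published presentation: per-person QALYs and
life-years to 4 decimal places, per-person costs to 2, percentages to 1,
population sums to integers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from ._utils import config_hash, round_half_up
from .catalogs import (
    default_biomarker_catalog,
    default_cost_catalog,
    default_risk_catalog,
    default_utility_catalog,
    load_biomarker_catalog,
    load_cost_catalog,
    load_risk_catalog,
    load_utility_catalog,
)
from .cohort import CohortProfile, generate_cohort, impute_missing, read_cohort
from .economics import aggregate_scenario_delta, composition_by_complication
from .engine import simulate_cohort
from .scenarios import Scenario, preset_scenarios, target_attainment

logger = logging.getLogger("t2dsim")

TABLE1_ROWS = ("hba1c", "bp", "ldl", "combined")


def format_percentage(x: float) -> float:
    return round_half_up(x, 1)


def format_per_person_qaly(x: float) -> float:
    return round_half_up(x, 4)


def format_per_person_cost(x: float) -> float:
    return round_half_up(x, 2)


def table1_percentages(counts: Mapping[str, int], total: int) -> dict[str, float]:
    """Percentages (1 dp) of the cohort failing each target, from counts.

    ``counts`` maps table rows (``hba1c``, ``bp``, ``ldl``, ``combined``) to
    the number of people not meeting that target; ``total`` is the cohort
    size.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    return {k: format_percentage(100.0 * v / total) for k, v in counts.items()}


def render_table1(cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of people *not* meeting each target, by sex.

    Percentages are relative to the full cohort so male + female percentages
    sum to the overall row value (to rounding). An empty cohort renders zero
    counts with null percentages.
    """
    rows = []
    if len(cohort) == 0:
        for r in TABLE1_ROWS:
            rows.append(
                {"factor": r, "n_total": 0, "pct_total": None, "n_male": 0,
                 "pct_male": None, "n_female": 0, "pct_female": None}
            )
        return pd.DataFrame(rows).set_index("factor")
    met = target_attainment(cohort)
    female = cohort["sex"].eq("female").to_numpy()
    total = len(cohort)
    fails = {
        "hba1c": ~met["hba1c_met"].to_numpy(),
        "bp": ~met["bp_met"].to_numpy(),
        "ldl": ~met["ldl_met"].to_numpy(),
        "combined": ~met["all_met"].to_numpy(),
    }
    for r in TABLE1_ROWS:
        f = fails[r]
        rows.append(
            {
                "factor": r,
                "n_total": int(f.sum()),
                "pct_total": format_percentage(100.0 * f.sum() / total),
                "n_male": int((f & ~female).sum()),
                "pct_male": format_percentage(100.0 * (f & ~female).sum() / total),
                "n_female": int((f & female).sum()),
                "pct_female": format_percentage(100.0 * (f & female).sum() / total),
            }
        )
    return pd.DataFrame(rows).set_index("factor")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    output_dir: str = "t2dsim_output"
    cohort_path: str | None = None  # CSV; None -> synthesise from profile
    profile: CohortProfile = field(default_factory=lambda: CohortProfile(n=5000, seed=0))
    risk_catalog_path: str | None = None
    biomarker_catalog_path: str | None = None
    utility_catalog_path: str | None = None
    cost_catalog_path: str | None = None
    scenarios: tuple[str, ...] = ("hba1c_only", "bp_only", "ldl_only", "combined")
    horizon: int = 10
    readout_horizons: tuple[int, ...] = (5, 10)
    master_seed: int = 12345

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["profile"] = self.profile.to_dict()
        return d


def _load_inputs(config: RunConfig):
    equations = (
        load_risk_catalog(config.risk_catalog_path)
        if config.risk_catalog_path
        else default_risk_catalog()
    )
    biomarker_catalog = (
        load_biomarker_catalog(config.biomarker_catalog_path)
        if config.biomarker_catalog_path
        else default_biomarker_catalog()
    )
    ucat = (
        load_utility_catalog(config.utility_catalog_path)
        if config.utility_catalog_path
        else default_utility_catalog()
    )
    ccat = (
        load_cost_catalog(config.cost_catalog_path)
        if config.cost_catalog_path
        else default_cost_catalog()
    )
    return equations, biomarker_catalog, ucat, ccat


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Synthesise/load -> impute -> classify -> simulate with common random
    numbers -> economics -> write tables. Idempotent given seeds; outputs
    embed the config hash."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.to_dict())
    outputs: dict[str, Path] = {}
    stage = "setup"

    def _stage(name):
        nonlocal stage
        stage = name
        logger.info("stage %s", name)

    try:
        _stage("cohort")
        if config.cohort_path:
            cohort = read_cohort(config.cohort_path)
        else:
            cohort = generate_cohort(config.profile)
        cohort = impute_missing(cohort)

        _stage("table1")
        t1 = render_table1(cohort)
        p = out / "table1.csv"
        t1.to_csv(p)
        outputs["table1"] = p

        _stage("simulate")
        equations, biomarker_catalog, ucat, ccat = _load_inputs(config)
        presets = preset_scenarios(horizon=config.horizon)
        natural = presets["natural"]
        base_ledger = simulate_cohort(
            cohort, equations, biomarker_catalog, natural,
            config.horizon, config.master_seed,
        )
        pop_tables = []
        comp_tables = []
        for name in config.scenarios:
            scn = presets[name] if name in presets else Scenario.from_dict(json.loads(name))
            ledger = simulate_cohort(
                cohort, equations, biomarker_catalog, scn,
                config.horizon, config.master_seed,
            )
            _stage(f"economics:{name}")
            delta = aggregate_scenario_delta(
                base_ledger, ledger, cohort, scn, ucat, ccat,
                horizons=config.readout_horizons,
            )
            pop_tables.append(delta)
            comp = composition_by_complication(base_ledger, ledger, ucat, ccat)
            comp["scenario"] = name
            comp_tables.append(comp.reset_index())

        _stage("report")
        outcomes = pd.concat(pop_tables, ignore_index=True)
        for c in ("qaly_gain", "ly_gain", "cost_saving"):
            outcomes[c] = outcomes[c].round(6)
            outcomes[f"{c}_per_person"] = outcomes[f"{c}_per_person"].map(
                lambda x: x if pd.isna(x) else (
                    format_per_person_cost(x) if c == "cost_saving" else format_per_person_qaly(x)
                )
            )
        p = out / "population_outcomes.csv"
        outcomes.to_csv(p, index=False)
        outputs["population_outcomes"] = p

        comp_all = pd.concat(comp_tables, ignore_index=True)
        p = out / "composition.csv"
        comp_all.to_csv(p, index=False)
        outputs["composition"] = p

        meta = {
            "config": config.to_dict(),
            "config_hash": chash,
            "n_persons": int(len(cohort)),
            "catalog_hash": base_ledger.attrs["catalog_hash"],
            "master_seed": config.master_seed,
        }
        p = out / "metadata.json"
        p.write_text(json.dumps(meta, indent=2, default=str))
        outputs["metadata"] = p
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return outputs
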