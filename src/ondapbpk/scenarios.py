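"""Study scenarios: trial designs wired to populations and regimens.

Each verification study contributes a dosing regimen and demographics for
its virtual population. Studies that do not report weights (and one that
reports no ages) fall back to an aggregate healthy-adult envelope built
from the union of the reported healthy ranges; the cirrhosis study reports
no weights at all, so cirrhotic subjects sample healthy-adult weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drug import DrugParameters
from .engine import DosingRegimen
from .population import PopulationResult, PopulationSpec, \
    generate_population, simulate_population

__all__ = [
    "StudyScenario",
    "AGGREGATE_HEALTHY_AGE",
    "AGGREGATE_HEALTHY_WEIGHT",
    "PRINTED_MEDIAN_AUC",
    "load_scenarios",
    "aggregate_healthy_spec",
    "disease_spec",
    "run_scenario",
]

#: Healthy-adult fallback envelope (union of the reported healthy ranges).
AGGREGATE_HEALTHY_AGE = (18.0, 43.0)
AGGREGATE_HEALTHY_WEIGHT = (57.5, 90.5)

#: Published median AUC0-inf (ng·h/mL) per scenario from the dose-adjustment
#: analysis; used as fixture inputs for exposure-increase arithmetic and as
#: the healthy targets for dose optimization.
PRINTED_MEDIAN_AUC = {
    ("iv", "healthy"): 312.4,
    ("iv", "A"): 476.46,
    ("iv", "B"): 801.90,
    ("iv", "C"): 1208.94,
    ("oral", "healthy"): 260.1,
    ("oral", "A"): 444.61,
    ("oral", "B"): 773.84,
    ("oral", "C"): 1114.82,
}


@dataclass(frozen=True)
class StudyScenario:
    """One verification study: id, regimen and population recipe."""

    study_id: str
    route: str                 # "iv" | "oral"
    regimen: DosingRegimen
    population: PopulationSpec
    cp_class: str | None = None


def _float(v):
    try:
        f = float(v)
        return None if math.isnan(f) else f
    except (TypeError, ValueError):
        return None


def load_scenarios(n: int = 1000, seed: int = 0,
                   cv: dict | None = None) -> list[StudyScenario]:
    """Build every Table-style study scenario from the packaged designs.

    The disease row expands into one scenario per Child-Pugh class (the
    source study stratified its cirrhotic cohort into the three classes).
    Each scenario gets an independent child seed.
    """
    from .synthetic import load_fixture

    designs = load_fixture("table4")
    seeds = np.random.SeedSequence(seed).spawn(len(designs) + 2)
    scenarios = []
    k = 0
    for _, row in designs.iterrows():
        dose = _float(row["dose_mg"])
        per_kg = _float(row["dose_mg_per_kg"])
        infusion = _float(row["infusion_min"])
        if row["route"] == "iv":
            regimen = DosingRegimen(route="iv_infusion",
                                    dose=dose if dose else 1.0,
                                    dose_per_kg=per_kg,
                                    infusion_duration=infusion)
        else:
            regimen = DosingRegimen(route="oral", dose=dose,
                                    dose_per_kg=per_kg)

        age_lo, age_hi = _float(row["age_low"]), _float(row["age_high"])
        age_ms = (_float(row["age_mean"]), _float(row["age_sd"]))
        wt_lo, wt_hi = _float(row["weight_low"]), _float(row["weight_high"])
        wt_ms = (_float(row["weight_mean"]), _float(row["weight_sd"]))
        kwargs = dict(
            n=n,
            female_fraction=float(row["female_n"]) / float(row["n"]),
            cv=cv if cv is not None else None,
        )
        if kwargs["cv"] is None:
            kwargs.pop("cv")
        kwargs["age_range"] = ((age_lo, age_hi)
                               if age_lo is not None else AGGREGATE_HEALTHY_AGE)
        if age_ms[0] is not None:
            kwargs["age_mean_sd"] = age_ms
        kwargs["weight_range"] = ((wt_lo, wt_hi)
                                  if wt_lo is not None
                                  else AGGREGATE_HEALTHY_WEIGHT)
        if wt_ms[0] is not None:
            kwargs["weight_mean_sd"] = wt_ms

        if row["population"] == "disease":
            for cp in ("A", "B", "C"):
                spec = PopulationSpec(cp_class=cp,
                                      seed=int(seeds[k].generate_state(1)[0]
                                               % (2 ** 31)), **kwargs)
                k += 1
                scenarios.append(StudyScenario(
                    study_id=f"cp_{cp.lower()}", route=row["route"],
                    regimen=regimen, population=spec, cp_class=cp))
        else:
            spec = PopulationSpec(seed=int(seeds[k].generate_state(1)[0]
                                           % (2 ** 31)), **kwargs)
            k += 1
            scenarios.append(StudyScenario(
                study_id=str(row["study_id"]), route=row["route"],
                regimen=regimen, population=spec))
    return scenarios


def aggregate_healthy_spec(n: int = 1000, seed: int = 0,
                           female_fraction: float = 0.18,
                           cv: dict | None = None) -> PopulationSpec:
    """Aggregate healthy-adult population for production simulations."""
    kwargs = {} if cv is None else {"cv": cv}
    return PopulationSpec(n=n, female_fraction=female_fraction,
                          age_range=AGGREGATE_HEALTHY_AGE,
                          weight_range=AGGREGATE_HEALTHY_WEIGHT,
                          seed=seed, **kwargs)


def disease_spec(cp_class: str, n: int = 1000, seed: int = 0,
                 cv: dict | None = None) -> PopulationSpec:
    """Cirrhotic population: disease-study ages, healthy-adult weights."""
    kwargs = {} if cv is None else {"cv": cv}
    return PopulationSpec(n=n, female_fraction=8.0 / 19.0,
                          age_range=(20.0, 69.0),
                          weight_range=AGGREGATE_HEALTHY_WEIGHT,
                          cp_class=cp_class, seed=seed, **kwargs)


def run_scenario(scenario: StudyScenario,
                 drug: DrugParameters) -> PopulationResult:
    """Generate the scenario's population and simulate it."""
    subjects = generate_population(scenario.population)
    return simulate_population(subjects, drug, scenario.regimen)


def qualification_table(drug: DrugParameters, n: int = 1000,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate every verification scenario and tabulate obs/pred ratios.

    For each study the virtual population's mean NCA parameters (AUC0-inf,
    Cmax, CL) are the model predictions; observed values come from the
    packaged study tables. Returns one row per study x parameter with the
    ratio and its symmetric fold deviation max(R, 1/R).
    """
    from .synthetic import load_fixture

    observed = pd.concat([load_fixture("table1"), load_fixture("table3")],
                         ignore_index=True)
    rows = []
    for scenario in load_scenarios(n=n, seed=seed):
        result = run_scenario(scenario, drug)
        preds = {
            "auc_0inf": float(result.pk["auc_0inf"].mean()),
            "cmax": float(result.pk["cmax"].mean()),
            "cl": float(result.pk["cl"].mean()),
        }
        medians = {
            "auc_0inf": float(result.pk["auc_0inf"].median()),
        }
        obs = observed.query("study_id == @scenario.study_id "
                             "and route == @scenario.route")
        for r in obs.itertuples():
            ratio = r.observed / preds[r.parameter]
            rows.append({
                "study_id": scenario.study_id, "route": scenario.route,
                "parameter": r.parameter, "observed": r.observed,
                "predicted": preds[r.parameter],
                "median_auc_0inf": medians["auc_0inf"],
                "printed_ratio": r.printed_ratio, "ratio": ratio,
                "fold": max(ratio, 1.0 / ratio),
                "n_subjects": len(result.subjects),
            })
    return pd.DataFrame(rows)
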