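"""Virtual populations and population-level simulation.

Subjects are sampled to match a trial's demographics (sex split, age and
weight ranges or mean +/- SD). Inter-individual variability is log-normal
with median 1 on hepatic intrinsic clearance, the absorption rate constant
and a global Kp scale; the default coefficients of variation (30% / 20% /
15%) are exposed on the spec. Cirrhotic subjects additionally receive the
deterministic Child-Pugh scaler set for their class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drug import DrugParameters
from .engine import (ConcentrationTimeProfile, DosingRegimen, build_model,
                     simulate_individual)
from .nca import PKParameters, pk_summary
from .physiology import (ReferencePhysiology, apply_cirrhosis,
                         build_reference_physiology, load_cp_scalers)

__all__ = [
    "PopulationSpec",
    "Subject",
    "PercentileEnvelope",
    "PopulationResult",
    "generate_population",
    "simulate_population",
]

#: Default inter-individual variability (log-normal CV).
DEFAULT_CV = {"clint": 0.30, "ka": 0.20, "kp": 0.15}


@dataclass(frozen=True)
class PopulationSpec:
    """Demographic recipe for a virtual population."""

    n: int
    female_fraction: float = 0.0
    age_range: tuple[float, float] = (18.0, 43.0)
    weight_range: tuple[float, float] | None = (57.5, 90.5)
    age_mean_sd: tuple[float, float] | None = None
    weight_mean_sd: tuple[float, float] | None = None
    cp_class: str | None = None
    seed: int = 0
    cv: dict = field(default_factory=lambda: dict(DEFAULT_CV))

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.age_mean_sd is None and self.age_range[1] <= self.age_range[0]:
            raise ValueError("age_range must be non-degenerate")
        if (self.weight_mean_sd is None and self.weight_range is not None
                and self.weight_range[1] <= self.weight_range[0]):
            raise ValueError("weight_range must be non-degenerate")


@dataclass(frozen=True)
class Subject:
    """One virtual subject: demographics, physiology and variability draws."""

    subject_id: int
    sex: str
    age: float
    body_weight: float
    physiology: ReferencePhysiology
    clint_multiplier: float
    ka_multiplier: float
    kp_scale: float


@dataclass(frozen=True)
class PercentileEnvelope:
    """Pointwise population envelope of plasma concentration."""

    times: np.ndarray
    median: np.ndarray
    p5: np.ndarray
    p95: np.ndarray
    minimum: np.ndarray
    maximum: np.ndarray
    p10: np.ndarray | None = None
    p90: np.ndarray | None = None

    def __post_init__(self) -> None:
        eps = 1e-9
        ok = (np.all(self.minimum <= self.p5 + eps)
              and np.all(self.p5 <= self.median + eps)
              and np.all(self.median <= self.p95 + eps)
              and np.all(self.p95 <= self.maximum + eps))
        if not ok:
            raise ValueError("envelope ordering violated")


@dataclass(frozen=True)
class PopulationResult:
    """Profiles, envelope and per-subject NCA for one simulated scenario."""

    subjects: list[Subject]
    profiles: list[ConcentrationTimeProfile]
    envelope: PercentileEnvelope
    pk: pd.DataFrame   # one row per subject: auc_0inf, cmax, tmax, cl, ...


def _lognormal(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Median-1 log-normal multipliers with the given CV (cv=0 -> ones)."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return np.exp(rng.normal(0.0, sigma, size))


def generate_population(spec: PopulationSpec) -> list[Subject]:
    """Sample a reproducible virtual population for the given spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    n_female = int(round(spec.female_fraction * n))
    sexes = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sexes)

    if spec.age_mean_sd is not None:
        mu, sd = spec.age_mean_sd
        ages = np.clip(rng.normal(mu, sd, n), 18.0, 85.0)
    else:
        ages = rng.uniform(*spec.age_range, n)
    if spec.weight_mean_sd is not None:
        mu, sd = spec.weight_mean_sd
        weights = np.clip(rng.normal(mu, sd, n), 40.0, 150.0)
    else:
        weights = rng.uniform(*spec.weight_range, n)

    m_cl = _lognormal(rng, spec.cv.get("clint", 0.0), n)
    m_ka = _lognormal(rng, spec.cv.get("ka", 0.0), n)
    m_kp = _lognormal(rng, spec.cv.get("kp", 0.0), n)

    scalers = load_cp_scalers(spec.cp_class) if spec.cp_class else None
    subjects = []
    for i in range(n):
        phys = build_reference_physiology(float(weights[i]), float(ages[i]),
                                          str(sexes[i]))
        if scalers is not None:
            phys = apply_cirrhosis(phys, scalers)
        subjects.append(Subject(
            subject_id=i, sex=str(sexes[i]), age=float(ages[i]),
            body_weight=float(weights[i]), physiology=phys,
            clint_multiplier=float(m_cl[i]), ka_multiplier=float(m_ka[i]),
            kp_scale=float(m_kp[i])))
    return subjects


def _envelope(times: np.ndarray, conc: np.ndarray) -> PercentileEnvelope:
    q = np.percentile(conc, [5, 10, 50, 90, 95], axis=0)
    return PercentileEnvelope(
        times=times, median=q[2], p5=q[0], p95=q[4],
        minimum=conc.min(axis=0), maximum=conc.max(axis=0),
        p10=q[1], p90=q[3])


def simulate_population(subjects: list[Subject], drug: DrugParameters,
                        regimen: DosingRegimen,
                        t_end: float | None = None) -> PopulationResult:
    """Simulate every subject, compute the envelope and per-subject NCA."""
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for a population envelope")
    profiles, rows = [], []
    common_times = None
    conc = None
    models = [build_model(drug, s.physiology, regimen,
                          clint_multiplier=s.clint_multiplier,
                          ka_multiplier=s.ka_multiplier, kp_scale=s.kp_scale)
              for s in subjects]
    if t_end is None:
        # a shared horizon so all subjects land on one output grid
        from .engine import _auto_t_end
        t_end = max(_auto_t_end(m) for m in models[:20])
    for s, model in zip(subjects, models):
        try:
            prof = simulate_individual(model, t_end=t_end,
                                       label=f"subject_{s.subject_id}")
        except Exception as err:
            raise RuntimeError(
                f"simulation failed for subject {s.subject_id}") from err
        profiles.append(prof)
        if common_times is None:
            common_times = prof.times
            conc = np.empty((len(subjects), common_times.size))
        if prof.times.size != common_times.size:
            raise RuntimeError("subjects returned differing output grids")
        conc[len(profiles) - 1] = prof.concentrations
        pk = pk_summary(prof, regimen, s.body_weight)
        rows.append({
            "subject_id": s.subject_id, "sex": s.sex, "age": s.age,
            "body_weight": s.body_weight, "auc_0t": pk.auc_0t,
            "auc_0inf": pk.auc_0inf, "cmax": pk.cmax, "tmax": pk.tmax,
            "lambda_z": pk.lambda_z, "t_half": pk.t_half, "cl": pk.cl,
            "extrapolated_fraction": pk.extrapolated_fraction,
        })
    return PopulationResult(
        subjects=list(subjects), profiles=profiles,
        envelope=_envelope(common_times, conc),
        pk=pd.DataFrame(rows))
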