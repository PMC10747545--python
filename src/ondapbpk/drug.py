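"""Drug parameter set and derived quantities.

Houses the ondansetron parameterization and the small pharmacology layer on
top of it:

* Poulin-Theil equilibrium tissue:plasma partition coefficients (olive-oil
  variant for adipose, octanol for all other tissues),
* blood:plasma concentration ratio from hematocrit and an
  erythrocyte-water partitioning assumption,
* plasma/blood unbound fractions, with hypoalbuminemia scaling of binding,
* the well-stirred hepatic clearance model,
* total hepatic intrinsic clearance from the per-pathway weights, CYP
  abundances and the frozen calibration factor,
* absolute renal clearance from the specific (per-kg) value and GFR status.

All functions are pure and operate on plain dataclasses.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import yaml

from .physiology import OrganSpec, PLASMA_COMPOSITION, ReferencePhysiology

__all__ = [
    "DrugParameters",
    "PartitionSet",
    "load_ondansetron",
    "log_d",
    "poulin_theil_kp",
    "partition_set",
    "blood_plasma_ratio",
    "fu_adjusted",
    "fu_blood",
    "well_stirred_hepatic_cl",
    "total_intrinsic_clearance",
    "renal_cl_absolute",
    "volume_of_distribution",
]


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemical and ADME inputs for one compound."""

    name: str
    molecular_weight: float          # g/mol
    log_p: float                     # octanol:water
    pka_base: float
    fu_plasma: float                 # fraction unbound in plasma
    solubility: float                # mg/L
    binding_protein: str             # "albumin" or "AGP"
    specific_intestinal_permeability: float  # cm/min
    specific_organ_permeability: float       # cm/min
    clint_cyp1a2: float              # L/min (pathway weight)
    clint_cyp3a4: float              # L/min (pathway weight)
    renal_clearance_specific: float  # mL/min/kg
    calibration_factor: float = 1.0  # frozen clearance calibration
    ka_per_h: float = 1.5            # first-order absorption constant, 1/h
    fa: float = 1.0                  # fraction reaching the absorption depot

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")
        if not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must be in (0, 1]")
        for name in ("clint_cyp1a2", "clint_cyp3a4",
                     "renal_clearance_specific"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PartitionSet:
    """Per-organ tissue:plasma Kp values plus the blood:plasma ratio."""

    kp: dict[str, float]
    blood_plasma_ratio: float

    def __post_init__(self) -> None:
        if self.blood_plasma_ratio <= 0:
            raise ValueError("blood_plasma_ratio must be > 0")
        bad = {k: v for k, v in self.kp.items() if not (v > 0 and math.isfinite(v))}
        if bad:
            raise ValueError(f"non-positive/non-finite Kp values: {bad}")


def load_ondansetron() -> DrugParameters:
    """Packaged ondansetron definition including frozen calibration."""
    path = importlib.resources.files("ondapbpk.data").joinpath("ondansetron.yaml")
    with path.open("r") as fh:
        raw = yaml.safe_load(fh)
    cal = raw.pop("calibration")
    return DrugParameters(**raw, calibration_factor=cal["calibration_factor"],
                          ka_per_h=cal["ka_per_h"], fa=cal["fa"])


def log_d(drug: DrugParameters, ph: float = 7.4) -> float:
    """log D at the given pH for a monoprotic base (Henderson-Hasselbalch)."""
    return drug.log_p - math.log10(1.0 + 10.0 ** (drug.pka_base - ph))


def poulin_theil_kp(drug: DrugParameters, organ: OrganSpec,
                    plasma_composition: OrganSpec = PLASMA_COMPOSITION,
                    fu_tissue: float | None = None) -> float:
    """Equilibrium tissue:plasma partition coefficient.

    Kp = [P(Vnl_t + 0.3 Vph_t) + (Vw_t + 0.7 Vph_t)]
       / [P(Vnl_p + 0.3 Vph_p) + (Vw_p + 0.7 Vph_p)] * fu_p / fu_t

    For non-adipose tissue P is the octanol:water distribution coefficient
    at pH 7.4 (10**logD, ionization-corrected for the weak base) and fu_t
    defaults to fu_p, so the unbound-fraction ratio drops out. Adipose uses
    the olive-oil:water variant (log Pvo = 1.115 logD - 1.35) with fu_t = 1,
    reflecting negligible macromolecule binding in fat.
    """
    if organ.water_fraction <= 0:
        raise ValueError(f"organ {organ.name!r}: zero water fraction is non-physical")
    if drug.fu_plasma <= 0:
        raise ValueError("fu_plasma must be > 0")

    if organ.name == "adipose":
        p = 10.0 ** (1.115 * log_d(drug) - 1.35)
        fu_t = 1.0 if fu_tissue is None else fu_tissue
    else:
        p = 10.0 ** log_d(drug)
        fu_t = drug.fu_plasma if fu_tissue is None else fu_tissue

    def lipid_water(c: OrganSpec) -> float:
        return (p * (c.neutral_lipid_fraction + 0.3 * c.phospholipid_fraction)
                + c.water_fraction + 0.7 * c.phospholipid_fraction)

    kp = lipid_water(organ) / lipid_water(plasma_composition) * drug.fu_plasma / fu_t
    if not (kp > 0 and math.isfinite(kp)):
        raise ValueError(f"non-physical Kp for organ {organ.name!r}: {kp}")
    return kp


def blood_plasma_ratio(drug: DrugParameters, hematocrit: float,
                       erythrocyte_water_fraction: float = 0.63,
                       plasma_water_fraction: float = 0.96) -> float:
    """Blood:plasma total concentration ratio.

    Assumes unit concentration ratio between plasma water and erythrocyte
    water, so the erythrocyte:plasma ratio equals the ratio of the water
    fractions: B:P = (1 - Hct) + Hct * (Vw_ery / Vw_plasma).
    """
    if not 0 < hematocrit < 1:
        raise ValueError("hematocrit must be in (0, 1)")
    return (1.0 - hematocrit) + hematocrit * (
        erythrocyte_water_fraction / plasma_water_fraction)


def fu_adjusted(drug: DrugParameters, albumin_factor: float) -> float:
    """Plasma unbound fraction after scaling binding-protein concentration.

    Binding capacity scales with albumin: bound:unbound = albumin_factor *
    (1 - fu)/fu, hence fu' = fu / (albumin_factor (1 - fu) + fu).
    """
    if albumin_factor <= 0:
        raise ValueError("albumin_factor must be > 0")
    fu = drug.fu_plasma
    return fu / (albumin_factor * (1.0 - fu) + fu)


def fu_blood(drug: DrugParameters, hematocrit: float,
             albumin_factor: float = 1.0) -> float:
    """Unbound fraction referenced to whole-blood concentration."""
    return fu_adjusted(drug, albumin_factor) / blood_plasma_ratio(drug, hematocrit)


def partition_set(drug: DrugParameters, phys: ReferencePhysiology,
                  kp_scale: float = 1.0) -> PartitionSet:
    """Kp for every perfused tissue plus the blood:plasma ratio.

    ``kp_scale`` is a subject-level variability multiplier applied uniformly
    to all tissue Kp values (blood compartments are unaffected).
    """
    kp = {}
    for name, organ in phys.organs.items():
        if name in ("arterial blood", "venous blood"):
            continue
        kp[name] = kp_scale * poulin_theil_kp(drug, organ)
    bp = blood_plasma_ratio(
        drug, phys.hematocrit,
        erythrocyte_water_fraction=phys.erythrocyte_water_fraction)
    return PartitionSet(kp=kp, blood_plasma_ratio=bp)


def well_stirred_hepatic_cl(q_liver: float, fu_blood_value: float,
                            clint_total: float) -> float:
    """Well-stirred liver model: CL_h = Q fu_b CLint / (Q + fu_b CLint).

    All arguments and the result are blood-referenced, L/min.
    """
    if q_liver <= 0:
        raise ValueError("q_liver must be > 0")
    if fu_blood_value < 0 or clint_total < 0:
        raise ValueError("fu_blood and clint_total must be >= 0")
    num = fu_blood_value * clint_total
    return q_liver * num / (q_liver + num)


def total_intrinsic_clearance(drug: DrugParameters,
                              phys: ReferencePhysiology) -> float:
    """Total hepatic intrinsic clearance (L/min, unbound, blood-referenced).

    Sum of the per-pathway weights times the physiology's CYP abundance
    factors, times the frozen calibration factor. Disease scaling enters
    through the abundances set by ``apply_cirrhosis`` (CYP1A2 whole-liver
    activity fraction; CYP3A4 per-mass abundance already combined with
    functional liver mass).
    """
    if phys.cyp1a2_abundance < 0 or phys.cyp3a4_abundance < 0:
        raise ValueError("CYP abundances must be >= 0")
    return (drug.clint_cyp1a2 * phys.cyp1a2_abundance
            + drug.clint_cyp3a4 * phys.cyp3a4_abundance) * drug.calibration_factor


def renal_cl_absolute(drug: DrugParameters, body_weight: float,
                      gfr_fraction: float = 1.0) -> float:
    """Absolute renal plasma clearance in mL/min."""
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    return drug.renal_clearance_specific * body_weight * gfr_fraction


def volume_of_distribution(partition: PartitionSet,
                           phys: ReferencePhysiology) -> float:
    """Plasma-referenced equilibrium distribution volume (L).

    Vss = sum_t Kp_t V_t + V_blood * B:P over all perfused tissues and the
    two blood pools.
    """
    v = 0.0
    for name, organ in phys.organs.items():
        if name in ("arterial blood", "venous blood"):
            v += organ.volume * partition.blood_plasma_ratio
        else:
            v += organ.volume * partition.kp[name]
    return v
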