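"""Reference-human physiology and its Child-Pugh cirrhosis transforms.

The whole-body model needs, per organ: a volume, a regional blood flow and a
tissue composition (water / neutral-lipid / phospholipid volume fractions)
for equilibrium partitioning. A single documented reference adult (73 kg,
cardiac output 6.5 L/min) is shipped as structured data; individual subjects
are derived by allometric scaling (organ volumes and flows proportional to
body weight).

Liver cirrhosis is represented by the Child-Pugh class scalers: reduced
functional liver mass and CYP abundances, hypoalbuminemia, anemia
(hematocrit set absolutely), portal-flow collapse with hepatic-arterial
compensation, a hyperdynamic increase of non-hepatic non-renal flows, and
reduced renal flow and GFR.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import yaml

__all__ = [
    "OrganSpec",
    "ReferencePhysiology",
    "CirrhosisScalers",
    "PLASMA_COMPOSITION",
    "ORGAN_NAMES",
    "build_reference_physiology",
    "load_reference_table",
    "load_cp_scalers",
    "apply_cirrhosis",
]

ORGAN_NAMES = (
    "lung", "heart", "brain", "muscle", "adipose", "skin", "bone",
    "liver", "gut", "spleen", "kidney", "rest-of-body",
    "arterial blood", "venous blood",
)

#: Organs drained by the portal vein (their venous outflow enters the liver).
PORTAL_ORGANS = ("gut", "spleen")

#: Systemic organs that receive the cirrhotic "other organs" flow factor
#: (everything perfused from the arterial pool except liver and kidney).
OTHER_FLOW_ORGANS = ("heart", "brain", "muscle", "adipose", "skin", "bone",
                     "rest-of-body")


@dataclass(frozen=True)
class OrganSpec:
    """One organ: volume (L), blood flow (L/min) and composition fractions."""

    name: str
    volume: float
    blood_flow: float
    water_fraction: float
    neutral_lipid_fraction: float
    phospholipid_fraction: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"organ {self.name!r}: volume must be > 0")
        if self.blood_flow < 0:
            raise ValueError(f"organ {self.name!r}: blood_flow must be >= 0")
        total = (self.water_fraction + self.neutral_lipid_fraction
                 + self.phospholipid_fraction)
        if not (0 < self.water_fraction <= 1) or total > 1 + 1e-12:
            raise ValueError(
                f"organ {self.name!r}: composition fractions invalid "
                f"(water={self.water_fraction}, sum={total:.4f})")


#: Plasma pseudo-composition used as the reference phase in partitioning.
PLASMA_COMPOSITION = OrganSpec(
    name="plasma", volume=3.0, blood_flow=0.0,
    water_fraction=0.96, neutral_lipid_fraction=0.0035,
    phospholipid_fraction=0.00225)


@dataclass(frozen=True)
class CirrhosisScalers:
    """Child-Pugh class multipliers/values applied to a healthy physiology.

    All entries except ``hematocrit_value`` are fractions or multipliers of
    the healthy control. ``cyp1a2_fraction`` is a whole-liver activity
    fraction; ``cyp3a4_fraction`` is an abundance per unit functional liver
    mass (total CYP3A4 capacity scales as
    ``cyp3a4_fraction * functional_liver_mass``).
    """

    cp_class: str
    functional_liver_mass: float
    cyp3a4_fraction: float
    cyp1a2_fraction: float
    albumin_fraction: float
    hematocrit_value: float
    portal_flow_fraction: float
    hepatic_arterial_flow_factor: float
    other_organs_flow_factor: float
    renal_flow_fraction: float
    gfr_fraction: float

    def __post_init__(self) -> None:
        if self.cp_class not in ("A", "B", "C"):
            raise ValueError(f"cp_class must be one of A, B, C, got {self.cp_class!r}")
        for name in ("functional_liver_mass", "cyp3a4_fraction",
                     "cyp1a2_fraction", "albumin_fraction",
                     "portal_flow_fraction", "hepatic_arterial_flow_factor",
                     "other_organs_flow_factor", "renal_flow_fraction",
                     "gfr_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"scaler {name} must be > 0")
        if not 0 < self.hematocrit_value < 1:
            raise ValueError("hematocrit_value must be in (0, 1)")


@dataclass(frozen=True)
class ReferencePhysiology:
    """A complete subject physiology (healthy or cirrhotic).

    Factors (``albumin_factor``, CYP abundances, ``functional_liver_mass_factor``)
    are 1.0 for a healthy subject and become the applied Child-Pugh
    multipliers after :func:`apply_cirrhosis`.
    """

    organs: dict[str, OrganSpec]
    body_weight: float
    hematocrit: float
    gfr: float
    portal_flow: float
    hepatic_arterial_flow: float
    renal_flow: float
    albumin_factor: float = 1.0
    cyp1a2_abundance: float = 1.0
    cyp3a4_abundance: float = 1.0
    functional_liver_mass_factor: float = 1.0
    condition: str = "healthy"
    erythrocyte_water_fraction: float = 0.63

    def __post_init__(self) -> None:
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must be in (0, 1)")
        missing = set(ORGAN_NAMES) - set(self.organs)
        if missing:
            raise ValueError(f"physiology missing organs: {sorted(missing)}")
        liver_in = self.portal_flow + self.hepatic_arterial_flow
        if abs(self.organs["liver"].blood_flow - liver_in) > 1e-9 * max(liver_in, 1.0):
            raise ValueError("liver blood_flow must equal portal + hepatic arterial flow")
        co = self.cardiac_output
        if abs(self.organs["lung"].blood_flow - co) > 0.01 * co:
            raise ValueError("lung (cardiac output) flow inconsistent with "
                             "sum of regional flows")

    @property
    def cardiac_output(self) -> float:
        """Cardiac output (L/min blood) = sum of systemic regional flows."""
        systemic = [o for name, o in self.organs.items()
                    if name not in ("lung", "arterial blood", "venous blood",
                                    "liver")]
        return sum(o.blood_flow for o in systemic) + self.hepatic_arterial_flow

    @property
    def total_volume(self) -> float:
        return sum(o.volume for o in self.organs.values())


def _data_path(name: str):
    return importlib.resources.files("ondapbpk.data").joinpath(name)


def load_reference_table() -> dict:
    """Raw packaged reference-human table (parsed YAML)."""
    with _data_path("reference_human.yaml").open("r") as fh:
        return yaml.safe_load(fh)


def build_reference_physiology(body_weight: float = 73.0, age: float = 30.0,
                               sex: str = "male") -> ReferencePhysiology:
    """Construct a healthy adult physiology by allometric scaling.

    Organ volumes scale linearly with body weight relative to the packaged
    73 kg reference; regional flows scale with cardiac output, itself taken
    proportional to body weight. Sex and age are recorded constraints of the
    accepted input space but do not alter the anatomy in this version.

    Parameters
    ----------
    body_weight : float
        kg, must lie in [40, 150].
    age : float
        years, must lie in [18, 85].
    sex : {"male", "female"}
    """
    if not 40 <= body_weight <= 150:
        raise ValueError(f"body_weight out of supported range [40, 150]: {body_weight}")
    if not 18 <= age <= 85:
        raise ValueError(f"age out of supported range [18, 85]: {age}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")

    table = load_reference_table()
    scale = body_weight / table["body_weight_kg"]
    organs = {}
    for name, row in table["organs"].items():
        organs[name] = OrganSpec(
            name=name,
            volume=row["volume"] * scale,
            blood_flow=row["blood_flow"] * scale,
            water_fraction=row["water_fraction"],
            neutral_lipid_fraction=row["neutral_lipid_fraction"],
            phospholipid_fraction=row["phospholipid_fraction"],
        )
    return ReferencePhysiology(
        organs=organs,
        body_weight=body_weight,
        hematocrit=table["hematocrit"],
        gfr=table["gfr_ml_min"],
        portal_flow=table["portal_flow"] * scale,
        hepatic_arterial_flow=table["hepatic_arterial_flow"] * scale,
        renal_flow=table["renal_flow"] * scale,
        erythrocyte_water_fraction=table["erythrocyte_water_fraction"],
    )


def load_cp_scalers(cp_class: str) -> CirrhosisScalers:
    """Load the packaged Child-Pugh scaler set for class A, B or C."""
    key = str(cp_class).upper()
    if key not in ("A", "B", "C"):
        raise ValueError(f"unknown Child-Pugh class: {cp_class!r}")
    with _data_path(f"cirrhosis_cp_{key.lower()}.yaml").open("r") as fh:
        raw = yaml.safe_load(fh)
    return CirrhosisScalers(**raw)


def apply_cirrhosis(phys: ReferencePhysiology,
                    scalers: CirrhosisScalers) -> ReferencePhysiology:
    """Transform a healthy physiology into a Child-Pugh cirrhotic one.

    Flow groups (portal organs, hepatic artery, kidney, all other systemic
    organs) are multiplied by their class factors and cardiac output is
    recomputed as the sum of the scaled regional flows. Hematocrit is set to
    the absolute class value; GFR, albumin and CYP abundances receive their
    fractional scalers. The input object is not modified.
    """
    if phys.condition != "healthy":
        raise ValueError(
            f"physiology is already scaled ({phys.condition}); "
            "apply_cirrhosis expects a healthy input")

    organs = dict(phys.organs)
    for name in PORTAL_ORGANS:
        organs[name] = replace(organs[name],
                               blood_flow=organs[name].blood_flow
                               * scalers.portal_flow_fraction)
    for name in OTHER_FLOW_ORGANS:
        organs[name] = replace(organs[name],
                               blood_flow=organs[name].blood_flow
                               * scalers.other_organs_flow_factor)
    organs["kidney"] = replace(organs["kidney"],
                               blood_flow=organs["kidney"].blood_flow
                               * scalers.renal_flow_fraction)
    portal = phys.portal_flow * scalers.portal_flow_fraction
    arterial = phys.hepatic_arterial_flow * scalers.hepatic_arterial_flow_factor
    organs["liver"] = replace(organs["liver"], blood_flow=portal + arterial)

    co = (sum(organs[n].blood_flow for n in OTHER_FLOW_ORGANS)
          + sum(organs[n].blood_flow for n in PORTAL_ORGANS)
          + organs["kidney"].blood_flow + arterial)
    for name in ("lung", "arterial blood", "venous blood"):
        organs[name] = replace(organs[name], blood_flow=co)

    return replace(
        phys,
        organs=organs,
        hematocrit=scalers.hematocrit_value,
        gfr=phys.gfr * scalers.gfr_fraction,
        portal_flow=portal,
        hepatic_arterial_flow=arterial,
        renal_flow=organs["kidney"].blood_flow,
        albumin_factor=scalers.albumin_fraction,
        cyp1a2_abundance=scalers.cyp1a2_fraction,
        cyp3a4_abundance=scalers.cyp3a4_fraction * scalers.functional_liver_mass,
        functional_liver_mass_factor=scalers.functional_liver_mass,
        condition=f"cirrhosis CP-{scalers.cp_class}",
    )
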