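"""Synthetic "observed" data and packaged printed-table fixtures.

The clinical concentration-time series behind the model-qualification
figures were digitized from literature plots and are not reprinted, so the
package generates stand-ins: closed-form one- or two-compartment disposition
(IV infusion or first-order oral absorption) sampled at protocol times,
multiplied by log-normal assay noise, with values below the lower limit of
quantification dropped. These synthetic profiles exercise the NCA and
evaluation machinery end to end.

The printed study tables (observed/predicted PK parameters, trial designs,
drug parameters, cirrhosis scalers) ship as plain CSV fixtures, loadable by
id and checksummed against the packaged source.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ConcentrationTimeProfile, DosingRegimen

__all__ = ["SyntheticProfileSpec", "generate_profile", "load_fixture",
           "FIXTURE_FILES"]

FIXTURE_FILES = {
    "table1": "table1_healthy_obs_pred.csv",
    "table3": "table3_cirrhosis_obs_pred.csv",
    "table4": "table4_trial_designs.csv",
    "table5": "table5_drug_parameters.csv",
    "table6": "table6_cirrhosis_scalers.csv",
}

# sha256 of the packaged fixture files; guards against silent edits
FIXTURE_SHA256 = {
    "table1": "904d502d5434f9b4cb9d3d80b996e5ba9c4d94397a74d08a1943c959f05f471e",
    "table3": "2f316b1d820862bef541a9b1acf5d5bf9d41ba5f02fd5319b0b3433d6827afa8",
    "table4": "43b58a4205bf5a8a41d8db76b536046186ba8b73610aa89f63b7124d60b0aea5",
    "table5": "5aa454f2623003dfa4196654bef6bf0a69bafa7b1682e5d08944962be9c657eb",
    "table6": "7a14728a7477308fe9c619a39d56aad43ed1a26a47331173ca3220fe5100e973",
}


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Kinetic and sampling recipe for one synthetic observed profile.

    ``cl`` (L/h) and ``v1`` (L) define a one-compartment model; adding ``q``
    and ``v2`` (L/h, L) makes it two-compartment. ``ka`` (1/h) and ``f``
    apply to oral dosing. ``noise_cv`` is the multiplicative log-normal
    assay CV; ``lloq`` (ng/mL) censors the tail.
    """

    model: str                       # "one_compartment" | "two_compartment"
    cl: float                        # L/h
    v1: float                        # L
    q: float | None = None           # L/h
    v2: float | None = None          # L
    ka: float = 1.5                  # 1/h
    f: float = 1.0
    noise_cv: float = 0.0
    lloq: float = 0.5                # ng/mL
    sampling_times: tuple = (0.083, 0.25, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 12, 16, 24)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("one_compartment", "two_compartment"):
            raise ValueError(f"unknown model: {self.model!r}")
        for name in ("cl", "v1", "ka", "f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.model == "two_compartment" and (not self.q or not self.v2):
            raise ValueError("two_compartment model needs q and v2")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _disposition_rates(spec: SyntheticProfileSpec):
    """Exponential rates and central-compartment weights for a unit bolus."""
    if spec.model == "one_compartment":
        k = spec.cl / spec.v1
        return np.array([k]), np.array([1.0])
    k10 = spec.cl / spec.v1
    k12 = spec.q / spec.v1
    k21 = spec.q / spec.v2
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    alpha, beta = (s + disc) / 2.0, (s - disc) / 2.0
    coefs = np.array([(alpha - k21) / (alpha - beta),
                      (k21 - beta) / (alpha - beta)])
    return np.array([alpha, beta]), coefs


def _infusion_conc(t, dose_ug, t_inf_h, rates, coefs, v1):
    """Central concentration for a constant-rate infusion (ng/mL)."""
    t = np.asarray(t, dtype=float)
    c = np.zeros_like(t)
    r0 = dose_ug / t_inf_h
    for lam, a in zip(rates, coefs):
        during = -np.expm1(-lam * np.minimum(t, t_inf_h))
        shift = np.exp(-lam * np.maximum(t - t_inf_h, 0.0))
        c += a / lam * during * shift
    return r0 * c / v1


def _oral_conc(t, dose_ug, spec, rates, coefs):
    """Central concentration after first-order oral absorption (ng/mL)."""
    t = np.asarray(t, dtype=float)
    ka = spec.ka
    c = np.zeros_like(t)
    for lam, a in zip(rates, coefs):
        if abs(ka - lam) < 1e-12:
            c += a * t * np.exp(-lam * t)
        else:
            c += a * (np.exp(-lam * t) - np.exp(-ka * t)) / (ka - lam)
    return spec.f * dose_ug * ka * c / spec.v1


def generate_profile(spec: SyntheticProfileSpec,
                     regimen: DosingRegimen) -> ConcentrationTimeProfile:
    """Closed-form profile at the sampling times with assay noise and LLOQ.

    Reproducible for a fixed ``spec.seed``; raises if every sample falls
    below the LLOQ.
    """
    t = np.asarray(spec.sampling_times, dtype=float)
    if np.any(np.diff(t) <= 0) or np.any(t < 0):
        raise ValueError("sampling_times must be non-negative and increasing")
    dose_ug = regimen.resolved_dose(70.0) * 1000.0
    rates, coefs = _disposition_rates(spec)
    if regimen.route == "iv_infusion":
        conc = _infusion_conc(t, dose_ug, regimen.infusion_duration / 60.0,
                              rates, coefs, spec.v1)
    else:
        conc = _oral_conc(t, dose_ug, spec, rates, coefs)

    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = np.sqrt(np.log(1.0 + spec.noise_cv ** 2))
        conc = conc * np.exp(rng.normal(0.0, sigma, conc.size))

    keep = conc >= spec.lloq
    if not np.any(keep):
        raise ValueError("all sampled concentrations fall below the LLOQ")
    return ConcentrationTimeProfile(
        times=t[keep], concentrations=conc[keep],
        label=f"synthetic_{spec.model}", dose_record=regimen)


def _fixture_bytes(table_id: str) -> bytes:
    try:
        fname = FIXTURE_FILES[table_id]
    except KeyError:
        raise ValueError(f"unknown fixture id: {table_id!r}; "
                         f"expected one of {sorted(FIXTURE_FILES)}") from None
    path = importlib.resources.files("ondapbpk.data").joinpath(fname)
    return path.read_bytes()


def load_fixture(table_id: str, verify_checksum: bool = True) -> pd.DataFrame:
    """Load a packaged printed-table fixture as a DataFrame."""
    raw = _fixture_bytes(table_id)
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        expected = FIXTURE_SHA256[table_id]
        if digest != expected:
            raise ValueError(f"fixture {table_id} checksum mismatch: "
                             f"{digest} != {expected}")
    from io import BytesIO
    return pd.read_csv(BytesIO(raw))
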