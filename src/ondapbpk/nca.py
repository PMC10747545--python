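"""Noncompartmental analysis of concentration-time profiles.

AUC uses the linear-up / log-down trapezoid (linear rule on rising or flat
segments, log rule on declining positive segments). The terminal rate
constant lambda_z comes from a log-linear regression whose window is chosen
by maximizing adjusted R^2 over all suffixes of >= 3 points strictly after
Tmax, ties resolved toward the longer window. Clearance is dose / AUC0-inf
normalized to body weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import ConcentrationTimeProfile, DosingRegimen

__all__ = ["PKParameters", "auc_trapezoid", "lambda_z", "pk_summary"]


@dataclass(frozen=True)
class PKParameters:
    """NCA outputs for one profile. ``cl`` is CL for IV and CL/F for oral."""

    auc_0t: float                 # ng·h/mL
    auc_0inf: float               # ng·h/mL
    cmax: float                   # ng/mL
    tmax: float                   # h
    lambda_z: float               # 1/h
    t_half: float                 # h
    cl: float                     # mL/min/kg
    extrapolated_fraction: float  # 0-1
    extrapolation_warning: bool = False


def _arrays(profile) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profile, ConcentrationTimeProfile):
        return profile.times, profile.concentrations
    t, c = profile
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t, c


def auc_trapezoid(profile) -> float:
    """Linear-up / log-down AUC over the observed range (ng·h/mL)."""
    t, c = _arrays(profile)
    if t.size < 2:
        raise ValueError("need at least 2 points for AUC")
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    lin = 0.5 * (c1 + c2) * dt
    down = (c2 < c1) & (c2 > 0) & (c1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logseg = (c1 - c2) * dt / np.log(c1 / c2)
    return float(np.sum(np.where(down, logseg, lin)))


def lambda_z(profile, min_points: int = 3) -> float:
    """Terminal elimination rate constant (1/h).

    Regresses log concentration on time over the suffix window (strictly
    after Tmax) with the best adjusted R^2; requires >= ``min_points``
    positive declining concentrations.
    """
    t, c = _arrays(profile)
    i_max = int(np.argmax(c))
    if i_max >= t.size - min_points:
        raise ValueError("profile still rising near the last sample; "
                         "no terminal phase to regress")
    tt, cc = t[i_max + 1:], c[i_max + 1:]
    if np.any(cc <= 0):
        raise ValueError("non-positive terminal concentrations")
    y = np.log(cc)
    n = tt.size

    # reversed prefix sums give every suffix-window regression in O(n)
    def rsum(v):
        return np.cumsum(v[::-1])[::-1]

    sx, sy = rsum(tt), rsum(y)
    sxx, sxy, syy = rsum(tt * tt), rsum(tt * y), rsum(y * y)
    ks = np.arange(n, 0, -1)          # window length for suffix starting at i
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / ks
        varx = sxx - sx * sx / ks
        vary = syy - sy * sy / ks
        slope = cov / varx
        r2 = np.where(vary > 0, cov * cov / (varx * vary), 1.0)
        adj = 1.0 - (1.0 - r2) * (ks - 1) / (ks - 2)

    valid = (ks >= min_points) & (slope < 0) & (varx > 0)
    if not np.any(valid):
        raise ValueError("no declining terminal window found")
    adj = np.where(valid, adj, -np.inf)
    best = adj.max()
    # ties -> longer window (smaller start index)
    i_best = int(np.nonzero(adj >= best - 1e-12)[0][0])
    return float(-slope[i_best])


def pk_summary(profile, regimen: DosingRegimen, body_weight: float,
               min_points: int = 3) -> PKParameters:
    """Full NCA parameter set for a single-dose profile."""
    t, c = _arrays(profile)
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    if t[0] > 0:
        # no pre-dose sample: standard single-dose convention C(0) = 0
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[0.0], c])
    auc_t = auc_trapezoid((t, c))
    lz = lambda_z((t, c), min_points=min_points)
    c_last = c[c > 0][-1]
    auc_inf = auc_t + c_last / lz
    extrap = (auc_inf - auc_t) / auc_inf
    i_max = int(np.argmax(c))
    dose_ng = regimen.resolved_dose(body_weight) * 1e6
    cl = dose_ng / auc_inf / body_weight / 60.0   # mL/min/kg
    return PKParameters(
        auc_0t=float(auc_t), auc_0inf=float(auc_inf), cmax=float(c[i_max]),
        tmax=float(t[i_max]), lambda_z=lz, t_half=math.log(2.0) / lz,
        cl=float(cl), extrapolated_fraction=float(extrap),
        extrapolation_warning=bool(extrap > 0.2))
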