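"""Non-compartmental analysis and model-evaluation statistics.

Implements the evaluation toolkit used to qualify the model: NCA metrics
(Cmax, tmax, AUC by linear-up/log-down trapezoids with log-linear tail
extrapolation), Guest's narrowing DDI acceptance window, the geometric
mean fold error (GMFE, signed — the literal form of the printed formula,
which can fall below 1 when predictions run low), CV/n-based "alternative
success" bounds at a configurable confidence level, dose-linearity
diagnostics and visual-predictive-check coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidDataError, InvalidParameterError

__all__ = ["PKMetrics", "GuestLimits", "GMFEResult", "nca", "guest_limits",
           "gmfe", "success_bounds", "dose_linearity", "vpc_coverage"]


@dataclass
class PKMetrics:
    cmax: float
    tmax: float
    auc_0_t: float
    auc_0_inf: float
    extrapolated_fraction: float
    lambda_z: float | None = None
    flags: list = field(default_factory=list)


def nca(times, concentrations, n_tail: int = 3) -> PKMetrics:
    """Non-compartmental metrics from a concentration-time profile.

    AUC0-t by linear-up/log-down trapezoids; the terminal slope lambda_z
    by log-linear regression on the last ``n_tail`` (or more, if the tail
    keeps declining monotonically) positive points after tmax;
    AUC0-inf = AUC0-t + Clast/lambda_z.  A non-estimable tail yields
    partial metrics with a flag instead of an error.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size != c.size or t.size < 2:
        raise InvalidDataError("need matching time/concentration arrays")
    if np.any(np.diff(t) <= 0):
        raise InvalidDataError("times must be strictly increasing")
    flags = []
    if not np.any(c > 0):
        return PKMetrics(0.0, float(t[0]), 0.0, 0.0, 0.0,
                         flags=["all-zero profile"])
    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])

    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    lin = (c1 + c2) / 2 * dt
    with np.errstate(divide="ignore", invalid="ignore"):
        logseg = (c1 - c2) / (np.log(c1) - np.log(c2)) * dt
    use_log = (c2 < c1) & (c2 > 0) & np.isfinite(logseg)
    auc_0_t = float(np.sum(np.where(use_log, logseg, lin)))

    # terminal fit on points after tmax
    tail = np.flatnonzero((t > tmax) & (c > 0))
    lam = None
    auc_inf = auc_0_t
    extrap = 0.0
    if tail.size >= n_tail:
        idx = tail[-n_tail:]
        res = stats.linregress(t[idx], np.log(c[idx]))
        if res.slope < 0:
            lam = -res.slope
            clast = float(c[tail[-1]])
            auc_inf = auc_0_t + clast / lam
            extrap = (auc_inf - auc_0_t) / auc_inf
            if extrap >= 0.2:
                flags.append("extrapolated fraction >= 20%")
        else:
            flags.append("terminal slope not estimable")
    else:
        flags.append("fewer than 3 points past tmax")
    return PKMetrics(cmax, tmax, auc_0_t, auc_inf, float(extrap),
                     lambda_z=lam, flags=flags)


@dataclass
class GuestLimits:
    robs: float
    lower: float
    upper: float
    delta: float = 1.0

    def contains(self, rpred: float) -> bool:
        return self.lower <= rpred <= self.upper


def guest_limits(robs: float, delta: float = 1.0) -> GuestLimits:
    """Guest's DDI prediction acceptance window around an observed ratio.

    L = (delta + 2*(R - 1)) / R for R >= 1; limits are (R/L, R*L).
    Observed ratios below 1 are evaluated on the reciprocal and mapped
    back, so the window narrows symmetrically toward unity from either
    side.  At R = 1 (with delta 1) the window collapses to a point; for
    large R it approaches the plain twofold window.
    """
    if robs <= 0:
        raise InvalidParameterError("observed ratio must be > 0")
    if delta < 1:
        raise InvalidParameterError("delta must be >= 1")
    r = robs if robs >= 1 else 1.0 / robs
    limit = (delta + 2.0 * (r - 1.0)) / r
    lo, hi = r / limit, r * limit
    if robs < 1:
        lo, hi = 1.0 / hi, 1.0 / lo
    return GuestLimits(robs=robs, lower=lo, upper=hi, delta=delta)


@dataclass
class GMFEResult:
    value: float
    n_pairs: int
    signed: bool


def gmfe(pairs, signed: bool = True) -> GMFEResult:
    """Geometric mean fold error over (observed, simulated) pairs.

    The signed form is 10**mean(log10(simulated/observed)) — exactly the
    printed formula, which drops below 1 when predictions run uniformly
    low.  ``signed=False`` gives the common absolute variant
    10**mean(|log10(sim/obs)|), always >= 1.
    """
    pairs = list(pairs)
    if not pairs:
        raise InvalidDataError("need at least one pair")
    logs = []
    for obs, sim in pairs:
        if obs <= 0 or sim <= 0:
            raise InvalidDataError("observed and simulated must be > 0")
        val = math.log10(sim / obs)
        logs.append(val if signed else abs(val))
    return GMFEResult(10.0 ** (sum(logs) / len(logs)), len(logs), signed)


def success_bounds(geo_mean: float, cv_percent: float | None,
                   n_subjects: int | None, confidence: float = 99.998,
                   twofold_cap: bool = False) -> tuple[float, float]:
    """CV/n-based acceptance window for a PK parameter.

    bounds = geo_mean * exp(-+ z * sigma_log / sqrt(n)) with
    sigma_log = sqrt(ln(1 + (cv/100)^2)) and z the two-sided quantile at
    the given confidence (99.998% by default).  When the study's CV or n
    is unknown the plain twofold window (geo_mean/2, geo_mean*2) is used;
    ``twofold_cap`` additionally clips a wider CV-based window to twofold.
    """
    if geo_mean <= 0:
        raise InvalidParameterError("geo_mean must be > 0")
    if cv_percent is None or n_subjects is None:
        return geo_mean / 2.0, geo_mean * 2.0
    if cv_percent <= 0:
        return geo_mean, geo_mean
    if n_subjects < 2:
        raise InvalidParameterError("n_subjects must be >= 2")
    sigma = math.sqrt(math.log(1.0 + (cv_percent / 100.0) ** 2))
    z = stats.norm.ppf(0.5 + confidence / 200.0)
    half = z * sigma / math.sqrt(n_subjects)
    if twofold_cap:
        half = min(half, math.log(2.0))
    return geo_mean * math.exp(-half), geo_mean * math.exp(half)


def dose_linearity(doses, aucs, reference_dose) -> dict:
    """Dose-normalized exposure ratios against a reference dose.

    ratio_d = (AUC_d/d) / (AUC_ref/ref); the deviation factor 1/ratio
    quantifies how far a sub-proportional dose falls below the
    proportionality line anchored at the reference.
    """
    doses = np.asarray(doses, dtype=float)
    aucs = np.asarray(aucs, dtype=float)
    if doses.size < 2:
        raise InvalidDataError("need at least two doses")
    if reference_dose not in doses:
        raise InvalidDataError("reference dose must be among the doses")
    ref_norm = aucs[doses == reference_dose][0] / reference_dose
    ratios = (aucs / doses) / ref_norm
    return {
        "doses": doses,
        "ratio": ratios,
        "deviation_factor": np.where(ratios > 0, 1.0 / ratios, np.inf),
    }


def vpc_coverage(obs_times, obs_conc, band_times, band_lower, band_upper) -> dict:
    """Fraction of observations inside a simulated 5th-95th percentile band.

    Band envelopes are linearly interpolated to the observation times;
    returns the coverage fraction and the excursion list.
    """
    ot = np.asarray(obs_times, dtype=float)
    oc = np.asarray(obs_conc, dtype=float)
    lo = np.interp(ot, band_times, band_lower)
    hi = np.interp(ot, band_times, band_upper)
    inside = (oc >= lo) & (oc <= hi)
    excursions = [(float(t), float(c)) for t, c, ok in zip(ot, oc, inside)
                  if not ok]
    return {"coverage": float(np.mean(inside)) if ot.size else float("nan"),
            "excursions": excursions}
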