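"""In vitro to in vivo extrapolation (IVIVE) of kinetic and binding parameters.

Converts raw in vitro measurements — plasma-stability incubations,
microsomal Michaelis-Menten rate data, permeability descriptors and
protein-binding measurements — into the model-ready constants consumed by
the gut and disposition modules: first-order plasma conversion rates,
whole-organ intrinsic clearances, intersystem extrapolation factors (ISEF),
effective human jejunal permeability and unbound blood fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import EstimationError, InvalidDataError, InvalidParameterError

__all__ = [
    "EnzymePathway",
    "TransporterPathway",
    "BindingParams",
    "InVitroDecayDataset",
    "MMKineticsDataset",
    "HalfLifeFit",
    "MMFit",
    "halflife_to_rate",
    "fit_halflife",
    "fit_mm",
    "compute_isef",
    "scale_clint_liver",
    "scale_clint_bile",
    "predict_peff",
    "fu_blood",
]

#: sentinel product id for CYP3A-mediated oxidative losses that are not
#: tracked as explicit compounds
OXIDATIVE_SINK = "oxidative_sink"

_ENZYMES = {"CYP3A4", "CYP3A5", "CES1", "CES2"}
_ORGANS = {"gut", "liver"}


@dataclass
class EnzymePathway:
    """One saturable metabolic pathway of a compound in one organ.

    ``vmax`` is expressed at whole-organ scale (umol/h) once built into a
    model; raw per-mg microsomal values go through :func:`scale_clint_liver`
    first.  ``km_u`` is the unbound Michaelis constant (uM).  ``isef``
    rescales recombinant-enzyme activity to tissue microsomes and applies to
    CYP pathways only.
    """

    enzyme_id: str
    organ: str
    vmax: float
    km_u: float
    product_id: str = OXIDATIVE_SINK
    isef: float = 1.0
    fu_inc: float = 1.0

    def __post_init__(self):
        if self.enzyme_id not in _ENZYMES:
            raise InvalidParameterError(f"unknown enzyme {self.enzyme_id!r}")
        if self.organ not in _ORGANS:
            raise InvalidParameterError(f"unknown organ {self.organ!r}")
        if self.vmax < 0:
            raise InvalidParameterError("vmax must be >= 0")
        if self.km_u <= 0:
            raise InvalidParameterError("km_u must be > 0")
        if not 0 < self.fu_inc <= 1:
            raise InvalidParameterError("fu_inc must be in (0, 1]")
        if self.isef < 0:
            raise InvalidParameterError("isef must be >= 0")
        if self.enzyme_id.startswith("CES") and self.isef != 1.0:
            raise InvalidParameterError("CES pathways carry no ISEF (must be 1)")

    @property
    def is_cyp(self) -> bool:
        return self.enzyme_id.startswith("CYP")


@dataclass
class TransporterPathway:
    """Apical efflux transporter (P-gp) on the gut wall.

    ``jmax`` is the whole-gut maximum transport rate (umol/h), distributed
    over segments by the physiology's P-gp abundance weights; ``km`` the
    Michaelis constant (uM, 2.6 for dabigatran etexilate).
    """

    transporter_id: str = "P-gp"
    jmax: float = 0.0
    km: float = 2.6

    def __post_init__(self):
        if self.jmax < 0:
            raise InvalidParameterError("jmax must be >= 0")
        if self.km <= 0:
            raise InvalidParameterError("km must be > 0")


@dataclass
class BindingParams:
    """Plasma/blood binding of one compound."""

    fu_plasma: float
    bp_ratio: float
    fu_gut: float = 1.0

    def __post_init__(self):
        if not 0 < self.fu_plasma <= 1:
            raise InvalidParameterError("fu_plasma must be in (0, 1]")
        if self.bp_ratio <= 0:
            raise InvalidParameterError("bp_ratio must be > 0")
        if not 0 < self.fu_gut <= 1:
            raise InvalidParameterError("fu_gut must be in (0, 1]")


@dataclass
class InVitroDecayDataset:
    """Plasma-stability incubation: concentration vs time, replicate-wise.

    ``concentrations`` has shape (n_replicates, n_times), in uM; times in
    minutes, strictly increasing.
    """

    times: np.ndarray
    concentrations: np.ndarray
    initial_concentration: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.atleast_2d(
            np.asarray(self.concentrations, dtype=float)
        )
        if np.any(np.diff(self.times) <= 0):
            raise InvalidDataError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise InvalidDataError("concentrations must be >= 0")
        if self.concentrations.shape[-1] != self.times.size:
            raise InvalidDataError("concentration / time shape mismatch")


@dataclass
class MMKineticsDataset:
    """Microsomal rate-vs-concentration data for Michaelis-Menten fitting."""

    substrate_concentrations: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        self.substrate_concentrations = np.asarray(
            self.substrate_concentrations, dtype=float
        )
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if np.any(self.substrate_concentrations <= 0):
            raise InvalidDataError("substrate concentrations must be > 0")
        if np.unique(self.substrate_concentrations).size < 4:
            raise InvalidDataError("need >= 4 distinct substrate concentrations")
        if self.rates.shape[-1] != self.substrate_concentrations.size:
            raise InvalidDataError("rate / concentration shape mismatch")


@dataclass
class HalfLifeFit:
    """Result of a log-linear plasma-decay fit."""

    t_half_min: float | None
    se_min: float | None
    stable: bool
    slope_p_value: float


@dataclass
class MMFit:
    vmax: float
    km_u: float
    vmax_se: float
    km_se: float
    warnings: list = field(default_factory=list)


def halflife_to_rate(t_half: float) -> float:
    """First-order rate constant (1/h) from an in vitro half-life in minutes.

    k = ln(2) * 60 / t_half.  E.g. the plasma half-lives of 364 and 55 min
    measured for the double-ester prodrug and its ethyl-ester intermediate
    map to 0.114 and 0.756 1/h.
    """
    if not t_half > 0:
        raise InvalidParameterError("t_half must be > 0")
    return math.log(2.0) * 60.0 / t_half


def fit_halflife(data: InVitroDecayDataset, alpha: float = 0.05) -> HalfLifeFit:
    """Estimate a plasma-decay half-life by log-linear regression.

    All replicate points are pooled; concentrations at or below zero are
    dropped (log domain).  When the decay slope is not distinguishable from
    zero (two-sided t-test at ``alpha``) the compound is flagged *stable*
    and no half-life is reported, mirroring the qualitative stability call
    for the desethyl intermediate.
    """
    if data.times.size < 4:
        raise InvalidDataError("need at least 4 time points")
    t = np.tile(data.times, data.concentrations.shape[0])
    c = data.concentrations.ravel()
    mask = c > 0
    if not mask.any():
        raise InvalidDataError("all concentrations are zero")
    res = stats.linregress(t[mask], np.log(c[mask]))
    # slope in 1/min; stable when we cannot reject slope == 0 or slope >= 0
    if res.pvalue > alpha or res.slope >= 0:
        return HalfLifeFit(None, None, stable=True, slope_p_value=res.pvalue)
    t_half = math.log(2.0) / (-res.slope)
    se = math.log(2.0) / res.slope**2 * res.stderr
    return HalfLifeFit(t_half, se, stable=False, slope_p_value=res.pvalue)


def fit_mm(data: MMKineticsDataset) -> MMFit:
    """Nonlinear least-squares fit of v = Vmax*C/(Km + C).

    Starting values come from a linearized Hanes-Woolf pass.  A warning is
    attached when the concentration design does not span 0.2x-5x the fitted
    Km (weak identifiability).
    """
    conc = np.tile(data.substrate_concentrations, data.rates.shape[0])
    v = data.rates.ravel()

    def model(c, vmax, km):
        return vmax * c / (km + c)

    v0 = max(v.max(), 1e-12)
    k0 = float(np.median(data.substrate_concentrations))
    try:
        popt, pcov = optimize.curve_fit(
            model, conc, v, p0=[v0, k0],
            bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        resid = v - model(conc, v0, k0)
        raise EstimationError(
            f"Michaelis-Menten fit did not converge: {exc}",
            last_objective=float(np.sum(resid**2)),
        ) from exc
    se = np.sqrt(np.diag(pcov))
    warnings = []
    cmin, cmax = conc.min(), conc.max()
    if cmin > 0.2 * popt[1] or cmax < 5.0 * popt[1]:
        warnings.append(
            "concentration design does not span 0.2x-5x the fitted Km; "
            "Vmax/Km weakly identifiable"
        )
    return MMFit(float(popt[0]), float(popt[1]), float(se[0]), float(se[1]),
                 warnings)


def compute_isef(clint_hlm: float, clint_rcyp: float, abundance: float) -> float:
    """Intersystem extrapolation factor for a recombinant CYP pathway.

    isef = CLint(HLM, uL/min/mg) / (CLint(rCYP, uL/min/pmol) * abundance
    (pmol/mg)).
    """
    if clint_hlm <= 0 or clint_rcyp <= 0 or abundance <= 0:
        raise InvalidParameterError("all ISEF inputs must be > 0")
    return clint_hlm / (clint_rcyp * abundance)


_UL_PER_MIN_TO_L_PER_H = 60.0 * 1e-6


def scale_clint_liver(vmax: float, km_u: float, isef: float, fu_inc: float,
                      mppgl: float, liver_mass: float) -> float:
    """Whole-liver unbound intrinsic clearance (L/h) from microsomal kinetics.

    CLint,u = isef * (vmax/km_u) * (1/fu_inc) * MPPGL * liver mass, with
    vmax in pmol/min/mg, km_u in uM, MPPGL in mg microsomal protein per g
    liver and liver mass in g; the uL/min result is converted to L/h.
    """
    if km_u <= 0 or not 0 < fu_inc <= 1 or mppgl <= 0 or liver_mass <= 0:
        raise InvalidParameterError("invalid scaling inputs")
    clint_ul_min = isef * (vmax / km_u) / fu_inc * mppgl * liver_mass
    return clint_ul_min * _UL_PER_MIN_TO_L_PER_H


def scale_clint_bile(clint_cell: float, hepatocellularity: float,
                     liver_mass: float) -> float:
    """Whole-liver biliary intrinsic clearance (L/h) from a per-cell value.

    clint_cell in uL/min per 1e6 hepatocytes, hepatocellularity in 1e6
    cells/g, liver mass in g.  The printed 273 uL/min/1e6 cells scales to
    about 3.2e3 L/h of intrinsic (pre-well-stirred) clearance.
    """
    if clint_cell < 0 or hepatocellularity <= 0 or liver_mass <= 0:
        raise InvalidParameterError("invalid biliary scaling inputs")
    return clint_cell * hepatocellularity * liver_mass * _UL_PER_MIN_TO_L_PER_H


def predict_peff(psa: float, hbd: float, coefficients=None) -> float:
    """Human jejunal effective permeability (1e-4 cm/s) from PSA and HBD.

    Uses the published human-jejunal regression of log10 Peff on dynamic
    polar surface area and hydrogen-bond-donor count,
    ``log10 Peff(cm/s) = c0 + c1*PSA + c2*HBD``; coefficients may be
    overridden (they live in the physiology config, not here).  Peff
    decreases monotonically in both descriptors.
    """
    if psa < 0 or hbd < 0:
        raise InvalidParameterError("psa and hbd must be >= 0")
    if coefficients is None:
        coefficients = PEFF_COEFFICIENTS
    c0, c1, c2 = coefficients
    log_peff_cm_s = c0 + c1 * psa + c2 * hbd
    return 10.0 ** log_peff_cm_s / 1e-4


#: default human-jejunal Peff regression coefficients (log10 cm/s scale):
#: intercept, slope per A^2 of PSA, slope per H-bond donor.
PEFF_COEFFICIENTS = (-2.546, -0.011, -0.278)


def fu_blood(binding: BindingParams) -> float:
    """Unbound fraction referenced to whole blood: fu_b = fu_p / (B:P)."""
    return binding.fu_plasma / binding.bp_ratio
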