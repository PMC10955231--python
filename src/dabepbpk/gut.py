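"""Multi-segment intestinal absorption mechanics.

Flux laws for the serial-transit gut model: diffusion-layer dissolution
with transient supersaturation, latched supersaturation-triggered
precipitation, passive apical uptake, apical P-gp efflux and enterocyte
metabolism.  All functions are numpy-vectorized over segments so the ODE
engine can evaluate them on whole segment arrays; each also works on
scalars for unit testing.

Units: amounts umol, concentrations uM, volumes L, time h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidParameterError, UndefinedMetricError

__all__ = [
    "FormulationSpec", "DLMParams", "dissolution_coefficient",
    "dissolution_flux", "precipitation_flux", "absorption_rate_constant",
    "pgp_efflux", "michaelis_rate", "first_pass_summary",
]

_FORMS = {"solution_with_precipitation", "solid_IR"}


@dataclass
class FormulationSpec:
    """Dosage form of the administered compound.

    ``csr`` is the critical supersaturation ratio (dimensionless, >= 1):
    once the luminal concentration reaches ``csr`` times the aqueous
    solubility in a segment, precipitation is triggered there and proceeds
    first-order with rate constant ``prc`` (1/h) until the concentration
    relaxes back to the solubility.  Solid immediate-release forms carry a
    particle radius and true density for the diffusion-layer model.
    """

    form: str = "solution_with_precipitation"
    particle_radius_um: float = 10.0
    density_g_ml: float = 1.2
    csr: float = 17.9
    prc: float = 2.88

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ConfigurationError(f"unknown formulation {self.form!r}")
        if self.csr < 1:
            raise InvalidParameterError("csr must be >= 1")
        if self.prc < 0:
            raise InvalidParameterError("prc must be >= 0")
        if self.form == "solid_IR" and self.particle_radius_um <= 0:
            raise InvalidParameterError("particle_radius must be > 0")


@dataclass
class DLMParams:
    """Pre-computed diffusion-layer-model constants for one dose of solid.

    ``kd`` multiplies solid^(2/3) * (C_surface - C_bulk) to give a
    dissolution flux; it follows the Wang-Flanagan spherical-particle form
    kd ~ 3*D*M0^(1/3) / (rho * r0 * h_eff) with the boundary-layer
    thickness h_eff = min(r0, 30 um).
    """

    kd: float          # umol/h per (umol^(2/3) * uM)
    mw: float

    @property
    def valid(self) -> bool:
        return self.kd > 0


def dissolution_coefficient(diffusion_cm2_s: float, density_g_ml: float,
                            particle_radius_um: float, dose_umol: float,
                            mw: float) -> DLMParams:
    """Diffusion-layer dissolution coefficient for a monodisperse dose.

    Halving the particle radius (at fixed mass) increases kd, i.e. speeds
    dissolution, through both the 1/r0 factor and the thinner boundary
    layer.
    """
    if diffusion_cm2_s <= 0 or density_g_ml <= 0 or particle_radius_um <= 0:
        raise InvalidParameterError("DLM inputs must be > 0")
    if dose_umol <= 0:
        return DLMParams(kd=0.0, mw=mw)
    d_cm2_h = diffusion_cm2_s * 3600.0
    r0_cm = particle_radius_um * 1e-4
    h_cm = min(r0_cm, 30e-4)
    m0_g = dose_umol * mw * 1e-6
    # flux_g/h = K * m^(2/3) * deltaC_g/cm3,  K = 3 D m0^(1/3)/(rho r0 h)
    k_mass = 3.0 * d_cm2_h * m0_g ** (1.0 / 3.0) / (density_g_ml * r0_cm * h_cm)
    # convert: m^(2/3) with m in umol -> (umol*mw*1e-6 g)^(2/3);
    # deltaC uM -> 1e-9*mw g/cm3; flux g/h -> /mw*1e6 umol/h
    kd = k_mass * (mw * 1e-6) ** (2.0 / 3.0) * (1e-9 * mw) / mw * 1e6
    return DLMParams(kd=kd, mw=mw)


def dissolution_flux(solid, dissolved_conc, solubility, dlm: DLMParams,
                     supersaturation_limit=None):
    """Dissolution flux (umol/h) from the solid pool into solution.

    The driving concentration is ``solubility`` by default; while a
    formulation supports transient supersaturation (before precipitation
    has nucleated in a segment) the particle-surface concentration is the
    supersaturation limit ``csr * solubility`` and may carry the bulk
    concentration above the equilibrium solubility.  The flux is clamped at
    >= 0: solution never deposits back onto particles here — that is the
    precipitation operation's job.
    """
    solid = np.asarray(solid, dtype=float)
    if np.any(solid < -1e-9):
        raise InvalidParameterError("negative solid amount")
    target = solubility if supersaturation_limit is None else supersaturation_limit
    drive = np.maximum(target - np.asarray(dissolved_conc, dtype=float), 0.0)
    return dlm.kd * np.maximum(solid, 0.0) ** (2.0 / 3.0) * drive


def precipitation_flux(dissolved_conc, solubility, form: FormulationSpec,
                       segment_volume_l, triggered):
    """Precipitation flux (umol/h) removing drug from solution.

    Zero until the supersaturation trigger has fired in a segment
    (``triggered``; latched by the engine when C/solubility first reaches
    the critical supersaturation ratio); afterwards first-order relaxation
    prc * (C - S) * V toward the solubility.
    """
    c = np.asarray(dissolved_conc, dtype=float)
    trig = np.asarray(triggered, dtype=bool)
    flux = form.prc * np.maximum(c - solubility, 0.0) * np.asarray(
        segment_volume_l, dtype=float)
    return np.where(trig, flux, 0.0)


def absorption_rate_constant(peff_1e4_cm_s, radius_cm):
    """Apical uptake rate constant ka = 2*Peff/R (1/h) for a cylindrical lumen.

    Peff is in 1e-4 cm/s; 1e-4 cm/s over a 1 cm radius gives 0.72 1/h.
    """
    peff = np.asarray(peff_1e4_cm_s, dtype=float)
    r = np.asarray(radius_cm, dtype=float)
    if np.any(peff < 0) or np.any(r <= 0):
        raise InvalidParameterError("peff must be >= 0 and radius > 0")
    return 2.0 * peff * 1e-4 * 3600.0 / r


def pgp_efflux(enterocyte_conc_u, jmax_segment, km, inhibition_factor=1.0):
    """Apical P-gp efflux flux (umol/h), enterocyte -> lumen.

    ``jmax_segment`` is the segment's share of whole-gut Jmax;
    ``inhibition_factor`` (>= 1) multiplies Km under competitive
    inhibition.  Saturates at jmax_segment for C >> Km regardless of the
    inhibitor.
    """
    c = np.maximum(np.asarray(enterocyte_conc_u, dtype=float), 0.0)
    factor = np.asarray(inhibition_factor, dtype=float)
    if np.any(factor < 1):
        raise InvalidParameterError("inhibition_factor must be >= 1")
    return np.asarray(jmax_segment, dtype=float) * c / (km * factor + c)


def michaelis_rate(conc_u, vmax, km, km_factor=1.0, activity=1.0):
    """Saturable metabolic rate vmax*C/(Km*factor + C), scaled by the
    active-enzyme fraction (mechanism-based inactivation knocks activity
    below 1)."""
    c = np.maximum(np.asarray(conc_u, dtype=float), 0.0)
    return np.asarray(activity, dtype=float) * np.asarray(vmax, dtype=float) \
        * c / (np.asarray(km, dtype=float) * km_factor + c)


def first_pass_summary(ledger: dict, dose_umol: float,
                       substrate: str, gut_compounds: list[str]) -> dict:
    """Fa and Fg per compound from the cumulative flux ledger.

    For the dosed substrate Fa is the net apical transfer into enterocytes
    over the dose and Fg the fraction of that net uptake reaching the
    portal vein un-metabolized.  Gut-formed metabolites have no Fa of
    their own (reported as 1); their Fg is basolateral escape over the
    amount formed in the enterocytes.
    """
    out = {}
    net_apical = ledger["apical_in"] - ledger["efflux"]
    if dose_umol <= 0:
        raise UndefinedMetricError("Fa undefined: nothing was dosed")
    for comp in gut_compounds:
        if comp == substrate:
            fa = net_apical / dose_umol
            denom = net_apical
        else:
            fa = 1.0
            denom = ledger["gut_formed"].get(comp, 0.0)
        baso = ledger["basolateral"].get(comp, 0.0)
        fg = baso / denom if denom > 0 else float("nan")
        out[comp] = {"fa": fa, "fg": fg}
    return out
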