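"""Systemic disposition building blocks.

The engine represents each compound's body as four compartments — portal
blood, a well-stirred liver, a central blood pool and one peripheral
distribution pool — connected by hepatic blood flow.  This module holds
the pure pieces: the well-stirred hepatic clearance identity, first-order
plasma-esterase conversion, the distribution parameterization, and the Fh
flux accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError, UndefinedMetricError

__all__ = ["DistributionParams", "well_stirred_clh", "plasma_conversion_flux",
           "fh_summary"]


@dataclass
class DistributionParams:
    """Lumped central-peripheral distribution of one compound.

    ``vss_l_kg`` is the (input, not predicted) steady-state volume of
    distribution; ``central_fraction`` the share assigned to the central
    pool; ``q_l_h`` the intercompartmental clearance.
    """

    vss_l_kg: float
    central_fraction: float = 1.0
    q_l_h: float = 0.0

    def __post_init__(self):
        if self.vss_l_kg <= 0:
            raise InvalidParameterError("vss must be > 0")
        if not 0 < self.central_fraction <= 1:
            raise InvalidParameterError("central_fraction must be in (0, 1]")
        if self.q_l_h < 0:
            raise InvalidParameterError("q must be >= 0")

    def volumes(self, body_weight_kg: float) -> tuple[float, float]:
        vss = self.vss_l_kg * body_weight_kg
        vc = vss * self.central_fraction
        return vc, vss - vc


def well_stirred_clh(qh: float, fu_b: float, clint_u: float) -> tuple[float, float]:
    """Well-stirred hepatic clearance and the escaping fraction.

    CLh = Qh * fu_b * CLint,u / (Qh + fu_b * CLint,u); Fh = 1 - CLh/Qh.
    Returns (CLh, Fh).
    """
    if qh <= 0 or fu_b <= 0 or clint_u < 0:
        raise InvalidParameterError("well-stirred inputs must be positive")
    x = fu_b * clint_u
    clh = qh * x / (qh + x)
    return clh, 1.0 - clh / qh


def plasma_conversion_flux(amount_umol, k_h: float):
    """First-order, concentration-independent esterase conversion flux
    k * amount (umol/h) in a blood pool.  Compounds that are stable in
    plasma carry k = 0 and are untouched."""
    if k_h < 0:
        raise InvalidParameterError("conversion rate must be >= 0")
    return k_h * amount_umol


def fh_summary(liver_in: dict, liver_out: dict) -> dict:
    """Fh per compound from cumulative hepatic flux accounting.

    Fh = (cumulative hepatic outflow to the systemic circulation) /
    (cumulative inflow: portal + arterial + in-liver formation).  With no
    hepatic elimination pathways the two ledgers match and Fh = 1.
    """
    out = {}
    for comp, inflow in liver_in.items():
        if inflow <= 0:
            out[comp] = float("nan")
            continue
        out[comp] = liver_out.get(comp, 0.0) / inflow
    if not out:
        raise UndefinedMetricError("no hepatic flux recorded")
    return out
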