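"""Perpetrator models and drug-drug interaction machinery.

Perpetrators (clarithromycin, itraconazole + hydroxy-itraconazole,
verapamil, rifampicin — all dual CYP3A/P-gp inhibitors here, none of them
CES inhibitors) are represented by empirical one-compartment oral PK with a
gastric/luminal front-end, so that gut-lumen, enterocyte and liver-inlet
exposures are all defined.  Interaction mechanisms are competitive Km
shifts and mechanism-based CYP3A inactivation with enzyme-turnover
dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import ComparisonError, ConfigurationError, InvalidParameterError

__all__ = [
    "InhibitionTerm", "EmpiricalPK", "Regimen", "PerpetratorSpec",
    "competitive_factor", "mbi_inactivation_rate", "mbi_rhs",
    "mbi_steady_state", "DDIOutcome", "ddi_outcome", "load_perpetrators",
]

_TARGETS = {"CYP3A", "P-gp"}
_ORGANS = {"gut", "liver"}
_MECHANISMS = {"competitive", "mbi"}


@dataclass
class InhibitionTerm:
    """One inhibitory interaction of a perpetrator species on one target.

    Competitive terms carry an unbound ``ki_u`` (uM); mechanism-based terms
    carry ``kinact`` (1/h) and the unbound apparent ``ki_app_u`` (uM).
    """

    target: str
    organ: str
    mechanism: str
    ki_u: float | None = None
    kinact: float | None = None
    ki_app_u: float | None = None

    def __post_init__(self):
        if self.target not in _TARGETS:
            raise ConfigurationError(f"unknown target {self.target!r}")
        if self.organ not in _ORGANS:
            raise ConfigurationError(f"unknown organ {self.organ!r}")
        if self.mechanism not in _MECHANISMS:
            raise ConfigurationError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "competitive":
            if self.ki_u is None or self.ki_u <= 0 or self.kinact is not None:
                raise ConfigurationError("competitive term needs ki_u > 0 only")
        else:
            if (self.kinact is None or self.kinact <= 0
                    or self.ki_app_u is None or self.ki_app_u <= 0
                    or self.ki_u is not None):
                raise ConfigurationError("mbi term needs kinact and ki_app_u > 0")


@dataclass
class EmpiricalPK:
    """One-compartment oral PK with a stomach/lumen absorption front-end."""

    ka_h: float
    v_f_l: float
    cl_f_l_h: float
    fu_plasma: float
    bp_ratio: float = 1.0
    mw_g_mol: float = 500.0

    def __post_init__(self):
        for name in ("ka_h", "v_f_l", "cl_f_l_h", "fu_plasma", "bp_ratio",
                     "mw_g_mol"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"perpetrator pk: {name} must be > 0")

    @property
    def ke_h(self) -> float:
        return self.cl_f_l_h / self.v_f_l


@dataclass
class Regimen:
    """Oral dosing regimen: ``dose_mg`` every ``interval_h`` for
    ``n_doses`` doses, first dose at ``start_h`` on the simulation clock."""

    dose_mg: float
    n_doses: int = 1
    interval_h: float = 24.0
    start_h: float = 0.0
    route: str = "po"

    def __post_init__(self):
        if self.route != "po":
            raise ConfigurationError(f"unsupported route {self.route!r}")
        if self.dose_mg < 0 or self.n_doses < 1 or self.interval_h <= 0:
            raise ConfigurationError("invalid regimen")
        if self.start_h < 0:
            raise ConfigurationError("regimen times must be non-negative")

    @property
    def dose_times(self) -> np.ndarray:
        return self.start_h + self.interval_h * np.arange(self.n_doses)


@dataclass
class MetabolitePerpetrator:
    """A circulating inhibitory metabolite (e.g. OH-itraconazole), formed
    from a fraction of the parent's elimination."""

    id: str
    formation_fraction: float
    v_l: float
    cl_l_h: float
    fu_plasma: float
    interactions: list[InhibitionTerm] = field(default_factory=list)

    def __post_init__(self):
        if not 0 < self.formation_fraction <= 1:
            raise ConfigurationError("formation_fraction must be in (0, 1]")
        if self.v_l <= 0 or self.cl_l_h <= 0 or not 0 < self.fu_plasma <= 1:
            raise ConfigurationError("invalid metabolite perpetrator pk")


@dataclass
class PerpetratorSpec:
    id: str
    regimen: Regimen
    pk: EmpiricalPK
    interactions: list[InhibitionTerm] = field(default_factory=list)
    metabolite: MetabolitePerpetrator | None = None

    def terms(self):
        """(species_tag, term) pairs over parent and metabolite."""
        for t in self.interactions:
            yield "parent", t
        if self.metabolite is not None:
            for t in self.metabolite.interactions:
                yield "metabolite", t


def competitive_factor(contributions) -> float:
    """Km multiplier 1 + sum(I_u / Ki_u) over all co-present competitive
    inhibitors (parent and metabolite species add independently).

    ``contributions`` is an iterable of (i_u, ki_u) pairs; e.g. 2 uM of an
    inhibitor with Ki 2 uM plus 5 uM of its metabolite with Ki 5 uM give a
    factor of 3.
    """
    total = 0.0
    for i_u, ki_u in contributions:
        if i_u < 0:
            raise InvalidParameterError("inhibitor concentration must be >= 0")
        if ki_u <= 0:
            raise InvalidParameterError("ki must be > 0")
        total += i_u / ki_u
    return 1.0 + total


def mbi_inactivation_rate(i_u: float, kinact: float, ki_app_u: float) -> float:
    """Saturable inactivation hazard kinact * I/(KI + I) (1/h)."""
    if i_u < 0:
        raise InvalidParameterError("inhibitor concentration must be >= 0")
    return kinact * i_u / (ki_app_u + i_u)


def mbi_rhs(e: float, i_u: float, kinact: float, ki_app_u: float,
            kdeg: float) -> float:
    """Enzyme-turnover ODE for mechanism-based inactivation:

    de/dt = kdeg*(1 - e) - e * kinact * I/(KI + I),

    where e is the active fraction (1 = baseline).  Without inhibitor the
    pool relaxes to 1 at rate kdeg.
    """
    return kdeg * (1.0 - e) - e * mbi_inactivation_rate(i_u, kinact, ki_app_u)


def mbi_steady_state(i_u: float, kinact: float, ki_app_u: float,
                     kdeg: float) -> float:
    """Closed-form steady state e* = kdeg / (kdeg + kinact*I/(KI+I))."""
    lam = mbi_inactivation_rate(i_u, kinact, ki_app_u)
    return kdeg / (kdeg + lam)


@dataclass
class DDIOutcome:
    """Victim-side interaction summary: active-metabolite exposure ratios
    plus the presystemic dissection (primed = inhibited condition)."""

    cmax_ratio: float
    auc_ratio: float
    fa_ratio: dict
    fg_ratio: dict
    fh_ratio: dict


def ddi_outcome(control, inhibited, analyte: str = "dab") -> DDIOutcome:
    """Compare an inhibited run against its control.

    Both runs must share the substrate regimen; ratios are
    inhibited/control for Cmax and AUC0-inf of the analyte (the active
    metabolite by default) and for Fa, Fg, Fh of every compound where both
    runs define them.
    """
    from .metrics import nca  # local import; metrics depends on nothing here

    if control.substrate != inhibited.substrate or not np.isclose(
            control.dose_mg, inhibited.dose_mg):
        raise ComparisonError("control and inhibited runs use different "
                              "substrate regimens")
    m_c = nca(control.times_after_dose, control.profile(analyte))
    m_i = nca(inhibited.times_after_dose, inhibited.profile(analyte))

    def ratios(key):
        out = {}
        for comp, vals_c in control.first_pass.items():
            vals_i = inhibited.first_pass.get(comp)
            if vals_i is None:
                continue
            c, i = vals_c.get(key), vals_i.get(key)
            if c and c > 0 and i == i and c == c:  # NaN-safe
                out[comp] = i / c
        return out

    fh_ratio = {c: inhibited.fh[c] / control.fh[c]
                for c in control.fh if control.fh.get(c, 0) > 0
                and inhibited.fh.get(c, float("nan")) == inhibited.fh.get(c)}
    return DDIOutcome(
        cmax_ratio=m_i.cmax / m_c.cmax,
        auc_ratio=m_i.auc_0_inf / m_c.auc_0_inf,
        fa_ratio=ratios("fa"),
        fg_ratio=ratios("fg"),
        fh_ratio=fh_ratio,
    )


def _term(row: dict) -> InhibitionTerm:
    return InhibitionTerm(
        target=row["target"], organ=row["organ"], mechanism=row["mechanism"],
        ki_u=row.get("ki_u"), kinact=row.get("kinact"),
        ki_app_u=row.get("ki_app_u"),
    )


def load_perpetrators(path=None) -> dict[str, "PerpetratorSpec"]:
    """Load the shipped perpetrator library (editable YAML).

    Regimens are attached per scenario, so the YAML stores PK and
    interaction constants only; :func:`make_perpetrator` binds a regimen.
    """
    if path is None:
        text = resources.files("dabepbpk.data").joinpath(
            "perpetrators.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out = {}
    for pid, row in raw.items():
        pk = EmpiricalPK(**row["pk"])
        met = None
        if row.get("metabolite"):
            m = row["metabolite"]
            met = MetabolitePerpetrator(
                id=m["id"], formation_fraction=float(m["formation_fraction"]),
                v_l=float(m["v_l"]), cl_l_h=float(m["cl_l_h"]),
                fu_plasma=float(m["fu_plasma"]),
                interactions=[_term(t) for t in m.get("interactions", [])],
            )
        out[pid] = PerpetratorSpec(
            id=pid, regimen=Regimen(0.0),  # placeholder, bound per scenario
            pk=pk, interactions=[_term(t) for t in row.get("interactions", [])],
            metabolite=met,
        )
    return out


def make_perpetrator(library: dict, pid: str, regimen: Regimen) -> PerpetratorSpec:
    base = library[pid]
    return PerpetratorSpec(id=pid, regimen=regimen, pk=base.pk,
                           interactions=base.interactions,
                           metabolite=base.metabolite)
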