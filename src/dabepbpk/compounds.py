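"""Compound parameterization and the shipped drug cascade fixtures.

One :class:`CompoundSpec` carries every drug-specific constant for a single
chemical species of the prodrug cascade: the double-ester parent (DABE),
its two intermediate monoesters (BIBR0951 — ethyl ester, BIBR1087 —
desethyl ester) and the active acid (dabigatran, DAB).  The shipped
parameter set in ``data/compounds.yaml`` mixes printed literature values
with calibrated stand-ins for constants the source platform does not
publish; every calibrated value is marked as such in the YAML.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .disposition import DistributionParams
from .errors import ConfigurationError
from .ivive import (OXIDATIVE_SINK, BindingParams, EnzymePathway,
                    TransporterPathway, halflife_to_rate)

__all__ = ["CompoundSpec", "load_compounds", "compound_map"]


@dataclass
class CompoundSpec:
    """All drug-specific parameters for one species of the cascade."""

    id: str
    mw_g_mol: float
    binding: BindingParams
    distribution: DistributionParams
    # intestinal
    peff_1e4_cm_s: float = 0.0
    colon_absorption: bool = False
    solubility_mg_ml: float | None = None
    diffusion_cm2_s: float = 5.0e-6
    kbl_h: float = 0.0                  # basolateral escape rate constant
    bl_scalar: float = 1.0              # global basolateral scalar (0.1 for BIBR0951)
    gut_pathways: list[EnzymePathway] = field(default_factory=list)
    pgp: TransporterPathway | None = None
    # hepatic / systemic
    liver_pathways: list[EnzymePathway] = field(default_factory=list)
    clint_bile_l_h: float = 0.0         # unbound intrinsic biliary clearance
    cl_renal_l_h: float = 0.0
    cl_other_l_h: float = 0.0           # lumped unspecified systemic clearance
    plasma_halflife_min: float | None = None
    plasma_product: str | None = None

    def __post_init__(self):
        if self.mw_g_mol <= 0:
            raise ConfigurationError(f"{self.id}: molecular weight must be > 0")
        if (self.plasma_halflife_min is None) != (self.plasma_product is None):
            raise ConfigurationError(
                f"{self.id}: plasma half-life and product must be set together")
        for pw in self.gut_pathways:
            if pw.organ != "gut":
                raise ConfigurationError(f"{self.id}: gut pathway in wrong organ")
        for pw in self.liver_pathways:
            if pw.organ != "liver":
                raise ConfigurationError(f"{self.id}: liver pathway in wrong organ")

    @property
    def fu_blood(self) -> float:
        return self.binding.fu_plasma / self.binding.bp_ratio

    @property
    def plasma_k_h(self) -> float:
        if self.plasma_halflife_min is None:
            return 0.0
        return halflife_to_rate(self.plasma_halflife_min)

    @property
    def solubility_um(self) -> float | None:
        if self.solubility_mg_ml is None:
            return None
        return self.solubility_mg_ml * 1e6 / self.mw_g_mol  # mg/mL -> uM

    def products(self) -> set[str]:
        out = set()
        for pw in self.gut_pathways + self.liver_pathways:
            if pw.product_id != OXIDATIVE_SINK:
                out.add(pw.product_id)
        if self.plasma_product:
            out.add(self.plasma_product)
        return out


def _pathway(organ: str, row: dict) -> EnzymePathway:
    return EnzymePathway(
        enzyme_id=row["enzyme_id"], organ=organ,
        vmax=float(row["vmax_umol_h"]), km_u=float(row["km_u"]),
        product_id=row.get("product", OXIDATIVE_SINK),
        isef=float(row.get("isef", 1.0)),
        fu_inc=float(row.get("fu_inc", 1.0)),
    )


def _from_dict(cid: str, row: dict) -> CompoundSpec:
    b = row["binding"]
    d = row["distribution"]
    pgp = None
    if row.get("pgp"):
        pgp = TransporterPathway(jmax=float(row["pgp"]["jmax_umol_h"]),
                                 km=float(row["pgp"]["km_u"]))
    return CompoundSpec(
        id=cid,
        mw_g_mol=float(row["mw_g_mol"]),
        binding=BindingParams(float(b["fu_plasma"]), float(b["bp_ratio"]),
                              float(b.get("fu_gut", 1.0))),
        distribution=DistributionParams(float(d["vss_l_kg"]),
                                        float(d.get("central_fraction", 1.0)),
                                        float(d.get("q_l_h", 0.0))),
        peff_1e4_cm_s=float(row.get("peff_1e4_cm_s", 0.0)),
        colon_absorption=bool(row.get("colon_absorption", False)),
        solubility_mg_ml=row.get("solubility_mg_ml"),
        diffusion_cm2_s=float(row.get("diffusion_cm2_s", 5.0e-6)),
        kbl_h=float(row.get("kbl_h", 0.0)),
        bl_scalar=float(row.get("bl_scalar", 1.0)),
        gut_pathways=[_pathway("gut", p) for p in row.get("gut_pathways", [])],
        pgp=pgp,
        liver_pathways=[_pathway("liver", p) for p in row.get("liver_pathways", [])],
        clint_bile_l_h=float(row.get("clint_bile_l_h", 0.0)),
        cl_renal_l_h=float(row.get("cl_renal_l_h", 0.0)),
        cl_other_l_h=float(row.get("cl_other_l_h", 0.0)),
        plasma_halflife_min=row.get("plasma_halflife_min"),
        plasma_product=row.get("plasma_product"),
    )


def load_compounds(path=None) -> list[CompoundSpec]:
    """Load the compound cascade from YAML (shipped fixture by default)."""
    if path is None:
        text = resources.files("dabepbpk.data").joinpath("compounds.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return [_from_dict(cid, row) for cid, row in raw.items()]


def compound_map(compounds: list[CompoundSpec]) -> dict[str, CompoundSpec]:
    out = {c.id: c for c in compounds}
    if len(out) != len(compounds):
        raise ConfigurationError("duplicate compound ids")
    return out


def clone_compounds(compounds: list[CompoundSpec]) -> list[CompoundSpec]:
    return copy.deepcopy(compounds)
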