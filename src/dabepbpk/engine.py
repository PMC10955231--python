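"""Model assembly and ODE integration.

``build_model`` turns a compound cascade, a physiology and a scenario into
one indexed ODE system; ``simulate`` integrates it piecewise over dose
events with latched precipitation triggers and audits the mass balance;
``simulate_population`` layers log-normal between-subject variability on
top.  State ordering (documented, deterministic):

1. substrate lumen pools: solid, dissolved, precipitated (9 segments each)
2. enterocyte amounts, one row per gut-resident compound x 9 segments
3. systemic amounts, one row per compound: portal, liver, central, peripheral
4. gut and liver CYP3A active fractions (enzyme-turnover states)
5. perpetrator states (stomach, lumen, central [, metabolite central]) per
   perpetrator
6. cumulative flux accumulators (the ledger)

Units: amounts umol, time h, concentrations uM, plasma output ng/mL.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import gut as gutmod
from .compounds import CompoundSpec, clone_compounds, compound_map
from .ddi import PerpetratorSpec, mbi_inactivation_rate
from .errors import ComparisonError, ConfigurationError, SolverError
from .gut import FormulationSpec, dissolution_coefficient
from .physiology import PhysiologySpec, default_physiology

__all__ = ["ScenarioSpec", "PopulationSpec", "SimulationResult",
           "build_model", "simulate", "simulate_population", "run_scenario"]

SINK = "oxidative_sink"


@dataclass
class PopulationSpec:
    n_subjects: int = 10
    n_trials: int = 10
    cv_map: dict = field(default_factory=dict)   # parameter path -> CV%
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("population block requires a seed")


@dataclass
class ScenarioSpec:
    """Dosing scenario: substrate regimen, formulation, perpetrators,
    horizon and solver settings."""

    substrate: str
    dose_mg: float
    formulation: FormulationSpec = field(default_factory=FormulationSpec)
    substrate_start_h: float = 0.0
    n_doses: int = 1
    interval_h: float = 24.0
    perpetrators: list[PerpetratorSpec] = field(default_factory=list)
    horizon_h: float = 48.0
    output_dt_h: float = 0.1
    rtol: float = 1e-7
    atol_scale: float = 1e-12     # atol = atol_scale * dose_umol (floor 1e-12)
    population: PopulationSpec | None = None

    def substrate_dose_times(self) -> np.ndarray:
        return self.substrate_start_h + self.interval_h * np.arange(self.n_doses)


class Model:
    """Indexed ODE system ready for integration (see module docstring for
    the state layout)."""

    def __init__(self, compounds, physiology, scenario):
        self.compounds = compounds
        self.physiology = physiology
        self.scenario = scenario
        self.cmap = compound_map(compounds)
        self._validate()
        self._index()
        self._precompute()

    # ------------------------------------------------------------------
    def _validate(self):
        ids = set(self.cmap)
        if self.scenario.substrate not in ids:
            raise ConfigurationError(
                f"substrate {self.scenario.substrate!r} not among compounds")
        for c in self.compounds:
            for prod in c.products():
                if prod not in ids:
                    raise ConfigurationError(
                        f"unresolved product {prod!r} of compound {c.id!r}")
        # routing cycle detection on the conversion graph
        graph = {c.id: c.products() for c in self.compounds}
        state = {}

        def visit(node):
            state[node] = 1
            for nxt in graph[node]:
                if state.get(nxt) == 1:
                    raise ConfigurationError(
                        f"routing cycle through {node!r} -> {nxt!r}")
                if state.get(nxt) is None:
                    visit(nxt)
            state[node] = 2

        for cid in graph:
            if state.get(cid) is None:
                visit(cid)
        # orphan warning: a compound unreachable from the substrate
        reach, stack = set(), [self.scenario.substrate]
        while stack:
            node = stack.pop()
            if node in reach:
                continue
            reach.add(node)
            stack.extend(graph[node])
        for cid in graph:
            if cid not in reach:
                warnings.warn(f"compound {cid!r} is orphaned: no conversion "
                              "route reaches it from the substrate")

    # ------------------------------------------------------------------
    def _index(self):
        ns = self.physiology.n_segments
        sub = self.cmap[self.scenario.substrate]
        # gut-resident compounds: the substrate plus anything formed by a
        # gut pathway (transitively)
        gut_ids = [sub.id]
        for c in self.compounds:
            for pw in c.gut_pathways:
                if pw.product_id != SINK and pw.product_id not in gut_ids:
                    gut_ids.append(pw.product_id)
        self.gut_ids = gut_ids
        self.comp_ids = [c.id for c in self.compounds]

        i = 0
        self.i_sol = slice(i, i + ns); i += ns
        self.i_dis = slice(i, i + ns); i += ns
        self.i_pre = slice(i, i + ns); i += ns
        self.i_ent = slice(i, i + ns * len(gut_ids)); i += ns * len(gut_ids)
        self.i_sys = slice(i, i + 4 * len(self.compounds))
        i += 4 * len(self.compounds)
        self.i_eg, self.i_el = i, i + 1; i += 2
        self.perp_slices = []
        for p in self.scenario.perpetrators:
            n = 3 + (1 if p.metabolite is not None else 0)
            self.perp_slices.append(slice(i, i + n)); i += n
        self.acc_index = {}

        def acc(name):
            nonlocal i
            self.acc_index[name] = i
            i += 1

        acc("apical_in"); acc("efflux"); acc("stool")
        for cid in gut_ids:
            acc(f"baso:{cid}")
        for cid in gut_ids:
            for j, pw in enumerate(self.cmap[cid].gut_pathways):
                acc(f"gutmet:{cid}:{j}")
        for c in self.compounds:
            acc(f"liverin:{c.id}"); acc(f"liverout:{c.id}")
            for j, pw in enumerate(c.liver_pathways):
                acc(f"livermet:{c.id}:{j}")
            if c.clint_bile_l_h > 0:
                acc(f"bile:{c.id}")
            acc(f"celim:{c.id}")
            if c.plasma_k_h > 0:
                acc(f"plasmaconv:{c.id}")
        self.n_states = i

    # ------------------------------------------------------------------
    def _precompute(self):
        phys, sc = self.physiology, self.scenario
        ns = phys.n_segments
        sub = self.cmap[sc.substrate]
        self.sub = sub
        self.kt = 1.0 / phys.array("transit_time_h")
        self.v_lum = phys.array("fluid_volume_ml") / 1000.0
        self.v_ent = phys.array("enterocyte_volume_ml") / 1000.0
        self.cyp_w = phys.array("cyp3a_abundance_fraction")
        self.pgp_w = phys.array("pgp_weight")
        radius = phys.array("radius_cm")
        self.seg_absorptive = (self.v_ent > 0)
        colon = np.array([s.name == "colon" for s in phys.segments])

        # apical uptake rate constants per gut compound (lumen only exists
        # for the substrate, but metabolites keep a basolateral rate)
        ka = gutmod.absorption_rate_constant(sub.peff_1e4_cm_s, radius)
        ka = np.where(self.seg_absorptive, ka, 0.0)
        if not sub.colon_absorption:
            ka = np.where(colon, 0.0, ka)
        self.ka_sub = ka

        # enterocyte-volume weights for CES (expression follows mucosal mass)
        ventw = np.where(self.seg_absorptive, self.v_ent, 0.0)
        self.ces_w = ventw / ventw.sum()

        # gut pathway table
        self.gut_pathways = []  # (ci, vmax_seg, km, prod_ci|-1, is_cyp, acc)
        for ci, cid in enumerate(self.gut_ids):
            comp = self.cmap[cid]
            for j, pw in enumerate(comp.gut_pathways):
                w = self.cyp_w if pw.is_cyp else self.ces_w
                prod = -1 if pw.product_id == SINK else self.gut_ids.index(
                    pw.product_id)
                self.gut_pathways.append(
                    (ci, pw.isef * pw.vmax * w, pw.km_u, prod, pw.is_cyp,
                     self.acc_index[f"gutmet:{cid}:{j}"]))

        # P-gp (substrate only)
        if sub.pgp is not None:
            self.jmax_seg = sub.pgp.jmax * self.pgp_w
            self.km_pgp = sub.pgp.km
        else:
            self.jmax_seg = None
        for cid in self.gut_ids:
            if cid != sub.id and self.cmap[cid].pgp is not None:
                warnings.warn(f"P-gp on non-substrate compound {cid!r} ignored")

        self.kbl_eff = np.array(
            [self.cmap[cid].kbl_h * self.cmap[cid].bl_scalar
             for cid in self.gut_ids])
        self.fu_gut = np.array(
            [self.cmap[cid].binding.fu_gut for cid in self.gut_ids])

        # systemic constants per compound
        bw = phys.body_weight_kg
        self.vpv, self.vli = phys.portal_volume_l, phys.liver_volume_l
        self.qpv = phys.q_portal_l_h
        self.qha = phys.qh_l_h - phys.q_portal_l_h
        self.qh = phys.qh_l_h
        self.vc = np.empty(len(self.compounds))
        self.vper = np.empty(len(self.compounds))
        self.qd = np.empty(len(self.compounds))
        self.fu_b = np.empty(len(self.compounds))
        self.cl_ren = np.empty(len(self.compounds))
        self.cl_oth = np.empty(len(self.compounds))
        self.k_plasma = np.empty(len(self.compounds))
        self.plasma_prod = np.full(len(self.compounds), -1)
        self.clint_bile = np.empty(len(self.compounds))
        for ci, c in enumerate(self.compounds):
            vc, vper = c.distribution.volumes(bw)
            self.vc[ci], self.vper[ci] = vc, vper
            self.qd[ci] = c.distribution.q_l_h
            self.fu_b[ci] = c.fu_blood
            self.cl_ren[ci] = c.cl_renal_l_h
            self.cl_oth[ci] = c.cl_other_l_h
            self.k_plasma[ci] = c.plasma_k_h
            if c.plasma_product:
                self.plasma_prod[ci] = self.comp_ids.index(c.plasma_product)
            self.clint_bile[ci] = c.clint_bile_l_h
        self.liver_pathways = []  # (ci, vmax, km, prod_ci|-1, is_cyp, acc)
        for ci, c in enumerate(self.compounds):
            for j, pw in enumerate(c.liver_pathways):
                prod = -1 if pw.product_id == SINK else self.comp_ids.index(
                    pw.product_id)
                self.liver_pathways.append(
                    (ci, pw.isef * pw.vmax, pw.km_u, prod, pw.is_cyp,
                     self.acc_index[f"livermet:{c.id}:{j}"]))

        # solubility / dissolution / precipitation (substrate only)
        self.sol_um = sub.solubility_um
        form = sc.formulation
        self.form = form
        dose_umol = sc.dose_mg * 1000.0 / sub.mw_g_mol
        self.dose_umol_per_admin = dose_umol
        if form.form == "solid_IR" and self.sol_um is not None:
            self.dlm = dissolution_coefficient(
                sub.diffusion_cm2_s, form.density_g_ml,
                form.particle_radius_um, dose_umol, sub.mw_g_mol)
        else:
            self.dlm = None
        self.latched = np.zeros(ns, dtype=bool)

        # perpetrators
        self.perp = []
        si_fluid = float(self.v_lum[self.seg_absorptive & ~colon].sum())
        self.si_fluid_l = si_fluid
        self.qvilli = phys.villous_flow_total_l_h
        for k, p in enumerate(sc.perpetrators):
            self.perp.append(_PerpRuntime(p, self, self.perp_slices[k]))

        self.kdeg_gut = phys.kdeg_cyp3a_gut_h
        self.kdeg_liv = phys.kdeg_cyp3a_liver_h
        self.gut_to_comp = np.array(
            [self.comp_ids.index(cid) for cid in self.gut_ids])

    # ------------------------------------------------------------------
    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_states)
        y0[self.i_eg] = 1.0
        y0[self.i_el] = 1.0
        return y0

    def apply_substrate_dose(self, y):
        """Instantaneous addition of one administration to the stomach."""
        amt = self.dose_umol_per_admin
        if self.form.form == "solid_IR":
            y[self.i_sol.start] += amt
        else:
            y[self.i_dis.start] += amt
        return y

    # ------------------------------------------------------------------
    def perp_inhibition(self, y):
        """Aggregate inhibition terms from all perpetrator species.

        Returns (cf_pgp, cf_cyp_gut, cf_cyp_liver, lam_gut, lam_liver):
        competitive Km multipliers and MBI inactivation hazards.
        """
        pgp_pairs, cg_pairs, cl_pairs = [], [], []
        lam_g = lam_l = 0.0
        for pr in self.perp:
            sl = y[pr.sl]
            conc = pr.concentrations(sl)
            for species, term in pr.spec.terms():
                c = conc[species]
                if term.target == "P-gp":
                    i_u = c["lumen"] + c["enterocyte"]
                    if term.mechanism == "competitive":
                        pgp_pairs.append((i_u, term.ki_u))
                elif term.organ == "gut":
                    i_u = c["enterocyte"]
                    if term.mechanism == "competitive":
                        cg_pairs.append((i_u, term.ki_u))
                    else:
                        lam_g += mbi_inactivation_rate(i_u, term.kinact,
                                                       term.ki_app_u)
                else:
                    i_u = c["portal_u"]
                    if term.mechanism == "competitive":
                        cl_pairs.append((i_u, term.ki_u))
                    else:
                        lam_l += mbi_inactivation_rate(i_u, term.kinact,
                                                       term.ki_app_u)
        from .ddi import competitive_factor
        return (competitive_factor(pgp_pairs), competitive_factor(cg_pairs),
                competitive_factor(cl_pairs), lam_g, lam_l)

    # ------------------------------------------------------------------
    def rhs(self, t, y):
        dy = np.zeros_like(y)
        ns = self.physiology.n_segments
        ngut = len(self.gut_ids)
        ncomp = len(self.compounds)

        sol = y[self.i_sol]
        dis = y[self.i_dis]
        ent = y[self.i_ent].reshape(ngut, ns)
        sysm = y[self.i_sys].reshape(ncomp, 4)
        d_sol = dy[self.i_sol]
        d_dis = dy[self.i_dis]
        d_pre = dy[self.i_pre]
        d_ent = dy[self.i_ent].reshape(ngut, ns)
        d_sys = dy[self.i_sys].reshape(ncomp, 4)
        acc = self.acc_index

        if self.perp:
            cf_pgp, cf_cg, cf_cl, lam_g, lam_l = self.perp_inhibition(y)
        else:
            cf_pgp = cf_cg = cf_cl = 1.0
            lam_g = lam_l = 0.0

        e_gut = y[self.i_eg]
        e_liv = y[self.i_el]
        dy[self.i_eg] = self.kdeg_gut * (1.0 - e_gut) - e_gut * lam_g
        dy[self.i_el] = self.kdeg_liv * (1.0 - e_liv) - e_liv * lam_l

        # ---- substrate lumen -------------------------------------------
        c_lum = np.maximum(dis, 0.0) / self.v_lum
        if self.sol_um is not None:
            s = self.sol_um
            target = np.where(self.latched, s, self.form.csr * s)
            if self.dlm is not None:
                flux_dis = gutmod.dissolution_flux(
                    np.maximum(sol, 0.0), c_lum, s, self.dlm,
                    supersaturation_limit=target)
            else:
                flux_dis = 0.0
            flux_pre = gutmod.precipitation_flux(
                c_lum, s, self.form, self.v_lum, self.latched)
        else:
            flux_dis = 0.0
            flux_pre = 0.0

        flux_abs = self.ka_sub * np.maximum(dis, 0.0)

        # serial transit of all three pools
        for pool, dpool in ((sol, d_sol), (dis, d_dis),
                            (y[self.i_pre], d_pre)):
            out = self.kt * pool
            dpool -= out
            dpool[1:] += out[:-1]
            dy[acc["stool"]] += out[-1]

        d_sol -= flux_dis
        d_dis += flux_dis - flux_pre - flux_abs
        d_pre += flux_pre

        # ---- enterocytes ----------------------------------------------
        cu = np.zeros((ngut, ns))
        np.divide(self.fu_gut[:, None] * np.maximum(ent, 0.0),
                  self.v_ent[None, :], out=cu,
                  where=self.v_ent[None, :] > 0)

        d_ent[0] += flux_abs
        dy[acc["apical_in"]] += flux_abs.sum()

        if self.jmax_seg is not None:
            eff = gutmod.pgp_efflux(cu[0], self.jmax_seg, self.km_pgp, cf_pgp)
            d_ent[0] -= eff
            d_dis += eff
            dy[acc["efflux"]] += eff.sum()

        for ci, vmax_seg, km, prod, is_cyp, ai in self.gut_pathways:
            factor = cf_cg if is_cyp else 1.0
            act = e_gut if is_cyp else 1.0
            rate = gutmod.michaelis_rate(cu[ci], vmax_seg, km, factor, act)
            d_ent[ci] -= rate
            if prod >= 0:
                d_ent[prod] += rate
            dy[ai] += rate.sum()

        for ci, cid in enumerate(self.gut_ids):
            baso = self.kbl_eff[ci] * np.maximum(ent[ci], 0.0)
            total = baso.sum()
            d_ent[ci] -= baso
            d_sys[self.gut_to_comp[ci], 0] += total
            dy[acc[f"baso:{cid}"]] += total

        # ---- systemic ---------------------------------------------------
        cpv = sysm[:, 0] / self.vpv
        cli = sysm[:, 1] / self.vli
        cc = sysm[:, 2] / self.vc
        cper = np.zeros(ncomp)
        np.divide(sysm[:, 3], self.vper, out=cper, where=self.vper > 0)

        d_sys[:, 0] += self.qpv * (cc - cpv)
        liver_in = self.qpv * cpv + self.qha * cc
        liver_out = self.qh * cli
        d_sys[:, 1] += liver_in - liver_out
        d_sys[:, 2] += liver_out - self.qh * cc
        exch = self.qd * (cc - cper)
        d_sys[:, 2] -= exch
        d_sys[:, 3] += exch
        celim = (self.cl_ren + self.cl_oth) * cc
        d_sys[:, 2] -= celim

        cu_li = self.fu_b * np.maximum(cli, 0.0)
        for ci, c in enumerate(self.compounds):
            dy[acc[f"liverin:{c.id}"]] += liver_in[ci]
            dy[acc[f"liverout:{c.id}"]] += liver_out[ci]
            dy[acc[f"celim:{c.id}"]] += celim[ci]
            if self.clint_bile[ci] > 0:
                bile = self.clint_bile[ci] * cu_li[ci]
                d_sys[ci, 1] -= bile
                dy[acc[f"bile:{c.id}"]] += bile

        for ci, vmax, km, prod, is_cyp, ai in self.liver_pathways:
            factor = cf_cl if is_cyp else 1.0
            act = e_liv if is_cyp else 1.0
            rate = gutmod.michaelis_rate(cu_li[ci], vmax, km, factor, act)
            d_sys[ci, 1] -= rate
            if prod >= 0:
                d_sys[prod, 1] += rate
                dy[acc[f"liverin:{self.comp_ids[prod]}"]] += rate
            dy[ai] += rate

        # plasma esterase conversion in portal + central blood
        for ci in range(ncomp):
            k = self.k_plasma[ci]
            if k <= 0:
                continue
            prod = self.plasma_prod[ci]
            f_pv = k * max(sysm[ci, 0], 0.0)
            f_c = k * max(sysm[ci, 2], 0.0)
            d_sys[ci, 0] -= f_pv
            d_sys[ci, 2] -= f_c
            d_sys[prod, 0] += f_pv
            d_sys[prod, 2] += f_c
            dy[acc[f"plasmaconv:{self.comp_ids[ci]}"]] += f_pv + f_c

        # ---- perpetrator kinetics --------------------------------------
        for pr in self.perp:
            pr.rhs(y[pr.sl], dy[pr.sl])

        return dy

    # ------------------------------------------------------------------
    # Fast finite-difference Jacobian via structural sparsity + column
    # coloring: the dense numerical Jacobian the solver would build costs
    # n rhs evaluations; the colored one costs ~a dozen.
    def _sparsity(self):
        if getattr(self, "_spars", None) is not None:
            return self._spars
        rng = np.random.default_rng(1234)
        n = self.n_states
        pattern = np.zeros((n, n), dtype=bool)
        saved = self.latched.copy()
        try:
            # probe every clamp/latch regime: dilute states keep the
            # dissolution drive (target - C) positive, concentrated ones
            # activate precipitation and saturation branches
            for latch in (False, True):
                self.latched[:] = latch
                for scale in (1e-4, 1.0):
                    y = rng.uniform(0.5, 2.0, n) * scale
                    f0 = self.rhs(0.0, y)
                    for j in range(n):
                        yp = y.copy()
                        yp[j] = yp[j] * 1.001 + 1e-9 * scale
                        pattern[:, j] |= np.abs(self.rhs(0.0, yp) - f0) > 0
        finally:
            self.latched[:] = saved
        # greedy column coloring: columns with disjoint row support share a
        # perturbation group
        groups, assigned = [], np.full(n, -1)
        for j in range(n):
            placed = False
            for gi, (cols, rows) in enumerate(groups):
                if not (pattern[:, j] & rows).any():
                    cols.append(j)
                    rows |= pattern[:, j]
                    assigned[j] = gi
                    placed = True
                    break
            if not placed:
                assigned[j] = len(groups)
                groups.append(([j], pattern[:, j].copy()))
        self._spars = (pattern, [np.array(c) for c, _ in groups])
        return self._spars

    def jacobian(self, t, y):
        pattern, groups = self._sparsity()
        n = self.n_states
        jac = np.zeros((n, n))
        f0 = self.rhs(t, y)
        for cols in groups:
            h = 1e-8 * np.maximum(np.abs(y[cols]), 1e-3)
            yp = y.copy()
            yp[cols] += h
            df = self.rhs(t, yp) - f0
            for j, hj in zip(cols, h):
                rows = pattern[:, j]
                jac[rows, j] = df[rows] / hj
        return jac

    # ------------------------------------------------------------------
    def mass_in_system(self, y) -> float:
        """Total substrate-equivalent amount accounted for (umol)."""
        acc = self.acc_index
        total = (y[self.i_sol].sum() + y[self.i_dis].sum()
                 + y[self.i_pre].sum() + y[self.i_ent].sum()
                 + y[self.i_sys].sum() + y[acc["stool"]])
        for ci, cid in enumerate(self.gut_ids):
            comp = self.cmap[cid]
            for j, pw in enumerate(comp.gut_pathways):
                if pw.product_id == SINK:
                    total += y[acc[f"gutmet:{cid}:{j}"]]
        for c in self.compounds:
            for j, pw in enumerate(c.liver_pathways):
                if pw.product_id == SINK:
                    total += y[acc[f"livermet:{c.id}:{j}"]]
            if c.clint_bile_l_h > 0:
                total += y[acc[f"bile:{c.id}"]]
            total += y[acc[f"celim:{c.id}"]]
        return total


class _PerpRuntime:
    """Per-perpetrator state block: stomach, lumen, central
    [, metabolite central], with exposure read-outs at the interaction
    sites."""

    def __init__(self, spec: PerpetratorSpec, model: Model, sl: slice):
        self.spec = spec
        self.sl = sl
        self.ke_st = 4.0                       # gastric emptying, 1/h
        self.k_out = 1.0 / 3.5                 # small-intestinal washout
        self.si_fluid = model.si_fluid_l
        self.qvilli = model.qvilli
        self.qpv = model.qpv
        self.dose_umol = (spec.regimen.dose_mg * 1000.0 / spec.pk.mw_g_mol)
        self.has_met = spec.metabolite is not None

    def rhs(self, y, dy):
        pk = self.spec.pk
        st, lum, cen = y[0], y[1], y[2]
        dy[0] += -self.ke_st * st
        dy[1] += self.ke_st * st - (pk.ka_h + self.k_out) * lum
        elim = pk.ke_h * max(cen, 0.0)
        dy[2] += pk.ka_h * lum - elim
        if self.has_met:
            met = self.spec.metabolite
            dy[3] += met.formation_fraction * elim \
                - met.cl_l_h / met.v_l * max(y[3], 0.0)

    def concentrations(self, y) -> dict:
        """Unbound exposures (uM) of parent and metabolite at the
        interaction sites.  The parent's enterocyte concentration follows
        its absorption flux over villous blood flow; the liver inlet adds
        the absorption flux over portal flow to the systemic level; the
        metabolite (formed systemically) acts through its plasma unbound
        concentration everywhere."""
        pk = self.spec.pk
        lum = max(y[1], 0.0)
        cen = max(y[2], 0.0)
        c_sys_u = pk.fu_plasma * cen / pk.v_f_l
        out = {"parent": {
            "lumen": lum / self.si_fluid,
            "enterocyte": pk.ka_h * lum / self.qvilli,
            "portal_u": c_sys_u + pk.fu_plasma * pk.ka_h * lum / self.qpv,
        }}
        if self.has_met:
            met = self.spec.metabolite
            cm_u = met.fu_plasma * max(y[3], 0.0) / met.v_l
            out["metabolite"] = {"lumen": cm_u, "enterocyte": cm_u,
                                 "portal_u": cm_u}
        return out


# ----------------------------------------------------------------------
@dataclass
class SimulationResult:
    """Time grids, concentrations, flux ledger and first-pass summary."""

    times: np.ndarray                 # h, global clock
    conc: dict                        # compound id -> plasma ng/mL
    substrate: str
    dose_mg: float
    substrate_start_h: float
    ledger: dict
    first_pass: dict
    fh: dict
    mass_balance_residual: float
    states: np.ndarray | None = None
    solver_stats: dict = field(default_factory=dict)

    @property
    def times_after_dose(self) -> np.ndarray:
        mask = self.times >= self.substrate_start_h - 1e-12
        return self.times[mask] - self.substrate_start_h

    def profile(self, compound: str) -> np.ndarray:
        mask = self.times >= self.substrate_start_h - 1e-12
        return self.conc[compound][mask]


def build_model(compounds, physiology=None, scenario=None,
                overrides=None) -> Model:
    """Assemble the indexed ODE system; validates the conversion cascade
    (every product resolves, no routing cycles) before indexing."""
    if physiology is None:
        physiology = default_physiology()
    if scenario is None:
        raise ConfigurationError("a ScenarioSpec is required")
    compounds = clone_compounds(compounds)
    if overrides:
        scenario = replace(scenario,
                           formulation=replace(scenario.formulation))
        apply_overrides(compounds, scenario, overrides)
    return Model(compounds, physiology, scenario)


_PATH_RE = re.compile(
    r"^(?P<head>\w+)(?:\.(?P<sub>gut|liver)\[(?P<idx>\d+)\])?"
    r"(?:\.(?P<field>[\w.]+))?$")


def apply_overrides(compounds, scenario, overrides: dict):
    """Set parameters by dotted path, e.g. ``bibr0951.clint_bile_l_h``,
    ``dabe.gut[0].vmax``, ``dabe.pgp.jmax``, ``formulation.csr``,
    ``dab.distribution.vss_l_kg``."""
    cmap = compound_map(compounds)
    for path, value in overrides.items():
        m = _PATH_RE.match(path)
        if not m:
            raise ConfigurationError(f"cannot parse override path {path!r}")
        head, sub, idx, fld = m.group("head", "sub", "idx", "field")
        if head == "formulation":
            setattr(scenario.formulation, fld, float(value))
            continue
        if head not in cmap:
            raise ConfigurationError(f"unknown compound {head!r} in override")
        target = cmap[head]
        if sub is not None:
            pws = target.gut_pathways if sub == "gut" else target.liver_pathways
            setattr(pws[int(idx)], fld, float(value))
            continue
        obj = target
        parts = fld.split(".")
        for part in parts[:-1]:
            obj = getattr(obj, part)
        if not hasattr(obj, parts[-1]):
            raise ConfigurationError(f"unknown field {fld!r} on {head!r}")
        setattr(obj, parts[-1], float(value))


def simulate(model: Model, keep_states: bool = False) -> SimulationResult:
    """Integrate the model piecewise over dose events.

    Precipitation triggers are handled as terminal integration events: when
    a segment's luminal concentration first reaches CSR x solubility the
    segment latches and integration restarts with precipitation active
    there.  The returned result carries a mass-balance audit (max residual
    over the output grid, as a fraction of administered dose).
    """
    sc = model.scenario
    t_grid = np.arange(0.0, sc.horizon_h + sc.output_dt_h / 2, sc.output_dt_h)
    dose_events = [(float(t), "substrate") for t in sc.substrate_dose_times()]
    for pr in model.perp:
        for t in pr.spec.regimen.dose_times:
            dose_events.append((float(t), pr))
    dose_events.sort(key=lambda x: x[0])
    if any(t > sc.horizon_h for t, _ in dose_events):
        raise ConfigurationError("dose scheduled beyond the horizon")

    dose_umol = model.dose_umol_per_admin
    atol = max(model.scenario.atol_scale * max(dose_umol, 1e-6), 1e-15)

    model.latched[:] = False
    y = model.initial_state()
    t_now = 0.0
    ts_out = [np.array([0.0])]
    ys_out = [y[None, :].copy()]
    dosed = [0.0]
    n_rhs = 0

    nodes = [t for t, _ in dose_events] + [sc.horizon_h]
    events_by_node = {}
    for t, what in dose_events:
        events_by_node.setdefault(t, []).append(what)

    total_dosed = 0.0
    uniq_nodes = sorted(set(nodes))
    has_precip = (model.sol_um is not None and model.form.prc > 0)

    for node in uniq_nodes:
        # integrate from t_now to node
        while node - t_now > 1e-12:
            # latch pre-check
            if has_precip:
                c = np.maximum(y[model.i_dis], 0.0) / model.v_lum
                model.latched |= (c >= model.form.csr * model.sol_um
                                  * (1 - 1e-12))
                ev = _make_latch_events(model)
            else:
                ev = []
            mask = (t_grid > t_now + 1e-12) & (t_grid <= node + 1e-12)
            t_eval = np.concatenate([t_grid[mask], [node]])
            t_eval = np.unique(t_eval)
            sol = solve_ivp(model.rhs, (t_now, node), y, method="LSODA",
                            t_eval=t_eval, events=ev, rtol=sc.rtol,
                            atol=atol, jac=model.jacobian,
                            dense_output=False)
            if not sol.success:
                raise SolverError(f"integration failed: {sol.message}",
                                  t_failure=t_now)
            n_rhs += sol.nfev
            sol_t = np.asarray(sol.t, dtype=float)
            sol_y = np.asarray(sol.y, dtype=float)
            if sol_y.size == 0:
                sol_y = sol_y.reshape(len(y), 0)
            if sol.t_events and any(len(te) for te in sol.t_events):
                t_ev = min(te[0] for te in sol.t_events if len(te))
                # keep output points strictly before the event
                keep = sol_t < t_ev - 1e-12
                ts_out.append(sol_t[keep])
                ys_out.append(sol_y[:, keep].T)
                dosed.extend([total_dosed] * int(keep.sum()))
                y = _event_state(sol)
                t_now = t_ev
                # latch any segment at/above threshold
                c = np.maximum(y[model.i_dis], 0.0) / model.v_lum
                model.latched |= (c >= model.form.csr * model.sol_um
                                  * (1 - 1e-9))
            else:
                ts_out.append(sol_t)
                ys_out.append(sol_y.T)
                dosed.extend([total_dosed] * len(sol_t))
                y = sol_y[:, -1].copy()
                t_now = node
        # apply doses at this node
        for what in events_by_node.get(node, []):
            if what == "substrate":
                model.apply_substrate_dose(y)
                total_dosed += dose_umol
            else:
                y[what.sl.start] += what.dose_umol
        # re-record state right after dosing
        ts_out.append(np.array([node]))
        ys_out.append(y[None, :].copy())
        dosed.append(total_dosed)

    times = np.concatenate(ts_out)
    states = np.vstack(ys_out)
    dosed = np.asarray(dosed)
    # collapse duplicate times, keeping the post-dose sample
    order = np.argsort(times, kind="stable")
    times, states, dosed = times[order], states[order], dosed[order]
    keep = np.ones(len(times), dtype=bool)
    keep[:-1] = np.diff(times) > 1e-12
    times, states, dosed = times[keep], states[keep], dosed[keep]

    return _summarize(model, times, states, dosed,
                      keep_states=keep_states, n_rhs=n_rhs)


def _event_state(sol):
    for te, ye in zip(sol.t_events, sol.y_events):
        if len(te):
            return ye[0].copy()
    raise RuntimeError("no event state")  # pragma: no cover


def _make_latch_events(model):
    thr = model.form.csr * model.sol_um
    events = []
    for s in np.flatnonzero(~model.latched):
        def g(t, y, s=s):
            return y[model.i_dis][s] / model.v_lum[s] - thr
        g.terminal = True
        g.direction = 1.0
        events.append(g)
    return events


def _summarize(model, times, states, dosed, keep_states, n_rhs):
    sc = model.scenario
    acc = model.acc_index
    yT = states[-1]
    ledger = {name: float(yT[idx]) for name, idx in acc.items()}

    # plasma concentrations, ng/mL
    conc = {}
    sysm = states[:, model.i_sys].reshape(len(times), len(model.compounds), 4)
    for ci, c in enumerate(model.compounds):
        cb = sysm[:, ci, 2] / model.vc[ci]          # uM in blood
        conc[c.id] = cb / c.binding.bp_ratio * c.mw_g_mol

    # mass balance audit
    residuals = np.empty(len(times))
    for i in range(len(times)):
        residuals[i] = dosed[i] - model.mass_in_system(states[i])
    total_dose = dosed[-1]
    mb = float(np.max(np.abs(residuals)) / total_dose) if total_dose > 0 \
        else float(np.max(np.abs(residuals)))

    # first-pass summary
    gut_formed = {}
    for ci, vmax_seg, km, prod, is_cyp, ai in model.gut_pathways:
        if prod >= 0:
            pid = model.gut_ids[prod]
            gut_formed[pid] = gut_formed.get(pid, 0.0) + float(yT[ai])
    led = {
        "apical_in": ledger["apical_in"],
        "efflux": ledger["efflux"],
        "basolateral": {cid: ledger[f"baso:{cid}"] for cid in model.gut_ids},
        "gut_formed": gut_formed,
    }
    if total_dose > 0:
        fp = gutmod.first_pass_summary(led, total_dose, sc.substrate,
                                       model.gut_ids)
    else:
        fp = {}
    liver_in = {c.id: ledger[f"liverin:{c.id}"] for c in model.compounds}
    liver_out = {c.id: ledger[f"liverout:{c.id}"] for c in model.compounds}
    from .disposition import fh_summary
    fh = fh_summary(liver_in, liver_out)

    return SimulationResult(
        times=times, conc=conc, substrate=sc.substrate, dose_mg=sc.dose_mg,
        substrate_start_h=float(sc.substrate_start_h), ledger=ledger,
        first_pass=fp, fh=fh, mass_balance_residual=mb,
        states=states if keep_states else None,
        solver_stats={"n_rhs": n_rhs, "n_times": len(times)},
    )


def run_scenario(compounds, scenario, physiology=None, overrides=None,
                 keep_states=False) -> SimulationResult:
    """Convenience: build + simulate in one call."""
    model = build_model(compounds, physiology, scenario, overrides)
    return simulate(model, keep_states=keep_states)


def simulate_population(compounds, scenario, physiology=None,
                        overrides=None):
    """Virtual-trial simulation with log-normal between-subject variability.

    Each subject draws one multiplicative log-normal factor (median 1,
    CV as configured) per entry of ``cv_map`` and is simulated as a mean
    individual otherwise.  Returns the pooled percentile bands (5th, 50th,
    95th) of every compound's plasma profile plus the per-trial band list.
    """
    pop = scenario.population
    if pop is None:
        raise ConfigurationError("scenario has no population block")
    rng = np.random.default_rng(pop.seed)
    base_overrides = dict(overrides or {})
    cmap = compound_map(compounds)
    base_vals = {}
    probe = clone_compounds(compounds)
    probe_sc = replace(scenario, formulation=replace(scenario.formulation))
    apply_overrides(probe, probe_sc, base_overrides)
    for path in pop.cv_map:
        base_vals[path] = _read_path(probe, probe_sc, path)

    all_profiles = []
    trials = []
    times_ref = None
    for trial in range(pop.n_trials):
        trial_profiles = []
        for subj in range(pop.n_subjects):
            ov = dict(base_overrides)
            for path, cv in pop.cv_map.items():
                sigma = math.sqrt(math.log(1.0 + (cv / 100.0) ** 2))
                ov[path] = base_vals[path] * math.exp(sigma * rng.standard_normal())
            res = run_scenario(compounds, scenario, physiology, ov)
            if times_ref is None:
                times_ref = res.times
            trial_profiles.append(res.conc)
        all_profiles.extend(trial_profiles)
        trials.append(trial_profiles)

    def bands(profiles):
        out = {}
        for cid in cmap:
            arr = np.vstack([p[cid] for p in profiles])
            out[cid] = {
                "p5": np.percentile(arr, 5, axis=0),
                "p50": np.percentile(arr, 50, axis=0),
                "p95": np.percentile(arr, 95, axis=0),
            }
        return out

    return {
        "times": times_ref,
        "pooled": bands(all_profiles),
        "per_trial": [bands(tp) for tp in trials],
        "n_subjects": pop.n_subjects * pop.n_trials,
    }


def _read_path(compounds, scenario, path):
    m = _PATH_RE.match(path)
    if not m:
        raise ConfigurationError(f"cannot parse path {path!r}")
    head, sub, idx, fld = m.group("head", "sub", "idx", "field")
    if head == "formulation":
        return getattr(scenario.formulation, fld)
    cmap = compound_map(compounds)
    target = cmap[head]
    if sub is not None:
        pws = target.gut_pathways if sub == "gut" else target.liver_pathways
        return getattr(pws[int(idx)], fld)
    obj = target
    parts = fld.split(".")
    for part in parts[:-1]:
        obj = getattr(obj, part)
    return getattr(obj, parts[-1])
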