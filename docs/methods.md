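# Methods

## The model

`dabepbpk` simulates the oral disposition of dabigatran etexilate (DABE),
a double-ester prodrug, through its two intermediate monoesters to the
active acid dabigatran (DAB):

```
            gut CES2                liver CES1
  DABE ────────────────▶ BIBR0951 ────────────▶ DAB ──▶ renal elimination
    │  (ethyl ester kept)     │  + plasma esterase (t½ 55 min)
    │                         ├─▶ gut/liver CYP3A oxidation (saturable, Km 1–3 µM)
    │                         └─▶ biliary excretion (CLint 273 µL/min/10⁶ cells)
    ├─▶ gut CYP3A oxidation (minor, saturable)
    └─▶ plasma esterase (t½ 364 min) ──▶ BIBR1087 ── liver CES ──▶ DAB
```

None of the three metabolites is a P-gp substrate; the parent is, with Km
fixed at 2.6 µM and a calibrated whole-gut Jmax.

**Gut.** Nine serial luminal segments (stomach, duodenum, two jejunal,
four ileal, colon) with first-order transit (small-intestinal residence
3.5 h). Each absorptive segment carries solid/dissolved/precipitated
luminal pools for the dosed compound and an enterocyte pool for the
parent and its gut-formed metabolites. Apical uptake is ka = 2·Peff/R;
apical P-gp efflux returns enterocyte drug to the lumen
(Michaelis–Menten on enterocyte unbound concentration, segment weights
distal-heavy); enterocyte CES2 and CYP3A compete for the parent
(CYP3A weights proximal-heavy), and gut-formed BIBR0951 is oxidized by
the same CYP3A pool — its *sole* gut clearance — before escaping
basolaterally. The basolateral escape rate of BIBR0951 carries the 0.1
global scalar reported for it.

**Dissolution / precipitation.** Wang–Flanagan diffusion-layer
dissolution from a monodisperse powder. The particle-surface driving
concentration is CSR×S (CSR 17.9, S = 0.003 mg/mL) while a segment has
not yet nucleated precipitate, and S afterwards; once the luminal
concentration reaches CSR×S a latched per-segment trigger turns on
first-order precipitation at PRC = 2.88 h⁻¹ toward S. Precipitate is
carried by transit but never redissolves (simplest reading of the
mechanism; a re-dissolution toggle is not provided because nothing
constrains it). The supersaturable driving term is a deliberate deviation
from a strict solubility-capped diffusion layer: with the printed
solubility alone, the fraction absorbed at 300 mg could not exceed a few
percent, while supersaturation-limited dissolution reproduces the
reported Fa ≈ 0.4 with an ordinary permeability.

**Body.** Per compound: portal blood, a well-stirred liver (saturable
CES/CYP pathways on unbound liver concentration, biliary CLint as a
terminal sink, products formed in place), a central blood pool and one
peripheral pool (Vss is an input, never predicted). Plasma esterase
hydrolysis is first-order and concentration-independent in portal and
central blood (DABE→BIBR1087, BIBR0951→DAB; BIBR1087 is plasma-stable).
DAB clearance is renal-dominant. DABE and BIBR1087 carry lumped
"other" systemic clearances — the literature does not constrain their
true Vss/CL, and without a non-productive sink every absorbed molecule
would eventually become DAB, an order of magnitude above the observed
~4% molar yield.

**DDI.** Perpetrators are empirical one-compartment oral models with a
gastric/luminal front-end. Site exposures: gut-lumen concentration for
P-gp competition (plus enterocyte), absorption-flux/villous-flow for
enterocyte CYP3A, systemic + absorption-flux/portal-flow unbound for
hepatic CYP3A. Competitive inhibition multiplies Km by 1 + ΣI/Ki;
mechanism-based inhibition drives per-organ enzyme-activity states
de/dt = kdeg(1−e) − e·kinact·I/(KI+I) with kdeg 0.019 h⁻¹ (liver) and
0.03 h⁻¹ (gut). Clarithromycin and verapamil are MBI + P-gp competitive;
itraconazole (+ its hydroxy metabolite, P-gp Ki 2/5 µM) and single-dose
rifampicin are purely competitive. No induction, no CES inhibition.

## Numerics

- Units: µmol / h / µM internally; plasma output in ng/mL via MW and B:P.
- LSODA, piecewise over dose events; precipitation triggers are terminal
  integration events (latch, restart). Default rtol 1e-7, atol scaled to
  the dose. The Jacobian is finite-differenced through a structurally
  probed sparsity pattern with greedy column coloring (~12 rhs calls per
  Jacobian instead of ~100), giving ~4× faster runs with identical
  trajectories to solver tolerance.
- Mass balance is audited at every output point: dose minus (all pools +
  all terminal sinks); the engine holds it at ~1e-14 of dose, against an
  acceptance bound of 1e-6.
- Nelder–Mead estimation works in log/logit-transformed space so box
  bounds never truncate the simplex; the WLS objective defaults to
  relative weights 1/obs² because concentrations span four orders of
  magnitude between micro- and therapeutic doses. Simulation failures
  inside the loss return a large penalty rather than raising.
- Identifiability: from a single oral-solution profile the
  supersaturation pair (CSR, PRC) is close to collinear — a lower
  trigger threshold trades off against a slower precipitation rate with
  sub-percent residual effect on the plasma curve. The recovery tests
  therefore fit jointly across dose arms that straddle the
  supersaturation threshold (a few mg in solution), where the CSR
  response is nearly all-or-nothing, and pre-screen a coarse log-grid
  before Nelder-Mead refinement.
- Morris screening uses the standard p-level one-at-a-time design
  (default 4 levels, 10 trajectories — the source platform's defaults are
  unpublished), with elementary effects computed in unit space so an
  additive linear model yields µ* = |slope| exactly.

## Calibration (what is printed vs what is ours)

Printed values used verbatim: solubility 0.003 mg/mL; CSR 17.9; PRC
2.88 h⁻¹; P-gp Km 2.6 µM; plasma t½ 364 / 55 min; fu,p 0.227 / 0.018;
B:P 0.6; BL scalar 0.1; CLint,bile 273 µL/min/10⁶ cells (scaled to
3243 L/h by hepatocellularity 120×10⁶/g × 1650 g); ITZ/OH-ITZ P-gp Ki
2/5 µM; CYP3A Km values kept inside the reported 1–3 µM band.

Everything else in `data/compounds.yaml` marked "calibrated, not
printed" was fitted, in this order, against the printed clinical tables:
(1) DAB renal clearance and volumes to the microdose exposure
(Cmax 0.15, AUC 1.44 ng·h/mL); (2) the gut CES2/CYP3A split of DABE and
the BIBR0951 pathway constants to the micro- vs therapeutic-dose
clarithromycin ratios; (3) nothing — the printed biopharmaceutic
constants stay fixed; (4) Peff and Jmax to the 300 mg fraction absorbed
and the DDI dissection. The resulting mean-individual model gives
(values the test suite recomputes): microdose Cmax/AUC 0.154/1.40;
300 mg Fa 0.46 and AUC 2377 (inside the printed twofold window
610–2440); CTC AUC ratios 5.7 (micro) and 1.94 (therapeutic) inside
their Guest windows; Fg′/Fg of BIBR0951 3.8 vs 1.2; dose-normalized
microdose exposure 0.47× the 300 mg reference.

## Synthetic data: what a green test establishes

The generators emulate (a) 2 h plasma-decay incubations, (b) 8-point
Michaelis–Menten rate designs, and (c) sparse clinical-like plasma
sampling with multiplicative log-normal error and LLOQ censoring
(default 0.01 ng/mL, plausible against a 0.15 ng/mL microdose Cmax).
They share the exact CSV/array dialects the fitters consume and are
bit-reproducible by seed. They do **not** emulate between-study design
heterogeneity, assay-specific bias, or real digitization error — so
green round-trip tests establish estimator correctness and
identifiability under the stated error model, not agreement with any
clinical dataset. Observed clinical profiles, intermediate-metabolite
plasma levels (over-predicted by design admission) and the proprietary
virtual-population bands are explicitly outside the acceptance surface.

## Known limitations

- Single aqueous solubility everywhere (no pH profile, no bile-micelle
  solubilization, fed state, or regional ionization).
- Population variability is a convenience log-normal layer on named
  parameters (defaults CV 30% on clearances, 20% on Vss), not a covariate
  model; percentile bands are therefore only face-valid.
- Intermediate-metabolite plasma concentrations are structurally
  over-predicted (lumped stand-in disposition).
- The verapamil-vs-clarithromycin Fa′/Fa contrast (1.2 vs 1.05 in the
  source dissection) compresses to ~1.1 for both: with luminal inhibitor
  concentrations far above either Ki, P-gp occupancy saturates for both
  perpetrators.
- Hepatic hydrolysis of intact DABE is configurable but off by default
  (in vivo relevance unresolved); biliary-excreted BIBR0951 never
  recirculates.
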