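# dabepbpk

A mechanistic, whole-course PBPK simulator for **dabigatran etexilate
(DABE)** — the double-ester prodrug used clinically as an intestinal
P-glycoprotein probe — linked through its two intermediate monoesters
(BIBR0951, BIBR1087) to the active anticoagulant **dabigatran (DAB)**.
It is built for DMPK modelers who want to probe, at desk scale, why the
drug–drug interaction (DDI) magnitude with dual CYP3A/P-gp inhibitors is
so much larger after a microdose (375 µg) than after a therapeutic dose
(300 mg), and why DAB exposure is mildly sub-proportional at low doses.

The model couples:

- a nine-segment intestinal absorption model with diffusion-layer
  dissolution, supersaturation-triggered precipitation (critical
  supersaturation ratio CSR = 17.9, precipitation rate constant
  PRC = 2.88 h⁻¹), passive uptake, apical P-gp efflux
  (Km 2.6 µM) and enterocyte CES2/CYP3A metabolism;
- sequential first-pass and systemic disposition of all four species,
  with plasma esterase conversion (t½ 364 / 55 min), hepatic CES1/CYP3A
  routing, biliary excretion of BIBR0951
  (CLint 273 µL/min/10⁶ cells) and renal-dominant DAB elimination;
- perpetrator models (clarithromycin, itraconazole + OH-itraconazole,
  verapamil, rifampicin) with competitive Km shifts, 1 + ΣI/Ki, and
  mechanism-based CYP3A inactivation via enzyme-turnover states,
  de/dt = kdeg(1−e) − e·kinact·I/(KI+I);
- the evaluation statistics used to qualify such models: NCA, Guest's
  narrowing DDI acceptance window L = (δ + 2(R−1))/R, signed geometric
  mean fold error GMFE = 10^mean(log₁₀ sim/obs), CV/n-based success
  bounds at 99.998% confidence, and VPC band coverage;
- weighted-least-squares / Nelder–Mead top-down estimation and a Morris
  elementary-effects sensitivity screen.

Oral bioavailability decomposes as F ≈ Fa·Fg·Fh; the package reports Fa
and Fg per compound from cumulative flux accounting and Fh from hepatic
inflow/outflow ledgers, so a DDI can be dissected into Fa′/Fa, Fg′/Fg
and Fh′/Fh exactly as the clinical analysis does.

## Worked example

```python
import dabepbpk as d

comps = d.load_compounds()          # calibrated four-compound cascade
lib   = d.load_perpetrators()

# microdose DABE with and without clarithromycin 500 mg BID x 5 days
ctrl = d.run_scenario(comps, d.ddi_scenario(0.375, "ctc", library=lib,
                                            with_perpetrator=False))
inh  = d.run_scenario(comps, d.ddi_scenario(0.375, "ctc", library=lib))
out  = d.ddi_outcome(ctrl, inh)
print(f"AUC ratio {out.auc_ratio:.2f}  "
      f"Fg'/Fg(BIBR0951) {out.fg_ratio['bibr0951']:.2f}  "
      f"Fa'/Fa {out.fa_ratio['dabe']:.2f}")
```

prints

```
AUC ratio 5.70  Fg'/Fg(BIBR0951) 3.80  Fa'/Fa 1.03
```

i.e. the microdose interaction (observed ratio 4.02, Guest window
2.30–7.04) is carried almost entirely by inhibition of the gut CYP3A
oxidation of the intermediate BIBR0951 — not by P-gp efflux of the
parent, whose Fa barely moves. Running the same pair at 300 mg gives an
AUC ratio of 1.94 with Fg′/Fg = 1.21: the gut CYP3A pathway is already
saturated at therapeutic luminal concentrations, which is the mechanism
behind the dose disparity. A single 300 mg run reports Fa ≈ 0.46
(solubility-limited) versus ≈ 0.96 at the microdose, and the
dose-normalized microdose DAB AUC lands 2.1-fold below the 300 mg
reference.

The numbered scripts under `analysis/` rerun the full story — in vitro
fits, the 0.375–400 mg dose sweep, the six-scenario DDI suite, the
Morris screen and the evaluation report — writing tables to `results/`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's acceptance targets — the upper Guest acceptance
limits for the observed microdose Cmax ratio (4.57) and the
therapeutic-dose AUC ratio (1.97) — through `dabepbpk.guest_limits`, and
writes them as JSON keyed by target id.

See `docs/methods.md` for the model's assumptions, the calibration
provenance of every parameter (printed vs calibrated stand-in), and
known limitations.
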