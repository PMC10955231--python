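"""Single-dose simulations across the 0.375-400 mg range: exposure,
dose-normalized AUC and the presystemic dissection (Fa, Fg, Fh).

The two opposing saturable mechanisms show up directly: Fa of the parent
falls with dose (solubility-limited absorption) while Fg of the
ethyl-ester intermediate rises (saturation of its gut CYP3A oxidation).
Writes results/dose_range.csv.
"""

import pathlib

import pandas as pd

import dabepbpk as d

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

comps = d.load_compounds()
rows = []
designs = [(0.375, "solution_with_precipitation"),
           (0.75, "solution_with_precipitation"),
           (3.0, "solid_IR"), (30.0, "solid_IR"), (75.0, "solid_IR"),
           (150.0, "solid_IR"), (300.0, "solid_IR"), (400.0, "solid_IR")]

for dose, form in designs:
    res = d.run_scenario(comps, d.substrate_scenario(dose, form=form))
    m = d.nca(res.times_after_dose, res.profile("dab"))
    fp = res.first_pass
    rows.append({
        "dose_mg": dose, "formulation": form,
        "dab_cmax_ng_ml": m.cmax, "dab_auc_ng_h_ml": m.auc_0_inf,
        "auc_per_mg": m.auc_0_inf / dose,
        "fa_dabe": fp["dabe"]["fa"], "fg_dabe": fp["dabe"]["fg"],
        "fg_bibr0951": fp["bibr0951"]["fg"],
        "fh_bibr0951": res.fh["bibr0951"],
    })
    print(f"{dose:7.3f} mg  AUC {m.auc_0_inf:9.2f}  AUC/mg "
          f"{m.auc_0_inf / dose:7.2f}  Fa {fp['dabe']['fa']:.2f}  "
          f"Fg(951) {fp['bibr0951']['fg']:.2f}")

tab = pd.DataFrame(rows)
lin = d.dose_linearity(tab.dose_mg, tab.dab_auc_ng_h_ml, 300.0)
tab["dose_norm_ratio_vs_300mg"] = lin["ratio"]
tab.to_csv(OUT / "dose_range.csv", index=False)

micro = tab[tab.dose_mg == 0.375].iloc[0]
print(f"\nmicrodose dose-normalized exposure is "
      f"{1 / micro.dose_norm_ratio_vs_300mg:.2f}-fold below the 300 mg "
      "reference (solubility-limited Fa and saturable gut oxidation pull "
      "in opposite directions)")
print(f"wrote {OUT / 'dose_range.csv'}")
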