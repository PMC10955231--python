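"""The full DDI suite: substrate with each dual CYP3A/P-gp inhibitor,
mean individual, against the printed observed ratios and Guest windows.

Each scenario runs a control and an inhibited arm and dissects the
interaction into its presystemic components (Fa'/Fa, Fg'/Fg, Fh'/Fh).
Writes results/ddi_summary.csv.
"""

import pathlib
import time

import pandas as pd

import dabepbpk as d
from dabepbpk.ddi import ddi_outcome

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

comps = d.load_compounds()
lib = d.load_perpetrators()
observed = d.load_observed_ddi()

designs = [
    ("1", 0.375, "ctc", "solution_with_precipitation"),
    ("2", 300.0, "ctc", "solid_IR"),
    ("7", 0.375, "itz", "solution_with_precipitation"),
    ("8", 0.375, "rf", "solution_with_precipitation"),
    ("10", 150.0, "vp", "solid_IR"),
    ("11", 150.0, "vp_1h", "solid_IR"),
]

rows = []
t0 = time.time()
for set_id, dose, perp, form in designs:
    ctrl = d.run_scenario(comps, d.ddi_scenario(dose, perp, form=form,
                                                library=lib,
                                                with_perpetrator=False))
    inh = d.run_scenario(comps, d.ddi_scenario(dose, perp, form=form,
                                               library=lib))
    out = ddi_outcome(ctrl, inh)
    obs = observed[(observed.set_id.astype(str) == set_id)
                   & (observed.metric == "auc_ratio")].iloc[0]
    in_window = obs.guest_lo <= out.auc_ratio <= obs.guest_hi
    rows.append({
        "set_id": set_id, "dose_mg": dose, "perpetrator": perp,
        "auc_ratio": out.auc_ratio, "cmax_ratio": out.cmax_ratio,
        "auc_ratio_observed": obs.observed,
        "guest_lo": obs.guest_lo, "guest_hi": obs.guest_hi,
        "within_guest": in_window,
        "fa_ratio_dabe": out.fa_ratio["dabe"],
        "fg_ratio_dabe": out.fg_ratio["dabe"],
        "fg_ratio_bibr0951": out.fg_ratio["bibr0951"],
        "fh_ratio_bibr0951": out.fh_ratio["bibr0951"],
    })
    print(f"set {set_id:>2} {perp:5s} {dose:7.3f} mg: AUCr "
          f"{out.auc_ratio:.2f} (obs {obs.observed:.2f}, window "
          f"{obs.guest_lo:.2f}-{obs.guest_hi:.2f}, "
          f"{'PASS' if in_window else 'MISS'})  Fg'/Fg(951) "
          f"{out.fg_ratio['bibr0951']:.2f}  Fa'/Fa {out.fa_ratio['dabe']:.2f}")

pd.DataFrame(rows).to_csv(OUT / "ddi_summary.csv", index=False)
print(f"\n{len(rows)} scenarios in {time.time() - t0:.0f}s; the gut-level "
      "disparity lives almost entirely in Fg'/Fg of the ethyl-ester "
      "intermediate, not in the P-gp-driven Fa'/Fa")
print(f"wrote {OUT / 'ddi_summary.csv'}")
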