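"""Model-evaluation report over the printed observed/simulated tables:
GMFE, Guest pass/fail and success-bound verdicts.

Consumes the shipped evaluation tables (training + qualification
datasets) and emits results/evaluation.json.
"""

import json
import pathlib

import dabepbpk as d
from dabepbpk import gmfe, guest_limits, success_bounds

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

pk = d.load_observed_pk()
ddi = d.load_observed_ddi()
report = {"gmfe": {}, "guest": [], "success_bounds": []}

for metric in ("cmax", "auc"):
    rows = pk[(pk.role == "qualification") & (pk.metric == metric)]
    report["gmfe"][f"pk_{metric}"] = round(
        gmfe(zip(rows.observed, rows.simulated)).value, 2)
for metric in ("cmax_ratio", "auc_ratio"):
    rows = ddi[(ddi.role == "qualification") & (ddi.metric == metric)]
    report["gmfe"][f"ddi_{metric}"] = round(
        gmfe(zip(rows.observed, rows.simulated)).value, 2)

for _, row in ddi.iterrows():
    g = guest_limits(row.observed)
    report["guest"].append({
        "set_id": str(row.set_id), "metric": row.metric,
        "observed": row.observed, "simulated": row.simulated,
        "lower": round(g.lower, 2), "upper": round(g.upper, 2),
        "simulated_within": bool(g.contains(row.simulated)),
    })

for _, row in pk.iterrows():
    if row.bound_type == "twofold":
        lo, hi = success_bounds(row.observed, None, None)
    else:
        lo, hi = success_bounds(row.observed, row.cv_percent,
                                int(row.n_inferred))
    report["success_bounds"].append({
        "set_id": str(row.set_id), "metric": row.metric,
        "lower": round(lo, 2), "upper": round(hi, 2),
        "simulated_within": bool(lo <= row.simulated <= hi),
    })

(OUT / "evaluation.json").write_text(json.dumps(report, indent=2) + "\n")
print("GMFE:", report["gmfe"])
n_pass = sum(r["simulated_within"] for r in report["guest"])
print(f"Guest: {n_pass}/{len(report['guest'])} printed simulations inside "
      "their windows")
print(f"wrote {OUT / 'evaluation.json'}")
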