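# Perpetrator library: empirical one-compartment oral PK with published
# population-mean parameters, plus CYP3A/P-gp interaction constants.
# All four are dual CYP3A/P-gp inhibitors; none inhibits CES1/2.
# P-gp Ki of itraconazole (2 uM) and hydroxy-itraconazole (5 uM) are the
# printed values; other constants are public literature values (the source
# platform's inhibitor files are proprietary) and the CYP3A constants of
# clarithromycin/verapamil are calibrated within their literature ranges.

ctc:   # clarithromycin 500 mg PO BID
  pk: {ka_h: 0.55, v_f_l: 191.0, cl_f_l_h: 32.0, fu_plasma: 0.3, bp_ratio: 1.0, mw_g_mol: 748.0}
  interactions:
    - {target: CYP3A, organ: gut, mechanism: mbi, kinact: 2.0, ki_app_u: 5.0}
    - {target: CYP3A, organ: liver, mechanism: mbi, kinact: 2.0, ki_app_u: 5.0}
    - {target: P-gp, organ: gut, mechanism: competitive, ki_u: 4.0}

itz:   # itraconazole 200 mg (solution) PO QD
  pk: {ka_h: 1.0, v_f_l: 700.0, cl_f_l_h: 22.0, fu_plasma: 0.036, bp_ratio: 1.0, mw_g_mol: 705.6}
  interactions:
    - {target: CYP3A, organ: gut, mechanism: competitive, ki_u: 0.0013}
    - {target: CYP3A, organ: liver, mechanism: competitive, ki_u: 0.0013}
    - {target: P-gp, organ: gut, mechanism: competitive, ki_u: 2.0}   # printed
  metabolite:
    id: oh_itz
    formation_fraction: 0.35
    v_l: 400.0
    cl_l_h: 30.0
    fu_plasma: 0.015
    interactions:
      - {target: CYP3A, organ: gut, mechanism: competitive, ki_u: 0.0023}
      - {target: CYP3A, organ: liver, mechanism: competitive, ki_u: 0.0023}
      - {target: P-gp, organ: gut, mechanism: competitive, ki_u: 5.0}  # printed

vp:    # verapamil IR 120 mg PO SD
  pk: {ka_h: 1.5, v_f_l: 350.0, cl_f_l_h: 50.0, fu_plasma: 0.1, bp_ratio: 0.84, mw_g_mol: 454.6}
  interactions:
    - {target: CYP3A, organ: gut, mechanism: mbi, kinact: 2.5, ki_app_u: 1.0}
    - {target: CYP3A, organ: liver, mechanism: mbi, kinact: 2.5, ki_app_u: 1.0}
    - {target: P-gp, organ: gut, mechanism: competitive, ki_u: 0.05}   # potent (>20-fold below other reports)

rf:    # rifampicin 600 mg PO SD (inhibitor here: single dose, no induction)
  pk: {ka_h: 1.0, v_f_l: 55.0, cl_f_l_h: 7.0, fu_plasma: 0.2, bp_ratio: 0.9, mw_g_mol: 822.9}
  interactions:
    - {target: CYP3A, organ: gut, mechanism: competitive, ki_u: 12.0}
    - {target: CYP3A, organ: liver, mechanism: competitive, ki_u: 10.0}
    - {target: P-gp, organ: gut, mechanism: competitive, ki_u: 9.0}
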