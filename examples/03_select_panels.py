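"""Select the six-gene stress panel and the five-gene modality panel.

Uses the packaged differential-expression fixture (two stress-vs-control
contrasts with the 124/196/44 Venn structure, plus a stress-vs-stress
contrast at FDR 0.1) and applies the selection criteria: protein-coding,
consistent fold-change sign and magnitude across contrasts, stable control
expression, then top-k by effect size.
"""

from ssge import common_and_specific, select_modality_panel, select_ssge_panel, synthgen as sg

de_cvs, de_cs, controls = sg.make_selection_fixture(seed=1)
cvs_only, cs_only, common = common_and_specific(de_cvs, de_cs, fdr=0.05)
print(f"significant genes: CVS {len(cvs_only) + len(common)}, "
      f"CS {len(cs_only) + len(common)}, shared {len(common)}")

panel = select_ssge_panel(common, de_cvs, de_cs, controls)
print("\nstress panel (direction, control mean):")
for m in panel:
    print(f"  {m.name:8s} {m.direction:4s} {m.control_mean:8.2f}")

de_mod, controls_mod = sg.make_modality_fixture(seed=1)
modality = select_modality_panel(de_mod, controls_mod)
print("\nmodality panel (CS vs CVS, FDR 0.1):", ", ".join(modality.genes))
print("\nThe shared-response genes feed the stress index; the modality panel "
      "separates shock-based from variable-stress protocols.")
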