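"""Quantify a simulated qPCR plate back into expression values.

Simulates amplification curves for a handful of animals (six target genes
plus 18S/28S reference wells per animal), calls the threshold-crossing
cycle Cq for every well, converts Cq to relative expression, normalizes to
the rRNA average, and compares the recovered table with the simulated
ground truth.
"""

from ssge import build_expression_table, synthgen as sg

sim = sg.paper_design()
expr = sg.simulate_cohort(sim, seed=2).head(4)
curves = sg.simulate_amp_curves(expr, sim, seed=2)
print(f"plate: {curves['well'].nunique()} wells x {curves['cycle'].max()} cycles")

table = build_expression_table(curves)
genes = list(sim.design.genes)
recovered = table.set_index("animal_id")[genes]
truth = expr.set_index("animal_id")[genes]
rel_err = (recovered / truth - 1).abs()

print("\nrecovered expression (rRNA-normalized):")
print(recovered.round(3))
print(f"\nmax relative quantification error: {rel_err.max().max():.2%}")
print("Noise-free curves round-trip to well under 1% because the crossing "
      "cycle is interpolated on the log-fluorescence scale.")
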