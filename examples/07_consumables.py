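"""Consumables for a large viability screen, method by method.

A 2,267-measurement screen (a realistic compound-library campaign) costed
in pipette tips, tip boxes, Petri dishes and agar mass.
"""

from gva import consumables_estimate, savings_ratio

for method in ("drop_cfu", "spiral_plater", "gva"):
    e = consumables_estimate(2267, method)
    dishes = "-" if e.petri_dishes is None else e.petri_dishes
    agar = "-" if e.agar_g is None else f"{e.agar_g:.1f} g"
    print(f"{method:>13}: {e.tips:6d} tips = {e.tip_boxes:3d} boxes, "
          f"{dishes:>5} dishes, {agar:>8} agar")

print(f"\ntip savings, drop assay vs geometric assay: "
      f"{savings_ratio('drop_cfu', 'gva', 'tips'):g}x")

# One tip per sample instead of fifteen: 24 tip boxes instead of 355, and
# no Petri dishes at all (the spiral plater would need one per sample).
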