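"""Estimate a sample's CFU/mL from a handful of colony positions.

Three colonies at 9, 18 and 27 mm from the tip of a standard p200 cone
(36 mm axis, 150 µL gel, sample diluted 1:100 into the gel).
"""

from gva import ColonySet, ConeGeometry, estimate_cfu, limit_of_detection

geom = ConeGeometry("circular_cone", axial_length_mm=36.0, volume_uL=150.0)
tip = ColonySet("demo", [9.0, 18.0, 27.0], geom, dilution_factor=100.0)

est = estimate_cfu(tip, k=3, mode="interval")
print(f"counted N = {est.n_counted} colonies in [{est.interval_mm[0]:.0f}, "
      f"{est.interval_mm[1]:.0f}) mm")
print(f"sample concentration: {est.cfu_per_ml_sample:,.0f} CFU/mL")
print(f"whole-cone count gives: "
      f"{estimate_cfu(tip, k='all', mode='full_volume').cfu_per_ml_sample:,.0f} CFU/mL")
print(f"detection limit at this volume/dilution: "
      f"{limit_of_detection(geom, 100.0):.0f} CFU/mL")

# The interval estimate (3,282 CFU/mL) uses only where the colonies sit; the
# whole-cone count (2,000 CFU/mL) is the classical count-everything answer.
# With so few colonies both are noisy; they agree within a factor of 2.
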