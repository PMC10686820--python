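"""Generate a printable, camera-free readout ruler.

The expected position of the 10th colony from the tip is x10 = h(10/m)^(1/3)
where m is the expected colony number in the gel.  Printing ticks for a
concentration grid at 1:1 scale turns a piece of paper into the readout.
"""

from gva import ConeGeometry, RulerSpec, kth_colony_position, render_ruler

geom = ConeGeometry("circular_cone", 36.0, 150.0)
concs = (1e5, 1e6, 1e7, 1e8, 1e9)  # sample-scale CFU/mL, 1:100 embedding

for c in concs:
    x = kth_colony_position(geom, c, dilution_factor=100.0, k=10)
    print(f"{c:8.0e} CFU/mL -> 10th colony expected {x:6.2f} mm from the tip")

svg = render_ruler(RulerSpec(geom=geom, k=10, concentrations=concs), "ruler.svg")
print("\nwrote ruler.svg — print at 100% scale and align the tip apex with the circle")

# Each 10x in concentration moves the tick 10^(1/3) ~ 2.15x closer to the
# apex; five decades of concentration fit on a 36 mm axis.
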