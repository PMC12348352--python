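"""Tour of the calibrated torsional free-energy surface.

Builds the default (phi, psi) landscape for the conformational
transformation of 4-pyridone-3-carboxylic acid, locates its critical
points, and shows how an external electric field shifts the saddle.
"""

import numpy as np

from fieldstring import (FieldSpec, OPPoint, build_default_landscape,
                         free_energy, locate_minima, locate_saddle)
from fieldstring.landscape import E_MAX

landscape = build_default_landscape()

(conf1, conf2), (f1, f2) = locate_minima(landscape)
saddle, height = locate_saddle(landscape)

print("Conformer basins (from deterministic minimization):")
print(f"  conformation 1 at (phi, psi) = ({conf1.phi:7.2f}, {conf1.psi:7.2f}), "
      f"F = {f1:5.2f} kJ/mol")
print(f"  conformation 2 at (phi, psi) = ({conf2.phi:7.2f}, {conf2.psi:7.2f}), "
      f"F = {f2:5.2f} kJ/mol")
print(f"Principal saddle at ({saddle.phi:.1f}, {saddle.psi:.1f}), "
      f"{height:.1f} kJ/mol above conformation 2")

# hydrogen-bond sub-barrier from the analytic profile
s = np.linspace(0.70, 0.99, 10001)
p = landscape.profile(s)
sub = p[(s > 0.82) & (s < 0.95)].max() - p[(s > 0.72) & (s < 0.85)].min()
print(f"Intramolecular H-bond sub-barrier: {sub:.1f} kJ/mol "
      "(the late, easy step of the transformation)")

for axis in "xyz":
    _, h = locate_saddle(landscape, FieldSpec(axis, 1, E_MAX))
    print(f"Saddle height at 41.14e8 V/m along +{axis}: {h:.1f} kJ/mol")
print("The field raises the barrier identically on every axis: the "
      "transformation barely couples to the field direction.")

print(f"\nPeriodicity check: F(48, 92.7) = "
      f"{free_energy(landscape, OPPoint(48.0, 92.7)):.1f} kJ/mol equals "
      f"F(48 - 360, 92.7) = "
      f"{free_energy(landscape, OPPoint(48.0 - 360, 92.7)):.1f} kJ/mol")
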