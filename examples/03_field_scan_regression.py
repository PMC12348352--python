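"""Linear field response of the proton-transfer observables.

Generates the synthetic per-direction field scans (H...O distance, AIM
density, imaginary frequency, barrier, surface-potential statistics) and
fits each signed-direction series against field strength, reproducing the
first-order-Stark linearity the observables show.
"""

from fieldstring import fit_all_series, fit_linear_response, generate_field_scan

table = generate_field_scan(seed=1, noise_fraction=0.02)
print(f"generated {len(table)} rows "
      f"({table.data['quantity'].nunique()} observables, signed x/y series)")

fit = fit_linear_response(table, "R_H6O4", "x", 1)
print(f"\nH6...O4' distance vs +x field: slope = {fit.slope * 41.14e8:+.3f} "
      f"angstrom at max field, R^2 = {fit.r_squared:.4f}")
print("(the distance grows along +x: the O5-H6 bond strengthens and the "
      "proton is harder to transfer)")

print("\nall series:")
print(f"{'quantity':>12} {'dir':>4} {'slope@Emax':>12} {'R^2':>8}")
for f in sorted(fit_all_series(table), key=lambda f: (f.quantity, f.axis, -f.sign)):
    direction = f"{'+' if f.sign > 0 else '-'}{f.axis}"
    print(f"{f.quantity:>12} {direction:>4} {f.slope * 41.14e8:12.4f} "
          f"{f.r_squared:8.4f}")
print("\nEvery structural/electronic series is tightly linear (R^2 > 0.98); "
      "the change at the maximum field equals the calibration anchor.")
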