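"""Tunneling-corrected rates and the mechanism competition.

Computes Wigner tunneling factors and Eyring rates for the double-proton
transfer barriers, then compares proton transfer against conformational
transformation across field conditions.
"""

from fieldstring import (competition_report, eyring_rate, relative_change,
                         wigner_kappa)

T = 298.15
kappa = wigner_kappa(1102.5, T)
print(f"Wigner tunneling factor for the 1102.5 cm^-1 imaginary mode at "
      f"{T} K: kappa = {kappa:.2f}")
print("(a factor >2: proton tunneling doubles the classical TST rate)")

print("\nEyring rates with tunneling:")
for label, dg in [("no field", 17.3), ("+x, 41.14e8 V/m", 5.7)]:
    k = eyring_rate(dg, T, kappa)
    print(f"  {label:>18}: dG = {dg:5.1f} kJ/mol -> k = {k:.2e} s^-1")

print(f"\nRelative barrier decrease at maximum +x field: "
      f"{relative_change(17.3, 11.6):.1f}%")
print(f"Relative barrier increase at maximum -x field: "
      f"{relative_change(17.3, 2.6):.1f}%")

table, max_diff = competition_report(
    proton_barriers=[21.4, 16.3, 8.6, 7.7],
    conf_barriers=[17.3, 15.2, 5.7, 6.8],
    labels=["no field (CCSD(T)//M06-2X)", "no field (CCSD(T))",
            "+x max field (CCSD(T)//M06-2X)", "+x max field (CCSD(T))"])
print("\nproton transfer vs conformational transformation:")
print(table.to_string(index=False))
print(f"\nmax |difference| = {max_diff:.1f} kJ/mol — the two mechanisms stay "
      "within 5 kJ/mol of each other, i.e. they genuinely compete.")
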