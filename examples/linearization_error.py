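"""How much error does linearizing the Boltzmann factor introduce?

A salt bridge between hydrated carboxylate and amino groups at 5 Å in a
medium of relative permittivity 78 has a Coulomb energy of about
-0.85 kcal/mol — already larger than the thermal energy, so the
linearized PB solver's first-order Taylor truncation is noticeably off.
This script prints the exact Boltzmann factor, its first three Taylor
approximations, and the equivalent error in pKa units.
"""
from membpka import PhysicalConstants, coulomb_energy, linearization_error_report

const = PhysicalConstants(temperature=298.15)
delta_e = coulomb_energy(-1, +1, 5.0, 78.0, const)
print(f"salt-bridge Coulomb energy: {delta_e:.3f} kcal/mol")

kbt = 0.593  # ambient-temperature thermal energy, kcal/mol
rep = linearization_error_report(delta_e, kbt, max_order=3)
print(f"x = |dE|/kBT = {rep.x:.3f},  exact exp(x) = {rep.exact:.3f}")
for _, row in rep.table.iterrows():
    print(
        f"  order {int(row['order'])}: approx {row['approximation']:.3f}  "
        f"rel. error {row['relative_error'] * 100:.0f}%  "
        f"pKa error {row['pka_error']:.2f}"
    )
# The first-order (linearized) solve underestimates the factor by ~42%,
# i.e. about a quarter of a pKa unit for this single interaction; the
# error shrinks quickly as higher Taylor orders are added.
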