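"""Construct a U7(7^6) uniform design, map it to herb doses, and convert
the human daily dose to its rat equivalent."""

from udpharm import (
    bsa_convert,
    centered_l2_discrepancy,
    default_dose_ranges,
    glp_design,
    scale_doses,
)

table = glp_design(n_runs=7, n_factors=6, generators=[1, 2, 3, 4, 5, 6])
print("U7(7^6) level table (each column a permutation of 1..7):")
print(table.to_frame().to_string(index=False))
print(f"\ncentered L2 discrepancy CD2 = {centered_l2_discrepancy(table):.6f}")
print("(lower CD2 = runs spread more uniformly over the factor space)")

doses = scale_doses(table, default_dose_ranges())
print("\nHerb doses in grams (levels mapped linearly into each herb's range):")
print(doses.to_frame().round(2).to_string(index=False))

rat = bsa_convert(human_daily_dose_g=35.0, human_mass_kg=70.0, factor=6.3)
print(f"\nBSA conversion: 35 g/day for a 70 kg adult x 6.3 -> {rat:.2f} g/kg/day")
print("(the rat-equivalent dose of the reference formulation)")
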