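"""Exact monoisotopic masses and adduct ion m/z.

Computes the neutral masses of two diagnostic neutral losses
(trimethylamine, phosphocholine) and the m/z of a few calibration ions,
showing why the electron mass matters at FTICR accuracy.
"""

from msimet import ion_mz, mass_error, monoisotopic_mass, parse_formula
from msimet.chem import ADDUCTS

for formula in ("C3H9N", "C5H14NO4P"):
    f = parse_formula(formula)
    print(f"{formula:12s} neutral monoisotopic mass = {monoisotopic_mass(f):.6f} Da")

print()
for formula, adduct in [
    ("C5H14NO4P", "[M+H]+"),   # phosphocholine, calibration ion
    ("C10H16N5O13P3", "[M-H]-"),  # ATP
    ("C7H6O4", "[M+Na]+"),     # DHB matrix peak
]:
    f = parse_formula(formula)
    mz = ion_mz(f, adduct)
    a = ADDUCTS[adduct]
    no_electron = (
        monoisotopic_mass(f) + monoisotopic_mass(a.added) - monoisotopic_mass(a.removed)
    )
    print(f"{formula:16s} {adduct:8s} m/z = {mz:.6f}  "
          f"(ignoring the electron would be off by {abs(no_electron - mz)*1e3:.2f} mDa)")

# a published ATP observation vs theory: sub-ppm agreement
theo = ion_mz(parse_formula("C10H16N5O13P3"), "[M-H]-")
err = mass_error(505.98833, theo)
print(f"\nobserved ATP m/z 505.98833 vs theoretical {theo:.6f}: "
      f"{err.ppm:+.3f} ppm ({err.ppb:+.0f} ppb)")
print("Sub-ppm errors like this are what make formula-level annotation possible.")
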