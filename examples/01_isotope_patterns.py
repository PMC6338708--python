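"""Formula arithmetic: exact masses, adduct m/z and isotope envelopes.

Computes the quantities every suspect-screening decision rests on: the
monoisotopic mass of a formula, the m/z of its deprotonated ion, and the
isotopologue envelope a 0.005-Da extraction window would resolve.
"""

from edcscreen import adduct_mz, isotope_pattern, monoisotopic_mass, parse_formula

for name, formula in [
    ("ethylparaben", "C9H10O3"),
    ("triclosan", "C12H7Cl3O2"),
    ("bisphenol A sulphate", "C15H16O5S"),
]:
    f = parse_formula(formula)
    print(f"{name} ({formula})")
    print(f"  monoisotopic mass : {monoisotopic_mass(f):.4f} Da")
    print(f"  [M-H]- quantifier : {adduct_mz(f, '[M-H]-'):.4f} m/z")
    pattern = isotope_pattern(f)
    channels = ", ".join(
        f"{m:.4f} ({a:.1f}%)" for m, a in zip(pattern.mz, pattern.abundance) if a >= 1
    )
    print(f"  isotope envelope  : {channels}")
    print()

# Triclosan's three chlorines give the distinctive M : M+2 : M+4 staircase
# (about 100 : 96 : 31) that identifies the compound even without fragments.
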