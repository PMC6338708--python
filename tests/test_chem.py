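"""Formula arithmetic, adduct masses and isotope patterns."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edcscreen.chem import (
    ELECTRON_MASS,
    PROTON_MASS,
    ElementalFormula,
    FormulaError,
    IsotopePattern,
    adduct_mz,
    get_adduct,
    isotope_pattern,
    isotope_table,
    monoisotopic_mass,
    parse_formula,
    pattern_deviation,
    ppm_error,
)
from conftest import brute_force_pattern


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C15H16O5S", {"C": 15, "H": 16, "O": 5, "S": 1}),
            ("H", {"H": 1}),
            ("C12H7Cl3O2", {"C": 12, "H": 7, "Cl": 3, "O": 2}),
            ("C9H10O3", {"C": 9, "H": 10, "O": 3}),
        ],
    )
    def test_tokenizes(self, text, expected):
        assert parse_formula(text).counts == expected

    def test_round_trip(self):
        assert parse_formula("C12H7Cl3O2").hill() == "C12H7Cl3O2"

    @pytest.mark.parametrize("bad", ["Xx5", "C0", "", "C2.5", "c12"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)


class TestMonoisotopicMass:
    def test_empty_formula_is_massless(self):
        assert monoisotopic_mass(ElementalFormula({})) == 0.0

    def test_carbon12_standard(self):
        assert monoisotopic_mass("C") == 12.0

    def test_ethylparaben_neutral(self):
        # independently cross-checked exact mass of C9H10O3
        assert monoisotopic_mass("C9H10O3") == pytest.approx(166.0630, abs=1e-4)

    @given(
        st.dictionaries(
            st.sampled_from(sorted(isotope_table())),
            st.integers(min_value=1, max_value=30),
            min_size=1,
            max_size=5,
        ),
        st.dictionaries(
            st.sampled_from(sorted(isotope_table())),
            st.integers(min_value=1, max_value=30),
            min_size=1,
            max_size=5,
        ),
    )
    @settings(max_examples=50, derandomize=True)
    def test_mass_additivity(self, c1, c2):
        f1, f2 = ElementalFormula(c1), ElementalFormula(c2)
        assert monoisotopic_mass(f1) + monoisotopic_mass(f2) == pytest.approx(
            monoisotopic_mass(f1 + f2), abs=1e-9
        )


class TestAdductMz:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C9H10O3", 165.0557),    # ethylparaben
            ("C12H7Cl3O2", 286.9439),  # triclosan
            ("C15H16O5S", 307.0646),  # bisphenol A sulphate
            ("C7H7ClO4S", 220.9681),  # 4-Cl-3-methylphenol sulfate ester
        ],
    )
    def test_deprotonated_mz_to_4dp(self, formula, expected):
        assert round(adduct_mz(formula, "[M-H]-"), 4) == expected

    def test_radical_anion_carries_electron_mass(self):
        # ethyl-radical loss from deprotonated ethylparaben
        mz = monoisotopic_mass("C7H4O3") + ELECTRON_MASS
        assert round(mz, 4) == 136.0166
        assert adduct_mz("C7H4O3", "[M]-") == pytest.approx(mz)

    def test_protonated_deprotonated_symmetry(self):
        m = monoisotopic_mass("C8H14ClN5")
        assert adduct_mz("C8H14ClN5", "[M+H]+") == pytest.approx(m + PROTON_MASS)
        assert adduct_mz("C8H14ClN5", "[M-H]-") == pytest.approx(m - PROTON_MASS)

    def test_unknown_adduct(self):
        with pytest.raises(KeyError):
            get_adduct("[M+2H]2+")


class TestPpmError:
    def test_identity_and_definition(self):
        assert ppm_error(200.0, 200.0) == 0.0
        assert ppm_error(200.002, 200.0) == pytest.approx(10.0)

    def test_bpa_trace_within_criterion(self):
        theoretical = adduct_mz("C15H16O2", "[M-H]-")
        assert abs(ppm_error(227.1096, theoretical)) < 10.0

    def test_non_positive_theoretical(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)

    @given(
        st.floats(min_value=50, max_value=2000),
        st.floats(min_value=50, max_value=2000),
    )
    @settings(max_examples=50, derandomize=True)
    def test_antisymmetry(self, a, b):
        # swapping observed/theoretical flips the sign up to the scale a/b
        assert ppm_error(a, b) == pytest.approx(-ppm_error(b, a) * a / b, rel=1e-9)


class TestIsotopePattern:
    def test_single_chlorine_ratio(self):
        p = isotope_pattern("Cl")
        assert len(p.mz) == 2
        assert p.abundance[0] == 100.0
        assert p.abundance[1] == pytest.approx(32.0, abs=0.5)

    def test_deuterium_below_floor(self):
        p = isotope_pattern("H2", abundance_floor=1e-3)
        assert len(p.mz) == 1
        assert p.abundance[0] == 100.0

    def test_triclosan_chlorine_envelope(self):
        p = isotope_pattern("C12H7Cl3O2")
        by_offset: dict[int, float] = {}
        for m, a in zip(p.mz, p.abundance):
            off = round(m - p.mz[0])
            by_offset[off] = max(by_offset.get(off, 0.0), a)
        assert by_offset[0] == 100.0
        assert by_offset[2] == pytest.approx(96, abs=2)
        assert by_offset[4] == pytest.approx(31, abs=2)

    @pytest.mark.parametrize("formula", ["Cl3", "Br2Cl2", "S4", "Cl2S", "BrCl"])
    def test_convolution_matches_enumeration_exactly(self, formula):
        """Few polyisotopic atoms: channel-exact match with the oracle."""
        p = isotope_pattern(formula, abundance_floor=0.005)
        masses, abundances = brute_force_pattern(formula)
        assert len(p.mz) == len(masses)
        np.testing.assert_allclose(p.mz, masses, atol=1e-6)
        np.testing.assert_allclose(p.abundance, abundances, rtol=1e-6, atol=1e-6)

    @pytest.mark.parametrize("formula", ["C12H7Cl3O2", "C15H16O5S", "C6H4BrCl"])
    def test_convolution_matches_enumeration_per_isotopologue_bin(self, formula):
        """Large formulas: abundance per nominal isotope offset matches the oracle.

        Channel-level splits near the merge tolerance may differ between the
        stepwise convolution and the end-merged enumeration, but the total
        abundance inside each nominal M+k bin must agree.
        """
        p = isotope_pattern(formula, abundance_floor=0.0)
        masses, abundances = brute_force_pattern(formula, floor=0.0)

        def binned(ms, abs_):
            out: dict[int, float] = {}
            for m, a in zip(ms, abs_):
                off = round(m - min(ms))
                out[off] = out.get(off, 0.0) + a
            return out

        ours, oracle = binned(p.mz, p.abundance), binned(masses, abundances)
        for off in oracle:
            assert ours.get(off, 0.0) == pytest.approx(oracle[off], rel=1e-6, abs=1e-6)

    def test_empty_formula_rejected(self):
        with pytest.raises(FormulaError):
            isotope_pattern(ElementalFormula({}))

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "O", "S", "Br"]),
            st.integers(min_value=1, max_value=12),
            min_size=1,
            max_size=3,
        )
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_base_is_100_and_chlorine_monotonicity(self, counts):
        f = ElementalFormula(counts)
        p = isotope_pattern(f)
        assert max(p.abundance) == 100.0
        assert all(0 < a <= 100 for a in p.abundance)

        def m2_ratio(pattern):
            base_m = pattern.mz[pattern.base_index]
            cands = [
                a for m, a in zip(pattern.mz, pattern.abundance)
                if 1.5 < m - base_m < 2.5
            ]
            return max(cands) / 100.0 if cands else 0.0

        with_cl = isotope_pattern(f + ElementalFormula({"Cl": 1}))
        assert m2_ratio(with_cl) > m2_ratio(p)


class TestPatternDeviation:
    def test_self_comparison_is_zero(self):
        p = isotope_pattern("C12H7Cl3O2")
        observed = list(zip(p.mz, p.abundance))
        assert pattern_deviation(p, observed) == 0.0

    def test_chlorine_deviation_value(self):
        p = isotope_pattern("Cl")
        observed = [(p.mz[0], 100.0), (p.mz[1], 35.0)]
        assert pattern_deviation(p, observed) == pytest.approx(3.0, abs=0.1)

    def test_missing_m2_counts_full_abundance(self):
        p = isotope_pattern("C12H7Cl3O2")
        base = p.base_index
        observed = [
            (m, a) for m, a in zip(p.mz, p.abundance)
            if not 1.5 < m - p.mz[base] < 2.5
        ]
        dev = pattern_deviation(p, observed)
        assert dev == pytest.approx(96, abs=2)

    def test_missing_base_channel_errors(self):
        p = isotope_pattern("Cl")
        with pytest.raises(ValueError):
            pattern_deviation(p, [(p.mz[1], 30.0)])

    def test_scaling_invariance(self):
        p = isotope_pattern("C15H16O5S")
        observed = [(m, a * 7.3e4) for m, a in zip(p.mz, p.abundance)]
        assert pattern_deviation(p, observed) == pytest.approx(0.0, abs=1e-9)


def test_isotope_table_invariants():
    table = isotope_table()
    for element, isotopes in table.items():
        masses = [m for m, _ in isotopes]
        assert masses == sorted(masses)
        assert sum(a for _, a in isotopes) == pytest.approx(1.0, abs=1e-9)


def test_pattern_channel_invariants():
    with pytest.raises(ValueError):
        IsotopePattern(mz=(100.0, 99.0), abundance=(100.0, 10.0))
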