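"""Formula algebra, ion mass conventions, and CF2 Kendrick arithmetic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pfas_screen.chem import (
    CF2_EXACT,
    CF2_NOMINAL,
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    ElementalFormula,
    FormulaError,
    fragment_mz,
    kendrick_mass,
    kendrick_mass_defect,
    monoisotopic_mass,
    mz_deprotonated,
    parse_formula,
    ppm_error,
)

# the 11-compound benchmark set: formula -> printed theoretical [M-H]- m/z
BENCHMARK_MZ = {
    "C4HF9O3S": 298.943,
    "C5HF11O3S": 348.9398,
    "C6HF13O3S": 398.9366,
    "C8HF17O3S": 498.9302,
    "C8H5F13O3S": 426.9679,
    "C4H2F9NO2S": 297.959,
    "C6H2F13NO2S": 397.9526,
    "C3H2F7NO2S": 247.9622,
    "C3HF7O3S": 248.9462,
    "C5HF11": 268.983,
    "C7HF15": 368.9766,
}


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C4HF9O3S", {"C": 4, "H": 1, "F": 9, "O": 3, "S": 1}),
            ("C5HF11", {"C": 5, "H": 1, "F": 11}),
            ("H", {"H": 1}),
            ("C8H5F13O3S", {"C": 8, "H": 5, "F": 13, "O": 3, "S": 1}),
        ],
    )
    def test_examples(self, text, expected):
        assert parse_formula(text).counts == expected

    @pytest.mark.parametrize("bad", ["", "  ", "Xx4", "C0", "C4h", "C-2"])
    def test_rejects_invalid(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_zero_count_dataclass(self):
        with pytest.raises(FormulaError):
            ElementalFormula({"C": 0})

    @pytest.mark.parametrize("text", list(BENCHMARK_MZ))
    def test_round_trip(self, text):
        assert str(parse_formula(text)) == text


class TestMasses:
    def test_cf2_constant_consistency(self):
        assert abs(
            CF2_EXACT - (MONOISOTOPIC_MASS["C"] + 2 * MONOISOTOPIC_MASS["F"])
        ) < 1e-6

    @pytest.mark.parametrize(
        "formula,expected",
        [("C4HF9O3S", 299.950269), ("C", 12.0), ("CF2", 49.9968064)],
    )
    def test_monoisotopic_examples(self, formula, expected):
        assert monoisotopic_mass(formula) == pytest.approx(expected, abs=1e-5)

    def test_against_independent_mass_oracle(self):
        """Cross-check the frozen mass table against pyteomics.mass."""
        from pyteomics import mass as pmass

        for formula in BENCHMARK_MZ:
            ours = monoisotopic_mass(formula)
            theirs = pmass.calculate_mass(formula=formula)
            assert ours == pytest.approx(theirs, abs=2e-5)

    def test_unknown_element(self):
        with pytest.raises(FormulaError):
            parse_formula("Zz2")

    def test_additivity_over_formula_union(self):
        a, b = parse_formula("C2F5"), parse_formula("C2F4HO3S")
        assert monoisotopic_mass(a + b) == pytest.approx(
            monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-9
        )

    def test_deprotonated_vs_fragment_consistency(self):
        # [M-H]- of (f + H) and the f anion differ by proton+electron masses
        f = parse_formula("C4F9HO3S")  # arbitrary
        mh = mz_deprotonated(monoisotopic_mass(parse_formula("C4F9H2O3S")))
        fr = fragment_mz(f)
        assert mh - fr == pytest.approx(
            monoisotopic_mass("H") - PROTON_MASS - ELECTRON_MASS, abs=1e-9
        )


class TestDeprotonatedMz:
    @pytest.mark.parametrize("formula,printed", sorted(BENCHMARK_MZ.items()))
    def test_reproduces_printed_values(self, formula, printed):
        """Every benchmark theoretical [M-H]- reproduces to its printed decimals."""
        mz = mz_deprotonated(monoisotopic_mass(formula))
        decimals = len(str(printed).split(".")[1])
        assert round(mz, decimals) == printed

    def test_rejects_tiny_mass(self):
        with pytest.raises(ValueError):
            mz_deprotonated(0.5)


class TestFragmentMz:
    @pytest.mark.parametrize(
        "formula,expected",
        [("SO3", 79.957363), ("C2F5", 118.992566), ("CF3", 68.995758)],
    )
    def test_anion_masses(self, formula, expected):
        assert fragment_mz(formula) == pytest.approx(expected, abs=2e-6)


class TestPpmError:
    def test_identity_is_exactly_zero(self):
        assert ppm_error(298.9430, 298.9430) == 0.0

    def test_signed_arithmetic(self):
        assert ppm_error(398.93700, 398.93660) == pytest.approx(1.0027, abs=1e-3)
        assert ppm_error(398.93620, 398.93660) < 0

    @given(
        st.floats(min_value=70, max_value=1040),
        st.floats(min_value=70, max_value=1040),
    )
    def test_antisymmetry_up_to_denominator(self, a, b):
        # swapping arguments flips the sign; magnitudes differ only by the
        # denominator change
        assert np.sign(ppm_error(a, b)) == -np.sign(ppm_error(b, a))
        assert ppm_error(a, b) * b == pytest.approx(-ppm_error(b, a) * a, rel=1e-9)


class TestKendrick:
    def test_examples(self):
        assert kendrick_mass(298.9430) == pytest.approx(298.962098, abs=1e-5)
        assert kendrick_mass(49.9968064) == pytest.approx(50.0, abs=1e-9)
        assert kendrick_mass(348.9398) == pytest.approx(348.962094, abs=1e-5)

    def test_kmd_examples(self):
        assert kendrick_mass_defect(298.9430).kmd == pytest.approx(0.037902, abs=1e-5)
        assert kendrick_mass_defect(49.9968064).kmd == pytest.approx(0.0, abs=1e-9)

    def test_homologs_share_kmd(self):
        # adjacent sulfonate homologs agree to ~1e-4
        a = kendrick_mass_defect(298.9430).kmd
        b = kendrick_mass_defect(348.9398).kmd
        assert abs(a - b) < 1e-4

    def test_invariant_bounds(self):
        p = kendrick_mass_defect(412.9664)
        assert abs(p.kmd) <= 0.5
        assert p.kmd == pytest.approx(round(p.kendrick_mass) - p.kendrick_mass)

    def test_negative_kmd_legal(self):
        # the 1H-perfluoroalkane series sits just below zero
        assert kendrick_mass_defect(268.983).kmd < 0

    @given(
        st.floats(min_value=80, max_value=600),
        st.integers(min_value=1, max_value=8),
    )
    def test_homolog_invariance_under_cf2_shifts(self, mz, k):
        """KMD is invariant when adding whole CF2 units (no boundary crossing)."""
        base = kendrick_mass_defect(mz)
        shifted = kendrick_mass_defect(mz + k * CF2_EXACT)
        km = base.kendrick_mass
        # skip masses too close to a rounding boundary for the invariance claim
        if min(km - np.floor(km), np.ceil(km) - km) > 1e-6 and abs(km - round(km)) < 0.499:
            assert shifted.kmd == pytest.approx(base.kmd, abs=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            kendrick_mass(0.0)
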