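import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crankms import (
    ADDUCTS,
    ChemicalFormula,
    adduct_mz,
    annotate_mz,
    mass_defect,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    read_compound_table,
)
from crankms.annotation import (
    ISOTOPE_MASS,
    NEGATIVE_MODE_ADDUCTS,
    POSITIVE_MODE_ADDUCTS,
)


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C21H8F28O8", {"C": 21, "H": 8, "F": 28, "O": 8}),
            ("C_21_H_8_F_28_O_8_", {"C": 21, "H": 8, "F": 28, "O": 8}),
            ("H2O", {"H": 2, "O": 1}),
            ("C27H46", {"C": 27, "H": 46}),
            ("C₆H₁₂O₆", {"C": 6, "H": 12, "O": 6}),
            ("NaCl", {"Na": 1, "Cl": 1}),
        ],
    )
    def test_examples(self, text, expected):
        assert parse_formula(text).as_dict() == expected

    @pytest.mark.parametrize("text", ["", "Xx2", "C21h8", "12C"])
    def test_malformed_rejected(self, text):
        with pytest.raises(ValueError):
            parse_formula(text)


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula,mass",
        [("H2O", 18.010565), ("C27H46", 370.359951), ("C", 12.0)],
    )
    def test_known_masses(self, formula, mass):
        assert monoisotopic_mass(parse_formula(formula)) == pytest.approx(mass, abs=1e-5)

    @pytest.mark.parametrize(
        "formula", ["C21H8F28O8", "C30H52O2", "C37H66O5", "C28H44O", "C6H12O6", "C5H5N5"]
    )
    def test_agrees_with_pyteomics_oracle(self, formula):
        from pyteomics import mass as pyt_mass

        ours = monoisotopic_mass(parse_formula(formula))
        theirs = pyt_mass.calculate_mass(formula=formula)
        assert ours == pytest.approx(theirs, abs=1e-4)

    @given(
        st.dictionaries(
            st.sampled_from(sorted(ISOTOPE_MASS)), st.integers(1, 50), min_size=1
        ),
        st.dictionaries(
            st.sampled_from(sorted(ISOTOPE_MASS)), st.integers(1, 50), min_size=1
        ),
    )
    def test_mass_is_additive_over_formula_composition(self, a, b):
        fa = ChemicalFormula(tuple(a.items()))
        fb = ChemicalFormula(tuple(b.items()))
        assert monoisotopic_mass(fa + fb) == pytest.approx(
            monoisotopic_mass(fa) + monoisotopic_mass(fb), abs=1e-9
        )


class TestAdductsAndPpm:
    def test_sodiated_pfas_ion(self):
        # C21H8F28O8 neutral 919.977206 Da; +Na -e -> 942.966426
        assert adduct_mz(919.977206, ADDUCTS["[M+Na]+"]) == pytest.approx(
            942.966426, abs=1e-5
        )

    def test_protonation_is_plus_proton(self):
        assert adduct_mz(100.0, ADDUCTS["[M+H]+"]) == pytest.approx(101.007276, abs=1e-6)

    def test_water_loss_ion(self):
        # vitamin D2: C28H44O 396.339216 Da; +H -H2O -> 379.335928
        mass = monoisotopic_mass(parse_formula("C28H44O"))
        assert mass == pytest.approx(396.339216, abs=1e-5)
        assert adduct_mz(mass, ADDUCTS["[M+H-H2O]+"]) == pytest.approx(379.335928, abs=1e-5)

    def test_deprotonation_subtracts_proton(self):
        assert adduct_mz(100.0, ADDUCTS["[M-H]-"]) == pytest.approx(98.992724, abs=1e-6)

    def test_ppm_error_examples(self):
        assert ppm_error(942.9824, 942.966426) == pytest.approx(16.9, abs=0.05)
        assert ppm_error(500.0, 500.0) == 0.0
        x = 200.0
        assert ppm_error(x * (1 + 2e-5), x) == pytest.approx(20.0)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            adduct_mz(0.0, ADDUCTS["[M+H]+"])
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)


class TestMassDefect:
    def test_fluorinated_ion_flagged(self):
        defect, flagged = mass_defect(942.9824)
        assert defect == pytest.approx(-0.0176, abs=1e-4)
        assert flagged

    def test_chno_metabolite_not_flagged(self):
        defect, flagged = mass_defect(467.3822)
        assert defect == pytest.approx(0.3822, abs=1e-4)
        assert not flagged

    def test_integer_mz_not_flagged(self):
        assert mass_defect(100.0) == (0.0, False)


class TestAnnotate:
    def test_pfas_matches_via_sodiation(self, compound_db):
        matches = annotate_mz(942.9824, compound_db, POSITIVE_MODE_ADDUCTS)
        assert len(matches) == 1
        m = matches[0]
        assert str(m.compound.formula) == "C21F28H8O8"
        assert m.adduct.name == "[M+Na]+"
        assert abs(m.ppm) <= 20
        assert m.exogenous_flag

    def test_far_mz_yields_empty_list(self, compound_db):
        assert annotate_mz(150.0, compound_db, POSITIVE_MODE_ADDUCTS) == []

    def test_matches_sorted_by_absolute_ppm(self):
        from crankms import CompoundRecord

        # two isomers at identical mass, distinguished only by id order
        iso1 = CompoundRecord("A2", "iso-b", parse_formula("C6H12O6"))
        iso2 = CompoundRecord("A1", "iso-a", parse_formula("C6H12O6"))
        near = CompoundRecord("B1", "close", parse_formula("C7H14O5"))
        mz = adduct_mz(monoisotopic_mass(parse_formula("C6H12O6")), ADDUCTS["[M+H]+"])
        matches = annotate_mz(mz * (1 + 2e-6), [near, iso1, iso2], [ADDUCTS["[M+H]+"]],
                              tolerance_ppm=50)
        assert [m.compound.id for m in matches][:2] == ["A1", "A2"]  # |ppm| tie -> id
        assert abs(matches[0].ppm) <= abs(matches[-1].ppm)

    def test_tightening_tolerance_never_adds_matches(self, compound_db):
        rng = np.random.default_rng(5)
        for mz in rng.uniform(100, 1000, size=20):
            wide = {
                (m.compound.id, m.adduct.name)
                for m in annotate_mz(mz, compound_db, POSITIVE_MODE_ADDUCTS, 50.0)
            }
            tight = {
                (m.compound.id, m.adduct.name)
                for m in annotate_mz(mz, compound_db, POSITIVE_MODE_ADDUCTS, 5.0)
            }
            assert tight <= wide

    def test_neutral_mass_and_mz_searches_agree(self, compound_db):
        # neutralizing the observed m/z then comparing neutral masses gives the
        # same candidate set as comparing adduct-shifted m/z values
        rng = np.random.default_rng(6)
        tol = 20.0
        for mz in list(rng.uniform(300, 1000, size=30)) + [942.9824, 467.3822]:
            via_mz = {
                (m.compound.id, m.adduct.name)
                for m in annotate_mz(mz, compound_db, POSITIVE_MODE_ADDUCTS, tol)
            }
            via_neutral = set()
            for adduct in POSITIVE_MODE_ADDUCTS:
                neutral = mz * abs(adduct.charge) - adduct.delta
                for c in compound_db:
                    theo_mz = adduct_mz(c.monoisotopic_mass, adduct)
                    if abs((neutral - c.monoisotopic_mass) / theo_mz * 1e6) <= tol:
                        via_neutral.add((c.id, adduct.name))
            assert via_mz == via_neutral

    def test_negative_mode_uses_deprotonation(self, compound_db):
        mass = monoisotopic_mass(parse_formula("C30H52O2"))
        mz = adduct_mz(mass, ADDUCTS["[M-H]-"])
        matches = annotate_mz(mz, compound_db, NEGATIVE_MODE_ADDUCTS)
        assert matches and matches[0].adduct.name == "[M-H]-"

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            annotate_mz(500.0, [], POSITIVE_MODE_ADDUCTS)


class TestCompoundTable:
    def test_bundled_markers_load(self, compound_db):
        assert len(compound_db) == 5
        ids = {c.id for c in compound_db}
        assert len(ids) == 5
        for c in compound_db:
            assert c.monoisotopic_mass > 300

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tname\nX\tthing\n")
        with pytest.raises(ValueError, match="formula"):
            read_compound_table(path)
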