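"""Isotope-pattern engine: grammar, convolution algebra, approximations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

import isodecomp as iso
from isodecomp import IsotopePattern, PruneConfig

from conftest import brute_force_power

EXACT = PruneConfig(0.0, 0.0)


class TestParseFormula:
    @pytest.mark.parametrize("text, counts, z", [
        ("X2", {"X": 2}, 1),
        ("(C60)3Na12", {"C": 180, "Na": 12}, 1),
        ("C40 2+", {"C": 40}, 2),
        ("C40++", {"C": 40}, 2),
        ("[(C60)3Na12H2O]+", {"C": 180, "Na": 12, "H": 2, "O": 1}, 1),
        ("[(C60)2]3+", {"C": 120}, 3),
        ("He", {"He": 1}, 1),
        ("H2O", {"H": 2, "O": 1}, 1),
        ("((CH2)2O)2", {"C": 4, "H": 8, "O": 2}, 1),
    ])
    def test_grammar_cases(self, text, counts, z):
        f = iso.parse_formula(text)
        assert f.as_dict() == counts
        assert f.charge == z
        assert f.label == text

    def test_unknown_element_names_token(self):
        with pytest.raises(iso.FormulaError, match="Qq"):
            iso.parse_formula("Qq2")

    @pytest.mark.parametrize("bad", ["", "2H", "(C60", "C60)", "Na0+2", "()", "C-3"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(iso.FormulaError):
            iso.parse_formula(bad)

    def test_groups_preserved_for_labelling(self):
        f = iso.parse_formula("(C60)3Na12")
        assert f.groups == (("C60", 3), ("Na", 12))


class TestElementPattern:
    def test_artificial_x(self, element_x):
        p = iso.element_pattern(element_x)
        assert p.sticks() == [(1.0, 0.2), (2.0, 0.8)]

    def test_single_isotope(self):
        p = iso.element_pattern(iso.get_element("Na"))
        assert len(p) == 1
        assert p.abundances[0] == 1.0

    @pytest.mark.parametrize("sym", ["C", "O", "S", "Kr", "Xe"])
    def test_abundances_normalised(self, sym):
        p = iso.element_pattern(iso.get_element(sym))
        assert p.total_abundance == pytest.approx(1.0, abs=1e-6)


class TestConvolve:
    def test_x2_brute_force(self, element_x):
        p = iso.element_pattern(element_x)
        out = iso.convolve(p, p, EXACT)
        assert out.masses.tolist() == [2.0, 3.0, 4.0]
        assert out.abundances == pytest.approx([0.04, 0.32, 0.64])

    def test_unit_identity(self, x10_x11):
        unit = IsotopePattern(np.array([0.0]), np.array([1.0]))
        p = x10_x11[0]
        out = iso.convolve(p, unit, EXACT)
        np.testing.assert_allclose(out.masses, p.masses)
        np.testing.assert_allclose(out.abundances, p.abundances)

    def test_abundance_sum_multiplies(self, element_x):
        p = iso.element_pattern(element_x)
        q = iso.prune_low(p, 0.5)  # partial pattern, sum 0.8
        out = iso.convolve(p, q, EXACT)
        assert out.total_abundance == pytest.approx(p.total_abundance * q.total_abundance)

    def test_empty_input_rejected(self, element_x):
        p = iso.element_pattern(element_x)
        empty = IsotopePattern(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            iso.convolve(p, empty)


class TestPruneMerge:
    def test_prune_drops_below_threshold(self):
        p = IsotopePattern.from_sticks([(2, 0.04), (3, 0.32), (4, 0.64)])
        out = iso.prune_low(p, 0.05)
        assert out.sticks() == [(3.0, 0.32), (4.0, 0.64)]

    def test_prune_zero_is_identity(self, x10_x11):
        p = x10_x11[0]
        assert iso.prune_low(p, 0.0) is p

    def test_prune_does_not_renormalise(self):
        p = IsotopePattern.from_sticks([(2, 0.04), (3, 0.32), (4, 0.64)])
        out = iso.prune_low(p, 0.05)
        assert out.total_abundance == pytest.approx(0.96)

    def test_x10_mass_retained_after_mild_pruning(self, element_x):
        p = iso.pattern_power(iso.element_pattern(element_x), 10, PruneConfig(1e-6, 0.0))
        assert p.total_abundance >= 1 - 11 * 1e-6

    def test_merge_weighted_centre_of_mass(self):
        p = IsotopePattern.from_sticks([(10.000, 0.3), (10.005, 0.1)])
        out = iso.merge_close(p, 0.01)
        assert len(out) == 1
        assert out.masses[0] == pytest.approx(10.00125)
        assert out.abundances[0] == pytest.approx(0.4)

    def test_merge_zero_is_identity(self, x10_x11):
        p = x10_x11[0]
        assert iso.merge_close(p, 0.0) is p

    def test_merge_run_semantics(self):
        # chained gaps below eps_m form one run even if the ends are far apart
        p = IsotopePattern.from_sticks([(1.0, 1.0), (1.05, 1.0), (1.10, 1.0), (2.0, 1.0)])
        out = iso.merge_close(p, 0.06)
        assert len(out) == 2
        assert out.masses[0] == pytest.approx(1.05)


class TestPatternPower:
    def test_power_one_is_identity(self, element_x):
        p = iso.element_pattern(element_x)
        out = iso.pattern_power(p, 1, EXACT)
        np.testing.assert_allclose(out.masses, p.masses)

    def test_power_two_equals_convolve(self, element_x):
        p = iso.element_pattern(element_x)
        a = iso.pattern_power(p, 2, EXACT)
        b = iso.convolve(p, p, EXACT)
        np.testing.assert_allclose(a.masses, b.masses)
        np.testing.assert_allclose(a.abundances, b.abundances)

    def test_binomial_closed_form(self, element_x):
        # X_10 abundances are Binomial(10, 0.8) over the heavy-isotope count
        p = iso.pattern_power(iso.element_pattern(element_x), 10, EXACT)
        k = (p.masses - 10).astype(int)
        np.testing.assert_allclose(p.abundances, binom.pmf(k, 10, 0.8), atol=1e-12)

    def test_large_power_no_fp_stick_splitting(self):
        # different summation orders in the binary exponentiation reach the
        # same isotopologue at masses ~1e-10 Da apart; these must combine,
        # so C60 follows Binomial(60, a_13C) stick-for-stick
        p = iso.element_pattern(iso.get_element("C"))
        out = iso.pattern_power(p, 60, EXACT)
        k = np.rint(out.masses - 60 * 12.0).astype(int)
        assert len(np.unique(k)) == len(k)
        np.testing.assert_allclose(out.abundances, binom.pmf(k, 60, 0.0107),
                                   rtol=1e-9)

    @pytest.mark.parametrize("masses, abund, n", [
        ((1.0, 2.0), (0.2, 0.8), 6),
        ((1.0, 2.25, 3.5), (0.5, 0.3, 0.2), 5),
        ((1.0, 2.0, 3.5, 5.0), (0.4, 0.3, 0.2, 0.1), 4),
    ])
    def test_matches_exhaustive_enumeration(self, masses, abund, n):
        p = IsotopePattern(np.array(masses), np.array(abund))
        out = iso.pattern_power(p, n, EXACT)
        m_ref, a_ref = brute_force_power(masses, abund, n)
        np.testing.assert_allclose(out.masses, m_ref, atol=1e-9)
        np.testing.assert_allclose(out.abundances, a_ref, atol=1e-12)

    def test_invalid_power(self, element_x):
        with pytest.raises(ValueError):
            iso.pattern_power(iso.element_pattern(element_x), 0)


class TestSpeciesPattern:
    def test_x2(self):
        p = iso.species_pattern(iso.parse_formula("X2"), EXACT)
        assert p.abundances == pytest.approx([0.04, 0.32, 0.64])

    def test_charge_divides_masses(self):
        p1 = iso.species_pattern(iso.parse_formula("X2"), EXACT)
        p2 = iso.species_pattern(iso.parse_formula("X2 2+"), EXACT)
        np.testing.assert_allclose(p2.masses, p1.masses / 2)
        np.testing.assert_allclose(p2.abundances, p1.abundances)

    def test_electron_mass_correction_opt_in(self):
        f = iso.parse_formula("Na 1+")
        off = iso.species_pattern(f, EXACT)
        on = iso.species_pattern(f, EXACT, electron_mass_correction=True)
        assert off.masses[0] - on.masses[0] == pytest.approx(iso.ELECTRON_MASS_DA)

    @pytest.mark.parametrize("formula", ["X2", "X10", "H2O", "(C60)3Na12", "C40 2+"])
    def test_normalisation(self, formula):
        p = iso.species_pattern(iso.parse_formula(formula), EXACT)
        assert p.total_abundance == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

def patterns(max_sticks=8):
    return st.lists(
        st.tuples(st.floats(0.5, 500.0), st.floats(1e-6, 1.0)),
        min_size=1, max_size=max_sticks,
        unique_by=lambda t: round(t[0], 6),
    ).map(IsotopePattern.from_sticks)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(p=patterns(), eps_m=st.floats(0.0, 10.0))
def test_merge_conserves_moments(p, eps_m):
    out = iso.merge_close(p, eps_m)
    assert out.total_abundance == pytest.approx(p.total_abundance, rel=1e-12)
    assert np.sum(out.masses * out.abundances) == pytest.approx(
        np.sum(p.masses * p.abundances), rel=1e-12)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(p=patterns(), eps1=st.floats(0.0, 0.5), eps2=st.floats(0.0, 0.5))
def test_pruning_monotone_in_threshold(p, eps1, eps2):
    lo, hi = sorted([eps1, eps2])
    a, b = iso.prune_low(p, lo), iso.prune_low(p, hi)
    assert len(b) <= len(a)
    assert b.total_abundance <= a.total_abundance + 1e-15


@settings(max_examples=40, deadline=None, derandomize=True)
@given(p=patterns(4), q=patterns(4))
def test_convolution_distributes_abundance(p, q):
    out = iso.convolve(p, q, EXACT)
    assert out.total_abundance == pytest.approx(
        p.total_abundance * q.total_abundance, rel=1e-9)


def test_series_enumeration_count():
    series = iso.expand_series([("C60", 1, 10), ("Na", 0, 40), ("H2O", 0, 1)])
    helium = iso.expand_series([("He", 1, 200)])
    sodium = iso.expand_series([("Na", 1, 100)])
    assert len(series) == 820
    assert len(helium) == 200
    assert len(sodium) == 100
    assert len(series) + len(helium) + len(sodium) == 1120
    assert all(f.charge == 1 for f in series)
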