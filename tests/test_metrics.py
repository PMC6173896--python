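"""Community metrics: Hill numbers, corrections, label ratio, unit maths."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stf

from admsplit.metrics import (CommunityProfile, c13_pathway_ratio,
                              copy_number_correct, evenness, hill_diversity,
                              mrta_correct, vfa_unit_convert)


def brute_force_hill(p, q):
    """Directly from the definition, no shortcuts."""
    p = [x for x in p if x > 0]
    if q == 0:
        return len(p)
    if q == 1:
        return math.exp(-sum(x * math.log(x) for x in p))
    return sum(x ** q for x in p) ** (1 / (1 - q))


class TestHillNumbers:
    @pytest.mark.parametrize("p,q,expected", [
        ([0.5, 0.5], 0.0, 2.0),
        ([0.5, 0.5], 1.0, 2.0),
        ([0.5, 0.5], 2.0, 2.0),
        ([0.75, 0.25], 2.0, 1.6),                       # 1/(0.5625+0.0625)
        ([0.75, 0.25], 1.0, math.exp(0.5623351446)),    # exp(Shannon)
    ])
    def test_reference_values(self, p, q, expected):
        assert hill_diversity(p, q) == pytest.approx(expected, rel=1e-9)

    @given(counts=stf.lists(stf.floats(0.01, 100.0), min_size=1, max_size=30),
           q=stf.sampled_from([0.0, 0.5, 1.0, 2.0, 3.0]))
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_on_random_profiles(self, counts, q):
        p = np.asarray(counts) / np.sum(counts)
        assert hill_diversity(p, q) == pytest.approx(
            brute_force_hill(p, q), rel=1e-12)

    @given(counts=stf.lists(stf.floats(0.01, 100.0), min_size=2, max_size=20))
    @settings(max_examples=40, deadline=None)
    def test_nonincreasing_in_q_and_evenness_bounded(self, counts):
        p = np.asarray(counts) / np.sum(counts)
        qs = [0.0, 0.5, 1.0, 2.0, 4.0]
        d = [hill_diversity(p, q) for q in qs]
        assert all(b <= a + 1e-9 for a, b in zip(d, d[1:]))
        for q in qs:
            assert 0.0 < evenness(p, q) <= 1.0 + 1e-12

    def test_evenness_reference_points(self):
        assert evenness([0.25] * 4, 2.0) == pytest.approx(1.0)
        assert evenness([0.75, 0.25], 0.0) == pytest.approx(1.0)
        assert evenness([0.75, 0.25], 2.0) == pytest.approx(0.8)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            hill_diversity([0.5, 0.5], -1.0)


class TestCopyNumberCorrection:
    def test_equal_copies_change_nothing(self):
        p = CommunityProfile(("a", "b"), np.array([0.3, 0.7]),
                             copy_numbers=np.array([4.0, 4.0]))
        out = copy_number_correct(p)
        assert out.abundances == pytest.approx([0.3, 0.7])

    def test_high_copy_taxon_is_deflated(self):
        p = CommunityProfile(("a", "b"), np.array([0.5, 0.5]),
                             copy_numbers=np.array([4.0, 1.0]))
        out = copy_number_correct(p)
        assert out.abundances == pytest.approx([0.2, 0.8])

    def test_idempotent_once_copies_are_one(self):
        p = CommunityProfile(("a", "b"), np.array([0.5, 0.5]),
                             copy_numbers=np.array([4.0, 1.0]))
        once = copy_number_correct(p)
        unit = CommunityProfile(once.labels, once.abundances,
                                copy_numbers=np.ones(2))
        again = copy_number_correct(unit)
        assert again.abundances == pytest.approx(once.abundances)
        assert again.abundances.sum() == pytest.approx(1.0)

    def test_missing_copies_rejected(self):
        p = CommunityProfile(("a",), np.array([1.0]))
        with pytest.raises(ValueError):
            copy_number_correct(p)


class TestMrtaCorrection:
    def test_absent_orders_change_nothing(self):
        p = CommunityProfile(("a", "b"), np.array([0.4, 0.6]),
                             orders=("Methanosarcinales", "Methanomicrobiales"))
        assert mrta_correct(p).abundances == pytest.approx([0.4, 0.6])

    def test_double_copy_order_is_halved_then_renormalised(self):
        p = CommunityProfile(("mb", "other"), np.array([0.4, 0.6]),
                             orders=("Methanobacteriales", "Methanosarcinales"))
        assert mrta_correct(p).abundances == pytest.approx([0.25, 0.75])

    def test_all_double_copy_profile_still_sums_to_one(self):
        p = CommunityProfile(("a", "b"), np.array([0.5, 0.5]),
                             orders=("Methanobacteriales", "Methanococcales"))
        out = mrta_correct(p)
        assert out.abundances.sum() == pytest.approx(1.0)
        assert out.abundances == pytest.approx([0.5, 0.5])


class TestC13Ratio:
    def test_equal_label_is_the_boundary(self):
        assert c13_pathway_ratio(0.5, 0.5) == (1.0, "boundary")

    def test_low_ratio_flags_acetoclastic(self):
        ratio, flag = c13_pathway_ratio(0.03, 1.0)
        assert ratio == pytest.approx(0.03)
        assert flag == "acetoclastic"

    def test_scale_invariance(self):
        r1, _ = c13_pathway_ratio(0.2, 0.8)
        r2, _ = c13_pathway_ratio(2.0, 8.0)
        assert r1 == pytest.approx(r2)

    def test_no_methane_is_oxidative_sentinel(self):
        ratio, flag = c13_pathway_ratio(1.0, 0.0)
        assert math.isinf(ratio) and flag == "oxidative"


class TestVfaUnitConvert:
    """The 45/10/45 COD-based acid mixture of the reactor medium."""

    FRACTIONS = {"acetic": 0.45, "propionic": 0.10, "butyric": 0.45}

    def test_mass_per_gcod(self):
        df = vfa_unit_convert(self.FRACTIONS, 1.0)
        assert df["mass"].sum() == pytest.approx(0.74, abs=0.005)

    def test_mass_at_experiment_concentration(self):
        df = vfa_unit_convert(self.FRACTIONS, 37.2)
        assert df["mass"].sum() == pytest.approx(27.4, abs=0.05)

    def test_mol_and_mass_fractions(self):
        df = vfa_unit_convert(self.FRACTIONS, 1.0)
        mol = (100 * df["mol_fraction"]).round().astype(int)
        mass = (100 * df["mass_fraction"]).round().astype(int)
        assert (mol["acetic"], mol["propionic"], mol["butyric"]) == (65, 8, 26)
        assert (mass["acetic"], mass["propionic"], mass["butyric"]) == (57, 9, 34)

    def test_round_trip_mass_to_cod(self):
        df = vfa_unit_convert(self.FRACTIONS, 37.2)
        from admsplit.metrics import VFA_COD_FACTORS
        back = sum(df.loc[a, "mass"] * VFA_COD_FACTORS[a] for a in df.index)
        assert back == pytest.approx(37.2, rel=1e-12)

    def test_bad_fraction_sum_rejected(self):
        with pytest.raises(ValueError):
            vfa_unit_convert({"acetic": 0.5, "butyric": 0.49}, 1.0)
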