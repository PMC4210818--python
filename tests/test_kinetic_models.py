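import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicekin import kinetic_models as km


class TestGeneLayout:
    def test_default_layout_invariants(self, layout):
        assert layout.pp7_start < layout.pp7_end <= layout.ss3
        assert layout.ss3 < layout.ms2_start < layout.ms2_end <= layout.polyA

    def test_cassette_separation(self, layout):
        assert layout.cassette_separation == 2573

    def test_cassette_lengths_are_12x_repeat_units(self, layout):
        assert layout.pp7_length == 1452 == 12 * 121
        assert layout.ms2_length == 1308 == 12 * 109

    def test_3ss_to_end_time_is_55s_at_control_rate(self, layout):
        t = km.elongation_time(layout.ss3, layout.polyA, 2.60)
        assert t == pytest.approx(55.0, abs=0.01)
        assert layout.polyA - layout.ss3 == 2383

    def test_order_violation_rejected(self):
        with pytest.raises(ValueError):
            km.GeneLayout(pp7_start=100, pp7_end=50, ss3=200, ms2_start=300,
                          ms2_end=400, polyA=500)

    def test_dict_round_trip(self, layout):
        assert km.GeneLayout.from_dict(layout.to_dict()) == layout


class TestElongationTime:
    def test_cassette_separation_at_observed_rate(self):
        # 2573 nt at 2.573 kb/min is one minute
        assert km.elongation_time(0, 2573, 2.573) == pytest.approx(60.0)

    def test_zero_distance(self):
        assert km.elongation_time(1000, 1000, 1.7) == 0.0

    def test_ssa_rate_traversal(self):
        assert km.elongation_time(0, 2383, 2.41) == pytest.approx(
            2383 / (2410 / 60), rel=1e-12)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            km.elongation_time(0, 100, 0.0)
        with pytest.raises(ValueError):
            km.elongation_time(0, 100, -1.0)

    def test_implied_rate(self):
        assert km.implied_elongation_rate(2573, 60.0) == pytest.approx(2.573)

    def test_coat_protein_binding_time(self):
        assert km.coat_protein_binding_time(0.54, 1.0) == pytest.approx(
            1.0 / 0.54)


class TestDelaySpec:
    def test_dirac_has_zero_variance(self):
        d = km.dirac(42.0)
        assert d.var == 0.0
        assert np.all(d.sample(np.random.default_rng(0), 100) == 42.0)

    def test_gamma_shape_one_equals_exponential(self):
        u = np.linspace(0.01, 0.99, 50)
        g = km.gamma_delay(30.0, shape=1.0).ppf(u)
        e = km.exponential(30.0).ppf(u)
        np.testing.assert_allclose(g, e, rtol=1e-8)

    def test_sample_moments(self):
        rng = np.random.default_rng(3)
        x = km.gamma_delay(100.0, shape=4.0).sample(rng, 200_000)
        assert x.mean() == pytest.approx(100.0, rel=0.02)
        assert x.var() == pytest.approx(100.0 ** 2 / 4.0, rel=0.05)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            km.DelaySpec("weibull", 10.0)
        with pytest.raises(ValueError):
            km.DelaySpec("exponential", -1.0)
        with pytest.raises(ValueError):
            km.DelaySpec("gamma", 10.0)  # missing shape


class TestKineticModel:
    def test_there_are_21_variants(self):
        assert len(km.VARIANTS) == 21
        schemes = {v.scheme for v in km.VARIANTS.values()}
        assert schemes == set(km.SCHEMES)

    def test_model_ii4_has_three_free_parameters(self):
        spec = km.VARIANTS["II.4"]
        assert spec.k_params == 3
        assert spec.free_params == ("v", "splice.mean", "release.mean")

    @pytest.mark.parametrize("variant,k", [
        ("I.1", 1), ("I.2", 2), ("I.3", 2), ("I.4", 3),
        ("II.1", 2), ("II.5", 4), ("II.8", 4),
        ("III.1", 2), ("IV.1", 2), ("IV.3", 4), ("V.3", 4)])
    def test_free_parameter_counts(self, variant, k):
        assert km.VARIANTS[variant].k_params == k

    def test_inactive_delay_must_be_dirac_zero(self):
        with pytest.raises(ValueError):
            km.KineticModel(variant="I.1", v=2.6, splice=km.exponential(100.0))

    def test_wrong_family_rejected(self):
        with pytest.raises(ValueError):
            km.KineticModel(variant="II.4", v=2.6, splice=km.exponential(267.0),
                            release=km.exponential(116.0))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            km.make_model("VI.1", v=2.6)

    def test_dict_round_trip(self, control_model):
        again = km.KineticModel.from_dict(control_model.to_dict())
        assert again == control_model

    def test_with_params(self, control_model):
        m = control_model.with_params(**{"splice.mean": 300.0, "v": 3.0})
        assert m.splice.mean == 300.0
        assert m.v == 3.0
        assert m.release == control_model.release


class TestPreReleaseFraction:
    def test_control_closed_form(self, control_model, layout):
        # exp(-(267 - 55) / 116.1), cf. the reference 15.9 %
        expected = math.exp(-(267.0 - 55.0) / 116.1)
        frac = km.pre_release_fraction(control_model, layout)
        assert frac == pytest.approx(expected, abs=1e-4)
        assert abs(100 * frac - 15.9) < 0.3

    def test_ssa_closed_form(self, layout):
        model = km.make_model("II.4", v=2.41, splice_mean=485.0,
                              release_mean=126.7)
        t_el = 2383 / (2410 / 60)
        expected = math.exp(-(485.0 - t_el) / 126.7)
        frac = km.pre_release_fraction(model, layout)
        assert frac == pytest.approx(expected, abs=1e-4)
        assert abs(100 * frac - 3.5) < 0.3

    def test_splicing_during_elongation_gives_one(self, layout):
        model = km.make_model("II.4", v=2.60, splice_mean=30.0,
                              release_mean=116.1)
        assert km.pre_release_fraction(model, layout) == 1.0

    def test_scheme_i_zero_scheme_v_one(self, layout):
        mi = km.make_model("I.3", v=2.6, release_mean=100.0)
        mv = km.make_model("V.2", v=2.6, splice_mean=150.0, release_mean=100.0)
        assert km.pre_release_fraction(mi, layout) == 0.0
        assert km.pre_release_fraction(mv, layout) == 1.0

    def test_scheme_iii_and_iv_by_construction(self, layout):
        assert km.pre_release_fraction(
            km.make_model("III.1", v=2.6, splice_mean=150.0), layout) == 1.0
        assert km.pre_release_fraction(
            km.make_model("IV.2", v=2.6, splice_mean=60.0,
                          release_mean=100.0), layout) == 1.0

    def test_iv4_competition(self, layout):
        m = km.make_model("IV.4", v=2.6, splice_mean=60.0, release_mean=90.0)
        assert km.pre_release_fraction(m, layout) == pytest.approx(
            90.0 / 150.0)

    def test_monotone_in_splice_time_and_release_time(self, layout):
        for tr in (50.0, 116.1, 300.0):
            fracs = [km.pre_release_fraction(
                km.make_model("II.4", v=2.6, splice_mean=s, release_mean=tr),
                layout) for s in (60.0, 150.0, 267.0, 500.0, 900.0)]
            assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))
        for s in (150.0, 267.0, 500.0):
            fracs = [km.pre_release_fraction(
                km.make_model("II.4", v=2.6, splice_mean=s, release_mean=tr),
                layout) for tr in (30.0, 80.0, 116.1, 250.0, 600.0)]
            assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_generic_mc_matches_closed_form(self, layout):
        # II.7 (both exponential) has the closed form tr/(tr + ts) after
        # accounting for the elongation head start:
        # P(S < t_el + R) with S ~ Exp(ts), R ~ Exp(tr)
        ts_, tr = 200.0, 116.1
        t_el = km.elongation_time(layout.ss3, layout.polyA, 2.60)
        m = km.make_model("II.7", v=2.60, splice_mean=ts_, release_mean=tr)
        # P(S > t_el + R) = E[e^-(t_el+R)/ts] = e^(-t_el/ts) * ts/(ts+tr)
        p_post = math.exp(-t_el / ts_) * ts_ / (ts_ + tr)
        frac, se = km.pre_release_fraction(m, layout, n_mc=400_000,
                                           rng=np.random.default_rng(7),
                                           return_se=True)
        assert frac == pytest.approx(1.0 - p_post, abs=3 * se + 1e-9)

    def test_mc_se_scaling(self, layout):
        m = km.make_model("II.7", v=2.6, splice_mean=200.0, release_mean=100.0)
        _, se1 = km.pre_release_fraction(m, layout, n_mc=10_000,
                                         rng=np.random.default_rng(0),
                                         return_se=True)
        _, se2 = km.pre_release_fraction(m, layout, n_mc=40_000,
                                         rng=np.random.default_rng(0),
                                         return_se=True)
        assert se2 == pytest.approx(se1 / 2.0, rel=0.15)

    def test_negative_parameters_rejected(self, layout):
        with pytest.raises(ValueError):
            km.make_model("II.4", v=2.6, splice_mean=-5.0, release_mean=100.0)


class TestExpectedLabelRatio:
    def test_control_value(self, control_model, layout):
        # closed form for model II.4 with the default geometry; the companion
        # Monte Carlo oracle is test_closed_form_matches_mc below
        ratio = km.expected_label_ratio(control_model, layout)
        assert ratio == pytest.approx(1.295, abs=0.005)

    def test_never_spliced_symmetric_layout_gives_one(self):
        # tiny cassettes adjacent to the poly(A) site and a dominant release
        # dwell: both labels persist until release, ratio -> 1
        lay = km.GeneLayout(pp7_start=0, pp7_end=2, ss3=2, ms2_start=3,
                            ms2_end=5, polyA=5)
        m = km.make_model("II.4", v=2.6, splice_mean=1e9, release_mean=1e6)
        assert km.expected_label_ratio(m, lay) == pytest.approx(1.0, abs=1e-3)

    def test_closed_form_matches_mc(self, control_model, layout):
        ratio_mc, se = km.expected_label_ratio(
            control_model.with_params(v=control_model.v), layout,
            return_se=True)
        red, green = km.label_occupancies_mc(control_model, layout, 1_000_000,
                                             np.random.default_rng(11))
        mc_ratio = red.mean() / green.mean()
        closed = km.expected_label_ratio(control_model, layout)
        # SE of the MC ratio via the delta method
        cov = np.cov(red, green) / len(red)
        g = np.array([1 / green.mean(), -red.mean() / green.mean() ** 2])
        mc_se = np.sqrt(g @ cov @ g)
        assert mc_ratio == pytest.approx(closed, abs=3 * mc_se)

    def test_derived_quantities_bundle(self, control_model, layout):
        d = km.derived_quantities(control_model, layout)
        assert 0.0 <= d.pre_release_fraction <= 1.0
        assert d.label_ratio > 0
        assert d.t_elong_3ss_to_end == pytest.approx(55.0, abs=0.01)


@settings(max_examples=25, deadline=None)
@given(splice=st.floats(60.0, 900.0), release=st.floats(20.0, 400.0),
       v=st.floats(0.8, 5.0))
def test_pre_release_fraction_in_unit_interval(splice, release, v):
    layout = km.default_reporter_layout()
    m = km.make_model("II.4", v=v, splice_mean=splice, release_mean=release)
    assert 0.0 <= km.pre_release_fraction(m, layout) <= 1.0
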