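import numpy as np
import pytest
from shapely.geometry import Polygon

from splicekin import kinetic_models as km
from splicekin import spatial as sp
from splicekin import trace_simulator as ts


@pytest.fixture(scope="module")
def nucleus():
    return Polygon(ts.circle_polygon(8.0))


class TestPairing:
    def test_identical_lists_all_paired_at_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-5, 5, (30, 2))
        paired = sp.pair_colocalized(pts, pts, radius=0.25)
        assert paired.n_colocalized == 30
        np.testing.assert_allclose(paired.pair_distances, 0.0)
        assert len(paired.red_only) == 0 and len(paired.green_only) == 0

    def test_distant_spots_unpaired(self):
        red = np.array([[0.0, 0.0]])
        green = np.array([[1.0, 1.0]])
        paired = sp.pair_colocalized(red, green, radius=0.25)
        assert paired.n_colocalized == 0
        assert len(paired.red_only) == 1 and len(paired.green_only) == 1

    def test_symmetric_under_channel_swap(self):
        rng = np.random.default_rng(1)
        red = rng.uniform(-3, 3, (20, 2))
        green = red + rng.normal(0, 0.05, red.shape)
        a = sp.pair_colocalized(red, green, 0.25)
        b = sp.pair_colocalized(green, red, 0.25)
        assert a.n_colocalized == b.n_colocalized
        np.testing.assert_allclose(np.sort(a.pair_distances),
                                   np.sort(b.pair_distances))

    def test_invariant_to_ordering(self):
        rng = np.random.default_rng(2)
        red = rng.uniform(-3, 3, (25, 2))
        green = red + rng.normal(0, 0.05, red.shape)
        perm = rng.permutation(25)
        a = sp.pair_colocalized(red, green, 0.25)
        b = sp.pair_colocalized(red[perm], green, 0.25)
        assert a.n_colocalized == b.n_colocalized
        np.testing.assert_allclose(np.sort(a.pair_distances),
                                   np.sort(b.pair_distances), atol=1e-12)

    def test_mutual_method(self):
        red = np.array([[0.0, 0.0], [0.2, 0.0]])
        green = np.array([[0.05, 0.0]])
        greedy = sp.pair_colocalized(red, green, 0.25, method="greedy")
        mutual = sp.pair_colocalized(red, green, 0.25, method="mutual")
        assert greedy.n_colocalized == mutual.n_colocalized == 1
        assert greedy.pair_distances[0] == pytest.approx(0.05)

    def test_recall_on_simulated_field_with_jitter(self):
        # ground-truth pre-mRNA (both channels) with 50 nm localization
        # jitter: pairing at 250 nm recovers > 95 %
        field = ts.simulate_particle_field(
            0.12, km.exponential(12.7), emission_rate=2.0,
            nucleus=ts.circle_polygon(8.0), n_frames=80,
            rng_seed=3, loc_jitter_sd=0.05)
        df = field.particles
        n_pre, n_paired = 0, 0
        for _, grp in df.groupby("frame"):
            red = grp[grp.channel == "red"][["x_um", "y_um"]].to_numpy()
            green = grp[grp.channel == "green"][["x_um", "y_um"]].to_numpy()
            paired = sp.pair_colocalized(red, green, 0.25)
            n_pre += len(red)
            n_paired += paired.n_colocalized
        assert n_pre > 300
        assert n_paired / n_pre > 0.95

    def test_rejects_bad_radius(self):
        with pytest.raises(ValueError):
            sp.pair_colocalized(np.zeros((1, 2)), np.zeros((1, 2)), 0.0)


class TestRadialProfile:
    def test_uniform_particles_flat_at_one(self, nucleus):
        rng = np.random.default_rng(4)
        pts = sp.uniform_points_in_polygon(nucleus, 30_000, rng)
        prof = sp.radial_profile(pts, np.zeros(2), nucleus, n_null=100_000,
                                 bins=np.arange(0, 8.0, 0.5), rng_seed=5)
        ok = np.isfinite(prof.density_ratio)
        assert np.all(np.abs(prof.density_ratio[ok] - 1.0) < 0.15)
        assert np.nanmean(prof.density_ratio[ok]) == pytest.approx(1.0,
                                                                   abs=0.03)

    def test_enriched_field_decays_with_distance(self, nucleus):
        field = ts.simulate_particle_field(
            0.12, km.exponential(12.7), 2.0, ts.circle_polygon(8.0),
            n_frames=100, rng_seed=6)
        df = field.particles
        pre = df[df.channel == "red"][["x_um", "y_um"]].to_numpy()
        prof = sp.radial_profile(pre, np.zeros(2), nucleus, n_null=50_000,
                                 bins=np.arange(0, 8.0, 1.0), rng_seed=7)
        vals = prof.density_ratio
        assert vals[0] > 5.0
        assert vals[0] > vals[2] > vals[-1]

    def test_fish_mode_uniform_reference_flat(self, nucleus):
        rng = np.random.default_rng(8)
        pre = sp.uniform_points_in_polygon(nucleus, 20_000, rng)
        mrna = sp.uniform_points_in_polygon(nucleus, 20_000, rng)
        prof = sp.radial_profile(pre, np.zeros(2), nucleus,
                                 null_particles=mrna,
                                 bins=np.arange(0, 8.0, 0.5), rng_seed=9)
        ok = np.isfinite(prof.density_ratio)
        assert np.abs(prof.density_ratio[ok] - 1.0).max() < 0.2

    def test_empty_rejected(self, nucleus):
        with pytest.raises(ValueError):
            sp.radial_profile(np.zeros((0, 2)), np.zeros(2), nucleus)

    def test_multi_cell_bootstrap_sem(self, nucleus):
        rng = np.random.default_rng(10)
        cells = [sp.uniform_points_in_polygon(nucleus, 2000, rng)
                 for _ in range(5)]
        prof = sp.radial_profile(cells, [np.zeros(2)] * 5, [nucleus] * 5,
                                 n_null=20_000, bins=np.arange(0, 8.0, 1.0),
                                 n_boot=100, rng_seed=11)
        assert prof.sem is not None
        assert np.all(prof.sem[np.isfinite(prof.sem)] >= 0)


class TestFitEnrichment:
    def _profile(self, sigma=2.4, h=5.0, y0=1.0, noise=0.05, seed=0):
        edges = np.arange(0.0, 10.5, 0.5)
        r = 0.5 * (edges[1:] + edges[:-1])
        rng = np.random.default_rng(seed)
        y = y0 + h * np.exp(-r ** 2 / (2 * sigma ** 2)) + rng.normal(0, noise,
                                                                     len(r))
        return sp.RadialProfile(edges, y, np.full(len(r), noise))

    def test_round_trip_recovery(self):
        prof = self._profile()
        enr = sp.fit_enrichment(prof, exclusion_um=1.0)
        assert enr.sigma == pytest.approx(2.4, abs=3 * enr.sigma_se)
        assert enr.height == pytest.approx(5.0, abs=3 * enr.height_se)
        assert enr.baseline == pytest.approx(1.0, abs=3 * enr.baseline_se)

    def test_flat_profile_flagged_unidentifiable(self):
        prof = self._profile(h=0.0, noise=0.02, seed=1)
        enr = sp.fit_enrichment(prof)
        assert not enr.identifiable
        assert "unidentifiable" in enr.message

    def test_exclusion_drops_artifact_bins(self):
        prof = self._profile()
        # corrupt the artifact region: must not affect the fit
        prof.density_ratio[:2] = 0.0
        enr = sp.fit_enrichment(prof, exclusion_um=1.0)
        assert enr.sigma == pytest.approx(2.4, abs=3 * enr.sigma_se)

    def test_too_few_bins_rejected(self):
        edges = np.arange(0.0, 2.0, 0.5)
        prof = sp.RadialProfile(edges, np.ones(3))
        with pytest.raises(ValueError):
            sp.fit_enrichment(prof)


class TestSpliceTimeClock:
    def test_reference_inputs(self):
        # sigma = 2.421 um, D = 0.12 um^2/s -> 12.2 s by the formula
        assert sp.post_release_splice_time(2.421, 0.12) == pytest.approx(
            2.421 ** 2 / 0.48)

    def test_quadratic_in_sigma(self):
        t1 = sp.post_release_splice_time(1.0, 0.12)
        t2 = sp.post_release_splice_time(2.0, 0.12)
        assert t2 == pytest.approx(4 * t1)

    def test_inverse_linear_in_d(self):
        assert sp.post_release_splice_time(2.0, 0.24) == pytest.approx(
            sp.post_release_splice_time(2.0, 0.12) / 2)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sp.post_release_splice_time(0.0, 0.12)
        with pytest.raises(ValueError):
            sp.post_release_splice_time(1.0, 0.0)

    def test_end_to_end_pipeline_calibration(self):
        """Full chain on a large simulated field.

        A Gaussian fitted to the diffusing-age mixture profile carries the
        profile's second moment, 2*sigma^2 ~ E[r^2] = 4*D*tau, so the
        sigma^2/(4D) clock reads ~tau/2 for exponential lifetimes.  This
        pins down the pipeline's actual calibration; the nominal-tau
        version of this check lives in the acceptance suite.
        """
        D, tau = 0.12, 12.7
        nuc_poly = ts.circle_polygon(12.0)
        field = ts.simulate_particle_field(D, km.exponential(tau), 3.0,
                                           nuc_poly, n_frames=130,
                                           frame_interval=3.26, rng_seed=12,
                                           substep=2)
        df = field.particles
        n_pre, coloc = 0, []
        for _, grp in df.groupby("frame"):
            red = grp[grp.channel == "red"][["x_um", "y_um"]].to_numpy()
            green = grp[grp.channel == "green"][["x_um", "y_um"]].to_numpy()
            paired = sp.pair_colocalized(red, green, 0.25)
            n_pre += len(red)
            if paired.n_colocalized:
                coloc.append(paired.colocalized.mean(axis=1))
        pre = np.vstack(coloc)
        assert len(pre) >= 4000
        prof = sp.radial_profile(pre, np.zeros(2), Polygon(nuc_poly),
                                 n_null=100_000,
                                 bins=np.arange(0, 12.5, 0.5), rng_seed=13)
        enr = sp.fit_enrichment(prof, exclusion_um=1.0)
        t_rec = sp.post_release_splice_time(enr.sigma, D)
        assert t_rec == pytest.approx(tau / 2.0, rel=0.3)


class TestCounting:
    def test_ts_intensity_five_times_single(self):
        singles = np.full(20, 2.0)
        n_red, n_green, ratio = sp.count_nascent(10.0, 4.0, singles, singles)
        assert n_red == 5.0 and n_green == 2.0 and ratio == 2.5

    def test_simulated_counting_recovers_k(self):
        rng = np.random.default_rng(14)
        k = 7
        singles_r = rng.normal(1.0, 0.1, 200)
        singles_g = rng.normal(1.0, 0.1, 200)
        ts_r = k * 1.0 + rng.normal(0, 0.2)
        ts_g = k * 1.0 + rng.normal(0, 0.2)
        n_red, n_green, _ = sp.count_nascent(ts_r, ts_g, singles_r, singles_g)
        se = k * 0.1 / np.sqrt(200) + 0.2
        assert n_red == pytest.approx(k, abs=3 * se)
        assert n_green == pytest.approx(k, abs=3 * se)

    def test_requires_ten_singles(self):
        with pytest.raises(ValueError):
            sp.count_nascent(5.0, 5.0, np.ones(5), np.ones(20))


class TestPremrnaFraction:
    def _paired(self, n_coloc, n_green):
        coloc = np.zeros((n_coloc, 2, 2))
        return sp.PairedParticles(coloc, np.zeros(n_coloc),
                                  np.zeros((0, 2)), np.zeros((n_green, 2)),
                                  0.2)

    def test_no_colocalized_zero(self):
        assert sp.premrna_fraction(self._paired(0, 10)) == 0.0

    def test_all_colocalized_one(self):
        assert sp.premrna_fraction(self._paired(12, 0)) == 1.0

    def test_ts_excluded_by_intensity(self):
        paired = self._paired(5, 5)
        intensities = [1.0, 1.0, 1.0, 5.0, 6.0]  # two TSs at > 2x single
        frac = sp.premrna_fraction(paired, intensities, 1.0)
        assert frac == pytest.approx(3 / 8)

    def test_binomial_recovery_of_16_percent(self):
        rng = np.random.default_rng(15)
        n = 4000
        is_pre = rng.random(n) < 0.16
        frac = sp.premrna_fraction(self._paired(int(is_pre.sum()),
                                                int((~is_pre).sum())))
        se = np.sqrt(0.16 * 0.84 / n)
        assert frac == pytest.approx(0.16, abs=3 * se)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            sp.premrna_fraction(self._paired(0, 0))
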