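"""Sensitized-emission pixel FRET: calibration, maps, ROIs, histograms, peaks."""

import numpy as np
import pytest

from dilfret import (
    BleedThrough,
    CalibrationError,
    EffHistogram,
    ThreeChannelImage,
    broad_vs_narrow_score,
    detect_peaks,
    efficiency_map,
    estimate_bleedthrough,
    histogram_efficiency,
    make_eff_histogram,
    ring_roi_mask,
)
from dilfret.synthetic_data import MixtureSpec


def _flat_image(donor, acceptor, fret, shape=(64, 64)):
    return ThreeChannelImage(
        donor=np.full(shape, float(donor)),
        acceptor=np.full(shape, float(acceptor)),
        fret=np.full(shape, float(fret)),
    )


def _calibration_pair(beta_d=0.2, beta_a=0.1, noise=0.0, rng=None, shape=(100, 100)):
    if rng is None:
        rng = np.random.default_rng(0)
    donor = rng.uniform(50.0, 500.0, shape)
    donor_only = ThreeChannelImage(
        donor=donor,
        acceptor=np.zeros(shape),
        fret=beta_d * donor * (1.0 + noise * rng.standard_normal(shape)),
    )
    acceptor = rng.uniform(50.0, 500.0, shape)
    acceptor_only = ThreeChannelImage(
        donor=np.zeros(shape),
        acceptor=acceptor,
        fret=beta_a * acceptor * (1.0 + noise * rng.standard_normal(shape)),
    )
    return donor_only, acceptor_only


class TestBleedThrough:
    def test_exact_recovery_without_noise(self):
        d_only, a_only = _calibration_pair()
        bt = estimate_bleedthrough(d_only, a_only)
        assert bt.beta_donor == pytest.approx(0.2, abs=1e-9)
        assert bt.beta_acceptor == pytest.approx(0.1, abs=1e-9)

    def test_recovery_under_noise(self, rng):
        d_only, a_only = _calibration_pair(noise=0.05, rng=rng)
        bt = estimate_bleedthrough(d_only, a_only)
        assert bt.beta_donor == pytest.approx(0.2, rel=0.01)
        assert bt.beta_acceptor == pytest.approx(0.1, rel=0.01)

    def test_all_zero_calibration_rejected(self):
        blank = _flat_image(0, 0, 0)
        with pytest.raises(CalibrationError):
            estimate_bleedthrough(blank, blank)


class TestEfficiencyMap:
    def test_algebraic_inverse_round_trip(self, rng):
        # pixels built through the inverse formula, no bleed-through, gamma=1
        shape = (40, 40)
        true_e = rng.uniform(0.1, 0.9, shape)
        donor = np.full(shape, 200.0) * (1.0 - true_e)
        fret = np.full(shape, 200.0) * true_e
        image = ThreeChannelImage(donor=donor, acceptor=np.zeros(shape), fret=fret)
        bt = BleedThrough(0.0, 0.0, gamma=1.0)
        eff, mask = efficiency_map(
            image, bt, background_rule=np.ones(shape, bool), subtract_background=False
        )
        assert mask.all()
        np.testing.assert_allclose(eff, true_e, atol=1e-12)

    def test_donor_only_pixels_score_zero(self):
        shape = (32, 32)
        donor = np.full(shape, 300.0)
        image = ThreeChannelImage(
            donor=donor, acceptor=np.zeros(shape), fret=0.2 * donor
        )
        eff, mask = efficiency_map(
            image, BleedThrough(0.2, 0.0),
            background_rule=np.ones(shape, bool), subtract_background=False,
        )
        np.testing.assert_allclose(eff[mask], 0.0, atol=1e-12)

    def test_gamma_must_be_positive(self):
        image = _flat_image(10, 10, 10)
        with pytest.raises(ValueError):
            efficiency_map(image, BleedThrough(0.1, 0.1, gamma=0.0))


class TestRingRoi:
    def test_everything_inside_wide_ring(self):
        # off-lattice center: every pixel sits strictly between the radii
        mask = ring_roi_mask((20, 20), (10.5, 10.5), 1e-4, 100.0)
        assert mask.all()

    def test_area_matches_annulus(self):
        inner, outer = 20.0, 30.0
        mask = ring_roi_mask((200, 200), (100, 100), inner, outer)
        expected = np.pi * (outer**2 - inner**2)
        assert mask.sum() == pytest.approx(expected, rel=0.02)

    def test_center_outside_image_selects_arc(self):
        mask = ring_roi_mask((50, 50), (-10, -10), 30.0, 40.0)
        assert 0 < mask.sum() < 50 * 50

    def test_invalid_radii(self):
        with pytest.raises(ValueError):
            ring_roi_mask((10, 10), (5, 5), 5.0, 5.0)


class TestHistogram:
    def test_uniform_map_single_bin(self):
        eff = np.full((20, 20), 0.5)
        hist = histogram_efficiency(eff, n_bins=50)
        assert np.count_nonzero(hist.counts) == 1
        assert hist.counts.sum() == 400

    def test_counts_conserved_and_partition_additive(self, rng):
        eff = rng.uniform(0.0, 1.0, (60, 60))
        left = np.zeros((60, 60), bool)
        left[:, :30] = True
        whole = histogram_efficiency(eff, n_bins=40)
        h_left = histogram_efficiency(eff, left, n_bins=40)
        h_right = histogram_efficiency(eff, ~left, n_bins=40)
        assert whole.counts.sum() == 3600
        np.testing.assert_array_equal(h_left.counts + h_right.counts, whole.counts)

    def test_empty_selection_rejected(self):
        eff = np.full((10, 10), np.nan)
        with pytest.raises(ValueError):
            histogram_efficiency(eff)


class TestPeaks:
    def test_single_gaussian_recovered(self):
        hist, _ = make_eff_histogram(
            MixtureSpec(means=(0.60,), sds=(0.07,), n_samples=100_000), seed=3
        )
        peaks = detect_peaks(hist)
        assert len(peaks) == 1
        assert peaks[0].mean == pytest.approx(0.60, abs=0.01)

    def test_uniform_histogram_has_no_spurious_narrow_structure(self):
        # a flat density is approximated by broad components only; nothing
        # narrower than a few bin widths should appear, and the mixture's
        # overall dispersion must stay at the uniform value 1/sqrt(12)
        hist = EffHistogram(
            bin_edges=np.linspace(0, 1, 51), counts=np.full(50, 2000.0)
        )
        peaks = detect_peaks(hist)
        # narrow components may appear only at the sharp edges of the
        # uniform support, never in the interior
        assert all(p.sd > 1.5 * 0.02 for p in peaks if 0.1 < p.mean < 0.9)
        mix_mean = sum(p.weight * p.mean for p in peaks)
        mix_var = sum(p.weight * (p.sd**2 + (p.mean - mix_mean) ** 2) for p in peaks)
        assert np.sqrt(mix_var) == pytest.approx(1 / np.sqrt(12), rel=0.05)

    def test_two_component_recovery(self):
        hist, _ = make_eff_histogram(
            MixtureSpec(means=(0.36, 0.62), sds=(0.08, 0.04), n_samples=100_000),
            seed=5,
        )
        peaks = detect_peaks(hist, max_components=4)
        assert len(peaks) == 2
        assert peaks[0].mean == pytest.approx(0.36, abs=0.02)
        assert peaks[1].mean == pytest.approx(0.62, abs=0.02)

    def test_agrees_with_sample_level_em_oracle(self):
        """On a well-separated mixture the binned fit must match an
        independent sample-level EM (scikit-learn) on the raw draws."""
        from sklearn.mixture import GaussianMixture

        hist, samples = make_eff_histogram(
            MixtureSpec(means=(0.3, 0.7), sds=(0.05, 0.04), n_samples=50_000),
            seed=8,
        )
        binned = detect_peaks(hist, max_components=4)
        oracle = GaussianMixture(2, n_init=5, random_state=0).fit(
            samples.reshape(-1, 1)
        )
        oracle_means = np.sort(oracle.means_.ravel())
        assert len(binned) == 2
        for peak, ref in zip(binned, oracle_means):
            assert peak.mean == pytest.approx(ref, abs=0.005)

    def test_invariant_to_count_rescaling(self):
        hist, _ = make_eff_histogram(
            MixtureSpec(means=(0.3, 0.7), sds=(0.05, 0.05), n_samples=50_000), seed=9
        )
        scaled = EffHistogram(bin_edges=hist.bin_edges, counts=hist.counts * 7.0)
        p1 = detect_peaks(hist)
        p2 = detect_peaks(scaled)
        assert [round(p.mean, 6) for p in p1] == [round(p.mean, 6) for p in p2]

    def test_single_occupied_bin_short_circuit(self):
        counts = np.zeros(50)
        counts[25] = 100.0
        hist = EffHistogram(bin_edges=np.linspace(0, 1, 51), counts=counts)
        peaks = detect_peaks(hist)
        assert len(peaks) == 1
        assert peaks[0].mean == pytest.approx(0.51, abs=1e-9)

    def test_too_few_bins_rejected(self):
        hist = EffHistogram(bin_edges=np.linspace(0, 1, 6), counts=np.ones(5))
        with pytest.raises(ValueError):
            detect_peaks(hist, max_components=6)


class TestDispersionScore:
    def test_delta_like_scores_bin_width_floor(self):
        counts = np.zeros(50)
        counts[10] = 500.0
        hist = EffHistogram(bin_edges=np.linspace(0, 1, 51), counts=counts)
        assert broad_vs_narrow_score(hist) == pytest.approx(0.02 / np.sqrt(12), rel=1e-9)

    def test_uniform_scores_one_over_sqrt12(self):
        hist = EffHistogram(bin_edges=np.linspace(0, 1, 51), counts=np.full(50, 10.0))
        assert broad_vs_narrow_score(hist) == pytest.approx(1 / np.sqrt(12), rel=1e-3)

    def test_broad_beats_narrow(self):
        narrow, _ = make_eff_histogram(
            MixtureSpec(means=(0.6,), sds=(0.02,), n_samples=20_000), seed=1
        )
        broad, _ = make_eff_histogram(
            MixtureSpec(means=(0.5,), sds=(0.25,), n_samples=20_000), seed=2
        )
        assert broad_vs_narrow_score(broad) > broad_vs_narrow_score(narrow)
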