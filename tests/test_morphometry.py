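"""Accumulation detection, diameter statistics, swellings, NMJ metrics, scoring."""

import numpy as np
import pytest

from axotrace import morphometry as mm
from axotrace import synthetic_data as sd


def nerve_image(regions=(), canvas=(100.0, 20.0), noise_sd=0.0, seed=0,
                membrane_base=60.0, px_per_um=5.0, cargo_band=(20.0, 20.0)):
    """Two-channel image whose membrane channel outlines a bright nerve band.

    Planted regions should keep ch0 at or mildly above ``membrane_base`` so
    the nerve mask (Otsu + largest component) is the band, not a region.
    ``cargo_band`` gives the cargo channel a left-to-right gradient inside
    the band so the within-nerve MAD is non-zero when needed.
    """
    spec = sd.PlantedImageSpec(canvas=canvas, regions=tuple(regions),
                               noise_sd=noise_sd, seed=seed, px_per_um=px_per_um)
    img, truth = sd.make_planted_image(spec)
    membrane, cargo = img[0].copy(), img[1].copy()
    H, W = membrane.shape
    band = slice(int(0.1 * H), int(0.9 * H))
    membrane[band] = np.maximum(membrane[band], membrane_base)
    gradient = np.linspace(cargo_band[0], cargo_band[1], W)
    cargo[band] = np.maximum(cargo[band], gradient[None, :])
    return mm.TwoChannelImage(membrane, cargo, 1.0 / px_per_um), truth, band


class TestDetectAccumulations:
    def test_no_cobright_regions(self):
        img, _, _ = nerve_image()
        res = mm.detect_accumulations(img)
        assert res.n_accumulations == 0
        assert res.area_fraction == 0.0

    def test_planted_cobright_count_per_1000um2(self):
        regions = [sd.PlantedRegion("disk", (20.0 + 20 * i, 10.0), 2.0, 100.0, 220.0)
                   for i in range(4)]
        img, truth, band = nerve_image(regions)
        res = mm.detect_accumulations(img)
        assert res.n_accumulations == 4
        assert res.count_per_1000um2 == pytest.approx(4 / (res.nerve_area_um2 / 1000.0))
        assert res.area_fraction == pytest.approx(truth.total_area_um2 / res.nerve_area_um2,
                                                  rel=0.05)

    def test_cargo_only_region_not_counted(self):
        # bright in the cargo channel alone: simultaneity required
        regions = [sd.PlantedRegion("disk", (50.0, 10.0), 2.0, 60.0, 220.0)]
        img, _, _ = nerve_image(regions)
        assert mm.detect_accumulations(img).n_accumulations == 0

    def test_threshold_monotonicity(self):
        # cargo intensities straddle the rising threshold; regions are
        # uniform disks, so raising k can only drop whole regions
        regions = [sd.PlantedRegion("disk", (20.0 + 15 * i, 10.0), 1.5, 100.0, 40.0 + 15 * i)
                   for i in range(5)]
        img, _, _ = nerve_image(regions, cargo_band=(15.0, 25.0))
        prev_n, prev_frac = np.inf, np.inf
        for k in (2.0, 4.0, 8.0, 16.0):
            res = mm.detect_accumulations(img, k_mad=k)
            assert res.n_accumulations <= prev_n
            assert res.area_fraction <= prev_frac + 1e-12
            prev_n, prev_frac = res.n_accumulations, res.area_fraction

    def test_scale_invariance_under_upsampling(self):
        regions = [sd.PlantedRegion("rect", (30.0, 10.0), (4.0, 4.0), 100.0, 220.0),
                   sd.PlantedRegion("rect", (70.0, 10.0), (4.0, 4.0), 100.0, 220.0)]
        img, _, _ = nerve_image(regions)
        res1 = mm.detect_accumulations(img)
        up = mm.TwoChannelImage(np.kron(img.membrane, np.ones((2, 2))),
                                np.kron(img.cargo, np.ones((2, 2))),
                                img.um_per_px / 2)
        res2 = mm.detect_accumulations(up)
        assert res2.n_accumulations == res1.n_accumulations
        assert res2.count_per_1000um2 == pytest.approx(res1.count_per_1000um2, rel=1e-6)
        assert res2.area_fraction == pytest.approx(res1.area_fraction, rel=1e-6)

    def test_flat_membrane_rejected(self):
        img = mm.TwoChannelImage(np.full((40, 40), 5.0), np.full((40, 40), 5.0), 0.2)
        with pytest.raises(ValueError):
            mm.detect_accumulations(img)


class TestDiameterStats:
    def test_odd_count_median(self):
        res = mm.diameter_stats([0.2, 0.25, 0.3])
        assert res.median == pytest.approx(0.25)

    def test_constant_list_all_equal(self):
        res = mm.diameter_stats([0.4] * 10)
        assert res.median == res.q1 == res.q3 == res.p1 == res.p99 == pytest.approx(0.4)

    def test_percentiles_monotone(self):
        rng = np.random.default_rng(1)
        res = mm.diameter_stats(rng.lognormal(-1.2, 0.4, size=301))
        assert res.p1 <= res.q1 <= res.median <= res.q3 <= res.p99

    def test_lognormal_median_recovery(self):
        # 301 draws from lognormal(mu, sigma): sample median within the
        # analytic 95% CI of the distribution median exp(mu)
        mu, sigma, n = np.log(0.25), 0.5, 301
        rng = np.random.default_rng(7)
        res = mm.diameter_stats(rng.lognormal(mu, sigma, size=n))
        # CI via order statistics of the median at level 0.95
        half = 1.96 * np.sqrt(0.25 / n)
        lo, hi = (np.exp(mu + sigma * np.sqrt(2) * _probit(q))
                  for q in (0.5 - half, 0.5 + half))
        assert lo <= res.median <= hi

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mm.diameter_stats([])
        with pytest.raises(ValueError):
            mm.diameter_stats([0.2, -0.1])


def _probit(q):
    from scipy.stats import norm
    return norm.ppf(q)


class TestDetectSwellings:
    def test_flat_profile_no_events(self):
        prof = [(0.1 * i, 0.3) for i in range(50)]
        assert mm.detect_swellings(prof) == []

    def test_ten_fold_step_within_micron(self):
        xs = np.arange(0, 10, 0.25)
        d = np.where(xs < 5.0, 0.25, 2.5)
        events = mm.detect_swellings(np.column_stack([xs, d]), fold_threshold=3.0)
        assert len(events) == 1
        assert events[0].max_fold == pytest.approx(10.0)
        assert events[0].start_um < 5.0 <= events[0].end_um

    def test_gradual_rise_not_an_event(self):
        xs = np.arange(0, 10.25, 0.25)
        d = 0.3 * 2 ** (xs / 10.0)   # 2-fold over 10 um
        assert mm.detect_swellings(np.column_stack([xs, d]),
                                   fold_threshold=3.0, within_um=1.0) == []

    def test_overlapping_events_merged(self):
        # a narrow plateau: rising- and falling-edge pairs overlap and merge
        # into a single event; two well-separated bumps stay two events
        xs = np.arange(0, 12, 0.25)
        d = np.full_like(xs, 0.3)
        d[(xs >= 2.0) & (xs <= 3.0)] = 1.5
        d[(xs >= 8.0) & (xs <= 9.0)] = 1.5
        events = mm.detect_swellings(np.column_stack([xs, d]), fold_threshold=3.0)
        assert len(events) == 2
        assert events[0].end_um < events[1].start_um
        assert events[0].start_um < 2.0 <= events[0].end_um

    def test_sparse_sampling_rejected(self):
        with pytest.raises(ValueError):
            mm.detect_swellings([(0.0, 0.3), (1.0, 0.3), (2.0, 0.3)])


class TestNMJMetrics:
    def _nmj(self, puncta_centers, punctum_area_um2=2.0, px_per_um=5.0):
        r = float(np.sqrt(punctum_area_um2 / np.pi))
        regions = [sd.PlantedRegion("disk", c, r, 10.0, 200.0) for c in puncta_centers]
        spec = sd.PlantedImageSpec(canvas=(20.0, 20.0), regions=tuple(regions),
                                   background=10.0, px_per_um=px_per_um)
        img, truth = sd.make_planted_image(spec)
        membrane = img[0].copy()
        H, W = membrane.shape
        yy, xx = np.mgrid[0:H, 0:W]
        # circular NMJ mask of ~100 um^2 (radius 5.64 um)
        r_px = np.sqrt(100.0 / np.pi) * px_per_um
        nmj = (xx - W / 2) ** 2 + (yy - H / 2) ** 2 <= r_px**2
        membrane[nmj] = 120.0
        return mm.TwoChannelImage(membrane, img[1], 1.0 / px_per_um), truth

    def test_no_puncta(self):
        img, _ = self._nmj([])
        res = mm.nmj_metrics(img)
        assert res.mito_number == 0
        assert res.mito_density == 0.0

    def test_planted_puncta_number_size_density(self):
        centers = [(7.0, 7.0), (13.0, 7.0), (7.0, 13.0), (13.0, 13.0), (10.0, 10.0)]
        img, truth = self._nmj(centers)
        res = mm.nmj_metrics(img)
        assert res.mito_number == 5
        assert res.nmj_area == pytest.approx(100.0, rel=0.05)
        assert res.mito_mean_size == pytest.approx(2.0, rel=0.15)
        assert res.mito_density == pytest.approx(5 * 2.0 / 100.0, rel=0.2)

    def test_determinism(self):
        img, _ = self._nmj([(8.0, 8.0), (12.0, 12.0)])
        r1, r2 = mm.nmj_metrics(img), mm.nmj_metrics(img)
        assert (r1.mito_number, r1.mito_mean_size, r1.mito_density) == \
               (r2.mito_number, r2.mito_mean_size, r2.mito_density)


class TestDegenerationScore:
    def test_all_flags_false_zero(self):
        assert mm.degeneration_score(
            {"retraction": False, "dystrophic": False, "minor": False}).total == 0

    def test_minor_alteration_only(self):
        assert mm.degeneration_score({"minor": True}).total == 1

    def test_weighted_sum(self):
        score = mm.degeneration_score(
            {"retraction": 1, "dystrophic": 2, "minor": 1},
            weights={"retraction": 2, "dystrophic": 1, "minor": 1},
        )
        assert score.total == 2 + 2 + 1

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            mm.degeneration_score({"minor": 1}, weights={"minor": -1})

    def test_retraction_requires_simultaneous_absence(self):
        assert mm.retraction_flag(True, True, True)
        assert not mm.retraction_flag(True, False, True)   # membrane still present
        assert not mm.retraction_flag(False, True, True)   # SV marker still present
        assert not mm.retraction_flag(True, True, False)   # postsynaptic gone too
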