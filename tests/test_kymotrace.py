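"""Kymograph construction, trace extraction, classification, velocity, flux."""

import numpy as np
import pytest

from axotrace import kymotrace as kt
from axotrace import synthetic_data as sd
from conftest import kymograph_of, make_mover, make_stationary

PROTO = kt.TransportProtocol.fly()


class TestBuildKymograph:
    def test_stationary_spot_gives_vertical_ridge(self, quiet_spec):
        truth = sd.ParticleTruth([make_stationary(0, 10.0, quiet_spec)], quiet_spec)
        kym = kymograph_of(truth)
        ridge = kym.data.argmax(axis=0)
        assert np.all(ridge == ridge[0])
        assert ridge[0] * kym.pos_step_um == pytest.approx(10.0, abs=kym.pos_step_um)

    def test_moving_ridge_slope_matches_speed(self, quiet_spec):
        v = 0.5
        truth = sd.ParticleTruth([make_mover(0, sd.ANTERO, v, 0.0, quiet_spec)], quiet_spec)
        kym = kymograph_of(truth)
        cols = range(1, 9)   # the particle traverses 20 um in ~9.4 frames
        pos = np.array([kym.data[:, j].argmax() for j in cols]) * kym.pos_step_um
        slopes = np.diff(pos) / kym.time_step_s
        assert abs(np.mean(slopes) - v) <= 0.5 * kym.pos_step_um / kym.time_step_s

    def test_bleach_mask_covers_window_from_bleach_frame(self):
        spec = sd.TransportSimSpec(seed=0, antero_rate=0, retro_rate=0, n_stationary=0,
                                   noise_sd=1.0, bleach_time=10 * 4.26)
        truth = sd.ParticleTruth(
            [make_stationary(i, x, spec) for i, x in enumerate((1.0, 5.0, 9.0, 13.0, 17.0, 19.0))],
            spec,
        )
        kym = kymograph_of(truth, detect_bleach=True)
        assert kym.bleach_mask is not None
        frames = np.nonzero(kym.bleach_mask.any(axis=0))[0]
        assert frames[0] == 10 and frames[-1] == kym.data.shape[1] - 1
        rows = np.nonzero(kym.bleach_mask.any(axis=1))[0] * kym.pos_step_um
        assert rows[0] <= 2.0 and rows[-1] >= 18.0

    def test_no_bleach_event_gives_no_mask(self, quiet_spec):
        truth = sd.ParticleTruth([make_stationary(0, 10.0, quiet_spec)], quiet_spec)
        kym = kymograph_of(truth, detect_bleach=True)
        assert kym.bleach_mask is None

    def test_path_outside_image_rejected(self, quiet_spec):
        truth = sd.ParticleTruth([make_stationary(0, 10.0, quiet_spec)], quiet_spec)
        stack = sd.render_nerve_stack(truth)
        bad = kt.NervePath.straight(500.0, 0, stack.shape[2] - 1, 0.2)
        with pytest.raises(ValueError, match="exits"):
            kt.build_kymograph(stack, bad)

    def test_fewer_than_two_frames_rejected(self, quiet_spec):
        truth = sd.ParticleTruth([make_stationary(0, 10.0, quiet_spec)], quiet_spec)
        stack = sd.render_nerve_stack(truth)[:1]
        path = kt.NervePath.straight((stack.shape[1] - 1) / 2, 0, stack.shape[2] - 1, 0.2)
        with pytest.raises(ValueError, match="2 frames"):
            kt.build_kymograph(stack, path)


class TestExtractTraces:
    def test_empty_kymograph_gives_no_traces(self):
        kym = kt.Kymograph(np.full((101, 50), 10.0), 0.2, 4.26)
        assert kt.extract_traces(kym) == []

    def test_three_noncrossing_particles_recovered(self, quiet_spec):
        truth = sd.ParticleTruth(
            [
                make_mover(0, sd.ANTERO, 0.5, 0.0, quiet_spec),
                make_mover(1, sd.ANTERO, 0.4, 150.0, quiet_spec),
                make_mover(2, sd.RETRO, 0.45, 300.0, quiet_spec),
            ],
            quiet_spec,
        )
        kym = kymograph_of(truth)
        traces = kt.extract_traces(kym)
        assert len(traces) == 3
        # positions match truth within half a position step
        for tr in sorted(traces, key=lambda t: t.t[0]):
            p = min(truth.particles, key=lambda p: abs(p.t[0] - tr.t[0]))
            for t, x in zip(tr.t, tr.x):
                x_true = np.interp(t, p.t, p.x)
                assert abs(x - x_true) <= 0.5 * kym.pos_step_um + 1e-6

    def test_crossing_traces_keep_identity(self, quiet_spec):
        # one antero and one retro crossing once mid-segment
        truth = sd.ParticleTruth(
            [
                make_mover(0, sd.ANTERO, 0.5, 0.0, quiet_spec),
                make_mover(1, sd.RETRO, 0.5, 0.0, quiet_spec),
            ],
            quiet_spec,
        )
        kym = kymograph_of(truth)
        traces = kt.extract_traces(kym)
        classes = sorted(kt.classify_trace(t, PROTO) for t in traces)
        assert classes == ["antero", "retro"]


class TestClassifyAndVelocity:
    @pytest.mark.parametrize("net, expected", [
        (4.0, "stationary"),   # less than 5 um moved => stationary
        (6.0, "antero"),
        (-6.0, "retro"),
        (5.0, "antero"),       # exactly 5 um counts as moving (strict <)
        (-5.0, "retro"),
    ])
    def test_net_displacement_rule(self, net, expected):
        tr = kt.ParticleTrace(0, [0.0, 10.0, 20.0], [8.0, 8.0 + net / 2, 8.0 + net])
        assert kt.classify_trace(tr, PROTO) == expected

    def test_constant_slope_velocity(self):
        t = np.arange(10) * 4.26
        tr = kt.ParticleTrace(0, t, 0.5 * t)
        assert kt.trace_velocity(tr) == pytest.approx(0.5)

    def test_pause_excluded_velocity(self):
        t = np.arange(20) * 1.0
        x = np.concatenate([np.arange(10) * 1.0, np.full(10, 9.0)])  # move then pause
        tr = kt.ParticleTrace(0, t, x, pos_step_um=0.2)
        assert kt.trace_velocity(tr) == pytest.approx(1.0)
        assert kt.trace_net_velocity(tr) == pytest.approx(9.0 / 19.0)

    def test_stationary_trace_rejected(self):
        tr = kt.ParticleTrace(0, [0.0, 4.26, 8.52], [5.0, 5.0, 5.0], pos_step_um=0.2)
        with pytest.raises(ValueError, match="no moving steps"):
            kt.trace_velocity(tr)


class TestComputeFlux:
    def test_no_traces_zero_flux(self):
        res = kt.compute_flux([], PROTO)
        assert res.antero_flux == 0.0 and res.retro_flux == 0.0
        assert np.isnan(res.ratio_retro_antero)

    def test_two_section_average(self):
        # one antero trace crossing both sections once in 30 min
        proto = kt.TransportProtocol.mouse()
        t = np.arange(0, 1800, 60.0)
        tr = kt.ParticleTrace(0, t, np.linspace(0, 20, len(t)), klass=sd.ANTERO)
        res = kt.compute_flux([tr], proto)
        assert res.antero_flux == pytest.approx((1 + 1) / 2 / 30.0)

    def test_midpoint_crossings_fly_window(self):
        # 3 antero crossings of the midpoint in 426 s -> 3 / 7.1 min
        traces = [
            kt.ParticleTrace(i, [0.0, 213.0, 426.0], [0.0, 10.0 + 1e-9, 20.0], klass=sd.ANTERO)
            for i in range(3)
        ]
        res = kt.compute_flux(traces, PROTO)
        assert res.antero_flux == pytest.approx(3 / 7.1)
        assert res.retro_flux == 0.0

    def test_flux_scales_inversely_with_window(self):
        tr = kt.ParticleTrace(0, [0.0, 100.0], [0.0, 20.0], klass=sd.ANTERO)
        f1 = kt.compute_flux([tr], kt.TransportProtocol(window_s=426.0))
        f2 = kt.compute_flux([tr], kt.TransportProtocol(window_s=852.0))
        assert f1.antero_flux == pytest.approx(2 * f2.antero_flux)

    def test_oracle_equivalence_noise_free(self, quiet_spec):
        """Flux and classification from extracted traces equal truth exactly."""
        truth = sd.ParticleTruth(
            [
                make_mover(0, sd.ANTERO, 0.5, 0.0, quiet_spec),
                make_mover(1, sd.ANTERO, 0.4, 150.0, quiet_spec),
                make_mover(2, sd.RETRO, 0.45, 300.0, quiet_spec),
            ],
            quiet_spec,
        )
        kym = kymograph_of(truth)
        extracted = kt.extract_traces(kym)
        truth_traces = kt.traces_from_truth(truth)
        f_ext = kt.compute_flux(extracted, PROTO)
        f_tru = kt.compute_flux(truth_traces, PROTO)
        assert f_ext.section_counts == f_tru.section_counts
        assert f_ext.antero_flux == f_tru.antero_flux
        assert f_ext.retro_flux == f_tru.retro_flux
        assert (sorted(kt.classify_trace(t, PROTO) for t in extracted)
                == sorted(kt.classify_trace(t, PROTO) for t in truth_traces))


class TestCompareBleach:
    def test_identical_inputs_zero_differences(self):
        f = kt.FluxResult(1.0, 0.5, 426.0, "fly")
        c = kt.compare_bleach(f, f)
        assert c.antero_diff == 0.0 and c.retro_diff == 0.0
        assert c.ratio_diff == 0.0

    def test_mismatched_protocols_rejected(self):
        a = kt.FluxResult(1.0, 0.5, 426.0, "fly")
        b = kt.FluxResult(1.0, 0.5, 1800.0, "mouse")
        with pytest.raises(ValueError):
            kt.compare_bleach(a, b)


class TestProtocol:
    def test_mouse_protocol_sections_inside_segment(self):
        p = kt.TransportProtocol.mouse()
        assert len(p.sections) == 2
        assert all(0 < s < p.segment_length for s in p.sections)
        assert p.window_s == 1800.0

    def test_sections_outside_segment_rejected(self):
        with pytest.raises(ValueError):
            kt.TransportProtocol(cross_sections=(25.0,))
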