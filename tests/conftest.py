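import numpy as np
import pytest

from axotrace import kymotrace as kt
from axotrace import synthetic_data as sd


def make_mover(pid, klass, speed, t_start, spec, entry=None):
    """Construct a constant-speed particle sampled at the spec's frame times."""
    sign = +1.0 if klass == sd.ANTERO else -1.0
    if entry is None:
        entry = 0.0 if klass == sd.ANTERO else spec.segment_length
    ts, xs = [], []
    for t in spec.frame_times:
        if t < t_start:
            continue
        x = entry + sign * speed * (t - t_start)
        if 0.0 <= x <= spec.segment_length:
            ts.append(t)
            xs.append(x)
    return sd.Particle(pid, klass, np.asarray(ts), np.asarray(xs), float(t_start), speed)


def make_stationary(pid, x0, spec):
    t = spec.frame_times
    return sd.Particle(pid, sd.STATIONARY, t.copy(), np.full_like(t, x0), None, 0.0)


def center_path(stack, px_per_um):
    return kt.NervePath.straight(
        (stack.shape[1] - 1) / 2, 0, stack.shape[2] - 1, 1.0 / px_per_um
    )


def kymograph_of(truth, detect_bleach=False, **render_kw):
    stack = sd.render_nerve_stack(truth, **render_kw)
    path = center_path(stack, truth.spec.px_per_um)
    return kt.build_kymograph(
        stack, path, time_step_s=truth.spec.frame_interval, detect_bleach=detect_bleach
    )


@pytest.fixture
def quiet_spec():
    """Transport spec with no random movers (construct particles by hand)."""
    return sd.TransportSimSpec(seed=0, antero_rate=0.0, retro_rate=0.0,
                               n_stationary=0, noise_sd=0.0)
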