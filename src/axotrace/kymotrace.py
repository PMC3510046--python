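"""Kymograph construction and axonal-transport quantification.

A kymograph resamples a time-lapse stack along a 1-D nerve path: each
column is one frame, each row one position along the path, so stationary
organelles appear as vertical lines and movers as oblique lines. From the
kymograph this module extracts particle traces, classifies them by the
5 µm net-displacement rule (net |Δx| < 5 µm within the 20 µm segment =
stationary), estimates pause-excluded velocities, and counts directional
flux at one or two cross-sections:

* fly protocol — one cross-section at the segment midpoint, 426 s window;
* mouse-culture protocol — two cross-sections, 30 min window, flux per
  direction is the average of the two sections' counts.

`traces_from_truth` converts ground-truth trajectories into the same
trace representation, so flux and classification can be computed along
two independent routes (pixels vs truth) and compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .synthetic_data import ANTERO, RETRO, STATIONARY, ParticleTruth

__all__ = [
    "NervePath",
    "Kymograph",
    "ParticleTrace",
    "TransportProtocol",
    "FluxResult",
    "BleachComparison",
    "build_kymograph",
    "extract_traces",
    "classify_trace",
    "trace_velocity",
    "trace_net_velocity",
    "compute_flux",
    "compare_bleach",
    "traces_from_truth",
]


@dataclass(frozen=True)
class NervePath:
    """Polyline along the nerve in pixel coordinates, cell-body end first."""

    points: np.ndarray          # (N, 2) array of (x, y) px
    um_per_px: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("path needs at least two (x, y) points")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")

    @classmethod
    def straight(cls, y_px: float, x0_px: float, x1_px: float, um_per_px: float) -> "NervePath":
        return cls(np.array([[x0_px, y_px], [x1_px, y_px]]), um_per_px)

    def sample(self, step_px: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Equally spaced sample points and unit normals along the polyline."""
        seg = np.diff(self.points, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = cum[-1]
        s = np.arange(0.0, total + step_px / 2, step_px)
        xs = np.interp(s, cum, self.points[:, 0])
        ys = np.interp(s, cum, self.points[:, 1])
        # tangents by finite differences, then left-hand normals
        tx = np.gradient(xs)
        ty = np.gradient(ys)
        norm = np.hypot(tx, ty)
        norm[norm == 0] = 1.0
        normals = np.column_stack([-ty / norm, tx / norm])
        return np.column_stack([xs, ys]), normals

    @property
    def length_um(self) -> float:
        seg = np.diff(self.points, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum() * self.um_per_px)


@dataclass
class Kymograph:
    """Position (rows) x time (columns) intensity matrix with calibration."""

    data: np.ndarray            # (n_positions, n_frames)
    pos_step_um: float
    time_step_s: float
    bleach_mask: np.ndarray | None = None   # bool, same shape

    @property
    def positions_um(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.pos_step_um

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) * self.time_step_s


@dataclass
class ParticleTrace:
    """One tracked particle: ordered (t, x) samples plus optional class."""

    trace_id: int
    t: np.ndarray               # s, strictly increasing
    x: np.ndarray               # µm along the path (cell body -> terminal)
    klass: str | None = None
    pos_step_um: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if len(self.t) != len(self.x) or len(self.t) < 1:
            raise ValueError("trace needs matching, non-empty t and x")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trace samples must be strictly increasing in t")

    @property
    def net_displacement(self) -> float:
        return float(self.x[-1] - self.x[0])


@dataclass(frozen=True)
class TransportProtocol:
    """Analysis segment, stationarity rule, cross-sections and window."""

    segment_length: float = 20.0
    stationary_threshold: float = 5.0
    cross_sections: tuple[float, ...] | None = None   # None -> segment midpoint
    window_s: float = 426.0
    name: str = "fly"

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        for s in self.sections:
            if not (0 < s < self.segment_length):
                raise ValueError("cross_sections must lie inside the segment")

    @property
    def sections(self) -> tuple[float, ...]:
        if self.cross_sections is None:
            return (self.segment_length / 2.0,)
        return tuple(self.cross_sections)

    @classmethod
    def fly(cls, segment_length: float = 20.0, window_s: float = 426.0) -> "TransportProtocol":
        """Single midpoint cross-section, bleached-segment window."""
        return cls(segment_length, 5.0, None, window_s, "fly")

    @classmethod
    def mouse(cls, segment_length: float = 20.0, window_s: float = 1800.0) -> "TransportProtocol":
        """Two cross-sections at 1/4 and 3/4 of the segment; flux is their average."""
        s = segment_length
        return cls(s, 5.0, (0.25 * s, 0.75 * s), window_s, "mouse")


@dataclass
class FluxResult:
    """Directional flux (min⁻¹) plus the retro/antero ratio."""

    antero_flux: float
    retro_flux: float
    window_s: float
    protocol: str
    n_stationary: int = 0
    section_counts: dict = field(default_factory=dict)

    @property
    def ratio_retro_antero(self) -> float:
        return self.retro_flux / self.antero_flux if self.antero_flux > 0 else float("nan")


@dataclass
class BleachComparison:
    antero_diff: float          # bleached - native, min⁻¹
    retro_diff: float
    ratio_bleached: float
    ratio_native: float

    @property
    def ratio_diff(self) -> float:
        return self.ratio_bleached - self.ratio_native


# ---------------------------------------------------------------------------
# kymograph construction
# ---------------------------------------------------------------------------

def build_kymograph(
    stack: np.ndarray,
    path: NervePath,
    width_px: int = 3,
    time_step_s: float = 4.26,
    detect_bleach: bool = True,
) -> Kymograph:
    """Resample a stack along a nerve path into a position x time matrix.

    For every frame, intensity at each path position is the maximum across
    the path's normal within ``width_px``. 4-D (t, z, y, x) stacks are
    maximum-projected over z first. A bleach event is auto-detected as a
    contiguous position range whose mean background-subtracted intensity
    drops by more than 50% between two consecutive frames; the mask covers
    that range from the drop frame to the end.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 4:
        stack = stack.max(axis=1)
    if stack.ndim != 3:
        raise ValueError("stack must be (t, y, x) or (t, z, y, x)")
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 frames")

    pts, normals = path.sample(step_px=1.0)
    H, W = stack.shape[1:]
    if (pts[:, 0].min() < -0.5 or pts[:, 0].max() > W - 0.5
            or pts[:, 1].min() < -0.5 or pts[:, 1].max() > H - 0.5):
        raise ValueError("path exits the image bounds")

    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    # coords: (2, n_positions, n_offsets) in (row, col) order
    rows = pts[:, 1][:, None] + normals[:, 1][:, None] * offsets[None, :]
    cols = pts[:, 0][:, None] + normals[:, 0][:, None] * offsets[None, :]
    coords = np.stack([rows, cols])

    kym = np.empty((len(pts), stack.shape[0]))
    for j in range(stack.shape[0]):
        samp = ndimage.map_coordinates(stack[j], coords.reshape(2, -1), order=1, mode="nearest")
        kym[:, j] = samp.reshape(len(pts), width_px).max(axis=1)

    k = Kymograph(kym, pos_step_um=path.um_per_px, time_step_s=time_step_s)
    if detect_bleach:
        k.bleach_mask = _detect_bleach_mask(k)
    return k


def _detect_bleach_mask(kym: Kymograph, min_run_um: float = 2.0) -> np.ndarray | None:
    """Locate a >50% drop of smoothed intensity over a contiguous position run."""
    data = kym.data
    bg = float(np.median(data))
    sub = np.clip(data - bg, 0.0, None)
    mad = float(np.median(np.abs(data - bg)))
    floor = max(3 * 1.4826 * mad, 1e-6)
    smooth_px = max(3, int(round(4.0 / kym.pos_step_um)))
    smoothed = ndimage.uniform_filter1d(sub, smooth_px, axis=0)
    min_run = max(2, int(round(min_run_um / kym.pos_step_um)))

    for j in range(data.shape[1] - 1):
        bright = smoothed[:, j] > floor
        # contiguous runs of bright positions that lose >50% intensity;
        # all runs dropping at the same frame belong to one bleach event
        lab, n = ndimage.label(bright)
        dropped = []
        for r in range(1, n + 1):
            run = lab == r
            if run.sum() < min_run:
                continue
            before = smoothed[run, j].mean()
            after = smoothed[run, j + 1].mean()
            if before > floor and after < 0.5 * before:
                dropped.append(np.nonzero(run)[0])
        if dropped:
            lo = min(int(d[0]) for d in dropped)
            hi = max(int(d[-1]) for d in dropped)
            mask = np.zeros_like(data, dtype=bool)
            mask[lo:hi + 1, j + 1:] = True
            return mask
    return None


# ---------------------------------------------------------------------------
# trace extraction
# ---------------------------------------------------------------------------

def _detect_column(col: np.ndarray, thresh: float, min_sep_px: int) -> np.ndarray:
    """Sub-pixel peak positions (in row units) above threshold in one column."""
    peaks, _ = signal.find_peaks(col, height=thresh, distance=min_sep_px)
    if len(peaks) == 0:
        return np.empty(0)
    refined = peaks.astype(float)
    for i, p in enumerate(peaks):
        if 0 < p < len(col) - 1:
            denom = col[p - 1] - 2 * col[p] + col[p + 1]
            if denom < 0:
                refined[i] = p + 0.5 * (col[p - 1] - col[p + 1]) / denom
    return refined


def extract_traces(
    kym: Kymograph,
    k_mad: float = 3.0,
    v_max_um_s: float = 1.5,
    min_samples: int = 4,
    min_separation_um: float = 0.6,
) -> list[ParticleTrace]:
    """Detect and link particle positions across kymograph columns.

    Per time column, local maxima above (background median + k·MAD) are
    detections; detections are linked column-to-column to the nearest
    predicted position within ``v_max_um_s * Δt``, preferring the
    straightest continuation (the prediction extrapolates each trace's
    last local slope, so at crossings the candidate that least changes a
    trace's slope wins). Traces with fewer than ``min_samples`` columns
    are dropped.
    """
    data = kym.data
    bg = float(np.median(data))
    mad = float(np.median(np.abs(data - bg)))
    thresh = bg + k_mad * 1.4826 * mad + 1e-9
    min_sep_px = max(1, int(round(min_separation_um / kym.pos_step_um)))
    dt0 = kym.time_step_s
    max_gap_s = 2 * dt0 + 1e-9

    max_pos_um = (data.shape[0] - 1) * kym.pos_step_um
    active: list[dict] = []
    done: list[dict] = []
    for j in range(data.shape[1]):
        t = j * kym.time_step_s
        det_um = _detect_column(data[:, j], thresh, min_sep_px) * kym.pos_step_um
        # predicted next position for each active trace; a prediction beyond
        # the kymograph extent means the particle has exited - close the
        # trace rather than let it capture a different particle entering
        # at the same end
        preds = []
        gates = []
        still = []
        for tr in active:
            if len(tr["x"]) >= 2:
                # slope over the last few samples is robust to a single
                # displaced sample from a merge with a crossing trace
                k = min(3, len(tr["x"]) - 1)
                slope = (tr["x"][-1] - tr["x"][-1 - k]) / (tr["t"][-1] - tr["t"][-1 - k])
            else:
                slope = 0.0
            gap = t - tr["t"][-1]
            pred = tr["x"][-1] + slope * gap
            if pred < 0.0 or pred > max_pos_um:
                done.append(tr)
                continue
            # a fresh trace's speed is unknown (gate = v_max); once the
            # slope is established the prediction is good and a tight gate
            # prevents identity theft at trace crossings
            if len(tr["x"]) >= 3:
                gate = 0.5 * v_max_um_s * gap + 2 * kym.pos_step_um
            else:
                gate = v_max_um_s * gap + kym.pos_step_um
            still.append(tr)
            preds.append(pred)
            gates.append(gate)
        active = still
        # greedy assignment over globally sorted prediction errors
        pairs = sorted(
            ((abs(det_um[d] - preds[a]), a, d)
             for a in range(len(active)) for d in range(len(det_um))),
            key=lambda p: p[0],
        )
        used_a: set[int] = set()
        used_d: set[int] = set()
        for dist, a, d in pairs:
            if dist > gates[a] or a in used_a or d in used_d:
                continue
            active[a]["t"].append(t)
            active[a]["x"].append(det_um[d])
            used_a.add(a)
            used_d.add(d)
        # a trace whose peak was absorbed by a close neighbour may share
        # the merged detection: two particles within the resolution limit
        # produce one peak, and dropping one trace would lose a particle
        share_gate = 2 * kym.pos_step_um
        for a, tr in enumerate(active):
            if a in used_a or len(tr["x"]) < 3 or len(det_um) == 0:
                continue
            err = np.abs(det_um - preds[a])
            d = int(np.argmin(err))
            if d in used_d and err[d] <= share_gate:
                tr["t"].append(t)
                tr["x"].append(det_um[d])
                used_a.add(a)
        # close traces unmatched beyond the gap tolerance, start new ones
        still = []
        for a, tr in enumerate(active):
            if a in used_a or t - tr["t"][-1] < max_gap_s:
                still.append(tr)
            else:
                done.append(tr)
        active = still
        for d in range(len(det_um)):
            if d not in used_d:
                active.append({"t": [t], "x": [det_um[d]]})
    done.extend(active)
    done = _stitch_fragments(done, v_max_um_s, dt0, kym.pos_step_um, max_pos_um)
    done = _split_reversals(done)

    traces = [
        ParticleTrace(i, np.asarray(tr["t"]), np.asarray(tr["x"]), pos_step_um=kym.pos_step_um)
        for i, tr in enumerate(tr for tr in done if len(tr["t"]) >= min_samples)
    ]
    return traces


def _split_reversals(
    fragments: list[dict],
    min_leg_um: float = 3.0,
    min_leg_samples: int = 3,
) -> list[dict]:
    """Split traces at a sustained direction reversal.

    A trace whose position extremum lies in its interior with both legs
    longer than ``min_leg_um`` is split there: either the particle truly
    reversed (then each run should be counted in its own direction) or
    two crossing particles were chained into one V/Λ-shaped trace and the
    split restores them. Applied recursively to each half.
    """
    out = []
    stack_ = list(fragments)
    while stack_:
        tr = stack_.pop()
        x = np.asarray(tr["x"])
        if len(x) < 2 * min_leg_samples:
            out.append(tr)
            continue
        split_at = None
        for extremum in (int(np.argmax(x)), int(np.argmin(x))):
            if (min_leg_samples - 1 <= extremum <= len(x) - min_leg_samples
                    and abs(x[extremum] - x[0]) >= min_leg_um
                    and abs(x[extremum] - x[-1]) >= min_leg_um):
                split_at = extremum
                break
        if split_at is None:
            out.append(tr)
        else:
            stack_.append({"t": list(tr["t"][: split_at + 1]), "x": list(tr["x"][: split_at + 1])})
            stack_.append({"t": list(tr["t"][split_at + 1:]), "x": list(tr["x"][split_at + 1:])})
    return out


def _stitch_fragments(
    fragments: list[dict],
    v_max_um_s: float,
    dt: float,
    pos_step_um: float,
    max_pos_um: float,
    max_gap_frames: int = 3,
) -> list[dict]:
    """Rejoin collinear trace fragments separated by short gaps.

    A crossing or a missed detection can split one particle's trace in
    two; fragment B continues fragment A when B starts within
    ``max_gap_frames`` after A ends, A's extrapolation stays inside the
    kymograph (the particle has not exited) and lands on B's first sample
    with a slope consistent between the two fragments.
    """
    def slope_of(tr, head: bool) -> float:
        t, x = tr["t"], tr["x"]
        if len(t) < 2:
            return 0.0
        k = min(3, len(t) - 1)
        return (x[k] - x[0]) / (t[k] - t[0]) if head else (x[-1] - x[-1 - k]) / (t[-1] - t[-1 - k])

    frags = sorted(fragments, key=lambda tr: (tr["t"][0], tr["x"][0]))
    candidates = []
    for i, a in enumerate(frags):
        sa = slope_of(a, head=False)
        for j, b in enumerate(frags):
            gap = b["t"][0] - a["t"][-1]
            if i == j or gap <= 0 or gap > max_gap_frames * dt + 1e-9:
                continue
            pred = a["x"][-1] + sa * gap
            if pred < 0.0 or pred > max_pos_um:
                continue
            sb = slope_of(b, head=True)
            if len(a["t"]) >= 2 and len(b["t"]) >= 2 and abs(sa - sb) > 0.4 * v_max_um_s:
                continue
            err = abs(pred - b["x"][0])
            if err <= 0.25 * v_max_um_s * gap + 2 * pos_step_um:
                candidates.append((err, i, j))
    candidates.sort(key=lambda c: c[0])
    next_of = {}
    has_prev = set()
    for err, i, j in candidates:
        if i in next_of or j in has_prev:
            continue
        next_of[i] = j
        has_prev.add(j)
    merged = []
    for i, tr in enumerate(frags):
        if i in has_prev:
            continue
        chain = dict(tr)
        chain = {"t": list(tr["t"]), "x": list(tr["x"])}
        k = i
        while k in next_of:
            k = next_of[k]
            chain["t"].extend(frags[k]["t"])
            chain["x"].extend(frags[k]["x"])
        merged.append(chain)
    return merged


# ---------------------------------------------------------------------------
# per-trace measures
# ---------------------------------------------------------------------------

def classify_trace(trace: ParticleTrace, protocol: TransportProtocol) -> str:
    """Stationary if |net displacement| < threshold (5 µm), else by sign.

    Exactly 5 µm counts as moving (the stationarity rule is a strict
    "less than").
    """
    if len(trace.t) < 2:
        raise ValueError("trace needs at least two samples")
    net = trace.net_displacement
    if abs(net) < protocol.stationary_threshold:
        return STATIONARY
    return ANTERO if net > 0 else RETRO


def trace_velocity(trace: ParticleTrace, moving_step_um: float | None = None) -> float:
    """Pause-excluded mean speed: mean |Δx|/Δt over moving steps only.

    A step counts as moving when |Δx| exceeds half the kymograph position
    step (or ``moving_step_um`` when given); pure pauses contribute
    nothing. Raises on a trace with no moving steps.
    """
    if moving_step_um is None:
        moving_step_um = max(0.5 * trace.pos_step_um, 1e-9)
    dx = np.diff(trace.x)
    dt = np.diff(trace.t)
    moving = np.abs(dx) > moving_step_um
    if not np.any(moving):
        raise ValueError("trace has no moving steps (stationary trace?)")
    return float(np.mean(np.abs(dx[moving]) / dt[moving]))


def trace_net_velocity(trace: ParticleTrace) -> float:
    """Net speed: |total displacement| / total duration (pauses included)."""
    span = trace.t[-1] - trace.t[0]
    if span <= 0:
        raise ValueError("trace spans no time")
    return abs(trace.net_displacement) / span


# ---------------------------------------------------------------------------
# flux
# ---------------------------------------------------------------------------

def _count_crossings(x: np.ndarray, section: float) -> int:
    """Passages of x across the section between consecutive samples.

    A passage is counted once per frame pair by the net step direction,
    so back-and-forth jitter within one pair counts once.
    """
    a, b = x[:-1], x[1:]
    return int(np.sum(((a < section) & (b >= section)) | ((a >= section) & (b < section))))


def compute_flux(traces: list[ParticleTrace], protocol: TransportProtocol) -> FluxResult:
    """Directional flux from classified traces at the protocol's sections.

    Every section crossing of a moving trace is attributed to the trace's
    overall direction. With one section, flux = crossings / window; with
    two (mouse protocol), flux per direction is the mean of the two
    sections' counts divided by the window. Units: min⁻¹.
    """
    sections = protocol.sections
    counts = {ANTERO: np.zeros(len(sections)), RETRO: np.zeros(len(sections))}
    n_stationary = 0
    for tr in traces:
        klass = tr.klass if tr.klass is not None else classify_trace(tr, protocol)
        if klass == STATIONARY:
            n_stationary += 1
            continue
        for i, s in enumerate(sections):
            counts[klass][i] += _count_crossings(tr.x, s)
    window_min = protocol.window_s / 60.0
    return FluxResult(
        antero_flux=float(counts[ANTERO].mean() / window_min),
        retro_flux=float(counts[RETRO].mean() / window_min),
        window_s=protocol.window_s,
        protocol=protocol.name,
        n_stationary=n_stationary,
        section_counts={k: v.tolist() for k, v in counts.items()},
    )


def compare_bleach(bleached: FluxResult, native: FluxResult) -> BleachComparison:
    """Per-direction flux differences and retro/antero ratios across conditions."""
    if bleached.protocol != native.protocol or bleached.window_s != native.window_s:
        raise ValueError("bleached and native results use different protocols")
    return BleachComparison(
        antero_diff=bleached.antero_flux - native.antero_flux,
        retro_diff=bleached.retro_flux - native.retro_flux,
        ratio_bleached=bleached.ratio_retro_antero,
        ratio_native=native.ratio_retro_antero,
    )


def traces_from_truth(truth: ParticleTruth) -> list[ParticleTrace]:
    """Ground-truth trajectories as traces (the truth route for comparisons)."""
    return [
        ParticleTrace(p.particle_id, p.t, p.x, klass=None, pos_step_um=0.0)
        for p in truth.particles
        if len(p.t) >= 2
    ]
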