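"""Seeded synthetic data with ground truth for every analysis stage.

Three generators emulate the three kinds of raw data the quantification
pipeline consumes:

* `simulate_transport` / `render_nerve_stack` — bidirectional punctate
  organelle traffic in a ~20 µm nerve segment imaged at ~4.26 s/frame,
  optionally with a photobleaching event that darkens every fluorophore
  present in the bleach window at bleach time (newly entering organelles
  stay bright, which is what makes bleaching useful for visualising flux).
* `simulate_arena` — multi-larva crawling movies: smooth random-heading
  walks of elongated bright blobs on a dark agar plate, with optional
  forced larva-larva contact intervals.
* `make_planted_image` — two-channel images with planted regions of known
  mask, area and per-channel intensity, the oracle for accumulation / NMJ
  morphometry.

Every generator is a pure function of its spec (including the seed):
identical spec gives bit-identical truth and pixels.

Moving organelles are inserted at the segment entry ends as a Poisson
process at the stated per-direction rate. Insertion runs from a burn-in
interval before t=0 (1.5x the pause-corrected traversal time) so that the
segment is statistically stationary when recording starts; insertion
counts reported by the truth refer to insertion times inside the recorded
window only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransportSimSpec",
    "Particle",
    "ParticleTruth",
    "ArenaSpec",
    "ArenaTruth",
    "PlantedRegion",
    "PlantedImageSpec",
    "PlantedTruth",
    "simulate_transport",
    "render_nerve_stack",
    "simulate_arena",
    "make_planted_image",
]

ANTERO = "antero"
RETRO = "retro"
STATIONARY = "stationary"


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransportSimSpec:
    """Scene parameters for one nerve-segment transport movie.

    Defaults follow the in-vivo fly protocol: a 20 µm segment recorded as
    100 frames over 426 s (4.26 s/frame). Rates are insertions per minute
    per direction; speeds are per-particle constants drawn from a normal
    distribution (µm/s); ``pause_prob_per_frame`` makes a mover skip a
    whole frame interval with the given probability.
    """

    segment_length: float = 20.0
    duration: float = 426.0
    frame_interval: float = 4.26
    antero_rate: float = 1.2          # insertions / min
    retro_rate: float = 0.8           # insertions / min
    antero_speed_mean: float = 0.45   # µm / s
    antero_speed_sd: float = 0.08
    retro_speed_mean: float = 0.35
    retro_speed_sd: float = 0.08
    n_stationary: int = 3
    pause_prob_per_frame: float = 0.0
    bleach_time: float | None = None
    bleach_window: tuple[float, float] = (0.0, 20.0)
    psf_sigma: float = 0.3            # µm
    noise_sd: float = 0.0             # intensity units
    px_per_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("antero_rate", "retro_rate", "antero_speed_mean", "retro_speed_mean"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in ("antero_speed_sd", "retro_speed_sd", "psf_sigma", "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not (0.0 <= self.pause_prob_per_frame <= 1.0):
            raise ValueError("pause_prob_per_frame must lie in [0, 1]")
        if self.frame_interval <= 0 or self.duration <= 0 or self.segment_length <= 0:
            raise ValueError("segment_length, duration and frame_interval must be > 0")
        lo, hi = self.bleach_window
        if not (0.0 <= lo < hi <= self.segment_length):
            raise ValueError("bleach_window must be a non-empty subinterval of [0, segment_length]")
        if self.n_stationary < 0:
            raise ValueError("n_stationary must be >= 0")

    @property
    def frame_times(self) -> np.ndarray:
        n = int(round(self.duration / self.frame_interval))
        return np.arange(n) * self.frame_interval


@dataclass
class Particle:
    """One ground-truth organelle: class label plus its sampled trajectory."""

    particle_id: int
    klass: str                      # antero | retro | stationary
    t: np.ndarray                   # s, at frame times
    x: np.ndarray                   # µm along cell-body -> terminal axis
    insertion_time: float | None    # s; None for stationary particles
    speed: float                    # µm/s (0 for stationary)

    @property
    def net_displacement(self) -> float:
        return float(self.x[-1] - self.x[0])


@dataclass
class ParticleTruth:
    """All ground-truth particles of one simulated movie plus the spec."""

    particles: list[Particle]
    spec: TransportSimSpec
    insertion_times: dict = field(default_factory=lambda: {ANTERO: [], RETRO: []})

    def n_insertions(self, direction: str) -> int:
        """Insertions with insertion time inside the recorded window [0, duration]."""
        times = np.asarray(self.insertion_times[direction], dtype=float)
        return int(np.sum((times >= 0.0) & (times <= self.spec.duration)))

    def particles_of(self, klass: str) -> list[Particle]:
        return [p for p in self.particles if p.klass == klass]


def _clip_speed(v: float, mean: float) -> float:
    # keep per-particle speeds strictly positive
    return max(v, max(0.05 * mean, 1e-3))


def simulate_transport(spec: TransportSimSpec) -> ParticleTruth:
    """Simulate ground-truth organelle trajectories for one transport movie.

    Movers arrive at the segment entry ends (anterograde at x=0 moving +x,
    retrograde at x=L moving -x) as independent Poisson processes; each
    advances at its own constant speed, skipping a frame interval with
    probability ``pause_prob_per_frame``. Stationary particles sit at
    uniform positions for the whole movie. Trajectories are sampled exactly
    at the frame times and truncated to the segment.
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.frame_times
    dt = spec.frame_interval
    L = spec.segment_length

    particles: list[Particle] = []
    insertion_times: dict = {ANTERO: [], RETRO: []}
    pid = 0

    # stationary particles first (fixed draw order => determinism)
    stat_x = rng.uniform(0.0, L, size=spec.n_stationary)
    for x0 in stat_x:
        particles.append(
            Particle(pid, STATIONARY, times.copy(), np.full_like(times, x0), None, 0.0)
        )
        pid += 1

    p_pause = spec.pause_prob_per_frame
    for klass, rate, v_mean, v_sd, entry, sign in (
        (ANTERO, spec.antero_rate, spec.antero_speed_mean, spec.antero_speed_sd, 0.0, +1.0),
        (RETRO, spec.retro_rate, spec.retro_speed_mean, spec.retro_speed_sd, L, -1.0),
    ):
        if rate <= 0:
            continue
        move_frac = max(1.0 - p_pause, 1e-3)
        burn_in = 1.5 * L / (max(v_mean, 1e-3) * move_frac)
        window = burn_in + spec.duration
        n_ins = rng.poisson(rate / 60.0 * window)
        t_ins = np.sort(rng.uniform(-burn_in, spec.duration, size=n_ins))
        insertion_times[klass] = t_ins.tolist()
        for ti in t_ins:
            v = _clip_speed(rng.normal(v_mean, v_sd), v_mean)
            # first frame-grid time at or after insertion
            k0 = int(np.ceil(ti / dt - 1e-12))
            pos = entry + sign * v * (k0 * dt - ti)
            ts, xs = [], []
            k = k0
            while True:
                t_k = k * dt
                if t_k > times[-1] + 1e-9 or pos < -1e-9 or pos > L + 1e-9:
                    break
                if t_k >= -1e-9:
                    ts.append(t_k)
                    xs.append(min(max(pos, 0.0), L))
                if rng.random() >= p_pause:
                    pos += sign * v * dt
                k += 1
            if ts:
                particles.append(
                    Particle(pid, klass, np.asarray(ts), np.asarray(xs), float(ti), v)
                )
                pid += 1

    return ParticleTruth(particles=particles, spec=spec, insertion_times=insertion_times)


def render_nerve_stack(
    truth: ParticleTruth,
    height_um: float = 4.0,
    amplitude: float = 100.0,
    stationary_amplitude: float | None = None,
    background: float = 10.0,
) -> np.ndarray:
    """Render ground-truth trajectories into a (frames, H, W) image stack.

    Each particle becomes an isotropic Gaussian spot of width ``psf_sigma``
    on the mid-row of a ``height_um``-tall canvas. If the spec carries a
    bleach event, every particle located inside the bleach window at
    ``bleach_time`` is dark from then on; particles entering later remain
    bright. Additive Gaussian noise of sd ``noise_sd`` is applied last.
    """
    spec = truth.spec
    if height_um <= 4 * spec.psf_sigma:
        raise ValueError("canvas height too small for the PSF")
    if spec.segment_length * spec.px_per_um < 2:
        raise ValueError("canvas too small for segment_length")
    if stationary_amplitude is None:
        stationary_amplitude = amplitude

    times = spec.frame_times
    W = int(round(spec.segment_length * spec.px_per_um)) + 1
    H = int(round(height_um * spec.px_per_um)) + 1
    y0 = (H - 1) / 2.0
    sig_px = spec.psf_sigma * spec.px_per_um

    bleached = np.zeros(len(truth.particles), dtype=bool)
    if spec.bleach_time is not None:
        lo, hi = spec.bleach_window
        tb = spec.bleach_time
        for i, p in enumerate(truth.particles):
            if p.t[0] - 1e-9 <= tb <= p.t[-1] + 1e-9:
                xb = float(np.interp(tb, p.t, p.x))
                bleached[i] = lo - 1e-9 <= xb <= hi + 1e-9

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    stack = np.full((len(times), H, W), background, dtype=np.float64)
    for j, t in enumerate(times):
        frame = stack[j]
        for i, p in enumerate(truth.particles):
            if bleached[i] and spec.bleach_time is not None and t >= spec.bleach_time - 1e-9:
                continue
            idx = np.searchsorted(p.t, t - 1e-9)
            if idx >= len(p.t) or abs(p.t[idx] - t) > 1e-6:
                continue
            xc = p.x[idx] * spec.px_per_um
            amp = stationary_amplitude if p.klass == STATIONARY else amplitude
            frame += amp * np.exp(-((xx - xc) ** 2 + (yy - y0) ** 2) / (2 * sig_px**2))

    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng([spec.seed, 0xB1EAC])
        stack += noise_rng.normal(0.0, spec.noise_sd, size=stack.shape)
    return stack.astype(np.float32)


# ---------------------------------------------------------------------------
# larval arena
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArenaSpec:
    """Crawling-assay movie parameters.

    Defaults mirror the locomotion protocol: a 15x15 cm agar plate filmed
    at 30 fps for 10 min. Tests and the analysis drivers pass smaller
    arenas and durations; the walk statistics are unaffected.
    """

    arena_size: tuple[float, float] = (150.0, 150.0)   # mm
    n_larvae: int = 20
    length_dist: tuple[float, float] = (3.0, 0.8)      # mm mean, sd
    speed_dist: tuple[float, float] = (0.7, 0.2)       # mm/s mean, sd
    fps: float = 30.0
    duration: float = 600.0                            # s
    touch_prob: float = 0.0
    seed: int = 0
    # rendering details
    px_per_mm: float = 4.0
    body_width: float = 0.5                            # mm
    turn_sd: float = 0.05                              # rad / frame
    background: float = 10.0
    amplitude: float = 200.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_larvae < 1:
            raise ValueError("n_larvae must be >= 1")
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be > 0")
        if not (0.0 <= self.touch_prob <= 1.0):
            raise ValueError("touch_prob must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


@dataclass
class ArenaTruth:
    """Ground truth for one arena movie."""

    lengths: np.ndarray            # mm, per larva
    speeds: np.ndarray             # mm/s, per larva
    centroids: np.ndarray          # (n_frames, n_larvae, 2) mm
    headings: np.ndarray           # (n_frames, n_larvae) rad
    touch_intervals: list          # (larva_i, larva_j, frame_start, frame_stop)
    spec: ArenaSpec

    def size_group(self, larva: int, small=(1.0, 3.0), large=(3.0, 5.0)) -> str | None:
        ln = self.lengths[larva]
        if small[0] <= ln < small[1]:
            return "small"
        if large[0] <= ln <= large[1]:
            return "large"
        return None


def simulate_arena(spec: ArenaSpec, render: bool = True) -> tuple[ArenaTruth, np.ndarray | None]:
    """Simulate (and optionally render) one multi-larva arena movie.

    Each larva performs a smooth random-heading walk at its drawn speed
    (per-frame heading increment ~ N(0, turn_sd)), reflecting off the
    arena walls. With probability ``touch_prob`` one larva pair is forced
    into contact for the middle third of the movie and the interval is
    recorded in the truth. Larvae are rendered as bright capsules whose
    centreline length equals the true body length.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.arena_size
    n, nf = spec.n_larvae, spec.n_frames

    lengths = np.clip(rng.normal(*spec.length_dist, size=n), 0.5, 5.0)
    speeds = np.clip(rng.normal(*spec.speed_dist, size=n), 0.02, None)
    margin = lengths.max() / 2 + spec.body_width
    if w <= 2 * margin or h <= 2 * margin:
        raise ValueError("arena too small for larvae of the requested length")

    pos = np.column_stack(
        [rng.uniform(margin, w - margin, n), rng.uniform(margin, h - margin, n)]
    )
    theta = rng.uniform(0, 2 * np.pi, n)

    touch_intervals: list = []
    if n >= 2 and rng.random() < spec.touch_prob:
        f0, f1 = nf // 3, 2 * nf // 3
        touch_intervals.append((0, 1, f0, f1))

    centroids = np.empty((nf, n, 2))
    headings = np.empty((nf, n))
    step = speeds / spec.fps
    for f in range(nf):
        for (i, j, f0, f1) in touch_intervals:
            if f0 <= f < f1:
                # hold larva j alongside larva i so their blobs overlap
                off = 0.6 * spec.body_width
                normal = theta[i] + np.pi / 2
                pos[j] = pos[i] + off * np.array([np.cos(normal), np.sin(normal)])
                theta[j] = theta[i]
        centroids[f] = pos
        headings[f] = theta
        theta = theta + rng.normal(0.0, spec.turn_sd, n)
        d = np.column_stack([np.cos(theta), np.sin(theta)]) * step[:, None]
        pos = pos + d
        # reflect at walls
        for k in range(2):
            lim = (w, h)[k]
            over = pos[:, k] > lim - margin
            under = pos[:, k] < margin
            pos[over, k] = 2 * (lim - margin) - pos[over, k]
            pos[under, k] = 2 * margin - pos[under, k]
            flip = over | under
            if np.any(flip):
                theta[flip] = (np.pi * (1 - k)) - theta[flip] if k == 0 else -theta[flip]
        theta = np.mod(theta, 2 * np.pi)

    truth = ArenaTruth(lengths, speeds, centroids, headings, touch_intervals, spec)
    stack = _render_arena(truth) if render else None
    return truth, stack


def _render_arena(truth: ArenaTruth) -> np.ndarray:
    spec = truth.spec
    w, h = spec.arena_size
    W = int(round(w * spec.px_per_mm))
    H = int(round(h * spec.px_per_mm))
    nf, n = truth.centroids.shape[:2]
    half_w_px = 0.5 * spec.body_width * spec.px_per_mm

    yy, xx = np.mgrid[0:H, 0:W]
    stack = np.full((nf, H, W), spec.background, dtype=np.float64)
    for f in range(nf):
        frame = stack[f]
        for i in range(n):
            cx, cy = truth.centroids[f, i] * spec.px_per_mm
            th = truth.headings[f, i]
            half = 0.5 * truth.lengths[i] * spec.px_per_mm
            ux, uy = np.cos(th), np.sin(th)
            # distance from pixel to the centreline segment
            x0, y0 = cx - half * ux, cy - half * uy
            lo = max(0, int(min(x0, cx + half * ux) - 3 * half_w_px))
            hi = min(W, int(max(x0, cx + half * ux) + 3 * half_w_px) + 1)
            lo_y = max(0, int(min(y0, cy + half * uy) - 3 * half_w_px))
            hi_y = min(H, int(max(y0, cy + half * uy) + 3 * half_w_px) + 1)
            if lo >= hi or lo_y >= hi_y:
                continue
            px = xx[lo_y:hi_y, lo:hi] - x0
            py = yy[lo_y:hi_y, lo:hi] - y0
            s = np.clip(px * ux + py * uy, 0.0, 2 * half)
            d2 = (px - s * ux) ** 2 + (py - s * uy) ** 2
            frame[lo_y:hi_y, lo:hi] = np.where(
                d2 <= half_w_px**2, spec.amplitude, frame[lo_y:hi_y, lo:hi]
            )
    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng([spec.seed, 0xA7E9A])
        stack += noise_rng.normal(0.0, spec.noise_sd, size=stack.shape)
    return stack.astype(np.float32)


# ---------------------------------------------------------------------------
# planted two-channel images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedRegion:
    """A planted bright region: a disk or axis-aligned rectangle, in µm."""

    shape: str                      # "disk" | "rect"
    center: tuple[float, float]     # µm (x, y)
    size: float | tuple[float, float]  # disk radius, or rect (width, height)
    ch0: float                      # membrane-channel intensity
    ch1: float                      # cargo-channel intensity


@dataclass(frozen=True)
class PlantedImageSpec:
    canvas: tuple[float, float] = (100.0, 20.0)   # µm (width, height)
    px_per_um: float = 5.0
    regions: tuple = ()
    background: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        for r in self.regions:
            if min(r.ch0, r.ch1) < self.background:
                raise ValueError("region intensities must be >= background")


@dataclass
class PlantedTruth:
    masks: list                 # boolean pixel masks, one per region
    areas_um2: np.ndarray       # pixel-counted area per region
    regions: tuple
    px_per_um: float

    @property
    def total_area_um2(self) -> float:
        return float(self.areas_um2.sum())


def _region_mask(region: PlantedRegion, shape_px: tuple[int, int], px_per_um: float) -> np.ndarray:
    H, W = shape_px
    yy, xx = np.mgrid[0:H, 0:W]
    cx, cy = (c * px_per_um for c in region.center)
    if region.shape == "disk":
        r_px = float(region.size) * px_per_um
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
    if region.shape == "rect":
        rw, rh = region.size
        return (np.abs(xx - cx) <= rw * px_per_um / 2) & (np.abs(yy - cy) <= rh * px_per_um / 2)
    raise ValueError(f"unknown region shape {region.shape!r}")


def make_planted_image(spec: PlantedImageSpec) -> tuple[np.ndarray, PlantedTruth]:
    """Render a two-channel image with planted regions and return exact truth.

    Returns ``(image, truth)`` where ``image`` has shape (2, H, W)
    (channel 0 = membrane, channel 1 = cargo) and ``truth`` carries the
    pixel mask and pixel-counted area of every planted region.
    """
    W = int(round(spec.canvas[0] * spec.px_per_um))
    H = int(round(spec.canvas[1] * spec.px_per_um))
    masks = []
    for r in spec.regions:
        m = _region_mask(r, (H, W), spec.px_per_um)
        if not m.any():
            raise ValueError("planted region lies outside the canvas")
        cx, cy = r.center
        if not (0 <= cx <= spec.canvas[0] and 0 <= cy <= spec.canvas[1]):
            raise ValueError("planted region centre outside canvas")
        masks.append(m)
    if not spec.allow_overlap:
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if np.any(masks[i] & masks[j]):
                    raise ValueError(f"regions {i} and {j} overlap")

    img = np.full((2, H, W), spec.background, dtype=np.float64)
    for r, m in zip(spec.regions, masks):
        img[0][m] = r.ch0
        img[1][m] = r.ch1
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 0xF1A7])
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    areas = np.array([m.sum() / spec.px_per_um**2 for m in masks])
    return img.astype(np.float32), PlantedTruth(masks, areas, spec.regions, spec.px_per_um)
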