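"""Fluorescence morphometry of segmental nerves and neuromuscular junctions.

Covers four measurement families from two-channel confocal images
(channel 0: neuronal membrane marker, anti-HRP-like; channel 1: cargo):

* axonal cargo accumulations — regions inside the nerve that are
  simultaneously bright in membrane and cargo channel, reported as a
  count per 1000 µm² of nerve and as an area fraction;
* axon diameter statistics — median, quartiles and 1st/99th percentiles
  of tabulated diameters, and focal-swelling detection along a diameter
  profile (a ≥ fold_threshold diameter increase within a micron scale);
* NMJ metrics — NMJ area from the membrane mask plus number, mean size
  and density (area fraction within the NMJ) of cargo puncta such as
  mitochondria or glutamate-receptor fields;
* an additive degeneration score combining retraction, dystrophic-bouton
  and minor-alteration categories with configurable weights.

"Bright" is everywhere defined as exceeding the within-mask median by
``k_mad`` median absolute deviations (default k=3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, filters, measure, segmentation

__all__ = [
    "TwoChannelImage",
    "AccumulationResult",
    "AxonDiameterSet",
    "SwellingEvent",
    "NMJMorphology",
    "DegenerationScore",
    "detect_accumulations",
    "diameter_stats",
    "detect_swellings",
    "nmj_metrics",
    "degeneration_score",
    "retraction_flag",
]


@dataclass
class TwoChannelImage:
    """Membrane + cargo channel pair with a common µm/px calibration."""

    membrane: np.ndarray
    cargo: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        self.membrane = np.asarray(self.membrane, dtype=float)
        self.cargo = np.asarray(self.cargo, dtype=float)
        if self.membrane.shape != self.cargo.shape:
            raise ValueError("channel dimensions differ")
        if self.um_per_px <= 0:
            raise ValueError("calibration must be > 0")

    @classmethod
    def from_stack(cls, img: np.ndarray, um_per_px: float) -> "TwoChannelImage":
        """Build from a (2, H, W) array (channel 0 membrane, 1 cargo)."""
        return cls(img[0], img[1], um_per_px)

    @property
    def px_area_um2(self) -> float:
        return self.um_per_px**2


@dataclass
class AccumulationResult:
    n_accumulations: int
    count_per_1000um2: float
    area_fraction: float
    nerve_area_um2: float
    labels: np.ndarray = field(repr=False, default=None)


@dataclass
class AxonDiameterSet:
    diameters: np.ndarray
    median: float
    q1: float
    q3: float
    p1: float
    p99: float


@dataclass(frozen=True)
class SwellingEvent:
    start_um: float
    end_um: float
    max_fold: float


@dataclass
class NMJMorphology:
    nmj_area: float         # µm²
    synapse_count: int      # puncta count (receptor fields / mitochondria)
    mito_number: int
    mito_mean_size: float   # µm²
    mito_density: float     # mito area fraction within the NMJ mask
    labels: np.ndarray = field(repr=False, default=None)


@dataclass
class DegenerationScore:
    flags: dict
    weights: dict
    total: int


def _mask_from_membrane(membrane: np.ndarray) -> np.ndarray:
    """Threshold the membrane channel and keep the largest component."""
    if membrane.max() - membrane.min() < 1e-12:
        raise ValueError("membrane channel is flat; no mask obtainable")
    thr = filters.threshold_otsu(membrane)
    fg = membrane > thr
    if not fg.any():
        raise ValueError("empty membrane mask")
    labels = measure.label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return ndimage.binary_fill_holes(labels == largest)


def _bright_threshold(values: np.ndarray, k_mad: float) -> float:
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med + k_mad * mad


# ---------------------------------------------------------------------------
# accumulations
# ---------------------------------------------------------------------------

def detect_accumulations(
    img: TwoChannelImage,
    k_mad: float = 3.0,
    min_area_um2: float = 1.0,
) -> AccumulationResult:
    """Count co-bright (membrane AND cargo) regions inside the nerve.

    The nerve mask is the largest thresholded membrane component. An
    accumulation is a connected region inside the nerve where both
    channels exceed their within-nerve median + k·MAD; regions smaller
    than ``min_area_um2`` are discarded. Counts are normalised per
    1000 µm² of nerve-mask area, and the area fraction is accumulation
    area over nerve area.
    """
    nerve = _mask_from_membrane(img.membrane)
    thr_m = _bright_threshold(img.membrane[nerve], k_mad)
    thr_c = _bright_threshold(img.cargo[nerve], k_mad)
    co = nerve & (img.membrane > thr_m) & (img.cargo > thr_c)
    labels = measure.label(co)
    min_px = min_area_um2 / img.px_area_um2
    acc_area_px = 0
    n = 0
    out = np.zeros_like(labels)
    for rp in measure.regionprops(labels):
        if rp.area >= min_px:
            n += 1
            acc_area_px += rp.area
            out[labels == rp.label] = n
    nerve_area = float(nerve.sum() * img.px_area_um2)
    return AccumulationResult(
        n_accumulations=n,
        count_per_1000um2=n / (nerve_area / 1000.0),
        area_fraction=acc_area_px * img.px_area_um2 / nerve_area,
        nerve_area_um2=nerve_area,
        labels=out,
    )


# ---------------------------------------------------------------------------
# diameters and swellings
# ---------------------------------------------------------------------------

def diameter_stats(diameters) -> AxonDiameterSet:
    """Median, quartiles and 1st/99th percentiles (linear interpolation)."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter list")
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError("diameters must be positive and finite")
    p1, q1, med, q3, p99 = np.percentile(d, [1, 25, 50, 75, 99])
    return AxonDiameterSet(d, float(med), float(q1), float(q3), float(p1), float(p99))


def detect_swellings(
    profile,
    fold_threshold: float = 3.0,
    within_um: float = 1.0,
) -> list[SwellingEvent]:
    """Detect focal swellings along an axon-diameter profile.

    ``profile`` is a sequence of (position µm, diameter µm) sampled at
    ≤ 0.5 µm spacing. An event is any position pair closer than
    ``within_um`` whose diameter ratio (larger/smaller) reaches
    ``fold_threshold``; overlapping events are merged.
    """
    prof = np.asarray(profile, dtype=float)
    if prof.ndim != 2 or prof.shape[1] != 2 or len(prof) < 2:
        raise ValueError("profile must be a list of (position, diameter) pairs")
    x, d = prof[:, 0], prof[:, 1]
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    if np.any(np.diff(x) <= 0):
        raise ValueError("positions must be strictly increasing")
    if np.max(np.diff(x)) > 0.5 + 1e-9:
        raise ValueError("profile must be sampled at <= 0.5 µm spacing")

    intervals: list[tuple[float, float, float]] = []
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if x[j] - x[i] > within_um + 1e-12:
                break
            hi, lo = max(d[i], d[j]), min(d[i], d[j])
            fold = hi / lo
            if fold >= fold_threshold:
                intervals.append((x[i], x[j], fold))
    if not intervals:
        return []
    intervals.sort()
    merged: list[list[float]] = [list(intervals[0])]
    for a, b, fold in intervals[1:]:
        if a <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], b)
            merged[-1][2] = max(merged[-1][2], fold)
        else:
            merged.append([a, b, fold])
    return [SwellingEvent(a, b, f) for a, b, f in merged]


# ---------------------------------------------------------------------------
# NMJ metrics
# ---------------------------------------------------------------------------

def nmj_metrics(
    img: TwoChannelImage,
    k_mad: float = 3.0,
    min_punctum_area_um2: float = 0.2,
    min_distance_px: int = 3,
) -> NMJMorphology:
    """NMJ area from the membrane mask; puncta metrics from the cargo channel.

    Puncta (mitochondria or receptor fields) are local-maximum-seeded
    watershed regions of above-threshold cargo signal inside the NMJ
    mask. Density is the puncta area fraction of the NMJ area.
    """
    nmj = _mask_from_membrane(img.membrane)
    nmj_area = float(nmj.sum() * img.px_area_um2)
    thr = _bright_threshold(img.cargo[nmj], k_mad)
    binary = nmj & (img.cargo > thr)
    if binary.any():
        # smooth before seeding so pixel noise cannot split one punctum
        smooth = ndimage.gaussian_filter(img.cargo, 1.0)
        peaks = feature.peak_local_max(
            np.where(binary, smooth, 0.0), min_distance=min_distance_px, labels=binary
        )
        markers = np.zeros(binary.shape, dtype=int)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            labels = measure.label(binary)
        else:
            labels = segmentation.watershed(-smooth, markers, mask=binary)
    else:
        labels = np.zeros(binary.shape, dtype=int)

    min_px = min_punctum_area_um2 / img.px_area_um2
    areas = [rp.area for rp in measure.regionprops(labels) if rp.area >= min_px]
    n = len(areas)
    total_area_um2 = float(sum(areas) * img.px_area_um2)
    return NMJMorphology(
        nmj_area=nmj_area,
        synapse_count=n,
        mito_number=n,
        mito_mean_size=(total_area_um2 / n if n else 0.0),
        mito_density=total_area_um2 / nmj_area,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# degeneration score
# ---------------------------------------------------------------------------

def retraction_flag(sv_absent: bool, membrane_absent: bool, postsynaptic_intact: bool) -> bool:
    """A retraction requires simultaneous absence of the synaptic-vesicle
    marker and the presynaptic membrane over a region with intact
    postsynaptic signal."""
    return bool(sv_absent and membrane_absent and postsynaptic_intact)


def degeneration_score(flags: dict, weights: dict | None = None) -> DegenerationScore:
    """Additive degeneration score: total = Σ weight x flag.

    ``flags`` maps category names (e.g. 'retraction', 'dystrophic',
    'minor') to booleans or small non-negative counts; default weight is
    1 per category.
    """
    weights = dict(weights or {})
    for cat in flags:
        weights.setdefault(cat, 1)
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be non-negative")
    if any(int(v) != v or v < 0 for v in flags.values()):
        raise ValueError("flags must be booleans or non-negative integers")
    total = int(sum(weights[c] * int(v) for c, v in flags.items()))
    return DegenerationScore(dict(flags), weights, total)
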