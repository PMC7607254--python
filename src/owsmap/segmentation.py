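"""Beat detection, pacing-cycle-length segmentation, and beat windowing.

Beats are detected on the tissue-average signal (never per pixel), the record
is split into sections of constant pacing cycle length (PCL), and every pixel
is windowed around the *same* tissue-average peak times so beats stay aligned
across the image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .preprocess import TissueSignal
from .stackio import ImageStack, ValidationError

log = logging.getLogger("owsmap")


def round_half_away(x: float) -> int:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass
class BeatCatalog:
    """Detected peaks, per-beat PCLs, and constant-PCL sections.

    ``pcl[i]`` is the time from peak ``i-1`` to peak ``i``; the first beat has
    no PCL (NaN).  ``section_bounds`` holds inclusive ``(first, last)`` beat
    indices; sections are contiguous and ordered.
    """

    peak_times: np.ndarray            # ms
    pcl: np.ndarray                   # ms; pcl[0] = NaN
    sampling_rate: float
    section_bounds: list = field(default_factory=list)
    section_pcl: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=np.float64)
        self.pcl = np.asarray(self.pcl, dtype=np.float64)
        if self.peak_times.size and np.any(np.diff(self.peak_times) <= 0):
            raise ValidationError("peak_times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.peak_times.size)

    @property
    def n_sections(self) -> int:
        return len(self.section_bounds)

    def section_of(self, beat: int) -> int:
        for k, (a, b) in enumerate(self.section_bounds):
            if a <= beat <= b:
                return k
        raise IndexError(f"beat {beat} not in any section")


@dataclass
class WindowSpec:
    """Beat window: ``pre_ms`` before and ``post_ms`` after the alignment peak.

    ``minima_trim`` enables the pairwise trimming used for guinea-pig data,
    where the window for each OAP *pair* runs from the closest pre-peak local
    minimum (of either OAP) to the closest post-peak local minimum.
    """

    pre_ms: float
    post_ms: float
    minima_trim: bool = False

    def __post_init__(self) -> None:
        if not (self.pre_ms > 0 and self.post_ms > 0):
            raise ValidationError("window pre_ms and post_ms must be > 0")

    @classmethod
    def for_species(cls, species: str) -> "WindowSpec":
        from .preprocess import SPECIES_PRESETS

        p = SPECIES_PRESETS[species]
        return cls(p["window_pre_ms"], p["window_post_ms"], p["minima_trim"])

    def frames(self, sampling_rate: float) -> tuple[int, int]:
        """(pre, post) window half-lengths in whole frames (half away from zero)."""
        pre = round_half_away(self.pre_ms * sampling_rate / 1000.0)
        post = round_half_away(self.post_ms * sampling_rate / 1000.0)
        return pre, post


@dataclass
class AlignedBeatSet:
    """Windowed raw OAP vectors for every masked pixel, globally aligned.

    ``raw`` has shape ``(n_pixels, n_beats, K)``; window sample ``peak_sample``
    coincides with the tissue-average peak of that beat.  Normalised vectors
    (zero-mean, unit L2 norm) are computed lazily; when pairwise minima
    trimming is enabled the similarity layer re-normalises per pair instead.
    """

    raw: np.ndarray                       # (P, M, K)
    peak_sample: int                      # index of the alignment peak inside the window
    alignment_times: np.ndarray           # ms, per retained beat
    beat_indices: np.ndarray              # catalog beat index per retained beat
    pixel_coords: np.ndarray              # (P, 2) row/col of each pixel
    sampling_rate: float
    minima_trim: bool
    dropped_beats: list = field(default_factory=list)
    catalog: BeatCatalog | None = None

    @property
    def n_pixels(self) -> int:
        return self.raw.shape[0]

    @property
    def n_beats(self) -> int:
        return self.raw.shape[1]

    @property
    def samples_per_beat(self) -> int:
        return self.raw.shape[2]

    def normalised(self) -> np.ndarray:
        """Zero-corrected, unit-norm copies of every windowed beat."""
        return normalise_beats(self.raw)

    def pixel(self, p: int) -> np.ndarray:
        """Raw windowed beats (M, K) of one pixel."""
        return self.raw[p]

    def section_slices(self) -> list:
        """Per-section slices into the retained-beat axis.

        Sections come from the catalog; beats dropped at record edges are
        skipped, so a slice may be shorter than the catalog section.
        """
        if self.catalog is None or not self.catalog.section_bounds:
            return [(None, np.arange(self.n_beats))]
        out = []
        for k, (a, b) in enumerate(self.catalog.section_bounds):
            sel = np.nonzero((self.beat_indices >= a) & (self.beat_indices <= b))[0]
            if sel.size:
                out.append((k, sel))
        return out


def normalise_beats(raw: np.ndarray) -> np.ndarray:
    """Zero-correct (subtract mean) and L2-normalise along the last axis.

    Constant vectors (zero variance) come back as all-zero rather than NaN so
    degenerate pixels degrade gracefully downstream.
    """
    raw = np.asarray(raw, dtype=np.float64)
    centred = raw - raw.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(centred, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = centred / norm
    return np.where(norm > 0, out, 0.0)


# ---------------------------------------------------------------------------
# peak detection and PCL segmentation
# ---------------------------------------------------------------------------

def detect_peaks(
    signal: TissueSignal,
    amp_fraction: float = 0.5,
    min_distance_ms: float = 40.0,
) -> BeatCatalog:
    """Find beats as local maxima of the tissue-average signal.

    A candidate must exceed ``amp_fraction`` of the signal maximum; of two
    candidates closer than ``min_distance_ms`` the higher one is kept.  PCL is
    the time from the previous peak.
    """
    y = signal.f_tissue
    if y.size < 3:
        raise ValidationError("signal too short for peak detection")
    height = amp_fraction * y.max()
    distance = max(1, round_half_away(min_distance_ms * signal.sampling_rate / 1000.0))
    idx, _ = sp_signal.find_peaks(y, height=height, distance=distance)
    if idx.size == 0:
        warnings.warn("no peaks found in tissue-average signal", stacklevel=2)
        return BeatCatalog(
            peak_times=np.empty(0),
            pcl=np.empty(0),
            sampling_rate=signal.sampling_rate,
        )
    times = signal.time_origin + idx * (1000.0 / signal.sampling_rate)
    pcl = np.empty(times.size)
    pcl[0] = np.nan
    pcl[1:] = np.diff(times)
    log.info("detected %d peaks", idx.size)
    return BeatCatalog(peak_times=times, pcl=pcl, sampling_rate=signal.sampling_rate)


def segment_by_pcl(catalog: BeatCatalog, change_threshold_ms: float = 10.0) -> BeatCatalog:
    """Split the beat train into sections of constant PCL.

    A new section starts at beat ``i`` when its PCL deviates from the current
    section's PCL (the median of the PCLs accumulated so far) by at least
    ``change_threshold_ms``.  Section PCL is finalised as the median PCL of
    the section's beats.
    """
    if catalog.n_beats < 2:
        catalog.section_bounds = [(0, max(catalog.n_beats - 1, 0))] if catalog.n_beats else []
        catalog.section_pcl = [np.nan] * len(catalog.section_bounds)
        return catalog

    bounds: list[tuple[int, int]] = []
    start = 0
    current: list[float] = []
    for i in range(catalog.n_beats):
        p = catalog.pcl[i]
        if np.isnan(p):
            continue
        if current and abs(p - float(np.median(current))) >= change_threshold_ms:
            bounds.append((start, i - 1))
            start = i
            current = [p]
        else:
            current.append(p)
    bounds.append((start, catalog.n_beats - 1))

    pcls = []
    for a, b in bounds:
        vals = catalog.pcl[a : b + 1]
        vals = vals[~np.isnan(vals)]
        pcls.append(float(np.median(vals)) if vals.size else np.nan)
    catalog.section_bounds = bounds
    catalog.section_pcl = pcls
    log.info("segmented %d beats into %d sections (PCLs %s)", catalog.n_beats, len(bounds), pcls)
    return catalog


def restrict_to_time_range(catalog: BeatCatalog, t0_ms: float, t1_ms: float) -> BeatCatalog:
    """Keep only beats inside a user-supplied time range (one section).

    This is the fibrillation path: automatic PCL segmentation is unreliable
    during VF, so the caller selects the arrhythmic period explicitly and all
    retained beats form a single section.
    """
    keep = (catalog.peak_times >= t0_ms) & (catalog.peak_times <= t1_ms)
    times = catalog.peak_times[keep]
    pcl = np.empty(times.size)
    if times.size:
        pcl[0] = np.nan
        pcl[1:] = np.diff(times)
    out = BeatCatalog(peak_times=times, pcl=pcl, sampling_rate=catalog.sampling_rate)
    if times.size:
        vals = pcl[~np.isnan(pcl)]
        out.section_bounds = [(0, times.size - 1)]
        out.section_pcl = [float(np.median(vals)) if vals.size else np.nan]
    return out


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def window_beats(stack: ImageStack, catalog: BeatCatalog, spec: WindowSpec) -> AlignedBeatSet:
    """Extract the window [peak - pre_ms, peak + post_ms] around every
    tissue-average peak, for every masked pixel.

    Windows are inclusive of both endpoints, so at rate ``r`` a window holds
    ``pre + post + 1`` frames.  Beats whose windows run off the record are
    dropped (and logged), never truncated.  Overlapping windows (fast pacing
    with minima trimming off) are permitted with a warning.
    """
    pre, post = spec.frames(stack.sampling_rate)
    if pre + post + 1 < 3:
        raise ValidationError("window shorter than 3 frames")

    peak_frames = np.array(
        [round_half_away((t - stack.time_origin) * stack.sampling_rate / 1000.0)
         for t in catalog.peak_times],
        dtype=int,
    )
    keep, dropped = [], []
    for b, pf in enumerate(peak_frames):
        if pf - pre < 0 or pf + post >= stack.n_frames:
            dropped.append(b)
        else:
            keep.append(b)
    if dropped:
        log.info("dropped %d beat(s) at record edges: %s", len(dropped), dropped)

    if not spec.minima_trim and catalog.n_beats >= 2:
        min_pcl = np.nanmin(catalog.pcl) if np.any(~np.isnan(catalog.pcl)) else np.inf
        if (pre + post) * (1000.0 / stack.sampling_rate) > min_pcl:
            warnings.warn(
                "beat windows overlap (window longer than the shortest PCL)",
                stacklevel=2,
            )

    coords = np.argwhere(stack.mask)
    K = pre + post + 1
    raw = np.empty((coords.shape[0], len(keep), K))
    for j, b in enumerate(keep):
        pf = peak_frames[b]
        win = stack.frames[pf - pre : pf + post + 1]      # (K, rows, cols)
        raw[:, j, :] = win[:, coords[:, 0], coords[:, 1]].T

    return AlignedBeatSet(
        raw=raw,
        peak_sample=pre,
        alignment_times=catalog.peak_times[keep],
        beat_indices=np.asarray(keep, dtype=int),
        pixel_coords=coords,
        sampling_rate=stack.sampling_rate,
        minima_trim=spec.minima_trim,
        dropped_beats=dropped,
        catalog=catalog,
    )
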