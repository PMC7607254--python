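"""Optical wave similarity (OWS) and regularity index (RI).

Every windowed optical action potential (OAP) ``A`` is zero-corrected and
L2-normalised,

    An = (A - mean(A)) / ||A - mean(A)||,

so the similarity of two OAPs is their cosine similarity ``s = An1 . An2``
(1 identical morphology, 0 unrelated, -1 opposite phase).  For a sequence of
M OAPs,

    OWS = 2 / (M (M - 1)) * sum_{i<j} s(Ai, Aj),

the mean over all unordered pairs.  The regularity index converts each
similarity to an angular wave distance ``d = arccos(s)`` in [0, pi] and counts
the fraction of pairs with ``d <= epsilon``:

    RI = 2 / (M (M - 1)) * sum_{i<j} H(epsilon - d(Ai, Aj)).

OWS needs no threshold; RI's behaviour depends strongly on epsilon (default
pi/6, where the two measures correlate best).  Both are invariant to per-beat
affine rescaling of the raw fluorescence.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .segmentation import AlignedBeatSet, BeatCatalog, WindowSpec, normalise_beats, window_beats
from .stackio import ImageStack, ValidationError

log = logging.getLogger("owsmap")

#: Default RI distance threshold (radians).
DEFAULT_EPSILON = math.pi / 6


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise OAP cosine similarities, entries in [-1, 1]."""

    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.float64)
        if self.s.ndim != 2 or self.s.shape[0] != self.s.shape[1]:
            raise ValidationError("similarity matrix must be square")

    @property
    def m(self) -> int:
        return self.s.shape[0]

    def distances(self) -> np.ndarray:
        """Angular wave distances arccos(s), radians in [0, pi]."""
        return np.arccos(np.clip(self.s, -1.0, 1.0))

    def upper_mean(self) -> float:
        iu = np.triu_indices(self.m, k=1)
        return float(self.s[iu].mean())


@dataclass
class OWSResult:
    """Per-pixel OWS mapping output."""

    ows_map: np.ndarray                       # 2-D, NaN outside mask
    mean_ows: float
    per_section: list                         # [(section_pcl_ms, mean_ows)]
    single_beat: np.ndarray | None = None     # (M-1,) mean series over pixels
    single_beat_maps: np.ndarray | None = None  # (M-1, rows, cols)
    section_maps: list = field(default_factory=list)  # [(pcl, 2-D map)]
    boundary_transitions: list = field(default_factory=list)
    degenerate_pixels: int = 0


@dataclass
class RIResult:
    """Per-pixel regularity-index mapping output."""

    epsilon: float
    ri_map: np.ndarray
    mean_ri: float
    per_section: list
    d: np.ndarray | None = None               # pairwise distances (single-pixel use)
    section_maps: list = field(default_factory=list)
    degenerate_pixels: int = 0


# ---------------------------------------------------------------------------
# pairwise windows: closest-minima trimming
# ---------------------------------------------------------------------------

def closest_minima(vec: np.ndarray, peak: int) -> tuple[int, int]:
    """Indices of the local minima nearest the peak on each side.

    The search is restricted to the window itself; if a side is monotone
    (no interior local minimum) the window edge is returned.  On a plateau
    the sample nearest the peak wins because the scan walks outward from the
    peak.
    """
    n = vec.size
    lo = 0
    for i in range(peak - 1, 0, -1):
        if vec[i] <= vec[i - 1] and vec[i] <= vec[i + 1]:
            lo = i
            break
    hi = n - 1
    for i in range(peak + 1, n - 1):
        if vec[i] <= vec[i - 1] and vec[i] <= vec[i + 1]:
            hi = i
            break
    return lo, hi


def pair_trim_bounds(
    a: np.ndarray, b: np.ndarray, peak: int
) -> tuple[int, int]:
    """Shared trimmed window for an OAP pair.

    Runs from the closest pre-peak minimum of *either* OAP to the closest
    post-peak minimum of either OAP; degenerate results fall back to the
    3 samples around the peak.
    """
    lo_a, hi_a = closest_minima(a, peak)
    lo_b, hi_b = closest_minima(b, peak)
    lo = max(lo_a, lo_b)
    hi = min(hi_a, hi_b)
    if hi - lo + 1 < 3:
        lo = max(peak - 1, 0)
        hi = min(peak + 1, a.size - 1)
    return lo, hi


def _snap(s):
    """Clamp to [-1, 1] and snap float-identical pairs to exactly +/-1 so
    identical OAPs get wave distance exactly 0 (arccos is steep near 1)."""
    s = np.clip(s, -1.0, 1.0)
    return np.where(np.abs(s) > 1.0 - 1e-12, np.sign(s), s)


def _normalise_1d(v: np.ndarray) -> np.ndarray | None:
    c = v - v.mean()
    n = np.linalg.norm(c)
    if n == 0:
        return None
    return c / n


def wave_similarity(
    a: np.ndarray,
    b: np.ndarray,
    trim: bool = False,
    peak: int | None = None,
) -> float:
    """Cosine similarity of two raw OAP vectors.

    Each vector is zero-corrected and unit-normalised before the dot product;
    the result is clamped to [-1, 1] against rounding.  With ``trim`` on, the
    pair is first restricted to the shared closest-minima window around
    ``peak``.  A constant (zero-variance) vector carries no morphology and
    yields similarity 0 with a warning.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size != b.size:
        raise ValidationError(f"OAP vectors differ in length ({a.size} vs {b.size})")
    if a.size < 3:
        raise ValidationError("OAP vectors must have at least 3 samples")
    if trim:
        if peak is None:
            peak = int(np.argmax(a + b))
        lo, hi = pair_trim_bounds(a, b, peak)
        a = a[lo : hi + 1]
        b = b[lo : hi + 1]
    na = _normalise_1d(a)
    nb = _normalise_1d(b)
    if na is None or nb is None:
        warnings.warn("constant OAP vector: similarity defined as 0", stacklevel=2)
        return 0.0
    return float(_snap(np.dot(na, nb)))


# ---------------------------------------------------------------------------
# per-pixel metrics on a beat sequence (M, K)
# ---------------------------------------------------------------------------

def similarity_matrix(
    beats: np.ndarray, trim: bool = False, peak: int | None = None
) -> SimilarityMatrix:
    """All pairwise similarities of a beat sequence (rows = beats).

    Without trimming this is a single normalised Gram matrix; with trimming
    each pair is re-normalised on its shared closest-minima window (the
    per-beat minima are cached, so trimming costs O(M^2 K)).
    """
    beats = np.asarray(beats, dtype=np.float64)
    if beats.ndim != 2:
        raise ValidationError("beats must be a 2-D (M, K) array")
    m = beats.shape[0]
    if not trim:
        nb = normalise_beats(beats)
        s = _snap(nb @ nb.T)
        np.fill_diagonal(s, [1.0 if np.any(row != 0) else 0.0 for row in nb])
        return SimilarityMatrix(s=s)

    if peak is None:
        peak = int(np.argmax(beats.mean(axis=0)))
    bounds = [closest_minima(beats[i], peak) for i in range(m)]
    s = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            lo = max(bounds[i][0], bounds[j][0])
            hi = min(bounds[i][1], bounds[j][1])
            if hi - lo + 1 < 3:
                lo = max(peak - 1, 0)
                hi = min(peak + 1, beats.shape[1] - 1)
            na = _normalise_1d(beats[i, lo : hi + 1])
            nbv = _normalise_1d(beats[j, lo : hi + 1])
            sij = 0.0 if na is None or nbv is None else float(_snap(np.dot(na, nbv)))
            s[i, j] = s[j, i] = sij
    return SimilarityMatrix(s=s)


def ows(beats: np.ndarray, trim: bool = False, peak: int | None = None) -> float:
    """OWS of one pixel's beat sequence: mean of all unordered pairwise
    similarities.  NaN (with a warning) when fewer than 2 beats."""
    beats = np.asarray(beats, dtype=np.float64)
    if beats.shape[0] < 2:
        warnings.warn("OWS undefined for fewer than 2 beats", stacklevel=2)
        return float("nan")
    return similarity_matrix(beats, trim=trim, peak=peak).upper_mean()


def single_beat_ows(
    beats: np.ndarray, trim: bool = False, peak: int | None = None
) -> np.ndarray:
    """Series of similarities of each OAP with the subsequent OAP (length M-1)."""
    beats = np.asarray(beats, dtype=np.float64)
    if beats.shape[0] < 2:
        warnings.warn("single-beat OWS undefined for fewer than 2 beats", stacklevel=2)
        return np.empty(0)
    return np.array(
        [
            wave_similarity(beats[i], beats[i + 1], trim=trim, peak=peak)
            for i in range(beats.shape[0] - 1)
        ]
    )


def wave_distances(
    beats: np.ndarray, trim: bool = False, peak: int | None = None
) -> np.ndarray:
    """Pairwise angular wave distances arccos(s), radians in [0, pi]."""
    return similarity_matrix(beats, trim=trim, peak=peak).distances()


def regularity_index(
    beats: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    trim: bool = False,
    peak: int | None = None,
    d: np.ndarray | None = None,
) -> float:
    """Fraction of unordered OAP pairs with wave distance <= epsilon.

    Boundary pairs (d == epsilon) count as similar.  A precomputed distance
    matrix ``d`` may be passed to amortise threshold sweeps.
    """
    if not 0 <= epsilon <= math.pi:
        raise ValidationError(f"epsilon must be in [0, pi], got {epsilon}")
    if d is None:
        beats = np.asarray(beats, dtype=np.float64)
        if beats.shape[0] < 2:
            warnings.warn("RI undefined for fewer than 2 beats", stacklevel=2)
            return float("nan")
        d = wave_distances(beats, trim=trim, peak=peak)
    iu = np.triu_indices(d.shape[0], k=1)
    return float(np.mean(d[iu] <= epsilon))


def ri_threshold_sweep(
    beats: np.ndarray,
    epsilons,
    trim: bool = False,
    peak: int | None = None,
) -> np.ndarray:
    """RI at several distance thresholds, from one cached distance matrix.

    The output is non-decreasing in epsilon by construction.
    """
    epsilons = np.asarray(list(epsilons), dtype=np.float64)
    if np.any((epsilons < 0) | (epsilons > math.pi)):
        raise ValidationError("all epsilons must lie in [0, pi]")
    d = wave_distances(np.asarray(beats, dtype=np.float64), trim=trim, peak=peak)
    return np.array([regularity_index(None, e, d=d) for e in epsilons])


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------

def _pixel_metric(beats, metric, trim, peak, epsilon):
    if metric == "ows":
        return ows(beats, trim=trim, peak=peak)
    if metric == "ri":
        return regularity_index(beats, epsilon=epsilon, trim=trim, peak=peak)
    raise ValidationError(f"unknown metric {metric!r}")


def map_over_pixels(
    stack: ImageStack,
    catalog: BeatCatalog,
    spec: WindowSpec,
    metric: str = "ows",
    epsilon: float = DEFAULT_EPSILON,
    beats: AlignedBeatSet | None = None,
):
    """Compute an OWS, RI or single-beat-OWS map over all masked pixels.

    The metric is evaluated independently per pixel and per PCL section
    (beat pairs never straddle a section change, except the explicitly
    flagged single-beat transitions).  Unmasked pixels are NaN; pixels whose
    beats are all degenerate come back NaN and are counted.
    """
    if beats is None:
        beats = window_beats(stack, catalog, spec)
    shape = stack.mask.shape
    coords = beats.pixel_coords
    sections = beats.section_slices()

    if metric == "single_beat":
        m = beats.n_beats
        if m < 2:
            raise ValidationError("single-beat OWS needs at least 2 retained beats")
        maps = np.full((m - 1, *shape), np.nan)
        for p in range(beats.n_pixels):
            series = single_beat_ows(beats.raw[p], trim=beats.minima_trim, peak=beats.peak_sample)
            maps[:, coords[p, 0], coords[p, 1]] = series
        flagged = []
        if beats.catalog is not None and beats.catalog.section_bounds:
            last_of_section = {b for _, b in beats.catalog.section_bounds[:-1]}
            flagged = [
                i for i in range(m - 1) if int(beats.beat_indices[i]) in last_of_section
            ]
        mean_series = np.nanmean(maps.reshape(m - 1, -1), axis=1)
        overall = np.nanmean(maps, axis=0)
        finite = overall[np.isfinite(overall)]
        return OWSResult(
            ows_map=overall,
            mean_ows=float(finite.mean()) if finite.size else float("nan"),
            per_section=[],
            single_beat=mean_series,
            single_beat_maps=maps,
            boundary_transitions=flagged,
        )

    section_maps = []
    degenerate = 0
    for sec_idx, sel in sections:
        if sel.size < 2:
            continue
        m2 = np.full(shape, np.nan)
        for p in range(beats.n_pixels):
            seq = beats.raw[p][sel]
            if np.ptp(seq, axis=1).max() == 0:
                degenerate += 1
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m2[coords[p, 0], coords[p, 1]] = _pixel_metric(
                    seq, metric, beats.minima_trim, beats.peak_sample, epsilon
                )
        pcl = (
            beats.catalog.section_pcl[sec_idx]
            if (beats.catalog is not None and sec_idx is not None)
            else float("nan")
        )
        section_maps.append((pcl, m2))
    if not section_maps:
        raise ValidationError("no section holds 2 or more retained beats")
    if degenerate:
        log.info("%d degenerate pixel/section combinations set to NaN", degenerate)

    stacked = np.stack([m2 for _, m2 in section_maps])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        overall = np.nanmean(stacked, axis=0)
    finite = overall[np.isfinite(overall)]
    mean_val = float(finite.mean()) if finite.size else float("nan")
    per_section = [
        (pcl, float(np.nanmean(m2)) if np.isfinite(m2).any() else float("nan"))
        for pcl, m2 in section_maps
    ]
    if metric == "ows":
        return OWSResult(
            ows_map=overall,
            mean_ows=mean_val,
            per_section=per_section,
            section_maps=section_maps,
            degenerate_pixels=degenerate,
        )
    return RIResult(
        epsilon=epsilon,
        ri_map=overall,
        mean_ri=mean_val,
        per_section=per_section,
        section_maps=section_maps,
        degenerate_pixels=degenerate,
    )
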