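"""Comparator metrics: APD80 alternans maps and dominant-frequency maps.

APD80 is measured from the time of maximum upstroke velocity (dF/dt max)
to 80% repolarisation toward baseline; its beat-to-beat absolute difference
(delta-APD80) quantifies alternans magnitude.  Dominant frequency is the
frequency of maximal spectral magnitude of a pixel's Hann-windowed,
zero-padded FFT within a physiological band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .segmentation import AlignedBeatSet, BeatCatalog, WindowSpec, round_half_away, window_beats
from .stackio import ImageStack, Trace, ValidationError

log = logging.getLogger("owsmap")

#: Dominant-frequency defaults: search band (Hz) and bin resolution (Hz).
DF_BAND = (0.5, 50.0)
DF_RESOLUTION = 0.05


@dataclass
class APDMapResult:
    """Per-pixel APD80 and alternans output.

    ``apd80`` is (n_pixels, n_beats) in ms, NaN where excluded;
    ``delta_apd80`` is the per-pair |difference| (n_pixels, n_beats-1);
    ``alternans_map`` averages pairs within each section and then maps
    per-pixel values onto the image grid.
    """

    apd80: np.ndarray
    delta_apd80: np.ndarray
    act_time: np.ndarray
    excluded: np.ndarray                  # boolean image map: any beat excluded
    alternans_map: np.ndarray             # 2-D ms, NaN where excluded/unmasked
    per_section: list                     # [(section_pcl, mean delta_apd80)]
    section_maps: list = field(default_factory=list)


@dataclass
class DFResult:
    df_map: np.ndarray                    # Hz per pixel, NaN outside mask
    freq_resolution: float
    band: tuple
    mean_df: float = float("nan")


# ---------------------------------------------------------------------------
# APD80
# ---------------------------------------------------------------------------

def apd80(
    values: np.ndarray,
    times_ms: np.ndarray,
    baseline: float | None = None,
    next_peak_time: float | None = None,
) -> tuple[float, float]:
    """APD80 of a single beat window.

    Returns ``(apd80_ms, activation_time_ms)``; ``(nan, nan)`` marks an
    excluded beat (no peak, or 80% repolarisation not reached before the next
    depolarisation).

    Activation is the midpoint of the sample pair with the steepest upstroke
    (search from window start to the peak); repolarisation is the first
    post-peak crossing of ``baseline + 0.2 * (peak - baseline)``, located by
    linear interpolation.  ``baseline`` defaults to the pre-upstroke minimum
    of the window.
    """
    v = np.asarray(values, dtype=np.float64)
    t = np.asarray(times_ms, dtype=np.float64)
    if v.size != t.size:
        raise ValidationError("values and times differ in length")
    if v.size < 4:
        return float("nan"), float("nan")
    # first prominent local maximum = this beat's peak (the global argmax can
    # sit on the next beat's upstroke when the segment runs to the next peak)
    prominent = v.min() + 0.5 * (v.max() - v.min())
    ip = 0
    for i in range(1, v.size - 1):
        if v[i] >= v[i - 1] and v[i] >= v[i + 1] and v[i] >= prominent:
            ip = i
            break
    if ip == 0:
        ip = int(np.argmax(v))
    if ip == 0 or ip == v.size - 1:
        return float("nan"), float("nan")        # no interior peak

    dv = np.diff(v[: ip + 1])
    if dv.size == 0 or dv.max() <= 0:
        return float("nan"), float("nan")
    iu = int(np.argmax(dv))
    act = 0.5 * (t[iu] + t[iu + 1])              # midpoint of steepest pair

    if baseline is None:
        baseline = float(v[: iu + 1].min())
    peak = float(v[ip])
    if peak <= baseline:
        return float("nan"), float("nan")
    level = baseline + 0.2 * (peak - baseline)

    repol = None
    for i in range(ip, v.size - 1):
        if v[i] > level >= v[i + 1]:
            frac = (v[i] - level) / (v[i] - v[i + 1])
            repol = t[i] + frac * (t[i + 1] - t[i])
            break
    if repol is None or (next_peak_time is not None and repol >= next_peak_time):
        return float("nan"), float("nan")        # excluded: not repolarised in time
    return float(repol - act), float(act)


def _beat_segments(catalog: BeatCatalog, spec: WindowSpec, n_frames: int, rate: float,
                   time_origin: float):
    """Per-beat analysis segments [peak - pre_ms, next peak) as frame slices."""
    pre, _ = spec.frames(rate)
    segs = []
    peak_frames = [
        round_half_away((pt - time_origin) * rate / 1000.0) for pt in catalog.peak_times
    ]
    for b, pf in enumerate(peak_frames):
        start = pf - pre
        stop = peak_frames[b + 1] if b + 1 < len(peak_frames) else n_frames
        if start < 0 or stop - start < 4:
            segs.append(None)
        else:
            segs.append((start, stop, catalog.peak_times[b + 1] if b + 1 < len(peak_frames) else None))
    return segs


def delta_apd80_map(
    stack: ImageStack,
    catalog: BeatCatalog,
    spec: WindowSpec,
) -> APDMapResult:
    """APD80 alternans over all masked pixels.

    Per pixel and beat, APD80 is measured on the segment from ``pre_ms``
    before the tissue-average peak up to the next peak; per-pair absolute
    differences are averaged within each PCL section.  Any excluded beat
    excludes the pairs it participates in.
    """
    rate = stack.sampling_rate
    times = stack.times_ms()
    segs = _beat_segments(catalog, spec, stack.n_frames, rate, stack.time_origin)
    coords = np.argwhere(stack.mask)
    n_pix, n_beats = coords.shape[0], catalog.n_beats

    apd = np.full((n_pix, n_beats), np.nan)
    act = np.full((n_pix, n_beats), np.nan)
    for b, seg in enumerate(segs):
        if seg is None:
            continue
        start, stop, next_pt = seg
        win = stack.frames[start:stop]
        twin = times[start:stop]
        for p in range(n_pix):
            r, c = coords[p]
            apd[p, b], act[p, b] = apd80(win[:, r, c], twin, next_peak_time=next_pt)

    delta = np.abs(np.diff(apd, axis=1))

    # average pairs within each section, then map
    shape = stack.mask.shape
    section_maps = []
    per_section = []
    bounds = catalog.section_bounds or [(0, n_beats - 1)]
    pcls = catalog.section_pcl or [float("nan")]
    for (a, b), pcl in zip(bounds, pcls):
        pair_cols = np.arange(a, b)           # pair i pairs beats i and i+1
        if pair_cols.size == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_pix = np.nanmean(delta[:, pair_cols], axis=1)
        m2 = np.full(shape, np.nan)
        m2[coords[:, 0], coords[:, 1]] = per_pix
        section_maps.append((pcl, m2))
        finite = per_pix[np.isfinite(per_pix)]
        per_section.append((pcl, float(finite.mean()) if finite.size else float("nan")))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        overall = (
            np.nanmean(np.stack([m for _, m in section_maps]), axis=0)
            if section_maps
            else np.full(shape, np.nan)
        )
    excluded = np.zeros(shape, dtype=bool)
    excl_pix = np.isnan(apd).any(axis=1)
    excluded[coords[:, 0], coords[:, 1]] = excl_pix
    if excl_pix.any():
        log.info("APD80: %d pixel(s) have excluded beats", int(excl_pix.sum()))
    return APDMapResult(
        apd80=apd,
        delta_apd80=delta,
        act_time=act,
        excluded=excluded,
        alternans_map=overall,
        per_section=per_section,
        section_maps=section_maps,
    )


def mean_delta_apd80(
    values: np.ndarray,
    rate: float,
    peak_frames: np.ndarray,
    pre_ms: float = 50.0,
) -> float:
    """Mean |beat-to-beat APD80 difference| of a single trace.

    Convenience for model trains: beats are delimited by the given peak
    frames; NaN pairs (excluded beats) are ignored.
    """
    times = np.arange(values.size) * (1000.0 / rate)
    pre = round_half_away(pre_ms * rate / 1000.0)
    apds = []
    for b, pf in enumerate(peak_frames):
        start = max(pf - pre, 0)
        stop = peak_frames[b + 1] if b + 1 < len(peak_frames) else values.size
        nxt = times[peak_frames[b + 1]] if b + 1 < len(peak_frames) else None
        if stop - start < 4:
            apds.append(float("nan"))
            continue
        a, _ = apd80(values[start:stop], times[start:stop], next_peak_time=nxt)
        apds.append(a)
    apds = np.asarray(apds)
    d = np.abs(np.diff(apds))
    d = d[np.isfinite(d)]
    return float(d.mean()) if d.size else float("nan")


# ---------------------------------------------------------------------------
# dominant frequency
# ---------------------------------------------------------------------------

def _padded_length(n: int, rate: float, resolution: float) -> int:
    nfft = 1
    while rate / nfft > resolution or nfft < n:
        nfft *= 2
    return nfft


def dominant_frequency(
    trace: Trace,
    band: tuple = DF_BAND,
    resolution: float = DF_RESOLUTION,
) -> float:
    """Frequency of maximal spectral magnitude within ``band``.

    The mean is subtracted, a Hann window applied, and the signal zero-padded
    to the smallest power of two giving bins no wider than ``resolution``.
    """
    lo, hi = band
    nyq = trace.sampling_rate / 2.0
    if not (0 < lo < hi):
        raise ValidationError(f"invalid band {band}")
    if hi > nyq:
        raise ValidationError(f"band upper edge {hi} Hz exceeds Nyquist ({nyq} Hz)")
    v = trace.values - trace.values.mean()
    if v.size < 2 * trace.sampling_rate / lo:
        warnings.warn(
            "trace shorter than 2 cycles of the band's low edge; "
            "dominant frequency may be unreliable",
            stacklevel=2,
        )
    w = np.hanning(v.size)
    nfft = _padded_length(v.size, trace.sampling_rate, resolution)
    spec = np.abs(np.fft.rfft(v * w, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / trace.sampling_rate)
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValidationError("no FFT bins inside the requested band")
    return float(freqs[sel][np.argmax(spec[sel])])


def df_map(
    stack: ImageStack,
    time_range_ms: tuple | None = None,
    band: tuple = DF_BAND,
    resolution: float = DF_RESOLUTION,
) -> DFResult:
    """Dominant frequency per masked pixel over an optional time range."""
    times = stack.times_ms()
    if time_range_ms is not None:
        t0, t1 = time_range_ms
        sel = (times >= t0) & (times <= t1)
        if sel.sum() < 4:
            raise ValidationError("time range selects fewer than 4 frames")
        frames = stack.frames[sel]
    else:
        frames = stack.frames
    out = np.full(stack.mask.shape, np.nan)
    coords = np.argwhere(stack.mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r, c in coords:
            out[r, c] = dominant_frequency(
                Trace(values=frames[:, r, c], sampling_rate=stack.sampling_rate),
                band=band,
                resolution=resolution,
            )
    finite = out[np.isfinite(out)]
    return DFResult(
        df_map=out,
        freq_resolution=resolution,
        band=band,
        mean_df=float(finite.mean()) if finite.size else float("nan"),
    )
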