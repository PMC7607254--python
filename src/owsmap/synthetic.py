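"""Synthetic data: modelled AP trains, calibrated noise, and activation movies.

This module generates every input the tests and validation experiments use:

* paced action-potential trains from an ionic backend (Luo–Rudy guinea pig or
  a compact mouse ventricular model, see :mod:`owsmap._ionic`) or from a fast
  parametric template waveform;
* alternans-like temporal irregularity, induced in the ionic backend by
  scaling the repolarising K+ conductances on odd beats only (guinea pig
  x1.7, mouse x0.55) and in the template backend by modulating odd-beat APD;
* additive Gaussian noise whose standard deviation is a stated percentage of
  the AP amplitude, with seeded repeats;
* 2-D plane-wave activation movies with per-pixel noise and recorded ground
  truth, for end-to-end map tests.

Exported voltage trains are min-max rescaled to [0, 1], standing in for
normalised fluorescence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stackio import ImageStack, Trace, ValidationError

#: Defaults for the validation protocol, per species:
#: (pacing CL ms, camera rate Hz, odd-beat K+ conductance scale)
MODEL_DEFAULTS = {
    "guineapig": {"pacing_cl_ms": 400.0, "output_rate": 500.0, "alternans_scale": 1.7},
    "mouse": {"pacing_cl_ms": 150.0, "output_rate": 1000.0, "alternans_scale": 0.55},
}

#: Template waveform parameters per species (ms).
TEMPLATE_SHAPES = {
    "guineapig": {"apd_ms": 250.0, "upstroke_ms": 2.0, "repol_tau_ms": 18.0},
    "mouse": {"apd_ms": 25.0, "upstroke_ms": 1.0, "repol_tau_ms": 6.0},
}


@dataclass
class ModelSpec:
    """Configuration of a simulated AP train.

    ``conductance_scale`` multiplies the repolarising K+ conductances on odd
    beats only (1.0 disables alternans); with the template backend it instead
    divides the odd-beat APD, giving the same direction of effect.
    """

    species: str = "guineapig"
    backend: str = "ionic"                    # "ionic" | "template"
    conductance_scale: float = 1.0
    n_beats_total: int = 1000
    n_beats_analysed: int | None = None   # default: min(20, n_beats_total)
    pacing_cl_ms: float | None = None
    output_rate: float | None = None

    def __post_init__(self) -> None:
        if self.species not in MODEL_DEFAULTS:
            raise ValidationError(f"unknown species {self.species!r}")
        if self.backend not in ("ionic", "template"):
            raise ValidationError(f"unknown backend {self.backend!r}")
        if self.n_beats_analysed is None:
            self.n_beats_analysed = min(20, self.n_beats_total)
        if self.n_beats_analysed > self.n_beats_total:
            raise ValidationError("n_beats_analysed must be <= n_beats_total")
        defaults = MODEL_DEFAULTS[self.species]
        if self.pacing_cl_ms is None:
            self.pacing_cl_ms = defaults["pacing_cl_ms"]
        if self.output_rate is None:
            self.output_rate = defaults["output_rate"]

    @classmethod
    def alternans(cls, species: str, **kw) -> "ModelSpec":
        """Spec with the species' published odd-beat conductance scaling."""
        return cls(
            species=species,
            conductance_scale=MODEL_DEFAULTS[species]["alternans_scale"],
            **kw,
        )


@dataclass
class NoiseSpec:
    """Additive Gaussian noise, SD expressed as % of AP amplitude."""

    level: float
    n_repeats: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValidationError(f"noise level must be >= 0, got {self.level}")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")


# ---------------------------------------------------------------------------
# template waveform backend
# ---------------------------------------------------------------------------

def template_beat(
    t_ms: np.ndarray,
    apd_ms: float,
    upstroke_ms: float,
    repol_tau_ms: float,
    peak_time_ms: float = 0.0,
) -> np.ndarray:
    """Parametric AP waveform: sigmoid upstroke, plateau, sigmoid repolarisation.

    Amplitude 1, resting level 0; ``apd_ms`` is roughly the time from upstroke
    to late repolarisation.
    """
    from scipy.special import expit

    tt = np.asarray(t_ms, dtype=np.float64) - peak_time_ms
    rise = expit(tt / (upstroke_ms / 4.0))
    fall = expit(-(tt - apd_ms) / repol_tau_ms)
    return rise * fall


#: Diastolic lead-in returned before the first analysed beat, so that the
#: first beat's pre-peak window always fits inside the record (ms).
LEAD_IN_MS = 100.0


def _template_train(spec: ModelSpec, lead_ms: float) -> np.ndarray:
    shape = TEMPLATE_SHAPES[spec.species]
    rate = spec.output_rate
    cl = spec.pacing_cl_ms
    n = spec.n_beats_analysed
    # template beats are steady from beat 1; only the analysed tail is built
    first_beat = spec.n_beats_total - n
    n_samples = int(round((lead_ms + cl * n) * rate / 1000.0))
    t = np.arange(n_samples) * (1000.0 / rate) - lead_ms
    v = np.zeros(n_samples)
    stim_offset = 5.0  # ms from beat start to AP foot
    # phantom neighbour beats outside the record keep every analysed beat's
    # neighbourhood identical, so a regular train is exactly periodic
    for b in range(-2, n + 2):
        beat_index = first_beat + b           # 0-based; odd beats are index%2==0
        apd = shape["apd_ms"]
        if (beat_index % 2) == 0 and spec.conductance_scale != 1.0:
            apd = apd / spec.conductance_scale
        v += template_beat(
            t,
            apd_ms=apd,
            upstroke_ms=shape["upstroke_ms"],
            repol_tau_ms=shape["repol_tau_ms"],
            peak_time_ms=b * cl + stim_offset + shape["upstroke_ms"],
        )
    return v


# ---------------------------------------------------------------------------
# simulate_ap_train
# ---------------------------------------------------------------------------

def simulate_ap_train(spec: ModelSpec) -> Trace:
    """Simulate a paced AP train and return the analysed tail.

    The full ``n_beats_total`` beats are integrated (ionic backend) so the
    model reaches steady state; the last ``n_beats_analysed`` beats are
    returned, sampled at ``output_rate`` and min-max rescaled to [0, 1].

    The returned trace's ``meta`` carries the pacing cycle length, per-beat
    odd/even parity labels, and the nominal beat-start sample indices.
    """
    rate = spec.output_rate
    cl = spec.pacing_cl_ms
    lead_ms = min(LEAD_IN_MS, cl)
    if spec.backend == "template":
        v = _template_train(spec, lead_ms)
    else:
        from ._ionic import run_model

        v_full = run_model(
            species=spec.species,
            cl_ms=cl,
            n_beats=spec.n_beats_total,
            k_scale_odd=spec.conductance_scale,
            output_rate=rate,
        )
        start = int(
            round(((spec.n_beats_total - spec.n_beats_analysed) * cl - lead_ms) * rate / 1000.0)
        )
        v = v_full[max(start, 0):]

    vmin, vmax = v.min(), v.max()
    if vmax <= vmin:
        raise ValidationError("simulated train is constant")
    v = (v - vmin) / (vmax - vmin)

    first_beat = spec.n_beats_total - spec.n_beats_analysed
    samples_per_beat = cl * rate / 1000.0
    lead_samples = lead_ms * rate / 1000.0
    beat_starts = np.round(lead_samples + np.arange(spec.n_beats_analysed) * samples_per_beat).astype(int)
    if spec.backend == "ionic":
        _check_capture(v, beat_starts)
    parity = [(first_beat + b) % 2 == 0 for b in range(spec.n_beats_analysed)]
    return Trace(
        values=v,
        sampling_rate=rate,
        label=f"{spec.species}-{spec.backend}",
        meta={
            "pacing_cl_ms": cl,
            "n_beats": spec.n_beats_analysed,
            "beat_start_samples": beat_starts,
            "odd_beat": np.asarray(parity),
            "conductance_scale": spec.conductance_scale,
            "species": spec.species,
        },
    )


def _check_capture(v: np.ndarray, beat_starts: np.ndarray) -> None:
    """Every pacing interval must contain a depolarisation (1:1 capture)."""
    amp = v.max() - v.min()
    for b, s0 in enumerate(beat_starts):
        s1 = beat_starts[b + 1] if b + 1 < len(beat_starts) else v.size
        seg = v[s0:s1]
        if seg.size and (seg.max() - v.min()) < 0.5 * amp:
            raise ValidationError(
                f"loss of 1:1 capture: beat {b + 1} of the analysed train has no "
                "action potential (pacing cycle length too short)"
            )


def beat_peak_samples(trace: Trace) -> np.ndarray:
    """Per-beat peak positions: argmax of the trace inside each pacing interval.

    Works on clean and noisy trains alike; this is the model-train alignment
    rule (each AP aligned by its own peak).
    """
    starts = trace.meta["beat_start_samples"]
    n = trace.values.size
    peaks = []
    for b, s0 in enumerate(starts):
        s1 = starts[b + 1] if b + 1 < len(starts) else n
        peaks.append(s0 + int(np.argmax(trace.values[s0:s1])))
    return np.asarray(peaks, dtype=int)


def stepped_pcl_train(
    pcls_ms=(170.0, 150.0, 130.0, 110.0, 90.0),
    beats_per_level: int = 10,
    species: str = "guineapig",
    rate: float = 500.0,
    alternans_gain: float = 1.0,
    restitution_pcl_ms: float = 170.0,
) -> Trace:
    """Template train whose pacing cycle length steps down in blocks.

    Emulates the dynamic-pacing protocol (PCL reduced every block of beats):
    APD adapts to the cycle length (it never exceeds ~60% of the PCL) and
    rate-dependent alternans appears below ``restitution_pcl_ms`` — the
    odd-beat APD is reduced by ``alternans_gain * (1 - pcl / restitution)``,
    so temporal irregularity grows as pacing accelerates.
    """
    shape = TEMPLATE_SHAPES[species]
    stim_offset = 5.0
    # stimulus times first; each beat's shape follows its PRECEDING interval,
    # the way APD restitution works
    stim_times, intervals = [], []
    t_now = LEAD_IN_MS
    for level, pcl in enumerate(pcls_ms):
        for k in range(beats_per_level):
            stim_times.append(t_now)
            if stim_times[:-1]:
                intervals.append(t_now - stim_times[-2])
            else:
                intervals.append(pcl)
            t_now += pcl
    # phantom beats just outside the record keep the first and last real
    # beats' neighbourhoods identical to their section mates
    stim_times = (
        [stim_times[0] - 2 * pcls_ms[0], stim_times[0] - pcls_ms[0]]
        + stim_times
        + [t_now, t_now + pcls_ms[-1]]
    )
    intervals = [pcls_ms[0], pcls_ms[0]] + intervals + [pcls_ms[-1], pcls_ms[-1]]
    peak_times, apds, taus = [], [], []
    for b, (st, di) in enumerate(zip(stim_times, intervals)):
        base_apd = min(shape["apd_ms"], 0.6 * di)
        alt = alternans_gain * max(0.0, 1.0 - di / restitution_pcl_ms)
        scale = (1.0 - alt) if b % 2 == 0 else 1.0
        peak_times.append(st + stim_offset + shape["upstroke_ms"])
        apds.append(base_apd * scale)
        # strong alternans also collapses the dome into a spike
        taus.append(shape["repol_tau_ms"] * max(scale, 0.2))
    peak_times_real = peak_times[2:-2]
    n_samples = int(round((t_now + LEAD_IN_MS) * rate / 1000.0))
    t = np.arange(n_samples) * (1000.0 / rate)
    v = np.zeros(n_samples)
    for pt, apd, tau in zip(peak_times, apds, taus):
        v += template_beat(t, apd_ms=apd, upstroke_ms=shape["upstroke_ms"],
                           repol_tau_ms=tau, peak_time_ms=pt)
    v = (v - v.min()) / (v.max() - v.min())
    return Trace(
        values=v,
        sampling_rate=rate,
        label="stepped-pcl",
        meta={"pcls_ms": tuple(pcls_ms), "beats_per_level": beats_per_level,
              "peak_times_ms": np.asarray(peak_times_real)},
    )


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def ap_amplitude(trace: Trace) -> float:
    """AP amplitude: maximum minus diastolic baseline (the trace minimum)."""
    amp = float(trace.values.max() - trace.values.min())
    if amp <= 0:
        raise ValidationError("AP amplitude must be > 0")
    return amp


def add_noise(trace: Trace, spec: NoiseSpec) -> list[Trace]:
    """Return ``n_repeats`` independent noisy copies of a clean train.

    Each sample is perturbed by Gaussian noise with SD = level/100 x AP
    amplitude.  Repeat ``k`` uses its own generator seeded from
    ``(spec.seed, k)``, so any repeat is reproducible independently.
    """
    amp = ap_amplitude(trace)
    sd = spec.level / 100.0 * amp
    out = []
    for k in range(spec.n_repeats):
        rng = np.random.default_rng([spec.seed, k])
        noisy = trace.values + rng.normal(0.0, sd, size=trace.values.size) if sd > 0 else trace.values.copy()
        out.append(
            Trace(
                values=noisy,
                sampling_rate=trace.sampling_rate,
                label=f"{trace.label}+noise{spec.level}%r{k}",
                time_origin=trace.time_origin,
                meta=dict(trace.meta),
            )
        )
    return out


def measure_noise(trace: Trace, diastolic_window_ms: tuple) -> float:
    """Noise level (%) the inverse way round: 100 x SD(diastolic segment) / amplitude."""
    t0, t1 = diastolic_window_ms
    times = trace.times_ms()
    sel = (times >= t0) & (times <= t1)
    if sel.sum() < 2:
        raise ValidationError("diastolic window selects fewer than 2 samples")
    seg = trace.values[sel]
    amp = float(trace.values.max() - seg.mean())
    if amp <= 0:
        raise ValidationError("no OAP amplitude above the diastolic window")
    return 100.0 * float(seg.std(ddof=1)) / amp


# ---------------------------------------------------------------------------
# 2-D activation movies
# ---------------------------------------------------------------------------

def make_movie(
    rows: int,
    cols: int,
    train: Trace,
    conduction_velocity: float,
    region_map: np.ndarray | None = None,
    region_trains: dict | None = None,
    noise: NoiseSpec | None = None,
) -> tuple[ImageStack, dict]:
    """Plane-wave activation movie: pixel (r, c) plays its region's train
    delayed by column-distance / velocity (pixels per ms).

    ``region_map`` (int labels) assigns pixels to the trains in
    ``region_trains``; label 0 / missing labels fall back to ``train``.
    Per-pixel independent Gaussian noise is added when ``noise`` is given.
    Returns the stack and a ground-truth dict (delays, labels, trains).
    """
    if rows < 2 or cols < 2:
        raise ValidationError("movie must be at least 2x2 pixels")
    if not conduction_velocity > 0:
        raise ValidationError("conduction velocity must be > 0")
    rate = train.sampling_rate
    if region_map is None:
        region_map = np.zeros((rows, cols), dtype=int)
    else:
        region_map = np.asarray(region_map, dtype=int)
        if region_map.shape != (rows, cols):
            raise ValidationError("region_map shape must match (rows, cols)")
    region_trains = dict(region_trains or {})
    region_trains.setdefault(0, train)

    delays_ms = np.tile(np.arange(cols) / conduction_velocity, (rows, 1))
    n = train.values.size
    frames = np.empty((n, rows, cols))
    for r in range(rows):
        for c in range(cols):
            src = region_trains.get(int(region_map[r, c]), train)
            if src.sampling_rate != rate or src.values.size != n:
                raise ValidationError("all region trains must share rate and length")
            shift = int(round(delays_ms[r, c] * rate / 1000.0))
            shifted = np.empty(n)
            shifted[shift:] = src.values[: n - shift] if shift else src.values
            shifted[:shift] = src.values[0]
            frames[:, r, c] = shifted

    if noise is not None and noise.level > 0:
        amp = ap_amplitude(train)
        rng = np.random.default_rng([noise.seed, rows, cols])
        frames = frames + rng.normal(0.0, noise.level / 100.0 * amp, size=frames.shape)

    truth = {
        "delay_ms": delays_ms,
        "region_map": region_map,
        "region_trains": region_trains,
    }
    return ImageStack(frames=frames, sampling_rate=rate), truth


# ---------------------------------------------------------------------------
# model-train analysis protocol
# ---------------------------------------------------------------------------

def analyse_train(
    trace: Trace,
    window_pre_ms: float | None = None,
    window_post_ms: float | None = None,
) -> dict:
    """OWS, single-beat OWS and mean delta-APD80 of one (possibly noisy) train.

    Each beat is aligned by its own peak (argmax within its pacing interval)
    and windowed with the species' fixed window — the windows sit well inside
    the pacing cycle, so no minima trimming is needed for model trains.
    """
    from .altmetrics import mean_delta_apd80
    from .preprocess import SPECIES_PRESETS
    from .segmentation import round_half_away
    from .similarity import ows as ows_fn
    from .similarity import single_beat_ows

    species = trace.meta.get("species", "guineapig")
    preset = SPECIES_PRESETS[species]
    pre_ms = preset["window_pre_ms"] if window_pre_ms is None else window_pre_ms
    post_ms = preset["window_post_ms"] if window_post_ms is None else window_post_ms
    rate = trace.sampling_rate
    pre = round_half_away(pre_ms * rate / 1000.0)
    post = round_half_away(post_ms * rate / 1000.0)

    peaks = beat_peak_samples(trace)
    windows = []
    for p in peaks:
        if p - pre >= 0 and p + post < trace.values.size:
            windows.append(trace.values[p - pre : p + post + 1])
    if len(windows) < 2:
        raise ValidationError("fewer than 2 complete beat windows in the train")
    beats = np.asarray(windows)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            "ows": ows_fn(beats),
            "single_beat_ows": single_beat_ows(beats),
            "delta_apd80_ms": mean_delta_apd80(trace.values, rate, peaks, pre_ms=pre_ms),
            "n_beats": beats.shape[0],
            "peaks": peaks,
        }
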