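# Methods

## Wave similarity and regularity index

The package treats each beat at each pixel as a vector: the fluorescence
samples in a fixed window around the beat's alignment peak. A windowed OAP
`A` is zero-corrected (mean removed) and scaled to unit L2 norm, so two OAPs
compare by cosine similarity `s = An1 · An2`. The normalisation makes both
metrics exactly invariant to per-beat affine transforms `A → αA + β` (α > 0):
amplitude alternans is therefore invisible by design — only *shape* changes
register. For M beats, OWS is the mean similarity over all M(M−1)/2 unordered
pairs; RI is the fraction of pairs whose wave distance `d = arccos(s)` is at
or below a threshold ε (boundary pairs count as similar). Single-beat OWS is
the series `s(beat i, beat i+1)`, i = 1 … M−1, and is the only quantity
computed across pacing-section boundaries (those transitions are flagged in
the output); OWS and RI proper never pair beats across a PCL change.

Assumptions: beats are aligned on the *tissue-average* peak times, so the
method measures morphology change at fixed activation phase, not conduction
changes; signals are depolarisation-up (readers expose an `invert` flag);
a constant (zero-variance) window carries no morphology and is assigned
similarity 0 rather than raising, so low-amplitude fibrillating pixels
degrade gracefully to NaN/low map values.

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| spatial_kernel | 3 | px | small Gaussian smooth, preserves local morphology |
| spatial_sigma | 1.0 | px | unstated in the protocol; common optical-mapping practice, configurable |
| tophat_ms | 200 (guinea pig), 100 (mouse) | ms | flat structuring element longer than one AP, shorter than drift |
| mask_fraction | 0.5 | — | pixel kept if time-average ≥ 50% of brightest; rule unstated, configurable; manual masks accepted |
| amp_fraction | 0.5 | — | peak threshold: half of maximum tissue signal |
| min_distance_ms | 40 | ms | minimum peak separation, both species |
| pcl_change_ms | 10 | ms | PCL step that starts a new section |
| window (pre/post) | 50/150 (guinea pig), 20/40 (mouse) | ms | species window presets; guinea pig additionally trims pairs at closest minima |
| epsilon | π/6 | rad | the RI threshold at which RI and OWS track each other best; sweeps show π/3 collapses dynamic range and π/18 loses discrimination |
| df_band, df_resolution | 0.5–50 Hz, 0.05 Hz | Hz | dominant-frequency search band and zero-padded bin width |

Top-hat baseline correction is the white top-hat (signal minus its grey-scale
opening) with a flat element of the stated length, rounded to the nearest odd
sample count; it pins the diastolic level near zero and is idempotent on
pulse-on-flat signals. The Gaussian spatial filter renormalises its kernel
over the in-mask, in-image support so masked-out pixels never dilute tissue
values. No temporal filtering exists anywhere in the pipeline.

Windowing conventions: ms→frame conversion rounds half away from zero;
windows include both endpoints (a 50/150 ms window at 500 Hz is 101 samples);
beats whose windows overrun the record are dropped and logged, never
truncated or padded. With minima trimming on, the shared window of each OAP
*pair* runs from the closest pre-peak local minimum of either OAP to the
closest post-peak local minimum of either OAP, searched inside the untrimmed
window; a monotone side falls back to the window edge, plateaus resolve to
the sample nearest the peak, and a degenerate (<3 sample) result falls back
to peak ± 1 sample. During fibrillation the automatic PCL segmentation is
bypassed: the caller supplies an explicit time range and detection runs
inside it with unchanged parameters, yielding one section.

## APD80 and dominant frequency

APD80 runs from the maximum upstroke velocity (steepest first difference
between window start and the beat peak, assigned to the midpoint of its
sample pair) to the first post-peak crossing of `baseline + 0.2 · (peak −
baseline)`, located by linear interpolation — sub-sample precision matters at
0.5 kHz (2 ms quantisation). Baseline is the pre-upstroke window minimum
(≈ 0 after top-hat correction). The beat's peak is the first prominent local
maximum of its segment, not the global argmax, because analysis segments run
to the next beat's peak. A beat that has not reached 80% repolarisation
before the next depolarisation is excluded (NaN, never 0), and exclusion
propagates to both pairs it would join. ΔAPD80 is the absolute difference of
consecutive APD80s, averaged over pairs within a section and then over pixels.

Dominant frequency: mean subtraction, Hann window, zero-padding to the
smallest power of two giving bins ≤ 0.05 Hz, argmax of spectral magnitude
inside 0.5–50 Hz.

## Ionic model backends

Integration (both models): Rush–Larsen updates for all gating variables,
forward Euler for voltage and calcium, fixed 5 µs step, voltage recorded at
the camera rate. 1000 beats are paced so the models reach their periodic
steady state; the last 20 are analysed. Simulated trains are min–max rescaled
to [0, 1] before export, standing in for normalised fluorescence. Temporal
irregularity is induced by scaling the repolarising K⁺ conductances on odd
beats (1-indexed) only: ×1.7 for the guinea pig (IK, IK1), ×0.55 for the
mouse (Ito, IKss, IKs, IK1, IKur). Loss of 1:1 capture raises an error naming
the first failed beat. Pacing cycle lengths (unstated in the validation
protocol) default to 400 ms (guinea pig) and 150 ms (mouse).

*Guinea pig* — the Luo–Rudy 1991 ventricular formulation (INa, slow inward,
IK, IK1, plateau K, background). Our implementation reproduces its published
hallmarks (resting potential −84.4 mV, peak ≈ +43 mV, dV/dt_max ≈ 355 V/s,
APD90 ≈ 362 ms at CL 1000 ms). At CL 400 ms the odd-beat scaling yields
steady APD80 alternation of roughly 130/334 ms.

*Mouse* — a compact Hodgkin–Huxley-style ventricular model written for this
package. It carries the murine repolarising currents the protocol scales —
Ito,f (dominant early repolariser), IKur, IKss, IKs and an inward-rectifier
IK1 — plus a fast INa, an L-type Ca²⁺ current and a background Na⁺ leak.
Steady-state activation/inactivation curves follow standard murine
formulations; Ito,f inactivation is calibrated to the consensus fast
transient-outward time constant (~26 ms at +30 mV, fast recovery at rest).
The model is calibrated to physiological murine AP morphology only (resting
potential ≈ −86 mV, peak ≈ +30 mV, brief triangular AP, APD80 ≈ 13 ms at
CL 150 ms); it is *not* a re-derivation of a full Markov-chain mouse model,
and its alternans morphology contrast under the ×0.55 scaling is weaker than
full formulations exhibit (see Limitations).

*Template backend* — a parametric waveform (sigmoid upstroke × sigmoid/
exponential repolarisation, species presets) for fast deterministic tests.
`conductance_scale` divides the odd-beat APD, mirroring the ionic
conventions' direction of effect (K⁺ up ⇒ shorter odd beats, K⁺ down ⇒
longer). Phantom neighbour beats outside the record keep every analysed
beat's neighbourhood identical, so a regular template train is exactly
periodic and scores OWS = 1 to float precision.

## Model-train analysis protocol

Model trains are analysed with fixed peak-referenced windows and no minima
trimming: at the default cycle lengths the windows sit well inside the
pacing cycle, so the diastolic-interval encroachment that motivates trimming
in fast-paced recordings does not arise. Each beat is aligned by its own
peak — the argmax of the analysed trace inside its known pacing interval.
For noisy trains the argmax is taken on the *noisy* trace: the alignment jitter
this produces is part of what noise does to the analysis and is the dominant
mechanism by which OWS degrades on plateau-shaped (guinea-pig-like) APs.

Noise is additive i.i.d. Gaussian, SD expressed as a percentage of the AP
amplitude (max − diastolic minimum); each of the 15 repeats uses its own
generator seeded from (base seed, repeat index), so any repeat is
reproducible in isolation. `measure_noise` inverts the definition —
100 × SD(diastolic segment) / amplitude — and round-trips the injected level
within ~1 percentage point on trains of a few thousand samples.

## Synthetic movies and stepped-PCL trains

`make_movie` builds plane-wave activation: pixel (r, c) replays its region's
train delayed by column distance / conduction velocity, with optional
per-pixel Gaussian noise; region labels, delays and source trains are
returned as ground truth. `stepped_pcl_train` emulates a dynamic-pacing
protocol: blocks of beats at decreasing PCL, each beat's APD following its
*preceding* interval (restitution-style, never exceeding 60% of it), with
alternans appearing below a restitution threshold (default 170 ms) and
growing as PCL shortens — odd beats shorten and their dome collapses toward a
spike. Phantom beats outside the record keep edge beats' neighbourhoods
complete. These generators emulate morphology dynamics only: they contain no
motion artefact, photobleaching, spatially correlated noise, conduction-
velocity heterogeneity, wave curvature or calcium signal, so passing map
tests demonstrates correctness of the analysis, not robustness to every
failure mode of real recordings.

## Numerical choices

Cosine similarities are clamped to [−1, 1] before arccos, and values within
1e−12 of ±1 are snapped to exactly ±1 so identical beats get wave distance
exactly 0 (arccos is infinitely steep at 1, so bit-level rounding would
otherwise produce spurious ~1e−8 rad distances and break RI at ε = 0).
RI threshold sweeps reuse one cached distance matrix per pixel and are
non-decreasing in ε by construction. Peak detection uses height ≥
amp_fraction × max and a greedy minimum-distance rule that keeps the higher
of two close candidates. PCL segmentation compares each beat's PCL to the
running median of the current section and finalises section PCL as the median
over its beats. Sections are data-driven; the protocol block sizes (10 beats
guinea pig, 20 mouse) are not enforced.

## Limitations

* The compact mouse model underestimates the morphology contrast induced by
  the ×0.55 K⁺ scaling relative to full Markov-chain murine formulations:
  its scaled beats lengthen (APD80 ≈ 13 → 30 ms) but do not develop a
  sustained plateau, which bounds how far alternans can depress OWS.
* With the Luo–Rudy guinea-pig model, the ×1.7 IK/IK1 scaling produces large
  APD alternans (ΔAPD80 ≈ 200 ms at CL 400 ms) yet both beat types remain
  plateau-dominated inside the 50/150 ms window, keeping clean-train OWS
  near 0.9; pacing-CL and window-length sweeps (250–1000 ms, 150–345 ms)
  do not change this qualitatively.
* Per-pixel activation-time alignment and arrhythmia-specific active-time
  detection are out of scope; during VF the tissue-average peak times are a
  known weak point of the alignment strategy.
* OWS deliberately ignores amplitude alternans (affine invariance) and does
  not localise *where* in the waveform a difference occurs.
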