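"""Ionic action-potential model backends (numba-compiled).

Two paced single-cell ventricular models are provided:

* guinea pig — the Luo–Rudy 1991 formulation (INa, Isi, IK, IK1, IKp, Ib),
  whose repolarising potassium currents IK and IK1 can be scaled per beat to
  induce alternans-like behaviour;
* mouse — a compact Hodgkin–Huxley-style formulation carrying the murine
  repolarising currents Ito,f, IKur, IKss, IKs and IK1 (plus INa, ICaL and a
  background leak), calibrated to physiological murine AP morphology
  (resting potential about -85 mV, brief triangular AP).

Both integrators use Rush–Larsen updates for gating variables and forward
Euler for voltage/calcium at a 5 microsecond step, with membrane voltage
recorded at the requested camera rate.  Beat-parity conductance scaling is
applied to the listed K+ currents on odd beats (1-indexed) only.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Luo-Rudy 1991 guinea-pig ventricular model
# ---------------------------------------------------------------------------

_RTF = 26.71  # RT/F at 310 K, mV

_LR_ENA = _RTF * math.log(140.0 / 18.0)
_LR_EK = _RTF * math.log((5.4 + 0.01833 * 140.0) / (145.0 + 0.01833 * 18.0))
_LR_EK1 = _RTF * math.log(5.4 / 145.0)


@njit(cache=True, fastmath=True)
def _lr91_run(cl_ms, n_beats, dt, k_scale_odd, stim_amp, stim_ms, out_every, out):
    """Pace LR91 for n_beats at cl_ms; record V every out_every steps."""
    v = -84.5
    m, h, j = 0.0017, 0.983, 0.995
    d, f, x = 0.003, 1.0, 0.0057
    cai = 2.0e-4

    ena, ek, ek1 = _LR_ENA, _LR_EK, _LR_EK1
    gk_base = 0.282
    gk1_base = 0.6047

    n_steps = int(round(cl_ms * n_beats / dt))
    stim_steps = int(round(stim_ms / dt))
    steps_per_beat = int(round(cl_ms / dt))
    i_out = 0
    for step in range(n_steps):
        beat = step // steps_per_beat
        in_beat = step - beat * steps_per_beat
        scale = k_scale_odd if (beat % 2) == 0 else 1.0
        istim = stim_amp if in_beat < stim_steps else 0.0

        # gate rates
        am = 0.32 * (v + 47.13) / (1.0 - math.exp(-0.1 * (v + 47.13)))
        bm = 0.08 * math.exp(-v / 11.0)
        if v < -40.0:
            ah = 0.135 * math.exp((80.0 + v) / -6.8)
            bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
            aj = (
                (-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
                * (v + 37.78)
                / (1.0 + math.exp(0.311 * (v + 79.23)))
            )
            bj = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
        else:
            ah = 0.0
            bh = 1.0 / (0.13 * (1.0 + math.exp((v + 10.66) / -11.1)))
            aj = 0.0
            bj = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
        ad = 0.095 * math.exp(-0.01 * (v - 5.0)) / (1.0 + math.exp(-0.072 * (v - 5.0)))
        bd = 0.07 * math.exp(-0.017 * (v + 44.0)) / (1.0 + math.exp(0.05 * (v + 44.0)))
        af = 0.012 * math.exp(-0.008 * (v + 28.0)) / (1.0 + math.exp(0.15 * (v + 28.0)))
        bf = 0.0065 * math.exp(-0.02 * (v + 30.0)) / (1.0 + math.exp(-0.2 * (v + 30.0)))
        ax = 0.0005 * math.exp(0.083 * (v + 50.0)) / (1.0 + math.exp(0.057 * (v + 50.0)))
        bx = 0.0013 * math.exp(-0.06 * (v + 20.0)) / (1.0 + math.exp(-0.04 * (v + 20.0)))

        # currents
        ina = 23.0 * m * m * m * h * j * (v - ena)
        esi = 7.7 - 13.0287 * math.log(cai)
        isi = 0.09 * d * f * (v - esi)
        if v > -100.0:
            if abs(v + 77.0) < 1e-6:
                xi = 2.837 * 0.04 / math.exp(0.04 * (v + 35.0))
            else:
                xi = (
                    2.837
                    * (math.exp(0.04 * (v + 77.0)) - 1.0)
                    / ((v + 77.0) * math.exp(0.04 * (v + 35.0)))
                )
        else:
            xi = 1.0
        ik = scale * gk_base * xi * x * (v - ek)
        ak1 = 1.02 / (1.0 + math.exp(0.2385 * (v - ek1 - 59.215)))
        bk1 = (
            0.49124 * math.exp(0.08032 * (v - ek1 + 5.476))
            + math.exp(0.06175 * (v - ek1 - 594.31))
        ) / (1.0 + math.exp(-0.5143 * (v - ek1 + 4.753)))
        k1inf = ak1 / (ak1 + bk1)
        ik1 = scale * gk1_base * k1inf * (v - ek1)
        kp = 1.0 / (1.0 + math.exp((7.488 - v) / 5.98))
        ikp = 0.0183 * kp * (v - ek1)
        ib = 0.03921 * (v + 59.87)

        dv = -(ina + isi + ik + ik1 + ikp + ib + istim)
        v += dt * dv
        cai += dt * (-1.0e-4 * isi + 0.07 * (1.0e-4 - cai))
        if cai < 1e-8:
            cai = 1e-8

        # Rush-Larsen gate updates
        m = am / (am + bm) + (m - am / (am + bm)) * math.exp(-dt * (am + bm))
        h = ah / (ah + bh) + (h - ah / (ah + bh)) * math.exp(-dt * (ah + bh))
        j = aj / (aj + bj) + (j - aj / (aj + bj)) * math.exp(-dt * (aj + bj))
        d = ad / (ad + bd) + (d - ad / (ad + bd)) * math.exp(-dt * (ad + bd))
        f = af / (af + bf) + (f - af / (af + bf)) * math.exp(-dt * (af + bf))
        x = ax / (ax + bx) + (x - ax / (ax + bx)) * math.exp(-dt * (ax + bx))

        if step % out_every == 0:
            if i_out < out.size:
                out[i_out] = v
            i_out += 1
    return i_out


# ---------------------------------------------------------------------------
# compact mouse ventricular model
# ---------------------------------------------------------------------------

_MS_ENA = 61.0
_MS_EK = _RTF * math.log(5.4 / 143.7)
_MS_ECA = 63.0


@njit(cache=True, fastmath=True)
def _mouse_run(cl_ms, n_beats, dt, k_scale_odd, stim_amp, stim_ms, out_every, out,
               g_tof, g_kur, g_kss, g_ks, g_k1):
    """Pace the compact mouse model; record V every out_every steps."""
    v = -85.0
    m, h, j = 0.0017, 0.983, 0.995
    d, f = 0.0, 1.0
    ato, ito = 0.0, 1.0
    aur, iur = 0.0, 1.0
    ass = 0.0
    nks = 0.0

    ena, ek, eca = _MS_ENA, _MS_EK, _MS_ECA

    n_steps = int(round(cl_ms * n_beats / dt))
    stim_steps = int(round(stim_ms / dt))
    steps_per_beat = int(round(cl_ms / dt))
    i_out = 0
    for step in range(n_steps):
        beat = step // steps_per_beat
        in_beat = step - beat * steps_per_beat
        scale = k_scale_odd if (beat % 2) == 0 else 1.0
        istim = stim_amp if in_beat < stim_steps else 0.0

        # INa gates (LR-style kinetics, fast enough for murine upstroke)
        am = 0.32 * (v + 47.13) / (1.0 - math.exp(-0.1 * (v + 47.13)))
        bm = 0.08 * math.exp(-v / 11.0)
        if v < -40.0:
            ah = 0.135 * math.exp((80.0 + v) / -6.8)
            bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
            aj = (
                (-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
                * (v + 37.78)
                / (1.0 + math.exp(0.311 * (v + 79.23)))
            )
            bj = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
        else:
            ah = 0.0
            bh = 1.0 / (0.13 * (1.0 + math.exp((v + 10.66) / -11.1)))
            aj = 0.0
            bj = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))

        # ICaL gates
        dinf = 1.0 / (1.0 + math.exp(-(v + 11.1) / 7.2))
        taud = 0.6 + 1.2 * math.exp(-((v + 15.0) / 25.0) ** 2)
        finf = 1.0 / (1.0 + math.exp((v + 25.5) / 5.7))
        tauf = 8.0 + 15.0 * math.exp(-((v + 35.0) / 25.0) ** 2)

        # Ito,f gates
        aa = 0.18064 * math.exp(0.03577 * (v + 30.0))
        ba = 0.3956 * math.exp(-0.06237 * (v + 30.0))
        ai = (0.000152 * math.exp(-(v + 13.5) / 7.0)) / (
            0.067083 * math.exp(-(v + 33.5) / 7.0) + 1.0
        )
        # inactivation tuned to the murine fast transient outward current:
        # tau ~= 26 ms at +30 mV and for recovery at rest
        bi = (0.002 * math.exp((v + 33.5) / 7.0)) / (
            0.051335 * math.exp((v + 33.5) / 7.0) + 1.0
        )

        # IKur / IKss gates
        aurinf = 1.0 / (1.0 + math.exp(-(v + 22.5) / 7.7))
        tauaur = 0.493 * math.exp(-0.0629 * v) + 2.058
        iurinf = 1.0 / (1.0 + math.exp((v + 45.2) / 5.7))
        tauiur = 1200.0
        tauass = 39.3 * math.exp(-0.0862 * v) + 13.17

        # IKs gate (small, slow)
        nksinf = 1.0 / (1.0 + math.exp(-(v + 26.5) / 7.8))
        taunks = 750.0

        # currents
        ina = 13.0 * m * m * m * h * j * (v - ena)
        ical = 0.17 * d * f * (v - eca)
        itof = scale * g_tof * ato * ato * ato * ito * (v - ek)
        ikur = scale * g_kur * aur * iur * (v - ek)
        ikss = scale * g_kss * ass * (v - ek)
        iks = scale * g_ks * nks * nks * (v - ek)
        ik1 = scale * g_k1 * (v - ek) / (1.0 + math.exp(0.0896 * (v - ek)))
        inab = 0.0026 * (v - ena)

        dv = -(ina + ical + itof + ikur + ikss + iks + ik1 + inab + istim)
        v += dt * dv

        m = am / (am + bm) + (m - am / (am + bm)) * math.exp(-dt * (am + bm))
        h = ah / (ah + bh) + (h - ah / (ah + bh)) * math.exp(-dt * (ah + bh))
        j = aj / (aj + bj) + (j - aj / (aj + bj)) * math.exp(-dt * (aj + bj))
        d = dinf + (d - dinf) * math.exp(-dt / taud)
        f = finf + (f - finf) * math.exp(-dt / tauf)
        ato = aa / (aa + ba) + (ato - aa / (aa + ba)) * math.exp(-dt * (aa + ba))
        ito = ai / (ai + bi) + (ito - ai / (ai + bi)) * math.exp(-dt * (ai + bi))
        aur = aurinf + (aur - aurinf) * math.exp(-dt / tauaur)
        iur = iurinf + (iur - iurinf) * math.exp(-dt / tauiur)
        ass = aurinf + (ass - aurinf) * math.exp(-dt / tauass)
        nks = nksinf + (nks - nksinf) * math.exp(-dt / taunks)

        if step % out_every == 0:
            if i_out < out.size:
                out[i_out] = v
            i_out += 1
    return i_out


def run_model(
    species: str,
    cl_ms: float,
    n_beats: int,
    k_scale_odd: float,
    output_rate: float,
    dt: float = 0.005,
    stim_amp: float = -80.0,
    stim_ms: float = 0.5,
    mouse_conductances: tuple = (0.4067, 0.16, 0.05, 0.00575, 0.27),
) -> np.ndarray:
    """Pace a model and return membrane voltage sampled at ``output_rate``.

    ``k_scale_odd`` multiplies the species' repolarising K+ conductances on
    odd beats (1-indexed); 1.0 disables alternans induction.
    """
    out_every = int(round((1000.0 / output_rate) / dt))
    if out_every < 1:
        raise ValueError(
            f"output_rate {output_rate} Hz exceeds the solver rate ({1000.0 / dt:.0f} Hz)"
        )
    n_steps = int(round(cl_ms * n_beats / dt))
    n_out = (n_steps + out_every - 1) // out_every
    out = np.empty(n_out, dtype=np.float64)
    if species == "guineapig":
        n = _lr91_run(cl_ms, n_beats, dt, k_scale_odd, stim_amp, stim_ms, out_every, out)
    elif species == "mouse":
        g_tof, g_kur, g_kss, g_ks, g_k1 = mouse_conductances
        n = _mouse_run(
            cl_ms, n_beats, dt, k_scale_odd, stim_amp, stim_ms, out_every, out,
            g_tof, g_kur, g_kss, g_ks, g_k1,
        )
    else:
        raise ValueError(f"unknown species {species!r}")
    return out[:n]
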