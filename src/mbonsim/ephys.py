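"""Patch-clamp trace analysis: passive properties and spike metrics.

Implements the four recording protocols used to characterize the neuron:

1. voltage-clamp 5 mV / 100 ms step without series-resistance compensation
   → series, input and membrane resistance from the capacitive transient and
   the steady-state current;
2. current-clamp de-/hyperpolarizing steps at 50 kHz → membrane time
   constant from the −10 pA sweep, maximal deflection and action-potential
   amplitudes from fixed sample-count windows;
3. 60 s zero-current recording → resting potential and spontaneous rate;
4. −10 pA / 200 ms steps at 20 kHz → averaged, baseline-normalized traces
   for model fitting.

Window sizes stated in samples (70 / 500 / 400 / 700) are interpreted at the
recording's native sampling rate, as the protocols specify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .cable import TraceSet

__all__ = [
    "CellProperties",
    "SpikeStats",
    "CohortSummary",
    "AnalysisError",
    "resistance_from_voltage_step",
    "time_constant",
    "whole_cell_capacitance",
    "specific_capacitance",
    "spike_metrics",
    "normalize_trace",
    "cohort_stats",
]


class AnalysisError(RuntimeError):
    pass


@dataclass
class CellProperties:
    """Per-cell passive properties (units as recorded in cohort tables)."""

    Vm_rest: float = np.nan        # mV
    tau_m: float = np.nan          # ms
    Rm: float = np.nan             # MΩ
    Cm: float = np.nan             # pF
    Cspec: float = np.nan          # μF/cm²
    firing_rate_spont: float = np.nan  # Hz


@dataclass
class SpikeStats:
    count: int
    frequency: float          # Hz over the analysis window
    absolute_peak: float      # mV
    relative_amplitude: float  # mV
    max_deflection: float     # mV


@dataclass
class CohortSummary:
    n: int
    mean: float
    sd: float
    sem: float


def _series(trace, site=None):
    """Accept a TraceSet (optionally a site) or a (time, values) pair."""
    if isinstance(trace, TraceSet):
        return trace.time, trace[site or trace.sites[0]]
    t, v = trace
    return np.asarray(t, float), np.asarray(v, float)


# ---------------------------------------------------------------------------
# Protocol 1: resistances from an uncompensated voltage step
# ---------------------------------------------------------------------------

def resistance_from_voltage_step(current_trace, dv: float, step=None, site=None):
    """Series, input and membrane resistance from a voltage-step current trace.

    Parameters
    ----------
    current_trace : TraceSet or (time_ms, current_nA)
        The recorded current response to an uncompensated voltage step.
    dv : float
        Step amplitude, mV.
    step : (t_on, t_off) or None
        Step window in ms; detected from the largest current jump if None.

    Returns
    -------
    (Rseries, Rinput, Rm) in MΩ: Rseries = dV / peak transient current,
    Rinput = dV / steady-state current, Rm = |Rinput − Rseries| (the series
    and membrane resistances add up to the input resistance in the
    uncompensated voltage-clamp circuit).
    """
    t, i = _series(current_trace, site)
    if step is None:
        jump = np.abs(np.diff(i))
        on = int(np.argmax(jump)) + 1
        t_on, t_off = t[on], t[-1]
    else:
        t_on, t_off = step
    pre = i[t < t_on]
    i_base = float(pre.mean()) if pre.size else 0.0
    inwin = (t >= t_on) & (t <= t_off)
    if not inwin.any():
        raise AnalysisError("step window outside the trace")
    seg = i[inwin]
    i_peak = seg[np.argmax(np.abs(seg - i_base))]
    if i_peak == i_base:
        raise AnalysisError("no detectable transient in the current trace")
    tail = seg[int(0.75 * seg.size):]
    i_ss = float(tail.mean())
    r_series = abs(dv / (i_peak - i_base))
    if i_ss == i_base:
        raise AnalysisError("no steady-state current step")
    r_input = abs(dv / (i_ss - i_base))
    return r_series, r_input, abs(r_input - r_series)


# ---------------------------------------------------------------------------
# Protocol 2: time constant, deflections, spikes
# ---------------------------------------------------------------------------

def time_constant(trace, step_onset: float, t_end: float | None = None,
                  site=None) -> float:
    """Membrane time constant from a hyperpolarizing step response, ms.

    Fits V(t) = V∞ + (V₀ − V∞)·exp(−(t − onset)/τ) to the deflection after
    ``step_onset`` (up to ``t_end`` if given, else the trace end).
    """
    t, v = _series(trace, site)
    mask = t >= step_onset
    if t_end is not None:
        mask &= t <= t_end
    ts, vs = t[mask] - step_onset, v[mask]
    if ts.size < 4:
        raise AnalysisError("too few samples after step onset")
    v0, vinf = vs[0], float(vs[int(0.9 * vs.size):].mean())
    if v0 == vinf:
        raise AnalysisError("no deflection to fit")
    # initial τ from the 1/e crossing
    target = vinf + (v0 - vinf) / np.e
    crossed = np.nonzero((vs - target) * np.sign(v0 - vinf) < 0)[0]
    tau0 = ts[crossed[0]] if crossed.size else ts[-1] / 3.0

    def model(tt, vi, dv, tau):
        return vi + dv * np.exp(-tt / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, ts, vs, p0=(vinf, v0 - vinf, max(tau0, ts[1])),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - curve_fit failure
        raise AnalysisError(f"exponential fit failed: {exc}") from exc
    tau = float(abs(popt[2]))
    return tau


def whole_cell_capacitance(tau: float, rm: float) -> float:
    """Cm = τm / Rm, returned in pF (τ in ms, Rm in MΩ)."""
    if tau <= 0 or rm <= 0:
        raise ValueError("tau and Rm must be positive")
    return tau / rm * 1e3


def specific_capacitance(cm_pf: float, area_um2: float) -> float:
    """Specific capacitance Cm/area in μF/cm² (Cm in pF, area in μm²)."""
    if cm_pf <= 0 or area_um2 <= 0:
        raise ValueError("Cm and area must be positive")
    return cm_pf / area_um2 * 100.0


def spike_metrics(trace, stim_window, site=None,
                  threshold_mv: float = 1.0, refractory_ms: float = 2.0,
                  sharpness_ms: float = 1.5) -> SpikeStats:
    """Deflection and action-potential metrics of one stimulation sweep.

    Fixed sample-count conventions (at the native sampling rate):
    the maximal deflection is the mean of the last 70 samples inside the
    stimulation window minus the resting level (mean of the first 500
    samples); the absolute peak is the trace maximum; the relative amplitude
    subtracts a 400-sample baseline starting 700 samples before the peak.

    Spikes are local maxima of prominence ≥ ``threshold_mv`` separated by
    ``refractory_ms`` that both rise *and* fall by ≥ ``threshold_mv`` within
    ``sharpness_ms``: an action potential collapses as fast as it rises,
    whereas passive deflections decay with the ~16 ms membrane time constant
    and are therefore not counted.
    """
    t, v = _series(trace, site)
    t_on, t_off = stim_window
    if t_off > t[-1] or t_on < t[0]:
        raise ValueError("stimulation window exceeds the trace")
    dt = t[1] - t[0]

    pre = v[t < t_on]
    rest = float(pre[:500].mean()) if pre.size else float(v[0])
    sweep = v[(t >= t_on) & (t <= t_off)]
    max_deflection = float(sweep[-70:].mean() - rest)

    ipk = int(np.argmax(v))
    absolute_peak = float(v[ipk])
    b0 = max(ipk - 700, 0)
    base_win = v[b0:b0 + 400]
    relative_amplitude = float(absolute_peak - base_win.mean())

    cand, _ = signal.find_peaks(
        v, prominence=threshold_mv,
        distance=max(1, int(round(refractory_ms / dt))),
    )
    cand = cand[(t[cand] >= t_on) & (t[cand] <= t_off)]
    w = max(1, int(round(sharpness_ms / dt)))
    count = 0
    for pk in cand:
        rise = v[pk] - v[max(pk - w, 0):pk + 1].min()
        fall = v[pk] - v[pk:pk + w + 1].min()
        if min(rise, fall) >= threshold_mv:
            count += 1
    frequency = count / ((t_off - t_on) * 1e-3)
    return SpikeStats(count=count, frequency=frequency,
                      absolute_peak=absolute_peak,
                      relative_amplitude=relative_amplitude,
                      max_deflection=max_deflection)


# ---------------------------------------------------------------------------
# Protocol 4: normalization; cohort statistics
# ---------------------------------------------------------------------------

def normalize_trace(trace: TraceSet, baseline_end: float) -> TraceSet:
    """Baseline-relative normalization (V − V₀)/V₀ per recording site.

    V₀ is the mean voltage before ``baseline_end`` (the pre-stimulus window).
    Not idempotent: renormalizing a normalized trace rescales by its own new
    baseline.
    """
    mask = trace.time < baseline_end
    if not mask.any():
        raise ValueError("no samples before baseline_end")
    out = {}
    for k, v in trace.data.items():
        v0 = float(v[mask].mean())
        if v0 == 0:
            raise AnalysisError(f"zero baseline at site {k!r}")
        out[k] = (v - v0) / v0
    return TraceSet(time=trace.time.copy(), data=out)


def cohort_stats(values) -> CohortSummary:
    """Mean, sample SD (n−1) and SEM = SD/√n of per-cell values."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("cohort statistics need n >= 2")
    sd = float(x.std(ddof=1))
    return CohortSummary(n=x.size, mean=float(x.mean()), sd=sd,
                         sem=sd / np.sqrt(x.size))
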