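"""Simulation campaigns: single-synapse sweep, per-KC activation, ensembles.

Three campaigns probe how Kenyon-cell input shapes the MBON's somatic
voltage:

* **single-synapse sweep** — one alpha synapse at the center of every
  synapse-bearing dendritic section; local, proximal-neurite and somatic
  peaks quantify dendritic attenuation and the neuron's electrotonic
  compactness (somatic peaks nearly identical across thousands of sites).
* **per-KC activation** — all contacts of one KC fire simultaneously; the
  somatic peak scales almost linearly with the KC's synapse count.
* **ensemble trials** — an "odor": a random set of KCs (≈5% of the
  population) fires one volley; repeated over many trials and over ±25%
  manipulations of KC count or synaptic strength, mirroring the two
  candidate plasticity modes (recruitment vs. synaptic gain).

Every campaign is a pure function of its configuration and seed; per-trial
RNG substreams are spawned from the campaign seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cable import (
    CompartmentModel,
    StimulusProtocol,
    SynapseParams,
    peak_depolarization,
    simulate,
)
from .morphology import ConnectivityTable, SynapseSite, path_distances_from

__all__ = [
    "RegressionResult",
    "ComparisonResult",
    "single_synapse_sweep",
    "kc_activation",
    "random_synapse_trials",
    "ensemble_trials",
    "amplitude_regression",
    "compare_conditions",
    "calibrate_gmax",
]

#: Per-trial horizon: settling + post-onset window that comfortably contains
#: the peak (synaptic τs = 0.44 ms, membrane τ ≈ 16 ms).
EQUILIBRATION_MS = 30.0
POST_ONSET_MS = 60.0


@dataclass
class RegressionResult:
    slope: float      # mV per synapse
    intercept: float  # mV
    r2: float


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    group_means: dict


def _volley(sites, strength, dt):
    return StimulusProtocol.synaptic_volley(
        sites, strength=strength, equilibration=EQUILIBRATION_MS,
        window=POST_ONSET_MS, dt=dt,
    )


def _soma_peak(model, sites, strength, syn, dt):
    prot = _volley(sites, strength, dt)
    tr = simulate(model, prot, sites=("soma",), syn_params=syn)
    return peak_depolarization(tr, "soma", EQUILIBRATION_MS)


# ---------------------------------------------------------------------------

def single_synapse_sweep(
    model: CompartmentModel,
    conn: ConnectivityTable,
    syn: SynapseParams = SynapseParams(),
    strength: float = 1.0,
    dt: float = 0.025,
) -> pd.DataFrame:
    """Stimulate each synapse-bearing section once with a single synapse.

    Returns one row per synapse-bearing section with the local dendritic
    peak, the proximal-neurite and somatic peaks, the somatic attenuation
    (1 − soma/dendrite)·100 %, the section volume and its path distance to
    the soma.
    """
    m = model.morphology
    soma_id = m.find_region("soma")
    dist = path_distances_from(m, soma_id)
    rows = []
    for sid in conn.synapse_bearing_sections():
        site = SynapseSite("stim", sid, 0.5)
        prot = _volley([site], strength, dt)
        tr = simulate(model, prot,
                      sites=((sid, 0.5), "proximal_neurite", "soma"),
                      syn_params=syn)
        names = tr.sites
        dpk = peak_depolarization(tr, names[0], EQUILIBRATION_MS)
        npk = peak_depolarization(tr, "proximal_neurite", EQUILIBRATION_MS)
        spk = peak_depolarization(tr, "soma", EQUILIBRATION_MS)
        att = (1.0 - spk / dpk) * 100.0 if dpk > 0 else np.nan
        rows.append({
            "section_id": sid,
            "dendrite_peak_mv": dpk,
            "neurite_peak_mv": npk,
            "soma_peak_mv": spk,
            "attenuation_pct": att,
            "volume_um3": m.sections[sid].volume,
            "distance_to_soma_um": dist[sid],
        })
    return pd.DataFrame(rows)


def kc_activation(
    model: CompartmentModel,
    conn: ConnectivityTable,
    kc_id: str,
    strength: float = 1.0,
    syn: SynapseParams = SynapseParams(),
    dt: float = 0.025,
) -> float:
    """Somatic peak (mV) from simultaneous activation of one KC's synapses."""
    sites = conn.sites_of(kc_id)
    if not sites:
        raise KeyError(f"unknown KC {kc_id!r}")
    if strength == 0.0:
        return 0.0
    return _soma_peak(model, sites, strength, syn, dt)


def random_synapse_trials(
    model: CompartmentModel,
    conn: ConnectivityTable,
    n_synapses: int,
    n_trials: int,
    seed: int = 0,
    strength: float = 1.0,
    syn: SynapseParams = SynapseParams(),
    dt: float = 0.025,
) -> np.ndarray:
    """Somatic peaks from ``n_trials`` draws of ``n_synapses`` random sites.

    Sites are sampled uniformly without replacement from all synapses,
    regardless of KC identity (the counterpart of activating one KC with the
    same number of contacts at its anatomical locations).
    """
    if n_synapses > conn.n_synapses:
        raise ValueError("n_synapses exceeds the table size")
    streams = np.random.SeedSequence(seed).spawn(n_trials)
    peaks = np.empty(n_trials)
    for k, ss in enumerate(streams):
        if n_synapses == 0:
            peaks[k] = 0.0
            continue
        rng = np.random.default_rng(ss)
        idx = rng.choice(conn.n_synapses, size=n_synapses, replace=False)
        sites = [conn.sites[int(i)] for i in idx]
        peaks[k] = _soma_peak(model, sites, strength, syn, dt)
    return peaks


def ensemble_trials(
    model: CompartmentModel,
    conn: ConnectivityTable,
    n_kcs: int,
    strength: float = 1.0,
    n_trials: int = 1000,
    seed: int = 0,
    syn: SynapseParams = SynapseParams(),
    dt: float = 0.025,
) -> pd.DataFrame:
    """Odor-like trials: random KC sets firing one simultaneous volley.

    Each trial samples ``n_kcs`` distinct KCs uniformly, activates all their
    synapses with the peak conductance scaled by ``strength``, and records
    the somatic peak.  Returns a DataFrame with per-trial KC ids (';'
    joined), activated-synapse count, seed and peak.
    """
    kcs = conn.kc_ids()
    if n_kcs > len(kcs):
        raise ValueError("n_kcs exceeds the KC population")
    by_kc: dict[str, list] = {k: [] for k in kcs}
    for s in conn.sites:
        by_kc[s.kc_id].append(s)
    streams = np.random.SeedSequence(seed).spawn(n_trials)
    rows = []
    for k, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        chosen = [kcs[int(i)] for i in rng.choice(len(kcs), size=n_kcs,
                                                  replace=False)]
        sites = [s for kc in chosen for s in by_kc[kc]]
        peak = _soma_peak(model, sites, strength, syn, dt) if sites else 0.0
        rows.append({
            "trial": k,
            "seed": int(ss.generate_state(1)[0] % (2**31)),
            "kc_ids": ";".join(chosen),
            "n_activated_synapses": len(sites),
            "strength": strength,
            "soma_peak_mv": peak,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def amplitude_regression(trials: pd.DataFrame) -> RegressionResult:
    """OLS of somatic peak on activated-synapse count across trials."""
    x = trials["n_activated_synapses"].to_numpy(float)
    y = trials["soma_peak_mv"].to_numpy(float)
    if np.unique(x).size < 2:
        raise ValueError("regression needs >= 2 distinct synapse counts")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r2=float(res.rvalue**2))


def compare_conditions(groups: dict, design: str = "oneway",
                       equal_var: bool = True) -> ComparisonResult:
    """t-test (pairwise) or one-way ANOVA (multi-group) on peak vectors.

    ``design='pairwise'`` runs an unpaired parametric t-test (Student by
    default, Welch with ``equal_var=False``); ``design='oneway'`` an ordinary
    one-way ANOVA.
    """
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has n < 2")
    means = {k: float(v.mean()) for k, v in arrays.items()}
    if design == "pairwise":
        if len(arrays) != 2:
            raise ValueError("pairwise design needs exactly two groups")
        a, b = arrays.values()
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        name = "student_t" if equal_var else "welch_t"
        return ComparisonResult(name, float(t), float(p), means)
    if design == "oneway":
        f, p = stats.f_oneway(*arrays.values())
        return ComparisonResult("oneway_anova", float(f), float(p), means)
    raise ValueError(f"unknown design {design!r}")


def calibrate_gmax(
    model: CompartmentModel,
    conn: ConnectivityTable,
    target_single_kc_mv: float = 0.37,
    syn: SynapseParams = SynapseParams(),
    rtol: float = 0.01,
    max_iter: int = 20,
    dt: float = 0.025,
    kc_sample: int | None = None,
    seed: int = 0,
) -> float:
    """Peak conductance (μS) at which the mean single-KC somatic peak hits
    the target depolarization.

    Proportional fixed-point iteration on gmax (the response is nearly
    linear in gmax in the small-signal regime), to within ``rtol``.  Raises
    if the target exceeds what the synaptic driving force can produce.
    ``kc_sample`` restricts the mean to a random KC subsample for speed on
    large populations.
    """
    if target_single_kc_mv <= 0:
        raise ValueError("target must be positive")
    headroom = syn.E_rev - model.e_pas
    if target_single_kc_mv >= headroom:
        raise ValueError(
            f"target {target_single_kc_mv} mV exceeds the driving force "
            f"({headroom:.1f} mV)"
        )
    g = syn.gmax
    kcs = conn.kc_ids()
    if kc_sample is not None and kc_sample < len(kcs):
        rng = np.random.default_rng(seed)
        kcs = [kcs[int(i)] for i in
               rng.choice(len(kcs), size=kc_sample, replace=False)]
    for _ in range(max_iter):
        s = SynapseParams(tau_s=syn.tau_s, E_rev=syn.E_rev, gmax=g)
        mean_peak = float(np.mean([
            kc_activation(model, conn, kc, syn=s, dt=dt) for kc in kcs
        ]))
        if mean_peak <= 0:
            raise ValueError("model produces no depolarization")
        if abs(mean_peak - target_single_kc_mv) <= rtol * target_single_kc_mv:
            return g
        new_g = g * target_single_kc_mv / mean_peak
        if not np.isfinite(new_g) or new_g > 1e6 * syn.gmax:
            raise ValueError("target depolarization unattainable")
        g = new_g
    return g
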