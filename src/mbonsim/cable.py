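"""Passive compartmental cable model: assembly, integration, oracles.

The neuron is purely passive: every compartment carries a membrane
capacitance and a leak conductance, adjacent compartments are coupled by
axial conductances from linear cable theory, and cholinergic Kenyon-cell
synapses are alpha-shaped conductance transients.  The membrane equation per
compartment is

    C dV/dt = -g_leak (V - e_pas) - Σ g_syn(t) (V - E_rev) + I_axial + I_inj

integrated implicitly (backward Euler by default, Crank–Nicolson optionally)
so each time step is a single O(n) tree solve (Hines elimination).

Internal units: μm, ms, mV, nA, μS, nF.  Specific parameters are given in
the conventional Ω·cm (Ra), μF/cm² (cm) and S/cm² (g_pas) and converted on
assembly:

    C [nF]        = cm [μF/cm²] · area [μm²] · 1e-5
    g_leak [μS]   = g_pas [S/cm²] · area [μm²] · 1e-2
    R_axial [MΩ]  = 0.04 · Ra [Ω·cm] · ℓ [μm] / (π d² [μm²])
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .morphology import Morphology, SynapseSite

__all__ = [
    "PassiveParams",
    "SynapseParams",
    "CompartmentModel",
    "StimulusProtocol",
    "TraceSet",
    "SimulationError",
    "build_model",
    "alpha_conductance",
    "simulate",
    "steady_state",
    "space_constant",
    "peak_depolarization",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane parameters.

    Defaults are the values fitted to the −10 pA somatic current-step
    response of MBON-α3.
    """

    Ra: float = 85.41        # cytoplasm resistivity, Ω·cm
    cm: float = 0.6961       # specific membrane capacitance, μF/cm²
    g_pas: float = 9.399e-6  # passive membrane conductance, S/cm²
    e_pas: float = -55.64    # leak reversal potential, mV

    def __post_init__(self):
        if self.Ra <= 0 or self.cm <= 0 or self.g_pas <= 0:
            raise ValueError("Ra, cm and g_pas must be positive")


@dataclass(frozen=True)
class SynapseParams:
    """Cholinergic KC→MBON alpha-synapse parameters.

    ``gmax`` is the peak conductance reached at ``tau_s`` after onset
    (1.5627e-5 μS ≈ 1.56e-11 S), calibrated to the target single-KC somatic
    depolarization.
    """

    tau_s: float = 0.44      # time to peak conductance, ms
    E_rev: float = 8.9       # reversal potential, mV
    gmax: float = 1.5627e-5  # peak conductance, μS

    def __post_init__(self):
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.gmax < 0:
            raise ValueError("gmax must be non-negative")


def alpha_conductance(t, onset: float, s: SynapseParams, strength: float = 1.0):
    """Alpha-function conductance in μS at time(s) ``t`` (ms).

    g(t) = strength·gmax·((t−onset)/τs)·exp(−(t−onset−τs)/τs) for t ≥ onset,
    zero before; the peak is exactly ``strength·gmax`` at t = onset + τs.
    """
    t = np.asarray(t, dtype=float)
    dt = t - onset
    g = np.where(
        dt > 0,
        strength * s.gmax * (dt / s.tau_s) * np.exp(-(dt - s.tau_s) / s.tau_s),
        0.0,
    )
    return g if g.shape else float(g)


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

@dataclass
class CompartmentModel:
    """Assembled passive electrical system on a morphology.

    Arrays are indexed by compartment in an order where every parent precedes
    its children (root = compartment 0).
    """

    morphology: Morphology
    params: PassiveParams
    parent: np.ndarray          # (n,) int, -1 for root
    c: np.ndarray               # (n,) nF
    g_leak: np.ndarray          # (n,) μS
    g_axial: np.ndarray         # (n,) μS coupling to parent, 0 at root
    area: np.ndarray            # (n,) μm²
    section_of_comp: np.ndarray  # (n,) section ids
    first_comp: dict = field(repr=False, default_factory=dict)
    nseg: dict = field(repr=False, default_factory=dict)

    @property
    def n_compartments(self) -> int:
        return self.parent.shape[0]

    @property
    def e_pas(self) -> float:
        return self.params.e_pas

    @property
    def total_capacitance(self) -> float:
        """Whole-cell capacitance, nF."""
        return float(self.c.sum())

    @property
    def total_leak_conductance(self) -> float:
        """Whole-cell leak conductance, μS."""
        return float(self.g_leak.sum())

    def comp_index(self, section_id: int, position: float = 0.5) -> int:
        """Compartment holding fractional ``position`` of a section."""
        n = self.nseg[section_id]
        k = min(int(position * n), n - 1)
        return self.first_comp[section_id] + k

    def resolve_site(self, site) -> int:
        """Map a recording/stimulus site spec to a compartment index.

        Accepts a region name (``"soma"``, ``"proximal_neurite"``), a section
        id, a ``(section_id, position)`` pair or a :class:`SynapseSite`.
        """
        if isinstance(site, str):
            return self.comp_index(self.morphology.find_region(site), 0.5)
        if isinstance(site, SynapseSite):
            return self.comp_index(site.section_id, site.position)
        if isinstance(site, tuple):
            return self.comp_index(int(site[0]), float(site[1]))
        return self.comp_index(int(site), 0.5)


def build_model(
    m: Morphology,
    p: PassiveParams = PassiveParams(),
    nseg_rule=1,
) -> CompartmentModel:
    """Discretize a morphology into a :class:`CompartmentModel`.

    ``nseg_rule`` sets the number of electrical compartments per section: an
    int (uniform), a ``{section_id: n}`` dict, or a callable
    ``section -> n``.  Refinement redistributes membrane over more nodes but
    conserves total capacitance and leak conductance exactly.
    """
    def nseg_of(s):
        if callable(nseg_rule):
            n = nseg_rule(s)
        elif isinstance(nseg_rule, dict):
            n = nseg_rule.get(s.id, 1)
        else:
            n = int(nseg_rule)
        if n < 1:
            raise ValueError("nseg must be >= 1")
        return int(n)

    order = m.traversal_order()
    first_comp: dict[int, int] = {}
    nseg: dict[int, int] = {}
    n_total = 0
    for sid in order:
        nseg[sid] = nseg_of(m.sections[sid])
        first_comp[sid] = n_total
        n_total += nseg[sid]

    parent = np.full(n_total, -1, dtype=np.int64)
    c = np.zeros(n_total)
    gl = np.zeros(n_total)
    gax = np.zeros(n_total)
    area = np.zeros(n_total)
    sec_of = np.zeros(n_total, dtype=np.int64)

    def half_R(sid: int) -> float:
        """Axial resistance from a compartment center to its boundary, MΩ."""
        s = m.sections[sid]
        l_comp = s.length / nseg[sid]
        return 0.04 * p.Ra * (l_comp / 2.0) / (math.pi * s.diameter**2)

    for sid in order:
        s = m.sections[sid]
        n = nseg[sid]
        l_comp = s.length / n
        a_comp = math.pi * s.diameter * l_comp
        base = first_comp[sid]
        for k in range(n):
            i = base + k
            sec_of[i] = sid
            area[i] = a_comp
            c[i] = p.cm * a_comp * 1e-5
            gl[i] = p.g_pas * a_comp * 1e-2
            if k > 0:
                parent[i] = i - 1
                gax[i] = 1.0 / (2.0 * half_R(sid))
        if s.parent_id is not None:
            psid = s.parent_id
            if s.parent_attach >= 0.5:
                pcomp = first_comp[psid] + nseg[psid] - 1
            else:
                pcomp = first_comp[psid]
            parent[base] = pcomp
            gax[base] = 1.0 / (half_R(sid) + half_R(psid))

    if np.any(parent[1:] >= np.arange(1, n_total)):
        raise SimulationError("compartment ordering violated (parent >= child)")
    return CompartmentModel(
        morphology=m, params=p, parent=parent, c=c, g_leak=gl, g_axial=gax,
        area=area, section_of_comp=sec_of, first_comp=first_comp, nseg=nseg,
    )


# ---------------------------------------------------------------------------
# Stimuli and traces
# ---------------------------------------------------------------------------

@dataclass
class StimulusProtocol:
    """Current steps and synapse events on an absolute time axis.

    ``current_steps``: (site, onset ms, duration ms, amplitude nA).
    ``synapse_events``: (SynapseSite, onset ms, strength multiplier).
    ``equilibration`` is the stimulus-free settling period the protocol
    reserves before the first stimulus (30 ms by convention); onsets are
    absolute simulation times.
    """

    current_steps: list = field(default_factory=list)
    synapse_events: list = field(default_factory=list)
    equilibration: float = 30.0
    t_stop: float = 260.0
    dt: float = 0.025

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for _, onset, dur, _ in self.current_steps:
            if onset < 0 or dur < 0:
                raise ValueError("current step onset/duration must be >= 0")
        for _, onset, _ in self.synapse_events:
            if onset < 0:
                raise ValueError("synapse onset must be >= 0")

    @classmethod
    def soma_step(cls, amplitude_na: float = -0.010, duration: float = 200.0,
                  equilibration: float = 30.0, tail: float = 30.0,
                  dt: float = 0.025) -> "StimulusProtocol":
        """The standard somatic square-pulse protocol (−10 pA, 200 ms)."""
        return cls(
            current_steps=[("soma", equilibration, duration, amplitude_na)],
            equilibration=equilibration,
            t_stop=equilibration + duration + tail,
            dt=dt,
        )

    @classmethod
    def synaptic_volley(cls, sites: Sequence[SynapseSite], strength: float = 1.0,
                        equilibration: float = 30.0, window: float = 60.0,
                        dt: float = 0.025) -> "StimulusProtocol":
        """Simultaneous activation of ``sites`` after the settling period."""
        onset = equilibration
        return cls(
            synapse_events=[(s, onset, strength) for s in sites],
            equilibration=equilibration,
            t_stop=equilibration + window,
            dt=dt,
        )


@dataclass
class TraceSet:
    """Time-aligned voltage traces at named recording sites."""

    time: np.ndarray             # ms
    data: dict[str, np.ndarray]  # site name -> mV

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for k, v in self.data.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.time.shape:
                raise ValueError(f"trace {k!r} length mismatch")
            self.data[k] = v

    def __getitem__(self, site: str) -> np.ndarray:
        return self.data[site]

    @property
    def sites(self) -> list[str]:
        return list(self.data)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ms": self.time, **self.data})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TraceSet":
        import pandas as pd

        df = pd.read_csv(path)
        t = df.pop("time_ms").to_numpy()
        return cls(time=t, data={c: df[c].to_numpy() for c in df.columns})

    def baseline(self, t_end: float) -> dict[str, float]:
        mask = self.time < t_end
        return {k: float(v[mask].mean()) for k, v in self.data.items()}


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

@njit(cache=True)
def _integrate_tree(parent, cdt, gl, gax, epas,
                    syn_comp, syn_onset, syn_g, tau, erev,
                    stim_comp, stim_on, stim_off, stim_amp,
                    dt, nsteps, rec, theta):
    n = parent.shape[0]
    V = np.full(n, epas * 1.0)  # float state even if epas arrives integer
    out = np.empty((nsteps + 1, rec.shape[0]))
    for j in range(rec.shape[0]):
        out[0, j] = V[rec[j]]
    diag = np.empty(n)
    rhs = np.empty(n)
    gsyn_old = np.zeros(n)
    i_old = np.zeros(n)
    for step in range(1, nsteps + 1):
        t = step * dt
        for i in range(n):
            diag[i] = cdt[i] + theta * gl[i]
            rhs[i] = cdt[i] * V[i] + theta * gl[i] * epas \
                + (1.0 - theta) * (gl[i] * (epas - V[i])
                                   + gsyn_old[i] * (erev - V[i]) + i_old[i])
            gsyn_old[i] = 0.0
            i_old[i] = 0.0
        for k in range(syn_comp.shape[0]):
            dtk = t - syn_onset[k]
            if dtk > 0.0:
                g = syn_g[k] * (dtk / tau) * math.exp(-(dtk - tau) / tau)
                i = syn_comp[k]
                diag[i] += theta * g
                rhs[i] += theta * g * erev
                gsyn_old[i] += g
        for k in range(stim_comp.shape[0]):
            if stim_on[k] <= t < stim_off[k]:
                rhs[stim_comp[k]] += theta * stim_amp[k]
                i_old[stim_comp[k]] += stim_amp[k]
        if theta < 1.0:
            for i in range(1, n):
                ia = gax[i] * (V[parent[i]] - V[i])
                rhs[i] += (1.0 - theta) * ia
                rhs[parent[i]] -= (1.0 - theta) * ia
        for i in range(1, n):
            diag[i] += theta * gax[i]
            diag[parent[i]] += theta * gax[i]
        # Hines elimination: children (higher index) into parents
        for i in range(n - 1, 0, -1):
            og = theta * gax[i]
            f = og / diag[i]
            diag[parent[i]] -= f * og
            rhs[parent[i]] += f * rhs[i]
        V[0] = rhs[0] / diag[0]
        for i in range(1, n):
            V[i] = (rhs[i] + theta * gax[i] * V[parent[i]]) / diag[i]
        for j in range(rec.shape[0]):
            out[step, j] = V[rec[j]]
    return out


def simulate(
    model: CompartmentModel,
    prot: StimulusProtocol,
    sites: Sequence = ("soma",),
    syn_params: SynapseParams = SynapseParams(),
    method: str = "backward_euler",
) -> TraceSet:
    """Integrate the passive model under a stimulus protocol.

    Voltages start at the leak reversal (the model's resting state, so the
    equilibration window is exact) and are recorded at ``sites`` every ``dt``.
    ``method`` is ``"backward_euler"`` (default) or ``"crank_nicolson"``.
    """
    theta = {"backward_euler": 1.0, "crank_nicolson": 0.5}.get(method)
    if theta is None:
        raise ValueError(f"unknown method {method!r}")

    rec = np.array([model.resolve_site(s) for s in sites], dtype=np.int64)
    names = [s if isinstance(s, str) else f"site_{model.resolve_site(s)}"
             for s in sites]

    syn_comp = np.array(
        [model.resolve_site(site) for site, _, _ in prot.synapse_events],
        dtype=np.int64,
    )
    syn_onset = np.array([on for _, on, _ in prot.synapse_events])
    syn_g = np.array(
        [strength * syn_params.gmax for _, _, strength in prot.synapse_events]
    )
    stim_comp = np.array(
        [model.resolve_site(site) for site, _, _, _ in prot.current_steps],
        dtype=np.int64,
    )
    stim_on = np.array([on for _, on, _, _ in prot.current_steps])
    stim_off = np.array([on + d for _, on, d, _ in prot.current_steps])
    stim_amp = np.array([a for _, _, _, a in prot.current_steps])

    nsteps = int(round(prot.t_stop / prot.dt))
    out = _integrate_tree(
        model.parent, model.c / prot.dt, model.g_leak, model.g_axial,
        float(model.e_pas),
        syn_comp, syn_onset.astype(float), syn_g.astype(float),
        float(syn_params.tau_s), float(syn_params.E_rev),
        stim_comp, stim_on.astype(float), stim_off.astype(float),
        stim_amp.astype(float),
        float(prot.dt), nsteps, rec, float(theta),
    )
    if not np.all(np.isfinite(out)):
        bad = int(np.argmax(~np.isfinite(out).all(axis=1)))
        raise SimulationError(f"non-finite voltage at step {bad}")
    time = np.arange(nsteps + 1) * prot.dt
    return TraceSet(time=time, data={n: out[:, j] for j, n in enumerate(names)})


def steady_state(model: CompartmentModel, constant_currents=None) -> np.ndarray:
    """Exact steady-state voltages (mV) under constant injected currents (nA).

    Solves the linear system G·V = g_leak·e_pas + I with the full axial
    coupling; serves as an independent oracle for the integrator.
    """
    from scipy import sparse
    from scipy.sparse.linalg import spsolve

    n = model.n_compartments
    I = np.zeros(n)
    if constant_currents is not None:
        for site, amp in (constant_currents.items()
                          if isinstance(constant_currents, dict)
                          else enumerate(np.asarray(constant_currents))):
            I[model.resolve_site(site) if not isinstance(site, (int, np.integer))
              else site] += amp
    rows, cols, vals = [], [], []
    diag = model.g_leak.copy()
    for i in range(1, n):
        p = model.parent[i]
        g = model.g_axial[i]
        diag[i] += g
        diag[p] += g
        rows += [i, p]
        cols += [p, i]
        vals += [-g, -g]
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    G = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    b = model.g_leak * model.e_pas + I
    V = spsolve(G, b)
    if not np.all(np.isfinite(V)):
        raise SimulationError("singular steady-state system")
    return V


def space_constant(d: float, p: PassiveParams) -> float:
    """Steady-state space constant λ = sqrt(d/(4·Ra·g_pas)) in μm.

    ``d`` is the cable diameter in μm.  With the fitted parameters and the
    mean dendritic diameter of 0.29 μm this evaluates to ≈950 μm — large
    against the dendritic path lengths, which is the analytic footprint of
    the neuron's electrotonic compactness.
    """
    if d <= 0:
        raise ValueError("diameter must be positive")
    d_cm = d * 1e-4
    return math.sqrt(d_cm / (4.0 * p.Ra * p.g_pas)) * 1e4


def peak_depolarization(trace: TraceSet, site: str, stim_onset: float) -> float:
    """Maximal upward deflection from the pre-stimulus level, mV.

    max over t ≥ onset of V(t) − V(onset); a flat or hyperpolarizing response
    yields 0 because the onset sample itself is included.
    """
    if site not in trace.data:
        raise KeyError(f"site {site!r} not recorded")
    v = trace.data[site]
    i0 = int(np.searchsorted(trace.time, stim_onset))
    i0 = min(i0, len(v) - 1)
    return float(np.max(v[i0:] - v[i0]))
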