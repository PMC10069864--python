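"""Synthetic morphologies, KC connectivity and noisy recordings.

Stand-ins for the electron-microscopy reconstruction and the patch-clamp
data, with the statistical structure the analysis assumes: a branched
dendritic tree whose sections match the reconstruction's summary statistics
(mean section length 1.24 μm, mean diameter 0.29 μm over 4342 sections,
soma diameter 6.45 μm), distally tapering diameters, an overdispersed
per-KC synapse-count distribution with mean 13.47 (948 KCs, 12,770 sites,
range ~1–27 plus a 38-contact outlier), and Gaussian recording noise on
ground-truth simulations.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cable import CompartmentModel, StimulusProtocol, SynapseParams, TraceSet, simulate
from .morphology import (
    ConnectivityTable,
    Morphology,
    MorphologyError,
    Section,
    SynapseSite,
    augment_axon_soma,
)

__all__ = [
    "SynthMorphSpec",
    "SynthConnSpec",
    "NoiseSpec",
    "generate_morphology",
    "generate_connectivity",
    "generate_recording",
]

#: Modest axon/terminal placeholder for synthetic trees: short enough that
#: small test morphologies keep the target mean section length, long enough
#: to separate soma from dendrite.  (lengths, diameters) in μm.
_SYNTH_AXON_SPEC = (
    (6.0, 0.80),
    (5.0, 0.60),
    (4.0, 0.50),
    (3.0, 0.50),
    (2.0, 0.60),
)


@dataclass(frozen=True)
class SynthMorphSpec:
    """Target statistics for a synthetic morphology.

    Defaults state the reconstruction's summary geometry.  The realized mean
    section length and diameter match the spec exactly (the generator
    normalizes after sampling).  ``taper_exponent`` > 0 makes distal sections
    thinner; ``branch_probability`` is the chance a new section starts a side
    branch instead of extending the current path.
    """

    n_sections: int = 4342
    mean_section_length: float = 1.24
    mean_diameter: float = 0.29
    taper_exponent: float = 1.0
    branch_probability: float = 0.45
    soma_diameter: float = 6.45
    seed: int = 0
    axon_spec: tuple = _SYNTH_AXON_SPEC

    def __post_init__(self):
        if (self.mean_section_length <= 0 or self.mean_diameter <= 0
                or self.soma_diameter <= 0):
            raise ValueError("spec lengths/diameters must be positive")
        if not (0.0 <= self.branch_probability <= 1.0):
            raise ValueError("branch_probability must be in [0, 1]")


@dataclass(frozen=True)
class SynthConnSpec:
    """Target statistics for synthetic KC→MBON connectivity.

    ``dispersion`` is the negative-binomial size parameter of the per-KC
    synapse-count distribution (smaller = more overdispersed); ``outliers``
    forces specific counts (e.g. the single 38-contact KC).
    ``distal_bias`` > 0 weights placement toward distal sections; 0 is
    uniform over dendritic sections.  ``cluster_radius_um`` > 0 confines each
    KC's contacts to sections within that path distance of a random anchor,
    emulating the spatial correlation of contacts along a real KC axon
    (off by default: placement is uniform and independent).
    """

    n_kcs: int = 948
    total_synapses: int = 12770
    dispersion: float = 6.0
    outliers: tuple = ()
    distal_bias: float = 0.0
    cluster_radius_um: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.total_synapses < self.n_kcs:
            raise ValueError("need at least one synapse per KC")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """I.i.d. Gaussian voltage noise added to clean simulated traces."""

    sd: float = 0.1  # mV
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def generate_morphology(spec: SynthMorphSpec = SynthMorphSpec()) -> Morphology:
    """Grow a random branched tree matching the spec's summary statistics.

    The dendritic tree has ``n_sections - 6`` sections; the remaining six are
    the appended axon chain and soma (see
    :func:`mbonsim.morphology.augment_axon_soma`).  Section lengths are
    gamma-distributed, directions follow a persistent random walk, and
    diameters decay with path distance from the root with strength
    ``taper_exponent``.  Lengths and diameters are rescaled so the realized
    whole-cell means equal the spec exactly.
    """
    if spec.n_sections < 8:
        raise MorphologyError("n_sections must be >= 8 (6 appended + root + 1)")
    rng = np.random.default_rng(spec.seed)
    n_dend = spec.n_sections - 6

    # topology: parent ids and child counts
    parent = np.full(n_dend, -1, dtype=int)
    nchild = np.zeros(n_dend, dtype=int)
    for i in range(1, n_dend):
        if rng.random() < spec.branch_probability or nchild[i - 1] >= 2:
            elig = np.flatnonzero(nchild[:i] < 2)
            p = int(rng.choice(elig))
        else:
            p = i - 1
        parent[i] = p
        nchild[p] += 1

    # raw lengths (gamma, CV=0.5) and path distances for the taper
    raw_len = rng.gamma(shape=4.0, scale=spec.mean_section_length / 4.0,
                        size=n_dend)
    raw_len = np.maximum(raw_len, 0.05 * spec.mean_section_length)
    dist_mid = np.empty(n_dend)
    dist_end = np.empty(n_dend)
    for i in range(n_dend):
        base = 0.0 if parent[i] < 0 else dist_end[parent[i]]
        dist_mid[i] = base + raw_len[i] / 2.0
        dist_end[i] = base + raw_len[i]

    scale_len = dist_end.max() / 3.0 if dist_end.max() > 0 else 1.0
    raw_diam = (1.0 + dist_mid / scale_len) ** (-spec.taper_exponent)
    raw_diam *= 1.0 + 0.1 * rng.standard_normal(n_dend)
    raw_diam = np.maximum(raw_diam, 0.05)

    # normalize so whole-cell (dendrite + appended) means hit the spec
    aux_len = sum(L for L, _ in spec.axon_spec) + spec.soma_diameter
    aux_diam = sum(d for _, d in spec.axon_spec) + spec.soma_diameter
    target_len = spec.mean_section_length * spec.n_sections - aux_len
    target_diam = spec.mean_diameter * spec.n_sections - aux_diam
    if target_len <= 0 or target_diam <= 0:
        raise MorphologyError(
            "axon/soma spec too large for the requested section count"
        )
    lengths = raw_len * (target_len / raw_len.sum())
    diams = raw_diam * (target_diam / raw_diam.sum())

    # 3D layout: persistent random walk, branches deflected
    dirs = np.empty((n_dend, 3))
    start = np.empty((n_dend, 3))
    end = np.empty((n_dend, 3))
    sections = []
    for i in range(n_dend):
        if parent[i] < 0:
            start[i] = np.zeros(3)
            d = np.array([1.0, 0.0, 0.0])
        else:
            start[i] = end[parent[i]]
            jitter = 0.4 if parent[i] == i - 1 else 1.2
            d = _unit(dirs[parent[i]] + jitter * rng.standard_normal(3))
        dirs[i] = d
        end[i] = start[i] + d * lengths[i]
        sections.append(Section(
            id=i,
            parent_id=None if parent[i] < 0 else int(parent[i]),
            points=np.vstack([start[i], end[i]]),
            diameter=float(diams[i]),
            region="dendrite",
        ))

    dend = Morphology(sections, provenance=f"synthetic(seed={spec.seed})")
    return augment_axon_soma(dend, axon_spec=spec.axon_spec,
                             soma_diameter=spec.soma_diameter)


# ---------------------------------------------------------------------------

def _counts_conditioned(rng, n: int, total: int, mean_extra: float,
                        dispersion: float, forced: Sequence[int]) -> np.ndarray:
    """Per-KC counts: forced outliers + truncated NB conditioned on the sum."""
    counts = np.empty(n, dtype=int)
    nf = len(forced)
    counts[:nf] = forced
    free = n - nf
    budget = total - int(np.sum(forced[:nf])) if nf else total
    if free == 0:
        if budget != 0:
            raise ValueError("forced counts do not sum to the total")
        return counts
    if budget < free:
        raise ValueError("forced counts leave less than one synapse per KC")
    p = dispersion / (dispersion + mean_extra)
    draw = 1 + rng.negative_binomial(dispersion, p, size=free)
    # repair the sum by unit steps at random positions, keeping counts >= 1
    diff = budget - int(draw.sum())
    while diff != 0:
        j = int(rng.integers(free))
        if diff > 0:
            draw[j] += 1
            diff -= 1
        elif draw[j] > 1:
            draw[j] -= 1
            diff += 1
    counts[nf:] = draw
    return counts


def generate_connectivity(
    m: Morphology, spec: SynthConnSpec = SynthConnSpec()
) -> ConnectivityTable:
    """Place synthetic KC synapses on the dendritic sections of ``m``.

    Per-KC contact counts are 1-truncated negative binomial draws conditioned
    to sum exactly to ``total_synapses`` (so the realized mean per KC equals
    ``total/n_kcs`` exactly); sites are placed uniformly over dendritic
    sections (optionally distally biased) at uniform fractional positions.
    """
    dend = m.section_ids(["dendrite"])
    if not dend:
        raise MorphologyError("morphology has no dendritic sections")
    rng = np.random.default_rng(spec.seed)
    mean_extra = spec.total_synapses / spec.n_kcs - 1.0
    counts = _counts_conditioned(rng, spec.n_kcs, spec.total_synapses,
                                 mean_extra, spec.dispersion,
                                 list(spec.outliers))

    if spec.distal_bias > 0:
        from .morphology import path_distances_from

        root = m.root.id
        dist = path_distances_from(m, root)
        w = np.array([(1.0 + dist[s]) ** spec.distal_bias for s in dend])
        w = w / w.sum()
    else:
        w = None

    if spec.cluster_radius_um > 0:
        from .morphology import path_distances_from

        dist_from: dict[int, dict] = {}

    width = len(str(spec.n_kcs))
    sites = []
    for k, c in enumerate(counts):
        kc = f"KC{k:0{width}d}"
        if spec.cluster_radius_um > 0:
            anchor = int(rng.choice(dend, p=w))
            if anchor not in dist_from:
                dist_from[anchor] = path_distances_from(m, anchor)
            d = dist_from[anchor]
            pool = [s for s in dend if d[s] <= spec.cluster_radius_um]
            if len(pool) < 2:  # radius too tight for this anchor
                pool = sorted(dend, key=lambda s: d[s])[:max(2, c)]
            secs = rng.choice(pool, size=c)
        else:
            secs = rng.choice(dend, size=c, p=w)
        pos = rng.random(c)
        for s, q in zip(secs, pos):
            sites.append(SynapseSite(kc, int(s), float(q)))
    return ConnectivityTable(sites)


# ---------------------------------------------------------------------------

def generate_recording(
    model: CompartmentModel,
    protocol: StimulusProtocol,
    noise: NoiseSpec = NoiseSpec(),
    sites: Sequence = ("soma",),
    syn_params: SynapseParams = SynapseParams(),
    n_average: int = 1,
) -> TraceSet:
    """Simulate the model and add i.i.d. Gaussian noise of ``noise.sd`` mV.

    With ``sd = 0`` the clean simulation is returned unchanged.
    ``n_average`` > 1 returns the mean of that many independent noisy sweeps
    of the same stimulus, as recording protocols do (e.g. 35 repetitions of
    the −10 pA step per cell), shrinking the effective noise by √n.
    """
    clean = simulate(model, protocol, sites=sites, syn_params=syn_params)
    if noise.sd == 0:
        return clean
    rng = np.random.default_rng(noise.seed)
    noisy = {
        k: v + rng.normal(0.0, noise.sd, size=(n_average,) + v.shape).mean(axis=0)
        for k, v in clean.data.items()
    }
    return TraceSet(time=clean.time, data=noisy)
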