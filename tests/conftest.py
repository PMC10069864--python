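"""Shared fixtures: small hand-built morphologies and the desk-scale model.

The "desk" fixtures are the scaled-down stand-in for the full
reconstruction: a 500-section synthetic tree carrying 100 KCs with the
per-KC contact statistics of the real neuron (mean 13.47 synapses/KC, one
38-contact outlier), with the synaptic peak conductance calibrated so the
mean single-KC somatic response is 0.37 mV.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mbonsim as mb
from mbonsim.morphology import Morphology, Section

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def chain_morphology(lengths, diameters=None, region_first="soma"):
    """Unbranched chain of 2-point sections along +x."""
    diameters = diameters or [1.0] * len(lengths)
    x, secs = 0.0, []
    for i, (L, d) in enumerate(zip(lengths, diameters)):
        secs.append(Section(
            id=i, parent_id=None if i == 0 else i - 1,
            points=[[x, 0, 0], [x + L, 0, 0]], diameter=d,
            region=region_first if i == 0 else "dendrite",
        ))
        x += L
    return Morphology(secs)


def random_tree(n, seed, mean_len=5.0, diam=0.8, region_first="soma"):
    """Random small tree for solver tests (soma at the root)."""
    rng = np.random.default_rng(seed)
    secs = [Section(0, None, [[0, 0, 0], [mean_len, 0, 0]], diam,
                    region=region_first)]
    tips = {0: np.array([mean_len, 0.0, 0.0])}
    for i in range(1, n):
        p = int(rng.integers(i))
        start = tips.get(p, np.array([0.0, 0.0, 0.0]))
        step = rng.normal(size=3)
        step = step / np.linalg.norm(step) * rng.uniform(0.5, 2.0) * mean_len
        secs.append(Section(i, p, np.vstack([start, start + step]),
                            diam * rng.uniform(0.5, 1.5)))
        tips[i] = start + step
    return Morphology(secs)


@pytest.fixture(scope="session")
def desk_morph():
    return mb.generate_morphology(mb.SynthMorphSpec(n_sections=500, seed=11))


@pytest.fixture(scope="session")
def desk_conn(desk_morph):
    return mb.generate_connectivity(
        desk_morph,
        mb.SynthConnSpec(n_kcs=100, total_synapses=1347, outliers=(38,),
                         seed=12),
    )


@pytest.fixture(scope="session")
def desk_model(desk_morph):
    return mb.build_model(desk_morph, mb.PassiveParams())


@pytest.fixture(scope="session")
def desk_syn(desk_model, desk_conn):
    """Synapse parameters calibrated to 0.37 mV mean single-KC peak."""
    g = mb.calibrate_gmax(desk_model, desk_conn, target_single_kc_mv=0.37)
    return mb.SynapseParams(gmax=g)


@pytest.fixture(scope="session")
def sweep_df(desk_model, desk_conn, desk_syn):
    """Single-synapse sweep over every synapse-bearing section (desk scale)."""
    return mb.single_synapse_sweep(desk_model, desk_conn, syn=desk_syn)


@pytest.fixture(scope="session")
def single_comp_morph():
    return Morphology([Section(0, None, [[0, 0, 0], [100, 0, 0]], 1.0,
                               region="soma")])
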