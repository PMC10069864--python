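"""End-to-end reproduction pipeline for an archived reconstruction.

Runs the full analysis on a real morphology/synapse archive (SWC dendrite,
JSON synapse table): model assembly with the fitted passive parameters,
single-synapse sweep, per-KC activation, and the 9-condition ensemble grid
(38/50/63 KCs × 75/100/125 % synaptic strength).  The reconstruction
archive itself is not shipped with the package; point ``archive_dir`` at a
local copy containing the SWC and synapse-location JSON exports.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cable import PassiveParams, SynapseParams, build_model
from .experiments import (
    amplitude_regression,
    ensemble_trials,
    kc_activation,
    single_synapse_sweep,
)
from .morphology import (
    ConnectivityTable,
    Morphology,
    augment_axon_soma,
    load_synapse_json,
    map_synapses,
    read_swc,
)

__all__ = ["load_reconstruction", "run_reproduction"]


def load_reconstruction(
    archive_dir,
    swc_name: str = "dendrite.swc",
    synapse_name: str = "synapses.json",
    unit_scale: float = 1.0,
    per_node: bool = False,
) -> tuple[Morphology, ConnectivityTable]:
    """Load an archived dendrite SWC + synapse JSON and assemble the neuron.

    The synapse JSON may be coordinate-based (mapped to nearest sections) or
    section-based (used as-is).  The dendritic tree is augmented with the
    standard five axon sections and the soma.
    """
    archive_dir = Path(archive_dir)
    swc_path = archive_dir / swc_name
    syn_path = archive_dir / synapse_name
    if not swc_path.exists() or not syn_path.exists():
        raise FileNotFoundError(
            f"reconstruction archive not found under {archive_dir} "
            f"(expected {swc_name} and {synapse_name}); download the archived "
            "dataset and place the exports there"
        )
    dend = read_swc(swc_path, unit_scale=unit_scale, per_node=per_node)
    m = augment_axon_soma(dend)
    loaded = load_synapse_json(syn_path)
    if isinstance(loaded, ConnectivityTable):
        conn = loaded
        conn.validate_against(m)
    else:
        conn = map_synapses(m, loaded)
    return m, conn


def run_reproduction(
    m: Morphology,
    conn: ConnectivityTable,
    params: PassiveParams = PassiveParams(),
    syn: SynapseParams = SynapseParams(),
    n_trials: int = 1000,
    seed: int = 0,
    kc_grid=(38, 50, 63),
    strength_grid=(0.75, 1.0, 1.25),
) -> dict:
    """Run the full campaign suite and summarize the headline quantities.

    Returns a dict with the sweep table, the per-KC peaks and their mean,
    the ensemble grid summary (mean peak, mean activated synapses and
    regression slope per condition) and the somatic-peak spread across
    single synapses.
    """
    model = build_model(m, params)
    sweep = single_synapse_sweep(model, conn, syn=syn)
    kc_peaks = pd.Series(
        {kc: kc_activation(model, conn, kc, syn=syn) for kc in conn.kc_ids()}
    )
    grid = []
    for n_kcs in kc_grid:
        for strength in strength_grid:
            trials = ensemble_trials(model, conn, n_kcs, strength=strength,
                                     n_trials=n_trials, seed=seed, syn=syn)
            reg = amplitude_regression(trials)
            grid.append({
                "n_kcs": n_kcs,
                "strength": strength,
                "mean_peak_mv": float(trials["soma_peak_mv"].mean()),
                "min_peak_mv": float(trials["soma_peak_mv"].min()),
                "max_peak_mv": float(trials["soma_peak_mv"].max()),
                "mean_activated_synapses":
                    float(trials["n_activated_synapses"].mean()),
                "slope_mv_per_synapse": reg.slope,
            })
    return {
        "sweep": sweep,
        "kc_peaks": kc_peaks,
        "mean_single_kc_peak_mv": float(kc_peaks.mean()),
        "soma_peak_range_mv":
            float(sweep["soma_peak_mv"].max() - sweep["soma_peak_mv"].min()),
        "ensemble_grid": pd.DataFrame(grid),
    }
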