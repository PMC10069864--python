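"""Analyze patch-clamp style traces: resistances, τm, capacitance, cohort.

Runs the recording protocols on synthetic data: a voltage-clamp step current
(series/input/membrane resistance), a simulated −10 pA response (membrane
time constant), and the per-cell passive-property table with cohort
statistics (mean / SD / SEM).
"""

import numpy as np

import mbonsim as mb
from mbonsim.ephys import (
    cohort_stats,
    resistance_from_voltage_step,
    specific_capacitance,
    time_constant,
    whole_cell_capacitance,
)

# Protocol 1: 5 mV voltage step on a known Rs=10 MΩ / Rm=900 MΩ / 16 pF cell
t = np.arange(0.0, 110.0, 0.05)
rs, rm, c, dv = 10.0, 900.0, 0.016, 5.0
tau_vc = c * rs * rm / (rs + rm)
i = np.where(t >= 10.0,
             dv / (rs + rm) + (dv / rs - dv / (rs + rm))
             * np.exp(-np.maximum(t - 10.0, 0.0) / tau_vc), 0.0)
rser, rin, rmem = resistance_from_voltage_step((t, i), dv, step=(10.0, 110.0))
print("Protocol 1: Rseries %.1f MΩ, Rinput %.1f MΩ, Rm %.1f MΩ"
      % (rser, rin, rmem))

# Protocol 2/4: τm from a simulated −10 pA step on the synthetic neuron
morph = mb.generate_morphology(mb.SynthMorphSpec(n_sections=200, seed=5))
model = mb.build_model(morph, mb.PassiveParams())
trace = mb.simulate(model, mb.StimulusProtocol.soma_step(), sites=("soma",))
tau = time_constant(trace, step_onset=30.0, t_end=230.0)
print("Protocol 2: membrane time constant τm = %.2f ms" % tau)

# Whole-cell and specific capacitance from cohort-scale numbers
cm_pf = whole_cell_capacitance(16.06, 926.0)
print("Cm = τm/Rm = %.2f pF;  Cspec on 6168.32 μm² = %.3f μF/cm²"
      % (cm_pf, specific_capacitance(cm_pf, 6168.32)))

# Cohort statistics over five recorded cells (per-cell Cm in pF)
cells_cm = [12.35, 20.79, 21.60, 15.83, 13.21]
s = cohort_stats(cells_cm)
print("cohort Cm: mean %.2f, SD %.2f, SEM %.2f pF (n=%d)"
      % (s.mean, s.sd, s.sem, s.n))
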