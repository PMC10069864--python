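"""Recover passive membrane parameters from a noisy current-step recording.

A ground-truth model (the fitted parameters of the real neuron) is simulated
under the standard −10 pA / 200 ms somatic step; the fit target is the
average of 35 sweeps with 0.1 mV recording noise each, as the recording
protocol produces.  The fitter searches (Ra, cm, g_pas) inside physiological
bounds; the printed relative errors show how well each parameter is
constrained.  (Fitting a single noisy sweep instead leaves Ra off by ~10%:
the somatic trace of a compact cell carries little Ra information.)
"""

import mbonsim as mb

morph = mb.generate_morphology(mb.SynthMorphSpec(n_sections=200, seed=21))
truth = mb.PassiveParams(Ra=85.41, cm=0.6961, g_pas=9.399e-6, e_pas=-55.64)
model = mb.build_model(morph, truth)

protocol = mb.StimulusProtocol.soma_step(amplitude_na=-0.010, duration=200.0)
target = mb.generate_recording(model, protocol, mb.NoiseSpec(sd=0.1, seed=7),
                               n_average=35)

result = mb.fit_passive(morph, target, seed=0)
p = result.params
print("         fitted        truth     rel. error")
print("Ra     %8.2f Ω·cm %8.2f   %.2g" % (p.Ra, truth.Ra,
                                          abs(p.Ra - truth.Ra) / truth.Ra))
print("cm     %8.4f μF/cm² %7.4f  %.2g" % (p.cm, truth.cm,
                                           abs(p.cm - truth.cm) / truth.cm))
print("g_pas  %8.3e S/cm² %.3e  %.2g" % (p.g_pas, truth.g_pas,
                                         abs(p.g_pas - truth.g_pas) / truth.g_pas))
print("e_pas  %8.2f mV (pinned to the pre-stimulus baseline)" % p.e_pas)
print("mse    %8.5f mV² over the fit window (≈ the 0.1²/35 mV² noise floor)"
      % result.mse)
print("evaluations: %d, converged: %s, degenerate: %s"
      % (result.n_evaluations, result.converged, result.degenerate))
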