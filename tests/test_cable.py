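"""Cable solver: closed forms, dense oracles and physical invariants."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

import mbonsim as mb
from mbonsim.cable import (
    PassiveParams,
    StimulusProtocol,
    SynapseParams,
    alpha_conductance,
    build_model,
    peak_depolarization,
    simulate,
    space_constant,
    steady_state,
)
from mbonsim.morphology import SynapseSite

from conftest import chain_morphology, random_tree


def dense_system(model, currents=None):
    """Dense (G, C, b) of the compartmental ODE C dV/dt = -G V + b."""
    n = model.n_compartments
    G = np.diag(model.g_leak.astype(float))
    for i in range(1, n):
        p = model.parent[i]
        g = model.g_axial[i]
        G[i, i] += g
        G[p, p] += g
        G[i, p] -= g
        G[p, i] -= g
    b = model.g_leak * model.e_pas
    if currents is not None:
        for comp, amp in currents.items():
            b[comp] += amp
    return G, np.diag(model.c), b


class TestAlphaConductance:
    syn = SynapseParams(tau_s=0.44, E_rev=8.9, gmax=2.0e-5)

    @pytest.mark.parametrize("t_rel, expected_frac", [
        (0.0, 0.0),            # zero at onset
        (0.44, 1.0),           # peak = gmax at tau_s
        (0.88, 2 * math.exp(-1)),  # closed form at 2*tau
        (-0.1, 0.0),           # zero before onset
    ])
    def test_closed_form_values(self, t_rel, expected_frac):
        g = alpha_conductance(10.0 + t_rel, 10.0, self.syn)
        assert g == pytest.approx(self.syn.gmax * expected_frac, abs=1e-18)

    def test_strength_scales_peak(self):
        g = alpha_conductance(10.44, 10.0, self.syn, strength=0.75)
        assert g == pytest.approx(0.75 * self.syn.gmax)

    def test_peak_location(self):
        t = np.linspace(0, 5, 2001)
        g = alpha_conductance(t, 0.0, self.syn)
        assert t[np.argmax(g)] == pytest.approx(self.syn.tau_s, abs=0.01)


class TestAssembly:
    def test_leak_conductance_unit_conversion(self):
        # L=100 μm, d=1 μm, g_pas=1e-5 S/cm² -> π×1e-11 S = π×1e-5 μS
        m = chain_morphology([100.0])
        model = build_model(m, PassiveParams(Ra=100, cm=1.0, g_pas=1e-5))
        assert model.total_leak_conductance == pytest.approx(math.pi * 1e-5)

    def test_axial_conductance_series_formula(self):
        m = chain_morphology([50.0, 80.0], diameters=[1.0, 0.5])
        p = PassiveParams(Ra=120.0, cm=1.0, g_pas=1e-5)
        model = build_model(m, p)
        r_half = lambda L, d: 0.04 * p.Ra * (L / 2) / (math.pi * d**2)  # MΩ
        expected = 1.0 / (r_half(50, 1.0) + r_half(80, 0.5))
        assert model.g_axial[1] == pytest.approx(expected)

    def test_totals_invariant_under_refinement(self, desk_morph):
        p = PassiveParams()
        m1 = build_model(desk_morph, p, nseg_rule=1)
        m3 = build_model(desk_morph, p, nseg_rule=3)
        assert m3.total_capacitance == pytest.approx(m1.total_capacitance)
        assert m3.total_leak_conductance == pytest.approx(
            m1.total_leak_conductance)
        assert m3.n_compartments == 3 * m1.n_compartments


class TestIntegrator:
    def test_rc_step_closed_form(self, single_comp_morph):
        p = PassiveParams(Ra=100, cm=1.0, g_pas=1e-5, e_pas=-60.0)
        model = build_model(single_comp_morph, p)
        prot = StimulusProtocol(current_steps=[("soma", 30.0, 200.0, -0.01)],
                                t_stop=260.0, dt=0.025)
        tr = simulate(model, prot, sites=("soma",))
        tau = model.total_capacitance / model.total_leak_conductance
        R = 1.0 / model.total_leak_conductance
        t = tr.time
        mask = (t >= 30.0) & (t <= 230.0)
        exact = -60.0 - 0.01 * R * (1 - np.exp(-(t[mask] - 30.0) / tau))
        rel = np.max(np.abs(tr["soma"][mask] - exact)) / (0.01 * R)
        assert rel < 1e-3

    def test_equilibrium_stays_at_rest(self, desk_model):
        prot = StimulusProtocol(t_stop=50.0, dt=0.1)
        tr = simulate(desk_model, prot, sites=("soma", "proximal_neurite"))
        for v in tr.data.values():
            assert np.max(np.abs(v - desk_model.e_pas)) < 1e-9

    def test_matrix_exponential_oracle(self):
        """Implicit solver vs dense expm solution on small random trees."""
        for seed in (1, 2, 3):
            m = random_tree(12, seed=seed)
            model = build_model(m, PassiveParams(Ra=150, cm=1.0, g_pas=2e-5,
                                                e_pas=-60.0))
            k = model.n_compartments - 1
            prot = StimulusProtocol(
                current_steps=[((m.sections[k // 2].id, 0.5), 0.0, 1e9, 0.02)],
                t_stop=20.0, dt=0.0025)
            tr = simulate(model, prot, sites=[(i, 0.5) for i in m.sections])
            G, C, b = dense_system(
                model, {model.resolve_site((m.sections[k // 2].id, 0.5)): 0.02})
            A = -np.linalg.solve(C, G)
            vss = np.linalg.solve(G, b)
            v0 = np.full(model.n_compartments, model.e_pas)
            comps = [model.resolve_site((sid, 0.5)) for sid in m.sections]
            for t_chk in (5.0, 20.0):
                exact = vss + expm(A * t_chk) @ (v0 - vss)
                i = int(round(t_chk / prot.dt))
                got = np.empty(model.n_compartments)
                for name, comp in zip(tr.sites, comps):
                    got[comp] = tr.data[name][i]
                scale = np.max(np.abs(exact - model.e_pas))
                assert np.max(np.abs(got - exact)) / scale < 1e-3

    def test_superposition_of_currents(self, desk_model):
        sid = desk_model.morphology.section_ids(["dendrite"])[10]
        def resp(steps):
            prot = StimulusProtocol(current_steps=steps, t_stop=80.0, dt=0.05)
            return simulate(desk_model, prot, sites=("soma",))["soma"]
        a = resp([("soma", 30.0, 40.0, -0.01)])
        b = resp([((sid, 0.5), 20.0, 30.0, 0.02)])
        ab = resp([("soma", 30.0, 40.0, -0.01), ((sid, 0.5), 20.0, 30.0, 0.02)])
        base = desk_model.e_pas
        assert np.allclose(ab - base, (a - base) + (b - base), atol=1e-9)

    def test_reciprocity(self, desk_model):
        sid = desk_model.morphology.section_ids(["dendrite"])[200]
        prot1 = StimulusProtocol(
            current_steps=[((sid, 0.5), 10.0, 40.0, 0.01)], t_stop=60.0, dt=0.05)
        prot2 = StimulusProtocol(
            current_steps=[("soma", 10.0, 40.0, 0.01)], t_stop=60.0, dt=0.05)
        v_soma = simulate(desk_model, prot1, sites=("soma",))["soma"]
        v_k = simulate(desk_model, prot2, sites=((sid, 0.5),))
        assert np.allclose(v_soma, v_k.data[v_k.sites[0]], atol=1e-9)

    def test_bounds_with_excitatory_synapses(self, desk_model, desk_conn):
        sites = desk_conn.sites[:300]
        syn = SynapseParams()
        prot = StimulusProtocol.synaptic_volley(sites, equilibration=5.0,
                                                window=40.0)
        rec = ["soma", "proximal_neurite", (sites[0].section_id, 0.5)]
        tr = simulate(desk_model, prot, sites=rec, syn_params=syn)
        for v in tr.data.values():
            assert np.all(v >= desk_model.e_pas - 1e-9)
            assert np.all(v <= syn.E_rev + 1e-9)

    def test_convergence_in_dt_and_nseg(self, desk_morph, desk_conn):
        syn = SynapseParams()
        sites = desk_conn.sites[:13]
        def peak(dt, nseg):
            model = build_model(desk_morph, PassiveParams(), nseg_rule=nseg)
            prot = StimulusProtocol.synaptic_volley(sites, equilibration=5.0,
                                                    window=40.0, dt=dt)
            tr = simulate(model, prot, sites=("soma",), syn_params=syn)
            return peak_depolarization(tr, "soma", 5.0)
        p0 = peak(0.025, 1)
        assert abs(peak(0.0125, 1) - p0) / p0 < 0.005
        assert abs(peak(0.025, 2) - p0) / p0 < 0.005

    def test_crank_nicolson_matches_backward_euler(self, single_comp_morph):
        model = build_model(single_comp_morph,
                            PassiveParams(cm=1.0, g_pas=1e-4, e_pas=-60.0))
        prot = StimulusProtocol(current_steps=[("soma", 5.0, 20.0, 0.01)],
                                t_stop=40.0, dt=0.025)
        be = simulate(model, prot, sites=("soma",))["soma"]
        cn = simulate(model, prot, sites=("soma",),
                      method="crank_nicolson")["soma"]
        assert np.max(np.abs(be - cn)) < 0.05 * np.max(np.abs(be + 60.0))


class TestSteadyState:
    def test_zero_current_equilibrium(self, desk_model):
        V = steady_state(desk_model)
        assert np.allclose(V, desk_model.e_pas, atol=1e-9)

    def test_single_compartment_ohms_law(self, single_comp_morph):
        model = build_model(single_comp_morph,
                            PassiveParams(g_pas=1e-5, e_pas=-60.0))
        V = steady_state(model, {"soma": 0.01})
        assert V[0] == pytest.approx(-60.0 + 0.01 / model.total_leak_conductance)

    def test_sealed_end_cable_cosh_profile(self):
        # 1000 μm unbranched cable, 200 compartments, current at the far end
        n = 200
        L, d = 1000.0, 1.0
        m = chain_morphology([L / n] * n, diameters=[d] * n,
                             region_first="dendrite")
        p = PassiveParams(Ra=100.0, cm=1.0, g_pas=1e-4, e_pas=0.0)
        model = build_model(m, p)
        V = steady_state(model, {(n - 1, 0.5): 0.1})
        lam = space_constant(d, p)
        x = (np.arange(n) + 0.5) * (L / n)
        profile = np.cosh(x / lam)  # distance from sealed (distal=injected) end
        ratio = V / V[0]
        expected = profile / profile[0]
        assert np.max(np.abs(ratio - expected) / expected) < 0.01


class TestSpaceConstant:
    def test_sqrt_diameter_scaling(self):
        p = PassiveParams()
        assert space_constant(4 * 0.29, p) == pytest.approx(
            2 * space_constant(0.29, p))

    def test_fitted_parameter_value(self):
        # direct formula evaluation with the fitted parameters
        lam = space_constant(0.29, PassiveParams())
        assert lam == pytest.approx(950.0, rel=0.01)

    def test_exceeds_twice_max_path_length(self, desk_morph):
        from mbonsim.morphology import path_distances_from
        lam = space_constant(0.29, PassiveParams())
        dist = path_distances_from(desk_morph, desk_morph.root.id)
        assert lam > 2 * max(dist.values())

    def test_invalid_diameter(self):
        with pytest.raises(ValueError):
            space_constant(0.0, PassiveParams())


class TestPeakDepolarization:
    def test_flat_trace_zero(self):
        tr = mb.TraceSet(time=np.arange(0, 10, 0.1),
                         data={"soma": np.full(100, -60.0)})
        assert peak_depolarization(tr, "soma", 2.0) == 0.0

    def test_hyperpolarizing_step_zero(self, single_comp_morph):
        model = build_model(single_comp_morph)
        prot = StimulusProtocol(current_steps=[("soma", 10.0, 30.0, -0.01)],
                                t_stop=50.0, dt=0.05)
        tr = simulate(model, prot, sites=("soma",))
        assert peak_depolarization(tr, "soma", 10.0) == 0.0

    def test_single_compartment_alpha_response_oracle(self, single_comp_morph):
        """Peak matches a fine-dt reference within 1%."""
        model = build_model(single_comp_morph,
                            PassiveParams(cm=1.0, g_pas=1e-4, e_pas=-60.0))
        site = SynapseSite("k", 0, 0.5)
        def pk(dt):
            prot = StimulusProtocol.synaptic_volley([site], equilibration=2.0,
                                                    window=30.0, dt=dt)
            tr = simulate(model, prot, sites=("soma",),
                          syn_params=SynapseParams(gmax=1e-4))
            return peak_depolarization(tr, "soma", 2.0)
        assert abs(pk(0.025) - pk(0.0025)) / pk(0.0025) < 0.01

    def test_missing_site_raises(self):
        tr = mb.TraceSet(time=np.arange(3.0), data={"soma": np.zeros(3)})
        with pytest.raises(KeyError):
            peak_depolarization(tr, "dendrite", 0.0)
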