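"""Rate laws, ODE construction, simulation and steady-state extraction."""

import numpy as np
import pytest

from dhaflux import kinetics
from dhaflux.kinetics import (
    KineticModel,
    KineticsError,
    RateLaw,
    build_kinetic_model,
    build_ode_system,
    configure_scenario,
    evaluate_rate,
    find_steady_state,
    read_rate_laws,
    simulate,
    write_rate_laws,
)
from dhaflux.netcore import Compartment, MetabolicNetwork, Metabolite, Reaction


class TestEvaluateRate:
    def test_half_saturation(self):
        law = RateLaw("irreversible_mm", Vm=2.0, Km={"s": 0.5})
        assert evaluate_rate(law, {"s": 0.5}, ["s"]) == pytest.approx(1.0)

    def test_reversible_zero_at_equilibrium(self):
        law = RateLaw("reversible_mm_haldane", Vm=5.0,
                      Km={"s": 0.1, "p": 0.1}, Keq=2.0)
        # mass-action ratio p/s equals Keq -> no net flux
        assert evaluate_rate(law, {"s": 1.0, "p": 2.0}, ["s"], ["p"]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_reversible_runs_backwards(self):
        law = RateLaw("reversible_mm_haldane", Vm=5.0,
                      Km={"s": 0.1, "p": 0.1}, Keq=1.0)
        assert evaluate_rate(law, {"s": 0.0, "p": 1.0}, ["s"], ["p"]) < 0

    @pytest.mark.parametrize("form", ["constant_flux", "irreversible_mm",
                                      "mass_action"])
    def test_vm_zero_gives_zero(self, form):
        law = RateLaw(form, Vm=0.0, Km={"s": 0.1})
        assert evaluate_rate(law, {"s": 1.0}, ["s"]) == 0.0

    def test_negative_concentration_rejected(self):
        law = RateLaw("irreversible_mm", Vm=1.0, Km={"s": 0.1})
        with pytest.raises(KineticsError, match="negative"):
            evaluate_rate(law, {"s": -0.5}, ["s"])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RateLaw("irreversible_mm", Vm=-1.0)
        with pytest.raises(ValueError):
            RateLaw("reversible_mm_haldane", Keq=0.0)
        with pytest.raises(ValueError):
            RateLaw("unknown_form")


def _single_pool_model(v_in: float, k_out: float) -> KineticModel:
    """Inflow at constant v, first-order outflow kC: C(t) -> v/k."""
    net = MetabolicNetwork(
        [Compartment("c", "cytosol", 1.0)],
        [Metabolite("src", compartment="c", is_boundary=True),
         Metabolite("a", compartment="c"),
         Metabolite("snk", compartment="c", is_boundary=True)],
        [Reaction("in", stoichiometry={"src": -1, "a": 1}),
         Reaction("out", stoichiometry={"a": -1, "snk": 1})],
    )
    laws = {"in": RateLaw("constant_flux", Vm=v_in),
            "out": RateLaw("mass_action", Vm=k_out)}
    return KineticModel(net, laws, {"src": 1.0, "snk": 0.0})


class TestSimulate:
    def test_single_pool_matches_closed_form(self):
        v, k = 2.0, 0.5
        model = _single_pool_model(v, k)
        traj = simulate(model, {"a": 0.0}, t_end=40.0, n_points=50)
        expected = v / k * (1.0 - np.exp(-k * traj.times))
        assert np.allclose(traj.concentrations["a"].to_numpy(), expected,
                           atol=1e-6)

    def test_zero_everything_stays_zero(self):
        model = _single_pool_model(0.0, 0.5)
        traj = simulate(model, {"a": 0.0}, t_end=10.0)
        assert np.all(traj.concentrations.to_numpy() == 0.0)

    def test_concentrations_nonnegative(self, kinetic_model):
        scen = configure_scenario(kinetic_model, "glucose", 3.58)
        traj = simulate(scen, None, t_end=200.0, n_points=40)
        assert (traj.concentrations.to_numpy() >= 0).all()

    def test_glucose_fluxes_approach_constants(self, kinetic_model):
        scen = configure_scenario(kinetic_model, "glucose", 3.58)
        traj = simulate(scen, None, t_end=4000.0, n_points=100)
        late = traj.fluxes.iloc[-10:]
        assert float(late.std().max()) < 1e-4

    def test_bad_t_end_rejected(self, kinetic_model):
        with pytest.raises(ValueError):
            simulate(kinetic_model, None, t_end=-1.0)


class TestOdeSystem:
    def test_missing_rate_law_names_reaction(self, kinetic_network):
        model = build_kinetic_model()
        laws = dict(model.rate_laws)
        laws.pop("acl")
        with pytest.raises(KineticsError, match="acl"):
            KineticModel(model.network, laws)

    def test_two_compartment_amount_conservation(self, kinetic_model):
        # total amount change from a transport flux must cancel between
        # compartments: sum_i dC_i * V_i = net exchange with boundary
        scen = configure_scenario(kinetic_model, "glucose", 3.58)
        state_ids, rhs = build_ode_system(scen)
        y = np.full(len(state_ids), 0.2)
        dy = rhs(0.0, y)
        vols = np.array([scen.volumes[scen.network.metabolites[m].compartment]
                         for m in state_ids])
        fluxes = rhs.flux_vector(y)
        flux_of = dict(zip(rhs.rxn_ids, fluxes))
        # carbon bookkeeping: d(total C amount)/dt = uptake C - CO2 - sink C
        n_c = {m: scen.network.metabolites[m].n_carbon for m in state_ids}
        dcarbon = float(sum(dy[i] * vols[i] * n_c[m]
                            for i, m in enumerate(state_ids)))
        co2 = sum(flux_of[r] * scen.network.reactions[r].stoichiometry.get("co2_m", 0)
                  for r in flux_of) - flux_of["pyc"] * 0  # hco3 input counted below
        hco3 = -sum(flux_of[r] * scen.network.reactions[r].stoichiometry.get("hco3_m", 0)
                    for r in flux_of)
        expected = 6 * flux_of["glc_up"] - co2 + hco3 - 2 * flux_of["accoa_sink"]
        assert dcarbon == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestScenario:
    def test_glycerol_scenario(self, kinetic_model):
        scen = configure_scenario(kinetic_model, "glycerol", 2.42)
        assert scen.rate_laws["glyc_up"].Vm == pytest.approx(2.42)
        assert scen.rate_laws["glc_up"].Vm == 0.0
        assert scen.rate_laws["etoh_up"].Vm == 0.0
        assert scen.rate_laws["pdh"].Vm == pytest.approx(907.0)

    def test_ethanol_scenario_shuts_pdh(self, kinetic_model):
        scen = configure_scenario(kinetic_model, "ethanol", 7.76)
        assert scen.rate_laws["pdh"].Vm == pytest.approx(1e-6)

    def test_unknown_substrate(self, kinetic_model):
        with pytest.raises(KineticsError):
            configure_scenario(kinetic_model, "sucrose", 1.0)


class TestSteadyState:
    def test_zero_uptake_all_zero(self, kinetic_model):
        scen = configure_scenario(kinetic_model, "glucose", 0.0)
        state = find_steady_state(scen)
        assert all(abs(v) < 1e-12 for v in state.fluxes.values())

    def test_flux_balance_at_steady_state(self, kinetic_model):
        scen = configure_scenario(kinetic_model, "glucose", 3.58)
        state = find_steady_state(scen)
        _, rhs = build_ode_system(scen)
        y = np.array([state.concentrations[m] for m in rhs.state_ids])
        assert np.max(np.abs(rhs(0.0, y))) <= 10 * scen.steady_state_tol

    def test_carbon_throughput_closes(self, kinetic_model):
        scen = configure_scenario(kinetic_model, "glucose", 3.58)
        f = find_steady_state(scen).fluxes
        carbon_in = 6 * f["glc_up"] + f["pyc"]  # bicarbonate fixation
        co2_out = f["pdh"] + f["ide"] + f["ogdh"] + f["me"]
        sink_out = 2 * f["accoa_sink"]
        assert carbon_in == pytest.approx(co2_out + sink_out, rel=1e-6)

    def test_ethanol_pdh_shut_down(self, kinetic_model):
        scen = configure_scenario(kinetic_model, "ethanol", 7.76)
        f = find_steady_state(scen).fluxes
        assert f["pdh"] < 1e-4 * f["cs"]

    def test_linear_chain_carries_input_flux(self):
        v, k = 1.5, 2.0
        model = _single_pool_model(v, k)
        f = find_steady_state(model).fluxes
        assert f["in"] == pytest.approx(v)
        assert f["out"] == pytest.approx(v, rel=1e-8)

    def test_initial_condition_robustness(self, kinetic_model):
        scen = configure_scenario(kinetic_model, "glycerol", 2.42)
        ref = find_steady_state(scen)
        for factor in (0.1, 10.0):
            init = {m: c * factor for m, c in ref.concentrations.items()}
            alt = find_steady_state(scen, initial_concentrations=init)
            for rid, v in ref.fluxes.items():
                assert alt.fluxes[rid] == pytest.approx(v, rel=1e-5, abs=1e-8)

    def test_sink_flux_monotone_in_uptake(self, kinetic_model):
        sinks = []
        prev_state = None
        for uptake in (0.5, 1.5, 2.5, 3.58):
            scen = configure_scenario(kinetic_model, "glucose", uptake)
            state = find_steady_state(scen, initial_concentrations=prev_state)
            prev_state = state.concentrations
            sinks.append(state.fluxes["accoa_sink"])
        assert all(b >= a - 1e-9 for a, b in zip(sinks, sinks[1:]))


class TestRateLawIO:
    def test_roundtrip(self, kinetic_model, tmp_path):
        path = tmp_path / "laws.tsv"
        write_rate_laws(kinetic_model.rate_laws, path)
        back = read_rate_laws(path)
        assert set(back) == set(kinetic_model.rate_laws)
        for rid, law in kinetic_model.rate_laws.items():
            assert back[rid].form == law.form
            assert back[rid].Vm == pytest.approx(law.Vm)
            assert back[rid].Km == pytest.approx(law.Km)
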