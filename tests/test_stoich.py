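"""Constraint-based model: construction, FBA core, growth and DHA scans."""

import itertools

import numpy as np
import pytest

from dhaflux import netcore, stoich
from dhaflux.netcore import Compartment, MetabolicNetwork, Metabolite, Reaction
from dhaflux.stoich import (
    KINETIC_TO_STOICH,
    StoichModel,
    build_stoich_model,
    dha_potential_scan,
    max_growth,
    min_carbon_per_biomass,
    solve_fba,
)
from dhaflux.synthdata import gen_biomass_composition


class TestConstruction:
    def test_grows_on_each_single_substrate(self, stoich_model):
        for sub, up in [("glucose", 0.65), ("glycerol", 0.44),
                        ("ethanol", 1.41), ("acetate", 0.60)]:
            mu, sol = max_growth(stoich_model, sub, up)
            assert sol.status == "optimal" and mu > 0, sub

    def test_all_uptakes_closed_no_growth(self, stoich_model):
        sol = solve_fba(stoich_model, "biomass")
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_biomass_mass_closes_to_one_gram(self, stoich_model):
        # sum of coefficient x molar mass ~ 1000 mg/gDW within 5% (ash excluded)
        assert stoich_model.composition.mass_per_gdw() == \
            pytest.approx(1000.0, rel=0.05)

    def test_carbon_conservation_everywhere(self, stoich_model):
        assert netcore.validate_network(stoich_model.network,
                                        check_elements=True) == []

    def test_at_least_35_transport_reactions(self, stoich_model):
        n = sum(1 for r in stoich_model.network.reactions.values()
                if r.is_transport)
        assert n >= 35

    def test_kinetic_subnetwork_embedded(self, stoich_model, kinetic_network):
        for rid in kinetic_network.reactions:
            mapped = KINETIC_TO_STOICH.get(rid, rid)
            assert mapped in stoich_model.network.reactions, rid

    def test_unknown_precursor_rejected(self):
        comp = gen_biomass_composition()
        comp.components["unobtainium_c"] = 1.0
        with pytest.raises(KeyError):
            build_stoich_model(comp)


class TestFBACore:
    def _chain_model(self):
        net = MetabolicNetwork(
            [Compartment("c", "c", 1.0)],
            [Metabolite("a", compartment="c")],
            [Reaction("in", stoichiometry={"a": 1}, lower_bound=0, upper_bound=5),
             Reaction("out", stoichiometry={"a": -1}, lower_bound=0,
                      upper_bound=100)],
        )
        return StoichModel(net, gen_biomass_composition())

    def test_toy_chain_capacity(self):
        model = self._chain_model()
        sol = solve_fba(model, "out")
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(5.0)

    def test_infeasible_reported_not_raised(self):
        model = self._chain_model()
        sol = solve_fba(model, "out", {"in": (0.0, 0.0), "out": (1.0, 2.0)})
        assert sol.status == "infeasible"

    def test_unbounded_reported(self):
        net = MetabolicNetwork(
            [Compartment("c", "c", 1.0)],
            [Metabolite("a", compartment="c")],
            [Reaction("r1", stoichiometry={"a": 1}, reversible=True),
             Reaction("r2", stoichiometry={"a": -1}, reversible=True)],
        )
        model = StoichModel(net, gen_biomass_composition())
        sol = solve_fba(model, "r1", {"r1": (0, float("inf")),
                                      "r2": (0, float("inf"))})
        assert sol.status in ("unbounded", "optimal")
        if sol.status == "optimal":  # solver may cap at the big-M bound
            assert sol.objective_value >= 1e3

    def test_optimum_satisfies_mass_balance_and_bounds(self, stoich_model):
        model = stoich_model.copy()
        # open the glucose exchange in the model itself so the declared
        # bounds are the effective ones
        for sub, (ex, _) in stoich.SUBSTRATE_EXCHANGES.items():
            rxn = model.network.reactions[ex]
            rxn.lower_bound = -0.65 if sub == "glucose" else 0.0
            rxn.upper_bound = 0.0
        sol = solve_fba(model, "biomass", parsimonious=True)
        assert sol.status == "optimal"
        v = np.array([sol.fluxes[r] for r in model.reaction_ids])
        assert np.max(np.abs(model.S @ v)) <= 1e-9
        for rid, (lo, hi) in zip(model.reaction_ids, model.bounds_vector()):
            assert lo - 1e-9 <= sol.fluxes[rid] <= hi + 1e-9, rid

    def test_parsimonious_canonicalization_keeps_objective(self, stoich_model):
        mu1, plain = max_growth(stoich_model, "glycerol", 0.44)
        mu2, pars = max_growth(stoich_model, "glycerol", 0.44,
                               parsimonious=True)
        assert mu1 == pytest.approx(mu2, rel=1e-9)
        total_plain = sum(abs(v) for v in plain.fluxes.values())
        total_pars = sum(abs(v) for v in pars.fluxes.values())
        assert total_pars <= total_plain + 1e-6


def _random_model(rng):
    n_m = rng.integers(2, 5)
    n_r = rng.integers(3, 9)
    mets = [Metabolite(f"m{i}", compartment="c") for i in range(n_m)]
    rxns = []
    for j in range(n_r):
        coeffs = {}
        for i in range(n_m):
            c = rng.integers(-2, 3)
            if c:
                coeffs[f"m{i}"] = float(c)
        if not coeffs:
            coeffs = {f"m{rng.integers(0, n_m)}": 1.0}
        lo, hi = float(rng.integers(-5, 1)), float(rng.integers(0, 8))
        rxns.append(Reaction(f"r{j}", stoichiometry=coeffs, reversible=True,
                             lower_bound=lo, upper_bound=hi))
    net = MetabolicNetwork([Compartment("c", "c", 1.0)], mets, rxns)
    return StoichModel(net, gen_biomass_composition())


def _brute_force_optimum(model, objective):
    """Enumerate basic feasible solutions (vertices) of the flux polytope."""
    S, n = model.S, model.S.shape[1]
    k = n - np.linalg.matrix_rank(S)
    bounds = model.bounds_vector()
    j_obj = model._index[objective]
    best = None
    for fix in itertools.combinations(range(n), k):
        free = [i for i in range(n) if i not in fix]
        A = S[:, free]
        for choice in itertools.product(
                *[[bounds[i][0], bounds[i][1]] for i in fix]):
            b = -S[:, fix] @ np.array(choice)
            x_free, *_ = np.linalg.lstsq(A, b, rcond=None)
            v = np.zeros(n)
            for i, c in zip(fix, choice):
                v[i] = c
            for i, x in zip(free, x_free):
                v[i] = x
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if any(v[i] < bounds[i][0] - 1e-8 or v[i] > bounds[i][1] + 1e-8
                   for i in range(n)):
                continue
            if best is None or v[j_obj] > best:
                best = float(v[j_obj])
    return best


class TestLPAgainstVertexEnumeration:
    def test_100_seeded_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            model = _random_model(rng)
            objective = model.reaction_ids[
                int(rng.integers(0, len(model.reaction_ids)))]
            sol = solve_fba(model, objective)
            assert sol.status == "optimal", trial
            expected = _brute_force_optimum(model, objective)
            assert expected is not None, trial
            assert sol.objective_value == pytest.approx(
                expected, rel=1e-6, abs=1e-6), trial


class TestGrowth:
    @pytest.mark.parametrize("sub,uptake,mu_exp", [
        ("glucose", 0.65, 0.051), ("glycerol", 0.44, 0.023),
        ("ethanol", 1.41, 0.046),
    ])
    def test_mumax_reaches_observed_growth(self, stoich_model, sub, uptake,
                                           mu_exp):
        mu, _ = max_growth(stoich_model, sub, uptake)
        assert mu >= mu_exp

    def test_zero_uptake_zero_growth(self, stoich_model):
        mu, _ = max_growth(stoich_model, "glucose", 0.0)
        assert mu == pytest.approx(0.0, abs=1e-9)

    def test_unknown_substrate(self, stoich_model):
        with pytest.raises(KeyError):
            max_growth(stoich_model, "sucrose", 1.0)


class TestCarbonPerBiomass:
    def test_glucose_in_published_band(self, stoich_model):
        assert 36.0 <= min_carbon_per_biomass(stoich_model, "glucose") <= 49.0

    def test_substrates_agree_closely(self, stoich_model):
        vals = [min_carbon_per_biomass(stoich_model, s)
                for s in ("glucose", "glycerol", "ethanol")]
        assert np.std(vals) / np.mean(vals) <= 0.05

    def test_scale_invariance(self, stoich_model):
        a = min_carbon_per_biomass(stoich_model, "glycerol", uptake=0.44)
        b = min_carbon_per_biomass(stoich_model, "glycerol", uptake=0.88)
        assert a == pytest.approx(b, rel=1e-6)

    def test_carbon_balance_at_optimum(self, stoich_model):
        mu, sol = max_growth(stoich_model, "glucose", 0.65)
        carbon_in = -6 * sol.fluxes["EX_glc"]
        biomass_c = mu * sum(
            coeff * stoich_model.network.metabolites[met].n_carbon
            for met, coeff in stoich_model.composition.components.items())
        co2_out = sol.fluxes["EX_co2"]
        dha_out = 22 * sol.fluxes["EX_dha"]
        assert carbon_in == pytest.approx(biomass_c + co2_out + dha_out,
                                          rel=1e-6)


class TestDHAScan:
    def test_monotone_increase_as_biomass_drops(self, stoich_model):
        scan = dha_potential_scan(stoich_model, "glucose", 0.65,
                                  [1.0, 0.8, 0.4])
        pct = [r.pct_carbon_to_dha for r in scan]
        assert all(r.feasible for r in scan)
        assert pct[2] > pct[1] > pct[0]

    def test_bounds_respected(self, stoich_model):
        scan = dha_potential_scan(stoich_model, "glycerol", 0.44, [1.0])
        row = scan[0]
        assert row.dha_flux >= -1e-9
        assert row.pct_carbon_to_dha <= 100.0

    def test_dha_flux_non_increasing_in_biomass_fraction(self, stoich_model):
        scan = dha_potential_scan(stoich_model, "ethanol", 1.41,
                                  [0.4, 0.8, 1.0])
        flux = {r.fraction: r.dha_flux for r in scan}
        assert flux[0.4] >= flux[0.8] - 1e-9 >= flux[1.0] - 2e-9

    def test_invalid_fraction_rejected(self, stoich_model):
        with pytest.raises(ValueError):
            dha_potential_scan(stoich_model, "glucose", 0.65, [0.0])


class TestCobraCrossCheck:
    """The LP core checked against an independent COBRA implementation."""

    def _to_cobra(self, model):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("crosscheck")
        mets = {mid: cobra.Metabolite(mid, compartment=m.compartment)
                for mid, m in model.network.metabolites.items()}
        rxns = []
        for rid, r in model.network.reactions.items():
            cr = cobra.Reaction(rid, lower_bound=max(r.lower_bound, -1000),
                                upper_bound=min(r.upper_bound, 1000))
            rxns.append(cr)
        cm.add_reactions(rxns)
        for rid, r in model.network.reactions.items():
            cm.reactions.get_by_id(rid).add_metabolites(
                {mets[k]: v for k, v in r.stoichiometry.items()})
        return cm

    @pytest.mark.parametrize("sub,uptake", [("glucose", 0.65),
                                            ("ethanol", 1.41)])
    def test_mumax_matches_cobrapy(self, stoich_model, sub, uptake):
        cm = self._to_cobra(stoich_model)
        for s2, (ex, up_id) in stoich.SUBSTRATE_EXCHANGES.items():
            rx = cm.reactions.get_by_id(ex)
            rx.lower_bound = -uptake if s2 == sub else 0.0
            rx.upper_bound = 0.0
        cm.objective = "biomass"
        mu_cobra = cm.optimize().objective_value
        mu_ours, _ = max_growth(stoich_model, sub, uptake)
        assert mu_ours == pytest.approx(mu_cobra, abs=1e-6)
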