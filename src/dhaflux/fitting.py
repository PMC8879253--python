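"""Parameter estimation for the kinetic model against target flux datasets.

The fitted observables are steady-state fluxes.  The objective is a relative
weighted sum of squares over dataset entries plus smooth quadratic penalties
for internal metabolite concentrations exceeding their caps (12 mmol/L, with
cellular ethanol allowed up to 32 mmol/L).  The default free parameters are
the ``Vm`` scaling factors of the enzymatic reactions; substrate uptake rates
are scenario inputs, and PDH's Vmax is fixed by the substrate parameterization
(907 for glucose/glycerol, 1e-6 for ethanol), so neither is fitted.

Glucose and glycerol datasets are fitted jointly with a single parameter set;
ethanol is fitted separately (one parameter set cannot describe all three
substrates because the ethanol route requires PDH to be shut off).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import differential_evolution, minimize

from .kinetics import (
    KineticModel,
    KineticsError,
    SteadyState,
    configure_scenario,
    find_steady_state,
)

__all__ = [
    "FluxDataset",
    "EstimationConfig",
    "FitResult",
    "objective_sse",
    "fit_parameters",
    "check_constraints",
    "default_free_parameters",
    "apply_parameters",
    "read_flux_dataset",
    "write_flux_dataset",
    "load_packaged_dataset",
    "packaged_free_parameters",
    "packaged_calibration_config",
    "BRANCH_REACTIONS",
]

_PENALTY_WEIGHT = 1e3     # weight of the concentration-cap penalty
_FAILURE_PENALTY = 1e6    # large finite objective for non-converging models
_EPS = 1e-6


@dataclass
class FluxDataset:
    """Target fluxes for one substrate scenario (kinetic units mmol/min/L)."""

    label: str
    entries: dict[str, tuple[float, float]]  # reaction id -> (flux, weight)
    substrate: str
    uptake_rate: float

    def __post_init__(self) -> None:
        if self.uptake_rate < 0:
            raise ValueError("uptake_rate must be >= 0")
        for rid, (flux, weight) in self.entries.items():
            if weight < 0:
                raise ValueError(f"negative weight for {rid}")


@dataclass
class EstimationConfig:
    free_parameters: list[tuple[str, str, float, float]] = field(default_factory=list)
    conc_cap: float = 12.0
    ethanol_conc_cap: float = 32.0
    n_starts: int = 3
    seed: int = 0
    method: str = "de"
    #: differential-evolution effort knobs (kept modest; the search space is
    #: log10(Vm) over a handful of branch-point enzymes)
    de_maxiter: int = 40
    de_popsize: int = 8
    polish: bool = True
    #: integration horizon for steady-state search inside the objective;
    #: parameter sets that have not settled by then are penalized
    ss_t_max: float = 1.4e4

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for rid, pname, lo, hi in self.free_parameters:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bad bounds for {rid}.{pname}")


@dataclass
class FitResult:
    parameters: dict[tuple[str, str], float]
    objective: float
    per_dataset_residuals: dict[str, float]
    constraint_violations: list[str]
    n_evaluations: int
    seed: int = 0


#: branch-point reactions whose Vm determines the steady-state flux partition
BRANCH_REACTIONS = ("aco", "cit_t", "acl", "mde", "me", "pyc", "cs", "accoa_sink")


def default_free_parameters(
    model: KineticModel,
    reactions: tuple[str, ...] | None = None,
    lo: float = 1e-6,
    hi: float = 1e4,
) -> list[tuple[str, str, float, float]]:
    """Vm of every enzymatic reaction (uptakes and PDH excluded), or a subset."""
    out = []
    for rid in model.network.reactions:
        if rid in ("glc_up", "glyc_up", "etoh_up", "pdh"):
            continue
        if reactions is not None and rid not in reactions:
            continue
        out.append((rid, "Vm", lo, hi))
    return out


def apply_parameters(model: KineticModel,
                     parameters: dict[tuple[str, str], float]) -> KineticModel:
    out = model.copy()
    for (rid, pname), value in parameters.items():
        law = out.rate_laws[rid]
        if pname == "Vm":
            law.Vm = value
        elif pname == "k_over":
            law.k_over = value
        elif pname == "Keq":
            law.Keq = value
        elif pname.startswith("Km:"):
            law.Km[pname.split(":", 1)[1]] = value
        else:
            raise KeyError(f"unknown parameter {pname!r} for {rid}")
    return out


def check_constraints(steady_state: SteadyState,
                      config: EstimationConfig | None = None) -> list[str]:
    """Internal metabolites above their concentration cap (ethanol cap 32)."""
    cfg = config or EstimationConfig()
    out = []
    for met, conc in steady_state.concentrations.items():
        cap = cfg.ethanol_conc_cap if met.startswith("etoh") else cfg.conc_cap
        if conc > cap:
            out.append(f"{met}: {conc:.3f} > cap {cap:g} mmol/L")
    return out


def _cap_penalty(state: SteadyState, cfg: EstimationConfig) -> float:
    pen = 0.0
    for met, conc in state.concentrations.items():
        cap = cfg.ethanol_conc_cap if met.startswith("etoh") else cfg.conc_cap
        if conc > cap:
            pen += ((conc - cap) / cap) ** 2
    return _PENALTY_WEIGHT * pen


def _dataset_sse(state: SteadyState, dataset: FluxDataset) -> float:
    sse = 0.0
    for rid, (target, weight) in dataset.entries.items():
        if weight == 0.0:
            continue
        v = state.fluxes.get(rid, 0.0)
        sse += weight * (v - target) ** 2 / max(abs(target), _EPS) ** 2
    return sse


def objective_sse(
    model: KineticModel,
    datasets: list[FluxDataset],
    config: EstimationConfig | None = None,
    warm_starts: dict[str, dict[str, float]] | None = None,
) -> float:
    """Relative weighted SSE over all datasets plus concentration penalties.

    Steady-state failures contribute a large finite penalty instead of raising,
    so stochastic optimizers can traverse bad parameter regions.
    """
    cfg = config or EstimationConfig()
    total = 0.0
    for ds in datasets:
        scen = configure_scenario(model, ds.substrate, ds.uptake_rate)
        warm = None if warm_starts is None else warm_starts.get(ds.substrate)
        state = None
        for init in ([warm] if warm is not None else []) + [None]:
            try:
                state = find_steady_state(scen, initial_concentrations=init,
                                          t_max=cfg.ss_t_max, fast=True)
                break
            except KineticsError:
                continue
        if state is None:
            total += _FAILURE_PENALTY
            continue
        if warm_starts is not None:
            warm_starts[ds.substrate] = state.concentrations
        total += _dataset_sse(state, ds) + _cap_penalty(state, cfg)
    return total


def fit_parameters(model: KineticModel, datasets: list[FluxDataset],
                   config: EstimationConfig) -> FitResult:
    """Global stochastic search (differential evolution over log10 parameters)
    followed by a local Nelder-Mead refinement; best of ``n_starts`` runs."""
    if not config.free_parameters:
        raise ValueError("free parameter list is empty")
    names = [(rid, pname) for rid, pname, _, _ in config.free_parameters]
    log_bounds = [(np.log10(lo), np.log10(hi))
                  for _, _, lo, hi in config.free_parameters]
    n_eval = 0
    # seed warm starts with the full solver at the current parameters so the
    # fast objective never has to bootstrap a steady state from scratch
    warm: dict[str, dict[str, float]] = {}
    for ds in datasets:
        try:
            st = find_steady_state(configure_scenario(model, ds.substrate,
                                                      ds.uptake_rate))
            warm[ds.substrate] = st.concentrations
        except KineticsError:
            pass

    def evaluate(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        params = {name: 10.0 ** xi for name, xi in zip(names, x)}
        return objective_sse(apply_parameters(model, params), datasets, config, warm)

    # anchor the initial population at the model's current (working) parameters
    current = []
    for rid, pname in names:
        law = model.rate_laws[rid]
        if pname.startswith("Km:"):
            val = law.Km.get(pname.split(":", 1)[1], 0.1)
        else:
            val = {"Vm": law.Vm, "k_over": law.k_over, "Keq": law.Keq}[pname]
        current.append(np.log10(max(val, 1e-12)))
    current = np.clip(current, [b[0] for b in log_bounds], [b[1] for b in log_bounds])

    best_x, best_f, diagnostics = None, np.inf, []
    for start in range(config.n_starts):
        seed = (config.seed + 7919 * start) % (2**31 - 1)
        rng = np.random.default_rng(seed)
        n_pop = max(5, config.de_popsize * len(names))
        init = rng.uniform(
            [b[0] for b in log_bounds], [b[1] for b in log_bounds],
            size=(n_pop, len(names)),
        )
        init[0] = current
        # a few mild perturbations of the anchor keep early generations alive
        for i in range(1, min(4, n_pop)):
            init[i] = np.clip(current + rng.normal(0, 0.3, len(names)),
                              [b[0] for b in log_bounds], [b[1] for b in log_bounds])
        try:
            res = differential_evolution(
                evaluate, log_bounds, seed=seed, maxiter=config.de_maxiter,
                popsize=config.de_popsize, tol=1e-10, mutation=(0.4, 1.0),
                recombination=0.8, polish=False, init=init,
            )
            x, f = res.x, res.fun
            if config.polish:
                loc = minimize(evaluate, x, method="Nelder-Mead",
                               options={"maxiter": 60 * len(x), "xatol": 1e-8,
                                        "fatol": 1e-12})
                if loc.fun < f:
                    x, f = loc.x, loc.fun
            diagnostics.append((seed, float(f)))
            if f < best_f:
                best_x, best_f = x, float(f)
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append((seed, f"failed: {exc}"))
    if best_x is None:
        raise RuntimeError(f"all optimization starts failed: {diagnostics}")

    params = {name: 10.0 ** xi for name, xi in zip(names, best_x)}
    fitted = apply_parameters(model, params)
    per_ds, violations = {}, []
    for ds in datasets:
        scen = configure_scenario(fitted, ds.substrate, ds.uptake_rate)
        state = find_steady_state(scen, check=False)
        per_ds[ds.label] = _dataset_sse(state, ds)
        violations.extend(
            f"[{ds.label}] {v}" for v in check_constraints(state, config)
        )
    return FitResult(
        parameters=params,
        objective=best_f,
        per_dataset_residuals=per_ds,
        constraint_violations=violations,
        n_evaluations=n_eval,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# dataset file I/O and the packaged fixtures
# ---------------------------------------------------------------------------

def write_flux_dataset(dataset: FluxDataset, path,
                       notes: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# label: {dataset.label}\n")
        fh.write(f"# substrate: {dataset.substrate}\n")
        fh.write(f"# uptake_rate: {dataset.uptake_rate:.10g}\n")
        fh.write("# units: mmol.min-1.L-1\n")
        fh.write("reaction\tflux\tweight\tnote\n")
        for rid, (flux, weight) in dataset.entries.items():
            note = (notes or {}).get(rid, "")
            fh.write(f"{rid}\t{flux:.10g}\t{weight:g}\t{note}\n")


def read_flux_dataset(path) -> FluxDataset:
    meta: dict[str, str] = {}
    entries: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            elif line and not line.startswith("reaction\t"):
                parts = line.split("\t")
                entries[parts[0]] = (float(parts[1]), float(parts[2]))
    return FluxDataset(
        label=meta.get("label", "dataset"),
        entries=entries,
        substrate=meta["substrate"],
        uptake_rate=float(meta["uptake_rate"]),
    )


def packaged_free_parameters(model: KineticModel) -> list[tuple[str, str, float, float]]:
    """The packaged calibration's degrees of freedom.

    Vm of the branch-point reactions that set the steady-state flux partition,
    plus the citrate affinities of aconitase and the citrate exporter.  The
    latter two are free because the citrate node is the only branch whose
    operating point differs between the jointly fitted glucose and glycerol
    scenarios, so its saturation behaviour is identifiable from (and needed to
    reconcile) the two datasets.
    """
    free = default_free_parameters(model, BRANCH_REACTIONS, lo=1e-2, hi=1e3)
    free += [("cit_t", "Km:cit_m", 1e-3, 1e2), ("aco", "Km:cit_m", 1e-3, 1e2)]
    return free


def packaged_calibration_config(kind: str, model: KineticModel,
                                seed: int = 1) -> EstimationConfig:
    """Estimation settings used for the packaged fixtures.

    ``kind`` is ``glucose_glycerol`` (joint fit, one parameter set) or
    ``ethanol`` (separate fit; PDH is pinned at its near-zero Vmax by the
    scenario, not by the optimizer).
    """
    free = packaged_free_parameters(model)
    if kind == "glucose_glycerol":
        return EstimationConfig(free_parameters=free, n_starts=1, seed=seed,
                                de_maxiter=12, de_popsize=4, ss_t_max=6e3)
    if kind == "ethanol":
        return EstimationConfig(free_parameters=free, n_starts=2, seed=seed,
                                de_maxiter=25, de_popsize=4, ss_t_max=6e3)
    raise ValueError(f"unknown calibration kind {kind!r}")


def load_packaged_dataset(substrate: str) -> FluxDataset:
    """The packaged calibration fixtures (glucose / glycerol / ethanol).

    Uptake and acetyl-CoA production (ACL) entries carry the measured values;
    entries flagged ``synthetic`` in the file follow from the carbon identity
    of the network rather than from measurement.  TCA-cycle entries that are
    inconsistent with that identity are recorded with weight 0 (see
    docs/methods.md).
    """
    ref = resources.files("dhaflux.data") / f"fluxes_{substrate}.tsv"
    with resources.as_file(ref) as path:
        return read_flux_dataset(path)
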