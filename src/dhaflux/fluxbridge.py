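"""Kinetic-to-stoichiometric flux validation (the model-coupling bridge).

Tests whether a kinetic steady-state flux set is feasible inside the
constraint-based model at the experimentally observed growth rate: each
supplied flux is pinned to a symmetric relative band, other substrates'
transports are closed, optionally the upper-glycolysis reactions (PGI, PFK,
fructose-bisphosphate aldolase) are left free because the kinetic model
carries no pentose phosphate flux, and biomass is then maximized.  The set is
feasible when the LP is optimal and the achieved growth rate reaches the
target within the same tolerance.

Unit conversion between the kinetic (mmol/min/L) and stoichiometric
(mmol/gDW/h) systems uses the dry-weight assumptions factor 5.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .rates import VOL_PER_GDW_FACTOR
from .stoich import KINETIC_TO_STOICH, SUBSTRATE_EXCHANGES, StoichModel, solve_fba

__all__ = [
    "FluxValidationSpec",
    "FluxValidationResult",
    "convert_flux_set",
    "validate_flux_set",
    "packaged_validation_spec",
    "PPP_RELAX_REACTIONS",
]

#: reactions freed by the pentose-phosphate relaxation
PPP_RELAX_REACTIONS = ("pgi", "pfk", "ald")

#: per-substrate relative tolerance bands of the packaged validations
SUBSTRATE_TOLERANCE = {"glucose": 0.04, "glycerol": 0.10, "ethanol": 0.03}


@dataclass
class FluxValidationSpec:
    """One validation task: fluxes to pin (mmol/gDW/h), band, relaxations."""

    flux_set: dict[str, float]
    tolerance: float
    target_mu: float
    substrate: str
    relax_ppp: bool = False
    zeroed_exchanges: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.tolerance < 1:
            raise ValueError("tolerance must be in [0, 1)")
        if self.target_mu < 0:
            raise ValueError("target_mu must be >= 0")


@dataclass
class FluxValidationResult:
    feasible: bool
    achieved_mu: float
    binding_reactions: list[str]
    relaxations_applied: list[str]
    diagnostics: list[str] = field(default_factory=list)


def convert_flux_set(kinetic_fluxes: dict[str, float],
                     to: str = "gdw_h") -> dict[str, float]:
    """Convert a reaction->flux map between the two unit systems.

    ``to='gdw_h'`` divides by 5.5 (kinetic volumetric -> biomass-specific);
    ``to='vol_min'`` multiplies back.  Round-trips are exact.
    """
    if to == "gdw_h":
        f = 1.0 / VOL_PER_GDW_FACTOR
    elif to == "vol_min":
        f = VOL_PER_GDW_FACTOR
    else:
        raise ValueError(f"unknown unit target {to!r}")
    return {rid: v * f for rid, v in kinetic_fluxes.items()}


def _banded_bounds(flux_set: dict[str, float], tol: float
                   ) -> dict[str, tuple[float, float]]:
    """Symmetric relative bands, sign-preserving; zero fluxes get an absolute
    band of tol x the median nonzero magnitude (a relative band on zero would
    pin the reaction exactly)."""
    nonzero = [abs(v) for v in flux_set.values() if abs(v) > 1e-12]
    abs_band = tol * (float(np.median(nonzero)) if nonzero else 1.0)
    out = {}
    for rid, v in flux_set.items():
        if abs(v) <= 1e-12:
            out[rid] = (-abs_band, abs_band)
        else:
            lo, hi = v * (1 - tol), v * (1 + tol)
            out[rid] = (min(lo, hi), max(lo, hi))
    return out


def validate_flux_set(model: StoichModel,
                      spec: FluxValidationSpec) -> FluxValidationResult:
    """Pin the flux set, close other substrates, maximize biomass.

    On infeasibility, a greedy single-constraint relaxation ranking is
    reported: dropping which single pinned reaction (alone) restores
    feasibility — the automated analogue of discovering by hand that the
    upper-glycolysis reactions needed freeing.
    """
    unknown = set(spec.flux_set) - set(model.network.reactions)
    if unknown:
        raise KeyError(f"flux set contains unknown reactions: {sorted(unknown)}")
    fixed: dict[str, tuple[float, float]] = {}
    # scenario substrate open, everything else closed
    for sub, (ex_id, up_id) in SUBSTRATE_EXCHANGES.items():
        if sub == spec.substrate:
            fixed[ex_id] = (-1000.0, 0.0)   # actual rate pinned via the uptake flux
        else:
            fixed[ex_id] = (0.0, 0.0)
            fixed[up_id] = (0.0, 0.0)
    for rid in spec.zeroed_exchanges:
        fixed[rid] = (0.0, 0.0)
    bands = _banded_bounds(spec.flux_set, spec.tolerance)
    relaxed = []
    for rid, b in bands.items():
        if spec.relax_ppp and rid in PPP_RELAX_REACTIONS:
            relaxed.append(rid)
            continue
        fixed[rid] = b

    sol = solve_fba(model, "biomass", fixed)
    if sol.status == "optimal":
        mu = sol.objective_value
        feasible = mu >= spec.target_mu * (1 - spec.tolerance)
        binding = [
            rid for rid, b in fixed.items()
            if rid in sol.fluxes and (
                abs(sol.fluxes[rid] - b[0]) < 1e-7 or
                abs(sol.fluxes[rid] - b[1]) < 1e-7
            )
        ]
        diag = [] if feasible else [
            f"achieved mu {mu:.4f} below target {spec.target_mu:.4f} "
            f"(tolerance {spec.tolerance:.0%})"
        ]
        return FluxValidationResult(feasible, mu, binding, relaxed, diag)

    # greedy diagnostics: which single pinned reaction unblocks the LP?
    diag = []
    for rid in bands:
        if rid in relaxed:
            continue
        trial = dict(fixed)
        trial.pop(rid, None)
        s2 = solve_fba(model, "biomass", trial)
        if s2.status == "optimal":
            diag.append(f"dropping {rid} restores feasibility "
                        f"(mu {s2.objective_value:.4f})")
    return FluxValidationResult(False, 0.0, [], relaxed,
                                diag or ["no single-constraint relaxation found"])


def packaged_validation_spec(substrate: str,
                             kinetic_fluxes: dict[str, float] | None = None,
                             relax_ppp: bool | None = None
                             ) -> FluxValidationSpec:
    """The packaged per-substrate validation tasks.

    The pinned set is the measured/anchor subset of the kinetic fluxes: the
    substrate's committed entry route, the TCA cycle flux (aconitase) and —
    for glucose and glycerol — the acetyl-CoA output (ACL).  Pinning the full
    kinetic steady-state vector is never biomass-feasible: the kinetic model's
    only carbon exits are CO2 and the acetyl-CoA sink, so its steady state
    commits all carbon and leaves none for the non-lipid part of biomass.
    For ethanol the ACL flux is additionally left free because the printed
    acetyl output together with the observed growth rate over-commits carbon
    (see docs/methods.md); its near-zero glycolytic fluxes are pinned, which
    is exactly what the pentose-phosphate relaxation must undo.

    ``kinetic_fluxes`` (mmol/min/L) defaults to the printed anchor values.
    """
    f = VOL_PER_GDW_FACTOR
    if substrate == "glucose":
        base = {"glc_up": 3.58, "aco": 2.43, "acl": 3.87}
        mu, relax = 0.051, False
    elif substrate == "glycerol":
        base = {"glyc_up": 2.42, "glk": 2.42, "g3pdh": 2.42,
                "aco": 0.90, "acl": 1.44, "pgi": 0.0, "pfk": 0.0, "ald": 0.0}
        mu, relax = 0.023, True
    elif substrate == "ethanol":
        base = {"etoh_up": 7.76, "adh": 7.76, "aldh": 7.76, "acalig": 7.76,
                "aco": 3.00, "pgi": 0.0, "pfk": 0.0, "ald": 0.0}
        mu, relax = 0.046, True
    else:
        raise KeyError(f"no packaged validation for {substrate!r}")
    if kinetic_fluxes is not None:
        base = {KINETIC_TO_STOICH.get(r, r): v for r, v in kinetic_fluxes.items()
                if KINETIC_TO_STOICH.get(r, r) in base}
    if relax_ppp is not None:
        relax = relax_ppp
    return FluxValidationSpec(
        flux_set={rid: v / f for rid, v in base.items()},
        tolerance=SUBSTRATE_TOLERANCE[substrate],
        target_mu=mu,
        substrate=substrate,
        relax_ppp=relax,
    )


# ---------------------------------------------------------------------------
# spec/result JSON I/O
# ---------------------------------------------------------------------------

def write_validation_result(result: FluxValidationResult, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "feasible": result.feasible,
            "achieved_mu": result.achieved_mu,
            "binding_reactions": result.binding_reactions,
            "relaxations_applied": result.relaxations_applied,
            "diagnostics": result.diagnostics,
        }, fh, indent=1)


def read_validation_spec(path) -> FluxValidationSpec:
    with open(path) as fh:
        d = json.load(fh)
    return FluxValidationSpec(
        flux_set=d["flux_set"], tolerance=d["tolerance"],
        target_mu=d["target_mu"], substrate=d["substrate"],
        relax_ppp=d.get("relax_ppp", False),
        zeroed_exchanges=d.get("zeroed_exchanges", []),
    )
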