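"""Synthetic inputs for the analysis pipeline (no downloads required).

Every generator is deterministic under a fixed seed and records its ground
truth, so each downstream estimator has an exact-recovery test at zero noise.

The batch-curve generator emulates the regimes of the cultivation
experiments: exponential growth at mu in the observed 0.017-0.051 /h range
with substrate-proportional consumption, a hard substrate-exhaustion
transition and multiplicative lognormal measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netcore import SUBSTRATE_MOLAR_MASS
from .rates import GrowthCurve

__all__ = [
    "CurveSpec",
    "gen_batch_curve",
    "gen_flux_dataset",
    "gen_biomass_composition",
    "DEFAULT_MACRO_FRACTIONS",
]


@dataclass
class CurveSpec:
    """Ground truth for one synthetic batch cultivation."""

    substrate: str = "glycerol"
    mu_true: float = 0.023        # h-1, the glycerol batch value
    q_s_true: float = 0.44        # mmol/gDW/h
    x0: float = 0.5               # g/L inoculum
    s0: float = 14.0              # g/L initial substrate
    t_end: float = 120.0          # h
    n_points: int = 25
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_true", "q_s_true", "x0", "s0", "t_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not 0 <= self.noise_cv <= 0.2:
            raise ValueError("noise_cv must be in [0, 0.2]")
        if self.substrate not in SUBSTRATE_MOLAR_MASS:
            raise ValueError(f"unknown substrate {self.substrate!r}")


def gen_batch_curve(spec: CurveSpec) -> GrowthCurve:
    """X(t) = x0*exp(mu t) until substrate exhaustion, then flat;
    S(t) = s0 - (q_s*M/1000) * integral X dt, clipped at 0.

    Multiplicative lognormal noise with the given CV is applied to both
    channels; the noiseless truth and the spec are kept in ``metadata``.
    """
    m = SUBSTRATE_MOLAR_MASS[spec.substrate] / 1000.0  # g/mmol
    rate = spec.q_s_true * m                           # g substrate per gDW.h
    # exhaustion time: s0 = rate * x0/mu * (exp(mu t) - 1)
    t_exhaust = np.log(1.0 + spec.s0 * spec.mu_true / (rate * spec.x0)) / spec.mu_true
    t = np.linspace(0.0, spec.t_end, spec.n_points)
    tg = np.minimum(t, t_exhaust)
    x = spec.x0 * np.exp(spec.mu_true * tg)
    s = np.clip(spec.s0 - rate * spec.x0 / spec.mu_true
                * (np.exp(spec.mu_true * tg) - 1.0), 0.0, None)
    x_true, s_true = x.copy(), s.copy()
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = np.sqrt(np.log(1.0 + spec.noise_cv ** 2))
        mu_ln = -0.5 * sigma ** 2  # unit-mean lognormal
        x = x * rng.lognormal(mu_ln, sigma, size=x.shape)
        s = s * rng.lognormal(mu_ln, sigma, size=s.shape)
    return GrowthCurve(
        time=t, biomass=x, substrate={spec.substrate: s},
        metadata={
            "spec": spec, "t_exhaust": float(t_exhaust),
            "biomass_true": x_true, "substrate_true": s_true,
        },
    )


def gen_flux_dataset(model, substrate: str, uptake_rate: float,
                     noise_cv: float = 0.0, seed: int = 0,
                     weight: float = 1.0):
    """Steady-state fluxes of ``model`` under a scenario, multiplicatively
    perturbed — the parameter-recovery harness for the fitting module.

    Returns a :class:`dhaflux.fitting.FluxDataset` whose metadata-free entries
    satisfy node balance exactly at zero noise (they are a steady state).
    """
    from .fitting import FluxDataset
    from .kinetics import configure_scenario, find_steady_state

    scen = configure_scenario(model, substrate, uptake_rate)
    state = find_steady_state(scen)
    rng = np.random.default_rng(seed)
    entries = {}
    for rid, v in state.fluxes.items():
        noisy = v
        if noise_cv > 0:
            sigma = np.sqrt(np.log(1.0 + noise_cv ** 2))
            noisy = v * rng.lognormal(-0.5 * sigma ** 2, sigma)
        entries[rid] = (noisy, weight)
    return FluxDataset(
        label=f"synthetic_{substrate}_cv{noise_cv:g}_seed{seed}",
        entries=entries, substrate=substrate, uptake_rate=uptake_rate,
    )


#: default macromolecular composition, g per gDW; lipid includes the DHA share
DEFAULT_MACRO_FRACTIONS = {
    "protein": 0.45,
    "carbohydrate": 0.25,
    "lipid": 0.20,        # includes DHA
    "rna": 0.06,
    "dna": 0.01,
    "dha": 0.035,         # part of lipid, listed separately for carbon splits
}


def gen_biomass_composition(fraction_overrides: dict[str, float] | None = None):
    """Biomass composition from macromolecule mass fractions.

    Returns a :class:`dhaflux.stoich.BiomassComposition`; precursor
    coefficients (mmol/gDW) are the mass fractions divided by the monomer
    molar masses used by the stoichiometric reconstruction.
    """
    from .stoich import BiomassComposition, composition_from_fractions

    fractions = dict(DEFAULT_MACRO_FRACTIONS)
    if fraction_overrides:
        unknown = set(fraction_overrides) - set(fractions)
        if unknown:
            raise KeyError(f"unknown macromolecule fractions: {sorted(unknown)}")
        fractions.update(fraction_overrides)
    core = [fractions[k] for k in ("protein", "carbohydrate", "lipid", "rna", "dna")]
    if sum(core) > 1.0 + 1e-9:
        raise ValueError("macromolecule fractions sum to more than 1 g/gDW")
    if fractions["dha"] > fractions["lipid"] + 1e-12:
        raise ValueError("DHA fraction cannot exceed the lipid fraction")
    return composition_from_fractions(fractions)
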