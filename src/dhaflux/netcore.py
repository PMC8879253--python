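"""Compartmentalized metabolic networks shared by the kinetic and stoichiometric models.

The central object is :class:`MetabolicNetwork`, a plain container of
compartments, metabolites and reactions.  Both the pathway-scale kinetic model
(glycolysis + glycerol/ethanol entry routes + TCA cycle + citrate export to
cytosolic acetyl-CoA) and the medium-scale constraint-based model are built on
top of it.  Carbon bookkeeping (``n_carbon`` per metabolite) is first-class
because downstream carbon-yield metrics and conservation checks depend on it.

Identifier conventions: lowercase reaction ids (``hk``, ``pgi``, ... ``acl``),
metabolite ids suffixed by compartment (``_e``, ``_c``, ``_m``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Compartment",
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "build_kinetic_network",
    "carbon_count",
    "validate_network",
    "parse_formula",
    "read_network_tables",
    "write_network_tables",
    "read_sbml",
    "write_sbml",
]

_INF = float("inf")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string like ``C6H12O6`` into counts."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"malformed formula: {formula!r}")
    counts: dict[str, int] = {}
    for elem, num in _FORMULA_RE.findall(formula):
        if elem:
            counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    return counts


@dataclass
class Compartment:
    """A cellular compartment with a volume relative to the cytosol."""

    id: str
    name: str = ""
    relative_volume: float = 1.0

    def __post_init__(self) -> None:
        if self.relative_volume <= 0:
            raise ValueError(f"compartment {self.id}: relative_volume must be > 0")


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    n_carbon: int = 0
    is_boundary: bool = False
    #: molar mass in g/mmol * 1000 (g/mol); optional, used for biomass mass checks
    molar_mass: float | None = None

    def __post_init__(self) -> None:
        if self.n_carbon < 0:
            raise ValueError(f"metabolite {self.id}: n_carbon must be >= 0")
        if self.formula is not None:
            n_c = parse_formula(self.formula).get("C", 0)
            if self.n_carbon and self.n_carbon != n_c:
                raise ValueError(
                    f"metabolite {self.id}: n_carbon={self.n_carbon} disagrees "
                    f"with formula {self.formula} (C{n_c})"
                )
            self.n_carbon = n_c


@dataclass
class Reaction:
    """A (possibly transport) reaction with signed stoichiometry.

    Flux bounds are interpreted in whichever unit system the enclosing model
    uses: mmol.min-1.L-1 in the kinetic context, mmol.gDW-1.h-1 in the
    stoichiometric context.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    reversible: bool = False
    lower_bound: float | None = None
    upper_bound: float | None = None
    is_transport: bool = False
    ec_code: str | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound is None:
            self.lower_bound = -_INF if self.reversible else 0.0
        if self.upper_bound is None:
            self.upper_bound = _INF
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"reaction {self.id}: lower_bound > upper_bound")
        if not self.reversible and self.lower_bound < 0:
            raise ValueError(f"reaction {self.id}: irreversible but lower_bound < 0")

    @property
    def substrates(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    @property
    def is_exchange(self) -> bool:
        """Single-species boundary reactions (uptake/secretion)."""
        return len(self.stoichiometry) == 1

    def equation(self) -> str:
        def side(items: Mapping[str, float]) -> str:
            parts = []
            for m in sorted(items):
                c = items[m]
                parts.append(m if c == 1 else f"{c:g} {m}")
            return " + ".join(parts)

        arrow = "<=>" if self.reversible else "->"
        return f"{side(self.substrates)} {arrow} {side(self.products)}".strip()


class MetabolicNetwork:
    """Container of compartments, metabolites and reactions with id lookups."""

    def __init__(
        self,
        compartments: Iterable[Compartment] = (),
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        id: str = "network",
    ) -> None:
        self.id = id
        self.compartments: dict[str, Compartment] = {}
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        for c in compartments:
            self.add_compartment(c)
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    def add_compartment(self, c: Compartment) -> None:
        if c.id in self.compartments:
            raise ValueError(f"duplicate compartment id {c.id}")
        self.compartments[c.id] = c

    def add_metabolite(self, m: Metabolite) -> None:
        if m.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {m.id}")
        self.metabolites[m.id] = m

    def add_reaction(self, r: Reaction) -> None:
        if r.id in self.reactions:
            raise ValueError(f"duplicate reaction id {r.id}")
        self.reactions[r.id] = r

    def reaction_compartments(self, rxn_id: str) -> set[str]:
        r = self.reactions[rxn_id]
        return {
            self.metabolites[m].compartment
            for m in r.stoichiometry
            if m in self.metabolites
        }

    def internal_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.is_boundary]

    def carbon_balance(self, rxn_id: str) -> float:
        """Sum of coefficient * n_carbon over a reaction (0 == balanced)."""
        r = self.reactions[rxn_id]
        return sum(
            c * self.metabolites[m].n_carbon
            for m, c in r.stoichiometry.items()
            if m in self.metabolites
        )

    def copy(self) -> "MetabolicNetwork":
        import copy as _copy

        return _copy.deepcopy(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicNetwork {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites, "
            f"{len(self.compartments)} compartments>"
        )


# ---------------------------------------------------------------------------
# carbon bookkeeping
# ---------------------------------------------------------------------------

#: carbons per molecule for common substrates / species referred to by name
_SUBSTRATE_CARBONS = {
    "glucose": 6,
    "glycerol": 3,
    "ethanol": 2,
    "acetate": 2,
    "acetyl-coa": 2,  # acetyl moiety
    "dha": 22,
    "co2": 1,
    "bicarbonate": 1,
    "water": 0,
    "ammonia": 0,
    "oxygen": 0,
}

#: molar masses (g/mol) of the growth substrates, used for unit conversion
SUBSTRATE_MOLAR_MASS = {
    "glucose": 180.16,
    "glycerol": 92.09,
    "ethanol": 46.07,
    "acetate": 60.05,
}


def carbon_count(name: str, network: MetabolicNetwork | None = None) -> int:
    """Carbons per molecule of a substrate name or a network metabolite id."""
    key = name.strip().lower()
    if key in _SUBSTRATE_CARBONS:
        return _SUBSTRATE_CARBONS[key]
    if network is not None and name in network.metabolites:
        met = network.metabolites[name]
        if met.formula is not None:
            return parse_formula(met.formula).get("C", 0)
        return met.n_carbon
    raise KeyError(f"unknown metabolite or substrate: {name!r}")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_network(
    network: MetabolicNetwork,
    check_elements: bool = False,
    atol: float = 1e-9,
) -> list[str]:
    """Return a list of invariant violations (empty list == valid).

    With ``check_elements`` every non-exchange, non-biomass reaction is checked
    for exact carbon conservation (transports included: a transported species
    keeps its carbons).  Nitrogen is checked additionally for reactions whose
    participants all carry full formulas.
    """
    violations: list[str] = []
    for m in network.metabolites.values():
        if m.compartment not in network.compartments:
            violations.append(f"metabolite {m.id}: unknown compartment {m.compartment}")
    for r in network.reactions.values():
        for met_id in r.stoichiometry:
            if met_id not in network.metabolites:
                violations.append(f"reaction {r.id}: unknown metabolite {met_id}")
        if r.lower_bound > r.upper_bound:
            violations.append(f"reaction {r.id}: lower_bound > upper_bound")
        if not r.reversible and r.lower_bound < 0:
            violations.append(f"reaction {r.id}: irreversible with negative lower bound")
    if not check_elements:
        return violations
    for r in network.reactions.values():
        if r.is_exchange or r.id == "biomass" or "biomass" in r.id:
            continue
        if any(m not in network.metabolites for m in r.stoichiometry):
            continue  # already reported above
        bal = network.carbon_balance(r.id)
        if abs(bal) > atol:
            violations.append(f"reaction {r.id}: carbon imbalance {bal:+g}")
        formulas = {
            m: network.metabolites[m].formula for m in r.stoichiometry
        }
        if all(f is not None for f in formulas.values()):
            n_bal = sum(
                c * parse_formula(formulas[m]).get("N", 0)
                for m, c in r.stoichiometry.items()
            )
            if abs(n_bal) > atol:
                violations.append(f"reaction {r.id}: nitrogen imbalance {n_bal:+g}")
    return violations


# ---------------------------------------------------------------------------
# the pathway-scale kinetic network (3 compartments, 35 reactions, 36 species)
# ---------------------------------------------------------------------------

def _met(id, name, comp, formula=None, n_carbon=0, boundary=False):
    return Metabolite(id, name, comp, formula, n_carbon, boundary)


def build_kinetic_network() -> MetabolicNetwork:
    """The three-compartment substrate-uptake network feeding cytosolic acetyl-CoA.

    Scope: uptake of external glucose / glycerol / ethanol; glycolysis from
    hexokinase to pyruvate kinase; the glycerol entry route (glycerol kinase,
    glycerol-3-phosphate dehydrogenase); the ethanol route (alcohol and
    acetaldehyde dehydrogenases, acetate-CoA ligase); the mitochondrial TCA
    cycle with pyruvate dehydrogenase / carboxylase and malic enzyme; ATP
    citrate lyase in the cytosol; and the pyruvate, acetate, citrate and
    oxaloacetate shuttles plus a cytosolic acetyl-CoA sink standing for fatty
    acid synthesis.  No pentose phosphate pathway, no glutamate dehydrogenase,
    and no energy/redox cofactor moieties.

    CO2 and bicarbonate are boundary species so that every decarboxylation
    (PDH, IDE, OGDH, ME) and the PYC carboxylation balance carbon exactly.
    """
    comps = [
        Compartment("e", "extracellular", 1.0),
        Compartment("c", "cytosol", 1.0),
        Compartment("m", "mitochondria", 0.01),
    ]
    mets = [
        _met("glc_e", "external glucose", "e", "C6H12O6", boundary=True),
        _met("glyc_e", "external glycerol", "e", "C3H8O3", boundary=True),
        _met("etoh_e", "external ethanol", "e", "C2H6O", boundary=True),
        _met("fa_e", "fatty-acid precursor pool (acetyl units)", "e",
             n_carbon=2, boundary=True),
        _met("glc_c", "glucose", "c", "C6H12O6"),
        _met("glyc_c", "glycerol", "c", "C3H8O3"),
        _met("etoh_c", "ethanol", "c", "C2H6O"),
        _met("g6p_c", "glucose 6-phosphate", "c", "C6H13O9P"),
        _met("f6p_c", "fructose 6-phosphate", "c", "C6H13O9P"),
        _met("fdp_c", "fructose 1,6-bisphosphate", "c", "C6H14O12P2"),
        _met("dhap_c", "dihydroxyacetone phosphate", "c", "C3H7O6P"),
        _met("gap_c", "glyceraldehyde 3-phosphate", "c", "C3H7O6P"),
        _met("bpg13_c", "glycerate 1,3-bisphosphate", "c", "C3H8O10P2"),
        _met("pg3_c", "glycerate 3-phosphate", "c", "C3H7O7P"),
        _met("pg2_c", "glycerate 2-phosphate", "c", "C3H7O7P"),
        _met("pep_c", "phosphoenolpyruvate", "c", "C3H5O6P"),
        _met("pyr_c", "pyruvate", "c", "C3H4O3"),
        _met("glyc3p_c", "glycerol 3-phosphate", "c", "C3H9O6P"),
        _met("acald_c", "acetaldehyde", "c", "C2H4O"),
        _met("ac_c", "acetate", "c", "C2H4O2"),
        _met("cit_c", "citrate", "c", "C6H8O7"),
        _met("accoa_c", "acetyl-CoA (acetyl moiety)", "c", n_carbon=2),
        _met("oaa_c", "oxaloacetate", "c", "C4H4O5"),
        _met("pyr_m", "pyruvate", "m", "C3H4O3"),
        _met("ac_m", "acetate", "m", "C2H4O2"),
        _met("accoa_m", "acetyl-CoA (acetyl moiety)", "m", n_carbon=2),
        _met("oaa_m", "oxaloacetate", "m", "C4H4O5"),
        _met("cit_m", "citrate", "m", "C6H8O7"),
        _met("icit_m", "isocitrate", "m", "C6H8O7"),
        _met("akg_m", "2-oxoglutarate", "m", "C5H6O5"),
        _met("succoa_m", "succinyl-CoA (succinyl moiety)", "m", n_carbon=4),
        _met("succ_m", "succinate", "m", "C4H6O4"),
        _met("fum_m", "fumarate", "m", "C4H4O4"),
        _met("mal_m", "malate", "m", "C4H6O5"),
        _met("co2_m", "carbon dioxide", "m", "CO2", boundary=True),
        _met("hco3_m", "bicarbonate", "m", "CHO3", boundary=True),
    ]

    def rxn(id, name, stoich, rev=False, transport=False, ec=None):
        return Reaction(id, name, stoich, reversible=rev, is_transport=transport,
                        ec_code=ec)

    rxns = [
        rxn("glc_up", "glucose uptake", {"glc_e": -1, "glc_c": 1}, transport=True),
        rxn("glyc_up", "glycerol uptake", {"glyc_e": -1, "glyc_c": 1}, transport=True),
        rxn("etoh_up", "ethanol uptake", {"etoh_e": -1, "etoh_c": 1}, transport=True),
        rxn("hk", "hexokinase", {"glc_c": -1, "g6p_c": 1}, ec="2.7.1.1"),
        rxn("pgi", "phosphoglucose isomerase", {"g6p_c": -1, "f6p_c": 1},
            rev=True, ec="5.3.1.9"),
        rxn("pfk", "phosphofructokinase", {"f6p_c": -1, "fdp_c": 1}, ec="2.7.1.11"),
        rxn("ald", "fructose-bisphosphate aldolase",
            {"fdp_c": -1, "dhap_c": 1, "gap_c": 1}, rev=True, ec="4.1.2.13"),
        rxn("tpi", "triosephosphate isomerase", {"dhap_c": -1, "gap_c": 1},
            rev=True, ec="5.3.1.1"),
        rxn("gra3pdh", "glyceraldehyde-3-phosphate dehydrogenase",
            {"gap_c": -1, "bpg13_c": 1}, rev=True, ec="1.2.1.12"),
        rxn("pgk", "3-phosphoglycerate kinase", {"bpg13_c": -1, "pg3_c": 1},
            rev=True, ec="2.7.2.3"),
        rxn("pgm", "phosphoglycerate mutase", {"pg3_c": -1, "pg2_c": 1},
            rev=True, ec="5.4.2.11"),
        rxn("eno", "enolase", {"pg2_c": -1, "pep_c": 1}, rev=True, ec="4.2.1.11"),
        rxn("pyk", "pyruvate kinase", {"pep_c": -1, "pyr_c": 1}, ec="2.7.1.40"),
        rxn("glk", "glycerol kinase", {"glyc_c": -1, "glyc3p_c": 1}, ec="2.7.1.30"),
        rxn("g3pdh", "glycerol-3-phosphate dehydrogenase",
            {"glyc3p_c": -1, "dhap_c": 1}, rev=True, ec="1.1.1.8"),
        rxn("adh", "alcohol dehydrogenase", {"etoh_c": -1, "acald_c": 1},
            rev=True, ec="1.1.1.1"),
        rxn("aldh", "acetaldehyde dehydrogenase", {"acald_c": -1, "ac_c": 1},
            ec="1.2.1.3"),
        rxn("ac_t", "acetate mitochondrial transport", {"ac_c": -1, "ac_m": 1},
            transport=True),
        rxn("acalig", "acetate-CoA ligase", {"ac_m": -1, "accoa_m": 1},
            ec="6.2.1.1"),
        rxn("pyr_t", "pyruvate mitochondrial transport",
            {"pyr_c": -1, "pyr_m": 1}, transport=True),
        rxn("pdh", "pyruvate dehydrogenase",
            {"pyr_m": -1, "accoa_m": 1, "co2_m": 1}, ec="1.2.4.1"),
        rxn("pyc", "pyruvate carboxylase",
            {"pyr_m": -1, "hco3_m": -1, "oaa_m": 1}, ec="6.4.1.1"),
        rxn("cs", "citrate synthase",
            {"accoa_m": -1, "oaa_m": -1, "cit_m": 1}, ec="2.3.3.1"),
        rxn("aco", "aconitase", {"cit_m": -1, "icit_m": 1}, rev=True,
            ec="4.2.1.3"),
        rxn("ide", "isocitrate dehydrogenase",
            {"icit_m": -1, "akg_m": 1, "co2_m": 1}, ec="1.1.1.41"),
        rxn("ogdh", "2-oxoglutarate dehydrogenase",
            {"akg_m": -1, "succoa_m": 1, "co2_m": 1}, ec="1.2.4.2"),
        rxn("ss", "succinyl-CoA synthetase", {"succoa_m": -1, "succ_m": 1},
            rev=True, ec="6.2.1.5"),
        rxn("sde", "succinate dehydrogenase", {"succ_m": -1, "fum_m": 1},
            rev=True, ec="1.3.5.1"),
        rxn("fuh", "fumarase", {"fum_m": -1, "mal_m": 1}, rev=True, ec="4.2.1.2"),
        rxn("mde", "malate dehydrogenase", {"mal_m": -1, "oaa_m": 1},
            rev=True, ec="1.1.1.37"),
        rxn("me", "malic enzyme", {"mal_m": -1, "pyr_m": 1, "co2_m": 1},
            ec="1.1.1.40"),
        rxn("cit_t", "citrate export to cytosol", {"cit_m": -1, "cit_c": 1},
            transport=True),
        rxn("acl", "ATP-citrate lyase", {"cit_c": -1, "accoa_c": 1, "oaa_c": 1},
            ec="2.3.3.8"),
        rxn("oaa_t", "oxaloacetate return to mitochondria",
            {"oaa_c": -1, "oaa_m": 1}, transport=True),
        rxn("accoa_sink", "cytosolic acetyl-CoA sink (fatty acid synthesis)",
            {"accoa_c": -1, "fa_e": 1}, transport=True),
    ]
    return MetabolicNetwork(comps, mets, rxns, id="cohnii_kinetic")


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

_EQ_ARROWS = ("<=>", "->")


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse ``a A + b B -> c C`` (or ``<=>``) into stoichiometry + reversible."""
    for arrow in _EQ_ARROWS:
        if arrow in eq:
            lhs, rhs = eq.split(arrow)
            reversible = arrow == "<=>"
            break
    else:
        raise ValueError(f"no arrow in equation: {eq!r}")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 2:
                coeff, met = float(parts[0]), parts[1]
            elif len(parts) == 1:
                coeff, met = 1.0, parts[0]
            else:
                raise ValueError(f"malformed term {term!r} in {eq!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    return stoich, reversible


def write_network_tables(network: MetabolicNetwork, metabolites_path, reactions_path) -> None:
    import pandas as pd

    mrows = [
        {
            "id": m.id,
            "name": m.name,
            "compartment": m.compartment,
            "formula": m.formula or "",
            "n_carbon": m.n_carbon,
            "boundary": int(m.is_boundary),
        }
        for m in network.metabolites.values()
    ]
    pd.DataFrame(mrows).to_csv(metabolites_path, sep="\t", index=False)
    rrows = [
        {
            "id": r.id,
            "name": r.name,
            "equation": r.equation(),
            "reversible": int(r.reversible),
            "lb": r.lower_bound,
            "ub": r.upper_bound,
            "transport": int(r.is_transport),
        }
        for r in network.reactions.values()
    ]
    pd.DataFrame(rrows).to_csv(reactions_path, sep="\t", index=False)


def read_network_tables(metabolites_path, reactions_path,
                        compartments: Iterable[Compartment] | None = None) -> MetabolicNetwork:
    import pandas as pd

    mdf = pd.read_csv(metabolites_path, sep="\t").fillna({"formula": "", "name": ""})
    rdf = pd.read_csv(reactions_path, sep="\t").fillna({"name": ""})
    mets = [
        Metabolite(
            str(row.id), str(row.name), str(row.compartment),
            str(row.formula) or None, int(row.n_carbon), bool(row.boundary),
        )
        for row in mdf.itertuples()
    ]
    if compartments is None:
        comp_ids = sorted({m.compartment for m in mets})
        compartments = [
            Compartment(cid, cid, 0.01 if cid == "m" else 1.0) for cid in comp_ids
        ]
    rxns = []
    for row in rdf.itertuples():
        stoich, rev_eq = parse_equation(str(row.equation))
        rxns.append(
            Reaction(
                str(row.id), str(row.name), stoich,
                reversible=bool(row.reversible) or rev_eq,
                lower_bound=float(row.lb), upper_bound=float(row.ub),
                is_transport=bool(row.transport),
            )
        )
    return MetabolicNetwork(compartments, mets, rxns)


# ---------------------------------------------------------------------------
# SBML I/O (core constructs; bounds via the fbc package)
# ---------------------------------------------------------------------------

def write_sbml(network: MetabolicNetwork, path) -> None:
    """Export the network as SBML L3V1 with fbc flux bounds."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(network.id)
    fbc_model = model.getPlugin("fbc")
    fbc_model.setStrict(False)

    for c in network.compartments.values():
        sc = model.createCompartment()
        sc.setId(c.id)
        sc.setName(c.name)
        sc.setSize(c.relative_volume)
        sc.setConstant(True)

    for m in network.metabolites.values():
        sp = model.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setBoundaryCondition(m.is_boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
        fbc_sp = sp.getPlugin("fbc")
        if m.formula:
            fbc_sp.setChemicalFormula(m.formula)
        sp.appendNotes(
            f"<body xmlns='http://www.w3.org/1999/xhtml'>"
            f"<p>n_carbon: {m.n_carbon}</p></body>"
        )

    def _bound_param(value: float, pid: str) -> str:
        p = model.createParameter()
        p.setId(pid)
        p.setValue(value if abs(value) != _INF else (1e9 if value > 0 else -1e9))
        p.setConstant(True)
        return pid

    for r in network.reactions.values():
        sr = model.createReaction()
        sr.setId(r.id)
        sr.setName(r.name)
        sr.setReversible(r.reversible)
        sr.setFast(False)
        for met_id, coeff in r.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        fbc_r = sr.getPlugin("fbc")
        fbc_r.setLowerFluxBound(_bound_param(r.lower_bound, f"lb_{r.id}"))
        fbc_r.setUpperFluxBound(_bound_param(r.upper_bound, f"ub_{r.id}"))
        if r.is_transport:
            sr.appendNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'><p>transport: true</p></body>"
            )
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")


def read_sbml(path) -> MetabolicNetwork:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ValueError(f"SBML parse errors in {path}")
    model = doc.getModel()
    comps = [
        Compartment(c.getId(), c.getName() or c.getId(),
                    c.getSize() if c.isSetSize() else 1.0)
        for c in model.getListOfCompartments()
    ]
    mets = []
    for sp in model.getListOfSpecies():
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        if fbc_sp is not None and fbc_sp.isSetChemicalFormula():
            formula = fbc_sp.getChemicalFormula()
        n_carbon = 0
        notes = sp.getNotesString() or ""
        m = re.search(r"n_carbon:\s*(\d+)", notes)
        if m:
            n_carbon = int(m.group(1))
        mets.append(
            Metabolite(sp.getId(), sp.getName() or sp.getId(), sp.getCompartment(),
                       formula, n_carbon, sp.getBoundaryCondition())
        )
    rxns = []
    for sr in model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in sr.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in sr.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        fbc_r = sr.getPlugin("fbc")
        lb, ub = None, None
        if fbc_r is not None:
            if fbc_r.isSetLowerFluxBound():
                p = model.getParameter(fbc_r.getLowerFluxBound())
                lb = p.getValue() if p else None
                if lb is not None and lb <= -1e9:
                    lb = -_INF
            if fbc_r.isSetUpperFluxBound():
                p = model.getParameter(fbc_r.getUpperFluxBound())
                ub = p.getValue() if p else None
                if ub is not None and ub >= 1e9:
                    ub = _INF
        is_transport = "transport: true" in (sr.getNotesString() or "")
        rxns.append(
            Reaction(sr.getId(), sr.getName() or sr.getId(), stoich,
                     reversible=sr.getReversible(), lower_bound=lb,
                     upper_bound=ub, is_transport=is_transport)
        )
    return MetabolicNetwork(comps, mets, rxns, id=model.getId() or "network")
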