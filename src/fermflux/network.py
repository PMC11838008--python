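"""Constraint-based metabolic network layer.

Loads genome-scale models from SBML (via cobrapy) into a lightweight
matrix form, resolves the designated reactions the dynamic FBA needs
(biomass, ATP maintenance, protein synthesis, exchanges), maps kinetic
states to exchange reactions, and decomposes growth-associated ATP
maintenance (GAM) into a base term plus macromolecule polymerization
costs.

Sign convention (COBRA): exchange reactions are written ``met -> ∅``, so
uptake is negative flux and secretion positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "MetabolicNetwork",
    "CompoundMap",
    "CompoundEntry",
    "GamSpec",
    "load_network",
    "toy_network",
    "gam_total",
    "NOISY_COMPOUNDS",
]

#: kinetic states whose measurements carry high relative noise; their
#: exchange bounds are relaxed to inequalities instead of equalities.
NOISY_COMPOUNDS = ("His", "Succ", "Lac", "Mal", "Iobut", "Iamo", "PEA", "PE")


@dataclass
class MetabolicNetwork:
    """Stoichiometric model with designated-reaction roles resolved.

    ``s_matrix`` is (n_metabolites x n_reactions); ``lb``/``ub`` are
    mmol/(gDW·h) except the biomass reaction (1/h). ``boundary`` flags
    exchange/demand/pseudo reactions excluded from elemental balance
    checks; ``carbon`` gives carbon atoms per metabolite where annotated.
    """

    s_matrix: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    reaction_ids: tuple[str, ...]
    metabolite_ids: tuple[str, ...]
    biomass_reaction: str
    atp_maintenance_reaction: str
    protein_reaction: str
    exchange_reactions: tuple[str, ...]
    boundary: tuple[str, ...] = ()
    carbon: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s_matrix = np.asarray(self.s_matrix, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        n_met, n_rxn = self.s_matrix.shape
        if len(self.reaction_ids) != n_rxn or len(self.metabolite_ids) != n_met:
            raise ValueError("identifier lists do not match matrix shape")
        if len(set(self.reaction_ids)) != n_rxn:
            raise ValueError("reaction ids must be unique")
        if np.any(self.lb > self.ub):
            raise ValueError("require lb <= ub for every reaction")
        for role, rid in (
            ("biomass", self.biomass_reaction),
            ("atp_maintenance", self.atp_maintenance_reaction),
            ("protein_synthesis", self.protein_reaction),
        ):
            if rid not in self.reaction_ids:
                raise ValueError(f"designated {role} reaction {rid!r} not in model")
        missing = set(self.exchange_reactions) - set(self.reaction_ids)
        if missing:
            raise ValueError(f"exchange reactions not in model: {sorted(missing)}")
        self._index = {r: i for i, r in enumerate(self.reaction_ids)}

    @property
    def n_reactions(self) -> int:
        return self.s_matrix.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.s_matrix.shape[0]

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self._index[reaction_id]
        except KeyError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    def copy_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.lb.copy(), self.ub.copy()

    def carbon_imbalance(self, reaction_id: str) -> float | None:
        """Net carbon of one reaction column, or None if any participating
        metabolite lacks a carbon annotation."""
        j = self.reaction_index(reaction_id)
        total = 0.0
        for i, met in enumerate(self.metabolite_ids):
            coeff = self.s_matrix[i, j]
            if coeff == 0:
                continue
            if met not in self.carbon:
                return None
            total += coeff * self.carbon[met]
        return total


@dataclass(frozen=True)
class CompoundEntry:
    """One kinetic state mapped to its exchange reaction."""

    state: str
    reaction_id: str
    mw: float  # g/mol
    bound_class: str  # "equality" | "inequality"

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.state}: molecular weight must be > 0")
        if self.bound_class not in ("equality", "inequality"):
            raise ValueError(f"{self.state}: unknown bound class {self.bound_class!r}")


class CompoundMap:
    """Mapping kinetic states -> exchange reactions with molecular weights.

    States in :data:`NOISY_COMPOUNDS` default to the inequality bound class
    (measurement noise too high for an exact equality constraint).
    """

    def __init__(self, entries: Iterable[CompoundEntry]):
        from .kinetics import STATE_INDEX

        self.entries: dict[str, CompoundEntry] = {}
        for e in entries:
            if e.state not in STATE_INDEX:
                raise KeyError(f"unknown kinetic state {e.state!r}")
            if e.state in self.entries:
                raise ValueError(f"duplicate mapping for state {e.state!r}")
            self.entries[e.state] = e
        rxns = [e.reaction_id for e in self.entries.values()]
        if len(set(rxns)) != len(rxns):
            raise ValueError("each exchange reaction may be mapped at most once")

    def __iter__(self):
        return iter(self.entries.values())

    def __contains__(self, state: str) -> bool:
        return state in self.entries

    def __getitem__(self, state: str) -> CompoundEntry:
        return self.entries[state]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, tuple[str, float]]) -> "CompoundMap":
        """Build from {state: (reaction_id, mw)}; bound class defaults by
        the noisy-compound list."""
        entries = [
            CompoundEntry(
                state, rid, mw,
                "inequality" if state in NOISY_COMPOUNDS else "equality",
            )
            for state, (rid, mw) in mapping.items()
        ]
        return cls(entries)

    def to_yaml(self, path) -> None:
        data = {
            e.state: {"reaction": e.reaction_id, "mw": e.mw, "class": e.bound_class}
            for e in self
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CompoundMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            CompoundEntry(state, d["reaction"], d["mw"],
                          d.get("class", "inequality" if state in NOISY_COMPOUNDS
                                 else "equality"))
            for state, d in data.items()
        )


@dataclass(frozen=True)
class GamSpec:
    """Growth-associated ATP maintenance decomposition.

    ``gam_b`` (mmol ATP/gDW) covers non-polymerization growth costs; the
    ``c_*`` coefficients (mmol ATP per g of macromolecule synthesised) are
    literature-style yeast polymerization costs shipped as configuration
    data, not code.
    """

    gam_b: float = 30.0
    c_prot: float = 39.1
    c_rna: float = 7.5
    c_carbs: float = 12.3

    def __post_init__(self) -> None:
        for name in ("gam_b", "c_prot", "c_rna", "c_carbs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"gam_b": self.gam_b, "c_prot": self.c_prot,
                 "c_rna": self.c_rna, "c_carbs": self.c_carbs}, fh)

    @classmethod
    def from_yaml(cls, path) -> "GamSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def gam_total(
    gam: GamSpec,
    macromolecule_rates: Mapping[str, float],
    growth_rate: float = 1.0,
) -> float:
    """Total growth-associated ATP demand, mmol ATP/(gDW·h).

    GAM = gam_b * growth_rate + sum(class cost x class synthesis rate), with
    synthesis rates in g/(gDW·h) for keys among {"protein", "rna",
    "carbohydrate"}. With all polymerization coefficients zero and unit
    growth this reduces to the base term gam_b.
    """
    costs = {"protein": gam.c_prot, "rna": gam.c_rna, "carbohydrate": gam.c_carbs}
    total = gam.gam_b * max(growth_rate, 0.0)
    for cls_name, rate in macromolecule_rates.items():
        if cls_name not in costs:
            raise KeyError(f"unknown macromolecule class {cls_name!r}")
        if rate < 0:
            raise ValueError(f"{cls_name}: synthesis rate must be >= 0")
        total += costs[cls_name] * rate
    return total


# ---------------------------------------------------------------------------
# SBML loading
# ---------------------------------------------------------------------------

def load_network(
    sbml_source,
    biomass_reaction: str,
    atp_maintenance_reaction: str,
    protein_reaction: str,
) -> MetabolicNetwork:
    """Load an SBML (Level 3 FBC) model into a :class:`MetabolicNetwork`.

    Designated reactions are resolved from the given identifiers (so a toy
    model and a genome-scale reconstruction such as Yeast8 share one code
    path); a missing role raises an error naming the role.
    """
    import cobra
    from cobra.util.array import create_stoichiometric_matrix

    model = cobra.io.read_sbml_model(str(sbml_source))
    reaction_ids = tuple(r.id for r in model.reactions)
    for role, rid in (
        ("biomass", biomass_reaction),
        ("atp_maintenance", atp_maintenance_reaction),
        ("protein_synthesis", protein_reaction),
    ):
        if rid not in reaction_ids:
            raise ValueError(
                f"designated {role} reaction {rid!r} not found in SBML model")
    s = create_stoichiometric_matrix(model)
    carbon = {}
    for met in model.metabolites:
        elements = met.elements or {}
        if "C" in elements:
            carbon[met.id] = int(elements["C"])
    return MetabolicNetwork(
        s_matrix=s,
        lb=np.array([r.lower_bound for r in model.reactions]),
        ub=np.array([r.upper_bound for r in model.reactions]),
        reaction_ids=reaction_ids,
        metabolite_ids=tuple(m.id for m in model.metabolites),
        biomass_reaction=biomass_reaction,
        atp_maintenance_reaction=atp_maintenance_reaction,
        protein_reaction=protein_reaction,
        exchange_reactions=tuple(r.id for r in model.exchanges),
        boundary=tuple(r.id for r in model.boundary) + (
            biomass_reaction, atp_maintenance_reaction),
        carbon=carbon,
    )


# ---------------------------------------------------------------------------
# toy network
# ---------------------------------------------------------------------------

#: biomass composition of the toy model: mmol of macromolecule "monomer"
#: per gDW, from 0.59/0.29/0.12 g/gDW at unit monomer masses of 89 g/mol
#: (alanine-like residue), 162 g/mol (anhydroglucose) and 320 g/mol (RNA
#: nucleotide).
TOY_BIOMASS = {"prot": 6.629, "carb": 1.790, "rna": 0.375}


def toy_network() -> MetabolicNetwork:
    """Deterministic ~25-reaction anaerobic yeast stand-in.

    Lumped glycolysis produces ATP and NADH from hexoses; ethanol,
    acetate, succinate and 2,3-butanediol drain pyruvate; glycerol and
    2,3-butanediol re-oxidise NADH (glycerol is the classic anaerobic redox
    valve); amino-acid, protein, carbohydrate and RNA syntheses consume ATP
    and feed a biomass pseudo-reaction; an ATP-maintenance hydrolysis
    carries the GAM demand. Every reaction that chemically transforms
    carbon is carbon-balanced. Small enough that each pFBA sub-problem can
    be checked by exhaustive vertex enumeration.
    """
    mets = ("glc", "fru", "pyr", "nh4", "aa", "atp", "nadh", "eth", "glyc",
            "ace", "succ", "bdo", "co2", "prot", "carb", "rna")
    carbon = {"glc": 6, "fru": 6, "pyr": 3, "nh4": 0, "aa": 3, "atp": 0,
              "nadh": 0, "eth": 2, "glyc": 3, "ace": 2, "succ": 4, "bdo": 4,
              "co2": 1, "prot": 3, "carb": 6, "rna": 6}

    reactions: list[tuple[str, dict[str, float], float, float]] = [
        # exchanges (met -> ∅; uptake negative, secretion positive)
        ("EX_glc", {"glc": -1}, -10.0, 0.0),
        ("EX_fru", {"fru": -1}, -10.0, 0.0),
        ("EX_nh4", {"nh4": -1}, -5.0, 0.0),
        ("EX_aa", {"aa": -1}, -5.0, 5.0),
        ("EX_eth", {"eth": -1}, 0.0, 50.0),
        ("EX_glyc", {"glyc": -1}, 0.0, 50.0),
        ("EX_ace", {"ace": -1}, 0.0, 50.0),
        ("EX_succ", {"succ": -1}, 0.0, 50.0),
        ("EX_bdo", {"bdo": -1}, 0.0, 50.0),
        ("EX_co2", {"co2": -1}, 0.0, 1000.0),
        # central carbon
        ("FRUISO", {"fru": -1, "glc": 1}, 0.0, 10.0),
        ("GLYCO", {"glc": -1, "pyr": 2, "atp": 2, "nadh": 2}, 0.0, 20.0),
        ("PDCADH", {"pyr": -1, "nadh": -1, "eth": 1, "co2": 1}, 0.0, 40.0),
        ("ALDH", {"pyr": -1, "ace": 1, "co2": 1, "nadh": 1}, 0.0, 20.0),
        ("SUCCS", {"pyr": -1, "co2": -1, "nadh": -2, "succ": 1}, 0.0, 20.0),
        ("GLYCS", {"glc": -1, "nadh": -2, "glyc": 2}, 0.0, 20.0),
        # net redox sink per glc routed through GLYCO (+2 NADH) then BDOS
        # (-3 NADH): the butanediol branch drains surplus NADH
        ("BDOS", {"pyr": -2, "nadh": -3, "bdo": 1, "co2": 2}, 0.0, 20.0),
        # cofactor-free overflow routes (carbon waste): keep every kinetic
        # bound combination closable without touching the redox balance
        ("PYRSINK", {"pyr": -1, "co2": 3}, 0.0, 20.0),
        ("GLCSINK", {"glc": -1, "co2": 6}, 0.0, 20.0),
        # anabolism; polymerization ATP costs are charged through the GAM
        # decomposition on ATPM, so syntheses carry only small activation
        # costs (no double counting)
        ("AAS", {"glc": -0.5, "nh4": -1, "atp": -0.5, "aa": 1, "nadh": 1},
         0.0, 20.0),
        ("PROTS", {"aa": -1, "atp": -1, "prot": 1}, 0.0, 40.0),
        ("CARBS", {"glc": -1, "atp": -0.5, "carb": 1}, 0.0, 20.0),
        ("RNAS", {"glc": -0.5, "aa": -1, "atp": -1, "rna": 1}, 0.0, 20.0),
        # pseudo-reactions
        ("GROWTH", {"prot": -TOY_BIOMASS["prot"], "carb": -TOY_BIOMASS["carb"],
                    "rna": -TOY_BIOMASS["rna"]}, 0.0, 2.0),
        ("DM_prot", {"prot": -1}, 0.0, 20.0),
        ("ATPM", {"atp": -1}, 0.0, 1000.0),
    ]

    met_index = {m: i for i, m in enumerate(mets)}
    s = np.zeros((len(mets), len(reactions)))
    lb = np.zeros(len(reactions))
    ub = np.zeros(len(reactions))
    rids = []
    for j, (rid, stoich, lo, hi) in enumerate(reactions):
        rids.append(rid)
        lb[j], ub[j] = lo, hi
        for met, coeff in stoich.items():
            s[met_index[met], j] = coeff

    exchanges = tuple(r for r in rids if r.startswith("EX_"))
    boundary = exchanges + ("GROWTH", "DM_prot", "ATPM")
    return MetabolicNetwork(
        s_matrix=s, lb=lb, ub=ub,
        reaction_ids=tuple(rids), metabolite_ids=mets,
        biomass_reaction="GROWTH",
        atp_maintenance_reaction="ATPM",
        protein_reaction="PROTS",
        exchange_reactions=exchanges,
        boundary=boundary,
        carbon=carbon,
    )


def toy_compound_map() -> CompoundMap:
    """Kinetic-state -> toy-exchange mapping (MW in g/mol)."""
    return CompoundMap.from_mapping({
        "Glx": ("EX_glc", 180.16),
        "F": ("EX_fru", 180.16),
        "NH4Cl": ("EX_nh4", 53.49),
        "Eth": ("EX_eth", 46.07),
        "Glycerol": ("EX_glyc", 92.09),
        "Ace": ("EX_ace", 60.05),
        "Succ": ("EX_succ", 118.09),
    })
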