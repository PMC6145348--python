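"""Chemical species, balanced redox reactions, and kinetic rate laws.

The process set describes the redox cascade of a seasonally stratified
lake water column: aerobic respiration, denitrification, iron and sulfate
reduction, methanogenesis, the corresponding re-oxidation reactions, two
chemolithotrophic denitrification pathways (sulfide- and methane-driven
nitrate reduction), and a first-order sink for reduced sulfur
(precipitation as iron sulfides / organic S).

Stoichiometric balance is checked in exact rational arithmetic; floating
point enters only in the kinetics.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence

import sympy
import yaml

__all__ = [
    "Species",
    "RateLaw",
    "Reaction",
    "ReactionNetwork",
    "check_balance",
    "balance_minimal",
    "rate",
    "knockout",
    "default_network",
]


@dataclass(frozen=True)
class Species:
    """A chemical species tracked by the model.

    Parameters
    ----------
    name : str
        Unique identifier, e.g. ``"HS-"``.
    charge : int
        Net charge in elementary units.
    elements : mapping of element symbol to count
        Elemental composition; counts are nonnegative integers.
    mobile : bool
        Whether the species is transported by turbulent diffusion
        (dissolved) or fixed in place (particulate precipitate).
    """

    name: str
    charge: int = 0
    elements: Mapping[str, int] = field(default_factory=dict)
    mobile: bool = True

    def __post_init__(self):
        for el, n in self.elements.items():
            if not (isinstance(n, int) and n >= 0):
                raise ValueError(
                    f"species {self.name}: element count {el}={n} must be a "
                    "nonnegative integer"
                )


@dataclass(frozen=True)
class RateLaw:
    """Dual-Monod kinetics with optional inhibition.

    ``r = k * [donor]/(K_donor+[donor]) * [acceptor]/(K_acceptor+[acceptor])
    * K_inhibit/(K_inhibit+[inhibitor])``, each factor 1 when its species
    is ``None``.  With ``first_order=True`` the donor factor is replaced by
    the donor concentration itself (``r = k*[donor]``, k in y^-1), used for
    the reduced-sulfur precipitation sink.

    k is in uM y^-1 (or y^-1 when first order); half-saturation and
    inhibition constants are in uM.
    """

    k: float
    donor: str | None = None
    K_donor: float = 1.0
    acceptor: str | None = None
    K_acceptor: float = 1.0
    inhibitor: str | None = None
    K_inhibit: float = 1.0
    first_order: bool = False

    def __post_init__(self):
        if self.k < 0:
            raise ValueError(f"rate constant k={self.k} must be >= 0")
        for nm, K in (
            (self.donor, self.K_donor),
            (self.acceptor, self.K_acceptor),
            (self.inhibitor, self.K_inhibit),
        ):
            if nm is not None and not K > 0:
                raise ValueError(f"half-saturation constant for {nm} must be > 0")


@dataclass(frozen=True)
class Reaction:
    """A balanced reaction: stoichiometry plus a rate law.

    ``stoich`` maps species name to a signed rational coefficient,
    reactants negative and products positive.
    """

    id: str
    process_label: str
    stoich: Mapping[str, Fraction]
    rate_law: RateLaw

    def __post_init__(self):
        stoich = {s: Fraction(c) for s, c in self.stoich.items()}
        object.__setattr__(self, "stoich", stoich)
        if not any(c < 0 for c in stoich.values()) or not any(
            c > 0 for c in stoich.values()
        ):
            raise ValueError(
                f"reaction {self.id}: needs at least one reactant and one product"
            )

    @property
    def reactants(self) -> list[str]:
        return [s for s, c in self.stoich.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [s for s, c in self.stoich.items() if c > 0]


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ValueError("duplicate species names in network")
        self._by_name = {s.name: s for s in self.species}
        for rxn in self.reactions:
            resid = check_balance(rxn, self.species)
            bad = {k: v for k, v in resid.items() if v != 0}
            if bad:
                raise ValueError(f"reaction {rxn.id} is unbalanced: {bad}")

    def species_by_name(self, name: str) -> Species:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}") from None

    @property
    def process_labels(self) -> list[str]:
        return [r.process_label for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"unknown reaction id {rxn_id!r}")

    # ---- YAML round trip -------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "species": [
                {
                    "name": s.name,
                    "charge": s.charge,
                    "elements": dict(s.elements),
                    "mobile": s.mobile,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "id": r.id,
                    "process_label": r.process_label,
                    "stoich": {s: str(c) for s, c in r.stoich.items()},
                    "rate_law": {
                        k: v
                        for k, v in {
                            "k": r.rate_law.k,
                            "donor": r.rate_law.donor,
                            "K_donor": r.rate_law.K_donor,
                            "acceptor": r.rate_law.acceptor,
                            "K_acceptor": r.rate_law.K_acceptor,
                            "inhibitor": r.rate_law.inhibitor,
                            "K_inhibit": r.rate_law.K_inhibit,
                            "first_order": r.rate_law.first_order,
                        }.items()
                        if v is not None
                    },
                }
                for r in self.reactions
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ReactionNetwork":
        doc = yaml.safe_load(text)
        species = [
            Species(
                name=d["name"],
                charge=int(d.get("charge", 0)),
                elements={k: int(v) for k, v in d.get("elements", {}).items()},
                mobile=bool(d.get("mobile", True)),
            )
            for d in doc["species"]
        ]
        reactions = [
            Reaction(
                id=d["id"],
                process_label=d["process_label"],
                stoich={s: Fraction(c) for s, c in d["stoich"].items()},
                rate_law=RateLaw(**d["rate_law"]),
            )
            for d in doc["reactions"]
        ]
        return cls(species=species, reactions=reactions)


def check_balance(
    reaction: Reaction, species: Sequence[Species]
) -> dict[str, Fraction]:
    """Element and charge residuals of a reaction's stoichiometry.

    Returns a map element-symbol (plus ``"charge"``) -> residual
    ``sum_s nu_s * count_s``; an all-zero map means the reaction is
    balanced.  Exact rational arithmetic throughout.
    """
    by_name = {s.name: s for s in species}
    unknown = [n for n in reaction.stoich if n not in by_name]
    if unknown:
        raise KeyError(f"reaction {reaction.id}: unknown species {unknown}")
    residual: dict[str, Fraction] = {}
    for name, coeff in reaction.stoich.items():
        sp = by_name[name]
        for el, n in sp.elements.items():
            residual[el] = residual.get(el, Fraction(0)) + coeff * n
        residual["charge"] = residual.get("charge", Fraction(0)) + coeff * sp.charge
    return residual


def balance_minimal(
    reactant_names: Sequence[str],
    product_names: Sequence[str],
    species: Sequence[Species],
) -> tuple[dict[str, int], dict[str, int]]:
    """Smallest positive integer coefficients balancing the given reaction.

    Solves the element/charge conservation system exactly (sympy rational
    nullspace); requires the positive solution space to be one-dimensional.
    Returns ``(reactant_coeffs, product_coeffs)``, two maps of species name
    to positive, jointly coprime integer coefficients.

    Raises
    ------
    ValueError
        If no strictly positive solution exists or the solution space is
        not one-dimensional.
    KeyError
        If a name is not among the given species.
    """
    by_name = {s.name: s for s in species}
    names = list(reactant_names) + list(product_names)
    for n in names:
        if n not in by_name:
            raise KeyError(f"unknown species {n!r}")

    if sorted(reactant_names) == sorted(product_names):
        # identity reaction: 1 -> 1
        return (
            {n: 1 for n in reactant_names},
            {n: 1 for n in product_names},
        )
    if set(reactant_names) & set(product_names):
        raise ValueError("a species may not appear on both sides")

    signs = [-1] * len(reactant_names) + [1] * len(product_names)
    elements = sorted({el for n in names for el in by_name[n].elements})
    rows = [
        [sg * by_name[n].elements.get(el, 0) for n, sg in zip(names, signs)]
        for el in elements
    ]
    rows.append([sg * by_name[n].charge for n, sg in zip(names, signs)])
    null = sympy.Matrix(rows).nullspace()
    if len(null) != 1:
        raise ValueError(
            f"conservation system has a {len(null)}-dimensional solution space; "
            "cannot balance uniquely"
        )
    vec = [sympy.Rational(x) for x in null[0]]
    scale = sympy.lcm([x.q for x in vec])
    ints = [sympy.Integer(x * scale) for x in vec]
    g = sympy.gcd(ints)
    ints = [int(x / g) for x in ints]
    if all(x < 0 for x in ints):
        ints = [-x for x in ints]
    if any(x <= 0 for x in ints):
        raise ValueError("no strictly positive balancing solution exists")
    n_r = len(reactant_names)
    return (
        dict(zip(reactant_names, ints[:n_r])),
        dict(zip(product_names, ints[n_r:])),
    )


def rate(reaction: Reaction, conc: Mapping[str, float]) -> float:
    """Evaluate the reaction's rate law at the given concentrations (uM).

    Returns the reaction rate in uM y^-1, expressed per mole of electron
    donor (the donor-normalised convention used by the transport model).
    """
    rl = reaction.rate_law
    r = rl.k
    for nm in (rl.donor, rl.acceptor, rl.inhibitor):
        if nm is not None and conc.get(nm, 0.0) < 0:
            raise ValueError(f"negative concentration for {nm}")
    if rl.donor is not None:
        c = conc.get(rl.donor, 0.0)
        r *= c if rl.first_order else c / (rl.K_donor + c)
    if rl.acceptor is not None:
        c = conc.get(rl.acceptor, 0.0)
        r *= c / (rl.K_acceptor + c)
    if rl.inhibitor is not None:
        c = conc.get(rl.inhibitor, 0.0)
        r *= rl.K_inhibit / (rl.K_inhibit + c)
    return r


def knockout(network: ReactionNetwork, process_labels: set[str]) -> ReactionNetwork:
    """A copy of the network with k = 0 for every listed process.

    The original network is left untouched; unknown labels raise KeyError.
    """
    known = set(network.process_labels)
    missing = set(process_labels) - known
    if missing:
        raise KeyError(f"unknown process labels: {sorted(missing)}")
    new_reactions = []
    for rxn in network.reactions:
        if rxn.process_label in process_labels:
            rxn = replace(rxn, rate_law=replace(rxn.rate_law, k=0.0))
        new_reactions.append(rxn)
    return ReactionNetwork(
        species=copy.deepcopy(network.species), reactions=new_reactions
    )


# ---------------------------------------------------------------------------
# Default lake network
# ---------------------------------------------------------------------------

#: Species inventory.  CH2O is the organic-matter proxy; S_ppt is the
#: immobile reduced-sulfur precipitate (same composition as HS-).
DEFAULT_SPECIES: list[Species] = [
    Species("CH2O", 0, {"C": 1, "H": 2, "O": 1}),
    Species("O2", 0, {"O": 2}),
    Species("CO2", 0, {"C": 1, "O": 2}),
    Species("CH4", 0, {"C": 1, "H": 4}),
    Species("NO3-", -1, {"N": 1, "O": 3}),
    Species("NH4+", +1, {"N": 1, "H": 4}),
    Species("N2", 0, {"N": 2}),
    Species("SO42-", -2, {"S": 1, "O": 4}),
    Species("HS-", -1, {"H": 1, "S": 1}),
    Species("S_ppt", -1, {"H": 1, "S": 1}, mobile=False),
    Species("Fe2+", +2, {"Fe": 1}),
    Species("Fe3+", +3, {"Fe": 1}),
    Species("H+", +1, {"H": 1}),
    Species("H2O", 0, {"H": 2, "O": 1}),
]

# default kinetic constants: k in uM/y (precipitation: 1/y), K in uM.
# Magnitudes chosen so the default season develops the canonical redox
# zonation (oxic epilimnion, ferruginous/sulfidic/methanic hypolimnion).
_K_O2_IN = 5.0  # O2 inhibition constant on anaerobic processes

_DEFAULT_REACTIONS: list[tuple] = [
    # (id, label, reactants, products, rate-law kwargs)
    ("R1", "aerobic_heterotrophy", {"CH2O": -1, "O2": -1}, {"CO2": 1, "H2O": 1},
     dict(k=3000.0, donor="CH2O", K_donor=50.0, acceptor="O2", K_acceptor=8.0)),
    ("R2", "denitrification", {"CH2O": -5, "NO3-": -4, "H+": -4},
     {"CO2": 5, "N2": 2, "H2O": 7},
     dict(k=2000.0, donor="CH2O", K_donor=50.0, acceptor="NO3-", K_acceptor=10.0,
          inhibitor="O2", K_inhibit=_K_O2_IN)),
    ("R3", "iron_reduction", {"CH2O": -1, "Fe3+": -4, "H2O": -1},
     {"CO2": 1, "Fe2+": 4, "H+": 4},
     dict(k=600.0, donor="CH2O", K_donor=50.0, acceptor="Fe3+", K_acceptor=20.0,
          inhibitor="O2", K_inhibit=_K_O2_IN)),
    ("R4", "sulfate_reduction", {"CH2O": -2, "SO42-": -1, "H+": -1},
     {"CO2": 2, "HS-": 1, "H2O": 2},
     dict(k=1200.0, donor="CH2O", K_donor=50.0, acceptor="SO42-", K_acceptor=100.0,
          inhibitor="O2", K_inhibit=_K_O2_IN)),
    ("R5", "methanogenesis", {"CH2O": -2}, {"CH4": 1, "CO2": 1},
     dict(k=300.0, donor="CH2O", K_donor=50.0,
          inhibitor="O2", K_inhibit=_K_O2_IN)),
    ("R6", "nitrification", {"NH4+": -1, "O2": -2},
     {"NO3-": 1, "H2O": 1, "H+": 2},
     dict(k=2000.0, donor="NH4+", K_donor=10.0, acceptor="O2", K_acceptor=8.0)),
    ("R7", "methane_ox_o2", {"CH4": -1, "O2": -2}, {"CO2": 1, "H2O": 2},
     dict(k=3000.0, donor="CH4", K_donor=20.0, acceptor="O2", K_acceptor=8.0)),
    ("R8", "methane_ox_so4", {"CH4": -1, "SO42-": -1, "H+": -1},
     {"CO2": 1, "HS-": 1, "H2O": 2},
     dict(k=150.0, donor="CH4", K_donor=20.0, acceptor="SO42-", K_acceptor=100.0,
          inhibitor="O2", K_inhibit=_K_O2_IN)),
    ("R9", "sulfide_ox_o2", {"HS-": -1, "O2": -2}, {"SO42-": 1, "H+": 1},
     dict(k=5000.0, donor="HS-", K_donor=10.0, acceptor="O2", K_acceptor=8.0)),
    ("R10", "iron_ox_o2", {"Fe2+": -4, "O2": -1, "H+": -4},
     {"Fe3+": 4, "H2O": 2},
     dict(k=5000.0, donor="Fe2+", K_donor=20.0, acceptor="O2", K_acceptor=8.0)),
    ("R11", "iron_ox_no3", {"Fe2+": -10, "NO3-": -2, "H+": -12},
     {"Fe3+": 10, "N2": 1, "H2O": 6},
     dict(k=800.0, donor="Fe2+", K_donor=20.0, acceptor="NO3-", K_acceptor=10.0,
          inhibitor="O2", K_inhibit=_K_O2_IN)),
    # The two chemolithotrophic denitrification pathways:
    ("R12", "sulfide_ox_no3", {"HS-": -5, "NO3-": -8, "H+": -3},
     {"SO42-": 5, "N2": 4, "H2O": 4},
     dict(k=1000.0, donor="HS-", K_donor=10.0, acceptor="NO3-", K_acceptor=10.0,
          inhibitor="O2", K_inhibit=_K_O2_IN)),
    ("R13", "methane_ox_no3", {"CH4": -5, "NO3-": -8, "H+": -8},
     {"CO2": 5, "N2": 4, "H2O": 14},
     dict(k=500.0, donor="CH4", K_donor=20.0, acceptor="NO3-", K_acceptor=10.0,
          inhibitor="O2", K_inhibit=_K_O2_IN)),
    # First-order reduced-sulfur precipitation (FeS/pyrite/organic-S proxy)
    ("R14", "sulfur_precipitation", {"HS-": -1}, {"S_ppt": 1},
     dict(k=5.0, donor="HS-", first_order=True)),
]


def default_network(rate_constants: Mapping[str, float] | None = None) -> ReactionNetwork:
    """The 14-process default lake network, all reactions exactly balanced.

    Parameters
    ----------
    rate_constants : optional mapping process_label -> k
        Overrides for individual maximum rate constants (uM y^-1; the
        precipitation constant in y^-1).
    """
    overrides = dict(rate_constants or {})
    reactions = []
    for rid, label, reac, prod, kw in _DEFAULT_REACTIONS:
        if label in overrides:
            kw = dict(kw, k=float(overrides.pop(label)))
        stoich = {s: Fraction(c) for s, c in {**reac, **prod}.items()}
        reactions.append(
            Reaction(id=rid, process_label=label, stoich=stoich, rate_law=RateLaw(**kw))
        )
    if overrides:
        raise KeyError(f"unknown process labels in rate_constants: {sorted(overrides)}")
    return ReactionNetwork(species=copy.deepcopy(DEFAULT_SPECIES), reactions=reactions)
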