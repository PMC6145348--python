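"""1D vertical reactive-transport model of a stratified lake column.

The column is discretised into uniform cells (default 23 x 1 m, matching
a ~23 m lake sampled at 1-2 m intervals).  Mobile species are mixed by a
depth-dependent turbulent diffusivity (two-layer: well-mixed epilimnion
over a quiescent hypolimnion); every species reacts according to the
network's rate laws.  The method-of-lines ODE system

    dC_s/dt = d/dz( D(z) dC_s/dz ) + sum_r nu_{s,r} R_r(C)

is integrated with a stiff solver (LSODA, banded Jacobian structure).

Units: depth m, time days internally; concentrations uM; process rates
are reported in uM y^-1.  H+ and H2O are tracked for stoichiometric
balance only and excluded from the transported state (pH and the water
budget are not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .reaction_network import ReactionNetwork

__all__ = [
    "LakeGrid",
    "ModelState",
    "SimulationResult",
    "Scenario",
    "IntegrationError",
    "two_layer_grid",
    "integrate",
    "process_rate_profile",
    "column_total",
]

DAYS_PER_YEAR = 365.0

#: species never included in transport/kinetics state
EXCLUDED_SPECIES = ("H+", "H2O")


class IntegrationError(RuntimeError):
    """Solver failure; carries the last time reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time: {last_time} d)")
        self.last_time = last_time


@dataclass
class LakeGrid:
    """Uniform vertical grid with per-interface diffusivity.

    ``diffusivity`` holds D at the n_cells-1 interior cell interfaces
    (m^2 day^-1).  ``surface_bc`` maps species name to a fixed surface
    concentration (uM, Dirichlet); species absent from it get zero flux.
    ``bottom_bc`` maps species name to a sediment influx (uM m day^-1,
    Neumann); absent species get zero flux.  Depth increases downward,
    cell centres at (i + 0.5) dz.
    """

    n_cells: int = 23
    dz: float = 1.0
    diffusivity: np.ndarray = field(default_factory=lambda: np.zeros(22))
    surface_bc: dict[str, float] = field(default_factory=dict)
    bottom_bc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.diffusivity = np.asarray(self.diffusivity, dtype=float)
        if self.diffusivity.shape != (self.n_cells - 1,):
            raise ValueError(
                f"diffusivity must have n_cells-1={self.n_cells - 1} interface values"
            )
        if np.any(self.diffusivity < 0):
            raise ValueError("diffusivity must be >= 0 everywhere")

    @property
    def depths(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.dz

    @property
    def total_depth(self) -> float:
        return self.n_cells * self.dz


def two_layer_grid(
    n_cells: int = 23,
    dz: float = 1.0,
    d_epilimnion: float = 50.0,
    d_hypolimnion: float = 0.2,
    thermocline_depth: float = 8.0,
    surface_bc: Mapping[str, float] | None = None,
    bottom_bc: Mapping[str, float] | None = None,
) -> LakeGrid:
    """Two-layer diffusivity: vigorous epilimnetic mixing above the
    thermocline, weak hypolimnetic dispersion below.

    Defaults give a hypolimnetic mixing time (L^2/D ~ 1000 d) much longer
    than a stratified season, so the hypolimnion is effectively isolated.
    """
    iface_depth = np.arange(1, n_cells) * dz
    D = np.where(iface_depth <= thermocline_depth, d_epilimnion, d_hypolimnion)
    return LakeGrid(
        n_cells=n_cells,
        dz=dz,
        diffusivity=D,
        surface_bc=dict(surface_bc or {}),
        bottom_bc=dict(bottom_bc or {}),
    )


@dataclass
class ModelState:
    """Concentration snapshot: time (days) and per-species profiles (uM)."""

    time: float
    conc: dict[str, np.ndarray]

    def copy(self) -> "ModelState":
        return ModelState(self.time, {s: v.copy() for s, v in self.conc.items()})


@dataclass
class SimulationResult:
    """Saved concentration and process-rate fields of one model run.

    ``conc[species]`` is (n_cells, n_times) in uM; ``rates[label]`` is
    (n_cells, n_times) in uM y^-1 (donor-normalised reaction rate).
    ``clipped_mass`` logs the total negative mass removed per species when
    clipping saved states at zero.
    """

    times: np.ndarray
    conc: dict[str, np.ndarray]
    rates: dict[str, np.ndarray]
    grid: LakeGrid
    network: ReactionNetwork
    clipped_mass: dict[str, float] = field(default_factory=dict)

    def state_at(self, index: int) -> ModelState:
        return ModelState(
            float(self.times[index]), {s: v[:, index].copy() for s, v in self.conc.items()}
        )


# ---------------------------------------------------------------------------


def _compile_network(network: ReactionNetwork, species_names: list[str]):
    """Precompute per-reaction index arrays for vectorised rate evaluation.

    Each reaction contributes nu_s/|nu_ref| * r to species s, where ref is
    the electron donor (or the first reactant when no donor is set), so r
    is in donor-consumption units.
    """
    idx = {s: i for i, s in enumerate(species_names)}
    compiled = []
    for rxn in network.reactions:
        rl = rxn.rate_law
        ref = rl.donor if rl.donor is not None else rxn.reactants[0]
        norm = abs(float(rxn.stoich.get(ref, -1)))
        targets = [
            (idx[s], float(c) / norm)
            for s, c in rxn.stoich.items()
            if s in idx
        ]
        compiled.append(
            dict(
                label=rxn.process_label,
                k=rl.k,
                donor=idx.get(rl.donor) if rl.donor else None,
                K_donor=rl.K_donor,
                first_order=rl.first_order,
                acceptor=idx.get(rl.acceptor) if rl.acceptor else None,
                K_acceptor=rl.K_acceptor,
                inhibitor=idx.get(rl.inhibitor) if rl.inhibitor else None,
                K_inhibit=rl.K_inhibit,
                targets=targets,
            )
        )
    return compiled


def _reaction_rates(compiled, C: np.ndarray) -> list[np.ndarray]:
    """Per-reaction rate profiles (uM day^-1) at concentrations C
    (n_species x n_cells, clipped at 0)."""
    Cc = np.maximum(C, 0.0)
    out = []
    for cr in compiled:
        r = np.full(C.shape[1], cr["k"] / DAYS_PER_YEAR)
        if cr["donor"] is not None:
            c = Cc[cr["donor"]]
            r = r * (c if cr["first_order"] else c / (cr["K_donor"] + c))
        if cr["acceptor"] is not None:
            c = Cc[cr["acceptor"]]
            r = r * c / (cr["K_acceptor"] + c)
        if cr["inhibitor"] is not None:
            c = Cc[cr["inhibitor"]]
            r = r * cr["K_inhibit"] / (cr["K_inhibit"] + c)
        out.append(r)
    return out


def integrate(
    grid: LakeGrid,
    network: ReactionNetwork,
    initial: ModelState,
    t_end: float,
    save_every: float,
    tolerance: float = 1e-6,
) -> SimulationResult:
    """Integrate the column model from ``initial.time`` to ``t_end`` days.

    Saves states (clipped at zero, clipped mass logged) and per-process
    rate fields every ``save_every`` days.  Deterministic for fixed inputs.
    """
    if t_end <= initial.time:
        raise ValueError("t_end must exceed the initial time")
    species_names = [
        s.name for s in network.species if s.name not in EXCLUDED_SPECIES
    ]
    mobile = np.array(
        [network.species_by_name(s).mobile for s in species_names], dtype=bool
    )
    n_s, n_z = len(species_names), grid.n_cells
    C0 = np.zeros((n_s, n_z))
    for i, s in enumerate(species_names):
        if s in initial.conc:
            prof = np.asarray(initial.conc[s], dtype=float)
            if prof.shape != (n_z,):
                raise ValueError(f"initial profile for {s} has wrong length")
            if np.any(prof < 0):
                raise ValueError(f"negative initial concentration for {s}")
            C0[i] = prof

    compiled = _compile_network(network, species_names)
    D = grid.diffusivity  # interior interfaces, m^2/day
    dz = grid.dz
    d_surf = D[0] if len(D) else 0.0
    surf_idx = [
        (i, grid.surface_bc[s]) for i, s in enumerate(species_names)
        if s in grid.surface_bc
    ]
    bot_idx = [
        (i, grid.bottom_bc[s]) for i, s in enumerate(species_names)
        if s in grid.bottom_bc
    ]

    def rhs(t, y):
        C = y.reshape(n_z, n_s).T  # state is cell-major for banded structure
        dC = np.zeros_like(C)
        # diffusion of mobile species
        Cm = C[mobile]
        flux = -D * np.diff(Cm, axis=1) / dz          # interior interface fluxes
        dCm = np.zeros_like(Cm)
        dCm[:, :-1] -= flux / dz
        dCm[:, 1:] += flux / dz
        dC[mobile] = dCm
        # boundary conditions
        for i, cbc in surf_idx:
            dC[i, 0] += d_surf * (cbc - C[i, 0]) / (dz / 2.0) / dz
        for i, influx in bot_idx:
            dC[i, -1] += influx / dz
        # reactions
        for cr, r in zip(compiled, _reaction_rates(compiled, C)):
            for si, coeff in cr["targets"]:
                dC[si] += coeff * r
        return dC.T.ravel()

    n_save = int(round((t_end - initial.time) / save_every))
    t_eval = initial.time + save_every * np.arange(n_save + 1)
    t_eval[-1] = t_end

    sol = solve_ivp(
        rhs,
        (initial.time, t_end),
        C0.T.ravel(),
        method="LSODA",
        t_eval=t_eval,
        rtol=tolerance,
        atol=tolerance * 1e-2,
        lband=n_s,
        uband=n_s,
    )
    if not sol.success:
        raise IntegrationError(sol.message, float(sol.t[-1]) if len(sol.t) else initial.time)

    conc: dict[str, np.ndarray] = {}
    clipped: dict[str, float] = {}
    fields = sol.y.reshape(n_z, n_s, -1)  # (cell, species, time)
    for i, s in enumerate(species_names):
        raw = fields[:, i, :]
        clip_amt = float(np.abs(np.minimum(raw, 0.0)).sum() * dz)
        if clip_amt > 0:
            clipped[s] = clip_amt
        conc[s] = np.maximum(raw, 0.0)

    rates = {cr["label"]: np.zeros((n_z, len(sol.t))) for cr in compiled}
    for ti in range(len(sol.t)):
        C = fields[:, :, ti].T
        for cr, r in zip(compiled, _reaction_rates(compiled, C)):
            rates[cr["label"]][:, ti] += r * DAYS_PER_YEAR
    return SimulationResult(
        times=sol.t.copy(),
        conc=conc,
        rates=rates,
        grid=grid,
        network=network,
        clipped_mass=clipped,
    )


def process_rate_profile(
    result: SimulationResult, process_labels: set[str] | Sequence[str]
) -> np.ndarray:
    """Elementwise sum of the rate fields of the listed processes
    (n_cells x n_times, uM y^-1)."""
    labels = list(process_labels)
    missing = [l for l in labels if l not in result.rates]
    if missing:
        raise KeyError(f"unknown process labels: {missing}")
    out = np.zeros_like(next(iter(result.rates.values())))
    for l in sorted(set(labels)):  # deterministic summation order
        out = out + result.rates[l]
    return out


def column_total(result: SimulationResult, species: str) -> float:
    """Concentration summed over all depths and saved time points,
    weighted by cell thickness (uM * m summed over times)."""
    if species not in result.conc:
        raise KeyError(f"unknown species {species!r}")
    return float(result.conc[species].sum() * result.grid.dz)


def element_totals(result: SimulationResult, time_index: int) -> dict[str, float]:
    """Column inventory of each element at one saved time (uM*m),
    computed from the tracked species' compositions."""
    totals: dict[str, float] = {}
    for s, fieldv in result.conc.items():
        sp = result.network.species_by_name(s)
        amount = float(fieldv[:, time_index].sum() * result.grid.dz)
        for el, n in sp.elements.items():
            totals[el] = totals.get(el, 0.0) + n * amount
    return totals


# ---------------------------------------------------------------------------
# Scenario: a self-contained run configuration
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """Everything needed for one reproducible model run."""

    grid: LakeGrid
    network: ReactionNetwork
    initial: ModelState
    t_end: float = 180.0
    save_every: float = 45.0
    tolerance: float = 1e-6

    def run(self, network: ReactionNetwork | None = None) -> SimulationResult:
        return integrate(
            self.grid,
            network if network is not None else self.network,
            self.initial.copy(),
            self.t_end,
            self.save_every,
            self.tolerance,
        )

    def to_yaml(self) -> str:
        doc = {
            "grid": {
                "n_cells": self.grid.n_cells,
                "dz": self.grid.dz,
                "diffusivity": [float(x) for x in self.grid.diffusivity],
                "surface_bc": {k: float(v) for k, v in self.grid.surface_bc.items()},
                "bottom_bc": {k: float(v) for k, v in self.grid.bottom_bc.items()},
            },
            "network": yaml.safe_load(self.network.to_yaml()),
            "initial": {
                "time": float(self.initial.time),
                "conc": {s: [float(x) for x in v] for s, v in self.initial.conc.items()},
            },
            "t_end": float(self.t_end),
            "save_every": float(self.save_every),
            "tolerance": float(self.tolerance),
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "Scenario":
        doc = yaml.safe_load(text)
        g = doc["grid"]
        grid = LakeGrid(
            n_cells=int(g["n_cells"]),
            dz=float(g["dz"]),
            diffusivity=np.asarray(g["diffusivity"], dtype=float),
            surface_bc={k: float(v) for k, v in g.get("surface_bc", {}).items()},
            bottom_bc={k: float(v) for k, v in g.get("bottom_bc", {}).items()},
        )
        network = ReactionNetwork.from_yaml(yaml.safe_dump(doc["network"]))
        initial = ModelState(
            time=float(doc["initial"]["time"]),
            conc={
                s: np.asarray(v, dtype=float)
                for s, v in doc["initial"]["conc"].items()
            },
        )
        return cls(
            grid=grid,
            network=network,
            initial=initial,
            t_end=float(doc["t_end"]),
            save_every=float(doc["save_every"]),
            tolerance=float(doc.get("tolerance", 1e-6)),
        )
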