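"""Seed-reproducible synthetic inputs with the statistical structure the
analysis assumes.

Real inputs to this kind of study — seasonal chemistry casts, marker-gene
depth profiles from shotgun libraries, amplicon and metagenome OTU tables,
contig coverage tables — are not redistributable here, so every stage is
exercised on synthetic data generated from a known truth:

* a stratified-lake scenario whose "true" rate constants are drawn inside
  the calibration bounds and recorded;
* chemistry and gene observations sampled from the true model run with
  multiplicative lognormal noise;
* a community with planted OTU<->MAG pairs (one latent depth-bump
  population expressed through two independently noised OTU tables and a
  set of contigs), partner-less extra OTUs, and flagged control pairs for
  tolerance training.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ParameterSpec
from .community import RANKS, AbundanceMatrix, ContigRecord, TaxonomyPath
from .gene_mapping import (
    DEFAULT_GENE_PROCESS_MAP,
    ChemistryObservation,
    GeneProcessMap,
    GeneProfile,
    l1_normalize,
    modeled_gene_proxy,
)
from .lake_model import (
    LakeGrid,
    ModelState,
    Scenario,
    SimulationResult,
    two_layer_grid,
)
from .reaction_network import default_network

__all__ = [
    "SyntheticTruth",
    "CALIBRATION_BOUNDS",
    "DEFAULT_FREE_PARAMETERS",
    "OBSERVED_CHEMISTRY",
    "default_scenario",
    "make_scenario",
    "make_observations",
    "make_gene_tables",
    "make_community",
    "parameter_specs",
]

#: literature-style search bounds for each process's maximum rate
#: constant (uM y^-1; precipitation y^-1): a factor of 5 either side of
#: the default, the typical spread of published Monod rate constants.
CALIBRATION_BOUNDS: dict[str, tuple[float, float]] = {
    "aerobic_heterotrophy": (600.0, 15000.0),
    "denitrification": (400.0, 10000.0),
    "iron_reduction": (120.0, 3000.0),
    "sulfate_reduction": (240.0, 6000.0),
    "methanogenesis": (60.0, 1500.0),
    "nitrification": (400.0, 10000.0),
    "methane_ox_o2": (600.0, 15000.0),
    "methane_ox_so4": (30.0, 750.0),
    "sulfide_ox_o2": (1000.0, 25000.0),
    "iron_ox_o2": (1000.0, 25000.0),
    "iron_ox_no3": (160.0, 4000.0),
    "sulfide_ox_no3": (200.0, 5000.0),
    "methane_ox_no3": (100.0, 2500.0),
    "sulfur_precipitation": (1.0, 25.0),
}

#: the rate constants left free in the default calibration experiment:
#: the two added nitrate-coupled oxidations plus the two main S/C sinks
#: they compete with.
DEFAULT_FREE_PARAMETERS = (
    "sulfide_ox_no3",
    "methane_ox_no3",
    "sulfate_reduction",
    "methane_ox_o2",
)

#: chemistry species observed by the field campaign
OBSERVED_CHEMISTRY = ("O2", "NO3-", "SO42-", "Fe2+")


def parameter_specs(names: tuple[str, ...] = DEFAULT_FREE_PARAMETERS) -> list[ParameterSpec]:
    """Calibration ParameterSpecs (bounds from CALIBRATION_BOUNDS)."""
    return [
        ParameterSpec(name=n, lower=CALIBRATION_BOUNDS[n][0], upper=CALIBRATION_BOUNDS[n][1])
        for n in names
    ]


def default_scenario(
    rate_constants: dict[str, float] | None = None,
    t_end: float = 180.0,
    save_every: float = 45.0,
    tolerance: float = 1e-6,
) -> Scenario:
    """The default stratified-season scenario: 23 x 1 m column, two-layer
    mixing, oxygen-saturated surface, sediment sources of reduced
    species, run over a ~6-month stratified season."""
    grid = two_layer_grid(
        surface_bc={"O2": 300.0, "CH4": 0.0, "HS-": 0.0, "NH4+": 0.0},
        bottom_bc={"CH4": 50.0, "NH4+": 20.0, "Fe2+": 10.0, "HS-": 5.0, "CH2O": 20.0},
    )
    z = grid.depths
    # smooth initial oxycline / nitracline around the thermocline (8 m)
    s = 1.0 / (1.0 + np.exp((z - 8.0) / 1.5))  # 1 at surface -> 0 at depth
    initial = ModelState(
        time=0.0,
        conc={
            "O2": 300.0 * s + 40.0 * (1 - s),
            "NO3-": 30.0 * s + 15.0 * (1 - s),
            "SO42-": np.full_like(z, 60.0),
            "Fe3+": np.full_like(z, 2.0),
            "Fe2+": np.zeros_like(z),
            "CH4": np.zeros_like(z),
            "HS-": np.zeros_like(z),
            "NH4+": np.zeros_like(z),
            "CH2O": np.full_like(z, 20.0),
            "CO2": np.zeros_like(z),
            "N2": np.zeros_like(z),
            "S_ppt": np.zeros_like(z),
        },
    )
    network = default_network(rate_constants)
    return Scenario(
        grid=grid,
        network=network,
        initial=initial,
        t_end=t_end,
        save_every=save_every,
        tolerance=tolerance,
    )


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate a synthetic study and score
    recovery against it."""

    seed: int
    scenario: Scenario
    true_parameters: dict[str, float]
    noise_sd: dict[str, float] = field(default_factory=dict)
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    control_pairs: list[tuple[str, str]] = field(default_factory=list)


def make_scenario(
    seed: int,
    n_free_params: int = len(DEFAULT_FREE_PARAMETERS),
    **scenario_kwargs,
) -> tuple[SyntheticTruth, SimulationResult]:
    """Known-truth lake scenario: the first ``n_free_params`` free rate
    constants are drawn log-uniformly inside their calibration bounds
    (recorded in the truth); the run uses the default season."""
    rng = np.random.default_rng(seed)
    free = DEFAULT_FREE_PARAMETERS[:n_free_params]
    true_params = {}
    for name in free:
        lo, hi = CALIBRATION_BOUNDS[name]
        # keep truth away from the very edges of the sampled range
        true_params[name] = float(np.exp(rng.uniform(np.log(lo * 1.5), np.log(hi / 1.5))))
    scenario = default_scenario(rate_constants=true_params, **scenario_kwargs)
    result = scenario.run()
    truth = SyntheticTruth(seed=seed, scenario=scenario, true_parameters=true_params)
    return truth, result


def make_observations(
    result: SimulationResult,
    depths: np.ndarray | None = None,
    times: np.ndarray | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    species: tuple[str, ...] = OBSERVED_CHEMISTRY,
) -> list[ChemistryObservation]:
    """Chemistry casts: model values interpolated to the sample points
    with multiplicative lognormal noise (sigma = noise_sd in log space;
    noise_sd=0 reproduces the model exactly)."""
    rng = np.random.default_rng(seed)
    if depths is None:
        depths = np.arange(1.0, result.grid.total_depth, 2.0)
    depths = np.asarray(depths, dtype=float)
    if np.any(depths < 0) or np.any(depths > result.grid.total_depth):
        raise ValueError("sample depth outside the model grid")
    if times is None:
        times = np.asarray(result.times[1:], dtype=float)
    obs = []
    for sp in species:
        for t in np.asarray(times, dtype=float):
            ti = int(np.argmin(np.abs(result.times - t)))
            vals = np.interp(depths, result.grid.depths, result.conc[sp][:, ti])
            if noise_sd > 0:
                vals = vals * rng.lognormal(0.0, noise_sd, size=len(vals))
            obs.append(
                ChemistryObservation(species=sp, time=float(t), depths=depths.copy(), values=vals)
            )
    return obs


def make_gene_tables(
    result: SimulationResult,
    gpm: GeneProcessMap = DEFAULT_GENE_PROCESS_MAP,
    noise_sd: float = 0.1,
    seed: int = 0,
    depths: np.ndarray | None = None,
    sample_time: float | None = None,
) -> list[GeneProfile]:
    """Marker-gene depth profiles under the proportionality assumption:
    the L1-normalised summed rate of the mapped processes, perturbed by
    multiplicative lognormal noise and renormalised."""
    rng = np.random.default_rng(seed)
    if depths is None:
        depths = np.arange(1.0, result.grid.total_depth, 2.0)
    depths = np.asarray(depths, dtype=float)
    t = float(result.times[-1]) if sample_time is None else float(sample_time)
    out = []
    for gene_set in gpm.mapping:
        proxy = modeled_gene_proxy(result, gpm, gene_set, depths, t)
        vals = proxy.values
        if noise_sd > 0:
            vals = vals * rng.lognormal(0.0, noise_sd, size=len(vals))
            vals, _ = l1_normalize(vals)
        out.append(
            GeneProfile(
                gene_set=gene_set,
                sample_depths=depths.copy(),
                values=vals,
                normalization_state="l1",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Community tables with planted OTU <-> MAG matches
# ---------------------------------------------------------------------------


def _toy_taxonomy(rng: np.random.Generator, n_choices: int = 4) -> dict[str, tuple[str, float]]:
    """A random 6-rank path in a toy hierarchy; names encode the rank."""
    return {
        r: (f"{r[0]}_{rng.integers(n_choices)}", float(rng.uniform(60, 100)))
        for r in RANKS
    }


@dataclass
class SyntheticCommunity:
    otu_amplicon: AbundanceMatrix      # raw counts
    otu_metagenomic: AbundanceMatrix   # raw counts
    contigs: list[ContigRecord]
    library_reads: dict[str, int]
    taxonomies: dict[str, TaxonomyPath]
    planted_pairs: list[tuple[str, str]]
    control_pairs: list[tuple[str, str]]
    sample_ids: list[str]


def make_community(
    seed: int,
    n_populations: int = 12,
    n_extra_otus: int = 50,
    n_samples: int = 11,
    noise_sd: float = 0.2,
    n_controls: int = 8,
    partial_tax_fraction: float = 0.25,
) -> SyntheticCommunity:
    """Matched amplicon/metagenome OTU tables and MAG contig records with
    planted one-to-one OTU<->MAG pairs.

    Each population is a latent Gaussian abundance bump over depth.  Its
    amplicon OTU row is multinomial counts over that profile (sequencing
    noise); its metagenome OTU row and its MAG's contig coverages carry
    independent lognormal noise (``noise_sd`` in log space).  At
    ``noise_sd=0`` the generator is fully noise-free: expected counts
    replace the multinomial draw.  Extra OTUs
    have no MAG partner.  Planted pairs share the MAG's assigned
    taxonomy; a ``partial_tax_fraction`` of MAGs are classified only to
    family (genus unassigned), as is common for contig-derived
    taxonomy.  The first ``n_controls`` pairs are flagged known-correct
    for tolerance training.
    """
    if n_controls > n_populations:
        raise ValueError("n_controls must be <= n_populations")
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{j:02d}" for j in range(n_samples)]
    depths = np.linspace(2.0, 22.0, n_samples)

    n_total = n_populations + n_extra_otus
    centers = rng.uniform(2.0, 22.0, size=n_total)
    widths = rng.uniform(1.5, 5.0, size=n_total)
    amps = rng.lognormal(0.0, 1.0, size=n_total)
    latent = amps[:, None] * np.exp(
        -0.5 * ((depths[None, :] - centers[:, None]) / widths[:, None]) ** 2
    ) + 1e-4

    # amplicon table: per-sample multinomial over the community
    # (noise_sd = 0 means a fully noise-free generator: expected counts)
    amp_reads = 50_000
    comp = latent / latent.sum(axis=0, keepdims=True)
    if noise_sd == 0:
        amp_counts = comp * amp_reads
    else:
        amp_counts = np.column_stack(
            [rng.multinomial(amp_reads, comp[:, j]) for j in range(n_samples)]
        ).astype(float)

    # metagenome-derived OTU table: independent lognormal channel
    met_noise = rng.lognormal(0.0, noise_sd, size=latent.shape)
    met_counts = latent * met_noise * 1000.0

    otu_ids = [f"OTU_{i:03d}" for i in range(n_total)]
    planted = list(range(n_populations))
    mag_ids = [f"bin.{i:02d}" for i in planted]

    # MAG contigs: 3-10 contigs whose coverage reproduces the latent
    # profile with lognormal noise
    contigs: list[ContigRecord] = []
    library_reads = {s: int(2_000_000) for s in sample_ids}
    for i, mag in zip(planted, mag_ids):
        n_contigs = int(rng.integers(3, 11))
        lengths = rng.integers(5_000, 200_000, size=n_contigs)
        for ci in range(n_contigs):
            noise = rng.lognormal(0.0, noise_sd, size=n_samples)
            cov = latent[i] * 50.0 * noise
            contigs.append(
                ContigRecord(
                    contig_id=f"{mag}_c{ci}",
                    bin_id=mag,
                    length=int(lengths[ci]),
                    coverage=dict(zip(sample_ids, cov)),
                )
            )

    # taxonomies: each planted MAG shares its OTU's path, sometimes
    # classified only down to family (shallow contig-based assignment)
    taxonomies: dict[str, TaxonomyPath] = {}
    for i, otu in enumerate(otu_ids):
        taxonomies[otu] = TaxonomyPath(feature_id=otu, ranks=_toy_taxonomy(rng))
    for i, mag in zip(planted, mag_ids):
        ranks = dict(taxonomies[otu_ids[i]].ranks)
        if rng.random() < partial_tax_fraction:
            ranks["genus"] = ("unassigned", 0.0)
        taxonomies[mag] = TaxonomyPath(feature_id=mag, ranks=ranks)

    amp = AbundanceMatrix(
        table=pd.DataFrame(amp_counts, index=otu_ids, columns=sample_ids)
    )
    met = AbundanceMatrix(
        table=pd.DataFrame(met_counts, index=otu_ids, columns=sample_ids)
    )
    pairs = [(otu_ids[i], mag) for i, mag in zip(planted, mag_ids)]
    return SyntheticCommunity(
        otu_amplicon=amp,
        otu_metagenomic=met,
        contigs=contigs,
        library_reads=library_reads,
        taxonomies=taxonomies,
        planted_pairs=pairs,
        control_pairs=pairs[:n_controls],
        sample_ids=sample_ids,
    )
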