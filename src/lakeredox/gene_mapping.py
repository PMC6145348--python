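"""Functional-gene profiles, gene-to-process proxies, and the fit metric.

Marker-gene read counts are normalised to copies per million within each
sample (library-size normalisation) and then L1-normalised across the
depth profile of each gene, so a profile describes *where* in the column
a gene is abundant, not *how* abundant.  Under the proportionality
assumption — the relative depth distribution of a marker gene tracks the
relative rates of the processes its enzymes mediate — the modelled
counterpart of a gene profile is the L1-normalised sum of the mapped
process-rate fields.  The calibration objective averages the mean
absolute error (MAE) over all chemistry and gene observables, each
L1-normalised so they share a scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .lake_model import SimulationResult, process_rate_profile

__all__ = [
    "GeneProfile",
    "GeneProcessMap",
    "FitObjective",
    "DEFAULT_GENE_PROCESS_MAP",
    "normalize_gene_profile",
    "modeled_gene_proxy",
    "mae",
    "build_objective",
    "l1_normalize",
]


@dataclass
class GeneProfile:
    """Depth profile of one marker-gene set's relative abundance."""

    gene_set: str
    sample_depths: np.ndarray
    values: np.ndarray
    normalization_state: str = "raw"  # raw | cpm | l1
    all_zero: bool = False

    def __post_init__(self):
        self.sample_depths = np.asarray(self.sample_depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError(f"gene profile {self.gene_set}: negative values")


@dataclass
class GeneProcessMap:
    """Map gene_set -> list of modelled process labels it reports on."""

    mapping: dict[str, list[str]]

    def processes_for(self, gene_set: str) -> list[str]:
        try:
            return self.mapping[gene_set]
        except KeyError:
            raise KeyError(f"gene set {gene_set!r} not in gene-process map") from None

    def validate(self, process_labels: Sequence[str]) -> None:
        known = set(process_labels)
        for g, procs in self.mapping.items():
            missing = [p for p in procs if p not in known]
            if missing:
                raise ValueError(f"gene set {g}: unknown processes {missing}")


#: marker-gene sets and the processes whose summed rates proxy them.
#: pmoABC (particulate monooxygenase) co-metabolises ammonia and methane;
#: dsrAB runs forward (sulfate reduction) and reverse (sulfide oxidation);
#: nosDZ covers both organotrophic and lithotrophic denitrification.
DEFAULT_GENE_PROCESS_MAP = GeneProcessMap(
    {
        "pmoABC": ["nitrification", "methane_ox_o2", "methane_ox_so4"],
        "dsrAB": [
            "sulfate_reduction",
            "sulfide_ox_o2",
            "sulfide_ox_no3",
        ],
        "nosDZ": [
            "denitrification",
            "iron_ox_no3",
            "sulfide_ox_no3",
            "methane_ox_no3",
        ],
        "mxaCGKL": ["methane_ox_o2", "methane_ox_so4"],
        "hao": ["nitrification"],
        "ironred": ["iron_reduction"],
    }
)


def l1_normalize(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Divide by the sum; an all-zero vector is returned unchanged with a
    flag (and a warning)."""
    values = np.asarray(values, dtype=float)
    total = values.sum()
    if total == 0:
        warnings.warn("L1 normalization of an all-zero profile", stacklevel=2)
        return values.copy(), True
    return values / total, False


def normalize_gene_profile(
    gene_set: str,
    counts: np.ndarray,
    library_sizes: np.ndarray,
    sample_depths: np.ndarray | None = None,
) -> GeneProfile:
    """CPM then L1: counts / library_size * 1e6 per sample, then divided
    by the sum across samples."""
    counts = np.asarray(counts, dtype=float)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative gene counts")
    if np.any(library_sizes <= 0):
        raise ValueError("library sizes must be > 0")
    cpm = counts / library_sizes * 1e6
    values, all_zero = l1_normalize(cpm)
    depths = (
        np.arange(len(counts), dtype=float)
        if sample_depths is None
        else np.asarray(sample_depths, dtype=float)
    )
    return GeneProfile(
        gene_set=gene_set,
        sample_depths=depths,
        values=values,
        normalization_state="l1",
        all_zero=all_zero,
    )


def modeled_gene_proxy(
    result: SimulationResult,
    gpm: GeneProcessMap,
    gene_set: str,
    sample_depths: Sequence[float],
    sample_time: float,
) -> GeneProfile:
    """L1-normalised summed rate of the processes mapped to a gene set,
    linearly interpolated to the sample depths at the nearest saved time."""
    labels = gpm.processes_for(gene_set)
    field_rates = process_rate_profile(result, labels)
    depths = np.asarray(sample_depths, dtype=float)
    grid_depths = result.grid.depths
    if np.any(depths < 0) or np.any(depths > result.grid.total_depth):
        raise ValueError("sample depth outside the model grid")
    ti = int(np.argmin(np.abs(result.times - sample_time)))
    profile = np.interp(depths, grid_depths, field_rates[:, ti])
    values, all_zero = l1_normalize(profile)
    return GeneProfile(
        gene_set=gene_set,
        sample_depths=depths,
        values=values,
        normalization_state="l1",
        all_zero=all_zero,
    )


def mae(observed: np.ndarray, modeled: np.ndarray) -> float:
    """Mean absolute error between two equal-length profiles."""
    observed = np.asarray(observed, dtype=float)
    modeled = np.asarray(modeled, dtype=float)
    if observed.shape != modeled.shape:
        raise ValueError(
            f"profile length mismatch: {observed.shape} vs {modeled.shape}"
        )
    return float(np.mean(np.abs(observed - modeled)))


@dataclass
class FitObjective:
    """Per-observable MAEs and their unweighted mean (the calibration
    objective)."""

    observables: list[tuple[str, str]]  # (kind, name)
    per_observable_mae: list[float]
    weights: np.ndarray | None = None

    @property
    def average_mae(self) -> float:
        maes = np.asarray(self.per_observable_mae)
        if self.weights is None:
            return float(maes.mean())
        w = np.asarray(self.weights, dtype=float)
        return float((maes * w).sum() / w.sum())


@dataclass
class ChemistryObservation:
    """Observed depth profile of one species at one sample time (uM)."""

    species: str
    time: float
    depths: np.ndarray
    values: np.ndarray


def build_objective(
    result: SimulationResult,
    chem_obs: Sequence[ChemistryObservation],
    gene_obs: Sequence[GeneProfile],
    gpm: GeneProcessMap,
    gene_sample_time: float | None = None,
    weights: np.ndarray | None = None,
) -> FitObjective:
    """One MAE per chemistry (species, time) profile and one per gene set;
    chemistry profiles are L1-normalised per profile so chemistry and
    gene observables share the [0, 1] scale of relative distributions."""
    names: list[tuple[str, str]] = []
    maes: list[float] = []
    for obs in chem_obs:
        if obs.species not in result.conc:
            raise KeyError(f"missing observable: species {obs.species!r}")
        ti = int(np.argmin(np.abs(result.times - obs.time)))
        modeled = np.interp(
            np.asarray(obs.depths, dtype=float),
            result.grid.depths,
            result.conc[obs.species][:, ti],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs_n, _ = l1_normalize(obs.values)
            mod_n, _ = l1_normalize(modeled)
        names.append(("chemistry", f"{obs.species}@t={obs.time:g}"))
        maes.append(mae(obs_n, mod_n))
    t_gene = gene_sample_time if gene_sample_time is not None else float(result.times[-1])
    for gp in gene_obs:
        proxy = modeled_gene_proxy(result, gpm, gp.gene_set, gp.sample_depths, t_gene)
        names.append(("gene", gp.gene_set))
        maes.append(mae(gp.values, proxy.values))
    return FitObjective(observables=names, per_observable_mae=maes, weights=weights)
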