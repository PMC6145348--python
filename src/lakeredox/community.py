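"""Linking 16S OTUs to metagenome-assembled genomes (MAGs).

An OTU and a MAG that represent the same population should co-vary in
abundance across samples and agree taxonomically.  Both signals are
combined into one score:

    m = ||a_otu - a_mag||_2 - f

where the abundance vectors are L1-normalised along both axes (within
samples first, then within each feature) and f is the fraction of the
MAG's assigned taxonomic ranks (kingdom..genus, each rank compared
independently) that the OTU matches.  m = -1 is a perfect match
(identical relative abundance profile, full taxonomic agreement).  The
acceptance threshold is trained on control pairs of known identity: the
smallest tolerance admitting every control.  A pair is accepted only if
it passes in both the amplicon-derived and the metagenome-derived OTU
dataset.

MAG abundance in sample j is the length-weighted mean contig coverage
A_j = sum_i l_i c_ij / sum_i l_i, divided by the library read count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import spearmanr

__all__ = [
    "ContigRecord",
    "AbundanceMatrix",
    "TaxonomyPath",
    "MatchCandidate",
    "RANKS",
    "bin_abundance",
    "bin_abundance_table",
    "dual_l1_normalize",
    "taxonomy_fraction",
    "combined_distance",
    "train_tolerance",
    "match",
    "filter_taxonomy",
    "cluster_gene_content",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ContigRecord:
    contig_id: str
    bin_id: str
    length: int
    coverage: Mapping[str, float]  # sample_id -> mean depth

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"contig {self.contig_id}: length must be > 0")
        if any(c < 0 for c in self.coverage.values()):
            raise ValueError(f"contig {self.contig_id}: negative coverage")


def bin_abundance(
    contigs: Sequence[ContigRecord], sample: str, library_reads: int | None = None
) -> float:
    """Length-weighted mean coverage of a bin in one sample,
    A_j = sum(l_i c_ij) / sum(l_i), optionally divided by the library's
    read count."""
    if not contigs:
        raise ValueError("bin has no contigs")
    total_len = sum(c.length for c in contigs)
    if total_len == 0:
        raise ValueError("zero total contig length")
    a = sum(c.length * c.coverage.get(sample, 0.0) for c in contigs) / total_len
    if library_reads is not None:
        if library_reads <= 0:
            raise ValueError("library_reads must be > 0")
        a /= library_reads
    return a


def bin_abundance_table(
    contigs: Sequence[ContigRecord],
    sample_ids: Sequence[str],
    library_reads: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """MAG x sample abundance table from contig records."""
    bins: dict[str, list[ContigRecord]] = {}
    for c in contigs:
        bins.setdefault(c.bin_id, []).append(c)
    rows = {
        b: [
            bin_abundance(cs, s, library_reads[s] if library_reads else None)
            for s in sample_ids
        ]
        for b, cs in sorted(bins.items())
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(sample_ids))


@dataclass
class AbundanceMatrix:
    """Feature (OTU or MAG) x sample abundance table with an explicit
    normalisation state."""

    table: pd.DataFrame
    normalization_state: str = "raw"  # raw | dual_l1

    def __post_init__(self):
        if (self.table.values < 0).any():
            raise ValueError("negative abundances")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.columns)

    def row(self, feature_id: str) -> np.ndarray:
        return self.table.loc[feature_id].to_numpy(dtype=float)


def dual_l1_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """L1 along both axes: within samples (columns) first, then within
    each feature (row).  Zero columns/rows stay zero."""
    if matrix.normalization_state != "raw":
        raise ValueError("dual_l1_normalize expects a raw matrix")
    vals = matrix.table.to_numpy(dtype=float)
    col_sums = vals.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(col_sums > 0, vals / col_sums, 0.0)
    row_sums = vals.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(row_sums > 0, vals / row_sums, 0.0)
    out = pd.DataFrame(vals, index=matrix.table.index, columns=matrix.table.columns)
    return AbundanceMatrix(table=out, normalization_state="dual_l1")


@dataclass
class TaxonomyPath:
    """RDP-style fixed-rank classification, kingdom to genus, each rank a
    (name, confidence 0-100) pair; ``UNASSIGNED`` marks removed ranks."""

    feature_id: str
    ranks: dict[str, tuple[str, float]] = field(default_factory=dict)

    def assigned(self) -> dict[str, str]:
        return {
            r: n
            for r, (n, _) in self.ranks.items()
            if n != UNASSIGNED
        }


def filter_taxonomy(
    paths: Sequence[TaxonomyPath], min_conf: float = 50.0
) -> list[TaxonomyPath]:
    """RDP fixed-rank output filter: ranks with confidence below the
    threshold, or named Incertae Sedis, become unassigned.  Ranks are
    independent — a removed phylum does not remove an above-threshold
    genus."""
    out = []
    for p in paths:
        new_ranks = {}
        for r, (name, conf) in p.ranks.items():
            if conf < min_conf or "incertae sedis" in name.lower():
                new_ranks[r] = (UNASSIGNED, conf)
            else:
                new_ranks[r] = (name, conf)
        out.append(TaxonomyPath(feature_id=p.feature_id, ranks=new_ranks))
    return out


def taxonomy_fraction(otu_tax: TaxonomyPath, mag_tax: TaxonomyPath) -> float:
    """Fraction of the MAG's assigned ranks that the OTU matches, each
    rank compared independently; the MAG taxonomy is the denominator."""
    mag_assigned = mag_tax.assigned()
    if not mag_assigned:
        raise ValueError(
            f"MAG {mag_tax.feature_id}: taxonomy fully unassigned"
        )
    otu_assigned = otu_tax.assigned()
    hits = sum(
        1 for r, name in mag_assigned.items() if otu_assigned.get(r) == name
    )
    return hits / len(mag_assigned)


def combined_distance(
    otu_row: np.ndarray, mag_row: np.ndarray, f: float
) -> float:
    """Euclidean distance between dual-L1 rows minus the taxonomy match
    fraction; -1 is a perfect match."""
    otu_row = np.asarray(otu_row, dtype=float)
    mag_row = np.asarray(mag_row, dtype=float)
    if otu_row.shape != mag_row.shape:
        raise ValueError("abundance rows have different sample sets")
    return float(np.linalg.norm(otu_row - mag_row) - f)


def train_tolerance(control_scores: Sequence[float]) -> float:
    """Smallest threshold admitting every known-correct control pair,
    i.e. the maximum control score."""
    if len(control_scores) == 0:
        raise ValueError("no control pairs to train on")
    return float(max(control_scores))


@dataclass
class MatchCandidate:
    otu_id: str
    mag_id: str
    d_amplicon: float
    d_metagenomic: float
    f: float
    m_amplicon: float
    m_metagenomic: float
    accepted: bool


def _score_pairs(
    otus: AbundanceMatrix,
    mags: AbundanceMatrix,
    taxonomies: Mapping[str, TaxonomyPath],
) -> dict[tuple[str, str], tuple[float, float]]:
    scores = {}
    for otu in otus.feature_ids:
        for mag in mags.feature_ids:
            f = taxonomy_fraction(taxonomies[otu], taxonomies[mag])
            d = float(np.linalg.norm(otus.row(otu) - mags.row(mag)))
            scores[(otu, mag)] = (d, f)
    return scores


def match(
    otu_amplicon: AbundanceMatrix,
    otu_metagenomic: AbundanceMatrix,
    mags: AbundanceMatrix,
    taxonomies: Mapping[str, TaxonomyPath],
    tol_amplicon: float,
    tol_metagenomic: float,
    one_to_one: bool = True,
) -> list[MatchCandidate]:
    """Assign OTUs to MAGs.

    A pair is accepted only if its combined score passes the trained
    tolerance in *both* datasets.  Assignment is greedy one-to-one by
    ascending amplicon score (ties broken lexicographically by ids);
    ``one_to_one=False`` accepts every pair under both tolerances.
    """
    for mat in (otu_amplicon, otu_metagenomic, mags):
        if mat.normalization_state != "dual_l1":
            raise ValueError("matrices must be dual_l1-normalised")
    shared = set(otu_amplicon.sample_ids) & set(mags.sample_ids)
    if not shared:
        raise ValueError("amplicon and MAG tables share no samples")
    common_otus = [
        o for o in otu_amplicon.feature_ids if o in set(otu_metagenomic.feature_ids)
    ]

    s_amp = _score_pairs(otu_amplicon, mags, taxonomies)
    s_met = _score_pairs(otu_metagenomic, mags, taxonomies)

    candidates = []
    for otu in common_otus:
        for mag in mags.feature_ids:
            d_a, f = s_amp[(otu, mag)]
            d_m, _ = s_met[(otu, mag)]
            candidates.append(
                MatchCandidate(
                    otu_id=otu,
                    mag_id=mag,
                    d_amplicon=d_a,
                    d_metagenomic=d_m,
                    f=f,
                    m_amplicon=d_a - f,
                    m_metagenomic=d_m - f,
                    accepted=False,
                )
            )
    candidates.sort(key=lambda c: (c.m_amplicon, c.otu_id, c.mag_id))
    used_otus: set[str] = set()
    used_mags: set[str] = set()
    for c in candidates:
        if c.m_amplicon > tol_amplicon or c.m_metagenomic > tol_metagenomic:
            continue
        if one_to_one and (c.otu_id in used_otus or c.mag_id in used_mags):
            continue
        c.accepted = True
        used_otus.add(c.otu_id)
        used_mags.add(c.mag_id)
    return candidates


def cluster_gene_content(profiles: pd.DataFrame) -> np.ndarray:
    """Complete-linkage hierarchical clustering on 1 - Spearman rank
    correlation of feature gene-content profiles.

    Returns a scipy linkage matrix; features are clustered in the
    (lexicographically sorted) row order of ``profiles``.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 features to cluster")
    profiles = profiles.sort_index()
    vals = profiles.to_numpy(dtype=float)
    for fid, row in zip(profiles.index, vals):
        if np.ptp(row) == 0:
            raise ValueError(
                f"feature {fid}: constant profile, Spearman undefined"
            )
    rho = spearmanr(vals, axis=1).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for two variables
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - rho
    iu = np.triu_indices(len(vals), k=1)
    return hierarchy.linkage(dist[iu], method="complete")
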