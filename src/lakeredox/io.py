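"""Plain-text table formats shared by the CLI, the drivers, and the
validators.

* OTU / MAG tables: TSV, rows = feature ids, columns = sample ids.
* Contig records: TSV with contig_id, bin_id, length_bp, then one
  ``cov_<sample>`` column per sample.
* Taxonomy: RDP fixed-rank dialect — feature_id, then a name and a
  confidence column per rank, kingdom to genus.
* Chemistry observations: long TSV with sample_id, depth_m, time_day,
  observable, value.
* Gene profiles: TSV with gene_set, depth_m, value.
* Simulation output: one TSV per species/process, rows = depth,
  columns = saved times.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .community import RANKS, AbundanceMatrix, ContigRecord, TaxonomyPath
from .gene_mapping import ChemistryObservation, GeneProfile
from .lake_model import SimulationResult

__all__ = [
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_contigs_tsv",
    "write_contigs_tsv",
    "read_taxonomy_tsv",
    "write_taxonomy_tsv",
    "read_observations_tsv",
    "write_observations_tsv",
    "read_gene_profiles_tsv",
    "write_gene_profiles_tsv",
    "write_simulation_tsvs",
]


def read_abundance_tsv(path: str | Path) -> AbundanceMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    return AbundanceMatrix(table=table)


def write_abundance_tsv(matrix: AbundanceMatrix, path: str | Path) -> None:
    matrix.table.to_csv(path, sep="\t", index_label="feature_id")


def write_contigs_tsv(contigs: Sequence[ContigRecord], path: str | Path) -> None:
    samples = sorted({s for c in contigs for s in c.coverage})
    rows = [
        {
            "contig_id": c.contig_id,
            "bin_id": c.bin_id,
            "length_bp": c.length,
            **{f"cov_{s}": c.coverage.get(s, 0.0) for s in samples},
        }
        for c in contigs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_contigs_tsv(path: str | Path) -> list[ContigRecord]:
    df = pd.read_csv(path, sep="\t")
    cov_cols = [c for c in df.columns if c.startswith("cov_")]
    return [
        ContigRecord(
            contig_id=str(r["contig_id"]),
            bin_id=str(r["bin_id"]),
            length=int(r["length_bp"]),
            coverage={c[4:]: float(r[c]) for c in cov_cols},
        )
        for _, r in df.iterrows()
    ]


def write_taxonomy_tsv(paths: Sequence[TaxonomyPath], out: str | Path) -> None:
    rows = []
    for p in paths:
        row: dict = {"feature_id": p.feature_id}
        for r in RANKS:
            name, conf = p.ranks.get(r, ("unassigned", 0.0))
            row[r] = name
            row[f"{r}_conf"] = conf
        rows.append(row)
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)


def read_taxonomy_tsv(path: str | Path) -> list[TaxonomyPath]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        ranks = {
            rank: (str(r[rank]), float(r[f"{rank}_conf"]))
            for rank in RANKS
            if rank in df.columns
        }
        out.append(TaxonomyPath(feature_id=str(r["feature_id"]), ranks=ranks))
    return out


def write_observations_tsv(
    obs: Sequence[ChemistryObservation], path: str | Path
) -> None:
    rows = []
    for o in obs:
        for d, v in zip(o.depths, o.values):
            rows.append(
                {
                    "sample_id": f"{o.species}_t{o.time:g}_d{d:g}",
                    "depth_m": d,
                    "time_day": o.time,
                    "observable": o.species,
                    "value": v,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_observations_tsv(path: str | Path) -> list[ChemistryObservation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (sp, t), grp in df.groupby(["observable", "time_day"], sort=True):
        grp = grp.sort_values("depth_m")
        out.append(
            ChemistryObservation(
                species=str(sp),
                time=float(t),
                depths=grp["depth_m"].to_numpy(float),
                values=grp["value"].to_numpy(float),
            )
        )
    return out


def write_gene_profiles_tsv(
    profiles: Sequence[GeneProfile], path: str | Path
) -> None:
    rows = [
        {"gene_set": p.gene_set, "depth_m": d, "value": v}
        for p in profiles
        for d, v in zip(p.sample_depths, p.values)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_profiles_tsv(path: str | Path) -> list[GeneProfile]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for g, grp in df.groupby("gene_set", sort=True):
        grp = grp.sort_values("depth_m")
        out.append(
            GeneProfile(
                gene_set=str(g),
                sample_depths=grp["depth_m"].to_numpy(float),
                values=grp["value"].to_numpy(float),
                normalization_state="l1",
            )
        )
    return out


def write_simulation_tsvs(result: SimulationResult, outdir: str | Path) -> None:
    """One depth x time TSV per species and per process, plus a run log
    with the clipped-mass (conservation) ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [f"t{t:g}" for t in result.times]
    depths = result.grid.depths
    for sp, vals in result.conc.items():
        safe = sp.replace("+", "p").replace("-", "m")
        pd.DataFrame(vals, index=depths, columns=cols).to_csv(
            outdir / f"conc_{safe}.tsv", sep="\t", index_label="depth_m"
        )
    for label, vals in result.rates.items():
        pd.DataFrame(vals, index=depths, columns=cols).to_csv(
            outdir / f"rate_{label}.tsv", sep="\t", index_label="depth_m"
        )
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"saved_times_day\t{list(map(float, result.times))}\n")
        fh.write(f"n_cells\t{result.grid.n_cells}\n")
        fh.write(f"dz_m\t{result.grid.dz}\n")
        for sp, amt in sorted(result.clipped_mass.items()):
            fh.write(f"clipped_uM_m\t{sp}\t{amt:.6g}\n")
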