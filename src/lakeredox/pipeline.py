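"""Config-driven multi-stage runs: synth -> simulate -> calibrate ->
knockout/sweep -> match, in order, with partial pipelines supported.

The config is a single YAML document with a ``seed``, a ``stages`` list,
and one optional section per stage.  Outputs land in per-stage
subdirectories of the run directory; a manifest records enough to
reproduce the run.  Schema problems raise ``ConfigError`` (exit 2 at
the CLI); stage failures raise ``StageError`` naming the stage (exit 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .calibration import calibrate
from .community import (
    AbundanceMatrix,
    bin_abundance_table,
    combined_distance,
    dual_l1_normalize,
    match,
    taxonomy_fraction,
    train_tolerance,
)
from .gene_mapping import DEFAULT_GENE_PROCESS_MAP, build_objective
from .scenario import _with_rate_constants, knockout_compare, parameter_sweep
from .synthetic import (
    CALIBRATION_BOUNDS,
    DEFAULT_FREE_PARAMETERS,
    make_community,
    make_gene_tables,
    make_observations,
    make_scenario,
    parameter_specs,
)

KNOWN_STAGES = ("synth", "simulate", "calibrate", "knockout", "sweep", "match")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineState:
    """Objects passed between stages within one run."""

    truth: object = None
    result: object = None
    community: object = None


def _validate_config(config: dict) -> None:
    if "seed" not in config:
        raise ConfigError("config missing required field: seed")
    stages = config.get("stages")
    if not stages:
        raise ConfigError("config missing required field: stages")
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    for name in ("knockout", "sweep"):
        if name in stages:
            procs = config.get(name, {}).get("processes")
            if not procs:
                raise ConfigError(f"config section '{name}' missing field: processes")
            bad = [p for p in procs if p not in CALIBRATION_BOUNDS]
            if bad:
                raise ConfigError(
                    f"'{name}.processes' lists parameters without bounds: {bad}"
                )
    if "calibrate" in stages:
        free = config.get("calibrate", {}).get(
            "free", list(DEFAULT_FREE_PARAMETERS)
        )
        bad = [p for p in free if p not in CALIBRATION_BOUNDS]
        if bad:
            raise ConfigError(f"no calibration bounds for parameter(s): {bad}")


def run_pipeline(config: dict, outdir: str | Path) -> Path:
    """Execute the configured stages in canonical order; returns the run
    directory.  All randomness derives from ``config['seed']``."""
    _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = [s for s in KNOWN_STAGES if s in config["stages"]]
    state = PipelineState()

    for stage in stages:
        opts = config.get(stage, {}) or {}
        try:
            _STAGE_FNS[stage](state, opts, seed, outdir / stage)
        except (ConfigError,):
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc

    manifest = {
        "stages": stages,
        "seed": seed,
        "config": config,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def _ensure_scenario(state: PipelineState, seed: int):
    if state.truth is None:
        state.truth, state.result = make_scenario(seed)
    return state.truth, state.result


def _stage_synth(state, opts, seed, out):
    out.mkdir(parents=True, exist_ok=True)
    noise = float(opts.get("noise_sd", 0.2))
    truth, result = _ensure_scenario(state, seed)
    obs = make_observations(result, noise_sd=noise, seed=seed + 1)
    genes = make_gene_tables(result, noise_sd=noise, seed=seed + 2)
    comm = make_community(seed + 3, noise_sd=noise)
    state.community = comm
    lio.write_observations_tsv(obs, out / "chemistry.tsv")
    lio.write_gene_profiles_tsv(genes, out / "gene_profiles.tsv")
    lio.write_abundance_tsv(comm.otu_amplicon, out / "otu_amplicon.tsv")
    lio.write_abundance_tsv(comm.otu_metagenomic, out / "otu_metagenomic.tsv")
    lio.write_contigs_tsv(comm.contigs, out / "contigs.tsv")
    lio.write_taxonomy_tsv(list(comm.taxonomies.values()), out / "taxonomy.tsv")
    (out / "scenario.yaml").write_text(truth.scenario.to_yaml())


def _stage_simulate(state, opts, seed, out):
    _, result = _ensure_scenario(state, seed)
    lio.write_simulation_tsvs(result, out)


def _stage_calibrate(state, opts, seed, out):
    out.mkdir(parents=True, exist_ok=True)
    truth, result = _ensure_scenario(state, seed)
    free = tuple(opts.get("free", DEFAULT_FREE_PARAMETERS))
    m = int(opts.get("m", 60))
    noise = float(opts.get("noise_sd", 0.0))
    chem = make_observations(result, noise_sd=noise, seed=seed + 1)
    genes = make_gene_tables(result, noise_sd=noise, seed=seed + 2)
    base = truth.scenario

    def objective(x):
        net = _with_rate_constants(base.network, dict(zip(free, x)))
        return build_objective(
            base.run(network=net), chem, genes, DEFAULT_GENE_PROCESS_MAP
        ).average_mae

    cal = calibrate(
        objective, parameter_specs(free), m=m, seed=seed,
        polish_maxiter=int(opts.get("polish_maxiter", 30)),
    )
    (out / "calibrated_parameters.json").write_text(
        json.dumps(
            {"parameters": cal.as_dict(), "final_objective": cal.final_objective},
            indent=2,
        )
    )


def _stage_knockout(state, opts, seed, out):
    out.mkdir(parents=True, exist_ok=True)
    truth, _ = _ensure_scenario(state, seed)
    rep = knockout_compare(truth.scenario, opts["processes"])
    pd.DataFrame(
        [
            {
                "species": sp,
                "total_with": rep.total_with[sp],
                "total_without": rep.total_without[sp],
                "percent_change": rep.percent_change[sp],
            }
            for sp in rep.total_with
        ]
    ).to_csv(out / "knockout_report.tsv", sep="\t", index=False)


def _stage_sweep(state, opts, seed, out):
    out.mkdir(parents=True, exist_ok=True)
    truth, _ = _ensure_scenario(state, seed)
    specs = parameter_specs(tuple(CALIBRATION_BOUNDS))
    rep = parameter_sweep(
        truth.scenario, specs, n=int(opts.get("n", 20)), seed=seed,
        process_labels=opts["processes"],
    )
    pd.DataFrame(
        [{"species": sp, **rep.summary(sp)} for sp in sorted(rep.percent_changes)]
    ).to_csv(out / "sweep_report.tsv", sep="\t", index=False)


def _stage_match(state, opts, seed, out):
    out.mkdir(parents=True, exist_ok=True)
    comm = state.community or make_community(seed + 3, noise_sd=float(opts.get("noise_sd", 0.2)))
    amp = dual_l1_normalize(comm.otu_amplicon)
    met = dual_l1_normalize(comm.otu_metagenomic)
    mags = dual_l1_normalize(
        AbundanceMatrix(
            table=bin_abundance_table(comm.contigs, comm.sample_ids, comm.library_reads)
        )
    )
    ta, tm = [], []
    for otu, mag in comm.control_pairs:
        f = taxonomy_fraction(comm.taxonomies[otu], comm.taxonomies[mag])
        ta.append(combined_distance(amp.row(otu), mags.row(mag), f))
        tm.append(combined_distance(met.row(otu), mags.row(mag), f))
    cands = match(
        amp, met, mags, comm.taxonomies, train_tolerance(ta), train_tolerance(tm)
    )
    pd.DataFrame(
        [
            {
                "otu_id": c.otu_id, "mag_id": c.mag_id, "f": c.f,
                "m_amplicon": c.m_amplicon, "m_metagenomic": c.m_metagenomic,
                "accepted": c.accepted,
            }
            for c in cands
        ]
    ).to_csv(out / "match_report.tsv", sep="\t", index=False)


_STAGE_FNS = {
    "synth": _stage_synth,
    "simulate": _stage_simulate,
    "calibrate": _stage_calibrate,
    "knockout": _stage_knockout,
    "sweep": _stage_sweep,
    "match": _stage_match,
}


def load_config(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError("config must be a YAML mapping")
    return doc
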