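"""Process-knockout comparison and parameter-space sweep.

A knockout removes one or more processes by setting their maximum rate
constants to zero while holding everything else fixed, then compares
chemical inventories (concentration summed over all depths and saved
times) between the baseline and knockout runs.  The sweep repeats the
comparison across random draws of the rate constants within their
calibration bounds, to ask whether the knockout's impact is robust to
parameter uncertainty rather than an artefact of one calibrated point.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .calibration import ParameterSpec
from .lake_model import Scenario, column_total
from .reaction_network import ReactionNetwork, knockout

__all__ = ["KnockoutReport", "SweepReport", "knockout_compare", "parameter_sweep"]

logger = logging.getLogger(__name__)


@dataclass
class KnockoutReport:
    """Per-species inventories with/without the knocked-out processes.

    ``percent_change[s] = 100 * (without - with) / with``; species with a
    zero baseline inventory are reported as None (undefined), not 0.
    """

    process_labels: tuple[str, ...]
    total_with: dict[str, float]
    total_without: dict[str, float]
    percent_change: dict[str, float | None]


@dataclass
class SweepReport:
    n_samples: int
    seed: int
    process_labels: tuple[str, ...]
    percent_changes: dict[str, list[float]]  # per species, one per valid draw
    n_failed: int = 0

    def summary(self, species: str) -> dict[str, float]:
        vals = np.asarray(self.percent_changes[species])
        return {
            "mean": float(vals.mean()),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n": len(vals),
        }


def knockout_compare(
    scenario: Scenario, process_labels: set[str] | Sequence[str]
) -> KnockoutReport:
    """Run the scenario with and without the listed processes and report
    the percent change of every species' depth-and-time-summed
    concentration."""
    labels = tuple(process_labels)
    ko_net = knockout(scenario.network, set(labels))  # validates labels up front
    baseline = scenario.run()
    without = scenario.run(network=ko_net)

    total_with, total_without, pct = {}, {}, {}
    for sp in baseline.conc:
        w = column_total(baseline, sp)
        wo = column_total(without, sp)
        total_with[sp] = w
        total_without[sp] = wo
        pct[sp] = 100.0 * (wo - w) / w if w > 0 else None
    return KnockoutReport(
        process_labels=labels,
        total_with=total_with,
        total_without=total_without,
        percent_change=pct,
    )


def parameter_sweep(
    scenario: Scenario,
    specs: Sequence[ParameterSpec],
    n: int,
    seed: int,
    process_labels: set[str] | Sequence[str],
) -> SweepReport:
    """Repeat knockout_compare for ``n`` uniform draws of the rate
    constants (named by process label) within their bounds.

    Individual failed simulations are logged and excluded; more than 10%
    failures aborts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = tuple(process_labels)
    rng = np.random.default_rng(seed)
    draws = np.column_stack(
        [rng.uniform(s.lower, s.upper, size=n) for s in specs]
    )
    changes: dict[str, list[float]] = {}
    n_failed = 0
    for i in range(n):
        overrides = {s.name: draws[i, j] for j, s in enumerate(specs)}
        net = _with_rate_constants(scenario.network, overrides)
        sc = Scenario(
            grid=scenario.grid,
            network=net,
            initial=scenario.initial,
            t_end=scenario.t_end,
            save_every=scenario.save_every,
            tolerance=scenario.tolerance,
        )
        try:
            rep = knockout_compare(sc, labels)
        except Exception as exc:  # solver failure on an extreme draw
            logger.warning("sweep draw %d failed: %s", i, exc)
            n_failed += 1
            continue
        for sp, v in rep.percent_change.items():
            if v is not None:
                changes.setdefault(sp, []).append(v)
    if n_failed > 0.1 * n:
        raise RuntimeError(f"{n_failed}/{n} sweep simulations failed")
    return SweepReport(
        n_samples=n,
        seed=seed,
        process_labels=labels,
        percent_changes=changes,
        n_failed=n_failed,
    )


def _with_rate_constants(network, overrides: dict[str, float]):
    """Copy of a network with some processes' k replaced."""
    known = set(network.process_labels)
    missing = set(overrides) - known
    if missing:
        raise KeyError(f"unknown process labels: {sorted(missing)}")
    reactions = [
        replace(r, rate_law=replace(r.rate_law, k=float(overrides[r.process_label])))
        if r.process_label in overrides
        else r
        for r in network.reactions
    ]
    return ReactionNetwork(
        species=copy.deepcopy(network.species), reactions=reactions
    )
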