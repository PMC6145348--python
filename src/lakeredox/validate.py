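"""Schema and consistency checks for the TSV inputs.

``validate_inputs`` returns a machine-readable report (a list of
violation dicts, empty when clean) rather than raising, so a pipeline
can report every problem at once.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["validate_inputs", "Violation"]

Violation = dict


def _check_abundance(path: Path, report: list[Violation]) -> set[str] | None:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        report.append({"file": str(path), "error": f"unreadable: {exc}"})
        return None
    if df.empty:
        report.append({"file": str(path), "error": "empty table"})
        return None
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(num.isna().to_numpy())
    for i, j in bad[:10]:
        report.append(
            {
                "file": str(path),
                "error": "non-numeric value",
                "row": str(df.index[i]),
                "column": str(df.columns[j]),
            }
        )
    neg = np.argwhere((num.to_numpy() < 0))
    for i, j in neg[:10]:
        report.append(
            {
                "file": str(path),
                "error": "negative abundance",
                "row": str(df.index[i]),
                "column": str(df.columns[j]),
            }
        )
    return set(map(str, df.columns))


def _check_contigs(path: Path, report: list[Violation]) -> set[str] | None:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        report.append({"file": str(path), "error": f"unreadable: {exc}"})
        return None
    for col in ("contig_id", "bin_id", "length_bp"):
        if col not in df.columns:
            report.append({"file": str(path), "error": f"missing column {col}"})
            return None
    if (df["length_bp"] <= 0).any():
        rows = df.index[df["length_bp"] <= 0].tolist()[:10]
        report.append(
            {"file": str(path), "error": "non-positive contig length", "rows": rows}
        )
    cov_cols = [c for c in df.columns if c.startswith("cov_")]
    for c in cov_cols:
        if (df[c] < 0).any():
            report.append({"file": str(path), "error": "negative coverage", "column": c})
    return {c[4:] for c in cov_cols}


def validate_inputs(paths: dict[str, str | Path]) -> list[Violation]:
    """Validate input tables and cross-file sample consistency.

    ``paths`` maps a role to a file path; recognised roles:
    ``otu_amplicon``, ``otu_metagenomic`` (abundance TSVs),
    ``contigs`` (contig-record TSV), ``taxonomy`` (fixed-rank TSV),
    ``observations``, ``gene_profiles``.
    Unknown roles are reported; missing files are reported.
    """
    report: list[Violation] = []
    sample_sets: dict[str, set[str]] = {}
    for role, p in paths.items():
        p = Path(p)
        if not p.exists():
            report.append({"file": str(p), "error": "file not found", "role": role})
            continue
        if role in ("otu_amplicon", "otu_metagenomic"):
            s = _check_abundance(p, report)
            if s is not None:
                sample_sets[role] = s
        elif role == "contigs":
            s = _check_contigs(p, report)
            if s is not None:
                sample_sets[role] = s
        elif role == "taxonomy":
            try:
                df = pd.read_csv(p, sep="\t")
                if "feature_id" not in df.columns:
                    report.append({"file": str(p), "error": "missing feature_id column"})
            except Exception as exc:
                report.append({"file": str(p), "error": f"unreadable: {exc}"})
        elif role == "observations":
            try:
                df = pd.read_csv(p, sep="\t")
                need = {"depth_m", "time_day", "observable", "value"}
                missing = need - set(df.columns)
                if missing:
                    report.append(
                        {"file": str(p), "error": f"missing columns {sorted(missing)}"}
                    )
                elif (df["value"] < 0).any():
                    report.append({"file": str(p), "error": "negative concentration"})
            except Exception as exc:
                report.append({"file": str(p), "error": f"unreadable: {exc}"})
        elif role == "gene_profiles":
            try:
                df = pd.read_csv(p, sep="\t")
                need = {"gene_set", "depth_m", "value"}
                missing = need - set(df.columns)
                if missing:
                    report.append(
                        {"file": str(p), "error": f"missing columns {sorted(missing)}"}
                    )
                elif (df["value"] < 0).any():
                    report.append({"file": str(p), "error": "negative gene abundance"})
            except Exception as exc:
                report.append({"file": str(p), "error": f"unreadable: {exc}"})
        else:
            report.append({"role": role, "error": "unknown input role"})

    # cross-file: abundance-bearing tables must share samples
    roles = list(sample_sets)
    for i in range(len(roles)):
        for j in range(i + 1, len(roles)):
            if not sample_sets[roles[i]] & sample_sets[roles[j]]:
                report.append(
                    {
                        "error": "disjoint sample sets",
                        "files": [roles[i], roles[j]],
                    }
                )
    return report
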