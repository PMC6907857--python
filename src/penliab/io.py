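"""Readers and writers for scoring tables, Ct tables, configs and results.

File dialect
------------
Scoring tables are TSV (or CSV, by extension) with the mandatory columns
``animal_id, strain, generation, family_id``, one column per locus using the
genotype tokens ``+/+ , +/- , -/- , NA`` and one column per phenotype holding
``1``/``0``/empty (present / absent / unscored).  Ct tables are long-format
TSV with columns ``sample_id, gene, group, ct``.  Every tabular result is
written as TSV next to a JSON run summary recording inputs, configuration,
seed and software version, so a run can be audited and re-executed.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .datatypes import (
    CORE_COLUMNS,
    GENOTYPE_TOKENS,
    TOKEN_FOR_CALL,
    AnalysisConfig,
    CtTable,
    GenotypeCall,
    ScoringTable,
)
from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "load_scoring_table",
    "write_scoring_table",
    "load_ct_table",
    "write_ct_table",
    "load_analysis_config",
    "write_results",
]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_scoring_table(path: str | Path, config: AnalysisConfig) -> ScoringTable:
    """Load and validate a per-animal scoring table.

    Genotype tokens map onto the four-value call set; empty or ``NA``
    phenotype cells become *unscored* and are excluded from penetrance
    denominators downstream.
    """
    path = Path(path)
    raw = _read_table(path)
    missing = [c for c in CORE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    loci = [c for c in config.loci if c in raw.columns]
    if not loci:
        raise SchemaError(f"{path.name}: no locus column among {config.loci}")
    phenotypes = [c for c in raw.columns if c in config.phenotypes]
    if not phenotypes:
        raise SchemaError(f"{path.name}: no phenotype column among {config.phenotypes}")

    df = raw.copy()
    for locus in loci:
        calls = []
        for i, token in enumerate(df[locus]):
            token = token.strip()
            if token == "":
                token = "NA"
            if token not in GENOTYPE_TOKENS:
                raise ParseError(
                    f"{path.name} row {i + 2}: unrecognized genotype token "
                    f"{token!r} in column {locus!r}"
                )
            calls.append(GENOTYPE_TOKENS[token].value)
        df[locus] = calls

    for phen in phenotypes:
        vals = []
        for i, cell in enumerate(df[phen]):
            cell = cell.strip()
            if cell in ("", "NA", "na"):
                vals.append(pd.NA)
            elif cell in ("1", "present", "True", "true"):
                vals.append(True)
            elif cell in ("0", "absent", "False", "false"):
                vals.append(False)
            else:
                raise ParseError(
                    f"{path.name} row {i + 2}: unrecognized phenotype flag "
                    f"{cell!r} in column {phen!r}"
                )
        df[phen] = pd.array(vals, dtype="boolean")

    df["generation"] = pd.to_numeric(df["generation"], errors="raise").astype(int)
    if (df["generation"] < 0).any():
        raise ValidationError(f"{path.name}: negative generation numbers")
    return ScoringTable(
        data=df[list(CORE_COLUMNS) + loci + phenotypes],
        loci=tuple(loci),
        phenotypes=tuple(phenotypes),
        provenance=str(path),
    )


def write_scoring_table(table: ScoringTable, path: str | Path) -> None:
    """Write a scoring table back to the TSV/CSV dialect read by the loader."""
    path = Path(path)
    out = table.data.copy()
    for locus in table.loci:
        out[locus] = out[locus].map(lambda v: TOKEN_FOR_CALL[GenotypeCall(v)])
    for phen in table.phenotypes:
        out[phen] = out[phen].map(
            lambda v: "" if pd.isna(v) else ("1" if v else "0")
        )
    out.to_csv(path, sep=_sep_for(path), index=False)


def load_ct_table(path: str | Path, config: AnalysisConfig) -> CtTable:
    """Load a long-format Ct table and validate it against the configured
    reference gene.  ``undetermined`` cells are accepted only when the config
    declares a ceiling Ct to substitute for them."""
    path = Path(path)
    raw = _read_table(path)
    missing = [c for c in CtTable.REQUIRED if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    cts = []
    for i, cell in enumerate(raw["ct"]):
        cell = cell.strip()
        if cell.lower() in ("undetermined", "undet", "na", ""):
            if config.undetermined_ct_ceiling is None:
                raise ParseError(
                    f"{path.name} row {i + 2}: Ct {cell!r} is not numeric and no "
                    "undetermined-Ct ceiling is configured"
                )
            cts.append(config.undetermined_ct_ceiling)
        else:
            try:
                cts.append(float(cell))
            except ValueError as exc:
                raise ParseError(
                    f"{path.name} row {i + 2}: non-numeric Ct {cell!r}"
                ) from exc
    table = CtTable(raw.assign(ct=cts))
    table.require_reference(config.reference_gene)
    return table


def write_ct_table(table: CtTable, path: str | Path) -> None:
    path = Path(path)
    table.data.to_csv(path, sep=_sep_for(path), index=False)


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML (or JSON) key-value file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: config must be a key-value mapping")
    return AnalysisConfig.from_dict(payload)


def write_results(
    results: pd.DataFrame | Any,
    path: str | Path,
    *,
    inputs: list[str] | None = None,
    config: dict | None = None,
    seed: int | None = None,
    precision: int | None = None,
) -> None:
    """Write a stage result as TSV plus a JSON run summary alongside.

    Accepts a DataFrame or any object exposing ``to_frame()``.  The summary
    file (``<stem>.summary.json``) records inputs, config snapshot, seed and
    the package version; the seed of any stochastic stage is always echoed.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = results if isinstance(results, pd.DataFrame) else results.to_frame()
    out = frame.copy()
    if precision is not None:
        out = out.round(precision)
    try:
        out.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    summary = {
        "output": path.name,
        "inputs": inputs or [],
        "config": config or {},
        "seed": seed,
        "version": __version__,
    }
    summary_path = path.with_suffix(".summary.json")
    summary_path.write_text(json.dumps(summary, indent=2, default=str) + "\n")
    print(f"[penliab] wrote {path} (seed={seed})", file=sys.stderr)
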