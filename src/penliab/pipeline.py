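"""End-to-end orchestration: simulate -> score -> liability/qPCR -> reports.

Each run writes its tables into a fresh directory together with a
:class:`RunManifest` (JSON) recording the config snapshot, input digests,
seeds, executed stages and output paths — enough to re-execute every
deterministic stage bit-identically and every stochastic stage from its
recorded seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datatypes import AnalysisConfig
from .errors import PenliabError, ValidationError
from .io import load_ct_table, load_scoring_table, write_results
from .liability import (
    fit_multiple_threshold,
    incidence_to_liability,
    liability_trajectory,
    strain_liability_difference,
)
from .penetrance import compare_penetrance_groups, estimate_penetrance
from .qpcr import compare_expression_groups, compute_relative_expression
from .simulate import (
    FocalLocusModel,
    LiabilityArchitecture,
    SimConfig,
    run_breeding_program,
)

__all__ = [
    "RunManifest",
    "run_analysis_pipeline",
    "run_replication_experiment",
    "load_sim_config",
]


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]  # path -> sha256 digest
    seeds: list[int]
    stages: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    version: str = __version__

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _fresh_dir(out_dir: str | Path) -> Path:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        raise ValidationError(f"output directory {out} exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)
    return out


def load_sim_config(path: str | Path) -> SimConfig:
    """Read a :class:`SimConfig` from a nested YAML/JSON key-value file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    arch = LiabilityArchitecture(**payload.pop("architecture", {}))
    focal = FocalLocusModel(**payload.pop("focal", {}))
    return SimConfig(architecture=arch, focal=focal, **payload)


def run_analysis_pipeline(
    config_path: str | Path,
    scoring_paths: list[str | Path],
    ct_paths: list[str | Path],
    out_dir: str | Path,
    *,
    seed: int | None = None,
) -> RunManifest:
    """Run the configured analyses over scoring and Ct tables.

    Stages (each skipped when it has no input): penetrance estimation and
    low-vs-high comparison per phenotype; liability transform per
    (strain, phenotype) cell plus the multiple-threshold fit; comparative-Ct
    folds and group comparisons for every non-reference gene.  Fully
    penetrant or fully unaffected cells are capped on the liability scale,
    flagged, and excluded from the fit rather than erroring.
    """
    out = _fresh_dir(out_dir)
    config = AnalysisConfig.from_dict(yaml.safe_load(Path(config_path).read_text()) or {})
    inputs = {str(p): _digest(p) for p in list(scoring_paths) + list(ct_paths)}
    inputs[str(config_path)] = _digest(config_path)
    manifest = RunManifest(config=config.to_dict(), inputs=inputs, seeds=[seed] if seed is not None else [])

    for path in scoring_paths:
        table = load_scoring_table(path, config)
        stem = Path(path).stem
        strains = sorted(table.data["strain"].unique())
        mutant = {"genotype": {"mef2ca": "mut"}}

        est_rows, cells = [], {}
        for strain in strains:
            for phen in table.phenotypes:
                sel = {"strain": strain, **mutant}
                try:
                    est = estimate_penetrance(
                        table, phen, sel, alpha=config.alpha, label=strain
                    )
                except PenliabError as exc:
                    manifest.warnings.append(f"{stem}:{strain}:{phen}: {exc}")
                    continue
                est_rows.append(est.to_frame())
                lv = incidence_to_liability(est.proportion, cap=config.liability_cap)
                cells[(strain, phen)] = lv
        est_table = pd.concat(est_rows, ignore_index=True)
        write_results(est_table, out / f"{stem}.penetrance.tsv", inputs=[str(path)],
                      config=config.to_dict(), seed=seed)
        manifest.stages.append(f"penetrance[{stem}]")
        manifest.outputs.append(f"{stem}.penetrance.tsv")

        liab_rows = [
            {"strain": s, "phenotype": k, "x": lv.x, "incidence": lv.incidence,
             "capped": lv.capped}
            for (s, k), lv in cells.items()
        ]
        write_results(pd.DataFrame(liab_rows), out / f"{stem}.liability.tsv",
                      inputs=[str(path)], config=config.to_dict(), seed=seed)
        manifest.stages.append(f"liability[{stem}]")
        manifest.outputs.append(f"{stem}.liability.tsv")

        if len(strains) >= 2:
            try:
                model = fit_multiple_threshold(cells, anchor=strains[0])
                frame = model.to_frame()
                if model.excluded:
                    manifest.warnings.append(
                        f"{stem}: capped cells excluded from threshold fit: "
                        f"{model.excluded}"
                    )
                write_results(frame, out / f"{stem}.threshold_model.tsv",
                              inputs=[str(path)], config=config.to_dict(), seed=seed)
                manifest.stages.append(f"threshold_fit[{stem}]")
                manifest.outputs.append(f"{stem}.threshold_model.tsv")
            except PenliabError as exc:
                manifest.warnings.append(f"{stem}: threshold fit skipped: {exc}")

            cmp = compare_penetrance_groups(
                table, list(table.phenotypes),
                {"strain": strains[0], **mutant}, {"strain": strains[1], **mutant},
                config, label_a=strains[0], label_b=strains[1],
            )
            write_results(cmp, out / f"{stem}.comparison.tsv", inputs=[str(path)],
                          config=config.to_dict(), seed=seed)
            manifest.stages.append(f"comparison[{stem}]")
            manifest.outputs.append(f"{stem}.comparison.tsv")

    for path in ct_paths:
        ct = load_ct_table(path, config)
        stem = Path(path).stem
        groups = list(dict.fromkeys(ct.data["group"]))
        genes = [g for g in dict.fromkeys(ct.data["gene"]) if g != config.reference_gene]
        folds = []
        for gene in genes:
            for group in groups[1:]:
                fc = compute_relative_expression(
                    ct, gene, config.reference_gene, groups[0], group
                )
                folds.append(fc.to_frame())
        write_results(pd.concat(folds, ignore_index=True), out / f"{stem}.folds.tsv",
                      inputs=[str(path)], config=config.to_dict(), seed=seed)
        manifest.stages.append(f"qpcr_folds[{stem}]")
        manifest.outputs.append(f"{stem}.folds.tsv")
        if len(groups) >= 2 and ct.data.groupby(["group", "gene"])["sample_id"].nunique().min() >= 2:
            comparisons = compare_expression_groups(
                ct, genes, groups, alpha=config.alpha, reference=config.reference_gene
            )
            write_results(comparisons, out / f"{stem}.expression_tests.tsv",
                          inputs=[str(path)], config=config.to_dict(), seed=seed)
            manifest.stages.append(f"qpcr_tests[{stem}]")
            manifest.outputs.append(f"{stem}.expression_tests.tsv")

    manifest.write(out / "manifest.json")
    return manifest


def replication_summary(
    sim_config: SimConfig, *, directions: tuple[str, ...] = ("low", "high")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate the breeding program and aggregate its trajectories.

    Runs ``sim_config.n_replicates`` replicates per direction with seeds
    ``base_seed*1000 + 1 .. + n``, and returns (per-replicate long table,
    per-generation summary with median and quartiles of mutant penetrance of
    the scoring phenotype, heterozygote penetrance, and mutant viability).
    """
    phen = sim_config.scoring_phenotype
    long_rows = []
    for direction in directions:
        cfg = dataclasses.replace(sim_config, direction=direction)
        for r in range(1, cfg.n_replicates + 1):
            seed = cfg.base_seed * 1000 + r
            traj = run_breeding_program(cfg, seed)
            t = traj.table
            for _, row in t.iterrows():
                long_rows.append(
                    {
                        "direction": direction,
                        "replicate": r,
                        "seed": seed,
                        "generation": int(row["generation"]),
                        "mut_penetrance": row[f"mut_penetrance[{phen}]"],
                        "het_penetrance": row[f"het_penetrance[{phen}]"],
                        "mutant_viability": row["mutant_viability"],
                        "mean_liability": row["mean_liability"],
                        "additive_variance": row["additive_variance"],
                    }
                )
    long = pd.DataFrame(long_rows)
    summary = (
        long.groupby(["direction", "generation"], as_index=False)
        .agg(
            median_mut_penetrance=("mut_penetrance", "median"),
            q25_mut_penetrance=("mut_penetrance", lambda s: s.quantile(0.25)),
            q75_mut_penetrance=("mut_penetrance", lambda s: s.quantile(0.75)),
            median_het_penetrance=("het_penetrance", "median"),
            median_mutant_viability=("mutant_viability", "median"),
            median_mean_liability=("mean_liability", "median"),
        )
    )
    return long, summary


def run_replication_experiment(
    config_path: str | Path | None,
    out_dir: str | Path,
    *,
    sim_config: SimConfig | None = None,
    cap: float = 4.0,
) -> RunManifest:
    """Run the selective-breeding experiment in both directions.

    Aggregates per-generation penetrance across replicates, applies the
    probit liability transform to the per-generation medians, and reports
    the final-generation liability separation between the two directions.
    """
    out = _fresh_dir(out_dir)
    if sim_config is None:
        if config_path is None:
            raise ValidationError("either a config path or a SimConfig is required")
        sim_config = load_sim_config(config_path)
    inputs = {str(config_path): _digest(config_path)} if config_path else {}
    seeds = [sim_config.base_seed * 1000 + r for r in range(1, sim_config.n_replicates + 1)]
    manifest = RunManifest(config=sim_config.to_dict(), inputs=inputs, seeds=seeds)

    long, summary = replication_summary(sim_config)
    write_results(long, out / "trajectories.tsv", config=sim_config.to_dict(),
                  seed=sim_config.base_seed)
    write_results(summary, out / "trajectory_summary.tsv", config=sim_config.to_dict(),
                  seed=sim_config.base_seed)
    manifest.stages += ["simulate[low]", "simulate[high]", "aggregate"]
    manifest.outputs += ["trajectories.tsv", "trajectory_summary.tsv"]

    liab_frames, final_x = [], {}
    for direction, block in summary.groupby("direction"):
        series = list(zip(block["generation"], block["median_mut_penetrance"]))
        traj = liability_trajectory(series, cap=cap)
        frame = traj.to_frame()
        frame.insert(0, "direction", direction)
        liab_frames.append(frame)
        final_x[direction] = incidence_to_liability(
            float(block["median_mut_penetrance"].iloc[-1]), cap=cap
        )
    liab = pd.concat(liab_frames, ignore_index=True)
    write_results(liab, out / "liability_trajectory.tsv", config=sim_config.to_dict(),
                  seed=sim_config.base_seed)
    manifest.stages.append("liability_trajectory")
    manifest.outputs.append("liability_trajectory.tsv")

    if {"low", "high"} <= set(final_x):
        separation = strain_liability_difference(
            final_x["low"], final_x["high"], allow_capped=True
        )
        sep_frame = pd.DataFrame(
            [
                {
                    "quantity": "final_generation_liability_separation",
                    "value": separation,
                    "low_capped": final_x["low"].capped,
                    "high_capped": final_x["high"].capped,
                }
            ]
        )
        write_results(sep_frame, out / "liability_separation.tsv",
                      config=sim_config.to_dict(), seed=sim_config.base_seed)
        manifest.stages.append("liability_separation")
        manifest.outputs.append("liability_separation.tsv")

    manifest.write(out / "manifest.json")
    return manifest
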