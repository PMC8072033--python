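"""End-to-end orchestration: simulate -> difftest -> classify -> CpG.

Each stage writes a plain-text TSV/JSON artifact so every intermediate is
diffable and individually re-consumable; a manifest records the seed, the
effective configuration, input checksums and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_table, summarize_classes
from .cpg import group_means, mann_whitney, oe_cpg_table
from .diffaccess import adjust_effective_bonferroni, call_accessibility, stage_pair_test
from .errors import PipelineError
from .expression import cpm_filter, gate_table, log2fc_table
from .genomic_io import assign_dhs_to_promoters
from .synthetic import SimConfig, SyntheticDataset, read_fixtures, simulate_dataset, write_fixtures

STAGE_PAIRS = (("LSK", "DN1"), ("DN1", "DN2b"))


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the full analysis, with the standard defaults:
    alpha 0.05, log2FC gate 2, CPM filter 1 in >= 2 samples, 2-kb promoter
    window, 150-bp smoothing bandwidth, 20-bp bins, <= 10000 permutations."""

    alpha: float = 0.05
    log2fc_threshold: float = 2.0
    min_cpm: float = 1.0
    min_samples: int = 2
    pseudocount: float = 0.5
    window: int = 2000
    bandwidth_bp: float = 150.0
    bin_size: int = 20
    max_perms: int = 10_000
    statistic: str = "kn"
    pvalue_method: str = "pooled"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["sim"]["stages"] = list(config.sim.stages)
    if isinstance(d["sim"]["target_cpg_oe"], Mapping):
        d["sim"]["target_cpg_oe"] = dict(d["sim"]["target_cpg_oe"])
    return d


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    dataset: SyntheticDataset | None = None,
    fixtures_dir: str | Path | None = None,
) -> dict:
    """Run the full chain and write all stage outputs under ``out_dir``.

    With neither ``dataset`` nor ``fixtures_dir`` supplied, a synthetic
    dataset is generated from ``config.sim`` (seeded by ``config.seed``).
    Returns the result bundle: classification table, class summary, CpG
    comparison, and the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def _record(stage: str, path: Path, n_rows: int) -> None:
        manifest["stages"][stage] = {
            "path": path.name,
            "rows": int(n_rows),
            "sha256": _sha256(path),
        }

    stage = "simulate"
    try:
        if dataset is None and fixtures_dir is not None:
            dataset = read_fixtures(fixtures_dir)
        if dataset is None:
            sim = SimConfig(**{**asdict(config.sim), "seed": config.seed,
                               "bin_size": config.bin_size})
            dataset = simulate_dataset(sim)
        fixture_paths = write_fixtures(dataset, out / "fixtures")
        _record(stage, fixture_paths["truth"], len(dataset.truth))

        stage = "difftest"
        diff_tables = []
        for pair_i, (a, b) in enumerate(STAGE_PAIRS):
            t = stage_pair_test(
                dataset.profiles, a, b,
                statistic=config.statistic,
                method=config.pvalue_method,
                max_perms=config.max_perms,
                seed=np.random.default_rng([config.seed, 100 + pair_i]),
                bandwidth_bp=config.bandwidth_bp,
            )
            diff_tables.append(t)
        diffs = adjust_effective_bonferroni(
            pd.concat(diff_tables, ignore_index=True), dataset.profiles.regions
        )
        diff_path = out / "diffaccess.tsv"
        diffs.to_csv(diff_path, sep="\t", index=False)
        _record(stage, diff_path, len(diffs))

        stage = "accessibility"
        calls = call_accessibility(dataset.profiles)
        calls_path = out / "accessibility_calls.tsv"
        calls.to_csv(calls_path, sep="\t", index=False)
        _record(stage, calls_path, len(calls))

        stage = "expression"
        filtered = cpm_filter(dataset.rna, config.min_cpm, config.min_samples)
        fc = log2fc_table(filtered, pseudocount=config.pseudocount)
        gates = gate_table(fc, config.log2fc_threshold)
        expr_path = out / "expression_gates.tsv"
        pd.concat([fc.table, gates.add_prefix("gate_")], axis=1).to_csv(expr_path, sep="\t")
        _record(stage, expr_path, len(gates))

        stage = "classify"
        assignments = assign_dhs_to_promoters(dataset.profiles.regions, dataset.promoters)
        classifications = classify_table(assignments, calls, diffs, gates, config.alpha)
        class_path = out / "classifications.tsv"
        classifications.to_csv(class_path, sep="\t", index=False)
        _record(stage, class_path, len(classifications))
        summary = summarize_classes(classifications)

        stage = "cpg"
        cpg_table = oe_cpg_table({p.gene_id: p.sequence for p in dataset.promoters})
        priority = {"high": 0, "low_I": 1, "low_II": 2, "unclassified": 3}
        class_of = (
            classifications.assign(_rank=classifications["dose_class"].map(priority))
            .sort_values(["gene_id", "_rank"])
            .drop_duplicates("gene_id")
            .set_index("gene_id")["dose_class"]
        )
        cpg_table["dose_class"] = (
            cpg_table["gene_id"].map(class_of).fillna("unclassified")
        )
        cpg_path = out / "cpg_ratios.tsv"
        cpg_table.to_csv(cpg_path, sep="\t", index=False)
        _record(stage, cpg_path, len(cpg_table))
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    bundle = {
        "classifications": classifications,
        "summary": summary,
        "cpg_table": cpg_table,
        "diffs": diffs,
        "manifest": manifest,
    }
    report = make_report(bundle, config)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["report"] = report
    return bundle


def make_report(bundle: dict, config: PipelineConfig) -> dict:
    """Summarise a result bundle: class sizes, overlaps, CpG group statistics."""
    summary = bundle["summary"]
    cpg_table = bundle["cpg_table"]
    by_class = {
        "high": cpg_table.loc[cpg_table["dose_class"] == "high", "oe_ratio"],
        "low": cpg_table.loc[
            cpg_table["dose_class"].isin(["low_I", "low_II"]), "oe_ratio"
        ],
    }
    means = group_means(by_class).set_index("dose_class").to_dict(orient="index")
    report = {
        "class_sizes": summary["class_sizes"],
        "overlaps": summary["overlaps"],
        "n_unique_low_dose": summary["n_unique_low_dose"],
        "n_unique_high_dose": summary["n_unique_high_dose"],
        "cpg_group_means": means,
        "config": _config_dict(config),
    }
    if len(by_class["high"].dropna()) and len(by_class["low"].dropna()):
        cmp = mann_whitney(by_class["high"], by_class["low"],
                           label_a="high", label_b="low")
        report["cpg_comparison"] = {
            "n_high": cmp.n_a,
            "n_low": cmp.n_b,
            "mean_high": cmp.mean_a,
            "mean_low": cmp.mean_b,
            "u_statistic": cmp.u_statistic,
            "p_value": cmp.p_value,
            "method": cmp.method,
        }
    else:
        report["cpg_comparison"] = None
        report["note"] = "a dose class is empty; group comparison omitted"
    return report
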