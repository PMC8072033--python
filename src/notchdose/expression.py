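"""RNA count filtering and stage-pair log2 fold-change gates.

Counts are normalised to counts per million (CPM) by plain column scaling;
no between-sample normalisation (TMM etc.) is applied.  Fold-changes are
computed on mean CPM per stage with a pseudocount added on the CPM scale to
both numerator and denominator, which keeps genes silent in the control from
producing infinite log2FC.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

RNA_STAGES = ("DN1", "DN2a", "DN2b", "ctrl")
GATE_PAIRS = (("DN1", "ctrl"), ("DN2b", "ctrl"), ("DN2b", "DN1"))


@dataclass
class CountMatrix:
    """A genes x samples integer count table with a sample sheet.

    ``samples`` is indexed by sample id with columns ``stage`` and
    ``replicate``; every count column must appear in it.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing stage labels: {sorted(missing)}")
        if "stage" not in self.samples.columns:
            raise ValueError("sample sheet needs a 'stage' column")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def stage_samples(self, stage: str) -> list[str]:
        hits = [s for s in self.counts.columns if self.samples.loc[s, "stage"] == stage]
        if not hits:
            raise KeyError(f"no samples for stage {stage!r}")
        return hits


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per sample (columns each sum to 1e6)."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    return counts * (1e6 / totals)


def cpm_filter(
    cm: CountMatrix, min_cpm: float = 1.0, min_samples: int = 2
) -> CountMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    ``min_samples`` defaults to 2, the size of the smallest replicate group.
    """
    keep = (cpm(cm.counts) >= min_cpm).sum(axis=1) >= min_samples
    return CountMatrix(cm.counts.loc[keep], cm.samples)


def log2fc(
    cm: CountMatrix,
    stage_a: str,
    stage_b: str,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-gene log2((mean CPM_a + pc) / (mean CPM_b + pc))."""
    c = cpm(cm.counts)
    mean_a = c[cm.stage_samples(stage_a)].mean(axis=1)
    mean_b = c[cm.stage_samples(stage_b)].mean(axis=1)
    values = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    values.name = f"{stage_a}_vs_{stage_b}"
    return values


@dataclass
class Log2FCTable:
    """Gene x stage-pair log2 fold-changes (column ``A_vs_B``)."""

    table: pd.DataFrame
    pseudocount: float

    def value(self, gene: str, stage_a: str, stage_b: str) -> float:
        col = f"{stage_a}_vs_{stage_b}"
        if col not in self.table.columns:
            raise KeyError(f"stage pair {stage_a}/{stage_b} not in table")
        if gene not in self.table.index:
            raise KeyError(f"gene {gene!r} not in table")
        return float(self.table.loc[gene, col])


def log2fc_table(
    cm: CountMatrix,
    pairs: tuple[tuple[str, str], ...] = GATE_PAIRS,
    pseudocount: float = 0.5,
) -> Log2FCTable:
    cols = {f"{a}_vs_{b}": log2fc(cm, a, b, pseudocount) for a, b in pairs}
    return Log2FCTable(pd.DataFrame(cols), pseudocount)


def expression_gate(
    table: Log2FCTable, gene: str, gate: str, threshold: float = 2.0
) -> bool:
    """Evaluate the low- or high-dose expression gate for one gene.

    low gate:  log2FC(DN1, ctrl) >= threshold.
    high gate: log2FC(DN2b, ctrl) >= threshold AND
               log2FC(DN2b, DN1) >= threshold (conjunction).
    Thresholds are inclusive.
    """
    if gate == "low":
        return table.value(gene, "DN1", "ctrl") >= threshold
    if gate == "high":
        return (
            table.value(gene, "DN2b", "ctrl") >= threshold
            and table.value(gene, "DN2b", "DN1") >= threshold
        )
    raise ValueError(f"unknown gate {gate!r}")


def gate_table(table: Log2FCTable, threshold: float = 2.0) -> pd.DataFrame:
    """Vectorised low/high gate booleans for every gene in the table."""
    t = table.table
    return pd.DataFrame(
        {
            "low": t["DN1_vs_ctrl"] >= threshold,
            "high": (t["DN2b_vs_ctrl"] >= threshold) & (t["DN2b_vs_DN1"] >= threshold),
        }
    )


def read_count_matrix(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return CountMatrix(counts, samples)


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.samples.to_csv(samples_path, sep="\t")
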