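"""Synthetic fixtures with the statistical structure the analysis assumes.

The generator emulates a stage-resolved DNase + RNA experiment over five
conditions (LSK, DN1, DN2a, DN2b and a no-Notch control):

* 4-kb DHS windows with per-bin Poisson cut counts.  An accessible stage
  adds one Gaussian bump (apex ``peak_amplitude`` extra cuts per bin, SD
  ``peak_width_sd``) to a flat ``background_rate``; the three alternatives of
  interest are expressed as peak/no-peak, height-change and positional-shift
  patterns across stages.
* negative-binomial RNA counts with planted stage-pair log2 fold-changes, so
  classified genes meet (and null genes fail) the expression gates in
  expectation.
* 2-kb promoter sequences from a first-order dinucleotide Markov chain whose
  stationary CpG observed/expected ratio equals a per-class target.

Every planted region carries a ground-truth class so downstream recovery is
measurable.  A fixed seed yields byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .expression import RNA_STAGES, CountMatrix, read_count_matrix, write_count_matrix
from .genomic_io import (
    GenomicInterval,
    PromoterRecord,
    read_bed,
    read_bedgraph_matrix,
    read_fasta,
    read_tss_table,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_tss_table,
)
from .profiles import ProfileSet

TRUE_CLASSES = ("low_I", "low_II", "high", "null", "shift_only", "height_only")

# Per-stage peak-amplitude multipliers per planted class.  low_II is
# accessible in LSK at reduced height; high acquires accessibility de novo in
# DN2 (partially in DN2a, fully in DN2b); the control never gains a peak
# beyond its LSK-like baseline.
_AMPLITUDE: dict[str, dict[str, float]] = {
    "null": {"LSK": 0.0, "DN1": 0.0, "DN2a": 0.0, "DN2b": 0.0, "ctrl": 0.0},
    "low_I": {"LSK": 0.0, "DN1": 1.0, "DN2a": 1.0, "DN2b": 1.0, "ctrl": 0.0},
    "low_II": {"LSK": 0.4, "DN1": 1.0, "DN2a": 1.0, "DN2b": 1.0, "ctrl": 0.4},
    "high": {"LSK": 0.0, "DN1": 0.0, "DN2a": 0.5, "DN2b": 1.0, "ctrl": 0.0},
    "height_only": {"LSK": 1.0, "DN1": 2.0, "DN2a": 2.0, "DN2b": 2.0, "ctrl": 1.0},
    "shift_only": {"LSK": 1.0, "DN1": 1.0, "DN2a": 1.0, "DN2b": 1.0, "ctrl": 1.0},
}

# Baseline RNA mean counts (control stage) per class; dose-responsive genes
# start low and are induced, the null backdrop sits at a typical expressed
# level.
_BASE_EXPR: dict[str, float] = {
    "null": 100.0,
    "low_I": 50.0,
    "low_II": 50.0,
    "high": 20.0,
    "height_only": 100.0,
    "shift_only": 100.0,
}

# Default per-class stationary CpG observed/expected targets: dose classes
# echo the reported group means (high-dose promoters CpG-poor), the backdrop
# sits near the unconstrained regime.
_DEFAULT_CPG_TARGETS: dict[str, float] = {
    "high": 0.43,
    "low_I": 0.60,
    "low_II": 0.60,
    "null": 0.85,
    "height_only": 0.85,
    "shift_only": 0.85,
}

_REGION_SPACING = 6000  # bp between region starts; windows never overlap
_REGION_OFFSET = 2000


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment."""

    n_regions: int = 500
    region_length: int = 4000
    bin_size: int = 20
    stages: tuple[str, ...] = ("LSK", "DN1", "DN2a", "DN2b", "ctrl")
    replicates_per_stage: int = 3
    library_size: float = 1e7
    background_rate: float = 0.5
    peak_amplitude: float = 5.0
    peak_width_sd: float = 300.0
    shift_bp: int = 300
    nb_dispersion: float = 0.05
    planted_log2fc: float = 3.0
    target_cpg_oe: Mapping[str, float] | float = field(
        default_factory=lambda: dict(_DEFAULT_CPG_TARGETS)
    )
    gc_content: float = 0.5
    n_background_genes: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_length % self.bin_size:
            raise ConfigurationError("region_length must be divisible by bin_size")
        if self.replicates_per_stage < 2:
            raise ConfigurationError("need >= 2 replicates per stage")
        if self.library_size <= 0:
            raise ConfigurationError("library size must be positive")
        if self.background_rate < 0 or self.peak_amplitude < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if not 0 < self.gc_content < 1:
            raise ConfigurationError("gc_content must be in (0, 1)")

    @property
    def n_bins(self) -> int:
        return self.region_length // self.bin_size

    def cpg_target(self, true_class: str) -> float:
        if isinstance(self.target_cpg_oe, Mapping):
            return float(self.target_cpg_oe.get(true_class, 0.85))
        return float(self.target_cpg_oe)

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic child stream for one generator component."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class PlantedTruth:
    """Ground truth for one region/gene: class, per-stage peak parameters,
    and the planted expression offsets (log2, relative to the control)."""

    region_id: str
    gene_id: str
    true_class: str
    amplitude: dict[str, float]
    center_offset_bp: dict[str, float]
    accessible: dict[str, bool]
    expr_log2_offset: dict[str, float]

    def __post_init__(self) -> None:
        if self.true_class not in TRUE_CLASSES:
            raise ConfigurationError(f"unknown class {self.true_class!r}")
        if self.true_class == "high" and (
            self.accessible["LSK"] or self.accessible["DN1"] or not self.accessible["DN2b"]
        ):
            raise ConfigurationError("high class requires LSK/DN1 closed, DN2b open")
        if self.true_class == "low_I" and (self.accessible["LSK"] or not self.accessible["DN1"]):
            raise ConfigurationError("low_I class requires LSK closed, DN1 open")
        if self.true_class == "low_II" and not (
            self.accessible["LSK"] and self.accessible["DN1"]
        ):
            raise ConfigurationError("low_II class requires LSK and DN1 open")


def _planted_record(i: int, true_class: str, config: SimConfig) -> PlantedTruth:
    amp = dict(_AMPLITUDE[true_class])
    offsets = {stage: 0.0 for stage in config.stages}
    if true_class == "shift_only":
        for stage in ("DN1", "DN2a", "DN2b"):
            offsets[stage] = float(config.shift_bp)
    lfc = config.planted_log2fc
    if true_class in ("low_I", "low_II"):
        expr = {"ctrl": 0.0, "DN1": lfc, "DN2a": lfc, "DN2b": lfc}
    elif true_class == "high":
        expr = {"ctrl": 0.0, "DN1": 0.0, "DN2a": lfc / 2.0, "DN2b": lfc}
    else:
        expr = {stage: 0.0 for stage in RNA_STAGES}
    return PlantedTruth(
        region_id=f"dhs{i:04d}",
        gene_id=f"g{i:04d}",
        true_class=true_class,
        amplitude=amp,
        center_offset_bp=offsets,
        accessible={stage: amp[stage] > 0 for stage in config.stages},
        expr_log2_offset=expr,
    )


def make_truth(
    config: SimConfig,
    n_per_class: Mapping[str, int] | None = None,
) -> list[PlantedTruth]:
    """Build the planted truth table.

    The default composition plants 20 genes in each dose class and fills the
    remainder with nulls, mirroring a sparse-signal screen.
    """
    if n_per_class is None:
        planted = min(20, config.n_regions // 25)
        n_per_class = {"low_I": planted, "low_II": planted, "high": planted}
    total_planted = sum(n_per_class.values())
    if total_planted > config.n_regions:
        raise ConfigurationError("more planted regions than n_regions")
    classes: list[str] = []
    for cls, n in n_per_class.items():
        classes.extend([cls] * n)
    classes.extend(["null"] * (config.n_regions - total_planted))
    return [_planted_record(i, cls, config) for i, cls in enumerate(classes)]


def truth_frame(truth: Sequence[PlantedTruth], stages: Sequence[str]) -> pd.DataFrame:
    columns = (
        ["region_id", "gene_id", "true_class"]
        + [f"accessible_{s}" for s in stages]
        + [f"expr_log2_{s}" for s in RNA_STAGES]
    )
    if not truth:
        return pd.DataFrame(columns=columns)
    rows = []
    for t in truth:
        row = {"region_id": t.region_id, "gene_id": t.gene_id, "true_class": t.true_class}
        for stage in stages:
            row[f"accessible_{stage}"] = t.accessible[stage]
        for stage in RNA_STAGES:
            row[f"expr_log2_{stage}"] = t.expr_log2_offset[stage]
        rows.append(row)
    return pd.DataFrame(rows)


def _regions(config: SimConfig, truth: Sequence[PlantedTruth]) -> list[GenomicInterval]:
    return [
        GenomicInterval(
            "chr1",
            _REGION_OFFSET + i * _REGION_SPACING,
            _REGION_OFFSET + i * _REGION_SPACING + config.region_length,
            id=t.region_id,
        )
        for i, t in enumerate(truth)
    ]


def rate_profile(config: SimConfig, truth: PlantedTruth, stage: str) -> np.ndarray:
    """Noise-free expected cuts per bin for one region and stage."""
    x = (np.arange(config.n_bins) + 0.5) * config.bin_size
    center = config.region_length / 2.0 + truth.center_offset_bp[stage]
    bump = np.exp(-0.5 * ((x - center) / config.peak_width_sd) ** 2)
    return config.background_rate + truth.amplitude[stage] * config.peak_amplitude * bump


def simulate_dhs_profiles(
    config: SimConfig, truth: Sequence[PlantedTruth]
) -> ProfileSet:
    """Per-sample Poisson cut-count profiles over the planted regions."""
    if len(truth) != config.n_regions:
        raise ConfigurationError("need one truth record per region")
    rng = config.rng(0)
    sample_ids, stages_col, reps_col = [], [], []
    for stage in config.stages:
        for rep in range(1, config.replicates_per_stage + 1):
            sample_ids.append(f"{stage}_r{rep}")
            stages_col.append(stage)
            reps_col.append(rep)
    samples = pd.DataFrame(
        {
            "stage": stages_col,
            "replicate": reps_col,
            "library_size": config.library_size,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    rates = np.empty((len(config.stages), config.n_regions, config.n_bins))
    for si, stage in enumerate(config.stages):
        for ri, t in enumerate(truth):
            rates[si, ri] = rate_profile(config, t, stage)
    # rates are calibrated to the reference depth of 1e7 mapped reads; other
    # library sizes scale the Poisson mean proportionally
    depth_factor = config.library_size / 1e7
    counts = np.empty((len(sample_ids), config.n_regions, config.n_bins), dtype=np.int64)
    for smp_idx, stage in enumerate(stages_col):
        si = config.stages.index(stage)
        counts[smp_idx] = rng.poisson(rates[si] * depth_factor)
    return ProfileSet(counts, samples, _regions(config, truth), config.bin_size)


def simulate_rna_counts(
    config: SimConfig, truth: Sequence[PlantedTruth]
) -> CountMatrix:
    """Negative-binomial gene counts with the planted log2FC structure.

    Counts are gamma-Poisson draws with mean ``base * 2**offset(stage)`` and
    variance ``mu + dispersion * mu^2``.  A backdrop of
    ``n_background_genes`` null genes emulates the rest of the transcriptome
    so that planted fold-changes survive CPM renormalisation undistorted.
    """
    rng = config.rng(1)
    gene_ids = [t.gene_id for t in truth] + [
        f"bg{i:04d}" for i in range(config.n_background_genes)
    ]
    base = np.array(
        [_BASE_EXPR[t.true_class] for t in truth]
        + [_BASE_EXPR["null"]] * config.n_background_genes
    )
    sample_ids, stages_col, reps_col = [], [], []
    for stage in RNA_STAGES:
        for rep in range(1, config.replicates_per_stage + 1):
            sample_ids.append(f"rna_{stage}_r{rep}")
            stages_col.append(stage)
            reps_col.append(rep)
    offsets = np.zeros((len(gene_ids), len(RNA_STAGES)))
    for gi, t in enumerate(truth):
        for si, stage in enumerate(RNA_STAGES):
            offsets[gi, si] = t.expr_log2_offset[stage]
    means = base[:, None] * 2.0 ** offsets  # genes x stages
    alpha = config.nb_dispersion
    counts = np.empty((len(gene_ids), len(sample_ids)), dtype=np.int64)
    for ci, stage in enumerate(stages_col):
        mu = means[:, RNA_STAGES.index(stage)]
        lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
        counts[:, ci] = rng.poisson(lam)
    samples = pd.DataFrame(
        {"stage": stages_col, "replicate": reps_col},
        index=pd.Index(sample_ids, name="sample"),
    )
    return CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        samples,
    )


_BASES = np.array(list("ACGT"))


def cpg_transition_matrix(
    target_oe: float, gc_content: float
) -> tuple[np.ndarray, np.ndarray]:
    """First-order Markov transition matrix with a prescribed CpG o/e.

    Returns ``(P, pi)`` over the base order A, C, G, T such that ``pi`` is the
    stationary distribution (GC content as requested) and the stationary
    dinucleotide probability of CG equals ``target_oe * pi_C * pi_G``, making
    the long-run observed/expected CpG ratio equal to the target.  Raises
    :class:`ConfigurationError` when no stochastic matrix satisfies the pair.
    """
    if target_oe < 0:
        raise ConfigurationError("target CpG o/e must be >= 0")
    at = (1.0 - gc_content) / 2.0
    gcq = gc_content / 2.0
    pi = np.array([at, gcq, gcq, at])
    c_idx, g_idx = 1, 2
    q = np.outer(pi, pi)
    delta = (1.0 - target_oe) * pi[c_idx] * pi[g_idx]
    q[c_idx, g_idx] = target_oe * pi[c_idx] * pi[g_idx]
    others_g = [i for i in range(4) if i != g_idx]
    others_c = [i for i in range(4) if i != c_idx]
    q[c_idx, others_g] += delta * pi[others_g] / (1.0 - pi[g_idx])
    q[others_c, g_idx] += delta * pi[others_c] / (1.0 - pi[c_idx])
    q[np.ix_(others_c, others_g)] -= (
        delta
        * np.outer(pi[others_c], pi[others_g])
        / ((1.0 - pi[c_idx]) * (1.0 - pi[g_idx]))
    )
    if (q < -1e-12).any():
        raise ConfigurationError(
            f"target CpG o/e {target_oe} is incompatible with GC content {gc_content}"
        )
    q = np.clip(q, 0.0, None)
    p = q / q.sum(axis=1, keepdims=True)
    return p, pi


def _sample_markov_sequences(
    n: int, length: int, p: np.ndarray, pi: np.ndarray, rng: np.random.Generator
) -> list[str]:
    cum_p = np.cumsum(p, axis=1)
    states = np.searchsorted(np.cumsum(pi), rng.random(n), side="right")
    out = np.empty((n, length), dtype=np.int8)
    out[:, 0] = states
    for pos in range(1, length):
        u = rng.random(n)
        states = (u[:, None] > cum_p[states]).sum(axis=1)
        out[:, pos] = states
    return ["".join(row) for row in _BASES[out]]


def simulate_promoters(
    config: SimConfig, truth: Sequence[PlantedTruth]
) -> list[PromoterRecord]:
    """2-kb promoter sequences with class-specific CpG observed/expected.

    The TSS of each gene is placed at the midpoint of its DHS window, so the
    promoter window sits inside the region and midpoint-overlap assignment
    recovers the one-to-one gene/region pairing.
    """
    rng = config.rng(2)
    regions = _regions(config, truth)
    by_class: dict[str, list[int]] = {}
    for i, t in enumerate(truth):
        by_class.setdefault(t.true_class, []).append(i)
    sequences: dict[int, str] = {}
    for cls in sorted(by_class):
        idx = by_class[cls]
        p, pi = cpg_transition_matrix(config.cpg_target(cls), config.gc_content)
        for i, seq in zip(idx, _sample_markov_sequences(len(idx), 2000, p, pi, rng)):
            sequences[i] = seq
    return [
        PromoterRecord(
            truth[i].gene_id, regions[i].chrom, regions[i].midpoint, "+", sequences[i]
        )
        for i in range(len(truth))
    ]


@dataclass
class SyntheticDataset:
    """A complete synthetic experiment bundle."""

    profiles: ProfileSet
    rna: CountMatrix
    promoters: list[PromoterRecord]
    truth: pd.DataFrame
    config: SimConfig | None = None


def simulate_dataset(
    config: SimConfig, n_per_class: Mapping[str, int] | None = None
) -> SyntheticDataset:
    truth = make_truth(config, n_per_class)
    return SyntheticDataset(
        profiles=simulate_dhs_profiles(config, truth),
        rna=simulate_rna_counts(config, truth),
        promoters=simulate_promoters(config, truth),
        truth=truth_frame(truth, config.stages),
        config=config,
    )


def write_fixtures(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text fixtures; round-trips via read_fixtures."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["regions"] = out / "regions.bed"
    write_bed(dataset.profiles.regions, paths["regions"])
    for i, sample in enumerate(dataset.profiles.samples.index):
        p = out / f"dnase_{sample}.bedGraph"
        write_bedgraph(
            dataset.profiles.counts[i],
            dataset.profiles.regions,
            dataset.profiles.bin_size,
            p,
        )
        paths[f"dnase_{sample}"] = p
    paths["dnase_samples"] = out / "dnase_samples.tsv"
    dataset.profiles.samples.to_csv(paths["dnase_samples"], sep="\t")

    paths["rna_counts"] = out / "rna_counts.tsv"
    paths["rna_samples"] = out / "rna_samples.tsv"
    write_count_matrix(dataset.rna, paths["rna_counts"], paths["rna_samples"])

    paths["promoters"] = out / "promoters.fa"
    write_fasta({p.gene_id: p.sequence for p in dataset.promoters}, paths["promoters"])
    paths["tss"] = out / "tss.tsv"
    write_tss_table(dataset.promoters, paths["tss"])

    paths["truth"] = out / "truth.tsv"
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)

    if dataset.config is not None:
        paths["config"] = out / "config.yaml"
        cfg = asdict(dataset.config)
        cfg["stages"] = list(dataset.config.stages)
        if isinstance(cfg["target_cpg_oe"], Mapping):
            cfg["target_cpg_oe"] = dict(cfg["target_cpg_oe"])
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


def read_fixtures(out_dir: str | Path, bin_size: int | None = None) -> SyntheticDataset:
    """Read a fixture directory written by :func:`write_fixtures`."""
    out = Path(out_dir)
    config = None
    if (out / "config.yaml").exists():
        with open(out / "config.yaml") as fh:
            raw = yaml.safe_load(fh)
        raw["stages"] = tuple(raw["stages"])
        config = SimConfig(**raw)
    if bin_size is None:
        if config is None:
            raise ConfigurationError("bin_size required when config.yaml is absent")
        bin_size = config.bin_size

    regions = read_bed(out / "regions.bed")
    samples = pd.read_csv(out / "dnase_samples.tsv", sep="\t", index_col=0)
    matrices = read_bedgraph_matrix(
        {s: out / f"dnase_{s}.bedGraph" for s in samples.index}, regions, bin_size
    )
    counts = np.stack([matrices[s] for s in samples.index]).astype(np.int64)
    profiles = ProfileSet(counts, samples, regions, bin_size)

    rna = read_count_matrix(out / "rna_counts.tsv", out / "rna_samples.tsv")
    sequences = read_fasta(out / "promoters.fa")
    promoters = [
        rec.with_sequence(sequences[rec.gene_id]) for rec in read_tss_table(out / "tss.tsv")
    ]
    # keep_default_na: the class label "null" must survive the round trip
    truth = pd.read_csv(out / "truth.tsv", sep="\t", keep_default_na=False)
    return SyntheticDataset(profiles, rna, promoters, truth, config)
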