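"""Promoter CpG observed/expected analysis and group comparison.

The observed/expected CpG ratio of a promoter sequence is

    observed / (n_C * n_G / L)

where observed is the number of CG dinucleotides, n_C and n_G the C and G
counts and L the sequence length.  Unconstrained sequence gives a ratio near
1; CpG-depleted (low-CpG-content, LCG) promoters sit well below 1.  Group
differences are assessed with a Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

_VALID = set("ACGTN")


@dataclass(frozen=True)
class CpGResult:
    """CpG counts and observed/expected ratio for one promoter."""

    gene_id: str
    observed_cpg: int
    n_c: int
    n_g: int
    length: int
    oe_ratio: float | None  # None when expected = 0 (no C or no G)

    @property
    def expected_cpg(self) -> float:
        return self.n_c * self.n_g / self.length


def oe_cpg(sequence: str, gene_id: str = "") -> CpGResult:
    """Observed/expected CpG of a DNA sequence (A/C/G/T/N, forward strand).

    N contributes to the length but not to any count, and an N breaks the
    dinucleotide it touches.  Returns ``oe_ratio=None`` when the expected
    count is zero (sequence lacks C or G entirely).
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    extra = set(seq) - _VALID
    if extra:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(extra)}")
    n_c = seq.count("C")
    n_g = seq.count("G")
    observed = seq.count("CG")
    expected = n_c * n_g / len(seq)
    ratio = observed / expected if expected > 0 else None
    return CpGResult(gene_id, observed, n_c, n_g, len(seq), ratio)


def oe_cpg_table(sequences: Mapping[str, str]) -> pd.DataFrame:
    rows = []
    for gene_id, seq in sequences.items():
        r = oe_cpg(seq, gene_id)
        rows.append(
            {
                "gene_id": r.gene_id,
                "observed_cpg": r.observed_cpg,
                "n_c": r.n_c,
                "n_g": r.n_g,
                "length": r.length,
                "expected_cpg": r.expected_cpg,
                "oe_ratio": np.nan if r.oe_ratio is None else r.oe_ratio,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Mann-Whitney comparison of observed/expected ratios of two groups."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float
    method: str
    n_excluded: int = 0


def _clean(values: Iterable[float], label: str) -> np.ndarray:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    n_bad = int(np.isnan(arr).sum())
    if n_bad:
        warnings.warn(
            f"excluding {n_bad} undefined observed/expected ratio(s) from group {label!r}"
        )
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError(f"group {label!r} is empty after excluding undefined ratios")
    return arr


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Two-group Mann-Whitney U test on observed/expected ratios.

    Exact enumeration over rank assignments when ``n_a + n_b <= 16`` and
    there are no ties; otherwise the normal approximation with tie and
    continuity correction.  Undefined (NaN) ratios are excluded.
    """
    group_a, group_b = list(group_a), list(group_b)
    raw_n = len(group_a) + len(group_b)
    a = _clean(group_a, label_a)
    b = _clean(group_b, label_b)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size + b.size <= 16 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method, use_continuity=True)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
        n_excluded=raw_n - int(a.size) - int(b.size),
    )


def group_means(ratios_by_class: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-class mean observed/expected ratio, excluding undefined values."""
    rows = []
    for label, values in ratios_by_class.items():
        arr = np.asarray(list(values), dtype=float)
        defined = arr[~np.isnan(arr)]
        rows.append(
            {
                "dose_class": label,
                "n": int(defined.size),
                "n_excluded": int(arr.size - defined.size),
                "mean_oe": float(defined.mean()) if defined.size else np.nan,
                "median_oe": float(np.median(defined)) if defined.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
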