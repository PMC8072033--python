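"""Nonparametric spatial differential-accessibility testing on DHS windows.

Two replicate-aware scores compare the binned, RPM-normalised cut-count
profiles of a 4-kb DHS window between two conditions:

``ts_dnun``
    An unsmoothed, heteroscedasticity-robust score: the per-bin squared
    difference of condition means, standardised by the per-bin Welch variance
    ``s_A^2/n_A + s_B^2/n_B`` (plus a variance floor), averaged over bins.
``ts_kn``
    The same quadratic form computed on kernel-smoothed condition-mean curves
    (Nadaraya-Watson, Gaussian kernel on the bp scale) with a kernel-smoothed
    Welch variance term.  In the bandwidth -> 0 limit it equals ``ts_dnun``.

Both are sensitive to the three alternatives of interest: a peak present in
one condition only, a peak-height change, and a positional shift of the peak.

The null is built by permuting replicate labels.  Per region, all
``C(n_A + n_B, n_A)`` assignments are enumerated when feasible
(:func:`permutation_pvalue`).  With 2-3 replicates per condition that
enumeration is too coarse for small alpha, so the batch route
(:func:`stage_pair_test`) pools permutation statistics across all regions of
a run into a common null, with a generalized-Pareto tail fit for observations
beyond the pool's resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genomic_io import GenomicInterval, read_bed
from .profiles import ProfileSet

Statistic = Literal["dnun", "kn"]

DEFAULT_BANDWIDTH_BP = 150.0
DEFAULT_MAX_PERMS = 10_000
_ABS_FLOOR = 1e-12


def normalize_rpm(counts: np.ndarray, library_sizes: np.ndarray | float) -> np.ndarray:
    """Scale counts to reads per million mapped reads.

    ``library_sizes`` broadcasts against the leading (sample) axis of
    ``counts``.
    """
    counts = np.asarray(counts, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    shape = (libs.shape + (1,) * (counts.ndim - libs.ndim)) if libs.ndim else libs.shape
    return counts * (1e6 / libs.reshape(shape))


def gaussian_weights(n_bins: int, bin_size: float, bandwidth_bp: float) -> np.ndarray:
    """Row-normalised Gaussian kernel weight matrix on the bp scale.

    Row i holds the Nadaraya-Watson weights of every bin for the estimate at
    bin i; rows sum to 1, so a constant profile is preserved exactly.
    """
    if bandwidth_bp <= 0:
        raise ValueError("bandwidth must be positive")
    centers = (np.arange(n_bins) + 0.5) * bin_size
    z = (centers[:, None] - centers[None, :]) / bandwidth_bp
    # exp underflows harmlessly to 0 far from the diagonal
    with np.errstate(under="ignore"):
        w = np.exp(-0.5 * z**2)
    return w / w.sum(axis=1, keepdims=True)


def smooth_profile(
    profile: np.ndarray,
    bandwidth_bp: float = DEFAULT_BANDWIDTH_BP,
    bin_size: float = 20.0,
) -> np.ndarray:
    """Nadaraya-Watson smooth of a binned profile (last axis = bins)."""
    profile = np.asarray(profile, dtype=float)
    if profile.shape[-1] < 2:
        raise ValueError("need at least 2 bins")
    w = gaussian_weights(profile.shape[-1], bin_size, bandwidth_bp)
    return profile @ w.T


def _group_moments(x: np.ndarray, masks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-assignment group means and ddof-1 variances for the masked rows.

    ``x`` is (n, B); ``masks`` is a (K, n) boolean matrix selecting group
    members per assignment (all assignments share the group size).
    Returns (means, variances), each (K, B).
    """
    n = int(masks[0].sum())
    if n < 2:
        raise ValueError("need >= 2 replicates per condition")
    m = masks.astype(float)
    s1 = m @ x
    s2 = m @ (x**2)
    mean = s1 / n
    var = np.clip((s2 - n * mean**2) / (n - 1), 0.0, None)
    return mean, var


def _assignment_stats(
    x: np.ndarray,
    masks_a: np.ndarray,
    n_a: int,
    n_b: int,
    statistic: Statistic,
    bandwidth_bp: float = DEFAULT_BANDWIDTH_BP,
    bin_size: float = 20.0,
    smoother: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate a TS statistic for every replicate-label assignment.

    ``x`` is the pooled (n_a + n_b, B) RPM matrix; row i of ``masks_a``
    selects the rows assigned to condition A in assignment i.
    """
    mean_a, var_a = _group_moments(x, masks_a)
    mean_b, var_b = _group_moments(x, ~masks_a)
    welch = var_a / n_a + var_b / n_b
    diff = mean_a - mean_b
    if statistic == "kn":
        w = smoother
        if w is None:
            w = gaussian_weights(x.shape[1], bin_size, bandwidth_bp)
        diff = diff @ w.T
        welch = welch @ w.T
    elif statistic != "dnun":
        raise ValueError(f"unknown statistic {statistic!r}")
    eps = 0.5 * np.median(welch, axis=1, keepdims=True) + _ABS_FLOOR
    return np.mean(diff**2 / (welch + eps), axis=1)


def _pooled(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int, int]:
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("conditions have different bin counts")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 replicates per condition")
    return np.vstack([a, b]), a.shape[0], b.shape[0]


def _identity_first_masks(n_a: int, n_b: int) -> np.ndarray:
    """Replicate-label assignments as boolean masks, identity first.

    Both TS statistics are invariant under swapping the two group labels, so
    when ``n_a == n_b`` every assignment and its complement give the same
    value.  Each complementary pair is then enumerated once (sample 0 pinned
    to group A), which leaves tail counts over the full ``C(n, n_a)``
    enumeration unchanged while keeping duplicate values out of pooled nulls.
    """
    n = n_a + n_b
    if n_a == n_b:
        combos = [(0,) + rest for rest in combinations(range(1, n), n_a - 1)]
    else:
        combos = list(combinations(range(n), n_a))
    masks = np.zeros((len(combos), n), dtype=bool)
    for i, combo in enumerate(combos):
        masks[i, list(combo)] = True
    return masks  # combinations() yields (0..n_a-1) first = identity


def ts_dnun(a: np.ndarray, b: np.ndarray) -> float:
    """Unsmoothed heteroscedasticity-robust differential-accessibility score.

    ``a`` and ``b`` are (n_replicates, n_bins) RPM profiles of one region
    under the two conditions.
    """
    x, n_a, n_b = _pooled(a, b)
    masks = np.zeros((1, n_a + n_b), dtype=bool)
    masks[0, :n_a] = True
    return float(_assignment_stats(x, masks, n_a, n_b, "dnun")[0])


def ts_kn(
    a: np.ndarray,
    b: np.ndarray,
    bandwidth_bp: float = DEFAULT_BANDWIDTH_BP,
    bin_size: float = 20.0,
) -> float:
    """Kernel-smoothed differential-accessibility score."""
    x, n_a, n_b = _pooled(a, b)
    masks = np.zeros((1, n_a + n_b), dtype=bool)
    masks[0, :n_a] = True
    return float(
        _assignment_stats(x, masks, n_a, n_b, "kn", bandwidth_bp, bin_size)[0]
    )


def permutation_stats(
    a: np.ndarray,
    b: np.ndarray,
    statistic: Statistic = "dnun",
    max_perms: int = DEFAULT_MAX_PERMS,
    seed: int | np.random.Generator | None = None,
    bandwidth_bp: float = DEFAULT_BANDWIDTH_BP,
    bin_size: float = 20.0,
    smoother: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Statistic values over replicate-label assignments, identity first.

    Exhaustive over all ``C(n_a+n_b, n_a)`` assignments when that count is
    <= ``max_perms``; otherwise the identity plus ``max_perms`` Monte-Carlo
    draws.  Returns ``(values, exhaustive)``.
    """
    x, n_a, n_b = _pooled(a, b)
    n = n_a + n_b
    total = math.comb(n, n_a)
    if total < 2:
        raise ValueError("fewer than 2 label assignments exist")
    if total <= max_perms:
        masks = _identity_first_masks(n_a, n_b)
        exhaustive = True
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        masks = np.zeros((max_perms + 1, n), dtype=bool)
        masks[0, :n_a] = True
        draws = np.argsort(rng.random((max_perms, n)), axis=1)[:, :n_a]
        rows = np.repeat(np.arange(1, max_perms + 1), n_a)
        masks[rows, draws.ravel()] = True
        exhaustive = False
    values = _assignment_stats(
        x, masks, n_a, n_b, statistic, bandwidth_bp, bin_size, smoother
    )
    return values, exhaustive


def permutation_pvalue(
    a: np.ndarray,
    b: np.ndarray,
    statistic: Statistic = "dnun",
    max_perms: int = DEFAULT_MAX_PERMS,
    seed: int | np.random.Generator | None = None,
    bandwidth_bp: float = DEFAULT_BANDWIDTH_BP,
    bin_size: float = 20.0,
) -> tuple[float, int]:
    """Per-region permutation p-value for one condition pair.

    Exhaustive enumeration counts every assignment with statistic >= observed
    (identity included, so p > 0 always); Monte-Carlo uses the add-one
    estimator.  Ties count as >= (conservative).  Returns
    ``(p, n_assignments_evaluated)``.
    """
    values, exhaustive = permutation_stats(
        a, b, statistic, max_perms, seed, bandwidth_bp, bin_size
    )
    observed = values[0]
    ge = int(np.sum(values >= observed * (1.0 - 1e-12) - _ABS_FLOOR))
    n_a = np.atleast_2d(a).shape[0]
    n_b = np.atleast_2d(b).shape[0]
    if exhaustive:
        # tail fractions over distinct splits equal those over the full
        # C(n_a+n_b, n_a) enumeration (label-swap symmetry)
        p = ge / len(values)
        n_eval = math.comb(n_a + n_b, n_a)
    else:
        # identity row excluded from the draws; add-one on both sides
        ge_mc = int(np.sum(values[1:] >= observed * (1.0 - 1e-12) - _ABS_FLOOR))
        p = (1 + ge_mc) / len(values)
        n_eval = len(values)
    return float(p), int(n_eval)


def pooled_pvalues(
    observed: np.ndarray,
    pool: np.ndarray,
    min_tail_count: int = 10,
    tail_frac: float = 0.05,
) -> np.ndarray:
    """p-values of observed statistics against a pooled permutation null.

    The baseline estimate is the add-one empirical tail probability
    ``(1 + #{pool >= obs}) / (1 + N)``.  When fewer than ``min_tail_count``
    pooled values reach the observation, the estimate is refined by a
    generalized-Pareto fit to the exceedances over the pool's
    ``(1 - tail_frac)`` quantile, which extends resolution below ``1/(N+1)``
    without touching calibration at moderate significance levels.
    """
    observed = np.asarray(observed, dtype=float)
    pool = np.sort(np.asarray(pool, dtype=float))
    n = pool.size
    if n == 0:
        raise ValueError("empty permutation pool")
    ge = n - np.searchsorted(pool, observed * (1.0 - 1e-12) - _ABS_FLOOR, side="left")
    p = (1.0 + ge) / (1.0 + n)

    needs_tail = ge < min_tail_count
    if not needs_tail.any():
        return p
    u = pool[int(np.floor((1.0 - tail_frac) * (n - 1)))]
    exceed = pool[pool > u] - u
    if exceed.size >= 30:
        try:
            shape, _, scale = sps.genpareto.fit(exceed, floc=0.0)
            frac = exceed.size / n
            with np.errstate(over="ignore", invalid="ignore"):
                tail_p = frac * sps.genpareto.sf(observed - u, shape, loc=0.0, scale=scale)
            ok = needs_tail & (observed > u) & np.isfinite(tail_p)
            # never above the empirical estimate; never exactly 0
            p[ok] = np.clip(np.minimum(p[ok], tail_p[ok]), 1e-300, None)
        except Exception:  # fit failure -> keep empirical estimates
            pass
    return p


@dataclass
class StagePairResult:
    """Differential-accessibility results for one stage pair (a DataFrame plus
    the permutation pool used to compute the p-values)."""

    table: pd.DataFrame
    null_pool: np.ndarray


def stage_pair_test(
    pset: ProfileSet,
    stage_a: str,
    stage_b: str,
    statistic: Statistic = "dnun",
    method: Literal["pooled", "per_region"] = "pooled",
    max_perms: int = DEFAULT_MAX_PERMS,
    seed: int | np.random.Generator | None = None,
    bandwidth_bp: float = DEFAULT_BANDWIDTH_BP,
) -> pd.DataFrame:
    """Test every region of a profile set for differential accessibility.

    Returns a DataFrame with columns ``region_id, stage_a, stage_b, ts_kn,
    ts_dnun, p_perm, p_adjusted, delta_mean_rpm, n_permutations``
    (``p_adjusted`` is NaN until :func:`adjust_effective_bonferroni`).

    ``method='pooled'`` builds a common null from the non-identity
    permutation statistics of all regions (valid because regions are tested
    under a shared exchangeability null); ``method='per_region'`` uses the
    exact per-region enumeration, whose resolution is limited to
    ``1/C(n_a+n_b, n_a)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ia = pset.sample_indices(stage_a)
    ib = pset.sample_indices(stage_b)
    rpm = pset.rpm()
    smoother = gaussian_weights(pset.n_bins, pset.bin_size, bandwidth_bp)

    rows = []
    obs_chosen = np.empty(pset.n_regions)
    pool_parts = []
    for ri in range(pset.n_regions):
        a = rpm[ia, ri, :]
        b = rpm[ib, ri, :]
        kn = float(
            _assignment_stats(
                np.vstack([a, b]),
                np.arange(len(ia) + len(ib))[None, :] < len(ia),
                len(ia), len(ib), "kn", smoother=smoother,
            )[0]
        )
        dnun = ts_dnun(a, b)
        values, _ = permutation_stats(
            a, b, statistic, max_perms, rng,
            bandwidth_bp, pset.bin_size, smoother,
        )
        obs_chosen[ri] = values[0]
        pool_parts.append(values[1:])
        rows.append(
            {
                "region_id": pset.regions[ri].id,
                "stage_a": stage_a,
                "stage_b": stage_b,
                "ts_kn": kn,
                "ts_dnun": dnun,
                "delta_mean_rpm": float(a.mean(axis=0).mean() - b.mean(axis=0).mean()),
                "n_permutations": len(values) - 1,
            }
        )
    table = pd.DataFrame(rows)

    if method == "pooled":
        pool = np.concatenate(pool_parts)
        table["p_perm"] = pooled_pvalues(obs_chosen, pool)
        table["n_permutations"] = pool.size
    elif method == "per_region":
        pvals = []
        for ri in range(pset.n_regions):
            p, _ = permutation_pvalue(
                rpm[ia, ri, :], rpm[ib, ri, :], statistic, max_perms, rng,
                bandwidth_bp, pset.bin_size,
            )
            pvals.append(p)
        table["p_perm"] = pvals
    else:
        raise ValueError(f"unknown method {method!r}")
    table["p_adjusted"] = np.nan
    return table[
        [
            "region_id", "stage_a", "stage_b", "ts_kn", "ts_dnun",
            "p_perm", "p_adjusted", "delta_mean_rpm", "n_permutations",
        ]
    ]


def overlap_clusters(regions: Sequence[GenomicInterval]) -> dict[str, int]:
    """Single-linkage clusters of genomically overlapping regions.

    Returns region id -> cluster index; the cluster count operationalises the
    effective number of tests.
    """
    order = sorted(range(len(regions)), key=lambda i: (regions[i].chrom, regions[i].start))
    cluster_of: dict[str, int] = {}
    cluster = -1
    cur_chrom, cur_end = None, -1
    for i in order:
        r = regions[i]
        if r.chrom != cur_chrom or r.start >= cur_end:
            cluster += 1
            cur_chrom, cur_end = r.chrom, r.end
        else:
            cur_end = max(cur_end, r.end)
        cluster_of[r.id] = cluster
    return cluster_of


def adjust_effective_bonferroni(
    results: pd.DataFrame,
    regions: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Bonferroni adjustment on the effective number of tests.

    Overlapping regions are merged into single-linkage clusters; the cluster
    p is the minimum member p and the effective number of tests is the number
    of clusters.  Per member,
    ``p_adjusted = min(1, max(p_perm, cluster_p * n_clusters))`` so the
    adjustment never decreases any region's p-value while the cluster-level
    call is driven by its best member.  Applied within each stage pair.
    """
    cluster_of = overlap_clusters(regions)
    out = results.copy()
    out["cluster_id"] = out["region_id"].map(cluster_of)
    if out["cluster_id"].isna().any():
        missing = out.loc[out["cluster_id"].isna(), "region_id"].iloc[0]
        raise KeyError(f"region {missing!r} not in the supplied region list")
    adj = np.empty(len(out))
    for _, idx in out.groupby(["stage_a", "stage_b"]).groups.items():
        sub = out.loc[idx]
        n_clusters = sub["cluster_id"].nunique()
        cluster_min = sub.groupby("cluster_id")["p_perm"].transform("min")
        adj_vals = np.minimum(1.0, np.maximum(sub["p_perm"], cluster_min * n_clusters))
        adj[out.index.get_indexer(idx)] = adj_vals
    out["p_adjusted"] = adj
    return out


def call_accessibility(
    pset: ProfileSet,
    hotspot_beds: Mapping[str, str] | None = None,
    tau: float | None = None,
    central_bp: int = 1000,
) -> pd.DataFrame:
    """Per-region, per-stage accessibility calls.

    With ``hotspot_beds`` (stage -> BED path of hotspot intervals), a region
    is accessible in a stage iff its midpoint falls inside a hotspot.
    Otherwise a threshold rule is used: accessible iff the mean RPM per bin
    over the central ``central_bp`` of the window is >= ``tau``; the default
    ``tau`` is 3x a background estimate taken as the stage's 25th percentile
    of per-bin mean RPM across all regions.
    """
    rpm = pset.rpm()
    b0 = (pset.n_bins - central_bp // pset.bin_size) // 2
    b1 = b0 + central_bp // pset.bin_size
    rows = []
    if hotspot_beds is not None:
        trees: dict[str, dict[str, "object"]] = {}
        from intervaltree import IntervalTree

        for stage, path in hotspot_beds.items():
            per_chrom: dict[str, IntervalTree] = {}
            for iv in read_bed(path):
                per_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
            trees[stage] = per_chrom
    for stage in pset.stages:
        idx = pset.sample_indices(stage)
        mean_profile = rpm[idx].mean(axis=0)  # (n_regions, n_bins)
        central = mean_profile[:, b0:b1].mean(axis=1)
        if hotspot_beds is not None:
            if stage not in trees:
                raise KeyError(f"no hotspot BED supplied for stage {stage!r}")
            for ri, region in enumerate(pset.regions):
                tree = trees[stage].get(region.chrom)
                hit = bool(tree is not None and tree.at(region.midpoint))
                rows.append(
                    {
                        "region_id": region.id,
                        "stage": stage,
                        "accessible": hit,
                        "mean_rpm": float(central[ri]),
                        "source": "hotspot_bed",
                    }
                )
        else:
            stage_tau = tau
            if stage_tau is None:
                background = float(np.percentile(mean_profile, 25))
                stage_tau = 3.0 * background
            for ri, region in enumerate(pset.regions):
                rows.append(
                    {
                        "region_id": region.id,
                        "stage": stage,
                        "accessible": bool(central[ri] >= stage_tau),
                        "mean_rpm": float(central[ri]),
                        "source": "threshold",
                    }
                )
    return pd.DataFrame(rows)
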