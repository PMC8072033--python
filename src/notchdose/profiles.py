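"""In-memory container for binned DNase cut-count profiles.

A :class:`ProfileSet` holds, for a common set of fixed-length DHS windows,
one binned cut-count track per sample, together with the per-sample stage
label and library size needed for reads-per-million normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import GenomicInterval


@dataclass
class ProfileSet:
    """Binned cut-count profiles for a set of equal-length regions.

    Attributes
    ----------
    counts
        Array of shape ``(n_samples, n_regions, n_bins)`` of cut counts.
    samples
        DataFrame indexed by sample id with columns ``stage``, ``replicate``
        and ``library_size`` (total mapped reads of the sample).
    regions
        The DHS windows, all of the same length ``n_bins * bin_size``.
    bin_size
        Bin width in bp.
    """

    counts: np.ndarray
    samples: pd.DataFrame
    regions: list[GenomicInterval]
    bin_size: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must have shape (n_samples, n_regions, n_bins)")
        n_samples, n_regions, n_bins = self.counts.shape
        if len(self.samples) != n_samples:
            raise ValueError("sample sheet does not match counts")
        if len(self.regions) != n_regions:
            raise ValueError("region list does not match counts")
        for col in ("stage", "library_size"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        if self.regions and len(self.regions[0]) != n_bins * self.bin_size:
            raise ValueError("region length != n_bins * bin_size")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_regions(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.samples["stage"]))

    def sample_indices(self, stage: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["stage"] == stage).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no samples for stage {stage!r}")
        return idx

    def rpm(self) -> np.ndarray:
        """Reads-per-million normalised profiles, same shape as counts."""
        from .diffaccess import normalize_rpm  # local import avoids a cycle

        libs = self.samples["library_size"].to_numpy(dtype=float)
        return normalize_rpm(self.counts, libs)

    def stage_rpm(self, stage: str) -> np.ndarray:
        """RPM profiles of one stage, shape (n_replicates, n_regions, n_bins)."""
        return self.rpm()[self.sample_indices(stage)]

    def region_index(self, region_id: str) -> int:
        for i, region in enumerate(self.regions):
            if region.id == region_id:
                return i
        raise KeyError(f"unknown region {region_id!r}")


def region_profile(pset: ProfileSet, region_id: str, stage: str) -> np.ndarray:
    """RPM profiles of one region and stage, shape (n_replicates, n_bins)."""
    return pset.stage_rpm(stage)[:, pset.region_index(region_id), :]


def concat_profile_sets(sets: Sequence[ProfileSet]) -> ProfileSet:
    """Concatenate sets that share a sample sheet along the region axis."""
    first = sets[0]
    for other in sets[1:]:
        if not first.samples.equals(other.samples):
            raise ValueError("profile sets have different sample sheets")
    counts = np.concatenate([s.counts for s in sets], axis=1)
    regions = [r for s in sets for r in s.regions]
    return ProfileSet(counts, first.samples, regions, first.bin_size)
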