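"""Diversity indices for benthic macroinvertebrate count data.

Three classical community summaries, all computed from a vector of
per-taxon individual counts for one station-month sample:

* Shannon index  ``H = -sum_i P_i ln P_i``  — entropy of the relative
  abundance distribution; 0 for a monoculture, ``ln s`` at perfect evenness.
* Simpson index  ``D = 1 - sum_i P_i^2``  — probability that two randomly
  drawn individuals belong to different taxa; bounded by ``1 - 1/s``.
* Margalef index ``MI = (s - 1) / ln N`` — taxon richness normalised by
  sample size; undefined for N <= 1.

Here ``P_i`` is the relative abundance of taxon *i*, ``s`` the number of taxa
present, and ``N`` the total number of individuals. Natural logarithms
throughout. Zero-count taxa contribute nothing (0 ln 0 := 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, DuplicateSampleError, InvalidSampleError

__all__ = [
    "AbundanceVector",
    "shannon_index",
    "simpson_index",
    "margalef_index",
    "compute_indices_table",
    "INDEX_COLUMNS",
]

INDEX_COLUMNS = ("shannon", "simpson", "margalef")


@dataclass(frozen=True)
class AbundanceVector:
    """Taxon counts for one station-month sample.

    Counts are non-negative integers; at least one must be positive.
    """

    station: str
    month: int
    taxon_ids: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.taxon_ids) != len(self.counts):
            raise InvalidSampleError("taxon_ids and counts differ in length")
        if len(self.counts) == 0:
            raise InvalidSampleError("empty count vector")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise InvalidSampleError("counts must be non-negative integers")
        if sum(self.counts) == 0:
            raise InvalidSampleError("all-zero count vector")

    @property
    def n_individuals(self) -> int:
        return int(sum(self.counts))

    @property
    def richness(self) -> int:
        return int(sum(1 for c in self.counts if c > 0))

    def relative_abundances(self) -> np.ndarray:
        """P_i over taxa with count > 0; sums to 1."""
        counts = np.asarray([c for c in self.counts if c > 0], dtype=float)
        return counts / counts.sum()


def _positive_counts(counts) -> np.ndarray:
    if isinstance(counts, AbundanceVector):
        counts = counts.counts
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidSampleError("count vector must be a non-empty 1-D array")
    if np.any(arr < 0):
        raise InvalidSampleError("counts must be non-negative")
    arr = arr[arr > 0]
    if arr.size == 0:
        raise InvalidSampleError("all-zero count vector")
    return arr


def shannon_index(counts) -> float:
    """Shannon entropy -sum P_i ln P_i of the abundance distribution."""
    arr = _positive_counts(counts)
    p = arr / arr.sum()
    return float(-np.sum(p * np.log(p)))


def simpson_index(counts) -> float:
    """Simpson diversity 1 - sum P_i^2."""
    arr = _positive_counts(counts)
    p = arr / arr.sum()
    return float(1.0 - np.sum(p * p))


def margalef_index(counts) -> float:
    """Margalef richness (s - 1) / ln N; requires N >= 2."""
    arr = _positive_counts(counts)
    n = arr.sum()
    if n < 2:
        raise DegenerateSampleError(f"Margalef index undefined for N={int(n)} (ln N <= 0)")
    return float((arr.size - 1) / np.log(n))


def compute_indices_table(samples: Iterable[AbundanceVector] | pd.DataFrame) -> pd.DataFrame:
    """Compute all three indices per station-month sample.

    Accepts either an iterable of :class:`AbundanceVector` or a wide count
    DataFrame with ``station`` and ``month`` columns followed by one integer
    column per taxon. Returns a tidy frame with columns
    ``station, month, shannon, simpson, margalef``.
    """
    if isinstance(samples, pd.DataFrame):
        samples = abundance_vectors_from_frame(samples)
    rows = []
    seen: set[tuple[str, int]] = set()
    for sample in samples:
        key = (sample.station, sample.month)
        if key in seen:
            raise DuplicateSampleError(f"duplicate sample key {key}")
        seen.add(key)
        rows.append(
            {
                "station": sample.station,
                "month": sample.month,
                "shannon": shannon_index(sample),
                "simpson": simpson_index(sample),
                "margalef": margalef_index(sample),
            }
        )
    return pd.DataFrame(rows, columns=["station", "month", *INDEX_COLUMNS])


def abundance_vectors_from_frame(counts: pd.DataFrame) -> list[AbundanceVector]:
    """Split a wide count table into per-sample abundance vectors."""
    for col in ("station", "month"):
        if col not in counts.columns:
            raise InvalidSampleError(f"count table missing {col!r} column")
    taxa = [c for c in counts.columns if c not in ("station", "month")]
    if not taxa:
        raise InvalidSampleError("count table has no taxon columns")
    out = []
    for _, row in counts.iterrows():
        out.append(
            AbundanceVector(
                station=str(row["station"]),
                month=int(row["month"]),
                taxon_ids=tuple(taxa),
                counts=tuple(int(row[t]) for t in taxa),
            )
        )
    return out
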