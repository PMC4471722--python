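"""Survey coverage statistics for a flow-sorted chromosome read set.

Given per-library read counts N and mean read lengths L, a chromosome
size estimate S and a flow-sorting purity, this module computes
sequencing coverage (total bases / S) and the probability that any given
chromosome position is represented at least once in the read set.

Two conventions for applying purity to the representation probability are
supported:

``exponent``
    P = 1 − (1 − L/S)^(N·purity) — purity thins the effective read count.
``outer`` (default)
    P = purity · [1 − (1 − L/S)^N] — a position can only be represented if
    the locus was sorted at all; among sorted material coverage is complete
    with probability 1 − (1 − L/S)^N.

The two differ by ~3% at survey-scale inputs; both are reported, see
docs/methods.md for the discrepancy discussion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import ReadRecord


@dataclass
class LibraryStats:
    """Aggregate metrics for one sequencing library."""

    name: str
    n_reads: int
    mean_len: float
    total_len: int

    def __post_init__(self) -> None:
        if self.n_reads < 0 or self.total_len < 0:
            raise ValueError(f"library {self.name!r}: negative counts")


@dataclass
class SurveyParams:
    """Chromosome size estimate (bases) and sorting purity (fraction)."""

    chromosome_size: float
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.chromosome_size <= 0:
            raise ValueError("chromosome_size must be positive")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must be in (0, 1]")


def library_stats(
    reads_by_library: Mapping[str, Sequence[ReadRecord]] | Iterable[LibraryStats],
) -> list[LibraryStats]:
    """Per-library stats plus a "Combined" row.

    The combined mean read length follows the survey-table convention: the
    unweighted arithmetic mean of the per-library means, rounded to one
    decimal. The length-weighted mean (total_len / n_reads) is recoverable
    from the combined totals and generally differs.
    """
    stats: list[LibraryStats] = []
    if isinstance(reads_by_library, Mapping):
        for name, reads in reads_by_library.items():
            if not reads:
                raise ValueError(f"library {name!r} is empty")
            total = sum(len(r) for r in reads)
            stats.append(
                LibraryStats(
                    name=name,
                    n_reads=len(reads),
                    mean_len=round(total / len(reads), 1),
                    total_len=total,
                )
            )
    else:
        stats = list(reads_by_library)
    if not stats:
        raise ValueError("at least one library required")
    combined = LibraryStats(
        name="Combined",
        n_reads=sum(s.n_reads for s in stats),
        mean_len=round(sum(s.mean_len for s in stats) / len(stats), 1),
        total_len=sum(s.total_len for s in stats),
    )
    return stats + [combined]


def weighted_mean_length(stats: Sequence[LibraryStats]) -> float:
    """Length-weighted combined mean: total bases over total reads."""
    per_lib = [s for s in stats if s.name != "Combined"]
    n = sum(s.n_reads for s in per_lib)
    if n == 0:
        raise ValueError("no reads")
    return sum(s.total_len for s in per_lib) / n


def sequencing_coverage(total_len: float, chromosome_size: float) -> float:
    """Fold-coverage of the chromosome: total read bases / S, 2 decimals."""
    if chromosome_size <= 0:
        raise ValueError("chromosome_size must be positive")
    return round(total_len / chromosome_size, 2)


def representation_probability(
    n_reads: float,
    mean_len: float,
    chromosome_size: float,
    purity: float = 1.0,
    mode: str = "outer",
) -> float:
    """Probability that a given chromosome position is covered >= once.

    Reads are modelled as independently, uniformly placed intervals of
    length L on a chromosome of size S; a fixed position is missed by one
    read with probability 1 − L/S. Purity enters per ``mode`` (module
    docstring). Result lies in [0, 1]; in outer mode it cannot exceed the
    purity.
    """
    if chromosome_size <= 0:
        raise ValueError("chromosome_size must be positive")
    if mean_len >= chromosome_size:
        raise ValueError("mean read length must be smaller than the chromosome")
    if mean_len <= 0 and n_reads > 0:
        raise ValueError("mean read length must be positive")
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    if n_reads == 0:
        return 0.0
    miss = 1.0 - mean_len / chromosome_size
    if mode == "exponent":
        return 1.0 - miss ** (n_reads * purity)
    if mode == "outer":
        return purity * (1.0 - miss**n_reads)
    raise ValueError(f"unknown mode {mode!r}")


def poisson_approximation(
    n_reads: float, mean_len: float, chromosome_size: float, purity: float = 1.0
) -> float:
    """Poisson-coverage limit 1 − exp(−N·purity·L/S) of the exponent-mode
    formula, exposed for numerical cross-checks."""
    return 1.0 - math.exp(-n_reads * purity * mean_len / chromosome_size)


def survey_table(
    stats: Sequence[LibraryStats], params: SurveyParams, prob_mode: str = "outer"
) -> pd.DataFrame:
    """Survey summary table: one row per library plus the combined row with
    coverage and representation probability (both purity conventions)."""
    rows = []
    for s in stats:
        row: dict[str, object] = {
            "library": s.name,
            "n_reads": s.n_reads,
            "mean_len_bp": s.mean_len,
            "total_len_bp": s.total_len,
        }
        if s.name == "Combined":
            row["coverage"] = sequencing_coverage(s.total_len, params.chromosome_size)
            row["probability"] = round(
                representation_probability(
                    s.n_reads, s.mean_len, params.chromosome_size, params.purity, prob_mode
                ),
                3,
            )
            alt = "exponent" if prob_mode == "outer" else "outer"
            row[f"probability_{alt}"] = round(
                representation_probability(
                    s.n_reads, s.mean_len, params.chromosome_size, params.purity, alt
                ),
                3,
            )
        rows.append(row)
    return pd.DataFrame(rows)
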