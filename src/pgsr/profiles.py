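"""Hit-table and read-mapping filters, relative abundance, habitat categories.

All homology evidence enters the pipeline as tabular records: BLAST-style
alignment hits (``AlignmentHit``) and per-read mapping records
(``ReadMapRecord``).  Every screen in the pipeline is a threshold filter
over these records; every numeric threshold is *inclusive* ("or over",
"or lower", "or more").  Relative abundance is expressed as valid hits per
megabase of the searched data set; virome representation as reads mapped
per megabase of reference sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "AlignmentHit",
    "ReadMapRecord",
    "StringencyPolicy",
    "HIGH_STRINGENCY",
    "LOW_STRINGENCY",
    "LOW_STRINGENCY_75",
    "AbundanceProfile",
    "HabitatCall",
    "filter_hits",
    "deduplicate_best_hit",
    "orf_relative_abundance",
    "filter_read_mappings",
    "representation",
    "classify_habitat",
    "chi_square_proportions",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise homology hit (BLAST tabular semantics).

    ``align_len`` is in the unit of the search (nt for blastn-style, aa for
    translated searches); callers state which via the filters they apply.
    Coverages are fractions of the respective full-length sequence and are
    populated on ingestion from a companion id -> length table (the
    12-column tabular dialect does not carry them).
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_len: int
    e_value: float
    bit_score: float
    subject_coverage: float = math.nan
    query_coverage: float = math.nan

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent_identity outside [0,100]: {self.percent_identity}")
        if self.e_value < 0:
            raise ValueError(f"negative e-value: {self.e_value}")
        for cov in (self.subject_coverage, self.query_coverage):
            if not math.isnan(cov) and not 0.0 <= cov <= 1.0:
                raise ValueError(f"coverage outside [0,1]: {cov}")


@dataclass(frozen=True)
class ReadMapRecord:
    """One read mapped to one reference sequence."""

    read_id: str
    reference_id: str
    percent_identity: float
    read_fraction_aligned: float
    mismatch_fraction: float
    gap_fraction: float

    def __post_init__(self) -> None:
        for name in ("read_fraction_aligned", "mismatch_fraction", "gap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {v}")


@dataclass(frozen=True)
class StringencyPolicy:
    """Thresholds for read-mapping filters; all inclusive."""

    name: str
    min_identity: float
    min_read_fraction: float
    max_mismatch_fraction: float
    max_gap_fraction: float

    def accepts(self, rec: ReadMapRecord) -> bool:
        return (
            rec.percent_identity >= self.min_identity
            and rec.read_fraction_aligned >= self.min_read_fraction
            and rec.mismatch_fraction <= self.max_mismatch_fraction
            and rec.gap_fraction <= self.max_gap_fraction
        )


#: 90% identity over 90% of the read, max 10% mismatches, no gaps.
HIGH_STRINGENCY = StringencyPolicy("high", 90.0, 0.90, 0.10, 0.00)
#: 70% identity over 25% of the read, max 10% mismatches and 10% gaps.
LOW_STRINGENCY = StringencyPolicy("low", 70.0, 0.25, 0.10, 0.10)
#: Variant of the low-stringency policy with the identity floor at 75%.
LOW_STRINGENCY_75 = StringencyPolicy("low75", 75.0, 0.25, 0.10, 0.10)


@dataclass(frozen=True)
class AbundanceProfile:
    """Valid-hit count normalized by data-set size in Mb."""

    reference_set_id: str
    dataset_size_mb: float
    hit_count: int
    hits_per_mb: float


@dataclass(frozen=True)
class HabitatCall:
    """Habitat affiliation of one phage from gut vs non-gut hit rates.

    Categories: GT gut-only, NG non-gut-only, GAH both with gut majority,
    GAL both with non-gut majority or tie, UNCLASS no valid hits anywhere.
    """

    phage_id: str
    category: str
    gut_rate: float
    nongut_rate: float


def filter_hits(
    hits: list[AlignmentHit],
    min_identity: float | None = None,
    min_align_len: int | None = None,
    max_e: float | None = None,
    min_subject_coverage: float | None = None,
) -> list[AlignmentHit]:
    """Keep hits passing every given threshold (all inclusive)."""
    out = []
    for h in hits:
        if min_identity is not None and h.percent_identity < min_identity:
            continue
        if min_align_len is not None and h.align_len < min_align_len:
            continue
        if max_e is not None and h.e_value > max_e:
            continue
        if min_subject_coverage is not None and not (
            h.subject_coverage >= min_subject_coverage
        ):
            continue
        out.append(h)
    return out


def deduplicate_best_hit(
    hits: list[AlignmentHit], key: str = "subject"
) -> list[AlignmentHit]:
    """Reduce a hit table to the single best hit per subject (or query).

    Best = maximum bit score; ties broken by lower e-value, then by
    lexicographic id of the other end of the pair.  Output is ordered by
    key id.
    """
    if key not in ("subject", "query"):
        raise ValueError("key must be 'subject' or 'query'")
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        k = h.subject_id if key == "subject" else h.query_id
        other = h.query_id if key == "subject" else h.subject_id
        cur = best.get(k)
        if cur is None:
            best[k] = h
            continue
        cur_other = cur.query_id if key == "subject" else cur.subject_id
        if (-h.bit_score, h.e_value, other) < (-cur.bit_score, cur.e_value, cur_other):
            best[k] = h
    return [best[k] for k in sorted(best)]


def orf_relative_abundance(
    hits: list[AlignmentHit],
    dataset_size_mb: float,
    min_identity: float = 35.0,
    min_align_len: int = 30,
    max_e: float = 1e-5,
    reference_set_id: str = "",
) -> AbundanceProfile:
    """Relative abundance of an ORF in a data set, as valid hits per Mb.

    A valid hit has >= 35% identity over >= 30 aa at e-value <= 1e-5
    (defaults; all thresholds inclusive).
    """
    if dataset_size_mb <= 0:
        raise ValueError("dataset_size_mb must be positive")
    kept = filter_hits(hits, min_identity, min_align_len, max_e)
    return AbundanceProfile(
        reference_set_id, dataset_size_mb, len(kept), len(kept) / dataset_size_mb
    )


def filter_read_mappings(
    records: list[ReadMapRecord], policy: StringencyPolicy
) -> list[ReadMapRecord]:
    """Apply a stringency policy, keeping each read at most once.

    A read is only permitted to map to a single reference sequence per data
    set: among its surviving records the best identity wins (ties by
    reference id, for determinism).
    """
    survivors = [r for r in records if policy.accepts(r)]
    best: dict[str, ReadMapRecord] = {}
    for r in survivors:
        cur = best.get(r.read_id)
        if cur is None or (-r.percent_identity, r.reference_id) < (
            -cur.percent_identity,
            cur.reference_id,
        ):
            best[r.read_id] = r
    return [best[k] for k in sorted(best)]


def representation(records_kept: list[ReadMapRecord] | int, reference_size_mb: float) -> float:
    """Reads mapped per Mb of reference sequence.

    Accepts either the kept records or their count.  The percentage variant
    (% reads mapped / Mb) used for the low-stringency habitat screen is the
    same normalization applied to 100 * kept / total reads.
    """
    if reference_size_mb <= 0:
        raise ValueError("reference_size_mb must be positive")
    n = records_kept if isinstance(records_kept, int) else len(records_kept)
    return n / reference_size_mb


def classify_habitat(phage_id: str, gut_rate: float, nongut_rate: float) -> HabitatCall:
    """Assign a phage to GT / NG / GAH / GAL / UNCLASS from normalized hit rates."""
    if gut_rate < 0 or nongut_rate < 0:
        raise ValueError("hit rates must be non-negative")
    if gut_rate > 0 and nongut_rate == 0:
        cat = "GT"
    elif nongut_rate > 0 and gut_rate == 0:
        cat = "NG"
    elif gut_rate == 0 and nongut_rate == 0:
        cat = "UNCLASS"
    elif gut_rate > nongut_rate:
        cat = "GAH"
    else:
        cat = "GAL"
    return HabitatCall(phage_id, cat, gut_rate, nongut_rate)


def chi_square_proportions(contingency) -> tuple[float, int, float]:
    """Pearson chi-square test on a 2 x k (or r x k) count table.

    Returns (statistic, degrees of freedom, upper-tail p-value).  Expected
    counts are the usual product-of-margins estimates; any zero expected
    cell is an error.
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = row * col / total
    if np.any(expected <= 0):
        raise ValueError("zero expected count in contingency table")
    statistic = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p
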