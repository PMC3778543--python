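"""Tetranucleotide usage profiles (TUPs).

A TUP is the 256-entry vector of Z-scores measuring the divergence of a
sequence's observed tetranucleotide counts from the expectation under a
maximal-order Markov model, i.e. the expectation implied by the sequence's
own trinucleotide and dinucleotide counts:

    E[n1n2n3n4]   = N(n1n2n3) * N(n2n3n4) / N(n2n3)
    Var[n1n2n3n4] = E * (N(n2n3) - N(n1n2n3)) * (N(n2n3) - N(n2n3n4)) / N(n2n3)^2
    Z[n1n2n3n4]   = (O - E) / sqrt(Var)

Sequences are extended by their reverse complement before counting, which
makes the signature strand-invariant.  Extension is implemented by counting
the two strands independently and summing — no window ever spans the
junction of a literal string concatenation.  Windows containing an
ambiguous base (anything outside A/C/G/T) contribute nothing at any k.

Degenerate cases (N(n2n3) = 0, or Var <= 0) map to Z = 0 so that every
signature is a finite fixed-length vector and Pearson correlation between
signatures is always well defined.

All 256-entry vectors are ordered lexicographically AAAA..TTTT.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .sequences import NucleotideSequence, reverse_complement

#: The 256 tetranucleotides in canonical lexicographic order.
TETRANUCLEOTIDES: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=4)
)

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


class UndefinedCorrelationError(ValueError):
    """Raised when Pearson correlation is requested for a zero-variance vector."""


@dataclass(frozen=True)
class KmerCountTable:
    """Counts of all 4**k k-mers of one sequence, lexicographic order.

    ``windows_counted`` is the number of valid (ambiguity-free) windows that
    contributed; it always equals ``counts.sum()``.
    """

    sequence_id: str
    k: int
    counts: np.ndarray = field(repr=False)
    windows_counted: int = 0
    extended_by_revcomp: bool = True

    def __post_init__(self) -> None:
        if self.k not in (2, 3, 4):
            raise ValueError(f"k must be in {{2,3,4}}, got {self.k}")
        if self.counts.shape != (4**self.k,):
            raise ValueError("counts has wrong length for k")


@dataclass(frozen=True)
class SignatureVector:
    """TUP of one sequence: 256 finite Z-scores in lexicographic order."""

    sequence_id: str
    z: np.ndarray = field(repr=False)
    extended_by_revcomp: bool = True

    def __post_init__(self) -> None:
        if self.z.shape != (256,):
            raise ValueError("signature must have exactly 256 entries")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("signature entries must be finite")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric matrix of pairwise Pearson correlations between signatures."""

    labels: tuple[str, ...]
    r: np.ndarray = field(repr=False)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.r[i, j])


def _encode(residues: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def _count_one_strand(codes: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    n = codes.size
    if n < k:
        return np.zeros(4**k, dtype=np.int64), 0
    idx = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        c = codes[j : n - k + 1 + j]
        valid = c < 4
        idx = idx * 4 + np.where(valid, c, 0)
        ok &= valid
    counts = np.bincount(idx[ok], minlength=4**k).astype(np.int64)
    return counts, int(ok.sum())


def count_kmers(
    seq: NucleotideSequence, k: int, extend_revcomp: bool = True
) -> KmerCountTable:
    """Count all k-mer windows of ``seq`` (and of its reverse complement).

    The two strands are counted independently and summed; windows containing
    an ambiguous base are skipped.
    """
    if k not in (2, 3, 4):
        raise ValueError(f"k must be in {{2,3,4}}, got {k}")
    if len(seq) < k:
        raise ValueError(f"sequence {seq.id!r} shorter than k={k}")
    counts, windows = _count_one_strand(_encode(seq.residues), k)
    if extend_revcomp:
        rc_counts, rc_windows = _count_one_strand(
            _encode(reverse_complement(seq.residues)), k
        )
        counts = counts + rc_counts
        windows += rc_windows
    return KmerCountTable(seq.id, k, counts, windows, extend_revcomp)


# index helpers mapping each tetranucleotide to its prefix/suffix
# trinucleotide and its central dinucleotide
_T = np.arange(256)
_PREFIX3 = _T // 4          # n1n2n3
_SUFFIX3 = _T % 64          # n2n3n4
_MID2 = (_T // 4) % 16      # n2n3


def zscore_signature(
    c4: KmerCountTable, c3: KmerCountTable, c2: KmerCountTable
) -> SignatureVector:
    """Convert tetra/tri/dinucleotide counts of one sequence into its TUP."""
    if not (c4.k, c3.k, c2.k) == (4, 3, 2):
        raise ValueError("tables must have k = 4, 3, 2 in that order")
    if len({c4.sequence_id, c3.sequence_id, c2.sequence_id}) != 1:
        raise ValueError("count tables derive from different sequences")
    if len({c4.extended_by_revcomp, c3.extended_by_revcomp, c2.extended_by_revcomp}) != 1:
        raise ValueError("count tables mix reverse-complement extension flags")

    observed = c4.counts.astype(float)
    n3 = c3.counts.astype(float)
    n2 = c2.counts.astype(float)

    n2_mid = n2[_MID2]
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = n3[_PREFIX3] * n3[_SUFFIX3] / n2_mid
        variance = (
            expected
            * (n2_mid - n3[_PREFIX3])
            * (n2_mid - n3[_SUFFIX3])
            / n2_mid**2
        )
        z = (observed - expected) / np.sqrt(variance)
    z = np.where((n2_mid == 0) | ~(variance > 0), 0.0, z)
    return SignatureVector(c4.sequence_id, z, c4.extended_by_revcomp)


def signature(seq: NucleotideSequence, extend_revcomp: bool = True) -> SignatureVector:
    """Compute the TUP of ``seq`` directly."""
    return zscore_signature(
        count_kmers(seq, 4, extend_revcomp),
        count_kmers(seq, 3, extend_revcomp),
        count_kmers(seq, 2, extend_revcomp),
    )


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors.

    Raises
    ------
    UndefinedCorrelationError
        If either vector has zero variance (screening treats this as no-hit).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("vectors must be 1-D, equal length >= 3")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom == 0.0:
        raise UndefinedCorrelationError("zero-variance vector")
    return float(np.clip((da @ db) / denom, -1.0, 1.0))


def correlate_signatures(sigs: list[SignatureVector]) -> CorrelationMatrix:
    """Pairwise Pearson correlation matrix over a list of signatures."""
    if len(sigs) < 2:
        raise ValueError("need at least two signatures")
    labels = tuple(s.sequence_id for s in sigs)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate signature ids")
    z = np.stack([s.z for s in sigs])
    if np.any(z.std(axis=1) == 0):
        bad = [labels[i] for i in np.nonzero(z.std(axis=1) == 0)[0]]
        raise UndefinedCorrelationError(f"constant signature(s): {bad}")
    r = np.corrcoef(z)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(labels, r)
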