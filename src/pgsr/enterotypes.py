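"""Inter-individual variation: viral-enterotype grouping and its validation.

The phage x sample matrix holds relative abundances (valid hits per Mb of
each sample's metagenome; valid = >=80% identity over >=50% of the subject
sequence at e <= 1e-5).  Contigs designated as parts of one scaffold are
merged into a single row by summing abundances.

Samples are grouped by a two-pass hierarchical heuristic: starting from a
randomly selected sample, every sample with a similar abundance *profile*
(regardless of level — operationalized as Spearman rank correlation >= tau)
joins group A; the next unassigned sample founds B, and so on through D,
with the remainder unclassified (UC).  A second pass re-assigns every
sample against the pass-1 founders to refine the initial grouping.  Phage
rows with homologues in >= 40% of samples are treated as noise and hidden
from the heuristic (but kept for Bray-Curtis / ordination).

Groupings are validated by non-metric MDS of the Bray-Curtis matrix
(Kruskal stress-1, monotone regression, best of random restarts) and by
ANOSIM (Clarke's rank-based R with a permutation p-value; exhaustive
enumeration when the label multiset is small enough).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .phylogeny import DistanceMatrix
from .profiles import AlignmentHit, filter_hits

__all__ = [
    "SampleAbundanceMatrix",
    "EnterotypeAssignment",
    "OrdinationResult",
    "AnosimResult",
    "build_abundance_matrix",
    "heuristic_group",
    "bray_curtis",
    "nmds",
    "anosim",
]

GROUP_LETTERS = ("A", "B", "C", "D", "E", "F", "G", "H")


@dataclass(frozen=True)
class SampleAbundanceMatrix:
    """Phage (rows) x sample (columns) hits-per-Mb matrix."""

    phage_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    scaffold_groups: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.phage_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match ids")
        if np.any(self.values < 0):
            raise ValueError("abundances must be non-negative")

    @property
    def incidence(self) -> np.ndarray:
        """Per-phage % of samples with a positive abundance."""
        return 100.0 * (self.values > 0).mean(axis=1)


@dataclass(frozen=True)
class EnterotypeAssignment:
    assignments: dict[str, str]
    founders: dict[str, str]
    passes: int
    parameters: dict


@dataclass(frozen=True)
class OrdinationResult:
    sample_ids: tuple[str, ...]
    coordinates: np.ndarray = field(repr=False)
    stress: float = math.nan
    restarts_used: int = 0
    seed: int | None = None
    converged: bool = True


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    exact: bool = False


def build_abundance_matrix(
    hit_tables: dict[str, list[AlignmentHit]],
    sample_sizes_mb: dict[str, float],
    phage_ids: list[str],
    min_identity: float = 80.0,
    min_subject_coverage: float = 0.50,
    max_e: float = 1e-5,
    scaffold_groups: dict[str, frozenset[str]] | None = None,
) -> SampleAbundanceMatrix:
    """Count valid hits of each phage (query) in each sample's assembly.

    ``hit_tables`` maps sample id to the hits of all phage queries against
    that sample's contigs.  Scaffold groups are merged into single rows
    (summed abundance) named after the group; incidence is computed on the
    merged matrix.  A sample with no hit table contributes a zero column.
    """
    sample_ids = tuple(sorted(sample_sizes_mb))
    for sid, size in sample_sizes_mb.items():
        if size <= 0:
            raise ValueError(f"sample {sid!r}: non-positive size")
    raw = np.zeros((len(phage_ids), len(sample_ids)))
    row_of = {p: i for i, p in enumerate(phage_ids)}
    for j, sid in enumerate(sample_ids):
        table = hit_tables.get(sid)
        if table is None:
            warnings.warn(f"sample {sid!r} has no hit table; column of zeros")
            continue
        valid = filter_hits(
            table, min_identity, None, max_e, min_subject_coverage=min_subject_coverage
        )
        for h in valid:
            if h.query_id in row_of:
                raw[row_of[h.query_id], j] += 1.0
        raw[:, j] /= sample_sizes_mb[sid]

    scaffold_groups = scaffold_groups or {}
    merged_member = {p: g for g, members in scaffold_groups.items() for p in members}
    out_ids: list[str] = []
    rows: list[np.ndarray] = []
    done_groups: set[str] = set()
    for p in phage_ids:
        g = merged_member.get(p)
        if g is None:
            out_ids.append(p)
            rows.append(raw[row_of[p]])
        elif g not in done_groups:
            members = [m for m in phage_ids if merged_member.get(m) == g]
            out_ids.append(g)
            rows.append(raw[[row_of[m] for m in members]].sum(axis=0))
            done_groups.add(g)
    return SampleAbundanceMatrix(
        tuple(out_ids), sample_ids, np.stack(rows), dict(scaffold_groups)
    )


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    rho = stats.spearmanr(a, b).statistic
    return -1.0 if math.isnan(rho) else float(rho)


def heuristic_group(
    matrix: SampleAbundanceMatrix,
    noise_incidence: float = 40.0,
    tau: float = 0.6,
    max_groups: int = 4,
    seed: int | None = None,
) -> EnterotypeAssignment:
    """Two-pass hierarchical heuristic grouping of samples by phage profile.

    Deterministic given the seed, and invariant (up to the identity of the
    random start) to the order samples arrive in: samples are handled in
    sorted-id order and the random start is drawn over that order.
    """
    if seed is None:
        raise ValueError("a seed is required (the starting sample is random)")
    if len(matrix.sample_ids) < 2:
        raise ValueError("need at least two samples")
    keep = matrix.incidence < noise_incidence
    if not np.any(keep):
        raise ValueError("every phage row is noise; nothing to group on")
    order = np.argsort(np.asarray(matrix.sample_ids))
    sample_ids = [matrix.sample_ids[i] for i in order]
    profiles = {
        sid: matrix.values[keep][:, matrix.sample_ids.index(sid)] for sid in sample_ids
    }

    rng = np.random.default_rng(seed)
    start = sample_ids[int(rng.integers(len(sample_ids)))]

    # pass 1: greedy founding
    founders: dict[str, str] = {}
    assigned: dict[str, str] = {}
    queue = [start] + [s for s in sample_ids if s != start]
    for letter in GROUP_LETTERS[:max_groups]:
        founder = next((s for s in queue if s not in assigned), None)
        if founder is None:
            break
        founders[letter] = founder
        assigned[founder] = letter
        for s in queue:
            if s not in assigned and _spearman(profiles[founder], profiles[s]) >= tau:
                assigned[s] = letter
    # pass 2: refine every sample against the pass-1 founders
    final: dict[str, str] = {}
    for s in sample_ids:
        best_letter, best_rho = "UC", -np.inf
        for letter, founder in founders.items():
            rho = 1.0 if s == founder else _spearman(profiles[founder], profiles[s])
            if rho > best_rho:
                best_letter, best_rho = letter, rho
        final[s] = best_letter if best_rho >= tau else "UC"
    return EnterotypeAssignment(
        final,
        founders,
        passes=2,
        parameters={
            "noise_incidence": noise_incidence,
            "tau": tau,
            "max_groups": max_groups,
            "seed": seed,
        },
    )


def bray_curtis(matrix: SampleAbundanceMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns, over ALL phage rows.

    d(i,j) = sum|x_i - x_j| / sum(x_i + x_j); a pair of all-zero columns
    has d = 0 by convention.
    """
    x = matrix.values
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    n = x.shape[1]
    if n < 2:
        raise ValueError("need at least two samples")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = np.abs(x[:, i] - x[:, j]).sum()
            den = (x[:, i] + x[:, j]).sum()
            d[i, j] = d[j, i] = num / den if den > 0 else 0.0
    return DistanceMatrix(matrix.sample_ids, d)


def _stress1(config: np.ndarray, dissim: np.ndarray) -> float:
    iu = np.triu_indices(config.shape[0], k=1)
    dvec = dissim[iu]
    cd = np.sqrt(((config[iu[0]] - config[iu[1]]) ** 2).sum(axis=1))
    disparities = IsotonicRegression().fit_transform(dvec, cd)
    denom = (cd**2).sum()
    if denom == 0:
        return math.inf
    return math.sqrt(((cd - disparities) ** 2).sum() / denom)


def nmds(
    D: DistanceMatrix,
    dims: int = 2,
    n_restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1, best of random restarts.

    Stress-1 is computed from the final configuration with monotone
    (isotonic) regression of configuration distances on dissimilarities;
    coordinates are centered at the origin.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible ordination")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, math.inf
    for _ in range(n_restarts):
        rs = int(rng.integers(2**31 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, _ = smacof(
                D.d,
                metric=False,
                n_components=dims,
                n_init=1,
                max_iter=max_iter,
                eps=1e-9,
                random_state=rs,
                normalized_stress=True,
            )
        s = _stress1(coords, D.d)
        if s < best_stress:
            best_coords, best_stress = coords, s
    best_coords = best_coords - best_coords.mean(axis=0)
    return OrdinationResult(
        D.labels, best_coords, best_stress, n_restarts, seed, converged=True
    )


def _anosim_r(ranks: np.ndarray, within: np.ndarray, m: int) -> float:
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)


def anosim(
    D: DistanceMatrix,
    groups: dict[str, str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """Analysis of similarities on a dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 and mid-ranks for ties.  Samples labelled "UC" are
    excluded.  When the number of distinct relabelings does not exceed
    ``n_permutations`` the permutation distribution is enumerated
    exhaustively (p = #{R_perm >= R_obs} / #relabelings, identity
    included); otherwise p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations)
    under random relabeling with fixed group sizes.
    """
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    keep = [s for s in D.labels if groups.get(s, "UC") != "UC"]
    labels = np.array([groups[s] for s in keep])
    sizes: dict[str, int] = {}
    for g in labels:
        sizes[g] = sizes.get(g, 0) + 1
    if len(sizes) < 2:
        raise ValueError("need at least two groups")
    if min(sizes.values()) < 2:
        raise ValueError("every group must contain at least two samples")
    idx = [D.labels.index(s) for s in keep]
    sub = D.d[np.ix_(idx, idx)]
    n = len(keep)
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(sub[iu])
    m = n * (n - 1) // 2

    def r_for(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return _anosim_r(ranks, within, m)

    r_obs = r_for(labels)
    tol = 1e-12

    n_distinct = math.factorial(n)
    for c in sizes.values():
        n_distinct //= math.factorial(c)
    if n_distinct <= n_permutations:
        from sympy.utilities.iterables import multiset_permutations

        count = sum(
            1
            for perm in multiset_permutations(list(labels))
            if r_for(np.array(perm)) >= r_obs - tol
        )
        return AnosimResult(r_obs, count / n_distinct, n_distinct, sizes, exact=True)

    rng = np.random.default_rng(seed)
    count = 0
    lab = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if r_for(lab) >= r_obs - tol:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return AnosimResult(r_obs, p, n_permutations, sizes, exact=False)
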