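"""Independent naive reference implementations used only by the tests.

These deliberately avoid the package's vectorized code paths: plain
dictionary sliding-window counting, a literal transcription of the Z-score
formulas, textbook Pearson correlation, a quadrature-based chi-square
tail, and exhaustive two-group ANOSIM enumeration.
"""

from __future__ import annotations

import itertools
import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(s))


def naive_count(residues: str, k: int, extend_revcomp: bool) -> dict[str, int]:
    """Sliding-window k-mer counts, skipping windows with ambiguous bases."""
    counts: dict[str, int] = {}
    strands = [residues.upper()]
    if extend_revcomp:
        strands.append(revcomp(residues.upper()))
    for s in strands:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if all(c in "ACGT" for c in w):
                counts[w] = counts.get(w, 0) + 1
    return counts


def naive_signature(residues: str, extend_revcomp: bool = True) -> dict[str, float]:
    """Literal transcription of the maximal-order Markov Z-score formulas."""
    c4 = naive_count(residues, 4, extend_revcomp)
    c3 = naive_count(residues, 3, extend_revcomp)
    c2 = naive_count(residues, 2, extend_revcomp)
    z: dict[str, float] = {}
    for w in ("".join(p) for p in itertools.product("ACGT", repeat=4)):
        n2 = c2.get(w[1:3], 0)
        if n2 == 0:
            z[w] = 0.0
            continue
        pre = c3.get(w[:3], 0)
        suf = c3.get(w[1:], 0)
        e = pre * suf / n2
        var = e * (n2 - pre) * (n2 - suf) / n2**2
        if var <= 0:
            z[w] = 0.0
        else:
            z[w] = (c4.get(w, 0) - e) / math.sqrt(var)
    return z


def naive_pearson(a, b) -> float:
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    den = math.sqrt(sum((x - ma) ** 2 for x in a) * sum((y - mb) ** 2 for y in b))
    return num / den


def chi2_sf_quadrature(x: float, df: int) -> float:
    """Upper-tail chi-square probability by numerical integration of the density."""
    from scipy.integrate import quad

    def density(t: float) -> float:
        return math.exp(
            (df / 2 - 1) * math.log(t) - t / 2 - math.lgamma(df / 2) - (df / 2) * math.log(2)
        )

    p, _ = quad(density, x, math.inf, limit=200)
    return p


def exact_anosim_two_groups(d, labels) -> tuple[float, float]:
    """Exhaustive ANOSIM over all distinct two-group relabelings.

    ``d`` is a full square dissimilarity matrix (list of lists), ``labels``
    a list of two distinct group labels.  Returns (R_observed, exact p).
    """
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    values = [d[i][j] for i, j in pairs]
    order = sorted(range(len(values)), key=lambda k: values[k])
    ranks = [0.0] * len(values)
    k = 0
    while k < len(order):
        j = k
        while j + 1 < len(order) and values[order[j + 1]] == values[order[k]]:
            j += 1
        mid = (k + j) / 2 + 1
        for t in range(k, j + 1):
            ranks[order[t]] = mid
        k = j + 1
    m = len(pairs)

    def r_stat(lab):
        within = [ranks[p] for p, (i, j) in enumerate(pairs) if lab[i] == lab[j]]
        between = [ranks[p] for p, (i, j) in enumerate(pairs) if lab[i] != lab[j]]
        return (sum(between) / len(between) - sum(within) / len(within)) / (m / 2)

    r_obs = r_stat(labels)
    groups = sorted(set(labels))
    n_a = labels.count(groups[0])
    count = total = 0
    for combo in itertools.combinations(range(n), n_a):
        lab = [groups[0] if i in combo else groups[1] for i in range(n)]
        total += 1
        if r_stat(lab) >= r_obs - 1e-12:
            count += 1
    # each grouping counted twice (labels are exchangeable) unless sizes differ
    return r_obs, count / total
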