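"""Genome signature-based recovery (PGSR) of phage-like contigs.

The core screen: every metagenome contig of at least 10 kb gets a
tetranucleotide usage profile, and contigs whose TUP correlates at 0.6 or
over with *any* driver phage signature are retained.  Retained contigs are
then binned from ORF-level functional evidence as

* ``phage`` — at least one unambiguous phage-related gene (function label
  matching the phage lexicon) and/or at least one ORF shared with a driver
  sequence;
* ``non_phage`` — no phage-related ORF and at least one ORF with a typical
  chromosomal (housekeeping) function;
* ``unclassified`` — no ORF providing a clear indication either way.

Host taxonomy is affiliated first at nucleotide level (best valid blastn-
style hit: >=75% identity, >=1 kb, e<=1e-5), and where that fails at ORF
level, requiring at least two ORFs with valid hits to species of the same
bacterial order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

from .profiles import AlignmentHit, filter_hits
from .sequences import NucleotideSequence, reverse_complement
from .signatures import (
    SignatureVector,
    UndefinedCorrelationError,
    pearson_correlation,
    signature,
)

__all__ = [
    "Driver",
    "DriverSet",
    "ScreenHit",
    "OrfAnnotation",
    "FunctionalBin",
    "HostAffiliation",
    "default_phage_lexicon",
    "default_housekeeping_lexicon",
    "screen_contigs",
    "bin_contig",
    "find_orfs",
    "affiliate_host_nt",
    "affiliate_host_orf",
]

MIN_CONTIG_LEN = 10_000
DEFAULT_R_MIN = 0.6


@dataclass(frozen=True)
class Driver:
    """A characterized phage genome seeding the signature screen."""

    id: str
    signature: SignatureVector
    host_genus: str = "unknown"
    host_order: str = "unknown"
    note: str = ""


@dataclass(frozen=True)
class DriverSet:
    drivers: tuple[Driver, ...]

    def __post_init__(self) -> None:
        if not self.drivers:
            raise ValueError("driver set must contain at least one driver")
        ids = [d.id for d in self.drivers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate driver ids")

    @classmethod
    def from_sequences(
        cls,
        seqs: list[NucleotideSequence],
        host_taxa: dict[str, tuple[str, str]] | None = None,
        min_len: int = MIN_CONTIG_LEN,
    ) -> "DriverSet":
        """Build drivers from genome sequences (each must be >= ``min_len``)."""
        drivers = []
        for s in seqs:
            if len(s) < min_len:
                raise ValueError(f"driver {s.id!r} shorter than {min_len} bp")
            genus, order = (host_taxa or {}).get(s.id, ("unknown", "unknown"))
            drivers.append(Driver(s.id, signature(s), genus, order))
        return cls(tuple(drivers))

    def __iter__(self):
        return iter(self.drivers)

    def __len__(self) -> int:
        return len(self.drivers)


@dataclass(frozen=True)
class ScreenHit:
    """Best driver correlation of one retained contig."""

    contig_id: str
    best_driver_id: str
    r_best: float
    all_driver_r: dict[str, float] = field(repr=False)
    passed: bool = False


@dataclass(frozen=True)
class OrfAnnotation:
    """One predicted ORF with its functional evidence.

    Coordinates are 1-based inclusive on the forward strand of the contig.
    ``evidence_source`` is one of conserved-domain, phage-homology,
    driver-homology, none.
    """

    contig_id: str
    orf_id: str
    start: int
    end: int
    strand: str
    function_label: str = "hypothetical protein"
    evidence_source: str = "none"
    evidence_evalue: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad ORF coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.evidence_evalue is not None and self.evidence_evalue < 0:
            raise ValueError("negative e-value")


@dataclass(frozen=True)
class FunctionalBin:
    contig_id: str
    category: str  # phage | non_phage | unclassified
    supporting_orfs: tuple[str, ...]
    rationale: str


@dataclass(frozen=True)
class HostAffiliation:
    contig_id: str
    taxon_genus: str
    taxon_order: str
    method: str  # nucleotide | orf | none
    support: int


def _load_lexicon(name: str) -> tuple[str, ...]:
    text = resources.files("pgsr").joinpath("data", name).read_text()
    terms = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.append(line.lower())
    return tuple(terms)


def default_phage_lexicon() -> tuple[str, ...]:
    """Curated phage-function terms shipped with the package (editable)."""
    return _load_lexicon("phage_terms.txt")


def default_housekeeping_lexicon() -> tuple[str, ...]:
    """Curated chromosomal-function terms shipped with the package."""
    return _load_lexicon("housekeeping_terms.txt")


def screen_contigs(
    contigs: list[NucleotideSequence],
    drivers: DriverSet,
    r_min: float = DEFAULT_R_MIN,
    min_len: int = MIN_CONTIG_LEN,
) -> list[ScreenHit]:
    """Correlate contig TUPs against every driver signature.

    Contigs shorter than ``min_len`` are excluded before any signature is
    computed.  A contig passes when its best correlation over all drivers
    is >= ``r_min``.  Output is sorted by descending best correlation, ties
    by contig id; best-driver ties break by driver id.
    """
    if not contigs:
        raise ValueError("no contigs supplied")
    if not 0.0 < r_min <= 1.0:
        raise ValueError(f"r_min must be in (0, 1], got {r_min}")
    retained = [c for c in contigs if len(c) >= min_len]
    if not retained:
        warnings.warn(f"no contig reaches the {min_len} bp length gate")
        return []
    hits = []
    for contig in retained:
        sig = signature(contig)
        all_r: dict[str, float] = {}
        for d in drivers:
            try:
                all_r[d.id] = pearson_correlation(sig.z, d.signature.z)
            except UndefinedCorrelationError:
                continue  # degenerate signature: no hit against this driver
        if not all_r:
            hits.append(ScreenHit(contig.id, "", float("nan"), {}, False))
            continue
        best_id = min(all_r, key=lambda k: (-all_r[k], k))
        r_best = all_r[best_id]
        hits.append(ScreenHit(contig.id, best_id, r_best, all_r, r_best >= r_min))
    hits.sort(key=lambda h: (-h.r_best, h.contig_id))
    return hits


def _matches(label: str, lexicon: tuple[str, ...]) -> bool:
    low = label.lower()
    return any(term in low for term in lexicon)


def bin_contig(
    contig_id: str,
    orfs: list[OrfAnnotation],
    phage_lexicon: tuple[str, ...] | None = None,
    housekeeping_lexicon: tuple[str, ...] | None = None,
    driver_orf_ids: frozenset[str] = frozenset(),
) -> FunctionalBin:
    """Categorize a contig as phage / non_phage / unclassified.

    A pure function of the annotation set: ORF order never affects the
    outcome (supporting ORFs are reported sorted by id).
    """
    phage_lex = phage_lexicon if phage_lexicon is not None else default_phage_lexicon()
    if not phage_lex:
        raise ValueError("phage lexicon must be non-empty")
    hk_lex = (
        housekeeping_lexicon
        if housekeeping_lexicon is not None
        else default_housekeeping_lexicon()
    )

    phage_orfs = sorted(
        o.orf_id
        for o in orfs
        if _matches(o.function_label, phage_lex)
        or o.evidence_source == "driver-homology"
        or o.orf_id in driver_orf_ids
    )
    if phage_orfs:
        return FunctionalBin(contig_id, "phage", tuple(phage_orfs), "phage-related gene present")
    if any(_matches(o.function_label, hk_lex) for o in orfs):
        return FunctionalBin(contig_id, "non_phage", (), "chromosomal functions, no phage gene")
    return FunctionalBin(contig_id, "unclassified", (), "no informative ORF")


_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(seq: NucleotideSequence, min_aa: int = 60) -> list[OrfAnnotation]:
    """Naive six-frame ORF caller (ATG start, standard stops).

    Emits every maximal ATG-to-stop span of at least ``min_aa`` codons
    (excluding the stop); coordinates are 1-based inclusive on the forward
    strand and include the stop codon.  Exists so synthetic fixtures are
    self-contained; it is not a gene-prediction replacement.
    """
    if min_aa < 10:
        raise ValueError("min_aa must be >= 10")
    length = len(seq)
    spans: list[tuple[int, int, str]] = []
    for strand, s in (("+", seq.residues), ("-", reverse_complement(seq.residues))):
        for frame in range(3):
            first_atg: int | None = None
            for ci in range((len(s) - frame) // 3):
                codon = s[frame + 3 * ci : frame + 3 * ci + 3]
                if codon in _STOPS:
                    if first_atg is not None and ci - first_atg >= min_aa:
                        start_s = frame + 3 * first_atg + 1
                        end_s = frame + 3 * ci + 3
                        if strand == "+":
                            spans.append((start_s, end_s, "+"))
                        else:
                            spans.append((length - end_s + 1, length - start_s + 1, "-"))
                    first_atg = None
                elif codon == "ATG" and first_atg is None:
                    first_atg = ci
    spans.sort(key=lambda t: (t[0], t[2], t[1]))
    return [
        OrfAnnotation(seq.id, f"{seq.id}_orf{i + 1}", a, b, st)
        for i, (a, b, st) in enumerate(spans)
    ]


def _resolve_taxon(
    subject_id: str, taxon_map: dict[str, tuple[str, str]]
) -> tuple[str, str] | None:
    taxon = taxon_map.get(subject_id)
    if taxon is None:
        warnings.warn(f"subject {subject_id!r} missing from taxon map; hit skipped")
    return taxon


def affiliate_host_nt(
    contig_id: str,
    hits: list[AlignmentHit],
    min_identity: float = 75.0,
    min_align_len: int = 1000,
    max_e: float = 1e-5,
    taxon_map: dict[str, tuple[str, str]] | None = None,
) -> HostAffiliation:
    """Nucleotide-level host affiliation: genus/order of the top valid hit."""
    taxon_map = taxon_map or {}
    surviving = []
    for h in filter_hits(hits, min_identity, min_align_len, max_e):
        if _resolve_taxon(h.subject_id, taxon_map) is not None:
            surviving.append(h)
    if not surviving:
        return HostAffiliation(contig_id, "unaffiliated", "unaffiliated", "none", 0)
    top = min(surviving, key=lambda h: (-h.bit_score, h.e_value, h.subject_id))
    genus, order = taxon_map[top.subject_id]
    return HostAffiliation(contig_id, genus, order, "nucleotide", 1)


def affiliate_host_orf(
    contig_id: str,
    orf_hits: list[AlignmentHit],
    min_identity: float = 75.0,
    max_e: float = 1e-5,
    taxon_map: dict[str, tuple[str, str]] | None = None,
) -> HostAffiliation:
    """ORF-level fallback affiliation (when nucleotide level found nothing).

    Requires at least two ORFs whose best valid hits agree at the order
    level; the genus is affiliated only when those ORFs also agree on it.
    """
    taxon_map = taxon_map or {}
    by_orf: dict[str, AlignmentHit] = {}
    for h in filter_hits(orf_hits, min_identity, None, max_e):
        if _resolve_taxon(h.subject_id, taxon_map) is None:
            continue
        cur = by_orf.get(h.query_id)
        if cur is None or (-h.bit_score, h.e_value, h.subject_id) < (
            -cur.bit_score,
            cur.e_value,
            cur.subject_id,
        ):
            by_orf[h.query_id] = h
    order_votes: dict[str, list[str]] = {}
    for h in by_orf.values():
        genus, order = taxon_map[h.subject_id]
        order_votes.setdefault(order, []).append(genus)
    candidates = {o: g for o, g in order_votes.items() if len(g) >= 2}
    if not candidates:
        return HostAffiliation(contig_id, "unaffiliated", "unaffiliated", "none", 0)
    order = min(candidates, key=lambda o: (-len(candidates[o]), o))
    genera = set(candidates[order])
    genus = genera.pop() if len(genera) == 1 else "unaffiliated"
    return HostAffiliation(contig_id, genus, order, "orf", len(candidates[order]))
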