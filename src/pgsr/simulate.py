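"""Synthetic communities with the compositional structure the screen assumes.

Genus-specific nucleotide composition is emulated with order-3 Markov
models (64 trinucleotide contexts x 4 emissions).  An order-3 model is the
natural choice here: the tetranucleotide Z-score measures exactly the
third-order structure left over after the maximal-order (trinucleotide-
based) Markov expectation is removed, so planted genus signal is neither
trivially detectable nor adversarial.

Each genus model is a mixture (1 - delta) * base + delta * genus-specific
Dirichlet draw, per context.  ``delta`` controls compositional divergence:
at delta = 0 all genera share one model; larger delta drives the expected
between-genus signature correlation down while within-genus correlation
stays high.  The shipped default is calibrated so that 50 kb samples give
between-genus signature correlations below 0.3 and within-genus above 0.9,
bracketing the 0.6 screening threshold from both sides.

Prophages are drawn from the *same* genus model as their host chromosome —
the compositional-amelioration premise the screen relies on — and planted
as contiguous insertions.  Fragmentation cuts at prophage boundaries, so
every contig is unambiguously phage or chromosomal in the truth table.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .screening import OrfAnnotation
from .profiles import AlignmentHit, ReadMapRecord
from .sequences import NucleotideSequence
from .signatures import signature, pearson_correlation

__all__ = [
    "CompositionModel",
    "SyntheticCommunity",
    "make_composition_models",
    "calibration_report",
    "sample_genome",
    "plant_prophage",
    "fragment",
    "make_community",
    "make_fixture_tables",
    "make_enterotype_cohort",
    "random_additive_tree",
]

_BASES = "ACGT"
_CONTEXTS = ["".join(p) for p in itertools.product(_BASES, repeat=3)]

#: Default divergence of the genus models (see module docstring).
DEFAULT_DELTA = 0.75


@dataclass(frozen=True)
class CompositionModel:
    """Order-3 Markov model of genus-specific nucleotide composition."""

    genus: str
    transitions: np.ndarray = field(repr=False)  # (64, 4), rows sum to 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transitions.shape != (64, 4):
            raise ValueError("transition matrix must be 64 x 4")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each context's emission probabilities must sum to 1")


@dataclass
class SyntheticCommunity:
    """Contigs plus complete ground truth for every emitted record."""

    models: list[CompositionModel]
    chromosomes: dict[str, NucleotideSequence]
    prophage_intervals: dict[str, tuple[int, int]]  # chromosome id -> (start, end)
    contigs: list[NucleotideSequence]
    drivers: dict[str, NucleotideSequence]  # driver id -> sequence (per genus)
    truth: dict[str, dict]  # contig id -> {genus, label, source, interval}
    driver_host: dict[str, tuple[str, str]]  # driver id -> (genus, order)


def make_composition_models(
    n_genera: int,
    delta: float = DEFAULT_DELTA,
    seed: int = 0,
    base_alpha: float = 1.0,
) -> list[CompositionModel]:
    """Dirichlet-perturb a common base model into ``n_genera`` genus models.

    Between-model divergence grows monotonically with ``delta`` in (0, 1];
    delta -> 0 recovers identical models.
    """
    if n_genera < 2:
        raise ValueError("need at least two genera")
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must be in [0, 1]")
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(4, base_alpha), size=64)
    models = []
    for g in range(n_genera):
        own = rng.dirichlet(np.full(4, base_alpha), size=64)
        trans = (1.0 - delta) * base + delta * own
        trans /= trans.sum(axis=1, keepdims=True)
        models.append(CompositionModel(f"g{g + 1}", trans, seed))
    return models


def sample_genome(model: CompositionModel, length: int, seed: int) -> NucleotideSequence:
    """Draw one sequence of ``length`` bp from an order-3 Markov model."""
    if length < 4:
        raise ValueError("length must be >= 4")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(model.transitions, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    # uniform random start context
    ctx = int(rng.integers(64))
    out[0], out[1], out[2] = ctx // 16, (ctx // 4) % 4, ctx % 4
    for i in range(3, length):
        row = cum[ctx]
        b = int(np.searchsorted(row, u[i], side="right"))
        if b > 3:
            b = 3
        out[i] = b
        ctx = (ctx * 4 + b) % 64
    residues = "".join(_BASES[b] for b in out)
    return NucleotideSequence(f"{model.genus}_sample_{seed}", residues)


def calibration_report(
    models: list[CompositionModel], sample_len: int = 50_000, seed: int = 0
) -> dict:
    """Realized within/between-genus signature correlations at ``sample_len``.

    Two independent samples are drawn per model; the report confirms that
    the configured divergence brackets the screening threshold.
    """
    sigs = {}
    for k, m in enumerate(models):
        sigs[m.genus] = [
            signature(sample_genome(m, sample_len, seed * 1000 + 2 * k)),
            signature(sample_genome(m, sample_len, seed * 1000 + 2 * k + 1)),
        ]
    within = {
        g: pearson_correlation(pair[0].z, pair[1].z) for g, pair in sigs.items()
    }
    between = {}
    genera = [m.genus for m in models]
    for i, a in enumerate(genera):
        for b in genera[i + 1 :]:
            between[f"{a}:{b}"] = pearson_correlation(sigs[a][0].z, sigs[b][0].z)
    return {
        "sample_len": sample_len,
        "within": within,
        "between": between,
        "min_within": min(within.values()),
        "max_between": max(between.values()) if between else None,
    }


def plant_prophage(
    host_seq: NucleotideSequence, phage_seq: NucleotideSequence, position: int
) -> tuple[NucleotideSequence, tuple[int, int]]:
    """Insert a prophage before 1-based ``position`` of the host chromosome.

    Returns the combined chromosome and the truth interval
    [position, position + len(phage) - 1].
    """
    if len(phage_seq) > len(host_seq):
        raise ValueError("prophage longer than host chromosome")
    if not 1 <= position <= len(host_seq) + 1:
        raise ValueError("position outside host chromosome")
    combined = (
        host_seq.residues[: position - 1]
        + phage_seq.residues
        + host_seq.residues[position - 1 :]
    )
    return (
        NucleotideSequence(f"{host_seq.id}+{phage_seq.id}", combined),
        (position, position + len(phage_seq) - 1),
    )


def fragment(
    seq: NucleotideSequence,
    min_len: int = 10_000,
    mean_len: int = 15_000,
    seed: int = 0,
    breakpoints: tuple[int, ...] = (),
) -> list[tuple[NucleotideSequence, tuple[int, int]]]:
    """Cut a sequence into non-overlapping contigs tiling it completely.

    Fragment lengths are drawn uniformly in [min_len, 2*mean_len - min_len].
    Mandatory ``breakpoints`` (1-based positions that must start a new
    contig) are honored exactly.  A trailing remnant shorter than min_len
    is merged into the previous contig.  Provenance intervals are 1-based
    inclusive on the input sequence.
    """
    if mean_len < min_len:
        raise ValueError("mean_len must be >= min_len")
    rng = np.random.default_rng(seed)
    length = len(seq)
    bounds = sorted({1, length + 1, *[b for b in breakpoints if 1 < b <= length]})
    pieces: list[tuple[int, int]] = []
    for seg_start, seg_end in zip(bounds[:-1], bounds[1:]):
        pos = seg_start
        while pos < seg_end:
            frag = int(rng.integers(min_len, 2 * mean_len - min_len + 1))
            end = min(pos + frag - 1, seg_end - 1)
            if seg_end - 1 - end + 1 < min_len and end != seg_end - 1:
                end = seg_end - 1  # absorb a too-short remnant
            pieces.append((pos, end))
            pos = end + 1
    out = []
    for i, (a, b) in enumerate(pieces):
        contig = NucleotideSequence(f"{seq.id}_c{i + 1:03d}", seq.residues[a - 1 : b])
        out.append((contig, (a, b)))
    return out


def make_community(
    n_genera: int = 3,
    chrom_len: int = 120_000,
    prophage_len: int = 30_000,
    delta: float = DEFAULT_DELTA,
    mean_contig_len: int = 15_000,
    seed: int = 0,
) -> SyntheticCommunity:
    """Build the default synthetic community with complete truth tables.

    Per genus: one chromosome with one planted prophage drawn from the same
    genus model, one independent driver genome, and >= 10 kb contigs from
    fragmentation with cuts forced at the prophage boundaries.
    """
    rng = np.random.default_rng(seed)
    models = make_composition_models(n_genera, delta, seed=int(rng.integers(2**31)))
    chromosomes: dict[str, NucleotideSequence] = {}
    intervals: dict[str, tuple[int, int]] = {}
    contigs: list[NucleotideSequence] = []
    drivers: dict[str, NucleotideSequence] = {}
    truth: dict[str, dict] = {}
    driver_host: dict[str, tuple[str, str]] = {}
    for m in models:
        host = sample_genome(m, chrom_len, int(rng.integers(2**31)))
        host = NucleotideSequence(f"{m.genus}_chrom", host.residues)
        phage = sample_genome(m, prophage_len, int(rng.integers(2**31)))
        phage = NucleotideSequence(f"{m.genus}_prophage", phage.residues)
        position = int(rng.integers(20_000, chrom_len - 20_000))
        chrom, interval = plant_prophage(host, phage, position)
        chrom = NucleotideSequence(f"{m.genus}_chrom", chrom.residues)
        chromosomes[chrom.id] = chrom
        intervals[chrom.id] = interval
        driver = sample_genome(m, prophage_len, int(rng.integers(2**31)))
        driver = NucleotideSequence(f"{m.genus}_driver", driver.residues)
        drivers[driver.id] = driver
        driver_host[driver.id] = (m.genus, f"{m.genus}_order")
        frags = fragment(
            chrom,
            min_len=10_000,
            mean_len=mean_contig_len,
            seed=int(rng.integers(2**31)),
            breakpoints=(interval[0], interval[1] + 1),
        )
        for contig, (a, b) in frags:
            inside = interval[0] <= a and b <= interval[1]
            contigs.append(contig)
            truth[contig.id] = {
                "genus": m.genus,
                "label": "phage" if inside else "non_phage",
                "source": chrom.id,
                "interval": (a, b),
            }
    return SyntheticCommunity(
        models, chromosomes, intervals, contigs, drivers, truth, driver_host
    )


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with branch lengths uniform on [0.1, 1].

    Leaf-to-leaf path distances of such a tree form an additive matrix;
    used to validate distance-based tree reconstruction by inversion.
    """
    from .phylogeny import Tree, TreeNode

    if n_taxa < 3:
        raise ValueError("need at least three taxa")

    def bl() -> float:
        return float(rng.uniform(0.1, 1.0))

    root = TreeNode(
        children=[(TreeNode("t1"), bl()), (TreeNode("t2"), bl()), (TreeNode("t3"), bl())]
    )
    for i in range(4, n_taxa + 1):
        edges: list = []

        def walk(node):
            for ci in range(len(node.children)):
                edges.append((node, ci))
                walk(node.children[ci][0])

        walk(root)
        parent, ci = edges[int(rng.integers(len(edges)))]
        child, length = parent.children[ci]
        split = float(rng.uniform(0.2, 0.8)) * length
        mid = TreeNode(children=[(child, length - split), (TreeNode(f"t{i}"), bl())])
        parent.children[ci] = (mid, split)
    return Tree(root)


_PHAGE_LABELS = (
    "phage major capsid protein",
    "large subunit terminase",
    "tail fibre protein",
    "portal protein",
    "phage integrase",
)
_HOUSEKEEPING_LABELS = (
    "ribosomal protein L3",
    "ABC transporter permease",
    "tRNA ligase",
    "DNA gyrase subunit A",
    "branched-chain amino acid aminotransferase",
)


def make_fixture_tables(community: SyntheticCommunity, seed: int = 0) -> dict:
    """Annotation, hit-table and read-mapping fixtures consistent with truth.

    Phage-truth contigs receive at least one lexicon-matching ORF label and
    chromosomal contigs receive housekeeping labels.  Host-affiliation hit
    tables put each phage contig's best hit on its true genus, flanked by
    decoy hits exactly at, and one unit-in-the-last-decimal below, every
    filter threshold, to pin the inclusive-boundary convention.  Read
    tables likewise contain records exactly on every stringency-policy
    boundary.
    """
    rng = np.random.default_rng(seed)
    orfs: dict[str, list[OrfAnnotation]] = {}
    nt_hits: dict[str, list[AlignmentHit]] = {}
    taxon_map: dict[str, tuple[str, str]] = {}
    for m in community.models:
        taxon_map[f"{m.genus}_ref"] = (m.genus, f"{m.genus}_order")
    for contig in community.contigs:
        info = community.truth[contig.id]
        genus = info["genus"]
        labels = _PHAGE_LABELS if info["label"] == "phage" else _HOUSEKEEPING_LABELS
        n_orfs = int(rng.integers(2, 4))
        contig_orfs = []
        pos = 1
        for k in range(n_orfs):
            label = labels[int(rng.integers(len(labels)))]
            span = int(rng.integers(300, 1500))
            end = min(pos + span, len(contig))
            contig_orfs.append(
                OrfAnnotation(
                    contig.id,
                    f"{contig.id}_orf{k + 1}",
                    pos,
                    end,
                    "+" if rng.random() < 0.5 else "-",
                    label,
                    "conserved-domain",
                    1e-10,
                )
            )
            pos = end + 50
        # one uninformative ORF on every contig
        contig_orfs.append(
            OrfAnnotation(
                contig.id, f"{contig.id}_orfX", pos, min(pos + 300, len(contig)),
                "+", "hypothetical protein", "none", None,
            )
        )
        orfs[contig.id] = contig_orfs
        if info["label"] == "phage":
            subject = f"{genus}_ref"
            nt_hits[contig.id] = [
                # genuine best hit: passes every nucleotide-level threshold
                AlignmentHit(contig.id, subject, 80.0, 1200, 1e-10, 400.0),
                # decoys exactly at each threshold (must pass, inclusive)
                AlignmentHit(contig.id, subject, 75.0, 1000, 1e-5, 200.0),
                # decoys one unit below each threshold (must fail)
                AlignmentHit(contig.id, subject, 74.0, 1200, 1e-10, 390.0),
                AlignmentHit(contig.id, subject, 80.0, 999, 1e-10, 380.0),
                AlignmentHit(contig.id, subject, 80.0, 1200, 1e-4, 370.0),
            ]
    # read-mapping boundary records, one per stringency rule
    reads = [
        ReadMapRecord("rd_pass_high", "ref1", 90.0, 0.90, 0.10, 0.00),
        ReadMapRecord("rd_fail_id", "ref1", 89.0, 0.95, 0.05, 0.00),
        ReadMapRecord("rd_fail_frac", "ref1", 95.0, 0.89, 0.05, 0.00),
        ReadMapRecord("rd_fail_mm", "ref1", 95.0, 0.95, 0.11, 0.00),
        ReadMapRecord("rd_fail_gap", "ref1", 95.0, 0.95, 0.05, 0.01),
        ReadMapRecord("rd_pass_low", "ref1", 70.0, 0.25, 0.10, 0.10),
        ReadMapRecord("rd_fail_low_id", "ref1", 69.0, 0.30, 0.05, 0.05),
        ReadMapRecord("rd_multi", "ref1", 91.0, 0.95, 0.05, 0.00),
        ReadMapRecord("rd_multi", "ref2", 95.0, 0.95, 0.05, 0.00),
    ]
    # ORF-abundance boundary hits (aa search): at and just below thresholds
    orf_hits = [
        AlignmentHit("orfQ", "s1", 35.0, 30, 1e-5, 60.0),   # exactly at: valid
        AlignmentHit("orfQ", "s2", 34.0, 40, 1e-9, 60.0),   # identity fails
        AlignmentHit("orfQ", "s3", 50.0, 29, 1e-9, 60.0),   # length fails
        AlignmentHit("orfQ", "s4", 50.0, 40, 1e-4, 60.0),   # e-value fails
        AlignmentHit("orfQ", "s5", 60.0, 80, 1e-12, 90.0),  # comfortably valid
    ]
    return {
        "orfs": orfs,
        "nt_hits": nt_hits,
        "taxon_map": taxon_map,
        "read_records": reads,
        "orf_abundance_hits": orf_hits,
        "truth": community.truth,
    }


def make_enterotype_cohort(
    n_samples: int = 40,
    n_groups: int = 4,
    n_phage: int = 60,
    n_noise_phage: int = 10,
    n_shared: int = 4,
    noise_cv: float = 0.5,
    seed: int = 0,
):
    """Planted-enterotype abundance cohort with known sample labels.

    Each group has a template profile: a block of phage of its own plus
    ``n_shared`` phage shared with each adjacent group on a ring (real
    enterotype groups overlap rather than separating cleanly, and the
    overlap gives the cohort a low-dimensional between-group geometry).
    Template abundances are log-uniform on [0.1, 10]; a sample is its group
    template under multiplicative log-normal noise of the stated coefficient
    of variation.  ``n_noise_phage`` rows are present in every sample
    (incidence 100%, i.e. over the 40% noise rule) regardless of group;
    shared-block phage sit at 2/``n_groups`` incidence.

    Returns (SampleAbundanceMatrix, {sample_id: true group letter}).
    """
    from .enterotypes import GROUP_LETTERS, SampleAbundanceMatrix

    if n_samples < 2 * n_groups:
        raise ValueError("need at least two samples per group")
    if n_noise_phage >= n_phage:
        raise ValueError("n_noise_phage must be < n_phage")
    rng = np.random.default_rng(seed)
    n_signal = n_phage - n_noise_phage
    per_group = n_signal // n_groups
    if n_shared >= per_group:
        raise ValueError("n_shared must be smaller than the per-group block")
    n_own = per_group - n_shared
    sigma = float(np.sqrt(np.log(1.0 + noise_cv**2)))

    def template_values(n: int) -> np.ndarray:
        return np.exp(rng.uniform(np.log(0.1), np.log(10.0), n))

    templates = np.zeros((n_groups, n_phage))
    for g in range(n_groups):
        templates[g, g * n_own : (g + 1) * n_own] = template_values(n_own)
    base = n_groups * n_own
    if n_groups > 2 and n_shared > 0:
        for g in range(n_groups):  # ring: block shared by groups g and g+1
            vals = template_values(n_shared)
            lo = base + g * n_shared
            templates[g, lo : lo + n_shared] = vals
            templates[(g + 1) % n_groups, lo : lo + n_shared] = vals
        base += n_groups * n_shared
    # any leftover signal rows become extra own-block phage, round robin
    for k, p in enumerate(range(base, n_signal)):
        templates[k % n_groups, p] = template_values(1)[0]

    labels_true: dict[str, str] = {}
    sample_ids = [f"s{i + 1:02d}" for i in range(n_samples)]
    values = np.zeros((n_phage, n_samples))
    for j, sid in enumerate(sample_ids):
        g = j % n_groups
        labels_true[sid] = GROUP_LETTERS[g]
        noise = np.exp(rng.normal(0.0, sigma, n_phage)) if noise_cv > 0 else 1.0
        col = templates[g] * noise
        # noise phage: present everywhere
        if noise_cv > 0:
            col[n_signal:] = np.exp(rng.uniform(np.log(0.5), np.log(2.0), n_noise_phage))
        else:
            col[n_signal:] = 1.0
        values[:, j] = col
    matrix = SampleAbundanceMatrix(
        tuple(f"p{i + 1:03d}" for i in range(n_phage)), tuple(sample_ids), values
    )
    return matrix, labels_true
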