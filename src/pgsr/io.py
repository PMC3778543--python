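"""Readers and writers for the standard interchange formats.

FASTA via Biopython; alignment hits in the 12-column BLAST tabular dialect
(qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore) with coverages computed from a companion id -> length
table; ORF annotations as GFF3 (attributes carry function_label,
evidence_source, evidence_evalue); square matrices and signature tables as
TSV; trees as Newick.  Malformed records raise ``ParseError`` naming the
file and line.  Floats in signature and matrix tables are written with 10
significant digits.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylogeny import DistanceMatrix, Tree, parse_newick
from .profiles import AlignmentHit, ReadMapRecord
from .screening import OrfAnnotation
from .sequences import NucleotideSequence, check_unique_ids
from .signatures import TETRANUCLEOTIDES, CorrelationMatrix, SignatureVector

__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_hit_table",
    "read_lengths_table",
    "read_gff3",
    "write_gff3",
    "read_read_map_tsv",
    "read_read_map_sam",
    "write_signature_table",
    "read_signature_table",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_newick",
    "read_newick",
    "write_abundance_matrix",
    "read_abundance_matrix",
]


class ParseError(ValueError):
    """Malformed record in an input file; message carries file:line."""


def read_fasta(path) -> list[NucleotideSequence]:
    seqs = [
        NucleotideSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise ParseError(f"{path}: no FASTA records found")
    check_unique_ids(seqs)
    return seqs


def write_fasta(seqs: list[NucleotideSequence], path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_lengths_table(path) -> dict[str, int]:
    """Two-column id -> length TSV."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            try:
                out[parts[0]] = int(parts[1])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: non-integer length {parts[1]!r}") from e
    return out


def read_hit_table(path, lengths_path=None) -> list[AlignmentHit]:
    """Parse BLAST outfmt-6 rows into AlignmentHit records.

    If a lengths table is given, query/subject coverages are computed as
    alignment length over the full sequence length.
    """
    lengths = read_lengths_table(lengths_path) if lengths_path else {}
    hits = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(f"{path}:{ln}: expected 12 columns, got {len(parts)}")
            try:
                qid, sid = parts[0], parts[1]
                pident = float(parts[2])
                alen = int(parts[3])
                evalue = float(parts[10])
                bits = float(parts[11])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: non-numeric field ({e})") from e
            qcov = alen / lengths[qid] if qid in lengths else math.nan
            scov = alen / lengths[sid] if sid in lengths else math.nan
            hits.append(
                AlignmentHit(
                    qid, sid, pident, alen, evalue, bits,
                    subject_coverage=min(scov, 1.0) if not math.isnan(scov) else scov,
                    query_coverage=min(qcov, 1.0) if not math.isnan(qcov) else qcov,
                )
            )
    return hits


_GFF_SOURCE = "pgsr"


def write_gff3(orfs: list[OrfAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            ev = "" if o.evidence_evalue is None else f";evidence_evalue={o.evidence_evalue!r}"
            attrs = (
                f"ID={o.orf_id};function_label={o.function_label}"
                f";evidence_source={o.evidence_source}{ev}"
            )
            fh.write(
                f"{o.contig_id}\t{_GFF_SOURCE}\tCDS\t{o.start}\t{o.end}\t.\t{o.strand}\t0\t{attrs}\n"
            )


def read_gff3(path) -> list[OrfAnnotation]:
    orfs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{ln}: expected 9 columns, got {len(parts)}")
            attrs = {}
            for item in parts[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = v
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: non-integer coordinate") from e
            ev = attrs.get("evidence_evalue")
            try:
                orfs.append(
                    OrfAnnotation(
                        parts[0],
                        attrs.get("ID", f"{parts[0]}_orf{ln}"),
                        start,
                        end,
                        parts[6],
                        attrs.get("function_label", "hypothetical protein"),
                        attrs.get("evidence_source", "none"),
                        None if ev is None else float(ev),
                    )
                )
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: {e}") from e
    return orfs


def read_read_map_tsv(path) -> list[ReadMapRecord]:
    """Native six-column read-mapping TSV: read, reference, %id, fractions."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"{path}:{ln}: expected 6 columns, got {len(parts)}")
            try:
                out.append(
                    ReadMapRecord(
                        parts[0], parts[1], float(parts[2]),
                        float(parts[3]), float(parts[4]), float(parts[5]),
                    )
                )
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: {e}") from e
    return out


def read_read_map_sam(path) -> list[ReadMapRecord]:
    """Derive mapping records from a SAM file (NM tag and CIGAR)."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_length in (None, 0):
                continue
            stats = dict(zip("MIDNSHP=X", [0] * 9))
            for op, n in aln.cigartuples or []:
                stats["MIDNSHP=X"[op]] += n
            aligned = stats["M"] + stats["="] + stats["X"] + stats["I"]
            gaps = stats["I"] + stats["D"]
            read_len = aln.infer_read_length() or aln.query_length
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            mismatches = max(0, nm - gaps)
            denom = aligned + stats["D"]
            pid = 100.0 * (1.0 - nm / denom) if denom else 0.0
            out.append(
                ReadMapRecord(
                    aln.query_name,
                    aln.reference_name,
                    max(0.0, pid),
                    min(1.0, aligned / read_len),
                    min(1.0, mismatches / read_len),
                    min(1.0, gaps / read_len),
                )
            )
    return out


def write_signature_table(sigs: list[SignatureVector], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\t" + "\t".join(TETRANUCLEOTIDES) + "\n")
        for s in sigs:
            fh.write(s.sequence_id + "\t" + "\t".join(f"{v:.10g}" for v in s.z) + "\n")


def read_signature_table(path) -> list[SignatureVector]:
    sigs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:1] != ["sequence_id"] or len(header) != 257:
            raise ParseError(f"{path}:1: bad signature table header")
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 257:
                raise ParseError(f"{path}:{ln}: expected 257 columns, got {len(parts)}")
            try:
                z = np.array([float(v) for v in parts[1:]])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: non-numeric Z-score") from e
            sigs.append(SignatureVector(parts[0], z))
    return sigs


def write_matrix_tsv(labels, matrix: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(labels) + "\n")
        for lbl, row in zip(labels, matrix):
            fh.write(lbl + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_matrix_tsv(path, kind: str = "distance"):
    """Read a square labelled TSV as a DistanceMatrix or CorrelationMatrix."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        labels = tuple(header[1:])
        rows = []
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(labels) + 1:
                raise ParseError(f"{path}:{ln}: ragged matrix row")
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: non-numeric entry") from e
    m = np.array(rows)
    if m.shape != (len(labels), len(labels)):
        raise ParseError(f"{path}: matrix is not square")
    if kind == "distance":
        return DistanceMatrix(labels, m)
    return CorrelationMatrix(labels, m)


def write_newick(tree: Tree, path, include_support: bool = True) -> None:
    Path(path).write_text(tree.to_newick(include_support) + "\n")


def read_newick(path) -> Tree:
    return parse_newick(Path(path).read_text())


def write_abundance_matrix(matrix, path) -> None:
    """Phage x sample TSV with `#scaffold_group` sidecar comment lines."""
    with open(path, "w") as fh:
        for g, members in sorted(matrix.scaffold_groups.items()):
            fh.write(f"#scaffold_group\t{g}\t{','.join(sorted(members))}\n")
        fh.write("phage_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for pid, row in zip(matrix.phage_ids, matrix.values):
            fh.write(pid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_abundance_matrix(path):
    from .enterotypes import SampleAbundanceMatrix

    groups: dict[str, frozenset[str]] = {}
    header = None
    phage_ids, rows = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#scaffold_group\t"):
                _, g, members = line.split("\t")
                groups[g] = frozenset(members.split(","))
                continue
            if header is None:
                header = line.split("\t")
                if header[0] != "phage_id":
                    raise ParseError(f"{path}:{ln}: bad abundance header")
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ParseError(f"{path}:{ln}: ragged abundance row")
            phage_ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: non-numeric abundance") from e
    if header is None:
        raise ParseError(f"{path}: empty abundance matrix")
    return SampleAbundanceMatrix(
        tuple(phage_ids), tuple(header[1:]), np.array(rows), groups
    )
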