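"""Readers and writers for the formats the toolkit touches.

Standard formats (FASTA, SAM, VCF, newick) are parsed with Biopython, pysam
and dendropy.  The Consensus Call Format (CCF) — a per-position TSV audit
trail of every consensus decision — is defined and implemented here.

Coordinates are 1-based inclusive in everything read or written.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pysam
from Bio import SeqIO

from .errors import DataError

BASES = ("A", "C", "G", "T")

_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def revcomp(seq: str) -> str:
    """Reverse complement (gaps and N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N,-}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("sequence record with empty id")
        if not self.sequence:
            raise DataError(f"sequence record {self.id!r} has empty sequence")


@dataclass(frozen=True)
class AlignedRead:
    """One mapped fragment with per-base molecule-terminus distances.

    ``bases`` is the read painted onto the reference: one character per
    reference position from ``ref_start``, with ``-`` at deletions.
    ``dist5[k]``/``dist3[k]`` give the distance of the base at offset ``k``
    from the molecule's own 5'/3' terminus (0-based, measured in the read's
    orientation, soft/hard-clipped bases included in the molecule length);
    -1 at deletion slots.  Deamination is a molecule-end phenomenon, so for
    reverse-strand reads the 5' terminus sits at the rightmost aligned base.
    """

    id: str
    ref_name: str
    ref_start: int  # 1-based
    strand: str  # '+' or '-'
    bases: str
    dist5: tuple[int, ...]
    dist3: tuple[int, ...]

    @property
    def ref_end(self) -> int:
        """Last reference position covered (1-based inclusive)."""
        return self.ref_start + len(self.bases) - 1


@dataclass(frozen=True)
class VariantRecord:
    contig: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    allele_depths: tuple[int, ...]  # ref first, then alts
    kind: str  # 'snp' | 'indel'

    @property
    def total_depth(self) -> int:
        return sum(self.allele_depths)


@dataclass
class CCFRecord:
    """Per-position consensus bookkeeping.

    ``call`` is one of A/C/G/T/N, ``-`` for an applied deletion, or an
    inserted base string for INDEL_INS rows (anchored at the preceding
    reference position).
    """

    contig: str
    pos: int
    ref_base: str
    call: str
    reason: str  # CALLED | LOW_COV | LOW_FREQ | NO_DATA | INDEL_INS | INDEL_DEL
    raw_depth: int
    adj_depth: int
    removed_damage_count: int
    raw_counts: dict[str, int] = field(default_factory=dict)
    adj_counts: dict[str, int] = field(default_factory=dict)
    winning_frequency: float | None = None


@dataclass(frozen=True)
class GeneAnnotation:
    """A protein-coding gene interval in reference coordinates."""

    gene: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    genetic_code: int = 2  # NCBI table 2, vertebrate mitochondrial

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"annotation {self.gene}: start > end")
        if self.strand not in "+-":
            raise DataError(f"annotation {self.gene}: bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file.

    Lower case is normalised to upper and U to T.  Duplicate ids raise
    :class:`DataError`; an empty file yields an empty list.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_SUPPORTED_CIGAR = set("MIDSH=X")


def read_alignment(path: str | Path) -> list[AlignedRead]:
    """Read mapped reads from a SAM file (header required).

    Unmapped records are skipped.  CIGAR operations outside M/I/D/S/H/=/X
    raise :class:`DataError` naming the offending operation.
    """
    try:
        af = pysam.AlignmentFile(str(path), "r", check_sq=True)
    except ValueError as exc:
        raise DataError(f"cannot read SAM {path}: {exc}") from exc
    reads: list[AlignedRead] = []
    with af:
        if not af.header.references:
            raise DataError(f"SAM {path} has no @SQ reference header")
        for seg in af:
            if seg.is_unmapped:
                continue
            reads.append(_segment_to_read(seg))
    return reads


def _segment_to_read(seg: pysam.AlignedSegment) -> AlignedRead:
    for op, _ in seg.cigartuples or []:
        opchar = "MIDNSHP=XB"[op]
        if opchar not in _SUPPORTED_CIGAR:
            raise DataError(
                f"read {seg.query_name}: unsupported CIGAR operation {opchar!r}"
            )
    cigar = seg.cigartuples or []
    hard_left = cigar[0][1] if cigar and cigar[0][0] == 5 else 0
    # molecule length includes soft- and hard-clipped bases
    mol_len = seg.infer_read_length()
    if mol_len is None:  # pragma: no cover - CIGAR always present for mapped reads
        raise DataError(f"read {seg.query_name}: cannot infer read length")
    strand = "-" if seg.is_reverse else "+"
    seq = seg.query_sequence or ""

    bases: list[str] = []
    d5: list[int] = []
    d3: list[int] = []
    qpos = 0  # index into SEQ (soft clips included, hard clips not)
    for op, length in cigar:
        opchar = "MIDNSHP=XB"[op]
        if opchar in "M=X":
            for k in range(length):
                q_mol = qpos + k + hard_left
                bases.append(seq[qpos + k].upper() if seq else "N")
                if strand == "+":
                    d5.append(q_mol)
                    d3.append(mol_len - 1 - q_mol)
                else:
                    d5.append(mol_len - 1 - q_mol)
                    d3.append(q_mol)
            qpos += length
        elif opchar == "I":
            qpos += length
        elif opchar == "D":
            bases.extend("-" * length)
            d5.extend([-1] * length)
            d3.extend([-1] * length)
        elif opchar == "S":
            qpos += length
    return AlignedRead(
        id=seg.query_name or "",
        ref_name=seg.reference_name or "",
        ref_start=seg.reference_start + 1,
        strand=strand,
        bases="".join(bases),
        dist5=tuple(d5),
        dist3=tuple(d3),
    )


def _read_cigar(read: AlignedRead) -> str:
    """CIGAR for an AlignedRead: M/D runs, with hard clips encoding any
    molecule portion outside this record (e.g. the other segment of a
    fragment that wraps a circular reference), so terminus distances
    survive a SAM round-trip."""
    covered = [k for k, b in enumerate(read.bases) if b != "-"]
    if not covered:
        raise DataError(f"read {read.id}: no aligned bases")
    first, last = covered[0], covered[-1]
    # position within the full molecule, in SEQ (reference) orientation
    qm = read.dist5 if read.strand == "+" else read.dist3
    mol_len = read.dist5[first] + read.dist3[first] + 1
    left = qm[first]
    right = mol_len - 1 - qm[last]
    ops: list[str] = []
    if left:
        ops.append(f"{left}H")
    run_op, run_len = None, 0
    for b in read.bases:
        op = "D" if b == "-" else "M"
        if op == run_op:
            run_len += 1
        else:
            if run_op:
                ops.append(f"{run_len}{run_op}")
            run_op, run_len = op, 1
    ops.append(f"{run_len}{run_op}")
    if right:
        ops.append(f"{right}H")
    return "".join(ops)


def write_sam(
    reads: Sequence[AlignedRead],
    ref_name: str,
    ref_length: int,
    path: str | Path,
) -> None:
    """Write reads as plain-text SAM (deterministic, bit-stable)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{ref_name}\tLN:{ref_length}\n")
        for r in reads:
            flag = 16 if r.strand == "-" else 0
            seq = r.bases.replace("-", "")
            fh.write(
                f"{r.id}\t{flag}\t{ref_name}\t{r.ref_start}\t60\t{_read_cigar(r)}\t*\t0\t0\t{seq}\t*\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF 4.x file with per-allele depths.

    Depths come from the first sample's ``AD`` FORMAT field, falling back to
    ``INFO/AD``.  A record without allele depths raises :class:`DataError`
    naming the record.  Records are returned sorted by (contig, pos).
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ad = None
            if rec.samples:
                sample = rec.samples[0]
                if "AD" in sample and sample["AD"] is not None:
                    ad = sample["AD"]
            if ad is None and "AD" in rec.info:
                ad = rec.info["AD"]
            if ad is None or any(x is None for x in ad):
                raise DataError(
                    f"VCF record {rec.chrom}:{rec.pos} {rec.ref}->"
                    f"{','.join(rec.alts or ['.'])} has no allele-depth (AD) field"
                )
            alts = tuple(rec.alts or ())
            depths = tuple(int(x) for x in ad)
            if len(depths) != 1 + len(alts):
                raise DataError(
                    f"VCF record {rec.chrom}:{rec.pos}: AD has {len(depths)} values "
                    f"for {1 + len(alts)} alleles"
                )
            kind = "snp" if all(len(a) == 1 for a in (rec.ref, *alts)) else "indel"
            out.append(
                VariantRecord(
                    contig=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=alts,
                    allele_depths=depths,
                    kind=kind,
                )
            )
    out.sort(key=lambda v: (v.contig, v.pos))
    return out


# ---------------------------------------------------------------------------
# CCF — Consensus Call Format
# ---------------------------------------------------------------------------

CCF_COLUMNS = (
    "contig",
    "pos",
    "ref_base",
    "call",
    "reason",
    "raw_depth",
    "adj_depth",
    "removed_damage",
    "raw_A",
    "raw_C",
    "raw_G",
    "raw_T",
    "adj_A",
    "adj_C",
    "adj_G",
    "adj_T",
    "winning_frequency",
)


def write_ccf(records: Sequence[CCFRecord], path: str | Path) -> None:
    """Write CCF: TSV, one header line, one row per record.

    Records must be position-sorted (INDEL_INS rows share the anchor
    position of the preceding record).  Output is bit-exact across runs.
    """
    last: tuple[str, int] | None = None
    for rec in records:
        key = (rec.contig, rec.pos)
        if last is not None and key < last:
            raise DataError(f"CCF records not sorted at {rec.contig}:{rec.pos}")
        last = key
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CCF_COLUMNS)
        for rec in records:
            freq = "." if rec.winning_frequency is None else f"{rec.winning_frequency:.6f}"
            w.writerow(
                [
                    rec.contig,
                    rec.pos,
                    rec.ref_base,
                    rec.call,
                    rec.reason,
                    rec.raw_depth,
                    rec.adj_depth,
                    rec.removed_damage_count,
                    *(rec.raw_counts.get(b, 0) for b in BASES),
                    *(rec.adj_counts.get(b, 0) for b in BASES),
                    freq,
                ]
            )


def read_ccf(path: str | Path) -> list[CCFRecord]:
    records: list[CCFRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise DataError(f"CCF {path} is empty (header line required)")
        if tuple(header) != CCF_COLUMNS:
            raise DataError(f"CCF {path} has unexpected header")
        for row in reader:
            freq = None if row[16] == "." else round(float(row[16]), 6)
            records.append(
                CCFRecord(
                    contig=row[0],
                    pos=int(row[1]),
                    ref_base=row[2],
                    call=row[3],
                    reason=row[4],
                    raw_depth=int(row[5]),
                    adj_depth=int(row[6]),
                    removed_damage_count=int(row[7]),
                    raw_counts={b: int(row[8 + i]) for i, b in enumerate(BASES)},
                    adj_counts={b: int(row[12 + i]) for i, b in enumerate(BASES)},
                    winning_frequency=freq,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Trees, clade maps, annotation tables
# ---------------------------------------------------------------------------


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a newick tree (labels preserved verbatim)."""
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
    )


def read_clade_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``leaf_label<TAB>clade_label``."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise DataError(f"clade map {path}: malformed row {row!r}")
            if row[0] in mapping:
                raise DataError(f"clade map {path}: duplicate leaf {row[0]!r}")
            mapping[row[0]] = row[1]
    return mapping


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a CDS table: TSV with columns gene, start, end, strand[, code]."""
    out: list[GeneAnnotation] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "gene":
                continue
            code = int(row[4]) if len(row) > 4 and row[4] else 2
            out.append(GeneAnnotation(row[0], int(row[1]), int(row[2]), row[3], code))
    return out
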