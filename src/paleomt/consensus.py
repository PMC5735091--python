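"""Damage-aware haploid consensus calling.

The caller collapses aligned ancient-DNA reads into a single consensus
sequence.  Before a position is called, every observation consistent with
post-mortem deamination (C→T near the molecule 5' terminus, G→A near the
3' terminus for double-stranded libraries) is removed from its allele count
and from the position's depth — the coverage of the miscoding base is
artificially reduced — so that terminal damage cannot masquerade as a
variant.  A position is then called only if its adjusted depth reaches
``c_min`` and the winning allele's frequency reaches ``f_min``; otherwise
an N is emitted.  Every decision is recorded as a CCF row.

Insertions and deletions are taken from a VCF (no terminus information, so
no damage adjustment) and applied with the same depth/frequency thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .damage import DEFAULT_DAMAGE_WINDOW, DamageProfile, is_damage_consistent
from .errors import DataError, UsageError
from .io import (
    BASES,
    AlignedRead,
    CCFRecord,
    SequenceRecord,
    VariantRecord,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class ConsensusParams:
    """Calling thresholds.

    ``c_min`` — minimum adjusted coverage for a call (default 5).
    ``f_min`` — minimum winning-allele frequency (default 0.75); both
    thresholds are inclusive.  ``d`` — damage window in bases from each
    terminus within which deamination-consistent observations are
    discounted (``d=0`` disables the adjustment entirely).
    """

    c_min: int = 5
    f_min: float = 0.75
    d: int = DEFAULT_DAMAGE_WINDOW
    use_indels: bool = True

    def __post_init__(self) -> None:
        if self.c_min < 1:
            raise UsageError("c_min must be >= 1")
        if not (0.5 < self.f_min <= 1.0):
            raise UsageError("f_min must lie in (0.5, 1]")
        if self.d < 0:
            raise UsageError("damage window d must be >= 0")


@dataclass
class PileupColumn:
    """Raw per-position observations: (base, dist5, dist3, strand).

    Bases are in reference orientation; distances in molecule orientation.
    """

    pos: int  # 1-based
    ref_base: str
    observations: list[tuple[str, int, int, str]] = field(default_factory=list)

    @property
    def raw_depth(self) -> int:
        return len(self.observations)

    def raw_counts(self) -> dict[str, int]:
        counts = {b: 0 for b in BASES}
        for base, _, _, _ in self.observations:
            counts[base] += 1
        return counts


@dataclass
class AdjustedColumn:
    pos: int
    ref_base: str
    raw_counts: dict[str, int]
    adj_counts: dict[str, int]
    removed_damage_count: int

    @property
    def raw_depth(self) -> int:
        return sum(self.raw_counts.values())

    @property
    def adj_depth(self) -> int:
        return sum(self.adj_counts.values())


@dataclass(frozen=True)
class ConsensusCall:
    pos: int
    ref_base: str
    call: str  # A/C/G/T/N
    reason: str  # CALLED | LOW_COV | LOW_FREQ | NO_DATA
    winning_frequency: float | None


@dataclass
class ConsensusResult:
    """Output bundle of :func:`generate_consensus`.

    ``record`` is the edited consensus (deletions removed, insertions
    spliced in); ``gapped`` keeps reference length with ``-`` at applied
    deletions, for alignment use.  ``ccf`` has one row per reference
    position plus insertion rows.
    """

    record: SequenceRecord
    gapped: str
    ccf: list[CCFRecord]
    completeness: float
    mean_adj_coverage: float
    n_by_reason: dict[str, int]
    damage_flagged_positions: frozenset[int] = frozenset()


def build_pileup(
    reads: Iterable[AlignedRead], reference: str | SequenceRecord
) -> list[PileupColumn]:
    """Build one column per reference position from aligned reads.

    Observations with non-ACGT bases are dropped.
    """
    ref = reference.sequence if isinstance(reference, SequenceRecord) else reference
    columns = [PileupColumn(pos=i + 1, ref_base=ref[i]) for i in range(len(ref))]
    for read in reads:
        for k, base in enumerate(read.bases):
            if base not in "ACGT":
                continue
            pos0 = read.ref_start - 1 + k
            if 0 <= pos0 < len(ref):
                columns[pos0].observations.append(
                    (base, read.dist5[k], read.dist3[k], read.strand)
                )
    return columns


def adjust_column(column: PileupColumn, d: int) -> AdjustedColumn:
    """Remove damage-consistent observations from counts and depth.

    The deamination predicate is evaluated in the molecule's own
    orientation: for reverse-strand observations both the reference and the
    observed base are complemented before the test, so a reference-G→A
    mismatch near a reverse read's 5' terminus is recognised as molecule
    C→T deamination.
    """
    raw = column.raw_counts()
    adj = {b: 0 for b in BASES}
    removed = 0
    for base, d5, d3, strand in column.observations:
        ref_m, obs_m = column.ref_base, base
        if strand == "-":
            ref_m = _COMP.get(ref_m, ref_m)
            obs_m = _COMP[obs_m]
        if is_damage_consistent(ref_m, obs_m, d5, d3, d):
            removed += 1
        else:
            adj[base] += 1
    return AdjustedColumn(column.pos, column.ref_base, raw, adj, removed)


def call_column(adjusted: AdjustedColumn, params: ConsensusParams) -> ConsensusCall:
    """Apply the coverage and frequency thresholds to one adjusted column.

    Exact count ties between distinct winning bases yield N (LOW_FREQ):
    there is no basis to prefer either allele.
    """
    depth = adjusted.adj_depth
    if depth == 0:
        return ConsensusCall(adjusted.pos, adjusted.ref_base, "N", "NO_DATA", None)
    if depth < params.c_min:
        return ConsensusCall(adjusted.pos, adjusted.ref_base, "N", "LOW_COV", None)
    best = max(adjusted.adj_counts.values())
    winners = [b for b in BASES if adjusted.adj_counts[b] == best]
    freq = best / depth
    if len(winners) > 1:
        return ConsensusCall(adjusted.pos, adjusted.ref_base, "N", "LOW_FREQ", freq)
    if freq >= params.f_min:
        return ConsensusCall(adjusted.pos, adjusted.ref_base, winners[0], "CALLED", freq)
    return ConsensusCall(adjusted.pos, adjusted.ref_base, "N", "LOW_FREQ", freq)


@dataclass(frozen=True)
class _AcceptedIndel:
    pos: int  # anchor position (1-based)
    kind: str  # 'ins' | 'del'
    ref_allele: str
    alt_allele: str

    @property
    def deleted_range(self) -> tuple[int, int]:
        # ref CAA alt C at pos p deletes p+1 .. p+len(ref)-1
        return (self.pos + len(self.alt_allele), self.pos + len(self.ref_allele) - 1)


def _accept_indels(
    indel_records: Sequence[VariantRecord], params: ConsensusParams
) -> list[_AcceptedIndel]:
    accepted: list[_AcceptedIndel] = []
    for rec in indel_records:
        if rec.kind != "indel":
            continue
        total = rec.total_depth
        if total == 0:
            continue
        for alt, depth in zip(rec.alt_alleles, rec.allele_depths[1:]):
            if len(alt) == len(rec.ref_allele):
                continue  # MNV, not handled as indel
            if depth >= params.c_min and depth / total >= params.f_min:
                kind = "ins" if len(alt) > len(rec.ref_allele) else "del"
                accepted.append(_AcceptedIndel(rec.pos, kind, rec.ref_allele, alt))
    # overlap check: any two accepted events touching the same positions
    spans: list[tuple[int, int, _AcceptedIndel]] = []
    for ev in accepted:
        if ev.kind == "del":
            spans.append((*ev.deleted_range, ev))
        else:
            spans.append((ev.pos, ev.pos, ev))
    spans.sort(key=lambda t: (t[0], t[1]))
    for (s1, e1, a), (s2, e2, b) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise DataError(
                f"overlapping accepted indels at positions {a.pos} and {b.pos}"
            )
    return accepted


def apply_indels(
    calls: Sequence[ConsensusCall],
    indel_records: Sequence[VariantRecord],
    params: ConsensusParams,
    contig: str = "consensus",
) -> tuple[str, str, list[CCFRecord]]:
    """Splice accepted insertions/deletions into the called sequence.

    An event is applied iff its supporting depth >= ``c_min`` and its
    allele fraction >= ``f_min`` (indels carry no terminus information, so
    no damage adjustment applies).  Returns (edited sequence, gapped
    reference-length sequence, indel CCF rows).  Overlapping accepted
    events raise :class:`DataError`.
    """
    accepted = _accept_indels(indel_records, params)
    deleted: dict[int, _AcceptedIndel] = {}
    insertions: dict[int, _AcceptedIndel] = {}
    for ev in accepted:
        if ev.kind == "del":
            s, e = ev.deleted_range
            for p in range(s, e + 1):
                deleted[p] = ev
        else:
            insertions[ev.pos] = ev

    edited: list[str] = []
    gapped: list[str] = []
    indel_ccf: list[CCFRecord] = []
    for call in calls:
        if call.pos in deleted:
            gapped.append("-")
            indel_ccf.append(
                CCFRecord(
                    contig=contig,
                    pos=call.pos,
                    ref_base=call.ref_base,
                    call="-",
                    reason="INDEL_DEL",
                    raw_depth=0,
                    adj_depth=0,
                    removed_damage_count=0,
                )
            )
        else:
            edited.append(call.call)
            gapped.append(call.call)
        if call.pos in insertions:
            ins = insertions[call.pos]
            inserted = ins.alt_allele[len(ins.ref_allele) :]
            edited.append(inserted)
            indel_ccf.append(
                CCFRecord(
                    contig=contig,
                    pos=call.pos,
                    ref_base=call.ref_base,
                    call=inserted,
                    reason="INDEL_INS",
                    raw_depth=0,
                    adj_depth=0,
                    removed_damage_count=0,
                )
            )
    return "".join(edited), "".join(gapped), indel_ccf


def generate_consensus(
    reads: Iterable[AlignedRead],
    reference: SequenceRecord,
    snp_vcf: Sequence[VariantRecord] | None = None,
    indel_vcf: Sequence[VariantRecord] | None = None,
    params: ConsensusParams = ConsensusParams(),
    consensus_id: str | None = None,
) -> ConsensusResult:
    """Run the full damage-aware caller over a reference.

    Emits exactly one CCF record per reference position (insertion rows are
    anchored at the preceding position).  When ``snp_vcf`` is given it acts
    as a site restriction: positions absent from it may only be called as
    the reference base or N.  ``completeness`` is the fraction of non-N
    positions in the pre-indel consensus; ``mean_adj_coverage`` the mean
    adjusted depth.
    """
    reads = list(reads)
    for r in reads:
        if r.ref_name != reference.id:
            raise DataError(
                f"read {r.id} mapped to contig {r.ref_name!r}, reference is "
                f"{reference.id!r}"
            )
    if snp_vcf:
        bad = {v.contig for v in snp_vcf if v.contig != reference.id}
        if bad:
            raise DataError(f"SNP VCF contigs {sorted(bad)} do not match reference")
    if indel_vcf:
        bad = {v.contig for v in indel_vcf if v.contig != reference.id}
        if bad:
            raise DataError(f"InDel VCF contigs {sorted(bad)} do not match reference")

    allowed_variant_sites = (
        {v.pos for v in snp_vcf if v.kind == "snp"} if snp_vcf is not None else None
    )

    columns = build_pileup(reads, reference)
    calls: list[ConsensusCall] = []
    ccf: list[CCFRecord] = []
    reasons: dict[str, int] = {}
    total_adj_depth = 0
    for col in columns:
        adj = adjust_column(col, params.d)
        call = call_column(adj, params)
        if (
            allowed_variant_sites is not None
            and call.reason == "CALLED"
            and call.call != col.ref_base
            and col.pos not in allowed_variant_sites
        ):
            call = ConsensusCall(col.pos, col.ref_base, col.ref_base, "CALLED",
                                 call.winning_frequency)
        calls.append(call)
        total_adj_depth += adj.adj_depth
        reasons[call.reason] = reasons.get(call.reason, 0) + 1
        ccf.append(
            CCFRecord(
                contig=reference.id,
                pos=col.pos,
                ref_base=col.ref_base,
                call=call.call,
                reason=call.reason,
                raw_depth=adj.raw_depth,
                adj_depth=adj.adj_depth,
                removed_damage_count=adj.removed_damage_count,
                raw_counts=adj.raw_counts,
                adj_counts=adj.adj_counts,
                winning_frequency=call.winning_frequency,
            )
        )

    if params.use_indels and indel_vcf:
        edited, gapped, indel_ccf = apply_indels(
            calls, indel_vcf, params, contig=reference.id
        )
        by_pos: dict[tuple[int, str], CCFRecord] = {}
        for rec in indel_ccf:
            by_pos[(rec.pos, rec.reason)] = rec
        merged: list[CCFRecord] = []
        for rec in ccf:
            if (rec.pos, "INDEL_DEL") in by_pos:
                dele = by_pos[(rec.pos, "INDEL_DEL")]
                dele.raw_depth = rec.raw_depth
                dele.adj_depth = rec.adj_depth
                dele.removed_damage_count = rec.removed_damage_count
                dele.raw_counts = rec.raw_counts
                dele.adj_counts = rec.adj_counts
                merged.append(dele)
            else:
                merged.append(rec)
            if (rec.pos, "INDEL_INS") in by_pos:
                merged.append(by_pos[(rec.pos, "INDEL_INS")])
        ccf = merged
    else:
        edited = "".join(c.call for c in calls)
        gapped = edited

    n_positions = len(columns)
    non_n = sum(1 for c in calls if c.call != "N")
    return ConsensusResult(
        record=SequenceRecord(
            consensus_id or f"{reference.id}_consensus", edited or "N"
        ),
        gapped=gapped,
        ccf=ccf,
        completeness=(non_n / n_positions) if n_positions else 0.0,
        mean_adj_coverage=(total_adj_depth / n_positions) if n_positions else 0.0,
        n_by_reason=reasons,
    )


def consensus_from_vcf(
    snp_vcf: Sequence[VariantRecord],
    reference: SequenceRecord,
    params: ConsensusParams = ConsensusParams(),
    damage_profile: DamageProfile | None = None,
    indel_vcf: Sequence[VariantRecord] | None = None,
    consensus_id: str | None = None,
) -> ConsensusResult:
    """VCF-only calling mode (no read alignment available).

    Allele counts come from the VCF's per-allele depths.  Without terminus
    distances the per-observation damage adjustment is impossible; when a
    :class:`DamageProfile` with measurable terminal damage is supplied,
    positions whose evidence matches the deamination signature (reference C
    with T support, or reference G with A support) are flagged in
    ``damage_flagged_positions`` — an approximation, documented as such —
    but their counts are not altered.
    """
    for v in snp_vcf:
        if v.contig != reference.id:
            raise DataError(f"VCF contig {v.contig!r} does not match reference")
    by_pos = {v.pos: v for v in snp_vcf if v.kind == "snp"}
    flag_damage = damage_profile is not None and (
        float(np.nanmax(damage_profile.ct5, initial=0.0)) > 0
        or float(np.nanmax(damage_profile.ga3, initial=0.0)) > 0
    )

    calls: list[ConsensusCall] = []
    ccf: list[CCFRecord] = []
    reasons: dict[str, int] = {}
    flagged: set[int] = set()
    total_depth = 0
    for i, ref_base in enumerate(reference.sequence):
        pos = i + 1
        counts = {b: 0 for b in BASES}
        if pos in by_pos:
            v = by_pos[pos]
            for allele, depth in zip((v.ref_allele, *v.alt_alleles), v.allele_depths):
                if allele in counts:
                    counts[allele] += depth
            if flag_damage and (
                (ref_base == "C" and counts["T"] > 0)
                or (ref_base == "G" and counts["A"] > 0)
            ):
                flagged.add(pos)
        adj = AdjustedColumn(pos, ref_base, dict(counts), counts, 0)
        call = call_column(adj, params)
        calls.append(call)
        total_depth += adj.adj_depth
        reasons[call.reason] = reasons.get(call.reason, 0) + 1
        ccf.append(
            CCFRecord(
                contig=reference.id,
                pos=pos,
                ref_base=ref_base,
                call=call.call,
                reason=call.reason,
                raw_depth=adj.raw_depth,
                adj_depth=adj.adj_depth,
                removed_damage_count=0,
                raw_counts=adj.raw_counts,
                adj_counts=adj.adj_counts,
                winning_frequency=call.winning_frequency,
            )
        )

    if params.use_indels and indel_vcf:
        edited, gapped, indel_ccf = apply_indels(
            calls, indel_vcf, params, contig=reference.id
        )
        extra = {(r.pos, r.reason): r for r in indel_ccf}
        merged = []
        for rec in ccf:
            if (rec.pos, "INDEL_DEL") in extra:
                merged.append(extra[(rec.pos, "INDEL_DEL")])
            else:
                merged.append(rec)
            if (rec.pos, "INDEL_INS") in extra:
                merged.append(extra[(rec.pos, "INDEL_INS")])
        ccf = merged
    else:
        edited = "".join(c.call for c in calls)
        gapped = edited

    n_positions = len(reference.sequence)
    non_n = sum(1 for c in calls if c.call != "N")
    return ConsensusResult(
        record=SequenceRecord(
            consensus_id or f"{reference.id}_consensus", edited or "N"
        ),
        gapped=gapped,
        ccf=ccf,
        completeness=(non_n / n_positions) if n_positions else 0.0,
        mean_adj_coverage=(total_depth / n_positions) if n_positions else 0.0,
        n_by_reason=reasons,
        damage_flagged_positions=frozenset(flagged),
    )

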