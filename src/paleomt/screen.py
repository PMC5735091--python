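"""Library screening arithmetic: endogenous fraction, capture efficiency,
competitive species assignment, NUMT read filtering, and mitogenome QC
categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import UsageError


@dataclass(frozen=True)
class ScreeningStats:
    """Per-library endogenous percentages and enrichment efficiency."""

    endogenous_pre_pct: float
    endogenous_post_pct: float
    capture_efficiency: float | None  # None when pre-capture endogenous is 0

    @property
    def efficiency_defined(self) -> bool:
        return self.capture_efficiency is not None


@dataclass(frozen=True)
class QCVerdict:
    mean_coverage: float
    completeness: float  # fraction of mitogenome covered, [0,1]
    support: float  # nucleotide support fraction, [0,1]
    category: str  # 'fail' | 'relaxed' | 'strict'


def numt_filter(
    mito_mapped_ids: Iterable[str], nuclear_mapped_ids: Iterable[str]
) -> list[str]:
    """Retain mitochondrial reads that did not also map to the nuclear genome.

    A fragment mapping to both compartments may be a NUMT (nuclear copy of
    mitochondrial sequence) and is removed.  Input order is preserved.
    """
    nuclear = set(nuclear_mapped_ids)
    return [rid for rid in mito_mapped_ids if rid not in nuclear]


def screening_stats(
    pre_mapped: int, pre_total: int, post_mapped: int, post_total: int
) -> ScreeningStats:
    """Endogenous percentages before/after capture and their ratio.

    Capture efficiency = post-capture endogenous % / pre-capture endogenous
    %; undefined (None, not an error) when nothing mapped before capture.
    """
    if pre_total <= 0 or post_total <= 0:
        raise UsageError("read totals must be positive")
    if not (0 <= pre_mapped <= pre_total and 0 <= post_mapped <= post_total):
        raise UsageError("mapped counts must lie in [0, total]")
    pre = 100.0 * pre_mapped / pre_total
    post = 100.0 * post_mapped / post_total
    eff = (post / pre) if pre > 0 else None
    return ScreeningStats(pre, post, eff)


def species_assign(
    mapped_counts: Mapping[str, int], ratio_threshold: float = 10.0
) -> str:
    """Competitive-mapping species assignment.

    A taxon is assigned iff its mapped-read count is at least
    ``ratio_threshold`` times every other taxon's count (ten-fold by
    default).  Returns the taxon name, ``"ambiguous"``, or
    ``"undetermined"`` when no reads mapped anywhere.
    """
    if len(mapped_counts) < 2:
        raise UsageError("species_assign needs counts for at least two taxa")
    if all(c == 0 for c in mapped_counts.values()):
        return "undetermined"
    for taxon, count in mapped_counts.items():
        others = [c for t, c in mapped_counts.items() if t != taxon]
        if all(count >= ratio_threshold * c for c in others) and count > 0:
            return taxon
    return "ambiguous"


def qc_classify(mean_coverage: float, completeness: float, support: float) -> QCVerdict:
    """Classify a reconstructed mitogenome as strict / relaxed / fail.

    Strict: >10-fold average coverage, >80% of the genome covered, and
    nucleotide support >= 90%.  Relaxed: >3-fold coverage and >66%
    covered.  Support is interpreted as the fraction of called positions
    whose winning-allele frequency is at least 0.90.
    """
    if not (0.0 <= completeness <= 1.0 and 0.0 <= support <= 1.0):
        raise UsageError("completeness and support must lie in [0, 1]")
    if mean_coverage > 10 and completeness > 0.80 and support >= 0.90:
        category = "strict"
    elif mean_coverage > 3 and completeness > 0.66:
        category = "relaxed"
    else:
        category = "fail"
    return QCVerdict(mean_coverage, completeness, support, category)


def nucleotide_support(ccf_records: Sequence) -> float:
    """Fraction of CALLED positions with winning-allele frequency >= 0.90."""
    called = [r for r in ccf_records if r.reason == "CALLED"]
    if not called:
        return 0.0
    good = sum(
        1
        for r in called
        if r.winning_frequency is not None and r.winning_frequency >= 0.90
    )
    return good / len(called)
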