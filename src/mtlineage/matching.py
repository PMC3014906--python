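"""Exact haplotype matching within and between sample sets.

Two records match when, over the intersection of their covered ranges
(which must reach a minimum overlap length), their variant sets restricted
to that range are identical.  Records whose shared coverage is too thin are
reported as *indeterminate* rather than novel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import InputError, SampleRecord

__all__ = [
    "MIN_OVERLAP_DEFAULT",
    "MatchReport",
    "exact_match",
    "shared_haplotypes",
    "novelty_screen",
    "contamination_check",
]

#: below this many jointly covered positions no found/novel verdict is made.
MIN_OVERLAP_DEFAULT = 250


@dataclass(frozen=True)
class MatchReport:
    query: str
    matched: tuple[str, ...]
    shared_window: tuple[int, int] | None
    status: str  # "found" | "novel" | "indeterminate"

    def __post_init__(self) -> None:
        if self.status == "novel" and self.matched:
            raise InputError("novel report cannot carry matches")


def _restricted_tokens(record: SampleRecord, shared: frozenset[int]) -> frozenset[str]:
    motif = record.motif.without_length_variants()
    return frozenset(v.token for v in motif.variants if v.position in shared)


def exact_match(
    query: SampleRecord,
    references: Sequence[SampleRecord],
    min_overlap: int = MIN_OVERLAP_DEFAULT,
) -> MatchReport:
    """Compare one resolved query against a reference set."""
    if not query.resolved:
        raise InputError(f"unresolved query motif: {query.id}")
    q_cov = query.covered_positions()
    matched: list[str] = []
    usable = False
    span: tuple[int, int] | None = None
    for ref in references:
        if not ref.resolved:
            continue
        shared = q_cov & ref.covered_positions()
        if len(shared) < min_overlap:
            continue
        usable = True
        if _restricted_tokens(query, shared) == _restricted_tokens(ref, shared):
            matched.append(ref.id)
            span = (min(shared), max(shared))
    if matched:
        return MatchReport(query.id, tuple(sorted(matched)), span, "found")
    if not usable:
        return MatchReport(query.id, (), None, "indeterminate")
    return MatchReport(query.id, (), None, "novel")


def shared_haplotypes(
    pop_a: Sequence[SampleRecord],
    pop_b: Sequence[SampleRecord],
    min_overlap: int = MIN_OVERLAP_DEFAULT,
) -> list[tuple[str, str, int, int]]:
    """All cross-population exact-match pairs as
    (label_a, label_b, count_a, count_b), count-weighted."""
    if not pop_a or not pop_b:
        raise InputError("both populations must be non-empty")
    pairs = []
    for a in pop_a:
        if not a.resolved:
            continue
        report = exact_match(a, [b for b in pop_b if b.resolved], min_overlap)
        for b_label in report.matched:
            b = next(r for r in pop_b if r.id == b_label)
            pairs.append((a.id, b.id, a.count, b.count))
    return sorted(pairs)


def novelty_screen(
    queries: Sequence[SampleRecord],
    database: Sequence[SampleRecord],
    min_overlap: int = MIN_OVERLAP_DEFAULT,
) -> tuple[list[MatchReport], int]:
    """Label every query found/novel/indeterminate against the database;
    returns the reports and the novel count."""
    if not database:
        raise InputError("database must be non-empty")
    reports = [exact_match(q, database, min_overlap) for q in queries]
    return reports, sum(1 for r in reports if r.status == "novel")


def contamination_check(
    sample_records: Sequence[SampleRecord],
    personnel_records: Sequence[SampleRecord],
    min_overlap: int = MIN_OVERLAP_DEFAULT,
) -> list[tuple[str, str]]:
    """Flag any exact match between analysed samples and laboratory
    personnel profiles as potential contamination."""
    flags: list[tuple[str, str]] = []
    if not personnel_records:
        return flags
    for rec in sample_records:
        if not rec.resolved:
            continue
        report = exact_match(rec, personnel_records, min_overlap)
        flags.extend((rec.id, person) for person in report.matched)
    return sorted(flags)
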