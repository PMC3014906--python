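"""Reference-anchored sequence windows, variant/motif calling and file I/O.

Coordinates are 1-based positions on the mitochondrial reference, with
inclusive windows.  A haplotype *motif* is the canonical ordered set of
differences of a sequence from the reference within a window; variants are
written in ``16223T`` style (position immediately followed by the derived
allele; ``16189-`` marks a deletion and ``16193+C`` an insertion after the
position).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "InputError",
    "ConsistencyError",
    "GapError",
    "ParseError",
    "ReferenceWindow",
    "Variant",
    "HaplotypeMotif",
    "SampleRecord",
    "FragmentRead",
    "MergeResult",
    "reference_window",
    "hvsi_window",
    "sequence_to_motif",
    "motif_to_sequence",
    "merge_fragments",
    "strand_concordance_filter",
    "read_haplotype_table",
    "write_haplotype_table",
    "read_fasta",
    "write_fasta",
    "POLYC_REGION",
    "DEFAULT_HVSI",
    "FRAGMENT_1",
    "FRAGMENT_2",
]

IUPAC = set("ACGTRYSWKMBDHVN")
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

#: poly-cytosine length-variation region around 16189; length variants here
#: are excluded by default from classification, matching and distances.
POLYC_REGION = range(16180, 16194)

#: default HVSI analysis window (318 bp).
DEFAULT_HVSI = (16045, 16362)
#: default overlapping amplicon layout used for degraded samples.
FRAGMENT_1 = (15989, 16251)
FRAGMENT_2 = (16190, 16410)

_REF_START, _REF_END = 15989, 16410


class InputError(ValueError):
    """Invalid user-supplied value."""


class ConsistencyError(ValueError):
    """Internally inconsistent data (e.g. variant ref disagrees with reference)."""


class GapError(ValueError):
    """Fragment set leaves an internal gap; carries the uncovered positions."""

    def __init__(self, positions: Sequence[int]):
        self.positions = tuple(positions)
        super().__init__(f"uncovered internal positions: {self.positions}")


class ParseError(ValueError):
    """File parse failure; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(message + where)


def _load_reference_segment() -> str:
    data = resources.files("mtlineage.data").joinpath("reference_15989_16410.txt")
    return data.read_text().strip().upper()


_REFERENCE_SEGMENT = _load_reference_segment()


@dataclass(frozen=True)
class ReferenceWindow:
    """An inclusive [start, end] slice of the reference with its bases."""

    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InputError(f"window end {self.end} < start {self.start}")
        if len(self.sequence) != len(self):
            raise InputError(
                f"window sequence length {len(self.sequence)} != span {len(self)}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def base_at(self, position: int) -> str:
        if position not in self:
            raise InputError(f"position {position} outside window {self.start}-{self.end}")
        return self.sequence[position - self.start]

    def positions(self) -> range:
        return range(self.start, self.end + 1)

    def sub(self, start: int, end: int) -> "ReferenceWindow":
        if start not in self or end not in self:
            raise InputError(f"{start}-{end} not within {self.start}-{self.end}")
        return ReferenceWindow(start, end, self.sequence[start - self.start : end - self.start + 1])


def reference_window(start: int = _REF_START, end: int = _REF_END) -> ReferenceWindow:
    """Packaged reference over [start, end] ⊆ [15989, 16410]."""
    if start < _REF_START or end > _REF_END:
        raise InputError(
            f"packaged reference covers {_REF_START}-{_REF_END}, requested {start}-{end}"
        )
    return ReferenceWindow(start, end, _REFERENCE_SEGMENT[start - _REF_START : end - _REF_START + 1])


def hvsi_window() -> ReferenceWindow:
    """The default 318-bp HVSI window, 16045-16362."""
    return reference_window(*DEFAULT_HVSI)


_VARIANT_TOKEN = re.compile(r"^(\d+)(?:([ACGT-])|\+([ACGT]+))$")


@dataclass(frozen=True, order=True)
class Variant:
    """A single substitution or length variant relative to the reference."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise InputError(f"ref == alt at {self.position}")
        if self.ref not in IUPAC and self.ref != "-":
            raise InputError(f"non-IUPAC ref {self.ref!r} at {self.position}")

    @property
    def klass(self) -> str:
        if self.alt == "-" or self.alt.startswith("+") or self.ref == "-":
            return "indel"
        if (self.ref in PURINES) == (self.alt in PURINES):
            return "transition"
        return "transversion"

    @property
    def is_length_variant(self) -> bool:
        return self.klass == "indel" and self.position in POLYC_REGION

    @property
    def token(self) -> str:
        return f"{self.position}{self.alt}"

    @classmethod
    def from_token(cls, token: str, window: ReferenceWindow) -> "Variant":
        m = _VARIANT_TOKEN.match(token.strip())
        if not m:
            raise InputError(f"unrecognised variant token {token!r}")
        position = int(m.group(1))
        alt = m.group(2) or f"+{m.group(3)}"
        if position not in window:
            raise InputError(
                f"position {position} outside window {window.start}-{window.end}"
            )
        ref = window.base_at(position)
        return cls(position, ref, alt)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.token


@dataclass(frozen=True)
class HaplotypeMotif:
    """Canonical ordered variant set of one haplotype within a window."""

    window: ReferenceWindow
    variants: tuple[Variant, ...]
    label: str | None = None

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.variants, key=lambda v: (v.position, v.alt)))
        object.__setattr__(self, "variants", ordered)
        positions = [v.position for v in ordered]
        if len(set(positions)) != len(positions):
            dup = sorted({p for p in positions if positions.count(p) > 1})
            raise ConsistencyError(f"duplicate variant positions {dup}")
        for v in ordered:
            if v.position not in self.window:
                raise ConsistencyError(
                    f"variant {v.token} outside window {self.window.start}-{self.window.end}"
                )
            if not v.alt.startswith("+") and v.ref != self.window.base_at(v.position):
                raise ConsistencyError(
                    f"variant {v.token} ref {v.ref} != reference "
                    f"{self.window.base_at(v.position)} at {v.position}"
                )

    def tokens(self) -> tuple[str, ...]:
        return tuple(v.token for v in self.variants)

    def token_set(self) -> frozenset[str]:
        return frozenset(v.token for v in self.variants)

    def positions(self) -> frozenset[int]:
        return frozenset(v.position for v in self.variants)

    def without_length_variants(self) -> "HaplotypeMotif":
        """Drop poly-C-region length variants (default analysis convention)."""
        kept = tuple(v for v in self.variants if not v.is_length_variant)
        if len(kept) == len(self.variants):
            return self
        return replace(self, variants=kept)

    def restricted(self, start: int, end: int) -> "HaplotypeMotif":
        """Variants within [start, end], on the corresponding sub-window."""
        sub = self.window.sub(max(start, self.window.start), min(end, self.window.end))
        kept = tuple(v for v in self.variants if v.position in sub)
        return HaplotypeMotif(sub, kept, self.label)

    @classmethod
    def from_tokens(
        cls, tokens: Iterable[str], window: ReferenceWindow, label: str | None = None
    ) -> "HaplotypeMotif":
        return cls(window, tuple(Variant.from_token(t, window) for t in tokens), label)

    def __len__(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class SampleRecord:
    """One sampled individual (or collapsed haplotype class) in a population.

    ``motif`` may be None for unresolved records whose sequence is withheld;
    such records still count in frequency spectra by label but are rejected
    by sequence-based analyses.
    """

    id: str
    population: str
    motif: HaplotypeMotif | None
    count: int = 1
    covered: frozenset[int] | None = None
    strand_calls: Mapping[str, frozenset[Variant]] | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise InputError(f"count must be >= 1, got {self.count}")
        if self.motif is not None and self.covered is not None:
            missing = self.motif.positions() - self.covered
            if missing:
                raise ConsistencyError(
                    f"motif positions {sorted(missing)} not in covered set for {self.id}"
                )

    @property
    def resolved(self) -> bool:
        return self.motif is not None

    def covered_positions(self) -> frozenset[int]:
        if self.covered is not None:
            return self.covered
        if self.motif is None:
            return frozenset()
        return frozenset(self.motif.window.positions())


@dataclass(frozen=True)
class FragmentRead:
    """A called sequence over a sub-range of the reference, with strand."""

    start: int
    end: int
    bases: str
    strand: str = "forward"

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise InputError(f"strand must be forward/reverse, got {self.strand!r}")
        if len(self.bases) != self.end - self.start + 1:
            raise InputError(
                f"read bases length {len(self.bases)} != span {self.end - self.start + 1}"
            )
        bad = set(self.bases.upper()) - IUPAC
        if bad:
            raise InputError(f"non-IUPAC characters in read: {sorted(bad)}")


# ---------------------------------------------------------------------------
# variant calling


def sequence_to_motif(
    seq: str, window: ReferenceWindow, label: str | None = None
) -> HaplotypeMotif:
    """Call the motif of ``seq`` against the reference window.

    Positions carrying ``N`` (or any ambiguity code) are treated as no-call:
    they contribute no variant.  Use :func:`covered_positions` to recover the
    effective coverage of such a sequence.
    """
    seq = seq.upper()
    if len(seq) != len(window):
        raise InputError(f"sequence length {len(seq)} != window length {len(window)}")
    bad = set(seq) - IUPAC
    if bad:
        raise InputError(f"non-IUPAC characters: {sorted(bad)}")
    variants = []
    for offset, base in enumerate(seq):
        ref = window.sequence[offset]
        if base in "ACGT" and base != ref:
            variants.append(Variant(window.start + offset, ref, base))
    return HaplotypeMotif(window, tuple(variants), label)


def covered_positions(seq: str, window: ReferenceWindow) -> frozenset[int]:
    """Positions of ``seq`` with an unambiguous base call."""
    seq = seq.upper()
    if len(seq) != len(window):
        raise InputError(f"sequence length {len(seq)} != window length {len(window)}")
    return frozenset(
        window.start + i for i, b in enumerate(seq) if b in "ACGT"
    )


def motif_to_sequence(motif: HaplotypeMotif) -> str:
    """Reference window sequence with the motif's substitutions applied.

    Length variants are not expressed (the returned string stays aligned to
    the window); they survive a round trip through the motif itself, not the
    sequence.
    """
    bases = list(motif.window.sequence)
    for v in motif.variants:
        if v.klass == "indel":
            continue
        bases[v.position - motif.window.start] = v.alt
    return "".join(bases)


# ---------------------------------------------------------------------------
# ancient-fragment consensus


@dataclass(frozen=True)
class MergeResult:
    start: int
    end: int
    sequence: str
    covered: frozenset[int]
    conflicts: tuple[int, ...]


def merge_fragments(reads: Sequence[FragmentRead]) -> MergeResult:
    """Merge overlapping fragment reads into one consensus.

    Positions seen by a single read take that read's base; positions seen by
    several reads must agree, otherwise the position is reported as a
    conflict and set to ``N``.  The union of the ranges must be contiguous.
    """
    if not reads:
        raise InputError("no reads to merge")
    start = min(r.start for r in reads)
    end = max(r.end for r in reads)
    claimed: set[int] = set()
    for r in reads:
        claimed.update(range(r.start, r.end + 1))
    gaps = [p for p in range(start, end + 1) if p not in claimed]
    if gaps:
        raise GapError(gaps)

    calls: dict[int, set[str]] = {}
    for r in sorted(reads, key=lambda r: (r.start, r.end, r.strand, r.bases)):
        for offset, base in enumerate(r.bases.upper()):
            if base == "N":
                continue
            calls.setdefault(r.start + offset, set()).add(base)

    out = []
    conflicts = []
    covered = set()
    for pos in range(start, end + 1):
        seen = calls.get(pos, set())
        if not seen:
            out.append("N")
        elif len(seen) == 1:
            out.append(next(iter(seen)))
            covered.add(pos)
        else:
            out.append("N")
            conflicts.append(pos)
    return MergeResult(start, end, "".join(out), frozenset(covered), tuple(conflicts))


def strand_concordance_filter(
    forward: Iterable[Variant], reverse: Iterable[Variant]
) -> tuple[frozenset[Variant], frozenset[Variant]]:
    """Split strand-specific variant calls into validated and discordant sets.

    Validated variants were called on both strands; everything seen on a
    single strand is returned for review, never silently kept (the standard
    defence against phantom mutations introduced by sequencing chemistry).
    """
    fwd = frozenset(forward)
    rev = frozenset(reverse)
    return fwd & rev, fwd ^ rev


# ---------------------------------------------------------------------------
# tabular / FASTA I/O

_TABLE_COLUMNS = ["label", "population", "count", "variants", "window_start", "window_end"]
UNRESOLVED_TOKEN = "?"


def write_haplotype_table(records: Sequence[SampleRecord], path: str | Path) -> None:
    path = Path(path)
    lines = ["\t".join(_TABLE_COLUMNS)]
    for rec in records:
        if rec.motif is not None:
            window = rec.motif.window
            variants = ";".join(rec.motif.tokens())
        else:
            window = hvsi_window()
            variants = UNRESOLVED_TOKEN
        lines.append(
            "\t".join(
                [rec.id, rec.population, str(rec.count), variants, str(window.start), str(window.end)]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_haplotype_table(path: str | Path) -> list[SampleRecord]:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError("empty file, header row required", line=1)
    header = lines[0].rstrip("\n").split("\t")
    if header != _TABLE_COLUMNS:
        raise ParseError(f"unexpected header {header!r}", line=1)
    records: list[SampleRecord] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != len(_TABLE_COLUMNS):
            raise ParseError(f"expected {len(_TABLE_COLUMNS)} columns, got {len(fields)}", lineno)
        label, population, count_s, variants_s, ws, we = fields
        try:
            count = int(count_s)
            window = reference_window(int(ws), int(we))
        except (ValueError, InputError) as exc:
            raise ParseError(str(exc), lineno) from exc
        if variants_s.strip() == UNRESOLVED_TOKEN:
            motif = None
        else:
            tokens = [t for t in variants_s.split(";") if t.strip()]
            try:
                motif = HaplotypeMotif.from_tokens(tokens, window, label)
            except (InputError, ConsistencyError) as exc:
                raise ParseError(str(exc), lineno) from exc
        try:
            records.append(SampleRecord(label, population, motif, count))
        except InputError as exc:
            raise ParseError(str(exc), lineno) from exc
    return records


def write_fasta(sequences: Mapping[str, str] | Sequence[tuple[str, str]], path: str | Path) -> None:
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def records_to_fasta(records: Sequence[SampleRecord], path: str | Path) -> None:
    """Write resolved records as sequences; unresolved records are skipped."""
    write_fasta(
        [(rec.id, motif_to_sequence(rec.motif)) for rec in records if rec.motif is not None],
        path,
    )
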