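"""Multi-tier mtDNA haplogroup assignment.

Three independent evidence tiers are supported and reconciled:

1. HVSI control-region motif rules (diagnostic variant sets);
2. an RFLP marker panel on coding-region sites (plus the region-V 9-bp
   deletion for haplogroup B);
3. a coding-region minisequencing SNP panel resolving the Amerindian
   sub-haplogroups (B2, C1, D1 ...), optionally conditioned on an HVSI
   variant.

A combined call is concordant when all available tiers agree, with a
sub-haplogroup refining its parent (C1 refines C).  Contradictory tiers
yield ``unclassified`` rather than a guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .core import HaplotypeMotif, InputError, SampleRecord

__all__ = [
    "UNCLASSIFIED",
    "MotifRule",
    "RFLPMarker",
    "CodingPanelRule",
    "HvsiCall",
    "RflpCall",
    "PanelCall",
    "HaplogroupCall",
    "default_motif_rules",
    "default_rflp_panel",
    "default_coding_panel",
    "load_rules",
    "classify_hvsi",
    "type_rflp",
    "classify_panel",
    "combined_call",
    "amerindian_screen",
    "AMERINDIAN_HAPLOGROUPS",
]

UNCLASSIFIED = "unclassified"

#: labels accepted by the Amerindian screen (major haplogroups and their
#: Amerindian sub-haplogroups).
AMERINDIAN_HAPLOGROUPS = frozenset({"A", "B", "C", "D", "X", "A2", "B2", "C1", "D1"})

_PARENT = {"A2": "A", "B2": "B", "C1": "C", "D1": "D"}


@dataclass(frozen=True)
class MotifRule:
    """HVSI diagnostic rule: all ``required`` variant tokens must be present."""

    haplogroup: str
    required: frozenset[str]
    forbidden: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.required:
            raise InputError(f"rule {self.haplogroup}: empty required set")
        if self.required & self.forbidden:
            raise InputError(f"rule {self.haplogroup}: required/forbidden overlap")


@dataclass(frozen=True)
class RFLPMarker:
    """One diagnostic restriction site (or the 9-bp deletion for B)."""

    haplogroup: str
    site: int | None = None
    enzyme: str | None = None
    polarity: str | None = None  # "gain" | "loss"
    special: str | None = None  # "9bp-deletion"

    def __post_init__(self) -> None:
        has_site = self.site is not None and self.enzyme is not None
        if has_site == (self.special is not None):
            raise InputError(
                f"marker {self.haplogroup}: exactly one of (site, enzyme) or special required"
            )
        if has_site and self.polarity not in ("gain", "loss"):
            raise InputError(f"marker {self.haplogroup}: polarity must be gain/loss")

    @property
    def key(self) -> str:
        if self.special:
            return self.special
        return f"{self.site}_{self.enzyme}"

    def diagnostic_state(self) -> str:
        if self.special:
            return "deleted"
        return "present" if self.polarity == "gain" else "absent"


@dataclass(frozen=True)
class CodingPanelRule:
    """Minisequencing rule: derived alleles expected at coding positions,
    optionally plus one HVSI variant token."""

    subhaplogroup: str
    positions: Mapping[int, str]
    hvsi_addendum: str | None = None

    def __post_init__(self) -> None:
        if not self.positions:
            raise InputError(f"panel rule {self.subhaplogroup}: empty position set")


@dataclass(frozen=True)
class HvsiCall:
    haplogroup: str
    rule: MotifRule | None = None
    ambiguous: bool = False
    partial: bool = False


@dataclass(frozen=True)
class RflpCall:
    haplogroup: str
    conflict: bool = False
    markers: tuple[str, ...] = ()


@dataclass(frozen=True)
class PanelCall:
    subhaplogroup: str
    missing: tuple[int, ...] = ()


@dataclass(frozen=True)
class HaplogroupCall:
    sample_id: str
    hvsi: str | None = None
    rflp: str | None = None
    panel: str | None = None
    final: str = UNCLASSIFIED
    concordant: bool = False
    trace: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# default rules


def default_motif_rules() -> list[MotifRule]:
    return [
        MotifRule("A", frozenset({"16111T", "16223T", "16290T", "16319A", "16362C"})),
        MotifRule("B", frozenset({"16189C", "16217C"})),
        MotifRule("C", frozenset({"16223T", "16298C", "16325C", "16327T"})),
        MotifRule("D", frozenset({"16223T", "16325C", "16362C"})),
    ]


def default_rflp_panel() -> list[RFLPMarker]:
    return [
        RFLPMarker("A", site=663, enzyme="HaeIII", polarity="gain"),
        RFLPMarker("B", special="9bp-deletion"),
        RFLPMarker("C", site=13259, enzyme="HincII", polarity="loss"),
        RFLPMarker("D", site=5176, enzyme="AluI", polarity="loss"),
        RFLPMarker("X", site=1715, enzyme="DdeI", polarity="loss"),
    ]


def default_coding_panel() -> list[CodingPanelRule]:
    # B2/D1/C coding markers; C1 = C coding markers + HVSI 16325C.
    return [
        CodingPanelRule(
            "B2", {3547: "G", 4977: "C", 6473: "T", 9950: "C", 11177: "C"}
        ),
        CodingPanelRule("D1", {2092: "T"}),
        CodingPanelRule("C", {14318: "C", 15487: "T"}),
        CodingPanelRule("C1", {14318: "C", 15487: "T"}, hvsi_addendum="16325C"),
    ]


def load_rules(path: str | Path) -> tuple[list[MotifRule], list[RFLPMarker], list[CodingPanelRule]]:
    """Load a YAML rules file; missing sections fall back to the defaults."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    motif = [
        MotifRule(
            r["haplogroup"],
            frozenset(r["required"]),
            frozenset(r.get("forbidden", [])),
        )
        for r in doc.get("motif_rules", [])
    ] or default_motif_rules()
    rflp = [
        RFLPMarker(
            r["haplogroup"],
            site=r.get("site"),
            enzyme=r.get("enzyme"),
            polarity=r.get("polarity"),
            special=r.get("special"),
        )
        for r in doc.get("rflp_markers", [])
    ] or default_rflp_panel()
    panel = [
        CodingPanelRule(
            r["subhaplogroup"],
            {int(k): v for k, v in r["positions"].items()},
            r.get("hvsi_addendum"),
        )
        for r in doc.get("coding_panel", [])
    ] or default_coding_panel()
    return motif, rflp, panel


# ---------------------------------------------------------------------------
# tier 1: HVSI motif rules


def classify_hvsi(
    motif: HaplotypeMotif,
    rules: Sequence[MotifRule] | None = None,
    *,
    allow_partial: bool = True,
    min_partial: int = 2,
) -> HvsiCall:
    """Assign a haplogroup from an HVSI motif.

    The most specific rule (largest required set) fully contained in the
    motif wins; a specificity tie is reported as ambiguous.  When no rule is
    fully contained and ``allow_partial`` is set, the rule matching the
    largest number of required variants wins, provided the match is unique,
    covers at least ``min_partial`` variants and a strict majority of the
    rule; such calls are flagged ``partial``.  Private variants and
    back-mutations at rule sites are thereby tolerated, which the strict
    containment pass is not able to do.
    """
    if rules is None:
        rules = default_motif_rules()
    if not rules:
        raise InputError("empty rule set")
    tokens = motif.without_length_variants().token_set()

    eligible = [r for r in rules if not (r.forbidden & tokens)]
    contained = [r for r in eligible if r.required <= tokens]
    if contained:
        best = max(len(r.required) for r in contained)
        winners = [r for r in contained if len(r.required) == best]
        if len(winners) == 1:
            return HvsiCall(winners[0].haplogroup, winners[0])
        return HvsiCall(UNCLASSIFIED, ambiguous=True)

    if allow_partial:
        scored = [(len(r.required & tokens), r) for r in eligible]
        scored = [
            (s, r)
            for s, r in scored
            if s >= min_partial and 2 * s >= len(r.required)
        ]
        if scored:
            best = max(s for s, _ in scored)
            winners = [r for s, r in scored if s == best]
            if len(winners) == 1:
                return HvsiCall(winners[0].haplogroup, winners[0], partial=True)
            return HvsiCall(UNCLASSIFIED, ambiguous=True)
    return HvsiCall(UNCLASSIFIED)


# ---------------------------------------------------------------------------
# tier 2: RFLP markers


def type_rflp(
    marker_calls: Mapping[str, str],
    panel: Sequence[RFLPMarker] | None = None,
) -> RflpCall:
    """Type a sample from restriction-site states.

    ``marker_calls`` maps marker keys (``"663_HaeIII"``, ``"9bp-deletion"``,
    ...) to observed states in {present, absent, deleted, normal}.  Exactly
    one diagnostic observation yields its haplogroup; several yield a
    conflict.
    """
    if panel is None:
        panel = default_rflp_panel()
    if not marker_calls:
        raise InputError("at least one marker call required")
    by_key = {m.key: m for m in panel}
    valid_states = {"present", "absent", "deleted", "normal"}
    hits = []
    for key, state in marker_calls.items():
        if key not in by_key:
            raise InputError(f"unknown marker {key!r}")
        if state not in valid_states:
            raise InputError(f"unknown marker state {state!r} for {key}")
        marker = by_key[key]
        if state == marker.diagnostic_state():
            hits.append(marker)
    if len(hits) == 1:
        return RflpCall(hits[0].haplogroup, markers=(hits[0].key,))
    if len(hits) > 1:
        return RflpCall(UNCLASSIFIED, conflict=True, markers=tuple(m.key for m in hits))
    return RflpCall(UNCLASSIFIED)


# ---------------------------------------------------------------------------
# tier 3: coding-region minisequencing panel


def classify_panel(
    panel_calls: Mapping[int, str],
    rules: Sequence[CodingPanelRule] | None = None,
    hvsi_motif: HaplotypeMotif | None = None,
) -> PanelCall:
    """Assign a sub-haplogroup from coding-region SNP calls.

    A rule matches when every one of its positions was called with the
    expected derived allele (and its HVSI addendum, if any, is present in
    ``hvsi_motif``).  The most specific matching rule wins; a partial
    position match reports the missing positions.
    """
    if rules is None:
        rules = default_coding_panel()
    if not panel_calls:
        raise InputError("calls at >= 1 panel position required")
    for pos, allele in panel_calls.items():
        if allele not in {"A", "C", "G", "T", "N"}:
            raise InputError(f"invalid allele {allele!r} at {pos}")

    hvsi_tokens = hvsi_motif.token_set() if hvsi_motif is not None else frozenset()
    matches = []
    best_missing: tuple[int, ...] | None = None
    for rule in rules:
        missing = tuple(
            sorted(p for p, a in rule.positions.items() if panel_calls.get(p) != a)
        )
        if missing:
            if any(p in panel_calls for p in rule.positions):
                if best_missing is None or len(missing) < len(best_missing):
                    best_missing = missing
            continue
        if rule.hvsi_addendum and rule.hvsi_addendum not in hvsi_tokens:
            continue
        matches.append(rule)
    if matches:
        best = max(
            matches,
            key=lambda r: (len(r.positions), r.hvsi_addendum is not None),
        )
        return PanelCall(best.subhaplogroup)
    return PanelCall("unknown", missing=best_missing or ())


# ---------------------------------------------------------------------------
# combination and screening


def _compatible(a: str, b: str) -> bool:
    return a == b or _PARENT.get(a) == b or _PARENT.get(b) == a


def _finest(labels: Iterable[str]) -> str:
    return max(labels, key=lambda l: (l in _PARENT, len(l)))


def combined_call(
    sample_id: str,
    hvsi: HvsiCall | None = None,
    rflp: RflpCall | None = None,
    panel: PanelCall | None = None,
) -> HaplogroupCall:
    """Reconcile the available tiers into one concordance-checked call."""
    if hvsi is None and rflp is None and panel is None:
        raise InputError("at least one tier required")
    tiers: dict[str, str] = {}
    trace: list[str] = []
    if hvsi is not None and hvsi.haplogroup != UNCLASSIFIED:
        tiers["hvsi"] = hvsi.haplogroup
        trace.append(
            f"hvsi:{hvsi.haplogroup}" + (":partial" if hvsi.partial else "")
        )
    if rflp is not None and rflp.haplogroup != UNCLASSIFIED:
        tiers["rflp"] = rflp.haplogroup
        trace.append(f"rflp:{rflp.haplogroup}:{','.join(rflp.markers)}")
    if panel is not None and panel.subhaplogroup not in (UNCLASSIFIED, "unknown"):
        tiers["panel"] = panel.subhaplogroup
        trace.append(f"panel:{panel.subhaplogroup}")

    labels = list(tiers.values())
    if not labels:
        return HaplogroupCall(sample_id,
                              hvsi=hvsi.haplogroup if hvsi else None,
                              rflp=rflp.haplogroup if rflp else None,
                              panel=panel.subhaplogroup if panel else None)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if not _compatible(labels[i], labels[j]):
                return HaplogroupCall(
                    sample_id,
                    hvsi=tiers.get("hvsi"),
                    rflp=tiers.get("rflp"),
                    panel=tiers.get("panel"),
                    final=UNCLASSIFIED,
                    concordant=False,
                )
    return HaplogroupCall(
        sample_id,
        hvsi=tiers.get("hvsi"),
        rflp=tiers.get("rflp"),
        panel=tiers.get("panel"),
        final=_finest(labels),
        concordant=True,
        trace=tuple(trace),
    )


def amerindian_screen(
    records: Sequence[SampleRecord],
    calls: Mapping[str, HaplogroupCall],
    amerindian: frozenset[str] = AMERINDIAN_HAPLOGROUPS,
) -> tuple[list[SampleRecord], float]:
    """Select records whose final call is Amerindian; count-weighted fraction."""
    missing = [r.id for r in records if r.id not in calls]
    if missing:
        raise InputError(f"records without a haplogroup call: {missing}")
    subset = [r for r in records if calls[r.id].final in amerindian]
    total = sum(r.count for r in records)
    if total == 0:
        return [], math.nan
    hit = sum(r.count for r in subset)
    return subset, hit / total
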