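"""Matriline partitioning from pedigrees and per-matriline deduplication.

Individuals are grouped by following mother links up to a founder female;
one representative per matriline is then kept so that no two retained
samples share a maternal lineage.  Individuals with an unknown mother found
their own matriline (lineages are never merged without evidence).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .core import InputError, ParseError, SampleRecord

__all__ = [
    "Individual",
    "Pedigree",
    "Matriline",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "build_matrilines",
    "select_representatives",
]

UNKNOWN = "0"


class PedigreeError(ValueError):
    """Structural pedigree problem (cycle, missing mother record)."""


@dataclass(frozen=True)
class Individual:
    id: str
    father: str = UNKNOWN
    mother: str = UNKNOWN
    sex: str = "unknown"  # "male" | "female" | "unknown"
    sampled: bool = False
    family: str = "0"


@dataclass(frozen=True)
class Matriline:
    founder: str
    members: frozenset[str]


class Pedigree:
    def __init__(self, individuals: Sequence[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.id}")
            self.individuals[ind.id] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self.individuals.values():
            if ind.mother != UNKNOWN:
                mother = self.individuals.get(ind.mother)
                if mother is None:
                    raise PedigreeError(
                        f"individual {ind.id}: mother {ind.mother} has no record"
                    )
                if mother.sex == "male":
                    raise PedigreeError(
                        f"individual {ind.id}: mother {ind.mother} is recorded male"
                    )

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Pedigree) and self.individuals == other.individuals


def build_matrilines(ped: Pedigree) -> list[Matriline]:
    """Partition every individual into matrilines by maternal founder.

    Returned in deterministic order (sorted by founder id).  Cycles in the
    mother links are structural errors.
    """
    founder_of: dict[str, str] = {}

    def resolve(ind_id: str, seen: tuple[str, ...]) -> str:
        if ind_id in founder_of:
            return founder_of[ind_id]
        if ind_id in seen:
            raise PedigreeError(f"cycle in mother links at {ind_id}")
        ind = ped.individuals[ind_id]
        if ind.mother == UNKNOWN:
            founder = ind_id
        else:
            founder = resolve(ind.mother, seen + (ind_id,))
        founder_of[ind_id] = founder
        return founder

    for ind in ped:
        resolve(ind.id, ())

    groups: dict[str, set[str]] = {}
    for ind_id, founder in founder_of.items():
        groups.setdefault(founder, set()).add(ind_id)
    return [
        Matriline(founder, frozenset(members))
        for founder, members in sorted(groups.items())
    ]


def select_representatives(
    matrilines: Sequence[Matriline],
    records: Mapping[str, SampleRecord] | Sequence[SampleRecord],
    policy: str = "lexicographic-id",
    seed: int | None = None,
) -> list[SampleRecord]:
    """Pick one sampled record per matriline.

    ``lexicographic-id`` (default) is deterministic; ``random`` requires a
    seed.  Matrilines without any sampled member are skipped.
    """
    if isinstance(records, Mapping):
        by_id = dict(records)
    else:
        by_id = {r.id: r for r in records}
    if policy == "random":
        if seed is None:
            raise InputError("random policy requires a seed")
        rng = random.Random(seed)
    elif policy != "lexicographic-id":
        raise InputError(f"unknown policy {policy!r}")

    out: list[SampleRecord] = []
    for line in sorted(matrilines, key=lambda m: m.founder):
        sampled = sorted(m for m in line.members if m in by_id)
        if not sampled:
            continue
        chosen = sampled[0] if policy == "lexicographic-id" else rng.choice(sampled)
        out.append(by_id[chosen])
    return out


# ---------------------------------------------------------------------------
# PED-style I/O: family, id, father, mother, sex (1=male/2=female/0=unknown),
# sampled status (1=sampled/0=not). 0 denotes an unknown parent.

_SEX_IN = {"1": "male", "2": "female", "0": "unknown"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


def read_pedigree(path: str | Path) -> Pedigree:
    individuals = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 6:
            raise ParseError(f"expected 6 columns, got {len(fields)}", lineno)
        family, ind_id, father, mother, sex, status = fields
        if sex not in _SEX_IN:
            raise ParseError(f"bad sex code {sex!r}", lineno)
        if status not in ("0", "1"):
            raise ParseError(f"bad sampled status {status!r}", lineno)
        individuals.append(
            Individual(ind_id, father, mother, _SEX_IN[sex], status == "1", family)
        )
    return Pedigree(individuals)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    lines = [
        "\t".join(
            [
                ind.family,
                ind.id,
                ind.father,
                ind.mother,
                _SEX_OUT[ind.sex],
                "1" if ind.sampled else "0",
            ]
        )
        for ind in sorted(ped, key=lambda i: (i.family, i.id))
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
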