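"""Synthetic data with the statistical structure the analysis assumes.

Provides seeded generators for: matrilineal Wright-Fisher drift of motif
lineages (with bottlenecks), admixed modern samples, three-generation
pedigrees with shared matrilines, ancient two-fragment reads with
strand-specific phantom artifacts, and the bundled worked-example panels.
All outputs are deterministic functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    FRAGMENT_1,
    FRAGMENT_2,
    FragmentRead,
    HaplotypeMotif,
    InputError,
    ReferenceWindow,
    SampleRecord,
    hvsi_window,
    motif_to_sequence,
    reference_window,
)
from .matriline import Individual, Pedigree
from . import panels

__all__ = [
    "SimParams",
    "TruthRecord",
    "SimulationError",
    "simulate_matrilineal_population",
    "simulate_admixed_samples",
    "simulate_pedigree",
    "simulate_ancient_samples",
    "AncientTooth",
    "make_paper_fixtures",
    "rural_admixed_params",
    "NON_AMERINDIAN_MOTIFS",
]


class SimulationError(RuntimeError):
    pass


#: cosmopolitan (non-Amerindian) motif pool; chosen so that none satisfies
#: the default Amerindian motif rules, keeping synthetic truth unambiguous.
NON_AMERINDIAN_MOTIFS: dict[str, list[str]] = {
    "H": [],
    "U5": ["16270T"],
    "J": ["16069T", "16126C"],
    "L2": ["16223T", "16278T"],
}


@dataclass(frozen=True)
class SimParams:
    """Scenario parameters; ``seed`` is mandatory for every generator."""

    founder_motifs: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            hg: tuple(m.tokens()) for hg, m in panels.founder_motifs().items()
        }
    )
    founder_frequencies: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25}
    )
    mutation_rate: float = 1e-4  # per site per generation
    ts_tv_bias: float = 20.0
    generations: int = 20
    size_trajectory: tuple[int, ...] | None = None  # overrides constant size
    population_size: int = 200
    bottleneck: tuple[int, int, int] | None = None  # (start gen, length, depth)
    admixture_fraction: float = 0.27
    sample_size: int = 74
    n_families: int = 74
    sibship_size: int = 3
    phantom_rate: float = 0.0  # per-position per-strand
    fragment_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        freq = sum(self.founder_frequencies.values())
        if abs(freq - 1.0) > 1e-9:
            raise InputError(f"founder frequencies sum to {freq}, not 1")
        for name in ("mutation_rate", "phantom_rate", "fragment_dropout"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if not 0.0 <= self.admixture_fraction <= 1.0:
            raise InputError("admixture fraction must lie in [0, 1]")

    def trajectory(self) -> list[int]:
        if self.size_trajectory is not None:
            sizes = list(self.size_trajectory)
        else:
            sizes = [self.population_size] * (self.generations + 1)
        if self.bottleneck is not None:
            start, length, depth = self.bottleneck
            for g in range(start, min(start + length, len(sizes))):
                sizes[g] = depth
        if any(s <= 0 for s in sizes):
            raise SimulationError("size trajectory hits zero: lineage pool extinct")
        return sizes


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    haplogroup: str
    motif_tokens: tuple[str, ...]
    matriline: str | None = None
    contaminated: bool = False


def _toggle(
    tokens: frozenset[str],
    window: ReferenceWindow,
    derived_at: dict[int, str],
    rng: np.random.Generator,
    ts_tv_bias: float,
) -> frozenset[str]:
    pos = int(rng.integers(window.start, window.end + 1))
    ref = window.base_at(pos)
    if pos in derived_at:
        alt = derived_at[pos]
    else:
        transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
        if rng.random() < ts_tv_bias / (ts_tv_bias + 1.0):
            alt = transitions[ref]
        else:
            alt = str(rng.choice([b for b in "ACGT" if b != ref and b != transitions[ref]]))
        derived_at[pos] = alt
    token = f"{pos}{alt}"
    return tokens - {token} if token in tokens else tokens | {token}


def simulate_matrilineal_population(
    params: SimParams, seed: int | None = None
) -> tuple[list[SampleRecord], list[TruthRecord]]:
    """Wright-Fisher matrilineal copying of motif lineages.

    Each generation every lineage copies a uniformly chosen mother from the
    previous generation; per-site mutations toggle binary states off the
    founder motifs (the derived allele at a site is fixed at first hit, so
    sites stay biallelic within a run).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    window = hvsi_window()
    sizes = params.trajectory()
    hgs = sorted(params.founder_frequencies)
    probs = np.array([params.founder_frequencies[h] for h in hgs])

    derived_at: dict[int, str] = {}
    for hg in hgs:
        for t in params.founder_motifs.get(hg, ()):
            pos = int(t[:-1])
            derived_at[pos] = t[-1]

    pool_hg = [hgs[i] for i in rng.choice(len(hgs), size=sizes[0], p=probs)]
    pool = [frozenset(params.founder_motifs.get(h, ())) for h in pool_hg]
    L = len(window)
    for size in sizes[1:]:
        parents = rng.integers(0, len(pool), size=size)
        new_pool = []
        new_hg = []
        for p in parents:
            tokens = pool[p]
            for _ in range(rng.binomial(L, params.mutation_rate)):
                tokens = _toggle(tokens, window, derived_at, rng, params.ts_tv_bias)
            new_pool.append(tokens)
            new_hg.append(pool_hg[p])
        pool, pool_hg = new_pool, new_hg

    k = min(params.sample_size, len(pool))
    chosen = rng.choice(len(pool), size=k, replace=False)
    records, truth = [], []
    for i, idx in enumerate(sorted(chosen)):
        sid = f"SIM{i:04d}"
        motif = HaplotypeMotif.from_tokens(sorted(pool[idx]), window, sid)
        records.append(SampleRecord(sid, "SIM", motif, 1))
        truth.append(TruthRecord(sid, pool_hg[idx], motif.tokens()))
    return records, truth


def simulate_admixed_samples(
    amerindian_pool: Sequence[tuple[str, Sequence[str]]],
    non_amerindian_pool: Sequence[tuple[str, Sequence[str]]],
    fraction: float,
    n: int,
    seed: int,
    population: str = "RURAL",
) -> tuple[list[SampleRecord], list[TruthRecord]]:
    """Draw each sample from the Amerindian pool with probability
    ``fraction``, else from the non-Amerindian pool."""
    if not amerindian_pool or not non_amerindian_pool:
        raise InputError("both motif pools must be non-empty")
    if not 0.0 <= fraction <= 1.0:
        raise InputError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    window = hvsi_window()
    records, truth = [], []
    for i in range(n):
        sid = f"{population}{i:04d}"
        if rng.random() < fraction:
            hg, tokens = amerindian_pool[int(rng.integers(len(amerindian_pool)))]
        else:
            hg, tokens = non_amerindian_pool[int(rng.integers(len(non_amerindian_pool)))]
        motif = HaplotypeMotif.from_tokens(tokens, window, sid)
        records.append(SampleRecord(sid, population, motif, 1))
        truth.append(TruthRecord(sid, hg, motif.tokens()))
    return records, truth


def simulate_pedigree(
    params: SimParams,
    seed: int | None = None,
    n_sampled: int | None = None,
    motif_pool: Sequence[tuple[str, Sequence[str]]] | None = None,
) -> tuple[Pedigree, list[SampleRecord], list[TruthRecord]]:
    """Three-generation families with known matriline truth.

    Every matrilineal descendant of a founder female carries her motif.
    ``n_sampled`` individuals are drawn (at least one per family, the rest
    over-drawn within matrilines to exercise deduplication).
    """
    if params.n_families < 1:
        raise InputError("families >= 1 required")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    window = hvsi_window()
    if motif_pool is None:
        motif_pool = [
            (hg, tokens) for hg, tokens in sorted(params.founder_motifs.items())
        ]
    individuals: list[Individual] = []
    matriline_members: dict[str, list[str]] = {}
    founder_motif: dict[str, tuple[str, Sequence[str]]] = {}

    for f in range(params.n_families):
        fam = f"F{f:03d}"
        founder = f"{fam}-G1-M"
        spouse = f"{fam}-G1-F"
        hg, tokens = motif_pool[int(rng.integers(len(motif_pool)))]
        founder_motif[founder] = (hg, tokens)
        individuals.append(Individual(founder, sex="female", family=fam))
        individuals.append(Individual(spouse, sex="male", family=fam))
        members = [founder]
        for c in range(params.sibship_size):
            child = f"{fam}-G2-{c}"
            sex = "female" if rng.random() < 0.5 else "male"
            individuals.append(Individual(child, father=spouse, mother=founder, sex=sex, family=fam))
            members.append(child)
            if sex == "female":
                partner = f"{fam}-G2-{c}-P"
                individuals.append(Individual(partner, sex="male", family=fam))
                for g in range(params.sibship_size):
                    gc = f"{fam}-G3-{c}-{g}"
                    individuals.append(
                        Individual(
                            gc,
                            father=partner,
                            mother=child,
                            sex="female" if rng.random() < 0.5 else "male",
                            family=fam,
                        )
                    )
                    members.append(gc)
        matriline_members[founder] = members

    total = n_sampled if n_sampled is not None else params.sample_size
    if total < params.n_families:
        raise InputError("n_sampled must be >= number of families")
    sampled: list[str] = []
    for founder, members in sorted(matriline_members.items()):
        sampled.append(members[int(rng.integers(len(members)))])
    extra_pool = sorted(
        set(m for members in matriline_members.values() for m in members) - set(sampled)
    )
    extra = rng.choice(len(extra_pool), size=total - len(sampled), replace=False)
    sampled.extend(extra_pool[i] for i in sorted(extra))

    sampled_set = set(sampled)
    individuals = [
        replace(ind, sampled=ind.id in sampled_set) for ind in individuals
    ]
    ped = Pedigree(individuals)

    member_founder = {
        m: founder for founder, members in matriline_members.items() for m in members
    }
    records, truth = [], []
    for sid in sorted(sampled_set):
        founder = member_founder[sid]
        hg, tokens = founder_motif[founder]
        motif = HaplotypeMotif.from_tokens(tokens, window, sid)
        records.append(SampleRecord(sid, "PED", motif, 1))
        truth.append(TruthRecord(sid, hg, motif.tokens(), matriline=founder))
    return ped, records, truth


@dataclass(frozen=True)
class AncientTooth:
    sample_id: str
    reads: tuple[FragmentRead, ...]
    true_tokens: tuple[str, ...]
    phantoms: Mapping[str, frozenset[str]]  # strand -> phantom tokens


def simulate_ancient_samples(
    source_motifs: Sequence[tuple[str, Sequence[str]]],
    params: SimParams,
    seed: int | None = None,
) -> list[AncientTooth]:
    """Per tooth: the two standard overlapping amplicons on each strand,
    with optional fragment dropout and per-strand phantom variants (never
    injected on both strands)."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    full = reference_window()
    teeth = []
    for label, tokens in source_motifs:
        motif = HaplotypeMotif.from_tokens(tokens, full, label)
        true_seq = motif_to_sequence(motif)
        fragments = [FRAGMENT_1]
        if rng.random() >= params.fragment_dropout:
            fragments.append(FRAGMENT_2)
        reads = []
        phantoms: dict[str, frozenset[str]] = {}
        used_positions: set[int] = set()
        for strand in ("forward", "reverse"):
            covered = sorted(
                {p for s, e in fragments for p in range(s, e + 1)}
            )
            eligible = [p for p in covered if p not in used_positions]
            k = rng.binomial(len(eligible), params.phantom_rate)
            hit = sorted(
                eligible[i] for i in rng.choice(len(eligible), size=k, replace=False)
            ) if k else []
            used_positions.update(hit)
            strand_seq = list(true_seq)
            tok = set()
            for pos in hit:
                old = strand_seq[pos - full.start]
                new = str(rng.choice([b for b in "ACGT" if b != old]))
                strand_seq[pos - full.start] = new
                tok.add(f"{pos}{new}")
            phantoms[strand] = frozenset(tok)
            seq = "".join(strand_seq)
            for s, e in fragments:
                reads.append(
                    FragmentRead(s, e, seq[s - full.start : e - full.start + 1], strand)
                )
        teeth.append(
            AncientTooth(label, tuple(reads), tuple(sorted(tokens)), phantoms)
        )
    return teeth


def rural_admixed_params(seed: int = 0) -> SimParams:
    """Named scenario mirroring the worked example: ~27% Amerindian
    matrilineages, C-skewed founders, 74 matrilines sampled as 173."""
    return SimParams(
        founder_frequencies={"A": 0.0, "B": 0.2, "C": 0.7, "D": 0.1},
        admixture_fraction=0.27,
        sample_size=173,
        n_families=74,
        generations=15,
        population_size=120,
        seed=seed,
    )


def make_paper_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Materialise the bundled worked-example panels (acceptance inputs)."""
    return panels.write_panel_files(outdir)
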