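"""Population statistics: diversity estimators, contingency tests and the
exact test of population differentiation.

Gene diversity uses the unbiased estimator H = n(1 - sum p_i^2)/(n - 1)
with Nei's sampling variance; nucleotide diversity uses the n/(n-1)
pairwise estimator with the Nei/Tajima total variance.  Differentiation is
tested by Pearson chi-square, by a fixed-margin Monte-Carlo chi-square, and
by an exact (conditional multivariate hypergeometric) test computed either
by full enumeration or by Markov-chain Monte Carlo.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import InputError, SampleRecord

__all__ = [
    "FrequencySpectrum",
    "DiversityEstimate",
    "ContingencyTable",
    "DifferentiationResult",
    "gene_diversity",
    "nucleotide_diversity",
    "pairwise_differences",
    "haplogroup_table",
    "pearson_chi2",
    "mc_chi2_pvalue",
    "exact_differentiation_test",
]


@dataclass(frozen=True)
class FrequencySpectrum:
    """Category (haplotype or haplogroup) counts within one population."""

    population: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for k, v in self.counts.items():
            if v < 0:
                raise InputError(f"negative count for {k!r}")
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_records(cls, records: Sequence[SampleRecord], population: str | None = None):
        recs = [r for r in records if population is None or r.population == population]
        counts: dict[str, int] = {}
        for r in recs:
            counts[r.id] = counts.get(r.id, 0) + r.count
        pop = population or (recs[0].population if recs else "")
        return cls(pop, counts)


@dataclass(frozen=True)
class DiversityEstimate:
    value: float
    sd: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if self.value < 0 or self.sd < 0:
            raise InputError("diversity and its sd must be non-negative")


@dataclass(frozen=True)
class ContingencyTable:
    rows: tuple[str, ...]
    cols: tuple[str, ...]
    values: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        for row in self.values:
            if len(row) != len(self.cols):
                raise InputError("ragged contingency table")
            if any(v < 0 for v in row):
                raise InputError("negative cell")

    @classmethod
    def from_spectra(cls, spectra: Sequence[FrequencySpectrum]) -> "ContingencyTable":
        cols = tuple(sorted(set(itertools.chain.from_iterable(s.counts for s in spectra))))
        values = tuple(
            tuple(s.counts.get(c, 0) for c in cols) for s in spectra
        )
        return cls(tuple(s.population for s in spectra), cols, values)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_array(), index=list(self.rows), columns=list(self.cols))


@dataclass(frozen=True)
class DifferentiationResult:
    statistic: float
    p_value: float
    method: str
    replicates: int | None = None
    seed: int | None = None
    details: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise InputError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# diversity


def gene_diversity(spectrum: FrequencySpectrum) -> DiversityEstimate:
    """Unbiased gene (haplotype) diversity with Nei's sampling variance."""
    n = spectrum.n
    if n < 2:
        raise InputError(f"gene diversity undefined for n={n}")
    p = np.array([c for c in spectrum.counts.values() if c > 0], dtype=float) / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    h = n * (1.0 - s2) / (n - 1)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2
    )
    return DiversityEstimate(h, math.sqrt(max(var, 0.0)), n, "nei-unbiased")


def pairwise_differences(a: SampleRecord, b: SampleRecord) -> int:
    """Number of differing sites over the jointly covered positions,
    poly-C length variants excluded."""
    for r in (a, b):
        if not r.resolved:
            raise InputError(f"unresolved motif: {r.id}")
    shared = a.covered_positions() & b.covered_positions()
    ta = {v.position: v.alt for v in a.motif.without_length_variants().variants}
    tb = {v.position: v.alt for v in b.motif.without_length_variants().variants}
    return sum(
        1
        for pos in set(ta) | set(tb)
        if pos in shared and ta.get(pos) != tb.get(pos)
    )


def nucleotide_diversity(
    records: Sequence[SampleRecord], window_length: int | None = None
) -> DiversityEstimate:
    """Per-site nucleotide diversity over resolved records with counts.

    pi = [n/(n-1)] * sum_ij p_i p_j d_ij / L.  Unresolved records must be
    excluded by the caller; passing one is an error (listed by label).
    """
    unresolved = [r.id for r in records if not r.resolved]
    if unresolved:
        raise InputError(f"unresolved motifs must be excluded: {unresolved}")
    if not records:
        raise InputError("no records")
    n = sum(r.count for r in records)
    if n < 2:
        raise InputError(f"nucleotide diversity undefined for n={n}")
    L = window_length or len(records[0].motif.window)
    if L <= 0:
        raise InputError("window length must be positive")

    total = 0.0
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            total += 2.0 * (a.count / n) * (b.count / n) * pairwise_differences(a, b)
    pi = (n / (n - 1)) * total / L
    # Nei/Tajima total variance of the per-site estimate.
    var = ((n + 1) / (3.0 * (n - 1))) * pi / L + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    return DiversityEstimate(pi, math.sqrt(max(var, 0.0)), n, "nei-tajima")


# ---------------------------------------------------------------------------
# haplogroup tables


def haplogroup_table(
    calls_by_population: Mapping[str, Sequence[tuple[str, int]]]
) -> tuple[ContingencyTable, pd.DataFrame]:
    """Count-weighted haplogroup table plus a percentage report (1 decimal)."""
    cols = tuple(
        sorted(set(lab for calls in calls_by_population.values() for lab, _ in calls))
    )
    rows = tuple(calls_by_population)
    values = []
    for pop in rows:
        counts: dict[str, int] = {}
        for label, count in calls_by_population[pop]:
            counts[label] = counts.get(label, 0) + count
        values.append(tuple(counts.get(c, 0) for c in cols))
    table = ContingencyTable(rows, cols, tuple(values))
    arr = table.to_array()
    totals = arr.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.round(100.0 * arr / totals, 1)
    report = pd.DataFrame(pct, index=list(rows), columns=list(cols))
    return table, report


# ---------------------------------------------------------------------------
# chi-square tests


def pearson_chi2(table: ContingencyTable) -> tuple[float, np.ndarray]:
    """Pearson chi-square with fixed-margin expectations; returns the
    statistic and the per-cell contributions (audit trail)."""
    obs = table.to_array()
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        raise InputError("degenerate table: zero row or column margin")
    expected = np.outer(row_sums, col_sums) / obs.sum()
    contrib = (obs - expected) ** 2 / expected
    return float(contrib.sum()), contrib


def _random_fixed_margin_table(
    rng: np.random.Generator, row_sums: np.ndarray, col_sums: np.ndarray
) -> np.ndarray:
    labels = np.repeat(np.arange(len(col_sums)), col_sums)
    rng.shuffle(labels)
    out = np.zeros((len(row_sums), len(col_sums)))
    start = 0
    for i, r in enumerate(row_sums):
        chunk = labels[start : start + int(r)]
        out[i] = np.bincount(chunk, minlength=len(col_sums))
        start += int(r)
    return out


def mc_chi2_pvalue(
    table: ContingencyTable, replicates: int = 10_000, seed: int | None = None
) -> DifferentiationResult:
    """Monte-Carlo chi-square p-value under fixed margins (permutation of
    category labels), with the +1 correction so p is never reported as 0."""
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    if seed is None:
        raise InputError("seed required for Monte-Carlo test")
    observed, _ = pearson_chi2(table)
    obs = table.to_array()
    row_sums = obs.sum(axis=1).astype(int)
    col_sums = obs.sum(axis=0).astype(int)
    total = obs.sum()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(replicates):
        sim = _random_fixed_margin_table(rng, row_sums, col_sums)
        expected = np.outer(row_sums, col_sums) / total
        stat = float(((sim - expected) ** 2 / expected).sum())
        if stat >= observed - 1e-12:
            hits += 1
    p = (1 + hits) / (replicates + 1)
    return DifferentiationResult(observed, p, "mc-chi2", replicates=replicates, seed=seed)


# ---------------------------------------------------------------------------
# exact test of population differentiation (Raymond-Rousset style)


def _log_table_prob(x1: np.ndarray, col_sums: np.ndarray, n: int, n1: int) -> float:
    # P(table | margins) = prod_j C(c_j, x1j) / C(n, n1)
    log_c = gammaln(col_sums + 1) - gammaln(x1 + 1) - gammaln(col_sums - x1 + 1)
    return float(log_c.sum() - (gammaln(n + 1) - gammaln(n1 + 1) - gammaln(n - n1 + 1)))


def _enumerate_tables(col_sums: np.ndarray, n1: int):
    """Yield every admissible first-row vector x1 with sum n1, 0<=x1<=c."""
    k = len(col_sums)

    def rec(j: int, remaining: int, prefix: tuple[int, ...]):
        if j == k - 1:
            if 0 <= remaining <= col_sums[j]:
                yield prefix + (remaining,)
            return
        tail_cap = int(col_sums[j + 1 :].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(int(col_sums[j]), remaining)
        for x in range(lo, hi + 1):
            yield from rec(j + 1, remaining - x, prefix + (x,))

    yield from rec(0, n1, ())


def _state_space_size(col_sums: np.ndarray, n1: int) -> int:
    # DP count of admissible first rows (cheap; bounds the enumeration).
    counts = {0: 1}
    for c in col_sums:
        nxt: dict[int, int] = {}
        for s, m in counts.items():
            for x in range(0, int(c) + 1):
                if s + x <= n1:
                    nxt[s + x] = nxt.get(s + x, 0) + m
        counts = nxt
    return counts.get(n1, 0)


def exact_differentiation_test(
    spec_a: FrequencySpectrum,
    spec_b: FrequencySpectrum,
    *,
    max_enumeration: int = 200_000,
    burn_in: int = 10_000,
    steps: int = 100_000,
    seed: int | None = None,
) -> DifferentiationResult:
    """Exact test of haplotype-frequency differentiation between two samples.

    Conditional on the margins, the p-value is the total probability of
    tables no more probable than the observed one under the multivariate
    hypergeometric null.  Full enumeration is used while the state space is
    within ``max_enumeration``; otherwise a Metropolis Markov chain over
    two-column +/-1 moves is run (burn-in, step count and seed recorded).
    """
    if spec_a.n == 0 or spec_b.n == 0:
        raise InputError("both populations must be non-empty")
    cats = sorted(set(spec_a.counts) | set(spec_b.counts))
    x1 = np.array([spec_a.counts.get(c, 0) for c in cats], dtype=int)
    x2 = np.array([spec_b.counts.get(c, 0) for c in cats], dtype=int)
    col_sums = x1 + x2
    keep = col_sums > 0
    x1, col_sums = x1[keep], col_sums[keep]
    n1, n = int(x1.sum()), int(col_sums.sum())
    log_p_obs = _log_table_prob(x1, col_sums, n, n1)

    size = _state_space_size(col_sums, n1)
    if size <= max_enumeration:
        total = 0.0
        for row in _enumerate_tables(col_sums, n1):
            lp = _log_table_prob(np.array(row), col_sums, n, n1)
            if lp <= log_p_obs + 1e-9:
                total += math.exp(lp)
        return DifferentiationResult(
            math.exp(log_p_obs),
            min(total, 1.0),
            "exact-rr",
            details={"mode": "enumeration", "state_space": size},
        )

    if seed is None:
        raise InputError("seed required for MCMC exact test")
    rng = np.random.default_rng(seed)
    x = x1.copy()
    k = len(col_sums)
    lf = gammaln(np.arange(n + 2) + 1.0)  # lf[m] = log(m!)

    def log_choose(c: int, m: int) -> float:
        return lf[c] - lf[m] - lf[c - m]

    hits = 0
    kept = 0
    log_p = log_p_obs
    pairs = rng.integers(0, k, size=(burn_in + steps, 2))
    uniforms = rng.random(burn_in + steps)
    for step in range(burn_in + steps):
        i, j = pairs[step]
        # move one individual of category i from row 1 to row 2 and one of
        # category j the other way; Metropolis on the conditional law
        if i != j and x[i] > 0 and x[j] < col_sums[j]:
            delta = (
                log_choose(col_sums[i], x[i] - 1)
                - log_choose(col_sums[i], x[i])
                + log_choose(col_sums[j], x[j] + 1)
                - log_choose(col_sums[j], x[j])
            )
            if math.log(uniforms[step]) < delta:
                x[i] -= 1
                x[j] += 1
                log_p += delta
        if step % 4096 == 0:  # cancel accumulated float drift
            log_p = _log_table_prob(x, col_sums, n, n1)
        if step >= burn_in:
            kept += 1
            if log_p <= log_p_obs + 1e-9:
                hits += 1
    return DifferentiationResult(
        math.exp(log_p_obs),
        hits / kept,
        "exact-rr",
        replicates=steps,
        seed=seed,
        details={"mode": "mcmc", "burn_in": burn_in},
    )
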