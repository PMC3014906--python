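import numpy as np
import pytest

from mtlineage import panels
from mtlineage.core import HaplotypeMotif, SampleRecord, hvsi_window


@pytest.fixture(scope="session")
def window():
    return hvsi_window()


@pytest.fixture(scope="session")
def queix():
    return panels.queix_records()


@pytest.fixture(scope="session")
def botocudo():
    return panels.botocudo_records()


@pytest.fixture(scope="session")
def botocudo_resolved(botocudo):
    return [r for r in botocudo if r.resolved]


@pytest.fixture(scope="session")
def founder_c(window):
    return HaplotypeMotif.from_tokens(
        ["16223T", "16298C", "16325C", "16327T"], window, "founder-C"
    )


def random_motif(rng: np.random.Generator, window, n_variants: int, label=None):
    """Random substitution-only motif used by round-trip and network tests."""
    positions = rng.choice(len(window), size=n_variants, replace=False)
    tokens = []
    for off in sorted(int(p) for p in positions):
        pos = window.start + off
        ref = window.base_at(pos)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        tokens.append(f"{pos}{alt}")
    return HaplotypeMotif.from_tokens(tokens, window, label)


@pytest.fixture(scope="session")
def make_random_motif():
    return random_motif


def as_record(motif, label=None, population="TEST", count=1, covered=None):
    return SampleRecord(label or motif.label or "X", population, motif, count, covered)


@pytest.fixture(scope="session")
def make_record():
    return as_record
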