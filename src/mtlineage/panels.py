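"""Bundled worked-example haplotype panels.

Three small published-style panels are shipped as in-memory data and can be
materialised to the standard TSV dialect:

* ``QUEIX`` — 13 Amerindian HVSI haplotypes (20 samples) from a rural
  community screen;
* ``BOT`` — 6 haplotypes (14 samples) typed from 19th-century teeth, two of
  them with withheld sequences (unresolved motifs);
* ``MGNE`` — haplogroup counts for the cosmopolitan control sample.

These are the canonical inputs of the example analysis and of the
acceptance checks.
"""

from __future__ import annotations

from pathlib import Path

from .core import (
    DEFAULT_HVSI,
    HaplotypeMotif,
    SampleRecord,
    hvsi_window,
    write_haplotype_table,
)

__all__ = [
    "queix_records",
    "botocudo_records",
    "mgne_haplogroup_counts",
    "figure_c_records",
    "novelty_database_records",
    "founder_motifs",
    "write_panel_files",
]

_QUEIX_ROWS = [
    ("MG18", 1, ["16178C", "16189C", "16217C"]),
    ("MG22", 1, ["16178C", "16189C", "16217C", "16223T"]),
    ("MG23", 1, ["16111T", "16178C", "16189C", "16217C"]),
    ("MG24", 1, ["16117C", "16178C", "16189C", "16217C"]),
    ("MG28", 1, ["16223T", "16298C", "16325C", "16327T", "16362C"]),
    ("MG30", 3, ["16051G", "16217C", "16223T", "16287T", "16298C", "16325C", "16327T"]),
    ("MG31", 1, ["16051G", "16172C", "16223T", "16295T", "16298C", "16325C", "16327T", "16335G"]),
    ("MG32", 2, ["16126C", "16223T", "16298C", "16325C", "16327T"]),
    ("MG33", 5, ["16166G", "16223T", "16224C", "16260T", "16298C", "16325C", "16327T", "16356C"]),
    ("MG34", 1, ["16113C", "16223T", "16295T", "16298C", "16311C", "16325C"]),
    ("MG36", 1, ["16223T", "16325C", "16327T"]),
    ("MG37", 1, ["16223T", "16325C", "16362C"]),
    ("MG39", 1, ["16153A", "16213A", "16223T", "16278T", "16311C", "16362C"]),
]

_BOT_ROWS = [
    ("Bot01", 3, ["16223T", "16298C", "16325C", "16327T"]),
    ("Bot02", 1, ["16129A", "16223T", "16298C", "16325C", "16327T"]),
    ("Bot03", 4, ["16051G", "16223T", "16298C", "16325C", "16327T"]),
    ("Bot04", 4, ["16051G", "16172C", "16223T", "16295T", "16298C", "16325C", "16327T", "16335G"]),
    ("Bot05", 1, None),  # sequence withheld
    ("Bot06", 1, None),  # sequence withheld
]

#: cosmopolitan control: Amerindian haplogroup counts (24 of 100 lineages).
_MGNE_COUNTS = {"A": 9, "B": 7, "C": 4, "D": 4}

#: founder HVSI motifs of the major Native American haplogroups.
_FOUNDERS = {
    "B": ["16189C", "16217C"],
    "C": ["16223T", "16298C", "16325C", "16327T"],
    "D": ["16223T", "16325C", "16362C"],
    "A": ["16111T", "16223T", "16290T", "16319A", "16362C"],
}


def _records(rows, population: str) -> list[SampleRecord]:
    window = hvsi_window()
    out = []
    for label, count, tokens in rows:
        motif = None if tokens is None else HaplotypeMotif.from_tokens(tokens, window, label)
        out.append(SampleRecord(label, population, motif, count))
    return out


def queix_records() -> list[SampleRecord]:
    """The 13 rural-community Amerindian haplotypes (n=20)."""
    return _records(_QUEIX_ROWS, "QUEIX")


def botocudo_records() -> list[SampleRecord]:
    """The 6 ancient-teeth haplotypes (n=14, two unresolved)."""
    return _records(_BOT_ROWS, "BOT")


def mgne_haplogroup_counts() -> dict[str, int]:
    return dict(_MGNE_COUNTS)


def founder_motifs() -> dict[str, HaplotypeMotif]:
    window = hvsi_window()
    return {
        hg: HaplotypeMotif.from_tokens(tokens, window, f"founder-{hg}")
        for hg, tokens in _FOUNDERS.items()
    }


def figure_c_records() -> list[SampleRecord]:
    """The haplogroup-C motif set used for the example network.

    The seven rural C haplotypes plus two cosmopolitan founder-derived
    lineages (MG27 = founder C, MG29 = founder C + 16311C).
    """
    window = hvsi_window()
    queix_c = [r for r in queix_records() if r.id in
               {"MG28", "MG30", "MG31", "MG32", "MG33", "MG34", "MG36"}]
    extra = [
        SampleRecord("MG27", "MGNE",
                     HaplotypeMotif.from_tokens(_FOUNDERS["C"], window, "MG27"), 1),
        SampleRecord("MG29", "MGNE",
                     HaplotypeMotif.from_tokens(_FOUNDERS["C"] + ["16311C"], window, "MG29"), 1),
    ]
    return queix_c + extra


def novelty_database_records() -> list[SampleRecord]:
    """Reference-database stand-in reproducing the worked example's
    found/novel pattern: founder motifs plus the four rural lineages known
    from the literature (MG28/MG32/MG36/MG37 types) and the Bot02 type."""
    window = hvsi_window()
    rows = [
        ("REF-B-founder", _FOUNDERS["B"]),
        ("REF-C-founder", _FOUNDERS["C"]),
        ("REF-D-founder", _FOUNDERS["D"]),
        ("REF-A-founder", _FOUNDERS["A"]),
        ("REF-MG28-type", ["16223T", "16298C", "16325C", "16327T", "16362C"]),
        ("REF-MG32-type", ["16126C", "16223T", "16298C", "16325C", "16327T"]),
        ("REF-MG36-type", ["16223T", "16325C", "16327T"]),
        ("REF-Bot02-type", ["16129A", "16223T", "16298C", "16325C", "16327T"]),
    ]
    return [
        SampleRecord(label, "DB", HaplotypeMotif.from_tokens(tokens, window, label), 1)
        for label, tokens in rows
    ]


def write_panel_files(outdir: str | Path) -> dict[str, Path]:
    """Materialise every bundled panel to TSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "queix": outdir / "queix_haplotypes.tsv",
        "botocudo": outdir / "botocudo_haplotypes.tsv",
        "figure_c": outdir / "figure_c_motifs.tsv",
        "novelty_db": outdir / "novelty_database.tsv",
        "mgne": outdir / "mgne_haplogroup_counts.tsv",
    }
    write_haplotype_table(queix_records(), paths["queix"])
    write_haplotype_table(botocudo_records(), paths["botocudo"])
    write_haplotype_table(figure_c_records(), paths["figure_c"])
    write_haplotype_table(novelty_database_records(), paths["novelty_db"])
    lines = ["haplogroup\tcount"] + [f"{k}\t{v}" for k, v in _MGNE_COUNTS.items()]
    paths["mgne"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    return paths
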