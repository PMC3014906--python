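# mtlineage

A toolkit for mitochondrial-DNA HVSI haplotype analysis of admixed
populations and degraded (ancient) samples:

* **core** — rCRS-anchored window handling, variant/motif calling
  (`16223T`-style tokens), FASTA and haplotype-table I/O, overlapping
  amplicon consensus, strand-concordance filtering of phantom mutations;
* **classify** — three-tier haplogroup assignment (HVSI motif rules, an
  RFLP coding-region marker panel, a minisequencing SNP panel resolving
  B2/C1/D1) with concordance-checked combined calls and an Amerindian
  lineage screen;
* **matriline** — matriline partitioning from three-generation pedigrees
  (PED-style TSV) and one-representative-per-matriline deduplication;
* **stats** — unbiased gene diversity with Nei's sampling variance,
  nucleotide diversity, haplogroup contingency tables, Pearson and
  fixed-margin Monte-Carlo chi-square, and an exact test of population
  differentiation (full enumeration or MCMC);
* **network** — minimum-spanning and median-joining haplotype networks
  with TSV/GML export;
* **matching** — exact haplotype matching over shared covered ranges,
  novelty screening against reference databases, contamination checks;
* **simulate** — seeded generators: matrilineal Wright-Fisher drift with
  bottlenecks, admixed samples, pedigrees, two-fragment ancient reads
  with strand-specific artifacts, plus the bundled worked-example panels;
* **cli** — `mtlineage` command with `classify | dedup | stats | network |
  match | simulate | run-all` subcommands, each writing a reproducibility
  manifest.

## CLI quick start

```sh
mtlineage simulate --scenario panels --out panels/   # bundled example data
mtlineage run-all \
    --records panels/queix_haplotypes.tsv \
    --compare panels/botocudo_haplotypes.tsv \
    --database panels/novelty_database.tsv \
    --seed 1 --out run/
cat run/summary.txt
```

`mtlineage simulate --seed 3 --out sim/` generates a synthetic rural
scenario (74 matrilines over-sampled as 173 individuals) whose pedigree
can be fed to `mtlineage dedup`.

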