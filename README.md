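# mitocompare

Comparative mitochondrial genome analysis for two-clade studies.

Sister clades can follow sharply different modes of mitogenome
evolution: one lineage may accumulate amino-acid substitutions quickly
while freezing its gene order, while its sister rearranges genes
freely but evolves slowly at the sequence level. The motivating system
is the wood-boring bivalve families Teredinidae (shallow-water
shipworms) and Xylophagaidae (deep-sea woodborers), whose circular
~14.5–18.6 kb mitogenomes carry 12 protein-coding genes, 22 tRNAs and
2 rRNAs on a single strand. `mitocompare` packages the analyses such
a study needs:

- **Gene-order rearrangement inference** on signed circular
  permutations: breakpoint distances, common intervals,
  single-event classification and parsimony scenarios over the CRex
  event vocabulary — transposition, reverse transposition, reversal,
  and tandem duplication–random loss (TDRL) — plus a
  parsimony-among-observed ancestral-order proposal.
- **Replication-origin prediction** from cumulative base-composition
  walks (GC and AT skew) combined with a scored scan for stable
  stem-loops with T-rich loops; OriH/OriL calls are localized to named
  intergenic regions (e.g. "cob–trnM IGR") or reported "ND".
- **Amino-acid supermatrix construction**: translation with the
  invertebrate mitochondrial code (NCBI table 5), Gblocks-default
  conserved-block selection, and partitioned concatenation.
- **Substitution-rate contrasts** as root-to-tip distances: for tip
  *i*, *d(i)* = Σ branch lengths on the path from the MRCA of the two
  focal clades to *i*; clade means are compared by Welch's *t*-test
  with Bonferroni adjustment, subclades by the Kruskal–Wallis *H*-test.
- **A synthetic-data generator** producing complete two-clade studies
  (genomes, annotations, alignments, trees, ground truth) with the
  statistical structure above planted and known exactly.

## Worked example

Simulate a study at the full geometry (26 + 16 taxa + 3 outgroup,
~4,135 supermatrix columns, 1.4-fold clade rate contrast) and test the
genome-property contrasts:

```python
from mitocompare import (SimulationConfig, simulate_study, root_to_tip_rates,
                         build_property_table, compare_families)

study = simulate_study(SimulationConfig(seed=42))
rates = root_to_tip_rates(study.estimated_tree_newick, study.clade_map,
                          ("Teredinidae", "Xylophagaidae"))
for clade, (mean, sd, n) in rates.per_clade.items():
    print(f"{clade:14s} {mean:.2f} +/- {sd:.2f} substitutions/site (n={n})")
table = build_property_table(study.records, rates=rates)
for res in compare_families(table):
    print(f"{res.property:11s} p_adj={res.p_adjusted:.2e} significant={res.significant}")
```

```
Teredinidae    2.17 +/- 0.14 substitutions/site (n=26)
Xylophagaidae  1.58 +/- 0.02 substitutions/site (n=16)
size_bp     p_adj=1.00e+00 significant=False
gc_percent  p_adj=5.54e-06 significant=True
rate        p_adj=5.14e-18 significant=True
```

The fast clade runs ~1.4× faster in substitutions/site; GC content and
rate separate the clades at adjusted *p* < 0.01 while genome size does
not — the qualitative pattern such two-family comparisons show.

The same stages are exposed on the command line:

```bash
mitocompare simulate --seed 42 --out study/
mitocompare ori study/genomes.fasta
mitocompare rates study/tree_estimated.nwk study/clades.tsv
mitocompare stats study/genomes.fasta study/clades.tsv --tree study/tree_estimated.nwk
```

Real data enter as GenBank flat files or FASTA plus a feature-table
TSV (`read_records`), with trees as rooted Newick.

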