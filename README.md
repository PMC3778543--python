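# pgsr — phage genome signature-based recovery

`pgsr` recovers phage sequences — in particular quiescent, integrated
prophage — from conventional whole-community metagenome assemblies, where
they are invisible to virus-like-particle (VLP) sequencing and hard to
separate from their host's chromosomal background by homology alone.

The approach exploits the *genome signature*: temperate phage ameliorate
toward the oligonucleotide composition of their hosts, so a phage genome
with a known host range (a **driver**) can pull compositionally similar
contigs — prophage of related phage, plus fragments of the host lineages
they infect — out of a mixed assembly. Functional evidence then separates
the two.

## The method

For each sequence (extended by its reverse complement), the tetranucleotide
usage profile (TUP) is the vector of 256 Z-scores measuring divergence of
observed tetranucleotide counts *O(w)* from a maximal-order Markov
expectation computed from the sequence's own tri- and dinucleotide counts.
For *w* = n₁n₂n₃n₄:

```
E(w)   = N(n₁n₂n₃) · N(n₂n₃n₄) / N(n₂n₃)
Var(w) = E(w) · [N(n₂n₃) − N(n₁n₂n₃)] · [N(n₂n₃) − N(n₂n₃n₄)] / N(n₂n₃)²
Z(w)   = (O(w) − E(w)) / √Var(w)
```

The pipeline then:

1. **screens** every contig ≥ 10 kb, retaining those whose TUP has Pearson
   correlation ≥ 0.6 with any driver signature;
2. **bins** retained contigs as `phage` (≥ 1 unambiguous phage-related gene,
   e.g. capsid / terminase / tail, or an ORF shared with a driver),
   `non_phage` (no phage gene, chromosomal housekeeping functions present),
   or `unclassified`;
3. **affiliates host taxonomy** from alignment hit tables (nucleotide level:
   top valid hit at ≥ 75% identity over ≥ 1 kb, e ≤ 1e−5; ORF level
   fallback: ≥ 2 ORFs agreeing at the order level);
4. builds **signature phylograms**: neighbor joining on Pearson
   dissimilarity (1 − r), with supports from 200 bootstrap resamplings of
   the 256 tetranucleotide columns;
5. **profiles abundance and habitat**: valid-hit counts normalized to hits
   per Mb, read recruitment under high (90% id / 90% of read) and low
   (70% id / 25% of read) stringency, and gut vs non-gut habitat categories
   (GT / NG / GAH / GAL / UNCLASS);
6. groups samples into **viral-enterotypes** by a two-pass heuristic over
   per-sample abundance profiles (Spearman similarity, 40%-incidence noise
   rule), validated with Bray–Curtis dissimilarity, non-metric MDS
   (Kruskal stress-1) and ANOSIM.

A first-class synthetic-community generator (order-3 Markov genus models,
planted prophages sharing host composition, fragmentation into ≥ 10 kb
contigs, planted enterotype cohorts) makes every stage testable without any
external data. See `docs/methods.md` for model details and design choices.

## Worked example

```bash
python examples/01_screen_community.py
```

screens a three-genus synthetic community (28 contigs, one driver per
genus) and prints, for every passing contig, its best driver correlation
and functional bin:

```
28 contigs screened against 3 drivers
  g2_chrom_c001            r=0.988 via g2_driver    -> non_phage (truth: non_phage)
  g2_chrom_c002            r=0.984 via g2_driver    -> phage     (truth: phage)
  ...
```

Every contig passes the 0.6 screen (prophage and host chromosome share
composition by construction — exactly the situation the method faces), and
binning cleanly separates the six planted prophage fragments from the
chromosomal background. `examples/02_signature_phylogram.py` prints a
bootstrap-annotated Newick tree in which two planted genera separate with
100% support, and `examples/03_viral_enterotypes.py` recovers a planted
4-group cohort with adjusted Rand index 1.0, ANOSIM R = 1.0 (p = 0.001)
and NMDS stress 0.046.

The same stages are available as a CLI:
`pgsr signature|screen|bin|phylo|profile|habitat|enterotype|simulate|run`
(e.g. `pgsr run --out-dir runs/demo --seed 1`).

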