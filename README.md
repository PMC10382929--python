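# minikaryo

Comparative analysis of fragmented mitochondrial (mt) genomes of the kind
found in sucking lice, where the genome is split across ~10–20 circular
**minichromosomes**, each carrying a short gene cluster and one large
non-coding region (NCR).

The package provides:

- **Karyotype model** (`minikaryo.model`) — a compact karyotype-string
  grammar (one minichromosome per line, genes joined by `-`, `~` for
  reverse orientation, `p` for pseudo genes, `#2` for duplicate copies,
  optional tab-separated size columns), a parser/serializer that
  round-trips byte-identically, the canonical 37-gene mitochondrial
  vocabulary, summary statistics, and packaged karyotype fixtures for two
  louse species plus two ancestral (MRCA) reconstructions.
- **Karyotype comparison** (`minikaryo.compare`) — identical-minichromosome
  detection, optimal ancestral↔derived chromosome matching by shared gene
  content, and merger-candidate flagging.
- **Recombination-event inference** (`minikaryo.recomb`) — parsimony
  classification of every gene occurrence on a branch (retained,
  translocated, duplicated, partially duplicated to a pseudo gene,
  degenerated in place, deleted, or merged), location anchors, per-anchor
  minimum-recombination-event lower bounds (distinct donor count), and
  hotspot tallies across branches.
- **Sequence evidence** (`minikaryo.stretch`) — global-alignment percent
  difference, longest shared identical stretch (with reverse-complement
  search and a Monte-Carlo chance null), and discovery of motifs exactly
  conserved across all NCRs.
- **Synthetic data** (`minikaryo.synth`) — a deterministic generator for
  minichromosomal genomes with planted AT-rich/GC-rich NCR motifs, a
  recombination-event applier with a replayable ground-truth log, and a
  paired-end read simulator (300 bp reads / 530 bp inserts by default).
- **Toy assembler** (`minikaryo.assembler`) — read filtering (>10% N or
  >50% bases at Q≤20 drops the pair), iterative seed-and-extend assembly
  of circular minichromosomes (minimum overlap 200 bp at 99% identity by
  default), shared-NCR consensus between two seed assemblies, and
  NCR-bait recovery of the remaining minichromosomes.

## CLI

```sh
minikaryo compare L_vituli L_africanus --out-dir out/
minikaryo infer-events --ancestral MRCA_Linognathus --derived L_africanus --out-dir out/
minikaryo hotspots out/events_*.json --out-dir out/
minikaryo run-all L_vituli L_africanus \
    --ancestral MRCA_Linognathus --stem-ancestral MRCA_Anoplura --out-dir out/
minikaryo simulate --seed 3 --coverage 30 --out-dir sim/
minikaryo assemble --reads-1 sim/reads_1.fastq --reads-2 sim/reads_2.fastq \
    --seed-fasta seeds.fasta --out-dir asm/
minikaryo stretches --fasta genes.fa --revcomp
minikaryo motifs --ncr-fasta ncrs.fa --min-len 20
```

Karyotype arguments accept either a packaged fixture name (`L_vituli`,
`L_africanus`, `MRCA_Anoplura`, `MRCA_Linognathus`) or a path to a
karyotype grammar file. Every published parameter default appears in the
`--help` text of the relevant subcommand.

## Notes

- The two species fixtures are transcribed verbatim from the published
  per-minichromosome tables; known internal discrepancies of those tables
  (per-row cluster+NCR vs total, and one printed column total) are
  preserved as-is. Size additivity is enforced only for synthetic genomes.
- The MRCA karyotypes are ancestral reconstructions; all algorithms treat
  them as swappable inputs, not constants.
- Per-gene percent differences depend on alignment parameters; the scoring
  scheme (match +1, mismatch −1, gap −2, gap columns count as differences)
  is declared in the function documentation and configurable.
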