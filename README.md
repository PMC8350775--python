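# mitoring

Structural analysis of circular (plant mitochondrial) genomes:

- **repeat_finder** — discovery of repeated sequence pairs (direct and
  inverted, circular-aware, nesting allowed), naming by descending size
  (R01…Rn) and cross-genome homology mapping;
- **assembly** — post-assembler logic: flagging repeat contigs in an overlap
  graph, circularizing contigs by terminal overlap or via a repeat, and
  merging circular chromosomes through recombination-like events at shared
  repeats;
- **isoform** — decomposition of genome pairs into shared blocks delimited by
  repeats, and a breadth-first search over recombination moves (inversion /
  fission / fusion) deciding whether two circles are structural isoforms,
  with a replayable move path or the irreducible differences;
- **plastid_insertions** — detection of plastid-derived insertions (MTPTs)
  with plastid-gene attribution and shared/variable classification across
  genomes (mutually exclusive variants at one locus are recognized);
- **rna_editing** — a transparent threshold caller for C-to-U editing sites
  from per-site base-count pileups, restricted to coding regions, with
  in-silico codon effects (start gain, stop gain in overlapping frames, …)
  and the m1A misincorporation diagnostic;
- **divergence** — concatenated-CDS extraction, global affine-gap pairwise
  alignment (anchored mode for long inputs), SNP/gap-event counting,
  conserved-position counting, p-distance matrices and neighbor-joining
  trees with newick output;
- **synthetic_data** — seeded generators for circular genomes with planted
  repeats, genes, plastid insertions and editing sites, isoform shuffles,
  terminal-overlap contigs and simulated pileups, all with machine-readable
  ground truth;
- **genome_io** — the circular-coordinate data model (0-based half-open,
  origin-spanning features) and FASTA / GFF3 / BED / pileup-TSV / newick IO.

## Command line

All subcommands write a JSON run manifest next to their outputs.

```bash
mitoring simulate --seed 42 -o sim/            # genome + GFF3 + truth + pileup
mitoring repeats sim/genome.fasta -o repeats.bed --min-len 50 --min-identity 0.99
mitoring circularize contig.fasta --min-overlap 1000
mitoring merge a.fasta b.fasta -o merged.fasta
mitoring isoform a.fasta b.fasta --min-repeat 500 --json verdict.json
mitoring cpinsert mt.fasta cp.fasta --cp-gff cp.gff3 -o inserts.bed
mitoring editing sim/genome.fasta sim/genome.gff3 sim/pileup.tsv -o sites.tsv
mitoring divergence --genes genes.txt --gff gffdir/ g1.fasta g2.fasta g3.fasta \
    -o table.tsv --tree out.nwk
mitoring tree g1.fasta g2.fasta g3.fasta -o tree.nwk
```

A converter from `samtools mpileup` text to the pileup TSV is provided as
plumbing in `scripts/sam_pileup_to_tsv.py`.

## Conventions

- Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) and
  reported positions convert only at file boundaries.
- Features spanning the circular origin are stored as `start > end` and
  written to GFF3 as two-part features sharing an `ID`.
- Repeat pairs are maximal, verified by direct sequence comparison, and named
  strictly by descending length; homologous repeats in other genomes inherit
  the reference names by reciprocal best match.
- Isoform equivalence is judged between single circles but the search may
  pass through multi-circle (subgenomic) intermediates; repeats under
  `--min-repeat` (default 500 bp) do not generate moves but are still
  reported by the structural diff.
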