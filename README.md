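# stemfuse

Toolkit for designing intron-targeting chimeric RNAs at complementary
"genomic stems" between two genes, and for modeling the gene fusions such
RNAs can drive:

- **stem discovery** — local alignment of one gene's intronic sense strand
  against the reverse complement of another's, per intron pair, yielding
  ranked imperfect complementary stems;
- **chimera design** — antisense (and matched sense) two-arm RNAs whose
  50-nt arms hybridize to intronic windows flanking a stem, forming a
  three-way junction; plus pol-III expression-cassette inserts with a
  `TTTTTT` terminator;
- **fusion modeling** — construction of the rearranged allele from intronic
  breakpoints (with untemplated insertions or microhomology), prediction of
  the spliced fusion transcript joining annotated exon boundaries, and the
  inverse problem: single-base breakpoint/insertion/microhomology inference
  from junction-spanning reads;
- **in-silico PCR** — pure sequence-matching amplicon prediction, nested
  (multi-round) schemes, and multiplex tiling primer design for scanning an
  unknown breakpoint across two introns;
- **synthetic data** — a deterministic generator of two-gene fixture genomes
  with planted stems, fusion events and junction reads, so the entire
  pipeline is testable offline.

Internally all coordinates are 0-based half-open; reports use 1-based
inclusive positions. BED exports follow the BED convention.

## Test

```sh
python -m pytest tests/
```

One acceptance test (`test_grch38_amplicon_sizes_from_printed_breakpoints`)
requires external reference sequence and a published primer list that are
not distributable with the repository; it fails with an explanatory message
unless `data/external/loci.fa`, `loci.json` and `primers.tsv` are provided.

## CLI

Everything is reachable through the `stemfuse` entry point:

```sh
# generate a synthetic two-gene genome (scaled-down preset) with truth record
stemfuse simulate --preset jazf1-suz12-like --scale 0.05 --seed 7 --out sim/

# discover complementary stems between the two genes' introns
stemfuse find-stems --genome sim/genome.fa --annotation sim/genes.gff3 \
    --gene-a geneA --gene-b geneB --min-identity 0.7 --min-length 20

# design antisense/sense chimera pairs (50-nt arms by default)
stemfuse design --genome sim/genome.fa --annotation sim/genes.gff3 \
    --gene-a geneA --gene-b geneB --arm-length 50 --offset 0 -o designs

# predict the fusion allele and spliced transcript for a breakpoint pair
stemfuse predict-transcript --genome sim/genome.fa --annotation sim/genes.gff3 \
    --gene-a geneA --gene-b geneB --breakpoint-a 1825 --breakpoint-b 132 -o pred

# infer breakpoints from junction-spanning reads
stemfuse infer-breakpoint --genome sim/genome.fa --annotation sim/genes.gff3 \
    --gene-a geneA --gene-b geneB --reads sim/reads.fa

# in-silico PCR, tiling design, breakpoint scan
stemfuse ispcr --template sim/genome.fa --primers primers.tsv --forward F --reverse R
stemfuse tile --genome sim/genome.fa --annotation sim/genes.gff3 \
    --gene-a geneA --gene-b geneB --intron-a 3 --intron-b 1 --n-forward 56 --n-reverse 10
stemfuse scan --genome sim/genome.fa --annotation sim/genes.gff3 \
    --gene-a geneA --gene-b geneB --allele sim/alleles.fa

# full pipeline from a YAML config (CLI flags override config values)
stemfuse run --config config.yaml --seed 7
```

A minimal pipeline config:

```yaml
outdir: out
seed: 7
simulate: {preset: jazf1-suz12-like, scale: 0.05}
pcr: {n_forward: 20, n_reverse: 4}
```

For real inputs replace `simulate:` with `genome:`, `annotation:`,
`gene_a:`, `gene_b:` paths/ids. Unknown config keys are rejected; the run
writes a `manifest.json` with SHA-256 provenance for every artifact, and the
whole run is deterministic under a fixed config and seed.

## Layout

- `src/stemfuse/genome_model.py` — FASTA/GFF3(GTF) I/O, intervals,
  strand-aware extraction, intron derivation
- `src/stemfuse/stem_finder.py` — intron-pair local alignment and stem ranking
- `src/stemfuse/chimera_design.py` — arm placement, antisense/sense duality,
  cassette building, batch design
- `src/stemfuse/fusion_model.py` — fusion allele/transcript construction and
  breakpoint inference
- `src/stemfuse/pcr_toolkit.py` — in-silico PCR, nested schemes, tiling, scans
- `src/stemfuse/synthetic_data.py` — deterministic fixture generator and presets
- `src/stemfuse/cli.py` — CLI and config-driven pipeline
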