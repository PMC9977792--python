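# tc1scout

Structure-based discovery and characterization of IS630/Tc1/mariner DNA
transposons. The pipeline calls an element on three pieces of evidence —
identical terminal inverted repeats (TIRs) at both ends, excision-site/TSD
symmetry on the flanks, and a transposase ORF carrying a DDE/DDD catalytic
triad — and then characterizes it: spacing-class nomenclature (DD34E,
DD40E, ...), frameshift repair of broken ORFs, full-length copy census
(strict >90% coverage rule), boundary inference from homolog
presence/absence groups, amino-acid composition profiling with PCC ranking
against a proteome, and neighbor-joining phylogeny of aligned domains.

A first-class synthetic-genome module plants elements with configurable TIR
length/identity, TA target-site duplication, D..D..D/E triads at chosen
spacings, inter-copy substitutions and indels, solo TIRs, truncated copies,
and frameshift-breaking insertions — with ground-truth annotations — so the
whole pipeline is testable offline.

## Layout

| module | role |
| --- | --- |
| `tc1scout.core_io` | FASTA/GFF3/BED/TSV I/O, 1-based inclusive coordinates, reverse complement |
| `tc1scout.synthetic_genome` | genomes with planted elements + truth records |
| `tc1scout.orf_tools` | ORF scan, translation, exact frameshift repair (DP) |
| `tc1scout.element_structure` | TIR detection, excision-site checks, five-segment layout, boundary inference |
| `tc1scout.copy_census` | seed-and-extend copy census, solo-TIR scan, copy-vs-copy divergence |
| `tc1scout.dde_motif` | DDE/DDD triad scan, spacing classes, aligned-domain identity/positives |
| `tc1scout.composition_profile` | composition vectors, PCC ranking, SR/SAP/PS/SP-rich labels |
| `tc1scout.phylo_nj` | p-distances, neighbor joining, outgroup rooting, clade report |
| `tc1scout.pipeline` / `tc1scout.cli` | end-to-end discovery workflow and the `tc1scout` CLI |

## CLI

```sh
tc1scout simulate --length 60000 --seed 7 --out sim/        # genome.fa + truth.gff3/tsv
tc1scout discover --genome sim/genome.fa --out disc/        # elements.gff3/tsv + failed_evidence.tsv
tc1scout annotate --genome g.fa --candidates c.gff3 --out layout.tsv
tc1scout census   --genome g.fa --element element.fa --out cens/
tc1scout compose  --query domain.fa --proteome proteome.fa --out comp/
tc1scout phylo    --alignment domains.afa --outgroup IS630-AB1 --out tree/
```

`discover` accepts a TOML config (`--config`) whose keys mirror
`PipelineConfig` (start codons, minimum ORF length, triad spacing set, TIR
bounds/identity, TSD, flank search width); unknown keys are rejected and
every threshold is echoed into `run.log`. Exit codes: 0 success (including
empty results), 2 usage error, 3 data error.

## Notes

- All public coordinates are 1-based inclusive; BED output converts to
  0-based half-open at the writing boundary only.
- "Full-length copy" means coverage strictly greater than 0.90 of the
  reference element.
- Frameshift repair prefers the fewest removal segments (one segment = one
  insertion event), then the smallest total length, then the leftmost
  placement, and is exact within `max_insert_len` (default 50 bp).
- Tree inference is neighbor joining on p-distances (Poisson correction via
  `--poisson`); alignment inference and Bayesian/ML methods are out of scope.
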