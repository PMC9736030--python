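# bzipscan

A toolkit for characterizing plant bZIP transcription factor families:
domain architecture annotation, DNA-binding specificity group calling,
leucine-zipper dimerization statistics, intra-domain intron typing,
duplication-event classification, and FPKM expression filtering — with a
fully seeded synthetic-data module that generates every input alongside
ground-truth tables, so the whole pipeline is testable offline.

## What it does

| Stage | Module | Summary |
| --- | --- | --- |
| annotate | `domain_annotator` | Finds the 16-residue basic region via the invariant N-x7-R/K motif, the hinge, and 2–9 leucine-zipper heptads with the `g a b c d e f` register (anchor at the d position). |
| classify | `specificity` | Projects each domain onto a 30-column basic+hinge signature window and matches it against per-group column templates (groups A–J incl. merged F/K and G/M/S), reporting the putative DNA-binding site. |
| dimerize | `dimerization` | Residue frequencies at a/d/e/g, per-heptad Asn-at-a rates, electrostatic g↔e′ pair typing (repulsive basic/acidic, attractive basic–acidic / acidic–basic), and a per-protein dimer propensity summary. |
| introns | `gene_structure` | Maps the basic+hinge region onto the gene model and types intron patterns (Types 1–4) with splice phases P0/P1/P2 (= splicing after the 3rd/2nd/1st codon nucleotide; equal to the downstream CDS GFF3 phase). |
| dups | `duplication` | Classifies homolog pairs as tandem (adjacent, same chromosome), segmental (anchors of dynamic-programming collinear blocks), or dispersed; also inter-genome collinearity. |
| express | `expression` | Expressed (FPKM ≥ 1) / highly-expressed (FPKM ≥ 20) / tissue-preferential sets, row z-scoring, and fold-change differential calls. |
| simulate | `synthetic_data` | Seeded generators for proteins, gene models (GFF3), genome layouts with planted tandem arrays and collinear blocks, and FPKM matrices — each with a truth sidecar. |

## CLI

```sh
# generate a synthetic input bundle with ground truth
bzipscan simulate --config sim.yaml --out simdir/ --seed 7

# run stages individually
bzipscan annotate --proteins simdir/proteins.fasta --out annotations.tsv
bzipscan classify --annotations annotations.tsv --proteins simdir/proteins.fasta --out groups.tsv
bzipscan dimerize --annotations annotations.tsv --proteins simdir/proteins.fasta \
    --out dimer.tsv --freq-out freq_tables/
bzipscan introns --gff simdir/genes.gff3 --annotations annotations.tsv \
    --proteins simdir/proteins.fasta --out introns.tsv
bzipscan dups --gff simdir/genes.gff3 --pairs simdir/pairs.tsv --out events.tsv
bzipscan express --fpkm simdir/fpkm.tsv --drought simdir/drought.tsv --out expr/

# or the whole pipeline from one YAML config
bzipscan run --config run.yaml --out report_dir/
```

A `run.yaml` names the inputs and optional thresholds:

```yaml
proteins: simdir/proteins.fasta
gff: simdir/genes.gff3
pairs: simdir/pairs.tsv
fpkm: simdir/fpkm.tsv
drought: simdir/drought.tsv
min_anchors: 5
max_gap: 25
tandem_max_gap: 1
```

All outputs are TSV with `#` comment headers recording the tool version
and parameters; the merged `family_report.tsv` has one row per input
protein.

## Conventions

- Genomic coordinates are GFF3-native (1-based inclusive); protein
  positions are 1-based.
- Non-standard residue letters map to `X`, which matches no template
  column and belongs to no residue class.
- Splice-phase naming follows the family-analysis figure convention
  (P0/P1/P2 = after 3rd/2nd/1st nucleotide), the inverse of classical
  intron phase; it coincides with the downstream CDS segment's GFF3
  phase.
- Group templates live in `src/bzipscan/data/group_templates.tsv` as a
  versioned plain-text resource.
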