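# tollscan

A tested, reusable pipeline for Toll-like receptor (TLR) gene-family
analysis: detect TLRs in protein sequence sets by domain architecture,
classify them scc/mcc, collapse per-species redundancy, assign gene-tree
clades (α/β/γ), reconstruct clade gains and losses on a metazoan species
tree under Dollo parsimony, and call developmental expression from
stage-specific abundance tables. A first-class synthetic-data module
generates every input with ground truth, so the whole pipeline runs and is
testable with no downloads.

## Modules

| module | what it does |
| --- | --- |
| `tollscan.domain_scan` | LRR repeats (LxxLxLxxNxL position-weight profile), LRRNT/LRRCT cysteine caps, Kyte–Doolittle transmembrane segment, TIR domain (bundled seed profile); resolved `Architecture` per sequence |
| `tollscan.receptor_survey` | TLR vs TLR-like calls (TIR + TM + ≥1 LRR), pairwise-identity redundancy collapse (>90% within species), Table-1-style survey counts |
| `tollscan.receptor_typing` | scc (one membrane-proximal LRRCT) / mcc (≥2 LRRCT) / NC typing |
| `tollscan.phylo` | core-region extraction, gappyout trimming, region masking, insertion detection, neighbor-joining builder, outgroup rooting, support-thresholded clade assignment |
| `tollscan.scenario` | presence matrix, Dollo gain/loss event maps on the packaged metazoan species tree, ranking of origin hypotheses (1A/1B × 2A/2B/2C) |
| `tollscan.expression` | per-stage TPM, cross-stage TMM factors, ≥0.15 expression calls, temporal classes |
| `tollscan.synthetic` | seeded generators (proteomes, clade evolution, alignments with insertions, count matrices) with JSON ground truth |

## CLI

```sh
tollscan simulate proteome --seed 1 --out demo/         # synthetic input + truth.json
tollscan annotate --fasta demo/proteome.fasta --out demo/annot
tollscan survey --fasta demo/proteome.fasta --out demo/survey
tollscan trim --aln aln.fasta --mode mask --range 349:354 --out masked.fasta
tollscan clades --tree gene.nwk --outgroup-file og.txt --anchors anchors.tsv --out clades.tsv
tollscan scenario --clade-tsv clades.tsv --cnidarian-tips cn1,cn2 --out scen/
tollscan expression --counts counts.tsv --threshold 0.15 --out expr/
```

External ML tree inference is intentionally out of process. The documented
reproduction path for a publication-grade gene tree is:

```sh
mafft --localpair --maxiterate 1000 tlrs.fasta > aln.fasta   # L-INS-i
# trim: tollscan core extraction + gappyout, then
iqtree -s trimmed.fasta -m LG+R8 -bb 1000                    # ML + ultrafast bootstrap
```

The resulting newick (with support values) feeds `tollscan clades`.

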