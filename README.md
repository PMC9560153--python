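# utorf

Proteogenomic discovery and evolutionary characterization of unannotated
translated open reading frames (utORFs).

## Scientific problem

Genome annotations miss many short protein-coding sequences: standard gene
finders discard open reading frames (ORFs) below conventional length cutoffs,
so genuinely translated short proteins go uncatalogued. Direct protein
evidence from shotgun mass spectrometry can recover them, but only if the
search database contains every candidate ORF — which inflates the database by
orders of magnitude and breaks the usual false-discovery-rate (FDR)
machinery. Once a set of unannotated ORFs is supported by peptide evidence,
the follow-up questions are evolutionary and functional: how old is each
utORF, did it arise de novo from non-coding sequence or lose detectable
homologs along some lineages, and which candidates show independent support
from expression and ribosome profiling?

This package implements that full workflow:

1. **ORF cataloguing** (`utorf.orf_catalog`) — exhaustive six-frame
   enumeration of potential ORFs (stop-free codon spans; spans are broken at
   soft-masked or ambiguous bases), with a permissive length rule (≥ 8 amino
   acids, or ≥ 20 amino acids for ORFs without an ATG start), deduplication
   on the exact amino-acid string, and genomic annotation (location class,
   GC content).
2. **Proteogenomic search scaffolding** (`utorf.proteomics`) — in-silico
   tryptic digestion, target-decoy FDR estimation with q-values, a
   **two-round search**: a permissive discovery round (FDR ≤ 0.2) against the
   full candidate database selects a small set of candidates, which is then
   verified at strict FDR ≤ 0.01 against a reduced database (annotated
   proteome + survivors only). Post-search screens include a trie-based
   minimum-distance check of novel peptides against the annotated proteome
   (Hamming and Levenshtein, to catch near-misses from polymorphism or
   modification) and a retention-time plausibility filter.
3. **Syntenic similarity** (`utorf.synteny`, `utorf.alignment`) — each utORF
   locus is looked up in a whole-genome multiple sequence alignment; the
   aligned sequence of every informant species is translated in all three
   forward frames and scored against the reference protein with a zero-gap
   local similarity score (BLOSUM62, stops = −4), normalized by reference
   length. The significance threshold (2.5) is calibrated on a simulated
   null of 10,000 random protein pairs.
4. **Evolutionary inference** (`utorf.phylo`) — phylostratigraphic age (MRCA
   of the species with significant similarity), de novo origination calls
   (requiring homologous-but-sub-threshold sequence in ≥ 2 outgroup species
   spanning ≥ 2 independent lineages), and Dollo-parsimony loss counts
   (maximal all-lost subtrees; species with missing data never create or
   block a loss). Per-locus evolutionary-rate percentiles are combined
   across loci with Fisher's method.
5. **Latent class analysis** (`utorf.lca`) — categorical-mixture model over
   binned utORF indicators (length, expression, age, ...), fitted by EM with
   a short-run multi-restart strategy, model selection by BIC with an
   under-identification check, posterior class assignment.
6. **Expression and ribosome-profiling support** (`utorf.expression`) —
   tissue-specificity index tau, strict TPM support (max TPM > 0.2),
   one-sided binomial test for triplet periodicity of ribosome footprints
   (testable only with > 2 unique footprints), and a rank-averaged priority
   ordering of candidates.
7. **Synthetic data** (`utorf.simulate`) — a fully synthetic benchmark:
   sequence evolution along an invented 27-leaf insect-like tree with
   planted conserved / de novo / lost ORFs, synthetic PSM tables for the
   two-round search, latent-class tables, expression matrices and footprint
   counts — all with recorded ground truth so every stage's recovery can be
   measured.
8. **Pipeline** (`utorf.pipeline`, `utorf.cli`) — an end-to-end driver and a
   `utorf` command-line interface exposing each stage.

## Worked example

Run the whole pipeline on synthetic inputs and inspect recovery of the
planted truth:

```bash
utorf run-all --seed 0 --n-loci 60 --out-dir results/demo
cat results/demo/manifest.json
```

Or drive the stages individually:

```bash
# Enumerate a six-frame ORF database from a genome FASTA
utorf orfdb --genome genome.fa --min-len 8 --out-fasta orfs.fa

# Tryptic peptides of one protein
utorf digest --protein MKAILVVLLYTFATANADTLCIGYHANNSTDTVDTVLEK

# Target-decoy FDR on a PSM table (TSV with peptide, score, is_decoy, ...)
utorf fdr --psms psms.tsv --alpha 0.01

# Two-round selection
utorf two-round --round1 round1.tsv --round2 round2.tsv \
    --db-ids db_ids.txt --fdr1 0.2 --fdr2 0.01

# Null calibration of the similarity score
utorf calibrate-null --n-pairs 10000 --seed 0

# Age / de novo / loss calls from per-species similarity scores
utorf age --scores scores.tsv --tree tree.nwk --reference dmel

# Framing test: 20 in-frame footprints, 4 and 3 out of frame
utorf framing --n0 20 --n1 4 --n2 3 --n-unique 27
```

Every command prints JSON or TSV to stdout unless `--out` is given.

## Reproduction

The `analysis/` directory contains numbered thin driver scripts that
regenerate all results under `results/` (all computation lives in the
library; the drivers only wire inputs to outputs):

```bash
python analysis/01_simulate_inputs.py      # synthetic MSA loci + PSM tables
python analysis/02_two_round_ms.py         # two-round candidate selection
python analysis/03_null_calibration.py     # similarity-score null (3 seeds)
python analysis/04_ages_denovo_losses.py   # ages, de novo calls, loss counts
python analysis/05_latent_classes.py       # LCA fit, BIC selection, recovery
python analysis/06_expression_support.py   # tau, TPM support, framing, ranks
python analysis/07_end_to_end.py           # consolidated pipeline run
```

`scripts/acceptance.py` recomputes the null-calibration summary statistics
from scratch:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All simulations are seeded and deterministic: identical seeds yield
byte-identical outputs. Methodological details and deliberate modeling
choices are documented in [docs/methods.md](docs/methods.md).
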