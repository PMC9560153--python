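# Methods

This note records the precise conventions and deliberate modeling choices
behind each stage of the package, including places where a simpler or more
robust formulation was chosen over a more literal one.

## ORF enumeration

Potential ORFs are stop-free codon spans in all six frames. A span ends at a
stop codon, at the sequence end, or at any codon containing a soft-masked
(lowercase) or ambiguous (non-ACGT) base; masked codons therefore *break*
spans rather than merely being skipped. A span is reported when it encodes
at least 8 amino acids, or at least 20 amino acids if it contains no ATG (in
frame) — the permissive no-start rule admits ORFs whose true start is a
non-canonical codon or lies outside the assembled sequence. Reverse-strand
coordinates follow the convention that frame −k over a sequence of length n
covers reference coordinates [n − end, n − start) of the forward strand.
Catalog deduplication keys on the exact amino-acid string.

## Two-round proteogenomic selection

FDR at a score cutoff is estimated as (number of decoy PSMs at or above the
cutoff) / (number of target PSMs at or above the cutoff); q-values are the
running minimum of FDR taken from the worst score upward, with ties resolved
decoys-first (conservative). Group-level FDR uses the best PSM per group.

The two-round design addresses the database-inflation problem: round 1
searches the full six-frame candidate database at a permissive FDR (0.2) to
*discover* candidates; round 2 searches only the annotated proteome plus the
round-1 survivors at strict FDR (0.01) to *verify* them. A candidate is
reported only if it survives both rounds. If round 1 yields no survivors, or
round 2 contains no target PSMs, the verified set is empty by definition
(no error).

Post-search screens: novel peptides are compared against a trie of annotated
peptides under bounded Hamming and Levenshtein distance (near-misses are
flagged as possible polymorphisms/modifications of annotated proteins), and
candidate peptides must fall within the 95th percentile of the
retention-time error distribution of confidently identified annotated
peptides.

## Syntenic similarity score and its null

For each utORF locus, the corresponding slice of a whole-genome multiple
alignment (plus a 9-column flank) is extracted; alignment gaps are stripped
per species, the remaining nucleotides are translated in all three forward
frames, and each frame is scored against the reference protein with a
zero-gap local similarity: the best-scoring gapless monotone pairing of
residues under BLOSUM62 with stop characters scored −4, computed by a
vectorized prefix-maximum dynamic program. The per-species score is the best
frame's score divided by the reference protein length. The reference
scores ~4 against itself (average BLOSUM62 diagonal); unrelated sequences
score near 2.

The significance threshold of 2.5 is justified by a simulated null: 10,000
pairs of random proteins with proteome-like residue frequencies. The two
members of a pair share a common length drawn uniformly from 20–150 —
equal lengths are the conservative choice, since length mismatch only
lowers the normalized score. The null mean is ≈ 1.94 and mean + 2 sd ≈ 2.26,
comfortably below 2.5.

## Evolutionary inference

*Age*: the origin stratum is the most recent common ancestor of the
reference plus all species with significant similarity; the call also
records whether those species are monophyletic (species with missing data
are ignored for monophyly).

*De novo origination*: a young utORF is called de novo when homologous but
sub-threshold sequence (i.e., the orthologous locus exists and aligns, but
does not encode similar protein) is present in at least 2 outgroup species
spanning at least 2 distinct first-branching lineages outside the origin
clade. Requiring two independent lineages guards against a single lineage's
idiosyncratic alignment.

*Losses*: given the origin stratum, losses are counted by Dollo parsimony as
the number of maximal subtrees within the origin clade in which every
scored species lacks significant similarity; leaves with unknown status
neither create losses nor split an otherwise-contiguous lost subtree.

*Rate percentiles*: a locus's statistic is placed in an empirical null
distribution with the mid-rank convention
p = max((#less + 0.5·#equal)/n, 1/(n + 1)) — bounded away from zero so that
downstream combination is well-defined. Percentiles are combined across
loci with Fisher's method (−2Σlog p ~ χ² with 2m degrees of freedom).

## Latent class analysis

Indicators are binned categorically (half-open bins; missing values
propagate). The K-class model assumes conditional independence of
indicators given class; parameters are fitted by EM. To make 100 restarts
affordable, a short-run strategy is used: every restart runs a 100-iteration
burn-in, the top max(5, n_restarts/10) runs by log-likelihood are polished
to convergence, and the best polished run is reported. Runs converging to
distinct top optima flag the fit as under-identified, which excludes that K
from BIC selection. Model size is (K − 1) + K·Σ(L_j − 1). Class labels are
arbitrary up to permutation; recovery checks align labels by the best
permutation.

## Expression and ribosome-profiling support

Tissue specificity uses the tau index. TPM support is strict: max TPM
across samples > 0.2. The framing test is a one-sided binomial upper tail
P(X ≥ n0 | n, 1/3) for in-frame footprint counts, testable only for loci
with more than 2 unique footprints. Candidate prioritization averages
midranks of max TPM (higher better), tau (higher better), and framing p
(lower better); midranks make the ordering invariant under monotone
transforms of any factor.

## Synthetic benchmark

The simulator is a study instrument, not a fit to any real dataset; its
defaults define the benchmark conditions.

- **Tree**: an invented 27-leaf insect-like species tree (reference `dmel`,
  origin clade {dmel, dsim, dsec, dyak, dere}). Names are evocative only;
  the tree, branch lengths, and sequences are synthetic.
- **Sequence evolution**: Jukes–Cantor-like substitutions (rate 0.15 per
  branch-length unit) plus geometric-length deletions. Insertions are
  omitted so that root coordinates remain valid in every descendant — this
  keeps the planted-truth bookkeeping exact while still degrading
  alignability with divergence. ORF codons on the path from the root to the
  reference are protected from stop-introducing changes so the reference
  retains an intact ORF.
- **De novo loci** are planted by applying a shared nucleotide shuffle of
  the ORF columns in all species outside the origin clade: the locus still
  exists and aligns (homologous sub-threshold sequence) but encodes no
  similar protein — exactly the signature the de novo caller requires.
- **Losses** are planted by a shared nucleotide shuffle plus a 1-bp
  frameshifting deletion in each lost clade.
- **PSM tables** are score draws from separated target/decoy distributions
  with planted true positives, enabling calibration checks of the two-round
  procedure (pooled false-positive counts are compared against binomial
  bounds).
- **Latent classes** use maximally separated preference patterns: each
  class concentrates mass (0.8) on its own level of each indicator, with
  merged classes on small indicators rotated so that every pair of classes
  differs in preferred level on most indicators. This keeps the K-class
  model identifiable at benchmark sample sizes; with naively assigned
  patterns two classes can share preferences on all small indicators and
  parameter recovery becomes impossible for any sample.
- **Expression** plants one-hot (tau = 1), uniform (tau = 0), and noisy
  profiles; **footprints** draw frame counts binomially around a planted
  in-frame probability (default 1/3, i.e., no bias, for type-I-error
  checks).

What the benchmark does *not* emulate: insertion events, alignment-tool
artifacts, spectral-level mass-spectrometry physics (PSMs are abstracted as
scores), transcript-level expression estimation noise models, and
population-level polymorphism. Conclusions about these aspects should not
be drawn from synthetic recovery rates.

## Determinism

Every stochastic routine takes an explicit seed and uses an isolated
`numpy.random.Generator`; identical configurations produce byte-identical
output files.
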