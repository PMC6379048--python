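# Methods

## The model

The quantity modeled is the tissue-specific protein-to-mRNA ratio
`y_ij = log10(protein_ij / mRNA_ij)` of gene `i` in tissue `j`.  Two
ordinary-least-squares variants are fitted on a genes x features design
matrix `X` of sequence-derived predictors:

- per-tissue: `y_ij = b_j0 + x_i' b_j + e_ij`, one coefficient vector
  per tissue (tissue-specific effects, motif heat maps);
- shared: `y_ij = b_j0 + x_i' b + e_ij`, tissue intercepts with one
  shared coefficient vector (tissue-independent effects).

Both are plain OLS on observed cells: per-tissue fits drop rows whose
`y` is missing in that tissue; the shared fit stacks all observed
(gene, tissue) cells in long form with tissue-indicator intercepts.
Standard errors use the unbiased residual variance; p-values come from
the t distribution; a rank-deficient design raises an error carrying the
aliased columns (QR with pivoting) rather than silently pseudo-inverting.

The codon effect summary is the PTR adaptation index
`PTR-AI = 10^beta` for the coefficient of a codon's log2 frequency: the
multiplicative change in PTR expected per doubling of that codon's
frequency.  Amino-acid effects replace the 61 codon columns with 20
amino-acid log2-frequency columns and are reported the same way.

Explained variance is out-of-fold: 10-fold cross-validation with
*gene-level* fold assignment (a gene is held out in every tissue at
once, so tissue-shared gene effects cannot leak), predictions pooled
over folds, and `R^2 = 1 - SSE/SST` with SST about the overall mean of
the held-out values.  Per-group decompositions refit the model on one
column group at a time.

Covariate-corrected effects use full Frisch–Waugh–Lovell
residualization: both the response and the target columns are
residualized on the remaining covariates, so the corrected effect equals
the coefficient the target would receive in the joint OLS (this also
fixes the degrees of freedom to the joint model's).  Positional scans
(folding-energy windows, context nucleotides) apply this per position
and adjust with Benjamini–Hochberg across the scanned family.

## The design matrix

With the packaged defaults the matrix has 204 columns in 14 groups:
61 codon log2 frequencies (terminal stop excluded; zero counts replaced
by 0.5 before dividing so absent codons stay finite), 36 start-context
and 39 stop-context indicators, 3 log2 region lengths, 3 region GC
fractions, 20 3'UTR motif columns, 25 5'UTR motif columns, 3 CDS
amino-acid motif counts (CG, KRR, NS), 6 linear protein-motif
indicators, 3 folding-energy windows, 2 codon-pair principal components,
PEST indicator, isoelectric point, and N-terminal hydrophobicity.

Two context encodings are provided.  The default one-hot encoding emits
4 indicators per variable position (positions -6..-1 and +3..+5 around
each of start and stop, plus 3 stop identities) and reproduces the
canonical 36 + 39 bookkeeping; it is intentionally collinear with the
intercept and suited to column accounting, not fitting.  The
dropped-reference encoding (27 + 29 columns; start reference = Kozak
consensus gccAcc|AUG|Gcc, stop reference = A at every position with TAA
as reference stop) is identifiable and is what the model-fitting entry
points use.  The stop-context reference letters are an arbitrary
identifiability choice, not a biological claim.

The packaged UTR motif rosters contain every element reported in the
literature this pipeline builds on (the polyadenylation signal AAUAAA,
the AU-rich elements UAUUUAU and AUUUUUA, the Pumilio site UGUAAAUA,
the 5'UTR elements CUGUCCU, UUCCG, CCCACCC, GGCCCCUG, AGCGGAA, GCCGCC,
and others), padded to the canonical 25/20 roster sizes with synthetic
placeholder k-mers flagged `synthetic=True`; real analyses should
replace them with a project-specific motif list (the CLI accepts a TSV).
The AUG column is the out-of-frame upstream-AUG indicator (frame
relative to the main ORF = `(len(utr5) - p) mod 3`); AAUAAA is a
presence indicator; every other motif is an overlapping site count.
The six linear protein-motif regexes are curated approximations of the
published eukaryotic-linear-motif patterns and are likewise replaceable.

RNA folding windows are 51 nt wide with centers given relative to the
first CDS nucleotide (position 0, upstream negative); the anchor is the
last 100 UTR nt plus the first 101 CDS nt so that the extreme center
+75 fits (transcripts need utr5 > 100 nt and cds > 100 nt; others are
dropped with a report).  The per-window feature is
`log2(1 + max(0, -MFE))`: the +1 offset keeps the unstructured case
(MFE = 0) defined and maps it to 0 while preserving monotonicity.  The
default energy engine is an exact base-pair-maximisation dynamic
program (Watson–Crick + GU, minimum hairpin loop 3, -1 per pair) — a
deliberately simple, exactly testable proxy; a thermodynamic engine via
ViennaRNA satisfies the same provider contract when available.

PEST regions are maximal K/R/H-free stretches of >= 10 residues between
charged flanks containing at least one P, one D/E and one S/T, scored
`0.55 * mole%(DEPST) - 0.5 * mean(10*KD + 45)` with the conventional +5
"potential" threshold (the alternative any-valid-hit reading is
selectable).  The isoelectric point solves the Henderson–Hasselbalch
net charge for zero by bisection on [0, 14] to |Q| < 1e-6 with a fixed
EMBOSS-style pKa table (documented constant; swappable).

## Expression preprocessing

Mature-mRNA signal per sample = exonic reads / (exonic kb) - intronic
reads / (intronic kb); negative differences (intron density exceeding
exon density) are floored at 0 and flagged.  Size factors are
median-of-ratios against a geometric-mean reference over rows with all
positive signal and are computed on the mature signal.  Densities below
10 reads/kb (after size-factor normalization) are censored per sample;
technical replicates are summarised by the median of surviving
densities on the natural scale and then log10-transformed — censor,
median, then log, in that order.  Protein levels are log10 iBAQ with
zeros as missing and an additive per-tissue constant aligning every
tissue median to the global median; the PTR matrix is the elementwise
difference.  The 10 reads/kb cutoff and the median are both stated
rules; their ordering and the natural-scale median are this package's
documented choices (the two orderings differ only for even replicate
counts).

## Motif discovery

For each region, k-mer counts (overlapping, sense strand only) for k in
the configured range form `Z`; zero-variance columns are dropped and the
rest column-standardized.  The mixed model
`y = Wa + x_k b_k + u + e`, `u ~ N(0, s2_g K)`, `K = ZZ'/p`, tests each
k-mer while the random effect absorbs the joint contribution of all
k-mers, with `W` = intercept + log2 region length + region GC.  The
variance ratio `lambda = s2_g/s2_e` is estimated once per phenotype by
REML on the null model — profiled restricted likelihood over
log10(lambda) in [-10, 10] on a grid refined by golden-section search to
1e-4, boundary lambda = 0 always considered — and held fixed for all
Wald tests (the standard association approximation; the kinship
includes the tested k-mer).  When the number of k-mers p is below the
number of genes n, the spectral decomposition of K is obtained from the
p x p Gram matrix and all `A' (I + lambda K)^-1 B` cross products use
the low-rank inverse identity, making the scan O(n p^2); tests reduce
exactly to weighted least squares in the eigenbasis and are verified
against a dense GLS oracle in the test suite.

Phenotype contexts are the per-gene median PTR across tissues and, for
tissue specificity, each tissue's gene-centered PTR (y minus the gene's
median).  BH adjustment runs across all contexts and regions jointly;
the significance threshold is q < 0.1.  Significant k-mers of one
region and context are assembled deterministically: two k-mers are
linked iff one contains the other or they overlap suffix-to-prefix by
at least (shorter length - 1) with equal effect signs; connected
components merge to a greedy longest-overlap superstring (ties broken
lexicographically), the representative inheriting its most significant
member's statistics.  This is a reproducible surrogate for what is
usually a manual curation step, and is documented as such.

Conservation testing pairs, per exact motif occurrence with full 10-nt
flanks, the mean score over motif positions with the mean over the 20
flank positions, and applies a one-sided Wilcoxon signed-rank test
(motif more conserved); at least 5 usable occurrences are required.

## The synthetic-data generator

The generator is the package's study system.  True PTR is
`intercept + sum_c e_c * log2 freq_c + sum_m e_m * sites_m +
covariate effects + tissue offset + per-cell Gaussian noise`: codon
effects are *realized* — per-gene codon usage is drawn from a Dirichlet
around the uniform base (concentration 100) and the truth uses the
realized log2 frequencies — and motif effects multiply the actual
occurrence count in the final sequence (planted insertions plus
incidental background matches).  Planted motifs are substituted in
place at uniform positions avoiding the start/stop context windows and
each other (re-draw up to 100 times).  Defaults emulate the
best-characterised elements: AAUAAA (+0.083 log10/site, 60% carriers),
UAUUUAU (-0.041, 27%), UGUAAAUA (-0.046, 11%), CUGUCCU in the 5'UTR
(-0.050, 10%), per-doubling codon effect sd 0.05, per-cell noise sd
0.15, tissue offset sd 0.10.  Region lengths are log-normal around 180
nt (5'UTR), 400 codons (CDS, Poisson), 800 nt (3'UTR), background GC
0.45.

Expression data: exonic counts are negative binomial
(`var = mu + disp*mu^2`, default dispersion 0.05) around mature +
pre-mRNA signal scaled by exonic length; intronic counts around
pre-mRNA signal (a 0.10 fraction of mature) scaled by intronic length;
`nb_dispersion = 0` means the noiseless limit and emits expected counts
directly, with true densities defined from integer exonic read totals
so the zero-noise pipeline identity holds to machine precision.  iBAQ
intensities are `10^(log10 mRNA + PTR + noise + tissue shift)` with
missingness below a detection floor; the per-tissue shifts exist
precisely so the median-alignment step has work to do.  Conservation
tracks are Beta(2,8) background with Beta(8,2) inside conserved planted
motif instances.  All randomness flows from one seed through named
substreams (one per operation), so adding a stage never perturbs
earlier ones.

What the generator does *not* emulate: real human codon-usage
marginals, isoform structure, correlated tissue programs, shared
technical covariance between mRNA and protein measurements, or
position-dependent motif effects.  Passing recovery tests therefore
demonstrates the estimators' correctness under the generative
assumptions, not performance on real tissue data.

## Problem sizes and numerical choices

The test suite and acceptance script run the recovery studies at
n = 3,000 genes (codon-effect and motif recovery), n = 1,000 (null
calibration), n = 500 (zero-noise identity), with k-mer scans at
k = 3..5 and 300-nt 3'UTRs — sizes chosen so the whole suite completes
in minutes while leaving the estimators' asymptotics visible.  The full
k = 3..8 range and longer UTRs are supported through the same code
paths.  Null-scan p-values are slightly conservative at small n because
the REML variance ratio absorbs some noise along k-mer directions and
the kinship contains each tested k-mer (proximal contamination, of
order 1/p); both effects shrink with n and p and are within the
calibration tolerances tested.

Other conventions: 0-based half-open coordinates throughout; positions
relative to a codon put 0 on its first nucleotide; RNA is canonicalized
to DNA internally and reported back in the RNA alphabet; TSVs use "NA"
for missing and 12-significant-digit floats (lossless round trip);
BH families are per scan (folding: across positions; k-mers: all
contexts jointly; fit tables: the whole coefficient family); ties in
major-isoform selection break lexicographically and are flagged; the
N-terminal residue is computed but excluded from the default design
(an inclusion flag exists).

## Known limitations

- The base-pair-maximisation folding engine ignores stacking and loop
  thermodynamics; its feature is a structure proxy, not an energy.
- The Wald scan fixes lambda at the null estimate; per-marker REML
  re-optimisation is not implemented (the dense-GLS oracle defines the
  contract at fixed lambda).
- Motif assembly is a deterministic stand-in for expert curation and
  can merge k-mers that an expert would keep separate.
- The packaged motif rosters beyond the literature-named elements are
  synthetic placeholders for column bookkeeping.
- OLS on observed cells assumes missingness unrelated to the residuals;
  the detection-floor missingness in the generator mildly violates this,
  as it does in real proteomics.
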