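# Methods

This note records the models, parameter choices and deliberate
simplifications behind each stage of the pipeline, and what the bundled
synthetic benchmark does and does not demonstrate.

## Coordinates and annotation handling

All interval arithmetic is 0-based half-open internally; GFF3 I/O
converts to and from the format's 1-based inclusive convention. Only
CDS, tRNA and rRNA features delimit intergenic regions; IGR sequences
are reported on the forward strand and are never trimmed at their
extremes, since sRNA boundaries relative to the flanking genes are
variable. Terminal gaps (before the first or after the last gene of a
replicon) are excluded by default because the four orientation classes
require two flanking genes; a flag reports them separately. Overlapping
or abutting genes yield no IGR, and replicons are treated as linear.

When two annotation sets are merged (e.g. two independent sRNA
detectors), records on the same replicon and strand overlapping by at
least 1 nt collapse into one record spanning their union, with both
sources recorded; the minimum overlap is a parameter because the notion
of "overlap" between detector outputs is not standardised. Merging is
idempotent and commutative up to record naming.

Coding potential is the longest open reading frame over six frames with
start codons ATG or GTG (GTG starts are common in actinobacteria) and
stops TAA/TAG/TGA. Residues are counted strictly between the start and
stop codons, so `ATG + k codons + stop` scores `k`; the default
is-coding threshold is 100 residues.

## Conservation

Homology between IGRs uses an exact-13-mer seed prefilter (both
strands) followed by optimal local affine alignment (Biopython's
PairwiseAligner; match +1, mismatch −2, gap open 5, gap extend 2, with
the first gap position costing open+extend). Significance is a
Karlin–Altschul-style e-value `K·m·n·exp(−λ·S)` with documented
defaults (K = 0.71, λ = 1.28); only the crossing of the 1e−5 threshold
matters downstream, so no attempt is made to reproduce BLAST's
edge-effect or gapped-λ corrections. Coverage is query-relative (the
`qcovs` convention). The best hit per query per genome is chosen by
score with ties broken toward the lowest subject identifier, then gated
on e-value and coverage; a pair is reciprocal when each member is the
other's best hit. "Conserved" means an RBBH partner in at least 4
genomes, counting genomes, not raw hits. IGR families are connected
components of the RBBH graph.

## Structure screen

Folding uses a base-pair energy model — GC = −3, AU = −2, GU = −1
kcal/mol per pair, hairpin loops of at least 3 nt, no loop entropies or
stacking terms — solved exactly by dynamic programming. This is a
deliberate simplification: the screen needs a stability *ranking*
against shuffled backgrounds, not accurate free energies, and the same
kernel folds single sequences and consensus alignments.

The thermodynamic feature is the z-score of the folding energy against
dinucleotide-preserving shuffles (Altschul–Erickson Euler-path
algorithm; shuffles provably preserve the 16-entry dinucleotide count
vector). The default background is 40 shuffles; windows whose quick
15-shuffle estimate is clearly unstructured (z > −1.5, far above the
decision boundary near −2.9) keep that estimate, which saves most of
the folding work without affecting decisions near the boundary.

The conservation feature is the structure conservation index: the
consensus minimum energy of the alignment divided by the mean single-row
minimum energy. A column pair is scored only when ≥ 70% of rows can
pair there; its energy is the mean over all rows, with rows unable to
pair contributing +3 kcal/mol (the alignment-folding convention that
inconsistent rows destabilise a consensus helix — without this penalty,
unrelated sequences still reach SCI ≈ 0.7 by chance at 4 rows). An
alignment of identical rows scores exactly 1; compensatory GC↔CG
substitutions preserve the score.

Windows are ≤ 200 alignment columns with step 100; per window, rows
under 70% identity to the reference are dropped (the reference is always
kept) and both strands are scored, reporting the better strand. The
structured-class probability is a logistic over (−z, SCI) with
coefficients (a, b, c) = (2.11, 0.76, −6.94), calibrated once on the
bundled synthetic generator (`scripts/calibrate_structure.py`, seed
20240, logistic regression on window features labelled by planted-locus
overlap) and frozen; the decision rule is p > 0.5. Positive windows on
one strand overlapping by ≥ 1 nt merge into a single call, so one IGR
can yield several calls. Family alignments are reference-anchored
(pairwise global alignments merged on reference coordinates), which is
adequate at the few-percent divergences the screen targets and keeps
the stack dependency-free; the aligner is pluggable.

Specificity is estimated by passing column-permuted real family
alignments through the identical screen: permutation preserves each
row's composition and the column-wise conservation pattern while
destroying secondary structure and covariation, which is the
appropriate null for a screen keyed on structure. Sensitivity is the
screen's recall of a supplied known-ncRNA family set.

Terminator scanning looks for a hairpin of ≥ 4 stem pairs
(Watson–Crick or GU), a 3–10 nt loop, and ≥ 3 thymines within 8 nt
downstream, scored `stem + tail_T − loop/2`, greedily de-overlapped.

## Expression

TPM divides counts by transcript length and scales each sample to 1e6.
"Expressed in a sample" means count > 0 for breadth curves; the
reliability filter for putative sRNAs is the stricter joint rule —
at least 20 reads in each of at least 10 samples — resolving the
ambiguity between "detected in 10 libraries" and "20 reads per sample"
in favour of the conjunction, with both thresholds exposed. Operon
statistics classify transcription units as single/pair/multi-gene; the
mean genes-per-operon is computed over units with ≥ 2 genes (singletons
are not operons), with the alternative available. An sRNA belongs to a
TU when its interval lies within the TU's genomic span on the same
replicon regardless of strand (antisense membership is flagged), and to
a BGC when overlapping its interval by ≥ 1 nt.

## Differential expression

The engine is intentionally minimal: median-of-ratios size factors
(features with positive counts in every sample), per-feature
method-of-moments NB dispersion pooled across groups and floored at
0.01, a Wald test on the log2 ratio of normalised group means
(delta-method variance `(1/n)(1/μ + α)` per group, standard-normal
reference, 0.5 pseudo-count on group means), and Benjamini–Hochberg
adjustment per contrast. Calls require |log2FC| ≥ 2 and adjusted
p ≤ 0.01. Each later time point is contrasted against the 24 h
reference. The engine's empirical type-I rate at padj ≤ 0.01 is ~1–2%
on a 3v3 NB null and its power for planted log2FC = 3 at base mean 100
exceeds 0.95 (both asserted in the tests); it is not a DESeq2
re-implementation — no shrinkage, no outlier refitting — because the
bespoke content downstream is the calling/OE/consensus logic.

Opposite expression pairs an sRNA and an mRNA that carry opposite
up/down calls in at least two contrasts.

## Target prediction

The duplex model is nearest-neighbour stacking: Watson–Crick stack free
energies at 37 °C (Xia-style values embedded in `targets.STACK_ENERGY`)
with approximate composite values for GU-containing stacks, completed
under duplex-reversal symmetry; +4.1 kcal/mol duplex initiation;
one-sided bulges of 1–2 nt penalised +3 kcal/mol per bulged nucleotide
with no stacking across the bulge (two-sided interior loops are not
modelled). Interaction sites are capped at 60 nt. The cap is enforced
exactly on the sRNA side by a per-start DP; a fast unconstrained DP
serves as the first tier and equals the capped optimum whenever its
site already fits the cap (asserted against the capped kernel in
tests). The `seed_extend` scorer requires a ≥ 7-bp perfect
Watson–Crick seed and extends it without bulges. Interaction search
covers the whole mRNA, with no positional restriction relative to start
or stop codons. sRNAs of ≤ 50 nt are excluded with a reason code.

"Probability" is defined operationally as an empirical-null exceedance:
the fraction of ≥ 100 dinucleotide-shuffled versions of the sRNA whose
best duplex against the same mRNA is less stable than the observed one.
A consensus target requires both scorers below −20 kcal/mol and
probability > 0.5; sRNAs with ≥ 10 consensus targets are flagged as
global regulators. The probability is evaluated only for candidates
both scorers support, since it cannot rescue a pair that fails the
energy gate.

## Synthetic benchmark

The generator is fully deterministic given its seed. Defaults: 8
comparator strains diverged from a 200-kb, 72%-GC reference (the
GC-richness of *Streptomyces* genomes) at 5% per-site substitution,
with single-nucleotide indels at 10% of the substitution rate; 150
genes of 350–750 nt separated by 100–450-nt IGRs (the screen-performance
and end-to-end evaluations use 225 genes so that ~200 unplanted IGRs
are available as negatives — a problem-size choice, stated wherever the
numbers are reported). Twenty planted sRNAs, each two stacked GC-rich
hairpins with stems of `hairpin_stem + 4..8` bp (≥ the configured
10-bp floor) and 4-nt loops, ~75 nt total with ~60–75% of bases paired
— the long stable helices typical of structured bacterial RNAs.
Planted loci receive substitutions at 0.2× the background rate, no
indels, and pair-preserving stem swaps (GC↔CG etc.) at 0.04 per pair
per strain; the swap rate is kept below the background substitution
rate so planted loci remain *less* diverged than background in raw
identity while still exercising covariation-aware scoring.

Counts follow a negative binomial with log-normal base means (planted
sRNAs are well expressed, ~300 mean, so a down-shifted sRNA still
clears the read filter at its low phase; "noise" sRNAs at mean ~2
exercise the filter's rejection side) and dispersion 0.1 over
4 time points × 3 replicates. Ten sRNA–target pairs are differentially
expressed at |log2FC| = 3; the pairs rotate over six expression
programs (three 2-contrast patterns × sign) because a single shared
program would make every co-regulated cross-pair satisfy the
opposite-expression rule and dominate false consensus calls. Each
target mRNA carries an exact 20-nt reverse-complement site of its sRNA
mid-sequence. Decoy and target mRNAs are 200 nt at uniform (50% GC)
composition: at organism-level GC (~72%), chance duplexes pass both
scorers at −20 kcal/mol for roughly half of random pairs, which makes a
shuffled-sRNA negative control uninformative; at neutral composition
the chance-consensus rate is ~4% and the energy gate is meaningful. The
200-nt length is a desk-scale reduction of ~1-kb coding sequences.

What passing the synthetic benchmark shows: every stage's logic —
thresholds, reciprocity, windowing, gating, corroboration — recovers
known truth under its stated assumptions, at realistic noise levels,
deterministically. What it does not show: performance on real data with
repetitive DNA, horizontal transfer, assembly and annotation errors,
expression batch effects, secondary structures outside the simple
energy model, or GC-extreme mRNA pools (where the −20 kcal/mol energy
gate alone loses discrimination and target lists grow large — the
multi-target "global regulator" regime).

## Numerical and degenerate-input conventions

Folding energies are float32; e-values use exact exponentials; TPM
columns sum to 1e6 within 1e−6 relative tolerance. Degenerate cases:
all-N sequences have undefined GC (NaN); a homopolymer's shuffle
background has zero variance, so its z-score is reported as 0 with a
warning; all-zero count features are `ns` with missing statistics;
all-zero samples get zero TPM with a warning; a degenerate interaction
null makes the probability missing and the target uncallable; fewer
than two usable alignment rows skips a window. Best-hit ties break
toward the lowest subject id; randomization and shuffle streams are
driven by explicit numpy Generators so every reported number is
reproducible from a seed.
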