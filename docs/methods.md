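# Methods

`brocmir` re-implements, as one tested pipeline, the computational procedure
used in salt-stress small-RNA studies of *Brassica* crops: quality filtering
and tag collapsing of two sRNA-seq libraries, genome mapping and annotation
triage, conserved miRNA family assignment, hairpin-based novel-miRNA
discovery, two-library differential expression with the Audic–Claverie
statistic, plant-style target prediction, stem-loop qPCR quantification and
term enrichment.  Because no public crop dataset accompanies this workflow,
every stage is exercised on synthetic data with machine-readable ground
truth; this note records the models, the parameter choices and what the
synthetic benchmark does and does not demonstrate.

## Read cleaning (`preprocess`)

A raw read survives iff it has no N, at most 4 bases below Q10, at most 6
bases below Q13, and its insert after 3'-adapter removal is 18–30 nt.
Qualities are ASCII − offset (offset 64 by default, 33 selectable) and the
filters are applied to the full read before trimming: the quality string
describes the sequencer's read, not the insert.  Adapter removal takes the
leftmost exact match of the adapter's first 8 nt, else the longest ≥ 6 nt
read-suffix/adapter-prefix overlap; untrimmable reads longer than 30 nt are
dropped.  The filters are conjunctive, so their order only decides which
rejection counter a multiply-bad read increments (N > Q10 > Q13 >
adapter/length).  Survivors collapse to unique tags with per-library counts.

## Mapping and annotation (`genomemap`)

Tags map to the genome with at most 1 mismatch and no indels (a 0-mismatch
mode is also exposed).  The mapper is exact at this scale: seeding with the
two non-overlapping terminal 9-mers guarantees, by pigeonhole, that every
≤ 1-mismatch placement of an 18–30 nt tag is found; candidates are verified
by direct comparison.  Coordinates are 1-based inclusive in memory and in
locus strings; on-disk BED is half-open.  A tag overlapping several feature
classes is counted once under the priority
rRNA > known miRNA > tRNA > snRNA > snoRNA > repeat > exon > intron
(the published rule orders the first four; structural RNAs are kept above
genic classes, consistent with category tables that list rRNA/tRNA
separately).  Genic hits split sense/antisense against the feature strand.

## Conserved families (`conserved`)

Tags join a known family when within 2 edits (substitutions and gaps, unit
cost) of the family's mature sequence, or of the best window of its
precursor (infix alignment).  Ties go to the smaller distance, then to the
family with more reference sequences, then lexicographic.  Family counts
sum member reads; the highest-count member is the representative.  A family
whose representative has no genomic locus folding into a passing hairpin is
a pseudo-miRNA (reason recorded: "no locus" vs "no hairpin").

The expression noise floor is adaptive.  A geometric distribution (support
1, 2, …) is fitted by maximum likelihood to unique-tag counts at or below
their 90th percentile — the MLE corrects for that truncation by solving
E[X | X ≤ T] = observed mean with Brent's method — and candidate thresholds
c are scanned upward.  The threshold is the smallest c at which the
one-sample KS distance between the empirical distribution of counts ≥ c and
the fitted conditional tail exceeds the α = 0.01 critical value
1.628/√n_c.  On pure geometric data no c triggers and max(count)+1 is
returned: nothing is declared above noise.  The scan stops when fewer than
10 tags remain.  Discreteness and the estimated parameter both make the
test conservative, which is the desired direction for a noise floor.  The
published threshold of this procedure (38 reads) is a data-dependent
outcome, not a constant of the method.

## Folding and hairpin screening (`hairpin`)

Folding is an exact Zuker-style dynamic program over pseudoknot-free
structures for a self-contained nearest-neighbor model: Watson–Crick and
G:U pairs; Turner-like stacking energies for the 36 pair-on-pair stacks;
Jacobson–Stockmayer loop penalties (hairpin 4.5 + 1.6·ln(n/3), the
initiation constant net of terminal-mismatch stabilization; bulge
3.8 + 1.6·ln n; internal 4.0 + 1.6·ln(n/2) + min(0.5·|asymmetry|, 3));
affine multiloops (4.6 + 0.4 per branch); minimum hairpin loop 3 nt; DP
loop-size bound 30 nt.  Two deliberate departures from measured stacks:
weak G:U stacks are floored at −0.3 so stem extension is monotone, and
every wobble-containing stack is kept weaker than its Watson–Crick
counterpart so a wobble never stabilises a duplex (this makes target rule
scoring monotone; see below).  Energies are reported in the model's
kcal/mol scale; all constants live in `ENERGY_MODEL` so an external
thermodynamic folder can be swapped in.  The DP equals exhaustive structure
enumeration on short sequences (tested), and the O(n³) kernels are
numba-compiled, folding a 340-nt window in well under a second.

Novel-miRNA screening follows the MIREAP-style criterion set with the
printed defaults: mature length 18–25, precursor energy ≤ −18 kcal/mol,
≥ 16 mature bases paired to the star arm, mature bulge ≤ 4, duplex
asymmetry ≤ 4, flank 20 nt, maximal space 300 nt, at most 20 genomic
copies.  Unannotated, unassigned tags are clustered into loci (gap ≤ 30 nt
— the 300 nt "space" bounds the precursor, not the read cluster), the most
abundant tag per locus is the mature candidate, and two windows are excised
(mature on the 5' arm: [start − 20, end + 300]; on the 3' arm:
[start − 300, end + 20]), folded and screened; the passing window with the
lower energy wins.  Duplex metrics come from the pairing map: mature bases
pairing outside the mature on the dominant side define the star span;
the bulge is the longest non-star run between the first and last
star-paired base; asymmetry is the difference in unpaired counts between
the two duplex spans.  A tag inside a hairpin can also map to the star arm
on the opposite strand; overlapping candidates driven by the same mature
tag are merged (lower energy wins) while distinct tags with overlapping
windows remain separate loci.  The reference-mature length bounds (20/23)
are treated as bounds on the reported reference sequence, not as a read
filter.  Published candidate tables for real genomes are format examples
only; their energies depend on the original genome and energy tables.

## Differential expression (`diffexpr`)

Counts normalise to reads per million, NC = raw/total × 10⁶; a zero NC is
replaced by 0.01 for fold-change purposes, and a miRNA with both NCs < 1 is
excluded before fold-change computation as unquantifiable.  Fold change is
log2(NC_treated/NC_control).  Significance uses the Audic–Claverie
probability

    p(y|x) = r^y (x+y)! / ( x! y! (1+r)^(x+y+1) ),  r = N2/N1,

evaluated via an exact binomial coefficient for x+y ≤ 500 and log-gamma
beyond; the lower tail C is the exact finite sum (compensated summation),
the upper tail D runs the term recurrence until terms fall below 1e-15 of
the accumulated sum, and the two-sided p doubles the smaller tail, capped
at 1.  The source workflow labels this per-miRNA probability "FDR"; it is
reported as-is for fidelity, with an optional Benjamini–Hochberg adjustment
exposed but off by default.  Calls require |log2FC| > 1 and p < 0.01, both
strict.  Note the equal-count case x = y yields p = 1 through the cap, not
through exact tail symmetry (the conditional distribution of y given x has
mean (x+1)·r, so the tails differ slightly even at r = 1).

RPM normalization carries the usual composition effect: if strongly
up-regulated miRNAs enlarge the treated library, every estimated log2FC is
shifted by −log2 of the depth ratio.  The synthetic end-to-end run shows
this (planted |log2FC| = 2 estimated near 1.6 with the 0-fold-change
miRNAs near −0.4); calls at the |log2FC| > 1 cut are unaffected at these
effect sizes, and the count-level experiments with equal totals recover
fold changes to a median absolute error near 0.1.

## Target prediction (`targetscan`)

Sites are ungapped duplexes between a miRNA (5'→3', positions 1-based from
the 5' end) and an equal-length transcript window; each position is a
Watson–Crick match, a G:U wobble (0.5 mismatches) or a full mismatch.  A
site passes iff (i) total mismatch score ≤ 4; (ii) no adjacent mismatched
positions within 2–12; (iii) no run of ≥ 3 mismatches anywhere; (iv) no
mismatch at 10–11 and at most 2.5 mismatches over 1–12; (v) duplex energy
at least 75% of the miRNA bound to its perfect complement.  Wobbles count
as mismatched positions for rules i–iv but pair (and stack) energetically.
Duplex energy sums the folding module's stacks over consecutive paired
positions; each full mismatch breaks stacking and adds +0.5.  Rule v's
reference is the miRNA·exact-complement duplex (not the best transcript
window).  All violated rules are reported, not just the first.  Gapped
(bulged) sites are out of scope: the rule set speaks only of mismatches.
The wobble-weakness constraint on the stack table makes acceptance monotone:
converting a match to a mismatch can never rescue a rejected site.

## qPCR quantification (`quantpcr`)

Per replicate ΔCt = Ct(miRNA) − Ct(U6); ΔΔCt = mean ΔCt(treated) − mean
ΔCt(control); relative expression is the Livak 2^(−ΔΔCt) — the minus sign
is stated explicitly because the method is often written "2^ΔΔCt" while the
reported up/down directions require the negative exponent.  Groups are
compared with an independent two-sample t-test, pooled variance by default
(matching the SPSS default), Welch behind a flag; zero variance in both
groups reports an undefined t/p rather than ±∞.  Stars: * p < 0.05,
** p < 0.01.

## Enrichment (`enrich`)

Targets are classified against flat term sets (three GO namespaces plus
"pathway") and enriched with the upper-tail hypergeometric probability
P(X ≥ k) given term size, background size and target-list size, optional
BH adjustment.  The test choice is this package's decision (the source
workflow names GO/KEGG usage without a statistic).  No DAG propagation.

## Synthetic study (`synthdata`)

The generator emulates the study's inputs at desk scale with a recorded
truth table.  Defaults: 100 kb genome over two chromosomes; 20 hairpin
loci; 8 conserved families (homolog tags spiked at 0/1/2 edits, each with a
planted genomic hairpin annotated as known miRNA); 3 contaminant features
per class (rRNA, tRNA, snRNA, snoRNA, repeat, exon, intron; 80–300 nt);
per-miRNA expression λ = 200 reads; true log2 fold changes cycling through
(−2, 0, +2); 21-nt matures; reads of 36 nt with the standard Illumina
small-RNA 3' adapter appended and phred-64 qualities (the adapter is a
configurable realism choice, not a claim about any particular study);
5% random degradation tags; read defects off unless enabled.

Construction is generate-and-verify.  Precursors are a sampled mature, an
8–15 nt loop, and the reverse complement of the mature with 2–3 G:U
wobbles; each planted locus must pass the exact excision-window check the
predictor applies, otherwise it is resampled.  The wobbles also break
reverse-complement symmetry (a G:U pair reads as an unpairable C:A on the
mirror strand), which is what lets the predictor recover the strand from
single-arm reads.  Per-source read counts are Poisson (λ for miRNAs in
control, λ·2^log2FC in treated, 50 per contaminant feature); degradation
noise adds exactly round(noise_tag_rate · library_depth) random 18–30-mers,
so the realized library size is the component sum plus the noise budget and
the truth table's per-source counts always equal the reads written.
Defects hit reads independently at the configured rate (N base, 5 bases
below Q10, 7 bases at Q10–12, truncated insert, missing adapter), making
per-filter acceptance exactly checkable.  Target transcripts carry, per
planted miRNA, a perfect-complement site, a compliant 2-mismatch site
(placement resampled until the scanner accepts it) and one violator per
rule i–v (mismatch placements chosen so the intended rule is violated;
heavy damage may additionally violate rule v, and the truth records the
intended rule); every site is verified through the scanner at generation.

What passing on this benchmark does not show: robustness to sequencing
error and ligation bias (reads are exact copies plus planted defects),
genome-scale repeat structure and multi-mapping ambiguity, dispersion
beyond Poisson (no biological replicates in the two-library design), and
agreement of the folding model's absolute energies with measured
thermodynamics (only its ranking behavior is exercised).

## Problem sizes and numerical choices

Desk-scale defaults (100 kb genome, ~15–20k reads per library, 20 loci)
keep a full end-to-end run around half a minute on one core; these sizes
are the package's chosen benchmark conditions.  Numerical constants:
tail-sum truncation 1e-15 relative; KS scan stops below 10 tags; fold
traceback tolerance 1e-6; length-distribution fractions sum to 1 within
1e-9.  Degenerate inputs are defined, not fatal: empty FASTQ gives an
empty table; a histogram with one distinct count returns threshold 1 with
a warning; a precursor window beyond chromosome bounds is truncated.
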