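# Methods

`wgdkit` implements a desk-scale pipeline for detecting, dating and
characterising whole-genome duplications (WGDs) from gene order and
synonymous divergence, together with a clade simulator that provides
ground truth for every stage. This note records the models, the defaults
and why, the numerical choices, and what the synthetic data do and do not
demonstrate.

## Ka/Ks estimation (Nei–Gojobori 1986)

Gene pairs are aligned in protein space (global alignment, BLOSUM62,
affine gaps: open −10, extend −0.5) and back-translated so gaps fall on
codon boundaries. The NG86 counting method is then applied:

- Per codon, each position contributes a fractional synonymous site count
  `s = (# synonymous single-base changes)/3`; changes that would create a
  stop codon count as nonsynonymous, which keeps the invariant
  `S + N = 3 × compared columns` exact.
- Codons differing at several positions are resolved by averaging
  synonymous/nonsynonymous step counts over all minimal substitution
  pathways; pathways through stop codons are excluded, and a column whose
  every pathway is blocked is dropped from both site and difference
  counts. Gap columns and columns with non-ACGT bases are excluded
  pairwise.
- Proportions `ps = Sd/S`, `pn = Nd/N` receive the Jukes–Cantor
  correction `d = −(3/4)·ln(1 − 4p/3)`; `p ≥ 3/4` is reported as a
  saturated estimate (flag, not an exception).

NG86 was chosen over ML codon models because it is closed-form and
exactly testable: the implementation is checked against an independent
exhaustive pathway-enumeration oracle over two-codon alignments, and
against the hand-computable four-fold-degenerate example (100×GCT vs
90×GCT+10×GCC ⇒ S=100, N=200, Ks=−0.75·ln(1−0.4/3)≈0.1073, Ka=0). The
universal nuclear code is used (plant nuclear genes); the code table and
the estimator choice are config hooks with one implemented member each.

## Clade simulator

Four species — two outgroups without the WGD, two ingroups sharing it —
descend from an ancestor of `n_genes` genes (default 200) on
`n_chromosomes` chromosomes (default 2). Defaults emulate a recent
shared WGD younger than the outgroup split and older than the ingroup
split: `wgd_age = 7.4` My, speciation ages (20, 3) My, synonymous rate
`syn_rate = 0.012` per site per My, so the expected paralog Ks peak is
`2 × 0.012 × 7.4 = 0.1776` and the expected ortholog divergence peak
`2 × 0.012 × 3 = 0.072` — the divergence-younger-than-WGD ordering the
shared-WGD test must recover. The nonsynonymous rate is
`ka_ks_ratio × syn_rate` (default 0.2, typical purifying selection).

Sequence evolution is a per-site Poisson substitution process with
multiple hits allowed, so the JC-corrected estimator is consistent. By
default all codons come from the eight families whose third position is
four-fold degenerate; third positions are then exactly synonymous sites
(one per codon) and first/second positions exactly nonsynonymous, making
expectations closed-form. Substitutions that would create a stop codon or
leave the four-fold set are redrawn among allowed bases; with
`fourfold_only=False` site categories are taken from the starting codon
and are approximate. Indels, codon-usage bias, recombination and TEs are
not modelled.

Post-WGD fractionation deletes whole genes (`loss_prob`, default 0.2 per
homoeolog pair per species), assigning the loss to subgenome B with
probability `loss_bias` (0.5 = unbiased). Tandem duplicates arise per
retained copy (`tandem_prob = 0.02`) at a shallow divergence
(`tandem_age = 1` My) and are inserted adjacent to their parent. Perfect
(TTTAGGG)n arrays (default 30 units) are planted at the 5′ end of each
chromosome with the reverse complement at the 3′ end; genes are separated
by 60 bp random intergenic spacers, giving ~50 kb chromosomes. All
randomness flows from one `numpy` SeedSequence; identical seeds give
byte-identical FASTA/GFF3/truth outputs.

Because real hit tables need a similarity search, synthetic runs use a
k-mer Jaccard scorer (k = 10, minimum Jaccard 0.03) in place of BLAST;
at the simulator's divergences homologs score ≥ 0.05 and unrelated genes
≈ 0.003, so the stand-in is cleanly separable. Real analyses consume
standard 12-column tabular hits (e-value ≤ 1e−10, top 5 non-self
subjects per query, best record per unordered pair — all configurable).

## Collinear blocks and duplicate classes

Anchors are chained per scaffold pair by an O(n²) dynamic program in both
orientations, with score = 10 per anchor − 1 per skipped rank unit,
strict monotonicity in both gene ranks, and a maximum rank gap of 25.
Blocks are extracted greedily by descending chain score (no anchor in two
blocks); chains shorter than `min_block = 5` are discarded — 5 is the
within-genome duplicate-calling default, while a span of 30 genes is the
convention for cross-species visualisation-scale blocks. Ties between
equal-score chains break toward the smaller starting rank, making the
output deterministic. The DP is validated against exhaustive chain
enumeration on anchor sets of ≤ 12.

Duplicate pairs are classified with precedence wgd > tandem > proximal >
dispersed: block anchors are wgd; otherwise same-scaffold pairs within
rank distance 1 are tandem and within 10 proximal; everything else is
dispersed. Gene rank is the strand-ignorant ordinal of gene starts per
scaffold. Syntenic depth of a reference gene is the number of blocks
covering its rank; the modal depth expresses the quota (2:1 for a
once-duplicated genome vs an unduplicated reference), with ties broken
toward the smaller depth so a tie never claims a duplication.

## Ks mixture model and dating

Ks values are filtered to [0.005, 3.0] by default — wide enough to admit
an ancient triplication peak near Ks 2, while excluding zero-inflation
from allelic/recent duplicates; saturated and non-finite estimates are
dropped. The mixture is fitted on log Ks with Gaussian components
(log-normal in Ks space), by EM with quantile-based initialisation plus
9 randomly perturbed restarts, `max_iter = 500`, tolerance ΔlogL < 1e−8,
and a component-sd floor of 1e−3 to prevent collapse. The
log-likelihood is asserted non-decreasing every iteration. K runs from 1
to 5 and is selected by minimum BIC (`p = 3K − 1`), ties toward smaller
K; fits need ≥ 50 values (configurable floor). Each component's peak is
reported as its Ks-space median `exp(μ_log)` — peaks behave like central
tendencies, and the median is invariant to the log transform, unlike the
log-normal mode; the choice is documented here and isolated in
`extract_peaks`.

A peak converts to an age by linear calibration
`age = calib_age × peak/calib_peak`; the default anchor is the
Brassicaceae alpha-WGD (Ks 0.85 at 35 My), under which Ks 0.18 dates to
7.41 ≈ 7.4 My. A WGD peak is called shared between two species when
their ortholog-divergence peak lies below it by more than a tolerance
(default 0.02 Ks), lineage-specific when above, ambiguous within.

## Telomere scan

The query is `motif × repeats` (default TTTAGGG × 3 = 21 bp) counted at
every start position — overlapping matches count, so a perfect array of
k units contains exactly k − 2 copies of the query — in non-overlapping
windows (default 1 Mb), forward and reverse complement. A window is
retained when the joint count reaches `min_count = 20` (a flag switches
to per-strand thresholds). Matches are assigned to the window containing
their start, so boundary-spanning matches are neither lost nor double
counted; N never matches. A scaffold is telomere-to-telomere when its
first and last windows are both retained; interior telomeric windows are
reported but do not make an "end".

## Fractionation and retention

Against an unduplicated reference, the two scaffolds of the duplicated
genome carrying most mapped genes per reference scaffold are the
homoeologs (ties by name). For each window of 100 consecutive reference
genes (non-overlapping by default; a step parameter makes them slide;
the pipeline's simulated runs use 25-gene windows to get enough windows
from 200-gene genomes), retention is the percentage of window genes with
a syntenic copy on each homoeolog. Bias is tested by a two-sided exact
sign test on per-window retention differences (zeros dropped; all-zero
gives p = 1) at α = 0.01 — a deliberate formalisation of what is usually
a visual call.

Pangenes are filtered to single-copy in both outgroups with each ingroup
in {1, 2} copies; rows with 0 or > 2 ingroup copies are excluded rather
than coerced. The four classes (retained in both / single in both /
retained in A only / in B only) partition the filtered set exactly,
checked by exhaustive enumeration over copy counts 0..3. GO
over-representation is a one-sided hypergeometric (classic Fisher) test
per term with expected counts `total × |group|/|universe|`; p-values are
reported uncorrected, the convention for exploratory GO scans, and
hierarchy-aware GO-graph algorithms (topGO's elim/weight family) are
intentionally not reimplemented —
GO maps are assumed pre-propagated to ancestors if that is wanted.

## What the synthetic data do not show

The simulator has collinear gene order by construction, no indels or
pseudogenes, perfect telomere arrays, and a homogeneous clock; real
genomes add alignment noise, rate variation, segmental rearrangement and
annotation error, all of which widen Ks peaks and fray blocks. Passing
recovery tests therefore demonstrates correctness of the computations and
their calibration logic, not robustness to assembly artefacts. Problem
sizes (200–300 ancestral genes, 150-codon CDS, 3,000-value mixture
samples) were chosen so every stage's sampling error sits well inside the
10% recovery tolerances while a full run stays interactive.
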