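# Methods

## Background and model

DNA polymerase ε synthesizes the leading strand of the replication fork.
Tumors with a damaged POLE exonuclease (proofreading) domain are
hypermutators whose characteristic errors — above all C→A in a TpCpT
context — are laid down on the leading strand only. Around a replication
origin the leading-strand template switches sides, so on the reference
plus strand the same mutational process is seen as TCT→TAT upstream of an
origin and as the reverse complement AGA→ATA downstream. Because somatic
mutations accumulate over many rounds of replication in vivo, this
asymmetry marks *constitutive* origins — those that fire in essentially
every cell cycle.

### The PMA score

For genome position `n`, with per-bin counts summed over patients —
`k_i^lead` (leading-strand-specific classes), `k_i^lag` (their reverse
complements) and `k_i^N` (all substitutions) — the asymmetry score is

    PMA_n = 4/W_n^2 * ( Σ_{i=n-d}^{n-1} k_i^lead * Σ_{i=n}^{n+d} k_i^lag
                        - Σ_{i=n-d}^{n-1} k_i^lag * Σ_{i=n}^{n+d} k_i^lead )
    W_n   = Σ_{i=n-d}^{n+d} k_i^N

`PMA_n ∈ [-1, 1]`: +1 at an ideally covered origin (every upstream
mutation lead-type, every downstream mutation lag-type, balanced counts),
−1 at the reversed pattern expected where two forks meet (termination).
The position's own bin belongs to the downstream sum, following the index
bounds above. `W_n = 0` masks the position (NaN) rather than forcing 0,
which would fake symmetry; masks propagate through smoothing.

The track-based scan computes this with prefix sums in 1-kb bins over a
±100-kb window (`d = 100` bins). `pma_at_positions` evaluates the same
sums at exact base-pair coordinates, free of binning; the binned scan
assigns the center bin wholly downstream, which costs ~0.005 of score at
an origin under ideal conditions.

### Detection pipeline

1. bin counts (1 kb) → PMA profile → moving-average smoothing (n = 100
   bins, centered, edge-truncating, NaN-aware);
2. peak picking: a bin is a candidate iff it is the maximum within
   ±neighlim (100) bins — strictly above the left window and at least as
   high as the right window, so an exactly tied plateau yields its
   leftmost bin; candidates closer than neighlim merge keeping the higher
   score; candidates with smoothed score < 0.1 are dropped (the threshold
   is a fixed configurable default; recomputing it as the observed median
   of peak scores is available as `use_median_min_score`);
3. peak localization: smoothing stabilizes detection but lets the
   maximum wander by up to half the smoothing window (~10 kb measured on
   planted-truth simulations), while the raw profile's maximum localizes
   the origin within ~1 kb; each smoothed peak is therefore refined to
   the raw-PMA argmax within ±smooth_n/2 bins before reporting;
4. filtering: per peak, a two-sided Fisher's exact test on the 2×2 table
   `[[Σup lead, Σup lag], [Σdown lead, Σdown lag]]` over the ±d window —
   exactly the contrast whose reversal PMA measures, power-limited by the
   mutation count, which is what the filter is for (it removes peaks
   supported by too few mutations). Benjamini–Hochberg correction runs
   across all peaks genome-wide; calls with q < 0.01 are kept.

Chromosome ends truncate windows; positions with under 10% of the
nominal window in-chromosome are masked.

### Two-stage detection and the 96 mutation types

Stage 1 uses only the two POLE-exo-specific types (TCT→TAT, TCG→TTG,
both orientations), after restricting to samples in which these types
make up at least 20% of all mutations (inclusive threshold; the selection
removes samples whose POLE variant is a passenger without a
strand-specific pattern).

Stage 2 broadens the class set. At the 1000 highest-scoring stage-1
origins, each of the 96 trinucleotide mutation types is profiled
per-sample: the type's PMA is computed with its C/A-reference observation
as the lead form and the type's own mutations as `W`, so every cell lies
in [−1, 1] and measures per-type asymmetry independent of abundance. A
positive column means the C/A form is leading-strand-specific. Columns
are clustered (agglomerative, Euclidean, complete linkage, k = 3 —
deterministic; masked cells enter as 0) into the most-positive cluster A,
most-negative cluster B, and a flat remainder. The combined scheme takes,
for each type in A, its C/A-reference observation as lead, and for each
type in B, its G/T-reference observation; the lagging set is the
element-wise reverse complement by construction. A type claimed by both
clusters is contradictory input and rejected. Stage 2 reruns the full
pipeline with this scheme.

## OK-seq fork directionality

Replication fork directionality per 1-kb window is
`RFD = (C − W)/(C + W)` from Crick- and Watson-strand read counts; +1 is
purely rightward-moving forks, −1 purely leftward, and an origin is an
upshift from −1 toward +1. Crick counts are rescaled genome-wide so the
strand totals match before RFD is computed. Windows with no reads are
masked. Origins are called at maxima of the ordinary-least-squares slope
of RFD over a sliding 200-kb window (assigned to the window center;
windows with under 50% unmasked values or fewer than 2 points are
masked), smoothed with n = 200 bins, using the same peak contract as
above with a default score threshold of 0 (no amplitude threshold is
applied, matching the procedure's stated use; one is configurable).
Input is a per-window stranded count table (two bedGraphs or a 4-column
TSV); BAM splitting is upstream of this package.

## NVA and MNVA

Two sets of origin positions on one chromosome, as sorted numeric
vectors A and B, are aligned by dynamic programming with

    S[i,j] = min( S[i-1,j-1] + |A_i - B_j|, S[i,j-1] + d, S[i-1,j] + d )

`S[0,0] = 0`, all-gap borders, minimization (the reverse of classical
sequence-alignment scoring: small distance = similar). The gap penalty
defaults to d = 1,000,000 bp-equivalents. Traceback ties prefer diagonal,
then the A-gap, then the B-gap move — diagonal preference maximizes
pairings at equal cost and fixes determinism. The score is the terminal
cell: paired |A_i − B_j| costs plus d per unpaired element. The consensus
averages paired elements and carries unpaired ones through, sorted.
Alignment is per chromosome; chromosomes present in one set only
contribute all-gap alignments. `pairwise_similarity` reports the total
score normalized by the combined element count (mean per-element cost;
the heatmap statistic is not specified more precisely anywhere, so this
normalization is this package's choice).

The multiple alignment (MNVA) proceeds in four steps: (1) all pairwise
NVA scores; (2) a neighbor-joining guide tree on the score matrix (scores
are used as distances unchanged: non-negative, zero on identity; built
once from genome-wide totals, the same leaf order serving every
chromosome); (3) progressive alignment in tree order — the two leaves
closest by patristic distance first, then accretion of the unplaced leaf
nearest the placed set, each vector aligned against the running consensus
whose columns hold the running mean of their members (the pairwise
consensus rule generalized); (4) each source vector re-aligned to the
final consensus without introducing new columns, i.e. a monotone
assignment of source elements to consensus columns minimizing the summed
distance — pairing to any column is allowed, including columns that were
gapped for other sources. Columns that end up empty are dropped. The
result is an n×m matrix whose row r, gaps removed, reproduces source r
exactly; per-column detection fractions and consensus positions support
agreement-threshold selection (≥ or strictly >, per flag).

Note one behavior of the minimizing recurrence worth keeping in mind:
with the default d = 10^6, positions hundreds of kilobases apart still
pair (pairing at distance x beats two gaps whenever x < 2d). The gap
penalty is the resolution knob, and comparisons should hold it fixed
across all pairs.

## Feature context

- **Enrichment profile**: feature elements (interval midpoints by
  default; a full-overlap mode bins every covered window) are assigned to
  their *nearest* origin only — no double counting between close origins
  — and histogrammed into 20-kb signed-offset bins over ±500 kb (the
  figure scale; both configurable). Each row is divided by its minimum
  (fold change); a zero minimum divides by 1 with a warning; empty
  feature sets drop the row.
- **Loop profile**: each origin is measured from the nearest chromatin
  loop anchor; interior offsets run inward from the nearer anchor, capped
  at the loop midpoint; exterior offsets run outward to 500 kb. Every
  loop tied at the nearest-anchor distance receives the origin (so
  co-anchored loops share it, and duplicating every loop scales counts
  and normalizer together). Interior bins are normalized by the number of
  loops whose half-length reaches that depth — loops are of unequal
  length, and without this the interior profile decays for purely
  geometric reasons; exterior bins are normalized by the total loop
  count.
- **Signal profile**: per-bin mean of probe values (e.g. methylation
  beta) by distance from the nearest origin; empty bins are masked.
- **Random positions**: uniform over the gap-excluded genome (or a
  restricted interval set), distinct, seeded. Uniform order statistics
  coincide with the event positions of a conditioned Poisson process, so
  inter-position gaps are exponential — the basis of the spacing check
  below.
- **Spacing statistics**: within-chromosome successive gaps of two
  position sets compared by medians, variances, and a two-sided Wilcoxon
  rank-sum test (p = 1 when every gap in both sets is identical). For
  uniform positions the median gap is ln 2 × the mean gap; a regular grid
  has far smaller gap variance than uniform at equal density.

## Synthetic data generator

The generator plants origins and emits the statistical structure the
detectors assume; it is first-class, tested code and the package's test
bed.

- **Genome**: by default one 20-Mb chromosome with 25 origins at least
  500 kb apart on a jittered grid — a desk-scale stand-in for a
  hypermutator cohort (20 samples, 50,000 mutations, orientation
  fidelity 0.9).
- **Mutations**: positions are uniform per bp (an origin's replicon draws
  mutations in proportion to its length); replicon boundaries are the
  midpoints between adjacent origins. An oriented type is emitted as its
  leading-strand form upstream of its origin and as the reverse
  complement downstream with probability `orientation_fidelity` f (and
  flipped otherwise); symmetric noise types are emitted in either
  orientation with probability 1/2. The default mix is dominated by
  TCT→TAT and TCG→TTG (so the 20% sample-selection rule passes), with a
  further C/A-led type (TCC→TAC), a G/T-led type (TTT→TGT) so both
  asymmetric cluster directions exist, and one symmetric noise type.
  Contexts are carried in the mutation table; a synthetic reference FASTA
  consistent with them can be written for exercising context annotation
  end-to-end (overlapping stamped contexts drop the contradicted
  records, reported).
- **Expected-score law**: substituting expected counts into the score
  gives mean PMA = 2f − 1 at a planted origin when every mutation is
  oriented and scheme-counted. The *exact* finite-count expectation with
  W window mutations is (2f − 1)(1 − 1/W) — verified in the tests by
  exhaustive multinomial enumeration at small W — so simulated means are
  compared against the finite-count form; the 2f − 1 limit holds to
  O(1/W). With a fraction ρ of mutations scheme-counted the plug-in
  value scales as ρ²(2f − 1).
- **OK-seq**: expected RFD is a sawtooth — +1 immediately after each
  origin, linear decay to −1 at the next. The simulated chromosome
  stands for an interior genomic window, not a telomere-to-telomere
  chromosome: virtual flanking origins sit one neighbor-spacing outside
  each end, so the outermost planted origins are flanked by decay
  segments like any interior origin. Per-window Crick reads are
  Binomial(depth, (1+RFD)/2); a deterministic mode emits the expectation
  so the empirical RFD equals the sawtooth exactly.
- **Feature tracks**: origin-coupled features (configurable offset and
  SD), uniform background, and loop anchors tied to a random subset of
  origins.

### What the generator does not emulate

Real human genome composition and its mutational covariates: replication
timing, transcription-coupled repair and expression-linked mutation-rate
variation, copy-number and clonality structure, assembly gaps and
mappability, flexible/dormant origins firing in a subset of cycles, and
origin-efficiency gradients. Passing recovery tests therefore shows the
estimators are correct under the model's assumptions — uniform background
rate, fixed fidelity, well-separated constitutive origins — not that real
cohorts will reach the same sensitivity.

## Numerical and procedural choices

- Internal coordinates are 0-based half-open everywhere; VCF/table input
  (1-based) converts on read; "1" vs "chr1" naming reconciles through a
  configurable alias map.
- Moving averages use centered windows with edge truncation and NaN
  exclusion; even window widths are half-bin asymmetric (window
  `[i−n/2, i+n/2−1]`), matching the slope scan's convolution window.
- The slope fit uses the closed-form OLS slope on window sums; x enters
  in bp so the slope's units are RFD per bp (a full −1→1 ramp across the
  200-kb window is 1×10⁻⁵ per bp).
- Agglomerative clustering and the NJ-derived leaf order are
  deterministic given the input; remaining ties break toward the lower
  input index.
- Problem sizes in the test-suite simulations (20-Mb genomes, 4–10 Mb
  law/recovery studies, 50-replicate ensembles) were chosen to give the
  recovery and law checks clear statistical margins at desk scale.

## Known limitations

- Peak localization degrades when neighboring replicons differ strongly
  in length: the wide smoothing windows (100 bins for the mutation scan,
  200 for the OK-seq slope) shift the smoothed maximum toward the longer
  replicon. Raw-score refinement compensates for the mutation scan; the
  OK-seq caller reports the smoothed-slope maximum, and on strongly
  jittered origin spacings its error can exceed ±5 kb.
- Termination zones appear as local minima of the PMA track but no
  minima-calling procedure is defined; only the raw track is exposed.
- The NVA gap penalty must be held fixed across compared pairs; sets of
  very different sizes (e.g. >100k positions vs ~5k) are not meaningfully
  comparable under one penalty.
- The Fisher filter tests the up/down lead–lag contrast only; it does
  not model overdispersion across patients.
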