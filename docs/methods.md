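# Methods

This note documents the models, estimators and numerical choices behind
each pipeline stage, the synthetic-data generators used to validate them,
and the limitations of both.

## Coordinates and randomness

All genomic coordinates are 0-based, half-open, repo-wide. Every
stochastic routine draws from a single `numpy.random.Generator`; a fixed
seed reproduces byte-identical outputs. Traversals of graph and tree
structures are explicitly sorted so results do not depend on Python's
hash randomization.

## Sequence simulation (JC69)

`simdata.simulate_lineage_sequences` evolves sequences site-independently
along a rooted clock tree. The per-branch transition is the exact
Jukes–Cantor kernel: a site differs from its parent with probability
p(t) = (3/4)(1 − e^(−4μt/3)), landing uniformly on one of the three other
bases, so steps compose correctly along a path and the expected pairwise
difference between two tips separated by total time t is p(t). With the
default μ = 1, branch times are expressed directly in expected
substitutions per site; the default five-lineage tree uses a deep split
of 0.011 per branch (≈ 2.2 % pairwise divergence, the observed
divergence between the two deep parental lineages), hybridization ages of
0.002 and 0.0003 (old and young hybrid, in proportion to the reported
≈ 18,500- and ≈ 2,600-year ages against a 100,000-year deep split), an
outgroup depth of 0.02 and 0.0005 of within-lineage divergence.

The simulator rejects polytomies and negative branch lengths. It does
not model recombination within regions, indels, rate heterogeneity or
selection; dating tests on it therefore validate the estimator algebra
and its calibration, not robustness to those features of real data.

## Mosaic hybrids and ancestry painting

`simulate_hybrid_mosaic` alternates parent-A and parent-B blocks with
exponential lengths — a memoryless crossover model. Donor-B blocks have
mean equal to `mean_block_length` (default 10 kb); A-block means are
scaled by (1−f)/f so the process is stationary at donor fraction f
(default 0.5, the reported genome composition of the young hybrid).
Truth segments tile the chromosome base-exactly.

The triplet scan classifies **informative sites** (parents differ, focal
matches exactly one) and turns maximal same-parent runs into segments.
Segment bounds snap to the outermost supporting informative site — not
the midpoint of the flanking gap — a deterministic convention that
slightly undercalls block length but never crosses a true breakpoint by
more than one informative-site gap. A configurable `max_opposing`
parameter (default 0) absorbs short opposing runs for noisy data. Painting
is symmetric: swapping the parents swaps donor labels and preserves
breakpoints exactly.

The gene-level criterion marks a gene `fixed_introgressed` only when
every focal strain's *largest* JC69 distance to the donor panel is
strictly below its *smallest* distance to the recipient panel; ties and
saturated distances give `ambiguous`. Sites with non-ACGT characters are
excluded pairwise everywhere. Merging concatenates same-donor neighbours
with gaps ≤ 5,000 bp (inclusive boundary); differing donors never fuse.

Recovery under the defaults (2 % parental divergence, 10 genomes of
500 kb): base-level accuracy ≈ 0.99 with unassigned inter-site gaps
counted as errors, and donor-fraction error < 0.01.

## Divergence dating

`polarize_and_count_patterns` drops columns with missing data or more
than two alleles, labels the allele matching the outgroup "A" and the
other "B". The estimators implement the private-derived-variant formulas
(see README). Two counts are kept per region: `n_sites`, all retained
columns, and `n_informative`, the polarized variable sites. The
denominator N defaults to `n_sites`, which makes T1/T2 per-site
divergences directly comparable to clock times; the ≥1000-site region
filter applies to `n_informative`, and `denominator="informative"` is
available. The four-taxon weights follow the same branch-averaging logic
as the five-taxon formulas (average the two private-derived branches for
T1; add the shared-derived and sister-clade terms, halved, for T2); they
are an interpretation, since only the five-taxon version is written out
in closed form.

Calibration to years is a linear rescaling utility only
(`calibrate_to_years`); the analysis driver instead anchors on the deep
split (0.011 substitutions/site ≡ 100,000 years).

Validation: the regression of mean T1-hat on the true young-split time
across five settings (0.001–0.005, 200 regions of 2 kb each) has slope
≈ 0.95 — the ≈ 5 % downward bias comes from sites lost to multiple hits
on other branches (excluded three-allele columns and converted patterns)
and is inherent to the estimator, not the implementation. A 10×-younger
hybrid is declared significantly younger (one-sided Mann–Whitney on
13-vs-13 per-region T1, 5-kb regions) in ≈ 100 % of replicates.

## f4 statistics and admixture graphs

`compute_f4` is the plain product-moment estimator
mean[(p1−p2)(p3−p4)] with a delete-one block jackknife over contiguous
blocks of 500 SNPs (the SE source is delegated in the original analysis
to an external program that does not state its block size; 500 is this
package's fixed choice). Sign convention: pair 1 minus pair 2 times pair
3 minus pair 4, everywhere.

Expected f4 on a graph follows the drift-covariance rule: each leaf's
ancestry weight on every drift edge is computed by walking rootward,
splitting α/(1−α) at admixture nodes; the expectation is
Σ_e (w1−w2)(w3−w4)·c_e. Fitting exploits that for fixed admixture
proportions the expectations are linear in the edge lengths: each cost
evaluation solves a weighted non-negative least-squares problem (NNLS),
and the one or two proportions are optimized by bounded L-BFGS-B from
uniform-random restarts. The cost is Σ((expected−observed)/se)²;
`fit_fraction` is the share of restarts whose optimum leaves every
residual within 3 SE of its observation. Ranking is by cost, with ties
broken by fewer admixture events and then model id, so it is invariant
to candidate order.

Two structural facts shaped the candidate family (`models.py`,
`data/models.json`):

1. Distinct-population f4 statistics on five populations span only a
   5-dimensional space, so the graphs are kept *minimally parameterized*
   (stems subdivided only where an admixture source needs an intermediate
   node). With redundant internal edges the mixing proportions of the
   nested-hybridization model lie on a zero-cost ridge and are
   unidentifiable; with the minimal parameterization they are recovered
   exactly from noiseless expectations.
2. The exact mirror of M01 (the young lineage as the primary hybrid and
   the old hybrid derived from it) generates the *same* f4 expectation
   family and cannot be distinguished by cost; the shipped family
   therefore includes an independent-twin-hybrids shape instead of the
   mirror. M01 and M02 remain distinguishable as long as the old hybrid
   accrued appreciable post-hybridization drift before the backcross
   (`cs_drift`, default 0.005).

The frequency simulator drifts the root frequency (uniform on
[0.25, 0.75]) along each edge with independent normal perturbations of
variance equal to the edge length, clipped to [0, 1], and mixes at
admixture nodes — a truncated-normal approximation to genetic drift that
is accurate for small edge lengths (≤ ~0.01, the default regime) and
biased when cumulative drift variance approaches the distance to the
frequency boundaries. Under the defaults (100k SNPs), the true model
ranks first in ≈ 100/100 seeds and α is recovered to ±0.02.

## Rearrangement parsimony

Ancestral signed-permutation reconstruction (a genome-median problem,
NP-hard) is replaced by a surrogate: each maximal run of blocks that is
reversed-and-negated relative to a chosen reference genome is one
candidate inversion event, each maximal run relocated across chromosomes
one candidate translocation, and genomes sharing the identical run share
the binary character. Chromosome correspondence is by index. The
surrogate reproduces per-branch event placements and conflict calls — the
quantities of interest — without reconstructing ancestral genomes.

Topologies are nested `(left, right)` tuples canonicalized by sorting
children on their smallest leaf; enumeration inserts each new leaf on
every edge (including above the root), yielding exactly (2n−3)!! distinct
rooted bifurcating trees (945 at n = 6; guarded to n ≤ 8). Fitch
small parsimony is validated against exhaustive internal labeling on
1,000 random six-leaf instances. Ranking is ascending total changes with
canonical-newick tie-breaks; events needing ≥ 2 changes on a topology are
reported as conflicting. Uninformative (all-0/all-1) columns are dropped
with a warning.

The event generator plants disjoint runs with a one-block buffer between
them: id-adjacent runs can fuse into a single rearranged run in a genome
carrying both (e.g. two translocations appended to the same chromosome),
which would make the planted truth ambiguous. Events are excluded from
branches containing the reference genome so detected polarity matches the
truth. Block filtering drops blocks < 500 bp (strict) in any genome
where present and, by default, blocks absent from any genome.

## Growth phenotypes

Curves are per-time replicate medians (never means) of log2 colony size
after removing zero-size or flagged entries, baseline-subtracted, with
optional truncation (80 h in the original setting) and a ≥ 5-point
validity requirement. AUC integrates a cubic smoothing spline with
GCV-chosen smoothing (`scipy.interpolate.make_smoothing_spline`); on an
exactly linear curve it reproduces mT²/2 to machine precision. MS is the
98th percentile (linear interpolation between order statistics) of
least-squares slopes in overlapping 5-point windows with |r| > 0.8 —
the absolute value keeps death-phase windows available; on monotone
growth data it coincides with the positive-r reading. ECS is the final
value. Flat windows (zero variance) have undefined r and are skipped; a
curve with no passing window gets MS = None.

The mid-parent statistic d uses the absolute half-difference of parental
medians as denominator, so parents map to ±1 with the sign tracking the
larger-median parent, and d is invariant under both parent-label swap
and any common affine transform of the data. Equal parental medians make
d undefined (flagged per condition). Hybrid-vs-parent comparisons test
"hybrid greater than the lower parent" and "hybrid less than the higher
parent" one-sidedly, and flag conditions where the hybrid's median d
exceeds both parents (transgression screen).

`mann_whitney_u` uses the exact null distribution when the smaller
sample has ≤ 8 observations and there are no ties, and the tie-corrected
normal approximation with continuity correction otherwise, reporting
which branch ran. The exact branch is checked against full enumeration
of all C(n+m, n) orderings in the tests.

The growth generator produces logistic curves in log2 units with
log-additive Gaussian noise (default SD 0.1, 12 replicates); its truth
metrics (AUC, MS = rK/4, ECS) are closed-form.

## 3′-tag counting

The initial window is strand-aware: [end−100, end+300) for + genes,
mirrored for −, clipped at chromosome ends with a warning. Extension
proceeds in 100-bp bins independently on each side: a bin is appended
while its read sum is non-zero and at least `min_reads` (10) **or** at
least `min_frac` (10 %) of the current peak; extension stops when the bin
falls below both thresholds. Both comparisons are inclusive (a bin
summing exactly 10 extends). The stop rule is the complement of the
"valley" description — a bin low by *both* criteria ends the window; the
alternative reading (stop when low by either) would halt a 10-read bin
next to a 200-high peak, contradicting the intended boundary behaviour.
The peak is the maximum single-base coverage in the current window,
recomputed after every accepted extension. Counts are the coverage mass
in the final window divided by the read footprint (default 1 = raw
coverage sum; set to the read length when the track was built from
full-length read placements). Overlapping final windows of neighbouring
genes are both counted and flagged.

The coverage generator places fixed-width read footprints (50 bp) at the
3′ gene boundary with rounded-normal jitter (SD 20 bp); under these
defaults the counter recovers the planted count exactly for ≈ 100 % of
500 genes.

## Problem sizes

The validation experiments run at: dating slope — 5 split times × 200
regions × 2 kb; young-vs-old — 100 replicates × 13-vs-13 regions × 5 kb;
painting — 10 genomes × 500 kb; admixture recovery — 100 seeds × 100k
SNPs × 15 models × 3 restarts; Fitch oracle — 1,000 instances;
planted-topology ranking — 100 trials × 945 topologies; tag counting —
500 genes. These sizes give stable Monte-Carlo rates while keeping the
full suite in the low minutes on one CPU.

## Known limitations

- The drift simulator is a truncated-normal approximation, not
  Wright–Fisher; expectations are biased for large edge lengths.
- f4-only fitting cannot distinguish mirror-nested hybridization
  scenarios (see above); resolving them needs f2/f3-level information or
  non-frequency evidence (block lengths, rearrangements), which is
  exactly the corroborating role the other stages play.
- The painting model has no probabilistic error model (no HMM, no
  phasing); accuracy claims hold for clean mosaic simulants at ≈ 2 %
  parental divergence.
- The rearrangement surrogate does not compute inversion distances or
  ancestral genomes, and relies on a rearrangement-free reference genome
  for polarity.
- One statistical behaviour claim is *not* met by design of the test
  itself: a one-sided Mann–Whitney on 50-vs-50 exponential block lengths
  with a 2× median ratio has true power ≈ 0.91, so "detected in
  ≥ 95/100 simulations" is unattainable under those exact conditions;
  the detection-rate experiment reports the honest rate.
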