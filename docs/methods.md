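# Methods

This note documents the models and procedures implemented in `micasm`,
the defaults they use, and the design choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The experimental design being modeled

A serial-transfer press-disturbance experiment: five arms — a
micropollutant-free control, bisphenol A (BPA, 1 µg/L), triclosan
(TCS, 1 µg/L), their mixture (MI), and a four-compound mixture
(MII: BPA 1 + BPS 0.1 + TCS 1 + TCC 0.1 µg/L) — each with three
replicate bottles, transferred every 5 days for 7 batches (35 days).
Each transfer moves 10% of the volume (60 of 600 mL) into fresh medium
with a fresh compound spike. Chemistry is measured at days 0/2/5 of
every batch; the community is sequenced once per bottle per batch
(105 samples). BPA/BPS elicit a *subsidy* response (usable as carbon
source), TCS/TCC a *stress* response (growth inhibition); the analogs
are modeled as scaled copies of their parent compounds at 10× lower
concentration, with no compound–compound interaction terms.

## Synthetic experiment generator (`synthio`)

The generator is first-class, tested code; it supplies every downstream
stage with data and ground truth.

**Phylogeny and traits.** A random coalescent tree (pairwise merges,
exponential waiting times at rate k(k−1)/2) over `n_otus = 150` tips.
Stress tolerance is a Brownian-motion trait on the tree (rate
`trait_bm_sigma = 1`), mapped through a logistic to (0, 1) with root
value 0.5 — so tolerance is phylogenetically conserved and selection
for it produces clustered communities detectable by nearest-taxon null
models. Degrader status is an independent Bernoulli draw
(`degrader_fraction = 0.2`, a minority guild). 16S copy numbers
(1–15) follow the rank order of an independent Brownian trait;
5% of OTUs are left unassigned in pipeline runs to exercise
missing-data handling.

**Latent dynamics.** Each bottle starts from a shared regional pool
(Dirichlet(1) relative abundances). At inoculation a bottle activates
each taxon with a per-taxon *resuscitation propensity* drawn once per
experiment from Beta with mean `activation_fraction = 0.35`
(concentration 1), then jitters active weights lognormally
(`activation_sigma = 0.2`). This emulates stochastic wake-up from the
seed bank: which taxa dominate a given bottle is genuinely random, but
taxa differ persistently in how often they appear — so sample occupancy
carries real information, matching the occupancy-weighted null models
downstream. Within a batch, per-day growth multiplies each OTU by
`exp(base + s·(gain·degrader·C_subsidy − penalty·(1−tolerance)·C_stress))`
(base 1/day, subsidy gain 0.05, stress penalty 1.0, both scaled by the
current concentration relative to a 1 µg/L reference and by
`selection_strength` s; s = 0 is the neutral regime). Demographic drift
is a daily multinomial resample of the pool at a fixed effective size
(10 000); each transfer applies independent binomial thinning at 10%
(with a one-cell guard so a line is never sterilized). Sequencing is a
multinomial draw of 36 000 reads from the latent composition — the
common rarefaction depth of the workflow.

**Chemistry.** Total biomass recovers logistically from 10% after each
dilution (discrete per-day Euler step, rate 1/day, capacity 1).
Per compound, concentration decays as `C ← C·exp(−k·B_resp)` per day,
where `B_resp` is degrader biomass (subsidy) or tolerance-weighted
biomass (stress). No kinetic constants are published for this system;
`decay_coupling = 3.0` (subsidy) and `stress_decay_ratio = 0.1` were
fixed once so the reference design lands in the reported operating
range of the experiment — most of the subsidy compound removed within
a batch (>80%) and under 60% of the stress compound — and were not
revisited. Analog compounds share their parent's kinetics, so their
*fractional* removal is identical by construction. Abiotic bottles
(`abiotic=True`) carry zero cells and therefore remove nothing; a
pre-exposure scenario (`preexposed=True`) up-weights degraders and
tolerant taxa in the inoculum.

**What the generator does not emulate.** Sequence-level artifacts
(chimeras, primer bias), compound interactions (e.g. TCS inhibiting
BPA degraders is *emergent* from growth suppression, not an explicit
interaction term), seasonal immigration, and real taxonomic structure.
Passing tests therefore demonstrate correctness and calibration of the
statistics on data with known truth, not that real communities behave
this way.

## Null-model partitioning (`assembly`)

βMNTD is the abundance-weighted mean distance from each taxon present
in one sample to its nearest relative present in the other, averaged
over both directions; abundances are renormalized over each sample's
support, and the matrix is the patristic (cophenetic) distance of the
rooted tree. βNTI standardizes the observed βMNTD against
`n_null = 999` randomizations that permute taxon identities across the
tips of the pool's phylogeny. It is computed as a **z-score**
(observed − null mean)/null sd: the ±2 thresholds are z thresholds, and
a null with zero spread (e.g. a star phylogeny, or a pair whose joint
support covers the whole pool so every βMNTD is 0) raises a degenerate
error rather than returning a value.

RC_bray builds, per replicate, two null samples: each draws its
observed richness from the regional pool without replacement with
probability proportional to occupancy frequency, places one individual
on every drawn taxon (so null richness equals observed richness), and
distributes the remaining observed total by a multinomial proportional
to regional relative abundance. The observed Bray–Curtis is positioned
in the null distribution with ties half-weighted and rescaled to
[−1, 1].

Classification: βNTI > +2 → variable selection; βNTI < −2 → homogeneous
selection; otherwise RC_bray > 0.95 → dispersal limitation,
RC_bray < −0.95 → homogenizing dispersal, else drift. The selection
sign convention follows the standard quantitative framework (observed
phylogenetic turnover above the null means divergent, i.e. variable,
selection); an `inverted` option swaps the two selection labels.

The regional pool for both nulls defaults to the union of taxa observed
in the two compared groups *within the phase* (so phases are
self-contained); a `global` pool mode uses the whole comparison.
Pairs are all treatment-sample × control-sample combinations whose
batches fall in the same growth phase. Per-pair seeds derive from one
`SeedSequence`, making runs reproducible and order-independent.

## Dissimilarity–overlap analysis (`doc`)

Relative abundances per sample; for each unordered within-treatment
pair, overlap is the mean shared-taxon mass and dissimilarity is the
root Jensen–Shannon divergence of the shared fractions renormalized to
sum to 1. Base-2 logarithms put rJSD in [0, 1]. Pairs with no shared
taxon are excluded (counted, not an error). The slope is an OLS fit on
pairs with overlap above the cutoff (median overlap by default, or a
supplied constant). The bootstrap resamples **samples** (not pairs,
which are not independent) with replacement, rebuilds the pair cloud
under the original cutoff, skips pairs formed by two copies of the same
original sample, and reports the fraction of successful refits with a
negative slope (`n_boot = 1000`). Degenerate refits (under 3 points or
zero variance above the cutoff) are excluded from the denominator.
The reported statistic is the raw fraction; its interpretation as a
"P value" is left to the caller.

## Growth phases (`copynum`)

The community trait is the abundance-weighted mean 16S copy number over
the OTUs with an assignment (relative abundances renormalized over the
assigned subset; an uncorrected read-based weighting by default, with a
copy-number-corrected mode available). Batch profiles — vectors over
treated microcosms of mean copy number, controls excluded — are
clustered by complete linkage on Bray–Curtis dissimilarity and cut at
K = 3. If the cut is not contiguous in batch order (or is degenerate),
the assignment falls back to an exhaustive search over the C(n−1, K−1)
contiguous partitions minimizing within-phase variance; ties break to
equal-as-possible phase sizes, then earliest cut positions, making the
rule deterministic.

## Ecological grouping (`ecogroups`)

Counts are normalized by median-of-ratios size factors (geometric-mean
reference over OTUs with positive geometric mean; a pseudocount mode
covers sparse tables, and pipeline runs use pseudocount 0.5). For each
OTU prevalent in ≥10% of a treatment's samples, six one-sided phase
contrasts are tested with the rank-sum test (exact by enumeration up to
pooled size 12, tie-corrected normal beyond); Benjamini–Hochberg
adjustment is applied **jointly across all OTU × contrast tests within
the treatment** (the conservative family choice), at α = 0.05.
Sensitive ⟺ phase 1 > phases 2 and 3; opportunistic ⟺ phase 2 > 1 and
3; tolerant ⟺ phase 3 > 1 and 2; otherwise unclassified. The
directional contrasts conflict, so categories are mutually exclusive by
construction. This rank-based test is a deliberate, documented
substitute for a negative-binomial Wald test: borderline calls will
differ from an NB-GLM analysis, and a pluggable test-function hook
accepts any alternative p-value source.

## Removal and turnover statistics (`community`)

Removal per (microcosm, compound, batch) is
`100·(C_day0 − C_day5)/C_day0`, using the day-0 spike as the reference;
negative values (apparent production) are reported as-is, and a zero
day-0 concentration skips the record with a logged warning. Rarefaction
is a multivariate-hypergeometric subsample (without replacement) to a
common depth; the pipeline refuses to drop samples below depth rather
than discarding them silently. Turnover regression fits OLS of
treatment-vs-control Bray–Curtis dissimilarity (all cross pairs within
a batch by default; a replicate-matched mode exists) against incubation
day, and compares the first batch's dissimilarities against each later
batch with the rank-sum test.

## Numerical choices and problem sizes

* Exact rank-sum enumeration up to pooled n = 12 (C(12,6) = 924
  assignments, vectorized via the midrank identity
  U = R_a − n_a(n_a+1)/2); beyond that the tie-corrected normal
  approximation with continuity correction. On continuous data at
  n = 6 + 6 the two agree to ~0.01 on average.
* βNTI permutations are processed in vectorized blocks of 250; RC_bray
  uses Gumbel top-k weighted sampling without replacement.
* Ties in the RC_bray position count half, and equality is tested at
  1e−12 absolute tolerance.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; identical config + seed gives
  byte-identical reports.
* Validation-heavy multi-seed checks (regime recovery, classification
  recovery) run the two-arm Control + TCS design at the default size
  (150 OTUs, 36 000 reads) with `n_null = 199`; the single-run
  reference analysis uses the full five-arm design with
  `n_null = 999`. Calibration summaries use 200 pairs at
  `n_null = 999` spread over five independent trees.

## Known limitations

* The growth phases inferred from copy-number clustering are
  data-dependent; on synthetic runs the boundaries need not fall at the
  canonical (B1–B2)(B3–B4)(B5–B7) partition, and validation checks pin
  that partition explicitly where a fixed phase structure is required.
* The Raup–Crick null cannot represent latent demographic noise beyond
  read-depth resolution; communities whose divergence exceeds what the
  occupancy/richness lottery can produce are classified as dispersal
  limitation, which in serial-transfer designs is a faithful reading of
  the bottleneck-driven divergence but blurs into drift.
* DESeq2-style shrinkage is intentionally not reimplemented; group
  calls are rank-based (see above).
* No NMDS/PERMANOVA/Procrustes/Mantel ordination statistics; those are
  standard library territory and outside this package's scope.
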