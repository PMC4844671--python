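# Methods

`invnet` implements the analytical machinery for studying pairwise
invasibility among competing microbial strains — the kind of screen in
which every ordered pair of a strain panel is competed twice, once with
each strain as the abundant *resident* and once as the rare *invader*,
and the invader is scored by whether it rises to a stated fraction of the
community.  This note records the models, the statistics, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## Invasion and inhibition networks

The primitive observable is ternary: for an ordered pair (invader i,
resident j), i either invades j, fails to invade, or the competition is
missing (failed or ambiguous experiment).  The package stores this as an
n x n matrix with rows = invader, columns = resident, diagonal missing by
construction.  Inhibition, measured by a cross-streak assay, is the
analogous binary matrix (rows = inhibitor).

Each unordered pair falls in one of four categories from its two ordered
entries: **bistable** (neither invades: whichever strain is common
persists — positive frequency dependence, "survival of the common"),
**hierarchical** (exactly one invades), **coexistence** (mutual
invasion — each increases when rare), or **incomplete** (any entry
missing).  Every downstream statistic excludes incomplete pairs and
reports how many were excluded.  Replicate isolates are ordinary distinct
labels; no automatic merging or consensus policy is applied, because a
principled consensus depends on experiment-specific information the
matrix does not carry.

## Triad motifs

With four possible states per unordered pair, a triple of strains admits
4^3 = 64 labeled configurations which collapse into exactly 16 classes
under node relabeling — the classical directed-triad types, named here by
their standard MAN codes (003 ... 300).  The class table is built at
import by brute-force canonicalization (minimum over the 6 node
permutations of the triple's adjacency matrix); class labels come from
the standard triad typing, and the partition is cross-checked in the test
suite against an independent orbit enumeration and against
`networkx.triadic_census`.

The census counts all C(n,3) triples (triples touching a missing entry
are excluded and reported).  Enrichment compares the observed census to
random networks that preserve the *number* of each pairwise link type
(0, 1 or 2 invasions) while placing the types on pairs by a uniform
permutation and drawing the direction of single invasions uniformly.
Re-randomizing single-invasion directions (rather than preserving each
pair's observed direction) is the deliberate default: the null is
constrained only by the count of each link type.  Empirical p-values use
the add-one convention p = (1 + #extreme) / (1 + n_null), so a finite
null set never yields p = 0.

## Hierarchy inference

A hierarchy assignment maps each strain to an integer level (larger =
higher).  Its score sums, over every observed directed invasion i -> j,
a reward (+1) if h(i) > h(j), a penalty (−1) if h(i) < h(j), and zero for
equal levels; missing entries contribute nothing.  Reward and penalty
magnitudes are configurable but only their ratio can change the optimal
ordering; a `gap_weighted` flag makes the penalty scale with the number
of levels climbed.  Invasions between equal-level strains are unscored on
purpose: same-level (typically bistable) pairs carry no ordering
information.

Two optimizers:

* `exhaustive_optimal` enumerates all level assignments in 1..n
  (lossless after canonicalization onto levels 1..L with no gaps) and
  returns the complete set of canonical co-optima.  It refuses n > 7.
* `search_optimal` runs multi-restart local search: each restart starts
  from a uniformly random ranking and greedily applies the first
  improving move in a seeded random scan, where moves are single-strain
  level changes *and* pairwise level swaps.  Swap moves matter: with only
  single-strain moves the search can stall in states where two strains
  share a level and the only free level is far from both.  The default of
  1,000 restarts reflects the scale at which the optimum is found in a
  large majority of restarts for panels around n = 18; the fraction of
  restarts attaining the best score is reported as a convergence
  diagnostic.

A planted strict hierarchy with all invasions pointing down is recovered
exactly (the optimum is unique and equals the planted order).  With a
fraction q of invasions flipped upward, recovery has an identifiability
ceiling: a flip between *adjacent* ranks produces a matrix that is a
perfect hierarchy of the adjacent-transposed ranking (its score exceeds
the planted ranking's by 2), so no scoring method can prefer the planted
order there.  The package's recovery checks therefore assert exact
recovery (Kendall tau = 1) in the noiseless case and
score-at-least-planted under flips, reporting tau.

The inhibition-excluded variant drops from the score all invasions within
pairs showing inhibition in either direction, then averages each strain's
level over the set of unique canonical co-optima (arithmetic mean), since
excluding pairs typically leaves score ties.

## Permutation tests for inhibition-invasion association

All inference is permutation-based; no parametric tests are used.  The
inhibition null randomizes the matrix preserving the number of each
pairwise link type (0, 1, 2 inhibitions), as for invasions above.  The
association statistic for ordered-pair questions is the enrichment ratio
of a 2 x 2 table — (invasions : non-invasions with inhibition) over
(invasions : non-invasions without) — with a Haldane 0.5 added to every
cell when any cell is zero (flagged, and applied consistently to observed
and null statistics).  One-sided directions:

* **resident protection** (does A inhibiting B protect A from invasion by
  B?): extreme = ratio ≤ observed;
* **invader advantage** (does A inhibiting B help A invade B?): extreme =
  ratio ≥ observed;
* **gap-controlled invader test**: the invader-advantage question
  restricted to ordered pairs 1–3 hierarchy levels apart (default
  gap_max = 3), with the permutation shuffling inhibitions only within
  the restricted pairs while preserving the counts pointing up and down
  the hierarchy.  This controls for inhibition's downward bias along the
  hierarchy, which otherwise confounds the pooled table (Simpson's
  paradox); extreme = ratio ≤ observed;
* **hubs of bistability**: statistic = summed bistability degree of the
  top three strains, null = link-type-preserving invasion randomization,
  extreme = ≥ observed;
* **bistability enrichment with inhibition**: statistic = bistable
  fraction among inhibition-bearing pairs over bistable fraction among
  inhibition-free pairs (a pair "has inhibition" if either direction
  does), extreme = strictly greater than observed; outlier strains can be
  excluded from both matrices first.

Add-one p-values on discrete statistics are mildly conservative; the
calibration suite verifies that each test's false-positive rate at the
5% level, on data generated under its own null, stays within three
binomial standard deviations of 5% (200 replicates of 12-strain networks,
199 permutations each), and small instances are checked against exact
enumeration of the permutation space.

## Inhibition-zone population model

Species i grows at rate g_i > 0 discounted by the inhibition it receives:
f_i = g_i exp(−Σ_j K[j,i] X_j), with K[j,i] ≥ 0 the inhibition-zone area
species j projects onto i and X the relative-abundance vector.  Relative
abundances follow replicator dynamics dX_i/dt = X_i (f_i − Σ_j X_j f_j),
which conserve the simplex.  This is the minimal multi-species form
consistent with the two-species boundary fitness f_invader =
g_invader e^{−K_resident}; producers derive no immediate benefit from
inhibiting, and antibiotic degradation appears only implicitly as reduced
effective K.

Closed-form invasibility: i invades resident j iff g_i e^{−K[j,i]} > g_j,
strictly; ties within 1e−12 count as non-invasion.  The induced ternary
matrix feeds all network analyses.

**Theorem (bistable pairs in coexisting communities).**  Any set of
species coexisting under these dynamics contains at least one bistable
pair.  The fastest grower must be inhibited by some community member
(else it unconditionally wins); pair it with its strongest inhibitor.
Were that pair not bistable, the fastest grower's minimum fitness over
community states would exceed the inhibitor's maximum fitness, excluding
the inhibitor — contradicting coexistence.  The package verifies this by
Monte-Carlo: sample models, detect coexisting sets by integration, and
count closed-form bistable pairs inside each detected set.

### Numerical choices

* Integration: adaptive RK45, rtol 1e−8 / atol 1e−10; output states are
  clipped at zero and renormalized onto the simplex, with the worst
  pre-correction drift reported (observed ~1e−8, asserted ≤ 1e−6).
  Species starting at exactly zero stay at zero.
* Coexistence detection: integrate from the barycenter plus Dirichlet(1)
  interior starts; a species persists if X_i ≥ 1e−3 at the horizon
  (default 1000 time units).  Two safeguards prevent transients from
  masquerading as coexistence.  First, the horizon doubles (up to 64x)
  while any above-threshold species is monotonically declining and the
  state has not converged (sup-norm change < 1e−6 over the second half of
  the run); limit cycles stop immediately because their trajectories are
  not monotone, so persistent cycles still count as coexistence.  Second,
  every candidate set is re-verified on its own face: the model is
  restricted to the set and re-integrated from the renormalized final
  state, iterating while the set shrinks — only self-sustaining sets are
  reported.  Residual limitation: growth-rate ties finer than ~1e−7 can
  outlast the capped horizon; under the default sampler this affects of
  order 1 in 10^4 runs.
* Theorem Monte-Carlo: 500 models per run, species counts 3–5, growth
  rates uniform on (0.5, 1.5), inhibition entries present with density
  0.5 and exponential magnitude (mean 1), plus a 20% admixture of
  equal-growth cyclic-inhibition models that guarantee detected
  coexisting sets so the check cannot pass vacuously; 5 interior starts
  plus the barycenter per model, chosen to keep a run in minutes on one
  core while leaving set detection unchanged on spot checks against
  larger start counts.

## Sequencing background model and invasion calling

Communities are demultiplexed by dual (i5, i7) indices.  Index hopping
misassigns a small fraction of reads to a wrong i7 within their i5 group:
a read hops into index i7 with probability epsilon x N(i7)/ΣN, where
N(i7) is the lane-wide total of reads carrying that i7 (hop targets
attract in proportion to their read share; lane-wide normalization is the
default).  The expected background of strain s in sample (i5, i7) is that
probability times the summed reads of s in other samples with the same
i5.  Epsilon is fitted by the method of moments over cells whose strain
is known absent (by default, every non-inoculated strain): total observed
reads in those cells divided by the background predicted at epsilon = 1.

Invasion calling, per community: the invader's reads are compared with
its expected background b.  Reads at or below b + 4*sqrt(b) — the Poisson
fluctuation band of pure hopping — are below the detection limit and
called non-invasion; reads detectably above background but under 2x b are
too marginal to call and the community is marked defective (excluded
downstream as missing data); otherwise frequencies are computed from
background-subtracted counts over the inoculated strains and the invader
is called only if it both exceeds its inoculation frequency and reaches
1% of the community.  The Poisson band is essential: without it, ordinary
sampling noise around the background (roughly half of all true
non-invasions) would be misread as marginal.  The 2x defectiveness factor
and the 4-sigma band are package choices, both configurable.

## Synthetic data

The generators produce every input the pipeline consumes, with known
ground truth and a mandatory seed:

* i.i.d. pair-category invasion matrices; default mix (bistable 0.40,
  hierarchical 0.55, coexistence 0.05) loosely mirrors a screen in which
  roughly a third of competitions end in invasion and mutual invasion is
  rare — a fixture default, not a claim about any dataset;
* planted-hierarchy matrices (round-robin level assignment, downward
  invasions flipped upward with probability flip_prob, same-level pairs
  bistable) with the planted levels returned;
* hierarchy-biased inhibition matrices (p_down for high-to-low ordered
  pairs, p_up for the reverse, their mean for equal levels);
* community-model samplers as in the theorem section;
* read-count tables: final compositions set by the outcome (successful
  invaders reach 0.95, displacing the resident; failed invaders are
  absent), multinomial sampling at ~10^4 reads per community, invaders
  inoculated at 10^-3, and read-wise i7 hopping at epsilon = 0.001 into
  same-i5 partners with lane-wide attraction weights.

What they do **not** emulate: PCR amplification bias, sequence errors or
read-level structure (counts only), chimeras, partial invasions,
replicate communities, or correlated pair outcomes (real invasion
matrices are strongly transitive; the i.i.d. generator is not).  Passing
tests therefore demonstrate the correctness and calibration of the
*machinery* on data obeying the stated models, not the biological
conclusions one would draw from any particular strain panel.

## Problem sizes used in the checks

The shipped verification runs use: 500 community models for the theorem;
100 two-species models for closed-form-versus-dynamics agreement; 12
strains for hierarchy recovery and 100 random instances at n ≤ 6 for the
exhaustive-oracle comparison; 200 replicates x 199 permutations per
permutation-test calibration; 48 communities at 10^4 reads for epsilon
recovery and 30 communities at 10^5 reads for exact end-to-end matrix
recovery.  These sizes were chosen so a full verification completes in
minutes on a single core while keeping every stochastic check's
tolerance meaningful.
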