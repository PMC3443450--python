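# Methods

## Genetic model

Every marker is a dominant presence/absence band carried in a single dose
by one or both parents of an outcrossed F1.  The package assumes faithful
bivalent pairing, so a simplex locus in a polyploid transmits exactly like
a diploid heterozygote; ploidy is never represented explicitly.  This
"diploidized" reduction is what makes D1 loci (heterozygous in parent 1
only) segregate 1:1, D2 loci likewise for parent 2, and C loci (simplex ×
simplex) 3:1.  Loci nullizygous in both parents, or with a missing parental
score, are reported as `invalid` and never tested.

An F1 individual's state at a locus is the pair of parental transmissions
(a, b) ∈ {0,1}²: which of parent 1's two homologs and which of parent 2's
it received.  Band presence is a deterministic function of (a, b), the
cross type, and the **linkage phase** (which homolog carries the band
allele): D1 shows a band iff a equals the carrier homolog, D2 via b, C via
either parent.  All linkage structure in the package — two-point tables,
the multipoint chain — derives from this one mapping.

A single recombination fraction per interval is shared by both parental
meioses.  This is the integrated-map convention: with markers of both
parents interleaved on one group there is one distance scale, not two
sex-specific ones.

## Segregation testing

Counts of present/absent bands over non-missing progeny are tested with a
plain Pearson χ² (1 df) against 1:1 or 3:1; no continuity correction.
Missing scores are dropped, never imputed.  The Bonferroni level is
α_global / n_tests with n_tests = number of markers with a valid cross type
and at least one scored progeny; markers below the per-test level are
excluded from linkage analysis as distorted.  Under the null this excludes
at least one marker in ≈ α_global of populations (family-wise control),
which the test suite verifies by simulation.

## Two-point estimation

For a pair of loci, each parent recombines independently with probability
r, giving closed-form joint band-pattern probabilities per pair class and
phase configuration (coupling/repulsion per informative parent).  Useful
facts exploited in the implementation:

* D1×D1 and D2×D2 are binomial in q = P(transmissions match the phase);
  the MLE is the recombinant fraction, clamped to the phase's admissible
  range.
* D×C likelihoods are concave in q; the score equation is solved by
  bisection to ~1e-12.
* C×C tables depend on the phases only through m = q₁·q₂, so the
  (coupling, repulsion) and (repulsion, coupling) configurations are
  indistinguishable from two-point data; ties break toward coupling in
  parent 1 (repulsion linkages across polyploid homologs are rarely
  detectable, making coupling the field prior).
* D1×D2 pairs ride on independent meioses: their joint distribution is the
  product of the marginals for every r.  They are reported as
  noninformative and can never contribute a linkage-graph edge — only C
  loci bridge the parental marker sets.

LOD is the log₁₀ likelihood ratio of (r̂, best phase) against r = ½.
rf estimates are truncated to [0, 0.5].  `all_pairs` computes all pairwise
pattern counts by integer matrix products (pairwise-complete: individuals
missing either marker are dropped per pair), so a 730-marker sweep
(~266,000 pairs) takes seconds.

## Grouping

Co-segregation groups are connected components of the undirected graph
with an edge for every informative pair at LOD ≥ 6 and r̂ ≤ 0.35 (the
reference thresholds; both are parameters).  Components are ordered by
marker count, then lexicographically, so the partition and the provisional
names are independent of input order.  Markers in no edge are "unlinked"
and excluded from ordering.

## Multipoint ordering

The hidden chain has 4 states (a, b) per locus; transitions factorize over
the parents as t(a,a′; r)·t(b,b′; r) with t = 1−r on retention.  Emissions
are exact (no genotyping-error term, matching the software generation this
reproduces; robustness to simulator error is tested empirically), and
missing observations emit 1.  The forward algorithm runs scaled, uniform
initial distribution 1/4; an all-missing individual contributes exactly 0
to the log-likelihood.

Interval rfs are fitted by Baum–Welch: the E-step accumulates the expected
number of recombination events per interval per parent
(Σ α T n_diff β / normalizer), the M-step divides by 2N.  The
log-likelihood is asserted non-decreasing every iteration.  Initial values
come from two-point estimates of adjacent pairs, clamped to
[1e-4, 0.49]; fitted values are clamped to [1e-6, 0.4999] so the chain
never degenerates.  Convergence: |Δ loglik| < 1e-6, cap 200 iterations.

**Phases before ordering.**  Absolute band-carrier homologs are assigned
per parent by propagating the best two-point relative phases along a
maximum-LOD spanning tree of the markers informative in that parent (the
root's label is arbitrary — flipping an entire component is a homolog
relabeling and leaves the likelihood invariant).  Weakly anchored markers
(typically a C marker with no strong mate in one parent) can still come
out wrong, which shows up as a spuriously free interval; a **per-marker
phase re-check** therefore refits every admissible single-marker flip
(batched) after ordering and accepts strict improvements.  Ordering and
phase re-checks alternate (ripple → re-check) until both are stable, since
a wrong phase can fake a wrong order and vice versa.

**Order search.**  Groups of ≤ 6 markers are ordered exhaustively (all
n!/2 orientation-unique permutations, each EM-refitted; deterministic
lexicographic tie-break).  Larger groups use a frame of the 5 most
LOD-connected markers ordered exhaustively, then likelihood-best insertion
of the remaining markers one at a time; a marker whose best and
second-best insertion differ by < 3 log₁₀ units is deferred and afterwards
force-inserted at its best position and flagged (`OrderedCG.forced`) —
the "safe ordering" behaviour of sequential map builders.  (Deferred
markers are force-inserted at their best slot rather than literally
appended to the tail: appending would corrupt positions for every marker
after an ambiguous one.)  A sliding-window ripple (window 4) then tries
all window permutations and accepts strict gains until a pass changes
nothing.

**Performance choices** (pure optimizations; they do not change which
order wins beyond likelihood ties): candidate orders are fitted in batch —
the forward/backward recursions are vectorized over (candidate ×
individual) — and ripple candidates are warm-started from the incumbent
fit, screened with a single forward pass at the incumbent rfs, and only
the top 4 are EM-refitted.  Small groups (≤ 9 markers) use
fully-converged comparisons (cap 60 EM iterations) because their
candidates are near-tied; larger groups cap search-mode EM at 15
iterations and rely on the final full fit.

Distances: Kosambi d = 25 ln((1+2r)/(1−2r)) cM, cumulative from 0 per
group; r = 0.5 would be infinite and is excluded by the clamps.

## Homo(eo)logous groups

Alleles of one multiallelic EST-SSR locus land on different homologs, so
shared locus codes connect CGs from one chromosome set.  Locus codes are
recovered from marker names; because code and allele size are concatenated
without separator (`ESTB94279` = ESTB94 + 279 bp), a declared locus list
takes priority and a 3-digit-size heuristic is the fallback.  CG pairs
sharing ≥ 2 distinct locus codes form HG cores (with transitive closure);
CGs sharing exactly one locus attach as putative members to the core they
share most with.  Duplicated alleles of one locus inside a single CG are
collapsed (sets) and create no evidence.  HGs take Roman numerals by
descending total marker count; within an HG, CGs are renamed `<numeral>-k`
by descending cM length; leftovers become `U-k`.  (The numbering rule is a
convention: the reference naming is reproduced qualitatively — its largest
HG is numbered I — but no explicit rule was ever published.)

## Retrotransposon analyses

**Binning.**  The map is cut into 10 cM bins; by default bins restart at 0
within each CG, half-open [k·10, (k+1)·10), and a trailing partial bin
counts as one bin (`scope="whole_map"` concatenates groups first — the
published description does not say which was used, so both are exposed).

**Poisson goodness of fit.**  λ̂ = mean markers per bin; classes 0..x_max
with no pooling, χ² = Σ(O−E)²/E, df = c − 1 − 1 (one parameter
estimated).  At realistic sparsity (λ ≈ 0.12, tail classes with expected
counts ≪ 1) the χ² reference distribution is anticonservative — measured
type-I error 11–15% at nominal 5% — so two remedies are provided:
`pool_sparse` merges trailing classes until every expected count reaches
1 (restores size at some power cost), and `method="bootstrap"` keeps the
unpooled statistic but simulates its null distribution at λ̂ (999
replicates by default), which holds the 5% size and retains ≥ 80% power
against the package's planted-cluster alternative.  The default output
remains the plain χ² for comparability with published usage.

**Clusters.**  Within each CG the target-system markers are taken in map
order (other systems ignored); maximal runs with every adjacent gap
strictly below 5 cM and ≥ 2 members are reported with their spans.

**Copy number.**  Each enzyme/primer combination samples the same set of
genomic element copies, so total anchored fragments divided by the number
of combinations estimates the copy number; the rounded value uses half-up
rounding (357/6 = 59.5 → 60).  The per-parent variant uses
parent-present fragment totals.

## Synthetic data generator

`simulate_population` draws, per individual per parent per chromosome, a
gamete from a two-homolog meiosis with crossovers as a no-interference
Poisson process at 1 event / 100 cM (Haldane: r(d) = (1 − e^(−d/50))/2).
The generator's defaults are the study conditions: 188 individuals; 730
single-dose markers split (AFLP 197/192/146, EST-SSR 41/60/29, RT 23/32/10
over D1/D2/C); six planted retrotransposon clusters of 2–3 markers with
within-cluster gaps below 5 cM (uniform-placement null mode available);
missing rate 5% and scoring-error rate 1% (unpublished for the reference
data; typical for silver-stained gel scoring).  The simulated genome is
92 linkage elements of 52.64 cM (≈ 4843 cM total), mirroring the
fragmented map structure of a high polyploid — each mapped homolog is its
own small group of 2–39 markers — rather than a handful of long
chromosomes.  EST-SSR loci are multiallelic: each locus's alleles are
spread across the homologs of one homeology set, which is what makes HG
assembly testable end to end.  Optional distorted markers are simulated as
unlinked loci with a forced band-transmission bias.  Ground truth
(placements, phases, cluster ids, transmitted homologs per marker per
individual) is returned and written as a sidecar TSV.

What the generator does **not** emulate: multivalent pairing and double
reduction, higher-dose (duplex+) markers, sex-specific map lengths,
crossover interference (simulation is Haldane; reported distances are
Kosambi, which is a unit convention, not a simulation claim), locus-level
distortion gradients, and genotyping error correlated within gels.
Passing recovery tests therefore demonstrate correctness of the estimators
under the stated model, not robustness to every artefact of real
polyploid data.

The NBS-profile generator draws, per combination, a Binomial(copies,
detection probability) set of detected fragments; a detected fragment is
absent from a given parent with probability polymorphism_rate/2.  With
perfect detection and no polymorphism the copy-number estimator is exact
by construction.

## Problem sizes used by the test suite and acceptance script

Full-pipeline checks run at study scale (188 × 730; about 4 minutes);
order-recovery uses 50 independent 8-marker chromosomes at 10 cM spacing;
calibration uses 500 null replicates (Poisson test) and 30–40 null
populations (segregation filter); oracle comparisons use 50 random r draws
per pair class.  Unit tests use 3-chromosome miniatures so the whole suite
stays well inside a desktop coffee break.

## Known limitations

* Orders inside dense integrated groups (markers a few cM apart, few C
  bridges) are only weakly identified at n = 188; the likelihood can
  genuinely prefer a locally permuted order, and such markers are exactly
  the ones the insertion step flags as forced.  This mirrors the "safe
  ordering" caveats of the software generation the pipeline reproduces.
* The HMM has no genotyping-error emission; scoring errors inflate
  adjacent interval estimates slightly (≈ +0.01 at 1% error).
* Two-point C×C data cannot separate mixed-phase configurations (see
  above); multipoint context usually resolves them via the phase
  re-check, but isolated C pairs remain ambiguous.
* The copy-number estimator assumes equal detectability of all copies per
  combination; partial detection biases it downward (by design it is a
  lower-bound-flavoured estimate, as in the motivating analysis).
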