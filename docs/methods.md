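# Methods

## Screen model and coordinates

A deficiency panel is a set of deletion intervals on chromosome arms,
0-based half-open in abstract integer units. The package deliberately does
not translate cytological band definitions into coordinates: a panel file
must already carry numeric positions (real or synthetic). The default arm
set is the five major arms (X, 2L, 2R, 3L, 3R) with lengths approximating
the euchromatic extents of the *D. melanogaster* arms (23.5–32.1 Mb); arms
collapse to chromosome labels (2L, 2R → 2) for chromosome-level models.
Abutting intervals ([0,10) vs [10,20)) do not overlap; panel euchromatin
coverage is the length of the union of deficiency∩euchromatin divided by
total euchromatin length.

## Viability inference

Counts are pooled over vials per stock × species × temperature before
testing; no per-vial test is attempted, because replicate vials of one
cross are draws from the same genotype and the screen's published
per-stock tallies are pooled. The relative viability is
v̂ = n_df/(n_df+n_bal), 0.5 under equal survival. The segregation test is
the 1-d.f. Pearson χ² against 1:1 with no continuity correction; its tail
tracks the mid-p two-sided exact binomial within 0.005 for totals ≥ 50
(the plain exact test differs by up to the point mass, ~0.1 at total 50,
which is why the oracle tests use the mid-p convention).

HI call rule: p < α AND n_df < n_bal AND pooled total ≥ `min_total`.
Defaults α = 0.05 (conventional; the call threshold is exposed as a flag)
and `min_total` = 20 pooled progeny — below that the χ² approximation is
unreliable and a stock is reported as untestable rather than negative.
Complete lethality (n_df = 0 with n_bal ≥ `min_total`) is always called HI.
The one-sided rule means the null call rate is ≈ α/2, not α; a significant
*excess* of df-class daughters is reported but never called HI. No
multiple-testing correction is applied across stocks by default, matching
the per-stock calling convention of such screens; the α flag allows
sensitivity analyses.

## Minimal causal regions

Two corrections for overlapping HI deletions are computed and both are
reported, because "number of distinct regions" is ambiguous for a chain of
pairwise-overlapping intervals with no common base:

* **component count** — connected components of the interval-overlap graph
  (end-point sweep per arm);
* **minimal count** — minimum stabbing set per arm: sort intervals by end,
  place a point at `end − 1` of the first uncovered interval, skip every
  interval containing it. The greedy rule is exact for interval stabbing;
  a brute-force oracle over candidate points (all `end − 1` coordinates)
  guards it on inputs ≤ 12 intervals.

Always component_count ≤ minimal_count ≤ set size. Representative stabbing
points are emitted so candidate regions can be inspected.

The per-arm density test compares observed per-arm locus counts with equal
expected counts per arm (not length-weighted — the scientific question is
whether the same *number* of HI alleles sits on each arm). The statistic is
Pearson's χ²; the p-value is simulated with 2000 multinomial replicates by
default, using the (1+b)/(B+1) estimator, which never returns 0 and is
deterministic given the seed. Ties with the observed statistic count as
extreme (within 1e-12, guarding float noise in the statistic).

## Overlap between conditions

The comparison universe is the set of stocks testable at *both*
temperatures; untestable stocks and their HI flags are excluded first. The
randomization null redraws one set as a uniformly random same-size subset
of the universe, holding the other fixed — equivalent to simple label
shuffling, with the hypergeometric tail as its closed form, which is used
as an oracle in tests but never as the reported statistic. The p estimator
is again (1+b)/(B+1); default 100,000 permutations (the estimator's floor
is then ~1e-5, giving headroom below the 1e-4 resolution the headline
result needs). Enrichment (overlap ≥ observed) is the default tail; a
depletion tail is available.

## Effect models

The response everywhere is the pooled per-stock v̂, one value per stock ×
species × temperature; the modeling frame keeps only complete cases
(stocks with testable values in all four condition cells), which makes the
factorial design balanced — 223 complete stocks give 892 rows, hence
residual d.f. 888 for the 4-cell temperature × species structure and 880
for the 12-cell chromosome × species × temperature structure.

* Paired t-tests: per-stock difference v̂(18°) − v̂(24°) within one hybrid
  genotype, two-sided, symmetric 95% CI.
* Factorial ANOVA: OLS with sequential (Type I) sums of squares in formula
  order. On the balanced complete-case frame Type I/II/III coincide for
  these terms, so the simpler sequential decomposition is used; the total
  sum of squares is conserved to 1e-9 relative.
* Cell-means models: the crossed factor fitted as a single factor; overall
  F with (cells − 1, n − cells) d.f. Chromosome-level models use the three
  large chromosomes (X, 2, 3); stocks on any other chromosome are excluded
  from those models only.
* Adjusted contrasts: estimate = difference of cell means; SE from the
  pooled residual variance; family-wise adjustment by the single-step
  max-|t| method (the generalization of Tukey's HSD to arbitrary contrast
  families on a linear model), approximated by Monte Carlo from the
  multivariate-t null with a fixed seed (20,000 draws by default). The
  Monte-Carlo estimate is floored at the marginal two-sided t p-value,
  which the exact single-step adjusted p can never undercut. The packaged
  6-contrast family is the within-species 24° − 18° comparison per
  chromosome. Agreement with R's `multcomp::glht` single-step adjustment
  is verified in the test suite on a small frame.

## Synthetic screens

The generator emulates the screen's statistical structure, not fly
biology. Per stock × species × temperature × vial, the two scored progeny
classes are independent Poissons: n_bal ~ Poisson(λ),
n_df ~ Poisson(λ·v), with v the product of (1 − penetrance) over the HI
loci the deletion uncovers (independent lethality across loci; no count
model or interaction model is dictated by the screen itself, and binomial
thinning of a common clutch gives the same likelihood). Balancer-class
viability is fixed at 1 — dominant balancer costs and meiotic drive are
not modeled. A vial produces no progeny with probability 0.5 (default),
emulating screens where about half of ≥ 20 replicate vials yield
offspring; λ defaults to 12 per class per productive vial, so a cross
pools ~240 scored daughters — enough that penetrance ≥ 0.5 is almost
always detected at α = 0.05 while weak effects remain noisy, which is the
regime such screens operate in.

Panels tile each arm with deficiencies allocated proportionally to arm
length, neighbouring tiles sharing 15% of a tile by default (jittered
lengths, ±10%); overlap 0 yields pairwise-disjoint tiles. Presets:
`san_like` plants 70 loci in the san genome with penetrance drawn
U(0.5, 1), 85% equal at both temperatures, the temperature-restricted rest
alternating between temperatures; `sim_like` plants 15 loci in the sim
genome, 90% penetrant (≥ 0.8) at 24° only. These mirror a cross dense in
temperature-robust incompatibilities versus one dominated by
temperature-restricted ones. All randomness derives from one seed through
fixed-order named streams (panel, counts, loci), so outputs are
byte-reproducible; a truth table of planted loci supports recovery tests.

What the generator does *not* emulate: male lethality and sterility
phenotypes, balancer viability costs, clutch-size overdispersion beyond
Poisson, linkage between loci, and cytology-to-coordinate uncertainty.
Passing recovery tests therefore validates the inference chain under the
stated count model, not robustness to these real-data features.

## Numerical and design notes

* Simulated and randomization p-values use (1+b)/(B+1); Monte-Carlo
  tolerances in tests are 3 standard errors.
* The randomization test draws subsets via top-k of i.i.d. uniforms in
  20,000-replicate chunks (vectorized, memory-bounded).
* Degenerate inputs fail loudly: zero pooled totals, empty cells,
  rank-deficient designs, infeasible overlap counts and infeasible tilings
  raise with the offending record named; panel parsing errors name the
  line number.
* Geometric recovery tests classify with a stringent α so that calls come
  from the deterministic complete-lethal rule rather than chance, isolating
  the stabbing-count geometry from the test's false-positive load.
* Pipeline problem sizes: the default synthetic screen is the full
  223-stock panel with 20 vials per cross; validation suites use 50
  null-screen replicates and 20 paired seed replicates for the
  direction-of-interaction property, sizes at which Monte-Carlo error is
  well below the tested margins.

## Known limitations

* The viability response is treated as Gaussian in the linear models, as
  in the screen's own analysis; a binomial GLM would weight stocks by
  progeny counts and is a natural extension.
* The randomization null ignores spatial structure (per-arm counts are not
  preserved); with arm-uniform panels the simple null and the hypergeometric
  agree, but a spatially stratified null could differ for clustered HI sets.
* Minimal stabbing counts are lower bounds on the number of causal loci;
  fine-mapping within a cluster is out of scope.
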