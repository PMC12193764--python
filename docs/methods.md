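# Methods

## Data model

The pipeline consumes three CSV tables: catches (`trap_id,species,count`),
trap metadata (`trap_id,plot_id,habitat,altitude_m,active_days`) and
species traits (`species,B,Z,E` with 0/1 flags for brachypterous,
specialized zoophagous and Alpine-endemic). Counts are specimens; the
working abundance is activity density (AD = count / days of trap
activity), which removes differences in trap exposure. `active_days` is
taken as supplied; when only dates are available the helper converts them
with a start-inclusive, end-exclusive convention, isolated in one function
because field protocols differ on this point.

Habitat codes are rewritten through a configurable merge map before any
analysis; the default merges limestone cliffs (8210) and limestone
pavements (8240) into one unit, since traps commonly sit on their boundary
and the two host very similar communities. Traps that caught nothing are
excluded everywhere (their composition is undefined); traps outside any
classified habitat are kept for the per-trap index but excluded from
habitat-level comparisons (ANOSIM, IndVal, summaries). Species caught but
missing from the trait table fail loudly by default; permissive modes
either treat them as trait-free or exclude them, both logged — silently
assuming all-false would bias the index downward invisibly.

## Index of Natural Value

For each trap and trait X ∈ {B, Z, E}: FrT_X (trait share of trap
richness), FrA_X (trap's share of the area-wide trait-X species pool) and
ArT_X (trait share of the trap's total AD). INV is 100 × the mean of the
nine components. Conventions:

- The FrA denominator is the pool of species *recorded in the retained
  dataset*, not an external regional checklist; a checklist can be
  substituted by passing explicit pools to `trait_profile`. Species listed
  in the trait table but never caught contribute nothing.
- If no recorded species carries a trait, FrA for that trait is 0 (there
  is no pool to hold a share of), avoiding 0/0.
- Presence means count ≥ 1 (equivalently AD > 0).

INV is scale-invariant within a trap (doubling all counts changes
nothing), lies in [0, 100], and is 0 exactly when the trap holds no
trait-bearing species.

## Community statistics

**Bray–Curtis / ANOSIM.** Distances are computed on AD by default
(switchable to raw counts). ANOSIM uses mid-ranks for tied distances and
R = (mean between-group rank − mean within-group rank) / (n(n−1)/4).
Significance is by label permutation with the (1 + more-extreme)/(1 +
n_perm) estimator, so p can never be 0 and p ≥ 1/(n_perm+1). Groups with a
single site abort in strict mode and are dropped with a warning otherwise.
Pairwise ANOSIMs run per group pair on the sub-matrix with independent
sub-seeds; Bonferroni multiplies by the number of pairs actually tested.

**IndVal.** Specificity uses *group mean* abundance (the original
formulation, robust to unequal group sizes), fidelity is within-group
occupancy, and the tested statistic is each species' max-over-groups
IndVal. The permutation null shuffles site labels; Bonferroni multiplies
by the number of species tested (one max-statistic test per species; a
species × group family is available via the components table if wanted).

**Correspondence analysis** runs on the trap × 9 trait-component matrix
(the trait make-up of communities, not the species matrix). Implementation
is the classical SVD of D_r^{-1/2}(P − rc^T)D_c^{-1/2}; principal inertias
are squared singular values and total inertia equals the table's
chi-square over its grand total. Traps with all-zero profiles (INV = 0)
carry no mass and are excluded with a logged list. Principal coordinates
are the default (standard coordinates via a switch). Axis signs are fixed
by forcing the largest-magnitude column loading positive on each axis —
the SVD's sign is otherwise arbitrary and outputs must be reproducible.
Axes below 1e-12 of total inertia are treated as null space. Note that
duplicating a row changes the mass distribution and hence the solution;
the invariance CA does guarantee (and the suite tests) is distributional
equivalence: splitting a row into identical-profile halves is a no-op.

**Kendall τ_b and Shapiro–Wilk** delegate to scipy (asymptotic,
tie-corrected τ; Royston's W approximation). The suite cross-checks τ_b
against an O(n²) concordance count with tie terms and W against the
original 1965 order-statistic coefficients at n = 5 (tolerance 5e-3, the
scale of the approximation difference).

## Prioritization

Habitat summaries report per-habitat trap count, mean/min/max INV and the
altitude span; cartographic areas are pass-through attributes. Ranking is
by descending mean INV with ties broken by habitat code so outputs are
deterministic. GeoJSON polygons are annotated by attribute join on the
habitat code; color-bin edges are equal intervals over [min of habitat
means, max of habitat means]. No geometry is computed or modified.

## Synthetic generator

The generator emulates a multi-year Alpine campaign: 8 habitats × 13
traps (plus 6 unclassified traps) ≈ 110 traps, staggered 400 m altitude
bands covering ~1100–2900 m, 28 species. Counts are negative-binomial with
mean = active_days × affinity[habitat, species] × exp(Σ_X slope_X ·
flag_X · Δaltitude_km), where Δ is the offset from the overall range
midpoint (keeps slopes O(1) and mean catch stable). Defaults, chosen to
make one realization resemble a real campaign of this design and held
fixed:

- trait probabilities (p_B, p_Z, p_E) = (0.5, 0.2, 0.25) — roughly the
  proportions seen in Alpine carabid pools, with overlapping flags;
- lognormal base rates (median ≈ 0.005 specimens/trap-day, σ = 1) and
  active days uniform in 60–120, yielding ~20 specimens per trap;
- per-species habitat preferences from a Dirichlet(0.5) rescaled to mean
  1, giving the habitat structure ANOSIM and IndVal exercise;
- NB dispersion k = 1 (pitfall catches are strongly overdispersed;
  k → ∞ recovers Poisson);
- 15% of traps emptied, matching the typical fraction of zero-catch traps
  in campaigns of this kind.

Presets: `gradient` plants altitude slopes (km⁻¹) of 0.4 for B and 1.2
for Z and E — a positive INV–altitude association; `indicator` plants one
species confined to one habitat at fidelity 0.8 (mean count 20 in occupied
traps, so expected IndVal ≈ 100 × fidelity minus a small shortfall from
rare zero catches); `null` makes habitats fully exchangeable (shared
affinities, one shared altitude band, no trait effects) for type-I-error
calibration.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring traps, season/phenology structure, observation error in
traits, and real taxon-specific abundance patterns. Passing tests
therefore demonstrate that the statistics behave correctly under the
stated sampling model, not that any particular field system satisfies that
model.

## Simulation experiments

Calibration uses the null preset scaled to 2 habitats × 8 traps and 12
species with 199 permutations per test, 500 simulated datasets per suite —
sizes chosen so the Monte-Carlo error on a 5% rate (≈ ±1%) resolves the
acceptance band while the suite runs in seconds. The IndVal calibration
scores the most prevalent species in each simulated dataset: every species
is neutral under the null, and a common species has the least-discrete
permutation null, making it the sharpest probe of calibration (rare
species are conservative by discreteness). Recovery experiments use 100
generator seeds: the gradient preset must show τ_b > 0 with p < 0.01, and
the indicator preset must return the planted species as the top observed
IndVal hit in its planted habitat.

## Reproducibility and numerics

A single run seed expands into per-stage sub-seeds via
`numpy.random.SeedSequence.spawn` in a fixed stage order, so a stage rerun
in isolation sees the same stream. Permutation p-values are exactly
reproducible given (seed, n_perm). All output tables are written with
6-decimal fixed formatting; row/column orders are stable (trap-table order
for traps, sorted names for species, a fixed documented order for the nine
trait components).

## Limitations

- The permutation tests assume exchangeable sites under the null; nested
  designs (traps within plots) are not modelled — with strong plot-level
  autocorrelation the tests would be anticonservative.
- INV treats the three traits as equally weighted and binary; ordinal or
  weighted trait schemes are out of scope.
- The FrA pool from the recorded fauna makes INV values comparable within
  a study but not across studies with different sampling effort.
- Pairwise ANOSIM on small groups has low power, and Bonferroni across
  many pairs is strict; non-significant pairs are not evidence of
  equivalence.
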