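# natval

Trait-based conservation prioritization of ground-beetle (Carabidae)
communities from pitfall-trap data.

Carabid beetles are classic terrestrial bioindicators: communities rich in
wingless (brachypterous, **B**), trophically specialized (**Z**, e.g.
snail-feeding) and regionally endemic (**E**) species mark little-disturbed,
often high-altitude habitats that are most exposed to disturbance and
climate change. `natval` turns raw pitfall catches into a per-trap
**Index of Natural Value (INV)** and the community statistics needed to
rank protected habitats by conservation priority. It is written for
ecologists running multi-habitat pitfall campaigns (e.g. across Natura 2000
habitat types on an Alpine elevation gradient).

## The index and the statistics

All abundances are **activity densities** (AD = specimens / days the trap
was active). For a trap *t* and each trait *X* ∈ {B, Z, E}:

- FrT_X = |S_t^X| / |S_t| — the trait's share of the trap's species richness,
- FrA_X = |S_t^X| / |S_A^X| — the trap's share of the area-wide pool of
  trait-X species (species recorded anywhere in the study),
- ArT_X = Σ_{s∈S_t^X} AD_{t,s} / Σ_{s∈S_t} AD_{t,s} — the trait's share of
  the trap's total activity density,

and **INV = 100 × mean of the nine components**, a score in [0, 100].

Around the index the package implements the standard community-analysis
toolkit: Bray–Curtis distances with one-way and pairwise **ANOSIM**
(mid-ranked distances, seeded label permutations, Bonferroni-adjusted
pairs), **Dufrêne–Legendre IndVal** indicator-species analysis with a
permutation test, **correspondence analysis** of the trap × 9
trait-component matrix (inertia decomposition, principal coordinates,
deterministic axis signs), Kendall's τ_b for the INV–altitude trend,
Shapiro–Wilk for the INV distribution, and habitat-level summaries with
map-ready GeoJSON attributes (mean INV, priority rank, color bins). A
seedable synthetic-data generator emulates a full field campaign so every
stage can be validated against planted effects.

## Worked example

Generate a synthetic campaign (~8 habitats × 13 traps plus 6 unclassified
traps, 28 species, a planted positive altitude trend for Z and E species)
and run the full pipeline:

```sh
natval synth --preset gradient --out demo/in --seed 1
natval run --catches demo/in/catches.csv --traps demo/in/traps.csv \
           --traits demo/in/traits.csv --out demo/out --n-perm 999 --seed 42
```

The run prints a summary (also written to `demo/out/summary.json`); with
the seeds above:

```
"n_traps_input": 110,
"n_traps_retained": 91,
"inv": {"min": 9.72, "max": 51.56, "mean": 32.77},
"kendall_inv_altitude": {"tau_b": 0.444, "p": 4.7e-10, "n": 91},
"shapiro_wilk": {"W": 0.977, "p": 0.115},
"ca_percent_inertia": [41.5, 36.8, ...],
"anosim_global": {"R": 0.676, "p": 0.001, "n_sites": 87}
```

Reading: 19 of 110 traps caught nothing and were excluded; INV spans
9.7–51.6 and rises significantly with altitude (τ_b = 0.44, the planted
trend); the first two CA axes carry ~78% of the trait-profile variation;
and habitat communities differ overall (ANOSIM R = 0.68 on the 87
classified traps, p at the permutation floor). `demo/out/` also contains
`inv.csv` (per-trap index and components), `anosim.json` (global +
pairwise), `indval.csv`, `ca_rows.csv`/`ca_cols.csv`/`ca_summary.json`,
`habitat_summary.csv` and, when `--polygons` is given, `priority.geojson`.

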