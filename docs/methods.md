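# Methods

## The model and the question

The package analyses species-level body size in a regional fauna across an
extinction/re-diversification boundary.  Its working currency is shell
length in mm measured parallel to the coiling axis, log-transformed for all
clade-level comparisons (clade size distributions are treated as
approximately lognormal; species within a clade commonly span an order of
magnitude).  Three time bins are recognised — pre-extinction, an
intermediate post-extinction interval, and the modern fauna — but the
turnover comparison uses only the first and last; the intermediate bin
exists so that survivorship structure can be represented in the data without
entering the test.  Bin membership is an input column: stratigraphic
assignment is upstream of this package.

Two questions are asked at two levels:

1. **Clade level.**  Is the modern species pool of a clade larger or
   smaller, on average, than expected if extinction and origination had been
   blind to size?  The null ("non-selective turnover") is operationalised by
   bootstrap: draw N_m species log-sizes with replacement from the N_f
   pre-extinction species values, take the mean, repeat B times.  The modern
   pool is bootstrapped the same way at its own size N_m, and the mean of
   that modern resampled distribution is compared with the central-coverage
   window of the null distribution.
2. **Lineage level.**  Within each surviving species lineage (identity or
   an externally supplied anagenetic ancestor→descendant pairing), are the
   modern specimens a different size from the fossil specimens?  This is a
   plain two-sample problem on raw mm lengths.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_boot` (B) | 1000 | bootstrap draws per distribution |
| `coverage` | 0.5 | central window of the null; 0.5 = 25th–75th percentile |
| `log_base` | natural | size logarithm; the decision is provably invariant to it |
| species metric | mean (typical for Conidae) | which per-species descriptor enters the fauna vector; max-size runs are a standard sensitivity |
| `alpha`, `m` | 0.05, #lineages | raw level and Bonferroni multiplicity of the lineage battery |
| `n_perm` | 9999 | Monte-Carlo permutations (exhaustive enumeration auto-selected when C(n₁+n₂, n₁) ≤ 2×10⁵) |

N_m is taken as the number of *extant* species in the region (not merely
surviving lineages): the modern fauna being compared is the whole modern
species pool, survivors plus post-extinction originations.

"Typical size" is a pluggable per-species rule (default: arithmetic mean of
specimen lengths).  The Conidae literature uses a specialised typical-size
metric whose computation lives in taxon-specific sources; reproducing
published Conidae numbers exactly requires registering that rule — the
package deliberately does not guess it.

Measurements digitised from published figures carry a `from_figure` flag and
are included by default; sensitivity runs can drop them
(`include_figures=False`), mirroring standard practice when figure-derived
lengths are less trusted.

## Decision-rule semantics and calibration

The classification is deliberately not a hypothesis test: no p-value is
attached, and ties on a window bound count as NO_CHANGE ("fell within").
Its null operating characteristics are measurable by simulation
(`decision_rates`), and two facts deserve emphasis:

- **The null flag rate is ≈ 1 − coverage by construction.**  With a 50%
  window, about half of size-neutral faunas are flagged larger or smaller.
  The rule describes where a fauna sits relative to the null's central
  mass; it does not control a 5% error rate.
- **The exact null rate depends on the survivor/origination mix.**  The
  modern center concentrates (as B grows) at the modern sample mean, whose
  null sampling variance depends on how the modern fauna was assembled.
  When all modern species are new, independent draws from the same species
  pool, the NO_CHANGE rate is approximately
  2Φ(z₀.₇₅/√(1 + N_m/N_f)) − 1 (≈ 0.42 at N_f = 20, N_m = 10) — slightly
  below the coverage because the window is centred on the *fossil sample*
  mean, itself noisy.  When all modern species are survivors, the shared
  sampling of the two bins makes the rate overshoot (≈ 0.63 at the same
  sizes).  The package's reference null scenario
  (`null_turnover_scenario`: 20 pre-extinction species, survival
  probability 0.25, five size-neutral originations, E[N_m] = 10) mixes the
  two regimes as all three clades of the study system do, and its measured
  NO_CHANGE rate sits at 0.46–0.50 over 500-replicate runs.

Power is monotone in effect size: over origination shifts of {0, 0.5, 1.0}
log units (between-species SD 0.25) the LARGER rate rises from its null
level to ≈ 1 by 0.5 log units at these fauna sizes.

## The synthetic fauna generator

`SimScenario` draws species mean log sizes from Normal(μ, σ²_between),
specimen lengths lognormally about each species mean (σ_within), survival
as Bernoulli with logit(p) = logit(base_survival) + β·(species mean − μ),
survivors re-sampled with fresh specimens in the modern bin (an optional
`survivor_shift` emulates anagenetic change), and originations from
Normal(μ + shift, σ²_between).  Default moments (μ = 3 log-mm ≈ 20 mm,
σ_between = 0.5, σ_within = 0.2, six specimens per species) are typical of
the shelly gastropod assemblages the analysis targets.  The generator
reproduces the statistical structure the analysis *assumes* — it does not
model abundance, taphonomy, geographic structure, or measurement error
beyond within-species scatter, so passing simulation tests demonstrates
correctness of the machinery and the rule's calibration under the model,
not robustness of the method to real-data pathologies.

## The synthetic study table

`datasets.synthetic_ppwa_table` is a synthetic stand-in for the regional
specimen compilation: three clades with the published regional species
counts (Conidae 24 pre / 24 modern; Tegulidae 4 / 6; Turritellidae 20 / 2),
clade mean sizes matched exactly to the reported values (40.9 → 35.4 mm
typical size; 8.6 → 19.0 mm, 11.7 mm excluding *Cittarium pica*; 65 →
38 mm), and eight surviving lineages whose populations are engineered to
exact means and SDs so their t statistics are deterministic and reproduce
the reported significance pattern (e.g. *Conasprella stearnsii* n = 15/15,
SD 2.5 mm gives t = 2.848, p = 0.0081 — significant raw, not after
Bonferroni).  Quantities the published summaries do not pin down — the
dispersions of the non-lineage species — are free parameters, set as
follows: Conidae pre-extinction log-SD 0.8 (regional cones span roughly an
order of magnitude), Turritellidae 0.28 (solved so the clade-level
permutation t on mm species means lands near the reported 1.7), Tegulidae
0.4–0.5; the Conidae *modern* dispersion is solved at build time by 1-D
root finding so the clade's mean log size is exactly unchanged across the
boundary — making "no change" the dataset's ground truth rather than an
accident of sampling.  The stand-in is for exercising and demonstrating the
pipeline; it is not the study's raw data.

## Numerical choices

- Quantiles use the linear-interpolation convention (`np.quantile` default);
  the 50% window is [Q₀.₂₅, Q₀.₇₅] of the B null means.
- The three bootstrap distributions draw from independent substreams spawned
  from one root seed; every public entry point is deterministic given its
  seed, and batch runs derive per-replicate seeds by seed-sequence spawning.
- The permutation test statistic is the pooled t; if any evaluated labeling
  degenerates (zero pooled variance, or undefined df with singleton groups)
  the statistic falls back to the absolute mean difference for all
  labelings, keeping the reference distribution comparable.  Monte-Carlo
  p-values count the observed labeling ((1 + k)/(n_perm + 1)), so p is never 0.
- Pooled and Welch t-tests are computed by `scipy.stats.ttest_ind`; both are
  reported for every lineage.  Tests are two-sided throughout (direction is
  read off the sign post hoc).
- Degenerate inputs fail loudly: non-positive lengths, empty bins, samples
  of fewer than two specimens, and zero-variance t-test inputs raise with
  the offending species, row, or bin named.

## Problem sizes

Simulation-based checks run at B = 1000 with 200–500 replicate faunas of
20 pre-extinction species — large enough that Monte-Carlo error (binomial
SE ≈ 0.02 at 500 replicates) is small against the tolerances asserted,
small enough that the whole suite completes in well under a minute on a
single core.

## Known limitations

- The decision rule's null flag rate makes it unsuitable as a significance
  test; treat LARGER/SMALLER as descriptive flags.
- Bonferroni correction is conservative for the small batteries typical
  here; the multiplicity m of the published analysis is not recoverable
  from summary sources, so it defaults to the number of lineages tested and
  is overridable.
- Taxonomic synonymy, geographic filtering, and stratigraphic assignment
  are all upstream of the package: species names and bins are taken as
  given.
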