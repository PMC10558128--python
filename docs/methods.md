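# Methods

This note documents the models behind `tractdate`, the estimator and
numerical choices that were genuinely open, and what the synthetic-data
generator does and does not emulate.

## Tract model and the tract-length clock

A single admixture pulse `T` generations before sampling is modelled as a
Markovian mosaic along each haplotype: recombination breakpoints fall as a
Poisson process with rate `T − 1` per morgan (the number of meioses since
the pulse that could have split a tract), and each inter-breakpoint segment
carries minor ancestry independently with probability `f`. After merging
adjacent same-ancestry segments — which is what any local-ancestry caller
reports — minor-tract lengths are exponential with mean
`[(1 − f)(T − 1)]⁻¹` morgans: a minor run survives a breakpoint with
probability `f`, giving the `(1 − f)` thinning. Genetic and physical
length are related by a constant per-chromosome recombination rate
(1 cM/Mb = 10⁻⁸ morgan/bp); no fine-scale map is modelled.

The tract-length estimator inverts this relation per dating unit:

* **Mean tract length.** `L̄` is the censored-data MLE for an exponential
  mean: total minor-tract length divided by the number of tracts that end
  at a breakpoint rather than at the chromosome end. A run touching the
  chromosome end is an incomplete observation; counting it as complete
  biases `L̄` down and the date up — by ~10% at `T ≈ 18` on 50-Mb
  chromosomes and far more for recent pulses, where tracts are a sizable
  fraction of a chromosome. A run starting at position 0 needs no special
  treatment: by memorylessness its observed length has the same
  exponential distribution. The uncorrected plain mean is available as
  `censoring="none"`.
* **Dating unit.** Default `unit="chromosome"`: tracts from all
  individuals are pooled within each chromosome and `f` is the mean
  per-individual diploid minor fraction. Pooling matters because
  `E[1/L̄] = n/(n−1) · 1/L` for exponential data: with only ~6 minor
  tracts per (individual, chromosome), per-individual-per-chromosome units
  carry a ~20% upward bias, while ~40 tracts per pooled chromosome reduce
  it to ~2–3%. The finer units remain available (`"individual"`,
  `"individual_chromosome"`) for per-individual dating, with this caveat.
* **Uncertainty.** The per-unit dates are bootstrapped (resampling units
  with replacement, default 10,000 replicates, seeded) and the CI is the
  percentile interval. The point estimate is the mean over units; the
  bootstrap mean is reported alongside.

`f` enters as the measured per-individual diploid minor-ancestry fraction
(or an explicit override), so a dating run needs nothing beyond the tract
table and the genome map.

## Ancestry-decay clock

Two loci at genetic distance `g` on one haplotype share their ancestry
source with probability

```
P(same) = f² + (1 − f)² + 2 f (1 − f) e^{−(T−1) g}
```

under the same Markov mosaic. The estimator samples, for each haplotype,
chromosome and distance bin, `n_pairs` locus pairs at the bin-centre
separation, pools pair counts per haplotype, and fits
`A·e^{−λg} + c` (one pulse) or `A₁·e^{−λ₁g} + A₂·e^{−λ₂g} + c`
(two pulses) by count-weighted least squares. The date is `T = λ + 1`,
consistent with the tract model's breakpoint rate.

Design choices that were genuinely open:

* **Offset.** By default the long-range level `c` is pinned to the
  analytic asymptote `mean_i[f_i² + (1 − f_i)²]` computed from the
  realised per-individual fractions (`offset="fixed"`). The asymptote is
  known, and leaving it free couples it to `λ` strongly enough that
  long-range fluctuations of a finite mosaic leak into the decay rate:
  in repeated simulations at `T = 8.9` the worst-case recovery error
  dropped from ~29% (free offset) to ~12% (fixed) over 61 replicates.
  `offset="free"` restores the fully free fit.
* **Fit range.** `AncestryDecayDating` picks the range adaptively
  (`max_dist="auto"`): a pilot curve over 0.3 morgans gives provisional
  rates, and the final curve extends to 1.6 decay lengths of the slowest
  meaningful component (amplitude ≥ 10% of the total), clipped to
  [0.02 M, min(0.5 M, 90% of the shortest chromosome)]. Distances far
  beyond the decay length contribute no signal but let mosaic noise
  perturb the rate; too short a window starves the fit. A fixed
  `max_dist` can be given instead.
* **Pulse-count selection.** `model="auto"` compares one vs two pulses by
  cross-validation over haplotypes on the wide pilot window: the binned
  residuals of one haplotype are correlated across bins (one realised
  mosaic generates them all), so an in-sample information criterion
  overfits — AICc misselected a second pulse in 10–45% of one-pulse-truth
  simulations, while the CV rule (accept two pulses only if held-out error
  drops ≥5% and two pulses win ≥70% of splits) classified 36/36 one- and
  two-pulse truths correctly. Selection uses a free offset because each
  held-out half carries its own realised asymptote. AICc on the weighted
  RSS is still computed and reported in the results for reference.
* **Uncertainty and reporting.** A bootstrap over haplotypes (default 100
  replicates) refits the chosen model; the reported point estimate is the
  bootstrap mean (the full-data fit is kept in `extra["t_full_fit"]`).
  For a two-pulse fit the headline date comes from the largest-amplitude
  pulse; both pulses are reported.

## Supporting statistics

* **Folded SFS.** Built from called diploid genotypes; sites with any
  missing call are dropped. π uses `2i(n−i)/(n(n−1))` per folded bin with
  the `n/2` bin counted once; the denominator is every site in the SFS
  (monomorphic included), so π is per assayed site. Tajima's D uses the
  standard `a₁…e₂` constants and is an error at `S = 0`. Per-individual
  heterozygosity is the `n = 2` polymorphic fraction.
* **Windowed statistics.** 50-kb windows by default; π's denominator is
  the window's physical size (unsampled sites are assumed callable and
  monomorphic — use explicit callable tracks when that assumption fails).
  Windows under `min_sites` are masked, not zeroed, and excluded from
  genome means. F_ST is Hudson's ratio-of-averages with the unbiased
  within-population heterozygosity.
* **RoH / F_RoH.** Maximal runs of consecutive windows with
  heterozygosity below 0.482×10⁻³ become RoHs when they span ≥2 windows
  and ≥150 kbp (window boundary to window boundary; the length floor only
  binds for partial terminal windows). F_RoH is the RoH fraction of the
  assayed length. All thresholds are arguments.
* **f-statistics.** Frequency-based f₃ `E[(c−a)(c−b)]` (optional target
  heterozygosity correction `c(1−c)/(n_c−1)` for small samples — sampling
  noise otherwise masks a weakly negative f₃), frequency-generalised
  ABBA-BABA D polarized by a fixed outgroup allele (polymorphic-outgroup
  sites excluded), and the f₄-ratio `f₄(a,o;x,c)/f₄(a,o;b,c)` with a
  non-estimability error when the denominator sits within one SE of zero.
  SEs come from a delete-one block jackknife over contiguous 5-Mb blocks
  (configurable); sites with missing data in any involved population are
  dropped listwise.
* **Rank-sum contrasts.** `temporal_comparison` reports
  W = #{pairs a > b} (ties half-weighted) with an exact two-sided p for
  tie-free combined n ≤ 20 and a tie-corrected normal approximation
  otherwise; all-tied input yields p = 1 with a warning.
* **Mutation rate.** `μ = d/(2·t_div) · generation_time` with defaults
  t_div = 34 Myr and 14.2 y/generation; the divergence `d` may come from
  the polymorphic-site fraction or IBS mismatch of pseudo-haploidized
  sequences, and multiple approaches combine by arithmetic mean.
* **Years.** `generations_to_years` is strict arithmetic,
  `round(T × generation_time)`; anchoring to calendar dates (e.g. to a
  sampling year) is deliberately left to the caller.

## Synthetic-data generator

The generator exists so that every stage has inputs with exactly the
statistical structure the estimators assume; its defaults describe the
study system this package was built around: 6 diploid hybrid individuals,
24 equal 50-Mb chromosomes (~1.2 Gb) at 1.63 cM/Mb, one pulse 18.1
generations back with minor fraction 0.3, 100-kb heterozygosity windows,
and an admixture proportion of 0.297 for the allele-count fixture.

* Tract mosaics follow the Markov model above; a second pulse is painted
  over the older mosaic. There is no back-coalescence, drift of tract
  ancestry, or selection, so tract lengths are exactly exponential — real
  local-ancestry data additionally carries caller error and phasing
  switch errors that fragment tracts and bias dates upward (no switch
  -error model is included; treat real-data dates as lower bounds on tract
  integrity grounds).
* Allele counts come from a truncated-Gaussian frequency drift on a
  `(((P1,P2),P3),O)` tree with an optional admixed population `X` mixing
  two lineage frequencies (default `X = α·p(P3) + (1−α)·p(P2)`). This is
  a fixture for sign/zero/recovery tests of f-statistics, not a
  population-genetic model: clipping at [0,1] distorts extreme
  frequencies, and the outgroup is a single pseudo-haploid draw.
* Heterozygosity tracks are constant-baseline with embedded
  low-heterozygosity segments (a window takes a segment's value when
  fully inside it) and optional truncated Gaussian noise; the final
  partial window covers the chromosome remainder.
* The divergent pair flips a Binomial(n, d) set of sites of a random
  0/1 sequence.

All streams derive from `SimConfig.seed` via fixed `SeedSequence` spawn
keys (tracts=0, het=1, counts=2, pair=3), so any config is byte-identical
across runs and platforms. Passing recovery tests on these fixtures shows
the estimators are correct under their own assumptions at realistic scale;
it does not validate local-ancestry calling, phasing, or genotype quality
on real data.

## Degenerate inputs and tie-breaks

`T = 1` yields whole-chromosome tracts (breakpoint rate 0); `f = 0` is
accepted and produces an all-major mosaic; `T < 1` and `f ≥ 1` are
errors. The tract-length equation is undefined at `T ≤ 1` and errors.
Units without a single complete minor tract are excluded from dating (and
counted in the results); a tract set with none errors. Morgan→bp edge
rounding drops zero-length segments and re-merges labels. VCF reading
keeps biallelic sites only; dosage −1 marks missing. Block jackknife
requires ≥2 non-empty blocks and equal block weights.

## Problem sizes

The test suite and the acceptance script run simulations at the defaults
above (study scale) for the dating recoveries, 10⁴–10⁵ sites for
statistic oracles and f₄-ratio recovery, and 20 seeded replicates for
coverage/null-calibration checks; the full suite completes in about a
minute on one core.

## Known limitations

* The two clocks assume hard, errorless local-ancestry calls; confidence
  or posterior columns of ancestry callers are ignored.
* Only two ancestry sources are supported.
* The exponential tract approximation degrades for very old pulses
  (tracts shorter than caller resolution) and for very recent pulses on
  short chromosomes (few tracts per unit; use pooled units).
* SFS statistics operate on called genotypes, not genotype likelihoods;
  low-coverage or damage-prone data should be filtered/transversion
  -restricted upstream.
* The mutation-rate arithmetic omits any ancestral-polymorphism
  correction; divergence is split equally across both lineages.
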