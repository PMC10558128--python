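# tractdate

Dating the onset of admixture from local-ancestry tracts, with the
surrounding temporal population-genomics toolkit.

When two diverged populations begin interbreeding — as the Atlantic puffin
subspecies *F. a. naumanni* (High Arctic) and *F. a. arctica* (temperate)
did on the island of Bjørnøya — recombination progressively chops the
introgressed chromosome segments into shorter pieces. The length
distribution of the surviving minor-ancestry tracts, and the rate at which
ancestry co-inheritance decays along the genome, are therefore molecular
clocks for the onset of hybridization. `tractdate` implements both clocks
as fitted models with bootstrap uncertainty, plus the statistics a temporal
(historical-vs-modern) genomics study needs around them: folded-SFS
diversity (π, Tajima's D, heterozygosity), windowed Hudson F<sub>ST</sub>,
runs-of-homozygosity / F<sub>RoH</sub> inbreeding calling, f₃ / ABBA-BABA D
/ f₄-ratio admixture validation with block-jackknife errors, and two-way
mutation-rate calibration against an outgroup. A seeded synthetic-data
generator reproduces the statistical structure every stage assumes, so the
entire pipeline is testable offline.

It is written for population geneticists who already have local-ancestry
calls (e.g. RFMix2 `.msp.tsv` output or any BED-like tract table), called
genotypes in VCF, or windowed heterozygosity tracks, and want reproducible,
scriptable estimates rather than one-off notebook arithmetic.

## The two clocks

**Tract-length inversion.** Under a single admixture pulse `T` generations
ago with minor-ancestry fraction `f`, observed minor-ancestry tract lengths
are approximately exponential with mean

```
L = [ (1 − f) · r · (T − 1) ]⁻¹        (bp; r in morgan/bp)
```

so each dating unit (by default: one chromosome, pooling all individuals)
yields `T = 1 + [(1 − f) · r · L̄]⁻¹`. `L̄` is the censored-data MLE of the
exponential mean — tracts cut off by a chromosome end contribute length but
no "event" — which removes the end-truncation bias that a plain mean
carries. The point estimate is the mean over units and the CI a seeded
percentile bootstrap (default 10,000 replicates) over the per-unit dates.

**Ancestry-decay fitting.** The probability that two loci on one haplotype
share their ancestry source exceeds its long-range asymptote
`f² + (1 − f)²` by `2f(1 − f)·exp(−(T − 1)·g)` at genetic distance `g`.
`tractdate` bins sampled locus pairs by distance, fits one- or two-pulse
exponentials (pulse count chosen by cross-validation over haplotypes), and
dates the onset as `T = λ + 1`, with a bootstrap over haplotypes (default
100 replicates) for the CI.

Generations convert to calendar years with a generation time of 14.2 years
(the Atlantic puffin value; configurable), and the CIs of the two
estimators can be combined into a single plausible span.

## Worked example

Simulate a study-scale hybrid cohort — 6 diploid individuals on a
24 × 50 Mb genome at 1.63 cM/Mb, one admixture pulse 18.1 generations ago
with 30% minor ancestry — and date the pulse back with both clocks:

```python
import tractdate as td

cfg = td.SimConfig(seed=42)            # the defaults above
ts = td.simulate_admixed_tracts(cfg)
f = td.global_ancestry_fraction(ts, "naumanni")
print("mean diploid naumanni fraction: %.3f" % f.mean())

est = td.TractLengthDating(ts, "naumanni").fit(n_boot=10_000, seed=0)
print(est.summary())

est2 = td.AncestryDecayDating(ts, "naumanni").fit(model="auto", n_boot=100, seed=0)
print(est2.summary())

print("combined CI span (years):", td.combine_ci(est, est2))
```

prints

```
mean diploid naumanni fraction: 0.296

Admixture dating (tract_length)
========================================
Onset: 18.5 generations (CI95% [17.3, 19.7])
       262 years (CI95% [245, 279]) at 14.2 y/generation
Bootstrap: 10000 replicates, mean 18.48
Dating units: 24

Admixture dating (decay)
========================================
Onset: 17.6 generations (CI95% [16.4, 18.6])
       250 years (CI95% [233, 265]) at 14.2 y/generation
Bootstrap: 100 replicates, mean 17.59
model: one_pulse

combined CI span (years): (233, 279)
```

Both estimators recover the simulated truth of 18.1 generations: the
tract-length clock reads 18.5 [17.3, 19.7] and the decay clock 17.6
[16.4, 18.6]; the decay fit also correctly prefers a single pulse over
two. The combined CI span (233–279 years at 14.2 y/generation) is the kind
of statement a study would make about when hybridization began.

The same operations are available from the shell:

```
tractdate simulate --seed 42 --out-dir demo/
tractdate date-tracts --tracts demo/tracts.bed.tsv --map demo/genome_map.tsv \
    --minor naumanni --boot 10000 --seed 0 --out date.json
tractdate roh --het demo/het_track.tsv
tractdate run --config config.yaml       # staged pipeline with a manifest
```

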