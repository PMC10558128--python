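import numpy as np
import pytest

import tractdate as td
from tractdate.dating import (
    DecayCurve,
    coancestry_decay_curve,
    fit_decay,
)

from conftest import constant_tract_set


# ----------------------------------------------------------------------
# closed form
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "f,r,t_gen,expected",
    [
        (0.0, 1e-8, 101.0, 1e6),
        (0.5, 1e-8, 2.0, 2e8),
        # the study's printed ancestry fraction and mean rate
        (0.297, 1.63e-8, 18.1, 1.0 / (0.703 * 1.63e-8 * 17.1)),
    ],
)
def test_expected_tract_length(f, r, t_gen, expected):
    assert td.expected_tract_length(f, r, t_gen) == pytest.approx(expected)


def test_expected_tract_length_undefined_at_t1():
    with pytest.raises(ValueError, match="undefined"):
        td.expected_tract_length(0.3, 1e-8, 1.0)


@pytest.mark.parametrize(
    "t_gen,gen_time,years",
    [(8.9, 14.2, 126), (5.8, 14.2, 82), (20.8, 14.2, 295), (0.0, 14.2, 0)],
)
def test_generations_to_years(t_gen, gen_time, years):
    assert td.generations_to_years(t_gen, gen_time).years == years


def test_generations_to_years_rejects_negative():
    with pytest.raises(ValueError):
        td.generations_to_years(-1.0)


def _est(t, lo, hi, method="tract_length"):
    return td.AdmixtureEstimate(
        method=method, t_generations=t, ci_low=lo, ci_high=hi,
        ci_level=0.95, n_boot=1, bootstrap_mean=t,
    )


def test_combine_ci_reproduces_combined_span():
    # the two study estimators' CIs combine to [82, 295] years
    a = _est(18.1, 17.3, 20.8)
    b = _est(8.9, 5.8, 12.8, method="decay")
    assert td.combine_ci(a, b, 14.2) == (82, 295)


def test_combine_ci_identity_and_nesting():
    a = _est(6.0, 2.0, 10.0)
    assert td.combine_ci(a, a, 10.0) == (20, 100)
    b = _est(5.0, 4.0, 6.0)
    assert td.combine_ci(a, b, 10.0) == (20, 100)


# ----------------------------------------------------------------------
# tract-length dating
# ----------------------------------------------------------------------
def test_exact_inversion_single_unit():
    """Constant 1-Mb tracts, f=0, r=1e-8 -> T = 101 exactly, degenerate CI."""
    genome = td.GenomeMap([td.Chromosome("chr1", 100_000_000, 1.0)])
    ts = constant_tract_set(genome, minor_len_bp=1_000_000, n_minor=5, spacer_bp=2_000_000)
    model = td.TractLengthDating(ts, "naumanni", ancestry_fraction=0.0)
    est = model.fit(n_boot=200, seed=0)
    assert est.t_generations == pytest.approx(101.0)
    assert est.ci_low == pytest.approx(101.0)
    assert est.ci_high == pytest.approx(101.0)


@pytest.mark.parametrize("t_gen", [2.0, 18.1, 101.0])
def test_closed_form_inversion_roundtrip(t_gen):
    """date_from_tracts on constant-length tracts generated by
    expected_tract_length(f, r, T) returns exactly T."""
    f, rate_cm = 0.25, 1.63
    r = rate_cm * 1e-8
    length = int(round(td.expected_tract_length(f, r, t_gen)))
    genome = td.GenomeMap([td.Chromosome("chr1", 20 * length, rate_cm)])
    ts = constant_tract_set(genome, minor_len_bp=length, n_minor=3, spacer_bp=2 * length)
    est = td.date_from_tracts(ts, "naumanni", n_boot=100, seed=1, ancestry_fraction=f)
    # bp rounding of the tract length is the only error source
    assert est.t_generations == pytest.approx(t_gen, rel=1e-6)


def test_no_minor_tracts_errors(one_chrom_genome):
    import pandas as pd

    df = pd.DataFrame(
        [("chr1", 0, 100_000_000, "a", 0, "arctica"),
         ("chr1", 0, 100_000_000, "a", 1, "arctica")],
        columns=["chrom", "start", "end", "individual", "haplotype", "ancestry"],
    )
    ts = td.TractSet(one_chrom_genome, df, labels=("naumanni", "arctica"))
    with pytest.raises(ValueError, match="no 'naumanni' tracts"):
        td.date_from_tracts(ts, "naumanni")


def test_monotonicity_longer_tracts_smaller_t():
    genome = td.GenomeMap([td.Chromosome("chr1", 100_000_000, 1.0)])
    short = constant_tract_set(genome, minor_len_bp=500_000, n_minor=5, spacer_bp=2_000_000)
    long = constant_tract_set(genome, minor_len_bp=2_000_000, n_minor=5, spacer_bp=2_000_000)
    t_short = td.date_from_tracts(short, "naumanni", n_boot=50, seed=0, ancestry_fraction=0.1)
    t_long = td.date_from_tracts(long, "naumanni", n_boot=50, seed=0, ancestry_fraction=0.1)
    assert t_long.t_generations < t_short.t_generations


def test_ci_width_shrinks_with_more_units(rng):
    """Bootstrap CI width decreases (stochastically) with more dating units."""
    widths = []
    for n_chrom in (4, 24):
        cfg = td.SimConfig(seed=9, genome=td.uniform_genome(n_chrom), n_sites=10)
        ts = td.simulate_admixed_tracts(cfg)
        est = td.date_from_tracts(ts, "naumanni", n_boot=2000, seed=5)
        widths.append(est.ci_high - est.ci_low)
    assert widths[1] < widths[0]


def test_tract_dating_recovery_small():
    """Single-pulse truth recovered within 15% on a reduced genome."""
    cfg = td.SimConfig(seed=21, pulse_times=(10.0,), minor_fractions=(0.3,),
                       genome=td.uniform_genome(12), n_sites=10)
    ts = td.simulate_admixed_tracts(cfg)
    est = td.date_from_tracts(ts, "naumanni", n_boot=2000, seed=2)
    assert est.t_generations == pytest.approx(10.0, rel=0.15)


# ----------------------------------------------------------------------
# decay dating
# ----------------------------------------------------------------------
def test_decay_curve_validations(sim_tracts):
    with pytest.raises(ValueError, match="bins"):
        coancestry_decay_curve(sim_tracts, "naumanni", n_bins=2)
    with pytest.raises(ValueError, match="shortest chromosome"):
        coancestry_decay_curve(sim_tracts, "naumanni", max_dist=2.0)
    with pytest.raises(ValueError, match="label"):
        coancestry_decay_curve(sim_tracts, "nope")


def test_t1_mosaic_flat_curve(one_chrom_genome):
    """Whole-chromosome ancestries (T=1): no decay, excess ~ 0 everywhere."""
    cfg = td.SimConfig(seed=13, n_individuals=40, pulse_times=(1.0,),
                       minor_fractions=(0.4,), genome=one_chrom_genome, n_sites=10)
    ts = td.simulate_admixed_tracts(cfg)
    curve = coancestry_decay_curve(ts, "naumanni", max_dist=0.5, n_bins=10,
                                   n_pairs=200, seed=0)
    assert (curve.coancestry == 1.0).all()  # same whole-chromosome tract
    # asymptote uses realised f: excess is the (constant) mosaic-level gap
    assert np.ptp(curve.excess) == pytest.approx(0.0, abs=1e-12)


def test_short_distance_coancestry_near_one(sim_tracts):
    curve = coancestry_decay_curve(sim_tracts, "naumanni", max_dist=0.2,
                                   n_bins=40, n_pairs=200, seed=1)
    assert curve.coancestry[0] > 0.95


def test_decay_monotone_in_expectation():
    """Excess co-ancestry decreases across distance (averaged over bins halves)."""
    cfg = td.SimConfig(seed=17, pulse_times=(8.9,), minor_fractions=(0.3,),
                       n_sites=10)
    ts = td.simulate_admixed_tracts(cfg)
    curve = coancestry_decay_curve(ts, "naumanni", seed=3)
    n = curve.n_bins // 2
    assert curve.excess[:n].mean() > curve.excess[n:].mean()


def test_fit_recovers_noiseless_curve():
    """Fitting its own generating function: 0.2 exp(-7.9 g) + 0.58."""
    g = (np.arange(25) + 0.5) * (0.3 / 25)
    y = 0.2 * np.exp(-7.9 * g) + 0.58
    counts = np.full((1, 25), 10_000.0)
    curve = DecayCurve(
        bin_centers=g, same=y[None, :] * counts, total=counts,
        hap_index=[("ind0", 0)], asymptote=0.58, minor_ancestry="naumanni",
    )
    est = fit_decay(curve, model="one_pulse", n_boot=5, seed=0)
    assert est.extra["t_full_fit"] == pytest.approx(8.9, rel=1e-4)
    amp, lam = est.extra["pulses"][0]["amplitude"], est.extra["pulses"][0]["rate_per_morgan"]
    assert amp == pytest.approx(0.2, rel=1e-3)
    assert lam == pytest.approx(7.9, rel=1e-3)


def test_decay_recovery_and_model_choice():
    """One-pulse truth at T=8.9: replicate-mean date within 15%, one-pulse
    preferred in every replicate."""
    ests = []
    for seed in (0, 1, 2):
        cfg = td.SimConfig(seed=seed, pulse_times=(8.9,), minor_fractions=(0.3,),
                           n_sites=10)
        ts = td.simulate_admixed_tracts(cfg)
        est = td.AncestryDecayDating(ts, "naumanni").fit(model="auto", n_boot=20,
                                                         seed=seed)
        assert est.extra["model"] == "one_pulse"
        ests.append(est.t_generations)
    assert np.mean(ests) == pytest.approx(8.9, rel=0.15)


def test_two_pulse_truth_selects_two_pulse():
    cfg = td.SimConfig(seed=3, pulse_times=(50.0, 5.0), minor_fractions=(0.3, 0.25),
                       n_sites=10)
    ts = td.simulate_admixed_tracts(cfg)
    est = td.AncestryDecayDating(ts, "naumanni").fit(model="auto", n_boot=10, seed=6)
    assert est.extra["model"] == "two_pulse"


# ----------------------------------------------------------------------
# joint parameter-recovery grid (both estimators)
# ----------------------------------------------------------------------
@pytest.mark.parametrize("t_gen", [5.0, 10.0, 18.1, 30.0])
def test_recovery_grid(t_gen):
    """Across the T grid at f in {0.1, 0.3}: estimator means within 15%.

    Uses a genome sized so each chromosome is long relative to the expected
    tract length (short-T regimes need more map length for the exponential
    tail to be observable).
    """
    reps = 3
    for frac in (0.1, 0.3):
        n_chrom = 8
        chrom_bp = max(50_000_000, int(30 * td.expected_tract_length(frac, 1.63e-8, t_gen)))
        genome = td.uniform_genome(n_chrom, chrom_bp)
        ests = []
        for rep in range(reps):
            cfg = td.SimConfig(seed=100 * rep + int(t_gen * 10), n_individuals=6,
                               pulse_times=(t_gen,), minor_fractions=(frac,),
                               genome=genome, n_sites=10)
            ts = td.simulate_admixed_tracts(cfg)
            est = td.date_from_tracts(ts, "naumanni", n_boot=500, seed=rep)
            ests.append(est.t_generations)
        assert np.mean(ests) == pytest.approx(t_gen, rel=0.15)
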