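import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tractdate as td
from tractdate.diversity import (
    folded_sfs,
    hudson_fst,
    temporal_comparison,
    windowed_stats,
)


# ----------------------------------------------------------------------
# brute-force oracles (site-by-site, haplotype-pair enumeration)
# ----------------------------------------------------------------------
def _haplotypes(gt: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Expand dosages to per-haplotype alleles; het phase is irrelevant for
    the frequency statistics checked here."""
    n_sites, n_ind = gt.shape
    haps = np.zeros((n_sites, 2 * n_ind), dtype=int)
    haps[:, 0::2] = (gt >= 1).astype(int)
    haps[:, 1::2] = (gt == 2).astype(int)
    return haps


def oracle_pi_total(gt: np.ndarray) -> float:
    """Mean pairwise difference summed over sites, by pair enumeration."""
    haps = _haplotypes(gt, None)
    n = haps.shape[1]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += (haps[:, i] != haps[:, j]).sum()
    return total / (n * (n - 1) / 2)


def oracle_folded_sfs(gt: np.ndarray) -> np.ndarray:
    n = 2 * gt.shape[1]
    counts = np.zeros(n // 2 + 1, dtype=int)
    for row in gt:
        alt = int(row.sum())
        counts[min(alt, n - alt)] += 1
    return counts


def oracle_tajimas_d(gt: np.ndarray) -> float:
    """Textbook Tajima's D from pairwise diversity and segregating sites."""
    n = 2 * gt.shape[1]
    alt = gt.sum(axis=1)
    s = int(((alt > 0) & (alt < n)).sum())
    pi = oracle_pi_total(gt)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def oracle_hudson_fst(gt1: np.ndarray, gt2: np.ndarray) -> float:
    """Hudson F_ST via explicit within/between haplotype-pair mismatch."""
    h1, h2 = _haplotypes(gt1, None), _haplotypes(gt2, None)
    n1, n2 = h1.shape[1], h2.shape[1]
    hw_sum = 0.0
    for h, n in ((h1, n1), (h2, n2)):
        within = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                within += (h[:, i] != h[:, j]).sum()
        hw_sum += within / (n * (n - 1) / 2)
    between = 0.0
    for i in range(n1):
        for j in range(n2):
            between += (h1[:, i] != h2[:, j]).sum()
    between /= n1 * n2
    return 1 - (hw_sum / 2) / between


# ----------------------------------------------------------------------
def test_folded_sfs_folding_identity():
    # 2 diploids (n=4), derived counts 0..4 -> folded bins {0:2, 1:2, 2:1}
    gt = np.array([[0, 0], [1, 0], [2, 0], [2, 1], [2, 2]])
    sfs = folded_sfs(gt)
    assert sfs.counts.tolist() == [2, 2, 1]
    assert sfs.total_sites == 5


def test_folded_sfs_monomorphic_and_missing():
    gt = np.zeros((10, 3), dtype=int)
    gt[4, 1] = -1  # missing -> site dropped
    sfs = folded_sfs(gt)
    assert sfs.counts[0] == 9 and sfs.segregating_sites == 0


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_folded_sfs_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    gt = rng.integers(0, 3, size=(200, rng.integers(2, 6)))
    assert np.array_equal(folded_sfs(gt).counts, oracle_folded_sfs(gt))


def test_pi_simple_case():
    # n=2, one het site among 100 -> pi = 0.01
    sfs = td.FoldedSFS(n_haplotypes=2, counts=np.array([99, 1]))
    assert td.nucleotide_diversity(sfs) == pytest.approx(0.01)
    mono = td.FoldedSFS(n_haplotypes=2, counts=np.array([100, 0]))
    assert td.nucleotide_diversity(mono) == 0.0


def test_pi_matches_pairwise_oracle(rng):
    gt = rng.integers(0, 3, size=(10_000, 5))
    sfs = folded_sfs(gt)
    expected = oracle_pi_total(gt) / sfs.total_sites
    assert td.nucleotide_diversity(sfs) == pytest.approx(expected, abs=1e-12)


def test_pi_scale_invariance():
    sfs1 = td.FoldedSFS(4, np.array([90, 8, 2]))
    sfs2 = td.FoldedSFS(4, np.array([900, 80, 20]))
    assert td.nucleotide_diversity(sfs1) == pytest.approx(
        td.nucleotide_diversity(sfs2), abs=1e-15
    )


def test_tajimas_d_errors():
    with pytest.raises(ValueError, match="segregating"):
        td.tajimas_d(td.FoldedSFS(4, np.array([10, 0, 0])))
    with pytest.raises(ValueError, match="haplotypes"):
        td.tajimas_d(td.FoldedSFS(2, np.array([9, 1])))


def test_tajimas_d_matches_oracle(rng):
    gt = rng.integers(0, 3, size=(500, 4))
    assert td.tajimas_d(folded_sfs(gt)) == pytest.approx(oracle_tajimas_d(gt), abs=1e-12)


def test_tajimas_d_sign_convention():
    """Excess intermediate-frequency variants -> D > 0; excess rare -> D < 0."""
    n = 20
    balanced = np.zeros(n // 2 + 1, dtype=int)
    balanced[n // 2] = 50
    balanced[0] = 1000
    rare = np.zeros(n // 2 + 1, dtype=int)
    rare[1] = 50
    rare[0] = 1000
    assert td.tajimas_d(td.FoldedSFS(n, balanced)) > 0
    assert td.tajimas_d(td.FoldedSFS(n, rare)) < 0


def test_individual_heterozygosity():
    sfs = td.FoldedSFS(2, np.array([99, 1]))
    assert td.individual_heterozygosity(sfs) == pytest.approx(0.01)
    assert td.individual_heterozygosity(td.FoldedSFS(2, np.array([50, 0]))) == 0.0
    with pytest.raises(ValueError, match="n = 2"):
        td.individual_heterozygosity(td.FoldedSFS(4, np.array([1, 0, 0])))


def test_individual_het_equals_genotype_walk(rng):
    gt = rng.integers(0, 3, size=(5_000, 1))
    sfs = folded_sfs(gt)
    assert td.individual_heterozygosity(sfs) == pytest.approx((gt == 1).mean())


# ----------------------------------------------------------------------
def test_fst_identical_frequencies_near_zero(rng):
    freqs = rng.uniform(0.1, 0.9, 2_000)
    gt1 = rng.binomial(2, freqs[:, None], size=(2_000, 20))
    gt2 = rng.binomial(2, freqs[:, None], size=(2_000, 20))
    assert abs(hudson_fst(gt1, gt2)) < 0.01


def test_fst_fixed_differences_is_one():
    gt1 = np.zeros((100, 5), dtype=int)
    gt2 = np.full((100, 5), 2, dtype=int)
    assert hudson_fst(gt1, gt2) == pytest.approx(1.0)


def test_fst_matches_bruteforce_oracle(rng):
    gt1 = rng.integers(0, 3, size=(10_000, 4))
    gt2 = rng.integers(0, 3, size=(10_000, 4))
    assert hudson_fst(gt1, gt2) == pytest.approx(
        oracle_hudson_fst(gt1, gt2), abs=1e-12
    )


def test_windowed_stats_masking_and_means(rng):
    positions = np.sort(rng.integers(0, 150_000, 300))
    gts = {
        "a": rng.integers(0, 3, size=(300, 4)),
        "b": rng.integers(0, 3, size=(300, 4)),
    }
    res = windowed_stats(positions, gts, seq_length=200_000, window_bp=50_000,
                         min_sites=5)
    assert len(res.windows) == 4
    # last window has no sites -> masked, not zero
    assert np.isnan(res.windows.iloc[-1]["pi_a"])
    assert res.genome_means["pi_a"] == pytest.approx(
        res.windows["pi_a"].dropna().mean()
    )
    assert 0 <= res.genome_means["fst"] <= 1 or abs(res.genome_means["fst"]) < 0.1


# ----------------------------------------------------------------------
def test_expected_hybrid_het_limits():
    h1, h2, fst = 0.002, 0.003, 0.1
    assert td.expected_hybrid_heterozygosity(h1, h2, fst, 1.0) == pytest.approx(h1)
    assert td.expected_hybrid_heterozygosity(h1, h2, fst, 0.0) == pytest.approx(h2)
    # no differentiation, equal parents -> h for any alpha
    assert td.expected_hybrid_heterozygosity(0.002, 0.002, 0.0, 0.37) == pytest.approx(0.002)


def test_expected_hybrid_het_formula_value():
    h1, h2, fst, alpha = 0.002, 0.003, 0.1, 0.5
    h_b = ((h1 + h2) / 2) / (1 - fst)
    expected = alpha**2 * h1 + (1 - alpha) ** 2 * h2 + 2 * alpha * (1 - alpha) * h_b
    assert td.expected_hybrid_heterozygosity(h1, h2, fst, alpha) == pytest.approx(
        expected, abs=1e-15
    )
    with pytest.raises(ValueError, match="fst = 1"):
        td.expected_hybrid_heterozygosity(h1, h2, 1.0, alpha)


def test_expected_hybrid_het_linear_in_parents():
    base = td.expected_hybrid_heterozygosity(0.002, 0.003, 0.1, 0.3)
    bumped = td.expected_hybrid_heterozygosity(0.004, 0.003, 0.1, 0.3)
    double = td.expected_hybrid_heterozygosity(0.006, 0.003, 0.1, 0.3)
    assert double - bumped == pytest.approx(bumped - base, abs=1e-15)


# ----------------------------------------------------------------------
def test_rank_sum_w_convention_and_exact_p():
    """{1,2,3} vs {4,5,6}: W = 0 and exact two-sided p = 2/20 = 0.1."""
    res = temporal_comparison([1, 2, 3], [4, 5, 6])
    assert res.w == 0
    assert res.p_value == pytest.approx(0.1)
    mirror = temporal_comparison([4, 5, 6], [1, 2, 3])
    assert mirror.w == 9  # all n_a * n_b pairs
    assert mirror.p_value == pytest.approx(0.1)


def test_rank_sum_all_tied_warns():
    with pytest.warns(UserWarning, match="tied"):
        res = temporal_comparison([2, 2, 2], [2, 2, 2])
    assert res.p_value == 1.0


def test_rank_sum_exact_matches_enumeration(rng):
    """Exact p equals full enumeration of group assignments."""
    from itertools import combinations

    a = [0.3, 1.7, 2.2, 4.0]
    b = [0.9, 2.9, 3.1]
    pooled = np.array(a + b)
    w_obs = sum(x > y for x in a for y in b)
    n_a = len(a)
    ws = []
    for idx in combinations(range(len(pooled)), n_a):
        grp_a = pooled[list(idx)]
        grp_b = np.delete(pooled, list(idx))
        ws.append(sum(x > y for x in grp_a for y in grp_b))
    ws = np.array(ws)
    mu = len(a) * len(b) / 2
    p_exact = np.mean(np.abs(ws - mu) >= abs(w_obs - mu))
    res = temporal_comparison(a, b)
    assert res.w == w_obs
    assert res.p_value == pytest.approx(p_exact)
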