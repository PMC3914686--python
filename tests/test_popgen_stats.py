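import logging
import math

import numpy as np
import pandas as pd
import pytest

from indelpop import popgen_stats as pg


# ---------------------------------------------------------------------------
# Tajima's D

def brute_force_d(matrix):
    """Literal-textbook Tajima's D from a 0/1 haplotype matrix: explicit
    pairwise-difference count and constants written out long-hand."""
    n, S = matrix.shape
    pi = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pi += int(np.sum(matrix[i] != matrix[j]))
            npairs += 1
    pi /= npairs
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def test_tajimas_d_zero_when_pi_equals_watterson():
    n, S = 10, 5
    a1 = pg.tajima_constants(n)["a1"]
    assert pg.tajimas_d(S, S / a1, n) == pytest.approx(0.0)


def test_tajimas_d_hand_computed_n4():
    # two sites with derived counts (1, 2) in n=4: pi = 7/6, S = 2
    assert pg.tajimas_d(2, 7 / 6, 4) == pytest.approx(0.592, abs=5e-3)


def test_tajimas_d_negative_for_all_singletons():
    counts = np.ones(20, dtype=int)
    summ = pg.diversity_summary(counts, 10)
    assert summ.D < 0


def test_tajimas_d_matches_brute_force_on_random_matrices(rng):
    for _ in range(1000):
        n = int(rng.integers(4, 11))
        S = int(rng.integers(1, 25))
        matrix = np.zeros((n, S), dtype=int)
        for s in range(S):
            k = int(rng.integers(1, n))
            matrix[rng.choice(n, size=k, replace=False), s] = 1
        summ = pg.diversity_summary(matrix.sum(axis=0), n)
        assert summ.D == pytest.approx(brute_force_d(matrix), rel=1e-12)


def test_tajimas_d_undefined_without_segregation():
    assert math.isnan(pg.tajimas_d(0, 0.0, 10))
    assert math.isnan(pg.diversity_summary([], 10).D)


# ---------------------------------------------------------------------------
# Normalized Fay & Wu's H

def test_h_zero_when_pi_equals_theta_l():
    # for n=4 only the i=2 class has equal pi and theta_L weights
    assert pg.fay_wu_h_norm([0, 7, 0], 4) == pytest.approx(0.0)


def test_h_hand_computed_n4():
    assert pg.fay_wu_h_norm([2, 1, 0], 4) == pytest.approx(0.71, abs=5e-3)


def test_h_negative_under_high_frequency_derived_excess():
    assert pg.fay_wu_h_norm([0, 0, 12], 4) < 0


def test_h_anti_monotone_in_high_frequency_mass():
    n = 10
    base = np.array([5, 3, 2, 1, 1, 0, 0, 0, 0])
    shifted = base.copy()
    shifted[0] -= 2
    shifted[-1] += 2  # move mass from singletons to near-fixed derived
    assert pg.fay_wu_h_norm(shifted, n) < pg.fay_wu_h_norm(base, n)


def test_h_requires_polarized_spectrum_shape():
    with pytest.raises(ValueError):
        pg.fay_wu_h_norm([1, 2], 4)


# ---------------------------------------------------------------------------
# SFS / MAF

def test_sfs_and_maf_example():
    folded, maf, mean = pg.sfs_and_maf([1, 5, 9], 10)
    np.testing.assert_array_equal(folded, [2, 0, 0, 0, 1])
    np.testing.assert_allclose(sorted(maf), [0.1, 0.1, 0.5])
    assert mean == pytest.approx(0.7 / 3)


def test_sfs_excludes_monomorphic():
    folded, maf, _ = pg.sfs_and_maf([0, 10, 3], 10, warn_monomorphic=False)
    assert folded.sum() == 1 and len(maf) == 1


# ---------------------------------------------------------------------------
# Polarization

def test_polarize_cases():
    g = pd.DataFrame(
        {f"L{i}": [1 if i < 3 else 0, 1 if i < 3 else 0, 1 if i < 5 else 0]
         for i in range(10)}, index=["derived_del", "ancestral_del", "mixed_og"])
    og = pd.DataFrame({"OUT0": [0, 1, 0], "OUT1": [0, 1, 1]}, index=g.index)
    res = pg.polarize(g, og)
    assert res.loc["derived_del", "derived"] == 1
    assert res.loc["derived_del", "derived_is_minor"]
    assert res.loc["ancestral_del", "derived"] == 0
    assert not res.loc["ancestral_del", "derived_is_minor"]
    assert math.isnan(res.loc["mixed_og", "derived"])
    assert res.attrs["minor_derived_fraction"] == pytest.approx(0.5)


def test_polarize_exact_on_synthetic_truth(small_truth):
    """Error-free outgroups polarize every planted indel correctly."""
    geno = small_truth.indel_genotypes()
    cfg = small_truth.config
    og = pd.DataFrame(
        {o: [0 if r.deletion_is_derived else 1
             for r in small_truth.variants.itertuples()]
         for o in cfg.outgroup_lines}, index=geno.index)
    res = pg.polarize(geno, og)
    expect = small_truth.variants.set_index("id")["deletion_is_derived"]
    got = res["derived"] == 1
    assert (got == expect).all()


# ---------------------------------------------------------------------------
# Jackknife

def test_jackknife_constant_statistic_zero_width():
    mean, lo, hi, se = pg.jackknife_ci(list(range(10)), lambda xs: 42.0)
    assert (mean, se) == (42.0, 0.0) and lo == hi == 42.0


def test_jackknife_se_of_mean_matches_analytic():
    data = list(range(1, 11))
    _, _, _, se = pg.jackknife_ci(data, lambda xs: float(np.mean(xs)))
    analytic = np.std(data, ddof=1) / math.sqrt(len(data))
    assert se == pytest.approx(analytic, rel=1e-12)


def test_jackknife_needs_three_units():
    with pytest.raises(ValueError):
        pg.jackknife_ci([1, 2], np.mean)


# ---------------------------------------------------------------------------
# pi_A and allele age

def test_pi_a_mean_pairwise_over_window():
    h = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]])  # pairwise diffs 1,2,1
    assert pg.pi_a(h, 500) == pytest.approx((1 + 2 + 1) / 3 / 500)


def test_pi_a_identical_carriers_zero():
    assert pg.pi_a(np.zeros((4, 6)), 500) == 0.0


def test_pi_a_singleton_rejected():
    with pytest.raises(ValueError):
        pg.pi_a(np.zeros((1, 5)))


def test_pi_a_ignores_uncallable_sites():
    h = np.array([[0.0, np.nan], [1.0, 1.0]])
    assert pg.pi_a(h, 500) == pytest.approx(1 / 500)


@pytest.mark.parametrize("pia,expected", [(0.0031, 0.36), (0.0047, 0.54),
                                          (0.0055, 0.63), (0.0087, 1.0)])
def test_allele_age_scaling(pia, expected):
    assert round(pg.allele_age(pia, 0.0087), 2) == expected


def test_allele_age_invariant_to_joint_scaling():
    assert pg.allele_age(0.004, 0.008) == pg.allele_age(0.4, 0.8)


def test_allele_age_requires_positive_grand_mean():
    with pytest.raises(ValueError):
        pg.allele_age(0.003, 0.0)


# ---------------------------------------------------------------------------
# Diffusion mean age and |NeS| inversion

def test_neutral_closed_form():
    x = 0.2
    assert pg.mean_allele_age(x, 0.0) == pytest.approx(0.8047, abs=1e-4)
    # the numerical integrator converges to the closed form
    assert pg.mean_allele_age(x, 1e-4) == pytest.approx(
        pg.mean_allele_age(x, 0.0), abs=1e-4)


def test_mean_age_symmetric_in_selection_sign():
    for g in (0.5, 2.0, 7.5):
        assert pg.mean_allele_age(0.3, g) == pytest.approx(
            pg.mean_allele_age(0.3, -g), rel=1e-9)


def test_mean_age_strictly_decreasing_in_selection():
    ages = [pg.mean_allele_age(0.2, g) for g in (0.0, 1.0, 3.0, 10.0, 30.0)]
    assert all(a > b for a, b in zip(ages, ages[1:]))


def test_nes_recovery_on_gamma_grid():
    for g in (0.5, 1.9, 5.4, 12.0):
        T = pg.mean_allele_age(0.2, g)
        assert pg.nes_from_age(T, 0.2) == pytest.approx(g, rel=1e-4)


def test_nes_clamped_when_older_than_neutral(caplog):
    with caplog.at_level(logging.WARNING, logger="indelpop.popgen_stats"):
        assert pg.nes_from_age(1.5, 0.2) == 0.0
    assert "neutral" in caplog.text
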