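import numpy as np
import pytest

from psibound.geno_io import MISSING
from psibound.psi_stats import (
    adjacent_ld,
    binom_test_pair,
    heterozygosity,
    project_pair,
    projection_probs,
    psi_matrix,
    psi_pair,
)

from conftest import make_dataset, random_dataset


def test_projection_probs_match_hypergeometric():
    from scipy.stats import hypergeom

    for m, d in [(2, 0), (2, 1), (2, 2), (8, 3), (10, 10), (7, 1)]:
        p0, p1, p2 = projection_probs([d], [m])
        expect = hypergeom.pmf([0, 1, 2], m, d, 2)
        np.testing.assert_allclose([p0[0], p1[0], p2[0]], expect, atol=1e-12)


def test_projection_identity_for_two_copies():
    # one diploid: the projection must return the genotype itself
    p0, p1, p2 = projection_probs([0, 1, 2], [2, 2, 2])
    np.testing.assert_allclose(p0, [1, 0, 0])
    np.testing.assert_allclose(p1, [0, 1, 0])
    np.testing.assert_allclose(p2, [0, 0, 1])


def test_hand_counted_pair(two_pop_hand_dataset):
    f_ab, f_ba, S = project_pair(two_pop_hand_dataset, "A", "B")
    assert (f_ab, f_ba, S) == (1.0, 2.0, 5.0)
    assert psi_pair(f_ab, f_ba, S) == pytest.approx(-0.2)
    res = psi_matrix(two_pop_hand_dataset)
    assert res.psi[0, 1] == pytest.approx(-0.2)
    np.testing.assert_allclose(res.f_counts, [[0.0, 1.0], [2.0, 0.0]])
    assert res.seg_sites[0, 1] == pytest.approx(5.0)


def test_psi_direction_follows_fixation_excess():
    # B is fixed derived where A is het at 3 sites; no mirror sites
    ds = make_dataset([[1, 2], [1, 2], [1, 2], [1, 1]], ["A", "B"])
    res = psi_matrix(ds)
    # expansion signal points from A toward B: psi_AB > 0
    assert res.psi[0, 1] > 0


def test_psi_matrix_antisymmetric_zero_diagonal(rng):
    ds = random_dataset(rng, n_sites=300, pops=("A", "B", "C", "D"),
                        missing_rate=0.1)
    res = psi_matrix(ds)
    np.testing.assert_allclose(res.psi, -res.psi.T, atol=1e-14)
    np.testing.assert_allclose(np.diag(res.psi), 0.0, atol=0)


def test_psi_matrix_agrees_with_pairwise(rng):
    ds = random_dataset(rng, n_sites=150, pops=("A", "B", "C"), missing_rate=0.15)
    res = psi_matrix(ds)
    pops = res.populations
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            f_ij, f_ji, S = project_pair(ds, pops[i], pops[j])
            assert res.psi[i, j] == pytest.approx(psi_pair(f_ij, f_ji, S))
            assert res.f_counts[i, j] == pytest.approx(f_ij)
            assert res.seg_sites[i, j] == pytest.approx(S)


def test_psi_invariant_to_sample_size_at_fixed_frequencies():
    # psi depends only on per-population frequencies: doubling every individual
    # leaves the projection expectations unchanged
    base = np.array([[1, 2], [0, 1], [2, 1], [1, 1]])
    small = make_dataset(base, ["A", "B"])
    doubled = make_dataset(np.repeat(base, 2, axis=1),
                           ["A", "A", "B", "B"])
    f1 = project_pair(small, "A", "B")
    f2 = project_pair(doubled, "A", "B")
    # counts rescale but psi is identical
    assert psi_pair(*f1) == pytest.approx(psi_pair(*f2))


def test_binom_test_exact_values():
    assert binom_test_pair(10, 0)[0] == pytest.approx(0.001953125, abs=0, rel=0)
    assert binom_test_pair(2, 1)[0] == pytest.approx(1.0)
    p, degenerate = binom_test_pair(0, 0)
    assert p == 1.0 and degenerate


def test_binom_test_rounds_half_to_even():
    # 2.5 -> 2 and 1.5 -> 2 under numpy rounding
    p_a, _ = binom_test_pair(2.5, 1.5)
    p_b, _ = binom_test_pair(2, 2)
    assert p_a == p_b


def test_psi_pair_warns_on_zero_segregating():
    with pytest.warns(UserWarning, match="segregating"):
        assert np.isnan(psi_pair(0.0, 0.0, 0.0))


def test_psi_matrix_bonferroni_alpha():
    ds = make_dataset([[1, 2, 0], [0, 1, 1]], ["A", "B", "C"])
    res = psi_matrix(ds, alpha=0.05)
    assert res.alpha_adjusted == pytest.approx(0.05 / 3)


def test_psi_matrix_rejects_uncalled_population():
    ds = make_dataset([[1, MISSING], [0, MISSING]], ["A", "B"])
    with pytest.raises(ValueError, match="no called genotypes"):
        psi_matrix(ds)


def test_min_called_individuals_masks_sites():
    # second site has only 1 called individual in B at min 2 -> excluded
    dosages = [[1, 1, 2, 2], [1, 1, 2, MISSING]]
    ds = make_dataset(dosages, ["A", "A", "B", "B"])
    _, _, S2 = project_pair(ds, "A", "B", min_called_individuals=2)
    _, _, S1 = project_pair(ds, "A", "B", min_called_individuals=1)
    assert S2 < S1


def test_heterozygosity_values():
    ds = make_dataset([[1, 0], [2, 1], [0, 2]], ["A", "B"])
    div = heterozygosity(ds)
    # pop A freqs: 0.5, 1, 0 -> 2p(1-p) = 0.5, 0, 0 -> mean 1/6
    assert div.as_dict()["A"] == pytest.approx(1 / 6)
    assert div.as_dict()["B"] == pytest.approx(1 / 6)


def test_adjacent_ld_perfect_and_zero():
    # sites 1 and 2: identical columns -> r^2 = 1; site 3 orthogonal
    dosages = np.array([
        [0, 1, 2, 0, 1, 2],
        [0, 1, 2, 0, 1, 2],
        [2, 2, 2, 0, 0, 0],
        [0, 1, 2, 0, 1, 2],
    ])
    ds = make_dataset(dosages, ["A"] * 3 + ["B"] * 3,
                      positions=[10, 20, 30, 40])
    frac, n_pairs = adjacent_ld(ds, threshold=0.2)
    assert n_pairs == 3
    assert frac == pytest.approx(1 / 3)


def test_adjacent_ld_orders_by_position():
    # same data, shuffled row order with positions preserved
    dosages = np.array([
        [0, 1, 2, 0, 1, 2],
        [2, 2, 2, 0, 0, 0],
        [0, 1, 2, 0, 1, 2],
        [0, 1, 2, 0, 1, 2],
    ])
    ds = make_dataset(dosages, ["A"] * 3 + ["B"] * 3,
                      positions=[10, 30, 20, 40])
    frac, n_pairs = adjacent_ld(ds, threshold=0.2)
    assert (frac, n_pairs) == (pytest.approx(1 / 3), 3)


def test_adjacent_ld_requires_positions():
    ds = make_dataset([[0, 1], [1, 0]], ["A", "B"])
    with pytest.raises(ValueError, match="positions"):
        adjacent_ld(ds)
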