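"""Dissimilarity statistics against hand arithmetic and brute-force oracles."""

import math

import numpy as np
import pytest

from cidrgn.statistics import (
    combine,
    gamma_j,
    gamma_lambda_subnetwork,
    gamma_profile,
    gamma_subnetwork,
    gsca_statistic,
    lambda_j,
    lambda_profile,
    lambda_subnetwork,
    regulatory_effects,
    samgs_statistic,
    ss_gamma_profile,
    ss_lambda_j,
    ss_lambda_profile,
    ss_regulatory_effects,
    ss_effect_tensor,
)

from conftest import random_instance


# ---------------------------------------------------------------------------
# SAM-GS
# ---------------------------------------------------------------------------

def test_samgs_hand_computed_single_gene():
    # one gene, x_A = (1,2,3), x_B = (3,4,5), s0 = 0:
    # a = (1/3+1/3)/4 = 1/6, pooled SS = 4, s = sqrt(4/6), D = 4/s
    values = np.array([[1.0], [2.0], [3.0], [3.0], [4.0], [5.0]])
    in_a = np.array([True, True, True, False, False, False])
    d = samgs_statistic(values, in_a, ~in_a, np.array([0]), s0=0.0)
    s = math.sqrt(4.0 / 6.0)
    assert d == pytest.approx(4.0 / s, abs=1e-12)
    assert d == pytest.approx(4.899, abs=1e-3)


def test_samgs_zero_when_means_equal():
    values = np.array([[1.0, 2.0]] * 6)
    in_a = np.array([True] * 3 + [False] * 3)
    assert samgs_statistic(values, in_a, ~in_a, np.array([0, 1]), s0=1.0) == 0.0


def test_samgs_decreases_in_s0():
    values, in_a, in_b, *_ = random_instance(0)
    idx = np.arange(3)
    d1 = samgs_statistic(values, in_a, in_b, idx, s0=0.5)
    d2 = samgs_statistic(values, in_a, in_b, idx, s0=1.0)
    assert d2 < d1


def test_samgs_requires_two_cell_lines_per_phenotype():
    values = np.ones((3, 2))
    in_a = np.array([True, False, False])
    with pytest.raises(ValueError):
        samgs_statistic(values, in_a, ~in_a, np.array([0]))


@pytest.mark.parametrize("scatter", ["sqrt", "raw"])
def test_samgs_matches_loop_oracle(scatter):
    for seed in range(20):
        values, in_a, in_b, *_ = random_instance(seed)
        idx = np.array([0, 2, 4])
        na, nb = in_a.sum(), in_b.sum()
        a = (1 / na + 1 / nb) / (na + nb - 2)
        s = []
        for j in range(values.shape[1]):
            xa, xb = values[in_a, j], values[in_b, j]
            ss = ((xa - xa.mean()) ** 2).sum() + ((xb - xb.mean()) ** 2).sum()
            s.append(math.sqrt(a * ss) if scatter == "sqrt" else a * ss)
        s0 = float(np.median(s))
        expected = sum(
            (values[in_a, j].mean() - values[in_b, j].mean()) ** 2 / (s[j] + s0)
            for j in idx
        )
        got = samgs_statistic(values, in_a, in_b, idx, s0="median", scatter=scatter)
        assert got == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# GSCA
# ---------------------------------------------------------------------------

def test_gsca_zero_for_identical_correlations():
    values, in_a, in_b, *_ = random_instance(1)
    values[in_b] = values[in_a]  # identical data => identical correlations
    assert gsca_statistic(values, in_a, in_b, np.arange(4)) == pytest.approx(0.0)

def test_gsca_two_genes_opposite_correlation():
    # c_A = 1, c_B = -1 -> (1-(-1))^2 / 1 = 4
    t = np.linspace(0, 1, 5)
    values = np.concatenate([np.column_stack([t, t]),
                             np.column_stack([t, -t])])
    in_a = np.array([True] * 5 + [False] * 5)
    assert gsca_statistic(values, in_a, ~in_a, np.array([0, 1])) == pytest.approx(4.0)


def test_gsca_matches_pairwise_loop_oracle():
    for seed in range(20):
        values, in_a, in_b, *_ = random_instance(seed, g=4)
        k = 4
        total = 0.0
        for kk in range(1, k):
            for j in range(kk):
                ca = np.corrcoef(values[in_a][:, kk], values[in_a][:, j])[0, 1]
                cb = np.corrcoef(values[in_b][:, kk], values[in_b][:, j])[0, 1]
                total += (ca - cb) ** 2
        expected = total / (k * (k - 1) / 2)
        got = gsca_statistic(values, in_a, in_b, np.arange(k))
        assert got == pytest.approx(expected, abs=1e-10)


def test_gsca_constant_gene_contributes_zero_correlation():
    values, in_a, in_b, *_ = random_instance(2, g=3)
    values[in_a, 0] = 5.0  # constant within phenotype A
    with pytest.warns(UserWarning):
        got = gsca_statistic(values, in_a, in_b, np.arange(3))
    cb = np.corrcoef(values[in_b], rowvar=False)
    ca = np.corrcoef(values[in_a], rowvar=False)
    ca = np.nan_to_num(ca, nan=0.0)
    expected = (
        (ca[1, 0] - cb[1, 0]) ** 2
        + (ca[2, 0] - cb[2, 0]) ** 2
        + (ca[2, 1] - cb[2, 1]) ** 2
    ) / 3
    assert got == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# Regulatory effects, gamma, lambda
# ---------------------------------------------------------------------------

def test_regulatory_effects_single_edge():
    coef = np.zeros((3, 3))
    coef[1, 0] = 2.0  # gene 0 regulates target 1
    means = np.array([0.5, 1.0, 1.0])
    r = regulatory_effects(coef, means, 0)
    assert r[1] == pytest.approx(1.0)  # first block, target 1
    assert np.count_nonzero(r) == 1
    assert r.size == 6


def test_regulatory_effects_matches_elementwise_oracle():
    for seed in range(10):
        values, in_a, in_b, coef_a, _ = random_instance(seed)
        means = values[in_a].mean(axis=0)
        g = coef_a.shape[0]
        for j in range(g):
            expected = np.concatenate(
                [[coef_a[l, j] * means[j] for l in range(g)],
                 [coef_a[j, k] * means[k] for k in range(g)]]
            )
            assert np.allclose(regulatory_effects(coef_a, means, j), expected,
                               atol=1e-12)


def test_regulatory_effects_target_mean_reading():
    coef = np.zeros((3, 3))
    coef[1, 0] = 2.0
    means = np.array([0.5, 4.0, 1.0])
    r = regulatory_effects(coef, means, 0, mean_of="target")
    assert r[1] == pytest.approx(8.0)  # scaled by the target's mean
    with pytest.raises(ValueError):
        regulatory_effects(coef, means, 0, mean_of="nope")


def test_gamma_j_examples():
    assert gamma_j([1.0, 0, 0, 0], [0.0, 0, 0, 0]) == pytest.approx(0.25)
    v = np.arange(20.0)
    assert gamma_j(v, v) == 0.0
    with pytest.raises(ValueError):
        gamma_j([1.0], [1.0, 2.0])


def test_gamma_and_lambda_subnetwork_means():
    assert gamma_subnetwork([0.2, 0.4]) == pytest.approx(0.3)
    assert lambda_subnetwork([0.0, 1.0]) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        gamma_subnetwork([])


def test_lambda_j_examples():
    assert lambda_j({"a", "b"}, {"a", "b"}) == 0.0
    assert lambda_j({"g2", "g3"}, {"g3", "g4"}) == pytest.approx(2.0 / 3.0)
    assert lambda_j({"a"}, {"b"}) == 1.0
    assert lambda_j(set(), set()) == 0.0  # identically disconnected genes


def test_gamma_lambda_examples():
    gam = np.array([0.5])
    assert gamma_lambda_subnetwork(gam, np.array([0.5])) == pytest.approx(0.75)
    gammas = np.array([0.1, 0.2, 0.3])
    assert gamma_lambda_subnetwork(gammas, np.zeros(3)) == pytest.approx(
        gamma_subnetwork(gammas)
    )


def test_combine_variants():
    assert combine(1, gamma_lambda=1.5, samgs=-0.5) == pytest.approx(1.0)
    assert combine(2, gamma=1.0, lam=2.0, samgs=3.0) == pytest.approx(6.0)
    assert combine(2, gamma=0.0, lam=0.0, samgs=0.0) == 0.0
    with pytest.raises(ValueError):
        combine(3, gamma=1, lam=1, samgs=1)


def test_vectorized_profiles_match_per_gene_oracles():
    """gamma_profile / lambda_profile agree with the scalar definitions."""
    for seed in range(25):
        values, in_a, in_b, coef_a, coef_b = random_instance(seed)
        mean_a = values[in_a].mean(axis=0)
        mean_b = values[in_b].mean(axis=0)
        g = coef_a.shape[0]
        gp = gamma_profile(coef_a, coef_b, mean_a, mean_b)
        adj_a = (np.abs(coef_a) > 0) | (np.abs(coef_a.T) > 0)
        adj_b = (np.abs(coef_b) > 0) | (np.abs(coef_b.T) > 0)
        np.fill_diagonal(adj_a, False)
        np.fill_diagonal(adj_b, False)
        lp = lambda_profile(adj_a, adj_b)
        for j in range(g):
            ra = regulatory_effects(coef_a, mean_a, j)
            rb = regulatory_effects(coef_b, mean_b, j)
            assert gp[j] == pytest.approx(gamma_j(ra, rb), abs=1e-10)
            na = {k for k in range(g) if adj_a[j, k]}
            nb = {k for k in range(g) if adj_b[j, k]}
            assert lp[j] == pytest.approx(lambda_j(na, nb), abs=1e-10)


# ---------------------------------------------------------------------------
# Sample-specific variants
# ---------------------------------------------------------------------------

def test_ss_regulatory_effects_median_examples():
    # all effects equal c -> entry c; (1, 2, 100) -> median 2
    g = 2
    coef = np.zeros((3, g, g))
    coef[:, 1, 0] = [1.0, 2.0, 100.0]
    x = np.ones((3, g))
    eff = ss_effect_tensor(coef, x)
    r = ss_regulatory_effects(eff, np.array([True] * 3), 0)
    assert r[1] == pytest.approx(2.0)


def test_ss_effects_and_profiles_match_loop_oracles():
    for seed in range(15):
        rng = np.random.default_rng(seed)
        n, g = 10, 5
        coef = rng.standard_normal((n, g, g))
        di = np.arange(g)
        coef[:, di, di] = 0.0
        x = rng.standard_normal((n, g))
        in_a = np.zeros(n, dtype=bool)
        in_a[:5] = True
        in_b = ~in_a
        eff = ss_effect_tensor(coef, x)
        # oracle: explicit per-cell-line products and medians
        gp = ss_gamma_profile(eff, in_a, in_b)
        for j in range(g):
            ra, rb = [], []
            for block in ("targets", "regulators"):
                for k in range(g):
                    if block == "targets":
                        pa = [coef[a, k, j] * x[a, j] for a in range(n) if in_a[a]]
                        pb = [coef[a, k, j] * x[a, j] for a in range(n) if in_b[a]]
                    else:
                        pa = [coef[a, j, k] * x[a, k] for a in range(n) if in_a[a]]
                        pb = [coef[a, j, k] * x[a, k] for a in range(n) if in_b[a]]
                    ra.append(np.median(pa))
                    rb.append(np.median(pb))
            assert gp[j] == pytest.approx(gamma_j(ra, rb), abs=1e-10)
            assert np.allclose(
                ss_regulatory_effects(eff, in_a, j), ra, atol=1e-12
            )
        # neighborhoods: unions within phenotypes then Jaccard
        adj = np.abs(coef) > 0.8
        adj = adj | adj.transpose(0, 2, 1)
        adj[:, di, di] = False
        lp = ss_lambda_profile(adj, in_a, in_b)
        for j in range(g):
            neigh = [
                {k for k in range(g) if adj[a, j, k]} for a in range(n)
            ]
            assert lp[j] == pytest.approx(
                ss_lambda_j(neigh, in_a, in_b), abs=1e-10
            )


def test_ss_lambda_union_example():
    # A-union {1,2,3}, B-union {3} -> 1 - 1/3
    neigh = [{1, 2}, {3}, {3}]
    in_a = np.array([True, True, False])
    in_b = np.array([False, False, True])
    assert ss_lambda_j(neigh, in_a, in_b) == pytest.approx(2.0 / 3.0)


# ---------------------------------------------------------------------------
# Invariance properties
# ---------------------------------------------------------------------------

def test_statistics_invariant_to_gene_relabeling_and_cell_order():
    values, in_a, in_b, coef_a, coef_b = random_instance(3)
    idx = np.arange(5)
    base_samgs = samgs_statistic(values, in_a, in_b, idx)
    base_gsca = gsca_statistic(values, in_a, in_b, idx)
    # permute cell-line order
    rng = np.random.default_rng(0)
    order = rng.permutation(values.shape[0])
    assert samgs_statistic(values[order], in_a[order], in_b[order], idx) == (
        pytest.approx(base_samgs, abs=1e-10)
    )
    assert gsca_statistic(values[order], in_a[order], in_b[order], idx) == (
        pytest.approx(base_gsca, abs=1e-10)
    )
    # permute gene labels (columns) consistently
    gperm = rng.permutation(5)
    gp = gamma_profile(coef_a, coef_b, values[in_a].mean(0), values[in_b].mean(0))
    gp_perm = gamma_profile(
        coef_a[np.ix_(gperm, gperm)],
        coef_b[np.ix_(gperm, gperm)],
        values[in_a].mean(0)[gperm],
        values[in_b].mean(0)[gperm],
    )
    assert np.allclose(np.sort(gp), np.sort(gp_perm), atol=1e-10)
    assert gp[gperm] == pytest.approx(gp_perm, abs=1e-10)
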