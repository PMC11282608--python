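"""Heterozygosity, nucleotide diversity, Tajima's D, incidence, Spearman."""

import numpy as np
import pytest
from scipy import stats

from hetscan.diversity_stats import (
    rank_correlation,
    site_heterozygosity,
    site_pi,
    snp_her_incidence,
    tajima_constants,
    tajimas_d,
)
from hetscan.her_detection import DetectionParams, detect_hers

from conftest import make_gm, random_gm
from _oracles import coverage_count, pairwise_pi, textbook_tajima_d


def test_all_heterozygous_site():
    gm = make_gm(np.ones((4, 1), dtype=int), [100])
    row = site_heterozygosity(gm).iloc[0]
    assert row.obs_het == 1.0
    assert row.exp_het == pytest.approx(0.5)  # p = 0.5


def test_monomorphic_site_has_zero_heterozygosity():
    gm = make_gm(np.zeros((6, 1), dtype=int), [100])
    row = site_heterozygosity(gm).iloc[0]
    assert row.obs_het == 0.0 and row.exp_het == 0.0


def test_heterozygosity_matches_allele_counting_oracle():
    gm = random_gm(np.random.default_rng(0), n_ind=15, n_sites=30)
    table = site_heterozygosity(gm)
    for j in range(gm.n_sites):
        col = gm.calls[:, j]
        called = col[col != -1]
        if len(called) == 0:
            assert np.isnan(table.obs_het[j])
            continue
        assert table.obs_het[j] == pytest.approx(
            np.mean(called == 1), abs=1e-12
        )
        p = sum({0: 0, 1: 1, 2: 2}[int(g)] for g in called) / (2 * len(called))
        assert table.exp_het[j] == pytest.approx(2 * p * (1 - p), abs=1e-12)


def test_pi_single_discordant_pair():
    gm = make_gm(np.array([[1]]), [100])  # k=2 alleles, j=1
    assert site_pi(gm)["pi"][0] == pytest.approx(1.0)


def test_pi_monomorphic_is_zero():
    gm = make_gm(np.zeros((5, 1), dtype=int), [100])
    assert site_pi(gm)["pi"][0] == 0.0


def test_pi_k10_j3_equals_42_over_90():
    # 5 individuals, alt dosages summing to 3
    gm = make_gm(np.array([[2], [1], [0], [0], [0]]), [100])
    assert site_pi(gm)["pi"][0] == pytest.approx(42 / 90)


def test_pi_matches_pair_enumeration_oracle():
    gm = random_gm(np.random.default_rng(1), n_ind=8, n_sites=25)
    pi = site_pi(gm)["pi"].to_numpy()
    for j in range(gm.n_sites):
        expected = pairwise_pi(gm.calls[:, j])
        if np.isnan(expected):
            assert np.isnan(pi[j])
        else:
            assert pi[j] == pytest.approx(expected, abs=1e-12)


def test_pi_exp_het_closed_form_relation():
    # pi = 2 p_hat (1 - p_hat) * k / (k - 1) at fully called sites
    gm = random_gm(np.random.default_rng(5), n_ind=10, n_sites=40,
                   missing_rate=0.0)
    het = site_heterozygosity(gm)
    pi = site_pi(gm)["pi"].to_numpy()
    k = 2 * gm.n_samples
    np.testing.assert_allclose(
        pi, het["exp_het"].to_numpy() * k / (k - 1), atol=1e-12
    )


# -- Tajima's D ---------------------------------------------------------


def test_a1_for_two_sequences_is_one():
    assert tajima_constants(2)["a1"] == pytest.approx(1.0)


def test_window_without_polymorphism_has_undefined_d():
    gm = make_gm(np.zeros((5, 4), dtype=int), [10, 20, 30, 40])
    tw = tajimas_d(gm, window_bp=100)
    assert len(tw) == 1 and np.isnan(tw.D[0]) and tw.S[0] == 0


def test_too_few_individuals_rejected():
    gm = make_gm(np.array([[1, 0, 1]]), [10, 20, 30])
    with pytest.raises(ValueError, match="at least 2"):
        tajimas_d(gm, 100)


def test_d_matches_brute_force_on_small_matrix():
    rng = np.random.default_rng(3)
    gm = random_gm(rng, n_ind=6, n_sites=8, missing_rate=0.0)
    tw = tajimas_d(gm, window_bp=10**9)  # one window per chromosome
    assert len(tw) == 1
    row = tw.iloc[0]
    pi_sum = sum(pairwise_pi(gm.calls[:, j]) for j in range(8))
    S = sum(
        1
        for j in range(8)
        if 0 < sum(int(g) for g in gm.calls[:, j]) < 2 * 6
    )
    expected = textbook_tajima_d(S, pi_sum, n=12)
    assert row.S == S
    assert row.D == pytest.approx(expected, abs=1e-9)


def test_windows_partition_sites(ref_gm, ref_tajima):
    assert ref_tajima["n_sites"].sum() == ref_gm.n_sites
    assert (ref_tajima["window_end"] - ref_tajima["window_start"] == 9_999).all()


def test_planted_islands_raise_windowed_d(ref_gm, ref_truth, ref_tajima):
    tw = ref_tajima
    inside = np.zeros(len(tw), dtype=bool)
    for isl in ref_truth:
        inside |= (
            (tw.chrom == isl.chrom)
            & (tw.window_start <= isl.end)
            & (tw.window_end >= isl.start)
        ).to_numpy()
    assert np.nanmean(tw.D[inside]) > np.nanmean(tw.D[~inside])
    assert (tw.D[inside].dropna() > 0).all()


# -- incidence ----------------------------------------------------------


def test_incidence_all_and_none():
    gm = make_gm(np.ones((3, 6), dtype=int), np.arange(1, 7) * 100)
    hers = detect_hers(gm, DetectionParams(1, 1000, 0, 0))
    track = snp_her_incidence(hers, gm)
    np.testing.assert_allclose(track, 1.0)
    empty = detect_hers(gm, DetectionParams(10, 1000, 0, 0))
    np.testing.assert_allclose(snp_her_incidence(empty, gm), 0.0)


def test_incidence_matches_interval_stabbing_oracle():
    rng = np.random.default_rng(8)
    geno = rng.choice([-1, 0, 1, 2], size=(12, 60), p=[0.05, 0.25, 0.5, 0.2])
    pos = np.cumsum(rng.integers(1, 500, size=60))
    gm = make_gm(geno, pos)
    hers = detect_hers(gm, DetectionParams(2, 1000, 0, 1))
    track = snp_her_incidence(hers, gm)
    rows = [
        (r.individual, r.chrom, r.start, r.end) for r in hers.itertuples()
    ]
    for j in range(gm.n_sites):
        assert track[j] == pytest.approx(
            coverage_count(rows, "1", pos[j]) / 12, abs=1e-12
        )


def test_incidence_positive_inside_planted_islands(ref_gm, ref_truth,
                                                   scenarios9_tracks):
    chroms = ref_gm.sites["chrom"].to_numpy()
    pos = ref_gm.sites["pos"].to_numpy()
    for isl in ref_truth:
        sel = (chroms == isl.chrom) & (pos >= isl.start) & (pos <= isl.end)
        for track in scenarios9_tracks.values():
            assert track[sel].mean() > 0.10


# -- Spearman -----------------------------------------------------------


def test_rank_correlation_monotone_vectors():
    x = np.array([1.0, 2.0, 5.0, 9.0])
    assert rank_correlation(x, x * 3 + 1) == pytest.approx(1.0)
    assert rank_correlation(x, -x) == pytest.approx(-1.0)


def test_rank_correlation_with_ties_matches_rank_then_pearson():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 5, size=40).astype(float)  # heavy ties
    y = rng.integers(0, 5, size=40).astype(float)
    expected = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
    assert rank_correlation(x, y) == pytest.approx(expected, abs=1e-12)


def test_rank_correlation_constant_vector_flagged():
    with pytest.warns(UserWarning, match="constant"):
        assert np.isnan(rank_correlation([1, 1, 1, 1], [1, 2, 3, 4]))


def test_rank_correlation_uses_paired_nonmissing():
    x = np.array([1, 2, 3, np.nan, 5])
    y = np.array([2, 4, 6, 8, np.nan])
    assert rank_correlation(x, y) == pytest.approx(1.0)


def test_incidence_correlates_with_heterozygosity(ref_gm, scenarios9_tracks):
    het = site_heterozygosity(ref_gm)["obs_het"].to_numpy()
    for track in scenarios9_tracks.values():
        assert rank_correlation(track, het) > 0
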