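"""Scanner semantics: greedy consecutive runs, trimming, filters, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hetscan.her_detection import (
    BELOW_RANGE_LABEL,
    DetectionParams,
    chromosome_coverage,
    classify_lengths,
    detect_hers,
)

from conftest import make_gm
from _oracles import brute_force_hers


def _runs(gm, params):
    df = detect_hers(gm, params)
    return [
        (int(r.start_idx), int(r.end_idx), int(r.n_hom), int(r.n_miss))
        for r in df.itertuples()
    ]


def test_all_homozygous_yields_no_runs():
    gm = make_gm(np.zeros((3, 12), dtype=int), np.arange(1, 13) * 100)
    assert len(detect_hers(gm, DetectionParams(1, 10_000, 0, 5, 5))) == 0


def test_textbook_run_of_six_heterozygotes():
    gm = make_gm([[1, 1, 1, 1, 1, 1]], [100, 200, 300, 400, 500, 600])
    df = detect_hers(gm, DetectionParams(min_snp=5, max_gap=500_000,
                                         min_length=0, max_hom=0))
    assert len(df) == 1
    row = df.iloc[0]
    assert (row.start, row.end, row.n_snp, row.length_bp) == (100, 600, 6, 500)


def test_boundaries_are_trimmed_to_heterozygous_snps():
    # hom flanks around a het core must not inflate the interval
    gm = make_gm([[0, 0, 1, 0, 1, 1, 0, 0]], np.arange(1, 9) * 1000)
    df = detect_hers(gm, DetectionParams(min_snp=1, max_gap=10_000,
                                         min_length=0, max_hom=1))
    # run is the het core 3000..6000 (hets at 3000, 5000, 6000, one
    # tolerated hom at 4000); the hom flanks are never part of the interval
    assert (df["start"].tolist(), df["end"].tolist()) == ([3000], [6000])
    assert df.iloc[0].n_hom == 1


def test_gap_rule_splits_runs_regardless_of_genotype():
    pos = [100, 200, 300, 10_000_000, 10_000_100]
    gm = make_gm([[1, 1, 1, 1, 1]], pos)
    df = detect_hers(gm, DetectionParams(1, 1000, 0, 0))
    assert df["start"].tolist() == [100, 10_000_000]
    assert df["end"].tolist() == [300, 10_000_100]


def test_missing_calls_tolerated_up_to_max_miss():
    gm = make_gm([[1, -1, 1, -1, 1]], [10, 20, 30, 40, 50])
    one = detect_hers(gm, DetectionParams(1, 100, 0, 0, max_miss=2))
    assert len(one) == 1 and one.iloc[0].n_miss == 2
    split = detect_hers(gm, DetectionParams(1, 100, 0, 0, max_miss=1))
    assert len(split) == 2  # second missing call closes the first run


def test_runs_never_overlap_within_individual(ref_gm):
    df = detect_hers(ref_gm, DetectionParams(5, 500_000, 0, 2))
    for (_, chrom), grp in df.groupby(["individual", "chrom"]):
        grp = grp.sort_values("start")
        assert (grp["start"].to_numpy()[1:] > grp["end"].to_numpy()[:-1]).all()


@pytest.mark.parametrize("seed", range(8))
def test_matches_brute_force_enumeration_on_random_chromosomes(seed):
    rng = np.random.default_rng(seed)
    geno = rng.choice([-1, 0, 1, 2], size=20, p=[0.1, 0.3, 0.35, 0.25])
    pos = np.cumsum(rng.integers(1, 1000, size=20))
    gm = make_gm(geno, pos)
    for params in [
        DetectionParams(1, 600, 0, 0, 0),
        DetectionParams(2, 600, 2000, 1, 1),
        DetectionParams(5, 5000, 3000, 3, 2),
        DetectionParams(1, 10**9, 0, 5, 5),
    ]:
        assert _runs(gm, params) == brute_force_hers(geno, pos, params)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    geno=st.lists(st.sampled_from([-1, 0, 1, 2]), min_size=1, max_size=18),
    gaps=st.lists(st.integers(1, 500), min_size=18, max_size=18),
    max_gap=st.integers(50, 2000),
    max_hom=st.integers(0, 4),
    max_miss=st.integers(0, 3),
    min_snp=st.integers(1, 6),
    min_length=st.integers(0, 3000),
)
def test_scanner_equals_oracle_property(
    geno, gaps, max_gap, max_hom, max_miss, min_snp, min_length
):
    pos = np.cumsum(gaps[: len(geno)])
    gm = make_gm(np.asarray(geno), pos)
    params = DetectionParams(min_snp, max_gap, min_length, max_hom, max_miss)
    assert _runs(gm, params) == brute_force_hers(geno, pos, params)


def test_count_monotone_in_post_filters():
    rng = np.random.default_rng(7)
    geno = rng.choice([0, 1, 2], size=(10, 200), p=[0.3, 0.45, 0.25])
    pos = np.cumsum(rng.integers(1, 2000, size=200))
    gm = make_gm(geno, pos)
    counts_snp = [
        len(detect_hers(gm, DetectionParams(ms, 10_000, 0, 2)))
        for ms in (1, 3, 5, 8, 12)
    ]
    assert counts_snp == sorted(counts_snp, reverse=True)
    counts_len = [
        len(detect_hers(gm, DetectionParams(1, 10_000, ml, 2)))
        for ml in (0, 2000, 5000, 20_000)
    ]
    assert counts_len == sorted(counts_len, reverse=True)


def test_reversed_chromosome_gives_mirrored_runs():
    # exact mirror symmetry holds for tolerance-free runs (max_hom=0,
    # max_miss=0); with tolerance the greedy left-to-right closure is
    # directional by design
    rng = np.random.default_rng(11)
    geno = rng.choice([-1, 0, 1, 2], size=40, p=[0.05, 0.3, 0.4, 0.25])
    pos = np.cumsum(rng.integers(1, 800, size=40))
    params = DetectionParams(1, 1500, 0, 0, 0)
    fwd = detect_hers(make_gm(geno, pos), params)
    total = pos[-1] + 1
    rev = detect_hers(make_gm(geno[::-1].copy(), total - pos[::-1]), params)
    mirrored = sorted(
        (int(total - r.end), int(total - r.start)) for r in rev.itertuples()
    )
    assert sorted((int(r.start), int(r.end)) for r in fwd.itertuples()) == mirrored


# -- length classification and coverage ---------------------------------


def test_length_classes_bin_edges():
    counts = classify_lengths(np.array([12_000, 25_000, 55_000]))
    assert counts["10-20 Kb"] == 1
    assert counts["20-30 Kb"] == 1
    assert counts[">=50 Kb"] == 1
    assert counts[BELOW_RANGE_LABEL] == 0


def test_length_exactly_20kb_falls_in_left_closed_bin():
    assert classify_lengths(np.array([20_000]))["20-30 Kb"] == 1


def test_reference_largest_island_length_class():
    # the longest island of the packaged Holstein set: 359.06 Kb
    length = 24_459_318 - 24_100_254
    assert length == 359_064
    assert classify_lengths(np.array([length]))[">=50 Kb"] == 1


def test_short_runs_counted_in_below_range_bucket():
    counts = classify_lengths(np.array([5_000, 9_999, 10_000]))
    assert counts[BELOW_RANGE_LABEL] == 2
    assert counts.sum() == 3


def test_chromosome_coverage_arithmetic():
    hers = pd.DataFrame(
        {"individual": ["a"], "chrom": ["1"], "start": [10],
         "end": [1010], "length_bp": [1000]}
    )
    cov = chromosome_coverage(hers, {"1": 100_000}, n_individuals=1)
    assert cov["1"] == pytest.approx(1.0)
    # averaged over two individuals the coverage halves
    cov2 = chromosome_coverage(hers, {"1": 100_000}, n_individuals=2)
    assert cov2["1"] == pytest.approx(0.5)


def test_chromosome_coverage_empty_and_errors():
    empty = pd.DataFrame(
        columns=["individual", "chrom", "start", "end", "length_bp"]
    )
    assert (chromosome_coverage(empty, {"1": 1000}, 5) == 0).all()
    with pytest.raises(ValueError):
        chromosome_coverage(empty, {"1": 0}, 5)


def test_coverage_matches_direct_summation(ref_gm):
    hers = detect_hers(ref_gm, DetectionParams(10, 500_000, 10_000, 2))
    lengths = {"1": 5_000_000, "2": 5_000_000}
    cov = chromosome_coverage(hers, lengths, ref_gm.n_samples)
    for chrom in lengths:
        direct = (
            hers.loc[hers.chrom == chrom, "length_bp"].sum()
            / (lengths[chrom] * ref_gm.n_samples)
            * 100
        )
        assert cov[chrom] == pytest.approx(direct, abs=1e-12)
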