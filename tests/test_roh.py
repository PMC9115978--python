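"""Scanner unit tests, the brute-force window oracle, and summaries."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from rohscan import (
    ROHParams,
    ROHSegment,
    ROHSet,
    SampleRecord,
    call_roh_for_sample,
    chromosome_coverage,
    detect_roh,
    length_class_table,
    min_roh_snps,
    snp_in_run_flags,
    window_pass_flags,
)
from rohscan.genotype_io import MISSING
from rohscan.roh import read_segments_tsv, write_segments_tsv

from conftest import make_dataset

# ---------------------------------------------------------------------------
# brute-force oracle: materialise every window and every per-SNP ratio
# ---------------------------------------------------------------------------


def brute_force_segments(calls, pos, params):
    """Naive reference scanner for one chromosome."""
    calls = np.asarray(calls)
    pos = np.asarray(pos)
    n = calls.size
    w = params.window_snps
    windows = []
    for s in range(n - w + 1):
        chunk = calls[s : s + w]
        windows.append(
            (chunk == 1).sum() <= params.window_max_het
            and (chunk == MISSING).sum() <= params.window_max_missing
        )
    qual = []
    for i in range(n):
        containing = [s for s in range(len(windows)) if s <= i <= s + w - 1]
        if not containing:
            qual.append(False)
            continue
        frac = sum(windows[s] for s in containing) / len(containing)
        qual.append(frac >= params.window_threshold)
    # maximal runs of qualifying SNPs, split at large gaps, then filter
    segments = []
    i = 0
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and qual[j + 1]:
            j += 1
        pieces = [[i]]
        for k in range(i + 1, j + 1):
            if pos[k] - pos[k - 1] > params.max_gap_kb * 1000.0:
                pieces.append([])
            pieces[-1].append(k)
        for piece in pieces:
            n_snps = len(piece)
            start_bp, end_bp = int(pos[piece[0]]), int(pos[piece[-1]])
            length_bp = end_bp - start_bp + 1
            if (
                n_snps >= params.min_snps
                and length_bp >= params.min_length_kb * 1000.0
                and (length_bp / 1000.0) / n_snps <= params.min_density_kb_per_snp
            ):
                segments.append((start_bp, end_bp, n_snps))
        i = j + 1
    return segments


def random_chromosome(rng, n):
    """Genotypes with alternating high/low-heterozygosity stretches so that
    runs, splits and near-threshold windows all occur."""
    calls = np.empty(n, dtype=np.int8)
    i = 0
    while i < n:
        block = int(rng.integers(20, 200))
        p_het = rng.choice([0.0, 0.005, 0.02, 0.3, 0.5])
        block = min(block, n - i)
        r = rng.random(block)
        calls[i : i + block] = np.where(
            r < p_het, 1, np.where(rng.random(block) < 0.5, 0, 2)
        )
        miss = rng.random(block) < rng.choice([0.0, 0.02, 0.1])
        calls[i : i + block][miss] = MISSING
        i += block
    gaps = rng.choice(
        [20_000, 40_000, 80_000, 1_500_000], size=n - 1, p=[0.5, 0.3, 0.19, 0.01]
    )
    pos = 50_000 + np.concatenate([[0], np.cumsum(gaps)])
    return calls, pos.astype(np.int64)


def production_segments(calls, pos, params):
    ds = make_dataset(calls.reshape(1, -1), positions=pos)
    segs = call_roh_for_sample(ds, "s0", params)
    return [(s.start_bp, s.end_bp, s.n_snps) for s in segs]


def test_scanner_matches_brute_force_small_batch(rng):
    params = ROHParams()
    for _ in range(20):
        n = int(rng.integers(10, 800))
        calls, pos = random_chromosome(rng, n)
        assert production_segments(calls, pos, params) == brute_force_segments(
            calls, pos, params
        )


def test_scanner_matches_brute_force_unusual_params(rng):
    params = ROHParams(
        min_length_kb=200.0,
        min_snps=10,
        max_gap_kb=300.0,
        min_density_kb_per_snp=60.0,
        window_snps=10,
        window_max_het=0,
        window_max_missing=2,
        window_threshold=0.5,
    )
    for _ in range(20):
        n = int(rng.integers(5, 400))
        calls, pos = random_chromosome(rng, n)
        assert production_segments(calls, pos, params) == brute_force_segments(
            calls, pos, params
        )


# ---------------------------------------------------------------------------
# minimum-SNP rule
# ---------------------------------------------------------------------------


def test_min_roh_snps_powers_of_half():
    # alpha/(n_s*n_i) = 0.25, het = 0.5 -> ln(.25)/ln(.5) = 2 exactly
    assert min_roh_snps(alpha=0.25, n_s=1, n_i=1, het=0.5) == 2


def test_min_roh_snps_high_precision_oracle():
    alpha, n_s, n_i, het = 0.05, 54075, 320, 0.33
    exact = sympy.log(sympy.Rational(alpha * 1e9, int(n_s * n_i * 1e9))) / sympy.log(
        1 - sympy.Rational(33, 100)
    )
    expected = int(sympy.ceiling(exact.evalf(50)))
    assert expected == 50  # frozen from the arbitrary-precision evaluation
    assert min_roh_snps(alpha, n_s, n_i, het) == expected


def test_min_roh_snps_monotone_in_het():
    values = [min_roh_snps(0.05, 50_000, 300, h) for h in (0.1, 0.2, 0.3, 0.4, 0.5)]
    assert values == sorted(values, reverse=True)


def test_min_roh_snps_domain_errors():
    with pytest.raises(ValueError):
        min_roh_snps(0.05, 100, 10, 0.0)
    with pytest.raises(ValueError):
        min_roh_snps(0.05, 100, 10, 1.0)


# ---------------------------------------------------------------------------
# window / per-SNP operations
# ---------------------------------------------------------------------------


def test_window_one_het_passes():
    calls = np.zeros(50, dtype=np.int8)
    calls[10] = 1
    assert window_pass_flags(calls, ROHParams()).tolist() == [True]


def test_window_two_hets_fail():
    calls = np.zeros(50, dtype=np.int8)
    calls[[10, 20]] = 1
    assert window_pass_flags(calls, ROHParams()).tolist() == [False]


def test_window_six_missing_fail():
    calls = np.zeros(50, dtype=np.int8)
    calls[:6] = MISSING
    assert window_pass_flags(calls, ROHParams()).tolist() == [False]
    calls[5] = 0  # five missing is allowed
    assert window_pass_flags(calls, ROHParams()).tolist() == [True]


def test_short_chromosome_yields_no_windows():
    assert window_pass_flags(np.zeros(49, dtype=np.int8), ROHParams()).size == 0


def test_snp_in_run_all_passing():
    flags = np.ones(100, dtype=bool)
    qual = snp_in_run_flags(flags, ROHParams())
    assert qual.all()


def test_snp_in_run_all_failing():
    flags = np.zeros(100, dtype=bool)
    qual = snp_in_run_flags(flags, ROHParams())
    assert not qual.any()


def test_snp_in_run_zero_windows():
    qual = snp_in_run_flags(np.zeros(0, dtype=bool), ROHParams(), n_snps=30)
    assert qual.size == 30 and not qual.any()


# ---------------------------------------------------------------------------
# segment calling
# ---------------------------------------------------------------------------


def test_all_heterozygous_sample_empty():
    ds = make_dataset(np.ones((1, 200), dtype=np.int8))
    assert call_roh_for_sample(ds, "s0") == []


def test_unknown_sample_errors(small_cohort):
    dataset, _ = small_cohort
    with pytest.raises(KeyError):
        call_roh_for_sample(dataset, "nope")


def test_planted_tract_recovered_exactly(small_cohort):
    """Tract bounds in the seeded cohort are recovered at the planted SNPs."""
    dataset, truth = small_cohort
    rohset = detect_roh(dataset)
    by_key = {}
    for seg in rohset.segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    eligible = truth.tracts[truth.tracts.n_snps >= 51]
    n_exact = 0
    for row in eligible.itertuples(index=False):
        segs = by_key.get((row.sample_id, row.chrom), [])
        if any(s.start_bp == row.start_bp and s.end_bp == row.end_bp for s in segs):
            n_exact += 1
    # missingness can perturb an occasional guard SNP; near-total exactness
    assert n_exact >= 0.95 * len(eligible)


def _plant_tract(n, lo, hi):
    """Simulator-style tract in a heterozygous background: homozygous run
    with heterozygous first/last SNPs (the flanks are already het)."""
    calls = np.ones((1, n), dtype=np.int8)
    calls[0, lo + 1 : hi] = 0
    return calls


def test_tract_of_49_snps_not_called():
    n = 400
    calls = _plant_tract(n, 100, 148)  # 49 SNPs including het endpoints
    ds = make_dataset(calls, positions=[50_000 * (j + 1) for j in range(n)])
    assert call_roh_for_sample(ds, "s0") == []


def test_tract_of_60_snps_called_with_exact_bounds():
    n = 400
    pos = [40_000 * (j + 1) for j in range(n)]  # 60 SNPs span ~2.4 Mb
    calls = _plant_tract(n, 100, 159)
    ds = make_dataset(calls, positions=pos)
    segs = call_roh_for_sample(ds, "s0")
    assert len(segs) == 1
    assert (segs[0].start_bp, segs[0].end_bp, segs[0].n_snps) == (
        pos[100],
        pos[159],
        60,
    )


def test_detect_roh_min_length_monotone(small_cohort):
    dataset, _ = small_cohort
    base = detect_roh(dataset, ROHParams(min_length_kb=1000.0))
    doubled = detect_roh(dataset, ROHParams(min_length_kb=2000.0))
    assert len(doubled.segments) <= len(base.segments)


def test_detect_roh_empty_cohort():
    ds = make_dataset(np.zeros((1, 60), dtype=np.int8)).subset(sample_idx=[])
    assert detect_roh(ds).segments == []


def test_detect_roh_deterministic(small_cohort):
    dataset, _ = small_cohort
    a = detect_roh(dataset).to_frame()
    b = detect_roh(dataset).to_frame()
    pd.testing.assert_frame_equal(a, b)


def test_scanner_polarity_invariant(small_cohort):
    dataset, _ = small_cohort
    flipped_calls = dataset.calls.copy()
    hom = (flipped_calls == 0) | (flipped_calls == 2)
    flipped_calls[hom] = 2 - flipped_calls[hom]
    flipped = make_dataset(
        flipped_calls,
        positions=dataset.positions,
        chroms=dataset.chromosomes,
    )
    orig = make_dataset(
        dataset.calls, positions=dataset.positions, chroms=dataset.chromosomes
    )
    for sid in ("s0", "s5", "s17"):
        a = [(s.chrom, s.start_bp, s.end_bp) for s in call_roh_for_sample(orig, sid)]
        b = [(s.chrom, s.start_bp, s.end_bp) for s in call_roh_for_sample(flipped, sid)]
        assert a == b


def test_emitted_segments_satisfy_constraints(small_cohort):
    dataset, _ = small_cohort
    params = ROHParams()
    rohset = detect_roh(dataset, params)
    rohset.validate(params)  # raises on any violation
    pos = dataset.positions
    slices = dataset.chrom_slices()
    for seg in rohset.segments:
        sl = slices[seg.chrom]
        cpos = pos[sl]
        lo = np.searchsorted(cpos, seg.start_bp)
        hi = np.searchsorted(cpos, seg.end_bp, side="right") - 1
        gaps = np.diff(cpos[lo : hi + 1])
        assert (gaps <= params.max_gap_kb * 1000.0).all()


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def _segment(sample, length_mb, chrom=1, start=1_000_000, breed="B1"):
    start = int(start)
    end = start + int(length_mb * 1e6) - 1
    return ROHSegment(sample, chrom, start, end, n_snps=60, breed=breed)


def test_length_class_single_segment():
    samples = [SampleRecord("s0", breed="B1", group="G1")]
    rohset = ROHSet([_segment("s0", 3.0)], samples)
    table = length_class_table(rohset)
    assert table.class_counts.loc["B1", "1-5"] == 1
    assert table.class_counts.loc["B1"].drop("1-5").sum() == 0


def test_length_class_below_first_edge_errors():
    samples = [SampleRecord("s0", breed="B1", group="G1")]
    rohset = ROHSet([_segment("s0", 0.5)], samples)
    with pytest.raises(ValueError, match="below the first class edge"):
        length_class_table(rohset)


def test_length_class_shares_sum_to_100(small_cohort):
    dataset, _ = small_cohort
    rohset = detect_roh(dataset)
    table = length_class_table(rohset)
    shares = table.summary.group_class_share_pct
    sums = shares.sum(axis=0)
    nonzero = table.summary.class_totals > 0
    assert np.allclose(sums[nonzero.to_numpy()], 100.0)


def test_chromosome_coverage_zero_without_roh():
    ds = make_dataset(np.ones((2, 120), dtype=np.int8))
    rohset = ROHSet([], list(ds.samples))
    cov = chromosome_coverage(rohset, ds)
    assert (cov.to_numpy() == 0).all()


def test_chromosome_coverage_full_span():
    n = 100
    pos = [10_000 * (j + 1) for j in range(n)]
    ds = make_dataset(np.zeros((1, n), dtype=np.int8), positions=pos)
    seg = ROHSegment("s0", 1, pos[0], pos[-1], n_snps=n, breed="B1")
    rohset = ROHSet([seg], [SampleRecord("s0", breed="B1", group="other")])
    cov = chromosome_coverage(rohset, ds)
    assert cov.loc["B1", 1] == pytest.approx(1.0)


def test_chromosome_coverage_matches_truth(small_cohort):
    dataset, truth = small_cohort
    rohset = detect_roh(dataset)
    cov = chromosome_coverage(rohset, dataset)
    spans = dataset.chrom_spans()
    breed = "BR01"
    members = [s.sample_id for s in dataset.samples if s.breed == breed]
    for chrom in list(spans)[:4]:
        span = spans[chrom][1] - spans[chrom][0] + 1
        t = truth.tracts[(truth.tracts.breed == breed) & (truth.tracts.chrom == chrom)]
        expected = t.length_bp.sum() / span / len(members)
        assert cov.loc[breed, chrom] == pytest.approx(expected, abs=0.01)


def test_segments_tsv_round_trip(tmp_path, small_cohort):
    dataset, _ = small_cohort
    rohset = detect_roh(dataset)
    path = write_segments_tsv(rohset, tmp_path / "segs.tsv")
    back = read_segments_tsv(path, dataset.samples)
    assert [
        (s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snps) for s in back.segments
    ] == [
        (s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snps) for s in rohset.segments
    ]
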