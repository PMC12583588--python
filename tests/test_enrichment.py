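"""TE enrichment: counting rules, dual tests, shuffles, verdicts, coverage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enhevo.enrichment import (
    ControlSummary,
    _FastCounter,
    count_overlaps,
    coverage_by_class,
    genome_background,
    match_length_groups,
    shuffle_matched,
    verdict_table,
)
from enhevo.enrichment import test_subfamilies as subfamily_tests
from enhevo.intervals import RegionSet
from enhevo.simulate import gen_enrichment_scenario

from conftest import bitmap_cover_bp


# ---------------------------------------------------------------- counting

def test_min_overlap_rule(region_set_factory, te_factory):
    regions = region_set_factory([("chr1", 100, 200)])
    te = te_factory(
        [("chr1", 91, 120, "A"),    # 20 bp overlap -> counted
         ("chr1", 191, 300, "B"),   # 9 bp overlap -> not counted
         ("chr1", 190, 300, "C")],  # 10 bp overlap -> counted
        {},
    )
    out = count_overlaps(regions, te)
    assert out.loc["A", "n_copies"] == 1
    assert out.loc["B", "n_copies"] == 0
    assert out.loc["C", "n_copies"] == 1
    # coverage counts overlapping bases of counted and uncounted copies
    assert out.loc["B", "bp_in_regions"] == 9


def test_count_and_coverage_sum(region_set_factory, te_factory):
    regions = region_set_factory([("chr1", 0, 1000)])
    te = te_factory(
        [("chr1", 0, 50, "X"), ("chr1", 800, 1200, "X")], {"X": ("Alu", "human")}
    )
    out = count_overlaps(regions, te)
    assert out.loc["X", "n_copies"] == 2
    assert out.loc["X", "bp_in_regions"] == 250
    assert bitmap_cover_bp([(0, 50)], 0, 1000) + bitmap_cover_bp([(800, 1200)], 0, 1000) == 250


# ------------------------------------------------------------------- tests

def _background(te_factory):
    # genome: 2000 copies total, 100 of X
    rows = [("chr1", i * 40, i * 40 + 20, "X") for i in range(100)]
    rows += [("chr1", 4000 + i * 40, 4000 + i * 40 + 20, "Y") for i in range(1900)]
    te = te_factory(rows, {})
    return te, genome_background(te, 100_000)


def test_fold_and_hypergeometric_oracle(te_factory):
    te, bg = _background(te_factory)
    counts = pd.DataFrame(
        {"n_copies": [20, 30], "bp_in_regions": [400, 600]}, index=["X", "Y"]
    )
    counts.index.name = "subfamily"
    out = subfamily_tests(counts, bg, region_bp=5000)
    assert out.loc["X", "fold_count"] == pytest.approx((20 / 50) / (100 / 2000))
    # exact tail-sum oracle for the hypergeometric p
    rv = stats.hypergeom(2000, 100, 50)
    oracle = sum(rv.pmf(k) for k in range(20, 51))
    assert out.loc["X", "p_hyper"] == pytest.approx(oracle, rel=1e-9)


def test_null_center_and_absent_subfamily(te_factory):
    te, bg = _background(te_factory)
    # expectation for X: draws=50 -> 50*100/2000 = 2.5; observe close to it
    counts = pd.DataFrame(
        {"n_copies": [2, 48], "bp_in_regions": [50, 1000]}, index=["X", "Y"]
    )
    counts.index.name = "subfamily"
    out = subfamily_tests(counts, bg, region_bp=5000)
    assert out.loc["X", "p_hyper"] > 0.4
    absent = pd.DataFrame(
        {"n_copies": [0, 50], "bp_in_regions": [0, 1000]}, index=["X", "Y"]
    )
    absent.index.name = "subfamily"
    out2 = subfamily_tests(absent, bg, region_bp=5000)
    assert out2.loc["X", "fold_count"] == 0.0
    assert out2.loc["X", "p_hyper"] == pytest.approx(1.0, abs=1e-9)


def test_untestable_zero_genome_copies(te_factory):
    te = te_factory([("chr1", 0, 20, "X")], {})
    bg = genome_background(te, 1000)
    bg = bg.reindex(["X", "Z"]).fillna(0).astype(int)
    bg.attrs["total_copies"] = 1
    bg.attrs["genome_bp"] = 1000
    counts = pd.DataFrame({"n_copies": [1], "bp_in_regions": [20]}, index=["X"])
    counts.index.name = "subfamily"
    out = subfamily_tests(counts, bg, region_bp=100)
    assert bool(out.loc["Z", "untestable"])


# ---------------------------------------------------------------- shuffles

def test_shuffle_preserves_length_multiset(region_set_factory):
    regions = region_set_factory([("chr1", 0, 100), ("chr1", 500, 700), ("chr1", 900, 1200)])
    reps = shuffle_matched(regions, {"chr1": 50_000}, n=20, seed=3)
    want = sorted([100, 200, 300])
    for rep in reps:
        got = sorted((rep.df["end"] - rep.df["start"]).tolist())
        assert got == want


def test_shuffle_respects_excluded_space(region_set_factory):
    regions = region_set_factory([("chr1", 0, 100)] * 5)
    excluded = region_set_factory([("chr1", 0, 40_000), ("chr1", 50_000, 100_000)])
    reps = shuffle_matched(
        regions, {"chr1": 100_000}, n=10, excluded=excluded, seed=0
    )
    for rep in reps:
        assert (rep.df["start"] >= 40_000).all()
        assert (rep.df["end"] <= 50_000).all()


def test_shuffle_deterministic_and_fails_when_no_room(region_set_factory):
    regions = region_set_factory([("chr1", 0, 100)])
    a = shuffle_matched(regions, {"chr1": 10_000}, n=3, seed=7)
    b = shuffle_matched(regions, {"chr1": 10_000}, n=3, seed=7)
    for x, y in zip(a, b):
        assert x == y
    big = region_set_factory([("chr1", 0, 9_000)])
    excluded = region_set_factory([("chr1", 2_000, 10_000)])
    with pytest.raises(ValueError, match="cannot place"):
        shuffle_matched(big, {"chr1": 10_000}, n=1, excluded=excluded, seed=0)


def test_match_length_groups_sizes(region_set_factory, rng):
    starts = rng.integers(0, 90_000, size=60)
    lens = rng.integers(50, 500, size=60)
    shuffled = RegionSet.from_arrays(["chr1"] * 60, starts, starts + lens)
    groups = {"a": lens[:30], "b": lens[30:50], "c": lens[50:]}
    out = match_length_groups(shuffled, groups, seed=1)
    assert {k: len(v) for k, v in out.items()} == {"a": 30, "b": 20, "c": 10}
    # partition: no region used twice
    used = pd.concat([v.df for v in out.values()])
    assert len(used) == len(used.drop_duplicates())


# ----------------------------------------------------------------- verdict

def _real_frame(q=0.001):
    df = pd.DataFrame(
        {
            "q_hyper": [q], "q_binom": [q], "untestable": [False],
            "genome_copies": [100], "genome_bp": [1000],
            "n_copies": [20], "bp_in_regions": [400],
            "fold_count": [3.0], "fold_coverage": [3.0],
            "p_hyper": [q], "p_binom": [q],
        },
        index=pd.Index(["X"], name="subfamily"),
    )
    return df


@pytest.mark.parametrize("hit_frac, expected", [(0.04, True), (0.05, True), (0.06, False)])
def test_verdict_tolerance_rule(hit_frac, expected):
    controls = {
        "mirrored": ControlSummary(pd.Series({"X": hit_frac}), 1000),
        "reclassified": ControlSummary(pd.Series({"X": 0.0}), 1000),
    }
    out = verdict_table(_real_frame(), controls)
    assert bool(out.loc["X", "verdict"]) is expected


def test_verdict_requires_real_significance():
    controls = {
        "mirrored": ControlSummary(pd.Series({"X": 0.0}), 1000),
        "reclassified": ControlSummary(pd.Series({"X": 0.0}), 1000),
    }
    out = verdict_table(_real_frame(q=0.5), controls)
    assert not bool(out.loc["X", "verdict"])


# ---------------------------------------------------------------- coverage

def test_coverage_by_class_simple(region_set_factory, te_factory):
    regions = region_set_factory([("chr1", 0, 1000)])
    te = te_factory([("chr1", 100, 400, "AluY")], {"AluY": ("Alu", "human")})
    out = coverage_by_class(regions, te).set_index("class")
    assert out.loc["Alu", "percent"] == pytest.approx(30.0)
    assert out.loc["non-TE", "percent"] == pytest.approx(70.0)
    assert out["percent"].sum() == pytest.approx(100.0, abs=1e-6)


def test_coverage_by_class_nested_assigned_once(region_set_factory, te_factory):
    regions = region_set_factory([("chr1", 0, 1000)])
    te = te_factory(
        [("chr1", 100, 700, "L1PA3"), ("chr1", 200, 500, "AluY")],
        {"L1PA3": ("pLINE", "great-ape"), "AluY": ("Alu", "human")},
    )
    out = coverage_by_class(regions, te).set_index("class")
    # nested Alu (shorter) wins its bases; L1 keeps the remainder
    assert out.loc["Alu", "bp"] == 300
    assert out.loc["pLINE", "bp"] == 300
    assert out["percent"].sum() == pytest.approx(100.0, abs=1e-6)
    oracle_alu = bitmap_cover_bp([(200, 500)], 0, 1000)
    assert out.loc["Alu", "bp"] == oracle_alu


def test_coverage_te_free(region_set_factory, te_factory):
    regions = region_set_factory([("chr1", 0, 500)])
    te = te_factory([("chr2", 0, 100, "AluY")], {"AluY": ("Alu", "human")})
    out = coverage_by_class(regions, te).set_index("class")
    assert out.loc["non-TE", "percent"] == pytest.approx(100.0)


# ------------------------------------------------------- fast path parity

def test_fast_counter_matches_public_path():
    regions, te, sizes = gen_enrichment_scenario(4, planted_subfamily="SF01")
    bg = genome_background(te, sum(sizes.values()))
    fast = _FastCounter(te, bg, sum(sizes.values()))
    df = regions.df
    k, kbp, rbp = fast.counts(
        df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy(), 10
    )
    slow = subfamily_tests(count_overlaps(regions, te), bg, regions.merge().total_bp())
    assert list(slow.index) == fast.subfamilies
    assert (slow["n_copies"].to_numpy() == k).all()
    assert (slow["bp_in_regions"].to_numpy() == kbp).all()
    assert rbp == regions.merge().total_bp()
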