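"""PWM scoring, exact DP p-values vs exhaustive enumeration, bound calls,
group tests and affinity trajectories."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enhevo.intervals import RegionSet
from enhevo.io import PWM
from enhevo.motifs import (
    affinity_delta,
    call_bound,
    exact_pvalue,
    group_motif_test,
    match_consensus,
    scan_sequence,
    score_distribution,
    score_positions,
)


def random_pwm(width, seed, pseudocount=0.8):
    rng = np.random.default_rng(seed)
    return PWM(f"R{width}_{seed}", rng.integers(1, 100, size=(4, width)).astype(float),
               pseudocount=pseudocount)


def enumerate_scores(pwm):
    lo = pwm.log_odds()
    words = np.array(list(itertools.product(range(4), repeat=pwm.width)))
    return lo[words, np.arange(pwm.width)].sum(axis=1)


# ------------------------------------------------------------------ scoring

def test_uniform_pwm_scores_zero(uniform_pwm):
    scores = score_positions("ACGTACGTAC", uniform_pwm)["score"]
    assert np.allclose(scores, 0.0)


def test_strand_symmetry(info_pwm, rng):
    """Forward score of a sequence equals minus-strand score of its reverse
    complement at the mirrored position."""
    comp = str.maketrans("ACGT", "TGCA")
    for _ in range(10):
        seq = "".join(rng.choice(list("ACGT"), 40))
        rc = seq.translate(comp)[::-1]
        fwd = score_positions(seq, info_pwm)
        rev = score_positions(rc, info_pwm)
        n = 40 - info_pwm.width + 1
        f = fwd[fwd.strand == "+"]["score"].to_numpy()
        r = rev[rev.strand == "-"]["score"].to_numpy()[::-1]
        assert np.allclose(f, r)


def test_planted_word_scores_maximum():
    counts = np.array([[99, 1], [1, 99], [1, 1], [1, 1]], dtype=float)  # favors AC
    pwm = PWM("AC", counts)
    scores = {
        "".join(w): score_positions("".join(w), pwm)["score"].iloc[0]
        for w in itertools.product("ACGT", repeat=2)
    }
    assert max(scores, key=scores.get) == "AC"


def test_ambiguous_windows_dropped(info_pwm):
    seq = "ACGTN" + "ACGTACGTAC"
    hits = scan_sequence(seq, info_pwm)
    # windows covering the N (positions 0..4 overlap it) are absent
    assert not ((hits["start"] <= 4) & (hits["end"] > 4)).any()


# ------------------------------------------------------- exact p-values DP

@pytest.mark.parametrize("width", [2, 4, 6, 8])
def test_dp_matches_exhaustive_enumeration(width):
    pwm = random_pwm(width, seed=width)
    scores = enumerate_scores(pwm)
    probs = np.full(len(scores), 0.25**width)
    dist = score_distribution(pwm)
    # query at midpoints between well-separated achievable scores, so the
    # grid discretisation cannot flip any word across the threshold
    uniq = np.unique(scores)
    gaps = np.diff(uniq)
    wide = gaps > 2 * width / dist.scale
    mids = (uniq[:-1][wide] + uniq[1:][wide]) / 2
    take = mids[:: max(1, len(mids) // 50)]
    for s in take:
        p_enum = probs[scores >= s].sum()
        p_dp = exact_pvalue(pwm, float(s))
        assert p_dp == pytest.approx(p_enum, rel=1e-4)


def test_pvalue_boundaries_and_monotonicity(info_pwm):
    scores = enumerate_scores(random_pwm(4, seed=0))
    pwm = random_pwm(4, seed=0)
    assert exact_pvalue(pwm, float(scores.min())) == 1.0
    assert exact_pvalue(pwm, float(scores.min()) - 5.0) == 1.0
    grid = np.linspace(scores.min(), scores.max() + 1, 200)
    ps = [exact_pvalue(pwm, float(s)) for s in grid]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
    # p just above the maximum equals the probability of the best word(s)
    p_max = exact_pvalue(pwm, float(scores.max()))
    assert 0 < p_max <= (scores >= scores.max()).sum() * 0.25**4 + 1e-12


def test_pvalue_requires_pseudocount():
    pwm = PWM("Z", np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0], [0.0, 0.0]]),
              pseudocount=0.0)
    with pytest.raises(ValueError, match="pseudocount"):
        exact_pvalue(pwm, 0.0)


def test_best_hit_pvalue_super_uniform(info_pwm, rng):
    """Under the background model the per-position p-value of the best hit
    in random sequence is super-uniform (ECDF below the diagonal)."""
    best = []
    for _ in range(400):
        seq = "".join(rng.choice(list("ACGT"), 60))
        best.append(scan_sequence(seq, info_pwm)["p"].min())
    best = np.sort(best)
    ecdf = np.arange(1, len(best) + 1) / len(best)
    # best-of-m p-values: ECDF(p) <= m*p; at minimum ECDF(p) <= 1 never below p
    assert (ecdf - best <= 0.10 + 102 * best).all()


# --------------------------------------------------------------- consensus

def test_match_consensus_planted_vs_random(rng):
    # a 12-column information-rich matrix: the max word is rare enough that
    # BH over a 300 bp scan keeps its q below the stringent cutoff
    consensus12 = "GGGACTTTCCAA"
    counts = [[90.0 if c == b else 10.0 / 3 for c in consensus12] for b in "ACGT"]
    pwm = PWM("MA12", np.array(counts))
    word = "".join("ACGT"[i] for i in np.argmax(pwm.log_odds(), axis=0))
    planted = ("".join(rng.choice(list("ACGT"), 150)) + word
               + "".join(rng.choice(list("ACGT"), 150)))
    res = match_consensus(planted, [pwm])
    assert res.loc[0, "match"] == "stringent"
    none_count = 0
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), 300))
        r = match_consensus(seq, [pwm])
        none_count += r.loc[0, "match"] == "none"
    assert none_count >= 19
    assert match_consensus(planted, []).empty


# ------------------------------------------------------------------- bound

def test_call_bound_single_peak_containment(region_set_factory):
    peaks = region_set_factory([("chr1", 100, 200), ("chr1", 200, 300)])
    hits = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "start": [110, 95, 190, 110],
            "end": [120, 105, 210, 120],
        }
    )
    out = call_bound(hits, peaks)
    # inside one peak; 1bp outside; spanning two unmerged peaks; wrong chrom
    assert list(out["bound"]) == [True, False, False, False]
    merged = call_bound(hits, peaks.merge())
    assert list(merged["bound"]) == [True, False, True, False]  # growth is monotone


# ------------------------------------------------------------- group tests

def two_sided_hypergeom_oracle(k_a, n_a, k_b, n_b):
    rv = stats.hypergeom(n_a + n_b, k_a + k_b, n_a)
    return min(1.0, 2 * min(rv.sf(k_a - 1), rv.cdf(k_a)))


def test_group_motif_test_example():
    res = group_motif_test(30, 100, 10, 100)
    assert res.odds_ratio == pytest.approx((30 * 90) / (70 * 10))
    # oracle: direct tail summation of the hypergeometric pmf
    rv = stats.hypergeom(200, 40, 100)
    upper = sum(rv.pmf(k) for k in range(30, 41))
    lower = sum(rv.pmf(k) for k in range(0, 31))
    assert res.p == pytest.approx(min(1.0, 2 * min(upper, lower)), rel=1e-10)
    assert not res.continuity_corrected


def test_group_motif_test_null_and_zero_cell():
    res = group_motif_test(20, 100, 20, 100)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p == pytest.approx(1.0)
    zero = group_motif_test(0, 50, 10, 50)
    assert zero.continuity_corrected and zero.odds_ratio > 0


# ---------------------------------------------------------------- affinity

def test_affinity_delta_trajectories(info_pwm, rng):
    seq = "".join(rng.choice(list("ACGT"), 30))
    same = affinity_delta(seq, seq, info_pwm)
    assert same.delta == 0.0 and same.trajectory == "neutral"

    word = "".join("ACGT"[i] for i in np.argmax(info_pwm.log_odds(), axis=0))
    weak = "".join(rng.choice(list("ACGT"), 30))
    strong = weak[:10] + word + weak[20:]
    up = affinity_delta(strong, weak, info_pwm)
    if up.delta >= 2:
        assert up.trajectory == "increasing"
    down = affinity_delta(weak, strong, info_pwm)
    assert down.delta == pytest.approx(-up.delta)
    traj_pairs = {"increasing": "decreasing", "decreasing": "increasing",
                  "neutral": "neutral"}
    assert down.trajectory == traj_pairs[up.trajectory]


def test_affinity_delta_inclusive_boundary(uniform_pwm, monkeypatch):
    import enhevo.motifs as m

    scores = iter([1.0, 3.0])
    monkeypatch.setattr(m, "_max_score", lambda seq, pwm: next(scores))
    cmp = m.affinity_delta("AAAA", "CCCC", uniform_pwm)
    assert cmp.delta == -2.0 and cmp.trajectory == "decreasing"
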