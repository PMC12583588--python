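"""FST/PBS/empirical-p/Fisher/Sidak/BH chain and SNP labelling."""

from decimal import Decimal, getcontext

import numpy as np
import pandas as pd
import pytest

from enhevo.intervals import RegionSet
from enhevo.io import PWM, FrequencyPanel
from enhevo.selection import (
    allele_affinity_effect,
    bh_flag,
    empirical_p,
    enhancer_p,
    fisher_combine,
    label_snps,
    pbs,
    reynolds_fst,
    reynolds_fst_components,
    scan_panel,
    sidak,
    snp_table,
)
from enhevo.simulate import SimulationConfig, gen_population_freqs


# ------------------------------------------------------------------- FST

def test_reynolds_large_sample_closed_form():
    got = reynolds_fst(np.array([0.9]), np.array([1e5]), np.array([0.1]), np.array([1e5]))
    expected = 0.64 / 0.82  # (p1-p2)^2 / (p1(1-p2)+p2(1-p1))
    assert got[0] == pytest.approx(expected, abs=1e-3)


def test_reynolds_no_differentiation_and_clipping():
    f = reynolds_fst(np.array([0.3, 0.0, 1.0]), np.full(3, 10),
                     np.array([0.3, 0.0, 1.0]), np.full(3, 10))
    assert (f == 0).all()
    f2 = reynolds_fst(np.array([1.0]), np.array([1000]), np.array([0.0]), np.array([1000]))
    assert 0 < f2[0] < 1


def test_reynolds_input_validation():
    with pytest.raises(ValueError, match="sample sizes"):
        reynolds_fst(np.array([0.5]), np.array([1]), np.array([0.5]), np.array([10]))
    with pytest.raises(ValueError, match="frequencies"):
        reynolds_fst(np.array([1.5]), np.array([10]), np.array([0.5]), np.array([10]))


def test_reynolds_recovers_drift_parameter():
    """Balding-Nichols panels: multi-locus estimate within 3 SE of F."""
    cfg = SimulationConfig(seed=5, n_snps=10_000, n_sweeps=0,
                           snps_in_enhancers=False, n_haploid=100_000)
    panel, _ = gen_population_freqs(cfg)
    a, b = reynolds_fst_components(
        panel.freqs("AFR"), panel.sizes("AFR"), panel.freqs("EUR"), panel.sizes("EUR")
    )
    ratios = a / (a + b)
    est = a.sum() / (a + b).sum()
    se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
    assert abs(est - 0.05) < 3 * se + 0.005


# ------------------------------------------------------------------- PBS

def test_pbs_closed_forms():
    assert pbs(0.0, 0.0, 0.0) == pytest.approx(0.0)
    assert pbs(0.1, 0.1, 0.1) == pytest.approx(-np.log(0.9) / 2, abs=1e-9)


def test_pbs_additive_identity(rng):
    """raw PBS_A + raw PBS_B = T_AB for any FST triple."""
    for _ in range(200):
        ab, ac, bc = rng.uniform(0, 0.9, size=3)
        raw_a = pbs(ab, ac, bc, clip=False)
        raw_b = pbs(ab, bc, ac, clip=False)
        assert raw_a + raw_b == pytest.approx(-np.log1p(-ab), abs=1e-12)


def test_pbs_rejects_invalid_fst():
    with pytest.raises(ValueError):
        pbs(1.0, 0.1, 0.1)


# ------------------------------------------------------------ empirical p

def test_empirical_p_plus_one_rule():
    bg = [1.0, 2.0, 3.0, 4.0]
    assert empirical_p(5.0, bg) == pytest.approx(0.2)    # (0+1)/(4+1)
    assert empirical_p(0.5, bg) == pytest.approx(1.0)
    assert empirical_p(3.0, bg) == pytest.approx(3 / 5)  # ties count as >=
    med = empirical_p(3.0, np.arange(1.0, 6.0))
    assert med == pytest.approx(4 / 6)
    with pytest.raises(ValueError):
        empirical_p(1.0, [])


# ---------------------------------------------------------------- Fisher

def closed_form_fisher(p1, p2):
    x = -2 * (np.log(p1) + np.log(p2))
    return np.exp(-x / 2) * (1 + x / 2)


@pytest.mark.parametrize("p1, p2", [(1.0, 1.0), (0.05, 0.05), (0.3, 0.8), (1e-6, 0.5)])
def test_fisher_combine_closed_form(p1, p2):
    assert fisher_combine(p1, p2) == pytest.approx(closed_form_fisher(p1, p2), rel=1e-10)


def test_fisher_combine_with_unit_second_p(rng):
    for p in rng.uniform(1e-8, 1, size=50):
        assert fisher_combine(p, 1.0) == pytest.approx(p * (1 - np.log(p)), rel=1e-9)


def test_fisher_combine_grid_matches_oracle(rng):
    p1 = rng.uniform(1e-12, 1, size=10_000)
    p2 = rng.uniform(1e-12, 1, size=10_000)
    got = fisher_combine(p1, p2)
    assert np.allclose(got, closed_form_fisher(p1, p2), rtol=1e-10, atol=1e-300)


def test_fisher_combine_rejects_nonpositive():
    with pytest.raises(ValueError):
        fisher_combine(0.0, 0.5)


# ----------------------------------------------------------------- Sidak

def test_sidak_values_and_stability():
    assert sidak(0.01, 1) == pytest.approx(0.01)
    assert sidak(0.01, 10) == pytest.approx(1 - 0.99**10, rel=1e-12)
    # stability for tiny p: high-precision decimal oracle
    getcontext().prec = 60
    exact = 1 - (Decimal(1) - Decimal(10) ** -12) ** 1_000_000
    got = sidak(1e-12, 1_000_000)
    assert got == pytest.approx(float(exact), rel=1e-9)


def test_enhancer_p_records_best_cell():
    p = np.array([[0.5, 0.01], [0.2, 0.9]])
    res = enhancer_p("e1", ["s1", "s2"], ["P1", "P2"], p)
    assert res.n_variant_tests == 4
    assert (res.best_snp, res.best_population) == ("s1", "P2")
    assert res.p_sidak == pytest.approx(1 - 0.99**4)
    with pytest.raises(ValueError, match="untested"):
        enhancer_p("e2", [], ["P1"], np.empty((0, 1)))


# -------------------------------------------------------------------- BH

def bh_oracle(ps):
    """Brute-force BH definition: q_i = min_{j: p_j >= p_i} (m * p_j / rank_j)."""
    ps = np.asarray(ps, dtype=float)
    m = len(ps)
    order = np.argsort(ps)
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * ps[i] / rank_from_top)
        q[i] = running
    return q


@pytest.mark.parametrize(
    "ps, fdr, expected_flags",
    [
        ([0.01, 0.02, 0.03, 0.04], 0.05, [True] * 4),
        ([0.04], 0.05, [True]),
        ([1.0, 1.0, 1.0], 0.05, [False] * 3),
    ],
)
def test_bh_flag_examples(ps, fdr, expected_flags):
    q, flags = bh_flag(ps, fdr=fdr)
    assert np.allclose(q, bh_oracle(ps))
    assert list(flags) == expected_flags


def test_bh_flag_random_matches_oracle(rng):
    ps = rng.uniform(size=200)
    q, _ = bh_flag(ps)
    assert np.allclose(q, bh_oracle(ps))


# ---------------------------------------------------------------- labels

@pytest.mark.parametrize(
    "p_comb, expected",
    [
        ([0.005, 0.3, 0.6], "PS-SNP"),
        ([0.6, 0.7, 0.9], "neutral"),
        ([0.2, 0.6, 0.9], "unlabeled"),
    ],
)
def test_label_snps(p_comb, expected):
    assert label_snps(np.array([p_comb]))[0] == expected


# ------------------------------------------------------------ panel-level

def _tiny_panel(p_relate_override=None):
    n = 300
    rng = np.random.default_rng(0)
    data = {
        "chrom": ["chr1"] * n,
        "pos0": np.arange(10, 10 + n),
        "ancestral": ["A"] * n,
        "derived": ["G"] * n,
    }
    for pop in ("P1", "P2", "P3"):
        data[f"freq_{pop}"] = rng.uniform(0.1, 0.9, size=n)
        data[f"n_{pop}"] = np.full(n, 100)
        data[f"p_relate_{pop}"] = rng.uniform(size=n)
    if p_relate_override is not None:
        data["p_relate_P1"] = p_relate_override(data["p_relate_P1"])
    return FrequencyPanel(pd.DataFrame(data))


def test_snp_table_requires_three_populations():
    df = _tiny_panel().df.drop(columns=["freq_P3", "n_P3", "p_relate_P3"])
    with pytest.raises(ValueError, match="exactly 3"):
        snp_table(FrequencyPanel(df))


def test_scan_panel_monotone_in_relate_p(region_set_factory):
    """Decreasing one SNP's external p never increases its enhancer's p."""
    enh = region_set_factory([("chr1", 0, 500)])
    panel_a = _tiny_panel()
    _, res_a = scan_panel(panel_a, enh)
    panel_b = _tiny_panel(lambda p: np.concatenate([[1e-8], p[1:]]))
    _, res_b = scan_panel(panel_b, enh)
    assert res_b.loc[0, "p_sidak"] <= res_a.loc[0, "p_sidak"] + 1e-12


def test_scan_panel_untested_enhancers_excluded(region_set_factory):
    enh = region_set_factory([("chr1", 0, 500), ("chr2", 0, 500)])
    snps, res = scan_panel(_tiny_panel(), enh)
    assert list(res["tested"]) == [True, False]
    assert np.isnan(res.loc[1, "q_bh"]) and not res.loc[1, "ps_flag"]
    assert {"label"} <= set(snps.columns)


# ------------------------------------------------- allele affinity effect

def test_allele_affinity_effect(info_pwm):
    word = "".join("ACGT"[i] for i in np.argmax(info_pwm.log_odds(), axis=0))
    # derived allele completes the consensus at offset 14 (word position 4)
    broken = word[:4] + ("A" if word[4] != "A" else "C") + word[5:]
    window = "ACGTACGTAC" + broken + "ACGTACGTAC"
    cmp, flag = allele_affinity_effect(window, 14, broken[4], word[4], info_pwm)
    assert cmp.trajectory == "increasing" and not flag

    same, flag = allele_affinity_effect(window, 14, "A", "A", info_pwm)
    assert same.delta == 0.0

    weak = "AC" * 15
    cmp2, flag2 = allele_affinity_effect(weak, 10, "A", "C", info_pwm, min_score=5.0)
    assert flag2 and cmp2.trajectory == "neutral"
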