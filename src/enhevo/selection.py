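"""Composite positive-selection scan over a three-population SNP panel.

Per SNP and population the pipeline chains:

1. Reynolds' coancestry estimator of FST between each population pair,
2. the population branch statistic PBS_A = (T_AB + T_AC - T_BC)/2 with
   T = -ln(1 - FST), which isolates allele-frequency change on one branch,
3. an empirical PBS p-value against the genome-wide background of common
   variants (minor allele frequency > 5%) in that population,
4. Fisher's combination of the empirical PBS p with an external per-variant
   selection p-value (genealogy-based, supplied as input),

and per enhancer a Sidak correction over (overlapping SNPs x populations)
followed by Benjamini-Hochberg across enhancers at 5% FDR.

SNPs are labelled positively selected when the minimum combined p across
populations is < 0.01 and neutral when it is > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import RegionSet
from .io import PWM, FrequencyPanel
from .motifs import AffinityComparison, affinity_delta, bh_qvalues

__all__ = [
    "reynolds_fst",
    "reynolds_fst_components",
    "pbs",
    "empirical_p",
    "fisher_combine",
    "sidak",
    "enhancer_p",
    "bh_flag",
    "label_snps",
    "allele_affinity_effect",
    "scan_panel",
    "snp_table",
]

_FST_CAP = 1.0 - 1e-12


def reynolds_fst_components(freq_a, n_a, freq_b, n_b) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus numerator ``a`` and denominator remainder ``b`` of the
    Reynolds estimator (multi-locus estimates use sum(a)/sum(a+b))."""
    p1 = np.asarray(freq_a, dtype=float)
    p2 = np.asarray(freq_b, dtype=float)
    n1 = np.asarray(n_a, dtype=float)
    n2 = np.asarray(n_b, dtype=float)
    if (n1 < 2).any() or (n2 < 2).any():
        raise ValueError("haploid sample sizes must be >= 2")
    if ((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)).any():
        raise ValueError("frequencies must lie in [0,1]")
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = 2.0 * n1 * n2 / (n1 + n2)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    inner = p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r
    a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * inner
    return a, b


def reynolds_fst(freq_a, n_a, freq_b, n_b, clip: bool = True) -> np.ndarray:
    """Per-locus Reynolds coancestry estimator for biallelic loci.

    Haploid gene-count form of the a/(a+b) estimator (two populations,
    within-individual component absent): with sample sizes ``n_a``/``n_b``
    haploid genomes and derived-allele frequencies p_a/p_b,

        n_bar = (n_a+n_b)/2,  n_c = 2 n_a n_b / (n_a+n_b),
        p_bar = weighted mean frequency,
        s2 = [n_a (p_a-p_bar)^2 + n_b (p_b-p_bar)^2] / n_bar,
        a  = (n_bar/n_c) [ s2 - (p_bar(1-p_bar) - s2/2) / (n_bar-1) ],
        b  = (n_bar/(n_bar-1)) [ p_bar(1-p_bar) - s2/2 ],
        FST = a / (a + b).

    Its large-sample limit is (p_a-p_b)^2 / (p_a(1-p_b) + p_b(1-p_a)).
    Negative estimates are clipped to 0; estimates >= 1 to 1 - 1e-12.
    Loci monomorphic for the same allele in both populations return 0.
    """
    a, b = reynolds_fst_components(freq_a, n_a, freq_b, n_b)
    p1 = np.asarray(freq_a, dtype=float)
    p2 = np.asarray(freq_b, dtype=float)
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom > 0, a / np.where(denom > 0, denom, 1.0), 0.0)
    # monomorphic with identical frequency: no information, define as 0
    fst = np.where((p1 == p2) & ((p1 == 0) | (p1 == 1)), 0.0, fst)
    if clip:
        fst = np.clip(fst, 0.0, _FST_CAP)
    return fst


def pbs(fst_ab, fst_ac, fst_bc, clip: bool = True) -> np.ndarray:
    """Population branch statistic for population A.

    T_xy = -ln(1 - FST_xy); PBS_A = (T_AB + T_AC - T_BC)/2. Raw values may
    be negative; pass ``clip=False`` to retain them for audit (the raw
    values satisfy PBS_A + PBS_B = T_AB).
    """
    t_ab = _branch(fst_ab)
    t_ac = _branch(fst_ac)
    t_bc = _branch(fst_bc)
    raw = (t_ab + t_ac - t_bc) / 2.0
    return np.maximum(raw, 0.0) if clip else raw


def _branch(fst) -> np.ndarray:
    fst = np.asarray(fst, dtype=float)
    if ((fst < 0) | (fst >= 1)).any():
        raise ValueError("FST must lie in [0, 1)")
    return -np.log1p(-fst)


def empirical_p(values, background) -> np.ndarray:
    """Empirical tail p of each value against a background distribution.

    p = (1 + #{background >= value}) / (N + 1); ties count as >=. The +1
    keeps p strictly positive so it can enter Fisher's method.
    """
    bg = np.sort(np.asarray(background, dtype=float))
    n = len(bg)
    if n < 1:
        raise ValueError("empty background")
    v = np.atleast_1d(np.asarray(values, dtype=float))
    n_ge = n - np.searchsorted(bg, v, side="left")
    out = (1.0 + n_ge) / (n + 1.0)
    return out if np.ndim(values) else float(out[0])


def fisher_combine(p_relate, p_emp) -> np.ndarray:
    """Fisher's method for two p-values: chi-square(4 df) survival of
    X = -2(ln p1 + ln p2), i.e. e^{-X/2}(1 + X/2)."""
    p1 = np.asarray(p_relate, dtype=float)
    p2 = np.asarray(p_emp, dtype=float)
    if ((p1 <= 0) | (p1 > 1) | (p2 <= 0) | (p2 > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * (np.log(p1) + np.log(p2))
    out = stats.chi2.sf(x, df=4)
    return out if (np.ndim(p_relate) or np.ndim(p_emp)) else float(out)


def sidak(p_min, m) -> np.ndarray:
    """Family-wise adjustment 1 - (1 - p)^m, stable for tiny p."""
    p = np.asarray(p_min, dtype=float)
    m = np.asarray(m, dtype=float)
    out = -np.expm1(m * np.log1p(-p))
    return out if np.ndim(p_min) else float(out)


@dataclass(frozen=True)
class EnhancerSelectionResult:
    enhancer_id: str
    n_variant_tests: int
    best_snp: str
    best_population: str
    p_sidak: float


def enhancer_p(
    enhancer_id: str,
    snp_ids,
    populations,
    p_comb: np.ndarray,
) -> EnhancerSelectionResult:
    """Single selection p for one enhancer from its SNP x population grid.

    ``p_comb`` is an (n_snps, n_pops) array of combined p-values; the Sidak
    family size is its full element count.
    """
    p_comb = np.asarray(p_comb, dtype=float)
    if p_comb.size == 0:
        raise ValueError("no overlapping SNPs: enhancer is untested")
    m = p_comb.size
    flat = int(np.argmin(p_comb))
    i, j = np.unravel_index(flat, p_comb.shape)
    p_min = float(p_comb[i, j])
    return EnhancerSelectionResult(
        enhancer_id, m, str(list(snp_ids)[i]), str(list(populations)[j]),
        sidak(p_min, m),
    )


def bh_flag(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """BH q-values and significance flags at the given FDR."""
    p = np.asarray(p_values, dtype=float)
    q = bh_qvalues(p)
    return q, q <= fdr


def label_snps(p_comb: np.ndarray, ps_cut: float = 0.01, neutral_cut: float = 0.5):
    """PS-SNP / neutral / unlabeled from the per-population combined p's.

    The minimum across populations drives both rules: < ps_cut -> PS-SNP,
    > neutral_cut -> neutral, otherwise unlabeled.
    """
    p_comb = np.asarray(p_comb, dtype=float)
    p_min = p_comb.min(axis=-1)
    return np.where(
        p_min < ps_cut, "PS-SNP", np.where(p_min > neutral_cut, "neutral", "unlabeled")
    )


def allele_affinity_effect(
    window_seq: str,
    offset: int,
    ancestral: str,
    derived: str,
    pwm: PWM,
    min_score: float | None = None,
) -> tuple[AffinityComparison, bool]:
    """Affinity delta of derived vs ancestral allele within a motif window.

    ``window_seq`` carries the reference bases of the motif-bearing window
    (motif interval padded by the PWM width); ``offset`` is the SNP position
    within it.  Returns the comparison (a = derived, b = ancestral) plus a
    no-motif flag set when neither allele reaches ``min_score``; flagged
    comparisons are forced neutral.
    """
    if not (0 <= offset < len(window_seq)):
        raise ValueError("SNP offset outside window")
    seq_anc = window_seq[:offset] + ancestral.upper() + window_seq[offset + 1 :]
    seq_der = window_seq[:offset] + derived.upper() + window_seq[offset + 1 :]
    cmp = affinity_delta(seq_der, seq_anc, pwm)
    no_motif = False
    if min_score is not None and max(cmp.max_score_a, cmp.max_score_b) < min_score:
        no_motif = True
        cmp = AffinityComparison(cmp.matrix_id, cmp.max_score_a, cmp.max_score_b,
                                 cmp.delta, "neutral")
    return cmp, no_motif


# ---------------------------------------------------------------------------
# Panel-level driver
# ---------------------------------------------------------------------------

def snp_table(panel: FrequencyPanel, maf: float = 0.05) -> pd.DataFrame:
    """Per-SNP FST/PBS/empirical/combined p table for a 3-population panel.

    For each population the PBS background is the set of variants common
    (minor allele frequency > ``maf``) in that population; the background is
    recomputed per dataset and never pooled across populations.
    """
    pops = panel.populations
    if len(pops) != 3:
        raise ValueError(
            f"selection scan requires exactly 3 populations, got {len(pops)}"
        )
    a, b, c = pops
    out = panel.df[["chrom", "pos0"]].copy()
    out["snp_id"] = [f"snp{i}" for i in range(len(panel.df))]
    freqs = {p: panel.freqs(p) for p in pops}
    sizes = {p: panel.sizes(p) for p in pops}
    fst = {}
    for x, y in ((a, b), (a, c), (b, c)):
        fst[(x, y)] = reynolds_fst(freqs[x], sizes[x], freqs[y], sizes[y])
        out[f"fst_{x}_{y}"] = fst[(x, y)]
    trio = {a: (b, c), b: (a, c), c: (a, b)}
    for pop, (o1, o2) in trio.items():
        f_po1 = fst[(pop, o1)] if (pop, o1) in fst else fst[(o1, pop)]
        f_po2 = fst[(pop, o2)] if (pop, o2) in fst else fst[(o2, pop)]
        f_oo = fst[(o1, o2)] if (o1, o2) in fst else fst[(o2, o1)]
        raw = pbs(f_po1, f_po2, f_oo, clip=False)
        out[f"pbs_raw_{pop}"] = raw
        out[f"pbs_{pop}"] = np.maximum(raw, 0.0)
        common = np.minimum(freqs[pop], 1.0 - freqs[pop]) > maf
        if common.sum() < 1:
            raise ValueError(f"no common variants in population {pop}")
        out[f"p_pbs_emp_{pop}"] = empirical_p(
            out[f"pbs_{pop}"].to_numpy(), out.loc[common, f"pbs_{pop}"].to_numpy()
        )
        out[f"p_comb_{pop}"] = fisher_combine(
            panel.relate_p(pop), out[f"p_pbs_emp_{pop}"].to_numpy()
        )
    p_comb = out[[f"p_comb_{p}" for p in pops]].to_numpy()
    out["label"] = label_snps(p_comb)
    return out


def scan_panel(
    panel: FrequencyPanel,
    enhancers: RegionSet,
    maf: float = 0.05,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full scan: per-SNP table plus per-enhancer Sidak/BH results.

    Enhancers without overlapping SNPs are excluded from the FDR universe
    and reported with ``tested = False``.
    """
    snps = snp_table(panel, maf=maf)
    pops = panel.populations
    p_comb = snps[[f"p_comb_{p}" for p in pops]].to_numpy()
    pos = snps["pos0"].to_numpy()
    chroms = snps["chrom"].to_numpy()

    rows = []
    for row in enhancers.df.itertuples(index=False):
        mask = (chroms == row.chrom) & (pos >= row.start) & (pos < row.end)
        if not mask.any():
            rows.append((row.id, False, 0, "", "", np.nan))
            continue
        res = enhancer_p(
            str(row.id), snps.loc[mask, "snp_id"].tolist(), pops, p_comb[mask]
        )
        rows.append(
            (row.id, True, res.n_variant_tests, res.best_snp,
             res.best_population, res.p_sidak)
        )
    enh = pd.DataFrame(
        rows,
        columns=["enhancer_id", "tested", "n_variant_tests", "best_snp",
                 "best_population", "p_sidak"],
    )
    tested = enh["tested"].to_numpy()
    q = np.full(len(enh), np.nan)
    flag = np.zeros(len(enh), dtype=bool)
    if tested.any():
        q_t, flag_t = bh_flag(enh.loc[tested, "p_sidak"].to_numpy(), fdr=fdr)
        q[tested] = q_t
        flag[tested] = flag_t
    enh["q_bh"] = q
    enh["ps_flag"] = flag
    return snps, enh
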