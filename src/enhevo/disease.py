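"""Inflammatory-disease enhancers (IDEs) and group comparison statistics.

Core disease genes are those shared by at least 30% of the surveyed
conditions; an enhancer is an IDE when (i) a link table connects it to at
least one core gene and (ii) an inflammatory-TF ChIP-seq peak overlaps it
by >= 50% of the peak's length.  Group proportions are compared with
two-sided Fisher's exact tests (chi-square with continuity correction also
reported), BH-adjusted across a batch, with exact Clopper-Pearson intervals
on each proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import RegionSet
from .motifs import bh_qvalues

__all__ = [
    "core_genes",
    "define_ides",
    "compare_proportions",
    "compare_proportions_batch",
    "binomial_ci",
    "ide_profiles",
]


def core_genes(matrix: pd.DataFrame, threshold: float = 0.30) -> set[str]:
    """Genes present in >= ``threshold`` of the disease columns."""
    if matrix.shape[1] == 0:
        return set()
    share = matrix.sum(axis=1) / matrix.shape[1]
    return set(matrix.index[share >= threshold])


def define_ides(
    enhancers: RegionSet,
    links: pd.DataFrame,
    core: set[str],
    peaks: RegionSet,
    min_peak_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-enhancer IDE record.

    ``links`` columns: enhancer_id, gene.  The ChIP condition holds when
    some peak has >= ``min_peak_frac`` of the *peak's* length inside the
    enhancer (peaks pooled and merged upstream).  is_ide = linked-to-core
    AND chip-overlap.
    """
    linked = (
        links[links["gene"].isin(core)].groupby("enhancer_id")["gene"].agg(set)
        if len(links)
        else pd.Series(dtype=object)
    )
    pk = peaks.merge().df
    enh_by_chrom = {
        chrom: sub for chrom, sub in enhancers.df.groupby("chrom")
    }
    chip_ok: dict[str, bool] = {str(r.id): False for r in enhancers.df.itertuples(index=False)}
    for row in pk.itertuples(index=False):
        sub = enh_by_chrom.get(row.chrom)
        if sub is None:
            continue
        plen = row.end - row.start
        ov = np.minimum(sub["end"].to_numpy(), row.end) - np.maximum(
            sub["start"].to_numpy(), row.start
        )
        hit = ov >= min_peak_frac * plen
        for eid in sub["id"].to_numpy()[hit]:
            chip_ok[str(eid)] = True
    rows = []
    for r in enhancers.df.itertuples(index=False):
        eid = str(r.id)
        genes = linked.get(eid, set())
        rows.append(
            (eid, sorted(genes), bool(genes), chip_ok[eid],
             bool(genes) and chip_ok[eid])
        )
    return pd.DataFrame(
        rows,
        columns=["enhancer_id", "core_genes", "linked_core", "chip_overlap_ok", "is_ide"],
    )


@dataclass(frozen=True)
class ProportionComparison:
    odds_ratio: float
    p_exact: float
    p_chi2: float
    or_infinite: bool
    or_corrected: bool


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> ProportionComparison:
    """Two-sided exact test on a 2x2, plus continuity-corrected chi-square.

    Zero cells: the odds ratio gets a 0.5 Haldane correction and is flagged;
    the exact p is unaffected.
    """
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if (table < 0).any():
        raise ValueError("invalid counts")
    orr_raw, p_exact = stats.fisher_exact(table, alternative="two-sided")
    try:
        chi2 = stats.chi2_contingency(table, correction=True)
        p_chi2 = float(chi2.pvalue)
    except ValueError:  # zero margin
        p_chi2 = float("nan")
    corrected = bool((table == 0).any())
    infinite = bool(np.isinf(orr_raw))
    if corrected:
        t = table + 0.5
        orr = float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
    else:
        orr = float(orr_raw)
    return ProportionComparison(orr, float(p_exact), p_chi2, infinite, corrected)


def compare_proportions_batch(
    comparisons: Sequence[tuple[int, int, int, int]]
) -> pd.DataFrame:
    """Batch comparisons with BH adjustment of the exact p-values."""
    rows = [compare_proportions(*c) for c in comparisons]
    out = pd.DataFrame(
        {
            "odds_ratio": [r.odds_ratio for r in rows],
            "p_exact": [r.p_exact for r in rows],
            "p_chi2": [r.p_chi2 for r in rows],
            "or_corrected": [r.or_corrected for r in rows],
        }
    )
    out["q_exact"] = bh_qvalues(out["p_exact"].to_numpy())
    return out


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper-Pearson interval for a binomial proportion."""
    if not (0 <= k <= n) or n <= 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return float(ci.low), float(ci.high)


def ide_profiles(
    ide: pd.DataFrame,
    features: Mapping[str, Mapping[str, bool]],
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-group (IDE vs non-IDE) proportions of qualifying enhancers.

    ``features`` maps feature name -> {enhancer_id: bool}.  For each
    feature the IDE and non-IDE proportions come with exact binomial CIs
    and a two-sided exact comparison; empty groups report missing values.
    """
    ids = ide["enhancer_id"].to_numpy()
    is_ide = ide["is_ide"].to_numpy(dtype=bool)
    rows = []
    for feat, lookup in features.items():
        has = np.array([bool(lookup.get(e, False)) for e in ids])
        k1, n1 = int(has[is_ide].sum()), int(is_ide.sum())
        k2, n2 = int(has[~is_ide].sum()), int((~is_ide).sum())
        if n1 == 0 or n2 == 0:
            rows.append((feat, k1, n1, np.nan, np.nan, np.nan, k2, n2,
                         np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        lo1, hi1 = binomial_ci(k1, n1, level)
        lo2, hi2 = binomial_ci(k2, n2, level)
        cmp = compare_proportions(k1, n1, k2, n2)
        rows.append(
            (feat, k1, n1, k1 / n1, lo1, hi1, k2, n2, k2 / n2, lo2, hi2,
             cmp.odds_ratio, cmp.p_exact)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "feature", "k_ide", "n_ide", "prop_ide", "ci_lo_ide", "ci_hi_ide",
            "k_other", "n_other", "prop_other", "ci_lo_other", "ci_hi_other",
            "odds_ratio", "p_exact",
        ],
    )
    if len(out):
        valid = out["p_exact"].notna()
        q = np.full(len(out), np.nan)
        if valid.any():
            q[valid] = bh_qvalues(out.loc[valid, "p_exact"].to_numpy())
        out["q_exact"] = q
    return out
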