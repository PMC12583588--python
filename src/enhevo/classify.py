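"""Gap/alignability-based evolutionary classification.

Every rule here reduces to coverage arithmetic of a feature against merged
interval sets describing, per outgroup genome, which human bases align
(``aligned``) or fall in lineage-specific gaps (``gaps``):

* enhancers -> static / intermediate / rapid by alignable fraction against
  two outgroups (orthology threshold 0.97), with a 0.5 quasi-ortholog rescue;
* TE copies -> gained vs an outgroup under a loose (any-overlap) or strict
  (>=90% of length) gap rule;
* TF binding motifs -> gained when 100% gap-contained; TE-derived when 100%
  contained in a single repeat copy;
* accessible-chromatin peaks -> shared / novel by the 50% rule, and
  Alu/pERV-derived when >=50% of their bases come from that biotype.

Threshold ties always resolve by the >= reading of the printed cutoff.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import GenomeInterval, RegionSet
from .io import TEAnnotation

__all__ = [
    "alignable_fraction",
    "classify_enhancer",
    "classify_enhancers",
    "find_quasi_ortholog",
    "classify_te_loose",
    "classify_te_strict",
    "classify_te_annotation",
    "classify_tfbs",
    "assign_motif_origin",
    "classify_peak",
    "peak_te_origin",
]

GROUPS = ("static", "intermediate", "rapid")


def alignable_fraction(region: GenomeInterval, aligned: RegionSet) -> float:
    """Fraction of ``region`` bases covered by the merged aligned set."""
    return aligned.coverage_fraction(region)


def classify_enhancer(
    region: GenomeInterval,
    aligned_chimp: RegionSet,
    aligned_macaque: RegionSet,
    minmatch: float = 0.97,
) -> str:
    """Stratify one enhancer by cross-species alignability.

    static: orthologous in both outgroups (fraction >= minmatch for both);
    intermediate: orthologous in chimp only; rapid: neither.
    """
    f_chimp = alignable_fraction(region, aligned_chimp)
    f_mac = alignable_fraction(region, aligned_macaque)
    if f_chimp >= minmatch and f_mac >= minmatch:
        return "static"
    if f_chimp >= minmatch:
        return "intermediate"
    return "rapid"


def classify_enhancers(
    regions: RegionSet,
    aligned_chimp: RegionSet,
    aligned_macaque: RegionSet,
    minmatch: float = 0.97,
    quasi_minmatch: float = 0.5,
) -> pd.DataFrame:
    """Vectorized stratification of a whole RegionSet.

    Returns a frame with id, group, aligned fractions per outgroup and the
    macaque quasi-ortholog flag (evaluated for dynamic enhancers).
    """
    for rs in (aligned_chimp, aligned_macaque):
        if not rs.is_merged():
            raise ValueError("alignability sets must be merged")
    df = regions.df
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    lengths = (ends - starts).astype(float)
    f_chimp = aligned_chimp.coverage_of(chroms, starts, ends) / lengths
    f_mac = aligned_macaque.coverage_of(chroms, starts, ends) / lengths
    group = np.where(
        (f_chimp >= minmatch) & (f_mac >= minmatch),
        "static",
        np.where(f_chimp >= minmatch, "intermediate", "rapid"),
    )
    quasi = f_mac >= quasi_minmatch
    return pd.DataFrame(
        {
            "id": df["id"].to_numpy(),
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "group": group,
            "aligned_chimp": f_chimp,
            "aligned_macaque": f_mac,
            "quasi_ortholog_macaque": quasi,
        }
    )


def find_quasi_ortholog(
    region: GenomeInterval, aligned_macaque: RegionSet, minmatch: float = 0.5
) -> bool:
    """True iff a relaxed alignability threshold recovers a macaque locus."""
    return bool(alignable_fraction(region, aligned_macaque) >= minmatch)


# ---------------------------------------------------------------------------
# TE gain dating
# ---------------------------------------------------------------------------

def classify_te_loose(
    te: GenomeInterval, gaps_macaque: RegionSet, gaps_chimp: RegionSet
) -> set[str]:
    """Any-overlap gain codes for one TE copy against both outgroups.

    Returns a set of provenance codes: {"gained_vs_macaque"} and/or
    {"gained_vs_chimp"}; empty set means shared (no gap overlap at all,
    regardless of the aligned length).
    """
    codes: set[str] = set()
    if gaps_macaque.coverage_of([te.chrom], [te.start], [te.end])[0] > 0:
        codes.add("gained_vs_macaque")
    if gaps_chimp.coverage_of([te.chrom], [te.start], [te.end])[0] > 0:
        codes.add("gained_vs_chimp")
    return codes


def classify_te_strict(
    te: GenomeInterval, gaps: RegionSet, min_frac: float = 0.9
) -> bool:
    """Strict gain rule: >=90% of the copy length falls in outgroup gaps."""
    bp = gaps.coverage_of([te.chrom], [te.start], [te.end])[0]
    return bool(bp / te.length >= min_frac)


def classify_te_annotation(
    te: TEAnnotation,
    gaps_macaque: RegionSet,
    gaps_chimp: RegionSet,
    strict_frac: float = 0.9,
) -> pd.DataFrame:
    """Loose and strict gain calls for every instance, vectorized."""
    for rs in (gaps_macaque, gaps_chimp):
        if not rs.is_merged():
            raise ValueError("gap sets must be merged")
    df = te.instances
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    lengths = (ends - starts).astype(float)
    mac_bp = gaps_macaque.coverage_of(chroms, starts, ends)
    chimp_bp = gaps_chimp.coverage_of(chroms, starts, ends)
    out = df[["chrom", "start", "end", "subfamily", "biotype", "age_clade"]].copy()
    out["gained_vs_macaque_loose"] = mac_bp > 0
    out["gained_vs_chimp_loose"] = chimp_bp > 0
    out["gained_vs_macaque_strict"] = mac_bp / lengths >= strict_frac
    out["gained_vs_chimp_strict"] = chimp_bp / lengths >= strict_frac
    out["provenance_loose"] = np.where(
        out["gained_vs_chimp_loose"],
        "gained_vs_chimp",
        np.where(out["gained_vs_macaque_loose"], "gained_vs_macaque", "shared"),
    )
    return out


# ---------------------------------------------------------------------------
# TFBS and peak classification
# ---------------------------------------------------------------------------

def classify_tfbs(motif_interval: GenomeInterval, gaps: RegionSet) -> str:
    """"gained" iff the motif is fully contained in the union of gaps."""
    return "gained" if gaps.contains_interval(motif_interval) else "not_gained"


def assign_motif_origin(
    motif_interval: GenomeInterval, te: TEAnnotation
) -> str:
    """Biotype of the TE copy fully containing the motif, else "non-TE".

    Containment must hold within a single instance; among nested containing
    instances the shortest (most specific element) wins.
    """
    df = te.instances
    mask = (
        (df["chrom"] == motif_interval.chrom)
        & (df["start"] <= motif_interval.start)
        & (df["end"] >= motif_interval.end)
    )
    if not mask.any():
        return "non-TE"
    sub = df[mask]
    lengths = sub["end"] - sub["start"]
    return str(sub.loc[lengths.idxmin(), "biotype"])


def classify_peak(
    peak: GenomeInterval,
    aligned_macaque: RegionSet,
    gaps_macaque: RegionSet,
    min_frac: float = 0.5,
) -> str:
    """shared if >=50% aligned; else novel if >50% gap; else ambiguous."""
    aligned_frac = aligned_macaque.coverage_fraction(peak)
    if aligned_frac >= min_frac:
        return "shared"
    gap_frac = gaps_macaque.coverage_fraction(peak)
    if gap_frac > min_frac:
        return "novel"
    return "ambiguous"


def peak_te_origin(
    peak: GenomeInterval,
    te: TEAnnotation,
    biotype: str,
    min_frac: float = 0.5,
) -> bool:
    """True iff >= min_frac of the peak's bases derive from that biotype.

    Bases covered by several copies of the biotype count once (union).
    """
    df = te.instances
    sub = df[df["biotype"] == biotype]
    rs = RegionSet(sub[["chrom", "start", "end"]]).merge()
    bp = rs.coverage_of([peak.chrom], [peak.start], [peak.end])[0]
    return bool(bp / peak.length >= min_frac)
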