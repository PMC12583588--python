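"""Substitution-rate and conservation summaries per region.

The point-mutation rate of a region relative to an outgroup is measured on
gapped pairwise alignment blocks: only gap-free alignment columns enter the
denominator, ambiguity codes are excluded entirely, and multiple blocks for
one region are pooled (mismatch and denominator sums), not averaged.  The
distance-to-gap profile is the diagnostic for gap-induced misalignment:
mismatch density as a function of alignment-column distance to the nearest
gap column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeInterval
from .io import AlignmentBlock

__all__ = [
    "DivergenceRecord",
    "mismatch_rate",
    "gap_distance_profile",
    "mean_track_score",
]

_GAP = "-"
_AMBIG = set("NnXx")


@dataclass
class DivergenceRecord:
    """Pooled mismatch summary for one region."""

    region_id: str
    aligned_gapfree_bp: int
    mismatches: int
    mismatch_pct: float | None  # None when no gap-free columns exist

    @property
    def is_defined(self) -> bool:
        return self.mismatch_pct is not None


def _column_classes(block: AlignmentBlock):
    """Per-column flags: gap, ambiguous, mismatch (case-insensitive)."""
    q = np.frombuffer(block.qseq.upper().encode(), dtype="S1")
    s = np.frombuffer(block.sseq.upper().encode(), dtype="S1")
    gap = (q == b"-") | (s == b"-")
    ambig = (q == b"N") | (s == b"N") | (q == b"X") | (s == b"X")
    usable = ~gap & ~ambig
    mismatch = usable & (q != s)
    return gap, usable, mismatch


def mismatch_rate(
    blocks: Sequence[AlignmentBlock], region_id: str = ""
) -> DivergenceRecord:
    """Pooled single-nucleotide mismatch percentage over gap-free columns."""
    if not blocks:
        raise ValueError("need at least one alignment block")
    denom = 0
    mm = 0
    for block in blocks:
        _, usable, mismatch = _column_classes(block)
        denom += int(usable.sum())
        mm += int(mismatch.sum())
    pct = 100.0 * mm / denom if denom else None
    return DivergenceRecord(region_id, denom, mm, pct)


def gap_distance_profile(
    blocks: Sequence[AlignmentBlock], bin_edges: Sequence[float]
) -> pd.DataFrame:
    """Mismatch counts and densities by distance to the nearest gap column.

    Distance is measured in alignment columns. Mismatches (and gap-free
    columns) from blocks without any gap are tallied in a separate "no-gap"
    row and excluded from the binned densities. Bins are half-open
    (lo, hi] on distance, matching the >=1-column distance of any non-gap
    column to a gap.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or not (np.diff(edges) > 0).all():
        raise ValueError("bin_edges must be increasing with >=2 values")
    n_bins = len(edges) - 1
    mm_counts = np.zeros(n_bins, dtype=int)
    col_counts = np.zeros(n_bins, dtype=int)
    nogap_mm = 0
    nogap_cols = 0
    for block in blocks:
        gap, usable, mismatch = _column_classes(block)
        idx = np.arange(len(gap))
        gap_idx = idx[gap]
        if len(gap_idx) == 0:
            nogap_mm += int(mismatch.sum())
            nogap_cols += int(usable.sum())
            continue
        # distance of every column to nearest gap column
        pos = np.searchsorted(gap_idx, idx)
        left = np.where(pos > 0, idx - gap_idx[np.maximum(pos - 1, 0)], np.iinfo(int).max)
        right = np.where(
            pos < len(gap_idx), gap_idx[np.minimum(pos, len(gap_idx) - 1)] - idx,
            np.iinfo(int).max,
        )
        dist = np.minimum(left, right)
        which = np.searchsorted(edges, dist[usable], side="left") - 1
        ok = (which >= 0) & (which < n_bins)
        col_counts += np.bincount(which[ok], minlength=n_bins)
        which_mm = np.searchsorted(edges, dist[mismatch], side="left") - 1
        ok_mm = (which_mm >= 0) & (which_mm < n_bins)
        mm_counts += np.bincount(which_mm[ok_mm], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(col_counts > 0, mm_counts / np.maximum(col_counts, 1), np.nan)
    out = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "mismatches": mm_counts,
            "gapfree_columns": col_counts,
            "density": density,
        }
    )
    out.attrs["no_gap_mismatches"] = nogap_mm
    out.attrs["no_gap_columns"] = nogap_cols
    return out


def mean_track_score(
    region: GenomeInterval, track: pd.DataFrame
) -> tuple[float | None, float]:
    """Base-weighted mean of a per-base score track over one region.

    ``track`` is a (chrom, start, end, score) frame. Bases without data are
    excluded from the mean (never imputed as 0); the second return value is
    the fraction of the region covered by data so callers can filter.
    """
    sub = track[
        (track["chrom"] == region.chrom)
        & (track["end"] > region.start)
        & (track["start"] < region.end)
    ]
    if sub.empty:
        return None, 0.0
    lo = np.maximum(sub["start"].to_numpy(), region.start)
    hi = np.minimum(sub["end"].to_numpy(), region.end)
    w = (hi - lo).astype(float)
    covered = float(w.sum())
    mean = float((sub["score"].to_numpy() * w).sum() / covered)
    return mean, covered / region.length
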