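"""TE-subfamily enrichment with dual tests and matched shuffle controls.

A subfamily is called enriched in a region group only when four conditions
hold simultaneously: the copy-count (hypergeometric) and bp-coverage
(binomial) tests are both significant against the genome background after
Benjamini-Hochberg adjustment across subfamilies, AND the subfamily does not
reach significance in more than a small tolerated fraction (default <= 5%)
of matched random-region replicates, under each of two control groupings:

  (i) shuffled regions resampled to mirror the real group's count and
      length distribution;
 (ii) shuffled regions re-classified by the same alignability rules applied
      to the real regions.

The hypergeometric universe is TE *copies* (draws = copies overlapping the
regions by >= 10 bp); the binomial probes *coverage* (region bp vs the
subfamily's genome-wide bp density), so the two tests are complementary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import RegionSet, _covered_bp, _merge_arrays
from .io import TEAnnotation
from .motifs import bh_qvalues

__all__ = [
    "count_overlaps",
    "genome_background",
    "test_subfamilies",
    "shuffle_matched",
    "match_length_groups",
    "verdict_table",
    "coverage_by_class",
    "run_enrichment",
]

MIN_OVERLAP_BP = 10


def count_overlaps(
    regions: RegionSet, te: TEAnnotation, min_bp: int = MIN_OVERLAP_BP
) -> pd.DataFrame:
    """Per-subfamily copy counts and bp coverage within the regions.

    A copy counts when its overlap with the merged regions is >= ``min_bp``;
    coverage sums the overlapping bases of every intersecting copy.
    """
    merged = regions.merge()
    df = te.instances
    bp = merged.coverage_of(
        df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy()
    )
    counted = bp >= min_bp
    tab = pd.DataFrame({"subfamily": df["subfamily"], "bp": bp, "counted": counted})
    out = tab.groupby("subfamily").agg(
        n_copies=("counted", "sum"), bp_in_regions=("bp", "sum")
    )
    out["n_copies"] = out["n_copies"].astype(int)
    return out


def genome_background(te: TEAnnotation, genome_bp: int) -> pd.DataFrame:
    """Genome-wide per-subfamily copy counts and bp, plus totals."""
    out = pd.DataFrame(
        {
            "genome_copies": te.subfamily_counts(),
            "genome_bp": te.subfamily_bp(),
        }
    )
    out.attrs["total_copies"] = int(out["genome_copies"].sum())
    out.attrs["genome_bp"] = int(genome_bp)
    return out


def test_subfamilies(
    counts: pd.DataFrame,
    background: pd.DataFrame,
    region_bp: int,
    adjust: bool = True,
) -> pd.DataFrame:
    """Hypergeometric (counts) and binomial (coverage) enrichment tests.

    counts: output of :func:`count_overlaps` for one region group;
    background: output of :func:`genome_background`.  One-sided upper tests;
    fold changes are observed/expected under each model.  BH adjustment runs
    across subfamilies within the group.
    """
    sub = background.join(counts, how="left").fillna({"n_copies": 0, "bp_in_regions": 0})
    sub["n_copies"] = sub["n_copies"].astype(int)
    sub["bp_in_regions"] = sub["bp_in_regions"].astype(int)
    M = background.attrs["total_copies"]
    genome_bp = background.attrs["genome_bp"]
    draws = int(sub["n_copies"].sum())

    K = sub["genome_copies"].to_numpy()
    k = sub["n_copies"].to_numpy()
    untestable = K == 0
    p_hyper = np.ones(len(sub))
    if draws > 0:
        p_hyper = stats.hypergeom.sf(k - 1, M, K, draws)
    exp_count = draws * K / M if M else np.zeros(len(sub))
    with np.errstate(invalid="ignore", divide="ignore"):
        fold_count = np.where(exp_count > 0, k / np.where(exp_count > 0, exp_count, 1), np.nan)

    rate = sub["genome_bp"].to_numpy() / genome_bp
    kbp = sub["bp_in_regions"].to_numpy()
    p_binom = stats.binom.sf(kbp - 1, region_bp, rate)
    exp_bp = region_bp * rate
    with np.errstate(invalid="ignore", divide="ignore"):
        fold_cov = np.where(exp_bp > 0, kbp / np.where(exp_bp > 0, exp_bp, 1), np.nan)

    out = sub.copy()
    out["fold_count"] = fold_count
    out["fold_coverage"] = fold_cov
    out["p_hyper"] = p_hyper
    out["p_binom"] = p_binom
    out["untestable"] = untestable
    if adjust:
        out["q_hyper"] = bh_qvalues(p_hyper)
        out["q_binom"] = bh_qvalues(p_binom)
    return out


# ---------------------------------------------------------------------------
# Matched shuffles
# ---------------------------------------------------------------------------

def shuffle_matched(
    regions: RegionSet,
    chrom_sizes: Mapping[str, int],
    n: int = 1000,
    excluded: RegionSet | None = None,
    seed: int | np.random.Generator = 0,
    max_tries: int = 100,
) -> list[RegionSet]:
    """Random region sets matched for number and length multiset.

    Each replicate keeps the exact multiset of region lengths; placements
    are uniform over the allowed space (chromosomes minus ``excluded``),
    requiring each placed region to fit entirely inside one allowed block.
    Overlaps among placed regions are allowed, mirroring the default
    behaviour of genome shufflers.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    allowed = (
        (excluded or RegionSet()).complement(chrom_sizes)
        if excluded is not None
        else RegionSet(
            pd.DataFrame(
                [(c, 0, s) for c, s in chrom_sizes.items()],
                columns=["chrom", "start", "end"],
            )
        )
    )
    blocks = allowed.df
    b_chrom = blocks["chrom"].to_numpy()
    b_start = blocks["start"].to_numpy()
    b_len = (blocks["end"] - blocks["start"]).to_numpy()
    lengths = (regions.df["end"] - regions.df["start"]).to_numpy()
    out = []
    for _ in range(n):
        chroms, starts = _place_lengths(lengths, b_chrom, b_start, b_len, rng)
        out.append(
            RegionSet.from_arrays(chroms, starts, starts + lengths, name="shuffle")
        )
    return out


def _place_lengths(lengths, b_chrom, b_start, b_len, rng):
    """Place each length uniformly over the allowed blocks it fits in."""
    starts = np.empty(len(lengths), dtype=np.int64)
    chroms = np.empty(len(lengths), dtype=object)
    for i, w in enumerate(lengths):
        slots = np.maximum(b_len - w + 1, 0)
        cum = np.cumsum(slots)
        if cum[-1] <= 0:
            raise ValueError(
                f"cannot place a region of length {w}: no allowed block is "
                "long enough"
            )
        offset = rng.integers(cum[-1])
        bi = int(np.searchsorted(cum, offset, side="right"))
        prev = int(cum[bi - 1]) if bi else 0
        starts[i] = b_start[bi] + (offset - prev)
        chroms[i] = b_chrom[bi]
    return chroms, starts


def _match_length_indices(
    lengths: np.ndarray,
    group_lengths: Mapping[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Greedy nearest-length assignment of shuffled regions to groups."""
    order = np.argsort(lengths, kind="mergesort")
    pool_idx = list(order)                     # sorted by length, ascending
    pool_len = [int(lengths[i]) for i in order]
    out_idx: dict[str, np.ndarray] = {}
    names = list(group_lengths)
    rng.shuffle(names)
    for name in names:
        want = np.sort(np.asarray(group_lengths[name]))
        if len(want) > len(pool_idx):
            raise ValueError("not enough shuffled regions to mirror groups")
        picks = []
        for w in want:
            j = int(np.searchsorted(pool_len, w))
            # nearest available neighbour in the sorted pool
            cands = [k for k in (j - 1, j) if 0 <= k < len(pool_len)]
            best = min(cands, key=lambda k: abs(pool_len[k] - w))
            picks.append(pool_idx.pop(best))
            pool_len.pop(best)
        out_idx[name] = np.array(sorted(picks), dtype=np.int64)
    return out_idx


def match_length_groups(
    shuffled: RegionSet,
    group_lengths: Mapping[str, np.ndarray],
    seed: int | np.random.Generator = 0,
) -> dict[str, RegionSet]:
    """Control grouping (i): sample shuffled regions to mirror each real
    group's count and length distribution.

    For every real group, each region is matched to the unused shuffled
    region of closest length (greedy on sorted lengths), so group sizes are
    exact and length distributions are as close as the replicate allows.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    lengths = (shuffled.df["end"] - shuffled.df["start"]).to_numpy()
    idx = _match_length_indices(lengths, group_lengths, rng)
    n = len(lengths)
    return {
        name: shuffled.subset(np.isin(np.arange(n), idx[name]))
        for name in sorted(idx)
    }


def _significant(tested: pd.DataFrame, alpha: float) -> pd.Series:
    """Either test significant after BH (per replicate family)."""
    return (tested["q_hyper"] < alpha) | (tested["q_binom"] < alpha)


@dataclass
class ControlSummary:
    """Fraction of control replicates in which each subfamily reached
    significance (either test, BH-adjusted), per control scheme."""

    hit_fraction: pd.Series
    n_replicates: int


def verdict_table(
    real: pd.DataFrame,
    control_hits: Mapping[str, ControlSummary],
    alpha: float = 0.01,
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Final per-subfamily verdicts.

    enriched iff both adjusted real p's < alpha and, for every control
    scheme, the subfamily is significant in <= tolerance of the replicates.
    """
    out = real.copy()
    sig_real = (out["q_hyper"] < alpha) & (out["q_binom"] < alpha) & ~out["untestable"]
    ok_controls = pd.Series(True, index=out.index)
    for scheme, summary in control_hits.items():
        frac = summary.hit_fraction.reindex(out.index).fillna(0.0)
        out[f"shuffle_hit_fraction_{scheme}"] = frac
        ok_controls &= frac <= tolerance
    out["verdict"] = sig_real & ok_controls
    return out


# ---------------------------------------------------------------------------
# Sequence-class coverage
# ---------------------------------------------------------------------------

def coverage_by_class(
    regions: RegionSet,
    te: TEAnnotation,
    classes: Sequence[str] = ("Alu", "pERV", "pLINE", "pDNA", "SVA", "ancient"),
) -> pd.DataFrame:
    """bp and percent of total region length per sequence class.

    Overlapping annotations are resolved per base with priority to the
    shortest overlapping element, making classes mutually exclusive; the
    remainder is "non-TE", so percentages sum to exactly 100.
    """
    merged = regions.merge()
    df = te.instances
    lengths = (df["end"] - df["start"]).to_numpy()
    order = np.argsort(lengths, kind="mergesort")  # shortest first wins
    bp = {c: 0 for c in classes}
    total = 0
    class_codes = {c: i + 1 for i, c in enumerate(classes)}
    for row in merged.df.itertuples(index=False):
        L = row.end - row.start
        total += L
        owner = np.zeros(L, dtype=np.int8)
        sub = df[(df["chrom"] == row.chrom) & (df["end"] > row.start) & (df["start"] < row.end)]
        sub_order = np.argsort((sub["end"] - sub["start"]).to_numpy(), kind="mergesort")
        for r in sub.iloc[sub_order].itertuples(index=False):
            code = class_codes.get(r.biotype)
            if code is None:
                continue
            lo = max(r.start, row.start) - row.start
            hi = min(r.end, row.end) - row.start
            seg = owner[lo:hi]
            seg[seg == 0] = code
        counts = np.bincount(owner, minlength=len(classes) + 1)
        for c, code in class_codes.items():
            bp[c] += int(counts[code])
    rows = [(c, bp[c]) for c in classes]
    non_te = total - sum(bp.values())
    rows.append(("non-TE", non_te))
    out = pd.DataFrame(rows, columns=["class", "bp"])
    out["percent"] = 100.0 * out["bp"] / total if total else 0.0
    return out


# ---------------------------------------------------------------------------
# Full driver
# ---------------------------------------------------------------------------

class _FastCounter:
    """Array-level per-subfamily overlap counting, bypassing DataFrames.

    Results agree exactly with :func:`count_overlaps`/:func:`test_subfamilies`
    (asserted in the test suite); this path exists because the shuffle
    controls evaluate thousands of replicates.
    """

    def __init__(self, te: TEAnnotation, background: pd.DataFrame, genome_bp: int):
        inst = te.instances
        self.subfamilies = list(background.index)
        code_of = {s: i for i, s in enumerate(self.subfamilies)}
        self.n_sub = len(self.subfamilies)
        self.by_chrom = {}
        for chrom, sub in inst.groupby("chrom"):
            self.by_chrom[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["subfamily"].map(code_of).to_numpy(),
            )
        self.K = background["genome_copies"].to_numpy()
        self.M = int(background.attrs["total_copies"])
        self.rate = background["genome_bp"].to_numpy() / genome_bp

    def counts(self, chroms, starts, ends, min_bp):
        """(copy counts, bp coverage, merged region bp) per subfamily."""
        k = np.zeros(self.n_sub, dtype=np.int64)
        kbp = np.zeros(self.n_sub, dtype=np.int64)
        region_bp = 0
        chroms = np.asarray(chroms)
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        for chrom in np.unique(chroms):
            mask = chroms == chrom
            order = np.argsort(starts[mask], kind="mergesort")
            ms, me = _merge_arrays(starts[mask][order], ends[mask][order])
            region_bp += int((me - ms).sum())
            if chrom not in self.by_chrom:
                continue
            ts, te_, code = self.by_chrom[chrom]
            bp = _covered_bp(ms, me, ts, te_)
            k += np.bincount(code[bp >= min_bp], minlength=self.n_sub)
            kbp += np.bincount(code, weights=bp, minlength=self.n_sub).astype(np.int64)
        return k, kbp, region_bp

    def significant(self, k, kbp, region_bp, draws, alpha):
        p_hyper = (
            stats.hypergeom.sf(k - 1, self.M, self.K, draws)
            if draws > 0
            else np.ones(self.n_sub)
        )
        p_binom = stats.binom.sf(kbp - 1, region_bp, self.rate)
        sig = (bh_qvalues(p_hyper) < alpha) | (bh_qvalues(p_binom) < alpha)
        return pd.Series(sig, index=self.subfamilies)


def run_enrichment(
    groups: Mapping[str, RegionSet],
    te: TEAnnotation,
    chrom_sizes: Mapping[str, int],
    classify_shuffled,
    n_shuffles: int = 1000,
    alpha: float = 0.01,
    tolerance: float = 0.05,
    min_bp: int = MIN_OVERLAP_BP,
    seed: int = 0,
    excluded: RegionSet | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-group enrichment with both control schemes.

    ``groups`` maps group name -> real RegionSet; ``classify_shuffled`` is a
    callable RegionSet -> group labels (one per region) implementing the
    alignability-based control grouping (scheme ii); ``excluded`` defaults
    to the union of all real regions (shuffles avoid real regions).
    """
    genome_bp = int(sum(chrom_sizes.values()))
    background = genome_background(te, genome_bp)
    fast = _FastCounter(te, background, genome_bp)
    all_regions = RegionSet(
        pd.concat([g.df for g in groups.values()], ignore_index=True)
    )
    if excluded is None:
        excluded = all_regions.merge()
    rng = np.random.default_rng(seed)
    allowed = excluded.complement(chrom_sizes).df
    b_chrom = allowed["chrom"].to_numpy()
    b_start = allowed["start"].to_numpy()
    b_len = (allowed["end"] - allowed["start"]).to_numpy()
    lengths = (all_regions.df["end"] - all_regions.df["start"]).to_numpy()
    group_lengths = {
        name: (g.df["end"] - g.df["start"]).to_numpy() for name, g in groups.items()
    }

    hit_counts_i = {name: np.zeros(fast.n_sub) for name in groups}
    hit_counts_ii = {name: np.zeros(fast.n_sub) for name in groups}

    def sig_for(chroms, starts, ends):
        k, kbp, rbp = fast.counts(chroms, starts, ends, min_bp)
        return fast.significant(k, kbp, rbp, int(k.sum()), alpha).to_numpy()

    for _ in range(n_shuffles):
        chroms, starts = _place_lengths(lengths, b_chrom, b_start, b_len, rng)
        ends = starts + lengths
        idx = _match_length_indices(lengths, group_lengths, rng)
        labels = np.asarray(
            classify_shuffled(RegionSet.from_arrays(chroms, starts, ends))
        )
        for name in groups:
            sel = idx[name]
            hit_counts_i[name] += sig_for(chroms[sel], starts[sel], ends[sel])
            mask = labels == name
            if mask.any():
                hit_counts_ii[name] += sig_for(
                    chroms[mask], starts[mask], ends[mask]
                )

    results = {}
    for name, g in groups.items():
        counts = count_overlaps(g, te, min_bp=min_bp)
        real = test_subfamilies(counts, background, g.merge().total_bp())
        controls = {
            "mirrored": ControlSummary(
                pd.Series(hit_counts_i[name] / n_shuffles, index=fast.subfamilies),
                n_shuffles,
            ),
            "reclassified": ControlSummary(
                pd.Series(hit_counts_ii[name] / n_shuffles, index=fast.subfamilies),
                n_shuffles,
            ),
        }
        results[name] = verdict_table(real, controls, alpha=alpha, tolerance=tolerance)
    return results
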