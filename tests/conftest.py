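"""Shared fixtures: small deterministic objects used across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from enhevo.intervals import GenomeInterval, RegionSet
from enhevo.io import PWM, TEAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def region_set_factory():
    def make(triples, name="rs"):
        return RegionSet(
            pd.DataFrame(triples, columns=["chrom", "start", "end"]), name=name
        )

    return make


@pytest.fixture
def info_pwm():
    """Information-rich 10-column PWM (GGGACTTTCC core)."""
    consensus = "GGGACTTTCC"
    counts = [[90.0 if c == b else 10.0 / 3 for c in consensus] for b in "ACGT"]
    return PWM("MA_test", np.array(counts), name="NFKB-like")


@pytest.fixture
def uniform_pwm():
    return PWM("MA_flat", np.full((4, 4), 25.0))


@pytest.fixture
def te_factory():
    """TEAnnotation from (chrom, start, end, subfamily) rows plus clades."""

    def make(rows, clades):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "subfamily"])
        df["strand"] = "+"
        df["repclass"] = "X"
        return TEAnnotation(df, clades)

    return make


def bitmap_union_bp(intervals, chrom_len=10_000):
    """Per-base oracle for union bp of intervals on one chromosome."""
    mask = np.zeros(chrom_len, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return int(mask.sum())


def bitmap_cover_bp(blocks, qs, qe, chrom_len=10_000):
    """Per-base oracle: bp of [qs,qe) covered by the union of blocks."""
    mask = np.zeros(chrom_len, dtype=bool)
    for s, e in blocks:
        mask[s:e] = True
    return int(mask[qs:qe].sum())
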