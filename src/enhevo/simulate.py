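"""Seed-deterministic synthetic cohort with known ground truth.

The generator builds, from one integer seed, every input the pipeline
consumes: a small genome with planted TE copies (consensus sequences mutated
at a per-subfamily rate, each copy carrying a ground-truth age), outgroup
alignability maps in which copies younger than an outgroup's divergence sit
inside gaps, enhancers placed so that their planted static/intermediate/
rapid labels are recoverable from those maps, motif instances inherited
from consensus sequences, ChIP-like peaks covering a stated fraction of
motifs, a three-population Balding-Nichols SNP panel with planted sweeps
and genealogy-style selection p-values, and a gene-disease matrix with a
planted core-gene block plus enhancer-gene links.

Ground-truth tables are emitted alongside every output so downstream
classifiers can be scored without re-simulation.  One global seed fans out
to per-component child streams by fixed offsets, so adding a generator
never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import RegionSet
from .io import PWM, FrequencyPanel, TEAnnotation

__all__ = [
    "SubfamilyModel",
    "SimulationConfig",
    "SyntheticGenome",
    "gen_genome",
    "gen_alignability",
    "gen_population_freqs",
    "gen_peaks_and_links",
    "generate_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# fixed child-stream offsets: one per generator
_STREAM = {"genome": 0, "alignability": 1, "pops": 2, "peaks": 3, "disease": 4}


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAM[stream]])


@dataclass
class SubfamilyModel:
    biotype: str               # Alu | pERV | pLINE | pDNA | SVA | ancient
    age: str                   # ancient | shared-primate | great-ape | human
    n_copies: int
    consensus_length: int
    substitution_rate: float   # per-base divergence of each copy from consensus


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort (defaults are the study conditions)."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 200_000
    # TE landscape: subfamily name -> model
    te_model: dict[str, SubfamilyModel] = field(
        default_factory=lambda: {
            "AluY": SubfamilyModel("Alu", "human", 25, 300, 0.01),
            "AluSx": SubfamilyModel("Alu", "great-ape", 50, 300, 0.04),
            "AluJb": SubfamilyModel("Alu", "shared-primate", 40, 300, 0.10),
            "THE1B": SubfamilyModel("pERV", "great-ape", 25, 350, 0.06),
            "L1PA3": SubfamilyModel("pLINE", "great-ape", 15, 600, 0.05),
            "SVA_E": SubfamilyModel("SVA", "human", 8, 400, 0.01),
            "MIR3": SubfamilyModel("ancient", "ancient", 40, 200, 0.20),
        }
    )
    # enhancers
    n_enhancers: int = 150
    enhancer_length: tuple[int, int] = (500, 1500)
    group_fractions: dict[str, float] = field(
        default_factory=lambda: {"static": 0.50, "intermediate": 0.42, "rapid": 0.08}
    )
    # alignability
    background_gap_rate: float = 0.0      # expected background gaps per 100 kb
    background_gap_length: tuple[int, int] = (50, 500)
    # motifs planted in consensus sequences: pwm id -> (subfamilies, offset)
    motif_plant: dict[str, tuple[tuple[str, ...], int]] = field(
        default_factory=lambda: {"MA0105.4": (("AluY", "AluSx", "THE1B"), 120)}
    )
    # peaks
    peak_fraction: float = 0.6
    peak_flank: int = 50
    # population panel
    populations: tuple[str, ...] = ("AFR", "EUR", "EAS")
    pop_f: dict[str, float] = field(
        default_factory=lambda: {"AFR": 0.05, "EUR": 0.05, "EAS": 0.05}
    )
    n_haploid: int = 200
    n_snps: int = 2000
    maf_floor: float = 0.05
    n_sweeps: int = 20
    sweep_delta: float = 0.4
    sweep_population: str = "EUR"
    relate_beta: tuple[float, float] = (0.1, 10.0)
    snps_in_enhancers: bool = True
    # disease layer
    n_genes: int = 200
    n_diseases: int = 10
    core_block_size: int = 20
    core_membership: int = 4              # diseases per core gene (of n_diseases)
    background_membership: int = 1
    link_core_prob: float = 0.3           # P(enhancer linked to a core gene)
    link_other_prob: float = 0.5

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


# ---------------------------------------------------------------------------
# genome + TE + enhancers
# ---------------------------------------------------------------------------

def _random_seq(n: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        # draw a different base for every hit position
        cur = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = _BASES[(cur + shift) % 4]
    return arr.tobytes().decode()


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    chrom_sizes: dict[str, int]
    te: TEAnnotation
    consensus: dict[str, str]
    enhancers: RegionSet
    enhancer_truth: pd.DataFrame         # id, group
    motif_truth: pd.DataFrame            # chrom, start, end, pwm_id, subfamily


def gen_genome(config: SimulationConfig) -> SyntheticGenome:
    rng = _child_rng(config.seed, "genome")
    sizes = config.chrom_sizes
    chrom_names = list(sizes)

    # consensus library, with planted motif words where requested
    consensus: dict[str, str] = {}
    for name, model in config.te_model.items():
        consensus[name] = _random_seq(model.consensus_length, rng)

    total_te_bp = sum(m.n_copies * m.consensus_length for m in config.te_model.values())
    genome_bp = sum(sizes.values())
    if total_te_bp >= 0.5 * genome_bp:
        raise ValueError("infeasible packing: planted TE bp exceed half the genome")

    # place TE copies without overlap
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def place(length: int, max_tries: int = 500) -> tuple[str, int]:
        for _ in range(max_tries):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            start = int(rng.integers(0, sizes[chrom] - length))
            if all(e <= start or s >= start + length for s, e in occupied[chrom]):
                occupied[chrom].append((start, start + length))
                return chrom, start
        raise ValueError(f"infeasible packing: cannot place a {length} bp feature")

    te_rows = []
    copy_seqs: list[tuple[str, int, str]] = []
    clade_table = {
        name: (m.biotype, m.age) for name, m in config.te_model.items()
    }
    for name, model in config.te_model.items():
        for _ in range(model.n_copies):
            chrom, start = place(model.consensus_length)
            seq = _mutate(consensus[name], model.substitution_rate, rng)
            te_rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + model.consensus_length,
                    "strand": "+",
                    "subfamily": name,
                    "repclass": model.biotype,
                }
            )
            copy_seqs.append((chrom, start, seq))
    te_df = pd.DataFrame(te_rows)
    te = TEAnnotation(te_df, clade_table)

    # enhancers: placement anchored so planted groups are recoverable
    young = {"great-ape", "human"}
    inst = te.instances
    human_copies = inst[inst["age_clade"] == "human"]
    ga_copies = inst[inst["age_clade"] == "great-ape"]
    if config.group_fractions.get("intermediate", 0) > 0 and ga_copies.empty:
        raise ValueError("intermediate enhancers need great-ape-age TE copies")
    if config.group_fractions.get("rapid", 0) > 0 and human_copies.empty:
        raise ValueError("rapid enhancers need human-age TE copies")
    young_by_chrom = {
        c: sub[["start", "end"]].to_numpy()
        for c, sub in inst[inst["age_clade"].isin(young)].groupby("chrom")
    }
    placed_enh: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def overlaps_young(chrom: str, s: int, e: int) -> int:
        arr = young_by_chrom.get(chrom)
        if arr is None:
            return 0
        ov = np.minimum(arr[:, 1], e) - np.maximum(arr[:, 0], s)
        return int(np.maximum(ov, 0).sum())

    def free_of_enh(chrom: str, s: int, e: int) -> bool:
        return all(pe <= s or ps >= e for ps, pe in placed_enh[chrom])

    n_per_group = {
        g: int(round(f * config.n_enhancers))
        for g, f in config.group_fractions.items()
    }
    lo, hi = config.enhancer_length
    enh_rows = []
    idx = 0
    for group, n_g in n_per_group.items():
        for _ in range(n_g):
            length = int(rng.integers(lo, hi + 1))
            for _ in range(500):
                if group == "static":
                    chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                    start = int(rng.integers(0, sizes[chrom] - length))
                    if overlaps_young(chrom, start, start + length):
                        continue
                else:
                    anchors = ga_copies if group == "intermediate" else human_copies
                    a = anchors.iloc[int(rng.integers(len(anchors)))]
                    need = max(int(0.03 * length) + 10, 15)
                    need = min(need, int(a.end - a.start))
                    if rng.random() < 0.5:
                        start = int(a.end) - need  # anchor at left edge
                    else:
                        start = int(a.start) + need - length
                    if start < 0 or start + length > sizes[a.chrom]:
                        continue
                    chrom = str(a.chrom)
                    # forbid stray young overlap that would break the label
                    stray = overlaps_young(chrom, start, start + length) - min(
                        need, max(0, min(int(a.end), start + length) - max(int(a.start), start))
                    )
                    if stray > 0:
                        continue
                    if group == "intermediate" and (
                        (human_copies["chrom"] == chrom)
                        & (human_copies["end"] > start)
                        & (human_copies["start"] < start + length)
                    ).any():
                        continue
                if not free_of_enh(chrom, start, start + length):
                    continue
                placed_enh[chrom].append((start, start + length))
                enh_rows.append(
                    (chrom, start, start + length, f"enh{idx:04d}", 0.0, ".", group)
                )
                idx += 1
                break
            else:
                raise ValueError(f"could not place a {group} enhancer of {length} bp")
    enh_df = pd.DataFrame(
        enh_rows, columns=["chrom", "start", "end", "id", "score", "strand", "group"]
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    enhancers = RegionSet(enh_df.drop(columns="group"), name="enhancers")
    truth = enh_df[["id", "group"]].copy()

    # assemble chromosome sequences: background + copy sequences
    seqs = {c: np.frombuffer(_random_seq(sizes[c], rng).encode(), dtype="S1").copy()
            for c in chrom_names}
    for chrom, start, seq in copy_seqs:
        seqs[chrom][start : start + len(seq)] = np.frombuffer(seq.encode(), dtype="S1")
    sequences = {c: a.tobytes().decode() for c, a in seqs.items()}

    # ground-truth motif instances mapped through each copy (no indels)
    motif_rows = []
    for pwm_id, (subs, offset) in config.motif_plant.items():
        for row in te.instances.itertuples(index=False):
            if row.subfamily in subs:
                motif_rows.append(
                    (row.chrom, row.start + offset, pwm_id, row.subfamily)
                )
    motif_truth = pd.DataFrame(
        motif_rows, columns=["chrom", "start", "pwm_id", "subfamily"]
    )
    return SyntheticGenome(
        sequences, dict(sizes), te, consensus, enhancers, truth, motif_truth
    )


def plant_motif_words(
    genome: SyntheticGenome, pwms: Mapping[str, PWM]
) -> SyntheticGenome:
    """Overwrite planted motif loci with each PWM's maximum-score word.

    Called after :func:`gen_genome` so the consensus library and every copy
    carry an exact motif instance; copy-level substitutions are re-applied
    only outside the motif so ground-truth instances stay intact.
    """
    arrs = {c: np.frombuffer(s.encode(), dtype="S1").copy()
            for c, s in genome.sequences.items()}
    widths = {}
    for pwm_id, pwm in pwms.items():
        word = "".join("ACGT"[i] for i in np.argmax(pwm.log_odds(), axis=0))
        widths[pwm_id] = pwm.width
        wordarr = np.frombuffer(word.encode(), dtype="S1")
        for row in genome.motif_truth.itertuples(index=False):
            if row.pwm_id != pwm_id:
                continue
            arrs[row.chrom][row.start : row.start + pwm.width] = wordarr
        # also plant in the consensus library
        for sub, seq in list(genome.consensus.items()):
            mask = genome.motif_truth[
                (genome.motif_truth["pwm_id"] == pwm_id)
                & (genome.motif_truth["subfamily"] == sub)
            ]
            if len(mask):
                # all copies of a subfamily share the consensus offset
                first_copy_start = int(
                    genome.te.instances.loc[
                        genome.te.instances["subfamily"] == sub, "start"
                    ].iloc[0]
                )
                offset = int(mask["start"].iloc[0]) - first_copy_start
                genome.consensus[sub] = (
                    seq[:offset] + word + seq[offset + pwm.width :]
                )
    genome.sequences = {c: a.tobytes().decode() for c, a in arrs.items()}
    truth = genome.motif_truth.copy()
    truth["end"] = truth["start"] + truth["pwm_id"].map(widths)
    genome.motif_truth = truth[["chrom", "start", "end", "pwm_id", "subfamily"]]
    return genome


# ---------------------------------------------------------------------------
# alignability
# ---------------------------------------------------------------------------

def gen_alignability(
    config: SimulationConfig, te: TEAnnotation
) -> dict[str, dict[str, RegionSet]]:
    """Per-outgroup gap and aligned interval sets.

    macaque gaps contain every copy younger than the human-macaque split
    (great-ape and human ages); chimp gaps contain human-age copies only;
    ancient and shared-primate copies are gap-free.  Background gaps are
    added at ``background_gap_rate`` per 100 kb, avoiding nothing (they are
    the noise model for alignment artefacts).
    """
    rng = _child_rng(config.seed, "alignability")
    sizes = config.chrom_sizes
    younger = {"macaque": {"great-ape", "human"}, "chimp": {"human"}}
    out: dict[str, dict[str, RegionSet]] = {}
    inst = te.instances
    for outgroup, ages in younger.items():
        sub = inst[inst["age_clade"].isin(ages)]
        rows = list(
            zip(sub["chrom"].tolist(), sub["start"].tolist(), sub["end"].tolist())
        )
        n_bg = rng.poisson(config.background_gap_rate * sum(sizes.values()) / 1e5)
        lo, hi = config.background_gap_length
        for _ in range(int(n_bg)):
            chrom = list(sizes)[int(rng.integers(len(sizes)))]
            glen = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, sizes[chrom] - glen))
            rows.append((chrom, start, start + glen))
        gaps = RegionSet(
            pd.DataFrame(rows, columns=["chrom", "start", "end"])
        ).merge()
        out[outgroup] = {"gaps": gaps, "aligned": gaps.complement(sizes)}
    return out


# ---------------------------------------------------------------------------
# population panel
# ---------------------------------------------------------------------------

def gen_population_freqs(
    config: SimulationConfig, enhancers: RegionSet | None = None
) -> tuple[FrequencyPanel, pd.DataFrame]:
    """Balding-Nichols three-population panel with planted sweeps.

    Ancestral frequency p ~ U(0.05, 0.95); each population draws its
    frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) (variance p(1-p)F). SNPs
    below the MAF floor in every population are redrawn.  Sweep SNPs get a
    +delta shift (clipped) and a Beta(a, b), a < 1, selection p-value in the
    swept population; all other selection p-values are Uniform(0, 1).
    """
    rng = _child_rng(config.seed, "pops")
    pops = list(config.populations)
    n = config.n_snps

    def draw(n_draw: int) -> dict[str, np.ndarray]:
        p = rng.uniform(0.05, 0.95, size=n_draw)
        freqs = {}
        for pop in pops:
            f = config.pop_f[pop]
            a = p * (1.0 - f) / f
            b = (1.0 - p) * (1.0 - f) / f
            freqs[pop] = rng.beta(a, b)
        return freqs

    freqs = draw(n)
    for _ in range(100):
        maf_ok = np.zeros(n, dtype=bool)
        for pop in pops:
            maf_ok |= np.minimum(freqs[pop], 1 - freqs[pop]) > config.maf_floor
        bad = ~maf_ok
        if not bad.any():
            break
        redraw = draw(int(bad.sum()))
        for pop in pops:
            freqs[pop][bad] = redraw[pop]

    sweep = np.zeros(n, dtype=bool)
    if config.n_sweeps > 0:
        sweep[rng.choice(n, size=min(config.n_sweeps, n), replace=False)] = True
    target = config.sweep_population
    freqs[target] = np.where(
        sweep, np.clip(freqs[target] + config.sweep_delta, 0.0, 1.0), freqs[target]
    )

    # genealogy-style selection evidence: Uniform under the null, small
    # Beta(a, b) with a < 1 at sweep sites, independently per population
    relate = {pop: rng.uniform(size=n) for pop in pops}
    a_b, b_b = config.relate_beta
    for pop in pops:
        relate[pop] = np.where(sweep, rng.beta(a_b, b_b, size=n), relate[pop])
    # keep p in (0,1]
    for pop in pops:
        relate[pop] = np.clip(relate[pop], 1e-300, 1.0)

    # positions: inside enhancers when requested, else uniform over genome
    sizes = config.chrom_sizes
    if config.snps_in_enhancers and enhancers is not None and len(enhancers):
        edf = enhancers.df
        lens = (edf["end"] - edf["start"]).to_numpy()
        pick = rng.choice(len(edf), size=n, p=lens / lens.sum())
        offs = (rng.random(n) * lens[pick]).astype(np.int64)
        chroms = edf["chrom"].to_numpy()[pick]
        pos = edf["start"].to_numpy()[pick] + offs
    else:
        chrom_names = list(sizes)
        pick = rng.integers(len(chrom_names), size=n)
        chroms = np.array(chrom_names, dtype=object)[pick]
        pos = (rng.random(n) * np.array([sizes[c] for c in chroms])).astype(np.int64)

    alleles = np.array(list("ACGT"))
    anc_i = rng.integers(4, size=n)
    der_i = (anc_i + rng.integers(1, 4, size=n)) % 4
    data = {
        "chrom": chroms,
        "pos0": pos,
        "ancestral": alleles[anc_i],
        "derived": alleles[der_i],
    }
    for pop in pops:
        data[f"freq_{pop}"] = freqs[pop]
        data[f"n_{pop}"] = np.full(n, config.n_haploid, dtype=int)
        data[f"p_relate_{pop}"] = relate[pop]
    df = pd.DataFrame(data)
    order = np.lexsort((df["pos0"].to_numpy(), df["chrom"].to_numpy()))
    df = df.iloc[order].reset_index(drop=True)
    truth = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos0": df["pos0"],
            "is_sweep": sweep[order],
            "sweep_population": np.where(sweep[order], target, ""),
        }
    )
    return FrequencyPanel(df), truth


# ---------------------------------------------------------------------------
# peaks, disease matrix, links
# ---------------------------------------------------------------------------

def gen_peaks_and_links(
    config: SimulationConfig, genome: SyntheticGenome
) -> dict[str, object]:
    """ChIP-like peaks over planted motifs, disease matrix, enhancer links."""
    rng = _child_rng(config.seed, "peaks")
    mt = genome.motif_truth
    if len(mt) and "end" not in mt.columns:
        raise ValueError(
            "motif instances not planted yet: call plant_motif_words first"
        )
    covered = rng.random(len(mt)) < config.peak_fraction
    flank = config.peak_flank
    rows = []
    for i, row in enumerate(mt.itertuples(index=False)):
        if not covered[i]:
            continue
        size = genome.chrom_sizes[row.chrom]
        rows.append(
            (row.chrom, max(0, row.start - flank), min(size, row.end + flank))
        )
    peaks = RegionSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end"])
    ).merge()
    peaks.name = "chip_peaks"

    drng = _child_rng(config.seed, "disease")
    genes = [f"gene{i:04d}" for i in range(config.n_genes)]
    diseases = [f"disease{j:02d}" for j in range(config.n_diseases)]
    mat = np.zeros((config.n_genes, config.n_diseases), dtype=int)
    core = genes[: config.core_block_size]
    for gi in range(config.core_block_size):
        cols = drng.choice(config.n_diseases, size=config.core_membership, replace=False)
        mat[gi, cols] = 1
    for gi in range(config.core_block_size, config.n_genes):
        k = min(config.background_membership, config.n_diseases)
        cols = drng.choice(config.n_diseases, size=k, replace=False)
        mat[gi, cols] = 1
    matrix = pd.DataFrame(mat, index=genes, columns=diseases)
    matrix.index.name = "gene"

    link_rows = []
    ide_truth = []
    enh_ids = genome.enhancers.df["id"].tolist()
    non_core = genes[config.core_block_size :]
    for eid in enh_ids:
        if drng.random() < config.link_core_prob:
            g = core[int(drng.integers(len(core)))]
            link_rows.append((eid, g, "core"))
            ide_truth.append((eid, True))
        elif drng.random() < config.link_other_prob:
            g = non_core[int(drng.integers(len(non_core)))]
            link_rows.append((eid, g, "background"))
            ide_truth.append((eid, False))
        else:
            ide_truth.append((eid, False))
    links = pd.DataFrame(link_rows, columns=["enhancer_id", "gene", "tag"])
    return {
        "peaks": peaks,
        "disease_matrix": matrix,
        "links": links,
        "core_genes_truth": core,
        "linked_core_truth": pd.DataFrame(
            ide_truth, columns=["enhancer_id", "linked_core"]
        ),
    }


def gen_enrichment_scenario(
    seed: int,
    n_regions: int = 100,
    region_length: int = 800,
    chrom_length: int = 500_000,
    n_subfamilies: int = 8,
    copies_per_subfamily: int = 200,
    te_length: int = 50,
    planted_subfamily: str | None = None,
    fold: float = 3.0,
) -> tuple[RegionSet, TEAnnotation, dict[str, int]]:
    """Coordinate-only scenario for enrichment calibration and power studies.

    TE copies are placed uniformly at random over one chromosome (the null
    condition); when ``planted_subfamily`` is given, that subfamily's
    within-region copy count is raised to ``fold`` times its genome-wide
    density by placing the excess copies inside regions.  Regions are
    non-overlapping and uniform.  Short copies relative to the region length
    keep the coverage (binomial) null close to its nominal calibration.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 11])
    sizes = {"chr1": chrom_length}
    # non-overlapping uniform regions
    placed: list[tuple[int, int]] = []
    for _ in range(n_regions):
        for _ in range(500):
            s = int(rng.integers(0, chrom_length - region_length))
            if all(e <= s or b >= s + region_length for b, e in placed):
                placed.append((s, s + region_length))
                break
        else:
            raise ValueError("cannot place non-overlapping regions")
    placed.sort()
    regions = RegionSet(
        pd.DataFrame(
            [("chr1", s, e, f"r{i:03d}", 0.0, ".") for i, (s, e) in enumerate(placed)],
            columns=["chrom", "start", "end", "id", "score", "strand"],
        ),
        name="regions",
    )
    region_bp = n_regions * region_length
    region_starts = np.array([s for s, _ in placed])

    names = [f"SF{i:02d}" for i in range(n_subfamilies)]
    rows = []
    for name in names:
        n_inside = 0
        if name == planted_subfamily:
            expected = copies_per_subfamily * region_bp / chrom_length
            n_inside = int(round(fold * expected))
        for j in range(copies_per_subfamily):
            if j < n_inside:
                ri = int(rng.integers(n_regions))
                s = int(region_starts[ri] + rng.integers(0, region_length - te_length))
            else:
                s = int(rng.integers(0, chrom_length - te_length))
            rows.append(
                {
                    "chrom": "chr1",
                    "start": s,
                    "end": s + te_length,
                    "strand": "+",
                    "subfamily": name,
                    "repclass": "SINE",
                }
            )
    te = TEAnnotation(
        pd.DataFrame(rows), {name: ("Alu", "great-ape") for name in names}
    )
    return regions, te, sizes


def generate_cohort(config: SimulationConfig, pwms: Mapping[str, PWM] | None = None):
    """Run every generator; returns a dict of all artefacts + ground truth."""
    genome = gen_genome(config)
    if pwms:
        genome = plant_motif_words(genome, pwms)
    maps = gen_alignability(config, genome.te)
    panel, sweep_truth = gen_population_freqs(config, genome.enhancers)
    peaks = gen_peaks_and_links(config, genome)
    return {
        "genome": genome,
        "alignability": maps,
        "panel": panel,
        "sweep_truth": sweep_truth,
        **peaks,
    }
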