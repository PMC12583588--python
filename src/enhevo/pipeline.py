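"""End-to-end orchestration: config, deterministic seeding, manifest.

A run is a pure function of (config, seed): every stage writes plain
TSV/BED/FASTA outputs with stable formatting, and the manifest records the
config hash, the seed, every threshold actually used and the SHA-256 of
every output, so re-running with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import disease as _disease
from . import divergence as _divergence
from . import enrichment as _enrichment
from . import motifs as _motifs
from . import selection as _selection
from .intervals import RegionSet
from .io import (
    PWM,
    AlignmentBlock,
    write_alignment_blocks,
    write_bed,
    write_clade_table,
    write_fasta,
    write_frequency_panel,
    write_gene_disease_matrix,
    write_links,
    write_repeatmasker,
)
from .simulate import SimulationConfig, SubfamilyModel, generate_cohort

logger = logging.getLogger("enhevo")

__all__ = ["Thresholds", "PipelineConfig", "validate_config", "run_all", "default_pwms"]

STAGES = ("simulate", "classify", "diverge", "enrich", "scan-motifs", "select", "ide")


@dataclass
class Thresholds:
    """Every printed threshold of the analysis, with its standard default."""

    minmatch: float = 0.97
    quasi_minmatch: float = 0.5
    te_loose_min_bp: int = 10
    te_strict_frac: float = 0.9
    peak_frac: float = 0.5
    motif_q_stringent: float = 1e-4
    motif_q_permissive: float = 1e-3
    motif_p_hit: float = 1e-4
    delta_boundary: float = 2.0
    alpha: float = 0.01
    tolerance: float = 0.05
    fdr: float = 0.05
    maf: float = 0.05
    n_shuffles: int = 1000
    core_gene_share: float = 0.30
    ide_peak_frac: float = 0.5


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "enhevo_out"
    stages: tuple[str, ...] = STAGES
    thresholds: Thresholds = field(default_factory=Thresholds)
    synthetic: SimulationConfig | None = field(default_factory=SimulationConfig)
    # group-dependent point-substitution rates for synthetic alignment blocks
    divergence_rates: dict[str, float] = field(
        default_factory=lambda: {"static": 0.01, "intermediate": 0.03, "rapid": 0.05}
    )
    gap_rate: float = 0.002

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if "outdir" in raw:
            cfg.outdir = str(raw["outdir"])
        if "stages" in raw:
            cfg.stages = tuple(raw["stages"])
        for key, val in (raw.get("thresholds") or {}).items():
            if not hasattr(cfg.thresholds, key):
                raise ValueError(f"unknown threshold {key!r}")
            setattr(cfg.thresholds, key, type(getattr(cfg.thresholds, key))(val))
        syn = raw.get("synthetic")
        if syn is not None:
            sc = SimulationConfig(seed=cfg.seed)
            for key, val in syn.items():
                if key == "te_model":
                    sc.te_model = {
                        name: SubfamilyModel(**m) for name, m in val.items()
                    }
                elif not hasattr(sc, key):
                    raise ValueError(f"unknown synthetic field {key!r}")
                else:
                    cur = getattr(sc, key)
                    if isinstance(cur, tuple):
                        val = tuple(val)
                    setattr(sc, key, val)
            cfg.synthetic = sc
        if "divergence_rates" in raw:
            cfg.divergence_rates = dict(raw["divergence_rates"])
        return cfg

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = {
            "seed": self.seed,
            "outdir": self.outdir,
            "stages": list(self.stages),
            "thresholds": asdict(self.thresholds),
            "divergence_rates": dict(self.divergence_rates),
        }
        if self.synthetic is not None:
            d["synthetic"] = asdict(self.synthetic)
        return d


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; empty means valid."""
    errors = []
    if config.synthetic is None:
        errors.append("no synthetic section: external-input mode needs file paths")
    else:
        if "select" in config.stages and len(config.synthetic.populations) != 3:
            errors.append(
                "selection stage requires exactly 3 populations "
                f"(got {len(config.synthetic.populations)})"
            )
        if config.synthetic.sweep_population not in config.synthetic.populations:
            errors.append("sweep_population not among populations")
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        errors.append(f"unknown stages: {sorted(unknown)}")
    return errors


def default_pwms() -> dict[str, PWM]:
    """Built-in NF-kB-like 10-column matrix (GGGACTTTCC core) for toy runs."""
    consensus = "GGGACTTTCC"
    counts = []
    for b in "ACGT":
        counts.append([90.0 if c == b else 10.0 / 3 for c in consensus])
    return {"MA0105.4": PWM("MA0105.4", np.array(counts), name="NFKB1")}


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _synthetic_blocks(config: PipelineConfig, genome, truth) -> dict:
    """Emulated gap-containing pairwise alignments per enhancer."""
    rng = np.random.default_rng([config.seed % (2**31), 7])
    from .simulate import _mutate  # substitution model shared with the genome

    blocks = {}
    rates = config.divergence_rates
    group_of = dict(zip(truth["id"], truth["group"]))
    for row in genome.enhancers.df.itertuples(index=False):
        seq = genome.sequences[row.chrom][row.start : row.end]
        rate = rates.get(group_of.get(str(row.id), "static"), 0.01)
        subject = _mutate(seq, rate, rng)
        sarr = list(subject)
        n_gaps = rng.poisson(config.gap_rate * len(sarr))
        for _ in range(int(n_gaps)):
            glen = int(rng.integers(1, 10))
            pos = int(rng.integers(0, max(1, len(sarr) - glen)))
            sarr[pos : pos + glen] = "-" * glen
        blocks[str(row.id)] = [
            AlignmentBlock(str(row.id), f"{row.id}_outgroup", 0.0, seq, "".join(sarr))
        ]
    return blocks


def run_all(config: PipelineConfig) -> dict:
    """Run the requested stages in dependency order; return the manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "thresholds": config.to_dict()["thresholds"],
        "outputs": {},
        "stages_run": [],
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }

    sc = config.synthetic
    sc.seed = config.seed
    pwms = default_pwms()
    cohort = generate_cohort(sc, pwms)
    genome = cohort["genome"]
    maps = cohort["alignability"]

    if "simulate" in config.stages:
        logger.info("stage simulate: writing synthetic cohort")
        write_fasta(genome.sequences, outdir / "genome.fa")
        write_repeatmasker(genome.te, outdir / "repeats.out")
        write_clade_table(genome.te.clade_table, outdir / "clades.tsv")
        write_bed(genome.enhancers, outdir / "enhancers.bed")
        _write_tsv(genome.enhancer_truth, outdir / "truth_enhancer_groups.tsv")
        _write_tsv(genome.motif_truth, outdir / "truth_motifs.tsv")
        for outgroup in maps:
            write_bed(maps[outgroup]["gaps"], outdir / f"gaps_{outgroup}.bed", bed6=False)
            write_bed(
                maps[outgroup]["aligned"], outdir / f"aligned_{outgroup}.bed", bed6=False
            )
        write_frequency_panel(cohort["panel"], outdir / "panel.tsv")
        _write_tsv(cohort["sweep_truth"], outdir / "truth_sweeps.tsv")
        write_bed(cohort["peaks"], outdir / "chip_peaks.bed")
        write_gene_disease_matrix(cohort["disease_matrix"], outdir / "disease_matrix.tsv")
        write_links(cohort["links"], outdir / "links.tsv")
        for p in sorted(outdir.iterdir()):
            if p.is_file() and p.suffix in {".bed", ".tsv", ".fa", ".out"}:
                record(p.name, p)
        manifest["stages_run"].append("simulate")

    enh_table = _classify.classify_enhancers(
        genome.enhancers,
        maps["chimp"]["aligned"],
        maps["macaque"]["aligned"],
        minmatch=thr.minmatch,
        quasi_minmatch=thr.quasi_minmatch,
    )
    te_table = _classify.classify_te_annotation(
        genome.te,
        maps["macaque"]["gaps"],
        maps["chimp"]["gaps"],
        strict_frac=thr.te_strict_frac,
    )
    if "classify" in config.stages:
        logger.info("stage classify")
        _write_tsv(enh_table, outdir / "enhancer_groups.tsv")
        _write_tsv(te_table, outdir / "te_provenance.tsv")
        record("enhancer_groups.tsv", outdir / "enhancer_groups.tsv")
        record("te_provenance.tsv", outdir / "te_provenance.tsv")
        manifest["stages_run"].append("classify")

    if "diverge" in config.stages:
        logger.info("stage diverge")
        blocks = _synthetic_blocks(config, genome, genome.enhancer_truth)
        write_alignment_blocks(blocks, outdir / "alignments.tsv")
        rows = []
        for rid, bl in blocks.items():
            rec = _divergence.mismatch_rate(bl, rid)
            rows.append(
                (rid, rec.aligned_gapfree_bp, rec.mismatches,
                 rec.mismatch_pct if rec.is_defined else np.nan)
            )
        div = pd.DataFrame(
            rows, columns=["id", "aligned_gapfree_bp", "mismatches", "mismatch_pct"]
        ).merge(genome.enhancer_truth, on="id")
        _write_tsv(div, outdir / "divergence.tsv")
        profile = _divergence.gap_distance_profile(
            [b for bl in blocks.values() for b in bl], [0, 50, 100, 300, 1000]
        )
        _write_tsv(profile, outdir / "gap_distance_profile.tsv")
        record("alignments.tsv", outdir / "alignments.tsv")
        record("divergence.tsv", outdir / "divergence.tsv")
        record("gap_distance_profile.tsv", outdir / "gap_distance_profile.tsv")
        manifest["stages_run"].append("diverge")

    groups = {
        g: genome.enhancers.subset((enh_table["group"] == g).to_numpy())
        for g in ("static", "intermediate", "rapid")
        if (enh_table["group"] == g).any()
    }
    if "enrich" in config.stages:
        logger.info("stage enrich: %d shuffles", thr.n_shuffles)

        def classify_shuffled(rs: RegionSet):
            return _classify.classify_enhancers(
                rs, maps["chimp"]["aligned"], maps["macaque"]["aligned"],
                minmatch=thr.minmatch,
            )["group"].to_numpy()

        results = _enrichment.run_enrichment(
            groups,
            genome.te,
            genome.chrom_sizes,
            classify_shuffled,
            n_shuffles=thr.n_shuffles,
            alpha=thr.alpha,
            tolerance=thr.tolerance,
            min_bp=thr.te_loose_min_bp,
            seed=config.seed,
        )
        frames = []
        for g, res in results.items():
            res = res.reset_index(names="subfamily")
            res.insert(0, "group", g)
            frames.append(res)
        _write_tsv(pd.concat(frames, ignore_index=True), outdir / "te_enrichment.tsv")
        cov = _enrichment.coverage_by_class(genome.enhancers, genome.te)
        _write_tsv(cov, outdir / "coverage_by_class.tsv")
        record("te_enrichment.tsv", outdir / "te_enrichment.tsv")
        record("coverage_by_class.tsv", outdir / "coverage_by_class.tsv")
        manifest["stages_run"].append("enrich")

    hits_all = []
    if "scan-motifs" in config.stages or "ide" in config.stages:
        logger.info("stage scan-motifs")
        for row in genome.enhancers.df.itertuples(index=False):
            seq = genome.sequences[row.chrom][row.start : row.end]
            for pwm in pwms.values():
                if len(seq) < pwm.width:
                    continue
                hits = _motifs.scan_sequence(seq, pwm)
                hits = hits[hits["p"] < thr.motif_p_hit].copy()
                if hits.empty:
                    continue
                hits["chrom"] = row.chrom
                hits["start"] = hits["start"] + row.start
                hits["end"] = hits["end"] + row.start
                hits["enhancer_id"] = row.id
                hits_all.append(hits)
    if hits_all:
        hits_df = pd.concat(hits_all, ignore_index=True)
        from .intervals import GenomeInterval

        origin, gained_mac, gained_chimp = [], [], []
        for h in hits_df.itertuples(index=False):
            iv = GenomeInterval(h.chrom, int(h.start), int(h.end))
            origin.append(_classify.assign_motif_origin(iv, genome.te))
            gained_mac.append(
                _classify.classify_tfbs(iv, maps["macaque"]["gaps"]) == "gained"
            )
            gained_chimp.append(
                _classify.classify_tfbs(iv, maps["chimp"]["gaps"]) == "gained"
            )
        hits_df["origin"] = origin
        hits_df["age"] = np.where(
            np.array(gained_mac) & ~np.array(gained_chimp),
            "great_ape_specific",
            np.where(gained_mac, "human_specific", "shared"),
        )
        hits_df = _motifs.call_bound(hits_df, cohort["peaks"])
    else:
        hits_df = pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "score", "p", "matrix_id",
                     "enhancer_id", "origin", "age", "bound"]
        )
    if "scan-motifs" in config.stages:
        out_hits = hits_df[
            ["chrom", "start", "end", "matrix_id", "strand", "score", "p",
             "enhancer_id", "origin", "age", "bound"]
        ].sort_values(["chrom", "start", "end", "strand"], kind="mergesort")
        _write_tsv(out_hits, outdir / "motif_hits.tsv")
        record("motif_hits.tsv", outdir / "motif_hits.tsv")
        manifest["stages_run"].append("scan-motifs")

    snps = enh_sel = None
    if "select" in config.stages or "ide" in config.stages:
        logger.info("stage select")
        snps, enh_sel = _selection.scan_panel(
            cohort["panel"], genome.enhancers, maf=thr.maf, fdr=thr.fdr
        )
    if "select" in config.stages:
        _write_tsv(snps, outdir / "snp_selection.tsv")
        _write_tsv(enh_sel, outdir / "enhancer_selection.tsv")
        record("snp_selection.tsv", outdir / "snp_selection.tsv")
        record("enhancer_selection.tsv", outdir / "enhancer_selection.tsv")
        manifest["stages_run"].append("select")

    if "ide" in config.stages:
        logger.info("stage ide")
        core = _disease.core_genes(
            cohort["disease_matrix"], threshold=thr.core_gene_share
        )
        ide = _disease.define_ides(
            genome.enhancers, cohort["links"], core, cohort["peaks"],
            min_peak_frac=thr.ide_peak_frac,
        )
        features: dict[str, dict[str, bool]] = {}
        if len(hits_df):
            has_motif = set(hits_df["enhancer_id"].astype(str))
            bound = set(hits_df.loc[hits_df["bound"], "enhancer_id"].astype(str))
            gained = set(
                hits_df.loc[hits_df["age"] != "shared", "enhancer_id"].astype(str)
            )
            features["nfkb_motif"] = {e: True for e in has_motif}
            features["bound_nfkb_motif"] = {e: True for e in bound}
            features["gained_nfkb_motif"] = {e: True for e in gained}
        if enh_sel is not None:
            features["ps_enhancer"] = {
                str(r.enhancer_id): bool(r.ps_flag)
                for r in enh_sel.itertuples(index=False)
            }
        profiles = _disease.ide_profiles(ide, features)
        _write_tsv(ide.assign(core_genes=ide["core_genes"].map(",".join)),
                   outdir / "ide_records.tsv")
        _write_tsv(profiles, outdir / "ide_profiles.tsv")
        record("ide_records.tsv", outdir / "ide_records.tsv")
        record("ide_profiles.tsv", outdir / "ide_profiles.tsv")
        manifest["stages_run"].append("ide")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
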