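"""File-format boundary of the pipeline.

Readers produce the in-memory containers the analysis stages consume
(:class:`~enhevo.intervals.RegionSet`, :class:`TEAnnotation`, :class:`PWM`,
:class:`FrequencyPanel`, alignment blocks); writers emit the same dialects so
every format round-trips. 1-based inclusive coordinates (RepeatMasker .out)
are converted to the package's 0-based half-open convention here and only
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeInterval, RegionSet

__all__ = [
    "ParseError",
    "TEAnnotation",
    "PWM",
    "AlignmentBlock",
    "FrequencyPanel",
    "read_bed",
    "write_bed",
    "read_clade_table",
    "write_clade_table",
    "read_repeatmasker",
    "write_repeatmasker",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_alignment_blocks",
    "write_alignment_blocks",
    "read_frequency_panel",
    "write_frequency_panel",
    "read_fasta",
    "write_fasta",
    "read_track",
    "write_track",
    "read_gene_disease_matrix",
    "write_gene_disease_matrix",
    "read_links",
    "write_links",
    "BIOTYPES",
    "AGE_CLADES",
]


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


BIOTYPES = ("Alu", "pERV", "pLINE", "pDNA", "SVA", "ancient")
# age clades ordered old -> young relative to the human lineage
AGE_CLADES = ("ancient", "shared-primate", "great-ape", "human")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, name: str | None = None) -> RegionSet:
    """Read BED3/BED6 into a RegionSet (coordinates kept verbatim)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            rid = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], start, end, rid, score, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "score", "strand"])
    return RegionSet(df, name=name or path.stem)


def write_bed(regions: RegionSet, path: str | Path, bed6: bool = True) -> None:
    with open(path, "w") as fh:
        for row in regions.df.itertuples(index=False):
            if bed6:
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.id}\t"
                    f"{_fmt_score(row.score)}\t{row.strand}\n"
                )
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


def _fmt_score(x: float) -> str:
    return f"{int(x)}" if float(x) == int(x) else f"{x:g}"


# ---------------------------------------------------------------------------
# TE annotation (RepeatMasker .out dialect)
# ---------------------------------------------------------------------------

class TEAnnotation:
    """Repeat instances plus the subfamily -> (biotype, age clade) lookup.

    ``instances`` is a DataFrame with columns chrom, start, end, strand,
    subfamily, repclass, biotype, age_clade. Subfamilies absent from the
    clade table default to biotype/age "ancient".
    """

    def __init__(self, instances: pd.DataFrame, clade_table: Mapping[str, tuple[str, str]]):
        self.clade_table = dict(clade_table)
        df = instances.copy().reset_index(drop=True)
        bio, age = [], []
        for sub in df["subfamily"]:
            b, a = self.clade_table.get(sub, ("ancient", "ancient"))
            bio.append(b)
            age.append(a)
        df["biotype"] = bio
        df["age_clade"] = age
        self.instances = df

    def __len__(self) -> int:
        return len(self.instances)

    def subfamily_counts(self) -> pd.Series:
        return self.instances.groupby("subfamily").size()

    def subfamily_bp(self) -> pd.Series:
        df = self.instances
        return (df["end"] - df["start"]).groupby(df["subfamily"]).sum()

    def as_region_set(self, name: str = "TE") -> RegionSet:
        df = self.instances.rename(columns={"subfamily": "id"})[
            ["chrom", "start", "end", "id", "strand"]
        ].copy()
        df["score"] = 0.0
        return RegionSet(df, name=name)

    def subset(self, mask) -> "TEAnnotation":
        return TEAnnotation(
            self.instances[np.asarray(mask)].drop(columns=["biotype", "age_clade"]),
            self.clade_table,
        )


def read_clade_table(path: str | Path) -> dict[str, tuple[str, str]]:
    """TSV with columns subfamily, biotype, age_clade."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {r.subfamily: (r.biotype, r.age_clade) for r in df.itertuples(index=False)}


def write_clade_table(table: Mapping[str, tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("subfamily\tbiotype\tage_clade\n")
        for sub in sorted(table):
            b, a = table[sub]
            fh.write(f"{sub}\t{b}\t{a}\n")


def read_repeatmasker(
    path: str | Path,
    clade_table: Mapping[str, tuple[str, str]] | None = None,
) -> TEAnnotation:
    """Parse RepeatMasker .out (1-based inclusive -> 0-based half-open)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            # header lines start with "SW"/"score" tokens, data with an integer
            if not parts[0].lstrip("-").isdigit():
                continue
            if len(parts) < 11:
                raise ParseError(f"{path}:{lineno}: truncated RepeatMasker line")
            try:
                begin = int(parts[5])
                end = int(parts[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            strand = "+" if parts[8] == "+" else "-"
            rows.append(
                {
                    "chrom": parts[4],
                    "start": begin - 1,
                    "end": end,
                    "strand": strand,
                    "subfamily": parts[9],
                    "repclass": parts[10],
                }
            )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "subfamily", "repclass"]
    )
    return TEAnnotation(df, clade_table or {})


_RM_HEADER = (
    "   SW   perc perc perc  query     position in query    matching"
    "  repeat              position in repeat\n"
    "score   div. del. ins.  sequence  begin end   (left)   repeat"
    "  class/family      begin end  (left) ID\n\n"
)


def write_repeatmasker(te: TEAnnotation, path: str | Path) -> None:
    """Write the .out dialect back (synthetic score/divergence columns)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, row in enumerate(te.instances.itertuples(index=False), start=1):
            strand = "+" if row.strand == "+" else "C"
            fh.write(
                f"  {1000} {0.0:4.1f} {0.0:4.1f} {0.0:4.1f}  {row.chrom} "
                f"{row.start + 1} {row.end} (0) {strand} {row.subfamily} "
                f"{row.repclass} 1 {row.end - row.start} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

_BASES = "ACGT"


@dataclass
class PWM:
    """A position frequency matrix with background model and pseudocount.

    ``counts`` is a 4xW array (rows A, C, G, T). Column probabilities are
    (count + pseudocount*background) / (colsum + pseudocount); the log-odds
    matrix is log2(prob / background) and is finite whenever pseudocount > 0.
    """

    matrix_id: str
    counts: np.ndarray
    name: str = ""
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.8

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4xW matrix")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def probabilities(self) -> np.ndarray:
        colsum = self.counts.sum(axis=0)
        return (self.counts + self.pseudocount * self.background[:, None]) / (
            colsum + self.pseudocount
        )

    def log_odds(self) -> np.ndarray:
        return np.log2(self.probabilities() / self.background[:, None])


def read_jaspar_pfm(path: str | Path) -> list[PWM]:
    """Parse JASPAR-style PFM text (>ID NAME header + 4 bracketed rows)."""
    path = Path(path)
    pwms: list[PWM] = []
    header: str | None = None
    rows: dict[str, list[float]] = {}

    def flush(lineno: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        if set(rows) != set(_BASES):
            raise ParseError(f"{path}:{lineno}: record {header} missing base rows")
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise ParseError(f"{path}:{lineno}: rows of unequal width in {header}")
        fields = header.split(None, 1)
        pwms.append(
            PWM(
                matrix_id=fields[0],
                name=fields[1] if len(fields) > 1 else "",
                counts=np.array([rows[b] for b in _BASES]),
            )
        )
        header, rows = None, {}

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].strip()
            else:
                base = line[0].upper()
                if base not in _BASES:
                    raise ParseError(f"{path}:{lineno}: unexpected row {line[:20]!r}")
                nums = line[1:].replace("[", " ").replace("]", " ").split()
                try:
                    rows[base] = [float(x) for x in nums]
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad count") from exc
        flush(lineno + 1)
    return pwms


def write_jaspar_pfm(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.matrix_id} {pwm.name}".rstrip() + "\n")
            for b, row in zip(_BASES, pwm.counts):
                vals = " ".join(_fmt_score(v) for v in row)
                fh.write(f"{b} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Pairwise alignment blocks (tabular, qseq/sseq columns)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentBlock:
    """One gapped pairwise alignment; qseq and sseq have equal length."""

    query_id: str
    subject_id: str
    pident: float
    qseq: str
    sseq: str

    def __post_init__(self) -> None:
        if len(self.qseq) != len(self.sseq):
            raise ParseError(
                f"block {self.query_id}/{self.subject_id}: aligned strings of "
                f"unequal length ({len(self.qseq)} vs {len(self.sseq)})"
            )


def read_alignment_blocks(path: str | Path) -> dict[str, list[AlignmentBlock]]:
    """Tabular blocks: query id, subject id, percent identity, qseq, sseq."""
    path = Path(path)
    out: dict[str, list[AlignmentBlock]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields")
            try:
                block = AlignmentBlock(
                    parts[0], parts[1], float(parts[2]), parts[3], parts[4]
                )
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.setdefault(block.query_id, []).append(block)
    return out


def write_alignment_blocks(
    blocks: Mapping[str, Sequence[AlignmentBlock]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for qid in blocks:
            for b in blocks[qid]:
                fh.write(f"{b.query_id}\t{b.subject_id}\t{b.pident:g}\t{b.qseq}\t{b.sseq}\n")


# ---------------------------------------------------------------------------
# Frequency panel (three-population allele frequencies + external p-values)
# ---------------------------------------------------------------------------

class FrequencyPanel:
    """Per-SNP derived-allele frequencies, haploid sample sizes and external
    per-population selection p-values for a fixed set of populations.

    Backed by a DataFrame with columns chrom, pos0, ancestral, derived and,
    per population POP: freq_POP, n_POP, p_relate_POP.
    """

    def __init__(self, df: pd.DataFrame):
        pops = sorted(
            c[len("freq_"):] for c in df.columns if c.startswith("freq_")
        )
        if not pops:
            raise ValueError("no freq_POP columns found")
        for pop in pops:
            for prefix in ("freq_", "n_", "p_relate_"):
                if prefix + pop not in df.columns:
                    raise ValueError(f"missing column {prefix + pop}")
            f = df[f"freq_{pop}"]
            if ((f < 0) | (f > 1)).any():
                raise ValueError(f"freq_{pop} outside [0,1]")
            if (df[f"n_{pop}"] < 2).any():
                raise ValueError(f"n_{pop} below 2")
            p = df[f"p_relate_{pop}"]
            if ((p <= 0) | (p > 1)).any():
                raise ValueError(f"p_relate_{pop} outside (0,1]")
        self.df = df.reset_index(drop=True)
        self.populations = pops

    def __len__(self) -> int:
        return len(self.df)

    def freqs(self, pop: str) -> np.ndarray:
        return self.df[f"freq_{pop}"].to_numpy(dtype=float)

    def sizes(self, pop: str) -> np.ndarray:
        return self.df[f"n_{pop}"].to_numpy(dtype=float)

    def relate_p(self, pop: str) -> np.ndarray:
        return self.df[f"p_relate_{pop}"].to_numpy(dtype=float)

    def positions(self) -> RegionSet:
        df = pd.DataFrame(
            {
                "chrom": self.df["chrom"],
                "start": self.df["pos0"].astype(np.int64),
                "end": self.df["pos0"].astype(np.int64) + 1,
                "id": [f"snp{i}" for i in range(len(self.df))],
            }
        )
        return RegionSet(df, name="snps")


def read_frequency_panel(path: str | Path) -> FrequencyPanel:
    return FrequencyPanel(pd.read_csv(path, sep="\t"))


def write_frequency_panel(panel: FrequencyPanel, path: str | Path) -> None:
    panel.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# FASTA / score track / disease tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                seqs[current] = []
            elif current is None:
                raise ParseError(f"{path}: sequence before header")
            else:
                seqs[current].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_track(path: str | Path) -> pd.DataFrame:
    """BedGraph-style 4-column TSV: chrom, start, end, score."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "score"],
        comment="#",
    )
    if not np.isfinite(df["score"]).all():
        raise ParseError(f"{path}: non-finite track values")
    return df


def write_track(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")


def read_gene_disease_matrix(path: str | Path) -> pd.DataFrame:
    """Genes (rows) x diseases (columns) binary membership matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.isin([0, 1]).all().all():
        raise ParseError(f"{path}: entries must be 0/1")
    return df.astype(int)


def write_gene_disease_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_links(path: str | Path) -> pd.DataFrame:
    """Enhancer -> gene link table (enhancer_id, gene, tag)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("enhancer_id", "gene"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col}")
    return df


def write_links(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
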