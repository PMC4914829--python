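"""Readers and writers for the plain-text formats the pipeline exchanges:
FASTA genomes, BED/bedGraph intervals and tracks, TSV count and expression
tables, and TIFF images. Coordinates are 0-based half-open (BED)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .damid import DamCounts, FragmentMap
from .synthetic import ExprMatrix, GenomeModel

log = logging.getLogger("lamshift")

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "write_bedgraph",
    "read_bedgraph",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_regions_bed",
]


def write_fasta(genome: GenomeModel, path: str | Path, width: int = 60) -> None:
    if genome.sequence is None:
        raise ValueError("genome has no sequence")
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequence[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> GenomeModel:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    names = list(fa.keys())
    seqs = {n: str(fa[n][:]) for n in names}
    fa.close()
    return GenomeModel(names, [len(seqs[n]) for n in names], seqs)


# ---------------------------------------------------------------------------
# intervals


def _validate_interval_frame(frame: pd.DataFrame, path, offset: int = 1) -> None:
    bad = frame.index[(frame["start"] < 0) | (frame["start"] >= frame["end"])]
    if len(bad):
        raise ValueError(
            f"{path}: invalid interval at line {int(bad[0]) + offset + 1}"
        )


def write_bed(frame: pd.DataFrame, path: str | Path, sort: bool = True) -> None:
    """BED3+ writer; extra columns after chrom/start/end are kept in order."""
    cols = ["chrom", "start", "end"] + [
        c for c in frame.columns if c not in ("chrom", "start", "end")
    ]
    out = frame[cols]
    if sort:
        out = out.sort_values(["chrom", "start", "end"], kind="stable")
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    """BED3+ reader with per-line coordinate validation."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    base = ["chrom", "start", "end"]
    if names is None:
        names = base + [f"col{i}" for i in range(3, frame.shape[1])]
    frame.columns = names[: frame.shape[1]]
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    _validate_interval_frame(frame, path, offset=0)
    return frame


def write_bedgraph(track_frame: pd.DataFrame, path: str | Path) -> None:
    out = track_frame[["chrom", "start", "end", "value"]].copy()
    out = out[np.isfinite(out["value"])]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    frame = read_bed(path, ["chrom", "start", "end", "value"])
    frame["value"] = frame["value"].astype(float)
    # overlapping intervals are legal in this dialect; warn only
    srt = frame.sort_values(["chrom", "start"])
    prev_end = srt.groupby("chrom")["end"].shift()
    if bool((srt["start"] < prev_end).any()):
        log.warning("%s: bedGraph has overlapping intervals", path)
    return frame


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Shift regions / LADs as BED: name = direction, score = -10 log10 p."""
    out = regions[["chrom", "start", "end"]].copy()
    out["name"] = regions.get("direction", pd.Series(["LAD"] * len(regions))).to_numpy()
    if "p_empirical" in regions:
        p = np.clip(regions["p_empirical"].to_numpy(float), 1e-300, 1.0)
        out["score"] = np.round(-10.0 * np.log10(p), 2)
    write_bed(out, path)


# ---------------------------------------------------------------------------
# counts


def write_counts_tsv(counts: DamCounts, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> DamCounts:
    frame = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: missing columns {required - set(frame.columns)}")
    boundaries = {}
    for c, sub in frame.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        if not np.array_equal(starts[1:], ends[:-1]) or starts[0] != 0:
            raise ValueError(f"{path}: fragments on {c} do not tile the chromosome")
        boundaries[c] = np.concatenate([starts, ends[-1:]])
    fragmap = FragmentMap(boundaries)
    conds = sorted(
        {col.split("_", 1)[1] for col in frame.columns if col.startswith("dam_")}
    )
    dam = {k: {} for k in conds}
    lamin = {k: {} for k in conds}
    for c, sub in frame.groupby("chrom", sort=False):
        for cond in conds:
            dam[cond][c] = sub[f"dam_{cond}"].to_numpy(np.int64)
            lamin[cond][c] = sub[f"lamin_{cond}"].to_numpy(np.int64)
    return DamCounts(fragmap, dam, lamin)


# ---------------------------------------------------------------------------
# expression


def write_expression_tsv(expr: ExprMatrix, path: str | Path) -> None:
    out = expr.data.copy()
    out.columns = [f"{s}:{expr.conditions[s]}" for s in out.columns]
    out.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path) -> ExprMatrix:
    """Genes x samples TSV with header ``sample:condition`` columns."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    conditions = {}
    samples = []
    for col in frame.columns:
        if ":" not in col:
            raise ValueError(f"{path}: column {col!r} lacks ':condition' suffix")
        sample, cond = col.rsplit(":", 1)
        conditions[sample] = cond
        samples.append(sample)
    for j, col in enumerate(frame.columns):
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            i = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValueError(f"{path}: non-numeric value at row {i + 2}, column {j + 2}")
        frame[col] = vals.astype(float)
    frame.columns = samples
    return ExprMatrix(frame, conditions)
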