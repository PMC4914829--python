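"""DamID core: GATC fragment maps, read counting, log-ratio tracks and
windowed statistics.

The resolution unit of DamID is the DpnI fragment: the interval between
consecutive GATC motif starts. Per fragment, the ratio
``log2(Lamin B1 Dam / soluble Dam)`` measures contact with the nuclear
lamina. Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("lamshift")

GATC_RE = re.compile(b"GATC")

__all__ = [
    "FragmentMap",
    "DamCounts",
    "RatioTrack",
    "BinnedTrack",
    "GeneDelta",
    "digest_gatc",
    "count_reads_to_fragments",
    "log2_ratio",
    "running_mean",
    "running_ratio",
    "gene_delta",
    "gene_deltas",
]


# ---------------------------------------------------------------------------
# fragment map


class FragmentMap:
    """Ordered GATC-bounded fragments tiling each chromosome.

    ``boundaries[chrom]`` is an int64 array ``[0, b1, ..., L]``; fragment
    ``i`` is ``[b_i, b_{i+1})``. The tiling is exact: no gaps, no overlaps.
    """

    def __init__(self, boundaries: Mapping[str, np.ndarray]):
        self.boundaries = {
            c: np.asarray(b, dtype=np.int64) for c, b in boundaries.items()
        }
        for c, b in self.boundaries.items():
            if len(b) < 2 or b[0] != 0:
                raise ValueError(f"{c}: boundaries must start at 0")
            if np.any(np.diff(b) <= 0):
                raise ValueError(f"{c}: boundaries must be strictly increasing")

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str]) -> "FragmentMap":
        return cls({c: _gatc_boundaries(s) for c, s in seqs.items()})

    @property
    def chroms(self) -> list[str]:
        return list(self.boundaries)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: int(b[-1]) for c, b in self.boundaries.items()}

    def n_fragments(self, chrom: str) -> int:
        return len(self.boundaries[chrom]) - 1

    @property
    def total_fragments(self) -> int:
        return sum(self.n_fragments(c) for c in self.chroms)

    def starts(self, chrom: str) -> np.ndarray:
        return self.boundaries[chrom][:-1]

    def ends(self, chrom: str) -> np.ndarray:
        return self.boundaries[chrom][1:]

    def midpoints(self, chrom: str) -> np.ndarray:
        b = self.boundaries[chrom]
        return (b[:-1] + b[1:]) // 2

    def fragment_index(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Index of the fragment containing each position (half-open rule:
        a position at a boundary belongs to the fragment starting there).
        Out-of-bounds positions get -1."""
        b = self.boundaries[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        idx = np.searchsorted(b, pos, side="right") - 1
        bad = (pos < 0) | (pos >= b[-1])
        idx[bad] = -1
        return idx

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chroms:
            rows.append(
                pd.DataFrame(
                    {"chrom": c, "start": self.starts(c), "end": self.ends(c)}
                )
            )
        return pd.concat(rows, ignore_index=True)


def _gatc_boundaries(sequence: str) -> np.ndarray:
    if not sequence:
        raise ValueError("empty sequence")
    data = sequence.upper().encode("ascii")
    pos = [m.start() for m in GATC_RE.finditer(data)]
    L = len(sequence)
    b = [0] + [p for p in pos if 0 < p < L] + [L]
    return np.array(sorted(set(b)), dtype=np.int64)


def digest_gatc(sequence: str, chrom: str = "chr1") -> FragmentMap:
    """In-silico DpnI digestion: fragment boundaries at every GATC start.

    Leading/trailing fragments are included; a motif at position 0 adds no
    boundary (the zero-width fragment is suppressed). N runs never match.
    """
    return FragmentMap({chrom: _gatc_boundaries(sequence)})


# ---------------------------------------------------------------------------
# counts


@dataclass
class DamCounts:
    """Per-fragment read counts for the Dam-only and Dam-LaminB1 channels,
    keyed by condition (e.g. MB, MT) then chromosome."""

    fragmap: FragmentMap
    dam: dict[str, dict[str, np.ndarray]]
    lamin: dict[str, dict[str, np.ndarray]]

    def __post_init__(self):
        for cond in self.conditions:
            for chan in (self.dam[cond], self.lamin[cond]):
                for c, arr in chan.items():
                    if len(arr) != self.fragmap.n_fragments(c):
                        raise ValueError(f"counts not aligned to fragmap on {c}")
                    if np.any(arr < 0):
                        raise ValueError("negative counts")

    @property
    def conditions(self) -> list[str]:
        return list(self.dam)

    def totals(self, condition: str) -> tuple[int, int]:
        d = sum(int(a.sum()) for a in self.dam[condition].values())
        l = sum(int(a.sum()) for a in self.lamin[condition].values())
        return d, l

    def to_frame(self) -> pd.DataFrame:
        frame = self.fragmap.to_frame()
        for cond in self.conditions:
            frame[f"dam_{cond}"] = np.concatenate(
                [self.dam[cond][c] for c in self.fragmap.chroms]
            )
            frame[f"lamin_{cond}"] = np.concatenate(
                [self.lamin[cond][c] for c in self.fragmap.chroms]
            )
        return frame


def count_reads_to_fragments(
    read_starts: Mapping[tuple[str, str], pd.DataFrame],
    fragmap: FragmentMap,
) -> DamCounts:
    """Assign reads to the fragment containing their 5' start.

    ``read_starts`` maps ``(condition, channel)`` with channel in
    {"dam", "lamin"} to a BED-like frame with columns chrom/start. Reads
    outside chromosome bounds are skipped with a logged warning; retained
    read totals are conserved in the fragment counts.
    """
    dam: dict[str, dict[str, np.ndarray]] = {}
    lamin: dict[str, dict[str, np.ndarray]] = {}
    n_skipped = 0
    for (cond, channel), frame in read_starts.items():
        if channel not in ("dam", "lamin"):
            raise ValueError(f"unknown channel {channel!r}")
        store = dam if channel == "dam" else lamin
        per_chrom = {
            c: np.zeros(fragmap.n_fragments(c), dtype=np.int64)
            for c in fragmap.chroms
        }
        for c, sub in frame.groupby("chrom", sort=False):
            if c not in per_chrom:
                n_skipped += len(sub)
                continue
            idx = fragmap.fragment_index(c, sub["start"].to_numpy())
            ok = idx >= 0
            n_skipped += int((~ok).sum())
            np.add.at(per_chrom[c], idx[ok], 1)
        store[cond] = per_chrom
    if n_skipped:
        log.warning("count_reads_to_fragments: skipped %d out-of-bounds reads", n_skipped)
    conds = sorted(set(dam) | set(lamin))
    zeros = lambda: {
        c: np.zeros(fragmap.n_fragments(c), dtype=np.int64) for c in fragmap.chroms
    }
    for cond in conds:
        dam.setdefault(cond, zeros())
        lamin.setdefault(cond, zeros())
    return DamCounts(fragmap, dam, lamin)


# ---------------------------------------------------------------------------
# ratio tracks


@dataclass
class RatioTrack:
    """Per-fragment log2(LaminB1/Dam) values for one condition. NaN marks
    fragments masked out (e.g. empty in both channels with mask_empty)."""

    fragmap: FragmentMap
    condition: str
    values: dict[str, np.ndarray]


def _scale_factors(
    total_dam: int, total_lamin: int, scale_libraries: bool
) -> tuple[float, float]:
    if not scale_libraries:
        return 1.0, 1.0
    target = 0.5 * (total_dam + total_lamin)
    sd = target / total_dam if total_dam > 0 else 1.0
    sl = target / total_lamin if total_lamin > 0 else 1.0
    return sd, sl


def log2_ratio(
    counts: DamCounts,
    condition: str,
    pseudocount: float = 1.0,
    scale_libraries: bool = True,
    mask_empty: bool = False,
) -> RatioTrack:
    """Per-fragment log2((lamin*sl + c) / (dam*sd + c)).

    With ``scale_libraries`` the two channels are scaled to a common total
    so channel depth does not bias the ratio. Fragments empty in both
    channels get 0 (the pseudocount floor) unless ``mask_empty``.
    """
    td, tl = counts.totals(condition)
    if td == 0 and tl == 0:
        raise ValueError(f"condition {condition}: both channels are all-zero")
    sd, sl = _scale_factors(td, tl, scale_libraries)
    values = {}
    for c in counts.fragmap.chroms:
        d = counts.dam[condition][c].astype(float)
        l = counts.lamin[condition][c].astype(float)
        v = np.log2((l * sl + pseudocount) / (d * sd + pseudocount))
        if mask_empty:
            v[(d == 0) & (l == 0)] = np.nan
        values[c] = v
    return RatioTrack(counts.fragmap, condition, values)


# ---------------------------------------------------------------------------
# windowed statistics


@dataclass
class BinnedTrack:
    """Fixed-step windows with a per-window value. ``value`` is NaN where a
    window contains no fragments."""

    frame: pd.DataFrame  # chrom, start, end, value, n_fragments
    window_bp: int
    step_bp: int

    def values(self, chrom: str) -> np.ndarray:
        return self.frame.loc[self.frame["chrom"] == chrom, "value"].to_numpy()


def _window_grid(L: int, window_bp: int, step_bp: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, L, step_bp, dtype=np.int64)
    ends = np.minimum(starts + window_bp, L)
    return starts, ends


def _window_sums(
    mids: np.ndarray, per_frag: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    cum = np.concatenate([[0.0], np.cumsum(per_frag)])
    i0 = np.searchsorted(mids, starts, side="left")
    i1 = np.searchsorted(mids, ends, side="left")
    return cum[i1] - cum[i0]


def running_mean(
    track: RatioTrack, window_bp: int = 100_000, step_bp: int = 10_000
) -> BinnedTrack:
    """Unweighted mean of fragment values whose midpoint falls in each
    running window (default 100 kb windows, 10 kb step)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if step_bp <= 0:
        raise ValueError("step_bp must be positive")
    rows = []
    for c in track.fragmap.chroms:
        L = track.fragmap.chrom_lengths[c]
        mids = track.fragmap.midpoints(c)
        v = track.values[c]
        finite = np.isfinite(v)
        starts, ends = _window_grid(L, window_bp, step_bp)
        s = _window_sums(mids, np.where(finite, v, 0.0), starts, ends)
        n = _window_sums(mids, finite.astype(float), starts, ends)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "start": starts,
                    "end": ends,
                    "value": mean,
                    "n_fragments": n.astype(np.int64),
                }
            )
        )
    return BinnedTrack(pd.concat(rows, ignore_index=True), window_bp, step_bp)


def running_ratio(
    counts: DamCounts,
    condition: str,
    window_bp: int = 100_000,
    step_bp: int = 10_000,
    pseudocount: float = 1.0,
    scale_libraries: bool = True,
) -> BinnedTrack:
    """Pooled-count windowed log ratio: counts are summed over each window
    before the ratio is formed. Unlike the mean of per-fragment ratios this
    is not shrunk toward 0 by the pseudocount at low coverage, so it
    recovers the true window-level fold change at any depth."""
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window and step must be positive")
    td, tl = counts.totals(condition)
    if td == 0 and tl == 0:
        raise ValueError(f"condition {condition}: both channels are all-zero")
    sd, sl = _scale_factors(td, tl, scale_libraries)
    rows = []
    for c in counts.fragmap.chroms:
        L = counts.fragmap.chrom_lengths[c]
        mids = counts.fragmap.midpoints(c)
        starts, ends = _window_grid(L, window_bp, step_bp)
        dw = _window_sums(mids, counts.dam[condition][c].astype(float), starts, ends)
        lw = _window_sums(mids, counts.lamin[condition][c].astype(float), starts, ends)
        n = _window_sums(mids, np.ones(len(mids)), starts, ends)
        value = np.log2((lw * sl + pseudocount) / (dw * sd + pseudocount))
        value[n == 0] = np.nan
        rows.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "start": starts,
                    "end": ends,
                    "value": value,
                    "n_fragments": n.astype(np.int64),
                }
            )
        )
    return BinnedTrack(pd.concat(rows, ignore_index=True), window_bp, step_bp)


# ---------------------------------------------------------------------------
# gene-level scores


@dataclass
class GeneDelta:
    """Windowed MT - MB lamin-association change around one gene."""

    gene_id: str
    delta: float
    mean_mt: float
    mean_mb: float
    window_mode: str
    n_fragments: int


def _window_mean(track: RatioTrack, chrom: str, lo: int, hi: int) -> tuple[float, int]:
    mids = track.fragmap.midpoints(chrom)
    v = track.values[chrom]
    i0, i1 = np.searchsorted(mids, [lo, hi], side="left")
    sel = v[i0:i1]
    sel = sel[np.isfinite(sel)]
    if len(sel) == 0:
        return np.nan, 0
    return float(sel.mean()), int(len(sel))


def gene_delta(
    track_mt: RatioTrack,
    track_mb: RatioTrack,
    gene: Mapping,
    window_mode: str = "flank_100kb",
    flank_bp: int = 50_000,
) -> GeneDelta:
    """MT mean minus MB mean of the log ratio around a gene.

    ``flank_100kb`` averages over the gene span extended symmetrically by
    ``flank_bp`` each side (100 kb added in total by default);
    ``gene_body`` averages over [start, end)."""
    if window_mode not in ("flank_100kb", "gene_body"):
        raise ValueError(f"unknown window_mode {window_mode!r}")
    chrom = gene["chrom"]
    if window_mode == "flank_100kb":
        lo = max(0, int(gene["start"]) - flank_bp)
        hi = int(gene["end"]) + flank_bp
    else:
        lo, hi = int(gene["start"]), int(gene["end"])
    m_mt, n_mt = _window_mean(track_mt, chrom, lo, hi)
    m_mb, n_mb = _window_mean(track_mb, chrom, lo, hi)
    n = min(n_mt, n_mb)
    if n == 0:
        log.warning("gene_delta: no fragments in window for %s", gene.get("gene_id"))
        delta = np.nan
    else:
        delta = m_mt - m_mb
    return GeneDelta(
        str(gene.get("gene_id", "")), delta, m_mt, m_mb, window_mode, n
    )


def gene_deltas(
    track_mt: RatioTrack,
    track_mb: RatioTrack,
    genes: pd.DataFrame,
    window_mode: str = "flank_100kb",
    flank_bp: int = 50_000,
) -> pd.DataFrame:
    out = [
        gene_delta(track_mt, track_mb, row, window_mode, flank_bp)
        for row in genes.to_dict("records")
    ]
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in out],
            "delta": [g.delta for g in out],
            "mean_mt": [g.mean_mt for g in out],
            "mean_mb": [g.mean_mb for g in out],
            "n_fragments": [g.n_fragments for g in out],
        }
    )
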