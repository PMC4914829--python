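"""Joining repositioning calls with expression calls.

Genes are assigned to IP/PI regions by gene-body overlap; direction
concordance (IP with repression, PI with activation) is tested on the 2x2
table with a plain chi-square (no continuity correction), effect-size
asymmetry with a two-sample KS test on |log2 FC|, and knockdown gene sets
are summarized by overlap fractions against the myogenic gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .domains import fisher_exact_p
from .intervals import overlap_matrix

log = logging.getLogger("lamshift")

__all__ = [
    "ConcordanceResult",
    "SetOverlapSummary",
    "assign_genes",
    "concordance_test",
    "magnitude_ks",
    "kd_overlap",
    "direction_counter",
    "chi2_2x2",
]


def assign_genes(genes: pd.DataFrame, shift_regions: pd.DataFrame) -> pd.DataFrame:
    """Gene -> IP/PI/none membership by >= 1 bp gene-body overlap.

    A gene overlapping regions of both directions goes to the larger
    overlap and is flagged ambiguous (exact ties also flagged). Returns a
    frame with gene_id, membership, overlap_bp, ambiguous.
    """
    for frame, cols in ((genes, ("start", "end")), (shift_regions, ("start", "end"))):
        if len(frame) and np.any(frame[cols[0]] >= frame[cols[1]]):
            raise ValueError("malformed intervals (start >= end)")
    membership = np.array(["none"] * len(genes), dtype=object)
    overlap_bp = np.zeros(len(genes), dtype=np.int64)
    ambiguous = np.zeros(len(genes), dtype=bool)
    genes = genes.reset_index(drop=True)
    for c, sub in genes.groupby("chrom", sort=False):
        reg = shift_regions[shift_regions["chrom"] == c] if len(shift_regions) else shift_regions
        if len(reg) == 0:
            continue
        ov = overlap_matrix(
            sub[["start", "end"]].to_numpy(), reg[["start", "end"]].to_numpy()
        )
        dirs = reg["direction"].to_numpy()
        per_dir = {
            d: ov[:, dirs == d].sum(axis=1) if (dirs == d).any() else np.zeros(len(sub))
            for d in ("IP", "PI")
        }
        best = np.where(per_dir["IP"] >= per_dir["PI"], "IP", "PI")
        best_ov = np.maximum(per_dir["IP"], per_dir["PI"])
        has = best_ov > 0
        membership[sub.index[has]] = best[has]
        overlap_bp[sub.index] = best_ov.astype(np.int64)
        ambiguous[sub.index] = (per_dir["IP"] > 0) & (per_dir["PI"] > 0)
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "membership": membership,
            "overlap_bp": overlap_bp,
            "ambiguous": ambiguous,
        }
    )


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction:
    n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, 1))


@dataclass
class ConcordanceResult:
    """Direction-of-repositioning x direction-of-expression 2x2 outcome."""

    table: np.ndarray  # rows IP, PI; cols down, up
    fraction_concordant: float
    chi2_stat: float
    chi2_p: float
    n: int
    test_used: str = "chi2"


def concordance_test(assignment: pd.DataFrame, de_calls: pd.DataFrame) -> ConcordanceResult:
    """Position-expression concordance among genes significant in both.

    Only genes with membership != none and call != nc enter. Concordant
    means (IP & down) or (PI & up). Chi-square is computed without
    continuity correction; if any expected cell is below 5 a Fisher's exact
    fallback is used with a warning.
    """
    merged = assignment.merge(de_calls[["gene_id", "call"]], on="gene_id")
    merged = merged[(merged["membership"] != "none") & (merged["call"] != "nc")]
    table = np.zeros((2, 2), dtype=np.int64)
    for i, m in enumerate(("IP", "PI")):
        for j, call in enumerate(("down", "up")):
            table[i, j] = int(
                ((merged["membership"] == m) & (merged["call"] == call)).sum()
            )
    n = int(table.sum())
    concordant = int(table[0, 0] + table[1, 1])
    frac = concordant / n if n else float("nan")
    if n == 0:
        return ConcordanceResult(table, frac, 0.0, 1.0, 0)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / n
    if (expected < 5).any():
        log.warning("concordance_test: expected cell < 5, Fisher fallback")
        p = fisher_exact_p(table)
        return ConcordanceResult(table, frac, np.nan, p, n, test_used="fisher")
    chi2, p = chi2_2x2(table)
    return ConcordanceResult(table, frac, chi2, p, n)


def magnitude_ks(
    concordant_absfc: np.ndarray, discordant_absfc: np.ndarray
) -> tuple[float, float]:
    """Two-sample KS on |log2 FC| of concordant vs discordant genes."""
    a = np.asarray(concordant_absfc, dtype=float)
    b = np.asarray(discordant_absfc, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass
class SetOverlapSummary:
    """Gene-set overlap bookkeeping for knockdown (KD) contrasts."""

    per_set: pd.DataFrame  # label, n, n_in_myogenic, frac_of_myogenic, frac_myogenic
    union_fraction: float
    union_n: int
    myogenic_n: int


def kd_overlap(
    de_sets: dict[str, set], myogenic_set: set, universe: set | None = None
) -> SetOverlapSummary:
    """Per-KD and combined fractions of the myogenic gene set affected."""
    if universe is not None:
        for label, s in list(de_sets.items()) + [("myogenic", myogenic_set)]:
            extra = set(s) - universe
            if extra:
                raise ValueError(f"{label}: genes outside universe: {sorted(extra)[:3]}")
    myo = set(myogenic_set)
    if not myo:
        raise ValueError("empty myogenic set")
    rows = []
    for label, s in de_sets.items():
        s = set(s)
        inter = s & myo
        rows.append(
            {
                "label": label,
                "n": len(s),
                "n_in_myogenic": len(inter),
                "frac_of_myogenic": len(inter) / len(myo),
                "frac_myogenic": len(inter) / len(s) if s else float("nan"),
            }
        )
    union = set().union(*de_sets.values()) if de_sets else set()
    union_inter = union & myo
    return SetOverlapSummary(
        pd.DataFrame(rows),
        union_fraction=len(union_inter) / len(myo),
        union_n=len(union_inter),
        myogenic_n=len(myo),
    )


def direction_counter(de_kd: pd.DataFrame, de_myogenic: pd.DataFrame) -> float:
    """Fraction of genes called in both contrasts whose KD change opposes
    the normal myogenic change (sign(KD) == -sign(myogenic))."""
    kd = de_kd[de_kd["call"] != "nc"][["gene_id", "log2fc"]]
    myo = de_myogenic[de_myogenic["call"] != "nc"][["gene_id", "log2fc"]]
    merged = kd.merge(myo, on="gene_id", suffixes=("_kd", "_myo"))
    if len(merged) == 0:
        raise ValueError("no genes called in both contrasts")
    opposed = np.sign(merged["log2fc_kd"]) == -np.sign(merged["log2fc_myo"])
    return float(opposed.mean())
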