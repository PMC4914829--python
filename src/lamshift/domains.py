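"""LAD segmentation, LAD-sharing statistics, and the differential
lamina-association (IP/PI) region caller.

IP regions gain lamin B1 contact from myoblast (MB) to myotube (MT)
(interior -> periphery, MT - MB delta > 0); PI regions lose it. The caller
follows the published recipe: mean MT - MB log2(LaminB1/Dam) differences
along a running 100-kb window, a 2-fold (|delta log2| >= 1) threshold,
significance by Fisher's exact test against randomized fragment samples
over 1,000 iterations, and rejection of regions with p > 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import intervals as ivl
from .damid import BinnedTrack, DamCounts, log2_ratio, running_ratio

log = logging.getLogger("lamshift")

__all__ = [
    "LADSet",
    "LADSharing",
    "call_lads",
    "lad_sharing",
    "candidate_shift_regions",
    "fisher_exact_p",
    "fisher_randomization_test",
    "call_shift_regions",
    "summarize_regions",
]


# ---------------------------------------------------------------------------
# LAD calling


@dataclass
class LADSet:
    """Called lamina-associated domains for one condition."""

    condition: str
    frame: pd.DataFrame  # chrom, start, end, mean_ratio
    chrom_lengths: dict[str, int]

    def intervals(self, chrom: str) -> np.ndarray:
        sub = self.frame[self.frame["chrom"] == chrom]
        return sub[["start", "end"]].to_numpy(dtype=np.int64).reshape(-1, 2)

    @property
    def total_bp(self) -> int:
        return int((self.frame["end"] - self.frame["start"]).sum())


def _hmm_lad_states(values: np.ndarray, lengths: list[int], random_state: int):
    """Two-state Gaussian HMM Viterbi labels (True = LAD state), or None if
    the fit is unusable (threshold-at-zero fallback applies)."""
    try:
        from hmmlearn.hmm import GaussianHMM

        model = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            n_iter=100,
            random_state=random_state,
        )
        X = values.reshape(-1, 1)
        model.fit(X, lengths)
        means = model.means_.ravel()
        if abs(means[0] - means[1]) < 0.2:
            return None, means
        states = model.predict(X, lengths)
        high = int(np.argmax(means))
        return states == high, means
    except Exception as exc:  # pragma: no cover - rare numerical failures
        log.warning("HMM fit failed (%s); falling back to threshold at 0", exc)
        return None, np.array([0.0, 0.0])


def call_lads(
    binned_track: BinnedTrack,
    min_lad_bp: int = 100_000,
    merge_gap_bp: int = 30_000,
    condition: str = "",
    random_state: int = 0,
) -> LADSet:
    """Two-state segmentation of a binned log-ratio track into LAD/non-LAD.

    A 2-state Gaussian HMM (Viterbi path) is fit on the defined bin means;
    the higher-mean state is LAD provided its mean is positive. If the HMM
    degenerates (states closer than 0.2 log2 units, or fit failure) the
    fallback labels bins with mean > 0 as LAD. Gaps shorter than
    ``merge_gap_bp`` are merged, LADs shorter than ``min_lad_bp`` dropped.
    """
    frame = binned_track.frame
    finite = np.isfinite(frame["value"].to_numpy())
    if not finite.any():
        raise ValueError("all-missing track")
    chroms = list(dict.fromkeys(frame["chrom"]))
    vals, lengths, index = [], [], []
    for c in chroms:
        sub = frame[frame["chrom"] == c]
        ok = np.isfinite(sub["value"].to_numpy())
        if ok.sum() == 0:
            continue
        vals.append(sub["value"].to_numpy()[ok])
        lengths.append(int(ok.sum()))
        index.append((c, sub.index.to_numpy()[ok]))
    values = np.concatenate(vals)

    lad_flag, means = (None, None)
    if values.min() < 0 < values.max():
        lad_flag, means = _hmm_lad_states(values, lengths, random_state)
    if lad_flag is None:
        lad_flag = values > 0.0
    elif max(means) <= 0:
        lad_flag = np.zeros(len(values), dtype=bool)

    rows = []
    off = 0
    for (c, idx), n in zip(index, lengths):
        flags = lad_flag[off : off + n]
        off += n
        sub = frame.loc[idx]
        iv = np.column_stack(
            [sub["start"].to_numpy()[flags], sub["end"].to_numpy()[flags]]
        )
        merged = ivl.merge(iv, gap=merge_gap_bp)
        for s, e in merged:
            if e - s < min_lad_bp:
                continue
            in_lad = (sub["start"].to_numpy() >= s) & (sub["end"].to_numpy() <= e)
            mean_ratio = float(np.nanmean(sub["value"].to_numpy()[in_lad])) if in_lad.any() else np.nan
            rows.append({"chrom": c, "start": int(s), "end": int(e), "mean_ratio": mean_ratio})
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_ratio"])
    lengths_by_chrom = (
        frame.groupby("chrom", sort=False)["end"].max().astype(int).to_dict()
    )
    return LADSet(condition, out, lengths_by_chrom)


@dataclass
class LADSharing:
    """Coverage decomposition of the union of two LAD sets."""

    shared_bp: int
    mb_only_bp: int
    mt_only_bp: int

    @property
    def union_bp(self) -> int:
        return self.shared_bp + self.mb_only_bp + self.mt_only_bp

    @property
    def shared_fraction(self) -> float:
        return self.shared_bp / self.union_bp if self.union_bp else float("nan")

    @property
    def fractions(self) -> tuple[float, float, float]:
        u = self.union_bp
        if u == 0:
            return (float("nan"),) * 3
        return (self.shared_bp / u, self.mb_only_bp / u, self.mt_only_bp / u)


def lad_sharing(lads_mb: LADSet, lads_mt: LADSet) -> LADSharing:
    """Interval-arithmetic shared / MB-only / MT-only coverage."""
    if set(lads_mb.chrom_lengths) != set(lads_mt.chrom_lengths):
        raise ValueError("mismatched chromosome names between LAD sets")
    shared = a_only = b_only = 0
    for c in lads_mb.chrom_lengths:
        a = lads_mb.intervals(c)
        b = lads_mt.intervals(c)
        inter = ivl.total_length(ivl.intersect(a, b))
        shared += inter
        a_only += ivl.total_length(a) - inter
        b_only += ivl.total_length(b) - inter
    return LADSharing(shared, a_only, b_only)


# ---------------------------------------------------------------------------
# candidate regions


def candidate_shift_regions(
    delta_binned_track: BinnedTrack, fold_threshold: float = 2.0
) -> pd.DataFrame:
    """Maximal consistent-sign runs of windows with |mean delta| >= log2(fold).

    Because running windows overlap, the extents of passing windows of one
    sign are unioned (merged where they touch), so a single noisy window
    inside a region does not split it. Returns chrom/start/end/direction.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    cut = np.log2(fold_threshold)
    frame = delta_binned_track.frame
    rows = []
    for c, sub in frame.groupby("chrom", sort=False):
        v = sub["value"].to_numpy()
        passing = np.isfinite(v) & (np.abs(v) >= cut)
        for sign, direction in ((1, "IP"), (-1, "PI")):
            sel = passing & (np.sign(v) == sign)
            if not sel.any():
                continue
            iv = np.column_stack(
                [sub["start"].to_numpy()[sel], sub["end"].to_numpy()[sel]]
            )
            for s, e in ivl.merge(iv):
                rows.append(
                    {"chrom": c, "start": int(s), "end": int(e), "direction": direction}
                )
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fisher randomization test


def _hypergeom_pmf(x: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """P(X = x) for X ~ Hypergeometric(N, K, n), vectorized over x."""
    x = np.asarray(x, dtype=np.int64)
    logp = (
        gammaln(K + 1)
        - gammaln(x + 1)
        - gammaln(K - x + 1)
        + gammaln(N - K + 1)
        - gammaln(n - x + 1)
        - gammaln(N - K - (n - x) + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return np.exp(logp)


def fisher_exact_p(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table by hypergeometric
    enumeration: sum of all outcome probabilities <= P(observed)."""
    (a, b), (c, d) = np.asarray(table, dtype=np.int64)
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    N = a + b + c + d
    if N == 0:
        return 1.0
    K = a + c  # column-1 total
    n1 = a + b  # row-1 total
    lo = max(0, K - (c + d))
    hi = min(n1, K)
    support = np.arange(lo, hi + 1)
    pmf = _hypergeom_pmf(support, N, K, n1)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def fisher_randomization_test(
    candidate_deltas: np.ndarray,
    pool_deltas: np.ndarray,
    direction: str,
    n_iter: int = 1000,
    seed: int = 0,
    delta_cut: float = 1.0,
    min_fragments: int = 10,
    aggregate: str = "median",
) -> float:
    """Empirical significance of a candidate region.

    Each iteration draws a random fragment set of the candidate's size from
    the genome-wide pool and forms the 2x2 table (fragments with
    sign-matching |delta| >= delta_cut vs not) x (candidate vs random set);
    two-sided Fisher's exact p is computed per table and the ``aggregate``
    (median by default, mean optional) over iterations is returned.
    Sampling fragment sets without replacement is realized exactly as a
    hypergeometric draw of the random set's pass count.
    """
    cand = np.asarray(candidate_deltas, dtype=float)
    pool = np.asarray(pool_deltas, dtype=float)
    n = len(cand)
    if n < min_fragments:
        raise ValueError(f"candidate has {n} fragments (< {min_fragments})")
    if len(pool) < n:
        raise ValueError("pool smaller than candidate")
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    sign = 1.0 if direction == "IP" else -1.0
    k_cand = int(np.sum(np.isfinite(cand) & (sign * cand >= delta_cut)))
    pool_pass = int(np.sum(np.isfinite(pool) & (sign * pool >= delta_cut)))
    rng = np.random.default_rng(seed)
    k_rand = rng.hypergeometric(pool_pass, len(pool) - pool_pass, n, size=n_iter)
    uniq, inv = np.unique(k_rand, return_inverse=True)
    p_uniq = np.array(
        [fisher_exact_p([[k_cand, n - k_cand], [int(k), n - int(k)]]) for k in uniq]
    )
    ps = p_uniq[inv]
    return float(np.median(ps) if aggregate == "median" else np.mean(ps))


# ---------------------------------------------------------------------------
# full caller


def _refine_candidate(
    sign: float,
    bin_starts: np.ndarray,
    bin_ends: np.ndarray,
    bin_delta: np.ndarray,
    lo: int,
    hi: int,
    cut: float,
    penalty_frac: float = 0.75,
) -> tuple[int, int] | None:
    """Refine a candidate span to the maximum-scoring run of fine bins.

    Score per bin is sign*delta - penalty_frac*cut; the best contiguous
    subarray within [lo, hi) localizes boundaries at bin rather than
    running-window resolution. The penalty is set above cut/2 (the balanced
    step-fit value) because fine-bin deltas are noisy at low coverage and a
    weaker penalty lets the span wander into the flanks."""
    sel = (bin_starts >= lo) & (bin_ends <= hi)
    if not sel.any():
        return None
    d = bin_delta[sel]
    score = np.where(np.isfinite(d), sign * d - penalty_frac * cut, 0.0)
    best, best_range = -np.inf, None
    cur, cur_start = 0.0, 0
    for i, s in enumerate(score):
        if cur <= 0:
            cur, cur_start = s, i
        else:
            cur += s
        if cur > best:
            best, best_range = cur, (cur_start, i + 1)
    if best_range is None or best <= 0:
        return None
    starts = bin_starts[sel]
    ends = bin_ends[sel]
    return int(starts[best_range[0]]), int(ends[best_range[1] - 1])


def _mle_boundaries(
    sign: float,
    bin_starts: np.ndarray,
    bin_ends: np.ndarray,
    bin_delta: np.ndarray,
    span_lo: int,
    span_hi: int,
    delta_core: float,
    window_bp: int,
) -> tuple[int, int]:
    """Maximum-likelihood boundary placement with an interior anchor.

    Given the region's core delta, each boundary is placed (within
    +/- window_bp of the current span edge) at the position maximizing the
    summed step-fit score sign*delta - delta_core/2 of the fine bins between
    the boundary and the span midpoint. With the far end anchored inside the
    region this has much lighter error tails than letting both ends of a
    max-subarray float."""
    lam = delta_core / 2.0
    mid = (span_lo + span_hi) // 2
    score = np.where(np.isfinite(bin_delta), sign * bin_delta - lam, 0.0)

    left = np.flatnonzero(
        (bin_starts >= span_lo - window_bp) & (bin_ends <= mid)
    )
    if len(left):
        suffix = np.cumsum(score[left][::-1])[::-1]
        new_lo = int(bin_starts[left[int(np.argmax(suffix))]])
    else:
        new_lo = span_lo
    right = np.flatnonzero(
        (bin_ends <= span_hi + window_bp) & (bin_starts >= mid)
    )
    if len(right):
        prefix = np.cumsum(score[right])
        new_hi = int(bin_ends[right[int(np.argmax(prefix))]])
    else:
        new_hi = span_hi
    if new_hi <= new_lo:
        return span_lo, span_hi
    return new_lo, new_hi


def _crossing_boundaries(
    sign: float,
    centers: np.ndarray,
    f: np.ndarray,
    span_lo: int,
    span_hi: int,
    delta_core: float,
    window_bp: int,
) -> tuple[int, int]:
    """Boundary placement at the half-height crossings of the centered
    running-window delta (a window centered on a step boundary averages
    half in-region, half flank). Walks outward from the span midpoint and
    tolerates dips shorter than 3 consecutive windows."""
    half = delta_core / 2.0
    g = sign * f
    mid = 0.5 * (span_lo + span_hi)
    inside = np.flatnonzero((centers >= span_lo) & (centers <= span_hi) & np.isfinite(f))
    if len(inside) == 0:
        return span_lo, span_hi
    i_mid = inside[np.argmin(np.abs(centers[inside] - mid))]
    if g[i_mid] < half:
        return span_lo, span_hi
    lo_limit, hi_limit = span_lo - window_bp, span_hi + window_bp

    def _walk(direction: int):
        i = i_mid
        below = 0
        first_below = None
        while True:
            nxt = i + direction
            if nxt < 0 or nxt >= len(g) or not (lo_limit <= centers[nxt] <= hi_limit):
                return None
            if np.isfinite(g[nxt]) and g[nxt] >= half:
                below, first_below = 0, None
            else:
                below += 1
                if first_below is None:
                    first_below = nxt
                if below >= 3:
                    return first_below
            i = nxt

    new_lo, new_hi = span_lo, span_hi
    stop = _walk(-1)
    if stop is not None:
        i = stop + 1
        if np.isfinite(g[stop]) and g[i] != g[stop]:
            frac = (g[i] - half) / (g[i] - g[stop])
            new_lo = int(round(centers[i] - frac * (centers[i] - centers[stop])))
        else:
            new_lo = int(centers[stop])
    stop = _walk(+1)
    if stop is not None:
        j = stop - 1
        if np.isfinite(g[stop]) and g[j] != g[stop]:
            frac = (g[j] - half) / (g[j] - g[stop])
            new_hi = int(round(centers[j] + frac * (centers[stop] - centers[j])))
        else:
            new_hi = int(centers[stop])
    if new_hi <= new_lo:
        return span_lo, span_hi
    return new_lo, new_hi


def _pooled_region_delta(
    counts: DamCounts,
    scales: dict[str, tuple[float, float]],
    chrom: str,
    lo: int,
    hi: int,
    pseudocount: float,
) -> tuple[float, int]:
    mids = counts.fragmap.midpoints(chrom)
    i0, i1 = np.searchsorted(mids, [lo, hi], side="left")
    if i1 <= i0:
        return np.nan, 0
    vals = {}
    for cond in ("MT", "MB"):
        sd, sl = scales[cond]
        dsum = counts.dam[cond][chrom][i0:i1].sum()
        lsum = counts.lamin[cond][chrom][i0:i1].sum()
        vals[cond] = np.log2((lsum * sl + pseudocount) / (dsum * sd + pseudocount))
    return float(vals["MT"] - vals["MB"]), int(i1 - i0)


def call_shift_regions(
    counts: DamCounts,
    window_bp: int = 100_000,
    step_bp: int = 10_000,
    fold_threshold: float = 2.0,
    n_iter: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    min_fragments: int = 10,
    pseudocount: float = 1.0,
    refine_bin_bp: int = 10_000,
    refine_penalty_frac: float = 0.6,
    aggregate: str = "median",
    bh_correct: bool = False,
    center_delta: bool = True,
) -> pd.DataFrame:
    """Full IP/PI caller: windowed MT - MB delta -> threshold candidates ->
    boundary refinement -> Fisher randomization test -> retain p <= alpha.

    Window and region deltas are pooled-count log ratios (robust at low
    coverage); the per-fragment deltas entering the Fisher pass criterion
    (sign-matching |delta| >= log2(fold_threshold)) come from the
    per-fragment ratio tracks. Returns a sorted frame of non-overlapping
    regions: chrom, start, end, direction, mean_delta, n_fragments,
    p_empirical.
    """
    fragmap = counts.fragmap
    cut = np.log2(fold_threshold)

    # per-fragment deltas for the Fisher pass criterion
    tr_mt = log2_ratio(counts, "MT", pseudocount)
    tr_mb = log2_ratio(counts, "MB", pseudocount)
    frag_delta = {c: tr_mt.values[c] - tr_mb.values[c] for c in fragmap.chroms}
    pool = np.concatenate([frag_delta[c] for c in fragmap.chroms])

    # pooled-count window deltas
    win_mt = running_ratio(counts, "MT", window_bp, step_bp, pseudocount)
    win_mb = running_ratio(counts, "MB", window_bp, step_bp, pseudocount)
    delta_vals = win_mt.frame["value"] - win_mb.frame["value"]
    # residual library-composition offset between the two conditions biases
    # IP vs PI sensitivity asymmetrically; the genome-wide median delta
    # (dominated by non-shifting territory) estimates and removes it
    offset = float(np.nanmedian(delta_vals)) if center_delta else 0.0
    delta_win = BinnedTrack(
        win_mt.frame.assign(value=delta_vals - offset), window_bp, step_bp
    )
    candidates = candidate_shift_regions(delta_win, fold_threshold)
    if offset != 0.0:
        frag_delta = {c: v - offset for c, v in frag_delta.items()}
        pool = pool - offset

    # fine bins for boundary refinement
    bin_mt = running_ratio(counts, "MT", refine_bin_bp, refine_bin_bp, pseudocount)
    bin_mb = running_ratio(counts, "MB", refine_bin_bp, refine_bin_bp, pseudocount)
    bins = bin_mt.frame.assign(
        value=bin_mt.frame["value"] - bin_mb.frame["value"] - offset
    )

    scales = {}
    for cond in ("MT", "MB"):
        td, tl = counts.totals(cond)
        target = 0.5 * (td + tl)
        scales[cond] = (target / td if td else 1.0, target / tl if tl else 1.0)

    # a transient noise dip can break the run of passing windows inside one
    # true region: bridge same-sign candidates closer than one window before
    # refinement, and merge refined spans that meet afterwards
    merged_cands = []
    if len(candidates):
        for (c, direction), sub in candidates.groupby(["chrom", "direction"], sort=False):
            for s, e in ivl.merge(sub[["start", "end"]].to_numpy(), gap=window_bp):
                merged_cands.append(
                    {"chrom": c, "start": int(s), "end": int(e), "direction": direction}
                )
    refined_spans = []
    for i, cand in enumerate(merged_cands):
        c = cand["chrom"]
        sub = bins[bins["chrom"] == c]
        sign = 1.0 if cand["direction"] == "IP" else -1.0
        lo = max(0, cand["start"] - window_bp)
        hi = min(fragmap.chrom_lengths[c], cand["end"] + window_bp)
        refined = _refine_candidate(
            sign,
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["value"].to_numpy(),
            lo,
            hi,
            cut,
            refine_penalty_frac,
        )
        if refined is None:
            continue
        refined_spans.append({**cand, "start": refined[0], "end": refined[1], "i": i})
    final_spans = []
    if refined_spans:
        rs = pd.DataFrame(refined_spans)
        for (c, direction), sub in rs.groupby(["chrom", "direction"], sort=False):
            for s, e in ivl.merge(sub[["start", "end"]].to_numpy(), gap=refine_bin_bp):
                final_spans.append(
                    {"chrom": c, "start": int(s), "end": int(e), "direction": direction}
                )
    final_spans.sort(key=lambda r: (r["chrom"], r["start"]))

    rows = []
    for i, cand in enumerate(final_spans):
        c = cand["chrom"]
        sign = 1.0 if cand["direction"] == "IP" else -1.0
        r_lo, r_hi = cand["start"], cand["end"]
        # core delta from the central half of the span (undiluted by any
        # boundary error), then snap boundaries to half-height crossings
        quarter = (r_hi - r_lo) // 4
        core_delta, _ = _pooled_region_delta(
            counts, scales, c, r_lo + quarter, r_hi - quarter, pseudocount
        )
        core_delta -= offset
        mag = sign * core_delta if np.isfinite(core_delta) else cut
        bsub = bins[bins["chrom"] == c]
        mle_lo, mle_hi = _mle_boundaries(
            sign,
            bsub["start"].to_numpy(),
            bsub["end"].to_numpy(),
            bsub["value"].to_numpy(),
            r_lo,
            r_hi,
            mag,
            window_bp,
        )
        wsub = delta_win.frame[delta_win.frame["chrom"] == c]
        centers = ((wsub["start"] + wsub["end"]) // 2).to_numpy()
        crs_lo, crs_hi = _crossing_boundaries(
            sign, centers, wsub["value"].to_numpy(), r_lo, r_hi, mag, window_bp
        )
        # three boundary estimators with distinct failure modes; the
        # per-boundary median is robust to any single one going astray
        r_lo = int(np.median([r_lo, mle_lo, crs_lo]))
        r_hi = int(np.median([r_hi, mle_hi, crs_hi]))
        mean_delta, n_frag = _pooled_region_delta(
            counts, scales, c, r_lo, r_hi, pseudocount
        )
        mean_delta -= offset
        if n_frag < min_fragments or not np.isfinite(mean_delta):
            continue
        if abs(mean_delta) < cut or np.sign(mean_delta) != sign:
            continue
        mids = fragmap.midpoints(c)
        i0, i1 = np.searchsorted(mids, [r_lo, r_hi], side="left")
        p = fisher_randomization_test(
            frag_delta[c][i0:i1],
            pool,
            cand["direction"],
            n_iter=n_iter,
            seed=seed + i,
            delta_cut=cut,
            min_fragments=min_fragments,
            aggregate=aggregate,
        )
        rows.append(
            {
                "chrom": c,
                "start": r_lo,
                "end": r_hi,
                "direction": cand["direction"],
                "mean_delta": mean_delta,
                "n_fragments": n_frag,
                "p_empirical": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "direction",
            "mean_delta",
            "n_fragments",
            "p_empirical",
        ],
    )
    if len(out):
        if bh_correct:
            from statsmodels.stats.multitest import multipletests

            out["p_adjusted"] = multipletests(out["p_empirical"], method="fdr_bh")[1]
            out = out[out["p_adjusted"] <= alpha]
        else:
            out = out[out["p_empirical"] <= alpha]
        out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
        out = _resolve_overlaps(out)
    return out.reset_index(drop=True)


def _resolve_overlaps(regions: pd.DataFrame) -> pd.DataFrame:
    """Called regions never overlap: same-direction overlaps are merged
    (keeping the stronger region's statistics), opposite-direction overlaps
    are trimmed at the boundary of the earlier region."""
    kept: list[dict] = []
    for row in regions.to_dict("records"):
        if kept and row["chrom"] == kept[-1]["chrom"] and row["start"] < kept[-1]["end"]:
            prev = kept[-1]
            if row["direction"] == prev["direction"]:
                prev["end"] = max(prev["end"], row["end"])
                if abs(row["mean_delta"]) > abs(prev["mean_delta"]):
                    for k in ("mean_delta", "p_empirical"):
                        prev[k] = row[k]
                prev["n_fragments"] += row["n_fragments"]
                continue
            row["start"] = prev["end"]
            if row["start"] >= row["end"]:
                continue
        kept.append(row)
    return pd.DataFrame(kept, columns=regions.columns)


def summarize_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-direction region count, mean/median span, and the number of
    distinct genes overlapping a region by >= 1 bp."""
    rows = []
    for direction in ("IP", "PI"):
        sub = regions[regions["direction"] == direction] if len(regions) else regions
        if len(sub) == 0:
            rows.append(
                {
                    "direction": direction,
                    "n_regions": 0,
                    "mean_size": 0.0,
                    "median_size": 0.0,
                    "n_genes": 0,
                }
            )
            continue
        sizes = (sub["end"] - sub["start"]).to_numpy()
        n_genes = 0
        for c, gsub in genes.groupby("chrom", sort=False):
            reg = sub[sub["chrom"] == c]
            if len(reg) == 0:
                continue
            ov = ivl.overlap_matrix(
                gsub[["start", "end"]].to_numpy(), reg[["start", "end"]].to_numpy()
            )
            n_genes += int((ov.max(axis=1) > 0).sum())
        rows.append(
            {
                "direction": direction,
                "n_regions": int(len(sub)),
                "mean_size": float(sizes.mean()),
                "median_size": float(np.median(sizes)),
                "n_genes": n_genes,
            }
        )
    return pd.DataFrame(rows)
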