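"""Synthetic data with planted ground truth.

Generates the four kinds of input the analysis consumes: a random genome,
a planted LAD/shift architecture, two-condition fragment-level DamID counts,
replicated expression matrices, and nucleus midplane images. Every planted
quantity (shared-LAD fraction, per-region delta, position-expression
concordance, radial spot position) is recorded so downstream modules can be
scored against truth.

All randomness flows from explicit integer seeds; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .damid import DamCounts, FragmentMap
from .intervals import merge, overlap_matrix, total_length

__all__ = [
    "GenomeModel",
    "PlantedArchitecture",
    "SimParams",
    "PlacementError",
    "make_genome",
    "plant_architecture",
    "simulate_damid_counts",
    "simulate_expression",
    "simulate_nucleus_image",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(ValueError):
    """Requested intervals do not fit in the genome."""


@dataclass
class GenomeModel:
    chrom_names: list[str]
    chrom_lengths: list[int]
    sequence: dict[str, str] | None = None

    def __post_init__(self):
        if any(L <= 0 for L in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.sequence is not None:
            for c, L in zip(self.chrom_names, self.chrom_lengths):
                if len(self.sequence[c]) != L:
                    raise ValueError(f"{c}: sequence length != declared length")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))


@dataclass
class PlantedArchitecture:
    """Planted truth: per-condition LAD interval sets, IP/PI shift regions
    with their log2 deltas, and per-gene membership.

    ``shift_truth`` columns: chrom, start, end, direction (IP/PI), delta.
    ``gene_truth`` columns: gene_id, chrom, start, end, membership,
    planted_log2fc (NaN until expression is simulated).
    """

    genome: GenomeModel
    lads_mb: dict[str, np.ndarray]
    lads_mt: dict[str, np.ndarray]
    shift_truth: pd.DataFrame
    gene_truth: pd.DataFrame

    def __post_init__(self):
        lengths = self.genome.lengths
        for lads in (self.lads_mb, self.lads_mt):
            for c, iv in lads.items():
                if len(iv) and (iv.min() < 0 or iv.max() > lengths[c]):
                    raise ValueError(f"{c}: LAD outside chromosome bounds")
        st = self.shift_truth
        if len(st):
            ip = st["direction"] == "IP"
            if not (st.loc[ip, "delta"] > 0).all():
                raise ValueError("IP regions must have delta > 0")
            if not (st.loc[~ip, "delta"] < 0).all():
                raise ValueError("PI regions must have delta < 0")

    def shared_lad_fraction(self) -> float:
        """Planted shared LAD coverage as a fraction of the union."""
        from .intervals import intersect

        shared = union = 0
        for c in self.genome.chrom_names:
            a = self.lads_mb.get(c, np.empty((0, 2), dtype=np.int64))
            b = self.lads_mt.get(c, np.empty((0, 2), dtype=np.int64))
            shared += total_length(intersect(a, b))
            union += total_length(np.vstack([a.reshape(-1, 2), b.reshape(-1, 2)]))
        return shared / union if union else float("nan")


@dataclass
class SimParams:
    """Generative settings for DamID counts and expression.

    depth: expected reads per fragment per channel (default 5; typical
      DamID genome coverage constrains this only loosely).
    dispersion: negative-binomial overdispersion (variance = m + a*m^2);
      0 gives the Poisson limit.
    lad_mu / interlad_mu: mean log2(LaminB1/Dam) inside / outside LADs.
    ratio_sd: fragment-level lognormal wobble of the lamin mean (log2 units).
    shift_delta: planted |MT - MB| log2 difference in shift regions.
    concordance: planted fraction of shift-region genes whose expression
      changes in the opposite direction to the repositioning (IP -> down).
    noise_sd: replicate noise SD on log2 intensities.
    n_replicates: samples per condition.
    """

    seed: int = 0
    depth: float = 5.0
    dispersion: float = 0.1
    lad_mu: float = 0.8
    interlad_mu: float = -0.8
    ratio_sd: float = 0.3
    shift_delta: float = 1.2
    concordance: float = 0.70
    noise_sd: float = 0.25
    n_replicates: int = 3

    def __post_init__(self):
        if not (0.0 <= self.concordance <= 1.0):
            raise ValueError("concordance must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


# ---------------------------------------------------------------------------
# genome


def make_genome(
    seed: int, n_chrom: int = 1, lengths: int | list[int] = 1_000_000
) -> GenomeModel:
    """Random i.i.d. uniform DNA; GATC occurs every ~256 bp in expectation."""
    if np.isscalar(lengths):
        lengths = [int(lengths)] * n_chrom
    lengths = [int(L) for L in lengths]
    if len(lengths) != n_chrom:
        raise ValueError("len(lengths) must equal n_chrom")
    if any(L <= 0 for L in lengths):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs = {}
    for name, L in zip(names, lengths):
        codes = rng.integers(0, 4, size=L, dtype=np.uint8)
        seqs[name] = _BASES[codes].tobytes().decode("ascii")
    return GenomeModel(names, lengths, seqs)


# ---------------------------------------------------------------------------
# architecture


class _Placer:
    """Places non-overlapping intervals into remaining free gaps, keeping a
    clearance margin around every placed interval."""

    def __init__(self, lengths: Mapping[str, int]):
        self.free: list[tuple[str, int, int]] = [(c, 0, L) for c, L in lengths.items()]

    def place(self, size: int, clearance: int, rng: np.random.Generator) -> tuple[str, int]:
        need = size + 2 * clearance
        fits = [i for i, (_, s, e) in enumerate(self.free) if e - s >= need]
        if not fits:
            raise PlacementError(f"no room for a {size} bp interval")
        # weight gaps by the number of admissible start positions
        w = np.array([self.free[i][2] - self.free[i][1] - need + 1 for i in fits], float)
        gi = fits[rng.choice(len(fits), p=w / w.sum())]
        chrom, gs, ge = self.free.pop(gi)
        start = gs + clearance + int(rng.integers(0, ge - gs - need + 1))
        end = start + size
        if start - clearance > gs:
            self.free.append((chrom, gs, start - clearance))
        if end + clearance < ge:
            self.free.append((chrom, end + clearance, ge))
        return chrom, start


def _default_lad_sizes(rng: np.random.Generator, n: int) -> np.ndarray:
    # log-normal, median ~450 kb, echoing observed LAD/region scales
    sizes = rng.lognormal(mean=np.log(450_000), sigma=0.5, size=n)
    return np.clip(sizes, 100_000, 2_000_000).astype(np.int64)


def plant_architecture(
    genome: GenomeModel,
    n_lads: int = 60,
    lad_size_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    shared_fraction: float = 0.94,
    n_ip: int = 20,
    n_pi: int = 20,
    size_range: tuple[int, int] = (300_000, 600_000),
    seed: int = 0,
    shift_delta: float = 1.2,
    n_genes: int = 2_000,
    gene_size_range: tuple[int, int] = (5_000, 50_000),
) -> PlantedArchitecture:
    """Plant a two-condition LAD architecture with IP/PI shift regions.

    Shared LADs are placed first; condition-unique LAD intervals are then
    added so the realized shared coverage fraction of the union equals
    ``shared_fraction`` exactly (up to 1 bp rounding), with the remainder
    split equally between MB-only and MT-only. Shift regions (IP: interior
    in MB, peripheral in MT; PI: the reverse) are planted in the remaining
    inter-LAD space, disjoint from LADs and from each other. Genes are
    placed uniformly; membership is by largest gene-body overlap.
    """
    if not (0.0 < shared_fraction <= 1.0):
        raise ValueError("shared_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    placer = _Placer(genome.lengths)
    size_fn = lad_size_dist or _default_lad_sizes

    # shift regions first: their sizes are pinned and their flanks must stay
    # clear, so they get the unfragmented genome
    shift_rows = []
    directions = ["IP"] * n_ip + ["PI"] * n_pi
    for direction in directions:
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        chrom, start = placer.place(size, 150_000, rng)
        shift_rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + size,
                "direction": direction,
                "delta": shift_delta if direction == "IP" else -shift_delta,
            }
        )

    lad_sizes = np.sort(size_fn(rng, n_lads))[::-1]  # big first packs better
    base: dict[str, list] = {c: [] for c in genome.chrom_names}
    for size in lad_sizes:
        chrom, start = placer.place(int(size), 50_000, rng)
        base[chrom].append((start, start + int(size)))

    shared_bp = int(lad_sizes.sum())
    extra_bp = shared_bp * (1.0 - shared_fraction) / (2.0 * shared_fraction)
    uniq = {"MB": {c: [] for c in genome.chrom_names},
            "MT": {c: [] for c in genome.chrom_names}}
    for cond in ("MB", "MT"):
        placed = 0
        while placed < int(round(extra_bp)):
            size = int(rng.integers(100_000, 300_001))
            size = min(size, int(round(extra_bp)) - placed)
            size = max(size, 1)
            chrom, start = placer.place(size, 50_000, rng)
            uniq[cond][chrom].append((start, start + size))
            placed += size
    shift_truth = pd.DataFrame(
        shift_rows, columns=["chrom", "start", "end", "direction", "delta"]
    )
    if len(shift_truth):
        shift_truth = shift_truth.sort_values(["chrom", "start"]).reset_index(drop=True)

    def _as_set(base_iv, extra_iv):
        out = {}
        for c in genome.chrom_names:
            iv = np.array(base_iv[c] + extra_iv[c], dtype=np.int64).reshape(-1, 2)
            out[c] = merge(iv)
        return out

    lads_mb = _as_set(base, uniq["MB"])
    lads_mt = _as_set(base, uniq["MT"])

    # genes: uniform placement, membership by largest overlap with a region
    lengths = genome.lengths
    probs = np.array([lengths[c] for c in genome.chrom_names], float)
    probs /= probs.sum()
    g_chrom = rng.choice(genome.chrom_names, size=n_genes, p=probs)
    g_size = rng.integers(gene_size_range[0], gene_size_range[1] + 1, size=n_genes)
    g_start = np.array(
        [rng.integers(0, lengths[c] - s) for c, s in zip(g_chrom, g_size)],
        dtype=np.int64,
    )
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "chrom": g_chrom,
            "start": g_start,
            "end": g_start + g_size,
        }
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    genes["membership"] = _truth_membership(genes, shift_truth)
    genes["planted_log2fc"] = np.nan
    return PlantedArchitecture(genome, lads_mb, lads_mt, shift_truth, genes)


def _truth_membership(genes: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    membership = np.array(["none"] * len(genes), dtype=object)
    if len(regions) == 0:
        return membership
    for c, sub in genes.groupby("chrom", sort=False):
        reg = regions[regions["chrom"] == c]
        if len(reg) == 0:
            continue
        ov = overlap_matrix(
            sub[["start", "end"]].to_numpy(), reg[["start", "end"]].to_numpy()
        )
        best = ov.argmax(axis=1)
        has = ov.max(axis=1) > 0
        membership[sub.index[has]] = reg["direction"].to_numpy()[best[has]]
    return membership


# ---------------------------------------------------------------------------
# DamID counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + a*m^2; Poisson when a == 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    # gamma-Poisson mixture
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def _in_intervals(pos: np.ndarray, iv: np.ndarray) -> np.ndarray:
    """Boolean membership of positions in a merged, sorted interval set."""
    iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return np.zeros(len(pos), dtype=bool)
    flat = iv.ravel()
    idx = np.searchsorted(flat, pos, side="right")
    return idx % 2 == 1


def simulate_damid_counts(
    arch: PlantedArchitecture, fragmap: FragmentMap, params: SimParams
) -> DamCounts:
    """Two channels x two conditions of per-fragment counts.

    Dam-only ~ NB(depth). LaminB1 ~ NB(depth * 2^(mu + eps)) with
    eps ~ N(0, ratio_sd) per fragment (shared between conditions so the
    planted MT - MB delta is exact in expectation). mu is lad_mu inside the
    condition's LADs, interlad_mu outside; inside a shift region the MB
    level is interlad_mu (IP) or lad_mu (PI) and MT = MB + delta.
    """
    if fragmap is None:
        raise ValueError("fragment map is required")
    rng = np.random.default_rng(params.seed)
    dam = {"MB": {}, "MT": {}}
    lamin = {"MB": {}, "MT": {}}
    st = arch.shift_truth
    for c in fragmap.chroms:
        mids = fragmap.midpoints(c)
        n = len(mids)
        mu_mb = np.where(
            _in_intervals(mids, arch.lads_mb.get(c, np.empty((0, 2)))),
            params.lad_mu,
            params.interlad_mu,
        )
        mu_mt = np.where(
            _in_intervals(mids, arch.lads_mt.get(c, np.empty((0, 2)))),
            params.lad_mu,
            params.interlad_mu,
        )
        reg = st[st["chrom"] == c] if len(st) else st
        for row in reg.itertuples():
            sel = (mids >= row.start) & (mids < row.end)
            base = params.interlad_mu if row.direction == "IP" else params.lad_mu
            mu_mb[sel] = base
            mu_mt[sel] = base + row.delta
        eps = rng.normal(0.0, params.ratio_sd, size=n)
        for cond, mu in (("MB", mu_mb), ("MT", mu_mt)):
            dam[cond][c] = _nb_draw(rng, np.full(n, params.depth), params.dispersion)
            lamin[cond][c] = _nb_draw(
                rng, params.depth * np.exp2(mu + eps), params.dispersion
            )
    return DamCounts(fragmap, dam, lamin)


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExprMatrix:
    """Replicated log2 intensities, genes x samples, plus a sample ->
    condition map."""

    data: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self):
        missing = [s for s in self.data.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")

    def samples(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]


def simulate_expression(
    genes: pd.DataFrame, arch: PlantedArchitecture, params: SimParams
) -> ExprMatrix:
    """Replicated MB/MT log2 intensities with planted fold changes.

    The concordant fraction is planted exactly: of the n genes in shift
    regions, round(concordance * n) change expression opposite to their
    repositioning direction (IP -> repressed, PI -> activated); which genes
    is randomized. Non-member genes get no planted effect. Effect sizes are
    |N(1.0, 0.3)| clipped to >= 0.3 log2 units; replicate noise is Gaussian.
    """
    if params.n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    if "membership" not in genes.columns:
        raise ValueError("every gene needs a membership (IP, PI, or none)")
    rng = np.random.default_rng(params.seed + 1)
    n = len(genes)
    lfc = np.zeros(n)
    member = genes["membership"].to_numpy()
    for direction, expected_sign in (("IP", -1.0), ("PI", +1.0)):
        idx = np.flatnonzero(member == direction)
        if len(idx) == 0:
            continue
        mag = np.clip(np.abs(rng.normal(1.0, 0.3, size=len(idx))), 0.3, None)
        n_conc = int(round(params.concordance * len(idx)))
        signs = np.full(len(idx), -expected_sign)
        signs[:n_conc] = expected_sign
        rng.shuffle(signs)
        lfc[idx] = signs * mag
    arch.gene_truth = arch.gene_truth.copy()
    if len(arch.gene_truth) == n and (
        arch.gene_truth["gene_id"].to_numpy() == genes["gene_id"].to_numpy()
    ).all():
        arch.gene_truth["planted_log2fc"] = lfc

    baseline = rng.normal(8.0, 2.0, size=n)
    cols = {}
    conditions = {}
    for cond, sign in (("MB", -0.5), ("MT", +0.5)):
        for r in range(params.n_replicates):
            name = f"{cond}_{r + 1}"
            cols[name] = baseline + sign * lfc + rng.normal(0, params.noise_sd, size=n)
            conditions[name] = cond
    data = pd.DataFrame(cols, index=genes["gene_id"].to_numpy())
    data.index.name = "gene_id"
    return ExprMatrix(data, conditions)


# ---------------------------------------------------------------------------
# nucleus images


def analytic_shell(radial_frac: float, n_shells: int = 5) -> int:
    """Equal-area shell of a point at a given radial fraction of a disk:
    shell 1 is peripheral, shell n central; boundaries at r*sqrt(k/n)."""
    if not (0.0 <= radial_frac <= 1.0):
        raise ValueError("radial fraction must be in [0, 1]")
    inner_area = radial_frac**2  # area fraction enclosed
    return int(n_shells - min(np.floor(inner_area * n_shells), n_shells - 1))


def simulate_nucleus_image(
    radius_px: int = 100,
    spot_radial_frac: float = 0.5,
    territory_profile: list[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    axis_ratio: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """One synthetic nucleus midplane: elliptical mask, a FISH spot at a
    controlled radial fraction, and a territory channel whose intensity per
    equal-area shell follows ``territory_profile`` (default uniform).

    Returns (mask, spot_channel, territory_channel, truth) where truth
    records the intended shell and spot position.
    """
    if not (0.0 <= spot_radial_frac <= 1.0):
        raise ValueError("spot_radial_frac must be in [0, 1]")
    if territory_profile is None:
        territory_profile = [0.2] * 5
    profile = np.asarray(territory_profile, dtype=float)
    if np.any(profile < 0) or profile.sum() <= 0:
        raise ValueError("territory_profile must be non-negative with mass")
    profile = profile / profile.sum()
    n_shells = len(profile)

    rng = np.random.default_rng(seed)
    a = radius_px  # semi-axis along columns
    b = max(1, int(round(radius_px * axis_ratio)))  # along rows
    pad = 5
    h, w = 2 * b + 2 * pad + 1, 2 * a + 2 * pad + 1
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    rho = np.sqrt(((yy - cy) / b) ** 2 + ((xx - cx) / a) ** 2)
    mask = rho <= 1.0

    # spot: gaussian blob centered at the requested radial fraction
    theta = rng.uniform(0, 2 * np.pi)
    sy = cy + spot_radial_frac * b * np.sin(theta)
    sx = cx + spot_radial_frac * a * np.cos(theta)
    spot = np.exp(-(((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * 2.0**2)))

    # territory: piecewise-constant intensity over analytic equal-area shells
    shell_of_px = np.clip(
        n_shells - np.floor(rho**2 * n_shells), 1, n_shells
    ).astype(int)
    areas = np.array(
        [np.sum(mask & (shell_of_px == k)) for k in range(1, n_shells + 1)], float
    )
    density = np.where(areas > 0, profile / np.maximum(areas, 1), 0.0)
    territory = np.zeros((h, w))
    territory[mask] = density[shell_of_px[mask] - 1]
    territory /= territory.max() if territory.max() > 0 else 1.0

    if noise_sd > 0:
        spot = np.clip(spot + rng.normal(0, noise_sd, spot.shape), 0, None)
        territory = np.clip(territory + rng.normal(0, noise_sd, territory.shape), 0, None)

    truth = {
        "shell": analytic_shell(spot_radial_frac, n_shells),
        "spot_rowcol": (sy, sx),
        "radial_frac": spot_radial_frac,
        "profile": profile.tolist(),
    }
    return mask, spot, territory, truth
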