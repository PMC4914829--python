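"""LAD calling, sharing arithmetic, and the IP/PI caller, checked against
planted truth and exhaustive hypergeometric enumeration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lamshift.damid import BinnedTrack, FragmentMap
from lamshift.domains import (
    LADSet,
    call_lads,
    call_shift_regions,
    candidate_shift_regions,
    fisher_exact_p,
    fisher_randomization_test,
    lad_sharing,
    summarize_regions,
)
from lamshift.synthetic import (
    SimParams,
    make_genome,
    plant_architecture,
    simulate_damid_counts,
)


def _binned(values, bin_bp=10_000, chrom="chr1"):
    n = len(values)
    starts = np.arange(n) * bin_bp
    frame = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + bin_bp,
            "value": values,
            "n_fragments": 10,
        }
    )
    return BinnedTrack(frame, bin_bp, bin_bp)


class TestCallLads:
    def test_step_signal_recovers_boundary(self):
        values = np.concatenate([np.full(50, 1.0), np.full(50, -1.0)])
        lads = call_lads(_binned(values))
        assert len(lads.frame) == 1
        row = lads.frame.iloc[0]
        assert row.start == 0
        assert abs(row.end - 500_000) <= 10_000
        assert row.mean_ratio > 0

    def test_all_negative_track_gives_empty_set(self):
        lads = call_lads(_binned(np.full(100, -0.5)))
        assert len(lads.frame) == 0

    def test_all_missing_track_rejected(self):
        with pytest.raises(ValueError):
            call_lads(_binned(np.full(20, np.nan)))

    def test_noisy_planted_lads_recovered(self, rng):
        # mu_in=0.8, mu_out=-0.8, sd=0.3 on 10 kb bins
        truth = np.zeros(1000, dtype=bool)
        for s in (100, 400, 700):
            truth[s : s + 60] = True
        values = np.where(truth, 0.8, -0.8) + rng.normal(0, 0.3, 1000)
        lads = call_lads(_binned(values))
        called = np.zeros(1000, dtype=bool)
        for row in lads.frame.itertuples():
            called[row.start // 10_000 : row.end // 10_000] = True
        recovered = (called & truth).sum() / truth.sum()
        assert recovered >= 0.95


class TestLadSharing:
    def _set(self, intervals, cond="MB"):
        frame = pd.DataFrame(
            [{"chrom": "chr1", "start": s, "end": e, "mean_ratio": 1.0} for s, e in intervals]
        )
        if not len(intervals):
            frame = pd.DataFrame(columns=["chrom", "start", "end", "mean_ratio"])
        return LADSet(cond, frame, {"chr1": 10_000_000})

    def test_identical_sets_share_everything(self):
        a = self._set([(0, 100), (500, 900)])
        assert lad_sharing(a, a).shared_fraction == 1.0

    def test_disjoint_sets_share_nothing(self):
        sh = lad_sharing(self._set([(0, 100)]), self._set([(200, 300)], "MT"))
        assert sh.shared_fraction == 0.0
        assert sh.mb_only_bp == 100 and sh.mt_only_bp == 100

    def test_fractions_sum_to_one(self):
        sh = lad_sharing(
            self._set([(0, 1000), (2000, 2500)]),
            self._set([(500, 1200), (3000, 3100)], "MT"),
        )
        assert sum(sh.fractions) == pytest.approx(1.0)

    def test_mismatched_chromosomes_rejected(self):
        a = self._set([(0, 100)])
        b = LADSet("MT", a.frame.assign(chrom="chrX"), {"chrX": 1_000_000})
        with pytest.raises(ValueError):
            lad_sharing(a, b)


class TestCandidates:
    def test_null_delta_yields_no_candidates(self):
        out = candidate_shift_regions(_binned(np.zeros(200)))
        assert len(out) == 0

    @pytest.mark.parametrize("sign,direction", [(1, "IP"), (-1, "PI")])
    def test_planted_block_recovered_with_direction(self, sign, direction):
        values = np.zeros(300)
        values[100:130] = sign * 1.2  # 300 kb block on 10 kb windows
        out = candidate_shift_regions(_binned(values))
        assert len(out) == 1
        row = out.iloc[0]
        assert row.direction == direction
        assert abs(row.start - 1_000_000) <= 10_000
        assert abs(row.end - 1_300_000) <= 10_000

    def test_threshold_at_one_rejected(self):
        with pytest.raises(ValueError):
            candidate_shift_regions(_binned(np.zeros(10)), fold_threshold=1.0)


class TestFisher:
    def scipy_oracle(self, table):
        return stats.fisher_exact(table, alternative="two-sided")[1]

    def test_frozen_example(self):
        assert fisher_exact_p([[8, 2], [2, 8]]) == pytest.approx(0.023, abs=5e-4)

    def test_matches_scipy_on_all_small_tables(self):
        # exhaustive: every 2x2 table with total <= 22
        for n in range(1, 23):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        table = [[a, b], [c, d]]
                        assert fisher_exact_p(table) == pytest.approx(
                            self.scipy_oracle(table), abs=1e-10
                        ), table

    def test_matches_scipy_on_random_tables_to_50(self, rng):
        for _ in range(500):
            t = rng.integers(0, 14, size=4)
            if t.sum() > 50 or t.sum() == 0:
                continue
            table = [[t[0], t[1]], [t[2], t[3]]]
            assert fisher_exact_p(table) == pytest.approx(
                self.scipy_oracle(table), abs=1e-10
            )

    def test_enriched_candidate_is_significant(self, rng):
        pool = rng.normal(0, 0.3, 20_000)
        cand = np.full(30, 1.5)  # every fragment passes
        p = fisher_randomization_test(cand, pool, "IP", n_iter=200, seed=1)
        assert p < 0.001

    def test_null_candidate_not_significant(self, rng):
        pool = rng.normal(0, 0.3, 20_000)
        hits = 0
        for seed in range(20):
            cand = pool[seed * 50 : seed * 50 + 50]
            p = fisher_randomization_test(cand, pool, "IP", n_iter=100, seed=seed)
            hits += p > 0.01
        assert hits >= 19  # type-I control in >= 95% of draws

    def test_pool_smaller_than_candidate_rejected(self):
        with pytest.raises(ValueError):
            fisher_randomization_test(np.ones(50), np.ones(10), "IP")

    def test_deterministic_under_seed(self, rng):
        pool = rng.normal(0, 0.5, 5000)
        cand = pool[:100] + 0.5
        a = fisher_randomization_test(cand, pool, "IP", n_iter=100, seed=3)
        b = fisher_randomization_test(cand, pool, "IP", n_iter=100, seed=3)
        assert a == b


@pytest.fixture(scope="module")
def shift_dataset():
    genome = make_genome(61, 3, 15_000_000)
    arch = plant_architecture(
        genome,
        n_lads=25,
        shared_fraction=1.0,
        n_ip=6,
        n_pi=6,
        size_range=(300_000, 600_000),
        seed=62,
        n_genes=400,
    )
    fragmap = FragmentMap.from_sequences(genome.sequence)
    counts = simulate_damid_counts(arch, fragmap, SimParams(seed=63, depth=0.5))
    return arch, counts


class TestCallShiftRegions:
    def test_planted_regions_recovered(self, shift_dataset):
        arch, counts = shift_dataset
        regs = call_shift_regions(counts, seed=64)
        truth = arch.shift_truth
        recovered = 0
        for t in truth.itertuples():
            m = regs[
                (regs.chrom == t.chrom)
                & (regs.direction == t.direction)
                & (regs.end > t.start)
                & (regs.start < t.end)
            ]
            if len(m) == 1:
                err = 0.5 * (
                    abs(m.iloc[0].start - t.start) + abs(m.iloc[0].end - t.end)
                )
                recovered += err < 50_000
        assert recovered >= int(0.8 * len(truth))

    def test_called_regions_pass_thresholds_and_are_disjoint(self, shift_dataset):
        _, counts = shift_dataset
        regs = call_shift_regions(counts, seed=64)
        assert (regs["p_empirical"] <= 0.01).all()
        assert (np.abs(regs["mean_delta"]) >= 1.0).all()
        ip = regs[regs.direction == "IP"]
        assert (ip["mean_delta"] > 0).all()
        for c, sub in regs.groupby("chrom"):
            srt = sub.sort_values("start")
            assert (srt["start"].to_numpy()[1:] >= srt["end"].to_numpy()[:-1]).all()

    def test_sign_symmetry_swaps_labels(self, shift_dataset):
        # exchanging the MB and MT labels must swap IP <-> PI exactly
        _, counts = shift_dataset
        from lamshift.damid import DamCounts

        swapped = DamCounts(
            counts.fragmap,
            {"MB": counts.dam["MT"], "MT": counts.dam["MB"]},
            {"MB": counts.lamin["MT"], "MT": counts.lamin["MB"]},
        )
        fwd = call_shift_regions(counts, seed=64)
        rev = call_shift_regions(swapped, seed=64)
        flip = {"IP": "PI", "PI": "IP"}
        assert sorted(fwd["direction"].map(flip)) == sorted(rev["direction"])

    def test_monotone_in_fold_threshold_and_alpha(self, shift_dataset):
        _, counts = shift_dataset
        base = call_shift_regions(counts, seed=64)
        stricter = call_shift_regions(counts, seed=64, fold_threshold=2.5)
        lower_alpha = call_shift_regions(counts, seed=64, alpha=0.001)
        assert len(stricter) <= len(base)
        assert len(lower_alpha) <= len(base)

    def test_subthreshold_shifts_not_called(self):
        genome = make_genome(71, 2, 8_000_000)
        arch = plant_architecture(
            genome,
            n_lads=8,
            shared_fraction=1.0,
            n_ip=2,
            n_pi=2,
            seed=72,
            shift_delta=0.8,  # below the 2-fold rule
            n_genes=50,
        )
        fragmap = FragmentMap.from_sequences(genome.sequence)
        counts = simulate_damid_counts(arch, fragmap, SimParams(seed=73, depth=0.5))
        regs = call_shift_regions(counts, seed=74)
        assert len(regs) <= 1  # planted 0.8 shifts must stay (almost) silent


class TestSummarize:
    def _regions(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 500_000],
                "end": [100_000, 800_000],
                "direction": ["IP", "IP"],
            }
        )

    def test_mean_size(self):
        genes = pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])
        out = summarize_regions(self._regions(), genes)
        ip = out[out.direction == "IP"].iloc[0]
        assert ip.n_regions == 2 and ip.mean_size == 200_000

    def test_gene_in_two_regions_counted_once(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "start": [50_000], "end": [600_000]}
        )
        out = summarize_regions(self._regions(), genes)
        assert out[out.direction == "IP"].iloc[0].n_genes == 1

    def test_empty_regions(self):
        genes = pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])
        out = summarize_regions(pd.DataFrame(columns=self._regions().columns), genes)
        assert (out.n_regions == 0).all()
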