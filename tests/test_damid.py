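"""Fragment map, counting and track operations against independent oracles
(direct motif scans, brute-force window recomputation, hand arithmetic)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamshift.damid import (
    DamCounts,
    FragmentMap,
    count_reads_to_fragments,
    digest_gatc,
    gene_delta,
    log2_ratio,
    running_mean,
    running_ratio,
)
from lamshift.synthetic import SimParams, simulate_damid_counts


def naive_gatc_fragments(seq):
    """Oracle: scan every position for the motif."""
    cuts = [i for i in range(len(seq) - 3) if seq[i : i + 4] == "GATC" and i > 0]
    b = [0] + cuts + [len(seq)]
    return list(zip(b[:-1], b[1:]))


class TestDigest:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGATCCGATCG", [(0, 1), (1, 6), (6, 11)]),
            ("AAAA", [(0, 4)]),  # no cut sites: single fragment
            ("GATCGATC", [(0, 4), (4, 8)]),  # motif at 0 adds no boundary
        ],
    )
    def test_frozen_examples(self, seq, expected):
        fm = digest_gatc(seq)
        got = list(zip(fm.starts("chr1"), fm.ends("chr1")))
        assert got == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            digest_gatc("")

    def test_n_runs_do_not_match(self):
        fm = digest_gatc("AAGANCNNNTCAA")
        assert fm.n_fragments("chr1") == 1

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=300))
    @settings(max_examples=200, deadline=None)
    def test_matches_position_scan_oracle(self, seq):
        fm = digest_gatc(seq)
        got = list(zip(fm.starts("chr1"), fm.ends("chr1")))
        assert got == naive_gatc_fragments(seq.upper())

    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    @settings(max_examples=100, deadline=None)
    def test_fragments_tile_exactly(self, seq):
        fm = digest_gatc(seq)
        s, e = fm.starts("chr1"), fm.ends("chr1")
        assert s[0] == 0 and e[-1] == len(seq)
        assert np.array_equal(s[1:], e[:-1])


class TestCountReads:
    def fragmap(self):
        return digest_gatc("A" * 50 + "GATC" + "A" * 50 + "GATC" + "A" * 20)

    def test_reads_in_one_fragment(self):
        fm = self.fragmap()
        reads = {("MB", "dam"): pd.DataFrame({"chrom": "chr1", "start": [5, 10, 40]})}
        counts = count_reads_to_fragments(reads, fm)
        assert counts.dam["MB"]["chr1"].tolist() == [3, 0, 0]

    def test_boundary_read_goes_to_fragment_starting_there(self):
        fm = self.fragmap()
        reads = {("MB", "dam"): pd.DataFrame({"chrom": "chr1", "start": [50]})}
        counts = count_reads_to_fragments(reads, fm)
        assert counts.dam["MB"]["chr1"].tolist() == [0, 1, 0]

    def test_total_conservation_and_oob_skipping(self, rng):
        fm = self.fragmap()
        starts = rng.integers(-20, 150, size=10_000)
        reads = {("MT", "lamin"): pd.DataFrame({"chrom": "chr1", "start": starts})}
        counts = count_reads_to_fragments(reads, fm)
        retained = ((starts >= 0) & (starts < 128)).sum()
        assert counts.lamin["MT"]["chr1"].sum() == retained


def _counts_1chrom(dam, lamin, cond="MB"):
    n = len(dam)
    fm = FragmentMap({"chr1": np.arange(0, 10 * (n + 1), 10)})
    z = {c: {"chr1": np.zeros(n, dtype=np.int64)} for c in (cond,)}
    return DamCounts(
        fm,
        {cond: {"chr1": np.asarray(dam, dtype=np.int64)}},
        {cond: {"chr1": np.asarray(lamin, dtype=np.int64)}},
    )


class TestLog2Ratio:
    def test_equal_counts_give_zero(self):
        counts = _counts_1chrom([10], [10])
        track = log2_ratio(counts, "MB", pseudocount=1.0)
        assert track.values["chr1"][0] == 0.0

    def test_hand_arithmetic(self):
        # equal library totals: scale factors cancel -> log2(31/11)
        counts = _counts_1chrom([10, 30], [30, 10])
        track = log2_ratio(counts, "MB", pseudocount=1.0)
        assert track.values["chr1"][0] == pytest.approx(np.log2(31 / 11))

    def test_empty_fragment_floors_at_zero(self):
        counts = _counts_1chrom([0, 5], [0, 5])
        track = log2_ratio(counts, "MB")
        assert track.values["chr1"][0] == 0.0

    def test_all_zero_rejected(self):
        counts = _counts_1chrom([0, 0], [0, 0])
        with pytest.raises(ValueError):
            log2_ratio(counts, "MB")

    def test_antisymmetric_under_channel_swap(self, rng):
        dam = rng.integers(0, 20, 50)
        lam = rng.integers(0, 20, 50)
        a = log2_ratio(_counts_1chrom(dam, lam), "MB").values["chr1"]
        b = log2_ratio(_counts_1chrom(lam, dam), "MB").values["chr1"]
        np.testing.assert_allclose(a, -b, atol=1e-12)


class TestRunningMean:
    def brute_force(self, fm, values, window, step):
        """Oracle: fragment-by-fragment recomputation."""
        out = []
        L = fm.chrom_lengths["chr1"]
        mids = fm.midpoints("chr1")
        for ws in range(0, L, step):
            we = min(ws + window, L)
            sel = (mids >= ws) & (mids < we)
            out.append(values[sel].mean() if sel.any() else np.nan)
        return np.array(out)

    def test_constant_track(self, small_fragmap):
        from lamshift.damid import RatioTrack

        track = RatioTrack(
            small_fragmap,
            "MB",
            {c: np.ones(small_fragmap.n_fragments(c)) for c in small_fragmap.chroms},
        )
        out = running_mean(track)
        assert np.allclose(out.frame["value"].dropna(), 1.0)

    def test_matches_brute_force_oracle(self, rng):
        fm = FragmentMap({"chr1": np.sort(np.unique(np.concatenate(
            [[0, 1_000_000], rng.integers(1, 1_000_000, 4000)])))})
        from lamshift.damid import RatioTrack

        values = rng.normal(size=fm.n_fragments("chr1"))
        track = RatioTrack(fm, "MB", {"chr1": values})
        out = running_mean(track, 100_000, 10_000)
        expected = self.brute_force(fm, values, 100_000, 10_000)
        got = out.frame["value"].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-9, equal_nan=True)

    def test_bad_window_rejected(self, small_fragmap):
        from lamshift.damid import RatioTrack

        track = RatioTrack(
            small_fragmap,
            "MB",
            {c: np.ones(small_fragmap.n_fragments(c)) for c in small_fragmap.chroms},
        )
        with pytest.raises(ValueError):
            running_mean(track, window_bp=0)


class TestRunningRatio:
    def test_pooled_ratio_unshrunk_at_low_depth(self, small_arch, small_fragmap):
        # per-fragment ratio means are pseudocount-shrunk at depth 0.5;
        # the pooled window ratio is not
        p = SimParams(seed=40, depth=0.5, ratio_sd=0.0, dispersion=0.0)
        counts = simulate_damid_counts(small_arch, small_fragmap, p)
        pooled = running_ratio(counts, "MB", 100_000, 100_000, scale_libraries=False)
        c = small_fragmap.chroms[0]
        flat = small_arch.lads_mb[c].ravel()
        sub = pooled.frame[pooled.frame.chrom == c]
        centers = ((sub.start + sub.end) // 2).to_numpy()
        in_lad = np.searchsorted(flat, centers, side="right") % 2 == 1
        full_lad = in_lad & (np.searchsorted(flat, sub.start.to_numpy(), side="right") % 2 == 1) \
            & (np.searchsorted(flat, sub.end.to_numpy() - 1, side="right") % 2 == 1)
        vals = sub["value"].to_numpy()[full_lad]
        assert abs(np.nanmean(vals) - p.lad_mu) < 0.1


class TestGeneDelta:
    def _tracks(self, fm, v_mt, v_mb):
        from lamshift.damid import RatioTrack

        mk = lambda v: {c: np.full(fm.n_fragments(c), v) for c in fm.chroms}
        return (
            RatioTrack(fm, "MT", mk(v_mt)),
            RatioTrack(fm, "MB", mk(v_mb)),
        )

    def test_constant_tracks(self, small_fragmap):
        mt, mb = self._tracks(small_fragmap, 1.0, 0.0)
        gene = {"gene_id": "g", "chrom": "chr1", "start": 100_000, "end": 150_000}
        assert gene_delta(mt, mb, gene).delta == pytest.approx(1.0)
        assert gene_delta(mt, mt, gene).delta == pytest.approx(0.0)

    def test_gene_body_vs_flank_windows(self, small_fragmap):
        mt, mb = self._tracks(small_fragmap, 0.5, 0.0)
        gene = {"gene_id": "g", "chrom": "chr1", "start": 200_000, "end": 260_000}
        gb = gene_delta(mt, mb, gene, window_mode="gene_body")
        fl = gene_delta(mt, mb, gene, window_mode="flank_100kb")
        assert gb.delta == pytest.approx(0.5)
        assert fl.n_fragments > gb.n_fragments

    def test_recovers_planted_shift_at_high_depth(self, small_arch, small_fragmap):
        p = SimParams(seed=41, depth=200.0)
        counts = simulate_damid_counts(small_arch, small_fragmap, p)
        mt = log2_ratio(counts, "MT")
        mb = log2_ratio(counts, "MB")
        region = small_arch.shift_truth.iloc[0]
        span = region.end - region.start
        gene = {
            "gene_id": "g",
            "chrom": region.chrom,
            "start": region.start + span // 2 - 30_000,
            "end": region.start + span // 2 + 30_000,
        }
        gd = gene_delta(mt, mb, gene)
        assert gd.delta == pytest.approx(region.delta, abs=0.1)

    def test_unknown_mode_rejected(self, small_fragmap):
        mt, mb = self._tracks(small_fragmap, 1.0, 0.0)
        with pytest.raises(ValueError):
            gene_delta(mt, mb, {"chrom": "chr1", "start": 0, "end": 10}, "nope")
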