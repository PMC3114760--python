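"""Homopolymer detection, indel-repeat relations, repeat-density bins."""

import re

import numpy as np
import pytest

import indelflank as f
from indelflank import (AlignedRegionPair, bin_windows_by_repeats,
                        classify_indel_repeat_relation, find_homopolymers,
                        repeat_position_histogram)
from indelflank.repeats import compare_bins, indel_reference_interval


class TestFindHomopolymers:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAAT", [("A", 0, 4)]),
        ("AAATAAAA", [("A", 4, 8)]),
        ("", []),
        ("ACGT", []),
        ("AAAANAAAA", [("A", 0, 4), ("A", 5, 9)]),  # N breaks runs
        ("TTTTT", [("T", 0, 5)]),
    ])
    def test_examples(self, seq, expected):
        runs = [(r.base, r.start, r.end) for r in find_homopolymers(seq)]
        assert runs == expected

    def test_against_regex_oracle(self, rng):
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGTN"), size=500,
                                     p=[0.3, 0.2, 0.2, 0.28, 0.02]))
            expected = [(m.group()[0], m.start(), m.end())
                        for m in re.finditer(r"(A+|C+|G+|T+)", seq)
                        if m.end() - m.start() >= 4]
            got = [(r.base, r.start, r.end) for r in find_homopolymers(seq)]
            assert got == expected

    def test_min_len_parameter(self):
        assert find_homopolymers("AAA", min_len=3)[0].length == 3
        assert find_homopolymers("AAA", min_len=4) == []


class TestRelation:
    RUNS = find_homopolymers("TTGCAAAAGCTT" + "G" * 20, min_len=4)  # A-run at 4..8

    def test_indel_inside_run_contiguous(self):
        assert classify_indel_repeat_relation((6, 7), self.RUNS) == "contiguous"

    def test_indel_adjacent_to_run_contiguous(self):
        assert classify_indel_repeat_relation((8, 9), self.RUNS) == "contiguous"
        assert classify_indel_repeat_relation((3, 4), self.RUNS) == "contiguous"

    def test_run_within_five_proximal(self):
        assert classify_indel_repeat_relation((10, 11), self.RUNS) == "proximal"

    def test_run_beyond_five_none(self):
        runs = find_homopolymers("AAAA" + "CGT" * 10)
        assert classify_indel_repeat_relation((10, 11), runs) == "none"

    def test_every_indel_classified_once(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        runs = find_homopolymers(seq)
        cats = [classify_indel_repeat_relation((p, p + 1), runs)
                for p in rng.integers(0, 1999, size=300)]
        assert set(cats) <= {"contiguous", "proximal", "none"}
        assert len(cats) == 300

    def test_null_contiguous_fraction_matches_coverage_oracle(self, rng):
        """With indels placed uniformly, the contiguous fraction must match
        the permutation expectation from repeat coverage."""
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        runs = find_homopolymers(seq)
        # oracle: exhaustively classify every possible 1-bp indel position
        all_cats = np.array([classify_indel_repeat_relation((p, p + 1), runs)
                             == "contiguous" for p in range(len(seq) - 1)])
        expected = all_cats.mean()
        n = 3000
        pos = rng.integers(0, len(seq) - 1, size=n)
        frac = np.mean([classify_indel_repeat_relation((p, p + 1), runs)
                        == "contiguous" for p in pos])
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * sd


class TestHistogram:
    def test_run_scored_at_termination(self):
        # run of four A's occupying positions -5..-1 relative to the indel
        seq = ("ACG" * 12)[:35] + "AAAA" + ("TCG" * 10)[:25]  # indel site at 39
        runs = find_homopolymers(seq)
        assert [(r.base, r.start, r.end) for r in runs] == [("A", 35, 39)]
        offsets, counts, skipped = repeat_position_histogram(
            [(39, 40)], [runs], [len(seq)])
        assert skipped == 0
        assert counts[list(offsets).index(-1)] == 1
        assert counts.sum() == 1

    def test_no_runs_all_zero(self):
        offsets, counts, _ = repeat_position_histogram([(30, 31)], [[]], [100])
        assert counts.sum() == 0

    def test_truncated_flank_skipped(self):
        _, counts, skipped = repeat_position_histogram([(5, 6)], [[]], [100])
        assert skipped == 1

    def test_total_conserved(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        runs = find_homopolymers(seq)
        intervals = [(int(p), int(p) + 1)
                     for p in rng.integers(100, 4900, size=50)]
        offsets, counts, _ = repeat_position_histogram(
            intervals, [runs] * 50, [len(seq)] * 50)
        expected = 0
        for a, b in intervals:
            for r in runs:
                term = r.end - 1
                rel = term - a if term < a else (term - b + 1 if term >= b else 0)
                expected += -20 <= rel <= 20
        assert counts.sum() == expected

    def test_simulated_indels_at_repeats_concentrate_near_zero(self):
        cfg = f.SimConfig(length=2101, repeat_spec=(("A", 6, 1),),
                          divergence_per_branch=0.002, seed=1)
        rs = f.simulate_region_set(cfg, 200, seed=2)
        intervals, runs_list, lens = [], [], []
        for reg in rs.regions:
            (ev,) = f.find_indels(reg)
            ref_row = 1 if 0 in ev.gapped_rows else 0
            seq = reg.rows[ref_row].replace("-", "")
            intervals.append(indel_reference_interval(reg, ev, ref_row))
            runs_list.append(find_homopolymers(seq))
            lens.append(len(seq))
        offsets, counts, _ = repeat_position_histogram(intervals, runs_list, lens)
        # every indel is planted in a 6-bp tract, so the tract's termination
        # scores within a few bases of the indel; far bins carry only
        # background runs
        near_mask = np.abs(offsets) <= 4
        near = counts[near_mask].sum()
        near_per_bin = near / near_mask.sum()
        far_mean = counts[np.abs(offsets) >= 10].mean()
        assert near >= 0.9 * len(rs.regions)
        assert near_per_bin > 3 * max(far_mean, 0.5)


def _aln_with_runs():
    """300-bp pair: window 0 has AAAA+TTTT, window 1 clean, window 2 gap."""
    rng = np.random.default_rng(9)
    base = list("".join(rng.choice(list("ACGT"), size=300)))
    # scrub accidental runs, then plant
    for i in range(0, 297):
        if base[i] == base[i + 1] == base[i + 2]:
            base[i + 2] = "ACGT"[("ACGT".index(base[i + 2]) + 1) % 4]
    base[10:14] = list("AAAA")
    base[40:44] = list("TTTT")
    r0 = base.copy()
    r1 = base.copy()
    r1[250] = "-"
    return AlignedRegionPair(region_id="r", rows=["".join(r0), "".join(r1)])


class TestBins:
    def test_window_repeat_counts(self):
        reg = _aln_with_runs()
        bins = bin_windows_by_repeats(reg, width=100, exclude_indel_windows=True)
        by_k = {b.k: b for b in bins}
        assert by_k[2].n_windows == 1       # the AAAA+TTTT window
        assert by_k[0].n_windows == 1       # the clean window
        assert sum(b.n_windows for b in bins) == 2  # gap window excluded

    def test_interrupted_run_not_counted(self):
        reg = _aln_with_runs()
        rows = [list(r) for r in reg.rows]
        rows[1][11] = "G"  # break AAAA in the partner row
        reg2 = AlignedRegionPair(region_id="r2",
                                 rows=["".join(r) for r in rows])
        bins = bin_windows_by_repeats(reg2, width=100)
        ks = sorted(b.k for b in bins for _ in range(b.n_windows))
        assert 2 not in ks
        assert 1 in ks  # TTTT still intact

    def test_monotone_d_in_repeat_density(self):
        """Simulated region effect: windows holding rate-elevated repeat
        tracts diverge more than repeat-free windows.

        Tracts of 6 bp are implanted and binning uses min_len=6 so that
        the counted runs are overwhelmingly the implanted (elevated)
        ones rather than chance 4-mers of the random background.
        """
        cfg = f.SimConfig(length=100_000, repeat_spec=(("A", 6, 60),),
                          region_multiplier=3.0, region_radius=50,
                          divergence_per_branch=0.01, seed=3)
        from indelflank.sim import generate_ancestor

        anc = generate_ancestor(cfg)
        reg, _ = f.evolve_lineages(anc, cfg, f.pair_topology(0.01), seed=4)
        bins = bin_windows_by_repeats(reg, width=100, min_len=6)
        by_k = {b.k: b for b in bins if b.n_windows >= 20}
        ks = sorted(by_k)
        assert len(ks) >= 2
        assert by_k[ks[-1]].d > by_k[0].d
        pvals = compare_bins([by_k[k] for k in ks])
        assert pvals[ks[-1]] < 0.05
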