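"""Alignment ingestion, orthology filters, and indel calling."""

import itertools

import numpy as np
import pytest

from indelflank import (AlignedRegionPair, AlignmentFormatError, dedupe_indels,
                        filter_orthologous, find_indels, load_alignments,
                        write_alignments)


def test_region_rejects_ragged_rows():
    with pytest.raises(AlignmentFormatError, match="ragged"):
        AlignedRegionPair(region_id="r", rows=["ACGT", "ACG"])


def test_region_rejects_all_gap_column():
    reg = AlignedRegionPair(region_id="r", rows=["AC-T", "AG-T"])
    with pytest.raises(AlignmentFormatError, match="gapped in every row"):
        _ = reg.codes


def test_quartet_rows_accepted():
    reg = AlignedRegionPair(region_id="r", rows=["ACGT"] * 4)
    assert reg.codes.shape == (4, 4)


def test_percent_identity_over_nongap_columns():
    # 1 mismatch in 3 comparable columns; the gap column is excluded
    reg = AlignedRegionPair(region_id="r", rows=["ACG-T", "ACTAT"])
    assert reg.percent_identity() == pytest.approx(100 * 3 / 4)


def test_roundtrip_fasta(tmp_path):
    regs = [
        AlignedRegionPair(region_id="regA", rows=["ACGT-ACG", "ACGTTACG"],
                          ids=["s1", "s2"],
                          coords=[("chr1", 100, 107), ("chr2", 0, 8)]),
        AlignedRegionPair(region_id="regB", rows=["AAAA", "AAAT", "AATT"]),
    ]
    path = tmp_path / "aln.fasta"
    write_alignments(regs, path)
    back = load_alignments(path)
    assert [r.region_id for r in back] == ["regA", "regB"]
    assert back[0].rows == regs[0].rows
    assert back[0].coords[0] == ("chr1", 100, 107)
    assert len(back[1].rows) == 3


def test_load_plain_headers_one_region_per_file(tmp_path):
    path = tmp_path / "plain.fasta"
    path.write_text(">s1\nACGT-ACG\n>s2\nACGTTACG\n")
    regs = load_alignments(path)
    assert len(regs) == 1
    assert len(regs[0].rows) == 2
    assert regs[0].region_id == "plain"


class TestFindIndels:
    def test_single_gap(self):
        reg = AlignedRegionPair(region_id="r", rows=["ACGT-ACG", "ACGTTACG"])
        (ev,) = find_indels(reg)
        assert (ev.start, ev.end, ev.length, ev.gapped_row) == (4, 5, 1, 0)
        assert (ev.anchor_left, ev.anchor_right) == (3, 5)
        assert not ev.ambiguous

    def test_adjacent_gaps_merge_into_one_run(self):
        reg = AlignedRegionPair(region_id="r", rows=["AC--GT", "ACTTGT"])
        events = find_indels(reg)
        assert len(events) == 1
        assert events[0].length == 2

    def test_identical_span_in_two_rows_is_one_ambiguous_event(self):
        reg = AlignedRegionPair(region_id="r",
                                rows=["AC--GT", "AC--GT", "ACTTGT"])
        (ev,) = find_indels(reg)
        assert ev.ambiguous
        assert ev.gapped_rows == (0, 1)

    def test_planted_runs_recovered_exactly(self, rng):
        # plant 100 separated gap runs into a random pair; recovery must be exact
        n, spacing = 100, 30
        length = n * spacing + 200
        base = "".join(rng.choice(list("ACGT"), size=length))
        rows = [list(base), list(base)]
        truth = []
        for i in range(n):
            start = 10 + i * spacing
            glen = int(rng.integers(1, 6))
            row = int(rng.integers(2))
            for c in range(start, start + glen):
                rows[row][c] = "-"
            truth.append((start, start + glen, row))
        reg = AlignedRegionPair(region_id="r",
                                rows=["".join(r) for r in rows])
        found = sorted((e.start, e.end, e.gapped_row) for e in find_indels(reg))
        assert found == sorted(truth)


class TestFilters:
    @staticmethod
    def _region(length, ident=1.0, rid="r", coords=None):
        a = "A" * length
        n_mismatch = round(length * (1 - ident))
        b = "C" * n_mismatch + "A" * (length - n_mismatch)
        return AlignedRegionPair(region_id=rid, rows=[a, b], coords=coords)

    def test_length_boundary_inclusive(self):
        short = self._region(2999)
        exact = self._region(3000)
        assert filter_orthologous([short, exact]) == [exact]

    def test_identity_boundary_inclusive(self):
        low = self._region(4000, ident=0.799, rid="low")
        edge = self._region(4000, ident=0.800, rid="edge")
        kept = filter_orthologous([low, edge])
        assert [r.region_id for r in kept] == ["edge"]

    def test_multiply_hit_spans_removed(self):
        regs = [self._region(3000, rid=f"r{i}",
                             coords=[("src", i * 5000, i * 5000 + 3000)] * 2)
                for i in range(5)]
        umap = {"src": [(10_000, 12_000)]}  # overlaps r2 only
        kept = filter_orthologous(regs, uniqueness_map=umap)
        assert [r.region_id for r in kept] == ["r0", "r1", "r3", "r4"]

    def test_require_indel(self):
        gapped = AlignedRegionPair(region_id="g",
                                   rows=["A" * 1500 + "-" + "A" * 1500,
                                         "A" * 3001])
        plain = self._region(3000, rid="p")
        kept = filter_orthologous([gapped, plain], require_indel=True)
        assert [r.region_id for r in kept] == ["g"]

    def test_filters_order_independent(self):
        regs = [self._region(2999, rid="short"),
                self._region(3500, ident=0.7, rid="lowid"),
                self._region(3500, rid="good",
                             coords=[("src", 0, 3500)] * 2),
                self._region(3500, rid="multi",
                             coords=[("src", 10_000, 13_500)] * 2)]
        umap = {"src": [(11_000, 11_100)]}

        def by_len(rs):
            return [r for r in rs if r.ungapped_length(0) >= 3000]

        def by_id(rs):
            return [r for r in rs if r.percent_identity() >= 80.0]

        def by_uni(rs):
            return [r for r in rs
                    if not any(r.coords[0][1] < e and s < r.coords[0][2]
                               for s, e in umap.get(r.coords[0][0], ()))]

        results = set()
        for perm in itertools.permutations([by_len, by_id, by_uni]):
            rs = regs
            for fn in perm:
                rs = fn(rs)
            results.add(tuple(r.region_id for r in rs))
        assert results == {("good",)}
        assert [r.region_id
                for r in filter_orthologous(regs, uniqueness_map=umap)] == ["good"]


class TestDedupe:
    @staticmethod
    def _reg_with_gap(rid, src_start):
        rows = ["ACGT-ACGT", "ACGTTACGT"]
        return AlignedRegionPair(region_id=rid, rows=rows,
                                 coords=[("ref", src_start, src_start + 8),
                                         ("oth", 0, 9)])

    def test_shared_anchor_drops_all_copies(self):
        r1 = self._reg_with_gap("a1", 100)
        r2 = self._reg_with_gap("a2", 100)
        by_id = {"a1": r1, "a2": r2}
        events = find_indels(r1) + find_indels(r2)
        assert dedupe_indels(events, by_id) == []

    def test_unique_indels_kept_and_empty_ok(self):
        r1 = self._reg_with_gap("a1", 100)
        r2 = self._reg_with_gap("a2", 500)
        by_id = {"a1": r1, "a2": r2}
        events = find_indels(r1) + find_indels(r2)
        assert len(dedupe_indels(events, by_id)) == 2
        assert dedupe_indels([], by_id) == []
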