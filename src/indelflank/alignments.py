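"""Gapped alignments of orthologous regions, filters, and indel calling.

An :class:`AlignedRegionPair` holds 2-4 gapped rows of equal length over
the alphabet {A,C,G,T,N,-}.  Indels are called as maximal gap runs per
row; runs sharing an identical column span across several rows are
emitted once and flagged ambiguous.  Orthology filters reproduce the
standard criteria for strict orthologous regions: minimum ungapped
length, minimum percent identity over non-gap columns, and exclusion of
spans that align to multiple genomic locations.

Coordinates are 0-based half-open throughout; alignment columns are
indexed from 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAP_CODE",
    "N_CODE",
    "ALPHABET",
    "AlignmentFormatError",
    "AlignedRegionPair",
    "IndelEvent",
    "encode_seq",
    "decode_codes",
    "load_alignments",
    "write_alignments",
    "filter_orthologous",
    "FilterCounts",
    "find_indels",
    "dedupe_indels",
]

ALPHABET = "ACGT-N"
GAP_CODE = 4
N_CODE = 5

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _ch in enumerate(ALPHABET):
    _ENCODE[ord(_ch)] = _i
    _ENCODE[ord(_ch.lower())] = _i
_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


class AlignmentFormatError(ValueError):
    """Raised for malformed alignment input (ragged rows, all-gap columns...)."""


def encode_seq(seq: str) -> np.ndarray:
    """Encode a sequence string to uint8 codes (A=0,C=1,G=2,T=3,-=4,N=5)."""
    return _ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def decode_codes(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


@dataclass
class AlignedRegionPair:
    """An aligned orthologous region of 2-4 gapped rows of equal length.

    ``coords`` gives, per row, the (source_id, start, end) half-open
    interval of the ungapped sequence on its source genome; defaults to
    the ungapped length starting at 0.
    """

    region_id: str
    rows: list
    ids: list = None
    coords: list = None
    _codes: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not 2 <= len(self.rows) <= 4:
            raise AlignmentFormatError(
                f"region {self.region_id!r}: need 2-4 rows, got {len(self.rows)}")
        lens = {len(r) for r in self.rows}
        if len(lens) != 1:
            raise AlignmentFormatError(
                f"region {self.region_id!r}: ragged rows of lengths {sorted(lens)}")
        if self.ids is None:
            self.ids = [f"row{i}" for i in range(len(self.rows))]
        if self.coords is None:
            self.coords = [(sid, 0, len(r) - r.count("-"))
                           for sid, r in zip(self.ids, self.rows)]

    @property
    def codes(self) -> np.ndarray:
        """(n_rows, n_cols) uint8 code matrix; cached."""
        if self._codes is None:
            self._codes = np.stack([encode_seq(r) for r in self.rows])
            if bool(((self._codes == GAP_CODE).all(axis=0)).any()):
                raise AlignmentFormatError(
                    f"region {self.region_id!r}: column gapped in every row")
        return self._codes

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def ungapped_length(self, row: int = 0) -> int:
        return self.n_cols - self.rows[row].count("-")

    def percent_identity(self, row_a: int = 0, row_b: int = 1) -> float:
        """Percent identical bases over columns non-gap in both rows.

        N is never a comparable site.  Returns 100.0 for an empty
        comparison (no comparable columns).
        """
        a, b = self.codes[row_a], self.codes[row_b]
        comp = (a < GAP_CODE) & (b < GAP_CODE)
        n = int(comp.sum())
        if n == 0:
            return 100.0
        return 100.0 * float((a[comp] == b[comp]).sum()) / n

    def ungapped_pos(self, row: int, col: int) -> int:
        """Ungapped offset on ``row`` of alignment column ``col``."""
        r = self.codes[row]
        return int((r[:col] != GAP_CODE).sum())

    def source_pos(self, row: int, col: int) -> int:
        sid, start, _end = self.coords[row]
        return start + self.ungapped_pos(row, col)


@dataclass(frozen=True)
class IndelEvent:
    """A maximal gap run in one (or, if ambiguous, several) alignment rows.

    ``start``/``end`` are the half-open column span; the anchors are the
    last non-gap column to the left (``start - 1``) and the first
    non-gap column to the right (``end``).
    """

    region_id: str
    start: int
    end: int
    gapped_row: int
    gapped_rows: tuple = None
    ambiguous: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def anchor_left(self) -> int:
        return self.start - 1

    @property
    def anchor_right(self) -> int:
        return self.end


# ---------------------------------------------------------------------------
# I/O

def _parse_header(header: str):
    """Parse ``region|row_label|source:start-end`` headers, tolerating
    plain ids (no pipes)."""
    parts = header.split("|")
    region_id = parts[0]
    row_label = parts[1] if len(parts) > 1 else None
    coords = None
    if len(parts) > 2 and parts[2]:
        src = parts[2]
        if ":" in src:
            sid, span = src.rsplit(":", 1)
            lo, hi = span.split("-")
            coords = (sid, int(lo), int(hi))
        else:
            coords = (src, 0, -1)
    return region_id, row_label, coords


def load_alignments(path) -> list:
    """Load aligned-FASTA region groups.

    Consecutive records sharing the same region id (the header up to the
    first ``|``) form one region of 2-4 rows.  Headers may carry
    ``region|row_label|source:start-end``; plain single-token headers
    are grouped into one region per file.  Ragged rows raise
    :class:`AlignmentFormatError` naming the region.
    """
    from Bio import SeqIO

    groups: list = []
    order: list = []
    by_id: dict = {}
    plain = True
    for rec in SeqIO.parse(str(path), "fasta"):
        region_id, row_label, coords = _parse_header(rec.id)
        if row_label is not None:
            plain = False
        if region_id not in by_id:
            by_id[region_id] = []
            order.append(region_id)
        by_id[region_id].append((row_label or rec.id, str(rec.seq).upper(), coords))
    if plain and len(order) > 1 and all(len(by_id[r]) == 1 for r in order):
        # plain headers: whole file is one region, records are rows
        from pathlib import Path

        rid = Path(str(path)).stem
        rows = [by_id[r][0] for r in order]
        by_id, order = {rid: rows}, [rid]
    for rid in order:
        entries = by_id[rid]
        labels = [e[0] for e in entries]
        rows = [e[1] for e in entries]
        coords = [e[2] for e in entries]
        if {len(r) for r in rows} and len({len(r) for r in rows}) != 1:
            raise AlignmentFormatError(
                f"region {rid!r}: rows have unequal gapped lengths "
                f"{[len(r) for r in rows]}")
        coords = None if any(c is None for c in coords) else coords
        groups.append(AlignedRegionPair(region_id=rid, rows=rows, ids=labels,
                                        coords=coords))
    return groups


def write_alignments(regions, path) -> None:
    """Write regions as aligned FASTA with ``region|row|source:start-end`` headers."""
    with open(path, "w") as fh:
        for reg in regions:
            for label, row, (sid, lo, hi) in zip(reg.ids, reg.rows, reg.coords):
                fh.write(f">{reg.region_id}|{label}|{sid}:{lo}-{hi}\n")
                for i in range(0, len(row), 80):
                    fh.write(row[i:i + 80] + "\n")


# ---------------------------------------------------------------------------
# filters

@dataclass
class FilterCounts:
    input: int = 0
    too_short: int = 0
    low_identity: int = 0
    multiply_hit: int = 0
    no_indel: int = 0
    kept: int = 0


def _overlaps(lo: int, hi: int, intervals) -> bool:
    return any(lo < e and s < hi for s, e in intervals)


def filter_orthologous(regions, min_len: int = 3000, min_identity: float = 80.0,
                       uniqueness_map=None, require_indel: bool = False,
                       counts: FilterCounts = None) -> list:
    """Apply the orthologous-region filters; order-independent.

    A region survives iff its ungapped row-0 length is >= ``min_len``
    (inclusive), its identity over non-gap columns is >= ``min_identity``
    (inclusive), and its row-0 source interval overlaps no interval of
    ``uniqueness_map`` (a dict: source id -> list of half-open multiply-
    hit spans).  With ``require_indel``, regions without any gap column
    are also removed.
    """
    uniqueness_map = uniqueness_map or {}
    counts = counts if counts is not None else FilterCounts()
    counts.input = len(regions)
    kept = []
    for reg in regions:
        if reg.ungapped_length(0) < min_len:
            counts.too_short += 1
            continue
        if reg.percent_identity(0, 1) < min_identity:
            counts.low_identity += 1
            continue
        sid, lo, hi = reg.coords[0]
        if _overlaps(lo, hi, uniqueness_map.get(sid, ())):
            counts.multiply_hit += 1
            continue
        if require_indel and not any("-" in r for r in reg.rows):
            counts.no_indel += 1
            continue
        kept.append(reg)
    counts.kept = len(kept)
    return kept


# ---------------------------------------------------------------------------
# indel calling

def _gap_runs(codes_row: np.ndarray):
    gap = codes_row == GAP_CODE
    if not gap.any():
        return []
    d = np.diff(gap.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if gap[0]:
        starts.insert(0, 0)
    if gap[-1]:
        ends.append(len(gap))
    return list(zip(starts, ends))


def find_indels(region: AlignedRegionPair) -> list:
    """Call one :class:`IndelEvent` per maximal gap run per row.

    Runs gapped in multiple rows over an identical span are emitted once
    with ``ambiguous=True`` and ``gapped_rows`` listing all gapped rows.
    """
    spans: dict = {}
    for r in range(len(region.rows)):
        for s, e in _gap_runs(region.codes[r]):
            spans.setdefault((s, e), []).append(r)
    events = []
    for (s, e), rows_gapped in sorted(spans.items()):
        events.append(IndelEvent(
            region_id=region.region_id, start=s, end=e,
            gapped_row=rows_gapped[0], gapped_rows=tuple(rows_gapped),
            ambiguous=len(rows_gapped) > 1))
    return events


def dedupe_indels(events, regions_by_id, reference_row: int = 0) -> list:
    """Drop every indel whose source anchor position recurs across alignments.

    The anchor is the left-anchor column mapped onto the source
    coordinates of ``reference_row`` (the shared reference genome).  All
    members of a duplicated anchor group are removed, not just the
    extras.
    """
    keyed = []
    for ev in events:
        reg = regions_by_id[ev.region_id]
        key = (reg.coords[reference_row][0],
               reg.source_pos(reference_row, max(ev.anchor_left, 0)))
        keyed.append((key, ev))
    from collections import Counter

    multiplicity = Counter(k for k, _e in keyed)
    return [ev for k, ev in keyed if multiplicity[k] == 1]
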