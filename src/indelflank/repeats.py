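"""Homopolymer runs, indel-repeat spatial relations, repeat-density bins.

Repeat units are maximal homopolymer runs of at least ``min_len``
identical nucleotides (default 4; N breaks runs).  An indel is

* *contiguous* with a repeat if it lies inside the run or immediately
  adjacent to it,
* *proximal* if any run base lies within 5 nt on either side, and
* *none* otherwise.

For the repeat-density analysis, a pairwise alignment is divided into
non-overlapping 100-column windows, each binned by its count of intact
homopolymer runs; runs interrupted in the partner row by a substitution
(so that fewer than ``min_len`` contiguous identical bases remain) are
not counted.  Windows overlapping any gap column can be excluded so the
repeat-density effect is measured away from indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignments import GAP_CODE, AlignedRegionPair, IndelEvent, encode_seq

__all__ = [
    "HomopolymerRun",
    "RepeatBin",
    "find_homopolymers",
    "indel_reference_interval",
    "classify_indel_repeat_relation",
    "repeat_position_histogram",
    "bin_windows_by_repeats",
    "compare_bins",
]


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of >= min_len identical bases, half-open on the
    ungapped sequence."""

    base: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def find_homopolymers(seq: str, min_len: int = 4):
    """All maximal homopolymer runs of length >= ``min_len``, in order.

    ``seq`` is an ungapped sequence over {A,C,G,T,N}; N (or any other
    symbol) breaks runs and never forms one.
    """
    codes = encode_seq(seq)
    if codes.size == 0:
        return []
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [codes.size]))
    out = []
    for s, e in zip(starts, ends):
        if e - s >= min_len and codes[s] < GAP_CODE:
            out.append(HomopolymerRun(base="ACGT"[codes[s]], start=int(s), end=int(e)))
    return out


def indel_reference_interval(region: AlignedRegionPair, indel: IndelEvent,
                             ref_row: int) -> tuple:
    """The indel's footprint on the ungapped coordinates of ``ref_row``.

    For a deletion observed against an ungapped reference the interval
    covers the bases opposite the gap; when the reference row itself is
    gapped the interval is the zero-length insertion point.
    """
    a = region.ungapped_pos(ref_row, indel.start)
    span = region.codes[ref_row, indel.start:indel.end]
    b = a + int((span != GAP_CODE).sum())
    return a, b


def classify_indel_repeat_relation(indel_interval: tuple, runs,
                                   window: int = 5) -> str:
    """Classify one indel as 'contiguous', 'proximal', or 'none'.

    ``indel_interval`` is the (start, end) footprint on the same
    ungapped coordinates as ``runs``.  Contiguous: the indel overlaps a
    run or sits immediately next to one.  Proximal: any run base within
    ``window`` nt on either side.
    """
    a, b = indel_interval
    for run in runs:
        if run.start < b and run.end > a:      # overlap (indel inside/over run)
            return "contiguous"
        if run.end == a or run.start == b:     # immediately adjacent
            return "contiguous"
    for run in runs:
        if run.start < b + window and run.end > a - window:
            return "proximal"
    return "none"


def repeat_position_histogram(indel_intervals, runs_per_indel, seq_lengths,
                              flank: int = 20):
    """Histogram of run terminations around indels (positions -flank..+flank).

    Each run is scored once, at the position where it terminates (its
    rightmost base) relative to the indel: upstream positions are
    negative (-1 abuts the indel), downstream positions positive (+1 is
    the first base after the indel), 0 means the run terminates inside
    the indel footprint.  Indels whose +/-``flank`` nt are truncated by
    the region edge are skipped and counted.

    Returns ``(offsets, counts, n_skipped)``.
    """
    offsets = np.arange(-flank, flank + 1)
    counts = np.zeros(offsets.size, dtype=np.int64)
    n_skipped = 0
    for (a, b), runs, seq_len in zip(indel_intervals, runs_per_indel, seq_lengths):
        if a < flank or b + flank > seq_len:
            n_skipped += 1
            continue
        for run in runs:
            term = run.end - 1
            if term < a:
                rel = term - a
            elif term >= b:
                rel = term - b + 1
            else:
                rel = 0
            if -flank <= rel <= flank:
                counts[rel + flank] += 1
    return offsets, counts, n_skipped


@dataclass
class RepeatBin:
    """Windows sharing a repeat count k, with pooled divergence counts."""

    k: int
    n_windows: int
    mismatches: int
    sites: int
    ts: int
    tv: int
    per_window_d: list = field(default_factory=list)

    @property
    def d(self) -> float:
        from .windows import jukes_cantor

        return jukes_cantor(self.mismatches, self.sites)


def _intact_in_row(row_codes: np.ndarray, base_code: int, min_len: int) -> bool:
    """True if the partner row retains >= min_len contiguous copies of
    the run base across the run's columns."""
    best = cur = 0
    for c in row_codes:
        cur = cur + 1 if c == base_code else 0
        best = max(best, cur)
    return best >= min_len


def bin_windows_by_repeats(region: AlignedRegionPair, width: int = 100,
                           min_len: int = 4, exclude_indel_windows: bool = True,
                           require_intact_in_both: bool = True,
                           min_sites: int = 50, rows=(0, 1), ref_row: int = 0):
    """Bin non-overlapping alignment windows by homopolymer-run count.

    Runs are found on ``ref_row``'s ungapped sequence and mapped to
    alignment columns; with ``require_intact_in_both`` a run interrupted
    in the partner row (fewer than ``min_len`` continuous identical
    bases remain) is not counted.  Each counted run is assigned to the
    window containing its starting column.  Windows overlapping any gap
    column are dropped when ``exclude_indel_windows``; windows with
    fewer than ``min_sites`` comparable sites are always dropped.
    Returns a list of :class:`RepeatBin` sorted by k.
    """
    codes = region.codes
    a, b = codes[rows[0]], codes[rows[1]]
    other = rows[0] if ref_row == rows[1] else rows[1]
    ref = codes[ref_row]
    nongap_cols = np.flatnonzero(ref != GAP_CODE)
    ref_seq = "".join("ACGT-N"[c] for c in ref[nongap_cols])
    runs = find_homopolymers(ref_seq, min_len=min_len)
    run_start_cols = []
    for run in runs:
        cols = nongap_cols[run.start:run.end]
        if require_intact_in_both and not _intact_in_row(
                codes[other, cols], "ACGT".index(run.base), min_len):
            continue
        run_start_cols.append(cols[0])
    run_start_cols = np.asarray(run_start_cols, dtype=np.int64)

    n_win = region.n_cols // width
    comp = (a < GAP_CODE) & (b < GAP_CODE)
    mism = comp & (a != b)
    has_gap = (a == GAP_CODE) | (b == GAP_CODE)
    from .spectra import _PAIR_INDEX, _TS_IDX
    from .windows import jukes_cantor

    bins: dict = {}
    for w in range(n_win):
        lo, hi = w * width, (w + 1) * width
        if exclude_indel_windows and bool(has_gap[lo:hi].any()):
            continue
        sites = int(comp[lo:hi].sum())
        if sites < min_sites:
            continue
        k = int(((run_start_cols >= lo) & (run_start_cols < hi)).sum())
        mm = int(mism[lo:hi].sum())
        mcols = np.flatnonzero(mism[lo:hi]) + lo
        ts = tv = 0
        if mcols.size:
            pidx = _PAIR_INDEX[a[mcols], b[mcols]]
            ts = int(np.isin(pidx, _TS_IDX).sum())
            tv = int(mcols.size - ts)
        bin_ = bins.setdefault(k, RepeatBin(k=k, n_windows=0, mismatches=0,
                                            sites=0, ts=0, tv=0))
        bin_.n_windows += 1
        bin_.mismatches += mm
        bin_.sites += sites
        bin_.ts += ts
        bin_.tv += tv
        bin_.per_window_d.append(jukes_cantor(mm, sites))
    return [bins[k] for k in sorted(bins)]


def compare_bins(bins):
    """Wilcoxon rank-sum p-value of per-window D for each bin k vs k=0."""
    from scipy.stats import ranksums

    base = next((b for b in bins if b.k == 0), None)
    out = {}
    for b in bins:
        if base is None or b.k == 0 or not b.per_window_d or not base.per_window_d:
            out[b.k] = float("nan") if b.k != 0 else 1.0
            continue
        out[b.k] = float(ranksums(b.per_window_d, base.per_window_d).pvalue)
    return out
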