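"""Indel-flanking windows and Jukes-Cantor divergence profiles.

For every indel, up to 1,000 alignment columns on each side of its
anchors are partitioned into distance windows.  The default scheme uses
a 50-column window nearest the indel (W1), eight 100-column windows
(W2-W9) and an outermost 150-column window (W10); all-50 and all-100
schemes are available as alternatives.  Divergence per window is the
Jukes-Cantor-corrected mismatch proportion D = -(3/4) ln(1 - 4p/3),
pooled over mismatch/site counts from all usable flanks (per-indel D
values are retained separately for distribution tests).  The background
divergence Db is the mean pooled D over the windows outside the indel's
influence (windows 3-10 in the default scheme).

A flank is usable only if the full 1,000 columns exist within the region
and contain no other indel; shorter flanks are discarded entirely so
that window denominators stay comparable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignments import GAP_CODE, AlignedRegionPair, IndelEvent

__all__ = [
    "WindowScheme",
    "DEFAULT_SCHEME",
    "FlankSet",
    "WindowProfile",
    "JCDomainError",
    "assign_window",
    "jukes_cantor",
    "extract_flanks",
    "window_profile",
    "background_db",
]


class JCDomainError(ValueError):
    """Mismatch proportion at or above 3/4: Jukes-Cantor undefined."""


@dataclass(frozen=True)
class WindowScheme:
    """Partition of flank offsets 1..total into distance windows.

    ``background_start`` is the 0-based index of the first window used
    for the background divergence Db (windows whose offsets all exceed
    the reach of the indel/region effect).
    """

    widths: tuple = (50, 100, 100, 100, 100, 100, 100, 100, 100, 150)
    background_start: int = 2

    @property
    def n_windows(self) -> int:
        return len(self.widths)

    @property
    def total(self) -> int:
        return sum(self.widths)

    @property
    def edges(self) -> np.ndarray:
        return np.cumsum((0,) + self.widths)

    def offset_windows(self) -> np.ndarray:
        """0-based window index for each offset 1..total."""
        return np.repeat(np.arange(self.n_windows), self.widths)

    @classmethod
    def all50(cls) -> "WindowScheme":
        return cls(widths=(50,) * 20, background_start=3)

    @classmethod
    def all100(cls) -> "WindowScheme":
        return cls(widths=(100,) * 10, background_start=2)


DEFAULT_SCHEME = WindowScheme()


def assign_window(offset: int, scheme: WindowScheme = DEFAULT_SCHEME):
    """Map a 1-based column distance from the anchor to a 1-based window
    index, or None beyond the outermost window."""
    if offset < 1:
        raise ValueError(f"offset must be >= 1, got {offset}")
    if offset > scheme.total:
        return None
    return int(np.searchsorted(scheme.edges, offset, side="left"))


def jukes_cantor(mismatches: float, sites: float) -> float:
    """Jukes-Cantor distance D = -(3/4) ln(1 - 4p/3) with p = mismatches/sites.

    Returns NaN (undefined-value sentinel) for ``sites == 0``; raises
    :class:`JCDomainError` for p >= 3/4.
    """
    if sites < 0 or mismatches < 0 or mismatches > sites:
        raise ValueError("need 0 <= mismatches <= sites")
    if sites == 0:
        return math.nan
    p = mismatches / sites
    if p >= 0.75:
        raise JCDomainError(f"mismatch proportion {p:.3f} >= 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _jc_vec(mismatches: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Vectorised JC; NaN where sites==0 or p>=3/4 (with a warning)."""
    m = np.asarray(mismatches, dtype=float)
    s = np.asarray(sites, dtype=float)
    out = np.full(m.shape, np.nan)
    ok = s > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(ok, m / np.where(ok, s, 1.0), np.nan)
        dom = ok & (p < 0.75)
        out[dom] = -0.75 * np.log1p(-4.0 * p[dom] / 3.0)
    if bool((ok & ~dom).any()):
        warnings.warn("window mismatch proportion >= 3/4; D set to NaN")
    return out


@dataclass
class FlankSet:
    """Usability of the two 1,000-column flanks of one indel."""

    indel: IndelEvent
    upstream_usable: bool
    downstream_usable: bool
    flank_len: int = 1000

    @property
    def any_usable(self) -> bool:
        return self.upstream_usable or self.downstream_usable


def extract_flanks(region: AlignedRegionPair, indel: IndelEvent, all_indels,
                   flank_len: int = 1000) -> FlankSet:
    """Mark each side usable iff ``flank_len`` columns exist within the
    region and no other indel's span intersects them."""
    up_lo, up_hi = indel.start - flank_len, indel.start
    dn_lo, dn_hi = indel.end, indel.end + flank_len
    up = up_lo >= 0
    dn = dn_hi <= region.n_cols
    for other in all_indels:
        if (other.start, other.end, other.gapped_rows) == (
                indel.start, indel.end, indel.gapped_rows):
            continue
        if up and other.end > up_lo and other.start < up_hi:
            up = False
        if dn and other.end > dn_lo and other.start < dn_hi:
            dn = False
        if not (up or dn):
            break
    return FlankSet(indel=indel, upstream_usable=up, downstream_usable=dn,
                    flank_len=flank_len)


@dataclass
class WindowProfile:
    """Pooled mismatch/site counts and D per window, plus per-indel D.

    ``per_indel_d`` is an (n_indels, n_windows) array with NaN for
    windows without comparable sites in that indel's flanks.
    """

    scheme: WindowScheme
    mismatches: np.ndarray
    sites: np.ndarray
    per_indel_d: np.ndarray
    n_indels: int

    @property
    def d(self) -> np.ndarray:
        return _jc_vec(self.mismatches, self.sites)

    @property
    def dw1(self) -> float:
        return float(self.d[0])

    @property
    def db(self) -> float:
        return background_db(self)

    @property
    def excess(self) -> float:
        """Indel-associated divergence DW1 - Db."""
        return self.dw1 - self.db

    @property
    def mean_per_indel_d(self) -> np.ndarray:
        """Averaged (rather than pooled) per-window D across indels."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.per_indel_d, axis=0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "window": np.arange(1, self.scheme.n_windows + 1),
            "sites": self.sites.astype(int),
            "mismatches": self.mismatches.astype(int),
            "d": self.d,
            "n_indels": self.n_indels,
        })


def flank_window_columns(fs: FlankSet, scheme: WindowScheme):
    """Yield (window-index array, column array) for each usable side."""
    widx = scheme.offset_windows()
    n = scheme.total
    if fs.upstream_usable:
        yield widx, fs.indel.anchor_left - np.arange(n)
    if fs.downstream_usable:
        yield widx, fs.indel.anchor_right + np.arange(n)


def window_profile(items, rows=(0, 1), scheme: WindowScheme = DEFAULT_SCHEME):
    """Pool window counts over all usable flanks of ``items``.

    ``items`` is a sequence of ``(region, flankset)`` or
    ``(region, flankset, rows)`` tuples (the per-item rows override the
    ``rows`` argument, which selects the pair of alignment rows to
    compare).  A comparable site is a column where both compared rows
    hold an unambiguous base (not gap, not N).
    """
    nw = scheme.n_windows
    pooled_m = np.zeros(nw)
    pooled_s = np.zeros(nw)
    per_indel = []
    n_indels = 0
    for item in items:
        if len(item) == 2:
            region, fs = item
            item_rows = rows
        else:
            region, fs, item_rows = item
        if not fs.any_usable:
            continue
        codes = region.codes
        a, b = codes[item_rows[0]], codes[item_rows[1]]
        im = np.zeros(nw)
        isite = np.zeros(nw)
        for widx, cols in flank_window_columns(fs, scheme):
            ca, cb = a[cols], b[cols]
            comp = (ca < GAP_CODE) & (cb < GAP_CODE)
            mism = comp & (ca != cb)
            isite += np.bincount(widx[comp], minlength=nw)
            im += np.bincount(widx[mism], minlength=nw)
        pooled_m += im
        pooled_s += isite
        per_indel.append(_jc_vec(im, isite))
        n_indels += 1
    per_indel_d = np.array(per_indel) if per_indel else np.empty((0, nw))
    return WindowProfile(scheme=scheme, mismatches=pooled_m, sites=pooled_s,
                         per_indel_d=per_indel_d, n_indels=n_indels)


def background_db(profile: WindowProfile) -> float:
    """Background divergence: arithmetic mean of pooled D over the
    background windows (3-10 in the default scheme).  NaN with a warning
    if any background window has no comparable sites."""
    sl = slice(profile.scheme.background_start, profile.scheme.n_windows)
    d = profile.d[sl]
    if bool(np.isnan(d).any()):
        warnings.warn("empty background window; Db undefined")
        return math.nan
    return float(d.mean())
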