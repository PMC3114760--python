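"""Transition/transversion spectra of indel-proximal substitutions.

Substitutions are classified as transitions (purine<->purine or
pyrimidine<->pyrimidine: the unordered pairs {A,G} and {C,T}) or
transversions (the other four unordered pairs), direction-agnostic.
Spectra are tallied per distance window using the same comparability
rule as the divergence profiles (columns with gap or N excluded), and
the ts:tv ratio is a counts ratio without site-composition correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignments import GAP_CODE
from .windows import DEFAULT_SCHEME, WindowScheme, flank_window_columns

__all__ = [
    "PAIR_NAMES",
    "TRANSITION_PAIRS",
    "classify_substitution",
    "SpectrumByWindow",
    "spectrum_by_window",
]

PAIR_NAMES = ("AC", "AG", "AT", "CG", "CT", "GT")
TRANSITION_PAIRS = frozenset({"AG", "CT"})

# unordered pair index for base codes (A=0, C=1, G=2, T=3)
_PAIR_INDEX = np.full((4, 4), -1, dtype=np.int8)
for _i, _p in enumerate(PAIR_NAMES):
    _a, _b = ("ACGT".index(_p[0]), "ACGT".index(_p[1]))
    _PAIR_INDEX[_a, _b] = _PAIR_INDEX[_b, _a] = _i

_TS_IDX = np.array([PAIR_NAMES.index(p) for p in sorted(TRANSITION_PAIRS)])


def classify_substitution(a: str, b: str) -> str:
    """Classify the unordered substitution {a, b}."""
    a, b = a.upper(), b.upper()
    if a not in "ACGT" or b not in "ACGT" or len(a) != 1 or len(b) != 1:
        raise ValueError(f"bases must be distinct members of ACGT, got {a!r}, {b!r}")
    if a == b:
        raise ValueError("not a substitution: identical bases")
    return "transition" if "".join(sorted(a + b)) in TRANSITION_PAIRS else "transversion"


@dataclass
class SpectrumByWindow:
    """Per-window counts of the six unordered base pairs.

    ``pair_counts`` has shape (n_windows, 6) in PAIR_NAMES order;
    ``per_indel_tv_fraction`` has one row per indel and NaN for windows
    without mismatches, feeding the window-vs-window distribution
    comparisons.
    """

    scheme: WindowScheme
    pair_counts: np.ndarray
    per_indel_tv_fraction: np.ndarray
    n_indels: int

    @property
    def totals(self) -> np.ndarray:
        return self.pair_counts.sum(axis=1)

    @property
    def ts_counts(self) -> np.ndarray:
        return self.pair_counts[:, _TS_IDX].sum(axis=1)

    @property
    def tv_counts(self) -> np.ndarray:
        return self.totals - self.ts_counts

    @property
    def proportions(self) -> np.ndarray:
        """Pair proportions per window; NaN rows where a window is empty."""
        tot = self.totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.pair_counts / tot[:, None]
        out[tot == 0] = np.nan
        return out

    @property
    def tv_fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.tv_counts / self.totals.astype(float)
        out[self.totals == 0] = np.nan
        return out

    @property
    def ts_tv_ratio(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.ts_counts / self.tv_counts.astype(float)
        out[self.tv_counts == 0] = np.nan
        return out

    def compare_windows(self, window_a: int = 1, window_b: int = 4):
        """Two-sample comparison of per-indel transversion fractions
        between two windows (1-based), via the test-selection gate."""
        from .stats import select_and_test

        fa = self.per_indel_tv_fraction[:, window_a - 1]
        fb = self.per_indel_tv_fraction[:, window_b - 1]
        return select_and_test(fa[~np.isnan(fa)], fb[~np.isnan(fb)])

    def to_frame(self):
        import pandas as pd

        rows = []
        for w in range(self.scheme.n_windows):
            for i, name in enumerate(PAIR_NAMES):
                rows.append((w + 1, name,
                             "transition" if name in TRANSITION_PAIRS else "transversion",
                             int(self.pair_counts[w, i])))
        return pd.DataFrame(rows, columns=["window", "pair", "class", "count"])


def spectrum_by_window(items, rows=(0, 1),
                       scheme: WindowScheme = DEFAULT_SCHEME) -> SpectrumByWindow:
    """Tally the six unordered substitution pairs per window.

    ``items`` as in :func:`indelflank.windows.window_profile`:
    ``(region, flankset)`` or ``(region, flankset, rows)`` tuples.
    """
    nw = scheme.n_windows
    counts = np.zeros((nw, 6), dtype=np.int64)
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
        tv_m = np.zeros(nw)
        tot_m = np.zeros(nw)
        for widx, cols in flank_window_columns(fs, scheme):
            ca, cb = a[cols], b[cols]
            mism = (ca < GAP_CODE) & (cb < GAP_CODE) & (ca != cb)
            if not mism.any():
                continue
            pidx = _PAIR_INDEX[ca[mism], cb[mism]]
            widx_m = widx[mism]
            np.add.at(counts, (widx_m, pidx), 1)
            tot_m += np.bincount(widx_m, minlength=nw)
            is_ts = np.isin(pidx, _TS_IDX)
            tv_m += np.bincount(widx_m[~is_ts], minlength=nw)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot_m > 0, tv_m / tot_m, np.nan)
        per_indel.append(frac)
        n_indels += 1
    per_indel_tv = np.array(per_indel) if per_indel else np.empty((0, nw))
    return SpectrumByWindow(scheme=scheme, pair_counts=counts,
                            per_indel_tv_fraction=per_indel_tv, n_indels=n_indels)
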