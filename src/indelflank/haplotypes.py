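"""Outgroup polarization of indels and partition of divergence.

With a three-genome alignment (two ingroups plus an outgroup) the
lineage on which each indel arose can be inferred by parsimony: the
ingroup row whose state over the gap span differs from the outgroup is
the indel haplotype.  Divergence near the indel then splits into

* Di  -- window divergence of the indel haplotype measured against the
  outgroup (indel + region effect),
* Dni -- window divergence of the non-indel haplotype against the
  outgroup (region effect alone), and
* Db  -- background divergence of the two ingroups (mean pooled D over
  the background windows of the ingroup-ingroup comparison).

The attribution ratio R = (Di - Db)/(Dni - Db) for window 1 measures the
proportion of the near-indel excess attributable to the indel itself;
R = 1 means no indel-specific excess over the regional effect.

Four-genome alignments of two recently diverged pairs classify indels as
*old* (gap shared by both rows of one pair) or *new* (gap private to a
single row); divergence profiles for the two classes come from the
within-pair comparison (new) and a one-genome-per-pair comparison (old).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .alignments import GAP_CODE, N_CODE, AlignedRegionPair, IndelEvent
from .windows import (DEFAULT_SCHEME, FlankSet, WindowProfile, WindowScheme,
                      _jc_vec, flank_window_columns, window_profile)

__all__ = [
    "HaplotypePartition",
    "polarize_indel",
    "partition_divergence",
    "attribution_ratio",
    "classify_old_new",
    "old_new_divergence",
]


def polarize_indel(region: AlignedRegionPair, indel: IndelEvent,
                   ingroup_rows=(0, 1), outgroup_row: int = 2):
    """Infer the ingroup row on which the indel event occurred.

    Returns the indel-haplotype row index, or None when the outgroup is
    uninformative (N or a mixed gap/base state over the span, or the gap
    is shared by both ingroups).
    """
    gapped = set(indel.gapped_rows or (indel.gapped_row,))
    in_gapped = gapped & set(ingroup_rows)
    if len(in_gapped) != 1:
        return None
    r = in_gapped.pop()
    other = ingroup_rows[0] if r == ingroup_rows[1] else ingroup_rows[1]
    out = region.codes[outgroup_row, indel.start:indel.end]
    if bool((out == N_CODE).any()):
        return None
    if bool((out == GAP_CODE).all()):
        # outgroup shares the gap: the ungapped ingroup gained an insertion
        return other
    if bool((out < GAP_CODE).all()):
        # outgroup has bases: the gapped ingroup suffered a deletion
        return r
    return None


@dataclass
class HaplotypePartition:
    """Window-wise Di/Dni pools, ingroup background Db, and R.

    ``per_indel_di`` / ``per_indel_dni`` are (n_pairs, n_windows) arrays
    of per-indel window D values (NaN where a window had no sites);
    distribution tests between the two haplotype classes operate on
    these.
    """

    scheme: WindowScheme
    di_mismatches: np.ndarray
    di_sites: np.ndarray
    dni_mismatches: np.ndarray
    dni_sites: np.ndarray
    db: float
    per_indel_di: np.ndarray
    per_indel_dni: np.ndarray
    n_pairs: int

    @property
    def di(self) -> np.ndarray:
        return _jc_vec(self.di_mismatches, self.di_sites)

    @property
    def dni(self) -> np.ndarray:
        return _jc_vec(self.dni_mismatches, self.dni_sites)

    @property
    def r(self) -> float:
        return attribution_ratio(float(self.di[0]), float(self.dni[0]), self.db)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "window": np.arange(1, self.scheme.n_windows + 1),
            "di_sites": self.di_sites.astype(int),
            "di_mismatches": self.di_mismatches.astype(int),
            "di": self.di,
            "dni_sites": self.dni_sites.astype(int),
            "dni_mismatches": self.dni_mismatches.astype(int),
            "dni": self.dni,
            "db": self.db,
            "n_pairs": self.n_pairs,
        })


def partition_divergence(items, ingroup_rows=(0, 1), outgroup_row: int = 2,
                         scheme: WindowScheme = DEFAULT_SCHEME) -> HaplotypePartition:
    """Pool Di/Dni window counts over polarized indels with usable flanks.

    ``items`` is a sequence of ``(region, indel, flankset)`` triples from
    three-row alignments.  Indels whose polarization is ambiguous are
    dropped from the pools.  Comparable columns for the Di/Dni pools are
    non-gap, non-N in all three rows; Db comes from the ingroup-ingroup
    comparison over the background windows.
    """
    nw = scheme.n_windows
    di_m = np.zeros(nw); di_s = np.zeros(nw)
    dni_m = np.zeros(nw); dni_s = np.zeros(nw)
    bg_m = np.zeros(nw); bg_s = np.zeros(nw)
    pi_di, pi_dni = [], []
    n_pairs = 0
    for region, indel, fs in items:
        if not fs.any_usable:
            continue
        hap = polarize_indel(region, indel, ingroup_rows, outgroup_row)
        if hap is None:
            continue
        non = ingroup_rows[0] if hap == ingroup_rows[1] else ingroup_rows[1]
        codes = region.codes
        rows3 = (ingroup_rows[0], ingroup_rows[1], outgroup_row)
        ind_m = np.zeros(nw); ind_s = np.zeros(nw)
        nin_m = np.zeros(nw); nin_s = np.zeros(nw)
        for widx, cols in flank_window_columns(fs, scheme):
            sub = codes[np.ix_(rows3, cols)]
            comp = (sub < GAP_CODE).all(axis=0)
            out = codes[outgroup_row, cols]
            mi = comp & (codes[hap, cols] != out)
            mn = comp & (codes[non, cols] != out)
            mb = comp & (codes[ingroup_rows[0], cols] != codes[ingroup_rows[1], cols])
            cw = np.bincount(widx[comp], minlength=nw)
            ind_s += cw; nin_s += cw
            ind_m += np.bincount(widx[mi], minlength=nw)
            nin_m += np.bincount(widx[mn], minlength=nw)
            bg_s += cw
            bg_m += np.bincount(widx[mb], minlength=nw)
        di_m += ind_m; di_s += ind_s
        dni_m += nin_m; dni_s += nin_s
        pi_di.append(_jc_vec(ind_m, ind_s))
        pi_dni.append(_jc_vec(nin_m, nin_s))
        n_pairs += 1
    bg_sl = slice(scheme.background_start, nw)
    bg_d = _jc_vec(bg_m[bg_sl], bg_s[bg_sl])
    db = float(bg_d.mean()) if not bool(np.isnan(bg_d).any()) else math.nan
    return HaplotypePartition(
        scheme=scheme,
        di_mismatches=di_m, di_sites=di_s,
        dni_mismatches=dni_m, dni_sites=dni_s, db=db,
        per_indel_di=np.array(pi_di) if pi_di else np.empty((0, nw)),
        per_indel_dni=np.array(pi_dni) if pi_dni else np.empty((0, nw)),
        n_pairs=n_pairs)


def attribution_ratio(di: float, dni: float, db: float) -> float:
    """R = (Di - Db)/(Dni - Db); 1 means no indel-specific excess.

    Returns NaN (with a warning) when Dni - Db <= 0, where the ratio is
    undefined.
    """
    denom = dni - db
    if not denom > 0:
        warnings.warn("Dni - Db <= 0; attribution ratio undefined")
        return math.nan
    return (di - db) / denom


def classify_old_new(region: AlignedRegionPair, indel: IndelEvent,
                     pair_a=(0, 1), pair_b=(2, 3)):
    """Classify a quartet indel as 'old', 'new', or None.

    New: the gap is private to a single row.  Old: the gap is shared by
    both rows of exactly one pair and absent from the other.  Any other
    pattern (homoplasy-like) returns None.  Indel spans must match
    exactly across rows to count as the same indel; find_indels already
    groups identical spans.
    """
    gapped = set(indel.gapped_rows or (indel.gapped_row,))
    if len(gapped) == 1:
        return "new"
    if gapped == set(pair_a) or gapped == set(pair_b):
        return "old"
    return None


def old_new_divergence(items, pair_a=(0, 1), pair_b=(2, 3),
                       scheme: WindowScheme = DEFAULT_SCHEME):
    """Pooled window profiles for old and new indels of quartet regions.

    ``items`` is a sequence of ``(region, indel, flankset)``.  The new
    profile compares the two rows of the pair containing the private
    gap; the old profile compares one genome from each pair (the first
    of each), so a site where the two similar genomes differ from each
    other and from the other pair enters the old pool as one
    substitution.  Returns ``(old_profile, new_profile)``.
    """
    old_items, new_items = [], []
    for region, indel, fs in items:
        cls = classify_old_new(region, indel, pair_a, pair_b)
        if cls is None or not fs.any_usable:
            continue
        if cls == "new":
            row = (indel.gapped_rows or (indel.gapped_row,))[0]
            pair = pair_a if row in pair_a else pair_b
            new_items.append((region, fs, tuple(pair)))
        else:
            old_items.append((region, fs, (pair_a[0], pair_b[0])))
    old_profile = window_profile(old_items, scheme=scheme)
    new_profile = window_profile(new_items, scheme=scheme)
    return old_profile, new_profile
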