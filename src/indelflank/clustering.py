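"""Hypergeometric clustering tests for single-gene mutant collections.

Given a collection of independent single-event mutants of one gene,
each site is classified *mutable* if at least one observed substitution
lies within ``radius`` bp (default 5) of it.  Under the null hypothesis
that a query set of n events falls uniformly over the gene's N
candidate positions, the number k landing in the m "success" positions
follows a hypergeometric distribution; the reported p-value is the
upper tail P(X >= k).

Two queries are implemented: whether indels co-cluster with
substitutions (success = the indel's site is mutable), and, for every
tetranucleotide motif, whether its occurrences are contiguous with
mutable sites.  For the motif scan the success set is computed by
applying the same contiguity predicate to every candidate start
position, so that the null success probability is exactly m/N and the
hypergeometric model is self-consistent.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "MutabilityMap",
    "HypergeomTest",
    "build_mutability_map",
    "hypergeom_tail",
    "indel_substitution_association",
    "tetranucleotide_scan",
    "ScanResult",
]


@dataclass
class MutabilityMap:
    """Per-site mutable flags: a site is mutable iff >= 1 observed
    substitution lies within ``radius`` bp of it."""

    gene_length: int
    radius: int
    mutable: np.ndarray

    @property
    def m(self) -> int:
        return int(self.mutable.sum())


@dataclass(frozen=True)
class HypergeomTest:
    """Parameters and upper-tail p of one hypergeometric draw."""

    N: int
    m: int
    n: int
    k: int
    p: float


def build_mutability_map(gene_length: int, substitution_positions,
                         radius: int = 5) -> MutabilityMap:
    """Union of +/-radius intervals around the observed substitutions."""
    mutable = np.zeros(gene_length, dtype=bool)
    for p in substitution_positions:
        if not 0 <= p < gene_length:
            raise ValueError(f"position {p} outside [0, {gene_length})")
        mutable[max(0, p - radius): p + radius + 1] = True
    return MutabilityMap(gene_length=gene_length, radius=radius, mutable=mutable)


def hypergeom_tail(N: int, m: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, m, n)."""
    if not (0 <= m <= N and 0 <= n <= N and 0 <= k <= min(m, n)):
        raise ValueError(f"invalid hypergeometric bounds N={N} m={m} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(min(1.0, max(0.0, hypergeom.sf(k - 1, N, m, n))))


def indel_substitution_association(collection, radius: int = 5) -> HypergeomTest:
    """Do the collection's indels fall in substitution-defined mutable windows?

    The mutability map is built from the substitutions only; the test
    counts the indels landing on mutable sites.  Degenerate maps (all or
    no sites mutable) return p = 1 with a warning.
    """
    subs = collection.substitution_positions
    indels = collection.indel_positions
    if not subs or not indels:
        raise ValueError("collection needs >= 1 substitution and >= 1 indel")
    L = len(collection.gene)
    amap = build_mutability_map(L, subs, radius)
    k = int(amap.mutable[np.asarray(indels)].sum())
    if amap.m in (0, L):
        warnings.warn("degenerate mutability map (all or no windows mutable); p = 1")
        return HypergeomTest(N=L, m=amap.m, n=len(indels), k=k, p=1.0)
    return HypergeomTest(N=L, m=amap.m, n=len(indels), k=k,
                         p=hypergeom_tail(L, amap.m, len(indels), k))


ALL_TETRAMERS = tuple("".join(t) for t in itertools.product("ACGT", repeat=4))


@dataclass
class ScanResult:
    """Per-motif hypergeometric tests, sorted by p."""

    table: object          # DataFrame: motif, N, m, n, k, p, p_bonferroni
    alpha: float
    expected_false_positives: float


def _contiguous_eligible(mutable: np.ndarray, motif_len: int) -> np.ndarray:
    """Start positions whose motif occurrence would overlap or abut a
    mutable site: any of columns i-1 .. i+motif_len mutable."""
    L = mutable.size
    n_pos = L - motif_len + 1
    elig = np.zeros(n_pos, dtype=bool)
    for off in range(-1, motif_len + 1):
        lo = max(0, -off)
        hi = min(n_pos, L - off)
        elig[lo:hi] |= mutable[lo + off: hi + off]
    return elig


def tetranucleotide_scan(collection, radius: int = 5, alpha: float = 0.01,
                         use_indels: bool = True) -> ScanResult:
    """Hypergeometric association of each 4-mer with the mutable sites.

    The mutability map is built from all observed mutations (or, with
    ``use_indels=False``, substitutions only).  For each motif, n is its
    occurrence count in the gene, k the occurrences contiguous
    (overlapping or immediately adjacent) with a mutable site, and the
    draw space is the gene's candidate start positions with the same
    contiguity predicate defining the m successes.  Motifs absent from
    the gene are skipped; p values are raw, with a Bonferroni column for
    convenience and the chance expectation 256*alpha reported alongside.
    """
    import pandas as pd

    gene = collection.gene
    L = len(gene)
    if L < 4:
        return ScanResult(table=pd.DataFrame(
            columns=["motif", "N", "m", "n", "k", "p", "p_bonferroni"]),
            alpha=alpha, expected_false_positives=256 * alpha)
    positions = [p for p, kind in collection.events
                 if use_indels or kind == "substitution"]
    amap = build_mutability_map(L, positions, radius)
    elig = _contiguous_eligible(amap.mutable, 4)
    N = L - 3
    m = int(elig.sum())
    rows = []
    for motif in ALL_TETRAMERS:
        starts = []
        i = gene.find(motif)
        while i != -1:
            starts.append(i)
            i = gene.find(motif, i + 1)
        n = len(starts)
        if n == 0:
            continue
        k = int(elig[np.asarray(starts)].sum())
        p = hypergeom_tail(N, m, n, k)
        rows.append((motif, N, m, n, k, p, min(1.0, p * 256)))
    table = pd.DataFrame(rows, columns=["motif", "N", "m", "n", "k", "p",
                                        "p_bonferroni"])
    table = table.sort_values("p", kind="stable").reset_index(drop=True)
    return ScanResult(table=table, alpha=alpha,
                      expected_false_positives=256 * alpha)
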