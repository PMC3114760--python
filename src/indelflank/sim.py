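"""Synthetic sequence evolution under a repeat-localised mutation model.

This module generates the data every other module consumes: orthologous
region pairs/triples/quartets evolved from a random ancestor, with

* a baseline per-branch substitution rate (expected substitutions/site),
* an optional *region effect*: a multiplicative rate elevation within a
  fixed radius of implanted repeat tracts (modelling recurrent recruitment
  of error-prone polymerases to polymerase-stalling motifs),
* an optional transversion bias restricted to the same repeat
  neighbourhood,
* indels (geometric lengths), optionally anchored at repeats, and
* an optional *transient pulse*: extra substitutions deposited once, on
  the indel-bearing lineage, at indel birth (modelling a single
  multi-mutation event).

Everything is reproducible from ``(config, seed)``; per-branch PRNG
streams are split hierarchically so adding lineages does not perturb
existing ones.

Two generation paths are provided.  :func:`evolve_lineages` is the fully
general single-region path (arbitrary topology, random indels, evolving
inserted material) used for oracle-equivalence tests.
:func:`simulate_region_set` is a vectorised batch path that produces many
independent regions each carrying exactly one indel at the region centre
-- the configuration used throughout the downstream analyses.

The module also simulates Luria-Delbruck fluctuation assays
(:func:`simulate_fluctuation`) and independent single-gene mutant
collections with configurable motif-proximal enrichment
(:func:`generate_mutant_collection`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .alignments import GAP_CODE, decode_codes, AlignedRegionPair

__all__ = [
    "SimConfig",
    "ConfigError",
    "Ancestor",
    "TruthEvent",
    "TruthLog",
    "Branch",
    "pair_topology",
    "triple_topology",
    "quartet_topology",
    "generate_ancestor",
    "evolve_lineages",
    "RegionSet",
    "simulate_region_set",
    "simulate_fluctuation",
    "MutantCollection",
    "generate_mutant_collection",
]

_A, _C, _G, _T = 0, 1, 2, 3


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the region-effect ("3R") mutation model.

    Attributes
    ----------
    length : int
        Ancestor length in bp.
    gc_fraction : float
        Expected G+C proportion of the random ancestor.
    repeat_spec : tuple of (motif, copies, count)
        Repeat tracts to implant: each entry implants ``count``
        non-overlapping tracts of ``motif * copies``.
    divergence_per_branch : float
        Baseline expected substitutions/site on each branch (far from
        repeats).  Branch lengths in a topology override this.
    region_multiplier : float
        Rate factor (lambda >= 1) applied within ``region_radius`` bp of
        any implanted repeat tract.
    region_radius : int
        Radius in bp of the elevated-rate region around repeat tracts.
    tv_bias_near_repeat : float or None
        Probability that a substitution inside the repeat region is a
        transversion.  ``None`` keeps the far-field composition.
    ts_fraction : float
        Far-field probability that a substitution is a transition
        (default 2/3, i.e. a 2:1 transition bias).
    indel_rate : float
        Expected indel events per site per branch (general path only).
    indel_at_repeat_fraction : float
        Fraction of indels anchored at an implanted repeat tract.
    indel_mean_length : float
        Mean of the geometric indel-length distribution (bp).
    transient_indel_pulse : float
        Expected number of extra substitutions deposited once, within
        ``pulse_radius`` of a new indel, on the indel lineage.
    pulse_radius : int
        Radius in bp of the transient pulse.
    seed : int
        PRNG seed; identical (config, seed) reproduces outputs exactly.
    """

    length: int = 2101
    gc_fraction: float = 0.5
    repeat_spec: tuple = ()
    divergence_per_branch: float = 0.005
    region_multiplier: float = 1.0
    region_radius: int = 50
    tv_bias_near_repeat: float | None = None
    ts_fraction: float = 2.0 / 3.0
    indel_rate: float = 0.0
    indel_at_repeat_fraction: float = 0.0
    indel_mean_length: float = 2.0
    transient_indel_pulse: float = 0.0
    pulse_radius: int = 50
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.length <= 0:
            raise ConfigError("length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigError("gc_fraction must be in [0, 1]")
        if self.region_multiplier < 1.0:
            raise ConfigError("region_multiplier must be >= 1")
        for name in ("divergence_per_branch", "indel_rate",
                     "indel_at_repeat_fraction", "transient_indel_pulse"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.tv_bias_near_repeat is not None and not 0.0 <= self.tv_bias_near_repeat <= 1.0:
            raise ConfigError("tv_bias_near_repeat must be in [0, 1]")
        if self.indel_mean_length < 1.0:
            raise ConfigError("indel_mean_length must be >= 1")
        total_repeat = sum(len(m) * c * k for m, c, k in self.repeat_spec)
        if total_repeat > self.length:
            raise ConfigError("total implanted repeat bp exceeds ancestor length")
        return self


@dataclass
class Ancestor:
    """A random ancestral sequence with logged repeat implants."""

    codes: np.ndarray                      # uint8 in {0..3}
    implants: list                         # (start, end, motif) half-open

    @property
    def sequence(self) -> str:
        return decode_codes(self.codes)

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class TruthEvent:
    lineage: str
    pos: int            # position on the ancestor coordinate (floor for insertions)
    kind: str           # substitution | insertion | deletion
    detail: str         # "A>G" for substitutions, length for indels
    near_repeat: bool


@dataclass
class TruthLog:
    """Ground-truth record of every mutational event in a simulation."""

    events: list = field(default_factory=list)

    def add(self, *args) -> None:
        self.events.append(TruthEvent(*args))

    def of_kind(self, kind: str) -> list:
        return [e for e in self.events if e.kind == kind]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(e.lineage, e.pos, e.kind, e.detail, e.near_repeat) for e in self.events],
            columns=["lineage", "pos", "kind", "detail", "near_repeat"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# topology

@dataclass(frozen=True)
class Branch:
    """A branch of the (rooted) simulation topology.

    ``length`` is the expected substitutions/site accumulated along the
    branch leading to this node; the root carries length 0.
    """

    name: str
    length: float
    children: tuple = ()

    def leaves(self) -> list:
        if not self.children:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def validate(self) -> "Branch":
        if self.length < 0:
            raise ConfigError(f"negative branch length on {self.name!r}")
        for ch in self.children:
            ch.validate()
        return self


def pair_topology(d: float, names=("A", "B")) -> Branch:
    """Two lineages diverging from a common ancestor, each of length d."""
    return Branch("root", 0.0, tuple(Branch(n, d) for n in names))


def triple_topology(d_in: float, d_out: float, names=("A", "B", "OUT")) -> Branch:
    """Two ingroup lineages (length ``d_in``) plus an outgroup (``d_out``)."""
    a, b, o = names
    return Branch("root", 0.0, (Branch(a, d_in), Branch(b, d_in), Branch(o, d_out)))


def quartet_topology(d_recent: float, d_deep: float,
                     names=("A1", "A2", "B1", "B2")) -> Branch:
    """Two recently diverged pairs separated by deep internal branches."""
    a1, a2, b1, b2 = names
    return Branch(
        "root", 0.0,
        (
            Branch("A", d_deep, (Branch(a1, d_recent), Branch(a2, d_recent))),
            Branch("B", d_deep, (Branch(b1, d_recent), Branch(b2, d_recent))),
        ),
    )


# ---------------------------------------------------------------------------
# ancestor generation

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


_CODE_OF = {"A": 0, "C": 1, "G": 2, "T": 3}


def _motif_codes(motif: str, copies: int) -> np.ndarray:
    tract = motif.upper() * copies
    try:
        return np.array([_CODE_OF[b] for b in tract], dtype=np.uint8)
    except KeyError as exc:
        raise ConfigError(f"repeat motif {motif!r} contains non-ACGT base") from exc


def generate_ancestor(cfg: SimConfig, rng=None) -> Ancestor:
    """Draw a random ancestor and implant the configured repeat tracts.

    Tracts are placed uniformly at random without overlap; placement
    failure after many attempts (or total repeat bp > length) raises
    :class:`ConfigError`.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    codes = rng.choice(4, size=cfg.length, p=_base_probs(cfg.gc_fraction)).astype(np.uint8)
    implants: list = []
    occupied = np.zeros(cfg.length, dtype=bool)
    for motif, copies, count in cfg.repeat_spec:
        tract = _motif_codes(motif, copies)
        tlen = len(tract)
        if tlen > cfg.length:
            raise ConfigError("repeat tract longer than ancestor")
        for _ in range(count):
            for _attempt in range(1000):
                s = int(rng.integers(0, cfg.length - tlen + 1))
                if not occupied[s:s + tlen].any():
                    break
            else:
                raise ConfigError("could not place repeat tracts without overlap")
            codes[s:s + tlen] = tract
            occupied[s:s + tlen] = True
            implants.append((s, s + tlen, motif))
    implants.sort()
    return Ancestor(codes=codes, implants=implants)


def _zone_profiles(length: int, implants, cfg: SimConfig):
    """Per-site rate multiplier and transversion probability."""
    mult = np.ones(length)
    tvp = np.full(length, 1.0 - cfg.ts_fraction)
    for s, e, _m in implants:
        lo = max(0, s - cfg.region_radius)
        hi = min(length, e + cfg.region_radius)
        mult[lo:hi] = cfg.region_multiplier
        if cfg.tv_bias_near_repeat is not None:
            tvp[lo:hi] = cfg.tv_bias_near_repeat
    return mult, tvp


def _substitute(rng, frm: np.ndarray, tvp: np.ndarray) -> np.ndarray:
    """Vectorised substitution targets.

    Transitions pair A<->G and C<->T, which is ``code ^ 2``; the two
    transversion partners are ``code ^ 1`` and ``code ^ 3``.
    """
    istv = rng.random(len(frm)) < tvp
    flip = np.where(rng.random(len(frm)) < 0.5, 1, 3)
    return np.where(istv, frm ^ flip, frm ^ 2).astype(np.uint8)


# ---------------------------------------------------------------------------
# general single-region evolution

def _geometric_lengths(rng, n: int, mean: float, cap: int = 50) -> np.ndarray:
    p = 1.0 / mean
    return np.minimum(rng.geometric(p, size=n), cap)


def evolve_lineages(ancestor: Ancestor, cfg: SimConfig, topology: Branch,
                    seed=None, forced_indels=None,
                    region_id: str = "region0") -> tuple:
    """Evolve an ancestor along a rooted topology; return the true alignment.

    Substitution counts per site are Poisson with rate ``branch length x
    local multiplier``; multiple hits at one site are applied (and
    logged) individually.  Indels arise at rate ``cfg.indel_rate`` per
    site per branch with geometric lengths; inserted material is evolved
    on descendant branches.  ``forced_indels`` is an optional list of
    ``(branch_name, ancestor_pos, kind, length)`` tuples injected
    deterministically (used to plant indels at known sites).

    Returns ``(AlignedRegionPair, TruthLog)``; the emitted alignment is
    the truth alignment, with gaps exactly at logged indels.
    """
    cfg.validate()
    topology.validate()
    if seed is None:
        seed = cfg.seed
    mult, tvp = _zone_profiles(len(ancestor), ancestor.implants, cfg)
    near = mult > 1.0
    log = TruthLog()
    leaves: list = []
    forced = forced_indels or []
    counter = [0]  # per-region event counter, keeps insertion keys distinct

    def pos_of(key: float) -> int:
        return min(int(key), len(ancestor) - 1)

    def apply_subs(rng, keys, bases, branch_name, d):
        posint = np.minimum(keys.astype(np.int64), len(ancestor) - 1)
        counts = rng.poisson(d * mult[posint])
        max_c = int(counts.max(initial=0))
        for rnd in range(1, max_c + 1):
            idx = np.flatnonzero(counts >= rnd)
            if idx.size == 0:
                break
            frm = bases[idx].copy()
            to = _substitute(rng, frm, tvp[posint[idx]])
            bases[idx] = to
            for i, f, t in zip(idx, frm, to):
                log.add(branch_name, pos_of(keys[i]), "substitution",
                        f"{'ACGT'[f]}>{'ACGT'[t]}", bool(near[posint[i]]))

    def insert_keys(keys, i, g):
        lo = keys[i] if i >= 0 else keys[0] - 1.0
        hi = keys[i + 1] if i + 1 < len(keys) else lo + 1.0
        counter[0] += 1
        jitter = (hi - lo) * 1e-9 * counter[0]
        step = (hi - lo) / (g + 1.001)
        return lo + step * np.arange(1, g + 1) + jitter

    def apply_indel(rng, keys, bases, branch_name, kind, i, g):
        anchor_pos = pos_of(keys[min(i, len(keys) - 1)])
        if kind == "deletion":
            g = min(g, len(keys) - i)
            if g <= 0 or len(keys) - g < 2:
                return keys, bases
            keys = np.delete(keys, slice(i, i + g))
            bases = np.delete(bases, slice(i, i + g))
        else:
            newk = insert_keys(keys, i, g)
            newb = rng.choice(4, size=g, p=_base_probs(cfg.gc_fraction)).astype(np.uint8)
            keys = np.insert(keys, i + 1, newk)
            bases = np.insert(bases, i + 1, newb)
        log.add(branch_name, anchor_pos, kind, str(g), bool(near[anchor_pos]))
        if cfg.transient_indel_pulse > 0:
            npulse = rng.poisson(cfg.transient_indel_pulse)
            if npulse:
                ok = np.flatnonzero(np.abs(keys - anchor_pos) <= cfg.pulse_radius)
                if ok.size:
                    hit = rng.choice(ok, size=npulse, replace=True)
                    for i2 in hit:
                        f = bases[i2]
                        t = _substitute(rng, np.array([f]), np.array([1 - cfg.ts_fraction]))[0]
                        bases[i2] = t
                        log.add(branch_name, pos_of(keys[i2]), "substitution",
                                f"{'ACGT'[f]}>{'ACGT'[t]}", bool(near[pos_of(keys[i2])]))
        return keys, bases

    def walk(node, keys, bases, ss):
        rng = np.random.default_rng(ss)
        if node.length > 0 or node.name != "root":
            apply_subs(rng, keys, bases, node.name, node.length)
            for bname, pos, kind, g in forced:
                if bname == node.name:
                    i = int(np.searchsorted(keys, pos))
                    i = min(i, len(keys) - 1)
                    keys, bases = apply_indel(rng, keys, bases, node.name, kind, i, int(g))
            n_ind = rng.poisson(cfg.indel_rate * len(keys))
            for _ in range(n_ind):
                g = int(_geometric_lengths(rng, 1, cfg.indel_mean_length)[0])
                if ancestor.implants and rng.random() < cfg.indel_at_repeat_fraction:
                    s, e, _m = ancestor.implants[rng.integers(len(ancestor.implants))]
                    pos = int(rng.integers(s, e))
                    i = min(int(np.searchsorted(keys, pos)), len(keys) - 1)
                else:
                    i = int(rng.integers(len(keys)))
                kind = "deletion" if rng.random() < 0.5 else "insertion"
                keys, bases = apply_indel(rng, keys, bases, node.name, kind, i, g)
        if node.children:
            subs = ss.spawn(len(node.children))
            for ch, child_ss in zip(node.children, subs):
                walk(ch, keys.copy(), bases.copy(), child_ss)
        else:
            leaves.append((node.name, keys, bases))

    root_ss = np.random.SeedSequence(seed)
    keys0 = np.arange(len(ancestor), dtype=np.float64)
    walk(topology, keys0, ancestor.codes.copy(), root_ss)

    all_keys = np.unique(np.concatenate([k for _n, k, _b in leaves]))
    rows, names = [], []
    for name, keys, bases in leaves:
        row = np.full(len(all_keys), GAP_CODE, dtype=np.uint8)
        row[np.searchsorted(all_keys, keys)] = bases
        rows.append(decode_codes(row))
        names.append(name)
    region = AlignedRegionPair(region_id=region_id, rows=rows, ids=names)
    return region, log


# ---------------------------------------------------------------------------
# batched region sets (one forced indel per region)

@dataclass
class RegionSet:
    """A batch of independent simulated regions, one indel per region.

    ``indels`` / ``substitutions`` are ground-truth tables
    (pandas DataFrames); ``indel_rows`` gives, per region, the alignment
    row indices that are gapped at the indel.
    """

    regions: list
    leaf_names: list
    indels: object          # DataFrame: region_id, branch, kind, length, col_start, col_end
    substitutions: object   # DataFrame: region_id, branch, pos, from_base, to_base, near_repeat, pulse
    indel_rows: list
    config: SimConfig

    def __len__(self) -> int:
        return len(self.regions)


def _leaves_under(topology: Branch):
    """Map branch name -> leaf-index set, leaves in topology order."""
    leaf_names = [l.name for l in topology.leaves()]
    index = {n: i for i, n in enumerate(leaf_names)}

    under = {}

    def walk(node):
        if not node.children:
            under[node.name] = {index[node.name]}
            return under[node.name]
        s = set()
        for ch in node.children:
            s |= walk(ch)
        under[node.name] = s
        return s

    walk(topology)
    return leaf_names, under


def simulate_region_set(cfg: SimConfig, n_regions: int, topology: Branch = None,
                        indel_branches=None, branch_probs=None,
                        indel_kinds=("deletion", "insertion"),
                        seed=None, region_prefix: str = "region") -> RegionSet:
    """Vectorised batch of regions, each with exactly one indel at its centre.

    Every region has an independent random ancestor of ``cfg.length``; if
    ``cfg.repeat_spec`` is non-empty the first tract is implanted at the
    region centre and the indel falls inside it (indel-at-repeat
    condition), otherwise the indel sits in plain sequence.  The forced
    indel is assigned to a branch drawn from ``indel_branches`` (default:
    the leaf branches; for quartets include internal branches to generate
    "old" indels).  Substitutions are Poisson per site with the
    region-effect multiplier; the transient pulse, if configured, adds
    substitutions on the indel lineage within ``pulse_radius`` of the
    indel anchors.
    """
    import pandas as pd

    cfg.validate()
    if topology is None:
        topology = pair_topology(cfg.divergence_per_branch)
    topology.validate()
    if seed is None:
        seed = cfg.seed
    L = cfg.length
    c0 = L // 2
    leaf_names, under = _leaves_under(topology)
    n_leaves = len(leaf_names)
    if indel_branches is None:
        indel_branches = [n for n in leaf_names]
    if branch_probs is None:
        branch_probs = [1.0 / len(indel_branches)] * len(indel_branches)

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    # ancestors: (n_regions, L) with the first repeat tract implanted centred
    anc = rng.choice(4, size=(n_regions, L), p=_base_probs(cfg.gc_fraction)).astype(np.uint8)
    implants = []
    if cfg.repeat_spec:
        motif, copies, _count = cfg.repeat_spec[0]
        tract = _motif_codes(motif, copies)
        ts = c0 - len(tract) // 2
        anc[:, ts:ts + len(tract)] = tract
        implants = [(ts, ts + len(tract), motif)]
    mult, tvp = _zone_profiles(L, implants, cfg)
    near = mult > 1.0

    # forced indel parameters per region
    glen = _geometric_lengths(rng, n_regions, cfg.indel_mean_length, cap=40)
    kind_idx = rng.integers(0, len(indel_kinds), size=n_regions)
    kinds = np.array(indel_kinds)[kind_idx]
    br_idx = rng.choice(len(indel_branches), size=n_regions, p=branch_probs)
    branches = np.array(indel_branches)[br_idx]

    # evolve: per-branch substitution matrices accumulated down the tree
    sub_events = {"region": [], "branch": [], "pos": [], "frm": [], "to": []}

    def apply_branch(branch_rng, mat, d, branch_name):
        if d <= 0:
            return
        counts = branch_rng.poisson(d * mult[None, :], size=mat.shape)
        max_c = int(counts.max(initial=0))
        for rnd in range(1, max_c + 1):
            rs, cs = np.nonzero(counts >= rnd)
            if rs.size == 0:
                break
            frm = mat[rs, cs].copy()
            to = _substitute(branch_rng, frm, tvp[cs])
            mat[rs, cs] = to
            sub_events["region"].append(rs)
            sub_events["branch"].append(np.full(rs.size, branch_name, dtype=object))
            sub_events["pos"].append(cs)
            sub_events["frm"].append(frm)
            sub_events["to"].append(to)

    leaf_mats = {}

    def walk(node, mat, node_ss):
        branch_rng = np.random.default_rng(node_ss)
        if node.name != "root":
            apply_branch(branch_rng, mat, node.length, node.name)
        if node.children:
            for ch, child_ss in zip(node.children, node_ss.spawn(len(node.children))):
                walk(ch, mat.copy() if len(node.children) > 1 else mat, child_ss)
        else:
            leaf_mats[node.name] = mat

    walk(topology, anc.copy(), ss.spawn(1)[0])

    # transient pulse on the indel lineage(s)
    pulse_flags = []
    if cfg.transient_indel_pulse > 0:
        npulse = rng.poisson(cfg.transient_indel_pulse, size=n_regions)
        for i in np.flatnonzero(npulse):
            g = int(glen[i])
            for _ in range(int(npulse[i])):
                off = int(rng.integers(1, cfg.pulse_radius + 1))
                side = rng.random() < 0.5
                if kinds[i] == "deletion":
                    col = c0 - off if side else c0 + g + off - 1
                else:
                    col = c0 - off if side else c0 + off - 1
                col = int(np.clip(col, 0, L - 1))
                frm = None
                for leaf in under[branches[i]]:
                    mat = leaf_mats[leaf_names[leaf]]
                    if frm is None:
                        frm = int(mat[i, col])
                        to = int(_substitute(rng, np.array([frm], dtype=np.uint8),
                                             np.array([1 - cfg.ts_fraction]))[0])
                    mat[i, col] = to
                sub_events["region"].append(np.array([i]))
                sub_events["branch"].append(np.array([branches[i]], dtype=object))
                sub_events["pos"].append(np.array([col]))
                sub_events["frm"].append(np.array([frm], dtype=np.uint8))
                sub_events["to"].append(np.array([to], dtype=np.uint8))
                pulse_flags.append(len(pulse_flags))

    # assemble aligned regions
    regions, indel_rows, ind_rows_tab = [], [], []
    ins_bases_cache = {}
    for i in range(n_regions):
        g = int(glen[i])
        b = branches[i]
        gap_leaves = under[b] if kinds[i] == "deletion" else set(range(n_leaves)) - under[b]
        rows = []
        if kinds[i] == "deletion":
            for j, name in enumerate(leaf_names):
                codes = leaf_mats[name][i]
                if j in gap_leaves:
                    codes = codes.copy()
                    codes[c0:c0 + g] = GAP_CODE
                rows.append(decode_codes(codes))
            col_start, col_end = c0, c0 + g
        else:
            if implants:
                # slippage-style duplication of the sequence at the anchor,
                # so insertions at a repeat tract extend the repeat
                ins = anc[i, c0:c0 + g].copy()
            else:
                ins = rng.choice(4, size=g,
                                 p=_base_probs(cfg.gc_fraction)).astype(np.uint8)
            ins_bases_cache[i] = ins
            gap_seg = np.full(g, GAP_CODE, dtype=np.uint8)
            for j, name in enumerate(leaf_names):
                codes = leaf_mats[name][i]
                seg = gap_seg if j in gap_leaves else ins
                rows.append(decode_codes(np.concatenate([codes[:c0], seg, codes[c0:]])))
            col_start, col_end = c0, c0 + g
        rid = f"{region_prefix}{i:05d}"
        regions.append(AlignedRegionPair(region_id=rid, rows=rows, ids=list(leaf_names)))
        indel_rows.append(tuple(sorted(gap_leaves)))
        ind_rows_tab.append((rid, b, kinds[i], g, col_start, col_end))

    indels = pd.DataFrame(ind_rows_tab, columns=["region_id", "branch", "kind",
                                                 "length", "col_start", "col_end"])
    if sub_events["region"]:
        reg = np.concatenate(sub_events["region"])
        subs = pd.DataFrame({
            "region_id": [f"{region_prefix}{r:05d}" for r in reg],
            "branch": np.concatenate(sub_events["branch"]),
            "pos": np.concatenate(sub_events["pos"]),
            "from_base": [("ACGT")[c] for c in np.concatenate(sub_events["frm"])],
            "to_base": [("ACGT")[c] for c in np.concatenate(sub_events["to"])],
            "near_repeat": near[np.concatenate(sub_events["pos"])],
        })
    else:
        subs = pd.DataFrame(columns=["region_id", "branch", "pos", "from_base",
                                     "to_base", "near_repeat"])
    return RegionSet(regions=regions, leaf_names=list(leaf_names), indels=indels,
                     substitutions=subs, indel_rows=indel_rows, config=cfg)


# ---------------------------------------------------------------------------
# fluctuation assays

def simulate_fluctuation(m_true: float, Nt: int, n_cultures: int, seed=None, rng=None):
    """Simulate per-culture mutant counts under the Lea-Coulson model.

    Mutational events per culture are Poisson(``m_true``); each event
    founds a clone whose final size follows P(S >= k) = 1/k (the
    deterministic-growth clone-size law), sampled as ``floor(1/U)`` and
    capped at ``Nt``.  The resulting counts follow the Luria-Delbruck
    (Lea-Coulson) distribution with parameter ``m_true``.
    """
    if m_true < 0:
        raise ValueError("m_true must be >= 0")
    if Nt < 1 or n_cultures < 1:
        raise ValueError("Nt and n_cultures must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_mut = rng.poisson(m_true, size=n_cultures)
    total = int(n_mut.sum())
    if total == 0:
        return np.zeros(n_cultures, dtype=np.int64)
    sizes = np.minimum(np.floor(1.0 / rng.random(total)), Nt).astype(np.int64)
    culture = np.repeat(np.arange(n_cultures), n_mut)
    counts = np.bincount(culture, weights=sizes, minlength=n_cultures)
    return np.minimum(counts, Nt).astype(np.int64)


# ---------------------------------------------------------------------------
# mutant collections

@dataclass
class MutantCollection:
    """Independent single-event mutants of one gene.

    ``events`` is a list of ``(position, kind)`` with kind in
    {"substitution", "indel"}; ``gene`` is the gene sequence the
    positions refer to.
    """

    gene: str
    events: list
    cluster_motifs: tuple = ()

    @property
    def substitution_positions(self):
        return [p for p, k in self.events if k == "substitution"]

    @property
    def indel_positions(self):
        return [p for p, k in self.events if k == "indel"]


def _motif_starts(seq: str, motif: str):
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def generate_mutant_collection(gene_length: int, n_mutants: int, cluster_motifs=(),
                               cluster_odds: float = 1.0, seed=None, gene: str = None,
                               indel_fraction: float = 0.25,
                               radius: int = 5) -> MutantCollection:
    """Draw independent mutants of a single gene with motif-proximal enrichment.

    Each mutant is one event at one site; sites within ``radius`` bp of
    any occurrence of a ``cluster_motifs`` entry carry ``cluster_odds``
    times the baseline mutation probability.  Kinds are substitution or
    indel with fixed proportions.
    """
    if cluster_odds < 1.0:
        raise ConfigError("cluster_odds must be >= 1")
    if n_mutants < 0:
        raise ConfigError("n_mutants must be >= 0")
    if n_mutants > 5 * gene_length:
        raise ConfigError("n_mutants exceeds the saturation bound (5 x gene length)")
    rng = np.random.default_rng(seed)
    if gene is None:
        gene = decode_codes(rng.choice(4, size=gene_length).astype(np.uint8))
    elif len(gene) != gene_length:
        raise ConfigError("gene length does not match gene_length")
    weights = np.ones(gene_length)
    for motif in cluster_motifs:
        for s in _motif_starts(gene, motif):
            weights[max(0, s - radius): s + len(motif) + radius] = cluster_odds
    if n_mutants == 0:
        return MutantCollection(gene=gene, events=[], cluster_motifs=tuple(cluster_motifs))
    pos = rng.choice(gene_length, size=n_mutants, replace=True, p=weights / weights.sum())
    is_indel = rng.random(n_mutants) < indel_fraction
    events = [(int(p), "indel" if b else "substitution") for p, b in zip(pos, is_indel)]
    return MutantCollection(gene=gene, events=events, cluster_motifs=tuple(cluster_motifs))
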