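# indelflank

Analysis of **indel-proximal nucleotide-substitution clustering**: do the
sequences flanking insertion/deletion mutations accumulate extra
substitutions, and is that excess caused by the indel itself or by the
mutagenic *region* (typically a repeat tract) in which the indel sits?

The package is aimed at molecular-evolution and mutation-rate
researchers working with pairwise or multi-genome alignments of closely
related strains (bacteria, yeasts, flies, segmental duplications), and
at anyone running fluctuation assays or single-gene mutant-collection
analyses.

## What it computes

**Windowed divergence profiles.** For every indel (a maximal gap run in
an aligned orthologous region), 1 kb of flanking alignment on each side
is split into distance windows — W1 the 50 columns nearest the indel,
W2–W9 of 100 columns, W10 the outermost 150 — and per-window divergence
is the Jukes–Cantor distance

    D = -(3/4) ln(1 - 4p/3),    p = mismatches / comparable sites,

pooled over all usable flanks.  The background divergence **Db** is the
mean D over windows 3–10; **DW1 − Db** is the indel-associated excess.

**Haplotype partition with an outgroup.**  With a third genome the
lineage carrying each indel is inferred by parsimony, splitting the
window-1 divergence into **Di** (indel haplotype vs outgroup, indel +
region effect), **Dni** (non-indel haplotype vs outgroup, region effect
only) and Db.  The attribution ratio

    R = (Di - Db) / (Dni - Db)

equals 1 when the indel adds nothing beyond the regional effect.

**Old vs new indels.**  In four-genome alignments of two recently
diverged pairs, a gap private to one genome is *new* (post-split), a gap
shared by one pair is *old* (pre-split); divergence profiles of the two
classes test whether flanking substitutions keep accumulating over time.

**Spectra, repeats, clustering, rates.**  Transition/transversion
spectra by window; homopolymer-run detection with contiguous/proximal
classification of indels and repeat-density binning of 100-bp windows;
a hypergeometric test for the co-clustering of indels, substitutions
and tetranucleotide motifs in a single-gene mutant collection; and
Luria–Delbrück fluctuation-assay rates via the Ma–Sandri–Sarkar maximum
likelihood (µ = m/Nt, Rosche–Foster 95% CIs, Welch t-tests between
strains).

**Synthetic data.**  All analyses are exercised end-to-end on alignments
evolved under a configurable *region-effect* model: a baseline
substitution rate per branch, multiplied by λ within a fixed radius of
repeat tracts (optionally transversion-biased there), indels anchored at
repeats, and an optional one-off mutation pulse at indel birth.  The
simulator emits truth logs so every caller can be validated exactly.

## Worked example

```python
import numpy as np
import indelflank as f

cfg = f.SimConfig(length=2101, repeat_spec=(("A", 6, 1),),
                  region_multiplier=3.0, region_radius=50,
                  divergence_per_branch=0.005, seed=0)
rs = f.simulate_region_set(cfg, 500, seed=1)

items = []
for region in rs.regions:
    (indel,) = f.find_indels(region)
    items.append((region, f.extract_flanks(region, indel, [indel])))
profile = f.window_profile(items)

print("D per window:", np.round(profile.d, 4))
print(f"DW1 = {profile.dw1:.4f}, Db = {profile.db:.4f}, "
      f"excess DW1-Db = {profile.excess:.4f}")
```

prints

```
D per window: [0.0303 0.0106 0.0105 0.0101 0.0093 0.0095 0.0097 0.0094 0.0098 0.0103]
DW1 = 0.0303, Db = 0.0098, excess DW1-Db = 0.0205
```

Each of the 500 regions diverged at 0.5% per branch (1% pairwise) and
carries one indel inside a 6-bp poly(A) tract whose 50-bp neighbourhood
mutates 3× faster.  The window-1 divergence (0.0303) recovers the 3×
elevation over the background Db (0.0098) almost exactly; windows 2–10
sit at the background, showing the effect is confined to the sequence
nearest the indel.

## Command line

Every stage is also a CLI verb operating on files
(`indelflank --help`): `simulate`, `indels`, `profile`, `haplotypes`,
`oldnew`, `spectra`, `repeats`, `cluster-test`, `fluctuation`, `stats`.
Each run writes TSV outputs plus a JSON manifest of parameters and
per-filter counts.

```bash
indelflank simulate --mode triple --n-regions 200 --region-multiplier 3 \
    --repeat-motif A --divergence 0.005 --seed 1 --out sim/
indelflank haplotypes sim/regions.fasta --min-len 2000 --out hap/
```

## Analysis scripts

`analysis/01_simulate_regions.py` … `06_mutation_clustering_rates.py`
are thin narrative drivers that run the library end-to-end on the
synthetic cohorts and write their tables under `results/analysis/`.
Run them in order from the repository root.

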