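"""End-to-end runs over files: load, filter, analyse, write TSVs + manifest.

Each ``run_*`` function is a thin orchestration of the library modules:
it reads standard inputs (aligned FASTA, TSV tables), applies the
configured filters, runs one analysis, and writes TSV outputs plus a
JSON run manifest recording parameters and per-filter counts.  Outputs
are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .alignments import (FilterCounts, dedupe_indels, filter_orthologous,
                         find_indels, load_alignments, write_alignments)
from .windows import DEFAULT_SCHEME, WindowScheme, extract_flanks, window_profile

__all__ = [
    "scheme_by_name",
    "run_simulate",
    "run_profile",
    "run_haplotypes",
    "run_oldnew",
    "run_spectra",
    "run_repeats",
    "run_cluster",
    "run_fluctuation",
    "run_stats",
]


def scheme_by_name(name: str) -> WindowScheme:
    if name == "default":
        return DEFAULT_SCHEME
    if name == "all50":
        return WindowScheme.all50()
    if name == "all100":
        return WindowScheme.all100()
    raise ValueError(f"unknown window scheme {name!r}")


def _write_manifest(out_dir: Path, stage: str, params: dict, counts: dict) -> Path:
    manifest = {
        "stage": stage,
        "version": __version__,
        "parameters": params,
        "counts": counts,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path


def _prepare(aln_path, out_dir, min_len, min_identity, require_indel,
             dedupe=False, flank_len=1000):
    """Shared front end: load -> filter -> call indels -> flanks."""
    regions = load_alignments(aln_path)
    counts = FilterCounts()
    kept = filter_orthologous(regions, min_len=min_len, min_identity=min_identity,
                              require_indel=require_indel, counts=counts)
    items = []
    all_events = []
    by_id = {}
    for reg in kept:
        evs = find_indels(reg)
        by_id[reg.region_id] = reg
        all_events.extend(evs)
    if dedupe:
        all_events = dedupe_indels(all_events, by_id)
    n_usable = 0
    events_by_region: dict = {}
    for ev in all_events:
        events_by_region.setdefault(ev.region_id, []).append(ev)
    for rid, evs in events_by_region.items():
        reg = by_id[rid]
        for ev in evs:
            fs = extract_flanks(reg, ev, evs, flank_len=flank_len)
            if fs.any_usable:
                n_usable += 1
            items.append((reg, ev, fs))
    stats = {
        "filter": asdict(counts),
        "indels_called": len(all_events),
        "indels_with_usable_flank": n_usable,
    }
    return items, stats


def run_simulate(params: dict, out_dir) -> dict:
    """Simulate a region set from a parameter dict and write it out.

    Recognised keys: every SimConfig field, plus ``mode`` (pair, triple,
    quartet), ``n_regions``, ``divergence`` (per recent branch),
    ``outgroup_divergence``, ``deep_divergence``, ``seed``.
    """
    from .sim import (SimConfig, pair_topology, quartet_topology,
                      simulate_region_set, triple_topology)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mode = params.get("mode", "pair")
    n_regions = int(params.get("n_regions", 100))
    seed = int(params.get("seed", 0))
    cfg_keys = SimConfig.__dataclass_fields__.keys()
    cfg_kwargs = {k: v for k, v in params.items() if k in cfg_keys}
    if "repeat_spec" in cfg_kwargs:
        cfg_kwargs["repeat_spec"] = tuple(tuple(r) for r in cfg_kwargs["repeat_spec"])
    d = float(params.get("divergence", cfg_kwargs.get("divergence_per_branch", 0.005)))
    cfg = SimConfig(**{**cfg_kwargs, "divergence_per_branch": d})
    if mode == "pair":
        topo, branches = pair_topology(d), None
    elif mode == "triple":
        topo = triple_topology(d, float(params.get("outgroup_divergence", d)))
        branches = ["A", "B"]
    elif mode == "quartet":
        topo = quartet_topology(d, float(params.get("deep_divergence", 10 * d)))
        branches = ["A1", "A2", "B1", "B2", "A", "B"]
    else:
        raise ValueError(f"unknown simulate mode {mode!r}")
    rs = simulate_region_set(cfg, n_regions, topology=topo,
                             indel_branches=branches, seed=seed)
    write_alignments(rs.regions, out_dir / "regions.fasta")
    rs.indels.to_csv(out_dir / "truth_indels.tsv", sep="\t", index=False)
    rs.substitutions.to_csv(out_dir / "truth_substitutions.tsv", sep="\t", index=False)
    import yaml

    (out_dir / "config.yaml").write_text(
        yaml.safe_dump({**{k: getattr(cfg, k) for k in cfg_keys},
                        "repeat_spec": [list(r) for r in cfg.repeat_spec],
                        "mode": mode, "n_regions": n_regions, "seed": seed}))
    counts = {"regions": len(rs), "indels": len(rs.indels),
              "substitutions": len(rs.substitutions)}
    _write_manifest(out_dir, "simulate", params, counts)
    return counts


def run_profile(aln_path, out_dir, min_len: int = 3000, min_identity: float = 80.0,
                require_indel: bool = False, scheme: str = "default",
                flank_len: int = 1000, plot: bool = True) -> dict:
    """Windowed divergence profile of all indels in an alignment file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sch = scheme_by_name(scheme)
    items, stats = _prepare(aln_path, out_dir, min_len, min_identity,
                            require_indel, flank_len=flank_len)
    prof = window_profile([(reg, fs) for reg, _ev, fs in items], scheme=sch)
    prof.to_frame().to_csv(out_dir / "windows.tsv", sep="\t", index=False)
    import pandas as pd

    per = pd.DataFrame(prof.per_indel_d,
                       columns=[f"w{i + 1}" for i in range(sch.n_windows)])
    per.insert(0, "indel", np.arange(len(per)))
    per.to_csv(out_dir / "per_indel_d.tsv", sep="\t", index=False, na_rep="NA")
    if plot and prof.n_indels:
        _plot_profile(prof, out_dir / "profile.png")
    stats.update({"n_profiled_indels": prof.n_indels,
                  "dw1": prof.dw1, "db": prof.db})
    _write_manifest(out_dir, "profile",
                    {"min_len": min_len, "min_identity": min_identity,
                     "scheme": scheme, "flank_len": flank_len}, stats)
    return stats


def _plot_profile(prof, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    w = np.arange(1, prof.scheme.n_windows + 1)
    ax.plot(w, prof.d, "o-", color="black", label="pooled D")
    ax.axhline(prof.db, ls="--", color="grey", label="Db (windows 3-10)")
    ax.set_xlabel("window (distance from indel)")
    ax.set_ylabel("nucleotide divergence D")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_haplotypes(aln_path, out_dir, min_len: int = 3000,
                   min_identity: float = 80.0, scheme: str = "default",
                   outgroup_row: int = 2) -> dict:
    """Di/Dni/Db partition and attribution ratio from 3-row alignments."""
    from .haplotypes import partition_divergence, polarize_indel

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sch = scheme_by_name(scheme)
    items, stats = _prepare(aln_path, out_dir, min_len, min_identity, False)
    for reg, _e, _fs in items:
        if len(reg.rows) < outgroup_row + 1:
            raise ValueError(f"region {reg.region_id!r} has {len(reg.rows)} rows; "
                             "haplotype partition needs an outgroup row")
    part = partition_divergence([(r, e, fs) for r, e, fs in items],
                                outgroup_row=outgroup_row, scheme=sch)
    part.to_frame().to_csv(out_dir / "haplotype_windows.tsv", sep="\t", index=False)
    import pandas as pd

    pol = pd.DataFrame(
        [(r.region_id, e.start, e.end,
          polarize_indel(r, e, outgroup_row=outgroup_row))
         for r, e, _fs in items],
        columns=["region_id", "col_start", "col_end", "indel_row"])
    pol.to_csv(out_dir / "polarization.tsv", sep="\t", index=False, na_rep="NA")
    stats.update({"n_pairs": part.n_pairs, "di_w1": float(part.di[0]),
                  "dni_w1": float(part.dni[0]), "db": part.db,
                  "attribution_ratio": part.r})
    _write_manifest(out_dir, "haplotypes",
                    {"min_len": min_len, "min_identity": min_identity,
                     "scheme": scheme, "outgroup_row": outgroup_row}, stats)
    return stats


def run_oldnew(aln_path, out_dir, min_len: int = 3000, min_identity: float = 80.0,
               scheme: str = "default") -> dict:
    """Old/new indel classification and profiles from 4-row alignments."""
    from .haplotypes import old_new_divergence

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sch = scheme_by_name(scheme)
    items, stats = _prepare(aln_path, out_dir, min_len, min_identity, False)
    for reg, _e, _fs in items:
        if len(reg.rows) != 4:
            raise ValueError(f"region {reg.region_id!r} has {len(reg.rows)} rows; "
                             "old/new dating needs quartet alignments")
    old, new = old_new_divergence([(r, e, fs) for r, e, fs in items], scheme=sch)
    for name, prof in (("old", old), ("new", new)):
        df = prof.to_frame()
        df.insert(0, "age", name)
        df.to_csv(out_dir / f"{name}_windows.tsv", sep="\t", index=False)
    stats.update({"n_old": old.n_indels, "n_new": new.n_indels,
                  "old_dw1": old.dw1, "new_dw1": new.dw1})
    _write_manifest(out_dir, "oldnew",
                    {"min_len": min_len, "min_identity": min_identity,
                     "scheme": scheme}, stats)
    return stats


def run_spectra(aln_path, out_dir, min_len: int = 3000, min_identity: float = 80.0,
                scheme: str = "default") -> dict:
    """Transition/transversion spectrum by window."""
    from .spectra import spectrum_by_window

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sch = scheme_by_name(scheme)
    items, stats = _prepare(aln_path, out_dir, min_len, min_identity, False)
    spec = spectrum_by_window([(r, fs) for r, _e, fs in items], scheme=sch)
    spec.to_frame().to_csv(out_dir / "spectrum.tsv", sep="\t", index=False)
    rep = None
    if spec.n_indels >= 3:
        try:
            rep = spec.compare_windows(1, 4)
        except ValueError:
            rep = None
    stats.update({"n_indels": spec.n_indels,
                  "tv_fraction_w1": float(spec.tv_fraction[0]),
                  "w1_vs_w4_test": rep.test if rep else None,
                  "w1_vs_w4_p": rep.p if rep else None})
    _write_manifest(out_dir, "spectra",
                    {"min_len": min_len, "min_identity": min_identity,
                     "scheme": scheme}, stats)
    return stats


def run_repeats(aln_path, out_dir, min_len: int = 3000, min_identity: float = 80.0,
                repeat_min_len: int = 4, proximity_window: int = 5,
                bin_width: int = 100) -> dict:
    """Indel-repeat relations, termination histogram, repeat-density bins."""
    import pandas as pd

    from .repeats import (bin_windows_by_repeats, classify_indel_repeat_relation,
                          compare_bins, find_homopolymers,
                          indel_reference_interval, repeat_position_histogram)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    items, stats = _prepare(aln_path, out_dir, min_len, min_identity, False)
    rel_rows, intervals, runs_list, seq_lens = [], [], [], []
    run_cache: dict = {}
    for reg, ev, _fs in items:
        ref_row = 1 if 0 in (ev.gapped_rows or (ev.gapped_row,)) else 0
        key = (reg.region_id, ref_row)
        if key not in run_cache:
            seq = reg.rows[ref_row].replace("-", "")
            run_cache[key] = (find_homopolymers(seq, repeat_min_len), len(seq))
        runs, slen = run_cache[key]
        iv = indel_reference_interval(reg, ev, ref_row)
        rel = classify_indel_repeat_relation(iv, runs, window=proximity_window)
        rel_rows.append((reg.region_id, ev.start, ev.end, rel))
        intervals.append(iv)
        runs_list.append(runs)
        seq_lens.append(slen)
    rel_df = pd.DataFrame(rel_rows, columns=["region_id", "col_start", "col_end",
                                             "relation"])
    rel_df.to_csv(out_dir / "relations.tsv", sep="\t", index=False)
    offsets, counts, n_skip = repeat_position_histogram(intervals, runs_list, seq_lens)
    pd.DataFrame({"offset": offsets, "count": counts}).to_csv(
        out_dir / "histogram.tsv", sep="\t", index=False)
    regions_seen, bin_rows = set(), {}
    for reg, _ev, _fs in items:
        if reg.region_id in regions_seen:
            continue
        regions_seen.add(reg.region_id)
        for b in bin_windows_by_repeats(reg, width=bin_width,
                                        min_len=repeat_min_len):
            agg = bin_rows.setdefault(b.k, [0, 0, 0, 0, 0, []])
            agg[0] += b.n_windows
            agg[1] += b.mismatches
            agg[2] += b.sites
            agg[3] += b.ts
            agg[4] += b.tv
            agg[5].extend(b.per_window_d)
    from .repeats import RepeatBin

    bins = [RepeatBin(k=k, n_windows=v[0], mismatches=v[1], sites=v[2],
                      ts=v[3], tv=v[4], per_window_d=v[5])
            for k, v in sorted(bin_rows.items())]
    pvals = compare_bins(bins)
    pd.DataFrame(
        [(b.k, b.n_windows, b.sites, b.mismatches, b.d, b.ts, b.tv, pvals[b.k])
         for b in bins],
        columns=["k", "n_windows", "sites", "mismatches", "d", "ts", "tv",
                 "p_vs_k0"]).to_csv(out_dir / "repeat_bins.tsv", sep="\t",
                                    index=False, na_rep="NA")
    frac = rel_df["relation"].value_counts(normalize=True).to_dict()
    stats.update({"relation_fractions": frac, "histogram_skipped": n_skip})
    _write_manifest(out_dir, "repeats",
                    {"min_len": min_len, "min_identity": min_identity,
                     "repeat_min_len": repeat_min_len,
                     "proximity_window": proximity_window,
                     "bin_width": bin_width}, stats)
    return stats


def run_cluster(gene_fasta, mutants_tsv, out_dir, radius: int = 5,
                alpha: float = 0.01) -> dict:
    """Hypergeometric clustering tests on a mutant-collection table."""
    import pandas as pd
    from Bio import SeqIO

    from .clustering import indel_substitution_association, tetranucleotide_scan
    from .sim import MutantCollection

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gene = str(next(SeqIO.parse(str(gene_fasta), "fasta")).seq).upper()
    tab = pd.read_csv(mutants_tsv, sep="\t")
    events = [(int(r.position), str(r.kind)) for r in tab.itertuples()]
    col = MutantCollection(gene=gene, events=events)
    assoc = indel_substitution_association(col, radius=radius)
    scan = tetranucleotide_scan(col, radius=radius, alpha=alpha)
    pd.DataFrame([{"test": "indel_substitution", "N": assoc.N, "m": assoc.m,
                   "n": assoc.n, "k": assoc.k, "p": assoc.p}]).to_csv(
        out_dir / "association.tsv", sep="\t", index=False)
    scan.table.to_csv(out_dir / "tetranucleotide_scan.tsv", sep="\t", index=False)
    stats = {"n_events": len(events), "association_p": assoc.p,
             "n_motifs_tested": len(scan.table),
             "expected_false_positives": scan.expected_false_positives}
    _write_manifest(out_dir, "cluster", {"radius": radius, "alpha": alpha}, stats)
    return stats


def run_fluctuation(counts_tsv, out_dir, reference: str = None) -> dict:
    """MLE mutation rates per strain/replicate from a fluctuation table.

    Input TSV columns: strain, replicate, culture, count, Nt.
    """
    import pandas as pd

    from .fluctuation import FluctuationExperiment, compare_strains, \
        estimate_experiment

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        tab = pd.read_csv(counts_tsv, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty or malformed counts table: {counts_tsv}") from exc
    missing = {"strain", "replicate", "count", "Nt"} - set(tab.columns)
    if missing:
        raise ValueError(f"counts table lacks columns: {sorted(missing)}")
    rows = []
    for (strain, rep), grp in tab.groupby(["strain", "replicate"], sort=True):
        exp = FluctuationExperiment(grp["count"].to_numpy(),
                                    Nt=float(grp["Nt"].iloc[0]))
        est = estimate_experiment(exp)
        rows.append((strain, rep, exp.C, est.m, est.mu, est.ci_lo, est.ci_hi))
    rates = pd.DataFrame(rows, columns=["strain", "replicate", "cultures",
                                        "m", "mu", "ci_lo", "ci_hi"])
    rates.to_csv(out_dir / "rates.tsv", sep="\t", index=False)
    comp_rows = []
    strains = sorted(rates["strain"].unique())
    ref = reference if reference is not None else strains[0]
    ref_mu = rates.loc[rates["strain"] == ref, "mu"].to_numpy()
    for strain in strains:
        if strain == ref:
            continue
        mu = rates.loc[rates["strain"] == strain, "mu"].to_numpy()
        if mu.size >= 2 and ref_mu.size >= 2:
            t, p = compare_strains(mu, ref_mu)
            comp_rows.append((strain, ref, t, p))
    comp = pd.DataFrame(comp_rows, columns=["strain", "reference", "t", "p"])
    comp.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
    stats = {"n_strains": len(strains), "reference": ref,
             "n_estimates": len(rates)}
    _write_manifest(out_dir, "fluctuation", {"reference": ref}, stats)
    return stats


def run_stats(file_a, file_b, out_dir) -> dict:
    """KS-gated comparison of two single-column value files."""
    from .stats import select_and_test

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    a = np.loadtxt(file_a, ndmin=1)
    b = np.loadtxt(file_b, ndmin=1)
    rep = select_and_test(a, b)
    result = asdict(rep)
    (out_dir / "test_report.json").write_text(
        json.dumps(result, indent=2, sort_keys=True) + "\n")
    _write_manifest(out_dir, "stats", {"n_a": int(a.size), "n_b": int(b.size)},
                    {"test": rep.test, "p": rep.p})
    return result
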