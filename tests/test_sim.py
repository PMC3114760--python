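"""Simulator contracts: ancestors, evolution, truth logs, assays."""

import numpy as np
import pytest
from scipy.linalg import expm

import indelflank as f
from indelflank.sim import generate_ancestor


class TestGenerateAncestor:
    def test_length_and_no_implants(self):
        cfg = f.SimConfig(length=1000, seed=1)
        anc = generate_ancestor(cfg)
        assert len(anc) == 1000
        assert anc.implants == []
        assert set(anc.sequence) <= set("ACGT")

    def test_implant_logged_and_present(self):
        cfg = f.SimConfig(length=100, repeat_spec=(("A", 12, 1),), seed=2)
        anc = generate_ancestor(cfg)
        (s, e, motif) = anc.implants[0]
        assert e - s == 12
        assert anc.sequence[s:e] == "A" * 12

    def test_gc_fraction_within_3sd(self):
        n = 100_000
        cfg = f.SimConfig(length=n, gc_fraction=0.5, seed=3)
        anc = generate_ancestor(cfg)
        gc = sum(b in "GC" for b in anc.sequence) / n
        sd = np.sqrt(0.25 / n)
        assert abs(gc - 0.5) < 3 * sd

    def test_implant_overflow_raises(self):
        cfg = f.SimConfig(length=50, repeat_spec=(("A", 30, 2),))
        with pytest.raises(f.ConfigError):
            generate_ancestor(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(f.ConfigError):
            f.SimConfig(length=0).validate()
        with pytest.raises(f.ConfigError):
            f.SimConfig(region_multiplier=0.5).validate()
        with pytest.raises(f.ConfigError):
            f.Branch("x", -0.1).validate()


class TestEvolveLineages:
    def test_zero_divergence_identical_rows(self):
        cfg = f.SimConfig(length=800, seed=4)
        anc = generate_ancestor(cfg)
        reg, log = f.evolve_lineages(anc, cfg, f.pair_topology(0.0))
        assert reg.rows[0] == reg.rows[1]
        assert "-" not in reg.rows[0]
        assert log.events == []

    def test_reproducibility(self):
        cfg = f.SimConfig(length=1000, divergence_per_branch=0.01,
                          indel_rate=0.001, seed=5)
        anc = generate_ancestor(cfg)
        r1, l1 = f.evolve_lineages(anc, cfg, f.pair_topology(0.01), seed=9)
        r2, l2 = f.evolve_lineages(anc, cfg, f.pair_topology(0.01), seed=9)
        assert r1.rows == r2.rows
        assert l1.to_frame().equals(l2.to_frame())

    def test_mismatch_fraction_matches_markov_oracle(self):
        """Pooled pairwise mismatch fraction vs the exact substitution-chain
        expectation (matrix exponential of the per-hit transition kernel)."""
        d = 0.004
        # per-hit kernel: transition with prob 2/3, each transversion 1/6
        M = np.zeros((4, 4))
        for a in range(4):
            M[a, a ^ 2] = 2 / 3
            M[a, a ^ 1] = M[a, a ^ 3] = 1 / 6
        B = expm(d * (M - np.eye(4)))  # branch substitution kernel
        p_same = float(np.mean(np.diag(B @ B.T)))  # uniform ancestor bases
        expected = 1.0 - p_same
        cfg = f.SimConfig(length=2000, gc_fraction=0.5, seed=6)
        mism = sites = 0
        for rep in range(200):
            anc = generate_ancestor(f.SimConfig(length=2000, seed=600 + rep))
            reg, _ = f.evolve_lineages(anc, cfg, f.pair_topology(d),
                                       seed=1200 + rep)
            a = np.frombuffer(reg.rows[0].encode(), dtype=np.uint8)
            b = np.frombuffer(reg.rows[1].encode(), dtype=np.uint8)
            mism += int((a != b).sum())
            sites += a.size
        sd = np.sqrt(expected * (1 - expected) * sites)
        assert abs(mism - expected * sites) < 3 * sd

    def test_region_multiplier_recovered_from_emitted_alignment(self):
        """Near-repeat vs far-field mismatch rates recover lambda within 15%."""
        lam = 3.0
        cfg = f.SimConfig(length=200_000, repeat_spec=(("A", 5, 80),),
                          region_multiplier=lam, region_radius=50,
                          divergence_per_branch=0.01, seed=7)
        anc = generate_ancestor(cfg)
        reg, _ = f.evolve_lineages(anc, cfg, f.pair_topology(0.01), seed=8)
        a = np.frombuffer(reg.rows[0].encode(), dtype=np.uint8)
        b = np.frombuffer(reg.rows[1].encode(), dtype=np.uint8)
        mism = a != b
        zone = np.zeros(len(anc), dtype=bool)
        for s, e, _m in anc.implants:
            zone[max(0, s - 50):e + 50] = True
        ratio = (mism[zone].mean()) / (mism[~zone].mean())
        assert abs(ratio - lam) / lam < 0.15

    def test_truth_log_replay_reconstructs_leaves(self):
        cfg = f.SimConfig(length=3000, seed=9)
        anc = generate_ancestor(cfg)
        topo = f.triple_topology(0.01, 0.02)
        reg, log = f.evolve_lineages(anc, cfg, topo, seed=10)
        seqs = {n: list(anc.sequence) for n in ("A", "B", "OUT")}
        for e in log.events:
            assert e.kind == "substitution"
            frm, to = e.detail.split(">")
            assert seqs[e.lineage][e.pos] == frm
            seqs[e.lineage][e.pos] = to
        for i, n in enumerate(("A", "B", "OUT")):
            assert "".join(seqs[n]) == reg.rows[i].replace("-", "")

    def test_indel_truth_matches_called_events(self):
        cfg = f.SimConfig(length=6000, indel_rate=0.0015, seed=11)
        anc = generate_ancestor(cfg)
        reg, log = f.evolve_lineages(anc, cfg, f.pair_topology(0.0), seed=12)
        logged = [e for e in log.events if e.kind != "substitution"]
        called = f.find_indels(reg)
        assert len(called) == len(logged)
        assert sorted(ev.length for ev in called) == \
            sorted(int(e.detail) for e in logged)

    def test_forced_indel_lands_at_requested_position(self):
        cfg = f.SimConfig(length=2000, seed=13)
        anc = generate_ancestor(cfg)
        reg, log = f.evolve_lineages(
            anc, cfg, f.pair_topology(0.0), seed=14,
            forced_indels=[("A", 1000, "deletion", 3)])
        (ev,) = f.find_indels(reg)
        assert ev.length == 3
        assert ev.gapped_row == 0
        assert abs(ev.start - 1000) <= 1


class TestRegionSet:
    def test_reproducible_and_truth_consistent(self):
        cfg = f.SimConfig(length=2101, repeat_spec=(("A", 6, 1),),
                          region_multiplier=3.0, divergence_per_branch=0.005,
                          seed=15)
        rs1 = f.simulate_region_set(cfg, 30, seed=16)
        rs2 = f.simulate_region_set(cfg, 30, seed=16)
        assert [r.rows for r in rs1.regions] == [r.rows for r in rs2.regions]
        assert rs1.substitutions.equals(rs2.substitutions)
        # every called indel matches the truth table
        for reg, (_, t) in zip(rs1.regions, rs1.indels.iterrows()):
            (ev,) = f.find_indels(reg)
            assert ev.length == t.length
            assert ev.start == t.col_start

    def test_substitution_tally_matches_alignment(self):
        """Mismatch count from the emitted alignment equals the truth-log
        tally after multiple-hit collision accounting."""
        cfg = f.SimConfig(length=2101, divergence_per_branch=0.004, seed=17)
        rs = f.simulate_region_set(cfg, 50, seed=18)
        total_mism = 0
        for reg in rs.regions:
            a, b = (np.frombuffer(r.encode(), dtype=np.uint8) for r in reg.rows)
            ok = (a != ord("-")) & (b != ord("-"))
            total_mism += int(((a != b) & ok).sum())
        # replay events per (region, position) to get the net difference count:
        # the ancestral base is the from_base of the first event at a site,
        # each lineage's final base is its last to_base (or ancestral if the
        # lineage was never hit), and sites inside a deletion span are not
        # comparable in the alignment
        deleted = {}
        for t in rs.indels.itertuples():
            if t.kind == "deletion":
                deleted[t.region_id] = range(t.col_start, t.col_end)
        net = 0
        for (rid, pos), grp in rs.substitutions.groupby(["region_id", "pos"]):
            if pos in deleted.get(rid, ()):  # masked by the gap
                continue
            ancestral = grp.iloc[0].from_base
            final = {"A": ancestral, "B": ancestral}
            for t in grp.itertuples():
                final[t.branch] = t.to_base
            if final["A"] != final["B"]:
                net += 1
        assert total_mism == net

    def test_pulse_only_hits_indel_lineage(self):
        cfg = f.SimConfig(length=2101, divergence_per_branch=0.0,
                          transient_indel_pulse=3.0, pulse_radius=50, seed=19)
        topo = f.triple_topology(0.0, 0.0)
        rs = f.simulate_region_set(cfg, 40, topology=topo,
                                   indel_branches=["A", "B"], seed=20)
        subs = rs.substitutions
        assert len(subs) > 0
        truth = rs.indels.set_index("region_id")["branch"]
        for t in subs.itertuples():
            assert t.branch == truth[t.region_id]


class TestFluctuationSim:
    def test_zero_rate_all_zero(self):
        assert f.simulate_fluctuation(0.0, 10**6, 20, seed=1).sum() == 0

    def test_p0_matches_closed_form(self):
        counts = f.simulate_fluctuation(2.0, 10**7, 10_000, seed=2)
        p0 = (counts == 0).mean()
        expected = np.exp(-2.0)
        sd = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(p0 - expected) < 3 * sd

    def test_jackpots_heavy_tail(self):
        counts = f.simulate_fluctuation(2.0, 10**7, 10_000, seed=3)
        assert counts.max() / max(np.median(counts), 1) > 5

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            f.simulate_fluctuation(-1.0, 10**6, 10)
        with pytest.raises(ValueError):
            f.simulate_fluctuation(1.0, 0, 10)


class TestMutantCollection:
    def test_empty_collection(self):
        col = f.generate_mutant_collection(100, 0, seed=1)
        assert col.events == []

    def test_saturation_bound(self):
        with pytest.raises(f.ConfigError):
            f.generate_mutant_collection(10, 1000, seed=1)

    def test_uniform_positions_pass_gof(self):
        col = f.generate_mutant_collection(10_000, 10_000, cluster_odds=1.0, seed=2)
        from scipy.stats import chisquare

        pos = np.array([p for p, _k in col.events])
        obs = np.bincount(pos // 500, minlength=20)
        assert chisquare(obs).pvalue > 0.001

    def test_cluster_odds_enrich_motif_zone(self):
        col = f.generate_mutant_collection(5000, 2000, cluster_motifs=("TGTG",),
                                           cluster_odds=10.0, seed=3)
        from indelflank.sim import _motif_starts

        zone = np.zeros(5000, dtype=bool)
        for s in _motif_starts(col.gene, "TGTG"):
            zone[max(0, s - 5):s + 9] = True
        pos = np.array([p for p, _k in col.events])
        frac_zone = zone[pos].mean()
        assert frac_zone > 3 * zone.mean()  # strong enrichment over coverage
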