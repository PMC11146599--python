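"""Simulator: root genome, branch evolution, clade simulation, genes, I/O."""

import math

import numpy as np
import pytest
from scipy import stats

from syntevo.errors import ConfigError, InputError
from syntevo.genome import Genome
from syntevo.simulate import (
    EvolutionRates, SimulationConfig, SizeDist, TrueEvent, apply_event,
    evolve_branch, make_root_genome, read_journal, replay, simulate_clade,
    synthesize_genes, tree_from_string, write_fixture, write_journal,
)
from syntevo.pair_stats import patristic_distance


class TestRootGenome:
    def test_shape_and_gc(self):
        cfg = SimulationConfig(n_chromosomes=2, chromosome_length=5000, gc_fraction=0.5, seed=7)
        g = make_root_genome(cfg)
        assert g.names == ["chr1", "chr2"]
        for n in g.names:
            assert g.length(n) == 5000
            seq = g.seq(n)
            gc = (seq.count("G") + seq.count("C")) / 5000
            sigma = math.sqrt(0.5 * 0.5 / 5000)
            assert abs(gc - 0.5) < 3 * sigma

    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_chromosomes=11, chromosome_length=10_000, gc_fraction=0.39, seed=1)
        assert make_root_genome(cfg) == make_root_genome(cfg)
        other = make_root_genome(SimulationConfig(11, 10_000, 0.39, seed=2))
        assert other != make_root_genome(cfg)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_chromosomes": 0},
            {"chromosome_length": 500},
            {"gc_fraction": 0.0},
            {"gc_fraction": 1.2},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ConfigError):
            make_root_genome(SimulationConfig(**kwargs))


class TestEvolveBranch:
    def test_zero_branch_is_identity(self):
        g = make_root_genome(SimulationConfig(2, 5000, seed=3))
        out, journal = evolve_branch(g, 0.0, EvolutionRates(), seed=5)
        assert out == g
        assert journal == []

    def test_substitution_count_poisson(self):
        # rate 1e-3/bp over 100 kbp, t=1 -> mean 100, 3 sigma = 30
        g = make_root_genome(SimulationConfig(1, 100_000, seed=4))
        rates = EvolutionRates(
            substitution_rate=1e-3, small_indel_rate=0, inversion_rate=0,
            translocation_rate=0, duplication_rate=0, insertion_rate=0, deletion_rate=0,
        )
        out, journal = evolve_branch(g, 1.0, rates, seed=6)
        n_sub = sum(1 for ev in journal if ev.event_type == "SUB")
        assert 70 <= n_sub <= 130
        assert len(out) == len(g)  # substitutions never change length

    def test_forced_inversion_operator(self):
        g = make_root_genome(SimulationConfig(1, 2000, seed=8))
        ev = TrueEvent("b", "INV", "chr1", 100, 200, size=100)
        out = g.copy()
        apply_event(out, ev)
        from syntevo._util import revcomp

        assert out.seq("chr1", 100, 200) == revcomp(g.seq("chr1", 100, 200))
        assert out.seq("chr1", 0, 100) == g.seq("chr1", 0, 100)
        assert out.seq("chr1", 200) == g.seq("chr1", 200)

    def test_translocation_and_duplication_operators(self):
        g = make_root_genome(SimulationConfig(2, 2000, seed=9))
        seg = g.seq("chr1", 100, 250)
        tr = TrueEvent("b", "TRANS", "chr1", 100, 250, dest_chrom="chr2", dest_start=500, size=150)
        out = g.copy()
        apply_event(out, tr)
        assert out.length("chr1") == 1850 and out.length("chr2") == 2150
        assert out.seq("chr2", 500, 650) == seg
        du = TrueEvent("b", "DUP", "chr1", 0, 100, dest_chrom="chr1", dest_start=100, size=100)
        out2 = g.copy()
        apply_event(out2, du)
        assert out2.seq("chr1", 0, 100) == out2.seq("chr1", 100, 200) == g.seq("chr1", 0, 100)

    def test_length_conserving_classes(self):
        g = make_root_genome(SimulationConfig(3, 20_000, seed=10))
        rates = EvolutionRates(
            substitution_rate=1e-3, small_indel_rate=0, inversion_rate=5,
            translocation_rate=5, duplication_rate=0, insertion_rate=0, deletion_rate=0,
            inversion_size=SizeDist("uniform", 500, 2000),
            translocation_size=SizeDist("uniform", 500, 2000),
        )
        out, _ = evolve_branch(g, 1.0, rates, seed=11)
        assert len(out) == len(g)

    def test_negative_branch_rejected(self):
        g = make_root_genome(SimulationConfig(1, 1000, seed=1))
        with pytest.raises(InputError):
            evolve_branch(g, -0.1, EvolutionRates(), seed=1)

    def test_oversized_event_skipped_with_warning(self, caplog):
        g = make_root_genome(SimulationConfig(1, 1000, seed=1))
        rates = EvolutionRates(
            substitution_rate=0, small_indel_rate=0, translocation_rate=0,
            duplication_rate=0, insertion_rate=0, deletion_rate=0,
            inversion_size=SizeDist("constant", 5000),
        ).with_fixed_counts(INV=1)
        with caplog.at_level("WARNING"):
            out, journal = evolve_branch(g, 1.0, rates, seed=2)
        assert journal == []
        assert out == g
        assert any("skipped" in r.message for r in caplog.records)


class TestSimulateClade:
    def test_star_tree_zero_rates(self):
        tree = tree_from_string("(A:1,B:1,C:1);")
        cfg = SimulationConfig(2, 5000, seed=12)
        rates = EvolutionRates(0, 0, 0, 0, 0, 0, 0)
        res = simulate_clade(tree, cfg, rates, seed=12)
        gs = list(res.tip_genomes.values())
        assert len(gs) == 3
        assert gs[0] == gs[1] == gs[2] == res.root_genome

    def test_determinism(self):
        tree = tree_from_string("((A:0.1,B:0.1):0.1,C:0.2);")
        cfg = SimulationConfig(2, 5000, seed=13)
        r1 = simulate_clade(tree, cfg, EvolutionRates(), seed=13)
        tree2 = tree_from_string("((A:0.1,B:0.1):0.1,C:0.2);")
        r2 = simulate_clade(tree2, cfg, EvolutionRates(), seed=13)
        assert r1.tip_genomes == r2.tip_genomes
        assert len(r1.journal) == len(r2.journal)

    def test_replay_reproduces_tips(self):
        tree = tree_from_string("((A:0.2,B:0.2):0.2,C:0.4);")
        cfg = SimulationConfig(2, 10_000, seed=14)
        res = simulate_clade(tree, cfg, EvolutionRates(), seed=14)
        for tip, genome in res.tip_genomes.items():
            assert replay(res.root_genome, res.events_for_tip(tip)) == genome

    def test_divergence_tracks_patristic_distance(self):
        tree = tree_from_string("((((A:0.01,B:0.01):0.01,C:0.02):0.02,D:0.04):0.04,E:0.08);")
        cfg = SimulationConfig(1, 20_000, seed=15)
        rates = EvolutionRates(
            substitution_rate=0.5, small_indel_rate=0, inversion_rate=0,
            translocation_rate=0, duplication_rate=0, insertion_rate=0, deletion_rate=0,
        )
        res = simulate_clade(tree, cfg, rates, seed=15)
        tips = sorted(res.tip_genomes)
        dists, diffs = [], []
        for i in range(len(tips)):
            for j in range(i + 1, len(tips)):
                a = res.tip_genomes[tips[i]].codes("chr1")
                b = res.tip_genomes[tips[j]].codes("chr1")
                dists.append(patristic_distance(res.tree, tips[i], tips[j]))
                diffs.append(np.mean(a != b))
        rho = stats.spearmanr(dists, diffs).statistic
        assert rho > 0

    def test_single_tip_rejected(self):
        tree = tree_from_string("(A:1);")
        with pytest.raises(InputError):
            simulate_clade(tree, SimulationConfig(1, 1000, seed=1), EvolutionRates(), 1)


class TestSynthesizeGenes:
    def _sim(self, seed=16, n_tips=5):
        nwk = "(" + ",".join(f"T{i}:0.1" for i in range(n_tips)) + ");"
        tree = tree_from_string(nwk)
        cfg = SimulationConfig(2, 20_000, seed=seed)
        return simulate_clade(tree, cfg, EvolutionRates(0, 0, 0, 0, 0, 0, 0), seed=seed)

    def test_core_only(self):
        res = self._sim()
        _, table = synthesize_genes(res, core_fraction=1.0, private_fraction=0.0, seed=1)
        counts = table.groupby("og_id")["species"].nunique()
        assert (counts == 5).all()

    def test_private_only(self):
        res = self._sim()
        _, table = synthesize_genes(res, core_fraction=0.0, private_fraction=1.0, seed=1)
        counts = table.groupby("og_id")["species"].nunique()
        assert (counts == 1).all()

    def test_recount_matches_requested_classes(self):
        res = self._sim(seed=17)
        _, table = synthesize_genes(
            res, gene_density=0.2, core_fraction=0.2, private_fraction=0.05, seed=2
        )
        counts = table.groupby("og_id")["species"].nunique()
        n_ogs = len(counts)
        core = int((counts == 5).sum())
        private = int((counts == 1).sum())
        # multinomial 3-sigma bounds around requested fractions
        for obs, p in ((core, 0.2), (private, 0.05)):
            sigma = math.sqrt(n_ogs * p * (1 - p))
            assert abs(obs - n_ogs * p) <= 3 * sigma + 1

    def test_gene_intervals_disjoint_and_in_bounds(self):
        res = self._sim(seed=18)
        gene_sets, _ = synthesize_genes(res, gene_density=0.2, seed=3)
        for tip, genes in gene_sets.items():
            genome = res.tip_genomes[tip]
            by_chrom = {}
            for g in genes:
                assert 0 <= g.start < g.end <= genome.length(g.chrom)
                by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
            for ivs in by_chrom.values():
                ivs.sort()
                assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_impossible_density_rejected(self):
        res = self._sim(seed=19)
        with pytest.raises(InputError):
            synthesize_genes(res, gene_density=2.0, gene_length=(3000, 3000), seed=4)


class TestFixtureIO:
    def test_roundtrips(self, tmp_path):
        tree = tree_from_string("((A:0.1,B:0.1):0.1,C:0.2);")
        cfg = SimulationConfig(2, 5000, seed=20)
        res = simulate_clade(tree, cfg, EvolutionRates(), seed=20)
        synthesize_genes(res, gene_density=0.1, seed=5)
        paths = write_fixture(res, tmp_path)
        # FASTA round-trip is byte-identical
        assert Genome.from_fasta(paths["genome:A"]) == res.tip_genomes["A"]
        # journal TSV: constant column count and lossless round-trip
        lines = paths["journal"].read_text().splitlines()
        assert len({len(l.split("\t")) for l in lines}) == 1
        back = read_journal(paths["journal"])
        assert len(back) == len(res.journal)
        assert all(
            (a.branch_id, a.event_type, a.chrom, a.start, a.end, a.size)
            == (b.branch_id, b.event_type, b.chrom, b.start, b.end, b.size)
            for a, b in zip(back, res.journal)
        )

    def test_journal_write_read_identity(self, tmp_path):
        evs = [
            TrueEvent("b1", "INV", "chr1", 10, 60, size=50),
            TrueEvent("b2", "TRANS", "chr1", 5, 25, dest_chrom="chr2", dest_start=0,
                      size=20, detail="inverted"),
            TrueEvent("b2", "SUB", "chr2", 3, 4, size=1, detail="G"),
        ]
        p = tmp_path / "j.tsv"
        write_journal(evs, p)
        back = read_journal(p)
        assert [(e.branch_id, e.event_type, e.chrom, e.start, e.end, e.dest_chrom,
                 e.dest_start, e.size, e.detail) for e in back] == [
            (e.branch_id, e.event_type, e.chrom, e.start, e.end, e.dest_chrom,
             e.dest_start, e.size, e.detail) for e in evs]
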