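"""Homology assignment, backbone selection, block classification, partition."""

import numpy as np
import pytest

from syntevo.alignment import AlignConfig, AlignmentBlock
from syntevo.classification import (
    Annotation, PairAnnotation, RegionAnnotation, annotate_unaligned,
    assign_chromosome_homology, chain_gain, classify_blocks, classify_pair,
    merge_adjacent, read_pair_tsv, select_backbone, trim_chain, write_pair_tsv,
)
from syntevo.errors import ConsistencyError
from syntevo.pair_stats import pair_summary
from syntevo.simulate import (
    EvolutionRates, SimulationConfig, SizeDist, TrueEvent, apply_event,
    make_root_genome, simulate_clade, tree_from_string,
)


def block(rc, rs, re_, qc, qs, qe, orient="+", ident=99.0):
    return AlignmentBlock(rc, rs, re_, qc, qs, qe, orient, identity=ident,
                          anchor_bp=min(re_ - rs, qe - qs))


class TestChromosomeHomology:
    def test_identity_mapping(self):
        blocks = [block("chr1", 0, 100, "chr1", 0, 100), block("chr2", 0, 100, "chr2", 0, 100)]
        assert assign_chromosome_homology(blocks) == {"chr1": "chr1", "chr2": "chr2"}

    def test_max_weight_wins(self):
        blocks = [
            block("chr1", 0, 800_000, "chrA", 0, 800_000),
            block("chr1", 0, 10_000, "chrB", 0, 10_000),
        ]
        assert assign_chromosome_homology(blocks) == {"chr1": "chrA"}

    def test_tie_prefers_lexicographic_query(self):
        blocks = [
            block("chr1", 0, 100, "chrB", 0, 100),
            block("chr1", 200, 300, "chrA", 0, 100),
        ]
        assert assign_chromosome_homology(blocks) == {"chr1": "chrA"}


class TestSelectBackbone:
    def test_collinear_blocks_all_selected(self):
        blocks = [
            block("c", 0, 100, "d", 0, 100),
            block("c", 150, 300, "d", 160, 310),
            block("c", 400, 500, "d", 400, 500),
        ]
        assert select_backbone(blocks) == sorted(blocks, key=lambda b: b.ref_start)

    def test_crossing_block_excluded(self):
        a = block("c", 0, 100, "d", 0, 100)
        b = block("c", 100, 300, "d", 300, 500)
        c = block("c", 300, 400, "d", 100, 200)
        chain = select_backbone([a, b, c])
        assert chain == [a, b]
        assert sum(x.weight for x in chain) == 300

    def test_no_forward_blocks(self):
        assert select_backbone([block("c", 0, 100, "d", 0, 100, "-")]) == []

    def test_brute_force_small_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            blocks = _random_blocks(rng, rng.integers(1, 7))
            assert _chain_score(select_backbone(blocks)) == _brute_force_best(blocks)


def _random_blocks(rng, n):
    out = []
    for _ in range(n):
        rs = int(rng.integers(0, 5000))
        qs = int(rng.integers(0, 5000))
        rl = int(rng.integers(50, 1500))
        ql = int(rng.integers(50, 1500))
        out.append(block("c", rs, rs + rl, "d", qs, qs + ql))
    return out


def _chain_score(chain):
    if not chain:
        return 0
    total = chain[0].weight
    for a, b in zip(chain, chain[1:]):
        total += chain_gain(a, b)
    return total


def _brute_force_best(blocks):
    """Exhaustive maximum over all valid chains (ref-sorted subsequences)."""
    order = sorted(blocks, key=lambda b: (b.ref_start, b.ref_end, b.qry_start))
    best = 0

    def extend(i, last, score):
        nonlocal best
        best = max(best, score)
        for j in range(i, len(order)):
            b = order[j]
            if last is None:
                extend(j + 1, b, b.weight)
            else:
                g = chain_gain(last, b)
                if g is not None:
                    extend(j + 1, b, score + g)

    extend(0, None, 0)
    return best


class TestTrimChain:
    def test_tandem_overlap_trimmed_to_residual(self):
        a = block("c", 0, 1000, "d", 0, 1000)
        b = block("c", 1000, 3000, "d", 500, 2500)  # 500 bp qry overlap
        trimmed, residuals = trim_chain([a, b])
        assert trimmed[0] == a
        assert trimmed[1].ref_start == 1500 and trimmed[1].qry_start == 1000
        assert len(residuals) == 1
        r = residuals[0]
        assert (r.ref_start, r.ref_end, r.qry_start, r.qry_end) == (1000, 1500, 500, 1000)

    def test_sub_threshold_overlap_dropped_silently(self):
        a = block("c", 0, 1000, "d", 0, 1000)
        b = block("c", 995, 3000, "d", 1000, 3005)  # 5 bp jitter
        trimmed, residuals = trim_chain([a, b])
        assert residuals == []
        assert trimmed[1].ref_start == 1000


class TestClassifyBlocks:
    def test_reversed_block_between_backbone_is_inversion(self):
        bb1 = block("c", 0, 1000, "d", 0, 1000)
        bb2 = block("c", 2000, 3000, "d", 2000, 3000)
        inv = block("c", 1000, 2000, "d", 1000, 2000, "-")
        anns = classify_blocks(
            [bb1, bb2, inv], {"c": [bb1, bb2]}, {"c": "d"},
            {"c": 3000}, {"d": 3000},
        )
        types = {a.event_type for a in anns}
        assert types == {"SYN", "INV"}
        ia = next(a for a in anns if a.event_type == "INV")
        assert (ia.ref_start, ia.ref_end) == (1000, 2000)

    def test_fresh_cross_chromosome_block_is_translocation(self):
        bb = block("c", 0, 1000, "d", 0, 1000)
        tr = block("c", 2000, 2500, "e", 100, 600)
        anns = classify_blocks([bb, tr], {"c": [bb]}, {"c": "d"}, {"c": 3000}, {"d": 3000, "e": 1000})
        assert {a.event_type for a in anns} == {"SYN", "TRANS"}

    def test_redundant_block_is_duplication(self):
        bb = block("c", 0, 1000, "d", 0, 1000)
        dup = block("c", 200, 700, "d", 1500, 2000)  # ref side re-covers SYN
        anns = classify_blocks([bb, dup], {"c": [bb]}, {"c": "d"}, {"c": 3000}, {"d": 3000})
        assert {a.event_type for a in anns} == {"SYN", "DUP"}


class TestMergeAdjacent:
    def test_adjacent_same_type_merged(self):
        regs = [
            RegionAnnotation("c", 100, 200, "TRANS", 90.0),
            RegionAnnotation("c", 200, 300, "TRANS", 90.0),
        ]
        out = merge_adjacent(regs)
        assert out == [RegionAnnotation("c", 100, 300, "TRANS", 90.0)]

    def test_broken_series_untouched(self):
        regs = [
            RegionAnnotation("c", 100, 200, "TRANS", 90.0),
            RegionAnnotation("c", 200, 250, "SYN", 95.0),
            RegionAnnotation("c", 250, 300, "TRANS", 90.0),
        ]
        assert merge_adjacent(regs) == regs

    def test_merged_identity_is_length_weighted(self):
        regs = [
            RegionAnnotation("c", 0, 100, "SYN", 90.0),
            RegionAnnotation("c", 100, 400, "SYN", 80.0),
        ]
        out = merge_adjacent(regs)
        assert len(out) == 1
        assert out[0].identity == pytest.approx(82.5)


class TestAnnotateUnaligned:
    def test_fully_tiled_genome(self):
        regions = {"A": [RegionAnnotation("c", 0, 1000, "SYN", 99.0)],
                   "B": [RegionAnnotation("d", 0, 1000, "SYN", 99.0)]}
        pair = annotate_unaligned(regions, {"A": {"c": 1000}, "B": {"d": 1000}}, "A", "B")
        assert all(r.event_type != "UNALIGNED" for r in pair.regions["A"])

    def test_complement_becomes_unaligned(self):
        regions = {"A": [RegionAnnotation("c", 0, 600, "SYN", 99.0)], "B": []}
        pair = annotate_unaligned(regions, {"A": {"c": 1000}, "B": {"d": 500}}, "A", "B")
        una = [r for r in pair.regions["A"] if r.event_type == "UNALIGNED"]
        assert una == [RegionAnnotation("c", 600, 1000, "UNALIGNED", None)]
        assert pair.regions["B"] == [RegionAnnotation("d", 0, 500, "UNALIGNED", None)]

    def test_overlapping_aligned_annotations_rejected(self):
        regions = {
            "A": [RegionAnnotation("c", 0, 600, "SYN", 99.0),
                  RegionAnnotation("c", 500, 700, "TRANS", 99.0)],
            "B": [],
        }
        with pytest.raises(ConsistencyError):
            annotate_unaligned(regions, {"A": {"c": 1000}, "B": {"d": 100}}, "A", "B")


class TestClassifyPair:
    def test_self_comparison_is_syntenic(self):
        g = make_root_genome(SimulationConfig(2, 10_000, seed=21))
        pair = classify_pair(g, g, ref_id="A", qry_id="B")
        s = pair_summary(pair, min_event_length=0)
        assert s.percent("A", "SYN") >= 99.0
        assert s.per_genome["A"]["INV"].count == 0
        assert s.per_genome["A"]["TRANS"].count == 0

    def test_planted_inversion_recovered(self):
        g = make_root_genome(SimulationConfig(2, 20_000, seed=22))
        mutated = g.copy()
        apply_event(mutated, TrueEvent("b", "INV", "chr1", 5000, 10000, size=5000))
        pair = classify_pair(g, mutated, ref_id="A", qry_id="B")
        invs = [a for a in pair.events if a.event_type == "INV"]
        assert len(invs) == 1
        assert abs(invs[0].ref_start - 5000) <= 100
        assert abs(invs[0].ref_end - 10000) <= 100

    def test_planted_dispersed_duplication_recovered(self):
        g = make_root_genome(SimulationConfig(2, 20_000, seed=23))
        mutated = g.copy()
        apply_event(
            mutated,
            TrueEvent("b", "DUP", "chr1", 3000, 5000, dest_chrom="chr2",
                      dest_start=12_000, size=2000),
        )
        pair = classify_pair(g, mutated, ref_id="A", qry_id="B")
        dups = [a for a in pair.events if a.event_type == "DUP"]
        assert len(dups) == 1
        d = dups[0]
        assert d.qry_chrom == "chr2"
        assert abs(d.qry_start - 12_000) <= 100 and abs(d.qry_end - 14_000) <= 100

    def test_partition_property_on_simulation(self):
        tree = tree_from_string("(A:0.05,B:0.05);")
        res = simulate_clade(tree, SimulationConfig(2, 30_000, seed=24), EvolutionRates(), 24)
        pair = classify_pair(res.tip_genomes["A"], res.tip_genomes["B"], ref_id="A", qry_id="B")
        pair.check_partition()  # raises on violation
        for gid in ("A", "B"):
            total = sum(r.length for r in pair.regions[gid])
            assert total == len(res.tip_genomes[gid])

    def test_substitution_rate_monotonicity(self):
        """More substitution noise never increases the shared proportion."""
        shared = []
        for rate in (0.002, 0.02, 0.06):
            tree = tree_from_string("(A:1,B:1);")
            rates = EvolutionRates(
                substitution_rate=rate, small_indel_rate=1e-4,
                inversion_rate=0, translocation_rate=2, duplication_rate=4,
                insertion_rate=2, deletion_rate=2,
                translocation_size=SizeDist("uniform", 500, 1500),
                duplication_size=SizeDist("uniform", 300, 900),
            )
            res = simulate_clade(tree, SimulationConfig(2, 25_000, seed=25), rates, 25)
            pair = classify_pair(res.tip_genomes["A"], res.tip_genomes["B"], ref_id="A", qry_id="B")
            s = pair_summary(pair)
            shared.append(s.shared_percent("A"))
        assert shared[0] >= shared[1] >= shared[2]


class TestPairTsv:
    def test_roundtrip(self, tmp_path):
        g = make_root_genome(SimulationConfig(2, 10_000, seed=26))
        mutated = g.copy()
        apply_event(mutated, TrueEvent("b", "INV", "chr1", 2000, 6000, size=4000))
        pair = classify_pair(g, mutated, ref_id="A", qry_id="B")
        p = tmp_path / "pair.tsv"
        write_pair_tsv(pair, p)
        back = read_pair_tsv(p)
        assert back.ref_id == "A" and back.qry_id == "B"
        for gid in ("A", "B"):
            assert [
                (r.chrom, r.start, r.end, r.event_type) for r in back.regions[gid]
            ] == [(r.chrom, r.start, r.end, r.event_type) for r in pair.regions[gid]]
        back.check_partition()
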