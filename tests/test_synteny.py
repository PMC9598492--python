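import numpy as np
import pandas as pd
import pytest

from wgdpop import io_formats as io
from wgdpop import synteny
from wgdpop.io_formats import HIT_COLUMNS
from wgdpop.synteny import Anchor


def make_hits(rows):
    """rows: (query, subject, bit_score)"""
    return pd.DataFrame(
        [(q, s, 100.0, 100, 0, 0, 1, 100, 1, 100, 1e-50, b) for q, s, b in rows],
        columns=HIT_COLUMNS,
    )


def catalog_from_ranks(chrom_genes):
    """chrom_genes: {chrom: [gene ids in rank order]}"""
    genes = []
    for chrom, ids in chrom_genes.items():
        for j, gid in enumerate(ids):
            genes.append(io.GeneModel(gid, chrom, "+", [(j * 100, j * 100 + 30)]))
    return io.GeneCatalog.from_genes(genes)


class TestCollapseTandem:
    def test_adjacent_pair_collapsed(self):
        cat = catalog_from_ranks({"c1": ["a", "b", "x"], "c2": ["y"]})
        hits = make_hits([("a", "b", 100), ("a", "y", 90), ("b", "y", 80)])
        out = synteny.collapse_tandem(hits, cat, max_tandem_rank_gap=1)
        # 'a' (total score 190+100) beats 'b' (180); b's hits removed
        assert set(out["query_id"]) | set(out["subject_id"]) <= {"a", "y"}

    def test_distant_pair_kept(self):
        cat = catalog_from_ranks({"c1": ["a", "p", "q", "r", "b"]})
        hits = make_hits([("a", "b", 100)])
        out = synteny.collapse_tandem(hits, cat, max_tandem_rank_gap=1)
        assert len(out) == 1

    def test_three_gene_array_single_representative(self):
        """A three-member adjacent array keeps exactly one member's hits."""
        cat = catalog_from_ranks({"c1": ["a", "b", "c", "f1", "f2", "f3", "z"]})
        hits = make_hits(
            [("a", "b", 50), ("b", "c", 50), ("a", "c", 50),
             ("a", "z", 60), ("b", "z", 70), ("c", "z", 80)]
        )
        out = synteny.collapse_tandem(hits, cat, max_tandem_rank_gap=1)
        survivors = set(out["query_id"]) | set(out["subject_id"])
        assert len(survivors & {"a", "b", "c"}) == 1
        assert survivors & {"a", "b", "c"} == {"c"}  # highest total bit score


class TestBuildAnchors:
    def test_intra_dedupes_reciprocals(self):
        cat = catalog_from_ranks({"c1": [f"g{i}" for i in range(12)],
                                  "c2": [f"h{i}" for i in range(12)]})
        rows = [(f"g{i}", f"h{i}", 100) for i in range(12)]
        rows += [(f"h{i}", f"g{i}", 100) for i in range(12)]  # reciprocal rows
        anchors = synteny.build_anchors(make_hits(rows), cat)
        assert len(anchors) == 12

    def test_empty(self):
        cat = catalog_from_ranks({"c1": ["a"]})
        assert synteny.build_anchors(make_hits([]), cat) == []

    def test_unknown_gene_dropped(self):
        cat = catalog_from_ranks({"c1": ["a", "b"]})
        anchors = synteny.build_anchors(make_hits([("a", "nope", 10), ("a", "b", 10)]), cat)
        assert len(anchors) == 1


def exhaustive_best_chain(anchors, max_intervening):
    """Oracle: enumerate every monotone chain, both orientations, return the
    best (count, summed score)."""
    best = (0, 0.0)

    for orientation in ("same", "inverted"):
        sign = 1 if orientation == "same" else -1

        def extend(chain):
            nonlocal best
            cand = (len(chain), sum(a.score for a in chain))
            if cand > best:
                best = cand
            last = chain[-1]
            for a in anchors:
                da = a.rank_a - last.rank_a
                db = sign * (a.rank_b - last.rank_b)
                if da > 0 and db > 0 and da - 1 <= max_intervening and db - 1 <= max_intervening:
                    extend(chain + [a])

        for a in anchors:
            extend([a])
    return best


def random_instance(rng, n_anchors, rank_range=14):
    pairs = set()
    while len(pairs) < n_anchors:
        pairs.add((int(rng.integers(0, rank_range)), int(rng.integers(0, rank_range))))
    return [
        Anchor(f"a{i}", f"b{i}", "cA", "cB", ra, rb, float(rng.integers(10, 100)))
        for i, (ra, rb) in enumerate(sorted(pairs))
    ]


class TestChainAnchors:
    def test_perfect_colinear_run_is_one_block(self):
        anchors = [Anchor(f"a{i}", f"b{i}", "cA", "cB", i, i, 50.0) for i in range(12)]
        blocks = synteny.chain_anchors(anchors, min_block_genes=10, max_intervening=5)
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 12
        assert blocks[0].orientation == "same"
        # brute-force confirmation on the same instance
        assert exhaustive_best_chain(anchors, 5) == (12, 600.0)

    def test_nine_anchors_below_threshold(self):
        anchors = [Anchor(f"a{i}", f"b{i}", "cA", "cB", i, i, 50.0) for i in range(9)]
        assert synteny.chain_anchors(anchors, 10, 5) == []

    def test_large_gap_splits_chain(self):
        """Ranks {1..5} and {12..16} leave 6 intervening genes: the chain is
        split and neither half reaches 10 anchors."""
        ranks = list(range(1, 6)) + list(range(12, 17))
        anchors = [Anchor(f"a{r}", f"b{r}", "cA", "cB", r, r, 50.0) for r in ranks]
        assert synteny.chain_anchors(anchors, 10, 5) == []
        assert exhaustive_best_chain(anchors, 5)[0] == 5

    def test_inverted_block(self):
        anchors = [Anchor(f"a{i}", f"b{i}", "cA", "cB", i, 11 - i, 50.0) for i in range(12)]
        blocks = synteny.chain_anchors(anchors, 10, 5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_matches_exhaustive_oracle_on_random_instances(self):
        """DP chaining equals brute-force enumeration on >=100 random
        instances with <=15 anchors."""
        rng = np.random.default_rng(42)
        for _ in range(120):
            n = int(rng.integers(1, 16))
            mi = int(rng.integers(0, 7))
            anchors = random_instance(rng, n)
            blocks = synteny.chain_anchors(anchors, min_block_genes=1, max_intervening=mi)
            assert blocks, "min_block_genes=1 must always yield a block"
            top = max(blocks, key=lambda b: (b.n_anchors, b.score))
            got = (top.n_anchors, top.score)
            expected = exhaustive_best_chain(anchors, mi)
            assert got == pytest.approx(expected)
            synteny.validate_block(top, 1, mi)

    def test_every_block_satisfies_invariants(self, small_wgd_sim):
        cat = small_wgd_sim["catalog"]
        hits = io.read_homology_table(small_wgd_sim["paths"]["hits"], 1e-10)
        blocks = synteny.find_blocks(hits, cat)
        assert blocks
        for b in blocks:
            synteny.validate_block(b, 10, 5)

    def test_reversing_b_ranks_flips_orientation(self):
        rng = np.random.default_rng(7)
        anchors = random_instance(rng, 12)
        blocks = synteny.chain_anchors(anchors, 3, 5)
        flipped = [
            Anchor(a.gene_a, a.gene_b, a.chrom_a, a.chrom_b, a.rank_a, 13 - a.rank_b, a.score)
            for a in anchors
        ]
        blocks_f = synteny.chain_anchors(flipped, 3, 5)
        orient = {"same": "inverted", "inverted": "same"}
        assert sorted(
            (frozenset(x.gene_a for x in b.anchors), b.orientation) for b in blocks
        ) == sorted(
            (frozenset(x.gene_a for x in b.anchors), orient[b.orientation]) for b in blocks_f
        )


class TestHomeologPairs:
    def test_single_block(self):
        anchors = [Anchor(f"a{i}", f"b{i}", "cA", "cB", i, i, 50.0) for i in range(12)]
        blocks = synteny.chain_anchors(anchors, 10, 5)
        pairs, dup = synteny.homeolog_pairs(blocks)
        assert len(pairs) == 12 and dup == []

    def test_disjoint_blocks_sum(self):
        a1 = [Anchor(f"a{i}", f"b{i}", "cA", "cB", i, i, 50.0) for i in range(12)]
        a2 = [Anchor(f"x{i}", f"y{i}", "cC", "cD", i, i, 50.0) for i in range(11)]
        pairs, dup = synteny.homeolog_pairs(synteny.chain_anchors(a1 + a2, 10, 5))
        assert len(pairs) == 23 and dup == []

    def test_shared_pair_reported_once_and_flagged(self):
        b1 = synteny.SyntenyBlock("cA", "cB", "same",
                                  [Anchor(f"a{i}", f"b{i}", "cA", "cB", i, i, 1.0) for i in range(10)])
        b2 = synteny.SyntenyBlock("cA", "cB", "same",
                                  [Anchor("a0", "b0", "cA", "cB", 0, 0, 1.0)]
                                  + [Anchor(f"c{i}", f"d{i}", "cA", "cB", i, i, 1.0) for i in range(1, 10)])
        pairs, dup = synteny.homeolog_pairs([b1, b2])
        assert len(pairs) == 19
        assert dup == [("a0", "b0")]


class TestIntergenomic:
    def test_self_identity_gives_full_length_blocks(self):
        cat = catalog_from_ranks({"c1": [f"g{i}" for i in range(15)]})
        hits = make_hits([(f"g{i}", f"g{i}", 100) for i in range(15)])
        # inter-genomic mode: no self-pair dedup, catalog_b == catalog_a
        anchors = synteny.build_anchors(hits, cat, cat, intra=False)
        blocks = synteny.chain_anchors(anchors, 10, 5)
        assert len(blocks) == 1 and blocks[0].n_anchors == 15

    def test_shuffled_partner_order_has_no_block(self):
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(30)]
        cat_a = catalog_from_ranks({"c1": ids})
        shuffled = list(ids)
        rng.shuffle(shuffled)
        cat_b = catalog_from_ranks({"c1": shuffled})
        hits = make_hits([(g, g, 100) for g in ids])
        anchors = synteny.build_anchors(hits, cat_a, cat_b, intra=False)
        blocks = synteny.chain_anchors(anchors, 10, 5)
        assert blocks == []

    def test_wgd_fixture_yields_block_per_chromosome_pair(self, small_wgd_sim):
        cat = small_wgd_sim["catalog"]
        hits = io.read_homology_table(small_wgd_sim["paths"]["hits"], 1e-10)
        blocks = synteny.find_blocks(hits, cat)
        chrom_pairs = {(b.chrom_a, b.chrom_b) for b in blocks}
        assert chrom_pairs == {(f"chr{c:02d}", f"chr{c:02d}d") for c in (1, 2, 3)}
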