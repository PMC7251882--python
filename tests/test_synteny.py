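"""Tests for gene ranking, block chaining, classification and dot plots."""

import numpy as np
import pandas as pd
import pytest

import wgdsig as w
from wgdsig.synteny import (
    RELAXED,
    STRINGENT,
    block_summary,
    blocks_frame,
    chain_collinear_blocks,
    classify_block_topology,
    classify_duplicates,
    macrosynteny_dotplot,
    rank_genes,
)

from oracles import chain_blocks_bruteforce


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])


def _pairs(pairs):
    return pd.DataFrame(
        [(a, b, 1e-40, 100.0) for a, b in pairs],
        columns=["gene_a", "gene_b", "evalue", "bitscore"],
    )


def _grid_layout(hits, n=12):
    """Two scaffolds with n genes each; hits given as (qrank, trank)."""
    rows = []
    for s in ("s1", "s2"):
        for i in range(n):
            rows.append((f"{s}g{i}", s, 1 + 1000 * i, 500 + 1000 * i, "+"))
    genes = rank_genes(_genes(rows))
    pairs = _pairs([(f"s1g{q}", f"s2g{t}") for q, t in hits])
    return genes, pairs


class TestRankGenes:
    def test_ranks_follow_start_coordinates(self):
        genes = rank_genes(_genes([
            ("g1", "s", 100, 150, "+"), ("g2", "s", 50, 80, "+"), ("g3", "s", 200, 260, "-"),
        ]))
        assert dict(zip(genes.gene_id, genes["rank"])) == {"g2": 0, "g1": 1, "g3": 2}

    def test_scaffolds_ranked_independently(self):
        genes = rank_genes(_genes([
            ("a1", "s1", 100, 150, "+"), ("a2", "s1", 300, 350, "+"),
            ("b1", "s2", 500, 550, "+"),
        ]))
        assert genes.set_index("gene_id")["rank"].to_dict() == {"a1": 0, "a2": 1, "b1": 0}

    def test_start_ties_break_lexicographically(self):
        genes = rank_genes(_genes([
            ("zz", "s", 100, 150, "+"), ("aa", "s", 100, 160, "+"),
        ]))
        assert genes.set_index("gene_id")["rank"].to_dict() == {"aa": 0, "zz": 1}


class TestChaining:
    def test_perfect_diagonal_one_parallel_block(self):
        genes, pairs = _grid_layout([(i, i) for i in range(5)])
        blocks = chain_collinear_blocks(pairs, genes, seed_size=5)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.orientation == "parallel" and b.anchor_count == 5
        assert b.topology == "inter_scaffold"

    def test_perfect_antidiagonal_one_inverted_block(self):
        genes, pairs = _grid_layout([(i, 4 - i) for i in range(5)])
        blocks = chain_collinear_blocks(pairs, genes, seed_size=5)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_gap_constraint_splits_chains(self):
        # two diagonal runs separated by a rank jump beyond max_gap
        hits = [(i, i) for i in range(3)] + [(i + 8, i + 8) for i in range(3)]
        genes, pairs = _grid_layout(hits)
        blocks = chain_collinear_blocks(pairs, genes, seed_size=3, max_gap=5)
        assert sorted(b.anchor_count for b in blocks) == [3, 3]
        merged = chain_collinear_blocks(pairs, genes, seed_size=3, max_gap=25)
        assert [b.anchor_count for b in merged] == [6]

    def test_subseed_chains_not_emitted(self):
        genes, pairs = _grid_layout([(0, 0), (1, 1)])
        assert chain_collinear_blocks(pairs, genes, seed_size=3) == []

    def test_matches_bruteforce_on_random_grids(self, rng):
        for rep in range(60):
            n_hits = int(rng.integers(3, 11))
            cells = rng.choice(100, size=n_hits, replace=False)
            hits = [(int(c // 10), int(c % 10)) for c in cells]
            genes, pairs = _grid_layout(hits)
            seed_size, max_gap = 3, int(rng.integers(4, 26))
            blocks = chain_collinear_blocks(
                pairs, genes, seed_size=seed_size, max_gap=max_gap
            )
            info = genes.set_index("gene_id")["rank"]
            oracle_hits = [
                (int(info[a]), int(info[b]), (a, b, np.nan))
                for a, b in zip(pairs.gene_a, pairs.gene_b)
            ]
            expected = chain_blocks_bruteforce(
                oracle_hits, seed_size, max_gap,
                STRINGENT.match_reward, STRINGENT.gap_penalty,
            )
            got = [
                (b.score, b.orientation, [(a, bb) for a, bb in b.anchors])
                for b in blocks
            ]
            exp = [
                (score, orient, [(k[0], k[1]) for k in chain])
                for score, orient, chain in expected
            ]
            assert got == exp, f"rep {rep}: {got} != {exp}"

    def test_relaxed_never_fewer_anchors_than_stringent(self, rng):
        for rep in range(10):
            lay = w.simulate_genome_layout(
                6, 200,
                [("inter_scaffold", 6, 0.8), ("palindrome", 5, 0.3),
                 ("tandem_array", 5, 0.2)],
                tandem_singletons=3, dispersed_pairs=8, seed=int(rng.integers(1e6)),
            )
            n_str = sum(
                b.anchor_count
                for b in chain_collinear_blocks(
                    lay.pairs, lay.genes, STRINGENT.seed_size, STRINGENT.max_gap,
                    STRINGENT.evalue_cutoff,
                )
            )
            n_rel = sum(
                b.anchor_count
                for b in chain_collinear_blocks(
                    lay.pairs, lay.genes, RELAXED.seed_size, RELAXED.max_gap,
                    RELAXED.evalue_cutoff,
                )
            )
            assert n_rel >= n_str

    def test_self_hits_ignored(self):
        genes = rank_genes(_genes([("g0", "s", 1, 10, "+"), ("g1", "s", 20, 30, "+")]))
        pairs = _pairs([("g0", "g0"), ("g0", "g1")])
        assert chain_collinear_blocks(pairs, genes, seed_size=1) != []  # g0-g1 only
        blocks = chain_collinear_blocks(pairs, genes, seed_size=1)
        assert all((a != b) for blk in blocks for a, b in blk.anchors)


class TestClassification:
    def test_adjacent_non_anchor_pair_is_tandem(self):
        genes = rank_genes(_genes([("g0", "s", 1, 10, "+"), ("g1", "s", 20, 30, "+")]))
        out = classify_duplicates(_pairs([("g0", "g1")]), [], genes)
        assert list(out.classification) == ["tandem"]

    def test_anchor_precedence_over_tandem(self):
        # palindrome of 3 anchors: central pair is rank-adjacent yet anchor
        lay = w.simulate_genome_layout(2, 100, [("palindrome", 3, 0.3)], seed=3)
        blocks = chain_collinear_blocks(lay.pairs, lay.genes, seed_size=3, max_gap=40)
        assert len(blocks) == 1
        out = classify_duplicates(lay.pairs, blocks, lay.genes)
        assert (out.classification == "segmental_anchor").all()

    def test_registry_round_trip(self, rng):
        for rep in range(10):
            lay = w.simulate_genome_layout(
                8, 220,
                [("inter_scaffold", 5, 0.8), ("palindrome", 4, 0.3),
                 ("tandem_array", 4, 0.2)],
                tandem_singletons=3, dispersed_pairs=10,
                seed=int(rng.integers(1e6)),
            )
            blocks = chain_collinear_blocks(
                lay.pairs, lay.genes, RELAXED.seed_size, RELAXED.max_gap,
                RELAXED.evalue_cutoff,
            )
            out = classify_duplicates(lay.pairs, blocks, lay.genes)
            assert (out.classification == out.true_class).all()
            got_topo = sorted(b.topology for b in blocks)
            exp_topo = sorted(
                lay.blocks.groupby("block_id")["topology"].first()
            )
            assert got_topo == exp_topo

    def test_classification_is_a_partition(self):
        lay = w.simulate_genome_layout(4, 150, [("inter_scaffold", 5, 0.8)],
                                       tandem_singletons=2, dispersed_pairs=5, seed=8)
        blocks = chain_collinear_blocks(lay.pairs, lay.genes, 3, 40, 1e-5)
        out = classify_duplicates(lay.pairs, blocks, lay.genes)
        assert len(out) == len(lay.pairs)
        assert set(out.classification) <= {"segmental_anchor", "tandem", "dispersed"}


class TestTopology:
    def test_trivial_topologies(self):
        mk = lambda sa, sb, orient: w.CollinearBlock(0, sa, sb, orient, [], 0.0)
        assert classify_block_topology(mk("s1", "s2", "parallel")) == "inter_scaffold"
        assert classify_block_topology(mk("s1", "s1", "inverted")) == "palindrome"
        assert classify_block_topology(mk("s1", "s1", "parallel")) == "tandem_array"

    def test_reversing_one_scaffold_flips_inter_scaffold_orientation(self):
        lay = w.simulate_genome_layout(2, 120, [("inter_scaffold", 5, 0.8)], seed=4)
        blocks = chain_collinear_blocks(lay.pairs, lay.genes, 5, 25)
        assert len(blocks) == 1
        # reverse the coordinate system of the second scaffold only
        genes2 = lay.genes.copy()
        scf = blocks[0].scaffold_b
        m = genes2.scaffold == scf
        L = genes2.loc[m, "end"].max() + 1
        s, e = genes2.loc[m, "start"].copy(), genes2.loc[m, "end"].copy()
        genes2.loc[m, "start"], genes2.loc[m, "end"] = L - e, L - s
        blocks2 = chain_collinear_blocks(
            lay.pairs, rank_genes(genes2.drop(columns="rank")), 5, 25
        )
        assert len(blocks2) == 1
        assert blocks2[0].orientation != blocks[0].orientation
        assert {frozenset(p) for p in blocks2[0].anchors} == {
            frozenset(p) for p in blocks[0].anchors
        }


class TestDotplot:
    def test_row_per_pair_and_anchor_flags(self):
        lay = w.simulate_genome_layout(3, 150, [("inter_scaffold", 5, 0.8)],
                                       dispersed_pairs=4, seed=5)
        blocks = chain_collinear_blocks(lay.pairs, lay.genes, 5, 25)
        dp = macrosynteny_dotplot(lay.pairs, lay.genes, blocks)
        assert len(dp) == len(lay.pairs)
        assert dp.is_anchor.sum() == sum(b.anchor_count for b in blocks)

    def test_single_intra_scaffold_pair_off_diagonal(self):
        genes = rank_genes(_genes([("g0", "s", 100, 200, "+"), ("g1", "s", 900, 1000, "+")]))
        dp = macrosynteny_dotplot(_pairs([("g0", "g1")]), genes)
        assert len(dp) == 1 and dp.x.iloc[0] != dp.y.iloc[0]

    def test_summary_and_frame_helpers(self):
        lay = w.simulate_genome_layout(4, 150, [("inter_scaffold", 5, 0.8),
                                                ("palindrome", 4, 0.3)], seed=6)
        blocks = chain_collinear_blocks(lay.pairs, lay.genes, 3, 40)
        s = block_summary(blocks)
        assert s["n_blocks"] == 2 and s["inter_scaffold_fraction"] == 0.5
        bf = blocks_frame(blocks)
        assert len(bf) == 2 and set(bf.topology) == {"inter_scaffold", "palindrome"}
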