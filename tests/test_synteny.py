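"""Anchor building and collinear chain extraction."""

import numpy as np
import pandas as pd
import pytest

from synnetflow.synteny import Anchor, build_anchors, chain_anchors, detect_all
from synnetflow.simulate import SimConfig, simulate

from conftest import ranked_genome


def hits_df(pairs):
    return pd.DataFrame(
        [(q, s, 90.0, 1e-20, 100.0) for q, s in pairs],
        columns=["query_id", "subject_id", "identity_pct", "evalue", "bitscore"])


def exhaustive_best_chain(anchors, max_gap):
    """Oracle: maximum sign-consistent chain length by depth-first search."""
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].rank_a, anchors[i].rank_b))
    best = 0

    def extend(last, sign, length):
        nonlocal best
        best = max(best, length)
        la, lb = anchors[last].rank_a, anchors[last].rank_b
        for j in order:
            da = anchors[j].rank_a - la
            if da <= 0 or da > max_gap:
                continue
            db = anchors[j].rank_b - lb
            if sign == 0:
                for s in (1, -1):
                    if 0 < db * s <= max_gap:
                        extend(j, s, length + 1)
            elif 0 < db * sign <= max_gap:
                extend(j, sign, length + 1)

    for i in order:
        extend(i, 0, 1)
    return best


class TestBuildAnchors:
    def test_inter_genome_one_anchor_per_pair(self):
        ga = ranked_genome("A", {"chr1": 10})
        gb = ranked_genome("B", {"chr1": 10})
        pairs = [(f"A_chr1_{i}", f"B_chr1_{i}") for i in range(5)]
        assert len(build_anchors(ga, gb, hits_df(pairs))) == 5

    def test_intra_adjacent_pair_excluded_distant_kept(self):
        g = ranked_genome("A", {"chr1": 50})
        anchors = build_anchors(g, g, hits_df([
            ("A_chr1_7", "A_chr1_8"),    # distance 1: tandem, excluded
            ("A_chr1_7", "A_chr1_40"),   # distance 33: kept
            ("A_chr1_3", "A_chr1_3"),    # self-diagonal: never
        ]))
        assert [(a.gene_a, a.gene_b) for a in anchors] == [("A_chr1_7", "A_chr1_40")]

    def test_duplicate_directions_collapse(self):
        ga = ranked_genome("A", {"chr1": 5})
        gb = ranked_genome("B", {"chr1": 5})
        anchors = build_anchors(ga, gb, hits_df(
            [("A_chr1_1", "B_chr1_2"), ("B_chr1_2", "A_chr1_1")]))
        assert len(anchors) == 1

    def test_unknown_gene_errors(self):
        ga = ranked_genome("A", {"chr1": 5})
        gb = ranked_genome("B", {"chr1": 5})
        with pytest.raises(ValueError, match="unknown"):
            build_anchors(ga, gb, hits_df([("A_chr1_1", "GHOST")]))


class TestChainAnchors:
    def test_perfect_diagonal_forward_block(self):
        anchors = [Anchor(f"a{i}", f"b{i}", i, i, "c1", "c2") for i in range(6)]
        blocks = chain_anchors(anchors, min_anchors=5, max_gap=25)
        assert len(blocks) == 1
        assert blocks[0].orientation == "forward"
        assert blocks[0].score == 6

    def test_anti_diagonal_inverted_block(self):
        anchors = [Anchor(f"a{i}", f"b{i}", i, 7 - i, "c1", "c2") for i in range(1, 7)]
        blocks = chain_anchors(anchors, min_anchors=5, max_gap=25)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"
        assert blocks[0].score == 6

    def test_min_anchors_filters_short_chains(self):
        anchors = [Anchor(f"a{i}", f"b{i}", i, i, "c1", "c2") for i in range(4)]
        assert chain_anchors(anchors, min_anchors=5, max_gap=25) == []

    def test_chain_score_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(150):
            n = int(rng.integers(2, 13))
            coords = set()
            while len(coords) < n:
                coords.add((int(rng.integers(0, 16)), int(rng.integers(0, 16))))
            anchors = [Anchor(f"a{i}", f"b{i}", ra, rb, "c1", "c2")
                       for i, (ra, rb) in enumerate(sorted(coords))]
            gap = int(rng.integers(2, 8))
            blocks = chain_anchors(anchors, min_anchors=1, max_gap=gap)
            got = max((b.score for b in blocks), default=0)
            assert got == exhaustive_best_chain(anchors, gap)

    def test_blocks_partition_their_anchors(self):
        rng = np.random.default_rng(8)
        coords = {(int(rng.integers(0, 40)), int(rng.integers(0, 40))) for _ in range(80)}
        anchors = [Anchor(f"a{i}", f"b{i}", ra, rb, "c1", "c2")
                   for i, (ra, rb) in enumerate(sorted(coords))]
        blocks = chain_anchors(anchors, min_anchors=3, max_gap=10)
        seen = set()
        for b in blocks:
            for a in b.anchors:
                assert a not in seen  # no anchor in two blocks
                seen.add(a)

    def test_parameter_monotonicity(self):
        rng = np.random.default_rng(9)
        coords = {(int(rng.integers(0, 30)), int(rng.integers(0, 30))) for _ in range(60)}
        anchors = [Anchor(f"a{i}", f"b{i}", ra, rb, "c1", "c2")
                   for i, (ra, rb) in enumerate(sorted(coords))]

        def anchored(min_anchors, max_gap):
            return sum(b.score for b in chain_anchors(anchors, min_anchors, max_gap))

        assert anchored(3, 10) >= anchored(5, 10)   # lowering min_anchors
        assert anchored(5, 15) >= anchored(5, 10)   # raising max_gap


class TestDetectAll:
    def test_identical_genomes_fully_anchored(self):
        cfg = SimConfig(tree="(a:0.0,b:0.0):0.0;", root_genes=100, chromosomes=2,
                        rates={k: 0.0 for k in ("inversion", "loss", "tandem_dup",
                                                "proximal_dup", "dispersed_dup")},
                        seed=4)
        genomes, hits, _ = simulate(cfg)
        blocks = detect_all(genomes, hits)
        cross = [b for b in blocks if b.species_a != b.species_b]
        anchored = {a.gene_a for b in cross for a in b.anchors}
        assert anchored == set(genomes["a"].df["gene_id"])

    def test_disjoint_families_give_no_blocks(self):
        ga = ranked_genome("A", {"chr1": 20})
        gb = ranked_genome("B", {"chr1": 20})
        assert detect_all({"A": ga, "B": gb}, hits_df([])) == []

    def test_inversion_splits_or_inverts_blocks(self):
        ga = ranked_genome("A", {"chr1": 30})
        rows = []
        order = list(range(10)) + list(range(19, 9, -1)) + list(range(20, 30))
        for pos, i in enumerate(order):
            rows.append((f"B_chr1_{i}", "chr1", 1000 * pos + 1, 1000 * pos + 500, "+"))
        from conftest import make_genome
        gb = make_genome("B", rows)
        pairs = [(f"A_chr1_{i}", f"B_chr1_{i}") for i in range(30)]
        blocks = detect_all({"A": ga, "B": gb}, hits_df(pairs))
        assert len(blocks) >= 2
        assert any(b.orientation == "inverted" for b in blocks)
        anchored = {a.gene_a for b in blocks for a in b.anchors}
        assert anchored == {f"A_chr1_{i}" for i in range(30)}

    def test_every_block_is_sign_consistent(self, zero_noise_run):
        for b in zero_noise_run["blocks"]:
            ra = [a.rank_a for a in b.anchors]
            rb = [a.rank_b for a in b.anchors]
            assert all(y > x for x, y in zip(ra, ra[1:]))
            step = 1 if b.orientation == "forward" else -1
            assert all((y - x) * step > 0 for x, y in zip(rb, rb[1:]))
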