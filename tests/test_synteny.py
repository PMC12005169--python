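"""Anchor chaining vs brute force, duplicate classes, syntenic depth."""

from __future__ import annotations

import itertools

import pytest

from wgdkit.models import GeneHit, rank_index
from wgdkit.simulate import kmer_hits
from wgdkit.synteny import (Anchor, CollinearBlock, _chain_dp, chain_anchors,
                            classify_duplicates, syntenic_depth_ratio)

REWARD, GAP = 10.0, 1.0


def _mk(hits_xy, scaf_a="s1", scaf_b="s2"):
    """Build hits + ranks from (rank_a, rank_b) pairs."""
    hits, ranks = [], {}
    for ra, rb in hits_xy:
        ga, gb = f"a{ra}", f"b{rb}"
        ranks[ga] = (scaf_a, ra)
        ranks[gb] = (scaf_b, rb)
        hits.append(GeneHit(ga, gb, score=50.0, evalue=1e-50))
    return hits, ranks


def _brute_best_chain(points, orientation, max_gap):
    """Exhaustive best-chain score over all anchor subsets (n <= 12)."""
    best = 0.0
    n = len(points)
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            pts = [points[i] for i in combo]
            pts.sort()
            ok = True
            for (a1, b1), (a2, b2) in zip(pts, pts[1:]):
                da = a2 - a1
                db = (b2 - b1) if orientation == "same" else (b1 - b2)
                if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                    ok = False
                    break
            if not ok:
                continue
            score = r * REWARD
            for (a1, b1), (a2, b2) in zip(pts, pts[1:]):
                db = (b2 - b1) if orientation == "same" else (b1 - b2)
                score -= GAP * ((a2 - a1 - 1) + (db - 1))
            best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# chaining

def test_collinear_run_gives_one_block():
    hits, ranks = _mk([(i, i) for i in range(10)])
    blocks = chain_anchors(hits, ranks, min_block=5)
    assert len(blocks) == 1
    assert len(blocks[0].anchors) == 10
    assert blocks[0].orientation == "same"


def test_inversion_gives_two_opposite_blocks():
    fwd = [(i, i) for i in range(6)]
    inv = [(10 + i, 25 - i) for i in range(6)]
    hits, ranks = _mk(fwd + inv)
    blocks = chain_anchors(hits, ranks, min_block=5)
    assert len(blocks) == 2
    assert sorted(b.orientation for b in blocks) == ["inverted", "same"]
    assert all(len(b.anchors) == 6 for b in blocks)


def test_below_min_block_gives_no_blocks():
    hits, ranks = _mk([(i, i) for i in range(3)])
    assert chain_anchors(hits, ranks, min_block=5) == []


def test_unknown_gene_rejected():
    hits, ranks = _mk([(1, 1)])
    del ranks["b1"]
    with pytest.raises(KeyError, match="b1"):
        chain_anchors(hits, ranks)


@pytest.mark.parametrize("seed", range(8))
def test_dp_matches_brute_force_on_random_anchor_sets(seed):
    """DP chain score equals exhaustive enumeration for n <= 12 anchors."""
    import random

    rnd = random.Random(seed)
    n = rnd.randint(4, 12)
    pts = set()
    while len(pts) < n:
        pts.add((rnd.randint(0, 15), rnd.randint(0, 15)))
    points = sorted(pts)
    anchors = [Anchor(f"a{i}", f"b{i}", ra, rb)
               for i, (ra, rb) in enumerate(points)]
    for orientation in ("same", "inverted"):
        idx, score = _chain_dp(anchors, orientation, max_gap=6,
                               anchor_reward=REWARD, gap_penalty=GAP)
        brute = _brute_best_chain(points, orientation, max_gap=6)
        assert score == pytest.approx(brute)


def test_no_anchor_in_two_blocks_and_orientation_consistent():
    hits, ranks = _mk([(i, i) for i in range(8)]
                      + [(i, 20 + (i % 4)) for i in range(8)])
    blocks = chain_anchors(hits, ranks, min_block=4)
    seen = set()
    for b in blocks:
        for a in b.anchors:
            key = (a.gene_a, a.gene_b)
            assert key not in seen
            seen.add(key)
        ras = [a.rank_a for a in b.anchors]
        rbs = [a.rank_b for a in b.anchors]
        assert ras == sorted(ras)
        if b.orientation == "same":
            assert rbs == sorted(rbs)
        else:
            assert rbs == sorted(rbs, reverse=True)


# ---------------------------------------------------------------------------
# classification

def test_adjacent_pair_outside_blocks_is_tandem():
    ranks = {"g5": ("s1", 5), "g6": ("s1", 6)}
    hits = [GeneHit("g5", "g6", 100.0)]
    pairs = classify_duplicates(hits, ranks, [])
    assert pairs[0].mode == "tandem"


def test_cross_scaffold_pair_outside_blocks_is_dispersed():
    ranks = {"g1": ("s1", 5), "g2": ("s2", 5)}
    pairs = classify_duplicates([GeneHit("g1", "g2", 100.0)], ranks, [])
    assert pairs[0].mode == "dispersed"


def test_near_pair_is_proximal_and_classification_is_partition():
    ranks = {f"g{i}": ("s1", i) for i in range(20)}
    hits = [GeneHit("g0", "g5", 10.0), GeneHit("g0", "g15", 10.0),
            GeneHit("g3", "g4", 10.0)]
    pairs = classify_duplicates(hits, ranks, [])
    modes = {(p.gene_a, p.gene_b): p.mode for p in pairs}
    assert modes[("g0", "g5")] == "proximal"
    assert modes[("g0", "g15")] == "dispersed"
    assert modes[("g3", "g4")] == "tandem"
    assert len(pairs) == len(hits)  # every pair exactly one class


def test_truth_wgd_pairs_recovered_from_simulation(sim_default):
    """>= 95% of surviving truth WGD pairs classified wgd; tandems never."""
    res = sim_default
    cds = res.cds_dict("ingA")
    ranks = rank_index(res.genes["ingA"])
    hits = kmer_hits(cds)
    blocks = chain_anchors(hits, ranks, min_block=5, max_gap=25)
    pairs = classify_duplicates(hits, ranks, blocks)
    mode_of = {frozenset((p.gene_a, p.gene_b)): p.mode for p in pairs}
    truth_wgd = [frozenset((a, b)) for a, b, _ in res.truth.wgd_pairs
                 if a in cds and b in cds]
    called = [mode_of.get(p) for p in truth_wgd if p in mode_of]
    assert len(called) / len(truth_wgd) > 0.9
    assert sum(1 for m in called if m == "wgd") / len(called) >= 0.95
    truth_tandem = [frozenset((a, b)) for a, b, _ in res.truth.tandem_pairs
                    if a.startswith("ingA")]
    assert all(mode_of.get(p) != "wgd" for p in truth_tandem)


# ---------------------------------------------------------------------------
# syntenic depth

def test_duplicated_genome_has_modal_depth_two(sim_default):
    res = sim_default
    ranks_ref = rank_index(res.genes["out1"])
    ranks_q = rank_index(res.genes["ingA"])
    hits = kmer_hits(res.cds_dict("out1"), res.cds_dict("ingA"))
    blocks = chain_anchors(hits, {**ranks_ref, **ranks_q}, min_block=5,
                           max_gap=25)
    hist, modal = syntenic_depth_ratio(blocks, ranks_ref)
    assert modal == 2


def test_unduplicated_genome_has_modal_depth_one(sim_default):
    res = sim_default
    ranks_ref = rank_index(res.genes["out1"])
    ranks_q = rank_index(res.genes["out2"])
    hits = kmer_hits(res.cds_dict("out1"), res.cds_dict("out2"))
    blocks = chain_anchors(hits, {**ranks_ref, **ranks_q}, min_block=5,
                           max_gap=25)
    _, modal = syntenic_depth_ratio(blocks, ranks_ref)
    assert modal == 1


def test_deleted_region_drops_to_depth_one():
    # reference genes r0..r19; query has two homoeologous scaffolds but one
    # lost its copies of the last 10 genes
    hits, ranks = [], {}
    for i in range(20):
        ranks[f"r{i}"] = ("ref", i)
    for i in range(20):
        ranks[f"qa{i}"] = ("qA", i)
        hits.append(GeneHit(f"r{i}", f"qa{i}", 50.0))
    for i in range(14):
        ranks[f"qb{i}"] = ("qB", i)
        hits.append(GeneHit(f"r{i}", f"qb{i}", 50.0))
    blocks = chain_anchors(hits, ranks, min_block=5)
    depth, modal = syntenic_depth_ratio(
        blocks, {f"r{i}": ("ref", i) for i in range(20)})
    assert modal == 2
    assert depth == {2: 14, 1: 6}
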