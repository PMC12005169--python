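"""Collinear block chaining and duplicate-mode classification.

Anchors (similarity hits between positionally ranked genes) are chained by
dynamic programming within each scaffold pair, in both orientations, into
collinear blocks — the gene-order signature of segmental/whole-genome
duplication. Duplicate pairs are then classified with the usual precedence:

    wgd (block anchor) > tandem (adjacent in rank) > proximal (near) >
    dispersed (everything else)

Chaining scores are ``anchor_reward`` per anchor minus a linear
``gap_penalty`` per skipped rank unit on either scaffold; chains shorter
than ``min_block`` anchors are discarded, and blocks are extracted greedily
by descending chain score so no anchor belongs to two blocks. Ties between
equal-score chains are broken toward the smaller starting rank.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import GeneHit


@dataclass
class Anchor:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    score: float = 0.0


@dataclass
class CollinearBlock:
    block_id: int
    scaffold_a: str
    scaffold_b: str
    orientation: str  # "same" | "inverted"
    anchors: list[Anchor]
    chain_score: float

    @property
    def span_a(self) -> tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def span_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def pairs(self) -> set[frozenset[str]]:
        return {frozenset((a.gene_a, a.gene_b)) for a in self.anchors}


@dataclass
class DuplicatePair:
    gene_a: str
    gene_b: str
    mode: str  # wgd | tandem | proximal | dispersed
    block_id: int | None = None


def _chain_dp(
    anchors: list[Anchor],
    orientation: str,
    max_gap: int,
    anchor_reward: float,
    gap_penalty: float,
) -> tuple[list[int], float]:
    """Best single chain (indices into ``anchors``) for one orientation.

    Same-orientation chains must be strictly increasing in both ranks;
    inverted chains increase in rank_a while decreasing in rank_b. O(n^2).
    """
    n = len(anchors)
    order = sorted(
        range(n),
        key=lambda i: (anchors[i].rank_a,
                       anchors[i].rank_b if orientation == "same"
                       else -anchors[i].rank_b),
    )
    best = [anchor_reward] * n
    prev = [-1] * n
    for oi, i in enumerate(order):
        ai = anchors[i]
        for j in order[:oi]:
            aj = anchors[j]
            da = ai.rank_a - aj.rank_a
            if orientation == "same":
                db = ai.rank_b - aj.rank_b
            else:
                db = aj.rank_b - ai.rank_b
            if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                continue
            cand = best[j] + anchor_reward - gap_penalty * ((da - 1) + (db - 1))
            if cand > best[i] + 1e-12:
                best[i] = cand
                prev[i] = j
    if not n:
        return [], float("-inf")
    # tie-break: higher score, then smaller starting rank of the chain
    def chain_of(i: int) -> list[int]:
        out = []
        while i != -1:
            out.append(i)
            i = prev[i]
        return out[::-1]

    best_i = max(
        range(n),
        key=lambda i: (best[i], -anchors[chain_of(i)[0]].rank_a,
                       -anchors[chain_of(i)[0]].rank_b),
    )
    return chain_of(best_i), best[best_i]


def chain_anchors(
    hits: list[GeneHit],
    gene_ranks: dict[str, tuple[str, int]],
    min_block: int = 5,
    max_gap: int = 25,
    anchor_reward: float = 10.0,
    gap_penalty: float = 1.0,
) -> list[CollinearBlock]:
    """Chain similarity hits into collinear blocks per scaffold pair."""
    if min_block < 2:
        raise ValueError("min_block must be >= 2")
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    for h in hits:
        for g in (h.query, h.subject):
            if g not in gene_ranks:
                raise KeyError(f"hit references unknown gene {g!r}")
        sa, ra = gene_ranks[h.query]
        sb, rb = gene_ranks[h.subject]
        ga, gb = h.query, h.subject
        # canonical orientation of the scaffold pair
        if (sa, ra) > (sb, rb):
            sa, ra, sb, rb, ga, gb = sb, rb, sa, ra, gb, ga
        by_pair.setdefault((sa, sb), []).append(
            Anchor(ga, gb, ra, rb, h.score)
        )

    blocks: list[CollinearBlock] = []
    bid = 0
    for (sa, sb) in sorted(by_pair):
        pool = by_pair[(sa, sb)]
        while True:
            cands = []
            for orientation in ("same", "inverted"):
                idx, score = _chain_dp(pool, orientation, max_gap,
                                       anchor_reward, gap_penalty)
                if idx and len(idx) >= min_block:
                    cands.append((score, orientation, idx))
            if not cands:
                break
            cands.sort(key=lambda c: (-c[0], c[1],
                                      pool[c[2][0]].rank_a))
            score, orientation, idx = cands[0]
            chain = [pool[i] for i in idx]
            blocks.append(CollinearBlock(
                block_id=bid, scaffold_a=sa, scaffold_b=sb,
                orientation=orientation, anchors=chain, chain_score=score,
            ))
            bid += 1
            used = set(idx)
            pool = [a for i, a in enumerate(pool) if i not in used]
    return blocks


def classify_duplicates(
    hits: list[GeneHit],
    gene_ranks: dict[str, tuple[str, int]],
    blocks: list[CollinearBlock],
    tandem_gap: int = 1,
    proximal_gap: int = 10,
) -> list[DuplicatePair]:
    """Partition duplicate pairs into wgd / tandem / proximal / dispersed."""
    anchor_block: dict[frozenset[str], int] = {}
    for b in blocks:
        for p in b.pairs:
            anchor_block.setdefault(p, b.block_id)
    out = []
    seen: set[frozenset[str]] = set()
    for h in hits:
        pair = h.pair
        if pair in seen:
            continue
        seen.add(pair)
        sa, ra = gene_ranks[h.query]
        sb, rb = gene_ranks[h.subject]
        if pair in anchor_block:
            mode, bid = "wgd", anchor_block[pair]
        elif sa == sb and abs(ra - rb) <= tandem_gap:
            mode, bid = "tandem", None
        elif sa == sb and abs(ra - rb) <= proximal_gap:
            mode, bid = "proximal", None
        else:
            mode, bid = "dispersed", None
        out.append(DuplicatePair(h.query, h.subject, mode, bid))
    return out


def syntenic_depth_ratio(
    blocks: list[CollinearBlock],
    ref_ranks: dict[str, tuple[str, int]],
) -> tuple[dict[int, int], int]:
    """Per-reference-gene syntenic depth histogram and its mode.

    Depth of a reference gene = number of blocks whose reference-side rank
    span covers its rank. A once-duplicated genome aligned to an
    unduplicated reference has modal depth 2 (the 2:1 quota); no
    duplication gives modal depth 1.
    """
    ref_genes: dict[str, list[int]] = {}
    for gid, (scaf, rank) in ref_ranks.items():
        ref_genes.setdefault(scaf, []).append(rank)
    depth: dict[tuple[str, int], int] = {
        (scaf, r): 0 for scaf, ranks in ref_genes.items() for r in ranks
    }
    for b in blocks:
        # which side of the block is the reference?
        for side in ("a", "b"):
            genes = [getattr(a, f"gene_{side}") for a in b.anchors]
            if all(g in ref_ranks for g in genes):
                scaf = getattr(b, f"scaffold_{side}")
                lo, hi = (b.span_a if side == "a" else b.span_b)
                for r in range(lo, hi + 1):
                    if (scaf, r) in depth:
                        depth[(scaf, r)] += 1
                break
    hist: dict[int, int] = {}
    for d in depth.values():
        hist[d] = hist.get(d, 0) + 1
    modal = max(sorted(hist), key=lambda d: (hist[d], -d)) if hist else 0
    return hist, modal
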