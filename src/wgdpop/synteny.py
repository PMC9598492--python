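"""Colinear (synteny) block detection from gene ranks and homology hits.

A whole-genome duplication leaves genome-wide runs of paralogous genes in
conserved order.  Blocks are detected as monotone chains of anchors (pairs
of homologous genes) with bounded gaps: a block needs at least
``min_block_genes`` anchors and allows at most ``max_intervening``
non-anchor genes between consecutive anchors on *each* side.

Chains are found per chromosome pair and orientation by longest-chain
dynamic programming scored by (anchor count, summed bit score); overlapping
chains are resolved greedily best-first with used anchors removed.  All
tie-breaks are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import GeneCatalog

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    score: float


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    anchors: list[Anchor]

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def score(self) -> float:
        return sum(a.score for a in self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def span_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks)


def validate_block(block: SyntenyBlock, min_block_genes: int, max_intervening: int) -> None:
    """Raise AssertionError if a block violates its defining invariants."""
    assert block.n_anchors >= min_block_genes, "block below minimum anchor count"
    sign = 1 if block.orientation == "same" else -1
    for prev, cur in zip(block.anchors, block.anchors[1:]):
        assert cur.rank_a > prev.rank_a, "rank_a not strictly increasing"
        db = sign * (cur.rank_b - prev.rank_b)
        assert db > 0, "rank_b not monotone for orientation"
        assert cur.rank_a - prev.rank_a - 1 <= max_intervening, "gap on side a too large"
        assert db - 1 <= max_intervening, "gap on side b too large"


# ---------------------------------------------------------------------------
# Tandem collapse


def collapse_tandem(
    hits: pd.DataFrame, catalog: GeneCatalog, max_tandem_rank_gap: int = 1
) -> pd.DataFrame:
    """Collapse tandem duplicate arrays before intra-genomic chaining.

    Mutually-hitting genes on the same chromosome within
    ``max_tandem_rank_gap`` ranks form an array; only the member with the
    highest summed bit score keeps its hits.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for q, s in zip(hits["query_id"], hits["subject_id"]):
        if q in catalog and s in catalog:
            gq, gs = catalog[q], catalog[s]
            if gq.chromosome == gs.chromosome and abs(gq.rank - gs.rank) <= max_tandem_rank_gap:
                union(q, s)

    members: dict[str, list[str]] = {}
    for g in set(parent) | {v for v in parent.values()}:
        members.setdefault(find(g), []).append(g)

    total_score = hits.groupby("query_id")["bit_score"].sum().add(
        hits.groupby("subject_id")["bit_score"].sum(), fill_value=0.0
    )
    removed: set[str] = set()
    for comp in members.values():
        if len(comp) < 2:
            continue
        rep = max(comp, key=lambda g: (total_score.get(g, 0.0), _rev(g)))
        removed.update(g for g in comp if g != rep)
    if removed:
        log.info("tandem collapse removed hits of %d genes", len(removed))
    keep = ~(hits["query_id"].isin(removed) | hits["subject_id"].isin(removed))
    return hits[keep].reset_index(drop=True)


class _rev(str):
    """Reverses lexicographic order so max() prefers the smallest id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)


# ---------------------------------------------------------------------------
# Anchors


def build_anchors(
    hits: pd.DataFrame,
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog | None = None,
    intra: bool | None = None,
) -> list[Anchor]:
    """One anchor per retained (query, subject) hit pair with ranks attached.

    In intra-genomic mode (``catalog_b is None`` or ``intra=True``) each
    unordered pair appears once, genes in lexicographic order, keeping the
    best bit score among reciprocal rows.  Hits referencing genes absent
    from a catalog are dropped with a warning.
    """
    if catalog_b is None:
        catalog_b = catalog_a
        intra = True if intra is None else intra
    intra = bool(intra)

    best: dict[tuple[str, str], float] = {}
    n_unknown = 0
    for q, s, score in zip(hits["query_id"], hits["subject_id"], hits["bit_score"]):
        if intra:
            q, s = (q, s) if q <= s else (s, q)
        if q not in catalog_a or s not in catalog_b:
            n_unknown += 1
            continue
        key = (q, s)
        if score > best.get(key, float("-inf")):
            best[key] = score
    if n_unknown:
        log.warning("dropped %d hits referencing genes absent from the catalog", n_unknown)

    anchors = []
    for (q, s), score in sorted(best.items()):
        ga, gb = catalog_a[q], catalog_b[s]
        anchors.append(
            Anchor(
                gene_a=q, gene_b=s,
                chrom_a=ga.chromosome, chrom_b=gb.chromosome,
                rank_a=ga.rank, rank_b=gb.rank, score=float(score),
            )
        )
    return anchors


# ---------------------------------------------------------------------------
# Chaining


def _best_chain(
    anchors: list[Anchor], orientation: str, max_intervening: int
) -> list[Anchor]:
    """Best monotone chain by DP; score = (count, summed bit score, -start rank)."""
    sign = 1 if orientation == "same" else -1
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].rank_a, anchors[i].rank_b))
    n = len(order)
    count = [1] * n
    score = [anchors[order[i]].score for i in range(n)]
    pred = [-1] * n
    for j in range(n):
        aj = anchors[order[j]]
        for i in range(j):
            ai = anchors[order[i]]
            da = aj.rank_a - ai.rank_a
            db = sign * (aj.rank_b - ai.rank_b)
            if da <= 0 or db <= 0 or da - 1 > max_intervening or db - 1 > max_intervening:
                continue
            cand = (count[i] + 1, score[i] + aj.score)
            if cand > (count[j], score[j]):
                count[j], score[j] = cand
                pred[j] = i
    if n == 0:
        return []
    best_j = max(
        range(n),
        key=lambda j: (count[j], score[j], -_chain_start(order, pred, anchors, j)),
    )
    chain = []
    j = best_j
    while j != -1:
        chain.append(anchors[order[j]])
        j = pred[j]
    return chain[::-1]


def _chain_start(order, pred, anchors, j) -> int:
    while pred[j] != -1:
        j = pred[j]
    return anchors[order[j]].rank_a


def chain_anchors(
    anchors: list[Anchor], min_block_genes: int = 10, max_intervening: int = 5
) -> list[SyntenyBlock]:
    """Extract synteny blocks from anchors, greedily best-first.

    Per chromosome pair: repeatedly take the best remaining chain over both
    orientations (count, then summed bit score, then smallest start rank,
    then orientation "same" first), remove its anchors, and stop when the
    best chain falls below ``min_block_genes``.
    """
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[SyntenyBlock] = []
    for (ca, cb) in sorted(by_pair):
        remaining = list(by_pair[(ca, cb)])
        while remaining:
            candidates = []
            for orientation in ("same", "inverted"):
                chain = _best_chain(remaining, orientation, max_intervening)
                if chain:
                    candidates.append(
                        (
                            len(chain),
                            sum(x.score for x in chain),
                            -chain[0].rank_a,
                            orientation == "same",
                            orientation,
                            chain,
                        )
                    )
            if not candidates:
                break
            best = max(candidates)
            orientation, chain = best[4], best[5]
            if len(chain) < min_block_genes:
                break
            blocks.append(SyntenyBlock(chrom_a=ca, chrom_b=cb, orientation=orientation, anchors=chain))
            used = set(chain)
            remaining = [a for a in remaining if a not in used]

    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, -b.n_anchors, b.anchors[0].rank_a))
    return blocks


def homeolog_pairs(blocks: list[SyntenyBlock]) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Concatenated anchor pairs across blocks, deduplicated.

    Returns (unique pairs in first-seen order, pairs seen in more than one
    block).
    """
    seen: dict[tuple[str, str], int] = {}
    for block in blocks:
        for a in block.anchors:
            seen[(a.gene_a, a.gene_b)] = seen.get((a.gene_a, a.gene_b), 0) + 1
    pairs = list(seen)
    duplicated = [p for p, c in seen.items() if c > 1]
    return pairs, duplicated


def find_blocks(
    hits: pd.DataFrame,
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog | None = None,
    min_block_genes: int = 10,
    max_intervening: int = 5,
    max_tandem_rank_gap: int = 1,
) -> list[SyntenyBlock]:
    """End-to-end block detection.

    Intra-genomic mode (one catalog): tandem arrays are collapsed and
    reciprocal hits deduplicated.  Inter-genomic mode (two catalogs): the
    identical chaining machinery with no self-pair dedup and no tandem
    collapse.
    """
    if catalog_b is None:
        hits = collapse_tandem(hits, catalog_a, max_tandem_rank_gap)
    anchors = build_anchors(hits, catalog_a, catalog_b)
    return chain_anchors(anchors, min_block_genes, max_intervening)


def blocks_table(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    rows = [
        {
            "block_id": i,
            "chrom_a": b.chrom_a,
            "chrom_b": b.chrom_b,
            "orientation": b.orientation,
            "n_anchors": b.n_anchors,
            "score": b.score,
            "start_rank_a": b.span_a[0],
            "end_rank_a": b.span_a[1],
            "start_rank_b": b.span_b[0],
            "end_rank_b": b.span_b[1],
        }
        for i, b in enumerate(blocks)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "block_id", "chrom_a", "chrom_b", "orientation", "n_anchors",
            "score", "start_rank_a", "end_rank_a", "start_rank_b", "end_rank_b",
        ],
    )
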