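"""Collinearity: anchor chaining, dotplot tiers, ortholog assignment, quartets.

Chaining works in gene-index (rank) coordinates rather than base pairs,
which makes block detection robust to intergenic length variation — the
natural coordinate system for gene-level dotplots.  Blocks are maximal-
scoring monotone chains of homology anchors (same or inverted orientation)
extracted greedily by descending chain score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .homology import (
    DEFAULT_SCORING,
    HomologyHit,
    ScoringScheme,
    global_align,
    percent_identity,
)

__all__ = [
    "Anchor",
    "CollinearBlock",
    "HomologQuartet",
    "BreakRegion",
    "chain_anchors",
    "classify_dotplot",
    "detect_insertion_breaks",
    "assign_orthologs",
    "detect_quartets",
    "pick_outgroup",
]


@dataclass(frozen=True)
class Anchor:
    """A homology hit placed at gene-rank coordinates on both chromosomes."""

    index_a: int
    index_b: int
    hit: HomologyHit


@dataclass
class CollinearBlock:
    anchors: list[Anchor]
    orientation: str  # "same" | "inverted"
    score: float
    block_id: int = -1

    @property
    def genes_a(self) -> list[str]:
        return [a.hit.query_id for a in self.anchors]

    @property
    def genes_b(self) -> list[str]:
        return [a.hit.subject_id for a in self.anchors]

    @property
    def span_a(self) -> tuple[int, int]:
        idx = [a.index_a for a in self.anchors]
        return (min(idx), max(idx) + 1)

    @property
    def span_b(self) -> tuple[int, int]:
        idx = [a.index_b for a in self.anchors]
        return (min(idx), max(idx) + 1)


@dataclass
class BreakRegion:
    """A run of consecutive block-less genes interrupting collinearity."""

    genome: str  # "a" | "b"
    start_index: int
    end_index: int  # half-open in gene-rank units
    n_genes: int
    left_block: int | None
    right_block: int | None


@dataclass
class HomologQuartet:
    species_with_paralogs: str  # "A" | "B"
    paralog_1: str
    paralog_2: str
    ortholog_1: str
    ortholog_2: str
    outgroup: str | None = None
    paralog_identity: float = 0.0
    separation: int = 0


def _best_chain(
    anchors: Sequence[Anchor], inverted: bool, gap_penalty: float
) -> tuple[list[int], float]:
    """Best monotone chain over the anchors by sparse dynamic programming.

    Chain score = sum of anchor scores − gap_penalty · (index gaps on both
    axes).  Returns member indices (into ``anchors``) and the chain score.
    """
    n = len(anchors)
    if n == 0:
        return [], 0.0
    order = sorted(
        range(n),
        key=lambda i: (
            anchors[i].index_a,
            -anchors[i].index_b if inverted else anchors[i].index_b,
        ),
    )
    best = [anchors[i].hit.score for i in order]
    prev: list[int | None] = [None] * n
    for pi in range(n):
        i = order[pi]
        ai, bi = anchors[i].index_a, anchors[i].index_b
        for pj in range(pi):
            j = order[pj]
            aj, bj = anchors[j].index_a, anchors[j].index_b
            if aj >= ai:
                continue
            if (bj >= bi) if not inverted else (bj <= bi):
                continue
            gap = (ai - aj - 1) + abs(bi - bj) - 1
            cand = best[pj] + anchors[i].hit.score - gap_penalty * gap
            if cand > best[pi] + 1e-12:
                best[pi] = cand
                prev[pi] = pj
    end = max(range(n), key=lambda pi: best[pi])
    chain_pos: list[int] = []
    p: int | None = end
    while p is not None:
        chain_pos.append(order[p])
        p = prev[p]
    chain_pos.reverse()
    return chain_pos, best[end]


def chain_anchors(
    hits: Sequence[HomologyHit],
    order_a: Sequence[str],
    order_b: Sequence[str],
    gap_penalty: float = 1.0,
    min_block_anchors: int = 3,
) -> list[CollinearBlock]:
    """Chain cross-genome hits into non-overlapping collinear blocks.

    Anchors are chained separately in same and inverted orientation; the
    highest-scoring chain is extracted, its anchors removed, and the
    process repeats until no chain of at least ``min_block_anchors``
    remains (greedy non-overlapping extraction).
    """
    rank_a = {g: i for i, g in enumerate(order_a)}
    rank_b = {g: i for i, g in enumerate(order_b)}
    pool = [
        Anchor(rank_a[h.query_id], rank_b[h.subject_id], h)
        for h in hits
        if h.query_id in rank_a and h.subject_id in rank_b
    ]
    # one anchor per (gene_a, gene_b): keep the best-scoring hit
    dedup: dict[tuple[int, int], Anchor] = {}
    for a in pool:
        key = (a.index_a, a.index_b)
        if key not in dedup or a.hit.score > dedup[key].hit.score:
            dedup[key] = a
    pool = list(dedup.values())

    blocks: list[CollinearBlock] = []
    while pool:
        members_s, score_s = _best_chain(pool, inverted=False, gap_penalty=gap_penalty)
        members_i, score_i = _best_chain(pool, inverted=True, gap_penalty=gap_penalty)
        if len(members_s) >= len(members_i) and score_s >= score_i:
            members, score, orient = members_s, score_s, "same"
        else:
            members, score, orient = members_i, score_i, "inverted"
        if len(members) < min_block_anchors:
            break
        chain = [pool[i] for i in members]
        blocks.append(CollinearBlock(chain, orient, score))
        used = set(members)
        used_a = {pool[i].index_a for i in members}
        used_b = {pool[i].index_b for i in members}
        pool = [
            a
            for i, a in enumerate(pool)
            if i not in used and a.index_a not in used_a and a.index_b not in used_b
        ]
    blocks.sort(key=lambda b: -b.score)
    for i, b in enumerate(blocks):
        b.block_id = i
    return blocks


def classify_dotplot(
    hits: Sequence[HomologyHit],
    blocks: Sequence[CollinearBlock],
    order_a: Sequence[str],
    order_b: Sequence[str],
) -> list[dict]:
    """Label every hit with its dotplot tier.

    red: best-rank hit sitting on a block anchor (orthologous diagonal);
    blue: secondary-rank hit; gray: everything else.
    """
    rank_a = {g: i for i, g in enumerate(order_a)}
    rank_b = {g: i for i, g in enumerate(order_b)}
    anchor_pairs = {
        (a.hit.query_id, a.hit.subject_id) for b in blocks for a in b.anchors
    }
    rows = []
    for h in hits:
        if h.rank == "best" and (h.query_id, h.subject_id) in anchor_pairs:
            tier = "red"
        elif h.rank == "secondary":
            tier = "blue"
        else:
            tier = "gray"
        rows.append(
            {
                "gene_a": h.query_id,
                "gene_b": h.subject_id,
                "index_a": rank_a.get(h.query_id, -1),
                "index_b": rank_b.get(h.subject_id, -1),
                "tier": tier,
            }
        )
    return rows


def detect_insertion_breaks(
    blocks: Sequence[CollinearBlock],
    order_a: Sequence[str],
    order_b: Sequence[str],
    min_gap_genes: int = 5,
) -> list[BreakRegion]:
    """Report runs of consecutive non-anchored genes between blocks.

    A break is at least ``min_gap_genes`` consecutive genes in either
    genome that belong to no block, annotated with the flanking blocks.
    """
    if not blocks:
        return []
    breaks: list[BreakRegion] = []
    for genome, order in (("a", order_a), ("b", order_b)):
        membership: list[int | None] = [None] * len(order)
        for b in blocks:
            for anc in b.anchors:
                idx = anc.index_a if genome == "a" else anc.index_b
                membership[idx] = b.block_id
        i = 0
        n = len(order)
        while i < n:
            if membership[i] is None:
                j = i
                while j < n and membership[j] is None:
                    j += 1
                if j - i >= min_gap_genes:
                    left = membership[i - 1] if i > 0 else None
                    right = membership[j] if j < n else None
                    breaks.append(BreakRegion(genome, i, j, j - i, left, right))
                i = j
            else:
                i += 1
    return breaks


def assign_orthologs(
    blocks: Sequence[CollinearBlock], hits: Sequence[HomologyHit] | None = None
) -> tuple[dict[str, str], list[str]]:
    """1:1 ortholog map from block anchors, plus orphan list.

    Anchors inside blocks define ortholog pairs; a gene claimed by two
    blocks goes to the higher-scoring block.  Genes of genome A never
    anchored in any block are returned as orphans (genome-B orphans follow
    by set difference on the caller's side).
    """
    fwd: dict[str, str] = {}
    rev: dict[str, str] = {}
    claimed_score: dict[str, float] = {}
    for block in sorted(blocks, key=lambda b: -b.score):
        for anc in block.anchors:
            qa, qb = anc.hit.query_id, anc.hit.subject_id
            if claimed_score.get(qa, -1) >= block.score:
                continue
            if qb in rev and claimed_score.get(rev[qb], -1) >= block.score:
                continue
            if qa in fwd:
                rev.pop(fwd[qa], None)
            if qb in rev:
                fwd.pop(rev[qb], None)
            fwd[qa] = qb
            rev[qb] = qa
            claimed_score[qa] = block.score
    orphans = []
    if hits is not None:
        queried = {h.query_id for h in hits}
        orphans = sorted(q for q in queried if q not in fwd)
    return fwd, orphans


def detect_quartets(
    paralog_hits_a: Sequence[HomologyHit],
    paralog_hits_b: Sequence[HomologyHit],
    ortholog_map: Mapping[str, str],
    order_a: Sequence[str],
    order_b: Sequence[str],
    max_paralog_separation: int = 50,
    paralog_min_identity: float = 0.80,
) -> list[HomologQuartet]:
    """Build homologous gene quartets from proximal within-genome paralogs.

    For each within-genome paralog pair above the identity floor and within
    the gene-separation cap, a quartet is emitted when both members have a
    collinearity-supported ortholog in the other genome.  Pairs failing the
    ortholog requirement are conversion-uninformative and skipped.
    """
    rev_map = {v: k for k, v in ortholog_map.items()}
    quartets: list[HomologQuartet] = []
    specs = [
        ("A", paralog_hits_a, order_a, lambda g: ortholog_map.get(g)),
        ("B", paralog_hits_b, order_b, lambda g: rev_map.get(g)),
    ]
    for species, hits, order, ortho_of in specs:
        rank = {g: i for i, g in enumerate(order)}
        seen: set[tuple[str, str]] = set()
        for h in sorted(hits, key=lambda h: (h.query_id, h.subject_id)):
            p1, p2 = sorted((h.query_id, h.subject_id))
            if (p1, p2) in seen:
                continue
            seen.add((p1, p2))
            if h.identity < paralog_min_identity:
                continue
            if p1 not in rank or p2 not in rank:
                continue
            sep = abs(rank[p1] - rank[p2])
            if sep > max_paralog_separation:
                continue
            o1, o2 = ortho_of(p1), ortho_of(p2)
            if o1 is None or o2 is None or o1 == o2:
                continue
            quartets.append(
                HomologQuartet(
                    species_with_paralogs=species,
                    paralog_1=p1,
                    paralog_2=p2,
                    ortholog_1=o1,
                    ortholog_2=o2,
                    paralog_identity=h.identity,
                    separation=sep,
                )
            )
    return quartets


def pick_outgroup(
    quartet_cds: Mapping[str, str],
    outgroup_cds: Mapping[str, str],
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_identity: float = 0.5,
    kmer_size: int = 11,
    min_shared_kmers: int = 3,
) -> str | None:
    """Best-hit outgroup gene for a quartet, or None below the identity floor.

    The outgroup candidate maximizing the summed alignment score against
    all quartet members wins; equal scores break on gene id (logged by the
    caller).  Candidates sharing no k-mers with any member are skipped.
    """

    def kmers(seq: str) -> set[str]:
        s = seq.upper()
        return {s[i : i + kmer_size] for i in range(len(s) - kmer_size + 1)}

    member_kmers = [kmers(s) for s in quartet_cds.values()]
    best_id: str | None = None
    best_key: tuple[float, str] | None = None
    for ogid in sorted(outgroup_cds):
        oseq = outgroup_cds[ogid]
        okmers = kmers(oseq)
        if all(len(okmers & mk) < min_shared_kmers for mk in member_kmers):
            continue
        total = 0.0
        idents = []
        for seq in quartet_cds.values():
            aln = global_align(seq, oseq, scoring)
            total += aln.score
            try:
                idents.append(percent_identity(aln))
            except ValueError:
                idents.append(0.0)
        if max(idents) < min_identity:
            continue
        key = (-total, ogid)
        if best_key is None or key < best_key:
            best_key = key
            best_id = ogid
    return best_id
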