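"""Collinear-block chaining and syntenic depth ratios.

Gene positions are ordinal ranks along chromosomes (gene-level
collinearity, as in MCscan-style analyses), not base-pair coordinates.
Anchor pairs (putative homologues between two genomes) are chained into
strictly collinear blocks by sparse dynamic programming — a longest
increasing (or, for inverted blocks, decreasing) subsequence with a hard
cap on the rank gap allowed on either genome — and a block is reported
when it contains at least ``min_block`` anchor pairs.  Syntenic depth of
a target-genome gene is the number of reported blocks whose target-side
span covers it; the modal depths of the two reciprocal comparisons give
the depth ratio (e.g. 2:1 after one whole-genome duplication).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Genome", "GeneLocus", "AnchorPair", "SyntenyBlock", "DepthProfile",
           "chain_anchors", "syntenic_depth", "depth_ratio", "SyntenyError"]


class SyntenyError(ValueError):
    pass


@dataclass(frozen=True)
class GeneLocus:
    gene: str
    chrom: str
    index: int  # 0-based ordinal rank along the chromosome
    strand: str = "+"


class Genome:
    """Ordered gene lists per chromosome with a gene -> locus index."""

    def __init__(self, chromosomes: dict[str, list[str]]):
        self.chromosomes = {c: list(genes) for c, genes in chromosomes.items()}
        self.loci: dict[str, GeneLocus] = {}
        for chrom, genes in self.chromosomes.items():
            for i, g in enumerate(genes):
                if g in self.loci:
                    raise SyntenyError(f"duplicate gene id {g!r}")
                self.loci[g] = GeneLocus(g, chrom, i)

    @property
    def n_genes(self) -> int:
        return len(self.loci)

    def __contains__(self, gene: str) -> bool:
        return gene in self.loci


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    score: float = 1.0


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    anchors: list[tuple[int, int, AnchorPair]]  # (index_a, index_b, pair)

    @property
    def size(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        idx = [a for a, _, _ in self.anchors]
        return min(idx), max(idx)

    @property
    def span_b(self) -> tuple[int, int]:
        idx = [b for _, b, _ in self.anchors]
        return min(idx), max(idx)


@dataclass
class DepthProfile:
    depths: dict[str, int]  # gene -> number of covering blocks
    histogram: dict[int, int] = field(init=False)
    modal_depth: int = field(init=False)

    def __post_init__(self) -> None:
        self.histogram = dict(sorted(Counter(self.depths.values()).items()))
        covered = [d for d in self.depths.values() if d >= 1]
        self.modal_depth = Counter(covered).most_common(1)[0][0] if covered else 0


def _best_chain(pts: list[tuple[int, int, AnchorPair]], max_gap: int):
    """Best strictly-increasing chain (on both coordinates) with rank gaps
    capped at max_gap; unit score per anchor.  Returns list of point
    indices, best first chain by (score, then earliest start)."""
    n = len(pts)
    score = np.ones(n, dtype=np.int64)
    back = np.full(n, -1, dtype=np.int64)
    ax = np.array([p[0] for p in pts])
    bx = np.array([p[1] for p in pts])
    # pts sorted by (a, b); predecessors must be strictly smaller on both
    for j in range(n):
        da = ax[j] - ax[:j]
        db = bx[j] - bx[:j]
        ok = (da > 0) & (db > 0) & (da <= max_gap) & (db <= max_gap)
        if ok.any():
            cand = np.where(ok, score[:j], 0)
            i = int(cand.argmax())
            if cand[i] > 0:
                score[j] = cand[i] + 1
                back[j] = i
    j = int(score.argmax())
    chain = []
    while j != -1:
        chain.append(j)
        j = int(back[j])
    chain.reverse()
    return chain


def chain_anchors(anchors: list[AnchorPair], genome_a: Genome, genome_b: Genome,
                  max_gap: int = 25, min_block: int = 5) -> list[SyntenyBlock]:
    """Chain anchor pairs into non-overlapping collinear blocks.

    Within each chromosome pair, chains are extracted greedily in score
    order (deterministic tie-break by chromosome ids then start index);
    blocks collinear on reversed B-coordinates are reported as
    ``inverted``.  No two returned blocks share an anchor.
    """
    by_chrom: dict[tuple[str, str], list[tuple[int, int, AnchorPair]]] = defaultdict(list)
    for pair in anchors:
        if pair.gene_a not in genome_a:
            raise SyntenyError(f"anchor gene {pair.gene_a!r} not in genome A")
        if pair.gene_b not in genome_b:
            raise SyntenyError(f"anchor gene {pair.gene_b!r} not in genome B")
        la = genome_a.loci[pair.gene_a]
        lb = genome_b.loci[pair.gene_b]
        by_chrom[(la.chrom, lb.chrom)].append((la.index, lb.index, pair))

    blocks: list[SyntenyBlock] = []
    for (ca, cb) in sorted(by_chrom):
        pts_all = sorted(by_chrom[(ca, cb)], key=lambda p: (p[0], p[1]))
        remaining = list(pts_all)
        while len(remaining) >= min_block:
            # forward orientation
            fwd = _best_chain(remaining, max_gap)
            # inverted orientation: negate b-coordinates
            flipped = sorted(((a, -b, p) for a, b, p in remaining),
                             key=lambda p: (p[0], p[1]))
            rev = _best_chain(flipped, max_gap)
            if len(fwd) >= len(rev):
                chain_pts = [remaining[i] for i in fwd]
                orientation = "same"
            else:
                chain_pts = [(a, -b, p) for a, b, p in (flipped[i] for i in rev)]
                orientation = "inverted"
            if len(chain_pts) < min_block:
                break
            blocks.append(SyntenyBlock(ca, cb, orientation,
                                       [(a, b, p) for a, b, p in chain_pts]))
            used = {id(p) for _, _, p in chain_pts}
            remaining = [pt for pt in remaining if id(pt[2]) not in used]
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.span_a[0], b.orientation))
    return blocks


def syntenic_depth(blocks: list[SyntenyBlock], target_genome: Genome,
                   side: str = "a") -> DepthProfile:
    """Per-gene count of blocks covering each target-genome gene.

    ``side`` names the side of the blocks that lies on the target genome
    ("a" or "b"); a block covers every rank within its span on that side.
    """
    if side not in ("a", "b"):
        raise SyntenyError("side must be 'a' or 'b'")
    cover: dict[str, np.ndarray] = {
        chrom: np.zeros(len(genes) + 1, dtype=np.int64)
        for chrom, genes in target_genome.chromosomes.items()
    }
    for block in blocks:
        chrom = block.chrom_a if side == "a" else block.chrom_b
        lo, hi = block.span_a if side == "a" else block.span_b
        if chrom not in cover:
            raise SyntenyError(f"block chromosome {chrom!r} not in target genome")
        cover[chrom][lo] += 1
        cover[chrom][hi + 1] -= 1
    depths: dict[str, int] = {}
    for chrom, genes in target_genome.chromosomes.items():
        depth = np.cumsum(cover[chrom][:-1])
        for i, g in enumerate(genes):
            depths[g] = int(depth[i])
    return DepthProfile(depths)


def depth_ratio(profile_a: DepthProfile, profile_b: DepthProfile) -> tuple[int, int]:
    """Reduced modal-depth ratio (coverage-of-A : coverage-of-B)."""
    da, db = profile_a.modal_depth, profile_b.modal_depth
    if da == 0 or db == 0:
        raise SyntenyError("modal depth is zero on one side; no ratio defined")
    g = math.gcd(da, db)
    return da // g, db // g
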