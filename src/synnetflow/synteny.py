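"""Collinear block detection from rank positions and homology hits.

An *anchor* is a homologous gene pair placed at integer rank
coordinates in two genomes (possibly the same genome).  A *block* is a
chain of anchors strictly monotone in both genomes — increasing in
genome A and either increasing (forward) or decreasing (inverted) in
genome B — with consecutive anchors at most ``max_gap`` ranks apart on
both sides.  Chains are scored by anchor count and extracted greedily:
find the best chain by dynamic programming, remove its anchors, repeat
while the best chain has at least ``min_anchors`` anchors.  Unit
scoring keeps the chainer exactly checkable against exhaustive search;
strand is ignored (orientation is fully determined by rank geometry).

Intra-genome anchoring excludes pairs closer than ``tandem_exclusion``
ranks (default 1: only immediately adjacent pairs) — those are tandem,
not collinear, signal — and never produces the trivial self-diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from synnetflow.genome_io import GenomeTable

__all__ = [
    "Anchor",
    "SyntenyBlock",
    "build_anchors",
    "chain_anchors",
    "detect_all",
    "write_collinearity",
]


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    chrom_a: str
    chrom_b: str


@dataclass
class SyntenyBlock:
    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    anchors: list  # of Anchor, rank_a strictly increasing
    orientation: str  # "forward" | "inverted"

    @property
    def score(self) -> int:
        return len(self.anchors)

    def __post_init__(self):
        ra = [a.rank_a for a in self.anchors]
        rb = [a.rank_b for a in self.anchors]
        if any(y <= x for x, y in zip(ra, ra[1:])):
            raise ValueError("block anchors not strictly increasing in genome A")
        step = 1 if self.orientation == "forward" else -1
        if any((y - x) * step <= 0 for x, y in zip(rb, rb[1:])):
            raise ValueError(f"block anchors not strictly {self.orientation} in genome B")


def build_anchors(
    genome_a: GenomeTable,
    genome_b: GenomeTable,
    hits: pd.DataFrame,
    tandem_exclusion: int = 1,
) -> list:
    """One anchor per undirected homologous pair between two genomes.

    ``hits`` may contain either or both directions; pairs are
    deduplicated.  For intra-genome anchoring (``genome_a is
    genome_b``), self pairs and same-chromosome pairs with rank
    distance ≤ ``tandem_exclusion`` are excluded.  A hit naming a gene
    absent from both genomes is an error.
    """
    intra = genome_a.species == genome_b.species
    seen = set()
    anchors = []
    unknown = []
    for q, s in zip(hits["query_id"], hits["subject_id"]):
        if q in genome_a and s in genome_b:
            ga, gb = q, s
        elif s in genome_a and q in genome_b:
            ga, gb = s, q
        else:
            unknown.append((q, s))
            continue
        if intra and ga == gb:
            continue
        key = (min(ga, gb), max(ga, gb)) if intra else (ga, gb)
        if key in seen:
            continue
        seen.add(key)
        ca, ra = genome_a.position(ga)
        cb, rb = genome_b.position(gb)
        if intra:
            if ca == cb and abs(ra - rb) <= tandem_exclusion:
                continue
            # canonical orientation: lower (chrom, rank) on the A side
            if (cb, rb) < (ca, ra):
                ga, gb, ca, ra, cb, rb = gb, ga, cb, rb, ca, ra
        anchors.append(Anchor(ga, gb, ra, rb, ca, cb))
    if unknown:
        raise ValueError(f"hits reference unknown genes, e.g. {unknown[:3]}")
    anchors.sort(key=lambda a: (a.chrom_a, a.chrom_b, a.rank_a, a.rank_b))
    return anchors


def _best_chain(ra, rb, order, max_gap):
    """Best sign-consistent chain over anchors (list indices in ``order``).

    Returns (score, [indices], orientation).  DP over anchors sorted by
    (rank_a, rank_b); predecessor window limited to the rank_a gap by
    bisect.  Ties broken by smaller start (rank_a, rank_b), then by
    forward before inverted orientation.
    """
    import bisect

    n = len(order)
    ras = [ra[i] for i in order]
    candidates = []
    for sign, name in ((1, "forward"), (-1, "inverted")):
        dp = [1] * n
        parent = [-1] * n
        for j in range(n):
            raj = ras[j]
            rbj = rb[order[j]]
            lo = bisect.bisect_left(ras, raj - max_gap)
            hi = bisect.bisect_left(ras, raj)  # strict increase in rank_a
            bj, pj = 1, -1
            for i in range(lo, hi):
                diff = (rbj - rb[order[i]]) * sign
                if 0 < diff <= max_gap and dp[i] + 1 > bj:
                    bj, pj = dp[i] + 1, i
            dp[j] = bj
            parent[j] = pj
        score = max(dp)
        j = dp.index(score)
        chain = []
        while j != -1:
            chain.append(order[j])
            j = parent[j]
        chain.reverse()
        start = (ra[chain[0]], rb[chain[0]])
        candidates.append((-score, start, name != "forward", chain, name))
    candidates.sort(key=lambda c: c[:3])
    top = candidates[0]
    return -top[0], top[3], top[4]


def chain_anchors(
    anchors: list,
    min_anchors: int = 5,
    max_gap: int = 25,
    species_a: str = "",
    species_b: str = "",
) -> list:
    """Greedy best-chain extraction on anchors of one chromosome pair."""
    if not anchors:
        return []
    chrom_a, chrom_b = anchors[0].chrom_a, anchors[0].chrom_b
    pool = sorted(range(len(anchors)), key=lambda i: (anchors[i].rank_a, anchors[i].rank_b))
    ra = [a.rank_a for a in anchors]
    rb = [a.rank_b for a in anchors]
    blocks = []
    while len(pool) >= min_anchors:
        score, chain, orientation = _best_chain(ra, rb, pool, max_gap)
        if score < min_anchors:
            break
        blocks.append(SyntenyBlock(
            species_a, species_b, chrom_a, chrom_b,
            [anchors[i] for i in chain], orientation,
        ))
        used = set(chain)
        pool = [i for i in pool if i not in used]
    return blocks


def detect_all(genomes: dict, hits: pd.DataFrame, params: dict | None = None) -> list:
    """Chain anchors over every species pair (unordered, including self).

    ``params`` may set ``min_anchors`` (default 5), ``max_gap`` (25)
    and ``tandem_exclusion`` (1).  Output order is deterministic:
    (species pair, chromosome pair, start rank).
    """
    params = params or {}
    min_anchors = params.get("min_anchors", 5)
    max_gap = params.get("max_gap", 25)
    tandem_exclusion = params.get("tandem_exclusion", 1)

    species_of = {}
    for sp, gt in genomes.items():
        for g in gt.df["gene_id"]:
            species_of[g] = sp
    qsp = hits["query_id"].map(species_of)
    ssp = hits["subject_id"].map(species_of)
    bad = qsp.isna() | ssp.isna()
    if bad.any():
        missing = pd.concat([
            hits.loc[qsp.isna(), "query_id"], hits.loc[ssp.isna(), "subject_id"]
        ]).unique()
        raise ValueError(f"hits reference genes absent from all genomes: {list(missing[:5])}")
    lo = qsp.where(qsp <= ssp, ssp)
    hi = ssp.where(qsp <= ssp, qsp)

    blocks = []
    species = sorted(genomes)
    for i, sa in enumerate(species):
        for sb in species[i:]:
            sub = hits[(lo == sa) & (hi == sb)]
            if sub.empty:
                continue
            anchors = build_anchors(genomes[sa], genomes[sb], sub, tandem_exclusion)
            by_cp: dict = {}
            for a in anchors:
                by_cp.setdefault((a.chrom_a, a.chrom_b), []).append(a)
            for cp in sorted(by_cp):
                if len(by_cp[cp]) < min_anchors:
                    continue
                blocks.extend(chain_anchors(
                    by_cp[cp], min_anchors, max_gap, species_a=sa, species_b=sb,
                ))
    blocks.sort(key=lambda b: (
        b.species_a, b.species_b, b.chrom_a, b.chrom_b,
        b.anchors[0].rank_a, b.anchors[0].rank_b,
    ))
    return blocks


def write_collinearity(blocks: list, path) -> None:
    """Write blocks in an MCScanX-style ``.collinearity`` text layout."""
    with open(path, "w") as fh:
        fh.write("############### collinear blocks ###############\n")
        for n, b in enumerate(blocks):
            fh.write(
                f"## Alignment {n}: score={b.score} e_value=NA N={len(b.anchors)} "
                f"{b.chrom_a}&{b.chrom_b} {b.orientation}\n"
            )
            for i, a in enumerate(b.anchors):
                fh.write(f"{n}-{i}:\t{a.gene_a}\t{a.gene_b}\n")
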