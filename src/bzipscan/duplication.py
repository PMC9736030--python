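"""Tandem / segmental / dispersed classification of homolog pairs.

Segmental support comes from collinear blocks: chains of homolog
anchors whose gene-order ranks are strictly monotone on both
chromosomes with bounded per-step gaps, found by dynamic programming
and extracted greedily (longest chain first, each anchor in at most one
block).  Defaults (min_anchors=5, max_gap=25, tandem adjacency gap 1)
mirror the common collinearity-scanner convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_MIN_ANCHORS = 5
DEFAULT_MAX_GAP = 25
DEFAULT_TANDEM_MAX_GAP = 1

# gene_ranks: gene id -> (chromosome, rank)
GeneRanks = dict[str, tuple[str, int]]


@dataclass
class Anchor:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int

    @property
    def pair_key(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class CollinearBlock:
    id: str
    chrom_a: str
    chrom_b: str
    anchors: list[Anchor] = field(default_factory=list)
    orientation: str = "same"

    def __len__(self) -> int:
        return len(self.anchors)

    def validate(self, min_anchors: int, max_gap: int) -> None:
        """Assert this block's own invariants; raises AssertionError."""
        assert len(self.anchors) >= min_anchors
        ra = [a.rank_a for a in self.anchors]
        rb = [a.rank_b for a in self.anchors]
        assert all(y > x for x, y in zip(ra, ra[1:])), "rank_a not increasing"
        if self.orientation == "same":
            assert all(y > x for x, y in zip(rb, rb[1:])), "rank_b not increasing"
        else:
            assert all(y < x for x, y in zip(rb, rb[1:])), "rank_b not decreasing"
        assert all(y - x <= max_gap for x, y in zip(ra, ra[1:]))
        assert all(abs(y - x) <= max_gap for x, y in zip(rb, rb[1:]))


@dataclass(frozen=True)
class DuplicationEvent:
    pair: tuple[str, str]
    label: str  # tandem | segmental | dispersed
    block_id: str | None = None


def _oriented_anchor(pair: tuple[str, str], gene_ranks: GeneRanks) -> tuple[tuple[str, str], Anchor]:
    for gene in pair:
        if gene not in gene_ranks:
            raise KeyError(f"gene {gene!r} has no (chromosome, rank) assignment")
    a, b = pair
    (ca, ra), (cb, rb) = gene_ranks[a], gene_ranks[b]
    # canonical orientation: lexicographically smaller chromosome first,
    # smaller rank first on the same chromosome
    if (cb, rb, b) < (ca, ra, a):
        a, b, ca, ra, cb, rb = b, a, cb, rb, ca, ra
    return (ca, cb), Anchor(a, b, ra, rb)


def _best_chain(anchors: list[Anchor], max_gap: int) -> tuple[list[int], str]:
    """Longest valid chain over anchors (as indices into the given list).

    Among maximum-length chains the deterministic winner is: orientation
    'same' preferred over 'inverted', then the lexicographically
    smallest (rank_a, rank_b) anchor sequence.  Anchors must be sorted
    by (rank_a, rank_b).
    """
    best: tuple[list[int], str] = ([], "same")
    for orientation in ("same", "inverted"):
        chain = _best_chain_oriented(anchors, max_gap, orientation)
        if len(chain) > len(best[0]):
            best = (chain, orientation)
    return best


def _step_ok(x: Anchor, y: Anchor, max_gap: int, orientation: str) -> bool:
    if not 0 < y.rank_a - x.rank_a <= max_gap:
        return False
    db = y.rank_b - x.rank_b
    if orientation == "same":
        return 0 < db <= max_gap
    return -max_gap <= db < 0


def _best_chain_oriented(
    anchors: list[Anchor], max_gap: int, orientation: str
) -> list[int]:
    n = len(anchors)
    if n == 0:
        return []
    # f[i] = length of the longest valid chain starting at anchor i
    f = [1] * n
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if _step_ok(anchors[i], anchors[j], max_gap, orientation) and f[j] + 1 > f[i]:
                f[i] = f[j] + 1
    target = max(f)
    # greedy reconstruction gives the lexicographically smallest maximum chain
    chain: list[int] = []
    need = target
    prev: int | None = None
    for _ in range(target):
        for i in range(0 if prev is None else prev + 1, n):
            if f[i] != need:
                continue
            if prev is not None and not _step_ok(
                anchors[prev], anchors[i], max_gap, orientation
            ):
                continue
            chain.append(i)
            prev = i
            need -= 1
            break
    return chain


def chain_collinear_anchors(
    pairs: list[tuple[str, str]],
    gene_ranks: GeneRanks,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[CollinearBlock]:
    """Chain homolog anchors into collinear blocks per chromosome pair.

    Blocks are extracted iteratively: the longest remaining chain is
    emitted and its anchors removed, until no chain reaches
    ``min_anchors``.  Output is sorted longest first; each anchor
    belongs to at most one block.  Unknown genes raise KeyError.
    """
    by_chrom_pair: dict[tuple[str, str], list[Anchor]] = {}
    seen: set[tuple[tuple[str, str], frozenset[str]]] = set()
    for pair in pairs:
        chrom_pair, anchor = _oriented_anchor(pair, gene_ranks)
        key = (chrom_pair, anchor.pair_key)
        if key in seen:
            continue
        seen.add(key)
        by_chrom_pair.setdefault(chrom_pair, []).append(anchor)

    raw_blocks: list[CollinearBlock] = []
    for chrom_pair in sorted(by_chrom_pair):
        remaining = sorted(
            by_chrom_pair[chrom_pair], key=lambda a: (a.rank_a, a.rank_b, a.gene_a)
        )
        while True:
            chain_idx, orientation = _best_chain(remaining, max_gap)
            if len(chain_idx) < min_anchors:
                break
            chosen = [remaining[i] for i in chain_idx]
            raw_blocks.append(
                CollinearBlock(
                    id="",
                    chrom_a=chrom_pair[0],
                    chrom_b=chrom_pair[1],
                    anchors=chosen,
                    orientation=orientation,
                )
            )
            chain_set = set(chain_idx)
            remaining = [a for i, a in enumerate(remaining) if i not in chain_set]

    raw_blocks.sort(key=lambda b: (-len(b), b.chrom_a, b.chrom_b, b.anchors[0].rank_a))
    blocks = []
    for i, block in enumerate(raw_blocks, 1):
        block.id = f"block{i}"
        block.validate(min_anchors, max_gap)
        blocks.append(block)
    return blocks


def classify_duplication(
    pairs: list[tuple[str, str]],
    blocks: list[CollinearBlock],
    gene_ranks: GeneRanks,
    tandem_max_gap: int = DEFAULT_TANDEM_MAX_GAP,
) -> list[DuplicationEvent]:
    """Label each homolog pair tandem, segmental or dispersed.

    Tandem (same chromosome, rank gap <= ``tandem_max_gap``) takes
    precedence over block membership.
    """
    block_of: dict[frozenset[str], str] = {}
    for block in blocks:
        for anchor in block.anchors:
            block_of.setdefault(anchor.pair_key, block.id)
    events = []
    for pair in pairs:
        a, b = pair
        (ca, ra), (cb, rb) = gene_ranks[a], gene_ranks[b]
        key = frozenset(pair)
        if ca == cb and abs(ra - rb) <= tandem_max_gap:
            events.append(DuplicationEvent(tuple(pair), "tandem"))
        elif key in block_of:
            events.append(DuplicationEvent(tuple(pair), "segmental", block_of[key]))
        else:
            events.append(DuplicationEvent(tuple(pair), "dispersed"))
    return events


def inter_genome_collinearity(
    genome_ranks: dict[str, GeneRanks],
    pairs: list[tuple[str, str]],
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[list[CollinearBlock], pd.DataFrame, dict[str, set[str]]]:
    """Collinearity between genomes sharing a homolog-pair universe.

    ``genome_ranks`` maps genome name -> gene_ranks; chromosomes are
    namespaced by genome so the intra-genome chaining machinery applies
    unchanged.  Returns the blocks, a per-genome-pair collinear-anchor
    count table (symmetric in genome order), and, per genome, the genes
    collinear with at least two distinct partner genomes.
    """
    genome_of: dict[str, str] = {}
    merged: GeneRanks = {}
    for genome, ranks in genome_ranks.items():
        for gene, (chrom, rank) in ranks.items():
            if gene in merged:
                raise ValueError(f"gene {gene!r} present in more than one genome")
            genome_of[gene] = genome
            merged[gene] = (f"{genome}:{chrom}", rank)

    blocks = chain_collinear_anchors(pairs, merged, min_anchors, max_gap)

    pair_counts: dict[tuple[str, str], int] = {}
    partners: dict[str, set[str]] = {}
    for block in blocks:
        for anchor in block.anchors:
            ga, gb = genome_of[anchor.gene_a], genome_of[anchor.gene_b]
            gp = tuple(sorted((ga, gb)))
            pair_counts[gp] = pair_counts.get(gp, 0) + 1
            partners.setdefault(anchor.gene_a, set()).add(gb)
            partners.setdefault(anchor.gene_b, set()).add(ga)

    counts = pd.DataFrame(
        [
            {"genome_a": gp[0], "genome_b": gp[1], "collinear_pairs": n}
            for gp, n in sorted(pair_counts.items())
        ],
        columns=["genome_a", "genome_b", "collinear_pairs"],
    )
    multi: dict[str, set[str]] = {g: set() for g in genome_ranks}
    for gene, partner_genomes in partners.items():
        if len(partner_genomes - {genome_of[gene]}) >= 2:
            multi[genome_of[gene]].add(gene)
    return blocks, counts, multi


def ranks_from_models(models) -> GeneRanks:
    """Build the gene -> (chromosome, rank) map from gene models."""
    return {m.gene_id: (m.chromosome, m.rank) for m in models}


def event_table(events: list[DuplicationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": e.pair[0],
                "gene_b": e.pair[1],
                "label": e.label,
                "block_id": e.block_id or "",
            }
            for e in events
        ],
        columns=["gene_a", "gene_b", "label", "block_id"],
    )


def block_table(blocks: list[CollinearBlock]) -> pd.DataFrame:
    rows = []
    for block in blocks:
        for anchor in block.anchors:
            rows.append(
                {
                    "block_id": block.id,
                    "chrom_a": block.chrom_a,
                    "chrom_b": block.chrom_b,
                    "orientation": block.orientation,
                    "gene_a": anchor.gene_a,
                    "gene_b": anchor.gene_b,
                    "rank_a": anchor.rank_a,
                    "rank_b": anchor.rank_b,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "block_id", "chrom_a", "chrom_b", "orientation",
            "gene_a", "gene_b", "rank_a", "rank_b",
        ],
    )
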