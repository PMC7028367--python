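"""Conserved micro-synteny detection.

A focal gene *b* with neighbours ``a`` (-1) and ``c`` (+1) sits in conserved
micro-synteny with a target genome when homologues *a'* and *c'* of its
neighbours lie on one target chromosome separated by one or two
protein-coding genes.  The intervening gene(s) "opposite" the focal gene are
its predicted homologues.  Candidates whose anchors share an orthology group
(apparent paralogues) are discarded.

Three stringency levels:

* ``relaxed``   — the anchor-pair rule only.
* ``standard``  — additionally, the homologue of the -2 neighbour, when one
  exists, must be adjacent or separated by one gene from the -1 homologue
  (and symmetrically +2/+1).  Absent outer homologues never disqualify.
* ``stringent`` — extends the same conditional rule to the -3/+3 neighbours.

The rank-distance checks are direction-agnostic, so micro-inversions are
tolerated; anchor orientation is recorded on the block.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .genome_model import Gene, GeneOrder, OrthologyMap, eligible_focal_genes, homologues_of

__all__ = [
    "STRINGENCIES",
    "SyntenyBlock",
    "find_micro_synteny",
    "enumerate_blocks",
    "stringency_nesting_check",
    "write_blocks_tsv",
    "read_blocks_tsv",
]

STRINGENCIES = ("relaxed", "standard", "stringent")

#: how many outer neighbour layers each stringency checks beyond the anchors
_OUTER_LAYERS = {"relaxed": 0, "standard": 1, "stringent": 2}

#: "adjacent or separated by one gene" = rank distance 1 or 2
_MAX_OUTER_GAP = 2


@dataclass(frozen=True)
class SyntenyBlock:
    """One conserved micro-synteny configuration for a focal gene."""

    focal_gene: Gene
    target_chrom: str
    left_anchor: Gene
    right_anchor: Gene
    opposite: tuple[Gene, ...]
    stringency: str
    anchor_orientation: str  # same | inverted

    def __post_init__(self) -> None:
        if not 1 <= len(self.opposite) <= 2:
            raise ValueError("opposite gene count must be 1 or 2")
        if self.stringency not in STRINGENCIES:
            raise ValueError(f"unknown stringency {self.stringency!r}")

    @property
    def opposite_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.opposite)


def _outer_chain_ok(
    focal: Gene,
    side: int,
    layers: int,
    anchor: Gene,
    focal_order: GeneOrder,
    target_order: GeneOrder,
    orth: OrthologyMap,
    target_species: str,
) -> bool:
    """Check the conditional outer-neighbour rule on one side.

    Walks outward from the focal gene (side -1 or +1) ``layers`` neighbour
    layers past the immediate one.  Each outer neighbour that has homologues
    on the anchor's chromosome must place one of them within rank distance
    <= 2 of the current chain anchor; that homologue then becomes the anchor
    for the next layer.  Neighbours without homologues (or past the
    chromosome end) are tolerated and leave the anchor unchanged.
    """
    focal_species = focal_order.species
    current = anchor
    for depth in range(2, 2 + layers):
        nb = focal_order.neighbour(focal, side * depth)
        if nb is None:
            break
        homs = [
            h
            for h in homologues_of(nb, focal_species, target_species, orth, target_order)
            if h.chrom == current.chrom
        ]
        if not homs:
            continue
        near = [h for h in homs if 1 <= abs(h.rank - current.rank) <= _MAX_OUTER_GAP]
        if not near:
            return False
        current = min(near, key=lambda h: (abs(h.rank - current.rank), h.rank))
    return True


def find_micro_synteny(
    focal: Gene,
    focal_order: GeneOrder,
    target_order: GeneOrder,
    orth: OrthologyMap,
    stringency: str = "standard",
) -> list[SyntenyBlock]:
    """All conserved micro-synteny blocks for one focal gene.

    Every pairwise combination of -1 and +1 neighbour homologues is
    evaluated; each surviving combination yields a distinct block.  A focal
    gene lacking a -1 or +1 neighbour simply has no blocks.
    """
    if stringency not in STRINGENCIES:
        raise ValueError(f"unknown stringency {stringency!r}")
    left_nb = focal_order.neighbour(focal, -1)
    right_nb = focal_order.neighbour(focal, +1)
    if left_nb is None or right_nb is None:
        return []
    focal_species = focal_order.species
    target_species = target_order.species
    left_homs = homologues_of(left_nb, focal_species, target_species, orth, target_order)
    right_homs = homologues_of(right_nb, focal_species, target_species, orth, target_order)
    layers = _OUTER_LAYERS[stringency]
    blocks: list[SyntenyBlock] = []
    for a in sorted(left_homs, key=lambda g: (g.chrom, g.rank)):
        for c in sorted(right_homs, key=lambda g: (g.chrom, g.rank)):
            if a.chrom != c.chrom or a.gene_id == c.gene_id:
                continue
            between = abs(a.rank - c.rank) - 1
            if between not in (1, 2):
                continue
            # paralogue filter: anchors in one orthology group
            if orth.same_group((target_species, a.gene_id), (target_species, c.gene_id)):
                continue
            if layers:
                if not _outer_chain_ok(
                    focal, -1, layers, a, focal_order, target_order, orth, target_species
                ):
                    continue
                if not _outer_chain_ok(
                    focal, +1, layers, c, focal_order, target_order, orth, target_species
                ):
                    continue
            lo, hi = sorted((a.rank, c.rank))
            opposite = tuple(target_order.chromosomes[a.chrom][lo + 1 : hi])
            blocks.append(
                SyntenyBlock(
                    focal_gene=focal,
                    target_chrom=a.chrom,
                    left_anchor=a,
                    right_anchor=c,
                    opposite=opposite,
                    stringency=stringency,
                    anchor_orientation="same" if a.rank < c.rank else "inverted",
                )
            )
    return blocks


def enumerate_blocks(
    focal_order: GeneOrder,
    target_order: GeneOrder,
    orth: OrthologyMap,
    stringency: str = "standard",
    overlap_threshold: float = 0.8,
) -> tuple[dict[str, list[SyntenyBlock]], int]:
    """Blocks for every eligible focal gene, chromosome by chromosome.

    Returns (focal gene_id -> blocks, count of focal genes with >= 1 block).
    Focal genes overlapping a neighbour by more than ``overlap_threshold``
    are excluded up front.
    """
    out: dict[str, list[SyntenyBlock]] = {}
    for gene in eligible_focal_genes(focal_order, overlap_threshold):
        out[gene.gene_id] = find_micro_synteny(
            gene, focal_order, target_order, orth, stringency
        )
    n_with = sum(1 for v in out.values() if v)
    return out, n_with


def stringency_nesting_check(
    blocks_relaxed: dict[str, list[SyntenyBlock]],
    blocks_standard: dict[str, list[SyntenyBlock]],
    blocks_stringent: dict[str, list[SyntenyBlock]],
) -> bool:
    """True iff focal-gene sets nest: stringent ⊆ standard ⊆ relaxed."""

    def with_blocks(d: dict[str, list[SyntenyBlock]]) -> set[str]:
        return {g for g, v in d.items() if v}

    rel, std, strg = map(with_blocks, (blocks_relaxed, blocks_standard, blocks_stringent))
    return strg <= std <= rel


_TSV_HEADER = (
    "focal_gene\ttarget_chrom\tleft_anchor\tright_anchor\topposite_genes"
    "\tstringency\torientation\n"
)


def write_blocks_tsv(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for b in sorted(
            blocks,
            key=lambda b: (b.focal_gene.gene_id, b.target_chrom, b.left_anchor.rank),
        ):
            fh.write(
                f"{b.focal_gene.gene_id}\t{b.target_chrom}\t{b.left_anchor.gene_id}\t"
                f"{b.right_anchor.gene_id}\t{','.join(b.opposite_ids)}\t"
                f"{b.stringency}\t{b.anchor_orientation}\n"
            )


def read_blocks_tsv(path: str | Path) -> list[dict[str, str]]:
    """Read a blocks TSV back as plain records (ids, not resolved genes)."""
    rows: list[dict[str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows
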