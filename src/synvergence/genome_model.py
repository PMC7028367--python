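"""Genome annotations, sequences, orthology groups and species trees.

This module provides the substrate everything else scans: per-chromosome
ordered gene lists (:class:`GeneOrder`), the orthology lookup used to find
candidate homologues (:class:`OrthologyMap`), and the species tree with
divergence times used for phylostratigraphy (:class:`SpeciesTree`).

Coordinates are 0-based half-open internally; GFF3 I/O converts to and from
the on-disk 1-based inclusive convention.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "GeneOrder",
    "OrthologyMap",
    "SpeciesTree",
    "GenomeBundle",
    "GffParseError",
    "read_gff",
    "write_gff",
    "read_fasta",
    "write_fasta",
    "read_orthology",
    "write_orthology",
    "read_species_tree",
    "load_bundle",
    "overlap_fraction",
    "eligible_focal_genes",
    "homologues_of",
    "reverse_proteome",
]


class GffParseError(ValueError):
    """Raised for a malformed GFF3 line; message names the line number."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene with 0-based half-open genomic coordinates.

    ``rank`` is the gene's position within its chromosome's start-sorted
    order and is what the synteny scanner means by "the +1 / -1 neighbour".
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int
    protein_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must be < end ({self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneOrder:
    """Ordered, indexed gene lists for one species' genome."""

    species: str
    chromosomes: dict[str, list[Gene]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id: dict[str, Gene] = {}
        for chrom, genes in self.chromosomes.items():
            genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
            for rank, g in enumerate(genes):
                if g.rank != rank or g.chrom != chrom:
                    g = Gene(g.gene_id, chrom, g.start, g.end, g.strand, rank, g.protein_ids)
                    genes[rank] = g
                if g.gene_id in self._by_id:
                    raise ValueError(f"duplicate gene id {g.gene_id}")
                self._by_id[g.gene_id] = g

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __len__(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    def get(self, gene_id: str) -> Gene | None:
        return self._by_id.get(gene_id)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def genes(self) -> Iterator[Gene]:
        for chrom in sorted(self.chromosomes):
            yield from self.chromosomes[chrom]

    def neighbour(self, gene: Gene, offset: int) -> Gene | None:
        """The gene ``offset`` positions away in rank order, or None at ends."""
        genes = self.chromosomes[gene.chrom]
        i = gene.rank + offset
        if 0 <= i < len(genes):
            return genes[i]
        return None


class OrthologyMap:
    """Orthology groups: group_id -> {(species, gene_id)} plus the inverse index.

    A gene belongs to at most one group (the highest-level grouping).
    """

    def __init__(self, groups: dict[str, set[tuple[str, str]]]):
        self.groups: dict[str, set[tuple[str, str]]] = {
            gid: set(members) for gid, members in groups.items()
        }
        self.index: dict[tuple[str, str], str] = {}
        for gid, members in self.groups.items():
            for member in members:
                if member in self.index:
                    raise ValueError(
                        f"gene {member} appears in groups {self.index[member]} and {gid}"
                    )
                self.index[member] = gid

    def group_of(self, species: str, gene_id: str) -> str | None:
        return self.index.get((species, gene_id))

    def same_group(self, a: tuple[str, str], b: tuple[str, str]) -> bool:
        ga = self.index.get(a)
        return ga is not None and ga == self.index.get(b)

    def members(self, group_id: str) -> set[tuple[str, str]]:
        return self.groups[group_id]


@dataclass
class SpeciesTree:
    """Species tree over the focal species and its targets.

    ``divergence_times`` maps each target species to its time since
    divergence from the focal species (million years; a config input).
    """

    tree: dendropy.Tree
    focal: str
    divergence_times: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # species trees are rooted; unrooted handling would collapse the
        # basal bifurcation during bipartition encoding (e.g. in mrca)
        self.tree.is_rooted = True
        labels = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        if self.focal not in labels:
            raise ValueError(f"focal species {self.focal!r} not a leaf of the tree")
        for sp, t in self.divergence_times.items():
            if t < 0:
                raise ValueError(f"negative divergence time for {sp}")
        self._leaves = labels

    @property
    def leaf_labels(self) -> set[str]:
        return set(self._leaves)

    def require_species(self, species: Iterable[str]) -> None:
        missing = sorted(set(species) - self._leaves)
        if missing:
            raise ValueError(f"species missing from tree: {', '.join(missing)}")

    def is_clade(self, species: set[str]) -> bool:
        """True iff ``species`` is exactly the leaf set of some clade."""
        if not species:
            return False
        self.require_species(species)
        mrca = self.tree.mrca(taxon_labels=sorted(species))
        leaves = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        return leaves == set(species)

    def focal_lineage_strata(self, targets: Iterable[str] | None = None) -> list[set[str]]:
        """Nested target-species sets along the focal lineage, youngest first.

        Each ancestor of the focal leaf defines a phylostratum: the target
        species inside its subtree. Consecutive identical sets (unbranched
        or irrelevant nodes) are collapsed.
        """
        wanted = set(targets) if targets is not None else self._leaves - {self.focal}
        leaf = self.tree.find_node_with_taxon_label(self.focal)
        strata: list[set[str]] = []
        node = leaf.parent_node
        while node is not None:
            inside = {
                l.taxon.label for l in node.leaf_iter() if l.taxon.label in wanted
            }
            if not strata or inside != strata[-1]:
                strata.append(inside)
            node = node.parent_node
        return strata


@dataclass
class GenomeBundle:
    """Everything the pipeline needs for one species.

    proteins: gene_id -> {protein_id: amino-acid sequence} (all isoforms);
    cds: protein_id -> coding sequence; chromosomes: chrom -> DNA sequence.
    """

    species: str
    order: GeneOrder
    proteins: dict[str, dict[str, str]]
    cds: dict[str, str] = field(default_factory=dict)
    chromosomes: dict[str, str] = field(default_factory=dict)

    def proteome(self) -> dict[str, dict[str, str]]:
        return self.proteins

    def proteome_residues(self) -> int:
        return sum(len(s) for iso in self.proteins.values() for s in iso.values())


# ---------------------------------------------------------------------------
# I/O


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_gff(path: str | Path, species: str | None = None) -> GeneOrder:
    """Read a GFF3 file into a :class:`GeneOrder`.

    One Gene per protein-coding gene (a gene feature with at least one mRNA
    carrying CDS features); genes with no CDS are skipped with a warning.
    1-based inclusive coordinates are converted to 0-based half-open.
    """
    import gffutils

    path = Path(path)
    lines: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                lines.append(line)
                continue
            ncols = len(line.rstrip("\n").split("\t"))
            if ncols != 9:
                raise GffParseError(
                    f"{path.name} line {lineno}: expected 9 tab-separated columns, got {ncols}"
                )
            lines.append(line)
    db = gffutils.create_db(
        "".join(lines),
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    chromosomes: dict[str, list[Gene]] = {}
    for gf in db.features_of_type("gene"):
        protein_ids = []
        for mrna in db.children(gf, featuretype="mRNA"):
            if any(True for _ in db.children(mrna, featuretype="CDS")):
                protein_ids.append(mrna.id)
        if not protein_ids:
            logger.warning("gene %s has no CDS-bearing mRNA; skipped", gf.id)
            continue
        gene = Gene(
            gene_id=gf.id,
            chrom=gf.seqid,
            start=gf.start - 1,
            end=gf.end,
            strand=gf.strand if gf.strand in {"+", "-"} else "+",
            rank=0,
            protein_ids=tuple(protein_ids),
        )
        chromosomes.setdefault(gf.seqid, []).append(gene)
    return GeneOrder(species=species or path.stem, chromosomes=chromosomes)


def write_gff(order: GeneOrder, path: str | Path) -> None:
    """Write a GeneOrder as GFF3 (gene/mRNA/CDS; 1-based inclusive on disk)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for gene in order.genes():
            start1, end1 = gene.start + 1, gene.end
            base = f"{gene.chrom}\tsynvergence\t"
            fh.write(
                f"{base}gene\t{start1}\t{end1}\t.\t{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for pid in gene.protein_ids:
                fh.write(
                    f"{base}mRNA\t{start1}\t{end1}\t.\t{gene.strand}\t.\t"
                    f"ID={pid};Parent={gene.gene_id}\n"
                )
                fh.write(
                    f"{base}CDS\t{start1}\t{end1}\t.\t{gene.strand}\t0\t"
                    f"ID=cds-{pid};Parent={pid}\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_orthology(path: str | Path) -> OrthologyMap:
    """Read a 3-column orthology flat file: group_id, species, gene_id.

    Tab-separated, ``#`` comments — a minimal stand-in for orthology
    database flat files.
    """
    groups: dict[str, set[tuple[str, str]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"orthology file line {lineno}: expected 3 columns, got {len(parts)}"
                )
            gid, species, gene_id = parts
            groups.setdefault(gid, set()).add((species, gene_id))
    return OrthologyMap(groups)


def write_orthology(orth: OrthologyMap, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("# group_id\tspecies\tgene_id\n")
        for gid in sorted(orth.groups):
            for species, gene_id in sorted(orth.groups[gid]):
                fh.write(f"{gid}\t{species}\t{gene_id}\n")


def read_species_tree(
    path: str | Path, focal: str, divergence_times: dict[str, float] | None = None
) -> SpeciesTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    times = dict(divergence_times or {})
    if not times:
        # fall back to patristic distance from the focal leaf if branch
        # lengths are present
        pdm = tree.phylogenetic_distance_matrix()
        focal_taxon = tree.taxon_namespace.get_taxon(focal)
        if focal_taxon is not None:
            for taxon in tree.taxon_namespace:
                if taxon is not focal_taxon:
                    times[taxon.label] = pdm.patristic_distance(focal_taxon, taxon) / 2
    return SpeciesTree(tree=tree, focal=focal, divergence_times=times)


def load_bundle(
    species: str,
    gff: str | Path,
    protein_fasta: str | Path,
    cds_fasta: str | Path | None = None,
    genome_fasta: str | Path | None = None,
) -> GenomeBundle:
    """Assemble a :class:`GenomeBundle` from on-disk files."""
    order = read_gff(gff, species=species)
    flat = read_fasta(protein_fasta)
    proteins: dict[str, dict[str, str]] = {}
    for gene in order.genes():
        iso = {pid: flat[pid] for pid in gene.protein_ids if pid in flat}
        missing = [pid for pid in gene.protein_ids if pid not in flat]
        if missing:
            logger.warning(
                "gene %s: %d protein id(s) missing from FASTA", gene.gene_id, len(missing)
            )
        if iso:
            proteins[gene.gene_id] = iso
    cds = read_fasta(cds_fasta) if cds_fasta else {}
    chroms = read_fasta(genome_fasta) if genome_fasta else {}
    return GenomeBundle(
        species=species, order=order, proteins=proteins, cds=cds, chromosomes=chroms
    )


# ---------------------------------------------------------------------------
# primitives


def overlap_fraction(a: Gene, b: Gene, denominator: str = "focal") -> float:
    """Fraction of gene ``a`` covered by gene ``b``.

    ``denominator="focal"`` divides the intersection length by len(a);
    ``"symmetric"`` takes max(inter/len(a), inter/len(b)).
    """
    if a.chrom != b.chrom:
        raise ValueError(
            f"genes on different chromosomes: {a.chrom} vs {b.chrom}"
        )
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    if denominator == "focal":
        return inter / a.length
    if denominator == "symmetric":
        return max(inter / a.length, inter / b.length)
    raise ValueError(f"unknown denominator mode {denominator!r}")


def eligible_focal_genes(
    order: GeneOrder, threshold: float = 0.8, denominator: str = "focal"
) -> list[Gene]:
    """Genes overlapping neither immediate neighbour by more than ``threshold``.

    Chromosome-terminal genes are evaluated against their existing
    neighbours only.
    """
    keep: list[Gene] = []
    for gene in order.genes():
        ok = True
        for off in (-1, +1):
            nb = order.neighbour(gene, off)
            if nb is not None and overlap_fraction(gene, nb, denominator) > threshold:
                ok = False
                break
        if ok:
            keep.append(gene)
    return keep


def homologues_of(
    gene: Gene,
    focal_species: str,
    target_species: str,
    orth: OrthologyMap,
    target_order: GeneOrder,
) -> set[Gene]:
    """All target-species members of the gene's orthology group.

    Target gene ids present in the group but absent from the target
    annotation are dropped with a warning.
    """
    gid = orth.group_of(focal_species, gene.gene_id)
    if gid is None:
        return set()
    out: set[Gene] = set()
    for species, gene_id in orth.members(gid):
        if species != target_species:
            continue
        hit = target_order.get(gene_id)
        if hit is None:
            logger.warning(
                "orthology group %s member %s absent from %s annotation; dropped",
                gid, gene_id, target_species,
            )
            continue
        out.add(hit)
    return out


def reverse_proteome(proteins: dict[str, str]) -> dict[str, str]:
    """Character-reverse every protein sequence (ids preserved).

    Reversal destroys biological signal while preserving length and
    composition, which is what makes reversed proteomes usable as decoys:
    biological sequences do not evolve by reversal.
    """
    out: dict[str, str] = {}
    for name, seq in proteins.items():
        if not seq:
            raise ValueError(f"empty sequence for {name}")
        out[name] = seq[::-1]
    return out
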