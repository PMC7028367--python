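"""Simulated focal/target genome pairs with planted ground truth.

A single ancestral genome descends into a focal and a target genome.  On the
way, per-gene substitutions erode sequence similarity gradually; a planted
fraction of genes is scrambled beyond recognition (composition-preserving
residue shuffle verified to share no significant local alignment with its
counterpart); genes are lost, tandem-duplicated, or born de novo; and
segmental inversions shuffle local gene order.  The emitted orthology map
contains only detectably related pairs — scrambled pairs are excluded by
construction, mimicking the fact that orthology databases cannot group
homologues that no longer share similarity — while the ground-truth table
records everything, so every estimator downstream is testable by parameter
recovery.

All randomness flows through one integer-seeded generator; outputs are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_model import (
    Gene,
    GeneOrder,
    GenomeBundle,
    OrthologyMap,
    SpeciesTree,
    write_fasta,
    write_gff,
    write_orthology,
)
from .simsearch import ScoringParams, evalue_of, sw_score

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedPair",
    "simulate_pair",
    "scramble_beyond_recognition",
    "ladder_tree_series",
    "write_pair",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"

_CODONS: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            from Bio.Seq import Seq as _Seq

            _aa = str(_Seq(_codon).translate())
            if _aa in _AA:
                _CODONS.setdefault(_aa, []).append(_codon)


@dataclass
class SimConfig:
    """Parameters of one simulated focal/target pair.

    ``divergence_mean``/``divergence_sd`` set the per-gene substitution
    fraction distribution (truncated normal on [0, max_divergence]), split
    evenly between the two descendant lineages.  ``f_scrambled`` is the
    planted fraction of genes diverged beyond recognition.  The seed is
    mandatory: the simulator defines study conditions and must be exactly
    reproducible.
    """

    seed: int
    n_genes: int = 1000
    n_chromosomes: int = 4
    mean_gene_length: int = 200  # codons
    divergence_mean: float = 0.25
    divergence_sd: float = 0.10
    max_divergence: float = 0.60
    f_scrambled: float = 0.05
    p_loss: float = 0.05
    p_tandem_dup: float = 0.02
    p_denovo: float = 0.05
    #: de novo gene birth rate in the target lineage; None mirrors p_denovo.
    #: Target-side insertions can create non-homologous "opposite" genes
    #: (apparent micro-synteny around a lost or de novo focal gene), the
    #: false-positive class that makes the estimator an upper bound.
    p_denovo_target: float | None = None
    n_inversions: int = 5
    inversion_mean_len: int = 6
    intergenic_spacer: int = 200
    include_scrambled_in_orthology: bool = False

    def __post_init__(self) -> None:
        for name in ("f_scrambled", "p_loss", "p_tandem_dup", "p_denovo"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.f_scrambled + self.p_denovo + self.p_loss >= 1:
            raise ValueError("f_scrambled + p_denovo + p_loss must leave genes over")
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one gene and one chromosome")
        if self.n_genes < self.n_chromosomes:
            raise ValueError("fewer genes than chromosomes")


@dataclass
class GroundTruth:
    """What the simulator actually planted.

    ``origin`` partitions the focal gene set into conserved,
    diverged_detectable, diverged_beyond_recognition, de_novo and
    lost_in_target.  ``planted_d`` is the beyond-recognition fraction among
    focal genes with surviving syntenic context — surviving genes whose
    immediate focal neighbours both have detectable target homologues, the
    population the micro-synteny estimator samples (the bookkeeping ignores
    rearrangements, so it is exact when duplications/inversions/target-side
    insertions are off and approximate otherwise).
    ``planted_orphan_fraction`` is the fraction of focal genes with no
    target homologue detectable by any means (scrambled + de novo + lost),
    i.e. the planted X/n.
    """

    origin: dict[str, str]
    true_target_homologue: dict[str, str | None]
    planted_d: float
    planted_orphan_fraction: float
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def planted_contribution(self) -> float:
        if self.planted_orphan_fraction == 0:
            return 0.0
        return min(1.0, self.planted_d / self.planted_orphan_fraction)


@dataclass
class SimulatedPair:
    config: SimConfig
    focal: GenomeBundle
    target: GenomeBundle
    orthology: OrthologyMap
    truth: GroundTruth


# ---------------------------------------------------------------------------


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.integers(0, 20, size=length - 1)
    return "M" + "".join(_AA[i] for i in body)


def _mutate(rng: np.random.Generator, seq: str, fraction: float) -> str:
    """Substitute ~fraction of residues with uniformly chosen different ones."""
    if fraction <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < fraction
    hit[0] = False  # keep the initiator residue
    n = int(hit.sum())
    if n == 0:
        return seq
    repl = rng.integers(0, 20, size=n)
    aa_bytes = np.frombuffer(_AA.encode(), dtype=np.uint8)
    new = aa_bytes[repl]
    same = new == arr[hit]
    while same.any():
        new[same] = aa_bytes[rng.integers(0, 20, size=int(same.sum()))]
        same = new == arr[hit]
    arr[hit] = new
    return arr.tobytes().decode()


def scramble_beyond_recognition(
    seq: str,
    rng: np.random.Generator,
    reference: str | None = None,
    params: ScoringParams = ScoringParams(),
    evalue_floor: float = 1e-3,
    max_attempts: int = 100,
) -> str:
    """Residue-shuffle a protein until it shares no similarity with ``reference``.

    The shuffle preserves the residue multiset exactly.  Candidates are
    resampled until the best local alignment against the reference (the
    homologue the scramble must be unrecognisable from; defaults to the
    input) has E > ``evalue_floor`` at the pairwise search-space size — the
    strictest space the pipeline will ever evaluate the pair at.  Raises
    for inputs (e.g. homopolymers) that cannot lose similarity.
    """
    if len(seq) < 10:
        raise ValueError("sequence too short to scramble meaningfully (< 10 residues)")
    ref = reference if reference is not None else seq
    p = params.with_space(len(ref), len(seq))
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for _ in range(max_attempts):
        cand = arr[rng.permutation(arr.size)].tobytes().decode()
        score = sw_score(cand, ref, p)
        if score <= 0 or evalue_of(score, p) > evalue_floor:
            return cand
    raise ValueError(
        "could not scramble away all similarity in "
        f"{max_attempts} attempts (low-complexity input?)"
    )


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    picks = rng.integers(0, 6, size=len(protein))
    parts = []
    for aa, k in zip(protein, picks):
        codons = _CODONS[aa]
        parts.append(codons[int(k) % len(codons)])
    parts.append("TAA")
    return "".join(parts)


def _assemble_genome(
    rng: np.random.Generator,
    species: str,
    chrom_genes: dict[str, list[tuple[str, str, str]]],  # chrom -> [(gene_id, strand, cds)]
    spacer: int,
) -> GenomeBundle:
    """Lay genes out on chromosomes with random spacers; build the bundle."""
    from Bio.Seq import Seq

    chromosomes: dict[str, str] = {}
    order_chroms: dict[str, list[Gene]] = {}
    proteins: dict[str, dict[str, str]] = {}
    cds_map: dict[str, str] = {}
    for chrom in sorted(chrom_genes):
        parts: list[str] = []
        pos = 0
        genes: list[Gene] = []
        for gene_id, strand, cds in chrom_genes[chrom]:
            gap = int(rng.poisson(spacer)) + 50
            parts.append("".join("ACGT"[i] for i in rng.integers(0, 4, size=gap)))
            pos += gap
            dna = cds if strand == "+" else str(Seq(cds).reverse_complement())
            start, end = pos, pos + len(dna)
            parts.append(dna)
            pos = end
            pid = gene_id + ".p1"
            genes.append(Gene(gene_id, chrom, start, end, strand, 0, (pid,)))
            prot = str(Seq(cds[:-3]).translate())
            proteins[gene_id] = {pid: prot}
            cds_map[pid] = cds
        tail = int(rng.poisson(spacer)) + 50
        parts.append("".join("ACGT"[i] for i in rng.integers(0, 4, size=tail)))
        chromosomes[chrom] = "".join(parts)
        order_chroms[chrom] = genes
    order = GeneOrder(species=species, chromosomes=order_chroms)
    return GenomeBundle(
        species=species,
        order=order,
        proteins=proteins,
        cds=cds_map,
        chromosomes=chromosomes,
    )


@dataclass
class _Ancestor:
    """The focal genome plus everything a derived target needs.

    The focal genome carries the ancestral sequences; each target accrues
    the full per-gene divergence, which is equivalent pairwise and lets one
    focal genome be shared by many targets at different times.
    """

    config: SimConfig
    gene_ids: list[str]
    proteins: list[str]
    strands: list[str]
    chrom_of: np.ndarray
    denovo_focal: dict[str, str]
    bundle: GenomeBundle


def _make_ancestor(config: SimConfig) -> _Ancestor:
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    lengths = np.maximum(
        30, rng.normal(config.mean_gene_length, config.mean_gene_length / 4, size=n)
    ).astype(int)
    proteins = [_random_protein(rng, int(L)) for L in lengths]
    gene_ids = [f"g{i:05d}" for i in range(n)]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n)]
    n_denovo = int(round(config.p_denovo * n))
    denovo_focal = {
        f"dnf{i:04d}": _random_protein(rng, int(max(30, rng.normal(config.mean_gene_length, 30))))
        for i in range(n_denovo)
    }
    chrom_of = np.sort(rng.integers(0, config.n_chromosomes, size=n))
    layout: dict[str, list[tuple[str, str, str]]] = {
        f"chr{c + 1}": [] for c in range(config.n_chromosomes)
    }
    for i in range(n):
        chrom = f"chr{chrom_of[i] + 1}"
        layout[chrom].append((gene_ids[i], strands[i], _back_translate(rng, proteins[i])))
    for gid, prot in denovo_focal.items():
        chrom = f"chr{int(rng.integers(0, config.n_chromosomes)) + 1}"
        pos = int(rng.integers(0, len(layout[chrom]) + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        layout[chrom].insert(pos, (gid, strand, _back_translate(rng, prot)))
    bundle = _assemble_genome(rng, "focal", layout, config.intergenic_spacer)
    return _Ancestor(
        config=config,
        gene_ids=gene_ids,
        proteins=proteins,
        strands=strands,
        chrom_of=chrom_of,
        denovo_focal=denovo_focal,
        bundle=bundle,
    )


def _derive_target(
    anc: _Ancestor,
    config: SimConfig,
    rng: np.random.Generator,
    name: str,
) -> tuple[GenomeBundle, dict[int, set[tuple[str, str]]], GroundTruth]:
    """Evolve one target genome from the ancestor.

    Returns the target bundle, detectable orthology members per ancestral
    gene index, and the ground-truth table for this focal-target pair.
    """
    n = config.n_genes
    gene_ids = anc.gene_ids

    perm = rng.permutation(n)
    n_loss = int(round(config.p_loss * n))
    n_scram = int(round(config.f_scrambled * n))
    lost = set(perm[:n_loss].tolist())
    scrambled = set(perm[n_loss : n_loss + n_scram].tolist())
    survivors = [i for i in range(n) if i not in lost]
    dup_pool = [i for i in survivors if i not in scrambled]
    n_dup = int(round(config.p_tandem_dup * n))
    dups = (
        set(rng.choice(dup_pool, size=min(n_dup, len(dup_pool)), replace=False).tolist())
        if n_dup
        else set()
    )
    div = np.clip(
        rng.normal(config.divergence_mean, config.divergence_sd, size=n),
        0.0,
        config.max_divergence,
    )

    target_prot: dict[int, str] = {}
    origin: dict[str, str] = {}
    true_hom: dict[str, str | None] = {}
    for i in range(n):
        gid = gene_ids[i]
        if i in lost:
            origin[gid] = "lost_in_target"
            true_hom[gid] = None
            continue
        t = _mutate(rng, anc.proteins[i], div[i])
        if i in scrambled:
            t = scramble_beyond_recognition(t, rng, reference=anc.proteins[i])
            origin[gid] = "diverged_beyond_recognition"
        elif div[i] == 0:
            origin[gid] = "conserved"
        else:
            origin[gid] = "diverged_detectable"
        target_prot[i] = t
        true_hom[gid] = gid
    for gid in anc.denovo_focal:
        origin[gid] = "de_novo"
        true_hom[gid] = None

    p_dn_t = config.p_denovo if config.p_denovo_target is None else config.p_denovo_target
    n_denovo_t = int(round(p_dn_t * n))
    denovo_target = {
        f"dnt{i:04d}": _random_protein(rng, int(max(30, rng.normal(config.mean_gene_length, 30))))
        for i in range(n_denovo_t)
    }

    layout: dict[str, list[tuple[str, str, str]]] = {
        f"chr{c + 1}": [] for c in range(config.n_chromosomes)
    }
    dup_ids: dict[int, str] = {}
    for i in range(n):
        if i in lost:
            continue
        chrom = f"chr{anc.chrom_of[i] + 1}"
        layout[chrom].append((gene_ids[i], anc.strands[i], _back_translate(rng, target_prot[i])))
        if i in dups:
            dup_id = gene_ids[i] + "d"
            dup_ids[i] = dup_id
            dup_prot = _mutate(rng, target_prot[i], div[i] / 2)
            layout[chrom].append((dup_id, anc.strands[i], _back_translate(rng, dup_prot)))
    for gid, prot in denovo_target.items():
        chrom = f"chr{int(rng.integers(0, config.n_chromosomes)) + 1}"
        pos = int(rng.integers(0, len(layout[chrom]) + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        layout[chrom].insert(pos, (gid, strand, _back_translate(rng, prot)))
    for _ in range(config.n_inversions):
        chrom = f"chr{int(rng.integers(0, config.n_chromosomes)) + 1}"
        genes = layout[chrom]
        if len(genes) < 2:
            continue
        seg = min(len(genes), 2 + int(rng.geometric(1.0 / max(1, config.inversion_mean_len - 1))))
        start = int(rng.integers(0, len(genes) - seg + 1))
        flipped = [
            (gid, "-" if strand == "+" else "+", cds)
            for gid, strand, cds in reversed(genes[start : start + seg])
        ]
        layout[chrom][start : start + seg] = flipped
    bundle = _assemble_genome(rng, name, layout, config.intergenic_spacer)

    # detectable orthology members per ancestral gene index
    members: dict[int, set[tuple[str, str]]] = {}
    for i in range(n):
        if i in lost:
            continue
        if i in scrambled and not config.include_scrambled_in_orthology:
            continue
        m = {(name, gene_ids[i])}
        if i in dup_ids:
            m.add((name, dup_ids[i]))
        members[i] = m

    # planted d over genes with surviving syntenic context: both immediate
    # focal neighbours (in the focal gene order, de novo insertions
    # included) must have a detectable surviving homologue
    detectable_ids = {
        gene_ids[i] for i in range(n) if i not in lost and i not in scrambled
    }
    idx_of = {gid: i for i, gid in enumerate(gene_ids)}
    n_context = n_context_scrambled = 0
    for chrom in anc.bundle.order.chromosomes:
        genes = anc.bundle.order.chromosomes[chrom]
        for k in range(1, len(genes) - 1):
            i = idx_of.get(genes[k].gene_id)
            if i is None or i in lost:  # de novo or absent from target
                continue
            if (
                genes[k - 1].gene_id in detectable_ids
                and genes[k + 1].gene_id in detectable_ids
            ):
                n_context += 1
                n_context_scrambled += i in scrambled
    planted_d = n_context_scrambled / n_context if n_context else 0.0
    n_focal_total = n + len(anc.denovo_focal)
    planted_x = (len(scrambled) + len(lost) + len(anc.denovo_focal)) / n_focal_total
    counts = {
        "conserved": sum(1 for v in origin.values() if v == "conserved"),
        "diverged_detectable": sum(1 for v in origin.values() if v == "diverged_detectable"),
        "diverged_beyond_recognition": len(scrambled),
        "de_novo": len(anc.denovo_focal),
        "lost_in_target": len(lost),
    }
    truth = GroundTruth(
        origin=origin,
        true_target_homologue=true_hom,
        planted_d=planted_d,
        planted_orphan_fraction=planted_x,
        counts=counts,
    )
    return bundle, members, truth


def _orthology_from_members(
    anc: _Ancestor, member_sets: Sequence[dict[int, set[tuple[str, str]]]]
) -> OrthologyMap:
    groups: dict[str, set[tuple[str, str]]] = {}
    for i, gid in enumerate(anc.gene_ids):
        merged: set[tuple[str, str]] = set()
        for members in member_sets:
            merged |= members.get(i, set())
        if merged:
            groups[f"OG{i:05d}"] = {("focal", gid)} | merged
    return OrthologyMap(groups)


def simulate_pair(config: SimConfig, target_name: str = "target") -> SimulatedPair:
    """Simulate one focal/target genome pair with planted ground truth."""
    anc = _make_ancestor(config)
    rng = np.random.default_rng([config.seed, 1])
    target, members, truth = _derive_target(anc, config, rng, target_name)
    orthology = _orthology_from_members(anc, [members])
    return SimulatedPair(
        config=config, focal=anc.bundle, target=target, orthology=orthology, truth=truth
    )


def ladder_tree_series(
    base: SimConfig,
    times: Sequence[float],
    d_slope: float = 0.02,
    divergence_base: float = 0.05,
    divergence_slope: float = 0.06,
) -> tuple[list[tuple[float, SimulatedPair]], SpeciesTree]:
    """One focal genome vs a series of targets at increasing divergence times.

    The target at time t gets f_scrambled = d_slope * t and substitution
    level divergence_base + divergence_slope * t (capped), so the planted
    rate of divergence beyond recognition grows linearly with time.  All
    targets descend from the same focal genome, and the merged orthology map
    reflects what is detectable per target.  Returns the simulated pairs
    (sharing the focal bundle and orthology) and a ladder species tree with
    those divergence times.
    """
    if list(times) != sorted(times):
        raise ValueError("times must be sorted ascending")
    import dendropy
    from dataclasses import replace

    anc = _make_ancestor(base)
    derived = []
    for j, t in enumerate(times):
        cfg = replace(
            base,
            f_scrambled=min(0.9, d_slope * t),
            divergence_mean=min(base.max_divergence, divergence_base + divergence_slope * t),
        )
        rng = np.random.default_rng([base.seed, j + 1])
        derived.append((t, cfg) + _derive_target(anc, cfg, rng, f"target{j + 1}"))
    orthology = _orthology_from_members(anc, [m for _, _, _, m, _ in derived])
    pairs = [
        (t, SimulatedPair(config=cfg, focal=anc.bundle, target=bundle, orthology=orthology, truth=truth))
        for t, cfg, bundle, _, truth in derived
    ]

    # ladder newick: focal splits most recently, deeper targets join outward
    newick = "focal"
    prev_t = 0.0
    for j, t in enumerate(times):
        newick = f"({newick}:{t - prev_t},target{j + 1}:{t})"
        prev_t = t
    tree = dendropy.Tree.get(data=newick + ";", schema="newick")
    div_times = {f"target{j + 1}": float(t) for j, t in enumerate(times)}
    return pairs, SpeciesTree(tree=tree, focal="focal", divergence_times=div_times)


def write_pair(pair: SimulatedPair, outdir: str | Path) -> dict[str, Path]:
    """Write all pipeline inputs plus the ground-truth table to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for bundle in (pair.focal, pair.target):
        prefix = outdir / bundle.species
        write_gff(bundle.order, prefix.with_suffix(".gff3"))
        flat = {pid: s for iso in bundle.proteins.values() for pid, s in iso.items()}
        write_fasta(flat, prefix.with_name(bundle.species + "_proteins.fa"))
        write_fasta(bundle.cds, prefix.with_name(bundle.species + "_cds.fa"))
        write_fasta(bundle.chromosomes, prefix.with_name(bundle.species + "_genome.fa"))
        paths[bundle.species] = prefix
    write_orthology(pair.orthology, outdir / "orthology.tsv")
    with open(outdir / "ground_truth.tsv", "w") as fh:
        fh.write("gene_id\torigin\ttrue_target_homologue\n")
        for gid in sorted(pair.truth.origin):
            hom = pair.truth.true_target_homologue.get(gid) or "-"
            fh.write(f"{gid}\t{pair.truth.origin[gid]}\t{hom}\n")
    with open(outdir / "planted.tsv", "w") as fh:
        fh.write("planted_d\tplanted_orphan_fraction\tplanted_contribution\n")
        fh.write(
            f"{pair.truth.planted_d:.6g}\t{pair.truth.planted_orphan_fraction:.6g}"
            f"\t{pair.truth.planted_contribution:.6g}\n"
        )
    return paths
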