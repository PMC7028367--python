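from __future__ import annotations

import numpy as np
import pytest

from synvergence.genome_model import Gene, GeneOrder, OrthologyMap

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


def make_order(species: str, layout: dict[str, list[tuple]]) -> GeneOrder:
    """layout: chrom -> [(gene_id, start, end[, strand])]."""
    chroms = {}
    for chrom, entries in layout.items():
        genes = []
        for e in entries:
            gene_id, start, end = e[:3]
            strand = e[3] if len(e) > 3 else "+"
            genes.append(Gene(gene_id, chrom, start, end, strand, 0, (gene_id + ".p1",)))
        chroms[chrom] = genes
    return GeneOrder(species=species, chromosomes=chroms)


def spaced_order(species: str, ids_by_chrom: dict[str, list[str]], length=100, gap=100) -> GeneOrder:
    layout = {}
    for chrom, ids in ids_by_chrom.items():
        layout[chrom] = [
            (gid, i * (length + gap), i * (length + gap) + length) for i, gid in enumerate(ids)
        ]
    return make_order(species, layout)


def random_genome_pair(rng: np.random.Generator):
    """A random focal/target gene-order pair with a messy orthology map.

    Exercises losses, duplications, unrelated insertions, local shuffles,
    segment inversions, overlapping focal genes and merged (paralogous)
    orthology groups — everything the micro-synteny rules must handle.
    """
    n = int(rng.integers(20, 51))
    n_chrom_f = int(rng.integers(1, 3))
    n_chrom_t = int(rng.integers(1, 3))
    ids = [f"g{i}" for i in range(n)]

    # focal layout with occasional heavy overlaps (80%-rule fodder)
    focal_layout: dict[str, list[tuple]] = {}
    assign_f = np.sort(rng.integers(0, n_chrom_f, size=n))
    pos = {}
    for c in range(n_chrom_f):
        chrom = f"fc{c}"
        entries = []
        x = 0
        for i in np.nonzero(assign_f == c)[0]:
            if entries and rng.random() < 0.15:
                # overlap the previous gene by 50-100%
                prev = entries[-1]
                shift = int(rng.integers(0, 50))
                entries.append((ids[i], prev[1] + shift, prev[2] + shift + 1))
            else:
                entries.append((ids[i], x, x + 100))
            x = entries[-1][2] + 100
        focal_layout[chrom] = entries
    focal = make_order("focal", focal_layout)

    # target gene list: survivors + duplications + unrelated genes, shuffled locally
    survivors = [i for i in range(n) if rng.random() > 0.15]
    tlist: list[str] = []
    groups: dict[str, set] = {}
    for i in survivors:
        tlist.append(f"t{i}")
        groups[f"OG{i}"] = {("focal", ids[i]), ("target", f"t{i}")}
        if rng.random() < 0.1:
            tlist.append(f"t{i}d")
            groups[f"OG{i}"].add(("target", f"t{i}d"))
    for j in range(int(rng.integers(0, 6))):
        tlist.insert(int(rng.integers(0, len(tlist) + 1)), f"x{j}")
    # merge some groups into paralogous super-groups
    keys = sorted(groups)
    for _ in range(int(rng.integers(0, 4))):
        if len(keys) < 2:
            break
        a, b = rng.choice(len(keys), size=2, replace=False)
        ka, kb = keys[int(a)], keys[int(b)]
        if ka != kb and kb in groups and ka in groups:
            groups[ka] |= groups.pop(kb)
            keys.remove(kb)
    # local shuffling: a few swaps and one segment inversion
    tarr = list(tlist)
    for _ in range(int(rng.integers(0, 8))):
        k = int(rng.integers(0, max(1, len(tarr) - 1)))
        tarr[k], tarr[min(k + 1, len(tarr) - 1)] = tarr[min(k + 1, len(tarr) - 1)], tarr[k]
    if len(tarr) > 4 and rng.random() < 0.5:
        s = int(rng.integers(0, len(tarr) - 3))
        L = int(rng.integers(2, 5))
        tarr[s : s + L] = tarr[s : s + L][::-1]
    assign_t = np.sort(rng.integers(0, n_chrom_t, size=len(tarr)))
    target_ids = {f"tc{c}": [tarr[i] for i in np.nonzero(assign_t == c)[0]] for c in range(n_chrom_t)}
    target = spaced_order("target", target_ids)
    return focal, target, OrthologyMap(groups)


@pytest.fixture(scope="session")
def small_pair():
    """A moderately sized simulated pair shared across tests (read-only)."""
    from synvergence.synthetic_data import SimConfig, simulate_pair

    return simulate_pair(SimConfig(seed=11, n_genes=150, f_scrambled=0.2))
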