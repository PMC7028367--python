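"""Independent oracles used by the test suite.

These deliberately share no code with the package: the synteny oracle is a
plain nested-loop enumeration of the written micro-synteny rules, and the
alignment oracle scores every substring pair with its own affine-gap DP.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def local_align_oracle(q: str, s: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Best local alignment score by exhaustive start-pair enumeration.

    For every start pair (i, j) runs a start-anchored affine-gap DP over the
    suffixes and takes the maximum over all end cells — an O(m^2 n^2)
    all-substring scorer (optimal local alignments start and end on aligned
    residue pairs, so leading/trailing gaps need not be considered).
    """
    best = 0.0
    first = gap_open + gap_extend
    for i in range(len(q)):
        for j in range(len(s)):
            la, lb = len(q) - i, len(s) - j
            M = [[NEG] * lb for _ in range(la)]
            X = [[NEG] * lb for _ in range(la)]
            Y = [[NEG] * lb for _ in range(la)]
            for a in range(la):
                qa = q[i + a]
                for b in range(lb):
                    sub = _B62[qa][s[j + b]]
                    if a == 0 and b == 0:
                        M[0][0] = sub
                    else:
                        prev = NEG
                        if a > 0 and b > 0:
                            prev = max(M[a - 1][b - 1], X[a - 1][b - 1], Y[a - 1][b - 1])
                        if prev > NEG:
                            M[a][b] = sub + prev
                    if a > 0:
                        X[a][b] = max(M[a - 1][b] - first, X[a - 1][b] - gap_extend)
                    if b > 0:
                        Y[a][b] = max(M[a][b - 1] - first, Y[a][b - 1] - gap_extend)
                    if M[a][b] > best:
                        best = M[a][b]
    return best


# ---------------------------------------------------------------------------
# micro-synteny brute force


def _overlap_frac(a, b) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    return max(0, inter) / (a.end - a.start)


def _group_of(orth, species, gene_id):
    for gid, members in orth.groups.items():
        if (species, gene_id) in members:
            return gid
    return None


def _homologues(orth, focal_species, gene_id, target_species, target_order):
    gid = _group_of(orth, focal_species, gene_id)
    if gid is None:
        return []
    out = []
    for sp, tg in orth.groups[gid]:
        if sp == target_species:
            g = target_order.get(tg)
            if g is not None:
                out.append(g)
    return out


def _outer_ok(orth, focal_species, target_species, focal_genes, idx, side, layers, anchor, target_order):
    current = anchor
    for depth in range(2, 2 + layers):
        k = idx + side * depth
        if k < 0 or k >= len(focal_genes):
            break
        homs = [
            h
            for h in _homologues(orth, focal_species, focal_genes[k].gene_id, target_species, target_order)
            if h.chrom == current.chrom
        ]
        if not homs:
            continue
        near = [h for h in homs if 1 <= abs(h.rank - current.rank) <= 2]
        if not near:
            return False
        near.sort(key=lambda h: (abs(h.rank - current.rank), h.rank))
        current = near[0]
    return True


def brute_force_blocks(focal_order, target_order, orth, stringency, threshold=0.8):
    """Every micro-synteny block, as (focal, left, right, opposite ids) tuples."""
    layers = {"relaxed": 0, "standard": 1, "stringent": 2}[stringency]
    focal_species = focal_order.species
    target_species = target_order.species
    found = set()
    for chrom in focal_order.chromosomes:
        genes = focal_order.chromosomes[chrom]
        for idx, g in enumerate(genes):
            # 80% overlap eligibility against existing immediate neighbours
            if idx > 0 and _overlap_frac(g, genes[idx - 1]) > threshold:
                continue
            if idx + 1 < len(genes) and _overlap_frac(g, genes[idx + 1]) > threshold:
                continue
            if idx == 0 or idx + 1 >= len(genes):
                continue
            lefts = _homologues(orth, focal_species, genes[idx - 1].gene_id, target_species, target_order)
            rights = _homologues(orth, focal_species, genes[idx + 1].gene_id, target_species, target_order)
            for a in lefts:
                for c in rights:
                    if a.chrom != c.chrom or a.gene_id == c.gene_id:
                        continue
                    if abs(a.rank - c.rank) - 1 not in (1, 2):
                        continue
                    ga = _group_of(orth, target_species, a.gene_id)
                    gc = _group_of(orth, target_species, c.gene_id)
                    if ga is not None and ga == gc:
                        continue
                    if layers and not _outer_ok(
                        orth, focal_species, target_species, genes, idx, -1, layers, a, target_order
                    ):
                        continue
                    if layers and not _outer_ok(
                        orth, focal_species, target_species, genes, idx, +1, layers, c, target_order
                    ):
                        continue
                    lo, hi = sorted((a.rank, c.rank))
                    opp = tuple(
                        x.gene_id for x in target_order.chromosomes[a.chrom][lo + 1 : hi]
                    )
                    found.add((g.gene_id, a.gene_id, c.gene_id, opp))
    return found
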