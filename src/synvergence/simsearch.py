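"""Similarity search: local alignment, E-values, and the cascaded protocol.

The cascade, run for every focal gene that sits in conserved micro-synteny,
asks in order:

1. does the focal protein match any "opposite" gene's protein (the predicted
   homologue position)?                          -> found_opposite / proteome_opposite
2. does it match the opposite gene's genomic region +/- a flank, in any of
   the six reading frames?                       -> found_opposite / local_genomic
3. does it match anywhere in the target proteome?-> found_elsewhere / proteome_wide
4. does it match anywhere in the target genome (six-frame, at a fixed
   stringent cutoff)?                            -> found_elsewhere / genome_wide
5. otherwise the pair is an undetectable homology (not_found).

The built-in engine is Smith-Waterman with affine gaps (BLOSUM62 11/1 by
default) with Karlin-Altschul E-values.  Whole-proteome and whole-genome
steps use exact k-mer seeding before alignment, as BLAST-family tools do; an
exhaustive mode aligns every pair and is used where weak, random-level hits
matter (reversed-proteome decoy searches at generous cutoffs).  An optional
adapter shells out to BLAST+ when the binaries are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .genome_model import Gene, GenomeBundle
from .synteny import SyntenyBlock

__all__ = [
    "ScoringParams",
    "Hit",
    "CascadeOutcome",
    "local_align",
    "evalue_of",
    "bitscore_of",
    "six_frame_translations",
    "TargetIndex",
    "search_protein_vs_proteins",
    "search_protein_vs_dna",
    "cascade_search",
    "outcome_at",
    "genome_wide_best_evalues",
    "reversed_best_evalues",
    "reversed_false_homology_search",
    "GENOME_STEP_CUTOFF",
]

#: Fixed cutoff for the final whole-genome translated step; this step is
#: excluded from E-value threshold optimisation.
GENOME_STEP_CUTOFF = 1e-6

_STEP_ORDER = ("proteome_opposite", "local_genomic", "proteome_wide", "genome_wide")


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix, gap penalties and Karlin-Altschul statistics.

    ``lam``/``K`` default to values calibrated for this engine by fitting a
    Gumbel distribution to optimal local alignment scores of random
    uniform-composition protein pairs (the standard way extreme-value
    parameters are obtained for gapped alignment, where no analytic form
    exists).  ``search_space`` is (query residues m, database residues n)
    and is set per search.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.240
    K: float = 0.035
    search_space: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def with_space(self, m: int, n: int) -> "ScoringParams":
        return ScoringParams(
            self.matrix, self.gap_open, self.gap_extend, self.lam, self.K, (m, n)
        )


@dataclass(frozen=True)
class Hit:
    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    query_span: tuple[int, int] = (0, 0)
    subject_span: tuple[int, int] = (0, 0)
    frame: int = 0

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("E-value must be positive")


@dataclass
class CascadeOutcome:
    """Which search step, if any, detected similarity for one focal gene."""

    focal_gene: str
    target_species: str
    status: str  # found_opposite | found_elsewhere | not_found
    step_found: str  # proteome_opposite | local_genomic | proteome_wide | genome_wide | none
    best_hit: Hit | None
    cutoff_used: float
    #: best (minimum) E-value observed at each executed step; steps skipped
    #: by short-circuiting are absent.
    step_evalues: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# engine


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load(matrix)
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    return al


@lru_cache(maxsize=8)
def _alphabet(matrix: str) -> frozenset[str]:
    return frozenset(str(substitution_matrices.load(matrix).alphabet))


def _check_protein(seq: str, params: ScoringParams) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _alphabet(params.matrix)
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")


def sw_score(query: str, subject: str, params: ScoringParams) -> float:
    """Smith-Waterman score only (fast path; no traceback)."""
    if not query or not subject:
        return 0.0
    return _aligner(params.matrix, params.gap_open, params.gap_extend).score(
        query, subject
    )


def local_align(
    query: str, subject: str, params: ScoringParams = ScoringParams()
) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Optimal local alignment: (score, query span, subject span).

    Ties between co-optimal alignments break deterministically toward the
    lowest query start, then the lowest subject start.
    """
    _check_protein(query, params)
    _check_protein(subject, params)
    al = _aligner(params.matrix, params.gap_open, params.gap_extend)
    alignments = al.align(query, subject)
    if alignments.score <= 0:
        return 0.0, (0, 0), (0, 0)
    best = None
    # co-optimal alignment counts can explode on degenerate input; examining
    # a bounded prefix keeps the tie-break deterministic and cheap
    for i, aln in enumerate(alignments):
        qspan = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
        sspan = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
        key = (qspan[0], sspan[0])
        if best is None or key < best[0]:
            best = (key, qspan, sspan)
        if i >= 31:
            break
    return float(alignments.score), best[1], best[2]


def evalue_of(score: float, params: ScoringParams) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if params.search_space is None:
        raise ValueError("search_space not set")
    if score <= 0:
        raise ValueError("score must be positive")
    m, n = params.search_space
    return params.K * m * n * math.exp(-params.lam * score)


def bitscore_of(score: float, params: ScoringParams) -> float:
    return (params.lam * score - math.log(params.K)) / math.log(2)


def _safe_evalue(score: float, params: ScoringParams) -> float:
    return evalue_of(score, params) if score > 0 else math.inf


# ---------------------------------------------------------------------------
# k-mer indexing (the seeding layer of the built-in engine)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(_AA):
    _AA_CODE[ord(_c)] = _i


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all valid k-mers (positions with rare letters dropped)."""
    arr = _AA_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (win < 20).all(axis=1)
    powers = (20 ** np.arange(k)).astype(np.int64)
    codes = win.astype(np.int64) @ powers
    codes[~valid] = -1
    return codes


class _ProteinKmerIndex:
    """Exact k-mer inverted index over a protein database, gene-level owners."""

    def __init__(self, gene_isoforms: dict[str, dict[str, str]], k: int = 5):
        self.k = k
        self.gene_ids: list[str] = sorted(gene_isoforms)
        codes_all: list[np.ndarray] = []
        owners_all: list[np.ndarray] = []
        for gi, gene_id in enumerate(self.gene_ids):
            for seq in gene_isoforms[gene_id].values():
                codes = _kmer_codes(seq, k)
                codes = codes[codes >= 0]
                if codes.size:
                    codes_all.append(codes)
                    owners_all.append(np.full(codes.size, gi, dtype=np.int32))
        if codes_all:
            codes = np.concatenate(codes_all)
            owners = np.concatenate(owners_all)
            sort = np.argsort(codes, kind="stable")
            self.codes = codes[sort]
            self.owners = owners[sort]
        else:
            self.codes = np.empty(0, dtype=np.int64)
            self.owners = np.empty(0, dtype=np.int32)

    def candidates(self, query: str) -> list[str]:
        """Gene ids sharing >=1 k-mer with the query, most shared first."""
        if self.codes.size == 0:
            return []
        q = np.unique(_kmer_codes(query, self.k))
        q = q[q >= 0]
        if q.size == 0:
            return []
        lo = np.searchsorted(self.codes, q, side="left")
        hi = np.searchsorted(self.codes, q, side="right")
        counts = np.zeros(len(self.gene_ids), dtype=np.int64)
        for a, b in zip(lo, hi):
            if b > a:
                np.add.at(counts, self.owners[a:b], 1)
        hit_idx = np.nonzero(counts)[0]
        order = hit_idx[np.argsort(-counts[hit_idx], kind="stable")]
        return [self.gene_ids[i] for i in order]


class _FrameKmerIndex:
    """k-mer index over six-frame translations of whole chromosomes."""

    def __init__(self, frames: list[tuple[str, int, str]], k: int = 6):
        # frames: (chrom, frame in {+1..+3,-1..-3}, translated protein)
        self.k = k
        self.frames = frames
        codes_all, frame_all, pos_all = [], [], []
        for fi, (_, _, prot) in enumerate(frames):
            codes = _kmer_codes(prot, k)
            valid = codes >= 0
            pos = np.nonzero(valid)[0].astype(np.int32)
            if pos.size:
                codes_all.append(codes[valid])
                frame_all.append(np.full(pos.size, fi, dtype=np.int32))
                pos_all.append(pos)
        if codes_all:
            codes = np.concatenate(codes_all)
            sort = np.argsort(codes, kind="stable")
            self.codes = codes[sort]
            self.frame_idx = np.concatenate(frame_all)[sort]
            self.pos = np.concatenate(pos_all)[sort]
        else:
            self.codes = np.empty(0, dtype=np.int64)
            self.frame_idx = np.empty(0, dtype=np.int32)
            self.pos = np.empty(0, dtype=np.int32)

    def seed_windows(self, query: str, pad: int) -> list[tuple[int, int, int]]:
        """(frame index, window start, window end) clusters of seed matches."""
        if self.codes.size == 0:
            return []
        q = np.unique(_kmer_codes(query, self.k))
        q = q[q >= 0]
        if q.size == 0:
            return []
        lo = np.searchsorted(self.codes, q, side="left")
        hi = np.searchsorted(self.codes, q, side="right")
        take = np.concatenate(
            [np.arange(a, b) for a, b in zip(lo, hi) if b > a] or [np.empty(0, int)]
        ).astype(np.int64)
        if take.size == 0:
            return []
        frames = self.frame_idx[take]
        poss = self.pos[take]
        windows: list[tuple[int, int, int]] = []
        for fi in np.unique(frames):
            p = np.sort(poss[frames == fi])
            start = int(p[0])
            prev = int(p[0])
            for x in p[1:]:
                x = int(x)
                if x - prev > pad:
                    windows.append((int(fi), max(0, start - pad), prev + self.k + pad))
                    start = x
                prev = x
            windows.append((int(fi), max(0, start - pad), prev + self.k + pad))
        return windows


def six_frame_translations(dna: str) -> list[tuple[int, str]]:
    """(frame, protein) for frames +1,+2,+3,-1,-2,-3; stops kept as '*'."""
    out: list[tuple[int, str]] = []
    fwd = Seq(dna)
    rev = fwd.reverse_complement()
    for off in range(3):
        for sign, seq in ((+1, fwd), (-1, rev)):
            sub = seq[off : len(seq) - ((len(seq) - off) % 3)]
            if len(sub) >= 3:
                out.append((sign * (off + 1), str(sub.translate())))
    out.sort(key=lambda t: (-t[0] if t[0] > 0 else 3 - t[0]))
    return out


# ---------------------------------------------------------------------------
# searches


def _gene_best_score(
    query_isoforms: Iterable[str], subject_isoforms: Iterable[str], params: ScoringParams
) -> float:
    best = 0.0
    subject_isoforms = list(subject_isoforms)
    for q in query_isoforms:
        for s in subject_isoforms:
            sc = sw_score(q, s, params)
            if sc > best:
                best = sc
    return best


def search_protein_vs_proteins(
    query: dict[str, str] | str,
    db: dict[str, dict[str, str]],
    cutoff: float,
    params: ScoringParams = ScoringParams(),
    *,
    index: "_ProteinKmerIndex | None" = None,
    exhaustive: bool = False,
    query_id: str = "query",
    first_only: bool = False,
) -> list[Hit]:
    """Search query isoforms against a proteome; per-gene best hit.

    ``db`` maps gene_id -> {protein_id: sequence}.  With ``exhaustive`` every
    gene is aligned; otherwise only k-mer seeded candidates are (BLAST-style
    heuristic).  Hits with E <= cutoff, ordered (evalue, -bitscore, subject).
    """
    if isinstance(query, str):
        query = {query_id: query}
    if not db:
        return []
    m = max(len(s) for s in query.values())
    n = sum(len(s) for iso in db.values() for s in iso.values())
    p = params.with_space(m, n)
    if exhaustive:
        candidates: Sequence[str] = sorted(db)
    else:
        if index is None:
            index = _ProteinKmerIndex(db)
        candidates = [g for g in index.candidates(next(iter(query.values()))) if g in db]
        if len(query) > 1:  # seed with every isoform
            seen = set(candidates)
            for q in list(query.values())[1:]:
                for g in index.candidates(q):
                    if g not in seen and g in db:
                        candidates.append(g)
                        seen.add(g)
    hits: list[Hit] = []
    for gene_id in candidates:
        score = _gene_best_score(query.values(), db[gene_id].values(), p)
        if score <= 0:
            continue
        e = evalue_of(score, p)
        if e <= cutoff:
            hits.append(
                Hit(query_id=query_id, subject_id=gene_id, bitscore=bitscore_of(score, p), evalue=e)
            )
            if first_only:
                break
    hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    return hits


def search_protein_vs_dna(
    query: dict[str, str] | str,
    region: str,
    cutoff: float,
    params: ScoringParams = ScoringParams(),
    *,
    query_id: str = "query",
    subject_id: str = "region",
) -> list[Hit]:
    """Translated search of a query protein against a DNA region (six frames)."""
    if isinstance(query, str):
        query = {query_id: query}
    frames = six_frame_translations(region)
    if not frames:
        return []
    m = max(len(s) for s in query.values())
    n = sum(len(prot) for _, prot in frames)
    p = params.with_space(m, n)
    hits: list[Hit] = []
    for frame, prot in frames:
        best = 0.0
        for q in query.values():
            sc = sw_score(q, prot, p)
            best = max(best, sc)
        if best <= 0:
            continue
        e = evalue_of(best, p)
        if e <= cutoff:
            hits.append(
                Hit(
                    query_id=query_id,
                    subject_id=subject_id,
                    bitscore=bitscore_of(best, p),
                    evalue=e,
                    frame=frame,
                )
            )
    hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id, h.frame))
    return hits


class TargetIndex:
    """Precomputed search structures for one target genome.

    Builds the proteome k-mer index eagerly and the whole-genome six-frame
    index lazily (it is only needed for queries that fail every earlier
    step).
    """

    def __init__(
        self,
        bundle: GenomeBundle,
        params: ScoringParams = ScoringParams(),
        k_protein: int = 5,
        k_genome: int = 6,
    ):
        self.bundle = bundle
        self.params = params
        self.protein_index = _ProteinKmerIndex(bundle.proteins, k=k_protein)
        self.proteome_residues = bundle.proteome_residues()
        self.k_genome = k_genome
        self._genome_index: _FrameKmerIndex | None = None
        self._genome_residues: int | None = None

    @property
    def genome_index(self) -> _FrameKmerIndex:
        if self._genome_index is None:
            frames: list[tuple[str, int, str]] = []
            for chrom in sorted(self.bundle.chromosomes):
                for frame, prot in six_frame_translations(self.bundle.chromosomes[chrom]):
                    frames.append((chrom, frame, prot))
            self._genome_index = _FrameKmerIndex(frames, k=self.k_genome)
            self._genome_residues = sum(len(p) for _, _, p in frames)
        return self._genome_index

    @property
    def genome_residues(self) -> int:
        _ = self.genome_index
        return self._genome_residues or 1

    def best_proteome_evalue(
        self, query: dict[str, str], *, exhaustive: bool = False, stop_at: float | None = None
    ) -> float:
        """Minimum E-value of the query against the whole target proteome.

        ``stop_at``: early-return as soon as a hit at or below this E-value
        is found (the minimum over remaining candidates cannot matter for a
        found/not-found decision at that cutoff).
        """
        db = self.bundle.proteins
        if not db:
            return math.inf
        m = max(len(s) for s in query.values())
        p = self.params.with_space(m, self.proteome_residues)
        if exhaustive:
            candidates: Iterable[str] = db
        else:
            seen: set[str] = set()
            cand: list[str] = []
            for q in query.values():
                for g in self.protein_index.candidates(q):
                    if g not in seen:
                        seen.add(g)
                        cand.append(g)
            candidates = cand
        best = math.inf
        for gene_id in candidates:
            score = _gene_best_score(query.values(), db[gene_id].values(), p)
            e = _safe_evalue(score, p)
            if e < best:
                best = e
                if stop_at is not None and best <= stop_at:
                    break
        return best

    def best_genome_evalue(self, query: dict[str, str]) -> float:
        """Minimum E-value of the query against the six-frame translated genome."""
        idx = self.genome_index
        m = max(len(s) for s in query.values())
        p = self.params.with_space(m, self.genome_residues)
        best = math.inf
        for q in query.values():
            pad = max(len(q), 50)
            for fi, lo, hi in idx.seed_windows(q, pad):
                prot = idx.frames[fi][2][lo:hi]
                score = sw_score(q, prot, p)
                e = _safe_evalue(score, p)
                best = min(best, e)
        return best

    def opposite_region(self, gene: Gene, flank: int) -> str:
        chrom = self.bundle.chromosomes.get(gene.chrom, "")
        lo = max(0, gene.start - flank)
        hi = min(len(chrom), gene.end + flank)
        return chrom[lo:hi]


def cascade_search(
    focal_gene: Gene,
    focal_proteins: dict[str, str],
    blocks: Sequence[SyntenyBlock],
    target: TargetIndex,
    cutoff: float,
    flank: int = 2000,
    *,
    record: bool = False,
    stop_at: float | None = None,
    skip_local: bool = False,
) -> CascadeOutcome:
    """Run the cascaded search protocol for one focal gene in micro-synteny.

    With ``record=True`` every step is force-run and its best E-value stored,
    so outcomes at other cutoffs can be re-derived without re-searching (the
    final genome-wide step keeps its fixed cutoff regardless).

    ``stop_at`` (record mode): once any step's best E-value reaches this
    threshold, remaining steps are skipped and within-step searches may stop
    early — sound when outcomes will only ever be read at cutoffs >= the
    threshold.  ``skip_local`` omits the local translated step; its E-value
    feeds neither the d-excluding-local estimator nor fixed-cutoff outcomes
    once an earlier step has hit, so pipelines that need no calibration
    curve skip its cost.
    """
    if not blocks:
        raise ValueError("cascade_search requires at least one synteny block")
    species = target.bundle.species
    opposite: dict[str, Gene] = {}
    for b in blocks:
        for g in b.opposite:
            opposite[g.gene_id] = g
    step_e: dict[str, float] = {}

    # step: proteome_opposite — protein match at the predicted location
    m = max(len(s) for s in focal_proteins.values())
    p_prot = target.params.with_space(m, max(target.proteome_residues, 1))
    best = math.inf
    for gid in sorted(opposite):
        iso = target.bundle.proteins.get(gid, {})
        score = _gene_best_score(focal_proteins.values(), iso.values(), p_prot)
        best = min(best, _safe_evalue(score, p_prot))
    step_e["proteome_opposite"] = best

    def _done() -> bool:
        found = min(step_e.values(), default=math.inf)
        if not record:
            return found <= cutoff
        return stop_at is not None and found <= stop_at

    if _done():
        return _finish(focal_gene, species, cutoff, step_e)

    # step: local_genomic — translated search of each opposite region +/- flank
    if not skip_local:
        best = math.inf
        for gid in sorted(opposite):
            region = target.opposite_region(opposite[gid], flank)
            if len(region) < 3:
                continue
            hits = search_protein_vs_dna(
                focal_proteins, region, math.inf, target.params, subject_id=gid
            )
            if hits:
                best = min(best, hits[0].evalue)
        step_e["local_genomic"] = best
        if _done():
            return _finish(focal_gene, species, cutoff, step_e)

    # step: proteome_wide
    stop = stop_at if record else cutoff
    step_e["proteome_wide"] = target.best_proteome_evalue(focal_proteins, stop_at=stop)
    if _done():
        return _finish(focal_gene, species, cutoff, step_e)

    # step: genome_wide — fixed stringent cutoff, never re-thresholded
    step_e["genome_wide"] = target.best_genome_evalue(focal_proteins)
    return _finish(focal_gene, species, cutoff, step_e)


def outcome_at(step_evalues: dict[str, float], cutoff: float) -> tuple[str, str]:
    """(status, step_found) implied by recorded step E-values at a cutoff."""
    for step in _STEP_ORDER:
        e = step_evalues.get(step, math.inf)
        limit = GENOME_STEP_CUTOFF if step == "genome_wide" else cutoff
        if e <= limit:
            status = "found_opposite" if step in ("proteome_opposite", "local_genomic") else "found_elsewhere"
            return status, step
    return "not_found", "none"


def _finish(
    focal_gene: Gene, species: str, cutoff: float, step_e: dict[str, float]
) -> CascadeOutcome:
    status, step = outcome_at(step_e, cutoff)
    best_hit = None
    if step != "none":
        e = step_e[step]
        best_hit = Hit(query_id=focal_gene.gene_id, subject_id=species, bitscore=0.0, evalue=e)
    return CascadeOutcome(
        focal_gene=focal_gene.gene_id,
        target_species=species,
        status=status,
        step_found=step,
        best_hit=best_hit,
        cutoff_used=cutoff,
        step_evalues=step_e,
    )


def genome_wide_best_evalues(
    focal_proteins: dict[str, str],
    target: TargetIndex,
    *,
    proteome_stop_at: float | None = None,
    skip_genome_if_proteome_below: float | None = None,
) -> tuple[float, float]:
    """(best proteome E, best genome E) for one focal gene vs the target.

    Used to flag genes with no similarity anywhere in the target (the X of
    the X/n genome-wide proportion).  ``skip_genome_if_proteome_below``: the
    genome scan is skipped (E=inf recorded) when the proteome already hit,
    since the flag is decided by the proteome step alone.
    """
    e_prot = target.best_proteome_evalue(focal_proteins, stop_at=proteome_stop_at)
    if (
        skip_genome_if_proteome_below is not None
        and e_prot <= skip_genome_if_proteome_below
    ):
        return e_prot, math.inf
    return e_prot, target.best_genome_evalue(focal_proteins)


# ---------------------------------------------------------------------------
# reversed-proteome decoy searches


def _reverse_bundle(bundle: GenomeBundle) -> GenomeBundle:
    rev_prot = {
        g: {pid: s[::-1] for pid, s in iso.items()} for g, iso in bundle.proteins.items()
    }
    rev_chrom = {c: s[::-1] for c, s in bundle.chromosomes.items()}
    return GenomeBundle(
        species=bundle.species + "_reversed",
        order=bundle.order,
        proteins=rev_prot,
        cds=bundle.cds,
        chromosomes=rev_chrom,
    )


def reversed_best_evalues(
    focal_proteins: dict[str, dict[str, str]],
    target_bundle: GenomeBundle,
    blocks: dict[str, Sequence[SyntenyBlock]] | None = None,
    params: ScoringParams = ScoringParams(),
    flank: int = 2000,
    *,
    exhaustive: bool = True,
) -> dict[str, float]:
    """Best E-value of each focal gene against the reversed target.

    Every focal protein is searched against the character-reversed target
    proteome; focal genes in micro-synteny are additionally searched against
    the reversed genomic region of their opposite genes (translated).
    Returns focal gene_id -> minimum E-value (inf if no alignment scored).
    """
    rev = _reverse_bundle(target_bundle)
    rev_index = TargetIndex(rev, params)
    out: dict[str, float] = {}
    for gene_id in sorted(focal_proteins):
        iso = focal_proteins[gene_id]
        e = rev_index.best_proteome_evalue(iso, exhaustive=exhaustive)
        gene_blocks = (blocks or {}).get(gene_id, ())
        opposite: dict[str, Gene] = {}
        for b in gene_blocks:
            for g in b.opposite:
                opposite[g.gene_id] = g
        for gid in sorted(opposite):
            g = opposite[gid]
            chrom = target_bundle.chromosomes.get(g.chrom, "")
            lo = max(0, g.start - flank)
            hi = min(len(chrom), g.end + flank)
            region = chrom[lo:hi][::-1]
            if len(region) >= 3:
                hits = search_protein_vs_dna(iso, region, math.inf, params, subject_id=gid)
                if hits:
                    e = min(e, hits[0].evalue)
        out[gene_id] = e
    return out


def reversed_false_homology_search(
    focal_proteins: dict[str, dict[str, str]],
    target_bundle: GenomeBundle,
    blocks: dict[str, Sequence[SyntenyBlock]] | None = None,
    cutoff: float = 1.0,
    params: ScoringParams = ScoringParams(),
    **kw,
) -> float:
    """Proportion of the focal proteome with a hit to the reversed target."""
    best = reversed_best_evalues(focal_proteins, target_bundle, blocks, params, **kw)
    if not best:
        return 0.0
    return sum(1 for e in best.values() if e <= cutoff) / len(best)
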