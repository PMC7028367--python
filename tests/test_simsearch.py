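import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from synvergence.genome_model import GenomeBundle
from synvergence.simsearch import (
    ScoringParams,
    TargetIndex,
    bitscore_of,
    cascade_search,
    evalue_of,
    local_align,
    outcome_at,
    reversed_false_homology_search,
    search_protein_vs_dna,
    search_protein_vs_proteins,
    sw_score,
)
from synvergence.synthetic_data import SimConfig, simulate_pair
from synvergence.synteny import enumerate_blocks

from conftest import random_protein
from oracles import local_align_oracle

B62 = substitution_matrices.load("BLOSUM62")


class TestLocalAlign:
    def test_self_alignment_is_diagonal_sum(self):
        seq = "MKVLANQWERTY"
        score, qspan, sspan = local_align(seq, seq)
        assert score == sum(B62[c][c] for c in seq)
        assert qspan == (0, len(seq)) and sspan == (0, len(seq))

    def test_single_residue_match(self):
        score, _, _ = local_align("A", "A")
        assert score == B62["A"]["A"]

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            local_align("MK1V", "MKV")

    def test_matches_all_substring_oracle_on_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(60):
            q = random_protein(rng, int(rng.integers(4, 13)))
            s = random_protein(rng, int(rng.integers(4, 13)))
            assert sw_score(q, s, ScoringParams()) == local_align_oracle(q, s)

    def test_deterministic_tie_break(self):
        # two identical motifs in the subject: span must pick the first
        score1, q1, s1 = local_align("WWW", "AAWWWAAWWWAA")
        score2, q2, s2 = local_align("WWW", "AAWWWAAWWWAA")
        assert (score1, q1, s1) == (score2, q2, s2)
        assert s1 == (2, 5)


class TestEvalue:
    def test_linear_in_search_space(self):
        p1 = ScoringParams().with_space(100, 1000)
        p2 = ScoringParams().with_space(100, 2000)
        p3 = ScoringParams().with_space(200, 1000)
        assert evalue_of(50, p2) == pytest.approx(2 * evalue_of(50, p1))
        assert evalue_of(50, p3) == pytest.approx(2 * evalue_of(50, p1))

    def test_strictly_decreasing_in_score(self):
        p = ScoringParams().with_space(100, 1000)
        es = [evalue_of(s, p) for s in range(10, 200, 5)]
        assert all(a > b for a, b in zip(es, es[1:]))
        assert evalue_of(10000, p) == pytest.approx(0.0, abs=1e-200)

    def test_closed_form_unit_evalue(self):
        p = ScoringParams().with_space(137, 4211)
        s_unit = math.log(p.K * 137 * 4211) / p.lam
        assert evalue_of(s_unit, p) == pytest.approx(1.0)

    def test_positive_score_required(self):
        with pytest.raises(ValueError):
            evalue_of(0, ScoringParams().with_space(10, 10))

    def test_bitscore_monotone(self):
        p = ScoringParams()
        assert bitscore_of(100, p) > bitscore_of(50, p)


class TestProteomeSearch:
    def _db(self, rng, n=30, length=120):
        return {f"p{i}": {f"p{i}.1": random_protein(rng, length)} for i in range(n)}

    def test_identical_protein_ranked_first(self):
        rng = np.random.default_rng(1)
        db = self._db(rng)
        query = db["p7"]["p7.1"]
        hits = search_protein_vs_proteins(query, db, cutoff=1e-3)
        assert hits and hits[0].subject_id == "p7"

    def test_reversed_decoys_rarely_hit_at_stringent_cutoff(self):
        rng = np.random.default_rng(2)
        db = {k: {pk: s[::-1] for pk, s in v.items()} for k, v in self._db(rng, 50).items()}
        n_hit = 0
        for _ in range(40):
            q = random_protein(rng, 120)
            n_hit += bool(search_protein_vs_proteins(q, db, cutoff=1e-5, exhaustive=True))
        assert n_hit == 0

    def test_isoforms_collapse_to_gene_best_hit(self):
        rng = np.random.default_rng(3)
        db = self._db(rng, 10)
        q = db["p3"]["p3.1"]
        db["p3"]["p3.2"] = q[:60]  # weaker isoform of the same gene
        hits = search_protein_vs_proteins(q, db, cutoff=1.0)
        assert sum(1 for h in hits if h.subject_id == "p3") == 1

    def test_seeded_and_exhaustive_agree_on_clear_hits(self):
        rng = np.random.default_rng(4)
        db = self._db(rng, 40)
        for gene in ("p0", "p11", "p25"):
            q = db[gene][gene + ".1"]
            seeded = search_protein_vs_proteins(q, db, cutoff=1e-5)
            exhaustive = search_protein_vs_proteins(q, db, cutoff=1e-5, exhaustive=True)
            assert seeded[0].subject_id == exhaustive[0].subject_id == gene


class TestTranslatedSearch:
    def _back_translate(self, protein):
        table = {}
        for c in ("TTT", "TGG", "ATG", "AAA", "GAA", "GAT", "TGT", "CAT", "CCT", "GGT",
                  "GCT", "GTT", "CTT", "ATT", "TCT", "ACT", "TAT", "CAA", "AAT", "CGT",
                  "AGT", "AGG"):
            table.setdefault(str(Seq(c).translate()), c)
        return "".join(table[a] for a in protein)

    def test_exact_back_translation_hits_frame_plus_one(self):
        rng = np.random.default_rng(5)
        prot = random_protein(rng, 60)
        dna = self._back_translate(prot)
        hits = search_protein_vs_dna(prot, dna, cutoff=1e-6)
        assert hits and hits[0].frame == 1

    def test_reverse_complement_hits_negative_frame(self):
        rng = np.random.default_rng(6)
        prot = random_protein(rng, 60)
        dna = str(Seq(self._back_translate(prot)).reverse_complement())
        hits = search_protein_vs_dna(prot, dna, cutoff=1e-6)
        assert hits and hits[0].frame < 0

    def test_random_dna_never_hits_at_stringent_cutoff(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            prot = random_protein(rng, 80)
            dna = "".join("ACGT"[i] for i in rng.integers(0, 4, size=600))
            assert search_protein_vs_dna(prot, dna, cutoff=1e-6) == []

    def test_short_region_empty(self):
        assert search_protein_vs_dna("MKV", "AC", cutoff=1.0) == []


def _sim_bundle_pair(seed=21, **kw):
    defaults = dict(n_genes=60, f_scrambled=0.1, p_loss=0.0, p_denovo=0.05,
                    p_tandem_dup=0.0, n_inversions=0, p_denovo_target=0.0)
    defaults.update(kw)
    return simulate_pair(SimConfig(seed=seed, **defaults))


@pytest.fixture(scope="module")
def pair():
    return _sim_bundle_pair()


@pytest.fixture(scope="module")
def run(pair):
    blocks, _ = enumerate_blocks(pair.focal.order, pair.target.order, pair.orthology)
    index = TargetIndex(pair.target)
    outcomes = {}
    for g, bl in blocks.items():
        if bl:
            outcomes[g] = cascade_search(
                pair.focal.order[g], pair.focal.proteins[g], bl, index,
                cutoff=1e-3, record=True,
            )
    return outcomes


class TestCascade:
    def test_detectable_homologue_found_opposite(self, pair, run):
        for g, out in run.items():
            if pair.truth.origin[g] == "diverged_detectable":
                assert out.status == "found_opposite", g
                assert out.step_found == "proteome_opposite"

    def test_scrambled_genes_not_found(self, pair, run):
        scrambled = [g for g in run if pair.truth.origin[g] == "diverged_beyond_recognition"]
        assert scrambled, "fixture must place scrambled genes in micro-synteny"
        for g in scrambled:
            assert run[g].status == "not_found"

    def test_cutoff_monotonicity_of_outcomes(self, run):
        order = {"not_found": 0, "found_elsewhere": 1, "found_opposite": 1}
        for out in run.values():
            prev = 0
            for cutoff in (1e-10, 1e-6, 1e-3, 1e-1, 1.0):
                status, _ = outcome_at(out.step_evalues, cutoff)
                assert order[status] >= prev
                prev = order[status]

    def test_found_elsewhere_when_paralogue_exists(self):
        """Scrambled opposite but a detectable copy elsewhere -> found_elsewhere."""
        pair = _sim_bundle_pair(seed=33, f_scrambled=0.0)
        blocks, _ = enumerate_blocks(pair.focal.order, pair.target.order, pair.orthology)
        focal_gene = next(g for g, bl in blocks.items() if bl)
        bl = blocks[focal_gene]
        # scramble every opposite gene's protein; plant a detectable copy
        # of the focal protein far away in the target proteome
        rng = np.random.default_rng(0)
        target = pair.target
        for b in bl:
            for g in b.opposite:
                for pid, s in target.proteins[g.gene_id].items():
                    arr = np.frombuffer(s.encode(), np.uint8)
                    target.proteins[g.gene_id][pid] = arr[rng.permutation(arr.size)].tobytes().decode()
        target.proteins["planted"] = {"planted.p1": pair.focal.proteins[focal_gene][focal_gene + ".p1"]}
        # drop the genomic layer: the opposite CDS would otherwise still be
        # discoverable by the local translated step, which is not under test
        target.chromosomes = {}
        out = cascade_search(
            pair.focal.order[focal_gene], pair.focal.proteins[focal_gene], bl,
            TargetIndex(target), cutoff=1e-3,
        )
        assert out.status == "found_elsewhere"
        assert out.step_found == "proteome_wide"

    def test_local_genomic_step_finds_unannotated_opposite(self):
        """Opposite protein missing from the proteome but present in the DNA."""
        pair = _sim_bundle_pair(seed=34, f_scrambled=0.0)
        blocks, _ = enumerate_blocks(pair.focal.order, pair.target.order, pair.orthology)
        focal_gene = next(
            g for g, bl in blocks.items()
            if bl and all(o.gene_id in pair.target.proteins for b in bl for o in b.opposite)
        )
        bl = blocks[focal_gene]
        target = pair.target
        for b in bl:
            for g in b.opposite:
                target.proteins.pop(g.gene_id, None)
        out = cascade_search(
            pair.focal.order[focal_gene], pair.focal.proteins[focal_gene], bl,
            TargetIndex(target), cutoff=1e-3,
        )
        assert (out.status, out.step_found) == ("found_opposite", "local_genomic")


class TestReversedSearch:
    def test_proportion_monotone_in_cutoff_and_zero_limit(self):
        small = _sim_bundle_pair(seed=55, n_genes=40)
        props = [
            reversed_false_homology_search(
                small.focal.proteins, small.target, cutoff=c, exhaustive=True
            )
            for c in (1e-30, 1e-6, 1e-2, 1.0, 10.0)
        ]
        assert props[0] == 0.0
        assert all(a <= b for a, b in zip(props, props[1:]))

    def test_matches_analytic_false_positive_expectation(self):
        """P(any decoy hit at E<=c) should track 1 - exp(-c) within binomial error."""
        rng = np.random.default_rng(8)
        queries = {f"q{i}": {f"q{i}.p": random_protein(rng, 150)} for i in range(120)}
        decoys = {f"d{i}": {f"d{i}.p": random_protein(rng, 150)} for i in range(60)}
        bundle = GenomeBundle(species="decoy", order=None, proteins=decoys)
        cutoff = 1.0
        prop = reversed_false_homology_search(queries, bundle, cutoff=cutoff, exhaustive=True)
        expected = 1 - math.exp(-cutoff)
        se = math.sqrt(expected * (1 - expected) / len(queries))
        assert abs(prop - expected) < 4 * se


class TestBlastConcordance:
    def test_builtin_and_blast_agree_on_hit_no_hit(self):
        from synvergence.blast_adapter import blast_available, blastp_search

        if not blast_available():
            pytest.skip("BLAST+ binaries not on PATH")
        rng = np.random.default_rng(10)
        agree = 0
        total = 0
        for i in range(50):
            a = random_protein(rng, 150)
            if i % 2:
                b = list(a)
                hit_positions = rng.random(len(b)) < 0.3
                for j in np.nonzero(hit_positions)[0]:
                    b[j] = random_protein(rng, 1)
                b = "".join(b)  # ~70% identical: unambiguous hit
            else:
                b = random_protein(rng, 150)  # unrelated: unambiguous miss
            builtin = bool(
                search_protein_vs_proteins(a, {"s": {"s.p": b}}, cutoff=1e-5, exhaustive=True)
            )
            blast = bool(blastp_search({"q": a}, {"s": b}, cutoff=1e-5))
            total += 1
            agree += builtin == blast
        assert agree == total
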