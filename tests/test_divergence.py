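import math

import numpy as np
import pytest

from synvergence.divergence import (
    assign_phylostratum,
    fit_rate_vs_time,
    lineage_specific_candidates,
    lineage_strata,
    pairwise_estimate,
    rank_effect_size,
    trg_contribution,
)
from synvergence.genome_model import read_species_tree


def make_steps(n_found, n_not_found, cutoff=1e-3):
    """Recorded cascade step E-values: found via the proteome, or nowhere."""
    steps = {}
    for i in range(n_found):
        steps[f"f{i}"] = {
            "proteome_opposite": cutoff / 10,
            "proteome_wide": cutoff / 10,
            "genome_wide": math.inf,
        }
    for i in range(n_not_found):
        steps[f"n{i}"] = {
            "proteome_opposite": math.inf,
            "proteome_wide": math.inf,
            "genome_wide": math.inf,
        }
    return steps


class TestPairwiseEstimate:
    def test_d_equal_to_xn_gives_contribution_one(self):
        steps = make_steps(80, 20)
        flags = {f"g{i}": i < 100 for i in range(500)}  # X/n = 0.2 = d
        est = pairwise_estimate(steps, flags, 1e-3)
        assert est.d == pytest.approx(0.2)
        assert est.contribution == pytest.approx(1.0)

    def test_zero_d_gives_zero_contribution(self):
        est = pairwise_estimate(make_steps(50, 0), {f"g{i}": i < 10 for i in range(100)}, 1e-3)
        assert est.d == 0.0 and est.contribution == 0.0

    def test_scale_free_under_duplication(self):
        steps = make_steps(30, 10)
        flags = {f"g{i}": i < 25 for i in range(200)}
        est1 = pairwise_estimate(steps, flags, 1e-3)
        steps2 = {k + sfx: v for sfx in ("", "_copy") for k, v in steps.items()}
        flags2 = {k + sfx: v for sfx in ("", "_copy") for k, v in flags.items()}
        est2 = pairwise_estimate(steps2, flags2, 1e-3)
        assert (est1.d, est1.x_over_n, est1.contribution) == (
            est2.d, est2.x_over_n, est2.contribution,
        )

    def test_capped_with_warning_when_d_exceeds_xn(self, caplog):
        steps = make_steps(50, 50)
        flags = {f"g{i}": i < 10 for i in range(100)}
        with caplog.at_level("WARNING"):
            est = pairwise_estimate(steps, flags, 1e-3)
        assert est.contribution == 1.0 and est.capped
        assert any("capped" in r.message for r in caplog.records)

    def test_standard_errors_are_binomial(self):
        est = pairwise_estimate(make_steps(80, 20), {f"g{i}": i < 50 for i in range(400)}, 1e-3)
        assert est.se_d == pytest.approx(math.sqrt(0.2 * 0.8 / 100))
        assert est.se_xn == pytest.approx(math.sqrt(0.125 * 0.875 / 400))

    def test_local_step_excluded_from_d(self):
        steps = make_steps(10, 0)
        # found ONLY by the local translated search: counts as not found for d
        steps["local_only"] = {
            "proteome_opposite": math.inf,
            "local_genomic": 1e-8,
            "proteome_wide": math.inf,
            "genome_wide": math.inf,
        }
        est = pairwise_estimate(steps, {f"g{i}": False for i in range(50)}, 1e-3)
        assert est.synteny_not_found == 1

    def test_empty_synteny_rejected(self):
        with pytest.raises(ValueError, match="micro-synteny"):
            pairwise_estimate({}, {"g": False}, 1e-3)


class TestRateFit:
    def test_collinear_points_exact(self):
        pts = [(t, 0.01 + 0.02 * t) for t in (1, 2, 3, 4, 5)]
        fit = fit_rate_vs_time(pts)
        assert fit.slope == pytest.approx(0.02)
        assert fit.intercept == pytest.approx(0.01)
        assert fit.p_value < 1e-10
        assert fit.r_squared == pytest.approx(1.0)

    def test_requires_three_points(self):
        with pytest.raises(ValueError, match="3"):
            fit_rate_vs_time([(1, 0.1), (2, 0.2)])

    def test_null_p_values_uniform(self):
        """Binomial d draws with no time trend: slope-test p ~ U(0,1)."""
        from scipy import stats

        rng = np.random.default_rng(77)
        times = [5, 10, 20, 40, 80]
        pvals = []
        for _ in range(300):
            pts = [(t, rng.binomial(500, 0.1) / 500) for t in times]
            pvals.append(fit_rate_vs_time(pts).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def ladder(tmp_path_factory):
    p = tmp_path_factory.mktemp("tree") / "t.nwk"
    p.write_text("(((((focal:1,t1:1):1,t2:2):1,t3:3):1,t4:4):1,t5:5);")
    return read_species_tree(p, "focal", {f"t{i}": i for i in range(1, 6)})


class TestPhylostrata:
    def test_extremes(self, ladder):
        targets = [f"t{i}" for i in range(1, 6)]
        all_match = assign_phylostratum({sp: True for sp in targets}, ladder)
        none_match = assign_phylostratum({sp: False for sp in targets}, ladder)
        assert all_match.species == frozenset(targets)  # oldest stratum
        assert none_match.rank == 0 and none_match.species == frozenset()

    def test_matches_brute_force_farthest_leaf_scan(self, ladder):
        rng = np.random.default_rng(13)
        targets = [f"t{i}" for i in range(1, 6)]
        strata = lineage_strata(ladder, targets)
        for _ in range(200):
            flags = {sp: bool(rng.random() < 0.5) for sp in targets}
            got = assign_phylostratum(flags, ladder, strata)
            matched = [sp for sp, f in flags.items() if f]
            if not matched:
                assert got.rank == 0
            else:
                farthest = max(matched, key=lambda sp: ladder.divergence_times[sp])
                expected = next(s for s in strata if farthest in s.species)
                assert got == expected

    def test_missing_species_error(self, ladder):
        with pytest.raises(ValueError, match="t9"):
            assign_phylostratum({"t1": True, "t9": False}, ladder)


class TestTrgContribution:
    def _strata(self, ladder):
        return lineage_strata(ladder, [f"t{i}" for i in range(1, 6)])

    def test_no_trgs_gives_zero(self, ladder):
        strata = self._strata(ladder)
        oldest = strata[-1]
        gene_strata = {f"g{i}": oldest for i in range(10)}
        blocks = {"t5": {f"g{i}" for i in range(10)}}
        est = trg_contribution(strata[1], gene_strata, blocks)
        assert est.contribution == 0.0

    def test_saturation_gives_one(self, ladder):
        strata = self._strata(ladder)
        young = strata[1]  # {t1}
        # all genes are TRGs of the stratum and all have outside blocks
        gene_strata = {f"g{i}": young for i in range(10)}
        blocks = {"t4": {f"g{i}" for i in range(10)}}
        est = trg_contribution(young, gene_strata, blocks)
        assert est.d_phylo == 1.0 and est.contribution == 1.0

    def test_agrees_with_pairwise_on_two_species_fixture(self, tmp_path):
        """Single-stratum tree: the phylostratum estimator reduces to d/(X/n)."""
        p = tmp_path / "two.nwk"
        p.write_text("((focal:1,tA:1):1,tB:2);")
        tree = read_species_tree(p, "focal", {"tA": 1, "tB": 2})
        strata = lineage_strata(tree, ["tA", "tB"])
        young = strata[1]  # {tA}
        genes = [f"g{i}" for i in range(100)]
        # 20 genes restricted to {tA} (no match in tB), all in micro-synteny with tB
        gene_strata = {g: (young if i < 20 else strata[2]) for i, g in enumerate(genes)}
        blocks = {"tB": set(genes), "tA": set(genes)}
        est = trg_contribution(young, gene_strata, blocks)
        # pairwise analogue vs tB: d = 20/100, X/n = 20/100
        assert est.d_phylo == pytest.approx(0.2)
        assert est.trg_fraction == pytest.approx(0.2)
        assert est.contribution == pytest.approx(1.0)

    def test_undefined_without_outside_blocks(self, ladder):
        strata = self._strata(ladder)
        with pytest.raises(ValueError, match="outside"):
            trg_contribution(strata[-1], {"g": strata[0]}, {"t1": {"g"}})


class TestLineageCandidates:
    def test_fig_style_witnesses(self, ladder):
        match = {sp: {} for sp in ("t1", "t2", "t3", "t4", "t5")}
        # accepted: undetectable in non-sister t2 and t4, no match in t5
        undet = {"t2": {"gA"}, "t4": {"gA"}, "t1": set(), "t3": set(), "t5": set()}
        for sp in match:
            match[sp]["gA"] = sp in ("t1", "t3")
        got = lineage_specific_candidates(undet, match, ladder)
        assert [c.gene_id for c in got] == ["gA"]
        # the loss branch is the ancestor of focal..t4 on the ladder
        assert got[0].loss_branch_leaves == frozenset({"focal", "t1", "t2", "t3", "t4"})

    def test_sister_only_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(((focal:2,(t1:1,t2:1):1):1,t3:3):1,t4:4);")
        tree = read_species_tree(p, "focal", {"t1": 2, "t2": 2, "t3": 3, "t4": 4})
        undet = {"t1": {"gB"}, "t2": {"gB"}, "t3": set(), "t4": set()}
        match = {sp: {"gB": False} for sp in ("t1", "t2", "t3", "t4")}
        assert lineage_specific_candidates(undet, match, tree) == []

    def test_match_beyond_farthest_undetectable_rejected(self, ladder):
        undet = {"t2": {"gC"}, "t4": {"gC"}, "t1": set(), "t3": set(), "t5": set()}
        match = {sp: {"gC": sp == "t5"} for sp in ("t1", "t2", "t3", "t4", "t5")}
        assert lineage_specific_candidates(undet, match, ladder) == []

    def test_single_undetectable_rejected(self, ladder):
        undet = {"t2": {"gD"}, "t1": set(), "t3": set(), "t4": set(), "t5": set()}
        match = {sp: {"gD": False} for sp in undet}
        assert lineage_specific_candidates(undet, match, ladder) == []

    def test_invariant_to_input_order(self, ladder):
        undet = {"t4": {"gA"}, "t2": {"gA"}, "t5": set(), "t3": set(), "t1": set()}
        match = {sp: {"gA": False} for sp in undet}
        a = lineage_specific_candidates(undet, match, ladder)
        b = lineage_specific_candidates(dict(reversed(list(undet.items()))), match, ladder)
        assert a == b


class TestRankEffectSize:
    def test_identical_groups_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        es = rank_effect_size(x, x)
        assert abs(es.R) < 1e-9

    def test_complete_separation_reaches_maximal_z(self):
        a = list(range(100, 150))
        b = list(range(50))
        es = rank_effect_size(a, b)
        z_max = (50 * 50 / 2) / math.sqrt(50 * 50 * 101 / 12)
        assert es.Z == pytest.approx(z_max)
        assert es.W == 2500
        assert es.R == pytest.approx(z_max / math.sqrt(100))

    def test_shift_recovers_expected_effect(self):
        rng = np.random.default_rng(2)
        rs = []
        for _ in range(100)[:50]:
            a = rng.normal(0.5, 1, 80)
            b = rng.normal(0.0, 1, 80)
            rs.append(rank_effect_size(a, b).R)
        # theoretical R for a 0.5 sigma shift: Z/sqrt(N) with
        # P(a>b)=Phi(0.5/sqrt(2))~0.638
        assert 0.15 < np.mean(rs) < 0.45
        assert all(r > 0 for r in rs[:10])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_effect_size([], [1.0])
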