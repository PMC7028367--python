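"""Headline estimators: rates and contributions of divergence beyond recognition.

Given cascade outcomes, this module computes, per focal-target pair, the
proportion *d* of micro-synteny genes with no detectable similarity, the
genome-wide proportion X/n of focal genes with no similarity anywhere in the
target, and their ratio d/(X/n) — the estimated contribution of divergence
beyond recognition to the pool of genes without similarity.  It also fits
the rate of divergence-beyond-recognition against divergence time, assigns
phylostrata from per-target match flags, extrapolates the contribution to
taxonomically restricted genes (TRGs), screens for lineage-specific
divergence candidates, and provides the rank-test effect size used to
compare evolutionary-rate covariates inside vs outside micro-synteny.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_model import SpeciesTree
from .simsearch import GENOME_STEP_CUTOFF

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseEstimate",
    "RateFit",
    "Phylostratum",
    "TrgEstimate",
    "LineageCandidate",
    "EffectSize",
    "pairwise_estimate",
    "fit_rate_vs_time",
    "assign_phylostratum",
    "trg_contribution",
    "lineage_specific_candidates",
    "rank_effect_size",
    "proportion_se",
]


def proportion_se(p: float, count: int) -> float:
    """Standard error of a proportion: sqrt(p(1-p)/count)."""
    if count <= 0:
        return math.nan
    return math.sqrt(p * (1 - p) / count)


@dataclass
class PairwiseEstimate:
    """The (n, X, d) triple and derived contribution for one genome pair."""

    focal: str
    target: str
    n: int
    X: int
    synteny_total: int
    synteny_not_found: int
    divergence_time: float | None = None

    def __post_init__(self) -> None:
        if self.synteny_total <= 0:
            raise ValueError("estimate undefined: no genes in micro-synteny")
        if self.n <= 0:
            raise ValueError("estimate undefined: no focal genes examined")
        self.d = self.synteny_not_found / self.synteny_total
        self.x_over_n = self.X / self.n
        self.capped = False
        if self.x_over_n == 0:
            self.contribution = 0.0
        else:
            raw = self.d / self.x_over_n
            if raw > 1:
                logger.warning(
                    "%s-%s: d (%.4f) exceeds X/n (%.4f); contribution capped at 1",
                    self.focal, self.target, self.d, self.x_over_n,
                )
                self.capped = True
            self.contribution = min(1.0, raw)
        self.se_d = proportion_se(self.d, self.synteny_total)
        self.se_xn = proportion_se(self.x_over_n, self.n)


def _found_excluding_local(step_evalues: Mapping[str, float], cutoff: float) -> bool:
    """Detected by the searches that also define X (local translated step excluded)."""
    if step_evalues.get("proteome_opposite", math.inf) <= cutoff:
        return True
    if step_evalues.get("proteome_wide", math.inf) <= cutoff:
        return True
    if step_evalues.get("genome_wide", math.inf) <= GENOME_STEP_CUTOFF:
        return True
    # a decisive "not found" needs the genome-wide steps to have actually run
    missing = {"proteome_wide", "genome_wide"} - set(step_evalues)
    if missing:
        raise ValueError(
            "cascade outcomes incomplete for a not-found decision "
            f"(missing {sorted(missing)}); re-run cascade_search(record=True)"
        )
    return False


def pairwise_estimate(
    step_evalues: Mapping[str, Mapping[str, float]],
    no_similarity: Mapping[str, bool],
    cutoff: float,
    focal: str = "focal",
    target: str = "target",
    divergence_time: float | None = None,
) -> PairwiseEstimate:
    """Build the pairwise estimate from recorded cascade step E-values.

    ``step_evalues``: per micro-synteny focal gene, best E-value per cascade
    step (record mode).  ``no_similarity``: for every focal gene examined,
    True when the gene has no match in the whole target proteome (at
    ``cutoff``) nor in the translated genome (at the fixed stringent
    cutoff) — the X flags.  d is computed over the same search set as X,
    i.e. the local translated search of the opposite region is excluded.
    """
    n = len(no_similarity)
    X = sum(1 for v in no_similarity.values() if v)
    synteny_total = len(step_evalues)
    not_found = sum(
        1 for ev in step_evalues.values() if not _found_excluding_local(ev, cutoff)
    )
    return PairwiseEstimate(
        focal=focal,
        target=target,
        n=n,
        X=X,
        synteny_total=synteny_total,
        synteny_not_found=not_found,
        divergence_time=divergence_time,
    )


@dataclass
class RateFit:
    slope: float
    intercept: float
    p_value: float
    slope_se: float
    slope_ci: tuple[float, float]
    r_squared: float
    n: int
    slope_through_origin: float


def fit_rate_vs_time(points: Sequence[tuple[float, float]]) -> RateFit:
    """OLS fit of d against divergence time (two-sided slope test).

    Also reports the zero-intercept slope, since whether the fit should be
    forced through the origin is a modelling choice left open.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 pairs to fit a rate")
    import statsmodels.api as sm

    t = np.asarray([p[0] for p in points], dtype=float)
    d = np.asarray([p[1] for p in points], dtype=float)
    model = sm.OLS(d, sm.add_constant(t)).fit()
    ci = model.conf_int(alpha=0.05)
    through_origin = sm.OLS(d, t.reshape(-1, 1)).fit()
    return RateFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        slope_se=float(model.bse[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        r_squared=float(model.rsquared),
        n=len(points),
        slope_through_origin=float(through_origin.params[0]),
    )


@dataclass(frozen=True)
class Phylostratum:
    """An ancestral branch of the focal lineage.

    ``rank`` counts by age: 0 is the youngest (focal-specific) stratum;
    ``species`` is the set of target species inside the stratum's subtree.
    """

    branch_id: str
    species: frozenset[str]
    rank: int


def lineage_strata(tree: SpeciesTree, targets: Sequence[str]) -> list[Phylostratum]:
    """Nested phylostrata along the focal lineage, youngest first.

    Stratum 0 is focal-specific (no targets); the deepest stratum contains
    every target.
    """
    tree.require_species(targets)
    sets = [set()] + tree.focal_lineage_strata(targets)
    return [
        Phylostratum(branch_id=f"ps{rank}", species=frozenset(s), rank=rank)
        for rank, s in enumerate(sets)
    ]


def assign_phylostratum(
    match_flags: Mapping[str, bool],
    tree: SpeciesTree,
    strata: Sequence[Phylostratum] | None = None,
) -> Phylostratum:
    """The phylostratum implied by per-target-species match flags.

    The assigned stratum is the youngest one whose subtree contains every
    species with a sequence-similarity match — equivalently, the stratum
    containing the phylogenetically farthest matching species.  A gene
    matching nothing is focal-specific (rank 0).
    """
    targets = sorted(match_flags)
    if strata is None:
        strata = lineage_strata(tree, targets)
    matched = {sp for sp, flag in match_flags.items() if flag}
    for stratum in strata:
        if matched <= stratum.species:
            return stratum
    raise ValueError("no stratum contains all matched species; tree/targets mismatch")


@dataclass
class TrgEstimate:
    """Phylostratum-based contribution of divergence to TRGs."""

    stratum: Phylostratum
    trg_total: int
    trg_with_outside_block: int
    genes_with_outside_block: int
    n_genes: int

    def __post_init__(self) -> None:
        if self.genes_with_outside_block == 0:
            raise ValueError("estimate undefined: no genes with outside-stratum blocks")
        if self.trg_total == 0:
            self.d_phylo = 0.0
            self.trg_fraction = 0.0
            self.contribution = 0.0
            return
        self.d_phylo = self.trg_with_outside_block / self.genes_with_outside_block
        self.trg_fraction = self.trg_total / self.n_genes
        if self.trg_fraction == 0:
            self.contribution = 0.0
        else:
            self.contribution = min(1.0, self.d_phylo / self.trg_fraction)


def trg_contribution(
    stratum: Phylostratum,
    gene_strata: Mapping[str, Phylostratum],
    blocks_per_species: Mapping[str, set[str]],
    n_genes: int | None = None,
) -> TrgEstimate:
    """Contribution of divergence beyond recognition to one stratum's TRGs.

    ``gene_strata``: phylostratum assigned to each focal gene from its match
    flags.  ``blocks_per_species``: per target species, the focal genes with
    at least one micro-synteny block (a predicted homologue) there.  TRGs of
    the stratum are genes whose assigned stratum is no older; the numerator
    counts those with a predicted homologue outside the stratum, the
    denominator all genes with a predicted homologue outside the stratum,
    and the ratio is compared with the overall TRG fraction.
    """
    n = n_genes if n_genes is not None else len(gene_strata)
    outside_species = {sp for sp in blocks_per_species if sp not in stratum.species}
    outside_block_genes: set[str] = set()
    for sp in outside_species:
        outside_block_genes |= blocks_per_species[sp]
    outside_block_genes &= set(gene_strata)
    trgs = {g for g, s in gene_strata.items() if s.rank <= stratum.rank}
    return TrgEstimate(
        stratum=stratum,
        trg_total=len(trgs),
        trg_with_outside_block=len(trgs & outside_block_genes),
        genes_with_outside_block=len(outside_block_genes),
        n_genes=n,
    )


@dataclass(frozen=True)
class LineageCandidate:
    gene_id: str
    undetectable_species: frozenset[str]
    loss_branch_leaves: frozenset[str]
    ambiguous: bool = False


def lineage_specific_candidates(
    undetectable: Mapping[str, set[str]],
    match_flags: Mapping[str, Mapping[str, bool]],
    tree: SpeciesTree,
) -> list[LineageCandidate]:
    """Focal genes whose similarity was plausibly lost on one ancestral branch.

    ``undetectable``: per target species, focal genes in conserved
    micro-synteny there with no detectable similarity (undetectable
    homologues).  ``match_flags``: per target species, per focal gene,
    whether any sequence match exists.  A candidate needs undetectable
    homologues in at least two target species that do not form a clade of
    the target-species tree, and no match in any target more distant than
    the farthest of those species.  The inferred branch of similarity loss
    is the ancestor of the focal species and the undetectable-homologue
    species (parsimony).  Output is sorted by gene id and invariant to
    input ordering.
    """
    times = tree.divergence_times
    tree.require_species(undetectable)
    genes: set[str] = set()
    for s in undetectable.values():
        genes |= set(s)
    out: list[LineageCandidate] = []
    for gene in sorted(genes):
        undet_sp = {sp for sp, s in undetectable.items() if gene in s}
        if len(undet_sp) < 2:
            continue
        if tree.is_clade(undet_sp):
            continue  # sister-only signal: one ordinary loss explains it
        farthest = max(times[sp] for sp in undet_sp)
        more_distant = [sp for sp in match_flags if times.get(sp, 0.0) > farthest]
        if any(match_flags[sp].get(gene, False) for sp in more_distant):
            continue
        mrca = tree.tree.mrca(taxon_labels=sorted(undet_sp | {tree.focal}))
        leaves = frozenset(l.taxon.label for l in mrca.leaf_iter())
        ambiguous = len(mrca.child_nodes()) > 2
        out.append(
            LineageCandidate(
                gene_id=gene,
                undetectable_species=frozenset(undet_sp),
                loss_branch_leaves=leaves,
                ambiguous=ambiguous,
            )
        )
    return out


@dataclass(frozen=True)
class EffectSize:
    W: float
    Z: float
    N: int
    R: float
    p_value: float


def rank_effect_size(
    group_a: Sequence[float], group_b: Sequence[float]
) -> EffectSize:
    """Two-sided rank-sum test with Rosenthal's effect size R = Z / sqrt(N).

    Z is the normal approximation of the Mann-Whitney U statistic (tie
    corrected), signed so that Z > 0 when group A tends to be larger.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    n1, n2 = a.size, b.size
    n = n1 + n2
    mu = n1 * n2 / 2.0
    combined = np.concatenate([a, b])
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = 0.0 if sigma2 <= 0 else (float(res.statistic) - mu) / math.sqrt(sigma2)
    return EffectSize(
        W=float(res.statistic),
        Z=z,
        N=n,
        R=z / math.sqrt(n),
        p_value=float(res.pvalue),
    )
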