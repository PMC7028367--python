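"""End-to-end orchestration of the synteny / search / calibration pipeline.

``run_pair`` takes one focal-target genome pair from gene orders to a
:class:`~synvergence.divergence.PairwiseEstimate`; ``run_all`` runs every
target, assigns phylostrata, extrapolates the TRG contribution per stratum
and screens lineage-specific divergence candidates.  Every number in the
summary tables is re-derivable from the step-level TSVs; ``verify_outputs``
recomputes and compares them.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import calibration as cal
from . import divergence as dv
from .genome_model import GenomeBundle, OrthologyMap, SpeciesTree
from .simsearch import (
    GENOME_STEP_CUTOFF,
    TargetIndex,
    cascade_search,
    genome_wide_best_evalues,
    outcome_at,
    reversed_best_evalues,
)
from .synteny import SyntenyBlock, enumerate_blocks, write_blocks_tsv

logger = logging.getLogger(__name__)

__all__ = ["PairResult", "run_pair", "run_all", "RunAllResult", "write_pair_outputs", "verify_outputs"]

#: focal proteome size above which the reversed decoy search switches from
#: exhaustive Smith-Waterman to the seeded heuristic
_REVERSED_EXHAUSTIVE_LIMIT = 400


@dataclass
class PairResult:
    focal_species: str
    target_species: str
    blocks: dict[str, list[SyntenyBlock]]
    n_with_block: int
    step_evalues: dict[str, dict[str, float]]
    no_similarity: dict[str, bool]
    cutoff_used: float
    estimate: dv.PairwiseEstimate
    curve: cal.CutoffCurve | None = None
    phylostrat_cutoff: float | None = None
    mcc_cutoff: float | None = None
    divergence_time: float | None = None

    def outcomes(self) -> dict[str, tuple[str, str]]:
        """(status, step_found) per micro-synteny focal gene at cutoff_used."""
        return {
            g: outcome_at(ev, self.cutoff_used) for g, ev in self.step_evalues.items()
        }

    def undetectable_genes(self) -> set[str]:
        return {g for g, (status, _) in self.outcomes().items() if status == "not_found"}

    def match_flags(self) -> dict[str, bool]:
        """Per focal gene: any sequence similarity in the target at all."""
        return {g: not flag for g, flag in self.no_similarity.items()}


def run_pair(
    focal: GenomeBundle,
    target: GenomeBundle,
    orthology: OrthologyMap,
    *,
    stringency: str = "standard",
    flank: int = 2000,
    cutoff: float | str = "auto",
    cutoffs: Sequence[float] = cal.DEFAULT_CUTOFF_GRID,
    compute_curve: bool = True,
    divergence_time: float | None = None,
    overlap_threshold: float = 0.8,
) -> PairResult:
    """Run synteny detection, the search cascade and estimation for one pair.

    With ``cutoff="auto"`` the phylostratigraphy-optimal cutoff from the
    calibration curve is used for all downstream counts; a numeric cutoff
    skips curve building unless ``compute_curve`` is set.  Deterministic:
    no randomness enters after the inputs.
    """
    blocks, n_with = enumerate_blocks(
        focal.order, target.order, orthology, stringency, overlap_threshold
    )
    index = TargetIndex(target)
    fixed_cutoff = None if cutoff == "auto" else float(cutoff)
    if fixed_cutoff is None and not compute_curve:
        raise ValueError("cutoff='auto' requires compute_curve=True")
    # record-mode cascade; when the cutoff is known in advance and no curve
    # is wanted, later steps may stop early / be skipped once one step hits
    stop_at = None if compute_curve else fixed_cutoff
    step_evalues: dict[str, dict[str, float]] = {}
    for gene_id in sorted(blocks):
        if not blocks[gene_id]:
            continue
        gene = focal.order[gene_id]
        proteins = focal.proteins.get(gene_id)
        if not proteins:
            logger.warning("focal gene %s has no protein sequence; skipped", gene_id)
            continue
        out = cascade_search(
            gene,
            proteins,
            blocks[gene_id],
            index,
            cutoff=fixed_cutoff if fixed_cutoff is not None else 1.0,
            flank=flank,
            record=True,
            stop_at=stop_at,
            skip_local=not compute_curve,
        )
        step_evalues[gene_id] = out.step_evalues

    curve = None
    phylo = mcc_cut = None
    if compute_curve and step_evalues:
        exhaustive = len(focal.proteins) <= _REVERSED_EXHAUSTIVE_LIMIT
        rev = reversed_best_evalues(
            focal.proteins,
            target,
            {g: blocks[g] for g in step_evalues},
            flank=flank,
            exhaustive=exhaustive,
        )
        curve = cal.build_curves(step_evalues, rev, cutoffs, divergence_time)
        try:
            phylo = cal.phylostrat_optimal_evalue(curve)
        except ValueError:
            logger.warning("no cutoff satisfies the false-homology cap for %s", target.species)
        mcc_cut = cal.mcc_optimal_evalue(curve)
    cutoff_used = fixed_cutoff if fixed_cutoff is not None else phylo
    if cutoff_used is None:
        raise ValueError(
            f"no usable cutoff for pair {focal.species}-{target.species}"
        )

    # genome-wide no-similarity flags (X): proteome at the pair cutoff,
    # translated genome at the fixed stringent cutoff
    no_similarity: dict[str, bool] = {}
    for gene_id in sorted(focal.proteins):
        proteins = focal.proteins[gene_id]
        e_prot, e_gen = genome_wide_best_evalues(
            proteins,
            index,
            proteome_stop_at=cutoff_used,
            skip_genome_if_proteome_below=cutoff_used,
        )
        no_similarity[gene_id] = not (
            e_prot <= cutoff_used or e_gen <= GENOME_STEP_CUTOFF
        )

    estimate = dv.pairwise_estimate(
        step_evalues,
        no_similarity,
        cutoff_used,
        focal=focal.species,
        target=target.species,
        divergence_time=divergence_time,
    )
    return PairResult(
        focal_species=focal.species,
        target_species=target.species,
        blocks=blocks,
        n_with_block=n_with,
        step_evalues=step_evalues,
        no_similarity=no_similarity,
        cutoff_used=cutoff_used,
        estimate=estimate,
        curve=curve,
        phylostrat_cutoff=phylo,
        mcc_cutoff=mcc_cut,
        divergence_time=divergence_time,
    )


@dataclass
class RunAllResult:
    pairs: dict[str, PairResult]  # keyed by target species
    strata: list[dv.Phylostratum]
    gene_strata: dict[str, dv.Phylostratum]
    trg_estimates: list[dv.TrgEstimate]
    rate_fit: dv.RateFit | None
    candidates: list[dv.LineageCandidate]
    note: str = ""


def run_all(
    focal: GenomeBundle,
    targets: Sequence[GenomeBundle],
    orthology: OrthologyMap,
    tree: SpeciesTree | None = None,
    **pair_kwargs,
) -> RunAllResult:
    """Run every focal-target pair plus the phylogeny-based analyses.

    Targets are processed (and reported) in ascending time since divergence.
    With fewer than two targets the phylostratum table is empty.
    """
    names = [t.species for t in targets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate target species")
    if focal.species in names:
        raise ValueError("focal species listed among targets")
    times = dict(tree.divergence_times) if tree is not None else {}
    if tree is not None:
        tree.require_species(names)
    ordered = sorted(targets, key=lambda t: (times.get(t.species, math.inf), t.species))

    pairs: dict[str, PairResult] = {}
    for t in ordered:
        pairs[t.species] = run_pair(
            focal,
            t,
            orthology,
            divergence_time=times.get(t.species),
            **pair_kwargs,
        )

    note = ""
    strata: list[dv.Phylostratum] = []
    gene_strata: dict[str, dv.Phylostratum] = {}
    trg_estimates: list[dv.TrgEstimate] = []
    candidates: list[dv.LineageCandidate] = []
    if tree is not None and len(ordered) >= 2:
        strata = dv.lineage_strata(tree, names)
        all_genes = sorted(focal.proteins)
        flags_by_gene = {
            g: {sp: pairs[sp].match_flags().get(g, False) for sp in pairs}
            for g in all_genes
        }
        for g in all_genes:
            gene_strata[g] = dv.assign_phylostratum(flags_by_gene[g], tree, strata)
        blocks_per_species = {
            sp: {g for g, bl in pr.blocks.items() if bl} for sp, pr in pairs.items()
        }
        for stratum in strata[:-1]:  # the oldest stratum has no outside species
            try:
                trg_estimates.append(
                    dv.trg_contribution(stratum, gene_strata, blocks_per_species)
                )
            except ValueError:
                logger.warning("stratum %s: no outside-stratum blocks", stratum.branch_id)
        undet = {sp: pr.undetectable_genes() for sp, pr in pairs.items()}
        match_by_species = {sp: pairs[sp].match_flags() for sp in pairs}
        candidates = dv.lineage_specific_candidates(undet, match_by_species, tree)
    elif len(ordered) < 2:
        note = "phylostratum analysis skipped: needs at least two target species"

    rate_fit = None
    points = [
        (pr.divergence_time, pr.estimate.d)
        for pr in pairs.values()
        if pr.divergence_time is not None
    ]
    if len(points) >= 3:
        rate_fit = dv.fit_rate_vs_time(points)

    return RunAllResult(
        pairs=pairs,
        strata=strata,
        gene_strata=gene_strata,
        trg_estimates=trg_estimates,
        rate_fit=rate_fit,
        candidates=candidates,
        note=note,
    )


# ---------------------------------------------------------------------------
# tabular outputs


_CASCADE_COLS = (
    "focal_gene",
    "target_species",
    "status",
    "step_found",
    "e_proteome_opposite",
    "e_local_genomic",
    "e_proteome_wide",
    "e_genome_wide",
    "no_similarity",
    "cutoff_used",
)

#: summary columns follow the conventional source-data vocabulary
_SUMMARY_COLS = (
    "target",
    "found opposite",
    "found elsewhere",
    "not found (and in micro-synteny)",
    "total in micro-synteny",
    "not found and outside micro-synteny",
    "total genes checked",
    "div. time",
    "Phylostrat. E-value",
    "general E-value",
    "d",
    "X",
    "X/n",
    "contribution",
    "se_d",
    "se_Xn",
)


def _fmt_e(e: float) -> str:
    return "inf" if math.isinf(e) else f"{e:.6g}"


def summary_row(pr: PairResult) -> dict[str, str]:
    outcomes = pr.outcomes()
    n_opp = sum(1 for s, _ in outcomes.values() if s == "found_opposite")
    n_else = sum(1 for s, _ in outcomes.values() if s == "found_elsewhere")
    n_nf = sum(1 for s, _ in outcomes.values() if s == "not_found")
    est = pr.estimate
    nf_outside = sum(
        1 for g, flag in pr.no_similarity.items() if flag and g not in pr.step_evalues
    )
    return {
        "target": pr.target_species,
        "found opposite": str(n_opp),
        "found elsewhere": str(n_else),
        "not found (and in micro-synteny)": str(n_nf),
        "total in micro-synteny": str(len(pr.step_evalues)),
        "not found and outside micro-synteny": str(nf_outside),
        "total genes checked": str(est.n),
        "div. time": "" if pr.divergence_time is None else f"{pr.divergence_time:g}",
        "Phylostrat. E-value": "" if pr.phylostrat_cutoff is None else f"{pr.phylostrat_cutoff:g}",
        "general E-value": "" if pr.mcc_cutoff is None else f"{pr.mcc_cutoff:g}",
        "d": f"{est.d:.6g}",
        "X": str(est.X),
        "X/n": f"{est.x_over_n:.6g}",
        "contribution": f"{est.contribution:.6g}",
        "se_d": f"{est.se_d:.6g}",
        "se_Xn": f"{est.se_xn:.6g}",
    }


def write_pair_outputs(pr: PairResult, outdir: str | Path) -> dict[str, Path]:
    """Write blocks, cascade, curve and summary TSVs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{pr.focal_species}__{pr.target_species}"
    paths: dict[str, Path] = {}

    p = outdir / f"{tag}.blocks.tsv"
    write_blocks_tsv([b for bl in pr.blocks.values() for b in bl], p)
    paths["blocks"] = p

    p = outdir / f"{tag}.cascade.tsv"
    with open(p, "w") as fh:
        fh.write("\t".join(_CASCADE_COLS) + "\n")
        for g in sorted(pr.step_evalues):
            ev = pr.step_evalues[g]
            status, step = outcome_at(ev, pr.cutoff_used)
            fh.write(
                "\t".join(
                    [
                        g,
                        pr.target_species,
                        status,
                        step,
                        _fmt_e(ev.get("proteome_opposite", math.inf)),
                        _fmt_e(ev.get("local_genomic", math.inf)),
                        _fmt_e(ev.get("proteome_wide", math.inf)),
                        _fmt_e(ev.get("genome_wide", math.inf)),
                        str(int(pr.no_similarity.get(g, False))),
                        f"{pr.cutoff_used:g}",
                    ]
                )
                + "\n"
            )
    paths["cascade"] = p

    p = outdir / f"{tag}.flags.tsv"
    with open(p, "w") as fh:
        fh.write("focal_gene\tno_similarity\tin_micro_synteny\n")
        for g in sorted(pr.no_similarity):
            fh.write(
                f"{g}\t{int(pr.no_similarity[g])}\t{int(g in pr.step_evalues)}\n"
            )
    paths["flags"] = p

    if pr.curve is not None:
        p = outdir / f"{tag}.curve.tsv"
        cal.write_curve_tsv(pr.curve, p)
        paths["curve"] = p

    p = outdir / f"{tag}.summary.tsv"
    row = summary_row(pr)
    with open(p, "w") as fh:
        fh.write("\t".join(_SUMMARY_COLS) + "\n")
        fh.write("\t".join(row[c] for c in _SUMMARY_COLS) + "\n")
    paths["summary"] = p

    manifest = {
        "focal": pr.focal_species,
        "target": pr.target_species,
        "cutoff_used": pr.cutoff_used,
        "n_with_block": pr.n_with_block,
        "outputs": {k: v.name for k, v in paths.items()},
    }
    mp = outdir / f"{tag}.manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mp
    return paths


def verify_outputs(outdir: str | Path, tag: str) -> list[str]:
    """Recompute every summary number from the step-level TSVs.

    Returns a list of discrepancy descriptions (empty means verified).
    """
    outdir = Path(outdir)
    discrepancies: list[str] = []
    cascade_path = outdir / f"{tag}.cascade.tsv"
    flags_path = outdir / f"{tag}.flags.tsv"
    summary_path = outdir / f"{tag}.summary.tsv"
    rows = _read_tsv(cascade_path)
    flags = _read_tsv(flags_path)
    summary = _read_tsv(summary_path)[0]
    cutoff = float(summary["general E-value"] or summary["Phylostrat. E-value"] or rows[0]["cutoff_used"]) if rows else 0.0
    cutoff = float(rows[0]["cutoff_used"]) if rows else cutoff

    def _e(s: str) -> float:
        return math.inf if s == "inf" else float(s)

    counts = {"found_opposite": 0, "found_elsewhere": 0, "not_found": 0}
    d_not_found = 0
    for r in rows:
        ev = {
            "proteome_opposite": _e(r["e_proteome_opposite"]),
            "local_genomic": _e(r["e_local_genomic"]),
            "proteome_wide": _e(r["e_proteome_wide"]),
            "genome_wide": _e(r["e_genome_wide"]),
        }
        status, step = outcome_at(ev, cutoff)
        if status != r["status"]:
            discrepancies.append(f"{r['focal_gene']}: status {r['status']} != recomputed {status}")
        counts[status] += 1
        found_d = (
            ev["proteome_opposite"] <= cutoff
            or ev["proteome_wide"] <= cutoff
            or ev["genome_wide"] <= GENOME_STEP_CUTOFF
        )
        if not found_d:
            d_not_found += 1

    n = len(flags)
    X = sum(1 for r in flags if r["no_similarity"] == "1")
    nf_outside = sum(
        1 for r in flags if r["no_similarity"] == "1" and r["in_micro_synteny"] == "0"
    )
    checks = {
        "found opposite": counts["found_opposite"],
        "found elsewhere": counts["found_elsewhere"],
        "not found (and in micro-synteny)": counts["not_found"],
        "total in micro-synteny": len(rows),
        "not found and outside micro-synteny": nf_outside,
        "total genes checked": n,
        "X": X,
    }
    for col, value in checks.items():
        if int(summary[col]) != value:
            discrepancies.append(f"summary {col}={summary[col]} != recomputed {value}")
    if rows:
        # compare at the precision the summary table prints
        d = d_not_found / len(rows)
        if f"{d:.6g}" != summary["d"]:
            discrepancies.append(f"summary d={summary['d']} != recomputed {d:.6g}")
        xn = X / n if n else 0.0
        contribution = min(1.0, d / xn) if xn > 0 else 0.0
        if f"{contribution:.6g}" != summary["contribution"]:
            discrepancies.append(
                f"summary contribution={summary['contribution']} != recomputed {contribution:.6g}"
            )
    return discrepancies


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [dict(zip(header, l.rstrip("\n").split("\t"))) for l in fh if l.strip()]
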