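"""E-value cutoff calibration against reversed-proteome decoys.

For one focal-target pair, undetectable homologies (micro-synteny genes with
no significant match) fall as the E-value cutoff is relaxed, while false
homologies (matches to the reversed target proteome, which cannot be real)
rise.  Two selection rules pick an operating point on that trade-off:

* phylostratigraphy-optimal: the highest cutoff keeping the false-homology
  proportion strictly under a cap (default 5%) — sensitivity-first;
* general-purpose optimal: the cutoff maximizing the Matthews correlation
  coefficient, treating undetectable homologies as false negatives and
  reversed matches as false positives, with ties (at 3-decimal rounding)
  resolved toward the higher cutoff.

The final whole-genome translated step runs at its own fixed cutoff and is
excluded from this optimisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .simsearch import outcome_at

__all__ = [
    "DEFAULT_CUTOFF_GRID",
    "CutoffCurve",
    "ConfusionCounts",
    "build_curves",
    "phylostrat_optimal_evalue",
    "mcc",
    "mcc_optimal_evalue",
    "write_curve_tsv",
]

#: Default E-value grid; the classic per-pair optima (1e-2, 1e-3, 1e-4) are
#: all on it.
DEFAULT_CUTOFF_GRID: tuple[float, ...] = (
    1e-20, 1e-15, 1e-10, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0,
)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class CutoffCurve:
    """Undetectable / false homology counts across an E-value grid."""

    cutoffs: tuple[float, ...]
    total_in_synteny: int
    focal_proteome_size: int
    not_found: tuple[int, ...]
    found_reversed: tuple[int, ...]
    divergence_time: float | None = None

    def __post_init__(self) -> None:
        if self.total_in_synteny <= 0:
            raise ValueError(
                "curve undefined: no focal genes in conserved micro-synteny"
            )
        if list(self.cutoffs) != sorted(self.cutoffs):
            raise ValueError("cutoffs must be ascending")

    @property
    def undetectable_proportion(self) -> tuple[float, ...]:
        return tuple(x / self.total_in_synteny for x in self.not_found)

    @property
    def false_proportion(self) -> tuple[float, ...]:
        return tuple(x / self.focal_proteome_size for x in self.found_reversed)

    def confusion(self, cutoff: float) -> ConfusionCounts:
        """Confusion counts at one grid cutoff.

        TP: micro-synteny homologies detected by sequence; FN: undetectable;
        FP: focal proteins matching the reversed target; TN: the rest of the
        focal proteome in the reversed search.
        """
        i = self.cutoffs.index(cutoff)
        fn = self.not_found[i]
        fp = self.found_reversed[i]
        return ConfusionCounts(
            TP=self.total_in_synteny - fn,
            FN=fn,
            FP=fp,
            TN=self.focal_proteome_size - fp,
        )


def build_curves(
    step_evalues: Mapping[str, Mapping[str, float]],
    reversed_evalues: Mapping[str, float],
    cutoffs: Sequence[float] = DEFAULT_CUTOFF_GRID,
    divergence_time: float | None = None,
) -> CutoffCurve:
    """Build the cutoff curve for one focal-target pair.

    ``step_evalues``: per micro-synteny focal gene, the best E-value recorded
    at each cascade step (the genome-wide step keeps its fixed cutoff when
    outcomes are re-derived).  ``reversed_evalues``: best E-value of every
    focal proteome gene against the reversed target.
    """
    cutoffs = tuple(sorted(cutoffs))
    if not step_evalues:
        raise ValueError("curve undefined: no micro-synteny genes supplied")
    not_found = []
    found_rev = []
    for c in cutoffs:
        nf = sum(
            1 for ev in step_evalues.values() if outcome_at(dict(ev), c)[0] == "not_found"
        )
        fr = sum(1 for e in reversed_evalues.values() if e <= c)
        not_found.append(nf)
        found_rev.append(fr)
    return CutoffCurve(
        cutoffs=cutoffs,
        total_in_synteny=len(step_evalues),
        focal_proteome_size=max(1, len(reversed_evalues)),
        not_found=tuple(not_found),
        found_reversed=tuple(found_rev),
        divergence_time=divergence_time,
    )


def phylostrat_optimal_evalue(curve: CutoffCurve, cap: float = 0.05) -> float:
    """Highest grid cutoff whose false-homology proportion is strictly < cap."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    ok = [c for c, fp in zip(curve.cutoffs, curve.false_proportion) if fp < cap]
    if not ok:
        raise ValueError(
            f"no grid cutoff keeps false homologies under {cap}; try a finer grid"
        )
    return max(ok)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 by convention on zero margins."""
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)


def mcc_optimal_evalue(curve: CutoffCurve, decimals: int = 3) -> float:
    """Grid cutoff maximizing MCC, rounded; ties go to the higher cutoff."""
    best_cut = None
    best_mcc = -math.inf
    for c in curve.cutoffs:  # ascending, so >= keeps the larger tied cutoff
        m = round(mcc(curve.confusion(c)), decimals)
        if m >= best_mcc:
            best_mcc = m
            best_cut = c
    return best_cut


def write_curve_tsv(curve: CutoffCurve, path: str | Path) -> None:
    """Export with the conventional column names: total, not_found, found, div."""
    div = "" if curve.divergence_time is None else f"{curve.divergence_time:g}"
    with open(path, "w") as fh:
        fh.write("evalue\ttotal\tnot_found\tfound\tdiv\n")
        for c, nf, fr in zip(curve.cutoffs, curve.not_found, curve.found_reversed):
            fh.write(f"{c:g}\t{curve.total_in_synteny}\t{nf}\t{fr}\t{div}\n")
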