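"""Affinity sweeps, the optimum probe pKD, and condition lookup tables.

Sweeping the probe (labeled ligand) affinity at a fixed baseline fraction
bound — rederiving the protein concentration at every point so the
no-inhibitor readout is constant — produces the characteristic valley:
weak probes need so much protein that competitor is soaked up by free
protein and barely perturbs the readout, while very tight probes resist
displacement. In between lies an interior optimum. The optimum is scored
as the mean deviation of the inhibited fraction bound from the baseline
across a set of inhibitor affinities; because the valley floor is flat, a
plateau width (the contiguous pKD span whose objective is within 1% of the
maximum) is reported alongside the point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assay import protein_for_target_fraction
from .equilibrium import CompetitionSystem, solve_competition
from .quantities import kd_from_pkd, pkd_from_kd

__all__ = [
    "PkdGrid",
    "SweepResult",
    "LookupEntry",
    "ligand_pkd_sweep",
    "inhibitor_pkd_sweep",
    "optimal_ligand_pkd",
    "lookup_table",
    "DEFAULT_INHIBITOR_PKDS",
    "DEFAULT_LIGAND_GRID",
]

#: Inhibitor affinities (pKD) the optimum is averaged over by default:
#: 10 uM down to 1 nM KD, the span a primary screen aims to detect.
DEFAULT_INHIBITOR_PKDS: tuple[float, ...] = (5.0, 6.0, 7.0, 8.0, 9.0)


@dataclass(frozen=True)
class PkdGrid:
    """A uniform grid on the pKD axis: start, stop (inclusive), step."""

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError("grid step must be > 0")
        if not self.start < self.stop:
            raise ValueError("grid start must be < stop")
        if (self.stop - self.start) / self.step < 2:
            raise ValueError("grid must contain at least 3 points")

    def points(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step))
        return float(self.start) + float(self.step) * np.arange(n + 1, dtype=float)


#: Probe-affinity grid used for the optimum search: pKD 4 (100 uM) to
#: pKD 10 (0.1 nM) in steps of 0.005.
DEFAULT_LIGAND_GRID = PkdGrid(4.0, 10.0, 0.005)


@dataclass(frozen=True)
class SweepResult:
    """Fraction-bound surface over probe and inhibitor affinities.

    ``fraction_bound[i, j]`` is the inhibited fraction bound at ligand pKD
    ``ligand_pkds[i]`` and inhibitor pKD ``inhibitor_pkds[j]``;
    ``p_totals[i]`` is the protein concentration (M) derived for that
    ligand affinity to hit ``baseline_fraction`` with no inhibitor.
    """

    ligand_pkds: np.ndarray
    inhibitor_pkds: np.ndarray
    fraction_bound: np.ndarray
    p_totals: np.ndarray
    baseline_fraction: float


@dataclass(frozen=True)
class LookupEntry:
    """Optimum probe affinity for one combination of assay conditions."""

    l_total: float
    i_total: float
    target_fraction: float
    optimal_ligand_pkd: float
    optimal_ligand_kd: float
    objective_value: float
    plateau_lo_pkd: float
    plateau_hi_pkd: float


def _sweep(
    l_total: float,
    i_total: float,
    f0: float,
    ligand_pkds: np.ndarray,
    inhibitor_pkds: np.ndarray,
) -> SweepResult:
    p_totals = np.empty(ligand_pkds.size)
    frac = np.empty((ligand_pkds.size, inhibitor_pkds.size))
    inhibitor_kds = [kd_from_pkd(q) for q in inhibitor_pkds]
    for i, lig_pkd in enumerate(ligand_pkds):
        kd_pl = kd_from_pkd(lig_pkd)
        p_total = protein_for_target_fraction(l_total, kd_pl, f0)
        p_totals[i] = p_total
        for j, kd_pi in enumerate(inhibitor_kds):
            state = solve_competition(
                CompetitionSystem(p_total, l_total, i_total, kd_pl, kd_pi)
            )
            frac[i, j] = state.fraction_ligand_bound()
    return SweepResult(
        ligand_pkds=np.asarray(ligand_pkds, dtype=float),
        inhibitor_pkds=np.asarray(inhibitor_pkds, dtype=float),
        fraction_bound=frac,
        p_totals=p_totals,
        baseline_fraction=f0,
    )


def ligand_pkd_sweep(
    l_total: float,
    i_total: float,
    f0: float,
    inhibitor_pkds: Sequence[float],
    grid: PkdGrid = DEFAULT_LIGAND_GRID,
) -> SweepResult:
    """Valley sweep: fraction bound vs probe pKD, one column per inhibitor.

    At each grid point the protein concentration is rederived so that the
    baseline fraction bound stays at ``f0``; for a detectable inhibitor
    each column then shows a single interior minimum.
    """
    if len(inhibitor_pkds) == 0:
        raise ValueError("inhibitor_pkds must be non-empty")
    return _sweep(l_total, i_total, f0, grid.points(), np.asarray(inhibitor_pkds, float))


def inhibitor_pkd_sweep(
    l_total: float,
    i_total: float,
    f0: float,
    ligand_kds: Sequence[float],
    grid: PkdGrid,
) -> SweepResult:
    """Response curves: fraction bound vs inhibitor pKD, one row per probe KD.

    The transposed view of the same surface; every curve is monotone
    non-increasing in inhibitor pKD.
    """
    if len(ligand_kds) == 0:
        raise ValueError("ligand_kds must be non-empty")
    ligand_pkds = np.asarray([pkd_from_kd(k) for k in ligand_kds], dtype=float)
    return _sweep(l_total, i_total, f0, ligand_pkds, grid.points())


def optimal_ligand_pkd(
    l_total: float,
    i_total: float,
    f0: float,
    inhibitor_pkds: Sequence[float] = DEFAULT_INHIBITOR_PKDS,
    grid: PkdGrid = DEFAULT_LIGAND_GRID,
) -> tuple[float, float, tuple[float, float]]:
    """Probe pKD maximizing mean deviation from the baseline readout.

    Returns ``(pkd, objective, (plateau_lo, plateau_hi))`` where the
    objective is mean(f0 - fraction_bound) over ``inhibitor_pkds``, the
    argmax ties break toward the lower pKD, and the plateau is the
    contiguous grid span around the optimum whose objective is within 1%
    of the maximum (the valley floor is nearly flat, so the span is the
    more honest answer).
    """
    sweep = ligand_pkd_sweep(l_total, i_total, f0, inhibitor_pkds, grid)
    objective = np.mean(f0 - sweep.fraction_bound, axis=1)
    best = int(np.argmax(objective))  # argmax returns the first (lowest-pKD) max
    threshold = objective[best] * 0.99
    lo = best
    while lo > 0 and objective[lo - 1] >= threshold:
        lo -= 1
    hi = best
    while hi < objective.size - 1 and objective[hi + 1] >= threshold:
        hi += 1
    plateau = (float(sweep.ligand_pkds[lo]), float(sweep.ligand_pkds[hi]))
    return float(sweep.ligand_pkds[best]), float(objective[best]), plateau


def lookup_table(
    l_totals: Sequence[float],
    i_totals: Sequence[float],
    f0s: Sequence[float],
    inhibitor_pkds: Sequence[float] = DEFAULT_INHIBITOR_PKDS,
    grid: PkdGrid = DEFAULT_LIGAND_GRID,
) -> list[LookupEntry]:
    """Optimum probe affinity over the Cartesian product of conditions.

    Row order is deterministic: ``l_total`` outermost, then ``i_total``,
    then ``f0``.
    """
    for name, axis in (("l_totals", l_totals), ("i_totals", i_totals), ("f0s", f0s)):
        if len(axis) == 0:
            raise ValueError(f"{name} must be non-empty")
    entries: list[LookupEntry] = []
    for l_total in l_totals:
        for i_total in i_totals:
            for f0 in f0s:
                pkd, obj, plateau = optimal_ligand_pkd(
                    l_total, i_total, f0, inhibitor_pkds, grid
                )
                entries.append(
                    LookupEntry(
                        l_total=l_total,
                        i_total=i_total,
                        target_fraction=f0,
                        optimal_ligand_pkd=pkd,
                        optimal_ligand_kd=kd_from_pkd(pkd),
                        objective_value=obj,
                        plateau_lo_pkd=plateau[0],
                        plateau_hi_pkd=plateau[1],
                    )
                )
    return entries
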