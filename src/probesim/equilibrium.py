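"""Exact equilibrium solutions for 1:1 binding and 1:1:1 competition.

A protein P binds a labeled ligand L (the probe) and, in competition
systems, an unlabeled inhibitor I at the same site, each with 1:1
stoichiometry governed by mass action:

    KD_PL = [P][L] / [PL]        KD_PI = [P][I] / [PI]

together with conservation of each species. For the binary system the
mass balances reduce to a quadratic in the complex concentration; for the
ternary competition system, substituting the mass-action expressions for
both complexes into protein conservation yields a monic cubic in the free
protein concentration p:

    p^3 + a p^2 + b p + c = 0
    a = KD_PL + KD_PI + L0 + I0 - P0
    b = KD_PL*KD_PI + KD_PI*(L0 - P0) + KD_PL*(I0 - P0)
    c = -KD_PL*KD_PI*P0

The protein-conservation function g(p) = p + p*L0/(KD_PL+p)
+ p*I0/(KD_PI+p) - P0 is strictly increasing on p >= 0 with g(0) <= 0 and
g(P0) >= 0, so exactly one root lies in [0, P0]: choosing the cubic root
in that interval is unambiguous, with no case analysis on which affinity
is larger. Roots are extracted with the companion-matrix method and
Newton-polished on g; if double precision cannot satisfy the conservation
residual the solve is repeated in 50-digit arbitrary-precision arithmetic,
which matters when concentrations and affinities differ by many orders of
magnitude.

An independent bisection solver on g is provided as a cross-check oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import mpmath
import numpy as np
from scipy.optimize import bisect

from .quantities import check_concentration, check_kd

__all__ = [
    "CompetitionSystem",
    "EquilibriumState",
    "solve_one_to_one",
    "competition_cubic_coefficients",
    "solve_competition",
    "bisection_oracle",
    "NumericalFailure",
]

#: Conservation / mass-action residual (relative) demanded of every solve;
#: exceeding it in double precision triggers the arbitrary-precision retry.
RESIDUAL_RTOL = 1e-9

#: Significant digits used for the arbitrary-precision fallback.
MP_DIGITS = 50


class NumericalFailure(RuntimeError):
    """No physically valid root found even after precision escalation.

    This signals an implementation defect or a malformed system, never an
    expected outcome for valid inputs.
    """


@dataclass(frozen=True)
class CompetitionSystem:
    """One 1:1:1 protein:ligand:inhibitor equilibrium problem.

    All concentrations and dissociation constants are in molar.

    Parameters
    ----------
    p_total : float
        Total protein concentration P0 (free + both complexes).
    l_total : float
        Total labeled-ligand (probe) concentration L0.
    i_total : float
        Total inhibitor (competitor) concentration I0; may be zero.
    kd_pl : float
        Protein-ligand dissociation constant KD_PL.
    kd_pi : float
        Protein-inhibitor dissociation constant KD_PI.
    """

    p_total: float
    l_total: float
    i_total: float
    kd_pl: float
    kd_pi: float

    def __post_init__(self) -> None:
        check_concentration(self.p_total, "p_total")
        check_concentration(self.l_total, "l_total")
        check_concentration(self.i_total, "i_total")
        check_kd(self.kd_pl, "kd_pl")
        check_kd(self.kd_pi, "kd_pi")

    def swapped(self) -> "CompetitionSystem":
        """The same system with the roles of ligand and inhibitor exchanged."""
        return CompetitionSystem(
            p_total=self.p_total,
            l_total=self.i_total,
            i_total=self.l_total,
            kd_pl=self.kd_pi,
            kd_pi=self.kd_pl,
        )


@dataclass(frozen=True)
class EquilibriumState:
    """Free and complexed species concentrations (molar) at equilibrium."""

    free_protein: float
    free_ligand: float
    free_inhibitor: float
    complex_pl: float
    complex_pi: float

    @property
    def p_total(self) -> float:
        return self.free_protein + self.complex_pl + self.complex_pi

    @property
    def l_total(self) -> float:
        return self.free_ligand + self.complex_pl

    @property
    def i_total(self) -> float:
        return self.free_inhibitor + self.complex_pi

    def fraction_ligand_bound(self) -> float:
        """Bound probe over total probe, [PL]/L0 — the normalized readout.

        Zero when no probe is present.
        """
        l0 = self.l_total
        if l0 == 0.0:
            return 0.0
        return min(1.0, max(0.0, self.complex_pl / l0))


def _state_from_free_protein(p: float, system: CompetitionSystem) -> EquilibriumState:
    """Assemble the full species vector from the free-protein root."""
    p = float(max(0.0, p))
    # Free ligand and inhibitor via mass action rather than subtraction from
    # the totals: L*KD/(KD+p) never cancels, while L - [PL] loses all digits
    # when the species is almost fully bound.
    return EquilibriumState(
        free_protein=p,
        free_ligand=system.l_total * system.kd_pl / (system.kd_pl + p),
        free_inhibitor=system.i_total * system.kd_pi / (system.kd_pi + p),
        complex_pl=p * system.l_total / (system.kd_pl + p),
        complex_pi=p * system.i_total / (system.kd_pi + p),
    )


def _conservation_residual(state: EquilibriumState, system: CompetitionSystem) -> float:
    """Largest relative mass-balance violation over the three species."""
    res = 0.0
    for total, recon in (
        (system.p_total, state.p_total),
        (system.l_total, state.l_total),
        (system.i_total, state.i_total),
    ):
        scale = max(total, 1e-300)
        res = max(res, abs(recon - total) / scale)
    return res


def solve_one_to_one(p_total: float, l_total: float, kd: float) -> EquilibriumState:
    """Solve the binary 1:1 protein-ligand equilibrium exactly.

    The complex concentration is the physically valid root of the
    mass-balance quadratic,

        [PL] = ((P0 + L0 + KD) - sqrt((P0 + L0 + KD)^2 - 4 P0 L0)) / 2.

    Internally the equivalent quadratic in free protein,
    p^2 + (KD + L0 - P0) p - KD P0 = 0, is solved with the sign-stable
    branch of the quadratic formula and the remaining species follow by
    mass action — every expression is cancellation-free, so the state
    satisfies conservation and mass action to machine precision across the
    full concentration range. Inhibitor fields are zero.
    """
    check_concentration(p_total, "p_total")
    check_concentration(l_total, "l_total")
    check_kd(kd)
    if p_total == 0.0 or l_total == 0.0:
        return EquilibriumState(p_total, l_total, 0.0, 0.0, 0.0)
    q = kd + l_total - p_total
    disc = math.sqrt(q * q + 4.0 * kd * p_total)
    p = 2.0 * kd * p_total / (q + disc) if q > 0 else (disc - q) / 2.0
    return EquilibriumState(
        free_protein=p,
        free_ligand=l_total * kd / (kd + p),
        free_inhibitor=0.0,
        complex_pl=p * l_total / (kd + p),
        complex_pi=0.0,
    )


def competition_cubic_coefficients(system: CompetitionSystem) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of the monic free-protein cubic.

    Derived by substituting [PL] = p*L0/(KD_PL+p) and [PI] = p*I0/(KD_PI+p)
    into protein conservation and clearing denominators.
    """
    p0, l0, i0 = system.p_total, system.l_total, system.i_total
    kl, ki = system.kd_pl, system.kd_pi
    # Grouped so every float operation is invariant under exchanging the
    # ligand and inhibitor roles: the swap symmetry then holds bitwise.
    a = (kl + ki) + (l0 + i0) - p0
    b = kl * ki + (ki * l0 + kl * i0) - p0 * (kl + ki)
    c = -(kl * ki) * p0
    return a, b, c


def _conservation_fn(system: CompetitionSystem):
    """g(p): strictly increasing on p >= 0, with the root at free protein."""
    p0, l0, i0 = system.p_total, system.l_total, system.i_total
    kl, ki = system.kd_pl, system.kd_pi

    def g(p: float) -> float:
        bound = p * l0 / (kl + p) + p * i0 / (ki + p)
        return (p + bound) - p0

    return g


def _solve_cubic_double(system: CompetitionSystem) -> float | None:
    """Free-protein root in [0, P0] in double precision, or None if unusable."""
    a, b, c = competition_cubic_coefficients(system)
    roots = np.roots([1.0, a, b, c])
    p0 = system.p_total
    hi = p0 * (1.0 + 1e-9)
    candidates = [
        r.real
        for r in roots
        if abs(r.imag) <= 1e-8 * max(1.0, abs(r)) and -1e-12 * p0 <= r.real <= hi
    ]
    if not candidates:
        return None
    g = _conservation_fn(system)
    p = min(candidates, key=lambda x: abs(g(max(0.0, x))))
    p = min(max(p, 0.0), p0)
    # Newton polish on the conservation function; g'(p) > 1 everywhere so the
    # iteration is well conditioned near the root.
    kl, ki = system.kd_pl, system.kd_pi
    l0, i0 = system.l_total, system.i_total
    for _ in range(50):
        gp = g(p)
        dg = 1.0 + (l0 * kl / (kl + p) ** 2 + i0 * ki / (ki + p) ** 2)
        step = gp / dg
        p_new = min(max(p - step, 0.0), p0)
        if p_new == p:
            break
        p = p_new
        if abs(step) <= 1e-17 * max(p, 1e-300):
            break
    return _canonical_root(p, system)


def _canonical_root(p: float, system: CompetitionSystem) -> float:
    """Snap a near-converged root to the largest double with g(p) <= 0.

    Both solve routes land within a couple of ulp of the root, but the
    exact ulp can depend on the starting point (LAPACK eigenvalue output
    varies with workspace alignment; the arbitrary-precision route returns
    a bracket midpoint). Fixing the canonical representative makes every
    solve of the same system bit-identical.
    """
    g = _conservation_fn(system)
    p0 = system.p_total
    p = float(min(max(p, 0.0), p0))
    if g(p) > 0.0:
        for _ in range(100):
            if p <= 0.0 or g(p) <= 0.0:
                break
            p = math.nextafter(p, 0.0)
    else:
        for _ in range(100):
            nxt = math.nextafter(p, math.inf)
            if nxt > p0 or g(nxt) > 0.0:
                break
            p = nxt
    return p


def _solve_mpmath(system: CompetitionSystem) -> float:
    """Arbitrary-precision solve of the conservation equation (50 digits)."""
    with mpmath.workdps(MP_DIGITS):
        p0 = mpmath.mpf(system.p_total)
        l0 = mpmath.mpf(system.l_total)
        i0 = mpmath.mpf(system.i_total)
        kl = mpmath.mpf(system.kd_pl)
        ki = mpmath.mpf(system.kd_pi)

        def g(p):
            return (p + (p * l0 / (kl + p) + p * i0 / (ki + p))) - p0

        lo, hi = mpmath.mpf(0), p0
        if g(hi) < 0:  # cannot happen analytically; guard roundoff
            raise NumericalFailure("conservation function not bracketed")
        for _ in range(MP_DIGITS * 4):
            mid = (lo + hi) / 2
            if g(mid) < 0:
                lo = mid
            else:
                hi = mid
        return _canonical_root(float((lo + hi) / 2), system)


def solve_competition(system: CompetitionSystem) -> EquilibriumState:
    """Solve the ternary 1:1:1 competition equilibrium exactly.

    The free-protein concentration is the unique root of the mass-balance
    cubic in [0, P0]; both complexes follow by mass action and the free
    ligand and inhibitor by conservation. Double-precision results whose
    conservation residual exceeds relative 1e-9 are recomputed at 50
    significant digits.

    Raises
    ------
    NumericalFailure
        If no root in [0, P0] survives precision escalation.
    """
    if system.p_total == 0.0:
        return EquilibriumState(0.0, system.l_total, system.i_total, 0.0, 0.0)
    if system.i_total == 0.0:
        # Exact reduction to the binary problem; keeps sweeps continuous.
        return solve_one_to_one(system.p_total, system.l_total, system.kd_pl)
    if system.l_total == 0.0:
        # No probe: the protein-inhibitor pair still equilibrates.
        base = solve_one_to_one(system.p_total, system.i_total, system.kd_pi)
        return EquilibriumState(
            free_protein=base.free_protein,
            free_ligand=0.0,
            free_inhibitor=base.free_ligand,
            complex_pl=0.0,
            complex_pi=base.complex_pl,
        )
    p = _solve_cubic_double(system)
    if p is not None:
        state = _state_from_free_protein(p, system)
        if _conservation_residual(state, system) <= RESIDUAL_RTOL:
            return state
    p = _solve_mpmath(system)
    state = _state_from_free_protein(p, system)
    if _conservation_residual(state, system) > RESIDUAL_RTOL * 10:
        raise NumericalFailure(
            f"equilibrium solve failed to meet residual tolerance for {system}"
        )
    return state


def bisection_oracle(system: CompetitionSystem, tolerance: float = 4e-16) -> EquilibriumState:
    """Independent solver: bisection on the protein-conservation function.

    g(p) is strictly increasing with g(0) = -P0 < 0 and g(P0) >= 0, so
    bisection on [0, P0] always converges; ``tolerance`` is the relative
    width of the final bracket around the root (floored at 4 ulp). Used as
    the cross-check oracle for :func:`solve_competition`; it shares no
    code path with the cubic route.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if system.p_total == 0.0:
        return EquilibriumState(0.0, system.l_total, system.i_total, 0.0, 0.0)
    g = _conservation_fn(system)
    p0 = system.p_total
    if g(p0) <= 0.0:  # root at (or within roundoff of) the upper bracket
        return _state_from_free_protein(p0, system)
    # Tiny absolute floor + relative tolerance: the root can sit many orders
    # of magnitude below P0, so convergence must be judged relative to it.
    p = bisect(
        g, 0.0, p0,
        xtol=5e-324, rtol=max(tolerance, 4 * np.finfo(float).eps), maxiter=1100,
    )
    return _state_from_free_protein(p, system)
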