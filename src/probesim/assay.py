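"""Screening-scenario construction and sensitivity metrics.

A competition-based primary screen is set up by fixing the probe
concentration L0 and choosing the protein concentration P0 so that a
target fraction f0 of the probe is bound before any competitor is added
(the assay baseline). Inverting the 1:1 binding quadratic for P0 at fixed
fraction bound f gives the closed form

    P0 = f * L0 + KD * f / (1 - f)

Adding a library compound at concentration I0 with affinity KD_PI
displaces the probe; the drop from the baseline, expressed as a percentage
of the baseline, is the assay's readout reduction (equivalently, the share
of the readout's dynamic range the compound consumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .equilibrium import CompetitionSystem, solve_competition
from .quantities import check_concentration, check_kd

__all__ = [
    "protein_for_target_fraction",
    "AssayScenario",
    "AssayReadout",
    "evaluate_scenario",
    "readout_reduction_percent",
]


def protein_for_target_fraction(l_total: float, kd_pl: float, f0: float) -> float:
    """Protein concentration (M) giving fraction ``f0`` of the probe bound.

    Closed-form inversion of the 1:1 depletion quadratic:
    P0 = f0*L0 + KD*f0/(1 - f0). Round-tripping through
    :func:`~probesim.equilibrium.solve_one_to_one` recovers ``f0`` to
    relative 1e-9.

    Raises
    ------
    ValueError
        If ``f0`` is outside the open interval (0, 1).
    """
    check_concentration(l_total, "l_total")
    check_kd(kd_pl, "kd_pl")
    if not 0.0 < f0 < 1.0:
        raise ValueError(f"target fraction must be in (0, 1), got {f0!r}")
    return f0 * l_total + kd_pl * f0 / (1.0 - f0)


def readout_reduction_percent(f0: float, f_inh: float) -> float:
    """Percent drop of the bound fraction from its no-inhibitor baseline.

    100 * (f0 - f_inh) / f0; also called the consumed share of the
    readout's dynamic range. ``f_inh`` may not exceed ``f0`` — a rise in
    bound probe upon compound addition is outside the competitive model.
    """
    if not 0.0 < f0 <= 1.0:
        raise ValueError(f"baseline fraction must be in (0, 1], got {f0!r}")
    if not 0.0 <= f_inh <= f0:
        raise ValueError(
            f"inhibited fraction {f_inh!r} must lie in [0, baseline {f0!r}]"
        )
    return 100.0 * (f0 - f_inh) / f0


@dataclass(frozen=True)
class AssayScenario:
    """One screening setup; P0 is derived from the baseline target.

    Parameters are molar except ``target_fraction`` (dimensionless, in
    (0, 1)). ``p_total`` is computed on construction via
    :func:`protein_for_target_fraction` and never supplied directly.
    """

    l_total: float
    i_total: float
    target_fraction: float
    kd_pl: float
    kd_pi: float
    p_total: float = field(init=False)

    def __post_init__(self) -> None:
        check_concentration(self.i_total, "i_total")
        check_kd(self.kd_pi, "kd_pi")
        object.__setattr__(
            self,
            "p_total",
            protein_for_target_fraction(self.l_total, self.kd_pl, self.target_fraction),
        )

    def system(self) -> CompetitionSystem:
        return CompetitionSystem(
            p_total=self.p_total,
            l_total=self.l_total,
            i_total=self.i_total,
            kd_pl=self.kd_pl,
            kd_pi=self.kd_pi,
        )


@dataclass(frozen=True)
class AssayReadout:
    """Baseline and inhibited fractions bound with sensitivity percentages."""

    baseline_fraction: float
    inhibited_fraction: float
    readout_reduction_percent: float

    @property
    def dynamic_range_consumed_percent(self) -> float:
        """Alias for the readout reduction; both names are in common use."""
        return self.readout_reduction_percent


def evaluate_scenario(scenario: AssayScenario) -> AssayReadout:
    """Solve the scenario's competition equilibrium and report sensitivity."""
    state = solve_competition(scenario.system())
    f_inh = state.fraction_ligand_bound()
    f0 = scenario.target_fraction
    # Roundoff can leave f_inh a hair above f0 when the inhibitor is inert.
    f_inh = min(f_inh, f0)
    return AssayReadout(
        baseline_fraction=f0,
        inhibited_fraction=f_inh,
        readout_reduction_percent=readout_reduction_percent(f0, f_inh),
    )
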