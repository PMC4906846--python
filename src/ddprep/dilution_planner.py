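"""Serial-dilution planning for ddPCR wells.

Droplet counting only works when most droplets are empty, so samples are
diluted until a reaction receives at most ~10,000 molecules (for 20,000
droplets that is a mean occupancy of 0.5).  This module converts an input
mass to an absolute molecule count (650 g/mol per bp of dsDNA by default)
and picks the smallest serial dilution — stages of a fixed factor, 10 by
default — that brings the expected molecules per reaction under the cap.
For a 500 ng library the planned factors land in the 1e5–1e7 range typical
of post-shearing library-prep steps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "AVOGADRO",
    "MW_PER_BP",
    "DEFAULT_CAP",
    "DilutionPlan",
    "molecules_from_mass",
    "plan_dilution",
    "scale_for_input",
]

AVOGADRO = 6.02214076e23
MW_PER_BP = 650.0  # g/mol per bp of dsDNA (660 is an accepted alternative)
DEFAULT_CAP = 10_000  # max molecules per ddPCR reaction


@dataclass
class DilutionPlan:
    """A serial dilution bringing one sample under the per-reaction cap."""

    step_label: str
    dilution_factor: float
    serial_stages: list[float]
    expected_molecules_per_reaction: float
    cap: int = DEFAULT_CAP
    #: molecules one undiluted reaction aliquot would carry (kept so plans
    #: can be rescaled for other input masses)
    molecules_per_reaction_undiluted: float = 0.0

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        prod = math.prod(self.serial_stages) if self.serial_stages else 1.0
        if not math.isclose(prod, self.dilution_factor, rel_tol=1e-9):
            raise ValueError("dilution_factor must equal the product of serial_stages")
        if self.expected_molecules_per_reaction > self.cap * (1 + 1e-9):
            raise ValueError("plan exceeds the molecule cap")


def molecules_from_mass(
    mass_ng: float,
    composition: list[tuple[float, float]],
    mw_per_bp: float = MW_PER_BP,
) -> float:
    """Convert a dsDNA mass to an absolute molecule count.

    ``composition`` lists ``(length_bp, molar_fraction)`` pairs; fractions
    must sum to 1.  The mean molar mass is ``mw_per_bp * sum(f_i * L_i)``.
    """
    if mass_ng < 0:
        raise ValueError("mass_ng must be non-negative")
    total_frac = sum(f for _, f in composition)
    if abs(total_frac - 1.0) > 1e-6:
        raise ValueError(f"molar fractions must sum to 1, got {total_frac}")
    mean_length = sum(f * L for L, f in composition)
    if mean_length <= 0:
        raise ValueError("mean fragment length must be positive")
    return mass_ng * 1e-9 / (mw_per_bp * mean_length) * AVOGADRO


def plan_dilution(
    molecules_total: float,
    sample_volume_ul: float = 50.0,
    template_volume_ul: float = 1.0,
    cap: int = DEFAULT_CAP,
    stage_base: int | None = 10,
    step_label: str = "",
) -> DilutionPlan:
    """Smallest serial dilution keeping a reaction at or under ``cap``.

    With ``stage_base`` set (default 10) the factor is the smallest power of
    the base satisfying the cap; with ``stage_base=None`` the exact
    (continuous) factor is used.
    """
    if molecules_total < 0:
        raise ValueError("molecules_total must be non-negative")
    if sample_volume_ul <= 0 or template_volume_ul <= 0:
        raise ValueError("volumes must be positive")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    per_rx = molecules_total / sample_volume_ul * template_volume_ul
    required = per_rx / cap
    if required <= 1.0:
        factor, stages = 1.0, []
    elif stage_base is None:
        factor = required
        stages = [factor]
    else:
        if stage_base < 2:
            raise ValueError("stage_base must be >= 2")
        k = math.ceil(math.log(required) / math.log(stage_base) - 1e-12)
        factor = float(stage_base) ** k
        stages = [float(stage_base)] * k
    return DilutionPlan(
        step_label=step_label,
        dilution_factor=factor,
        serial_stages=stages,
        expected_molecules_per_reaction=per_rx / factor,
        cap=cap,
        molecules_per_reaction_undiluted=per_rx,
    )


def scale_for_input(
    plan: DilutionPlan, input_ng: float, reference_ng: float = 500.0
) -> DilutionPlan:
    """Rescale a reference-input plan for a lower (or higher) input mass.

    The dilution factor scales proportionally with the input (100 ng -> /5,
    20 ng -> /25 of a 500 ng plan), which keeps the expected molecules per
    reaction unchanged.  Factors below 1 are clamped with a warning.
    """
    if input_ng <= 0:
        raise ValueError("input_ng must be positive")
    scale = input_ng / reference_ng
    factor = plan.dilution_factor * scale
    if factor < 1.0:
        warnings.warn(
            f"scaled dilution factor {factor:.3g} < 1; clamping to 1", stacklevel=2
        )
        factor = 1.0
    per_rx = plan.molecules_per_reaction_undiluted * scale
    return DilutionPlan(
        step_label=plan.step_label,
        dilution_factor=factor,
        serial_stages=[factor] if factor > 1 else [],
        expected_molecules_per_reaction=per_rx / factor,
        cap=plan.cap,
        molecules_per_reaction_undiluted=per_rx,
    )
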