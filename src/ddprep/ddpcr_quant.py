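"""Poisson-corrected droplet-digital-PCR quantification.

A ddPCR well partitions a diluted template aliquot into tens of thousands of
nanoliter droplets; after endpoint PCR each droplet reads out as positive
(it received at least one target molecule) or negative.  Under random
partitioning the per-droplet occupancy is Poisson, so the mean occupancy is
recovered from the fraction of *negative* droplets,

    lambda = -ln( n_negative / n_droplets ),

and the absolute number of target molecules in the undiluted sample follows
from the reaction volumes and the dilution factor — no standard curve is
required.  At the working dilutions used here (<= ~10^4 molecules per well)
the correction is small and the estimate reduces to naive positive-droplet
counting, but the full correction is applied throughout.

Confidence intervals are Wilson score intervals on the positive fraction,
transformed through the same monotone formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "CHANNELS",
    "DropletRun",
    "ConcentrationEstimate",
    "MergedEstimate",
    "estimate_copies",
    "merge_replicates",
]

#: Primer channels: the amplicon-specific pair detects every insert-bearing
#: molecule, the adaptor pair only ligated molecules, the P5/P7 pair only
#: finished library molecules.
CHANNELS = ("phix_total", "adaptor", "p5p7")

#: QX200-typical defaults; the droplet volume is metadata (the estimator
#: works on droplet counts and reaction volumes alone).
DEFAULT_N_DROPLETS = 20_000
DEFAULT_DROPLET_VOLUME_NL = 0.85


@dataclass
class DropletRun:
    """One ddPCR well: droplet counts plus dilution metadata."""

    sample_id: str
    step_label: str
    channel: str
    replicate: int
    n_droplets: int
    n_positive: int
    dilution_factor: float = 1.0
    template_volume_ul: float = 1.0
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    sample_volume_ul: float = 50.0

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if not 0 <= self.n_positive <= self.n_droplets:
            raise ValueError(
                f"n_positive must lie in [0, n_droplets], got "
                f"{self.n_positive}/{self.n_droplets}"
            )
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if min(self.template_volume_ul, self.droplet_volume_nl, self.sample_volume_ul) <= 0:
            raise ValueError("volumes must be positive")


@dataclass
class ConcentrationEstimate:
    """Absolute quantification result for one well (or a pooled set)."""

    copies_per_reaction: float
    copies_per_ul_diluted: float
    absolute_molecules_undiluted: float
    ci95: tuple[float, float]
    saturated: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not self.saturated:
            if not lo <= self.absolute_molecules_undiluted <= hi:
                raise ValueError("CI must bracket the point estimate")


def _occupancy(p_positive: float) -> float:
    """Poisson mean occupancy from the positive-droplet fraction."""
    if p_positive >= 1.0:
        return math.inf
    return -math.log1p(-p_positive)


def _wilson(x: int, n: int, level: float) -> tuple[float, float]:
    z = norm.ppf(0.5 + level / 2.0)
    phat = x / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def estimate_copies(run: DropletRun, ci_level: float = 0.95) -> ConcentrationEstimate:
    """Poisson-corrected absolute quantification of one well.

    Returns copies per reaction (``lambda * n_droplets``), copies per µL of
    the diluted template, and the absolute molecule count in the undiluted
    sample the aliquot came from.  A fully positive well has no finite point
    estimate and is returned with ``saturated=True`` (upper bound infinite,
    lower bound from the Wilson interval).
    """
    n, x = run.n_droplets, run.n_positive
    # copies/reaction -> absolute molecules in the undiluted sample
    scale = run.dilution_factor * run.sample_volume_ul / run.template_volume_ul

    lo_p, hi_p = _wilson(x, n, ci_level)
    abs_lo = _occupancy(lo_p) * n * scale
    abs_hi = _occupancy(hi_p) * n * scale

    if x == n:
        return ConcentrationEstimate(
            copies_per_reaction=math.inf,
            copies_per_ul_diluted=math.inf,
            absolute_molecules_undiluted=math.inf,
            ci95=(abs_lo, math.inf),
            saturated=True,
        )
    lam = _occupancy(x / n)
    copies_rx = lam * n
    copies_ul = copies_rx / run.template_volume_ul
    absolute = copies_ul * run.dilution_factor * run.sample_volume_ul
    return ConcentrationEstimate(
        copies_per_reaction=copies_rx,
        copies_per_ul_diluted=copies_ul,
        absolute_molecules_undiluted=absolute,
        ci95=(abs_lo, abs_hi),
        saturated=False,
    )


@dataclass
class MergedEstimate:
    """Pooled estimate for a replicate set plus the replicate spread."""

    pooled: ConcentrationEstimate
    per_replicate: list[ConcentrationEstimate] = field(default_factory=list)
    replicate_sd: float = 0.0
    n_replicates: int = 0
    saturated: bool = False


def merge_replicates(runs: list[DropletRun], ci_level: float = 0.95) -> MergedEstimate:
    """Pool replicate wells of one sample/step/channel.

    The pooled estimate treats the replicate set as one large partition
    (summed positives over summed droplets); the replicate spread is the
    sample standard deviation of the per-replicate absolute molecule counts.
    A saturated replicate marks the whole set saturated.
    """
    if not runs:
        raise ValueError("need at least one replicate")
    first = runs[0]
    for r in runs[1:]:
        if (r.sample_id, r.step_label, r.channel) != (
            first.sample_id,
            first.step_label,
            first.channel,
        ):
            raise ValueError("replicates must share sample, step and channel")
        if (r.dilution_factor, r.template_volume_ul, r.sample_volume_ul) != (
            first.dilution_factor,
            first.template_volume_ul,
            first.sample_volume_ul,
        ):
            raise ValueError("replicates must share dilution and volumes")

    per = [estimate_copies(r, ci_level) for r in runs]
    pooled_run = DropletRun(
        sample_id=first.sample_id,
        step_label=first.step_label,
        channel=first.channel,
        replicate=1,
        n_droplets=sum(r.n_droplets for r in runs),
        n_positive=sum(r.n_positive for r in runs),
        dilution_factor=first.dilution_factor,
        template_volume_ul=first.template_volume_ul,
        droplet_volume_nl=first.droplet_volume_nl,
        sample_volume_ul=first.sample_volume_ul,
    )
    pooled_all = estimate_copies(pooled_run, ci_level)
    # the summed partition estimates the occupancy; rescale to one well so
    # copies_per_reaction / absolute molecules refer to a single reaction
    k = float(len(runs))
    pooled = ConcentrationEstimate(
        copies_per_reaction=pooled_all.copies_per_reaction / k,
        copies_per_ul_diluted=pooled_all.copies_per_ul_diluted / k,
        absolute_molecules_undiluted=pooled_all.absolute_molecules_undiluted / k,
        ci95=(pooled_all.ci95[0] / k, pooled_all.ci95[1] / k),
        saturated=pooled_all.saturated,
    )
    saturated = pooled.saturated or any(e.saturated for e in per)
    finite = [e.absolute_molecules_undiluted for e in per if not e.saturated]
    sd = float(np.std(finite, ddof=1)) if len(finite) > 1 else 0.0
    return MergedEstimate(
        pooled=pooled,
        per_replicate=per,
        replicate_sd=sd,
        n_replicates=len(runs),
        saturated=saturated,
    )
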