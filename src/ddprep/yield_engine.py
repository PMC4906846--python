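"""Overall and stepwise library-preparation yields.

Two yield notions are kept distinct:

* **overall yield** — molecules detected in a given channel at a given step,
  divided by the input molecule count at protocol start.  It convolves every
  upstream physical loss and chemical efficiency, and may exceed 1 after PCR
  enrichment.
* **stepwise yield** — converted molecules divided by *total* molecules in
  the same post-step sample (e.g. adaptor-bearing over all remaining
  molecules just after ligation).  Because both numbers come from the same
  tube, the physical losses cancel and the ratio isolates the chemical
  efficiency of the step.

The ligation stepwise yield is, strictly, a chain composite: a molecule only
ligates if end repair and A-tailing also succeeded, so the reported number is
labelled a ligation-chain yield.  The PCR stepwise yield compares finished
(P5/P7-flanked) molecules after amplification with the adaptor-bearing
molecules that entered it, i.e. the net amplification fold.

Replicate standard deviations propagate through the ratios by the first-order
delta method, treating numerator and denominator as independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .ddpcr_quant import ConcentrationEstimate, MergedEstimate

__all__ = [
    "ChannelMeasurement",
    "MeasurementSet",
    "YieldRow",
    "YieldReport",
    "overall_yield",
    "stepwise_yield",
    "pcr_step_yield",
    "build_yield_report",
    "FLAG_NOT_MEASURED",
    "FLAG_SATURATED",
    "FLAG_UNDEFINED",
]

FLAG_NOT_MEASURED = "NM"
FLAG_SATURATED = "saturated"
FLAG_UNDEFINED = "undefined"


def _value(x) -> float:
    """Accept plain numbers, ConcentrationEstimates or merged estimates."""
    if isinstance(x, MergedEstimate):
        return x.pooled.absolute_molecules_undiluted
    if isinstance(x, ConcentrationEstimate):
        return x.absolute_molecules_undiluted
    if isinstance(x, ChannelMeasurement):
        return x.value
    return float(x)


@dataclass
class ChannelMeasurement:
    """One merged channel measurement feeding the yield algebra."""

    value: float
    sd: float = 0.0
    saturated: bool = False
    measured: bool = True

    @classmethod
    def not_measured(cls) -> "ChannelMeasurement":
        return cls(value=math.nan, sd=math.nan, measured=False)

    @classmethod
    def from_merged(cls, m: MergedEstimate) -> "ChannelMeasurement":
        return cls(
            value=m.pooled.absolute_molecules_undiluted,
            sd=m.replicate_sd,
            saturated=m.saturated,
        )


@dataclass
class MeasurementSet:
    """Channelled absolute-molecule measurements for one sample.

    ``steps`` maps step label -> channel -> measurement.  ``input_total`` is
    the molecule count of the starting input (amplicon-specific channel).
    """

    sample_id: str
    input_total: float
    steps: dict[str, dict[str, ChannelMeasurement]]
    input_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.input_total <= 0:
            raise ValueError("input_total must be positive")
        for label, chans in self.steps.items():
            if "phix_total" not in chans:
                raise ValueError(f"step {label!r} lacks the phix_total channel")


def overall_yield(measured, input_total) -> float:
    """Molecules at a step over molecules at protocol start (may exceed 1)."""
    denom = _value(input_total)
    if denom <= 0:
        raise ValueError("input_total must be positive")
    return _value(measured) / denom


def stepwise_yield(converted, total_same_step) -> float:
    """Converted over total molecules of the same post-step sample."""
    denom = _value(total_same_step)
    if denom <= 0:
        raise ValueError("total_same_step must be positive")
    return _value(converted) / denom


def pcr_step_yield(p5p7_post_pcr, adaptor_post_ligation) -> float:
    """Amplification fold: finished molecules over adaptor-bearing input."""
    denom = _value(adaptor_post_ligation)
    if denom <= 0:
        raise ValueError("adaptor_post_ligation must be positive")
    return _value(p5p7_post_pcr) / denom


def _ratio_sd(a: float, sa: float, b: float, sb: float) -> float:
    """Delta-method SD of a/b for independent a, b."""
    if a == 0 or b == 0 or any(map(math.isnan, (a, sa, b, sb))):
        return math.nan if (math.isnan(sa) or math.isnan(sb)) else 0.0
    r = a / b
    return abs(r) * math.sqrt((sa / a) ** 2 + (sb / b) ** 2)


@dataclass
class YieldRow:
    step_label: str
    channel: str
    kind: str  # "overall" | "stepwise_ligation" | "stepwise_pcr"
    value: float
    sd: float
    flag: str = ""


@dataclass
class YieldReport:
    sample_id: str
    rows: list[YieldRow] = field(default_factory=list)

    def get(self, kind: str, step_label: str | None = None, channel: str | None = None) -> YieldRow:
        for r in self.rows:
            if r.kind != kind:
                continue
            if step_label is not None and r.step_label != step_label:
                continue
            if channel is not None and r.channel != channel:
                continue
            return r
        raise KeyError((kind, step_label, channel))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": self.sample_id,
                    "step_label": r.step_label,
                    "channel": r.channel,
                    "kind": r.kind,
                    "value": r.value,
                    "sd": r.sd,
                    "flag": r.flag,
                }
                for r in self.rows
            ]
        )


def build_yield_report(
    ms: MeasurementSet,
    ligation_step: str = "post_ligation",
    pcr_step: str = "post_pcr",
) -> YieldReport:
    """Assemble the full per-step/per-channel yield report for one sample.

    Overall yields are computed for every measured step/channel pair;
    the ligation-chain stepwise yield from the adaptor and total channels of
    the post-ligation sample; and the PCR stepwise yield (amplification fold)
    from the post-PCR P5/P7 channel over the post-ligation adaptor channel.
    Missing channels produce flagged rows, never failures.
    """
    rep = YieldReport(sample_id=ms.sample_id)
    for label, chans in ms.steps.items():
        for channel, m in chans.items():
            if not m.measured:
                rep.rows.append(YieldRow(label, channel, "overall", math.nan, math.nan, FLAG_NOT_MEASURED))
                continue
            flag = FLAG_SATURATED if m.saturated else ""
            val = overall_yield(m, ms.input_total)
            sd = _ratio_sd(m.value, m.sd, ms.input_total, ms.input_sd)
            rep.rows.append(YieldRow(label, channel, "overall", val, sd, flag))

    lig = ms.steps.get(ligation_step, {})
    adaptor = lig.get("adaptor")
    total = lig.get("phix_total")
    if adaptor is None or not adaptor.measured:
        rep.rows.append(
            YieldRow(ligation_step, "adaptor", "stepwise_ligation", math.nan, math.nan, FLAG_NOT_MEASURED)
        )
    elif total is None or not total.measured or total.value <= 0:
        rep.rows.append(
            YieldRow(ligation_step, "adaptor", "stepwise_ligation", math.nan, math.nan, FLAG_UNDEFINED)
        )
    else:
        val = stepwise_yield(adaptor, total)
        sd = _ratio_sd(adaptor.value, adaptor.sd, total.value, total.sd)
        rep.rows.append(YieldRow(ligation_step, "adaptor", "stepwise_ligation", val, sd))

    pcr = ms.steps.get(pcr_step, {})
    p5p7 = pcr.get("p5p7")
    if p5p7 is None or not p5p7.measured:
        flag = FLAG_NOT_MEASURED if p5p7 is not None or pcr else FLAG_UNDEFINED
        rep.rows.append(YieldRow(pcr_step, "p5p7", "stepwise_pcr", math.nan, math.nan, flag))
    elif adaptor is None or not adaptor.measured or adaptor.value <= 0:
        rep.rows.append(YieldRow(pcr_step, "p5p7", "stepwise_pcr", math.nan, math.nan, FLAG_NOT_MEASURED))
    else:
        val = pcr_step_yield(p5p7, adaptor)
        sd = _ratio_sd(p5p7.value, p5p7.sd, adaptor.value, adaptor.sd)
        rep.rows.append(YieldRow(pcr_step, "p5p7", "stepwise_pcr", val, sd))
    return rep
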