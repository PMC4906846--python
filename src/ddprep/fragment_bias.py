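"""Fragment-representation bias from pre/post molar concentrations.

The three control amplicons enter library preparation in an equimolar
mixture (~33 % each).  Size-dependent losses during bead cleanups and
sequence effects shift that balance; the bias metric is, per amplicon, the
difference between the post- and pre-library molar percentage, in
percentage points.  The deltas always sum to zero.  A relative variant
(percent change of each amplicon's share) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["FragmentRatioTable", "RatioVariation", "molar_percentages", "ratio_variation"]


@dataclass
class FragmentRatioTable:
    """Molar concentrations per amplicon (any consistent unit)."""

    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        for a, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {a!r}")


@dataclass
class RatioVariation:
    """Per-amplicon change of molar share (percentage points by default)."""

    deltas: dict[str, float]
    relative: bool = False


def molar_percentages(table: FragmentRatioTable) -> dict[str, float]:
    """Molar share of each amplicon, in percent of the total."""
    total = sum(table.concentrations.values())
    if total <= 0:
        raise ValueError("at least one concentration must be positive")
    return {a: 100.0 * c / total for a, c in table.concentrations.items()}


def ratio_variation(
    pre: FragmentRatioTable, post: FragmentRatioTable, relative: bool = False
) -> RatioVariation:
    """Post minus pre molar percentages, per amplicon.

    With ``relative=True`` the change is expressed relative to the
    pre-library share ((post - pre) / pre * 100) instead of in percentage
    points.
    """
    if set(pre.concentrations) != set(post.concentrations):
        raise ValueError("pre and post tables must cover the same amplicons")
    p_pre = molar_percentages(pre)
    p_post = molar_percentages(post)
    if relative:
        deltas = {
            a: (p_post[a] - p_pre[a]) / p_pre[a] * 100.0 if p_pre[a] > 0 else float("nan")
            for a in p_pre
        }
    else:
        deltas = {a: p_post[a] - p_pre[a] for a in p_pre}
    return RatioVariation(deltas=deltas, relative=relative)
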