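"""Library-preparation protocol model.

A sequencing library is built from sheared double-stranded DNA by a chain of
enzymatic steps (end repair, A-tailing, adaptor ligation, PCR enrichment)
interleaved with paramagnetic-bead cleanups.  Each step both *loses* molecules
physically (beads, pipetting) and *converts* a fraction of the eligible
molecules chemically to the next end-state.  This module represents kit
protocols as ordered step lists and propagates molecule populations through
them, keeping physical retention strictly separate from chemical conversion so
that the two can later be deconvolved from droplet-digital-PCR measurements.

Populations can be propagated in ``expected`` mode (deterministic expected
counts, real-valued) or ``stochastic`` mode (binomial thinning of integer
counts, seeded).

Nine commercial kit workflows are shipped as built-in presets whose step
structure mirrors the published manuals; their retention/conversion parameters
are neutral placeholders (1.0) that callers — typically the synthetic-data
generator — must set via :func:`parameterize_kit`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "END_STATES",
    "AMPLICONS",
    "FragmentSpecies",
    "SamplePopulation",
    "PcrParams",
    "LogisticSizeRetention",
    "ProtocolStep",
    "KitProtocol",
    "apply_step",
    "run_protocol",
    "count_steps",
    "builtin_kits",
    "kit_protocol",
    "parameterize_kit",
    "kit_to_dict",
    "kit_from_dict",
]

#: Ordered molecule end-states.  Chemical steps only move molecules forward
#: along this order; PCR maps adaptor_ligated to p5p7_flanked.
END_STATES = ("sheared", "end_repaired", "a_tailed", "adaptor_ligated", "p5p7_flanked")
_STATE_INDEX = {s: i for i, s in enumerate(END_STATES)}

#: The three control amplicons used throughout: id -> length in bp.
AMPLICONS = {"A214": 214, "B397": 397, "C568": 568}

_PHYSICAL_KINDS = frozenset(
    {
        "mechanical_shear",
        "enzymatic_fragmentation",
        "bead_cleanup",
        "double_size_selection",
        "pcr_cleanup",
    }
)

# Default (from_state, to_state) transitions for chemical kinds.
_DEFAULT_TRANSITIONS = {
    "end_repair": ("sheared", "end_repaired"),
    "a_tail": ("end_repaired", "a_tailed"),
    "combined_er_at": ("sheared", "a_tailed"),
    "adaptor_ligation": ("a_tailed", "adaptor_ligated"),
}

_KNOWN_KINDS = (
    _PHYSICAL_KINDS
    | set(_DEFAULT_TRANSITIONS)
    | {"ligation_strand_extension", "pcr_amplification"}
)


class ConfigurationError(ValueError):
    """Raised for invalid step/kit definitions."""


@dataclass(frozen=True)
class FragmentSpecies:
    """A molecule class: amplicon identity, length and end-state."""

    amplicon_id: str
    length_bp: int
    end_state: str

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"length_bp must be positive, got {self.length_bp}")
        if self.end_state not in _STATE_INDEX:
            raise ValueError(f"unknown end_state {self.end_state!r}")


@dataclass
class SamplePopulation:
    """Absolute molecule counts per :class:`FragmentSpecies` in a volume.

    Counts are non-negative reals in expected mode and non-negative integers
    in stochastic mode.
    """

    counts: dict[FragmentSpecies, float]
    volume_ul: float = 50.0

    def __post_init__(self) -> None:
        if self.volume_ul <= 0:
            raise ValueError("volume_ul must be positive")
        for sp, c in self.counts.items():
            if not math.isfinite(c) or c < 0:
                raise ValueError(f"invalid count {c!r} for {sp}")

    def total(self) -> float:
        return float(sum(self.counts.values()))

    def count_in_states(self, states: Iterable[str]) -> float:
        states = set(states)
        return float(sum(c for sp, c in self.counts.items() if sp.end_state in states))

    def state_totals(self) -> dict[str, float]:
        out: dict[str, float] = {s: 0.0 for s in END_STATES}
        for sp, c in self.counts.items():
            out[sp.end_state] += c
        return out

    def is_integer(self) -> bool:
        return all(float(c).is_integer() for c in self.counts.values())

    @classmethod
    def equimolar(
        cls,
        total_molecules: float,
        end_state: str = "sheared",
        volume_ul: float = 50.0,
        amplicons: Mapping[str, int] = AMPLICONS,
    ) -> "SamplePopulation":
        """Equimolar mixture of the given amplicons, all in one end-state."""
        n = len(amplicons)
        counts = {
            FragmentSpecies(a, L, end_state): total_molecules / n
            for a, L in amplicons.items()
        }
        return cls(counts=counts, volume_ul=volume_ul)


@dataclass(frozen=True)
class PcrParams:
    cycles: int
    per_cycle_efficiency: float
    capacity: float = math.inf  # molecules; inf = unbounded

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ConfigurationError("cycles must be >= 1")
        if not 0.0 <= self.per_cycle_efficiency <= 1.0:
            raise ConfigurationError("per_cycle_efficiency must be in [0, 1]")
        if self.capacity <= 0:
            raise ConfigurationError("capacity must be positive")

    @property
    def fold(self) -> float:
        return (1.0 + self.per_cycle_efficiency) ** self.cycles


@dataclass(frozen=True)
class LogisticSizeRetention:
    """Length-dependent cleanup retention: a logistic curve in fragment length.

    retention(L) = floor + (ceiling - floor) / (1 + exp(-(L - midpoint)/scale))

    Small fragments sit on the low shoulder, emulating the preferential loss
    of short fragments during bead cleanups.
    """

    midpoint_bp: float = 250.0
    scale_bp: float = 60.0
    floor: float = 0.0
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.floor <= self.ceiling <= 1.0:
            raise ConfigurationError("need 0 <= floor <= ceiling <= 1")
        if self.scale_bp <= 0:
            raise ConfigurationError("scale_bp must be positive")

    def __call__(self, length_bp: float) -> float:
        z = (length_bp - self.midpoint_bp) / self.scale_bp
        return self.floor + (self.ceiling - self.floor) / (1.0 + math.exp(-z))


@dataclass
class ProtocolStep:
    """One protocol step with separate physical and chemical parameters.

    ``retention`` is the fraction of molecules physically kept (all species);
    ``conversion_efficiency`` the fraction of eligible molecules chemically
    advanced from ``from_state`` to ``to_state``.  ``size_retention``
    overrides the flat retention with a per-length curve.
    """

    kind: str
    label: str = ""
    retention: float = 1.0
    conversion_efficiency: float | None = None
    from_state: str | None = None
    to_state: str | None = None
    size_retention: Callable[[float], float] | None = None
    pcr_params: PcrParams | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KNOWN_KINDS:
            raise ConfigurationError(f"unknown step kind {self.kind!r}")
        if not 0.0 <= self.retention <= 1.0:
            raise ConfigurationError("retention must be in [0, 1]")
        if (self.pcr_params is not None) != (self.kind == "pcr_amplification"):
            raise ConfigurationError(
                "pcr_params must be given exactly for pcr_amplification steps"
            )
        if not self.label:
            self.label = self.kind
        if self.kind in _DEFAULT_TRANSITIONS:
            frm, to = _DEFAULT_TRANSITIONS[self.kind]
            self.from_state = self.from_state or frm
            self.to_state = self.to_state or to
        if self.kind == "ligation_strand_extension" and (
            self.from_state is None or self.to_state is None
        ):
            raise ConfigurationError(
                "ligation_strand_extension requires explicit from_state/to_state"
            )
        if self.is_chemical:
            if self.conversion_efficiency is None:
                self.conversion_efficiency = 1.0
            if not 0.0 <= self.conversion_efficiency <= 1.0:
                raise ConfigurationError("conversion_efficiency must be in [0, 1]")
            if _STATE_INDEX[self.to_state] < _STATE_INDEX[self.from_state]:
                raise ConfigurationError("chemical steps may not move end-state backward")

    @property
    def is_chemical(self) -> bool:
        """Chemical if it carries a state transition (PCR handled separately)."""
        if self.kind == "pcr_amplification":
            return False
        return self.to_state is not None


@dataclass
class KitProtocol:
    """An ordered library-prep workflow.

    ``adaptor_channel_measurable`` is False for kits whose bespoke adaptor
    chemistry prevents the adaptor-specific ddPCR channel from being assayed
    (the Accel kits).
    """

    name: str
    steps: list[ProtocolStep]
    adaptor_channel_measurable: bool = True
    declared_inputs_ng: list[float] = field(default_factory=lambda: [500.0])

    def __post_init__(self) -> None:
        if not self.steps:
            raise ConfigurationError("a kit needs at least one step")
        if any(n <= 0 for n in self.declared_inputs_ng):
            raise ConfigurationError("declared inputs must be positive")
        # step order must respect the end-state ordering
        reach = 0
        for st in self.steps:
            if st.is_chemical:
                if _STATE_INDEX[st.from_state] > reach:
                    raise ConfigurationError(
                        f"{self.name}: step {st.label!r} expects state "
                        f"{st.from_state!r} before any step can produce it"
                    )
                reach = max(reach, _STATE_INDEX[st.to_state])
            elif st.kind == "pcr_amplification":
                reach = max(reach, _STATE_INDEX["p5p7_flanked"])

    @property
    def has_pcr(self) -> bool:
        return any(s.kind == "pcr_amplification" for s in self.steps)


# ---------------------------------------------------------------------------
# Population propagation
# ---------------------------------------------------------------------------


def _retention_for(step: ProtocolStep, species: FragmentSpecies) -> float:
    if step.size_retention is not None:
        r = float(step.size_retention(species.length_bp))
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError("size_retention must return values in [0, 1]")
        return r
    return step.retention


def apply_step(
    pop: SamplePopulation,
    step: ProtocolStep,
    mode: str = "expected",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SamplePopulation:
    """Propagate a population through one protocol step.

    Physical steps multiply every species count by the retention (or its
    per-length curve).  Chemical steps additionally advance
    ``conversion_efficiency`` of the eligible molecules to the next
    end-state, leaving the remainder in place.  PCR multiplies
    adaptor-ligated molecules by ``(1+e)^cycles`` capped at the reaction
    capacity and relabels the product ``p5p7_flanked``; every other species
    passes through unamplified.  Stochastic mode replaces each thinning by a
    binomial draw with the same expectation.
    """
    if mode not in ("expected", "stochastic"):
        raise ValueError(f"mode must be 'expected' or 'stochastic', got {mode!r}")
    if mode == "stochastic":
        if rng is None:
            if seed is None:
                raise ValueError("stochastic mode requires a seed or rng")
            rng = np.random.default_rng(seed)
        if not pop.is_integer():
            raise ValueError("stochastic mode requires integer counts")

    def thin(count: float, p: float) -> float:
        if mode == "expected":
            return count * p
        return float(rng.binomial(int(count), p))

    new_counts: dict[FragmentSpecies, float] = {}

    def add(sp: FragmentSpecies, c: float) -> None:
        if c > 0:
            new_counts[sp] = new_counts.get(sp, 0.0) + c

    if step.kind == "pcr_amplification":
        params = step.pcr_params
        amplifiable = {
            sp: c for sp, c in pop.counts.items() if sp.end_state == "adaptor_ligated"
        }
        n_total = sum(amplifiable.values())
        if n_total > 0:
            target = min(n_total * params.fold, params.capacity)
            scale = target / n_total
            for sp, c in amplifiable.items():
                out = c * scale
                if mode == "stochastic":
                    out = float(round(out))
                add(replace(sp, end_state="p5p7_flanked"), out)
        for sp, c in pop.counts.items():
            if sp.end_state != "adaptor_ligated":
                add(sp, c)
        return SamplePopulation(counts=new_counts, volume_ul=pop.volume_ul)

    for sp, c in pop.counts.items():
        kept = thin(c, _retention_for(step, sp))
        if step.is_chemical and sp.end_state == step.from_state:
            converted = thin(kept, step.conversion_efficiency)
            add(replace(sp, end_state=step.to_state), converted)
            add(sp, kept - converted)
        else:
            add(sp, kept)
    return SamplePopulation(counts=new_counts, volume_ul=pop.volume_ul)


def run_protocol(
    pop0: SamplePopulation,
    kit: KitProtocol,
    mode: str = "expected",
    seed: int | None = None,
) -> list[tuple[str, SamplePopulation]]:
    """Run a full protocol, returning the population after every step.

    The returned trajectory starts with ``("input", pop0)``.  Expected mode
    is deterministic; stochastic mode derives one substream per step from the
    given seed.
    """
    rng = np.random.default_rng(seed) if mode == "stochastic" else None
    traj: list[tuple[str, SamplePopulation]] = [("input", pop0)]
    pop = pop0
    for st in kit.steps:
        pop = apply_step(pop, st, mode=mode, rng=rng)
        traj.append((st.label, pop))
    return traj


def count_steps(kit: KitProtocol) -> int:
    """Number of protocol steps after shearing.

    Convention: every listed step counts as 1.  A combined end-repair/
    A-tailing mix is a single step; "PCR & bead cleaning" is represented as
    two steps (amplification + cleanup) and therefore counts as 2; the
    fragmentase reaction of enzymatically sheared kits counts as 1.
    """
    return len(kit.steps)


# ---------------------------------------------------------------------------
# Built-in kit workflows
# ---------------------------------------------------------------------------

_PLACEHOLDER_PCR = PcrParams(cycles=6, per_cycle_efficiency=1.0)


def _classic(name: str, *, tail_cleanup: bool = True) -> list[ProtocolStep]:
    """ER / cleanup / A-tail / cleanup / ligation / cleanup / PCR / cleanup."""
    steps = [
        ProtocolStep("end_repair"),
        ProtocolStep("bead_cleanup", label="post_er_cleanup"),
        ProtocolStep("a_tail"),
    ]
    if tail_cleanup:
        steps.append(ProtocolStep("bead_cleanup", label="post_at_cleanup"))
    steps += [
        ProtocolStep("adaptor_ligation"),
        ProtocolStep("bead_cleanup", label="post_ligation_cleanup"),
        ProtocolStep("pcr_amplification", pcr_params=_PLACEHOLDER_PCR),
        ProtocolStep("pcr_cleanup"),
    ]
    return steps


def kit_protocol(name: str, with_pcr: bool | None = None) -> KitProtocol:
    """Build one named kit workflow.

    ``with_pcr`` toggles the optional amplification stage of the KAPA kits
    (their manuals allow a PCR-free route); it is ignored for kits whose
    protocol fixes the answer.  All retention/conversion values are neutral
    placeholders; see :func:`parameterize_kit`.
    """
    ext = "ligation_strand_extension"
    if name == "NEBNext":
        return KitProtocol(name, _classic(name))
    if name == "NEBNext Ultra":
        return KitProtocol(
            name,
            [
                ProtocolStep("combined_er_at"),
                ProtocolStep("adaptor_ligation"),
                ProtocolStep("bead_cleanup", label="post_ligation_cleanup"),
                ProtocolStep("pcr_amplification", pcr_params=_PLACEHOLDER_PCR),
                ProtocolStep("pcr_cleanup"),
            ],
        )
    if name == "SureSelectXT":
        return KitProtocol(name, _classic(name))
    if name == "Truseq Nano":
        return KitProtocol(
            name,
            [
                ProtocolStep("end_repair"),
                ProtocolStep("bead_cleanup", label="post_er_cleanup"),
                ProtocolStep("a_tail"),
                ProtocolStep("adaptor_ligation"),
                ProtocolStep("bead_cleanup", label="post_ligation_cleanup"),
                ProtocolStep("pcr_amplification", pcr_params=_PLACEHOLDER_PCR),
                ProtocolStep("pcr_cleanup"),
            ],
            declared_inputs_ng=[500.0, 100.0],
        )
    if name == "Truseq DNA PCR-free":
        # adaptors already carry P5/P7, so ligation yields sequencable molecules
        return KitProtocol(
            name,
            [
                ProtocolStep("end_repair"),
                ProtocolStep("double_size_selection", label="post_er_size_selection"),
                ProtocolStep("a_tail"),
                ProtocolStep("bead_cleanup", label="post_at_cleanup"),
                ProtocolStep("adaptor_ligation", to_state="p5p7_flanked"),
                ProtocolStep("bead_cleanup", label="post_ligation_cleanup"),
            ],
        )
    if name == "Accel-NGS 1S":
        return KitProtocol(
            name,
            [
                ProtocolStep(ext, label="adaptase", from_state="sheared", to_state="end_repaired"),
                ProtocolStep(ext, label="extension_1", from_state="end_repaired", to_state="a_tailed"),
                ProtocolStep("bead_cleanup", label="post_ext1_cleanup"),
                ProtocolStep(ext, label="extension_2", from_state="a_tailed", to_state="adaptor_ligated"),
                ProtocolStep("bead_cleanup", label="post_ext2_cleanup"),
                ProtocolStep("pcr_amplification", pcr_params=_PLACEHOLDER_PCR),
                ProtocolStep("pcr_cleanup"),
            ],
            adaptor_channel_measurable=False,
            declared_inputs_ng=[500.0, 100.0],
        )
    if name == "Accel-NGS 2S":
        # assumed decomposition of "4 different steps + 4 bead cleaning";
        # the 4th conversion completes stragglers of the second-strand ligation
        return KitProtocol(
            name,
            [
                ProtocolStep(ext, label="conversion_1", from_state="sheared", to_state="end_repaired"),
                ProtocolStep("bead_cleanup", label="cleanup_1"),
                ProtocolStep(ext, label="conversion_2", from_state="end_repaired", to_state="a_tailed"),
                ProtocolStep("bead_cleanup", label="cleanup_2"),
                ProtocolStep(ext, label="conversion_3", from_state="a_tailed", to_state="adaptor_ligated"),
                ProtocolStep("bead_cleanup", label="cleanup_3"),
                ProtocolStep(ext, label="conversion_4", from_state="a_tailed", to_state="adaptor_ligated"),
                ProtocolStep("bead_cleanup", label="cleanup_4"),
                ProtocolStep("pcr_amplification", pcr_params=_PLACEHOLDER_PCR),
                ProtocolStep("pcr_cleanup"),
            ],
            adaptor_channel_measurable=False,
            declared_inputs_ng=[500.0, 20.0],
        )
    if name in ("KAPA Hyper", "KAPA HyperPlus"):
        if with_pcr is None:
            with_pcr = True
        if name == "KAPA Hyper":
            steps = [ProtocolStep("combined_er_at")]
            inputs = [500.0]
        else:
            # fragmentase + end prep in a single reaction: unsheared input goes
            # straight to A-tailed fragments with no intermediate cleanup
            steps = [
                ProtocolStep(
                    "enzymatic_fragmentation",
                    label="fragmentation_end_prep",
                    from_state="sheared",
                    to_state="a_tailed",
                )
            ]
            inputs = [500.0, 20.0]
        steps += [
            ProtocolStep("adaptor_ligation"),
            ProtocolStep("bead_cleanup", label="post_ligation_cleanup"),
        ]
        if with_pcr:
            steps += [
                ProtocolStep("pcr_amplification", pcr_params=_PLACEHOLDER_PCR),
                ProtocolStep("pcr_cleanup"),
            ]
        return KitProtocol(name, steps, declared_inputs_ng=inputs)
    raise ConfigurationError(f"unknown kit {name!r}")


KIT_NAMES = (
    "NEBNext",
    "NEBNext Ultra",
    "SureSelectXT",
    "Truseq Nano",
    "Truseq DNA PCR-free",
    "Accel-NGS 1S",
    "Accel-NGS 2S",
    "KAPA Hyper",
    "KAPA HyperPlus",
)


def builtin_kits() -> dict[str, KitProtocol]:
    """The nine built-in kit workflows (KAPA kits in their with-PCR variant)."""
    return {name: kit_protocol(name) for name in KIT_NAMES}


def parameterize_kit(
    kit: KitProtocol,
    cleanup_retention: float | Callable[[float], float] | None = None,
    conversion_efficiencies: Mapping[str, float] | float | None = None,
    pcr: PcrParams | None = None,
    step_retention: Mapping[str, float] | None = None,
) -> KitProtocol:
    """Return a copy of ``kit`` with concrete efficiency parameters.

    ``cleanup_retention`` applies to every cleanup/size-selection step (a
    callable is installed as a per-length retention curve).
    ``conversion_efficiencies`` maps step labels to efficiencies (a scalar
    applies to every chemical step).  ``step_retention`` overrides retention
    for individual labels.
    """
    new_steps = []
    for st in kit.steps:
        st = replace(st)
        if st.kind in ("bead_cleanup", "double_size_selection", "pcr_cleanup"):
            if callable(cleanup_retention):
                st.size_retention = cleanup_retention
            elif cleanup_retention is not None:
                st.retention = float(cleanup_retention)
        if st.is_chemical and conversion_efficiencies is not None:
            if isinstance(conversion_efficiencies, Mapping):
                if st.label in conversion_efficiencies:
                    st.conversion_efficiency = float(conversion_efficiencies[st.label])
            else:
                st.conversion_efficiency = float(conversion_efficiencies)
        if st.kind == "pcr_amplification" and pcr is not None:
            st.pcr_params = pcr
        if step_retention and st.label in step_retention:
            st.retention = float(step_retention[st.label])
            st.size_retention = None
        new_steps.append(st)
    return KitProtocol(
        name=kit.name,
        steps=new_steps,
        adaptor_channel_measurable=kit.adaptor_channel_measurable,
        declared_inputs_ng=list(kit.declared_inputs_ng),
    )


# ---------------------------------------------------------------------------
# Kit (de)serialization — structured-config schema
# ---------------------------------------------------------------------------


def kit_to_dict(kit: KitProtocol) -> dict:
    steps = []
    for st in kit.steps:
        d: dict = {"kind": st.kind, "label": st.label, "retention": st.retention}
        if st.is_chemical:
            d["conversion_efficiency"] = st.conversion_efficiency
            d["from_state"] = st.from_state
            d["to_state"] = st.to_state
        if isinstance(st.size_retention, LogisticSizeRetention):
            sr = st.size_retention
            d["size_retention"] = {
                "midpoint_bp": sr.midpoint_bp,
                "scale_bp": sr.scale_bp,
                "floor": sr.floor,
                "ceiling": sr.ceiling,
            }
        if st.pcr_params is not None:
            p = st.pcr_params
            d["pcr_params"] = {
                "cycles": p.cycles,
                "per_cycle_efficiency": p.per_cycle_efficiency,
                "capacity": None if math.isinf(p.capacity) else p.capacity,
            }
        steps.append(d)
    return {
        "name": kit.name,
        "adaptor_channel_measurable": kit.adaptor_channel_measurable,
        "declared_inputs_ng": list(kit.declared_inputs_ng),
        "steps": steps,
    }


def kit_from_dict(d: Mapping) -> KitProtocol:
    steps = []
    for sd in d["steps"]:
        kwargs = dict(
            kind=sd["kind"],
            label=sd.get("label", ""),
            retention=float(sd.get("retention", 1.0)),
            conversion_efficiency=sd.get("conversion_efficiency"),
            from_state=sd.get("from_state"),
            to_state=sd.get("to_state"),
        )
        if "size_retention" in sd:
            kwargs["size_retention"] = LogisticSizeRetention(**sd["size_retention"])
        if "pcr_params" in sd:
            p = dict(sd["pcr_params"])
            if p.get("capacity") is None:
                p["capacity"] = math.inf
            kwargs["pcr_params"] = PcrParams(**p)
        steps.append(ProtocolStep(**kwargs))
    return KitProtocol(
        name=d["name"],
        steps=steps,
        adaptor_channel_measurable=bool(d.get("adaptor_channel_measurable", True)),
        declared_inputs_ng=[float(x) for x in d.get("declared_inputs_ng", [500.0])],
    )
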