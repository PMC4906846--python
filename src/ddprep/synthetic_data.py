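"""Synthetic study generator with known ground truth.

Emulates the study design end to end: an equimolar mixture of three control
amplicons (214/397/568 bp) sharing a homologous detection region, processed
in silico through the built-in kit workflows with per-kit ligation-chain
efficiencies, size-dependent bead-cleanup losses and a saturating PCR; each
sample measured by triplicate three-channel ddPCR wells (20,000 droplets,
molecules assigned uniformly at random to droplets); and 150-base paired-end
reads with low mismatch/indel rates emitted as aligned SAM against the
amplicon reference.  Every simulated parameter is written to a truth file so
the analysis modules can be validated against known values.

All randomness flows from a single user seed through spawned substreams, so
a fixed seed reproduces the study byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .ddpcr_quant import DropletRun, CHANNELS
from .dilution_planner import DilutionPlan, molecules_from_mass, plan_dilution
from .protocol_model import (
    AMPLICONS,
    FragmentSpecies,
    KitProtocol,
    LogisticSizeRetention,
    PcrParams,
    SamplePopulation,
    builtin_kits,
    parameterize_kit,
    run_protocol,
)

__all__ = [
    "CHANNEL_STATES",
    "LIGATION_STEP_LABELS",
    "DEFAULT_LIGATION_EFFICIENCIES",
    "StudyConfig",
    "StudyTruth",
    "simulate_droplet_partition",
    "simulate_measurement",
    "generate_study",
    "amplicon_references",
    "simulate_reads",
]

#: Which molecule end-states each primer channel detects.
CHANNEL_STATES = {
    "phix_total": frozenset(
        {"sheared", "end_repaired", "a_tailed", "adaptor_ligated", "p5p7_flanked"}
    ),
    "adaptor": frozenset({"adaptor_ligated", "p5p7_flanked"}),
    "p5p7": frozenset({"p5p7_flanked"}),
}

#: Step label completing the ligation chain in each built-in kit.
LIGATION_STEP_LABELS = {
    "NEBNext": "adaptor_ligation",
    "NEBNext Ultra": "adaptor_ligation",
    "SureSelectXT": "adaptor_ligation",
    "Truseq Nano": "adaptor_ligation",
    "Truseq DNA PCR-free": "adaptor_ligation",
    "Accel-NGS 1S": "extension_2",
    "Accel-NGS 2S": "conversion_3",
    "KAPA Hyper": "adaptor_ligation",
    "KAPA HyperPlus": "adaptor_ligation",
}

#: Default true ligation-chain efficiencies, one per kit, spanning the
#: reported range (3.5 % .. 100 %).  The Accel kits could not be assayed on
#: the adaptor channel in the wet lab; their truth values exist only to
#: drive the simulation.
DEFAULT_LIGATION_EFFICIENCIES = {
    "NEBNext": 0.20,
    "NEBNext Ultra": 0.035,
    "SureSelectXT": 0.15,
    "Truseq Nano": 0.30,
    "Truseq DNA PCR-free": 0.35,
    "Accel-NGS 1S": 0.20,
    "Accel-NGS 2S": 0.20,
    "KAPA Hyper": 0.40,
    "KAPA HyperPlus": 1.0,
}

# Table-style oligo fixtures embedded in the synthetic amplicons: forward
# primers (one per amplicon), the shared probe and the shared reverse primer.
_FWD_PRIMERS = {
    "A214": "GGCGCTCGTCTTTGGTATGT",
    "B397": "TGAATTGTTCGCGTTTACCTT",
    "C568": "GTACGCTGGACTTTGTAGGAT",
}
_PROBE = "GCGATAACCGGAGTAGTTGAAATG"
_REV_PRIMER = "GGCGTCCATCTCGAAG"

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def simulate_droplet_partition(
    molecules_in_reaction: int,
    n_droplets: int = 20_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    **run_fields,
) -> DropletRun:
    """Throw each molecule into a uniformly random droplet and count occupied.

    Extra keyword arguments populate the returned :class:`DropletRun`
    metadata (sample/step/channel/dilution...).
    """
    if molecules_in_reaction < 0 or n_droplets <= 0:
        raise ValueError("inputs must be non-negative / positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = int(molecules_in_reaction)
    if m == 0:
        positive = 0
    elif m <= 5_000_000:
        positive = int(np.unique(rng.integers(0, n_droplets, size=m)).size)
    else:
        # droplet saturation regime: occupancy is astronomically high and the
        # realized count of empty droplets is effectively its expectation
        positive = int(round(n_droplets * (1.0 - (1.0 - 1.0 / n_droplets) ** m)))
    defaults = dict(
        sample_id="sim",
        step_label="sim",
        channel="phix_total",
        replicate=1,
        dilution_factor=1.0,
    )
    defaults.update(run_fields)
    return DropletRun(n_droplets=n_droplets, n_positive=positive, **defaults)


def simulate_measurement(
    pop: SamplePopulation,
    channel: str,
    plan: DilutionPlan,
    replicates: int = 3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_droplets: int = 20_000,
    measurable: bool = True,
    sample_id: str = "sim",
    step_label: str = "sim",
) -> list[DropletRun]:
    """Triplicate (by default) ddPCR wells for one sample/channel.

    The channel-eligible molecules of the population are thinned binomially
    by the dilution and template fraction, then partitioned into droplets;
    each replicate uses its own substream.  A channel that cannot be assayed
    for this kit returns an empty (flagged-empty) list.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    if not measurable:
        return []
    if rng is None:
        rng = np.random.default_rng(seed)
    eligible = int(round(pop.count_in_states(CHANNEL_STATES[channel])))
    # 1 µL template aliquot per reaction: thin each molecule by
    # template_volume / (sample_volume * dilution)
    template_volume_ul = 1.0
    p = template_volume_ul / (pop.volume_ul * plan.dilution_factor)
    runs = []
    for rep in range(1, replicates + 1):
        in_rx = int(rng.binomial(eligible, p)) if eligible > 0 else 0
        runs.append(
            simulate_droplet_partition(
                in_rx,
                n_droplets=n_droplets,
                rng=rng,
                sample_id=sample_id,
                step_label=step_label,
                channel=channel,
                replicate=rep,
                dilution_factor=plan.dilution_factor,
                template_volume_ul=template_volume_ul,
                sample_volume_ul=pop.volume_ul,
            )
        )
    return runs


# ---------------------------------------------------------------------------
# Study configuration and truth
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Conditions of the simulated study (defaults mirror the wet-lab design)."""

    kits: Sequence[str] = field(default_factory=lambda: list(DEFAULT_LIGATION_EFFICIENCIES))
    input_ng: float = 500.0
    seed: int = 0
    replicates: int = 3
    n_droplets: int = 20_000
    sample_volume_ul: float = 50.0
    molecule_cap: int = 10_000
    ligation_efficiencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIGATION_EFFICIENCIES)
    )
    cleanup_retention: float = 0.9
    #: per-length cleanup retention emulating preferential short-fragment
    #: loss; set to None for flat retention
    cleanup_size_retention: LogisticSizeRetention | None = field(
        default_factory=lambda: LogisticSizeRetention(
            midpoint_bp=180.0, scale_bp=60.0, floor=0.55, ceiling=0.95
        )
    )
    #: the stringent double size selection of the PCR-free workflow
    double_selection_retention: float = 0.25
    pcr: PcrParams = field(
        default_factory=lambda: PcrParams(
            cycles=6, per_cycle_efficiency=0.95, capacity=4e12
        )
    )
    n_read_pairs: int = 2000
    read_length: int = 150
    mismatch_rate: float = 0.001
    insertion_rate: float = 0.0002
    deletion_rate: float = 0.0


@dataclass
class StudyTruth:
    """Every parameter and latent trajectory behind a generated study."""

    seed: int
    input_ng: float
    input_molecules: float
    kits: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _parameterized_kit(kit: KitProtocol, cfg: StudyConfig) -> KitProtocol:
    lig_label = LIGATION_STEP_LABELS[kit.name]
    conv = {lig_label: cfg.ligation_efficiencies[kit.name]}
    if kit.name == "Accel-NGS 2S":
        conv["conversion_4"] = 0.0  # stragglers not recovered in the default truth
    retention = (
        cfg.cleanup_size_retention
        if cfg.cleanup_size_retention is not None
        else cfg.cleanup_retention
    )
    k = parameterize_kit(
        kit,
        cleanup_retention=retention,
        conversion_efficiencies=conv,
        pcr=cfg.pcr,
    )
    if kit.name == "Truseq DNA PCR-free":
        k = parameterize_kit(
            k, step_retention={"post_er_size_selection": cfg.double_selection_retention}
        )
    return k


def _measurement_points(kit: KitProtocol) -> dict[str, int]:
    """Trajectory indices (into run_protocol output) of the assayed samples."""
    labels = [s.label for s in kit.steps]
    lig_label = LIGATION_STEP_LABELS[kit.name]
    i_lig = labels.index(lig_label)
    points = {"input": 0, "post_a_tailing": i_lig}  # sample entering ligation
    # sample after the ligation stage's cleanup (or the ligation itself)
    i = i_lig + 1
    while i < len(labels) and kit.steps[i].kind in ("bead_cleanup", "double_size_selection"):
        i += 1
    points["post_ligation"] = i
    if kit.has_pcr:
        points["post_pcr"] = len(labels)  # final sample
    return points


def generate_study(config: StudyConfig, outdir: str | Path) -> StudyTruth:
    """Generate every pipeline input with known truth under ``outdir``.

    Writes ``droplet_counts.csv``, ``manifest.tsv``, ``fragment_ratios.tsv``,
    ``reference.fasta``, one ``<sample>.sam`` per kit, ``kits.json`` and
    ``truth.json``.  Deterministic for a fixed config.
    """
    import pandas as pd

    from .protocol_model import kit_to_dict

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(config.seed)
    kit_seeds = root_ss.spawn(len(config.kits))

    composition = [(L, 1.0 / len(AMPLICONS)) for L in AMPLICONS.values()]
    input_molecules = molecules_from_mass(config.input_ng, composition)

    refs = amplicon_references(np.random.default_rng(root_ss.spawn(1)[0]))
    _write_fasta(refs, outdir / "reference.fasta")

    truth = StudyTruth(
        seed=config.seed, input_ng=config.input_ng, input_molecules=input_molecules
    )
    droplet_rows: list[DropletRun] = []
    manifest_rows = []
    ratio_rows = []
    kit_dicts = {}

    for kit_name, ss in zip(config.kits, kit_seeds):
        base = builtin_kits()[kit_name]
        kit = _parameterized_kit(base, config)
        kit_dicts[kit_name] = kit_to_dict(kit)
        sample_id = kit_name.replace(" ", "_")
        rng = np.random.default_rng(ss)

        pop0 = SamplePopulation(
            counts={
                FragmentSpecies(a, L, "sheared"): float(round(input_molecules / len(AMPLICONS)))
                for a, L in AMPLICONS.items()
            },
            volume_ul=config.sample_volume_ul,
        )
        traj = run_protocol(pop0, kit, mode="stochastic", seed=int(rng.integers(2**31)))
        points = _measurement_points(kit)

        for step_name, idx in points.items():
            pop = traj[idx][1]
            channels = ["phix_total"]
            if step_name == "post_ligation":
                channels.append("adaptor")
                if not kit.has_pcr:  # PCR-free: ligation products are the library
                    channels.append("p5p7")
            if step_name == "post_pcr":
                channels.append("p5p7")
            for channel in channels:
                measurable = kit.adaptor_channel_measurable or channel != "adaptor"
                eligible = pop.count_in_states(CHANNEL_STATES[channel])
                plan = plan_dilution(
                    max(eligible, 1.0),
                    sample_volume_ul=pop.volume_ul,
                    template_volume_ul=1.0,
                    cap=config.molecule_cap,
                    step_label=step_name,
                )
                droplet_rows.extend(
                    simulate_measurement(
                        pop,
                        channel,
                        plan,
                        replicates=config.replicates,
                        rng=rng,
                        n_droplets=config.n_droplets,
                        measurable=measurable,
                        sample_id=sample_id,
                        step_label=step_name,
                    )
                )

        # pre/post fragment molar ratios (concentration per µL of sample)
        for stage, idx in (("pre", 0), ("post", len(kit.steps))):
            pop = traj[idx][1]
            per_amp: dict[str, float] = {a: 0.0 for a in AMPLICONS}
            for sp, c in pop.counts.items():
                per_amp[sp.amplicon_id] += c
            for a, c in per_amp.items():
                ratio_rows.append(
                    dict(
                        sample_id=sample_id,
                        stage=stage,
                        amplicon_id=a,
                        molar_concentration=c / pop.volume_ul,
                    )
                )

        # reads from the final library composition
        final_pop = traj[-1][1]
        lib_states = (
            CHANNEL_STATES["p5p7"] if kit.has_pcr else CHANNEL_STATES["adaptor"]
        )
        weights = {a: 0.0 for a in AMPLICONS}
        for sp, c in final_pop.counts.items():
            if sp.end_state in lib_states:
                weights[sp.amplicon_id] += c
        simulate_reads(
            refs,
            weights,
            outdir / f"{sample_id}.sam",
            n_pairs=config.n_read_pairs,
            read_length=config.read_length,
            mismatch_rate=config.mismatch_rate,
            insertion_rate=config.insertion_rate,
            deletion_rate=config.deletion_rate,
            rng=rng,
        )

        manifest_rows.append(
            dict(
                sample_id=sample_id,
                kit=kit_name,
                input_ng=config.input_ng,
                ligation_step="post_ligation",
                pcr_step="post_pcr" if kit.has_pcr else "",
                adaptor_measurable=kit.adaptor_channel_measurable,
                sam_file=f"{sample_id}.sam",
            )
        )
        truth.kits[kit_name] = {
            "ligation_chain_efficiency": config.ligation_efficiencies[kit_name],
            "pcr": {
                "cycles": config.pcr.cycles,
                "per_cycle_efficiency": config.pcr.per_cycle_efficiency,
                "capacity": config.pcr.capacity,
            }
            if kit.has_pcr
            else None,
            "state_totals_by_step": {
                f"{i}:{label}": pop.state_totals() for i, (label, pop) in enumerate(traj)
            },
            "measurement_points": points,
        }

    pd.DataFrame([asdict(r) for r in droplet_rows]).to_csv(
        outdir / "droplet_counts.csv", index=False
    )
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame(ratio_rows).to_csv(outdir / "fragment_ratios.tsv", sep="\t", index=False)
    Path(outdir / "kits.json").write_text(json.dumps(kit_dicts, indent=1, sort_keys=True))
    truth.to_json(outdir / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# Reference sequences and read simulation
# ---------------------------------------------------------------------------


def amplicon_references(rng: np.random.Generator) -> dict[str, str]:
    """Synthetic amplicon sequences with the assay oligo sites embedded.

    Each amplicon starts with its forward primer and ends with the shared
    homologous region (Taqman probe site + reverse-primer binding site);
    the filler between is random.  True genomic coordinates are not modelled.
    """
    shared = _PROBE + "".join(rng.choice(_BASES, size=20)) + _revcomp(_REV_PRIMER)
    refs = {}
    for amp, L in AMPLICONS.items():
        fwd = _FWD_PRIMERS[amp]
        fill = L - len(fwd) - len(shared)
        refs[amp] = fwd + "".join(rng.choice(_BASES, size=fill)) + shared
        assert len(refs[amp]) == L
    return refs


def _write_fasta(refs: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in refs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _mutate_segment(
    ref: str,
    start: int,
    read_length: int,
    rng: np.random.Generator,
    p_mm: float,
    p_ins: float,
    p_del: float,
) -> tuple[str, list[tuple[int, int]], str, int]:
    """Copy a reference window into a read with point errors.

    Returns (query sequence, cigartuples, MD string, reference bases
    consumed).  MD covers matches, mismatched reference bases and deleted
    reference bases (^); insertions are invisible to MD, as in SAM.
    """
    seq: list[str] = []
    cigar: list[tuple[int, int]] = []
    md: list[str] = []
    match_run = 0
    rpos = start

    def push(op: int, length: int = 1) -> None:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))

    while len(seq) < read_length and rpos < len(ref):
        u = rng.random()
        if u < p_del:
            md.append(str(match_run))
            match_run = 0
            md.append("^" + ref[rpos])
            push(2)  # D
            rpos += 1
        elif u < p_del + p_ins:
            seq.append(str(rng.choice(_BASES)))
            push(1)  # I
        else:
            base = ref[rpos]
            if rng.random() < p_mm:
                choices = [b for b in "ACGT" if b != base]
                newbase = choices[int(rng.integers(3))]
                md.append(str(match_run))
                match_run = 0
                md.append(base)
                seq.append(newbase)
            else:
                seq.append(base)
                match_run += 1
            push(0)  # M
            rpos += 1
    md.append(str(match_run))
    return "".join(seq), cigar, "".join(md), rpos - start


def simulate_reads(
    refs: Mapping[str, str],
    weights: Mapping[str, float],
    sam_path: str | Path,
    n_pairs: int = 2000,
    read_length: int = 150,
    mismatch_rate: float = 0.001,
    insertion_rate: float = 0.0,
    deletion_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> None:
    """Write aligned paired-end reads as SAM with CIGAR, MD and NM tags.

    Pairs are drawn from the amplicons proportionally to ``weights``; mate 1
    starts at the 5' end, mate 2 covers the 3' end on the reverse strand.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    names = list(refs)
    w = np.array([max(weights.get(n, 0.0), 0.0) for n in names], dtype=float)
    if w.sum() <= 0:
        w = np.ones(len(names))
    w = w / w.sum()

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(refs[n])} for n in names],
    }
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for i in range(n_pairs):
            tid = int(rng.choice(len(names), p=w))
            ref = refs[names[tid]]
            rl = min(read_length, len(ref))
            starts = (0, len(ref) - rl)
            for mate, (start, is_rev) in enumerate(zip(starts, (False, True))):
                seq, cigar, md, span = _mutate_segment(
                    ref, start, rl, rng, mismatch_rate, insertion_rate, deletion_rate
                )
                a = pysam.AlignedSegment()
                a.query_name = f"pair{i:06d}"
                a.flag = (
                    0x1 | 0x2 | (0x40 if mate == 0 else 0x80) | (0x10 if is_rev else 0x20)
                )
                a.reference_id = tid
                a.reference_start = start
                a.mapping_quality = 60
                a.cigartuples = cigar
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                a.next_reference_id = tid
                a.next_reference_start = starts[1 - mate]
                a.template_length = (len(ref)) * (1 if mate == 0 else -1)
                a.set_tag("MD", md)
                a.set_tag("NM", _nm_from(md, cigar))
                out.write(a)


def _nm_from(md: str, cigar: list[tuple[int, int]]) -> int:
    """Edit distance: mismatches (from MD) plus inserted and deleted bases."""
    nm = sum(l for op, l in cigar if op in (1, 2))
    i = 0
    while i < len(md):
        ch = md[i]
        if ch == "^":
            i += 1
            while i < len(md) and md[i].isalpha():
                i += 1
        elif ch.isalpha():
            nm += 1
            i += 1
        else:
            i += 1
    return nm
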