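"""File formats, validation and the end-to-end pipeline.

One flat delimited schema per artifact: droplet-count tables (CSV/TSV with
exactly the DropletRun fields as columns), a per-sample manifest, merged
concentration estimates, yield/bias/error reports, and YAML kit configs.
Readers validate row by row and name the offending row in error messages;
writers never leak NaN — unavailable values are left empty alongside an
explicit flag column.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .ddpcr_quant import CHANNELS, DropletRun, MergedEstimate, merge_replicates
from .error_rates import error_rates_from_sam
from .fragment_bias import FragmentRatioTable, ratio_variation
from .protocol_model import KitProtocol, kit_from_dict, kit_to_dict
from .yield_engine import (
    ChannelMeasurement,
    MeasurementSet,
    YieldReport,
    build_yield_report,
)

__all__ = [
    "RunConfig",
    "read_droplet_table",
    "write_droplet_table",
    "quantify_droplet_table",
    "write_estimates",
    "read_manifest",
    "measurement_sets_from_estimates",
    "read_ratio_tables",
    "write_kit_yaml",
    "read_kit_yaml",
    "run_pipeline",
]

logger = logging.getLogger("ddprep")

_DROPLET_COLUMNS = [
    "sample_id",
    "step_label",
    "channel",
    "replicate",
    "n_droplets",
    "n_positive",
    "dilution_factor",
    "template_volume_ul",
    "droplet_volume_nl",
    "sample_volume_ul",
]


@dataclass
class RunConfig:
    """Paths and defaults for one pipeline run."""

    input_dir: str | Path
    output_dir: str | Path
    ci_level: float = 0.95
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_droplet_table(path: str | Path) -> list[DropletRun]:
    """Read and validate a droplet-count table (CSV or TSV)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in _DROPLET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    runs = []
    for i, row in df.iterrows():
        try:
            runs.append(
                DropletRun(
                    sample_id=str(row.sample_id),
                    step_label=str(row.step_label),
                    channel=str(row.channel),
                    replicate=int(row.replicate),
                    n_droplets=int(row.n_droplets),
                    n_positive=int(row.n_positive),
                    dilution_factor=float(row.dilution_factor),
                    template_volume_ul=float(row.template_volume_ul),
                    droplet_volume_nl=float(row.droplet_volume_nl),
                    sample_volume_ul=float(row.sample_volume_ul),
                )
            )
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}, row {i}: {err}") from err
    return runs


def write_droplet_table(runs: list[DropletRun], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in runs])[_DROPLET_COLUMNS].to_csv(
        path, sep=_sep_for(path), index=False
    )


def quantify_droplet_table(
    runs: list[DropletRun], ci_level: float = 0.95
) -> dict[tuple[str, str, str], MergedEstimate]:
    """Merge replicate wells: (sample, step, channel) -> pooled estimate."""
    groups: dict[tuple[str, str, str], list[DropletRun]] = {}
    for r in runs:
        groups.setdefault((r.sample_id, r.step_label, r.channel), []).append(r)
    return {k: merge_replicates(v, ci_level) for k, v in groups.items()}


def write_estimates(
    estimates: Mapping[tuple[str, str, str], MergedEstimate], path: str | Path
) -> None:
    rows = []
    for (sample, step, channel), m in sorted(estimates.items()):
        sat = m.saturated
        rows.append(
            {
                "sample_id": sample,
                "step_label": step,
                "channel": channel,
                "n_replicates": m.n_replicates,
                "absolute_molecules": "" if sat else m.pooled.absolute_molecules_undiluted,
                "ci95_low": m.pooled.ci95[0],
                "ci95_high": "" if math.isinf(m.pooled.ci95[1]) else m.pooled.ci95[1],
                "replicate_sd": m.replicate_sd,
                "saturated": sat,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").fillna("")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: manifest needs a sample_id column")
    return df


def measurement_sets_from_estimates(
    estimates: Mapping[tuple[str, str, str], MergedEstimate],
    manifest: pd.DataFrame,
) -> dict[str, tuple[MeasurementSet, str, str]]:
    """Assemble one MeasurementSet per manifest sample.

    The protocol input is taken from the sample's own ddPCR measurement at
    step ``input`` on the amplicon-total channel.  Returns sample_id ->
    (measurement set, ligation step label, pcr step label).
    """
    out = {}
    for _, row in manifest.iterrows():
        sample = str(row.sample_id)
        key = (sample, "input", "phix_total")
        if key not in estimates:
            logger.warning("%s: no input measurement; skipping", sample)
            continue
        inp = estimates[key]
        steps: dict[str, dict[str, ChannelMeasurement]] = {}
        for (s, step, channel), m in estimates.items():
            if s != sample or step == "input":
                continue
            steps.setdefault(step, {})[channel] = ChannelMeasurement.from_merged(m)
        lig_step = str(row.get("ligation_step", "post_ligation")) or "post_ligation"
        adaptor_measurable = bool(row.get("adaptor_measurable", True))
        if lig_step in steps and not adaptor_measurable:
            steps[lig_step]["adaptor"] = ChannelMeasurement.not_measured()
        ms = MeasurementSet(
            sample_id=sample,
            input_total=inp.pooled.absolute_molecules_undiluted,
            input_sd=inp.replicate_sd,
            steps=steps,
        )
        out[sample] = (ms, lig_step, str(row.get("pcr_step", "post_pcr")) or "post_pcr")
    return out


def read_ratio_tables(path: str | Path) -> dict[str, dict[str, FragmentRatioTable]]:
    """sample_id -> stage ('pre'/'post') -> ratio table."""
    df = pd.read_csv(path, sep=_sep_for(path))
    need = {"sample_id", "stage", "amplicon_id", "molar_concentration"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(need)}")
    out: dict[str, dict[str, FragmentRatioTable]] = {}
    for (sample, stage), grp in df.groupby(["sample_id", "stage"]):
        out.setdefault(str(sample), {})[str(stage)] = FragmentRatioTable(
            dict(zip(grp.amplicon_id, grp.molar_concentration.astype(float)))
        )
    return out


def write_kit_yaml(kits: Mapping[str, KitProtocol], path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({name: kit_to_dict(k) for name, k in kits.items()}, sort_keys=False)
    )


def read_kit_yaml(path: str | Path) -> dict[str, KitProtocol]:
    data = yaml.safe_load(Path(path).read_text())
    return {name: kit_from_dict(d) for name, d in data.items()}


def _yield_frame(reports: list[YieldReport]) -> pd.DataFrame:
    df = pd.concat([r.to_dataframe() for r in reports], ignore_index=True)
    return df


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Quantify, compute yields, fragment bias and error rates for a study.

    Expects under ``input_dir``: droplet_counts.csv and manifest.tsv
    (mandatory), fragment_ratios.tsv, reference.fasta and per-sample SAM
    files (optional).  Writes estimates.tsv, yields.tsv, yields.json and —
    when inputs allow — bias.tsv and error_rates.tsv under ``output_dir``.
    Deterministic given the inputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    indir = Path(config.input_dir)
    droplets_path = indir / "droplet_counts.csv"
    manifest_path = indir / "manifest.tsv"
    if not droplets_path.exists() or not manifest_path.exists():
        raise FileNotFoundError(
            f"{indir}: need droplet_counts.csv and manifest.tsv to run the pipeline"
        )
    runs = read_droplet_table(droplets_path)
    manifest = read_manifest(manifest_path)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    logger.info("quantifying %d wells (CI level %.2f)", len(runs), config.ci_level)
    estimates = quantify_droplet_table(runs, ci_level=config.ci_level)
    write_estimates(estimates, outdir / "estimates.tsv")
    written["estimates"] = outdir / "estimates.tsv"

    reports = []
    for sample, (ms, lig, pcr) in measurement_sets_from_estimates(
        estimates, manifest
    ).items():
        reports.append(build_yield_report(ms, ligation_step=lig, pcr_step=pcr))
    ydf = _yield_frame(reports)
    ydf.to_csv(outdir / "yields.tsv", sep="\t", index=False, na_rep="")
    (outdir / "yields.json").write_text(
        json.dumps(
            [
                {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in rec.items()}
                for rec in ydf.to_dict(orient="records")
            ],
            indent=1,
        )
    )
    written["yields"] = outdir / "yields.tsv"

    ratios_path = indir / "fragment_ratios.tsv"
    if ratios_path.exists():
        rows = []
        for sample, stages in read_ratio_tables(ratios_path).items():
            if {"pre", "post"} <= set(stages):
                rv = ratio_variation(stages["pre"], stages["post"])
                for amp, d in sorted(rv.deltas.items()):
                    rows.append(
                        {"sample_id": sample, "amplicon_id": amp, "delta_percentage_points": d}
                    )
        pd.DataFrame(rows).to_csv(outdir / "bias.tsv", sep="\t", index=False)
        written["bias"] = outdir / "bias.tsv"

    ref = indir / "reference.fasta"
    if "sam_file" in manifest.columns:
        rows = []
        for _, row in manifest.iterrows():
            sam = indir / str(row.sam_file)
            if not str(row.sam_file) or not sam.exists():
                continue
            rep = error_rates_from_sam(str(sam), str(ref) if ref.exists() else None)
            rows.append(
                {
                    "sample_id": row.sample_id,
                    "mismatch_rate": rep.mismatch_rate,
                    "insertion_rate": rep.insertion_rate,
                    "deletion_rate": rep.deletion_rate,
                    "denominator_bases": rep.denominator_bases,
                }
            )
        if rows:
            pd.DataFrame(rows).to_csv(outdir / "error_rates.tsv", sep="\t", index=False)
            written["error_rates"] = outdir / "error_rates.tsv"
    return written
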