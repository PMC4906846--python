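"""Synthetic study generator: partition statistics, determinism, round trips."""

import json
import math
from pathlib import Path

import numpy as np
import pytest

from ddprep.ddpcr_quant import estimate_copies, merge_replicates
from ddprep.dilution_planner import plan_dilution
from ddprep.protocol_model import SamplePopulation
from ddprep.synthetic_data import (
    CHANNEL_STATES,
    StudyConfig,
    amplicon_references,
    generate_study,
    simulate_droplet_partition,
    simulate_measurement,
)


class TestDropletPartition:
    def test_zero_molecules_give_zero_positives(self):
        assert simulate_droplet_partition(0, seed=1).n_positive == 0

    def test_occupancy_matches_the_closed_form(self, rng):
        # E[positives] = N (1 - (1 - 1/N)^M)
        n, m, reps = 20_000, 10_000, 120
        draws = [
            simulate_droplet_partition(m, n_droplets=n, rng=rng).n_positive
            for _ in range(reps)
        ]
        expected = n * (1 - (1 - 1 / n) ** m)
        assert expected == pytest.approx(7869, abs=1.0)
        sem = np.std(draws, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(draws) - expected) <= 3 * sem

    def test_saturation_limit(self):
        run = simulate_droplet_partition(10_000_000, n_droplets=1000, seed=3)
        assert run.n_positive == 1000

    def test_estimator_inverts_the_partition(self, rng):
        for m in (200, 2000, 20_000):
            run = simulate_droplet_partition(m, rng=rng)
            est = estimate_copies(run)
            lam = m / 20_000
            se = math.sqrt(20_000 * (math.exp(lam) - 1))
            assert abs(est.copies_per_reaction - m) <= 3 * se


class TestSimulateMeasurement:
    def test_channel_without_eligible_molecules_reads_all_negative(self, rng):
        pop = SamplePopulation.equimolar(1e6, end_state="sheared")
        plan = plan_dilution(1e6, sample_volume_ul=50.0)
        runs = simulate_measurement(pop, "adaptor", plan, rng=rng)
        assert len(runs) == 3
        assert all(r.n_positive == 0 for r in runs)

    def test_total_channel_counts_every_end_state(self):
        assert CHANNEL_STATES["phix_total"] == frozenset(
            {"sheared", "end_repaired", "a_tailed", "adaptor_ligated", "p5p7_flanked"}
        )
        assert CHANNEL_STATES["p5p7"] < CHANNEL_STATES["adaptor"]

    def test_unmeasurable_channel_returns_flagged_empty(self, rng):
        pop = SamplePopulation.equimolar(1e6, end_state="adaptor_ligated")
        plan = plan_dilution(1e6)
        assert simulate_measurement(pop, "adaptor", plan, rng=rng, measurable=False) == []

    def test_triplicate_estimates_recover_the_eligible_count(self, rng):
        truth = 3.0e9
        pop = SamplePopulation.equimolar(truth, end_state="adaptor_ligated")
        plan = plan_dilution(truth, sample_volume_ul=50.0)
        runs = simulate_measurement(pop, "adaptor", plan, replicates=3, rng=rng)
        merged = merge_replicates(runs)
        est = merged.pooled.absolute_molecules_undiluted
        n_tot = sum(r.n_droplets for r in runs)
        lam = merged.pooled.copies_per_reaction / n_tot
        # binomial SE of the pooled occupancy, relative scale
        rel_se = math.sqrt((math.exp(lam) - 1) / n_tot) / lam
        assert abs(est - truth) <= 3 * est * rel_se


class TestAmpliconReferences:
    def test_lengths_and_embedded_assay_sites(self, rng):
        refs = amplicon_references(rng)
        assert {k: len(v) for k, v in refs.items()} == {"A214": 214, "B397": 397, "C568": 568}
        for seq in refs.values():
            assert "GCGATAACCGGAGTAGTTGAAATG" in seq  # shared probe site
        assert refs["A214"].startswith("GGCGCTCGTCTTTGGTATGT")
        # shared homologous 3' region across all three amplicons
        tails = {seq[-60:] for seq in refs.values()}
        assert len(tails) == 1


class TestGenerateStudy:
    def test_fixed_seed_reproduces_byte_identical_outputs(self, tmp_path):
        cfg = StudyConfig(kits=["KAPA Hyper"], seed=11, n_read_pairs=50)
        generate_study(cfg, tmp_path / "a")
        generate_study(cfg, tmp_path / "b")
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files_a == sorted(p.name for p in (tmp_path / "b").iterdir())
        for name in files_a:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_study_files_and_truth_inventory(self, study_dir):
        out, truth = study_dir
        for fname in (
            "droplet_counts.csv",
            "manifest.tsv",
            "fragment_ratios.tsv",
            "reference.fasta",
            "truth.json",
            "kits.json",
        ):
            assert (out / fname).exists()
        payload = json.loads((out / "truth.json").read_text())
        assert payload["kits"]["KAPA HyperPlus"]["ligation_chain_efficiency"] == 1.0
        assert payload["kits"]["Truseq DNA PCR-free"]["pcr"] is None

    def test_generated_tables_round_trip_through_the_readers(self, study_dir):
        from ddprep.io import read_droplet_table, read_manifest, read_ratio_tables

        out, _ = study_dir
        runs = read_droplet_table(out / "droplet_counts.csv")
        assert runs and all(r.n_positive <= r.n_droplets for r in runs)
        manifest = read_manifest(out / "manifest.tsv")
        assert set(manifest.sample_id) == {
            "NEBNext_Ultra", "Truseq_DNA_PCR-free", "Accel-NGS_1S", "KAPA_HyperPlus",
        }
        ratios = read_ratio_tables(out / "fragment_ratios.tsv")
        assert set(ratios["KAPA_HyperPlus"]) == {"pre", "post"}

    def test_accel_sample_has_no_adaptor_wells(self, study_dir):
        from ddprep.io import read_droplet_table

        out, _ = study_dir
        runs = read_droplet_table(out / "droplet_counts.csv")
        accel = [r for r in runs if r.sample_id == "Accel-NGS_1S"]
        assert accel and not any(r.channel == "adaptor" for r in accel)

    def test_every_well_respects_the_molecule_cap_in_expectation(self, study_dir):
        from ddprep.io import read_droplet_table

        out, _ = study_dir
        for r in read_droplet_table(out / "droplet_counts.csv"):
            est = estimate_copies(r)
            if not est.saturated:
                # estimated molecules per reaction stay near/below the cap
                assert est.copies_per_reaction <= 10_000 * 1.15
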