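"""Protocol model: step semantics, kit presets and conservation laws."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddprep.protocol_model import (
    AMPLICONS,
    ConfigurationError,
    FragmentSpecies,
    KitProtocol,
    LogisticSizeRetention,
    PcrParams,
    ProtocolStep,
    SamplePopulation,
    apply_step,
    builtin_kits,
    count_steps,
    kit_from_dict,
    kit_protocol,
    kit_to_dict,
    parameterize_kit,
    run_protocol,
)


def make_pop(count=1e6, state="a_tailed", volume=50.0):
    return SamplePopulation.equimolar(count, end_state=state, volume_ul=volume)


class TestApplyStep:
    def test_lossless_fully_efficient_ligation_relabels_without_loss(self):
        pop = make_pop(1e6, "a_tailed")
        out = apply_step(pop, ProtocolStep("adaptor_ligation"))
        assert out.total() == pytest.approx(1e6, abs=1e-6)
        assert out.state_totals()["adaptor_ligated"] == pytest.approx(1e6)
        assert out.state_totals()["a_tailed"] == 0.0

    def test_bead_cleanup_thins_all_species_keeping_end_states(self):
        pop = make_pop(1e12, "sheared")
        out = apply_step(pop, ProtocolStep("bead_cleanup", retention=0.9))
        assert out.total() == pytest.approx(9e11)
        assert set(sp.end_state for sp in out.counts) == {"sheared"}

    def test_pcr_amplification_fold_and_relabel(self):
        pop = make_pop(1e7, "adaptor_ligated")
        step = ProtocolStep(
            "pcr_amplification",
            pcr_params=PcrParams(cycles=6, per_cycle_efficiency=0.95),
        )
        out = apply_step(pop, step)
        # (1 + 0.95)^6 = 54.98-fold
        assert out.total() == pytest.approx(5.498e8, rel=1e-3)
        assert out.count_in_states(["p5p7_flanked"]) == out.total()

    def test_pcr_capacity_caps_the_product(self):
        pop = make_pop(1e7, "adaptor_ligated")
        step = ProtocolStep(
            "pcr_amplification",
            pcr_params=PcrParams(cycles=6, per_cycle_efficiency=0.95, capacity=1e8),
        )
        assert apply_step(pop, step).total() == pytest.approx(1e8)

    def test_non_amplifiable_species_pass_through_pcr(self):
        counts = {
            FragmentSpecies("A214", 214, "sheared"): 100.0,
            FragmentSpecies("A214", 214, "adaptor_ligated"): 10.0,
        }
        pop = SamplePopulation(counts=counts)
        step = ProtocolStep(
            "pcr_amplification", pcr_params=PcrParams(cycles=2, per_cycle_efficiency=1.0)
        )
        out = apply_step(pop, step)
        assert out.state_totals()["sheared"] == 100.0
        assert out.state_totals()["p5p7_flanked"] == pytest.approx(40.0)

    def test_partial_conversion_leaves_remainder_in_place(self):
        pop = make_pop(1000.0, "a_tailed")
        out = apply_step(pop, ProtocolStep("adaptor_ligation", conversion_efficiency=0.35))
        assert out.state_totals()["adaptor_ligated"] == pytest.approx(350.0)
        assert out.state_totals()["a_tailed"] == pytest.approx(650.0)
        assert out.total() == pytest.approx(1000.0)

    def test_size_retention_curve_is_length_dependent(self):
        pop = make_pop(3e6, "sheared")
        curve = LogisticSizeRetention(midpoint_bp=300.0, scale_bp=50.0)
        out = apply_step(pop, ProtocolStep("bead_cleanup", size_retention=curve))
        per_amp = {sp.amplicon_id: c for sp, c in out.counts.items()}
        assert per_amp["A214"] < per_amp["B397"] < per_amp["C568"]
        for amp, L in AMPLICONS.items():
            assert per_amp[amp] == pytest.approx(1e6 * curve(L))

    def test_unknown_kind_and_bad_modes_raise(self):
        with pytest.raises(ConfigurationError):
            ProtocolStep("sonicate_twice")
        pop = SamplePopulation({FragmentSpecies("A214", 214, "sheared"): 10.5})
        with pytest.raises(ValueError, match="integer"):
            apply_step(pop, ProtocolStep("bead_cleanup", retention=0.5), mode="stochastic", seed=1)
        with pytest.raises(ValueError, match="seed"):
            apply_step(make_pop(10), ProtocolStep("bead_cleanup"), mode="stochastic")

    def test_stochastic_mode_is_binomial_with_matching_expectation(self, rng):
        pop = SamplePopulation({FragmentSpecies("A214", 214, "a_tailed"): 10_000.0})
        step = ProtocolStep("adaptor_ligation", retention=0.8, conversion_efficiency=0.5)
        draws = [
            apply_step(pop, step, mode="stochastic", rng=rng).state_totals()["adaptor_ligated"]
            for _ in range(300)
        ]
        expected = apply_step(pop, step).state_totals()["adaptor_ligated"]
        se = math.sqrt(10_000 * 0.4 * 0.6 / 300)
        assert abs(np.mean(draws) - expected) < 3 * se


class TestRunProtocol:
    def test_empty_population_stays_empty(self):
        pop = make_pop(0.0, "sheared")
        traj = run_protocol(pop, kit_protocol("NEBNext"))
        assert all(p.total() == 0 for _, p in traj)

    def test_identity_chain_preserves_input(self):
        kit = kit_protocol("Truseq DNA PCR-free")  # no PCR, placeholders are 1.0
        pop = make_pop(1e9, "sheared")
        traj = run_protocol(pop, kit)
        assert traj[-1][1].total() == pytest.approx(1e9)
        assert traj[0] == ("input", pop)

    def test_retention_chain_composes_multiplicatively(self):
        kit = KitProtocol(
            "two-cleanups",
            [
                ProtocolStep("bead_cleanup", label="c1", retention=0.9),
                ProtocolStep("bead_cleanup", label="c2", retention=0.8),
            ],
        )
        traj = run_protocol(make_pop(1e10, "sheared"), kit)
        assert traj[-1][1].total() == pytest.approx(0.72e10)

    @given(rets=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    def test_conversion_free_chain_equals_product_of_retentions(self, rets):
        kit = KitProtocol(
            "chain",
            [ProtocolStep("bead_cleanup", label=f"c{i}", retention=r) for i, r in enumerate(rets)],
        )
        total = run_protocol(make_pop(1e9, "sheared"), kit)[-1][1].total()
        assert total == pytest.approx(1e9 * math.prod(rets), rel=1e-12, abs=1e-12)

    def test_monotone_loss_without_pcr(self):
        kit = parameterize_kit(
            kit_protocol("NEBNext", with_pcr=True),
            cleanup_retention=0.8,
            conversion_efficiencies=0.5,
        )
        traj = run_protocol(make_pop(1e9, "sheared"), kit)
        totals = [p.total() for _, p in traj]
        labels = ["input"] + [s.label for s in kit.steps]
        for i in range(1, len(totals)):
            if labels[i] != "pcr_amplification":
                assert totals[i] <= totals[i - 1] + 1e-6

    def test_stochastic_trajectory_matches_expected_within_3se(self, rng):
        kit = parameterize_kit(
            kit_protocol("NEBNext Ultra"),
            cleanup_retention=0.85,
            conversion_efficiencies={"adaptor_ligation": 0.3},
            pcr=PcrParams(cycles=4, per_cycle_efficiency=0.9),
        )
        n0 = 30_000
        pop = SamplePopulation({FragmentSpecies("A214", 214, "sheared"): float(n0)})
        expected = [p.total() for _, p in run_protocol(pop, kit)]
        reps = 1000
        sums = np.zeros(len(expected))
        sums2 = np.zeros(len(expected))
        for _ in range(reps):
            totals = [
                p.total()
                for _, p in run_protocol(pop, kit, mode="stochastic", seed=int(rng.integers(2**31)))
            ]
            sums += totals
            sums2 += np.square(totals)
        mean = sums / reps
        sd = np.sqrt(np.maximum(sums2 / reps - mean**2, 0.0))
        se = sd / math.sqrt(reps)
        for m, e, s in zip(mean, expected, se):
            assert abs(m - e) <= 3 * max(s, 1e-9)


class TestKits:
    # printed per-kit step totals after shearing
    EXPECTED = {
        "NEBNext": 8,
        "NEBNext Ultra": 5,
        "SureSelectXT": 8,
        "Truseq Nano": 7,
        "Truseq DNA PCR-free": 6,
        "Accel-NGS 1S": 7,
        "Accel-NGS 2S": 10,
        "KAPA Hyper": 5,
        "KAPA HyperPlus": 5,
    }

    def test_step_counts_for_all_nine_kits(self):
        kits = builtin_kits()
        assert {n: count_steps(k) for n, k in kits.items()} == self.EXPECTED

    @pytest.mark.parametrize("name", ["KAPA Hyper", "KAPA HyperPlus"])
    def test_kapa_kits_drop_to_three_steps_without_pcr(self, name):
        assert count_steps(kit_protocol(name, with_pcr=False)) == 3
        assert count_steps(kit_protocol(name, with_pcr=True)) == 5

    def test_nebnext_ultra_combines_end_repair_and_a_tailing(self):
        kit = kit_protocol("NEBNext Ultra")
        assert kit.steps[0].kind == "combined_er_at"

    def test_kapa_hyperplus_starts_with_enzymatic_fragmentation(self):
        kit = kit_protocol("KAPA HyperPlus")
        assert kit.steps[0].kind == "enzymatic_fragmentation"
        assert not any(s.kind == "mechanical_shear" for s in kit.steps)

    def test_accel_kits_cannot_assay_the_adaptor_channel(self):
        kits = builtin_kits()
        for name, kit in kits.items():
            assert kit.adaptor_channel_measurable == (not name.startswith("Accel"))

    def test_misordered_protocol_is_rejected(self):
        with pytest.raises(ConfigurationError):
            KitProtocol("bad", [ProtocolStep("adaptor_ligation"), ProtocolStep("end_repair")])

    def test_kit_roundtrips_through_dict_schema(self):
        kit = parameterize_kit(
            kit_protocol("NEBNext"),
            cleanup_retention=LogisticSizeRetention(200.0, 50.0, 0.4, 0.95),
            conversion_efficiencies={"adaptor_ligation": 0.2},
            pcr=PcrParams(cycles=6, per_cycle_efficiency=0.95, capacity=4e12),
        )
        clone = kit_from_dict(kit_to_dict(kit))
        assert count_steps(clone) == count_steps(kit)
        pop = make_pop(1e9, "sheared")
        a = [p.total() for _, p in run_protocol(pop, kit)]
        b = [p.total() for _, p in run_protocol(pop, clone)]
        assert a == pytest.approx(b)
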