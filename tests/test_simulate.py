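"""Generator invariants: determinism, feasibility guards, exact inversion."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from tracerflux.errors import InfeasibleDesignError
from tracerflux.recovery import recover_transfer_efficiency, recovery_study
from tracerflux.simulate import (
    NoiseConfig,
    SimulationConfig,
    food_chain_record,
    simulate_experiment,
    simulate_food_chain,
)


def small_config(**kw):
    base = replace(
        SimulationConfig(seed=2),
        n_animals_per_group=2,
        n_controls=1,
        substrate_kinds=("dom",),
    )
    return replace(base, **kw)


class TestDeterminism:
    def test_same_seed_reproduces_every_frame(self):
        a = simulate_experiment(small_config())
        b = simulate_experiment(small_config())
        for name in ("specimens", "batches", "incubations", "o2_series", "ground_truth"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_same_seed_byte_identical_files(self, tmp_path):
        p1 = simulate_experiment(small_config()).write(tmp_path / "a")
        p2 = simulate_experiment(small_config()).write(tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_different_seed_changes_noise(self):
        a = simulate_experiment(small_config())
        b = simulate_experiment(small_config(seed=3))
        assert not np.allclose(
            a.incubations["dic_end_um"], b.incubations["dic_end_um"]
        )


class TestFeasibilityGuards:
    def test_o2_never_below_saturation_floor(self):
        config = small_config(noise=NoiseConfig.zero())
        sim = simulate_experiment(config)
        floor = config.o2_floor_fraction * config.o2_start
        assert sim.o2_series["o2_um"].min() >= floor

    def test_pool_exhaustion_names_the_pool(self):
        config = small_config()
        taxa = {"hma_sponge": replace(config.taxa["hma_sponge"], doc_release=-400.0)}
        with pytest.raises(InfeasibleDesignError, match="doc"):
            simulate_experiment(replace(config, taxa=taxa))

    def test_o2_floor_violation_names_oxygen(self):
        config = small_config()
        taxa = {"bivalve": replace(config.taxa["bivalve"], respiration=800.0)}
        with pytest.raises(InfeasibleDesignError, match="[Oo]2"):
            simulate_experiment(replace(config, taxa=taxa))

    def test_substrate_exhaustion_raises(self):
        config = small_config()
        taxa = {"bivalve": replace(config.taxa["bivalve"], incorporation=3000.0)}
        with pytest.raises(InfeasibleDesignError, match="substrate"):
            simulate_experiment(replace(config, taxa=taxa))

    def test_heavy_utilization_warns_of_depletion(self):
        config = small_config(noise=NoiseConfig.zero())
        # ~93% of the provided bacteria-tracer ends up incorporated
        taxa = {
            "hma_sponge": replace(
                config.taxa["hma_sponge"], incorporation=400.0, respiration=50.0,
                tracer_fraction_respiration=0.0, tracer_fraction_poc=0.0,
                tissue_oc_range=(0.062, 0.063),
            )
        }
        cfg = replace(config, taxa=taxa, substrate_kinds=("bacteria",))
        with pytest.warns(UserWarning, match="depletion"):
            simulate_experiment(cfg)


class TestParameterRecovery:
    def test_zero_noise_recovers_all_rates_exactly(self):
        df = recovery_study(
            seed=2, n_animals=2, n_controls=1, noise=NoiseConfig.zero()
        )
        assert df.rel_error.abs().max() < 1e-9

    def test_zero_true_fluxes_recover_as_zero_without_noise(self):
        config = small_config(noise=NoiseConfig.zero())
        taxa = {
            "bivalve": replace(
                config.taxa["bivalve"], respiration=0.0, poc_release=0.0,
                doc_release=0.0, incorporation=0.0,
                tracer_fraction_respiration=0.0, tracer_fraction_poc=0.0,
            )
        }
        sim = simulate_experiment(replace(config, taxa=taxa))
        from tracerflux import TracerBudgetModel

        budget = TracerBudgetModel.from_simulation(sim).fit().budget
        rates = budget[
            ["respiration_total", "poc_total", "doc_total",
             "incorporation_tracer", "respiration_tracer", "poc_tracer"]
        ].to_numpy()
        np.testing.assert_allclose(rates, 0.0, atol=1e-9)

    def test_mean_recovered_incorporation_within_5pct_at_default_noise(self):
        df = recovery_study(seed=1)
        inc = df[df["quantity"] == "incorporation_tracer"]
        assert (inc.n == 20).all()
        assert inc.rel_error.abs().max() < 0.05


class TestFoodChain:
    def test_zero_noise_inverts_true_efficiency(self):
        config = SimulationConfig(seed=4)
        config = replace(config, foodchain=replace(config.foodchain, relative_sd=0.0))
        truth, recovered = recover_transfer_efficiency(config)
        assert recovered == pytest.approx(truth, rel=1e-12)

    def test_complete_transfer_matches_pools(self):
        config = SimulationConfig(seed=4)
        config = replace(
            config,
            foodchain=replace(
                config.foodchain, true_transfer_efficiency=100.0, relative_sd=0.0
            ),
        )
        fc, _ = simulate_food_chain(config)
        rec = food_chain_record(fc)
        assert rec.consumer_13c_incorporated == pytest.approx(rec.fecal_13c_produced)

    def test_noisy_replicates_recover_mean_efficiency(self):
        config = SimulationConfig(seed=0)
        vals = [
            recover_transfer_efficiency(replace(config, seed=s))[1]
            for s in range(20)
        ]
        assert np.mean(vals) == pytest.approx(37.0, rel=0.05)

    def test_record_normalizes_to_full_window(self):
        fc, truth = simulate_food_chain(SimulationConfig(seed=4))
        rec = food_chain_record(fc)
        assert rec.period == pytest.approx(float(truth["n_cycles"].iloc[0]))
        assert len(rec.consumer_ids) == int(truth["n_ophiuroids"].iloc[0])


def test_generated_batches_match_printed_atom_fraction_ranges():
    from tracerflux.flux import SUBSTRATE_F13_RANGES

    sim = simulate_experiment(small_config())
    for _, b in sim.batches.iterrows():
        lo, hi = SUBSTRATE_F13_RANGES[b["kind"]]
        assert lo <= b["atom_fraction"] <= hi
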