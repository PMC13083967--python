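"""Orchestrated reaction cycles: determinism, checkpointing, plugins."""

import dataclasses

import numpy as np
import pytest

import molkmc as mk
from molkmc.errors import CheckpointError, ConfigurationError
from molkmc.orchestrator import (
    DimerizationPlugin,
    HATPlugin,
    HomolysisPlugin,
    HydrolysisPlugin,
    run_steps_and_checkpoint,
    torsion_angle,
)
from molkmc.rate_models import Constants


def small_hat_config(**overrides):
    base = dict(
        fixture={"name": "alkyl_radical", "n_carbons": 5, "radical_carbon": 0},
        temperature=500.0,
        sample_steps=6000,
        sample_stride=200,
        equilibration_steps=500,
        burn_in_steps=4000,
        plugins=[mk.PluginSpec("hat", {})],
        max_steps=6,
        seed=11,
    )
    base.update(overrides)
    return mk.RunConfig(**base)


class TestRunContract:
    def test_zero_steps_is_identity(self):
        cfg = small_hat_config(max_steps=0, burn_in_steps=0)
        res = mk.run(cfg)
        t0, f0 = mk.build_alkyl_radical(5, 0)
        assert res.records == []
        assert res.topology.isclose(t0)
        assert np.allclose(res.frame.positions, f0.positions)

    def test_fixed_seed_bitwise_reproducible(self):
        cfg = small_hat_config()
        r1, r2 = mk.run(cfg), mk.run(cfg)
        assert r1.records == r2.records
        assert np.array_equal(r1.frame.positions, r2.frame.positions)

    def test_seeds_are_independent(self):
        r1 = mk.run(small_hat_config(seed=1))
        r2 = mk.run(small_hat_config(seed=2))
        assert r1.records != r2.records

    def test_simulated_time_is_sum_of_delta_t(self):
        res = mk.run(small_hat_config())
        total = 0.0
        for rec in res.records:
            total += rec.delta_t
            assert rec.time == total  # exact: same accumulation order

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            mk.run(small_hat_config(plugins=[]))
        with pytest.raises(ConfigurationError):
            mk.run(small_hat_config(max_steps=None, max_time=None))
        with pytest.raises(ConfigurationError):
            mk.run(small_hat_config(fixture={"name": "nope"}))

    def test_max_time_stops_run(self):
        full = mk.run(small_hat_config())
        assert len(full.records) > 1
        t_cut = full.records[0].time
        res = mk.run(small_hat_config(max_time=t_cut))
        assert len(res.records) == 1

    def test_keep_states_records_products(self):
        res = mk.run(small_hat_config(max_steps=2, keep_states=True))
        assert len(res.states) == len(res.records)
        for (topo, frame), rec in zip(res.states, res.records):
            assert topo.digest() == rec.topology_digest

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_hat_config(output_dir=None)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert mk.RunConfig.from_yaml(path) == cfg

    def test_run_writes_outputs(self, tmp_path):
        out = tmp_path / "out"
        mk.run(small_hat_config(max_steps=2, output_dir=str(out)))
        for name in ("records.jsonl", "rates.tsv", "final.top", "final.pdb"):
            assert (out / name).exists()


class TestCheckpoint:
    def test_split_run_equals_straight_run(self, tmp_path):
        cfg = small_hat_config(max_steps=6)
        straight = mk.run(cfg)
        ck = tmp_path / "ck.json"
        first = run_steps_and_checkpoint(cfg, 3, ck)
        rest = mk.restart(ck)
        assert first.records + rest.records == straight.records

    def test_rng_state_round_trips_exactly(self, tmp_path):
        cfg = small_hat_config(max_steps=2)
        ck = tmp_path / "ck.json"
        run_steps_and_checkpoint(cfg, 1, ck)
        _, state = mk.restore(ck)
        import json

        with open(ck) as fh:
            saved = json.load(fh)["rng_state"]
        assert state.kmc_rng.bit_generator.state == saved

    def test_plugin_mismatch_rejected(self, tmp_path):
        cfg = small_hat_config(max_steps=2)
        ck = tmp_path / "ck.json"
        run_steps_and_checkpoint(cfg, 1, ck)
        other = small_hat_config(plugins=[mk.PluginSpec("homolysis", {})])
        with pytest.raises(ConfigurationError):
            mk.restore(ck, config=other)

    def test_corrupt_checkpoint_rejected(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text('{"schema_version": 1}')
        with pytest.raises(CheckpointError):
            mk.restore(bad)


class TestPlugins:
    def test_hat_candidates_respect_cutoff(self, octyl_radical):
        t, f = octyl_radical
        ens = mk.toy_sd_sample(
            t, f, mk.SamplerConfig(n_steps=2000, stride=200, seed=3, temperature=500.0)
        )
        tight = HATPlugin({"cutoff": 1.5}, Constants(T=500.0))
        loose = HATPlugin({"cutoff": 6.0}, Constants(T=500.0))
        assert len(tight.propose(t, ens)) <= len(loose.propose(t, ens))
        for ev in loose.propose(t, ens):
            assert ev.metadata["reaction_type"] == "hat"
            assert ev.rate >= 0

    def test_hat_rate_is_ensemble_average(self, propyl_radical):
        t, f = propyl_radical
        ens = mk.Ensemble(t, [f, f.copy()])
        plugin = HATPlugin({"cutoff": 100.0}, Constants(T=300.0))
        events = plugin.propose(t, ens)
        h, acc = events[0].metadata["atoms"]
        b = mk.surrogate_hat_barrier(t, h, acc, f)
        assert events[0].rate == pytest.approx(
            mk.ensemble_average_rate([b, b], Constants(T=300.0))
        )

    def test_homolysis_plugin_selects_cc_bonds(self, octane):
        t, f = octane
        ens = mk.Ensemble(t, [f])
        plugin = HomolysisPlugin({"force": 2000.0}, Constants())
        events = plugin.propose(t, ens)
        assert len(events) == 7  # the seven C-C bonds
        rate0 = mk.bell_rate(2000.0, mk.BellParams(), Constants())
        assert all(ev.rate == pytest.approx(rate0) for ev in events)

    def test_hydrolysis_plugin_finds_amide_site(self, dipeptide_water):
        t, f = dipeptide_water
        ens = mk.Ensemble(t, [f])
        plugin = HydrolysisPlugin({"force": 1000.0, "pH": 7.0}, Constants())
        events = plugin.propose(t, ens)
        assert len(events) == 1
        assert events[0].metadata["atoms"] == (6, 8)
        t2, _ = mk.apply_recipe(t, f, events[0].recipe)
        assert len(mk.find_radicals(t2)) == 0

    def test_dimerization_plugin_pairs_double_bonds(self, thymine_pair):
        t, f, sites = thymine_pair
        ens = mk.Ensemble(t, [f])
        plugin = DimerizationPlugin({"rate_threshold": 1.0})
        events = plugin.propose(t, ens)
        assert len(events) == 1
        assert set(events[0].metadata["atoms"]) == set(sites.values())

    def test_competition_homolysis_vs_hydrolysis(self, dipeptide_water):
        """At 1 nN on a single chain the heuristic hydrolysis rate beats the
        Bell homolysis rate; the event list reflects that."""
        t, f = dipeptide_water
        ens = mk.Ensemble(t, [f])
        c = Constants()
        homo = HomolysisPlugin({"force": 1000.0, "elements": ("C", "N")}, c)
        hydro = HydrolysisPlugin({"force": 1000.0}, c)
        h_events = [e for e in homo.propose(t, ens) if e.metadata["atoms"] == (6, 8)]
        w_events = hydro.propose(t, ens)
        assert w_events[0].rate > h_events[0].rate


def test_torsion_angle_known_geometries():
    p = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0], [2.0, 1.0, 0.0]])
    assert torsion_angle(*p) == pytest.approx(0.0, abs=1e-9)
    p[3] = [2.0, -1.0, 0.0]
    assert abs(torsion_angle(*p)) == pytest.approx(180.0)
    p[3] = [2.0, 0.0, 1.0]
    assert abs(torsion_angle(*p)) == pytest.approx(90.0)
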