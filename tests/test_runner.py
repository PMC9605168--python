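"""Pipeline orchestration: determinism, conservation, sweeps, config I/O, CLI."""

import dataclasses

import numpy as np
import pytest
from click.testing import CliRunner

from protolattice import (
    InitialConditionSpec,
    LatticeConfig,
    RunConfig,
    apply_parameter,
    initialize_grid,
    load_config,
    run,
    step,
    sweep,
)
from protolattice.cli import main as cli_main
from protolattice.runner import config_to_yaml, seed_geometry_region


def small_config(**kw) -> RunConfig:
    defaults = dict(lattice=LatticeConfig(20, 20), steps=30, seed=7,
                    ledger_every=10, report_every=10)
    defaults.update(kw)
    return RunConfig(**defaults)


class TestStep:
    def test_empty_grid_stays_empty(self, rng):
        cfg = small_config()
        init = InitialConditionSpec(
            mol1_per_cell=0, mol6_per_cell=0, mol7_per_cell=0,
            mol12_per_cell=0, mol14_per_cell=0, mol15_per_cell=0,
            seed_amount_mol2=0, seed_amount_mol3=0, polymer1_initial_count=0)
        grid = initialize_grid(cfg.lattice, init, rng)
        step(grid, cfg, rng)
        assert grid.grand_total() == 0

    def test_grand_total_conserved_over_100_steps(self, rng):
        cfg = small_config(steps=100)
        grid = initialize_grid(cfg.lattice, cfg.init, rng)
        total0 = grid.grand_total()
        for _ in range(100):
            step(grid, cfg, rng)
            assert grid.grand_total() == total0

    def test_bitwise_reproducibility(self):
        t1 = run(small_config(steps=40))
        t2 = run(small_config(steps=40))
        assert t1.final_grid.equals(t2.final_grid)
        assert t1.ledger.S_R_cumulative == t2.ledger.S_R_cumulative
        assert t1.ledger.S_D == t2.ledger.S_D

    def test_different_seeds_diverge(self):
        t1 = run(small_config(steps=40, seed=1))
        t2 = run(small_config(steps=40, seed=2))
        assert not t1.final_grid.equals(t2.final_grid)


class TestRun:
    def test_zero_steps_rejected(self):
        with pytest.raises(ValueError):
            small_config(steps=0)

    def test_run_reports_and_ledger_cadence(self):
        traj = run(small_config(steps=30))
        assert [r.step for r in traj.reports] == [0, 10, 20, 30]
        assert traj.ledger.steps == [0, 10, 20, 30]
        assert traj.conservation_ok

    def test_outputs_written(self, tmp_path):
        cfg = small_config(steps=20, snapshot_every=10,
                           output_dir=str(tmp_path / "out"))
        run(cfg)
        out = tmp_path / "out"
        assert (out / "entropy_ledger.tsv").exists()
        assert (out / "domain_reports.tsv").exists()
        assert (out / "snapshot_000020.tsv").exists()
        assert (out / "run_config.yaml").exists()

    def test_packaged_standard_config_matches_defaults(self):
        from importlib.resources import files
        path = files("protolattice") / "data" / "standard.yaml"
        cfg = load_config(path)
        ref = RunConfig()
        assert cfg.lattice == ref.lattice
        assert cfg.init == ref.init
        assert cfg.rates == ref.rates
        assert cfg.network.rules == ref.network.rules
        assert cfg.network.stage_f_gate == ref.network.stage_f_gate

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = apply_parameter(small_config(), "w", 0.675)
        cfg = apply_parameter(cfg, "removal_13", 55)
        path = tmp_path / "cfg.yaml"
        path.write_text(config_to_yaml(cfg))
        loaded = load_config(path)
        assert loaded.init.polymer1_initial_w == 0.675
        assert loaded.lattice == cfg.lattice
        rule = [r for r in loaded.network.rules
                if r.substrate == 13 and r.product == 1 and r.stage == "G"]
        assert rule[0].rate == pytest.approx(0.55)


class TestSweep:
    def test_single_value_sweep_equals_run(self):
        base = small_config(steps=20)
        trajs = sweep(base, "w", [0.650])
        direct = run(apply_parameter(base, "w", 0.650))
        assert trajs[0].final_grid.equals(direct.final_grid)

    def test_axis_values_are_applied(self):
        base = small_config(steps=20)
        trajs = sweep(base, "mol14", [1, 5])
        assert trajs[0].config.init.mol14_per_cell == 1
        assert trajs[1].config.init.mol14_per_cell == 5

    def test_unknown_axis_rejected(self):
        with pytest.raises(KeyError):
            sweep(small_config(), "frobnication", [1])

    def test_residual_axis_tracks_partner_species(self):
        cfg = apply_parameter(small_config(), "r_mol2", 0.85)
        assert cfg.rates.r[2] == 0.85
        assert cfg.rates.r[4] == 0.85  # molecule 4 shares molecule 2's rate


class TestSeedGeometryInsensitivity:
    def test_three_seed_layouts_same_early_behavior(self):
        # different central morphogen placements behave alike over the
        # early phase (steps 50-200): domains form, split, and persist
        for case in ["case1", "case2", "case3"]:
            cfg = RunConfig(lattice=LatticeConfig(40, 40), steps=200, seed=11,
                            ledger_every=50, report_every=10)
            cfg = apply_parameter(cfg, "seed_geometry", case)
            traj = run(cfg)
            early = {r.step: r for r in traj.reports}
            assert early[50].coverage > 0, case
            assert max(r.n_domains for r in traj.reports) >= 2, case
            assert early[200].coverage > 0, case

    def test_geometries_are_distinct_and_central(self):
        lat = LatticeConfig(40, 40)
        regions = {c: set(seed_geometry_region(c, lat))
                   for c in ["case1", "case2", "case3"]}
        assert regions["case1"] != regions["case2"] != regions["case3"]
        for cells in regions.values():
            rs = [r for r, _ in cells]
            cs = [c for _, c in cells]
            assert min(rs) > 10 and max(rs) < 30
            assert min(cs) > 10 and max(cs) < 30

    def test_unknown_geometry_rejected(self):
        with pytest.raises(KeyError):
            seed_geometry_region("case9", LatticeConfig(40, 40))


class TestCLI:
    def test_run_command_reports_outcome(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "run", "--steps", "20", "--seed", "3", "--set", "w=0.65",
            "-o", str(tmp_path / "out")])
        assert result.exit_code == 0, result.output
        assert "conservation_ok=True" in result.output
        assert "coverage=" in result.output

    def test_bad_override_rejected(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["run", "--steps", "5", "--set", "bogus=1"])
        assert result.exit_code != 0

    def test_classify_command(self, tmp_path):
        cfg = small_config(steps=30, output_dir=str(tmp_path / "o"))
        run(cfg)
        runner = CliRunner()
        result = runner.invoke(cli_main, ["classify",
                                          str(tmp_path / "o" / "domain_reports.tsv")])
        assert result.exit_code == 0, result.output
        assert result.output.strip() in {"mesh", "replicating", "stationary", "extinct"}
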