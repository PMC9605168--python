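"""Orchestration: the per-step pipeline, run configuration, sweeps and I/O.

A step applies, in order: (1) diffusion of every species and both polymer
kinds; (2) reaction stages A..F with the informant ratio read per cell;
(3) informant-polymer synthesis; (4) membrane-polymer synthesis;
(5) removal reactions (stage G); (6) membrane-polymer degradation.  The
grand monomer total is conserved exactly by every step, and a run is
bit-for-bit reproducible from its config and seed (single RNG stream,
fixed operation order).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diffusion import ResidualRateTable, diffuse_all
from .entropy import EntropyLedger
from .lattice import (
    GridState,
    InitialConditionSpec,
    LatticeConfig,
    hex_disk,
    hex_distance,
    initialize_grid,
)
from .patterns import DomainReport, domain_report, reports_to_frame
from .polymers import PolymerParams, degrade_polymer2_grid, local_w_grid, \
    synthesize_polymer1_grid, synthesize_polymer2_grid
from .reactions import NetworkDefinition, ReactionTally, apply_reaction_stages


@dataclass
class RunConfig:
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    init: InitialConditionSpec = field(default_factory=InitialConditionSpec)
    rates: ResidualRateTable = field(default_factory=ResidualRateTable)
    network: NetworkDefinition = field(default_factory=NetworkDefinition)
    polymer: PolymerParams = field(default_factory=PolymerParams)
    steps: int = 2000
    seed: int = 0
    ledger_every: int = 10
    report_every: int = 10
    snapshot_every: int = 0  # 0 = no snapshots
    mask_threshold: int = 1
    output_dir: str | None = None

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


@dataclass
class Trajectory:
    """Everything a run produced, with the exact config and seed that made it."""

    config: RunConfig
    ledger: EntropyLedger
    reports: list[DomainReport]
    final_grid: GridState
    conservation_ok: bool
    grand_total: int


def step(grid: GridState, config: RunConfig, rng: np.random.Generator) -> ReactionTally:
    """Advance the grid one time step in place; returns the reaction tally."""
    diffuse_all(grid, config.rates, rng)
    w_grid = local_w_grid(grid)
    tally = apply_reaction_stages(grid.species, config.network, w_grid, rng,
                                  stages=("A", "B", "C", "D", "E", "F"))
    synthesize_polymer1_grid(grid, config.polymer)
    synthesize_polymer2_grid(grid)
    apply_reaction_stages(grid.species, config.network, w_grid, rng,
                          stages=("G",), tally=tally)
    degrade_polymer2_grid(grid, rng, config.polymer)
    grid.time_step += 1
    return tally


def run(config: RunConfig, keep_masks: bool = False) -> Trajectory:
    """Execute a full seeded run, recording entropy and domain series."""
    rng = np.random.default_rng(config.seed)
    grid = initialize_grid(config.lattice, config.init, rng)
    total0 = grid.grand_total()

    ledger = EntropyLedger()
    reports: list[DomainReport] = [domain_report(grid, config.mask_threshold, keep_masks)]
    ledger.record(0, grid, 0)
    snapshots: list[pd.DataFrame] = []
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    conservation_ok = True
    for t in range(1, config.steps + 1):
        tally = step(grid, config, rng)
        if t % config.ledger_every == 0 or t == config.steps:
            ledger.record(t, grid, tally.net)
        else:
            ledger.accumulate(tally.net)
        if t % config.report_every == 0 or t == config.steps:
            reports.append(domain_report(grid, config.mask_threshold, keep_masks))
        if config.snapshot_every and (t % config.snapshot_every == 0 or t == config.steps):
            snap = snapshot_frame(grid)
            snapshots.append(snap)
            if out:
                snap.to_csv(out / f"snapshot_{t:06d}.tsv", sep="\t", index=False)
        if grid.grand_total() != total0:
            conservation_ok = False

    if out:
        ledger.write(out / "entropy_ledger.tsv")
        reports_to_frame(reports).to_csv(out / "domain_reports.tsv", sep="\t", index=False)
        (out / "run_config.yaml").write_text(config_to_yaml(config))

    return Trajectory(config=config, ledger=ledger, reports=reports,
                      final_grid=grid, conservation_ok=conservation_ok,
                      grand_total=total0)


# ---------------------------------------------------------------------------
# parameter axes (the sweep rows of the standard-parameter table)
# ---------------------------------------------------------------------------

def _set_w(c: RunConfig, v) -> RunConfig:
    return dataclasses.replace(c, init=dataclasses.replace(c.init, polymer1_initial_w=float(v)))


def _set_mol14(c: RunConfig, v) -> RunConfig:
    return dataclasses.replace(c, init=dataclasses.replace(c.init, mol14_per_cell=int(v)))


def _set_mol15(c: RunConfig, v) -> RunConfig:
    return dataclasses.replace(c, init=dataclasses.replace(c.init, mol15_per_cell=int(v)))


def _seed_geometry(c: RunConfig, v) -> RunConfig:
    region = seed_geometry_region(str(v), c.lattice)
    return dataclasses.replace(c, init=dataclasses.replace(c.init, seed_region=region))


def _set_residual(mol: int, tracked: int | None = None):
    def setter(c: RunConfig, v) -> RunConfig:
        r = dict(c.rates.r)
        r[mol] = float(v)
        if tracked is not None:
            r[tracked] = float(v)
        return dataclasses.replace(c, rates=dataclasses.replace(c.rates, r=r))
    return setter


def _set_poly_residual(which: int):
    def setter(c: RunConfig, v) -> RunConfig:
        key = "r_poly1" if which == 1 else "r_poly2"
        return dataclasses.replace(c, rates=dataclasses.replace(c.rates, **{key: float(v)}))
    return setter


def _set_rate(substrate: int, product: int, stage: str):
    def setter(c: RunConfig, v) -> RunConfig:
        return dataclasses.replace(c, network=c.network.with_rate(substrate, product, float(v), stage))
    return setter


def _set_int_field(name: str):
    def setter(c: RunConfig, v) -> RunConfig:
        return dataclasses.replace(c, **{name: int(v)})
    return setter


#: Recognized parameter axes (values as printed in the standard-parameter
#: table: residual rates as fractions, reaction/removal rates as percent).
PARAMETER_AXES = {
    "w": _set_w,
    "mol14": _set_mol14,
    "mol15": _set_mol15,
    "seed_geometry": _seed_geometry,
    "r_mol2": _set_residual(2, tracked=4),
    "r_mol3": _set_residual(3, tracked=5),
    "rate_2_4": _set_rate(2, 4, "A"),
    "rate_3_5": _set_rate(3, 5, "A"),
    "r_poly1": _set_poly_residual(1),
    "r_poly2": _set_poly_residual(2),
    "removal_4": _set_rate(4, 1, "G"),
    "removal_5": _set_rate(5, 1, "G"),
    "removal_10": _set_rate(10, 1, "G"),
    "removal_11": _set_rate(11, 1, "G"),
    "removal_13": _set_rate(13, 1, "G"),
    "steps": _set_int_field("steps"),
    "seed": _set_int_field("seed"),
}


def apply_parameter(config: RunConfig, axis: str, value) -> RunConfig:
    if axis not in PARAMETER_AXES:
        raise KeyError(f"unknown parameter axis {axis!r}; known: {sorted(PARAMETER_AXES)}")
    return PARAMETER_AXES[axis](config, value)


def sweep(base: RunConfig, axis: str, values, per_run_seeds: bool = False,
          keep_masks: bool = False) -> list[Trajectory]:
    """One run per value along a recognized parameter axis."""
    out = []
    for i, v in enumerate(values):
        cfg = apply_parameter(base, axis, v)
        if per_run_seeds:
            cfg = dataclasses.replace(cfg, seed=base.seed + i)
        out.append(run(cfg, keep_masks=keep_masks))
    return out


def seed_geometry_region(case: str, lattice: LatticeConfig) -> list[tuple[int, int]]:
    """The three initial-placement variants of the morphogen seed.

    case1: compact hex disk (radius 2); case2: hex ring at distance 2-3;
    case3: three small clusters around the center.  All central, all
    equivalent in outcome.
    """
    center = (lattice.height // 2, lattice.width // 2)
    if case == "case1":
        return hex_disk(center, 2, lattice)
    if case == "case2":
        disk = hex_disk(center, 3, lattice)
        return [c for c in disk
                if hex_distance(((c[0] - center[0] + lattice.height // 2) % lattice.height - lattice.height // 2,
                                 (c[1] - center[1] + lattice.width // 2) % lattice.width - lattice.width // 2)) >= 2]
    if case == "case3":
        cells = []
        for off in ((0, 0), (-4, 2), (4, -2)):
            cells.extend(hex_disk(((center[0] + off[0]) % lattice.height,
                                   (center[1] + off[1]) % lattice.width), 1, lattice))
        return sorted(set(cells))
    raise KeyError(f"unknown seed geometry {case!r}")


# ---------------------------------------------------------------------------
# snapshots and config files
# ---------------------------------------------------------------------------

def snapshot_frame(grid: GridState) -> pd.DataFrame:
    """Long-form snapshot: (step, row, col, kind, count), nonzero entries only."""
    rows = []
    H, W = grid.config.shape
    rr, cc = np.indices((H, W))
    for s in range(1, 16):
        cnt = grid.counts(s)
        nz = cnt > 0
        rows.append(pd.DataFrame({
            "step": grid.time_step, "row": rr[nz], "col": cc[nz],
            "kind": f"mol{s}", "count": cnt[nz]}))
    p1 = grid.poly1_count()
    nz = p1 > 0
    rows.append(pd.DataFrame({"step": grid.time_step, "row": rr[nz], "col": cc[nz],
                              "kind": "poly1", "count": p1[nz]}))
    nz = grid.poly2 > 0
    rows.append(pd.DataFrame({"step": grid.time_step, "row": rr[nz], "col": cc[nz],
                              "kind": "poly2", "count": grid.poly2[nz]}))
    return pd.concat(rows, ignore_index=True)


def config_to_dict(config: RunConfig) -> dict:
    rates = {f"mol{s}": float(v) for s, v in sorted(config.rates.r.items())}
    rates["poly1"] = config.rates.r_poly1
    rates["poly2"] = config.rates.r_poly2
    return {
        "lattice": {"width": config.lattice.width, "height": config.lattice.height},
        "init": {k: v for k, v in dataclasses.asdict(config.init).items()},
        "residual_rates": rates,
        "network": {
            "window_policy": config.network.window_policy,
            "stage_f_gate": config.network.stage_f_gate,
            "rates_percent": {
                "rate_2_4": _rule_pct(config, 2, 4, "A"),
                "rate_3_5": _rule_pct(config, 3, 5, "A"),
                "removal_4": _rule_pct(config, 4, 1, "G"),
                "removal_5": _rule_pct(config, 5, 1, "G"),
                "removal_10": _rule_pct(config, 10, 1, "G"),
                "removal_11": _rule_pct(config, 11, 1, "G"),
                "removal_13": _rule_pct(config, 13, 1, "G"),
            },
        },
        "polymer": {"p1_size": config.polymer.p1_size,
                    "p2_degradation_rate": config.polymer.p2_degradation_rate},
        "run": {"steps": config.steps, "seed": config.seed,
                "ledger_every": config.ledger_every,
                "report_every": config.report_every,
                "snapshot_every": config.snapshot_every,
                "mask_threshold": config.mask_threshold},
    }


def _rule_pct(config: RunConfig, sub: int, prod: int, stage: str) -> float:
    for r in config.network.rules:
        if r.substrate == sub and r.product == prod and r.stage == stage:
            return r.rate * 100.0
    raise KeyError((sub, prod, stage))


def config_to_yaml(config: RunConfig) -> str:
    return yaml.safe_dump(config_to_dict(config), sort_keys=False)


def config_from_dict(d: dict) -> RunConfig:
    init_kwargs = dict(d.get("init", {}))
    if init_kwargs.get("seed_region"):
        init_kwargs["seed_region"] = [tuple(c) for c in init_kwargs["seed_region"]]
    cfg = RunConfig(
        lattice=LatticeConfig(**d.get("lattice", {})),
        init=InitialConditionSpec(**init_kwargs),
        polymer=PolymerParams(**d.get("polymer", {})),
    )
    rr = d.get("residual_rates", {})
    r = dict(cfg.rates.r)
    for s in range(1, 16):
        if f"mol{s}" in rr:
            r[s] = float(rr[f"mol{s}"])
    cfg = dataclasses.replace(cfg, rates=ResidualRateTable(
        r=r,
        r_poly1=float(rr.get("poly1", cfg.rates.r_poly1)),
        r_poly2=float(rr.get("poly2", cfg.rates.r_poly2))))
    net = d.get("network", {})
    network = NetworkDefinition(window_policy=net.get("window_policy", "single_pass"),
                                stage_f_gate=net.get("stage_f_gate", "mol13"))
    for key, val in net.get("rates_percent", {}).items():
        cfg2 = apply_parameter(dataclasses.replace(cfg, network=network), key, val)
        network = cfg2.network
    cfg = dataclasses.replace(cfg, network=network)
    runblock = d.get("run", {})
    cfg = dataclasses.replace(cfg, **{k: int(v) for k, v in runblock.items()})
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})
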