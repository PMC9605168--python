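"""Residual-rate diffusion of free molecules and polymer boxes.

Each species carries a residual rate ``r``: the fraction of its molecules
that stay in their cell each step (the model's stand-in for an inverse
diffusion coefficient).  Of ``b`` molecules in a cell, ``round(b*r)`` stay;
the movers are split evenly six ways, and the remainder (``< 6`` units) is
handed one-by-one to distinct neighbors chosen uniformly at random.
Polymer boxes instead move as whole units: each box stays with probability
``r`` or hops to one uniformly chosen neighbor.  All updates are synchronous
(computed from the pre-step state) and exactly count-conserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .lattice import HEX_DIRECTIONS, GridState, roll_to_neighbor

# All 720 orderings of the six directions; a random row gives a uniformly
# random assignment of the <6 remainder units to distinct neighbors.
_PERMS = np.array(list(permutations(range(6))), dtype=np.int8)


def _standard_rates() -> dict[int, float]:
    # residual rates of the standard case (mol4/5 track mol2/3)
    return {
        1: 0.0, 2: 0.75, 3: 0.05, 4: 0.75, 5: 0.05,
        6: 0.0, 7: 0.0, 8: 1.0, 9: 1.0, 10: 1.0, 11: 1.0,
        12: 0.0, 13: 1.0, 14: 1.0, 15: 1.0,
    }


@dataclass
class ResidualRateTable:
    """Per-species residual rates plus the two polymer-box rates."""

    r: dict[int, float] = field(default_factory=_standard_rates)
    r_poly1: float = 0.1
    r_poly2: float = 0.75

    def __post_init__(self) -> None:
        for s, v in self.r.items():
            _check_rate(v, f"molecule {s}")
        _check_rate(self.r_poly1, "polymer 1")
        _check_rate(self.r_poly2, "polymer 2")


def _check_rate(r: float, what: str) -> None:
    if not (0.0 <= r <= 1.0):
        raise ValueError(f"residual rate of {what} must be in [0, 1], got {r}")


def _round_half_up(x: np.ndarray | float) -> np.ndarray | int:
    # plain round() half-even would bias tabulated rates like 0.5; a tiny
    # epsilon shields exact products (e.g. 600*0.75) from float error
    return np.floor(np.asarray(x) + 0.5 + 1e-9).astype(np.int64)


def diffuse_counts(counts: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """One synchronous diffusion step of a count grid; exactly conserving."""
    _check_rate(r, "species")
    if r == 1.0 or not counts.any():
        return counts.copy()
    stay = _round_half_up(counts * r)
    moved = counts - stay
    base = moved // 6
    rem = moved - 6 * base  # 0..5 remainder units per cell

    new = stay
    if base.any():
        for d in HEX_DIRECTIONS:
            new = new + roll_to_neighbor(base, d)
    else:
        new = new.copy()

    flat_rem = rem.ravel()
    idx = np.flatnonzero(flat_rem)
    if idx.size:
        perm = _PERMS[rng.integers(0, len(_PERMS), size=idx.size)]  # (k, 6)
        active = np.arange(6)[None, :] < flat_rem[idx, None]  # first rem slots
        extra = np.zeros(counts.size, dtype=np.int64)
        for d in range(6):
            sel = (active & (perm == d)).any(axis=1)
            if sel.any():
                extra[:] = 0
                extra[idx[sel]] = 1
                new = new + roll_to_neighbor(extra.reshape(counts.shape), HEX_DIRECTIONS[d])
    return new


def diffuse_box_counts(counts: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """One step of whole-box diffusion: Bernoulli stay, uniform-neighbor hop."""
    _check_rate(r, "box")
    if r == 1.0 or not counts.any():
        return counts.copy()
    stay = rng.binomial(counts, r)
    movers = counts - stay
    new = stay.astype(np.int64)
    if movers.any():
        split = rng.multinomial(movers.ravel(), np.full(6, 1 / 6))  # (n_cells, 6)
        for d in range(6):
            new = new + roll_to_neighbor(
                split[:, d].reshape(counts.shape).astype(np.int64), HEX_DIRECTIONS[d]
            )
    return new


def diffuse_species(grid: GridState, species: int, r: float, rng: np.random.Generator) -> None:
    """Diffuse one free species in place."""
    grid.species[species - 1] = diffuse_counts(grid.counts(species), r, rng)


def diffuse_boxes(grid: GridState, box_kind: int, r: float, rng: np.random.Generator) -> None:
    """Diffuse polymer boxes (kind 1 or 2) in place; compositions travel intact."""
    if box_kind == 1:
        for comp in list(grid.poly1):
            grid.poly1[comp] = diffuse_box_counts(grid.poly1[comp], r, rng)
    elif box_kind == 2:
        grid.poly2 = diffuse_box_counts(grid.poly2, r, rng)
    else:
        raise ValueError(f"unknown box kind {box_kind}")


def diffuse_all(grid: GridState, rates: ResidualRateTable, rng: np.random.Generator) -> None:
    """Diffuse every species (1..15 in order) and both polymer kinds."""
    for s in range(1, 16):
        diffuse_species(grid, s, rates.r[s], rng)
    diffuse_boxes(grid, 1, rates.r_poly1, rng)
    diffuse_boxes(grid, 2, rates.r_poly2, rng)
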