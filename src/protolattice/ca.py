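"""Reference cellular automaton: discretized Turing-pattern threshold rules.

A binary state per cell on the same periodic hexagonal lattice.  ``N1``
counts active cells within hex distance ``s`` of the focal cell (inclusive)
and ``N2`` within the outer range ``t_range`` (= 2s by convention).  The
basic rule activates a cell when short-range activity beats the weighted
long-range activity (``N1 > N2 * w``); the banded variant with two weights
``w1 < w2`` activates only inside a band, which yields self-dividing
domains.  The chemical model is built to realize the basic rule's
inequality through molecule counts, so this module serves as its
cross-validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import LatticeConfig, hex_distance, roll_to_neighbor


@dataclass(frozen=True)
class CARuleParams:
    w: float = 0.650
    w1: float = 0.650
    w2: float = 0.80
    s: int = 2
    t_range: int = 4

    def __post_init__(self):
        if self.s >= self.t_range:
            raise ValueError("inner range s must be smaller than t_range")
        if not (0.0 < self.w < 1.0):
            raise ValueError("w must lie in (0, 1)")
        if not (0.0 < self.w1 <= self.w2 < 1.0):
            raise ValueError("weights must satisfy 0 < w1 <= w2 < 1")


def _ring_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if hex_distance((dr, dc)) <= radius
    ]


def neighborhood_sum(grid: np.ndarray, radius: int) -> np.ndarray:
    """Per-cell count of active cells within hex distance ``radius`` (periodic)."""
    out = np.zeros_like(grid)
    for off in _ring_offsets(radius):
        out = out + roll_to_neighbor(grid, off)
    return out


def neighborhood_sums(grid: np.ndarray, cell: tuple[int, int], s: int,
                      t_range: int) -> tuple[int, int]:
    """(N1, N2) for one focal cell; N1 over radius s, N2 over t_range."""
    if s >= t_range:
        raise ValueError("s must be < t_range")
    n1 = int(neighborhood_sum(grid, s)[cell])
    n2 = int(neighborhood_sum(grid, t_range)[cell])
    return n1, n2


def step_expression1(grid: np.ndarray, params: CARuleParams) -> np.ndarray:
    """Synchronous threshold update: 1 if N1 > N2*w, 0 if N1 < N2*w, else hold.

    Equality is compared directly on the float product (no epsilon): integer
    N1 meets N2*w essentially only when both vanish, which keeps an all-zero
    grid fixed instead of flooding it.
    """
    n1 = neighborhood_sum(grid, params.s)
    n2 = neighborhood_sum(grid, params.t_range)
    thr = n2 * params.w
    return np.where(n1 > thr, 1, np.where(n1 < thr, 0, grid)).astype(grid.dtype)


def step_expression2(grid: np.ndarray, params: CARuleParams) -> np.ndarray:
    """Banded variant: active only in N2*w1 < N1 <= N2*w2; hold on N1 == N2*w1."""
    if not (0.0 < params.w1 <= params.w2 < 1.0):
        raise ValueError("need 1 > w2 >= w1 > 0")
    n1 = neighborhood_sum(grid, params.s)
    n2 = neighborhood_sum(grid, params.t_range)
    lo = n2 * params.w1
    hi = n2 * params.w2
    out = np.where(n1 > hi, 0,
                   np.where(n1 > lo, 1,
                            np.where(n1 == lo, grid, 0)))
    return out.astype(grid.dtype)


def random_seeding(config: LatticeConfig, density: float,
                   rng: np.random.Generator) -> np.ndarray:
    return (rng.random(config.shape) < density).astype(np.int8)


def run_ca(grid: np.ndarray, params: CARuleParams, steps: int,
           rule: str = "expression1") -> np.ndarray:
    step_fn = step_expression1 if rule == "expression1" else step_expression2
    for _ in range(steps):
        grid = step_fn(grid, params)
    return grid
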