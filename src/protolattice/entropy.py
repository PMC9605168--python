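"""Morphological entropy and entropy-production accounting.

Morphological (configuration) entropy measures spatial order: the
Stirling-approximated log-multiplicity of the equidistributed arrangement
minus that of the observed arrangement, in natural-log units (k = 1).
Zero means perfectly uniform placement; larger values mean molecules are
gathered into specific regions.

Entropy production has two parts.  The diffusive part discretizes
k D (grad C)^2 / C (with k = D = 1) into a sum over adjacent cell pairs of
(count difference)^2 over the pair mean.  The reactive part counts one unit
per molecule converted away from the feedstock (molecule 1) and minus one
per molecule returned to it, accumulated over time; polymerization and
degradation events move no molecule into or out of species 1 and tally 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lattice import GridState, roll_to_neighbor

# three of the six hex directions: each unordered adjacent pair once
_PAIR_DIRECTIONS = ((0, 1), (1, 0), (1, -1))


def _xlogx_minus_x(u: np.ndarray | float) -> np.ndarray | float:
    """u*log(u) - u with the 0*log0 := 0 convention (so the value at 0 is 0)."""
    u = np.asarray(u, dtype=float)
    safe = np.where(u > 0, u, 1.0)
    return np.where(u > 0, safe * np.log(safe) - safe, 0.0)


def max_config_entropy(m: float, X: int) -> float:
    """Log-multiplicity of m molecules spread evenly over X cells (Stirling)."""
    if X < 1:
        raise ValueError("X must be >= 1")
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return 0.0
    return float(_xlogx_minus_x(m) - X * _xlogx_minus_x(m / X))


def config_entropy(occupancies) -> float:
    """Log-multiplicity of the observed arrangement: (m log m - m) - sum(U log U - U)."""
    u = np.asarray(occupancies, dtype=float).ravel()
    if (u < 0).any():
        raise ValueError("occupancies must be non-negative")
    m = u.sum()
    if m == 0:
        return 0.0
    return float(_xlogx_minus_x(m) - _xlogx_minus_x(u).sum())


def morphological_entropy(occupancies) -> float:
    """Maximum configuration entropy minus configuration entropy; >= 0.

    0 for uniform occupancy; grows as molecules concentrate.
    """
    u = np.asarray(occupancies, dtype=float).ravel()
    value = max_config_entropy(u.sum(), u.size) - config_entropy(u)
    return max(value, 0.0)  # clip float residue on exactly-uniform input


def pairwise_diffusion_entropy(counts: np.ndarray) -> float:
    """Sum over adjacent cell pairs of (count difference)^2 / pair mean."""
    total = 0.0
    c = counts.astype(float)
    for d in _PAIR_DIRECTIONS:
        nb = roll_to_neighbor(c, d)
        mean = 0.5 * (c + nb)
        diff2 = (c - nb) ** 2
        np.divide(diff2, mean, out=diff2, where=mean > 0)
        total += float(diff2[mean > 0].sum())
    return total


def diffusion_entropy_production(grid: GridState, species: list[int] | None = None) -> float:
    """Discrete diffusive entropy production of the grid (k = 1, D = 1).

    Sums over every unordered adjacent pair and the selected free species
    (default: all 15); pairs with both counts zero contribute nothing.
    """
    if species is None:
        species = list(range(1, 16))
    return sum(pairwise_diffusion_entropy(grid.counts(s)) for s in species)


def reaction_entropy_production(event_log) -> float:
    """Cumulative reactive entropy production from per-step (away, back) tallies."""
    total = 0
    for away, back in event_log:
        total += away - back
    return float(total)


@dataclass
class EntropyLedger:
    """Time series of the three entropy observables."""

    steps: list[int] = field(default_factory=list)
    S_D: list[float] = field(default_factory=list)
    S_R_cumulative: list[float] = field(default_factory=list)
    H_morph: list[float] = field(default_factory=list)
    _running_S_R: int = 0

    def record(self, step: int, grid: GridState, tally_net: int,
               morph_species: str = "poly2",
               diffusion_species: list[int] | None = None) -> None:
        self._running_S_R += tally_net
        self.steps.append(step)
        self.S_D.append(diffusion_entropy_production(grid, diffusion_species))
        self.S_R_cumulative.append(float(self._running_S_R))
        occ = grid.poly2 if morph_species == "poly2" else grid.counts(int(morph_species))
        self.H_morph.append(morphological_entropy(occ))

    def accumulate(self, tally_net: int) -> None:
        """Fold a step's reaction tally into the running total without a row."""
        self._running_S_R += tally_net

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": self.steps,
            "S_D": self.S_D,
            "S_R_cumulative": self.S_R_cumulative,
            "H_morph": self.H_morph,
        })

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
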