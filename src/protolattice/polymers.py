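"""Synthesis, template copying and degradation of the two polymer kinds.

Polymers are bookkept as virtual boxes.  An informant polymer (kind 1) is a
box of ``P1_SIZE`` monomers of molecules 6 and 7 whose 6-fraction encodes
the morphology parameter ``w``; it is copied by template (same composition
as the boxes already in the cell) whenever molecule 11 is present, and
never decomposes.  A membrane polymer (kind 2) is a box of exactly 100
molecule-12 monomers, synthesized where molecule 13 is present and degraded
back to monomers (5% per box per step) only where molecule 13 is absent.
At most one synthesis of each kind happens per cell per step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import CellState, GridState, PolymerBox1

P1_SIZE_DEFAULT = 100


@dataclass(frozen=True)
class PolymerParams:
    p1_size: int = P1_SIZE_DEFAULT
    p2_degradation_rate: float = 0.05

    def __post_init__(self):
        if self.p1_size < 1:
            raise ValueError("p1_size must be positive")
        if not (0.0 <= self.p2_degradation_rate <= 1.0):
            raise ValueError("degradation rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# per-cell operations
# ---------------------------------------------------------------------------

def read_local_w(cell: CellState) -> float | None:
    """Molecule-6 fraction pooled over the cell's informant boxes.

    ``None`` when the cell holds no informant — downstream ratio conversion
    is then skipped (no informant, no specified rate).
    """
    n6 = sum(b.n6 for b in cell.polymer1_boxes)
    tot = sum(b.size for b in cell.polymer1_boxes)
    if tot == 0:
        return None
    return n6 / tot


def synthesize_polymer1(cell: CellState, rng: np.random.Generator,
                        params: PolymerParams = PolymerParams()) -> CellState:
    """Template-copy one informant box if molecule 11 and a template are present.

    The new box copies the pooled local composition ``round(w * P1_SIZE)``;
    its monomers are debited from the free molecule-6/7 pools.  No free
    monomers, no copy.
    """
    w = read_local_w(cell)
    if w is None or cell.count(11) < 1:
        return cell
    need6 = int(np.floor(w * params.p1_size + 0.5 + 1e-9))
    need7 = params.p1_size - need6
    if cell.count(6) < need6 or cell.count(7) < need7:
        return cell
    inv = cell.inventory.copy()
    inv[5] -= need6
    inv[6] -= need7
    return CellState(
        inventory=inv,
        polymer1_boxes=cell.polymer1_boxes + [PolymerBox1(need6, need7)],
        polymer2_count=cell.polymer2_count,
    )


def synthesize_polymer2(cell: CellState) -> CellState:
    """Link 100 molecule-12 monomers into one membrane box if molecule 13 is present."""
    if cell.count(13) < 1 or cell.count(12) < GridState.P2_SIZE:
        return cell
    inv = cell.inventory.copy()
    inv[11] -= GridState.P2_SIZE
    return CellState(
        inventory=inv,
        polymer1_boxes=list(cell.polymer1_boxes),
        polymer2_count=cell.polymer2_count + 1,
    )


def degrade_polymer2(cell: CellState, rng: np.random.Generator,
                     params: PolymerParams = PolymerParams()) -> CellState:
    """Degrade membrane boxes (each with prob. 5%) only when molecule 13 is absent."""
    if cell.count(13) >= 1 or cell.polymer2_count == 0:
        return cell
    degraded = int(rng.binomial(cell.polymer2_count, params.p2_degradation_rate))
    if degraded == 0:
        return cell
    inv = cell.inventory.copy()
    inv[11] += GridState.P2_SIZE * degraded
    return CellState(
        inventory=inv,
        polymer1_boxes=list(cell.polymer1_boxes),
        polymer2_count=cell.polymer2_count - degraded,
    )


# ---------------------------------------------------------------------------
# grid-level (vectorized) operations
# ---------------------------------------------------------------------------

def local_w_grid(grid: GridState) -> np.ndarray:
    """Per-cell pooled informant ratio; NaN where no informant box sits."""
    num = np.zeros(grid.config.shape, dtype=np.float64)
    den = np.zeros(grid.config.shape, dtype=np.float64)
    for (n6, n7), cnt in grid.poly1.items():
        num += n6 * cnt
        den += (n6 + n7) * cnt
    with np.errstate(invalid="ignore", divide="ignore"):
        w = num / den
    w[den == 0] = np.nan
    return w


def synthesize_polymer1_grid(grid: GridState, params: PolymerParams = PolymerParams()) -> int:
    """One template copy per eligible cell; returns the number of boxes made."""
    w = local_w_grid(grid)
    eligible = ~np.isnan(w) & (grid.counts(11) >= 1)
    if not eligible.any():
        return 0
    need6 = np.zeros(grid.config.shape, dtype=np.int64)
    need6[eligible] = np.floor(w[eligible] * params.p1_size + 0.5 + 1e-9).astype(np.int64)
    need7 = params.p1_size - need6
    ok = eligible & (grid.counts(6) >= need6) & (grid.counts(7) >= need7)
    if not ok.any():
        return 0
    grid.species[5][ok] -= need6[ok]
    grid.species[6][ok] -= need7[ok]
    made = 0
    for n6 in np.unique(need6[ok]):
        sel = ok & (need6 == n6)
        grid.add_poly1((int(n6), params.p1_size - int(n6)), sel.astype(np.int64))
        made += int(sel.sum())
    return made


def synthesize_polymer2_grid(grid: GridState) -> int:
    """One membrane box per cell holding molecule 13 and 100 free monomers."""
    ok = (grid.counts(13) >= 1) & (grid.counts(12) >= GridState.P2_SIZE)
    if not ok.any():
        return 0
    grid.species[11][ok] -= GridState.P2_SIZE
    grid.poly2[ok] += 1
    return int(ok.sum())


def degrade_polymer2_grid(grid: GridState, rng: np.random.Generator,
                          params: PolymerParams = PolymerParams()) -> int:
    """Binomial degradation of membrane boxes in molecule-13-free cells."""
    unguarded = grid.counts(13) == 0
    at_risk = np.where(unguarded, grid.poly2, 0)
    if not at_risk.any():
        return 0
    degraded = rng.binomial(at_risk, params.p2_degradation_rate).astype(np.int64)
    grid.poly2 -= degraded
    grid.species[11] += GridState.P2_SIZE * degraded
    return int(degraded.sum())
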