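"""Hexagonal periodic lattice topology, cell state containers and initialization.

The lattice is a rhombic torus in axial hex coordinates: cells are indexed
``(row, col)`` in a ``height x width`` array and the six neighbors of every
cell sit at the same six axial offsets, with wrap-around at the edges.  This
keeps the hexagonal topology (degree 6, symmetric neighbor relation,
isotropic adjacency) while letting every lattice-wide operation be expressed
as ``np.roll`` shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_SPECIES = 15

#: Axial hex neighbor offsets (drow, dcol); identical for every cell.
HEX_DIRECTIONS: tuple[tuple[int, int], ...] = (
    (0, 1),
    (0, -1),
    (1, 0),
    (-1, 0),
    (1, -1),
    (-1, 1),
)


@dataclass(frozen=True)
class LatticeConfig:
    """Dimensions of the periodic hexagonal grid.

    The boundary is always periodic; widths/heights below 3 would make the
    six neighbor offsets collide on the torus and are rejected.
    """

    width: int = 100
    height: int = 100

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ValueError("lattice must be at least 3x3")

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


def neighbors(coord: tuple[int, int], config: LatticeConfig) -> list[tuple[int, int]]:
    """Return the six (periodic) neighbor coordinates of ``coord``.

    Raises ``ValueError`` if ``coord`` lies outside the grid.
    """
    r, c = coord
    if not (0 <= r < config.height and 0 <= c < config.width):
        raise ValueError(f"coordinate {coord} outside {config.shape} grid")
    return [((r + dr) % config.height, (c + dc) % config.width) for dr, dc in HEX_DIRECTIONS]


def hex_distance(a: tuple[int, int], b: tuple[int, int] = (0, 0)) -> int:
    """Hex (ring) distance between two axial coordinates, ignoring wrap."""
    dr = a[0] - b[0]
    dc = a[1] - b[1]
    return (abs(dr) + abs(dc) + abs(dr + dc)) // 2


def hex_disk(center: tuple[int, int], radius: int, config: LatticeConfig) -> list[tuple[int, int]]:
    """All cells within hex distance ``radius`` of ``center`` (periodic)."""
    cells = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if hex_distance((dr, dc)) <= radius:
                cells.append(((center[0] + dr) % config.height, (center[1] + dc) % config.width))
    return cells


def roll_to_neighbor(arr: np.ndarray, direction: tuple[int, int]) -> np.ndarray:
    """Shift a per-cell array so each value lands on its neighbor in ``direction``."""
    return np.roll(arr, direction, axis=(0, 1))


@dataclass
class PolymerBox1:
    """One informant polymer: a composition of molecule-6 and molecule-7 monomers.

    The molecule-6 fraction ``w_box`` encodes the morphology parameter *w*.
    """

    n6: int
    n7: int

    def __post_init__(self) -> None:
        if self.n6 < 0 or self.n7 < 0 or self.n6 + self.n7 <= 0:
            raise ValueError("polymer-1 box needs non-negative monomers, at least one")

    @property
    def size(self) -> int:
        return self.n6 + self.n7

    @property
    def w_box(self) -> float:
        return self.n6 / (self.n6 + self.n7)


@dataclass
class CellState:
    """Per-cell multiset state: free molecule counts plus polymer boxes."""

    inventory: np.ndarray  # length-15 int64 vector, species 1..15 at index s-1
    polymer1_boxes: list[PolymerBox1] = field(default_factory=list)
    polymer2_count: int = 0

    def count(self, species: int) -> int:
        return int(self.inventory[species - 1])

    def total_monomers(self, p2_size: int = 100) -> int:
        free = int(self.inventory.sum())
        boxed1 = sum(b.size for b in self.polymer1_boxes)
        return free + boxed1 + p2_size * self.polymer2_count


class GridState:
    """Full lattice state.

    ``species[s-1]`` holds the per-cell count of free molecule ``s``;
    polymer-1 boxes are grouped by composition (``(n6, n7) -> count grid``,
    exploiting that boxes of equal composition are interchangeable);
    ``poly2`` is the per-cell membrane-polymer box count.
    """

    P2_SIZE = 100  # monomers of molecule 12 per membrane polymer

    def __init__(self, config: LatticeConfig):
        self.config = config
        self.species = np.zeros((N_SPECIES,) + config.shape, dtype=np.int64)
        self.poly1: dict[tuple[int, int], np.ndarray] = {}
        self.poly2 = np.zeros(config.shape, dtype=np.int64)
        self.time_step = 0

    # -- accessors -------------------------------------------------------

    def counts(self, species: int) -> np.ndarray:
        """Per-cell count grid for molecule ``species`` (1-based)."""
        return self.species[species - 1]

    def poly1_count(self) -> np.ndarray:
        """Per-cell total polymer-1 box count."""
        total = np.zeros(self.config.shape, dtype=np.int64)
        for grid in self.poly1.values():
            total += grid
        return total

    def add_poly1(self, comp: tuple[int, int], where: np.ndarray | tuple[int, int]) -> None:
        comp = (int(comp[0]), int(comp[1]))
        if comp not in self.poly1:
            self.poly1[comp] = np.zeros(self.config.shape, dtype=np.int64)
        if isinstance(where, tuple):
            self.poly1[comp][where] += 1
        else:
            self.poly1[comp] += where

    def cell(self, r: int, c: int) -> CellState:
        boxes = []
        for (n6, n7), grid in self.poly1.items():
            boxes.extend(PolymerBox1(n6, n7) for _ in range(int(grid[r, c])))
        return CellState(
            inventory=self.species[:, r, c].copy(),
            polymer1_boxes=boxes,
            polymer2_count=int(self.poly2[r, c]),
        )

    def set_cell(self, r: int, c: int, cell: CellState) -> None:
        self.species[:, r, c] = cell.inventory
        for grid in self.poly1.values():
            grid[r, c] = 0
        for box in cell.polymer1_boxes:
            self.add_poly1((box.n6, box.n7), (r, c))
        self.poly2[r, c] = cell.polymer2_count

    # -- conservation ledger ---------------------------------------------

    def grand_total(self) -> int:
        """Total monomer count: free species + polymer-1 contents + P2 contents.

        Conserved exactly by every diffusion/reaction/polymerization step.
        """
        total = int(self.species.sum())
        for (n6, n7), grid in self.poly1.items():
            total += (n6 + n7) * int(grid.sum())
        total += self.P2_SIZE * int(self.poly2.sum())
        return total

    def copy(self) -> "GridState":
        out = GridState(self.config)
        out.species = self.species.copy()
        out.poly1 = {comp: grid.copy() for comp, grid in self.poly1.items()}
        out.poly2 = self.poly2.copy()
        out.time_step = self.time_step
        return out

    def equals(self, other: "GridState") -> bool:
        if self.config != other.config or self.time_step != other.time_step:
            return False
        if not np.array_equal(self.species, other.species):
            return False
        if not np.array_equal(self.poly2, other.poly2):
            return False
        keys = {k for k, g in self.poly1.items() if g.any()}
        okeys = {k for k, g in other.poly1.items() if g.any()}
        if keys != okeys:
            return False
        return all(np.array_equal(self.poly1[k], other.poly1[k]) for k in keys)


@dataclass
class InitialConditionSpec:
    """Standard initial arrangement.

    A uniform background of feedstock (molecule 1), polymer-1 monomers
    (6, 7), membrane monomers (12) and the two gate species (14, 15) fills
    every cell; morphogen seeds (molecules 2, 3) and the founding informant
    polymers go in a small central region.
    """

    mol1_per_cell: int = 1_000_000
    mol6_per_cell: int = 50_000
    mol7_per_cell: int = 50_000
    mol12_per_cell: int = 100_000
    mol14_per_cell: int = 3
    mol15_per_cell: int = 9
    seed_amount_mol2: int = 100
    seed_amount_mol3: int = 100
    seed_region: list[tuple[int, int]] | None = None  # default: hex disk radius 2 at center
    seed_radius: int = 2
    polymer1_initial_count: int = 10
    polymer1_initial_w: float = 0.650
    polymer1_region_radius: int = 3
    p1_size: int = 100  # monomers per informant polymer

    def background_per_cell(self) -> int:
        return (
            self.mol1_per_cell
            + self.mol6_per_cell
            + self.mol7_per_cell
            + self.mol12_per_cell
            + self.mol14_per_cell
            + self.mol15_per_cell
        )


def initialize_grid(
    config: LatticeConfig,
    init: InitialConditionSpec,
    rng: np.random.Generator,
) -> GridState:
    """Build the t=0 grid from an initial-condition spec.

    Background counts fill every cell; molecules 2 and 3 are seeded in the
    central region; ``polymer1_initial_count`` informant boxes with
    composition ratio ``polymer1_initial_w`` are scattered uniformly at
    random over a central hex disk.
    """
    grid = GridState(config)
    center = (config.height // 2, config.width // 2)

    grid.species[0, :, :] = init.mol1_per_cell
    grid.species[5, :, :] = init.mol6_per_cell
    grid.species[6, :, :] = init.mol7_per_cell
    grid.species[11, :, :] = init.mol12_per_cell
    grid.species[13, :, :] = init.mol14_per_cell
    grid.species[14, :, :] = init.mol15_per_cell

    region = init.seed_region
    if region is None:
        region = hex_disk(center, init.seed_radius, config)
    if init.seed_amount_mol2 or init.seed_amount_mol3:
        if not region:
            raise ValueError("seed region is empty")
        for r, c in region:
            if not (0 <= r < config.height and 0 <= c < config.width):
                raise ValueError(f"seed cell {(r, c)} outside grid")
            grid.species[1, r, c] += init.seed_amount_mol2
            grid.species[2, r, c] += init.seed_amount_mol3

    if init.polymer1_initial_count > 0:
        n6 = int(round(init.polymer1_initial_w * init.p1_size))
        comp = (n6, init.p1_size - n6)
        disk = hex_disk(center, init.polymer1_region_radius, config)
        picks = rng.integers(0, len(disk), size=init.polymer1_initial_count)
        for i in picks:
            grid.add_poly1(comp, disk[int(i)])

    return grid
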