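"""Boundary-formation and replication metrics on the membrane-polymer field.

The membrane polymer's spatial accumulation defines the cell-like region;
these helpers threshold it into a binary mask, count connected domains
under periodic 6-neighbor adjacency, and classify a run's domain time
series into the qualitative pattern classes (mesh / replicating /
stationary / extinct).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .lattice import GridState, LatticeConfig, roll_to_neighbor


@dataclass
class DomainReport:
    """Snapshot of the membrane-domain structure at one step."""

    step: int
    n_domains: int
    coverage: float
    sizes: list[int] = field(default_factory=list)
    mask: np.ndarray | None = None


def polymer2_mask(grid: GridState, threshold: int = 1) -> np.ndarray:
    """Binary mask of cells holding at least ``threshold`` membrane boxes."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return grid.poly2 >= threshold


def count_domains(mask: np.ndarray, config: LatticeConfig | None = None
                  ) -> tuple[int, list[int]]:
    """Connected components of a mask under periodic hex 6-adjacency.

    Returns ``(n_components, sizes)``; deterministic (sizes sorted
    descending).
    """
    mask = np.asarray(mask, dtype=bool)
    k = int(mask.sum())
    if k == 0:
        return 0, []
    idx = np.full(mask.shape, -1, dtype=np.int64)
    idx[mask] = np.arange(k)
    rows, cols = [], []
    for d in ((0, 1), (1, 0), (1, -1)):  # one direction per unordered pair
        nb_mask = roll_to_neighbor(mask, d)
        nb_idx = roll_to_neighbor(idx, d)
        both = mask & nb_mask
        rows.append(idx[both])
        cols.append(nb_idx[both])
    i = np.concatenate(rows)
    j = np.concatenate(cols)
    adj = coo_matrix((np.ones(i.size, dtype=np.int8), (i, j)), shape=(k, k))
    n, labels = connected_components(adj, directed=False)
    sizes = sorted(np.bincount(labels).tolist(), reverse=True)
    return int(n), sizes


def domain_report(grid: GridState, threshold: int = 1,
                  keep_mask: bool = False) -> DomainReport:
    mask = polymer2_mask(grid, threshold)
    n, sizes = count_domains(mask, grid.config)
    return DomainReport(
        step=grid.time_step,
        n_domains=n,
        coverage=float(mask.mean()),
        sizes=sizes,
        mask=mask.copy() if keep_mask else None,
    )


def classify_pattern(reports: list[DomainReport],
                     mesh_coverage: float = 0.25,
                     min_steps: int = 500) -> str:
    """Label a domain time series: mesh / replicating / stationary / extinct.

    Operational thresholds for the visual categories: *mesh* when the final
    coverage exceeds ``mesh_coverage``; *extinct* when domains appeared then
    vanished; *replicating* when the domain count ever rose above one at
    sub-mesh coverage; otherwise *stationary*.
    """
    if not reports or reports[-1].step - reports[0].step + 1 < min_steps:
        raise ValueError(f"need at least {min_steps} steps of reports")
    coverages = [r.coverage for r in reports]
    final = coverages[-1]
    ever_populated = any(c > 0 for c in coverages)
    if final > mesh_coverage:
        return "mesh"
    if final == 0:
        return "extinct" if ever_populated else "stationary"
    if max(r.n_domains for r in reports) > 1:
        return "replicating"
    return "stationary"


def reports_to_frame(reports: list[DomainReport]) -> pd.DataFrame:
    return pd.DataFrame({
        "step": [r.step for r in reports],
        "n_domains": [r.n_domains for r in reports],
        "coverage": [r.coverage for r in reports],
        "largest_domain": [r.sizes[0] if r.sizes else 0 for r in reports],
    })
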