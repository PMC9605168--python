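"""Multiset rewriting of molecule counts inside each cell.

The fixed reaction network turns the threshold rule of the reference
cellular automaton into chemistry: short- and long-range morphogens
(molecules 2/4 and 3/5) catalyze production of comparator species 8, 9, 11
from the feedstock (molecule 1); the informant polymer's molecule-6 ratio
``w`` converts a matching share of 8+9 into molecule 10; pair annihilation
of 10 against 11 leaves molecule 11 standing exactly where local activity
exceeds the ``w`` threshold; a small gate subsystem (molecules 14/15/13)
restricts membrane formation to a band of molecule-11 counts; and removal
reactions close every path back to molecule 1.

Every rule conserves the cell's total molecule count.  Within a step the
stages run in a fixed order (A..G); rules inside a stage run in listed
order, each drawing on the then-current counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .lattice import CellState, GridState

_EPS = 1e-9

STAGE_ORDER = ("A", "B", "C", "D", "E", "F", "G")


def _round_half_up(x):
    return np.floor(np.asarray(x) + 0.5 + _EPS).astype(np.int64)


# ---------------------------------------------------------------------------
# scalar / array reaction primitives
# ---------------------------------------------------------------------------

def first_order_converted(count, p: float, rng: np.random.Generator):
    """Units converted when each molecule reacts with probability ``p``.

    Deterministic share ``floor(count*p)`` plus one extra unit with
    probability ``frac(count*p)``, so the expectation is exactly ``count*p``
    and counts stay integral.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"reaction probability must be in [0, 1], got {p}")
    count = np.asarray(count)
    expected = count * p
    base = np.floor(expected + _EPS).astype(np.int64)
    frac = np.maximum(expected - base, 0.0)
    if np.max(frac, initial=0.0) > _EPS:
        base = base + (rng.random(count.shape) < frac)
    return np.minimum(base, count)


def apply_first_order(count: int, p: float, rng: np.random.Generator) -> tuple[int, int]:
    """First-order conversion of a single count: ``(remaining, converted)``."""
    if count < 0:
        raise ValueError("count must be non-negative")
    converted = int(first_order_converted(count, p, rng))
    return count - converted, converted


def apply_catalytic(substrate_count: int, catalyst_count: int, p: float,
                    rng: np.random.Generator) -> int:
    """Catalytic conversion: each catalyst unit processes one substrate unit.

    At ``p = 1`` exactly ``min(substrate, catalyst)`` units convert; at
    lower rates that cap is thinned first-order.  The catalyst is untouched.
    """
    if substrate_count < 0 or catalyst_count < 0:
        raise ValueError("counts must be non-negative")
    cap = min(substrate_count, catalyst_count)
    if p == 1.0:
        return cap
    return int(first_order_converted(cap, p, rng))


def apply_pair_annihilation(count_a: int, count_b: int) -> tuple[int, int, int]:
    """Mutual annihilation ``a + b -> 1 + 1``: ``(a_left, b_left, released)``.

    The more abundant partner survives; ``released`` counts the molecule-1
    units returned (two per annihilated pair).
    """
    k = min(count_a, count_b)
    return count_a - k, count_b - k, 2 * k


def apply_ratio_conversion(count: int, w: float) -> int:
    """Units converted at the informant ratio ``w`` (``round(count*w)``)."""
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"ratio must be in [0, 1], got {w}")
    return int(_round_half_up(count * w))


def _window_single_pass_full(n11, n13, c14, c15):
    # (i) molecule 14 destroys up to c14 units of 11 back to 1;
    # (ii) molecule 15 converts up to c15 further units of 11 into 13;
    # (iii) each remaining 11 flips one 13 back into 11 (count conserving).
    # Molecule 13 survives only for a contiguous band of incoming n11 —
    # the membrane trigger window.
    n11 = np.asarray(n11)
    d = np.minimum(c14, n11)
    rem = n11 - d
    m = np.minimum(c15, rem)
    rem = rem - m
    stock13 = np.asarray(n13) + m
    k = np.minimum(stock13, rem)
    n11_out = rem + k
    n13_out = stock13 - k
    return n11_out, n13_out, d, m, k


WindowPolicy = Callable[..., tuple]

#: Swappable schedules for the gate subsystem.  ``single_pass`` applies the
#: three reactions once, in listed order; ``iterated`` replays the
#: 13 + 11 -> 11 + 11 pairing to exhaustion (kept for comparison: it
#: erases molecule 13 whenever any 11 survives, closing the window).
WINDOW_POLICIES: dict[str, WindowPolicy] = {}


def _register_policy(name):
    def deco(fn):
        WINDOW_POLICIES[name] = fn
        return fn
    return deco


@_register_policy("single_pass")
def _policy_single_pass(n11, n13, c14, c15):
    return _window_single_pass_full(n11, n13, c14, c15)


@_register_policy("iterated")
def _policy_iterated(n11, n13, c14, c15):
    n11_out, n13_out, d, m, k = _window_single_pass_full(n11, n13, c14, c15)
    # any surviving 11 pairs away the remaining 13 in one more sweep
    step = np.where(n11_out > 0, n13_out, 0)
    return n11_out + step, n13_out - step, d, m, k + step


def apply_window_subsystem(n11: int, n13: int, c14: int, c15: int,
                           policy: str = "single_pass") -> tuple[int, int, int]:
    """Gate subsystem on scalar counts: ``(n11', n13', released_mol1)``."""
    if min(n11, n13, c14, c15) < 0:
        raise ValueError("counts must be non-negative")
    n11_out, n13_out, d, _m, _k = WINDOW_POLICIES[policy](n11, n13, c14, c15)
    return int(n11_out), int(n13_out), int(d)


# ---------------------------------------------------------------------------
# network definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionRule:
    """One rewriting rule.

    ``rate`` is a per-step probability in [0, 1].  ``partner`` names the
    second reactant of a pair annihilation; the window rule names its gate
    species explicitly.  Every rule conserves total molecule count.
    """

    kind: str  # first_order | catalytic | ratio_conversion | pair_annihilation | window_subsystem
    stage: str
    substrate: int | None = None
    product: int | None = None
    catalyst: int | None = None
    partner: int | None = None
    rate: float = 1.0
    gate_low: int | None = None   # destroys substrate (molecule 14)
    gate_high: int | None = None  # converts substrate to intermediate (molecule 15)
    intermediate: int | None = None  # molecule 13

    def __post_init__(self):
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError(f"rate must be in [0, 1], got {self.rate}")
        if self.kind == "catalytic" and self.substrate == self.catalyst:
            raise ValueError("catalytic rule needs substrate != catalyst")
        if self.kind not in {"first_order", "catalytic", "ratio_conversion",
                             "pair_annihilation", "window_subsystem"}:
            raise ValueError(f"unknown rule kind {self.kind!r}")


def _pct(x: float) -> float:
    return x / 100.0


def canonical_network() -> "NetworkDefinition":
    """The full fixed reaction network, stages A..G."""
    R = ReactionRule
    rules = [
        # A: morphogen maturation
        R("first_order", "A", substrate=2, product=4, rate=_pct(5)),
        R("first_order", "A", substrate=3, product=5, rate=_pct(2)),
        # B: comparator production from the feedstock pool, in listed order
        R("catalytic", "B", substrate=1, product=8, catalyst=4, rate=1.0),
        R("catalytic", "B", substrate=1, product=11, catalyst=4, rate=1.0),
        R("catalytic", "B", substrate=1, product=9, catalyst=5, rate=1.0),
        # C: informant-ratio conversion, then comparator reset
        R("ratio_conversion", "C", substrate=8, product=10),
        R("ratio_conversion", "C", substrate=9, product=10),
        R("first_order", "C", substrate=8, product=1, rate=1.0),
        R("first_order", "C", substrate=9, product=1, rate=1.0),
        # D: threshold comparison by mutual annihilation
        R("pair_annihilation", "D", substrate=10, partner=11, product=1),
        # E: gate subsystem (membrane trigger window)
        R("window_subsystem", "E", substrate=11, product=1,
          gate_low=14, gate_high=15, intermediate=13),
        # F: morphogen regeneration
        R("catalytic", "F", substrate=1, product=2, catalyst=11, rate=1.0),
        R("catalytic", "F", substrate=1, product=3, catalyst=11, rate=1.0),
        R("catalytic", "F", substrate=1, product=2, catalyst=13, rate=1.0),
        R("catalytic", "F", substrate=1, product=3, catalyst=13, rate=1.0),
        R("catalytic", "F", substrate=1, product=2, catalyst=14, rate=1.0),
        R("catalytic", "F", substrate=1, product=3, catalyst=14, rate=1.0),
        # G: removals, closing every path back to molecule 1
        R("first_order", "G", substrate=4, product=1, rate=_pct(5)),
        R("first_order", "G", substrate=5, product=1, rate=_pct(5)),
        R("first_order", "G", substrate=8, product=1, rate=1.0),
        R("first_order", "G", substrate=9, product=1, rate=1.0),
        R("first_order", "G", substrate=10, product=1, rate=_pct(5)),
        R("first_order", "G", substrate=11, product=1, rate=_pct(5)),
        R("first_order", "G", substrate=13, product=1, rate=_pct(75)),
    ]
    return NetworkDefinition(rules=rules)


@dataclass
class NetworkDefinition:
    """Ordered rule list plus the schedule policies left open by the model.

    ``stage_f_gate`` controls where the morphogen-regeneration stage runs:
    ``"mol13"`` (default) runs it only in cells holding the membrane
    trigger (molecule 13) — the regeneration is stated to accompany
    membrane formation, and this keeps the quiescent background inert;
    ``"mol11_or_13"`` also admits cells with surviving comparator 11;
    ``"none"`` gates on catalyst presence alone (ubiquitous molecule 14
    then seeds morphogens everywhere).
    """

    rules: list[ReactionRule] = field(default_factory=lambda: canonical_network().rules)
    window_policy: str = "single_pass"
    stage_f_gate: str = "mol13"

    def __post_init__(self):
        if self.stage_f_gate not in {"none", "mol13", "mol11_or_13"}:
            raise ValueError(f"unknown stage_f_gate {self.stage_f_gate!r}")

    def stage_rules(self, stage: str) -> list[ReactionRule]:
        return [r for r in self.rules if r.stage == stage]

    def with_rate(self, substrate: int, product: int, rate_percent: float,
                  stage: str | None = None) -> "NetworkDefinition":
        """Copy with the rate of one (substrate -> product) rule replaced."""
        hit = False
        out = []
        for r in self.rules:
            if (r.substrate == substrate and r.product == product
                    and (stage is None or r.stage == stage)):
                out.append(replace(r, rate=rate_percent / 100.0))
                hit = True
            else:
                out.append(r)
        if not hit:
            raise KeyError(f"no rule {substrate} -> {product}" + (f" in stage {stage}" if stage else ""))
        return NetworkDefinition(rules=out, window_policy=self.window_policy,
                                 stage_f_gate=self.stage_f_gate)


# ---------------------------------------------------------------------------
# grid-level engine
# ---------------------------------------------------------------------------

@dataclass
class ReactionTally:
    """Per-step entropy bookkeeping: molecules converted away from vs. back
    to molecule 1 (polymerization events are entropy-neutral)."""

    away_from_1: int = 0
    back_to_1: int = 0

    @property
    def net(self) -> int:
        return self.away_from_1 - self.back_to_1


def apply_reaction_stages(
    species: np.ndarray,
    network: NetworkDefinition,
    w_grid: np.ndarray | float | None,
    rng: np.random.Generator,
    stages: tuple[str, ...] = STAGE_ORDER,
    tally: ReactionTally | None = None,
) -> ReactionTally:
    """Run the listed stages in place on a ``(15, H, W)`` count array.

    ``w_grid`` is the local informant ratio per cell; ``None`` (or NaN
    entries) means no informant is present and ratio conversion is skipped
    there (0 converted).
    """
    if tally is None:
        tally = ReactionTally()
    shape = species.shape[1:]
    if w_grid is None:
        w_arr = np.zeros(shape)
    else:
        w_arr = np.broadcast_to(np.asarray(w_grid, dtype=float), shape)
        w_arr = np.nan_to_num(w_arr, nan=0.0)

    def cnt(s):
        return species[s - 1]

    for stage in stages:
        gate = None
        if stage == "F" and network.stage_f_gate != "none":
            gate = cnt(13) >= 1
            if network.stage_f_gate == "mol11_or_13":
                gate = gate | (cnt(11) >= 1)
        for rule in network.stage_rules(stage):
            if rule.kind == "first_order":
                conv = first_order_converted(cnt(rule.substrate), rule.rate, rng)
                species[rule.substrate - 1] -= conv
                species[rule.product - 1] += conv
                _book(tally, rule.product, int(conv.sum()))
            elif rule.kind == "catalytic":
                cat = cnt(rule.catalyst)
                if gate is not None:
                    cat = np.where(gate, cat, 0)
                cap = np.minimum(cnt(rule.substrate), cat)
                conv = cap if rule.rate == 1.0 else first_order_converted(cap, rule.rate, rng)
                species[rule.substrate - 1] -= conv
                species[rule.product - 1] += conv
                _book(tally, rule.product, int(conv.sum()))
            elif rule.kind == "ratio_conversion":
                conv = np.minimum(_round_half_up(cnt(rule.substrate) * w_arr),
                                  cnt(rule.substrate))
                species[rule.substrate - 1] -= conv
                species[rule.product - 1] += conv
                _book(tally, rule.product, int(conv.sum()))
            elif rule.kind == "pair_annihilation":
                k = np.minimum(cnt(rule.substrate), cnt(rule.partner))
                species[rule.substrate - 1] -= k
                species[rule.partner - 1] -= k
                species[rule.product - 1] += 2 * k
                _book(tally, rule.product, 2 * int(k.sum()))
            elif rule.kind == "window_subsystem":
                n11, n13, d, m, k = WINDOW_POLICIES[network.window_policy](
                    cnt(rule.substrate), cnt(rule.intermediate),
                    cnt(rule.gate_low), cnt(rule.gate_high))
                species[rule.substrate - 1] = n11
                species[rule.intermediate - 1] = n13
                species[0] += d
                tally.back_to_1 += int(np.sum(d))
                tally.away_from_1 += int(np.sum(m)) + int(np.sum(k))
    return tally


def _book(tally: ReactionTally, product: int, n: int) -> None:
    if product == 1:
        tally.back_to_1 += n
    else:
        tally.away_from_1 += n


def step_cell_reactions(
    cell: CellState,
    network: NetworkDefinition,
    w_local: float | None,
    rng: np.random.Generator,
) -> CellState:
    """Apply all reaction stages A..G to a single cell; total count conserved."""
    species = cell.inventory.reshape(15, 1, 1).astype(np.int64).copy()
    w = None if w_local is None else float(w_local)
    apply_reaction_stages(species, network, w, rng)
    return CellState(
        inventory=species.reshape(15),
        polymer1_boxes=list(cell.polymer1_boxes),
        polymer2_count=cell.polymer2_count,
    )


def react_grid(
    grid: GridState,
    network: NetworkDefinition,
    w_grid: np.ndarray | None,
    rng: np.random.Generator,
    stages: tuple[str, ...] = STAGE_ORDER,
) -> ReactionTally:
    """Apply reaction stages to every cell of the grid, in place."""
    return apply_reaction_stages(grid.species, network, w_grid, rng, stages)
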