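"""Deterministic 2D gridworld MDP with feature-bearing items.

Agents move on a rectangular grid whose cells may contain collectable items.
Each item carries two binary features (colour and shape); an agent's utility
function maps those features to points. Episodes terminate when the acting
agent enters an item cell or exhausts a step budget, and every move costs a
fixed number of points, so efficient navigation toward preferred items is
rewarded.

Conventions
-----------
* Cells are 0-based ``(x, y)`` with the origin at the top-left; ``x`` grows
  rightward, ``y`` grows downward.
* Actions are the four cardinal moves plus a no-op. Moves into walls or off
  the grid leave the agent in place but still cost one step.
* The Boltzmann policy is ``pi(s, a) proportional to exp(Q(s, a) / beta)``:
  larger ``beta`` means a noisier, less reward-sensitive agent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

Cell = tuple[int, int]

#: Action names in canonical order.
ACTIONS: tuple[str, ...] = ("up", "down", "left", "right", "stay")
_ACTION_DELTA: dict[str, Cell] = {
    "up": (0, -1),
    "down": (0, 1),
    "left": (-1, 0),
    "right": (1, 0),
    "stay": (0, 0),
}
ACTION_INDEX = {a: i for i, a in enumerate(ACTIONS)}


@dataclass(frozen=True)
class FeatureSpace:
    """Binary feature dimensions an item can carry.

    ``dims`` maps each dimension name to its two levels; the second level of
    each pair is the "positive" one, i.e. the level a utility weight above
    0.5 prefers.
    """

    dims: tuple[tuple[str, tuple[str, str]], ...] = (
        ("colour", ("green", "yellow")),
        ("shape", ("triangle", "circle")),
    )

    @property
    def n_dims(self) -> int:
        return len(self.dims)

    def level_index(self, dim: int, level: str) -> int:
        name, levels = self.dims[dim]
        try:
            return levels.index(level)
        except ValueError:
            raise ValueError(f"unknown level {level!r} for dimension {name!r}")

    def item_levels(self, item: "ItemType") -> tuple[int, ...]:
        return tuple(
            self.level_index(d, getattr(item, self.dims[d][0]))
            for d in range(self.n_dims)
        )

    def all_items(self) -> list["ItemType"]:
        """The full cross of levels ('the four possible items')."""
        out = []
        for c in self.dims[0][1]:
            for s in self.dims[1][1]:
                out.append(ItemType(colour=c, shape=s))
        return out


DEFAULT_FEATURES = FeatureSpace()


@dataclass(frozen=True)
class ItemType:
    """A collectable item, described by its colour and shape."""

    colour: str
    shape: str


@dataclass(frozen=True)
class UtilityFunction:
    """Additive utility over binary item features.

    Each component of ``weights`` lies in [0, 1] with 0.5 meaning
    indifference on that dimension. The payoff of an item is additive across
    dimensions: dimension ``i`` contributes ``base + span * w_i`` when the
    item carries the positive level and ``base + span * (1 - w_i)``
    otherwise. Every step taken costs ``step_cost`` points.
    """

    weights: tuple[float, ...]
    step_cost: float = 1.0
    span: float = 10.0
    base: float = 0.0
    features: FeatureSpace = DEFAULT_FEATURES

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("utility weights must be finite")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    def item_value(self, item: ItemType) -> float:
        levels = self.features.item_levels(item)
        value = 0.0
        for w, lev in zip(self.weights, levels):
            value += self.base + self.span * (w if lev == 1 else 1.0 - w)
        return value


def item_values_for_lattice(
    weight_matrix: np.ndarray,
    items: Sequence[ItemType],
    features: FeatureSpace = DEFAULT_FEATURES,
    span: float = 10.0,
    base: float = 0.0,
) -> np.ndarray:
    """Item payoffs for many candidate weight vectors at once.

    Parameters
    ----------
    weight_matrix : (n_candidates, n_dims) array of weights in [0, 1].
    items : item types to evaluate.

    Returns
    -------
    (n_candidates, n_items) array of payoffs.
    """
    W = np.asarray(weight_matrix, dtype=float)
    levels = np.array([features.item_levels(it) for it in items])  # (I, D)
    # payoff per dim: base + span * (w if level==1 else 1-w)
    per_dim = np.where(levels[None, :, :] == 1, W[:, None, :], 1.0 - W[:, None, :])
    return (base + span * per_dim).sum(axis=2)


@dataclass(frozen=True)
class GridWorld:
    """A bounded deterministic gridworld with walls and item cells."""

    width: int
    height: int
    walls: frozenset = frozenset()
    items: Mapping[Cell, ItemType] = field(default_factory=dict)
    start_cells: tuple = ()
    level_id: str = "level"
    features: FeatureSpace = DEFAULT_FEATURES

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")
        object.__setattr__(self, "walls", frozenset(tuple(c) for c in self.walls))
        object.__setattr__(
            self, "items", dict((tuple(c), v) for c, v in dict(self.items).items())
        )
        object.__setattr__(
            self, "start_cells", tuple(tuple(c) for c in self.start_cells)
        )
        if not self.items:
            raise ValueError("grid must contain at least one item")
        for cell in list(self.walls) + list(self.items) + list(self.start_cells):
            if not self.in_bounds(cell):
                raise ValueError(f"cell {cell} out of bounds")
        if self.walls & set(self.items):
            raise ValueError("items and walls must be disjoint")
        for s in self.start_cells:
            if s in self.items:
                raise ValueError("start cells must not hold items")

    # -- geometry -----------------------------------------------------
    def in_bounds(self, cell: Cell) -> bool:
        x, y = cell
        return 0 <= x < self.width and 0 <= y < self.height

    def passable(self, cell: Cell) -> bool:
        return self.in_bounds(cell) and cell not in self.walls

    def step(self, cell: Cell, action: str) -> Cell:
        """Deterministic transition; blocked moves are no-ops."""
        dx, dy = _ACTION_DELTA[action]
        nxt = (cell[0] + dx, cell[1] + dy)
        return nxt if self.passable(nxt) else cell

    # -- state indexing ----------------------------------------------
    @property
    def n_states(self) -> int:
        return self.width * self.height

    def state_index(self, cell: Cell) -> int:
        return cell[1] * self.width + cell[0]

    def cell_of(self, index: int) -> Cell:
        return (index % self.width, index // self.width)

    def transition_table(self) -> np.ndarray:
        """(n_states, n_actions) array of successor state indices."""
        ns = np.empty((self.n_states, len(ACTIONS)), dtype=np.int64)
        for s in range(self.n_states):
            cell = self.cell_of(s)
            for ai, a in enumerate(ACTIONS):
                ns[s, ai] = self.state_index(
                    self.step(cell, a) if cell not in self.walls else cell
                )
        return ns

    def reachable_items_from(self, start: Cell) -> set:
        """Item cells reachable from ``start`` (BFS over passable cells)."""
        seen = {start}
        frontier = [start]
        found = set()
        while frontier:
            cell = frontier.pop()
            for a in ACTIONS[:4]:
                nxt = self.step(cell, a)
                if nxt in seen:
                    continue
                seen.add(nxt)
                if nxt in self.items:
                    found.add(nxt)  # absorbing: do not expand beyond items
                else:
                    frontier.append(nxt)
        return found

    def signature(self) -> tuple:
        """Hashable identity of the layout (for caching Q computations)."""
        return (
            self.width,
            self.height,
            tuple(sorted(self.walls)),
            tuple(sorted((c, it.colour, it.shape) for c, it in self.items.items())),
        )


@dataclass
class QTable:
    """Converged action values for one agent in one gridworld."""

    grid: GridWorld
    values: np.ndarray  # (n_states, n_actions)
    gamma: float
    unreachable_starts: tuple = ()

    def q(self, cell: Cell, action: str) -> float:
        return float(self.values[self.grid.state_index(cell), ACTION_INDEX[action]])


@dataclass
class Trajectory:
    """An ordered (cell, action) sequence for one agent on one level.

    ``end_cell`` is the cell occupied after the last recorded step (moves
    blocked by walls are no-ops, so it cannot always be derived from the
    final action without the grid).
    """

    agent_id: str
    level_id: str
    steps: list  # list[(Cell, str)]
    end_cell: Optional[Cell] = None
    collected_item: Optional[ItemType] = None

    def cells(self) -> list:
        """Visited cells including the final one (used for path similarity)."""
        if not self.steps:
            return [] if self.end_cell is None else [self.end_cell]
        path = [cell for cell, _ in self.steps]
        path.append(self.end_cell)
        return path

    def final_cell(self) -> Optional[Cell]:
        return self.end_cell

    def validate(self, grid: GridWorld) -> None:
        prev_end = None
        for cell, action in self.steps:
            if prev_end is not None and cell != prev_end:
                raise ValueError("trajectory cells inconsistent with transitions")
            prev_end = grid.step(cell, action)
        if self.steps and self.end_cell != prev_end:
            raise ValueError("end cell inconsistent with transitions")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _rewards_and_continuation(
    grid: GridWorld, item_vals: np.ndarray, step_cost: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reward array(s) and continuation mask shared by single/batch VI.

    ``item_vals`` has shape (n_candidates, n_items) aligned with the sorted
    item-cell order; returns (rewards (n_candidates, S, A), continue (S, A)
    boolean where the successor is non-terminal, terminal state mask (S,)).
    """
    ns = grid.transition_table()
    S, A = ns.shape
    item_cells = sorted(grid.items)
    item_state = {grid.state_index(c): k for k, c in enumerate(item_cells)}
    terminal = np.zeros(S, dtype=bool)
    for si in item_state:
        terminal[si] = True

    n_cand = item_vals.shape[0]
    rewards = np.full((n_cand, S, A), -step_cost)
    cont = ~terminal[ns]  # (S, A)
    for s in range(S):
        for a in range(A):
            k = item_state.get(ns[s, a])
            if k is not None:
                rewards[:, s, a] += item_vals[:, k]
    # Q is defined to be zero at terminal (item) states.
    rewards[:, terminal, :] = 0.0
    return rewards, cont, terminal


def compute_q_batch(
    grid: GridWorld,
    weight_matrix: np.ndarray,
    gamma: float = 0.95,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    step_cost: float = 1.0,
    span: float = 10.0,
    base: float = 0.0,
) -> np.ndarray:
    """Value iteration for many candidate utility weight vectors at once.

    Returns a (n_candidates, n_states, n_actions) Q array. Used to make
    lattice posteriors over utility functions affordable: the sweep is
    vectorised across candidates and the result is cached by layout at the
    call sites that need it.
    """
    if not (0 <= gamma < 1):
        raise ValueError("gamma must lie in [0, 1)")
    if tol <= 0:
        raise ValueError("tol must be positive")
    item_cells = sorted(grid.items)
    item_vals = item_values_for_lattice(
        weight_matrix, [grid.items[c] for c in item_cells], grid.features, span, base
    )
    rewards, cont, terminal = _rewards_and_continuation(grid, item_vals, step_cost)
    ns = grid.transition_table()
    n_cand, S, A = rewards.shape
    V = np.zeros((n_cand, S))
    for _ in range(max_sweeps):
        Q = rewards + gamma * (V[:, ns] * cont[None, :, :])
        V_new = Q.max(axis=2)
        V_new[:, terminal] = 0.0
        if np.max(np.abs(V_new - V)) < tol:
            V = V_new
            break
        V = V_new
    Q = rewards + gamma * (V[:, ns] * cont[None, :, :])
    Q[:, terminal, :] = 0.0
    return Q


def compute_q(
    grid: GridWorld,
    utility: UtilityFunction,
    gamma: float = 0.95,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
) -> QTable:
    """Solve the agent-specific MDP by value iteration.

    The reward for entering an item cell is the item's payoff minus the step
    cost; every other move costs one step. Item cells are absorbing with
    zero continuation value. Starts from which no item is reachable leave Q
    well-defined (pure step costs) and are flagged on the returned table.
    """
    W = np.asarray(utility.weights, dtype=float)[None, :]
    Q = compute_q_batch(
        grid,
        W,
        gamma=gamma,
        tol=tol,
        max_sweeps=max_sweeps,
        step_cost=utility.step_cost,
        span=utility.span,
        base=utility.base,
    )[0]
    unreachable = tuple(
        s for s in grid.start_cells if not grid.reachable_items_from(s)
    )
    return QTable(grid=grid, values=Q, gamma=gamma, unreachable_starts=unreachable)


@dataclass
class BoltzmannPolicy:
    """Softmax-in-Q action distribution, one row per state."""

    grid: GridWorld
    probs: np.ndarray  # (n_states, n_actions)

    def action_probs(self, cell: Cell) -> np.ndarray:
        return self.probs[self.grid.state_index(cell)]

    def log_prob(self, cell: Cell, action: str) -> float:
        return float(
            np.log(self.probs[self.grid.state_index(cell), ACTION_INDEX[action]])
        )


def boltzmann_probs(q_values: np.ndarray, beta: float) -> np.ndarray:
    """Row-wise softmax of Q/beta with max-shift for numerical stability."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    z = q_values / beta
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def boltzmann_policy(q: QTable, beta: float) -> BoltzmannPolicy:
    """Noisily reward-maximising policy: pi(s,a) ∝ exp(Q(s,a)/beta).

    ``beta`` is a temperature: larger beta yields a noisier agent, and the
    beta → 0 limit is greedy with ties split uniformly.
    """
    return BoltzmannPolicy(grid=q.grid, probs=boltzmann_probs(q.values, beta))


def greedy_policy(q: QTable) -> BoltzmannPolicy:
    """beta → 0 limit: uniform over the argmax action set per state."""
    v = q.values
    best = np.isclose(v, v.max(axis=1, keepdims=True), rtol=0, atol=1e-12)
    probs = best / best.sum(axis=1, keepdims=True)
    return BoltzmannPolicy(grid=q.grid, probs=probs)


def rollout(
    grid: GridWorld,
    policy: BoltzmannPolicy,
    start: Cell,
    max_steps: int = 50,
    rng: Optional[np.random.Generator] = None,
    agent_id: str = "agent",
) -> Trajectory:
    """Sample a trajectory until an item is collected or the budget runs out."""
    start = tuple(start)
    if not grid.passable(start) or start in grid.items:
        raise ValueError("start must be a legal non-item cell")
    rng = rng if rng is not None else np.random.default_rng()
    cell = start
    steps = []
    collected = None
    for _ in range(max_steps):
        p = policy.action_probs(cell)
        ai = int(rng.choice(len(ACTIONS), p=p))
        action = ACTIONS[ai]
        steps.append((cell, action))
        cell = grid.step(cell, action)
        if cell in grid.items:
            collected = grid.items[cell]
            break
    return Trajectory(
        agent_id=agent_id,
        level_id=grid.level_id,
        steps=steps,
        end_cell=cell,
        collected_item=collected,
    )


def trajectory_return(
    traj: Trajectory, utility: UtilityFunction, gamma: float = 0.95
) -> float:
    """Discounted return of a trajectory under a (possibly different) utility.

    R(tau; U) = sum_t gamma^(t-1) * U(S_t, A_t), where each step contributes
    minus the step cost and the collecting step additionally contributes the
    collected item's payoff under ``utility``.
    """
    total = 0.0
    n = len(traj.steps)
    for t in range(n):
        r = -utility.step_cost
        if t == n - 1 and traj.collected_item is not None:
            r += utility.item_value(traj.collected_item)
        total += (gamma**t) * r
    return total
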