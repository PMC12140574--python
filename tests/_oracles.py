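"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately avoid the implementation paths they check: the Fréchet
oracle enumerates monotone couplings, and the action-value oracle
enumerates raw action sequences in the deterministic MDP.
"""

import math

import numpy as np

from grouplearn.gridworld import ACTIONS


def frechet_oracle(p, q):
    """Minimum over monotone couplings of the maximum pointwise distance."""
    n, m = len(p), len(q)

    def dist(i, j):
        return math.hypot(p[i][0] - q[j][0], p[i][1] - q[j][1])

    best = [math.inf]

    def walk(i, j, cur):
        cur = max(cur, dist(i, j))
        if cur >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cur
            return
        if i + 1 < n:
            walk(i + 1, j, cur)
        if j + 1 < m:
            walk(i, j + 1, cur)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cur)

    walk(0, 0, 0.0)
    return best[0]


def grid_walks(size, max_len):
    """All walks (4-adjacent cell sequences) up to max_len on a size x size grid."""
    cells = [(x, y) for x in range(size) for y in range(size)]
    walks = [[c] for c in cells]
    out = list(walks)
    for _ in range(max_len - 1):
        nxt = []
        for w in walks:
            x, y = w[-1]
            for dx, dy in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                c = (x + dx, y + dy)
                if 0 <= c[0] < size and 0 <= c[1] < size:
                    nxt.append(w + [c])
        out.extend(nxt)
        walks = nxt
    return out


def enumerate_best_returns(grid, utility, gamma, horizon):
    """Max discounted return over every action sequence from the start.

    Pure recursive enumeration; episodes end on item collection. In a
    deterministic MDP the converged Q(s, a) equals this max for sequences
    beginning with ``a`` whenever the optimum is attained within the
    horizon.
    """

    def best_from(cell, depth):
        if depth == horizon:
            return 0.0
        best = -np.inf
        for a in ACTIONS:
            nxt = grid.step(cell, a)
            r = -utility.step_cost
            if nxt in grid.items:
                r += utility.item_value(grid.items[nxt])
                val = r
            else:
                val = r + gamma * best_from(nxt, depth + 1)
            best = max(best, val)
        return best

    out = {}
    start = grid.start_cells[0]
    for a in ACTIONS:
        nxt = grid.step(start, a)
        r = -utility.step_cost
        if nxt in grid.items:
            out[a] = r + utility.item_value(grid.items[nxt])
        else:
            out[a] = r + gamma * best_from(nxt, 1)
    return out
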