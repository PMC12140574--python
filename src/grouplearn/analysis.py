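"""Trajectory scoring and statistics.

Implements the measures used to quantify selective social learning: the
discrete Fréchet distance between paths, the exp(-F) trajectory similarity,
relative selectivity toward each of two demonstrators, exact two-sided
binomial tests against the indiscriminate-learning null, best-fit strategy
counting, the score-vs-fit relation, and the imitation return surface over
(preference similarity x demonstrator decision noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .gridworld import (
    Trajectory,
    UtilityFunction,
    boltzmann_policy,
    compute_q,
    rollout,
    trajectory_return,
)
from .layouts import four_goal_grid


# ---------------------------------------------------------------------------
# trajectory similarity
# ---------------------------------------------------------------------------

def discrete_frechet(p: Sequence, q: Sequence) -> float:
    """Discrete Fréchet distance between two 2D point sequences.

    Dynamic programme of Eiter & Mannila: the minimal over monotone
    couplings of the maximal Euclidean pointwise distance. Symmetric, zero
    iff the sequences are pointwise identical up to repetition structure.
    """
    if len(p) == 0 or len(q) == 0:
        raise ValueError("point sequences must be non-empty")
    P = np.asarray(p, dtype=float)
    Q = np.asarray(q, dtype=float)
    n, m = len(P), len(Q)
    d = np.sqrt(((P[:, None, :] - Q[None, :, :]) ** 2).sum(axis=2))
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]), d[i, j])
    return float(ca[n - 1, m - 1])


def trajectory_similarity(t1: Trajectory, t2: Trajectory) -> float:
    """s(tau_i, tau_j) = exp(-F) on the cell-coordinate sequences; in (0, 1]."""
    return math.exp(-discrete_frechet(t1.cells(), t2.cells()))


# ---------------------------------------------------------------------------
# selectivity
# ---------------------------------------------------------------------------

@dataclass
class SelectivityResult:
    """Mean similarity to each of two demonstrators plus copy counts.

    ``relative[m]`` is s̄_m / (s̄_1 + s̄_2); 0.5 means indiscriminate.
    ``copy_counts`` is (k, n): trajectories strictly more similar to the
    first demonstrator, out of all non-tied trajectories.
    """

    demonstrators: tuple
    mean_sim: dict
    relative: dict
    copy_counts: tuple  # (k, n)

    @property
    def k(self) -> int:
        return self.copy_counts[0]

    @property
    def n(self) -> int:
        return self.copy_counts[1]


def relative_selectivity(
    pairs: Sequence[tuple],
    demonstrators: tuple,
) -> SelectivityResult:
    """Relative selectivity of a participant (or cohort) toward two demonstrators.

    Parameters
    ----------
    pairs : sequence of (participant_traj, {demo_id: demo_traj}) per trial;
        each trial must supply both demonstrators' trajectories.
    demonstrators : (id_1, id_2); relative selectivity and copy counts are
        reported in favour of ``id_1``.

    Exact similarity ties are excluded from the copy count denominator.
    """
    d1, d2 = demonstrators
    sims = {d1: [], d2: []}
    k = 0
    n = 0
    for part_traj, demos in pairs:
        s1 = trajectory_similarity(part_traj, demos[d1])
        s2 = trajectory_similarity(part_traj, demos[d2])
        sims[d1].append(s1)
        sims[d2].append(s2)
        if s1 != s2:
            n += 1
            if s1 > s2:
                k += 1
    mean_sim = {m: float(np.mean(v)) if v else float("nan") for m, v in sims.items()}
    tot = mean_sim[d1] + mean_sim[d2]
    relative = {m: mean_sim[m] / tot for m in (d1, d2)}
    return SelectivityResult(
        demonstrators=(d1, d2),
        mean_sim=mean_sim,
        relative=relative,
        copy_counts=(k, n),
    )


def selectivity_from_records(
    records: Sequence,
    target: Optional[str] = None,
    phase: Optional[int] = None,
    context=None,
) -> SelectivityResult:
    """Pooled relative selectivity over simulated trial records.

    Each record is oriented toward its own aligned demonstrator (records
    carry per-participant counterbalancing); when no aligned demonstrator
    is defined — the groups-irrelevant conditions — ``target`` names the
    demonstrator to report selectivity toward. Filters by phase/context
    when given.
    """
    pairs = []
    for rec in records:
        if phase is not None and rec.phase != phase:
            continue
        if context is not None and rec.context != tuple(context):
            continue
        ref = rec.aligned_demonstrator or target
        if ref is None:
            raise ValueError("record has no aligned demonstrator; pass target=")
        other = [m for m in rec.demonstrators if m != ref]
        if len(other) != 1:
            raise ValueError("expected exactly two demonstrators per trial")
        pairs.append((
            rec.participant_trajectory,
            {
                "target": rec.demo_trajectories[ref],
                "other": rec.demo_trajectories[other[0]],
            },
        ))
    if not pairs:
        raise ValueError("no records matched the filter")
    return relative_selectivity(pairs, ("target", "other"))


@dataclass
class BinomialTestResult:
    k: int
    n: int
    p0: float
    p_value: float
    sidedness: str = "two-sided"

    @property
    def proportion(self) -> float:
        return self.k / self.n


def binomial_test(k: int, n: int, p0: float = 0.5) -> BinomialTestResult:
    """Exact two-sided binomial test (minimum-likelihood method).

    The p-value sums Pr(X = x) over all outcomes with probability no larger
    than that of the observed count — the null of indiscriminate social
    learning is p0 = 0.5.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    res = stats.binomtest(k, n, p0, alternative="two-sided")
    return BinomialTestResult(k=k, n=n, p0=p0, p_value=float(res.pvalue))


def proportion_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation confidence interval on a proportion."""
    p = k / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


# ---------------------------------------------------------------------------
# best-fit strategy counting
# ---------------------------------------------------------------------------

@dataclass
class StrategyFitResult:
    """Per-participant prediction accuracy of each candidate strategy.

    ``fractions[pid][strategy]`` is the fraction of that participant's test
    choices the strategy predicted (a strategy with no preference on a trial
    earns 0.5 credit, its expected hits). ``best_fit[pid]`` is the argmax
    set — a participant may be best captured by more than one strategy.
    """

    fractions: dict
    best_fit: dict

    def counts(self) -> dict:
        """Number of participants whose best-fit set contains each strategy."""
        out: dict = {}
        for pid, best in self.best_fit.items():
            for s in best:
                out[s] = out.get(s, 0) + 1
        return out

    def modal_strategies(self) -> set:
        counts = self.counts()
        top = max(counts.values())
        return {s for s, c in counts.items() if c == top}


def strategy_fit(records: Sequence, strategies: Sequence) -> StrategyFitResult:
    """Count, per participant, how well each strategy predicts their choices.

    ``records`` are TrialRecords from the population module: each carries
    the participant's realised choice (demonstrator id) and a prediction per
    candidate strategy (demonstrator id, or None when the strategy has no
    preference on that trial).
    """
    per_pid: dict = {}
    for rec in records:
        per_pid.setdefault(rec.participant_id, []).append(rec)
    fractions = {}
    best_fit = {}
    for pid, recs in per_pid.items():
        fr = {}
        for s in strategies:
            credit = 0.0
            for rec in recs:
                pred = rec.predictions.get(s)
                if pred is None:
                    credit += 0.5
                elif pred == rec.chosen_demonstrator:
                    credit += 1.0
            fr[s] = credit / len(recs)
        fractions[pid] = fr
        top = max(fr.values())
        best_fit[pid] = {s for s, v in fr.items() if v == top}
    return StrategyFitResult(fractions=fractions, best_fit=best_fit)


def score_fit_relation(
    records: Sequence, model, gamma: float = 1.0
) -> tuple[list, Optional[float]]:
    """Pair each participant's model-fit fraction with their test-level score.

    The score is the summed points the participant actually earned on the
    test levels (undiscounted by default), computed under their own utility.
    Returns (pairs, Spearman rho); rho is None when either variable is
    constant (degenerate, e.g. all participants perfectly fit).
    """
    if not records:
        raise ValueError("no trial records supplied")
    fit = strategy_fit(records, [model])
    scores: dict = {}
    for rec in records:
        pts = trajectory_return(rec.participant_trajectory, rec.ego_utility, gamma)
        scores[rec.participant_id] = scores.get(rec.participant_id, 0.0) + pts
    pids = sorted(scores)
    xs = [fit.fractions[pid][model] for pid in pids]
    ys = [scores[pid] for pid in pids]
    if len(set(xs)) < 2 or len(set(ys)) < 2:
        return list(zip(xs, ys)), None
    rho = stats.spearmanr(xs, ys).statistic
    return list(zip(xs, ys)), float(rho)


# ---------------------------------------------------------------------------
# imitation return surface
# ---------------------------------------------------------------------------

@dataclass
class ReturnSurface:
    """Mean imitator return over a (similarity x decision noise) grid."""

    sim_grid: np.ndarray
    beta_grid: np.ndarray
    mean_return: np.ndarray  # (len(sim_grid), len(beta_grid))
    mc_se: np.ndarray
    attained_sim: np.ndarray  # nearest attainable similarity actually used


def _demonstrator_weights_for_sim(sim: float) -> tuple[float, float]:
    """Demonstrator weights at a requested similarity to the fixed imitator.

    The imitator's utility is (1, 0): it values one feature level of each
    dimension maximally. Demonstrators on the segment (1-t, t) have
    similarity exactly 1 - t, so every sim in [0, 1] is attainable.
    """
    t = 1.0 - min(1.0, max(0.0, sim))
    return (1.0 - t, t)


def return_surface(
    sim_grid: Sequence[float],
    beta_grid: Sequence[float],
    n_trials: int = 200,
    rng: Optional[np.random.Generator] = None,
    gamma: float = 0.95,
    max_steps: int = 30,
    grid_size: int = 7,
) -> ReturnSurface:
    """Average return from imitating, as a function of preference similarity
    and demonstrator decision noise, in the four-goal arena.

    For each cell, demonstrators with the required similarity to the fixed
    imitator utility execute Boltzmann trajectories from randomised starts
    (with a fixed cost per step); the imitator's average return over those
    trajectories is reported with its Monte-Carlo standard error.

    ``gamma`` is used both for the demonstrators' planning and for scoring
    the imitator's returns — with mismatched objectives a noisy aligned
    demonstrator can systematically outscore a greedy one, which would
    break the surface's interpretation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    rng = rng if rng is not None else np.random.default_rng()
    grid = four_goal_grid(grid_size)
    ego = UtilityFunction(weights=(1.0, 0.0))
    sim_grid = np.asarray(sim_grid, dtype=float)
    beta_grid = np.asarray(beta_grid, dtype=float)
    mean = np.empty((len(sim_grid), len(beta_grid)))
    se = np.empty_like(mean)
    attained = np.empty_like(sim_grid)
    for i, sim in enumerate(sim_grid):
        w = _demonstrator_weights_for_sim(float(sim))
        attained[i] = 1.0 - w[1]
        demo_u = UtilityFunction(weights=w)
        q = compute_q(grid, demo_u, gamma=gamma)
        for j, beta in enumerate(beta_grid):
            pol = boltzmann_policy(q, float(beta))
            returns = np.empty(n_trials)
            for t in range(n_trials):
                start = grid.start_cells[rng.integers(len(grid.start_cells))]
                traj = rollout(grid, pol, start, max_steps=max_steps, rng=rng)
                returns[t] = trajectory_return(traj, ego, gamma)
            mean[i, j] = returns.mean()
            se[i, j] = returns.std(ddof=1) / math.sqrt(n_trials)
    return ReturnSurface(
        sim_grid=sim_grid,
        beta_grid=beta_grid,
        mean_return=mean,
        mc_se=se,
        attained_sim=attained,
    )
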