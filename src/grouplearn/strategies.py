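"""Demonstrator-selection strategies and path-choice heuristics.

Five hypothesised strategies for choosing whom to learn from:

* S1 indiscriminate — no systematic favouring of any demonstrator.
* S2 rational dyadic — expected preference similarity under utility
  posteriors inferred from each demonstrator's own observed behaviour;
  indiscriminate when that evidence is unavailable.
* S3 naive cue-based — ingroup bias on the explicit cue axis (label match,
  or negative cue distance), with no regard for what the cues predict.
* S4 rational cue-based — expected similarity under cue-conditional utility
  posteriors from the latent-group model (falling back to behavioural
  evidence when available).
* S5 agreement frequency — weight each cue group by how often its members'
  observed choices matched the ego's own preference, applied regardless of
  choice context.

Plus four non-social path heuristics (alternate sides, nearest item, copy
the first / the most recent demonstrator observed), and the shared
stochastic selection rule Pr(m) ∝ exp(w_m / beta_ego).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .gridworld import UtilityFunction
from .inference import UtilityPosterior


class StrategyId(str, Enum):
    S1_indiscriminate = "S1_indiscriminate"
    S2_rational_dyadic = "S2_rational_dyadic"
    S3_naive_cue = "S3_naive_cue"
    S4_rational_cue = "S4_rational_cue"
    S5_agreement_frequency = "S5_agreement_frequency"
    H_alternating = "H_alternating"
    H_closest = "H_closest"
    H_copy_first = "H_copy_first"
    H_copy_last = "H_copy_last"


SOCIAL_STRATEGIES = (
    StrategyId.S1_indiscriminate,
    StrategyId.S2_rational_dyadic,
    StrategyId.S3_naive_cue,
    StrategyId.S4_rational_cue,
    StrategyId.S5_agreement_frequency,
)
HEURISTICS = (
    StrategyId.H_alternating,
    StrategyId.H_closest,
    StrategyId.H_copy_first,
    StrategyId.H_copy_last,
)


class StrategyInapplicable(Exception):
    """The strategy cannot produce weights from the available evidence."""


@dataclass
class DemonstratorWeights:
    """Real-valued selection weights w_m over demonstrators."""

    weights: dict
    evidence_used: str = "none"  # none | behaviour | cues | both

    def __post_init__(self):
        if not self.weights:
            raise ValueError("at least one demonstrator required")
        for v in self.weights.values():
            if not math.isfinite(v):
                raise ValueError("weights must be finite")


ContextVector = tuple  # binary per feature dimension


def _weights_of(u) -> np.ndarray:
    if isinstance(u, UtilityFunction):
        return np.asarray(u.weights, dtype=float)
    return np.asarray(u, dtype=float)


def similarity(u_ego, u_m) -> float:
    """sim(U_ego, U_m) = sum_i |U_i^ego - 0.5| (1 - |U_i^ego - U_i^m|).

    Zero for an indifferent ego; maximal (sum_i |U_i^ego - 0.5|) when the
    demonstrator's weights coincide with the ego's.
    """
    e = _weights_of(u_ego)
    m = _weights_of(u_m)
    return float(np.sum(np.abs(e - 0.5) * (1.0 - np.abs(e - m))))


def contextual_similarity(u_ego, u_m, c: ContextVector) -> float:
    """Similarity restricted to the feature dimensions present in context c."""
    e = _weights_of(u_ego)
    m = _weights_of(u_m)
    cv = np.asarray(c, dtype=float)
    return float(np.sum(cv * np.abs(e - 0.5) * (1.0 - np.abs(e - m))))


def similarity_lattice(
    u_ego, candidates: np.ndarray, c: Optional[ContextVector] = None
) -> np.ndarray:
    """Per-candidate similarity values over a utility lattice (vectorised)."""
    e = _weights_of(u_ego)
    cv = np.ones(len(e)) if c is None else np.asarray(c, dtype=float)
    per_dim = np.abs(e - 0.5)[None, :] * (1.0 - np.abs(e[None, :] - candidates))
    return (cv[None, :] * per_dim).sum(axis=1)


def ingroup_weights(
    cues: Mapping, phi_ego, mode: str = "distance"
) -> DemonstratorWeights:
    """Naive ingroup bias weights on the explicit cue axis.

    ``label`` mode: +1 for demonstrators sharing the ego's group label, -1
    otherwise. ``distance`` mode: w_m = -|phi_m - phi_ego| on the scalar cue
    axis. An invisible ego cue makes the strategy inapplicable (the caller
    falls back to indiscriminate selection).
    """
    if mode == "label":
        w = {m: (1.0 if z == phi_ego else -1.0) for m, z in cues.items()}
    elif mode == "distance":
        if phi_ego is None:
            raise StrategyInapplicable("ego cue invisible in distance mode")
        w = {m: -abs(float(phi) - float(phi_ego)) for m, phi in cues.items()}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DemonstratorWeights(weights=w, evidence_used="cues")


def rational_weights(
    u_ego,
    posteriors: Mapping[str, UtilityPosterior],
    c: Optional[ContextVector] = None,
) -> DemonstratorWeights:
    """Posterior-expected (contextual) similarity per demonstrator.

    Covers both the dyadic strategy (posteriors inferred from each
    demonstrator's own behaviour) and the cue-based rational strategy
    (cue-conditional posteriors from the latent-group model).
    """
    w = {}
    for m, post in posteriors.items():
        sims = similarity_lattice(u_ego, post.grid.candidates, c)
        w[m] = post.expectation(sims)
    return DemonstratorWeights(weights=w, evidence_used="behaviour")


@dataclass(frozen=True)
class AgreementTrial:
    """One observed evidence choice: acting agent's cue group and whether its
    chosen item matched the ego's preference between the offered items."""

    group: str
    agrees: bool


def agreement_frequency_weights(
    history: Sequence[AgreementTrial], groups: Sequence[str]
) -> DemonstratorWeights:
    """Per-group agreement proportions over the observed evidence trials.

    w(group) = agreements / trials observed for that group; a group with no
    observed trials gets the uninformed weight 0.5. Deliberately ignores the
    current choice context.
    """
    w = {}
    for g in groups:
        trials = [t for t in history if t.group == g]
        w[g] = (sum(t.agrees for t in trials) / len(trials)) if trials else 0.5
    return DemonstratorWeights(weights=w, evidence_used="both")


def selection_probs(w: DemonstratorWeights, beta_ego: float) -> dict:
    """Pr(select m) ∝ exp(w_m / beta_ego); invariant to shifting all weights."""
    if beta_ego <= 0:
        raise ValueError("beta_ego must be positive")
    ids = list(w.weights)
    z = np.array([w.weights[m] for m in ids]) / beta_ego
    z -= z.max()
    e = np.exp(z)
    p = e / e.sum()
    return dict(zip(ids, p))


def select_demonstrator(
    w: DemonstratorWeights, beta_ego: float, rng: np.random.Generator
) -> str:
    """Sample a social learning target from the softmax selection rule."""
    probs = selection_probs(w, beta_ego)
    ids = list(probs)
    return ids[int(rng.choice(len(ids), p=[probs[m] for m in ids]))]


# ---------------------------------------------------------------------------
# path-choice heuristics
# ---------------------------------------------------------------------------

@dataclass
class TestLevelView:
    """What a non-social heuristic can see on one hidden-item test trial.

    ``demo_order`` lists demonstrators in the order their paths were shown;
    ``side_of`` maps each demonstrator to the arm (left/right) of the box
    they walked to; ``distance_of`` gives the ego's path distance to each
    demonstrator's box; ``last_side`` is the arm the ego chose on the
    previous trial (None on the first).
    """

    demo_order: tuple
    side_of: dict
    distance_of: dict
    last_side: Optional[str] = None


def heuristic_choice(
    strategy: StrategyId, view: TestLevelView
) -> Optional[str]:
    """Deterministic demonstrator prediction of a path heuristic.

    Returns the id of the demonstrator whose box the heuristic picks, or
    None when the rule has no preference (first trial for the alternating
    rule; exactly tied distances for the nearest-item rule) — callers
    resolve None uniformly at random.
    """
    if strategy == StrategyId.H_copy_first:
        return view.demo_order[0]
    if strategy == StrategyId.H_copy_last:
        return view.demo_order[-1]
    if strategy == StrategyId.H_alternating:
        if view.last_side is None:
            return None
        target = "right" if view.last_side == "left" else "left"
        for m, side in view.side_of.items():
            if side == target:
                return m
        return None
    if strategy == StrategyId.H_closest:
        ids = list(view.distance_of)
        dists = [view.distance_of[m] for m in ids]
        best = min(dists)
        tied = [m for m, d in zip(ids, dists) if d == best]
        return tied[0] if len(tied) == 1 else None
    raise ValueError(f"{strategy} is not a path heuristic")
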