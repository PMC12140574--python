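"""Synthetic agent populations and the three experiment designs.

Generates everything the behavioural experiments supplied to a participant:
latent-group populations (a Dirichlet-process mixture with Gaussian cue
distributions and group-conditioned utility distributions), the evidence and
test levels of each experiment, demonstrator behaviour, and simulated
participants following any of the selection strategies.

Experiment summaries (what the generator reproduces):

* **Experiment 1** — two known demonstrators, one sharing the participant's
  colour preference; 8 observed evidence trajectories (4 per agent) with
  visible items, then hidden-item test choices.
* **Experiment 2** — two latent groups whose cue (a scalar on a red-blue
  axis) correlates with a preference on one feature dimension. Five
  conditions cross group relevance with the participant's own cue
  (invisible / arbitrary / matched / mismatched). Phase 2 replicates
  Experiment 1 with grey known agents; phase 3 presents four cue-bearing
  evidence agents (two per group) and tests with two novel cue-bearing
  demonstrators.
* **Experiment 3** — groups align with the participant on different
  dimensions (colour vs shape); evidence contains 3 colour-contrast and 2
  shape-contrast choices per group, and tests alternate colour-only and
  shape-only hidden choices with the relevant dimension announced.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .gridworld import (
    GridWorld,
    ItemType,
    Trajectory,
    UtilityFunction,
    boltzmann_policy,
    compute_q,
    rollout,
)
from .inference import (
    G0Params,
    ObservedAgent,
    UtilityGrid,
    exact_partition_posterior,
    posterior_over_utility,
    utility_given_cue,
)
from .layouts import START, two_item_level
from .strategies import (
    AgreementTrial,
    ContextVector,
    DemonstratorWeights,
    StrategyId,
    StrategyInapplicable,
    agreement_frequency_weights,
    heuristic_choice,
    ingroup_weights,
    rational_weights,
    select_demonstrator,
    selection_probs,
    TestLevelView,
)

#: demonstrator decision noise (visibly goal-directed evidence paths)
DEMO_BETA = 0.2
#: selection noise used for all simulated strategy models
DEFAULT_BETA_EGO = 0.5

COLOURS = ("green", "yellow")
SHAPES = ("triangle", "circle")


# ---------------------------------------------------------------------------
# generative population model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Parameters of one latent group's cue and utility distributions."""

    utility_mean: tuple
    utility_sd: tuple
    cue_mean: float
    cue_sd: float

    def __post_init__(self):
        if self.cue_sd <= 0 or any(s <= 0 for s in self.utility_sd):
            raise ValueError("spread parameters must be positive")
        if not all(0.0 <= m <= 1.0 for m in self.utility_mean):
            raise ValueError("utility means must lie in [0, 1]")


@dataclass
class Agent:
    """A simulated agent: latent group, utility, explicit cue, noise level."""

    id: str
    z: Optional[str]
    utility: UtilityFunction
    phi: Optional[float]
    beta: float = DEMO_BETA


@dataclass
class StickWeights:
    """Truncated stick-breaking mixture weights."""

    rho: np.ndarray
    alpha: float

    def __post_init__(self):
        if np.any(self.rho < 0):
            raise ValueError("stick weights must be non-negative")


def sample_stick_weights(
    alpha: float, truncation: int, rng: np.random.Generator
) -> StickWeights:
    """rho_c = beta_c * prod_{j<c} (1 - beta_j) with beta_c ~ Beta(1, alpha)."""
    if alpha <= 0 or truncation < 1:
        raise ValueError("alpha must be positive and truncation >= 1")
    betas = rng.beta(1.0, alpha, size=truncation)
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - betas)[:-1]])
    return StickWeights(rho=betas * remaining, alpha=alpha)


def _trunc_normal(mean, sd, rng, size=None):
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_agent(
    group_label: str, params: GroupParams, rng: np.random.Generator, agent_id: str,
    beta: float = DEMO_BETA,
) -> Agent:
    w = tuple(
        float(_trunc_normal(m, s, rng))
        for m, s in zip(params.utility_mean, params.utility_sd)
    )
    phi = float(_trunc_normal(params.cue_mean, params.cue_sd, rng))
    return Agent(id=agent_id, z=group_label, utility=UtilityFunction(weights=w),
                 phi=phi, beta=beta)


def sample_population(
    groups: dict,
    M: int,
    rng: np.random.Generator,
    mixture_weights: Optional[Sequence[float]] = None,
    balanced: bool = False,
) -> list:
    """Sample M agents from fixed groups (optionally balanced across them).

    ``groups`` maps label -> GroupParams. Group assignments come from the
    mixture weights (uniform by default); ``balanced`` cycles labels
    deterministically, as the experiment rosters do.
    """
    if M < 1:
        raise ValueError("M must be at least 1")
    labels = list(groups)
    if balanced:
        zs = [labels[i % len(labels)] for i in range(M)]
    else:
        p = (
            np.asarray(mixture_weights, dtype=float)
            if mixture_weights is not None
            else np.full(len(labels), 1.0 / len(labels))
        )
        zs = [labels[int(i)] for i in rng.choice(len(labels), size=M, p=p / p.sum())]
    return [
        sample_agent(z, groups[z], rng, agent_id=f"agent{i}") for i, z in enumerate(zs)
    ]


def sample_dp_population(
    alpha: float,
    M: int,
    rng: np.random.Generator,
    truncation: int = 20,
    n_dims: int = 2,
) -> tuple:
    """Open-ended population: groups drawn from a simple base measure.

    Group utility means are uniform on [0, 1]^D (sd 0.1), cue means uniform
    on [0, 1] (sd 0.06); group frequencies follow the stick-breaking prior.
    Returns (agents, groups, stick_weights).
    """
    sticks = sample_stick_weights(alpha, truncation, rng)
    groups = [
        GroupParams(
            utility_mean=tuple(rng.uniform(0, 1, n_dims)),
            utility_sd=(0.1,) * n_dims,
            cue_mean=float(rng.uniform()),
            cue_sd=0.06,
        )
        for _ in range(truncation)
    ]
    p = sticks.rho / sticks.rho.sum()
    agents = []
    for i in range(M):
        k = int(rng.choice(truncation, p=p))
        agents.append(sample_agent(f"g{k}", groups[k], rng, f"agent{i}"))
    return agents, groups, sticks


# -- presets (group parameters of the two-group experiments) ----------------

RED_CUE_MEAN, BLUE_CUE_MEAN, CUE_SD = 0.2, 0.8, 0.06
DOM_MEAN, DOM_SD = 0.85, 0.08
NEUTRAL_MEAN, NEUTRAL_SD = 0.5, 0.15


def exp2_groups(relevant_dim: int = 0) -> dict:
    """Two groups separated on one utility dimension (colour by default).

    The red group prefers the positive level of the dominant dimension
    (mean 0.85), the blue group the other (0.15); both vary on the other
    dimension around indifference.
    """
    def mean_sd(dominant_high: bool):
        mean = [NEUTRAL_MEAN, NEUTRAL_MEAN]
        sd = [NEUTRAL_SD, NEUTRAL_SD]
        mean[relevant_dim] = DOM_MEAN if dominant_high else 1.0 - DOM_MEAN
        sd[relevant_dim] = DOM_SD
        return tuple(mean), tuple(sd)

    m_red, s_red = mean_sd(True)
    m_blue, s_blue = mean_sd(False)
    return {
        "red": GroupParams(m_red, s_red, RED_CUE_MEAN, CUE_SD),
        "blue": GroupParams(m_blue, s_blue, BLUE_CUE_MEAN, CUE_SD),
    }


def exp3_groups() -> dict:
    """Groups in opposite preference quadrants: red likes yellow circles,
    blue likes green triangles."""
    return {
        "red": GroupParams((DOM_MEAN, DOM_MEAN), (DOM_SD, DOM_SD),
                           RED_CUE_MEAN, CUE_SD),
        "blue": GroupParams((1 - DOM_MEAN, 1 - DOM_MEAN), (DOM_SD, DOM_SD),
                            BLUE_CUE_MEAN, CUE_SD),
    }


# ---------------------------------------------------------------------------
# experiment designs
# ---------------------------------------------------------------------------

EXP2_CONDITIONS = {
    1: ("irrelevant", "invisible"),
    2: ("irrelevant", "arbitrary"),
    3: ("relevant", "invisible"),
    4: ("relevant", "matched"),
    5: ("relevant", "mismatched"),
}
EXP3_CONDITIONS = ("invisible", "arbitrary")


def _contrast_items(dim: str, swap: bool) -> tuple:
    """An item pair differing only on ``dim``; ``swap`` flips the sides."""
    if dim == "colour":
        a = ItemType(colour="yellow", shape="triangle")
        b = ItemType(colour="green", shape="triangle")
    else:
        a = ItemType(colour="yellow", shape="circle")
        b = ItemType(colour="yellow", shape="triangle")
    return (b, a) if swap else (a, b)


@dataclass
class EvidenceLevel:
    grid: GridWorld
    actors: tuple  # agent ids acting on this level
    phase: int
    context: Optional[ContextVector] = None


@dataclass
class TestTrial:
    trial_id: str
    grid: GridWorld
    demonstrators: tuple  # (id, id)
    phase: int
    context: Optional[ContextVector] = None
    aligned: Optional[str] = None  # ground-truth suitable demonstrator
    uneven: bool = False


@dataclass
class ExperimentDesign:
    """A fully instantiated experiment for one cohort.

    Counterbalancing (which colour/shape the participant prefers, agent
    observation order, item sides) is resolved by the seed at build time.
    """

    experiment: int
    condition: object
    seed: int
    ego_utility: UtilityFunction
    ego_cue: Optional[float]
    agents: dict  # id -> Agent (all demonstrators, known and novel)
    evidence_levels: list
    test_trials: list
    groups: Optional[dict] = None
    counterbalanced: bool = False

    def group_of(self, agent_id: str) -> Optional[str]:
        return self.agents[agent_id].z


def _ego_for(pref_dim: int, high: bool) -> UtilityFunction:
    w = [0.5, 0.5]
    w[pref_dim] = DOM_MEAN if high else 1.0 - DOM_MEAN
    return UtilityFunction(weights=tuple(w))


def build_experiment(
    experiment: int,
    condition=None,
    seed: int = 0,
    uneven_tests: bool = False,
) -> ExperimentDesign:
    """Instantiate one of the three experiment designs.

    ``condition`` is the numbered Experiment-2 cell (1-5), an Experiment-3
    cue condition ("invisible" | "arbitrary"), or None for Experiment 1.
    ``uneven_tests`` builds test levels with unequal arm lengths (used when
    the nearest-item heuristic must be distinguishable).
    """
    rng = np.random.default_rng(seed)
    if experiment == 1:
        return _build_exp1(rng, seed, uneven_tests)
    if experiment == 2:
        if condition not in EXP2_CONDITIONS:
            raise ValueError(f"illegal Experiment 2 condition {condition!r}")
        return _build_exp2(condition, rng, seed, uneven_tests)
    if experiment == 3:
        if condition not in EXP3_CONDITIONS:
            raise ValueError(f"illegal Experiment 3 condition {condition!r}")
        return _build_exp3(condition, rng, seed, uneven_tests)
    raise ValueError(f"unknown experiment {experiment!r}")


def _build_exp1(rng, seed, uneven_tests) -> ExperimentDesign:
    cb = bool(rng.integers(2))  # counterbalance the preferred colour
    ego = _ego_for(0, high=not cb)
    aligned_u = _ego_for(0, high=not cb)
    misaligned_u = _ego_for(0, high=cb)
    # push demonstrator preferences to be unambiguous
    aligned_u = replace(aligned_u, weights=tuple(
        0.9 if w > 0.5 else (0.1 if w < 0.5 else 0.5) for w in aligned_u.weights))
    misaligned_u = replace(misaligned_u, weights=tuple(
        0.9 if w > 0.5 else (0.1 if w < 0.5 else 0.5) for w in misaligned_u.weights))
    agents = {
        "aligned": Agent("aligned", None, aligned_u, phi=None),
        "misaligned": Agent("misaligned", None, misaligned_u, phi=None),
    }
    evidence = []
    for i in range(4):  # 4 levels x 2 agents = 8 evidence trajectories
        grid = two_item_level(
            f"e1-ev{i}", *_contrast_items("colour", swap=bool(rng.integers(2)))
        )
        evidence.append(EvidenceLevel(grid=grid, actors=("aligned", "misaligned"),
                                      phase=1))
    tests = []
    for i in range(2):  # the two analysed hidden-item choices
        grid = two_item_level(
            f"e1-test{i}", *_contrast_items("colour", swap=bool(rng.integers(2))),
            hidden=True, uneven=uneven_tests,
        )
        tests.append(TestTrial(
            trial_id=f"e1-test{i}", grid=grid,
            demonstrators=("aligned", "misaligned"), phase=1,
            aligned="aligned", uneven=uneven_tests,
        ))
    return ExperimentDesign(
        experiment=1, condition="default", seed=seed, ego_utility=ego,
        ego_cue=None, agents=agents, evidence_levels=evidence,
        test_trials=tests, counterbalanced=cb,
    )


def _build_exp2(condition, rng, seed, uneven_tests) -> ExperimentDesign:
    relevance, cue_mode = EXP2_CONDITIONS[condition]
    cb = bool(rng.integers(2))
    groups = exp2_groups(relevant_dim=0)  # groups always separate on colour
    ego_dim = 0 if relevance == "relevant" else 1
    ego = _ego_for(ego_dim, high=not cb)
    # the group whose dominant colour preference matches the ego (only
    # meaningful when groups are relevant); 'red' prefers yellow
    aligned_group = ("red" if not cb else "blue") if relevance == "relevant" else None

    if cue_mode == "invisible":
        ego_cue = None
    elif cue_mode == "arbitrary":
        ego_cue = [RED_CUE_MEAN, BLUE_CUE_MEAN][int(rng.integers(2))]
    elif cue_mode == "matched":
        ego_cue = groups[aligned_group].cue_mean
    else:  # mismatched
        other = "blue" if aligned_group == "red" else "red"
        ego_cue = groups[other].cue_mean

    agents = {}
    # phase 2: grey known agents aligned/misaligned on the ego's dimension
    known_u = {
        "known_aligned": _ego_for(ego_dim, high=not cb),
        "known_misaligned": _ego_for(ego_dim, high=cb),
    }
    for aid, u in known_u.items():
        u = replace(u, weights=tuple(
            0.9 if w > 0.5 else (0.1 if w < 0.5 else 0.5) for w in u.weights))
        agents[aid] = Agent(aid, None, u, phi=None)
    # phase 3: two evidence agents per group plus one novel test agent each
    for g in ("red", "blue"):
        for j in range(2):
            aid = f"{g}_ev{j}"
            agents[aid] = sample_agent(g, groups[g], rng, aid)
        aid = f"{g}_test"
        agents[aid] = sample_agent(g, groups[g], rng, aid)

    ev_dim = "colour" if ego_dim == 0 else "shape"
    evidence = []
    for i in range(2):  # phase-2 evidence: both known agents on each level
        grid = two_item_level(
            f"e2-p2ev{i}", *_contrast_items(ev_dim, swap=bool(rng.integers(2))))
        evidence.append(EvidenceLevel(
            grid=grid, actors=("known_aligned", "known_misaligned"), phase=2))
    for i in range(2):  # phase-3 evidence: all four cue-bearing agents
        grid = two_item_level(
            f"e2-p3ev{i}", *_contrast_items("colour", swap=bool(rng.integers(2))))
        evidence.append(EvidenceLevel(
            grid=grid,
            actors=("red_ev0", "red_ev1", "blue_ev0", "blue_ev1"),
            phase=3))

    tests = []
    for i in range(4):  # phase-2 tests with the known agents
        grid = two_item_level(
            f"e2-p2test{i}", *_contrast_items(ev_dim, swap=bool(rng.integers(2))),
            hidden=True, uneven=uneven_tests)
        tests.append(TestTrial(
            trial_id=f"e2-p2test{i}", grid=grid,
            demonstrators=("known_aligned", "known_misaligned"), phase=2,
            aligned="known_aligned", uneven=uneven_tests))
    for i in range(4):  # phase-3 tests with the novel cue-bearing agents
        uneven = uneven_tests
        grid = two_item_level(
            f"e2-p3test{i}", *_contrast_items("colour", swap=bool(rng.integers(2))),
            hidden=True, uneven=uneven)
        tests.append(TestTrial(
            trial_id=f"e2-p3test{i}", grid=grid,
            demonstrators=("red_test", "blue_test"), phase=3,
            aligned=(f"{aligned_group}_test" if aligned_group else None),
            uneven=uneven))
    return ExperimentDesign(
        experiment=2, condition=condition, seed=seed, ego_utility=ego,
        ego_cue=ego_cue, agents=agents, evidence_levels=evidence,
        test_trials=tests, groups=groups, counterbalanced=cb,
    )


def _build_exp3(condition, rng, seed, uneven_tests) -> ExperimentDesign:
    cb = bool(rng.integers(2))
    groups = exp3_groups()
    # ego sits in one of the two mixed quadrants: shares colour preference
    # with one group and shape preference with the other
    ego = UtilityFunction(weights=(DOM_MEAN, 1 - DOM_MEAN) if not cb
                          else (1 - DOM_MEAN, DOM_MEAN))
    colour_aligned = "red" if ego.weights[0] > 0.5 else "blue"
    shape_aligned = "blue" if colour_aligned == "red" else "red"
    if condition == "invisible":
        ego_cue = None
    else:  # arbitrary: mean cue of the group sharing the ego's shape preference
        ego_cue = groups[shape_aligned].cue_mean

    agents = {}
    for g in ("red", "blue"):
        for j in range(2):
            aid = f"{g}_ev{j}"
            agents[aid] = sample_agent(g, groups[g], rng, aid)
        aid = f"{g}_test"
        agents[aid] = sample_agent(g, groups[g], rng, aid)

    evidence = []
    contrasts = ["colour"] * 3 + ["shape"] * 2  # footnote design: 3 vs 2
    for i, dim in enumerate(contrasts):
        grid = two_item_level(
            f"e3-ev{i}", *_contrast_items(dim, swap=bool(rng.integers(2))))
        actors = (f"red_ev{i % 2}", f"blue_ev{i % 2}")
        ctx = (1, 0) if dim == "colour" else (0, 1)
        evidence.append(EvidenceLevel(grid=grid, actors=actors, phase=3,
                                      context=ctx))
    tests = []
    order = ["colour", "shape"] * 4  # 4 repeats of each context
    for i, dim in enumerate(order):
        uneven = uneven_tests
        grid = two_item_level(
            f"e3-test{i}", *_contrast_items(dim, swap=bool(rng.integers(2))),
            hidden=True, uneven=uneven)
        ctx = (1, 0) if dim == "colour" else (0, 1)
        aligned = (colour_aligned if dim == "colour" else shape_aligned) + "_test"
        tests.append(TestTrial(
            trial_id=f"e3-test{i}", grid=grid,
            demonstrators=("red_test", "blue_test"), phase=3,
            context=ctx, aligned=aligned, uneven=uneven))
    return ExperimentDesign(
        experiment=3, condition=condition, seed=seed, ego_utility=ego,
        ego_cue=ego_cue, agents=agents, evidence_levels=evidence,
        test_trials=tests, groups=groups, counterbalanced=cb,
    )


# ---------------------------------------------------------------------------
# cohort evidence: demonstrator behaviour and precomputed inference
# ---------------------------------------------------------------------------

@dataclass
class CohortEvidence:
    """Everything shared by the participants of one cohort.

    All participants in a condition observe the same demonstrations, so the
    evidence rollouts and the strategy-side inference (utility posteriors,
    the latent-group partition posterior and the cue-conditional utility
    predictives) are computed once per cohort.
    """

    evidence_obs: dict  # agent id -> list[(grid, traj)]
    behaviour_posteriors: dict  # known demonstrator id -> UtilityPosterior
    cue_posteriors: dict  # novel demonstrator id -> UtilityPosterior
    test_paths: dict  # trial id -> {demo id: Trajectory}
    demo_order: dict  # trial id -> tuple of demo ids in observation order
    agreement_history: list  # list[AgreementTrial]
    partition_posterior: object = None


def _ego_preferred_item(grid: GridWorld, ego: UtilityFunction):
    cells = sorted(grid.items)
    vals = [ego.item_value(grid.items[c]) for c in cells]
    if abs(vals[0] - vals[1]) < 1e-12:
        return None
    return grid.items[cells[int(np.argmax(vals))]]


def generate_evidence(
    design: ExperimentDesign,
    rng: np.random.Generator,
    ugrid: Optional[UtilityGrid] = None,
    alpha: float = 1.0,
    g0: G0Params = G0Params(),
    gamma: float = 0.95,
) -> CohortEvidence:
    """Roll out demonstrator behaviour and precompute strategy inference."""
    ugrid = ugrid if ugrid is not None else UtilityGrid.regular()
    evidence_obs: dict = {aid: [] for aid in design.agents}
    q_cache: dict = {}

    def demo_policy(agent: Agent, grid: GridWorld):
        key = (agent.id, grid.signature())
        pol = q_cache.get(key)
        if pol is None:
            q = compute_q(grid, agent.utility, gamma=gamma)
            pol = boltzmann_policy(q, agent.beta)
            q_cache[key] = pol
        return pol

    for level in design.evidence_levels:
        for aid in level.actors:
            agent = design.agents[aid]
            traj = rollout(level.grid, demo_policy(agent, level.grid),
                           START, max_steps=40, rng=rng, agent_id=aid)
            evidence_obs[aid].append((level.grid, traj))

    # test-level demonstrations: each demonstrator walks to its chosen box
    test_paths: dict = {}
    demo_order: dict = {}
    for trial in design.test_trials:
        paths = {}
        for aid in trial.demonstrators:
            agent = design.agents[aid]
            paths[aid] = rollout(trial.grid, demo_policy(agent, trial.grid),
                                 START, max_steps=40, rng=rng, agent_id=aid)
        test_paths[trial.trial_id] = paths
        order = list(trial.demonstrators)
        rng.shuffle(order)
        demo_order[trial.trial_id] = tuple(order)

    # dyadic behavioural posteriors for demonstrators with observed evidence
    behaviour_posteriors = {
        aid: posterior_over_utility(obs, DEMO_BETA, ugrid, gamma)
        for aid, obs in evidence_obs.items()
        if obs
    }

    # latent-group posterior from the cue-bearing evidence agents
    partition_post = None
    cue_posteriors: dict = {}
    cue_bearing = [
        aid for aid, a in design.agents.items()
        if a.phi is not None and evidence_obs[aid]
    ]
    novel = [
        aid for trial in design.test_trials for aid in trial.demonstrators
        if aid not in behaviour_posteriors
    ]
    if cue_bearing:
        observed = [
            ObservedAgent(aid, design.agents[aid].phi, evidence_obs[aid])
            for aid in cue_bearing
        ]
        partition_post = exact_partition_posterior(
            observed, alpha=alpha, g0=g0, beta=DEMO_BETA, ugrid=ugrid, gamma=gamma
        )
        for aid in dict.fromkeys(novel):
            cue_posteriors[aid] = utility_given_cue(
                partition_post, design.agents[aid].phi
            )

    # agreement history for the frequency strategy (cue-group vs ego preference)
    agreement: list = []
    for level in design.evidence_levels:
        pref = _ego_preferred_item(level.grid, design.ego_utility)
        if pref is None:
            continue
        for aid in level.actors:
            agent = design.agents[aid]
            if agent.phi is None:
                continue
            group = "red" if agent.phi < 0.5 else "blue"
            for grid, traj in evidence_obs[aid]:
                if grid is not level.grid:
                    continue
                if traj.collected_item is None:
                    continue
                agreement.append(
                    AgreementTrial(group=group, agrees=traj.collected_item == pref)
                )
    return CohortEvidence(
        evidence_obs=evidence_obs,
        behaviour_posteriors=behaviour_posteriors,
        cue_posteriors=cue_posteriors,
        test_paths=test_paths,
        demo_order=demo_order,
        agreement_history=agreement,
        partition_posterior=partition_post,
    )


# ---------------------------------------------------------------------------
# participant simulation
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    """One hidden-item test trial of one simulated participant."""

    participant_id: str
    trial_id: str
    level_id: str
    phase: int
    context: Optional[ContextVector]
    demonstrators: tuple
    demo_trajectories: dict
    demo_groups: dict
    aligned_demonstrator: Optional[str]
    chosen_demonstrator: str
    participant_trajectory: Trajectory
    ego_utility: UtilityFunction
    predictions: dict  # StrategyId -> predicted demonstrator id or None
    sides: dict  # demo id -> "left" | "right"
    strategy_weights: dict = None  # generating strategy's w_m per demo
    selection_probabilities: dict = None  # softmax of the above


def _strategy_weights(
    strategy: StrategyId,
    design: ExperimentDesign,
    evidence: CohortEvidence,
    trial: TestTrial,
) -> DemonstratorWeights:
    """Selection weights of one social strategy on one test trial."""
    demos = trial.demonstrators
    equal = DemonstratorWeights(weights={m: 0.0 for m in demos})
    if strategy == StrategyId.S1_indiscriminate:
        return equal
    if strategy == StrategyId.S2_rational_dyadic:
        if all(m in evidence.behaviour_posteriors for m in demos):
            return rational_weights(
                design.ego_utility,
                {m: evidence.behaviour_posteriors[m] for m in demos},
            )
        return equal
    if strategy == StrategyId.S3_naive_cue:
        cues = {m: design.agents[m].phi for m in demos}
        if any(c is None for c in cues.values()):
            return equal
        try:
            return ingroup_weights(cues, design.ego_cue, mode="distance")
        except StrategyInapplicable:
            return equal
    if strategy == StrategyId.S4_rational_cue:
        if all(m in evidence.behaviour_posteriors for m in demos):
            return rational_weights(
                design.ego_utility,
                {m: evidence.behaviour_posteriors[m] for m in demos},
                c=trial.context,
            )
        if all(m in evidence.cue_posteriors for m in demos):
            return rational_weights(
                design.ego_utility,
                {m: evidence.cue_posteriors[m] for m in demos},
                c=trial.context,
            )
        return equal
    if strategy == StrategyId.S5_agreement_frequency:
        cues = {m: design.agents[m].phi for m in demos}
        if any(c is None for c in cues.values()) or not evidence.agreement_history:
            return equal
        gw = agreement_frequency_weights(
            evidence.agreement_history, groups=("red", "blue")
        )
        return DemonstratorWeights(
            weights={
                m: gw.weights["red" if cues[m] < 0.5 else "blue"] for m in demos
            },
            evidence_used="both",
        )
    raise ValueError(f"{strategy} is not a social strategy")


def _side_of(traj: Trajectory, grid: GridWorld) -> Optional[str]:
    end = traj.final_cell()
    if end is None:
        return None
    return "left" if end[0] < grid.width / 2 else "right"


def _trial_view(
    trial: TestTrial,
    evidence: CohortEvidence,
    last_side: Optional[str],
) -> TestLevelView:
    paths = evidence.test_paths[trial.trial_id]
    side_of = {m: _side_of(t, trial.grid) for m, t in paths.items()}
    dist = {}
    for m, t in paths.items():
        end = t.final_cell()
        dist[m] = abs(end[0] - START[0]) + abs(end[1] - START[1])
    return TestLevelView(
        demo_order=evidence.demo_order[trial.trial_id],
        side_of=side_of,
        distance_of=dist,
        last_side=last_side,
    )


def _argmax_or_none(weights: dict, tol: float = 1e-9) -> Optional[str]:
    ids = list(weights)
    vals = np.array([weights[m] for m in ids])
    top = vals.max()
    tied = [m for m, v in zip(ids, vals) if v >= top - tol]
    return tied[0] if len(tied) == 1 else None


def simulate_participant(
    design: ExperimentDesign,
    strategy: StrategyId,
    beta_ego: float = DEFAULT_BETA_EGO,
    rng: Optional[np.random.Generator] = None,
    evidence: Optional[CohortEvidence] = None,
    participant_id: str = "p0",
) -> list:
    """Simulate one participant's hidden-item test choices.

    On each test trial the participant computes the generating strategy's
    demonstrator weights, samples a social learning target from the softmax
    selection rule, and reproduces that demonstrator's path. Every trial
    record also carries each candidate strategy's prediction for later
    best-fit counting (None when a strategy has no preference).
    """
    rng = rng if rng is not None else np.random.default_rng()
    if evidence is None:
        evidence = generate_evidence(design, rng)
    records = []
    last_side: Optional[str] = None
    for trial in design.test_trials:
        view = _trial_view(trial, evidence, last_side)
        weights = {
            s: _strategy_weights(s, design, evidence, trial)
            for s in (
                StrategyId.S1_indiscriminate,
                StrategyId.S2_rational_dyadic,
                StrategyId.S3_naive_cue,
                StrategyId.S4_rational_cue,
                StrategyId.S5_agreement_frequency,
            )
        }
        predictions: dict = {
            s: _argmax_or_none(w.weights) for s, w in weights.items()
        }
        for h in (
            StrategyId.H_alternating,
            StrategyId.H_closest,
            StrategyId.H_copy_first,
            StrategyId.H_copy_last,
        ):
            predictions[h] = heuristic_choice(h, view)

        sel_w = sel_p = None
        if strategy in weights:
            chosen = select_demonstrator(weights[strategy], beta_ego, rng)
            sel_w = dict(weights[strategy].weights)
            sel_p = {m: float(v) for m, v in
                     selection_probs(weights[strategy], beta_ego).items()}
        else:
            pred = predictions[strategy]
            if pred is None:
                pred = trial.demonstrators[int(rng.integers(2))]
            chosen = pred
        paths = evidence.test_paths[trial.trial_id]
        copied = paths[chosen]
        part_traj = Trajectory(
            agent_id=participant_id,
            level_id=copied.level_id,
            steps=list(copied.steps),
            end_cell=copied.end_cell,
            collected_item=copied.collected_item,
        )
        last_side = _side_of(part_traj, trial.grid)
        records.append(TrialRecord(
            participant_id=participant_id,
            trial_id=trial.trial_id,
            level_id=trial.grid.level_id,
            phase=trial.phase,
            context=trial.context,
            demonstrators=trial.demonstrators,
            demo_trajectories=dict(paths),
            demo_groups={m: design.group_of(m) for m in trial.demonstrators},
            aligned_demonstrator=trial.aligned,
            chosen_demonstrator=chosen,
            participant_trajectory=part_traj,
            ego_utility=design.ego_utility,
            predictions=predictions,
            sides={m: _side_of(t, trial.grid) for m, t in paths.items()},
            strategy_weights=sel_w,
            selection_probabilities=sel_p,
        ))
    return records


def simulate_cohort(
    design: ExperimentDesign,
    strategy: StrategyId,
    n_participants: int,
    rng: Optional[np.random.Generator] = None,
    beta_ego: float = DEFAULT_BETA_EGO,
    evidence: Optional[CohortEvidence] = None,
    share_evidence: bool = False,
) -> tuple:
    """Simulate a cohort of participants on one design.

    By default every participant observes freshly sampled demonstrator
    populations and demonstrations (as each human participant did), so
    trial outcomes are independent across participants; ``share_evidence``
    reuses one set of demonstrations for the whole cohort instead. Returns
    (records, evidence_of_last_participant).
    """
    rng = rng if rng is not None else np.random.default_rng()
    if evidence is None and share_evidence:
        evidence = generate_evidence(design, rng)
    records = []
    last_ev = evidence
    for i in range(n_participants):
        ev = evidence if evidence is not None else generate_evidence(design, rng)
        records.extend(simulate_participant(
            design, strategy, beta_ego=beta_ego, rng=rng,
            evidence=ev, participant_id=f"p{i}",
        ))
        last_ev = ev
    if last_ev is None:
        last_ev = generate_evidence(design, rng)
    return records, last_ev


def simulate_condition(
    experiment: int,
    condition,
    strategy: StrategyId,
    n_participants: int,
    rng: Optional[np.random.Generator] = None,
    beta_ego: float = DEFAULT_BETA_EGO,
    uneven_tests: bool = False,
) -> list:
    """Simulate independent participants of one experimental condition.

    Every participant gets a freshly built design (their own counterbalance
    draw, sampled agent population and demonstrations), as in the
    behavioural experiments; records from all participants are pooled.
    """
    rng = rng if rng is not None else np.random.default_rng()
    records = []
    for i in range(n_participants):
        seed_i = int(rng.integers(2**31 - 1))
        design = build_experiment(experiment, condition, seed=seed_i,
                                  uneven_tests=uneven_tests)
        evidence = generate_evidence(design, rng)
        recs = simulate_participant(
            design, strategy, beta_ego=beta_ego, rng=rng,
            evidence=evidence, participant_id=f"p{i}",
        )
        records.extend(recs)
    return records
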