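"""Bayesian preference inference and latent-group (DPMM) posteriors.

Two layers of inference:

* **Individual level** — a discrete posterior over candidate utility
  functions on a lattice over [0, 1]^D, obtained by scoring observed
  state-action choices under Boltzmann-rational policies (inverse planning).
* **Group level** — a Dirichlet-process mixture over agents: each latent
  group draws its members' cues from a Gaussian (Normal-Inverse-Gamma base)
  and their utilities from a shared distribution over the lattice. The
  posterior over set partitions of the observed agents is computed exactly
  by Bell-number enumeration for small populations, or sampled by collapsed
  Gibbs using Chinese-restaurant-process conditionals.

All arithmetic is in log space with log-sum-exp normalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .gridworld import (
    ACTION_INDEX,
    GridWorld,
    UtilityFunction,
    boltzmann_probs,
    compute_q,
    compute_q_batch,
)


# ---------------------------------------------------------------------------
# utility lattice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UtilityGrid:
    """Finite lattice of candidate utility weight vectors with a prior.

    The default resolution is 21 points per dimension (step 0.05) over
    [0, 1]^2, which includes the indifference point 0.5 on each dimension.
    """

    candidates: np.ndarray  # (n, D)
    log_prior: np.ndarray  # (n,)

    @staticmethod
    def regular(resolution: int = 21, n_dims: int = 2) -> "UtilityGrid":
        axes = [np.linspace(0.0, 1.0, resolution)] * n_dims
        mesh = np.meshgrid(*axes, indexing="ij")
        cands = np.stack([m.ravel() for m in mesh], axis=1)
        n = len(cands)
        return UtilityGrid(
            candidates=cands, log_prior=np.full(n, -math.log(n))
        )

    @property
    def n(self) -> int:
        return len(self.candidates)

    def key(self) -> tuple:
        return (self.candidates.shape, self.candidates.tobytes())

    def __post_init__(self):
        lp = np.asarray(self.log_prior, dtype=float)
        if abs(logsumexp(lp)) > 1e-8:
            raise ValueError("prior must be normalised")


@dataclass
class UtilityPosterior:
    """Discrete posterior over the utility lattice."""

    grid: UtilityGrid
    log_weights: np.ndarray
    log_evidence: float = 0.0

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    def map_estimate(self) -> np.ndarray:
        """Posterior mode (realises the argmax inference under a flat prior)."""
        return self.grid.candidates[int(np.argmax(self.log_weights))]

    def mean(self) -> np.ndarray:
        return self.weights @ self.grid.candidates

    def expectation(self, values: np.ndarray) -> float:
        """E[f(U)] for per-candidate values ``values``."""
        return float(self.weights @ np.asarray(values, dtype=float))

    def mass(self, mask: np.ndarray) -> float:
        return float(self.weights[np.asarray(mask, dtype=bool)].sum())

    def to_dict(self) -> dict:
        """JSON-serialisable dump (candidates, weights, log evidence)."""
        return {
            "candidates": self.grid.candidates.tolist(),
            "weights": self.weights.tolist(),
            "log_evidence": float(self.log_evidence),
        }

    def save_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict()))


# ---------------------------------------------------------------------------
# cached candidate log-policies per layout
# ---------------------------------------------------------------------------

_LOG_POLICY_CACHE: dict = {}


def candidate_log_policies(
    grid: GridWorld,
    ugrid: UtilityGrid,
    beta: float,
    gamma: float = 0.95,
) -> np.ndarray:
    """(n_candidates, S, A) log Boltzmann policies, cached by layout.

    The value iteration is batched across lattice candidates; layouts recur
    across agents and participants so this cache dominates the speed of all
    posterior computations.
    """
    key = (grid.signature(), ugrid.key(), float(beta), float(gamma))
    out = _LOG_POLICY_CACHE.get(key)
    if out is None:
        Q = compute_q_batch(grid, ugrid.candidates, gamma=gamma)
        probs = boltzmann_probs(Q, beta)
        out = np.log(probs)
        _LOG_POLICY_CACHE[key] = out
    return out


Observation = tuple  # (GridWorld, Trajectory)


def choice_likelihood(
    observations: Sequence[Observation],
    utility: UtilityFunction,
    beta: float,
    gamma: float = 0.95,
) -> float:
    """Log-likelihood of observed state-action choices under one utility.

    Sums the log Boltzmann action probability over every (s, a) pair in the
    observed trajectories, with Q computed for ``utility`` in each level.
    """
    total = 0.0
    for grid, traj in observations:
        q = compute_q(grid, utility, gamma=gamma)
        probs = boltzmann_probs(q.values, beta)
        for cell, action in traj.steps:
            total += math.log(
                probs[grid.state_index(cell), ACTION_INDEX[action]]
            )
    return total


def loglik_lattice(
    observations: Sequence[Observation],
    ugrid: UtilityGrid,
    beta: float,
    gamma: float = 0.95,
) -> np.ndarray:
    """(n_candidates,) log-likelihood of the observations for every candidate."""
    total = np.zeros(ugrid.n)
    for grid, traj in observations:
        logp = candidate_log_policies(grid, ugrid, beta, gamma)
        for cell, action in traj.steps:
            total += logp[:, grid.state_index(cell), ACTION_INDEX[action]]
    return total


def posterior_over_utility(
    observations: Sequence[Observation],
    beta: float,
    prior: UtilityGrid,
    gamma: float = 0.95,
) -> UtilityPosterior:
    """Discrete posterior over utility candidates given observed choices.

    With no observations the posterior equals the prior. The posterior mode
    is the maximum-a-posteriori utility (the argmax estimate under a flat
    prior).
    """
    ll = loglik_lattice(observations, prior, beta, gamma)
    unnorm = prior.log_prior + ll
    log_ev = float(logsumexp(unnorm))
    if not np.isfinite(log_ev):
        raise AssertionError("all-zero likelihood row")
    return UtilityPosterior(
        grid=prior, log_weights=unnorm - log_ev, log_evidence=log_ev
    )


# ---------------------------------------------------------------------------
# DPMM over observed agents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class G0Params:
    """Normal-Inverse-Gamma base distribution for group cue parameters."""

    m0: float = 0.5
    kappa0: float = 1.0
    a0: float = 2.0
    b0: float = 0.01


@dataclass
class ObservedAgent:
    """One agent's evidence: an optional visible cue and observed choices."""

    id: str
    cue: Optional[float]
    observations: list  # list[Observation]


def _nig_log_marginal(xs: Sequence[float], g0: G0Params) -> float:
    """Log marginal likelihood of scalar cues under the NIG-Normal model."""
    n = len(xs)
    if n == 0:
        return 0.0
    x = np.asarray(xs, dtype=float)
    kn = g0.kappa0 + n
    an = g0.a0 + n / 2.0
    xbar = x.mean()
    ss = float(((x - xbar) ** 2).sum())
    bn = g0.b0 + 0.5 * ss + (g0.kappa0 * n * (xbar - g0.m0) ** 2) / (2.0 * kn)
    return float(
        gammaln(an)
        - gammaln(g0.a0)
        + g0.a0 * math.log(g0.b0)
        - an * math.log(bn)
        + 0.5 * (math.log(g0.kappa0) - math.log(kn))
        - (n / 2.0) * math.log(2.0 * math.pi)
    )


def _all_partitions(items: Sequence[int]):
    """All set partitions of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1 :]
        yield part + [{first}]


def _canonical(blocks: Iterable) -> tuple:
    return tuple(sorted((frozenset(b) for b in blocks), key=lambda b: sorted(b)))


@dataclass
class PartitionPosterior:
    """Posterior over set partitions of the observed agents.

    Holds everything needed to extend the population with a new agent
    (cue-conditional utility predictives): the agents' evidence, the
    utility lattice, the per-agent candidate log-likelihood matrix, and the
    model hyperparameters.
    """

    agents: list  # list[ObservedAgent]
    partitions: list  # list[tuple[frozenset, ...]]
    log_probs: np.ndarray
    ugrid: UtilityGrid
    agent_loglik: np.ndarray  # (M, n_candidates)
    alpha: float
    g0: G0Params

    def __post_init__(self):
        if abs(logsumexp(self.log_probs)) > 1e-8:
            raise ValueError("partition probabilities must be normalised")

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_probs)

    def coclustering(self) -> np.ndarray:
        """P(agents i and j share a block), for every agent pair."""
        M = len(self.agents)
        C = np.zeros((M, M))
        for blocks, p in zip(self.partitions, self.probs):
            for b in blocks:
                idx = sorted(b)
                for i in idx:
                    for j in idx:
                        C[i, j] += p
        return C

    def map_partition(self) -> tuple:
        return self.partitions[int(np.argmax(self.log_probs))]


def _block_choice_log_marginal(
    block: frozenset, agent_loglik: np.ndarray, log_prior: np.ndarray
) -> float:
    """Marginal likelihood of a block's choices under one shared utility.

    The block's members are assumed to share a utility drawn from the
    lattice prior; the marginal integrates the product of their choice
    likelihoods over that prior.
    """
    total = log_prior.copy()
    for m in block:
        total = total + agent_loglik[m]
    return float(logsumexp(total))


def _crp_log_prior(blocks: Sequence[frozenset], alpha: float) -> float:
    """CRP partition weight: alpha^|blocks| * prod (|b| - 1)! (unnormalised)."""
    lp = len(blocks) * math.log(alpha)
    for b in blocks:
        lp += gammaln(len(b))
    return lp


def exact_partition_posterior(
    agents: Sequence[ObservedAgent],
    alpha: float = 1.0,
    g0: G0Params = G0Params(),
    beta: float = 0.2,
    ugrid: Optional[UtilityGrid] = None,
    gamma: float = 0.95,
    max_agents: int = 10,
) -> PartitionPosterior:
    """Exact DPMM posterior over partitions by enumerating all of them.

    Each partition is scored by its Chinese-restaurant-process prior times,
    per block, the marginal likelihood of the members' cues (conjugate
    Normal with a Normal-Inverse-Gamma base) and of their choices (the
    block-shared utility marginalised over the lattice). Invisible cues
    contribute no cue term (missing at random).
    """
    agents = list(agents)
    M = len(agents)
    if M == 0:
        raise ValueError("need at least one agent")
    if M > max_agents:
        raise ValueError(
            f"{M} agents exceeds the enumeration bound ({max_agents}); "
            "use gibbs_partition_posterior"
        )
    ugrid = ugrid if ugrid is not None else UtilityGrid.regular()
    A = np.stack([loglik_lattice(a.observations, ugrid, beta, gamma) for a in agents])
    parts = []
    scores = []
    for blocks in _all_partitions(range(M)):
        canon = _canonical(blocks)
        lp = _crp_log_prior(canon, alpha)
        for b in canon:
            cues = [agents[m].cue for m in b if agents[m].cue is not None]
            lp += _nig_log_marginal(cues, g0)
            lp += _block_choice_log_marginal(b, A, ugrid.log_prior)
        parts.append(canon)
        scores.append(lp)
    scores = np.asarray(scores)
    log_probs = scores - logsumexp(scores)
    return PartitionPosterior(
        agents=agents,
        partitions=parts,
        log_probs=log_probs,
        ugrid=ugrid,
        agent_loglik=A,
        alpha=alpha,
        g0=g0,
    )


def gibbs_partition_posterior(
    agents: Sequence[ObservedAgent],
    alpha: float = 1.0,
    g0: G0Params = G0Params(),
    beta: float = 0.2,
    sweeps: int = 2000,
    rng: Optional[np.random.Generator] = None,
    ugrid: Optional[UtilityGrid] = None,
    gamma: float = 0.95,
    burn_in: float = 0.1,
) -> PartitionPosterior:
    """Collapsed Gibbs sampler over agent group assignments.

    Each sweep resamples every agent's block from its CRP conditional times
    the block's cue and choice predictives; block marginal likelihoods are
    memoised by member set, so long chains are cheap. Returns the empirical
    distribution over visited partitions.
    """
    if sweeps < 1:
        raise ValueError("sweeps must be at least 1")
    rng = rng if rng is not None else np.random.default_rng()
    agents = list(agents)
    M = len(agents)
    ugrid = ugrid if ugrid is not None else UtilityGrid.regular()
    A = np.stack([loglik_lattice(a.observations, ugrid, beta, gamma) for a in agents])

    choice_cache: dict = {frozenset(): 0.0}
    cue_cache: dict = {frozenset(): 0.0}

    def choice_marg(block: frozenset) -> float:
        v = choice_cache.get(block)
        if v is None:
            v = _block_choice_log_marginal(block, A, ugrid.log_prior)
            choice_cache[block] = v
        return v

    def cue_marg(block: frozenset) -> float:
        v = cue_cache.get(block)
        if v is None:
            cues = [agents[m].cue for m in block if agents[m].cue is not None]
            v = _nig_log_marginal(cues, g0)
            cue_cache[block] = v
        return v

    def block_score(block: frozenset) -> float:
        return choice_marg(block) + cue_marg(block)

    # start with every agent in its own block
    assignment = list(range(M))

    samples: dict = {}
    keep_from = int(sweeps * burn_in)
    for sweep in range(sweeps):
        for m in range(M):
            blocks: dict = {}
            for i, z in enumerate(assignment):
                if i != m:
                    blocks.setdefault(z, set()).add(i)
            labels = list(blocks)
            logw = []
            for z in labels:
                b = frozenset(blocks[z])
                logw.append(
                    math.log(len(b))
                    + block_score(b | {m})
                    - block_score(b)
                )
            logw.append(math.log(alpha) + block_score(frozenset({m})))
            logw = np.asarray(logw)
            p = np.exp(logw - logsumexp(logw))
            choice = int(rng.choice(len(p), p=p))
            if choice < len(labels):
                assignment[m] = labels[choice]
            else:
                assignment[m] = max(assignment) + 1 + m  # fresh label
        if sweep >= keep_from:
            blocks = {}
            for i, z in enumerate(assignment):
                blocks.setdefault(z, set()).add(i)
            canon = _canonical(blocks.values())
            samples[canon] = samples.get(canon, 0) + 1
    total = sum(samples.values())
    parts = list(samples)
    log_probs = np.log(np.array([samples[p] / total for p in parts]))
    return PartitionPosterior(
        agents=agents,
        partitions=parts,
        log_probs=log_probs,
        ugrid=ugrid,
        agent_loglik=A,
        alpha=alpha,
        g0=g0,
    )


def utility_given_cue(
    post: PartitionPosterior,
    phi_new: Optional[float],
    prior: Optional[UtilityGrid] = None,
) -> UtilityPosterior:
    """Cue-conditional utility predictive for a newly encountered agent.

    Marginalises over latent group assignments: under each partition the
    new agent joins an existing block with probability proportional to the
    block size times the block's cue predictive (or opens a new block with
    weight alpha times the prior predictive), and inherits the block's
    utility posterior (the prior for a new block). ``phi_new=None`` (an
    invisible cue) leaves only the rich-get-richer block-size weighting.
    With no observed population (``post=None``) the predictive is the prior.
    """
    if post is None:
        if prior is None:
            raise ValueError("need a prior lattice when no population observed")
        return UtilityPosterior(grid=prior, log_weights=prior.log_prior.copy())
    ugrid = prior if prior is not None else post.ugrid
    if ugrid is not post.ugrid and ugrid.key() != post.ugrid.key():
        raise ValueError("prior lattice must match the partition posterior's")
    mix = np.full(ugrid.n, -np.inf)
    g0 = post.g0
    for blocks, lp_part in zip(post.partitions, post.log_probs):
        # join weights: existing blocks then a new one
        options = []
        for b in blocks:
            lw = math.log(len(b))
            if phi_new is not None:
                cues = [post.agents[m].cue for m in b if post.agents[m].cue is not None]
                lw += _nig_log_marginal(list(cues) + [phi_new], g0) - _nig_log_marginal(
                    cues, g0
                )
            options.append((b, lw))
        lw_new = math.log(post.alpha)
        if phi_new is not None:
            lw_new += _nig_log_marginal([phi_new], g0)
        options.append((None, lw_new))
        norm = logsumexp(np.array([lw for _, lw in options]))
        for b, lw in options:
            if b is None:
                block_post = ugrid.log_prior
            else:
                unnorm = ugrid.log_prior.copy()
                for m in b:
                    unnorm = unnorm + post.agent_loglik[m]
                block_post = unnorm - logsumexp(unnorm)
            contrib = lp_part + (lw - norm) + block_post
            mix = np.logaddexp(mix, contrib)
    mix = mix - logsumexp(mix)
    return UtilityPosterior(grid=ugrid, log_weights=mix)
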