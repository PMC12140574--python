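# Methods

This note documents the models implemented in `grouplearn`, the defaults
they ship with, what the synthetic-participant generator does and does not
emulate, and the numerical choices that matter when interpreting results.

## The decision environment

Levels are deterministic gridworlds (default 9×9) with 0-based `(x, y)`
coordinates, origin top-left. Actions are the four cardinal moves plus a
no-op; moves into walls or off-grid are no-ops that still cost a step, so
every recorded step has unit duration. Items carry two binary features
(colour ∈ {green, yellow}, shape ∈ {triangle, circle}); entering an item
cell collects the item and ends the episode (item cells are absorbing with
zero continuation value).

**Utility functions.** An agent's utility is a weight vector
w ∈ [0, 1]^D with 0.5 = indifference on a dimension. Item payoffs are
additive across dimensions: dimension i contributes `base + span·wᵢ` if the
item carries that dimension's positive level and `base + span·(1 − wᵢ)`
otherwise, with defaults base = 0, span = 10 per dimension and a step cost
of 1 point per move. The experiments the generator emulates told
participants their point values but the published record does not include
them, so the payoff scale is a package default and fully configurable; all
qualitative results are invariant to positive affine rescalings of item
payoffs (tested).

**Planning.** Agent-specific action values Q(s, a | U) are computed by
value iteration (default γ = 0.95, convergence tolerance 1e-6, at most 10⁴
sweeps); the implementation batches the sweep across whole lattices of
candidate utilities, and converged tables are cached by layout signature,
which is what makes lattice posteriors affordable. Policies are Boltzmann:
π(s, a) ∝ exp(Q(s, a)/β). β is a temperature — *larger β is noisier* — and
the β → 0⁺ limit is greedy with ties split uniformly. Demonstrators use
β = 0.2 (visibly goal-directed paths); the simulated learner's selection
rule uses β_ego = 0.5 except where noted.

## Preference inference

The learner's hypothesis space is a regular lattice over [0, 1]^D (default
21 points per dimension, so D = 2 gives 441 candidates, always including
the indifference point) with a flat prior. Given observed state-action
pairs O, the posterior is p(U | O) ∝ p(U) ∏ π(s, a | U); the posterior mode
realises the maximum-likelihood utility estimate. All posterior arithmetic
is in log space with log-sum-exp normalisation; a Boltzmann likelihood is
strictly positive, so posteriors are always well-defined.

## Latent groups

Populations are modelled as a Dirichlet-process mixture: stick-breaking
weights ρ_c = β_c ∏_{j<c}(1 − β_j), β_c ~ Beta(1, α); each group k has
parameters θ_k governing a Gaussian cue distribution on the scalar [0, 1]
cue axis and a utility distribution; each agent draws its group z, then its
utility U and visible cue φ from that group. Defaults: α = 1 (the
concentration is not constrained by any published value), truncation level
20 when sampling open-ended populations.

Posterior inference is collapsed. A partition of the observed agents is
scored by its Chinese-restaurant prior α^{|blocks|} ∏ (|b| − 1)! times, per
block, (i) the marginal likelihood of the members' cues under a conjugate
Normal–Inverse-Gamma base (m₀ = 0.5, κ₀ = 1, a₀ = 2, b₀ = 0.01 — a broad
prior centred mid-axis) and (ii) the marginal likelihood of the members'
choices under one *shared* utility drawn from the flat lattice prior.
Agents with invisible cues contribute no cue term (missing at random, never
treated as a value). For up to 10 agents every partition is enumerated
(Bell numbers stay small); beyond that a collapsed Gibbs sampler resamples
each agent's block from its CRP conditional, with block marginals memoised
by member set so long chains cost little. The two routes agree to within
0.02 in co-clustering probability on the fixtures used in the tests.

A newly encountered agent with cue φ* joins each existing block with weight
∝ block size × cue predictive (Student-t), or a new block with weight ∝ α ×
prior predictive; its utility predictive p(U | φ*) is the corresponding
mixture of block utility posteriors (the prior, for a new block), averaged
over the partition posterior.

## Selection strategies

All strategies output real-valued demonstrator weights w⁽ᵐ⁾ fed to
Pr(copy m) ∝ exp(w⁽ᵐ⁾/β_ego). The rational weights are posterior-expected
similarity, sim(U, V) = Σᵢ |Uᵢ − 0.5|(1 − |Uᵢ − Vᵢ|), optionally masked by a
binary context vector over feature dimensions. One operation covers both
the dyadic strategy (posteriors inferred from the demonstrator's own
behaviour) and the cue-based strategy (cue-conditional posteriors). The
ingroup bias has two modes — ±1 on shared group labels, or the negative
cue distance −|φ_m − φ_ego| — and the simulations use the distance mode;
with an invisible own cue the strategy is inapplicable and falls back to
indiscriminate selection. The agreement-frequency strategy scores each cue
group by the *proportion* of its observed evidence choices that matched the
ego's preference between the offered items (proportions rather than raw
counts, so unequal trial numbers enter only through the deliberate
colour/shape imbalance of the design); groups without observations get the
uninformed weight 0.5, and the weights ignore choice context by
construction. Trials on which the ego is indifferent between the two
offered items carry no agreement information and are skipped.

## The synthetic experiments

The generator reproduces the structure of three behavioural designs:

1. **Known demonstrators.** Two agents, one sharing the participant's
   colour preference; 8 observed evidence trajectories (4 per agent) on
   visible-item levels, then 2 analysed hidden-item ("mystery box") test
   choices where only the demonstrators' paths are informative.
2. **Cue-bearing groups.** Two groups separated on one utility dimension
   (default cue means 0.2/0.8, cue SD 0.06; dominant-dimension utility mean
   0.85, SD 0.08; other dimension 0.5, SD 0.15). Five conditions cross
   group relevance with the participant's own cue (invisible, arbitrary,
   matched, mismatched — the cue mean of the group aligned, or misaligned,
   with the participant's utility). A known-agents phase (2 evidence levels
   × 2 grey agents, 4 test trials) precedes a phase with 4 cue-bearing
   evidence agents (2 per group, 2 choices each) and 4 test trials with 2
   *novel* cue-bearing demonstrators, so test-phase selectivity requires
   generalising through the latent group structure.
3. **Context dependence.** Groups occupy opposite preference quadrants
   ((0.85, 0.85) vs (0.15, 0.15)); participants sit in a mixed quadrant
   ((0.85, 0.15) or its mirror), sharing colour preference with one group
   and shape preference with the other. Evidence contains 3 colour-contrast
   and 2 shape-contrast choices per group — the imbalance that makes the
   agreement-frequency strategy always favour the colour-aligned group —
   followed by 4 hidden colour-only and 4 hidden shape-only test choices
   with the relevant dimension announced.

Group parameters are package defaults (the published record describes the
distributions graphically, not numerically) and are configurable.
Counterbalancing of preferred levels, item sides and demonstrator
presentation order is resolved per participant from the seed. Every
simulated participant receives a freshly sampled design and population, as
each human participant did; this keeps trial outcomes independent across
participants, which the binomial tests assume. (A shared-evidence mode
exists for cheap large cohorts but induces within-cohort correlation and
should not be used with those tests.)

Test levels place both boxes 9 moves from the start by construction; an
`uneven_tests` variant shortens one arm to 5 moves so the
nearest-item heuristic makes determinate predictions. Participants copy
their selected demonstrator's path exactly; scores are undiscounted points
under the participant's own utility.

**What the generator does not emulate:** human lapses and exclusions
(cohorts are balanced; the published per-condition trial counts vary),
reading-time or order effects, perceptual colour space (the cue is the
scalar coordinate that parameterises it), and any within-participant
learning across test trials. Passing pattern-recovery tests therefore shows
that the strategies separate under the stated generative conditions, not
that humans do (the published counts carry that evidence).

## Scoring

Trajectory similarity is s = exp(−F) on cell-centre coordinate sequences,
with F the discrete Fréchet distance (Eiter–Mannila dynamic programme,
Euclidean ground metric; action labels are ignored). Relative selectivity
toward demonstrator 1 is s̄₁/(s̄₁+s̄₂) over a trial set; each trajectory is
also classified to the strictly more similar demonstrator, with exact ties
excluded from the copy-count denominator (documented because the published
per-condition denominators vary without explanation). Departures from the
indiscriminate null use the exact minimum-likelihood two-sided binomial
test (p = Σ over outcomes no more probable than the observed count); the
normal-approximation 95% CI on proportions is provided for display. Of the
published p-values, every "< 0.001" claim reproduces under this test; two
numerically printed values do not (the published pair 0.523/0.648 for the
symmetric counts 63/120 and 57/120 cannot both come from one exact
two-sided test, which gives 0.648 for both), so the package reproduces the
count ratios exactly and reports its own exact p-values.

Best-fit strategy counting scores, per participant, the fraction of test
choices each candidate strategy predicts; a strategy with no preference on
a trial (tied weights, inapplicable rule) receives 0.5 — its expected hit
rate — and a participant's best-fit set is the argmax (ties allowed, so one
participant can be best-captured by several strategies). Self-recovery
cohorts are generated at β_ego = 0.1: the check validates the counting
logic, which requires generated choices to follow the strategy's preference
ordering rather than selection noise. One boundary case is inherent to
hit-based counting: an indiscriminate generator produces fair coin flips,
every deterministic candidate then scores Binomial(n, ½) hits, and the
maximum of several such scores exceeds ½ with high probability — so the
indiscriminate strategy is never modally recovered. This is a property of
the counting rule, not of the implementation, and it is the reason the
recovery driver reports that case as not recovered. The rational dyadic
strategy is recovered on the known-demonstrators design, where the
cue-based rational strategy necessarily ties it (no cues exist there);
ties count for both.

The return surface averages the imitator's return over Boltzmann
demonstrator rollouts (truncated at 30 steps) from uniformly random starts
in a four-goal arena, for demonstrators constructed at exact similarity t
to the fixed imitator utility (1, 0) via segment interpolation to (0, 1),
which attains every similarity in [0, 1]. One discount (default γ = 0.95)
is used for both the demonstrators' planning and the return scoring: with
mismatched objectives a mildly noisy aligned demonstrator systematically
outscores a greedy one (greedy discounted planning forgoes distant
high-value items that undiscounted scoring rewards), which would break the
surface's interpretation. Monte-Carlo standard errors are reported per
cell, and the monotonicity checks (non-decreasing in similarity at fixed
β, non-increasing in β at maximal similarity) are asserted within 3 SEs.

## Problem sizes and numerical choices

Default problem sizes used by the drivers and checks: 100–150 simulated
participants per condition (4–8 analysed test trials each), 100 simulated
populations for cue-posterior recovery, 5×10⁴ Gibbs sweeps for the
sampler-vs-enumeration comparison, 300–400 rollouts per return-surface
cell. The brute-force oracles run exhaustively where that is feasible
(every pair of grid walks of length ≤ 4 on a 3×3 grid for the Fréchet
programme; every action sequence to horizon 8 on ≤ 16-cell grids for value
iteration — the optimum there is attained well inside the horizon, so
truncation cannot bite). Posterior normalisations are asserted to 1e-10;
argmax predictions treat weight differences below 1e-9 as ties.

## Known limitations

* Two fixed latent groups in the presets; the DPMM supports more, but the
  experiment designs do not exercise hierarchical or overlapping structure.
* Demonstrator competence (β) is fixed and shared; inferring per-agent β
  is out of scope, as is any hybrid of ingroup bias with rational
  weighting.
* The utility lattice discretises preferences at 0.05 resolution; posterior
  means inherit that granularity.
* Agents never share a level simultaneously; there are no multi-agent
  dynamics.
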