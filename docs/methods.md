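# Methods

This note records the models, conventions and design choices behind
`ventrl`, in the order the pipeline runs.

## Synthetic ICU cohort

The simulator generates ventilated COVID-ARDS-like admissions at hourly
resolution. It is a *statistical* stand-in for restricted clinical data: its
purpose is to give the pipeline a cohort with the right structure (sparse
irregular observations, setting-dependent gas exchange, outcome-linked
severity, concentrated physician action transitions), not physiological
fidelity.

**Latent dynamics.** Each patient carries a scalar severity `z_t` following
`z_{t+1} = a·z_t − recovery + push(a_t) + ε`, `ε ~ N(0, σ_z²)`, with AR
coefficient `a = 0.9`. Treatment enters through `push`: PEEP mistuning
(quadratic distance from a 10 cmH2O optimum, width 4 cmH2O) slows recovery,
as does non-ventilation of a severe patient. Recovery drives `z` below a
discharge threshold; a per-step death hazard is logistic in severity,
`p_t = σ(h0 + h1·z_{t+1} + toxicity)`.

**Observables.** Gas exchange responds to a setting change at the *next*
hourly measurement (one-hour lag): P/F falls with severity and squared PEEP
mistuning and rises with the FiO2 in effect; Vd/Vt is logistic in severity
and PEEP excess; PaCO2 is linear in severity; auxiliary channels are AR(1)
processes loaded on severity. PaO2 is emitted as P/F × current FiO2, so the
builder recovers P/F exactly. Values are masked Bernoulli-independently at
per-variable missingness rates (defaults 0.2–0.35); settings are always
recorded.

**Physician behaviour.** A softmax over the 17 actions whose utility matches
ventilatory support (the ordinal sum of PEEP and FiO2 bins) to a
severity-dependent target, plus a strong bonus for staying within one king
step of the previous action. This reproduces the concentrated transition
structure of real setting changes: >95% of consecutive action pairs stay
within Chebyshev distance 1 under defaults.

**Mortality calibration.** The hazard intercept `h0` is, unless given
explicitly, found by bisection on a pilot cohort (2 × 2048 patients, common
random numbers, deterministic per configuration) so cohort mortality matches
a configurable target, 24.4% by default. Monotonicity checks that vary the
hazard slope pass an explicit intercept so the calibration does not cancel
the manipulation.

**What the simulator does not model** — and hence what passing tests do not
show about real data: multivariate physiology and treatment beyond
PEEP/FiO2, ventilator modes, informative (severity-dependent) missingness,
inter-centre variation, and admissions longer than the configured horizon
(default 72 h versus a real mean of roughly two weeks; kept short so suites
run in seconds).

## Trajectory construction

Long-format events become hourly trajectories: observations are bucketed to
hour, carry-forward imputed up to per-variable limits (defaults: 8 h for
blood gases, 4 h for vitals-like channels, unlimited for ventilator settings
within an episode; the limits are clinical cut-offs and fully configurable),
then optionally aggregated over trailing 4/6/24-hour windows (mean/min/max).
An observed/imputed/missing status is kept per slot; imputation never
overwrites an observation. Bins on the action lattice are
left-closed/right-open with the last bin closed, making binning a partition
of the (PEEP, FiO2) quarter-plane; FiO2 given as a fraction is auto-rescaled
to percent and negative PEEP clips to zero. Normalisation statistics are fit
on the training split only and frozen; remaining missing slots become the
column mean (zero after z-scoring). The reward engine reads gas-exchange
values only where *strictly observed* — carried-forward values never earn
intermediate reward, so imputation artefacts cannot be gamed.

The admission-level split is 70/30 by patient with a seeded shuffle.

## Reward family

The exact constants of the source formulation are not public; the engine
implements a parameterised family with two separable components. Intermediate:
`w_pf · clip(ΔPF/50 mmHg) − w_vd · clip(ΔVdVt/0.1)`, each component clipped
to ±1. Terminal: −1 on death; survival pays a destination multiplier
(home 1.0, rehab 0.75, other hospital 0.5) minus a length-of-stay cost
calibrated so 14 ICU days cost half the survival bonus. λ multiplies the
terminal component only; the study grid [0.25, 0.5, 1, 2, 4, 8] maps to
version ids v1..v6. The final step of a trajectory has no successor
measurement, so its intermediate component is zero and it carries
λ × terminal; rewards are therefore affine in λ at the terminal step and
constant in λ elsewhere (tested exactly).

## Q-agent

A dueling fully-connected network (3–5 hidden layers of 32/64/128 units,
ReLU) with a scalar value head and a 17-way advantage head,
`Q = V + A − mean(A)`. Training is offline: all transitions fill a replay
buffer; minibatches are drawn by proportional prioritised replay
(`P(i) ∝ p_i^α`, importance weights `(N·P)^{−β}` normalised by the batch
maximum, β annealed to 1); targets use the double-Q rule with a periodically
synced target network; priorities track |TD error| + ε; gradients are
norm-clipped; Adam with step-decay or reduce-on-plateau schedules.
Everything is hand-written NumPy, single-threaded and bit-deterministic
under a seed. Argmax ties break toward the lowest action index throughout.

An optional *restricted backup* confines the bootstrap argmax to the
king-knight neighbourhood of the logged action. This both matches the
semantics of evaluating restricted policies and substantially curbs the
value overestimation that offline max-bootstrap suffers at small sample
sizes, where the max ranges over actions the data barely covers.

The discount defaults to 0.99; experiments at desk scale use smaller values
(see limitations).

## Policies and behaviour estimate

Greedy: argmax Q over all 17 actions. King-knight: argmax over the mask of
the previous action — all ventilated actions within Chebyshev distance 1,
plus NV iff the previous action lies in the configured extubation set
(default: lowest PEEP bin × two lowest FiO2 bins), and everything from NV.
Mask cardinalities are 9/6/4 (+NV) for interior/edge/corner previous
actions. For evaluation, deterministic policies are ε-softened with the mass
spread over *allowed* actions only; recommendations shown to users stay
deterministic. The physician behaviour policy is estimated by exact
k-nearest-neighbour voting on z-scored states with additive smoothing
(defaults k=100, α=0.5), keeping every action's probability strictly
positive as the importance-sampling estimators require.

## Off-policy evaluation

Per-decision self-normalised weights: `ρ_t = Π_{u≤t} π_e/π_b`, frozen past a
trajectory's end (absorbing convention, reward 0), normalised across
trajectories at each step; `w_{−1} = 1/n`. PDWIS sums `γ^t w_t r_t`. The
partial-horizon WDR return g^(j) importance-samples the first j steps with
doubly-robust control variates from the model's q̂ and v̂ = E_{π_e}[Q] and
appends the model tail; j=0 is the pure model estimate, j=∞ full WDR. MAGIC
estimates the covariance of the g^(j) from per-trajectory contributions,
proxies bias by the signed distance of each g^(j) to a percentile-bootstrap
interval of g^(∞), and minimises x'(Ω + bb')x over the probability simplex
(SLSQP polished against vertex and dense-grid search; the grid is the test
oracle for |J| ≤ 3). Defaults: J = {0, 1, 2, 5, 10, 25, ∞}, 200 bootstrap
resamples, 90% percentile intervals. The reported CI bootstraps the blended
estimate with weights held fixed — the point estimate is not guaranteed to
lie inside it.

Relative value is `estimate − behaviour value` (the empirical mean
discounted return of the logged data); a difference rather than a ratio for
stability near zero.

**Cross-OPE.** Round 1 evaluates each policy under its own reward version
and passes it iff relative value > 0. Round 2 evaluates round-1 passers
under the remaining versions; passing all marks reward-shaping robustness.
Final ranking orders round-2-evaluated policies by their minimum (optionally
mean) relative value over all versions.

## Clinical inspection

Delta-Q = Q(s, policy action) − Q(s, physician action); zero is agreement,
and a greedy policy's delta-Q is non-negative by construction while a
restricted policy's may go negative when the clinician jumped outside the
mask to a globally better action. Aggregates: per-physician-action surfaces
(count, mean physician Q, mean policy Q, mean delta-Q; the count-weighted
cell mean reproduces the global mean exactly), per-action Q histograms over
all dataset states, and action counts stratified by survival for physician
versus policy. Per-trajectory series use a sign-preserving log compression
`sign(Δ)·ln(1 + |Δ|/σ)` with σ defaulting to the series' delta-Q standard
deviation. The alert rule — fire when |delta-Q(t) − median over the previous
6 h| exceeds a threshold (default 2σ) — operationalises "sudden changes in
delta-Q" and is deliberately simple; both parameters are exposed.

## Reward-shaping discrimination experiment

`synthetic_icu.conflict_config` defines a stress cohort in which supplemental
oxygen inflates the *measured* gas-exchange indices (P/F lift, transient
dead-space improvement) while FiO2 above 50% carries a steep death hazard,
and simulated physicians are conservative. The simulator's own on-policy
Monte-Carlo oracle confirms the designed crossover: a mild FiO2-escalation
policy is best under λ=0.25 but falls below behaviour under λ=8, while a
conservative policy beats behaviour under every weighting.
`orchestrator.discrimination_experiment` trains one agent per weighting
(short credit horizon γ=0.5 during training so the per-step toxicity credit
is not drowned by bootstrapped continuation values; masked backups; OPE at
γ=0.97) and runs the two-round cross-OPE selection. At its canonical
configuration the intermediate-chasing agent passes round 1 and fails the
terminal-dominated version while the terminal-aware agent passes all six.

## Known limitations

- Desk-scale offline DQN is noisy: with hundreds of admissions and small
  networks, Q-values overestimate (max-bootstrap over thinly covered
  actions) and trained-policy behaviour varies across seeds. The
  discrimination experiment's round-2 margin is small and sign-flips under
  some seeds; the experiment documents its canonical configuration rather
  than claiming seed-universal robustness.
- Per-decision weighted importance sampling degenerates on long horizons:
  weights concentrate on a handful of trajectories (deaths freeze their
  ratios early and dominate later steps). Estimates on the full 72-hour
  cohort lean heavily on the model term; the stress experiment uses short
  stays for exactly this reason.
- The simulator's missingness is non-informative and its dynamics
  univariate in severity; transfer of any conclusion to real ICU data is a
  claim about the method, not about medicine.
- The full published-scale grid (tens of thousands of models) is replaced
  by configurable desk-scale grids; counts and percentages from the full
  run are reproduced arithmetically by the report logic, not re-trained.
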