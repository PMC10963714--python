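# ventrl — safe offline RL for ICU ventilator settings

`ventrl` is a research pipeline for learning and — more importantly — *safely
evaluating* ventilator-setting policies (PEEP and FiO2) from retrospective
ICU data. It is aimed at clinical ML researchers who want to study offline
reinforcement learning for mechanical ventilation without access to
protected patient data: a seeded synthetic ICU simulator stands in for the
restricted source cohorts, and every component of the method stack is
exercised end to end on it.

## What it implements

**The decision problem.** One ICU admission is a trajectory of hourly states
`s_t` (ventilator settings, blood-gas values, auxiliary channels; carry-forward
imputed and z-scored), actions `a_t` on a 4×4 PEEP×FiO2 bin lattice plus a
single non-ventilated (NV) action (17 actions), and a shaped reward

```
r_t      = w_pf · clip(ΔPF/s_pf) − w_vd · clip(ΔVd/Vt / s_vd)        (t < T−1)
r_{T−1}  = λ · [ −R_death   if died
                 R_survive · dest_mult − c_los · LOS   otherwise ]
```

where PF = PaO2/FiO2 (oxygenation) and Vd/Vt = (PaCO2 − ETCO2)/PaCO2
(Enghoff–Bohr dead space). The weighting factor λ ∈ {0.25, 0.5, 1, 2, 4, 8}
defines six reward versions v1..v6.

**The method stack.**

- *Agent*: a dueling double-deep-Q network, Q(s,a) = V(s) + A(s,a) − mean A,
  trained offline with prioritised experience replay (pure NumPy, fully
  deterministic under a seed).
- *King-knight restriction*: recommendations are confined to the 3×3
  Chebyshev neighbourhood of the previous action; extubation (NV) may only
  be recommended from configured low-support actions, and from NV anything
  is allowed.
- *Off-policy evaluation*: per-decision weighted importance sampling (PDWIS),
  weighted doubly robust (WDR) partial-horizon returns g^(j), and the MAGIC
  estimator that blends the g^(j) with simplex weights minimising estimated
  bias² + variance, with bootstrap confidence intervals. The physician
  behaviour policy is estimated by smoothed k-nearest-neighbour voting.
- *Cross-OPE selection*: a policy trained under one reward version is
  evaluated under all six; passing its own version (value above behaviour)
  admits it to round 2, surviving every version marks it robust to
  reward-shaping choices. This is the pipeline's selection centrepiece.
- *Delta-Q inspection*: Δ(s) = Q(s, policy action) − Q(s, physician action),
  with per-action Q distributions, aggregate action-space surfaces,
  outcome-stratified action heatmaps, per-trajectory signed-log series and a
  median-window clinical alert rule.

## Worked example

```python
import ventrl
from ventrl.orchestrator import ExperimentConfig, run_experiment, report
import ventrl.q_agent as qa

cfg = ExperimentConfig(
    sim=ventrl.SimConfig(n_patients=150, max_horizon=48, seed=7),
    lambdas=(0.5, 2.0),                      # two of the six reward versions
    arch_grid=({"n_hidden_layers": 3, "width": 32},),
    train_grid=({"lr": 1e-3},),
    base_train=qa.TrainConfig(n_updates=800),
    behaviour_k=50, seed=7, out_dir="runs/demo")
manifest = run_experiment(cfg)
print(report(manifest))
```

On this configuration the simulated cohort has 35/150 deaths (23.3%
mortality, tracking the 24.4% calibration target), and the report prints

```
n_models 2        n_policies_evaluated 4
n_round1_selected 4   n_round2_passed 4   round2_pass_pct 100
```

with cross-OPE relative values such as `m_a0_t0_v2_greedy | v2 | +3.78` —
the estimated value of that policy minus the physician behaviour value under
reward version v2. The run directory holds the cohort CSVs, model
checkpoints with JSON sidecars, the cross-OPE table, histogram data and
inspection CSVs, indexed by `manifest.json`.

The same pipeline is available from the shell:

```bash
ventrl simulate --n-patients 200 --seed 7 --out runs/cohort
ventrl build --cohort runs/cohort --out runs/build.json
ventrl run --seed 7 --out runs/demo
ventrl mask-table          # audit the king-knight allowed-action table
```

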