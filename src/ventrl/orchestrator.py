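"""Config-driven experiment runner: simulate/load -> build -> shape (per
reward version) -> train the model grid -> derive greedy and king-knight
policies -> round-1 OPE -> cross-OPE -> rank -> inspection bundle.

The run directory holds every artefact (cohort CSVs, model checkpoints,
cross-OPE tables, inspection CSVs) with a JSON manifest as the index. A
re-run against an existing directory resumes: completed cohort and model
artefacts are reused if the configuration hash matches, and refused with a
diff if it does not. Per-model seeds are derived from the global seed with a
stable hash, so results do not depend on execution order.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_icu as sim
from . import trajectory_builder as tb
from . import reward_engine as rw
from . import q_agent as qa
from . import policy_engine as pe
from . import ope_engine as ope
from . import inspection as insp

logger = logging.getLogger(__name__)


def _stable_seed(*parts) -> int:
    h = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class ExperimentConfig:
    sim: sim.SimConfig = field(default_factory=lambda: sim.SimConfig(n_patients=200))
    cohort_dir: str | None = None          # load instead of simulate
    lambdas: tuple = rw.LAMBDA_GRID
    reward: rw.RewardConfig = field(default_factory=rw.RewardConfig)
    arch_grid: tuple = (
        {"n_hidden_layers": 3, "width": 32},
        {"n_hidden_layers": 3, "width": 64},
    )
    train_grid: tuple = (
        {"lr": 1e-3, "lr_schedule": "step"},
        {"lr": 1e-3, "lr_schedule": "plateau"},
    )
    base_train: qa.TrainConfig = field(default_factory=lambda: qa.TrainConfig(n_updates=1500))
    restriction: pe.RestrictionConfig = field(default_factory=pe.RestrictionConfig)
    ope: ope.CrossOPEConfig = field(default_factory=ope.CrossOPEConfig)
    behaviour_k: int = 100
    behaviour_alpha: float = 0.5
    soften_eps: float = 0.01
    train_fraction: float = 0.7
    max_missing_fraction: float = 0.9
    top_n: int = 100
    n_inspect: int = 2                     # top policies given inspection bundles
    seed: int = 0
    out_dir: str = "runs/default"

    def __post_init__(self):
        if not self.arch_grid or not self.train_grid or not self.lambdas:
            raise ValueError("every grid dimension needs at least one value")
        if any(l <= 0 for l in self.lambdas):
            raise ValueError("lambda values must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lambdas"] = list(self.lambdas)
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_or_simulate(cfg: ExperimentConfig, out: Path):
    cohort_dir = out / "cohort"
    if cfg.cohort_dir:
        return sim.load_cohort(cfg.cohort_dir)
    if (cohort_dir / "events.csv").exists():
        logger.info("resuming: reusing simulated cohort in %s", cohort_dir)
        return sim.load_cohort(cohort_dir)
    events, outcomes = sim.simulate_cohort(cfg.sim)
    sim.write_cohort(events, outcomes, cohort_dir, cfg.sim)
    return events, outcomes


def _prepare(cfg: ExperimentConfig, events, outcomes, grid):
    trajs = tb.build_trajectories(events, outcomes, grid=grid)
    trajs, excl_report = tb.exclude_low_quality(trajs, cfg.max_missing_fraction)
    train, test = tb.split_train_test(trajs, cfg.train_fraction, cfg.seed)
    stats = tb.fit_normalization(train)
    return tb.normalize(train, stats), tb.normalize(test, stats), stats, excl_report


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    chash = cfg.content_hash()
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") != chash:
            raise RuntimeError(
                "refusing to resume: run directory holds a different "
                f"configuration (hash {old.get('config_hash')} != {chash}); "
                "use a fresh out_dir or delete the old run")

    grid = tb.ActionGrid()
    timings = {}

    t0 = time.time()
    events, outcomes = _load_or_simulate(cfg, out)
    timings["cohort"] = time.time() - t0

    t0 = time.time()
    train, test, stats, excl_report = _prepare(cfg, events, outcomes, grid)
    timings["build"] = time.time() - t0

    # shaped rewards per version, train and test
    versions = [rw.version_id(l) for l in cfg.lambdas]
    rcfgs = {v: cfg.reward.with_lambda(l) for v, l in zip(versions, cfg.lambdas)}
    t0 = time.time()
    train_rewards = {v: rw.shape_cohort(train, rc) for v, rc in rcfgs.items()}
    test_rewards = {v: rw.shape_cohort(test, rc) for v, rc in rcfgs.items()}
    timings["shape"] = time.time() - t0

    # behaviour policy on training data
    t0 = time.time()
    Xtr = np.vstack([t.states for t in train])
    Atr = np.concatenate([t.actions for t in train])
    k = min(cfg.behaviour_k, len(Xtr))
    behaviour = pe.knn_behaviour_policy(Xtr, Atr, k, cfg.behaviour_alpha,
                                        grid.n_actions)
    timings["behaviour"] = time.time() - t0

    # model grid
    t0 = time.time()
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    models, model_rows = {}, []
    for ai, arch in enumerate(cfg.arch_grid):
        for ti, tg in enumerate(cfg.train_grid):
            for v in versions:
                mid = f"m_a{ai}_t{ti}_{v}"
                seed = _stable_seed(cfg.seed, ai, ti, v)
                ckpt = models_dir / f"{mid}.npz"
                if ckpt.exists() and (models_dir / f"{mid}.json").exists():
                    model = qa.QModel.load(models_dir / mid)
                    logger.info("resuming: loaded %s", mid)
                else:
                    spec = qa.QNetworkSpec(n_actions=grid.n_actions, **arch)
                    tc = dataclasses.replace(cfg.base_train, seed=seed, **tg)
                    model = qa.train_q(train, train_rewards[v], spec, tc,
                                       reward_version=v)
                    model.save(models_dir / mid)
                    pd.DataFrame({"loss": model.loss_trace}).to_csv(
                        models_dir / f"{mid}_loss.csv", index=False)
                models[mid] = model
                model_rows.append({
                    "model_id": mid, "arch": dict(arch), "train": dict(tg),
                    "reward_version": v, "seed": seed,
                    "checkpoint": str(ckpt), "hash": model.content_hash()})
    timings["train"] = time.time() - t0

    # two policies per model
    policies, own_version, policy_rows = {}, {}, []
    for mid, model in models.items():
        for kind, pol in (("greedy", pe.greedy_policy(model)),
                          ("king_knight", pe.restricted_policy(model, cfg.restriction, grid))):
            pid = f"{mid}_{kind}"
            policies[pid] = pe.soften(pol, cfg.soften_eps, cfg.restriction, grid)
            own_version[pid] = model.reward_version
            policy_rows.append({"policy_id": pid, "model_id": mid, "kind": kind,
                                "reward_version": model.reward_version})

    # precompute per-policy and per-version OPE ingredients on the test split
    t0 = time.time()
    lengths = np.array([t.T for t in test])
    Tmax = int(lengths.max())
    n = len(test)
    prevs = [np.concatenate([[grid.nv_index], t.actions[:-1]]) for t in test]
    pi_b = np.ones((n, Tmax))
    for i, traj in enumerate(test):
        Pb = behaviour.probs_batch(traj.states, prevs[i])
        pi_b[i, :traj.T] = Pb[np.arange(traj.T), traj.actions]
    R_by_version = {}
    for v in versions:
        R = np.zeros((n, Tmax))
        for i, r in enumerate(test_rewards[v]):
            R[i, :len(r)] = r
        R_by_version[v] = R

    model_of = {r["policy_id"]: r["model_id"] for r in policy_rows}
    policy_arrays = {}
    for pid, pol in policies.items():
        model = models[model_of[pid]]
        pi_e = np.ones((n, Tmax))
        Qh = np.zeros((n, Tmax))
        Vh = np.zeros((n, Tmax))
        for i, traj in enumerate(test):
            Pe = pol.probs_batch(traj.states, prevs[i])
            Q = model.evaluate(traj.states)
            T = traj.T
            pi_e[i, :T] = Pe[np.arange(T), traj.actions]
            Qh[i, :T] = Q[np.arange(T), traj.actions]
            Vh[i, :T] = (Pe * Q).sum(axis=1)
        policy_arrays[pid] = (pi_e, Qh, Vh)
    timings["ope_prep"] = time.time() - t0

    def make_dataset(pid, v):
        pi_e, Qh, Vh = policy_arrays[pid]
        return ope.OPEDataset(pi_b, pi_e, R_by_version[v], Qh, Vh, lengths)

    t0 = time.time()
    ocfg = dataclasses.replace(cfg.ope, seed=_stable_seed(cfg.seed, "ope"),
                               top_n=cfg.top_n)
    matrix = ope.cross_ope(policies, own_version, versions, make_dataset, ocfg)
    timings["cross_ope"] = time.time() - t0

    matrix.to_frame().to_csv(out / "cross_ope.csv", index=False)
    matrix.histogram_frame().to_csv(out / "ope_histograms.csv", index=False)

    # inspection bundle for the top-ranked policies
    t0 = time.time()
    insp_dir = out / "inspection"
    insp_dir.mkdir(exist_ok=True)
    for pid in matrix.ranking[:cfg.n_inspect]:
        model, pol = models[model_of[pid]], policies[pid]
        insp.aggregate_surfaces(test, model, pol, grid).to_csv(
            insp_dir / f"{pid}_surfaces.csv", index=False)
        insp.q_distribution_per_action(test, model, grid=grid).to_csv(
            insp_dir / f"{pid}_q_distributions.csv", index=False)
        insp.action_distribution_by_outcome(test, pol, grid).to_csv(
            insp_dir / f"{pid}_actions_by_outcome.csv", index=False)
    timings["inspection"] = time.time() - t0

    counts = {
        "n_models": len(models),
        "n_policies": len(policies),
        "n_round1_pass": int(sum(bool(v) for v in matrix.round1_pass.values())),
        "n_round2_pass": int(sum(bool(v) for v in matrix.round2_pass.values()
                                 if v is not None)),
    }
    manifest = {
        "config_hash": chash,
        "config": cfg.to_dict(),
        "exclusions": excl_report,
        "n_train": len(train), "n_test": len(test),
        "models": model_rows,
        "policies": policy_rows,
        "counts": counts,
        "cross_ope": matrix.to_frame().to_dict(orient="records"),
        "ranking": matrix.ranking,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "wall_time_s": round(time.time() - t_start, 3),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def discrimination_experiment(seed: int = 17, n_patients: int = 1000,
                              train_lambdas: tuple = (0.25, 2.0),
                              n_updates: int = 4000,
                              soften_eps: float = 0.3) -> dict:
    """Reward-shaping robustness stress test on the conflict simulator.

    Trains one dueling-DDQN agent per weighting in `train_lambdas` on a
    cohort where short-term P/F gains conflict with terminal mortality
    (see synthetic_icu.conflict_config), derives king-knight policies, and
    runs the two-round cross-OPE selection over all six reward versions.
    Training uses a short credit horizon (gamma 0.5) and the restricted
    backup so the per-decision oxygen-toxicity trade-off dominates learning;
    evaluation uses the full-horizon discount.

    Returns the relative-value table plus the discrimination indicators: the
    intermediate-chasing agent (lowest lambda) should pass round 1 under its
    own version yet fail under the terminal-dominated version, while the
    terminal-aware agent should pass every version.
    """
    cfg = sim.conflict_config(n_patients=n_patients, seed=seed)
    grid = tb.ActionGrid()
    events, outcomes = sim.simulate_cohort(cfg)
    trajs = tb.build_trajectories(events, outcomes)
    train, test = tb.split_train_test(trajs, 0.7, seed=seed)
    stats = tb.fit_normalization(train)
    train = tb.normalize(train, stats)
    test = tb.normalize(test, stats)
    masks = np.stack([pe.king_knight_mask(p, grid=grid)
                      for p in range(grid.n_actions)])
    Xtr = np.vstack([t.states for t in train])
    Atr = np.concatenate([t.actions for t in train])
    behaviour = pe.knn_behaviour_policy(Xtr, Atr, k=50, alpha_s=0.5,
                                        n_actions=grid.n_actions)
    versions = [rw.version_id(l) for l in rw.LAMBDA_GRID]
    gamma_eval = 0.97

    policies, own = {}, {}
    models = {}
    for lam in train_lambdas:
        v = rw.version_id(lam)
        rcfg = rw.RewardConfig(lambda_=lam)
        rewards = rw.shape_cohort(train, rcfg)
        tcfg = qa.TrainConfig(n_updates=n_updates, seed=_stable_seed(seed, v),
                              gamma=0.5, lr=3e-4, alpha=0.3, batch_size=512,
                              target_sync=500)
        model = qa.train_q(train, rewards, qa.QNetworkSpec(width=32), tcfg,
                           reward_version=v, backup_mask_by_prev=masks)
        pid = f"agent_{v}"
        models[pid] = model
        policies[pid] = pe.soften(pe.restricted_policy(model, grid=grid),
                                  soften_eps, grid=grid)
        own[pid] = v

    # shared OPE ingredients on the held-out split
    lengths = np.array([t.T for t in test])
    Tmax = int(lengths.max())
    n = len(test)
    prevs = [np.concatenate([[grid.nv_index], t.actions[:-1]]) for t in test]
    pi_b = np.ones((n, Tmax))
    for i, tr in enumerate(test):
        Pb = behaviour.probs_batch(tr.states, prevs[i])
        pi_b[i, :tr.T] = Pb[np.arange(tr.T), tr.actions]
    R_by_v = {}
    for lam in rw.LAMBDA_GRID:
        R = np.zeros((n, Tmax))
        for i, t_ in enumerate(test):
            r, _ = rw.shape_trajectory_rewards(t_, rw.RewardConfig(lambda_=lam))
            R[i, :len(r)] = r
        R_by_v[rw.version_id(lam)] = R
    arrays = {}
    for pid, pol in policies.items():
        model = models[pid]
        pi_e = np.ones((n, Tmax))
        Qh = np.zeros((n, Tmax))
        Vh = np.zeros((n, Tmax))
        for i, tr in enumerate(test):
            Pe = pol.probs_batch(tr.states, prevs[i])
            Q = model.evaluate(tr.states)
            T = tr.T
            pi_e[i, :T] = Pe[np.arange(T), tr.actions]
            Qh[i, :T] = Q[np.arange(T), tr.actions]
            Vh[i, :T] = (Pe * Q).sum(axis=1)
        arrays[pid] = (pi_e, Qh, Vh)

    def make_dataset(pid, v):
        pi_e, Qh, Vh = arrays[pid]
        return ope.OPEDataset(pi_b, pi_e, R_by_v[v], Qh, Vh, lengths)

    ocfg = ope.CrossOPEConfig(gamma=gamma_eval, seed=_stable_seed(seed, "xope"))
    matrix = ope.cross_ope(policies, own, versions, make_dataset, ocfg)

    lo = f"agent_{rw.version_id(min(train_lambdas))}"
    hi = f"agent_{rw.version_id(max(train_lambdas))}"
    # evaluate the low-lambda agent under v6 even if it failed earlier rounds
    for pid in (lo, hi):
        for v in versions:
            if (pid, v) not in matrix.results:
                ds = make_dataset(pid, v)
                res = ope.magic_estimate(ds, ocfg.gamma, ocfg.J, ocfg.n_bootstrap,
                                         ocfg.ci_level, ocfg.seed)
                res.with_behaviour(ope.behaviour_value(ds, ocfg.gamma))
                matrix.results[(pid, v)] = res
    rel = {(pid, v): matrix.results[(pid, v)].relative_value
           for pid in (lo, hi) for v in versions}
    indicators = {
        "low_lambda_round1_pass": bool(rel[(lo, own[lo])] > 0),
        "low_lambda_fails_v6": bool(rel[(lo, "v6")] < 0),
        "high_lambda_passes_all": bool(all(rel[(hi, v)] > 0 for v in versions)),
    }
    indicators["discriminates"] = all(indicators.values())
    return {
        "relative_values": {f"{pid}|{v}": float(x) for (pid, v), x in rel.items()},
        "round1_pass": dict(matrix.round1_pass),
        "round2_pass": dict(matrix.round2_pass),
        **indicators,
        "cohort_mortality": float(outcomes["died"].mean()),
    }


def report(manifest: dict) -> dict:
    """Summarise a run manifest (or a counts-only stub) into headline numbers.

    Works from raw counts so that pass percentages always recompute exactly:
    n_policies = 2 * n_models; the round-2 pass/fail percentages are taken
    over the round-1 selected policies.
    """
    counts = dict(manifest.get("counts", {}))
    if "n_models" not in counts:
        raise ValueError("manifest carries no counts — incomplete run")
    partial = "cross_ope" not in manifest
    n_models = counts["n_models"]
    n_policies = counts.get("n_policies", 2 * n_models)
    n_r1 = counts.get("n_round1_pass", 0)
    n_r2 = counts.get("n_round2_pass", 0)
    rep = {
        "n_models": n_models,
        "n_policies_evaluated": n_policies,
        "n_round1_selected": n_r1,
        "n_round2_passed": n_r2,
        "round1_pass_pct": round(100.0 * n_r1 / n_policies) if n_policies else 0,
        "round2_pass_pct": round(100.0 * n_r2 / n_r1) if n_r1 else 0,
        "round2_fail_pct": round(100.0 * (n_r1 - n_r2) / n_r1) if n_r1 else 0,
        "partial": partial,
    }
    if not partial:
        df = pd.DataFrame(manifest["cross_ope"])
        rep["histograms"] = (df.groupby(["version", "round2_pass"], dropna=False)
                               ["relative_value"].describe().reset_index()
                               .to_dict(orient="records"))
        rep["top_n"] = manifest.get("ranking", [])
    return rep
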