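"""Off-policy evaluation: self-normalised importance sampling, weighted
doubly robust partial-horizon returns, the MAGIC blend, and the two-round
cross-OPE selection framework.

Cross-OPE is the selection procedure at the heart of the pipeline: a policy
trained under one weighting of the shaped reward is re-evaluated under every
other weighting. Positive value relative to the physician behaviour under
its own reward version admits a policy to round 2; surviving every version
there marks it as robust to reward-shaping choices.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .policy_engine import Policy

INF = np.inf


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclass
class OPEDataset:
    """Padded per-trajectory arrays for the estimators.

    All arrays are (n, Tmax). Steps past a trajectory's end carry reward 0
    and q_hat = v_hat = 0 (absorbing convention); the importance ratio is
    frozen at its final value by setting both probabilities to 1 there.
    """
    pi_b: np.ndarray        # behaviour probability of the logged action
    pi_e: np.ndarray        # evaluation probability of the logged action
    rewards: np.ndarray
    q_hat: np.ndarray       # model Q(s_t, a_t)
    v_hat: np.ndarray       # model state value under pi_e
    lengths: np.ndarray     # (n,) true horizon per trajectory

    def __post_init__(self):
        if np.any(self.pi_b <= 0):
            bad = np.argwhere(self.pi_b <= 0)[0]
            raise ValueError(
                f"behaviour probability is zero at trajectory {bad[0]}, "
                f"step {bad[1]} — importance ratios undefined")

    @property
    def n(self) -> int:
        return len(self.lengths)

    @property
    def Tmax(self) -> int:
        return self.rewards.shape[1]

    def subset(self, idx) -> "OPEDataset":
        return OPEDataset(self.pi_b[idx], self.pi_e[idx], self.rewards[idx],
                          self.q_hat[idx], self.v_hat[idx], self.lengths[idx])


def build_ope_dataset(trajectories, rewards, behaviour: Policy, target: Policy,
                      model=None, first_prev_action: int | None = None,
                      ) -> OPEDataset:
    """Assemble the padded arrays for a (policy, reward-version) pair.

    The previous action at t=0 is NV by default (admissions begin
    unventilated). q_hat/v_hat are zero when no model is supplied (pure
    importance-sampling estimators).
    """
    n = len(trajectories)
    lengths = np.array([t.T for t in trajectories])
    Tmax = int(lengths.max())
    shp = (n, Tmax)
    pi_b = np.ones(shp)
    pi_e = np.ones(shp)
    R = np.zeros(shp)
    Qh = np.zeros(shp)
    Vh = np.zeros(shp)

    nv = target.n_actions - 1
    for i, (traj, r) in enumerate(zip(trajectories, rewards)):
        T = traj.T
        prev = np.concatenate([[nv if first_prev_action is None else first_prev_action],
                               traj.actions[:-1]])
        Pb = behaviour.probs_batch(traj.states, prev)
        Pe = target.probs_batch(traj.states, prev)
        taken = traj.actions
        pi_b[i, :T] = Pb[np.arange(T), taken]
        pi_e[i, :T] = Pe[np.arange(T), taken]
        R[i, :T] = r
        if model is not None:
            Q = model.evaluate(traj.states)
            Qh[i, :T] = Q[np.arange(T), taken]
            Vh[i, :T] = (Pe * Q).sum(axis=1)
    return OPEDataset(pi_b, pi_e, R, Qh, Vh, lengths)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

@dataclass
class OPEResult:
    point: float
    kind: str
    ci: tuple | None = None                 # (lower, upper, level)
    blend_weights: np.ndarray | None = None
    j_values: tuple | None = None
    contributions: np.ndarray | None = None
    behaviour_value: float | None = None
    relative_value: float | None = None
    extra: dict = field(default_factory=dict)

    def with_behaviour(self, vb: float) -> "OPEResult":
        self.behaviour_value = float(vb)
        self.relative_value = float(self.point - vb)
        return self


def importance_weights(dataset: OPEDataset) -> tuple[np.ndarray, np.ndarray]:
    """Self-normalised per-decision weights.

    rho_t^i = prod_{u<=t} pi_e/pi_b (frozen past termination, since padded
    probabilities are 1); w_t^i = rho_t^i / sum_j rho_t^j. Returns (w, rho)
    of shape (n, Tmax). The convention w_{-1} = 1/n is applied by the
    estimators directly.
    """
    ratio = dataset.pi_e / dataset.pi_b
    rho = np.cumprod(ratio, axis=1)
    denom = rho.sum(axis=0, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("all importance ratios vanished at some step")
    return rho / denom, rho


def behaviour_value(dataset: OPEDataset, gamma: float) -> float:
    """Empirical mean discounted return of the logged trajectories."""
    disc = gamma ** np.arange(dataset.Tmax)
    return float(np.mean((dataset.rewards * disc).sum(axis=1)))


def pdwis_estimate(dataset: OPEDataset, gamma: float) -> OPEResult:
    """Per-decision weighted importance sampling: sum_t gamma^t sum_i w_t^i r_t^i."""
    w, _ = importance_weights(dataset)
    disc = gamma ** np.arange(dataset.Tmax)
    contrib = (w * dataset.rewards * disc).sum(axis=1)
    return OPEResult(float(contrib.sum()), "PDWIS", contributions=contrib)


def j_step_return(dataset: OPEDataset, gamma: float, j) -> tuple[float, np.ndarray]:
    """WDR partial-horizon return g^(j) and its per-trajectory contributions.

    g^(j) uses importance-sampled rewards for the first j steps and the
    model value thereafter, with doubly-robust control variates on the
    sampled segment. j = 0 is the pure model estimate mean v_hat(s_0);
    j = inf (or j >= Tmax) is the full weighted doubly robust estimator.
    """
    n, Tmax = dataset.n, dataset.Tmax
    j_eff = Tmax if (j is INF or j >= Tmax) else int(j)
    w, _ = importance_weights(dataset)
    disc = gamma ** np.arange(Tmax)
    # w_{t-1}: shift right, first column = 1/n
    w_prev = np.concatenate([np.full((n, 1), 1.0 / n), w[:, :-1]], axis=1)

    contrib = np.zeros(n)
    if j_eff > 0:
        sl = slice(0, j_eff)
        contrib += (disc[sl] * w[:, sl] * dataset.rewards[:, sl]).sum(axis=1)
        contrib -= (disc[sl] * (w[:, sl] * dataset.q_hat[:, sl]
                                - w_prev[:, sl] * dataset.v_hat[:, sl])).sum(axis=1)
    if j_eff < Tmax:
        # tail model value; v_hat past termination is 0 by construction
        contrib += gamma ** j_eff * w_prev[:, j_eff] * dataset.v_hat[:, j_eff]
    # j_eff == Tmax: tail value is past every horizon, i.e. 0
    return float(contrib.sum()), contrib


def wdr_estimate(dataset: OPEDataset, gamma: float) -> OPEResult:
    g, c = j_step_return(dataset, gamma, INF)
    return OPEResult(g, "WDR", contributions=c)


def _simplex_grid_min(M: np.ndarray, steps: int = 60):
    """Dense grid search of x'Mx on the simplex (fallback/oracle for |J|<=3)."""
    J = M.shape[0]
    best_x, best_v = None, np.inf
    if J == 1:
        return np.ones(1), float(M[0, 0])
    ticks = np.linspace(0, 1, steps + 1)
    if J == 2:
        for a in ticks:
            x = np.array([a, 1 - a])
            v = x @ M @ x
            if v < best_v:
                best_x, best_v = x, v
    elif J == 3:
        for a in ticks:
            for b in np.linspace(0, 1 - a, int((1 - a) * steps) + 1):
                x = np.array([a, b, 1 - a - b])
                v = x @ M @ x
                if v < best_v:
                    best_x, best_v = x, v
    else:
        raise ValueError("grid fallback supports |J| <= 3")
    return best_x, float(best_v)


def _solve_simplex_qp(M: np.ndarray) -> np.ndarray:
    """argmin x'Mx on the probability simplex (M PSD)."""
    J = M.shape[0]
    cons = [{"type": "eq", "fun": lambda x: x.sum() - 1}]
    bounds = [(0.0, 1.0)] * J
    starts = [np.full(J, 1.0 / J)] + [np.eye(J)[k] for k in range(J)]
    best_x, best_v = None, np.inf
    for x0 in starts:
        res = minimize(lambda x: x @ M @ x, x0, jac=lambda x: 2 * M @ x,
                       method="SLSQP", bounds=bounds, constraints=cons,
                       options={"maxiter": 300, "ftol": 1e-14})
        if res.success or res.fun < best_v:
            x = np.clip(res.x, 0, None)
            x = x / x.sum()
            v = float(x @ M @ x)
            if v < best_v:
                best_x, best_v = x, v
    if J <= 3:
        gx, gv = _simplex_grid_min(M)
        if gv < best_v - 1e-12:
            best_x, best_v = gx, gv
    return best_x


def magic_estimate(dataset: OPEDataset, gamma: float,
                   J=(0, 1, 2, 5, 10, 25, INF), n_bootstrap: int = 200,
                   ci_level: float = 0.9, seed: int = 0) -> OPEResult:
    """MAGIC: blend the partial-horizon WDR returns g^(j), j in J, with
    simplex weights minimising estimated bias^2 + variance.

    The bias of each g^(j) is its signed distance to a percentile-bootstrap
    interval of the full WDR return g^(inf); the covariance of the g^(j) is
    estimated from per-trajectory contributions. The returned CI bootstraps
    the blended estimate with the weights held fixed.
    """
    J = tuple(J)
    if len(J) < 2:
        raise ValueError("MAGIC needs at least two horizons in J")
    n = dataset.n
    if n < 10:
        raise ValueError("MAGIC bootstrap unreliable below 10 trajectories")
    rng = np.random.default_rng(seed)

    g = np.empty(len(J))
    C = np.empty((n, len(J)))   # per-trajectory contributions, sum_i C = g
    for k, j in enumerate(J):
        g[k], C[:, k] = j_step_return(dataset, gamma, j)

    # covariance of the estimates: contributions scaled so each estimate is
    # a mean of n i.i.d.-ish terms
    D = n * C
    Omega = np.atleast_2d(np.cov(D, rowvar=False, ddof=1)) / n

    # bootstrap interval of g^(inf) for the bias proxy
    k_inf = J.index(INF) if INF in J else int(np.argmax(np.asarray(J)))
    d_inf = D[:, k_inf]
    boot = np.empty(n_bootstrap)
    idx_mat = rng.integers(0, n, size=(n_bootstrap, n))
    for b in range(n_bootstrap):
        boot[b] = d_inf[idx_mat[b]].mean()
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(boot, [alpha, 1 - alpha])
    bias = np.where(g < lo, g - lo, np.where(g > hi, g - hi, 0.0))

    M = Omega + np.outer(bias, bias)
    M = 0.5 * (M + M.T) + 1e-14 * np.eye(len(J))
    x = _solve_simplex_qp(M)
    est = float(x @ g)

    # CI of the blended estimate with fixed weights
    blend_i = D @ x
    boot_est = np.array([blend_i[idx_mat[b]].mean() for b in range(n_bootstrap)])
    ci = (float(np.quantile(boot_est, alpha)),
          float(np.quantile(boot_est, 1 - alpha)), ci_level)

    return OPEResult(est, "MAGIC", ci=ci, blend_weights=x, j_values=J,
                     contributions=C @ x,
                     extra={"g_j": g.tolist(), "bias": bias.tolist()})


# ---------------------------------------------------------------------------
# cross-OPE
# ---------------------------------------------------------------------------

@dataclass
class CrossOPEConfig:
    gamma: float = 0.99
    J: tuple = (0, 1, 2, 5, 10, 25, INF)
    n_bootstrap: int = 200
    ci_level: float = 0.9
    seed: int = 0
    pass_threshold: float = 0.0      # relative value must exceed this
    rank_rule: str = "min"           # min | mean over versions
    top_n: int = 100


@dataclass
class CrossOPEMatrix:
    """policies x reward-versions evaluation grid with round flags."""
    policy_ids: list
    versions: list
    results: dict                    # (policy_id, version) -> OPEResult
    round1_pass: dict                # policy_id -> bool
    round2_pass: dict                # policy_id -> bool | None (not evaluated)
    ranking: list                    # policy_ids, best first (round-2 evaluated)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pid, v), res in self.results.items():
            rows.append({
                "policy_id": pid, "version": v, "estimate": res.point,
                "behaviour_value": res.behaviour_value,
                "relative_value": res.relative_value,
                "ci_lower": res.ci[0] if res.ci else None,
                "ci_upper": res.ci[1] if res.ci else None,
                "round1_pass": self.round1_pass.get(pid),
                "round2_pass": self.round2_pass.get(pid),
            })
        return pd.DataFrame(rows)

    def histogram_frame(self) -> pd.DataFrame:
        """Relative values by version and round, for density plots of the
        selection outcome."""
        df = self.to_frame()
        df["round"] = np.where(df["round2_pass"].notna(), 2, 1)
        return df[["policy_id", "version", "relative_value", "round"]]


def cross_ope(policies: dict, own_version: dict, versions, make_dataset,
              cfg: CrossOPEConfig | None = None) -> CrossOPEMatrix:
    """Two-round cross-OPE selection.

    policies: {policy_id: Policy-with-model bundle accepted by make_dataset}.
    own_version: {policy_id: version id it was trained under}.
    make_dataset(policy_id, version) -> OPEDataset for that pairing.
    Round 1 evaluates each policy under its own reward version and passes it
    iff its value relative to the behaviour policy exceeds the threshold.
    Round 2 evaluates the passers under every remaining version and passes
    those positive everywhere. Ranking orders round-2-evaluated policies by
    descending minimum (or mean) relative value over all versions.
    """
    cfg = cfg or CrossOPEConfig()
    versions = list(versions)
    results, r1, r2 = {}, {}, {}

    def evaluate(pid, v):
        ds = make_dataset(pid, v)
        res = magic_estimate(ds, cfg.gamma, cfg.J, cfg.n_bootstrap,
                             cfg.ci_level, cfg.seed)
        res.with_behaviour(behaviour_value(ds, cfg.gamma))
        results[(pid, v)] = res
        return res

    for pid in policies:
        own = own_version[pid]
        if own not in versions:
            raise ValueError(f"policy {pid}: no dataset for version {own}")
        res = evaluate(pid, own)
        r1[pid] = bool(res.relative_value > cfg.pass_threshold)
        r2[pid] = None

    for pid, passed in r1.items():
        if not passed:
            continue
        ok = True
        for v in versions:
            if v == own_version[pid]:
                continue
            res = evaluate(pid, v)
            ok = ok and (res.relative_value > cfg.pass_threshold)
        r2[pid] = ok

    agg = np.min if cfg.rank_rule == "min" else np.mean
    scored = []
    for pid in policies:
        if r2[pid] is None:
            continue
        rel = [results[(pid, v)].relative_value for v in versions]
        scored.append((pid, float(agg(rel))))
    ranking = [pid for pid, _ in sorted(scored, key=lambda t: -t[1])][:cfg.top_n]

    return CrossOPEMatrix(list(policies), versions, results, r1, r2, ranking)
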