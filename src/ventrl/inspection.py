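"""Clinical policy inspection: delta-Q and its aggregate views.

delta-Q = Q(s, policy action) - Q(s, physician action) measures how much
better (positive) or worse (negative) the model rates its own recommendation
than the clinician's logged choice; zero means agreement. A greedy policy's
delta-Q is non-negative by construction; a king-knight-restricted policy can
go negative when the clinician jumped outside the allowed neighbourhood to a
globally better action. The module emits tidy tables for the standard
inspection views: per-action Q-value distributions, aggregate action-space
surfaces, outcome-stratified action heatmaps, per-trajectory log-delta-Q
series, and threshold-based clinical alerts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .policy_engine import Policy
from .q_agent import QModel
from .trajectory_builder import ActionGrid

logger = logging.getLogger(__name__)


@dataclass
class DeltaQRecord:
    patient_id: str
    time_h: int
    physician_action: int
    policy_action: int
    q_policy: float
    q_physician: float

    @property
    def delta_q(self) -> float:
        return self.q_policy - self.q_physician


def delta_q(model: QModel, policy: Policy, state, previous_action: int,
            physician_action: int, patient_id: str = "", time_h: int = 0,
            ) -> DeltaQRecord:
    """One delta-Q record for a single state."""
    q = model.evaluate(state)
    a_pol = policy.action(state, previous_action)
    return DeltaQRecord(patient_id, int(time_h), int(physician_action),
                        int(a_pol), float(q[a_pol]), float(q[physician_action]))


def delta_q_table(trajectories, model: QModel, policy: Policy,
                  grid: ActionGrid | None = None) -> pd.DataFrame:
    """Delta-Q for every step of a cohort, as a tidy frame."""
    grid = grid or ActionGrid()
    rows = []
    for traj in trajectories:
        prev = np.concatenate([[grid.nv_index], traj.actions[:-1]])
        Q = model.evaluate(traj.states)
        P = policy.probs_batch(traj.states, prev)
        a_pol = np.argmax(P, axis=1)
        idx = np.arange(traj.T)
        rows.append(pd.DataFrame({
            "patient_id": traj.patient_id,
            "time_h": idx + traj.t0,
            "physician_action": traj.actions,
            "policy_action": a_pol,
            "q_policy": Q[idx, a_pol],
            "q_physician": Q[idx, traj.actions],
            "died": traj.outcome.died,
        }))
    df = pd.concat(rows, ignore_index=True)
    df["delta_q"] = df["q_policy"] - df["q_physician"]
    return df


def aggregate_surfaces(trajectories, model: QModel, policy: Policy,
                       grid: ActionGrid | None = None) -> pd.DataFrame:
    """Per physician-action cell: count, mean physician Q, mean policy Q,
    mean delta-Q. Cells never visited are absent (missing, not zero)."""
    grid = grid or ActionGrid()
    df = delta_q_table(trajectories, model, policy, grid)
    out = (df.groupby("physician_action")
             .agg(count=("delta_q", "size"),
                  mean_q_physician=("q_physician", "mean"),
                  mean_q_policy=("q_policy", "mean"),
                  mean_delta_q=("delta_q", "mean"))
             .reset_index())
    out["label"] = out["physician_action"].map(grid.label)
    coords = out["physician_action"].map(
        lambda a: grid.coords(a) if grid.is_ventilated(a) else (None, None))
    out["i_peep"] = [c[0] for c in coords]
    out["i_fio2"] = [c[1] for c in coords]
    return out


def q_distribution_per_action(trajectories, model: QModel, bins=40,
                              grid: ActionGrid | None = None) -> pd.DataFrame:
    """Histogram of Q(s, a) over all dataset states, one row per (action, bin)."""
    grid = grid or ActionGrid()
    X = np.vstack([t.states for t in trajectories])
    Q = model.evaluate(X)
    edges = np.histogram_bin_edges(Q.ravel(), bins=bins)
    rows = []
    for a in range(grid.n_actions):
        counts, _ = np.histogram(Q[:, a], bins=edges)
        rows.append(pd.DataFrame({
            "action": a, "label": grid.label(a),
            "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts,
            "mean_q": float(Q[:, a].mean()),
        }))
    return pd.concat(rows, ignore_index=True)


def action_distribution_by_outcome(trajectories, policy: Policy,
                                   grid: ActionGrid | None = None) -> pd.DataFrame:
    """Counts of physician vs policy actions, stratified by survival.

    Four count vectors over the 17 actions: (physician | survivors),
    (policy | survivors), (physician | non-survivors), (policy | non-survivors).
    """
    grid = grid or ActionGrid()
    n = grid.n_actions
    counts = {("physician", False): np.zeros(n, dtype=int),
              ("policy", False): np.zeros(n, dtype=int),
              ("physician", True): np.zeros(n, dtype=int),
              ("policy", True): np.zeros(n, dtype=int)}
    for traj in trajectories:
        died = traj.outcome.died
        prev = np.concatenate([[grid.nv_index], traj.actions[:-1]])
        a_pol = np.argmax(policy.probs_batch(traj.states, prev), axis=1)
        counts[("physician", died)] += np.bincount(traj.actions, minlength=n)
        counts[("policy", died)] += np.bincount(a_pol, minlength=n)
    rows = []
    for (source, died), c in counts.items():
        for a in range(n):
            rows.append({"source": source, "died": died, "action": a,
                         "label": grid.label(a), "count": int(c[a])})
    return pd.DataFrame(rows)


def signed_log(x, sigma: float):
    """Sign-preserving log compression: sign(x) * ln(1 + |x|/sigma)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.log1p(np.abs(x) / sigma)


def trajectory_series(model: QModel, policy: Policy, trajectory,
                      sigma: float | None = None,
                      grid: ActionGrid | None = None) -> pd.DataFrame:
    """Time-indexed delta-Q records for one admission, with the signed-log
    transform used by the 3D trajectory view. sigma defaults to the
    trajectory's delta-Q standard deviation (guarded to 1 if degenerate)."""
    df = delta_q_table([trajectory], model, policy, grid)
    if sigma is None:
        sd = float(df["delta_q"].std(ddof=0))
        sigma = sd if sd > 1e-12 else 1.0
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    df["log_delta_q"] = signed_log(df["delta_q"].to_numpy(), sigma)
    df["sigma"] = sigma
    return df


def clinical_alerts(series: pd.DataFrame, jump_threshold: float,
                    window: int = 6) -> pd.DataFrame:
    """Flag hours where delta-Q jumps away from its recent history.

    An alert fires at t when |delta_q(t) - median(delta_q over the previous
    `window` hours)| exceeds the threshold. Returns the triggering records.
    A series shorter than the window yields no alerts (warning logged).
    """
    if jump_threshold <= 0:
        raise ValueError("jump_threshold must be positive")
    dq = series["delta_q"].to_numpy()
    if len(dq) <= window:
        logger.warning("series of length %d shorter than window %d: no alerts",
                       len(dq), window)
        return series.iloc[0:0].copy()
    flags = np.zeros(len(dq), dtype=bool)
    for t in range(window, len(dq)):
        ref = np.median(dq[t - window:t])
        flags[t] = np.isfinite(jump_threshold) and abs(dq[t] - ref) > jump_threshold
    return series[flags].copy()
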