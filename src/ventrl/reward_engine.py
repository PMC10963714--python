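"""Shaped clinical reward: gas-exchange deltas plus weighted terminal outcome.

The reward has two separable components. The intermediate component rewards
step-to-step improvement in oxygenation (P/F ratio) and penalises worsening
dead-space ventilation (Vd/Vt, Enghoff-Bohr estimate). The terminal component
encodes ICU mortality, length of stay and discharge destination. A single
weighting factor lambda scales the terminal component against the intermediate
one; the study grid is [0.25, 0.5, 1, 2, 4, 8] ("v1".."v6").
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_builder import Trajectory

#: the six reward-version weightings explored in the experiment grid
LAMBDA_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

#: ids "v1".."v6" keyed to the lambda grid
VERSION_IDS = tuple(f"v{i + 1}" for i in range(len(LAMBDA_GRID)))


def version_id(lam: float) -> str:
    for vid, l in zip(VERSION_IDS, LAMBDA_GRID):
        if np.isclose(l, lam):
            return vid
    return f"lam{lam:g}"


@dataclass(frozen=True)
class RewardConfig:
    """Parameters of the shaped reward family.

    lambda_ weights the terminal component (the intermediate component has
    implicit weight 1). s_pf and s_vd are the changes in P/F (mmHg) and Vd/Vt
    that earn one full clipped unit of reward. c_los defaults so that a
    14-day ICU stay costs half the survival bonus.
    """
    lambda_: float = 1.0
    w_pf: float = 1.0
    w_vd: float = 1.0
    s_pf: float = 50.0        # mmHg of P/F change per reward unit
    s_vd: float = 0.1         # Vd/Vt change per reward unit
    clip: float = 1.0         # max |component|
    R_death: float = 1.0
    R_survive: float = 1.0
    dest_multiplier: dict = field(default_factory=lambda: {
        "home": 1.0, "rehab": 0.75, "other_hospital": 0.5})
    c_los: float = 0.5 / (14 * 24)   # per hour; 14 d costs 0.5 * R_survive

    def __post_init__(self):
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.s_pf <= 0 or self.s_vd <= 0:
            raise ValueError("scales must be positive")
        if any(not 0 <= v <= 1 for v in self.dest_multiplier.values()):
            raise ValueError("dest_multiplier values must lie in [0, 1]")

    def with_lambda(self, lam: float) -> "RewardConfig":
        import dataclasses
        return dataclasses.replace(self, lambda_=lam)

    def to_dict(self) -> dict:
        import dataclasses
        return dataclasses.asdict(self)


def pf_ratio(pao2, fio2):
    """P/F ratio (mmHg): PaO2 over FiO2, FiO2 as a fraction in (0, 1]."""
    pao2 = np.asarray(pao2, dtype=float)
    fio2 = np.asarray(fio2, dtype=float)
    if np.any(fio2 <= 0):
        raise ValueError("FiO2 must be a positive fraction")
    return pao2 / fio2


def dead_space_fraction(paco2, etco2):
    """Enghoff-Bohr dead-space estimate (PaCO2 - ETCO2) / PaCO2, clipped [0,1]."""
    paco2 = np.asarray(paco2, dtype=float)
    etco2 = np.asarray(etco2, dtype=float)
    if np.any(paco2 <= 0):
        raise ValueError("PaCO2 must be positive")
    return np.clip((paco2 - etco2) / paco2, 0.0, 1.0)


def _component(delta, scale, clip):
    return np.clip(np.asarray(delta, dtype=float) / scale, -clip, clip)


def intermediate_reward_from_deltas(dpf, dvdvt, cfg: RewardConfig):
    """w_pf * clip(dPF/s_pf) - w_vd * clip(dVdVt/s_vd); arrays broadcast."""
    return (cfg.w_pf * _component(dpf, cfg.s_pf, cfg.clip)
            - cfg.w_vd * _component(dvdvt, cfg.s_vd, cfg.clip))


@dataclass(frozen=True)
class GasExchange:
    """One step's gas-exchange snapshot; pf or vdvt may be undefined (None)."""
    pf: float | None = None
    vdvt: float | None = None

    @classmethod
    def from_raw(cls, pao2=None, fio2=None, paco2=None, etco2=None):
        pf = float(pf_ratio(pao2, fio2)) if pao2 is not None and fio2 is not None else None
        vdvt = (float(dead_space_fraction(paco2, etco2))
                if paco2 is not None and etco2 is not None else None)
        return cls(pf, vdvt)


def intermediate_reward(g_t: GasExchange, g_next: GasExchange, cfg: RewardConfig,
                        ) -> tuple[float, bool]:
    """Reward for the transition g_t -> g_next, plus a validity flag.

    A component with an undefined endpoint contributes 0; the flag is True
    only when at least one component was computable.
    """
    r, valid = 0.0, False
    if g_t.pf is not None and g_next.pf is not None:
        r += cfg.w_pf * float(_component(g_next.pf - g_t.pf, cfg.s_pf, cfg.clip))
        valid = True
    if g_t.vdvt is not None and g_next.vdvt is not None:
        r -= cfg.w_vd * float(_component(g_next.vdvt - g_t.vdvt, cfg.s_vd, cfg.clip))
        valid = True
    return r, valid


def terminal_reward(outcome, cfg: RewardConfig) -> float:
    """-R_death on death; else R_survive * destination multiplier - LOS cost."""
    if outcome.died:
        return -cfg.R_death
    dest = outcome.discharge_destination
    if dest not in cfg.dest_multiplier:
        raise ValueError(
            f"unknown destination {dest!r}; valid: {sorted(cfg.dest_multiplier)}")
    return cfg.R_survive * cfg.dest_multiplier[dest] - cfg.c_los * outcome.los_h


def trajectory_gas_series(traj: Trajectory) -> tuple[np.ndarray, np.ndarray,
                                                     np.ndarray, np.ndarray]:
    """Per-hour (pf, pf_valid, vdvt, vdvt_valid) from a trajectory's raw gas
    frame. Only strictly observed PaO2/PaCO2/ETCO2 yield valid values, so the
    reward never pays for imputation artefacts."""
    g = traj.gas
    fio2 = g["fio2_frac"].to_numpy()
    pao2 = g["pao2"].to_numpy()
    pf_valid = g["pao2_observed"].to_numpy() & np.isfinite(fio2) & (fio2 > 0)
    pf = np.where(pf_valid, pao2 / np.where(fio2 > 0, fio2, 1.0), np.nan)
    paco2 = g["paco2"].to_numpy()
    etco2 = g["etco2"].to_numpy()
    vd_valid = (g["paco2_observed"].to_numpy() & g["etco2_observed"].to_numpy()
                & (paco2 > 0))
    vdvt = np.where(vd_valid,
                    np.clip((paco2 - etco2) / np.where(paco2 > 0, paco2, 1.0), 0, 1),
                    np.nan)
    return pf, pf_valid, vdvt, vd_valid


def shape_trajectory_rewards(traj: Trajectory, cfg: RewardConfig,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-step rewards r_0..r_{T-1} and a per-step validity mask.

    r_t is the intermediate reward for the observed transition t -> t+1; the
    final step has no successor, so its intermediate component is 0 and it
    carries lambda * terminal_reward instead. The validity mask flags steps
    whose intermediate component had at least one computable delta (the final
    step is flagged valid via its terminal component).
    """
    T = traj.T
    pf, pf_v, vdvt, vd_v = trajectory_gas_series(traj)
    r = np.zeros(T)
    valid = np.zeros(T, dtype=bool)
    if T > 1:
        dpf = pf[1:] - pf[:-1]
        dvd = vdvt[1:] - vdvt[:-1]
        ok_pf = pf_v[1:] & pf_v[:-1]
        ok_vd = vd_v[1:] & vd_v[:-1]
        r[:-1] += np.where(ok_pf, cfg.w_pf * _component(np.nan_to_num(dpf), cfg.s_pf, cfg.clip), 0.0)
        r[:-1] -= np.where(ok_vd, cfg.w_vd * _component(np.nan_to_num(dvd), cfg.s_vd, cfg.clip), 0.0)
        valid[:-1] = ok_pf | ok_vd
    r[-1] += cfg.lambda_ * terminal_reward(traj.outcome, cfg)
    valid[-1] = True
    return r, valid


def shape_cohort(trajectories, cfg: RewardConfig) -> list[np.ndarray]:
    """Reward sequences for a whole cohort under one reward version."""
    return [shape_trajectory_rewards(t, cfg)[0] for t in trajectories]
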