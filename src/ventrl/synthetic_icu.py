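"""Seeded stochastic simulator of ventilated COVID-ARDS-like ICU admissions.

Every admission carries a scalar latent severity z_t following an AR(1)
process that treatment modulates: PEEP near a patient-independent optimum
accelerates recovery, mistuned PEEP (quadratic penalty) and non-ventilation
of a severe patient slow it. Observables are noisy functions of severity and
the current settings — the P/F ratio falls with severity and with squared
PEEP mistuning, dead-space fraction rises with severity and with PEEP above
the optimum — and are masked at configurable missingness rates to exercise
carry-forward imputation downstream. Physicians pick PEEP/FiO2 bins by
softmax over a utility that matches ventilatory support to severity and
strongly favours staying within one grid step of the previous action, which
concentrates the empirical action-transition density near the diagonal.
A per-step death hazard is logistic in severity; the hazard intercept is
calibrated (deterministically, via pilot-cohort bisection) so the cohort
mortality matches a configurable target, 24.4% by default. Survivors are
discharged once severity crosses a threshold, with a severity-dependent
discharge destination.

All dynamics here are synthetic fixtures chosen for qualitative shape
(inverted-U PEEP response, severity-driven hazard), not physiological
fidelity; they exist so the pipeline has a cohort with the right statistical
structure and a ground-truth value oracle for tests.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reward_engine import RewardConfig, terminal_reward
from .trajectory_builder import ActionGrid, Outcome

#: observation vector layout handed to external policies during rollouts
OBS_NAMES_BASE = ("peep", "fio2", "ventilated", "pao2", "paco2", "etco2")

#: representative settings per bin, used to generate raw event values
PEEP_CENTERS = (3.0, 8.0, 12.0, 16.0)
FIO2_CENTERS = (0.30, 0.50, 0.70, 0.90)   # fractions


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass(frozen=True)
class SimConfig:
    """All coefficients of the generative model; defaults define the cohort
    the test-suite and the worked examples use."""
    n_patients: int = 100
    max_horizon: int = 72            # hours; real stays are longer, kept short for speed
    n_aux_features: int = 16
    seed: int = 0

    # latent severity dynamics
    severity_ar_coef: float = 0.9    # AR(1) coefficient, in (0,1)
    sigma_z: float = 0.12
    z0_mean: float = 1.0
    z0_sd: float = 0.4
    recovery: float = 0.03           # per-step drift toward health when treated
    e_mistune: float = 0.012         # severity push per unit squared PEEP mistuning
    e_nv_severe: float = 0.05        # extra push when a severe patient is unventilated
    nv_severe_threshold: float = 0.3
    discharge_z: float = -0.15

    # PEEP dose-response (inverted U)
    peep_optimum_center: float = 10.0   # cmH2O
    peep_optimum_width: float = 4.0     # cmH2O

    # observables
    pf_base: float = 250.0           # mmHg
    k_z: float = 80.0                # P/F drop per unit severity
    k_peep: float = 1.2              # P/F drop per (cmH2O mistuning)^2
    k_fio2: float = 40.0             # short-term P/F lift per unit FiO2 above 0.21
    pf_noise: float = 18.0
    vd_c0: float = -1.2
    vd_c1: float = 0.8
    vd_c2: float = 0.08              # per cmH2O of PEEP above optimum
    vd_k_fio2: float = 0.0           # measured Vd/Vt drop per unit FiO2 above 0.21
    vd_noise: float = 0.03
    paco2_base: float = 40.0
    paco2_k: float = 6.0
    paco2_noise: float = 3.0
    aux_ar: float = 0.8
    aux_load: float = 0.3            # |coupling| of aux channels to severity
    aux_noise: float = 0.3

    # physician behaviour
    behavior_temperature: float = 0.35
    u_support: float = 6.0           # severity-support matching strength
    u_proximity: float = 2.5         # bonus for staying within one grid step
    support_base: float = 0.2
    support_slope: float = 0.4
    nv_support_level: float = -0.15

    # outcome model
    h1: float = 2.0                  # hazard slope on severity
    hazard_intercept: float | None = None   # logit; None => calibrate
    mortality_calibration: float = 0.244    # target cohort mortality fraction
    fio2_toxicity: float = 0.0       # extra hazard logit per unit FiO2 above threshold
    fio2_toxicity_threshold: float = 0.6
    fio2_toxicity_mode: str = "level"   # "level": hazard while high; "event":
                                        # hazard spike on raising FiO2 into/within
                                        # the toxic range (one-off exposure)

    # missingness (fraction of slots masked); settings are always recorded
    missingness_rates: dict = field(default_factory=lambda: {
        "pao2": 0.30, "paco2": 0.30, "etco2": 0.35, "aux": 0.20})

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0 < self.severity_ar_coef < 1:
            raise ValueError("severity_ar_coef must lie in (0, 1)")
        if any(not 0 <= r <= 1 for r in self.missingness_rates.values()):
            raise ValueError("missingness rates must lie in [0, 1]")
        if self.max_horizon < 1:
            raise ValueError("max_horizon must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def aux_names(self) -> list[str]:
        return [f"aux_{j:02d}" for j in range(self.n_aux_features)]


# ---------------------------------------------------------------------------
# behaviour utility
# ---------------------------------------------------------------------------

_GRID = ActionGrid()


def _support_levels(grid: ActionGrid, cfg: SimConfig) -> np.ndarray:
    s = np.empty(grid.n_actions)
    denom = (grid.n_peep - 1) + (grid.n_fio2 - 1)
    for a in range(grid.nv_index):
        ip, if2 = grid.coords(a)
        s[a] = (ip + if2) / max(denom, 1)
    s[grid.nv_index] = cfg.nv_support_level
    return s


def _proximity_matrix(grid: ActionGrid) -> np.ndarray:
    """adj[prev, a]: staying within one king step (NV adjacent only to NV,
    plus the low-support extubation corner -> NV)."""
    n = grid.n_actions
    adj = np.zeros((n, n), dtype=bool)
    for p in range(grid.nv_index):
        for a in range(grid.nv_index):
            adj[p, a] = grid.chebyshev(p, a) <= 1
    nv = grid.nv_index
    adj[nv, nv] = True
    for corner in ((0, 0), (0, 1)):
        adj[grid.index(*corner), nv] = True
    return adj


def _behaviour_logits(z: np.ndarray, prev: np.ndarray | None, cfg: SimConfig,
                      grid: ActionGrid, support: np.ndarray, adj: np.ndarray,
                      ) -> np.ndarray:
    """(n, n_actions) softmax logits of the physician policy."""
    target = np.clip(cfg.support_base + cfg.support_slope * z, -0.3, 1.0)
    util = -cfg.u_support * (support[None, :] - target[:, None]) ** 2
    if prev is not None:
        util = util + cfg.u_proximity * adj[prev]
    return util / cfg.behavior_temperature


# ---------------------------------------------------------------------------
# core engine
# ---------------------------------------------------------------------------

class _History:
    """Fixed-capacity per-cohort recording arrays."""

    def __init__(self, n, H, n_aux):
        self.T = np.zeros(n, dtype=int)
        self.action = np.full((n, H), -1, dtype=int)
        self.peep = np.full((n, H), np.nan)
        self.fio2 = np.full((n, H), np.nan)   # fraction
        self.vent = np.zeros((n, H), dtype=bool)
        self.pao2 = np.full((n, H), np.nan)
        self.paco2 = np.full((n, H), np.nan)
        self.etco2 = np.full((n, H), np.nan)
        self.pf = np.full((n, H), np.nan)
        self.vdvt = np.full((n, H), np.nan)
        self.aux = np.full((n, H, n_aux), np.nan)
        self.died = np.zeros(n, dtype=bool)
        self.dest = np.empty(n, dtype=object)


def _simulate(cfg: SimConfig, seed_seq, policy=None, h0: float | None = None,
              grid: ActionGrid = _GRID) -> _History:
    """Run the generative model for one cohort.

    policy=None uses the internal physician behaviour (vectorised). An
    external policy is a callable (obs_vector, prev_action) -> probability
    vector over the 17 actions, called per patient per step.
    """
    rng = np.random.default_rng(seed_seq)
    n, H = cfg.n_patients, cfg.max_horizon
    hist = _History(n, H, cfg.n_aux_features)
    if n == 0:
        return hist
    if h0 is None:
        h0 = cfg.hazard_intercept
        assert h0 is not None, "hazard intercept must be resolved before simulation"

    support = _support_levels(grid, cfg)
    adj = _proximity_matrix(grid)
    peep_val = np.array(PEEP_CENTERS + (0.0,))     # NV -> no PEEP
    fio2_val = np.array(FIO2_CENTERS + (0.21,))    # NV -> ambient air
    peep_by_action = np.array([peep_val[grid.coords(a)[0]] if a != grid.nv_index
                               else 0.0 for a in range(grid.n_actions)])
    fio2_by_action = np.array([fio2_val[grid.coords(a)[1]] if a != grid.nv_index
                               else 0.21 for a in range(grid.n_actions)])

    z = rng.normal(cfg.z0_mean, cfg.z0_sd, size=n)
    aux = rng.normal(0.0, cfg.aux_noise, size=(n, cfg.n_aux_features))
    aux_sign = np.array([cfg.aux_load if j % 2 == 0 else -cfg.aux_load
                         for j in range(cfg.n_aux_features)])
    active = np.ones(n, dtype=bool)
    prev = np.full(n, grid.nv_index, dtype=int)    # admissions begin unventilated
    # settings physiologically in effect during the past hour (gas exchange
    # responds to a setting change only at the next hourly measurement)
    applied_peep = np.zeros(n)
    applied_fio2 = np.full(n, 0.21)
    applied_vent = np.zeros(n, dtype=bool)
    first_step = True

    for t in range(H):
        # --- fixed-order random draws (shapes independent of activity) ---
        gumbel = rng.gumbel(size=(n, grid.n_actions))
        eps_pf = rng.normal(0.0, cfg.pf_noise, size=n)
        eps_vd = rng.normal(0.0, cfg.vd_noise, size=n)
        eps_pc = rng.normal(0.0, cfg.paco2_noise, size=n)
        eps_aux = rng.normal(0.0, cfg.aux_noise, size=(n, cfg.n_aux_features))
        eps_z = rng.normal(0.0, cfg.sigma_z, size=n)
        u_death = rng.random(size=n)

        # --- choose actions ---
        if policy is None:
            logits = _behaviour_logits(z, None if first_step else prev, cfg,
                                       grid, support, adj)
            act = np.argmax(logits + gumbel, axis=1)
        else:
            act = prev.copy()
            for i in np.flatnonzero(active):
                obs = _observation(hist, i, t, cfg)
                p = np.asarray(policy(obs, int(prev[i])), dtype=float)
                with np.errstate(divide="ignore"):
                    act[i] = int(np.argmax(np.log(np.maximum(p, 0.0)) + gumbel[i]))
        act = np.where(active, act, prev)

        peep = peep_by_action[act]
        fio2 = fio2_by_action[act]
        vent = act != grid.nv_index
        if first_step:
            # admission gas drawn under the initial orders
            applied_peep, applied_fio2, applied_vent = peep, fio2, vent

        # --- observables: gas exchange reflects the settings of the past
        # hour, so an action's response appears at the next measurement ---
        mistune = np.where(applied_vent,
                           ((applied_peep - cfg.peep_optimum_center)
                            / cfg.peep_optimum_width) ** 2,
                           ((0.0 - cfg.peep_optimum_center) / cfg.peep_optimum_width) ** 2)
        mistune = np.minimum(mistune, 8.0)
        pf = (cfg.pf_base - cfg.k_z * z
              - cfg.k_peep * (cfg.peep_optimum_width ** 2) * mistune
              * np.where(applied_vent, 1.0, 0.25)
              + cfg.k_fio2 * (applied_fio2 - 0.21) + eps_pf)
        pf = np.maximum(pf, 30.0)
        pao2 = pf * fio2
        paco2 = np.maximum(cfg.paco2_base + cfg.paco2_k * z + eps_pc, 15.0)
        peep_excess = np.where(applied_vent,
                               np.maximum(applied_peep - cfg.peep_optimum_center, 0.0),
                               0.0)
        vdvt = np.clip(_sigmoid(cfg.vd_c0 + cfg.vd_c1 * z + cfg.vd_c2 * peep_excess)
                       - cfg.vd_k_fio2 * (applied_fio2 - 0.21) + eps_vd, 0.0, 0.95)
        etco2 = paco2 * (1.0 - vdvt)
        aux = cfg.aux_ar * aux + aux_sign[None, :] * z[:, None] + eps_aux

        # --- record ---
        rec = active
        hist.action[rec, t] = act[rec]
        hist.peep[rec, t] = np.where(vent, peep, np.nan)[rec]
        hist.fio2[rec, t] = np.where(vent, fio2, np.nan)[rec]
        hist.vent[rec, t] = vent[rec]
        hist.pao2[rec, t] = pao2[rec]
        hist.paco2[rec, t] = paco2[rec]
        hist.etco2[rec, t] = etco2[rec]
        hist.pf[rec, t] = pf[rec]
        hist.vdvt[rec, t] = vdvt[rec]
        hist.aux[rec, t] = aux[rec]
        hist.T[rec] = t + 1

        # --- severity update ---
        push = cfg.e_mistune * (cfg.peep_optimum_width ** 2) * mistune / 16.0
        push = push + np.where(~vent & (z > cfg.nv_severe_threshold), cfg.e_nv_severe, 0.0)
        z_next = cfg.severity_ar_coef * z - cfg.recovery + push + eps_z

        # --- terminal events ---
        tox = cfg.fio2_toxicity * np.maximum(fio2 - cfg.fio2_toxicity_threshold, 0.0)
        if cfg.fio2_toxicity_mode == "event":
            tox = tox * (fio2 > applied_fio2 + 1e-9)
        p_death = _sigmoid(h0 + cfg.h1 * z_next + tox)
        dies = active & (u_death < p_death)
        discharges = active & ~dies & (z_next < cfg.discharge_z)
        if t == H - 1:
            discharges = active & ~dies

        hist.died[dies] = True
        for i in np.flatnonzero(dies):
            hist.dest[i] = "died"
        idx = np.flatnonzero(discharges)
        if idx.size:
            zf = z_next[idx]
            logits = np.column_stack([1.2 - 2.5 * zf,
                                      np.full(idx.size, 0.6),
                                      2.0 * zf])
            g = rng.gumbel(size=(idx.size, 3))
            choice = np.argmax(logits + g, axis=1)
            dests = np.array(["home", "rehab", "other_hospital"], dtype=object)
            for k, i in enumerate(idx):
                hist.dest[i] = dests[choice[k]]

        active = active & ~dies & ~discharges
        z = z_next
        prev = act
        applied_peep, applied_fio2, applied_vent = peep, fio2, vent
        first_step = False
        if not active.any():
            break

    return hist


def _observation(hist: _History, i: int, t: int, cfg: SimConfig) -> np.ndarray:
    """Observation vector handed to an external policy: the previous hour's
    settings and labs (zeros before the first recorded hour)."""
    if t == 0:
        base = np.zeros(len(OBS_NAMES_BASE))
        return np.concatenate([base, np.zeros(cfg.n_aux_features)])
    s = t - 1
    base = np.array([
        np.nan_to_num(hist.peep[i, s]),
        np.nan_to_num(hist.fio2[i, s] * 100.0 if np.isfinite(hist.fio2[i, s]) else 21.0),
        float(hist.vent[i, s]),
        hist.pao2[i, s], hist.paco2[i, s], hist.etco2[i, s],
    ])
    return np.concatenate([base, hist.aux[i, s]])


# ---------------------------------------------------------------------------
# hazard-intercept calibration
# ---------------------------------------------------------------------------

_PILOT_N = 2048
_PILOT_TAG = 0x5EED
_CALIBRATION_CACHE: dict = {}


def resolve_hazard_intercept(cfg: SimConfig) -> float:
    """The hazard intercept used for a config: the explicit value if given,
    else deterministic bisection on a pilot cohort so the simulated mortality
    hits ``mortality_calibration``.

    The pilot reuses one fixed random stream for every candidate intercept
    (common random numbers), which makes pilot mortality a monotone step
    function of the intercept and lets bisection land within the pilot's
    counting resolution. Results are cached per configuration."""
    if cfg.hazard_intercept is not None:
        return float(cfg.hazard_intercept)
    key = json.dumps({**cfg.to_dict(), "n_patients": None}, sort_keys=True)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    pilot = dataclasses.replace(cfg, n_patients=_PILOT_N)

    def mortality(h0):
        m = [float(np.mean(_simulate(
            pilot, np.random.SeedSequence([cfg.seed, _PILOT_TAG + j]), h0=h0).died))
            for j in (0, 1)]
        return float(np.mean(m))

    lo, hi = -12.0, -1.0
    for _ in range(16):
        mid = 0.5 * (lo + hi)
        if mortality(mid) < cfg.mortality_calibration:
            lo = mid
        else:
            hi = mid
    h0 = 0.5 * (lo + hi)
    _CALIBRATION_CACHE[key] = h0
    return h0


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _tables_from_history(cfg: SimConfig, hist: _History,
                         seed_seq) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format event table (with missingness masking) + outcomes table."""
    rng = np.random.default_rng(seed_seq)
    rows_pid, rows_t, rows_var, rows_val = [], [], [], []
    rates = cfg.missingness_rates
    aux_rate = rates.get("aux", 0.0)
    n = cfg.n_patients
    pids = [f"p{i:05d}" for i in range(n)]

    def emit(pid, t, var, val):
        rows_pid.append(pid)
        rows_t.append(t)
        rows_var.append(var)
        rows_val.append(val)

    for i in range(n):
        T = hist.T[i]
        keep_pao2 = rng.random(T) >= rates.get("pao2", 0.0)
        keep_paco2 = rng.random(T) >= rates.get("paco2", 0.0)
        keep_etco2 = rng.random(T) >= rates.get("etco2", 0.0)
        keep_aux = rng.random((T, cfg.n_aux_features)) >= aux_rate
        for t in range(T):
            emit(pids[i], t, "ventilated", float(hist.vent[i, t]))
            if hist.vent[i, t]:
                emit(pids[i], t, "peep", float(hist.peep[i, t]))
                emit(pids[i], t, "fio2", float(hist.fio2[i, t] * 100.0))
            if keep_pao2[t]:
                emit(pids[i], t, "pao2", float(hist.pao2[i, t]))
            if keep_paco2[t]:
                emit(pids[i], t, "paco2", float(hist.paco2[i, t]))
            if keep_etco2[t]:
                emit(pids[i], t, "etco2", float(hist.etco2[i, t]))
            for j in range(cfg.n_aux_features):
                if keep_aux[t, j]:
                    emit(pids[i], t, cfg.aux_names[j], float(hist.aux[i, t, j]))

    events = pd.DataFrame({"patient_id": rows_pid, "time_h": rows_t,
                           "variable": rows_var, "value": rows_val})
    outcomes = pd.DataFrame({
        "patient_id": pids,
        "died": hist.died[:n].astype(bool),
        "los_h": hist.T[:n].astype(float),
        "discharge_destination": [hist.dest[i] for i in range(n)],
    })
    if n == 0:
        events = pd.DataFrame(columns=["patient_id", "time_h", "variable", "value"])
        outcomes = pd.DataFrame(columns=["patient_id", "died", "los_h",
                                         "discharge_destination"])
    return events, outcomes


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort under the physician behaviour policy.

    Returns (event_table, outcomes_table). Identical configs (including seed)
    produce bit-identical tables.
    """
    h0 = resolve_hazard_intercept(config)
    hist = _simulate(config, np.random.SeedSequence([config.seed, 1]), h0=h0)
    return _tables_from_history(config, hist,
                                np.random.SeedSequence([config.seed, 2]))


def write_cohort(events: pd.DataFrame, outcomes: pd.DataFrame, out_dir,
                 config: SimConfig) -> None:
    """CSV tables plus a JSON sidecar echoing the full SimConfig."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events.to_csv(out / "events.csv", index=False)
    outcomes.to_csv(out / "outcomes.csv", index=False)
    with open(out / "sim_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)


def load_cohort(in_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    p = Path(in_dir)
    return pd.read_csv(p / "events.csv"), pd.read_csv(p / "outcomes.csv")


def _history_returns(cfg: SimConfig, hist: _History, reward_cfg: RewardConfig,
                     discount: float) -> np.ndarray:
    """Discounted return per patient from the simulator's internal series,
    using the same reward arithmetic the pipeline applies to logged data."""
    from .reward_engine import intermediate_reward_from_deltas
    n = cfg.n_patients
    out = np.zeros(n)
    for i in range(n):
        T = hist.T[i]
        r = np.zeros(T)
        if T > 1:
            dpf = hist.pf[i, 1:T] - hist.pf[i, :T - 1]
            dvd = hist.vdvt[i, 1:T] - hist.vdvt[i, :T - 1]
            r[:-1] = intermediate_reward_from_deltas(dpf, dvd, reward_cfg)
        outc = Outcome(bool(hist.died[i]), float(T), str(hist.dest[i]))
        r[-1] += reward_cfg.lambda_ * terminal_reward(outc, reward_cfg)
        out[i] = float(np.sum(r * discount ** np.arange(T)))
    return out


def ground_truth_value(config: SimConfig, policy=None, discount: float = 0.99,
                       n_rollouts: int = 200, seed: int = 0,
                       reward_config: RewardConfig | None = None,
                       ) -> tuple[float, float]:
    """On-policy Monte-Carlo estimate of expected discounted return.

    policy=None rolls out the physician behaviour itself. Returns
    (estimate, standard_error). Used as the oracle when validating off-policy
    estimates on the simulator.
    """
    if n_rollouts < 2:
        raise ValueError("n_rollouts must be >= 2 for a standard error")
    reward_config = reward_config or RewardConfig()
    cfg = dataclasses.replace(config, n_patients=n_rollouts)
    h0 = resolve_hazard_intercept(config)
    hist = _simulate(cfg, np.random.SeedSequence([seed, 3]), policy=policy, h0=h0)
    returns = _history_returns(cfg, hist, reward_config, discount)
    return float(np.mean(returns)), float(np.std(returns, ddof=1) / np.sqrt(n_rollouts))


def conflict_config(n_patients: int = 1000, seed: int = 17) -> SimConfig:
    """A stress-test configuration in which chasing short-term gas-exchange
    gains conflicts with terminal mortality.

    Raising FiO2 immediately lifts the measured P/F ratio (large k_fio2) and
    transiently lowers measured dead-space (vd_k_fio2 > 0), so FiO2
    escalation pays intermediate reward; but FiO2 above 50% carries a steep
    per-hour death hazard (oxygen-toxicity term). Simulated physicians are
    deliberately conservative here (low support target, low temperature), so
    the logged behaviour is comparatively safe and a policy that escalates
    into the toxic range looks good only under intermediate-dominated reward
    weightings. Short stays (12 h) keep importance ratios usable. Used by the
    reward-shaping robustness (cross-OPE discrimination) experiment.
    """
    return SimConfig(
        n_patients=n_patients, max_horizon=12, seed=seed, n_aux_features=2,
        k_fio2=250.0, fio2_toxicity=14.0, fio2_toxicity_threshold=0.5,
        fio2_toxicity_mode="level", vd_k_fio2=0.25,
        h1=1.0, k_z=40.0, pf_noise=4.0, k_peep=0.3,
        hazard_intercept=-5.0, behavior_temperature=0.35,
        support_base=0.05, support_slope=0.2,
        z0_mean=0.8, discharge_z=-0.05,
        missingness_rates={"pao2": 0.0, "paco2": 0.0, "etco2": 0.0, "aux": 0.0})


def action_transition_concentration(event_table: pd.DataFrame,
                                    grid: ActionGrid = _GRID) -> float:
    """Fraction of consecutive physician action pairs that stay put or move
    at most one king step on the grid (NV->NV counts as staying; a switch
    between NV and a ventilated bin counts as a jump)."""
    from .trajectory_builder import bin_action
    wide = (event_table[event_table["variable"].isin(["peep", "fio2", "ventilated"])]
            .pivot_table(index=["patient_id", "time_h"], columns="variable",
                         values="value", aggfunc="last"))
    close = total = 0
    for pid, sub in wide.groupby(level=0, sort=True):
        sub = sub.sort_index()
        acts = []
        for _, row in sub.iterrows():
            vent = bool(row.get("ventilated", 0.0) == 1.0)
            acts.append(bin_action(row.get("peep", np.nan), row.get("fio2", np.nan),
                                   vent, grid))
        for a, b in zip(acts[:-1], acts[1:]):
            total += 1
            if a == b == grid.nv_index:
                close += 1
            elif grid.is_ventilated(a) and grid.is_ventilated(b):
                close += grid.chebyshev(a, b) <= 1
    return close / total if total else float("nan")
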