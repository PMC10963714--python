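"""Turn long-format ICU event tables into hourly, imputed, fixed-schema trajectories.

The MDP substrate of the pipeline: states are z-scored feature vectors on an
hourly grid, actions are indices on the PEEP x FiO2 lattice (plus the single
non-ventilated action), and each trajectory ends in a terminal outcome
(mortality, ICU length of stay, discharge destination).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# status codes for hourly slots
OBSERVED = 0
IMPUTED = 1
MISSING = 2

DESTINATIONS = ("home", "rehab", "other_hospital", "died")


# ---------------------------------------------------------------------------
# Action grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActionGrid:
    """PEEP x FiO2 bin lattice plus one non-ventilated (NV) action.

    The default clinical grid is 4 PEEP bins ([0,6), [6,10), [10,14), [14,inf))
    by 4 FiO2 bins ([21,40), [40,60), [60,80), [80,100]) for 17 actions total.
    Bins are left-closed/right-open with the last bin closed, so the bins
    partition the quarter-plane. Ventilated action index = i_peep * n_fio2 +
    i_fio2; NV is the last index. Reduced grids (e.g. 2x2+NV for toy MDPs) are
    supported by passing shorter edge sequences.
    """

    peep_edges: tuple = (0.0, 6.0, 10.0, 14.0, np.inf)
    fio2_edges: tuple = (21.0, 40.0, 60.0, 80.0, 100.0)

    def __post_init__(self):
        pe, fe = np.asarray(self.peep_edges), np.asarray(self.fio2_edges)
        if not (np.all(np.diff(pe) > 0) and np.all(np.diff(fe) > 0)):
            raise ValueError("bin edges must be strictly increasing")
        if len(pe) < 2 or len(fe) < 2:
            raise ValueError("need at least one bin per axis")

    @property
    def n_peep(self) -> int:
        return len(self.peep_edges) - 1

    @property
    def n_fio2(self) -> int:
        return len(self.fio2_edges) - 1

    @property
    def nv_index(self) -> int:
        return self.n_peep * self.n_fio2

    @property
    def n_actions(self) -> int:
        return self.n_peep * self.n_fio2 + 1

    def index(self, i_peep: int, i_fio2: int) -> int:
        if not (0 <= i_peep < self.n_peep and 0 <= i_fio2 < self.n_fio2):
            raise ValueError(f"coordinates ({i_peep}, {i_fio2}) off the grid")
        return i_peep * self.n_fio2 + i_fio2

    def coords(self, action: int) -> tuple[int, int]:
        """Ordinal (i_peep, i_fio2) of a ventilated action; NV has no coords."""
        if action == self.nv_index:
            raise ValueError("NV action has no grid coordinates")
        if not 0 <= action < self.nv_index:
            raise ValueError(f"invalid action index {action}")
        return divmod(action, self.n_fio2)

    def is_ventilated(self, action: int) -> bool:
        return 0 <= action < self.nv_index

    def label(self, action: int) -> str:
        if action == self.nv_index:
            return "NV"
        ip, if2 = self.coords(action)
        pe, fe = self.peep_edges, self.fio2_edges
        hi = "+" if np.isinf(pe[ip + 1]) else f"-{pe[ip + 1]:g}"
        return f"PEEP {pe[ip]:g}{hi} / FiO2 {fe[if2]:g}-{fe[if2 + 1]:g}%"

    def labels(self) -> list[str]:
        return [self.label(a) for a in range(self.n_actions)]

    def chebyshev(self, a: int, b: int) -> int:
        """Chebyshev distance between two ventilated actions on the lattice."""
        (pa, fa), (pb, fb) = self.coords(a), self.coords(b)
        return max(abs(pa - pb), abs(fa - fb))

    def to_dict(self) -> dict:
        return {
            "peep_edges": [None if np.isinf(e) else float(e) for e in self.peep_edges],
            "fio2_edges": [float(e) for e in self.fio2_edges],
            "nv_index": self.nv_index,
            "bin_convention": "left-closed/right-open, last bin closed",
        }


def bin_action(peep: float, fio2: float, invasively_ventilated: bool,
               grid: ActionGrid | None = None) -> int:
    """Map raw ventilator settings to an action index on the grid.

    Not ventilated maps to NV regardless of the other inputs. PEEP below 0 is
    clipped to 0; FiO2 given as a fraction (<= 1.0) is rescaled to percent.
    Ventilated FiO2 outside [21, 100]% raises (a data-cleaning flag).
    """
    grid = grid or ActionGrid()
    if not invasively_ventilated:
        return grid.nv_index
    if peep is None or fio2 is None or np.isnan(peep) or np.isnan(fio2):
        raise ValueError("ventilated rows require PEEP and FiO2")
    peep = max(float(peep), 0.0)
    fio2 = float(fio2)
    if fio2 <= 1.0:
        fio2 *= 100.0  # fraction dialect
    if not (grid.fio2_edges[0] <= fio2 <= grid.fio2_edges[-1]):
        raise ValueError(
            f"FiO2 {fio2:g}% outside [{grid.fio2_edges[0]:g}, "
            f"{grid.fio2_edges[-1]:g}]% for a ventilated row")
    i_peep = int(np.searchsorted(grid.peep_edges, peep, side="right") - 1)
    i_peep = min(max(i_peep, 0), grid.n_peep - 1)
    i_fio2 = int(np.searchsorted(grid.fio2_edges, fio2, side="right") - 1)
    i_fio2 = min(max(i_fio2, 0), grid.n_fio2 - 1)
    return grid.index(i_peep, i_fio2)


# ---------------------------------------------------------------------------
# Feature schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """One state-space variable and how to impute/aggregate/normalise it."""
    name: str
    unit: str = ""
    carry_forward_limit: float = 8.0   # hours; np.inf for settings
    windows: tuple = ()                # trailing aggregation windows, hours
    ops: tuple = ("last",)             # subset of {last, mean, min, max}
    normalization: str = "zscore"      # zscore | none

    def __post_init__(self):
        if self.carry_forward_limit <= 0:
            raise ValueError(f"{self.name}: carry_forward_limit must be > 0")
        bad = set(self.ops) - {"last", "mean", "min", "max"}
        if bad:
            raise ValueError(f"{self.name}: unknown aggregation ops {bad}")
        if set(self.windows) - {4, 6, 24}:
            raise ValueError(f"{self.name}: windows must be within {{4, 6, 24}} h")
        if self.normalization not in ("zscore", "none"):
            raise ValueError(f"{self.name}: unknown normalization")


@dataclass(frozen=True)
class FeatureSchema:
    features: tuple

    def __post_init__(self):
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def variable_names(self) -> list[str]:
        return [f.name for f in self.features]

    def column_names(self) -> list[str]:
        """Names of the produced state-vector columns, in order."""
        cols = []
        for f in self.features:
            if "last" in f.ops:
                cols.append(f.name)
            for op in f.ops:
                if op == "last":
                    continue
                for w in f.windows:
                    cols.append(f"{f.name}_{op}{w}h")
        return cols

    def to_dict(self) -> dict:
        return {"features": [dataclasses.asdict(f) for f in self.features]}


def default_schema(aux_names: Sequence[str] = ()) -> FeatureSchema:
    """Schema matching the synthetic cohort's variables.

    Ventilator settings carry forward indefinitely within a trajectory; blood
    gas values up to 8 h; auxiliary vitals-like channels up to 4 h.
    """
    feats = [
        FeatureSpec("peep", "cmH2O", np.inf),
        FeatureSpec("fio2", "%", np.inf),
        FeatureSpec("ventilated", "flag", np.inf, normalization="none"),
        FeatureSpec("pao2", "mmHg", 8.0, windows=(6,), ops=("last", "mean")),
        FeatureSpec("paco2", "mmHg", 8.0),
        FeatureSpec("etco2", "mmHg", 8.0),
    ]
    feats += [FeatureSpec(n, "", 4.0) for n in aux_names]
    return FeatureSchema(tuple(feats))


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def carry_forward_impute(times: np.ndarray, values: np.ndarray, limit: float,
                         t_start: int | None = None, t_end: int | None = None,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Carry-forward a sparse timestamped series onto an hourly grid.

    Observations are bucketed to hour floor(t); a slot with an observation in
    its own hour is OBSERVED (last value wins), otherwise the most recent
    earlier value no older than `limit` hours is carried (IMPUTED), otherwise
    the slot is MISSING (NaN). Returns (values, status) over hours
    t_start..t_end inclusive (default: span of the data).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("timestamps must be sorted ascending")
    if times.size == 0:
        if t_start is None or t_end is None:
            return np.empty(0), np.empty(0, dtype=np.int8)
        n = t_end - t_start + 1
        return np.full(n, np.nan), np.full(n, MISSING, dtype=np.int8)

    obs_hours = np.floor(times).astype(int)
    if t_start is None:
        t_start = int(obs_hours[0])
    if t_end is None:
        t_end = int(obs_hours[-1])
    hours = np.arange(t_start, t_end + 1)
    out = np.full(hours.size, np.nan)
    status = np.full(hours.size, MISSING, dtype=np.int8)

    # last observation bucket at or before each hour
    idx = np.searchsorted(obs_hours, hours, side="right") - 1
    has = idx >= 0
    age = np.where(has, hours - np.where(has, obs_hours[np.maximum(idx, 0)], 0), np.inf)
    take = has & (age <= limit)
    out[take] = values[np.maximum(idx, 0)][take]
    status[take & (age == 0)] = OBSERVED
    status[take & (age > 0)] = IMPUTED
    return out, status


def _trailing_agg(x: np.ndarray, window: int, op: str) -> np.ndarray:
    """Trailing-window aggregate of an hourly series, NaN-aware."""
    s = pd.Series(x)
    r = s.rolling(window=window, min_periods=1)
    return getattr(r, op)().to_numpy()


# ---------------------------------------------------------------------------
# Trajectory container
# ---------------------------------------------------------------------------

@dataclass
class Outcome:
    died: bool
    los_h: float
    discharge_destination: str

    def __post_init__(self):
        if self.discharge_destination not in DESTINATIONS:
            raise ValueError(
                f"unknown destination {self.discharge_destination!r}; "
                f"valid: {DESTINATIONS}")


@dataclass
class Trajectory:
    """One ICU admission: hourly states, binned actions, terminal outcome."""
    patient_id: str
    states: np.ndarray            # (T, F), NaN-free once normalised
    actions: np.ndarray           # (T,) ActionGrid indices
    feature_names: list
    status: np.ndarray            # (T, F) OBSERVED/IMPUTED/MISSING per base column
    gas: pd.DataFrame             # raw pao2, fio2_frac, paco2, etco2 + observed flags
    outcome: Outcome
    missing_fraction: float = 0.0  # pre-imputation, over base variables
    t0: int = 0

    @property
    def T(self) -> int:
        return len(self.actions)

    def __post_init__(self):
        if self.T < 1 or len(self.states) != self.T:
            raise ValueError("states and actions must align with T >= 1")


@dataclass
class NormalizationStats:
    """Per-column means/scales frozen on the training split."""
    columns: list
    mean: np.ndarray
    std: np.ndarray     # guarded to 1 where degenerate
    zscore: np.ndarray  # bool per column

    def to_dict(self) -> dict:
        return {"columns": list(self.columns), "mean": self.mean.tolist(),
                "std": self.std.tolist(), "zscore": self.zscore.tolist()}


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------

def _build_one(pid, ev: pd.DataFrame, out_row, schema: FeatureSchema,
               grid: ActionGrid) -> Trajectory:
    t0 = int(np.floor(ev["time_h"].min()))
    t1 = int(np.floor(ev["time_h"].max()))
    n = t1 - t0 + 1

    series, statuses = {}, {}
    for f in schema.features:
        sub = ev[ev["variable"] == f.name]
        vals, st = carry_forward_impute(
            sub["time_h"].to_numpy(), sub["value"].to_numpy(),
            f.carry_forward_limit, t0, t1)
        series[f.name] = vals
        statuses[f.name] = st

    # ventilator settings for action binning: carry forward without limit
    setting = {}
    for name in ("peep", "fio2", "ventilated"):
        sub = ev[ev["variable"] == name]
        vals, _ = carry_forward_impute(
            sub["time_h"].to_numpy(), sub["value"].to_numpy(), np.inf, t0, t1)
        setting[name] = vals

    actions = np.empty(n, dtype=np.int64)
    for t in range(n):
        vent = bool(setting["ventilated"][t] == 1.0) if np.isfinite(
            setting["ventilated"][t]) else False
        vent = vent and np.isfinite(setting["peep"][t]) and np.isfinite(setting["fio2"][t])
        actions[t] = bin_action(setting["peep"][t], setting["fio2"][t], vent, grid)

    cols, mats = [], []
    base_status = []
    for f in schema.features:
        vals, st = series[f.name], statuses[f.name]
        base_status.append(st)
        if "last" in f.ops:
            cols.append(f.name)
            mats.append(vals)
        for op in f.ops:
            if op == "last":
                continue
            for w in f.windows:
                cols.append(f"{f.name}_{op}{w}h")
                mats.append(_trailing_agg(vals, int(w), op))
    states = np.column_stack(mats) if mats else np.empty((n, 0))
    status = np.column_stack(base_status) if base_status else np.empty((n, 0), dtype=np.int8)

    # raw gas-exchange frame for the reward engine: only strictly observed
    # values count (carried-forward gas would reward imputation artefacts)
    def _obs(name):
        if name in series:
            v = series[name].copy()
            o = statuses[name] == OBSERVED
        else:
            v, o = np.full(n, np.nan), np.zeros(n, dtype=bool)
        return v, o

    pao2, pao2_obs = _obs("pao2")
    paco2, paco2_obs = _obs("paco2")
    etco2, etco2_obs = _obs("etco2")
    fio2_frac = np.where(np.isfinite(setting["fio2"]), setting["fio2"] / 100.0, np.nan)
    # NV hours breathe ambient air
    nv = actions == grid.nv_index
    fio2_frac = np.where(nv, 0.21, fio2_frac)
    gas = pd.DataFrame({
        "pao2": pao2, "fio2_frac": fio2_frac, "paco2": paco2, "etco2": etco2,
        "pao2_observed": pao2_obs, "paco2_observed": paco2_obs,
        "etco2_observed": etco2_obs,
    })

    miss = float(np.mean(status == MISSING)) if status.size else 0.0
    outcome = Outcome(bool(out_row["died"]), float(out_row["los_h"]),
                      str(out_row["discharge_destination"]))
    return Trajectory(str(pid), states, actions, cols, status, gas, outcome,
                      missing_fraction=miss, t0=t0)


def build_trajectories(event_table: pd.DataFrame, outcomes_table: pd.DataFrame,
                       schema: FeatureSchema | None = None,
                       grid: ActionGrid | None = None) -> list[Trajectory]:
    """Build one raw (un-normalised) Trajectory per admission.

    The hourly grid runs from the first to the last event of each patient.
    Features are carry-forward imputed up to their per-variable limits, then
    window-aggregated. Normalisation is a separate, explicitly-fitted step
    (``fit_normalization`` on the training split, then ``normalize``).
    """
    grid = grid or ActionGrid()
    if schema is None:
        aux = sorted(v for v in event_table["variable"].unique() if v.startswith("aux_"))
        schema = default_schema(aux)
    ev_ids = set(event_table["patient_id"].unique())
    out_ids = set(outcomes_table["patient_id"].unique())
    missing = sorted(ev_ids - out_ids)
    if missing:
        raise ValueError(f"patients missing from outcomes table: {missing}")

    outcomes = outcomes_table.set_index("patient_id")
    trajs = []
    for pid, ev in event_table.groupby("patient_id", sort=True):
        trajs.append(_build_one(pid, ev, outcomes.loc[pid], schema, grid))
    return trajs


def fit_normalization(trajectories: Iterable[Trajectory],
                      schema: FeatureSchema | None = None) -> NormalizationStats:
    """Column means/stds over a (training) cohort; degenerate std guarded to 1."""
    trajs = list(trajectories)
    X = np.vstack([t.states for t in trajs])
    cols = trajs[0].feature_names
    mean = np.nanmean(X, axis=0)
    std = np.nanstd(X, axis=0)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    std = np.where(np.isfinite(std) & (std > 1e-12), std, 1.0)
    if schema is not None:
        zmap = {f.name: f.normalization == "zscore" for f in schema.features}
        # windowed columns (name_op4h) inherit the base variable's choice
        zs = np.array([zmap.get(c, zmap.get(c.rsplit("_", 1)[0], True)) for c in cols])
    else:
        zs = np.ones(len(cols), dtype=bool)
    return NormalizationStats(list(cols), mean, std, zs)


def normalize(trajectories: Iterable[Trajectory], stats: NormalizationStats,
              ) -> list[Trajectory]:
    """Apply frozen normalisation; remaining missing slots become the column
    mean (i.e. 0 after z-scoring), so states carry no NaN."""
    out = []
    for t in trajectories:
        X = t.states.astype(float).copy()
        X = np.where(np.isnan(X), stats.mean, X)
        Z = (X - stats.mean) / stats.std
        X = np.where(stats.zscore, Z, X)
        out.append(dataclasses.replace(t, states=X))
    return out


def exclude_low_quality(trajectories: Sequence[Trajectory],
                        max_missing_fraction: float,
                        ) -> tuple[list[Trajectory], dict]:
    """Drop admissions whose pre-imputation missing fraction exceeds the cap."""
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    kept, excluded = [], []
    for t in trajectories:
        (excluded if t.missing_fraction > max_missing_fraction else kept).append(t)
    report = {
        "n_input": len(trajectories),
        "n_kept": len(kept),
        "n_excluded": {"excessive_missingness": len(excluded)},
        "threshold": max_missing_fraction,
        "excluded_ids": [t.patient_id for t in excluded],
    }
    return kept, report


def split_train_test(trajectories: Sequence[Trajectory], train_fraction: float = 0.7,
                     seed: int = 0) -> tuple[list[Trajectory], list[Trajectory]]:
    """Patient-level disjoint split with a seeded shuffle (default 70/30)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(trajectories)
    if n < 2:
        raise ValueError("need at least 2 trajectories to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    train = [trajectories[i] for i in order[:n_train]]
    test = [trajectories[i] for i in order[n_train:]]
    return train, test


def save_manifest(path, schema: FeatureSchema, grid: ActionGrid,
                  stats: NormalizationStats, split: dict) -> None:
    with open(path, "w") as fh:
        json.dump({"schema": schema.to_dict(), "grid": grid.to_dict(),
                   "normalization": stats.to_dict(), "split": split}, fh, indent=2)


def save_trajectories(trajectories: Sequence[Trajectory], out_dir,
                      stats: NormalizationStats | None = None,
                      grid: ActionGrid | None = None,
                      split: dict | None = None) -> None:
    """Write a cohort to a columnar (parquet) file plus a JSON manifest.

    One wide row per (patient, hour): state columns, the binned action, and
    outcome fields; the manifest records the grid, normalisation statistics
    and split assignment needed to reproduce the representation.
    """
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for t in trajectories:
        df = pd.DataFrame(t.states, columns=t.feature_names)
        df.insert(0, "patient_id", t.patient_id)
        df.insert(1, "time_h", np.arange(t.t0, t.t0 + t.T))
        df["action"] = t.actions
        df["died"] = t.outcome.died
        df["los_h"] = t.outcome.los_h
        df["discharge_destination"] = t.outcome.discharge_destination
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_parquet(out / "trajectories.parquet")
    manifest = {
        "grid": (grid or ActionGrid()).to_dict(),
        "normalization": stats.to_dict() if stats else None,
        "split": split or {},
        "n_trajectories": len(trajectories),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
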