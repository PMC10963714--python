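"""Trajectory construction: imputation, action binning, normalisation,
exclusion and splitting."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ventrl
from ventrl.trajectory_builder import (IMPUTED, MISSING, OBSERVED, ActionGrid,
                                       FeatureSchema, FeatureSpec, bin_action,
                                       carry_forward_impute)


class TestCarryForward:
    def test_hand_traced_example(self):
        vals, st_ = carry_forward_impute([0, 3], [5.0, 7.0], limit=4, t_start=0,
                                         t_end=7)
        assert vals[:3].tolist() == [5.0, 5.0, 5.0]
        assert vals[3:].tolist() == [7.0, 7.0, 7.0, 7.0, 7.0]
        assert st_.tolist() == [OBSERVED, IMPUTED, IMPUTED, OBSERVED,
                                IMPUTED, IMPUTED, IMPUTED, IMPUTED]

    def test_limit_expires(self):
        vals, st_ = carry_forward_impute([0], [5.0], limit=2, t_start=0, t_end=5)
        assert vals[:3].tolist() == [5.0, 5.0, 5.0]
        assert np.isnan(vals[3:]).all()
        assert (st_[3:] == MISSING).all()

    def test_empty_series_all_missing(self):
        vals, st_ = carry_forward_impute([], [], limit=4, t_start=0, t_end=3)
        assert np.isnan(vals).all() and (st_ == MISSING).all()

    def test_infinite_limit_single_observation(self):
        vals, st_ = carry_forward_impute([0], [3.5], limit=np.inf, t_start=0,
                                         t_end=9)
        assert (vals == 3.5).all()

    def test_unsorted_raises(self):
        with pytest.raises(ValueError):
            carry_forward_impute([3, 1], [1.0, 2.0], limit=4)

    def test_never_overwrites_observed(self):
        """Slots with their own observation stay OBSERVED with that value,
        and observed + imputed + missing partition all slots."""
        times = [0, 1, 5, 9]
        values = [1.0, 2.0, 3.0, 4.0]
        vals, st_ = carry_forward_impute(times, values, limit=3)
        for t, v in zip(times, values):
            assert vals[t] == v and st_[t] == OBSERVED
        counts = {s: int((st_ == s).sum()) for s in (OBSERVED, IMPUTED, MISSING)}
        assert sum(counts.values()) == len(vals)


class TestBinAction:
    def test_mid_grid(self, grid):
        assert bin_action(8, 50, True) == grid.index(1, 1)   # PEEP 6-10, FiO2 40-60

    def test_not_ventilated_is_nv(self, grid):
        assert bin_action(8, 50, False) == grid.nv_index
        assert bin_action(np.nan, np.nan, False) == grid.nv_index

    def test_top_corner_boundary(self, grid):
        assert bin_action(14, 100, True) == grid.index(3, 3)

    def test_left_closed_edges(self, grid):
        assert bin_action(6, 40, True) == grid.index(1, 1)
        assert bin_action(5.999, 39.9, True) == grid.index(0, 0)

    def test_fraction_dialect_and_clipping(self, grid):
        assert bin_action(-2, 0.5, True) == grid.index(0, 1)

    def test_invalid_fio2_raises(self):
        with pytest.raises(ValueError):
            bin_action(8, 15, True)
        with pytest.raises(ValueError):
            bin_action(8, 130, True)

    @given(peep=st.floats(0, 40), fio2=st.floats(21, 100))
    @settings(max_examples=200, deadline=None)
    def test_partition_against_interval_oracle(self, peep, fio2):
        """Binning agrees with independent interval membership and tiles the
        quarter-plane: every valid input maps to exactly one action."""
        grid = ActionGrid()
        a = bin_action(peep, fio2, True, grid)
        ip, if2 = grid.coords(a)
        pe, fe = grid.peep_edges, grid.fio2_edges
        assert pe[ip] <= peep and (peep < pe[ip + 1] or np.isinf(pe[ip + 1]))
        assert fe[if2] <= fio2 and (fio2 < fe[if2 + 1] or
                                    (if2 == grid.n_fio2 - 1 and fio2 <= fe[-1]))


class TestActionGrid:
    def test_seventeen_actions_bijection(self, grid):
        assert grid.n_actions == 17
        seen = {grid.index(*grid.coords(a)) for a in range(grid.nv_index)}
        assert seen == set(range(16))

    def test_invalid_edges(self):
        with pytest.raises(ValueError):
            ActionGrid(peep_edges=(0, 0, 10, 14, np.inf))


class TestBuildTrajectories:
    def test_single_patient_three_hours(self, grid):
        ev = pd.DataFrame({
            "patient_id": ["a"] * 9,
            "time_h": [0, 0, 0, 1, 1, 1, 2, 2, 2],
            "variable": ["peep", "fio2", "ventilated"] * 3,
            "value": [8, 50, 1, 8, 50, 1, 10, 60, 1],
        })
        out = pd.DataFrame({"patient_id": ["a"], "died": [False],
                            "los_h": [3.0], "discharge_destination": ["home"]})
        schema = FeatureSchema((FeatureSpec("peep", carry_forward_limit=np.inf),
                                FeatureSpec("fio2", carry_forward_limit=np.inf)))
        trajs = ventrl.build_trajectories(ev, out, schema)
        assert len(trajs) == 1 and trajs[0].T == 3
        assert trajs[0].actions.tolist() == [grid.index(1, 1), grid.index(1, 1),
                                             grid.index(2, 2)]

    def test_missing_outcome_raises(self):
        ev = pd.DataFrame({"patient_id": ["a"], "time_h": [0],
                           "variable": ["ventilated"], "value": [0.0]})
        out = pd.DataFrame({"patient_id": [], "died": [], "los_h": [],
                            "discharge_destination": []})
        with pytest.raises(ValueError, match="a"):
            ventrl.build_trajectories(ev, out)

    def test_constant_feature_normalises_to_zero(self, trajectories):
        """A zero-variance column z-scores to 0 (std guarded to 1)."""
        stats = ventrl.fit_normalization(trajectories)
        const_cols = np.flatnonzero(stats.std == 1.0)
        normed = ventrl.normalize(trajectories, stats)
        assert not any(np.isnan(t.states).any() for t in normed)
        X = np.vstack([t.states for t in normed])
        zcols = np.flatnonzero(stats.zscore)
        assert np.allclose(X[:, zcols].mean(axis=0), 0, atol=0.35)

    def test_imputed_fraction_matches_missingness(self):
        """With Bernoulli(m) missingness and carry-forward limit L, the
        expected non-observed fraction of hourly slots is m and the expected
        missing-after-imputation fraction approaches m^(L+1); check the
        observed-slot rate against its closed form within 0.02."""
        m = 0.3
        cfg = ventrl.SimConfig(n_patients=120, max_horizon=48, seed=21,
                               hazard_intercept=-5.34, n_aux_features=0,
                               missingness_rates={"pao2": m, "paco2": 0.0,
                                                  "etco2": 0.0})
        events, outcomes = ventrl.simulate_cohort(cfg)
        trajs = ventrl.build_trajectories(events, outcomes)
        # status columns follow the schema's base variables; pao2 is the 4th
        statuses = np.concatenate([t.status[:, 3] for t in trajs])
        observed_rate = float((statuses == OBSERVED).mean())
        assert abs(observed_rate - (1 - m)) < 0.02

    def test_idempotent_given_stats(self, trajectories):
        stats = ventrl.fit_normalization(trajectories)
        n1 = ventrl.normalize(trajectories, stats)
        n2 = ventrl.normalize(n1, ventrl.fit_normalization(trajectories))
        # normalising already-normalised data with its own fresh stats keeps
        # shapes and finiteness; applying the same frozen stats twice to raw
        # data gives identical output
        n3 = ventrl.normalize(trajectories, stats)
        for a, b in zip(n1, n3):
            np.testing.assert_array_equal(a.states, b.states)


class TestExcludeAndSplit:
    def test_threshold_one_keeps_all(self, trajectories):
        kept, report = ventrl.exclude_low_quality(trajectories, 1.0)
        assert len(kept) == len(trajectories)
        assert report["n_excluded"]["excessive_missingness"] == 0

    def test_threshold_zero_drops_any_missingness(self, trajectories):
        kept, report = ventrl.exclude_low_quality(trajectories, 0.0)
        assert all(t.missing_fraction == 0.0 for t in kept)
        assert report["n_kept"] + report["n_excluded"]["excessive_missingness"] \
            == report["n_input"]

    def test_exclusion_matches_brute_force(self, trajectories):
        thr = float(np.median([t.missing_fraction for t in trajectories]))
        kept, report = ventrl.exclude_low_quality(trajectories, thr)
        expected = {t.patient_id for t in trajectories if t.missing_fraction > thr}
        assert set(report["excluded_ids"]) == expected

    def test_split_sizes_70_30(self, trajectories):
        ten = trajectories[:10]
        train, test = ventrl.split_train_test(ten, 0.7, seed=1)
        assert (len(train), len(test)) == (7, 3)

    def test_split_deterministic_and_partition(self, trajectories):
        t1, s1 = ventrl.split_train_test(trajectories, 0.7, seed=9)
        t2, s2 = ventrl.split_train_test(trajectories, 0.7, seed=9)
        ids = lambda ts: [t.patient_id for t in ts]
        assert ids(t1) == ids(t2) and ids(s1) == ids(s2)
        union = set(ids(t1)) | set(ids(s1))
        assert union == {t.patient_id for t in trajectories}
        assert not set(ids(t1)) & set(ids(s1))

    def test_split_too_small_raises(self, trajectories):
        with pytest.raises(ValueError):
            ventrl.split_train_test(trajectories[:1], 0.7, seed=0)


def test_save_trajectories_columnar_roundtrip(tmp_path, trajectories):
    import pandas as pd
    stats = ventrl.fit_normalization(trajectories)
    normed = ventrl.normalize(trajectories, stats)
    ventrl.trajectory_builder.save_trajectories(normed, tmp_path, stats=stats)
    df = pd.read_parquet(tmp_path / "trajectories.parquet")
    assert len(df) == sum(t.T for t in normed)
    assert set(normed[0].feature_names) <= set(df.columns)
    assert (tmp_path / "manifest.json").exists()
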