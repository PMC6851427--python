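import numpy as np
import pandas as pd
import pytest

import refeval as rv
from refeval.ranking import PRESET_WEIGHTS, composite_frame, pool_statistics, zscore_frame

NATIVE_WEIGHTS = rv.RankingWeights(
    "native", {"gdt_ha": 0.4, "rms_ca": 0.2, "sg": 0.2, "lddt": 0.2}
)


def table_from(records):
    return rv.MetricTable(pd.DataFrame(records))


def single_metric_table(values, metric="gdt_ha", target="T0"):
    return table_from(
        [
            {"target_id": target, "group_id": f"G{i:02d}", "model_index": 1, metric: v}
            for i, v in enumerate(values)
        ]
    )


class TestCaspZscores:
    def test_two_point_symmetry(self):
        table = single_metric_table([10.0, 20.0])
        z = rv.casp_zscores(table, "gdt_ha")
        assert sorted(z.tolist()) == pytest.approx([-1.0, 1.0])

    def test_degenerate_pool_is_zero(self):
        table = single_metric_table([50.0, 50.0, 50.0])
        assert rv.casp_zscores(table, "gdt_ha").tolist() == pytest.approx([0, 0, 0])

    def test_orientation_flips_lower_better_metrics(self):
        table = single_metric_table([1.0, 3.0], metric="rms_ca")
        z = rv.casp_zscores(table, "rms_ca")
        assert z.iloc[0] == pytest.approx(1.0)  # smaller RMSD is better
        assert z.iloc[1] == pytest.approx(-1.0)

    def test_two_pass_matches_hand_computation(self):
        """Literal spreadsheet-style recomputation on a fixed 8-value pool."""
        values = [60.0, 62.0, 58.0, 61.0, 59.0, 63.0, 57.0, 20.0]  # one extreme outlier
        table = single_metric_table(values)
        config = rv.ZScoreConfig()
        z = rv.casp_zscores(table, "gdt_ha", config)

        x = np.array(values)
        mean1, sd1 = x.mean(), x.std()
        z1 = (x - mean1) / sd1
        survivors = x[z1 >= -2.0]
        assert len(survivors) == 7  # the outlier is dropped
        mean2, sd2 = survivors.mean(), survivors.std()
        expected = np.maximum((x - mean2) / sd2, -2.0)
        assert z.to_numpy() == pytest.approx(expected)
        assert z.iloc[-1] == pytest.approx(-2.0)  # outlier lands on the floor

    def test_pool_mean_zero_sd_one_without_outlier_pass(self):
        values = [55.0, 40.0, 61.0, 48.0, 52.0, 44.0]
        table = single_metric_table(values)
        config = rv.ZScoreConfig(outlier_threshold=-np.inf, floor=-np.inf)
        z = rv.casp_zscores(table, "gdt_ha", config).to_numpy()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_small_pool_rejected(self):
        table = single_metric_table([10.0])
        with pytest.raises(ValueError, match="pool"):
            rv.casp_zscores(table, "gdt_ha")

    def test_sample_sd_mode(self):
        values = np.array([10.0, 20.0])
        _, sd = pool_statistics(values, rv.ZScoreConfig(sd_mode="sample"))
        assert sd == pytest.approx(np.std(values, ddof=1))


class TestCompositeScore:
    def test_unit_z_gives_one_for_every_preset(self):
        for preset in PRESET_WEIGHTS.values():
            z = {m: 1.0 for m in preset.weights}
            assert rv.composite_score(z, preset) == pytest.approx(1.0)

    def test_rms_ca_coefficient(self):
        z = {"rms_ca": 1.0, "gdt_ha": 0.0, "sg": 0.0, "qcs": 0.0, "mp": 0.0}
        assert rv.composite_score(z, PRESET_WEIGHTS["casp12"]) == pytest.approx(0.46)

    def test_tbm_gdt_plus_ase(self):
        z = {"gdt_ha": 1.0, "lddt": 0.0, "cadaa": 0.0, "sg": 0.0, "ase": 1.0}
        assert rv.composite_score(z, PRESET_WEIGHTS["tbm"]) == pytest.approx(2.0 / 3.0)

    def test_presets_sum_to_one(self):
        for preset in PRESET_WEIGHTS.values():
            assert sum(preset.weights.values()) == pytest.approx(1.0)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        w = PRESET_WEIGHTS["casp12"]
        z1 = {m: rng.normal() for m in w.weights}
        z2 = {m: rng.normal() for m in w.weights}
        for alpha in (0.0, 0.3, 1.0):
            mix = {m: alpha * z1[m] + (1 - alpha) * z2[m] for m in w.weights}
            assert rv.composite_score(mix, w) == pytest.approx(
                alpha * rv.composite_score(z1, w) + (1 - alpha) * rv.composite_score(z2, w)
            )

    def test_strict_missing_raises(self):
        with pytest.raises(ValueError, match="missing"):
            rv.composite_score({"rms_ca": 1.0}, PRESET_WEIGHTS["casp12"])

    def test_renormalize_missing(self):
        z = {"gdt_ha": 1.0, "lddt": 1.0, "cadaa": 1.0, "sg": 1.0, "ase": np.nan}
        got = rv.composite_score(z, PRESET_WEIGHTS["tbm"], missing="renormalize")
        assert got == pytest.approx(1.0)

    def test_pool_min_substitution(self):
        z = {"gdt_ha": 0.0, "lddt": 0.0, "cadaa": 0.0, "sg": 0.0, "ase": np.nan}
        got = rv.composite_score(
            z, PRESET_WEIGHTS["tbm"], missing="pool_min", pool_min={"ase": -2.0}
        )
        assert got == pytest.approx(-2.0 / 3.0)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            rv.RankingWeights("bad", {"gdt_ha": 0.5, "sg": 0.2})


def three_group_table():
    """Single target, three groups with hand-checkable metric vectors."""
    return table_from(
        [
            {"target_id": "T0", "group_id": "GA", "model_index": 1,
             "gdt_ha": 70.0, "rms_ca": 1.0, "sg": 90.0, "lddt": 0.8},
            {"target_id": "T0", "group_id": "GB", "model_index": 1,
             "gdt_ha": 50.0, "rms_ca": 2.0, "sg": 70.0, "lddt": 0.6},
            {"target_id": "T0", "group_id": "GC", "model_index": 1,
             "gdt_ha": 30.0, "rms_ca": 3.0, "sg": 50.0, "lddt": 0.4},
        ]
    )


class TestRankGroups:
    def test_hand_computed_ordering(self):
        result = rv.rank_groups(three_group_table(), NATIVE_WEIGHTS)
        # GA dominates every metric; GC is dominated: z-vectors are
        # (+1.22..., 0, -1.22...) per metric so the composite order is GA, GB, GC
        assert result.table["group_id"].tolist() == ["GA", "GB", "GC"]
        expected_top = np.sqrt(1.5)  # z of the best of an even 3-point pool
        assert result.table["total"].iloc[0] == pytest.approx(expected_top, rel=1e-9)
        assert result.table["total"].iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_dominant_group_ranks_first(self):
        result = rv.rank_groups(three_group_table(), NATIVE_WEIGHTS)
        assert result.rank_of("GA") == 1

    def test_all_negative_scores_clamp_to_zero(self):
        result = rv.rank_groups(three_group_table(), NATIVE_WEIGHTS, mode="sum_positive")
        assert result.table.loc[result.table["group_id"] == "GC", "total"].iloc[0] == 0.0

    def test_mean_mode_keeps_negatives(self):
        result = rv.rank_groups(three_group_table(), NATIVE_WEIGHTS, mode="mean")
        assert result.table.loc[result.table["group_id"] == "GC", "total"].iloc[0] < 0

    def test_tie_break_lexicographic(self):
        table = table_from(
            [
                {"target_id": "T0", "group_id": g, "model_index": 1, "gdt_ha": 50.0}
                for g in ["GZ", "GA", "GM"]
            ]
        )
        w = rv.RankingWeights("gdt", {"gdt_ha": 1.0})
        result = rv.rank_groups(table, w)
        assert result.table["group_id"].tolist() == ["GA", "GM", "GZ"]


class TestNaiveBaseline:
    def test_everyone_resubmits_start_degenerate(self):
        # all groups identical to the start: every z is 0, baseline too
        rows = [
            {"target_id": "T0", "group_id": g, "model_index": 1,
             "gdt_ha": 55.0, "rms_ca": 2.0, "sg": 80.0, "lddt": 0.7}
            for g in ["GA", "GB", "GC"]
        ]
        start = pd.DataFrame(
            [{"target_id": "T0", "gdt_ha": 55.0, "rms_ca": 2.0, "sg": 80.0, "lddt": 0.7}]
        )
        res = rv.naive_baseline(table_from(rows), start, NATIVE_WEIGHTS)
        assert res.baseline_total == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.group_flags["total"], 0.0)
        assert res.n_beating == 0

    def test_start_strictly_worse_floors(self):
        table = three_group_table()
        start = pd.DataFrame(
            [{"target_id": "T0", "gdt_ha": 1.0, "rms_ca": 50.0, "sg": 1.0, "lddt": 0.01}]
        )
        res = rv.naive_baseline(table, start, NATIVE_WEIGHTS)
        # far below the pool on every oriented metric -> every z at the floor
        assert res.baseline_per_target.iloc[0] == pytest.approx(-2.0)

    def test_constructed_scenario_beat_count(self):
        """5 groups over 2 targets, exactly 2 constructed to beat the start."""
        rng = np.random.default_rng(0)
        rows, start_rows = [], []
        for tid in ["T0", "T1"]:
            start_val = 50.0
            start_rows.append({"target_id": tid, "gdt_ha": start_val})
            # two groups consistently above the start, three below
            for i, delta in enumerate([8.0, 5.0, -4.0, -6.0, -9.0]):
                rows.append(
                    {"target_id": tid, "group_id": f"G{i}", "model_index": 1,
                     "gdt_ha": start_val + delta + rng.normal(0, 0.1)}
                )
        w = rv.RankingWeights("gdt", {"gdt_ha": 1.0})
        res = rv.naive_baseline(table_from(rows), pd.DataFrame(start_rows), w)
        assert res.n_beating == 2
        flags = res.group_flags.set_index("group_id")["beats_baseline"]
        assert flags["G0"] and flags["G1"]
        assert not (flags["G2"] or flags["G3"] or flags["G4"])

    def test_missing_start_row_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            rv.naive_baseline(
                three_group_table(), pd.DataFrame([{"target_id": "TX", "gdt_ha": 1.0}]),
                rv.RankingWeights("gdt", {"gdt_ha": 1.0}),
            )

    def test_baseline_moves_only_through_pool_statistics(self):
        """Duplicating a group changes the baseline via the pool mean/SD only."""
        w = rv.RankingWeights("gdt", {"gdt_ha": 1.0})
        table = single_metric_table([70.0, 50.0, 30.0])
        start = pd.DataFrame([{"target_id": "T0", "gdt_ha": 40.0}])
        config = rv.ZScoreConfig()

        def literal_baseline(pool_values):
            mean, sd = pool_statistics(np.array(pool_values), config)
            return max((40.0 - mean) / sd, config.floor)

        base1 = rv.naive_baseline(table, start, w, mode="mean")
        assert base1.baseline_total == pytest.approx(literal_baseline([70, 50, 30]))
        # add a duplicate of the best group under a new id
        dup = table_from(
            [
                {"target_id": "T0", "group_id": g, "model_index": 1, "gdt_ha": v}
                for g, v in [("GA", 70.0), ("GB", 50.0), ("GC", 30.0), ("GD", 70.0)]
            ]
        )
        base2 = rv.naive_baseline(dup, start, w, mode="mean")
        assert base2.baseline_total == pytest.approx(literal_baseline([70, 50, 30, 70]))
        assert base2.baseline_total != pytest.approx(base1.baseline_total)


class TestFractionImproved:
    def make_tables(self):
        rows, start_rows = [], []
        better = {"GA": [True, True, True, False], "GB": [False, False, False, False]}
        for t, tid in enumerate(["T0", "T1", "T2", "T3"]):
            start_rows.append({"target_id": tid, "gdt_ha": 50.0})
            for gid in ("GA", "GB"):
                delta = 5.0 if better[gid][t] else (-5.0 if gid == "GB" else -3.0)
                rows.append({"target_id": tid, "group_id": gid, "model_index": 1,
                             "gdt_ha": 50.0 + delta})
        return table_from(rows), pd.DataFrame(start_rows)

    def test_identical_to_start_counts_zero(self):
        rows = [{"target_id": "T0", "group_id": g, "model_index": 1, "gdt_ha": 50.0}
                for g in ("GA", "GB")]
        start = pd.DataFrame([{"target_id": "T0", "gdt_ha": 50.0}])
        frac = rv.fraction_improved(table_from(rows), start, "gdt_ha")
        assert (frac == 0.0).all()  # ties are not improvements

    def test_three_of_four(self):
        table, start = self.make_tables()
        frac = rv.fraction_improved(table, start, "gdt_ha")
        assert frac["GA"] == pytest.approx(0.75)
        assert frac["GB"] == pytest.approx(0.0)

    def test_composite_spec_enumeration(self):
        """Composite-score comparison equals per-target boolean enumeration."""
        rng = np.random.default_rng(3)
        rows, start_rows = [], []
        for tid in [f"T{i}" for i in range(3)]:
            start_rows.append(
                {"target_id": tid, "gdt_ha": 50.0, "rms_ca": 2.0, "sg": 70.0, "lddt": 0.6}
            )
            for g in [f"G{i}" for i in range(5)]:
                rows.append(
                    {"target_id": tid, "group_id": g, "model_index": 1,
                     "gdt_ha": rng.uniform(35, 65), "rms_ca": rng.uniform(1, 4),
                     "sg": rng.uniform(50, 90), "lddt": rng.uniform(0.4, 0.8)}
                )
        table, start = table_from(rows), pd.DataFrame(start_rows)
        frac = rv.fraction_improved(table, start, NATIVE_WEIGHTS)
        # enumerate per target with the same z machinery
        zf = zscore_frame(table, list(NATIVE_WEIGHTS.weights))
        scores = composite_frame(zf, NATIVE_WEIGHTS)
        base = rv.naive_baseline(table, start, NATIVE_WEIGHTS)
        for g in [f"G{i}" for i in range(5)]:
            wins = sum(
                scores.loc[(scores.group_id == g) & (scores.target_id == tid), "score"].iloc[0]
                > base.baseline_per_target[tid]
                for tid in ["T0", "T1", "T2"]
            )
            assert frac[g] == pytest.approx(wins / 3)


class TestBestVsStart:
    def make(self):
        refined = table_from(
            [
                {"target_id": "T0", "group_id": "GA", "model_index": 1, "gdt_ts": 60.0},
                {"target_id": "T0", "group_id": "GB", "model_index": 1, "gdt_ts": 72.0},
                {"target_id": "T1", "group_id": "GA", "model_index": 1, "gdt_ts": 55.0},
                {"target_id": "T1", "group_id": "GB", "model_index": 1, "gdt_ts": 50.0},
            ]
        )
        initial = table_from(
            [
                {"target_id": "T0", "group_id": "S1", "model_index": 1, "gdt_ts": 65.0},
                {"target_id": "T1", "group_id": "S1", "model_index": 1, "gdt_ts": 58.0},
            ]
        )
        start = pd.DataFrame(
            [{"target_id": "T0", "gdt_ts": 55.0}, {"target_id": "T1", "gdt_ts": 48.0}]
        )
        return refined, initial, start

    def test_identical_tables_never_improved(self):
        refined, initial, start = self.make()
        res = rv.best_vs_start(refined, start, refined, "gdt_ts")
        assert not res["refined_better"].any()

    def test_triples_match_direct_max(self):
        refined, initial, start = self.make()
        res = rv.best_vs_start(refined, start, initial, "gdt_ts").set_index("target_id")
        assert res.loc["T0", "best_refined"] == 72.0
        assert res.loc["T0", "best_initial"] == 65.0
        assert bool(res.loc["T0", "refined_better"])
        assert res.loc["T1", "best_refined"] == 55.0
        assert not bool(res.loc["T1", "refined_better"])
        assert res.loc["T1", "start"] == 48.0


class TestTbmPrimeConsistency:
    def test_estimate_free_groups_keep_relative_order(self):
        """Dropping ASE (TBM -> TBM') never reorders two groups that both
        lack error estimates."""
        rng = np.random.default_rng(9)
        rows = []
        for tid in ["T0", "T1", "T2"]:
            for i in range(6):
                has_ase = i < 3  # groups G3..G5 provide no estimates
                rows.append(
                    {"target_id": tid, "group_id": f"G{i}", "model_index": 1,
                     "gdt_ha": rng.uniform(30, 70), "lddt": rng.uniform(0.4, 0.9),
                     "cadaa": rng.uniform(30, 70), "sg": rng.uniform(40, 90),
                     "ase": rng.uniform(60, 95) if has_ase else np.nan}
                )
        table = table_from(rows)
        tbm = rv.rank_groups(table, PRESET_WEIGHTS["tbm"], missing="pool_min", mode="mean")
        tbm_p = rv.rank_groups(table, PRESET_WEIGHTS["tbm_prime"], mode="mean")
        for a in ["G3", "G4", "G5"]:
            for b in ["G3", "G4", "G5"]:
                if a < b:
                    assert (tbm.rank_of(a) < tbm.rank_of(b)) == (
                        tbm_p.rank_of(a) < tbm_p.rank_of(b)
                    )
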