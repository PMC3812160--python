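"""Synthetic-data generator: determinism, anchors, truth tables, recovery hooks."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from seedage.simulate import (
    AgeingScenario,
    ArrayParams,
    QpcrParams,
    RedoxParams,
    GeneParams,
    gen_germination,
    gen_qpcr_curves,
    gen_redox_timecourse,
    gen_two_color_arrays,
    redox_truth,
)


def small_array_scenario(seed=3, **kw):
    defaults = dict(n_probes=300, n_blocks=4, de_fraction=0.05)
    defaults.update(kw)
    return AgeingScenario(seed=seed, array_params=ArrayParams(**defaults))


class TestDeterminism:
    def test_redox_bit_identical(self):
        a, _ = gen_redox_timecourse(AgeingScenario(seed=9))
        b, _ = gen_redox_timecourse(AgeingScenario(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_array_hash_identical(self):
        a, _ = gen_two_color_arrays(small_array_scenario())
        b, _ = gen_two_color_arrays(small_array_scenario())
        assert pd.util.hash_pandas_object(a).sum() == pd.util.hash_pandas_object(b).sum()

    def test_streams_differ_across_seeds(self):
        a, _ = gen_redox_timecourse(AgeingScenario(seed=1))
        b, _ = gen_redox_timecourse(AgeingScenario(seed=2))
        assert not a.equals(b)


class TestRedoxStream:
    def test_non_aged_anchors(self, scenario):
        truth = redox_truth(scenario)
        g0 = truth[(truth["couple"] == "GSSG/2GSH") & (truth["time_days"] == 0.0)].iloc[0]
        total = g0["thiol_umol_per_gDW"] + g0["disulphide_umol_per_gDW"]
        assert total == pytest.approx(1.9, rel=1e-9)
        assert g0["disulphide_umol_per_gDW"] / total == pytest.approx(0.11, rel=1e-9)

    def test_aged_anchors(self, scenario):
        truth = redox_truth(scenario)
        g = truth[truth["couple"] == "GSSG/2GSH"].sort_values("time_days").iloc[-1]
        total = g["thiol_umol_per_gDW"] + g["disulphide_umol_per_gDW"]
        assert total == pytest.approx(0.95, rel=1e-9)
        assert g["disulphide_umol_per_gDW"] / total == pytest.approx(0.37, rel=1e-9)

    def test_environment_negative_and_monotonically_less_negative(self, scenario):
        truth = redox_truth(scenario)
        env = truth.drop_duplicates("time_days").sort_values("time_days")[
            "redox_environment_mV_M"
        ].to_numpy()
        assert (env < 0).all()
        assert (np.diff(env) > 0).all()

    def test_zero_cv_gives_identical_replicates(self):
        sc = AgeingScenario(seed=4, redox_params=RedoxParams(replicate_cv=0.0))
        data, _ = gen_redox_timecourse(sc)
        spread = data.groupby(["time_days", "species"])["amount_umol_per_gDW"].nunique()
        assert (spread == 1).all()

    def test_replicate_count(self, scenario):
        data, _ = gen_redox_timecourse(scenario)
        counts = data.groupby(["time_days", "species"])["replicate"].nunique()
        assert (counts == scenario.redox_params.n_replicates).all()


class TestGerminationStream:
    def test_expected_tg_at_dose50(self):
        sc = AgeingScenario(seed=5)
        data, truth = gen_germination(sc, doses=[truth_d := sc.viability_params.dose50_mV])
        assert truth["p_germinate"][0] == pytest.approx(0.5)

    def test_high_viability_early_collapse_late(self, scenario):
        data, truth = gen_germination(scenario)
        by_dose = data.groupby("time_days").apply(
            lambda g: g["n_germinated"].sum() / g["n_tested"].sum(), include_groups=False
        )
        early = by_dose[by_dose.index <= 15]
        assert (early >= 0.9).all()
        assert by_dose[by_dose.index == 55.0].iloc[0] <= 0.15

    def test_steep_slope_gives_step(self):
        from seedage.simulate import ViabilityParams

        sc = AgeingScenario(seed=5, viability_params=ViabilityParams(slope_per_mV=-50.0))
        _, truth = gen_germination(sc, doses=[-190.0, -180.0])
        assert truth["p_germinate"][0] == pytest.approx(1.0, abs=1e-9)
        assert truth["p_germinate"][1] == pytest.approx(0.0, abs=1e-9)

    def test_end_to_end_dose50_recovery(self):
        from seedage.viability import GerminationRecord, dose_at_quantile, fit_probit

        covered = 0
        n_runs = 30
        doses = np.linspace(-200.0, -170.0, 8)
        for seed in range(n_runs):
            from seedage.simulate import ViabilityParams

            sc = AgeingScenario(
                seed=seed, viability_params=ViabilityParams(seeds_per_test=200, n_replicates=1)
            )
            data, truth = gen_germination(sc, doses=doses)
            recs = [
                GerminationRecord(r.dose, int(r.n_tested), int(r.n_germinated))
                for r in data.itertuples()
            ]
            m = fit_probit(recs)
            if not m.converged:
                continue
            z = dose_at_quantile(m, 0.5, level=0.95)
            if z.lower <= truth["dose50"] <= z.upper:
                covered += 1
        assert covered >= int(0.9 * n_runs) - 2


class TestQpcrStream:
    def test_fold_half_shifts_midpoint_by_one_cycle(self):
        qp = QpcrParams(
            genes={
                "REF": GeneParams(efficiency=2.0, base_c_half=21.0,
                                  fold_by_time={0.0: 1.0, 25.0: 1.0}, is_reference=True),
                "T": GeneParams(efficiency=2.0, base_c_half=24.0,
                                fold_by_time={0.0: 1.0, 25.0: 0.5}),
            },
            reference_gene="REF",
            time_points_days=(0.0, 25.0),
            noise_sigma=0.0,
        )
        _, truth = gen_qpcr_curves(AgeingScenario(seed=1, qpcr_params=qp))
        t = truth[truth["gene"] == "T"].set_index("time_days")
        assert t.loc[25.0, "true_c_half"] - t.loc[0.0, "true_c_half"] == pytest.approx(1.0)

    def test_unspiked_sample_has_no_reference_curve(self):
        # reference is emitted only for spiked samples by construction
        data, _ = gen_qpcr_curves(AgeingScenario(seed=2))
        ref = data[data["gene"] == "PBGD"]
        assert ref["spiked"].all()

    def test_curve_shape_matches_efficiency(self):
        data, truth = gen_qpcr_curves(AgeingScenario(seed=3))
        assert (truth["true_efficiency"] > 1.0).all()
        assert (truth["true_efficiency"] <= 2.0).all()

    def test_full_round_trip_recovers_fold_trajectory(self):
        from seedage.qpcr import (
            AmplificationCurve,
            estimate_efficiency_ct,
            expression_ratios_table,
            fit_amplification_sigmoid,
        )

        data, truth = gen_qpcr_curves(AgeingScenario(seed=17))
        rows = []
        for (sid, gene), grp in data.groupby(["sample_id", "gene"]):
            grp = grp.sort_values("cycle")
            cv = AmplificationCurve(sid, gene, grp["cycle"].to_numpy(float),
                                    grp["fluorescence"].to_numpy(float))
            ec = estimate_efficiency_ct(cv, fit_amplification_sigmoid(cv))
            rows.append({"gene": gene, "time_days": float(grp["time_days"].iloc[0]),
                         "replicate": grp["replicate"].iloc[0],
                         "efficiency": ec.efficiency, "ct": ec.ct})
        ratios = expression_ratios_table(pd.DataFrame(rows), "PBGD")
        mean_ratios = ratios.groupby(["gene", "time_days"])["ratio"].mean()
        for (gene, t), r in mean_ratios.items():
            true_fold = truth[(truth["gene"] == gene) & (truth["time_days"] == t)][
                "true_fold"
            ].iloc[0]
            assert r == pytest.approx(true_fold, rel=0.10)


class TestArrayStream:
    def test_structure(self):
        sc = small_array_scenario()
        data, truth = gen_two_color_arrays(sc)
        ap = sc.array_params
        assert len(data) == ap.n_probes * ap.spots_per_probe * ap.n_arrays * len(ap.time_points_days)
        assert set(data["spot_index"]) == {1, 2, 3}
        assert data["probe_id"].nunique() == ap.n_probes

    def test_truth_marks_de_fraction(self):
        sc = small_array_scenario(de_fraction=0.1)
        _, truth = gen_two_color_arrays(sc)
        frac = truth.groupby("time_days")["is_de"].mean()
        assert np.allclose(frac, 0.1, atol=0.01)
        mags = truth[truth["is_de"]]["true_log2_fc"].abs().unique()
        assert set(mags) <= {1.0, 1.5, 2.0}

    def test_null_bias_free_scenario_controls_false_calls(self):
        from seedage.arrays import average_replicate_spots, call_de, moderated_tests

        sc = small_array_scenario(seed=8, n_probes=800, de_fraction=0.0,
                                  block_bias_amplitude=0.0)
        data, _ = gen_two_color_arrays(sc)
        per_array = average_replicate_spots(data)
        res = moderated_tests(per_array)
        calls, _ = call_de(res)
        fp = (calls["passed_filter"]).mean()
        assert fp <= 0.02  # with all-null data essentially nothing passes q<0.05
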