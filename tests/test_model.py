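"""Modeling-table assembly, forest fitting, bias correction, importance."""

import numpy as np
import pandas as pd
import pytest

from toxpod.model import (
    EffectLevelForest,
    ModelingTable,
    assemble_table,
    block_availability,
    mtry_for,
)
from toxpod.study import InputError


class TestMtryRule:
    @pytest.mark.parametrize("p,expected", [(740, 246), (6, 2), (8, 2), (9, 3), (2, 1)])
    def test_one_third_rounded_down(self, p, expected):
        assert mtry_for(p) == expected


class TestAssembly:
    def test_baseline_tier_has_eight_covariates(self, small_effects):
        table = assemble_table(small_effects, "baseline")
        assert len(table.predictors) == 8
        assert len(table.frame) == len(small_effects)

    def test_benchmark_tier_appends_podmn(self, small_effects):
        table = assemble_table(small_effects, "benchmark")
        assert len(table.predictors) == 9
        assert table.predictors[-1] == "podmn"
        # podmn is the chemical mean over all of its studies
        chem = table.frame["chemical_id"].iloc[0]
        expected = small_effects.loc[
            small_effects.chemical_id == chem, "value_log10"
        ].mean()
        assert table.frame.loc[table.frame.chemical_id == chem, "podmn"].iloc[0] == pytest.approx(expected)

    def test_tier_membership_matches_set_intersection_oracle(self, small_effects, small_blocks):
        from toxpod.descriptors import concat_blocks, impute_median

        cont = {n: b for n, b in small_blocks.items() if n in ("physchem", "padel", "toxprint", "httk")}
        avail = block_availability(cont)
        combined = impute_median(concat_blocks(cont))
        for tier, needed in [("chem", ("physchem", "padel", "toxprint")),
                             ("chem_bio_kin", None)]:
            if needed is None:
                continue
            table = assemble_table(small_effects, tier, descriptors=combined, availability=avail)
            allowed = set.intersection(*(avail[b] for b in needed))
            expected_rows = small_effects.chemical_id.isin(allowed).sum()
            assert len(table.frame) == expected_rows
            assert set(table.frame.chemical_id) <= allowed

    def test_missing_block_named_in_error(self, small_effects):
        from toxpod.descriptors import DescriptorMatrix

        dummy = DescriptorMatrix(
            pd.DataFrame({"x": [1.0]}, index=["C00000"]), pd.Series("physchem", index=["x"])
        )
        with pytest.raises(InputError, match="padel"):
            assemble_table(small_effects, "chem", descriptors=dummy,
                           availability={"physchem": {"C00000"}})

    def test_unknown_tier_rejected(self, small_effects):
        with pytest.raises(InputError):
            assemble_table(small_effects, "super")


def toy_table(n=300, seed=0, signal=True):
    r = np.random.default_rng(seed)
    x1 = r.normal(size=n)
    x2 = r.normal(size=n)
    y = (2.0 * x1 if signal else 0.0) + r.normal(scale=0.3, size=n)
    frame = pd.DataFrame(
        {
            "study_id": [f"S{i}" for i in range(n)],
            "chemical_id": [f"C{i}" for i in range(n)],
            "value_log10": y,
            "x1": x1,
            "x2": x2,
        }
    )
    return ModelingTable(frame=frame, predictors=["x1", "x2"], tier="chem")


class TestForestFitting:
    def test_pure_signal_predictor_ranks_first(self):
        res = EffectLevelForest(toy_table()).fit(ntree=100, seed=0)
        assert res.importance.iloc[0]["descriptor"] == "x1"
        assert res.importance.iloc[0]["rank"] == 1

    def test_deterministic_given_seed(self):
        t = toy_table()
        r1 = EffectLevelForest(t).fit(ntree=50, seed=3)
        r2 = EffectLevelForest(t).fit(ntree=50, seed=3)
        np.testing.assert_array_equal(r1.predict(t.frame), r2.predict(t.frame))

    def test_constant_response_rejected(self):
        t = toy_table()
        t.frame["value_log10"] = 1.0
        with pytest.raises(InputError):
            EffectLevelForest(t)

    def test_training_beats_shuffled_response_control(self):
        t = toy_table(seed=1)
        res = EffectLevelForest(t).fit(ntree=100, seed=0)
        pred = res.predict(t.frame)
        rmse_fit = float(np.sqrt(np.mean((pred - t.response) ** 2)))
        shuffled = toy_table(seed=1)
        shuffled.frame["value_log10"] = (
            shuffled.frame["value_log10"].sample(frac=1, random_state=0).to_numpy()
        )
        res0 = EffectLevelForest(shuffled).fit(ntree=100, seed=0)
        pred0 = res0.predict(shuffled.frame)
        rmse_null = float(np.sqrt(np.mean((pred0 - t.response) ** 2)))
        assert rmse_fit < rmse_null

    def test_null_data_predicts_near_training_mean(self):
        t = toy_table(seed=2, signal=False)
        res = EffectLevelForest(t).fit(ntree=200, seed=0)
        pred = res.predict(t.frame.iloc[:50], bias_corrected=False)
        assert abs(pred.mean() - t.response.mean()) < 0.1

    def test_duplicated_row_identical_predictions(self):
        t = toy_table()
        res = EffectLevelForest(t).fit(ntree=50, seed=0)
        row = pd.concat([t.frame.iloc[[0]]] * 3, ignore_index=True)
        pred = res.predict(row)
        assert pred[0] == pred[1] == pred[2]

    def test_schema_mismatch_lists_missing_predictors(self):
        t = toy_table()
        res = EffectLevelForest(t).fit(ntree=10, seed=0)
        with pytest.raises(InputError, match="x2"):
            res.predict(t.frame.drop(columns=["x2"]))


class TestBiasCorrection:
    def test_identity_coefficients_change_nothing(self):
        t = toy_table()
        res = EffectLevelForest(t).fit(ntree=20, seed=0).set_bias(1.0, 0.0)
        np.testing.assert_allclose(res.bias_correct([1.0, 2.0, 3.0]), [1.0, 2.0, 3.0])

    def test_known_offset_applied(self):
        t = toy_table()
        res = EffectLevelForest(t).fit(ntree=20, seed=0).set_bias(1.0, 0.5)
        np.testing.assert_allclose(res.bias_correct([1.0, 2.0, 3.0]), [1.5, 2.5, 3.5])

    def test_coefficients_match_closed_form_ols(self, rng):
        # training predictions compressed by half around the mean:
        # observed = mean + 2*(pred - mean) -> slope 2 recovered
        from toxpod.model import _bias_coefficients

        obs = rng.normal(2.0, 1.0, size=500)
        pred = obs.mean() + 0.5 * (obs - obs.mean()) + 0.01 * rng.normal(size=500)
        slope, intercept = _bias_coefficients(obs, pred)
        cov = np.cov(pred, obs, ddof=0)
        slope_oracle = cov[0, 1] / cov[0, 0]
        intercept_oracle = obs.mean() - slope_oracle * pred.mean()
        assert slope == pytest.approx(slope_oracle, rel=1e-9)
        assert intercept == pytest.approx(intercept_oracle, rel=1e-9)
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_degenerate_predictions_fall_back_to_identity(self):
        from toxpod.model import _bias_coefficients

        with pytest.warns(UserWarning):
            slope, intercept = _bias_coefficients(np.array([1.0, 2.0]), np.array([1.0, 1.0]))
        assert (slope, intercept) == (1.0, 0.0)
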