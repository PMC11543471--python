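"""Dataset assembly, the split/tune/evaluate protocol and the IDAC ablation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from sfelip import profile_model as pm
from sfelip import synthetic_data as sd
from sfelip.io_core import ExtractionCondition, LipidRecord, RecoveryTable, ValidationError


def tiny_table(n_lipids=4, n_desc=29, abundances=None, with_idac=False, seed=0):
    rng = np.random.default_rng(seed)
    design = sd.default_design() if hasattr(sd, "default_design") else None
    from sfelip.io_core import default_design

    design = default_design()
    lipids = [
        LipidRecord(f"L{i}", f"S{i}", "glycerolipids") for i in range(n_lipids)
    ]
    if abundances is None:
        abundances = rng.lognormal(-5, 1, size=(n_lipids, 12))
    table = RecoveryTable(lipids=lipids, conditions=design, abundance=abundances)
    desc = pd.DataFrame(
        rng.normal(size=(n_lipids, n_desc)),
        index=[l.lipid_id for l in lipids],
        columns=[f"d{k}" for k in range(n_desc)],
    )
    idac = None
    if with_idac:
        idac = pd.DataFrame(
            rng.normal(size=(n_lipids, 12)),
            index=[l.lipid_id for l in lipids],
            columns=[c.id for c in design],
        )
    return pm.assemble_dataset(table, desc, design, idac)


class TestAssemble:
    def test_zero_abundance_imputed_at_floor(self):
        a = np.full((2, 12), 0.5)
        a[0, 0] = 0.0
        ft = tiny_table(n_lipids=2, abundances=a)
        assert ft.y.loc[("L0", "SC1")] == -7.0
        assert bool(ft.censored_mask.loc[("L0", "SC1")])
        assert ft.censored_mask.sum() == 1

    def test_unit_abundance_maps_to_zero(self):
        a = np.full((1, 12), 1.0)
        ft = tiny_table(n_lipids=1, abundances=a)
        assert (ft.y == 0.0).all()

    def test_full_scale_shape_with_and_without_idac(self, dummy_descriptors_29):
        config = sd.GeneratorConfig(seed=2)
        records, _ = sd.generate_lipid_library(config)
        table, _ = sd.generate_recovery_surface(records, config)
        design = config.resolved_design()
        rng = np.random.default_rng(0)
        idac = pd.DataFrame(
            rng.normal(size=(89, 12)),
            index=table.lipid_ids,
            columns=[c.id for c in design],
        )
        with_idac = pm.assemble_dataset(table, dummy_descriptors_29, design, idac)
        without = pm.assemble_dataset(table, dummy_descriptors_29, design)
        assert with_idac.X.shape == (1068, 33)
        assert without.X.shape == (1068, 32)
        assert int((with_idac.y == -7.0).sum()) == int((table.abundance == 0).sum())

    def test_missing_lipid_or_condition_rejected(self, toy_recovery):
        desc = pd.DataFrame(np.ones((1, 3)), index=["L0"], columns=list("abc"))
        with pytest.raises(ValidationError, match="lipids missing"):
            pm.assemble_dataset(toy_recovery, desc, toy_recovery.conditions)
        desc = pd.DataFrame(np.ones((2, 3)), index=["L0", "L1"], columns=list("abc"))
        with pytest.raises(ValidationError, match="conditions missing"):
            pm.assemble_dataset(toy_recovery, desc, toy_recovery.conditions[:1])


class TestSplit:
    def test_ratio_partition_and_determinism(self):
        ft = tiny_table(n_lipids=10, seed=3)  # 120 rows, 110 non-holdout
        spec = pm.SplitSpec(holdout_condition_id="SC5", test_fraction=0.2, seed=11)
        tr, te, va = pm.split_dataset(ft, spec)
        assert len(va) if hasattr(va, "__len__") else True
        assert len(va.X) == 10
        assert len(te.X) == 22 and len(tr.X) == 88
        all_idx = tr.X.index.append(te.X.index).append(va.X.index)
        assert set(all_idx) == set(ft.X.index)
        assert len(all_idx) == len(ft.X)
        tr2, te2, _ = pm.split_dataset(ft, spec)
        pd.testing.assert_frame_equal(tr.X, tr2.X)
        pd.testing.assert_frame_equal(te.X, te2.X)

    def test_missing_holdout_rejected(self):
        ft = tiny_table()
        with pytest.raises(ValidationError, match="holdout"):
            pm.split_dataset(ft, pm.SplitSpec(holdout_condition_id="SC99"))


class TestTuneTrainEvaluate:
    def test_singleton_grid_equals_direct_fit(self):
        ft = tiny_table(n_lipids=6, seed=4)
        model, chosen = pm.tune_and_train(
            "lasso", ft, grid={"model__alpha": [0.1]}, seed=0
        )
        assert chosen == {"model__alpha": 0.1}
        direct = pm.make_model("lasso", seed=0).set_params(model__alpha=0.1)
        direct.fit(ft.X.to_numpy(), ft.y.to_numpy())
        assert np.allclose(
            model.predict(ft.X.to_numpy()), direct.predict(ft.X.to_numpy())
        )

    def test_lasso_realizes_exact_linear_target(self):
        rng = np.random.default_rng(5)
        ft = tiny_table(n_lipids=8, seed=5)
        beta = rng.normal(size=ft.X.shape[1])
        y = pd.Series(ft.X.to_numpy() @ beta, index=ft.X.index)
        lin = pm.FeatureTable(X=ft.X, y=y, censored_mask=pd.Series(False, index=ft.X.index))
        model, _ = pm.tune_and_train("lasso", lin, grid={"model__alpha": [1e-4]}, seed=0)
        rep = pm.evaluate(model, {"train": lin})
        assert rep.metrics.loc["train", "R2"] >= 0.999

    def test_xgboost_beats_lasso_on_piecewise_constant_response(self):
        ft = tiny_table(n_lipids=8, seed=6)
        y = pd.Series(
            np.where(ft.X["d0"].to_numpy() > 0, 2.0, -2.0)
            + np.where(ft.X["d1"].to_numpy() > 0.5, 1.0, 0.0),
            index=ft.X.index,
        )
        step = pm.FeatureTable(X=ft.X, y=y, censored_mask=pd.Series(False, index=ft.X.index))
        xgb, _ = pm.tune_and_train("xgboost", step, grid={"model__max_depth": [3]}, seed=0)
        lasso, _ = pm.tune_and_train("lasso", step, grid={"model__alpha": [1e-3]}, seed=0)
        r_xgb = pm.evaluate(xgb, {"train": step}).metrics.loc["train", "R2"]
        r_lasso = pm.evaluate(lasso, {"train": step}).metrics.loc["train", "R2"]
        assert r_xgb > r_lasso

    def test_unknown_model_and_degenerate_grid(self):
        ft = tiny_table()
        with pytest.raises(ValidationError, match="unknown model"):
            pm.make_model("boosted_ferns")
        with pytest.raises(ValidationError, match="degenerate grid"):
            pm.tune_and_train("lasso", ft, grid={"model__alpha": []})

    def test_metric_exact_examples(self):
        class Identity:
            def predict(self, X):
                return self.vals

        m = Identity()
        idx = pd.MultiIndex.from_tuples(
            [("L0", "A"), ("L1", "A")], names=["lipid_id", "condition_id"]
        )
        mk = lambda y: pm.FeatureTable(
            X=pd.DataFrame({"f": [0.0, 1.0]}, index=idx),
            y=pd.Series(y, index=idx),
            censored_mask=pd.Series(False, index=idx),
        )
        m.vals = np.array([0.0, 1.0])
        rep = pm.evaluate(m, {"train": mk([0.0, 1.0])})
        assert rep.metrics.loc["train", ["RMSE", "MAE"]].tolist() == [0.0, 0.0]
        assert rep.metrics.loc["train", "R2"] == 1.0
        m.vals = np.array([1.0, 1.0])
        rep = pm.evaluate(m, {"train": mk([0.0, 2.0])})
        assert rep.metrics.loc["train", ["MSE", "RMSE", "MAE", "R2"]].tolist() == [
            1.0, 1.0, 1.0, 0.0,
        ]

    def test_metrics_match_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            y = rng.normal(size=20)
            yhat = rng.normal(size=20)
            got = pm._metrics(y, yhat)
            assert got["MSE"] == pytest.approx(mean_squared_error(y, yhat), abs=1e-12)
            assert got["MAE"] == pytest.approx(mean_absolute_error(y, yhat), abs=1e-12)
            assert got["R2"] == pytest.approx(r2_score(y, yhat), abs=1e-12)


class TestAblationAndRedundancy:
    def test_paired_report_count_and_without_equivalence(self):
        ft = tiny_table(n_lipids=8, with_idac=True, seed=8)
        spec = pm.SplitSpec(seed=1)
        models = ["lasso", "xgboost"]
        grids = {"lasso": {"model__alpha": [0.01]}, "xgboost": {"model__max_depth": [3]}}
        reports = pm.ablation_idac(ft, spec, models, grids, seed=1)
        assert len(reports) == 2 * len(models)
        assert [r.idac_included for r in reports] == [True, True, False, False]
        # dropping the column beforehand gives the identical "without" half
        alone, _ = pm.run_protocol(ft.without_idac(), spec, models, grids, seed=1)
        for a, b in zip(reports[2:], alone):
            pd.testing.assert_frame_equal(a.metrics, b.metrics)

    def test_requires_idac_column(self):
        ft = tiny_table(with_idac=False)
        with pytest.raises(ValidationError, match="IDAC"):
            pm.ablation_idac(ft, pm.SplitSpec())

    def test_redundancy_report_flags_planted_correlation(self):
        ft = tiny_table(n_lipids=10, with_idac=True, seed=9)
        X = ft.X.copy()
        rng = np.random.default_rng(9)
        X["d0"] = X[pm.IDAC_COLUMN]  # exact copy
        X["d1"] = X[pm.IDAC_COLUMN] + rng.normal(0, 0.05, size=len(X))
        planted = pm.FeatureTable(X=X, y=ft.y, censored_mask=ft.censored_mask)
        report = pm.feature_redundancy_report(planted)
        assert report.iloc[0]["feature"] == "d0"
        assert report.iloc[0]["r"] == pytest.approx(1.0)
        assert bool(report.iloc[0]["flagged"])
        assert report.iloc[1]["feature"] == "d1"

    def test_independent_feature_uncorrelated_at_large_n(self):
        rng = np.random.default_rng(10)
        idx = pd.MultiIndex.from_tuples(
            [(f"L{i}", "A") for i in range(1000)], names=["lipid_id", "condition_id"]
        )
        X = pd.DataFrame(
            {"noise": rng.normal(size=1000), pm.IDAC_COLUMN: rng.normal(size=1000)},
            index=idx,
        )
        ft = pm.FeatureTable(
            X=X, y=pd.Series(0.0, index=idx), censored_mask=pd.Series(False, index=idx)
        )
        report = pm.feature_redundancy_report(ft)
        assert abs(report.iloc[0]["r"]) < 0.1


class TestPredictProfile:
    def _fitted(self):
        ft = tiny_table(n_lipids=6, seed=11)
        model, _ = pm.tune_and_train("xgboost", ft, grid={"model__max_depth": [3]}, seed=0)
        return ft, model

    def test_output_length_and_training_consistency(self):
        ft, model = self._fitted()
        desc = ft.X.xs("SC1", level="condition_id").drop(
            columns=["temperature", "pressure", "ethanol_flow"]
        )
        cond = next(c for c in sd.GeneratorConfig().resolved_design() if c.id == "SC1")
        pred = pm.predict_profile(model, cond, desc)
        assert len(pred) == 6
        direct = model.predict(ft.X.xs("SC1", level="condition_id", drop_level=False).to_numpy())
        assert np.allclose(pred["log_recovery"].to_numpy(), direct)
        assert np.allclose(pred["recovery"], 10.0 ** pred["log_recovery"])

    def test_feature_mismatch_rejected(self):
        ft, model = self._fitted()
        desc = ft.X.xs("SC1", level="condition_id").iloc[:, :5]
        cond = sd.GeneratorConfig().resolved_design()[0]
        with pytest.raises(ValidationError, match="mismatch"):
            pm.predict_profile(model, cond, desc)


class TestReproducibility:
    def test_protocol_bitwise_reproducible(self):
        ft = tiny_table(n_lipids=8, with_idac=True, seed=12)
        spec = pm.SplitSpec(seed=5)
        grids = {"xgboost": {"model__max_depth": [3]}}
        a, _ = pm.run_protocol(ft, spec, ["xgboost"], grids, seed=5)
        b, _ = pm.run_protocol(ft, spec, ["xgboost"], grids, seed=5)
        pd.testing.assert_frame_equal(a[0].metrics, b[0].metrics)
        assert a[0].metrics.equals(b[0].metrics)
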