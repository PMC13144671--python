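import numpy as np
import pandas as pd
import pytest

from mced import ensemble as en


class TestLogit:
    def test_half_is_zero(self):
        assert en.logit(0.5) == pytest.approx(0.0)

    def test_clipping_keeps_finite(self):
        v = en.logit(1.0, eps=1e-6)
        assert np.isfinite(v)
        assert v == pytest.approx(np.log((1 - 1e-6) / 1e-6))

    def test_antisymmetry(self):
        for p in [0.1, 0.25, 0.4, 0.45]:
            assert en.logit(p) == pytest.approx(-en.logit(1 - p))

    def test_eps_bounds(self):
        with pytest.raises(ValueError):
            en.logit(0.5, eps=0.0)
        with pytest.raises(ValueError):
            en.logit(0.5, eps=0.6)

    def test_out_of_range_p(self):
        with pytest.raises(ValueError):
            en.logit(1.2)


def synthetic_scores(n_healthy, n_cancer, seed, informative=("amf",)):
    """Feature-score frame + demographics for ensemble tests."""
    rng = np.random.default_rng(seed)
    n = n_healthy + n_cancer
    y = np.r_[np.zeros(n_healthy, int), np.ones(n_cancer, int)]
    scores = {}
    for f in en.FEATURES:
        if f in informative:
            s = np.r_[rng.beta(2, 8, n_healthy), rng.beta(8, 2, n_cancer)]
        else:
            s = rng.beta(2, 2, n)
        scores[f] = s
    df = pd.DataFrame(scores, index=[f"s{i}" for i in range(n)])
    age = rng.normal(60, 8, n)
    sex = rng.integers(0, 2, n)
    return df, age, sex, y


class TestFitAndThreshold:
    def test_brute_force_threshold(self):
        rng = np.random.default_rng(0)
        h = rng.uniform(size=100)
        t = en.calibrate_threshold(h, 0.95)
        assert np.mean(h > t) <= 0.05
        # brute force: no smaller observed score satisfies the budget
        for cand in sorted(h):
            if cand >= t:
                break
            assert np.mean(h > cand) > 0.05

    def test_target_one_is_max(self):
        h = np.array([0.1, 0.5, 0.9])
        assert en.calibrate_threshold(h, 1.0) == pytest.approx(0.9)

    def test_fit_respects_training_budget(self):
        df, age, sex, y = synthetic_scores(100, 100, seed=1)
        model = en.fit_cse_csd(df, age, sex, y, target_spec=0.95, seed=0)
        score, _ = en.predict_csd(model, df, age, sex)
        exceed = (score.to_numpy()[y == 0] > model.threshold).mean()
        assert exceed <= 0.05

    def test_single_class_errors(self):
        df, age, sex, _ = synthetic_scores(10, 0, seed=2)
        with pytest.raises(ValueError, match="classes"):
            en.fit_cse_csd(df, age, sex, np.zeros(10, int))

    def test_no_harm_from_noise_features(self):
        from sklearn.metrics import roc_auc_score
        df, age, sex, y = synthetic_scores(150, 150, seed=3)
        model = en.fit_cse_csd(df, age, sex, y, seed=0)
        df2, age2, sex2, y2 = synthetic_scores(150, 150, seed=4)
        score, _ = en.predict_csd(model, df2, age2, sex2)
        ens_auc = roc_auc_score(y2, score)
        amf_auc = roc_auc_score(y2, df2["amf"])
        assert ens_auc >= amf_auc - 0.05

    def test_amf_weight_dominates_when_only_informative(self):
        df, age, sex, y = synthetic_scores(200, 200, seed=5)
        model = en.fit_cse_csd(df, age, sex, y, seed=0)
        w = model.standardized_coef()
        assert w["amf"] == max(w[f] for f in en.FEATURES)
        assert w["amf"] > 0


class TestPredictCSD:
    def _model(self):
        df, age, sex, y = synthetic_scores(50, 50, seed=6)
        return en.fit_cse_csd(df, age, sex, y, seed=0), df, age, sex

    def test_score_at_threshold_is_negative_call(self):
        model, df, age, sex = self._model()
        score, call = en.predict_csd(model, df, age, sex)
        at = (score == model.threshold)
        if at.any():
            assert not call[at].any()
        # strictness direct check
        assert (call == (score > model.threshold)).all()

    def test_all_zero_coef_constant_score(self):
        model, df, age, sex = self._model()
        model.coef = np.zeros_like(model.coef)
        model.intercept = -1.0
        score, call = en.predict_csd(model, df, age, sex)
        assert score.nunique() == 1
        model.threshold = float(score.iloc[0]) + 0.01
        _, call = en.predict_csd(model, df, age, sex)
        assert not call.any()

    def test_monotone_in_positive_feature(self):
        model, df, age, sex = self._model()
        f = "amf"
        i = list(model.feature_names).index(f)
        if model.coef[i] <= 0:
            pytest.skip("coefficient direction flipped on this toy draw")
        grid = df.copy()
        scores = []
        for v in np.linspace(0.05, 0.95, 10):
            grid[f] = v
            s, _ = en.predict_csd(model, grid, age, sex)
            scores.append(s.to_numpy())
        scores = np.stack(scores)
        assert (np.diff(scores, axis=0) >= -1e-12).all()

    def test_missing_feature_errors(self):
        model, df, age, sex = self._model()
        with pytest.raises(ValueError, match="missing feature"):
            en.predict_csd(model, df.drop(columns=["cnv"]), age, sex)
        df_nan = df.copy()
        df_nan.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="no imputation"):
            en.predict_csd(model, df_nan, age, sex)


class TestPredictTOO:
    TYPES = ["breast", "colorectal", "gastric", "liver",
             "lung", "ovarian", "pancreatic", "prostate"]

    def _cond(self, rows):
        return pd.DataFrame(rows, columns=self.TYPES, index=[f"s{i}" for i in range(len(rows))])

    def test_in_between_flag(self):
        probs = [0.40, 0.36, 0.04, 0.04, 0.04, 0.04, 0.04, 0.04]
        out = en.predict_too({"amf": 1.0}, {"amf": self._cond([probs])}, delta=0.07)
        assert out["in_between"].iloc[0]
        assert out["too_top1"].iloc[0] == "breast"
        assert out["too_top2"].iloc[0] == "colorectal"

    def test_degenerate_weight_matches_argmax(self):
        rng = np.random.default_rng(0)
        rows = rng.dirichlet(np.ones(8), size=20)
        cond = self._cond(rows)
        noise = self._cond(rng.dirichlet(np.ones(8), size=20).tolist())
        out = en.predict_too({"amf": 1.0, "fsd": 0.0}, {"amf": cond, "fsd": noise})
        assert (out["too_top1"] == cond.idxmax(axis=1)).all()

    def test_uniform_always_in_between(self):
        rows = [[1 / 8] * 8]
        out = en.predict_too({"amf": 1.0}, {"amf": self._cond(rows)}, delta=0.001)
        assert out["in_between"].iloc[0]
        assert out["too_top1_prob"].iloc[0] == pytest.approx(out["too_top2_prob"].iloc[0])

    def test_top1_geq_top2(self):
        rng = np.random.default_rng(1)
        cond = self._cond(rng.dirichlet(np.ones(8), size=50))
        out = en.predict_too({"amf": 1.0}, {"amf": cond})
        assert (out["too_top1_prob"] >= out["too_top2_prob"]).all()

    def test_weight_mismatch_errors(self):
        cond = self._cond([[1 / 8] * 8])
        with pytest.raises(ValueError, match="match"):
            en.predict_too({"amf": 0.5, "cnv": 0.5}, {"amf": cond})

    def test_tie_breaks_by_label_order(self):
        rows = [[0.2, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]]
        out = en.predict_too({"amf": 1.0}, {"amf": self._cond(rows)})
        assert out["too_top1"].iloc[0] == "breast"
        assert out["too_top2"].iloc[0] == "colorectal"


class TestEvaluate:
    def _frames(self, calls, labels, scores=None, too=None):
        n = len(calls)
        preds = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "csd_score": scores if scores is not None else np.linspace(0, 1, n),
            "csd_call": calls,
        })
        if too is not None:
            preds["too_top1"] = too[0]
            preds["too_top2"] = too[1]
            preds["in_between"] = too[2]
        truth = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "label": labels,
            "stage": ["NA" if l == "healthy" else "II" for l in labels],
        })
        return preds, truth

    def test_hand_tally(self):
        # 3 TP, 1 FN, 18 TN, 2 FP -> sens 75%, spec 90%
        labels = ["lung"] * 4 + ["healthy"] * 20
        calls = [True, True, True, False] + [False] * 18 + [True] * 2
        preds, truth = self._frames(calls, labels)
        m = en.evaluate(preds, truth).set_index(["metric", "group"])["value"]
        assert m[("sensitivity", "overall")] == pytest.approx(0.75)
        assert m[("specificity", "overall")] == pytest.approx(0.90)

    def test_perfect_predictions(self):
        labels = ["liver"] * 5 + ["healthy"] * 5
        calls = [True] * 5 + [False] * 5
        scores = [0.9] * 5 + [0.1] * 5
        too = (["liver"] * 5 + [None] * 5, ["lung"] * 5 + [None] * 5, [False] * 10)
        preds, truth = self._frames(calls, labels, scores, too)
        m = en.evaluate(preds, truth).set_index(["metric", "group"])["value"]
        assert m[("sensitivity", "overall")] == 1.0
        assert m[("specificity", "overall")] == 1.0
        assert m[("too_top1_accuracy", "overall")] == 1.0
        assert m[("roc_auc", "overall")] == 1.0

    def test_top2_geq_top1(self):
        rng = np.random.default_rng(0)
        types = ["lung", "liver", "breast", "gastric"]
        labels = [types[i % 4] for i in range(40)]
        top1 = [types[(i + rng.integers(0, 2)) % 4] for i in range(40)]
        top2 = [types[(i + 1) % 4] for i in range(40)]
        preds, truth = self._frames([True] * 40, labels,
                                    too=(top1, top2, [False] * 40))
        m = en.evaluate(preds, truth).set_index(["metric", "group"])["value"]
        assert m[("too_top2_accuracy", "overall")] >= m[("too_top1_accuracy", "overall")]

    def test_missing_truth_errors(self):
        preds, truth = self._frames([True], ["lung"])
        with pytest.raises(ValueError, match="no truth"):
            en.evaluate(preds, truth.iloc[0:0])

    def test_wilson_ci_present(self):
        preds, truth = self._frames([True, False], ["lung", "healthy"])
        out = en.evaluate(preds, truth)
        sens = out[(out.metric == "sensitivity") & (out.group == "overall")].iloc[0]
        assert 0 <= sens.ci_low <= sens.value <= sens.ci_high <= 1


class TestModelJSON:
    def test_round_trip(self, tmp_path):
        df, age, sex, y = synthetic_scores(30, 30, seed=9)
        model = en.fit_cse_csd(df, age, sex, y, seed=0)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = en.EnsembleModel.from_json(path)
        assert np.allclose(back.coef, model.coef)
        assert back.threshold == pytest.approx(model.threshold)
        assert back.feature_names == model.feature_names
        s1, _ = en.predict_csd(model, df, age, sex)
        s2, _ = en.predict_csd(back, df, age, sex)
        assert np.allclose(s1, s2)
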