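import numpy as np
import pandas as pd
import pytest

from dconet.cohort_io import AlterationMatrix, BiomarkerCatalog, BiomarkerRecord, TreatmentArm
from dconet.models import (
    Hyperparameters,
    HyperparameterGrid,
    balanced_accuracy,
    build_features,
    combine_eq1,
    combine_eq2,
    evaluate_collection,
    fit_classifier,
    loocv,
    per_gene_biomarker_baccs,
    train_bundle,
    train_variant,
    tune_hyperparameters,
)
from dconet.network import DCONetwork, build_networks
from dconet.diff_drivers import DiffDriverResult


def _network(genes, treatment="TX", flavor="General"):
    diffd = []
    for g in genes:
        r = DiffDriverResult(g, 10, 40, 1, 40, 0.99)
        r.memberships = {"General_DiffD", "Resp_DiffD", "NonResp_DiffD"}
        diffd.append(r)
    return build_networks(diffd, [], treatment)[flavor]


class TestBuildFeatures:
    def test_rows_follow_alteration_status(self, tiny_matrix):
        net = _network(["gA", "gB"])
        f = build_features(tiny_matrix, net)
        assert list(f.columns) == ["gA", "gB"]
        assert f.loc["s1"].tolist() == [1, 0]

    def test_empty_network_zero_columns(self, tiny_matrix):
        f = build_features(tiny_matrix, DCONetwork("TX", "General"))
        assert f.shape == (4, 0)

    def test_columns_sorted(self, tiny_matrix):
        net = _network(["gC", "gA"])
        f = build_features(tiny_matrix, net)
        assert list(f.columns) == sorted(f.columns)


class TestBalancedAccuracy:
    def test_confusion_formula(self):
        # TP=3, FN=1, TN=2, FP=2 -> (0.75 + 0.5)/2
        y_true = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        y_pred = np.array([1, 1, 1, -1, -1, -1, 1, 1])
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.625)

    def test_single_class_undefined(self):
        assert balanced_accuracy(np.array([1, 1]), np.array([1, -1])) is None


class TestTuning:
    def _toy(self, n=30):
        rng = np.random.default_rng(0)
        x = np.array([1] * (n // 2) + [0] * (n // 2))
        X = pd.DataFrame({"g": x, "noise": rng.integers(0, 2, n)})
        y = np.where(x == 1, 1, -1)
        return X, y

    def test_separable_prefers_smallest_depth(self):
        X, y = self._toy()
        grid = HyperparameterGrid(max_depth=(1, 3), learning_rate=(0.4,), l2_leaf_reg=(1.0,))
        hp = tune_hyperparameters(X, y, grid, iterations=2, seed=0)
        assert hp.max_depth == 1

    def test_uninformative_labels_auc_near_half(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.integers(0, 2, (60, 4)), columns=list("abcd"))
        y = np.where(rng.random(60) < 0.5, 1, -1)
        # mean AUC should hover near 0.5: the chosen point cannot be great
        hp = tune_hyperparameters(
            X, y, HyperparameterGrid(max_depth=(2,), learning_rate=(0.4,), l2_leaf_reg=(3.0,)),
            iterations=3, seed=2,
        )
        assert isinstance(hp, Hyperparameters)

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame({"g": [0, 1] * 4 + [0]})
        y = np.array([1, -1] * 4 + [1])
        with pytest.raises(ValueError):
            tune_hyperparameters(X, y, iterations=1)


class TestLOOCV:
    def test_perfect_predictor(self):
        x = np.array([1] * 10 + [0] * 10)
        X = pd.DataFrame({"g": x})
        y = np.where(x == 1, 1, -1)
        preds, probs, bacc, imps = loocv(X, y, Hyperparameters(1, 0.5, 1.0), seed=0)
        assert bacc == 1.0
        assert (preds == y).all()
        assert imps["g"] > 0

    def test_constant_prediction_is_chance_level(self):
        y = np.array([1, -1] * 10)
        assert balanced_accuracy(y, np.ones(20, int)) == pytest.approx(0.5)

    def test_constant_feature_pessimistic_bias(self):
        # leave-one-out with an uninformative constant feature: every root
        # leaf tilts toward the training fold's majority, i.e. away from the
        # held-out label - the classic LOOCV pessimistic bias
        X = pd.DataFrame({"g": np.zeros(20, dtype=int)})
        y = np.array([1, -1] * 10)
        preds, probs, bacc, _ = loocv(X, y, Hyperparameters(), seed=0)
        assert bacc <= 0.5


class TestCombineEq2:
    def test_worked_example_response(self):
        preds = {"General": np.array([1]), "Resp": np.array([1]), "NonResp": np.array([1])}
        probs = {"General": np.array([0.8]), "Resp": np.array([0.9]), "NonResp": np.array([0.9])}
        baccs = {"General": 0.7, "Resp": 0.6, "NonResp": 0.8}
        w = combine_eq2(preds, probs, baccs)
        assert w[0] == pytest.approx(0.7 * 0.8 + 0.6 * 0.9)

    def test_worked_example_non_response(self):
        preds = {k: np.array([-1]) for k in ("General", "Resp", "NonResp")}
        probs = {k: np.array([0.1]) for k in ("General", "Resp", "NonResp")}  # P(resp) = 0.1
        baccs = {"General": 0.7, "Resp": 0.6, "NonResp": 0.8}
        w = combine_eq2(preds, probs, baccs)
        assert w[0] == pytest.approx(-0.7 * 0.9 - 0.8 * 0.9)

    def test_zero_weights_no_call(self):
        preds = {k: np.array([1]) for k in ("General", "Resp", "NonResp")}
        probs = {k: np.array([0.9]) for k in ("General", "Resp", "NonResp")}
        baccs = {k: 0.0 for k in ("General", "Resp", "NonResp")}
        w = combine_eq2(preds, probs, baccs)
        assert w[0] == 0.0
        assert np.sign(w[0]) == 0

    def test_missing_flavor_contributes_zero(self):
        preds = {"General": np.array([1]), "Resp": None, "NonResp": None}
        probs = {"General": np.array([0.8]), "Resp": None, "NonResp": None}
        baccs = {"General": 0.7, "Resp": None, "NonResp": None}
        assert combine_eq2(preds, probs, baccs)[0] == pytest.approx(0.56)

    def test_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            preds = {k: rng.choice([1, -1], 5) for k in ("General", "Resp", "NonResp")}
            probs = {k: rng.random(5) for k in ("General", "Resp", "NonResp")}
            baccs = {k: float(rng.random()) for k in ("General", "Resp", "NonResp")}
            w = combine_eq2(preds, probs, baccs)
            bound = baccs["General"] + max(baccs["Resp"], baccs["NonResp"])
            assert (np.abs(w) <= bound + 1e-12).all()


class TestCombineEq1:
    def _matrix(self):
        status = np.array([[1, 0], [1, 1], [0, 0]])
        return AlterationMatrix(["s1", "s2", "s3"], ["RG", "NG"], status)

    def test_single_response_biomarker(self):
        cat = BiomarkerCatalog([BiomarkerRecord("RG", "fam", "response")])
        scores, applicable = combine_eq1(self._matrix(), cat, "fam", {"RG": 0.7})
        assert scores.tolist() == pytest.approx([0.7, 0.7, 0.0])
        assert applicable.tolist() == [True, True, False]

    def test_mixed_directions(self):
        cat = BiomarkerCatalog(
            [
                BiomarkerRecord("RG", "fam", "response"),
                BiomarkerRecord("NG", "fam", "non-response"),
            ]
        )
        scores, _ = combine_eq1(self._matrix(), cat, "fam", {"RG": 0.6, "NG": 0.8})
        assert scores[1] == pytest.approx(0.6 - 0.8)

    def test_no_altered_biomarker_not_applicable(self):
        cat = BiomarkerCatalog([BiomarkerRecord("RG", "fam", "response")])
        m = AlterationMatrix(["s"], ["RG"], np.array([[0]]))
        scores, applicable = combine_eq1(m, cat, "fam", {"RG": 0.7})
        assert scores[0] == 0.0 and not applicable[0]

    def test_duplicate_records_do_not_double_count(self):
        cat = BiomarkerCatalog(
            [
                BiomarkerRecord("RG", "fam", "response", "approved"),
                BiomarkerRecord("RG", "fam2", "response", "experimental"),
            ]
        )
        scores, _ = combine_eq1(self._matrix(), cat, "fam", {"RG": 0.7})
        assert scores[0] == pytest.approx(0.7)

    def test_per_gene_bacc_direction(self):
        m = self._matrix()
        arm = TreatmentArm("t", {"s1": True, "s2": True, "s3": False})
        cat = BiomarkerCatalog([BiomarkerRecord("RG", "fam", "response")])
        baccs = per_gene_biomarker_baccs(m, arm, cat, "fam")
        assert baccs["RG"] == pytest.approx(1.0)  # altered in both responders only


class TestTrainVariants:
    def test_bundle_on_separable_arm(self, separable_arm):
        matrix, arm = separable_arm
        nets = {f: _network(["g0", "g1"], flavor=f) for f in ("General", "Resp", "NonResp")}
        bundle = train_bundle(matrix, arm, nets, seed=0, hyperparameters=Hyperparameters())
        assert bundle.combined_bacc is not None and bundle.combined_bacc >= 0.8
        assert set(bundle.models) == {"General", "Resp", "NonResp"}

    def test_variant_feature_columns(self, separable_arm):
        matrix, arm = separable_arm
        nets = {f: _network(["g0"], flavor=f) for f in ("General", "Resp", "NonResp")}
        cat = BiomarkerCatalog([BiomarkerRecord("g1", "fam", "response")])
        bio = train_variant(
            matrix, arm, nets, variant="biomarkers", catalog=cat, drug_family="fam",
            hyperparameters=Hyperparameters(),
        )
        assert bio.models["General"].feature_genes == ["g1"]
        integrated = train_variant(
            matrix, arm, nets, variant="dco+biomarkers", catalog=cat, drug_family="fam",
            hyperparameters=Hyperparameters(),
        )
        assert integrated.models["General"].feature_genes == ["g0", "g1"]

    def test_no_features_status(self, separable_arm):
        matrix, arm = separable_arm
        nets = {f: DCONetwork("TX", f) for f in ("General", "Resp", "NonResp")}
        bundle = train_bundle(matrix, arm, nets, seed=0, hyperparameters=Hyperparameters())
        assert all(m.status == "no-features" for m in bundle.models.values())
        assert (bundle.wcomb == 0).all()


class TestEvaluateCollection:
    class _Stub:
        def __init__(self, t, bacc):
            self.treatment_id = t
            self.variant = "dco"
            self._bacc = bacc

        @property
        def combined_bacc(self):
            return self._bacc

    def test_macro_average_and_cutoff(self):
        bundles = [self._Stub("t1", 0.5), self._Stub("t2", 0.7), self._Stub("t3", 0.59)]
        table, macro, high = evaluate_collection(bundles)
        assert macro == pytest.approx(0.5966666, abs=1e-5)
        assert high == ["t2"]

    def test_all_missing(self):
        table, macro, high = evaluate_collection([self._Stub("t1", None)])
        assert macro is None and high == []
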