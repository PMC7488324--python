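"""Per-treatment drug-response classifiers on DCO features.

For each treatment arm, three gradient-boosted tree classifiers are trained
on the binary alteration status of the General / Resp / NonResp network
genes (DiffD_DiP feature vectors).  Edges are deliberately not encoded as
features: a depth>=2 tree ensemble natively exploits pairwise feature
interactions, i.e. driver co-occurrences.  Each classifier is evaluated by
leave-one-out cross-validation, and the three per-sample predictions are
merged into one weighted combination score (``wComb``) using the LOOCV
balanced accuracies as weights.  A gene-level biomarker baseline produces
the analogous ``wComb_bmk`` score.

Class labels are encoded +1 (response) / -1 (non-response).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cohort_io import AlterationMatrix, BiomarkerCatalog, TreatmentArm
from .network import DCONetwork

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparameters",
    "HyperparameterGrid",
    "FlavorModel",
    "TreatmentModelBundle",
    "build_features",
    "fit_classifier",
    "predict_response_probability",
    "tune_hyperparameters",
    "loocv",
    "balanced_accuracy",
    "combine_eq2",
    "combine_eq1",
    "train_flavor",
    "train_bundle",
    "train_variant",
    "evaluate_collection",
]

RESPONSE, NON_RESPONSE = 1, -1


@dataclass(frozen=True)
class Hyperparameters:
    """One gradient-boosting configuration; the tree count is fixed at 100."""

    max_depth: int = 3
    learning_rate: float = 0.4
    l2_leaf_reg: float = 3.0
    n_trees: int = 100


@dataclass(frozen=True)
class HyperparameterGrid:
    """Discretization of the tuning ranges: depth 1-7, learning rate
    0.2-1, L2 regularization 1-10; 100 trees throughout."""

    max_depth: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    learning_rate: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    l2_leaf_reg: tuple[float, ...] = (1.0, 3.0, 5.0, 10.0)
    n_trees: int = 100

    def points(self) -> list[Hyperparameters]:
        return [
            Hyperparameters(d, lr, l2, self.n_trees)
            for d, lr, l2 in itertools.product(self.max_depth, self.learning_rate, self.l2_leaf_reg)
        ]


def build_features(matrix: AlterationMatrix, network: DCONetwork) -> pd.DataFrame:
    """Boolean feature matrix over the network's genes (columns sorted
    lexicographically; edges are not encoded)."""
    genes = [g for g in network.feature_genes if g in set(matrix.gene_ids)]
    dropped = len(network.feature_genes) - len(genes)
    if dropped:
        logger.info("%d network genes absent from matrix; dropped from features", dropped)
    if not genes:
        return pd.DataFrame(index=list(matrix.sample_ids))
    idx = matrix.gene_index(genes)
    return pd.DataFrame(
        matrix.status[:, idx].astype(np.int8), index=list(matrix.sample_ids), columns=genes
    )


def _labels01(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (RESPONSE, NON_RESPONSE)).all():
        raise ValueError("labels must be +1 (response) / -1 (non-response)")
    return (labels == RESPONSE).astype(int)


def fit_classifier(
    features: pd.DataFrame, labels: np.ndarray, hp: Hyperparameters, seed: int = 0
) -> xgb.Booster:
    """Fit one boosted-tree classifier (logloss objective, fixed base score)."""
    y = _labels01(labels)
    dtrain = xgb.DMatrix(
        features.to_numpy(dtype=np.float32), label=y, feature_names=list(features.columns)
    )
    params = {
        "objective": "binary:logistic",
        "max_depth": hp.max_depth,
        "eta": hp.learning_rate,
        "lambda": hp.l2_leaf_reg,
        "base_score": 0.5,
        "tree_method": "exact",
        "seed": seed % (2**31),
        "nthread": 1,
    }
    return xgb.train(params, dtrain, num_boost_round=hp.n_trees)


def predict_response_probability(booster: xgb.Booster, features: pd.DataFrame) -> np.ndarray:
    """P(response) per sample."""
    dm = xgb.DMatrix(
        features.to_numpy(dtype=np.float32), feature_names=list(features.columns)
    )
    return booster.predict(dm)


def tune_hyperparameters(
    features: pd.DataFrame,
    labels: np.ndarray,
    grid: HyperparameterGrid = HyperparameterGrid(),
    folds: int = 5,
    iterations: int = 30,
    seed: int = 0,
) -> Hyperparameters:
    """Pick the grid point with the best mean AUC over repeated stratified
    k-fold cross-validation.

    Ties are broken toward the simpler model: smaller depth, then smaller
    learning rate, then larger L2 regularization.
    """
    y = _labels01(labels)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples to tune")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n_minority = int(min((y == 1).sum(), (y == 0).sum()))
    k = min(folds, n_minority)
    if k < 2:
        raise ValueError("cannot stratify: minority class too small")
    X = features.to_numpy(dtype=np.float32)
    splits = []
    for rep in range(iterations):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + rep) % (2**31))
        splits.extend(list(skf.split(X, y)))

    scored = []
    for hp in grid.points():
        aucs = []
        for train_idx, test_idx in splits:
            if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
                continue
            bst = fit_classifier(features.iloc[train_idx], np.where(y[train_idx] == 1, 1, -1), hp, seed)
            p = predict_response_probability(bst, features.iloc[test_idx])
            aucs.append(roc_auc_score(y[test_idx], p))
        if not aucs:
            raise ValueError("no evaluable folds; cannot tune")
        scored.append((float(np.mean(aucs)), hp))
    scored.sort(key=lambda t: (-t[0], t[1].max_depth, t[1].learning_rate, -t[1].l2_leaf_reg))
    return scored[0][1]


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float | None:
    """(sensitivity + specificity) / 2 on +1/-1 labels; None when either term
    is undefined (a class absent from y_true)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == RESPONSE
    neg = y_true == NON_RESPONSE
    if not pos.any() or not neg.any():
        return None
    sens = float((y_pred[pos] == RESPONSE).mean())
    spec = float((y_pred[neg] == NON_RESPONSE).mean())
    return (sens + spec) / 2.0


def loocv(
    features: pd.DataFrame,
    labels: np.ndarray,
    hp: Hyperparameters,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float, dict[str, float]]:
    """Leave-one-out cross-validation.

    Returns (out-of-fold class predictions in {+1,-1}, out-of-fold response
    probabilities, balanced accuracy, mean per-feature importances across the
    n fold models).
    """
    labels = np.asarray(labels)
    y = _labels01(labels)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples for LOOCV")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    probs = np.empty(n)
    importance_acc: dict[str, float] = {c: 0.0 for c in features.columns}
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = labels[mask]
        if len(np.unique(y_train)) < 2:  # pathological tiny arm
            probs[i] = float((y[mask] == 1).mean())
            continue
        bst = fit_classifier(features.iloc[mask], y_train, hp, seed)
        probs[i] = predict_response_probability(bst, features.iloc[[i]])[0]
        for feat, gain in bst.get_score(importance_type="gain").items():
            importance_acc[feat] += gain
    preds = np.where(probs >= 0.5, RESPONSE, NON_RESPONSE)
    bacc = balanced_accuracy(labels, preds)
    importances = {c: v / n for c, v in importance_acc.items()}
    return preds, probs, bacc, importances


def combine_eq2(
    preds: dict[str, np.ndarray | None],
    probs_response: dict[str, np.ndarray | None],
    baccs: dict[str, float | None],
) -> np.ndarray:
    """Weighted combination of the General / Resp / NonResp predictions.

    General contributes +BAcc*P(response) when it predicts response and
    -BAcc*P(non-response) when it predicts non-response; the Resp model
    contributes only positive response votes and the NonResp model only
    negative non-response votes.  A missing or untrainable flavor contributes
    0.  The predicted class is sign(wComb); 0 means "no call".
    """
    n = None
    for flavor in ("General", "Resp", "NonResp"):
        if preds.get(flavor) is not None:
            n = len(preds[flavor])
            break
    if n is None:
        raise ValueError("no flavor predictions available")
    w = np.zeros(n)
    gen_p, gen_pred, gen_b = probs_response.get("General"), preds.get("General"), baccs.get("General")
    if gen_pred is not None and gen_b is not None:
        p_s = np.asarray(gen_p)
        p_r = 1.0 - p_s
        w += gen_b * (
            (np.asarray(gen_pred) == RESPONSE) * p_s - (np.asarray(gen_pred) == NON_RESPONSE) * p_r
        )
    r_p, r_pred, r_b = probs_response.get("Resp"), preds.get("Resp"), baccs.get("Resp")
    if r_pred is not None and r_b is not None:
        w += r_b * (np.asarray(r_pred) == RESPONSE) * np.asarray(r_p)
    n_p, n_pred, n_b = probs_response.get("NonResp"), preds.get("NonResp"), baccs.get("NonResp")
    if n_pred is not None and n_b is not None:
        w -= n_b * (np.asarray(n_pred) == NON_RESPONSE) * (1.0 - np.asarray(n_p))
    return w


def combine_eq1(
    matrix: AlterationMatrix,
    catalog: BiomarkerCatalog,
    drug_family: str,
    per_gene_baccs: dict[str, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Biomarker-combination score per sample.

    wComb_bmk = sum over altered response-biomarker genes of their BAcc minus
    the same sum over non-response-biomarker genes.  Duplicate catalog
    records are deduplicated before summation.  Returns (scores, applicable)
    where ``applicable`` is False for samples with no altered biomarker gene
    ("not applicable" rather than a confident 0).
    """
    records = {
        (r.gene, r.direction) for r in catalog.for_family(drug_family)
    }  # dedup
    known = set(matrix.gene_ids)
    resp_genes = sorted({g for g, d in records if d == "response" and g in known})
    non_genes = sorted({g for g, d in records if d == "non-response" and g in known})
    skipped = len({g for g, _ in records}) - len(set(resp_genes) | set(non_genes))
    if skipped:
        logger.info("%d biomarker genes absent from matrix; ignored", skipped)
    scores = np.zeros(matrix.n_samples)
    any_altered = np.zeros(matrix.n_samples, dtype=bool)
    for gene in resp_genes:
        s = matrix.status[:, matrix.gene_index([gene])[0]].astype(float)
        scores += per_gene_baccs.get(gene, 0.0) * s
        any_altered |= s.astype(bool)
    for gene in non_genes:
        s = matrix.status[:, matrix.gene_index([gene])[0]].astype(float)
        scores -= per_gene_baccs.get(gene, 0.0) * s
        any_altered |= s.astype(bool)
    return scores, any_altered


def per_gene_biomarker_baccs(
    matrix: AlterationMatrix, arm: TreatmentArm, catalog: BiomarkerCatalog, drug_family: str
) -> dict[str, float]:
    """Balanced accuracy of each biomarker gene's naive call in this arm.

    A response biomarker predicts response when altered and non-response when
    not (non-response biomarkers invert); the BAcc is computed on the full
    arm, as a property of the biomarker itself.
    """
    labels = np.array(
        [RESPONSE if arm.binary_response[s] else NON_RESPONSE for s in arm.sample_ids]
    )
    sub = matrix.subset_samples(arm.sample_ids)
    out = {}
    for rec in catalog.for_family(drug_family):
        if rec.gene not in set(sub.gene_ids):
            continue
        s = sub.status[:, sub.gene_index([rec.gene])[0]].astype(bool)
        if rec.direction == "response":
            pred = np.where(s, RESPONSE, NON_RESPONSE)
        else:
            pred = np.where(s, NON_RESPONSE, RESPONSE)
        bacc = balanced_accuracy(labels, pred)
        if bacc is not None:
            out[rec.gene] = bacc
    return out


@dataclass
class FlavorModel:
    """One trained flavor classifier with its LOOCV evaluation."""

    flavor: str
    hyperparameters: Hyperparameters | None
    booster: xgb.Booster | None
    feature_genes: list[str]
    loocv_preds: np.ndarray | None
    loocv_probs: np.ndarray | None
    bacc: float | None
    mean_importances: dict[str, float] = field(default_factory=dict)
    status: str = "trained"  # or "no-features"


@dataclass
class TreatmentModelBundle:
    """The three flavor models for one arm plus the combined wComb scores."""

    treatment_id: str
    variant: str  # dco | biomarkers | dco+biomarkers
    sample_ids: list[str]
    labels: np.ndarray  # +1 / -1
    models: dict[str, FlavorModel]
    wcomb: np.ndarray
    predicted_class: np.ndarray  # sign(wComb); 0 = no call

    @property
    def combined_bacc(self) -> float | None:
        called = self.predicted_class != 0
        if not called.any():
            return None
        return balanced_accuracy(self.labels[called], self.predicted_class[called])

    def bacc_table(self) -> dict[str, float | None]:
        return {flavor: m.bacc for flavor, m in self.models.items()}


def train_flavor(
    features: pd.DataFrame,
    labels: np.ndarray,
    flavor: str,
    seed: int = 0,
    grid: HyperparameterGrid | None = None,
    hyperparameters: Hyperparameters | None = None,
    tune_iterations: int = 30,
) -> FlavorModel:
    """Tune (unless fixed hyperparameters are given), fit on the full arm,
    and evaluate by LOOCV.  Empty feature sets yield a 'no-features' model."""
    if features.shape[1] == 0:
        return FlavorModel(flavor, None, None, [], None, None, None, {}, "no-features")
    if hyperparameters is None:
        hp = tune_hyperparameters(
            features, labels, grid or HyperparameterGrid(), iterations=tune_iterations, seed=seed
        )
    else:
        hp = hyperparameters
    preds, probs, bacc, importances = loocv(features, labels, hp, seed)
    booster = fit_classifier(features, labels, hp, seed)
    return FlavorModel(flavor, hp, booster, list(features.columns), preds, probs, bacc, importances)


def train_bundle(
    matrix: AlterationMatrix,
    arm: TreatmentArm,
    networks: dict[str, DCONetwork],
    seed: int = 0,
    variant: str = "dco",
    extra_genes: list[str] | None = None,
    grid: HyperparameterGrid | None = None,
    hyperparameters: Hyperparameters | None = None,
    tune_iterations: int = 30,
) -> TreatmentModelBundle:
    """Train the three flavor classifiers for one arm and combine them.

    ``extra_genes`` (e.g. biomarker genes for the integrated variant) are
    appended to every flavor's feature set; the ``biomarkers`` variant is
    produced by passing empty networks plus the biomarker genes.
    """
    sample_ids = arm.sample_ids
    sub = matrix.subset_samples(sample_ids)
    labels = np.array([RESPONSE if arm.binary_response[s] else NON_RESPONSE for s in sample_ids])
    models: dict[str, FlavorModel] = {}
    for flavor, net in networks.items():
        feats = build_features(sub, net)
        if extra_genes:
            add = [g for g in sorted(set(extra_genes)) if g in set(sub.gene_ids) and g not in feats.columns]
            if add:
                idx = sub.gene_index(add)
                extra = pd.DataFrame(sub.status[:, idx].astype(np.int8), index=feats.index, columns=add)
                feats = pd.concat([feats, extra], axis=1)
            feats = feats.reindex(sorted(feats.columns), axis=1)
        models[flavor] = train_flavor(
            feats, labels, flavor, seed=seed, grid=grid,
            hyperparameters=hyperparameters, tune_iterations=tune_iterations,
        )
    preds = {f: m.loocv_preds for f, m in models.items()}
    probs = {f: m.loocv_probs for f, m in models.items()}
    baccs = {f: m.bacc for f, m in models.items()}
    if all(p is None for p in preds.values()):
        logger.warning("arm %s: no trainable flavor; every sample is a no-call", arm.treatment_id)
        wcomb = np.zeros(len(sample_ids))
    else:
        wcomb = combine_eq2(preds, probs, baccs)
    predicted = np.sign(wcomb).astype(int)
    return TreatmentModelBundle(arm.treatment_id, variant, sample_ids, labels, models, wcomb, predicted)


def train_variant(
    matrix: AlterationMatrix,
    arm: TreatmentArm,
    networks: dict[str, DCONetwork],
    variant: str = "dco",
    catalog: BiomarkerCatalog | None = None,
    drug_family: str | None = None,
    **kwargs,
) -> TreatmentModelBundle:
    """Run the identical pipeline with dco, biomarkers, or dco+biomarkers
    feature columns."""
    if variant == "dco":
        return train_bundle(matrix, arm, networks, variant=variant, **kwargs)
    if catalog is None or drug_family is None:
        raise ValueError(f"variant {variant!r} needs a biomarker catalog and drug family")
    bmk_genes = catalog.genes(drug_family)
    if variant == "biomarkers":
        from .network import DCONetwork as _Net

        empty = {f: _Net(arm.treatment_id, f) for f in networks}
        return train_bundle(matrix, arm, empty, variant=variant, extra_genes=bmk_genes, **kwargs)
    if variant == "dco+biomarkers":
        return train_bundle(matrix, arm, networks, variant=variant, extra_genes=bmk_genes, **kwargs)
    raise ValueError(f"unknown variant {variant!r}")


def evaluate_collection(
    bundles: list[TreatmentModelBundle], high_confidence: float = 0.6
) -> tuple[pd.DataFrame, float | None, list[str]]:
    """Per-treatment combined BAcc table, macro-average, and the subset of
    treatments meeting the high-confidence cutoff."""
    rows = []
    for b in bundles:
        rows.append({"treatment_id": b.treatment_id, "variant": b.variant, "bacc": b.combined_bacc})
    table = pd.DataFrame(rows)
    if table.empty or table["bacc"].dropna().empty:
        logger.warning("no treatment arm yielded a defined balanced accuracy")
        return table, None, []
    defined = table.dropna(subset=["bacc"])
    skipped = len(table) - len(defined)
    if skipped:
        logger.info("%d arms with undefined BAcc excluded from macro-average", skipped)
    macro = float(defined["bacc"].mean())
    high = defined.loc[defined["bacc"] >= high_confidence, "treatment_id"].tolist()
    return table, macro, high
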