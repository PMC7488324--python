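"""Model interpretation: additive (Shapley) explanations, pairwise
interaction summaries, genomic-linkage annotation, and the biomarker-overlap
enrichment test.

Per-sample, per-gene contributions come from the tree ensemble's native
TreeSHAP computation; together with the base value they sum exactly to the
model's margin output.  Pairwise interaction strengths use the SHAP
interaction decomposition.  For a co-occurring pair (A, B), samples are
split into the four status categories (A&B, A&!B, !A&B, !A&!B) and each
gene's mean contribution is reported per category, with a ``linked`` flag
when both genes map to the same chromosome arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .cohort_io import GeneCoordinates

__all__ = [
    "ExplanationTable",
    "InteractionSummary",
    "explain",
    "rank_interactions",
    "interaction_summary",
    "biomarker_overlap_fisher",
]

CATEGORIES = ("both", "a_only", "b_only", "neither")


@dataclass
class ExplanationTable:
    """Additive per-sample feature contributions on the margin (log-odds) scale."""

    sample_ids: list[str]
    feature_genes: list[str]
    contributions: np.ndarray  # (n_samples, n_features)
    base_value: float
    margins: np.ndarray  # model margin output per sample

    def __post_init__(self) -> None:
        resid = np.abs(
            self.base_value + self.contributions.sum(axis=1) - self.margins
        )
        if resid.size and resid.max() > 1e-5:
            raise AssertionError(
                f"explanations violate additivity (max residual {resid.max():.3g})"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sample_ids):
            for j, g in enumerate(self.feature_genes):
                rows.append({"sample": s, "gene": g, "contribution": self.contributions[i, j]})
        return pd.DataFrame(rows)

    def mean_by_status(self, features: pd.DataFrame, gene: str) -> dict[str, float]:
        """Mean contribution of ``gene`` among altered vs unaltered samples."""
        j = self.feature_genes.index(gene)
        altered = features[gene].to_numpy(dtype=bool)
        return {
            "altered": float(self.contributions[altered, j].mean()) if altered.any() else np.nan,
            "unaltered": float(self.contributions[~altered, j].mean()) if (~altered).any() else np.nan,
        }


def explain(booster: xgb.Booster, features: pd.DataFrame) -> ExplanationTable:
    """TreeSHAP additive explanations for every sample in ``features``."""
    if booster.feature_names != list(features.columns):
        raise ValueError("feature columns do not match the trained model")
    dm = xgb.DMatrix(features.to_numpy(dtype=np.float32), feature_names=list(features.columns))
    contrib = booster.predict(dm, pred_contribs=True).astype(np.float64)
    margins = booster.predict(dm, output_margin=True).astype(np.float64)
    base = float(contrib[0, -1]) if len(contrib) else 0.0
    return ExplanationTable(
        [str(s) for s in features.index],
        list(features.columns),
        contrib[:, :-1],
        base,
        margins,
    )


def margin_float64(booster: xgb.Booster, features: pd.DataFrame) -> np.ndarray:
    """Exact double-precision margin: per-tree leaf values summed in float64.

    The fast margin prediction accumulates ~100 leaf values in float32; for
    additivity checks at tight tolerances this independent evaluation of the
    dumped trees avoids that accumulation error.
    """
    import json

    trees = [json.loads(t) for t in booster.get_dump(dump_format="json")]
    names = booster.feature_names

    def leaf_value(tree: dict, x: dict) -> float:
        while "leaf" not in tree:
            children = {c["nodeid"]: c for c in tree["children"]}
            branch = tree["yes"] if x[tree["split"]] < tree["split_condition"] else tree["no"]
            tree = children[branch]
        return float(tree["leaf"])

    out = np.zeros(len(features))
    for i in range(len(features)):
        x = dict(zip(names, features.iloc[i].astype(np.float32)))
        out[i] = sum(leaf_value(t, x) for t in trees)
    return out


def shap_interaction_values(booster: xgb.Booster, features: pd.DataFrame) -> np.ndarray:
    """(n_samples, n_features+1, n_features+1) SHAP interaction tensor
    (last row/column is the bias term)."""
    dm = xgb.DMatrix(features.to_numpy(dtype=np.float32), feature_names=list(features.columns))
    return booster.predict(dm, pred_interactions=True).astype(np.float64)


def rank_interactions(
    booster: xgb.Booster, features: pd.DataFrame
) -> list[tuple[str, str, float]]:
    """Feature pairs ordered by interaction strength (descending).

    Strength is the mean absolute SHAP interaction value of the off-diagonal
    entry across samples; ties break lexicographically on the pair.
    """
    inter = shap_interaction_values(booster, features)
    genes = list(features.columns)
    k = len(genes)
    strength = np.abs(inter[:, :k, :k]).mean(axis=0)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = sorted((genes[i], genes[j]))
            out.append((a, b, float(strength[i, j] + strength[j, i])))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


@dataclass
class InteractionSummary:
    gene_a: str
    gene_b: str
    strength: float
    mean_contrib_a: dict[str, float]  # per status category; NaN when empty
    mean_contrib_b: dict[str, float]
    category_sizes: dict[str, int]
    linked: bool | None = None
    distance_bp: int | None = None


def interaction_summary(
    explanations: ExplanationTable,
    features: pd.DataFrame,
    pair: tuple[str, str],
    coordinates: GeneCoordinates | None = None,
    strength: float = float("nan"),
) -> InteractionSummary:
    """Four-category contribution summary for one driver pair.

    Shows the effect of having an alteration in gene A on the contribution of
    gene B (and vice versa): mean contributions within A&B, A&!B, !A&B and
    !A&!B, with category sizes.  Empty categories report NaN means.
    """
    gene_a, gene_b = pair
    for g in pair:
        if g not in explanations.feature_genes:
            raise ValueError(f"{g} not among explained features")
    ja = explanations.feature_genes.index(gene_a)
    jb = explanations.feature_genes.index(gene_b)
    sa = features[gene_a].to_numpy(dtype=bool)
    sb = features[gene_b].to_numpy(dtype=bool)
    masks = {
        "both": sa & sb,
        "a_only": sa & ~sb,
        "b_only": ~sa & sb,
        "neither": ~sa & ~sb,
    }
    sizes = {c: int(m.sum()) for c, m in masks.items()}
    assert sum(sizes.values()) == len(features)
    mean_a = {
        c: float(explanations.contributions[m, ja].mean()) if m.any() else float("nan")
        for c, m in masks.items()
    }
    mean_b = {
        c: float(explanations.contributions[m, jb].mean()) if m.any() else float("nan")
        for c, m in masks.items()
    }
    linked = coordinates.same_arm(gene_a, gene_b) if coordinates is not None else None
    dist = coordinates.distance_bp(gene_a, gene_b) if coordinates is not None else None
    return InteractionSummary(gene_a, gene_b, strength, mean_a, mean_b, sizes, linked, dist)


def biomarker_overlap_fisher(
    n_overlap: int, n_biomarker_assoc: int, n_dco_assoc: int, n_universe: int
) -> dict[str, float]:
    """Fisher's exact test for the overlap between two sets of drug-driver
    associations within a common universe of eligible pairs.

    The 2x2 table is (a = overlap, b = network-only, c = biomarker-only,
    d = remainder).  Returns the sample odds ratio (ad/bc), the conditional
    maximum-likelihood odds ratio, and the two-sided p-value.
    """
    a = n_overlap
    b = n_dco_assoc - n_overlap
    c = n_biomarker_assoc - n_overlap
    d = n_universe - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent counts: negative cell in the 2x2 table")
    table = np.array([[a, b], [c, d]])
    _, p = fisher_exact(table, alternative="two-sided")
    sample_or = (a * d) / (b * c) if b * c > 0 else float("inf")
    cmle_or = float(_odds_ratio(table).statistic)
    return {"sample_odds_ratio": float(sample_or), "cmle_odds_ratio": cmle_or, "p_value": float(p)}
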