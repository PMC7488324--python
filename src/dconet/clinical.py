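"""Adaptation to continuous clinical outcomes (treatment duration / PFS).

Instead of binary tumor-volume response calls, patients are partitioned into
duration tertiles: the shortest-benefit third becomes the non-responder
group, the longest third the responder group, and the middle third is left
unlabeled.  The standard pipeline (differential drivers, co-occurring pairs,
networks, classifiers) then runs on the two extreme groups; unlabeled
patients receive scores at prediction time only.  Confidence thresholds on
the combined score are chosen per side to bound the false discovery rate in
the LOOCV, and predicted groups are evaluated with Kaplan-Meier / log-rank /
Cox survival analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .cohort_io import AlterationMatrix, OutcomeTable, TreatmentArm
from .diff_drivers import DiffThresholds, select_diffd
from .driver_pairs import build_null, select_pairs
from .models import TreatmentModelBundle, train_bundle
from .network import build_networks

logger = logging.getLogger(__name__)

__all__ = [
    "TertileLabeling",
    "ConfidenceThresholds",
    "tertile_labels",
    "fit_continuous",
    "select_confidence_thresholds",
    "survival_evaluation",
]

NO_CONFIDENT_CALLS = "no confident calls"


@dataclass
class TertileLabeling:
    """Extreme-tertile labels: True = responder (longest benefit),
    False = non-responder (shortest), None = unlabeled middle third."""

    patient_ids: list[str]
    labels: list[bool | None]
    lower_cutoff: float
    upper_cutoff: float

    @property
    def responders(self) -> list[str]:
        return [p for p, l in zip(self.patient_ids, self.labels) if l is True]

    @property
    def non_responders(self) -> list[str]:
        return [p for p, l in zip(self.patient_ids, self.labels) if l is False]

    @property
    def unlabeled(self) -> list[str]:
        return [p for p, l in zip(self.patient_ids, self.labels) if l is None]


def tertile_labels(outcomes: OutcomeTable) -> TertileLabeling:
    """Partition patients into three equally sized duration groups.

    The shortest third are non-responders, the longest third responders; the
    cutoffs are the boundary order statistics.  Duration values tied across a
    boundary are resolved toward the middle (unlabeled) group; if everything
    ties, all patients stay unlabeled.
    """
    n = len(outcomes)
    if n < 9:
        raise ValueError("need at least 9 patients to form tertiles")
    durations = outcomes.durations
    order = np.argsort(durations, kind="stable")
    n_grp = n // 3
    labels: list[bool | None] = [None] * n
    low_ids = order[:n_grp]
    high_ids = order[n - n_grp :]
    lower_cutoff = float(durations[low_ids].max())
    upper_cutoff = float(durations[high_ids].min())
    if lower_cutoff > upper_cutoff:  # massive ties across the middle
        warnings.warn("duration ties prevent a clean tertile split; all unlabeled")
        return TertileLabeling(list(outcomes.patient_ids), labels, lower_cutoff, lower_cutoff)
    mid = set(order[n_grp : n - n_grp])
    mid_values = {durations[i] for i in mid}
    for i in low_ids:
        if durations[i] in mid_values and durations[i] == lower_cutoff:
            continue  # tie with the middle group -> unlabeled
        labels[i] = False
    for i in high_ids:
        if durations[i] in mid_values and durations[i] == upper_cutoff:
            continue
        labels[i] = True
    if not any(l is not None for l in labels):
        warnings.warn("duration ties left every patient unlabeled")
    return TertileLabeling(list(outcomes.patient_ids), labels, lower_cutoff, upper_cutoff)


def fit_continuous(
    matrix: AlterationMatrix,
    labeling: TertileLabeling,
    treatment_id: str = "continuous",
    thresholds: DiffThresholds = DiffThresholds(),
    n_permutations: int = 1000,
    seed: int = 0,
    min_group: int = 5,
    **train_kwargs,
) -> tuple[TreatmentModelBundle, dict]:
    """Run the full binary pipeline on the two extreme tertile groups.

    Middle-third patients never enter network inference or training folds;
    they are scored only at prediction time.  Returns the trained bundle and
    the inferred networks.
    """
    resp, non = labeling.responders, labeling.non_responders
    if len(resp) < min_group or len(non) < min_group:
        raise ValueError(
            f"extreme groups too small ({len(resp)} / {len(non)}; need >= {min_group})"
        )
    arm = TreatmentArm(
        treatment_id,
        {**{p: True for p in resp}, **{p: False for p in non}},
    )
    sub = matrix.subset_samples(arm.sample_ids)
    diffd = select_diffd(sub, arm, thresholds)
    null = build_null(sub, n_permutations=n_permutations, seed=seed)
    pairs = select_pairs(sub, arm, null, thresholds)
    networks = build_networks(diffd, pairs, treatment_id)
    bundle = train_bundle(matrix.subset_samples(arm.sample_ids), arm, networks, seed=seed, **train_kwargs)
    return bundle, networks


@dataclass
class ConfidenceThresholds:
    """Score thresholds bounding the LOOCV false discovery rate per side.

    Scores above ``upper`` are confident response calls; scores below
    ``lower`` are confident non-response calls.  ``status`` is the sentinel
    string when no threshold attains the bound on either side.
    """

    upper: float | None
    lower: float | None
    fdr_response: float | None
    fdr_non_response: float | None
    max_fdr: float
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.upper is not None and self.lower is not None and self.upper < self.lower:
            raise ValueError("upper threshold must be >= lower threshold")

    def call(self, scores: np.ndarray) -> np.ndarray:
        """+1 / -1 / 0 (no call) per score."""
        scores = np.asarray(scores, dtype=float)
        out = np.zeros(len(scores), dtype=int)
        if self.upper is not None:
            out[scores > self.upper] = 1
        if self.lower is not None:
            out[scores < self.lower] = -1
        return out


def _side_threshold(scores, is_true_positive, max_fdr, side):
    """Least extreme threshold whose labeled-LOOCV FDR is within the bound.

    Candidates stay on the natural side of the wComb decision boundary:
    response thresholds are positive, non-response thresholds negative, so a
    confident call always agrees with the sign of the combined score.
    """
    uniq = np.unique(scores)
    best = None
    best_fdr = None
    if side == "upper":
        candidates = sorted(u for u in uniq if u > 0)
    else:
        candidates = sorted((u for u in uniq if u < 0), reverse=True)
    for t in candidates:
        if side == "upper":
            called = scores >= t
        else:
            called = scores <= t
        n_called = int(called.sum())
        if n_called == 0:
            continue
        fdr = float((~is_true_positive[called]).mean())
        if fdr <= max_fdr:
            # thresholds are exclusive bounds placed just outside the called set
            eps = 1e-9
            bound = t - eps if side == "upper" else t + eps
            if best is None or (side == "upper" and bound < best) or (
                side == "lower" and bound > best
            ):
                best, best_fdr = bound, fdr
    return best, best_fdr


def select_confidence_thresholds(
    loocv_scores: np.ndarray,
    labels: np.ndarray,
    max_fdr: float = 0.30,
) -> ConfidenceThresholds:
    """Scan score thresholds independently per side so that each side's
    false discovery rate among labeled patients stays within ``max_fdr``.

    ``labels`` are +1 / -1 for the labeled extreme-tertile patients whose
    LOOCV scores are supplied; unlabeled patients are excluded from the FDR
    bookkeeping.  The least extreme qualifying thresholds are chosen, which
    maximizes coverage; when a side has no qualifying threshold the sentinel
    status is returned for it.
    """
    scores = np.asarray(loocv_scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must align")
    upper, fdr_up = _side_threshold(scores, labels == 1, max_fdr, "upper")
    lower, fdr_lo = _side_threshold(scores, labels == -1, max_fdr, "lower")
    if upper is not None and lower is not None and upper < lower:
        # keep the side with better achieved FDR; drop the other
        if (fdr_up or 0) <= (fdr_lo or 0):
            lower, fdr_lo = None, None
        else:
            upper, fdr_up = None, None
    status = "ok" if (upper is not None or lower is not None) else NO_CONFIDENT_CALLS
    if status == NO_CONFIDENT_CALLS:
        logger.warning("no score threshold attains FDR <= %.2f on either side", max_fdr)
    return ConfidenceThresholds(upper, lower, fdr_up, fdr_lo, max_fdr, status)


def survival_evaluation(
    predicted_groups: np.ndarray,
    durations: np.ndarray,
    events: np.ndarray,
    scores: np.ndarray | None = None,
    min_group: int = 5,
) -> dict:
    """Kaplan-Meier / log-rank comparison of two predicted groups plus an
    optional Cox fit of the event hazard on the continuous score.

    ``predicted_groups`` holds +1 / -1 calls (0 = no call, excluded).  Fully
    censored groups report their median as not-reached (inf).
    """
    predicted_groups = np.asarray(predicted_groups, dtype=int)
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    called = predicted_groups != 0
    g = predicted_groups[called]
    d = durations[called]
    e = events[called]
    n_pos, n_neg = int((g == 1).sum()), int((g == -1).sum())
    if n_pos < min_group or n_neg < min_group:
        raise ValueError(
            f"need >= {min_group} members per predicted group (got {n_pos}/{n_neg})"
        )
    medians = {}
    for grp, name in ((1, "predicted_response"), (-1, "predicted_non_response")):
        km = KaplanMeierFitter()
        km.fit(d[g == grp], e[g == grp])
        medians[name] = float(km.median_survival_time_)
    lr = logrank_test(d[g == 1], d[g == -1], e[g == 1], e[g == -1])
    out = {
        "median_months": medians,
        "logrank_statistic": float(lr.test_statistic),
        "logrank_p": float(lr.p_value),
        "n_groups": {"predicted_response": n_pos, "predicted_non_response": n_neg},
    }
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        df = pd.DataFrame({"duration": durations, "event": events, "score": scores})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="duration", event_col="event")
        out["cox_coef_score"] = float(cph.params_["score"])
        out["cox_p_score"] = float(cph.summary.loc["score", "p"])
    return out
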