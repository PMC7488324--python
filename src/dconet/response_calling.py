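"""Tumor-volume response calling: caliper volumes, mRECIST classes, binary labels.

Follows the modified RECIST convention used in large PDX drug screens: per
model x treatment trajectory, the percent change from baseline
``dVol_t = (V_t - V_i) / V_i * 100`` is summarized into

* BestResponse — the minimum ``dVol_t`` at or after ``min_day`` days, and
* BestAverageResponse — the minimum, over evaluation times at or after
  ``min_day``, of the running mean of ``dVol`` across all post-baseline
  observations up to that time,

which are mapped onto the ordered classes CR > PR > SD > PD.  PD models are
non-responders; CR/PR/SD are responders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VolumeSeries",
    "ResponseCall",
    "AxisOrderError",
    "InsufficientFollowUpError",
    "volume_from_caliper",
    "pct_change_series",
    "best_response",
    "best_average_response",
    "mrecist_classify",
    "binarize_response",
    "arm_eligible",
    "call_response",
    "read_volumes",
    "calls_to_frame",
]

MRECIST_CLASSES = ("CR", "PR", "SD", "PD")


class AxisOrderError(ValueError):
    """Raised when the caliper minor axis exceeds the major axis."""


class InsufficientFollowUpError(ValueError):
    """Raised when a trajectory has no observation at/after the minimum day."""


@dataclass
class VolumeSeries:
    """One tumor-volume trajectory (model x treatment)."""

    model_id: str
    treatment_id: str
    days: np.ndarray
    volumes: np.ndarray  # mm^3

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.days.shape != self.volumes.shape or self.days.ndim != 1:
            raise ValueError("days and volumes must be 1-D and aligned")
        if len(self.days) == 0:
            raise ValueError("empty volume series")
        if (np.diff(self.days) <= 0).any():
            raise ValueError("days must be strictly increasing")
        if self.days[0] < 0:
            raise ValueError("days must be non-negative")
        if (self.volumes <= 0).any():
            raise ValueError("volumes must be > 0")

    @property
    def baseline(self) -> float:
        """Baseline volume V_i: the earliest (ideally day-0) observation."""
        return float(self.volumes[0])


@dataclass
class ResponseCall:
    model_id: str
    treatment_id: str
    best_response: float
    best_average_response: float
    mrecist_class: str
    binary_response: bool  # True = responder

    def __post_init__(self) -> None:
        if self.mrecist_class not in MRECIST_CLASSES:
            raise ValueError(f"bad mRECIST class {self.mrecist_class!r}")
        if self.binary_response != (self.mrecist_class != "PD"):
            raise ValueError("binary response must be non-responder iff PD")


def volume_from_caliper(l: float, w: float) -> float:
    """Ellipsoid-approximation tumor volume from caliper axes: l * w^2 * pi/6.

    ``l`` is the major and ``w`` the minor tumor axis, in mm.
    """
    if w > l:
        raise AxisOrderError(f"minor axis w={w} exceeds major axis l={l}")
    if w < 0:
        raise ValueError("axes must be non-negative")
    return l * w * w * math.pi / 6.0


def pct_change_series(series: VolumeSeries) -> np.ndarray:
    """Percent change from baseline for every observation (baseline -> 0)."""
    v0 = series.baseline
    if v0 == 0:
        raise ValueError("degenerate baseline volume of 0")
    return (series.volumes - v0) / v0 * 100.0


def best_response(series: VolumeSeries, min_day: float = 10.0) -> float:
    """Minimum percent volume change over observations at/after ``min_day``."""
    dvol = pct_change_series(series)
    mask = series.days >= min_day
    if not mask.any():
        raise InsufficientFollowUpError(
            f"{series.model_id}/{series.treatment_id}: no observation at day >= {min_day}"
        )
    return float(dvol[mask].min())


def best_average_response(series: VolumeSeries, min_day: float = 10.0) -> float:
    """Minimum running mean of percent volume change, evaluated at/after ``min_day``.

    The running mean at time t averages dVol over all post-baseline
    observations up to and including t (the baseline's dVol = 0 is excluded).
    Observations before ``min_day`` feed the running means but are never
    themselves candidate evaluation times.
    """
    dvol = pct_change_series(series)
    post = series.days > series.days[0]
    days_post = series.days[post]
    dvol_post = dvol[post]
    eligible = days_post >= min_day
    if not eligible.any():
        raise InsufficientFollowUpError(
            f"{series.model_id}/{series.treatment_id}: no observation at day >= {min_day}"
        )
    running = np.cumsum(dvol_post) / np.arange(1, len(dvol_post) + 1)
    return float(running[eligible].min())


def mrecist_classify(best_resp: float, best_avg_resp: float) -> str:
    """Ordered-rule mRECIST classification; the first matching class wins.

    CR: best < -95 and avg < -40; PR: best < -50 and avg < -20;
    SD: best < 35 and avg < 30; anything else falls through to PD.
    """
    if not (math.isfinite(best_resp) and math.isfinite(best_avg_resp)):
        raise ValueError("response summaries must be finite")
    if best_resp < -95 and best_avg_resp < -40:
        return "CR"
    if best_resp < -50 and best_avg_resp < -20:
        return "PR"
    if best_resp < 35 and best_avg_resp < 30:
        return "SD"
    return "PD"


def binarize_response(mrecist_class: str) -> bool:
    """True (responder) for CR/PR/SD, False (non-responder) for PD."""
    if mrecist_class not in MRECIST_CLASSES:
        raise ValueError(f"bad mRECIST class {mrecist_class!r}")
    return mrecist_class != "PD"


def arm_eligible(n_responders: int, n_non_responders: int, min_group: int = 5) -> bool:
    """An arm is modelable when both response groups have >= min_group samples."""
    return n_responders >= min_group and n_non_responders >= min_group


def call_response(series: VolumeSeries, min_day: float = 10.0) -> ResponseCall:
    """Full per-trajectory response call (summaries, class, binary label)."""
    br = best_response(series, min_day)
    bar = best_average_response(series, min_day)
    cls = mrecist_classify(br, bar)
    return ResponseCall(series.model_id, series.treatment_id, br, bar, cls, binarize_response(cls))


def read_volumes(path) -> list[VolumeSeries]:
    """Read trajectories from CSV.

    Requires columns model_id, treatment_id, day and either volume_mm3 or the
    caliper axes l_mm, w_mm (which trigger the ellipsoid conversion).
    """
    df = pd.read_csv(path, comment="#")
    if "volume_mm3" in df.columns:
        vol = df["volume_mm3"].to_numpy(float)
    elif {"l_mm", "w_mm"} <= set(df.columns):
        vol = np.array(
            [volume_from_caliper(l, w) for l, w in zip(df["l_mm"], df["w_mm"])]
        )
    else:
        raise ValueError(f"{path}: need volume_mm3 or l_mm/w_mm columns")
    df = df.assign(_vol=vol)
    out = []
    for (model, treatment), grp in df.groupby(["model_id", "treatment_id"], sort=True):
        grp = grp.sort_values("day")
        out.append(
            VolumeSeries(str(model), str(treatment), grp["day"].to_numpy(float), grp["_vol"].to_numpy(float))
        )
    return out


def calls_to_frame(calls: list[ResponseCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model_id": [c.model_id for c in calls],
            "treatment_id": [c.treatment_id for c in calls],
            "best_response": [c.best_response for c in calls],
            "best_average_response": [c.best_average_response for c in calls],
            "mrecist_class": [c.mrecist_class for c in calls],
            "binary_response": [int(c.binary_response) for c in calls],
        }
    )
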