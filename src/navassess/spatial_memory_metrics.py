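"""Per-trial recall error in polar coordinates and per-cell aggregation.

Recall accuracy is expressed relative to the encoding item location (the
origin): ``r`` is the Euclidean distance (virtual units) between the encoding
and the recalled location, and ``theta`` the angle (degrees) of the
displacement vector.  The angle's zero direction is the environment +x axis,
counter-clockwise positive, range [0, 360); since theta is equivariant under
rotations only the internal consistency of this convention matters.  A recall
is classified correct when r is within the task's feedback radius (6 virtual
units, boundary inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import InputError
from .session_io import TrialRecord

#: task feedback radius in virtual units ("congratulations" iff r <= 6)
CORRECT_RADIUS = 6.0


@dataclass(frozen=True)
class PolarError:
    """Recall error as (r, theta); ``theta_deg`` is None when r = 0."""

    r: float
    theta_deg: float | None

    def __post_init__(self):
        if (self.r == 0.0) != (self.theta_deg is None):
            raise InputError("theta_deg must be None iff r == 0")


def polar_error(
    enc: tuple[float, float],
    rec: tuple[float, float],
    direction: str = "encoding_to_recall",
) -> PolarError:
    """Polar recall error of one trial.

    ``direction`` selects which displacement defines theta: the default
    ``"encoding_to_recall"`` uses rec - enc; ``"recall_to_encoding"`` flips it
    (the two differ by exactly 180 degrees).  r is unaffected.
    """
    ex, ez = enc
    rx, rz = rec
    if not all(math.isfinite(v) for v in (ex, ez, rx, rz)):
        raise InputError(f"non-finite coordinates enc={enc} rec={rec}")
    if direction not in ("encoding_to_recall", "recall_to_encoding"):
        raise InputError(f"unknown angle direction {direction!r}")
    dx, dz = rx - ex, rz - ez
    if direction == "recall_to_encoding":
        dx, dz = -dx, -dz
    r = math.hypot(dx, dz)
    if r == 0.0:
        return PolarError(r=0.0, theta_deg=None)
    theta = math.degrees(math.atan2(dz, dx)) % 360.0
    return PolarError(r=r, theta_deg=theta)


def classify_recall(err: PolarError, radius: float = CORRECT_RADIUS) -> bool:
    """True iff the recall lies within ``radius`` of the item (inclusive)."""
    if not radius > 0:
        raise InputError(f"radius must be positive, got {radius}")
    return err.r <= radius


def trials_to_frame(
    trials: Iterable[TrialRecord],
    direction: str = "encoding_to_recall",
    radius: float = CORRECT_RADIUS,
) -> pd.DataFrame:
    """Long-format trial table with r, theta and correctness per trial.

    ``theta_deg`` is NaN where r = 0.  This is the shared input of the cell
    summaries and the trial-level ANOVA.
    """
    rows = []
    for t in trials:
        err = polar_error((t.enc_x, t.enc_z), (t.rec_x, t.rec_z), direction=direction)
        rows.append(
            {
                "participant_id": t.participant_id,
                "condition": t.condition,
                "landmark": t.landmark,
                "item_id": t.item_id,
                "repetition": t.repetition,
                "r": err.r,
                "theta_deg": np.nan if err.theta_deg is None else err.theta_deg,
                "correct": classify_recall(err, radius=radius),
                "recall_latency_s": t.recall_latency,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "condition", "landmark", "item_id", "repetition",
            "r", "theta_deg", "correct", "recall_latency_s",
        ],
    )


def _sd(x: np.ndarray) -> float:
    # sample SD (n-1); undefined below 2 observations
    return float(np.std(x, ddof=1)) if x.size >= 2 else float("nan")


def summarize_errors(
    trials: Iterable[TrialRecord] | pd.DataFrame,
    direction: str = "encoding_to_recall",
    angle: str = "arithmetic",
) -> pd.DataFrame:
    """Per (landmark x condition) cell: mean/SD of r and of theta.

    Trials with r = 0 have no defined angle and are excluded from the angle
    aggregates only.  ``angle="arithmetic"`` takes the plain mean/SD of the
    degree values (matching the study's reported layout); ``angle="circular"``
    uses the circular mean and circular SD instead.
    """
    if angle not in ("arithmetic", "circular"):
        raise InputError(f"unknown angle aggregation {angle!r}")
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials, direction)
    cols = ["landmark", "condition", "n_trials", "mean_r", "sd_r", "n_theta", "mean_theta", "sd_theta"]
    if df.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for (lm, cond), sub in df.groupby(["landmark", "condition"], sort=True):
        r = sub["r"].to_numpy(dtype=float)
        th = sub["theta_deg"].to_numpy(dtype=float)
        th = th[np.isfinite(th)]
        if th.size == 0:
            mean_th = sd_th = float("nan")
        elif angle == "arithmetic":
            mean_th, sd_th = float(np.mean(th)), _sd(th)
        else:
            mean_th = float(stats.circmean(th, high=360.0, low=0.0))
            sd_th = float(stats.circstd(th, high=360.0, low=0.0)) if th.size >= 2 else float("nan")
        rows.append(
            {
                "landmark": lm,
                "condition": cond,
                "n_trials": int(r.size),
                "mean_r": float(np.mean(r)) if r.size else float("nan"),
                "sd_r": _sd(r),
                "n_theta": int(th.size),
                "mean_theta": mean_th,
                "sd_theta": sd_th,
            }
        )
    return pd.DataFrame(rows, columns=cols)
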