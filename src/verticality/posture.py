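"""Rigid-body center-of-pressure checks and the counteraction slope.

If a standing body were rigid on the platform, tilting the platform by
``phi`` would shift the lateral COP by ``h_com * tan(phi)`` (COM height
``h_com``, about half body height).  Regressing the measured COP on this
expectation gives a slope of 1 for a rigid body; a slope below 1 means
participants counteracted part of the tilt with their ankles, and
``1 - slope`` is the counteracted fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PostureParams",
    "expected_cop_shift",
    "cop_shift_to_tilt",
    "counteraction_slope",
    "cohort_counteraction",
]


@dataclass(frozen=True)
class PostureParams:
    body_height_m: float
    com_height_m: float | None = None

    def __post_init__(self) -> None:
        if self.body_height_m <= 0:
            raise ValueError("body_height_m must be positive")
        if self.com_height_m is not None and not (0 < self.com_height_m <= self.body_height_m):
            raise ValueError("com_height_m must lie in (0, body_height_m]")

    @property
    def com_m(self) -> float:
        return self.com_height_m if self.com_height_m is not None else self.body_height_m / 2.0


def expected_cop_shift(com_height_m: float, platform_tilt_deg) -> np.ndarray | float:
    """Lateral COP shift (cm) of a rigid body for a given platform tilt."""
    if com_height_m <= 0:
        raise ValueError("com_height_m must be positive")
    tilt = np.asarray(platform_tilt_deg, dtype=float)
    if np.any(np.abs(tilt) >= 90.0):
        raise ValueError("platform tilt must lie strictly inside (-90, 90) degrees")
    out = 100.0 * com_height_m * np.tan(np.radians(tilt))
    return float(out) if out.ndim == 0 else out


def cop_shift_to_tilt(shift_cm, com_height_m: float) -> np.ndarray | float:
    """Body tilt (deg) implied by a lateral COP shift at a given COM height."""
    if com_height_m <= 0:
        raise ValueError("com_height_m must be positive")
    out = np.degrees(np.arctan(np.asarray(shift_cm, dtype=float) / (100.0 * com_height_m)))
    return float(out) if out.ndim == 0 else out


def counteraction_slope(measured_cop, expected_cop) -> tuple[float, float]:
    """OLS slope and intercept of measured on rigid-body-expected COP."""
    x = np.asarray(expected_cop, dtype=float)
    y = np.asarray(measured_cop, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length series with at least two points")
    if np.ptp(x) == 0:
        raise ValueError("expected COP series is constant; slope is undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept)


def cohort_counteraction(trials: pd.DataFrame,
                         com_height_m: float = 0.93,
                         task: str = "RFT",
                         head_upright_only: bool = True) -> dict:
    """Pooled counteraction slope for a cohort's trial table.

    Uses the given task's trials (head-upright by default, matching the
    condition in which the platform tilt is actually held).  Measured and
    expected series are centered within participant before pooling, so
    between-participant COP offsets (stance, harness) do not bias the slope.
    """
    sel = trials[(trials["task"] == task) & trials["cop_y_cm"].notna()]
    if head_upright_only:
        sel = sel[~sel["head_tilted"]]
    if sel.empty:
        raise ValueError("no usable COP trials for the requested selection")
    xs, ys, per_participant = [], [], {}
    for pid, grp in sel.groupby("participant_id"):
        exp = expected_cop_shift(com_height_m, grp["platform_tilt_deg"].to_numpy())
        mea = grp["cop_y_cm"].to_numpy()
        exp_c, mea_c = exp - exp.mean(), mea - mea.mean()
        xs.append(exp_c)
        ys.append(mea_c)
        if np.ptp(exp_c) > 0:
            s, _ = counteraction_slope(mea_c, exp_c)
            per_participant[pid] = s
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    slope, intercept = counteraction_slope(y, x)
    return {
        "slope": slope,
        "intercept": intercept,
        "counteracted_fraction": 1.0 - slope,
        "n": int(x.size),
        "per_participant_slopes": per_participant,
    }
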