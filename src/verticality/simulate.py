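"""Synthetic experiment generator: design tables, responses, COP, cohorts.

The generator reproduces the study's crossed within-participant design —
7 camera-tilt levels x 3 platform-tilt levels, run once with the head
upright (3 repetitions per cell) and once with the head tilted on a collar
(2 repetitions), for each of the two tasks (RFT, SPV) — and samples
responses from the observer model's Gaussian predictive distributions.
Lateral center-of-pressure (COP) values follow a static rigid-body model
with a counteraction gain on platform tilt and a small visually induced
lean; sway dynamics are deliberately not modeled.

Trial tables are plain pandas DataFrames with one row per trial
(the ``TRIAL_COLUMNS`` schema); ground truth comes back as a parallel
parameter table so recovery tests can score the fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import (
    ModelVariant,
    ParticipantParameters,
    predict_response_arrays,
)
from .reference import MEDIAN_PARAMS

__all__ = [
    "DesignSpec",
    "CohortSpec",
    "TRIAL_COLUMNS",
    "EXCLUSION_REASONS",
    "build_design",
    "sample_responses",
    "sample_cop",
    "make_cohort",
]

#: Canonical column order of a trial table.
TRIAL_COLUMNS = [
    "participant_id", "task", "block", "platform_tilt_deg", "head_tilted",
    "ar_tilt_deg", "response_deg", "cop_y_cm", "valid", "exclusion_reason",
]

EXCLUSION_REASONS = ("none", "training", "mistake", "cop_quality")

#: Height of a participant whose center of mass sits at 0.93 m (m).
DEFAULT_BODY_HEIGHT_M = 1.86

#: Fraction of a platform tilt that survives as actual body tilt; the study
#: found standing participants counteracted platform tilt by about 27%.
DEFAULT_COUNTERACTION_GAIN = 0.73

#: Body lean per degree of camera tilt (deg/deg), negative: participants lean
#: against the visually suggested head tilt.  Calibrated so that a 36 deg
#: camera tilt produces about a -0.5 cm COP shift at a 0.93 m center of mass.
DEFAULT_VISUAL_LEAN = -math.degrees(math.atan(0.5 / 93.0)) / 36.0

DEFAULT_COP_NOISE_SD_CM = 0.3


@dataclass(frozen=True)
class DesignSpec:
    """Factor levels and repetition counts of the crossed design."""

    ar_levels: tuple[float, ...] = (-36.0, -13.0, -5.0, 0.0, 5.0, 13.0, 36.0)
    platform_levels: tuple[float, ...] = (-3.0, 0.0, 3.0)
    reps_upright: int = 3
    reps_tilted: int = 2
    tasks: tuple[str, ...] = ("RFT", "SPV")

    def __post_init__(self) -> None:
        if not self.ar_levels or not self.platform_levels:
            raise ValueError("ar_levels and platform_levels must be non-empty")
        if self.reps_upright < 0 or self.reps_tilted < 0:
            raise ValueError("repetition counts must be >= 0")
        if self.reps_upright + self.reps_tilted < 1:
            raise ValueError("at least one repetition across blocks is required")
        bad = set(self.tasks) - {"RFT", "SPV"}
        if bad or not self.tasks:
            raise ValueError(f"tasks must be a non-empty subset of RFT/SPV, got {self.tasks}")

    @property
    def n_trials_per_task(self) -> int:
        cells = len(self.ar_levels) * len(self.platform_levels)
        return cells * (self.reps_upright + self.reps_tilted)


def build_design(spec: DesignSpec | None = None,
                 participant_id: str = "p01",
                 seed: int | None = None) -> pd.DataFrame:
    """Full crossed design for one participant, responses left empty.

    Trial order is shuffled within each task x head block under ``seed``
    (order never enters the model, but mirrors the blocked randomization of
    the experiment).
    """
    spec = spec or DesignSpec()
    rng = np.random.default_rng(seed)
    frames = []
    for task in spec.tasks:
        for block, reps in (("upright", spec.reps_upright),
                            ("tilted", spec.reps_tilted)):
            if reps == 0:
                continue
            cells = pd.MultiIndex.from_product(
                [spec.ar_levels, spec.platform_levels, range(reps)],
                names=["ar_tilt_deg", "platform_tilt_deg", "rep"],
            ).to_frame(index=False)
            cells = cells.iloc[rng.permutation(len(cells))].reset_index(drop=True)
            cells["task"] = task
            cells["block"] = block
            frames.append(cells)
    out = pd.concat(frames, ignore_index=True)
    out["participant_id"] = participant_id
    out["head_tilted"] = out["block"] == "tilted"
    out["response_deg"] = np.nan
    out["cop_y_cm"] = np.nan
    out["valid"] = True
    out["exclusion_reason"] = "none"
    return out[TRIAL_COLUMNS]


def sample_responses(design: pd.DataFrame,
                     params: ParticipantParameters,
                     variant: ModelVariant | str = ModelVariant.MLE,
                     seed: int | None = None) -> pd.DataFrame:
    """Draw each trial's response from its predictive Gaussian."""
    out = design.copy()
    mean, sd = predict_response_arrays(
        params, variant,
        is_rft=(out["task"] == "RFT").to_numpy(),
        platform_tilt_deg=out["platform_tilt_deg"].to_numpy(),
        head_tilted=out["head_tilted"].to_numpy(),
        ar_tilt_deg=out["ar_tilt_deg"].to_numpy(),
    )
    rng = np.random.default_rng(seed)
    out["response_deg"] = rng.normal(mean, sd)
    return out


def sample_cop(design: pd.DataFrame,
               body_height_m: float = DEFAULT_BODY_HEIGHT_M,
               counteraction_gain: float = DEFAULT_COUNTERACTION_GAIN,
               visual_lean_deg_per_deg: float = DEFAULT_VISUAL_LEAN,
               noise_sd_cm: float = DEFAULT_COP_NOISE_SD_CM,
               seed: int | None = None) -> pd.DataFrame:
    """Fill lateral COP assuming a rigid body pivoting at the ankles.

    The effective platform tilt is attenuated by ``counteraction_gain`` in
    RFT trials and is zero in SPV trials (the participant returns the
    platform to their perceived upright, so the commanded tilt is only a
    starting point); camera tilt adds a small lean.  COM height is half the
    body height.
    """
    if body_height_m <= 0:
        raise ValueError(f"body_height_m must be positive, got {body_height_m!r}")
    out = design.copy()
    com_cm = 100.0 * body_height_m / 2.0
    phi_p_eff = np.where(out["task"] == "SPV", 0.0,
                         out["platform_tilt_deg"].to_numpy())
    lean = visual_lean_deg_per_deg * out["ar_tilt_deg"].to_numpy()
    rng = np.random.default_rng(seed)
    out["cop_y_cm"] = (
        com_cm * np.tan(np.radians(counteraction_gain * phi_p_eff))
        + com_cm * np.tan(np.radians(lean))
        + rng.normal(0.0, noise_sd_cm, size=len(out))
    )
    return out


_PARAM_FIELDS = ("neck_tilt_deg", "sigma_som", "sigma_pro", "sigma_com0", "k_com")

#: Per-field dispersion of the simulated cohort: sd of log for the sigma
#: parameters (multiplicative), plain sd in degrees / units otherwise.
#: Chosen so simulated cohorts stay within the observed per-participant range.
DEFAULT_PARAM_SPREAD = {
    "neck_tilt_deg": 5.0,
    "sigma_som": 0.30,
    "sigma_pro": 0.60,
    "sigma_com0": 0.60,
    "k_com": 0.12,
}

#: Truncation limits for sampled parameters (the fitting bounds).
PARAM_LIMITS = {
    "neck_tilt_deg": (-45.0, 45.0),
    "sigma_som": (0.05, 30.0),
    "sigma_pro": (0.1, 60.0),
    "sigma_com0": (0.1, 60.0),
    "k_com": (0.0, 2.0),
}

#: Relative frequency of the exclusion categories among flagged trials,
#: following the study's 72 training / 3 mistake / 10 COP-quality split.
_EXCLUSION_WEIGHTS = {"training": 72, "mistake": 3, "cop_quality": 10}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a simulated cohort with known ground truth."""

    n_participants: int = 10
    parameter_center: ParticipantParameters = MEDIAN_PARAMS
    parameter_spread: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_SPREAD))
    generating_variant: ModelVariant | str = ModelVariant.MLE
    design: DesignSpec = field(default_factory=DesignSpec)
    exclusion_rate: float = 0.04
    with_cop: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if any(v < 0 for v in self.parameter_spread.values()):
            raise ValueError("parameter_spread values must be >= 0")
        if not (0.0 <= self.exclusion_rate < 1.0):
            raise ValueError("exclusion_rate must lie in [0, 1)")


def _draw_params(center: ParticipantParameters, spread: dict,
                 rng: np.random.Generator) -> ParticipantParameters:
    values = {}
    for name in _PARAM_FIELDS:
        mu = getattr(center, name)
        s = spread.get(name, 0.0)
        if name.startswith("sigma"):
            v = mu * math.exp(rng.normal(0.0, s))  # log-normal, median at center
        else:
            v = rng.normal(mu, s)
        lo, hi = PARAM_LIMITS[name]
        values[name] = float(np.clip(v, lo, hi))
    return ParticipantParameters(**values)


def make_cohort(spec: CohortSpec | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (trial table, ground-truth parameter table).

    Per participant, coefficients are drawn around ``parameter_center``
    (log-normal for the noise sd's, normal for neck tilt and the visual
    noise gain, truncated to the fitting bounds), the full design is built
    and sampled, COP is filled, and ``exclusion_rate`` of trials are flagged
    for exclusion with reasons in the study's observed proportions.
    """
    spec = spec or CohortSpec()
    root = np.random.SeedSequence(spec.seed)
    reasons = list(_EXCLUSION_WEIGHTS)
    probs = np.array(list(_EXCLUSION_WEIGHTS.values()), dtype=float)
    probs /= probs.sum()

    trials, truth = [], []
    for i, ss in enumerate(root.spawn(spec.n_participants)):
        rng = np.random.default_rng(ss)
        pid = f"p{i + 1:02d}"
        params = _draw_params(spec.parameter_center, spec.parameter_spread, rng)
        design = build_design(spec.design, pid,
                              seed=rng.integers(2 ** 31))
        data = sample_responses(design, params, spec.generating_variant,
                                seed=rng.integers(2 ** 31))
        if spec.with_cop:
            data = sample_cop(data, seed=rng.integers(2 ** 31))
        if spec.exclusion_rate > 0:
            flagged = rng.random(len(data)) < spec.exclusion_rate
            data.loc[flagged, "valid"] = False
            data.loc[flagged, "exclusion_reason"] = rng.choice(
                reasons, size=int(flagged.sum()), p=probs)
        trials.append(data)
        truth.append({"participant_id": pid, **asdict(params)})

    return (pd.concat(trials, ignore_index=True),
            pd.DataFrame(truth).set_index("participant_id"))
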