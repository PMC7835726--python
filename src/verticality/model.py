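"""Forward Gaussian observer model of head- and body-centered verticality.

The observer stands on a tiltable platform (roll tilt ``phi_P``), may hold the
head tilted on the trunk (neck tilt ``phi_N``), and views the world through a
video feed-through display whose camera can be rolled by ``phi_AR``.  Three
noisy sensory channels report on this configuration:

* ``x_som`` — somatic graviceptors in the trunk; mean ``k_som * phi_P``,
  standard deviation ``sigma_som`` (body-in-space, BIS).
* ``x_pro`` — neck proprioceptors; mean ``phi_N`` when the head is tilted,
  0 otherwise, sd ``sigma_pro`` (head-on-body).
* ``x_com`` — a combined visual+vestibular head sensor; mean
  ``k_som*phi_P + phi_N + phi_AR``, sd ``K_com*|phi_AR| + sigma_com0``
  (head-in-space, HIS).  The eccentricity term makes visual tilt less
  reliable the further the scene is rolled.

Each latent construct has a *direct* estimate from its own sensor and an
*indirect* estimate built from the other construct's sensor corrected for
neck tilt (``HISi = x_som + x_pro``, ``BISi = x_com - x_pro``).  The percept
is a convex combination of the two, with the direct weight either pinned to
1 ("fixed"), left free ("free"), or set to the variance-optimal value
("mle").  Rod-and-frame (RFT) responses mirror the head percept with a sign
flip; subjective-postural-vertical (SPV) responses are the platform tilt
that nulls the body percept.

All angles are in degrees throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "ModelVariant",
    "StimulusCondition",
    "ParticipantParameters",
    "GaussianBelief",
    "SensoryChannels",
    "Weights",
    "visual_tilt",
    "sensory_channels",
    "indirect_bis",
    "indirect_his",
    "mle_weights",
    "combine",
    "predict_rft",
    "predict_spv",
    "predict_response_arrays",
]


class ModelVariant(str, Enum):
    """Weighting regime for the direct/indirect combination."""

    FIXED = "fixed"  # direct only: omega_HISd = omega_BISd = 1
    FREE = "free"    # omegas are per-participant free parameters in (0, 1)
    MLE = "mle"      # omegas from inverse-variance weighting, per condition


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class StimulusCondition:
    """One experimental cell: platform tilt, head posture, camera tilt (deg)."""

    platform_tilt_deg: float
    head_tilted: bool
    ar_tilt_deg: float

    def __post_init__(self) -> None:
        _check_finite("platform_tilt_deg", self.platform_tilt_deg)
        _check_finite("ar_tilt_deg", self.ar_tilt_deg)


@dataclass(frozen=True)
class ParticipantParameters:
    """Observer-model coefficients for one participant.

    ``omega_hisd``/``omega_bisd`` are only meaningful for the "free" variant.
    ``k_som`` is an optional gain on platform tilt (default 1: body tilt equals
    platform tilt); ``spv_neck_offset_deg`` is an optional additive bias of the
    SPV response in head-tilted blocks.  Both extensions default to the plain
    five-parameter model.
    """

    neck_tilt_deg: float
    sigma_som: float
    sigma_pro: float
    sigma_com0: float
    k_com: float
    omega_hisd: Optional[float] = None
    omega_bisd: Optional[float] = None
    k_som: float = 1.0
    spv_neck_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_som", "sigma_pro", "sigma_com0"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not (math.isfinite(self.k_com) and self.k_com >= 0):
            raise ValueError(f"k_com must be >= 0, got {self.k_com!r}")
        for name in ("omega_hisd", "omega_bisd"):
            v = getattr(self, name)
            if v is not None and not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        _check_finite("neck_tilt_deg", self.neck_tilt_deg)
        _check_finite("k_som", self.k_som)
        _check_finite("spv_neck_offset_deg", self.spv_neck_offset_deg)


@dataclass(frozen=True)
class GaussianBelief:
    """A Gaussian signal or percept: (mean, sd) in degrees."""

    mean_deg: float
    sd_deg: float

    def __post_init__(self) -> None:
        if self.sd_deg < 0:
            raise ValueError(f"sd_deg must be >= 0, got {self.sd_deg!r}")

    @property
    def var(self) -> float:
        return self.sd_deg ** 2


@dataclass(frozen=True)
class SensoryChannels:
    """The three channel signals for one condition."""

    som: GaussianBelief
    pro: GaussianBelief
    com: GaussianBelief


@dataclass(frozen=True)
class Weights:
    """Direct-representation weights; the indirect weight is 1 - direct."""

    omega_hisd: float
    omega_bisd: float

    def __post_init__(self) -> None:
        for name in ("omega_hisd", "omega_bisd"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


def visual_tilt(platform_tilt_deg: float, effective_neck_deg: float,
                ar_tilt_deg: float) -> float:
    """Tilt of the visual scene relative to gravity: phi_P + phi_N + phi_AR."""
    return (_check_finite("platform_tilt_deg", platform_tilt_deg)
            + _check_finite("effective_neck_deg", effective_neck_deg)
            + _check_finite("ar_tilt_deg", ar_tilt_deg))


def sigma_com(params: ParticipantParameters, ar_tilt_deg: float) -> float:
    """Eccentricity-dependent sd of the combined head sensor (deg)."""
    return params.k_com * abs(ar_tilt_deg) + params.sigma_com0


def sensory_channels(params: ParticipantParameters,
                     cond: StimulusCondition) -> SensoryChannels:
    """Channel signals (mean, sd) for one stimulus condition."""
    neck = params.neck_tilt_deg if cond.head_tilted else 0.0
    body = params.k_som * cond.platform_tilt_deg
    return SensoryChannels(
        som=GaussianBelief(body, params.sigma_som),
        pro=GaussianBelief(neck, params.sigma_pro),
        com=GaussianBelief(body + neck + cond.ar_tilt_deg,
                           sigma_com(params, cond.ar_tilt_deg)),
    )


def indirect_bis(ch: SensoryChannels) -> GaussianBelief:
    """Indirect body-in-space estimate: head sensor minus neck, BISi = x_com - x_pro."""
    return GaussianBelief(ch.com.mean_deg - ch.pro.mean_deg,
                          math.hypot(ch.com.sd_deg, ch.pro.sd_deg))


def indirect_his(ch: SensoryChannels) -> GaussianBelief:
    """Indirect head-in-space estimate: body sensor plus neck, HISi = x_som + x_pro."""
    return GaussianBelief(ch.som.mean_deg + ch.pro.mean_deg,
                          math.hypot(ch.som.sd_deg, ch.pro.sd_deg))


def mle_weights(var_hisd: float, var_hisi: float,
                var_bisd: float, var_bisi: float) -> Weights:
    """Inverse-variance (maximum-likelihood) weights on the direct estimates.

    omega_d = var_i / (var_d + var_i): the less reliable the indirect route,
    the more weight falls on the direct sensor.
    """
    for name, v in (("var_hisd", var_hisd), ("var_hisi", var_hisi),
                    ("var_bisd", var_bisd), ("var_bisi", var_bisi)):
        if not (math.isfinite(v) and v >= 0):
            raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
    if var_hisd + var_hisi <= 0 or var_bisd + var_bisi <= 0:
        raise ValueError("degenerate input: total variance must be positive")
    return Weights(omega_hisd=var_hisi / (var_hisd + var_hisi),
                   omega_bisd=var_bisi / (var_bisd + var_bisi))


def combine(direct: GaussianBelief, indirect: GaussianBelief,
            omega_direct: float) -> GaussianBelief:
    """Convex combination of direct and indirect Gaussian estimates."""
    w = float(omega_direct)
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"omega_direct must lie in [0, 1], got {omega_direct!r}")
    mean = w * direct.mean_deg + (1.0 - w) * indirect.mean_deg
    var = w ** 2 * direct.var + (1.0 - w) ** 2 * indirect.var
    return GaussianBelief(mean, math.sqrt(var))


def _omega_hisd(params: ParticipantParameters, variant: ModelVariant,
                var_hisd: float, var_hisi: float) -> float:
    variant = ModelVariant(variant)
    if variant is ModelVariant.FIXED:
        return 1.0
    if variant is ModelVariant.FREE:
        if params.omega_hisd is None:
            raise ValueError("variant 'free' requires params.omega_hisd")
        return params.omega_hisd
    return var_hisi / (var_hisd + var_hisi)


def _omega_bisd(params: ParticipantParameters, variant: ModelVariant,
                var_bisd: float, var_bisi: float) -> float:
    variant = ModelVariant(variant)
    if variant is ModelVariant.FIXED:
        return 1.0
    if variant is ModelVariant.FREE:
        if params.omega_bisd is None:
            raise ValueError("variant 'free' requires params.omega_bisd")
        return params.omega_bisd
    return var_bisi / (var_bisd + var_bisi)


def predict_rft(params: ParticipantParameters, cond: StimulusCondition,
                variant: ModelVariant | str) -> GaussianBelief:
    """Predictive distribution of the rod setting in the RFT task.

    The rod is reported in head-display coordinates, so the response mirrors
    the head-in-space percept: mean = -mu_HIS_hat, sd = sigma_HIS_hat.
    """
    ch = sensory_channels(params, cond)
    hisd = ch.com
    hisi = indirect_his(ch)
    w = _omega_hisd(params, ModelVariant(variant), hisd.var, hisi.var)
    his_hat = combine(hisd, hisi, w)
    return GaussianBelief(-his_hat.mean_deg, his_hat.sd_deg)


def predict_spv(params: ParticipantParameters, cond: StimulusCondition,
                variant: ModelVariant | str) -> GaussianBelief:
    """Predictive distribution of the platform setting in the SPV task.

    The participant tilts the platform until the body-in-space percept is
    zero.  Solving omega*mu_BISd + (1-omega)*mu_BISi = 0 for the platform
    setting (the neck terms cancel between mu_com and the proprioceptive
    correction) gives mean = -(1 - omega_BISd) * phi_AR / k_som, plus an
    optional neck-related offset in head-tilted blocks.  The response sd is
    the somatosensory noise sigma_som.
    """
    ch = sensory_channels(params, cond)
    bisd = ch.som
    bisi = indirect_bis(ch)
    w = _omega_bisd(params, ModelVariant(variant), bisd.var, bisi.var)
    mean = -(1.0 - w) * cond.ar_tilt_deg / params.k_som
    if cond.head_tilted:
        mean += params.spv_neck_offset_deg
    return GaussianBelief(mean, params.sigma_som)


def predict_response_arrays(
    params: ParticipantParameters,
    variant: ModelVariant | str,
    is_rft: np.ndarray,
    platform_tilt_deg: np.ndarray,
    head_tilted: np.ndarray,
    ar_tilt_deg: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized predictive (mean, sd) for arrays of trials.

    Same model as :func:`predict_rft` / :func:`predict_spv`, evaluated for
    all trials at once; used by the likelihood and the trial sampler.
    """
    variant = ModelVariant(variant)
    phi_p = np.asarray(platform_tilt_deg, dtype=float)
    phi_ar = np.asarray(ar_tilt_deg, dtype=float)
    tilted = np.asarray(head_tilted, dtype=bool)
    rft = np.asarray(is_rft, dtype=bool)

    neck = np.where(tilted, params.neck_tilt_deg, 0.0)
    body = params.k_som * phi_p
    s_com = params.k_com * np.abs(phi_ar) + params.sigma_com0
    var_hisd = s_com ** 2
    var_hisi = params.sigma_som ** 2 + params.sigma_pro ** 2
    var_bisd = params.sigma_som ** 2
    var_bisi = s_com ** 2 + params.sigma_pro ** 2

    if variant is ModelVariant.FIXED:
        w_his = np.ones_like(phi_ar)
        w_bis = np.ones_like(phi_ar)
    elif variant is ModelVariant.FREE:
        if params.omega_hisd is None or params.omega_bisd is None:
            raise ValueError("variant 'free' requires omega_hisd and omega_bisd")
        w_his = np.full_like(phi_ar, params.omega_hisd)
        w_bis = np.full_like(phi_ar, params.omega_bisd)
    else:
        w_his = var_hisi / (var_hisd + var_hisi)
        w_bis = var_bisi / (var_bisd + var_bisi)

    mu_hisd = body + neck + phi_ar
    mu_hisi = body + neck
    rft_mean = -(w_his * mu_hisd + (1.0 - w_his) * mu_hisi)
    rft_sd = np.sqrt(w_his ** 2 * var_hisd + (1.0 - w_his) ** 2 * var_hisi)

    spv_mean = -(1.0 - w_bis) * phi_ar / params.k_som \
        + np.where(tilted, params.spv_neck_offset_deg, 0.0)
    spv_sd = np.full_like(phi_ar, params.sigma_som)

    mean = np.where(rft, rft_mean, spv_mean)
    sd = np.where(rft, rft_sd, spv_sd)
    return mean, sd
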