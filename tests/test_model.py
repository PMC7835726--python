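"""Forward-model unit and property tests: channels, weights, predictions."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from verticality.model import (
    GaussianBelief,
    ModelVariant,
    ParticipantParameters,
    StimulusCondition,
    combine,
    indirect_bis,
    indirect_his,
    mle_weights,
    predict_response_arrays,
    predict_rft,
    predict_spv,
    sensory_channels,
    visual_tilt,
)

angles = st.floats(-60, 60, allow_nan=False)
sds = st.floats(0.1, 30, allow_nan=False)


@pytest.mark.parametrize("phi_p, neck, ar, expected", [
    (3, 15, -36, -18),
    (0, 0, 0, 0),
    (-3, 0, 36, 33),
])
def test_visual_tilt_is_sum_of_components(phi_p, neck, ar, expected):
    assert visual_tilt(phi_p, neck, ar) == expected


def test_visual_tilt_rejects_non_finite():
    with pytest.raises(ValueError):
        visual_tilt(float("nan"), 0, 0)


def test_sensory_channel_means_and_sds(median_params):
    """Channel means follow the stimulus geometry; the head-sensor sd grows
    linearly with camera eccentricity."""
    cond = StimulusCondition(0.0, False, 0.0)
    ch = sensory_channels(median_params, cond)
    assert ch.com.sd_deg == pytest.approx(8.572)
    assert ch.som.sd_deg == pytest.approx(0.811)
    assert ch.pro.sd_deg == pytest.approx(9.276)

    ch36 = sensory_channels(median_params, StimulusCondition(0.0, False, 36.0))
    assert ch36.com.sd_deg == pytest.approx(17.536)

    tilted = sensory_channels(median_params, StimulusCondition(3.0, True, 13.0))
    assert tilted.com.mean_deg == pytest.approx(3 + 9.416 + 13)
    assert tilted.pro.mean_deg == pytest.approx(9.416)
    # neck contributes nothing with the head upright
    assert sensory_channels(median_params, StimulusCondition(3.0, False, 13.0)
                            ).pro.mean_deg == 0.0


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        ParticipantParameters(0, sigma_som=-1, sigma_pro=1, sigma_com0=1, k_com=0)
    with pytest.raises(ValueError):
        ParticipantParameters(0, 1, 1, 1, k_com=-0.1)
    with pytest.raises(ValueError):
        ParticipantParameters(0, 1, 1, 1, 0, omega_hisd=1.0)


def test_indirect_estimates():
    """BISi subtracts the neck signal from the head signal, HISi adds it;
    variances add in both cases."""
    bis = indirect_bis(type("C", (), {
        "com": GaussianBelief(10, 3), "pro": GaussianBelief(15, 4),
        "som": GaussianBelief(0, 1)})())
    assert bis.mean_deg == -5 and bis.sd_deg == pytest.approx(5)

    his = indirect_his(type("C", (), {
        "som": GaussianBelief(3, 0.8), "pro": GaussianBelief(15, 9.276),
        "com": GaussianBelief(0, 1)})())
    assert his.mean_deg == 18
    assert his.sd_deg ** 2 == pytest.approx(0.64 + 86.044176)


def test_indirect_variances_at_median_parameters(median_params):
    ch = sensory_channels(median_params, StimulusCondition(0, False, 0))
    assert indirect_bis(ch).sd_deg ** 2 == pytest.approx(159.523, abs=1e-3)
    assert indirect_his(ch).sd_deg ** 2 == pytest.approx(86.702, abs=1e-3)


def _median_weights(params, ar):
    ch = sensory_channels(params, StimulusCondition(0, False, ar))
    return mle_weights(ch.com.var, indirect_his(ch).var,
                       ch.som.var, indirect_bis(ch).var)


def test_mle_weights_at_median_parameters(median_params):
    """Inverse-variance weights reproduce the published group profile."""
    w0 = _median_weights(median_params, 0.0)
    w36 = _median_weights(median_params, 36.0)
    assert round(w0.omega_bisd, 3) == 0.996
    assert round(w36.omega_bisd, 3) == 0.998
    assert round(w0.omega_hisd, 3) == 0.541
    assert round(w36.omega_hisd, 3) == 0.220


def test_mle_weights_equal_variances_and_errors():
    w = mle_weights(2.0, 2.0, 5.0, 5.0)
    assert w.omega_hisd == 0.5 and w.omega_bisd == 0.5
    with pytest.raises(ValueError):
        mle_weights(0.0, 0.0, 1.0, 1.0)


@given(vd=st.floats(0.01, 1e3), vi=st.floats(0.01, 1e3))
@settings(derandomize=True, max_examples=50)
def test_mle_weight_complementarity_and_optimality(vd, vi):
    """Direct+indirect weights sum to one, and the inverse-variance weight
    minimizes the combined variance over all convex weights."""
    w = mle_weights(vd, vi, vd, vi).omega_hisd
    omega_indirect = vd / (vd + vi)
    assert w + omega_indirect == pytest.approx(1.0)
    direct = GaussianBelief(0, math.sqrt(vd))
    indirect = GaussianBelief(0, math.sqrt(vi))
    best = combine(direct, indirect, w).var
    assert best == pytest.approx(vd * vi / (vd + vi), rel=1e-9)
    assert best <= min(vd, vi) + 1e-12
    for omega in np.linspace(0, 1, 21):
        assert combine(direct, indirect, float(omega)).var >= best - 1e-12


def test_combine_boundaries_and_midpoint():
    d = GaussianBelief(10, 2)
    i = GaussianBelief(0, 2)
    assert combine(d, i, 1.0) == d
    assert combine(d, i, 0.0) == i
    mid = combine(d, i, 0.5)
    assert mid.mean_deg == 5 and mid.var == pytest.approx(2.0)
    with pytest.raises(ValueError):
        combine(d, i, 1.5)


def test_predict_rft_examples(median_params, upright_ar36):
    fixed = predict_rft(median_params, upright_ar36, "fixed")
    assert fixed.mean_deg == pytest.approx(-36)
    assert fixed.sd_deg == pytest.approx(17.536)

    mle = predict_rft(median_params, upright_ar36, "mle")
    assert mle.mean_deg == pytest.approx(-7.918, abs=1e-3)

    # when direct and indirect means agree, the weight is irrelevant
    tilted0 = StimulusCondition(0, True, 0)
    for variant in ("fixed", "mle"):
        assert predict_rft(median_params, tilted0, variant).mean_deg == \
            pytest.approx(-9.416)


def test_predict_rft_free_requires_omegas(median_params, upright_ar36):
    with pytest.raises(ValueError):
        predict_rft(median_params, upright_ar36, "free")


def test_predict_spv_examples(median_params, free_params, upright_ar36):
    assert predict_spv(median_params, upright_ar36, "mle").mean_deg == \
        pytest.approx(-0.060, abs=1e-3)
    # omega_BISd = 1 (the fixed variant) nulls the visual effect entirely
    assert predict_spv(median_params, upright_ar36, "fixed").mean_deg == 0.0
    none = predict_spv(median_params, StimulusCondition(3, True, 0), "mle")
    assert none.mean_deg == pytest.approx(0.0)
    assert none.sd_deg == pytest.approx(0.811)
    # free variant: slope is exactly -(1 - omega_bisd)
    free = predict_spv(free_params, upright_ar36, "free")
    assert free.mean_deg == pytest.approx(-(1 - 0.99) * 36)


def test_spv_neck_offset_extension(median_params):
    p = dataclasses.replace(median_params, spv_neck_offset_deg=-2.4)
    cond = StimulusCondition(0, True, 0)
    assert predict_spv(p, cond, "mle").mean_deg == pytest.approx(-2.4)
    upright = StimulusCondition(0, False, 0)
    assert predict_spv(p, upright, "mle").mean_deg == pytest.approx(0.0)


def test_rft_slope_equals_minus_direct_weight(median_params):
    """The RFT mean response is -omega_HISd * phi_AR: the chord slope from
    the upright origin equals -omega_HISd at that eccentricity, and the
    local derivative equals it wherever the weight is constant in phi_AR
    (constant-omega regimes: free variant, or K_com = 0)."""
    ar = 20.0
    w = _median_weights(median_params, ar).omega_hisd
    mean = predict_rft(median_params, StimulusCondition(0, False, ar), "mle").mean_deg
    assert mean / ar == pytest.approx(-w, abs=1e-12)

    flat = dataclasses.replace(median_params, k_com=0.0)
    w_flat = _median_weights(flat, ar).omega_hisd
    eps = 1e-4
    hi = predict_rft(flat, StimulusCondition(0, False, ar + eps), "mle")
    lo = predict_rft(flat, StimulusCondition(0, False, ar - eps), "mle")
    assert (hi.mean_deg - lo.mean_deg) / (2 * eps) == pytest.approx(-w_flat,
                                                                    abs=1e-6)

    free = dataclasses.replace(median_params, omega_hisd=0.35, omega_bisd=0.99)
    hi = predict_rft(free, StimulusCondition(0, False, ar + eps), "free")
    lo = predict_rft(free, StimulusCondition(0, False, ar - eps), "free")
    assert (hi.mean_deg - lo.mean_deg) / (2 * eps) == pytest.approx(-0.35,
                                                                    abs=1e-6)


@given(phi_p=st.sampled_from([-3.0, 0.0, 3.0]), ar=angles,
       head=st.booleans())
@settings(derandomize=True, max_examples=50)
def test_spv_mean_independent_of_platform_and_head(median_params, phi_p, ar, head):
    ref = predict_spv(median_params, StimulusCondition(0.0, False, ar), "mle")
    got = predict_spv(median_params, StimulusCondition(phi_p, head, ar), "mle")
    assert got.mean_deg == pytest.approx(ref.mean_deg, abs=1e-12)


@given(phi_p=angles, ar=angles)
@settings(derandomize=True, max_examples=50)
def test_antisymmetry_with_zero_neck(phi_p, ar):
    """With no neck tilt, negating the stimuli negates both predicted means."""
    p = ParticipantParameters(0.0, 0.811, 9.276, 8.572, 0.249)
    for predict in (predict_rft, predict_spv):
        plus = predict(p, StimulusCondition(phi_p, False, ar), "mle")
        minus = predict(p, StimulusCondition(-phi_p, False, -ar), "mle")
        assert plus.mean_deg == pytest.approx(-minus.mean_deg, abs=1e-9)


def test_degenerate_noise_limit_recovers_direct_only(median_params):
    """As the neck signal becomes useless, both weights approach 1."""
    p = dataclasses.replace(median_params, sigma_pro=1e6)
    w = _median_weights(p, 13.0)
    assert w.omega_hisd == pytest.approx(1.0, abs=1e-6)
    assert w.omega_bisd == pytest.approx(1.0, abs=1e-6)


def test_vectorized_predictions_match_scalar(median_params, free_params):
    """The array fast path agrees with the scalar reference implementation."""
    rng = np.random.default_rng(7)
    n = 40
    phi_p = rng.choice([-3.0, 0.0, 3.0], n)
    ar = rng.choice([-36.0, -13.0, -5.0, 0.0, 5.0, 13.0, 36.0], n)
    head = rng.random(n) < 0.5
    is_rft = rng.random(n) < 0.5
    for variant, params in (("fixed", median_params), ("mle", median_params),
                            ("free", free_params)):
        mean, sd = predict_response_arrays(params, variant, is_rft, phi_p,
                                           head, ar)
        for i in range(n):
            cond = StimulusCondition(phi_p[i], bool(head[i]), ar[i])
            ref = (predict_rft if is_rft[i] else predict_spv)(params, cond, variant)
            assert mean[i] == pytest.approx(ref.mean_deg, abs=1e-12)
            assert sd[i] == pytest.approx(ref.sd_deg, abs=1e-12)
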