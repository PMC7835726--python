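"""Published group-level reference values used as simulation defaults.

These are the cohort medians of the fitted observer-model coefficients and
the group-level descriptive regression coefficients for the rod-and-frame
(RFT) task, from the original standing verticality-perception study
(10 participants, roll-tilt platform + video feed-through display).  They
anchor the synthetic-data generator so that simulated cohorts resemble the
real one, and serve as canonical inputs for worked examples.
"""

from __future__ import annotations

from .model import ParticipantParameters

#: Cohort-median observer-model coefficients (degrees; k_com unitless).
MEDIAN_PARAMS = ParticipantParameters(
    neck_tilt_deg=9.416,
    sigma_som=0.811,
    sigma_pro=9.276,
    sigma_com0=8.572,
    k_com=0.249,
)

#: Cohort SDs of the same coefficients, for cohort simulation dispersion.
PARAM_SD = {
    "neck_tilt_deg": 5.099,
    "sigma_som": 0.349,
    "sigma_pro": 7.168,
    "sigma_com0": 7.789,
    "k_com": 0.138,
}

#: Fixed-effect coefficients (deg) of the descriptive categorical regression
#: of RFT responses on camera tilt, relative to the phi_AR = -36 deg baseline.
LME_RFT_AR_COEF = {
    -36: 0.0,
    -13: -4.233,
    -5: -6.737,
    0: -9.266,
    5: -10.689,
    13: -13.699,
    36: -18.719,
}

#: Fraction of trials the study excluded (training / mistakes / COP quality).
EXCLUSION_FRACTION = 0.042

#: Fixed-effect slope of measured on rigid-body-expected lateral COP:
#: participants counteracted platform tilt by about 27%.
COP_COUNTERACTION_SLOPE = 0.731


def rft_peak_bias(ar_coef: dict[int, float] | None = None) -> float:
    """Peak rod bias implied by symmetric categorical tilt coefficients.

    With coefficients expressed against the most counter-clockwise camera
    tilt as baseline, the full swing between the two extreme tilts is the
    coefficient at the most clockwise level; under antisymmetry the peak
    bias at either extreme is half its magnitude.
    """
    coef = LME_RFT_AR_COEF if ar_coef is None else ar_coef
    lo, hi = min(coef), max(coef)
    return abs(coef[hi] - coef[lo]) / 2.0
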