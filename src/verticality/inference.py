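"""Per-participant maximum-likelihood fitting and BIC model comparison.

The observer model is fitted jointly to a participant's RFT and SPV
responses by maximizing the sum of Gaussian log-densities of each observed
response under its trial's predictive distribution.  Three weighting
regimes are compared:

* ``fixed`` — direct-only percepts (omega = 1); free parameters
  (phi_N, sigma_som, sigma_com0, K_com), k = 4.  sigma_pro never enters the
  predictions here, so it is excluded from the parameter vector.
* ``mle``   — inverse-variance weights recomputed per condition; adds
  sigma_pro, k = 5.
* ``free``  — constant weights fitted per participant; adds
  omega_HISd, omega_BISd, k = 7.

Optional extensions (a somatosensory gain ``k_som`` on platform tilt and an
SPV-specific neck offset) each add one parameter.

Optimization is multi-start bounded quasi-Newton (L-BFGS-B) in a
transformed space — log for the noise sd's, logit for the weights — with
Latin-hypercube starting points; the best start by final log-likelihood is
retained.  Model quality is summarized by BIC = k*ln(n) - 2*lnL with the
conventional 2/6/10 evidence bands on BIC differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .model import ModelVariant, ParticipantParameters, predict_response_arrays

__all__ = [
    "FitOptions",
    "FitResult",
    "ModelComparison",
    "loglik",
    "fit_participant",
    "fit_cohort",
    "bic",
    "evidence_category",
    "r_squared",
    "compare_variants",
    "cohort_summary",
    "DEFAULT_BOUNDS",
]

_LOG2PI = math.log(2.0 * math.pi)

#: Natural-space fitting bounds; generous brackets around the observed
#: per-participant ranges, excluding degenerate zero noise.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "neck_tilt_deg": (-45.0, 45.0),
    "sigma_som": (0.05, 30.0),
    "sigma_pro": (0.1, 60.0),
    "sigma_com0": (0.1, 60.0),
    "k_com": (0.0, 2.0),
    "omega_hisd": (1e-3, 1.0 - 1e-3),
    "omega_bisd": (1e-3, 1.0 - 1e-3),
    "k_som": (-10.0, 10.0),
    "spv_neck_offset_deg": (-30.0, 30.0),
}


@dataclass(frozen=True)
class FitOptions:
    n_starts: int = 20
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    tolerance: float = 1e-9
    seed: int = 0
    fit_k_som: bool = False
    fit_spv_offset: bool = False

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name!r}: ({lo}, {hi})")

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS[name])


@dataclass
class FitResult:
    variant: ModelVariant
    params: ParticipantParameters
    loglik: float
    n_trials: int
    k_params: int
    bic: float
    r_squared: float
    r_squared_by_task: dict[str, float]
    converged: bool
    n_starts_used: int


@dataclass
class ModelComparison:
    bic: dict[str, float]
    delta_bic: dict[str, float]
    evidence: dict[str, str]
    best: str
    fits: dict[str, FitResult]


def _trial_arrays(trials: pd.DataFrame):
    return (
        (trials["task"] == "RFT").to_numpy(),
        trials["platform_tilt_deg"].to_numpy(dtype=float),
        trials["head_tilted"].to_numpy(dtype=bool),
        trials["ar_tilt_deg"].to_numpy(dtype=float),
        trials["response_deg"].to_numpy(dtype=float),
    )


def _loglik_arrays(params, variant, is_rft, phi_p, head, phi_ar, resp) -> float:
    mean, sd = predict_response_arrays(params, variant, is_rft, phi_p, head, phi_ar)
    if not np.all(np.isfinite(mean)) or np.any(sd <= 0):
        return -np.inf
    z = (resp - mean) / sd
    return float(-0.5 * np.sum(z * z) - np.sum(np.log(sd)) - 0.5 * _LOG2PI * resp.size)


def loglik(params: ParticipantParameters, variant: ModelVariant | str,
           trials: pd.DataFrame) -> float:
    """Joint log-likelihood of one participant's responses under the model."""
    is_rft, phi_p, head, phi_ar, resp = _trial_arrays(trials)
    if not np.all(np.isfinite(resp)):
        raise ValueError("trials contain missing or non-finite responses")
    return _loglik_arrays(params, ModelVariant(variant), is_rft, phi_p, head,
                          phi_ar, resp)


def _free_param_names(variant: ModelVariant, options: FitOptions) -> list[str]:
    names = ["neck_tilt_deg", "sigma_som", "sigma_com0", "k_com"]
    if variant is not ModelVariant.FIXED:
        names.insert(2, "sigma_pro")
    if variant is ModelVariant.FREE:
        names += ["omega_hisd", "omega_bisd"]
    if options.fit_k_som:
        names.append("k_som")
    if options.fit_spv_offset:
        names.append("spv_neck_offset_deg")
    return names


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _transform(name: str, x: float) -> float:
    if name.startswith("sigma"):
        return math.log(x)
    if name.startswith("omega"):
        return _logit(x)
    return x


def _back(name: str, z: float) -> float:
    if name.startswith("sigma"):
        return math.exp(z)
    if name.startswith("omega"):
        return 1.0 / (1.0 + math.exp(-z))
    return z


def _build_params(names: list[str], z: np.ndarray,
                  variant: ModelVariant) -> ParticipantParameters:
    kwargs = {n: _back(n, v) for n, v in zip(names, z)}
    if variant is ModelVariant.FIXED:
        kwargs["sigma_pro"] = 1.0  # placeholder; never enters fixed predictions
    return ParticipantParameters(**kwargs)


def fit_participant(trials: pd.DataFrame, variant: ModelVariant | str,
                    options: FitOptions | None = None) -> FitResult:
    """Multi-start maximum-likelihood fit of one variant to one participant.

    Deterministic under ``options.seed``; ties between starts are broken by
    the first start index.  If no start converges, the best point found is
    still returned with ``converged=False``.
    """
    variant = ModelVariant(variant)
    options = options or FitOptions()
    is_rft, phi_p, head, phi_ar, resp = _trial_arrays(trials)
    if not np.all(np.isfinite(resp)):
        raise ValueError("trials contain missing or non-finite responses")
    n = int(resp.size)
    if n < 1:
        raise ValueError("no trials to fit")
    names = _free_param_names(variant, options)
    zbounds = [tuple(sorted((_transform(nm, lo), _transform(nm, hi))))
               for nm, (lo, hi) in ((nm, options.bound(nm)) for nm in names)]
    lo = np.array([b[0] for b in zbounds])
    hi = np.array([b[1] for b in zbounds])

    def nll(z: np.ndarray) -> float:
        try:
            params = _build_params(names, z, variant)
        except ValueError:
            return np.inf
        ll = _loglik_arrays(params, variant, is_rft, phi_p, head, phi_ar, resp)
        return np.inf if not np.isfinite(ll) else -ll

    sampler = qmc.LatinHypercube(d=len(names), seed=options.seed)
    starts = lo + sampler.random(options.n_starts) * (hi - lo)

    best, best_nll, converged = None, np.inf, False
    for z0 in starts:
        res = optimize.minimize(
            nll, z0, method="L-BFGS-B", bounds=list(zip(lo, hi)),
            options={"ftol": options.tolerance, "maxiter": 500})
        if res.fun < best_nll - 1e-12:
            best, best_nll = res, res.fun
            converged = bool(res.success)
    if best is None:  # pragma: no cover - minimize always returns a result
        raise RuntimeError("optimization produced no result")

    params = _build_params(names, best.x, variant)
    ll = -float(best_nll)
    k = len(names)
    r2_by_task = r_squared(trials, params, variant, by_task=True)
    return FitResult(
        variant=variant,
        params=params,
        loglik=ll,
        n_trials=n,
        k_params=k,
        bic=bic(ll, k, n),
        r_squared=r_squared(trials, params, variant),
        r_squared_by_task=r2_by_task,
        converged=converged,
        n_starts_used=options.n_starts,
    )


def fit_cohort(trials: pd.DataFrame, variant: ModelVariant | str,
               options: FitOptions | None = None) -> dict[str, FitResult]:
    """Fit one variant independently to every participant in a trial table."""
    return {pid: fit_participant(grp, variant, options)
            for pid, grp in trials.groupby("participant_id", sort=True)}


def bic(loglik: float, k_params: int, n_trials: int) -> float:
    """Bayesian information criterion: k*ln(n) - 2*lnL (lower is better)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return k_params * math.log(n_trials) - 2.0 * loglik


def evidence_category(delta_bic: float) -> str:
    """Kass–Raftery-style evidence label for a BIC difference.

    Bands: [0, 2) negligible, [2, 6) positive, [6, 10) strong,
    >= 10 decisive.
    """
    if delta_bic < 0:
        raise ValueError("delta_bic must be non-negative")
    if delta_bic < 2:
        return "negligible"
    if delta_bic < 6:
        return "positive"
    if delta_bic < 10:
        return "strong"
    return "decisive"


def r_squared(trials: pd.DataFrame, params: ParticipantParameters,
              variant: ModelVariant | str, by_task: bool = False):
    """Variance explained, 1 - SSE/SST, using per-trial predicted means.

    Pooled over both tasks by default; ``by_task=True`` returns a dict with
    one value per task.
    """
    is_rft, phi_p, head, phi_ar, resp = _trial_arrays(trials)
    mean, _ = predict_response_arrays(params, ModelVariant(variant),
                                      is_rft, phi_p, head, phi_ar)

    def one(mask: np.ndarray) -> float:
        r, m = resp[mask], mean[mask]
        sst = float(np.sum((r - r.mean()) ** 2))
        if sst == 0:
            raise ValueError("zero total variance; R^2 undefined")
        return 1.0 - float(np.sum((r - m) ** 2)) / sst

    if not by_task:
        return one(np.ones_like(is_rft, dtype=bool))
    return {task: one(is_rft if task == "RFT" else ~is_rft)
            for task in sorted(pd.unique(trials["task"]))}


def compare_variants(trials: pd.DataFrame,
                     options: FitOptions | None = None,
                     variants: tuple = ("fixed", "free", "mle")) -> ModelComparison:
    """Fit all variants to the same participant and rank them by BIC."""
    fits = {ModelVariant(v).value: fit_participant(trials, v, options)
            for v in variants}
    bics = {v: f.bic for v, f in fits.items()}
    best = min(bics, key=lambda v: (bics[v], v))
    deltas = {v: b - bics[best] for v, b in bics.items()}
    return ModelComparison(
        bic=bics,
        delta_bic=deltas,
        evidence={v: evidence_category(d) for v, d in deltas.items()},
        best=best,
        fits=fits,
    )


def cohort_summary(fit_results: dict[str, FitResult],
                   ar_levels: tuple[float, ...] = (0.0, 5.0, 13.0, 36.0)
                   ) -> dict[str, pd.DataFrame]:
    """Cohort coefficient table (median/SD rows) and weights at the medians.

    ``weights`` holds the inverse-variance direct weights omega_HISd and
    omega_BISd evaluated at the cohort-median parameters for each camera
    eccentricity, mirroring how the group-level weighting profile is
    reported.
    """
    if not fit_results:
        raise ValueError("no fit results to summarize")
    rows = []
    for pid, fr in fit_results.items():
        p = fr.params
        rows.append({
            "participant_id": pid,
            "neck_tilt_deg": p.neck_tilt_deg,
            "sigma_som": p.sigma_som,
            "sigma_pro": p.sigma_pro,
            "sigma_com0": p.sigma_com0,
            "k_com": p.k_com,
            "r_squared": fr.r_squared,
        })
    table = pd.DataFrame(rows).set_index("participant_id")
    table.loc["Median"] = table.median()
    table.loc["SD"] = table.iloc[:-1].std(ddof=1) if len(rows) > 1 else 0.0

    med = table.loc["Median"]
    med_params = ParticipantParameters(
        neck_tilt_deg=float(med["neck_tilt_deg"]),
        sigma_som=float(med["sigma_som"]),
        sigma_pro=float(med["sigma_pro"]),
        sigma_com0=float(med["sigma_com0"]),
        k_com=float(med["k_com"]),
    )
    from .model import mle_weights, sigma_com
    wrows = []
    var_hisi = med_params.sigma_som ** 2 + med_params.sigma_pro ** 2
    for ar in ar_levels:
        s = sigma_com(med_params, ar)
        w = mle_weights(s ** 2, var_hisi, med_params.sigma_som ** 2,
                        s ** 2 + med_params.sigma_pro ** 2)
        wrows.append({"ar_tilt_deg": ar, "omega_hisd": w.omega_hisd,
                      "omega_bisd": w.omega_bisd})
    weights = pd.DataFrame(wrows).set_index("ar_tilt_deg")
    return {"parameters": table, "weights": weights}
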