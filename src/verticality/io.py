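"""File formats, configuration, and the end-to-end pipeline runner.

Trial tables travel as RFC-4180 CSV with the ``TRIAL_COLUMNS`` schema
(angles in degrees, COP in cm, units embedded in the column names); fits
and reports are JSON; configs may be YAML or JSON.  ``run_pipeline``
orchestrates the full analysis: simulate or load trials, exclude and
mean-correct, fit the three weighting variants per participant, compare by
BIC, summarize the cohort, and run the posture checks, writing every
artifact plus a manifest under the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import FitOptions, FitResult, compare_variants, cohort_summary
from .model import ModelVariant, ParticipantParameters
from .posture import cohort_counteraction
from .preprocess import preprocess
from .simulate import TRIAL_COLUMNS, CohortSpec, DesignSpec, make_cohort

__all__ = [
    "PipelineConfig",
    "read_trials",
    "write_trials",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger("verticality")

_REQUIRED = ["participant_id", "task", "platform_tilt_deg", "head_tilted",
             "ar_tilt_deg", "response_deg"]


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial table; unknown columns pass through."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} is missing required columns: {missing}")
    for col in ("platform_tilt_deg", "ar_tilt_deg", "response_deg", "cop_y_cm"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    df["head_tilted"] = df["head_tilted"].astype(bool)
    if "block" not in df.columns:
        df["block"] = np.where(df["head_tilted"], "tilted", "upright")
    if "valid" not in df.columns:
        df["valid"] = True
    if "exclusion_reason" not in df.columns:
        df["exclusion_reason"] = "none"
    if "cop_y_cm" not in df.columns:
        df["cop_y_cm"] = np.nan
    ordered = TRIAL_COLUMNS + [c for c in df.columns if c not in TRIAL_COLUMNS]
    return df[ordered]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)


@dataclass(frozen=True)
class PipelineConfig:
    """One run: where data comes from, how to fit, where results go."""

    input: str = "simulate"            # "simulate" or a trial-table CSV path
    output_dir: str = "verticality_out"
    seed: int = 0
    variants: tuple[str, ...] = ("fixed", "free", "mle")
    cohort: dict = field(default_factory=dict)     # CohortSpec overrides
    design: dict = field(default_factory=dict)     # DesignSpec overrides
    fit: dict = field(default_factory=dict)        # FitOptions overrides
    posture: dict = field(default_factory=dict)    # cohort_counteraction kwargs
    verbosity: str = "INFO"


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("variants",):
        if key in data:
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def _cohort_spec(config: PipelineConfig) -> CohortSpec:
    cohort = dict(config.cohort)
    center = cohort.pop("parameter_center", None)
    if isinstance(center, dict):
        cohort["parameter_center"] = ParticipantParameters(**center)
    elif center is not None:
        cohort["parameter_center"] = center
    if config.design:
        cohort["design"] = DesignSpec(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in config.design.items()})
    cohort.setdefault("seed", config.seed)
    return CohortSpec(**cohort)


def _fit_result_record(pid: str, fr: FitResult) -> dict:
    return {
        "participant_id": pid,
        "variant": fr.variant.value,
        "params": dataclasses.asdict(fr.params),
        "loglik": fr.loglik,
        "n_trials": fr.n_trials,
        "k_params": fr.k_params,
        "bic": fr.bic,
        "r_squared": fr.r_squared,
        "r_squared_by_task": fr.r_squared_by_task,
        "converged": fr.converged,
        "n_starts_used": fr.n_starts_used,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory report bundle.

    Artifacts written under ``config.output_dir``: the (simulated or copied)
    trial table, the preprocessed table and report, per-participant fit
    JSONs, the BIC comparison CSV, the cohort coefficient summary CSV, the
    posture report JSON, and a run manifest with a hash of all numeric
    outputs.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate/load"
    try:
        if config.input == "simulate":
            spec = _cohort_spec(config)
            trials, truth = make_cohort(spec)
            truth.reset_index().to_json(out / "ground_truth.json",
                                        orient="records", indent=2)
        else:
            trials = read_trials(config.input)
            truth = None
        write_trials(trials, out / "trials.csv")
        log.info("%d trials from %s", len(trials), config.input)

        stage = "preprocess"
        clean, report = preprocess(trials)
        write_trials(clean, out / "trials_preprocessed.csv")
        (out / "preprocess_report.json").write_text(json.dumps({
            "n_input": report.n_input,
            "n_excluded_by_reason": report.n_excluded_by_reason,
            "fraction_excluded": report.fraction_excluded,
            "offsets": {f"{p}:{t}": v for (p, t), v
                        in report.per_participant_task_offsets.items()},
        }, indent=2))

        stage = "fit/compare"
        options = FitOptions(**{"seed": config.seed, **config.fit})
        comparisons = {}
        fit_records = []
        for pid, grp in clean.groupby("participant_id", sort=True):
            comp = compare_variants(grp, options, variants=config.variants)
            comparisons[pid] = comp
            for v, fr in comp.fits.items():
                fit_records.append(_fit_result_record(pid, fr))
            log.info("participant %s: best=%s BICs=%s", pid, comp.best,
                     {v: round(b, 2) for v, b in comp.bic.items()})
        (out / "fits.json").write_text(json.dumps(fit_records, indent=2))
        comp_rows = [{"participant_id": pid, "variant": v,
                      "bic": comp.bic[v], "delta_bic": comp.delta_bic[v],
                      "evidence": comp.evidence[v],
                      "best": v == comp.best}
                     for pid, comp in comparisons.items()
                     for v in comp.bic]
        comparison = pd.DataFrame(comp_rows)
        comparison.to_csv(out / "comparison.csv", index=False)

        stage = "summarize"
        best_counts = pd.Series([c.best for c in comparisons.values()]).value_counts()
        summaries = {}
        for v in config.variants:
            vv = ModelVariant(v).value
            summaries[vv] = cohort_summary({p: c.fits[vv]
                                            for p, c in comparisons.items()})
        preferred = "mle" if "mle" in summaries else list(summaries)[-1]
        summaries[preferred]["parameters"].to_csv(out / "cohort_summary.csv")
        summaries[preferred]["weights"].to_csv(out / "cohort_weights.csv")

        stage = "posture"
        posture_report = None
        if clean["cop_y_cm"].notna().any():
            posture_report = cohort_counteraction(clean, **config.posture)
            (out / "posture_report.json").write_text(json.dumps(
                posture_report, indent=2))

        stage = "manifest"
        digest = hashlib.sha256()
        for name in ("trials.csv", "trials_preprocessed.csv", "fits.json",
                     "comparison.csv", "cohort_summary.csv"):
            digest.update((out / name).read_bytes())
        manifest = {
            "package_version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "outputs_sha256": digest.hexdigest(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "trials": trials,
        "preprocessed": clean,
        "preprocess_report": report,
        "comparisons": comparisons,
        "comparison_table": comparison,
        "summary": summaries[preferred],
        "best_variant_counts": best_counts.to_dict(),
        "posture": posture_report,
        "manifest": manifest,
        "ground_truth": truth,
    }
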