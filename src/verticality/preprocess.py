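"""Trial exclusion and head-upright mean correction.

Before fitting, the study discarded training trials, self-reported
mistakes, and trials with COP-quality issues, and then removed
participant-specific constant biases (e.g., display misalignment on the
head, habitual posture) by subtracting each participant's mean head-upright
response — per task, pooled over all stimulus levels — from all of that
participant's responses in that task.  After correction, head-upright
responses are symmetric around zero within each participant and task, which
keeps constant offsets from inflating the fitted noise parameters.  COP
columns are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["PreprocessReport", "exclude_invalid", "mean_correct", "preprocess"]


@dataclass
class PreprocessReport:
    n_input: int
    n_excluded_by_reason: dict[str, int]
    fraction_excluded: float
    per_participant_task_offsets: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.n_excluded_by_reason.values())


def exclude_invalid(trials: pd.DataFrame) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop flagged trials; tally how many fell to each exclusion category."""
    reason = trials["exclusion_reason"].fillna("none")
    keep = reason == "none"
    counts = reason[~keep].value_counts().to_dict()
    report = PreprocessReport(
        n_input=len(trials),
        n_excluded_by_reason={k: int(v) for k, v in counts.items()},
        fraction_excluded=float((~keep).sum()) / len(trials) if len(trials) else 0.0,
    )
    return trials[keep].reset_index(drop=True), report


def mean_correct(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Subtract each (participant, task) head-upright mean from all responses.

    Every (participant, task) group must contain at least one head-upright
    trial; the offset is the pooled mean over all upright conditions.
    """
    out = trials.copy()
    out["response_deg"] = out["response_deg"].astype(float)
    offsets: dict[tuple[str, str], float] = {}
    for (pid, task), grp in out.groupby(["participant_id", "task"], sort=False):
        upright = grp.loc[~grp["head_tilted"], "response_deg"]
        if upright.empty:
            raise ValueError(
                f"no head-upright trials for participant {pid!r}, task {task!r}; "
                "cannot compute the mean correction")
        off = float(upright.mean())
        offsets[(pid, task)] = off
        out.loc[grp.index, "response_deg"] = grp["response_deg"] - off
    return out, offsets


def preprocess(trials: pd.DataFrame) -> tuple[pd.DataFrame, PreprocessReport]:
    """Exclusion followed by mean correction (in that order)."""
    kept, report = exclude_invalid(trials)
    corrected, offsets = mean_correct(kept)
    report.per_participant_task_offsets = offsets
    return corrected, report
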