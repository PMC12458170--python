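"""Motion quality control.

Subjects whose average root-mean-square (RMS) head displacement over the
diffusion scan exceeds one voxel (1.7 mm by default) are excluded; retained
subjects carry their mean RMS forward as the ``movement`` nuisance covariate
in the ROI regressions.  RMS summaries are consumed as precomputed numbers
(the eddy-current tool that produces them is upstream of this package).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MotionSummary", "apply_motion_exclusion", "motion_qc_table"]

DEFAULT_THRESHOLD_MM = 1.7


@dataclass(frozen=True)
class MotionSummary:
    subject_id: str
    mean_rms_mm: float
    excluded: bool = False

    def __post_init__(self):
        if not np.isfinite(self.mean_rms_mm) or self.mean_rms_mm < 0:
            raise ValueError("mean_rms_mm must be finite and >= 0")


def apply_motion_exclusion(
    summaries: list[MotionSummary],
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
) -> tuple[list[MotionSummary], list[MotionSummary]]:
    """Partition subjects into (retained, excluded) by mean RMS movement.

    Exclusion is strict: movement *greater than* the threshold excludes, so
    a subject exactly at the cutoff is retained.
    """
    retained, excluded = [], []
    for s in summaries:
        flag = s.mean_rms_mm > threshold_mm
        s = MotionSummary(s.subject_id, s.mean_rms_mm, excluded=flag)
        (excluded if flag else retained).append(s)
    return retained, excluded


def motion_qc_table(
    table: pd.DataFrame, threshold_mm: float = DEFAULT_THRESHOLD_MM
) -> pd.DataFrame:
    """CSV-oriented wrapper: adds an ``excluded`` column to a motion table."""
    if (table["mean_rms_mm"] < 0).any() or not np.isfinite(
        table["mean_rms_mm"]
    ).all():
        raise ValueError("mean_rms_mm must be finite and >= 0")
    out = table.copy()
    out["excluded"] = out["mean_rms_mm"] > threshold_mm
    return out
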