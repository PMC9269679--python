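"""Spatio-temporal gait parameters: step length, gait speed, step counts,
and the per-condition summary tables.

Conventions follow standard laboratory practice: step length is the 3D
Euclidean inter-malleolus distance at the instant of a foot contact; gait
speed is the net straight-line displacement of the anterior superior iliac
spine (ASIS) marker divided by elapsed time (net displacement, not path
length, so marker jitter does not inflate the estimate on straight walkway
trials); steps are counted as extrema of the anterior–posterior left–right
ankle-distance signal (each maximum is a left step, each minimum a right
step, or vice versa depending on axis orientation).

Summaries average per-step values within a trial, then across trials of the
same (subject, condition); grand "Mean"/"std" rows are the unweighted mean
and the sample (n-1) standard deviation of the per-row values, with missing
cells skipped pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_model import GaitEvents, SignalTrace, ValidationError

__all__ = [
    "Marker3D",
    "step_lengths",
    "gait_speed",
    "count_steps",
    "summarize_trials",
    "grand_rows",
]

# step-counting peak picking: no printed parameters exist for this step, so
# robust relative defaults are used (fractions of the signal's own spread)
PEAK_PROMINENCE_IQR_FRAC = 0.2
PEAK_MIN_SEPARATION_S = 0.3


@dataclass(frozen=True)
class Marker3D:
    """A 3D marker trajectory as three same-rate traces (x forward)."""

    x: SignalTrace
    y: SignalTrace
    z: SignalTrace

    def __post_init__(self) -> None:
        if not (self.x.rate_hz == self.y.rate_hz == self.z.rate_hz):
            raise ValidationError("marker axes must share one sampling rate")
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValidationError("marker axes must have equal length")

    @property
    def rate_hz(self) -> float:
        return self.x.rate_hz

    def position_at(self, t_s: float) -> np.ndarray:
        """Linear-interpolated 3D position at time ``t_s``."""
        t = self.x.times()
        if not (t[0] - 0.5 / self.rate_hz <= t_s <= t[-1] + 0.5 / self.rate_hz):
            raise ValidationError(
                f"time {t_s} s outside marker span [{t[0]}, {t[-1]}] s"
            )
        return np.array(
            [np.interp(t_s, t, ax.values) for ax in (self.x, self.y, self.z)]
        )


def step_lengths(
    ankle_left: Marker3D, ankle_right: Marker3D, events: GaitEvents
) -> np.ndarray:
    """Per-step lengths (m) for the side of ``events``.

    At each foot contact of that side the 3D Euclidean distance between the
    two lateral malleolus markers is taken as the step length.
    """
    out = []
    for t in events.foot_contacts_s:
        d = ankle_left.position_at(t) - ankle_right.position_at(t)
        out.append(float(np.linalg.norm(d)))
    return np.array(out)


def gait_speed(asis: Marker3D) -> float:
    """Net ASIS displacement divided by elapsed time (m/s)."""
    n = len(asis.x)
    if n < 2:
        raise ValidationError("marker trace too short for a speed estimate")
    p0 = np.array([ax.values[0] for ax in (asis.x, asis.y, asis.z)])
    p1 = np.array([ax.values[-1] for ax in (asis.x, asis.y, asis.z)])
    elapsed = (n - 1) / asis.rate_hz
    return float(np.linalg.norm(p1 - p0) / elapsed)


def count_steps(
    ankle_ap_left: SignalTrace,
    ankle_ap_right: SignalTrace,
    prominence_iqr_frac: float = PEAK_PROMINENCE_IQR_FRAC,
    min_separation_s: float = PEAK_MIN_SEPARATION_S,
) -> int:
    """Count steps as extrema of the left-right ankle AP-distance signal.

    Every sufficiently prominent local maximum *or* minimum of
    ``d(t) = AP_left - AP_right`` is one step (the two signs alternate
    between sides).  A monotone ``d`` has no extrema and counts zero steps.
    """
    if ankle_ap_left.rate_hz != ankle_ap_right.rate_hz:
        raise ValidationError("ankle traces must share a sampling rate")
    n = min(len(ankle_ap_left), len(ankle_ap_right))
    d = ankle_ap_left.values[:n] - ankle_ap_right.values[:n]
    iqr = float(np.subtract(*np.percentile(d, [75, 25])))
    prominence = max(prominence_iqr_frac * iqr, 1e-12)
    distance = max(int(round(min_separation_s * ankle_ap_left.rate_hz)), 1)
    peaks, _ = sps.find_peaks(d, prominence=prominence, distance=distance)
    troughs, _ = sps.find_peaks(-d, prominence=prominence, distance=distance)
    return int(len(peaks) + len(troughs))


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "step_length_left_mean_m",
    "step_length_right_mean_m",
    "step_length_left_std_m",
    "step_length_right_std_m",
    "gait_speed_mps",
    "n_steps_left",
    "n_steps_right",
]


def summarize_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-trial step data into per-(subject, condition) rows.

    ``trials`` needs columns ``subject_id``, ``condition``, ``gait_speed_mps``,
    ``n_steps_left``, ``n_steps_right`` and per-trial step-length lists (or
    scalars) ``step_lengths_left_m`` / ``step_lengths_right_m``.  Step lengths
    are averaged within each trial first, then across trials of the same
    subject and condition; step counts are summed across trials.
    """
    if len(trials) == 0:
        raise ValidationError("no trials to summarize")
    rows = []
    for (subject, condition), grp in trials.groupby(
        ["subject_id", "condition"], sort=True
    ):
        def _per_trial(col, fn):
            vals = []
            for item in grp[col]:
                arr = np.atleast_1d(np.asarray(item, dtype=float))
                arr = arr[np.isfinite(arr)]
                if arr.size:
                    vals.append(fn(arr))
            return vals

        means_l = _per_trial("step_lengths_left_m", np.mean)
        means_r = _per_trial("step_lengths_right_m", np.mean)
        stds_l = [
            s for s in _per_trial(
                "step_lengths_left_m",
                lambda a: np.std(a, ddof=1) if a.size > 1 else np.nan,
            ) if np.isfinite(s)
        ]
        stds_r = [
            s for s in _per_trial(
                "step_lengths_right_m",
                lambda a: np.std(a, ddof=1) if a.size > 1 else np.nan,
            ) if np.isfinite(s)
        ]
        rows.append(
            {
                "subject_id": subject,
                "condition": condition,
                "step_length_left_mean_m": float(np.mean(means_l)) if means_l else np.nan,
                "step_length_right_mean_m": float(np.mean(means_r)) if means_r else np.nan,
                "step_length_left_std_m": float(np.mean(stds_l)) if stds_l else np.nan,
                "step_length_right_std_m": float(np.mean(stds_r)) if stds_r else np.nan,
                "gait_speed_mps": float(grp["gait_speed_mps"].mean()),
                "n_steps_left": int(grp["n_steps_left"].sum()),
                "n_steps_right": int(grp["n_steps_right"].sum()),
            }
        )
    return pd.DataFrame(rows)


def grand_rows(summary: pd.DataFrame, columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Append grand ``Mean`` / ``std`` rows to a per-row summary table.

    Mean = unweighted column mean; std = sample (n-1) standard deviation;
    missing cells are skipped pairwise (each column uses its own n).  A
    column with fewer than two present values gets no std.
    """
    if len(summary) == 0:
        raise ValidationError("empty summary table")
    if columns is None:
        columns = [c for c in summary.columns if pd.api.types.is_numeric_dtype(summary[c])]
    mean_row = {"condition": "Mean"}
    std_row = {"condition": "std"}
    for c in columns:
        vals = pd.to_numeric(summary[c], errors="coerce").dropna()
        mean_row[c] = float(vals.mean()) if len(vals) else np.nan
        std_row[c] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
    return pd.concat(
        [summary, pd.DataFrame([mean_row, std_row])], ignore_index=True
    )
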