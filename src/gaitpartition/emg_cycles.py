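"""Time-normalized per-gait-cycle EMG activity curves.

A gait cycle runs from one foot contact to the next ipsilateral contact and
is resampled by linear interpolation onto the conventional 101-point
0–100 %-gait-cycle grid.  The per-cycle foot-off marks the stance-to-swing
transition as a percentage of the cycle.  Amplitudes are left in input
units (no normalization).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .signal_model import GaitEvents, SignalTrace, ValidationError

__all__ = ["NormalizedCycleCurves", "normalize_cycles", "export_cycle_plot"]

N_GRID = 101  # % gait cycle 0..100


@dataclass(frozen=True)
class NormalizedCycleCurves:
    per_cycle: tuple            # of 101-point np arrays
    mean_curve: np.ndarray      # 101-point pointwise mean
    swing_onset_pct: tuple      # per-cycle foot-off as % of cycle
    cycle_spans_s: tuple        # (start_s, end_s) per cycle

    def __post_init__(self) -> None:
        for c in self.per_cycle:
            if len(c) != N_GRID:
                raise ValidationError("each normalized curve must have 101 points")
        for p in self.swing_onset_pct:
            if not 0.0 < p < 100.0:
                raise ValidationError("swing onset % must be inside (0, 100)")

    @property
    def n_cycles(self) -> int:
        return len(self.per_cycle)


def normalize_cycles(envelope: SignalTrace, events: GaitEvents) -> NormalizedCycleCurves:
    """Resample the envelope of each contact->contact cycle onto 101 points.

    Only cycles containing exactly one foot-off strictly between the two
    contacts get a swing-onset percentage; cycles extending past the trace
    are dropped.  Raises if no complete cycle fits inside the trace.
    """
    t = envelope.times()
    if len(t) < 2:
        raise ValidationError("envelope too short")
    curves, onsets, spans = [], [], []
    contacts = events.foot_contacts_s
    for c0, c1 in zip(contacts, contacts[1:]):
        if c0 < t[0] - 1e-9 or c1 > t[-1] + 1e-9:
            continue
        grid_t = np.linspace(c0, c1, N_GRID)
        curves.append(np.interp(grid_t, t, envelope.values))
        offs_inside = [o for o in events.foot_offs_s if c0 < o < c1]
        onsets.append(100.0 * (offs_inside[0] - c0) / (c1 - c0) if offs_inside else np.nan)
        spans.append((c0, c1))
    if not curves:
        raise ValidationError("no complete gait cycle inside the trace")
    mean_curve = np.mean(np.vstack(curves), axis=0)
    return NormalizedCycleCurves(
        per_cycle=tuple(curves),
        mean_curve=mean_curve,
        swing_onset_pct=tuple(o for o in onsets if np.isfinite(o)),
        cycle_spans_s=tuple(spans),
    )


def export_cycle_plot(
    curves: NormalizedCycleCurves, csv_path: str, plot_path: str = None
) -> None:
    """Write the 101-point curves as CSV and optionally render a figure.

    CSV columns: ``pct_cycle``, one ``cycle_<i>`` column per cycle, ``mean``.
    The CSV content is deterministic; the figure shades the mean swing phase.
    """
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["pct_cycle"]
            + [f"cycle_{i + 1}" for i in range(curves.n_cycles)]
            + ["mean"]
        )
        for row in range(N_GRID):
            writer.writerow(
                [row]
                + [f"{c[row]:.9g}" for c in curves.per_cycle]
                + [f"{curves.mean_curve[row]:.9g}"]
            )
    if plot_path is None:
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pct = np.arange(N_GRID)
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, c in enumerate(curves.per_cycle):
        ax.plot(pct, c, color="0.7", lw=0.8, label="cycles" if i == 0 else None)
    ax.plot(pct, curves.mean_curve, color="k", lw=2, label="mean")
    if curves.swing_onset_pct:
        onset = float(np.mean(curves.swing_onset_pct))
        ax.axvspan(onset, 100, color="green", alpha=0.15, label="swing")
    ax.set_xlabel("% gait cycle")
    ax.set_ylabel("EMG envelope")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(plot_path, dpi=120)
    plt.close(fig)
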