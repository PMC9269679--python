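"""Ground-truth gait events: force-plate detection, manual-event ingestion,
and dual-stream synchronization.

Foot contact is declared at the first sample where the vertical ground
reaction force exceeds 10 N and stays above it for at least the debounce
dwell; foot off at the first sample where it drops below 10 N for at least
the dwell.  The 10 N rule alone chatters on noisy plates, hence the 50 ms
default debounce; crossing times are reported at single-sample resolution
(no sub-sample interpolation), matching a 1000 Hz plate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import FilterSpec, condition_accelerometer
from .signal_model import GaitEvents, SignalTrace, ValidationError, read_events

__all__ = [
    "ForcePlateSpec",
    "detect_events_forceplate",
    "read_manual_events",
    "synchronize_streams",
]


@dataclass(frozen=True)
class ForcePlateSpec:
    threshold_n: float = 10.0
    debounce_s: float = 0.05
    rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        if self.threshold_n <= 0:
            raise ValidationError("threshold_n must be > 0")
        if self.debounce_s < 0:
            raise ValidationError("debounce_s must be >= 0")


def detect_events_forceplate(
    grf: SignalTrace, spec: ForcePlateSpec = ForcePlateSpec(), side: str = "right"
) -> GaitEvents:
    """Threshold-crossing event detection on a vertical GRF trace.

    A state machine over runs of the boolean ``force > threshold`` signal:
    the loaded/unloaded state flips only when the opposite state persists for
    at least ``debounce_s``, and the event time is the first sample of that
    sustained run.  A quiet trace yields no events.
    """
    above = grf.values > spec.threshold_n
    n = len(above)
    if n == 0:
        return GaitEvents(foot_contacts_s=(), foot_offs_s=(), side=side)
    min_run = max(int(np.ceil(spec.debounce_s * grf.rate_hz)), 1)

    # run-length encode
    change = np.flatnonzero(np.diff(above.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])

    contacts: list = []
    offs: list = []
    state = False  # start unloaded; a leading loaded run still counts as contact
    for s, e in zip(starts, ends):
        run_state = bool(above[s])
        if run_state != state and (e - s) >= min_run:
            if run_state:
                contacts.append(grf.t0_s + s / grf.rate_hz)
            else:
                offs.append(grf.t0_s + s / grf.rate_hz)
            state = run_state
    # a trailing below-threshold run shorter than the dwell is not an event;
    # likewise at the start: we begin unloaded, so an initial short spike is
    # ignored and an initial long loaded run is a contact at its first sample.
    events = GaitEvents(
        foot_contacts_s=tuple(contacts), foot_offs_s=tuple(offs), side=side
    )
    events.check_alternating()
    return events


def read_manual_events(path: str) -> dict:
    """Read manually annotated events (events CSV) and check alternation."""
    events = read_events(path)
    for ev in events.values():
        ev.check_alternating()
    return events


def synchronize_streams(
    a: SignalTrace,
    b: SignalTrace,
    max_lag_s: float = 2.0,
    filter_spec: FilterSpec = FilterSpec(),
) -> float:
    """Delay (s) of ``b`` relative to ``a``; subtract it from b's times to align.

    Both traces are conditioned, magnitude-taken, resampled onto a common
    rate, mean-removed, and the lag maximizing cross-correlation over
    ``[-max_lag_s, +max_lag_s]`` is found, then refined to sub-sample
    precision by parabolic interpolation around the peak.  Antisymmetric:
    ``offset(a, b) == -offset(b, a)`` within one sample.
    """
    rate = min(a.rate_hz, b.rate_hz)

    def prep(tr: SignalTrace) -> np.ndarray:
        y = np.abs(condition_accelerometer(tr, filter_spec).values)
        if tr.rate_hz != rate:
            n_out = max(int(round(len(y) * rate / tr.rate_hz)), 2)
            t_src = np.arange(len(y)) / tr.rate_hz
            t_dst = np.arange(n_out) / rate
            y = np.interp(t_dst, t_src, y)
        y = y - y.mean()
        return y

    ya, yb = prep(a), prep(b)
    if np.allclose(ya, 0) or np.allclose(yb, 0):
        raise ValidationError("cannot synchronize flat (zero-variance) signals")
    max_lag = int(round(max_lag_s * rate))
    full = sps.correlate(ya, yb, mode="full")
    lags = sps.correlation_lags(len(ya), len(yb), mode="full")
    mask = np.abs(lags) <= max_lag
    cc, lag_set = full[mask], lags[mask]
    k = int(np.argmax(cc))
    lag = float(lag_set[k])
    if 0 < k < len(cc) - 1:  # parabolic refinement around the discrete peak
        y0, y1, y2 = cc[k - 1], cc[k], cc[k + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-12:
            lag += 0.5 * (y0 - y2) / denom
    # lag is where b's content sits inside a's index space: if b is a copy of
    # a delayed by D samples, the peak sits at lag = -D, so the delay of b is
    # -lag/rate, plus whatever their clocks already differ by.
    return (b.t0_s - a.t0_s) - lag / rate
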