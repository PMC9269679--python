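"""Synthetic multimodal gait recordings with exact ground-truth events.

The generator emulates a straight-walkway trial of a slow, impaired walker as
recorded by a gait laboratory: per-foot accelerometer (100 Hz), per-foot
vertical ground reaction force (1000 Hz), lateral-malleolus and ASIS marker
trajectories (100 Hz), and a gastrocnemius-like EMG channel (1000 Hz).  Every
channel is derived from one commanded event timeline, so the ground truth is
exact by construction:

* timing — per-cycle durations are ``1/cadence`` jittered by a coefficient of
  variation shared by both sides (the left side runs half a cycle out of
  phase), and every event time is snapped to the 1 ms force-plate grid;
* accelerometer — low-variance stance baseline plus two positive
  Gaussian-windowed transients per swing (push-off then heel-strike,
  amplitude ratio 2:3) and white noise;
* GRF — zero in swing; in stance a smooth double-bump loading curve that
  equals the 10 N detection threshold exactly at the commanded contact and
  foot-off instants, so threshold detection reproduces truth to one sample;
* markers — each ankle holds during stance and advances two step lengths per
  swing along the walking axis (cosine profile); the inter-malleolus distance
  at every contact is the commanded step length; the ASIS marker advances at
  the commanded speed; a terminal marker-only "feet together" repositioning
  closes the trial (no load transfer, hence no event and no step);
* EMG — band-limited noise bursts gated to late stance.

All randomness flows through one seeded generator, so recordings are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
from scipy import signal as sps

from .signal_model import GaitEvents, GaitRecording, SignalTrace, ValidationError

__all__ = ["SyntheticGaitSpec", "generate_recording", "generate_cohort"]

ACC_RATE_HZ = 100.0
GRF_RATE_HZ = 1000.0
EMG_RATE_HZ = 1000.0
MARKER_RATE_HZ = 100.0
GRF_THRESHOLD_N = 10.0
GRF_PEAK_N = 700.0
LEAD_S = 1.0            # quiet standing before the first and after the last event
CLOSURE_S = 0.5         # terminal feet-together marker repositioning
PUSH_OFF_AMP = 2.0      # m/s^2; heel-strike is 3.0 (the 2:3 ratio)
HEEL_STRIKE_AMP = 3.0
MARKER_NOISE_SD_M = 0.002
EMG_BASELINE_SD = 0.02


@dataclass(frozen=True)
class SyntheticGaitSpec:
    """Commanded trial parameters (defaults: a slow impaired adult walker)."""

    n_steps: int = 10               # landings per side; total steps = 2 * n_steps
    cadence_hz: float = 1.0         # gait cycles per second (per side)
    stance_fraction: float = 0.60   # stance / cycle duration
    step_length_m: float = 0.45
    walking_speed_mps: float = 0.90
    noise_sd: float = 0.15          # accelerometer white noise, m/s^2
    step_time_cv: float = 0.03      # coefficient of variation of cycle times
    emg_burst_gain: float = 1.0
    seed: int = 0
    subject_id: str = "synthetic"
    condition: str = "barefoot"

    def __post_init__(self) -> None:
        if not 0 < self.stance_fraction < 1:
            raise ValidationError("stance_fraction must be in (0, 1)")
        if self.n_steps < 0 or self.noise_sd < 0 or self.step_time_cv < 0:
            raise ValidationError("n_steps, noise_sd and step_time_cv must be >= 0")
        if self.cadence_hz <= 0:
            raise ValidationError("cadence_hz must be > 0")

    @property
    def total_steps(self) -> int:
        return 2 * self.n_steps


def _snap(t: float) -> float:
    """Snap an event time to the 1000 Hz force-plate grid."""
    return round(t * GRF_RATE_HZ) / GRF_RATE_HZ


def _timeline(spec: SyntheticGaitSpec, rng: np.random.Generator):
    """Commanded contacts/offs per side plus per-side footfall positions."""
    n = spec.n_steps
    T = 1.0 / spec.cadence_hz
    cycles = T * (1.0 + spec.step_time_cv * np.clip(rng.standard_normal(n), -3, 3))
    if np.any(cycles <= 0.05 * T):
        raise ValidationError("infeasible spec: jitter collapses a cycle duration")
    # shared cycle clock; left runs half a cycle out of phase, so the phase
    # offset never drifts into the other side's swing
    c_right = LEAD_S + np.concatenate([[0.0], np.cumsum(cycles)])       # n+1 contacts
    c_left = c_right + np.concatenate([cycles, [cycles[-1]]]) / 2.0
    events = {}
    for side, contacts in (("right", c_right), ("left", c_left)):
        durs = np.concatenate([cycles, [cycles[-1]]]) * spec.stance_fraction
        offs = contacts + durs
        events[side] = GaitEvents(
            foot_contacts_s=tuple(_snap(t) for t in contacts),
            foot_offs_s=tuple(_snap(t) for t in offs),
            side=side,
        )
    L = spec.step_length_m
    positions = {
        "right": -L + 2 * L * np.arange(n + 1),
        "left": 2 * L * np.arange(n + 1),
    }
    return events, positions


def _grf_values(t: np.ndarray, ev: GaitEvents) -> np.ndarray:
    """Double-bump stance loading; equals the threshold exactly at events."""
    f = np.zeros_like(t)
    for c, o in zip(ev.foot_contacts_s, ev.foot_offs_s):
        inside = (t > c) & (t < o)
        u = (t[inside] - c) / (o - c)
        bump = 4 * u * (1 - u) * (1 + 0.25 * np.cos(2 * np.pi * u))
        f[inside] = GRF_THRESHOLD_N + (GRF_PEAK_N - GRF_THRESHOLD_N) * bump
        f[np.isclose(t, c) | np.isclose(t, o)] = GRF_THRESHOLD_N
    return f


def _acc_values(
    t: np.ndarray, ev: GaitEvents, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    acc = rng.normal(0.0, noise_sd, t.shape)
    swings = list(zip(ev.foot_offs_s, ev.foot_contacts_s[1:]))
    for off, contact in swings:
        sw = contact - off
        if sw <= 0:
            continue
        po_c, po_s = off + 0.18 * sw, 0.11 * sw
        hs_c, hs_s = contact - 0.12 * sw, 0.08 * sw
        acc += PUSH_OFF_AMP * np.exp(-0.5 * ((t - po_c) / po_s) ** 2)
        acc += HEEL_STRIKE_AMP * np.exp(-0.5 * ((t - hs_c) / hs_s) ** 2)
    return acc


def _ankle_forward(
    t: np.ndarray, ev: GaitEvents, holds: np.ndarray
) -> np.ndarray:
    """Hold in stance, advance with a cosine profile in swing."""
    x = np.full_like(t, holds[0])
    contacts, offs = ev.foot_contacts_s, ev.foot_offs_s
    for k in range(len(holds) - 1):
        o, c_next = offs[k], contacts[k + 1]
        during = (t >= o) & (t < c_next)
        u = (t[during] - o) / (c_next - o)
        x[during] = holds[k] + (holds[k + 1] - holds[k]) * 0.5 * (1 - np.cos(np.pi * u))
        x[t >= c_next] = holds[k + 1]
    return x


def _emg_values(
    t: np.ndarray, ev: GaitEvents, gain: float, rng: np.random.Generator, rate: float
) -> np.ndarray:
    carrier = rng.standard_normal(t.shape)
    hi = min(450.0, 0.45 * rate)
    sos = sps.butter(4, [20.0, hi], btype="bandpass", fs=rate, output="sos")
    carrier = sps.sosfiltfilt(sos, carrier)
    gate = np.zeros_like(t)
    for c, o in zip(ev.foot_contacts_s, ev.foot_offs_s):
        st = o - c
        gate += np.exp(-0.5 * ((t - (c + 0.75 * st)) / (0.10 * st)) ** 2)
    return gain * gate * carrier + rng.normal(0.0, EMG_BASELINE_SD, t.shape)


def generate_recording(spec: SyntheticGaitSpec) -> GaitRecording:
    """Generate one multimodal recording with exact truth events."""
    rng = np.random.default_rng(spec.seed)
    if spec.n_steps == 0:
        duration = 2 * LEAD_S
        truth = {
            s: GaitEvents(foot_contacts_s=(), foot_offs_s=(), side=s)
            for s in ("left", "right")
        }
        events = truth
        positions = {"right": np.array([-spec.step_length_m]), "left": np.array([0.0])}
        closure_start = LEAD_S
    else:
        events, positions = _timeline(spec, rng)
        truth = events
        last_event = max(events["left"].foot_offs_s[-1], events["right"].foot_offs_s[-1])
        closure_start = last_event + 0.1
        duration = closure_start + CLOSURE_S + LEAD_S

    def times(rate: float) -> np.ndarray:
        return np.arange(int(round(duration * rate))) / rate

    traces: dict = {}
    for side in ("right", "left"):
        ev = events[side]
        t_acc = times(ACC_RATE_HZ)
        traces[f"acc_foot_{side[0]}"] = SignalTrace(
            name=f"acc_foot_{side[0]}",
            rate_hz=ACC_RATE_HZ,
            values=_acc_values(t_acc, ev, spec.noise_sd, rng) if spec.n_steps else
            rng.normal(0.0, spec.noise_sd, t_acc.shape),
            units="m/s^2",
        )
        t_grf = times(GRF_RATE_HZ)
        traces[f"grf_{side[0]}"] = SignalTrace(
            name=f"grf_{side[0]}",
            rate_hz=GRF_RATE_HZ,
            values=_grf_values(t_grf, ev) if spec.n_steps else np.zeros_like(t_grf),
            units="N",
        )

    # markers: x = walking axis, y = lateral, z = vertical
    t_mk = times(MARKER_RATE_HZ)
    noise = lambda: rng.normal(0.0, MARKER_NOISE_SD_M, t_mk.shape)
    for side in ("right", "left"):
        ev, holds = events[side], positions[side]
        if spec.n_steps:
            x = _ankle_forward(t_mk, ev, holds)
        else:
            x = np.full_like(t_mk, holds[0])
        # terminal repositioning: the trailing foot closes up (marker-only)
        final = {"right": holds[-1], "left": holds[-1]}[side]
        if side == "right" and spec.n_steps:
            target = positions["left"][-1]
            during = (t_mk >= closure_start) & (t_mk < closure_start + CLOSURE_S)
            u = (t_mk[during] - closure_start) / CLOSURE_S
            x[during] = final + (target - final) * 0.5 * (1 - np.cos(np.pi * u))
            x[t_mk >= closure_start + CLOSURE_S] = target
        z = np.full_like(t_mk, 0.02)
        if spec.n_steps:
            for off, contact in zip(ev.foot_offs_s, ev.foot_contacts_s[1:]):
                during = (t_mk > off) & (t_mk < contact)
                u = (t_mk[during] - off) / (contact - off)
                z[during] += 0.08 * np.sin(np.pi * u)
        for axis, vals in (("x", x), ("y", np.zeros_like(t_mk)), ("z", z)):
            nm = f"ankle_{side[0]}_{axis}"
            traces[nm] = SignalTrace(
                name=nm, rate_hz=MARKER_RATE_HZ, values=vals + noise(), units="m"
            )

    for axis, vals in (
        ("x", spec.walking_speed_mps * t_mk),
        ("y", np.zeros_like(t_mk)),
        ("z", np.full_like(t_mk, 0.95)),
    ):
        nm = f"asis_{axis}"
        traces[nm] = SignalTrace(
            name=nm, rate_hz=MARKER_RATE_HZ, values=vals + noise(), units="m"
        )

    t_emg = times(EMG_RATE_HZ)
    traces["emg_gas_r"] = SignalTrace(
        name="emg_gas_r",
        rate_hz=EMG_RATE_HZ,
        values=_emg_values(t_emg, events["right"], spec.emg_burst_gain, rng, EMG_RATE_HZ)
        if spec.n_steps
        else rng.normal(0.0, EMG_BASELINE_SD, t_emg.shape),
        units="mV",
    )

    return GaitRecording(
        traces=traces,
        side="both",
        condition=spec.condition,
        subject_id=spec.subject_id,
        truth_events=truth,
    )


#: cohort parameter ranges mirroring the span of slow clinical walkers
DEFAULT_COHORT_RANGES: Mapping[str, tuple] = {
    "cadence_hz": (0.7, 1.2),
    "stance_fraction": (0.55, 0.65),
    "step_length_m": (0.30, 0.60),
    "walking_speed_mps": (0.4, 1.3),
}


def generate_cohort(
    n_subjects: int,
    ranges: Optional[Mapping[str, tuple]] = None,
    seed: int = 1,
    base_spec: SyntheticGaitSpec = SyntheticGaitSpec(),
) -> list:
    """Generate a cohort of recordings with per-subject parameters.

    Subject ``i`` uses seed ``seed + i``; its spec fields named in ``ranges``
    are drawn uniformly from the given (lo, hi) intervals with that same
    per-subject seed, so the whole cohort is reproducible from one integer.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    ranges = dict(DEFAULT_COHORT_RANGES if ranges is None else ranges)
    cohort = []
    for i in range(n_subjects):
        sseed = seed + i
        rng = np.random.default_rng(sseed)
        draws = {}
        for key in sorted(ranges):
            lo, hi = ranges[key]
            if hi < lo:
                raise ValidationError(f"empty range for {key!r}")
            draws[key] = float(rng.uniform(lo, hi))
        spec = replace(
            base_spec, seed=sseed, subject_id=f"synthetic-{sseed}", **draws
        )
        cohort.append(generate_recording(spec))
    return cohort
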