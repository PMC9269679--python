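"""Core data types and text-file readers/writers for gait recordings.

All public times are in seconds.  Internally, sample indices are 0-based and
intervals are half-open ``[start_s, end_s)`` at sample resolution, so that the
mixed sampling rates of markers/accelerometers (100 Hz), EMG (500-1000 Hz) and
force plates (1000 Hz) can be compared in seconds without resampling.

On-disk dialects (all plain text):

* recording: a YAML manifest mapping channel name -> ``{file, rate_hz, units,
  role}`` plus one narrow CSV (``time_s,value``) per channel, or a single wide
  CSV (``time_s`` + one column per channel) for channels sharing a rate;
* hints: JSON lines, one object per hint
  (``{"channel", "start_s", "end_s", "polarity"}``);
* events: CSV with columns ``event_type,time_s,side``.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SignalTrace",
    "GaitRecording",
    "Hint",
    "GaitEvents",
    "CycleSet",
    "PartitionErrorReport",
    "ValidationError",
    "read_recording",
    "write_recording",
    "read_hints",
    "write_hints",
    "read_events",
    "write_events",
]

#: significant digits used by every text writer; round trips are exact to this.
TEXT_PRECISION = 9

SIDES = ("left", "right")
CONDITIONS = ("barefoot", "shoes_orthotics")
POLARITIES = ("as_is", "inverted", "auto")
CHANNEL_ROLES = ("accelerometer", "grf", "emg", "marker_x", "marker_y", "marker_z")


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalTrace:
    """One uniformly sampled channel.

    Sample ``i`` sits at time ``t0_s + i / rate_hz``.
    """

    name: str
    rate_hz: float
    values: np.ndarray
    t0_s: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        _require(self.rate_hz > 0, f"trace {self.name!r}: rate_hz must be > 0")
        vals = np.asarray(self.values, dtype=float)
        _require(
            bool(np.all(np.isfinite(vals))),
            f"trace {self.name!r}: values must be finite (no NaN/inf)",
        )
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.rate_hz

    @property
    def end_s(self) -> float:
        return self.t0_s + self.duration_s

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values)) / self.rate_hz

    def index_at(self, t_s: float) -> int:
        """Nearest sample index for time ``t_s`` (clipped to the trace)."""
        i = int(round((t_s - self.t0_s) * self.rate_hz))
        return min(max(i, 0), max(len(self.values) - 1, 0))

    def slice_s(self, start_s: float, end_s: float) -> "SignalTrace":
        """Half-open [start_s, end_s) slice at sample resolution."""
        _require(start_s < end_s, "slice: start_s must be < end_s")
        i0 = int(round((start_s - self.t0_s) * self.rate_hz))
        i1 = int(round((end_s - self.t0_s) * self.rate_hz))
        i0 = max(i0, 0)
        i1 = min(i1, len(self.values))
        return replace(self, values=self.values[i0:i1], t0_s=self.t0_s + i0 / self.rate_hz)

    def with_values(self, values: np.ndarray, name: Optional[str] = None) -> "SignalTrace":
        return replace(self, values=np.asarray(values, dtype=float), name=name or self.name)


@dataclass(frozen=True)
class GaitEvents:
    """Ordered foot-contact / foot-off times (s) for one body side."""

    foot_contacts_s: tuple
    foot_offs_s: tuple
    side: str

    def __post_init__(self) -> None:
        _require(self.side in SIDES, f"side must be one of {SIDES}, got {self.side!r}")
        fc = tuple(float(t) for t in self.foot_contacts_s)
        fo = tuple(float(t) for t in self.foot_offs_s)
        for nm, seq in (("foot_contacts_s", fc), ("foot_offs_s", fo)):
            _require(
                all(b > a for a, b in zip(seq, seq[1:])),
                f"{nm} must be strictly ascending",
            )
        object.__setattr__(self, "foot_contacts_s", fc)
        object.__setattr__(self, "foot_offs_s", fo)

    @property
    def n_events(self) -> int:
        return len(self.foot_contacts_s) + len(self.foot_offs_s)

    def interleaved(self) -> list:
        """All events merged in time order as (time_s, event_type) pairs."""
        ev = [(t, "foot_contact") for t in self.foot_contacts_s]
        ev += [(t, "foot_off") for t in self.foot_offs_s]
        ev.sort()
        return ev

    def check_alternating(self) -> None:
        """Raise unless contacts and offs alternate in time order."""
        ev = self.interleaved()
        for (t0, k0), (t1, k1) in zip(ev, ev[1:]):
            if k0 == k1:
                raise ValidationError(
                    f"events do not alternate: two {k0} events at "
                    f"{t0:.3f} s and {t1:.3f} s with nothing between"
                )


@dataclass(frozen=True)
class Hint:
    """A user-annotated swing interval (foot-off -> foot-contact) on one channel."""

    channel: str
    start_s: float
    end_s: float
    polarity: str = "auto"

    def __post_init__(self) -> None:
        _require(self.start_s < self.end_s, "hint: start_s must be < end_s")
        _require(
            self.polarity in POLARITIES,
            f"hint polarity must be one of {POLARITIES}, got {self.polarity!r}",
        )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def validate_against(self, trace: SignalTrace) -> None:
        _require(
            self.start_s >= trace.t0_s - 0.5 / trace.rate_hz
            and self.end_s <= trace.end_s + 0.5 / trace.rate_hz,
            f"hint [{self.start_s}, {self.end_s}] s outside the span of "
            f"channel {trace.name!r} ([{trace.t0_s}, {trace.end_s}] s)",
        )
        _require(
            self.duration_s * trace.rate_hz > 2,
            "hint interval must span more than 2 samples",
        )


@dataclass(frozen=True)
class CycleSet:
    """Non-overlapping swing intervals with match scores on one channel."""

    intervals: tuple  # of (start_s, end_s, score)
    channel: str
    template_length_s: float = 0.0

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b), float(s)) for a, b, s in self.intervals)
        for a, b, s in ivs:
            _require(a < b, f"cycle ({a}, {b}): start must be < end")
            _require(s >= 0, "cycle score must be >= 0")
        ivs = tuple(sorted(ivs))
        for (a0, b0, _), (a1, _b1, _) in zip(ivs, ivs[1:]):
            _require(b0 <= a1, f"cycles overlap: [{a0}, {b0}) and [{a1}, ...)")
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def starts_s(self) -> np.ndarray:
        return np.array([a for a, _, _ in self.intervals])

    @property
    def ends_s(self) -> np.ndarray:
        return np.array([b for _, b, _ in self.intervals])


@dataclass(frozen=True)
class PartitionErrorReport:
    """Per-event absolute timing errors of predicted vs ground-truth events."""

    per_event_abs_err_s: tuple
    n_matched: int
    n_unmatched_pred: int
    n_unmatched_truth: int
    threshold_s: float

    @property
    def mean_s(self) -> float:
        return float(np.mean(self.per_event_abs_err_s)) if self.per_event_abs_err_s else 0.0

    @property
    def std_s(self) -> Optional[float]:
        if len(self.per_event_abs_err_s) < 2:
            return None
        return float(np.std(self.per_event_abs_err_s, ddof=1))

    @property
    def max_s(self) -> float:
        return float(max(self.per_event_abs_err_s)) if self.per_event_abs_err_s else 0.0

    @property
    def escalate(self) -> bool:
        return any(e > self.threshold_s for e in self.per_event_abs_err_s)


@dataclass
class GaitRecording:
    """A bundle of named traces plus metadata and optional ground-truth events."""

    traces: dict  # name -> SignalTrace
    side: str = "both"
    condition: str = "barefoot"
    subject_id: str = ""
    truth_events: Optional[Mapping[str, GaitEvents]] = None

    def __post_init__(self) -> None:
        _require(
            self.side in SIDES + ("both",),
            f"recording side must be left/right/both, got {self.side!r}",
        )
        _require(
            self.condition in CONDITIONS,
            f"condition must be one of {CONDITIONS}, got {self.condition!r}",
        )
        for name, tr in self.traces.items():
            _require(
                name == tr.name,
                f"trace key {name!r} does not match trace name {tr.name!r}",
            )
        spans = [(tr.t0_s, tr.end_s) for tr in self.traces.values() if len(tr)]
        if len(spans) > 1:
            lo = max(a for a, _ in spans)
            hi = min(b for _, b in spans)
            _require(lo < hi, "traces do not share an overlapping time span")

    def __getitem__(self, name: str) -> SignalTrace:
        try:
            return self.traces[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in recording (has: {sorted(self.traces)})"
            ) from None

    @property
    def channel_names(self) -> list:
        return sorted(self.traces)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{float(x):.{TEXT_PRECISION}g}"


def _read_channel_csv(path: str, column: Optional[str] = None) -> np.ndarray:
    df = pd.read_csv(path)
    col = column if column is not None else "value"
    if col not in df.columns:
        raise ValidationError(f"{path}: missing column {col!r}")
    vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        row = int(bad[0])
        raise ValidationError(
            f"{path}: non-finite or non-numeric value in column {col!r}, "
            f"row {row + 2} (1-based, incl. header)"
        )
    return vals


def read_recording(path: str, manifest: Optional[Mapping] = None) -> GaitRecording:
    """Load a recording from a YAML manifest (path or parsed mapping).

    ``path`` is the manifest file; per-channel CSV paths inside it are resolved
    relative to the manifest's directory.  A channel entry may give ``column``
    to pick a column from a wide CSV shared by several channels.
    """
    if manifest is None:
        with open(path) as fh:
            manifest = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(path))
    channels = manifest.get("channels")
    _require(isinstance(channels, Mapping) and channels, "manifest: no channels declared")

    traces: dict = {}
    for name, entry in channels.items():
        _require(name not in traces, f"duplicate channel name {name!r}")
        rate = float(entry["rate_hz"])
        role = entry.get("role", "accelerometer")
        _require(role in CHANNEL_ROLES, f"channel {name!r}: unknown role {role!r}")
        fpath = os.path.join(base, entry["file"])
        if not os.path.exists(fpath):
            raise ValidationError(f"channel {name!r}: file not found: {fpath}")
        vals = _read_channel_csv(fpath, entry.get("column"))
        t = _read_channel_csv(fpath, "time_s")
        t0 = float(t[0]) if len(t) else 0.0
        if len(t) > 1:
            implied = (len(t) - 1) / (t[-1] - t[0])
            _require(
                math.isclose(implied, rate, rel_tol=1e-3),
                f"channel {name!r}: declared rate {rate} Hz but file implies "
                f"{implied:.4f} Hz over its time span",
            )
        traces[name] = SignalTrace(
            name=name, rate_hz=rate, values=vals, t0_s=t0, units=entry.get("units", "")
        )

    truth = None
    if manifest.get("truth_events_file"):
        truth = read_events(os.path.join(base, manifest["truth_events_file"]))
    return GaitRecording(
        traces=traces,
        side=manifest.get("side", "both"),
        condition=manifest.get("condition", "barefoot"),
        subject_id=str(manifest.get("subject_id", "")),
        truth_events=truth,
    )


def write_recording(rec: GaitRecording, out_dir: str, stem: str = "recording") -> str:
    """Write one CSV per channel plus a manifest; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    channels: dict = {}
    for name, tr in rec.traces.items():
        fname = f"{stem}_{name}.csv"
        with open(os.path.join(out_dir, fname), "w") as fh:
            fh.write("time_s,value\n")
            for t, v in zip(tr.times(), tr.values):
                fh.write(f"{_fmt(t)},{_fmt(v)}\n")
        channels[name] = {
            "file": fname,
            "rate_hz": tr.rate_hz,
            "units": tr.units,
            "role": "accelerometer",
        }
    manifest: dict = {
        "channels": channels,
        "side": rec.side,
        "condition": rec.condition,
        "subject_id": rec.subject_id,
    }
    if rec.truth_events:
        truth_file = f"{stem}_truth_events.csv"
        write_events(rec.truth_events, os.path.join(out_dir, truth_file))
        manifest["truth_events_file"] = truth_file
    mpath = os.path.join(out_dir, f"{stem}_manifest.yaml")
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return mpath


def read_hints(path: str, channels: Optional[Sequence[str]] = None) -> list:
    """Parse a JSON-lines hint file; hints are returned sorted by start time.

    If ``channels`` is given, each hint's channel must be among them.
    """
    hints = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed JSON ({exc})") from None
            try:
                hint = Hint(
                    channel=obj["channel"],
                    start_s=float(obj["start_s"]),
                    end_s=float(obj["end_s"]),
                    polarity=obj.get("polarity", "auto"),
                )
            except (KeyError, TypeError) as exc:
                raise ValidationError(f"{path}:{lineno}: bad hint record ({exc})") from None
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            if channels is not None and hint.channel not in channels:
                raise ValidationError(
                    f"{path}:{lineno}: channel {hint.channel!r} not among "
                    f"declared channels {sorted(channels)}"
                )
            hints.append(hint)
    hints.sort(key=lambda h: (h.start_s, h.channel))
    return hints


def write_hints(hints: Iterable[Hint], path: str) -> None:
    with open(path, "w") as fh:
        for h in hints:
            fh.write(
                json.dumps(
                    {
                        "channel": h.channel,
                        "start_s": float(_fmt(h.start_s)),
                        "end_s": float(_fmt(h.end_s)),
                        "polarity": h.polarity,
                    }
                )
                + "\n"
            )


def _events_rows(events) -> list:
    if isinstance(events, GaitEvents):
        events = {events.side: events}
    rows = []
    for side in sorted(events):
        ev = events[side]
        for t in ev.foot_contacts_s:
            rows.append(("foot_contact", t, side))
        for t in ev.foot_offs_s:
            rows.append(("foot_off", t, side))
    rows.sort(key=lambda r: (r[2], r[1], r[0]))
    return rows


def write_events(events, path: str) -> None:
    """Write GaitEvents (or a side -> GaitEvents mapping) to the events CSV."""
    with open(path, "w") as fh:
        fh.write("event_type,time_s,side\n")
        for kind, t, side in _events_rows(events):
            fh.write(f"{kind},{_fmt(t)},{side}\n")


def read_events(path: str) -> dict:
    """Read an events CSV into a side -> GaitEvents mapping."""
    df = pd.read_csv(path)
    for col in ("event_type", "time_s", "side"):
        _require(col in df.columns, f"{path}: missing column {col!r}")
    if len(df) == 0:
        return {}
    out = {}
    for side, grp in df.groupby("side"):
        fc = sorted(grp.loc[grp.event_type == "foot_contact", "time_s"].astype(float))
        fo = sorted(grp.loc[grp.event_type == "foot_off", "time_s"].astype(float))
        unknown = set(grp.event_type) - {"foot_contact", "foot_off"}
        _require(not unknown, f"{path}: unknown event types {sorted(unknown)}")
        out[str(side)] = GaitEvents(
            foot_contacts_s=tuple(fc), foot_offs_s=tuple(fo), side=str(side)
        )
    return out
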