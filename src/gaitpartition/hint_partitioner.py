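"""Few-shot, hint-driven gait partitioning by fuzzy time-domain matching.

The workflow this module implements:

1. a user marks one swing phase (foot-off -> foot-contact) on an accelerometer
   channel — a *hint*;
2. the conditioned channel is amplitude-quantized into ``L`` uniform bins
   spanning its 1st–99th percentile, turning the trace into a symbol sequence;
3. the hinted interval's symbols become a *template*, which is slid across the
   whole recording (stride one sample) at several length scale factors; at
   each offset a graded ("fuzzy") Hamming distance is computed — exact bin
   match costs 0, adjacent bins cost 1/2, two or more bins apart cost 1;
4. windows below an acceptance threshold are candidate cycles; a greedy
   best-first pass keeps a non-overlapping subset (with a refractory gap);
5. the template is re-estimated as the pointwise median of the matched
   instances and steps 3–5 repeat until the selected boundaries stop moving;
6. the resulting swing intervals yield foot-off (interval start) and
   foot-contact (interval end) events, scored against ground truth; any
   dataset whose event errors exceed the escalation bound (0.060 s) is moved
   into the training set and contributes one new hint — the reinforcement
   loop.

Because both the template and the target are quantized over their *own*
percentile range, templates transfer across recordings and subjects without
explicit amplitude normalization; signal polarity is handled by optionally
mirroring the template codes ("auto" tries both orientations and keeps the
better one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import FilterSpec, condition_accelerometer
from .signal_model import (
    CycleSet,
    GaitEvents,
    GaitRecording,
    Hint,
    PartitionErrorReport,
    SignalTrace,
    ValidationError,
)

__all__ = [
    "TemplateModel",
    "MatchCandidate",
    "NoMatchError",
    "quantize",
    "fuzzy_hamming",
    "match_template",
    "select_cycles",
    "refine_template",
    "template_from_hint",
    "partition_with_hints",
    "partition_with_templates",
    "cycles_to_events",
    "partition_error",
    "reinforcement_loop",
    "hint_fraction_pct",
]

log = logging.getLogger("gaitpartition.partitioner")

# matcher defaults; none are dictated by the method itself, all configurable.
# The acceptance threshold must sit between the fuzzy-distance noise floor of
# a correct match (~0.2-0.4: sensor noise flips adjacent bins at cost 1/2,
# and step-time variability misaligns transient edges) and the distance of
# template-vs-baseline windows (>= ~0.6 on conditioned accelerometry); 0.45
# splits that gap.
DEFAULT_LEVELS = 16
DEFAULT_ACCEPT_THRESHOLD = 0.45
DEFAULT_SCALES = (0.8, 0.9, 1.0, 1.1, 1.2)
DEFAULT_REFRACTORY_S = 0.10
MAX_ITERATIONS = 20
ESCALATION_THRESHOLD_S = 0.060  # partitioning-error bound triggering a new hint
EVENT_MATCH_WINDOW_S = 0.5


class NoMatchError(ValidationError):
    """No window matched the template below threshold: a new hint is needed."""


@dataclass(frozen=True)
class TemplateModel:
    """A quantized swing-phase template plus its matching parameters."""

    levels: int
    bin_edges: np.ndarray          # L+1 ascending thresholds of the source signal
    template_codes: np.ndarray     # symbols in 0..L-1
    rate_hz: float                 # rate the template was sampled at
    length_tolerances: tuple = DEFAULT_SCALES
    accept_threshold: float = DEFAULT_ACCEPT_THRESHOLD
    refractory_s: float = DEFAULT_REFRACTORY_S
    polarity: str = "auto"

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValidationError("levels must be >= 2")
        if not 0 < self.accept_threshold < 1:
            raise ValidationError("accept_threshold must be in (0, 1)")
        edges = np.asarray(self.bin_edges, dtype=float)
        if len(edges) != self.levels + 1 or np.any(np.diff(edges) < 0):
            raise ValidationError("bin_edges must be L+1 ascending thresholds")
        codes = np.asarray(self.template_codes, dtype=int)
        if codes.size and (codes.min() < 0 or codes.max() >= self.levels):
            raise ValidationError("template codes must lie in [0, levels)")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "template_codes", codes)

    @property
    def length_s(self) -> float:
        return len(self.template_codes) / self.rate_hz


@dataclass(frozen=True)
class MatchCandidate:
    start_s: float
    end_s: float
    distance: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValidationError("candidate: start_s must be < end_s")
        if not 0.0 <= self.distance <= 1.0:
            raise ValidationError("candidate distance must be in [0, 1]")


# ---------------------------------------------------------------------------
# Quantization and the fuzzy Hamming distance
# ---------------------------------------------------------------------------


def quantize(
    values: np.ndarray, levels: int, bin_edges: Optional[np.ndarray] = None
):
    """Amplitude-quantize a real signal into ``levels`` uniform bins.

    Bins span the 1st–99th percentile of ``values`` (outliers clip into the
    end bins); pass ``bin_edges`` to reuse an existing grid.  Returns
    ``(codes, bin_edges)``.
    """
    if levels < 2:
        raise ValidationError("quantize: levels must be >= 2")
    values = np.asarray(values, dtype=float)
    if bin_edges is None:
        if values.size == 0:
            raise ValidationError("quantize: empty signal and no bin_edges given")
        lo, hi = np.percentile(values, [1.0, 99.0])
        if hi <= lo:  # constant (or near-constant) signal: single occupied bin
            hi = lo + 1.0
        bin_edges = np.linspace(lo, hi, levels + 1)
    codes = np.searchsorted(bin_edges, values, side="right") - 1
    return np.clip(codes, 0, levels - 1).astype(int), np.asarray(bin_edges, float)


def fuzzy_hamming(a: np.ndarray, b: np.ndarray) -> float:
    """Mean graded mismatch between equal-length symbol sequences, in [0, 1].

    Per-symbol cost ``min(|a_i - b_i|, 2) / 2``: identical bins 0, adjacent
    bins 1/2, two or more bins apart 1.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        return 0.0
    return float(np.minimum(np.abs(a - b), 2).mean() / 2.0)


def _resample_codes(codes: np.ndarray, n: int) -> np.ndarray:
    """Linear-interpolate a code sequence onto ``n`` points and round."""
    if n < 1 or codes.size == 0:
        raise ValidationError("cannot resample an empty template")
    if codes.size == 1:
        return np.full(n, codes[0], dtype=int)
    src = np.linspace(0.0, 1.0, codes.size)
    dst = np.linspace(0.0, 1.0, n)
    return np.rint(np.interp(dst, src, codes.astype(float))).astype(int)


# ---------------------------------------------------------------------------
# Matching, selection, refinement
# ---------------------------------------------------------------------------


def match_template(
    model: TemplateModel,
    x: SignalTrace,
    signal_codes: Optional[np.ndarray] = None,
) -> list:
    """Slide the template over the trace at every scale and offset.

    The trace is quantized with its own percentile bin grid (so template and
    target are compared as range-normalized shapes) unless pre-computed
    ``signal_codes`` are supplied.  Returns candidates with distance below
    the model's acceptance threshold, sorted by distance then start time.
    """
    if model.template_codes.size == 0:
        raise ValidationError("empty template")
    if signal_codes is None:
        signal_codes, _ = quantize(x.values, model.levels)
    n = len(signal_codes)
    base_len = len(model.template_codes)
    candidates: list = []
    for scale in model.length_tolerances:
        m = int(round(base_len * scale))
        if m < 2 or m > n:
            continue
        tmpl = _resample_codes(model.template_codes, m)
        windows = sliding_window_view(signal_codes, m)
        dists = np.minimum(np.abs(windows - tmpl[None, :]), 2).mean(axis=1) / 2.0
        for off in np.flatnonzero(dists <= model.accept_threshold):
            candidates.append(
                MatchCandidate(
                    start_s=x.t0_s + off / x.rate_hz,
                    end_s=x.t0_s + (off + m) / x.rate_hz,
                    distance=float(dists[off]),
                )
            )
    if not candidates and all(
        int(round(base_len * s)) > n for s in model.length_tolerances
    ):
        raise ValidationError("trace shorter than the shortest scaled template")
    candidates.sort(key=lambda c: (c.distance, c.start_s))
    return candidates


def select_cycles(
    candidates: Sequence[MatchCandidate],
    refractory_s: float = DEFAULT_REFRACTORY_S,
    channel: str = "",
    template_length_s: float = 0.0,
) -> CycleSet:
    """Greedy best-first non-overlap selection.

    Candidates are taken in (distance, start) order; one is kept iff its
    interval, dilated by the refractory gap on each side, intersects no
    already-kept interval.  Deterministic; ties break toward earlier starts.
    """
    kept: list = []
    for c in candidates:
        a, b = c.start_s - refractory_s, c.end_s + refractory_s
        if all(b <= ka or a >= kb for ka, kb, _ in kept):
            kept.append((c.start_s, c.end_s, c.distance))
    kept.sort()
    return CycleSet(
        intervals=tuple(kept), channel=channel, template_length_s=template_length_s
    )


def refine_template(
    model: TemplateModel, cycles: CycleSet, x: SignalTrace
):
    """Re-estimate the template from the matched instances.

    New template = pointwise median of the matched signal segments, each
    resampled to the median matched length, re-quantized with the model's
    existing bin grid.  Empty cycles return the model unchanged plus a flag.
    Returns ``(model, refined: bool)``.
    """
    if len(cycles) == 0:
        return model, False
    lengths = [int(round((b - a) * x.rate_hz)) for a, b, _ in cycles.intervals]
    med_len = max(int(round(float(np.median(lengths)))), 2)
    grid = np.linspace(0.0, 1.0, med_len)
    instances = []
    for a, b, _ in cycles.intervals:
        seg = x.slice_s(a, b).values
        if len(seg) < 2:
            continue
        instances.append(np.interp(grid, np.linspace(0.0, 1.0, len(seg)), seg))
    if not instances:
        return model, False
    median_wave = np.median(np.vstack(instances), axis=0)
    codes, _ = quantize(median_wave, model.levels, bin_edges=model.bin_edges)
    return replace(model, template_codes=codes, rate_hz=x.rate_hz), True


# ---------------------------------------------------------------------------
# The iterative partitioning procedure
# ---------------------------------------------------------------------------


def template_from_hint(
    rec: GaitRecording,
    hint: Hint,
    levels: int = DEFAULT_LEVELS,
    accept_threshold: float = DEFAULT_ACCEPT_THRESHOLD,
    scales: tuple = DEFAULT_SCALES,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    filter_spec: FilterSpec = FilterSpec(),
) -> TemplateModel:
    """Build a template from one hinted swing interval of a recording.

    The template is cut from the *conditioned* channel (FFT smoothing then
    KZ), quantized over that channel's own percentile range.
    """
    trace = rec[hint.channel]
    hint.validate_against(trace)
    cond = condition_accelerometer(trace, filter_spec)
    codes, edges = quantize(cond.values, levels)
    seg = cond.slice_s(hint.start_s, hint.end_s)
    i0 = cond.index_at(seg.t0_s)
    tmpl = codes[i0 : i0 + len(seg.values)]
    if tmpl.size <= 2:
        raise ValidationError("hint interval spans too few samples for a template")
    return TemplateModel(
        levels=levels,
        bin_edges=edges,
        template_codes=tmpl,
        rate_hz=cond.rate_hz,
        length_tolerances=tuple(scales),
        accept_threshold=accept_threshold,
        refractory_s=refractory_s,
        polarity=hint.polarity,
    )


def _mirror(codes: np.ndarray, levels: int) -> np.ndarray:
    return (levels - 1) - codes


def _boundaries_idx(cycles: CycleSet, rate_hz: float) -> tuple:
    return tuple(
        (int(round(a * rate_hz)), int(round(b * rate_hz)))
        for a, b, _ in cycles.intervals
    )


def _iterate_one_template(
    model: TemplateModel, cond: SignalTrace, channel: str
):
    """Run match -> select -> refine to convergence for one oriented template.

    Returns ``(cycles, mean_distance, n_iterations)``.  Raises NoMatchError
    if the very first match pass selects nothing.
    """
    sig_codes, sig_edges = quantize(cond.values, model.levels)
    work = replace(model, bin_edges=sig_edges)  # refinement grid = target grid
    prev = None
    cycles = CycleSet(intervals=(), channel=channel)
    for it in range(1, MAX_ITERATIONS + 1):
        cands = match_template(work, cond, signal_codes=sig_codes)
        cycles = select_cycles(
            cands, work.refractory_s, channel=channel, template_length_s=work.length_s
        )
        if len(cycles) == 0:
            if it == 1:
                raise NoMatchError(
                    f"no window on channel {channel!r} matched the hint below "
                    f"threshold {work.accept_threshold}; provide a new hint"
                )
            cycles = prev_cycles  # refinement overshot: keep last good selection
            break
        bounds = _boundaries_idx(cycles, cond.rate_hz)
        if bounds == prev:
            break
        prev, prev_cycles = bounds, cycles
        work, refined = refine_template(work, cycles, cond)
        if not refined:
            break
    mean_d = float(np.mean([s for _, _, s in cycles.intervals])) if len(cycles) else 1.0
    return cycles, mean_d, it


def _oriented_variants(model: TemplateModel):
    if model.polarity == "as_is":
        signs = (1,)
    elif model.polarity == "inverted":
        signs = (-1,)
    else:
        signs = (1, -1)
    for sign in signs:
        codes = (
            model.template_codes
            if sign > 0
            else _mirror(model.template_codes, model.levels)
        )
        yield replace(model, template_codes=codes, polarity="as_is")


def partition_with_templates(
    rec: GaitRecording,
    channel: str,
    models: Sequence[TemplateModel],
    filter_spec: FilterSpec = FilterSpec(),
) -> CycleSet:
    """Partition one channel of a recording with a library of templates.

    Each template (and, under "auto" polarity, its mirror) is iterated to
    convergence independently; the per-template cycle sets are then merged by
    one more greedy non-overlap selection pass.  Raises NoMatchError when no
    template matches anywhere.
    """
    if not models:
        raise ValidationError("no templates given")
    cond = condition_accelerometer(rec[channel], filter_spec)
    merged: list = []
    template_len = 0.0
    any_match = False
    for model in models:
        best = None
        for variant in _oriented_variants(model):
            try:
                cycles, mean_d, _ = _iterate_one_template(variant, cond, channel)
            except NoMatchError:
                continue
            if best is None or (len(cycles), -mean_d) > (len(best[0]), -best[1]):
                best = (cycles, mean_d)
        if best is None:
            continue
        any_match = True
        template_len = best[0].template_length_s or template_len
        merged.extend(
            MatchCandidate(start_s=a, end_s=b, distance=s)
            for a, b, s in best[0].intervals
        )
    if not any_match:
        raise NoMatchError(
            f"no template matched channel {channel!r} below threshold; "
            "provide a new hint"
        )
    merged.sort(key=lambda c: (c.distance, c.start_s))
    refractory = models[0].refractory_s
    return select_cycles(
        merged, refractory, channel=channel, template_length_s=template_len
    )


def partition_with_hints(
    rec: GaitRecording,
    hints: Sequence[Hint],
    levels: int = DEFAULT_LEVELS,
    accept_threshold: float = DEFAULT_ACCEPT_THRESHOLD,
    scales: tuple = DEFAULT_SCALES,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    filter_spec: FilterSpec = FilterSpec(),
) -> CycleSet:
    """Partition a recording from user hints (the few-shot entry point).

    One template is built per hint; multiple hints may sit on different
    channels, in which case each channel is partitioned with its own hints
    and the cycle sets are merged by greedy non-overlap selection.
    """
    if not hints:
        raise ValidationError("at least one hint is required")
    by_channel: dict = {}
    for h in hints:
        by_channel.setdefault(h.channel, []).append(h)
    all_cycles: list = []
    channel0 = hints[0].channel
    template_len = 0.0
    for channel, channel_hints in by_channel.items():
        models = [
            template_from_hint(
                rec, h, levels, accept_threshold, scales, refractory_s, filter_spec
            )
            for h in channel_hints
        ]
        cycles = partition_with_templates(rec, channel, models, filter_spec)
        template_len = cycles.template_length_s or template_len
        all_cycles.extend(
            MatchCandidate(start_s=a, end_s=b, distance=s)
            for a, b, s in cycles.intervals
        )
    all_cycles.sort(key=lambda c: (c.distance, c.start_s))
    return select_cycles(
        all_cycles, refractory_s, channel=channel0, template_length_s=template_len
    )


# ---------------------------------------------------------------------------
# Events, scoring, and the reinforcement loop
# ---------------------------------------------------------------------------


def cycles_to_events(cycles: CycleSet, side: str) -> GaitEvents:
    """Swing intervals to events: foot-off at start, foot-contact at end."""
    return GaitEvents(
        foot_contacts_s=tuple(b for _, b, _ in cycles.intervals),
        foot_offs_s=tuple(a for a, _, _ in cycles.intervals),
        side=side,
    )


def partition_error(
    pred: GaitEvents,
    truth: GaitEvents,
    threshold_s: float = ESCALATION_THRESHOLD_S,
    match_window_s: float = EVENT_MATCH_WINDOW_S,
) -> PartitionErrorReport:
    """Absolute timing errors of predicted events vs ground truth.

    Each predicted event is matched to the nearest same-type truth event
    within ``match_window_s``; absolute differences are pooled over both
    event types.  ``escalate`` is true iff any matched error exceeds
    ``threshold_s`` (the bound that moves a dataset into the training set).
    """
    if truth.n_events == 0:
        raise ValidationError("cannot score against empty ground truth")
    if pred.side != truth.side:
        raise ValidationError(
            f"side mismatch: predicted {pred.side!r} vs truth {truth.side!r}"
        )
    errors: list = []
    n_unmatched_pred = 0
    matched_truth: set = set()
    for kind in ("foot_contacts_s", "foot_offs_s"):
        t_times = np.asarray(getattr(truth, kind))
        for p in getattr(pred, kind):
            if t_times.size == 0:
                n_unmatched_pred += 1
                continue
            j = int(np.argmin(np.abs(t_times - p)))
            d = abs(float(t_times[j]) - p)
            if d <= match_window_s:
                errors.append(d)
                matched_truth.add((kind, j))
            else:
                n_unmatched_pred += 1
    n_unmatched_truth = truth.n_events - len(matched_truth)
    return PartitionErrorReport(
        per_event_abs_err_s=tuple(errors),
        n_matched=len(errors),
        n_unmatched_pred=n_unmatched_pred,
        n_unmatched_truth=n_unmatched_truth,
        threshold_s=threshold_s,
    )


def _first_truth_swing_hint(rec: GaitRecording, channel: str, side: str) -> Hint:
    """Automated stand-in for the human GUI step: hint = first truth swing."""
    ev = rec.truth_events[side]
    for off in ev.foot_offs_s:
        later = [c for c in ev.foot_contacts_s if c > off]
        if later:
            return Hint(channel=channel, start_s=off, end_s=later[0], polarity="auto")
    raise ValidationError(f"no complete swing phase in truth events of side {side!r}")


def _count_truth_steps(rec: GaitRecording) -> int:
    """A step per complete swing (foot-off followed by a contact), both sides."""
    total = 0
    for ev in (rec.truth_events or {}).values():
        total += sum(
            1 for off in ev.foot_offs_s if any(c > off for c in ev.foot_contacts_s)
        )
    return total


def hint_fraction_pct(n_hints: int, total_steps: int) -> float:
    """Training-fraction bookkeeping: hints as a percentage of all steps."""
    if total_steps <= 0:
        raise ValidationError("total_steps must be positive")
    return 100.0 * n_hints / total_steps


@dataclass
class ReinforcementResult:
    hints: list                 # (dataset_index, Hint) pairs, in creation order
    training_indices: list     # datasets absorbed into the training set
    reports: dict              # dataset_index -> PartitionErrorReport (test sets)
    total_steps: int
    n_rounds: int

    @property
    def n_hints(self) -> int:
        return len(self.hints)

    @property
    def hint_fraction_pct(self) -> float:
        return hint_fraction_pct(self.n_hints, self.total_steps)


def reinforcement_loop(
    datasets: Sequence[GaitRecording],
    initial_hints: Sequence,
    channel: str,
    side: str = "right",
    threshold_s: float = ESCALATION_THRESHOLD_S,
    filter_spec: FilterSpec = FilterSpec(),
    **template_kwargs,
) -> ReinforcementResult:
    """Active-learning loop: partition, score, escalate, re-hint, repeat.

    ``initial_hints`` may be Hint objects (taken on ``datasets[0]``) or
    ``(dataset_index, Hint)`` pairs.  Every dataset must carry truth events
    for ``side``.  Each round partitions every non-training dataset with the
    template library built from all hints so far; any dataset whose report
    escalates (some event error > ``threshold_s``), or that matches nothing,
    is moved into the training set and contributes one automatically created
    hint — its first ground-truth swing interval.  The loop ends when a full
    round produces no escalation or when every dataset is in training.
    """
    hints: list = []
    for item in initial_hints:
        if isinstance(item, Hint):
            hints.append((0, item))
        else:
            idx, h = item
            hints.append((int(idx), h))
    if not hints:
        raise ValidationError("at least one initial hint is required")
    for i, rec in enumerate(datasets):
        if not rec.truth_events or side not in rec.truth_events:
            raise ValidationError(f"dataset {i} lacks truth events for side {side!r}")

    training = sorted({idx for idx, _ in hints})
    reports: dict = {}
    n_rounds = 0
    while True:
        n_rounds += 1
        models = [
            template_from_hint(datasets[idx], h, filter_spec=filter_spec, **template_kwargs)
            for idx, h in hints
        ]
        escalated = None
        for i, rec in enumerate(datasets):
            if i in training:
                continue
            try:
                cycles = partition_with_templates(rec, channel, models, filter_spec)
                pred = cycles_to_events(cycles, side)
                report = partition_error(pred, rec.truth_events[side], threshold_s)
            except NoMatchError:
                report = None
            reports[i] = report
            if report is None or report.escalate or report.n_matched == 0:
                escalated = i
                break
        if escalated is None:
            break
        log.info("dataset %d escalated; adding a hint from its truth swing", escalated)
        hints.append((escalated, _first_truth_swing_hint(datasets[escalated], channel, side)))
        training.append(escalated)
        reports.pop(escalated, None)
        if len(training) == len(datasets):
            break

    total_steps = sum(_count_truth_steps(rec) for rec in datasets)
    return ReinforcementResult(
        hints=hints,
        training_indices=sorted(training),
        reports=reports,
        total_steps=total_steps,
        n_rounds=n_rounds,
    )
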