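import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitpartition import (
    GaitEvents,
    GaitRecording,
    Hint,
    NoMatchError,
    SignalTrace,
    SyntheticGaitSpec,
    TemplateModel,
    ValidationError,
    cycles_to_events,
    fuzzy_hamming,
    generate_cohort,
    generate_recording,
    hint_fraction_pct,
    match_template,
    partition_error,
    partition_with_hints,
    quantize,
    refine_template,
    reinforcement_loop,
    select_cycles,
    template_from_hint,
)
from gaitpartition.hint_partitioner import MatchCandidate, _resample_codes
from tests.conftest import first_swing_hint

ESCALATION_S = 0.060


# ---------------------------------------------------------------------------
# quantize
# ---------------------------------------------------------------------------


class TestQuantize:
    def test_constant_signal_single_symbol(self):
        codes, edges = quantize(np.full(50, 1.3), levels=8)
        assert len(np.unique(codes)) == 1
        assert len(edges) == 9

    def test_ramp_gives_equal_runs(self):
        codes, _ = quantize(np.linspace(0, 1, 400), levels=4)
        runs = np.bincount(codes, minlength=4)
        # percentile clipping trims the extreme bins slightly
        assert runs.min() >= 90 and runs.max() <= 110
        assert np.all(np.diff(codes) >= 0)

    def test_bin_centers_are_fixed_points(self):
        _, edges = quantize(np.linspace(0, 1, 100), levels=6)
        centers = 0.5 * (edges[:-1] + edges[1:])
        codes, _ = quantize(centers, levels=6, bin_edges=edges)
        assert np.array_equal(codes, np.arange(6))

    def test_levels_below_two_rejected(self):
        with pytest.raises(ValidationError):
            quantize(np.zeros(10), levels=1)


# ---------------------------------------------------------------------------
# fuzzy Hamming distance
# ---------------------------------------------------------------------------


def naive_fuzzy_hamming(a, b):
    assert len(a) == len(b)
    if len(a) == 0:
        return 0.0
    total = 0.0
    for x, y in zip(a, b):
        d = abs(int(x) - int(y))
        total += min(d, 2) / 2.0
    return total / len(a)


class TestFuzzyHamming:
    def test_identical_sequences_zero(self):
        a = np.array([0, 3, 7, 2])
        assert fuzzy_hamming(a, a) == 0.0

    def test_two_bins_apart_is_maximal(self):
        assert fuzzy_hamming(np.zeros(4, int), np.full(4, 2)) == 1.0

    def test_adjacent_bins_cost_half(self):
        assert fuzzy_hamming(np.zeros(4, int), np.ones(4, int)) == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            fuzzy_hamming(np.zeros(3, int), np.zeros(4, int))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_per_symbol_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        a = rng.integers(0, 16, n)
        b = rng.integers(0, 16, n)
        assert fuzzy_hamming(a, b) == pytest.approx(naive_fuzzy_hamming(a, b))


# ---------------------------------------------------------------------------
# match_template vs exhaustive enumeration
# ---------------------------------------------------------------------------


def brute_force_candidates(model: TemplateModel, x: SignalTrace):
    """Independent enumeration over every scale and offset with naive
    per-symbol costs and naive linear-interp template resampling."""
    codes, _ = quantize(x.values, model.levels)
    base = model.template_codes.astype(float)
    out = []
    for scale in model.length_tolerances:
        m = int(round(len(base) * scale))
        if m < 2 or m > len(codes):
            continue
        if len(base) == 1:
            tmpl = np.full(m, int(base[0]))
        else:
            src = np.linspace(0, 1, len(base))
            dst = np.linspace(0, 1, m)
            tmpl = np.rint(np.interp(dst, src, base)).astype(int)
        for off in range(len(codes) - m + 1):
            d = naive_fuzzy_hamming(codes[off : off + m], tmpl)
            if d <= model.accept_threshold:
                out.append(
                    (x.t0_s + off / x.rate_hz, x.t0_s + (off + m) / x.rate_hz, d)
                )
    out.sort(key=lambda c: (c[2], c[0]))
    return out


def _make_model(codes, levels=16, threshold=0.45, scales=(0.8, 0.9, 1.0, 1.1, 1.2)):
    return TemplateModel(
        levels=levels,
        bin_edges=np.linspace(0, 1, levels + 1),
        template_codes=np.asarray(codes, int),
        rate_hz=100.0,
        length_tolerances=scales,
        accept_threshold=threshold,
    )


class TestMatchTemplate:
    def test_exact_subsequence_self_match(self):
        rng = np.random.default_rng(2)
        x = SignalTrace("x", 100.0, rng.standard_normal(300))
        codes, _ = quantize(x.values, 16)
        model = _make_model(codes[100:140])
        cands = match_template(model, x)
        exact = [c for c in cands if c.distance == 0.0]
        assert any(abs(c.start_s - 1.0) < 1e-9 for c in exact)

    def test_periodic_signal_minima_at_period_multiples(self):
        rate, period_s = 100.0, 1.0
        one_period = np.sin(2 * np.pi * np.arange(100) / 100.0)
        x = SignalTrace("p", rate, np.tile(one_period, 5))
        codes, _ = quantize(x.values, 16)
        model = _make_model(codes[:100], threshold=0.05, scales=(1.0,))
        cands = match_template(model, x)
        zero_starts = sorted(c.start_s for c in cands if c.distance == 0.0)
        for k in range(4):
            assert any(abs(s - k * period_s) < 1e-9 for s in zero_starts)

    @pytest.mark.parametrize("seed,threshold,levels", [(0, 0.45, 16), (1, 0.3, 8), (2, 0.6, 16)])
    def test_equals_exhaustive_enumeration(self, seed, threshold, levels):
        rng = np.random.default_rng(seed)
        x = SignalTrace("x", 100.0, np.cumsum(rng.standard_normal(300)) / 5.0)
        codes, _ = quantize(x.values, levels)
        model = _make_model(codes[120:160], levels=levels, threshold=threshold)
        got = [(c.start_s, c.end_s, c.distance) for c in match_template(model, x)]
        want = brute_force_candidates(model, x)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert g == pytest.approx(w)

    def test_empty_template_rejected(self):
        model = _make_model(np.zeros(0, int))
        with pytest.raises(ValidationError):
            match_template(model, SignalTrace("x", 100.0, np.zeros(100)))


# ---------------------------------------------------------------------------
# select_cycles
# ---------------------------------------------------------------------------


def enumerate_best_subset(cands, refractory):
    """All feasible (non-overlapping after dilation) subsets; maximize count,
    then minimize total distance."""
    best = None
    for r in range(len(cands), -1, -1):
        for combo in itertools.combinations(range(len(cands)), r):
            ivs = sorted((cands[i].start_s, cands[i].end_s, cands[i].distance) for i in combo)
            if all(b + refractory <= a2 for (_, b, _), (a2, _, _) in zip(ivs, ivs[1:])):
                tot = sum(d for _, _, d in ivs)
                if best is None or tot < best[1]:
                    best = (r, tot)
        if best is not None:
            return best
    return (0, 0.0)


class TestSelectCycles:
    def test_empty_in_empty_out(self):
        assert len(select_cycles([], 0.1)) == 0

    def test_disjoint_candidates_all_kept(self):
        cands = [
            MatchCandidate(0.0, 0.4, 0.2),
            MatchCandidate(1.0, 1.4, 0.1),
        ]
        cands.sort(key=lambda c: (c.distance, c.start_s))
        assert len(select_cycles(cands, 0.1)) == 2

    def test_overlap_keeps_lower_distance(self):
        cands = [
            MatchCandidate(0.0, 0.4, 0.1),
            MatchCandidate(0.2, 0.6, 0.2),
        ]
        cyc = select_cycles(cands, 0.1)
        assert len(cyc) == 1
        assert cyc.intervals[0][2] == 0.1

    def test_refractory_gap_enforced(self):
        cands = [
            MatchCandidate(0.0, 0.4, 0.1),
            MatchCandidate(0.45, 0.9, 0.2),  # gap 0.05 < refractory 0.1
        ]
        assert len(select_cycles(cands, 0.1)) == 1
        assert len(select_cycles(cands, 0.04)) == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_against_subset_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        cands = []
        for _ in range(int(rng.integers(2, 8))):
            a = float(rng.uniform(0, 4))
            cands.append(
                MatchCandidate(
                    round(a, 3),
                    round(a + float(rng.uniform(0.3, 0.6)), 3),
                    round(float(rng.uniform(0, 0.5)), 3),
                )
            )
        cands.sort(key=lambda c: (c.distance, c.start_s))
        refractory = 0.1
        cyc = select_cycles(cands, refractory)
        best_count, best_total = enumerate_best_subset(cands, refractory)
        # greedy is deterministic best-first: never beats the enumerated
        # optimum, always keeps the globally best candidate, and is maximal
        assert len(cyc) <= best_count
        assert cyc.intervals  # at least the best candidate survives
        assert any(s == cands[0].distance for _, _, s in cyc.intervals)
        for c in cands:  # maximality: nothing more can be added
            a, b = c.start_s - refractory, c.end_s + refractory
            fits = all(b <= ka or a >= kb for ka, kb, _ in cyc.intervals)
            assert not fits
        if len(cyc) == best_count:
            assert sum(s for _, _, s in cyc.intervals) <= best_total + 1e-9


# ---------------------------------------------------------------------------
# refine_template
# ---------------------------------------------------------------------------


class TestRefineTemplate:
    def _setup(self):
        import dataclasses

        wave = np.sin(np.linspace(0, np.pi, 40))
        x = np.concatenate([np.zeros(30), wave, np.zeros(30), wave, np.zeros(30)])
        tr = SignalTrace("x", 100.0, x)
        codes, edges = quantize(tr.values, 16)
        model = dataclasses.replace(_make_model(codes[30:70]), bin_edges=edges)
        return tr, model

    def test_identical_instances_fixed_point(self):
        tr, model = self._setup()
        from gaitpartition.signal_model import CycleSet

        cycles = CycleSet(intervals=((0.30, 0.70, 0.0), (1.00, 1.40, 0.0)), channel="x")
        refined, flag = refine_template(model, cycles, tr)
        assert flag
        assert np.array_equal(refined.template_codes, model.template_codes)

    def test_level_shifted_instances_give_pointwise_median(self):
        rate = 100.0
        base = np.sin(np.linspace(0, np.pi, 50))
        x = np.concatenate([base + 0.0, base + 0.2, base + 0.4])
        tr = SignalTrace("x", rate, x)
        _, edges = quantize(tr.values, 16)
        model = TemplateModel(
            levels=16, bin_edges=edges, template_codes=np.zeros(50, int), rate_hz=rate
        )
        from gaitpartition.signal_model import CycleSet

        cycles = CycleSet(
            intervals=((0.0, 0.5, 0.0), (0.5, 1.0, 0.0), (1.0, 1.5, 0.0)), channel="x"
        )
        refined, _ = refine_template(model, cycles, tr)
        want, _ = quantize(base + 0.2, 16, bin_edges=edges)  # the median instance
        assert np.mean(np.abs(refined.template_codes - want)) < 0.6

    def test_empty_cycles_returns_unchanged_with_flag(self):
        tr, model = self._setup()
        from gaitpartition.signal_model import CycleSet

        refined, flag = refine_template(model, CycleSet(intervals=(), channel="x"), tr)
        assert not flag
        assert refined is model


# ---------------------------------------------------------------------------
# partition_with_hints
# ---------------------------------------------------------------------------


def make_periodic_recording(n_periods=8, rate=100.0, period_s=1.0, burst_frac=0.4):
    """Noiseless periodic trace: one smooth burst per period on a baseline."""
    n = int(n_periods * period_s * rate) + int(rate)
    t = np.arange(n) / rate
    x = np.zeros(n)
    for k in range(n_periods):
        c = 0.5 + k * period_s + burst_frac * period_s / 2
        x += np.exp(-0.5 * ((t - c) / (0.08 * period_s)) ** 2)
    tr = SignalTrace("acc", rate, x, units="m/s^2")
    return GaitRecording(traces={"acc": tr}), t


class TestPartitionWithHints:
    def test_noiseless_periodic_recovers_every_period(self):
        rec, _ = make_periodic_recording(n_periods=8)
        hint = Hint(channel="acc", start_s=0.5, end_s=0.9, polarity="as_is")
        cycles = partition_with_hints(rec, [hint])
        assert len(cycles) == 8
        starts = cycles.starts_s
        np.testing.assert_allclose(np.diff(starts), 1.0, atol=0.011)

    def test_shift_equivariance(self):
        rec, _ = make_periodic_recording(n_periods=6)
        shift = 17  # samples
        tr = rec["acc"]
        shifted = SignalTrace(
            "acc", tr.rate_hz, np.concatenate([np.zeros(shift), tr.values[:-shift]])
        )
        rec2 = GaitRecording(traces={"acc": shifted})
        hint1 = Hint(channel="acc", start_s=0.5, end_s=0.9, polarity="as_is")
        hint2 = Hint(
            channel="acc", start_s=0.5 + shift / 100.0, end_s=0.9 + shift / 100.0,
            polarity="as_is",
        )
        c1 = partition_with_hints(rec, [hint1])
        c2 = partition_with_hints(rec2, [hint2])
        kept = min(len(c1), len(c2))
        np.testing.assert_allclose(
            c2.starts_s[:kept] - c1.starts_s[:kept], shift / 100.0, atol=0.011
        )

    def test_synthetic_recording_one_hint_recovers_swings(self, default_recording):
        rec = default_recording
        truth = rec.truth_events["right"]
        cycles = partition_with_hints(rec, [first_swing_hint(rec)])
        assert len(cycles) >= 18
        # every matched boundary within the escalation bound of a truth event
        report = partition_error(cycles_to_events(cycles, "right"), truth)
        assert report.n_matched >= 36
        assert report.max_s <= ESCALATION_S

    def test_polarity_auto_invariant_to_global_negation(self, default_recording):
        rec = default_recording
        neg_traces = {
            k: (v.with_values(-v.values) if k == "acc_foot_r" else v)
            for k, v in rec.traces.items()
        }
        rec_neg = GaitRecording(
            traces=neg_traces, side=rec.side, condition=rec.condition,
            truth_events=rec.truth_events,
        )
        hint = first_swing_hint(rec, polarity="auto")
        c_pos = partition_with_hints(rec, [hint])
        c_neg = partition_with_hints(rec_neg, [hint])
        assert len(c_pos) == len(c_neg)
        np.testing.assert_allclose(c_pos.starts_s, c_neg.starts_s, atol=0.011)

    def test_convergence_within_iteration_budget(self, default_recording):
        from gaitpartition.hint_partitioner import (
            _iterate_one_template,
            MAX_ITERATIONS,
        )
        from gaitpartition.preprocess import condition_accelerometer

        rec = default_recording
        model = template_from_hint(rec, first_swing_hint(rec, polarity="as_is"))
        cond = condition_accelerometer(rec["acc_foot_r"])
        cycles, _, n_iter = _iterate_one_template(model, cond, "acc_foot_r")
        assert n_iter <= MAX_ITERATIONS
        assert len(cycles) >= 18

    def test_cycles_never_overlap_after_dilation(self, default_recording):
        cycles = partition_with_hints(default_recording, [first_swing_hint(default_recording)])
        refractory = 0.10
        ivs = cycles.intervals
        for (a0, b0, _), (a1, _, _) in zip(ivs, ivs[1:]):
            assert b0 + refractory <= a1 + 1e-9

    def test_no_hints_rejected(self, small_recording):
        with pytest.raises(ValidationError):
            partition_with_hints(small_recording, [])

    def test_unmatchable_template_raises_no_match(self, small_recording):
        # a swing template cannot match an entirely flat recording (no gait
        # content) at any scale below threshold
        quiet = GaitRecording(
            traces={"acc": SignalTrace("acc", 100.0, np.zeros(1500), units="m/s^2")}
        )
        donor = generate_recording(SyntheticGaitSpec(n_steps=5, seed=2))
        model = template_from_hint(donor, first_swing_hint(donor, polarity="as_is"))
        from gaitpartition import partition_with_templates

        with pytest.raises(NoMatchError):
            partition_with_templates(quiet, "acc", [model])


# ---------------------------------------------------------------------------
# events and scoring
# ---------------------------------------------------------------------------


class TestEventsAndScoring:
    def test_swing_interval_maps_to_off_then_contact(self):
        from gaitpartition.signal_model import CycleSet

        cyc = CycleSet(intervals=((1.00, 1.42, 0.1),), channel="acc")
        ev = cycles_to_events(cyc, "right")
        assert ev.foot_offs_s == (1.00,)
        assert ev.foot_contacts_s == (1.42,)
        ev.check_alternating()

    def test_empty_cycles_empty_events(self):
        from gaitpartition.signal_model import CycleSet

        ev = cycles_to_events(CycleSet(intervals=(), channel="acc"), "left")
        assert ev.n_events == 0

    def test_perfect_prediction_scores_zero(self):
        ev = GaitEvents(foot_contacts_s=(1.0, 2.0), foot_offs_s=(1.6,), side="right")
        report = partition_error(ev, ev)
        assert report.mean_s == 0.0 and report.max_s == 0.0
        assert not report.escalate

    def test_single_event_beyond_bound_escalates(self):
        truth = GaitEvents(foot_contacts_s=(1.0,), foot_offs_s=(), side="right")
        pred = GaitEvents(foot_contacts_s=(1.07,), foot_offs_s=(), side="right")
        report = partition_error(pred, truth, threshold_s=0.060)
        assert report.escalate
        assert partition_error(
            GaitEvents(foot_contacts_s=(1.05,), foot_offs_s=(), side="right"), truth
        ).escalate is False

    def test_jittered_events_mean_matches_oracle(self):
        rng = np.random.default_rng(8)
        contacts = np.arange(1.0, 21.0, 1.0)
        jitter = rng.uniform(-0.03, 0.03, len(contacts))
        truth = GaitEvents(foot_contacts_s=tuple(contacts), foot_offs_s=(), side="left")
        pred = GaitEvents(
            foot_contacts_s=tuple(contacts + jitter), foot_offs_s=(), side="left"
        )
        report = partition_error(pred, truth)
        assert report.mean_s == pytest.approx(np.mean(np.abs(jitter)), abs=1e-12)

    def test_empty_truth_rejected(self):
        pred = GaitEvents(foot_contacts_s=(1.0,), foot_offs_s=(), side="left")
        empty = GaitEvents(foot_contacts_s=(), foot_offs_s=(), side="left")
        with pytest.raises(ValidationError):
            partition_error(pred, empty)


# ---------------------------------------------------------------------------
# reinforcement loop
# ---------------------------------------------------------------------------


class TestReinforcementLoop:
    def test_identical_datasets_need_no_new_hints(self):
        rec = generate_recording(SyntheticGaitSpec(n_steps=8, seed=5))
        datasets = [rec, rec, rec]
        res = reinforcement_loop(
            datasets, [first_swing_hint(rec)], channel="acc_foot_r", side="right"
        )
        assert res.n_hints == 1
        assert res.training_indices == [0]
        assert all(not r.escalate for r in res.reports.values())

    def test_cohort_terminates_with_few_hints_and_bounded_errors(self):
        cohort = generate_cohort(
            10,
            ranges={"cadence_hz": (0.7, 1.2), "stance_fraction": (0.55, 0.65)},
            seed=1,
        )
        res = reinforcement_loop(
            cohort, [first_swing_hint(cohort[0])], channel="acc_foot_r", side="right"
        )
        assert res.n_hints <= len(cohort)
        assert res.total_steps == 200  # 10 subjects x 10 landings x 2 sides
        for idx, report in res.reports.items():
            assert idx not in res.training_indices
            assert report.max_s <= ESCALATION_S

    def test_hint_fraction_bookkeeping(self):
        assert hint_fraction_pct(6, 567) == pytest.approx(100 * 6 / 567)
        assert hint_fraction_pct(6, 567) <= 2.0
        assert hint_fraction_pct(9, 368) <= 3.0
        with pytest.raises(ValidationError):
            hint_fraction_pct(1, 0)

    def test_dataset_without_truth_rejected(self, small_recording):
        bare = GaitRecording(traces=dict(small_recording.traces))
        with pytest.raises(ValidationError):
            reinforcement_loop(
                [bare], [first_swing_hint(small_recording)], channel="acc_foot_r"
            )
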