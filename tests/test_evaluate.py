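import math

import numpy as np
import pytest

from cce_triage import (
    PolypAnnotation,
    ReaderParams,
    ReviewEvent,
    ReviewTrace,
    ScorerParams,
    SensitivityCurve,
    TriageError,
    ValidationError,
    build_candidates,
    generate_study,
    match_detections,
    rank_frames,
    sensitivity_gain,
    sensitivity_time_curve,
    simulate_reader,
    simulate_scores,
    speedup_factor,
    stratified_sensitivity,
    super_expert_curve,
    time_to_parity,
)


def trace_of(events, study_id="s1", budget=math.inf):
    return ReviewTrace(study_id=study_id, events=events, budget_s=budget)


def ev(head, ts, decision="polyp", elapsed=None, rank=1, idx=0):
    return ReviewEvent(
        rank=rank,
        head=head,
        frame_index=idx,
        timestamp_s=ts,
        decision=decision,
        elapsed_s=elapsed if elapsed is not None else ts + 1,
    )


ANN = PolypAnnotation("p1", "front", 10.0, 20.0, 5.0, "flat", 5)


class TestMatchDetections:
    def test_closed_endpoints_count(self):
        for ts in (10.0, 20.0):
            v = match_detections(trace_of([ev("front", ts)]), [ANN])["p1"]
            assert v.detected

    def test_other_head_never_matches(self):
        v = match_detections(trace_of([ev("rear", 15.0)]), [ANN])["p1"]
        assert not v.detected

    def test_outside_interval_never_matches(self):
        v = match_detections(trace_of([ev("front", 20.5)]), [ANN])["p1"]
        assert not v.detected

    @pytest.mark.parametrize("decision", ["clear", "other"])
    def test_non_polyp_decisions_are_non_detections(self, decision):
        v = match_detections(trace_of([ev("front", 15.0, decision)]), [ANN])["p1"]
        assert not v.detected

    def test_first_detection_time_is_earliest_match(self):
        events = [
            ev("front", 15.0, elapsed=30.0),
            ev("front", 18.0, elapsed=60.0),
        ]
        v = match_detections(trace_of(events), [ANN])["p1"]
        assert v.first_detection_time_s == 30.0

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        """All-pairs interval-membership oracle over randomized traces."""
        for _ in range(200):
            anns = [
                PolypAnnotation(
                    f"p{j}",
                    rng.choice(["front", "rear"]),
                    float(lo := rng.uniform(0, 90)),
                    float(lo + rng.uniform(0, 10)),
                    5.0,
                    "flat",
                    3,
                )
                for j in range(10)
            ]
            events = []
            for i in range(25):
                events.append(
                    ReviewEvent(
                        rank=i + 1,
                        head=rng.choice(["front", "rear"]),
                        frame_index=i,
                        timestamp_s=float(rng.uniform(0, 100)),
                        decision=str(rng.choice(["polyp", "clear", "other"])),
                        elapsed_s=float(i + 1),
                    )
                )
            trace = trace_of(events)
            verdicts = match_detections(trace, anns)
            for a in anns:
                expect = [
                    e.elapsed_s
                    for e in events
                    if e.decision == "polyp"
                    and e.head == a.head
                    and a.first_ts <= e.timestamp_s <= a.last_ts
                ]
                v = verdicts[a.polyp_id]
                assert v.detected == bool(expect)
                assert v.first_detection_time_s == (min(expect) if expect else None)


class TestStratifiedSensitivity:
    def _verdicts(self, anns, detected_ids):
        from cce_triage.evaluate import DetectionVerdict

        return {
            a.polyp_id: DetectionVerdict(a.polyp_id, a.polyp_id in detected_ids, 1.0)
            for a in anns
        }

    def test_all_detected_table1_counts(self, table1_study):
        _, anns = table1_study
        df = stratified_sensitivity(self._verdicts(anns, {a.polyp_id for a in anns}), anns)
        assert (df["sensitivity_pct"].dropna() == 100.0).all()
        by = {(r.category, r.label): r.n_polyps for r in df.itertuples()}
        assert (by[("size", "small")], by[("size", "large")]) == (29, 23)
        assert (
            by[("visibility", "low")],
            by[("visibility", "normal")],
            by[("visibility", "high")],
        ) == (9, 15, 28)
        assert (
            by[("morphology", "pedunculated")],
            by[("morphology", "sessile")],
            by[("morphology", "flat")],
        ) == (4, 25, 23)
        assert by[("overall", "all")] == 52

    def test_none_detected_is_zero_everywhere(self, table1_study):
        _, anns = table1_study
        df = stratified_sensitivity(self._verdicts(anns, set()), anns)
        assert (df["sensitivity_pct"].dropna() == 0.0).all()

    def test_random_mask_matches_hand_count(self, table1_study, rng):
        _, anns = table1_study
        chosen = {a.polyp_id for a in anns if rng.random() < 0.6}
        df = stratified_sensitivity(self._verdicts(anns, chosen), anns)
        for row in df.itertuples():
            if row.category == "overall":
                members = anns
            elif row.category == "size":
                members = [a for a in anns if a.size_class == row.label]
            elif row.category == "visibility":
                members = [a for a in anns if a.visibility_class == row.label]
            else:
                members = [a for a in anns if a.morphology == row.label]
            hits = sum(a.polyp_id in chosen for a in members)
            assert row.n_polyps == len(members)
            assert row.sensitivity_pct == pytest.approx(100 * hits / len(members))

    def test_partition_counts_sum_to_total(self, table1_study):
        _, anns = table1_study
        df = stratified_sensitivity(self._verdicts(anns, set()), anns)
        for cat in ("size", "visibility", "morphology"):
            assert df.loc[df.category == cat, "n_polyps"].sum() == 52

    def test_empty_stratum_reports_null_not_crash(self):
        anns = [PolypAnnotation("p1", "front", 0, 4, 5.0, "flat", 3)]
        df = stratified_sensitivity(self._verdicts(anns, {"p1"}), anns)
        ped = df[(df.category == "morphology") & (df.label == "pedunculated")]
        assert ped.n_polyps.iloc[0] == 0
        assert np.isnan(ped.sensitivity_pct.iloc[0])


class TestSensitivityCurve:
    def test_single_detection_steps_at_its_time(self):
        from cce_triage.evaluate import DetectionVerdict

        verdicts = {"p1": DetectionVerdict("p1", True, 300.0)}
        curve = sensitivity_time_curve([(verdicts, 1)], t_max=600, grid_step_s=1.0)
        assert curve.value_at(299.0) == 0.0
        assert curve.value_at(300.0) == 1.0
        assert curve.final == 1.0

    def test_no_detections_is_flat_zero(self):
        from cce_triage.evaluate import DetectionVerdict

        verdicts = {"p1": DetectionVerdict("p1", False, None)}
        curve = sensitivity_time_curve([(verdicts, 1)], t_max=100)
        assert np.all(curve.sensitivity == 0.0)

    def test_mean_of_two_studies_is_pointwise_average(self):
        from cce_triage.evaluate import DetectionVerdict

        s1 = {"a": DetectionVerdict("a", True, 100.0)}
        s2 = {
            "b": DetectionVerdict("b", True, 200.0),
            "c": DetectionVerdict("c", False, None),
        }
        curve = sensitivity_time_curve([(s1, 1), (s2, 2)], t_max=400, grid_step_s=50)
        c1 = sensitivity_time_curve([(s1, 1)], t_max=400, grid_step_s=50)
        c2 = sensitivity_time_curve([(s2, 2)], t_max=400, grid_step_s=50)
        assert np.allclose(curve.sensitivity, (c1.sensitivity + c2.sensitivity) / 2)

    def test_zero_polyp_study_excluded_with_warning(self, caplog):
        from cce_triage.evaluate import DetectionVerdict

        s1 = {"a": DetectionVerdict("a", True, 10.0)}
        with caplog.at_level("WARNING"):
            curve = sensitivity_time_curve([(s1, 1), ({}, 0)], t_max=100)
        assert "zero lesions" in caplog.text
        assert curve.final == 1.0

    def test_curve_invariants_enforced(self):
        with pytest.raises(ValidationError):
            SensitivityCurve([0.0, 1.0], [0.5, 0.2])  # decreasing
        with pytest.raises(ValidationError):
            SensitivityCurve([1.0, 2.0], [0.0, 0.1])  # does not start at 0
        with pytest.raises(ValidationError):
            SensitivityCurve([], [])


class TestSuperExpertCurve:
    def test_steps_at_rank_times(self):
        """Lesions whose best candidates sit at ranks r1 < r2 are detected
        exactly at r1*t and r2*t seconds."""
        from conftest import make_frames

        frames = make_frames([0.9, 0.1, 0.8, 0.1, 0.7], dt=10.0)
        anns = [
            PolypAnnotation("pA", "front", 20.0, 20.0, 5.0, "flat", 1),  # rank 2
            PolypAnnotation("pB", "front", 40.0, 40.0, 5.0, "flat", 1),  # rank 3
        ]
        cands = build_candidates(rank_frames(frames), suppression_radius_s=0.0)
        curve = super_expert_curve(cands, anns, seconds_per_candidate=7.0, t_max=60)
        assert curve.value_at(13.9) == 0.0
        assert curve.value_at(14.0) == 0.5  # rank 2 * 7 s
        assert curve.value_at(21.0) == 1.0  # rank 3 * 7 s

    def test_flat_zero_when_no_center_hits(self):
        from conftest import make_frames

        frames = make_frames([0.5, 0.6], dt=2.0)
        anns = [PolypAnnotation("p1", "rear", 0.0, 2.0, 5.0, "flat", 2)]
        cands = build_candidates(rank_frames(frames), suppression_radius_s=0.0)
        curve = super_expert_curve(cands, anns, 3.0, t_max=30)
        assert np.all(curve.sensitivity == 0.0)

    def test_dominates_stochastic_readers(self, small_config):
        frames, anns = generate_study(small_config)
        scored = simulate_scores(frames, anns, ScorerParams(seed=4))
        cands = build_candidates(rank_frames(scored))
        expert = super_expert_curve(cands, anns, 3.0, t_max=900)
        for seed in range(20):
            params = ReaderParams(p_recognize=0.7, p_false_call=0.05, seed=seed)
            trace = simulate_reader(cands, anns, params, time_budget_s=900)
            verdicts = match_detections(trace, anns)
            curve = sensitivity_time_curve([(verdicts, len(anns))], t_max=900)
            assert np.all(expert.sensitivity - curve.sensitivity >= -1e-12)


class TestParityAndSpeedup:
    def test_already_at_target_returns_zero(self):
        curve = SensitivityCurve([0.0, 10.0], [0.0, 0.5])
        assert time_to_parity(curve, 0.0) == 0.0

    def test_unreachable_target_is_infinite(self):
        curve = SensitivityCurve([0.0, 10.0], [0.0, 0.5])
        assert time_to_parity(curve, 0.9) == math.inf

    def test_linear_interpolation_between_grid_points(self):
        curve = SensitivityCurve([0.0, 100.0, 200.0], [0.0, 0.75, 0.85])
        assert time_to_parity(curve, 0.8) == pytest.approx(150.0)

    def test_target_outside_unit_interval_rejected(self):
        curve = SensitivityCurve([0.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValidationError):
            time_to_parity(curve, 1.5)

    def test_reference_worked_example(self):
        """47.11 min of linear review vs 8.00 min to parity gives the
        factor-of-six speed-up (5.89 before rounding)."""
        factor = speedup_factor(47.11, 8.00)
        assert factor == pytest.approx(5.89, abs=0.005)
        assert round(factor) == 6

    @pytest.mark.parametrize("ref,par,expected", [(60.0, 12.0, 5.0), (7.0, 7.0, 1.0)])
    def test_direct_ratios(self, ref, par, expected):
        assert speedup_factor(ref, par) == expected

    @pytest.mark.parametrize("par", [0.0, math.inf, -3.0])
    def test_degenerate_parity_rejected(self, par):
        with pytest.raises(TriageError):
            speedup_factor(60.0, par)

    def test_sensitivity_gain_is_difference_in_points(self):
        assert sensitivity_gain(87.80, 81.08) == pytest.approx(6.72)


class TestConsistency:
    def test_curve_final_equals_overall_stratified(self, small_config):
        """The curve's value at budget end and the stratified overall row
        are two views of the same verdicts."""
        frames, anns = generate_study(small_config)
        scored = simulate_scores(frames, anns, ScorerParams(seed=8))
        cands = build_candidates(rank_frames(scored))
        params = ReaderParams(p_recognize=0.8, p_false_call=0.02, seed=3)
        trace = simulate_reader(cands, anns, params, time_budget_s=600)
        verdicts = match_detections(trace, anns)
        curve = sensitivity_time_curve([(verdicts, len(anns))], t_max=600)
        df = stratified_sensitivity(verdicts, anns)
        overall = df.loc[df.category == "overall", "sensitivity_pct"].iloc[0]
        assert 100 * curve.final == pytest.approx(overall)

    def test_end_to_end_recovery_equals_surviving_candidate_fraction(
        self, small_config
    ):
        """With a perfect reader and unlimited budget, recovered sensitivity
        is exactly the fraction of lesions with at least one surviving
        candidate center after suppression."""
        frames, anns = generate_study(small_config)
        scored = simulate_scores(frames, anns, ScorerParams(seed=12))
        cands = build_candidates(rank_frames(scored), suppression_radius_s=6.0)
        covered = sum(
            any(a.contains(c.head, c.center.timestamp_s) for c in cands)
            for a in anns
        )
        params = ReaderParams(p_recognize=1.0, p_false_call=0.0, seed=0)
        trace = simulate_reader(cands, anns, params, time_budget_s=math.inf)
        verdicts = match_detections(trace, anns)
        assert sum(v.detected for v in verdicts.values()) == covered
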