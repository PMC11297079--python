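import numpy as np
import pandas as pd
import pytest

from gazescene.core import TrialDesign
from gazescene.simulate import (
    SimulationParams,
    make_design,
    saccade_duration_ms,
    simulate_experiment,
    simulate_trial,
    start_position_deg,
)


def _design(**kw):
    base = dict(subject_id=1, image_id=1, block_label="A",
                task_level="Free_Viewing", posture_level="Chin_Rest",
                start_position_index=8,
                start_position_xy=start_position_deg(8))
    base.update(kw)
    return TrialDesign(**base)


class TestDesigns:
    def test_exp1_each_image_twice_once_per_task(self):
        designs = make_design(1, 2, 4, rng_seed=5)
        df = pd.DataFrame([(d.subject_id, d.image_id, d.task_level)
                           for d in designs],
                          columns=["subj", "img", "task"])
        counts = df.groupby(["subj", "img"]).size()
        assert (counts == 2).all()
        per_task = df.groupby(["subj", "img", "task"]).size()
        assert (per_task == 1).all()

    def test_exp1_posture_counterbalanced_within_task(self):
        designs = make_design(1, 2, 4, rng_seed=5)
        df = pd.DataFrame([(d.subject_id, d.task_level, d.posture_level,
                            d.block_label) for d in designs],
                          columns=["subj", "task", "posture", "block"])
        # within each subject and task, both postures appear equally often
        counts = df.groupby(["subj", "task", "posture"]).size().unstack()
        assert (counts["Chin_Rest"] == counts["Standing"]).all()
        # posture-to-block assignment flips between consecutive subjects
        b1 = df[(df.subj == 1) & (df.block == "A")].posture.iloc[0]
        b2 = df[(df.subj == 2) & (df.block == "A")].posture.iloc[0]
        assert b1 != b2

    def test_exp2_one_trial_per_posture_block(self):
        designs = make_design(2, 1, 4, rng_seed=2)
        assert len(designs) == 4
        assert {d.posture_level for d in designs} == \
            {"Chin_Rest", "Sitting", "Standing", "Balancing"}
        assert all(d.task_level == "Count_Animals" for d in designs)

    def test_block_divisibility_errors(self):
        with pytest.raises(ValueError, match="divisible by 2"):
            make_design(1, 1, 5)
        with pytest.raises(ValueError, match="divisible by 4"):
            make_design(2, 1, 6)

    def test_unknown_experiment(self):
        with pytest.raises(ValueError, match="experiment"):
            make_design(3, 1, 4)

    def test_seed_determinism(self):
        a = make_design(1, 2, 4, rng_seed=9)
        b = make_design(1, 2, 4, rng_seed=9)
        assert a == b

    def test_start_position_grid(self):
        # corner positions of the 3x5 grid on the projection screen
        x1, y1 = start_position_deg(1)
        x15, y15 = start_position_deg(15)
        assert x1 == pytest.approx(-x15) and y1 == pytest.approx(-y15)
        assert x1 < 0 and y1 > 0          # top-left quadrant
        xc, yc = start_position_deg(8)    # grid center = screen center
        assert xc == pytest.approx(0.0) and yc == pytest.approx(0.0)


class TestSimulateTrial:
    def test_ground_truth_partitions_trial(self):
        params = SimulationParams(rng_seed=1)
        _, events = simulate_trial(params, _design())
        assert events[0].onset_ms == 0.0
        assert events[-1].offset_ms == pytest.approx(8000.0)
        for prev, nxt in zip(events, events[1:]):
            assert nxt.onset_ms == pytest.approx(prev.offset_ms)
        kinds = [e.kind for e in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))  # alternating

    def test_seed_determinism_bit_identical(self):
        params = SimulationParams(rng_seed=77)
        rec1, _ = simulate_trial(params, _design())
        rec2, _ = simulate_trial(params, _design())
        pd.testing.assert_frame_equal(rec1.samples, rec2.samples)

    def test_full_anchor_no_noise_centers_all_fixations(self):
        params = SimulationParams(
            rng_seed=4, fixation_noise_sd=0.0, anchor_strength=1.0,
            anchor_floor=1.0, anchor_sd_deg=(1e-12, 1e-12), blink_rate=0.0,
            sd_log_fixdur=0.0,
        )
        _, events = simulate_trial(params, _design())
        fix = [e for e in events if e.kind == "fixation"][1:]
        for ev in fix:
            assert np.hypot(*ev.centroid_xy) < 1e-9

    def test_short_trial_single_fixation(self):
        params = SimulationParams(rng_seed=0, trial_duration_ms=50.0)
        _, events = simulate_trial(params, _design())
        assert len(events) == 1 and events[0].kind == "fixation"

    def test_fixation_count_matches_renewal_expectation(self):
        # brute-force renewal oracle: expected count = T / (mean fixation
        # duration + mean saccade duration), measured on the generated truth
        params = SimulationParams(rng_seed=0, blink_rate=0.0)
        counts, fixdur, sacdur = [], [], []
        for seed in range(300):
            p = SimulationParams(rng_seed=seed, blink_rate=0.0)
            _, events = simulate_trial(p, _design())
            counts.append(sum(e.kind == "fixation" for e in events))
            # untruncated durations only (interior events)
            fixdur += [e.duration_ms for e in events[1:-1]
                       if e.kind == "fixation"]
            sacdur += [e.duration_ms for e in events[1:-1]
                       if e.kind == "saccade"]
        expected = 8000.0 / (np.mean(fixdur) + np.mean(sacdur))
        assert np.mean(counts) == pytest.approx(expected, rel=0.05)
        # and the configured ~250 ms / ~6 deg regime gives roughly 28
        assert 24 < np.mean(counts) < 33

    def test_invalid_anchor_errors(self):
        with pytest.raises(ValueError, match="anchor"):
            SimulationParams(anchor_strength=1.5)


class TestSimulateExperiment:
    def test_duplicate_subject_image_task_errors(self):
        d = _design()
        params = SimulationParams(rng_seed=0)
        with pytest.raises(ValueError, match="duplicated"):
            simulate_experiment(params, [d, d])

    def test_no_effects_equal_condition_means(self):
        # zero condition effects and zero random SDs: per-condition mean log
        # ground-truth fixation durations agree within Monte-Carlo error
        params = SimulationParams(
            rng_seed=11, blink_rate=0.0,
            subject_sd={"log_duration": 0.0, "log_amplitude": 0.0,
                        "anchor": 0.0},
            image_sd={"log_duration": 0.0, "log_amplitude": 0.0,
                      "anchor": 0.0},
        )
        designs = make_design(1, 4, 6, rng_seed=11)
        ds = simulate_experiment(params, designs)
        logdur = {lvl: [] for lvl in ("Free_Viewing", "Guess_Time")}
        for d, rec in zip(designs, ds.recordings):
            evs = ds.ground_truth[rec.trial_id]
            logdur[d.task_level] += [np.log(e.duration_ms) for e in evs[1:-1]
                                     if e.kind == "fixation"]
        m1, m2 = np.mean(logdur["Free_Viewing"]), np.mean(logdur["Guess_Time"])
        pooled_se = np.sqrt(
            np.var(logdur["Free_Viewing"]) / len(logdur["Free_Viewing"])
            + np.var(logdur["Guess_Time"]) / len(logdur["Guess_Time"]))
        assert abs(m1 - m2) < 4 * pooled_se

    def test_condition_effect_shifts_ground_truth(self):
        shift = -0.2
        params = SimulationParams(
            rng_seed=21, blink_rate=0.0,
            condition_effects={"Guess_Time": {"log_duration": shift}},
            subject_sd={"log_duration": 0.0, "log_amplitude": 0.0,
                        "anchor": 0.0},
            image_sd={"log_duration": 0.0, "log_amplitude": 0.0,
                      "anchor": 0.0},
        )
        designs = make_design(1, 4, 6, rng_seed=21)
        ds = simulate_experiment(params, designs)
        logdur = {lvl: [] for lvl in ("Free_Viewing", "Guess_Time")}
        for d, rec in zip(designs, ds.recordings):
            evs = ds.ground_truth[rec.trial_id]
            logdur[d.task_level] += [np.log(e.duration_ms) for e in evs[1:-1]
                                     if e.kind == "fixation"]
        observed = np.mean(logdur["Guess_Time"]) - np.mean(logdur["Free_Viewing"])
        assert observed == pytest.approx(shift, abs=0.05)

    def test_random_intercepts_have_requested_sd(self):
        params = SimulationParams(
            rng_seed=31,
            subject_sd={"log_duration": 0.2, "log_amplitude": 0.0,
                        "anchor": 0.0},
        )
        designs = [
            _design(subject_id=s, image_id=1)
            for s in range(1, 201)
        ]
        ds = simulate_experiment(params, designs)
        re = ds.random_effects
        drawn = re[re["unit"] == "subject"]["log_duration"]
        assert drawn.std(ddof=1) == pytest.approx(0.2, rel=0.2)
        assert abs(drawn.mean()) < 0.05


def test_saccade_duration_main_sequence():
    assert saccade_duration_ms(0.0) == 21.0
    assert saccade_duration_ms(10.0) == 21.0 + 22.0
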