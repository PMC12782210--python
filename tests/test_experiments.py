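"""Split construction for all four experiment families and the run loop."""

import numpy as np
import pytest

from motionid import (
    HyperparameterGrid,
    ProtocolSpec,
    TransformerConfig,
    build_length_sweep,
    build_position_split,
    build_rq1_experiments,
    build_rq1_split,
    pick_decoys,
    position_split_candidates,
    run_experiment,
    sweep_timeline,
)
from motionid.experiments import ExperimentSpec, Selection

USERS_36 = [f"user{i:02d}" for i in range(36)]
FAST_GRID = HyperparameterGrid(knn_k=(5, 10))


class TestDecoys:
    def test_constant_across_calls_for_a_seed(self):
        assert pick_decoys(USERS_36, 7) == pick_decoys(USERS_36, 7)
        assert len(pick_decoys(USERS_36, 7)) == 4

    def test_cohort_too_small_for_decoys(self):
        with pytest.raises(ValueError):
            pick_decoys(USERS_36[:5], 7)


class TestRq1Split:
    def test_thirty_six_users_yield_thirty_two_specs(self):
        specs = build_rq1_experiments(USERS_36, seed=7)
        assert len(specs) == 32
        decoys = set(pick_decoys(USERS_36, 7))
        for spec in specs:
            assert spec.target_user_id not in decoys
            # each model trains on 32 users x 2 minutes
            assert len(spec.train_selection) == 32
            assert all(len(s.minutes) == 2 for s in spec.train_selection)

    def test_decoys_never_in_training(self):
        for spec in build_rq1_experiments(USERS_36, seed=3):
            train_users = {s.user_id for s in spec.train_selection}
            assert train_users.isdisjoint(spec.decoy_user_ids)

    def test_training_minutes_cover_both_positions(self):
        protocol = ProtocolSpec()
        spec = build_rq1_split(USERS_36, "user00", seed=7)
        for sel in spec.train_selection:
            lay, sit = sel.minutes
            assert lay in protocol.laying_minute_indices
            assert sit in protocol.sitting_minute_indices

    def test_test_set_is_target_plus_decoys_last_three_sitting(self):
        spec = build_rq1_split(USERS_36, "user00", seed=7)
        assert {s.user_id for s in spec.test_selection} == {
            "user00", *spec.decoy_user_ids
        }
        assert all(s.minutes == (13, 14, 15) for s in spec.test_selection)

    def test_target_train_sitting_minute_outside_test_block(self):
        for seed in range(5):
            target = next(
                u for u in USERS_36 if u not in pick_decoys(USERS_36, seed)
            )
            spec = build_rq1_split(USERS_36, target, seed=seed)
            target_sel = next(
                s for s in spec.train_selection if s.user_id == target
            )
            assert target_sel.minutes[1] in (11, 12)

    def test_same_seed_reproduces_minute_choices(self):
        a = build_rq1_split(USERS_36, "user09", seed=42)
        b = build_rq1_split(USERS_36, "user09", seed=42)
        assert a == b

    def test_decoy_target_rejected(self):
        decoy = pick_decoys(USERS_36, 7)[0]
        with pytest.raises(ValueError, match="decoy"):
            build_rq1_split(USERS_36, decoy, seed=7)


class TestLengthSweep:
    def test_timeline_is_nine_laying_plus_three_sitting(self):
        timeline = sweep_timeline()
        assert len(timeline) == 12
        assert timeline == (2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13)

    def test_forward_one_minute_has_eleven_minute_gap(self):
        spec = build_length_sweep(USERS_36, "user00", "forward_from_start", 1, 7)
        assert spec.gap_to_test_min == 11.0
        minutes = spec.train_selection[0].minutes
        assert minutes == (sweep_timeline()[0],)

    def test_backward_one_minute_precedes_test_block(self):
        spec = build_length_sweep(USERS_36, "user00", "backward_trim", 1, 7)
        assert spec.gap_to_test_min == 0.0
        assert spec.train_selection[0].minutes == (13,)  # minute before test (14, 15)

    def test_full_timeline_directions_coincide(self):
        fwd = build_length_sweep(USERS_36, "user00", "forward_from_start", 12, 7)
        bwd = build_length_sweep(USERS_36, "user00", "backward_trim", 12, 7)
        assert fwd.train_selection == bwd.train_selection
        assert fwd.test_selection == bwd.test_selection

    def test_each_sweep_has_twelve_configurations(self):
        specs = [
            build_length_sweep(USERS_36, "user00", "backward_trim", m, 7)
            for m in range(1, 13)
        ]
        assert len({s.meta["train_minutes"] for s in specs}) == 12

    @pytest.mark.parametrize("bad_m", [0, 13])
    def test_out_of_range_minutes_rejected(self, bad_m):
        with pytest.raises(ValueError, match="1..12"):
            build_length_sweep(USERS_36, "user00", "forward_from_start", bad_m, 7)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            build_length_sweep(USERS_36, "user00", "sideways", 3, 7)


class TestPositionSplit:
    def test_laying_on_laying_has_seven_offsets(self):
        assert len(position_split_candidates("laying2", "laying2")) == 7

    def test_sitting_on_sitting_has_fewer_offsets_than_laying(self):
        n_sit = len(position_split_candidates("sitting2", "sitting2"))
        assert n_sit == 2
        assert n_sit < len(position_split_candidates("laying2", "laying2"))

    def test_mixed_block_has_one_minute_per_position(self):
        protocol = ProtocolSpec()
        for cand in position_split_candidates("mixed1+1", "laying2"):
            lay, sit = cand
            assert lay in protocol.laying_minute_indices
            assert sit in protocol.sitting_minute_indices
        spec = build_position_split(USERS_36, "user00", "mixed1+1", "laying2", 0, 7)
        lay, sit = spec.train_selection[0].minutes
        assert lay in protocol.laying_minute_indices
        assert sit in protocol.sitting_minute_indices

    def test_training_block_never_overlaps_test_block(self):
        for train_kind in ("laying2", "sitting2", "mixed1+1"):
            for test_kind in ("laying2", "sitting2"):
                for off, cand in enumerate(
                    position_split_candidates(train_kind, test_kind)
                ):
                    spec = build_position_split(
                        USERS_36, "user00", train_kind, test_kind, off, 7
                    )
                    test_minutes = set(spec.test_selection[0].minutes)
                    assert test_minutes.isdisjoint(cand)

    def test_offset_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            build_position_split(USERS_36, "user00", "sitting2", "sitting2", 2, 7)

    def test_unknown_kinds_rejected(self):
        with pytest.raises(ValueError, match="train kind"):
            build_position_split(USERS_36, "user00", "standing2", "laying2", 0, 7)
        with pytest.raises(ValueError, match="test kind"):
            build_position_split(USERS_36, "user00", "laying2", "standing2", 0, 7)


class TestSpecInvariants:
    def test_decoy_in_training_selection_rejected(self):
        with pytest.raises(ValueError, match="decoy"):
            ExperimentSpec(
                rq_id="rq1",
                target_user_id="a",
                decoy_user_ids=("d",),
                train_selection=(
                    Selection("a", (1,)), Selection("d", (1,)),
                ),
                test_selection=(Selection("a", (14,)), Selection("d", (14,))),
                seed=0,
            )

    def test_overlapping_train_test_minutes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ExperimentSpec(
                rq_id="rq1",
                target_user_id="a",
                decoy_user_ids=("d",),
                train_selection=(Selection("a", (14,)), Selection("b", (1,))),
                test_selection=(Selection("a", (14,)), Selection("d", (14,))),
                seed=0,
            )


class TestRunExperiment:
    def test_backward_split_separates_users(self, small_cohort_data):
        """Adjacent same-position training identifies targets near-perfectly."""
        users = small_cohort_data.user_ids
        decoys = pick_decoys(users, 11)
        targets = [u for u in users if u not in decoys]
        f1s = []
        for target in targets:
            spec = build_length_sweep(users, target, "backward_trim", 2, 11)
            result = run_experiment(spec, "knn", small_cohort_data, grid=FAST_GRID)
            f1s.append(result.metrics.f1)
        assert float(np.median(f1s)) >= 0.9

    def test_result_shapes_and_provenance(self, small_cohort_data):
        users = small_cohort_data.user_ids
        decoys = pick_decoys(users, 11)
        target = [u for u in users if u not in decoys][0]
        spec = build_rq1_split(users, target, 11)
        result = run_experiment(spec, "knn", small_cohort_data, grid=FAST_GRID)
        # test set: target + 4 decoys, last 3 sitting minutes, 60 windows each
        assert result.n_test == 5 * 3 * 60
        assert result.metrics.total == result.n_test
        assert set(result.predictions["user_id"]) == {target, *decoys}
        assert result.n_train == len(spec.train_selection) * 2 * 60
        assert np.array_equal(
            result.predictions["decision"],
            (result.predictions["score"] >= 0.5).astype(int),
        )

    def test_rerun_is_deterministic(self, small_cohort_data):
        users = small_cohort_data.user_ids
        decoys = pick_decoys(users, 11)
        target = [u for u in users if u not in decoys][0]
        spec = build_length_sweep(users, target, "backward_trim", 1, 11)
        a = run_experiment(spec, "knn", small_cohort_data, grid=FAST_GRID)
        b = run_experiment(spec, "knn", small_cohort_data, grid=FAST_GRID)
        assert a.metrics == b.metrics
        assert np.array_equal(a.predictions["score"], b.predictions["score"])

    def test_swipeformer_requires_sequences(self, small_cohort_data):
        from motionid.experiments import CohortData

        users = small_cohort_data.user_ids
        decoys = pick_decoys(users, 11)
        target = [u for u in users if u not in decoys][0]
        spec = build_length_sweep(users, target, "backward_trim", 1, 11)
        stripped = CohortData(
            protocol=small_cohort_data.protocol,
            features=small_cohort_data.features,
            window_user=small_cohort_data.window_user,
            window_minute=small_cohort_data.window_minute,
            window_position=small_cohort_data.window_position,
            window_id=small_cohort_data.window_id,
            sequences=None,
        )
        with pytest.raises(ValueError, match="sequences"):
            run_experiment(spec, "swipeformer", stripped)

    def test_swipeformer_runs_end_to_end(self, small_cohort_data):
        users = small_cohort_data.user_ids
        decoys = pick_decoys(users, 11)
        target = [u for u in users if u not in decoys][0]
        spec = build_length_sweep(users, target, "backward_trim", 1, 11)
        cfg = TransformerConfig(
            sequence_length=small_cohort_data.protocol.sample_rate_hz,
            embedding_dim=16, epochs=8, seed=3,
        )
        result = run_experiment(
            spec, "swipeformer", small_cohort_data, transformer_config=cfg
        )
        assert 0.0 <= result.metrics.f1 <= 1.0
        assert result.metrics.f1 >= 0.8  # adjacent same-position training
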