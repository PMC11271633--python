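"""Oystercatcher-foraging optimizer: schedule, moves, loop, space codec."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mammopt.mml_eoo import (
    Candidate,
    ChoiceDim,
    FloatDim,
    IntDim,
    ScheduleState,
    SearchSpace,
    optimize,
    oyster_schedule,
    propose_move,
)


def sphere_params(p):
    x = np.array(list(p.values()))
    return float((x ** 2).sum())


def box_space(ndim, lo=-5.0, hi=5.0):
    return SearchSpace(tuple(FloatDim(lo, hi) for _ in range(ndim)),
                       tuple(f"x{i}" for i in range(ndim)))


class TestSchedule:
    def test_endpoints_and_midpoint(self):
        s0 = oyster_schedule(0, 50)
        assert (s0.O, s0.J, s0.Q) == pytest.approx((5.0, 5.0, 2.6), abs=1e-12)
        sR = oyster_schedule(50, 50)
        assert (sR.O, sR.J, sR.Q) == pytest.approx((3.0, -5.0, 0.6), abs=1e-12)
        assert sR.D == pytest.approx(0.5, abs=1e-12)
        sm = oyster_schedule(25, 50)
        assert (sm.O, sm.J, sm.Q) == pytest.approx((4.0, 0.0, 1.6), abs=1e-12)

    def test_oyster_size_affine_in_iteration(self):
        R = 37
        sizes = [oyster_schedule(r, R).O for r in range(R + 1)]
        diffs = np.diff(sizes)
        assert np.allclose(diffs, diffs[0], atol=1e-12)
        assert diffs[0] < 0

    def test_energy_requirement_tracks_bird_energy(self):
        s = oyster_schedule(30, 50)
        assert s.N == s.D

    def test_late_schedule_goes_negative(self):
        s = oyster_schedule(50, 50)
        assert s.J < 0 and s.J + s.N < 0

    def test_errors(self):
        with pytest.raises(ValueError):
            oyster_schedule(0, 0)
        with pytest.raises(ValueError):
            oyster_schedule(51, 50)
        with pytest.raises(ValueError):
            oyster_schedule(-1, 50)


class _HalfRng:
    """Stub rng whose uniform draws are always 0.5."""

    def uniform(self, low=0.0, high=1.0, size=None):
        return np.full(size, 0.5) if size is not None else 0.5


class TestProposeMove:
    def test_exploitation_at_best_is_fixed_point(self):
        space = box_space(3)
        sched = oyster_schedule(1, 50)  # early: J + N > 0
        best = Candidate(np.array([1.0, -2.0, 0.5]), 0.0)
        cand = Candidate(best.position.copy(), 1.0)
        out = propose_move(cand, best, sched, np.random.default_rng(0), space)
        assert np.allclose(out.position, best.position)

    def test_exploitation_displacement_term(self):
        space = box_space(2, -10, 10)
        sched = ScheduleState(r=1, R=50, O=4.0, J=3.0, Q=1.6, D=-0.5, N=0.5)
        cand = Candidate(np.array([0.0, 0.0]), None)
        best = Candidate(np.array([1.0, 1.0]), None)
        out = propose_move(cand, best, sched, _HalfRng(), space)
        # displacement O * f * (P_m - P) = 4 * 0.5 * 1 = 2 per dimension
        assert np.allclose(out.position, [2.0, 2.0])

    def test_exploration_identity_at_unit_calorie_gain(self):
        space = box_space(2)
        sched = ScheduleState(r=40, R=50, O=3.4, J=-3.0, Q=1.0, D=0.3, N=0.3)
        cand = Candidate(np.array([1.5, -2.5]), None)
        out = propose_move(cand, cand, sched, np.random.default_rng(0), space)
        assert np.allclose(out.position, cand.position)

    def test_moves_stay_in_bounds(self):
        space = box_space(4, -1.0, 2.0)
        rng = np.random.default_rng(1)
        lo, hi = space.internal_bounds()
        for r in (1, 10, 30, 49):
            sched = oyster_schedule(r, 50)
            for _ in range(50):
                cand = Candidate(rng.uniform(lo, hi))
                best = Candidate(rng.uniform(lo, hi))
                out = propose_move(cand, best, sched, rng, space)
                assert np.all(out.position >= lo - 1e-12)
                assert np.all(out.position <= hi + 1e-12)


class TestOptimize:
    def test_seeded_member_at_optimum_is_kept(self):
        space = box_space(3, -5, 5)  # midpoint = origin = sphere optimum

        res = optimize(sphere_params, space, pop_size=4, max_iter=5, seed=0,
                       seed_midpoint=True)
        assert res.history[0] == pytest.approx(0.0, abs=1e-12)
        assert res.best_fitness == pytest.approx(0.0, abs=1e-12)

    def test_history_non_increasing_and_budget(self):
        space = box_space(5)
        for seed in range(5):
            res = optimize(sphere_params, space, pop_size=6, max_iter=12,
                           seed=seed, cache=False)
            assert res.evaluations == 6 * 13
            assert len(res.history) == 13
            assert all(b <= a for a, b in zip(res.history, res.history[1:]))

    def test_same_seed_bit_identical(self):
        space = box_space(4)
        r1 = optimize(sphere_params, space, pop_size=5, max_iter=8, seed=42)
        r2 = optimize(sphere_params, space, pop_size=5, max_iter=8, seed=42)
        assert r1.history == r2.history
        assert np.array_equal(r1.best_position, r2.best_position)

    def test_single_round_equals_best_of_initial_plus_one_proposal(self):
        # with max_iter=1 the result is the best of pop + pop proposals
        space = box_space(2)
        seen = []

        def spy(p):
            v = sphere_params(p)
            seen.append(v)
            return v

        res = optimize(spy, space, pop_size=4, max_iter=1, seed=9, cache=False)
        assert res.best_fitness == min(seen)
        assert len(seen) == 8

    def test_objective_failure_carries_context(self):
        def bad(p):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="iteration 0, candidate 0"):
            optimize(bad, box_space(2), pop_size=3, max_iter=2, seed=0)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            optimize(sphere_params, box_space(2), pop_size=1, max_iter=5, seed=0)
        with pytest.raises(ValueError):
            optimize(sphere_params, box_space(2), pop_size=4, max_iter=0, seed=0)

    def test_run_log_records_every_evaluation(self, tmp_path):
        import json

        path = tmp_path / "log.jsonl"
        res = optimize(sphere_params, box_space(2), pop_size=3, max_iter=4,
                       seed=1, log_path=path)
        records = [json.loads(l) for l in path.read_text().splitlines()]
        assert len(records) == res.evaluations
        assert set(records[0]) == {"iteration", "candidate", "decoded_params",
                                   "fitness"}


class TestSpaceCodec:
    def test_choice_nearest_index_is_one_based(self):
        d = ChoiceDim((2, 4, 8, 16, 32, 64))
        assert d.decode(2.7) == 8
        assert d.decode(0.2) == 2
        assert d.decode(99.0) == 64

    def test_int_rounding_and_clamping(self):
        d = IntDim(5, 255)
        assert d.decode(254.6) == 255
        assert d.decode(-3.0) == 5
        assert d.decode(400.0) == 255

    def test_midpoint_decodes_to_median_element(self):
        space = SearchSpace(
            (IntDim(5, 255), IntDim(5, 50), IntDim(300, 1000),
             ChoiceDim((2, 4, 8, 16, 32, 64))),
            ("hidden", "epochs", "steps", "batch"),
        )
        mid = space.decode(space.midpoint())
        assert mid == {"hidden": 130, "epochs": 27, "steps": 650, "batch": 8}

    @pytest.mark.parametrize(
        "dim,values",
        [
            (IntDim(5, 255), range(5, 256)),
            (IntDim(5, 50), range(5, 51)),
            (IntDim(300, 1000), range(300, 1001)),
            (ChoiceDim((2, 4, 8, 16, 32, 64)), (2, 4, 8, 16, 32, 64)),
        ],
    )
    def test_decode_idempotent_on_grid(self, dim, values):
        for v in values:
            assert dim.decode(dim.encode(v)) == v

    @given(st.floats(-1000, 2000))
    def test_decode_always_lands_inside_printed_ranges(self, x):
        assert 5 <= IntDim(5, 255).decode(x) <= 255
        assert ChoiceDim((2, 4, 8, 16, 32, 64)).decode(x) in (2, 4, 8, 16, 32, 64)

    def test_space_validation(self):
        with pytest.raises(ValueError):
            IntDim(10, 5)
        with pytest.raises(ValueError):
            ChoiceDim(())
        with pytest.raises(ValueError):
            SearchSpace((), ())
        with pytest.raises(ValueError):
            SearchSpace((IntDim(0, 1),), ("a", "b"))
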