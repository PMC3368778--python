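"""Decelerated-motion kinematics: closed form, clamping, graded fields."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ocellus as oc
from ocellus.errors import InputError, InvalidFieldError, NotYetReleasedError
from ocellus.kinematics import MotionParams, position_at, trajectory


UNIT = oc.UniformField(-1.0)


class TestPositionAt:
    @pytest.mark.parametrize(
        "v0,a,s,t,expected",
        [
            (10, -1, 0, 0, 0.0),        # zero elapsed time
            (10, -1, 0, 10, 50.0),      # at the stopping time: v0^2/2
            (10, -1, 0, 25, 50.0),      # clamped long after stopping
            (9, -1, 0, 4, 28.0),        # quadratic midway: 36 - 8
            (12, -2, 0, 100, 36.0),     # -v0^2/2a
            (10, -1, 3, 9, 42.0),       # released at s=3: 60 - 18
            (0, -1, 0, 5, 0.0),         # zero initial velocity never moves
        ],
    )
    def test_uniform_closed_form(self, v0, a, s, t, expected):
        x = position_at(MotionParams(v0, s), oc.UniformField(a), t)
        assert x == pytest.approx(expected, abs=1e-12)

    def test_query_before_release_rejected(self):
        with pytest.raises(NotYetReleasedError):
            position_at(MotionParams(10, 5.0), UNIT, 4.0)

    def test_non_negative_field_rejected(self):
        with pytest.raises(InvalidFieldError):
            oc.UniformField(0.0)
        with pytest.raises(InvalidFieldError):
            oc.UniformField(1.0)
        with pytest.raises(InvalidFieldError):
            oc.GradedField(lambda x: -1.0 if x < 10 else 0.5, x_max=100)

    def test_piecewise_graded_field(self):
        # energy argument: v^2 = 100 - 2*25 = 50 at x=25, then
        # 50 - 4*(x-25) = 0 at x = 37.5
        gf = oc.GradedField(lambda x: -1.0 if x < 25 else -2.0, x_max=100)
        x = position_at(MotionParams(10), gf, 60.0)
        assert x == pytest.approx(37.5, abs=1e-2)

    def test_constant_graded_matches_uniform(self):
        gf = oc.GradedField(lambda x: -1.0, x_max=100)
        for t in (0.5, 3.0, 7.25, 10.0, 20.0):
            xg = position_at(MotionParams(10), gf, t)
            xu = position_at(MotionParams(10), UNIT, t)
            assert xg == pytest.approx(xu, rel=1e-6, abs=1e-9)


class TestStoppingAndFinal:
    @pytest.mark.parametrize(
        "v0,a,t_stop,x_final",
        [(10, -1, 10.0, 50.0), (0, -1, 0.0, 0.0), (12, -2, 6.0, 36.0),
         (9, -1, 9.0, 40.5)],
    )
    def test_values(self, v0, a, t_stop, x_final):
        assert oc.stopping_time(v0, a) == pytest.approx(t_stop)
        assert oc.final_position(v0, a) == pytest.approx(x_final)

    def test_final_equals_position_after_stop(self):
        for t in (10.0, 11.0, 1e6):
            assert position_at(MotionParams(10), UNIT, t) == oc.final_position(10, -1)

    @pytest.mark.parametrize("bad_a", [0.0, 0.5, np.inf])
    def test_invalid_field(self, bad_a):
        with pytest.raises(InvalidFieldError):
            oc.stopping_time(10, bad_a)
        with pytest.raises(InvalidFieldError):
            oc.final_position(10, bad_a)


class TestTrajectory:
    def test_sweep_maxima_at_stopping_time(self):
        grid = np.linspace(0, 15, 301)
        for v0 in (9, 10, 11, 12):
            traj = trajectory(MotionParams(v0), UNIT, grid)
            assert traj.x.max() == pytest.approx(v0 * v0 / 2.0)
            after = traj.x[grid >= v0]
            assert np.all(after == after[0])  # exactly constant after stop
            assert np.all(np.diff(traj.x) >= 0)

    def test_steeper_deceleration_stops_nearer(self):
        grid = np.linspace(0, 20, 101)
        x1 = trajectory(MotionParams(10), oc.UniformField(-1), grid).x.max()
        x2 = trajectory(MotionParams(10), oc.UniformField(-2), grid).x.max()
        assert (x1, x2) == (pytest.approx(50.0), pytest.approx(25.0))

    def test_unsorted_grid_rejected(self):
        with pytest.raises(InputError):
            trajectory(MotionParams(10), UNIT, [0.0, 2.0, 1.0])

    def test_tsv_export(self, tmp_path):
        traj = trajectory(MotionParams(10), UNIT, np.linspace(0, 12, 13))
        out = tmp_path / "traj.tsv"
        traj.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "t\tx\tv\tstopped"
        assert len(lines) == 14
        last = lines[-1].split("\t")
        assert float(last[1]) == 50.0 and last[3] == "1"


class TestOracleEquivalence:
    def test_thousand_random_draws(self, oracle, rng):
        """Closed form vs. the brute-force fine-step integrator."""
        worst = 0.0
        for _ in range(1000):
            v0 = rng.uniform(0.0, 20.0)
            a = rng.uniform(-5.0, -0.1)
            t = rng.uniform(0.0, 1.5 * oc.stopping_time(max(v0, 1e-6), a))
            x = position_at(MotionParams(v0), oc.UniformField(a), t)
            ref = oracle(v0, a, t)
            err = abs(x - ref) / max(abs(ref), 1e-9)
            worst = max(worst, err)
        assert worst < 1e-6


class TestMonotonicity:
    def test_final_position_monotone(self):
        v0s = np.linspace(0.5, 20, 40)
        finals = [oc.final_position(v, -1.0) for v in v0s]
        assert np.all(np.diff(finals) > 0)
        mags = np.linspace(0.1, 5, 40)
        finals_a = [oc.final_position(10.0, -m) for m in mags]
        assert np.all(np.diff(finals_a) < 0)

    def test_graded_steeper_everywhere_travels_less(self):
        uniform_final = oc.final_position(10, -1)
        gf = oc.GradedField(lambda x: -1.0 - 0.05 * x, x_max=100)
        xg = position_at(MotionParams(10), gf, 50.0)
        assert xg < uniform_final


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    v0=st.floats(0.0, 20.0),
    a=st.floats(-5.0, -0.1),
    t1=st.floats(0.0, 40.0),
    dt=st.floats(0.0, 40.0),
)
def test_clamped_quadratic_contract(v0, a, t1, dt):
    """x(t) never decreases, and is exactly the final position after stop."""
    f = oc.UniformField(a)
    x1 = position_at(MotionParams(v0), f, t1)
    x2 = position_at(MotionParams(v0), f, t1 + dt)
    assert x2 >= x1
    t_stop = oc.stopping_time(v0, a)
    if t1 >= t_stop:
        assert x1 == oc.final_position(v0, a)
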