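"""Exact HS1 propagator: hypergeometric basis, particular constants,
trajectories, and the self-induced-transparency closed form."""

import math

import mpmath as mp
import numpy as np
import pytest

import blochsolve as bs
from blochsolve.hs1 import HS1SolverContext, _evaluate_projective
from conftest import TWOPI, fig_hs1


@pytest.fixture
def pulse():
    return fig_hs1(0.1)


@pytest.fixture
def no_fm_pulse():
    beta = bs.beta_from_truncation(0.01)
    return bs.HS1Pulse(
        omega1m=bs.sit_amplitude(beta, 5e-3), A=0.0, beta=beta, Tp=5e-3
    )


class TestReparameterization:
    def test_center_and_boundaries(self, pulse):
        assert bs.hs1_p(pulse.tc, pulse) == pytest.approx(0.5)
        expected = (1 + math.tanh(pulse.beta)) / 2
        assert bs.hs1_p(pulse.tc + pulse.Tp / 2, pulse) == pytest.approx(expected)
        # limits
        assert bs.hs1_p(pulse.tc + 100 * pulse.Tp, pulse) == pytest.approx(1.0)
        assert bs.hs1_p(pulse.tc - 100 * pulse.Tp, pulse) == pytest.approx(0.0)

    def test_monotone_and_sech_identity(self, pulse):
        ts = np.linspace(pulse.t_start, pulse.t_end, 33)
        ps = bs.hs1_p(ts, pulse)
        assert np.all(np.diff(ps) > 0)
        # am^2 / w1m^2 = sech^2 = 4 p (1-p)
        lhs = (pulse.am(ts) / pulse.omega1m) ** 2
        assert lhs == pytest.approx(4 * ps * (1 - ps), rel=1e-12)


class TestHypergeometricParameters:
    def test_no_fm_reduction(self):
        p = bs.HS1Pulse(omega1m=TWOPI * 1000, A=0.0, beta=2.0, Tp=4e-3)
        Omega = TWOPI * 300
        a, b, c = bs.hs1_abc(p, Omega)
        assert complex(a) == pytest.approx(p.Tp * p.omega1m / (4 * p.beta))
        assert complex(b) == pytest.approx(-complex(a))
        assert complex(c) == pytest.approx(
            0.5 + 1j * p.Tp * Omega / (4 * p.beta)
        )
        # on resonance the third parameter is exactly 1/2
        _, _, c0 = bs.hs1_abc(p, 0.0)
        assert complex(c0) == pytest.approx(0.5)

    def test_structure_identities(self, pulse):
        """Sum/product identities pin the branch of the square root."""
        a, b, c = bs.hs1_abc(pulse, TWOPI * 100)
        pref = pulse.Tp / (4 * pulse.beta)
        assert complex(a + b) == pytest.approx(-1j * pulse.A * pulse.Tp
                                               / (2 * pulse.beta))
        # (-iA + s)(-iA - s) = -A^2 - s^2 = -omega1m^2
        assert complex(a * b) == pytest.approx(
            -(pref**2) * pulse.omega1m**2, rel=1e-12
        )
        assert complex(c).real == pytest.approx(0.5)

    def test_strong_sweep_parameters_pure_imaginary(self):
        # A > omega1m: the square root is pure imaginary (principal branch)
        p = bs.HS1Pulse(omega1m=TWOPI * 200, A=TWOPI * 2000, beta=2.0, Tp=4e-3)
        a, b, _ = bs.hs1_abc(p, 0.0)
        assert abs(complex(a).real) < 1e-12 * abs(complex(a))
        assert abs(complex(b).real) < 1e-12 * abs(complex(b))


class TestBasis:
    def test_gauss_series_at_origin(self, pulse):
        a, b, c = bs.hs1_abc(pulse, TWOPI * 50)
        with mp.workdps(30):
            FA, FB, _, _ = bs.hs1_basis(1e-12, a, b, c)
            assert abs(complex(FA) - 1.0) < 1e-9

    def test_derivatives_match_central_differences(self, pulse):
        a, b, c = bs.hs1_abc(pulse, TWOPI * 50)
        with mp.workdps(40):
            h = mp.mpf(10) ** -15
            for p0 in (0.2, 0.5, 0.8):
                FA, FB, FAp, FBp = bs.hs1_basis(p0, a, b, c)
                FA2, FB2, _, _ = bs.hs1_basis(p0 + h, a, b, c)
                FA1, FB1, _, _ = bs.hs1_basis(p0 - h, a, b, c)
                assert abs((FA2 - FA1) / (2 * h) - FAp) / abs(FAp) < mp.mpf(10) ** -8
                assert abs((FB2 - FB1) / (2 * h) - FBp) / abs(FBp) < mp.mpf(10) ** -8

    def test_wronskian_closed_form(self, pulse):
        """W = FA FB' - FB FA' obeys Abel's identity for the
        hypergeometric equation: W ~ p^-c (1-p)^(c-a-b-1)."""
        a, b, c = bs.hs1_abc(pulse, TWOPI * 50)
        with mp.workdps(30):
            def W(p):
                FA, FB, FAp, FBp = bs.hs1_basis(p, a, b, c)
                return FA * FBp - FB * FAp

            def abel(p):
                p = mp.mpf(p)
                return p ** (-c) * (1 - p) ** (c - a - b - 1)

            ratio = W(mp.mpf("0.3")) / W(mp.mpf("0.7"))
            expected = abel("0.3") / abel("0.7")
            assert abs(ratio - expected) / abs(expected) < mp.mpf(10) ** -20

    def test_invalid_p_rejected(self, pulse):
        a, b, c = bs.hs1_abc(pulse, 0.0)
        with pytest.raises(ValueError):
            bs.hs1_basis(1.5, a, b, c)


class TestParticularConstant:
    def test_anchor_reproduced(self, pulse):
        ctx = HS1SolverContext.create(pulse, TWOPI * 100)
        f0 = 0.31 - 0.4j
        t0 = pulse.t_start + 0.2 * pulse.duration
        const = bs.hs1_particular(bs.RiemannPoint.finite(f0), t0, ctx)
        back = bs.hs1_evaluate(ctx, const, t0)
        assert back.value == pytest.approx(f0, abs=1e-12)

    def test_south_pole_anchor(self, pulse):
        """An inverted-state anchor (f at infinity) propagates cleanly."""
        ctx = HS1SolverContext.create(pulse, TWOPI * 100)
        iso = bs.Isochromat(TWOPI * 100, bs.Magnetization(0.0, 0.0, -1.0))
        ts = np.linspace(pulse.t_start, pulse.t_end, 41)
        exact = bs.hs1_propagate(pulse, iso, ts)
        ref = bs.rk4_propagate(pulse, iso, 10_000, eval_times=ts)
        assert bs.compare_trajectories(exact, ref).mean < 1e-8

    def test_sit_constant_shrinks_with_truncation(self):
        """Equilibrium anchor gives C near zero, vanishing in the
        low-truncation limit (C ~ 2 x truncation)."""
        mags = {}
        for trunc in (0.01, 0.001):
            beta = bs.beta_from_truncation(trunc)
            p = bs.HS1Pulse(
                omega1m=bs.sit_amplitude(beta, 5e-3), A=0.0, beta=beta, Tp=5e-3
            )
            ctx = HS1SolverContext.create(p, 0.0)
            const = bs.hs1_particular(
                bs.RiemannPoint.finite(0.0), p.t_start, ctx
            )
            mags[trunc] = abs(const.C)
        assert mags[0.01] < 0.05
        assert mags[0.001] < 0.1 * mags[0.01]

    def test_projective_scale_invariance(self, pulse):
        ctx = HS1SolverContext.create(pulse, 0.0)
        t0 = pulse.t_start
        c1 = bs.hs1_particular(bs.RiemannPoint.finite(0.2j), t0, ctx)
        c2 = bs.ParticularConstant(5 * c1.CA, 5 * c1.CB)
        f1 = bs.hs1_evaluate(ctx, c1, pulse.tc)
        f2 = bs.hs1_evaluate(ctx, c2, pulse.tc)
        assert f1.value == pytest.approx(f2.value, rel=1e-13)

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError):
            bs.ParticularConstant(0, 0)

    def test_constant_of_motion_along_rk4_trajectory(self, pulse):
        iso = bs.Isochromat(
            TWOPI * 100, bs.Magnetization.from_array([0.3, -0.4, math.sqrt(0.75)])
        )
        anchors = np.linspace(
            pulse.t_start + 0.1 * pulse.duration,
            pulse.t_end - 0.1 * pulse.duration, 5,
        )
        traj = bs.rk4_propagate(pulse, iso, 100_000, eval_times=anchors)
        ctx = HS1SolverContext.create(pulse, iso.omega)
        Cs = [
            complex(
                bs.hs1_particular(
                    bs.project(bs.Magnetization.from_array(M)), float(t), ctx
                ).C
            )
            for t, M in zip(traj.times, traj.M)
        ]
        Cs = np.array(Cs)
        assert np.max(np.abs(Cs - Cs.mean())) / abs(Cs.mean()) < 1e-6


class TestPropagation:
    def test_identity_at_anchor_time(self, pulse, tilted_iso):
        traj = bs.hs1_propagate(pulse, tilted_iso, [pulse.t_start])
        assert traj.M[0] == pytest.approx(tilted_iso.M.as_array(), abs=1e-13)

    def test_adiabatic_inversion_matches_rk4(self, pulse, equilibrium):
        ts = np.linspace(pulse.t_start, pulse.t_end, 101)
        exact = bs.hs1_propagate(pulse, equilibrium, ts)
        ref = bs.rk4_propagate(pulse, equilibrium, 10_000, eval_times=ts)
        cmp = bs.compare_trajectories(exact, ref)
        assert cmp.mean < 1e-5  # headline agreement bound
        assert exact.final.mz < -0.94  # adiabatic inversion

    def test_norm_conserved_identically(self, pulse):
        iso = bs.Isochromat(TWOPI * 200, bs.Magnetization(0.1, 0.2, 0.4))
        ts = np.linspace(pulse.t_start, pulse.t_end, 21)
        traj = bs.hs1_propagate(pulse, iso, ts)
        norms = np.linalg.norm(traj.M, axis=1)
        assert norms == pytest.approx(iso.M.norm, rel=1e-14)

    def test_midpulse_anchor_consistency(self, pulse, tilted_iso):
        """Anchoring at the start or at an RK4 midpoint state yields the
        same trajectory, within the RK4 error of the midpoint state."""
        ts = np.linspace(pulse.t_start, pulse.t_end, 21)
        start_anchored = bs.hs1_propagate(pulse, tilted_iso, ts)
        mid = pulse.tc
        mid_state = bs.rk4_propagate(
            pulse, tilted_iso, 100_000, eval_times=[mid]
        ).final
        mid_anchored = bs.hs1_propagate(
            pulse, bs.Isochromat(tilted_iso.omega, mid_state), ts, t_init=mid
        )
        cmp = bs.compare_trajectories(start_anchored, mid_anchored)
        assert cmp.max < 1e-9

    def test_oracle_equivalence_randomized(self):
        """Random pulses and isochromats agree with a 1e4-step RK4 run."""
        rng = np.random.default_rng(17)
        for iso in bs.random_isochromats(seed=23, count=3):
            p = bs.hs1_from_spec(
                omega1m=TWOPI * rng.uniform(100, 5000),
                Tp=rng.uniform(1e-3, 10e-3),
                R=rng.uniform(0.0, 50.0),
                truncation_fraction=rng.uniform(0.001, 0.5),
            )
            ts = np.linspace(p.t_start, p.t_end, 31)
            exact = bs.hs1_propagate(p, iso, ts)
            ref = bs.rk4_propagate(p, iso, 10_000, eval_times=ts)
            assert bs.compare_trajectories(exact, ref).mean < 1e-6


class TestSIT:
    def test_final_angle_formula(self, no_fm_pulse):
        theta = bs.sit_final_angle(no_fm_pulse)
        expected = (
            no_fm_pulse.omega1m * no_fm_pulse.Tp / no_fm_pulse.beta
        ) * math.atan(math.exp(no_fm_pulse.beta))
        assert theta == pytest.approx(expected, rel=1e-14)
        assert theta == pytest.approx(TWOPI, rel=1e-12)

    def test_requires_no_fm(self, pulse):
        with pytest.raises(ValueError):
            bs.sit_closed_form(pulse.tc, pulse)

    def test_closed_form_matches_general_solution_with_zero_constant(
        self, no_fm_pulse
    ):
        """With C = 0 the hypergeometric solution reduces exactly to
        f = i tan(2 a arcsin sqrt(p))."""
        ctx = HS1SolverContext.create(no_fm_pulse, 0.0)
        const = bs.ParticularConstant(mp.mpc(1), mp.mpc(0))  # C = 0
        a = complex(ctx.a).real
        for t in np.linspace(
            no_fm_pulse.t_start, no_fm_pulse.t_end, 9
        ):
            fpt = bs.hs1_evaluate(ctx, const, float(t))
            p = bs.hs1_p(float(t), no_fm_pulse)
            expected = 1j * math.tan(2 * a * math.asin(math.sqrt(p)))
            assert fpt.value == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_closed_form_tracks_full_solution(self):
        """The y-z plane closed form approaches the equilibrium-anchored
        solution as the truncation shrinks."""
        eq = bs.Isochromat(0.0, bs.Magnetization.equilibrium())
        maxdev = {}
        for trunc in (0.01, 0.001):
            beta = bs.beta_from_truncation(trunc)
            p = bs.HS1Pulse(
                omega1m=bs.sit_amplitude(beta, 5e-3), A=0.0, beta=beta, Tp=5e-3
            )
            ts = np.linspace(p.t_start, p.t_end, 51)
            full = bs.hs1_propagate(p, eq, ts)
            _, M_cf = bs.sit_closed_form(ts, p)
            devs = [
                bs.angular_error(
                    full.magnetization(i), bs.Magnetization.from_array(M_cf[i])
                )
                for i in range(len(ts))
            ]
            maxdev[trunc] = max(devs)
        assert maxdev[0.001] < 1e-2
        assert maxdev[0.001] < maxdev[0.01]
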