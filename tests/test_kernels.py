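import numpy as np
import pytest

from kppmap.kernels import (
    BoundarySpec,
    SingularSystemError,
    StepParams,
    TridiagonalSystem,
    assemble_neumann_step,
    bc_operator,
    diffusion_operator,
    diffusion_trapezoid_dirichlet,
    diffusion_trapezoid_neumann,
    euler_predictor,
    neumann_full_system,
    short_segment_step,
    solve_tridiagonal,
    trapezoid_step_dirichlet,
)
from kppmap.oracles import reference_1d

# hand evaluation of the semi-implicit logistic update for u=0.5, K=1, h=0.1:
# uE = 0.525, then (1 - 0.05*(1-0.525)) u'' = (1 + 0.05*(1-0.5)) * 0.5
N1_EXPECTED = 0.5125 / 0.97625  # = 0.52496798975...


class TestDiffusionOperator:
    def test_constant(self):
        np.testing.assert_array_equal(
            diffusion_operator(np.ones(3)), [-1.0, 0.0, -1.0]
        )

    def test_impulse(self):
        np.testing.assert_array_equal(
            diffusion_operator(np.array([0.0, 1.0, 0.0])), [1.0, -2.0, 1.0]
        )

    def test_linear_ramp(self):
        np.testing.assert_array_equal(
            diffusion_operator(np.array([1.0, 2.0, 3.0])), [0.0, 0.0, -4.0]
        )

    def test_length_one(self):
        np.testing.assert_array_equal(diffusion_operator(np.array([3.0])), [-6.0])

    def test_neumann_mirror_ghosts_kill_flux(self):
        u = np.ones(5)
        np.testing.assert_array_equal(bc_operator(u, "neumann"), np.zeros(5))


class TestTridiagonalSolve:
    def test_identity(self):
        rhs = np.array([2.0, -1.0, 5.0])
        sys_ = TridiagonalSystem(np.zeros(2), np.ones(3), np.zeros(2), rhs)
        np.testing.assert_allclose(solve_tridiagonal(sys_), rhs)

    def test_symmetric_2x2(self):
        sys_ = TridiagonalSystem(
            np.array([1.0]), np.array([2.0, 2.0]), np.array([1.0]),
            np.array([3.0, 3.0]),
        )
        np.testing.assert_allclose(solve_tridiagonal(sys_), [1.0, 1.0])

    def test_against_dense_oracle(self, rng):
        n = 6
        sub = rng.normal(size=n - 1)
        sup = rng.normal(size=n - 1)
        diag = 4.0 + rng.random(n)  # diagonally dominant
        rhs = rng.normal(size=n)
        sys_ = TridiagonalSystem(sub, diag, sup, rhs)
        expected = np.linalg.solve(sys_.dense(), rhs)
        assert np.max(np.abs(solve_tridiagonal(sys_) - expected)) < 1e-12

    def test_corner_terms_use_dense_path(self, rng):
        n = 5
        diag = 3.0 + rng.random(n)
        sys_ = TridiagonalSystem(
            np.full(n - 1, -1.0), diag, np.full(n - 1, -1.0),
            rng.normal(size=n), corner_terms=[(0, 2, 0.5)],
        )
        expected = np.linalg.solve(sys_.dense(), sys_.rhs)
        np.testing.assert_allclose(solve_tridiagonal(sys_), expected)

    def test_singular_raises(self):
        sys_ = TridiagonalSystem(
            np.array([0.0]), np.array([0.0, 0.0]), np.array([0.0]),
            np.array([1.0, 1.0]),
        )
        with pytest.raises(SingularSystemError):
            solve_tridiagonal(sys_)

    def test_small_pivot_falls_back(self):
        # Thomas without pivoting hits a zero pivot; dense fallback succeeds
        sys_ = TridiagonalSystem(
            np.array([1.0]), np.array([0.0, 1.0]), np.array([1.0]),
            np.array([1.0, 1.0]),
        )
        np.testing.assert_allclose(
            solve_tridiagonal(sys_), np.linalg.solve(sys_.dense(), sys_.rhs)
        )


class TestEulerPredictor:
    def test_zero_fixed_point(self, scaled_params, neumann):
        u = np.zeros(5)
        K = np.ones(5)
        np.testing.assert_array_equal(
            euler_predictor(u, K, scaled_params, neumann), u
        )

    def test_capacity_fixed_point_neumann(self, scaled_params, neumann):
        K = np.full(6, 0.8)
        out = euler_predictor(K.copy(), K, scaled_params, neumann)
        np.testing.assert_allclose(out, K)

    def test_single_cell_hand_value(self, neumann):
        p = StepParams(h=0.1, dx=1.0, c=0.0)
        out = euler_predictor(np.array([0.5]), np.array([1.0]), p, neumann)
        np.testing.assert_allclose(out, [0.525])

    def test_nonpositive_capacity_rejected(self, scaled_params, neumann):
        with pytest.raises(ValueError):
            euler_predictor(
                np.array([0.1, 0.1]), np.array([1.0, 0.0]), scaled_params, neumann
            )

    def test_clamped_to_next_capacity(self, neumann):
        p = StepParams(h=0.5, dx=1.0, c=0.0)
        out = euler_predictor(
            np.array([0.9]), np.array([1.0]), p, neumann,
            K_next=np.array([0.5]),
        )
        assert out[0] == 0.5


class TestTrapezoidDirichlet:
    def test_zero_fixed_point(self, scaled_params):
        u = np.zeros(8)
        K = np.ones(8)
        out = trapezoid_step_dirichlet(u, u, K, K, scaled_params)
        np.testing.assert_array_equal(out, u)

    def test_coastal_suppression(self, scaled_params, dirichlet):
        # padded zeros pull the end cells below K while the interior holds
        K = np.ones(30)
        u = K.copy()
        uE = euler_predictor(u, K, scaled_params, dirichlet)
        out = trapezoid_step_dirichlet(u, uE, K, K, scaled_params)
        assert out[0] < 1.0 - 1e-3 and out[-1] < 1.0 - 1e-3
        assert abs(out[15] - 1.0) < 1e-6

    def test_fig1_configuration_vs_oracle(self, scaled_params, dirichlet):
        # h = 1/12, dx = 1/5, u0 = indicator(|x| < 1), advanced to t = 2 and
        # compared against the independent method-of-lines reference seeded
        # with the same coarse initial data
        p = scaled_params
        dx = p.dx
        x = np.arange(-20, 20 + dx / 2, dx)
        u0 = (np.abs(x) < 1).astype(float)
        K = np.ones(x.size)
        u = u0.copy()
        for _ in range(int(round(2.0 / p.h))):
            uE = euler_predictor(u, K, p, dirichlet)
            u = trapezoid_step_dirichlet(u, uE, K, K, p)
        ref = reference_1d(u0, x, p, 1.0, 2.0, dirichlet)
        assert np.max(np.abs(u - ref)) < 0.02


class TestNeumannAssembly:
    def test_capacity_fixed_point(self, scaled_params):
        K = np.full(10, 0.7)
        u = K.copy()
        uE = euler_predictor(u, K, scaled_params, BoundarySpec("neumann"))
        out = assemble_neumann_step(u, uE, K, K, scaled_params)
        np.testing.assert_allclose(out, K, atol=1e-12)

    def test_zero_fixed_point(self, scaled_params):
        u = np.zeros(10)
        K = np.ones(10)
        out = assemble_neumann_step(u, u, K, K, scaled_params)
        np.testing.assert_array_equal(out, u)

    def test_heun_vs_dense_bandwidth5(self, neumann):
        # smooth n=8 profile: the Heun-corrected tridiagonal solution tracks
        # the brute-force solve of the full bandwidth-5 system closely
        x8 = np.linspace(0.0, 1.0, 8)
        u = 0.3 + 0.2 * np.sin(2 * np.pi * x8)
        K = np.ones(8)
        p = StepParams(h=0.05, dx=0.25)
        uE = euler_predictor(u, K, p, neumann)
        corrected = assemble_neumann_step(u, uE, K, K, p)
        full = neumann_full_system(u, uE, K, K, p)
        dense = np.clip(np.linalg.solve(full.dense(), full.rhs), 0.0, 1.0)
        assert np.max(np.abs(corrected - dense)) < 2e-3

    def test_end_refresh_changes_little(self, neumann):
        x8 = np.linspace(0.0, 1.0, 8)
        u = 0.3 + 0.2 * np.sin(2 * np.pi * x8)
        K = np.ones(8)
        p = StepParams(h=0.05, dx=0.25)
        uE = euler_predictor(u, K, p, neumann)
        a = assemble_neumann_step(u, uE, K, K, p)
        b = assemble_neumann_step(u, uE, K, K, p, refresh_ends=True)
        assert np.max(np.abs(a - b)) < 1e-3

    def test_short_segment_rejected(self, scaled_params):
        u = np.zeros(3)
        K = np.ones(3)
        with pytest.raises(ValueError):
            assemble_neumann_step(u, u, K, K, scaled_params)


class TestShortSegments:
    def test_n1_hand_value(self):
        p = StepParams(h=0.1, dx=1.0, c=0.0)
        out = short_segment_step(np.array([0.5]), np.array([1.0]), np.array([1.0]), p)
        np.testing.assert_allclose(out, [N1_EXPECTED], rtol=1e-12)

    def test_n2_outputs_equal(self, scaled_params, rng):
        u = rng.random(2) * 0.8
        K = np.ones(2)
        out = short_segment_step(u, K, K, scaled_params)
        assert out[0] == out[1]
        assert 0.0 <= out[0] <= 1.0

    def test_n3_matches_dense_bordered_solve(self, scaled_params):
        u = np.array([0.2, 0.5, 0.3])
        K = np.ones(3)
        p = scaled_params
        out = short_segment_step(u, K, K, p)
        assert out[0] == out[1] == out[2]
        # brute-force 3x3 solve of the bordered system
        uE = euler_predictor(u, K, p, BoundarySpec("neumann"))
        s1 = -0.5 * p.k
        s2 = 1.0 + p.k - 0.5 * p.growth * (1.0 - uE[1])
        rhs2 = (
            u[1]
            + 0.5 * p.k * (u[0] - 2 * u[1] + u[2])
            + 0.5 * p.growth * (1.0 - u[1]) * u[1]
        )
        mat = np.array(
            [[1.0, -4.0 / 3.0, 1.0 / 3.0], [s1, s2, s1], [1.0 / 3.0, -4.0 / 3.0, 1.0]]
        )
        sol = np.linalg.solve(mat, np.array([0.0, rhs2, 0.0]))
        np.testing.assert_allclose(out, sol, atol=1e-12)
        np.testing.assert_allclose(sol[0], sol[1], atol=1e-12)

    def test_capacity_fixed_points_n1_n3(self, scaled_params):
        for n in (1, 3):
            K = np.full(n, 0.6)
            out = short_segment_step(K.copy(), K, K, scaled_params)
            np.testing.assert_allclose(out, K, atol=1e-12)

    def test_n2_operator_drains_constants(self, scaled_params):
        # the prescribed 2x2 operator ((-2,1),(1,-2)) is not zero on
        # constants, so a 2-cell zero-flux segment bleeds mass by design;
        # the update must still stay equal, non-negative and below K
        K = np.full(2, 0.6)
        out = short_segment_step(K.copy(), K, K, scaled_params)
        assert out[0] == out[1]
        assert 0.0 <= out[0] < 0.6

    def test_long_segment_rejected(self, scaled_params):
        u = np.zeros(4)
        K = np.ones(4)
        with pytest.raises(ValueError):
            short_segment_step(u, K, K, scaled_params)


class TestStabilityAndAccuracy:
    def test_semi_implicit_stable_explicit_diverges_at_k1(self, scaled_params):
        # k ~ 1.04 with h = 1/12, dx = 0.2: the semi-implicit step stays in
        # [0, 1] for 240 steps while explicit Euler overflows
        p = scaled_params
        dx = p.dx
        x = np.arange(-24, 24 + dx / 2, dx)
        K = np.ones(x.size)
        bc = BoundarySpec("neumann")
        u = (np.abs(x) < 1).astype(float)
        for _ in range(240):
            uE = euler_predictor(u, K, p, bc)
            u = assemble_neumann_step(u, uE, K, K, p)
            assert np.all(u >= 0.0) and np.all(u <= 1.0)
        ue = (np.abs(x) < 1).astype(float)
        diverged = False
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(240):
                ue = ue + p.k * diffusion_operator(ue) + p.growth * (1 - ue) * ue
                if not np.all(np.isfinite(ue)) or np.max(np.abs(ue)) > 1e6:
                    diverged = True
                    break
        assert diverged

    def test_second_order_accuracy(self):
        # halving (h, dx) cuts the error vs the independent reference ~4x
        def err(h, dx):
            x = np.arange(-8.0, 8.0 + dx / 2, dx)
            u = 0.5 * np.exp(-(x**2) / 2)
            K = np.ones(x.size)
            p = StepParams(h=h, dx=dx)
            bc = BoundarySpec("dirichlet")
            for _ in range(int(round(1.0 / h))):
                uE = euler_predictor(u, K, p, bc)
                u = trapezoid_step_dirichlet(u, uE, K, K, p)
            ref = reference_1d(
                lambda xx: 0.5 * np.exp(-(xx**2) / 2), x, p, 1.0, 1.0, bc, refine=6
            )
            return np.max(np.abs(u - ref))

        ratio = err(0.1, 0.4) / err(0.05, 0.2)
        assert 3.0 < ratio < 5.0

    def test_monotone_bounds_random_data(self, scaled_params, rng):
        K = 0.5 + rng.random(12)
        u = K * rng.random(12)
        p = scaled_params
        uE = euler_predictor(u, K, p, BoundarySpec("neumann"))
        for out in (
            uE,
            assemble_neumann_step(u, uE, K, K, p),
            trapezoid_step_dirichlet(u, uE, K, K, p),
            diffusion_trapezoid_neumann(u, p.k / 4),
            diffusion_trapezoid_dirichlet(u, p.k / 4),
        ):
            assert np.all(out >= -1e-15) and np.all(out <= K.max() + 1e-12)


class TestDiffusionTrapezoids:
    def test_neumann_constant_invariant(self, scaled_params):
        u = np.full(9, 0.4)
        np.testing.assert_allclose(
            diffusion_trapezoid_neumann(u, scaled_params.k / 4), u, atol=1e-14
        )

    def test_neumann_short_segments(self, scaled_params):
        kw = scaled_params.k / 4
        np.testing.assert_array_equal(
            diffusion_trapezoid_neumann(np.array([0.3]), kw), [0.3]
        )
        out2 = diffusion_trapezoid_neumann(np.array([0.2, 0.6]), kw)
        np.testing.assert_allclose(out2, [0.4, 0.4])
        u3 = np.array([0.1, 0.5, 0.2])
        expect = 0.5 + kw * (0.1 - 1.0 + 0.2)
        np.testing.assert_allclose(
            diffusion_trapezoid_neumann(u3, kw), np.full(3, expect)
        )

    def test_dirichlet_decays_ends(self, scaled_params):
        u = np.full(10, 1.0)
        out = diffusion_trapezoid_dirichlet(u, scaled_params.k / 4)
        assert out[0] < 1.0 - 1e-3 and out[-1] < 1.0 - 1e-3
        assert out[0] < out[2] < out[5]  # suppression fades toward the middle
        assert out[5] > 0.99
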