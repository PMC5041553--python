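import numpy as np
import pytest

from esalign import (
    AugmentedRotation,
    FixtureSpec,
    ParamGrid,
    SrvfCurve,
    apply_rotation,
    compare_chains,
    geodesic_distance,
    kabsch_rotation,
    make_chain,
    matching_cost,
    normalize_srvf,
    optimal_matching,
    optimal_rotation,
    rigid_motion,
    srvf_inner_product,
    validate_chain,
)
from esalign.errors import ContractError
from esalign.synthetic_fixtures import random_rotation


def _unit_srvf(values, k=0):
    values = np.asarray(values, dtype=float)
    grid = ParamGrid(np.linspace(0.0, 1.0, values.shape[1]))
    return normalize_srvf(SrvfCurve(values=values, grid=grid, k=k))


def _random_srvf(rng, n=12, k=2, unit=True):
    values = rng.normal(size=(3 + k, n))
    curve = SrvfCurve(values, ParamGrid(np.linspace(0, 1, n)), k=k)
    return normalize_srvf(curve) if unit else curve


def brute_force_min_path_cost(Q1, Q2, window):
    """Exhaustive enumeration over all monotone paths (oracle for small n)."""
    n = len(Q1.grid)
    best = [np.inf]

    def rec(i, j, acc):
        if i == n - 1 and j == n - 1:
            best[0] = min(best[0], acc)
            return
        for di in range(1, min(window, n - 1 - i) + 1):
            for dj in range(1, min(window, n - 1 - j) + 1):
                rec(i + di, j + dj, acc + matching_cost(Q1, Q2, i, i + di, j, j + dj))

    rec(0, 0, 0.0)
    return best[0]


class TestOptimalRotation:
    def test_identity_for_identical_curves(self, rng):
        Q = _random_srvf(rng)
        R = optimal_rotation(Q, Q)
        np.testing.assert_allclose(R.spatial, np.eye(3), atol=1e-8)

    def test_recovers_known_rotation(self, rng):
        Q1 = _random_srvf(rng, n=15, k=2)
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # Rz(π/2)
        values = Q1.values.copy()
        values[:3] = Rz @ values[:3]
        Q2 = SrvfCurve(values, Q1.grid, k=Q1.k)
        R = optimal_rotation(Q1, Q2)
        np.testing.assert_allclose(R.spatial, Rz.T, atol=1e-8)
        rotated = apply_rotation(Q2, R)
        assert srvf_inner_product(Q1, rotated) == pytest.approx(
            srvf_inner_product(Q1, Q1), abs=1e-10
        )

    def test_mirror_image_gets_proper_rotation(self, rng):
        # planar curve and its reflection: Kabsch must not return a reflection
        values = rng.normal(size=(3, 20))
        values[2] = 0.0
        Q1 = _unit_srvf(values)
        mirrored = values.copy()
        mirrored[0] = -mirrored[0]
        Q2 = _unit_srvf(mirrored)
        R = optimal_rotation(Q1, Q2)
        assert np.linalg.det(R.spatial) == pytest.approx(1.0, abs=1e-10)
        achieved = srvf_inner_product(Q1, apply_rotation(Q2, R))
        # brute-force check: no random proper rotation does better
        best_random = -np.inf
        for _ in range(10_000):
            Rr = random_rotation(rng)
            cand = SrvfCurve(np.vstack([Rr @ Q2.values[:3]]), Q2.grid)
            best_random = max(best_random, srvf_inner_product(Q1, cand))
        assert achieved >= best_random - 1e-9

    def test_kabsch_always_proper_on_random_inputs(self, rng):
        for _ in range(200):
            A = rng.normal(size=(3, 3))
            if rng.random() < 0.5:
                A[2] = 0.0  # rank-deficient, reflection-prone
            R = kabsch_rotation(A)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-10)


class TestApplyRotation:
    def test_identity_rotation_is_noop(self, rng):
        Q = _random_srvf(rng)
        out = apply_rotation(Q, AugmentedRotation(np.eye(3), k=Q.k))
        np.testing.assert_array_equal(out.values, Q.values)

    def test_preserves_inner_product(self, rng):
        Q = _random_srvf(rng)
        R = AugmentedRotation(random_rotation(rng), k=Q.k)
        rotated = apply_rotation(Q, R)
        assert srvf_inner_product(rotated, rotated) == pytest.approx(
            srvf_inner_product(Q, Q), abs=1e-12
        )

    def test_double_application_equals_squared_rotation(self, rng):
        Q = _random_srvf(rng)
        R = random_rotation(rng)
        twice = apply_rotation(apply_rotation(Q, AugmentedRotation(R, k=Q.k)),
                               AugmentedRotation(R, k=Q.k))
        once = apply_rotation(Q, AugmentedRotation(R @ R, k=Q.k))
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        Q = _random_srvf(rng, k=2)
        with pytest.raises(ContractError):
            apply_rotation(Q, AugmentedRotation(np.eye(3), k=0))


class TestMatchingCost:
    def test_identical_aligned_segments_cost_zero(self, rng):
        Q = _random_srvf(rng, n=8)
        assert matching_cost(Q, Q, 0, 3, 0, 3) == pytest.approx(0.0, abs=1e-15)

    def test_cost_nonnegative(self, rng):
        for _ in range(20):
            Q1, Q2 = _random_srvf(rng, n=6), _random_srvf(rng, n=6)
            assert matching_cost(Q1, Q2, 0, 5, 0, 5) >= 0.0

    def test_hand_quadrature_two_columns(self):
        # segment [0, 1] of both curves, identity warp: trapezoid of ‖q1-q2‖²
        grid = ParamGrid([0.0, 1.0])
        Q1 = SrvfCurve(np.array([[1.0, 2.0], [0, 0], [0, 0]]), grid)
        Q2 = SrvfCurve(np.array([[0.0, 1.0], [1.0, 0.0], [0, 0]]), grid)
        # integrand at t=0: (1-0)²+(0-1)² = 2 ; at t=1: (2-1)²+0 = 1
        assert matching_cost(Q1, Q2, 0, 1, 0, 1) == pytest.approx(1.5, abs=1e-12)

    def test_warp_factor_in_cost(self):
        # map [0, 0.5] of curve 1 onto [0, 1] of curve 2: γ̇ = 2
        grid = ParamGrid([0.0, 0.5, 1.0])
        Q1 = SrvfCurve(np.array([[1.0, 1.0, 1.0], [0, 0, 0], [0, 0, 0]]), grid)
        Q2 = SrvfCurve(np.array([[1.0, 1.0, 1.0], [0, 0, 0], [0, 0, 0]]), grid)
        # integrand constant: (1 − √2)², over an interval of length 0.5
        expected = 0.5 * (1 - np.sqrt(2.0)) ** 2
        assert matching_cost(Q1, Q2, 0, 1, 0, 2) == pytest.approx(expected, abs=1e-12)

    def test_non_monotone_segment_raises(self, rng):
        Q = _random_srvf(rng, n=6)
        with pytest.raises(ContractError):
            matching_cost(Q, Q, 3, 3, 0, 1)


class TestOptimalMatching:
    def test_identity_for_identical_curves(self, rng):
        Q = _random_srvf(rng, n=20)
        match = optimal_matching(Q, Q)
        assert match.matched_cost == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(match.gamma_values, match.change_points, atol=1e-12)
        np.testing.assert_allclose(match.warped.values, Q.values, atol=1e-10)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_equals_brute_force_enumeration(self, n, rng):
        for _ in range(10):
            Q1 = _random_srvf(rng, n=n, k=1)
            Q2 = _random_srvf(rng, n=n, k=1)
            dp = optimal_matching(Q1, Q2, window=3).matched_cost
            oracle = brute_force_min_path_cost(Q1, Q2, window=3)
            assert dp == oracle

    def test_beats_identity_warp_on_warped_copy(self, rng):
        # a warped copy of a curve should match better than the identity warp
        n = 30
        t = np.linspace(0, 1, n)
        base = np.vstack([np.cos(2 * t), np.sin(3 * t), t**2])
        gamma = t + 0.15 * np.sin(np.pi * t)  # smooth warp fixing endpoints
        warped = np.vstack([np.interp(gamma, t, row) for row in base])
        Q1 = _unit_srvf(base)
        Q2 = _unit_srvf(warped)
        match = optimal_matching(Q1, Q2, window=5)
        identity_cost = sum(
            matching_cost(Q1, Q2, i, i + 1, i, i + 1) for i in range(n - 1)
        )
        assert match.matched_cost <= identity_cost + 1e-12
        # the recovered warp tracks the inverse of the applied one (monotone)
        assert np.all(np.diff(match.gamma_values) >= 0)

    def test_gamma_endpoints_fixed(self, rng):
        Q1, Q2 = _random_srvf(rng, n=15), _random_srvf(rng, n=15)
        match = optimal_matching(Q1, Q2)
        assert match.gamma_values[0] == 0.0 and match.gamma_values[-1] == 1.0
        assert match.change_points[0] == 0.0 and match.change_points[-1] == 1.0


class TestGeodesicDistance:
    def test_identical_unit_srvfs(self, rng):
        Q = _random_srvf(rng)
        result = geodesic_distance(Q, Q)
        assert result.theta == pytest.approx(0.0, abs=1e-12)
        assert result.cosine == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_unit_srvfs(self):
        Q1 = _unit_srvf(np.array([[1.0, 1.0], [0, 0], [0, 0]]))
        Q2 = _unit_srvf(np.array([[0, 0], [1.0, 1.0], [0, 0]]))
        assert geodesic_distance(Q1, Q2).theta == pytest.approx(np.pi / 2, abs=1e-12)

    def test_matches_quadrature_oracle(self, rng):
        Q1, Q2 = _random_srvf(rng, n=9), _random_srvf(rng, n=9)
        t = Q1.grid.values
        integrand = np.einsum("ri,ri->i", Q1.values, Q2.values)
        oracle = np.arccos(np.clip(np.trapezoid(integrand, t), -1, 1))
        assert geodesic_distance(Q1, Q2).theta == pytest.approx(oracle, abs=1e-12)


class TestCompareChains:
    def test_self_distance_zero(self, helix_chain):
        assert compare_chains(helix_chain, helix_chain).theta < 1e-6

    def test_rigid_motion_invariance(self, helix_chain, rng):
        moved = validate_chain(
            rigid_motion(helix_chain, random_rotation(rng), rng.normal(size=3) * 40)
        )
        assert compare_chains(helix_chain, moved).theta < 1e-5

    def test_shape_change_dominates_noise(self, helix_chain, strand_chain):
        noisy = validate_chain(
            make_chain(FixtureSpec(n_residues=50, family="helix", seed=1, noise_sigma=0.1))
        )
        theta_strand = compare_chains(helix_chain, strand_chain).theta
        theta_noisy = compare_chains(helix_chain, noisy).theta
        assert theta_strand > theta_noisy

    def test_rough_symmetry_on_similar_pairs(self, helix_chain):
        # the DP matching is directional, so θ(A,B) ≠ θ(B,A) exactly; for
        # structurally close pairs the discrepancy stays small (for very
        # dissimilar shapes it can reach ~0.1 rad — see the methods note)
        noisy = validate_chain(
            make_chain(FixtureSpec(n_residues=50, family="helix", seed=1, noise_sigma=0.1))
        )
        ab = compare_chains(helix_chain, noisy).theta
        ba = compare_chains(noisy, helix_chain).theta
        assert abs(ab - ba) < 0.02

    def test_theta_in_range_and_provenance(self, helix_chain, strand_chain):
        result = compare_chains(helix_chain, strand_chain, feature_set=("HP",))
        assert 0.0 <= result.theta <= np.pi
        assert result.provenance["criterion"] == "ESA-CA"
        assert result.provenance["feature_set"] == ["HP"]
        assert result.rotation is not None and result.matching is not None
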