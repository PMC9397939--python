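"""Fixed points, Jacobians, phase classification and recruitment ranks."""

import numpy as np
import pytest

from epispread.model_core import EpileptorParams, drift_full, drift_reduced
from epispread.stability import (
    StabilityReport,
    classify_phase,
    critical_excitability_single,
    ez_mean_drive,
    find_fixed_points_single,
    find_network_fixed_point,
    network_jacobian,
    phase_from_eigenvalues,
    recruitment_ranks,
    single_node_stable_fixed_point,
)


class TestSingleNodeFixedPoints:
    def test_three_fixed_points_one_stable(self, params):
        fps = find_fixed_points_single(params, -2.2)
        assert len(fps) == 3
        assert sum(c == "stable" for _, c in fps) == 1

    def test_roots_have_tiny_residual(self, params):
        from epispread.model_core import single_node_drift

        for root, _ in find_fixed_points_single(params, -2.2):
            assert np.abs(single_node_drift(root, params, -2.2)).max() < 1e-9

    def test_reduced_roots_match_cubic_oracle(self, params):
        # x solves -x^3 - 2x^2 + 1 + I1 - 4(x - x0) = 0 with z = 4(x - x0)
        x0 = -2.2
        roots = np.roots([-1.0, -2.0, -4.0, 1.0 + params.I1 + 4.0 * x0])
        real = sorted(r.real for r in roots if abs(r.imag) < 1e-9)
        fps = find_fixed_points_single(params, x0, "reduced")
        found_x = sorted(r[0] for r, _ in fps)
        for fx in found_x:
            assert min(abs(fx - rx) for rx in real) < 1e-8
        for r, _ in fps:
            assert r[1] == pytest.approx(4.0 * (r[0] - x0), abs=1e-8)

    def test_no_stable_fixed_point_in_epileptic_regime(self, params):
        fps = find_fixed_points_single(params, -1.6)
        assert all(c == "unstable" for _, c in fps)


class TestCriticalExcitability:
    def test_full_model_value(self, params):
        xc = critical_excitability_single(params)
        assert abs(xc - (-2.061)) < 5e-3

    def test_reduced_model_closed_form(self, params):
        # trace of the 2x2 Jacobian vanishes at x* solving 3x^2+4x+1/tau0=0;
        # back-substitution into the cubic gives the critical x0
        x_star = (-4.0 - np.sqrt(16.0 - 12.0 / params.tau0)) / 6.0
        x0c_closed = (x_star**3 + 2 * x_star**2 + 4 * x_star - 1.0 - params.I1) / 4.0
        xc = critical_excitability_single(params, "reduced")
        assert abs(xc - x0c_closed) < 2e-4

    def test_epileptogenic_classification(self, params):
        xc = critical_excitability_single(params)
        assert -1.6 > xc   # EZ excitability exceeds the critical value
        assert -2.3 < xc   # surround range stays below it ...
        assert -2.09 < xc  # ... at both ends (non-epileptic)

    def test_bad_bracket_rejected(self, params):
        with pytest.raises(ValueError, match="bracket"):
            critical_excitability_single(params, bracket=(-2.3, -2.2))


class TestEzMeanDrive:
    def test_within_seizure_x1_bounds_and_deterministic(self, params):
        from epispread.simulator import reference_isolated_seizure

        v1 = ez_mean_drive(params)
        v2 = ez_mean_drive(params)
        assert v1 == v2
        ref = reference_isolated_seizure(params)
        # a mean lies within the extremes of the averaged signal; seizure
        # x1 oscillates roughly between -1.5 and 1.5
        assert -1.6 < v1 < 1.6
        assert ref.onset_step < ref.offset_step

    def test_dt_refinement_robustness(self, params):
        from epispread.simulator import reference_isolated_seizure

        coarse = reference_isolated_seizure(params, dt=0.05).x1_mean
        fine = reference_isolated_seizure(params, dt=0.025, max_steps=1_200_000).x1_mean
        assert abs(fine - coarse) / abs(coarse) < 0.01


class TestNetworkFixedPoint:
    def test_w_zero_equals_tiled_single_node(self, net10):
        p = EpileptorParams(w=0.0)
        fp = find_network_fixed_point(net10, p, -2.2, 0, "with_ez")
        single_surround = single_node_stable_fixed_point(p, -2.2)
        for i in range(1, 10):
            np.testing.assert_allclose(fp[i], single_surround, atol=1e-8)

    def test_homogeneous_network_keeps_tiling(self, net10, params):
        # without an EZ, diffusive coupling vanishes on the homogeneous
        # tiling, which must remain the fixed point at any w
        p = params.with_(w=2.0)
        fp_single = single_node_stable_fixed_point(p, -2.2)
        state = np.tile(fp_single, (10, 1))
        x0 = np.full(10, -2.2)
        d = drift_full(state, p, net10.weights, x0)
        assert np.abs(d).max() < 1e-9

    def test_residuals_below_tolerance(self, net10):
        p = EpileptorParams(w=1.0)
        fp = find_network_fixed_point(net10, p, -2.2, 0, "with_ez")
        x0 = np.full(10, -2.2)
        x0[0] = -1.6
        assert np.abs(drift_full(fp, p, net10.weights, x0)).max() < 1e-9

    def test_ez_removed_with_resting_drive_matches_no_input(self, net10):
        # freezing the EZ at the surround resting x1 exerts zero effective
        # drive: the surround fixed point is the plain homogeneous one
        p = EpileptorParams(w=1.0)
        rest = single_node_stable_fixed_point(p, -2.2)
        fp = find_network_fixed_point(
            net10, p, -2.2, 0, "ez_removed", x1_ez_mean=float(rest[0])
        )
        for i in range(9):
            np.testing.assert_allclose(fp[i], rest, atol=1e-7)


class TestJacobian:
    def _fd_jacobian(self, fun, x, eps=1e-6):
        m = len(x)
        jac = np.zeros((m, m))
        for k in range(m):
            d = np.zeros(m)
            d[k] = eps
            jac[:, k] = (fun(x + d) - fun(x - d)) / (2 * eps)
        return jac

    def _permutation(self, n, nv):
        perm = np.zeros((n * nv, n * nv))
        for i in range(n):
            for v in range(nv):
                perm[v * n + i, i * nv + v] = 1.0
        return perm

    @pytest.mark.parametrize("model,nv", [("full", 6), ("reduced", 2)])
    @pytest.mark.parametrize("variant", ["with_ez", "ez_removed"])
    def test_analytic_matches_finite_difference(self, net3, params, model, nv, variant):
        p = params.with_(w=1.3)
        x1_bar = ez_mean_drive(p)
        fp = find_network_fixed_point(
            net3, p, -2.25, 0, variant, model, x1_ez_mean=x1_bar
        )
        jac = network_jacobian(net3, p, fp, 0, variant, model)
        m = fp.shape[0]
        if variant == "with_ez":
            x0 = np.full(3, -2.25)
            x0[0] = -1.6
            fn = drift_full if model == "full" else drift_reduced

            def fun(flat):
                return fn(flat.reshape(m, nv), p, net3.weights, x0).ravel()
        else:
            from epispread.stability import _make_ez_removed_drift

            fun, *_ = _make_ez_removed_drift(
                net3.weights, 0, p, -2.25, x1_bar, model
            )
        fd = self._fd_jacobian(fun, fp.ravel())
        perm = self._permutation(m, nv)
        np.testing.assert_allclose(perm @ fd @ perm.T, jac, atol=1e-6)

    def test_g_block_is_minus_gamma_identity(self, net3, params):
        p = params.with_(w=0.5)
        fp = find_network_fixed_point(net3, p, -2.2, 0, "with_ez")
        jac = network_jacobian(net3, p, fp, 0, "with_ez")
        n = 3
        np.testing.assert_array_equal(
            jac[5 * n:, 5 * n:], -params.gamma * np.eye(n)
        )

    def test_w_zero_block_diagonal_across_nodes(self, net3, params):
        p = params.with_(w=0.0)
        fp = find_network_fixed_point(net3, p, -2.2, 0, "with_ez")
        jac = network_jacobian(net3, p, fp, 0, "with_ez")
        n = 3
        for a in range(6):
            for b in range(6):
                block = jac[a * n:(a + 1) * n, b * n:(b + 1) * n]
                off = block - np.diag(np.diag(block))
                assert np.abs(off).max() == 0.0

    def test_leading_eigenvalue_invariant_under_relabeling(self, net10):
        p = EpileptorParams(w=1.0)
        rep = classify_phase(net10, p, -2.2, 0)
        perm = np.r_[0, np.roll(np.arange(1, 10), 3)]
        from epispread.connectome import Connectome

        shuffled = Connectome(
            net10.weights[np.ix_(perm, perm)],
            net10.tract_lengths[np.ix_(perm, perm)],
            ez_nodes=(0,),
        )
        rep2 = classify_phase(shuffled, p, -2.2, 0)
        assert abs(rep.lambda_R - rep2.lambda_R) < 1e-10
        assert abs(rep.lambda_tilde_R - rep2.lambda_tilde_R) < 1e-10


class TestPhaseRule:
    @pytest.mark.parametrize(
        "lam,lam_t,expected",
        [
            (-0.001, 0.5, "no_seizure"),
            (-0.001, -0.5, "no_seizure"),
            (0.002, -0.001, "no_spread"),
            (0.002, 0.003, "spread"),
        ],
    )
    def test_joint_sign_logic(self, lam, lam_t, expected):
        assert phase_from_eigenvalues(lam, lam_t) == expected

    def test_classification_eigen_scale(self, net10):
        # near the no-seizure boundary the eigenvalues live on the slow
        # 1/tau0 scale, hence the tight numerical zero threshold
        rep = classify_phase(net10, EpileptorParams(w=12.0), -2.3, 0)
        assert rep.predicted_phase == "no_seizure"
        assert abs(rep.lambda_R) < 0.01


class TestRecruitmentRanks:
    def _report(self, v_z, phase="spread"):
        m = len(v_z)
        return StabilityReport(
            fixed_point=np.zeros((m + 1, 6)),
            lambda_R=0.1,
            lambda_tilde_R=0.1,
            x1_ez_mean=0.2,
            v_z=np.asarray(v_z, dtype=float),
            surround_nodes=np.arange(1, m + 1),
            predicted_phase=phase,
            active_ez=0,
            x0_surround=-2.2,
            w=1.0,
            model="full",
        )

    def test_largest_component_ranks_first(self):
        df = recruitment_ranks(self._report([0.5, 0.1, 0.3]))
        assert df["rank"].tolist() == [1, 3, 2]

    def test_exact_tie_broken_by_node_index(self):
        df = recruitment_ranks(self._report([0.2, 0.2]))
        assert df["rank"].tolist() == [1, 2]

    def test_requires_spread_phase(self):
        with pytest.raises(RuntimeError, match="spread"):
            recruitment_ranks(self._report([0.5, 0.1], phase="no_spread"))

    def test_chain_ranks_neighbor_of_ez_first(self, chain4, params):
        rep = classify_phase(chain4, params.with_(w=2.0), -2.09, 0)
        assert rep.predicted_phase == "spread"
        df = recruitment_ranks(rep)
        assert df.loc[1, "rank"] == 1  # direct neighbour of the EZ end

    def test_log_vz_tracks_log_ez_weight_on_hub(self, star8, params):
        import scipy.stats

        rep = classify_phase(star8, params.with_(w=2.5), -2.09, 0)
        assert rep.predicted_phase == "spread"
        w_ez = star8.weights[rep.surround_nodes, 0]
        rho = scipy.stats.spearmanr(np.log(rep.v_z), np.log(w_ez)).statistic
        assert rho > 0.8


class TestReducedVsFull:
    def test_phase_agreement_on_coarse_grid(self, net10, params):
        # both model variants should agree on the qualitative phase
        # structure over most of the (x0, w) plane
        x0s = np.linspace(-2.3, -2.09, 4)
        ws = np.geomspace(0.3, 15.0, 5)
        agree = total = 0
        for x0 in x0s:
            for w in ws:
                p = params.with_(w=float(w))
                full = classify_phase(net10, p, float(x0), 0, model="full")
                red = classify_phase(net10, p, float(x0), 0, model="reduced")
                agree += full.predicted_phase == red.predicted_phase
                total += 1
        assert agree / total >= 0.8
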