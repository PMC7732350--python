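import numpy as np
import pytest

from leakfree.exceptions import ConfigurationError, PSDViolationError
from leakfree.leakage import (
    build_estimator,
    decompose_expectation,
    estimate_interactions,
    extended_source_ratio,
    leakage_basis,
    set_rank,
    two_point_source_norms,
)
from leakfree.operators import minimum_norm_inverse, unvec, vec
from leakfree.spectra import InteractionSpec, sample_activity, sample_spectral_matrix, two_source_spectrum


class TestLeakageBasis:
    def test_sensor_space_basis_has_full_dimension(self, benchmark):
        proj = leakage_basis(benchmark, 1e-2, 3)
        assert proj.d == 21
        assert proj.B.shape == (benchmark.n ** 2, benchmark.p)

    def test_sensor_basis_columns_are_squared_forward_columns(self, benchmark):
        proj = leakage_basis(benchmark, 1e-2, 3)
        for i in (0, 7, 20):
            li = benchmark.L[:, i]
            assert np.max(np.abs(proj.B[:, i] - np.kron(li, li))) < 1e-14

    def test_source_basis_columns_are_squared_point_spreads(self, benchmark):
        # lambda = 0: point spreads come from the pseudoinverse resolution
        proj = leakage_basis(benchmark, 0.0, 1)
        R = minimum_norm_inverse(benchmark, 0.0).R
        for i in (0, 10, 20):
            ri = R[:, i]
            assert np.max(np.abs(proj.B[:, i] - np.kron(ri, ri))) < 1e-10


class TestRankKProjection:
    @pytest.mark.parametrize("family", [1, 2, 3])
    @pytest.mark.parametrize("k", [0, 1, 5, "max"])
    def test_symmetric_idempotent(self, benchmark, family, k):
        proj = set_rank(leakage_basis(benchmark, 1e-2, family), k)
        pi = proj.pi_k
        assert np.max(np.abs(pi - pi.T)) < 1e-12
        assert np.max(np.abs(pi @ pi - pi)) < 1e-10

    @pytest.mark.parametrize("family", [1, 2, 3])
    def test_rank_zero_is_identity(self, benchmark, family):
        proj = set_rank(leakage_basis(benchmark, 1e-2, family), 0)
        assert np.array_equal(proj.pi_k, np.eye(proj.B.shape[0]))

    @pytest.mark.parametrize("family", [1, 2, 3])
    def test_full_rank_nullifies_leakage_subspace(self, benchmark, family):
        proj = set_rank(leakage_basis(benchmark, 1e-2, family), "max")
        assert np.linalg.norm(proj.pi_k @ proj.B) < 1e-8 * np.linalg.norm(proj.B)

    def test_out_of_range_rank_rejected(self, benchmark):
        proj = leakage_basis(benchmark, 1e-2, 3)
        for bad in (-1, proj.d + 1):
            with pytest.raises(ConfigurationError):
                set_rank(proj, bad)

    @pytest.mark.parametrize("family", [1, 2, 3])
    def test_imaginary_part_invariant(self, benchmark, family, rng):
        # anti-symmetric (lagged) components are orthogonal to the leakage basis
        dim_src = benchmark.p if family != 3 else benchmark.n
        A = rng.standard_normal((dim_src, dim_src))
        v = vec(1j * (A - A.T))
        for k in (1, 5, "max"):
            proj = set_rank(leakage_basis(benchmark, 1e-2, family), k)
            assert np.max(np.abs(proj.pi_k @ v - v)) < 1e-9 * np.abs(v).max()


class TestCorrectedEstimators:
    def test_uncorrected_source_estimate_matches_direct_sandwich(self, benchmark, rng):
        sm = two_source_spectrum(
            benchmark, InteractionSpec.two_source(benchmark, 0.3, 45.0), sigma=0.01
        )
        samples = sample_activity(sm, benchmark, 100, seed=rng)
        S_y = sample_spectral_matrix(samples.Y)
        spec = build_estimator(benchmark, "E1", 1e-2, 0)
        est, defect = estimate_interactions(S_y, spec, benchmark, return_defect=True)
        Ls = minimum_norm_inverse(benchmark, 1e-2).L_sharp
        assert np.max(np.abs(est - Ls @ S_y @ Ls.T)) < 1e-10
        assert defect < 1e-10
        assert np.max(np.abs(est - est.conj().T)) == 0.0

    def test_sensor_space_correction_at_rank_zero_reduces_to_sensor_estimator(
        self, benchmark, rng
    ):
        sm = two_source_spectrum(
            benchmark, InteractionSpec.two_source(benchmark, 0.3, 20.0), sigma=0.05
        )
        S_y = sample_spectral_matrix(sample_activity(sm, benchmark, 80, seed=rng).Y)
        e2 = build_estimator(benchmark, "E2", 1e-2, 0)
        e3 = build_estimator(benchmark, "E3", 1e-2, 0)
        a = estimate_interactions(S_y, e2, benchmark)
        b = estimate_interactions(S_y, e3, benchmark)
        assert np.max(np.abs(a - b)) < 1e-8 * np.abs(a).max()

    @pytest.mark.parametrize("family", ["E1", "E2"])
    def test_full_correction_annihilates_pure_leakage(self, benchmark, family):
        # independent sources, no noise: the whole expectation is leakage
        sm = two_source_spectrum(
            benchmark, InteractionSpec.two_source(benchmark, 0.0, 0.0), sigma=0.0
        )
        spec = build_estimator(benchmark, family, 1e-2, "max")
        expect = decompose_expectation(sm, spec, benchmark).total
        off = expect - np.diag(np.diag(expect))
        assert np.max(np.abs(off)) < 1e-8 * np.abs(sm.S_x).max()

    def test_dimension_mismatch_rejected(self, benchmark):
        spec = build_estimator(benchmark, "E1", 1e-2, 0)
        with pytest.raises(ConfigurationError):
            estimate_interactions(np.eye(5), spec, benchmark)


class TestExpectationDecomposition:
    def _spec(self, benchmark, family="E1", k=0):
        return build_estimator(benchmark, family, 1e-2, k)

    def test_diagonal_source_matrix_has_no_interaction_term(self, benchmark):
        sm = two_source_spectrum(
            benchmark, InteractionSpec.two_source(benchmark, 0.0, 0.0), sigma=0.1
        )
        d = decompose_expectation(sm, self._spec(benchmark), benchmark)
        assert np.max(np.abs(d.interaction)) == 0.0
        assert np.max(np.abs(d.noise)) > 0.0

    def test_noiseless_model_has_no_noise_term(self, benchmark):
        sm = two_source_spectrum(
            benchmark, InteractionSpec.two_source(benchmark, 0.5, 30.0), sigma=0.0
        )
        d = decompose_expectation(sm, self._spec(benchmark), benchmark)
        assert np.max(np.abs(d.noise)) == 0.0

    def test_total_equals_operator_application(self, benchmark):
        sm = two_source_spectrum(
            benchmark, InteractionSpec.two_source(benchmark, 0.4, 60.0), sigma=0.05
        )
        spec = self._spec(benchmark, "E2", 5)
        d = decompose_expectation(sm, spec, benchmark)
        direct = unvec(
            spec.R @ vec(sm.S_x) + spec.F @ vec(sm.S_e), benchmark.p
        )
        assert np.max(np.abs(d.total - direct)) < 1e-10

    def test_leakage_term_is_sum_of_squared_point_spreads(self, benchmark, true_pair):
        sm = two_source_spectrum(
            benchmark, InteractionSpec.two_source(benchmark, 0.3, 45.0), sigma=0.0
        )
        spec = self._spec(benchmark)
        d = decompose_expectation(sm, spec, benchmark)
        R = minimum_norm_inverse(benchmark, 1e-2).R
        k, l = true_pair
        explicit = np.outer(R[:, k], R[:, k]) + np.outer(R[:, l], R[:, l])
        assert np.max(np.abs(d.leakage - explicit)) < 1e-10

    @pytest.mark.parametrize("family", ["E1", "E2"])
    def test_leakage_suppression_monotone_in_rank(self, benchmark, family):
        sm = two_source_spectrum(
            benchmark, InteractionSpec.two_source(benchmark, 0.3, 0.0), sigma=0.0
        )
        norms = []
        d_max = leakage_basis(benchmark, 1e-2, {"E1": 1, "E2": 2}[family]).d
        for k in range(0, d_max + 1, 4):
            spec = build_estimator(benchmark, family, 1e-2, k)
            norms.append(np.linalg.norm(
                decompose_expectation(sm, spec, benchmark).leakage
            ))
        assert np.all(np.diff(norms) <= 1e-12)
        spec = build_estimator(benchmark, family, 1e-2, "max")
        final = np.linalg.norm(decompose_expectation(sm, spec, benchmark).leakage)
        assert final < 1e-8 * norms[0]

    def test_interaction_scaling_leaves_leakage_unchanged(self, benchmark):
        # scaling the off-diagonal part by mu scales only the interaction term
        spec = self._spec(benchmark, "E1", 5)
        base = two_source_spectrum(
            benchmark, InteractionSpec.two_source(benchmark, 0.2, 40.0), sigma=0.0
        )
        scaled = two_source_spectrum(
            benchmark,
            InteractionSpec.two_source(benchmark, 0.6, 40.0),  # mu = 3
            sigma=0.0,
        )
        d0 = decompose_expectation(base, spec, benchmark)
        d1 = decompose_expectation(scaled, spec, benchmark)
        assert np.max(np.abs(d1.leakage - d0.leakage)) < 1e-12
        assert np.max(np.abs(d1.interaction - 3.0 * d0.interaction)) < 1e-12


class TestTwoPointGeometry:
    def test_zero_coherence_gives_zero_interaction_norm(self, benchmark):
        _, inter = two_point_source_norms(benchmark, 1e-2, 5, 15, gamma=0.0)
        assert inter == 0.0

    def test_closed_forms_match_direct_norms_and_inequality(self, benchmark, rng):
        R = minimum_norm_inverse(benchmark, 1e-2).R
        for _ in range(100):
            k, l = rng.choice(benchmark.p, size=2, replace=False)
            sk2, sl2 = rng.uniform(0.2, 2.0, size=2)
            gamma = rng.uniform(0.0, 1.0) * np.sqrt(sk2 * sl2)
            leak, inter = two_point_source_norms(
                benchmark, 1e-2, k, l, powers=(sk2, sl2), gamma=gamma
            )
            rk, rl = R[:, k], R[:, l]
            leak_direct = np.linalg.norm(sk2 * np.kron(rk, rk) + sl2 * np.kron(rl, rl))
            inter_direct = np.linalg.norm(gamma * (np.kron(rk, rl) + np.kron(rl, rk)))
            assert leak == pytest.approx(leak_direct, abs=1e-10 * max(1, leak_direct))
            assert inter == pytest.approx(inter_direct, abs=1e-10 * max(1, inter_direct))
            assert leak >= inter - 1e-12

    def test_supercritical_coherence_rejected(self, benchmark):
        with pytest.raises(PSDViolationError):
            two_point_source_norms(benchmark, 1e-2, 5, 15, powers=(1, 1), gamma=1.5)


class TestExtendedSource:
    def test_reference_value_and_scaling(self):
        assert extended_source_ratio(1.0, 1.0, 2) == pytest.approx(1.0)
        assert extended_source_ratio(1.0, 0.5, 3) == pytest.approx(
            2 * extended_source_ratio(1.0, 0.5, 5)
        )

    def test_homogeneous_patch_construction_approaches_formula(self):
        # m identical point spreads: leakage = m s^2 ||r x r||,
        # interaction = gamma m (m-1) ||r x r||; near-unit coherence makes the
        # printed approximation accurate
        m, sigma2, gamma = 9, 1.0, 0.9
        r = np.ones(7)  # shared point spread
        rr = np.kron(r, r)
        leak = np.linalg.norm(m * sigma2 * rr)
        inter = np.linalg.norm(gamma * m * (m - 1) * rr)
        exact = leak / inter
        approx = extended_source_ratio(sigma2, gamma, m)
        assert abs(exact - approx) / exact < 0.2

    def test_domain_errors(self):
        with pytest.raises(ConfigurationError):
            extended_source_ratio(1.0, 0.5, 1)
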