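import itertools

import numpy as np
import pytest

from soilpte import pmf, synthetic
from soilpte.core import ELEMENTS
from soilpte.pmf import (PMFError, bootstrap_diagnostic, build_uncertainty_matrix,
                         disp_diagnostic, element_contribution_percent,
                         factor_total_share, fit_pmf, match_factors,
                         normalize_contributions, q_value, select_factor_count)


class TestUncertaintyMatrix:
    def test_above_mdl_epa_formula(self):
        X = np.full((1, 9), 10.0)
        U = build_uncertainty_matrix(X, 0.1, {el: 1.0 for el in ELEMENTS})
        # sqrt((0.1*10)^2 + (0.5*1)^2) = sqrt(1.25)
        assert U.U[0, 0] == pytest.approx(1.1180, abs=1e-4)

    def test_below_mdl_five_sixths_rule(self):
        X = np.full((1, 9), 0.5)
        U = build_uncertainty_matrix(X, 0.1, {el: 1.2 for el in ELEMENTS})
        assert U.U[0, 0] == pytest.approx(1.0)

    def test_zero_mdl_reduces_to_error_fraction(self):
        X = np.full((1, 9), 10.0)
        U = build_uncertainty_matrix(X, 0.1, {el: 0.0 for el in ELEMENTS})
        assert U.U[0, 0] == pytest.approx(1.0)

    def test_zero_below_zero_mdl_is_an_error(self):
        X = np.zeros((1, 9))
        with pytest.raises(PMFError, match="MDL"):
            build_uncertainty_matrix(X, 0.1, {el: 0.0 for el in ELEMENTS})

    def test_weak_element_uncertainty_tripled(self):
        X = np.full((2, 9), 10.0)
        mdl = {el: 1.0 for el in ELEMENTS}
        strong = build_uncertainty_matrix(X, 0.1, mdl)
        weak = build_uncertainty_matrix(X, 0.1, mdl, weak=["As"])
        j = ELEMENTS.index("As")
        np.testing.assert_allclose(weak.U[:, j], 3 * strong.U[:, j])


class TestQValue:
    def test_exact_model_gives_zero(self):
        X = np.random.default_rng(0).uniform(1, 5, (4, 3))
        assert q_value(X, X, np.ones_like(X)) == 0.0

    @pytest.mark.parametrize("x,model,u,expected", [
        (10.0, 8.0, 1.0, 4.0),
        (3.0, 1.0, 2.0, 1.0),
    ])
    def test_single_cell(self, x, model, u, expected):
        assert q_value([[x]], [[model]], [[u]]) == pytest.approx(expected)

    def test_cells_accumulate(self):
        X = np.array([[1.0, 2.0]])
        GF = np.array([[0.0, 3.0]])
        assert q_value(X, GF, np.ones((1, 2))) == pytest.approx(2.0)

    def test_non_positive_uncertainty_rejected(self):
        with pytest.raises(PMFError):
            q_value([[1.0]], [[1.0]], [[0.0]])


class TestFit:
    def test_noiseless_rank2_recovery(self, noiseless_k2):
        ds, truth, U = noiseless_k2
        X = ds.concentrations()
        sol = fit_pmf(X, U, 2, n_starts=3, seed=3, robust=False)
        assert sol.Q < 1e-4
        _, cosines = match_factors(truth.F_true, sol.F)
        assert (cosines >= 0.99).all()

    def test_rank1_exact_reconstruction(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(0.5, 2.0, (30, 1))
        f = rng.uniform(1.0, 50.0, (1, 9))
        X = g @ f
        U = 0.1 * X
        sol = fit_pmf(X, U, 1, n_starts=2, seed=0, robust=False)
        assert sol.Q < 1e-8
        np.testing.assert_allclose(sol.G @ sol.F, X, rtol=1e-4)

    def test_bitwise_deterministic_under_seed(self, noisy_k4):
        ds, _, U = noisy_k4
        X = ds.concentrations()
        a = fit_pmf(X, U, 3, n_starts=2, seed=9, max_iter=300)
        b = fit_pmf(X, U, 3, n_starts=2, seed=9, max_iter=300)
        assert a.Q == b.Q
        np.testing.assert_array_equal(a.G, b.G)

    def test_q_non_increasing_within_run(self, noisy_k4):
        ds, _, U = noisy_k4
        sol = fit_pmf(ds.concentrations(), U, 4, n_starts=1, seed=3,
                      robust=False)
        q = sol.q_history
        assert (np.diff(q) <= 1e-9 * np.maximum(q[:-1], 1.0)).all()

    def test_non_negativity_of_solution(self, base_solution_k4):
        assert (base_solution_k4.G >= 0).all()
        assert (base_solution_k4.F >= 0).all()

    def test_reported_q_matches_independent_q_value(self, base_solution_k4,
                                                    noisy_k4):
        ds, _, _ = noisy_k4
        X = ds.concentrations()
        sol = base_solution_k4
        q = q_value(X, sol.G @ sol.F, sol.U_effective)
        assert sol.Q == pytest.approx(q, rel=1e-8)

    def test_normalization_preserves_model_and_q(self, base_solution_k4,
                                                 noisy_k4):
        ds, _, _ = noisy_k4
        sol = base_solution_k4
        norm = sol.normalized()
        np.testing.assert_allclose(norm.G @ norm.F, sol.G @ sol.F, rtol=1e-10)
        np.testing.assert_allclose(norm.G.mean(axis=0), 1.0, rtol=1e-12)
        assert norm.Q == sol.Q

    def test_q_expected_formula(self, base_solution_k4):
        assert base_solution_k4.Q_expected == 120 * 9 - 4 * (120 + 9)

    def test_noisy_recovery_meets_cosine_bound(self, noisy_k4,
                                               base_solution_k4):
        _, truth, _ = noisy_k4
        _, cosines = match_factors(truth.F_true, base_solution_k4.F)
        assert (cosines >= 0.9).all()

    def test_invalid_inputs_rejected(self):
        X = np.ones((5, 9))
        with pytest.raises(PMFError):
            fit_pmf(X, np.ones_like(X), 0, seed=0)
        with pytest.raises(PMFError):
            fit_pmf(X, np.zeros_like(X), 2, seed=0)
        with pytest.raises(PMFError):
            fit_pmf(X * np.nan, np.ones_like(X), 2, seed=0)


class TestFactorCountSelection:
    def test_selects_true_k_on_synthetic_data(self, noisy_k4):
        ds, _, U = noisy_k4
        k, table = select_factor_count(ds.concentrations(), U, range(3, 6),
                                       n_starts=3, seed=3)
        assert k == 4
        assert list(table["k"]) == [3, 4, 5]

    def test_rank1_data_select_smallest_k(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0.5, 2.0, (40, 1)) @ rng.uniform(1, 50, (1, 9))
        U = 0.1 * X
        k, table = select_factor_count(X, U, range(2, 5), n_starts=2, seed=1)
        assert k == 2
        assert len(table) == 3


class TestMatchFactors:
    def test_recovers_row_permutation(self):
        rng = np.random.default_rng(3)
        F = rng.uniform(0, 10, (4, 9))
        perm = np.array([2, 0, 3, 1])
        got, cosines = match_factors(F, F[perm])
        # row i of F sits at position argwhere(perm == i) in the shuffle
        np.testing.assert_array_equal(got, np.argsort(perm))
        np.testing.assert_allclose(cosines, 1.0, rtol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        F = rng.uniform(0, 10, (3, 9))
        _, cosines = match_factors(F, 2.0 * F)
        np.testing.assert_allclose(cosines, 1.0, rtol=1e-12)

    def test_agrees_with_brute_force_assignment(self):
        """Exhaustive search over permutations is the oracle for the
        Hungarian assignment on disjoint-support profiles."""
        rng = np.random.default_rng(5)
        F = np.zeros((3, 9))
        F[0, :3] = rng.uniform(1, 5, 3)
        F[1, 3:6] = rng.uniform(1, 5, 3)
        F[2, 6:] = rng.uniform(1, 5, 3)
        shuffled = F[[1, 2, 0]]
        got, _ = match_factors(F, shuffled)

        def total(perm):
            s = 0.0
            for i, j in enumerate(perm):
                a, b = F[i], shuffled[j]
                s += a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            return s

        best = max(itertools.permutations(range(3)), key=total)
        np.testing.assert_array_equal(got, best)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(PMFError):
            match_factors(np.ones((2, 9)), np.ones((3, 9)))


class TestBootstrap:
    def test_noiseless_well_separated_maps_fully(self, noiseless_k4):
        ds, _, U = noiseless_k4
        X = ds.concentrations()
        base = fit_pmf(X, U, 4, n_starts=5, seed=3, robust=False)
        report = bootstrap_diagnostic(X, U, base, n_runs=30, seed=0)
        assert all(v == 100.0 for v in report.bs_mapped_pct.values())

    def test_impossible_threshold_maps_nothing(self, noiseless_k2):
        ds, _, U = noiseless_k2
        X = ds.concentrations()
        base = fit_pmf(X, U, 2, n_starts=2, seed=3, robust=False)
        report = bootstrap_diagnostic(X, U, base, n_runs=5,
                                      map_threshold=1.01, seed=0)
        assert all(v == 0.0 for v in report.bs_mapped_pct.values())

    def test_single_run_counts(self, noiseless_k2):
        ds, _, U = noiseless_k2
        X = ds.concentrations()
        base = fit_pmf(X, U, 2, n_starts=2, seed=3, robust=False)
        report = bootstrap_diagnostic(X, U, base, n_runs=1, seed=1)
        assert report.bs_runs == 1
        assert set(report.bs_mapped_pct.values()) <= {0.0, 100.0}


class TestDisp:
    def test_noiseless_base_is_stable(self, noiseless_k4):
        ds, _, U = noiseless_k4
        X = ds.concentrations()
        base = fit_pmf(X, U, 4, n_starts=5, seed=3, robust=False)
        report = disp_diagnostic(X, U, base, seed=0)
        assert report.disp_stable
        assert report.disp_max_dq_pct < 1.0
        assert report.disp_swaps == 0

    def test_empty_grid_yields_zero_probes(self, base_solution_k4, noisy_k4):
        ds, _, U = noisy_k4
        report = disp_diagnostic(ds.concentrations(), U, base_solution_k4,
                                 perturbation_grid=(), seed=0)
        assert report.disp_probes == 0
        assert report.disp_stable

    def test_overfactored_model_shows_swaps(self, refs):
        """Fitting k_true + 2 factors produces degenerate sources whose
        identity does not survive displacement."""
        spec = synthetic.make_default_sourcespec(2, seed=1, noise_cv=0.1)
        ds, _ = synthetic.synthesize_dataset(spec, 30, mdl=refs.mdl, seed=1)
        X = ds.concentrations()
        U = build_uncertainty_matrix(ds, 0.1, refs.mdl)
        base = fit_pmf(X, U, 4, n_starts=3, seed=0)
        report = disp_diagnostic(X, U, base, perturbation_grid=(0.5, 0.9),
                                 seed=0)
        assert report.disp_swaps >= 1

    def test_unconverged_base_rejected(self, noisy_k4):
        ds, _, U = noisy_k4
        sol = fit_pmf(ds.concentrations(), U, 4, n_starts=1, seed=3,
                      max_iter=5)
        with pytest.raises(PMFError, match="converged"):
            disp_diagnostic(ds.concentrations(), U, sol)


class TestContributionSummaries:
    def test_single_factor_owns_every_element(self):
        F = np.random.default_rng(0).uniform(1, 10, (1, 9))
        np.testing.assert_allclose(element_contribution_percent(F), 100.0)

    def test_column_normalisation(self):
        F = np.array([[3.0], [1.0]])
        np.testing.assert_allclose(element_contribution_percent(F).ravel(),
                                   [75.0, 25.0])

    def test_columns_sum_to_100(self, base_solution_k4):
        pct = element_contribution_percent(base_solution_k4.F)
        np.testing.assert_allclose(pct.sum(axis=0), 100.0, atol=1e-9)

    def test_factor_share_trivial_cases(self):
        G = np.ones((10, 1))
        F = np.ones((1, 9))
        np.testing.assert_allclose(factor_total_share(G, F), [100.0])
        G2 = np.ones((10, 2))
        F2 = np.ones((2, 9))
        np.testing.assert_allclose(factor_total_share(G2, F2), [50.0, 50.0])

    def test_share_recovers_known_mixing_weights(self):
        """Rank-2 noiseless mixture with 70/30 mass split."""
        rng = np.random.default_rng(8)
        # disjoint-support profiles make the factorization identifiable,
        # so the mass split is recoverable, not just the directions
        F = np.array([[5.0, 2.0, 8.0, 1.0, 0, 0, 0, 0, 0],
                      [0, 0, 0, 0, 3.0, 7.0, 2.0, 6.0, 4.0]])
        F = F / F.sum(axis=1, keepdims=True)  # unit row mass
        G = rng.uniform(0.1, 1.0, (60, 2))
        G[:5, 1] = 0.0   # pure-source anchor rows pin the rotation
        G[5:10, 0] = 0.0
        G[:, 0] *= 0.7 * 2 / G[:, 0].mean()
        G[:, 1] *= 0.3 * 2 / G[:, 1].mean()
        X = G @ F
        U = 0.1 * X + 0.01 * X.mean()  # floor keeps zero cells well-posed
        sol = fit_pmf(X, U, 2, n_starts=4, seed=2, robust=False)
        _, cos = match_factors(F, sol.F)
        assert (cos > 0.99).all()
        perm, _ = match_factors(F, sol.F)
        shares = factor_total_share(sol.G, sol.F)[perm]
        np.testing.assert_allclose(shares, [70.0, 30.0], atol=2.0)

    def test_normalize_contributions(self):
        G = np.array([[1.0, 2.0], [3.0, 2.0]])
        out = normalize_contributions(G)
        np.testing.assert_allclose(out[:, 0], [0.5, 1.5])
        np.testing.assert_allclose(out.mean(axis=0), 1.0, atol=1e-12)
        with pytest.raises(PMFError):
            normalize_contributions(np.zeros((3, 2)))
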