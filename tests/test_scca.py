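import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import mirscca as m
from mirscca.profiles import ProfileMatrix


def bisection_oracle(a, bound, grid=200_000):
    """Independent threshold search: scan delta on a fine grid."""
    a = np.asarray(a, dtype=float)
    best = None
    for delta in np.linspace(0, np.abs(a).max() * (1 - 1e-9), grid // 100):
        s = np.sign(a) * np.maximum(np.abs(a) - delta, 0)
        norm = np.linalg.norm(s)
        if norm == 0:
            break
        u = s / norm
        if np.abs(u).sum() <= bound + 1e-9:
            best = u
            break
    return best


class TestSoftThreshold:
    def test_componentwise_definition(self):
        out = m.soft_threshold(np.array([3.0, -1.0, 0.5]), 1.0)
        np.testing.assert_allclose(out, [2.0, 0.0, 0.0])

    def test_zero_delta_is_identity(self):
        z = np.array([1.5, -2.0, 0.0])
        np.testing.assert_array_equal(m.soft_threshold(z, 0.0), z)

    def test_full_shrinkage(self):
        np.testing.assert_array_equal(
            m.soft_threshold(np.array([2.0, 2.0]), 5.0), [0.0, 0.0]
        )

    def test_negative_delta_errors(self):
        with pytest.raises(ValueError):
            m.soft_threshold(np.array([1.0]), -0.1)

    @settings(deadline=None, derandomize=True)
    @given(
        z=hnp.arrays(
            float,
            st.integers(1, 12),
            elements=st.floats(-50, 50, allow_nan=False),
        ),
        delta=st.floats(0, 10),
    )
    def test_shrinks_toward_zero_and_preserves_sign(self, z, delta):
        out = m.soft_threshold(z, delta)
        assert (np.abs(out) <= np.abs(z) + 1e-12).all()
        assert (out * z >= 0).all()


class TestL1UnitVector:
    def test_inactive_constraint_just_normalizes(self):
        out = m.l1_unit_vector(np.array([3.0, 4.0]), math.sqrt(2))
        np.testing.assert_allclose(out, [0.6, 0.8])

    def test_tight_bound_selects_dominant_coordinate(self):
        out = m.l1_unit_vector(np.array([2.0, 1.0]), 1.0)
        np.testing.assert_allclose(out, [1.0, 0.0], atol=1e-6)

    def test_tied_magnitudes_make_bound_unattainable(self):
        with pytest.warns(RuntimeWarning, match="unattainable"):
            out = m.l1_unit_vector(np.array([1.0, 1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(out, [0.5, 0.5, 0.5, 0.5])

    def test_all_zero_input_errors(self):
        with pytest.raises(ValueError):
            m.l1_unit_vector(np.zeros(3), 1.5)

    def test_matches_grid_scan_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=6)
            bound = rng.uniform(1.0, math.sqrt(6))
            ours = m.l1_unit_vector(a, bound)
            oracle = bisection_oracle(a, bound)
            assert abs(np.linalg.norm(ours) - 1) < 1e-9
            assert np.abs(ours).sum() <= bound + 1e-6
            # same objective value as the scan solution (alignment with a)
            assert a @ ours >= a @ oracle - 1e-3

    @settings(deadline=None, derandomize=True)
    @given(
        a=hnp.arrays(
            float,
            st.integers(2, 10),
            elements=st.floats(-20, 20, allow_nan=False),
        ).filter(lambda v: np.linalg.norm(v) > 1e-6),
        c=st.floats(0.05, 1.0),
    )
    def test_unit_norm_and_budget_invariants(self, a, c):
        bound = m.effective_l1_bound(c, len(a))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            u = m.l1_unit_vector(a, bound)
        assert abs(np.linalg.norm(u) - 1) < 1e-8
        # budget holds except in the tie-limit case, where L1 = sqrt(#ties)
        n_ties = int((np.abs(u) > 0).sum())
        assert np.abs(u).sum() <= max(bound, math.sqrt(n_ties)) + 1e-6


class TestEffectiveL1Bound:
    def test_clamps_infeasible_budget_to_one(self):
        assert m.effective_l1_bound(0.01, 2796) == 1.0

    def test_clamps_above_sqrt_m(self):
        assert m.effective_l1_bound(1.0, 9) == 3.0

    def test_passes_through_feasible_values(self):
        assert m.effective_l1_bound(0.5, 16) == pytest.approx(2.0)


class TestPmdRank1:
    def test_diagonal_matrix_leading_triple(self):
        alpha, beta, d = m.pmd_rank1(
            np.diag([2.0, 1.0]), math.sqrt(2), math.sqrt(2)
        )
        np.testing.assert_allclose(np.abs(alpha), [1, 0], atol=1e-9)
        np.testing.assert_allclose(np.abs(beta), [1, 0], atol=1e-9)
        assert d == pytest.approx(2.0)

    def test_nonbinding_bounds_match_svd_oracle(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(5, 4))
        alpha, beta, d = m.pmd_rank1(Z, math.sqrt(5), math.sqrt(4))
        u, s, vt = np.linalg.svd(Z)
        assert abs(d - s[0]) < 1e-6
        assert abs(alpha @ u[:, 0]) >= 1 - 1e-6

    def test_unit_bounds_select_largest_entry(self):
        alpha, beta, d = m.pmd_rank1(np.diag([2.0, 1.0]), 1.0, 1.0)
        assert d == pytest.approx(2.0)
        # brute force over all 1-sparse pairs: objective = max |Z_ij|
        assert np.count_nonzero(alpha) == 1
        assert np.count_nonzero(beta) == 1

    def test_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            m.pmd_rank1(np.zeros((3, 3)), 1.0, 1.0)

    def test_objective_is_nondecreasing_across_iterations(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            Z = rng.normal(size=(6, 5))
            bound1 = rng.uniform(1, math.sqrt(6))
            bound2 = rng.uniform(1, math.sqrt(5))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                # start from a feasible iterate (the SVD vector itself may
                # violate the L1 budget, so the first update could decrease)
                alpha = m.l1_unit_vector(Z @ np.linalg.svd(Z)[2][0], bound1)
                beta = m.l1_unit_vector(Z.T @ alpha, bound2)
                alpha = m.l1_unit_vector(Z @ beta, bound1)
                objectives = [alpha @ Z @ beta]
                for _ in range(30):
                    beta = m.l1_unit_vector(Z.T @ alpha, bound2)
                    alpha = m.l1_unit_vector(Z @ beta, bound1)
                    objectives.append(alpha @ Z @ beta)
            diffs = np.diff(objectives)
            assert (diffs >= -1e-9).all()

    def test_sparsity_monotone_in_c(self):
        rng = np.random.default_rng(21)
        Z = rng.normal(size=(12, 9))
        l1_norms = []
        for c in (1.0, 0.8, 0.6, 0.4, 0.2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                alpha, _, _ = m.pmd_rank1(
                    Z, m.effective_l1_bound(c, 12), math.sqrt(9)
                )
            l1_norms.append(np.abs(alpha).sum())
        assert all(b <= a + 1e-6 for a, b in zip(l1_norms, l1_norms[1:]))


class TestFitScca:
    def test_rank2_matrix_recovered_exactly(self):
        rng = np.random.default_rng(1)
        u = np.linalg.qr(rng.normal(size=(6, 2)))[0]
        v = np.linalg.qr(rng.normal(size=(5, 2)))[0]
        Z = 3.0 * np.outer(u[:, 0], v[:, 0]) + 1.0 * np.outer(u[:, 1], v[:, 1])
        triples = m.pmd_decompose(Z, math.sqrt(6), math.sqrt(5), K=2)
        d = [t[2] for t in triples]
        np.testing.assert_allclose(d, [3.0, 1.0], atol=1e-6)
        recon = sum(dk * np.outer(a, b) for a, b, dk in triples)
        assert np.linalg.norm(Z - recon) < 1e-6

    def test_requesting_more_components_than_rank_truncates(self):
        Z = np.outer([1.0, 2.0], [3.0, 0.0, 1.0])
        with pytest.warns(RuntimeWarning, match="truncating"):
            triples = m.pmd_decompose(Z, math.sqrt(2), math.sqrt(3), K=5)
        assert len(triples) == 1

    def test_identical_views_have_unit_leading_correlation(self, small_planted):
        X = small_planted.gene
        config = m.SCCAConfig(c1=1.0, c2=1.0, K=1)
        model = m.fit_scca(X, X, config)
        assert model.components[0].rho == pytest.approx(1.0, abs=1e-9)

    def test_row_mismatch_errors(self, small_planted):
        X = small_planted.gene
        Y = ProfileMatrix(
            small_planted.disease.values,
            tuple(reversed(small_planted.disease.row_ids)),
            small_planted.disease.col_ids,
        )
        with pytest.raises(ValueError):
            m.fit_scca(X, Y, m.SCCAConfig(K=1))

    def test_component_norm_invariants(self, small_model):
        config = small_model.config
        p = len(small_model.gene_ids)
        q = len(small_model.disease_ids)
        for comp in small_model.components:
            assert np.linalg.norm(comp.alpha) <= 1 + config.tol
            assert np.linalg.norm(comp.beta) <= 1 + config.tol
            assert np.abs(comp.alpha).sum() <= m.effective_l1_bound(
                config.c1, p
            ) + config.tol
            assert np.abs(comp.beta).sum() <= m.effective_l1_bound(
                config.c2, q
            ) + config.tol
            assert -1 <= comp.rho <= 1
            assert comp.d >= 0

    def test_sign_convention_largest_alpha_weight_positive(self, small_model):
        for comp in small_model.components:
            assert comp.alpha[np.argmax(np.abs(comp.alpha))] > 0

    def test_center_mode_stores_column_means(self, small_planted):
        config = m.SCCAConfig(c1=1.0, c2=1.0, K=2, center=True)
        model = m.fit_scca(small_planted.gene, small_planted.disease, config)
        np.testing.assert_allclose(
            model.gene_column_means, small_planted.gene.values.mean(axis=0)
        )


class TestCanonicalCorrelation:
    def test_self_correlation_is_one(self, small_planted):
        X = small_planted.gene.values
        alpha = np.ones(X.shape[1])
        assert m.canonical_correlation(X, X, alpha, alpha) == pytest.approx(1.0)

    def test_constant_variate_gives_zero(self):
        X = np.ones((4, 2))
        Y = np.array([[1.0], [0.0], [1.0], [0.0]])
        assert m.canonical_correlation(X, Y, np.array([1.0, 0.0]), np.array([1.0])) == 0.0

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        Y = rng.normal(size=(10, 2))
        alpha = np.array([0.2, -0.5, 1.0])
        beta = np.array([0.7, 0.1])
        u, v = X @ alpha, Y @ beta
        expected = np.corrcoef(u, v)[0, 1]
        assert m.canonical_correlation(X, Y, alpha, beta) == pytest.approx(expected)


class TestExtractCorrelatedSets:
    def _model_with_alpha(self, alpha, beta, gene_ids, disease_ids):
        comp = m.CanonicalComponent(
            alpha=np.array(alpha), beta=np.array(beta), d=1.0, rho=1.0
        )
        from mirscca.scca import _weight_set

        comp.gene_set = _weight_set(comp.alpha, gene_ids)
        comp.disease_set = _weight_set(comp.beta, disease_ids)
        return m.SCCAModel(
            components=[comp],
            gene_ids=gene_ids,
            disease_ids=disease_ids,
            config=m.SCCAConfig(K=1),
        )

    def test_nonzero_selection_and_ordering(self):
        model = self._model_with_alpha(
            [0.9, 0.0, 0.1], [1.0], ("g1", "g2", "g3"), ("d1",)
        )
        gene_set, _, _ = m.extract_correlated_sets(model, 1)
        assert gene_set == [("g1", 0.9), ("g3", 0.1)]

    def test_fully_shrunk_side_gives_empty_set(self):
        model = self._model_with_alpha([1.0], [0.0, 0.0], ("g1",), ("d1", "d2"))
        _, disease_set, _ = m.extract_correlated_sets(model, 1)
        assert disease_set == []

    def test_equal_weights_break_ties_lexicographically(self):
        model = self._model_with_alpha(
            [0.5, 0.5], [1.0], ("gB", "gA"), ("d1",)
        )
        gene_set, _, _ = m.extract_correlated_sets(model, 1)
        assert [g for g, _ in gene_set] == ["gA", "gB"]

    def test_out_of_range_index_errors(self, small_model):
        with pytest.raises(IndexError):
            m.extract_correlated_sets(small_model, small_model.K + 1)

    def test_contributing_mirnas_overlap_both_sides(self, small_planted, small_model):
        _, _, mirnas = m.extract_correlated_sets(small_model, 1)
        comp = small_model.components[0]
        for mid in mirnas:
            row = small_planted.gene.row(mid)
            assert abs(row @ comp.alpha) > 0
            drow = small_planted.disease.row(mid)
            assert abs(drow @ comp.beta) > 0


class TestSerialization:
    def test_json_round_trip_is_bit_exact(self, small_model, tmp_path):
        path = tmp_path / "model.json"
        small_model.to_json(path)
        back = m.SCCAModel.from_json(path)
        assert back.gene_ids == small_model.gene_ids
        assert back.disease_ids == small_model.disease_ids
        assert back.config == small_model.config
        for a, b in zip(small_model.components, back.components):
            np.testing.assert_array_equal(a.alpha, b.alpha)
            np.testing.assert_array_equal(a.beta, b.beta)
            assert a.d == b.d and a.rho == b.rho
            assert a.contributing_mirnas == b.contributing_mirnas
            assert a.gene_set == b.gene_set

    def test_refit_serialization_is_byte_identical(self, small_planted):
        config = m.SCCAConfig(c1=0.45, c2=0.45, K=3)
        one = m.fit_scca(small_planted.gene, small_planted.disease, config)
        two = m.fit_scca(small_planted.gene, small_planted.disease, config)
        assert one.to_json() == two.to_json()

    def test_component_report_lists_all_members(self, small_model, tmp_path):
        path = tmp_path / "components.tsv"
        small_model.component_report(path)
        lines = path.read_text().splitlines()
        n_rows = sum(
            len(c.gene_set) + len(c.disease_set) + len(c.contributing_mirnas)
            for c in small_model.components
        )
        assert len(lines) == n_rows + 1
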