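"""SVD basis derivation, quality metrics, feature-count selection, stability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitdi import (
    DomainError,
    GaitVector,
    InputError,
    SelectionCriteria,
    VECTOR_LENGTH,
    decompose,
    evaluate_basis,
    fidelity,
    generate_low_rank_cohort,
    load_basis,
    monte_carlo_stability,
    reconstruct,
    save_basis,
    select_feature_count,
    vaf,
)
from gaitdi.basis import ORTHONORMALITY_TOL

from conftest import cohort_from_matrix


def gram_singular_values(G):
    """Independent oracle: singular values as sqrt of Gram-matrix eigenvalues."""
    eigvals = np.linalg.eigh(G.T @ G)[0]
    return np.sqrt(np.clip(eigvals, 0.0, None))[::-1]


class TestDecompose:
    def test_rank_one_matrix(self, rng):
        v = rng.normal(size=VECTOR_LENGTH)
        cohort = cohort_from_matrix(np.column_stack([v, v, v]))
        basis = decompose(cohort)
        s = basis.singular_values
        assert s[0] == pytest.approx(np.sqrt(3) * np.linalg.norm(v))
        assert np.all(s[1:] < 1e-8 * s[0])
        direction = basis.features[:, 0]
        unit = v / np.linalg.norm(v)
        if unit[np.argmax(np.abs(unit))] < 0:
            unit = -unit
        np.testing.assert_allclose(direction, unit, atol=1e-10)

    def test_orthogonal_columns_are_their_own_svd(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(VECTOR_LENGTH, 5)))
        G = Q * np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        basis = decompose(cohort_from_matrix(G))
        np.testing.assert_allclose(basis.singular_values, [5, 4, 3, 2, 1], atol=1e-10)

    def test_singular_values_match_gram_eigendecomposition(self, rng):
        for _ in range(5):
            block = rng.normal(size=(20, 6))
            G = np.zeros((VECTOR_LENGTH, 6))
            G[:20] = block
            basis = decompose(cohort_from_matrix(G))
            np.testing.assert_allclose(
                basis.singular_values, gram_singular_values(G), atol=1e-8
            )

    def test_energy_conservation_and_orthonormality(self, control_cohort):
        basis = decompose(control_cohort)
        F = basis.features
        assert np.max(np.abs(F.T @ F - np.eye(F.shape[1]))) < ORTHONORMALITY_TOL
        total = np.sum(basis.singular_values**2)
        frob = np.linalg.norm(control_cohort.matrix) ** 2
        assert total == pytest.approx(frob, rel=1e-10)

    def test_sign_convention_is_deterministic(self, rng):
        G = rng.normal(size=(VECTOR_LENGTH, 8))
        b1 = decompose(cohort_from_matrix(G))
        b2 = decompose(cohort_from_matrix(G.copy()))
        np.testing.assert_array_equal(b1.features, b2.features)
        idx = np.argmax(np.abs(b1.features), axis=0)
        assert np.all(b1.features[idx, np.arange(b1.m)] >= 0)


class TestVaf:
    def test_two_value_example(self):
        assert vaf([4.0, 3.0], 1) == pytest.approx(64.0)

    def test_full_length_is_100(self):
        assert vaf([4.0, 3.0], 2) == pytest.approx(100.0)

    def test_partial_sum_example(self):
        assert vaf([2.0, 1.0, 1.0], 2) == pytest.approx(100 * 5 / 6)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(DomainError, match="zero"):
            vaf([0.0, 0.0], 1)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_vaf_non_decreasing_in_m(self, seed):
        s = np.sort(np.random.default_rng(seed).uniform(0.01, 10, size=12))[::-1]
        values = [vaf(s, m) for m in range(1, 13)]
        assert np.all(np.diff(values) >= -1e-12)
        assert values[-1] == pytest.approx(100.0)


@pytest.fixture(scope="module")
def basis(control_cohort):
    return decompose(control_cohort)


class TestReconstructAndFidelity:
    def test_in_span_vector_is_recovered_exactly(self, basis):
        g = GaitVector(7.0 * basis.features[:, 0])
        np.testing.assert_allclose(
            reconstruct(g, basis, 1).components, g.components, atol=1e-10
        )
        assert fidelity(g, reconstruct(g, basis, 1)) == pytest.approx(100.0)

    def test_orthogonal_vector_maps_to_zero(self, basis, rng):
        g = rng.normal(size=VECTOR_LENGTH)
        m = 5
        g -= basis.features[:, :m] @ (basis.features[:, :m].T @ g)
        rec = reconstruct(GaitVector(g), basis, m)
        np.testing.assert_allclose(rec.components, 0.0, atol=1e-9)
        assert fidelity(GaitVector(g), rec) == pytest.approx(0.0, abs=1e-6)

    def test_full_basis_is_complete(self, rng):
        G = rng.normal(size=(VECTOR_LENGTH, VECTOR_LENGTH))
        basis = decompose(cohort_from_matrix(G))
        g = rng.normal(size=VECTOR_LENGTH)
        rec = reconstruct(GaitVector(g), basis, VECTOR_LENGTH)
        np.testing.assert_allclose(rec.components, g, atol=1e-8)

    def test_hand_computed_projection_fidelity(self):
        g = np.zeros(VECTOR_LENGTH)
        g[0], g[1] = 3.0, 4.0
        g_hat = np.zeros(VECTOR_LENGTH)
        g_hat[0] = 3.0
        assert fidelity(GaitVector(g), GaitVector(g_hat)) == pytest.approx(60.0)

    def test_zero_norm_original_rejected(self):
        with pytest.raises(DomainError, match="zero"):
            fidelity(GaitVector(np.zeros(VECTOR_LENGTH)), GaitVector(np.zeros(VECTOR_LENGTH)))

    def test_fidelity_non_decreasing_in_m(self, basis, control_cohort):
        g = GaitVector(control_cohort.matrix[:, 0])
        fids = [fidelity(g, reconstruct(g, basis, m)) for m in range(1, 30)]
        assert np.all(np.diff(fids) >= -1e-10)


class TestEvaluateBasis:
    def test_training_set_with_full_basis_is_perfect(self, control_cohort):
        basis = decompose(control_cohort)
        q = evaluate_basis(control_cohort, basis, basis.m)
        assert q.vaf_percent == pytest.approx(100.0)
        assert q.mean_fidelity_percent == pytest.approx(100.0)
        assert q.pct_high_fidelity == pytest.approx(100.0)

    def test_prescribed_fidelities_average_and_percentage(self, rng):
        # strides built at exact angles to the feature subspace: fidelity = 100 cos(theta)
        Q, _ = np.linalg.qr(rng.normal(size=(VECTOR_LENGTH, 4)))
        basis = decompose(cohort_from_matrix(Q[:, :2] * [3.0, 2.0]))
        inside, outside = basis.features[:, 0], Q[:, 3]
        outside -= basis.features[:, :2] @ (basis.features[:, :2].T @ outside)
        outside /= np.linalg.norm(outside)
        cols = []
        for f in (0.96, 0.96, 0.96, 0.90):
            cols.append(f * inside + np.sqrt(1 - f**2) * outside)
        cohort = cohort_from_matrix(np.column_stack(cols))
        q = evaluate_basis(cohort, basis, 2, high_fidelity_threshold=95.0)
        assert q.mean_fidelity_percent == pytest.approx(94.5, abs=1e-9)
        assert q.pct_high_fidelity == pytest.approx(75.0)

    def test_foreign_set_reports_vaf_not_applicable(self, control_cohort, rng):
        basis = decompose(control_cohort)
        foreign = cohort_from_matrix(rng.normal(size=(VECTOR_LENGTH, 10)))
        q = evaluate_basis(foreign, basis, 15)
        assert q.vaf_percent is None
        assert 0.0 <= q.mean_fidelity_percent <= 100.0


class TestSelectFeatureCount:
    def test_known_rank_with_small_noise_selects_k(self):
        cohort = generate_low_rank_cohort(k=8, n=200, noise_sd=0.1, seed=11)
        result = select_feature_count(cohort, SelectionCriteria(m_min=1, m_max=30))
        assert result.m_star == 8
        trace = result.trace.set_index("m")
        assert trace.loc[7, "mean_fidelity_percent"] < 98.0

    def test_criteria_met_at_range_floor(self):
        cohort = generate_low_rank_cohort(k=3, n=100, noise_sd=0.0, seed=5)
        result = select_feature_count(cohort, SelectionCriteria())  # scan starts at 10
        assert result.m_star == 10
        row = result.trace.iloc[0]
        assert row["vaf_percent"] == pytest.approx(100.0)
        assert row["mean_fidelity_percent"] == pytest.approx(100.0)

    def test_unreachable_criteria_return_not_reached_with_trace(self):
        cohort = generate_low_rank_cohort(k=100, n=120, noise_sd=1.0, seed=2)
        result = select_feature_count(
            cohort, SelectionCriteria(vaf_min=100.0, m_min=10, m_max=30)
        )
        assert result.m_star is None
        assert not result.reached
        assert len(result.trace) == 21

    def test_noiseless_rank_recovery_boundary(self):
        # at m = k both metrics saturate; at m = k-1 fidelity is strictly lower
        cohort = generate_low_rank_cohort(k=12, n=200, noise_sd=0.0, seed=3)
        result = select_feature_count(cohort, SelectionCriteria(m_min=1, m_max=30))
        trace = result.trace.set_index("m")
        assert trace.loc[12, "vaf_percent"] == pytest.approx(100.0, abs=1e-9)
        assert trace.loc[12, "mean_fidelity_percent"] == pytest.approx(100.0, abs=1e-9)
        assert trace.loc[11, "mean_fidelity_percent"] < 100.0 - 1e-3


class TestMonteCarloStability:
    def test_noiseless_rank_k_is_perfectly_stable(self):
        cohort = generate_low_rank_cohort(k=6, n=120, noise_sd=0.0, seed=9)
        report = monte_carlo_stability(
            cohort, SelectionCriteria(m_min=1, m_max=30), iterations=10,
            holdout_fraction=0.05, seed=0,
        )
        assert report.m_fidelity == [6] * 10
        assert report.m_fidelity_mean_sd == (6.0, 0.0)
        assert report.m_vaf_mean_sd[1] == 0.0
        assert report.stable

    def test_same_seed_reproduces_report(self, control_cohort):
        kwargs = dict(iterations=4, holdout_fraction=0.05, seed=123)
        r1 = monte_carlo_stability(control_cohort, **kwargs)
        r2 = monte_carlo_stability(control_cohort, **kwargs)
        assert r1.to_dict() == r2.to_dict()

    def test_seed_independence_under_fixed_structure(self):
        cohort = generate_low_rank_cohort(k=5, n=100, noise_sd=0.0, seed=4)
        crit = SelectionCriteria(m_min=1, m_max=30)
        r1 = monte_carlo_stability(cohort, crit, iterations=5, seed=1)
        r2 = monte_carlo_stability(cohort, crit, iterations=5, seed=2)
        assert r1.m_joint == r2.m_joint == [5] * 5

    def test_noisy_known_rank_stays_within_one_feature(self):
        cohort = generate_low_rank_cohort(k=12, n=200, noise_sd=0.3, seed=21)
        report = monte_carlo_stability(
            cohort, SelectionCriteria(m_min=1, m_max=30), iterations=10, seed=0
        )
        assert all(m in (12, 13) for m in report.m_fidelity)
        assert report.m_fidelity_mean_sd[1] <= 0.5

    def test_holdout_emptying_matrix_rejected(self):
        cohort = generate_low_rank_cohort(k=1, n=1, noise_sd=0.0, seed=0)
        with pytest.raises(InputError, match="empty"):
            monte_carlo_stability(cohort, holdout_fraction=0.05)


class TestBasisFile:
    def test_save_load_roundtrip(self, control_cohort, tmp_path):
        basis = decompose(control_cohort)
        path = tmp_path / "basis.json"
        save_basis(basis, path, m=21)
        loaded = load_basis(path)
        assert loaded.m == 21
        np.testing.assert_array_equal(loaded.features, basis.features[:, :21])
        np.testing.assert_array_equal(loaded.singular_values, basis.singular_values)
        assert loaded.fingerprint() == basis.fingerprint(21)

    def test_tampered_file_rejected(self, control_cohort, tmp_path):
        import json

        basis = decompose(control_cohort)
        path = tmp_path / "basis.json"
        save_basis(basis, path, m=5)
        doc = json.loads(path.read_text())
        doc["features_row_major"][0] += 0.5
        path.write_text(json.dumps(doc))
        with pytest.raises(InputError):
            load_basis(path)
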