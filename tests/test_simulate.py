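import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from rosetta import (
    RosettaError,
    SigmaSpec,
    StudyConfig,
    apply_test_condition,
    build_sigma,
    make_case_status,
    read_pool,
    simulate_control,
    study2_preset,
)
from rosetta.simulate import write_study_csvs


class TestBuildSigma:
    def test_block_entries_land_where_expected(self):
        S = build_sigma(SigmaSpec(rho_within=0.75, rho_between=0.4))
        assert S[0, 1] == 0.75  # V1-V2, within domain A
        assert S[0, 3] == 0.4  # V1-V4, across domains A-B
        np.testing.assert_array_equal(np.diag(S), 1.0)
        np.testing.assert_array_equal(S, S.T)

    def test_zero_correlations_give_identity(self):
        np.testing.assert_array_equal(
            build_sigma(SigmaSpec(rho_within=0.0, rho_between=0.0)), np.eye(9)
        )

    def test_per_pair_between_values(self):
        S = build_sigma(SigmaSpec(rho_within=0.75, rho_between=(0.4, 0.3, 0.2)))
        assert S[0, 3] == 0.4 and S[0, 6] == 0.3 and S[3, 6] == 0.2

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.floats(min_value=0.0, max_value=0.95),
        st.floats(min_value=0.0, max_value=0.6),
    )
    def test_indefiniteness_detection_matches_eigen_oracle(self, within, between):
        """build_sigma errors exactly when the assembled matrix has a
        negative eigenvalue (numpy eigendecomposition as the oracle)."""
        S = np.eye(9)
        for d in range(3):
            b = 3 * d
            S[b : b + 3, b : b + 3] = (1 - within) * np.eye(3) + within
        for bx, by in ((0, 3), (0, 6), (3, 6)):
            S[bx : bx + 3, by : by + 3] = between
            S[by : by + 3, bx : bx + 3] = between
        indefinite = np.linalg.eigvalsh(S).min() < -1e-10
        spec = SigmaSpec(rho_within=within, rho_between=between)
        if indefinite:
            with pytest.raises(RosettaError, match="indefinite"):
                build_sigma(spec)
        else:
            np.testing.assert_array_equal(build_sigma(spec), S)


class TestSimulateControl:
    def test_deterministic_given_seed(self):
        spec = SigmaSpec(0.75, 0.5)
        cfg = StudyConfig(n_total=300, seed=12)
        a = simulate_control(spec, cfg).concat()
        b = simulate_control(spec, cfg).concat()
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())
        assert list(a.index) == list(b.index)

    def test_empirical_moments_match_the_generating_model(self):
        spec = SigmaSpec(0.75, 0.5)
        pool = simulate_control(spec, StudyConfig(n_total=3000, seed=4))
        big = pool.concat()
        assert np.abs(big.mean()).max() < 0.06
        assert np.abs(big.std(ddof=1) - 1).max() < 0.05
        emp = np.corrcoef(big.to_numpy().T)
        assert np.abs(emp - build_sigma(spec)).max() < 0.04

    def test_split_into_equal_disjoint_studies(self):
        pool = simulate_control(SigmaSpec(0.75, 0.5), StudyConfig(n_total=300, seed=1))
        assert [ds.n for ds in pool.datasets] == [100, 100, 100]
        ids = [set(ds.subjects) for ds in pool.datasets]
        assert not (ids[0] & ids[1]) and not (ids[1] & ids[2])


class TestTestCondition:
    @pytest.mark.parametrize("pattern", ["aligned", "rotated"])
    def test_each_study_keeps_two_measures_per_domain(self, pattern):
        pool = simulate_control(SigmaSpec(0.75, 0.5), StudyConfig(n_total=300, seed=6))
        test = apply_test_condition(pool, pattern)
        for ds in test.datasets:
            assert len(ds.available) == 6
            for dom_cols in (["V1", "V2", "V3"], ["V4", "V5", "V6"], ["V7", "V8", "V9"]):
                assert sum(c in ds.available for c in dom_cols) == 2
        # every measure survives in exactly two studies; none in all three
        for m in test.catalog.measure_ids:
            assert sum(m in ds.available for ds in test.datasets) == 2

    def test_aligned_pattern_drops_the_study_indexed_measure(self):
        pool = simulate_control(SigmaSpec(0.75, 0.5), StudyConfig(n_total=300, seed=6))
        test = apply_test_condition(pool, "aligned")
        assert set(test.datasets[0].available) == {"V2", "V3", "V5", "V6", "V8", "V9"}
        assert set(test.datasets[1].available) == {"V1", "V3", "V4", "V6", "V7", "V9"}

    def test_union_of_availabilities_covers_the_catalog(self):
        pool = simulate_control(SigmaSpec(0.75, 0.5), StudyConfig(n_total=300, seed=6))
        test = apply_test_condition(pool)
        union = set().union(*(set(ds.available) for ds in test.datasets))
        assert union == set(test.catalog.measure_ids)


class TestCaseStatus:
    def test_threshold_at_one_population_sd(self):
        pool = simulate_control(SigmaSpec(0.75, 0.5), StudyConfig(n_total=300, seed=9))
        labels = make_case_status(pool)
        v1 = pool.concat()["V1"]
        assert (labels == (v1 > 1.0).astype(int)).all()

    def test_case_fraction_near_the_normal_tail_mass(self):
        pool = simulate_control(SigmaSpec(0.75, 0.5), StudyConfig(n_total=3000, seed=10))
        expected = sps.norm.sf(1.0)  # upper-tail mass above one SD
        assert make_case_status(pool).mean() == pytest.approx(expected, abs=0.02)

    def test_all_negative_column_yields_no_cases(self, catalog9):
        import pandas as pd

        from tests.conftest import make_pool

        frame = pd.DataFrame(
            -np.abs(np.random.default_rng(0).standard_normal((10, 9))),
            columns=list(catalog9.measure_ids), index=[f"s{i}" for i in range(10)])
        pool = make_pool({"a": frame}, catalog9)
        assert make_case_status(pool).sum() == 0


class TestStudy2Preset:
    def test_reported_between_trait_correlations(self):
        spec = study2_preset()
        np.testing.assert_array_equal(spec.between, (0.952, 0.741, 0.763))
        assert "approximate" in spec.note

    def test_implied_matrix_is_positive_semidefinite(self):
        S = build_sigma(study2_preset())
        assert np.linalg.eigvalsh(S).min() >= -1e-10
        # trait-level between: measure-level cross entries are within * between
        assert S[0, 3] == pytest.approx(0.75 * 0.952)


    def test_harmonization_recovers_the_identifiable_structure(self):
        """With the first two traits correlated at 0.952 they sit at the edge
        of rotational identifiability, so the check targets what the data can
        support: the two best-determined traits track their complete-data
        counterparts, and the score sets share two near-perfect canonical
        dimensions."""
        from scipy.linalg import svd

        from rosetta import ExtractionConfig, apply_test_condition, harmonize
        from rosetta.benchmark import score_correlation_table

        control = simulate_control(study2_preset(), StudyConfig(n_total=3000, seed=11))
        test = apply_test_condition(control)
        ecfg = ExtractionConfig(k=3)
        ts, full = harmonize(test, ecfg), harmonize(control, ecfg)
        tab = score_correlation_table(ts, full)
        assert sorted(tab.diagonal)[1] > 0.9  # two of three diagonals
        X = ts.scores().loc[full.scores().index].to_numpy()
        Y = full.scores().to_numpy()
        qx, _ = np.linalg.qr(X - X.mean(0))
        qy, _ = np.linalg.qr(Y - Y.mean(0))
        canonical = svd(qx.T @ qy, compute_uv=False)
        assert canonical[1] > 0.9


def test_written_csvs_read_back_as_the_same_pool(tmp_path):
    pool = simulate_control(SigmaSpec(0.75, 0.5), StudyConfig(n_total=90, seed=2))
    test = apply_test_condition(pool)
    write_study_csvs(test, tmp_path, truth_pool=pool)
    back = read_pool(sorted(tmp_path.glob("study*.csv")), tmp_path / "catalog.csv")
    assert len(back.datasets) == 3
    for orig, re_read in zip(test.datasets, back.datasets):
        np.testing.assert_allclose(re_read.values.to_numpy(), orig.values.to_numpy(),
                                   atol=1e-12)
    assert back.catalog.domain_of == test.catalog.domain_of
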