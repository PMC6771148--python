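import numpy as np
import pandas as pd
import pytest

from rosetta import (
    DataPool,
    Dataset,
    MethodFailure,
    SigmaSpec,
    StudyConfig,
    apply_test_condition,
    make_case_status,
    run_imputation,
    run_meta,
    run_rosetta_test,
    run_truth,
    score_correlation_table,
    simulate_control,
)
from rosetta.benchmark import BenchmarkResult, match_factors_to_domains, power_grid


@pytest.fixture(scope="module")
def replicate():
    spec = SigmaSpec(rho_within=0.75, rho_between=0.4)
    control = simulate_control(spec, StudyConfig(n_total=900, seed=17))
    labels = make_case_status(control)
    test = apply_test_condition(control)
    return control, test, labels


class TestScoreCorrelationTable:
    def test_self_comparison_is_the_identity_diagonal(self, study1_run):
        tab = score_correlation_table(study1_run["full_scores"], study1_run["full_scores"])
        np.testing.assert_allclose(tab.diagonal, 1.0, atol=1e-12)

    def test_off_diagonals_match_full_data_trait_intercorrelations(self, study1_run):
        """The harmonized factors must remain three distinct traits: their
        cross-correlations with the full-data scores sit near the full-data
        trait intercorrelations, far from 1."""
        tab = score_correlation_table(study1_run["test_scores"], study1_run["full_scores"])
        full = study1_run["full_scores"].scores().to_numpy()
        inter = np.corrcoef(full.T)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(tab.matrix[off], inter[off], atol=0.06)
        assert np.abs(tab.matrix[off]).max() < 0.9

    def test_subject_mismatch_rejected(self, study1_run):
        from dataclasses import replace

        full = study1_run["full_scores"]
        truncated = replace(full, frame=full.frame.iloc[:-5])
        with pytest.raises(Exception, match="mismatch"):
            score_correlation_table(study1_run["test_scores"], truncated)


class TestFactorDomainMatching:
    def test_each_domain_gets_the_factor_loading_on_its_measures(self, study1_run):
        scores = study1_run["test_scores"]
        assignment = match_factors_to_domains(scores, study1_run["test"])
        ids = list(scores.model.measure_ids)
        for d, cols in (("A", ["V1", "V2", "V3"]), ("B", ["V4", "V5", "V6"]),
                        ("C", ["V7", "V8", "V9"])):
            idx = [ids.index(m) for m in cols]
            mass = np.abs(scores.model.Lambda[idx]).sum(axis=0)
            assert assignment[d] == int(np.argmax(mass))


class TestTruth:
    def test_detects_the_induced_group_difference(self, replicate):
        control, _, labels = replicate
        assert run_truth(control, labels) < 1e-6

    def test_all_control_labels_fail(self, replicate):
        control, _, labels = replicate
        with pytest.raises(MethodFailure):
            run_truth(control, labels * 0)


class TestMeta:
    def test_single_contributing_study_equals_that_study_p(self, replicate):
        control, test, labels = replicate
        from scipy import stats as sps

        # keep V7 in one study only
        datasets = []
        for i, ds in enumerate(test.datasets):
            vals = ds.values.drop(columns=["V7"], errors="ignore") if i != 1 else ds.values
            datasets.append(Dataset(ds.dataset_id, vals))
        pool = DataPool(catalog=test.catalog, datasets=datasets)
        p = run_meta(pool, labels)
        ds = pool.datasets[1]
        lab = labels.reindex(ds.subjects)
        y = ds.values["V7"]
        diff = y[lab == 1].mean() - y[lab == 0].mean()
        se = np.sqrt(y[lab == 1].var(ddof=1) / (lab == 1).sum()
                     + y[lab == 0].var(ddof=1) / (lab == 0).sum())
        expected = 2 * sps.norm.sf(abs(diff / se))
        assert p == pytest.approx(expected, rel=1e-12)

    def test_fixed_effect_pooling_closed_form(self, replicate):
        """Two equal-n studies with equal effects: the pooled estimate is the
        mean difference and its SE shrinks by sqrt(2); cross-checked against
        statsmodels' inverse-variance combination."""
        control, test, labels = replicate
        from scipy import stats as sps
        from statsmodels.stats.meta_analysis import combine_effects

        effects, variances = [], []
        for ds in test.datasets:
            if "V7" not in ds.available:
                continue
            y = ds.values["V7"]
            lab = labels.reindex(ds.subjects)
            effects.append(y[lab == 1].mean() - y[lab == 0].mean())
            variances.append(y[lab == 1].var(ddof=1) / (lab == 1).sum()
                             + y[lab == 0].var(ddof=1) / (lab == 0).sum())
        w = 1 / np.asarray(variances)
        pooled = np.sum(w * effects) / w.sum()
        se = np.sqrt(1 / w.sum())
        sm = combine_effects(np.asarray(effects), np.asarray(variances)).summary_frame()
        assert sm.loc["fixed effect", "eff"] == pytest.approx(pooled, rel=1e-10)
        assert sm.loc["fixed effect", "sd_eff"] == pytest.approx(se, rel=1e-10)
        assert run_meta(test, labels) == pytest.approx(
            2 * sps.norm.sf(abs(pooled / se)), rel=1e-10)
        # equal-n, equal-effect algebra on synthetic inputs
        v = np.array([0.1, 0.1])
        wts = 1 / v
        assert np.sum(wts * np.array([0.5, 0.5])) / wts.sum() == pytest.approx(0.5)
        assert np.sqrt(1 / wts.sum()) == pytest.approx(np.sqrt(0.1) / np.sqrt(2))


class TestImputation:
    def test_no_missing_data_reduces_to_the_complete_data_test(self, replicate):
        control, _, labels = replicate
        assert run_imputation(control, labels, seed=1) == run_truth(control, labels)

    def test_imputed_outcome_recovers_held_out_truth(self, replicate):
        """Masking experiment: the imputed values of the deleted outcome
        column reproduce the held-out truth's location and scale."""
        control, test, labels = replicate
        from rosetta.benchmark import _chained_normal_imputation

        big = test.concat()
        X = big.to_numpy()
        completed = _chained_normal_imputation(X, m=5, iters=50,
                                               rng=np.random.default_rng(3))
        j = list(big.columns).index("V7")
        mask = np.isnan(X[:, j])
        truth = control.concat().loc[big.index, "V7"].to_numpy()[mask]
        # pool the draws across imputations (averaging them would shrink the SD)
        imputed = np.concatenate([Xc[mask, j] for Xc in completed])
        assert np.mean(imputed) == pytest.approx(np.mean(truth), abs=0.1)
        assert np.std(imputed) == pytest.approx(np.std(truth), abs=0.1)

    def test_detects_the_group_difference_from_imputed_data(self, replicate):
        _, test, labels = replicate
        assert run_imputation(test, labels, seed=2) < 1e-4


class TestRosettaMethod:
    def test_detects_the_group_difference_via_factor_scores(self, replicate):
        _, test, labels = replicate
        assert run_rosetta_test(test, labels) < 1e-6

    def test_weak_structure_surfaces_as_method_failure(self):
        spec = SigmaSpec(rho_within=0.1, rho_between=0.05)
        control = simulate_control(spec, StudyConfig(n_total=900, seed=8))
        labels = make_case_status(control)
        test = apply_test_condition(control)
        with pytest.raises(MethodFailure):
            run_rosetta_test(test, labels)


class TestPowerGrid:
    def test_failures_count_as_non_rejections(self):
        cfg = StudyConfig(n_total=300, seed=5, replicates=3)
        table, results = power_grid([0.1], [0.05], cfg, methods=("rosetta",))
        cell = results[(0.1, 0.05)]["rosetta"]
        assert cell.failures == 3
        assert cell.power == 0.0
        assert table["Rosetta-c"].iloc[0] == 0.0

    def test_power_accounting(self):
        r = BenchmarkResult(method="x", alpha=0.05,
                            replicate_pvalues=[0.01, 0.2, float("nan"), 0.04])
        assert r.failures == 1
        assert r.power == pytest.approx(2 / 4)

    def test_grid_is_deterministic_given_seed(self):
        cfg = StudyConfig(n_total=300, seed=9, replicates=2)
        t1, _ = power_grid([0.75], [0.3], cfg, methods=("truth", "meta"))
        t2, _ = power_grid([0.75], [0.3], cfg, methods=("truth", "meta"))
        pd.testing.assert_frame_equal(t1, t2)
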