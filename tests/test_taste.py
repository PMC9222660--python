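import numpy as np
import pytest

from aslt.datamodel import ETongueProfile, PeriodBoundaries, PeriodLabel
from aslt.errors import DegenerateFitError, DomainError, InsufficientDataError
from aslt.synth import SimulationConfig, gen_etongue_study
from aslt.taste import (
    FisherDiscriminant,
    accuracy_table,
    label_periods,
    run_fda,
    run_pca,
)

B45 = PeriodBoundaries(318.15, 28.0, 56.0, 84.0)
B35 = PeriodBoundaries(308.15, 42.0, 126.0, 154.0)


def profile(i, values, day=0.0, temp=318.15):
    names = [f"a{j}" for j in range(len(values))]
    return ETongueProfile(f"s{i}", temp, day, dict(zip(names, values)))


def cluster_profiles(centers, n_per=8, sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    profiles, labels = [], []
    for c, center in enumerate(centers):
        for i in range(n_per):
            vals = np.asarray(center) + sd * rng.standard_normal(len(center))
            profiles.append(profile(f"{c}_{i}", vals))
            labels.append(PeriodLabel(c))
    return profiles, labels


class TestLabelPeriods:
    @pytest.mark.parametrize(
        "day,bounds,expected",
        [
            (0, B45, PeriodLabel.FULLY_ACCEPTABLE),
            (28, B45, PeriodLabel.FULLY_ACCEPTABLE),
            (30, B45, PeriodLabel.ACCEPTABLE),
            (56, B45, PeriodLabel.ACCEPTABLE),
            (84, B45, PeriodLabel.UNACCEPTABLE),
            (140, B35, PeriodLabel.UNACCEPTABLE),
        ],
    )
    def test_boundary_mapping(self, day, bounds, expected):
        assert label_periods(day, bounds) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            label_periods(85.0, B45)
        with pytest.raises(DomainError):
            label_periods(-1.0, B45)

    def test_partition_is_exhaustive_and_exclusive(self):
        days = np.linspace(0.0, B45.b3, 337)
        labels = [label_periods(d, B45) for d in days]
        assert all(isinstance(l, PeriodLabel) for l in labels)
        # labels are non-decreasing in storage time
        assert all(a <= b for a, b in zip(labels, labels[1:]))


class TestPCA:
    def test_collinear_samples_put_all_variance_on_pc1(self):
        pts = [profile(i, [v, 2 * v]) for i, v in enumerate([1.0, 2.0, 3.0, 4.0])]
        res = run_pca(pts, standardize=False)
        assert res.explained_pct[0] == pytest.approx(100.0)
        assert res.explained_pct[1] == pytest.approx(0.0, abs=1e-9)

    def test_explained_shares_match_eigen_oracle(self):
        profiles, _ = gen_etongue_study(SimulationConfig(seed=7))
        res = run_pca(profiles)
        x = np.vstack([p.vector(res.attribute_names) for p in profiles])
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(z.T)))[::-1]
        np.testing.assert_allclose(
            res.explained_pct, 100.0 * eigvals / eigvals.sum(), atol=1e-8
        )
        assert res.explained_pct[:2].sum() >= 80.0

    def test_loadings_orthonormal_and_shares_sum_to_100(self):
        profiles, _ = gen_etongue_study(SimulationConfig(seed=7))
        res = run_pca(profiles)
        np.testing.assert_allclose(
            res.loadings.T @ res.loadings, np.eye(res.loadings.shape[1]), atol=1e-9
        )
        assert res.explained_pct.sum() == pytest.approx(100.0)
        assert np.all(np.diff(res.explained_pct) <= 1e-9)

    def test_sample_permutation_leaves_shares_unchanged(self):
        profiles, _ = gen_etongue_study(SimulationConfig(seed=7))
        res1 = run_pca(profiles)
        rng = np.random.default_rng(0)
        res2 = run_pca([profiles[i] for i in rng.permutation(len(profiles))])
        np.testing.assert_allclose(res1.explained_pct, res2.explained_pct, atol=1e-9)

    def test_constant_attribute_rejected_under_standardization(self):
        pts = [profile(i, [v, 1.0]) for i, v in enumerate([1.0, 2.0, 3.0])]
        with pytest.raises(DegenerateFitError):
            run_pca(pts)


class TestFDA:
    def test_well_separated_clusters_classified_perfectly(self):
        profiles, labels = cluster_profiles(
            [(0, 0, 0), (3, 3, 0), (0, 3, 3)], sd=0.1
        )
        res = run_fda(profiles, labels, seed=1)
        assert res.calibration_accuracy_pct == 100.0
        assert res.prediction_accuracy_pct == 100.0

    def test_perfect_separation_across_100_seeds(self):
        profiles, labels = cluster_profiles(
            [(0, 0, 0), (6, 6, 0), (0, 6, 6)], sd=1.0, seed=3
        )
        for seed in range(100):
            res = run_fda(profiles, labels, seed=seed)
            assert res.calibration_accuracy_pct == 100.0
            assert res.prediction_accuracy_pct == 100.0

    def test_matches_sklearn_pooled_covariance_oracle(self):
        """Predictions agree exactly with sklearn's LDA (lsqr solver, pooled
        covariance, proportional priors) on overlapping clusters."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        profiles, labels = cluster_profiles(
            [(0.0, 0.0), (1.0, 0.8), (0.5, 1.5)], n_per=12, sd=0.7, seed=11
        )
        x = np.vstack([p.vector() for p in profiles])
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        y = np.array([int(l) for l in labels])
        res = run_fda(profiles, labels, seed=11)
        lda = LinearDiscriminantAnalysis(solver="lsqr").fit(
            x[res.train_indices], y[res.train_indices]
        )
        own = FisherDiscriminant().fit(x[res.train_indices], y[res.train_indices])
        np.testing.assert_array_equal(
            own.predict(x[res.test_indices]), lda.predict(x[res.test_indices])
        )
        oracle_pred_acc = 100.0 * np.mean(
            lda.predict(x[res.test_indices]) == y[res.test_indices]
        )
        assert res.prediction_accuracy_pct == pytest.approx(oracle_pred_acc)

    def test_class_renaming_preserves_overall_accuracy(self):
        profiles, labels = cluster_profiles(
            [(0.0, 0.0), (1.0, 0.8), (0.5, 1.5)], n_per=10, sd=0.6, seed=5
        )
        res = run_fda(profiles, labels, seed=2)
        relabeled = [PeriodLabel(2 - int(l)) for l in labels]
        res2 = run_fda(profiles, relabeled, seed=2)
        assert res2.calibration_accuracy_pct == pytest.approx(
            res.calibration_accuracy_pct
        )

    def test_split_sizes_match_two_thirds_rule(self):
        profiles, labels = cluster_profiles([(0, 0), (4, 4), (0, 4)], n_per=13)
        res = run_fda(profiles, labels, seed=0)
        assert len(res.train_indices) == 27  # round(2/3 · 13) = 9 per class
        assert len(res.test_indices) == 12
        assert not set(res.train_indices) & set(res.test_indices)

    def test_tiny_class_rejected(self):
        profiles, labels = cluster_profiles([(0, 0), (4, 4)], n_per=2)
        with pytest.raises(InsufficientDataError):
            run_fda(profiles, labels, train_fraction=0.5, seed=0)


class TestAccuracyTable:
    def test_layout_totals_and_percentages(self):
        profiles, labels = cluster_profiles(
            [(0, 0, 0), (6, 6, 0), (0, 6, 6)], n_per=12, sd=0.5
        )
        res = run_fda(profiles, labels, seed=0)
        table = accuracy_table(res)
        cal = table[table["block"] == "calibration"]
        total_row = cal[cal["class"] == "Total"].iloc[0]
        assert total_row["total"] == len(res.train_indices)
        assert total_row["correctly_classified_pct"] == 100.0
        # per-class rows sum to the total
        assert cal[cal["class"] != "Total"]["total"].sum() == total_row["total"]

    def test_partial_accuracy_rendered(self):
        res = run_fda(
            *cluster_profiles([(0.0, 0.0), (0.5, 0.5)], n_per=10, sd=1.0, seed=9),
            seed=4,
        )
        table = accuracy_table(res)
        pred_total = table[
            (table["block"] == "prediction") & (table["class"] == "Total")
        ].iloc[0]
        assert pred_total["correctly_classified_pct"] == pytest.approx(
            res.prediction_accuracy_pct, abs=0.01
        )
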