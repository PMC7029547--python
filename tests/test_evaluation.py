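import numpy as np
import pytest

from grlnmf.dataio import AssociationMatrix, SyntheticScenario, generate_synthetic
from grlnmf.evaluation import (
    PipelineConfig,
    five_fold_cv,
    global_loocv,
    roc_auc,
    run_pipeline,
    top_candidates,
)
from grlnmf.factorization import NMFConfig
from grlnmf.similarity import gip_kernel_from_associations
from grlnmf.wknkn import WknknConfig


def brute_force_auc(scores, labels):
    """Mann-Whitney oracle: fraction of positive-negative pairs won, ties = 1/2."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def small_config(seed=0, rank=4):
    return PipelineConfig(
        wknkn=WknknConfig(n_neighbors=3, decay=0.7),
        nmf=NMFConfig(rank=rank, max_iter=150, tol=1e-7, seed=seed),
    )


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_perfect_inversion(self):
        auc, _ = roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert auc == 0.0

    def test_hand_mixed_case(self):
        auc, _ = roc_auc([0.9, 0.8, 0.7], [1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="AUC undefined"):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pair_count_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(500):
            n = int(rng.integers(2, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # coarse grid forces plenty of ties
            scores = rng.integers(0, 5, size=n) / 4.0
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        for _ in range(20):
            labels = rng.integers(0, 2, size=80)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.normal(size=80).round(1)
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_negation_flips_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        auc, _ = roc_auc(scores, labels)
        flipped, _ = roc_auc(-scores, labels)
        assert auc == pytest.approx(1 - flipped, abs=1e-12)

    def test_roc_points_monotone_and_trapz_consistent(self):
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 4, size=60) / 3.0
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        auc, roc = roc_auc(scores, labels)
        assert tuple(roc[0]) == (0.0, 0.0)
        assert tuple(roc[-1]) == (1.0, 1.0)
        assert (np.diff(roc[:, 0]) >= 0).all() and (np.diff(roc[:, 1]) >= 0).all()
        assert auc == pytest.approx(np.trapezoid(roc[:, 1], roc[:, 0]), abs=1e-9)


@pytest.fixture(scope="module")
def planted():
    scenario = SyntheticScenario(n=20, m=15, rank=3, density=0.1, noise_sd=0.0, seed=7)
    return generate_synthetic(scenario)


class TestRunPipeline:
    def test_deterministic(self, planted):
        assoc, sm, sd, _ = planted
        s1 = run_pipeline(assoc.values, sm, sd, small_config())
        s2 = run_pipeline(assoc.values, sm, sd, small_config())
        np.testing.assert_array_equal(s1, s2)

    def test_masking_changes_gip(self, planted):
        # leakage check: training similarities really are recomputed
        assoc, *_ = planted
        Y = assoc.values
        i, j = np.argwhere(Y == 1)[0]
        Y_masked = Y.copy()
        Y_masked[i, j] = 0
        gd_full = gip_kernel_from_associations(Y, "disease")
        gd_masked = gip_kernel_from_associations(Y_masked, "disease")
        assert not np.allclose(gd_full, gd_masked)

    def test_zero_rows_handled(self, planted):
        assoc, sm, sd, _ = planted
        Y = assoc.values.copy()
        Y[0, :] = 0  # miRNA with no known association
        scores = run_pipeline(Y, sm, sd, small_config())
        assert np.isfinite(scores).all()


class TestGlobalLoocv:
    def test_planted_signal_recovered(self, planted):
        assoc, sm, sd, _ = planted
        report = global_loocv(assoc.values, sm, sd, small_config(), seed=0)
        assert report.auc > 0.9

    def test_subsample_accounting_and_errors(self, planted):
        assoc, sm, sd, _ = planted
        report = global_loocv(assoc.values, sm, sd, small_config(),
                              subsample=10, seed=0)
        assert report.manifest["n_tested"] == 10
        assert report.manifest["n_known"] == assoc.n_known
        with pytest.raises(ValueError, match="subsample"):
            global_loocv(assoc.values, sm, sd, small_config(),
                         subsample=assoc.n_known + 1)

    def test_improves_as_noise_decreases(self):
        aucs = []
        for noise in (0.5, 0.2, 0.0):
            scenario = SyntheticScenario(n=20, m=15, rank=3, density=0.1,
                                         noise_sd=noise, seed=7)
            assoc, sm, sd, _ = generate_synthetic(scenario)
            report = global_loocv(assoc.values, sm, sd, small_config(),
                                  subsample=15, seed=1)
            aucs.append(report.auc)
        assert aucs[0] < aucs[1] < aucs[2]

    def test_degenerate_tied_scores_no_crash(self):
        Y = np.zeros((6, 5))
        Y[[0, 1, 2], [0, 1, 2]] = 1
        sm = np.eye(6)
        sd = np.eye(5)
        config = PipelineConfig(
            wknkn=WknknConfig(n_neighbors=1),
            nmf=NMFConfig(rank=2, max_iter=5, seed=0))
        report = global_loocv(Y, sm, sd, config, seed=0)
        assert 0.0 <= report.auc <= 1.0


class TestFiveFoldCv:
    def test_fold_assignments_deterministic(self, planted):
        assoc, sm, sd, _ = planted
        r1 = five_fold_cv(assoc.values, sm, sd, small_config(), repeats=2, seed=4)
        r2 = five_fold_cv(assoc.values, sm, sd, small_config(), repeats=2, seed=4)
        for a, b in zip(r1.plan.fold_assignments, r2.plan.fold_assignments):
            np.testing.assert_array_equal(a, b)
        assert r1.per_fold_auc == r2.per_fold_auc

    def test_fold_sizes_differ_by_at_most_one(self, planted):
        assoc, sm, sd, _ = planted
        report = five_fold_cv(assoc.values, sm, sd, small_config(), repeats=1, seed=0)
        sizes = np.bincount(report.plan.fold_assignments[0], minlength=5)
        assert sizes.sum() == assoc.n_known
        assert sizes.max() - sizes.min() <= 1
        # each known pair in exactly one fold per repeat
        assert len(report.plan.fold_assignments[0]) == assoc.n_known

    def test_exact_multiple_splits_evenly(self):
        # 5430 = 5 * 1086: the partition rule gives five equal folds
        parts = np.array_split(np.arange(5430), 5)
        assert [len(p) for p in parts] == [1086] * 5

    def test_consistent_with_loocv_on_planted_fixture(self, planted):
        assoc, sm, sd, _ = planted
        loocv_report = global_loocv(assoc.values, sm, sd, small_config(), seed=0)
        cv_report = five_fold_cv(assoc.values, sm, sd, small_config(),
                                 repeats=5, seed=0)
        assert abs(cv_report.auc - loocv_report.auc) < 0.05

    def test_no_refold_variant_runs(self, planted):
        assoc, sm, sd, _ = planted
        report = five_fold_cv(assoc.values, sm, sd, small_config(),
                              repeats=1, seed=0, refold=False)
        assert 0.0 <= report.auc <= 1.0
        assert report.manifest["refold"] is False


class TestTopCandidates:
    def make_assoc(self):
        Y = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        return AssociationMatrix(Y, mirna_ids=["mA", "mB", "mC"],
                                 disease_ids=["d0", "d1"])

    def test_ranked_by_score(self):
        assoc = self.make_assoc()
        scores = np.array([[0.0, 0.3], [0.0, 0.9], [0.0, 0.1]])
        assert top_candidates(scores, assoc, "d1", 2) == [("mB", 0.9), ("mA", 0.3)]

    def test_known_pairs_excluded(self):
        assoc = self.make_assoc()
        scores = np.ones((3, 2))
        names = [m for m, _ in top_candidates(scores, assoc, "d0", 5)]
        assert names == ["mB", "mC"]  # mA is already known for d0

    def test_ties_broken_by_id(self):
        assoc = self.make_assoc()
        scores = np.full((3, 2), 0.5)
        assert [m for m, _ in top_candidates(scores, assoc, "d1", 2)] == ["mA", "mB"]

    def test_unknown_disease(self):
        with pytest.raises(KeyError):
            top_candidates(np.ones((3, 2)), self.make_assoc(), "nope")
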