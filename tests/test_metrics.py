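import itertools

import numpy as np
import pytest
from sklearn.metrics import homogeneity_completeness_v_measure

from scmethclust.metrics import (
    coclustering,
    epigenotype_hamming,
    evaluate_result,
    match_clusters,
    prevalence_mae,
    uncertainty_tpr,
    v_measure,
)
from scmethclust.model import fit_mixture
from scmethclust.simulate import simulate_dataset


# ----------------------------------------------------------------------
# V-measure
# ----------------------------------------------------------------------

class TestVMeasure:
    def test_perfect_clustering_up_to_relabeling(self):
        truth = ["a", "a", "b", "b", "c"]
        pred = [2, 2, 0, 0, 1]
        h, c, v = v_measure(truth, pred)
        assert (h, c, v) == (1.0, 1.0, 1.0)

    def test_single_cluster_prediction_zero(self):
        h, c, v = v_measure(["a", "a", "b", "b"], [1, 1, 1, 1])
        assert h == 0.0
        assert v == 0.0

    def test_partial_split_matches_entropy_bruteforce(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.array([1, 1, 1, 2])
        h, c, v = v_measure(truth, pred)
        # brute-force entropy tables
        def entropy(labels):
            _, counts = np.unique(labels, return_counts=True)
            p = counts / counts.sum()
            return -(p * np.log(p)).sum()

        def cond_entropy(a, b):
            out = 0.0
            for vb in np.unique(b):
                sel = b == vb
                out += sel.mean() * entropy(a[sel])
            return out

        h_exp = 1 - cond_entropy(truth, pred) / entropy(truth)
        c_exp = 1 - cond_entropy(pred, truth) / entropy(pred)
        assert h == pytest.approx(h_exp)
        assert c == pytest.approx(c_exp)
        assert v == pytest.approx(2 * h_exp * c_exp / (h_exp + c_exp))

    def test_matches_reference_implementation_on_random_partitions(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 13))
            truth = rng.integers(0, 4, size=n)
            pred = rng.integers(0, 4, size=n)
            h, c, v = v_measure(truth, pred)
            h2, c2, v2 = homogeneity_completeness_v_measure(truth, pred)
            assert h == pytest.approx(h2, abs=1e-12)
            assert c == pytest.approx(c2, abs=1e-12)
            assert v == pytest.approx(v2, abs=1e-12)

    def test_permutation_invariance(self, rng):
        truth = rng.integers(0, 3, size=20)
        pred = rng.integers(0, 3, size=20)
        v0 = v_measure(truth, pred)[2]
        perm = {0: 2, 1: 0, 2: 1}
        assert v_measure(
            [perm[t] for t in truth], [perm[p] for p in pred]
        )[2] == pytest.approx(v0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            v_measure([1, 2], [1])


# ----------------------------------------------------------------------
# prevalence MAE
# ----------------------------------------------------------------------

class TestPrevalenceMae:
    def test_identical_partitions_zero(self):
        labels = [0, 0, 1, 2, 2]
        assert prevalence_mae(labels, labels) == 0.0

    def test_collapsed_prediction_half(self):
        # truth (1/2, 1/2) vs a single predicted cluster:
        # matched pairs (1/2, 1) and (1/2, 0) -> MAE 1/2
        assert prevalence_mae([0, 0, 1, 1], [5, 5, 5, 5]) == pytest.approx(0.5)

    def test_invariant_to_relabeling(self, rng):
        truth = rng.integers(0, 3, size=30)
        pred = rng.integers(0, 4, size=30)
        base = prevalence_mae(truth, pred)
        assert prevalence_mae(truth, (pred + 7) % 11) == pytest.approx(base)

    def test_range_and_bruteforce_matching(self, rng):
        """The Hungarian matching attains the exhaustive-best overlap."""
        for _ in range(20):
            n = int(rng.integers(3, 13))
            truth = rng.integers(0, 3, size=n)
            pred = rng.integers(0, 3, size=n)
            mae = prevalence_mae(truth, pred)
            assert 0 <= mae <= 1
            # exhaustive maximum-overlap matchings
            tu, tc = np.unique(truth, return_counts=True)
            pu, pc = np.unique(pred, return_counts=True)
            T, P = len(tu), len(pu)
            C = np.zeros((T, P), dtype=int)
            for t, p in zip(truth, pred):
                C[np.searchsorted(tu, t), np.searchsorted(pu, p)] += 1
            size = max(T, P)
            best_overlap = -1
            best_maes = set()
            for perm in itertools.permutations(range(size)):
                overlap = sum(
                    C[i, perm[i]] for i in range(T) if perm[i] < P
                )
                errs = []
                matched_p = set()
                for i in range(size):
                    ft = tc[i] / n if i < T else 0.0
                    fp = pc[perm[i]] / n if perm[i] < P else 0.0
                    errs.append(abs(ft - fp))
                    matched_p.add(perm[i])
                if overlap > best_overlap:
                    best_overlap = overlap
                    best_maes = {round(float(np.mean(errs)), 12)}
                elif overlap == best_overlap:
                    best_maes.add(round(float(np.mean(errs)), 12))
            assert round(mae, 12) in best_maes


def test_match_clusters_pads_with_phantoms():
    pairs = match_clusters([0, 0, 1, 1], [3, 3, 3, 3])
    matched_true = {t for t, p in pairs if p is not None}
    assert len(matched_true) == 1
    assert any(p is None for _t, p in pairs)


# ----------------------------------------------------------------------
# Hamming distance
# ----------------------------------------------------------------------

class TestHamming:
    def test_identical_zero(self):
        a = np.array([[1, 0, 1]])
        assert epigenotype_hamming(a, a) == 0.0

    def test_single_discordance_proportion(self):
        a = np.zeros((2, 5), dtype=int)
        b = a.copy()
        b[0, 0] = 1
        assert epigenotype_hamming(a, b) == pytest.approx(1 / 10)

    def test_empty_mask_undefined(self):
        a = np.zeros((2, 2), dtype=int)
        assert np.isnan(epigenotype_hamming(a, a, mask=np.zeros((2, 2), bool)))

    def test_naive_can_differ_from_unadjusted(self):
        """Majority vote among cluster-mates and the state posterior can
        disagree: three cells, one cluster, a column observed (1, 1, 0)
        but with the model's error channel trusting a different column
        pattern."""
        X = np.array(
            [[1, 1], [1, np.nan], [0, np.nan]], dtype=float
        )
        res = fit_mixture(X, 1, init=np.zeros(3, dtype=int), max_iters=50)
        naive = res.impute("naive")
        unadj = res.impute("unadjusted")
        # both are valid completions; they agree on observed entries
        obs = np.isfinite(X)
        np.testing.assert_array_equal(naive[obs], unadj[obs])


# ----------------------------------------------------------------------
# uncertainty TPR
# ----------------------------------------------------------------------

class TestUncertaintyTpr:
    def _ambiguous_dataset(self):
        """Cell 0 observes only loci shared by clusters 0 and 1."""
        ds = simulate_dataset(n_cells=12, n_loci=60, n_regions=6,
                              n_clusters=2, missing_prop=0.0, seed=21)
        shared = np.where(
            ds.cluster_epigenotypes[0] == ds.cluster_epigenotypes[1]
        )[0]
        vals = ds.observed.values.copy()
        mask = np.ones(60, dtype=bool)
        mask[shared[:10]] = False
        vals[0, mask] = -1
        ds.observed.values = vals
        return ds

    def test_restricted_profile_equality_marks_ambiguous(self):
        ds = self._ambiguous_dataset()
        resp = np.zeros((12, 2))
        resp[:, 0] = 1.0  # fully confident everywhere
        assert uncertainty_tpr(ds, resp) == 0.0
        resp[0] = [0.5, 0.5]  # flag the ambiguous cell
        assert uncertainty_tpr(ds, resp) == 1.0

    def test_no_ambiguous_cells_undefined(self):
        ds = simulate_dataset(n_cells=10, n_loci=40, n_regions=4,
                              n_clusters=2, missing_prop=0.0, seed=22)
        resp = np.tile([0.5, 0.5], (10, 1))
        if np.isnan(uncertainty_tpr(ds, resp)):
            assert True
        else:  # all cells happen to be distinguishable
            assert 0 <= uncertainty_tpr(ds, resp) <= 1


# ----------------------------------------------------------------------
# co-clustering table
# ----------------------------------------------------------------------

class TestCoclustering:
    def test_perfect_agreement_permutation_of_100s(self):
        table = coclustering(["a", "a", "b"], [1, 1, 0])
        assert sorted(np.asarray(table).max(axis=1)) == [100.0, 100.0]
        assert np.asarray(table).sum() == pytest.approx(200.0)

    def test_rows_sum_to_100(self, rng):
        truth = rng.integers(0, 4, size=50)
        pred = rng.integers(0, 3, size=50)
        table = coclustering(truth, pred)
        np.testing.assert_allclose(np.asarray(table).sum(axis=1), 100.0,
                                   atol=1e-6)

    def test_counting_example(self):
        table = coclustering(["a", "a", "b", "b"], [1, 2, 2, 2])
        assert table.loc["a"].tolist() == [50.0, 50.0]
        assert table.loc["b"].tolist() == [0.0, 100.0]


def test_evaluate_result_assembles_full_report(small_dataset):
    res = fit_mixture(small_dataset.observed, 3,
                      init=small_dataset.true_labels)
    report = evaluate_result(small_dataset, res)
    d = report.to_dict()
    assert set(d) >= {
        "homogeneity", "completeness", "v_measure", "predicted_k",
        "prevalence_mae", "uncertainty_tpr", "hamming_unadjusted",
        "hamming_adjusted", "hamming_naive",
    }
    assert 0 <= d["v_measure"] <= 1
    assert report.coclustering.shape[0] == len(
        np.unique(small_dataset.true_labels)
    )
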