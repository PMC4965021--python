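"""Watershed cluster detection and meta-measure aggregation."""

import numpy as np
import pandas as pd
import pytest

import bodyatlas as ba
from bodyatlas.features import ClusterError, _clockwise_order, ClusterAssignment

from conftest import make_table


def flood_fill_oracle(dmap, seeds):
    """Brute-force basin segmentation: grow each seed to every unit whose
    steepest-descent path (strictly-lower neighbor of minimum value) reaches
    that seed. Independent of the implementation's path compression."""
    h, w = dmap.shape
    label = -np.ones((h, w), dtype=int)

    def descend(r, c):
        while True:
            best, arg = dmap[r, c], None
            for rr, cc in ((r-1,c),(r+1,c),(r,c-1),(r,c+1)):
                if 0 <= rr < h and 0 <= cc < w and dmap[rr, cc] < best:
                    best, arg = dmap[rr, cc], (rr, cc)
            if arg is None:
                return (r, c)
            r, c = arg

    for i, s in enumerate(seeds):
        for r in range(h):
            for c in range(w):
                if descend(r, c) == s:
                    label[r, c] = i
    return label


class TestDetectClusters:
    def test_flat_map_single_cluster(self):
        dmap = np.ones((5, 5))
        bmu = np.array([[0, 0], [2, 2], [4, 4], [1, 3]])
        a = ba.detect_clusters(dmap, bmu)
        assert a.n_clusters == 1
        assert (a.item_labels == a.item_labels[0]).all()

    def test_two_basin_hand_map_matches_flood_fill(self):
        """6x6 map: two basins with smooth gradients toward their minima,
        split by a high ridge column; membership must equal the brute-force
        flood fill from the two minima."""
        rr, cc = np.mgrid[0:6, 0:6]
        left = 1.0 + np.abs(rr - 1) + np.abs(cc - 1)      # minimum at (1, 1)
        right = 0.5 + np.abs(rr - 4) + np.abs(cc - 5)     # minimum at (4, 5)
        dmap = np.where(cc <= 2, left, right).astype(float)
        dmap[:, 3] = 9.0                                   # ridge column
        items = np.array([[1, 1], [0, 0], [5, 2], [4, 5], [2, 5], [0, 4]])
        a = ba.detect_clusters(dmap, items, theta=0.10)
        oracle = flood_fill_oracle(dmap, [(1, 1), (4, 5)])
        left = oracle[items[:, 0], items[:, 1]] == 0
        labels = a.item_labels
        assert a.n_clusters == 2
        assert len(set(labels[left])) == 1
        assert len(set(labels[~left])) == 1
        assert labels[left][0] != labels[~left][0]

    def test_shallow_ridge_merged(self):
        """A ridge below theta * range cannot separate two basins."""
        dmap = np.full((4, 6), 1.0)
        dmap[:, 3] = 1.4              # shallow ridge over range 10
        dmap[0, 0] = 0.0
        dmap[3, 5] = 0.2
        dmap[0, 5] = 10.0             # sets the dynamic range
        items = np.array([[0, 0], [3, 5]])
        merged = ba.detect_clusters(dmap, items, theta=0.30)
        assert merged.n_clusters == 1
        split = ba.detect_clusters(dmap, items, theta=0.05)
        assert split.n_clusters == 2

    def test_empty_basins_are_background(self):
        dmap = np.full((6, 6), 5.0)
        dmap[:, 3] = 9.0
        dmap[1, 1] = 1.0
        dmap[4, 5] = 0.5
        items = np.array([[1, 1], [2, 1]])  # only the left basin is occupied
        a = ba.detect_clusters(dmap, items, theta=0.10)
        assert a.n_clusters == 1
        right_units = a.unit_labels[:, 4:]
        assert (right_units == ba.UNASSIGNED).all()


class TestPruneSingletons:
    def test_sizes_3_1_2(self):
        a = ClusterAssignment(
            unit_labels=np.array([[0, 1, 2]]),
            item_labels=np.array([0, 0, 0, 1, 2, 2]),
            bmu=np.zeros((6, 2), dtype=int),
        )
        out = ba.prune_singletons(a, min_members=2)
        assert out.n_clusters == 2
        assert sorted(out.cluster_sizes.values()) == [2, 3]
        assert (out.item_labels == ba.UNASSIGNED).sum() == 1

    def test_min_members_1_identity(self):
        a = ClusterAssignment(
            unit_labels=np.array([[0, 1]]),
            item_labels=np.array([0, 1, 1]),
            bmu=np.zeros((3, 2), dtype=int),
        )
        out = ba.prune_singletons(a, min_members=1)
        np.testing.assert_array_equal(out.item_labels, a.item_labels)

    def test_all_dissolved_is_error(self):
        a = ClusterAssignment(
            unit_labels=np.array([[0, 1]]),
            item_labels=np.array([0, 1]),
            bmu=np.zeros((2, 2), dtype=int),
        )
        with pytest.raises(ClusterError):
            ba.prune_singletons(a, min_members=2)


class TestAggregateMetaMeasures:
    def _assignment(self, labels, bmu=None):
        labels = np.asarray(labels)
        return ClusterAssignment(
            unit_labels=np.zeros((4, 4), dtype=int),
            item_labels=labels,
            bmu=bmu if bmu is not None else np.zeros((len(labels), 2), dtype=int),
        )

    def test_duplicate_measure_mean_is_identity(self):
        vals = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        table = make_table(vals)
        meta = ba.aggregate_meta_measures(table, self._assignment([0, 0]))
        np.testing.assert_allclose(meta.values.iloc[:, 0], vals[:, 0])

    def test_arithmetic_mean(self):
        table = make_table([[1.0, 3.0], [3.0, 5.0]])
        meta = ba.aggregate_meta_measures(table, self._assignment([0, 0]))
        np.testing.assert_allclose(meta.values.iloc[:, 0], [2.0, 4.0])

    def test_matches_group_mean_oracle(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(7, 6))
        labels = np.array([0, 1, 0, 2, 1, 2])
        bmu = rng.integers(0, 4, size=(6, 2))
        table = make_table(vals)
        meta = ba.aggregate_meta_measures(table, self._assignment(labels, bmu))
        for name, members in meta.members.items():
            idx = [int(m[1:]) for m in members]
            np.testing.assert_allclose(meta.values[name], vals[:, idx].mean(axis=1))
        # conservation: members + singletons == all measures
        n_members = sum(len(m) for m in meta.members.values())
        assert n_members + len(meta.singletons_excluded) == 6

    def test_commutes_with_participant_reordering(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(size=(6, 4))
        labels = np.array([0, 0, 1, 1])
        t1 = make_table(vals)
        meta1 = ba.aggregate_meta_measures(t1, self._assignment(labels))
        perm = rng.permutation(6)
        t2 = ba.MeasureTable(
            values=t1.values.iloc[perm], covariates=t1.covariates.iloc[perm],
            measure_kind=t1.measure_kind,
        )
        meta2 = ba.aggregate_meta_measures(t2, self._assignment(labels))
        pd.testing.assert_frame_equal(meta2.values, meta1.values.iloc[perm])

    def test_clockwise_labelling_from_12_oclock(self):
        """Clusters at north, east, south, west of the map center must be
        labelled A, B, C, D in clockwise order starting at 12 o'clock."""
        bmu = np.array([[0, 5], [5, 10], [10, 5], [5, 0]])  # N, E, S, W on 11x11
        a = ClusterAssignment(
            unit_labels=np.zeros((11, 11), dtype=int),
            item_labels=np.array([0, 1, 2, 3]),
            bmu=bmu,
        )
        order = _clockwise_order(a, (11, 11))
        assert order == [0, 1, 2, 3]


class TestZNormalizeRows:
    def test_simple_row(self):
        meta = ba.MetaMeasureTable(
            values=pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("ABC")),
            members={}, singletons_excluded=[],
        )
        out = ba.z_normalize_rows(meta)
        np.testing.assert_allclose(out.values.iloc[0], [-1.0, 0.0, 1.0])

    def test_every_row_standardized_oracle(self):
        rng = np.random.default_rng(14)
        vals = rng.normal(size=(4, 5))
        meta = ba.MetaMeasureTable(
            values=pd.DataFrame(vals, columns=list("ABCDE")),
            members={}, singletons_excluded=[],
        )
        out = ba.z_normalize_rows(meta)
        expected = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
        np.testing.assert_allclose(out.values.to_numpy(), expected)
        assert out.row_normalized

    def test_flat_row_reported(self):
        meta = ba.MetaMeasureTable(
            values=pd.DataFrame([[1.0, 1.0, 1.0]], index=["p9"], columns=list("ABC")),
            members={}, singletons_excluded=[],
        )
        with pytest.raises(ClusterError, match="p9"):
            ba.z_normalize_rows(meta)


def test_feature_block_recovery_single_seed():
    """End-to-end feature typing recovers the planted 13-block partition on
    one default cohort (the 10-seed sweep lives in the acceptance suite)."""
    from sklearn.metrics import adjusted_rand_score

    cohort = ba.generate_cohort(ba.CohortConfig(n_participants=2000, seed=1))
    clean, _ = ba.filter_missing(cohort.to_measure_table())
    normed = ba.z_normalize_columns(ba.height_normalize(clean))
    fdata = normed.values.to_numpy(float).T
    som = ba.train_som(fdata, 30, 30, ba.TrainingSchedule(n_epochs=100), seed=101)
    assign = ba.prune_singletons(
        ba.detect_clusters(ba.distance_map(som), ba.best_matching_units(som, fdata))
    )
    truth = cohort.truth_block_of_measure.reindex(normed.measure_names)
    in_block = (truth != "singleton").to_numpy()
    ari = adjusted_rand_score(truth[in_block].to_numpy(), assign.item_labels[in_block])
    assert ari >= 0.9
    # conservation through aggregation
    meta = ba.aggregate_meta_measures(normed, assign)
    n_members = sum(len(m) for m in meta.members.values())
    assert n_members + len(meta.singletons_excluded) == normed.n_measures
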