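"""Body-type assignment, gender labelling, per-type summaries."""

import numpy as np
import pandas as pd
import pytest

import bodyatlas as ba
from bodyatlas.bodytypes import BodyTypeError
from bodyatlas.features import UNASSIGNED


def meta_from(values, index=None):
    values = np.asarray(values, dtype=float)
    idx = index if index is not None else pd.Index([f"p{i}" for i in range(len(values))])
    cols = [chr(ord("A") + j) for j in range(values.shape[1])]
    meta = ba.MetaMeasureTable(
        values=pd.DataFrame(values, index=idx, columns=cols),
        members={c: [] for c in cols},
        singletons_excluded=[],
    )
    return ba.z_normalize_rows(meta)


@pytest.fixture(scope="module")
def typed_cohort():
    """Default 4-component cohort pushed through feature + body typing."""
    cohort = ba.generate_cohort(ba.CohortConfig(n_participants=1000, seed=21))
    clean, _ = ba.filter_missing(cohort.to_measure_table())
    normed = ba.z_normalize_columns(ba.height_normalize(clean))
    fdata = normed.values.to_numpy(float).T
    fsom = ba.train_som(fdata, 30, 30, ba.TrainingSchedule(n_epochs=100), seed=121)
    assign = ba.prune_singletons(
        ba.detect_clusters(ba.distance_map(fsom), ba.best_matching_units(fsom, fdata))
    )
    meta_z = ba.z_normalize_rows(ba.aggregate_meta_measures(normed, assign))
    types = ba.assign_body_types(meta_z, grid=(12, 12), seed=221)
    return cohort, normed, types


class TestAssignBodyTypes:
    def test_requires_row_normalized_meta(self):
        meta = ba.MetaMeasureTable(
            values=pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)),
                                columns=list("ABC")),
            members={}, singletons_excluded=[],
        )
        with pytest.raises(BodyTypeError, match="row-Z"):
            ba.assign_body_types(meta, grid=(4, 4))

    def test_near_identical_participants_single_type(self):
        rng = np.random.default_rng(1)
        base = np.array([1.0, -0.5, 0.8, -1.3])
        vals = base + 1e-6 * rng.standard_normal((60, 4))
        types = ba.assign_body_types(meta_from(vals), grid=(4, 4), seed=2)
        assert types.n_types == 1
        assert types.n_unassigned == 0

    def test_conservation_assigned_plus_unassigned(self, typed_cohort):
        _, _, types = typed_cohort
        assert types.n_unassigned + sum(types.type_sizes.values()) == len(types.participants)

    def test_minimum_size_enforced(self, typed_cohort):
        _, _, types = typed_cohort
        assert all(n >= types.min_size for n in types.type_sizes.values())
        assert types.min_size == int(np.ceil(0.01 * len(types.participants)))

    def test_recovers_planted_component_count(self, typed_cohort):
        cohort, _, types = typed_cohort
        assert types.n_types == cohort.config.n_body_types

    def test_determinism(self):
        rng = np.random.default_rng(3)
        vals = np.vstack([rng.normal(0, 1, (40, 4)), rng.normal(6, 1, (40, 4))])
        a = ba.assign_body_types(meta_from(vals), grid=(6, 6), seed=5)
        b = ba.assign_body_types(meta_from(vals), grid=(6, 6), seed=5)
        np.testing.assert_array_equal(a.cluster_ids, b.cluster_ids)


class TestLabelByGender:
    def _types(self, cluster_ids, genders):
        idx = pd.Index([f"p{i}" for i in range(len(cluster_ids))])
        types = ba.BodyTypeAssignment(
            participants=idx,
            cluster_ids=np.asarray(cluster_ids),
            bmu=np.zeros((len(cluster_ids), 2), dtype=int),
            som=None, dmap=None, assignment=None, min_size=1,
        )
        return types, pd.Series(genders, index=idx)

    def test_pure_female_cluster(self):
        types, gender = self._types([0] * 10, ["F"] * 10)
        ba.label_by_gender(types, gender)
        assert types.type_names[0] == "F1"

    def test_balanced_cluster_is_B(self):
        types, gender = self._types([0] * 10, ["F"] * 5 + ["M"] * 5)
        ba.label_by_gender(types, gender, majority_threshold=0.8)
        assert types.type_names[0] == "B1"

    def test_fractions_095_010_055(self):
        """Female fractions (0.95, 0.10, 0.55) -> labels (F1, M1, B1)."""
        ids = [0] * 20 + [1] * 20 + [2] * 20
        genders = (["F"] * 19 + ["M"]) + (["F"] * 2 + ["M"] * 18) + (["F"] * 11 + ["M"] * 9)
        types, gender = self._types(ids, genders)
        ba.label_by_gender(types, gender)
        assert types.type_names == {0: "F1", 1: "M1", 2: "B1"}

    def test_numbering_by_descending_size(self):
        ids = [0] * 5 + [1] * 15 + [2] * 10
        genders = ["F"] * 30
        types, gender = self._types(ids, genders)
        ba.label_by_gender(types, gender)
        assert types.type_names == {1: "F1", 2: "F2", 0: "F3"}

    def test_gender_linked_components_get_gendered_labels(self, typed_cohort):
        cohort, normed, types = typed_cohort
        ba.label_by_gender(types, normed.covariates["gender"])
        letters = {v[0] for v in types.type_names.values()}
        assert "F" in letters and "M" in letters


class TestSummarizeBodyTypes:
    def test_hand_built_assignment(self):
        idx = pd.Index([f"p{i}" for i in range(6)])
        types = ba.BodyTypeAssignment(
            participants=idx,
            cluster_ids=np.array([0, 0, 0, 1, 1, UNASSIGNED]),
            bmu=np.zeros((6, 2), dtype=int),
            som=None, dmap=None, assignment=None, min_size=1,
            type_names={0: "F1", 1: "M1"},
        )
        cov = pd.DataFrame(
            {"gender": ["F", "F", "M", "M", "M", "F"],
             "age": [40.0, 50.0, 60.0, 42.0, 48.0, 70.0],
             "height": [160.0, 165.0, 170.0, 180.0, 184.0, 158.0]},
            index=idx,
        )
        summary = ba.summarize_body_types(types, cov)
        assert summary.loc["F1", "n"] == 3
        assert summary.loc["F1", "n_female"] == 2
        assert summary.loc["F1", "age_mean"] == pytest.approx(50.0)
        assert summary.loc["M1", "height_mean"] == pytest.approx(182.0)
        assert summary.loc["M1", "pct_cohort"] == pytest.approx(100 * 2 / 6)

    def test_single_type_percentages_sum_to_100(self):
        idx = pd.Index(["a", "b", "c"])
        types = ba.BodyTypeAssignment(
            participants=idx, cluster_ids=np.zeros(3, dtype=int),
            bmu=np.zeros((3, 2), dtype=int), som=None, dmap=None,
            assignment=None, min_size=1, type_names={0: "B1"},
        )
        cov = pd.DataFrame({"gender": ["F", "M", "F"], "age": [50.0] * 3,
                            "height": [170.0] * 3}, index=idx)
        summary = ba.summarize_body_types(types, cov)
        assert summary["pct_cohort"].sum() == pytest.approx(100.0)

    def test_bmi_bands_sum_to_type_n(self, typed_cohort):
        _, normed, types = typed_cohort
        cov = normed.covariates
        iset = ba.compute_indices(
            cov["weight"].to_numpy(float), cov["height"].to_numpy(float) / 100,
            cov["waist"].to_numpy(float) / 100, cov["hip"].to_numpy(float) / 100,
        )
        indices = pd.DataFrame(
            {"bmi": iset.bmi, "whr": iset.whr, "whtr": iset.whtr, "absi": iset.absi},
            index=cov.index,
        )
        ba.label_by_gender(types, cov["gender"])
        summary = ba.summarize_body_types(types, cov, indices)
        bmi_cols = [c for c in summary.columns if c.startswith("bmi_") and c != "bmi_mean"]
        whr_cols = ["whr_t1", "whr_t2", "whr_t3"]
        for _, row in summary.iterrows():
            assert sum(row[c] for c in bmi_cols) == row["n"]
            assert sum(row[c] for c in whr_cols) == row["n"]


def test_recovery_improves_with_separation():
    """Mean body-type recovery ARI is non-decreasing in component separation
    (means over 10 seeds at separations 1, 3, 5)."""
    from sklearn.metrics import adjusted_rand_score

    def mean_ari(sep):
        aris = []
        for seed in range(10):
            cohort = ba.generate_cohort(
                ba.CohortConfig(n_participants=600, component_separation=sep, seed=seed)
            )
            clean, _ = ba.filter_missing(cohort.to_measure_table())
            normed = ba.z_normalize_columns(ba.height_normalize(clean))
            truth_blocks = cohort.truth_block_of_measure.reindex(normed.measure_names)
            cols = {
                b: normed.values.loc[:, (truth_blocks == b).to_numpy()].mean(axis=1)
                for b in sorted(set(truth_blocks) - {"singleton"})
            }
            meta = ba.MetaMeasureTable(values=pd.DataFrame(cols),
                                       members={b: [] for b in cols},
                                       singletons_excluded=[])
            meta_z = ba.z_normalize_rows(meta)
            try:
                types = ba.assign_body_types(meta_z, grid=(10, 10), seed=seed + 50)
            except BodyTypeError:
                aris.append(0.0)
                continue
            truth = cohort.truth_body_type.reindex(types.participants).to_numpy()
            aris.append(adjusted_rand_score(truth, types.cluster_ids))
        return float(np.mean(aris))

    a1, a3, a5 = mean_ari(1.0), mean_ari(3.0), mean_ari(5.0)
    assert a1 <= a3 + 0.02
    assert a3 <= a5 + 0.02
    assert a5 > a1
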