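import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import binprofiler as bp
from binprofiler.io_model import MOA, PLATE, TREATMENT, WELL
from binprofiler.profiling import PROFILE_ID, cosine_distance

from conftest import make_matrix


class TestAssembleFingerprints:
    def test_extreme_bins_keep_two_columns_per_parameter(self, small_binned):
        binned, edges = small_binned
        full = {p for (_, p), es in edges.items() if es.instantiated_bins == (1, 2, 3, 4, 5)}
        matrix = bp.assemble_fingerprints(binned, "extreme_bins", parameters=sorted(full))
        per_param = pd.Series([f.split("__bin")[0] for f in matrix.features]).value_counts()
        assert (per_param == 2).all()
        assert all(f.endswith(("__bin1__z", "__bin5__z")) for f in matrix.features)

    def test_all_bins_has_more_features_than_extreme(self, small_binned):
        binned, _ = small_binned
        allb = bp.assemble_fingerprints(binned, "all_bins")
        extr = bp.assemble_fingerprints(binned, "extreme_bins")
        assert len(allb.features) > len(extr.features)
        assert not np.isnan(allb.values()).any()

    def test_controls_excluded_by_default(self, small_binned):
        binned, _ = small_binned
        matrix = bp.assemble_fingerprints(binned, "all_bins")
        assert (matrix.data[TREATMENT] != "DMSO").all()
        with_ctrl = bp.assemble_fingerprints(binned, "all_bins", include_controls=True)
        assert len(with_ctrl) > len(matrix)

    def test_missing_bearing_columns_dropped(self, small_binned):
        # A parameter missing in one well loses all its columns everywhere.
        binned, _ = small_binned
        param = binned["parameter"].iloc[0]
        poked = binned.copy()
        treated_rows = poked[TREATMENT] != "DMSO"
        first_well = poked.loc[treated_rows, WELL].iloc[0]
        mask = (poked["parameter"] == param) & (poked[WELL] == first_well) & treated_rows
        poked.loc[mask, "z"] = np.nan
        matrix = bp.assemble_fingerprints(poked, "all_bins")
        assert not any(f.startswith(f"{param}__bin") for f in matrix.features)

    def test_well_average_mode(self, small_screen):
        table, _ = small_screen
        profiles = bp.well_average(table)
        z, kept = bp.zscore_well_averages(profiles, table.features)
        matrix = bp.assemble_fingerprints(z, "well_average", features=kept)
        assert matrix.features == kept
        assert matrix.mode == "well_average"


class TestCosineDistance:
    def test_identical_vectors(self):
        assert cosine_distance([1.0, 2.0], [1.0, 2.0]) == pytest.approx(0.0)

    def test_orthogonal_vectors(self):
        assert cosine_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_antiparallel_vectors(self):
        assert cosine_distance([1.0, 1.0], [-1.0, -1.0]) == pytest.approx(2.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance([0.0, 0.0], [1.0, 1.0])

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.floats(0.1, 50),
    )
    def test_symmetry_and_scale_invariance(self, u, v, c):
        u, v = np.array(u), np.array(v)
        if np.linalg.norm(u) < 1e-6 or np.linalg.norm(v) < 1e-6:
            return
        d = cosine_distance(u, v)
        assert d == pytest.approx(cosine_distance(v, u))
        assert d == pytest.approx(cosine_distance(c * u, v), abs=1e-9)
        assert 0.0 <= d <= 2.0 + 1e-12


class TestNNLooClassify:
    def test_separable_classes_classify_perfectly(self):
        X = [[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0]]
        matrix = make_matrix(X, ["A", "A", "B", "B"])
        report = bp.nn_loo_classify(matrix)
        assert report.n_correct == 4
        assert report.accuracy == 1.0

    def test_wrong_nearest_label_counted_incorrect(self):
        # Brute-force over the 3x3 distance matrix: id000 (A) is nearest to
        # id002 (B), so it misclassifies; the other two are correct.
        X = [[1.0, 0.1], [0.1, 1.0], [1.0, 0.25]]
        matrix = make_matrix(X, ["A", "B", "A"], ids=["id000", "id001", "id002"])
        D = [[cosine_distance(a, b) for b in X] for a in X]
        assert D[0][2] < D[0][1]
        report = bp.nn_loo_classify(matrix, exclusion="self_only")
        per = report.per_profile.set_index(PROFILE_ID)
        assert per.loc["id000", "correct"]
        assert not per.loc["id001", "correct"]  # B's nearest is an A
        assert report.n_correct == 2
        assert report.accuracy == pytest.approx(2 / 3)

    def test_distance_tie_breaks_to_smaller_id(self):
        X = [[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]]
        matrix = make_matrix(X, ["A", "B", "C"], ids=["q", "a", "b"])
        report = bp.nn_loo_classify(matrix, exclusion="self_only")
        per = report.per_profile.set_index(PROFILE_ID)
        assert per.loc["q", "nn_id"] == "a"
        assert per.loc["q", "predicted"] == "B"

    def test_same_compound_replicates_excluded(self):
        X = [[1, 0], [1, 0], [0, 1], [0, 1]]
        matrix = make_matrix(
            X, ["A", "A", "B", "B"], treatments=["c1", "c1", "c2", "c2"]
        )
        report = bp.nn_loo_classify(matrix, exclusion="same_compound")
        # each profile's only candidates carry the other label
        assert report.n_correct == 0
        self_only = bp.nn_loo_classify(matrix, exclusion="self_only")
        assert self_only.n_correct == 4

    def test_no_candidates_reported_unclassifiable(self):
        X = [[1, 0], [1, 0.1]]
        matrix = make_matrix(X, ["A", "A"], treatments=["c1", "c1"])
        report = bp.nn_loo_classify(matrix, exclusion="same_compound")
        assert report.n_unclassifiable == 2
        assert report.n_profiles == 0

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 4))
        labels = ["A", "B", "C"] * 4
        matrix = make_matrix(X, labels)
        perm = rng.permutation(12)
        shuffled = bp.FingerprintMatrix(
            data=matrix.data.iloc[perm].reset_index(drop=True),
            features=matrix.features,
            mode=matrix.mode,
        )
        a = bp.nn_loo_classify(matrix).per_profile.set_index(PROFILE_ID)
        b = bp.nn_loo_classify(shuffled).per_profile.set_index(PROFILE_ID)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 5))
        matrix = make_matrix(X, ["A", "B"] * 5)
        scaled = make_matrix(X * 37.0, ["A", "B"] * 5)
        a = bp.nn_loo_classify(matrix).per_profile["predicted"]
        b = bp.nn_loo_classify(scaled).per_profile["predicted"]
        assert list(a) == list(b)

    def test_brute_force_agreement(self):
        # 50 random profiles over 5 classes, 10 compounds: predictions match
        # an independent all-pairs scan for both exclusion policies.
        rng = np.random.default_rng(123)
        X = rng.normal(size=(50, 8))
        labels = [f"moa{i % 5}" for i in range(50)]
        treatments = [f"cpd{i % 10}" for i in range(50)]
        ids = [f"id{i:03d}" for i in range(50)]
        matrix = make_matrix(X, labels, treatments=treatments, ids=ids)
        for policy in ("same_compound", "self_only"):
            report = bp.nn_loo_classify(matrix, exclusion=policy)
            per = report.per_profile.set_index(PROFILE_ID)
            for i in range(50):
                best = None
                for j in range(50):
                    if policy == "self_only" and j == i:
                        continue
                    if policy == "same_compound" and treatments[j] == treatments[i]:
                        continue
                    d = cosine_distance(X[i], X[j])
                    if best is None or d < best[0] or (d == best[0] and ids[j] < best[1]):
                        best = (d, ids[j], labels[j])
                row = per.loc[ids[i]]
                assert row["nn_id"] == best[1]
                assert row["predicted"] == best[2]

    def test_median_replicates_of_identical_vectors(self):
        # two compounds per class, identical replicate vectors: collapsing to
        # the median must not change the not-same-compound classification
        X = [[1.0, 2.0]] * 6 + [[2.0, -1.0]] * 6
        treatments = [t for t in ("c1", "c2", "c3", "c4") for _ in range(3)]
        matrix = make_matrix(X, ["A"] * 6 + ["B"] * 6, treatments=treatments)
        matrix.data["concentration"] = 1.0
        med = matrix.median_replicates()
        assert len(med) == 4
        rep = bp.nn_loo_classify(med, exclusion="same_compound")
        per_rep = bp.nn_loo_classify(matrix, exclusion="same_compound")
        assert rep.accuracy == per_rep.accuracy == 1.0


class TestHoldoutExperiment:
    def test_stability_selection_is_label_blind(self, small_screen, small_binned):
        # Removing a treatment class leaves the control-only retained sets
        # bit-identical, so the held-in stability artifacts equal full-data ones.
        table, truth = small_screen
        binned, _ = small_binned
        reports = bp.stability_fractions(bp.well_parameter_tests(binned))
        without = table.with_data(table.data[table.data[MOA] != "moa_1"])
        binned_wo, _ = bp.bin_profiles(without)
        reports_wo = bp.stability_fractions(bp.well_parameter_tests(binned_wo))
        full = bp.stability_ladder(reports)
        held = bp.stability_ladder(reports_wo)
        assert full == held

    def test_single_profile_holdout_counted(self, small_binned):
        binned, _ = small_binned
        reports = bp.stability_fractions(bp.well_parameter_tests(binned))
        matrix = bp.assemble_fingerprints(binned, "extreme_bins")
        keep = (matrix.data[MOA] != "moa_2") | (
            matrix.data[PROFILE_ID] == matrix.data.loc[matrix.data[MOA] == "moa_2", PROFILE_ID].iloc[0]
        )
        pruned = matrix.subset_rows(keep.to_numpy())
        result = bp.holdout_class_experiment(
            pruned, "moa_2", "stability", stability_reports=reports
        )
        assert result.holdout_n == 1
        assert result.holdout_misclassified in (0, 1)

    def test_missing_holdout_class_rejected(self, small_binned):
        binned, _ = small_binned
        matrix = bp.assemble_fingerprints(binned, "extreme_bins")
        with pytest.raises(bp.ValidationError):
            bp.holdout_class_experiment(matrix, "no_such_moa", "l1")
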