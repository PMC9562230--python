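"""Split, SMOTE interpolation, and the dummy-class construction."""

import numpy as np
import pandas as pd
import pytest

from winepi.augmentation import (
    AugmentationPlan,
    _interpolate,
    dummy_class_augment,
    smote_augment,
    split_dataset,
    write_provenance,
)


class TestPlan:
    def test_defaults_are_the_study_protocol(self):
        plan = AugmentationPlan()
        assert (plan.n_source, plan.n_holdout, plan.n_synth, plan.k_neighbors) == (12, 6, 1000, 5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(k_neighbors=12),  # >= n_source
            dict(k_neighbors=0),
            dict(formula="jitter"),
            dict(n_source=1),
        ],
    )
    def test_invalid_plans_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AugmentationPlan(**kwargs)


class TestSplit:
    def test_twelve_six_partition(self, study_table, default_plan):
        source, holdout = split_dataset(study_table, default_plan)
        assert (len(source), len(holdout)) == (12, 6)
        assert set(source.index) | set(holdout.index) == set(study_table.index)
        assert set(source.index) & set(holdout.index) == set()

    def test_seed_determinism(self, study_table, default_plan):
        s1, h1 = split_dataset(study_table, default_plan)
        s2, h2 = split_dataset(study_table, default_plan)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(h1, h2)

    def test_size_mismatch_rejected(self, study_table, default_plan):
        with pytest.raises(ValueError):
            split_dataset(study_table.iloc[:10], default_plan)


class TestInterpolationFormulas:
    def test_zero_gap_returns_seed_row(self):
        values = np.array([[1.0, 2.0], [5.0, 1.0]])
        out = _interpolate(values, np.array([0]), np.array([1]), np.array([0.0]), "paper-abs")
        np.testing.assert_array_equal(out, values[[0]])

    def test_paper_abs_moves_up_only(self):
        values = np.array([[1.0, 4.0], [3.0, 2.0]])
        out = _interpolate(values, np.array([0]), np.array([1]), np.array([0.5]), "paper-abs")
        np.testing.assert_allclose(out, [[2.0, 5.0]])  # x + 0.5*|x - xk|

    def test_standard_signed_moves_toward_neighbour(self):
        values = np.array([[1.0, 4.0], [3.0, 2.0]])
        out = _interpolate(values, np.array([0]), np.array([1]), np.array([0.5]), "standard-signed")
        np.testing.assert_allclose(out, [[2.0, 3.0]])


class TestSmoteAugment:
    def test_exactly_n_synth_rows(self, study_table, default_plan):
        source, _ = split_dataset(study_table, default_plan)
        assert len(smote_augment(source, default_plan).data) == 1000

    def test_identical_source_rows_reproduce_themselves(self, study_table):
        plan = AugmentationPlan(n_source=6, n_holdout=0, n_synth=50, k_neighbors=2, seed=1)
        row = study_table.iloc[[0]]
        source = pd.concat([row] * 6)
        source.index = [f"w{i}" for i in range(6)]
        out = smote_augment(source, plan)
        expected = np.tile(row.to_numpy(), (50, 1))
        np.testing.assert_allclose(out.data.to_numpy(), expected)

    @pytest.mark.parametrize("formula", ["paper-abs", "standard-signed"])
    def test_coordinate_bounds(self, study_table, formula):
        plan = AugmentationPlan(seed=2, formula=formula)
        source, _ = split_dataset(study_table, plan)
        out = smote_augment(source, plan)
        vals = source.to_numpy()
        x = vals[out.provenance["seed_index"].to_numpy()]
        xk = vals[out.provenance["neighbor_index"].to_numpy()]
        synth = out.data.to_numpy()
        if formula == "paper-abs":
            # never below the seed, never past seed + |seed - neighbour|
            assert (synth >= x - 1e-12).all()
            assert (synth <= x + np.abs(x - xk) + 1e-12).all()
        else:
            lo, hi = np.minimum(x, xk), np.maximum(x, xk)
            assert (synth >= lo - 1e-12).all() and (synth <= hi + 1e-12).all()

    def test_bit_for_bit_determinism(self, study_table, default_plan):
        source, _ = split_dataset(study_table, default_plan)
        a = smote_augment(source, default_plan)
        b = smote_augment(source, default_plan)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(a.provenance, b.provenance)

    def test_quality_interpolated_with_the_same_gap(self, study_table, default_plan):
        source, _ = split_dataset(study_table, default_plan)
        out = smote_augment(source, default_plan)
        vals = source["quality"].to_numpy()
        x = vals[out.provenance["seed_index"].to_numpy()]
        xk = vals[out.provenance["neighbor_index"].to_numpy()]
        gap = out.provenance["gap"].to_numpy()
        np.testing.assert_allclose(out.data["quality"].to_numpy(), x + gap * np.abs(x - xk))

    def test_too_few_source_rows_rejected(self, study_table):
        source = study_table.iloc[:4]
        plan = AugmentationPlan(n_source=12, n_holdout=6, n_synth=10, k_neighbors=5, seed=0)
        with pytest.raises(ValueError):
            smote_augment(source, plan)

    def test_non_numeric_feature_rejected(self, study_table, default_plan):
        source, _ = split_dataset(study_table, default_plan)
        source = source.copy()
        source["region"] = "otago"
        with pytest.raises(ValueError, match="region"):
            smote_augment(source, default_plan)


class TestDummyClassAugment:
    def test_thousand_rows_none_all_zero(self, study_table, default_plan):
        source, _ = split_dataset(study_table, default_plan)
        out = dummy_class_augment(source, default_plan)
        assert len(out.data) == 1000
        assert "class" not in out.data.columns
        assert not (out.data.to_numpy() == 0).all(axis=1).any()

    def test_original_rows_not_in_output(self, study_table, default_plan):
        source, _ = split_dataset(study_table, default_plan)
        out = dummy_class_augment(source, default_plan)
        assert not set(source.index) & set(out.data.index)

    def test_zero_synth_gives_empty_output(self, study_table):
        plan = AugmentationPlan(n_synth=0, seed=0)
        source, _ = split_dataset(study_table, plan)
        assert len(dummy_class_augment(source, plan).data) == 0

    def test_elementwise_equivalence_with_direct_smote(self, study_table, default_plan):
        source, _ = split_dataset(study_table, default_plan)
        direct = smote_augment(source, default_plan)
        dummy = dummy_class_augment(source, default_plan)
        np.testing.assert_allclose(
            direct.data.to_numpy(), dummy.data.to_numpy(), rtol=0, atol=1e-9
        )
        pd.testing.assert_frame_equal(direct.provenance, dummy.provenance)


class TestProvenance:
    def test_jsonl_record_per_row(self, study_table, tmp_path):
        plan = AugmentationPlan(n_synth=25, seed=3)
        source, _ = split_dataset(study_table, plan)
        out = smote_augment(source, plan)
        path = write_provenance(out, tmp_path / "prov.jsonl")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 25
        import json

        rec = json.loads(lines[0])
        assert set(rec) == {"row_id", "seed_index", "seed_row", "neighbor_index", "neighbor_row", "gap"}
        assert 0.0 <= rec["gap"] <= 1.0
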