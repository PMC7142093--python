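"""CART induction: Gini arithmetic, split search vs brute force, growth."""

import numpy as np
import pytest

import hfdx as H
from hfdx.errors import HfdxError

from util import oracle_best_split, random_records

D = H.Diagnosis


@pytest.mark.parametrize(
    "labels, expected",
    [
        ([D.HFrEF] * 5, 0.0),
        ([D.HFrEF, D.HFrEF, D.NoHF, D.NoHF], 0.5),
        ([D.HFrEF, D.HFmrEF, D.HFpEF, D.NoHF], 0.75),
        ([D.HFrEF, D.HFrEF, D.HFrEF, D.NoHF], 1.0 - (0.75 ** 2 + 0.25 ** 2)),
    ],
)
def test_gini_impurity_values(labels, expected):
    assert H.gini_impurity(labels) == pytest.approx(expected)


def test_gini_of_empty_set_is_an_error():
    with pytest.raises(HfdxError):
        H.gini_impurity([])


class TestBestSplit:
    ATTRS = ("lvef", "lavi", "male")

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed, schema):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 31))
        recs = random_records(rng, n, missing_rate=float(rng.uniform(0, 0.3)))
        got = H.best_split(recs, attributes=self.ATTRS, min_samples_leaf=1)
        want = oracle_best_split(recs, self.ATTRS, schema)
        if want is None:
            assert got is None
        else:
            name, t, dec, na_side = want
            assert got.attribute == name
            if t is None:
                assert got.threshold is None
            else:
                assert got.threshold == pytest.approx(t)
            assert got.decrease == pytest.approx(dec)
            assert got.na_side == na_side

    def test_perfect_separation_at_the_lvef_boundary(self):
        rng = np.random.default_rng(0)
        recs = random_records(rng, 40)
        for i, r in enumerate(recs):
            r.values["lvef"] = 30.0 + (i % 4) if i < 20 else 55.0 + (i % 4)
            r.gold_diagnosis = D.HFrEF if i < 20 else D.NoHF
        split = H.best_split(recs, min_samples_leaf=1)
        assert split.attribute == "lvef"
        assert split.threshold == pytest.approx((33.0 + 55.0) / 2)
        parent = H.gini_impurity([r.gold_diagnosis for r in recs])
        assert split.decrease == pytest.approx(parent)  # children are pure

    def test_tie_prefers_earlier_schema_attribute(self):
        recs = random_records(np.random.default_rng(1), 20)
        for i, r in enumerate(recs):
            r.values["male"] = r.values["abnormal_ecg"] = i < 10
            r.gold_diagnosis = D.HFrEF if i < 10 else D.NoHF
        split = H.best_split(recs, attributes=("abnormal_ecg", "male"), min_samples_leaf=1)
        assert split.attribute == "male"  # earlier in the schema

    def test_pure_labels_give_no_split(self):
        recs = random_records(np.random.default_rng(2), 10)
        for r in recs:
            r.gold_diagnosis = D.HFpEF
        assert H.best_split(recs) is None


class TestInduceCart:
    def test_single_record_gives_its_label(self):
        rec = random_records(np.random.default_rng(3), 1)[0]
        rec.gold_diagnosis = D.HFmrEF
        tree = H.induce_cart([rec])
        assert tree.root.is_leaf and tree.root.diagnosis is D.HFmrEF

    def test_depth_zero_gives_majority_leaf(self, small_cohort):
        tree = H.induce_cart(small_cohort, H.InductionParams(max_depth=0))
        counts = {}
        for r in small_cohort:
            counts[r.gold_diagnosis] = counts.get(r.gold_diagnosis, 0) + 1
        assert tree.root.is_leaf
        assert tree.root.diagnosis is max(counts, key=counts.get)

    def test_empty_training_set_rejected(self):
        with pytest.raises(HfdxError):
            H.induce_cart([])

    def test_training_set_consistency_with_unbounded_growth(self, small_cohort):
        """min_samples_leaf=1 and unlimited depth reproduce every training
        label when no two records share a feature vector with different
        labels."""
        recs = small_cohort[:80]
        tree = H.induce_cart(recs, H.InductionParams(max_depth=64, min_samples_leaf=1))
        for rec in recs:
            assert H.diagnose(tree, rec).outcome is rec.gold_diagnosis

    def test_root_splits_on_lvef_for_the_default_cohort(self, train_cohort):
        tree = H.induce_cart(train_cohort)
        assert tree.root.attribute == "lvef"
        for node in tree.walk():
            assert node.provenance == "learned"
            if not node.is_leaf:
                assert node.na_route is not None  # induced trees are total

    @pytest.mark.parametrize("seed", [0, 1])
    def test_lvef_thresholds_recover_the_generative_boundaries(self, seed):
        recs = H.generate_cohort(H.table1_default_spec(n=600, seed=seed))
        tree = H.induce_cart(recs)
        ths = [n.branches[1].interval.lo for n in tree.walk()
               if not n.is_leaf and n.attribute == "lvef"]
        assert ths, "expected at least one LVEF split"
        assert min(abs(t - 40) for t in ths) <= 2
        assert min(abs(t - 50) for t in ths) <= 2


class TestRankFeatures:
    def test_lvef_dominates_the_default_cohort(self, train_cohort):
        ranked = H.rank_features(train_cohort)
        assert ranked[0][0] == "lvef"
        assert sum(s for _, s in ranked) == pytest.approx(1.0)

    def test_permuted_labels_destroy_importance_concentration(self, small_cohort):
        labels = [r.gold_diagnosis for r in small_cohort]
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(len(labels))
            shuffled = [H.PatientRecord(r.patient_id, r.values, labels[p])
                        for r, p in zip(small_cohort, perm)]
            top = H.rank_features(shuffled)[0]
            assert top[1] <= 0.5

    def test_single_class_gives_all_zero_in_schema_order(self, schema, small_cohort):
        recs = [H.PatientRecord(r.patient_id, r.values, D.NoHF) for r in small_cohort[:20]]
        ranked = H.rank_features(recs)
        assert [name for name, _ in ranked] == list(schema.names)
        assert all(s == 0.0 for _, s in ranked)

    def test_single_attribute_takes_all_importance(self):
        s1 = H.AttributeSchema((H.Attribute("lvef", "continuous", "%", (0.0, 100.0)),))
        recs = [H.PatientRecord(f"p{i}", {"lvef": float(v)},
                                D.HFrEF if v < 40 else D.NoHF)
                for i, v in enumerate((10, 20, 30, 55, 60, 70))]
        assert H.rank_features(recs, schema=s1) == [("lvef", 1.0)]


def test_cross_validated_accuracy_is_high_on_separable_classes(small_cohort):
    acc = H.cross_val_accuracy(small_cohort, H.InductionParams(seed=5))
    assert 90.0 <= acc <= 100.0
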