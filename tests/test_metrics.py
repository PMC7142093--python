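"""Diagnostic-accuracy metrics, engine comparison, subgroups, summaries."""

import numpy as np
import pytest

import hfdx as H
from hfdx.errors import EvaluationError

D = H.Diagnosis
LABELS = list(D)


def vec(*pairs):
    gold, pred = [], []
    for g, p, k in pairs:
        gold += [g] * k
        pred += [p] * k
    return gold, pred


class TestEvaluate:
    def test_perfect_agreement(self):
        gold = [LABELS[i % 4] for i in range(598)]
        rep = H.evaluate(gold, gold)
        assert rep.overall_concordance == 100.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.association == pytest.approx(1.0)
        assert all(v == 100.0 for v in rep.per_class_concordance.values())

    def test_588_of_598_agreements_round_to_98_3(self):
        gold, pred = vec((D.HFrEF, D.HFrEF, 500), (D.NoHF, D.NoHF, 88),
                         (D.HFpEF, D.NoHF, 10))
        rep = H.evaluate(gold, pred)
        assert rep.n == 598
        assert round(rep.overall_concordance, 1) == 98.3

    def test_per_class_rate_11_of_12(self):
        gold, pred = vec((D.NoHF, D.NoHF, 11), (D.NoHF, D.HFpEF, 1),
                         (D.HFrEF, D.HFrEF, 5))
        rep = H.evaluate(gold, pred)
        assert rep.per_class_concordance[D.NoHF] == pytest.approx(100 * 11 / 12)

    def test_confusion_matrix_and_binary_collapse(self):
        gold, pred = vec((D.HFrEF, D.HFrEF, 6), (D.HFrEF, D.NoHF, 2),
                         (D.HFpEF, D.HFmrEF, 3), (D.NoHF, D.NoHF, 8),
                         (D.NoHF, D.HFpEF, 1))
        rep = H.evaluate(gold, pred)
        conf = rep.confusion
        assert conf.sum() == 20
        assert conf[0, 0] == 6 and conf[0, 3] == 2 and conf[2, 1] == 3
        # HF collapse: TP=9 (6 correct rEF + 3 pEF->mrEF), FN=2, TN=8, FP=1
        assert rep.sensitivity == pytest.approx(9 / 11)
        assert rep.specificity == pytest.approx(8 / 9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        gold = [LABELS[i] for i in rng.integers(0, 4, 100)]
        pred = [LABELS[i] if rng.random() < 0.7 else None for i in rng.integers(0, 4, 100)]
        base = H.evaluate(gold, pred)
        perm = rng.permutation(100)
        shuf = H.evaluate([gold[i] for i in perm], [pred[i] for i in perm])
        assert np.array_equal(base.confusion, shuf.confusion)
        assert base.overall_concordance == shuf.overall_concordance
        assert base.sensitivity == shuf.sensitivity

    def test_uncovered_policies(self):
        gold = [D.HFrEF] * 8 + [D.NoHF] * 2
        pred = [D.HFrEF] * 6 + [None] * 2 + [D.NoHF, None]
        excl = H.evaluate(gold, pred, uncovered="exclude")
        assert excl.n == 7 and excl.n_uncovered == 3
        assert excl.overall_concordance == pytest.approx(100.0)
        disc = H.evaluate(gold, pred, uncovered="discordant")
        assert disc.n == 10
        assert disc.overall_concordance == pytest.approx(70.0)
        assert disc.sensitivity == pytest.approx(6 / 8)   # uncovered HF = miss
        assert disc.specificity == pytest.approx(1 / 2)   # uncovered NoHF = false alarm

    def test_binary_accuracy_reconstructs_from_sens_spec(self):
        rng = np.random.default_rng(1)
        gold = [LABELS[i] for i in rng.integers(0, 4, 200)]
        pred = [LABELS[i] for i in rng.integers(0, 4, 200)]
        rep = H.evaluate(gold, pred)
        n_hf = sum(g.is_hf for g in gold)
        n_no = 200 - n_hf
        acc = (rep.sensitivity * n_hf + rep.specificity * n_no) / 200
        direct = np.mean([g.is_hf == p.is_hf for g, p in zip(gold, pred)])
        assert acc == pytest.approx(direct)

    def test_degenerate_association_flagged(self):
        rep = H.evaluate([D.HFrEF] * 5, [D.HFrEF] * 5)
        assert rep.association is None and rep.degenerate_association

    def test_errors(self):
        with pytest.raises(EvaluationError):
            H.evaluate([D.NoHF], [])
        with pytest.raises(EvaluationError):
            H.evaluate([D.NoHF], [None])


class TestCompareEngines:
    def test_identical_engines_report_identically(self, ckm, small_cohort):
        rep = H.compare_engines(small_cohort, {"a": ckm, "b": ckm})
        ra, rb = rep.reports["a"], rep.reports["b"]
        assert ra.overall_concordance == rb.overall_concordance
        assert np.array_equal(ra.confusion, rb.confusion)

    def test_single_engine_equals_plain_evaluate(self, ckm, small_cohort):
        gold = [r.gold_diagnosis for r in small_cohort]
        direct = H.evaluate(gold, H.predict(ckm, small_cohort), uncovered="discordant")
        rep = H.compare_engines(small_cohort, {"expert": ckm})
        assert rep.reports["expert"].overall_concordance == direct.overall_concordance

    def test_low_coverage_engine_is_flagged_not_fatal(self, ckm, small_cohort):
        blind = [r.masked(["hf_symptoms_signs"]) for r in small_cohort]
        rep = H.compare_engines(blind, {"expert": ckm})
        assert rep.flagged == ["expert"]

    def test_hybrid_dominates_expert_on_the_standard_split(self, ckm, train_cohort, test_cohort):
        """Grafting cannot lose agreements: under the common-denominator
        convention the refined model scores at least the expert model."""
        pm = H.induce_cart(train_cohort)
        rckm = H.hybridize(ckm, pm, train_cohort)
        rep = H.compare_engines(test_cohort, {"expert": ckm, "hybrid": rckm})
        assert (rep.reports["hybrid"].overall_concordance
                >= rep.reports["expert"].overall_concordance)

    def test_empty_engine_map_rejected(self, small_cohort):
        with pytest.raises(EvaluationError):
            H.compare_engines(small_cohort, {})


class TestSubgroups:
    def test_set_a_equals_plain_evaluate(self, ckm, small_cohort):
        gold = [r.gold_diagnosis for r in small_cohort]
        direct = H.evaluate(gold, H.predict(ckm, small_cohort))
        rep = H.subgroup_eval(small_cohort, ckm, "setA")
        assert rep.overall_concordance == direct.overall_concordance

    def test_set_b_masking_never_helps_the_expert_model(self, ckm, small_cohort):
        """Masking the extended echo panel can only turn covered records
        into uncovered ones for a model without NA routing."""
        a = H.subgroup_eval(small_cohort, ckm, "setA", uncovered="discordant")
        b = H.subgroup_eval(small_cohort, ckm, "setB", uncovered="discordant")
        assert b.overall_concordance <= a.overall_concordance
        assert b.n_uncovered >= a.n_uncovered

    def test_age_strata_partition_the_cohort(self, ckm, small_cohort):
        strata = H.subgroup_eval(small_cohort, ckm, ("age", [0, 65, 80, 120]),
                                 uncovered="discordant")
        assert sum(rep.n for rep in strata.values() if rep) == len(small_cohort)

    def test_empty_stratum_reports_none(self, ckm, small_cohort):
        strata = H.subgroup_eval(small_cohort, ckm, ("age", [0, 1, 120]),
                                 uncovered="discordant")
        assert strata["[0, 1)"] is None

    def test_invalid_subset_rejected(self, ckm, small_cohort):
        with pytest.raises(EvaluationError):
            H.subgroup_eval(small_cohort, ckm, ("age", [80, 20]))


class TestSummarize:
    def _group(self, n, dx, **over):
        base = {"age": 70.0, "male": True, "hf_symptoms_signs": True,
                "clinical_history": False, "physical_exam": False,
                "abnormal_ecg": False, "nt_probnp": 100.0, "lvef": 55.0,
                "lavi": 30.0, "lvmi": 90.0, "e_over_eprime": 10.0,
                "septal_eprime": 6.0, "trv": 2.5, "gls": 15.0}
        base.update(over)
        return [H.PatientRecord(f"{dx.value}{i}", dict(base), dx) for i in range(n)]

    def test_identical_groups_give_p_one(self):
        recs = []
        for i in range(10):
            recs.append(H.PatientRecord(f"a{i}", {"age": 60.0 + i, "male": i % 2 == 0,
                        **{n: None for n in H.default_schema().names
                           if n not in ("age", "male")}}, D.NoHF))
            recs.append(H.PatientRecord(f"b{i}", {"age": 60.0 + i, "male": i % 2 == 0,
                        **{n: None for n in H.default_schema().names
                           if n not in ("age", "male")}}, D.HFrEF))
        table = H.summarize_cohort(recs)
        assert table.loc["age", "p_value"] == pytest.approx(1.0)
        assert table.loc["male", "p_value"] == pytest.approx(1.0)

    def test_chi_square_on_a_20_10_contingency(self):
        no = self._group(20, D.NoHF, abnormal_ecg=True) + self._group(10, D.NoHF)
        hf = self._group(10, D.HFrEF, abnormal_ecg=True) + self._group(20, D.HFrEF)
        table = H.summarize_cohort(no + hf)
        row = table.loc["abnormal_ecg"]
        assert row["test"] == "chi2"
        assert row["p_value"] == pytest.approx(0.00982, abs=2e-4)
        assert row["p_value"] < 0.05

    def test_fisher_fallback_when_expected_counts_are_small(self):
        no = self._group(4, D.NoHF, abnormal_ecg=True) + self._group(4, D.NoHF)
        hf = self._group(1, D.HFrEF, abnormal_ecg=True) + self._group(7, D.HFrEF)
        table = H.summarize_cohort(no + hf)
        assert table.loc["abnormal_ecg", "test"] == "fisher"

    def test_degenerate_variance_flagged(self):
        recs = self._group(5, D.NoHF) + self._group(5, D.HFrEF)
        table = H.summarize_cohort(recs)
        assert table.loc["age", "p_value"] == 1.0
        assert bool(table.loc["age", "degenerate"])

    def test_hf_group_has_lower_lvef_in_the_default_cohort(self):
        recs = H.generate_cohort(H.table1_default_spec(n=598, seed=4))
        table = H.summarize_cohort(recs)
        hf_mean = float(table.loc["lvef", "hf"].split(" ")[0])
        no_mean = float(table.loc["lvef", "no_hf"].split(" ")[0])
        assert hf_mean < no_mean
        assert table.loc["lvef", "p_value"] < 0.001
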