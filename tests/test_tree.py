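"""Decision-tree structure, JSON round trips, validation, traversal."""

import json

import numpy as np
import pytest

import hfdx as H
from hfdx.errors import KnowledgeModelError
from hfdx.tree import tree_to_dict

from util import random_records, random_tree

INF = float("inf")


def leaf_tree(dx=H.Diagnosis.NoHF):
    return H.DecisionTree("leaf", H.DecisionNode("n0", "expert", diagnosis=dx))


def lvef_node(intervals):
    kids = [H.DecisionNode(f"k{i}", "expert", diagnosis=H.Diagnosis.NoHF)
            for i in range(len(intervals))]
    return H.DecisionTree("t", H.DecisionNode(
        "root", "expert", attribute="lvef",
        branches=[H.Branch(k, interval=iv) for k, iv in zip(kids, intervals)]))


class TestRoundTrip:
    def test_single_leaf(self, tmp_path):
        t = leaf_tree()
        H.save_tree(t, tmp_path / "t.json")
        assert H.load_tree(tmp_path / "t.json") == t

    def test_default_ckm(self, tmp_path, ckm):
        H.save_tree(ckm, tmp_path / "ckm.json")
        loaded = H.load_tree(tmp_path / "ckm.json")
        assert loaded == ckm
        assert tree_to_dict(loaded) == tree_to_dict(ckm)

    @pytest.mark.parametrize("seed", range(15))
    def test_random_trees(self, tmp_path, seed):
        t = random_tree(np.random.default_rng(seed))
        H.save_tree(t, tmp_path / "r.json")
        assert H.load_tree(tmp_path / "r.json") == t


class TestValidation:
    def test_default_ckm_is_clean(self, ckm, schema):
        issues = H.validate_tree(ckm, schema)
        assert [i for i in issues if i.severity == "error"] == []
        # no NA routing by design: every internal node reports an NA gap
        n_internal = sum(1 for n in ckm.walk() if not n.is_leaf)
        assert sum(1 for i in issues if i.kind == "na-gap") == n_internal

    def test_overlapping_branches_flagged(self):
        t = lvef_node([H.Interval(-INF, 40, False, False),
                       H.Interval(-INF, 50, False, False),
                       H.Interval(50, INF, True, False)])
        kinds = {i.kind for i in H.validate_tree(t)}
        assert "overlap" in kinds

    def test_gap_flagged(self):
        t = lvef_node([H.Interval(-INF, 40, False, False)])
        kinds = {i.kind for i in H.validate_tree(t)}
        assert "gap" in kinds

    def test_save_rejects_invalid(self, tmp_path):
        t = lvef_node([H.Interval(-INF, 40, False, False)])
        with pytest.raises(KnowledgeModelError):
            H.save_tree(t, tmp_path / "bad.json")

    def test_load_rejects_overlap_document(self, tmp_path, ckm):
        doc = tree_to_dict(ckm)
        # corrupt the LVEF node: make the first two intervals overlap
        node = doc["root"]["branches"][1]["child"]
        assert node["attribute"] == "lvef"
        node["branches"][0]["range"] = [None, 45.0]
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(KnowledgeModelError):
            H.load_tree(p)

    def test_load_rejects_malformed_json(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(KnowledgeModelError):
            H.load_tree(p)

    def test_binary_node_needs_both_values(self):
        t = H.DecisionTree("t", H.DecisionNode(
            "root", "expert", attribute="male",
            branches=[H.Branch(H.DecisionNode("k", "expert", diagnosis=H.Diagnosis.NoHF),
                               value=True)]))
        assert any(i.kind == "binary-branches" for i in H.validate_tree(t))


class TestTraversal:
    def test_single_leaf_diagnosis(self):
        trace = H.diagnose(leaf_tree(H.Diagnosis.HFpEF), random_records(np.random.default_rng(0), 1)[0])
        assert trace.outcome is H.Diagnosis.HFpEF
        assert trace.path == []

    @pytest.mark.parametrize("seed", range(10))
    def test_trace_replay(self, seed, schema):
        """White-box guarantee: re-applying each recorded test to the
        record reproduces the branch taken."""
        rng = np.random.default_rng(seed)
        tree = random_tree(rng)
        nodes = {n.node_id: n for n in tree.walk()}
        for rec in random_records(rng, 30, missing_rate=0.2):
            trace = H.diagnose(tree, rec, schema)
            for step in trace.path:
                node = nodes[step.node_id]
                assert node.attribute == step.attribute
                v = rec.get(step.attribute)
                assert v == step.observed
                if v is not None and "missing" not in step.branch:
                    matching = [b for b in node.branches if b.matches(v)]
                    assert len(matching) == 1
                    assert matching[0].describe(node.attribute) == step.branch
            if trace.is_covered:
                assert trace.failure_node is None
            else:
                assert trace.failure_reason in ("missing", "gap")
                assert trace.failure_node in nodes

    def test_missing_without_na_routing_is_uncovered(self, ckm):
        rec = random_records(np.random.default_rng(1), 1, missing_rate=0.0)[0]
        rec.values["hf_symptoms_signs"] = True
        rec.values["lvef"] = None
        trace = H.diagnose(ckm, rec)
        assert not trace.is_covered
        assert trace.failure_node == "lvef" and trace.failure_reason == "missing"

    def test_na_route_follows_majority_branch(self):
        yes = H.DecisionNode("y", "learned", diagnosis=H.Diagnosis.HFrEF)
        no = H.DecisionNode("n", "learned", diagnosis=H.Diagnosis.NoHF)
        t = H.DecisionTree("t", H.DecisionNode(
            "root", "learned", attribute="lvef",
            branches=[H.Branch(yes, interval=H.Interval(-INF, 40, False, False)),
                      H.Branch(no, interval=H.Interval(40, INF, True, False))],
            na_route=1))
        rec = random_records(np.random.default_rng(2), 1)[0]
        rec.values["lvef"] = None
        trace = H.diagnose(t, rec)
        assert trace.outcome is H.Diagnosis.NoHF
        assert "missing" in trace.path[0].branch


def test_dot_rendering_mentions_every_node(ckm):
    dot = H.tree_to_dot(ckm)
    for node in ckm.walk():
        assert f'"{node.node_id}"' in dot
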