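# Knowledge-model document formats

Both formats are plain JSON, versioned, and round-trip losslessly through
`save_tree`/`load_tree` and `export_rule_base`/`load_rule_base`. Loading
validates structure and rejects invalid documents (overlapping or gapped
branches, unknown labels, malformed JSON).

## Decision tree (`hfdx-tree`, version 1)

```json
{
  "format": "hfdx-tree",
  "version": 1,
  "tree_id": "ckm-default",
  "root": { ...node... }
}
```

A **leaf node**:

```json
{"id": "lvef_reduced", "provenance": "expert", "leaf": "HFrEF"}
```

An **internal node** tests one attribute and lists its branches:

```json
{
  "id": "lvef",
  "provenance": "expert",
  "attribute": "lvef",
  "branches": [
    {"range": [null, 40.0], "closed": [false, false], "child": {...}},
    {"range": [40.0, 50.0], "closed": [true, false],  "child": {...}},
    {"range": [50.0, null], "closed": [true, false],  "child": {...}}
  ]
}
```

* Continuous branches carry `range` (`null` = unbounded) and `closed`
  flags per bound. The branches of a node must tile the attribute's valid
  range — no overlap, no gap.
* Binary branches carry `"value": true|false` instead; exactly one of
  each is required.
* `provenance` is `expert`, `learned` or `grafted`.

Missing-value routing, when present, is one of two forms:

```json
"na": {"route": 1}          // Missing follows branch index 1 (induced trees)
"na": {"child": {...node}}  // dedicated Not-Available subtree (grafts)
```

A node with neither form leaves Missing values uncovered at that point
(reported as an informational NA-gap by `validate_tree`).

## Rule base (`hfdx-rules`, version 1)

```json
{
  "format": "hfdx-rules",
  "version": 1,
  "source_tree_id": "ckm-default+pm-cart",
  "code_map": {"lvef": "SCT:250908004"},
  "rules": [
    {
      "id": "R001",
      "provenance": "expert",
      "conclusion": "NoHF",
      "conditions": [
        {"attribute": "hf_symptoms_signs", "op": "is_false",
         "text": "hf_symptoms_signs is false"}
      ],
      "text": "IF hf_symptoms_signs is false THEN NoHF"
    }
  ]
}
```

Condition operators: `<`, `<=`, `>`, `>=`, `range` (value
`[lo, hi, lo_closed, hi_closed]`), `is_true`, `is_false`, `is_missing`.
A term with `"or_missing": true` also accepts a Missing value (the
majority-side routing of induced trees). Terms carry the terminology code
of their attribute when `code_map` provides one. Rules extracted from one
tree are mutually exclusive; the engine (`RuleBase.apply`) fires the
unique matching rule or reports the record uncovered.
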