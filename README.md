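# hfdx — white-box heart-failure diagnosis toolkit

`hfdx` is a small library + CLI for building, refining and evaluating
**white-box diagnostic knowledge models** for heart failure (HF). It targets
the knowledge-engineering workflow of a clinical decision-support system:

1. **Expert knowledge** — a guideline-style decision tree (the *clinical
   knowledge model*, CKM): HF requires symptoms/signs plus objective
   evidence, and is phenotyped by ejection fraction into HFrEF
   (LVEF < 40 %), HFmrEF (40 % ≤ LVEF < 50 %) and HFpEF (LVEF ≥ 50 %).
2. **Learned knowledge** — CART-style tree induction (Gini splitting,
   native Missing-value routing) over patient records with 14 clinical and
   echocardiographic attributes, plus Gini feature ranking and a rank score
   for choosing among candidate learners.
3. **Hybridization** — the coverage gaps of the expert model (above all its
   missing *Not-Available* paths: real records have Missing values the
   expert tree cannot route) are filled by grafting learned subtrees at
   each failure point, producing a *refined* CKM whose expert decisions are
   untouched and whose coverage can only grow.
4. **Rules & evaluation** — every tree exports a mutually exclusive
   IF-THEN production-rule base (a shareable JSON knowledge document with
   optional terminology codes), and an evaluation suite computes
   concordance with a gold standard, per-class rates, HF-vs-NoHF
   sensitivity/specificity, φ association, echo/age subgroup analyses and
   baseline-characteristics tables.

Every diagnosis is explainable: traversal returns the full node-by-node
reasoning path, or the exact failure point when a record is uncovered.

Because no public patient-level dataset exists for this task, the package
ships a **seeded synthetic cohort generator** whose per-class marginal
distributions (truncated normals, a lognormal NT-proBNP, Bernoulli
prevalences; configurable MCAR missingness) emulate the published
characteristics of a 598-patient HF test cohort.

## Worked example

```bash
hfdx generate  --n 600 --seed 11 --missingness 0.1 --out train.csv
hfdx generate  --n 598 --seed 12 --missingness 0.1 --out test.csv
hfdx build-ckm --out ckm.json
hfdx train     --cohort train.csv --out pm.json
hfdx hybridize --ckm ckm.json --pm pm.json --cohort train.csv --out rckm.json
# -> coverage 0.767 -> 1.000; wrote refined model to rckm.json
hfdx evaluate  --tree rckm.json --cohort test.csv
# -> overall concordance: 80.2% (n=596, uncovered=2)
#      HFrEF: 94.4%
#      HFmrEF: 75.0%
#      HFpEF: 80.9%
#      NoHF: 55.8%
#      HF sensitivity 0.90, specificity 0.56
hfdx compare   --cohort test.csv --engine expert=ckm.json \
               --engine ml=pm.json --engine hybrid=rckm.json
```

Reading the numbers: with 10 % of values missing completely at random, the
expert model alone covers only ~77 % of the training records (its tree has
no Not-Available paths). Hybridization grafts learned NA-subtrees at every
failure point — the rule base grows from 22 to ~43 rules — restoring full
coverage while preserving every expert decision. On the held-out cohort the
hybrid model therefore always scores at least the expert model. Note that
on *this* synthetic benchmark the pure learned model scores higher still;
the methods note (`docs/methods.md`) explains why that is an artifact of
generating class labels from independent marginal distributions rather than
from the clinical definition the expert model encodes.

A diagnosis with its explanation trace:

```bash
hfdx diagnose --tree rckm.json --cohort test.csv --explain | head -8
# P0001  NoHF
#     symptoms: hf_symptoms_signs is false
# P0002  NoHF
#     symptoms: hf_symptoms_signs is true
#     lvef: lvef >= 50
#     pe_bnp: nt_probnp < 125
#     pe_lavi: lavi <= 34
#     pe_sex: male is missing
```

Patient `P0002` shows a grafted Not-Available path in action: their sex is
unrecorded, so the expert model alone could not decide; the refined model
routes the Missing value into a learned subtree and still reaches (and
explains) a diagnosis.

The same workflow is available as a library — see `hfdx.default_hf_ckm`,
`hfdx.induce_cart`, `hfdx.hybridize`, `hfdx.extract_rules`,
`hfdx.compare_engines`, `hfdx.table1_default_spec`.

## Documentation

* `docs/methods.md` — models, parameters, numerical choices, what the
  synthetic generator does and does not emulate, known limitations.
* `docs/knowledge-model-format.md` — the JSON schemas for decision-tree
  and rule-base documents.
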