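# cdekit

A metadata-registry toolkit for clinical common data elements (CDEs),
built around the ISO/IEC 11179 picture of a data element — a data element
concept (object class + property) joined to a value domain (datatype,
unit, permissible values) — and extended with the composite semantics
real clinical forms need:

* **atomic CDEs** that may be *plain*, *variable* (values are keys of a
  controlled vocabulary / dictionary table) or *hybrid* (a value domain
  that is the ordered union of several member domains, e.g. a dialysis
  *Time* column accepting either `08:00` or the markers `Start`/`Finish`);
* **composite CDEs** that may be *general*, *repeated* (tabular multi-row
  entry) or *dictionary* (linked through a variable foreign-key member to
  a reference table carrying unit lists and unit-specific normal ranges);
* **constraint rules** in a prefix-notation expression language —
  `Operated` (formulas and assertions, e.g.
  `(* (/ CDE30 CDE31 CDE31) 10000)` for BMI in kg/m² from kg and cm, or
  `(< DE:47618 DE:47619)` for date ordering), `Required`, `Dependent`
  (skip logic of the shape `(IF ⟨condition⟩ ⟨target⟩ NULL)`), and
  `Ordered` (presentation order inside a composite).

It ships a validation engine that checks single records and repeated
record sets against these definitions with Kleene three-valued logic
(a comparison against an unanswered question is *indeterminate*, never
silently true or false), dictionary-backed laboratory range checking
(value in `[lo, hi]` ⇒ expected flag `Normal`, outside ⇒ `Abnormal`,
`Abnormal` ⇒ a non-null clinical-significance answer), and an
integration-metrics module that quantifies metadata reuse across document
corpora:

* reuse rate `(n_total − n_unique) / n_total × 100`
* capture share `n_captured / denominator × 100`
* representation count `n_ccde + n_free`
* integration reuse ratio `(n_total − n_ccde_unique − n_unique) / n_total × 100`

all rounded half-up to one decimal.

Audience: clinical-data managers and informatics engineers building or
auditing CDE registries, case-report forms and cross-institution data
dictionaries.

## Worked example

```python
from cdekit import fixtures, validation as ve, metrics as im

reg = fixtures.example_registry()

# A sodium result of 138 mEq/L sits inside the dictionary's 135~145
# normal range, the flag says Normal, significance is blank: clean.
report = ve.validate_record(reg, "DE:47571", fixtures.sodium_record())
print(report.n_errors)                      # 0

# 150 mEq/L flagged Normal: the dictionary check objects.
bad = ve.validate_record(reg, "DE:47571",
                         fixtures.sodium_record(result=150, flag="Normal"))
print([f.code for f in bad.errors()])       # ['flag_mismatch']

# Non-smoker who nevertheless has a start age: the skip rule fires.
rec = ve.DataRecord(values={"CDE20": "No", "CDE21": "No", "CDE22": 35})
print(ve.validate_record(reg, "CDE2X", rec).n_errors)   # 1

# BMI derivation fills the empty target.
bmi = ve.validate_record(reg, "CDE3X", ve.DataRecord(values={"CDE30": 70,
                                                             "CDE31": 175}))
print(round(bmi.derived[("CDE32", None)], 2))           # 22.86

# Reuse statistics from extraction counts: 1142 occurrences folding into
# 586 unique elements and 20 unique composites.
print(im.integration_reuse_ratio(1142, 20, 586))        # 46.9
print(im.reuse_rate(322, 227))                          # 29.5
```

The printed numbers read as: the electrolyte row is valid; the mutated
row carries exactly one flag error; the skip-logic record carries exactly
one dependency error; the derived body-mass index is 22.86 kg/m²; and
folding 1142 extracted elements into 586 unique plus 20 composites is a
46.9 % reduction, with 29.5 % of one hospital's 322 extractions being
repeats across its five documents.

## Command line

```sh
cde validate --registry registry.json --records records.csv --cde DE:47571
cde metrics  --corpus corpus.json --out table.csv
cde lint     --registry registry.json
cde fixture  --seed 7 --outdir fx/
cde derive   --registry registry.json --records bmi.csv --cde CDE3X
```

Exit codes: 0 clean, 1 findings present, 2 usage/I-O failure.

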