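# Methods

## The model

A registry item is either an atomic CDE (aCDE) or a composite CDE
(cCDE).  An aCDE couples a data element concept (object class +
property) with a value domain: one of the datatypes `numeric`, `text`,
`enumerated`, `time`, `date`, `datetime`, `boolean`, plus an optional
unit, a format (ISO 8601 for dates, `HH:MM` for times) and, for
enumerated domains, a non-empty list of unique permissible codes.

Three atomic subtypes extend this:

* **plain** — the ordinary case;
* **variable** — values are keys of a controlled vocabulary, carried as a
  `vocabulary_ref = (table id, key column)` into a dictionary table;
* **hybrid** — the element's effective domain is the ordered union of
  two or more *plain* members with pairwise distinct datatypes.  A hybrid
  carries no value domain of its own: keeping the members as the single
  source of truth avoids a representative domain drifting out of sync.
  Members are tried in declared order and the first that parses wins;
  this makes resolution deterministic when domains overlap (a time-like
  string could in principle be free text too).

Composites group ≥ 2 atomic members (never other composites — the data
model is deliberately two-level: cCDE → aCDE → hybrid members) and come
in three kinds: **general**, **repeated** (the member set is entered
many times as table rows) and **dictionary** (one *variable* member is
the foreign key into a reference table).  Declared member order is
meaningful: it is the default presentation sequence that `Ordered`
constraints check against.

### Constraint language

Rules are single parenthesized prefix-notation forms.  Operators:
arithmetic `+ - * /` (n-ary, left-folding, so `(/ a b c) = (a/b)/c`),
relational `= < > <= >=` (n-ary, chained pairwise) and `!=` (binary
only — an n-ary "not equal" is ambiguous between pairwise-distinct and
not-all-equal), logical `and`/`or` (n-ary, short-circuiting) and `not`,
and the forms `IF` (exactly 3 arguments), `Required` (≥ 1 plain
references) and `Ordered` (≥ 2 plain references).  Lexical conventions:
commas are whitespace, string literals take single quotes, `!=` may be
printed with an interior space, `NULL` is the (case-sensitive) null
literal, numeric literals are plain decimals, and the only attribute
access is `⟨id⟩.unit_of_measure`.  Arity violations fail at parse time.
`unparse` emits a canonical single-spaced form with
`parse(unparse(e)) = e`.

Evaluation uses Kleene (strong) three-valued logic.  Any comparison with
a NULL operand is *indeterminate*; indeterminacy propagates through the
connectives except where a determinate operand already decides the
result (`and` with a false conjunct is false, `or` with a true disjunct
is true).  This has a clinically meaningful consequence for skip logic
such as `(IF (or (!= CDE20 'Yes') (!= CDE21 'Yes')) CDE22 NULL)`: if the
past-use question is answered `No`, the skip condition is determinately
true regardless of an unanswered current-use question, and the engine
flags a filled-in start age as an error; only when every answered
disjunct is false does the unanswered one leave the condition
indeterminate, which the engine reports as an informational finding,
never an error.

Rule kinds are recoverable from expressions: `Required`/`Ordered` by
head symbol, `Dependent` as the exact shape
`(IF ⟨boolean-expr⟩ ⟨ref⟩ NULL)` ("condition true forces the target
null" — the only reading consistent with both shipped skip-logic
examples), everything else `Operated`.  A declared kind that disagrees
with the classifier is a lint finding.  `Dictionary` rules carry no
expression: their semantics are table-driven (below) and a prefix form
would only duplicate what the dictionary link already encodes.

The canonical BMI rule is written
`(IF (= CDE31.unit_of_measure 'm') (/ CDE30 CDE31 CDE31) (* (/ CDE30 CDE31 CDE31) 10000))`:
weight in kg divided by height squared, with an explicit ×10⁴ scaling on
the centimetre branch, which is the mathematically correct kg/cm² →
kg/m² conversion under left-fold division.

### Validation

`validate_record` parses every supplied raw value against its member's
domain, resolves hybrids, builds a typed evaluation context (entered
units, falling back to domain units, back the `unit_of_measure`
attribute), and then executes rules in the fixed order Required →
Dependent → Operated → Ordered → Dictionary, within a kind by rule id.
The order is a package choice made purely for report determinism.

Null handling is deliberately asymmetric.  `Required` inspects the *raw*
entered value: a value that was typed but fails to parse is still "a
value", so a datatype fault never doubles as a missing-value fault.
Operated and Dependent rules see *parsed* values, where an unparseable
entry degrades to NULL and any condition over it comes back
indeterminate — an informational finding, never an error, because
nullness is Required's job.  This preserves single-fault locality:
injecting exactly one violation yields errors that all name the injected
element.

Operated derivations with a numeric result and a declared target either
cross-check a filled-in target (relative tolerance 1e-6, absolute 1e-9 —
derived clinical values are reported to at most two decimals, so these
tolerances are far below reporting precision) or report the derived
value for fill-in.  `Ordered` passes when the rule's references occur in
the record's `field_order` as a subsequence; references not presented
are skipped with an info finding, and a record without any field order
yields a single "unverifiable" info finding.  Repeated cCDEs are
validated row by row; rows are independent (no cross-row constraints
such as monotone times are imposed — whether repeated entry implies them
is left open by the data model, so the engine stays conservative).

### Dictionary link

A dictionary table is CSV with a declared key column, a `'^'`-delimited
unit-list column and a range-map column holding a strict-JSON object
`{unit: "lo ~ hi"}`.  Every row is verified on load: unique non-empty
keys, no empty unit segments, every range unit present in the row's unit
list, every range a valid interval with `lo ≤ hi`.  Normal ranges are
*inclusive* at both bounds — the clinical convention for reference
intervals written `135 ~ 145`.

The record check runs in order: foreign-key value must be a table key
(exact match after trimming); the entered unit must be among that key's
units; a numeric result inside the unit's range implies expected flag
`Normal`, outside `Abnormal`, and a mismatch with the entered flag is an
error; an `Abnormal` flag with a null significance answer is an error,
while a `Normal` flag with a non-null one is only a warning (the form
reads "if abnormal, clinically significant?" — the reverse direction is
a plausibility nudge, not a stated constraint).  The flag vocabulary
defaults to `('Normal', 'Abnormal')` and is configurable per call.
Which members hold the result/unit/flag/significance roles is declared
on the composite (`dictionary_roles` in the registry JSON); the foreign
key itself comes from `dictionary_ref`.  Unit conversion between
parallel units (mEq/L vs mmol/L) is out of scope — tables store parallel
ranges instead.

### Integration metrics

Occurrences are opaque signatures (registry ids where both sides have
them, otherwise the canonical `signature()` text: case-folded,
whitespace-collapsed name + datatype + unit).  Deduplication counts each
element once per document; the reused set is the signatures appearing in
at least two documents.  The four statistics are given in the README;
the capture-share denominator is explicit because both the
unique-element pool and the total-extraction pool are legitimate bases
and both occur in practice.  Composite groupings are *inputs* (explicit
member assignments): grouping elements into composites is a judgment
call the tool does not attempt to automate.  A counts-only mode computes
the percentages directly from supplied totals so printed summary tables
can be checked without reconstructing occurrence lists.

Percentages are rounded half-up to one decimal (`37.85 → 37.9`);
banker's rounding would disagree at `.x5` boundaries with the convention
the reference tables use.

## Synthetic-data generator

`FixtureSpec`/`build_fixture` emulate a multi-institution extraction
study: by default 5 groups × 5 documents drawing 10–20 elements each
from a shared pool of 60 signatures, with probability 0.5 that a draw
reuses an element the group has already seen, and composites absorbing
~40 % of each group's unique pool in chunks of 2–5.  These defaults
mirror the shape of the evaluated study (five sources, five documents
each, roughly half of extraction events being repeats, composites
capturing just under half the unique pool).  The generator records its
own draws, so the answer key's counts are ground truth by construction,
not re-derivations.  Record fixtures use a five-field repeated history
table carrying one rule of each constraint kind; the violation plan
injects at most one fault per row (required → null a mandatory field,
dependent → mark not-ongoing while the end date stays filled, operated →
swap the dates, ordered → permute that row's field order, datatype → an
unparseable date), so expected error counts equal the plan exactly.

What the generator does *not* emulate: semantic near-duplicates (name
variants that a human would merge but `signature()` would not),
hospital-specific vocabulary drift, missing-not-at-random patterns, or
correlated multi-field faults.  Passing the recovery tests therefore
demonstrates that the counting and checking machinery is exact under
clean identity resolution — not that real-world element matching (a
curation task) is solved.

One file-format caveat: a CSV has a single shared header, so per-row
presentation order cannot survive a CSV round-trip.  The generator
writes `records.json` alongside `records.csv`; in the JSON form each
object's key order carries that row's field order, and the answer key's
ordered-violation counts are authoritative for the JSON/in-memory forms.

## Numerical and procedural choices

* Rounding: decimal half-up, via `decimal.Decimal`.
* Operated cross-check tolerance: 1e-6 relative / 1e-9 absolute.
* Dates/times: ISO 8601 (`YYYY-MM-DD`, `HH:MM`); unit strings compared
  case-sensitively after trimming.
* Identifiers match `[A-Za-z_][A-Za-z0-9_:.-]*`, so colon-bearing ids
  like `DE:47616` are single tokens.
* Strict mode (default) errors on unknown record keys and unbound rule
  references; lenient mode warns and maps unbound references to NULL,
  for partially filled forms.
* A hybrid may not itself be variable; disallowed pending a use case.
* Registry JSON saves are canonical (sorted keys, insertion-ordered
  arrays, trailing newline); loading registers elements in file order
  with deferral for forward member references, so dependency-consistent
  files round-trip byte-identically.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
fixtures of the sizes above (corpora of a few hundred occurrences,
record sets of ≤ 8 rows, 1,000-case expression-evaluation oracles,
20-seed recovery sweeps); the whole suite completes in a few seconds on
one CPU.

## Known limitations

* No terminology-service resolution (LOINC etc.); vocabularies are local
  tables.
* No cross-record (longitudinal) constraints; repeated rows are
  independent.
* No automatic semantic matching of element names; integration metrics
  trust the supplied identities.
* No versioned dictionaries (time-stamped normal ranges).
* No unit conversion; parallel units need parallel ranges.
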