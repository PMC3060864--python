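# Methods

## The semantic model

`semkb` represents a research domain as a typed property graph governed
by a project-specific meta-model with seven concept categories:
elements (nodes), relations (typed, optionally directed edges with
endpoint type constraints), annotation forms (nested, typed attribute
records shared by any number of objects), experiment formats (tabular
annotation keyed by elements of one type), context types (named object
sets such as pathways), ontologies, and read-only external sources.
Models are immutable values: `define_type` returns a new validated
model, never partially applies a failed definition, and is
order-insensitive for non-conflicting definitions. `validate_model`
returns violations as data (category, offending name, broken rule)
rather than exceptions, so a whole model can be audited in one pass.

The instance store validates every mutation against the model and logs
it to an audit trail with strictly increasing sequence numbers. The
store is event-sourced: the knowledge base is a pure function of its
model and audit log, and `replay_audit(model, kb.audit)` reproduces it
exactly. Record timestamps are excluded from equality so replay is
deterministic. We deliberately hold the store in plain in-memory
structures persisted as a text archive (model XML, instance TSVs for
human consumption, audit log as JSON-lines, ontology term tables); an
object-relational backend would add operational machinery without
changing any observable contract, since all contracts are phrased over
the public operations.

Identity is identifier-based. An element carries a set of
`(namespace, accession)` pairs, each unique knowledge-base-wide.
Import-time resolution reuses an element iff it already carries the
row's pair; otherwise a new instance is created. Name-based matching is
never attempted, and a pair found on an element of a different type is
reported as a conflict rather than silently reused. When several
namespaces could resolve a row, the first declared mapping wins — a
deliberate, predictable precedence rule.

### Deletion

Deletion refuses while inbound references exist (the safe default for a
shared resource); `force=True` cascades depth-first, detaching
annotations and context memberships where possible and deleting
dependants otherwise, one audit record per removal.

## Query semantics

A query is a clause tree over one target element type. Clause kinds:
annotation comparisons (per form), relation chains with a nested clause
on the partner, ontology inference, context membership, experiment-value
predicates, an identity test (used by per-row report queries), and
and/or/not combinators. Evaluation is existential-witness: a clause
holds for an object iff a satisfying witness exists (an annotation
instance meeting *all* of the clause's comparisons jointly, a relation
partner, an inferred term link, a matching experiment row); negation
holds iff no witness exists.

Three-valued logic is collapsed to false: a missing attribute value
fails every comparison, so `Age > 30` excludes patients with no recorded
age — and the negated clause *includes* them. This is the single most
surprising consequence of the semantics and is worth internalising
before writing exclusion queries.

"Inferred by" expands a term pattern (case-insensitive substring; `*`
wildcards stripped) or explicit term id to the matched terms plus their
transitive descendants over `is_a` and `part_of`, which are treated
equivalently for inference. Cycles are a load-time error, never broken
silently. Negation scopes over the whole existential clause ("never
diagnosed with any inferred term"), not just the final comparison.

Results are ordered by object id ascending. Two evaluators exist with
the same contract: the production evaluator uses the store's secondary
indexes; `brute_force_evaluate` enumerates all candidate witnesses with
no indexing and serves as the independent oracle in tests and in the
acceptance script. Smart folders store a query plus default variable
bindings and are re-evaluated at every call — no caching is observable.

## Subnetwork search

`connect_seeds` realises "most parsimonious network" as the union of one
minimum-cost path per unordered seed pair, where an edge of relation
type *t* costs `penalty[t]` (default 1.0, strictly positive). This is
not an exact Steiner tree — pairwise shortest paths match the mental
model of connecting evidence pair by pair, are deterministic and are
independently checkable; exact Steiner minimisation is a non-goal.
Relations are traversed undirected by default (physical interactions
are symmetric); a directed mode exists in the search configuration.

Ties among equal-cost paths are broken by the lexicographically
smallest node-id sequence, implemented by carrying the id sequence in
the priority key of a label-setting Dijkstra. With strictly positive
weights, optimal paths are simple, and for equal-cost paths ending at
the same node neither id sequence can be a prefix of the other, so the
prefix-optimality argument goes through and one best label per node
suffices. Unreachable pairs (or pairs beyond `max_path_cost`) are
reported with infinite cost rather than dropped.

Information layers evaluate one report view item per subnetwork node
and bin the value on a colour or size channel. Numeric bins are
half-open `[low, high)`: values below the first breakpoint fall in the
first bin, values at or above the last breakpoint in the last; nodes
with no value land in the explicit missing bin, so the binning is total.

## Imports

Templates are declarative YAML (an ordered operation list), standing in
for an interactive mapping wizard. Compilation validates every
operation against the model *and* against the types produced by earlier
operations — a relation may only join handles whose types satisfy its
endpoint constraints, a form must be applicable to the annotated
handle's type, an experiment row's element handle must match the
format's entity type. Execution is plan-then-apply per row: the row is
fully validated (references resolved, constraints checked, values
coerced to the declared attribute kinds) before any mutation, so a
failing row is skipped whole, with a reason, and contributes nothing to
the audit log. Re-running a template is idempotent: resolution finds
the previously created elements, and duplicate relations, annotations
(same form, values and targets), experiment rows and context members
are recognised and not recreated. Experiment rows and context members
accumulate across rows and are committed once per run.

## XML dialect and tag profiles

The data-model dialect has one `<data-model>` root, one section per
concept category (`<element-types>`, `<relation-types>`,
`<annotation-forms>`, `<experiment-formats>`, `<context-types>`,
`<ontologies>`, `<external-sources>`), one node per definition, scalar
fields as XML attributes and list fields as child nodes (`<source>`,
`<target>`, `<attribute>`, `<column>`, `<applies-to>`, `<subform>`,
`<allowed>`). Serialisation is deterministic: fixed category order,
definitions sorted by name, endpoint sets sorted. Foreign exports are
read through a declarative `TagProfile` — three mappings (foreign
section tags → categories, foreign item tags → dialect tags, foreign
attribute names → dialect names) — so a third-party export schema can
be described in a config file instead of code. Unknown section tags are
rejected by name. Because no real third-party export ships with the
repository, the profile machinery is exercised against a *synthetic*
full-scale export (`fixtures.synthetic_scaled_model_export`) written in
a deliberately foreign vocabulary at the configuration scale of a
mature chronic-disease knowledge base: 15 element types, 82 relation
types, 61 annotation forms carrying 892 attributes, 7 experiment
formats, 16 context types, 19 ontologies.

## Reports

A report is an ordered list of view items for one element type; values
come from own attributes, related objects (optionally rendered by a
nested report), assigned annotations, per-row query results (the row
object bound to the `row` variable), context memberships, experiment
values, or a registered computed column (a pure function of the row
object — the hook through which external computations plug in; the
statistics themselves are out of scope). Rendering is deterministic:
one row per input object in input order, multi-valued cells ordered by
related-object id. Nesting is validated acyclic at definition time, and
rendering a nested report inline equals rendering it standalone on the
related objects. TSV export flattens nested sub-tables — each sub-row
becomes one `|`-separated token with sub-columns joined by `", "` —
while XML export preserves the nesting structurally and round-trips
byte-identically through its parser.

## The synthetic knowledge base

`fixtures.generate_kb` emulates, at desk scale, the content of a
COPD-focused translational knowledge base: patients with
anthropometric, diagnostic and physiology forms; genes (including one
named MAPK14), proteins and compounds with standard-namespace
identifiers; protein/genetic interaction edges; gene–disease,
gene–compound, diagnosis and medication relations into a 60-term
disease thesaurus with a cancer branch; gene–function links into a
10-term process ontology with a signal-transduction branch; pathway and
disease-process contexts; and one expression experiment with per-gene
fold changes.

Defaults: 500 patients, 40 genes, 40 proteins, 15 compounds, 8
pathways, interaction density 0.08, 60 ontology terms. Attribute
distributions are arbitrary but fixed: Age uniform 25–80 years; Sex
uniform binary; BMI normal(24, 6) kg/m²; GOLD grade uniform 0–4;
smoking status Bernoulli(0.6); pack consumption uniform 0–40;
six-minute-walk distance before training uniform 60–130 m with an
after-training gain uniform 0–80 m. They were chosen so each benchmark
query selects a nonempty strict subset (roughly 5–30 %) of its target
population, so both satisfaction and rejection branches of every
predicate are exercised. A short backbone of interactions is planted
between the designated seed proteins and compounds so the seed
connection search has finite, nontrivial answers; the recorded
pairwise costs come from a library shortest-path oracle, and the
recorded query answers from the brute-force evaluator — never from the
code paths they validate. Generation is seeded (`random.Random`) and
bit-reproducible across platforms.

What the generator does **not** emulate: real database scale (tens of
thousands of genes, millions of connections), messy real-world
identifier cross-references, missing/contradictory clinical values
beyond simple absence, and realistic correlation structure between
clinical attributes. Passing tests therefore demonstrate the engine's
*semantics* — not performance at public-database scale, nor robustness
to dirty source data.

## Benchmark queries

Three fixed queries ship with the fixtures: (a) a seven-comparison
patient query across the three clinical forms (Age > 30, Sex male,
BMI-BeforeTraining ≥ 10, Smoking status = 1, Packs per ≥ 10,
Walk-AfterTraining ≥ 120, Walk-BeforeTraining ≤ 100 — the BMI threshold
of 10 is clinically odd but kept verbatim as a benchmark); (b) a
severity query with variables (GOLD > *gold_min*, BMI-BT < *bmi_max*,
never diagnosed with a term inferred by "cancer"); (c) a gene query
combining expression fold change beyond ±1.0 with inferred
signal-transduction function.

## Problem sizes used in verification

The acceptance script checks oracle agreement on 100 random
(knowledge base, query) pairs at ≤ ~200 objects and clause depth ≤ 4;
the subnetwork search against exhaustive simple-path enumeration on 50
random weighted graphs of ≤ 12 nodes plus a 10-step penalty sweep;
ontology closures against a breadth-first oracle on 200 random DAGs of
≤ 100 terms; the benchmark queries on the seed-42, 500-patient fixture;
and the round-trip/idempotence properties on mid-sized fixtures. These
sizes keep every check exact (enumeration oracles are exponential in
path length) while covering the combinatorics the engine must get
right.

## Known limitations

- No OWL reasoning, cross-ontology mappings or formal ontology editing;
  inference follows `is_a`/`part_of` only.
- One deterministic path per seed pair, not all co-optimal paths and
  not an exact Steiner tree.
- No query planner beyond straightforward index use; the brute-force
  evaluator is exponential-ish in clause nesting and meant for small
  oracles only.
- Duplicate `(type, source, target)` relation triples are rejected;
  multiple evidence records for one edge live as annotations on the
  single relation.
- No text-mining or sequence-similarity mapping, no live database
  connectors, no user/permission model, no graph rendering.
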