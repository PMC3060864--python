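# semkb

A configurable semantic knowledge-base engine for translational systems
biology, in pure Python.

Clinical research projects accumulate wildly heterogeneous knowledge —
genes, proteins and compounds from public databases; protein-interaction
and gene–disease evidence; pathway definitions; expression experiments;
and per-patient clinical record forms. `semkb` lets a project define its
**own** semantic data model (typed elements, typed relations, nested
annotation forms, experiment formats, contexts, ontologies, external
sources), populate it from delimited tables through declarative import
templates with strictly identifier-based entity resolution, and mine the
resulting knowledge graph with a structured query language,
penalty-weighted subnetwork search, information layers and nestable
reports. It is aimed at bioinformaticians building project-specific
knowledge bases who want warehouse-grade query semantics without a fixed
warehouse schema.

## The core ideas

**Seven concept categories.** A data model is a set of definitions in
seven categories: *element* types (the nodes: `Gene`, `Patient`, …),
*relation* types (typed edges with endpoint constraints:
`is medicated by: Patient → Compound`), *annotation forms* (nested,
typed attribute records attachable to any object), *experiment formats*
(tabular high-throughput annotation keyed by elements), *context* types
(named sub-networks such as pathways), *ontologies* (hierarchical
vocabularies whose terms are first-class, relatable objects) and
read-only *external sources*. Instances are validated against the model,
and every mutation is logged to a replayable audit trail (event
sourcing), so `replay_audit(model, kb.audit) == kb` always holds.

**Identifier-based semantic integration.** Records from different
sources map onto the same element iff they share a
`(namespace, accession)` identifier pair — e.g. `(UniProt, P04049)`.
Names are display labels, never identity; an identifier found on an
element of a different type is a conflict, not a merge. Imports are
row-atomic and idempotent.

**Ontology-aware queries.** Queries are clause trees mirroring wizard
sentences — *find Patients which simultaneously are annotated by
diagnostic data with GOLD > 2, and are annotated by anthropometrics with
BMI-BT < 18, and never are diagnosed with a term inferred by an entry
named like \*cancer\**. "Inferred by" expands a term pattern to its
transitive descendants, so a patient diagnosed with *pancreatic
carcinoma* is excluded by the cancer clause even though the term name
never mentions "cancer". Saved queries become *smart folders*,
re-evaluated on demand and parameterisable through query variables.

**Most-parsimonious subnetworks.** `connect_seeds` links a seed set
(e.g. proteins and compounds implicated by an expression analysis) by
one minimum-cost path per seed pair, where each traversed relation costs
the penalty weight configured for its type: the union of those paths is
the extracted mechanism candidate. The search is a deterministic
Dijkstra (lexicographic node-id tie-break); *information layers* then
bin a per-node view-item value (say, the number of associated
disease-specific pathways) into colour/size classes for display.

## Worked example

The package ships a deterministic synthetic COPD-like knowledge base
(500 patients, genes/proteins/compounds, a disease thesaurus with a
cancer branch) with oracle-computed ground truth:

```python
from semkb.fixtures import (FixtureSpec, generate_kb, benchmark_queries,
                            fixture_search_config)
from semkb.query import evaluate, bind_variables
from semkb.network import connect_seeds
from semkb.store import ObjectRef

kb, truth = generate_kb(FixtureSpec(seed=42, n_patients=500))

# severe COPD, low BMI, never diagnosed with an inferred cancer term
query = bind_variables(benchmark_queries()["severe-low-bmi-no-cancer"],
                       {"gold_min": 2})
hits = evaluate(kb, query)
print(f"{len(hits)} of 500 patients match")

# connect the designated seed proteins/compounds by penalty-weighted paths
seeds = [ObjectRef("element", i) for i in truth.seed_ids]
subnet = connect_seeds(kb, seeds, fixture_search_config())
print(f"subnetwork: {len(subnet.nodes)} nodes, {len(subnet.edges)} edges")
for pair, cost in sorted(subnet.path_costs.items(),
                         key=lambda kv: sorted(r.id for r in kv[0])):
    a, b = sorted(pair, key=lambda r: r.id)
    print(f"  {kb.describe(a)[2]} .. {kb.describe(b)[2]}: cost {cost}")
```

This prints:

```
32 of 500 patients match
subnetwork: 12 nodes, 13 edges
  PROT2 .. PROT7: cost 2.0
  PROT2 .. CPD1: cost 3.0
  PROT2 .. CPD3: cost 4.0
  PROT7 .. CPD1: cost 3.0
  PROT7 .. CPD3: cost 5.0
  CPD1 .. CPD3: cost 3.0
```

32 patients carry a diagnostic GOLD grade above 2 *and* a body-mass
index below 18 *and* no diagnosis inside the inferred cancer branch.
The two seed proteins sit two protein-interaction hops apart; each
protein reaches the seed compounds through the gene layer
(protein ← expressed-as ← gene — gene–compound), and gene–disease hops
cost double per the search's penalty set.

The same operations are scriptable from the shell via the `semkb` CLI
(`semkb fixture generate`, `semkb query run`, `semkb network connect`,
`semkb report render`, `semkb import run`, `semkb model stats`, …).

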