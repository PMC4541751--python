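"""Export association summaries as RDF and query them back.

Each vaccine-AE pair becomes one association resource with links to its
vaccine, symptom, stratified counts and PRR values; the graph round-trips
through Turtle and answers pattern queries.
"""

from pathlib import Path

from vaersnet import (
    compute_prrs,
    count_pairs,
    make_fixture,
    pairs_with_prr_above,
    query_association,
    to_rdf,
    write_turtle,
)

reports = make_fixture("toy_prr")
records, ctx = count_pairs(reports)
compute_prrs(records, ctx)

graph = to_rdf(records)
print(f"{len(records)} association records -> {len(graph)} RDF triples")

out = Path("scratch_toy_prr.ttl")
write_turtle(graph, out)
print(f"Turtle serialisation written to {out}")

rec = query_association(graph, "V", "S")
print(f"\nqueried (V, S): {rec.n_pair_total} co-reports, overall PRR "
      f"{rec.prr_overall}  — 2.0 means the symptom is reported twice as "
      "often with V as in the corpus at large")

print("pairs with overall PRR > 1:", pairs_with_prr_above(graph, 1.0))
out.unlink()
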