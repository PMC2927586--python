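"""Funnel success rates and Plant Ontology analytics on the packaged
study fixtures, plus a tissue query against the annotation store."""

from promoterforge.fixtures import funnel_records, load_funnel_fixture, load_table1_fixture
from promoterforge.tracking import FUNNEL_STAGES, AnnotationStore, success_rate

records = funnel_records()
counts = load_funnel_fixture()
print("construct funnel:")
for a, b in zip(FUNNEL_STAGES, FUNNEL_STAGES[1:]):
    if counts[a] != counts[b]:
        print(f"  {a} -> {b}: {counts[b]}/{counts[a]} = {success_rate(records, a, b)}%")
gfp = success_rate(records, "transgenic_positive", "gfp_positive")
print(f"  GFP-positive fraction of transformed constructs: {gfp}% (~56%)")

summary = load_table1_fixture()
print(f"\n{summary.n_distinct_codes} distinct PO expression regions")
code, n = summary.most_frequent
print(f"most frequent: {code} ({dict((r.po_code, r.po_name) for r in summary.rows)[code]}), "
      f"{n} promoters")

store = AnnotationStore()
store.load_vocabulary(summary.rows)
for row in store.query("tissue", "hydathode").summary_rows:
    print(f"query 'hydathode' -> {row.po_code} {row.po_name}: {row.n_promoters} promoters")
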