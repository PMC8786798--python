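"""Plant cis-regulatory elements into synthetic promoters, scan them back,
and categorize the hits into the four functional groups."""

from tlpfam import categorize_hits, load_element_table, scan_elements
from tlpfam.synthetic import generate_promoters

elements = load_element_table()
plan = {
    "geneA": ["GATA", "DPBFCOREDCD3", "WBOX"],
    "geneB": ["ARFAT", "EBOX"],
}
promoters, planted = generate_promoters(["geneA", "geneB"], elements, plan, seed=4)

print(f"planted {len(planted)} element instances:")
for p in planted:
    print(f"  {p.gene_id}: {p.element_name} ({p.strand}) at {p.start}-{p.end}")

all_hits = []
for promoter in promoters:
    hits = scan_elements(promoter, elements)
    all_hits.extend(hits)
    gene = promoter.id.removesuffix("_promoter")
    print(f"\n{gene}: {len(hits)} total hits in the 1.5 kb window "
          "(planted instances plus background chance matches)")

for gene, counts in categorize_hits(all_hits, elements).items():
    print(f"  {gene} per category:", dict(counts))

print("\nHormone- and stress-responsive element counts in upstream windows "
      "suggest which signals regulate each gene.")
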