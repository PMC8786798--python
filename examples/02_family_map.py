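"""Map a small synthetic family: homeolog triplets, duplicate pairs with
tandem/segmental kinds, chromosome distribution, and gene architecture."""

from tlpfam import (
    build_similarity_edges,
    chromosome_distribution,
    classify_duplication,
    find_duplicates,
    group_homeologs,
    intron_phases,
    screen_candidates,
)
from tlpfam.synthetic import FamilySpec, generate_family

family = generate_family(FamilySpec(n_homeolog_groups=4, seed=5))
accepted, _ = screen_candidates(family.proteins)
models = {m.gene_id: m for m in family.gene_models}

edges = build_similarity_edges(accepted)
groups = group_homeologs(edges, models)
print(f"{len(groups)} homeolog groups across the A/B/D subgenomes:")
for g in groups:
    print(f"  group {g.group_id}: {', '.join(g.members)}")

grouped = {m for g in groups for m in g.members}
dup_edges = [e for e in edges if not ({e.gene_a, e.gene_b} <= grouped)]
pairs = [classify_duplication(p, models) for p in find_duplicates(dup_edges)]
print(f"\n{len(pairs)} duplicate pairs (identity >= 80%, mutual best hits):")
for p in pairs:
    gap = f", gap {p.genomic_gap_bp/1000:.0f} kb" if p.genomic_gap_bp is not None else ""
    print(f"  {p.gene_a} - {p.gene_b}: {p.kind} ({p.identity_pct:.1f}% identity{gap})")

counts, _ = chromosome_distribution([models[p.id] for p in accepted])
print("\ngenes per chromosome:", dict(sorted(counts.items())))

arch = intron_phases(models[accepted[0].id])
print(f"\n{arch.gene_id}: {arch.exon_count} exon(s), intron phases {list(arch.intron_phases)}")
print("\nTandem pairs sit adjacent on one chromosome; segmental pairs span "
      "chromosomes — the split the duplication analysis reports for each crop.")
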