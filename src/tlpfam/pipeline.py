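"""End-to-end orchestration: identify -> structure -> evolution ->
promoters -> expression -> qpcr, with one declarative config, per-stage
TSV outputs and a JSON run report that records every threshold actually
used (so each filter's in/out counts are auditable)."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import expression as xp
from . import family as fam
from . import identification as ident
from . import promoters as prom
from .evolution import (
    CEREAL_RATE_R,
    backtranslate,
    divergence_time,
    ng86_kaks,
    tajima_relative_rate,
)
from .rounding import round_half_up
from .sequence_io import read_fasta, read_gff3


class PipelineError(RuntimeError):
    """Configuration or stage failure; the CLI maps this to a non-zero exit."""


ALL_STAGES = ("identify", "structure", "evolution", "promoters", "expression", "qpcr")


@dataclass
class PipelineConfig:
    # inputs
    proteins: Optional[str] = None
    cds: Optional[str] = None
    gff3: Optional[str] = None
    genome: Optional[str] = None
    promoters: Optional[str] = None  # pre-extracted promoter FASTA
    elements: Optional[str] = None  # cis-element table (bundled when None)
    domains: Optional[str] = None  # gene_id -> thaumatin-domain span TSV
    counts: Optional[str] = None
    lengths: Optional[str] = None
    totals: Optional[str] = None
    qpcr: Optional[str] = None
    # thresholds
    homeolog_identity: float = 90.0
    duplicate_identity: float = 80.0
    tandem_gap_kb: float = 100.0
    tandem_max_intervening: int = 5
    min_fold: float = 2.0
    pseudo: float = 0.01
    rate_r: float = CEREAL_RATE_R
    promoter_window: int = 1500
    expression_floor: float = 1.0
    r_min: float = 0.6
    cluster_k: int = 4
    control_condition: str = "control"
    tajima_outgroup: Optional[str] = None
    # run control
    stages: tuple[str, ...] = ALL_STAGES
    output_dir: str = "tlpfam_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        positive = {
            "homeolog_identity": self.homeolog_identity,
            "duplicate_identity": self.duplicate_identity,
            "tandem_gap_kb": self.tandem_gap_kb,
            "min_fold": self.min_fold,
            "rate_r": self.rate_r,
            "promoter_window": self.promoter_window,
            "cluster_k": self.cluster_k,
        }
        for name, value in positive.items():
            if value is None or value <= 0:
                raise PipelineError(f"threshold {name} must be positive, got {value}")
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise PipelineError(f"unknown stage {stage!r}")
        required = {
            "identify": ["proteins"],
            "structure": ["proteins", "gff3"],
            "evolution": ["proteins", "cds", "gff3"],
            "promoters": [],
            "expression": ["counts", "lengths", "totals"],
            "qpcr": ["qpcr"],
        }
        for stage in self.stages:
            for attr in required[stage]:
                if getattr(self, attr) is None:
                    raise PipelineError(f"stage {stage!r} requires input {attr!r}")
        if "promoters" in self.stages and self.promoters is None and not (
            self.genome and self.gff3
        ):
            raise PipelineError(
                "stage 'promoters' requires a promoter FASTA or genome + gff3"
            )
        for attr in (
            "proteins", "cds", "gff3", "genome", "promoters", "elements",
            "domains", "counts", "lengths", "totals", "qpcr",
        ):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise PipelineError(f"input {attr} not found: {path}")


def _fmt(x, nd):
    return "" if x is None else f"{round_half_up(x, nd):.{nd}f}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages in dependency order; each stage writes its
    TSVs under the output directory and contributes counts to the report."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "effective_config.yaml").write_text(
        yaml.safe_dump({**asdict(config), "stages": list(config.stages)})
    )
    report: dict = {"stages": {}, "thresholds": {
        "homeolog_identity": config.homeolog_identity,
        "duplicate_identity": config.duplicate_identity,
        "tandem_gap_kb": config.tandem_gap_kb,
        "tandem_max_intervening": config.tandem_max_intervening,
        "min_fold": config.min_fold,
        "rate_r": config.rate_r,
        "promoter_window": config.promoter_window,
    }}

    accepted = None
    groups = None
    pairs = []
    models = None

    if "identify" in config.stages:
        proteins = read_fasta(config.proteins, "protein")
        accepted, rejected = ident.screen_candidates(proteins)
        domain_table = {}
        if config.domains:
            df = pd.read_csv(config.domains, sep="\t")
            domain_table = {
                str(r.gene_id): (int(r.domain_start), int(r.domain_end))
                for r in df.itertuples()
            }
        rows = []
        for p in accepted:
            profile = ident.physicochemical_profile(p)
            hits = ident.scan_signature(p)
            d0, d1, proxy = ident.domain_span(p, domain_table.get(p.id))
            size = ident.classify_size(profile, d1 - d0 + 1)
            rows.append(
                dict(
                    id=p.id,
                    length=profile.length_aa,
                    mw_kda=round_half_up(profile.mw_kda, 2),
                    pi=round_half_up(profile.pi, 2),
                    cys_count=profile.cysteine_count,
                    signature_start=hits[0].start,
                    signature_end=hits[0].end,
                    size_class=size.size_class,
                    domain_len=d1 - d0 + 1,
                    domain_proxy=proxy,
                )
            )
        pd.DataFrame(rows).to_csv(out / "identification.tsv", sep="\t", index=False)
        pd.DataFrame(
            [dict(id=p.id, reason=r) for p, r in rejected]
        ).to_csv(out / "rejected.tsv", sep="\t", index=False)
        report["stages"]["identify"] = {
            "candidates": len(proteins),
            "accepted": len(accepted),
            "rejected": len(rejected),
        }

    if "structure" in config.stages:
        if accepted is None:
            accepted, _ = ident.screen_candidates(read_fasta(config.proteins, "protein"))
        models = {m.gene_id: m for m in read_gff3(config.gff3)}
        located = [p for p in accepted if p.id in models]
        edges = fam.build_similarity_edges(located)
        groups = fam.group_homeologs(edges, models, config.homeolog_identity)
        in_group: dict[str, int] = {}
        for g in groups:
            for member in g.members:
                in_group[member] = g.group_id
        # homeologous relationships arise from polyploidy, not duplication:
        # intra-group edges are excluded from duplicate detection
        dup_edges = [
            e
            for e in edges
            if in_group.get(e.gene_a) is None
            or in_group.get(e.gene_a) != in_group.get(e.gene_b)
        ]
        pairs = [
            fam.classify_duplication(
                p, models, int(config.tandem_gap_kb * 1000), config.tandem_max_intervening
            )
            for p in fam.find_duplicates(dup_edges, config.duplicate_identity)
        ]
        pd.DataFrame(
            [
                dict(group_id=g.group_id, members=",".join(g.members))
                for g in groups
            ]
        ).to_csv(out / "homeolog_groups.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                dict(
                    gene_a=p.gene_a, gene_b=p.gene_b,
                    identity=round_half_up(p.identity_pct, 2),
                    kind=p.kind, gap_bp=p.genomic_gap_bp,
                    intervening=p.intervening_genes,
                )
                for p in pairs
            ]
        ).to_csv(out / "duplicate_pairs.tsv", sep="\t", index=False)
        arch_rows = []
        for p in located:
            m = models[p.id]
            if not m.cds_segments:
                continue
            arch = fam.intron_phases(m)
            arch_rows.append(
                dict(
                    gene_id=arch.gene_id,
                    exon_count=arch.exon_count,
                    intronless=arch.intronless,
                    intron_phases=",".join(map(str, arch.intron_phases)),
                )
            )
        pd.DataFrame(arch_rows).to_csv(out / "gene_architecture.tsv", sep="\t", index=False)
        counts, unplaced = fam.chromosome_distribution(
            [models[p.id] for p in located]
        )
        pd.DataFrame(
            sorted(counts.items()), columns=["chromosome", "genes"]
        ).to_csv(out / "chromosome_distribution.tsv", sep="\t", index=False)
        report["stages"]["structure"] = {
            "located": len(located),
            "homeolog_groups": len(groups),
            "duplicate_pairs": len(pairs),
            "tandem": sum(1 for p in pairs if p.kind == "tandem"),
            "segmental": sum(1 for p in pairs if p.kind == "segmental"),
            "unplaced": len(unplaced),
        }

    if "evolution" in config.stages:
        if not pairs:
            report["stages"]["evolution"] = {"pairs": 0}
        else:
            prot_by_id = {p.id: p for p in accepted}
            cds_by_id = {c.id: c for c in read_fasta(config.cds, "dna")}
            paired_ids = {g for p in pairs for g in (p.gene_a, p.gene_b)}
            outgroup_id = config.tajima_outgroup or min(
                (p.id for p in accepted if p.id not in paired_ids and p.id in cds_by_id),
                default=None,
            )
            kaks_rows, taj_rows = [], []
            for p in pairs:
                a, b = prot_by_id[p.gene_a], prot_by_id[p.gene_b]
                aln_a, aln_b, _ = fam.global_align(a.residues, b.residues)
                codon_aln = backtranslate(
                    [(a.id, aln_a), (b.id, aln_b)], cds_by_id
                )
                result = ng86_kaks(codon_aln)
                t = divergence_time(result.ks, config.rate_r) if result.ks is not None else None
                kaks_rows.append(
                    dict(
                        gene_a=p.gene_a, gene_b=p.gene_b,
                        ka=_fmt(result.ka, 4), ks=_fmt(result.ks, 4),
                        ka_ks=_fmt(result.omega, 4),
                        selection=result.selection or "undefined",
                        t_mya="" if t is None else f"{t.t_mya:.1f}",
                        usable_codons=result.usable_codons,
                    )
                )
                if outgroup_id is not None:
                    o = prot_by_id[outgroup_id]
                    ta, tb, to = fam.align_three(a.residues, b.residues, o.residues)
                    codon3 = backtranslate(
                        [(a.id, ta), (b.id, tb), (o.id, to)], cds_by_id
                    )
                    nts = codon3.to_nucleotides()
                    taj = tajima_relative_rate(nts[a.id], nts[b.id], nts[o.id])
                    taj_rows.append(
                        dict(
                            group_a=p.gene_a, group_b=p.gene_b, outgroup=o.id,
                            nt=taj.nt, na=taj.na, nb=taj.nb,
                            chi2=_fmt(taj.chi2, 2), p=_fmt(taj.p, 5),
                        )
                    )
            pd.DataFrame(kaks_rows).to_csv(out / "kaks_divergence.tsv", sep="\t", index=False)
            pd.DataFrame(taj_rows).to_csv(out / "tajima_tests.tsv", sep="\t", index=False)
            report["stages"]["evolution"] = {
                "pairs": len(pairs),
                "purifying": sum(1 for r in kaks_rows if r["selection"] == "purifying"),
                "outgroup": outgroup_id,
            }

    if "promoters" in config.stages:
        elements = prom.load_element_table(config.elements)
        if config.promoters:
            windows = read_fasta(config.promoters, "dna")
        else:
            genome = {g.id: g for g in read_fasta(config.genome, "dna")}
            if models is None:
                models = {m.gene_id: m for m in read_gff3(config.gff3)}
            windows = [
                prom.extract_promoter(m, genome, config.promoter_window).record
                for m in models.values()
            ]
        all_hits = []
        for w in windows:
            gene = w.id.removesuffix("_promoter")
            for h in prom.scan_elements(w, elements):
                all_hits.append(
                    dict(
                        gene_id=gene, element=h.element_name, strand=h.strand,
                        start=h.start, end=h.end, matched=h.matched_seq,
                    )
                )
        pd.DataFrame(all_hits).to_csv(out / "promoter_hits.tsv", sep="\t", index=False)
        hit_objs = [
            prom.ElementHit(r["gene_id"], r["element"], r["strand"], r["start"], r["end"], r["matched"])
            for r in all_hits
        ]
        cats = prom.categorize_hits(hit_objs, elements)
        pd.DataFrame(
            [dict(gene_id=g, **counts) for g, counts in sorted(cats.items())]
        ).to_csv(out / "promoter_categories.tsv", sep="\t", index=False)
        report["stages"]["promoters"] = {
            "promoters": len(windows),
            "hits": len(all_hits),
            "elements": len(elements),
        }

    if "expression" in config.stages:
        counts_df = pd.read_csv(config.counts, sep="\t", index_col=0)
        lengths = pd.read_csv(config.lengths, sep="\t", index_col=0).iloc[:, 0]
        totals = pd.read_csv(config.totals, sep="\t", index_col=0).iloc[:, 0]
        matrix = xp.fpkm(counts_df, lengths, totals)
        matrix.values.to_csv(out / "fpkm.tsv", sep="\t")
        treated = [c for c in matrix.condition_ids if c != config.control_condition]
        calls = xp.differential_filter(
            matrix, config.control_condition, treated, config.min_fold, config.pseudo
        )
        flagged = [c.gene_id for c in calls if c.flagged]
        pd.DataFrame(
            [
                dict(gene_id=c.gene_id, flagged=c.flagged,
                     **{f"fold_{k}": round_half_up(v, 3) for k, v in c.folds.items()})
                for c in calls
            ]
        ).to_csv(out / "differential.tsv", sep="\t", index=False)
        cluster_ids = flagged if len(flagged) >= 2 else matrix.gene_ids
        sub = xp.ExpressionMatrix(matrix.values.loc[cluster_ids])
        k = min(config.cluster_k, len(cluster_ids))
        clusters = xp.cluster_genes(sub, k)
        pd.DataFrame(
            sorted(clusters.labels.items()), columns=["gene_id", "cluster"]
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        fate_rows = []
        for p in pairs:
            if p.gene_a in matrix.values.index and p.gene_b in matrix.values.index:
                f = xp.duplicate_fate(
                    matrix, (p.gene_a, p.gene_b), config.expression_floor, config.r_min
                )
                fate_rows.append(
                    dict(
                        gene_a=f.gene_a, gene_b=f.gene_b, fate=f.fate,
                        correlation="" if f.correlation is None else round_half_up(f.correlation, 3),
                        expressed_a=f.expressed_a, expressed_b=f.expressed_b,
                    )
                )
        pd.DataFrame(fate_rows).to_csv(out / "duplicate_fates.tsv", sep="\t", index=False)
        report["stages"]["expression"] = {
            "genes": len(matrix.gene_ids),
            "differential": len(flagged),
            "clusters": k,
            "fates": len(fate_rows),
        }

    if "qpcr" in config.stages:
        qdf = pd.read_csv(config.qpcr, sep="\t")
        table = xp.QpcrTable.from_dataframe(qdf, config.control_condition)
        folds = xp.ddct_fold(table)
        pd.DataFrame(
            [
                dict(
                    gene_id=f.gene_id, condition=f.condition,
                    fold=round_half_up(f.fold, 3),
                    log2_fold=round_half_up(f.log2_fold, 3),
                    sd="" if f.sd is None else round_half_up(f.sd, 3),
                    p_value="" if f.p_value is None else _fmt(f.p_value, 5),
                    significance=f.significance or "",
                )
                for f in folds
            ]
        ).to_csv(out / "qpcr_folds.tsv", sep="\t", index=False)
        report["stages"]["qpcr"] = {"fold_changes": len(folds)}

    (out / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
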