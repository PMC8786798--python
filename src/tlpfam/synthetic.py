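"""Synthetic TLP family generator with known ground truth.

Every input the pipeline consumes can be generated here: proteins with
planted thaumatin signature motifs and controlled cysteine censuses (16 for
long, 10 for small forms), homeologous triplets across the A/B/D subgenomes
of a hexaploid genome, duplicate gene pairs evolved by codon substitution at
controlled Ka/Ks, exon/intron structures, promoters with planted
cis-elements, and replicate expression matrices with archetype group
structure. Defaults mirror the scale of the wheat family this package was
built around: 32 homeologous groups, six duplicate pairs (five segmental,
one tandem), roughly one small TLP in five.

All generators are deterministic functions of (spec, seed); each
sub-generator draws from its own named child stream of the single seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

from .evolution import GENETIC_CODE, STOP_CODONS, _SITE_TABLE
from .identification import THAUMATIN_SIGNATURE, MotifDefinition, PositionSpec
from .promoters import IUPAC, CisElement, reverse_complement
from .sequence_io import GeneModel, SequenceRecord

#: Residues used for random protein background; cysteine is excluded so the
#: planted cysteine census is exact.
_BACKGROUND_AA = "ADEFGHIKLMNPQRSTVWY"

_STREAMS = {"family": 0, "evolve": 1, "promoters": 2, "expression": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# Specs and ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplicateSpec:
    kind: Literal["tandem", "segmental"]
    target_omega: float
    target_ks: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_ks < 2.0):
            raise ValueError("target_ks must be in [0, 2) to stay invertible")
        if self.target_omega < 0:
            raise ValueError("target_omega must be non-negative")


#: Default duplicate pairs: five segmental plus one tandem, under strong
#: purifying selection, with Ks low enough that protein identity stays
#: comfortably above the 80% duplicate-detection threshold.
DEFAULT_DUPLICATES = (
    DuplicateSpec("segmental", 0.10, 0.60),
    DuplicateSpec("segmental", 0.12, 0.50),
    DuplicateSpec("segmental", 0.08, 0.70),
    DuplicateSpec("segmental", 0.10, 0.55),
    DuplicateSpec("segmental", 0.12, 0.65),
    DuplicateSpec("tandem", 0.10, 0.45),
)


@dataclass(frozen=True)
class FamilySpec:
    n_homeolog_groups: int = 32
    ploidy_mode: Literal["diploid", "hexaploid"] = "hexaploid"
    duplicate_specs: tuple[DuplicateSpec, ...] = DEFAULT_DUPLICATES
    small_fraction: float = 0.2
    motif_plant_rate: float = 1.0
    n_decoys: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy_mode == "diploid" and self.n_homeolog_groups:
            raise ValueError("homeolog groups require hexaploid mode")
        if not (0.0 <= self.motif_plant_rate <= 1.0):
            raise ValueError("motif_plant_rate must be in [0, 1]")
        n_chroms = 21 if self.ploidy_mode == "hexaploid" else 10
        if 2 * len(self.duplicate_specs) > 8 * n_chroms:
            raise ValueError("more duplicate pairs than chromosome capacity")

    @property
    def n_genes(self) -> int:
        copies = 3 if self.ploidy_mode == "hexaploid" else 1
        return copies * self.n_homeolog_groups + 2 * len(self.duplicate_specs)


@dataclass
class GeneTruth:
    size_class: Literal["long", "small"]
    has_motif: bool
    motif_start: Optional[int]  # 1-based in the protein
    motif_end: Optional[int]
    cysteines: int
    subgenome: Optional[str]
    group_id: Optional[int]
    chromosome: str
    domain_start: Optional[int] = None  # thaumatin-domain span in the protein
    domain_end: Optional[int] = None


@dataclass
class PairTruth:
    gene_a: str
    gene_b: str
    kind: Literal["tandem", "segmental"]
    target_omega: float
    target_ks: float


@dataclass
class GroundTruth:
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    homeolog_groups: list[tuple[str, ...]] = field(default_factory=list)
    duplicate_pairs: list[PairTruth] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": {g: asdict(t) for g, t in self.genes.items()},
                "homeolog_groups": [list(g) for g in self.homeolog_groups],
                "duplicate_pairs": [asdict(p) for p in self.duplicate_pairs],
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# Protein / CDS construction
# ---------------------------------------------------------------------------


def _sample_motif_instance(rng: np.random.Generator, motif: MotifDefinition) -> str:
    """A concrete, cysteine-controlled instance of a PROSITE-style motif
    (wildcard positions avoid C so the cysteine census stays exact)."""
    out = []
    for spec in motif.positions:
        if spec.kind == "fixed":
            out.append(spec.residues)
        elif spec.kind == "set":
            out.append(spec.residues[rng.integers(len(spec.residues))])
        elif spec.kind == "any":
            out.append(_BACKGROUND_AA[rng.integers(len(_BACKGROUND_AA))])
        else:  # variable run
            n = int(rng.integers(spec.min_len, spec.max_len + 1))
            out.extend(_BACKGROUND_AA[k] for k in rng.integers(0, len(_BACKGROUND_AA), n))
    return "".join(out)


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(_BACKGROUND_AA[k] for k in rng.integers(0, len(_BACKGROUND_AA), n))


def _build_tlp_protein(
    rng: np.random.Generator,
    size_class: Literal["long", "small"],
    plant_motif: bool,
) -> tuple[str, Optional[tuple[int, int]], int, tuple[int, int]]:
    """Signal peptide + thaumatin domain (+ C-terminal extension for long
    TLPs). Returns (sequence, motif span, cysteine count, domain span);
    spans are 1-based inclusive in the full protein."""
    signal = "M" + _random_protein(rng, 23)
    domain_len = int(rng.integers(202, 218) if size_class == "long" else rng.integers(134, 155))
    target_cys = 16 if size_class == "long" else 10
    domain = list(_random_protein(rng, domain_len))
    motif_span = None
    motif_cys = 0
    if plant_motif:
        instance = _sample_motif_instance(rng, THAUMATIN_SIGNATURE)
        pos = int(rng.integers(10, domain_len - len(instance) - 10))
        domain[pos : pos + len(instance)] = list(instance)
        motif_cys = instance.count("C")
        motif_span = (len(signal) + pos + 1, len(signal) + pos + len(instance))
    # scatter the remaining cysteines outside the motif footprint
    free = [
        i
        for i in range(domain_len)
        if motif_span is None
        or not (motif_span[0] - len(signal) - 1 <= i < motif_span[1] - len(signal))
    ]
    for i in rng.choice(free, size=target_cys - motif_cys, replace=False):
        domain[i] = "C"
    tail = _random_protein(rng, int(rng.integers(55, 95))) if size_class == "long" else ""
    domain_span = (len(signal) + 1, len(signal) + domain_len)
    return signal + "".join(domain) + tail, motif_span, target_cys, domain_span


_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in GENETIC_CODE.items():
    _CODONS_FOR_AA.setdefault(_aa, []).append(_codon)


def reverse_translate(protein: str, rng: np.random.Generator, stop: bool = True) -> str:
    """A CDS that translates exactly to the protein, with random synonymous
    codon choice and an optional terminal stop codon."""
    codons = []
    for aa in protein:
        options = _CODONS_FOR_AA[aa]
        codons.append(options[rng.integers(len(options))])
    if stop:
        stops = sorted(STOP_CODONS)
        codons.append(stops[rng.integers(len(stops))])
    return "".join(codons)


def _mutate_copy(
    protein: str,
    rng: np.random.Generator,
    rate: float,
    protect: Optional[tuple[int, int]],
) -> str:
    """A homeolog-style near-identical copy: substitute ~rate of residues,
    never touching cysteines or the planted motif span."""
    seq = list(protein)
    for i in range(len(seq)):
        if seq[i] == "C":
            continue
        if protect and protect[0] - 1 <= i < protect[1]:
            continue
        if rng.random() < rate:
            seq[i] = _BACKGROUND_AA[rng.integers(len(_BACKGROUND_AA))]
    return "".join(seq)


# ---------------------------------------------------------------------------
# Codon-substitution simulation (evolve_pair)
# ---------------------------------------------------------------------------

#: For each codon, the admissible single-nucleotide mutants split by
#: synonymy, each tagged with the position (0-2) it changes; mutants that
#: are stop codons are excluded.
_SYN_ALTS: dict[str, list[tuple[str, int]]] = {}
_NONSYN_ALTS: dict[str, list[tuple[str, int]]] = {}
for _c in GENETIC_CODE:
    if _c in STOP_CODONS:
        continue
    syn, non = [], []
    for _pos in range(3):
        for _nt in "TCAG":
            if _nt == _c[_pos]:
                continue
            _m = _c[:_pos] + _nt + _c[_pos + 1 :]
            if _m in STOP_CODONS:
                continue
            (syn if GENETIC_CODE[_m] == GENETIC_CODE[_c] else non).append((_m, _pos))
    _SYN_ALTS[_c] = syn
    _NONSYN_ALTS[_c] = non


def _jc_forward(d: float) -> float:
    """Expected proportion of differing sites after divergence d under the
    Jukes-Cantor model (the inverse of the JC distance correction)."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def evolve_pair(
    cds: str,
    target_omega: float,
    target_ks: float,
    seed: int | np.random.Generator,
    protected_codons: Sequence[int] = (),
) -> tuple[str, str]:
    """Evolve two descendants of an ancestral CDS by codon substitution.

    Calibration inverts the Jukes-Cantor correction against the estimator's
    own difference counting: target counts of synonymous (non-synonymous)
    differences are drawn Poisson with mean ``sites * p`` where
    ``p = 3/4 (1 - exp(-4/3 Ks))`` (Ka = omega * Ks respectively), and
    substitutions are planted one at a time — each nucleotide position
    changing at most once across both descendants — until the
    pathway-averaged NG86 difference counts of the realized pair reach the
    targets. The JC-corrected estimates therefore recover the targets in
    expectation; realized values scatter around them. No stop codons are
    ever introduced, and ``protected_codons`` (0-based indices) accept no
    amino-acid change, emulating absolute purifying constraint — the family
    generator uses this for the signature motif.
    """
    from .evolution import _codon_differences

    if target_ks >= 2.0:
        raise ValueError("target_ks >= 2 would saturate the JC correction")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for k, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon at position {k + 1}")
    protected = frozenset(int(i) for i in protected_codons)

    s_sites = sum(_SITE_TABLE[c][0] for c in codons)
    n_sites = sum(_SITE_TABLE[c][1] for c in codons)
    # target proportions, with Poisson sampling noise on the planted counts
    p_syn = rng.poisson(s_sites * _jc_forward(target_ks)) / s_sites
    p_non = (
        rng.poisson(n_sites * _jc_forward(target_omega * target_ks)) / n_sites
    )

    children = [list(codons), list(codons)]
    used: list[set[int]] = [set() for _ in codons]  # positions already changed
    per_codon = [(0.0, 0.0)] * len(codons)  # NG86-counted (sd, nd) per codon
    sd = nd = 0.0
    # measured sites drift as codons mutate; track the pair average the
    # estimator will actually divide by
    S_pair, N_pair = float(s_sites), float(n_sites)
    per_codon_sites = [(float(_SITE_TABLE[c][0]), float(_SITE_TABLE[c][1])) for c in codons]

    def plant(kind: str) -> bool:
        nonlocal sd, nd, S_pair, N_pair
        branch = int(rng.integers(2))
        seq = children[branch]
        table = _SYN_ALTS if kind == "s" else _NONSYN_ALTS
        options = []
        for i, c in enumerate(seq):
            if kind == "n" and i in protected:
                options.append(())
                continue
            options.append(tuple(alt for alt in table[c] if alt[1] not in used[i]))
        weights = np.array([float(len(o)) for o in options])
        total = weights.sum()
        if total == 0:
            return False
        idx = int(rng.choice(len(seq), p=weights / total))
        mutant, pos = options[idx][rng.integers(len(options[idx]))]
        seq[idx] = mutant
        used[idx].add(pos)
        old_sd, old_nd = per_codon[idx]
        new = _codon_differences(children[0][idx], children[1][idx])
        per_codon[idx] = new
        sd += new[0] - old_sd
        nd += new[1] - old_nd
        s0 = _SITE_TABLE[children[0][idx]]
        s1 = _SITE_TABLE[children[1][idx]]
        old_sites = per_codon_sites[idx]
        new_sites = ((s0[0] + s1[0]) / 2.0, (s0[1] + s1[1]) / 2.0)
        per_codon_sites[idx] = new_sites
        S_pair += new_sites[0] - old_sites[0]
        N_pair += new_sites[1] - old_sites[1]
        return True

    max_events = int(6 * (p_syn * s_sites + p_non * n_sites)) + 20
    for _ in range(max_events):
        deficit_s = max(p_syn * S_pair - sd, 0.0)
        deficit_n = max(p_non * N_pair - nd, 0.0)
        if deficit_s <= 0.0 and deficit_n <= 0.0:
            break
        if deficit_n <= 0.0:
            kind = "s"
        elif deficit_s <= 0.0:
            kind = "n"
        else:
            kind = "s" if rng.random() < deficit_s / (deficit_s + deficit_n) else "n"
        if not plant(kind):
            break
    return "".join(children[0]), "".join(children[1])


# ---------------------------------------------------------------------------
# Family generation
# ---------------------------------------------------------------------------

_WHEAT_CHROM_NUMBERS = tuple(range(1, 8))
_SUBGENOMES = ("A", "B", "D")


@dataclass
class SyntheticFamily:
    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    gene_models: list[GeneModel]
    ground_truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        from .sequence_io import write_fasta, write_gff3

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.fasta")
        write_fasta(self.cds, outdir / "cds.fasta")
        write_gff3(self.gene_models, outdir / "genes.gff3")
        with open(outdir / "domains.tsv", "w") as fh:
            fh.write("gene_id\tdomain_start\tdomain_end\n")
            for gid, t in self.ground_truth.genes.items():
                if t.domain_start is not None:
                    fh.write(f"{gid}\t{t.domain_start}\t{t.domain_end}\n")
        (outdir / "ground_truth.json").write_text(self.ground_truth.to_json())


class _ChromosomePlacer:
    """Sequential gene placement with realistic spacing per chromosome."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.cursor: dict[str, int] = {}

    def place(
        self,
        gene_id: str,
        chrom: str,
        cds_len: int,
        n_exons: int,
        tandem_after: bool = False,
    ) -> GeneModel:
        rng = self.rng
        spacing = int(rng.integers(20_000, 60_000)) if tandem_after else int(
            rng.integers(150_000, 350_000)
        )
        start = self.cursor.get(chrom, 1) + spacing
        # split the CDS into exon segments of >= 30 bp each
        cuts = (
            sorted(int(c) for c in rng.choice(np.arange(30, cds_len - 29), size=n_exons - 1, replace=False))
            if n_exons > 1
            else []
        )
        bounds = [0, *cuts, cds_len]
        seg_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
        strand = "+" if rng.random() < 0.5 else "-"
        # lay segments along the genome; for - strand genes the genomic
        # order is the reverse of transcription order
        genomic_lens = seg_lens if strand == "+" else list(reversed(seg_lens))
        exons_genomic = []
        pos = start
        for ln in genomic_lens:
            exons_genomic.append((pos, pos + ln - 1))
            pos += ln + int(rng.integers(80, 400))
        end = exons_genomic[-1][1]
        self.cursor[chrom] = end
        exons = exons_genomic if strand == "+" else list(reversed(exons_genomic))
        cds_segments = []
        cumulative = 0
        for s, e in exons:
            phase = (3 - cumulative % 3) % 3
            cds_segments.append((s, e, phase))
            cumulative += e - s + 1
        sub = chrom[-1] if chrom[-1] in _SUBGENOMES else None
        return GeneModel(
            gene_id=gene_id,
            chromosome=chrom,
            strand=strand,
            start=start,
            end=end,
            exons=exons,
            cds_segments=cds_segments,
            subgenome=sub,
        )


def generate_family(spec: FamilySpec) -> SyntheticFamily:
    """Generate proteins, CDS, gene models and ground truth for a family.

    Homeolog triplets are near-identical copies (~98% identity) of one base
    protein placed on the same chromosome number of the A, B and D
    subgenomes; duplicate pairs are standalone genes evolved from a common
    ancestor at the spec's target omega/Ks; decoys carry no signature motif
    (and no cysteines) so the screen must reject them.
    """
    rng = _rng(spec.seed, "family")
    evolve_rng = _rng(spec.seed, "evolve")
    placer = _ChromosomePlacer(rng)
    truth = GroundTruth()
    proteins: list[SequenceRecord] = []
    cds_records: list[SequenceRecord] = []
    models: list[GeneModel] = []

    hexaploid = spec.ploidy_mode == "hexaploid"
    prefix = "Ta" if hexaploid else "Bd"

    def add_gene(
        gene_id, protein, motif_span, n_cys, size_class, chrom, group_id,
        domain_span, tandem_after=False,
    ):
        cds = reverse_translate(protein, rng)
        n_exons = 1 if size_class == "small" else int(rng.integers(1, 5))
        model = placer.place(gene_id, chrom, len(cds), n_exons, tandem_after)
        proteins.append(SequenceRecord(gene_id, protein, "protein"))
        cds_records.append(SequenceRecord(gene_id, cds, "dna"))
        models.append(model)
        truth.genes[gene_id] = GeneTruth(
            size_class=size_class,
            has_motif=motif_span is not None,
            motif_start=motif_span[0] if motif_span else None,
            motif_end=motif_span[1] if motif_span else None,
            cysteines=n_cys,
            subgenome=model.subgenome,
            group_id=group_id,
            chromosome=chrom,
            domain_start=domain_span[0] if domain_span else None,
            domain_end=domain_span[1] if domain_span else None,
        )

    # --- homeolog groups -------------------------------------------------
    for g in range(spec.n_homeolog_groups):
        size_class = "small" if rng.random() < spec.small_fraction else "long"
        plant = rng.random() < spec.motif_plant_rate
        base, motif_span, n_cys, domain_span = _build_tlp_protein(rng, size_class, plant)
        chrom_number = _WHEAT_CHROM_NUMBERS[g % len(_WHEAT_CHROM_NUMBERS)]
        members = []
        for sub in _SUBGENOMES:
            gene_id = f"{prefix}TLP{g + 1}-{sub}"
            copy = _mutate_copy(base, rng, 0.02, motif_span)
            add_gene(
                gene_id, copy, motif_span, n_cys, size_class,
                f"{chrom_number}{sub}", g + 1, domain_span,
            )
            members.append(gene_id)
        truth.homeolog_groups.append(tuple(members))

    # --- duplicate pairs --------------------------------------------------
    next_index = spec.n_homeolog_groups + 1
    seg_chrom_cycle = 0
    for d, dup in enumerate(spec.duplicate_specs):
        size_class = "long"
        base, motif_span, n_cys, domain_span = _build_tlp_protein(rng, size_class, True)
        anc_cds = reverse_translate(base, rng, stop=False)
        # the signature motif evolves only synonymously (absolute purifying
        # constraint), so both descendants remain screenable
        protected = range(motif_span[0] - 1, motif_span[1])
        cds_a, cds_b = evolve_pair(
            anc_cds, dup.target_omega, dup.target_ks, evolve_rng, protected
        )
        from .evolution import translate_cds

        prot_a, prot_b = translate_cds(cds_a), translate_cds(cds_b)
        if hexaploid:
            ids = (f"{prefix}TLP{next_index}-A", f"{prefix}TLP{next_index + 1}-A")
        else:
            ids = (f"{prefix}TLP{next_index}", f"{prefix}TLP{next_index + 1}")
        next_index += 2
        if dup.kind == "tandem":
            chrom_number = _WHEAT_CHROM_NUMBERS[d % len(_WHEAT_CHROM_NUMBERS)]
            chroms = (f"{chrom_number}A", f"{chrom_number}A") if hexaploid else (str(chrom_number), str(chrom_number))
        else:
            c1 = _WHEAT_CHROM_NUMBERS[seg_chrom_cycle % 7]
            c2 = _WHEAT_CHROM_NUMBERS[(seg_chrom_cycle + 3) % 7]
            seg_chrom_cycle += 1
            chroms = (f"{c1}A", f"{c2}A") if hexaploid else (str(c1), str(c2))
        for gid, prot, cds_seq, chrom, tandem_after in (
            (ids[0], prot_a, cds_a, chroms[0], False),
            (ids[1], prot_b, cds_b, chroms[1], dup.kind == "tandem"),
        ):
            full_cds = cds_seq + "TAA"
            n_exons = int(rng.integers(1, 5))
            model = placer.place(gid, chrom, len(full_cds), n_exons, tandem_after)
            proteins.append(SequenceRecord(gid, prot, "protein"))
            cds_records.append(SequenceRecord(gid, full_cds, "dna"))
            models.append(model)
            truth.genes[gid] = GeneTruth(
                size_class=size_class,
                has_motif=True,
                motif_start=motif_span[0],
                motif_end=motif_span[1],
                cysteines=prot.count("C"),
                subgenome=model.subgenome,
                group_id=None,
                chromosome=chrom,
                domain_start=domain_span[0],
                domain_end=domain_span[1],
            )
        truth.duplicate_pairs.append(
            PairTruth(ids[0], ids[1], dup.kind, dup.target_omega, dup.target_ks)
        )

    # --- decoys (no signature, rejected by the screen) --------------------
    for k in range(spec.n_decoys):
        gid = f"{prefix}DECOY{k + 1}"
        protein = "M" + _random_protein(rng, int(rng.integers(150, 300)))
        chrom = f"{_WHEAT_CHROM_NUMBERS[k % 7]}B" if hexaploid else str(_WHEAT_CHROM_NUMBERS[k % 7])
        cds = reverse_translate(protein, rng)
        model = placer.place(gid, chrom, len(cds), 1)
        proteins.append(SequenceRecord(gid, protein, "protein"))
        cds_records.append(SequenceRecord(gid, cds, "dna"))
        models.append(model)
        truth.genes[gid] = GeneTruth(
            size_class="long",
            has_motif=False,
            motif_start=None,
            motif_end=None,
            cysteines=0,
            subgenome=model.subgenome,
            group_id=None,
            chromosome=chrom,
        )

    return SyntheticFamily(proteins, cds_records, models, truth)


# ---------------------------------------------------------------------------
# Promoters with planted elements
# ---------------------------------------------------------------------------


def _sample_iupac_instance(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        IUPAC[c].replace("N", "")[rng.integers(len(IUPAC[c].replace("N", "")))]
        if c == "N"
        else IUPAC[c][rng.integers(len(IUPAC[c]))]
        for c in pattern
    )


@dataclass
class PlantedElement:
    gene_id: str
    element_name: str
    strand: Literal["+", "-"]
    start: int  # 1-based in the promoter
    end: int
    sequence: str  # pattern-matching orientation


def generate_promoters(
    gene_ids: Sequence[str],
    element_table: Sequence[CisElement],
    plant_plan: dict[str, list[str]],
    seed: int,
    window: int = 1500,
) -> tuple[list[SequenceRecord], list[PlantedElement]]:
    """Random-background promoter windows with planted element instances.

    ``plant_plan`` maps gene id to the list of element names to plant (with
    multiplicity). Planted instances never overlap each other; positions,
    strands and concrete sequences are returned as ground truth.
    """
    rng = _rng(seed, "promoters")
    by_name = {e.name: e for e in element_table}
    records = []
    truth: list[PlantedElement] = []
    for gid in gene_ids:
        seq = list("".join("ACGT"[k] for k in rng.integers(0, 4, window)))
        occupied: list[tuple[int, int]] = []
        for name in plant_plan.get(gid, []):
            element = by_name[name]
            instance = _sample_iupac_instance(element.iupac_pattern, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            planted_seq = instance if strand == "+" else reverse_complement(instance)
            for _ in range(200):  # rejection-sample a free slot
                pos = int(rng.integers(0, window - len(instance)))
                span = (pos, pos + len(instance))
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    break
            else:
                raise RuntimeError("could not place element without overlap")
            occupied.append(span)
            seq[span[0] : span[1]] = list(planted_seq)
            truth.append(
                PlantedElement(gid, name, strand, span[0] + 1, span[1], instance)
            )
        records.append(SequenceRecord(f"{gid}_promoter", "".join(seq), "dna"))
    return records, truth


# ---------------------------------------------------------------------------
# Expression matrices with archetype structure
# ---------------------------------------------------------------------------

#: Default archetypes: mean FPKM per condition (linear scale; noise is
#: applied on log2), mirroring the group structure of stress-series heat
#: maps: flat housekeeping-like profile, early up-regulation, late
#: up-regulation, down-regulation.
DEFAULT_CONDITIONS = ("control", "stress_1h", "stress_6h", "stress_24h")
DEFAULT_ARCHETYPES = {
    "flat": (8.0, 8.0, 8.0, 8.0),
    "early_up": (8.0, 32.0, 16.0, 8.0),
    "late_up": (8.0, 8.0, 16.0, 40.0),
    "down": (32.0, 8.0, 8.0, 8.0),
}


@dataclass
class ExpressionTruth:
    conditions: tuple[str, ...]
    archetype_of: dict[str, str]
    archetype_profiles: dict[str, tuple[float, ...]]
    differential: set[str]  # genes with a planted >= 2-fold change


def generate_expression(
    gene_ids: Sequence[str],
    archetypes: Optional[dict[str, tuple[float, ...]]] = None,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    noise_sd: float = 0.0,
    seed: int = 0,
    gene_length_bp: int = 1000,
    library_size: int = 1_000_000,
    min_fold: float = 2.0,
):
    """Counts, lengths and totals with archetype-structured ground truth.

    Gene lengths and library sizes are chosen so FPKM equals the archetype
    mean exactly at ``noise_sd`` 0 (counts stay integral); noise is
    log-normal on the log2 scale. Returns (counts DataFrame, lengths,
    totals, ExpressionTruth).
    """
    import pandas as pd

    rng = _rng(seed, "expression")
    archetypes = archetypes or DEFAULT_ARCHETYPES
    names = list(archetypes)
    assign = {g: names[i % len(names)] for i, g in enumerate(gene_ids)}
    rows = []
    for g in gene_ids:
        mean = np.asarray(archetypes[assign[g]], dtype=float)
        if noise_sd > 0:
            noisy = 2.0 ** (np.log2(mean) + rng.normal(0.0, noise_sd, len(mean)))
            rows.append(np.round(noisy).astype(int))
        else:
            rows.append(mean.astype(int))
    counts = pd.DataFrame(rows, index=list(gene_ids), columns=list(conditions))
    lengths = pd.Series(gene_length_bp, index=list(gene_ids), dtype=float)
    totals = pd.Series(library_size, index=list(conditions), dtype=float)
    differential = set()
    for g in gene_ids:
        prof = archetypes[assign[g]]
        ctrl = prof[0]
        if any(p / ctrl >= min_fold or p / ctrl <= 1.0 / min_fold for p in prof[1:]):
            differential.add(g)
    truth = ExpressionTruth(tuple(conditions), assign, dict(archetypes), differential)
    return counts, lengths, totals, truth


# ---------------------------------------------------------------------------
# One-call bundle: every pipeline input with ground truth
# ---------------------------------------------------------------------------


def simulate_bundle(
    outdir: str | Path,
    seed: int = 0,
    spec: Optional[FamilySpec] = None,
    noise_sd: float = 0.0,
    elements_per_gene: int = 3,
):
    """Write a complete synthetic input bundle for the pipeline.

    Emits proteins.fasta, cds.fasta, genes.gff3, domains.tsv,
    promoters.fasta, counts/lengths/totals TSVs, a ready-to-run
    config.yaml, and the ground truth (ground_truth.json,
    planted_elements.tsv, expression_truth.json). Returns
    (SyntheticFamily, planted elements, ExpressionTruth).
    """
    import pandas as pd

    from .promoters import load_element_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from dataclasses import replace as _replace

    spec = spec or FamilySpec(seed=seed)
    if spec.seed != seed:
        spec = _replace(spec, seed=seed)
    family = generate_family(spec)
    family.write(outdir)

    elements = load_element_table()
    family_ids = [g for g, t in family.ground_truth.genes.items() if t.has_motif]
    plan = {
        g: [elements[(i + k * 7) % len(elements)].name for k in range(elements_per_gene)]
        for i, g in enumerate(family_ids)
    }
    promoter_records, planted = generate_promoters(family_ids, elements, plan, seed)
    from .sequence_io import write_fasta

    write_fasta(promoter_records, outdir / "promoters.fasta")
    pd.DataFrame([asdict(p) for p in planted]).to_csv(
        outdir / "planted_elements.tsv", sep="\t", index=False
    )

    counts, lengths, totals, xtruth = generate_expression(
        family_ids, noise_sd=noise_sd, seed=seed
    )
    counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    lengths.rename("length_bp").to_csv(outdir / "lengths.tsv", sep="\t", index_label="gene_id")
    totals.rename("mapped_fragments").to_csv(outdir / "totals.tsv", sep="\t", index_label="condition")
    (outdir / "expression_truth.json").write_text(
        json.dumps(
            {
                "conditions": list(xtruth.conditions),
                "archetype_of": xtruth.archetype_of,
                "differential": sorted(xtruth.differential),
            },
            indent=1,
        )
    )

    config = {
        "proteins": str(outdir / "proteins.fasta"),
        "cds": str(outdir / "cds.fasta"),
        "gff3": str(outdir / "genes.gff3"),
        "domains": str(outdir / "domains.tsv"),
        "promoters": str(outdir / "promoters.fasta"),
        "counts": str(outdir / "counts.tsv"),
        "lengths": str(outdir / "lengths.tsv"),
        "totals": str(outdir / "totals.tsv"),
        "stages": ["identify", "structure", "evolution", "promoters", "expression"],
        "output_dir": str(outdir / "results"),
        "seed": seed,
    }
    import yaml

    (outdir / "config.yaml").write_text(yaml.safe_dump(config))
    return family, planted, xtruth
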