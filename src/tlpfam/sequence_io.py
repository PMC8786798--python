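"""Sequence and annotation I/O plus gene-nomenclature parsing.

Everything downstream of this module works with :class:`SequenceRecord`,
:class:`GeneModel` and :class:`GeneIdentity` rather than raw file handles.
Coordinates are stored 1-based inclusive, exactly as they appear in GFF3;
any half-open arithmetic is local to the operation that needs it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
DNA_ALPHABET = set("ACGT") | {"N"}

Alphabet = Literal["protein", "dna"]


class SequenceIOError(ValueError):
    """Raised on malformed FASTA/GFF3 input or invalid identifiers."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein or nucleotide sequence.

    Residues are stored uppercase; ``X`` (protein) and ``N`` (dna) are
    accepted as unknowns and flagged via :attr:`has_ambiguous`.
    """

    id: str
    residues: str
    alphabet: Alphabet = "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceIOError(f"empty sequence for record {self.id!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise SequenceIOError(
                    f"illegal {self.alphabet} character {ch!r} at position {pos} "
                    f"in record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def has_ambiguous(self) -> bool:
        unknown = "X" if self.alphabet == "protein" else "N"
        return unknown in self.residues


@dataclass
class GeneModel:
    """Gene coordinates and exon/CDS layout for one representative transcript.

    ``exons`` and ``cds_segments`` are kept in transcription order: ascending
    genomic coordinate on the + strand, descending on the - strand. CDS
    segments carry the annotated phase as a third element (or ``None``).
    """

    gene_id: str
    chromosome: str
    strand: Literal["+", "-"]
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_segments: list[tuple[int, int, Optional[int]]] = field(default_factory=list)
    subgenome: Optional[str] = None  # "A" / "B" / "D" for hexaploid genomes

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SequenceIOError(f"{self.gene_id}: gene start > end")
        for s, e in self.exons:
            if s > e:
                raise SequenceIOError(f"{self.gene_id}: exon start > end ({s},{e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise SequenceIOError(f"{self.gene_id}: overlapping exons")
        if self.exons:
            lo = min(s for s, _ in self.exons)
            hi = max(e for _, e in self.exons)
            for s, e, *_ in self.cds_segments:
                if s < lo or e > hi:
                    raise SequenceIOError(
                        f"{self.gene_id}: CDS segment ({s},{e}) outside exon span"
                    )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, *_ in self.cds_segments)

    @property
    def exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def chromosome_number(self) -> Optional[str]:
        """Numeric part of a wheat-style chromosome name ('5A' -> '5')."""
        m = re.match(r"(\d+)", self.chromosome)
        return m.group(1) if m else None


_GENE_ID_RE = re.compile(
    r"^(?P<prefix>[A-Z][a-z])TLP(?P<index>[1-9]\d*)"
    r"(?:-(?P<sub>[ABD])(?P<copy>\d+)?)?$"
)

#: Printed variants in the literature that do not follow the grammar.
GENE_ID_ALIASES = {"BdTLPK1": "BdTLP1", "BdTLPK2": "BdTLP2"}


@dataclass(frozen=True)
class GeneIdentity:
    """Parsed TLP gene symbol, e.g. TaTLP15-B2 -> (Ta, 15, B2)."""

    species_prefix: str
    family_index: int
    subgenome_tag: Optional[str] = None

    def format(self) -> str:
        base = f"{self.species_prefix}TLP{self.family_index}"
        return f"{base}-{self.subgenome_tag}" if self.subgenome_tag else base

    @property
    def subgenome(self) -> Optional[str]:
        return self.subgenome_tag[0] if self.subgenome_tag else None


def parse_gene_id(id_string: str) -> GeneIdentity:
    """Parse ``<Prefix>TLP<k>`` or ``<Prefix>TLP<k>-<S><copy?>`` symbols.

    Homeolog candidates share ``family_index`` and differ in the subgenome
    tag. Known typographic aliases (``BdTLPK1``) are resolved through an
    explicit table rather than by loosening the grammar.
    """
    canonical = GENE_ID_ALIASES.get(id_string, id_string)
    m = _GENE_ID_RE.match(canonical)
    if m is None:
        raise SequenceIOError(f"unparseable gene id: {id_string!r}")
    sub = m.group("sub")
    copy = m.group("copy")
    tag = (sub + copy) if (sub and copy) else sub
    return GeneIdentity(m.group("prefix"), int(m.group("index")), tag)


def format_gene_id(identity: GeneIdentity) -> str:
    return identity.format()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: Alphabet = "protein") -> list[SequenceRecord]:
    """Read a (possibly empty) multi-record FASTA file.

    Residues are uppercased; duplicate ids and illegal characters raise
    :class:`SequenceIOError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceIOError(f"duplicate FASTA id: {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq), alphabet, desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records wrapped at ``width`` columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon/CDS features).

    One representative transcript is kept per gene: the one with the longest
    total CDS, ties broken by lexicographically smallest transcript id.
    Exons of - strand genes are returned in transcription order (descending
    genomic coordinate). ``subgenome`` is inferred from wheat-style
    chromosome names ending in A/B/D.
    """
    text = Path(path).read_text()
    if not text.startswith("##gff-version 3"):
        raise SequenceIOError(f"{path}: missing ##gff-version 3 pragma")

    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise SequenceIOError(f"{path}:{lineno}: expected 9 columns")
        chrom, _src, ftype, start, end, _score, strand, phase, attrs = cols
        start_i, end_i = int(start), int(end)
        a = _gff_attributes(attrs)
        if ftype == "gene":
            gid = a.get("ID")
            if gid is None:
                raise SequenceIOError(f"{path}:{lineno}: gene without ID")
            genes[gid] = dict(chrom=chrom, strand=strand, start=start_i, end=end_i)
        elif ftype == "mRNA":
            tid, parent = a.get("ID"), a.get("Parent")
            if tid is None or parent is None:
                raise SequenceIOError(f"{path}:{lineno}: mRNA missing ID/Parent")
            transcripts[tid] = dict(gene=parent, exons=[], cds=[])
        elif ftype in ("exon", "CDS"):
            parent = a.get("Parent")
            if parent is None:
                raise SequenceIOError(f"{path}:{lineno}: {ftype} missing Parent")
            for tid in parent.split(","):
                if tid not in transcripts:
                    raise SequenceIOError(
                        f"{path}:{lineno}: Parent {tid!r} refers to unknown mRNA"
                    )
                if ftype == "exon":
                    transcripts[tid]["exons"].append((start_i, end_i))
                else:
                    ph = None if phase == "." else int(phase)
                    transcripts[tid]["cds"].append((start_i, end_i, ph))

    # representative transcript per gene: longest CDS, then smallest id
    by_gene: dict[str, list[str]] = {}
    for tid, t in transcripts.items():
        by_gene.setdefault(t["gene"], []).append(tid)

    models = []
    for gid, ginfo in genes.items():
        tids = by_gene.get(gid, [])
        if not tids:
            continue
        best = min(
            tids,
            key=lambda tid: (
                -sum(e - s + 1 for s, e, _ in transcripts[tid]["cds"]),
                tid,
            ),
        )
        t = transcripts[best]
        reverse = ginfo["strand"] == "-"
        exons = sorted(t["exons"], reverse=reverse)
        cds = sorted(t["cds"], reverse=reverse)
        sub = ginfo["chrom"][-1] if re.fullmatch(r"\d+[ABD]", ginfo["chrom"]) else None
        models.append(
            GeneModel(
                gene_id=gid,
                chromosome=ginfo["chrom"],
                strand=ginfo["strand"],
                start=ginfo["start"],
                end=ginfo["end"],
                exons=exons,
                cds_segments=cds,
                subgenome=sub,
            )
        )
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path, source: str = "tlpfam") -> None:
    """Emit gene/mRNA/exon/CDS features, one transcript per gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            base = f"{m.chromosome}\t{source}"
            attrs = f"ID={m.gene_id}"
            fh.write(f"{base}\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n")
            tid = f"{m.gene_id}.1"
            fh.write(
                f"{base}\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={m.gene_id}\n"
            )
            for s, e in sorted(m.exons):
                fh.write(f"{base}\texon\t{s}\t{e}\t.\t{m.strand}\t.\tParent={tid}\n")
            for s, e, ph in sorted((c[0], c[1], c[2]) for c in m.cds_segments):
                ph_s = "." if ph is None else str(ph)
                fh.write(f"{base}\tCDS\t{s}\t{e}\t.\t{m.strand}\t{ph_s}\tParent={tid}\n")
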