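"""Promoter extraction and degenerate cis-regulatory element scanning.

A 1.5 kb window upstream of the initiation codon is scanned on both strands
against a small, user-replaceable table of IUPAC consensus elements grouped
into four functional categories: growth and development, light, hormone,
and stress response.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from .sequence_io import GeneModel, SequenceRecord

Category = Literal["growth_development", "light", "hormone", "stress"]
CATEGORIES: tuple[Category, ...] = ("growth_development", "light", "hormone", "stress")

#: IUPAC nucleotide degeneracy codes. A sequence 'N' (unknown base) matches
#: only a pattern 'N'; unknowns never satisfy an informative pattern symbol.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CisElement:
    name: str
    iupac_pattern: str
    category: Category
    hormone_subclass: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.iupac_pattern) < 4:
            raise ValueError(f"{self.name}: pattern shorter than 4 bases")
        for ch in self.iupac_pattern:
            if ch not in IUPAC:
                raise ValueError(f"{self.name}: invalid IUPAC code {ch!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")

    @property
    def regex(self) -> re.Pattern:
        body = "".join(f"[{IUPAC[c]}]" for c in self.iupac_pattern)
        return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


def load_element_table(path: str | Path | None = None) -> list[CisElement]:
    """Load a cis-element TSV (name, iupac_pattern, category, subclass);
    with no path, the bundled table of elements commonly reported in cereal
    TLP promoters is returned."""
    if path is None:
        src = resources.files("tlpfam.data").joinpath("cis_elements.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    idx = {name: i for i, name in enumerate(header)}
    elements = []
    for ln in lines[1:]:
        cols = ln.split("\t")
        sub = cols[idx["subclass"]].strip() if "subclass" in idx and len(cols) > idx["subclass"] else ""
        elements.append(
            CisElement(
                name=cols[idx["name"]],
                iupac_pattern=cols[idx["iupac_pattern"]].upper(),
                category=cols[idx["category"]],  # type: ignore[arg-type]
                hormone_subclass=sub or None,
            )
        )
    return elements


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    record: SequenceRecord  # promoter in 5'->3' reading orientation
    chrom_start: int  # 1-based genomic span the window was cut from
    chrom_end: int
    strand: Literal["+", "-"]
    truncated: bool


def extract_promoter(
    model: GeneModel,
    genome: dict[str, SequenceRecord | str],
    window: int = 1500,
) -> PromoterWindow:
    """Cut the upstream window ending just before the initiation codon.

    On the + strand this is ``[cds_start - window, cds_start - 1]``; on the
    - strand the reverse complement of ``[cds_end + 1, cds_end + window]``.
    Windows hitting the chromosome boundary are truncated and flagged.
    """
    if model.chromosome not in genome:
        raise KeyError(f"chromosome {model.chromosome!r} not in genome")
    chrom_obj = genome[model.chromosome]
    chrom = chrom_obj.residues if isinstance(chrom_obj, SequenceRecord) else chrom_obj.upper()
    if not model.cds_segments:
        raise ValueError(f"{model.gene_id}: no CDS to anchor the promoter")
    first_cds = model.cds_segments[0]  # transcription order
    if model.strand == "+":
        atg = first_cds[0]
        start = max(1, atg - window)
        end = atg - 1
        seq = chrom[start - 1 : end]
        truncated = (atg - window) < 1
    else:
        atg_end = first_cds[1]
        start = atg_end + 1
        end = min(len(chrom), atg_end + window)
        seq = reverse_complement(chrom[start - 1 : end])
        truncated = end < atg_end + window
    if not seq:
        raise ValueError(f"{model.gene_id}: empty promoter window")
    rec = SequenceRecord(f"{model.gene_id}_promoter", seq, "dna")
    return PromoterWindow(model.gene_id, rec, start, end, model.strand, truncated)


@dataclass(frozen=True)
class ElementHit:
    gene_id: str
    element_name: str
    strand: Literal["+", "-"]
    start: int  # 1-based position within the promoter window
    end: int
    matched_seq: str  # satisfies the pattern (reverse-complemented for -)


def scan_elements(
    promoter: PromoterWindow | SequenceRecord,
    elements: Sequence[CisElement],
    both_strands: bool = True,
) -> list[ElementHit]:
    """All (overlapping) element matches in a promoter, on both strands by
    default. Coordinates are always reported on the promoter's forward
    coordinate system; - strand hits store the reverse-complement slice
    that satisfies the pattern."""
    if isinstance(promoter, PromoterWindow):
        gene_id, seq = promoter.gene_id, promoter.record.residues
    else:
        gene_id, seq = promoter.id, promoter.residues
    length = len(seq)
    rc = reverse_complement(seq)
    hits: list[ElementHit] = []
    for element in elements:
        pat = element.regex
        for m in pat.finditer(seq):
            frag = m.group(1)
            s = m.start() + 1
            hits.append(ElementHit(gene_id, element.name, "+", s, s + len(frag) - 1, frag))
        if both_strands:
            for m in pat.finditer(rc):
                frag = m.group(1)
                e = length - m.start()
                hits.append(
                    ElementHit(gene_id, element.name, "-", e - len(frag) + 1, e, frag)
                )
    hits.sort(key=lambda h: (h.start, h.end, h.element_name, h.strand))
    return hits


def categorize_hits(
    hits: Iterable[ElementHit], elements: Sequence[CisElement]
) -> dict[str, dict[Category, int]]:
    """Per-gene hit counts in the four functional categories."""
    cat_of = {e.name: e.category for e in elements}
    out: dict[str, dict[Category, int]] = {}
    for h in hits:
        per_gene = out.setdefault(h.gene_id, {c: 0 for c in CATEGORIES})
        per_gene[cat_of[h.element_name]] += 1
    return out
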