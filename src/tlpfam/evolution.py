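"""Molecular-evolution core: codon alignment by back-translation, the
Nei–Gojobori (1986) Ka/Ks estimator with Jukes–Cantor correction,
synonymous-clock divergence times, and Tajima's (1993) relative-rate test.

Conventions (documented, and fixed across the package):

* Synonymous/non-synonymous site fractions per codon count each of the
  three possible nucleotide changes at each position; changes creating a
  stop codon count as non-synonymous (the original NG86 site definition).
* Observed differences between a codon pair are averaged with equal weight
  over all minimal mutational pathways, excluding pathways that pass
  through a stop codon; if every pathway is blocked, all pathways are used.
* Proportions are corrected with Jukes–Cantor d = -(3/4) ln(1 - (4/3) p);
  p >= 3/4 is reported as saturated rather than as a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Optional, Sequence

from scipy.stats import chi2 as _chi2

from .rounding import round_half_up
from .sequence_io import SequenceRecord

NUCLEOTIDES = "TCAG"

#: Standard genetic code (DNA codons; '*' = stop).
GENETIC_CODE = {
    t1 + t2 + t3: aa
    for t1, row in zip(
        NUCLEOTIDES,
        [
            "FFLLSSSSYY**CC*W",
            "LLLLPPPPHHQQRRRR",
            "IIIMTTTTNNKKSSRR",
            "VVVVAAAADDEEGGGG",
        ],
    )
    for t2, quartet in zip(NUCLEOTIDES, [row[i : i + 4] for i in range(0, 16, 4)])
    for t3, aa in zip(NUCLEOTIDES, quartet)
}
STOP_CODONS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}
GAP_CODON = "---"


def translate_cds(cds: str) -> str:
    """Translate a CDS (length divisible by 3) with the standard code;
    codons containing N translate to X."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        out.append("X" if "N" in codon else GENETIC_CODE[codon])
    return "".join(out)


# ---------------------------------------------------------------------------
# Back-translation (protein alignment -> codon alignment)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonAlignment:
    """Aligned codon columns for two or more sequences; gap codons are
    '---'. Removing gaps reproduces each input CDS minus any terminal stop."""

    ids: tuple[str, ...]
    codons: tuple[tuple[str, ...], ...]  # one codon row per id

    def __post_init__(self) -> None:
        ncol = {len(row) for row in self.codons}
        if len(ncol) > 1:
            raise ValueError("codon rows differ in column count")

    @property
    def n_columns(self) -> int:
        return len(self.codons[0]) if self.codons else 0

    def row(self, seq_id: str) -> tuple[str, ...]:
        return self.codons[self.ids.index(seq_id)]

    def degapped(self, seq_id: str) -> str:
        return "".join(c for c in self.row(seq_id) if c != GAP_CODON)

    def to_nucleotides(self) -> dict[str, str]:
        """Flatten to aligned nucleotide strings (gap codon -> '---')."""
        return {i: "".join(row) for i, row in zip(self.ids, self.codons)}


def backtranslate(
    protein_alignment: Sequence[tuple[str, str]],
    cds_records: dict[str, SequenceRecord | str],
) -> CodonAlignment:
    """Thread each CDS onto its aligned protein (PAL2NAL-style).

    ``protein_alignment`` is a list of (id, gapped protein) pairs; each CDS
    must be 3x the ungapped protein length, or 3x + 3 with a trailing stop
    codon (stripped). A CDS that does not translate to its protein raises,
    naming the id and the offending codon position.
    """
    ids = []
    rows = []
    ncols = {len(gapped) for _, gapped in protein_alignment}
    if len(ncols) > 1:
        raise ValueError(f"aligned proteins differ in column count: {sorted(ncols)}")
    for seq_id, gapped in protein_alignment:
        if seq_id not in cds_records:
            raise KeyError(f"no CDS provided for {seq_id!r}")
        cds_obj = cds_records[seq_id]
        cds = cds_obj.residues if isinstance(cds_obj, SequenceRecord) else cds_obj.upper()
        protein = gapped.replace("-", "")
        if len(cds) == 3 * len(protein) + 3:
            tail = cds[-3:]
            if tail not in STOP_CODONS:
                raise ValueError(
                    f"{seq_id}: CDS is 3 codons + protein length but does not "
                    f"end in a stop codon ({tail})"
                )
            cds = cds[:-3]
        elif len(cds) != 3 * len(protein):
            raise ValueError(
                f"{seq_id}: CDS length {len(cds)} does not match protein "
                f"length {len(protein)} (expected 3x or 3x+3)"
            )
        row = []
        k = 0
        for aa in gapped:
            if aa == "-":
                row.append(GAP_CODON)
                continue
            codon = cds[3 * k : 3 * k + 3]
            observed = "X" if "N" in codon else GENETIC_CODE[codon]
            if observed == "*":
                raise ValueError(f"{seq_id}: internal stop codon at codon {k + 1}")
            if aa != observed and aa != "X" and observed != "X":
                raise ValueError(
                    f"{seq_id}: codon {k + 1} ({codon}) translates to "
                    f"{observed}, protein has {aa}"
                )
            row.append(codon)
            k += 1
        ids.append(seq_id)
        rows.append(tuple(row))
    return CodonAlignment(tuple(ids), tuple(rows))


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------


def _site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts for one codon."""
    syn = 0.0
    aa = GENETIC_CODE[codon]
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:  # stop mutants are non-synonymous
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


_SITE_TABLE = {c: _site_fractions(c) for c in GENETIC_CODE if c not in STOP_CODONS}


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two codons, averaged
    with equal weight over minimal mutational pathways; pathways through a
    stop codon are excluded (all pathways are used if every one is blocked)."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    blocked_results = []
    for order in permutations(diff_pos):
        cur = codon_a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (blocked_results if blocked else results).append((sd, nd))
    pool = results or blocked_results
    sd = sum(r[0] for r in pool) / len(pool)
    nd = sum(r[1] for r in pool) / len(pool)
    return sd, nd


_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    key = (codon_a, codon_b)
    if key not in _DIFF_CACHE:
        _DIFF_CACHE[key] = _pathway_differences(codon_a, codon_b)
    return _DIFF_CACHE[key]


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a proportion of differing sites."""
    if p >= 0.75:
        raise ValueError("proportion >= 3/4: distance saturated")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) or 0.0


Selection = Literal["purifying", "neutral", "positive"]


def classify_selection(omega: float) -> Selection:
    if omega < 1.0:
        return "purifying"
    if omega > 1.0:
        return "positive"
    return "neutral"


@dataclass(frozen=True)
class KaKsResult:
    ka: Optional[float]  # None when saturated
    ks: Optional[float]
    omega: Optional[float]  # None when ks == 0 or either distance saturated
    selection: Optional[Selection]
    usable_codons: int
    syn_sites: float
    nonsyn_sites: float
    syn_differences: float
    nonsyn_differences: float

    @property
    def ka_saturated(self) -> bool:
        return self.ka is None

    @property
    def ks_saturated(self) -> bool:
        return self.ks is None


def _usable_columns(row_a: Sequence[str], row_b: Sequence[str]):
    for ca, cb in zip(row_a, row_b):
        if GAP_CODON in (ca, cb) or "N" in ca or "N" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        yield ca, cb


def ng86_kaks(alignment: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori (1986) Ka and Ks for a pairwise codon alignment.

    Codon columns containing a gap, an N, or a stop codon in either
    sequence are skipped and do not count toward ``usable_codons``.
    """
    if len(alignment.ids) != 2:
        raise ValueError("ng86_kaks expects a pairwise alignment")
    row_a, row_b = alignment.codons
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    usable = 0
    for ca, cb in _usable_columns(row_a, row_b):
        usable += 1
        sa, na = _SITE_TABLE[ca]
        sb, nb = _SITE_TABLE[cb]
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        dsd, dnd = _codon_differences(ca, cb)
        sd += dsd
        nd += dnd
    if usable == 0:
        raise ValueError("no usable codon columns")
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = None if ps >= 0.75 else jukes_cantor(ps)
    ka = None if pn >= 0.75 else jukes_cantor(pn)
    omega = None
    selection = None
    if ka is not None and ks is not None and ks > 0.0:
        omega = ka / ks
        selection = classify_selection(omega)
    return KaKsResult(ka, ks, omega, selection, usable, s_sites, n_sites, sd, nd)


# ---------------------------------------------------------------------------
# Divergence time
# ---------------------------------------------------------------------------

#: Synonymous clock rate assumed for grasses, substitutions/site/year.
CEREAL_RATE_R = 6.5e-9


@dataclass(frozen=True)
class DivergenceEstimate:
    t_mya: float  # reported to 1 decimal
    rate_r: float
    t_years: float


def divergence_time(ks: float, rate_r: float = CEREAL_RATE_R) -> DivergenceEstimate:
    """Age of a duplication under a synonymous clock: T = Ks / (2 r)."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    years = ks / (2.0 * rate_r)
    return DivergenceEstimate(round_half_up(years / 1e6, 1), rate_r, years)


# ---------------------------------------------------------------------------
# Tajima relative-rate test
# ---------------------------------------------------------------------------


def chi2_sf(x: float, df: int = 1) -> float:
    """Upper-tail probability of the chi-squared distribution."""
    if x < 0:
        raise ValueError("chi-squared statistic must be non-negative")
    return float(_chi2.sf(x, df))


@dataclass(frozen=True)
class TajimaResult:
    nt: int  # sites identical in all three sequences
    na: int  # unique differences in lineage A
    nb: int  # unique differences in lineage B
    chi2: float
    p: float


_SKIP_SYMBOLS = {"-", "N", "X", "?"}


def tajima_relative_rate(a: str, b: str, outgroup: str) -> TajimaResult:
    """Tajima's (1993) 1-degree relative-rate test of lineages A and B
    against an outgroup, on three equal-length aligned sequences.

    Per column: identical in all three -> nt; A differs while B equals the
    outgroup -> na; B differs while A equals the outgroup -> nb; columns
    where all three differ, or where A = B differ jointly from the
    outgroup, contribute to none of the counts. Columns containing a gap or
    ambiguity symbol in any sequence are skipped. chi2 = (na-nb)^2/(na+nb)
    with 1 df; p = 1 when na + nb = 0.
    """
    if not (len(a) == len(b) == len(outgroup)):
        raise ValueError("sequences must be aligned to equal lengths")
    nt = na = nb = 0
    for x, y, o in zip(a.upper(), b.upper(), outgroup.upper()):
        if {x, y, o} & _SKIP_SYMBOLS:
            continue
        if x == y == o:
            nt += 1
        elif x != y:
            if y == o:
                na += 1
            elif x == o:
                nb += 1
    if na + nb == 0:
        return TajimaResult(nt, na, nb, 0.0, 1.0)
    stat = (na - nb) ** 2 / (na + nb)
    return TajimaResult(nt, na, nb, stat, chi2_sf(stat, 1))
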