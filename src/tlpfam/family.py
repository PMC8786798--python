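"""Family-level structure: similarity edges, duplicate pairs, homeolog
groups, chromosome distribution and exon/intron architecture.

Percent identity is defined over the columns of one canonical optimal global
alignment (Gotoh affine-gap dynamic programming, BLOSUM62, gap open 10 /
extend 0.5) with a fixed tie-break order, so results are deterministic and
independently recomputable. Columns in terminal gap overhangs, and columns
containing an unknown residue (X/N), are excluded from the identity
denominator.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import networkx as nx
import numpy as np
from numba import njit

from .sequence_io import GeneModel, SequenceRecord

GAP_OPEN = 10.0  # cost of the first residue of a gap
GAP_EXTEND = 0.5  # cost of each further residue

#: BLOSUM62 (standard half-bit matrix), indexed by residue order below.
_AA_ORDER = "ARNDCQEGHILKMFPSTWYVX"
_BLOSUM62_ROWS = [
    # A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V   X
    [ 4, -1, -2, -2,  0, -1, -1,  0, -2, -1, -1, -1, -1, -2, -1,  1,  0, -3, -2,  0, 0],
    [-1,  5,  0, -2, -3,  1,  0, -2,  0, -3, -2,  2, -1, -3, -2, -1, -1, -3, -2, -3, 0],
    [-2,  0,  6,  1, -3,  0,  0,  0,  1, -3, -3,  0, -2, -3, -2,  1,  0, -4, -2, -3, 0],
    [-2, -2,  1,  6, -3,  0,  2, -1, -1, -3, -4, -1, -3, -3, -1,  0, -1, -4, -3, -3, 0],
    [ 0, -3, -3, -3,  9, -3, -4, -3, -3, -1, -1, -3, -1, -2, -3, -1, -1, -2, -2, -1, 0],
    [-1,  1,  0,  0, -3,  5,  2, -2,  0, -3, -2,  1,  0, -3, -1,  0, -1, -2, -1, -2, 0],
    [-1,  0,  0,  2, -4,  2,  5, -2,  0, -3, -3,  1, -2, -3, -1,  0, -1, -3, -2, -2, 0],
    [ 0, -2,  0, -1, -3, -2, -2,  6, -2, -4, -4, -2, -3, -3, -2,  0, -2, -2, -3, -3, 0],
    [-2,  0,  1, -1, -3,  0,  0, -2,  8, -3, -3, -1, -2, -1, -2, -1, -2, -2,  2, -3, 0],
    [-1, -3, -3, -3, -1, -3, -3, -4, -3,  4,  2, -3,  1,  0, -3, -2, -1, -3, -1,  3, 0],
    [-1, -2, -3, -4, -1, -2, -3, -4, -3,  2,  4, -2,  2,  0, -3, -2, -1, -2, -1,  1, 0],
    [-1,  2,  0, -1, -3,  1,  1, -2, -1, -3, -2,  5, -1, -3, -1,  0, -1, -3, -2, -2, 0],
    [-1, -1, -2, -3, -1,  0, -2, -3, -2,  1,  2, -1,  5,  0, -2, -1, -1, -1, -1,  1, 0],
    [-2, -3, -3, -3, -2, -3, -3, -3, -1,  0,  0, -3,  0,  6, -4, -2, -2,  1,  3, -1, 0],
    [-1, -2, -2, -1, -3, -1, -1, -2, -2, -3, -3, -1, -2, -4,  7, -1, -1, -4, -3, -2, 0],
    [ 1, -1,  1,  0, -1,  0,  0,  0, -1, -2, -2,  0, -1, -2, -1,  4,  1, -3, -2, -2, 0],
    [ 0, -1,  0, -1, -1, -1, -1, -2, -2, -1, -1, -1, -1, -2, -1,  1,  5, -2, -2,  0, 0],
    [-3, -3, -4, -4, -2, -2, -3, -2, -2, -3, -2, -3, -1,  1, -4, -3, -2, 11,  2, -3, 0],
    [-2, -2, -2, -3, -2, -1, -2, -3,  2, -1, -1, -2, -1,  3, -3, -2, -2,  2,  7, -1, 0],
    [ 0, -3, -3, -3, -1, -2, -2, -3, -3,  3,  1, -2,  1, -1, -2, -2,  0, -3, -1,  4, 0],
    [ 0,  0,  0,  0,  0,  0,  0,  0,  0,  0,  0,  0,  0,  0,  0,  0,  0,  0,  0,  0, 0],
]
BLOSUM62 = np.array(_BLOSUM62_ROWS, dtype=np.float64)
_AA_INDEX = {aa: i for i, aa in enumerate(_AA_ORDER)}

_NEG_INF = -1e30


@njit(cache=False)
def _gotoh_fill(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG_INF)
    X = np.full((n + 1, m + 1), _NEG_INF)  # a_i aligned to gap (gap in b)
    Y = np.full((n + 1, m + 1), _NEG_INF)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + s
            x = M[i - 1, j] - gap_open
            if X[i - 1, j] - gap_extend > x:
                x = X[i - 1, j] - gap_extend
            if Y[i - 1, j] - gap_open > x:
                x = Y[i - 1, j] - gap_open
            X[i, j] = x
            y = M[i, j - 1] - gap_open
            if X[i, j - 1] - gap_open > y:
                y = X[i, j - 1] - gap_open
            if Y[i, j - 1] - gap_extend > y:
                y = Y[i, j - 1] - gap_extend
            Y[i, j] = y
    return M, X, Y


def _encode(seq: str) -> np.ndarray:
    # N only occurs in nucleotide input; map unknowns to the X row
    return np.array([_AA_INDEX.get(ch, _AA_INDEX["X"]) for ch in seq], dtype=np.int64)


def global_align(a: str, b: str) -> tuple[str, str, float]:
    """Canonical optimal global alignment of two protein sequences.

    Ties are broken by matrix preference M (substitution) > X (gap in b) >
    Y (gap in a), applied both at the terminus and at every traceback step;
    this fixed order is part of the operation's contract.
    """
    ea, eb = _encode(a), _encode(b)
    M, X, Y = _gotoh_fill(ea, eb, BLOSUM62, GAP_OPEN, GAP_EXTEND)
    i, j = len(a), len(b)
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))  # argmax keeps first max
    score = float([M[i, j], X[i, j], Y[i, j]][state])
    out_a: list[str] = []
    out_b: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == 0:
            s = BLOSUM62[ea[i - 1], eb[j - 1]]
            prev = M[i, j] - s
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if abs(M[i, j] - prev) < tol:
                state = 0
            elif abs(X[i, j] - prev) < tol:
                state = 1
            else:
                state = 2
        elif state == 1:
            cur = X[i, j]
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            if abs(M[i, j] - GAP_OPEN - cur) < tol:
                state = 0
            elif abs(X[i, j] - GAP_EXTEND - cur) < tol:
                state = 1
            else:
                state = 2
        else:
            cur = Y[i, j]
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
            if abs(M[i, j] - GAP_OPEN - cur) < tol:
                state = 0
            elif abs(X[i, j] - GAP_OPEN - cur) < tol:
                state = 1
            else:
                state = 2
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score


def identity_from_alignment(aln_a: str, aln_b: str) -> float:
    """Percent identity over alignment columns, excluding terminal gap
    overhangs and columns containing an unknown residue."""
    ncol = len(aln_a)
    lead = 0
    while lead < ncol and (aln_a[lead] == "-" or aln_b[lead] == "-"):
        lead += 1
    trail = ncol
    while trail > lead and (aln_a[trail - 1] == "-" or aln_b[trail - 1] == "-"):
        trail -= 1
    matches = columns = 0
    for x, y in zip(aln_a[lead:trail], aln_b[lead:trail]):
        if "X" in (x, y) or "N" in (x, y):
            continue
        columns += 1
        if x == y and x != "-":
            matches += 1
    if columns == 0:
        return 0.0
    return 100.0 * matches / columns


def align_three(a: str, b: str, outgroup: str) -> tuple[str, str, str]:
    """Three-way alignment by transitive merge anchored on ``a``.

    ``a`` is aligned pairwise to ``b`` and to ``outgroup``; the two pairwise
    alignments are merged column-wise on the shared ``a`` coordinates.
    Insertion columns (gap in ``a``) from the a-b alignment are emitted
    before those from the a-outgroup alignment at the same anchor position.
    """
    ab_a, ab_b, _ = global_align(a, b)
    ao_a, ao_o, _ = global_align(a, outgroup)
    out_a: list[str] = []
    out_b: list[str] = []
    out_o: list[str] = []
    i = j = 0
    while i < len(ab_a) or j < len(ao_a):
        if i < len(ab_a) and ab_a[i] == "-":
            out_a.append("-")
            out_b.append(ab_b[i])
            out_o.append("-")
            i += 1
        elif j < len(ao_a) and ao_a[j] == "-":
            out_a.append("-")
            out_b.append("-")
            out_o.append(ao_o[j])
            j += 1
        else:
            out_a.append(ab_a[i])
            out_b.append(ab_b[i])
            out_o.append(ao_o[j])
            i += 1
            j += 1
    return "".join(out_a), "".join(out_b), "".join(out_o)


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Global-alignment percent identity between two proteins (symmetric)."""
    # align in a fixed operand order so the canonical alignment (and hence
    # the reported identity) cannot depend on argument order
    if a.residues <= b.residues:
        aln_a, aln_b, _ = global_align(a.residues, b.residues)
    else:
        aln_b, aln_a, _ = global_align(b.residues, a.residues)
    return identity_from_alignment(aln_a, aln_b)


# ---------------------------------------------------------------------------
# Similarity edges and duplicate pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimilarityEdge:
    gene_a: str  # lexicographically smaller id
    gene_b: str
    identity_pct: float
    coverage_pct: float = 100.0
    best_hit_a_to_b: bool = False
    best_hit_b_to_a: bool = False

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            raise ValueError("edges are stored with gene_a < gene_b")
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity must be in [0, 100]")

    @property
    def mutual_best(self) -> bool:
        return self.best_hit_a_to_b and self.best_hit_b_to_a


def build_similarity_edges(proteins: Sequence[SequenceRecord]) -> list[SimilarityEdge]:
    """All-vs-all identities with bidirectional best-hit flags."""
    ids = [p.id for p in proteins]
    ident: dict[tuple[str, str], float] = {}
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            a, b = sorted((ids[i], ids[j]))
            ident[(a, b)] = pairwise_identity(proteins[i], proteins[j])
    best: dict[str, str] = {}
    for g in ids:
        partners = [(o, ident[tuple(sorted((g, o)))]) for o in ids if o != g]
        if partners:
            # highest identity, ties by id order
            best[g] = min(partners, key=lambda t: (-t[1], t[0]))[0]
    edges = []
    for (a, b), pct in sorted(ident.items()):
        edges.append(
            SimilarityEdge(
                a, b, pct,
                best_hit_a_to_b=best.get(a) == b,
                best_hit_b_to_a=best.get(b) == a,
            )
        )
    return edges


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    identity_pct: float
    kind: Optional[Literal["tandem", "segmental"]] = None
    chrom_a: Optional[str] = None
    chrom_b: Optional[str] = None
    genomic_gap_bp: Optional[int] = None
    intervening_genes: Optional[int] = None
    unplaced: bool = False


def find_duplicates(
    edges: Sequence[SimilarityEdge], identity_min: float = 80.0
) -> list[DuplicatePair]:
    """Disjoint duplicate pairs: identity >= threshold, mutual best hits,
    greedy by descending identity (ties by id order), one pair per gene."""
    qualifying = [e for e in edges if e.identity_pct >= identity_min and e.mutual_best]
    qualifying.sort(key=lambda e: (-e.identity_pct, e.gene_a, e.gene_b))
    used: set[str] = set()
    pairs = []
    for e in qualifying:
        if e.gene_a in used or e.gene_b in used:
            continue
        used.update((e.gene_a, e.gene_b))
        pairs.append(DuplicatePair(e.gene_a, e.gene_b, e.identity_pct))
    return pairs


UNPLACED_PREFIXES = ("scaffold", "Un", "un", "ctg")


def classify_duplication(
    pair: DuplicatePair,
    gene_models: dict[str, GeneModel],
    tandem_gap_bp: int = 100_000,
    tandem_max_intervening: int = 5,
) -> DuplicatePair:
    """Label a duplicate pair tandem or segmental.

    Tandem requires the same chromosome AND (genomic gap <= ``tandem_gap_bp``
    OR at most ``tandem_max_intervening`` family genes in between); anything
    else on placed chromosomes is segmental. Pairs involving an unplaced
    scaffold keep kind=None and are flagged.
    """
    ma, mb = gene_models[pair.gene_a], gene_models[pair.gene_b]
    if any(m.chromosome.startswith(UNPLACED_PREFIXES) for m in (ma, mb)):
        return replace(pair, chrom_a=ma.chromosome, chrom_b=mb.chromosome, unplaced=True)
    gap = None
    intervening = None
    kind: Literal["tandem", "segmental"] = "segmental"
    if ma.chromosome == mb.chromosome:
        lo, hi = sorted((ma, mb), key=lambda m: m.start)
        gap = max(0, hi.start - lo.end - 1)
        intervening = sum(
            1
            for g in gene_models.values()
            if g.chromosome == ma.chromosome
            and g.gene_id not in (pair.gene_a, pair.gene_b)
            and g.start > lo.end
            and g.end < hi.start
        )
        if gap <= tandem_gap_bp or intervening <= tandem_max_intervening:
            kind = "tandem"
    return replace(
        pair,
        kind=kind,
        chrom_a=ma.chromosome,
        chrom_b=mb.chromosome,
        genomic_gap_bp=gap,
        intervening_genes=intervening,
    )


# ---------------------------------------------------------------------------
# Homeolog groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HomeologGroup:
    group_id: int
    members: tuple[str, ...]  # gene ids, sorted


def group_homeologs(
    edges: Sequence[SimilarityEdge],
    gene_models: dict[str, GeneModel],
    identity_min: float = 90.0,
) -> list[HomeologGroup]:
    """Homeolog groups across the A/B/D subgenomes of a hexaploid genome.

    An edge qualifies when identity >= threshold and the two genes sit on the
    same chromosome number but different subgenomes; groups are the maximal
    cliques of the qualifying graph (cliques, not connected components, so a
    promiscuous member cannot chain unrelated triplets together). Singletons
    are not reported.
    """
    g = nx.Graph()
    for e in edges:
        if e.identity_pct < identity_min:
            continue
        ma, mb = gene_models.get(e.gene_a), gene_models.get(e.gene_b)
        if ma is None or mb is None:
            continue
        if ma.subgenome is None or mb.subgenome is None:
            continue
        if ma.subgenome == mb.subgenome:
            continue
        if ma.chromosome_number != mb.chromosome_number:
            continue
        g.add_edge(e.gene_a, e.gene_b)
    groups = sorted(
        (tuple(sorted(c)) for c in nx.find_cliques(g) if len(c) >= 2)
    )
    return [HomeologGroup(i + 1, members) for i, members in enumerate(groups)]


# ---------------------------------------------------------------------------
# Gene architecture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneArchitecture:
    gene_id: str
    exon_count: int
    intron_phases: tuple[int, ...]
    intronless: bool


def intron_phases(model: GeneModel) -> GeneArchitecture:
    """Intron phases from CDS segment lengths in transcription order.

    Phase of intron i = cumulative CDS length 5' of the intron, mod 3. A
    total CDS length not divisible by 3 triggers a warning but phases are
    still reported.
    """
    if not model.cds_segments:
        raise ValueError(f"{model.gene_id}: no CDS segments")
    lengths = [e - s + 1 for s, e, *_ in model.cds_segments]
    if sum(lengths) % 3 != 0:
        warnings.warn(
            f"{model.gene_id}: CDS length {sum(lengths)} not a multiple of 3",
            stacklevel=2,
        )
    phases = []
    cumulative = 0
    for ln in lengths[:-1]:
        cumulative += ln
        phases.append(cumulative % 3)
    n_exons = len(model.cds_segments)
    return GeneArchitecture(model.gene_id, n_exons, tuple(phases), n_exons == 1)


def chromosome_distribution(
    gene_models: Sequence[GeneModel],
) -> tuple[Counter, list[str]]:
    """Counts of placed genes per chromosome plus the unplaced gene ids."""
    counts: Counter = Counter()
    unplaced = []
    for m in gene_models:
        if m.chromosome.startswith(UNPLACED_PREFIXES):
            unplaced.append(m.gene_id)
        else:
            counts[m.chromosome] += 1
    return counts, unplaced
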