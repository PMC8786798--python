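"""TLP candidate screening and protein-level characterization.

Thaumatin-like proteins (PR-5 family) are diagnosed by the thaumatin
signature motif ``G-X-[GF]-X-C-X-T-[GA]-D-C-X(1,2)-G-X(2,3)-C`` and carry a
conserved set of cysteines (16 in long/L-type, 10 in small/S-type proteins)
plus the acidic-cleft REDDD motif. This module screens candidate proteins
for the complete signature, classifies long vs small forms, and computes
length/MW/pI profiles.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .sequence_io import SequenceRecord

# ---------------------------------------------------------------------------
# Motif patterns (PROSITE-like)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PositionSpec:
    """One position of a PROSITE-style pattern.

    kind 'fixed': exactly ``residues``; 'any': any residue; 'set': one of
    ``residues``; 'run': a variable-length run of any residues of length
    ``min_len``..``max_len``.
    """

    kind: Literal["fixed", "any", "set", "run"]
    residues: str = ""
    min_len: int = 1
    max_len: int = 1


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    positions: tuple[PositionSpec, ...]

    def __post_init__(self) -> None:
        if not any(p.kind == "fixed" for p in self.positions):
            raise ValueError(f"motif {self.name!r} has no fixed position")
        for p in self.positions:
            if p.kind == "run" and p.min_len > p.max_len:
                raise ValueError(f"motif {self.name!r}: run with min > max")

    @classmethod
    def from_prosite(cls, pattern: str, name: str) -> "MotifDefinition":
        """Parse 'G-X-[GF]-X(1,2)-C' style patterns."""
        specs: list[PositionSpec] = []
        for tok in pattern.replace(" ", "").split("-"):
            if not tok:
                continue
            m = re.fullmatch(r"[Xx]\((\d+),(\d+)\)", tok)
            if m:
                specs.append(PositionSpec("run", "", int(m.group(1)), int(m.group(2))))
            elif tok.upper() == "X":
                specs.append(PositionSpec("any"))
            elif re.fullmatch(r"\[[A-Z]+\]", tok):
                specs.append(PositionSpec("set", tok[1:-1]))
            elif re.fullmatch(r"[A-Z]", tok):
                specs.append(PositionSpec("fixed", tok))
            else:
                raise ValueError(f"cannot parse pattern token {tok!r} in {name!r}")
        return cls(name, tuple(specs))


THAUMATIN_SIGNATURE = MotifDefinition.from_prosite(
    "G-X-[GF]-X-C-X-T-[GA]-D-C-X(1,2)-G-X(2,3)-C", name="thaumatin_signature"
)


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int  # 1-based inclusive
    end: int
    matched_substring: str


def _match_at(seq: str, pos: int, specs: Sequence[PositionSpec], i: int) -> Optional[int]:
    """Return end offset (exclusive) of the shortest match of specs[i:] at pos."""
    if i == len(specs):
        return pos
    spec = specs[i]
    if spec.kind == "run":
        # non-greedy: shortest satisfying expansion first
        for n in range(spec.min_len, spec.max_len + 1):
            if pos + n > len(seq):
                break
            end = _match_at(seq, pos + n, specs, i + 1)
            if end is not None:
                return end
        return None
    if pos >= len(seq):
        return None
    ch = seq[pos]
    if spec.kind == "fixed" and ch != spec.residues:
        return None
    if spec.kind == "set" and ch not in spec.residues:
        return None
    return _match_at(seq, pos + 1, specs, i + 1)


def scan_signature(protein: SequenceRecord, motif: MotifDefinition = THAUMATIN_SIGNATURE) -> list[MotifHit]:
    """Report a hit at every start position where the motif matches.

    For variable-length runs the shortest satisfying expansion at each
    start is reported (non-greedy PROSITE semantics); overlapping hits at
    distinct starts are allowed. Hits are sorted by start.
    """
    seq = protein.residues
    hits: list[MotifHit] = []
    for start in range(len(seq)):
        end = _match_at(seq, start, motif.positions, 0)
        if end is not None:
            hits.append(MotifHit(motif.name, start + 1, end, seq[start:end]))
    return hits


def screen_candidates(
    proteins: Sequence[SequenceRecord], motif: MotifDefinition = THAUMATIN_SIGNATURE
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Split candidates into accepted (>= 1 complete signature hit) and
    rejected-with-reason, mirroring the screen that keeps only proteins with
    a complete family signature."""
    accepted, rejected = [], []
    for p in proteins:
        if scan_signature(p, motif):
            accepted.append(p)
        else:
            rejected.append((p, f"no complete {motif.name} match"))
    return accepted, rejected


# ---------------------------------------------------------------------------
# Physicochemical profile
# ---------------------------------------------------------------------------

#: Average (isotope-abundance-weighted) residue masses in Da, i.e. amino acid
#: monomer mass minus one water; free peptide mass = sum + WATER_MASS.
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153
_MEAN_RESIDUE_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)

#: Bjellqvist-style pKa values used for the charge model behind pI.
PKA_POSITIVE = {"NTERM": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"CTERM": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}


def compute_mw(protein: SequenceRecord) -> float:
    """Average molecular weight in kDa (sum of residue masses + one water).

    Unknown residues (X) contribute the mean residue mass, with a warning.
    """
    if not protein.residues:
        raise ValueError("cannot compute MW of an empty sequence")
    total = WATER_MASS
    for ch in protein.residues:
        if ch == "X":
            warnings.warn(
                f"{protein.id}: unknown residue X counted at mean residue mass",
                stacklevel=2,
            )
            total += _MEAN_RESIDUE_MASS
        else:
            total += RESIDUE_MASS[ch]
    return total / 1000.0


def net_charge(protein: SequenceRecord, ph: float) -> float:
    """Henderson–Hasselbalch net charge at the given pH."""
    counts: dict[str, int] = {}
    for ch in protein.residues:
        counts[ch] = counts.get(ch, 0) + 1
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["NTERM"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["CTERM"] - ph))
    for aa, pka in PKA_POSITIVE.items():
        if aa != "NTERM" and aa in counts:
            charge += counts[aa] / (1.0 + 10 ** (ph - pka))
    for aa, pka in PKA_NEGATIVE.items():
        if aa != "CTERM" and aa in counts:
            charge -= counts[aa] / (1.0 + 10 ** (pka - ph))
    return charge


def compute_pi(protein: SequenceRecord, tol: float = 1e-4) -> float:
    """Isoelectric point: pH at which net charge is zero, by bisection on
    [0, 14] to |charge| < tol."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(protein, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass(frozen=True)
class PhysicochemicalProfile:
    length_aa: int
    mw_kda: float
    pi: float
    cysteine_count: int


def physicochemical_profile(protein: SequenceRecord) -> PhysicochemicalProfile:
    return PhysicochemicalProfile(
        length_aa=len(protein),
        mw_kda=compute_mw(protein),
        pi=compute_pi(protein),
        cysteine_count=protein.residues.count("C"),
    )


# ---------------------------------------------------------------------------
# Long vs small classification
# ---------------------------------------------------------------------------

#: Thaumatin-domain length ranges are disjoint between long (202-217 aa) and
#: small (134-154 aa) forms, so length is the primary criterion; MW (< 22 kDa)
#: is a secondary guard on the small call.
LONG_DOMAIN_MIN_AA = 180
SMALL_MW_MAX_KDA = 22.0


@dataclass(frozen=True)
class SizeClassification:
    size_class: Literal["long", "small", "ambiguous"]
    basis_mw_kda: float
    basis_domain_len_aa: int


def classify_size(profile: PhysicochemicalProfile, domain_len_aa: int) -> SizeClassification:
    """Classify long vs small TLP from thaumatin-domain length with MW as a
    secondary guard; cases satisfying neither rule come back ambiguous."""
    if domain_len_aa <= 0:
        raise ValueError("domain length must be positive")
    if domain_len_aa >= LONG_DOMAIN_MIN_AA:
        cls = "long"
    elif profile.mw_kda < SMALL_MW_MAX_KDA:
        cls = "small"
    else:
        cls = "ambiguous"
    return SizeClassification(cls, profile.mw_kda, domain_len_aa)


def domain_span(
    protein: SequenceRecord,
    annotated: Optional[tuple[int, int]] = None,
    flank: int = 60,
) -> tuple[int, int, bool]:
    """Thaumatin-domain span (1-based inclusive) for a protein.

    Uses the externally supplied annotation when available; otherwise falls
    back to the signature-hit footprint extended by ``flank`` residues on
    each side, returning proxy=True to flag the approximation.
    """
    if annotated is not None:
        s, e = annotated
        return s, e, False
    hits = scan_signature(protein)
    if not hits:
        raise ValueError(f"{protein.id}: no annotation and no signature hit")
    s = max(1, hits[0].start - flank)
    e = min(len(protein), hits[-1].end + flank)
    return s, e, True


# ---------------------------------------------------------------------------
# REDDD motif check
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReddCheck:
    present: bool
    residues_found: tuple[tuple[int, str], ...]  # (alignment column, residue)
    substitutions: tuple[tuple[str, str], ...]  # (expected, observed)


REDDD = "REDDD"


def check_reddd(
    query_id: str,
    reference_alignment: dict[str, str],
    reddd_columns: Sequence[int],
    field_gap: str = "-",
) -> ReddCheck:
    """Inspect the five REDDD alignment columns for one aligned query.

    ``reference_alignment`` maps sequence id to aligned (gapped) residues;
    ``reddd_columns`` gives the five 1-based alignment columns annotated on
    the reference thaumatin. Present requires exactly R,E,D,D,D; anything
    else (including a gap) is reported as a substitution.
    """
    if len(reddd_columns) != 5:
        raise ValueError("REDDD check needs exactly 5 annotated columns")
    if query_id not in reference_alignment:
        raise KeyError(f"query {query_id!r} missing from alignment")
    aligned = reference_alignment[query_id]
    found = []
    subs = []
    for expected, col in zip(REDDD, reddd_columns):
        observed = aligned[col - 1] if col - 1 < len(aligned) else field_gap
        found.append((col, observed))
        if observed != expected:
            subs.append((expected, observed))
    return ReddCheck(not subs, tuple(found), tuple(subs))
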