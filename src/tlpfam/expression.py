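"""Expression analytics: FPKM, fold-change filters, hierarchical clustering,
2^-ddCt qPCR fold changes with replicate statistics, and expression-based
fate calls for duplicate gene pairs."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr, ttest_ind


@dataclass
class ExpressionMatrix:
    """FPKM values, genes x conditions (a thin wrapper over a DataFrame)."""

    values: pd.DataFrame  # index = gene ids, columns = condition ids
    replicate_map: Optional[dict[str, str]] = None  # condition -> group

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.columns.duplicated().any():
            raise ValueError("condition ids must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.values.columns)


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    totals: pd.Series,
) -> ExpressionMatrix:
    """Fragments per kilobase of exon per million mapped fragments:
    fpkm[g, s] = counts[g, s] * 1e9 / (length[g] * total[s])."""
    lengths = lengths.reindex(counts.index)
    totals = totals.reindex(counts.columns)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("every gene needs a positive exonic length")
    if (totals <= 0).any() or totals.isna().any():
        raise ValueError("every sample needs a positive mapped-fragment total")
    vals = counts.astype(float).mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    return ExpressionMatrix(vals)


@dataclass(frozen=True)
class DifferentialCall:
    gene_id: str
    folds: dict[str, float]  # treated condition -> fold vs control
    flagged: bool


def differential_filter(
    matrix: ExpressionMatrix,
    control_cond: str,
    treated_conds: Sequence[str],
    min_fold: float = 2.0,
    pseudo: float = 0.01,
) -> list[DifferentialCall]:
    """Flag genes with a >= ``min_fold`` change (up or down) in at least one
    treated condition. Fold = (treated + pseudo) / (control + pseudo); the
    pseudocount keeps zero-FPKM genes finite."""
    df = matrix.values
    if control_cond not in df.columns:
        raise KeyError(f"control condition {control_cond!r} absent")
    for c in treated_conds:
        if c not in df.columns:
            raise KeyError(f"treated condition {c!r} absent")
    calls = []
    ctrl = df[control_cond] + pseudo
    for gene in df.index:
        folds = {
            c: float((df.at[gene, c] + pseudo) / ctrl[gene]) for c in treated_conds
        }
        flagged = any(f >= min_fold or f <= 1.0 / min_fold for f in folds.values())
        calls.append(DifferentialCall(gene, folds, flagged))
    return calls


@dataclass(frozen=True)
class ClusterResult:
    linkage_matrix: np.ndarray
    labels: Optional[dict[str, int]]  # gene -> group (1..k) when k given


def cluster_genes(matrix: ExpressionMatrix, k: Optional[int] = None) -> ClusterResult:
    """Agglomerative clustering of genes on log2(FPKM + 1) rows with
    Euclidean distance and average (UPGMA) linkage; cut into k flat groups
    when k is given. Tie-breaking follows the deterministic order of the
    linkage implementation."""
    df = matrix.values
    if len(df) < 2:
        raise ValueError("clustering needs at least 2 genes")
    logged = np.log2(df.values + 1.0)
    if np.allclose(logged, logged[0]):
        warnings.warn("constant expression matrix: single cluster", stacklevel=2)
        lk = linkage(logged, method="average", metric="euclidean")
        labels = {g: 1 for g in df.index} if k else None
        return ClusterResult(lk, labels)
    lk = linkage(logged, method="average", metric="euclidean")
    labels = None
    if k is not None:
        flat = fcluster(lk, t=k, criterion="maxclust")
        labels = {g: int(c) for g, c in zip(df.index, flat)}
    return ClusterResult(lk, labels)


# ---------------------------------------------------------------------------
# qPCR (2^-ddCt)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrRow:
    gene_id: str
    condition: str
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not (0.0 < v < 45.0):
                raise ValueError(f"Ct value {v} outside (0, 45)")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass
class QpcrTable:
    rows: list[QpcrRow]
    control_condition: str

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, control_condition: str) -> "QpcrTable":
        rows = [
            QpcrRow(
                str(r.gene_id), str(r.condition), int(r.replicate),
                float(r.ct_target), float(r.ct_reference),
            )
            for r in df.itertuples()
        ]
        return cls(rows, control_condition)

    def delta_cts(self, gene_id: str, condition: str) -> list[float]:
        return [
            r.delta_ct
            for r in self.rows
            if r.gene_id == gene_id and r.condition == condition
        ]


SIGNIFICANCE_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> Literal["ns", "*", "**", "***"]:
    for cutoff, stars in SIGNIFICANCE_THRESHOLDS:
        if p <= cutoff:
            return stars  # type: ignore[return-value]
    return "ns"


@dataclass(frozen=True)
class FoldChangeResult:
    gene_id: str
    condition: str
    fold: float
    log2_fold: float
    sd: Optional[float]  # SD of per-replicate fold changes
    p_value: Optional[float]
    significance: Optional[str]
    insufficient_replicates: bool = False


def ddct_fold(qpcr: QpcrTable, control_cond: Optional[str] = None) -> list[FoldChangeResult]:
    """Relative quantification by the delta-delta Ct method.

    Per replicate, dCt = Ct(target) - Ct(reference); ddCt = mean dCt(treated)
    - mean dCt(control); fold = 2^-ddCt. The SD is that of the per-replicate
    folds 2^-(dCt_i - mean dCt control); p comes from a two-tailed
    equal-variance t-test on the two replicate dCt samples. With fewer than
    2 replicates on either side the fold is still reported, flagged, with
    statistics omitted.
    """
    control = control_cond or qpcr.control_condition
    results = []
    pairs = sorted({(r.gene_id, r.condition) for r in qpcr.rows if r.condition != control})
    for gene, cond in pairs:
        treated = qpcr.delta_cts(gene, cond)
        ctrl = qpcr.delta_cts(gene, control)
        if not treated or not ctrl:
            continue
        ddct = float(np.mean(treated) - np.mean(ctrl))
        fold = 2.0 ** (-ddct)
        if len(treated) >= 2 and len(ctrl) >= 2:
            rep_folds = [2.0 ** (-(t - float(np.mean(ctrl)))) for t in treated]
            sd = float(np.std(rep_folds, ddof=1))
            p = float(ttest_ind(treated, ctrl, equal_var=True).pvalue)
            results.append(
                FoldChangeResult(gene, cond, fold, math.log2(fold), sd, p, significance_stars(p))
            )
        else:
            results.append(
                FoldChangeResult(gene, cond, fold, math.log2(fold), None, None, None, True)
            )
    return results


# ---------------------------------------------------------------------------
# Duplicate-pair expression fate
# ---------------------------------------------------------------------------

Fate = Literal["retention", "pseudo_functionalization", "neo_functionalization"]


@dataclass(frozen=True)
class DuplicateFate:
    gene_a: str
    gene_b: str
    fate: Optional[Fate]
    correlation: Optional[float]
    expressed_a: bool
    expressed_b: bool
    correlation_undefined: bool = False


def duplicate_fate(
    matrix: ExpressionMatrix,
    pair: tuple[str, str],
    floor: float = 1.0,
    r_min: float = 0.6,
) -> DuplicateFate:
    """Classify a duplicate pair from its expression profiles.

    A gene is expressed when its maximum FPKM reaches ``floor``. Exactly one
    expressed gene -> pseudo-functionalization; both expressed with Pearson
    r >= ``r_min`` across conditions -> retention of function; both
    expressed but divergent profiles -> neo-functionalization. Neither
    expressed -> no call. Zero-variance profiles leave the correlation
    undefined; the call then rests on the expression floors alone and is
    flagged.
    """
    a, b = pair
    for g in pair:
        if g not in matrix.values.index:
            raise KeyError(f"gene {g!r} not in expression matrix")
    prof_a = matrix.values.loc[a].values.astype(float)
    prof_b = matrix.values.loc[b].values.astype(float)
    exp_a = bool(prof_a.max() >= floor)
    exp_b = bool(prof_b.max() >= floor)
    if exp_a != exp_b:
        return DuplicateFate(a, b, "pseudo_functionalization", None, exp_a, exp_b)
    if not (exp_a or exp_b):
        return DuplicateFate(a, b, None, None, False, False)
    if np.std(prof_a) == 0.0 or np.std(prof_b) == 0.0:
        return DuplicateFate(a, b, "retention", None, True, True, correlation_undefined=True)
    r = float(pearsonr(prof_a, prof_b).statistic)
    fate: Fate = "retention" if r >= r_min else "neo_functionalization"
    return DuplicateFate(a, b, fate, r, True, True)
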