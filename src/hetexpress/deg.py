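"""Fold-change DEG calling and cross-intersection set logic.

Differential expression between a hybrid and each of its parents is judged by
a *signed* (symmetric) fold change on pseudocounted abundances:

    fc(a, b) =  (a + c) / (b + c)   if a >= b
             = -(b + c) / (a + c)   otherwise

so fc is never inside the open interval (-1, 1), equal abundances give exactly
1, and fc(a, b) = -fc(b, a) whenever a != b.  A gene is called up-regulated
when fc >= 2 and down-regulated when fc <= -2 (thresholds inclusive and
configurable).  Genes differentially expressed in the same direction versus
BOTH parents of a cross form that cross's "common" sets; genes common to both
crosses with concordant direction form the "universal" sets, the object of
interest when two independent hybrid combinations are compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DEFAULT_PSEUDOCOUNT, DataError, ExpressionMatrix, TrioDesign

DEFAULT_UP_THRESHOLD = 2.0
DEFAULT_DOWN_THRESHOLD = -2.0


def signed_fold_change(a: float, b: float, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Symmetric signed ratio of two non-negative abundances.

    >>> signed_fold_change(8, 2, 0.01)
    3.985074626865672
    """
    if a < 0 or b < 0:
        raise DataError("abundances must be non-negative")
    if pseudocount <= 0:
        raise DataError("pseudocount must be positive")
    x = a + pseudocount
    y = b + pseudocount
    return x / y if x >= y else -y / x


@dataclass(frozen=True)
class DegCall:
    gene_id: str
    comparison: tuple[str, str]  # (hybrid_id, parent_id)
    signed_fc: float
    call: str  # "up" | "down" | "ns"


def _call(fc: float, up_threshold: float, down_threshold: float) -> str:
    if fc >= up_threshold:
        return "up"
    if fc <= down_threshold:
        return "down"
    return "ns"


def call_degs(
    expr: ExpressionMatrix,
    trio: TrioDesign,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
    min_abundance: float = 0.0,
) -> list[DegCall]:
    """Call DEGs for both hybrid-vs-parent comparisons of one trio.

    Returns exactly two calls per gene, in gene order then (maternal,
    paternal) comparison order.  ``min_abundance`` optionally requires the
    larger operand of a comparison to reach an expression floor before a
    non-"ns" call is made (no floor by default).
    """
    if up_threshold < 1 or down_threshold > -1:
        raise ValueError("thresholds must satisfy up >= 1 and down <= -1")
    expr.check_trio(trio)
    pc = expr.pseudocount
    calls: list[DegCall] = []
    hybrid = expr.values[trio.hybrid_id]
    for parent_id in (trio.maternal_id, trio.paternal_id):
        parent = expr.values[parent_id]
        for gene_id, h, p in zip(expr.gene_ids, hybrid.to_numpy(), parent.to_numpy()):
            fc = signed_fold_change(float(h), float(p), pc)
            call = _call(fc, up_threshold, down_threshold)
            if call != "ns" and max(h, p) < min_abundance:
                call = "ns"
            calls.append(DegCall(gene_id, (trio.hybrid_id, parent_id), fc, call))
    # interleave back to per-gene order: (gene, vs maternal), (gene, vs paternal)
    n = len(expr.gene_ids)
    return [calls[i + j * n] for i in range(n) for j in range(2)]


def common_degs_per_cross(
    calls: list[DegCall], trio: TrioDesign
) -> tuple[set[str], set[str]]:
    """Genes up (resp. down) versus BOTH parents of one cross.

    A gene up versus one parent and down versus the other belongs to neither
    set.
    """
    comparisons = {
        (trio.hybrid_id, trio.maternal_id),
        (trio.hybrid_id, trio.paternal_id),
    }
    by_gene: dict[str, dict[tuple[str, str], str]] = {}
    for c in calls:
        if c.comparison in comparisons:
            by_gene.setdefault(c.gene_id, {})[c.comparison] = c.call
    common_up: set[str] = set()
    common_down: set[str] = set()
    for gene_id, per_cmp in by_gene.items():
        if len(per_cmp) != 2:
            raise DataError(
                f"gene {gene_id!r}: calls must cover both comparisons of cross {trio.cross_id!r}"
            )
        directions = set(per_cmp.values())
        if directions == {"up"}:
            common_up.add(gene_id)
        elif directions == {"down"}:
            common_down.add(gene_id)
    return common_up, common_down


@dataclass(frozen=True)
class DegSets:
    """Common/universal/discordant DEG sets across two crosses."""

    cross_a_up: frozenset[str]
    cross_a_down: frozenset[str]
    cross_b_up: frozenset[str]
    cross_b_down: frozenset[str]
    universal_up: frozenset[str]
    universal_down: frozenset[str]
    discordant: frozenset[str]
    unique_union_count: int = field(default=0)


def universal_degs(
    cross_a_sets: tuple[set[str], set[str]],
    cross_b_sets: tuple[set[str], set[str]],
) -> DegSets:
    """Intersect the two crosses' common sets.

    universal_up / universal_down are the genes concordantly up / down in
    both crosses; ``discordant`` collects genes common to both crosses with
    opposite directions; ``unique_union_count`` is the number of distinct
    genes in any of the four input sets.
    """
    a_up, a_down = (set(s) for s in cross_a_sets)
    b_up, b_down = (set(s) for s in cross_b_sets)
    for label, up, down in (("A", a_up, a_down), ("B", b_up, b_down)):
        both = up & down
        if both:
            raise DataError(
                f"cross {label}: gene(s) {sorted(both)} appear in both up and down sets"
            )
    return DegSets(
        cross_a_up=frozenset(a_up),
        cross_a_down=frozenset(a_down),
        cross_b_up=frozenset(b_up),
        cross_b_down=frozenset(b_down),
        universal_up=frozenset(a_up & b_up),
        universal_down=frozenset(a_down & b_down),
        discordant=frozenset((a_up & b_down) | (a_down & b_up)),
        unique_union_count=len(a_up | a_down | b_up | b_down),
    )


def library_correlation(expr: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation between genotype libraries on log2(FPKM + c).

    Returns a symmetric genotype x genotype matrix with unit diagonal.  A
    zero-variance library yields NaN entries (flagged with a warning) rather
    than a silent 0.
    """
    if len(expr.gene_ids) < 2:
        raise DataError("library correlation requires at least 2 genes")
    log2 = expr.log2()
    zero_var = log2.columns[log2.std(axis=0).to_numpy() == 0].tolist()
    if zero_var:
        warnings.warn(
            f"zero-variance librar{'y' if len(zero_var)==1 else 'ies'} {zero_var}: "
            "correlation undefined (NaN)",
            stacklevel=2,
        )
    corr = log2.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    for g in zero_var:
        corr.loc[g, :] = np.nan
        corr.loc[:, g] = np.nan
    return corr
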