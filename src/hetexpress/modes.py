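"""Inheritance-mode classification of parent-hybrid expression patterns.

Each gene's expression across the maternal parent (M), hybrid (F1) and
paternal parent (P) is reduced to three pairwise states -- F1 vs M, F1 vs P,
M vs P -- each "higher", "lower" or "equal" by the same inclusive signed
fold-change threshold used for DEG calling (default 2; with a single
expression value per genotype there is no replicate-based test, so "~equal"
means |fc| < threshold).  The state triple, together with an F1-vs-midparent
state, maps each gene into one of 12 classes grouped into coarse modes:

* additive (classes 1, 12): F1 strictly between the parents and ~ equal to
  the mid-parent value (M+P)/2;
* expression-level dominance, ELD (classes 2, 11 paternal; 4, 9 maternal):
  F1 ~ one parent while the parents differ;
* overdominance (classes 5, 6, 8 transgressive up; 3, 7, 10 transgressive
  down): F1 above, resp. below, BOTH parents.

Within each transgressive triple the class number is fixed by the parent
relation (M>P / M~P / M<P, in that order).  Patterns matching none of these
(including no differential expression at all) are class "none".

A coarser per-hybrid rule, used when only the two hybrid-vs-parent fold
changes of a hybrid are known (e.g. for a printed table of universal DEGs):
significant same-signed change versus both parents -> overdominance; versus
exactly one -> dominance; versus neither -> additive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .deg import signed_fold_change
from .io import DEFAULT_PSEUDOCOUNT, ExpressionMatrix, TrioDesign

DEFAULT_MODE_THRESHOLD = 2.0

#: Coarse mode of each of the 12 classes.
COARSE_BY_CLASS: dict[int, str] = {
    1: "additive",
    12: "additive",
    2: "ELD_paternal",
    11: "ELD_paternal",
    4: "ELD_maternal",
    9: "ELD_maternal",
    5: "transgressive_up",
    6: "transgressive_up",
    8: "transgressive_up",
    3: "transgressive_down",
    7: "transgressive_down",
    10: "transgressive_down",
}

COARSE_MODES = (
    "additive",
    "ELD_maternal",
    "ELD_paternal",
    "transgressive_up",
    "transgressive_down",
)


def _state(fc: float, threshold: float) -> str:
    if fc >= threshold:
        return "higher"
    if fc <= -threshold:
        return "lower"
    return "equal"


def pairwise_states(
    maternal: float,
    hybrid: float,
    paternal: float,
    threshold: float = DEFAULT_MODE_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[str, str, str]:
    """States (F1 vs M, F1 vs P, M vs P), each higher/lower/equal."""
    return (
        _state(signed_fold_change(hybrid, maternal, pseudocount), threshold),
        _state(signed_fold_change(hybrid, paternal, pseudocount), threshold),
        _state(signed_fold_change(maternal, paternal, pseudocount), threshold),
    )


@dataclass(frozen=True)
class ModeClassification:
    gene_id: str
    cross_id: str
    class_1_12: int | None  # None <=> "none"
    coarse_mode: str  # one of COARSE_MODES or "none"
    fc_vs_maternal: float
    fc_vs_paternal: float
    fc_parents: float
    fc_vs_midparent: float


def classify_states(
    state_vs_maternal: str,
    state_vs_paternal: str,
    state_parents: str,
    state_vs_midparent: str,
) -> tuple[int | None, str]:
    """Map a state quadruple to (class 1-12 or None, coarse mode)."""
    s1, s2, s3, smp = state_vs_maternal, state_vs_paternal, state_parents, state_vs_midparent
    if s1 == "higher" and s2 == "higher":
        cls = {"higher": 5, "equal": 6, "lower": 8}[s3]
    elif s1 == "lower" and s2 == "lower":
        cls = {"higher": 3, "equal": 7, "lower": 10}[s3]
    elif s3 != "equal":
        if s1 == "equal" and s2 != "equal":
            cls = 4 if s3 == "higher" else 9
        elif s2 == "equal" and s1 != "equal":
            cls = 2 if s3 == "lower" else 11
        elif {s1, s2} == {"higher", "lower"} and smp == "equal":
            cls = 1 if s3 == "higher" else 12
        else:
            return None, "none"
    else:
        return None, "none"
    return cls, COARSE_BY_CLASS[cls]


def classify_12bin(
    maternal: float,
    hybrid: float,
    paternal: float,
    gene_id: str = "",
    cross_id: str = "",
    threshold: float = DEFAULT_MODE_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ModeClassification:
    """Classify one gene's (M, F1, P) abundance triple."""
    fc_m = signed_fold_change(hybrid, maternal, pseudocount)
    fc_p = signed_fold_change(hybrid, paternal, pseudocount)
    fc_mp = signed_fold_change(maternal, paternal, pseudocount)
    midparent = (maternal + paternal) / 2.0
    fc_mid = signed_fold_change(hybrid, midparent, pseudocount)
    cls, coarse = classify_states(
        _state(fc_m, threshold),
        _state(fc_p, threshold),
        _state(fc_mp, threshold),
        _state(fc_mid, threshold),
    )
    return ModeClassification(
        gene_id=gene_id,
        cross_id=cross_id,
        class_1_12=cls,
        coarse_mode=coarse,
        fc_vs_maternal=fc_m,
        fc_vs_paternal=fc_p,
        fc_parents=fc_mp,
        fc_vs_midparent=fc_mid,
    )


def classify_matrix(
    expr: ExpressionMatrix,
    trio: TrioDesign,
    gene_ids: list[str] | None = None,
    threshold: float = DEFAULT_MODE_THRESHOLD,
) -> list[ModeClassification]:
    """Classify every gene (or a subset, e.g. a cross's common DEGs)."""
    expr.check_trio(trio)
    genes = expr.gene_ids if gene_ids is None else list(gene_ids)
    out = []
    for gene_id in genes:
        m, h, p = expr.trio_values(gene_id, trio)
        out.append(
            classify_12bin(
                m, h, p,
                gene_id=gene_id,
                cross_id=trio.cross_id,
                threshold=threshold,
                pseudocount=expr.pseudocount,
            )
        )
    return out


def classify_per_hybrid_coarse(
    fc_vs_maternal: float,
    fc_vs_paternal: float,
    threshold: float = DEFAULT_MODE_THRESHOLD,
) -> str:
    """Coarse per-hybrid label from the two hybrid-vs-parent fold changes.

    Significant (|fc| >= threshold) same-signed change versus both parents ->
    "overdominance"; versus exactly one -> "dominance"; versus neither ->
    "additive"; significant but opposite-signed -> "discordant".
    """
    sig_m = abs(fc_vs_maternal) >= threshold
    sig_p = abs(fc_vs_paternal) >= threshold
    if sig_m and sig_p:
        if (fc_vs_maternal > 0) != (fc_vs_paternal > 0):
            return "discordant"
        return "overdominance"
    if sig_m or sig_p:
        return "dominance"
    return "additive"


@dataclass(frozen=True)
class ModeSummary:
    """Counts and percentages of coarse modes, per cross and pooled.

    ``percentages`` are over classified genes (class != none) and include the
    derived groupings dominance = ELD_maternal + ELD_paternal and
    overdominance = transgressive_up + transgressive_down.
    """

    per_cross_counts: dict[str, dict[str, int]]
    pooled_counts: dict[str, int]
    percentages: dict[str, float]
    n_classified: int
    n_none: int


def mode_summary(classifications: list[ModeClassification]) -> ModeSummary:
    if not classifications:
        raise ValueError("no classifications to summarize")
    per_cross: dict[str, dict[str, int]] = {}
    pooled = {mode: 0 for mode in COARSE_MODES}
    pooled["none"] = 0
    for c in classifications:
        counts = per_cross.setdefault(
            c.cross_id, {**{m: 0 for m in COARSE_MODES}, "none": 0}
        )
        counts[c.coarse_mode] += 1
        pooled[c.coarse_mode] += 1
    n_classified = sum(pooled[m] for m in COARSE_MODES)
    if n_classified:
        pct = {m: 100.0 * pooled[m] / n_classified for m in COARSE_MODES}
    else:
        pct = {m: 0.0 for m in COARSE_MODES}
    pct["dominance"] = pct["ELD_maternal"] + pct["ELD_paternal"]
    pct["overdominance"] = pct["transgressive_up"] + pct["transgressive_down"]
    return ModeSummary(
        per_cross_counts=per_cross,
        pooled_counts=pooled,
        percentages=pct,
        n_classified=n_classified,
        n_none=pooled["none"],
    )


def label_universal_degs(
    fc_table: pd.DataFrame,
    threshold: float = DEFAULT_MODE_THRESHOLD,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the coarse per-hybrid rule to a universal-DEG fold-change table.

    ``fc_table`` is indexed by gene id with four columns: the signed fold
    changes of hybrid 1 versus its two parents and hybrid 2 versus its two
    parents, in that order.  Returns the table with ``label_hybrid1`` /
    ``label_hybrid2`` columns appended, plus summary counts: genes
    overdominant in both hybrids and genes with all-positive / all-negative
    fold changes (consistently up- / down-regulated).
    """
    if fc_table.shape[1] < 4:
        raise ValueError("fold-change table needs 4 columns (2 per hybrid)")
    cols = list(fc_table.columns[:4])
    out = fc_table.copy()
    out["label_hybrid1"] = [
        classify_per_hybrid_coarse(r[cols[0]], r[cols[1]], threshold)
        for _, r in fc_table.iterrows()
    ]
    out["label_hybrid2"] = [
        classify_per_hybrid_coarse(r[cols[2]], r[cols[3]], threshold)
        for _, r in fc_table.iterrows()
    ]
    fcs = fc_table[cols].to_numpy()
    counts = {
        "n_overdominant_both": int(
            ((out["label_hybrid1"] == "overdominance")
             & (out["label_hybrid2"] == "overdominance")).sum()
        ),
        "n_all_up": int((fcs > 0).all(axis=1).sum()),
        "n_all_down": int((fcs < 0).all(axis=1).sum()),
    }
    return out, counts
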