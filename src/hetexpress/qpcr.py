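"""Relative quantification of qPCR data by the 2^-ddCt method.

For each genotype, dCt = Ct(target gene) - Ct(reference gene); for a sample
genotype against a calibrator genotype, ddCt = dCt(sample) - dCt(calibrator)
and the relative expression fold is 2^-ddCt (amplification efficiency fixed
at 2, the method's standard assumption).  Technical replicates are averaged
on the Ct scale before dCt; biological replicates are summarized as the
geometric mean of folds.

``concordance`` checks qPCR fold directions against RNA-seq DEG calls: an
"up" call agrees with fold > 1, "down" with fold < 1, and "ns" with a fold
inside a tolerance band [1/band, band].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .deg import DegCall
from .io import DataError, QpcrRecord

DEFAULT_NS_BAND = 1.5


@dataclass(frozen=True)
class RelativeExpression:
    gene_id: str
    sample_id: str
    calibrator_id: str
    delta_ct_sample: float
    delta_ct_calibrator: float
    ddct: float
    fold: float


def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        {
            "gene_id": r.gene_id,
            "genotype_id": r.genotype_id,
            "ct_target": r.ct_target,
            "ct_reference": r.ct_reference,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def delta_ct(records, gene_id: str, genotype_id: str) -> float:
    """dCt = mean Ct(target) - mean Ct(reference), technical reps averaged."""
    df = _to_frame(records)
    sel = df[(df["gene_id"] == gene_id) & (df["genotype_id"] == genotype_id)]
    if sel.empty:
        raise DataError(f"no qPCR record for gene {gene_id!r} in genotype {genotype_id!r}")
    ct_t = float(sel["ct_target"].mean())
    ct_r = float(sel["ct_reference"].mean())
    if not (math.isfinite(ct_t) and math.isfinite(ct_r)):
        raise DataError(f"non-finite Ct for gene {gene_id!r} in genotype {genotype_id!r}")
    return ct_t - ct_r


def relative_expression(
    records,
    gene_id: str,
    sample_id: str,
    calibrator_id: str,
) -> RelativeExpression:
    """2^-ddCt relative expression of one gene, sample versus calibrator."""
    d_s = delta_ct(records, gene_id, sample_id)
    d_c = delta_ct(records, gene_id, calibrator_id)
    ddct = d_s - d_c
    return RelativeExpression(
        gene_id=gene_id,
        sample_id=sample_id,
        calibrator_id=calibrator_id,
        delta_ct_sample=d_s,
        delta_ct_calibrator=d_c,
        ddct=ddct,
        fold=2.0 ** (-ddct),
    )


def fold_table(
    records,
    sample_id: str,
    calibrator_id: str,
    gene_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Relative-expression folds for many genes, one sample vs calibrator."""
    df = _to_frame(records)
    genes = sorted(df["gene_id"].unique()) if gene_ids is None else list(gene_ids)
    rows = [
        relative_expression(df, g, sample_id, calibrator_id).__dict__ for g in genes
    ]
    return pd.DataFrame(rows)


def summarize_folds(folds: Iterable[float]) -> tuple[float, float, float]:
    """Geometric mean and (min, max) range of biological-replicate folds."""
    arr = np.asarray(list(folds), dtype=float)
    if arr.size == 0 or (arr <= 0).any():
        raise DataError("folds must be a non-empty collection of positive values")
    return float(np.exp(np.log(arr).mean())), float(arr.min()), float(arr.max())


def concordance(
    qpcr_folds: Mapping[str, float],
    rnaseq_calls: Iterable[DegCall] | Mapping[str, str],
    band: float = DEFAULT_NS_BAND,
) -> tuple[pd.DataFrame, float]:
    """Direction agreement between qPCR folds and RNA-seq calls.

    ``rnaseq_calls`` maps gene id -> call, or is an iterable of DegCall (one
    comparison).  Returns a per-gene table and the overall agreement
    fraction over the overlapping genes.
    """
    if band <= 1:
        raise ValueError("ns band must exceed 1")
    if not isinstance(rnaseq_calls, Mapping):
        calls: dict[str, str] = {}
        for c in rnaseq_calls:
            if c.gene_id in calls and calls[c.gene_id] != c.call:
                raise DataError(
                    f"gene {c.gene_id!r}: conflicting calls; pass one comparison at a time"
                )
            calls[c.gene_id] = c.call
    else:
        calls = dict(rnaseq_calls)
    genes = sorted(set(qpcr_folds) & set(calls))
    if not genes:
        raise DataError("no overlap between qPCR genes and RNA-seq calls")
    rows = []
    for g in genes:
        fold = float(qpcr_folds[g])
        call = calls[g]
        if call == "up":
            agree = fold > 1
        elif call == "down":
            agree = fold < 1
        else:
            agree = (1.0 / band) <= fold <= band
        rows.append({"gene_id": g, "fold": fold, "call": call, "agree": bool(agree)})
    table = pd.DataFrame(rows)
    return table, float(table["agree"].mean())
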