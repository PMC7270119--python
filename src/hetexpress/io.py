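"""Tabular input/output and shared domain types.

Every stage of the pipeline works on a handful of small value types: a
:class:`TrioDesign` naming the maternal parent, paternal parent and F1 hybrid
of one cross; a :class:`TraitTrio` holding one trait's phenotypic means for
such a trio; an :class:`ExpressionMatrix` holding a gene x genotype grid of
FPKM-like abundances; and :class:`QpcrRecord` rows of qPCR cycle-threshold
measurements.  This module defines those types, validates them on
construction, and reads/writes the delimited-text tables they live in.

Missing values are treated as errors rather than imputed: an FPKM of 0 and an
absent measurement are different claims, and silently conflating them would
corrupt downstream fold changes.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Pseudocount added to both operands of every abundance ratio so that
#: fold changes are defined for zero-FPKM genes.  Recorded in run metadata.
DEFAULT_PSEUDOCOUNT = 0.01


class DataError(ValueError):
    """A malformed or internally inconsistent input table."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrioDesign:
    """One cross: maternal parent, paternal parent and their F1 hybrid."""

    cross_id: str
    maternal_id: str
    paternal_id: str
    hybrid_id: str

    def __post_init__(self) -> None:
        labels = (self.maternal_id, self.paternal_id, self.hybrid_id)
        if any(not str(x).strip() for x in labels) or not str(self.cross_id).strip():
            raise DataError("trio design labels must be non-empty")
        if len(set(labels)) != 3:
            raise DataError(
                f"trio design {self.cross_id!r}: genotype labels must be distinct, got {labels}"
            )

    @property
    def genotype_ids(self) -> tuple[str, str, str]:
        return (self.maternal_id, self.paternal_id, self.hybrid_id)


@dataclass(frozen=True)
class TraitTrio:
    """One trait's means for the maternal parent, paternal parent and hybrid."""

    trait_name: str
    maternal_mean: float
    paternal_mean: float
    hybrid_mean: float
    unit: str = ""

    def __post_init__(self) -> None:
        for name, value in (
            ("maternal_mean", self.maternal_mean),
            ("paternal_mean", self.paternal_mean),
            ("hybrid_mean", self.hybrid_mean),
        ):
            if not math.isfinite(value):
                raise DataError(f"trait {self.trait_name!r}: {name} is not finite")


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement: target and reference Ct for a gene in a genotype."""

    gene_id: str
    genotype_id: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, value in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not math.isfinite(value) or value <= 0:
                raise DataError(
                    f"qPCR record ({self.gene_id}, {self.genotype_id}): {name} must be finite and positive"
                )


@dataclass(frozen=True)
class ExpressionMatrix:
    """A gene x genotype table of non-negative abundances (FPKM-like).

    ``values`` is a DataFrame indexed by gene id with one column per genotype.
    The matrix carries the pseudocount used when forming ratios so that every
    downstream fold change is computed under the same convention.
    """

    values: pd.DataFrame
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise DataError("pseudocount must be positive")
        df = self.values
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise DataError("empty table")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene id: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate genotype id: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("non-numeric abundance value")
        if np.isnan(arr).any():
            genes = df.index[np.isnan(arr).any(axis=1)].tolist()
            raise DataError(f"missing abundance for genes {genes}")
        if (arr < 0).any():
            genes = df.index[(arr < 0).any(axis=1)].tolist()
            raise DataError(f"negative abundance for genes {genes}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.values.columns)

    def check_trio(self, trio: TrioDesign) -> None:
        missing = [g for g in trio.genotype_ids if g not in self.values.columns]
        if missing:
            raise DataError(
                f"trio {trio.cross_id!r} references unknown genotype id(s) {missing}"
            )

    def trio_values(self, gene_id: str, trio: TrioDesign) -> tuple[float, float, float]:
        """Return (maternal, hybrid, paternal) abundances for one gene."""
        self.check_trio(trio)
        row = self.values.loc[gene_id]
        return (
            float(row[trio.maternal_id]),
            float(row[trio.hybrid_id]),
            float(row[trio.paternal_id]),
        )

    def log2(self) -> pd.DataFrame:
        """log2(value + pseudocount) matrix, e.g. for heat-map export."""
        return np.log2(self.values + self.pseudocount)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _detect_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def read_expression_table(
    path: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a gene x genotype abundance table (TSV or CSV, by extension).

    The first column holds gene ids and the header row genotype ids.
    Duplicated identifiers, negative, non-numeric or missing cells raise
    :class:`DataError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"{path}: empty table")
    try:
        numeric = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: non-numeric abundance value ({exc})") from exc
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    try:
        return ExpressionMatrix(numeric, pseudocount=pseudocount)
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from exc


_TRAIT_COLUMNS = ("cross_id", "trait_name", "maternal_mean", "paternal_mean", "hybrid_mean")


def read_trait_table(path: str, sep: str | None = None) -> list[tuple[TrioDesign, TraitTrio]]:
    """Read a trait table into (TrioDesign, TraitTrio) pairs.

    Required columns: cross_id, trait_name, maternal_mean, paternal_mean,
    hybrid_mean.  Optional columns: unit, maternal_id, paternal_id, hybrid_id
    (genotype labels default to ``<cross>_P1`` / ``<cross>_P2`` / ``<cross>_F1``).
    Zero parental means load fine; they only become errors at heterosis time.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep))
    if df.shape[0] == 0:
        raise DataError(f"{path}: no records")
    missing = [c for c in _TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    out: list[tuple[TrioDesign, TraitTrio]] = []
    for i, row in df.iterrows():
        means = {}
        for col in ("maternal_mean", "paternal_mean", "hybrid_mean"):
            try:
                means[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise DataError(
                    f"{path}: row {i} ({row['cross_id']}, {row['trait_name']}): "
                    f"non-numeric value in column {col!r}"
                ) from exc
        cross = str(row["cross_id"])
        design = TrioDesign(
            cross_id=cross,
            maternal_id=str(row["maternal_id"]) if "maternal_id" in df.columns else f"{cross}_P1",
            paternal_id=str(row["paternal_id"]) if "paternal_id" in df.columns else f"{cross}_P2",
            hybrid_id=str(row["hybrid_id"]) if "hybrid_id" in df.columns else f"{cross}_F1",
        )
        trio = TraitTrio(
            trait_name=str(row["trait_name"]),
            maternal_mean=means["maternal_mean"],
            paternal_mean=means["paternal_mean"],
            hybrid_mean=means["hybrid_mean"],
            unit=str(row["unit"]) if "unit" in df.columns and not pd.isna(row["unit"]) else "",
        )
        out.append((design, trio))
    return out


def read_design_table(path: str, sep: str | None = None) -> list[TrioDesign]:
    """Read a cross-design table: cross_id, maternal_id, paternal_id, hybrid_id."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep))
    required = ("cross_id", "maternal_id", "paternal_id", "hybrid_id")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    if df.shape[0] == 0:
        raise DataError(f"{path}: no records")
    return [
        TrioDesign(str(r.cross_id), str(r.maternal_id), str(r.paternal_id), str(r.hybrid_id))
        for r in df.itertuples()
    ]


def read_qpcr_table(path: str, sep: str | None = None) -> pd.DataFrame:
    """Read a qPCR Ct table.

    Required columns: gene_id, genotype_id, ct_target, ct_reference; an
    optional ``replicate`` column marks technical replicates (averaged on the
    Ct scale downstream).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep))
    required = ("gene_id", "genotype_id", "ct_target", "ct_reference")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    if df.shape[0] == 0:
        raise DataError(f"{path}: no records")
    for col in ("ct_target", "ct_reference"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.isfinite(vals).all() or (vals <= 0).any():
            raise DataError(f"{path}: column {col!r} must be finite positive cycles")
        df[col] = vals
    return df


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

#: Columns used (in priority order) to impose a deterministic row ordering.
_SORT_PRIORITY = ("gene_id", "cross_id", "trait_name", "comparison", "genotype_id", "sample_id")


def write_report(result, path: str, sort: bool = True) -> None:
    """Write a stage result as a deterministic TSV.

    ``result`` may be a DataFrame or an iterable of dataclass-like records
    with a ``_asdict``/``__dict__``.  Rows are sorted by gene id then cross id
    (then any further identifying columns present) so repeated runs produce
    byte-identical files.
    """
    df = _as_frame(result)
    if sort:
        keys = [c for c in _SORT_PRIORITY if c in df.columns]
        if keys:
            df = df.sort_values(keys, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _as_frame(result) -> pd.DataFrame:
    if isinstance(result, pd.DataFrame):
        return result.copy()
    rows = []
    for item in result:
        if hasattr(item, "_asdict"):
            rows.append(item._asdict())
        elif hasattr(item, "__dataclass_fields__"):
            rows.append({k: getattr(item, k) for k in item.__dataclass_fields__})
        elif isinstance(item, dict):
            rows.append(item)
        else:
            raise TypeError(f"cannot tabulate {type(item)!r}")
    return pd.DataFrame(rows)


def write_metadata(metadata: dict, path: str) -> None:
    """Write run metadata (thresholds, pseudocount, seed) as sorted JSON."""
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
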