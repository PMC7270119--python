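"""Mid-parent and high-parent heterosis for phenotypic trait trios.

For a trait measured on both inbred parents and their F1 hybrid,

    MP  = (maternal + paternal) / 2          (mid-parent value)
    HP  = max(maternal, paternal)            (better-parent value)
    MPH = 100 * (F1 - MP) / MP               (mid-parent heterosis, %)
    HPH = 100 * (F1 - HP) / HP               (high-parent / better-parent heterosis, %)

The "better parent" is always the parent with the larger trait mean; whether a
larger value is agronomically desirable (e.g. earliness, where smaller is
better) is metadata, not arithmetic.  Computation is done in full precision;
reports round to 2 decimals, half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .io import TraitTrio, TrioDesign


class UndefinedHeterosisError(ValueError):
    """Raised when the mid- or high-parent value is zero."""


def mid_parent(trio: TraitTrio) -> float:
    return (trio.maternal_mean + trio.paternal_mean) / 2.0


def high_parent(trio: TraitTrio) -> float:
    return max(trio.maternal_mean, trio.paternal_mean)


def mid_parent_heterosis(trio: TraitTrio) -> float:
    """MPH in percent: 100 * (F1 - MP) / MP."""
    mp = mid_parent(trio)
    if mp == 0:
        raise UndefinedHeterosisError(
            f"undefined heterosis: zero mid-parent for trait {trio.trait_name!r}"
        )
    return 100.0 * (trio.hybrid_mean - mp) / mp


def high_parent_heterosis(trio: TraitTrio) -> float:
    """HPH in percent: 100 * (F1 - HP) / HP, HP the larger parental mean."""
    hp = high_parent(trio)
    if hp == 0:
        raise UndefinedHeterosisError(
            f"undefined heterosis: zero high-parent for trait {trio.trait_name!r}"
        )
    return 100.0 * (trio.hybrid_mean - hp) / hp


@dataclass(frozen=True)
class HeterosisResult:
    trait_name: str
    cross_id: str
    mid_parent: float
    high_parent: float
    mph_percent: float
    hph_percent: float


def heterosis_table(
    trait_records: list[tuple[TrioDesign, TraitTrio]],
) -> list[HeterosisResult]:
    """One HeterosisResult per (cross, trait), ordered by trait then cross."""
    if not trait_records:
        raise ValueError("no trait records")
    results = []
    for design, trio in trait_records:
        try:
            mph = mid_parent_heterosis(trio)
            hph = high_parent_heterosis(trio)
        except UndefinedHeterosisError as exc:
            raise UndefinedHeterosisError(
                f"cross {design.cross_id!r}, trait {trio.trait_name!r}: {exc}"
            ) from exc
        results.append(
            HeterosisResult(
                trait_name=trio.trait_name,
                cross_id=design.cross_id,
                mid_parent=mid_parent(trio),
                high_parent=high_parent(trio),
                mph_percent=mph,
                hph_percent=hph,
            )
        )
    results.sort(key=lambda r: (r.trait_name, r.cross_id))
    return results


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed tables conventionally do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def heterosis_frame(results: list[HeterosisResult], ndigits: int = 2) -> pd.DataFrame:
    """Report-ready table with percentages rounded half-up to ``ndigits``."""
    df = pd.DataFrame([r.__dict__ for r in results])
    for col in ("mph_percent", "hph_percent"):
        df[col] = df[col].map(lambda v: round_half_up(v, ndigits))
    return df
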