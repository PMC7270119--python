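"""Bundled example data: a two-cross Easter-lily heterosis experiment.

A published experiment on *Lilium longiflorum* crossed two pairs of inbred
lines (cross A: L2-4 x L2-28 -> hybrid L4-7; cross B: L2-22 x L2-20 ->
hybrid L4-104), measured phenotypic traits on parents and hybrids, and
RNA-sequenced one leaf library per genotype.  This module embeds the small
printed summary tables of that experiment -- trait means, the fold-change
matrix of the 28 universal DEGs with their per-hybrid inheritance labels,
and the Venn counts of the DEG intersections -- as worked examples and test
oracles for the pipeline.  The raw reads are not distributed; the synthetic
generator (:mod:`hetexpress.simulate`) stands in for them.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .io import TraitTrio, TrioDesign

CROSS_A = TrioDesign(cross_id="A", maternal_id="L2-4", paternal_id="L2-28", hybrid_id="L4-7")
CROSS_B = TrioDesign(cross_id="B", maternal_id="L2-22", paternal_id="L2-20", hybrid_id="L4-104")

# trait, unit, cross A (maternal, hybrid, paternal), cross B (maternal, hybrid, paternal)
_TRAITS = [
    ("plant_height", "cm", (37.2, 47.1, 34.7), (39.5, 51.8, 30.6)),
    ("leaf_length", "cm", (12.3, 14.5, 15.5), (13.0, 18.5, 12.2)),
    ("days_to_flowering", "days", (193.0, 184.0, 188.0), (194.0, 183.0, 189.0)),
    ("number_of_flowers", "count", (4.9, 10.3, 5.7), (3.7, 7.5, 3.8)),
    ("flower_diameter", "cm", (14.4, 13.3, 14.0), (13.7, 13.8, 14.3)),
]


def lily_trait_table() -> list[tuple[TrioDesign, TraitTrio]]:
    """Trait means of the lily experiment as (design, trait trio) pairs."""
    out = []
    for trait, unit, (ma, ha, pa), (mb, hb, pb) in _TRAITS:
        out.append((CROSS_A, TraitTrio(trait, ma, pa, ha, unit)))
        out.append((CROSS_B, TraitTrio(trait, mb, pb, hb, unit)))
    return out


# Published MPH/HPH percentages.  The flower-diameter HPH for cross A prints
# -8.27 although the printed means give -7.64; it (and the cross-B value,
# which differs from the means by one rounding step) is marked inconsistent
# and excluded from exact-reproduction checks.
_PUBLISHED_HETEROSIS = """\
trait_name,cross_id,mph_percent,hph_percent,consistent
plant_height,A,31.01,26.61,True
plant_height,B,47.79,31.14,True
leaf_length,A,4.32,-6.45,True
leaf_length,B,46.83,42.31,True
days_to_flowering,A,-3.41,-4.66,True
days_to_flowering,B,-4.44,-5.67,True
number_of_flowers,A,94.34,80.70,True
number_of_flowers,B,100.00,97.37,True
flower_diameter,A,-6.34,-8.27,False
flower_diameter,B,-1.43,-3.49,False
"""


def lily_published_heterosis() -> pd.DataFrame:
    """Printed MPH/HPH values with a consistency flag for the HPH column.

    ``consistent`` is False where the printed HPH cannot be recomputed from
    the printed means at 2-decimal rounding; MPH values are consistent for
    all ten rows.
    """
    return pd.read_csv(StringIO(_PUBLISHED_HETEROSIS))


# 28 universal DEGs: signed fold changes of hybrid 1 (L4-7) vs its parents
# (L2-4, L2-28) and hybrid 2 (L4-104) vs its parents (L2-22, L2-20), with the
# published per-hybrid coarse labels.  Direction: sign shared by all four FCs.
_UNIVERSAL_DEGS = """\
gene_id,fc_h1_vs_p1,fc_h1_vs_p2,fc_h2_vs_p1,fc_h2_vs_p2,direction,label_hybrid1,label_hybrid2
c47423g1i1,2.75,2.69,2.21,2.14,up,overdominance,overdominance
c54944g1i1,2.15,1.60,2.69,2.22,up,dominance,overdominance
c60389g1i1,1.23,1.35,2.75,3.69,up,additive,overdominance
c60389g1i2,1.18,1.14,2.35,3.02,up,additive,overdominance
c49702g1i1,2.96,2.77,4.85,3.18,up,overdominance,overdominance
c52443g1i1,2.27,1.75,7.99,7.26,up,dominance,overdominance
c57602g1i1,2.76,3.22,1.16,1.24,up,overdominance,additive
c59275g1i2,2.20,2.16,5.80,4.39,up,overdominance,overdominance
c62533g1i1,2.46,2.13,1.25,1.27,up,overdominance,additive
c63435g1i2,1.29,1.19,3.97,3.22,up,additive,overdominance
c64671g4i2,1.63,1.39,2.25,2.38,up,additive,overdominance
c60887g1i2,1.87,2.21,2.47,2.79,up,dominance,overdominance
c52384g1i2,-1.97,-2.96,-2.38,-2.18,down,dominance,overdominance
c58513g1i1,-2.63,-4.58,-2.84,-3.66,down,overdominance,overdominance
c47447g1i1,-4.33,-3.18,-1.92,-2.04,down,overdominance,dominance
c63663g3i2,-2.84,-2.49,-2.06,-2.11,down,overdominance,overdominance
c47368g1i1,-3.74,-2.04,-2.32,-2.88,down,overdominance,overdominance
c59731g1i1,-2.76,-4.20,-3.94,-2.22,down,overdominance,overdominance
c47856g3i1,-1.78,-1.66,-2.37,-2.39,down,additive,overdominance
c37944g1i1,-2.41,-5.84,-3.36,-2.88,down,overdominance,overdominance
c55548g2i1,-1.38,-1.45,-2.47,-2.08,down,additive,overdominance
c56718g1i1,-1.74,-1.59,-2.60,-2.71,down,additive,overdominance
c57368g1i1,-1.34,-1.19,-2.26,-2.03,down,additive,overdominance
c60709g3i1,-3.59,-4.70,-1.19,-1.13,down,overdominance,additive
c80430g1i1,-2.91,-4.30,-1.27,-1.27,down,overdominance,additive
c96948g1i1,-2.95,-6.14,-2.62,-1.99,down,overdominance,dominance
c13258g1i1,-2.33,-2.74,-3.25,-2.23,down,overdominance,overdominance
c22243g1i1,-2.83,-2.58,-1.59,-1.18,down,overdominance,additive
"""


def lily_universal_deg_folds() -> pd.DataFrame:
    """Fold-change matrix and published labels of the 28 universal DEGs."""
    df = pd.read_csv(StringIO(_UNIVERSAL_DEGS))
    return df.set_index("gene_id")


#: Venn counts of the lily DEG analysis: per-comparison up/down counts,
#: each cross's common (both-parent, same-direction) counts, and the
#: between-cross overlap structure.
LILY_DEG_COUNTS = {
    "per_comparison": {
        ("L4-7", "L2-4"): {"up": 855, "down": 686},
        ("L4-7", "L2-28"): {"up": 797, "down": 679},
        ("L4-104", "L2-22"): {"up": 848, "down": 786},
        ("L4-104", "L2-20"): {"up": 607, "down": 529},
    },
    "common": {"A": {"up": 276, "down": 189}, "B": {"up": 137, "down": 135}},
    "overlap": {
        "concordant_up": 11,
        "concordant_down": 7,
        "up_a_down_b": 14,
        "down_a_up_b": 2,
    },
}


def example_deg_sets() -> tuple[tuple[set, set], tuple[set, set]]:
    """Synthetic gene-id sets realizing the lily Venn-count structure.

    Builds ((a_up, a_down), (b_up, b_down)) with the published cardinalities
    and overlaps: |a_up| = 276, |a_down| = 189, |b_up| = 137, |b_down| = 135,
    sharing 11 concordant up, 7 concordant down and 14 + 2 discordant genes.
    Gene ids are synthetic placeholders; only the set structure is real.
    """
    ov = LILY_DEG_COUNTS["overlap"]
    common = LILY_DEG_COUNTS["common"]
    counter = iter(range(10**6))

    def fresh(n: int) -> set:
        return {f"set{next(counter):06d}" for _ in range(n)}

    uu = fresh(ov["concordant_up"])
    dd = fresh(ov["concordant_down"])
    ud = fresh(ov["up_a_down_b"])
    du = fresh(ov["down_a_up_b"])
    a_up = uu | ud | fresh(common["A"]["up"] - len(uu) - len(ud))
    a_down = dd | du | fresh(common["A"]["down"] - len(dd) - len(du))
    b_up = uu | du | fresh(common["B"]["up"] - len(uu) - len(du))
    b_down = dd | ud | fresh(common["B"]["down"] - len(dd) - len(ud))
    return (a_up, a_down), (b_up, b_down)
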