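"""Synthetic parent-hybrid expression trios with known ground truth.

The generator emulates the FPKM output of a replicate-free bulk RNA-seq
experiment on one or two crosses (maternal parent, F1 hybrid, paternal
parent per cross).  Each gene is assigned a true inheritance-mode class (one
of the 12 classes or "none"); its noise-free expression levels are built
from a log-normal baseline ``L`` so that the class-defining inequalities hold
exactly:

* "equal" levels are exactly equal (ratio 1);
* "different" levels differ by ``effect_size`` exactly (default 4), except in
  the additive classes, where the hybrid sits at the geometric mean of
  parents separated by ratio ``2*t^2 - 1`` (``t`` the classification
  threshold; sqrt(7) ~ 2.65 per hybrid-vs-parent gap at t = 2).  That is the
  equal-margin geometry: the gap to each parent and the closeness to the
  mid-parent value are then equally far (in log space) from the threshold,
  so additive genes are exactly recoverable without noise and maximally
  robust under noise.  A hybrid placed with parental gaps of 4 would sit
  more than 2-fold from the mid-parent value and no longer *be* additive
  under the classifier's own definition.

Multiplicative log2-normal noise (sd ``noise_sd``) is then applied to every
cell.  The ``paper_like`` preset uses coarse-mode proportions of roughly
19.4% additive, 4.8% dominance and 75.9% overdominance, the regime reported
for the lily study this pipeline emulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .heterosis import high_parent, mid_parent
from .io import DEFAULT_PSEUDOCOUNT, ExpressionMatrix, TraitTrio, TrioDesign

#: Table-2-style coarse-group percentages used by the "paper_like" preset.
PAPER_LIKE_GROUP_PERCENT = {
    "additive": 19.35,
    "ELD_paternal": 2.56,
    "ELD_maternal": 2.20,
    "transgressive_up": 41.68,
    "transgressive_down": 34.21,
}

_GROUP_CLASSES = {
    "additive": (1, 12),
    "ELD_paternal": (2, 11),
    "ELD_maternal": (4, 9),
    "transgressive_up": (5, 6, 8),
    "transgressive_down": (3, 7, 10),
}

#: Keys of class_proportions: the 12 classes plus "none".
CLASS_KEYS = tuple(range(1, 13)) + ("none",)


def paper_like_proportions() -> dict:
    """12-class + none proportions matching the paper_like coarse regime.

    Each coarse group's share is split evenly over its member classes.
    """
    total = sum(PAPER_LIKE_GROUP_PERCENT.values())
    props: dict = {k: 0.0 for k in CLASS_KEYS}
    for group, pct in PAPER_LIKE_GROUP_PERCENT.items():
        classes = _GROUP_CLASSES[group]
        for cls in classes:
            props[cls] = pct / total / len(classes)
    return props


def uniform_proportions(include_none: bool = True) -> dict:
    n = 13 if include_none else 12
    return {k: (1.0 / n if (k != "none" or include_none) else 0.0) for k in CLASS_KEYS}


@dataclass(frozen=True)
class UniversalOverlap:
    """Genes shared between the two crosses' common DEG sets.

    The first ``n_concordant_up`` genes are transgressively up-regulated in
    both crosses, and so on; the two discordant counts are up in cross A /
    down in cross B and the reverse.  Defaults mirror the two-cross lily
    experiment (11/7 concordant, 14/2 discordant).
    """

    n_concordant_up: int = 11
    n_concordant_down: int = 7
    n_up_a_down_b: int = 14
    n_down_a_up_b: int = 2

    @property
    def total(self) -> int:
        return (
            self.n_concordant_up
            + self.n_concordant_down
            + self.n_up_a_down_b
            + self.n_down_a_up_b
        )


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 1000
    class_proportions: dict | None = None  # default: uniform over 12 classes + none
    effect_size: float = 4.0
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.5
    baseline_floor: float = 0.5  # FPKM; keeps pseudocount distortion negligible
    noise_sd: float = 0.1  # sd of multiplicative noise on the log2 scale
    threshold: float = 2.0  # classification threshold the geometry targets
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    seed: int = 0
    n_crosses: int = 2
    overlap: UniversalOverlap | None = None

    def proportions(self) -> dict:
        props = self.class_proportions or uniform_proportions()
        keys = set(props)
        if keys != set(CLASS_KEYS):
            raise ValueError(f"class_proportions must cover exactly {CLASS_KEYS}")
        total = sum(props.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class proportions sum to {total}, not 1")
        if any(v < 0 for v in props.values()):
            raise ValueError("class proportions must be non-negative")
        return props

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.effect_size <= 1:
            raise ValueError("effect_size must exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")
        if self.n_crosses not in (1, 2):
            raise ValueError("n_crosses must be 1 or 2")
        if self.overlap is not None:
            if self.n_crosses != 2:
                raise ValueError("overlap injection requires n_crosses = 2")
            if self.overlap.total > self.n_genes:
                raise ValueError("overlap genes exceed n_genes")
        self.proportions()


def paper_like_config(**overrides) -> SimulationConfig:
    """Preset emulating the published two-cross regime (proportions and overlap)."""
    base = SimulationConfig(
        n_genes=5000,
        class_proportions=paper_like_proportions(),
        noise_sd=0.1,
        n_crosses=2,
        overlap=UniversalOverlap(),
    )
    return replace(base, **overrides)


@dataclass(frozen=True)
class SyntheticDataset:
    expression: ExpressionMatrix
    truth: pd.DataFrame  # gene_id, cross_id, true_class, true_coarse
    trios: list[TrioDesign]
    config: SimulationConfig


def class_levels(
    cls, baseline: float, effect_size: float, threshold: float
) -> tuple[float, float, float]:
    """Noise-free (maternal, hybrid, paternal) levels for one class.

    ``baseline`` is the low expression level L; "different" levels are L and
    e*L (or e^2*L where a transgressive hybrid must clear the farther
    parent), except for the additive classes (see module docstring).
    """
    L, e = baseline, effect_size
    if cls == "none":
        return (L, L, L)
    if cls in (1, 12):
        r = 2.0 * threshold * threshold - 1.0  # parent separation
        g = math.sqrt(r)  # hybrid-vs-parent gap
        hi, mid = L * r, L * g
        return (hi, mid, L) if cls == 1 else (L, mid, hi)
    table = {
        2: (L, e * L, e * L),
        11: (e * L, L, L),
        4: (e * L, e * L, L),
        9: (L, L, e * L),
        5: (e * L, e * e * L, L),
        6: (L, e * L, L),
        8: (L, e * e * L, e * L),
        3: (e * L, L / e, L),
        7: (e * L, L, e * L),
        10: (L, L / e, e * L),
    }
    return table[cls]


def _cross_labels(index: int) -> TrioDesign:
    name = chr(ord("A") + index)
    return TrioDesign(
        cross_id=name,
        maternal_id=f"{name}_P1",
        paternal_id=f"{name}_P2",
        hybrid_id=f"{name}_F1",
    )


def _overlap_classes(overlap: UniversalOverlap) -> list[tuple[int, int]]:
    """(class in cross A, class in cross B) for each injected universal gene."""
    out: list[tuple[int, int]] = []
    out += [(6, 6)] * overlap.n_concordant_up  # up in both
    out += [(7, 7)] * overlap.n_concordant_down  # down in both
    out += [(6, 7)] * overlap.n_up_a_down_b
    out += [(7, 6)] * overlap.n_down_a_up_b
    return out


def simulate_trios(config: SimulationConfig) -> SyntheticDataset:
    """Generate the expression matrix and per-gene, per-cross truth labels."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    props = config.proportions()
    keys = list(CLASS_KEYS)
    p = np.array([props[k] for k in keys], dtype=float)
    p = p / p.sum()

    n = config.n_genes
    gene_ids = [f"g{i:06d}" for i in range(n)]
    trios = [_cross_labels(i) for i in range(config.n_crosses)]

    # per-cross class draws; overlap genes get forced classes in both crosses
    draws = [rng.choice(len(keys), size=n, p=p) for _ in trios]
    classes = [[keys[j] for j in d] for d in draws]
    if config.overlap is not None:
        for i, (cls_a, cls_b) in enumerate(_overlap_classes(config.overlap)):
            classes[0][i] = cls_a
            classes[1][i] = cls_b

    baselines = np.maximum(
        config.baseline_floor,
        2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n),
    )

    columns: dict[str, np.ndarray] = {}
    truth_rows = []
    from .modes import COARSE_BY_CLASS  # local import to avoid cycle at import time

    for trio, cls_list in zip(trios, classes):
        m = np.empty(n)
        h = np.empty(n)
        pat = np.empty(n)
        for i, cls in enumerate(cls_list):
            m[i], h[i], pat[i] = class_levels(
                cls, baselines[i], config.effect_size, config.threshold
            )
            truth_rows.append(
                {
                    "gene_id": gene_ids[i],
                    "cross_id": trio.cross_id,
                    "true_class": cls,
                    "true_coarse": "none" if cls == "none" else COARSE_BY_CLASS[cls],
                }
            )
        columns[trio.maternal_id] = m
        columns[trio.hybrid_id] = h
        columns[trio.paternal_id] = pat

    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=values.shape)
        values = values * (2.0 ** noise)

    truth = pd.DataFrame(truth_rows)
    expression = ExpressionMatrix(values, pseudocount=config.pseudocount)
    return SyntheticDataset(expression=expression, truth=truth, trios=trios, config=config)


def simulate_trait_trios(
    seed: int = 0,
    n_traits: int = 8,
    parent_range: tuple[float, float] = (1.0, 100.0),
    mph_range: tuple[float, float] = (-20.0, 100.0),
) -> tuple[list[tuple[TrioDesign, TraitTrio]], pd.DataFrame]:
    """Random trait trios with known true MPH and HPH.

    Parents are drawn uniformly from ``parent_range``; a target MPH is drawn
    from ``mph_range`` and inverted (F1 = MP * (1 + MPH/100)), so running the
    heterosis stage on the output must reproduce the stored truth.
    """
    lo, hi = parent_range
    if not (0 < lo < hi):
        raise ValueError("parent_range must satisfy 0 < low < high")
    if mph_range[0] >= mph_range[1] or mph_range[0] <= -100:
        raise ValueError("mph_range must be increasing and above -100")
    rng = np.random.default_rng(seed)
    design = _cross_labels(0)
    records: list[tuple[TrioDesign, TraitTrio]] = []
    truth_rows = []
    for t in range(n_traits):
        maternal = float(rng.uniform(lo, hi))
        paternal = float(rng.uniform(lo, hi))
        mph = float(rng.uniform(*mph_range))
        mp = (maternal + paternal) / 2.0
        hybrid = mp * (1.0 + mph / 100.0)
        trio = TraitTrio(
            trait_name=f"trait_{t:02d}",
            maternal_mean=maternal,
            paternal_mean=paternal,
            hybrid_mean=hybrid,
        )
        hp = high_parent(trio)
        truth_rows.append(
            {
                "trait_name": trio.trait_name,
                "cross_id": design.cross_id,
                "true_mph": mph,
                "true_hph": 100.0 * (hybrid - hp) / hp,
            }
        )
        records.append((design, trio))
    return records, pd.DataFrame(truth_rows)
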