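"""End-to-end pipeline run: heterosis, DEG calling, set logic, mode labels.

``run_pipeline`` consumes a :class:`RunConfig`, executes whichever stages its
inputs allow, and writes deterministic TSV artifacts plus a ``metadata.json``
recording every threshold, the pseudocount and the seed, so a run can be
reproduced from its own output directory.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass

import pandas as pd

from . import deg, heterosis, modes
from .io import (
    DEFAULT_PSEUDOCOUNT,
    TrioDesign,
    read_design_table,
    read_expression_table,
    read_trait_table,
    write_metadata,
    write_report,
)

log = logging.getLogger("hetexpress")


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    expression_path: str | None = None
    trait_path: str | None = None
    design_path: str | None = None
    up_threshold: float = deg.DEFAULT_UP_THRESHOLD
    down_threshold: float = deg.DEFAULT_DOWN_THRESHOLD
    mode_threshold: float = modes.DEFAULT_MODE_THRESHOLD
    qpcr_band: float = 1.5
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    min_abundance: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _setup_logging(out_dir: str) -> logging.Handler:
    handler = logging.FileHandler(os.path.join(out_dir, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run every stage the configured inputs allow; return artifact paths."""
    os.makedirs(config.out_dir, exist_ok=True)
    handler = _setup_logging(config.out_dir)
    artifacts: dict[str, str] = {}

    def emit(name: str, result) -> None:
        path = os.path.join(config.out_dir, f"{name}.tsv")
        write_report(result, path)
        artifacts[name] = path
        log.info("wrote %s", path)

    try:
        if config.trait_path:
            records = read_trait_table(config.trait_path)
            results = heterosis.heterosis_table(records)
            emit("heterosis", heterosis.heterosis_frame(results))
        else:
            log.info("no trait table; heterosis stage skipped")

        if config.expression_path and config.design_path:
            _expression_stages(config, emit)
        else:
            log.info("no expression table or design; expression stages skipped")

        meta = {"config": config.to_dict(), "artifacts": sorted(artifacts)}
        meta_path = os.path.join(config.out_dir, "metadata.json")
        write_metadata(meta, meta_path)
        artifacts["metadata"] = meta_path
    finally:
        log.removeHandler(handler)
        handler.close()
    return artifacts


def _expression_stages(config: RunConfig, emit) -> None:
    expr = read_expression_table(config.expression_path, pseudocount=config.pseudocount)
    trios = read_design_table(config.design_path)
    if not 1 <= len(trios) <= 2:
        raise ValueError("pipeline expects one or two crosses")

    all_calls = []
    per_cross_sets: dict[str, tuple[set, set]] = {}
    count_rows = []
    classifications: list[modes.ModeClassification] = []
    for trio in trios:
        calls = deg.call_degs(
            expr,
            trio,
            up_threshold=config.up_threshold,
            down_threshold=config.down_threshold,
            min_abundance=config.min_abundance,
        )
        all_calls.extend(calls)
        up, down = deg.common_degs_per_cross(calls, trio)
        per_cross_sets[trio.cross_id] = (up, down)
        for parent in (trio.maternal_id, trio.paternal_id):
            cmp_calls = [c for c in calls if c.comparison == (trio.hybrid_id, parent)]
            count_rows.append(
                {
                    "cross_id": trio.cross_id,
                    "comparison": f"{trio.hybrid_id}_vs_{parent}",
                    "n_up": sum(c.call == "up" for c in cmp_calls),
                    "n_down": sum(c.call == "down" for c in cmp_calls),
                }
            )
        count_rows.append(
            {
                "cross_id": trio.cross_id,
                "comparison": "common_both_parents",
                "n_up": len(up),
                "n_down": len(down),
            }
        )
        common = sorted(up | down)
        classifications.extend(
            modes.classify_matrix(expr, trio, gene_ids=common, threshold=config.mode_threshold)
        )
        log.info(
            "cross %s: %d common up, %d common down", trio.cross_id, len(up), len(down)
        )

    emit(
        "deg_calls",
        pd.DataFrame(
            {
                "gene_id": c.gene_id,
                "comparison": f"{c.comparison[0]}_vs_{c.comparison[1]}",
                "signed_fc": c.signed_fc,
                "call": c.call,
            }
            for c in all_calls
        ),
    )

    if len(trios) == 2:
        sets = deg.universal_degs(
            per_cross_sets[trios[0].cross_id], per_cross_sets[trios[1].cross_id]
        )
        count_rows.append(
            {
                "cross_id": "both",
                "comparison": "universal",
                "n_up": len(sets.universal_up),
                "n_down": len(sets.universal_down),
            }
        )
        count_rows.append(
            {
                "cross_id": "both",
                "comparison": "discordant",
                "n_up": len(sets.discordant),
                "n_down": 0,
            }
        )
        count_rows.append(
            {
                "cross_id": "both",
                "comparison": "unique_union",
                "n_up": sets.unique_union_count,
                "n_down": 0,
            }
        )
        membership = [
            {"gene_id": g, "set": name}
            for name, genes in (
                ("universal_up", sets.universal_up),
                ("universal_down", sets.universal_down),
                ("discordant", sets.discordant),
            )
            for g in sorted(genes)
        ]
        emit("deg_sets", pd.DataFrame(membership, columns=["gene_id", "set"]))
        emit("universal_degs", _universal_table(expr, trios, sets, config.mode_threshold))

    emit("deg_set_counts", pd.DataFrame(count_rows))

    emit(
        "mode_classifications",
        pd.DataFrame(
            {
                "gene_id": c.gene_id,
                "cross_id": c.cross_id,
                "class_1_12": "none" if c.class_1_12 is None else c.class_1_12,
                "coarse_mode": c.coarse_mode,
                "fc_vs_maternal": c.fc_vs_maternal,
                "fc_vs_paternal": c.fc_vs_paternal,
                "fc_parents": c.fc_parents,
                "fc_vs_midparent": c.fc_vs_midparent,
            }
            for c in classifications
        ),
    )
    if classifications:
        summary = modes.mode_summary(classifications)
        rows = [
            {"statistic": f"percent_{mode}", "value": summary.percentages[mode]}
            for mode in sorted(summary.percentages)
        ]
        rows.append({"statistic": "n_classified", "value": summary.n_classified})
        rows.append({"statistic": "n_none", "value": summary.n_none})
        emit("mode_summary", pd.DataFrame(rows))

    corr = deg.library_correlation(expr)
    emit("library_correlation", corr.reset_index(names="genotype_id"))
    emit("log2_matrix", expr.log2().reset_index())


def _universal_table(expr, trios, sets, threshold) -> pd.DataFrame:
    """Fold changes and per-hybrid coarse labels for the universal/discordant genes."""
    from .deg import signed_fold_change

    genes = sorted(sets.universal_up | sets.universal_down | sets.discordant)
    rows = []
    for g in genes:
        row: dict = {"gene_id": g}
        fcs_by_trio = []
        for i, trio in enumerate(trios, start=1):
            m, h, p = expr.trio_values(g, trio)
            fm = signed_fold_change(h, m, expr.pseudocount)
            fp = signed_fold_change(h, p, expr.pseudocount)
            row[f"fc_h{i}_vs_maternal"] = fm
            row[f"fc_h{i}_vs_paternal"] = fp
            fcs_by_trio.append((fm, fp))
        for i, (fm, fp) in enumerate(fcs_by_trio, start=1):
            row[f"label_hybrid{i}"] = modes.classify_per_hybrid_coarse(fm, fp, threshold)
        rows.append(row)
    return pd.DataFrame(rows)
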