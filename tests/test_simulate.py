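"""Synthetic trio generator: determinism, truth recovery, noise behaviour."""

import numpy as np
import pandas as pd
import pytest

from hetexpress.deg import call_degs, common_degs_per_cross, universal_degs
from hetexpress.heterosis import heterosis_table
from hetexpress.modes import classify_matrix, mode_summary
from hetexpress.simulate import (
    SimulationConfig,
    UniversalOverlap,
    class_levels,
    paper_like_config,
    paper_like_proportions,
    simulate_trait_trios,
    simulate_trios,
    uniform_proportions,
)


def classify_dataset(dataset, threshold=2.0):
    """Per-(gene, cross) classifications for every gene of a simulated dataset."""
    rows = []
    for trio in dataset.trios:
        for c in classify_matrix(dataset.expression, trio, threshold=threshold):
            rows.append(
                {
                    "gene_id": c.gene_id,
                    "cross_id": c.cross_id,
                    "pred_class": "none" if c.class_1_12 is None else c.class_1_12,
                    "pred_coarse": c.coarse_mode,
                }
            )
    pred = pd.DataFrame(rows)
    return dataset.truth.merge(pred, on=["gene_id", "cross_id"], validate="1:1")


class TestConfig:
    def test_bad_proportions_rejected(self):
        props = uniform_proportions()
        props[1] += 0.1
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(class_proportions=props).validate()

    def test_paper_like_proportions_sum_to_one(self):
        assert sum(paper_like_proportions().values()) == pytest.approx(1.0, abs=1e-9)

    def test_overlap_requires_two_crosses(self):
        with pytest.raises(ValueError, match="n_crosses"):
            SimulationConfig(n_crosses=1, overlap=UniversalOverlap()).validate()


class TestDeterminism:
    def test_same_seed_same_matrices(self):
        cfg = SimulationConfig(n_genes=50, seed=11, noise_sd=0.3)
        a = simulate_trios(cfg)
        b = simulate_trios(cfg)
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a = simulate_trios(SimulationConfig(n_genes=50, seed=1, noise_sd=0.3))
        b = simulate_trios(SimulationConfig(n_genes=50, seed=2, noise_sd=0.3))
        assert not a.expression.values.equals(b.expression.values)


class TestNoiseFreeRecovery:
    def test_every_class_geometry_classifies_to_itself(self):
        from hetexpress.modes import classify_12bin

        for cls in list(range(1, 13)) + ["none"]:
            m, h, p = class_levels(cls, baseline=2.0, effect_size=4.0, threshold=2.0)
            got = classify_12bin(m, h, p, threshold=2.0)
            expected = None if cls == "none" else cls
            assert got.class_1_12 == expected, cls

    def test_full_recovery_at_noise_zero(self):
        dataset = simulate_trios(SimulationConfig(n_genes=1000, noise_sd=0.0, seed=3))
        merged = classify_dataset(dataset)
        assert (merged["pred_class"].astype(str) == merged["true_class"].astype(str)).all()

    def test_all_transgressive_up_called_up_everywhere(self):
        props = {k: 0.0 for k in uniform_proportions()}
        props[6] = 1.0
        dataset = simulate_trios(
            SimulationConfig(n_genes=100, class_proportions=props, noise_sd=0.0, seed=4,
                             n_crosses=1)
        )
        trio = dataset.trios[0]
        calls = call_degs(dataset.expression, trio)
        assert all(c.call == "up" for c in calls)

    def test_true_ratio_four_called_up_both_comparisons(self):
        """Spec'd guarantee: noise-free 4-fold hybrids are up at threshold 2."""
        props = {k: 0.0 for k in uniform_proportions()}
        props[6] = 1.0  # hybrid = 4x both parents
        dataset = simulate_trios(
            SimulationConfig(n_genes=64, class_proportions=props, noise_sd=0.0, seed=5)
        )
        for trio in dataset.trios:
            up, down = common_degs_per_cross(call_degs(dataset.expression, trio), trio)
            assert len(up) == 64 and not down


class TestNoise:
    def test_misclassification_monotone_in_noise(self):
        rates = []
        for noise in (0.0, 0.1, 0.25, 0.5):
            dataset = simulate_trios(
                SimulationConfig(n_genes=800, noise_sd=noise, seed=42, n_crosses=1)
            )
            merged = classify_dataset(dataset)
            err = (merged["pred_class"].astype(str) != merged["true_class"].astype(str)).mean()
            rates.append(err)
        assert rates[0] == 0.0
        assert all(a <= b + 1e-12 for a, b in zip(rates, rates[1:]))

    def test_paper_like_proportion_recovery(self):
        """Coarse proportions recovered within 3 points under realistic noise."""
        dataset = simulate_trios(paper_like_config(n_genes=5000, seed=7))
        merged = classify_dataset(dataset)
        classified = merged[merged["pred_coarse"] != "none"]
        recovered = classified["pred_coarse"].value_counts(normalize=True) * 100
        from hetexpress.simulate import PAPER_LIKE_GROUP_PERCENT

        for group, pct in PAPER_LIKE_GROUP_PERCENT.items():
            assert abs(recovered.get(group, 0.0) - pct) < 3.0, group


class TestOverlapInjection:
    def test_universal_counts_match_requested_overlap(self):
        cfg = SimulationConfig(
            n_genes=400, seed=9, noise_sd=0.0, overlap=UniversalOverlap(11, 7, 14, 2)
        )
        dataset = simulate_trios(cfg)
        sets_by_cross = {}
        for trio in dataset.trios:
            calls = call_degs(dataset.expression, trio)
            sets_by_cross[trio.cross_id] = common_degs_per_cross(calls, trio)
        sets = universal_degs(sets_by_cross["A"], sets_by_cross["B"])
        assert len(sets.universal_up) >= 11
        assert len(sets.universal_down) >= 7
        assert len(sets.discordant) >= 16
        # the injected genes themselves are exactly the first 34
        injected_up = {f"g{i:06d}" for i in range(11)}
        injected_down = {f"g{i:06d}" for i in range(11, 18)}
        assert injected_up <= sets.universal_up
        assert injected_down <= sets.universal_down


class TestTraitSimulation:
    def test_heterosis_stage_reproduces_truth(self):
        records, truth = simulate_trait_trios(seed=21, n_traits=12)
        results = {r.trait_name: r for r in heterosis_table(records)}
        for row in truth.itertuples():
            r = results[row.trait_name]
            assert r.mph_percent == pytest.approx(row.true_mph, rel=1e-9, abs=1e-9)
            assert r.hph_percent == pytest.approx(row.true_hph, rel=1e-9, abs=1e-9)

    def test_inverted_mph_construction(self):
        from hetexpress.heterosis import mid_parent_heterosis
        from hetexpress.io import TraitTrio

        mp = (40.0 + 30.0) / 2
        t = TraitTrio("t", 40.0, 30.0, 1.3101 * mp)
        assert mid_parent_heterosis(t) == pytest.approx(31.01)

    def test_f1_below_both_parents_negative_heterosis(self):
        records, truth = simulate_trait_trios(seed=5, n_traits=30, mph_range=(-40.0, -30.0))
        assert (truth["true_mph"] < 0).all()
        assert (truth["true_hph"] < 0).all()
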