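"""Normalisation, background filtering, modulation calls and set logic."""

import numpy as np
import pandas as pd
import pytest

from mirfate import (
    ExpressionExperiment,
    SimulationConfig,
    ValidationError,
    bidirectional_set,
    call_modulation,
    filter_background,
    generate_expression,
    generate_truth,
    multi_celltype_set,
    normalize,
)
from mirfate.expression import (
    either_arm_set,
    normalize_per_chip,
    normalize_per_gene,
)


def make_experiment(matrix: dict, background: float = 10.0,
                    cell: str = "HEK293") -> ExpressionExperiment:
    """Six-sample single-cell experiment: 2 control, 2 miR, 2 anti_miR."""
    samples = pd.DataFrame(
        {
            "sample_id": [f"{cell}_{c}_{r}" for c in
                          ("control", "miR", "anti_miR") for r in (1, 2)],
            "cell_type": cell,
            "condition": [c for c in ("control", "miR", "anti_miR")
                          for _ in (1, 2)],
            "replicate": [1, 2] * 3,
        }
    ).set_index("sample_id")
    mat = pd.DataFrame(matrix, index=samples.index).T
    mat.index.name = "gene"
    return ExpressionExperiment(mat, samples, background)


class TestExperimentValidation:
    def test_requires_two_replicates(self):
        samples = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "cell_type": "c",
             "condition": ["control", "miR"], "replicate": 1}
        ).set_index("sample_id")
        mat = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["g1"])
        with pytest.raises(ValidationError):
            ExpressionExperiment(mat, samples, 1.0)

    def test_rejects_negative_intensities(self):
        with pytest.raises(ValidationError):
            make_experiment({"g1": [1, 1, -2, 1, 1, 1]})


class TestFilterBackground:
    def test_below_in_four_of_six_excluded(self):
        exp = make_experiment({"g1": [5, 5, 5, 5, 20, 20]}, background=10)
        assert "g1" not in filter_background(exp)

    def test_exactly_half_retained(self):
        exp = make_experiment({"g1": [5, 5, 5, 20, 20, 20]}, background=10)
        assert "g1" in filter_background(exp)

    def test_all_above_retained(self):
        exp = make_experiment({"g1": [20] * 6}, background=10)
        assert "g1" in filter_background(exp)

    def test_threshold_boundary_counts_as_expressed(self):
        exp = make_experiment({"g1": [10, 10, 10, 5, 5, 5]}, background=10)
        assert "g1" in filter_background(exp)


def with_filler(matrix: dict, n: int = 30, value: float = 10.0) -> dict:
    """Add constant housekeeping genes so chip medians are anchored."""
    out = dict(matrix)
    for i in range(n):
        out[f"hk{i}"] = [value] * 6
    return out


class TestNormalize:
    def test_doubled_gene_normalises_to_two(self):
        exp = make_experiment(
            with_filler({"g1": [10, 10, 20, 20, 5, 5]}), background=1)
        norm = normalize(exp)
        ct = "HEK293"
        ctrl = norm.matrix.loc["g1", norm.sample_ids(ct, "control")]
        mir = norm.matrix.loc["g1", norm.sample_ids(ct, "miR")]
        assert (ctrl == 1.0).all()
        np.testing.assert_allclose(mir, 2.0)

    def test_chip_medians_are_one(self):
        rng = np.random.default_rng(0)
        mat = {f"g{i}": rng.uniform(5, 500, 6) for i in range(31)}
        exp = make_experiment(mat, background=1)
        chip = normalize_per_chip(exp)
        med = chip.matrix.median(axis=0)
        np.testing.assert_allclose(med, 1.0)

    def test_per_chip_idempotent(self):
        # the retained set is decided on raw intensities, so it is held
        # fixed across applications
        rng = np.random.default_rng(1)
        exp = make_experiment(
            {f"g{i}": rng.uniform(5, 500, 6) for i in range(31)}, background=1)
        retained = {"HEK293": filter_background(exp)}
        once = normalize_per_chip(exp, retained=retained)
        twice = normalize_per_chip(once, retained=retained)
        pd.testing.assert_frame_equal(once.matrix, twice.matrix)

    def test_per_gene_idempotent(self):
        rng = np.random.default_rng(2)
        exp = make_experiment(
            {f"g{i}": rng.uniform(5, 500, 6) for i in range(31)}, background=1)
        once = normalize_per_gene(exp)
        twice = normalize_per_gene(once)
        pd.testing.assert_frame_equal(once.matrix, twice.matrix)

    def test_zero_control_gene_excluded(self):
        exp = make_experiment(
            {"g1": [0, 0, 5, 5, 5, 5], "g2": [10, 10, 10, 10, 10, 10]},
            background=1)
        norm = normalize(exp)
        assert "g1" not in norm.matrix.index
        assert "g2" in norm.matrix.index


class TestCallModulation:
    def test_direction_conventions(self):
        exp = make_experiment(
            with_filler({
                "up_gene": [10, 10, 20, 20, 10, 10],     # miR ratio 2.0
                "flat_gene": [10, 10, 14, 14, 10, 10],   # ratio 1.4 < 1.5
                "down_gene": [10, 10, 5, 5, 10, 10],     # ratio 0.5
            }),
            background=1)
        calls = call_modulation(normalize(exp), mode="fc_only")
        mir = calls[calls["modulation"] == "miR"].set_index("gene")
        assert mir.loc["up_gene", "direction"] == "up"
        assert mir.loc["flat_gene", "direction"] == "unchanged"
        assert mir.loc["down_gene", "direction"] == "down"
        assert np.isnan(mir.loc["down_gene", "p_value"])

    def test_threshold_inclusive(self):
        exp = make_experiment(
            with_filler({"g1": [10, 10, 15, 15, 10, 10]}), background=1)
        calls = call_modulation(normalize(exp), mode="fc_only")
        mir = calls[calls["modulation"] == "miR"].set_index("gene")
        assert mir.loc["g1", "direction"] == "up"

    def test_p_gate_blocks_noisy_fold(self):
        # ratio above 1.5 but replicates so inconsistent the t-test fails
        exp = make_experiment(
            with_filler({"g1": [9, 11, 5, 60, 10, 10]}), background=1)
        calls = call_modulation(normalize(exp), mode="fc_and_p")
        mir = calls[calls["modulation"] == "miR"].set_index("gene")
        assert mir.loc["g1", "fold_change"] > 1.5
        assert mir.loc["g1", "direction"] == "unchanged"

    def test_every_gene_called_once_per_arm(self):
        exp = make_experiment(
            {f"g{i}": [10, 10, 10, 10, 10, 10] for i in range(5)},
            background=1)
        calls = call_modulation(normalize(exp), mode="fc_only")
        assert len(calls) == 10
        assert calls.groupby(["gene", "modulation"]).size().eq(1).all()

    def test_direction_antisymmetry(self):
        """Swapping treatment and control maps fold f -> 1/f, up <-> down."""
        rng = np.random.default_rng(3)
        values = rng.uniform(5, 200, (10, 6))
        mat = {f"g{i}": values[i] for i in range(10)}
        exp = make_experiment(mat, background=1)
        swapped_samples = exp.samples.copy()
        swapped_samples["condition"] = swapped_samples["condition"].map(
            {"control": "miR", "miR": "control", "anti_miR": "anti_miR"})
        swapped = ExpressionExperiment(exp.matrix, swapped_samples, 1.0)
        a = call_modulation(exp, mode="fc_only")
        b = call_modulation(swapped, mode="fc_only")
        am = a[a["modulation"] == "miR"].set_index("gene")
        bm = b[b["modulation"] == "miR"].set_index("gene")
        np.testing.assert_allclose(
            am["fold_change"], 1.0 / bm.loc[am.index, "fold_change"])
        flip = {"up": "down", "down": "up", "unchanged": "unchanged"}
        assert (am["direction"].map(flip)
                == bm.loc[am.index, "direction"]).all()

    def test_noiseless_calls_equal_truth(self):
        """With zero noise and a modest responder load, call directions
        reproduce the planted response modes exactly."""
        cfg = SimulationConfig(
            n_genes=300, n_cell_types=1, frac_predicted_targets=0.1,
            frac_canonical_responders=0.4, frac_noncanonical_responders=0.2,
            background_de_rate=0.0, noise_sd_log2=0.0,
            frac_below_background_per_cell=0.0, tf_regulon_size=5,
            rng_seed=11)
        truth = generate_truth(cfg)
        ct = truth.cell_types[0]
        exp = generate_expression(truth)[ct]
        calls = call_modulation(normalize(exp),
                                genes=filter_background(exp), mode="fc_only")
        mir = calls[calls["modulation"] == "miR"].set_index("gene")
        anti = calls[calls["modulation"] == "anti_miR"].set_index("gene")
        for gene, row in truth.genes.iterrows():
            mode = row["response_mode"]
            if mode == "canonical":
                assert mir.loc[gene, "direction"] == "down"
                assert anti.loc[gene, "direction"] == "up"
            elif mode == "noncanonical":
                assert mir.loc[gene, "direction"] == "up"
                assert anti.loc[gene, "direction"] == "down"
            else:
                assert mir.loc[gene, "direction"] == "unchanged"
                assert anti.loc[gene, "direction"] == "unchanged"


def calls_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene", "cell_type", "modulation", "direction",
                       "fold_change", "p_value"])


def direction_rows(cell, mir_down, anti_up, mir_up=(), anti_down=()):
    rows = []
    for g in mir_down:
        rows.append([g, cell, "miR", "down", 0.5, np.nan])
    for g in mir_up:
        rows.append([g, cell, "miR", "up", 2.0, np.nan])
    for g in anti_up:
        rows.append([g, cell, "anti_miR", "up", 2.0, np.nan])
    for g in anti_down:
        rows.append([g, cell, "anti_miR", "down", 0.5, np.nan])
    return rows


class TestSetLogic:
    def test_bidirectional_intersection(self):
        calls = calls_frame(direction_rows(
            "c1", mir_down=["A", "B", "C"], anti_up=["B", "C", "D"]))
        assert bidirectional_set(calls, "c1", "canonical") == {"B", "C"}

    def test_disjoint_arms_empty(self):
        calls = calls_frame(direction_rows("c1", ["A"], ["B"]))
        assert bidirectional_set(calls, "c1", "canonical") == set()

    def test_noncanonical_orientation(self):
        calls = calls_frame(direction_rows(
            "c1", mir_down=[], anti_up=[], mir_up=["X"], anti_down=["X"]))
        assert bidirectional_set(calls, "c1", "noncanonical") == {"X"}

    def test_orientations_disjoint(self):
        rows = direction_rows("c1", mir_down=["A"], anti_up=["A"],
                              mir_up=["B"], anti_down=["B"])
        calls = calls_frame(rows)
        canon = bidirectional_set(calls, "c1", "canonical")
        noncanon = bidirectional_set(calls, "c1", "noncanonical")
        assert canon & noncanon == set()
        assert canon == {"A"} and noncanon == {"B"}

    def test_missing_arm_rejected(self):
        calls = calls_frame([["A", "c1", "miR", "down", 0.5, np.nan]])
        with pytest.raises(ValidationError):
            bidirectional_set(calls, "c1", "canonical")

    def test_either_arm_orientation_filter(self):
        calls = calls_frame(direction_rows(
            "c1", mir_down=["A"], anti_up=["B"], mir_up=["C"],
            anti_down=["D"]))
        assert either_arm_set(calls, "c1", "canonical") == {"A", "B"}
        assert either_arm_set(calls, "c1", "noncanonical") == {"C", "D"}
        assert either_arm_set(calls, "c1") == {"A", "B", "C", "D"}

    def test_multi_celltype_membership(self):
        sets = {"c1": {"A", "B"}, "c2": {"B", "C"}, "c3": {"B"}}
        assert multi_celltype_set(sets, 3) == {"B"}
        assert multi_celltype_set(sets, 2) == {"B"}
        assert multi_celltype_set(sets, 1) == {"A", "B", "C"}

    def test_min_cells_bounds(self):
        with pytest.raises(ValidationError):
            multi_celltype_set({"c1": {"A"}}, 2)
        with pytest.raises(ValidationError):
            multi_celltype_set({"c1": {"A"}}, 0)
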