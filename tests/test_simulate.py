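"""Ground-truth generator: proportions, determinism, planted recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirfate import (
    ConfigError,
    SimulationConfig,
    Stratum,
    ValidationError,
    expected_confusion,
    generate_expression,
    generate_reporter_data,
    generate_truth,
    generate_utrs,
    scan_seed_sites,
)
from mirfate.reporter import reporter_response


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("frac_predicted_targets", 1.2),
            ("frac_canonical_responders", -0.1),
            ("replicates_per_condition", 1),
            ("effect_fold_range", (0.8, 2.0)),
            ("effect_fold_range", (3.0, 2.0)),
            ("noise_sd_log2", -0.1),
            ("background_de_rate", 0.6),
            ("tf_effect_orientation", "sideways"),
            ("anti_mir_attenuation", 0.0),
        ],
    )
    def test_invalid_field_named(self, field, value):
        cfg = SimulationConfig(**{field: value})
        with pytest.raises(ConfigError) as err:
            cfg.validate()
        assert field in str(err.value)

    def test_responder_fractions_capped(self):
        cfg = SimulationConfig(frac_canonical_responders=0.7,
                               frac_noncanonical_responders=0.6)
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_regulon_requires_targets(self):
        cfg = SimulationConfig(n_genes=50, frac_predicted_targets=0.0,
                               tf_regulon_size=5)
        with pytest.raises(ConfigError) as err:
            cfg.validate()
        assert "tf_regulon_size" in str(err.value)


class TestGenerateTruth:
    def test_category_counts_match_proportions(self):
        cfg = SimulationConfig(n_genes=100, frac_predicted_targets=0.2,
                               tf_regulon_size=0, rng_seed=1)
        truth = generate_truth(cfg)
        g = truth.genes
        assert int(g["is_predicted_target"].sum()) == 20
        pred = g[g["is_predicted_target"]]
        assert int(pred["conserved"].sum()) == round(0.25 * 20)
        assert (g.loc[~g["is_predicted_target"], "site_class"] == "none").all()
        assert g.loc[~g["is_predicted_target"], "pct"].isna().all()
        assert pred["pct"].notna().all()

    def test_deterministic_for_fixed_seed(self, small_config):
        a = generate_truth(small_config)
        b = generate_truth(small_config)
        pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_all_predicted_respond_when_fractions_sum_to_one(self):
        cfg = SimulationConfig(n_genes=100, frac_canonical_responders=0.5,
                               frac_noncanonical_responders=0.5,
                               tf_regulon_size=0, rng_seed=2)
        truth = generate_truth(cfg)
        pred = truth.genes[truth.genes["is_predicted_target"]]
        assert (pred["response_mode"] != "unresponsive").all()

    def test_tf_gene_is_predicted_target(self, small_truth):
        g = small_truth.genes
        assert g["is_tf_gene"].sum() == 1
        tf = g[g["is_tf_gene"]].iloc[0]
        assert tf["is_predicted_target"]
        assert not tf["in_tf_regulon"]
        regulon = g[g["in_tf_regulon"]]
        assert len(regulon) == small_truth.config.tf_regulon_size
        assert not regulon["is_predicted_target"].any()

    def test_responder_folds_in_range(self, small_truth):
        g = small_truth.genes
        lo, hi = small_truth.config.effect_fold_range
        responders = g["response_mode"] != "unresponsive"
        assert ((g.loc[responders, "true_effect_fold"] >= lo)
                & (g.loc[responders, "true_effect_fold"] <= hi)).all()
        assert (g.loc[~responders, "true_effect_fold"] == 1.0).all()


class TestGenerateUTRs:
    def test_planted_sites_exact(self, small_truth, mir181b):
        utrs = generate_utrs(small_truth, mir181b, utr_length=60)
        for gene, row in small_truth.genes.iterrows():
            classes = {s.site_class
                       for s in scan_seed_sites(utrs[gene], mir181b)}
            if row["is_predicted_target"]:
                assert classes == {row["site_class"]}
            else:
                assert classes == set()

    def test_no_targets_means_no_sites(self, mir181b):
        cfg = SimulationConfig(n_genes=40, frac_predicted_targets=0.0,
                               tf_regulon_size=0, rng_seed=3)
        truth = generate_truth(cfg)
        utrs = generate_utrs(truth, mir181b, utr_length=50)
        assert all(not scan_seed_sites(seq, mir181b)
                   for seq in utrs.values())

    def test_short_utr_rejected(self, small_truth, mir181b):
        with pytest.raises(ValidationError):
            generate_utrs(small_truth, mir181b, utr_length=20)

    def test_deterministic(self, small_truth, mir181b):
        assert generate_utrs(small_truth, mir181b) == \
            generate_utrs(small_truth, mir181b)


class TestGenerateExpression:
    def _noiseless_truth(self, **over):
        kwargs = dict(n_genes=60, n_cell_types=1, frac_predicted_targets=0.1,
                      frac_canonical_responders=0.5,
                      frac_noncanonical_responders=0.5,
                      noise_sd_log2=0.0, background_de_rate=0.0,
                      frac_below_background_per_cell=0.0, tf_regulon_size=0,
                      rng_seed=5)
        kwargs.update(over)
        return generate_truth(SimulationConfig(**kwargs))

    def test_noiseless_canonical_ratio_exact(self):
        truth = self._noiseless_truth()
        exps = generate_expression(truth)
        exp = exps[truth.cell_types[0]]
        ct = truth.cell_types[0]
        ctrl = exp.matrix[exp.sample_ids(ct, "control")].mean(axis=1)
        mir = exp.matrix[exp.sample_ids(ct, "miR")].mean(axis=1)
        anti = exp.matrix[exp.sample_ids(ct, "anti_miR")].mean(axis=1)
        g = truth.genes
        canonical = g.index[g["response_mode"] == "canonical"]
        fold = g.loc[canonical, "true_effect_fold"]
        a = truth.config.anti_mir_attenuation
        np.testing.assert_allclose(
            (mir.loc[canonical] / ctrl.loc[canonical]), 1.0 / fold
        )
        np.testing.assert_allclose(
            (anti.loc[canonical] / ctrl.loc[canonical]), fold ** a
        )

    def test_noiseless_unresponsive_constant(self):
        truth = self._noiseless_truth()
        exp = generate_expression(truth)[truth.cell_types[0]]
        g = truth.genes
        idle = g.index[g["response_mode"] == "unresponsive"]
        values = exp.matrix.loc[idle]
        assert (values.nunique(axis=1) == 1).all()

    def test_below_background_genes_stay_below(self):
        truth = generate_truth(SimulationConfig(
            n_genes=200, n_cell_types=1, frac_below_background_per_cell=0.3,
            tf_regulon_size=0, rng_seed=6))
        ct = truth.cell_types[0]
        exp = generate_expression(truth)[ct]
        below = truth.genes.index[~truth.genes[f"expressed_{ct}"]]
        assert (exp.matrix.loc[below] < exp.background_threshold).all().all()

    def test_unresponsive_noise_matches_half_normal_expectation(self):
        # Monte-Carlo vs the closed-form mean of |N(0, sigma*sqrt(2/r))|
        sigma = 0.1
        truth = generate_truth(SimulationConfig(
            n_genes=2000, n_cell_types=1, frac_predicted_targets=0.0,
            noise_sd_log2=sigma, background_de_rate=0.0,
            frac_below_background_per_cell=0.0, tf_regulon_size=0,
            rng_seed=8))
        ct = truth.cell_types[0]
        exp = generate_expression(truth)[ct]
        mir = exp.matrix[exp.sample_ids(ct, "miR")].mean(axis=1)
        ctrl = exp.matrix[exp.sample_ids(ct, "control")].mean(axis=1)
        observed = np.abs(np.log2(mir / ctrl)).mean()
        sd_ratio = sigma * np.sqrt(2.0 / 2)
        expected = sd_ratio * np.sqrt(2.0 / np.pi)
        se = sd_ratio * np.sqrt(1 - 2 / np.pi) / np.sqrt(2000)
        assert abs(observed - expected) < 4 * se

    def test_deterministic(self, small_truth):
        a = generate_expression(small_truth)
        b = generate_expression(small_truth)
        for ct in small_truth.cell_types:
            pd.testing.assert_frame_equal(a[ct].matrix, b[ct].matrix)


class TestGenerateReporterData:
    def test_noiseless_recovery_exact(self):
        df = generate_reporter_data(
            {"c1": -20.0}, rng_seed=1, noise_sd_log2=0.0, well_sd_log2=0.0,
            between_experiment_sd_log2=0.0,
        )
        result = reporter_response(df)
        assert result.percent_change == pytest.approx(-20.0)
        assert result.p_value is None  # zero variance flagged, not faked

    def test_block_structure(self):
        df = generate_reporter_data({"c1": 0.0, "c2": -50.0}, rng_seed=2)
        counts = df.groupby(["construct", "oligo", "experiment"]).size()
        assert (counts == 3).all()
        assert set(df["oligo"]) == {"treatment", "control"}
        assert df["renilla"].gt(0).all()

    def test_elevation_recovered(self):
        df = generate_reporter_data({"up": 52.0}, rng_seed=3)
        result = reporter_response(df)
        assert result.percent_change == pytest.approx(52.0, abs=10.0)
        assert result.percent_change > 0

    def test_empty_request_rejected(self):
        with pytest.raises(ValidationError):
            generate_reporter_data({})


class TestExpectedConfusion:
    def test_perfect_design_gives_perfect_rates(self):
        cfg = SimulationConfig(
            n_genes=200, n_cell_types=1, frac_canonical_responders=1.0,
            frac_noncanonical_responders=0.0, background_de_rate=0.0,
            noise_sd_log2=0.0, frac_below_background_per_cell=0.0,
            tf_regulon_size=0, rng_seed=9)
        truth = generate_truth(cfg)
        ec = expected_confusion(
            truth, Stratum("miR", truth.cell_types[0], "all", "canonical"))
        assert ec.summary.accuracy == pytest.approx(1.0)
        assert ec.summary.fpr == pytest.approx(0.0)
        assert ec.summary.fnr == pytest.approx(0.0)

    def test_category_accuracy_arithmetic(self):
        # 20% targets of which 40% respond; non-targets spuriously DE in
        # the expected direction at rate 0.1: accuracy = .2*.4 + .8*.9
        cfg = SimulationConfig(
            n_genes=1000, n_cell_types=1, frac_predicted_targets=0.2,
            frac_canonical_responders=0.4, frac_noncanonical_responders=0.0,
            background_de_rate=0.1, noise_sd_log2=0.0,
            frac_below_background_per_cell=0.0, tf_regulon_size=0,
            rng_seed=10)
        truth = generate_truth(cfg)
        ec = expected_confusion(
            truth, Stratum("miR", truth.cell_types[0], "all", "canonical"))
        assert ec.summary.accuracy == pytest.approx(0.2 * 0.4 + 0.8 * 0.9,
                                                    abs=1e-9)

    def test_empty_stratum_rejected(self, small_truth):
        with pytest.raises(ValidationError):
            expected_confusion(
                small_truth, Stratum("miR", "no-such-cell", "all", "canonical"))
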