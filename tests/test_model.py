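"""Decision-tree pattern classification: branches, gating, symmetry, recovery."""

import numpy as np
import pandas as pd
import pytest

from ishpattern import (
    AnalysisParams,
    PatternAnalysis,
    aggregate_measurements,
    classify_pattern,
    expected_call,
    generate_dataset,
    make_preset,
    measure_dataset,
    pattern_recovery_matrix,
    run_pipeline_once,
)

#: Near-noiseless generator settings: tiny shared section jitter and stain
#: granularity, small enough that every test decision is deterministic.
NEAR_NOISELESS = dict(sigma_section=0.005, sigma_pixel=0.5)

GENE_PRESETS = ["atoh7_e13", "hes1_e13", "pax6_e13", "eya2_e13", "ebf3_e13"]


def _aggregated(preset, seed=0, **overrides):
    ds = generate_dataset(make_preset(preset, seed=seed, **overrides))
    records = measure_dataset(ds.images, ds.roi_table, AnalysisParams(), rng=seed)
    return aggregate_measurements(records)


def _frame(values_by_roi):
    """Aggregated-format frame from {roi: [per-section values]}."""
    plane_of = {"RM": "rostral", "RL": "rostral", "MM": "middle", "MC": "middle",
                "ML": "middle", "CM": "caudal", "CL": "caudal"}
    rows = []
    for roi, values in values_by_roi.items():
        for i, v in enumerate(values):
            rows.append(
                {"gene": "toy", "section_id": f"{plane_of[roi]}_{i}",
                 "plane": plane_of[roi], "roi_name": roi, "value": v}
            )
    return pd.DataFrame(rows)


class TestDecisionTreeBranches:
    def test_constant_levels_give_homogeneous_by_convention(self):
        """Equal constant samples: t = 0, p = 1, homogeneous without error."""
        frame = _frame({r: [1.0, 1.0, 1.0] for r in ("RM", "RL", "MM", "MC", "ML", "CM", "CL")})
        call = classify_pattern(frame)
        assert call.category == "homogeneous"
        assert call.direction == "none"
        assert call.evidence["rostral_vs_caudal"].p_value == 1.0

    def test_homogeneous_skips_middle_tests(self):
        call = classify_pattern(_aggregated("homogeneous_null", seed=1))
        assert call.category == "homogeneous"
        assert set(call.evidence) == {"rostral_vs_caudal"}

    @pytest.mark.parametrize("preset", GENE_PRESETS + ["homogeneous_null"])
    def test_near_noiseless_presets_recover_expected_call(self, preset):
        call = classify_pattern(_aggregated(preset, seed=3, **NEAR_NOISELESS))
        want_category, want_direction = expected_call(preset)
        assert (call.category, call.direction) == (want_category, want_direction)

    def test_gradient_reports_medial_high(self):
        call = classify_pattern(_aggregated("pax6_e13", seed=3, **NEAR_NOISELESS))
        assert call.medial_lateral_direction == "medial_high"

    def test_selective_reports_medial_high(self):
        call = classify_pattern(_aggregated("ebf3_e13", seed=3, **NEAR_NOISELESS))
        assert call.category == "selective"
        assert call.medial_lateral_direction == "medial_high"

    def test_opposite_sign_middle_tests_stay_differential(self):
        """A significant V-shape MM < MC > ML is not a monotone gradient."""
        frame = _frame(
            {
                "RM": [1.50, 1.52, 1.48], "RL": [1.50, 1.51, 1.49],
                "MM": [0.80, 0.81, 0.79], "MC": [1.20, 1.21, 1.19],
                "ML": [0.80, 0.79, 0.81],
                "CM": [0.90, 0.91, 0.89], "CL": [0.90, 0.89, 0.91],
            }
        )
        call = classify_pattern(frame)
        assert call.evidence["MM_vs_MC"].significant
        assert call.evidence["MC_vs_ML"].significant
        assert call.category == "differential"
        assert call.medial_lateral_direction == "none"

    def test_mm_mc_flat_with_mc_ml_drop_stays_differential(self):
        """Selective requires the MM vs MC difference, not only MC vs ML."""
        frame = _frame(
            {
                "RM": [1.50, 1.52, 1.48], "RL": [1.50, 1.51, 1.49],
                "MM": [1.20, 1.21, 1.19], "MC": [1.20, 1.19, 1.21],
                "ML": [0.70, 0.69, 0.71],
                "CM": [0.90, 0.91, 0.89], "CL": [0.90, 0.89, 0.91],
            }
        )
        call = classify_pattern(frame)
        assert not call.evidence["MM_vs_MC"].significant
        assert call.evidence["MC_vs_ML"].significant
        assert call.category == "differential"

    def test_lateral_high_gradient_direction(self):
        frame = _frame(
            {
                "RM": [1.50, 1.52, 1.48], "RL": [1.50, 1.51, 1.49],
                "MM": [0.40, 0.41, 0.39], "MC": [0.70, 0.71, 0.69],
                "ML": [1.00, 0.99, 1.01],
                "CM": [0.90, 0.91, 0.89], "CL": [0.90, 0.89, 0.91],
            }
        )
        call = classify_pattern(frame)
        assert call.category == "gradient"
        assert call.medial_lateral_direction == "lateral_high"


class TestInvariants:
    def test_direction_flips_under_rostrocaudal_relabeling(self):
        agg = _aggregated("hes1_e13", seed=4)
        call = classify_pattern(agg)
        flipped = agg.copy()
        flipped["plane"] = flipped["plane"].map(
            {"rostral": "caudal", "caudal": "rostral", "middle": "middle"}
        )
        flipped["roi_name"] = flipped["roi_name"].map(
            {"RM": "CM", "RL": "CL", "CM": "RM", "CL": "RL"}
        ).fillna(flipped["roi_name"])
        flipped_call = classify_pattern(flipped)
        assert flipped_call.category == call.category
        assert {call.direction, flipped_call.direction} == {"rostral_high", "caudal_high"}

    def test_subpattern_gated_on_step1_significance(self):
        """Gradient/selective only ever appear on the differential branch."""
        for seed in range(40):
            cfg = make_preset("homogeneous_null", seed=seed, sigma_section=0.15)
            call = run_pipeline_once(cfg, AnalysisParams())
            if call.category in ("gradient", "selective"):
                assert call.evidence["rostral_vs_caudal"].significant
            if call.category == "homogeneous":
                assert call.direction == "none"

    def test_holm_correction_preserves_strong_calls(self):
        agg = _aggregated("pax6_e13", seed=3, **NEAR_NOISELESS)
        raw = classify_pattern(agg, AnalysisParams())
        adj = classify_pattern(agg, AnalysisParams(holm=True))
        assert adj.category == raw.category == "gradient"
        for name, t in adj.evidence.items():
            assert t.p_value >= raw.evidence[name].p_value


class TestModelResultsApi:
    def test_from_measurements_aggregates_replicates(self):
        ds = generate_dataset(make_preset("eya2_e13", seed=2))
        records = measure_dataset(ds.images, ds.roi_table, AnalysisParams(), rng=2)
        results = PatternAnalysis.from_measurements(records).fit()
        assert results.category == classify_pattern(records).category

    def test_summary_reports_call_and_tests(self):
        results = PatternAnalysis(_aggregated("pax6_e13", seed=3, **NEAR_NOISELESS)).fit()
        text = results.summary()
        assert "gradient" in text and "rostral_vs_caudal" in text and "p=" in text

    def test_to_frame_one_row_per_comparison(self):
        results = PatternAnalysis(_aggregated("ebf3_e13", seed=3, **NEAR_NOISELESS)).fit()
        frame = results.to_frame()
        assert set(frame["comparison"]) == {"rostral_vs_caudal", "MM_vs_MC", "MC_vs_ML"}
        assert (frame["category"] == "selective").all()

    def test_plot_returns_axes(self):
        import matplotlib

        matplotlib.use("Agg")
        results = PatternAnalysis(_aggregated("atoh7_e13", seed=1)).fit()
        ax = results.plot()
        assert ax.get_title().startswith("atoh7")

    def test_multiple_genes_rejected(self):
        agg = _aggregated("pax6_e13", seed=1)
        other = agg.copy()
        other["gene"] = "other"
        with pytest.raises(ValueError, match="one model per gene"):
            PatternAnalysis(pd.concat([agg, other]))


class TestRecoveryMatrix:
    def test_rows_sum_to_n_mc_and_deterministic(self):
        from conftest import SMALL

        a = pattern_recovery_matrix(["pax6_e13", "homogeneous_null"], n_mc=12, seed=8, **SMALL)
        b = pattern_recovery_matrix(["pax6_e13", "homogeneous_null"], n_mc=12, seed=8, **SMALL)
        assert (a.sum(axis=1) == 12).all()
        assert a.equals(b)

    def test_near_noiseless_gene_matrix_is_diagonal(self):
        """With vanishing noise every gene preset is classified correctly.

        The null preset is excluded: its step-1 false-positive rate is alpha
        by construction at any noise scale, so only the five gene presets are
        deterministic here (the null case is covered by the zero-noise
        convention test and the calibration suite).
        """
        matrix = pattern_recovery_matrix(GENE_PRESETS, n_mc=5, seed=8, **NEAR_NOISELESS)
        for preset in matrix.index:
            want_category, _ = expected_call(preset)
            assert matrix.loc[preset, want_category] == 5, matrix

    def test_default_noise_recovery_mostly_correct(self):
        from conftest import SMALL

        matrix = pattern_recovery_matrix(["eya2_e13"], n_mc=30, seed=8, **SMALL)
        assert matrix.loc["eya2_e13", "gradient"] >= 27
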