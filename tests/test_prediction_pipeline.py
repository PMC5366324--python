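"""Outcome coding, session split, Pearson-r evaluation, topographies."""

import numpy as np
import pandas as pd
import pytest

from eegnaming.prediction_pipeline import (
    EXCLUDED,
    coded_design,
    encode_outcome,
    evaluate,
    run_experiment,
    significance_tier,
    split_sessions,
    topography_correlations,
)
from eegnaming.session_model import ResponseCategory
from eegnaming.spectral_features import FeatureTable, SpectralConfig, feature_labels

C = ResponseCategory


class TestOutcomeCoding:
    @pytest.mark.parametrize(
        "category,expected",
        [(C.CORRECT, 1.0)] + [(c, 0.0) for c in C if c != C.CORRECT],
    )
    def test_accuracy_mode_is_total_first_attempt_rule(self, category, expected):
        assert encode_outcome(category, "accuracy") == expected

    @pytest.mark.parametrize(
        "category,expected",
        [
            (C.CORRECT, 2.0),
            (C.SELF_CORRECTED_FRAGMENT, 1.0),
            (C.SELF_CORRECTED_SEMANTIC, 1.0),
            (C.SELF_CORRECTED_PHONOLOGICAL, 1.0),
            (C.FRAGMENT_INCORRECT, 0.0),
            (C.SEMANTIC_ERROR, 0.0),
            (C.PHONOLOGICAL_NEOLOGISTIC, 0.0),
            (C.NO_RESPONSE, EXCLUDED),
            (C.CIRCUMLOCUTION, EXCLUDED),
            (C.PERSEVERATION, EXCLUDED),
        ],
    )
    def test_error_correction_mode(self, category, expected):
        assert encode_outcome(category, "error_correction") is expected or (
            encode_outcome(category, "error_correction") == expected
        )


def _table(rng, session_index, n, channels=("Fz", "Cz", "Pz")):
    cfg = SpectralConfig()
    labels = feature_labels(channels, cfg)
    cats = rng.choice([int(C.CORRECT), int(C.SEMANTIC_ERROR)], size=n)
    return FeatureTable(
        features=pd.DataFrame(rng.standard_normal((n, len(labels))), columns=labels),
        meta=pd.DataFrame(
            {
                "session_index": session_index,
                "trial_id": np.arange(n),
                "category_code": cats,
                "item": [f"i{t}" for t in range(n)],
                "set_index": 1,
            }
        ),
        channels=channels,
        config=cfg,
    )


class TestSplit:
    def test_train_600_test_300(self, rng):
        tables = [_table(rng, i, 300) for i in (1, 2, 3)]
        train, test = split_sessions(tables)
        assert train.n_trials == 600
        assert test.n_trials == 300
        assert set(train.meta["session_index"]) == {1, 2}
        assert set(test.meta["session_index"]) == {3}

    def test_row_order_preserved(self, rng):
        tables = [_table(rng, i, 50) for i in (1, 2, 3)]
        train, _ = split_sessions(tables)
        first = train.meta[train.meta.session_index == 1]["trial_id"].values
        assert np.array_equal(first, np.arange(50))

    def test_missing_session_rejected(self, rng):
        with pytest.raises(ValueError, match="missing"):
            split_sessions([_table(rng, 1, 10), _table(rng, 2, 10)])


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
        ev = evaluate(y, y, k=1)
        assert ev.r == 1.0 and ev.p == 0.0

    def test_df_convention_matches_published_tables(self, rng):
        pred = rng.standard_normal(600)
        obs = rng.choice([0.0, 1.0], 600)
        ev = evaluate(pred, obs, k=3)
        assert ev.df_pair == (3, 596)
        ev2 = evaluate(pred[:300], obs[:300], k=3)
        assert ev2.df_pair == (3, 296)

    def test_null_correlation_below_critical_value(self):
        # at n=300, df~298, the alpha=.05 two-sided critical |r| is 0.113
        inside = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            ev = evaluate(
                rng.standard_normal(300), rng.choice([0.0, 1.0], 300), k=0
            )
            inside += abs(ev.r) < 0.113
        assert inside >= 32  # ~95% expected; generous floor

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            evaluate(np.arange(5.0), np.ones(5), k=0)

    def test_significance_tiers(self):
        assert significance_tier(0.2) == ""
        assert significance_tier(0.04) == "*"
        assert significance_tier(0.004) == "**"
        assert significance_tier(0.0004) == "***"
        assert significance_tier(0.00004) == "****"

    def test_affine_recoding_leaves_r_unchanged(self, rng):
        pred = rng.standard_normal(200)
        obs = rng.choice([0.0, 1.0, 2.0], 200)
        base = evaluate(pred, obs, k=2).r
        for a, b in [(0.5, 3.0), (10.0, -1.0), (0.001, 100.0)]:
            assert evaluate(pred, a * obs + b, k=2).r == pytest.approx(
                base, abs=1e-12
            )


class TestTopography:
    def test_shuffled_accuracy_gives_small_correlations(self, rng):
        table = _table(rng, 1, 300, channels=("Fz", "Cz", "Pz"))
        acc = rng.permutation(
            (table.meta["category_code"] == int(C.CORRECT)).astype(float).values
        )
        topo = topography_correlations(table, acc)
        assert np.abs(topo.values.values).max() < 0.25

    def test_constant_feature_column_flagged_zero(self, rng):
        table = _table(rng, 1, 50)
        table.features["Fz_6-9"] = 2.0
        topo = topography_correlations(table)
        assert topo.values.loc["Fz", "6-9"] == 0.0
        assert ("Fz", "6-9") in topo.flagged

    def test_planted_cell_is_argmax(self, small_planted_participant):
        from eegnaming.spectral_features import build_feature_table

        _, _, sessions = small_planted_participant
        table = build_feature_table(sessions, "16")
        topo = topography_correlations(table)
        assert topo.argmax_cell() == ("Cz", "10-13")
        assert topo.values.loc["Cz", "10-13"] > 0  # higher amplitude when correct


class TestRunExperiment:
    def test_planted_participant_generalizes(self, small_planted_participant):
        _, _, sessions = small_planted_participant
        report = run_experiment(sessions, "3", "accuracy", seed=1)
        assert report["test"]["r"] > 0
        assert report["test"]["p"] < 0.05
        assert report["model"]["k"] >= 1
        assert len(report["coefficients"]) == 18

    def test_nine_channel_variant_has_54_coefficients(
        self, small_planted_participant
    ):
        _, _, sessions = small_planted_participant
        report = run_experiment(sessions, "9", "accuracy", seed=1)
        assert len(report["coefficients"]) == 54

    def test_report_is_deterministic(self, small_planted_participant):
        import json

        _, _, sessions = small_planted_participant
        a = run_experiment(sessions, "3", "error_correction", seed=5)
        b = run_experiment(sessions, "3", "error_correction", seed=5)
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_error_correction_mode_excludes_trials(self, rng):
        tables = [_table(rng, i, 60) for i in (1, 2, 3)]
        t = tables[0]
        t.meta.loc[:9, "category_code"] = int(C.CIRCUMLOCUTION)
        d = coded_design(t, "error_correction")
        assert d.n == 50
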