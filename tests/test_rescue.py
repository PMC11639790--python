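"""Rescue classifier: pattern partition, direction rule, report arithmetic."""

import numpy as np
import pandas as pd
import pytest

from splicerescue import (
    CLASSES,
    ComparisonTriple,
    classify_events,
    direction_concordance,
    expression_to_alteration,
    rank_recovered,
    summarize_rescue,
)
from conftest import make_alteration, random_triple


def triple_from_patterns(patterns):
    """Build a triple where feature i has the given (sig_cd, sig_dt, sig_ct)
    pattern with effects (+20, -18, +5) unless overridden."""
    ids = [f"F{i}" for i in range(len(patterns))]
    tables = {}
    for j, key in enumerate(("cd", "dt", "ct")):
        sig, eff = [], []
        for pat in patterns:
            entry = pat[j]
            if isinstance(entry, tuple):
                s, e = entry
            else:
                s, e = entry, (20.0, -18.0, 5.0)[j] if entry else 0.5
            sig.append(bool(s))
            eff.append(float(e))
        tables[key] = make_alteration(key.upper(), ids, eff, sig)
    return ComparisonTriple(alt_cd=tables["cd"], alt_dt=tables["dt"], alt_ct=tables["ct"])


class TestDirectionConcordance:
    @pytest.mark.parametrize("a, b, expected", [
        (20.0, -18.0, "contrary"),
        (20.0, 12.0, "same"),
        (-20.0, 20.0, "contrary"),
        (-20.0, -1.0, "same"),
    ])
    def test_sign_rule(self, a, b, expected):
        assert direction_concordance(a, b) == expected

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            direction_concordance(0.0, 5.0)


class TestClassifyEvents:
    def test_all_patterns(self):
        patterns = [
            ((1, 25.0), (1, -22.0), 0),   # contrary, CT quiet -> fully_recovered
            ((1, 25.0), (1, 18.0), 0),    # same direction -> aggravated
            (1, 1, 1),                    # all three -> non_specific
            (1, 0, 1),                    # disease_persistent
            (1, 0, 0),                    # disease_unresponsive
            (0, 1, 0),                    # treatment_only
            (0, 1, 1),                    # treatment_only (CT collapsed)
            (0, 0, 1),                    # residual_only
            (0, 0, 0),                    # not_altered
        ]
        labels = classify_events(triple_from_patterns(patterns)).set_index("feature_id")["label"]
        assert labels["F0"] == "fully_recovered"
        assert labels["F1"] == "aggravated"
        assert labels["F2"] == "non_specific"
        assert labels["F3"] == "disease_persistent"
        assert labels["F4"] == "disease_unresponsive"
        assert labels["F5"] == "treatment_only"
        assert labels["F6"] == "treatment_only"
        assert labels["F7"] == "residual_only"
        assert labels["F8"] == "not_altered"

    def test_partition_property(self):
        """Every feature gets exactly one label; counts sum to the universe."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            triple = random_triple(rng)
            labels = classify_events(triple)
            universe = triple.merged()
            assert len(labels) == len(universe)
            assert set(labels["feature_id"]) == set(universe.index)
            assert labels["label"].isin(CLASSES).all()

    def test_labels_invariant_to_feature_renaming(self):
        rng = np.random.default_rng(1)
        triple = random_triple(rng)
        counts1 = classify_events(triple)["label"].value_counts().to_dict()
        renamed = ComparisonTriple(
            *[make_alteration(a.label,
                              ["Z" + f for f in a.table["feature_id"]],
                              a.table["effect"].to_numpy(),
                              a.table["significant"].to_numpy())
              for a in (triple.alt_cd, triple.alt_dt, triple.alt_ct)]
        )
        counts2 = classify_events(renamed)["label"].value_counts().to_dict()
        assert counts1 == counts2


class TestExpressionAdapter:
    def test_significance_rule(self):
        rows = pd.DataFrame({
            "gene": ["g1", "g2", "g3"],
            "log2fc": [1.2, 0.9, -1.5],
            "p_adj": [0.01, 0.001, 0.2],
        })
        alt = expression_to_alteration(rows)
        t = alt.table.set_index("feature_id")
        assert bool(t.loc["g1", "significant"]) and t.loc["g1", "effect"] > 0
        assert not t.loc["g2", "significant"]   # below fold threshold
        assert not t.loc["g3", "significant"]   # fails alpha

    def test_malformed_row_reports_position(self):
        rows = pd.DataFrame({"gene": ["g1", "g2"], "log2fc": [1.0, "oops"],
                             "p_adj": [0.01, 0.02]})
        with pytest.raises(ValueError, match="row 1"):
            expression_to_alteration(rows)

    def test_classifier_is_source_agnostic(self):
        """Identical alteration tables give identical labels whatever produced them."""
        rng = np.random.default_rng(3)
        triple = random_triple(rng)
        labels1 = classify_events(triple)
        clone = ComparisonTriple(
            *[make_alteration("expr_" + a.label,
                              a.table["feature_id"].to_numpy(),
                              a.table["effect"].to_numpy(),
                              a.table["significant"].to_numpy())
              for a in (triple.alt_cd, triple.alt_dt, triple.alt_ct)]
        )
        pd.testing.assert_frame_equal(labels1, classify_events(clone))


class TestSummarizeRescue:
    def test_published_style_arithmetic(self):
        """132 recovered + 5 non-specific over 779 disease-altered events."""
        patterns = (
            [((1, 25.0), (1, -22.0), 0)] * 132
            + [(1, 1, 1)] * 5
            + [(1, 0, 0)] * (779 - 137)
            + [(0, 0, 0)] * 50
        )
        triple = triple_from_patterns(patterns)
        labels = classify_events(triple)
        report = summarize_rescue(labels, triple)
        assert report.n_cd_significant == 779
        assert report.treatment_specific_count == 137
        rendered = report.to_dict()
        assert rendered["full_recovery_pct"] == 16.9
        assert rendered["non_specific_pct"] == 0.6

    def test_counts_partition_universe_and_venn_sums(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            triple = random_triple(rng)
            labels = classify_events(triple)
            report = summarize_rescue(labels, triple)
            assert sum(report.class_counts.values()) == report.n_features
            m = triple.merged()
            n_any = int((m[["sig_cd", "sig_dt", "sig_ct"]].any(axis=1)).sum())
            assert sum(report.venn_counts.values()) == n_any
            assert report.treatment_specific_count == (
                report.class_counts["fully_recovered"] + report.class_counts["non_specific"]
            )

    def test_no_cd_significant_gives_undefined_percentages(self):
        triple = triple_from_patterns([(0, 0, 0), (0, 1, 0)])
        labels = classify_events(triple)
        report = summarize_rescue(labels, triple)
        assert report.full_recovery_pct is None
        assert report.to_dict()["non_specific_pct"] is None


class TestRankRecovered:
    def test_orders_by_abs_cd_effect_with_lexicographic_ties(self):
        patterns = [
            ((1, 10.0), (1, -9.0), 0),
            ((1, -30.0), (1, 28.0), 0),
            ((1, 30.0), (1, -25.0), 0),
            ((1, 20.0), (1, -19.0), 0),
            (1, 0, 0),
        ]
        triple = triple_from_patterns(patterns)
        labels = classify_events(triple)
        top = rank_recovered(labels, triple, k=10)
        # |effects|: F1=30, F2=30 (tie -> lexicographic), F3=20, F0=10
        assert top["feature_id"].tolist() == ["F1", "F2", "F3", "F0"]

    def test_returns_fewer_when_fewer_exist(self):
        triple = triple_from_patterns([((1, 25.0), (1, -22.0), 0), (0, 0, 0)])
        labels = classify_events(triple)
        assert len(rank_recovered(labels, triple, k=10)) == 1

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(5)
        triple = random_triple(rng, n_features=60)
        labels = classify_events(triple)
        top = rank_recovered(labels, triple, k=8)
        m = triple.merged()
        recovered = labels.loc[labels["label"] == "fully_recovered", "feature_id"]
        expected = sorted(
            ((fid, abs(m.loc[fid, "effect_cd"])) for fid in recovered),
            key=lambda t: (-t[1], t[0]),
        )[:8]
        assert top["feature_id"].tolist() == [fid for fid, _ in expected]
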