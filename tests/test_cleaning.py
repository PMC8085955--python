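"""Five-stage cleaning: text rules, swap/outlier detection, partitioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from digilabor.cleaning import (
    DEFAULT_WHITELIST,
    EXCLUSION_CATEGORIES,
    CleaningConfig,
    classify_setback,
    clean_sessions,
    compute_task_rate_stats,
    detect_swapped_entry,
    flag_field_outliers,
    normalize_free_text,
)
from digilabor.simulate import SESSION_COLUMNS


def _frame(rows):
    return pd.DataFrame(rows, columns=list(SESSION_COLUMNS)).astype(
        {"minutes": float, "specimens": "int64"}
    )


def _session(entry_id, minutes, specimens, task="imaging", reporter="r1", text=""):
    return [entry_id, reporter, "2020-01-01", "TENN", task, minutes, specimens, text]


class TestNormalizeFreeText:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("No Setbacks!", "no setbacks"),
            ("  NONE. ", "none"),
            ("Camera—repair needed", "camera repair needed"),
            ("", ""),
            ("   \t  ", ""),
            ("UPPER   lower\nMixed", "upper lower mixed"),
        ],
    )
    def test_normalization(self, raw, expected):
        assert normalize_free_text(raw) == expected

    @settings(max_examples=50, deadline=None)
    @given(st.text(max_size=40))
    def test_idempotent_total_function(self, text):
        once = normalize_free_text(text)
        assert normalize_free_text(once) == once


class TestClassifySetback:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("none", False),
            ("No setbacks", False),
            ("training blitz at TENN", True),
            ("", False),
            ("camera broke", True),
        ],
    )
    def test_whitelist_semantics(self, text, expected):
        assert classify_setback(text, DEFAULT_WHITELIST) is expected


class TestDetectSwappedEntry:
    STATS = {"mean_rate": 2.30, "sd_rate": 0.5, "low_rate_cutoff": 1.5}

    def test_typical_entry_not_flagged(self):
        report = {"minutes": 120, "specimens": 276}
        assert not detect_swapped_entry(report, self.STATS)

    def test_constructed_swap_flagged(self):
        # fields exchanged from the typical entry above: rate 0.43 is
        # extreme-low and the inverse 2.30 matches the task mean
        report = {"minutes": 276, "specimens": 120}
        assert detect_swapped_entry(report, self.STATS)
        # swapping back yields a typical rate again (brute-force check)
        unswapped = {"minutes": 120, "specimens": 276}
        rate = unswapped["specimens"] / unswapped["minutes"]
        assert abs(rate - self.STATS["mean_rate"]) <= 2 * self.STATS["sd_rate"]

    def test_slow_but_not_swapped(self):
        # rate 0.10 is low but the inverse 10.0 is nowhere near the mean
        report = {"minutes": 600, "specimens": 60}
        assert not detect_swapped_entry(report, self.STATS)

    def test_zero_specimens_not_classifiable(self):
        assert not detect_swapped_entry({"minutes": 60, "specimens": 0}, self.STATS)


class TestFlagFieldOutliers:
    def test_single_extreme_minutes_flagged(self):
        rows = [_session(f"e{i}", 60 + (i % 5), 120) for i in range(100)]
        rows.append(_session("e_out", 6000, 120))
        flagged = flag_field_outliers(_frame(rows), threshold_sd=5)
        assert flagged == {"e_out"}

    def test_identical_entries_no_flags(self):
        rows = [_session(f"e{i}", 60, 120) for i in range(20)]
        assert flag_field_outliers(_frame(rows)) == set()

    def test_exactly_at_threshold_not_flagged(self):
        """'Exceeding' the threshold is strict: a value at exactly
        threshold x SD stays."""
        vals = np.array([0.0, 0.0, 1.0])
        sd = vals.std(ddof=1)
        z_max = (vals - vals.mean()).max() / sd
        rows = [_session(f"e{i}", 100, 100 + int(v)) for i, v in enumerate(vals * 300)]
        flagged = flag_field_outliers(_frame(rows), threshold_sd=z_max + 1e-9)
        assert flagged == set()
        assert flag_field_outliers(_frame(rows), threshold_sd=z_max - 1e-6)

    def test_stats_are_per_task(self):
        # a 300-minute session is normal for task A but extreme for task B
        rows = [_session(f"a{i}", 300 + (i % 7), 600, task="imaging") for i in range(50)]
        rows += [_session(f"b{i}", 60 + (i % 7), 240, task="barcoding") for i in range(50)]
        rows.append(_session("b_out", 300, 240, task="barcoding"))
        flagged = flag_field_outliers(_frame(rows), threshold_sd=5)
        assert flagged == {"b_out"}


class TestCleanSessions:
    def test_no_anomalies_keeps_everything(self, anomaly_free_config):
        from digilabor.simulate import generate_sessions

        sessions, _ = generate_sessions(anomaly_free_config)
        outcome = clean_sessions(sessions, CleaningConfig())
        assert len(outcome.kept) == len(sessions)
        assert all(len(df) == 0 for df in outcome.excluded.values())

    def test_conservation_and_disjoint_categories(self, default_sessions, default_outcome):
        sessions, _ = default_sessions
        outcome = default_outcome
        total = len(outcome.kept) + sum(len(df) for df in outcome.excluded.values())
        assert total == len(sessions)
        ids = [outcome.kept["entry_id"]] + [
            df["entry_id"] for df in outcome.excluded.values()
        ]
        all_ids = pd.concat(ids)
        assert not all_ids.duplicated().any()
        assert set(outcome.excluded) == set(EXCLUSION_CATEGORIES)

    def test_injected_labels_recovered_exactly(self, default_sessions, default_outcome):
        """On the default synthetic fixture every injected anomaly is
        recovered by its cleaning stage: precision and recall 1.0."""
        _, labels = default_sessions
        expected = {
            "nonrepresentative_reporter": "fraudulent_reporter",
            "nonrepresentative_workflow": "nonrepresentative_workflow",
            "entry_error": "swapped_fields",
            "setback": "setback",
            "extreme_outlier": "extreme_outlier",
        }
        for category, label in expected.items():
            got = set(default_outcome.excluded[category]["entry_id"])
            want = set(labels.loc[labels["label"] == label, "entry_id"])
            assert got == want, category
        kept_labels = set(
            labels.set_index("entry_id").loc[default_outcome.kept["entry_id"], "label"]
        )
        assert kept_labels == {"clean"}

    def test_setback_takes_precedence_over_outlier(self):
        """An entry that is both a setback and a numeric outlier is
        categorized by the earlier stage (setback)."""
        rows = [_session(f"e{i}", 60 + (i % 5), 120 + (i % 7)) for i in range(100)]
        rows.append(_session("e_both", 6000, 120, text="camera broke"))
        outcome = clean_sessions(_frame(rows), CleaningConfig())
        assert list(outcome.excluded["setback"]["entry_id"]) == ["e_both"]
        assert len(outcome.excluded["extreme_outlier"]) == 0

    def test_manual_exclusion_lists_apply_first(self):
        rows = [
            _session("e1", 60, 120, reporter="bad_reporter", text="camera broke"),
            _session("e2", 60, 120),
            _session("e3", 60, 125),
        ]
        config = CleaningConfig(
            excluded_reporters=frozenset({"bad_reporter"}),
            excluded_workflow_entries=frozenset({"e2"}),
        )
        outcome = clean_sessions(_frame(rows), config)
        assert list(outcome.excluded["nonrepresentative_reporter"]["entry_id"]) == ["e1"]
        assert list(outcome.excluded["nonrepresentative_workflow"]["entry_id"]) == ["e2"]
        assert list(outcome.kept["entry_id"]) == ["e3"]

    def test_empty_input(self):
        outcome = clean_sessions(_frame([]), CleaningConfig())
        assert len(outcome.kept) == 0
        assert outcome.audit["n_entries"].sum() == 0

    def test_audit_hours_match_partitions(self, default_outcome):
        audit = default_outcome.audit.set_index("category")
        for cat, df in default_outcome.excluded.items():
            assert audit.loc[cat, "n_entries"] == len(df)
            assert audit.loc[cat, "hours"] == pytest.approx(df["minutes"].sum() / 60.0)
        assert audit.loc["kept", "hours"] == pytest.approx(
            default_outcome.kept["minutes"].sum() / 60.0
        )

    def test_idempotent_through_stage_four(self, default_outcome):
        """Re-cleaning the kept partition excludes nothing in stages 1-4;
        only the outlier stage may move (its SDs are recomputed)."""
        again = clean_sessions(default_outcome.kept, CleaningConfig())
        for category in (
            "nonrepresentative_reporter",
            "nonrepresentative_workflow",
            "entry_error",
            "setback",
        ):
            assert len(again.excluded[category]) == 0


class TestTaskRateStats:
    def test_zero_specimen_entries_ignored(self):
        rows = [_session(f"e{i}", 60, 120) for i in range(10)]
        rows.append(_session("curation", 60, 0, task="other"))
        stats = compute_task_rate_stats(_frame(rows))
        assert "other" not in stats
        assert stats["imaging"]["mean_rate"] == pytest.approx(2.0)
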