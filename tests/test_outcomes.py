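"""Outcome statistics: ingestion, scheme ranking, block performance, heatmap."""

import numpy as np
import pandas as pd
import pytest

from nanomcr import (
    block_performance,
    build_campaign,
    generate_bank,
    generate_outcomes,
    heatmap_matrix,
    ingest_calls,
    scheme_success_rates,
)
from nanomcr.outcomes import (
    CallVocabularyError,
    IncompleteTableError,
    UnknownWellError,
)


def _calls_frame(campaign, call_fn):
    rows = [
        (w.destination.plate_id, w.destination.well, call_fn(i, w))
        for i, w in enumerate(campaign.wells)
    ]
    return pd.DataFrame(rows, columns=["plate", "well", "call"])


@pytest.fixture(scope="module")
def gbb_campaign(registry, study_bank):
    return build_campaign([registry.get(1)], study_bank, 96, seed=3)


class TestIngestion:
    def test_complete_table(self, study_campaign):
        calls = _calls_frame(study_campaign, lambda i, w: "major")
        table = ingest_calls(calls, study_campaign)
        assert table.complete and len(table.calls) == 1536

    def test_vocabulary_enforced(self, gbb_campaign):
        calls = _calls_frame(gbb_campaign, lambda i, w: "trace")
        with pytest.raises(CallVocabularyError):
            ingest_calls(calls, gbb_campaign)

    def test_unknown_well_rejected(self, gbb_campaign):
        calls = _calls_frame(gbb_campaign, lambda i, w: "major")
        calls.loc[0, "well"] = "Z99"
        with pytest.raises(UnknownWellError):
            ingest_calls(calls, gbb_campaign)

    def test_missing_wells_reported(self, gbb_campaign):
        calls = _calls_frame(gbb_campaign, lambda i, w: "major").iloc[:-1]
        table = ingest_calls(calls, gbb_campaign)
        assert len(table.missing) == 1
        assert table.missing[0] == gbb_campaign.wells[-1].destination
        with pytest.raises(IncompleteTableError):
            scheme_success_rates(table)


class TestSchemeStats:
    def test_reference_gbb_fixture(self, gbb_campaign):
        """17 major + 38 medium + 41 none of 96 rounds to 57% success, 18% major."""
        seq = ["major"] * 17 + ["medium"] * 38 + ["none"] * 41
        calls = _calls_frame(gbb_campaign, lambda i, w: seq[i])
        stats = scheme_success_rates(ingest_calls(calls, gbb_campaign))
        row = stats.iloc[0]
        assert row["n_wells"] == 96
        assert row["frac_success"] == pytest.approx(55 / 96)
        assert row["pct_success"] == 57
        assert row["pct_major"] == 18

    def test_degenerate_tables(self, gbb_campaign):
        for call, field in [("none", "frac_none"), ("major", "frac_major")]:
            calls = _calls_frame(gbb_campaign, lambda i, w: call)
            stats = scheme_success_rates(ingest_calls(calls, gbb_campaign))
            assert stats.iloc[0][field] == 1.0
        assert stats.iloc[0]["frac_success"] == 1.0

    def test_fractions_normalised_and_sorted(self, study_campaign):
        calls = generate_outcomes(study_campaign, seed=9)
        stats = scheme_success_rates(ingest_calls(calls, study_campaign))
        assert len(stats) == 16
        np.testing.assert_allclose(
            stats[["frac_major", "frac_medium", "frac_none"]].sum(axis=1), 1.0
        )
        assert list(stats["frac_success"]) == sorted(stats["frac_success"], reverse=True)

    def test_row_order_invariance(self, study_campaign):
        calls = generate_outcomes(study_campaign, seed=9)
        shuffled = calls.sample(frac=1, random_state=0).reset_index(drop=True)
        a = scheme_success_rates(ingest_calls(calls, study_campaign))
        b = scheme_success_rates(ingest_calls(shuffled, study_campaign))
        pd.testing.assert_frame_equal(a, b)


class TestBlockPerformance:
    def test_hand_counted_amidine(self, registry, study_bank):
        campaign = build_campaign([registry.get(1)], study_bank, 96, seed=3)
        target = campaign.wells[0].slot_choice[0]  # an amidine id
        wells_using = [w for w in campaign.wells if w.slot_choice[0] == target]
        seq = {}
        pattern = ["major", "major", "none", "medium"]
        for k, w in enumerate(wells_using):
            seq[w.destination] = pattern[k % 4]
        calls = _calls_frame(
            campaign, lambda i, w: seq.get(w.destination, "none")
        )
        table = ingest_calls(calls, campaign)
        stats = block_performance(table, "amidine", study_bank, scheme_id=1)
        row = stats[stats["block_id"] == target].iloc[0]
        by_hand = pd.Series([seq[w.destination] for w in wells_using]).value_counts()
        assert row["n_major"] == by_hand.get("major", 0)
        assert row["n_medium"] == by_hand.get("medium", 0)
        assert row["n_used"] == len(wells_using)

    def test_usage_conservation(self, registry, study_bank):
        campaign = build_campaign([registry.get(1)], study_bank, 96, seed=3)
        calls = _calls_frame(campaign, lambda i, w: "medium")
        table = ingest_calls(calls, campaign)
        for cls in ("amidine", "aldehyde", "isocyanide"):
            stats = block_performance(table, cls, study_bank, scheme_id=1)
            assert stats["n_used"].sum() == 96  # one slot of each class per well
        assert (stats["n_success"] == stats["n_used"]).all()

    def test_unknown_class_rejected(self, gbb_campaign, study_bank):
        calls = _calls_frame(gbb_campaign, lambda i, w: "major")
        table = ingest_calls(calls, gbb_campaign)
        with pytest.raises(KeyError):
            block_performance(table, "phosphine", study_bank)


class TestHeatmap:
    def test_all_major_grid(self, study_campaign):
        calls = _calls_frame(study_campaign, lambda i, w: "major")
        grid = heatmap_matrix(ingest_calls(calls, study_campaign))
        assert grid.shape == (32, 48)
        assert np.nansum(grid == 2) == 1536

    def test_marginals_match_scheme_totals(self, study_campaign):
        calls = generate_outcomes(study_campaign, seed=5)
        table = ingest_calls(calls, study_campaign)
        grid = heatmap_matrix(table)
        stats = scheme_success_rates(table)
        total_major = (stats["frac_major"] * stats["n_wells"]).sum()
        assert np.nansum(grid == 2) == pytest.approx(total_major)

    def test_requires_four_plates(self, gbb_campaign):
        calls = _calls_frame(gbb_campaign, lambda i, w: "major")
        with pytest.raises(ValueError):
            heatmap_matrix(ingest_calls(calls, gbb_campaign))


class TestOutcomeGenerator:
    def test_degenerate_probabilities(self, gbb_campaign):
        all_major = generate_outcomes(gbb_campaign, {1: (1.0, 0.0)}, seed=0)
        assert set(all_major["call"]) == {"major"}
        all_none = generate_outcomes(gbb_campaign, {1: (0.0, 0.0)}, seed=0)
        assert set(all_none["call"]) == {"none"}

    def test_invalid_probabilities_rejected(self, gbb_campaign):
        with pytest.raises(ValueError):
            generate_outcomes(gbb_campaign, {1: (0.8, 0.5)}, seed=0)
        with pytest.raises(ValueError):
            generate_outcomes(gbb_campaign, {1: (-0.1, 0.5)}, seed=0)

    def test_parameter_recovery_binomial(self, gbb_campaign):
        """Across 500 seeded replicates the mean call fractions recover the
        generating probabilities within 3 standard errors."""
        p_major, p_medium = 0.18, 0.39
        n_rep, n_wells = 500, 96
        fractions = np.empty((n_rep, 2))
        for r in range(n_rep):
            calls = generate_outcomes(gbb_campaign, {1: (p_major, p_medium)}, seed=r)
            counts = calls["call"].value_counts()
            fractions[r] = (
                counts.get("major", 0) / n_wells,
                counts.get("medium", 0) / n_wells,
            )
        for k, p in enumerate((p_major, p_medium)):
            se = np.sqrt(p * (1 - p) / (n_rep * n_wells))
            assert abs(fractions[:, k].mean() - p) < 3 * se
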