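"""Rank tests, outlier flagging, summaries and the habitat-use classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elasmoiso import habitat, synthetic
from elasmoiso.habitat import (
    ClassifierThresholds,
    ToothMeasurement,
    classify_habitat_use,
    dunn_posthoc,
    flag_outliers,
    guild_compare,
    kruskal_wallis,
    summarize_by,
)


class TestKruskalWallis:
    def test_two_group_hand_computation(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857142857, abs=1e-6)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(3.857142857, 1), abs=1e-6)

    def test_identical_groups(self):
        h, _, p = kruskal_wallis([[5.0, 5.0], [5.0, 5.0]])
        assert h == 0.0
        assert p == 1.0

    def test_group_order_invariance(self):
        a, b, c = [1.0, 4.0, 2.5], [3.0, 8.0], [0.5, 6.0, 7.0]
        h1, _, p1 = kruskal_wallis([a, b, c])
        h2, _, p2 = kruskal_wallis([c, a, b])
        assert h1 == pytest.approx(h2)
        assert p1 == pytest.approx(p2)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])

    def test_exact_p_matches_two_group_enumeration(self):
        """Exact mode agrees with the textbook permutation p for {1,2,3} vs {4,5,6}."""
        h, _, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]], method="exact")
        # only 2 of the C(6,3)=20 assignments reach the maximal separation
        assert p == pytest.approx(2 / 20)
        assert h == pytest.approx(3.857142857, abs=1e-6)


class TestDunn:
    def test_identical_groups_all_p_one(self):
        table = dunn_posthoc([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert (table["p"] == 1.0).all()

    def test_two_group_direction_matches_rank_separation(self):
        table = dunn_posthoc([[1, 2, 3], [4, 5, 6]])
        z = table["z"].iloc[0]
        assert z < 0  # group a holds the smaller ranks
        assert table["p"].iloc[0] < 0.06

    def test_adjustment_monotonicity(self):
        groups = [[1.0, 2.0], [2.5, 3.5], [5.0, 6.0]]
        raw = dunn_posthoc(groups, adjustment="none")
        for adj in ("bonferroni", "holm"):
            table = dunn_posthoc(groups, adjustment=adj)
            assert (table["p_adjusted"].to_numpy() >= raw["p"].to_numpy() - 1e-12).all()

    def test_pairwise_symmetry_in_abs_z(self):
        groups = [[1.0, 4.0], [2.0, 5.0], [9.0, 10.0]]
        t1 = dunn_posthoc(groups, labels=["a", "b", "c"])
        t2 = dunn_posthoc(groups[::-1], labels=["c", "b", "a"])
        z1 = {frozenset((r.group_a, r.group_b)): abs(r.z) for r in t1.itertuples()}
        z2 = {frozenset((r.group_a, r.group_b)): abs(r.z) for r in t2.itertuples()}
        for key in z1:
            assert z1[key] == pytest.approx(z2[key], abs=1e-9)

    def test_fewer_than_two_groups_errors(self):
        with pytest.raises(ValueError):
            dunn_posthoc([[1.0, 2.0]])


class TestOutliers:
    def test_low_value_flagged(self):
        vals = [22.0, 22.3, 21.8, 22.1, 21.9, 22.2, 22.4, 21.7, 22.0, 22.1, 17.0]
        out = flag_outliers(vals)
        assert bool(out.loc[out["value"] == 17.0, "outlier"].iloc[0])
        assert out["outlier"].sum() == 1

    def test_threshold_arithmetic(self):
        """Pool with mean 22, SD 1.3 flags only values below 19.4."""
        rng = np.random.default_rng(0)
        base = rng.normal(0.0, 1.0, 400)
        base = (base - base.mean()) / base.std(ddof=1)  # exactly mean 0, sd 1
        vals = 22.0 + 1.3 * base
        out = flag_outliers(vals)
        cut = 22.0 - 2 * 1.3
        assert (out.loc[out["outlier"], "value"] < cut).all()
        assert (out.loc[~out["outlier"], "value"] >= cut).all()

    def test_only_low_side_flagged(self):
        vals = np.concatenate([np.zeros(10), [-5.0, 5.0]])
        out = flag_outliers(vals)
        flagged = out.loc[out["outlier"], "value"]
        assert (flagged < 0).all()

    def test_degenerate_pool(self):
        out = flag_outliers([3.0, 3.0, 3.0])
        assert out["degenerate"].all()
        assert out["z"].isna().all()


class TestSummaries:
    def test_single_value_group(self):
        df = pd.DataFrame({"telm": [5], "guild": ["pelagic"], "d18Op": [22.0]})
        out = summarize_by(df, ["telm"])
        row = out.iloc[0]
        assert row["mean"] == row["median"] == 22.0
        assert row["sd"] == 0.0 and row["sd_undefined"]

    def test_hand_computed_group(self):
        df = pd.DataFrame({"telm": [4] * 3, "d18Op": [21.0, 22.0, 23.0]})
        row = summarize_by(df, ["telm"]).iloc[0]
        assert row["mean"] == pytest.approx(22.0)
        assert row["median"] == pytest.approx(22.0)
        assert (row["min"], row["max"]) == (21.0, 23.0)

    def test_group_sizes_conserve_n(self, seymour_envelope):
        df = synthetic.make_tooth_dataset(synthetic.default_scenarios(), seymour_envelope, seed=3)
        out = summarize_by(df, ["telm", "guild"])
        assert out["n"].sum() == len(df)

    def test_unknown_key_errors(self):
        with pytest.raises(ValueError):
            summarize_by(pd.DataFrame({"d18Op": [1.0]}), ["nope"])


class TestToothMeasurement:
    def test_sanity_window_enforced(self):
        with pytest.raises(ValueError):
            ToothMeasurement("x", "Raja", 5, "benthic", 42.0)

    def test_bad_guild_rejected(self):
        with pytest.raises(ValueError):
            ToothMeasurement("x", "Raja", 5, "demersal", 22.0)


class TestClassifier:
    def test_values_matching_bivalves_inside_envelope_read_local(self, seymour_envelope, rng):
        lo, hi = seymour_envelope.range_of("d18Op_star")
        center = (lo + hi) / 2
        vals = rng.uniform(lo + 0.2, hi - 0.2, 20)
        vals += center - np.median(vals)
        call = classify_habitat_use(vals, seymour_envelope, center)
        assert call.label == "local"
        assert call.fraction_inside >= 0.75

    def test_printed_shift_scenario_reads_warm(self, seymour_envelope):
        """A taxon median 1.7 permil below the bivalve median is warm/brackish-shifted."""
        biv_median = 22.2
        taxon_median = 20.5
        vals = taxon_median + np.array([-0.3, -0.1, 0.0, 0.1, 0.3])
        call = classify_habitat_use(vals, seymour_envelope, biv_median)
        assert call.label == "warm_or_brackish_shifted"
        assert call.median_offset_bivalve == pytest.approx(-1.7, abs=1e-9)

    def test_cold_shift_symmetric(self, seymour_envelope):
        lo, hi = seymour_envelope.range_of("d18Op_star")
        vals = hi + 1.0 + np.array([-0.1, 0.0, 0.0, 0.1])
        call = classify_habitat_use(vals, seymour_envelope, (lo + hi) / 2)
        assert call.label == "cold_or_deep_shifted"

    def test_two_well_separated_modes_read_bimodal(self, seymour_envelope, rng):
        lo, hi = seymour_envelope.range_of("d18Op_star")
        center = (lo + hi) / 2
        vals = np.concatenate([
            rng.normal(center - 1.0, 0.2, 25),
            rng.normal(center + 1.0, 0.2, 25),
        ])
        call = classify_habitat_use(vals, seymour_envelope, center)
        assert call.label == "bimodal_mixed"
        assert call.mode_count >= 2

    def test_small_samples_insufficient(self, seymour_envelope):
        call = classify_habitat_use([22.0, 22.1, 21.9], seymour_envelope, 22.0)
        assert call.label == "insufficient_n"

    def test_widening_envelope_moves_toward_local(self, seymour_envelope, envelope_6x):
        """Threshold monotonicity: a wider envelope can only relax shifted calls."""
        lo, hi = seymour_envelope.range_of("d18Op_star")
        center = (lo + hi) / 2
        vals = np.full(6, lo - 0.6) + np.linspace(-0.05, 0.05, 6)
        narrow = classify_habitat_use(vals, seymour_envelope, np.median(vals) + 0.2)
        wide_env = synthetic.make_climate_grid(
            "3x", seasonal_amplitude=7.0, seed=0
        )
        from elasmoiso import climate
        wide = classify_habitat_use(
            vals,
            climate.extract_site_series(wide_env, climate.SEYMOUR_ISLAND),
            np.median(vals) + 0.2,
        )
        assert narrow.label == "warm_or_brackish_shifted"
        assert wide.label == "local"

    def test_missing_envelope_errors(self):
        with pytest.raises(ValueError):
            classify_habitat_use([22.0] * 5, None, 22.0)


class TestGuildCompare:
    def test_identical_guild_distributions(self):
        df = pd.DataFrame(
            {
                "telm": [5] * 8,
                "guild": ["pelagic"] * 4 + ["benthic"] * 4,
                "d18Op": [21.0, 22.0, 23.0, 24.0] * 2,
            }
        )
        out = guild_compare(df)
        assert out["H"].iloc[0] == pytest.approx(0.0, abs=0.1)
        assert not out["flagged"].iloc[0]

    def test_single_guild_rows_flagged_not_computed(self):
        df = pd.DataFrame(
            {
                "telm": [2] * 4 + [5] * 6,
                "guild": ["pelagic"] * 4 + ["pelagic"] * 3 + ["benthic"] * 3,
                "d18Op": np.linspace(21, 23, 10),
            }
        )
        out = guild_compare(df).set_index("telm")
        assert out.loc[2, "flagged"]
        assert np.isnan(out.loc[2, "H"])
        assert not out.loc[5, "flagged"]

    def test_detects_guild_shift(self, rng):
        """A +2 permil benthic offset at n=30/30 is detected in >=95/100 replicates."""
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "telm": [5] * 60,
                    "guild": ["pelagic"] * 30 + ["benthic"] * 30,
                    "d18Op": np.concatenate(
                        [r.normal(21.5, 1.0, 30), r.normal(23.5, 1.0, 30)]
                    ),
                }
            )
            hits += guild_compare(df)["p"].iloc[0] < 0.05
        assert hits >= 95
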