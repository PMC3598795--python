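"""Known-groups validity: grouping, ANOVA decomposition, eta effect sizes.

The field-test comparison table (three health-status groups, one row per
scale) prints n, mean and SD per group next to a p-value and an effect
size.  Recomputing the ANOVA from those printed summaries must reproduce
the printed effect sizes — that recomputation doubles as the check that the
implemented effect size is the correlation ratio.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from psychfield import (
    GroupSummary,
    anova_from_summary,
    anova_oneway,
    assign_groups,
    effect_size_label,
    known_groups_table,
)
from psychfield.dataset import ResponseDataset
from psychfield.known_groups import GROUP_LABELS, format_p, load_group_summaries
from psychfield.scoring import score_dataset
from psychfield.simulate import SimulationConfig, simulate

# Published field-test rows without a footnote marker: per scale, the three
# group summaries (n, mean, sd) and the printed effect size.
PUBLISHED_ROWS = {
    "Physical Functioning": ([(46, 79.66, 24.79), (46, 64.51, 25.99), (41, 43.29, 23.61)], 0.51),
    "Worry": ([(46, 51.38, 24.77), (43, 44.77, 24.65), (38, 29.71, 19.79)], 0.36),
    "Pain and Hurt": ([(46, 74.09, 28.45), (43, 58.53, 25.10), (38, 23.25, 22.77)], 0.63),
    "Paresthesias": ([(46, 73.10, 30.61), (43, 65.41, 25.71), (38, 34.21, 23.19)], 0.53),
    "Skin Irritation": ([(46, 77.83, 20.46), (43, 65.23, 22.47), (38, 50.53, 25.14)], 0.44),
    "Movement and Balance": ([(46, 87.91, 20.04), (42, 74.26, 21.08), (37, 51.69, 30.29)], 0.53),
    "Daily Activities": ([(46, 95.61, 15.45), (42, 94.49, 16.13), (36, 75.46, 22.91)], 0.45),
    "Fatigue": ([(46, 63.04, 27.81), (42, 58.93, 24.72), (36, 28.94, 19.05)], 0.52),
    "Treatment Anxiety": ([(46, 82.79, 23.33), (42, 77.78, 23.47), (36, 62.50, 27.78)], 0.32),
    "Total Score": ([(47, 74.37, 14.03), (46, 64.63, 15.64), (41, 48.37, 13.60)], 0.59),
}

# Full-sample means from the descriptive table, cross-checkable as weighted
# grand means of the group rows above.
FULL_SAMPLE_MEANS = {
    "Total Score": 63.07,
    "Worry": 42.66,
    "Paresthesias": 58.86,
    "Fatigue": 51.75,
    "Physical Functioning": 63.21,
}


def summaries(triples):
    return [
        GroupSummary(label=lab, n=n, mean=m, sd=sd)
        for lab, (n, m, sd) in zip(GROUP_LABELS, triples)
    ]


class TestAssignGroups:
    def test_five_levels_collapse_to_three(self):
        labels, excl = assign_groups(["excellent", "very good", "good", "fair", "poor"])
        assert labels.tolist() == [
            GROUP_LABELS[0], GROUP_LABELS[0], GROUP_LABELS[1], GROUP_LABELS[2], GROUP_LABELS[2],
        ]
        assert excl == 0

    def test_missing_excluded_and_counted(self):
        labels, excl = assign_groups(["good", None, float("nan"), "fair"])
        assert excl == 2
        assert labels.notna().sum() == 2

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="splendid"):
            assign_groups(["good", "splendid"])


class TestAnovaOneway:
    def test_equal_group_means_give_zero_f_and_eta(self):
        row = anova_oneway([1.0, 2, 3, 1, 2, 3], ["a", "a", "a", "b", "b", "b"])
        assert row.f == pytest.approx(0.0)
        assert row.eta == pytest.approx(0.0)

    def test_perfect_separation(self):
        row = anova_oneway([0.0, 0, 100, 100], ["a", "a", "b", "b"])
        assert row.ss_within == 0.0
        assert row.eta == 1.0
        assert row.p == 0.0

    def test_matches_brute_force_and_scipy(self):
        groups = {"g1": [55.0, 60, 70, 65, 50], "g2": [40.0, 45, 55, 35, 50], "g3": [20.0, 30, 25, 35, 15]}
        values = sum(groups.values(), [])
        labels = sum(([k] * 5 for k in groups), [])
        row = anova_oneway(values, labels)
        # brute force from explicit sums
        grand = np.mean(values)
        ssb = sum(5 * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(sum((x - np.mean(v)) ** 2 for x in v) for v in groups.values())
        assert row.ss_between == pytest.approx(ssb, abs=1e-10)
        assert row.ss_within == pytest.approx(ssw, abs=1e-10)
        f_scipy, p_scipy = stats.f_oneway(*groups.values())
        assert row.f == pytest.approx(f_scipy, abs=1e-10)
        assert row.p == pytest.approx(p_scipy, abs=1e-12)
        assert row.eta == pytest.approx(np.sqrt(ssb / (ssb + ssw)), abs=1e-12)

    def test_missing_scores_dropped_listwise(self):
        row = anova_oneway([1.0, 2, np.nan, 5, 6, 7], ["a", "a", "a", "b", "b", "b"])
        assert row.groups[0].n == 2 and row.groups[1].n == 3

    def test_group_emptied_by_missingness_rejected(self):
        with pytest.raises(ValueError, match="< 2 non-missing"):
            anova_oneway([1.0, np.nan, 5, 6], ["a", "a", "b", "b"])


class TestAnovaFromSummary:
    def test_equivalent_to_raw_anova(self):
        rng = np.random.default_rng(51)
        values = np.concatenate([rng.normal(50, 10, 20), rng.normal(60, 12, 25), rng.normal(40, 8, 15)])
        labels = ["a"] * 20 + ["b"] * 25 + ["c"] * 15
        raw = anova_oneway(values, labels)
        summ = anova_from_summary(raw.groups)
        assert summ.ss_between == pytest.approx(raw.ss_between, abs=1e-9)
        assert summ.ss_within == pytest.approx(raw.ss_within, abs=1e-9)
        assert summ.f == pytest.approx(raw.f, abs=1e-10)
        assert summ.eta == pytest.approx(raw.eta, abs=1e-12)

    def test_identical_groups_give_zero(self):
        g = [GroupSummary("a", 10, 50.0, 5.0), GroupSummary("b", 10, 50.0, 5.0)]
        row = anova_from_summary(g)
        assert row.f == 0.0 and row.eta == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 groups"):
            anova_from_summary([GroupSummary("a", 10, 50.0, 5.0)])

    @pytest.mark.parametrize("scale", sorted(PUBLISHED_ROWS))
    def test_published_effect_sizes_reproduced(self, scale):
        """Printed group summaries recompose to the printed eta (2 d.p.)."""
        triples, printed_eta = PUBLISHED_ROWS[scale]
        row = anova_from_summary(summaries(triples))
        assert round(row.eta, 2) == printed_eta

    @pytest.mark.parametrize("scale", sorted(FULL_SAMPLE_MEANS))
    def test_grand_means_match_descriptive_table(self, scale):
        triples, _ = PUBLISHED_ROWS[scale]
        row = anova_from_summary(summaries(triples))
        assert round(row.grand_mean, 2) == pytest.approx(FULL_SAMPLE_MEANS[scale], abs=0.005)

    def test_pain_row_is_significant_with_medium_effect(self):
        triples, _ = PUBLISHED_ROWS["Pain and Hurt"]
        row = anova_from_summary(summaries(triples))
        assert format_p(row.p) == "<.0001"
        assert effect_size_label(row.eta) == "medium"

    def test_summary_csv_round_trip(self, tmp_path):
        p = tmp_path / "summ.csv"
        p.write_text(
            "scale,group,n,mean,sd\n"
            "Pain and Hurt,excellent-very good,46,74.09,28.45\n"
            "Pain and Hurt,good,43,58.53,25.10\n"
            "Pain and Hurt,fair-poor,38,23.25,22.77\n"
        )
        loaded = load_group_summaries(p)
        row = anova_from_summary(loaded["Pain and Hurt"])
        assert round(row.eta, 2) == 0.63


class TestEffectSizeLabel:
    @pytest.mark.parametrize(
        "eta,label",
        [
            (0.63, "medium"), (0.22, "small"), (0.19, "sub-small"),
            (0.20, "small"), (0.50, "medium"), (0.80, "large"), (0.0, "sub-small"), (1.0, "large"),
        ],
    )
    def test_banding(self, eta, label):
        assert effect_size_label(eta) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            effect_size_label(1.2)


class TestKnownGroupsTable:
    def test_null_shifts_give_small_etas(self, spec, ds600_null):
        table = known_groups_table(ds600_null, spec)
        assert not table.skipped
        assert all(row.eta < 0.15 for row in table.rows.values())

    def test_ordered_shifts_recovered(self, spec, ds600_shift):
        table = known_groups_table(ds600_shift, spec)
        for scale, row in table.rows.items():
            if scale != "Total Score":
                assert 0.3 <= row.eta <= 0.6, scale
            means = [g.mean for g in row.groups]
            assert means[0] > means[1] > means[2], scale
        # the 67-item Total averages away item noise, so it separates at
        # least as strongly as the typical subscale
        subscale_etas = [r.eta for s, r in table.rows.items() if s != "Total Score"]
        assert table.rows["Total Score"].eta >= np.median(subscale_etas)

    def test_eta_increases_with_group_separation(self):
        base = [(30, 50.0, 10.0), (30, 50.0, 10.0), (30, 50.0, 10.0)]
        etas = []
        for delta in (0, 5, 10, 20):
            triples = [(30, 50.0 - delta, 10.0), (30, 50.0, 10.0), (30, 50.0 + delta, 10.0)]
            etas.append(anova_from_summary(summaries(triples)).eta)
        assert etas == sorted(etas) and etas[0] == 0.0 and etas[-1] > etas[1]

    def test_scale_with_empty_group_flagged_others_computed(self, spec):
        ds, _ = simulate(SimulationConfig(seed=61))
        raw = ds.raw.copy()
        fair_poor = ds.health_status.isin(["fair", "poor"])
        raw.loc[fair_poor, list(spec.subscale("Fatigue").item_ids)] = np.nan
        ds2 = ResponseDataset(raw=raw, health_status=ds.health_status)
        table = known_groups_table(ds2, spec)
        assert "Fatigue" in table.skipped
        assert "Pain and Hurt" in table.rows

    def test_missing_health_status_excluded_but_scored(self, spec):
        ds, _ = simulate(SimulationConfig(seed=62))
        hs = ds.health_status.copy()
        hs.iloc[:10] = np.nan
        ds2 = ResponseDataset(raw=ds.raw, health_status=hs)
        table = known_groups_table(ds2, spec)
        assert table.excluded_respondents == 10
        # the scoring side still covers everyone
        assert score_dataset(ds2, spec).scores.shape[0] == ds.n_respondents

    def test_group_means_ordered_as_health_worsens(self, spec, ds600_shift):
        """Better self-reported health -> higher HRQOL scores on every scale."""
        table = known_groups_table(ds600_shift, spec)
        row = table.rows["Total Score"]
        assert [g.label for g in row.groups] == list(GROUP_LABELS)
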