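import numpy as np
import pandas as pd
import pytest

from ventphen.mixture import PosteriorMatrix
from ventphen.outcomes import (
    profile_report,
    relative_excess,
    sofa_mortality_table,
    survival_curves,
)


def _cohort(n, sofa, dead, death_day=None, extra=None):
    df = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "sofa": sofa,
        "death28": dead,
    })
    if death_day is None:
        death_day = [7 if d else pd.NA for d in dead]
    df["death_day"] = pd.array(death_day, dtype="Int64")
    for k, v in (extra or {}).items():
        df[k] = v
    return df


def _onehot_post(df, labels, assignment):
    probs = np.zeros((len(df), len(labels)))
    for i, a in enumerate(assignment):
        probs[i, labels.index(a)] = 1.0
    return PosteriorMatrix(list(df["patient_id"]), probs, labels)


class TestProfileReport:
    def test_single_phenotype_proportions(self):
        df = _cohort(10, sofa=np.arange(10.0), dead=[False] * 10,
                     extra={"hr": np.linspace(60, 90, 10)})
        post = _onehot_post(df, [1], [1] * 10)
        prof = profile_report(df, post, ["hr", "sofa"])
        assert prof.summary["proportion"].tolist() == [1.0]
        assert prof.summary["n"].tolist() == [10]

    def test_published_count_proportions(self):
        """Assigned counts 2174/480/241/368/746 give the printed percentages."""
        counts = [2174, 480, 241, 368, 746]
        labels = [1, 2, 3, 4, 5]
        assignment = sum(([lab] * c for lab, c in zip(labels, counts)), [])
        n = sum(counts)
        df = _cohort(n, sofa=np.zeros(n), dead=[False] * n,
                     extra={"hr": np.zeros(n)})
        post = _onehot_post(df, labels, assignment)
        prof = profile_report(df, post, ["hr"])
        pct = (prof.summary["proportion"] * 100).round(1).tolist()
        assert pct == [54.2, 12.0, 6.0, 9.2, 18.6]

    def test_group_means_recover_generator_parameters(self, prepared_cohort,
                                                      panel):
        """Grouping by the true class reproduces per-phenotype age means."""
        cohort, completed, _, scaler = prepared_cohort
        merged = cohort.copy()
        merged[completed.columns] = completed.to_numpy()
        labels = [1, 2, 3, 4, 5]
        post = _onehot_post(merged, labels, merged["true_class"].tolist())
        prof = profile_report(merged, post, ["age", "hr"], scaler)
        age = next(f for f in panel if f.name == "age")
        for k, lab in enumerate(labels):
            n_k = int(prof.summary.loc[prof.summary["phenotype"] == lab,
                                       "n"].iloc[0])
            got = float(prof.feature_table.loc[
                prof.feature_table["feature"] == "age",
                f"mean_{lab}"].iloc[0])
            band = 3 * age.per_class_sd[k] / np.sqrt(n_k) + 0.3  # + clip bias
            assert abs(got - age.per_class_mean[k]) < band
        assert prof.anova_p["age"] < 1e-6

    def test_empty_phenotype_row_emitted(self):
        df = _cohort(4, sofa=np.ones(4), dead=[False] * 4,
                     extra={"hr": [60.0, 61.0, 62.0, 63.0]})
        post = _onehot_post(df, [1, 2], [1, 1, 1, 1])
        prof = profile_report(df, post, ["hr"])
        row = prof.summary.set_index("phenotype").loc[2]
        assert row["n"] == 0
        assert np.isnan(prof.feature_table.set_index("feature")
                        .loc["hr", "mean_2"])

    def test_proportions_invariant_under_reordering(self):
        rng = np.random.default_rng(0)
        n = 50
        df = _cohort(n, sofa=rng.uniform(0, 20, n), dead=[False] * n,
                     extra={"hr": rng.normal(80, 10, n)})
        labels = [1, 2]
        assignment = list(rng.choice(labels, n))
        post = _onehot_post(df, labels, assignment)
        prof1 = profile_report(df, post, ["hr"])
        perm = rng.permutation(n)
        post2 = PosteriorMatrix([df["patient_id"][i] for i in perm],
                                post.probs[perm], labels)
        prof2 = profile_report(df, post2, ["hr"])
        assert prof1.summary["proportion"].tolist() == \
            prof2.summary["proportion"].tolist()


class TestRelativeExcess:
    def test_published_peep_contrast(self):
        got = relative_excess(17.42, [5.74, 8.14, 10.21, 5.9])
        assert [round(v) for v in got[:2]] == [203, 114]
        assert round(got[2], 1) == 70.6
        assert round(got[3]) == 195

    def test_equal_value_is_zero_and_double_is_hundred(self):
        assert relative_excess(4.2, [4.2])[0] == pytest.approx(0.0)
        assert relative_excess(3.0, [1.5])[0] == pytest.approx(100.0)

    def test_rejects_zero_or_opposite_sign(self):
        with pytest.raises(ValueError):
            relative_excess(1.0, [0.0])
        with pytest.raises(ValueError):
            relative_excess(1.0, [-2.0])


class TestSofaSegments:
    def test_high_mortality_cell_flagged(self):
        """A (9,22] cell with 88 deaths among 198 shows rate >= 44%."""
        n = 198
        df = _cohort(n, sofa=np.full(n, 15.0),
                     dead=[True] * 88 + [False] * 110)
        post = _onehot_post(df, [4], [4] * n)
        table = sofa_mortality_table(df, post).table.set_index("segment")
        cell = table.loc["(9,22]"]
        assert cell["n"] == 198 and cell["deaths"] == 88
        assert cell["rate"] >= 0.44
        assert bool(cell["display"])

    def test_zero_death_cohort_never_displayed(self):
        df = _cohort(40, sofa=np.linspace(0, 22, 40), dead=[False] * 40)
        post = _onehot_post(df, [1], [1] * 40)
        table = sofa_mortality_table(df, post).table
        assert not table["display"].any()

    def test_boundary_sofa_four_in_first_bin(self):
        df = _cohort(3, sofa=[4.0, 4.5, 6.0], dead=[False] * 3)
        post = _onehot_post(df, [1], [1, 1, 1])
        table = sofa_mortality_table(df, post).table.set_index("segment")
        assert table.loc["[0,4]", "n"] == 1
        assert table.loc["(4,6]", "n"] == 2

    def test_cells_partition_cohort_and_deaths(self):
        rng = np.random.default_rng(1)
        n = 300
        df = _cohort(n, sofa=rng.uniform(0, 22, n),
                     dead=list(rng.random(n) < 0.2))
        labels = [1, 2, 3]
        post = _onehot_post(df, labels, list(rng.choice(labels, n)))
        res = sofa_mortality_table(df, post)
        assert res.table["n"].sum() == n
        assert res.table["deaths"].sum() == df["death28"].sum()
        for lab in labels:
            seg_deaths = res.table.loc[res.table["phenotype"] == lab,
                                       "deaths"].sum()
            true_deaths = df.loc[np.array(post.assignment) == lab,
                                 "death28"].sum()
            assert seg_deaths == true_deaths

    def test_out_of_range_sofa_clamped_with_warning(self):
        df = _cohort(2, sofa=[23.5, -1.0], dead=[False, False])
        post = _onehot_post(df, [1], [1, 1])
        with pytest.warns(UserWarning, match="clamped"):
            res = sofa_mortality_table(df, post)
        assert res.n_clamped == 2
        assert res.table["n"].sum() == 2


class TestSurvivalCurves:
    def test_published_day28_mortality(self):
        """101/368 deaths -> 27.4% and 87/480 -> 18.1% cumulative mortality."""
        n4, d4, n2, d2 = 368, 101, 480, 87
        df = _cohort(n4 + n2,
                     sofa=np.zeros(n4 + n2),
                     dead=[True] * d4 + [False] * (n4 - d4)
                          + [True] * d2 + [False] * (n2 - d2))
        post = _onehot_post(df, [4, 2], [4] * n4 + [2] * n2)
        res = survival_curves(df, post)
        assert round(100 * res.day28_mortality[4], 1) == 27.4
        assert round(100 * res.day28_mortality[2], 1) == 18.1

    def test_km_equals_crude_rate_with_administrative_censoring_only(self):
        rng = np.random.default_rng(2)
        n = 400
        dead = rng.random(n) < 0.3
        days = [int(rng.integers(1, 29)) if d else pd.NA for d in dead]
        df = _cohort(n, sofa=np.zeros(n), dead=list(dead), death_day=days)
        post = _onehot_post(df, [1], [1] * n)
        res = survival_curves(df, post)
        assert res.day28_mortality[1] == pytest.approx(dead.mean(), abs=1e-12)

    def test_curves_start_at_zero_and_are_monotone(self):
        rng = np.random.default_rng(3)
        n = 200
        dead = rng.random(n) < 0.25
        days = [int(rng.integers(1, 29)) if d else pd.NA for d in dead]
        df = _cohort(n, sofa=np.zeros(n), dead=list(dead), death_day=days)
        post = _onehot_post(df, [1], [1] * n)
        cur = survival_curves(df, post).curves[1]
        cm = cur["cum_mortality"].to_numpy()
        assert cm[0] == 0.0
        assert (np.diff(cm) >= -1e-12).all()
        assert cur["at_risk"].iloc[0] == n

    def test_all_survivors_flat_zero(self):
        df = _cohort(25, sofa=np.zeros(25), dead=[False] * 25)
        post = _onehot_post(df, [1], [1] * 25)
        res = survival_curves(df, post)
        assert (res.curves[1]["cum_mortality"] == 0.0).all()

    def test_invalid_death_day_rejected(self):
        df = _cohort(2, sofa=np.zeros(2), dead=[True, False],
                     death_day=[35, pd.NA])
        post = _onehot_post(df, [1], [1, 1])
        with pytest.raises(ValueError):
            survival_curves(df, post)
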