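"""Quality-control filters, design structures and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest

from hetvar.data import (
    apply_cleaning_filters,
    build_design,
    read_phenotypes,
    select_single_record,
    summarize,
)
from hetvar.pedigree import Pedigree


def make_table(groups, seed=0, age=400):
    """groups: dict cg -> list of scores (one record per synthetic animal)."""
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for cg, scores in groups.items():
        for s in scores:
            rows.append({"animal": f"an{k}", "score": s, "cg": cg, "age": age})
            k += 1
    return pd.DataFrame(rows)


class TestCleaning:
    def test_cg_size_boundary(self):
        tab = make_table({"g1": [4, 5] * 75, "g2": [4, 5] * 74 + [4]})  # 150 vs 149
        out, rep = apply_cleaning_filters(tab, min_cg_size=150)
        assert set(out["cg"]) == {"g1"}
        assert rep.dropped_by_rule["cg_size"] == 149
        assert rep.records_in == rep.records_out + sum(rep.dropped_by_rule.values())

    def test_single_score_category_dropped(self):
        tab = make_table({"g1": [5] * 150, "g2": [4, 5] * 75})
        out, rep = apply_cleaning_filters(tab)
        assert set(out["cg"]) == {"g2"}
        assert rep.dropped_by_rule["cg_variation"] == 150

    def test_age_window_inclusive(self):
        tab = make_table({"g": [4, 5] * 80})
        tab.loc[0, "age"] = 320
        tab.loc[1, "age"] = 321
        tab.loc[2, "age"] = 7796
        tab.loc[3, "age"] = 7797
        out, rep = apply_cleaning_filters(tab, min_cg_size=10)
        assert rep.dropped_by_rule["age"] == 2
        assert 321 in out["age"].values and 7796 in out["age"].values

    def test_fixed_point_iteration_cascades(self):
        # dropping out-of-age records shrinks g2 below threshold
        tab = make_table({"g1": [4, 5] * 75, "g2": [4, 5] * 75})
        tab.loc[tab["cg"] == "g2", "age"] = [400] * 140 + [100] * 10
        out, rep = apply_cleaning_filters(tab, min_cg_size=150)
        assert set(out["cg"]) == {"g1"}
        assert rep.dropped_by_rule["age"] == 10
        assert rep.dropped_by_rule["cg_size"] == 140
        assert rep.n_passes >= 1

    def test_idempotent(self):
        tab = make_table({"g1": [3, 4, 5, 6] * 50, "g2": [5] * 10})
        out1, _ = apply_cleaning_filters(tab)
        out2, rep2 = apply_cleaning_filters(out1)
        pd.testing.assert_frame_equal(out1.reset_index(drop=True), out2.reset_index(drop=True))
        assert sum(rep2.dropped_by_rule.values()) == 0

    def test_empty_result_is_valid(self):
        tab = make_table({"g": [5, 5, 5]})
        out, rep = apply_cleaning_filters(tab)
        assert len(out) == 0
        assert rep.records_out == 0


class TestSingleRecord:
    def make_repeats(self):
        return pd.DataFrame(
            {
                "animal": ["a", "a", "a", "b"],
                "score": [4.0, 5.0, 6.0, 7.0],
                "cg": ["g"] * 4,
                "age": [400.0] * 4,
                "date": pd.to_datetime(
                    ["2020-05-01", "2020-01-01", "2020-09-01", "2020-02-02"]
                ),
            }
        )

    def test_first_by_date_keeps_earliest(self):
        out = select_single_record(self.make_repeats(), policy="first_by_date")
        assert len(out) == 2
        assert out.loc[out["animal"] == "a", "score"].item() == 5.0

    def test_random_policy_reproducible(self):
        tab = self.make_repeats()
        out1 = select_single_record(tab, policy="random", seed=5)
        out2 = select_single_record(tab, policy="random", seed=5)
        pd.testing.assert_frame_equal(out1, out2)

    def test_single_record_animals_unchanged(self):
        tab = self.make_repeats()
        out = select_single_record(tab, policy="first_by_date")
        assert out.loc[out["animal"] == "b", "score"].item() == 7.0

    def test_missing_dates_raise(self):
        tab = self.make_repeats().drop(columns="date")
        with pytest.raises(ValueError, match="date"):
            select_single_record(tab, policy="first_by_date")


class TestDesign:
    def make_design_inputs(self):
        ped = Pedigree(
            ids=pd.Index(["x", "y", "z"]), sire=np.full(3, -1), dam=np.full(3, -1)
        )
        tab = pd.DataFrame(
            {
                "animal": ["x", "y", "z"],
                "score": [4.0, 5.0, 6.0],
                "cg": ["g1", "g1", "g2"],
                "age": [350.0, 420.0, 460.0],
            }
        )
        return tab, ped

    def test_dimensions(self):
        tab, ped = self.make_design_inputs()
        d = build_design(tab, ped)
        assert d.X.shape == (3, 3)  # 2 CG classes + age
        assert d.Z.shape == (3, 3)

    def test_centered_age_sums_to_zero(self):
        tab, ped = self.make_design_inputs()
        d = build_design(tab, ped)
        age_col = np.asarray(d.X[:, -1].todense()).ravel()
        assert age_col.sum() == pytest.approx(0.0)

    def test_record_animal_roundtrip(self):
        tab, ped = self.make_design_inputs()
        d = build_design(tab, ped)
        assert list(np.asarray(ped.ids)[d.animal_index]) == list(tab["animal"])

    def test_unknown_animal_raises(self):
        tab, ped = self.make_design_inputs()
        tab.loc[0, "animal"] = "nope"
        with pytest.raises(KeyError, match="nope"):
            build_design(tab, ped)


class TestSummarize:
    def test_two_point_closed_form(self):
        tab = pd.DataFrame(
            {"animal": ["a", "b"], "score": [4.0, 6.0], "cg": ["g", "g"], "age": [400] * 2}
        )
        s = summarize(tab)
        assert s["mean"] == pytest.approx(5.0)
        assert s["sd"] == pytest.approx(np.sqrt(2.0))  # sample SD
        assert summarize(tab, ddof=0)["sd"] == pytest.approx(1.0)

    def test_constant_scores_raise(self):
        tab = pd.DataFrame(
            {"animal": list("abc"), "score": [5.0] * 3, "cg": ["g"] * 3, "age": [400] * 3}
        )
        with pytest.raises(ValueError, match="constant"):
            summarize(tab)

    def test_normal_sample_moments(self):
        rng = np.random.default_rng(99)
        n = 200_000
        tab = pd.DataFrame(
            {
                "animal": np.arange(n).astype(str),
                "score": rng.standard_normal(n),
                "cg": "g",
                "age": 400,
            }
        )
        s = summarize(tab)
        se_skew = np.sqrt(6 / n)
        se_kurt = np.sqrt(24 / n)
        assert abs(s["skewness"]) < 3 * se_skew
        assert abs(s["kurtosis"]) < 3 * se_kurt
        assert summarize(tab, excess_kurtosis=False)["kurtosis"] == pytest.approx(
            s["kurtosis"] + 3
        )


def test_read_phenotypes_column_mapping(tmp_path):
    path = tmp_path / "phen.csv"
    path.write_text("id,foot,grp,days\n1,5,g1,400\n2,6,g1,380\n")
    tab = read_phenotypes(
        path, column_map={"animal": "id", "score": "foot", "cg": "grp", "age": "days"}
    )
    assert list(tab.columns[:4]) == ["animal", "score", "cg", "age"]
    assert tab["score"].tolist() == [5.0, 6.0]
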