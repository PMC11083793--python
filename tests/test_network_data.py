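"""Data model, fixture accounting, geometry and transitivity reporting."""

import numpy as np
import pandas as pd
import pytest

import armnma as am
from armnma.network_data import (
    NetworkValidationError,
    StudyCovariates,
    connectivity_report,
    descriptive_stats,
    fixture_network,
    load_network,
    transitivity_table,
    write_network,
)

from conftest import make_binary_ds


class TestLoadNetwork:
    def test_packaged_enrollment_network_shape(self):
        ds = fixture_network()
        assert len(ds.studies()) == 10
        assert len(ds.arms) == 20
        assert len(ds.treatments) == 4
        # reference defaults to the largest-enrollment treatment
        assert ds.reference.id == "OpDG"
        assert ds.treatment_ids[0] == "OpDG"

    def test_reference_override(self):
        ds = fixture_network(reference="RobDG")
        assert ds.reference.id == "RobDG"

    def test_empty_table_is_no_studies(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("study,treatment,events,total\n")
        with pytest.raises(NetworkValidationError, match="no studies"):
            load_network(p, "o", "binary")

    def test_duplicate_row_names_offender(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "study,treatment,events,total\n"
            "s1,A,1,10\ns1,B,2,10\ns2,A,1,10\ns2,B,0,10\ns2,B,1,10\n"
        )
        with pytest.raises(NetworkValidationError, match=r"\('s2', 'B'\)"):
            load_network(p, "o", "binary")

    def test_events_exceeding_total_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("study,treatment,events,total\ns1,A,11,10\ns1,B,2,10\n")
        with pytest.raises(NetworkValidationError, match="s1"):
            load_network(p, "o", "binary")

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "cols.csv"
        p.write_text("study,treatment,events\ns1,A,1\n")
        with pytest.raises(NetworkValidationError, match="total"):
            load_network(p, "o", "binary")

    def test_nonpositive_sd_rejected(self, tmp_path):
        p = tmp_path / "sd.csv"
        p.write_text("study,treatment,n,mean,sd\ns1,A,10,1.0,0.0\ns1,B,10,2.0,1.0\n")
        with pytest.raises(NetworkValidationError, match="sd"):
            load_network(p, "o", "continuous")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.csv"):
            load_network(tmp_path / "nope.csv", "o", "binary")

    def test_round_trip(self, tmp_path):
        ds = fixture_network()
        p = tmp_path / "rt.csv"
        write_network(ds, p)
        ds2 = load_network(p, ds.outcome_name, ds.outcome_kind, ds.direction)
        assert ds2.arms == ds.arms
        assert ds2.treatment_ids == ds.treatment_ids


class TestConnectivity:
    def test_fixture_is_one_component(self):
        rep = connectivity_report(fixture_network())
        assert rep["n_components"] == 1 and rep["connected"]
        assert sorted(rep["components"][0]) == ["LapAsDG", "LapDG", "OpDG", "RobDG"]
        # node totals drive geometry-plot node sizes: must equal enrollment
        assert rep["node_totals"] == {
            "OpDG": 1768, "LapDG": 1012, "LapAsDG": 902, "RobDG": 141,
        }

    def test_disjoint_studies_reported_not_raised(self):
        ds = make_binary_ds([
            ("s1", "A", 1, 10), ("s1", "B", 2, 10),
            ("s2", "C", 1, 10), ("s2", "D", 2, 10),
        ])
        rep = connectivity_report(ds)
        assert rep["n_components"] == 2 and not rep["connected"]

    def test_star_edge_study_counts(self):
        ds = make_binary_ds([
            ("s1", "A", 1, 10), ("s1", "B", 2, 10),
            ("s2", "A", 1, 10), ("s2", "C", 2, 10),
            ("s3", "A", 1, 10), ("s3", "D", 2, 10),
        ])
        rep = connectivity_report(ds)
        assert rep["edge_studies"] == {"A|B": 1, "A|C": 1, "A|D": 1}

    @pytest.mark.parametrize("perm", [
        {"OpDG": "T1", "LapDG": "T2", "LapAsDG": "T3", "RobDG": "T4"},
        {"OpDG": "Z", "LapDG": "Y", "LapAsDG": "X", "RobDG": "W"},
    ])
    def test_connectivity_invariant_under_relabeling(self, perm):
        ds = fixture_network()
        rep = connectivity_report(ds)
        rep2 = connectivity_report(ds.relabeled(perm))
        assert rep2["n_components"] == rep["n_components"]
        assert sorted(rep2["edge_studies"].values()) == sorted(rep["edge_studies"].values())
        assert sorted(rep2["node_totals"].values()) == sorted(rep["node_totals"].values())


class TestDescriptiveStats:
    def test_cohort_accounting(self):
        st = descriptive_stats()
        assert st["total_patients"] == 3823
        assert st["groups"]["OpDG"] == {"patients": 1768, "percent": 46.2}
        assert st["groups"]["RobDG"] == {"patients": 141, "percent": 3.7}
        assert st["male_percent"] == 68.4
        assert st["neoadjuvant_patients"] == 95
        assert st["neoadjuvant_percent"] == 2.5
        assert st["adjuvant_patients"] == 132
        assert st["adjuvant_percent"] == 34.9

    def test_group_percentages_sum_to_100(self):
        st = descriptive_stats()
        total_pct = sum(g["percent"] for g in st["groups"].values())
        assert total_pct == pytest.approx(100.0, abs=0.2)  # rounding slack


class TestTransitivity:
    def test_fixture_ages_within_published_range(self):
        tab = transitivity_table(fixture_network())
        ages = tab[["age_mean_min", "age_mean_max"]].to_numpy()
        ages = ages[np.isfinite(ages)]
        assert ages.size and np.all((ages >= 26) & (ages <= 81))
        assert set(tab["comparison"]) == {
            "LapAsDG vs OpDG", "LapDG vs OpDG", "LapDG vs RobDG",
        }

    def test_single_study_network_has_one_row(self):
        ds = make_binary_ds([("s1", "A", 1, 10), ("s1", "B", 2, 10)])
        ds.covariates = [StudyCovariates("s1", n=20, age_mean=60.0)]
        tab = transitivity_table(ds)
        assert len(tab) == 1
        assert tab.loc[0, "age_mean_wmean"] == 60.0

    def test_identical_covariates_balance_exactly(self):
        ds = make_binary_ds([
            ("s1", "A", 1, 10), ("s1", "B", 2, 10),
            ("s2", "A", 1, 10), ("s2", "C", 2, 10),
        ])
        ds.covariates = [
            StudyCovariates("s1", n=20, age_mean=60.0, prop_male=0.5, bmi_mean=23.0),
            StudyCovariates("s2", n=20, age_mean=60.0, prop_male=0.5, bmi_mean=23.0),
        ]
        tab = transitivity_table(ds)
        for col in ("age_mean_wmean", "prop_male_wmean", "bmi_mean_wmean"):
            assert tab[col].nunique() == 1  # zero between-comparison difference

    def test_missingness_flagged_never_imputed(self):
        tab = transitivity_table(fixture_network())
        row = tab[tab["comparison"] == "LapAsDG vs OpDG"].iloc[0]
        # Shi 2018 reports neither age nor sex
        assert row["age_mean_n_missing"] >= 1


class TestCovariateInvariants:
    def test_proportions_must_be_fractions(self):
        with pytest.raises(NetworkValidationError):
            StudyCovariates("s", prop_male=1.2)

    def test_stage_proportions_bounded(self):
        with pytest.raises(NetworkValidationError):
            StudyCovariates("s", stage={"I": 0.7, "II": 0.6})
        StudyCovariates("s", stage={"I": 0.5, "II": None})  # missingness allowed
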