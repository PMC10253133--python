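"""Per-core certification decision tree."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tmascreen import (
    CertificationParams,
    CoreSummary,
    certify,
    certify_all,
    summarize_core,
)
from tmascreen.core_certification import CoreCall


def make_cells(n_normal=0, n_tumour=0, n_immune=0, n_stroma=0, n_epi_pos=0):
    """Cell table with the requested tallies; the first n_epi_pos
    epithelial cells are marker-positive."""
    rows = []
    for cls, n in (
        ("NormalEpithelium", n_normal),
        ("Tumour", n_tumour),
        ("ImmuneInfiltrate", n_immune),
        ("Stroma", n_stroma),
    ):
        rows += [{"tissue_class": cls, "base_class": "Negative"}] * n
    df = pd.DataFrame(rows)
    if len(df):
        epi = df.index[df["tissue_class"].isin(["NormalEpithelium", "Tumour"])]
        df.loc[epi[:n_epi_pos], "base_class"] = "Positive"
        df["core_label"] = "A1"
    return df


class TestSummarizeCore:
    def test_counts_by_class_and_marker(self):
        cells = make_cells(n_tumour=80, n_stroma=20)
        s = summarize_core(cells, "A1")
        assert (s.n_tumour, s.n_stroma, s.n_epi_neg, s.n_epi_pos) == (80, 20, 80, 0)
        assert s.n_total == 100

    def test_empty_core_all_zero(self):
        s = summarize_core(pd.DataFrame(), "B2")
        assert s.n_total == 0

    def test_unscored_cells_excluded(self):
        cells = make_cells(n_tumour=10)
        cells.loc[0, "base_class"] = "Unscored"
        assert summarize_core(cells, "A1").n_tumour == 9

    def test_inconsistent_marker_counts_rejected(self):
        with pytest.raises(ValueError):
            CoreSummary(core_label="A1", n_tumour=10, n_epi_pos=4, n_epi_neg=4)


class TestCertify:
    def test_deficient_tumour_call(self):
        s = CoreSummary("A1", n_normal=0, n_tumour=90, n_stroma=10,
                        n_epi_pos=5, n_epi_neg=85)
        call = certify(s)
        assert call.call == "MLH1DeficientTumour"
        assert call.histology_fraction == pytest.approx(0.90)
        assert call.marker_fraction == pytest.approx(85 / 90)

    def test_split_histology_flagged(self):
        s = CoreSummary("A1", n_normal=50, n_tumour=50, n_epi_pos=10, n_epi_neg=90)
        call = certify(s)
        assert (call.call, call.flag_reason) == ("Flagged", "Histology")

    def test_midrange_marker_flagged(self):
        s = CoreSummary("A1", n_tumour=80, n_normal=0, n_immune=10, n_stroma=10,
                        n_epi_pos=56, n_epi_neg=24)
        call = certify(s)
        assert (call.call, call.flag_reason) == ("Flagged", "MLH1")
        assert call.marker_fraction == pytest.approx(0.70)

    def test_exact_threshold_certifies_inclusively(self):
        s = CoreSummary("A1", n_tumour=75, n_normal=0, n_immune=15, n_stroma=10,
                        n_epi_pos=57, n_epi_neg=18)  # 75/100 and 57/75 = 0.76
        assert certify(s).call == "MLH1ProficientTumour"
        s2 = CoreSummary("A1", n_tumour=75, n_normal=0, n_immune=15, n_stroma=10,
                         n_epi_pos=56, n_epi_neg=19)  # 56/75 < 0.75
        assert certify(s2).call == "Flagged"
        s3 = CoreSummary("A1", n_tumour=60, n_normal=0, n_immune=10, n_stroma=10,
                         n_epi_pos=45, n_epi_neg=15)  # both exactly 0.75
        assert certify(s3).call == "MLH1ProficientTumour"

    def test_few_cells_invalid(self):
        s = CoreSummary("A1", n_tumour=19, n_epi_neg=19)
        assert certify(s, CertificationParams(min_cells=20)).call == "Invalid"

    def test_no_epithelium_flagged_both(self):
        s = CoreSummary("A1", n_stroma=30, n_immune=10)
        call = certify(s)
        assert (call.call, call.flag_reason) == ("Flagged", "Both")

    def test_deficient_normal_warns(self):
        s = CoreSummary("A1", n_normal=90, n_stroma=10, n_epi_pos=2, n_epi_neg=88)
        with pytest.warns(UserWarning, match="deficient normal"):
            call = certify(s)
        assert call.call == "MLH1DeficientNormal"

    def test_epithelial_denominator_option(self):
        # 60 tumour of 100 cells fails over all cells but certifies
        # over epithelial cells only (60/70)
        s = CoreSummary("A1", n_tumour=60, n_normal=10, n_immune=20, n_stroma=10,
                        n_epi_pos=60, n_epi_neg=10)
        assert certify(s).call == "Flagged"
        params = CertificationParams(histology_denominator="epithelial_cells")
        assert certify(s, params).call == "MLH1ProficientTumour"

    def test_pure_function_of_inputs(self):
        s = CoreSummary("A1", n_tumour=80, n_normal=5, n_immune=10, n_stroma=5,
                        n_epi_pos=80, n_epi_neg=5)
        assert certify(s) == certify(s)

    @given(
        n_normal=st.integers(0, 60), n_tumour=st.integers(0, 60),
        n_immune=st.integers(0, 30), n_stroma=st.integers(0, 30),
        pos=st.floats(0.0, 1.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_raising_threshold_never_certifies_a_flagged_core(
        self, n_normal, n_tumour, n_immune, n_stroma, pos
    ):
        n_epi = n_normal + n_tumour
        n_pos = int(round(pos * n_epi))
        s = CoreSummary("A1", n_normal=n_normal, n_tumour=n_tumour,
                        n_immune=n_immune, n_stroma=n_stroma,
                        n_epi_pos=n_pos, n_epi_neg=n_epi - n_pos)
        lo = certify(s, CertificationParams(threshold=0.75, min_cells=1))
        hi = certify(s, CertificationParams(threshold=0.85, min_cells=1))
        if s.n_total >= 1 and lo.call == "Flagged":
            assert hi.call in ("Flagged", "Invalid")

    @given(
        n_normal=st.integers(0, 80), n_tumour=st.integers(0, 80),
        n_stroma=st.integers(0, 40), pos=st.floats(0.0, 1.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_at_most_one_class_certifies_above_half(self, n_normal, n_tumour, n_stroma, pos):
        n_epi = n_normal + n_tumour
        n_pos = int(round(pos * n_epi))
        s = CoreSummary("A1", n_normal=n_normal, n_tumour=n_tumour, n_stroma=n_stroma,
                        n_epi_pos=n_pos, n_epi_neg=n_epi - n_pos)
        call = certify(s, CertificationParams(min_cells=1))
        # the call is a single unambiguous outcome by construction
        assert call.call in (
            "MLH1ProficientNormal", "MLH1DeficientNormal", "MLH1ProficientTumour",
            "MLH1DeficientTumour", "Flagged", "Invalid",
        )


class TestCoreCallValidation:
    def test_flag_reason_must_match_call(self):
        with pytest.raises(ValueError):
            CoreCall(core_label="A1", call="Flagged", flag_reason="none")
        with pytest.raises(ValueError):
            CoreCall(core_label="A1", call="Invalid", flag_reason="MLH1")


class TestCertifyAll:
    def test_tallies_sum_to_cores(self):
        cells = pd.concat(
            [
                make_cells(n_tumour=80, n_stroma=20).assign(core_label="A1"),
                make_cells(n_normal=50, n_tumour=50, n_epi_pos=90).assign(core_label="A2"),
                make_cells(n_tumour=5).assign(core_label="A3"),
            ],
            ignore_index=True,
        )
        calls, tallies = certify_all(cells, core_labels=["A1", "A2", "A3", "A4"])
        assert len(calls) == 4
        assert (
            tallies["certified"] + tallies["flagged"] + tallies["invalid"]
            == tallies["n_cores"] == 4
        )
        assert calls.set_index("core_label").loc["A4", "call"] == "Invalid"

    def test_empty_table_all_invalid(self):
        calls, tallies = certify_all(
            pd.DataFrame(columns=["core_label", "tissue_class", "base_class"]),
            core_labels=["A1", "B1"],
        )
        assert (calls["call"] == "Invalid").all()
        assert tallies["invalid"] == 2


class TestParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"threshold": 0.5}, {"threshold": 1.2}, {"min_cells": 0},
        {"histology_denominator": "nuclei"},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CertificationParams(**kwargs)
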