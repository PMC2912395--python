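"""QC arithmetic: the beta formula, the strict sample rule, locus filters,
and the series-matrix reader."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methclass import BetaMatrix, compute_beta, locus_qc, read_series_matrix, run_qc, sample_qc
from methclass.io import read_beta_tsv, write_beta_tsv
from methclass.preprocess import locus_qc as locus_qc_fn


@pytest.mark.parametrize(
    "cy5,cy3,expected",
    [(0.0, 0.0, 0.0), (900.0, 0.0, 0.9), (-50.0, 200.0, 0.0), (100.0, 100.0, 100.0 / 300.0)],
)
def test_compute_beta_formula(cy5, cy3, expected):
    assert compute_beta(cy5, cy3) == pytest.approx(expected, abs=1e-12)


def test_compute_beta_rejects_nonfinite():
    with pytest.raises(ValueError):
        compute_beta(np.nan, 1.0)


@settings(max_examples=60, deadline=None)
@given(
    cy5=st.floats(-1e5, 1e5), delta=st.floats(0, 1e4), cy3=st.floats(0, 1e5)
)
def test_compute_beta_monotone_in_cy5(cy5, delta, cy3):
    assert compute_beta(cy5 + delta, cy3) >= compute_beta(cy5, cy3) - 1e-15
    assert 0.0 <= compute_beta(cy5, cy3) < 1.0


def test_sample_qc_all_detected_passes_all_failed_fails():
    det = pd.DataFrame(np.zeros((3, 10)), index=list("abc"))
    assert sample_qc(det).all()
    det1 = pd.DataFrame(np.ones((3, 10)), index=list("abc"))
    assert not sample_qc(det1).any()


def test_sample_qc_threshold_is_strict():
    # 76/100 detected -> pass; exactly 75/100 -> fail (strictly more than 75%)
    base = np.ones((1, 100))
    base[0, :76] = 0.0
    assert sample_qc(pd.DataFrame(base)).iloc[0]
    base[0, 75] = 1.0  # now exactly 75 below threshold
    assert not sample_qc(pd.DataFrame(base)).iloc[0]


def test_sample_qc_empty_grid_errors():
    with pytest.raises(ValueError):
        sample_qc(pd.DataFrame())


def _toy(n_loci=30, n_fail=0, n_x=0, n_samples=8, seed=0):
    rng = np.random.default_rng(seed)
    loci = [f"L{i}" for i in range(n_loci)]
    beta = BetaMatrix(pd.DataFrame(
        rng.uniform(0, 1, (n_samples, n_loci)),
        index=[f"s{i}" for i in range(n_samples)], columns=loci,
    ))
    det = pd.DataFrame(rng.uniform(0, 1e-6, (n_samples, n_loci)),
                       index=beta.sample_ids, columns=loci)
    det.iloc[:, :n_fail] = 0.2
    chrom = ["X" if n_fail <= i < n_fail + n_x else "7" for i in range(n_loci)]
    ann = pd.DataFrame({"gene": [f"G{i}" for i in range(n_loci)],
                        "chromosome": chrom}, index=loci)
    return beta, det, ann


def test_locus_qc_identity_when_nothing_fails():
    beta, det, ann = _toy()
    filtered, report = locus_qc(beta, det, ann)
    assert report.n_loci_final == beta.n_loci
    assert filtered.values.equals(beta.values)


def test_locus_qc_set_difference_counts():
    beta, det, ann = _toy(n_loci=1505, n_fail=10, n_x=20, n_samples=4, seed=1)
    filtered, report = locus_qc(beta, det, ann)
    assert report.n_loci_final == 1505 - 10 - 20
    assert len(report.loci_dropped_detection) == 10
    assert len(report.loci_dropped_x) == 20


def test_doubly_disqualified_locus_counted_under_detection_rule():
    beta, det, ann = _toy(n_loci=20, n_fail=3, n_x=0)
    ann.loc["L0", "chromosome"] = "X"  # L0 fails detection AND sits on X
    filtered, report = locus_qc(beta, det, ann)
    assert "L0" in report.loci_dropped_detection
    assert "L0" not in report.loci_dropped_x
    assert report.n_loci_final == 20 - 3


def test_locus_qc_is_idempotent():
    beta, det, ann = _toy(n_loci=40, n_fail=5, n_x=4)
    once, rep1 = locus_qc(beta, det, ann)
    twice, rep2 = locus_qc_fn(once, det[once.locus_ids], ann)
    assert twice.values.equals(once.values)
    assert rep2.n_loci_final == rep1.n_loci_final


def test_locus_qc_counts_reconcile(small_study):
    filtered, report = run_qc(
        small_study.beta, small_study.annotation, small_study.signals.detection_p
    )
    d = report.to_dict()
    assert (
        d["n_loci_dropped_detection"] + d["n_loci_dropped_x"] + d["n_loci_final"]
        == d["n_loci_input"]
    )
    assert set(report.loci_dropped_detection) == set(small_study.truth.failing_loci)
    assert set(report.loci_dropped_x) == set(small_study.truth.x_loci)


def test_locus_qc_unannotated_locus_named_in_error():
    beta, det, ann = _toy(n_loci=5)
    with pytest.raises(ValueError, match="L4"):
        locus_qc(beta, det, ann.drop(index="L4"))


SERIES_FIXTURE = """\
!Series_title\t"synthetic example"
!Sample_id\tGSM1\tGSM2
!series_matrix_table_begin
"ID_REF"\t"GSM1"\t"GSM2"
cg001\t0.10\t0.90
cg002\t0.25\t0.75
cg003\t0.50\t0.55
!series_matrix_table_end
"""


def test_read_series_matrix_fixture(tmp_path):
    path = tmp_path / "series.txt"
    path.write_text(SERIES_FIXTURE)
    beta, det = read_series_matrix(path)
    assert det is None
    assert beta.values.shape == (2, 3)
    assert beta.values.loc["GSM1", "cg001"] == pytest.approx(0.10)
    assert beta.values.loc["GSM2", "cg003"] == pytest.approx(0.55)


def test_read_series_matrix_metadata_only_errors(tmp_path):
    path = tmp_path / "empty.txt"
    path.write_text("!Series_title\tfoo\n!Sample_id\tGSM1\n")
    with pytest.raises(ValueError, match="no data table"):
        read_series_matrix(path)


def test_read_series_matrix_non_numeric_cell_located(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text('ID_REF\tGSM1\ncg001\t0.5\ncg002\toops\n')
    with pytest.raises(ValueError, match="cg002"):
        read_series_matrix(path)


def test_beta_tsv_round_trip(small_study, tmp_path):
    path = tmp_path / "beta.tsv"
    write_beta_tsv(small_study.beta, path)
    back = read_beta_tsv(path)
    np.testing.assert_allclose(
        back.to_numpy(), small_study.beta.to_numpy(), rtol=0, atol=1e-9
    )
    assert back.locus_ids == small_study.beta.locus_ids
    # and the series-matrix reader accepts the same file
    again, _ = read_series_matrix(path)
    np.testing.assert_allclose(
        again.to_numpy(), small_study.beta.to_numpy(), atol=1e-9
    )
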