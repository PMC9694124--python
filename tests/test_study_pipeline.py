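"""The full comparison matrix, report serialization, and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from iidrperm import (
    Cohort,
    EXPECTED_PATTERN_ALL_SUBJECTS,
    ItemResponseVector,
    StudyReport,
    all_subjects_within_pattern,
    default_comparison_matrix,
    figure3_preset,
    generate_cohort,
    pattern_diff,
    run_study,
    significance_pattern,
    summarize_means,
)
from iidrperm.__main__ import cli, cli_main


def test_default_matrix_shape():
    matrix = default_comparison_matrix()
    assert len(matrix) == 40 and len(set(matrix)) == 40
    within = [s for s in matrix if s.axis == "within_iidr"]
    between = [s for s in matrix if s.axis == "between_group"]
    assert len(within) == 24 and len(between) == 16


@pytest.fixture(scope="module")
def report(preset_cohort):
    return run_study(preset_cohort, n_resamples=4000, seed=5)


def test_report_covers_matrix_once(report):
    assert len(report.table) == 40
    keys = report.table[
        ["grouping", "axis", "material", "environment", "level_db_spl", "fixed_iidr"]
    ]
    assert not keys.duplicated().any()


def test_report_flags_consistent(report):
    t = report.table
    assert (t["sig_0.05"] == (t["p_value"] < 0.05)).all()
    assert (t["sig_0.01"] == (t["p_value"] < 0.01)).all()


def test_report_means_match_summaries(report, preset_cohort):
    means = {
        g: summarize_means(preset_cohort, g)
        for g in ("all", "preCSPL65", "preCSPL80")
    }
    for _, r in report.table.iterrows():
        if r["axis"] == "within_iidr":
            lookups = [(r["grouping"], "default", "mean_a"),
                       (r["grouping"], "wide", "mean_b")]
        else:
            lookups = [("preCSPL65", r["fixed_iidr"], "mean_a"),
                       ("preCSPL80", r["fixed_iidr"], "mean_b")]
        for grouping, iidr, col in lookups:
            df = means[grouping]
            cell = df[
                (df.material == r["material"])
                & (df.environment == r["environment"])
                & (df.level_db_spl == r["level_db_spl"])
                & (df.iidr == iidr)
            ]
            assert r[col] == pytest.approx(cell.mean_percent.iloc[0])
        # pooled item difference equals the difference of subject-mean scores
        # here because every subject contributes equally many items per side
        assert r["observed_diff"] == pytest.approx(r["mean_b"] - r["mean_a"])


def test_rerun_is_bit_identical(preset_cohort):
    r1 = run_study(preset_cohort, n_resamples=2000, seed=11)
    r2 = run_study(preset_cohort, n_resamples=2000, seed=11)
    pd.testing.assert_frame_equal(r1.table, r2.table)


def _null_cohort():
    """A cohort whose wide-program cells duplicate the default-program cells."""
    cohort = generate_cohort(figure3_preset(seed=13))
    cells = {}
    for (sid, cond), vec in cohort.cells.items():
        if cond.iidr == "default":
            cells[(sid, cond)] = vec
            wide = cond.with_iidr("wide")
            cells[(sid, wide)] = ItemResponseVector(
                sid, vec.group, wide, vec.responses.copy()
            )
    return Cohort(groups=dict(cohort.groups), cells=cells)


def test_identical_iidr_cells_give_null_p(preset_cohort):
    cohort = _null_cohort()
    report = run_study(cohort, n_resamples=2000, seed=3)
    within = report.table[report.table.axis == "within_iidr"]
    assert (within["observed_diff"] == 0).all()
    assert (within["p_value"] >= 0.5).all()


def test_significance_pattern_strict_boundary(report):
    table = report.table.copy()
    table["p_value"] = 0.05
    exactly_alpha = StudyReport(table=table, meta={})
    assert not any(significance_pattern(exactly_alpha, 0.05).values())
    table2 = table.copy()
    table2["p_value"] = 0.049
    assert all(significance_pattern(StudyReport(table=table2, meta={}), 0.05).values())


def test_pattern_diff_reports_mismatches():
    observed = {("a",): True, ("b",): False}
    assert pattern_diff(observed, {("a",): True, ("b",): False}) == {}
    diff = pattern_diff(observed, {("b",): True, ("c",): True})
    assert diff == {("b",): (False, True), ("c",): (None, True)}


def test_report_csv_roundtrip(report, tmp_path):
    path = tmp_path / "report.csv"
    report.to_csv(path)
    again = StudyReport.read_csv(path)
    assert again.meta["seed"] == "5"
    assert len(again.table) == 40
    np.testing.assert_allclose(again.table.p_value, report.table.p_value)


def test_all_subjects_pattern_rate_reported():
    """How often 50 replicate synthetic studies reproduce the published
    all-subjects significance pattern at alpha=0.05.

    The structurally large contrasts (noise conditions at both levels and
    sentences in quiet at the loud level) must each be significant in >= 90%
    of replicates; the full 8-cell pattern match rate, which also hinges on
    the two near-threshold quiet-word contrasts, is printed for the record.
    """
    robust = [
        ("word", "noise", 65),
        ("sentence", "noise", 65),
        ("word", "noise", 80),
        ("sentence", "quiet", 80),
        ("sentence", "noise", 80),
    ]
    matrix = [
        s for s in default_comparison_matrix()
        if s.grouping == "all" and s.axis == "within_iidr"
    ]
    robust_hits = {k: 0 for k in robust}
    full_matches = 0
    R = 50
    for r in range(R):
        cohort = generate_cohort(figure3_preset(seed=90_000 + r))
        report = run_study(cohort, n_resamples=20_000, seed=90_000 + r,
                           matrix=matrix)
        pattern = all_subjects_within_pattern(report, alpha=0.05)
        full_matches += pattern == dict(EXPECTED_PATTERN_ALL_SUBJECTS)
        for k in robust:
            robust_hits[k] += pattern[k]
    print(f"\nfull published-pattern match rate: {full_matches / R:.2f}")
    for k, hits in robust_hits.items():
        assert hits / R >= 0.9, (k, hits / R)


# -- CLI ---------------------------------------------------------------------


def test_cli_exact_test_matches_enumeration():
    runner = CliRunner()
    result = runner.invoke(
        cli, ["test", "--a", "all-zeros(3)", "--b", "all-ones(3)", "--mode", "exact"]
    )
    assert result.exit_code == 0
    payload = json.loads(result.output)
    assert payload["p_value"] == 0.05 and payload["mode"] == "exact"


def test_cli_generate_then_study_matches_one_shot(tmp_path):
    runner = CliRunner()
    cohort_csv = tmp_path / "c.csv"
    r = runner.invoke(
        cli, ["generate", "--preset", "figure3", "--seed", "7",
              "--out", str(cohort_csv)]
    )
    assert r.exit_code == 0 and cohort_csv.exists()

    out1 = tmp_path / "r1.csv"
    out2 = tmp_path / "r2.csv"
    r1 = runner.invoke(
        cli, ["study", str(cohort_csv), "--seed", "7",
              "--n-resamples", "2000", "--out", str(out1)]
    )
    r2 = runner.invoke(
        cli, ["study", "--synthetic", "--preset", "figure3", "--seed", "7",
              "--n-resamples", "2000", "--out", str(out2)]
    )
    assert r1.exit_code == 0 and r2.exit_code == 0
    t1 = StudyReport.read_csv(out1).table
    t2 = StudyReport.read_csv(out2).table
    pd.testing.assert_frame_equal(t1, t2)
    assert len(t1) == 40


def test_cli_study_synthetic_writes_40_rows(tmp_path):
    out = tmp_path / "report.csv"
    code = cli_main(["study", "--synthetic", "--seed", "3",
                     "--n-resamples", "1000", "--out", str(out)])
    assert code == 0
    assert len(StudyReport.read_csv(out).table) == 40


def test_cli_usage_and_validation_exit_codes(tmp_path):
    assert cli_main(["test"]) == 2  # neither --a/--b nor --cohort
    bad = tmp_path / "bad.csv"
    bad.write_text("subject_id,material\ns1,word\n")
    assert cli_main(["study", str(bad)]) == 1
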