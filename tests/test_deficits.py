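"""Normative classification: quantile oracles, Venn arithmetic, and the
binomial independence expectations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emosub.config import DOMAINS
from emosub.deficits import (
    EmptyBracketError,
    classify,
    empirical_quantile,
    estimate_thresholds,
    independence_expectation,
    venn_summary,
)


def _participants(brackets, group="TDC"):
    n = len(brackets)
    return pd.DataFrame(
        {"id": [f"P{i}" for i in range(n)], "group": group, "bracket": brackets}
    )


def _scores(values):
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = np.tile(arr[:, None], (1, 3))
    return pd.DataFrame(arr, columns=list(DOMAINS))


# --- quantile estimation ----------------------------------------------------


def test_quantile_conventions_against_sort_oracle():
    rng = np.random.default_rng(0)
    x = rng.permutation(np.arange(1.0, 101.0))
    srt = np.sort(x)
    # linear interpolation of order statistics at q = 0.10: position 9.9
    assert empirical_quantile(x, 0.10, "linear") == pytest.approx(
        srt[9] + 0.9 * (srt[10] - srt[9])
    )
    # nearest rank: ceil(0.1 * 100) = 10th smallest
    assert empirical_quantile(x, 0.10, "nearest_rank") == srt[9]
    cutoff = empirical_quantile(x, 0.10, "linear")
    assert (x <= cutoff).sum() == 10


@given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=20, max_size=80,
                unique=True),
       st.sampled_from([0.05, 0.10, 0.25]))
@settings(max_examples=50, deadline=None)
def test_quantile_flags_at_most_expected_fraction(values, q):
    x = np.asarray(values)
    cut = empirical_quantile(x, q, "linear")
    flagged = (x <= cut).sum()
    assert flagged == int(np.ceil(q * (len(x) - 1))) or flagged == int(
        np.floor(q * (len(x) - 1))
    ) + 1


def test_thresholds_per_bracket_and_q_zero():
    rng = np.random.default_rng(1)
    brackets = ["9-12"] * 50 + ["13-15"] * 50 + ["16-18"] * 50
    scores = _scores(rng.normal(size=150))
    part = _participants(brackets)
    th = estimate_thresholds(scores, part, q=0.10)
    assert th.cutoffs.shape == (3, 3)
    assert (th.n_controls == 50).all()
    th0 = estimate_thresholds(scores, part, q=0.0)
    flags = classify(scores, th0, part)
    assert flags["n_deficits"].sum() == 0


def test_large_sample_cutoff_approaches_normal_tenth_percentile():
    rng = np.random.default_rng(2)
    n = 200_000
    scores = _scores(rng.standard_normal(n))
    part = _participants(["9-12"] * n)
    th = estimate_thresholds(scores, part, q=0.10)
    assert th.cutoffs.iloc[0, 0] == pytest.approx(-1.2816, abs=0.02)


def test_empty_bracket_raises_and_small_bracket_warns():
    scores = _scores(np.arange(30.0))
    part = _participants(["9-12"] * 30)
    part.loc[0, "bracket"] = "13-15"
    part.loc[0, "group"] = "CD"  # bracket 13-15 has no controls
    with pytest.raises(EmptyBracketError):
        estimate_thresholds(scores, part)
    part.loc[0, "group"] = "TDC"
    with pytest.warns(UserWarning, match="only 1 controls"):
        estimate_thresholds(scores, part)


# --- classification ---------------------------------------------------------


def test_worked_fixture_matches_hand_tally():
    """20 hand-placed scores in one bracket; cutoff = 10th percentile of
    the 10 controls; flags verified by enumeration."""
    control_scores = np.array(
        [0.5, 1.2, -0.3, 0.8, 2.0, -0.9, 1.5, 0.1, -1.5, 0.9]
    )
    case_scores = np.array(
        [-2.0, -1.4, 0.0, 0.3, -0.95, 1.1, -1.6, 0.6, -3.0, 2.2]
    )
    # linear 10th percentile of the 10 controls: between -1.5 and -0.9
    expected_cutoff = -1.5 + 0.9 * (-0.9 - -1.5)
    part = _participants(["9-12"] * 10)
    part = pd.concat(
        [part, _participants(["9-12"] * 10, group="CD")], ignore_index=True
    )
    part["id"] = [f"P{i}" for i in range(20)]
    scores = _scores(np.concatenate([control_scores, case_scores]))
    th = estimate_thresholds(scores, part, q=0.10)
    assert th.cutoffs.iloc[0, 0] == pytest.approx(expected_cutoff)
    flags = classify(scores, th, part)
    hand = np.concatenate([control_scores, case_scores]) <= expected_cutoff
    np.testing.assert_array_equal(flags["recognition_deficit"].to_numpy(), hand)
    # hand tally at cutoff -0.96: control -1.5; cases -2.0, -1.4, -1.6, -3.0
    assert flags["n_deficits"].sum() == 5 * 3  # same scores in all domains


def test_in_sample_rate_equals_q_and_monotone_in_q():
    rng = np.random.default_rng(3)
    n = 300
    scores = _scores(rng.standard_normal((n, 3)))
    part = _participants(["9-12"] * n)
    th = estimate_thresholds(scores, part, q=0.10)
    flags = classify(scores, th, part)
    for d in DOMAINS:
        assert flags[f"{d}_deficit"].mean() == pytest.approx(0.10)
    flags_wide = classify(scores, estimate_thresholds(scores, part, q=0.25), part)
    for d in DOMAINS:
        assert (
            flags_wide[f"{d}_deficit"] | ~flags[f"{d}_deficit"]
        ).all()  # raising q never unflags


def test_boundary_rule_is_inclusive():
    scores = _scores(np.arange(10.0))
    part = _participants(["9-12"] * 10)
    th = estimate_thresholds(scores, part, q=0.10, method="nearest_rank")
    flags_incl = classify(scores, th, part, boundary_inclusive=True)
    flags_excl = classify(scores, th, part, boundary_inclusive=False)
    assert flags_incl["recognition_deficit"].sum() == 1
    assert flags_excl["recognition_deficit"].sum() == 0


def test_missing_scores_excluded_with_warning():
    rng = np.random.default_rng(4)
    scores = _scores(rng.normal(size=30))
    scores.iloc[3, 0] = np.nan
    part = _participants(["9-12"] * 30)
    th = estimate_thresholds(scores.dropna(), part.drop(3), q=0.10)
    with pytest.warns(UserWarning, match="missing scores"):
        flags = classify(scores, th, part)
    assert len(flags) == 29


def test_missing_bracket_threshold_raises():
    scores = _scores(np.arange(10.0))
    part = _participants(["9-12"] * 10)
    th = estimate_thresholds(scores, part, q=0.10)
    part2 = part.copy()
    part2.loc[0, "bracket"] = "16-18"
    with pytest.raises(KeyError, match="16-18"):
        classify(scores, th, part2)


# --- Venn summary -----------------------------------------------------------


def _flags_frame(rows):
    df = pd.DataFrame(
        rows, columns=["recognition_deficit", "learning_deficit",
                       "regulation_deficit", "group"]
    )
    df["id"] = [f"P{i}" for i in range(len(df))]
    cells = {
        (0, 0, 0): "none", (1, 0, 0): "REC", (0, 1, 0): "LRN",
        (0, 0, 1): "REG", (1, 1, 0): "REC+LRN", (1, 0, 1): "REC+REG",
        (0, 1, 1): "LRN+REG", (1, 1, 1): "REC+LRN+REG",
    }
    df["venn_cell"] = [
        cells[tuple(int(v) for v in row[:3])] for row in rows
    ]
    df["n_deficits"] = df[
        ["recognition_deficit", "learning_deficit", "regulation_deficit"]
    ].sum(axis=1)
    for c in ["recognition_deficit", "learning_deficit", "regulation_deficit"]:
        df[c] = df[c].astype(bool)
    return df


def test_venn_summary_counts_are_exact():
    rows = (
        [(0, 0, 0, "CD")] * 5 + [(1, 0, 0, "CD")] * 3 + [(1, 1, 1, "CD")] * 2
        + [(0, 0, 0, "TDC")] * 8 + [(0, 1, 0, "TDC")] * 2
    )
    flags = _flags_frame(rows)
    summary = venn_summary(flags)
    assert summary.counts.loc["CD", "none"] == 5
    assert summary.proportions.loc["CD", "REC"] == pytest.approx(0.3)
    assert summary.proportions.sum(axis=1).tolist() == pytest.approx([1.0, 1.0])
    # margins equal sums of their cells
    assert summary.margins.loc["CD", "recognition"] == pytest.approx(0.5)
    assert summary.aggregates.loc["CD", "all_3"] == pytest.approx(0.2)
    assert summary.aggregates.loc["TDC", "none"] == pytest.approx(0.8)
    assert set(summary.domain_tests.index) == set(DOMAINS)


def test_venn_all_false_flags():
    flags = _flags_frame([(0, 0, 0, "CD")] * 4 + [(0, 0, 0, "TDC")] * 4)
    summary = venn_summary(flags)
    assert summary.aggregates.loc["CD", "none"] == 1.0
    assert (summary.proportions.loc["CD"].drop("none") == 0).all()


# --- independence expectation -----------------------------------------------


def test_independence_expectation_closed_forms():
    exp = independence_expectation(0.10, 3)
    assert exp["all_k"] == pytest.approx(0.001)
    assert exp["ge_1"] == pytest.approx(0.271)
    assert exp["exactly_1"] == pytest.approx(0.243)
    assert exp["exactly_2"] == pytest.approx(0.027)
    total = sum(exp[f"exactly_{m}"] for m in range(4))
    assert total == pytest.approx(1.0)


@given(st.floats(0.01, 0.5), st.integers(1, 6))
@settings(max_examples=50, deadline=None)
def test_independence_expectation_properties(q, k):
    exp = independence_expectation(q, k)
    assert exp["ge_1"] == pytest.approx(1 - exp["none"])
    assert sum(exp[f"exactly_{m}"] for m in range(k + 1)) == pytest.approx(1.0)
    assert exp["all_k"] <= exp["ge_1"] + 1e-12


def test_independent_domains_match_binomial_expectation():
    """Monte-Carlo control overlap within 3 SEs of the closed forms."""
    rng = np.random.default_rng(5)
    n = 20_000
    scores = pd.DataFrame(
        rng.standard_normal((n, 3)), columns=list(DOMAINS)
    )
    part = _participants(["9-12"] * n)
    th = estimate_thresholds(scores, part, q=0.10)
    flags = classify(scores, th, part)
    exp = independence_expectation(0.10, 3)
    for key, observed in (
        ("ge_1", (flags["n_deficits"] >= 1).mean()),
        ("exactly_1", (flags["n_deficits"] == 1).mean()),
        ("exactly_2", (flags["n_deficits"] == 2).mean()),
        ("all_k", (flags["n_deficits"] == 3).mean()),
    ):
        se = np.sqrt(exp[key] * (1 - exp[key]) / n)
        assert abs(observed - exp[key]) < 3 * se + 1e-4, key


def test_end_to_end_prevalence_recovery(replication_run):
    """Classifier-estimated CD cell prevalences track the generator truth."""
    part = replication_run.cohort.participants
    flags = replication_run.flags
    cd = part["group"] == "TDC"
    merged = flags.merge(part[["id", "deficit_class"]], on="id")
    cd_rows = merged[merged["group"] == "CD"]
    true_rec = part.loc[part["group"] == "CD", "true_recognition_deficit"].mean()
    est_rec = cd_rows["recognition_deficit"].mean()
    # n = 542: Monte-Carlo half-width ~ 3 * sqrt(p q / n) ~ 5.5 pp, plus
    # classification error
    assert abs(est_rec - true_rec) < 0.06


def test_venn_figure_renders(replication_run):
    import matplotlib
    matplotlib.use("Agg")
    from emosub.deficits import plot_venn

    ax = plot_venn(replication_run.venn, group="CD")
    assert ax.get_title() == "Deficit overlap, CD group"
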