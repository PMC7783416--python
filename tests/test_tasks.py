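"""Task simulators and scorers: design structure, scoring oracles,
monotonicity, and the batch/log-level distributional agreement."""

import numpy as np
import pandas as pd
import pytest

from emosub import tasks
from emosub.config import TaskParams
from emosub.tasks import (
    CONTINUA,
    GONOGO_COLUMNS,
    HEX_COLUMNS,
    PA_COLUMNS,
    PA_MAGNITUDES,
    PA_PUNISHMENT_COLUMNS,
    PA_REWARD_COLUMNS,
    SCORE_COLUMNS,
    StructuralLogError,
    batch_gonogo_scores,
    batch_hexagon_scores,
    batch_pa_scores,
    score_gonogo,
    score_hexagon,
    score_pa,
    simulate_gonogo,
    simulate_hexagon,
    simulate_pa,
)


# --- independent brute-force scorers (test-side oracles) --------------------


def brute_hexagon(log: pd.DataFrame) -> dict:
    errors = {e: 0 for e in ("happy", "surprised", "fearful", "sad",
                             "disgusted", "angry")}
    for _, row in log.iterrows():
        a, b = row["pair"].split("-")
        major = int(row["morph"].split(":")[0])
        if major == 50:
            continue
        target = a if major > 50 else b
        if row["response"] != target:
            errors[target] += 1
    return errors


def brute_pa(log: pd.DataFrame) -> dict:
    out = {}
    for mag in PA_MAGNITUDES:
        com = om = 0
        for _, row in log.iterrows():
            if row["block"] == 1 or row["magnitude"] != mag:
                continue
            if row["valence"] == "punishment" and row["responded"]:
                com += 1
            if row["valence"] == "reward" and not row["responded"]:
                om += 1
        out[("punishment", mag)] = 100.0 * com / 9
        out[("reward", mag)] = 100.0 * om / 9
    return out


def brute_gonogo(log: pd.DataFrame) -> dict:
    out = {}
    for block, sub in log.groupby("block"):
        fa = int(sub[(sub["trial_type"] == "nogo") & sub["responded"]].shape[0])
        out[block] = 100.0 * fa / 13
    return out


# --- Emotion Hexagon --------------------------------------------------------


def test_hexagon_log_design_counts():
    log = simulate_hexagon(0.0, seed=1)
    assert len(log) == 150
    # one 50:50 morph per continuum per block: 6 x 5 = 30 unscored trials
    assert (log["morph"] == "50:50").sum() == 30
    counts = log.groupby(["block", "pair", "morph"]).size()
    assert (counts == 1).all() and len(counts) == 150


def test_hexagon_ceiling_ability_all_correct():
    params = TaskParams(hex_timeout_p=0.0)
    log = simulate_hexagon(60.0, seed=2, params=params)
    assert (score_hexagon(log) == 0).all()


def test_hexagon_all_wrong_scores_twenty_each():
    log = simulate_hexagon(0.0, seed=3)
    wrong = log.copy()
    wrong["response"] = "timeout"  # timeouts count as incorrect
    assert (score_hexagon(wrong) == 20).all()


def test_hexagon_constructed_errors_count_to_target():
    """Exactly 3 errors on happiness-scored morphs -> happiness = 3."""
    log = simulate_hexagon(0.0, seed=4)
    first = log["pair"].str.split("-").str[0]
    major = log["morph"].str.split(":").str[0].astype(int)
    target = np.where(major > 50, first,
                      log["pair"].str.split("-").str[1])
    scored = major != 50
    log.loc[scored, "response"] = target[scored]  # start error-free
    happy_rows = log.index[scored & (target == "happy")][:3]
    log.loc[happy_rows, "response"] = "sad"
    scores = score_hexagon(log)
    assert scores["Happiness"] == 3
    assert (scores.drop("Happiness") == 0).all()


@pytest.mark.parametrize("seed", range(20))
def test_hexagon_score_matches_brute_force(seed):
    log = simulate_hexagon(np.random.default_rng(seed).normal(), seed=seed)
    brute = brute_hexagon(log)
    scores = score_hexagon(log)
    expr_of = dict(zip(HEX_COLUMNS, ("happy", "surprised", "fearful", "sad",
                                     "disgusted", "angry")))
    for col in HEX_COLUMNS:
        assert scores[col] == brute[expr_of[col]]


def test_hexagon_mean_error_decreases_with_ability(rng):
    means = []
    for ability in (-2.0, 0.0, 2.0):
        scores = batch_hexagon_scores(np.full(500, ability), rng)
        means.append(scores.to_numpy().mean())
    assert means[0] > means[1] > means[2]


def test_hexagon_structural_error_names_location():
    log = simulate_hexagon(0.0, seed=5)
    broken = log.drop(log.index[10])
    with pytest.raises(StructuralLogError, match="150 trials"):
        score_hexagon(broken)
    dup = log.copy()
    dup.iloc[0], dup.iloc[1] = dup.iloc[2], dup.iloc[2]
    with pytest.raises(StructuralLogError, match=r"block \d+, pair"):
        score_hexagon(dup)


# --- Passive Avoidance ------------------------------------------------------


def test_pa_log_design_constants():
    log = simulate_pa(0.0, seed=1)
    assert len(log) == 80
    assert set(log["magnitude"]) == {1, 700, 1400, 2000}
    assert set(log["valence"]) == {"reward", "punishment"}
    assert log.loc[log["block"] == 1, "practice"].all()
    assert log["bank"].iloc[0] in (10_000 - log["magnitude"].iloc[0],
                                   10_000, 10_000 + log["magnitude"].iloc[0])
    counts = log.groupby(["block", "valence", "magnitude"]).size()
    assert (counts == 1).all() and len(counts) == 80


def test_pa_always_presser_rates():
    log = simulate_pa(0.0, seed=2)
    log["responded"] = True
    scores = score_pa(log)
    assert (scores[list(PA_PUNISHMENT_COLUMNS)] == 100.0).all()
    assert (scores[list(PA_REWARD_COLUMNS)] == 0.0).all()


def test_pa_zero_learning_rate_gives_constant_half_rates(rng):
    """lr = 0 and p0 = 0.5 -> expected 50% commission and omission rates."""
    params = TaskParams(pa_lr_intercept=-80.0, pa_lr_ability=0.0,
                        pa_lr_magnitude=0.0, pa_bias_sd=0.0)
    scores = batch_pa_scores(np.zeros(2000), rng, params,
                             biases=np.zeros(2000))
    for col in PA_COLUMNS:
        assert abs(scores[col].mean() - 50.0) < 3.0, col


@pytest.mark.parametrize("seed", range(20))
def test_pa_score_matches_brute_force(seed):
    log = simulate_pa(np.random.default_rng(seed).normal(), seed=seed,
                      bias=0.3)
    brute = brute_pa(log)
    scores = score_pa(log)
    for mag, col in zip(PA_MAGNITUDES, PA_PUNISHMENT_COLUMNS):
        assert scores[col] == pytest.approx(brute[("punishment", mag)])
    for mag, col in zip(PA_MAGNITUDES, PA_REWARD_COLUMNS):
        assert scores[col] == pytest.approx(brute[("reward", mag)])


def test_pa_commission_errors_decrease_with_ability(rng):
    lo = batch_pa_scores(np.full(1500, -2.0), rng, biases=np.zeros(1500))
    hi = batch_pa_scores(np.full(1500, 2.0), rng, biases=np.zeros(1500))
    for col in PA_PUNISHMENT_COLUMNS:
        assert lo[col].mean() > hi[col].mean() + 5


def test_pa_structural_error():
    log = simulate_pa(0.0, seed=3)
    with pytest.raises(StructuralLogError):
        score_pa(log.drop(log.index[5]))


# --- Emotional Go/Nogo ------------------------------------------------------


def test_gonogo_block_composition():
    log = simulate_gonogo(0.0, seed=1)
    counts = log.groupby(["block", "trial_type"]).size().unstack()
    assert (counts["go"] == 35).all()
    assert (counts["nogo"] == 13).all()
    assert len(log) == 6 * 48


def test_gonogo_extreme_rates():
    log = simulate_gonogo(0.0, seed=2)
    quiet = log.copy()
    quiet.loc[quiet["trial_type"] == "nogo", "responded"] = False
    assert (score_gonogo(quiet) == 0.0).all()
    loud = log.copy()
    block = loud["block"] == "neutral-happy"
    loud.loc[block & (loud["trial_type"] == "nogo"), "responded"] = True
    assert score_gonogo(loud)["Neutral/Happy"] == 100.0


@pytest.mark.parametrize("seed", range(20))
def test_gonogo_score_matches_brute_force(seed):
    log = simulate_gonogo(np.random.default_rng(seed).normal(), seed=seed)
    brute = brute_gonogo(log)
    scores = score_gonogo(log)
    mapping = {
        "Neutral/Happy": "neutral-happy", "Neutral/Fearful": "neutral-fearful",
        "Fearful/Happy": "fearful-happy", "Happy/Neutral": "happy-neutral",
        "Fearful/Neutral": "fearful-neutral", "Happy/Fearful": "happy-fearful",
    }
    for col, pairing in mapping.items():
        assert scores[col] == pytest.approx(brute[pairing])


def test_gonogo_false_alarms_decrease_with_ability(rng):
    lo = batch_gonogo_scores(np.full(1000, -2.0), rng)
    hi = batch_gonogo_scores(np.full(1000, 2.0), rng)
    assert lo.to_numpy().mean() > hi.to_numpy().mean() + 10


# --- cross-cutting ----------------------------------------------------------


def test_scoring_is_pure():
    log = simulate_hexagon(0.3, seed=9)
    a = score_hexagon(log)
    b = score_hexagon(log)
    pd.testing.assert_series_equal(a, b)


def test_batch_and_log_level_simulators_agree_in_distribution():
    """The vectorized samplers draw from the same distributions as the
    trial-level simulators followed by scoring."""
    n = 300
    ability = 0.4
    rng = np.random.default_rng(77)
    batch_hex = batch_hexagon_scores(np.full(n, ability), rng)
    batch_gng = batch_gonogo_scores(np.full(n, ability), rng)
    batch_pa = batch_pa_scores(np.full(n, ability), rng, biases=np.zeros(n))
    log_hex = np.array([
        score_hexagon(simulate_hexagon(ability, seed=1000 + i)).to_numpy()
        for i in range(n)
    ])
    log_gng = np.array([
        score_gonogo(simulate_gonogo(ability, seed=2000 + i)).to_numpy()
        for i in range(n)
    ])
    log_pa = np.array([
        score_pa(simulate_pa(ability, seed=3000 + i, bias=0.0)).to_numpy()
        for i in range(n)
    ])
    # overall means agree within Monte-Carlo error (3 SE of the difference)
    for batch, logs in ((batch_hex, log_hex), (batch_gng, log_gng),
                        (batch_pa, log_pa)):
        b = batch.to_numpy().mean(axis=0)
        l = logs.mean(axis=0)
        se = np.sqrt(batch.to_numpy().var(axis=0) / n + logs.var(axis=0) / n)
        assert np.all(np.abs(b - l) < 3.5 * se + 1e-9)


def test_score_table_layout(rng):
    abilities = rng.standard_normal((50, 3))
    table = tasks.batch_score_table(abilities, rng, ids=[f"P{i}" for i in range(50)])
    assert list(table.columns) == ["id"] + list(SCORE_COLUMNS)
    assert table[list(HEX_COLUMNS)].to_numpy().max() <= 20
    assert table[list(GONOGO_COLUMNS + PA_COLUMNS)].to_numpy().max() <= 100.0
    assert table[list(SCORE_COLUMNS)].to_numpy().min() >= 0.0


def test_reliability_of_variable_groups(rng):
    """Cronbach's alpha >= 0.70 per domain block on a default simulation."""
    abilities = rng.standard_normal((500, 3))
    table = tasks.batch_score_table(abilities, rng)
    alphas = tasks.group_reliabilities(table)
    for domain, alpha in alphas.items():
        assert alpha >= 0.70, (domain, alpha)
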