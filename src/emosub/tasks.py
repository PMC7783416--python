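"""Trial-level simulation and scoring of the three neuropsychological tasks.

Emotion Hexagon (facial-expression labelling over six morph continua),
Passive Avoidance Learning (trial-and-error response/withhold learning with
point feedback) and Emotional Go/Nogo (response inhibition under emotional
interference).  Each task has

* a per-participant log simulator (``simulate_*``) producing a trial table,
* a pure scorer (``score_*``) reducing a log to its Table-style variables,
* a vectorized batch sampler (``batch_*_scores``) drawing the scored
  variables directly from the same trial distributions, used for large
  cohorts where materializing logs would be wasteful.

Scoring conventions: timeouts and non-responses count as errors/omissions;
50:50 hexagon morphs and the passive-avoidance practice block are never
scored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import DOMAINS, TaskParams

# --- design constants -------------------------------------------------------

EXPRESSIONS = ("happy", "surprised", "fearful", "sad", "disgusted", "angry")
CONTINUA = (
    ("happy", "surprised"),
    ("surprised", "fearful"),
    ("fearful", "sad"),
    ("sad", "disgusted"),
    ("disgusted", "angry"),
    ("angry", "happy"),
)
MORPH_LEVELS = (90, 70, 50, 30, 10)  # percentage of the first prototype
HEX_BLOCKS = 5

PA_MAGNITUDES = (1, 700, 1400, 2000)
PA_BLOCKS = 10  # block 1 is practice
PA_SCORED_BLOCKS = PA_BLOCKS - 1
PA_START_POINTS = 10_000

GONOGO_PAIRINGS = (
    "neutral-happy",
    "neutral-fearful",
    "happy-neutral",
    "fearful-neutral",
    "happy-fearful",
    "fearful-happy",
)
GONOGO_GO = 35
GONOGO_NOGO = 13

# --- canonical score-table columns (Table-style labels) ---------------------

GONOGO_COLUMNS = (
    "Neutral/Happy",
    "Neutral/Fearful",
    "Fearful/Happy",
    "Happy/Neutral",
    "Fearful/Neutral",
    "Happy/Fearful",
)
_COLUMN_TO_PAIRING = {
    "Neutral/Happy": "neutral-happy",
    "Neutral/Fearful": "neutral-fearful",
    "Fearful/Happy": "fearful-happy",
    "Happy/Neutral": "happy-neutral",
    "Fearful/Neutral": "fearful-neutral",
    "Happy/Fearful": "happy-fearful",
}
PA_PUNISHMENT_COLUMNS = tuple(f"Losing {m:,} point{'s' if m > 1 else ''}" for m in PA_MAGNITUDES)
PA_REWARD_COLUMNS = tuple(f"Gaining {m:,} point{'s' if m > 1 else ''}" for m in PA_MAGNITUDES)
PA_COLUMNS = PA_PUNISHMENT_COLUMNS + PA_REWARD_COLUMNS
HEX_COLUMNS = ("Happiness", "Surprise", "Fear", "Sadness", "Disgust", "Anger")
_HEX_COLUMN_TO_EXPRESSION = dict(zip(HEX_COLUMNS, EXPRESSIONS))

SCORE_COLUMNS = GONOGO_COLUMNS + PA_COLUMNS + HEX_COLUMNS

#: Domain -> score-table columns (the a-priori variable blocks).
DOMAIN_PARTITION: dict[str, tuple[str, ...]] = {
    "regulation": GONOGO_COLUMNS,
    "learning": PA_COLUMNS,
    "recognition": HEX_COLUMNS,
}
#: Columns where a *lower* raw value would mean worse performance (reverse
#: keyed relative to the rest of the error battery): none -- every variable
#: is an error rate -- but the reward omission variables anti-correlate with
#: the punishment commission variables through response bias, which is why
#: they acquire negative loadings on the learning component.
REVERSE_KEYED_FOR_ALPHA = PA_REWARD_COLUMNS


class StructuralLogError(ValueError):
    """A task log violates its design structure (missing/duplicate trials)."""


# ===========================================================================
# Emotion Hexagon
# ===========================================================================


def _hex_majority(pair: tuple[str, str], morph: int) -> str | None:
    if morph > 50:
        return pair[0]
    if morph < 50:
        return pair[1]
    return None


def _hex_p_correct(ability: float | np.ndarray, morph: int, params: TaskParams):
    intercept = params.hex_intercept_90 if abs(morph - 50) == 40 else params.hex_intercept_70
    return expit(intercept + params.hex_slope * np.asarray(ability, dtype=float))


def simulate_hexagon(
    ability: float, seed=None, params: TaskParams | None = None
) -> pd.DataFrame:
    """Simulate one participant's 150-trial Emotion Hexagon log.

    The probability of choosing the majority prototype is a logistic
    function of ability, with 90:10 morphs easier than 70:30.  Errors fall
    mostly on the continuum's other prototype; a small timeout probability
    yields missing responses (logged as "timeout").
    """
    params = params or TaskParams()
    rng = np.random.default_rng(seed)
    rows = []
    for block in range(1, HEX_BLOCKS + 1):
        trials = [(pair, morph) for pair in CONTINUA for morph in MORPH_LEVELS]
        rng.shuffle(trials)
        for pair, morph in trials:
            majority = _hex_majority(pair, morph)
            other = pair[1] if majority == pair[0] else pair[0]
            if rng.random() < params.hex_timeout_p:
                response = "timeout"
            elif majority is None:
                # 50:50: split between the two prototypes, never scored
                response = pair[rng.integers(2)]
            elif rng.random() < _hex_p_correct(ability, morph, params):
                response = majority
            elif rng.random() < params.hex_other_prototype_mass:
                response = other
            else:
                rest = [e for e in EXPRESSIONS if e not in (majority, other)]
                response = rest[rng.integers(len(rest))]
            rows.append(
                {
                    "block": block,
                    "pair": f"{pair[0]}-{pair[1]}",
                    "morph": f"{morph}:{100 - morph}",
                    "response": response,
                }
            )
    return pd.DataFrame(rows)


def _validate_hexagon(log: pd.DataFrame) -> None:
    if len(log) != HEX_BLOCKS * 30:
        raise StructuralLogError(
            f"hexagon log must have {HEX_BLOCKS * 30} trials, got {len(log)}"
        )
    counts = log.groupby(["block", "pair", "morph"], observed=True).size()
    for block in range(1, HEX_BLOCKS + 1):
        for pair in CONTINUA:
            key = f"{pair[0]}-{pair[1]}"
            for morph in MORPH_LEVELS:
                label = f"{morph}:{100 - morph}"
                if counts.get((block, key, label), 0) != 1:
                    raise StructuralLogError(
                        f"hexagon log: block {block}, pair {key}, morph {label} "
                        "missing or duplicated"
                    )


def score_hexagon(log: pd.DataFrame) -> pd.Series:
    """Per-expression error counts (0-20); 50:50 morphs unscored.

    Each expression is scored on the 90:10 and 70:30 morphs toward it, on
    both continua containing it, across the five blocks (4 x 5 = 20
    trials); timeouts count as incorrect.
    """
    _validate_hexagon(log)
    errors = dict.fromkeys(EXPRESSIONS, 0)
    first = log["pair"].str.split("-", n=1).str[0]
    second = log["pair"].str.split("-", n=1).str[1]
    morph_major = log["morph"].str.split(":", n=1).str[0].astype(int)
    majority = np.where(morph_major > 50, first, np.where(morph_major < 50, second, ""))
    scored = majority != ""
    wrong = scored & (log["response"].to_numpy() != majority)
    for expr in EXPRESSIONS:
        errors[expr] = int(np.sum(wrong & (majority == expr)))
    return pd.Series(
        {col: errors[_HEX_COLUMN_TO_EXPRESSION[col]] for col in HEX_COLUMNS}
    )


def batch_hexagon_scores(
    abilities: np.ndarray, rng: np.random.Generator, params: TaskParams | None = None
) -> pd.DataFrame:
    """Draw per-expression error counts for many participants at once.

    Equivalent in distribution to ``score_hexagon(simulate_hexagon(a))``:
    per expression, 10 trials at 90:10 and 10 at 70:30, each correct with
    probability (1 - timeout_p) * p_correct.
    """
    params = params or TaskParams()
    abilities = np.asarray(abilities, dtype=float)
    n = abilities.shape[0]
    out = {}
    for col in HEX_COLUMNS:
        correct = np.zeros(n, dtype=int)
        for morph in (90, 70):
            p = (1.0 - params.hex_timeout_p) * _hex_p_correct(abilities, morph, params)
            correct += rng.binomial(10, p)
        out[col] = 20 - correct
    return pd.DataFrame(out)


# ===========================================================================
# Passive Avoidance Learning
# ===========================================================================

_PA_STIMULI = tuple(
    (valence, mag) for valence in ("reward", "punishment") for mag in PA_MAGNITUDES
)


def _pa_learning_rates(
    ability: float | np.ndarray, params: TaskParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-magnitude learning rates for (reward, punishment) stimuli."""
    ability = np.asarray(ability, dtype=float)
    mags = np.asarray(PA_MAGNITUDES, dtype=float) / 2000.0
    base = params.pa_lr_intercept + params.pa_lr_magnitude * mags
    lr_pun = expit(base[None, :] + params.pa_lr_ability * ability[..., None])
    lr_rew = expit(
        base[None, :]
        + params.pa_lr_ability * params.pa_reward_ability_frac * ability[..., None]
    )
    return lr_rew, lr_pun


def simulate_pa(
    ability: float,
    seed=None,
    params: TaskParams | None = None,
    bias: float = 0.0,
) -> pd.DataFrame:
    """Simulate one participant's Passive Avoidance log (10 blocks x 8 trials).

    Reinforcement model: each stimulus has a response propensity starting
    at ``pa_init_propensity`` (shifted by the participant's response-bias
    trait ``bias``, in logit units).  Feedback arrives only on responses:
    a rewarded response pushes the propensity up, a punished response
    pushes it down, by a learning rate that grows with ability (strongly
    for punishment, weakly for reward) and with point magnitude.  The
    running point bank starts at 10,000 and is tracked in the log.
    """
    params = params or TaskParams()
    rng = np.random.default_rng(seed)
    lr_rew, lr_pun = (np.ravel(a) for a in _pa_learning_rates(ability, params))
    p0 = expit(np.log(params.pa_init_propensity / (1 - params.pa_init_propensity)) + bias)
    propensity = {stim: p0 for stim in _PA_STIMULI}
    bank = PA_START_POINTS
    rows = []
    for block in range(1, PA_BLOCKS + 1):
        order = list(_PA_STIMULI)
        rng.shuffle(order)
        for valence, mag in order:
            p = propensity[(valence, mag)]
            responded = rng.random() < p
            if responded:
                j = PA_MAGNITUDES.index(mag)
                if valence == "reward":
                    bank += mag
                    p = p + float(lr_rew[j]) * (1.0 - p)
                else:
                    bank -= mag
                    p = p * (1.0 - float(lr_pun[j]))
                propensity[(valence, mag)] = p
            rows.append(
                {
                    "block": block,
                    "stimulus": f"{valence}_{mag}",
                    "valence": valence,
                    "magnitude": mag,
                    "responded": responded,
                    "practice": block == 1,
                    "bank": bank,
                }
            )
    return pd.DataFrame(rows)


def _validate_pa(log: pd.DataFrame) -> None:
    if len(log) != PA_BLOCKS * 8:
        raise StructuralLogError(
            f"passive-avoidance log must have {PA_BLOCKS * 8} trials, got {len(log)}"
        )
    counts = log.groupby(["block", "valence", "magnitude"], observed=True).size()
    for block in range(1, PA_BLOCKS + 1):
        for valence, mag in _PA_STIMULI:
            if counts.get((block, valence, mag), 0) != 1:
                raise StructuralLogError(
                    f"passive-avoidance log: block {block}, stimulus "
                    f"{valence}_{mag} missing or duplicated"
                )


def score_pa(log: pd.DataFrame) -> pd.Series:
    """Eight error rates in %: commission per punishment magnitude, omission
    per reward magnitude, over the 9 scored (non-practice) blocks."""
    _validate_pa(log)
    scored = log[log["block"] > 1]
    out = {}
    for mag, col in zip(PA_MAGNITUDES, PA_PUNISHMENT_COLUMNS):
        sel = scored[(scored["valence"] == "punishment") & (scored["magnitude"] == mag)]
        out[col] = 100.0 * sel["responded"].sum() / PA_SCORED_BLOCKS
    for mag, col in zip(PA_MAGNITUDES, PA_REWARD_COLUMNS):
        sel = scored[(scored["valence"] == "reward") & (scored["magnitude"] == mag)]
        out[col] = 100.0 * (~sel["responded"]).sum() / PA_SCORED_BLOCKS
    return pd.Series(out)


def batch_pa_scores(
    abilities: np.ndarray,
    rng: np.random.Generator,
    params: TaskParams | None = None,
    biases: np.ndarray | None = None,
) -> pd.DataFrame:
    """Vectorized Passive Avoidance error rates for many participants.

    Runs the same propensity-update model as ``simulate_pa`` with the block
    loop vectorized over participants and stimuli.  If ``biases`` is None,
    response-bias traits are drawn from N(0, pa_bias_sd).
    """
    params = params or TaskParams()
    abilities = np.asarray(abilities, dtype=float)
    n = abilities.shape[0]
    if biases is None:
        biases = rng.normal(0.0, params.pa_bias_sd, n)
    lr_rew, lr_pun = _pa_learning_rates(abilities, params)  # (n, 4) each
    logit0 = np.log(params.pa_init_propensity / (1 - params.pa_init_propensity))
    p_rew = np.tile(expit(logit0 + biases)[:, None], (1, 4))
    p_pun = p_rew.copy()
    commission = np.zeros((n, 4))
    omission = np.zeros((n, 4))
    for block in range(1, PA_BLOCKS + 1):
        resp_rew = rng.random((n, 4)) < p_rew
        resp_pun = rng.random((n, 4)) < p_pun
        if block > 1:
            commission += resp_pun
            omission += ~resp_rew
        p_rew = np.where(resp_rew, p_rew + lr_rew * (1 - p_rew), p_rew)
        p_pun = np.where(resp_pun, p_pun * (1 - lr_pun), p_pun)
    out = {}
    for j, col in enumerate(PA_PUNISHMENT_COLUMNS):
        out[col] = 100.0 * commission[:, j] / PA_SCORED_BLOCKS
    for j, col in enumerate(PA_REWARD_COLUMNS):
        out[col] = 100.0 * omission[:, j] / PA_SCORED_BLOCKS
    return pd.DataFrame(out)


# ===========================================================================
# Emotional Go/Nogo
# ===========================================================================


def _gonogo_p_fa(
    ability: float | np.ndarray, pairing: str, params: TaskParams
) -> np.ndarray:
    return expit(
        params.gonogo_base
        + params.gonogo_interference[pairing]
        - params.gonogo_slope * np.asarray(ability, dtype=float)
    )


def simulate_gonogo(
    ability: float, seed=None, params: TaskParams | None = None
) -> pd.DataFrame:
    """Simulate one participant's Emotional Go/Nogo log (6 blocks x 48 trials).

    Per block, 35 go and 13 nogo trials in random order; the probability of
    failing to inhibit on a nogo trial is a logistic function of regulation
    ability plus a per-pairing emotional-interference offset.  Go-trial
    omissions are logged but not analyzed.
    """
    params = params or TaskParams()
    rng = np.random.default_rng(seed)
    rows = []
    pairings = list(GONOGO_PAIRINGS)
    rng.shuffle(pairings)
    for pairing in pairings:
        p_fa = float(_gonogo_p_fa(ability, pairing, params))
        types = ["go"] * GONOGO_GO + ["nogo"] * GONOGO_NOGO
        rng.shuffle(types)
        for trial_type in types:
            if trial_type == "go":
                responded = rng.random() < params.gonogo_go_response_p
            else:
                responded = rng.random() < p_fa
            rows.append(
                {"block": pairing, "trial_type": trial_type, "responded": responded}
            )
    return pd.DataFrame(rows)


def _validate_gonogo(log: pd.DataFrame) -> None:
    counts = log.groupby(["block", "trial_type"], observed=True).size()
    for pairing in GONOGO_PAIRINGS:
        if counts.get((pairing, "go"), 0) != GONOGO_GO or counts.get(
            (pairing, "nogo"), 0
        ) != GONOGO_NOGO:
            raise StructuralLogError(
                f"go/nogo log: block {pairing} must have {GONOGO_GO} go and "
                f"{GONOGO_NOGO} nogo trials"
            )
    if len(log) != len(GONOGO_PAIRINGS) * (GONOGO_GO + GONOGO_NOGO):
        raise StructuralLogError("go/nogo log has extra trials")


def score_gonogo(log: pd.DataFrame) -> pd.Series:
    """Six false-alarm rates in % (nogo responses / 13), one per pairing."""
    _validate_gonogo(log)
    nogo = log[log["trial_type"] == "nogo"]
    fa = nogo.groupby("block", observed=True)["responded"].sum()
    return pd.Series(
        {
            col: 100.0 * float(fa[_COLUMN_TO_PAIRING[col]]) / GONOGO_NOGO
            for col in GONOGO_COLUMNS
        }
    )


def batch_gonogo_scores(
    abilities: np.ndarray, rng: np.random.Generator, params: TaskParams | None = None
) -> pd.DataFrame:
    """Vectorized Go/Nogo false-alarm rates (Binomial(13, p_fa) per pairing)."""
    params = params or TaskParams()
    abilities = np.asarray(abilities, dtype=float)
    out = {}
    for col in GONOGO_COLUMNS:
        p = _gonogo_p_fa(abilities, _COLUMN_TO_PAIRING[col], params)
        out[col] = 100.0 * rng.binomial(GONOGO_NOGO, p) / GONOGO_NOGO
    return pd.DataFrame(out)


# ===========================================================================
# Score table assembly
# ===========================================================================


def batch_score_table(
    abilities: np.ndarray,
    rng: np.random.Generator,
    params: TaskParams | None = None,
    ids=None,
) -> pd.DataFrame:
    """The 20-variable performance table for a cohort.

    ``abilities`` is (n, 3) in the domain order (recognition, learning,
    regulation).  Column order follows the canonical table layout:
    go/nogo false-alarm rates, passive-avoidance error rates, hexagon
    error counts.
    """
    params = params or TaskParams()
    abilities = np.asarray(abilities, dtype=float)
    rec, lrn, reg = abilities[:, 0], abilities[:, 1], abilities[:, 2]
    gonogo = batch_gonogo_scores(reg, rng, params)
    pa = batch_pa_scores(lrn, rng, params)
    hexagon = batch_hexagon_scores(rec, rng, params)
    table = pd.concat([gonogo, pa, hexagon], axis=1)[list(SCORE_COLUMNS)]
    if ids is not None:
        table.insert(0, "id", np.asarray(ids))
    return table


def score_table_from_logs(
    hexagon_log: pd.DataFrame, pa_log: pd.DataFrame, gonogo_log: pd.DataFrame
) -> pd.Series:
    """Score one participant's three logs into the 20 canonical variables."""
    parts = pd.concat(
        [score_gonogo(gonogo_log), score_pa(pa_log), score_hexagon(hexagon_log)]
    )
    return parts[list(SCORE_COLUMNS)]


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha of a variable group (columns = items, rows = cases)."""
    x = np.asarray(items, dtype=float)
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    return k / (k - 1) * (1 - item_var / total_var)


def group_reliabilities(scores: pd.DataFrame) -> dict[str, float]:
    """Cronbach's alpha per domain block (reward variables reverse-keyed)."""
    out = {}
    for domain in DOMAINS:
        cols = list(DOMAIN_PARTITION[domain])
        block = scores[cols].astype(float).copy()
        for col in cols:
            if col in REVERSE_KEYED_FOR_ALPHA:
                block[col] = -block[col]
        out[domain] = cronbach_alpha(block)
    return out
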