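"""Synthetic CSI experiments with known ground truth.

Three layers, each usable on its own:

* ``make_stimuli`` — a stimulus inventory shaped like the real material
  (24 categories of five exemplars under 8 superordinates, 40 fillers,
  German-looking upper-case names, some with accepted alternatives);
* ``simulate_trial_table`` / ``simulate_grid_table`` — the latency and
  error models run forward: per-trial mean latency
  ``mu = intercept + slope * (ordinal - 3) + subject/category intercepts and
  slopes`` with gamma(shape, mean mu) noise, and correctness drawn from a
  Bernoulli with ``logit p(error) = a + b * ordinal`` (raw positions 1..5);
* ``simulate_keystrokes`` — event streams realizing each trial as a planted
  response style (identical, backspace-corrected, near-miss typo below the
  distance cut-off, alternative naming, first-letter error, garbled entry,
  special-key or shift start, or no answer), with the first keystroke at the
  trial's latency and ground-truth labels returned alongside.

Latency and error defaults are the fitted values of the typed-naming
experiment this package models (intercept 1298.49 ms, slope 41.68 ms per
ordinal position; error log-odds −2.74 + 0.15·position).  Random-effect
standard deviations and the gamma shape are free generator choices, since
the source analyses do not publish variance components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import keylog
from .keylog import KeyEvent, TrialLog
from .match import jaro_distance
from .stimlist import DesignConfig, Stimulus, TrialList, generate_list

__all__ = [
    "RTModelParams",
    "ErrorModelParams",
    "TypingBehaviorParams",
    "make_stimuli",
    "simulate_trial_table",
    "simulate_grid_table",
    "simulate_keystrokes",
    "simulate_experiment",
]

_ALPHABET = "ABCDEFGHIJKLMNOPRSTUVWZ"
_VOWELS = "AEIOU"


@dataclass(frozen=True)
class RTModelParams:
    """Forward model for first-keystroke latencies (ms)."""

    intercept_ms: float = 1298.49
    slope_ms_per_position: float = 41.68
    sd_subject_intercept: float = 150.0
    sd_subject_slope: float = 20.0
    sd_category_intercept: float = 60.0
    sd_category_slope: float = 12.0
    gamma_shape: float = 18.0

    def __post_init__(self):
        if self.intercept_ms <= 0:
            raise ValueError("intercept must be positive")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        for f in (
            self.sd_subject_intercept,
            self.sd_subject_slope,
            self.sd_category_intercept,
            self.sd_category_slope,
        ):
            if f < 0:
                raise ValueError("random-effect SDs must be >= 0")


@dataclass(frozen=True)
class ErrorModelParams:
    """Bernoulli error process; logit p(error) = intercept + slope * position."""

    logit_intercept: float = -2.74
    logit_slope: float = 0.15


@dataclass(frozen=True)
class TypingBehaviorParams:
    """Keystroke-level response styles.

    For trials the error model marked correct: with ``p_alternative_name``
    the participant produces an accepted alternative instead of the picture
    name; independently, with ``p_typo`` a typo occurs, repaired with
    backspaces with probability ``p_backspace_repair`` (otherwise it stays
    in as a near-miss below the distance cut-off).  For incorrect trials
    the style is drawn among no-answer, special-key start, shift start,
    first-letter error, garbled-but-right-first-letter and wrong-word
    entries with the probabilities below (the last three share the
    remainder in the given ratio).  Defaults echo the observed error
    taxonomy of the modelled experiment.
    """

    p_typo: float = 0.18
    p_backspace_repair: float = 0.70
    p_alternative_name: float = 0.08
    p_special_start: float = 0.05
    p_shift_start: float = 0.02
    p_null_response: float = 0.29
    incorrect_split: tuple[float, float, float] = (0.69, 0.27, 0.04)
    # (first_letter_error, combined, distance_exceeded) shares of the rest
    p_terminal_enter: float = 0.5
    ikey_median_ms: float = 200.0
    ikey_sigma: float = 0.4

    def __post_init__(self):
        for name in (
            "p_typo",
            "p_backspace_repair",
            "p_alternative_name",
            "p_special_start",
            "p_shift_start",
            "p_null_response",
            "p_terminal_enter",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_special_start + self.p_shift_start + self.p_null_response > 1.0:
            raise ValueError(
                "exclusive incorrect-mode probabilities sum to more than 1"
            )
        if abs(sum(self.incorrect_split) - 1.0) > 1e-9:
            raise ValueError("incorrect_split must sum to 1")


# ---------------------------------------------------------------------------
# stimuli


def _word(rng: np.random.Generator, n_min=4, n_max=9) -> str:
    n = int(rng.integers(n_min, n_max + 1))
    chars = []
    for i in range(n):
        pool = _VOWELS if i % 2 == 1 else _ALPHABET
        chars.append(pool[rng.integers(len(pool))])
    return "".join(chars)


def make_stimuli(
    config: DesignConfig = DesignConfig(),
    seed: int = 0,
    p_alternative: float = 0.35,
) -> list[Stimulus]:
    """Generate a synthetic stimulus inventory matching the design shape.

    Categories are spread evenly over ``n_blocks`` superordinates; about
    ``p_alternative`` of the items get one accepted alternative name (a
    distinct word, as a synonym would be).
    """
    rng = np.random.default_rng(seed)
    names: set[str] = set()

    def fresh_word() -> str:
        for _ in range(1000):
            w = _word(rng)
            if w not in names:
                names.add(w)
                return w
        raise RuntimeError("name pool exhausted")

    stimuli: list[Stimulus] = []
    n_supers = config.n_blocks
    for c in range(config.n_categories):
        cat = f"cat{c:02d}"
        sup = f"sup{c % n_supers}"
        for e in range(config.exemplars_per_category):
            alts = (fresh_word(),) if rng.random() < p_alternative else ()
            stimuli.append(
                Stimulus(
                    item_id=f"t{c:02d}_{e}",
                    name=fresh_word(),
                    alternatives=alts,
                    category=cat,
                    superordinate=sup,
                )
            )
    for f in range(config.n_fillers):
        stimuli.append(
            Stimulus(item_id=f"f{f:02d}", name=fresh_word(), is_filler=True)
        )
    return stimuli


# ---------------------------------------------------------------------------
# trial tables


_ORDINAL_CENTER = 3.0  # mean of positions 1..5


def _random_effects(rng, n, sd_int, sd_slope):
    return rng.normal(0.0, sd_int, n), rng.normal(0.0, sd_slope, n)


def simulate_trial_table(
    lists: dict[str, TrialList],
    rt: RTModelParams = RTModelParams(),
    err: ErrorModelParams = ErrorModelParams(),
    seed: int = 0,
) -> pd.DataFrame:
    """Run the latency/error model forward over per-participant trial lists.

    ``lists`` maps participant id to that participant's randomized list.
    Returns one row per trial: participant, trial_index, item_id, category,
    ordinal_position, block, is_filler, rt_ms, correct.  Fillers get the
    intercept-only latency and the error rate of the centre position.
    Raises if any implied mean latency is non-positive (identity link).
    """
    rng = np.random.default_rng(seed)
    participants = sorted(lists)
    categories = sorted(
        {
            t.stimulus.category
            for tl in lists.values()
            for t in tl.trials
            if not t.stimulus.is_filler
        }
    )
    cat_idx = {c: i for i, c in enumerate(categories)}
    s_int, s_slp = _random_effects(
        rng, len(participants), rt.sd_subject_intercept, rt.sd_subject_slope
    )
    c_int, c_slp = _random_effects(
        rng, len(categories), rt.sd_category_intercept, rt.sd_category_slope
    )

    rows = []
    for pi, pid in enumerate(participants):
        for t in lists[pid].trials:
            stim = t.stimulus
            if stim.is_filler:
                pos_c = 0.0
                mu = rt.intercept_ms + s_int[pi]
                logit = err.logit_intercept + err.logit_slope * _ORDINAL_CENTER
                ordinal = np.nan
                cat = None
            else:
                ordinal = t.ordinal_position
                pos_c = ordinal - _ORDINAL_CENTER
                ci = cat_idx[stim.category]
                mu = (
                    rt.intercept_ms
                    + rt.slope_ms_per_position * pos_c
                    + s_int[pi]
                    + s_slp[pi] * pos_c
                    + c_int[ci]
                    + c_slp[ci] * pos_c
                )
                logit = err.logit_intercept + err.logit_slope * ordinal
                cat = stim.category
            if mu <= 0:
                raise ValueError(
                    f"implied mean latency {mu:.1f} <= 0 for participant {pid}; "
                    "reduce random-effect SDs or raise the intercept "
                    "(identity-link positivity)"
                )
            rt_ms = rng.gamma(rt.gamma_shape, mu / rt.gamma_shape)
            p_err = 1.0 / (1.0 + np.exp(-logit))
            rows.append(
                {
                    "participant": pid,
                    "trial_index": t.position + 1,
                    "item_id": stim.item_id,
                    "category": cat,
                    "ordinal_position": ordinal,
                    "block": t.block + 1,
                    "is_filler": stim.is_filler,
                    "rt_ms": rt_ms,
                    "correct": bool(rng.random() >= p_err),
                }
            )
    return pd.DataFrame(rows)


def simulate_grid_table(
    n_subjects: int,
    n_categories: int,
    rt: RTModelParams = RTModelParams(),
    err: ErrorModelParams = ErrorModelParams(),
    n_positions: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Vectorized targets-only table on the subject x category x position grid.

    Equivalent to the list-based generator with fillers and trial order
    stripped away; the fast path for power simulation and parameter-recovery
    studies.
    """
    rng = np.random.default_rng(seed)
    S, C, P = n_subjects, n_categories, n_positions
    s_int, s_slp = _random_effects(rng, S, rt.sd_subject_intercept, rt.sd_subject_slope)
    c_int, c_slp = _random_effects(rng, C, rt.sd_category_intercept, rt.sd_category_slope)

    subj = np.repeat(np.arange(S), C * P)
    cat = np.tile(np.repeat(np.arange(C), P), S)
    pos = np.tile(np.arange(1, P + 1), S * C)
    pos_c = pos - _ORDINAL_CENTER
    mu = (
        rt.intercept_ms
        + rt.slope_ms_per_position * pos_c
        + s_int[subj]
        + s_slp[subj] * pos_c
        + c_int[cat]
        + c_slp[cat] * pos_c
    )
    if np.any(mu <= 0):
        raise ValueError(
            "implied mean latency <= 0; reduce random-effect SDs or raise "
            "the intercept (identity-link positivity)"
        )
    rts = rng.gamma(rt.gamma_shape, mu / rt.gamma_shape)
    p_err = 1.0 / (1.0 + np.exp(-(err.logit_intercept + err.logit_slope * pos)))
    correct = rng.random(len(mu)) >= p_err
    return pd.DataFrame(
        {
            "participant": np.char.add("s", np.char.zfill(subj.astype(str), 3)),
            "category": np.char.add("cat", np.char.zfill(cat.astype(str), 3)),
            "ordinal_position": pos.astype(float),
            "is_filler": False,
            "rt_ms": rts,
            "correct": correct,
        }
    )


# ---------------------------------------------------------------------------
# keystroke simulation


def _other_letter(rng, exclude: str) -> str:
    while True:
        ch = _ALPHABET[rng.integers(len(_ALPHABET))]
        if ch != exclude:
            return ch


def _near_miss(rng, word: str, threshold: float) -> str | None:
    """A one-substitution corruption (not the first letter) with d < threshold."""
    if len(word) < 4:
        return None
    for _ in range(10):
        i = int(rng.integers(1, len(word)))
        cand = word[:i] + _other_letter(rng, word[i]) + word[i + 1 :]
        if cand != word and jaro_distance(cand, word) < threshold:
            return cand
    return None


def _garbled_same_first(rng, word: str, threshold: float) -> str | None:
    """Same first letter, Jaro distance >= threshold (distance_exceeded)."""
    for _ in range(50):
        n = int(rng.integers(4, 9))
        cand = word[0] + "".join(
            _ALPHABET[rng.integers(len(_ALPHABET))] for _ in range(n - 1)
        )
        if jaro_distance(cand, word) >= threshold:
            return cand
    return None


def _wrong_word(rng, word: str, threshold: float, require_far: bool) -> str:
    """Different first letter; if require_far also d >= threshold (combined)."""
    for _ in range(50):
        n = int(rng.integers(4, 9))
        first = _other_letter(rng, word[0])
        cand = first + "".join(
            _ALPHABET[rng.integers(len(_ALPHABET))] for _ in range(n - 1)
        )
        if not require_far or jaro_distance(cand, word) >= threshold:
            return cand
    return word[::-1]  # pathological fallback


def _typing_events(rng, text: str, t0: float, behavior: TypingBehaviorParams):
    """Timestamps for typing ``text`` starting at t0 (first char at t0)."""
    events = []
    t = t0
    for i, ch in enumerate(text):
        if i > 0:
            t += behavior.ikey_median_ms * np.exp(
                rng.normal(0.0, behavior.ikey_sigma)
            )
        key = "SPACE" if ch == " " else ch
        events.append(KeyEvent(key, t))
    return events, t


def _corrected_stream(rng, text: str, t0: float, behavior):
    """Type with one mid-word typo repaired by backspaces; ends exactly at text."""
    i = int(rng.integers(1, len(text)))  # typo position (never the first char)
    n_wrong = int(rng.integers(1, 3))
    wrong = "".join(_other_letter(rng, text[i]) for _ in range(n_wrong))
    seq = list(text[:i]) + list(wrong) + ["BACKSPACE"] * n_wrong + list(text[i:])
    events = []
    t = t0
    for j, key in enumerate(seq):
        if j > 0:
            t += behavior.ikey_median_ms * np.exp(rng.normal(0.0, behavior.ikey_sigma))
        events.append(KeyEvent("SPACE" if key == " " else key, t))
    return events, t


def simulate_keystrokes(
    trial_table: pd.DataFrame,
    stimuli: list[Stimulus],
    behavior: TypingBehaviorParams = TypingBehaviorParams(),
    seed: int = 0,
    threshold: float = 0.3,
) -> tuple[list[TrialLog], pd.DataFrame]:
    """Generate keystroke logs realizing each trial's correctness flag.

    Returns ``(trial_logs, truth)`` where truth records the planted response
    style per trial (columns: participant, trial_index, item_id,
    true_status, true_subtype).  The first keystroke of every non-null trial
    falls exactly at the trial's ``rt_ms``.
    """
    rng = np.random.default_rng(seed)
    by_id = {s.item_id: s for s in stimuli}
    logs: list[TrialLog] = []
    truth_rows = []

    for row in trial_table.itertuples(index=False):
        stim = by_id[row.item_id]
        t0 = float(row.rt_ms)
        events: list[KeyEvent] = []

        if row.correct:
            use_alt = bool(stim.alternatives) and rng.random() < behavior.p_alternative_name
            word = stim.alternatives[0] if use_alt else stim.name
            style = "identical"
            if rng.random() < behavior.p_typo:
                if rng.random() < behavior.p_backspace_repair:
                    style = "corrected"
                else:
                    near = _near_miss(rng, word, threshold)
                    if near is None:
                        style = "identical"
                    else:
                        style = "below_threshold"
                        word_typed = near
            if style == "corrected":
                events, t_end = _corrected_stream(rng, word, t0, behavior)
            else:
                typed = word if style == "identical" else word_typed
                events, t_end = _typing_events(rng, typed, t0, behavior)
            true_status, true_subtype = "correct", style
            basis = "alternative" if use_alt else "picture_name"
        else:
            basis = None
            r = rng.random()
            if r < behavior.p_null_response:
                true_status, true_subtype = "incorrect", "na"
                events, t_end = [], t0
            elif r < behavior.p_null_response + behavior.p_special_start:
                true_status, true_subtype = "incorrect", "special_key_start"
                key = ["SPACE", "BACKSPACE", "CAPSLOCK"][int(rng.integers(3))]
                tail, t_end = _typing_events(rng, stim.name, t0, behavior)
                shifted = [KeyEvent(key, t0)] + [
                    KeyEvent(e.key, e.t_ms + behavior.ikey_median_ms) for e in tail
                ]
                events = shifted
            elif (
                r
                < behavior.p_null_response
                + behavior.p_special_start
                + behavior.p_shift_start
            ):
                true_status, true_subtype = "incorrect", "shift_start"
                tail, t_end = _typing_events(rng, stim.name, t0, behavior)
                events = [KeyEvent("SHIFT", t0)] + [
                    KeyEvent(e.key, e.t_ms + behavior.ikey_median_ms) for e in tail
                ]
            else:
                w_fl, w_comb, w_dist = behavior.incorrect_split
                r2 = rng.random() * (w_fl + w_comb + w_dist)
                if r2 < w_fl:
                    true_subtype = "first_letter_error"
                    typed = _other_letter(rng, stim.name[0]) + stim.name[1:]
                elif r2 < w_fl + w_comb:
                    true_subtype = "combined"
                    typed = _wrong_word(rng, stim.name, threshold, require_far=True)
                else:
                    true_subtype = "distance_exceeded"
                    typed = _garbled_same_first(rng, stim.name, threshold)
                    if typed is None:
                        true_subtype = "combined"
                        typed = _wrong_word(rng, stim.name, threshold, require_far=True)
                true_status = "incorrect"
                events, t_end = _typing_events(rng, typed, t0, behavior)

        if events and rng.random() < behavior.p_terminal_enter:
            events = events + [
                KeyEvent(
                    "ENTER",
                    events[-1].t_ms
                    + behavior.ikey_median_ms
                    * float(np.exp(rng.normal(0.0, behavior.ikey_sigma))),
                )
            ]

        logs.append(
            TrialLog(
                participant_id=str(row.participant),
                trial_index=int(row.trial_index),
                item_id=row.item_id,
                events=events,
            )
        )
        truth_rows.append(
            {
                "participant": str(row.participant),
                "trial_index": int(row.trial_index),
                "item_id": row.item_id,
                "true_status": true_status,
                "true_subtype": true_subtype,
                "true_basis": basis,
            }
        )
    return logs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# whole experiments


def simulate_experiment(
    config: DesignConfig = DesignConfig(),
    n_subjects: int = 30,
    rt: RTModelParams = RTModelParams(),
    err: ErrorModelParams = ErrorModelParams(),
    behavior: TypingBehaviorParams = TypingBehaviorParams(),
    seed: int = 0,
    with_keystrokes: bool = True,
):
    """End-to-end synthetic experiment.

    Returns a dict with ``stimuli``, per-participant ``lists``, the ground
    truth ``trial_table`` and, when requested, ``trial_logs`` and ``truth``
    labels for the keystroke layer.  Deterministic in ``seed``.
    """
    root = np.random.SeedSequence(seed)
    s_stim, s_lists, s_table, s_keys = root.spawn(4)
    stimuli = make_stimuli(config, seed=int(s_stim.generate_state(1)[0] % 2**31))
    list_seeds = s_lists.generate_state(n_subjects) % 2**31
    lists = {
        f"s{i:03d}": generate_list(
            stimuli, config, seed=int(list_seeds[i]), list_id=f"L{i:03d}"
        )
        for i in range(n_subjects)
    }
    table = simulate_trial_table(
        lists, rt, err, seed=int(s_table.generate_state(1)[0] % 2**31)
    )
    out = {"stimuli": stimuli, "lists": lists, "trial_table": table}
    if with_keystrokes:
        logs, truth = simulate_keystrokes(
            table, stimuli, behavior, seed=int(s_keys.generate_state(1)[0] % 2**31)
        )
        out["trial_logs"] = logs
        out["truth"] = truth
    return out
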