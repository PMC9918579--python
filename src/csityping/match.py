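"""Automated correctness classification of typed naming responses.

A typed entry counts as correct when it starts with the right character —
before *and* after backspace correction — and its Jaro distance to the
picture name (or to a "best match" accepted alternative) is below a cut-off
(default .3).  Everything else is sorted into an error taxonomy: no answer,
special-key start, shift start, distance exceeded, first-letter error, or
the combination of the last two.

The Jaro distance is the primary metric (well suited to short human-typed
strings, tolerant of transpositions between nearby characters); normalized
Levenshtein and optimal string alignment (restricted Damerau–Levenshtein)
are provided for comparison with the same cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .keylog import (
    SHIFT,
    SPACE,
    BACKSPACE,
    CAPSLOCK,
    ENTER,
    ReconstructedEntry,
    TrialLog,
    reconstruct_entry,
    strip_terminal_keys,
)
from .stimlist import Stimulus

__all__ = [
    "MatchConfig",
    "ResponseClassification",
    "jaro_distance",
    "levenshtein_norm",
    "osa_norm",
    "best_match",
    "classify_entry",
    "classify_experiment",
    "taxonomy_summary",
]

#: keys whose appearance as the first event makes a trial a "special key
#: start" (shift starts are reported separately in the taxonomy)
SPECIAL_START_KEYS = frozenset({SPACE, BACKSPACE, CAPSLOCK, ENTER})

CORRECT = "correct"
INCORRECT = "incorrect"


@dataclass(frozen=True)
class MatchConfig:
    distance_kind: str = "jaro"  # jaro | levenshtein_norm | osa_norm
    threshold: float = 0.3

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.distance_kind not in _DISTANCES:
            raise ValueError(f"unknown distance {self.distance_kind!r}")

    @property
    def distance(self):
        return _DISTANCES[self.distance_kind]


@dataclass
class ResponseClassification:
    raw_string: str
    corrected_string: str
    matched_target: str | None
    d: float | None
    status: str  # correct | incorrect
    subtype: str  # identical | corrected | below_threshold | na | ...
    match_basis: str | None  # picture_name | alternative (correct trials)
    rt_ms: float | None = None


# ---------------------------------------------------------------------------
# distances


def jaro_distance(a: str, b: str) -> float:
    """Jaro distance in [0, 1]; 0 for identical strings.

    Characters match when equal and within a sliding window of
    ``floor(max(|a|,|b|)/2) - 1`` positions; with ``m`` matches and ``t``
    transposition pairs the similarity is ``(m/|a| + m/|b| + (m-t)/m)/3``
    (0 when nothing matches).  Equals Jaro–Winkler with prefix weight 0.
    """
    if a == b:
        return 0.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 1.0
    window = max(max(la, lb) // 2 - 1, 0)
    matched_a = [False] * la
    matched_b = [False] * lb
    m = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not matched_b[j] and b[j] == ca:
                matched_a[i] = matched_b[j] = True
                m += 1
                break
    if m == 0:
        return 1.0
    seq_a = [ca for i, ca in enumerate(a) if matched_a[i]]
    seq_b = [cb for j, cb in enumerate(b) if matched_b[j]]
    half_transpositions = sum(x != y for x, y in zip(seq_a, seq_b))
    t = half_transpositions / 2.0
    sim = (m / la + m / lb + (m - t) / m) / 3.0
    return 1.0 - sim


def _edit_distance(a: str, b: str, transpositions: bool) -> int:
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return la or lb
    prev2 = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                transpositions
                and i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


def levenshtein_norm(a: str, b: str) -> float:
    """Unit-cost Levenshtein distance divided by max(|a|, |b|); 0 if both empty."""
    n = max(len(a), len(b))
    return _edit_distance(a, b, transpositions=False) / n if n else 0.0


def osa_norm(a: str, b: str) -> float:
    """Normalized optimal string alignment distance.

    Levenshtein plus adjacent transposition as a unit-cost operation, each
    substring edited at most once (restricted Damerau–Levenshtein).
    """
    n = max(len(a), len(b))
    return _edit_distance(a, b, transpositions=True) / n if n else 0.0


_DISTANCES = {
    "jaro": jaro_distance,
    "levenshtein_norm": levenshtein_norm,
    "osa_norm": osa_norm,
}


# ---------------------------------------------------------------------------
# matching and classification


def best_match(
    corrected: str,
    picture_name: str,
    alternatives: Iterable[str] = (),
    cfg: MatchConfig = MatchConfig(),
) -> tuple[str, float]:
    """Pick the target the entry is scored against.

    An accepted alternative is favoured over the picture name only when it
    starts with the entry's first character *and* is strictly closer than
    the picture name.  Ties resolve to the picture name, then to earlier
    list order.
    """
    if not picture_name:
        raise ValueError("picture_name must be non-empty")
    dist = cfg.distance
    d_name = dist(corrected, picture_name)
    best_target, best_d = picture_name, d_name
    first = corrected[0] if corrected else None
    for alt in alternatives:
        if not alt or alt[0] != first:
            continue
        d_alt = dist(corrected, alt)
        if d_alt < d_name and d_alt < best_d:
            best_target, best_d = alt, d_alt
    return best_target, best_d


def classify_entry(
    entry: ReconstructedEntry,
    stimulus: Stimulus,
    cfg: MatchConfig = MatchConfig(),
) -> ResponseClassification:
    """Classify one reconstructed trial entry.

    Decision order: (1) no events → NA; (2) special-key or shift start;
    (3) best-match target selection on the corrected string; (4) correct iff
    the first printable character of the raw *and* corrected strings equals
    the target's first character and d < threshold; otherwise the incorrect
    subtype records which condition failed.
    """

    def result(status, subtype, target=None, d=None, basis=None):
        return ResponseClassification(
            raw_string=entry.raw_string,
            corrected_string=entry.corrected_string,
            matched_target=target,
            d=d,
            status=status,
            subtype=subtype,
            match_basis=basis,
            rt_ms=entry.rt_ms,
        )

    if entry.first_key is None:
        return result(INCORRECT, "na")
    if entry.first_key in SPECIAL_START_KEYS:
        return result(INCORRECT, "special_key_start")
    if entry.first_key == SHIFT:
        return result(INCORRECT, "shift_start")

    target, d = best_match(
        entry.corrected_string, stimulus.name, stimulus.alternatives, cfg
    )
    basis = "picture_name" if target == stimulus.name else "alternative"
    first_target = target[0]
    raw_first = entry.raw_string[0] if entry.raw_string else None
    corr_first = entry.corrected_string[0] if entry.corrected_string else None
    first_letter_ok = raw_first == first_target and corr_first == first_target
    below = d < cfg.threshold

    if first_letter_ok and below:
        if entry.corrected_string == target:
            subtype = "corrected" if entry.n_backspaces > 0 else "identical"
        else:
            subtype = "below_threshold"
        return result(CORRECT, subtype, target, d, basis)
    if not first_letter_ok and not below:
        return result(INCORRECT, "combined", target, d)
    if not first_letter_ok:
        return result(INCORRECT, "first_letter_error", target, d)
    return result(INCORRECT, "distance_exceeded", target, d)


def classify_experiment(
    trial_logs: list[TrialLog],
    stimuli: list[Stimulus],
    cfg: MatchConfig = MatchConfig(),
) -> pd.DataFrame:
    """Classify every trial; returns one row per trial.

    Trailing SPACE/ENTER submission keys are stripped before reconstruction.
    Unknown item ids raise, naming the trial.
    """
    by_id = {s.item_id: s for s in stimuli}
    rows = []
    for log in trial_logs:
        if log.item_id not in by_id:
            raise KeyError(
                f"unknown item_id {log.item_id!r} in trial "
                f"{log.participant_id}/{log.trial_index}"
            )
        stim = by_id[log.item_id]
        events = strip_terminal_keys(log.events)
        entry = reconstruct_entry(
            TrialLog(log.participant_id, log.trial_index, log.item_id, events)
        )
        c = classify_entry(entry, stim, cfg)
        rows.append(
            {
                "participant": log.participant_id,
                "trial_index": log.trial_index,
                "item_id": log.item_id,
                "raw_string": c.raw_string,
                "corrected_string": c.corrected_string,
                "matched_target": c.matched_target,
                "d": c.d,
                "status": c.status,
                "subtype": c.subtype,
                "match_basis": c.match_basis,
                "correct": c.status == CORRECT,
                "rt_ms": c.rt_ms,
            }
        )
    return pd.DataFrame(rows)


def taxonomy_summary(classified: pd.DataFrame) -> dict:
    """Counts and within-status percentages by status and subtype."""
    n = len(classified)
    summary: dict = {"n_total": n, "statuses": {}}
    for status, grp in classified.groupby("status"):
        entry = {
            "count": int(len(grp)),
            "pct_of_total": round(100.0 * len(grp) / n, 2) if n else None,
            "subtypes": {},
        }
        key = "subtype" if status == INCORRECT else ["subtype", "match_basis"]
        counts = grp.groupby(key).size()
        for k, v in counts.items():
            label = k if isinstance(k, str) else "/".join(map(str, k))
            entry["subtypes"][label] = {
                "count": int(v),
                "pct_within_status": round(100.0 * v / len(grp), 2),
            }
        summary["statuses"][status] = entry
    return summary
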