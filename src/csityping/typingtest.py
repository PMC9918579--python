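"""Copy-typing speed and accuracy via the five-character-word convention.

Typing skill is summarized from short copy-typing transcripts: the
backspace-corrected character stream (what ends up on screen, each
character stamped with the keystroke that finally produced it) is cut into
consecutive, non-overlapping five-character chunks aligned positionally
with the target text.  A chunk counts as correct when its five characters
match the target exactly and no backspace fell into its production span —
so a repaired chunk still counts as wrong, while correction keeps the rest
of the transcript aligned.  Accuracy is the percentage of correct chunks;
speed is correct chunks per minute of total production time.

Chunk timing convention: chunk *k* spans from the last keystroke of chunk
*k−1* (trial onset for the first chunk) to its own last keystroke, so the
spans tile the production period and the total time equals the timestamp of
the last chunk's final keystroke.  Backspaces are assigned to the chunk
whose span contains their timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .keylog import BACKSPACE, TrialLog, is_printable

__all__ = ["TypingTestResult", "typing_metrics", "CHUNK"]

CHUNK = 5  # characters per "word"


@dataclass
class TypingTestResult:
    wpm_5char: float | None  # correct five-character words per minute
    accuracy_pct: float | None  # % of chunks with no errors and no backspaces
    n_chunks: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "wpm_5char": self.wpm_5char,
                    "accuracy_pct": self.accuracy_pct,
                    "n_chunks": self.n_chunks,
                }
            ]
        )


def _trial_chunks(trial: TrialLog, target_text: str):
    """Yield (correct, span_minutes) per complete chunk of one trial."""
    target = target_text.upper()
    chars: list[tuple[str, float]] = []  # backspace-corrected stream
    backspaces: list[float] = []
    for e in trial.events:
        if e.key == BACKSPACE:
            backspaces.append(e.t_ms)
            if chars:
                chars.pop()
        elif is_printable(e.key):
            chars.append((" " if e.key == "SPACE" else e.key, e.t_ms))

    n_chunks = min(len(chars), len(target)) // CHUNK
    prev_end = 0.0
    for k in range(n_chunks):
        block = chars[k * CHUNK : (k + 1) * CHUNK]
        end = block[-1][1]
        text_ok = "".join(c for c, _ in block) == target[k * CHUNK : (k + 1) * CHUNK]
        bs_inside = any(prev_end < t <= end for t in backspaces)
        yield text_ok and not bs_inside, (end - prev_end) / 60000.0
        prev_end = end


def typing_metrics(
    trials: list[TrialLog],
    targets: dict[str, str] | list[str],
) -> TypingTestResult:
    """Score a set of copy-typing trials.

    ``targets`` maps item_id to target text (or is a positional list).
    An empty stream contributes no chunks; with zero chunks overall the
    metrics are reported as None, never NaN.
    """
    if isinstance(targets, dict):
        pairs = [(t, targets[t.item_id]) for t in trials]
    else:
        pairs = list(zip(trials, targets))

    n_chunks = 0
    n_correct = 0
    total_minutes = 0.0
    for trial, text in pairs:
        for ok, minutes in _trial_chunks(trial, text):
            n_chunks += 1
            n_correct += ok
            total_minutes += minutes

    if n_chunks == 0:
        return TypingTestResult(None, None, 0)
    accuracy = 100.0 * n_correct / n_chunks
    wpm = n_correct / total_minutes if total_minutes > 0 else None
    return TypingTestResult(wpm, accuracy, n_chunks)
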