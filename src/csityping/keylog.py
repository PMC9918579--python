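"""Keystroke logs from typed picture naming: parsing and reconstruction.

The on-disk dialect is JSON lines, one object per key event::

    {"pid": "s01", "trial": 12, "item": "i042", "key": "a", "t": 843.2}

``key`` follows the W3C ``KeyboardEvent.key`` vocabulary ("a".."z", "ß",
"Backspace", " ", "Enter", "Shift", "CapsLock", ...); ``t`` is milliseconds
since picture onset.  On ingestion printable characters are upper-cased
(participants type in capitals on a QWERTZ keyboard; umlauts and ß are
ordinary characters with direct keys) and control keys are normalized to the
symbolic names BACKSPACE, SPACE, ENTER, SHIFT, CAPSLOCK; anything else
multi-character maps to OTHER.

Reconstruction replays the stream through a minimal text editor: printable
keys append a character, BACKSPACE deletes the last one (no-op on an empty
buffer).  The first keystroke of *any* kind defines the trial's latency —
the response may legitimately start with a special key, which the classifier
then flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "KeyEvent",
    "TrialLog",
    "ReconstructedEntry",
    "SPECIAL_KEYS",
    "normalize_key",
    "parse_keylog",
    "write_keylog",
    "strip_terminal_keys",
    "reconstruct_entry",
    "entries_to_frame",
]

BACKSPACE = "BACKSPACE"
SPACE = "SPACE"
ENTER = "ENTER"
SHIFT = "SHIFT"
CAPSLOCK = "CAPSLOCK"
OTHER = "OTHER"

SPECIAL_KEYS = frozenset({BACKSPACE, SPACE, ENTER, SHIFT, CAPSLOCK, OTHER})

_KEY_ALIASES = {
    "backspace": BACKSPACE,
    " ": SPACE,
    "space": SPACE,
    "spacebar": SPACE,
    "enter": ENTER,
    "return": ENTER,
    "shift": SHIFT,
    "capslock": CAPSLOCK,
}


def normalize_key(key: str) -> str:
    """Map a raw key name onto the symbolic vocabulary."""
    if len(key) == 1:
        if key == " ":
            return SPACE
        return key.upper()
    return _KEY_ALIASES.get(key.lower(), OTHER)


def is_printable(key: str) -> bool:
    """True for keys that contribute a character to the typed string.

    SPACE contributes a literal space; ENTER, SHIFT, CAPSLOCK, BACKSPACE and
    OTHER contribute nothing.
    """
    return key == SPACE or (len(key) == 1 and key not in SPECIAL_KEYS)


def _key_char(key: str) -> str:
    return " " if key == SPACE else key


@dataclass(frozen=True)
class KeyEvent:
    key: str
    t_ms: float

    def __post_init__(self):
        if self.t_ms < 0:
            raise ValueError(f"negative timestamp {self.t_ms}")


@dataclass
class TrialLog:
    participant_id: str
    trial_index: int
    item_id: str
    events: list[KeyEvent] = field(default_factory=list)
    picture_duration_ms: float = 6000.0


@dataclass
class ReconstructedEntry:
    raw_string: str
    corrected_string: str
    first_key: str | None
    rt_ms: float | None
    n_backspaces: int = 0

    @property
    def first_printable_char(self) -> str | None:
        return self.raw_string[0] if self.raw_string else None


class KeylogParseError(ValueError):
    pass


def parse_keylog(source, strict: bool = False):
    """Parse a JSON-lines keystroke log.

    ``source`` is a path or an iterable of lines.  Returns
    ``(trial_logs, rejects)`` where rejects is a list of
    ``(line_number, line, reason)`` for malformed records (in strict mode the
    first malformed record raises instead).  Events are grouped by
    (participant, trial) and time-sorted; out-of-order timestamps are
    re-sorted and noted in the rejects report with reason ``"reordered"``.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source, encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        lines = list(source)

    groups: dict[tuple[str, int], TrialLog] = {}
    rejects: list[tuple[int, str, str]] = []
    for i, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            rec = json.loads(line)
            pid = str(rec["pid"])
            trial = int(rec["trial"])
            item = str(rec["item"])
            key = normalize_key(str(rec["key"]))
            event = KeyEvent(key, float(rec["t"]))
        except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
            if strict:
                raise KeylogParseError(f"line {i}: {exc}") from exc
            rejects.append((i, line, str(exc)))
            continue
        log = groups.setdefault((pid, trial), TrialLog(pid, trial, item))
        log.events.append(event)

    for (pid, trial), log in groups.items():
        ts = [e.t_ms for e in log.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            log.events.sort(key=lambda e: e.t_ms)
            rejects.append(
                (0, f"{pid}/{trial}", "reordered: out-of-order timestamps")
            )
    return list(groups.values()), rejects


_WIRE_NAMES = {
    BACKSPACE: "Backspace",
    SPACE: " ",
    ENTER: "Enter",
    SHIFT: "Shift",
    CAPSLOCK: "CapsLock",
    OTHER: "Unidentified",
}


def write_keylog(trial_logs: list[TrialLog], path) -> None:
    """Write trials back to the JSON-lines dialect (round-trips with parse)."""
    with open(path, "w", encoding="utf-8") as fh:
        for log in trial_logs:
            for e in log.events:
                key = _WIRE_NAMES.get(e.key, e.key)
                fh.write(
                    json.dumps(
                        {
                            "pid": log.participant_id,
                            "trial": log.trial_index,
                            "item": log.item_id,
                            "key": key,
                            "t": e.t_ms,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )


def strip_terminal_keys(events: list[KeyEvent]) -> list[KeyEvent]:
    """Drop the maximal trailing run of SPACE/ENTER events.

    Participants end a response with the space bar or enter key; those
    submission keys are not part of the typed word.  Interior SPACE/ENTER
    events are retained.  Idempotent.
    """
    end = len(events)
    while end > 0 and events[end - 1].key in (SPACE, ENTER):
        end -= 1
    return list(events[:end])


def reconstruct_entry(trial: TrialLog) -> ReconstructedEntry:
    """Replay a trial's events into raw and backspace-corrected strings.

    ``raw_string`` concatenates printable keys in typing order (e.g.
    C,H,E,⌫,A,I,R → raw "CHEAIR"); ``corrected_string`` is the editor replay
    of the same stream ("CHAIR").  ``rt_ms`` is the timestamp of the first
    event of any kind; None for an empty trial.
    """
    raw: list[str] = []
    buffer: list[str] = []
    n_backspaces = 0
    for e in trial.events:
        if e.key == BACKSPACE:
            n_backspaces += 1
            if buffer:
                buffer.pop()
        elif is_printable(e.key):
            ch = _key_char(e.key)
            raw.append(ch)
            buffer.append(ch)
        # SHIFT/CAPSLOCK/ENTER/OTHER contribute no characters
    first = trial.events[0] if trial.events else None
    return ReconstructedEntry(
        raw_string="".join(raw),
        corrected_string="".join(buffer),
        first_key=first.key if first else None,
        rt_ms=first.t_ms if first else None,
        n_backspaces=n_backspaces,
    )


def entries_to_frame(trial_logs: list[TrialLog], strip: bool = True) -> pd.DataFrame:
    """Per-trial reconstruction table (CSV-exportable)."""
    rows = []
    for log in trial_logs:
        events = strip_terminal_keys(log.events) if strip else log.events
        entry = reconstruct_entry(
            TrialLog(log.participant_id, log.trial_index, log.item_id, events)
        )
        rows.append(
            {
                "participant": log.participant_id,
                "trial_index": log.trial_index,
                "item_id": log.item_id,
                "raw_string": entry.raw_string,
                "corrected_string": entry.corrected_string,
                "first_key": entry.first_key,
                "rt_ms": entry.rt_ms,
                "n_backspaces": entry.n_backspaces,
            }
        )
    return pd.DataFrame(rows)
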