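"""Reconstruct and classify typed naming responses.

Runs a handful of hand-written keystroke streams through the backspace
editor replay and the Jaro-distance classifier, then prints the per-trial
decisions — the same path a real experiment's JSON-lines log would take.
"""

from csityping import Stimulus, classify_experiment
from csityping.keylog import KeyEvent, TrialLog

stimuli = [
    Stimulus(item_id="chair", name="CHAIR"),
    Stimulus(item_id="schloss", name="SCHLOSS", alternatives=("BURG",)),
    Stimulus(item_id="kelle", name="KELLE"),
    Stimulus(item_id="feile", name="FEILE"),
]


def trial(n, item, keys):
    return TrialLog("demo", n, item, [KeyEvent(k, 600.0 + 130 * i) for i, k in enumerate(keys)])


logs = [
    trial(1, "chair", list("CHE") + ["BACKSPACE"] + list("AIR") + ["ENTER"]),
    trial(2, "schloss", list("BURG")),                      # accepted alternative
    trial(3, "kelle", list("KESSEL")),                      # close neighbour, d<.3
    trial(4, "feile", list("PFEILE")),                      # wrong first letter
    trial(5, "schloss", list("BUR") + ["BACKSPACE"] * 3 + list("SCHLOSS")),
    trial(6, "chair", ["SHIFT"] + list("CHAIR")),           # shift start
]

table = classify_experiment(logs, stimuli)
cols = ["trial_index", "raw_string", "corrected_string", "matched_target",
        "d", "status", "subtype", "rt_ms"]
print(table[cols].round(3).to_string(index=False))

# Trial 1 repairs CHE<backspace>AIR into CHAIR (correct/corrected); trial 5
# is incorrect although the final string is perfect, because the raw entry
# started with "B" — the first-letter rule applies before and after
# backspace correction.  rt_ms is the first-keystroke latency used as the
# reaction time downstream.
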