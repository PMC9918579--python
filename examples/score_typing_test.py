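"""Score a copy-typing test with the five-character-word convention.

Builds a synthetic transcript of a participant copying a ~155-character
text with a couple of slips, and reports speed (correct five-character
words per minute) and accuracy (chunks without errors or backspaces).
"""

from csityping.keylog import KeyEvent, TrialLog
from csityping.typingtest import typing_metrics

TEXT = ("DER SCHNELLE BRAUNE FUCHS SPRINGT UEBER DEN FAULEN HUND "
        "WAEHREND DIE SONNE LANGSAM HINTER DEN BERGEN VERSINKT UND "
        "DER ABEND SICH UEBER DAS STILLE TAL LEGT")

typed = list(TEXT)
typed[23] = "X"  # one uncorrected slip

events, t = [], 0.0
for i, ch in enumerate(typed):
    t += 350.0  # ~171 keystrokes/min
    events.append(KeyEvent("SPACE" if ch == " " else ch, t))
    if i == 60:  # one corrected slip: stray key + backspace
        events.append(KeyEvent("Q", t + 100))
        events.append(KeyEvent("BACKSPACE", t + 200))

trial = TrialLog("demo", 1, "text1", events)
result = typing_metrics([trial], {"text1": TEXT})

print(f"chunks scored:   {result.n_chunks}")
print(f"accuracy:        {result.accuracy_pct:.1f} %")
print(f"speed:           {result.wpm_5char:.1f} five-character words/min")

# Two chunks are spoiled — one by the wrong character, one by the
# backspace that fell into its production span — so accuracy is below
# 100% while speed counts only the correct chunks against the total
# production time.
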