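"""String distances, best-match selection and the classification taxonomy."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from csityping.keylog import KeyEvent, ReconstructedEntry, TrialLog
from csityping.match import (
    MatchConfig,
    best_match,
    classify_entry,
    classify_experiment,
    jaro_distance,
    levenshtein_norm,
    osa_norm,
    taxonomy_summary,
)
from csityping.stimlist import Stimulus

ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZÄÖÜß"
words = st.text(alphabet=ALPHABET, max_size=12)


def reference_jaro(a: str, b: str) -> float:
    """Flag-array reference in the classic strcmp95 organization."""
    la, lb = len(a), len(b)
    if a == b:
        return 0.0
    if not la or not lb:
        return 1.0
    window = max(max(la, lb) // 2 - 1, 0)
    a_flag = [0] * la
    b_flag = [0] * lb
    m = 0
    for i in range(la):
        for j in range(max(0, i - window), min(lb, i + window + 1)):
            if not b_flag[j] and b[j] == a[i]:
                a_flag[i] = b_flag[j] = 1
                m += 1
                break
    if not m:
        return 1.0
    # count half-transpositions by walking both flag arrays
    k = trans = 0
    for i in range(la):
        if a_flag[i]:
            while not b_flag[k]:
                k += 1
            if a[i] != b[k]:
                trans += 1
            k += 1
    t = trans / 2
    return 1.0 - (m / la + m / lb + (m - t) / m) / 3.0


def brute_force_osa(a: str, b: str) -> int:
    """Exponential recursion straight from the operation definition."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0 or j == 0:
            return i or j
        best = min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(a), len(b))


class TestDistances:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("SCHLOSS", "SCHLOSS", 0.0),
            ("ABC", "XYZ", 1.0),
            ("KESSEL", "KELLE", 47 / 180),  # hand-evaluated: m=4, t=1
            ("GESCHIRR", "GESCHIRRSPÜLER", 1 / 7),  # m=8, t=0
            ("AB", "BA", 1.0),  # zero-width window: nothing matches
        ],
    )
    def test_jaro_worked_examples(self, a, b, expected):
        assert jaro_distance(a, b) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "a, b, lev, osa",
        [
            ("AB", "AB", 0.0, 0.0),
            ("AB", "BA", 1.0, 0.5),  # transposition counts once for OSA
            ("A", "", 1.0, 1.0),
            ("", "", 0.0, 0.0),
        ],
    )
    def test_edit_distance_examples(self, a, b, lev, osa):
        assert levenshtein_norm(a, b) == pytest.approx(lev)
        assert osa_norm(a, b) == pytest.approx(osa)

    @given(words, words)
    def test_jaro_matches_flag_array_reference(self, a, b):
        assert jaro_distance(a, b) == pytest.approx(reference_jaro(a, b), abs=1e-12)

    @given(words, words)
    def test_symmetry_range_and_identity(self, a, b):
        d = jaro_distance(a, b)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(jaro_distance(b, a))
        assert jaro_distance(a, a) == 0.0
        assert levenshtein_norm(a, b) == pytest.approx(levenshtein_norm(b, a))

    @given(st.text(alphabet="ABC", max_size=7), st.text(alphabet="ABC", max_size=7))
    def test_osa_never_exceeds_levenshtein_and_matches_brute_force(self, a, b):
        n = max(len(a), len(b), 1)
        assert osa_norm(a, b) <= levenshtein_norm(a, b) + 1e-12
        assert osa_norm(a, b) == pytest.approx(brute_force_osa(a, b) / n if (a or b) else 0.0)


class TestBestMatch:
    def test_alternative_preferred_when_closer_and_first_char_matches(self):
        target, d = best_match("BURG", "SCHLOSS", ["BURG"])
        assert (target, d) == ("BURG", 0.0)

    def test_picture_name_kept_when_entry_matches_it(self):
        target, d = best_match("SCHLOSS", "SCHLOSS", ["BURG"])
        assert (target, d) == ("SCHLOSS", 0.0)

    def test_no_alternatives_scores_against_picture_name(self):
        target, d = best_match("KESSEL", "KELLE", [])
        assert target == "KELLE"
        assert d == pytest.approx(47 / 180)

    def test_tie_resolves_to_picture_name(self):
        # alternative exactly as close as the name must not win
        target, _ = best_match("AB", "AB", ["AB"])
        assert target == "AB"
        t2, _ = best_match("ABX", "ABY", ["ABZ"])  # equal distances
        assert t2 == "ABY"

    def test_first_character_gate_excludes_alternatives(self):
        target, _ = best_match("KANNE", "KANNE", ["TASSE"])
        assert target == "KANNE"


def _entry(raw, corrected, first_key=None, n_backspaces=0, rt=800.0):
    return ReconstructedEntry(
        raw_string=raw,
        corrected_string=corrected,
        first_key=first_key or (raw[0] if raw else None),
        rt_ms=rt if (raw or first_key) else None,
        n_backspaces=n_backspaces,
    )


SCHLOSS = Stimulus(item_id="s1", name="SCHLOSS", alternatives=("BURG",))
FEILE = Stimulus(item_id="s2", name="FEILE")
KELLE = Stimulus(item_id="s3", name="KELLE")
TISCH = Stimulus(item_id="s4", name="TISCH")


class TestClassification:
    def test_backspaced_alternative_start_is_incorrect(self):
        # raw starts "B" (the alternative), corrected starts "S": first-letter
        # condition must hold before AND after correction
        entry = _entry("BURSCHLOSS", "SCHLOSS", n_backspaces=4)
        c = classify_entry(entry, SCHLOSS)
        assert c.status == "incorrect"

    def test_phonological_first_letter_slip_is_first_letter_error(self):
        c = classify_entry(_entry("PFEILE", "PFEILE"), FEILE)
        assert (c.status, c.subtype) == ("incorrect", "first_letter_error")

    def test_orthographic_neighbour_below_cutoff_is_correct(self):
        c = classify_entry(_entry("KESSEL", "KESSEL"), KELLE)
        assert c.status == "correct"
        assert c.subtype == "below_threshold"
        assert c.match_basis == "picture_name"
        assert c.d == pytest.approx(47 / 180)

    def test_exact_entry_is_correct_identical(self):
        c = classify_entry(_entry("TISCH", "TISCH"), TISCH)
        assert (c.status, c.subtype, c.d) == ("correct", "identical", 0.0)

    def test_backspace_repair_to_exact_name_is_corrected(self):
        c = classify_entry(_entry("TISSCH", "TISCH", n_backspaces=2), TISCH)
        assert (c.status, c.subtype) == ("correct", "corrected")

    def test_shift_start_reported_separately_from_special_keys(self):
        c = classify_entry(_entry("TISCH", "TISCH", first_key="SHIFT"), TISCH)
        assert (c.status, c.subtype) == ("incorrect", "shift_start")
        for key in ("SPACE", "BACKSPACE", "CAPSLOCK", "ENTER"):
            c = classify_entry(_entry("TISCH", "TISCH", first_key=key), TISCH)
            assert (c.status, c.subtype) == ("incorrect", "special_key_start")

    def test_no_keystrokes_is_na(self):
        c = classify_entry(_entry("", "", first_key=None), TISCH)
        assert (c.status, c.subtype) == ("incorrect", "na")
        assert c.d is None

    def test_far_entry_with_wrong_first_letter_is_combined(self):
        c = classify_entry(_entry("XYZQW", "XYZQW"), TISCH)
        assert (c.status, c.subtype) == ("incorrect", "combined")

    def test_far_entry_with_right_first_letter_is_distance_exceeded(self):
        c = classify_entry(_entry("TAAAAAA", "TAAAAAA"), TISCH)
        assert (c.status, c.subtype) == ("incorrect", "distance_exceeded")

    def test_fully_backspaced_entry_fails_first_letter_condition(self):
        entry = _entry("TIS", "", n_backspaces=3)
        c = classify_entry(entry, TISCH)
        assert c.status == "incorrect"

    @given(words)
    def test_raising_threshold_never_turns_correct_into_incorrect(self, typed):
        lo = classify_entry(_entry(typed, typed), TISCH, MatchConfig(threshold=0.25))
        hi = classify_entry(_entry(typed, typed), TISCH, MatchConfig(threshold=0.45))
        if lo.status == "correct":
            assert hi.status == "correct"

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            MatchConfig(threshold=0.0)
        with pytest.raises(ValueError):
            MatchConfig(distance_kind="hamming")


class TestExperimentClassification:
    def test_all_correct_batch_has_zero_incorrect(self):
        stim = [TISCH]
        logs = [
            TrialLog("p1", i, "s4", [KeyEvent(k, 500 + 100 * j) for j, k in enumerate("TISCH")])
            for i in range(10)
        ]
        df = classify_experiment(logs, stim)
        assert (df["status"] == "correct").all()
        summary = taxonomy_summary(df)
        assert "incorrect" not in summary["statuses"]
        assert summary["statuses"]["correct"]["count"] == 10

    def test_every_trial_gets_exactly_one_status_and_counts_sum(self, small_experiment):
        sim = small_experiment
        df = classify_experiment(sim["trial_logs"], sim["stimuli"])
        assert len(df) == len(sim["trial_logs"])
        assert set(df["status"].unique()) <= {"correct", "incorrect"}
        summary = taxonomy_summary(df)
        total = sum(s["count"] for s in summary["statuses"].values())
        assert total == len(df)
        for s in summary["statuses"].values():
            assert sum(v["count"] for v in s["subtypes"].values()) == s["count"]

    def test_unknown_item_id_raises_naming_the_trial(self):
        log = TrialLog("p9", 3, "nope", [KeyEvent("T", 500)])
        with pytest.raises(KeyError, match="p9/3"):
            classify_experiment([log], [TISCH])

    def test_planted_labels_recovered(self, small_experiment):
        sim = small_experiment
        df = classify_experiment(sim["trial_logs"], sim["stimuli"])
        merged = df.merge(sim["truth"], on=["participant", "trial_index", "item_id"])
        status_agreement = (merged["status"] == merged["true_status"]).mean()
        assert status_agreement >= 0.99
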