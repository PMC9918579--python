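"""Stimulus-list construction: block assignment, lag constraints, validation."""

import itertools

import numpy as np
import pytest

import csityping as ct
from csityping.stimlist import (
    DesignConfig,
    ListGenerationError,
    Stimulus,
    Trial,
    TrialList,
    assign_categories_to_blocks,
    generate_list,
    randomize_block,
    read_stimuli,
    read_trial_list,
    validate_list,
    write_stimuli,
    write_trial_list,
)

def _mini_stimuli(categories, per_cat=2, supers=None):
    out = []
    for ci, cat in enumerate(categories):
        for e in range(per_cat):
            out.append(
                Stimulus(
                    item_id=f"{cat}_{e}",
                    name=f"{cat}X{e}",
                    category=cat,
                    superordinate=(supers or {}).get(cat, f"sup_{cat}"),
                )
            )
    return out


class TestBlockAssignment:
    def test_default_design_assigns_three_categories_per_block(self, stimuli, default_config):
        assignment = assign_categories_to_blocks(stimuli, default_config)
        assert len(assignment) == 24
        counts = np.bincount(list(assignment.values()), minlength=8)
        assert (counts == 3).all()

    def test_shared_superordinate_pair_lands_in_different_blocks(self):
        supers = {"fish": "animals", "insects": "animals"}
        stim = _mini_stimuli(["fish", "insects"], per_cat=2, supers=supers)
        cfg = DesignConfig(
            n_categories=2, exemplars_per_category=2, n_fillers=2,
            n_blocks=2, categories_per_block=1, fillers_per_block=1,
        )
        assignment = assign_categories_to_blocks(stim, cfg)
        assert assignment["fish"] != assignment["insects"]

    def test_exhaustive_optimum_matches_brute_force(self):
        # 6 categories in 3 superordinate pairs over 3 blocks of 2
        cats = [f"c{i}" for i in range(6)]
        supers = {c: f"pair{i // 2}" for i, c in enumerate(cats)}
        stim = _mini_stimuli(cats, per_cat=2, supers=supers)
        cfg = DesignConfig(
            n_categories=6, exemplars_per_category=2, n_fillers=3,
            n_blocks=3, categories_per_block=2, fillers_per_block=1,
        )
        assignment = assign_categories_to_blocks(stim, cfg)

        pairs = [(a, b) for a, b in itertools.combinations(cats, 2) if supers[a] == supers[b]]

        def score(asg):
            return sum(abs(asg[a] - asg[b]) for a, b in pairs)

        best = -1  # brute force over all labeled balanced assignments
        for perm in itertools.permutations(range(6)):
            asg = {cats[perm[i]]: i // 2 for i in range(6)}
            best = max(best, score(asg))
        assert score(assignment) == best

    def test_category_count_mismatch_raises(self, stimuli):
        cfg = DesignConfig(
            n_categories=12, n_blocks=4, categories_per_block=3,
            n_fillers=40, fillers_per_block=10,
        )
        with pytest.raises(ValueError, match="12 categories"):
            assign_categories_to_blocks(stimuli, cfg)


class TestRandomization:
    def test_block_order_has_right_length_and_valid_lags(self, stimuli, default_config, rng):
        assignment = assign_categories_to_blocks(stimuli, default_config, rng)
        block0 = [s for s in stimuli if not s.is_filler and assignment[s.category] == 0]
        fillers = [s for s in stimuli if s.is_filler][:5]
        order = randomize_block(block0 + fillers, default_config, rng)
        assert len(order) == 20
        assert sorted(s.item_id for s in order) == sorted(
            s.item_id for s in block0 + fillers
        )
        last = {}
        for i, s in enumerate(order):
            if s.is_filler:
                continue
            if s.category in last:
                lag = i - last[s.category] - 1
                assert 2 <= lag <= 8
            last[s.category] = i

    def test_unsatisfiable_constraints_raise_named_error(self, rng):
        # two items of one category cannot be separated by >= 2 in a 2-item block
        stim = _mini_stimuli(["only"], per_cat=2)
        cfg = DesignConfig(
            n_categories=1, exemplars_per_category=2, n_fillers=0,
            n_blocks=1, categories_per_block=1, fillers_per_block=0,
            lag_min=2, lag_max=8,
        )
        with pytest.raises(ListGenerationError, match="lag"):
            randomize_block(stim, cfg, rng)

    def test_generated_lists_always_validate(self, stimuli, default_config):
        # generator/validator agreement across seeds
        for seed in range(12):
            tl = generate_list(stimuli, default_config, seed=seed)
            report = validate_list(tl)
            assert report.passed, report.violations

    def test_same_seed_reproduces_identical_list(self, stimuli, default_config):
        a = generate_list(stimuli, default_config, seed=99)
        b = generate_list(stimuli, default_config, seed=99)
        assert [t.stimulus.item_id for t in a.trials] == [
            t.stimulus.item_id for t in b.trials
        ]

    def test_list_is_permutation_with_full_ordinal_sets(self, trial_list, stimuli):
        assert len(trial_list) == 160
        assert sorted(t.stimulus.item_id for t in trial_list.trials) == sorted(
            s.item_id for s in stimuli
        )
        per_cat = {}
        for t in trial_list.trials:
            if not t.stimulus.is_filler:
                per_cat.setdefault(t.stimulus.category, []).append(t.ordinal_position)
        assert all(sorted(v) == [1, 2, 3, 4, 5] for v in per_cat.values())
        for b in range(8):
            assert sum(t.block == b for t in trial_list.trials) == 20


class TestValidation:
    def test_handcrafted_excess_lag_is_reported(self, default_config):
        cfg = DesignConfig(
            n_categories=1, exemplars_per_category=2, n_fillers=10,
            n_blocks=1, categories_per_block=1, fillers_per_block=10,
        )
        stim = _mini_stimuli(["a"], per_cat=2)
        fillers = [
            Stimulus(item_id=f"f{i}", name=f"FIL{i}", is_filler=True) for i in range(10)
        ]
        # category members at positions 0 and 10: lag 9 > 8
        order = [stim[0]] + fillers[:9] + [stim[1]] + fillers[9:]
        trials = [
            Trial(i, s, 0, (1 if s is stim[0] else 2) if not s.is_filler else None)
            for i, s in enumerate(order)
        ]
        report = validate_list(TrialList(trials, cfg))
        assert not report.passed
        assert any("lag_max" in v for v in report.violations)

    def test_category_split_across_blocks_is_reported(self):
        cfg = DesignConfig(
            n_categories=2, exemplars_per_category=2, n_fillers=2,
            n_blocks=2, categories_per_block=1, fillers_per_block=1,
            lag_min=1,
        )
        a = _mini_stimuli(["a"], per_cat=2)
        b = _mini_stimuli(["b"], per_cat=2)
        f = [Stimulus(item_id=f"f{i}", name=f"FIL{i}", is_filler=True) for i in range(2)]
        order = [a[0], b[0], f[0], a[1], b[1], f[1]]
        blocks = [0, 0, 0, 1, 1, 1]
        ords = [1, 1, None, 2, 2, None]
        trials = [Trial(i, s, blocks[i], ords[i]) for i, s in enumerate(order)]
        report = validate_list(TrialList(trials, cfg))
        assert any("block_composition" in v for v in report.violations)


class TestConfigAndIO:
    def test_inconsistent_design_rejected(self):
        with pytest.raises(ValueError):
            DesignConfig(n_categories=23)
        with pytest.raises(ValueError):
            DesignConfig(lag_min=0)
        with pytest.raises(ValueError):
            DesignConfig(lag_min=5, lag_max=4)

    def test_stimulus_and_list_csv_round_trip(self, tmp_path, stimuli, default_config):
        spath = tmp_path / "stimuli.csv"
        write_stimuli(stimuli, spath)
        back = read_stimuli(spath)
        assert [s.item_id for s in back] == [s.item_id for s in stimuli]
        assert [s.alternatives for s in back] == [s.alternatives for s in stimuli]

        tl = generate_list(stimuli, default_config, seed=3)
        lpath = tmp_path / "list.csv"
        write_trial_list(tl, lpath, participant="p01")
        back_tl = read_trial_list(lpath, stimuli, default_config)
        assert [t.stimulus.item_id for t in back_tl.trials] == [
            t.stimulus.item_id for t in tl.trials
        ]
        assert validate_list(back_tl, default_config).passed
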