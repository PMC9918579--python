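"""Experimental list construction for continuous-naming (CSI) designs.

A CSI experiment presents five exemplars of each semantic category embedded
in a seemingly unrelated picture sequence.  Lists are built in three steps:

1. categories are assigned to blocks such that categories sharing a
   superordinate category (e.g. *fish* and *insects*: animals) land as far
   apart as possible,
2. each block (targets of its categories plus fillers) is shuffled under
   lag constraints — consecutive members of the same category must be
   separated by at least ``lag_min`` and at most ``lag_max`` intervening
   items,
3. the resulting list is validated (block composition, lags, ordinal
   positions).

Ordinal position — the within-category occurrence rank 1..5 — is the
predictor of interest in the downstream latency models.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Stimulus",
    "DesignConfig",
    "Trial",
    "TrialList",
    "ValidationReport",
    "ListGenerationError",
    "assign_categories_to_blocks",
    "randomize_block",
    "generate_list",
    "validate_list",
    "read_stimuli",
    "write_stimuli",
    "write_trial_list",
    "read_trial_list",
]


class ListGenerationError(RuntimeError):
    """Raised when a valid list cannot be produced under the constraints."""


@dataclass(frozen=True)
class Stimulus:
    """One picture item.

    ``name`` and ``alternatives`` are stored upper-case (participants type in
    capitals; comparisons are case-insensitive by construction).  Fillers
    carry no category and are exempt from lag constraints.
    """

    item_id: str
    name: str
    alternatives: tuple[str, ...] = ()
    category: str | None = None
    superordinate: str | None = None
    is_filler: bool = False

    def __post_init__(self):
        if not self.name:
            raise ValueError("stimulus name must be non-empty")
        object.__setattr__(self, "name", self.name.upper())
        object.__setattr__(
            self, "alternatives", tuple(a.upper() for a in self.alternatives if a)
        )
        if self.is_filler:
            object.__setattr__(self, "category", None)


@dataclass(frozen=True)
class DesignConfig:
    """Design constants of the experiment.

    Defaults reproduce the standard layout: 24 target categories of five
    exemplars distributed over eight blocks of three categories, five fillers
    per block (20 items per block, 160 trials), within-category lags between
    2 and 8 intervening items.
    """

    n_categories: int = 24
    exemplars_per_category: int = 5
    n_fillers: int = 40
    n_blocks: int = 8
    categories_per_block: int = 3
    fillers_per_block: int = 5
    lag_min: int = 2
    lag_max: int = 8
    seed: int = 0
    max_retries: int = 10_000

    def __post_init__(self):
        if self.n_categories != self.n_blocks * self.categories_per_block:
            raise ValueError(
                "n_categories must equal n_blocks * categories_per_block "
                f"({self.n_categories} != {self.n_blocks}*{self.categories_per_block})"
            )
        if self.n_fillers != self.n_blocks * self.fillers_per_block:
            raise ValueError("n_fillers must equal n_blocks * fillers_per_block")
        if self.lag_min < 1:
            raise ValueError("lag_min must be >= 1")
        if self.lag_max < self.lag_min:
            raise ValueError("lag_max must be >= lag_min")

    @property
    def n_trials(self) -> int:
        return self.n_categories * self.exemplars_per_category + self.n_fillers

    @property
    def block_size(self) -> int:
        return (
            self.categories_per_block * self.exemplars_per_category
            + self.fillers_per_block
        )


@dataclass(frozen=True)
class Trial:
    position: int  # 0-based index within the whole list
    stimulus: Stimulus
    block: int  # 0-based block index
    ordinal_position: int | None  # 1-based within-category rank; None for fillers


@dataclass
class TrialList:
    trials: list[Trial]
    config: DesignConfig
    list_id: str = "list"
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": [t.position + 1 for t in self.trials],
                "block": [t.block + 1 for t in self.trials],
                "item_id": [t.stimulus.item_id for t in self.trials],
                "name": [t.stimulus.name for t in self.trials],
                "category": [t.stimulus.category for t in self.trials],
                "ordinal_position": [t.ordinal_position for t in self.trials],
                "is_filler": [t.stimulus.is_filler for t in self.trials],
            }
        )


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthiness == validity
        return self.passed


# ---------------------------------------------------------------------------
# block assignment


def _separation_score(assignment: dict[str, int], supers: dict[str, str]) -> int:
    """Sum of |block distance| over pairs of same-superordinate categories."""
    score = 0
    cats = list(assignment)
    for a, b in itertools.combinations(cats, 2):
        if supers.get(a) is not None and supers.get(a) == supers.get(b):
            score += abs(assignment[a] - assignment[b])
    return score


def _n_assignments(n_categories: int, n_blocks: int, per_block: int) -> float:
    return math.factorial(n_categories) / math.factorial(per_block) ** n_blocks


def assign_categories_to_blocks(
    stimuli: list[Stimulus],
    config: DesignConfig,
    rng: np.random.Generator | None = None,
    exhaustive_limit: int = 200_000,
    n_restarts: int = 40,
) -> dict[str, int]:
    """Assign categories to blocks, spreading same-superordinate categories.

    Maximizes the summed pairwise block distance between categories that share
    a superordinate.  Exhaustive search when the number of distinct
    assignments is small; otherwise seeded random restarts with pairwise-swap
    hill climbing.
    """
    targets = [s for s in stimuli if not s.is_filler]
    categories = sorted({s.category for s in targets})
    if len(categories) != config.n_categories:
        raise ValueError(
            f"expected {config.n_categories} categories, found {len(categories)}"
        )
    counts = pd.Series([s.category for s in targets]).value_counts()
    bad = counts[counts != config.exemplars_per_category]
    if len(bad):
        raise ValueError(
            f"categories without exactly {config.exemplars_per_category} "
            f"exemplars: {sorted(bad.index)}"
        )
    supers = {s.category: s.superordinate for s in targets}
    if rng is None:
        rng = np.random.default_rng(config.seed)

    k, B = config.categories_per_block, config.n_blocks

    if _n_assignments(len(categories), B, k) <= exhaustive_limit:
        best, best_score = None, -1

        def recurse(remaining: tuple[str, ...], blocks: list[tuple[str, ...]]):
            nonlocal best, best_score
            if not remaining:
                assignment = {
                    c: b for b, cats in enumerate(blocks) for c in cats
                }
                score = _separation_score(assignment, supers)
                if score > best_score:
                    best, best_score = assignment, score
                return
            # fix the first remaining category into the next block slot to
            # avoid counting permutations within a block
            first, rest = remaining[0], remaining[1:]
            b = len([bl for bl in blocks if len(bl) == k])
            open_blocks = [i for i, bl in enumerate(blocks) if len(bl) < k]
            for i in open_blocks:
                recurse(
                    rest,
                    [bl + (first,) if j == i else bl for j, bl in enumerate(blocks)],
                )

        recurse(tuple(categories), [() for _ in range(B)])
        return best

    # random restarts + swap hill climbing (incremental score updates)
    nc = len(categories)
    partners: list[list[int]] = [[] for _ in range(nc)]
    for i, j in itertools.combinations(range(nc), 2):
        si, sj = supers.get(categories[i]), supers.get(categories[j])
        if si is not None and si == sj:
            partners[i].append(j)
            partners[j].append(i)

    def score_of(blocks: np.ndarray) -> int:
        return sum(
            abs(int(blocks[i]) - int(blocks[j]))
            for i in range(nc)
            for j in partners[i]
            if j > i
        )

    def contribution(i: int, blocks: np.ndarray) -> int:
        return sum(abs(int(blocks[i]) - int(blocks[j])) for j in partners[i])

    best_blocks, best_score = None, -1
    for _ in range(n_restarts):
        blocks = np.repeat(np.arange(B), k)[rng.permutation(nc)]
        score = score_of(blocks)
        improved = True
        while improved:
            improved = False
            for i, j in itertools.combinations(range(nc), 2):
                if blocks[i] == blocks[j]:
                    continue
                before = contribution(i, blocks) + contribution(j, blocks)
                blocks[i], blocks[j] = blocks[j], blocks[i]
                # a shared (i,j) pair is double-counted on both sides but is
                # invariant under the swap, so the delta stays exact
                after = contribution(i, blocks) + contribution(j, blocks)
                if after > before:
                    score += after - before
                    improved = True
                else:
                    blocks[i], blocks[j] = blocks[j], blocks[i]
        if score > best_score:
            best_blocks, best_score = blocks.copy(), score
    return {categories[i]: int(best_blocks[i]) for i in range(nc)}


# ---------------------------------------------------------------------------
# block randomization


def _lag_violation(order: list[Stimulus], lag_min: int, lag_max: int) -> str | None:
    last_pos: dict[str, int] = {}
    for i, s in enumerate(order):
        if s.is_filler:
            continue
        if s.category in last_pos:
            lag = i - last_pos[s.category] - 1
            if lag < lag_min:
                return f"lag_min: category {s.category} lag {lag} < {lag_min}"
            if lag > lag_max:
                return f"lag_max: category {s.category} lag {lag} > {lag_max}"
        last_pos[s.category] = i
    return None


def randomize_block(
    block_stimuli: list[Stimulus],
    config: DesignConfig,
    rng: np.random.Generator,
) -> list[Stimulus]:
    """Produce a random block order satisfying the lag constraints.

    Seeded randomized backtracking over category slots: positions are
    filled left to right with a randomly ordered choice among the symbols
    (categories/fillers) still admissible there, backtracking on dead ends.
    Plain rejection sampling is hopeless here — at the default composition
    (three categories of five plus five fillers in 20 slots) fewer than one
    random shuffle in ~10^5 satisfies all pairwise lag windows.  The node
    budget is ``config.max_retries``; exhausting it raises
    :class:`ListGenerationError` naming the binding constraint.
    """
    n_targets = config.categories_per_block * config.exemplars_per_category
    targets = [s for s in block_stimuli if not s.is_filler]
    fillers = [s for s in block_stimuli if s.is_filler]
    if len(targets) != n_targets or len(fillers) != config.fillers_per_block:
        raise ValueError(
            f"block must contain {n_targets} targets and "
            f"{config.fillers_per_block} fillers; got {len(targets)}/{len(fillers)}"
        )

    by_cat: dict[str, list[Stimulus]] = {}
    for s in targets:
        by_cat.setdefault(s.category, []).append(s)
    symbols = sorted(by_cat) + ["__filler__"]
    remaining = {c: len(by_cat[c]) for c in by_cat}
    remaining["__filler__"] = len(fillers)
    n = len(block_stimuli)
    lag_lo, lag_hi = config.lag_min, config.lag_max

    budget = config.max_retries
    nodes = 0
    sequence: list[str] = []
    last_pos: dict[str, int] = {}

    def feasible_next(pos: int) -> list[str]:
        # any pending category past its lag_max deadline makes pos a dead end
        opts = []
        for sym in symbols:
            if remaining[sym] == 0:
                continue
            if sym != "__filler__" and sym in last_pos:
                lag = pos - last_pos[sym] - 1
                if lag < lag_lo:
                    continue
                if lag > lag_hi:
                    return []  # overdue category: prune the whole branch
            opts.append(sym)
        return opts

    def search(pos: int) -> bool:
        nonlocal nodes
        if pos == n:
            return True
        nodes += 1
        if nodes > budget:
            return False
        opts = feasible_next(pos)
        for i in rng.permutation(len(opts)):
            sym = opts[i]
            prev = last_pos.get(sym)
            remaining[sym] -= 1
            if sym != "__filler__":
                last_pos[sym] = pos
            sequence.append(sym)
            if search(pos + 1):
                return True
            sequence.pop()
            remaining[sym] += 1
            if sym != "__filler__":
                if prev is None:
                    del last_pos[sym]
                else:
                    last_pos[sym] = prev
        return False

    if not search(0):
        reason = (
            "node budget exhausted"
            if nodes > budget
            else f"lag_min={lag_lo}/lag_max={lag_hi} unsatisfiable for this composition"
        )
        raise ListGenerationError(
            f"no valid block order within {budget} search nodes; {reason}"
        )

    # map category slots to concrete exemplars in random order
    pools = {c: [by_cat[c][i] for i in rng.permutation(len(by_cat[c]))] for c in by_cat}
    pools["__filler__"] = [fillers[i] for i in rng.permutation(len(fillers))]
    order = [pools[sym].pop() for sym in sequence]
    assert _lag_violation(order, lag_lo, lag_hi) is None
    return order


def generate_list(
    stimuli: list[Stimulus],
    config: DesignConfig,
    seed: int | None = None,
    list_id: str = "list",
) -> TrialList:
    """Build a full randomized trial list (assignment + per-block shuffles)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    assignment = assign_categories_to_blocks(stimuli, config, rng)
    fillers = [s for s in stimuli if s.is_filler]
    if len(fillers) != config.n_fillers:
        raise ValueError(f"expected {config.n_fillers} fillers, got {len(fillers)}")
    fillers = [fillers[i] for i in rng.permutation(len(fillers))]

    trials: list[Trial] = []
    seen: dict[str, int] = {}
    pos = 0
    for b in range(config.n_blocks):
        block_targets = [
            s
            for s in stimuli
            if not s.is_filler and assignment[s.category] == b
        ]
        block_fillers = fillers[
            b * config.fillers_per_block : (b + 1) * config.fillers_per_block
        ]
        order = randomize_block(block_targets + block_fillers, config, rng)
        for s in order:
            ordinal = None
            if not s.is_filler:
                seen[s.category] = seen.get(s.category, 0) + 1
                ordinal = seen[s.category]
            trials.append(Trial(pos, s, b, ordinal))
            pos += 1
    return TrialList(trials, config, list_id=list_id, seed=seed)


# ---------------------------------------------------------------------------
# validation


def validate_list(trial_list: TrialList, config: DesignConfig | None = None) -> ValidationReport:
    """Check block composition, lag constraints and ordinal positions.

    Returns a report object; never raises on content.
    """
    cfg = config or trial_list.config
    report = ValidationReport()
    trials = trial_list.trials

    if len(trials) != cfg.n_trials:
        report.violations.append(
            f"length: expected {cfg.n_trials} trials, got {len(trials)}"
        )

    # block composition: each category wholly inside one block, counts right
    cat_blocks: dict[str, set[int]] = {}
    for t in trials:
        if not t.stimulus.is_filler:
            cat_blocks.setdefault(t.stimulus.category, set()).add(t.block)
    for cat, blocks in sorted(cat_blocks.items()):
        if len(blocks) > 1:
            report.violations.append(
                f"block_composition: category {cat} spans blocks {sorted(blocks)}"
            )
    for b in range(cfg.n_blocks):
        block = [t for t in trials if t.block == b]
        n_t = sum(not t.stimulus.is_filler for t in block)
        n_f = sum(t.stimulus.is_filler for t in block)
        if n_t != cfg.categories_per_block * cfg.exemplars_per_category:
            report.violations.append(f"block_composition: block {b} has {n_t} targets")
        if n_f != cfg.fillers_per_block:
            report.violations.append(f"block_composition: block {b} has {n_f} fillers")

    # lag constraints across the whole list
    last_pos: dict[str, int] = {}
    rank: dict[str, int] = {}
    for t in trials:
        s = t.stimulus
        if s.is_filler:
            if t.ordinal_position is not None:
                report.violations.append(
                    f"ordinal: filler {s.item_id} has an ordinal position"
                )
            continue
        if s.category in last_pos:
            lag = t.position - last_pos[s.category] - 1
            if lag < cfg.lag_min:
                report.violations.append(
                    f"lag_min: category {s.category} lag {lag} < {cfg.lag_min} "
                    f"at position {t.position}"
                )
            elif lag > cfg.lag_max:
                report.violations.append(
                    f"lag_max: category {s.category} lag {lag} > {cfg.lag_max} "
                    f"at position {t.position}"
                )
        last_pos[s.category] = t.position
        rank[s.category] = rank.get(s.category, 0) + 1
        if t.ordinal_position != rank[s.category]:
            report.violations.append(
                f"ordinal: category {s.category} position {t.position} has "
                f"ordinal {t.ordinal_position}, expected {rank[s.category]}"
            )
    return report


def category_lags(trial_list: TrialList) -> list[int]:
    """Intervening-item counts between consecutive same-category members."""
    last_pos: dict[str, int] = {}
    lags: list[int] = []
    for t in trial_list.trials:
        s = t.stimulus
        if s.is_filler:
            continue
        if s.category in last_pos:
            lags.append(t.position - last_pos[s.category] - 1)
        last_pos[s.category] = t.position
    return lags


# ---------------------------------------------------------------------------
# CSV interfaces


def read_stimuli(path) -> list[Stimulus]:
    """Read a stimulus table.

    Columns: item_id, name, alternatives (semicolon-separated), category,
    superordinate, is_filler.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        is_filler = str(row.is_filler).strip().lower() in {"1", "true", "yes"}
        alts = tuple(a for a in str(row.alternatives).split(";") if a)
        out.append(
            Stimulus(
                item_id=row.item_id,
                name=row.name,
                alternatives=alts,
                category=(row.category or None) if not is_filler else None,
                superordinate=row.superordinate or None,
                is_filler=is_filler,
            )
        )
    return out


def write_stimuli(stimuli: list[Stimulus], path) -> None:
    pd.DataFrame(
        {
            "item_id": [s.item_id for s in stimuli],
            "name": [s.name for s in stimuli],
            "alternatives": [";".join(s.alternatives) for s in stimuli],
            "category": [s.category or "" for s in stimuli],
            "superordinate": [s.superordinate or "" for s in stimuli],
            "is_filler": [s.is_filler for s in stimuli],
        }
    ).to_csv(path, index=False)


def write_trial_list(trial_list: TrialList, path, participant: str = "") -> None:
    df = trial_list.to_frame()
    df.insert(0, "list_id", trial_list.list_id)
    df.insert(0, "participant", participant)
    df.to_csv(path, index=False)


def read_trial_list(path, stimuli: list[Stimulus], config: DesignConfig) -> TrialList:
    df = pd.read_csv(path)
    by_id = {s.item_id: s for s in stimuli}
    trials = []
    for row in df.itertuples(index=False):
        s = by_id[str(row.item_id)]
        ordinal = None if pd.isna(row.ordinal_position) else int(row.ordinal_position)
        trials.append(Trial(int(row.trial_index) - 1, s, int(row.block) - 1, ordinal))
    list_id = str(df["list_id"].iloc[0]) if "list_id" in df else "list"
    return TrialList(trials, config, list_id=list_id)
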