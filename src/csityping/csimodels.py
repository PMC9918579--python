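"""Trial exclusion and mixed-model analysis of the CSI effect.

The latency analysis keeps correct non-filler trials and regresses the
first-keystroke latency on mean-centred ordinal position in a gamma GLMM
with identity link and crossed random intercepts and slopes for
participants and categories.  The error analysis keeps all non-filler
trials and fits a binomial-logit GLMM on the raw ordinal position, with the
convergence ladder used in practice when such models fail: raise the
iteration cap, zero the random-effect correlations, then drop slopes
(participant slope first, then category slope).  A linear mixed model on
log latency with the same structure serves as the refit engine for power
simulation.  All inference is Wald (estimate ± 1.96·SE, Z test).

Condition means for plotting come with Morey-adjusted within-subject
standard errors: observations are normalized by subtracting the subject
mean and adding the grand mean, and the per-condition variance is inflated
by K/(K−1) for K conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import (
    BINOMIAL_LOGIT,
    GAMMA_IDENTITY,
    GAUSSIAN_IDENTITY,
    GLMMFit,
    RandomTerm,
    fit_glmm,
)

__all__ = [
    "exclude_trials",
    "fit_rt_model",
    "fit_error_model",
    "fit_log_lmm",
    "within_subject_summary",
    "assemble_trial_table",
]

FitResult = GLMMFit  # public alias: fixed effects + Wald inference + trace

TRIAL_COLUMNS = (
    "participant",
    "category",
    "ordinal_position",
    "rt_ms",
    "correct",
    "is_filler",
)


# ---------------------------------------------------------------------------
# assembly and exclusion


def assemble_trial_table(
    lists: dict[str, "TrialList"],
    classified: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-participant trial lists with classification output.

    ``classified`` is the frame from :func:`csityping.match.classify_experiment`
    (one row per trial with ``correct`` and ``rt_ms``).  Returns the analysis
    table with the columns in ``TRIAL_COLUMNS``.
    """
    list_rows = []
    for pid, tl in lists.items():
        df = tl.to_frame()
        df.insert(0, "participant", pid)
        list_rows.append(
            df[["participant", "trial_index", "item_id", "category",
                "ordinal_position", "is_filler", "block"]]
        )
    design = pd.concat(list_rows, ignore_index=True)
    merged = design.merge(
        classified[["participant", "trial_index", "item_id", "correct", "rt_ms"]],
        on=["participant", "trial_index", "item_id"],
        how="left",
        validate="one_to_one",
    )
    if merged["correct"].isna().any():
        missing = merged.loc[merged["correct"].isna(),
                             ["participant", "trial_index"]].head()
        raise ValueError(f"trials without classification, e.g.\n{missing}")
    return merged


def exclude_trials(
    table: pd.DataFrame,
    classifications: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply the exclusion scheme and account for every trial.

    Returns ``(rt_table, error_table, accounting)``: the latency table keeps
    correct non-filler trials; the error table keeps all non-filler trials
    with their correctness flag.  The accounting dict satisfies
    ``n_retained = n_total - n_filler - n_erroneous + n_erroneous_fillers``
    (erroneous fillers would otherwise be subtracted twice).

    ``classifications`` (a frame with participant/trial_index/correct, as
    produced by ``classify_experiment``) overrides/provides the ``correct``
    column; if omitted the table must already carry one.
    """
    df = table.copy()
    if classifications is not None:
        df = df.drop(columns=[c for c in ("correct",) if c in df]).merge(
            classifications[["participant", "trial_index", "correct"]],
            on=["participant", "trial_index"],
            how="left",
            validate="one_to_one",
        )
    if "correct" not in df or df["correct"].isna().any():
        bad = df.loc[df.get("correct").isna() if "correct" in df else slice(None),
                     ["participant", "trial_index"]].head() if "correct" in df else None
        raise ValueError(f"trials missing classification, e.g.\n{bad}")
    df["correct"] = df["correct"].astype(bool)
    df["is_filler"] = df["is_filler"].astype(bool)

    n_total = len(df)
    n_filler = int(df["is_filler"].sum())
    n_err = int((~df["correct"]).sum())
    n_err_fill = int((~df["correct"] & df["is_filler"]).sum())
    rt_table = df[~df["is_filler"] & df["correct"]].copy()
    error_table = df[~df["is_filler"]].copy()
    accounting = {
        "n_total": n_total,
        "n_filler": n_filler,
        "n_erroneous": n_err,
        "n_erroneous_fillers": n_err_fill,
        "n_retained": len(rt_table),
    }
    assert accounting["n_retained"] == n_total - n_filler - n_err + n_err_fill
    return rt_table, error_table, accounting


# ---------------------------------------------------------------------------
# model fitting


def _design(table, response_col, center):
    df = table.dropna(subset=[response_col, "ordinal_position"])
    pos = df["ordinal_position"].to_numpy(dtype=float)
    offset = pos.mean() if center else 0.0
    x = pos - offset
    X = np.column_stack([np.ones(len(df)), x])
    subj = pd.Categorical(df["participant"])
    cat = pd.Categorical(df["category"])
    return df, X, x, subj, cat


def _terms(X, x, subj, cat, structure):
    """Random-effect terms for a named structure of the reduction ladder."""
    n = len(x)
    ones = np.ones(n)
    full = np.column_stack([ones, x])
    names2 = ("intercept", "ordinal_position")

    def term(name, codes, both, correlated):
        codes_arr = codes.codes
        design = full if both else ones[:, None]
        cols = names2 if both else ("intercept",)
        return RandomTerm(
            name,
            codes_arr,
            len(codes.categories),
            design,
            correlated=correlated,
            column_names=cols,
        )

    if structure == "full":
        return [term("participant", subj, True, True), term("category", cat, True, True)]
    if structure == "diagonal":
        return [term("participant", subj, True, False), term("category", cat, True, False)]
    if structure == "no_subject_slope":
        return [term("participant", subj, False, False), term("category", cat, True, False)]
    if structure == "no_category_slope":
        return [term("participant", subj, True, False), term("category", cat, False, False)]
    if structure == "intercepts_only":
        return [term("participant", subj, False, False), term("category", cat, False, False)]
    raise ValueError(f"unknown structure {structure!r}")


_LADDER = (
    ("full", 20_000),
    ("full", 200_000),  # raise the optimizer iteration cap first
    ("diagonal", 200_000),
    ("no_subject_slope", 200_000),
    ("no_category_slope", 200_000),
    ("intercepts_only", 200_000),
)


def _fit_with_ladder(y, X, x, subj, cat, family, structure, ladder, maxiter,
                     se_method="conditional"):
    trace: list[str] = []
    attempts = (
        [(structure, maxiter)]
        if not ladder
        else [s for s in _LADDER if _LADDER.index(s) >= [i for i, (nm, _) in enumerate(_LADDER) if nm == structure][0]]
    )
    last = None
    for struct, cap in attempts:
        label = f"{struct} (maxiter={cap})"
        trace.append(label)
        try:
            fit = fit_glmm(
                y,
                X,
                _terms(X, x, subj, cat, struct),
                family=family,
                fixef_names=("intercept", "ordinal_position"),
                maxiter=cap,
                structure_label=struct,
                se_method=se_method,
            )
        except RuntimeError as exc:
            last = None
            trace[-1] += f" -> error: {exc}"
            continue
        fit.reduction_trace = list(trace)
        if fit.converged and np.isfinite(fit.fixef["se"]).all():
            return fit
        trace[-1] += f" -> not converged ({fit.message})"
        last = fit
    if last is None:
        raise RuntimeError(
            "model failed at every rung of the reduction ladder: " + "; ".join(trace)
        )
    last.reduction_trace = list(trace)
    return last


def fit_rt_model(
    table: pd.DataFrame,
    structure: str = "full",
    ladder: bool = True,
    center: bool = True,
    maxiter: int = 20_000,
    se_method: str = "full",
) -> GLMMFit:
    """Gamma-identity GLMM: rt_ms ~ ordinal position (+ crossed REs).

    ``table`` is the retained latency table (correct, non-filler trials).
    Ordinal position is mean-centred on the analysed rows.  On
    non-convergence and with ``ladder=True`` the random structure is reduced
    step by step; the attempts are recorded in ``reduction_trace``.

    Standard errors default to the full-likelihood Wald covariance (the
    numerical Hessian over fixed effects, covariance parameters and shape),
    which propagates covariance-parameter uncertainty; ``se_method=
    "conditional"`` gives the cheaper profiled-information SEs instead.
    """
    df, X, x, subj, cat = _design(table, "rt_ms", center)
    y = df["rt_ms"].to_numpy(dtype=float)
    if len(df) == 0:
        raise ValueError("empty latency table")
    if np.any(y <= 0):
        raise ValueError("latencies must be positive")
    return _fit_with_ladder(
        y, X, x, subj, cat, GAMMA_IDENTITY, structure, ladder, maxiter,
        se_method=se_method,
    )


def fit_error_model(
    table: pd.DataFrame,
    structure: str = "diagonal",
    ladder: bool = True,
    center: bool = False,
    maxiter: int = 20_000,
) -> GLMMFit:
    """Binomial-logit GLMM: error ~ ordinal position (+ crossed REs).

    ``table`` is the non-filler error table; the response is 1 for an
    erroneous trial.  Ordinal position enters uncentred by default (the
    intercept then refers to position 0), matching the reported error
    models.  Default structure zeroes the random-effect correlations (the
    ``||`` formula); the ladder continues by dropping slopes.
    """
    df, X, x, subj, cat = _design(table, "correct", center)
    y = (~df["correct"].astype(bool)).to_numpy(dtype=float)
    return _fit_with_ladder(y, X, x, subj, cat, BINOMIAL_LOGIT, structure, ladder, maxiter)


def fit_log_lmm(
    table: pd.DataFrame,
    structure: str = "full",
    ladder: bool = True,
    center: bool = True,
    maxiter: int = 20_000,
) -> GLMMFit:
    """Linear mixed model on log latency, same fixed/random structure.

    The fallback engine for power simulation, where refitting the gamma
    GLMM hundreds of times is impractical.
    """
    df, X, x, subj, cat = _design(table, "rt_ms", center)
    y = df["rt_ms"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("latencies must be positive")
    logy = np.log(y)
    if np.var(logy) == 0:
        raise ValueError("constant latencies: zero residual variance")
    return _fit_with_ladder(logy, X, x, subj, cat, GAUSSIAN_IDENTITY, structure, ladder, maxiter)


# ---------------------------------------------------------------------------
# within-subject summaries


def within_subject_summary(
    table: pd.DataFrame,
    value: str = "rt_ms",
    unit: str = "participant",
    condition: str = "ordinal_position",
) -> pd.DataFrame:
    """Condition means with Morey-adjusted within-subject standard errors.

    Each observation is normalized by subtracting its subject's mean and
    adding the grand mean; the per-condition standard error of the
    normalized values is multiplied by sqrt(K/(K-1)) for K conditions.
    For balanced data the reported means equal the raw condition means.
    """
    df = table.dropna(subset=[value, condition]).copy()
    subjects = df[unit].unique()
    if len(subjects) < 2:
        raise ValueError("within-subject SE undefined for a single subject")
    conditions = df[condition].unique()
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    grand = df[value].mean()
    subj_means = df.groupby(unit)[value].transform("mean")
    df["_norm"] = df[value] - subj_means + grand
    k = len(conditions)
    morey = np.sqrt(k / (k - 1.0))

    def se(v):
        return v.std(ddof=1) / np.sqrt(len(v)) * morey

    out = (
        df.groupby(condition)
        .agg(mean=(value, "mean"), se_within=("_norm", se), n=(value, "size"))
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# deposited-data reproduction

def reproduce_deposited_analysis(data_dir) -> dict:
    """Recompute the headline numbers from a deposited raw-data directory.

    Expects ``events.jsonl`` (keystroke log dialect), ``stimuli.csv`` and
    ``lists/<participant>.csv`` trial lists under ``data_dir``, plus
    optionally ``manual_labels.csv`` (participant, trial_index, correct) for
    the manual/automatic agreement correlation.  Returns classification
    counts, the retained-trial count and the fitted ordinal-position slope.
    """
    import os

    from . import keylog as _keylog
    from .match import MatchConfig, classify_experiment
    from .stimlist import DesignConfig, read_stimuli, read_trial_list

    stimuli = read_stimuli(os.path.join(data_dir, "stimuli.csv"))
    logs, _ = _keylog.parse_keylog(os.path.join(data_dir, "events.jsonl"))
    classified = classify_experiment(logs, stimuli, MatchConfig())
    cfg = DesignConfig()
    lists = {}
    list_dir = os.path.join(data_dir, "lists")
    for fn in sorted(os.listdir(list_dir)):
        pid = os.path.splitext(fn)[0]
        lists[pid] = read_trial_list(os.path.join(list_dir, fn), stimuli, cfg)
    table = assemble_trial_table(lists, classified)
    rt_table, err_table, accounting = exclude_trials(table)
    fit = fit_rt_model(rt_table)
    out = {
        "n_correct": int(classified["correct"].sum()),
        "n_incorrect": int((~classified["correct"]).sum()),
        "mean_pct_incorrect_per_participant": float(
            classified.groupby("participant")["correct"]
            .apply(lambda s: 100.0 * (1 - s.mean()))
            .mean()
        ),
        "accounting": accounting,
        "slope_ms_per_position": fit.fixef.loc["ordinal_position", "estimate"],
    }
    manual_path = os.path.join(data_dir, "manual_labels.csv")
    if os.path.exists(manual_path):
        manual = pd.read_csv(manual_path)
        merged = classified.merge(
            manual, on=["participant", "trial_index"], suffixes=("", "_manual")
        )
        out["agreement_r"] = float(
            np.corrcoef(
                merged["correct"].astype(float),
                merged["correct_manual"].astype(float),
            )[0, 1]
        )
    return out
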