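# Methods

`csityping` implements the full computational workflow of a web-based typed
picture-naming experiment on cumulative semantic interference (CSI): list
construction, keystroke-log processing, automated response classification,
mixed-model analysis and simulation-based power estimation.  This note
documents the models, conventions and numerical choices, and what the
synthetic-data machinery does and does not establish about real data.

## The experimental design

A continuous-naming CSI experiment presents five exemplars of each of 24
semantic categories inside a seemingly unrelated picture sequence, plus 40
filler items, for 160 trials in eight blocks of 20 (three categories and
five fillers per block).  The predictor of interest is *ordinal position*
(1–5), a category member's within-category occurrence rank; naming latency
is expected to grow roughly linearly with it.

**Block assignment.** Categories sharing a superordinate (e.g. *fish* and
*insects* under *animals*) should sit in blocks as far apart as possible.
"As far apart as possible" is formalized here as maximizing the summed
pairwise |block-index difference| over same-superordinate category pairs —
an explicit objective chosen by this package, since verbal descriptions of
pseudorandomization do not pin one down.  The optimum is found exhaustively
when the number of distinct balanced assignments is small (≤ 2·10⁵) and by
seeded random restarts with pairwise-swap hill climbing otherwise.

**Within-block randomization.** Consecutive members of the same category
must be separated by at least `lag_min = 2` and at most `lag_max = 8`
intervening items (fillers included).  Uniform-shuffle rejection sampling
is hopeless at the default composition — fewer than one shuffle in ~10⁵
satisfies all constraints simultaneously — so the sampler performs seeded
randomized backtracking: positions are filled left to right with a randomly
ordered choice among the symbols still admissible there (a category is
inadmissible while its lag window has not opened; a branch dies when a
pending category passes its deadline), backtracking on dead ends, with a
configurable node budget (default 10 000).  This produces valid orders in
milliseconds; it does not sample uniformly from the set of valid orders,
which no practical sampler here would.  Lag is counted as the number of
*intervening* items: lag 2 means two items between the two members.

## Keystroke logs and reconstruction

Logs are JSON lines, one object per key event (`pid`, `trial`, `item`,
`key`, `t` in ms since picture onset), with `key` following the W3C
`KeyboardEvent.key` vocabulary.  Printable characters are upper-cased on
ingestion (participants type in capitals on QWERTZ keyboards; umlauts and ß
are ordinary characters, never transliterated); control keys normalize to
BACKSPACE, SPACE, ENTER, SHIFT, CAPSLOCK, and any other multi-character
name to OTHER.

Reconstruction replays the stream through a minimal editor: printable keys
append, BACKSPACE deletes the last character (no-op on an empty buffer),
SHIFT/CAPSLOCK/ENTER contribute nothing.  Two strings result: the *raw*
concatenation of printable keys and the *corrected* final buffer.  A
trailing run of SPACE/ENTER (the submission keys) is stripped before
reconstruction.  The trial latency is the timestamp of the first event of
*any* kind — a response may legitimately begin with a special key, which
the classifier then flags; latency analyses only ever see correct trials.

## Automated correctness classification

The primary distance is the Jaro distance: with match window
`floor(max(|a|,|b|)/2) − 1`, `m` matching characters and `t` transposition
pairs, similarity `(m/|a| + m/|b| + (m−t)/m)/3` (0 when `m = 0`), distance
= 1 − similarity.  This equals Jaro–Winkler with zero prefix weight.
Normalized Levenshtein and optimal string alignment (restricted
Damerau–Levenshtein, unit costs) are available under the same cut-off for
comparison; all three default to threshold .3.

Decision procedure per trial, on the stripped, reconstructed entry:

1. no events → **NA**;
2. first key SPACE/BACKSPACE/CAPSLOCK/ENTER → **special-key start**; first
   key SHIFT → **shift start** (reported separately);
3. *best match*: an accepted alternative replaces the picture name as the
   scoring target only if it starts with the corrected entry's first
   character **and** is strictly closer than the picture name; ties go to
   the picture name, then earlier list order;
4. **correct** iff the first printable character of the raw *and* of the
   corrected string equals the target's first character, and d <
   threshold.  Correct trials subdivide into *identical* (corrected string
   equals the target, no backspace), *corrected* (equals the target after
   ≥ 1 backspace) and *below-threshold*, each crossed with picture-name
   vs. alternative basis;
5. otherwise **first-letter error**, **distance exceeded**, or **combined**
   when both conditions fail.

Distances are computed on the backspace-corrected string; the raw string
contributes only its first printable character to the first-letter rule.
Raising the threshold can only enlarge the correct set (the best-match
choice does not depend on it).  An entry equally close to the picture name
and an alternative is attributed to the picture name (the strict-inequality
reading of "lower than").

## Typing-test metrics

Copy-typing skill uses the five-character-word convention: the
backspace-corrected transcript, each character stamped with the keystroke
that finally produced it, is cut into consecutive non-overlapping
5-character chunks aligned positionally with the target text.  A chunk is
correct iff its characters match the target and no backspace fell in its
production span; accuracy is the percentage of correct chunks and speed the
number of correct chunks per minute of total production time.  Chunk *k*'s
span runs from the last keystroke of chunk *k−1* (trial onset for the
first) to its own last keystroke, so spans tile the production period and
between-chunk pauses count toward the denominator — the published
convention is stated only at sentence level, so these choices (corrected
stream, tiling spans, pauses included) are this package's formalization.
Scoring on the corrected stream keeps one early slip from misaligning the
rest of the transcript, while repaired chunks still count as wrong through
the backspace rule.

## Statistical models

**Latency.** Correct, non-filler trials enter a gamma GLMM with identity
link: `rt ~ 1 + position_c + (1 + position_c | participant) +
(1 + position_c | category)`, `position_c` mean-centred on the analysed
rows.  The identity link keeps the effect additive in milliseconds while
the gamma family respects the right-skewed latency distribution.

**Errors.** All non-filler trials enter a binomial-logit GLMM with the same
crossed structure but *uncentred* ordinal position: the reported error-model
intercepts only reproduce observed per-position error rates under the
uncentred coding, so the generator and default fit use raw positions 1–5
(the latency models stay centred, as reported).

**Log-LMM.** A linear mixed model on log latency with identical structure
serves where hundreds of refits are needed (power curves); on this scale
the CSI effect is ≈ slope/intercept ≈ 0.03 per position.

**Estimation.** No Python library fits gamma/binomial GLMMs with crossed
vector random effects, so `csityping.glmm` implements the standard Laplace
scheme natively: random effects in spherical coordinates `b = Λ(θ)u`,
joint `(β, u)` mode by penalized IRLS (Fisher weights; step-halving keeps
the gamma mean positive — the identity link does not enforce positivity by
itself), and the profiled Laplace deviance
`−2Σ log f(y|μ̂) + ‖û‖² + log det(ΛᵀZᵀWZΛ + I)` minimized over θ and the
dispersion (gamma shape / residual SD) by L-BFGS-B with bounds keeping the
Cholesky diagonals non-negative.  The response is internally rescaled by
its standard deviation so covariance parameters are O(1) in any unit.  The
crossed-design algebra is dense `bincount` accumulation over level codes
(q ≈ 100 here), making one fit a fraction of a second.  Cross-checks
against independent implementations (glmmTMB for gamma-identity, lme4 for
the LMM and binomial models) agree to ≤ 1% on fixed effects and to three
digits on variance components; lme4's own gamma-with-free-dispersion path
is documented as unreliable and is not used as a reference for that family.

**Inference.** Wald throughout: CI = estimate ± 1.96·SE, p from the normal.
For the latency model the default SEs come from the full-likelihood Wald
covariance — the numerical Hessian of the Laplace deviance over (β, θ, log
shape) — which propagates covariance-parameter uncertainty; profiled
(conditional) SEs are available and are the convention the binomial and
log-LMM fits follow, matching lme4's reporting.

**Convergence ladder.** On non-convergence the error model follows the
reduction sequence: raise the optimizer iteration cap to 2·10⁵, zero the
random-effect correlations, drop the participant slope, drop the category
slope, intercepts only.  Every attempt is recorded in the fit's
`reduction_trace`.  The ladder order below the documented first two rungs
is this package's choice.  Quasi-separated data yield a flagged, finite
result rather than an exception.

**Trial exclusion.** The latency table keeps correct non-filler trials; the
accounting report satisfies `retained = total − fillers − erroneous +
erroneous fillers` on every input (erroneous fillers would otherwise be
subtracted twice).

**Within-subject summaries.** Condition means carry Morey-adjusted
within-subject SEs: observations are normalized by subtracting the subject
mean and adding the grand mean, and the per-condition variance is inflated
by K/(K−1) for K conditions.  Balanced data keep their raw condition means.

## Synthetic experiments

The generator runs the analysis models forward and is the package's test
bed; its defaults are the study conditions of the typed-naming experiment
it models:

| parameter | default | origin |
|---|---|---|
| latency intercept | 1298.49 ms | fitted value (typed naming) |
| CSI slope | 41.68 ms/position | fitted value (typed naming) |
| error log-odds | −2.74 + 0.15·position | fitted values (spoken naming) |
| participants × categories | 30 × 24 | study design |
| gamma shape | 18 | free choice: trial-level SD ≈ 305 ms at the mean |
| RE SDs (subj int/slope, cat int/slope) | 150 / 20 / 60 / 12 ms | free choice |
| inter-key interval | lognormal, median 200 ms, σ=0.4 | free choice |

The random-effect SDs and the gamma shape are free parameters because the
source analyses do not publish variance components; the chosen values give
slope standard errors of the observed order (≈ 6–7 ms).  Random effects are
drawn independently (zero correlation) — the fitted models allow
correlation, and the fitter estimates it; the generator simply does not
plant one.  Exact reproduction of the published power curves is therefore
impossible from published numbers alone, and the power module's claims are
about its own generating model.  Mean latencies at the identity link must
stay positive; the generator raises immediately if a parameter combination
implies a non-positive mean rather than silently truncating.

The keystroke simulator realizes each trial's correctness flag as an event
stream with planted labels: correct trials are typed exactly, via an
accepted alternative, repaired with backspaces, or left with a one-character
interior typo verified to stay under the distance cut-off; incorrect trials
are no-answers, special-key or shift starts, first-letter slips, garbled
entries with the right first letter (verified ≥ cut-off), or wrong words.
Mode probabilities echo the published error taxonomy (≈ 29% no-answer, ≈ 5%
special-key, ≈ 2% shift starts; remainder split 0.69/0.27/0.04).  The first
keystroke falls exactly at the trial's model latency.  What the simulator
does *not* emulate: real typo phonotactics and keyboard-adjacency
structure, inter-keystroke dynamics beyond i.i.d. lognormal intervals,
hardware timing jitter, or attention lapses — so classification accuracy on
simulated streams (≈ 100% by construction) bounds, but does not estimate,
accuracy on real data, where the published manual-vs-automatic agreement
(r = .97) is the relevant benchmark.

## Power curves

For each (participants, categories) grid point the generator simulates
targets-only experiments, drops erroneous trials, refits the log-LMM and
counts Wald p < α for the ordinal-position effect; non-convergent
replicates count as non-significant (conservative) and are reported.
Gamma-GLMM refits are available (`engine="gamma"`) but the log-LMM is the
default refit engine, as in practice power tools cannot refit gamma GLMMs
reliably at scale.  Each point reports `n_subjects × n_categories × 5`
target trials and a Clopper–Pearson 95% interval on the power estimate.
The default `n_sims = 200` keeps a desk run in minutes at correspondingly
wider intervals; 1000 simulations reproduce the published protocol's
precision.

## Problem sizes and verification scale

The test suite verifies end-to-end parameter recovery at the full study
design (30 × 24, 200 replicates: mean gamma-GLMM slope within 10% of the
generating 41.68 ms/position, 95% Wald-interval coverage within 95 ± 5
points) and type-I calibration of the power machinery (200 null refits at
the same size).  Distance implementations are checked against independent
references on 10⁴ random string pairs; list generation is validated on 100
seeded lists.  These sizes were chosen so the whole suite completes in
minutes on a single core while keeping Monte Carlo error well inside the
asserted tolerances.

## Known limitations

* The lag-constrained sampler is not a uniform sampler over valid orders.
* Wald intervals are first-order; at 24 categories the category-slope
  variance is estimated with few effective degrees of freedom, and interval
  coverage for the latency slope sits near the lower edge of the nominal
  band (≈ 92–94% empirically) even with full-likelihood SEs.
* The binomial ladder's drop order beyond the documented rungs, the
  best-match tie rule, and the typing-test chunk conventions are documented
  package choices; alternatives would be defensible.
* `reproduce_deposited_analysis` expects the deposited raw data converted
  to this package's formats; it cannot download them.
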