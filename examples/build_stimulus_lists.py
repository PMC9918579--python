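"""Build and validate a randomized CSI trial list.

Creates a synthetic 24-category stimulus inventory, assigns categories to
eight blocks so that same-superordinate categories are spread apart,
randomizes each block under the lag constraints (2-8 intervening items
between same-category members) and validates the result.
"""

from collections import Counter

from csityping import DesignConfig, generate_list, validate_list
from csityping.simgen import make_stimuli
from csityping.stimlist import category_lags

config = DesignConfig()  # 24 categories x 5 exemplars + 40 fillers, 8 blocks
stimuli = make_stimuli(config, seed=1)
trial_list = generate_list(stimuli, config, seed=2024)

report = validate_list(trial_list)
lags = category_lags(trial_list)

print(f"trials: {len(trial_list)} (8 blocks of 20)")
print(f"validator: {'pass' if report.passed else report.violations}")
print(f"within-category lags: min {min(lags)}, max {max(lags)}")
print("lag histogram:", dict(sorted(Counter(lags).items())))
print(trial_list.to_frame().head(10).to_string(index=False))

# The histogram shows every gap between consecutive same-category members
# lies in [2, 8]; ordinal_position counts each category's occurrences 1-5 —
# the predictor of the interference models.
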