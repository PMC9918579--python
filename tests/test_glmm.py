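"""Mixed-model engine: recovery, invariances and cross-implementation checks.

The R references (glmmTMB for the gamma-identity model, lme4::lmer for the
log-latency LMM, lme4::glmer for the binomial model) are run through
Rscript on a shared simulated fixture; they are oracles only — the package
never calls R at run time.
"""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import csityping as ct
from csityping.csimodels import fit_error_model, fit_log_lmm, fit_rt_model


@pytest.fixture(scope="module")
def fixture_table(tmp_path_factory):
    """A moderate crossed design shared by all cross-implementation checks."""
    tab = ct.simulate_grid_table(20, 12, seed=77)
    tab = tab[tab["correct"]].copy()
    tab["pos_c"] = tab["ordinal_position"] - tab["ordinal_position"].mean()
    path = tmp_path_factory.mktemp("fixture") / "fixture.csv"
    tab.to_csv(path, index=False)
    return tab, path


def _run_r(script: str) -> str:
    proc = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert proc.returncode == 0, proc.stderr
    return proc.stdout


class TestCrossImplementation:
    def test_gamma_identity_agrees_with_glmmtmb(self, fixture_table):
        tab, path = fixture_table
        fit = fit_rt_model(tab)
        out = _run_r(
            textwrap.dedent(f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv("{path}")
            m <- glmmTMB(rt_ms ~ pos_c + (pos_c | participant) + (pos_c | category),
                         data = d, family = Gamma(link = "identity"),
                         start = list(beta = c(mean(d$rt_ms), 0)))
            co <- summary(m)$coefficients$cond
            cat(co[1,1], co[2,1], co[2,2], sigma(m), sep=",")
            """)
        )
        r_int, r_slope, r_se, r_cv = map(float, out.strip().split(","))
        py_slope = fit.fixef.loc["ordinal_position", "estimate"]
        py_int = fit.fixef.loc["intercept", "estimate"]
        assert py_slope == pytest.approx(r_slope, rel=0.01)
        assert py_int == pytest.approx(r_int, rel=0.01)
        assert fit.fixef.loc["ordinal_position", "se"] == pytest.approx(r_se, rel=0.05)
        assert fit.dispersion == pytest.approx(1.0 / r_cv**2, rel=0.02)

    def test_log_lmm_agrees_with_lmer(self, fixture_table):
        tab, path = fixture_table
        fit = fit_log_lmm(tab)
        out = _run_r(
            textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{path}")
            m <- lmer(log(rt_ms) ~ pos_c + (pos_c | participant) + (pos_c | category),
                      data = d, REML = FALSE)
            co <- summary(m)$coefficients
            cat(co[2,1], co[2,2], sep=",")
            """)
        )
        r_slope, r_se = map(float, out.strip().split(","))
        assert fit.fixef.loc["ordinal_position", "estimate"] == pytest.approx(
            r_slope, rel=1e-4
        )
        assert fit.fixef.loc["ordinal_position", "se"] == pytest.approx(r_se, rel=1e-3)

    def test_binomial_agrees_with_glmer(self, tmp_path):
        tab = ct.simulate_grid_table(25, 16, seed=31)
        path = tmp_path / "err.csv"
        tab.assign(error=(~tab["correct"]).astype(int)).to_csv(path, index=False)
        fit = fit_error_model(tab, structure="diagonal", ladder=False)
        out = _run_r(
            textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{path}")
            m <- glmer(error ~ ordinal_position + (ordinal_position || participant)
                       + (ordinal_position || category),
                       data = d, family = binomial,
                       control = glmerControl(optimizer = "bobyqa"))
            co <- summary(m)$coefficients
            cat(co[1,1], co[2,1], co[2,2], sep=",")
            """)
        )
        r_int, r_slope, r_se = map(float, out.strip().split(","))
        assert fit.fixef.loc["ordinal_position", "estimate"] == pytest.approx(
            r_slope, abs=max(0.02, 0.05 * abs(r_slope))
        )
        assert fit.fixef.loc["intercept", "estimate"] == pytest.approx(r_int, rel=0.05)
        assert fit.fixef.loc["ordinal_position", "se"] == pytest.approx(r_se, rel=0.1)


class TestRecoveryAndInvariances:
    def test_null_slope_recovered_within_two_se(self):
        tab = ct.simulate_grid_table(
            20, 12, rt=ct.RTModelParams(slope_ms_per_position=0.0), seed=21
        )
        fit = fit_rt_model(tab[tab["correct"]])
        est = fit.fixef.loc["ordinal_position", "estimate"]
        se = fit.fixef.loc["ordinal_position", "se"]
        assert abs(est) < 2 * se

    def test_mean_centering_shifts_intercept_not_slope(self):
        tab = ct.simulate_grid_table(12, 8, seed=22)
        tab = tab[tab["correct"]]
        fit_c = fit_rt_model(tab, center=True, se_method="conditional")
        shifted = tab.copy()
        shifted["ordinal_position"] = shifted["ordinal_position"] + 7.0
        fit_s = fit_rt_model(shifted, center=True, se_method="conditional")
        assert fit_s.fixef.loc["ordinal_position", "estimate"] == pytest.approx(
            fit_c.fixef.loc["ordinal_position", "estimate"], rel=1e-3
        )
        # uncentred coding moves the intercept, not the slope; the two
        # parameterizations are equivalent only at the exact optimum, so
        # allow finite-optimizer slack here
        fit_u = fit_rt_model(tab, center=False, se_method="conditional")
        assert fit_u.fixef.loc["ordinal_position", "estimate"] == pytest.approx(
            fit_c.fixef.loc["ordinal_position", "estimate"], rel=5e-2
        )
        assert abs(
            fit_u.fixef.loc["intercept", "estimate"]
            - fit_c.fixef.loc["intercept", "estimate"]
        ) > 10

    def test_exact_lognormal_data_recovered_by_log_lmm(self):
        # multiplicative noise: the log-LMM is the true generating model,
        # so the mean estimate over replicates must sit on the true slope
        n_subj, n_cat = 24, 12
        true_slope = 0.028
        subj = np.repeat(np.arange(n_subj), n_cat * 5)
        cat = np.tile(np.repeat(np.arange(n_cat), 5), n_subj)
        pos = np.tile(np.arange(1.0, 6.0), n_subj * n_cat)
        estimates = []
        for rep in range(6):
            rng = np.random.default_rng(4000 + rep)
            b_subj = rng.normal(0, 0.12, n_subj)
            b_cat = rng.normal(0, 0.06, n_cat)
            logy = (
                7.1 + true_slope * (pos - 3.0) + b_subj[subj] + b_cat[cat]
                + rng.normal(0, 0.25, len(pos))
            )
            tab = pd.DataFrame(
                {
                    "participant": subj.astype(str),
                    "category": cat.astype(str),
                    "ordinal_position": pos,
                    "rt_ms": np.exp(logy),
                    "correct": True,
                    "is_filler": False,
                }
            )
            fit = fit_log_lmm(tab)
            estimates.append(fit.fixef.loc["ordinal_position", "estimate"])
        mean_est = np.mean(estimates)
        mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean_est - true_slope) < 3 * mc_se

    def test_constant_latencies_rejected(self):
        tab = pd.DataFrame(
            {
                "participant": ["a", "a", "b", "b"] * 3,
                "category": ["c1", "c2"] * 6,
                "ordinal_position": [1, 2, 3, 4, 5, 1, 2, 3, 4, 5, 1, 2],
                "rt_ms": 1000.0,
                "correct": True,
                "is_filler": False,
            }
        )
        with pytest.raises(ValueError, match="constant"):
            fit_log_lmm(tab)

    def test_separable_error_data_returns_flagged_result(self):
        # all errors at position 5: quasi-separation must not crash the fit
        n_subj, n_cat = 8, 6
        subj = np.repeat(np.arange(n_subj), n_cat * 5)
        cat = np.tile(np.repeat(np.arange(n_cat), 5), n_subj)
        pos = np.tile(np.arange(1.0, 6.0), n_subj * n_cat)
        tab = pd.DataFrame(
            {
                "participant": subj.astype(str),
                "category": cat.astype(str),
                "ordinal_position": pos,
                "rt_ms": 1000.0,
                "correct": pos < 5,
                "is_filler": False,
            }
        )
        fit = fit_error_model(tab)
        assert fit.reduction_trace  # a trace is always recorded
        assert np.isfinite(fit.fixef["estimate"]).all()
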