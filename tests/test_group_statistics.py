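"""Paired tests and the random-intercept mixed-model ANOVA."""

import itertools
import math
import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from navassess import (
    DegenerateVarianceError,
    InputError,
    ModelError,
    lmm_anova,
    paired_t,
    wilcoxon_signed_rank,
)


def _factorial_frame(rng, n_participants=6, participant_sd=5.0, noise_sd=10.0,
                     effects=None, dropout=0):
    """Balanced 2x2 factorial, 4 replicates per cell per participant."""
    effects = effects or {}
    rows = []
    for i in range(n_participants):
        b = rng.normal(0.0, participant_sd)
        conds = ["immersive", "semi_immersive"]
        if i < dropout:
            conds = ["semi_immersive"]
        for cond in conds:
            for lm in ("allocentric", "egocentric"):
                mu = 20.0 + b
                mu += effects.get("condition", 0.0) * (1 if cond == "immersive" else -1)
                mu += effects.get("landmark", 0.0) * (1 if lm == "allocentric" else -1)
                for _ in range(4):
                    rows.append(dict(participant_id=f"P{i:02d}", condition=cond,
                                     landmark=lm, r=mu + rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows)


class TestPairedT:
    def test_zero_mean_difference(self):
        r = paired_t([1.0, 2.0, 3.0, 5.0, 3.0], [1.0, 2.0, 3.0, 4.0, 4.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)
        assert r.tied_pairs == 3

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_matches_textbook_formula(self, rng):
        """t = mean(d) / (sd(d)/sqrt(n)), df = n-1, p from the t distribution."""
        for _ in range(20):
            n = int(rng.integers(3, 12))
            x = rng.normal(60, 20, n)
            y = x + rng.normal(2, 5, n)
            r = paired_t(x, y)
            d = x - y
            t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(n))
            p_ref = 2 * stats.t.sf(abs(t_ref), n - 1)
            assert r.statistic == pytest.approx(t_ref, abs=1e-10)
            assert r.p == pytest.approx(p_ref, abs=1e-10)
            assert r.df == n - 1

    def test_antisymmetric_in_arguments(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_missing_pairs_dropped(self):
        x = [1.0, float("nan"), 3.0, 4.0]
        y = [2.0, 5.0, 1.0, 9.0]
        assert paired_t(x, y).n_pairs == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InputError):
            paired_t([1.0], [2.0])


class TestWilcoxon:
    def test_all_negative_differences_give_w_zero(self):
        x = np.arange(6.0)
        r = wilcoxon_signed_rank(x, x + 3.0)
        assert r.statistic == 0.0

    def test_all_positive_differences_give_max_w(self):
        x = np.arange(6.0)
        r = wilcoxon_signed_rank(x + 3.0, x)
        assert r.statistic == 6 * 7 / 2

    def test_zero_differences_dropped_and_reported(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 2.0, 1.0, 6.0, 1.0]
        r = wilcoxon_signed_rank(x, y)
        assert r.tied_pairs == 2
        assert r.n_pairs == 5

    def test_all_zero_differences_rejected(self):
        with pytest.raises(InputError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_equals_sign_enumeration(self, seed):
        """Exact p equals brute-force enumeration over all 2^n sign vectors."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        x = rng.normal(0, 1, n)
        y = x + rng.normal(0.4, 1, n)
        if seed % 2:  # exercise midranks via duplicated |d|
            y[1] = x[1] + (x[0] - y[0])
        r = wilcoxon_signed_rank(x, y)
        d = x - y
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
        ws = np.array(
            [ranks[np.array(s) > 0].sum() for s in itertools.product((-1, 1), repeat=d.size)]
        )
        lo = float(np.mean(ws <= r.statistic))
        hi = float(np.mean(ws >= r.statistic))
        assert r.p == min(1.0, 2.0 * min(lo, hi))

    def test_w_range_invariant(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 20))
            x, y = rng.normal(0, 1, n), rng.normal(0, 1, n)
            r = wilcoxon_signed_rank(x, y)
            nz = r.n_pairs - r.tied_pairs
            assert 0 <= r.statistic <= nz * (nz + 1) / 2

    def test_large_sample_normal_approximation(self, rng):
        x = rng.normal(0, 1, 60)
        y = x + rng.normal(0.4, 1, 60)
        r = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, zero_method="wilcox", correction=True, method="approx")
        assert r.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestLmmAnova:
    def test_degenerate_limit_matches_classic_anova(self, rng):
        """With random-effect variance forced to 0, F equals a hand-computed
        balanced two-way fixed-effects ANOVA (tolerance 1e-6)."""
        df = _factorial_frame(rng)
        tab = lmm_anova(df, "r", ("landmark", "condition"), "participant_id",
                        re_variance=0.0)
        y = df["r"].to_numpy()
        n = y.size
        cm = df.groupby(["landmark", "condition"])["r"].mean().unstack()
        gm = y.mean()
        per_cell = n / 4
        ss_a = 2 * per_cell * ((cm.mean(axis=1) - gm) ** 2).sum()
        ss_b = 2 * per_cell * ((cm.mean(axis=0) - gm) ** 2).sum()
        resid_cell = cm - cm.mean(axis=1).to_numpy()[:, None] - cm.mean(axis=0).to_numpy()[None, :] + gm
        ss_ab = per_cell * (resid_cell**2).to_numpy().sum()
        sse = ((y - df.groupby(["landmark", "condition"])["r"].transform("mean")) ** 2).sum()
        mse = sse / (n - 4)
        assert tab["landmark"]["F"] == pytest.approx(ss_a / mse, abs=1e-6)
        assert tab["condition"]["F"] == pytest.approx(ss_b / mse, abs=1e-6)
        assert tab["landmark:condition"]["F"] == pytest.approx(ss_ab / mse, abs=1e-6)
        assert tab["landmark"]["den_df"] == n - 4
        assert tab.singular

    def test_matches_statsmodels_mixedlm_variances(self, rng):
        """REML variance components agree with statsmodels MixedLM."""
        import statsmodels.api as sm

        df = _factorial_frame(rng, participant_sd=6.0, dropout=1)
        tab = lmm_anova(df, "r", ("landmark", "condition"), "participant_id")
        X = pd.get_dummies(df[["landmark", "condition"]], drop_first=True, dtype=float)
        X["inter"] = X.iloc[:, 0] * X.iloc[:, 1]
        X = sm.add_constant(X)
        m = sm.MixedLM(df["r"], X, groups=df["participant_id"]).fit(reml=True)
        assert tab.sigma2 == pytest.approx(m.scale, rel=1e-4)
        assert tab.tau2 == pytest.approx(float(m.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-3)

    def test_matches_lmerTest_satterthwaite(self, rng, tmp_path):
        """F, den df and p agree with R lmerTest on unbalanced data."""
        df = _factorial_frame(rng, participant_sd=6.0, dropout=2,
                              effects={"landmark": 2.0})
        tab = lmm_anova(df, "r", ("landmark", "condition"), "participant_id")
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = (
            "suppressMessages(library(lmerTest));"
            f"d <- read.csv('{csv}');"
            "m <- lmer(r ~ landmark*condition + (1|participant_id), data=d, REML=TRUE,"
            " contrasts=list(landmark=contr.sum, condition=contr.sum));"
            "a <- anova(m, type=3);"
            "cat(sprintf('%s %.10f %.6f %.10f\\n', rownames(a), a$`F value`, a$DenDF, a$`Pr(>F)`))"
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        ).stdout
        ref = {}
        for line in out.strip().splitlines():
            term, F, den, p = line.split()
            ref[term] = (float(F), float(den), float(p))
        for mine, theirs in (("landmark", "landmark"), ("condition", "condition"),
                             ("landmark:condition", "landmark:condition")):
            row = tab[mine]
            F, den, p = ref[theirs]
            assert row["F"] == pytest.approx(F, rel=1e-5)
            assert row["den_df"] == pytest.approx(den, rel=1e-3)
            assert row["p"] == pytest.approx(p, abs=1e-6)

    def test_invariant_to_level_relabeling_and_row_order(self, rng):
        df = _factorial_frame(rng, participant_sd=4.0)
        tab1 = lmm_anova(df, "r", ("landmark", "condition"), "participant_id")
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        renamed = shuffled.assign(
            landmark=shuffled["landmark"].map({"allocentric": "zz", "egocentric": "aa"})
        )
        tab2 = lmm_anova(renamed, "r", ("landmark", "condition"), "participant_id")
        for term1, term2 in (("landmark", "landmark"), ("condition", "condition")):
            assert tab1[term1]["F"] == pytest.approx(tab2[term2]["F"], rel=1e-8)
            assert tab1[term1]["den_df"] == pytest.approx(tab2[term2]["den_df"], rel=1e-6)

    def test_unbalanced_participants_keep_all_observations(self, rng):
        """5 two-condition + 2 one-condition participants, 16 obs each -> 192 used."""
        rows = []
        for i in range(7):
            conds = ["immersive", "semi_immersive"] if i < 5 else ["semi_immersive"]
            b = rng.normal(0, 5)
            for cond in conds:
                for k in range(16):
                    rows.append(dict(participant_id=f"P{i}", condition=cond,
                                     landmark=("allocentric", "egocentric")[k % 2],
                                     r=20 + b + rng.normal(0, 10)))
        df = pd.DataFrame(rows)
        tab = lmm_anova(df, "r", ("landmark", "condition"), "participant_id")
        assert tab.n_obs == 192
        assert tab.n_groups == 7

    def test_empty_cell_names_the_level(self, rng):
        df = _factorial_frame(rng)
        df = df[~((df["landmark"] == "egocentric") & (df["condition"] == "immersive"))]
        with pytest.raises(ModelError, match="egocentric"):
            lmm_anova(df, "r", ("landmark", "condition"), "participant_id")

    def test_single_level_factor_rejected(self, rng):
        df = _factorial_frame(rng)
        df = df[df["condition"] == "immersive"]
        with pytest.raises(ModelError, match="condition"):
            lmm_anova(df, "r", ("landmark", "condition"), "participant_id")

    def test_power_exceeds_null_rejection_rate(self):
        """Injecting a 1-SD condition effect raises the rejection rate (smoke)."""
        def rate(effect, n_rep=40):
            hits = 0
            for k in range(n_rep):
                rng = np.random.default_rng(1000 + k)
                df = _factorial_frame(rng, n_participants=7, noise_sd=10.0,
                                      effects={"condition": effect / 2.0})
                tab = lmm_anova(df, "r", ("landmark", "condition"), "participant_id")
                hits += tab["condition"]["p"] < 0.05
            return hits / n_rep

        assert rate(10.0) > rate(0.0)
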