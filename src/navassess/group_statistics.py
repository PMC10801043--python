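"""Within-subject group statistics.

Paired comparisons are reported two ways, as usability studies conventionally
do for small samples: the paired Student t test and the Wilcoxon signed-rank
test (W = sum of positive-difference ranks; zero differences are dropped and
surfaced as tie diagnostics).  The exact signed-rank null distribution is used
up to n = 25 pairs; beyond that a normal approximation with tie correction and
continuity correction.

Trial-level factorial effects are tested with a linear mixed-effects ANOVA:

    response ~ A * B  +  (1 | participant)

fitted by REML.  Because the only random term is a participant intercept, the
marginal covariance is V = sigma^2 I + tau^2 Z Z' and the REML criterion can
be profiled down to a one-dimensional optimization over the variance ratio
lambda = tau^2 / sigma^2, with all per-group quantities in closed form.  Fixed
effects use sum-to-zero contrasts, so the Wald F tests are Type-III;
denominator degrees of freedom come from the Satterthwaite approximation
(delta method on the REML information matrix).  Unbalanced designs — e.g.
participants who completed only one condition — keep all their remaining
observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._exceptions import DegenerateVarianceError, InputError, ModelError

__all__ = ["StatTestResult", "AnovaTable", "paired_t", "wilcoxon_signed_rank", "lmm_anova"]


@dataclass(frozen=True)
class StatTestResult:
    method: str  # "paired_t" | "wilcoxon_signed_rank"
    statistic: float
    df: float | None
    p: float
    n_pairs: int
    tied_pairs: int


def _clean_pairs(x, y) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired samples must be 1-D arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep] - y[keep]


def paired_t(x, y) -> StatTestResult:
    """Paired Student t test on x - y (two-sided).

    Pairs with a missing value are dropped; zero differences are kept in the
    computation and reported in ``tied_pairs``.  A zero-variance difference
    vector has no defined t statistic and raises
    :class:`DegenerateVarianceError`.
    """
    d = _clean_pairs(x, y)
    n = d.size
    if n < 2:
        raise InputError(f"paired_t needs at least 2 complete pairs, got {n}")
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateVarianceError("all paired differences are identical; t is undefined")
    t = float(np.mean(d) / (sd / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return StatTestResult(
        method="paired_t",
        statistic=t,
        df=float(n - 1),
        p=p,
        n_pairs=n,
        tied_pairs=int(np.sum(d == 0.0)),
    )


def _signed_rank_exact_p(w2: int, dranks: np.ndarray) -> float:
    """Exact two-sided p for W+ given doubled ranks (integers).

    Builds the null distribution of 2*W+ by dynamic programming over all 2^n
    sign assignments; p = min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    total = int(dranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in dranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    denom = counts.sum()  # 2^n
    lo = counts[: w2 + 1].sum() / denom
    hi = counts[w2:].sum() / denom
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_signed_rank(x, y, exact_limit: int = 25) -> StatTestResult:
    """Wilcoxon signed-rank test on x - y (two-sided).

    W is the sum of ranks of the positive differences (so W = 0 when every
    pair decreases).  Zero differences are dropped before ranking and their
    count reported as ``tied_pairs``.  Up to ``exact_limit`` nonzero pairs the
    p-value is exact (full sign-assignment distribution, ties handled via
    midranks); above it, normal approximation with tie correction and
    continuity correction.
    """
    d = _clean_pairs(x, y)
    if d.size < 1:
        raise InputError("wilcoxon_signed_rank needs at least 1 complete pair")
    tied = int(np.sum(d == 0.0))
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise InputError("all paired differences are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_limit:
        dranks = np.rint(2.0 * ranks).astype(np.int64)  # midranks doubled -> integers
        p = _signed_rank_exact_p(int(round(2.0 * w)), dranks)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        if var <= 0:
            raise InputError("zero variance in signed-rank statistic")
        z = (w - mean - 0.5 * np.sign(w - mean)) / math.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return StatTestResult(
        method="wilcoxon_signed_rank",
        statistic=w,
        df=None,
        p=p,
        n_pairs=n + tied,
        tied_pairs=tied,
    )


# ---------------------------------------------------------------------------
# linear mixed-effects ANOVA (random intercept per participant)


@dataclass
class AnovaTable:
    """Type-III F table of a random-intercept mixed model.

    ``table`` has one row per term (two mains + interaction) with F, num_df,
    den_df (Satterthwaite) and p.  ``singular`` flags a random-intercept
    variance estimated at the boundary tau^2 = 0, in which case the
    denominator df fall back to the residual df of the fixed-effects model.
    """

    table: pd.DataFrame
    n_obs: int
    n_groups: int
    sigma2: float
    tau2: float
    singular: bool
    log_restricted_likelihood: float

    def __getitem__(self, term: str) -> pd.Series:
        sub = self.table[self.table["term"] == term]
        if sub.empty:
            raise KeyError(term)
        return sub.iloc[0]


def _sum_coded_design(data: pd.DataFrame, fa: str, fb: str):
    """Intercept + sum-coded mains + interaction columns; term -> column slice."""
    la = sorted(data[fa].astype(str).unique())
    lb = sorted(data[fb].astype(str).unique())
    for name, levels in ((fa, la), (fb, lb)):
        if len(levels) < 2:
            raise ModelError(f"factor {name!r} has fewer than 2 observed levels: {levels}")
    counts = data.groupby([fa, fb]).size()
    for a in la:
        for b in lb:
            if (a, b) not in counts.index:
                raise ModelError(f"no observations in cell {fa}={a!r}, {fb}={b!r}")

    def contrasts(col: pd.Series, levels: list[str]) -> np.ndarray:
        # sum-to-zero coding: last level is the negative reference
        vals = col.astype(str).to_numpy()
        out = np.zeros((len(vals), len(levels) - 1))
        for j, lev in enumerate(levels[:-1]):
            out[:, j] = np.where(vals == lev, 1.0, np.where(vals == levels[-1], -1.0, 0.0))
        return out

    ca = contrasts(data[fa], la)
    cb = contrasts(data[fb], lb)
    inter = np.einsum("ij,ik->ijk", ca, cb).reshape(len(data), -1)
    X = np.column_stack([np.ones(len(data)), ca, cb, inter])
    qa, qb = ca.shape[1], cb.shape[1]
    slices = {
        fa: slice(1, 1 + qa),
        fb: slice(1 + qa, 1 + qa + qb),
        f"{fa}:{fb}": slice(1 + qa + qb, 1 + qa + qb + qa * qb),
    }
    return X, slices


class _RandomInterceptREML:
    """Closed-form GLS/REML machinery for V = sigma^2 (I + lambda Z Z').

    With a single grouping factor, W(lambda) = I + lambda Z Z' is block
    diagonal; each m x m block inverts to I - lambda/(1 + lambda m) J and has
    log-determinant log(1 + lambda m), so every REML quantity is O(n p^2).
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        _, inv = np.unique(groups, return_inverse=True)
        self.group_idx = [np.nonzero(inv == g)[0] for g in range(inv.max() + 1)]
        self.sizes = np.array([len(ix) for ix in self.group_idx])
        # per-group sufficient statistics
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.Sx = np.stack([X[ix].sum(axis=0) for ix in self.group_idx])  # G x p
        self.Sy = np.array([y[ix].sum() for ix in self.group_idx])  # G

    def _gls(self, lam: float):
        c = lam / (1.0 + lam * self.sizes)  # per-group shrinkage
        XtWiX = self.XtX - (self.Sx * c[:, None]).T @ self.Sx
        XtWiy = self.Xty - self.Sx.T @ (c * self.Sy)
        ytWiy = self.yty - float(c @ self.Sy**2)
        beta = np.linalg.solve(XtWiX, XtWiy)
        rss = ytWiy - 2.0 * beta @ XtWiy + beta @ XtWiX @ beta
        rss = max(float(rss), 1e-300)
        logdetW = float(np.sum(np.log1p(lam * self.sizes)))
        sign, logdetXtWiX = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            raise ModelError("singular fixed-effects design (X'V^-1 X not positive definite)")
        return beta, XtWiX, rss, logdetW, logdetXtWiX

    def profile_negloglik(self, lam: float) -> float:
        _, _, rss, logdetW, logdetXtWiX = self._gls(lam)
        nmp = self.n - self.p
        return 0.5 * (nmp * math.log(rss / nmp) + logdetW + logdetXtWiX)

    def reml_loglik(self, tau2: float, sigma2: float) -> float:
        """Unprofiled restricted log-likelihood (up to an additive constant)."""
        lam = tau2 / sigma2
        _, _, rss, logdetW, logdetXtWiX = self._gls(lam)
        return -0.5 * (
            (self.n - self.p) * math.log(sigma2)
            + logdetW
            + logdetXtWiX
            + rss / sigma2
        )

    def fit(self, lam_fixed: float | None = None):
        if lam_fixed is not None:
            lam = lam_fixed
        else:
            res = optimize.minimize_scalar(
                lambda u: self.profile_negloglik(math.exp(u)),
                bounds=(-30.0, 15.0),
                method="bounded",
                options={"xatol": 1e-10},
            )
            lam = math.exp(res.x)
            if self.profile_negloglik(0.0) <= res.fun:
                lam = 0.0
        beta, XtWiX, rss, _, _ = self._gls(lam)
        sigma2 = rss / (self.n - self.p)
        tau2 = lam * sigma2
        C = np.linalg.inv(XtWiX) * sigma2  # cov(beta_hat)
        return lam, beta, sigma2, tau2, C

    def beta_cov(self, tau2: float, sigma2: float) -> np.ndarray:
        lam = tau2 / sigma2
        _, XtWiX, _, _, _ = self._gls(lam)
        return np.linalg.inv(XtWiX) * sigma2


def _satterthwaite_df(
    reml: _RandomInterceptREML,
    ell: np.ndarray,
    theta: tuple[float, float],
    vcov_theta: np.ndarray,
    f_hat: float,
) -> float:
    """df = 2 f^2 / Var(f), f(theta) = l' C(theta) l, by central differences."""
    tau2, sigma2 = theta

    def f(t2: float, s2: float) -> float:
        return float(ell @ reml.beta_cov(max(t2, 0.0), s2) @ ell)

    h_t = max(tau2, 1e-3 * sigma2) * 1e-5
    h_s = sigma2 * 1e-5
    g = np.array(
        [
            (f(tau2 + h_t, sigma2) - f(max(tau2 - h_t, 0.0), sigma2))
            / (tau2 + h_t - max(tau2 - h_t, 0.0)),
            (f(tau2, sigma2 + h_s) - f(tau2, sigma2 - h_s)) / (2 * h_s),
        ]
    )
    var_f = float(g @ vcov_theta @ g)
    if var_f <= 0 or not math.isfinite(var_f):
        return float(reml.n - reml.p)
    return 2.0 * f_hat**2 / var_f


def _vcov_theta(reml: _RandomInterceptREML, tau2: float, sigma2: float) -> np.ndarray:
    """Asymptotic covariance of (tau2, sigma2): inverse observed REML information."""
    h_t = max(tau2 * 1e-4, sigma2 * 1e-6)
    h_s = sigma2 * 1e-4

    def ll(t2, s2):
        return reml.reml_loglik(max(t2, 0.0), s2)

    H = np.empty((2, 2))
    f0 = ll(tau2, sigma2)
    H[0, 0] = (ll(tau2 + h_t, sigma2) - 2 * f0 + ll(tau2 - h_t, sigma2)) / h_t**2
    H[1, 1] = (ll(tau2, sigma2 + h_s) - 2 * f0 + ll(tau2, sigma2 - h_s)) / h_s**2
    H[0, 1] = H[1, 0] = (
        ll(tau2 + h_t, sigma2 + h_s)
        - ll(tau2 + h_t, sigma2 - h_s)
        - ll(tau2 - h_t, sigma2 + h_s)
        + ll(tau2 - h_t, sigma2 - h_s)
    ) / (4 * h_t * h_s)
    info = -H
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(info)


def lmm_anova(
    data: pd.DataFrame,
    response: str,
    fixed: tuple[str, str],
    grouping: str,
    re_variance: float | None = None,
) -> AnovaTable:
    """Type-III mixed-model ANOVA: response ~ A * B + (1 | grouping).

    Parameters
    ----------
    data
        Long-format observations; rows with a missing response are dropped,
        all others are kept even when a participant misses a whole condition.
    response, fixed, grouping
        Column names: the numeric response, the two categorical factors, and
        the participant identifier carrying the random intercept.
    re_variance
        ``None`` estimates the random-intercept variance by REML.  A fixed
        value (notably 0.0, which reduces the model to ordinary least squares
        with classic residual df) bypasses estimation; useful for degenerate-
        limit checks.
    """
    fa, fb = fixed
    for col in (response, fa, fb, grouping):
        if col not in data.columns:
            raise InputError(f"column {col!r} not in data")
    df = data.loc[np.isfinite(pd.to_numeric(data[response], errors="coerce"))].reset_index(drop=True)
    if df[grouping].nunique() < 2:
        raise ModelError("need at least 2 participants for a random intercept")
    y = df[response].to_numpy(dtype=float)
    X, slices = _sum_coded_design(df, fa, fb)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("rank-deficient design matrix (empty or aliased cells)")
    reml = _RandomInterceptREML(y, X, df[grouping].to_numpy())

    if re_variance is None:
        lam, beta, sigma2, tau2, C = reml.fit()
    elif re_variance == 0.0:
        lam, beta, sigma2, tau2, C = reml.fit(lam_fixed=0.0)
        tau2 = 0.0
    else:
        if re_variance < 0:
            raise InputError("re_variance must be >= 0")
        # solve sigma^2 self-consistently for the fixed tau^2
        res = optimize.minimize_scalar(
            lambda ls: -reml.reml_loglik(re_variance, math.exp(ls)),
            bounds=(-30.0, 30.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        sigma2 = math.exp(res.x)
        lam = re_variance / sigma2
        beta, XtWiX, rss, _, _ = reml._gls(lam)
        tau2 = re_variance
        C = np.linalg.inv(XtWiX) * sigma2

    singular = re_variance == 0.0 or (re_variance is None and tau2 <= 1e-10 * sigma2)
    fallback_df = float(reml.n - reml.p)
    vcov = None if singular else _vcov_theta(reml, tau2, sigma2)

    rows = []
    for term, sl in slices.items():
        idx = np.arange(sl.start, sl.stop)
        q = idx.size
        Lb = beta[idx]
        Cll = C[np.ix_(idx, idx)]
        F = float(Lb @ np.linalg.solve(Cll, Lb) / q)
        if singular:
            den_df = fallback_df
        else:
            evals, evecs = np.linalg.eigh(Cll)
            nus = []
            for j in range(q):
                ell = np.zeros(X.shape[1])
                ell[idx] = evecs[:, j]
                nus.append(
                    _satterthwaite_df(reml, ell, (tau2, sigma2), vcov, float(evals[j]))
                )
            if q == 1:
                den_df = nus[0]
            else:
                usable = [nu for nu in nus if nu > 2.0]
                if usable:
                    E = sum(nu / (nu - 2.0) for nu in usable)
                    den_df = 2.0 * E / (E - q) if E > q else min(nus)
                else:
                    den_df = min(nus)
        den_df = float(min(max(den_df, 1.0), fallback_df))
        p = float(stats.f.sf(F, q, den_df))
        rows.append({"term": term, "F": F, "num_df": q, "den_df": den_df, "p": p})

    return AnovaTable(
        table=pd.DataFrame(rows, columns=["term", "F", "num_df", "den_df", "p"]),
        n_obs=reml.n,
        n_groups=len(reml.group_idx),
        sigma2=float(sigma2),
        tau2=float(tau2),
        singular=bool(singular),
        log_restricted_likelihood=float(reml.reml_loglik(max(tau2, 0.0), sigma2)),
    )
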