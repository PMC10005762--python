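"""Statistical layer: paired permutation t-tests (with max-statistic
multiple-comparison correction), paired Cohen's d, Spearman correlations,
random-intercept mixed models, adaptive FDR and Freedman–Diaconis binning.

All tests are two-sided.  Permutation p-values use the add-one correction
p = (1 + #{|t*| >= |t|}) / (n_perms + 1), so p is never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .spike_state import hazen_percentile

__all__ = [
    "ContrastResult",
    "CorrResult",
    "LMEResult",
    "paired_permutation_ttest",
    "paired_permutation_ttest_family",
    "cohens_d_paired",
    "spearman_corr",
    "lme_random_intercept",
    "adaptive_fdr",
    "fd_bin_count",
]


@dataclass(frozen=True)
class ContrastResult:
    """Paired contrast bundle: t statistic, permutation p, Cohen's d."""

    t: float
    p: float
    n: int
    n_perms: int
    cohens_d: float
    seed: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 pairs")
        lo = 1.0 / (self.n_perms + 1)
        if not lo - 1e-12 <= self.p <= 1.0 + 1e-12:
            raise ValueError("p outside [1/(n_perms+1), 1]")


@dataclass(frozen=True)
class CorrResult:
    rho: float
    p: float
    n: int

    def __post_init__(self):
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| must not exceed 1")


@dataclass(frozen=True)
class LMEResult:
    """Fixed-effect bundle from a random-intercept mixed model."""

    estimate: float
    se: float
    t: float
    p: float
    var_intercept: float
    n_obs: int
    n_groups: int

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")


def _paired_t(d: np.ndarray) -> float:
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(d.mean() / (sd / np.sqrt(d.size)))


def paired_permutation_ttest(x: np.ndarray, y: np.ndarray,
                             n_perms: int = 50_000, seed: int = 0) -> ContrastResult:
    """Paired-samples permutation t-test via random sign flips.

    The null distribution is built by flipping the sign of each paired
    difference independently; the two-sided p compares |t| against that
    distribution.  All differences zero is the documented degenerate case
    (t = 0, p = 1).
    """
    res = paired_permutation_ttest_family(
        np.column_stack([np.asarray(x, dtype=float) - np.asarray(y, dtype=float)]),
        n_perms=n_perms, seed=seed)
    return res[0]


def paired_permutation_ttest_family(diffs: np.ndarray, n_perms: int = 50_000,
                                    seed: int = 0) -> list[ContrastResult]:
    """Family of paired contrasts with max-|t| multiple-comparison correction.

    ``diffs`` is (n_pairs, n_measures) of paired differences.  One set of
    sign flips is shared across measures; each measure's p compares its
    observed |t| with the permutation distribution of the maximum |t| across
    the family (for a single column this reduces to the uncorrected test).
    """
    d = np.atleast_2d(np.asarray(diffs, dtype=float))
    if d.ndim != 2:
        raise ValueError("diffs must be (n_pairs, n_measures)")
    n, m = d.shape
    if n < 2:
        raise ValueError("need at least 2 pairs")
    t_obs = np.array([_paired_t(d[:, j]) for j in range(m)])

    rng = np.random.default_rng(seed)
    max_abs_t = np.empty(n_perms)
    chunk = max(1, min(n_perms, 4_000_000 // (n * m + 1)))
    done = 0
    sqrt_n = np.sqrt(n)
    while done < n_perms:
        k = min(chunk, n_perms - done)
        signs = rng.integers(0, 2, size=(k, n)) * 2 - 1          # (k, n)
        flipped = signs[:, :, None] * d[None, :, :]              # (k, n, m)
        mean = flipped.mean(axis=1)
        sd = flipped.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.where(sd > 0, mean / (sd / sqrt_n), 0.0)
        max_abs_t[done:done + k] = np.abs(t_perm).max(axis=1)
        done += k

    results = []
    for j in range(m):
        dj = d[:, j]
        if np.all(dj == 0):
            t, p, cd = 0.0, 1.0, 0.0
        else:
            t = t_obs[j]
            p = float((1 + np.sum(max_abs_t >= abs(t))) / (n_perms + 1))
            sd = dj.std(ddof=1)
            cd = float(dj.mean() / sd) if sd > 0 else 0.0
        results.append(ContrastResult(t=float(t), p=p, n=n, n_perms=n_perms,
                                      cohens_d=cd, seed=seed))
    return results


def cohens_d_paired(x: np.ndarray, y: np.ndarray) -> float:
    """d = mean(x - y) / sd(x - y), sample SD with the n-1 denominator."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    return float(d.mean() / sd)


def spearman_corr(x: np.ndarray, y: np.ndarray) -> CorrResult:
    """Spearman rank correlation (mid-ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = sstats.spearmanr(x, y)
    return CorrResult(rho=float(rho), p=float(p), n=int(x.size))


def lme_random_intercept(values: np.ndarray, condition: np.ndarray,
                         group: np.ndarray) -> LMEResult:
    """value ~ condition + (1 | group), fitted by maximum likelihood.

    ``condition`` may be two-level categorical or numeric; the returned
    fixed effect is the condition slope (for a 0/1 coding, the adjusted
    between-condition difference).  p comes from the t statistic with
    residual degrees of freedom.  A singular random-intercept fit falls
    back to zero intercept variance with a warning.
    """
    import statsmodels.api as sm  # deferred: heavy import

    values = np.asarray(values, dtype=float)
    condition = np.asarray(condition)
    group = np.asarray(group)
    if not values.size == condition.size == group.size:
        raise ValueError("values, condition and group must be equal length")
    levels = pd.unique(condition)
    if np.issubdtype(np.asarray(condition).dtype, np.number):
        cond_num = condition.astype(float)
    else:
        if levels.size != 2:
            raise ValueError("categorical condition must be two-level")
        cond_num = (condition == levels[1]).astype(float)
    groups_unique = pd.unique(group)
    if groups_unique.size < 2:
        raise ValueError("need at least 2 groups")

    df = pd.DataFrame({"value": values, "cond": cond_num, "group": group})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula("value ~ cond", groups="group", data=df)
        try:
            fit = model.fit(reml=False)
        except Exception:
            fit = None
        if fit is None or not np.isfinite(fit.bse["cond"]):
            warnings.warn("singular mixed-model fit; falling back to "
                          "zero-variance random intercept (OLS)", stacklevel=2)
            ols = sm.OLS(df["value"], sm.add_constant(df["cond"])).fit()
            est, se = float(ols.params["cond"]), float(ols.bse["cond"])
            var_int = 0.0
        else:
            est, se = float(fit.params["cond"]), float(fit.bse["cond"])
            var_int = float(fit.cov_re.iloc[0, 0])
    t = est / se
    df_resid = values.size - 2
    p = float(2 * sstats.t.sf(abs(t), df_resid))
    return LMEResult(estimate=est, se=se, t=float(t), p=p,
                     var_intercept=var_int, n_obs=int(values.size),
                     n_groups=int(groups_unique.size))


def adaptive_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Two-stage adaptive linear step-up FDR procedure.

    Stage 1 runs the linear step-up procedure at q' = q/(1+q) to estimate
    the number of true nulls m0 = m - r1; stage 2 re-runs it at q'*m/m0.
    Returns a boolean rejection mask.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    reject, *_ = multipletests(p, alpha=q, method="fdr_tsbky")
    return reject


def fd_bin_count(data: np.ndarray) -> int:
    """Freedman–Diaconis histogram bin count.

    width = 2 IQR n^(-1/3) with the Hazen percentile convention; bins =
    ceil(range / width).  Zero IQR falls back to a single bin with a
    warning.
    """
    data = np.asarray(data, dtype=float)
    if data.size < 2:
        raise ValueError("need at least 2 data points")
    rng_ = data.max() - data.min()
    if rng_ <= 0:
        raise ValueError("data range must be positive")
    iqr = float(hazen_percentile(data, 75) - hazen_percentile(data, 25))
    if iqr == 0:
        warnings.warn("zero IQR; falling back to a single bin", stacklevel=2)
        return 1
    width = 2.0 * iqr * data.size ** (-1.0 / 3.0)
    return int(np.ceil(rng_ / width))
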