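"""Statistical comparisons for the motor-status analysis.

Paired band-power contrasts use the Wilcoxon signed-rank test (exact null
for small n) with Bonferroni correction across the eight bands of a region.
Within-subject comparisons of the freezing index and walking speed across
gait conditions use the Friedman test with Conover's post-hoc pairwise test.
The speed-beta relation is modelled with a linear mixed-effects model
(random intercept per subject, REML).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import (InsufficientDataError, InvalidArgumentError,
                     UndefinedStatisticError)

__all__ = [
    "StatResult",
    "LmmFit",
    "wilcoxon_paired",
    "bonferroni",
    "friedman_conover",
    "spearman",
    "lmm_speed_beta",
]


@dataclass
class StatResult:
    test: str
    statistic: float
    p: float
    n: int
    comparison: str = ""
    p_adjusted: float | None = None

    def adjust(self, m: int) -> "StatResult":
        self.p_adjusted = bonferroni([self.p], m)[0]
        return self


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------

def wilcoxon_paired(x, y, comparison: str = "") -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded (classic convention).  The exact null
    distribution is enumerated for n <= 25; the normal approximation is used
    above.  At n = 9 with all differences of one sign the exact two-sided
    p is 2/512, and 4/512 for W = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be equal-length 1-D samples")
    d = x - y
    d = d[d != 0]
    if d.size < 5:
        raise InsufficientDataError(
            f"need >= 5 nonzero differences, got {d.size}")
    method = "exact" if d.size <= 25 else "approx"
    res = _st.wilcoxon(d, alternative="two-sided", method=method)
    return StatResult(test="wilcoxon_signed_rank", statistic=float(res.statistic),
                      p=float(res.pvalue), n=int(d.size), comparison=comparison)


def bonferroni(p_values, m: int) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, p * m)."""
    p_values = list(np.atleast_1d(np.asarray(p_values, dtype=float)))
    if m < len(p_values):
        raise InvalidArgumentError("family size m must be >= number of tests")
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise InvalidArgumentError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, p * m))
    return out


# --------------------------------------------------------------------------
# Friedman + Conover post hoc
# --------------------------------------------------------------------------

def friedman_conover(matrix, condition_names: list[str] | None = None,
                     ) -> tuple[StatResult, list[StatResult]]:
    """Friedman omnibus test with Conover's all-pairs post-hoc test.

    ``matrix`` is subjects x conditions with no missing cells.  Conover's
    pairwise statistic compares column rank sums against a t distribution on
    (n-1)(k-1) degrees of freedom with the Friedman-adjusted variance.  Being
    rank-based, the result is invariant under any strictly monotone transform
    applied to all cells.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise InvalidArgumentError("matrix must be 2-D (subjects x conditions)")
    n, k = m.shape
    if k < 3:
        raise InvalidArgumentError("need >= 3 conditions")
    if n < 5:
        raise InsufficientDataError("need >= 5 subjects")
    if not np.all(np.isfinite(m)):
        raise InvalidArgumentError("missing cells are not allowed")
    names = condition_names or [f"cond{j}" for j in range(k)]

    ranks = np.apply_along_axis(_st.rankdata, 1, m)
    rank_sums = ranks.sum(axis=0)
    a1 = float(np.sum(ranks ** 2))
    c1 = n * k * (k + 1) ** 2 / 4.0

    if np.isclose(a1, c1):
        # all cells tied within every row: no information, chi^2 = 0
        omnibus = StatResult("friedman", 0.0, 1.0, n, "omnibus")
        pairwise = [StatResult("conover", 0.0, 1.0, n, f"{a} vs {b}")
                    for a, b in itertools.combinations(names, 2)]
        return omnibus, pairwise

    chi2 = (k - 1) * float(np.sum((rank_sums - n * (k + 1) / 2.0) ** 2)) / (a1 - c1)
    p_omni = float(_st.chi2.sf(chi2, k - 1))
    omnibus = StatResult("friedman", chi2, p_omni, n, "omnibus")

    df = (n - 1) * (k - 1)
    denom2 = 2.0 * n * (a1 - c1) / df * max(1.0 - chi2 / (n * (k - 1)), 1e-12)
    denom = np.sqrt(denom2)
    pairwise = []
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        t_stat = abs(rank_sums[i] - rank_sums[j]) / denom
        p = float(2.0 * _st.t.sf(t_stat, df))
        pairwise.append(StatResult("conover", float(t_stat), min(p, 1.0), n,
                                   f"{a} vs {b}"))
    return omnibus, pairwise


# --------------------------------------------------------------------------
# Spearman correlation
# --------------------------------------------------------------------------

def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p for the Spearman correlation (n <= 9).

    Enumerates all n! orderings of y; average ranks make this valid under
    ties as well.
    """
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]                                   # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(rxc ** 2) * np.sum(ryc ** 2, axis=1))
    rhos = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman(x, y, comparison: str = "") -> StatResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p-value: exact permutation null for n <= 9, t-approximation
    above.  Raises for constant input (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be equal-length 1-D samples")
    n = x.size
    if n < 5:
        raise InsufficientDataError("need n >= 5")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("correlation undefined for constant input")
    rx = _st.rankdata(x)
    ry = _st.rankdata(y)
    rho = float(_st.pearsonr(rx, ry).statistic)
    if n <= 9:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t_stat = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
            p = float(2.0 * _st.t.sf(abs(t_stat), n - 2))
    return StatResult(test="spearman", statistic=rho, p=p, n=n,
                      comparison=comparison)


# --------------------------------------------------------------------------
# Linear mixed-effects model: speed ~ beta power + medication + (1 | subject)
# --------------------------------------------------------------------------

@dataclass
class LmmFit:
    coef: dict            # name -> estimate
    se: dict              # name -> standard error
    p: dict               # name -> two-sided p
    conf_int: dict        # name -> (low, high), 95%
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_subjects: int
    singular: bool = False


def lmm_speed_beta(data: pd.DataFrame, speed_col: str = "speed",
                   beta_col: str = "beta_power", med_col: str = "med_state",
                   subject_col: str = "subject") -> LmmFit:
    """REML fit of speed = b0 + b1*beta + b2*medication + u_subject + e.

    ``med_col`` may be categorical ("Moff"/"Mon", coded 0/1) or already
    numeric.  Requires >= 3 subjects with >= 2 observations each.  A
    boundary fit with zero between-subject variance is returned with the
    ``singular`` flag set (with a warning) rather than raising.
    """
    import statsmodels.formula.api as smf

    df = data[[speed_col, beta_col, med_col, subject_col]].dropna().copy()
    counts = df[subject_col].value_counts()
    if (counts >= 2).sum() < 3:
        raise InsufficientDataError(
            "need >= 2 observations per subject for >= 3 subjects")
    if df[med_col].dtype == object:
        df["_med"] = (df[med_col] == "Mon").astype(float)
    else:
        df["_med"] = df[med_col].astype(float)
    df = df.rename(columns={speed_col: "_speed", beta_col: "_beta",
                            subject_col: "_subject"})

    has_med = df["_med"].nunique() > 1
    formula = "_speed ~ _beta + _med" if has_med else "_speed ~ _beta"
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups=df["_subject"])
        fit = model.fit(reml=True)
    boundary = any("boundary" in str(w.message) for w in caught)

    names = {"Intercept": "intercept", "_beta": "beta_power"}
    if has_med:
        names["_med"] = "medication"
    coef, se, p, ci = {}, {}, {}, {}
    conf = fit.conf_int()
    for raw, pretty in names.items():
        coef[pretty] = float(fit.params[raw])
        se[pretty] = float(fit.bse[raw])
        p[pretty] = float(fit.pvalues[raw])
        ci[pretty] = (float(conf.loc[raw, 0]), float(conf.loc[raw, 1]))
    re_var = float(np.asarray(fit.cov_re)[0, 0])
    # boundary fit: between-subject variance negligible vs residual variance,
    # or the optimizer itself reported a boundary solution
    singular = boundary or re_var <= 1e-2 * float(fit.scale)
    if singular:
        warnings.warn("singular fit: zero between-subject variance",
                      stacklevel=2)
    return LmmFit(coef=coef, se=se, p=p, conf_int=ci,
                  random_intercept_var=re_var, residual_var=float(fit.scale),
                  n_obs=int(len(df)), n_subjects=int(df["_subject"].nunique()),
                  singular=singular)
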