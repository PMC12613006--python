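"""Which drugs are predictable?  Response-distribution statistics,
predictable/unpredictable stratification, and median regression of
per-task performance on mechanism-of-action and tissue indicators with
permutation inference and bootstrap confidence intervals.

The median regression Median(SCC^dt) = β₀ + β₁·D_MoA + β₂·D_Tissue + ε is
least-absolute-deviations (quantile τ = 0.5); inference is by response
permutation (empirical p-values with the +1 correction) followed by
Benjamini-Hochberg FDR adjustment, and case-resampling bootstrap for
percentile CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.quantile_regression import QuantReg
from statsmodels.stats.multitest import multipletests

from .utils import rng_for

BIMODALITY_THRESHOLD = 5.0 / 9.0   # uniform-reference cut for Sarle's BC


@dataclass
class ResponseDistributionStats:
    std: float
    bc: float
    dc: float
    n: int


@dataclass
class MedianRegressionResult:
    coefficients: pd.Series
    p_values: pd.Series | None = None
    q_values: pd.Series | None = None
    ci_low: pd.Series | None = None
    ci_high: pd.Series | None = None


def distribution_stats(values, n_bins: int = 20) -> ResponseDistributionStats:
    """STD, Sarle's bimodality coefficient and density coverage.

    BC = (g₁² + 1) / (g₂ + 3(n−1)²/((n−2)(n−3))) with bias-corrected sample
    skewness g₁ and excess kurtosis g₂; values above 5/9 suggest
    bimodality.  DC is the fraction of ``n_bins`` equal-width bins over the
    observed range containing at least one observation (1.0 for a
    zero-range sample, which occupies its single degenerate bin).
    """
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 for the bimodality coefficient")
    std = float(np.std(x, ddof=1))
    if np.ptp(x) == 0:   # degenerate sample: moments are undefined
        return ResponseDistributionStats(std=0.0, bc=float("nan"), dc=1.0, n=n)
    g1 = float(stats.skew(x, bias=False))
    g2 = float(stats.kurtosis(x, bias=False))
    bc = (g1 ** 2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    counts, _ = np.histogram(x, bins=n_bins)
    dc = float((counts > 0).mean())
    return ResponseDistributionStats(std=std, bc=float(bc), dc=dc, n=n)


def stratify_drugs(scc_by_drug: dict[str, float]) -> tuple[set, set]:
    """Quartile split into predictable (top 25%) and unpredictable (bottom
    25%) drugs by SCC^d; boundary ties are included in the stratum."""
    if len(scc_by_drug) < 4:
        raise ValueError("need at least 4 drugs to stratify")
    values = np.array(list(scc_by_drug.values()), dtype=np.float64)
    lo = np.quantile(values, 0.25)
    hi = np.quantile(values, 0.75)
    predictable = {d for d, v in scc_by_drug.items() if v >= hi}
    unpredictable = {d for d, v in scc_by_drug.items() if v <= lo}
    return predictable, unpredictable


# ----------------------------------------------------------------------
# median regression of task predictability
# ----------------------------------------------------------------------

def build_design(task_table: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Indicator design from a task table (columns scc_dt, moa, tissue).

    One binary column per MoA class and tissue, dropping the first
    (alphabetical) category of each factor as the reference; plus an
    intercept.  Raises on rank deficiency, naming the collinear columns.
    """
    y = task_table["scc_dt"].astype(float)
    parts = [pd.Series(1.0, index=task_table.index, name="intercept")]
    for factor, prefix in (("moa", "moa"), ("tissue", "tissue")):
        if factor in task_table.columns:
            dummies = pd.get_dummies(task_table[factor].astype(str),
                                     prefix=prefix, drop_first=True,
                                     dtype=float)
            parts.append(dummies)
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by greedy elimination
        bad = []
        keep: list[str] = []
        for col in X.columns:
            sub = X[keep + [col]].to_numpy()
            if np.linalg.matrix_rank(sub) == len(keep) + 1:
                keep.append(col)
            else:
                bad.append(col)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return y, X


def median_regression(y: pd.Series, X: pd.DataFrame) -> pd.Series:
    """Least-absolute-deviations fit (quantile regression at τ = 0.5)."""
    if len(y) <= X.shape[1]:
        raise ValueError("need more rows than design columns")
    model = QuantReg(np.asarray(y, dtype=float), X.to_numpy())
    res = model.fit(q=0.5)
    return pd.Series(res.params, index=X.columns, name="coef")


def permutation_inference(y: pd.Series, X: pd.DataFrame,
                          iterations: int = 1000, seed: int = 0,
                          alpha: float = 0.05) -> MedianRegressionResult:
    """Permutation p-values for each coefficient plus BH-FDR q-values.

    The null resamples the response across rows; p = (1 + #{|β*| ≥ |β̂|}) /
    (1 + iterations).  The intercept is not tested.
    """
    coefs = median_regression(y, X)
    tested = [c for c in X.columns if c != "intercept"]
    observed = coefs[tested].abs()
    rng = rng_for(seed, "permutation")
    exceed = pd.Series(0, index=tested, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    for _ in range(iterations):
        y_perm = pd.Series(rng.permutation(y_arr), index=y.index)
        null_coefs = median_regression(y_perm, X)
        exceed += (null_coefs[tested].abs() >= observed).astype(float)
    p = (1.0 + exceed) / (1.0 + iterations)
    q = pd.Series(multipletests(p.to_numpy(), alpha=alpha, method="fdr_bh")[1],
                  index=tested)
    return MedianRegressionResult(coefficients=coefs, p_values=p, q_values=q)


def bootstrap_ci(y: pd.Series, X: pd.DataFrame, replicates: int = 1000,
                 seed: int = 0, level: float = 0.95) -> MedianRegressionResult:
    """Case-resampling percentile confidence intervals per coefficient."""
    coefs = median_regression(y, X)
    rng = rng_for(seed, "bootstrap")
    n = len(y)
    draws = np.empty((replicates, X.shape[1]))
    y_arr, X_arr = np.asarray(y, dtype=float), X.to_numpy()
    for b in range(replicates):
        idx = rng.integers(0, n, size=n)
        res = QuantReg(y_arr[idx], X_arr[idx]).fit(q=0.5)
        draws[b] = res.params
    lo = (1.0 - level) / 2.0
    ci_low = pd.Series(np.quantile(draws, lo, axis=0), index=X.columns)
    ci_high = pd.Series(np.quantile(draws, 1.0 - lo, axis=0), index=X.columns)
    return MedianRegressionResult(coefficients=coefs, ci_low=ci_low,
                                  ci_high=ci_high)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment (thin wrapper, kept for direct use)."""
    return multipletests(np.asarray(p_values, dtype=float),
                         method="fdr_bh")[1]
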