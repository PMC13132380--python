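"""Quantitative between-condition comparison of promoter mark intensities.

Follows the MAnorm recipe: express each gene as an (M, A) pair — M the log2
intensity ratio between conditions, A the mean log2 intensity — fit a linear
M ~ A trend on the *common* promoters (occupied in both conditions) and
rescale condition 2 so that common promoters centre on M = 0.  Per-gene
significance then comes from an exact conditional count test on the rounded
normalized intensities, and a change is called when p < alpha and
|log2FC| >= lfc_threshold (0.58 ~ 1.5-fold), the FC boundary inclusive.

The null model for two counts x1, x2 of a gene with no true change is

    P(y | x) = (x + y)! / (x! * y! * 2^(x + y + 1)),

equivalently, conditional on the total t = x1 + x2, x1 ~ Binomial(t, 1/2).
The two-sided p-value doubles the smaller conditional-binomial tail, which
makes it exactly symmetric in its arguments.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ma_transform",
    "null_count_log_pmf",
    "exact_count_pvalue",
    "MAnormScaler",
    "call_differential",
]


def ma_transform(x1, x2, pseudocount: float = 1.0):
    """Map intensity pairs to (M, A) = (log2 ratio, mean log2 intensity).

    ``M = log2((x1+c)/(x2+c))`` and ``A = 0.5*(log2(x1+c) + log2(x2+c))``
    with pseudocount ``c``.  Inputs must be finite and non-negative
    (strictly positive when ``c = 0``).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(~np.isfinite(x1)) or np.any(~np.isfinite(x2)):
        raise ValueError("intensities must be finite")
    if np.any(x1 < 0) or np.any(x2 < 0):
        raise ValueError("intensities must be non-negative")
    if pseudocount < 0 or (pseudocount == 0 and (np.any(x1 == 0) or np.any(x2 == 0))):
        raise ValueError("zero intensities require a positive pseudocount")
    l1 = np.log2(x1 + pseudocount)
    l2 = np.log2(x2 + pseudocount)
    return l1 - l2, 0.5 * (l1 + l2)


def null_count_log_pmf(y, x):
    """log P(y | x) under the exact conditional count null.

    ``P(y|x) = (x+y)! / (x! y! 2^(x+y+1))`` — the distribution of the second
    count given the first when both arise from the same underlying rate.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    return (
        gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log(2.0)
    )


def _as_counts(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if not np.all(np.isfinite(np.asarray(arr, dtype=float))):
        raise ValueError(f"{name} must be finite")
    rounded = np.rint(np.asarray(arr, dtype=float))
    if np.any(np.abs(np.asarray(arr, dtype=float) - rounded) > 1e-8):
        raise ValueError(f"{name} must be integer-valued")
    if np.any(rounded < 0):
        raise ValueError(f"{name} must be non-negative")
    return rounded.astype(np.int64)


def exact_count_pvalue(x1, x2):
    """Two-sided exact p-value for a pair of counts under the shared-rate null.

    Conditional on the total, the first count is Binomial(x1+x2, 1/2); the
    p-value is ``min(1, 2*min(lower tail, upper tail))``, both tails
    including the observed value.  Symmetric: p(x1, x2) == p(x2, x1).
    Accepts scalars or arrays (broadcast); returns float or ndarray.
    """
    c1 = _as_counts(x1, "x1")
    c2 = _as_counts(x2, "x2")
    t = c1 + c2
    # evaluate the tails at the smaller count: mathematically equivalent by
    # the symmetry of Binomial(t, 1/2), and exactly symmetric in floating
    # point because swapped arguments take the identical code path
    m = np.minimum(c1, c2)
    lower = stats.binom.cdf(m, t, 0.5)
    upper = stats.binom.sf(m - 1, t, 0.5)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    if np.isscalar(x1) and np.isscalar(x2):
        return float(p)
    return p


class MAnormScaler(BaseEstimator, TransformerMixin):
    """Linear M-A rescaling of condition 2 onto condition 1.

    Fits ``M = a + b*A`` by least squares on the common promoters (both raw
    intensities strictly positive), optionally with one robust pass dropping
    points whose residual exceeds ``outlier_mad`` scaled MADs, then rescales
    condition 2 by ``x2' = x2 * 2^(a + b*A)``.  The fit uses pseudocount 0
    (common promoters are strictly positive, so the model is exact on
    noise-free proportionally scaled data).

    Parameters
    ----------
    min_common : int
        Minimum number of common promoters required to fit.
    robust : bool
        Enable the single MAD-based outlier-trimming refit pass.
    outlier_mad : float
        Residual cutoff in units of the scaled MAD.

    Attributes
    ----------
    intercept_, slope_ : float
        Fitted a and b.
    scale_factor_ : float
        Implied global intensity ratio of condition 2 over condition 1,
        ``2**(-intercept_)``.
    median_m_ : float
        Median M on the common promoters after rescaling (should be ~0).
    n_common_ : int
        Number of common promoters used in the final fit.
    """

    def __init__(self, min_common: int = 10, robust: bool = True, outlier_mad: float = 3.0):
        self.min_common = min_common
        self.robust = robust
        self.outlier_mad = outlier_mad

    def _common_mask(self, X: np.ndarray) -> np.ndarray:
        return (X[:, 0] > 0) & (X[:, 1] > 0)

    def fit(self, X, y=None):
        X = self._validate(X)
        common = self._common_mask(X)
        if common.sum() < self.min_common:
            raise ValueError(
                f"only {int(common.sum())} common promoters; "
                f"need >= {self.min_common} to fit the normalization"
            )
        M, A = ma_transform(X[common, 0], X[common, 1], pseudocount=0.0)
        if np.ptp(A) < 1e-12:
            raise ValueError(
                "all common promoters share one A value; intensity input is "
                "degenerate (constant columns?)"
            )
        a, b = self._ols(A, M)
        if self.robust:
            resid = M - (a + b * A)
            mad = np.median(np.abs(resid - np.median(resid))) * 1.4826
            if mad > 0:
                keep = np.abs(resid) <= self.outlier_mad * mad
                if keep.sum() >= self.min_common and np.ptp(A[keep]) > 1e-12:
                    a, b = self._ols(A[keep], M[keep])
                    common_idx = np.flatnonzero(common)[keep]
                    common = np.zeros(len(X), dtype=bool)
                    common[common_idx] = True
        self.intercept_ = float(a)
        self.slope_ = float(b)
        self.scale_factor_ = float(2.0 ** (-a))
        self.n_common_ = int(common.sum())
        self._common_fit_mask = common
        M_after, _ = ma_transform(
            X[common, 0], self.transform(X)[common, 1], pseudocount=0.0
        )
        self.median_m_ = float(np.median(M_after))
        if abs(self.median_m_) > 0.05:
            warnings.warn(
                f"post-normalization median M on common promoters is "
                f"{self.median_m_:.3f} (expected within +/-0.05 of 0)",
                stacklevel=2,
            )
        return self

    def transform(self, X):
        X = self._validate(X)
        a, b = self.intercept_, self.slope_
        x1, x2 = X[:, 0], X[:, 1]
        # A with pseudocount 0 where both positive; fall back to c=1 at zeros
        both = (x1 > 0) & (x2 > 0)
        A = np.empty(len(X))
        _, A_pos = ma_transform(x1[both], x2[both], pseudocount=0.0)
        A[both] = A_pos
        if np.any(~both):
            _, A_zero = ma_transform(x1[~both], x2[~both], pseudocount=1.0)
            A[~both] = A_zero
        out = X.copy()
        out[:, 1] = x2 * 2.0 ** (a + b * A)
        return out

    @staticmethod
    def _ols(A: np.ndarray, M: np.ndarray) -> tuple[float, float]:
        b, a = np.polyfit(A, M, 1)
        return float(a), float(b)

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected an (n_genes, 2) intensity array")
        if np.any(~np.isfinite(X)) or np.any(X < 0):
            raise ValueError("intensities must be finite and non-negative")
        return X


def call_differential(
    signal_cond1: pd.Series,
    signal_cond2: pd.Series,
    genes=None,
    alpha: float = 0.05,
    lfc_threshold: float = 0.58,
    pseudocount: float = 1.0,
    mark: str | None = None,
    fdr: bool = False,
    scaler: MAnormScaler | None = None,
) -> pd.DataFrame:
    """Normalize, test and threshold per-promoter mark changes.

    The two columns must share one gene universe; ``genes`` optionally
    restricts the analysis (e.g. to the bona fide bivalent set).  Output is a
    DataFrame indexed by gene_id with columns ``x1``, ``x2_normalized``,
    ``log2FC`` (M after normalization, pseudocount applied), ``A``,
    ``p_value``, ``significant`` and ``direction``; significance requires
    p < alpha (strict) and |log2FC| >= lfc_threshold (inclusive).  ``fdr``
    adds a Benjamini-Hochberg ``q_value`` column and bases ``significant`` on
    it — an extension beyond the raw-p rule, off by default.
    """
    if not signal_cond1.index.equals(signal_cond2.index):
        if set(signal_cond1.index) != set(signal_cond2.index):
            raise ValueError("gene universes of the two conditions differ")
        signal_cond2 = signal_cond2.loc[signal_cond1.index]
    if genes is not None:
        genes = [g for g in signal_cond1.index if g in set(genes)]
        signal_cond1 = signal_cond1.loc[genes]
        signal_cond2 = signal_cond2.loc[genes]
        if len(signal_cond1) == 0:
            raise ValueError("no requested genes present in the signal columns")
    X = np.column_stack([signal_cond1.to_numpy(float), signal_cond2.to_numpy(float)])
    if scaler is None:
        scaler = MAnormScaler()
    scaler.fit(X)
    Xn = scaler.transform(X)
    x1, x2n = Xn[:, 0], Xn[:, 1]
    M, A = ma_transform(x1, x2n, pseudocount=pseudocount)
    p = exact_count_pvalue(np.rint(x1), np.rint(x2n))
    result = pd.DataFrame(
        {
            "x1": x1,
            "x2_normalized": x2n,
            "log2FC": M,
            "A": A,
            "p_value": p,
        },
        index=signal_cond1.index,
    )
    if mark is not None:
        result.insert(0, "mark", mark)
    crit_p = result["p_value"] < alpha
    if fdr:
        from statsmodels.stats.multitest import multipletests

        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
        crit_p = result["q_value"] < alpha
    big = np.abs(result["log2FC"]) >= lfc_threshold
    result["significant"] = crit_p & big
    result["direction"] = np.where(
        result["significant"] & (result["log2FC"] > 0),
        "up",
        np.where(result["significant"], "down", "none"),
    )
    result.attrs["scaler"] = scaler
    return result
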