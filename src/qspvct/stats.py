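"""Statistical layer: PRCC sensitivity analysis, binomial intervals,
small-cohort bootstrap, rank tests and ROC biomarker analysis.

These are the analysis primitives applied to virtual-trial output:
partial rank correlation coefficients (PRCC) between sampled parameters
and post-treatment observations, Agresti–Coull confidence intervals for
response proportions, the percentile bootstrap for small trial arms,
Wilcoxon rank-sum comparisons between responders and non-responders,
and ROC curves for candidate predictive biomarkers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# PRCC
# ---------------------------------------------------------------------------

@dataclass
class PRCCResult:
    parameters: list[str]
    prcc: np.ndarray  # (n_params,) or (n_params, n_outputs)
    p_values: np.ndarray

    def as_frame(self, output_names=None):
        import pandas as pd

        prcc = np.atleast_2d(self.prcc.T).T
        pv = np.atleast_2d(self.p_values.T).T
        cols = output_names or [f"output_{j}" for j in range(prcc.shape[1])]
        df = pd.DataFrame(prcc, index=self.parameters, columns=cols)
        for j, c in enumerate(cols):
            df[f"p_{c}"] = pv[:, j]
        return df


def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, axis=0)


def prcc(X: np.ndarray, y: np.ndarray, parameter_names=None) -> PRCCResult:
    """Partial rank correlation of each column of X with y.

    All variables are rank-transformed; the coefficient for parameter j
    is the Pearson correlation of the residuals of rank(x_j) and
    rank(y) after linear regression on the ranks of the remaining
    parameters.  p-values use the t approximation with n − k − 2
    degrees of freedom (k conditioning variables).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y must share the first dimension")
    if n < m + 2:
        raise ValueError("need at least n_params + 2 rows")
    names = list(parameter_names) if parameter_names is not None else [
        f"x{j}" for j in range(m)
    ]
    for j in range(m):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"constant column {names[j]!r}")
    if np.ptp(y) == 0:
        raise ValueError("constant output vector")

    R = _rank(X)
    ry = _rank(y)
    coeffs = np.empty(m)
    pvals = np.empty(m)
    dof = n - (m - 1) - 2
    for j in range(m):
        others = np.delete(R, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        res_x = R[:, j] - A @ np.linalg.lstsq(A, R[:, j], rcond=None)[0]
        res_y = ry - A @ np.linalg.lstsq(A, ry, rcond=None)[0]
        denom = np.linalg.norm(res_x) * np.linalg.norm(res_y)
        r = float(res_x @ res_y / denom) if denom > 0 else 0.0
        r = max(min(r, 1.0), -1.0)
        coeffs[j] = r
        if dof <= 0 or abs(r) >= 1.0:
            pvals[j] = 0.0 if abs(r) >= 1.0 else 1.0
        else:
            t = r * math.sqrt(dof / (1.0 - r * r))
            pvals[j] = 2.0 * sps.t.sf(abs(t), dof)
    return PRCCResult(parameters=names, prcc=coeffs, p_values=pvals)


def prcc_matrix(X: np.ndarray, Y: np.ndarray, parameter_names=None, output_names=None):
    """PRCC of every parameter against every output column."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    results = [prcc(X, Y[:, j], parameter_names) for j in range(Y.shape[1])]
    return PRCCResult(
        parameters=results[0].parameters,
        prcc=np.column_stack([r.prcc for r in results]),
        p_values=np.column_stack([r.p_values for r in results]),
    )


# ---------------------------------------------------------------------------
# binomial proportion machinery
# ---------------------------------------------------------------------------

def agresti_coull_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Agresti–Coull interval for a binomial proportion, clipped to [0, 1]."""
    if not 0 <= x <= n or n < 1:
        raise ValueError("require 0 <= x <= n, n >= 1")
    z = sps.norm.ppf(0.5 + level / 2.0)
    n_t = n + z * z
    p_t = (x + z * z / 2.0) / n_t
    half = z * math.sqrt(p_t * (1.0 - p_t) / n_t)
    return (max(p_t - half, 0.0), min(p_t + half, 1.0))


def bootstrap_orr_ci(
    responders: int,
    cohort: int,
    sample_size: int = 15,
    reps: int = 100_000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the response proportion in small arms.

    Draws ``sample_size`` patients with replacement from a cohort with
    the given responder count, ``reps`` times; the interval is the pure
    order-statistic (no interpolation) 2.5/97.5 percentile of the
    per-sample response proportion — sample proportions live on a
    1/sample_size grid, and interpolation would fabricate unattainable
    values.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    if not 0 <= responders <= cohort:
        raise ValueError("responders must be within [0, cohort]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = responders / cohort
    counts = rng.binomial(sample_size, p, size=reps)
    props = np.sort(counts / sample_size)
    alpha = (1.0 - level) / 2.0
    lo_idx = max(int(math.ceil(alpha * reps)) - 1, 0)
    hi_idx = min(int(math.ceil((1.0 - alpha) * reps)) - 1, reps - 1)
    return float(props[lo_idx]), float(props[hi_idx])


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

EXACT_MAX_N = 12  # exact enumeration up to this total sample size


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided rank-sum test with midranks for ties.

    Exact enumeration of all label assignments when n_a + n_b ≤ 12;
    otherwise the normal approximation with continuity and tie
    correction.  Returns (rank-sum statistic of sample a, p two-sided).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:na].sum())

    if na + nb <= EXACT_MAX_N:
        mu = na * (na + nb + 1) / 2.0
        dev = abs(w - mu)
        total = 0
        extreme = 0
        idx = range(na + nb)
        for comb in combinations(idx, na):
            ws = ranks[list(comb)].sum()
            total += 1
            if abs(ws - mu) >= dev - 1e-12:
                extreme += 1
        return w, extreme / total

    mu = na * (na + nb + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    n = na + nb
    tie_term = ((counts**3 - counts).sum()) / ((n) * (n - 1))
    var = na * nb / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    return w, 2.0 * sps.norm.sf(max(z, 0.0))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    cutoffs: np.ndarray
    tpr: np.ndarray  # sensitivity
    fpr: np.ndarray  # 1 - specificity
    auc: float


def roc_curve(values, labels, higher_is_positive: bool = True) -> ROCResult:
    """ROC over all distinct cutoff values of a biomarker.

    ``labels`` are truthy for responders.  Orientation follows the
    biomarker's stated direction (it is NOT flipped to force AUC ≥ 0.5);
    with ``higher_is_positive`` the classifier is value ≥ cutoff.  AUC
    is the trapezoid over the curve and equals the Mann–Whitney
    U-statistic / (n₁·n₂) under the same orientation.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels).astype(bool)
    if v.shape != lab.shape:
        raise ValueError("values and labels must align")
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    sign = 1.0 if higher_is_positive else -1.0
    sv = sign * v
    cuts = np.concatenate([[np.inf], np.unique(sv)[::-1], [-np.inf]])
    tpr = np.empty(cuts.size)
    fpr = np.empty(cuts.size)
    for i, c in enumerate(cuts):
        pred = sv >= c
        tpr[i] = (pred & lab).sum() / n_pos
        fpr[i] = (pred & ~lab).sum() / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(cutoffs=sign * cuts, tpr=tpr, fpr=fpr, auc=auc)
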