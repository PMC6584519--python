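"""Least-squares primitives shared by the scan and CIT modules.

Everything here is plain normal-equation OLS: design matrices are tiny
(four or five columns) while the pair/permutation counts run into the
hundreds of thousands, so closed-form solves beat model objects by orders
of magnitude. Correctness is pinned against statsmodels in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def covariate_design(cov: pd.DataFrame, sample_ids=None) -> np.ndarray:
    """Build the adjustment design [1, age, disease_status], row-aligned to samples."""
    tbl = cov.set_index("sample_id") if "sample_id" in cov.columns else cov
    if sample_ids is not None:
        tbl = tbl.loc[list(sample_ids)]
    n = len(tbl)
    return np.column_stack(
        [
            np.ones(n),
            tbl["age"].to_numpy(dtype=float),
            tbl["disease_status"].to_numpy(dtype=float),
        ]
    )


def ols_coef_test(y: np.ndarray, X: np.ndarray, idx: int):
    """OLS of ``y`` on ``X``; return (beta, se, t, p, df) for column ``idx``.

    Two-sided t test with df = n - k. ``X`` must include its own intercept.
    """
    n, k = X.shape
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - k
    s2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(XtX)
    se = float(np.sqrt(s2 * XtX_inv[idx, idx]))
    t = float(beta[idx]) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(beta[idx]), se, t, p, df


def residualize(M: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Project the columns of ``M`` off the column space of ``W`` (QR based)."""
    Q, _ = np.linalg.qr(W)
    return M - Q @ (Q.T @ M)


def partial_f_two_pred(
    y_r: np.ndarray, a_r: np.ndarray, b_rows: np.ndarray, n: int, n_adjust: int
) -> np.ndarray:
    """Partial F for predictor ``a`` in OLS y ~ a + b (+ already-removed adjusters).

    All inputs are residualized against the adjuster block (``n_adjust``
    columns including the intercept). ``b_rows`` holds one candidate ``b``
    vector per row so a whole permutation batch is scored in one call.
    Degenerate (collinear) rows return F = 0.
    """
    saa = float(a_r @ a_r)
    syy = float(y_r @ y_r)
    say = float(a_r @ y_r)
    sab = b_rows @ a_r
    sby = b_rows @ y_r
    sbb = np.einsum("ij,ij->i", b_rows, b_rows)
    det = saa * sbb - sab**2
    ok = det > 1e-12 * max(saa, 1e-300) * np.maximum(sbb, 1e-300)
    det_safe = np.where(ok, det, 1.0)
    beta_a = (sbb * say - sab * sby) / det_safe
    beta_b = (saa * sby - sab * say) / det_safe
    rss = syy - beta_a * say - beta_b * sby
    df = n - n_adjust - 2
    s2 = np.maximum(rss, 0.0) / df
    var_a = s2 * sbb / det_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(var_a > 0, beta_a**2 / var_a, np.inf)
    return np.where(ok, f, 0.0)
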