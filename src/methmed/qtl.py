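"""Cis-window QTL scanning with covariate adjustment and BH FDR.

Three pair types share one engine:

* ``meqtl`` — SNP (point) predicts CpG methylation (point); a pair is cis
  when the SNP lies within ``cis_window_bp`` of the CpG position.
* ``eqtm`` — CpG methylation predicts transcript expression; cis when the
  CpG lies within the window of the transcript's [TSS, TES] interval.
* ``eqtl`` — SNP predicts transcript expression; same interval rule.

Each candidate pair is fit by OLS of the response on
[1, predictor, age, disease_status]; the predictor's two-sided t test
p-value is corrected across all cis tests of the scan jointly by
Benjamini-Hochberg. Window boundaries are inclusive at exactly the window
size. Missing genotypes are handled by pairwise-complete deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import covariate_design, ols_coef_test, residualize
from .containers import OmicsMatrix, ROLE_METHYLATION

logger = logging.getLogger("methmed.qtl")

PAIR_TYPES = ("meqtl", "eqtm", "eqtl")

RESULT_COLUMNS = [
    "a_id",
    "b_id",
    "n_used",
    "beta_hat",
    "se",
    "t_stat",
    "p_value",
    "q_value",
    "distance_bp",
]

#: minimum complete observations for a pair fit (model has 4 parameters)
MIN_OBS = 5


@dataclass(frozen=True)
class ScanConfig:
    """Scan settings: pair type, cis window, FDR level, methylation transform."""

    pair_type: str
    cis_window_bp: int = 1_000_000
    fdr_threshold: float = 0.05
    transform: str | None = None  # None = raw beta; "logit" = logit(beta)

    def __post_init__(self) -> None:
        if self.pair_type not in PAIR_TYPES:
            raise ValueError(f"pair_type must be one of {PAIR_TYPES}")
        if self.cis_window_bp <= 0:
            raise ValueError("cis_window_bp must be positive")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.transform not in (None, "logit"):
            raise ValueError("transform must be None or 'logit'")


def _check_chroms(pred_ann: pd.DataFrame, resp_ann: pd.DataFrame) -> None:
    a, b = set(pred_ann["chrom"]), set(resp_ann["chrom"])
    if not a & b:
        raise ValueError(
            f"no shared chromosome names between tables: predictors use {sorted(a)}, "
            f"responses use {sorted(b)}"
        )


def cis_pairs(
    predictors: pd.DataFrame, responses: pd.DataFrame, cfg: ScanConfig
) -> pd.DataFrame:
    """Enumerate cis candidate pairs between two annotation tables.

    Returns a DataFrame (a_id, b_id, distance_bp) sorted by response
    chromosome, response position and predictor position. Distance is the
    signed predictor-minus-response offset for point responses, and the
    0-if-overlapping signed offset to the nearest interval boundary for
    transcript responses.
    """
    if not len(predictors) or not len(responses):
        raise ValueError("both annotation tables must be non-empty")
    _check_chroms(predictors, responses)
    w = cfg.cis_window_bp
    point_response = cfg.pair_type == "meqtl"
    rows = []
    pred_by_chrom = {
        c: grp.sort_values("pos", kind="mergesort")
        for c, grp in predictors.groupby("chrom", sort=False)
    }
    if point_response:
        resp_sorted = responses.assign(_start=responses["pos"], _end=responses["pos"])
    else:
        resp_sorted = responses.assign(_start=responses["tss"], _end=responses["tes"])
    resp_sorted = resp_sorted.sort_values(["chrom", "_start"], kind="mergesort")
    for _, resp in resp_sorted.iterrows():
        grp = pred_by_chrom.get(resp["chrom"])
        if grp is None:
            continue
        pos = grp["pos"].to_numpy(dtype=float)
        lo = float(resp["_start"]) - w
        hi = float(resp["_end"]) + w
        i0, i1 = np.searchsorted(pos, [lo, hi + 0.5])
        for j in range(i0, i1):
            p = pos[j]
            if p > hi:
                continue
            if point_response:
                dist = int(p - resp["_start"])
            elif resp["_start"] <= p <= resp["_end"]:
                dist = 0
            elif p < resp["_start"]:
                dist = int(p - resp["_start"])
            else:
                dist = int(p - resp["_end"])
            rows.append((grp.iloc[j]["feature_id"], resp["feature_id"], dist))
    return pd.DataFrame(rows, columns=["a_id", "b_id", "distance_bp"])


def fit_pair(x: np.ndarray, y: np.ndarray, cov: pd.DataFrame) -> dict:
    """OLS of y on [1, x, age, disease]; t test for the x coefficient.

    Missing predictor or response entries are removed pairwise (covariate
    rows follow). A predictor that is constant after deletion yields the
    degenerate convention p = 1 with NaN effect estimates. Fewer than 5
    complete observations raises ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = covariate_design(cov)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y, C = x[keep], y[keep], C[keep]
    n = len(x)
    if n < MIN_OBS:
        raise ValueError(f"only {n} complete observations; need >= {MIN_OBS}")
    if np.ptp(x) == 0.0:
        return {
            "n_used": n,
            "beta_hat": np.nan,
            "se": np.nan,
            "t_stat": np.nan,
            "p_value": 1.0,
            "degenerate": True,
        }
    X = np.column_stack([C[:, :1], x, C[:, 1:]])
    beta, se, t, p, _ = ols_coef_test(y, X, idx=1)
    return {
        "n_used": n,
        "beta_hat": beta,
        "se": se,
        "t_stat": t,
        "p_value": p,
        "degenerate": False,
    }


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fast_scan(xmat, ymat, ai, bi, n):
    """Vectorized per-pair OLS via Frisch-Waugh: residualize once, then slopes.

    Valid only when no values are missing; exact for the 4-parameter model
    with df = n - 4.
    """
    sxx_all = np.einsum("ij,ij->j", xmat, xmat)
    df = n - 4
    out = np.empty((len(ai), 4))
    chunk = 4096
    for s in range(0, len(ai), chunk):
        a = ai[s : s + chunk]
        b = bi[s : s + chunk]
        rx = xmat[:, a]
        ry = ymat[:, b]
        sxx = sxx_all[a]
        sxy = np.einsum("ij,ij->j", rx, ry)
        syy = np.einsum("ij,ij->j", ry, ry)
        degen = sxx <= 1e-12
        sxx_safe = np.where(degen, 1.0, sxx)
        beta = sxy / sxx_safe
        rss = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(rss / df / sxx_safe)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        beta[degen] = np.nan
        se[degen] = np.nan
        t[degen] = np.nan
        p[degen] = 1.0
        out[s : s + chunk] = np.column_stack([beta, se, t, p])
    return out


def run_scan(
    predictors: OmicsMatrix,
    responses: OmicsMatrix,
    predictor_ann: pd.DataFrame,
    response_ann: pd.DataFrame,
    cov: pd.DataFrame,
    cfg: ScanConfig,
) -> tuple[pd.DataFrame, dict]:
    """Run one full cis scan; return (AssocResult table, summary dict).

    The summary mirrors the usual per-scan report: number of tests,
    significant pairs at the FDR threshold, the maximum p-value among
    significant pairs, and unique predictor/response feature counts among
    significant pairs.
    """
    pairs = cis_pairs(predictor_ann, response_ann, cfg)
    if not len(pairs):
        logger.warning("scan %s: zero cis pairs", cfg.pair_type)
        empty = pd.DataFrame(columns=RESULT_COLUMNS)
        return empty, _summarize(empty, cfg)

    def _layer(m: OmicsMatrix) -> np.ndarray:
        vals = m.values
        if cfg.transform == "logit" and m.role == ROLE_METHYLATION:
            from scipy.special import logit as _logit

            vals = _logit(np.clip(vals, 1e-9, 1 - 1e-9))
        return vals

    xvals = _layer(predictors)
    yvals = _layer(responses)
    a_idx = pd.Index(predictors.feature_ids).get_indexer(pairs["a_id"])
    b_idx = pd.Index(responses.feature_ids).get_indexer(pairs["b_id"])
    if (a_idx < 0).any() or (b_idx < 0).any():
        raise ValueError("annotation references features absent from the matrices")
    n = predictors.n_samples
    C = covariate_design(cov, predictors.sample_ids)

    if not np.isnan(xvals).any() and not np.isnan(yvals).any():
        xr = residualize(xvals, C)
        yr = residualize(yvals, C)
        stats_block = _fast_scan(xr, yr, a_idx, b_idx, n)
        results = pairs.copy()
        results["n_used"] = n
        results[["beta_hat", "se", "t_stat", "p_value"]] = stats_block
    else:
        records = []
        for (_, pair), a, b in zip(pairs.iterrows(), a_idx, b_idx):
            try:
                fit = fit_pair(xvals[:, a], yvals[:, b], cov)
            except ValueError:
                logger.info("skipping pair %s-%s: too few observations", pair["a_id"], pair["b_id"])
                continue
            records.append({**pair.to_dict(), **fit})
        results = pd.DataFrame(records).drop(columns=["degenerate"], errors="ignore")
        if not len(results):
            empty = pd.DataFrame(columns=RESULT_COLUMNS)
            return empty, _summarize(empty, cfg)

    results["q_value"] = bh_fdr(results["p_value"].to_numpy())
    results = results[RESULT_COLUMNS]
    return results, _summarize(results, cfg)


def _summarize(results: pd.DataFrame, cfg: ScanConfig) -> dict:
    sig = results[results["q_value"] <= cfg.fdr_threshold] if len(results) else results
    return {
        "pair_type": cfg.pair_type,
        "n_tests": int(len(results)),
        "n_significant": int(len(sig)),
        "max_p_significant": float(sig["p_value"].max()) if len(sig) else float("nan"),
        "n_unique_predictors": int(sig["a_id"].nunique()) if len(sig) else 0,
        "n_unique_responses": int(sig["b_id"].nunique()) if len(sig) else 0,
    }


def significant_pairs(results: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Subset an AssocResult table to pairs passing the FDR threshold."""
    return results[results["q_value"] <= fdr_threshold].reset_index(drop=True)
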