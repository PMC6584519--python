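"""Trio assembly and the four-condition causal inference test (CIT).

A trio is a (SNP, CpG, transcript) triple whose three pairwise
associations are all significant in the meQTL, eQTM and eQTL scans. The
CIT asks whether the SNP's effect on expression is mediated by
methylation, requiring four simultaneous conditions with L = genotype,
G = methylation, T = expression (age and disease adjusted in every fit):

1. L and T are associated (marginal);
2. L is associated with G after adjusting for T;
3. G is associated with T after adjusting for L;
4. L is independent of T given G.

Conditions 1-3 are ordinary OLS t tests. Condition 4 is an equivalence
test, not an absence-of-evidence check: the observed partial F for L in
T ~ L + G + cov is compared with a permutation null in which the
residuals of G ~ L + cov are shuffled and recombined with the fitted
values, breaking any mediated path while preserving the L-G association.
Small p4 means the observed F sits in the *low* tail — L explains no more
of T, given G, than it would if G carried the whole effect. The omnibus
CIT p-value is the maximum of the four components; a trio is called a
mediation chain when that maximum falls below alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import covariate_design, ols_coef_test, partial_f_two_pred, residualize
from .containers import OmicsMatrix

logger = logging.getLogger("methmed.cit")

CIT_COLUMNS = [
    "snp_id",
    "cpg_id",
    "gene_id",
    "gene_symbol",
    "p1",
    "p2",
    "p3",
    "p4",
    "p_cit",
    "sign_lg",
    "sign_gt",
    "verdict",
]


@dataclass
class CitResult:
    """Component and omnibus p-values of one causal inference test."""

    p1: float
    p2: float
    p3: float
    p4: float
    p_cit: float
    sign_lg: int
    sign_gt: int
    n_permutations: int
    seed: int
    degenerate: bool = False

    @property
    def verdict(self) -> bool:
        """Mediation call at the conventional alpha = 0.05."""
        return self.p_cit < 0.05


def build_trios(
    meqtl_sig: pd.DataFrame,
    eqtm_sig: pd.DataFrame,
    eqtl_sig: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble candidate trios from the three significant pair tables.

    Combinatorial closure over (snp, cpg) in meqtl, (cpg, gene) in eqtm and
    (snp, gene) in eqtl, restricted to genes carrying a non-empty official
    symbol; deduplicated and sorted. Any empty input yields an empty list
    with a warning.
    """
    if not len(meqtl_sig) or not len(eqtm_sig) or not len(eqtl_sig):
        logger.warning("build_trios: at least one significant table is empty")
        return pd.DataFrame(columns=["snp_id", "cpg_id", "gene_id", "gene_symbol"])
    me = meqtl_sig.rename(columns={"a_id": "snp_id", "b_id": "cpg_id"})[["snp_id", "cpg_id"]]
    em = eqtm_sig.rename(columns={"a_id": "cpg_id", "b_id": "gene_id"})[["cpg_id", "gene_id"]]
    el = eqtl_sig.rename(columns={"a_id": "snp_id", "b_id": "gene_id"})[["snp_id", "gene_id"]]
    trios = me.merge(em, on="cpg_id").merge(el, on=["snp_id", "gene_id"])
    tx = annotation[annotation["feature_class"] == "transcript"]
    symbols = tx.set_index("feature_id")["gene_symbol"]
    trios["gene_symbol"] = trios["gene_id"].map(symbols).fillna("")
    trios = trios[trios["gene_symbol"] != ""]
    trios = (
        trios.drop_duplicates(["snp_id", "cpg_id", "gene_id"])
        .sort_values(["snp_id", "cpg_id", "gene_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return trios[["snp_id", "cpg_id", "gene_id", "gene_symbol"]]


def cit_test(
    L: np.ndarray,
    G: np.ndarray,
    T: np.ndarray,
    cov: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
) -> CitResult:
    """Run the four-condition CIT on one aligned, complete trio.

    p1-p3 are two-sided OLS t tests; p4 is the permutation equivalence
    p-value (1 + #{F* <= F_obs}) / (B + 1). Degenerate input (constant L,
    or zero-variance G or T) returns a flagged result with all p = 1.
    """
    L = np.asarray(L, dtype=float)
    G = np.asarray(G, dtype=float)
    T = np.asarray(T, dtype=float)
    n = len(L)
    if n < 10:
        raise ValueError("need at least 10 samples for the CIT")
    if B < 100:
        raise ValueError("need at least 100 permutations")
    if np.ptp(L) == 0.0 or np.ptp(G) == 0.0 or np.ptp(T) == 0.0:
        return CitResult(1.0, 1.0, 1.0, 1.0, 1.0, 0, 0, B, seed, degenerate=True)
    W = covariate_design(cov)  # [1, age, disease]

    def _p(y, *predictors, test_idx):
        X = np.column_stack([W[:, :1], *predictors, W[:, 1:]])
        return ols_coef_test(y, X, idx=test_idx)

    _, _, _, p1, _ = _p(T, L, test_idx=1)
    _, _, _, p2, _ = _p(G, L, T, test_idx=1)
    _, _, _, p3, _ = _p(T, G, L, test_idx=1)

    # marginal (covariate-adjusted) slopes for network edge signs
    b_lg, _, _, _, _ = _p(G, L, test_idx=1)
    b_gt, _, _, _, _ = _p(T, G, test_idx=1)

    # condition 4: permutation equivalence test of L _||_ T | G
    rng = np.random.default_rng([int(seed) % (2**31), 4])
    t_r = residualize(T[:, None], W)[:, 0]
    l_r = residualize(L[:, None], W)[:, 0]
    g_r = residualize(G[:, None], W)[:, 0]
    f_obs = float(partial_f_two_pred(t_r, l_r, g_r[None, :], n, W.shape[1])[0])
    # fit G ~ L + cov; permute residuals, recombine with fitted values
    XG = np.column_stack([W[:, :1], L, W[:, 1:]])
    coef = np.linalg.solve(XG.T @ XG, XG.T @ G)
    g_hat = XG @ coef
    resid = G - g_hat
    perms = rng.permuted(np.tile(resid, (B, 1)), axis=1)
    g_star = g_hat[None, :] + perms
    g_star_r = g_star - (g_star @ _proj(W)).astype(float)
    f_star = partial_f_two_pred(t_r, l_r, g_star_r, n, W.shape[1])
    p4 = (1.0 + int(np.sum(f_star <= f_obs))) / (B + 1.0)

    p_cit = max(p1, p2, p3, p4)
    return CitResult(
        p1=p1,
        p2=p2,
        p3=p3,
        p4=p4,
        p_cit=p_cit,
        sign_lg=int(np.sign(b_lg)),
        sign_gt=int(np.sign(b_gt)),
        n_permutations=B,
        seed=seed,
    )


def _proj(W: np.ndarray) -> np.ndarray:
    """Return P such that M @ P is the projection of M's rows onto col(W)... transposed.

    For row-vector batches X (B x n), X - X @ P removes the W component,
    where P = Qw Qw^T from the thin QR of W.
    """
    Q, _ = np.linalg.qr(W)
    return Q @ Q.T


def cit_batch(
    trios: pd.DataFrame,
    genotypes: OmicsMatrix,
    methylation: OmicsMatrix,
    expression: OmicsMatrix,
    cov: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Run the CIT over a trio table; return (CitResult table, summary).

    Per-trio seeds are derived deterministically from (seed, trio index) so
    batches are reproducible and order-independent at the trio level.
    Trios referencing absent features are skipped with a log line.
    """
    records = []
    for i, trio in trios.reset_index(drop=True).iterrows():
        try:
            L = genotypes.data[trio["snp_id"]].to_numpy(dtype=float)
            G = methylation.data[trio["cpg_id"]].to_numpy(dtype=float)
            T = expression.data[trio["gene_id"]].to_numpy(dtype=float)
        except KeyError as err:
            logger.warning("skipping trio %d: missing feature %s", i, err)
            continue
        keep = ~np.isnan(L)
        cov_i = cov if keep.all() else cov.iloc[np.where(keep)[0]]
        trio_seed = int((int(seed) * 1_000_003 + i) % (2**31))
        res = cit_test(L[keep], G[keep], T[keep], cov_i, B=B, seed=trio_seed)
        records.append(
            {
                "snp_id": trio["snp_id"],
                "cpg_id": trio["cpg_id"],
                "gene_id": trio["gene_id"],
                "gene_symbol": trio.get("gene_symbol", ""),
                "p1": res.p1,
                "p2": res.p2,
                "p3": res.p3,
                "p4": res.p4,
                "p_cit": res.p_cit,
                "sign_lg": res.sign_lg,
                "sign_gt": res.sign_gt,
                "verdict": bool(res.p_cit < alpha),
            }
        )
    table = pd.DataFrame(records, columns=CIT_COLUMNS)
    sig = table[table["verdict"]] if len(table) else table
    summary = {
        "n_tested": int(len(table)),
        "n_significant": int(len(sig)),
        "n_unique_snps": int(sig["snp_id"].nunique()) if len(sig) else 0,
        "n_unique_cpgs": int(sig["cpg_id"].nunique()) if len(sig) else 0,
        "n_unique_genes": int(sig["gene_id"].nunique()) if len(sig) else 0,
    }
    return table, summary
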