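"""Two-locus linkage disequilibrium from unphased genotypes.

Haplotype frequencies for a pair of biallelic loci are estimated by EM
over the double-heterozygote phase ambiguity (the classic
phase-unknown maximum-likelihood estimator): every genotype pair
determines its two haplotypes except (1, 1), which is split between
AB/ab and Ab/aB in proportion to the current frequency products. From the
converged frequencies we report

* ``D = pAB - pA * pB``,
* ``D' = D / Dmax`` (0 when D = 0),
* ``r^2 = D^2 / (pA (1-pA) pB (1-pB))``,

where allele A/B denotes the ALT allele at each locus. r = 0 means the
loci are independent; r^2 = 1 means the alleles at the two loci are
perfectly coupled. Both measures are invariant to swapping allele labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import OmicsMatrix

logger = logging.getLogger("methmed.ld")

EM_TOL = 1e-8
EM_MAX_ITER = 1000


class MonomorphicError(ValueError):
    """LD is undefined when either locus is monomorphic among complete pairs."""


@dataclass
class LdResult:
    """LD estimates for one SNP pair."""

    snp_i: str
    snp_j: str
    r2: float
    d_prime: float
    hap_freqs: tuple[float, float, float, float]  # (pAB, pAb, paB, pab)
    em_iterations: int
    converged: bool
    n_used: int
    log_likelihoods: list | None = None


def _pair_counts(g_i: np.ndarray, g_j: np.ndarray) -> np.ndarray:
    """3x3 table of genotype-pair counts over pairwise-complete samples."""
    keep = ~(np.isnan(g_i) | np.isnan(g_j))
    gi = g_i[keep].astype(int)
    gj = g_j[keep].astype(int)
    counts = np.zeros((3, 3))
    np.add.at(counts, (gi, gj), 1)
    return counts


def _log_likelihood(counts: np.ndarray, f: np.ndarray) -> float:
    pAB, pAb, paB, pab = f
    # multinomial genotype-pair probabilities under random haplotype pairing
    probs = np.array(
        [
            [pab**2, 2 * pab * paB, paB**2],
            [2 * pab * pAb, 2 * (pAB * pab + pAb * paB), 2 * paB * pAB],
            [pAb**2, 2 * pAb * pAB, pAB**2],
        ]
    )
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(np.maximum(probs[mask], 1e-300))))


def em_haplotypes(g_i, g_j, snp_i: str = "snp_i", snp_j: str = "snp_j") -> LdResult:
    """Estimate two-locus haplotype frequencies and LD by EM.

    Inputs are additive genotypes in {0, 1, 2} (NaN = missing, removed
    pairwise). Initialization is the linkage-equilibrium product of allele
    frequencies; iteration stops when the largest frequency change falls
    below 1e-8 or after 1000 iterations. The per-iteration log-likelihood
    trace is retained (it is non-decreasing, a property the tests check).
    """
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    counts = _pair_counts(g_i, g_j)
    n = counts.sum()
    if n == 0:
        raise MonomorphicError("no complete genotype pairs")
    pA = (counts.sum(axis=1) @ np.array([0, 1, 2])) / (2 * n)
    pB = (counts.sum(axis=0) @ np.array([0, 1, 2])) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MonomorphicError(
            f"monomorphic locus among complete pairs ({snp_i}: pA={pA:.3f}, {snp_j}: pB={pB:.3f})"
        )

    # unambiguous haplotype counts (AB, Ab, aB, ab); cell (1,1) handled in E-step
    fixed = np.array(
        [
            counts[1, 2] + counts[2, 1] + 2 * counts[2, 2],  # AB
            counts[1, 0] + counts[2, 1] + 2 * counts[2, 0],  # Ab
            counts[0, 1] + counts[1, 2] + 2 * counts[0, 2],  # aB
            counts[0, 1] + counts[1, 0] + 2 * counts[0, 0],  # ab
        ]
    )
    n11 = counts[1, 1]
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    lls = [_log_likelihood(counts, f)]
    converged = False
    iterations = 0
    for iterations in range(1, EM_MAX_ITER + 1):
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        w = coupling / (coupling + repulsion) if coupling + repulsion > 0 else 0.5
        expected = fixed + n11 * np.array([w, 1 - w, 1 - w, w])
        f_new = expected / (2 * n)
        delta = np.abs(f_new - f).max()
        f = f_new
        lls.append(_log_likelihood(counts, f))
        if delta < EM_TOL:
            converged = True
            break

    pAB, pAb, paB, pab = f
    pA_hat, pB_hat = pAB + pAb, pAB + paB
    D = pAB - pA_hat * pB_hat
    denom = pA_hat * (1 - pA_hat) * pB_hat * (1 - pB_hat)
    r2 = float(np.clip(D * D / denom, 0.0, 1.0)) if denom > 0 else float("nan")
    if D > 0:
        dmax = min(pA_hat * (1 - pB_hat), (1 - pA_hat) * pB_hat)
    elif D < 0:
        dmax = min(pA_hat * pB_hat, (1 - pA_hat) * (1 - pB_hat))
    else:
        dmax = 0.0
    d_prime = float(np.clip(abs(D) / dmax, 0.0, 1.0)) if dmax > 0 else 0.0
    return LdResult(
        snp_i=snp_i,
        snp_j=snp_j,
        r2=r2,
        d_prime=d_prime,
        hap_freqs=(float(pAB), float(pAb), float(paB), float(pab)),
        em_iterations=iterations,
        converged=converged,
        n_used=int(n),
        log_likelihoods=lls,
    )


def ld_matrix(genotypes: OmicsMatrix | pd.DataFrame, snp_ids=None) -> pd.DataFrame:
    """Pairwise LD over the upper triangle of a SNP set.

    Per-pair failures (monomorphic loci) become flagged rows with NaN
    estimates rather than aborting the table.
    """
    data = genotypes.data if isinstance(genotypes, OmicsMatrix) else genotypes
    ids = list(snp_ids) if snp_ids is not None else list(data.columns)
    if len(ids) < 2:
        raise ValueError("need at least 2 SNPs")
    rows = []
    for a, b in combinations(ids, 2):
        try:
            res = em_haplotypes(data[a].to_numpy(float), data[b].to_numpy(float), a, b)
            rows.append(
                {
                    "snp_i": a,
                    "snp_j": b,
                    "r2": res.r2,
                    "d_prime": res.d_prime,
                    "converged": res.converged,
                    "error": "",
                }
            )
        except MonomorphicError as err:
            logger.warning("LD undefined for %s-%s: %s", a, b, err)
            rows.append(
                {
                    "snp_i": a,
                    "snp_j": b,
                    "r2": float("nan"),
                    "d_prime": float("nan"),
                    "converged": False,
                    "error": str(err),
                }
            )
    return pd.DataFrame(rows)


def ld_group_summary(ld_table: pd.DataFrame, group_name: str = "group") -> dict:
    """Minimum and mean pairwise r-squared for one named SNP group."""
    ok = ld_table[ld_table["r2"].notna()]
    return {
        "group": group_name,
        "n_pairs": int(len(ok)),
        "min_r2": float(ok["r2"].min()) if len(ok) else float("nan"),
        "mean_r2": float(ok["r2"].mean()) if len(ok) else float("nan"),
    }
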