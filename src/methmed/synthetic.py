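"""Synthetic multi-omics generator with planted causal architectures.

Emulates the post-normalization data of a PBMC multi-omics study design:
biallelic genotypes with block LD, beta-valued methylation responding
additively to genotype on the logit scale, and log2 expression responding
to methylation and/or genotype, with age and disease-status covariate
effects on the molecular layers. Trios of (SNP, CpG, transcript) are
planted under one of four architectures:

``mediation``
    SNP -> methylation -> expression (beta_lg and beta_gt nonzero, no
    direct SNP->expression path).
``common_cause``
    SNP -> methylation and SNP -> expression independently (beta_lg and
    beta_lt nonzero, methylation does not drive expression).
``reverse``
    SNP -> expression -> methylation (beta_lt and beta_tg nonzero).
``null``
    no planted effects.

Generation order respects each architecture's DAG: methylation is drawn
before expression for all architectures except reverse causation, whose
CpGs receive their expression term in a second pass. All draws are
deterministic functions of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import (
    ANNOTATION_COLUMNS,
    CPG_ISLAND_CATEGORIES,
    GENE_REGION_CATEGORIES,
    OmicsMatrix,
    ROLE_EXPRESSION,
    ROLE_GENOTYPE,
    ROLE_METHYLATION,
)

ARCHITECTURES = ("mediation", "common_cause", "reverse", "null")

#: resting probabilities for CpG island-relation categories (450K-like mix)
_ISLAND_PROBS = (0.31, 0.12, 0.11, 0.05, 0.05, 0.36)
#: resting probabilities for CpG gene-region categories
_REGION_PROBS = (0.18, 0.09, 0.08, 0.03, 0.40, 0.04, 0.18)

_BETA_EPS = 1e-9


class LayoutError(ValueError):
    """Requested feature layout does not fit on the genome."""


@dataclass(frozen=True)
class TrioSpec:
    """How many trios of one architecture to plant, and with what effects.

    Effect sizes irrelevant to an architecture are forced to zero in the
    truth table (e.g. a mediation trio has no direct SNP->expression path).
    """

    architecture: str
    count: int
    beta_lg: float = 0.8  # SNP -> logit(methylation), per ALT allele
    beta_gt: float = 1.0  # centered logit(methylation) -> log2 expression
    beta_lt: float = 0.8  # SNP -> log2 expression, per ALT allele
    beta_tg: float = 1.0  # centered log2 expression -> logit(methylation)

    def planted_effects(self) -> tuple[float, float, float, float]:
        if self.architecture == "mediation":
            return (self.beta_lg, self.beta_gt, 0.0, 0.0)
        if self.architecture == "common_cause":
            return (self.beta_lg, 0.0, self.beta_lt, 0.0)
        if self.architecture == "reverse":
            return (0.0, 0.0, self.beta_lt, self.beta_tg)
        if self.architecture == "null":
            return (0.0, 0.0, 0.0, 0.0)
        raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass(frozen=True)
class SimConfig:
    """Study design for one synthetic dataset.

    Defaults mirror a small clinical multi-omics cohort (43 adult female
    subjects, rheumatoid-arthritis case mix); stochastic power checks use
    n_samples=500, where trio-level tests are stable.
    """

    n_samples: int = 43
    n_chromosomes: int = 2
    chrom_length_bp: int = 50_000_000
    n_snps: int = 200
    n_cpgs: int = 100
    n_genes: int = 40
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 5
    ld_decay: float = 0.3
    trio_specs: tuple[TrioSpec, ...] = (
        TrioSpec("mediation", 3),
        TrioSpec("common_cause", 3),
        TrioSpec("reverse", 3),
        TrioSpec("null", 3),
    )
    #: (age, disease) coefficients per molecular layer; age enters centered
    #: at 50 y so baselines stay interpretable
    covariate_effects: dict = field(
        default_factory=lambda: {
            "methylation": (0.01, 0.25),
            "expression": (0.01, 0.30),
        }
    )
    noise_sd: dict = field(
        default_factory=lambda: {"methylation": 0.5, "expression": 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("n_samples", "n_chromosomes", "chrom_length_bp", "n_snps", "n_cpgs", "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if not 0.0 <= self.ld_decay <= 1.0:
            raise ValueError("ld_decay must be in [0, 1]")
        for spec in self.trio_specs:
            if spec.architecture not in ARCHITECTURES:
                raise ValueError(f"unknown architecture {spec.architecture!r}")
            if spec.count < 0:
                raise ValueError("trio counts must be non-negative")

    @property
    def n_trios(self) -> int:
        return sum(s.count for s in self.trio_specs)


@dataclass
class SimData:
    """One fully generated dataset plus its ground truth."""

    config: SimConfig
    annotation: pd.DataFrame
    truth: pd.DataFrame
    genotypes: OmicsMatrix
    methylation: OmicsMatrix
    expression: OmicsMatrix
    covariates: pd.DataFrame


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng([int(cfg.seed) % (2**31), stream])


def _distinct_positions(rng, n, lo, hi):
    """Sample n distinct integer positions in [lo, hi]."""
    if hi - lo + 1 < n:
        raise LayoutError(
            f"cannot place {n} distinct features in a {hi - lo + 1} bp span"
        )
    taken: set[int] = set()
    out = []
    while len(out) < n:
        draw = rng.integers(lo, hi + 1, size=n - len(out))
        for p in draw:
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
    return out


def gen_feature_map(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out SNPs, CpGs and transcripts; return (annotation, truth_table).

    Trio members are co-located: each planted trio's SNP and CpG fall
    within 400 kb of the trio gene's TSS, guaranteeing cis eligibility
    (within 1 Mb of each other and of the gene interval) by construction.
    Remaining features are placed uniformly.
    """
    rng = _rng(cfg, 0)
    n_trios = cfg.n_trios
    if n_trios > 0 and cfg.n_genes == 0:
        raise LayoutError("trios requested but n_genes is 0")
    if n_trios > min(cfg.n_snps, cfg.n_cpgs, cfg.n_genes or n_trios):
        raise LayoutError(
            f"{n_trios} trios need at least that many SNPs, CpGs and genes "
            f"(have {cfg.n_snps}/{cfg.n_cpgs}/{cfg.n_genes})"
        )
    L = cfg.chrom_length_bp
    margin = 1_500_000
    if L <= 2 * margin:
        raise LayoutError(f"chromosome length {L} bp too short (needs > {2 * margin})")
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]

    # --- genes ---
    gene_chrom = [chroms[i % len(chroms)] for i in range(cfg.n_genes)]
    tss = {c: _distinct_positions(rng, gene_chrom.count(c), margin, L - margin) for c in chroms}
    counters = {c: 0 for c in chroms}
    genes = []
    for i in range(cfg.n_genes):
        c = gene_chrom[i]
        start = tss[c][counters[c]]
        counters[c] += 1
        length = int(rng.integers(5_000, 200_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            {
                "feature_id": f"tx{i:04d}",
                "feature_class": "transcript",
                "chrom": c,
                "pos": np.nan,
                "strand": strand,
                "tss": start,
                "tes": start + length,
                "gene_symbol": f"GENE{i:04d}",
                "cpg_island_category": "",
                "gene_region_category": "",
            }
        )
    gene_df = pd.DataFrame(genes)

    # --- trio assignment: one distinct gene per trio ---
    trio_rows = []
    gene_order = rng.permutation(cfg.n_genes) if cfg.n_genes else np.array([], dtype=int)
    k = 0
    for spec in cfg.trio_specs:
        for _ in range(spec.count):
            # effect magnitudes come from the spec; directions are random,
            # as in real QTLs where either allele can raise methylation
            blg, bgt, blt, btg = (
                b * (1.0 if rng.random() < 0.5 else -1.0)
                for b in spec.planted_effects()
            )
            trio_rows.append(
                {
                    "snp_id": f"snp{k:05d}",
                    "cpg_id": f"cg{k:08d}",
                    "gene_id": gene_df.iloc[gene_order[k]]["feature_id"],
                    "architecture": spec.architecture,
                    "beta_lg": blg,
                    "beta_gt": bgt,
                    "beta_lt": blt,
                    "beta_tg": btg,
                }
            )
            k += 1
    truth = pd.DataFrame(
        trio_rows,
        columns=["snp_id", "cpg_id", "gene_id", "architecture", "beta_lg", "beta_gt", "beta_lt", "beta_tg"],
    )

    # --- SNPs and CpGs: trio members near their gene, the rest uniform ---
    def _point_features(n, prefix, fmt, trio_genes):
        rows = []
        used: dict[str, set[int]] = {c: set() for c in chroms}
        for j in range(n):
            if j < len(trio_genes):
                g = gene_df.set_index("feature_id").loc[trio_genes[j]]
                c = g["chrom"]
                lo = max(1, int(g["tss"]) - 400_000)
                hi = min(L, int(g["tss"]) + 400_000)
            else:
                c = chroms[int(rng.integers(len(chroms)))]
                lo, hi = 1, L
            for _ in range(1000):
                p = int(rng.integers(lo, hi + 1))
                if p not in used[c]:
                    used[c].add(p)
                    break
            else:
                raise LayoutError(f"cannot place distinct {prefix} features")
            rows.append((fmt.format(j), c, p))
        return rows

    trio_genes = list(truth["gene_id"])
    snps = _point_features(cfg.n_snps, "snp", "snp{:05d}", trio_genes)
    cpgs = _point_features(cfg.n_cpgs, "cpg", "cg{:08d}", trio_genes)

    snp_df = pd.DataFrame(
        {
            "feature_id": [s[0] for s in snps],
            "feature_class": "snp",
            "chrom": [s[1] for s in snps],
            "pos": [s[2] for s in snps],
            "strand": "",
            "tss": np.nan,
            "tes": np.nan,
            "gene_symbol": "",
            "cpg_island_category": "",
            "gene_region_category": "",
        }
    )

    island_cat = rng.choice(CPG_ISLAND_CATEGORIES, size=cfg.n_cpgs, p=_ISLAND_PROBS)
    region_cat = rng.choice(GENE_REGION_CATEGORIES, size=cfg.n_cpgs, p=_REGION_PROBS)

    # nearest-gene symbol for each CpG (within 1 Mb of the gene interval)
    def _nearest_symbol(chrom, pos):
        cand = gene_df[gene_df["chrom"] == chrom]
        if not len(cand):
            return ""
        d = np.maximum.reduce(
            [cand["tss"].to_numpy() - pos, pos - cand["tes"].to_numpy(), np.zeros(len(cand))]
        )
        i = int(np.argmin(d))
        return cand.iloc[i]["gene_symbol"] if d[i] <= 1_000_000 else ""

    cpg_df = pd.DataFrame(
        {
            "feature_id": [s[0] for s in cpgs],
            "feature_class": "cpg",
            "chrom": [s[1] for s in cpgs],
            "pos": [s[2] for s in cpgs],
            "strand": "",
            "tss": np.nan,
            "tes": np.nan,
            "gene_symbol": [_nearest_symbol(s[1], s[2]) for s in cpgs],
            "cpg_island_category": island_cat,
            "gene_region_category": region_cat,
        }
    )

    ann = pd.concat([snp_df, cpg_df, gene_df], ignore_index=True)[ANNOTATION_COLUMNS]
    return ann, truth


def gen_covariates(cfg: SimConfig) -> pd.DataFrame:
    """Sample covariates: age ~ Uniform(30, 70) years, disease ~ Bernoulli(0.5)."""
    rng = _rng(cfg, 1)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(cfg.n_samples)],
            "age": np.round(rng.uniform(30, 70, size=cfg.n_samples), 1),
            "disease_status": rng.integers(0, 2, size=cfg.n_samples),
        }
    )


def gen_genotypes(cfg: SimConfig, annotation: pd.DataFrame) -> OmicsMatrix:
    """Draw additive genotypes with block LD via the haplotype-copy model.

    Within a block of ``ld_block_size`` position-consecutive SNPs, the
    first SNP's two haplotypes per sample are Bernoulli(MAF) draws; each
    subsequent SNP copies the previous SNP's haplotype allele with
    probability 1 - ld_decay, else re-draws from its own MAF. The two
    haplotypes are summed to a genotype. Blocks yielding a monomorphic or
    ultra-rare column (realized MAF < half the configured lower bound) are
    regenerated whole, preserving the within-block LD structure.
    """
    rng = _rng(cfg, 2)
    snp_ann = annotation[annotation["feature_class"] == "snp"].copy()
    snp_ann = snp_ann.sort_values(["chrom", "pos"], kind="mergesort")
    n = cfg.n_samples
    maf_lo, maf_hi = cfg.maf_range
    ids: list[str] = []
    cols: list[np.ndarray] = []
    for _, chrom_grp in snp_ann.groupby("chrom", sort=True):
        block_ids = chrom_grp["feature_id"].tolist()
        for start in range(0, len(block_ids), cfg.ld_block_size):
            block = block_ids[start : start + cfg.ld_block_size]
            mafs = rng.uniform(maf_lo, maf_hi, size=len(block))
            for _attempt in range(200):
                haps = np.empty((2 * n, len(block)), dtype=np.int8)
                haps[:, 0] = rng.random(2 * n) < mafs[0]
                for j in range(1, len(block)):
                    redraw = rng.random(2 * n) < cfg.ld_decay
                    fresh = rng.random(2 * n) < mafs[j]
                    haps[:, j] = np.where(redraw, fresh, haps[:, j - 1])
                geno = haps[:n] + haps[n:]
                freqs = geno.mean(axis=0) / 2.0
                realized_maf = np.minimum(freqs, 1 - freqs)
                if (realized_maf >= 0.5 * maf_lo).all():
                    break
            else:
                raise RuntimeError("could not draw a polymorphic LD block; check maf_range/n_samples")
            ids.extend(block)
            cols.append(geno)
    values = np.concatenate(cols, axis=1).astype(float)
    data = pd.DataFrame(values, index=[f"S{i:04d}" for i in range(n)], columns=ids)
    # restore the annotation's column order
    data = data[annotation.loc[annotation["feature_class"] == "snp", "feature_id"].tolist()]
    return OmicsMatrix(data=data, role=ROLE_GENOTYPE)


def _cov_terms(cfg: SimConfig, covariates: pd.DataFrame, layer: str) -> np.ndarray:
    age_c, dis_c = cfg.covariate_effects.get(layer, (0.0, 0.0))
    return age_c * (covariates["age"].to_numpy(dtype=float) - 50.0) + dis_c * covariates[
        "disease_status"
    ].to_numpy(dtype=float)


def gen_methylation(
    cfg: SimConfig,
    genotypes: OmicsMatrix,
    truth: pd.DataFrame,
    covariates: pd.DataFrame,
    expression: OmicsMatrix | None = None,
) -> OmicsMatrix:
    """Draw methylation betas: logit(beta) = baseline + genetic + covariate + noise.

    Per-CpG baselines are Uniform(-2, 2) on the logit scale. Trio CpGs with
    a nonzero ``beta_lg`` gain that slope per ALT allele of their trio SNP.
    When ``expression`` is supplied (the second pass of the two-pass
    scheme), reverse-causation CpGs additionally gain ``beta_tg`` times the
    mean-centered expression of their trio transcript. Random draws do not
    depend on whether ``expression`` is given, so the two passes agree
    everywhere except at reverse-trio CpGs. Returned betas are strictly
    inside (0, 1).
    """
    rng = _rng(cfg, 3)
    cpg_ids = [f"cg{j:08d}" for j in range(cfg.n_cpgs)]
    n = cfg.n_samples
    alpha = rng.uniform(-2.0, 2.0, size=cfg.n_cpgs)
    noise = rng.normal(0.0, cfg.noise_sd["methylation"], size=(n, cfg.n_cpgs))
    lg = np.tile(alpha, (n, 1)) + noise + _cov_terms(cfg, covariates, "methylation")[:, None]
    col = {c: j for j, c in enumerate(cpg_ids)}
    for _, row in truth.iterrows():
        j = col[row["cpg_id"]]
        if row["beta_lg"] != 0.0:
            g = genotypes.data[row["snp_id"]].to_numpy(dtype=float)
            lg[:, j] += row["beta_lg"] * g
        if expression is not None and row["beta_tg"] != 0.0:
            t = expression.data[row["gene_id"]].to_numpy(dtype=float)
            lg[:, j] += row["beta_tg"] * (t - t.mean())
    beta = np.clip(expit(lg), _BETA_EPS, 1.0 - _BETA_EPS)
    data = pd.DataFrame(beta, index=genotypes.sample_ids, columns=cpg_ids)
    return OmicsMatrix(data=data, role=ROLE_METHYLATION)


def gen_expression(
    cfg: SimConfig,
    genotypes: OmicsMatrix,
    methylation: OmicsMatrix,
    truth: pd.DataFrame,
    covariates: pd.DataFrame,
) -> OmicsMatrix:
    """Draw log2 expression: baseline + methylation and/or genetic terms + noise.

    Per-gene baselines are Uniform(6, 12) (log2 microarray scale). A trio
    gene gains ``beta_gt`` times the mean-centered logit methylation of its
    trio CpG (mediation) and/or ``beta_lt`` per ALT allele of its trio SNP
    (common cause, reverse causation).
    """
    rng = _rng(cfg, 4)
    gene_ids = [f"tx{j:04d}" for j in range(cfg.n_genes)]
    n = cfg.n_samples
    mu = rng.uniform(6.0, 12.0, size=cfg.n_genes)
    noise = rng.normal(0.0, cfg.noise_sd["expression"], size=(n, cfg.n_genes))
    expr = np.tile(mu, (n, 1)) + noise + _cov_terms(cfg, covariates, "expression")[:, None]
    col = {g: j for j, g in enumerate(gene_ids)}
    for _, row in truth.iterrows():
        j = col[row["gene_id"]]
        if row["beta_gt"] != 0.0:
            m = logit(methylation.data[row["cpg_id"]].to_numpy(dtype=float))
            expr[:, j] += row["beta_gt"] * (m - m.mean())
        if row["beta_lt"] != 0.0:
            g = genotypes.data[row["snp_id"]].to_numpy(dtype=float)
            expr[:, j] += row["beta_lt"] * g
    data = pd.DataFrame(expr, index=genotypes.sample_ids, columns=gene_ids)
    return OmicsMatrix(data=data, role=ROLE_EXPRESSION)


def simulate_dataset(cfg: SimConfig) -> SimData:
    """Generate a complete dataset, resolving architectures in DAG order.

    Two passes: methylation is first drawn without expression feedback,
    expression is drawn from it, then reverse-causation CpGs are re-drawn
    (same random stream) with their expression term included.
    """
    annotation, truth = gen_feature_map(cfg)
    covariates = gen_covariates(cfg)
    genotypes = gen_genotypes(cfg, annotation)
    meth_first = gen_methylation(cfg, genotypes, truth, covariates, expression=None)
    expression = gen_expression(cfg, genotypes, meth_first, truth, covariates)
    has_reverse = (truth["beta_tg"] != 0.0).any() if len(truth) else False
    methylation = (
        gen_methylation(cfg, genotypes, truth, covariates, expression=expression)
        if has_reverse
        else meth_first
    )
    return SimData(
        config=cfg,
        annotation=annotation,
        truth=truth,
        genotypes=genotypes,
        methylation=methylation,
        expression=expression,
        covariates=covariates,
    )
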