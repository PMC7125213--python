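"""Seeded generators for synthetic expression, gene-set and genotype data.

Every analysis in the package can be exercised end-to-end without any
external download: the generators plant known differential-variability
structure (per-gene variance ratios, gene sets with heterogeneous
covariance inflation, genotype-dependent expression variances) and emit a
machine-readable truth table alongside the data so tests can score
recovery. All generators are pure functions of their scenario and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, GenotypeMatrix, ValidationError
from .md_dispersion import GeneSetExpression
from .power_sim import SimulationConfig, simulate_dataset

__all__ = ["DVScenario", "EvqtlScenario", "gen_dv_matrix", "gen_geneset_matrix", "gen_evqtl_data"]


@dataclass
class DVScenario:
    """Single-gene differential-variability scenario.

    A fraction of genes is planted with case standard deviation
    sqrt(variance_ratio) x control standard deviation; all other genes are
    identically distributed in both groups.
    """

    n_genes: int = 1000
    n_per_group: int = 200
    fraction_dv: float = 0.05
    variance_ratio: float = 4.0
    base_mean: float = 5.0
    base_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance_ratio <= 0:
            raise ValidationError("variance_ratio must be > 0")
        if not 0 <= self.fraction_dv <= 1:
            raise ValidationError("fraction_dv must be in [0, 1]")


@dataclass
class EvqtlScenario:
    """Genotype-dependent variance scenario (case group only).

    Genotypes are sampled under Hardy-Weinberg equilibrium at the given
    minor-allele frequency. Case expression noise follows
    ``genotype_sd_map`` (sd per dosage 0/1/2); control noise has constant
    sd, so the planted pairs are case-specific evQTLs.
    """

    n_snps: int = 1
    maf: float = 0.4
    genotype_sd_map: tuple[float, float, float] = (1.0, 2.0, 4.0)
    control_sd: float = 1.0
    n_per_group: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValidationError("maf must be in (0, 0.5]")
        if any(s <= 0 for s in self.genotype_sd_map) or self.control_sd <= 0:
            raise ValidationError("standard deviations must be > 0")


def _sample_ids(n_case: int, n_control: int) -> tuple[list[str], list[str]]:
    return ([f"case_{i}" for i in range(n_case)], [f"control_{i}" for i in range(n_control)])


def _labels(case_ids: list[str], control_ids: list[str]) -> pd.Series:
    return pd.Series(
        ["case"] * len(case_ids) + ["control"] * len(control_ids),
        index=case_ids + control_ids, name="group",
    )


def gen_dv_matrix(s: DVScenario) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression matrix with planted differentially variable genes.

    Returns the matrix and a truth table (gene_id, is_dv, case_sd,
    control_sd).
    """
    rng = np.random.default_rng(s.seed)
    genes = [f"gene_{i:05d}" for i in range(s.n_genes)]
    n_dv = int(round(s.fraction_dv * s.n_genes))
    dv_idx = rng.choice(s.n_genes, size=n_dv, replace=False)
    is_dv = np.zeros(s.n_genes, dtype=bool)
    is_dv[dv_idx] = True
    case_sd = np.where(is_dv, s.base_sd * np.sqrt(s.variance_ratio), s.base_sd)

    case_ids, control_ids = _sample_ids(s.n_per_group, s.n_per_group)
    x_case = s.base_mean + rng.standard_normal((s.n_genes, s.n_per_group)) * case_sd[:, None]
    x_ctl = s.base_mean + rng.standard_normal((s.n_genes, s.n_per_group)) * s.base_sd
    values = pd.DataFrame(np.hstack([x_case, x_ctl]), index=pd.Index(genes, name="gene_id"),
                          columns=case_ids + control_ids)
    truth = pd.DataFrame({
        "gene_id": genes, "is_dv": is_dv,
        "case_sd": case_sd, "control_sd": s.base_sd,
    })
    return ExpressionMatrix(values=values, labels=_labels(case_ids, control_ids)), truth


def gen_geneset_matrix(
    cfg: SimulationConfig,
    n: int,
    n_planted_sets: int = 5,
    n_null_sets: int = 20,
    alpha: float = 3.0,
    n_extra_genes: int = 0,
) -> tuple[ExpressionMatrix, GeneSetCollection, pd.DataFrame]:
    """Expression matrix embedding simulated gene sets, plus a matching GMT.

    ``n_planted_sets`` sets carry the case-group covariance inflation
    mechanism of :func:`dispervar.power_sim.simulate_dataset` at exponent
    ``alpha``; ``n_null_sets`` sets are identically distributed in both
    groups (inflation disabled). ``n_extra_genes`` independent null genes
    outside any set can be appended. Returns (matrix, collection, truth)
    where truth lists each set with its planted status.
    """
    rng = np.random.default_rng(cfg.seed)
    d = cfg.d
    blocks, sets, truth_rows = [], {}, []
    gene_counter = 0
    for k in range(n_planted_sets + n_null_sets):
        planted = k < n_planted_sets
        sub_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7, k]))
        if planted:
            gse = simulate_dataset(cfg, n, alpha, sub_rng)
        else:
            null_cfg = SimulationConfig(
                mu0=cfg.mu0, mu1=cfg.mu1, sigma0=cfg.sigma0, sigma1=cfg.sigma0,
                alpha_grid=cfg.alpha_grid, n_grid=cfg.n_grid, seed=cfg.seed,
            )
            x0 = null_cfg.mu0 + sub_rng.standard_normal((n, d)) @ np.linalg.cholesky(null_cfg.sigma0).T
            x1 = null_cfg.mu1 + sub_rng.standard_normal((n, d)) @ np.linalg.cholesky(null_cfg.sigma0).T
            gse = GeneSetExpression(set_name="null", genes_used=[f"g{i}" for i in range(d)], X0=x0, X1=x1)
        name = f"{'PLANTED' if planted else 'NULL'}_SET_{k:03d}"
        gene_ids = [f"gene_{gene_counter + i:05d}" for i in range(d)]
        gene_counter += d
        blocks.append((gene_ids, gse))
        sets[name] = gene_ids
        truth_rows.append({"set_name": name, "planted": planted, "alpha": alpha if planted else 0.0})

    case_ids, control_ids = _sample_ids(n, n)
    parts = []
    index = []
    for gene_ids, gse in blocks:
        # X1 = cases, X0 = controls; matrix columns are cases then controls
        parts.append(np.hstack([gse.X1.T, gse.X0.T]))
        index.extend(gene_ids)
    if n_extra_genes:
        parts.append(rng.standard_normal((n_extra_genes, 2 * n)))
        index.extend(f"extra_{i:05d}" for i in range(n_extra_genes))
    values = pd.DataFrame(np.vstack(parts), index=pd.Index(index, name="gene_id"),
                          columns=case_ids + control_ids)
    matrix = ExpressionMatrix(values=values, labels=_labels(case_ids, control_ids))
    collection = GeneSetCollection(sets=sets, descriptions={k: "synthetic" for k in sets})
    return matrix, collection, pd.DataFrame(truth_rows)


def gen_evqtl_data(
    s: EvqtlScenario,
) -> tuple[ExpressionMatrix, GenotypeMatrix, pd.Series, pd.DataFrame]:
    """Genotypes and expression with planted case-specific variance QTLs.

    One gene per SNP: case-group expression noise has the sd of the
    sample's genotype class; control noise has constant sd. Returns
    (expression, genotypes, labels, truth) where truth lists the planted
    (snp_id, gene_id) pairs.
    """
    rng = np.random.default_rng(s.seed)
    n = s.n_per_group
    case_ids, control_ids = _sample_ids(n, n)
    labels = _labels(case_ids, control_ids)
    p = s.maf
    hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])

    geno_rows, expr_rows, truth_rows = [], [], []
    snp_ids = [f"snp_{j:04d}" for j in range(s.n_snps)]
    gene_ids = [f"gene_{j:04d}" for j in range(s.n_snps)]
    sd_map = np.asarray(s.genotype_sd_map, dtype=float)
    for j in range(s.n_snps):
        g = rng.choice(3, size=2 * n, p=hwe)
        e = np.empty(2 * n)
        e[:n] = rng.standard_normal(n) * sd_map[g[:n]]  # cases
        e[n:] = rng.standard_normal(n) * s.control_sd   # controls
        geno_rows.append(g)
        expr_rows.append(e)
        truth_rows.append({"snp_id": snp_ids[j], "gene_id": gene_ids[j],
                           "planted": not np.allclose(sd_map, s.control_sd)})

    samples = case_ids + control_ids
    geno = GenotypeMatrix(
        values=pd.DataFrame(np.vstack(geno_rows), index=pd.Index(snp_ids, name="snp_id"), columns=samples),
        positions=pd.DataFrame({"chrom": ["1"] * s.n_snps,
                                "pos": np.arange(1, s.n_snps + 1) * 1000},
                               index=pd.Index(snp_ids, name="snp_id")),
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame(np.vstack(expr_rows), index=pd.Index(gene_ids, name="gene_id"), columns=samples),
        labels=labels,
    )
    return expr, geno, labels, pd.DataFrame(truth_rows)
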