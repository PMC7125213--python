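"""Group-specific expression-variability QTL (evQTL) scanning.

An evQTL is a SNP whose genotype classes differ in the *variance* (not the
mean) of a gene's expression. The scan runs a genotype-stratified
Brown-Forsythe test separately within the case and control cohorts and
classifies each SNP-gene pair by a dual threshold: case-specific when the
pair is strongly significant in cases (p < p_sig) yet clearly null in
controls (p > p_null), and symmetrically for control-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix, ValidationError
from .core_stats import bf_test_matrix

__all__ = ["EvqtlCall", "group_maf", "maf_filter", "evqtl_scan", "qq_data"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvqtlCall:
    snp_id: str
    gene_id: str
    p_case: float
    p_control: float
    maf_case: float
    maf_control: float
    classification: str  # case_specific | control_specific | neither


def _split_labels(labels: pd.Series, case_label):
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValidationError(f"two group levels required, got {levels}")
    case = case_label if case_label is not None else levels[0]
    if case not in levels:
        raise ValidationError(f"case_label {case!r} not among group levels {levels}")
    control = next(l for l in levels if l != case)
    return case, control


def group_maf(geno: GenotypeMatrix, labels: pd.Series) -> pd.DataFrame:
    """Minor-allele frequency of every SNP, computed per group.

    MAF = folded allele frequency min(f, 1 - f) with
    f = sum(dosages) / (2 x non-missing genotypes), so the result is
    invariant to which allele is coded as minor. SNPs with all genotypes
    missing in a group get NaN there.
    """
    labels = labels.reindex(geno.samples)
    if labels.isna().any():
        raise ValidationError("every genotype sample needs a group label")
    arr = geno.values.to_numpy()
    out = {}
    for level in sorted(labels.unique()):
        block = arr[:, (labels == level).to_numpy()]
        obs = block >= 0
        n_obs = obs.sum(axis=1)
        alt = np.where(obs, block, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
        out[level] = np.minimum(f, 1.0 - f)
    return pd.DataFrame(out, index=geno.snps)


def maf_filter(geno: GenotypeMatrix, labels: pd.Series, threshold: float = 0.15) -> GenotypeMatrix:
    """Retain SNPs whose MAF exceeds ``threshold`` in *both* groups.

    SNPs unobserved (all missing) in either group are excluded and logged.
    """
    maf = group_maf(geno, labels)
    unobserved = maf.isna().any(axis=1)
    if unobserved.any():
        log.info("excluding %d SNP(s) with all genotypes missing in a group", int(unobserved.sum()))
    keep = (maf > threshold).all(axis=1) & ~unobserved
    log.info("MAF filter (> %.2f in both groups): %d of %d SNPs retained",
             threshold, int(keep.sum()), len(keep))
    positions = geno.positions.loc[keep[keep].index] if geno.positions is not None else None
    return GenotypeMatrix(values=geno.values.loc[keep], positions=positions)


def _stratified_bf(expr_block: np.ndarray, genotypes: np.ndarray, min_group: int) -> np.ndarray:
    """Brown-Forsythe p-values of each expression row across genotype classes.

    Missing genotypes are dropped; classes with fewer than ``min_group``
    samples are dropped from the test. Returns NaN for every row when fewer
    than two classes remain.
    """
    mask = genotypes >= 0
    g = genotypes[mask]
    classes, counts = np.unique(g, return_counts=True)
    keep_classes = classes[counts >= max(min_group, 2)]
    if keep_classes.size < 2:
        return np.full(expr_block.shape[0], np.nan)
    sel = np.isin(g, keep_classes)
    sub = expr_block[:, mask][:, sel]
    _, p = bf_test_matrix(sub, g[sel])
    return p


def evqtl_scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    pairs: list[tuple[str, str]] | None = None,
    p_sig: float = 1e-7,
    p_null: float = 0.05,
    min_group: int = 5,
    case_label=None,
    include_neither: bool = False,
) -> pd.DataFrame:
    """Scan SNP-gene pairs for group-specific variance QTLs.

    For each pair, a Brown-Forsythe test across the SNP's genotype classes
    (0/1/2) is run within cases and within controls separately. A pair is
    ``case_specific`` when p_case < ``p_sig`` and p_control > ``p_null``
    (strict inequalities), and symmetrically ``control_specific``. By
    default only specific calls are returned; ``include_neither=True``
    returns every tested pair exactly once.

    Parameters
    ----------
    pairs
        (snp_id, gene_id) pairs to test; ``None`` tests all SNP x gene
        combinations.
    min_group
        genotype classes with fewer samples are dropped from that SNP's
        test; pairs with < 2 remaining classes in a group are skipped
        (logged).
    """
    labels = expr.labels
    case, control = _split_labels(labels, case_label)
    common = expr.samples.intersection(geno.samples)
    if len(common) == 0:
        raise ValidationError("expression and genotype matrices share no samples")
    maf = group_maf(geno, labels.reindex(common))

    if pairs is None:
        by_snp: dict[str, list[str]] = {s: list(expr.genes) for s in geno.snps}
    else:
        by_snp = {}
        for snp, gene in pairs:
            if snp not in geno.snps:
                raise ValidationError(f"unknown SNP {snp!r}")
            if gene not in expr.genes:
                raise ValidationError(f"unknown gene {gene!r}")
            by_snp.setdefault(snp, []).append(gene)

    case_samples = [s for s in common if labels[s] == case]
    ctl_samples = [s for s in common if labels[s] == control]
    rows = []
    n_skipped = 0
    for snp, genes in by_snp.items():
        g_case = geno.values.loc[snp, case_samples].to_numpy()
        g_ctl = geno.values.loc[snp, ctl_samples].to_numpy()
        e_case = expr.values.loc[genes, case_samples].to_numpy()
        e_ctl = expr.values.loc[genes, ctl_samples].to_numpy()
        p_case_vec = _stratified_bf(e_case, g_case, min_group)
        p_ctl_vec = _stratified_bf(e_ctl, g_ctl, min_group)
        for gene, pc, p0 in zip(genes, p_case_vec, p_ctl_vec):
            if np.isnan(pc) or np.isnan(p0):
                n_skipped += 1
                continue
            if pc < p_sig and p0 > p_null:
                cls = "case_specific"
            elif p0 < p_sig and pc > p_null:
                cls = "control_specific"
            else:
                cls = "neither"
            if cls == "neither" and not include_neither:
                continue
            rows.append({
                "snp_id": snp, "gene_id": gene,
                "p_case": pc, "p_control": p0,
                "maf_case": maf.loc[snp, case], "maf_control": maf.loc[snp, control],
                "classification": cls,
            })
    if n_skipped:
        log.info("skipped %d pair(s) with < 2 usable genotype classes", n_skipped)
    cols = ["snp_id", "gene_id", "p_case", "p_control", "maf_case", "maf_control", "classification"]
    out = pd.DataFrame(rows, columns=cols)
    if geno.positions is not None and not out.empty:
        out = out.merge(geno.positions, left_on="snp_id", right_index=True, how="left")
    return out


def qq_data(p_y, p_x) -> pd.DataFrame:
    """Paired sorted -log10(p) quantiles for a quantile-quantile plot.

    Quantiles of both collections are evaluated at the plotting positions
    (i - 0.5)/m of the smaller collection, so collections of unequal size
    remain comparable. Identical collections fall on the diagonal. No
    plotting is performed.
    """
    p_y = np.asarray(p_y, dtype=float)
    p_x = np.asarray(p_x, dtype=float)
    if p_y.size == 0 or p_x.size == 0:
        return pd.DataFrame(columns=["neglog10_x", "neglog10_y"])
    m = min(p_y.size, p_x.size)
    probs = (np.arange(1, m + 1) - 0.5) / m
    qy = np.quantile(np.sort(-np.log10(p_y)), probs)
    qx = np.quantile(np.sort(-np.log10(p_x)), probs)
    return pd.DataFrame({"neglog10_x": qx, "neglog10_y": qy})
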