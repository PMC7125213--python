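"""Per-gene differential-variability testing.

The workhorse is the Brown-Forsythe test: a Levene-type test for equality
of group variances that scores each observation by its absolute deviation
from the group *median* (robust against non-normality) and compares the
scores across groups with a one-way ANOVA. Applied gene-by-gene to a
two-group expression matrix it yields a table of differentially variable
(DV) genes, with Benjamini-Hochberg control of the false discovery rate
across the whole scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ValidationError

__all__ = ["BFResult", "bf_test", "bf_test_matrix", "bh_fdr", "dv_scan"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BFResult:
    """One-way F test on absolute deviations from group medians."""

    statistic: float
    p_value: float
    df_between: int
    df_within: int


def _deviation_scores(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    return [np.abs(g - np.median(g)) for g in groups]


def bf_test(*groups) -> BFResult:
    """Brown-Forsythe test for equality of variances across k >= 2 groups.

    Parameters
    ----------
    *groups
        Two or more 1-d arrays of finite values, each of length >= 2.

    Returns
    -------
    BFResult
        F statistic on median-centred absolute deviations, its upper-tail
        p-value, and the ANOVA degrees of freedom.

    Notes
    -----
    When every deviation score is identical within and between groups the
    F statistic is a degenerate 0/0; by convention the test then reports
    statistic 0 and p = 1 ("no evidence of a variance difference").
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValidationError("bf_test requires at least two groups")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValidationError(f"group {i} has fewer than 2 observations")
        if not np.isfinite(a).all():
            raise ValidationError(f"group {i} contains non-finite values")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    z = _deviation_scores(arrays)
    grand = np.concatenate(z).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in z)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in z)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0 and ssb == 0.0:
        log.warning("degenerate Brown-Forsythe input (all deviations equal); reporting F=0, p=1")
        return BFResult(0.0, 1.0, df_b, df_w)
    if ssw == 0.0:
        return BFResult(float("inf"), 0.0, df_b, df_w)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return BFResult(float(f), p, df_b, df_w)


def bf_test_matrix(values: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Brown-Forsythe test over many features at once.

    Parameters
    ----------
    values
        (features x samples) array.
    groups
        Integer class code per sample; every class needs >= 2 samples.

    Returns
    -------
    (F, p)
        Arrays of length ``features``. Degenerate 0/0 rows yield (0, 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    codes = np.unique(groups)
    if codes.size < 2:
        raise ValidationError("bf_test_matrix requires at least two classes")
    n_total = values.shape[1]
    z_parts, means, sizes = [], [], []
    ssw = np.zeros(values.shape[0])
    for c in codes:
        block = values[:, groups == c]
        if block.shape[1] < 2:
            raise ValidationError(f"class {c!r} has fewer than 2 samples")
        z = np.abs(block - np.median(block, axis=1, keepdims=True))
        m = z.mean(axis=1)
        ssw += ((z - m[:, None]) ** 2).sum(axis=1)
        z_parts.append(z)
        means.append(m)
        sizes.append(block.shape[1])
    means = np.column_stack(means)
    sizes = np.asarray(sizes, dtype=float)
    grand = means @ sizes / n_total
    ssb = ((means - grand[:, None]) ** 2 @ sizes)
    df_b, df_w = codes.size - 1, n_total - codes.size
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = np.where(ssw > 0, stats.f.sf(np.where(ssw > 0, f, 0.0), df_b, df_w), 0.0)
    degenerate = (ssw == 0) & (ssb == 0)
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, p)
    return f, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; adjusted values are clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dv_scan(matrix: ExpressionMatrix, fdr_level: float = 0.05, case_label=None) -> pd.DataFrame:
    """Scan every gene for a case-vs-control difference in expression variance.

    Runs the Brown-Forsythe test per gene, adjusts all p-values jointly with
    Benjamini-Hochberg, and flags genes with q <= ``fdr_level``. The
    ``direction`` column is the sign of (case sample variance - control
    sample variance); it annotates but never enters the test.

    Parameters
    ----------
    matrix
        Expression matrix with exactly two group levels.
    fdr_level
        FDR threshold for the ``significant`` flag.
    case_label
        Which group level is the "case" group for the direction sign.
        Defaults to the first level in sorted order.

    Returns
    -------
    DataFrame indexed by gene with columns statistic, p_value, q_value,
    direction, significant.
    """
    levels = matrix.group_levels
    if len(levels) != 2:
        raise ValidationError(f"dv_scan requires exactly two group levels, got {levels}")
    if case_label is None:
        case_label = levels[0]
    elif case_label not in levels:
        raise ValidationError(f"case_label {case_label!r} not among group levels {levels}")
    control_label = next(l for l in levels if l != case_label)

    genes = list(matrix.genes)
    x_case = matrix.group_matrix(genes, case_label).T  # genes x n_case
    x_ctl = matrix.group_matrix(genes, control_label).T
    values = np.concatenate([x_case, x_ctl], axis=1)
    groups = np.concatenate([np.zeros(x_case.shape[1], int), np.ones(x_ctl.shape[1], int)])
    f, p = bf_test_matrix(values, groups)
    n_degenerate = int(((f == 0) & (p == 1)).sum())
    if n_degenerate:
        log.info("%d gene(s) with degenerate (constant-deviation) Brown-Forsythe input", n_degenerate)
    q = bh_fdr(p)
    direction = np.sign(x_case.var(axis=1, ddof=1) - x_ctl.var(axis=1, ddof=1))
    return pd.DataFrame(
        {
            "statistic": f,
            "p_value": p,
            "q_value": q,
            "direction": direction.astype(int),
            "significant": q <= fdr_level,
        },
        index=pd.Index(genes, name="gene_id"),
    )
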