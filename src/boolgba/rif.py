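"""Regulatory impact factors (RIF1, RIF2) for transcription factors.

RIF ranks transcription factors between two conditions by how much their
co-expression with the abundant, differentially expressed (DE) genes
changes. For TF j over the DE genes i:

    RIF1_j = (1 / n_DE) * sum_i PIF_i * (r_ijA - r_ijB)^2,
    PIF_i  = a_i * d_i

with a_i the mean abundance of DE gene i across the two conditions, d_i the
difference of its condition means, and r_ijA / r_ijB the within-condition
Pearson correlations between TF j and gene i (differential co-expression
with phenotype-relevant genes). RIF2 measures the change in the TF's
ability to predict DE gene abundance:

    RIF2_j = (1 / n_DE) * sum_i [(e_iA * r_ijA)^2 - (e_iB * r_ijB)^2]

with e the condition-mean abundance. Both are standardized to z-scores
across the TF set; regulators with |z| > 2 on either score are flagged
extreme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .expression import ExpressionMatrix

__all__ = ["RifScores", "rif_scores"]


@dataclass
class RifScores:
    """Raw and z-standardized RIF scores per transcription factor."""

    tf_ids: list[str]
    rif1_raw: np.ndarray
    rif2_raw: np.ndarray
    rif1_z: np.ndarray
    rif2_z: np.ndarray
    extreme: np.ndarray  # |z| > 2 on either score
    de_genes: list[str]
    conditions: tuple[str, str]
    excluded_tfs: list[str]

    def extreme_tfs(self) -> list[str]:
        return [t for t, e in zip(self.tf_ids, self.extreme) if e]


def _zscores(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _cond_stats(expr: ExpressionMatrix, condition: str):
    cols = expr.samples_in(condition)
    if len(cols) < 3:
        raise ValueError(
            f"condition {condition!r} has {len(cols)} samples; need >= 3"
        )
    sub = expr.values[:, cols]
    return sub, sub.mean(axis=1), sub.std(axis=1)


def rif_scores(
    expr: ExpressionMatrix,
    tf_list: set[str],
    de_genes: set[str],
    cond_a: str,
    cond_b: str,
    z_cut: float = 2.0,
) -> RifScores:
    """Compute RIF1/RIF2 for every TF between two conditions.

    TFs with zero expression variance in either condition are excluded with
    a warning (their correlations are undefined); a TF that is itself a DE
    gene is scored against the other DE genes only. Raises when no DE gene
    is present in the matrix.
    """
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    tfs = sorted(t for t in tf_list if t in gene_index)
    if not tfs:
        raise ValueError("no transcription factor present in the matrix")
    de = sorted(g for g in de_genes if g in gene_index)
    if not de:
        raise ValueError("no DE gene present in the expression matrix")

    sub_a, mean_a, sd_a = _cond_stats(expr, cond_a)
    sub_b, mean_b, sd_b = _cond_stats(expr, cond_b)

    de_idx = np.array([gene_index[g] for g in de])
    de_sd_ok = (sd_a[de_idx] > 0) & (sd_b[de_idx] > 0)
    if not de_sd_ok.all():
        warnings.warn(
            f"{int((~de_sd_ok).sum())} DE genes have zero variance in a "
            "condition; their correlation terms are treated as zero",
            stacklevel=2,
        )

    kept, excluded = [], []
    for t in tfs:
        i = gene_index[t]
        if sd_a[i] > 0 and sd_b[i] > 0:
            kept.append(t)
        else:
            excluded.append(t)
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} TFs with zero within-condition "
            "variance",
            stacklevel=2,
        )
    if not kept:
        raise ValueError("every TF has zero variance in some condition")

    abund = 0.5 * (mean_a[de_idx] + mean_b[de_idx])  # a_i
    ddiff = mean_a[de_idx] - mean_b[de_idx]  # d_i
    pif = abund * ddiff
    e_a, e_b = mean_a[de_idx], mean_b[de_idx]

    def _corr_row(tf_row: np.ndarray, sub: np.ndarray, tf_sd: float, sd: np.ndarray):
        """Pearson r between one TF and each DE gene within one condition."""
        tf_c = tf_row - tf_row.mean()
        de_c = sub[de_idx] - sub[de_idx].mean(axis=1, keepdims=True)
        cov = de_c @ tf_c / tf_row.size
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / (tf_sd * sd[de_idx])
        return np.where(de_sd_ok, np.nan_to_num(r), 0.0)

    rif1 = np.empty(len(kept))
    rif2 = np.empty(len(kept))
    for k, t in enumerate(kept):
        i = gene_index[t]
        r_a = _corr_row(sub_a[i], sub_a, sd_a[i], sd_a)
        r_b = _corr_row(sub_b[i], sub_b, sd_b[i], sd_b)
        self_mask = de_idx != i  # a TF never targets itself
        n_terms = int(self_mask.sum())
        if n_terms == 0:
            rif1[k] = rif2[k] = 0.0
            continue
        rif1[k] = float(
            (pif[self_mask] * (r_a[self_mask] - r_b[self_mask]) ** 2).sum() / n_terms
        )
        rif2[k] = float(
            (
                (e_a[self_mask] * r_a[self_mask]) ** 2
                - (e_b[self_mask] * r_b[self_mask]) ** 2
            ).sum()
            / n_terms
        )

    z1, z2 = _zscores(rif1), _zscores(rif2)
    extreme = (np.abs(z1) > z_cut) | (np.abs(z2) > z_cut)
    return RifScores(
        tf_ids=kept,
        rif1_raw=rif1,
        rif2_raw=rif2,
        rif1_z=z1,
        rif2_z=z2,
        extreme=extreme,
        de_genes=de,
        conditions=(cond_a, cond_b),
        excluded_tfs=excluded,
    )
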