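"""Expression normalization, mixture-model DE calling and condition specificity.

The analysis pipeline for a genes x samples matrix of log2 intensities with
samples grouped into experimental conditions (typically four: normal,
adenoma, carcinoma, inflammation):

1. :func:`normalize_expression` removes per-hybridization (sample) offsets
   with a parsimonious sequential ANOVA-style fit and returns per-condition
   normalized means per gene.
2. :func:`call_differential_expression` models the per-gene contrast
   differences as a two-component normal mixture (null vs differentially
   expressed) and flags genes at a target experiment-wise FDR.
3. :func:`condition_specificity` computes, per gene, the share of its
   expression attributable to each condition (CS_ij = x_ij / sum_j x_ij) and
   flags genes that are condition specific under three criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "NormalizationResult",
    "MixtureFit",
    "DeResult",
    "CsResult",
    "normalize_expression",
    "fit_two_component_mixture",
    "call_differential_expression",
    "condition_specificity",
    "drop_constant_genes",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression with condition labels.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers (rows).
    sample_ids : list of str
        Unique sample identifiers (columns).
    values : ndarray of shape (n_genes, n_samples)
        Finite log2-scale intensities.
    condition_of : dict
        Mapping from sample id to condition label; every sample must be
        mapped, and at least two distinct conditions are required.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        missing = [s for s in self.sample_ids if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if len(self.conditions) < 2:
            raise ValueError("at least two conditions are required")

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance (sample) order."""
        seen: list[str] = []
        for s in self.sample_ids:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_in(self, condition: str) -> list[int]:
        """Column indices of the samples belonging to ``condition``."""
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        return [
            j for j, s in enumerate(self.sample_ids) if self.condition_of[s] == condition
        ]


@dataclass
class NormalizationResult:
    """Sequentially estimated ANOVA effects and normalized condition means."""

    gene_ids: list[str]
    conditions: list[str]
    hybridization_effects: dict[str, float]
    gene_effects: dict[str, float]
    gene_condition_means: np.ndarray  # genes x conditions, normalized scale
    residuals: np.ndarray  # genes x samples

    def contrast_difference(self, cond_a: str, cond_b: str) -> np.ndarray:
        """Per-gene normalized difference ``mean(A) - mean(B)``."""
        for c in (cond_a, cond_b):
            if c not in self.conditions:
                raise KeyError(f"unknown condition {c!r}")
        a = self.conditions.index(cond_a)
        b = self.conditions.index(cond_b)
        return self.gene_condition_means[:, a] - self.gene_condition_means[:, b]


@dataclass
class MixtureFit:
    """Parameters and posteriors of a two-component normal mixture.

    The null component is the one whose mean is closer to zero (ties broken
    by the smaller standard deviation); ``posteriors`` hold, per input value,
    the probability of the alternative (non-null) component.
    """

    weight_null: float
    mean_null: float
    sd_null: float
    mean_alt: float
    sd_alt: float
    posteriors: np.ndarray
    converged: bool
    n_iterations: int
    log_likelihood: float = float("nan")


@dataclass
class DeResult:
    """Differential-expression call for one contrast."""

    contrast: tuple[str, str]
    gene_ids: list[str]
    difference: np.ndarray
    posterior: np.ndarray
    de_flag: np.ndarray
    fdr_target: float = 0.01
    mixture: MixtureFit | None = field(default=None, repr=False)

    def de_genes(self) -> set[str]:
        return {g for g, f in zip(self.gene_ids, self.de_flag) if f}


@dataclass
class CsResult:
    """Condition-specificity scores and flags.

    ``cs[i, j]`` is gene i's expression in condition j divided by its summed
    expression over all conditions; rows of excluded genes (zero total
    expression) are NaN and never flagged.
    """

    gene_ids: list[str]
    conditions: list[str]
    cs: np.ndarray
    cs_flag: np.ndarray
    excluded: np.ndarray  # per-gene bool: zero total expression
    shift: float = 0.0  # applied to make all means non-negative

    def specific_genes(self, condition: str) -> set[str]:
        j = self.conditions.index(condition)
        return {g for g, f in zip(self.gene_ids, self.cs_flag[:, j]) if f}


def normalize_expression(expr: ExpressionMatrix) -> NormalizationResult:
    """Estimate hybridization, gene and gene x condition effects sequentially.

    The hybridization (sample) effect is the column mean over genes; the gene
    effect is the row mean of hybridization-adjusted values; the
    gene x condition mean is the gene effect plus the condition-wise mean of
    the twice-adjusted values, i.e. the normalized per-condition expression
    consumed by the DE and condition-specificity steps. Residuals are the
    remainders and average to zero within every gene x condition cell.
    """
    if len(expr.gene_ids) < 2:
        raise ValueError("normalization requires at least 2 genes")
    conditions = expr.conditions
    cond_cols = {c: expr.samples_in(c) for c in conditions}
    for c, cols in cond_cols.items():
        if not cols:
            raise ValueError(f"condition {c!r} has no samples")

    v = expr.values
    hyb = v.mean(axis=0)  # per sample
    adj = v - hyb[None, :]
    gene_eff = adj.mean(axis=1)  # per gene
    adj2 = adj - gene_eff[:, None]

    n_genes = len(expr.gene_ids)
    gc_means = np.empty((n_genes, len(conditions)))
    residuals = np.empty_like(v)
    for k, c in enumerate(conditions):
        cols = cond_cols[c]
        cell_dev = adj2[:, cols].mean(axis=1)
        gc_means[:, k] = gene_eff + cell_dev
        residuals[:, cols] = adj2[:, cols] - cell_dev[:, None]

    return NormalizationResult(
        gene_ids=list(expr.gene_ids),
        conditions=conditions,
        hybridization_effects=dict(zip(expr.sample_ids, hyb.tolist())),
        gene_effects=dict(zip(expr.gene_ids, gene_eff.tolist())),
        gene_condition_means=gc_means,
        residuals=residuals,
    )


def _mixture_loglik(x: np.ndarray, w0, m0, s0, m1, s1) -> float:
    dens = w0 * stats.norm.pdf(x, m0, s0) + (1.0 - w0) * stats.norm.pdf(x, m1, s1)
    return float(np.log(np.maximum(dens, 1e-300)).sum())


def fit_two_component_mixture(
    values: np.ndarray,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureFit:
    """Fit a two-component normal mixture by EM.

    Initialization is a median split of the values (deterministic); ``seed``
    is accepted for interface stability and reserved for random restarts.
    The null component is the one with mean closer to zero, with ties broken
    by the smaller standard deviation. Raises on fewer than 10 values or a
    zero-variance input.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 10:
        raise ValueError(f"need at least 10 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in mixture input")
    if np.ptp(x) == 0.0:
        raise ValueError("zero-variance input: all values identical")

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    sd_floor = max(1e-8 * np.std(x), 1e-12)
    m0, s0 = lo.mean(), max(lo.std(), sd_floor)
    m1, s1 = hi.mean(), max(hi.std(), sd_floor)
    w0 = 0.5

    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step
        d0 = w0 * stats.norm.pdf(x, m0, s0)
        d1 = (1.0 - w0) * stats.norm.pdf(x, m1, s1)
        tot = np.maximum(d0 + d1, 1e-300)
        r1 = d1 / tot
        r0 = 1.0 - r1
        # M step
        n0, n1 = r0.sum(), r1.sum()
        if n0 < 1e-10 or n1 < 1e-10:
            break  # one component vanished; keep last parameters
        w0 = n0 / x.size
        m0 = float((r0 * x).sum() / n0)
        m1 = float((r1 * x).sum() / n1)
        s0 = max(float(np.sqrt((r0 * (x - m0) ** 2).sum() / n0)), sd_floor)
        s1 = max(float(np.sqrt((r1 * (x - m1) ** 2).sum() / n1)), sd_floor)
        ll = _mixture_loglik(x, w0, m0, s0, m1, s1)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll

    # identify the null component: mean closer to 0, tie-break by smaller sd
    comp0, comp1 = (w0, m0, s0), (1.0 - w0, m1, s1)
    key0 = (round(abs(m0), 12), s0)
    key1 = (round(abs(m1), 12), s1)
    if key1 < key0:
        comp0, comp1 = comp1, comp0
    wn, mn, sn = comp0
    _, ma, sa = comp1
    d_null = wn * stats.norm.pdf(x, mn, sn)
    d_alt = (1.0 - wn) * stats.norm.pdf(x, ma, sa)
    post = d_alt / np.maximum(d_null + d_alt, 1e-300)

    return MixtureFit(
        weight_null=float(wn),
        mean_null=float(mn),
        sd_null=float(sn),
        mean_alt=float(ma),
        sd_alt=float(sa),
        posteriors=post,
        converged=converged,
        n_iterations=n_iter,
        log_likelihood=ll_old,
    )


def call_differential_expression(
    norm: NormalizationResult,
    contrast: tuple[str, str],
    fdr_target: float = 0.01,
    seed: int = 0,
) -> DeResult:
    """Flag differentially expressed genes for one contrast.

    The per-gene contrast differences of normalized condition means are
    modeled as a two-component normal mixture; genes are flagged in
    decreasing order of alternative posterior for as long as the running
    mean of (1 - posterior) over the flagged set — the estimated
    experiment-wise FDR — stays at or below ``fdr_target``.
    """
    cond_a, cond_b = contrast
    diff = norm.contrast_difference(cond_a, cond_b)
    if np.ptp(diff) == 0.0:
        # no variation between conditions: nothing can be flagged
        n = len(norm.gene_ids)
        return DeResult(
            contrast=(cond_a, cond_b),
            gene_ids=list(norm.gene_ids),
            difference=diff.copy(),
            posterior=np.zeros(n),
            de_flag=np.zeros(n, dtype=bool),
            fdr_target=fdr_target,
        )
    fit = fit_two_component_mixture(diff, seed=seed)
    post = fit.posteriors
    order = np.argsort(-post, kind="stable")
    local_fdr = 1.0 - post[order]
    running_fdr = np.cumsum(local_fdr) / np.arange(1, diff.size + 1)
    ok = np.nonzero(running_fdr <= fdr_target)[0]
    flags = np.zeros(diff.size, dtype=bool)
    if ok.size:
        flags[order[: ok[-1] + 1]] = True
    return DeResult(
        contrast=(cond_a, cond_b),
        gene_ids=list(norm.gene_ids),
        difference=diff,
        posterior=post,
        de_flag=flags,
        fdr_target=fdr_target,
        mixture=fit,
    )


def condition_specificity(
    norm: NormalizationResult, include_focal: bool = False
) -> CsResult:
    """Compute CS_ij = x_ij / sum_j x_ij and the condition-specific flags.

    The normalized means are shifted by the global minimum when negative so
    that the ratio is taken over non-negative values (the shift is recorded).
    A gene is flagged specific to condition j iff its (shifted) expression is
    (1) above the gene-wise average expression in condition j, (2) strictly
    its own maximum across conditions, and (3) its CS_ij exceeds the mean
    plus three standard deviations of the CS values of all other genes in
    condition j (``include_focal=True`` includes the focal gene in that
    reference population).
    """
    x = norm.gene_condition_means.copy()
    shift = 0.0
    if x.min() < 0:
        shift = -float(x.min())
        x = x + shift

    totals = x.sum(axis=1)
    excluded = totals <= 0
    n_genes, n_cond = x.shape
    cs = np.full_like(x, np.nan)
    ok = ~excluded
    cs[ok] = x[ok] / totals[ok, None]

    flags = np.zeros_like(x, dtype=bool)
    col_means = x.mean(axis=0)
    n_ok = int(ok.sum())
    for j in range(n_cond):
        col = cs[:, j]
        if include_focal or n_ok < 2:
            mu = np.nanmean(col)
            sd = np.nanstd(col)
            thresh = np.full(n_genes, mu + 3.0 * sd)
        else:
            # leave-one-out mean/sd over the other genes' CS values
            s1 = np.nansum(col)
            s2 = np.nansum(col**2)
            m_loo = (s1 - np.where(ok, col, 0.0)) / (n_ok - 1)
            v_loo = (s2 - np.where(ok, col**2, 0.0)) / (n_ok - 1) - m_loo**2
            thresh = m_loo + 3.0 * np.sqrt(np.maximum(v_loo, 0.0))
        others_max = np.max(
            np.delete(x, j, axis=1), axis=1
        ) if n_cond > 1 else np.full(n_genes, -np.inf)
        crit1 = x[:, j] > col_means[j]
        crit2 = x[:, j] > others_max
        with np.errstate(invalid="ignore"):
            crit3 = col > thresh
        flags[:, j] = ok & crit1 & crit2 & crit3

    return CsResult(
        gene_ids=list(norm.gene_ids),
        conditions=list(norm.conditions),
        cs=cs,
        cs_flag=flags,
        excluded=excluded,
        shift=shift,
    )


def drop_constant_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Return a copy of ``expr`` without all-constant gene rows."""
    keep = np.ptp(expr.values, axis=1) > 0
    if keep.all():
        return expr
    dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
    warnings.warn(f"dropping {len(dropped)} constant gene rows", stacklevel=2)
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(expr.gene_ids, keep) if k],
        sample_ids=list(expr.sample_ids),
        values=expr.values[keep],
        condition_of=dict(expr.condition_of),
    )
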