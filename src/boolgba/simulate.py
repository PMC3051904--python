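"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Two generators cover the pipeline's three inputs:

* :func:`simulate_expression` builds a log2-scale genes x samples matrix over
  four conditions with per-sample hybridization offsets, Gaussian noise,
  planted differentially expressed genes (a mean shift in one designated
  condition) and planted condition-specific genes (a fold increase in one
  condition).
* :func:`simulate_attributes` builds the six-attribute table together with a
  disease/background split in which the disease genes carry enriched
  attribute frequencies, emulating the over-representation of attributes
  such as PTM and kinases among known disease genes.

Both record the planted truth so recovery can be checked, and are
bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionMatrix
from .profiles import ATTRIBUTES, AttributeTable, TrainingSet

__all__ = [
    "SyntheticTruth",
    "DEFAULT_CONDITIONS",
    "DEFAULT_BASE_RATES",
    "DEFAULT_ENRICHMENT_ODDS",
    "simulate_expression",
    "simulate_attributes",
]

DEFAULT_CONDITIONS: tuple[str, ...] = (
    "Normal",
    "Adenoma",
    "Carcinoma",
    "Inflammation",
)

#: Background attribute frequencies. KIN reflects ~500 kinase genes in a
#: ~21000-gene genome; SEC reflects ~1800 annotated secreted proteins; the
#: others are round figures of the same order.
DEFAULT_BASE_RATES: dict[str, float] = {
    "TS": 0.10,
    "TF": 0.08,
    "PTM": 0.10,
    "KIN": 0.024,
    "SEC": 0.08,
    "MET": 0.05,
}

#: Disease-set enrichment multipliers: PTMs are ~4x over-represented among
#: disease genes (~40% vs ~10%) and kinases ~12x (~30% vs ~2.4%); the
#: remaining attributes get modest enrichment.
DEFAULT_ENRICHMENT_ODDS: dict[str, float] = {
    "TS": 2.5,
    "TF": 3.0,
    "PTM": 4.0,
    "KIN": 12.0,
    "SEC": 2.0,
    "MET": 2.0,
}


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    de_genes: dict[str, set[str]] = field(default_factory=dict)  # condition -> genes
    de_contrast_genes: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    cs_genes: dict[str, set[str]] = field(default_factory=dict)  # condition -> genes
    disease_genes: set[str] = field(default_factory=set)
    background_genes: set[str] = field(default_factory=set)
    attribute_rates: dict[str, dict[str, float]] = field(default_factory=dict)


def _sample_counts(n_samples_per_condition, conditions) -> list[int]:
    if np.isscalar(n_samples_per_condition):
        return [int(n_samples_per_condition)] * len(conditions)
    counts = [int(c) for c in n_samples_per_condition]
    if len(counts) != len(conditions):
        raise ValueError("one sample count per condition required")
    return counts


def simulate_expression(
    n_genes: int = 1000,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    n_samples_per_condition=(8, 15, 15, 15),
    n_de: int = 30,
    de_effect_sd: float = 4.0,
    de_condition: str | None = "Carcinoma",
    n_cs: int = 5,
    cs_fold: float = 10.0,
    noise_sd: float = 0.5,
    hyb_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a log2-scale expression matrix with planted structure.

    Baseline gene means are drawn from Normal(8, 2) — the value range of
    typical log2 microarray intensities. Planted DE genes are shifted
    upward by ``de_effect_sd * noise_sd`` in ``de_condition`` (or, when
    ``de_condition`` is None, in a condition cycling over all four, which
    plants contrast-specific DE genes); planted condition-specific genes
    have one condition's mean multiplied by ``cs_fold``. Per-sample
    hybridization offsets (SD ``hyb_sd``) and i.i.d. Gaussian noise (SD
    ``noise_sd``) are added so the normalization step is exercised.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if n_de < 0 or n_cs < 0 or n_genes <= 0:
        raise ValueError("counts must be positive")
    if n_de + n_cs > n_genes:
        raise ValueError("n_de + n_cs exceeds n_genes")
    conditions = tuple(conditions)
    if de_condition is not None and de_condition not in conditions:
        raise ValueError(f"unknown de_condition {de_condition!r}")
    counts = _sample_counts(n_samples_per_condition, conditions)

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    baseline = rng.normal(8.0, 2.0, size=n_genes)
    n_cond = len(conditions)
    cond_means = np.tile(baseline[:, None], (1, n_cond))

    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_de": n_de,
            "de_effect_sd": de_effect_sd,
            "de_condition": de_condition,
            "n_cs": n_cs,
            "cs_fold": cs_fold,
            "noise_sd": noise_sd,
            "hyb_sd": hyb_sd,
        },
        de_genes={c: set() for c in conditions},
        cs_genes={c: set() for c in conditions},
    )

    planted = rng.choice(n_genes, size=n_de + n_cs, replace=False)
    de_rows, cs_rows = planted[:n_de], planted[n_de:]
    for k, i in enumerate(de_rows):
        cond = de_condition if de_condition is not None else conditions[k % n_cond]
        j = conditions.index(cond)
        cond_means[i, j] += de_effect_sd * noise_sd
        truth.de_genes[cond].add(gene_ids[i])
    for k, i in enumerate(cs_rows):
        j = k % n_cond
        cond_means[i, j] *= cs_fold
        truth.cs_genes[conditions[j]].add(gene_ids[i])

    # a gene is DE for contrast (A, B) iff it was shifted in A or in B
    for a in conditions:
        for b in conditions:
            if a != b:
                truth.de_contrast_genes[(a, b)] = truth.de_genes[a] | truth.de_genes[b]

    sample_ids: list[str] = []
    condition_of: dict[str, str] = {}
    cols: list[np.ndarray] = []
    for j, (c, n_s) in enumerate(zip(conditions, counts)):
        if n_s < 1:
            raise ValueError(f"condition {c!r} needs at least one sample")
        for s in range(n_s):
            sid = f"{c}_{s + 1:02d}"
            sample_ids.append(sid)
            condition_of[sid] = c
            offset = rng.normal(0.0, hyb_sd)
            cols.append(cond_means[:, j] + offset + rng.normal(0.0, noise_sd, n_genes))
    values = np.column_stack(cols)

    expr = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        condition_of=condition_of,
    )
    return expr, truth


def simulate_attributes(
    n_genes: int = 1000,
    disease_fraction: float = 0.1,
    enrichment_odds: dict[str, float] | None = None,
    base_rates: dict[str, float] | None = None,
    gene_ids: list[str] | None = None,
    seed: int = 0,
) -> tuple[AttributeTable, TrainingSet, SyntheticTruth]:
    """Generate an attribute table with an attribute-enriched disease set.

    Attribute a is true with probability ``base_rates[a]`` for background
    genes and ``base_rates[a] * enrichment_odds[a]`` for disease genes
    (raises when that product reaches 1). The first
    ``round(disease_fraction * n_genes)`` genes of a seeded permutation form
    the disease set.
    """
    base = dict(DEFAULT_BASE_RATES, **(base_rates or {}))
    odds = dict(DEFAULT_ENRICHMENT_ODDS, **(enrichment_odds or {}))
    for a in ATTRIBUTES:
        if not 0.0 < base[a] < 1.0:
            raise ValueError(f"base rate of {a} out of (0,1): {base[a]}")
        if odds[a] <= 0:
            raise ValueError(f"enrichment odds of {a} must be > 0")
        if base[a] * odds[a] >= 1.0:
            raise ValueError(
                f"disease probability of {a} reaches 1: "
                f"{base[a]} * {odds[a]} = {base[a] * odds[a]}"
            )
    if not 0.0 < disease_fraction < 1.0:
        raise ValueError("disease_fraction must be in (0,1)")
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    rng = np.random.default_rng(seed)
    n_disease = int(round(disease_fraction * n_genes))
    if not 0 < n_disease < n_genes:
        raise ValueError("disease set would be empty or cover all genes")
    perm = rng.permutation(n_genes)
    disease = {gene_ids[i] for i in perm[:n_disease]}
    background = {gene_ids[i] for i in perm[n_disease:]}

    flags: dict[str, dict[str, bool]] = {}
    for g in gene_ids:
        rates = {
            a: base[a] * odds[a] if g in disease else base[a] for a in ATTRIBUTES
        }
        flags[g] = {a: bool(rng.random() < rates[a]) for a in ATTRIBUTES}

    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "disease_fraction": disease_fraction,
            "base_rates": base,
            "enrichment_odds": odds,
        },
        disease_genes=disease,
        background_genes=background,
        attribute_rates={
            "background": base,
            "disease": {a: base[a] * odds[a] for a in ATTRIBUTES},
        },
    )
    return AttributeTable(flags=flags), TrainingSet(disease, background), truth
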