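"""Two-step computational validation of the GBA ranking.

Step 1 measures how much higher the mean GBA score of known disease genes is
than that of the other genes (the *fold ratio*). Step 2 runs a repeated
random 4/5-train / 1/5-test cross-validation: each iteration rebuilds the
truth table from the training fold, pools the held-out disease genes with
the background genes, ranks the pool, and records the fraction of held-out
disease genes captured in each top x-percentile. The smallest percentile at
which the mean enrichment (capture over x/100) reaches the step-1 fold
ratio calibrates the candidate cut-off.

Held-out disease genes are pooled with the full background for ranking;
genes with all-zero profiles cannot have roots and score 0, placing them at
the bottom of the ranking (ties broken by gene identifier), so capture
always reaches 1 at the 100th percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gba import build_truth_table, gba_score, percentile_cut
from .profiles import BooleanProfile, TrainingSet

__all__ = ["ValidationReport", "fold_ratio", "cross_validate"]


@dataclass
class ValidationReport:
    """Cross-validation calibration of the candidate percentile cut-off."""

    percentiles: np.ndarray  # 1..100
    capture: np.ndarray  # mean fraction of held-out disease genes captured
    enrichment: np.ndarray  # capture / (percentile/100)
    chosen_percentile: int | None
    target_ratio: float
    n_iterations: int
    split_fraction: float
    seed: int
    fold_ratio: float = float("nan")
    mean_score_disease: float = float("nan")
    mean_score_other: float = float("nan")


def fold_ratio(scores_disease, scores_other) -> float:
    """Ratio of mean disease-gene score to mean background-gene score."""
    d = np.asarray(scores_disease, dtype=float)
    o = np.asarray(scores_other, dtype=float)
    if d.size == 0 or o.size == 0:
        raise ValueError("both score vectors must be non-empty")
    mo = o.mean()
    if mo <= 0:
        raise ValueError("mean background score is zero: fold ratio undefined")
    return float(d.mean() / mo)


def _ranked_pool(
    pool: list[str],
    profiles: dict[str, BooleanProfile],
    table,
) -> list[str]:
    scores = {g: gba_score(profiles[g], table) for g in pool}
    return sorted(pool, key=lambda g: (-scores[g], g))


def cross_validate(
    profiles: dict[str, BooleanProfile],
    training: TrainingSet,
    n_iter: int = 1000,
    split: float = 0.8,
    target_ratio: float = 2.71,
    seed: int = 0,
) -> ValidationReport:
    """Repeated random-split cross-validation of the GBA percentile cut.

    Each iteration draws ``split`` of the disease genes without replacement
    as the training fold (genes with all-zero profiles never contribute to
    the truth table), builds a truth table from it, and ranks the held-out
    disease genes pooled with the full background. Capture at percentile x
    is the fraction of held-out disease genes within the top x% of the
    pool. ``chosen_percentile`` is the smallest integer percentile whose
    mean enrichment reaches ``target_ratio`` (None, with a warning, when
    never reached). Fully reproducible for a given ``seed``.
    """
    disease = sorted(g for g in training.disease if g in profiles)
    background = sorted(g for g in training.background if g in profiles)
    n_test = len(disease) - int(round(split * len(disease)))
    if n_test < 1:
        raise ValueError(
            f"training set too small: {len(disease)} scoreable disease genes "
            f"leave an empty test fold at split {split}"
        )
    if not background:
        raise ValueError("no scoreable background genes to rank against")

    rng = np.random.default_rng(seed)
    grid = np.arange(1, 101)
    capture_sum = np.zeros(100)
    disease_arr = np.array(disease)
    for _ in range(n_iter):
        perm = rng.permutation(len(disease_arr))
        test = disease_arr[perm[:n_test]]
        train = set(disease_arr[perm[n_test:]])
        table = build_truth_table(profiles, TrainingSet(disease=train))
        pool = list(test) + background
        ranked = _ranked_pool(pool, profiles, table)
        pos = {g: i + 1 for i, g in enumerate(ranked)}  # rank 1 = best
        test_ranks = np.sort([pos[g] for g in test])
        n_pool = len(ranked)
        cuts = np.array([percentile_cut(n_pool, int(x)) for x in grid])
        capture_sum += np.searchsorted(test_ranks, cuts, side="right") / n_test

    capture = capture_sum / n_iter
    enrichment = capture / (grid / 100.0)
    reached = np.nonzero(enrichment >= target_ratio)[0]
    if reached.size:
        chosen: int | None = int(grid[reached[0]])
    else:
        chosen = None
        warnings.warn(
            f"mean enrichment never reaches the target ratio {target_ratio}; "
            "chosen percentile is undefined",
            stacklevel=2,
        )
    return ValidationReport(
        percentiles=grid,
        capture=capture,
        enrichment=enrichment,
        chosen_percentile=chosen,
        target_ratio=target_ratio,
        n_iterations=n_iter,
        split_fraction=split,
        seed=seed,
    )
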