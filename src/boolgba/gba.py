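"""Probabilistic Boolean truth table and guilt-by-association scoring.

The truth table maps each Boolean profile observed among training (disease)
genes to the proportion of those genes exhibiting it. A candidate gene's
profile is decomposed into its *roots* — the non-empty sub-profiles present
in the table — and the GBA score is the sum of the root probabilities.
Because table entries are mutually exclusive profiles whose probabilities
sum to 1, every score lies in [0, 1], and a profile that bitwise contains
another can only accumulate more roots, so scores are monotone under subset
containment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .profiles import BooleanProfile, TrainingSet

__all__ = [
    "TruthTable",
    "GbaRanking",
    "build_truth_table",
    "enumerate_roots",
    "gba_score",
    "rank_candidates",
    "percentile_cut",
]


@dataclass
class TruthTable:
    """Mapping from observed profile string to training-set probability.

    ``counts``/``n_training`` are present when the table was built from a
    training set (probabilities are then exactly counts / n_training); a
    table may also be constructed directly from published probabilities, in
    which case counts are absent.
    """

    entries: dict[str, float]
    counts: dict[str, int] | None = None
    n_training: int | None = None

    def __post_init__(self) -> None:
        for p, prob in self.entries.items():
            if set(p) - {"0", "1"}:
                raise ValueError(f"invalid profile key {p!r}")
            if "1" not in p:
                raise ValueError("all-zero profile cannot be a truth-table entry")
            if not 0.0 < prob <= 1.0:
                raise ValueError(f"probability of {p} out of (0,1]: {prob}")
        if self.counts is not None:
            if self.n_training is None:
                raise ValueError("counts given without n_training")
            for p, c in self.counts.items():
                if self.entries.get(p) != c / self.n_training:
                    raise ValueError(f"probability of {p} != count/n_training")

    @property
    def width(self) -> int:
        return len(next(iter(self.entries)))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GbaRanking:
    """Candidate genes ranked by GBA score (rank 1 = best)."""

    gene_ids: list[str]  # in rank order
    scores: dict[str, float]
    ranks: dict[str, int]
    percentiles: dict[str, float]
    unscorable: set[str] = field(default_factory=set)  # all-zero profiles

    @property
    def n_scored(self) -> int:
        return len(self.gene_ids)

    def top_candidates(self, percentile: float) -> list[str]:
        """Genes whose percentile is at or below ``percentile`` (rank order)."""
        return [g for g in self.gene_ids if self.percentiles[g] <= percentile + 1e-9]


def percentile_cut(n_scored: int, percentile: float) -> int:
    """Number of genes in the top ``percentile`` of ``n_scored`` ranked genes.

    A gene is in the cut iff rank / n * 100 <= percentile, i.e. the count is
    floor(n * percentile / 100) up to a small guard against binary float
    round-off (so a 13.2% cut of 1017 genes is exactly 134, and of 1000
    genes exactly 132).
    """
    if not 0 < percentile <= 100:
        raise ValueError(f"percentile out of (0, 100]: {percentile}")
    return int(n_scored * percentile / 100.0 + 1e-9)


def build_truth_table(
    profiles: dict[str, BooleanProfile], training: TrainingSet
) -> TruthTable:
    """Count the profiles of training disease genes into a truth table.

    Only training genes with at least one set bit contribute; genes missing
    from ``profiles`` raise. Probabilities are exact proportions of the
    contributing genes.
    """
    missing = sorted(g for g in training.disease if g not in profiles)
    if missing:
        raise KeyError(f"training genes without profiles: {missing[:5]}")
    counts: dict[str, int] = {}
    n = 0
    for g in sorted(training.disease):
        p = profiles[g]
        if p.popcount == 0:
            continue
        counts[p.string] = counts.get(p.string, 0) + 1
        n += 1
    if n == 0:
        raise ValueError("every training gene has an all-zero profile")
    entries = {p: c / n for p, c in counts.items()}
    return TruthTable(entries=entries, counts=counts, n_training=n)


def enumerate_roots(profile: BooleanProfile, table: TruthTable) -> list[str]:
    """All non-empty sub-profiles of ``profile`` present in the table.

    A root q satisfies q AND profile == q; the full profile itself is a root
    when the table contains it. Returned in ascending integer order of the
    profile string, deterministically. Runs in O(table size) by filtering
    the table's keys rather than enumerating the 2^popcount subsets.
    """
    if table.width != len(profile):
        raise ValueError(
            f"profile length {len(profile)} != table width {table.width}"
        )
    p = profile.as_int()
    roots = [q for q in table.entries if int(q, 2) & p == int(q, 2)]
    roots.sort(key=lambda q: int(q, 2))
    return roots


def gba_score(profile: BooleanProfile, table: TruthTable) -> float:
    """Sum of the truth-table probabilities of the profile's roots.

    Uses exact (correctly rounded) float summation so the score does not
    depend on summation order and matches the decimal sum of published
    probability tables to full precision.
    """
    if not table.entries:
        raise ValueError("empty truth table")
    return math.fsum(table.entries[q] for q in enumerate_roots(profile, table))


def rank_candidates(
    profiles: dict[str, BooleanProfile],
    table: TruthTable,
    exclude: TrainingSet,
) -> GbaRanking:
    """Score and rank all non-training genes with a non-zero profile.

    Ties are broken by ascending gene identifier; percentile is
    rank / n_scored * 100. Genes with all-zero profiles are reported as
    unscorable rather than ranked.
    """
    candidates = {
        g: p for g, p in profiles.items() if g not in exclude.disease
    }
    if not candidates:
        raise ValueError("no candidate genes outside the training set")
    unscorable = {g for g, p in candidates.items() if p.popcount == 0}
    scored = {
        g: gba_score(p, table) for g, p in candidates.items() if g not in unscorable
    }
    if not scored:
        raise ValueError("all candidate genes have all-zero profiles")
    order = sorted(scored, key=lambda g: (-scored[g], g))
    n = len(order)
    ranks = {g: i + 1 for i, g in enumerate(order)}
    percentiles = {g: ranks[g] / n * 100.0 for g in order}
    return GbaRanking(
        gene_ids=order,
        scores=scored,
        ranks=ranks,
        percentiles=percentiles,
        unscorable=unscorable,
    )
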