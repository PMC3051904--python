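"""Boolean gene profiles: the 13-variable binarization and attribute handling.

Every gene is summarized by an ordered 13-bit Boolean profile:

====  =========================================================
bit   variable
====  =========================================================
1-3   differentially expressed in contrast 1 / 2 / 3
4-7   condition specific in condition 1 / 2 / 3 / 4
8-13  functional attributes TS, TF, PTM, KIN, SEC, MET
====  =========================================================

where TS = tissue specificity, TF = transcription factor, PTM =
post-translational modification, KIN = kinase, SEC = secreted protein and
MET = CpG island methylation. The canonical string form writes bit 1 first,
e.g. a gene differentially expressed in the second contrast only and
carrying TF, PTM and MET is ``"0100000011001"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .expression import CsResult, DeResult

__all__ = [
    "ATTRIBUTES",
    "N_BITS",
    "BooleanProfile",
    "AttributeTable",
    "TrainingSet",
    "binarize_genes",
    "chi_square_independence",
]

ATTRIBUTES: tuple[str, ...] = ("TS", "TF", "PTM", "KIN", "SEC", "MET")
N_BITS = 13


@dataclass(frozen=True)
class BooleanProfile:
    """An ordered fixed-length Boolean profile (13 bits by default).

    Profiles compare, hash and round-trip through their canonical '0'/'1'
    string form losslessly.
    """

    bits: tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", tuple(bool(b) for b in self.bits))

    @classmethod
    def from_string(cls, s: str) -> "BooleanProfile":
        if set(s) - {"0", "1"}:
            raise ValueError(f"profile string may contain only 0/1: {s!r}")
        return cls(tuple(c == "1" for c in s))

    @property
    def string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.string

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def popcount(self) -> int:
        return sum(self.bits)

    def as_int(self) -> int:
        """Integer value of the profile, bit 1 most significant."""
        return int(self.string, 2) if self.bits else 0

    def is_subset_of(self, other: "BooleanProfile") -> bool:
        """True iff every set bit of self is also set in ``other``."""
        if len(self) != len(other):
            raise ValueError("profiles of different length")
        return all((not a) or b for a, b in zip(self.bits, other.bits))


@dataclass
class AttributeTable:
    """Per-gene boolean flags for the six functional attributes.

    ``flags[gene]`` is a dict over :data:`ATTRIBUTES`.
    """

    flags: dict[str, dict[str, bool]]

    def __post_init__(self) -> None:
        for g, row in self.flags.items():
            missing = [a for a in ATTRIBUTES if a not in row]
            if missing:
                raise ValueError(f"gene {g!r} missing attributes {missing}")
            for a in ATTRIBUTES:
                v = row[a]
                if not isinstance(v, (bool, np.bool_)):
                    raise ValueError(
                        f"attribute {a} of gene {g!r} is not boolean: {v!r}"
                    )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.flags)

    def genes_with(self, attribute: str) -> set[str]:
        if attribute not in ATTRIBUTES:
            raise KeyError(f"unknown attribute {attribute!r}")
        return {g for g, row in self.flags.items() if row[attribute]}


@dataclass
class TrainingSet:
    """Disjoint sets of known disease genes and background genes."""

    disease: set[str]
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.disease = set(self.disease)
        self.background = set(self.background)
        if not self.disease:
            raise ValueError("disease gene set is empty")
        overlap = self.disease & self.background
        if overlap:
            raise ValueError(
                f"disease and background sets overlap: {sorted(overlap)[:5]}"
            )


def binarize_genes(
    de: list[DeResult],
    cs: CsResult,
    attrs: AttributeTable,
) -> dict[str, BooleanProfile]:
    """Assemble the 13-bit profile for every gene in the union of inputs.

    Expects exactly three DE results (one per contrast) and four conditions
    in the CS result; genes absent from any one input get false bits there
    (absent from the attribute table triggers a warning).
    """
    if len(de) != 3:
        raise ValueError(f"expected 3 DE results, got {len(de)}")
    if len(cs.conditions) != 4:
        raise ValueError(
            f"expected 4 conditions in the CS result, got {len(cs.conditions)}"
        )
    de_sets = [d.de_genes() for d in de]
    cs_sets = [cs.specific_genes(c) for c in cs.conditions]

    universe: list[str] = []
    seen: set[str] = set()
    for source in ([*de[0].gene_ids], cs.gene_ids, attrs.gene_ids):
        for g in source:
            if g not in seen:
                seen.add(g)
                universe.append(g)
    for d in de[1:]:
        for g in d.gene_ids:
            if g not in seen:
                seen.add(g)
                universe.append(g)

    no_attrs = [g for g in universe if g not in attrs.flags]
    if no_attrs:
        warnings.warn(
            f"{len(no_attrs)} genes absent from the attribute table; "
            "their attribute bits are set to false",
            stacklevel=2,
        )

    profiles: dict[str, BooleanProfile] = {}
    for g in universe:
        bits = [g in s for s in de_sets]
        bits += [g in s for s in cs_sets]
        row = attrs.flags.get(g)
        bits += [bool(row[a]) for a in ATTRIBUTES] if row else [False] * 6
        profiles[g] = BooleanProfile(tuple(bits))
    return profiles


def chi_square_independence(table) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 count table.

    No continuity correction is applied. Raises if a marginal total is zero
    (expected counts undefined).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() <= 0:
        raise ValueError("empty table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: expected counts are undefined")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)
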