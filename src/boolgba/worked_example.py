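"""Reference truth-table excerpt for the MEF2C worked example.

MEF2C — differentially expressed in the second contrast and carrying the
TF, PTM and MET attributes — has the Boolean profile ``"0100000011001"``.
Against the published truth-table excerpt below, that profile decomposes
into 14 roots whose probabilities sum to 0.58868, the gene's GBA score.
These rows are the canonical regression anchor for the root decomposition
and scoring machinery.
"""

from __future__ import annotations

from .gba import TruthTable

__all__ = ["MEF2C_PROFILE", "MEF2C_TABLE_ROWS", "mef2c_truth_table"]

MEF2C_PROFILE = "0100000011001"

#: (profile, probability) rows of the published excerpt, in printed order.
MEF2C_TABLE_ROWS: tuple[tuple[str, float], ...] = (
    ("0000000000001", 0.05094),
    ("0000000001000", 0.23019),
    ("0000000001001", 0.02453),
    ("0000000010000", 0.10755),
    ("0000000010001", 0.03396),
    ("0000000011000", 0.07925),
    ("0000000011001", 0.03019),
    ("0100000000000", 0.01509),
    ("0100000000001", 0.00377),
    ("0100000001000", 0.00377),
    ("0100000001001", 0.00189),
    ("0100000010000", 0.00377),
    ("0100000010001", 0.00189),
    ("0100000011000", 0.00189),
)


def mef2c_truth_table() -> TruthTable:
    """The worked-example excerpt as a :class:`TruthTable` (no counts)."""
    return TruthTable(entries=dict(MEF2C_TABLE_ROWS))
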