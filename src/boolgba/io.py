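"""Tab-separated readers and writers for every pipeline artifact.

All tabular inputs and outputs are TSV with a header row; networks are
additionally exported as Cytoscape SIF. pandas does the parsing; these
helpers add the validation the typed containers require (unique ids,
complete condition maps, boolean attribute columns) and report offending
rows by name.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CsResult, DeResult, ExpressionMatrix, NormalizationResult
from .gba import GbaRanking, TruthTable
from .network import ConservedNetwork
from .profiles import ATTRIBUTES, AttributeTable, BooleanProfile, TrainingSet
from .rif import RifScores
from .validation import ValidationReport

__all__ = [
    "read_expression_matrix",
    "read_attribute_table",
    "read_training_list",
    "read_profiles",
    "read_truth_table",
    "write_expression_matrix",
    "write_attribute_table",
    "write_training_list",
    "write_normalized_means",
    "write_de_result",
    "write_cs_result",
    "write_profiles",
    "write_truth_table",
    "write_ranking",
    "write_validation_report",
    "write_conserved_network",
    "write_sif",
    "write_node_attributes",
    "write_rif_scores",
]


def read_expression_matrix(matrix_path, samples_path) -> ExpressionMatrix:
    """Read the expression TSV (gene rows, sample columns) and sample map."""
    m = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if m.index.has_duplicates:
        dup = m.index[m.index.duplicated()][0]
        raise ValueError(f"duplicated gene id in {matrix_path}: {dup!r}")
    meta = pd.read_csv(samples_path, sep="\t")
    if meta.shape[1] < 2:
        raise ValueError(f"{samples_path} needs sample and condition columns")
    sample_col, cond_col = meta.columns[:2]
    if meta[sample_col].duplicated().any():
        dup = meta.loc[meta[sample_col].duplicated(), sample_col].iloc[0]
        raise ValueError(f"duplicated sample id in {samples_path}: {dup!r}")
    condition_of = dict(zip(meta[sample_col].astype(str), meta[cond_col].astype(str)))
    return ExpressionMatrix(
        gene_ids=[str(g) for g in m.index],
        sample_ids=[str(s) for s in m.columns],
        values=m.to_numpy(dtype=float),
        condition_of=condition_of,
    )


def read_attribute_table(path) -> AttributeTable:
    """Read the attribute TSV: gene column plus 0/1 columns TS..MET."""
    t = pd.read_csv(path, sep="\t")
    gene_col = t.columns[0]
    missing = [a for a in ATTRIBUTES if a not in t.columns]
    if missing:
        raise ValueError(f"{path} missing attribute columns {missing}")
    if t[gene_col].duplicated().any():
        dup = t.loc[t[gene_col].duplicated(), gene_col].iloc[0]
        raise ValueError(f"duplicated gene id in {path}: {dup!r}")
    flags: dict[str, dict[str, bool]] = {}
    for _, row in t.iterrows():
        vals = {}
        for a in ATTRIBUTES:
            v = row[a]
            if v not in (0, 1):
                raise ValueError(
                    f"non-binary attribute value for gene {row[gene_col]!r}, "
                    f"column {a}: {v!r}"
                )
            vals[a] = bool(v)
        flags[str(row[gene_col])] = vals
    return AttributeTable(flags=flags)


def read_training_list(path) -> set[str]:
    """Read a plain-text gene list, one identifier per line."""
    genes: set[str] = set()
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        g = line.strip()
        if not g or g.startswith("#"):
            continue
        if g in genes:
            raise ValueError(f"{path}:{i}: duplicated gene id {g!r}")
        genes.add(g)
    if not genes:
        raise ValueError(f"{path}: empty training list")
    return genes


def read_profiles(path) -> dict[str, BooleanProfile]:
    t = pd.read_csv(path, sep="\t", dtype={"profile": str})
    return {
        str(row.gene): BooleanProfile.from_string(row.profile)
        for row in t.itertuples()
    }


def read_truth_table(path) -> TruthTable:
    t = pd.read_csv(path, sep="\t", dtype={"profile": str})
    if "count" in t.columns and t["count"].notna().all():
        counts = dict(zip(t["profile"], t["count"].astype(int)))
        n = int(counts_total := sum(counts.values()))
        entries = {p: c / n for p, c in counts.items()}
        return TruthTable(entries=entries, counts=counts, n_training=counts_total)
    return TruthTable(entries=dict(zip(t["profile"], t["probability"].astype(float))))


# ---------------------------------------------------------------- writers


def write_expression_matrix(expr: ExpressionMatrix, matrix_path, samples_path) -> None:
    pd.DataFrame(
        expr.values, index=pd.Index(expr.gene_ids, name="gene"), columns=expr.sample_ids
    ).to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {
            "sample": expr.sample_ids,
            "condition": [expr.condition_of[s] for s in expr.sample_ids],
        }
    ).to_csv(samples_path, sep="\t", index=False)


def write_attribute_table(attrs: AttributeTable, path) -> None:
    rows = [
        {"gene": g, **{a: int(v[a]) for a in ATTRIBUTES}} for g, v in attrs.flags.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_training_list(training: TrainingSet, path) -> None:
    Path(path).write_text("\n".join(sorted(training.disease)) + "\n")


def write_normalized_means(norm: NormalizationResult, path) -> None:
    pd.DataFrame(
        norm.gene_condition_means,
        index=pd.Index(norm.gene_ids, name="gene"),
        columns=norm.conditions,
    ).to_csv(path, sep="\t")


def write_de_result(de: DeResult, path) -> None:
    pd.DataFrame(
        {
            "gene": de.gene_ids,
            "contrast": f"{de.contrast[0]}-{de.contrast[1]}",
            "difference": de.difference,
            "posterior": de.posterior,
            "de_flag": de.de_flag.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def write_cs_result(cs: CsResult, path) -> None:
    rows = []
    for i, g in enumerate(cs.gene_ids):
        for j, c in enumerate(cs.conditions):
            rows.append(
                {
                    "gene": g,
                    "condition": c,
                    "cs": cs.cs[i, j],
                    "cs_flag": int(cs.cs_flag[i, j]),
                    "excluded": int(cs.excluded[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_profiles(profiles: dict[str, BooleanProfile], path) -> None:
    pd.DataFrame(
        {
            "gene": list(profiles),
            "profile": [p.string for p in profiles.values()],
            "popcount": [p.popcount for p in profiles.values()],
        }
    ).to_csv(path, sep="\t", index=False)


def write_truth_table(table: TruthTable, path) -> None:
    profiles = sorted(table.entries, key=lambda p: int(p, 2))
    pd.DataFrame(
        {
            "profile": profiles,
            "count": [
                table.counts.get(p, np.nan) if table.counts else np.nan
                for p in profiles
            ],
            "probability": [table.entries[p] for p in profiles],
        }
    ).to_csv(path, sep="\t", index=False)


def write_ranking(
    ranking: GbaRanking, profiles: dict[str, BooleanProfile], path
) -> None:
    pd.DataFrame(
        {
            "gene": ranking.gene_ids,
            "profile": [profiles[g].string for g in ranking.gene_ids],
            "score": [ranking.scores[g] for g in ranking.gene_ids],
            "rank": [ranking.ranks[g] for g in ranking.gene_ids],
            "percentile": [ranking.percentiles[g] for g in ranking.gene_ids],
        }
    ).to_csv(path, sep="\t", index=False)


def write_validation_report(report: ValidationReport, path) -> None:
    pd.DataFrame(
        {
            "percentile": report.percentiles,
            "mean_capture": report.capture,
            "mean_enrichment": report.enrichment,
        }
    ).to_csv(path, sep="\t", index=False)


def write_conserved_network(net: ConservedNetwork, path) -> None:
    rows = []
    for (a, b), flags in sorted(net.edges.items()):
        row = {"geneA": a, "geneB": b}
        for c in net.conditions:
            row[f"r_{c}"] = net.weights.get((a, b), {}).get(c, np.nan)
            row[f"sig_{c}"] = int(flags[c])
        row["conservation_count"] = sum(flags.values())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sif(edges, path, interaction: str = "co") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{interaction}\t{b}\n")


def write_node_attributes(node_attrs: dict[str, dict[str, bool]], path) -> None:
    rows = []
    for g, flags in sorted(node_attrs.items()):
        rows.append({"gene": g, **{k: int(v) for k, v in flags.items()}})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_rif_scores(rif: RifScores, path) -> None:
    pd.DataFrame(
        {
            "tf": rif.tf_ids,
            "rif1_raw": rif.rif1_raw,
            "rif2_raw": rif.rif2_raw,
            "rif1_z": rif.rif1_z,
            "rif2_z": rif.rif2_z,
            "extreme": rif.extreme.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)
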