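"""End-to-end orchestration: expression -> profiles -> GBA -> validation ->
networks -> RIF.

:func:`run_pipeline` executes the stages in order on the three inputs
(expression matrix + sample map, attribute table, training gene list),
writes every stage artifact into a run directory, and returns a
machine-readable summary. The pipeline is a pure function of
(inputs, config, seed): two runs with the same arguments produce
byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .expression import (
    ExpressionMatrix,
    call_differential_expression,
    condition_specificity,
    drop_constant_genes,
    normalize_expression,
)
from .gba import build_truth_table, rank_candidates
from .network import build_condition_network, conserved_network, resolution_views
from .profiles import ATTRIBUTES, AttributeTable, TrainingSet, binarize_genes
from .rif import rif_scores
from .validation import cross_validate, fold_ratio

__all__ = ["RunConfig", "run_pipeline", "read_inputs"]

log = logging.getLogger("boolgba")

DEFAULT_CONTRASTS = (
    ("Carcinoma", "Normal"),
    ("Carcinoma", "Adenoma"),
    ("Carcinoma", "Inflammation"),
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    matrix_path: str = ""
    samples_path: str = ""
    attributes_path: str = ""
    training_path: str = ""
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    fdr_target: float = 0.01
    cv_iterations: int = 1000
    min_conserved: int = 3
    top_percentile: float = 13.2
    rif_conditions: tuple[str, str] = ("Carcinoma", "Normal")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_percentile <= 100:
            raise ValueError(f"top_percentile out of (0,100]: {self.top_percentile}")
        self.contrasts = tuple(tuple(c) for c in self.contrasts)
        self.rif_conditions = tuple(self.rif_conditions)

    def to_file(self, path) -> None:
        lines = []
        for k, v in asdict(self).items():
            if k == "contrasts":
                v = ";".join(f"{a},{b}" for a, b in v)
            elif k == "rif_conditions":
                v = ",".join(v)
            lines.append(f"{k}={v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs: dict = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{i}: expected key=value, got {line!r}")
            k, v = line.split("=", 1)
            k, v = k.strip(), v.strip()
            if k == "contrasts":
                kwargs[k] = tuple(tuple(p.split(",")) for p in v.split(";") if p)
            elif k == "rif_conditions":
                kwargs[k] = tuple(v.split(","))
            elif k in ("fdr_target", "top_percentile"):
                kwargs[k] = float(v)
            elif k in ("cv_iterations", "min_conserved", "seed"):
                kwargs[k] = int(v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


def read_inputs(
    matrix_path, samples_path, attributes_path, training_path
) -> tuple[ExpressionMatrix, AttributeTable, set[str]]:
    """Load and validate the three pipeline inputs."""
    expr = io.read_expression_matrix(matrix_path, samples_path)
    attrs = io.read_attribute_table(attributes_path)
    training = io.read_training_list(training_path)
    return expr, attrs, training


def _subset_expression(expr: ExpressionMatrix, genes: list[str]) -> ExpressionMatrix:
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = [index[g] for g in genes]
    return ExpressionMatrix(
        gene_ids=list(genes),
        sample_ids=list(expr.sample_ids),
        values=expr.values[rows],
        condition_of=dict(expr.condition_of),
    )


def run_pipeline(
    config: RunConfig,
    out_dir,
    expr: ExpressionMatrix | None = None,
    attrs: AttributeTable | None = None,
    training_genes: set[str] | None = None,
) -> dict:
    """Run every stage, write artifacts under ``out_dir``, return the summary.

    Inputs may be passed as objects (overriding the config paths). Any stage
    failure propagates with the stage named in the exception chain.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if expr is None or attrs is None or training_genes is None:
        expr, attrs, training_genes = read_inputs(
            config.matrix_path,
            config.samples_path,
            config.attributes_path,
            config.training_path,
        )
    config.to_file(out / "config.txt")
    summary: dict = {"seed": config.seed, "stages": {}}

    def stage(name):
        log.info("stage %s", name)
        return _StageTimer(name)

    with stage("normalize"):
        expr = drop_constant_genes(expr)
        norm = normalize_expression(expr)
        io.write_normalized_means(norm, out / "normalized_means.tsv")

    de_results = []
    with stage("differential_expression"):
        for k, contrast in enumerate(config.contrasts, start=1):
            de = call_differential_expression(
                norm, tuple(contrast), fdr_target=config.fdr_target, seed=config.seed
            )
            io.write_de_result(de, out / f"de_{k}.tsv")
            de_results.append(de)
    summary["stages"]["n_de_per_contrast"] = {
        f"{a}-{b}": int(d.de_flag.sum())
        for (a, b), d in zip(config.contrasts, de_results)
    }

    with stage("condition_specificity"):
        cs = condition_specificity(norm)
        io.write_cs_result(cs, out / "cs.tsv")
    summary["stages"]["n_cs_per_condition"] = {
        c: len(cs.specific_genes(c)) for c in cs.conditions
    }

    with stage("binarize"):
        profiles = binarize_genes(de_results, cs, attrs)
        io.write_profiles(profiles, out / "profiles.tsv")

    train_in_universe = {g for g in training_genes if g in profiles}
    if not train_in_universe:
        raise ValueError("stage truth_table: no training gene found in the inputs")
    background = set(profiles) - train_in_universe
    training = TrainingSet(disease=train_in_universe, background=background)

    with stage("truth_table"):
        table = build_truth_table(profiles, training)
        io.write_truth_table(table, out / "truth_table.tsv")
    summary["stages"]["n_training_used"] = table.n_training
    summary["stages"]["n_training_listed"] = len(train_in_universe)
    summary["stages"]["n_truth_table_combinations"] = len(table)

    with stage("score"):
        ranking = rank_candidates(profiles, table, training)
        io.write_ranking(ranking, profiles, out / "ranking.tsv")
        top = ranking.top_candidates(config.top_percentile)
        Path(out / "top_candidates.txt").write_text("\n".join(top) + "\n")
    summary["stages"]["n_scored"] = ranking.n_scored
    summary["stages"]["n_unscorable"] = len(ranking.unscorable)
    summary["stages"]["n_top_candidates"] = len(top)

    with stage("validate"):
        from .gba import gba_score

        disease_scores = [
            gba_score(profiles[g], table)
            for g in sorted(train_in_universe)
            if profiles[g].popcount > 0
        ]
        other_scores = [ranking.scores[g] for g in ranking.gene_ids]
        ratio = fold_ratio(disease_scores, other_scores)
        report = cross_validate(
            profiles,
            training,
            n_iter=config.cv_iterations,
            target_ratio=ratio,
            seed=config.seed,
        )
        report.fold_ratio = ratio
        report.mean_score_disease = float(np.mean(disease_scores))
        report.mean_score_other = float(np.mean(other_scores))
        io.write_validation_report(report, out / "validation.tsv")
    summary["stages"]["fold_ratio"] = round(ratio, 6)
    summary["stages"]["chosen_percentile"] = report.chosen_percentile

    with stage("network"):
        # node universe: truth-table genes plus candidates captured by at
        # least one of the seven expression-based variables
        expr_captured = {
            g
            for g in ranking.gene_ids
            if any(profiles[g].bits[:7])
        }
        nodes = sorted(
            {g for g in train_in_universe if profiles[g].popcount > 0} | expr_captured
        )
        net_summary: dict = {"n_nodes_universe": len(nodes)}
        if len(nodes) >= 3:
            sub = _subset_expression(expr, nodes)
            nets = [
                build_condition_network(sub, c) for c in sub.conditions
            ]
            net = conserved_network(nets, min_conditions=config.min_conserved)
            net.node_attrs = {
                g: {
                    **{a: attrs.flags.get(g, {}).get(a, False) for a in ATTRIBUTES},
                    "training": g in train_in_universe,
                    "top_candidate": g in set(top),
                }
                for g in nodes
            }
            io.write_conserved_network(net, out / "conserved_network.tsv")
            io.write_sif(set(net.edges), out / "conserved_network.sif")
            io.write_node_attributes(net.node_attrs, out / "node_attributes.tsv")
            views = resolution_views(net, set(top)) if top else (set(),) * 4
            for i, v in enumerate(views, start=1):
                io.write_sif(v, out / f"view{i}.sif")
            net_summary.update(
                {
                    "n_edges_per_condition": {
                        n.condition: len(n.edges) for n in nets
                    },
                    "n_conserved_edges": len(net.edges),
                    "n_conserved_nodes": len(net.nodes),
                    "view_edges": [len(v) for v in views],
                }
            )
        else:
            net_summary["skipped"] = "fewer than 3 network nodes"
    summary["stages"]["network"] = net_summary

    with stage("rif"):
        tf_genes = attrs.genes_with("TF") & set(expr.gene_ids)
        de_union = set().union(*(d.de_genes() for d in de_results))
        rif_summary: dict = {}
        if tf_genes and de_union & set(expr.gene_ids):
            rif = rif_scores(
                expr,
                tf_genes,
                de_union,
                config.rif_conditions[0],
                config.rif_conditions[1],
            )
            io.write_rif_scores(rif, out / "rif.tsv")
            rif_summary = {
                "n_tfs_scored": len(rif.tf_ids),
                "n_extreme": int(rif.extreme.sum()),
                "extreme_tfs": rif.extreme_tfs(),
            }
        else:
            rif_summary["skipped"] = "no TF or no DE gene in the matrix"
    summary["stages"]["rif"] = rif_summary

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


class _StageTimer:
    """Context manager logging per-stage wall time and naming failures."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            log.error("stage %s failed after %.2fs: %s", self.name, dt, exc)
            raise RuntimeError(f"stage {self.name} failed: {exc}") from exc
        log.info("stage %s done in %.2fs", self.name, dt)
        return False
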