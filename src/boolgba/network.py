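"""Co-expression network reconstruction with PCIT and network post-processing.

One Pearson correlation network is built per experimental condition from
that condition's samples; PCIT (partial correlation with information
theory) keeps a correlation edge only if no gene trio dominates it under a
locally computed tolerance. The per-condition significant-edge sets are
intersected into the *always-conserved network* (edges significant in at
least 3 of 4 conditions), which is then dissected into resolution views,
attribute-restricted subnetworks and connectivity diagnostics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .expression import ExpressionMatrix
from .profiles import ATTRIBUTES

__all__ = [
    "ConditionNetwork",
    "ConservedNetwork",
    "condition_correlations",
    "pcit_significant_edges",
    "conserved_network",
    "resolution_views",
    "attribute_subnetwork",
    "connectivity_stats",
    "build_condition_network",
]

Edge = tuple[str, str]


def _edge(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class ConditionNetwork:
    """PCIT-significant co-expression network for one condition."""

    condition: str
    node_ids: list[str]
    correlations: np.ndarray  # nodes x nodes Pearson r
    edges: dict[Edge, float]  # significant edges -> correlation weight


@dataclass
class ConservedNetwork:
    """Edges conserved across condition networks.

    ``edges`` maps a (sorted) gene pair to per-condition significance flags;
    ``conservation`` is the number of conditions in which the pair was
    significant. ``node_attrs`` may carry per-node booleans (the six
    functional attributes, training flag, top-candidate flag).
    """

    conditions: list[str]
    edges: dict[Edge, dict[str, bool]]
    weights: dict[Edge, dict[str, float]] = field(default_factory=dict)
    node_attrs: dict[str, dict[str, bool]] = field(default_factory=dict)
    min_conditions: int = 3

    def conservation(self, edge: Edge) -> int:
        return sum(self.edges[edge].values())

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), flags in self.edges.items():
            g.add_edge(a, b, conservation=sum(flags.values()))
        return g


def condition_correlations(
    expr: ExpressionMatrix, condition: str
) -> tuple[list[str], np.ndarray]:
    """Pearson correlations across the samples of one condition.

    Genes with zero variance within the condition are excluded with a
    warning (their correlation is undefined). Returns the retained gene ids
    and the symmetric, unit-diagonal correlation matrix.
    """
    cols = expr.samples_in(condition)
    if len(cols) < 3:
        raise ValueError(
            f"condition {condition!r} has {len(cols)} samples; need >= 3"
        )
    sub = expr.values[:, cols]
    keep = np.ptp(sub, axis=1) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance genes in "
            f"condition {condition!r}",
            stacklevel=2,
        )
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    r = np.corrcoef(sub[keep])
    np.fill_diagonal(r, 1.0)
    return genes, r


def pcit_significant_edges(corr: np.ndarray) -> set[tuple[int, int]]:
    """Significant edges of a correlation matrix under the PCIT trio rule.

    For every gene trio (x, y, z) the three first-order partial correlations
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)) (and cyclic
    variants) define a local tolerance eps = mean of the three
    partial-to-direct ratios; the edge (x, y) is eliminated if in some trio
    both |r_xy| <= |eps * r_xz| and |r_xy| <= |eps * r_yz|. Surviving pairs
    are returned as index tuples (i < j). A trio containing a zero direct
    correlation cannot eliminate an edge (its ratio is undefined); an
    off-diagonal correlation of magnitude 1 raises, naming the pair.
    """
    r = np.asarray(corr, dtype=float)
    n = r.shape[0]
    if r.shape != (n, n):
        raise ValueError("correlation matrix must be square")
    if n < 3:
        raise ValueError("PCIT needs at least 3 nodes (no trios otherwise)")
    off = np.abs(r - np.diag(np.diag(r)))
    if (off >= 1.0 - 1e-12).any():
        i, j = np.argwhere(off >= 1.0 - 1e-12)[0]
        raise ValueError(
            f"unit correlation between nodes {i} and {j}: partial "
            "correlations are undefined (duplicate rows?)"
        )

    eliminated = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        for z in range(n):
            cz = r[:, z]
            denom_z = np.sqrt(np.outer(1.0 - cz**2, 1.0 - cz**2))
            a = (r - np.outer(cz, cz)) / denom_z  # r_xy.z
            # r_xz.y over pairs (x, y): (r_xz - r_xy r_yz)/sqrt((1-r_xy^2)(1-r_yz^2))
            b = (cz[:, None] - r * cz[None, :]) / np.sqrt(
                (1.0 - r**2) * (1.0 - cz[None, :] ** 2)
            )
            ratios = np.stack((a / r, b / cz[:, None], b.T / cz[None, :]))
            valid = np.isfinite(ratios).all(axis=0)
            eps = ratios.sum(axis=0) / 3.0
            dominated = (
                valid
                & (np.abs(r) <= np.abs(eps * cz[:, None]))
                & (np.abs(r) <= np.abs(eps * cz[None, :]))
            )
            dominated[z, :] = False
            dominated[:, z] = False
            dominated[idx, idx] = False
            eliminated |= dominated

    sig: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if not eliminated[i, j]:
                sig.add((i, j))
    return sig


def build_condition_network(
    expr: ExpressionMatrix,
    condition: str,
    min_abs_r_small: float = 0.95,
) -> ConditionNetwork:
    """Correlate within one condition and keep the PCIT-significant edges.

    With fewer than 3 retained genes the trio rule is undefined; edges with
    |r| above ``min_abs_r_small`` are kept instead, with a warning.
    """
    genes, r = condition_correlations(expr, condition)
    edges: dict[Edge, float] = {}
    if len(genes) < 3:
        warnings.warn(
            f"condition {condition!r} has <3 usable genes; keeping edges "
            f"with |r| > {min_abs_r_small}",
            stacklevel=2,
        )
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if abs(r[i, j]) > min_abs_r_small:
                    edges[_edge(genes[i], genes[j])] = float(r[i, j])
    else:
        for i, j in pcit_significant_edges(r):
            edges[_edge(genes[i], genes[j])] = float(r[i, j])
    return ConditionNetwork(
        condition=condition, node_ids=genes, correlations=r, edges=edges
    )


def conserved_network(
    nets: list[ConditionNetwork], min_conditions: int = 3
) -> ConservedNetwork:
    """Intersect condition networks into the always-conserved network.

    Retains edges significant in at least ``min_conditions`` of the input
    networks and records per-condition significance flags and correlation
    weights. Node universes are intersected when they differ (logged).
    """
    if not 1 <= min_conditions <= len(nets):
        raise ValueError(
            f"min_conditions must be in 1..{len(nets)}, got {min_conditions}"
        )
    universes = [set(n.node_ids) for n in nets]
    common = set.intersection(*universes)
    if any(u != common for u in universes):
        warnings.warn(
            "condition networks have differing node universes; "
            f"intersecting to {len(common)} shared nodes",
            stacklevel=2,
        )
    conditions = [n.condition for n in nets]
    all_edges: set[Edge] = set()
    for n in nets:
        all_edges |= {e for e in n.edges if e[0] in common and e[1] in common}
    edges: dict[Edge, dict[str, bool]] = {}
    weights: dict[Edge, dict[str, float]] = {}
    for e in sorted(all_edges):
        flags = {n.condition: e in n.edges for n in nets}
        if sum(flags.values()) >= min_conditions:
            edges[e] = flags
            weights[e] = {
                n.condition: n.edges[e] for n in nets if e in n.edges
            }
    return ConservedNetwork(
        conditions=conditions,
        edges=edges,
        weights=weights,
        min_conditions=min_conditions,
    )


def resolution_views(
    net: ConservedNetwork,
    top_candidates: set[str],
    optional_conditions: tuple[str, str] = ("Normal", "Carcinoma"),
) -> tuple[set[Edge], set[Edge], set[Edge], set[Edge]]:
    """The four resolution views of the conserved network.

    view1: edges significant in all conditions, or in all but the first or
    all but the second of ``optional_conditions``; view2: view1 edges
    touching at least one top candidate; view3: view2 edges whose both
    endpoints have degree > 2 within view2; view4: view2 edges significant
    in all conditions.
    """
    if not top_candidates:
        raise ValueError("top candidate set is empty")
    n_cond = len(net.conditions)
    view1: set[Edge] = set()
    for e, flags in net.edges.items():
        cnt = sum(flags.values())
        if cnt == n_cond:
            view1.add(e)
        elif cnt == n_cond - 1:
            missing = next(c for c, f in flags.items() if not f)
            if missing in optional_conditions:
                view1.add(e)
    view2 = {e for e in view1 if e[0] in top_candidates or e[1] in top_candidates}
    deg: dict[str, int] = {}
    for a, b in view2:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    view3 = {e for e in view2 if deg[e[0]] > 2 and deg[e[1]] > 2}
    view4 = {e for e in view2 if sum(net.edges[e].values()) == n_cond}
    return view1, view2, view3, view4


def attribute_subnetwork(net: ConservedNetwork, attribute: str) -> set[Edge]:
    """Edges of the conserved network whose both endpoints carry ``attribute``."""
    if attribute not in ATTRIBUTES:
        raise KeyError(f"unknown attribute {attribute!r}; expected one of {ATTRIBUTES}")
    carriers = {
        g for g, flags in net.node_attrs.items() if flags.get(attribute, False)
    }
    return {e for e in net.edges if e[0] in carriers and e[1] in carriers}


def _log_binned_fit(degrees: np.ndarray) -> tuple[float, float]:
    """OLS power-law fit on logarithmically binned degree frequencies.

    Returns (exponent, r_squared) for frequency ~ degree^-exponent.
    """
    degrees = degrees[degrees >= 1]
    kmax = degrees.max()
    edges = [1.0]
    while edges[-1] <= kmax:
        edges.append(edges[-1] * 1.5)
    edges_arr = np.array(edges)
    counts, _ = np.histogram(degrees, bins=edges_arr)
    widths = np.diff(edges_arr)
    centers = np.sqrt(edges_arr[:-1] * edges_arr[1:])
    density = counts / widths
    keep = counts > 0
    if keep.sum() < 2:
        return float("nan"), float("nan")
    lx = np.log10(centers[keep])
    ly = np.log10(density[keep])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(-slope), r2


@dataclass
class ConnectivityStats:
    degrees: dict[str, int]
    hubs: list[str]
    power_law_exponent: float | None
    fit_r_squared: float | None


def connectivity_stats(
    net: ConservedNetwork, hub_quantile: float = 0.99
) -> ConnectivityStats:
    """Degree distribution diagnostics of a conserved network.

    Hubs are the nodes at or above the ``hub_quantile`` degree quantile
    (default: top 1%). The power-law exponent is fit by OLS on the
    log-binned degree frequencies; a network whose nodes all share one
    degree has no defined exponent (reported as None).
    """
    g = net.to_graph()
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges")
    degrees = dict(g.degree())
    vals = np.array(list(degrees.values()))
    cut = np.quantile(vals, hub_quantile)
    hubs = sorted(
        (n for n, d in degrees.items() if d >= cut),
        key=lambda n: (-degrees[n], n),
    )
    if np.ptp(vals) == 0:
        return ConnectivityStats(degrees, hubs, None, None)
    exponent, r2 = _log_binned_fit(vals)
    if math.isnan(exponent):
        return ConnectivityStats(degrees, hubs, None, None)
    return ConnectivityStats(degrees, hubs, exponent, r2)
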