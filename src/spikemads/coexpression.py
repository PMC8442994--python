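"""Correlation-set assignment over a developmental time course.

Genes are grouped by thresholding the Pearson correlation matrix of their
time-course profiles: a *correlation set* is a group in which every member
correlates above a primary threshold (default r > 0.9, strict) with at
least ``m`` (default 2) other members of the same group. That
membership-consistent reading is exactly the ``m``-core of the thresholded
correlation graph: iterated deletion of low-degree nodes converges to a
unique fixpoint regardless of deletion order. Connected components of the
core are the sets, numbered by the mean peak stage of their members
(earliest first).

Genes failing the strict rule may still form a looser *pseudoset*: the
largest connected component above a secondary threshold (default 0.75)
among the unassigned genes. Everything else is left ungrouped.

A hierarchical-clustering cross-check (z-scored profiles, Euclidean
distance, complete linkage) and the adjusted Rand index quantify how well
the threshold-graph grouping agrees with an unsupervised clustering of the
same profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from .qpcr import ExpressionMatrix
from .stages import StageGrid

logger = logging.getLogger(__name__)

UNGROUPED = "ungrouped"
PSEUDOSET = "pseudoset"


@dataclass(frozen=True)
class SetRuleParams:
    """Thresholds of the correlation-set rule.

    tau
        Primary threshold; an edge requires r strictly greater than tau.
    m
        Minimum number of qualifying partners each member must have
        within its own set.
    tau2
        Secondary (pseudoset) threshold.
    min_set_size
        Smallest group reported as a set or pseudoset.
    membership_consistent
        If True (default), partners must themselves be set members
        (m-core reading); if False, any gene above tau counts as a
        partner.
    """

    tau: float = 0.9
    m: int = 2
    tau2: float = 0.75
    min_set_size: int = 3
    membership_consistent: bool = True

    def __post_init__(self) -> None:
        if not (-1.0 < self.tau2 <= self.tau < 1.0):
            raise ValueError("need -1 < tau2 <= tau < 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass
class SetAssignment:
    """Partition of genes into ordered sets, one pseudoset and ungrouped."""

    label_of: dict[str, str]
    #: set label -> ordered member list, keys "set_1" .. "set_K", "pseudoset"
    members: dict[str, list[str]]
    #: per-gene count of within-group partners above the relevant threshold
    n_partners: dict[str, int]
    peak_stage: dict[str, str]

    @property
    def genes(self) -> list[str]:
        return list(self.label_of)

    @property
    def n_sets(self) -> int:
        return sum(1 for k in self.members if k.startswith("set_"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.label_of),
                "label": [self.label_of[g] for g in self.label_of],
                "n_partners": [self.n_partners.get(g, 0) for g in self.label_of],
                "peak_stage": [self.peak_stage.get(g, "none")
                               for g in self.label_of],
            }
        )


def pearson_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Pearson product-moment correlation of per-gene mean profiles.

    Zero-variance profiles yield missing (NaN) correlations against every
    partner; a missing r never exceeds any threshold. The diagonal is 1.
    """
    if expr.mean.shape[1] < 3:
        raise ValueError("need at least 3 conditions for correlation")
    x = expr.mean.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    np.fill_diagonal(corr, 1.0)
    zero_var = np.std(x, axis=1) == 0.0
    corr[zero_var, :] = np.nan
    corr[:, zero_var] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=expr.mean.index, columns=expr.mean.index)


def _peak_stages(expr: ExpressionMatrix) -> tuple[dict[str, str], dict[str, float]]:
    """Per-gene stage of maximum mean expression (ties -> earliest stage)."""
    labels: dict[str, str] = {}
    values: dict[str, float] = {}
    grid = expr.grid
    cond_values = (
        [grid.value_of(c) for c in expr.conditions]
        if grid is not None
        else list(range(len(expr.conditions)))
    )
    for gene in expr.genes:
        row = expr.mean.loc[gene].to_numpy(dtype=float)
        if np.all(row == 0.0):
            labels[gene] = "none"
            values[gene] = np.nan
        else:
            i = int(np.argmax(row))
            labels[gene] = expr.conditions[i]
            values[gene] = cond_values[i]
    return labels, values


def _threshold_graph(corr: pd.DataFrame, genes, threshold: float) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(genes)
    sub = corr.loc[genes, genes].to_numpy(dtype=float)
    idx = list(genes)
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            r = sub[i, j]
            if np.isfinite(r) and r > threshold:
                g.add_edge(idx[i], idx[j])
    return g


def assign_sets(corr: pd.DataFrame, params: SetRuleParams,
                expr: ExpressionMatrix) -> SetAssignment:
    """Assign genes to strict correlation sets, a pseudoset and ungrouped.

    Builds the graph of pairs with r > tau, reduces it to its m-core
    (iterated deletion of nodes with fewer than m neighbours), and reports
    each connected component with at least ``min_set_size`` genes as a set.
    Sets are numbered by ascending mean peak stage. Unassigned genes are
    passed to :func:`detect_pseudoset`.
    """
    genes = list(corr.index)
    graph = _threshold_graph(corr, genes, params.tau)
    if params.membership_consistent:
        core = nx.k_core(graph, k=params.m)
    else:
        core = graph.subgraph(
            [n for n in graph if graph.degree(n) >= params.m]
        ).copy()
    components = [sorted(c) for c in nx.connected_components(core)
                  if len(c) >= params.min_set_size]

    peak_labels, peak_values = _peak_stages(expr)
    components.sort(
        key=lambda comp: (
            float(np.nanmean([peak_values[g] for g in comp])), comp
        )
    )

    label_of: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    n_partners: dict[str, int] = {}
    for rank, comp in enumerate(components, start=1):
        name = f"set_{rank}"
        members[name] = comp
        for gene in comp:
            label_of[gene] = name
            n_partners[gene] = sum(
                1 for other in comp
                if other != gene and np.isfinite(corr.at[gene, other])
                and corr.at[gene, other] > params.tau
            )

    unassigned = [g for g in genes if g not in label_of]
    pseudo, ungrouped = detect_pseudoset(corr, unassigned, params,
                                         peak_values=peak_values)
    if pseudo:
        members[PSEUDOSET] = sorted(pseudo)
        for gene in pseudo:
            label_of[gene] = PSEUDOSET
            n_partners[gene] = sum(
                1 for other in pseudo
                if other != gene and np.isfinite(corr.at[gene, other])
                and corr.at[gene, other] > params.tau2
            )
    for gene in ungrouped:
        label_of[gene] = UNGROUPED
        n_partners[gene] = 0
    # restore original gene order
    label_of = {g: label_of[g] for g in genes}
    return SetAssignment(label_of, members, n_partners, peak_labels)


def detect_pseudoset(corr: pd.DataFrame, unassigned, params: SetRuleParams,
                     peak_values: dict[str, float] | None = None
                     ) -> tuple[list[str], list[str]]:
    """Split the unassigned genes into pseudoset members and ungrouped.

    Components of the r > tau2 graph with at least ``min_set_size`` members
    are candidates; the most populous one (ties: earliest mean peak stage,
    then lexicographic) is *the* pseudoset.
    """
    unassigned = list(unassigned)
    graph = _threshold_graph(corr, unassigned, params.tau2)
    candidates = [sorted(c) for c in nx.connected_components(graph)
                  if len(c) >= params.min_set_size]
    if not candidates:
        return [], unassigned
    if peak_values is None:
        peak_values = {g: np.nan for g in unassigned}
    candidates.sort(
        key=lambda comp: (
            -len(comp),
            float(np.nanmean([peak_values.get(g, np.nan) for g in comp]))
            if np.any(np.isfinite([peak_values.get(g, np.nan) for g in comp]))
            else np.inf,
            comp,
        )
    )
    pseudo = candidates[0]
    ungrouped = [g for g in unassigned if g not in pseudo]
    return pseudo, ungrouped


def hierarchical_cluster(expr: ExpressionMatrix, k: int) -> dict[str, int]:
    """Complete-linkage clustering of z-scored profiles into ``k`` clusters.

    Rows are standardized to mean 0 / sd 1 (the heat-map convention for
    expression data spanning orders of magnitude), distances are Euclidean,
    and the tree is cut into ``k`` flat clusters. Zero-variance genes are
    excluded with a logged warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = expr.mean.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0.0
    dropped = [g for g, ok in zip(expr.genes, keep) if not ok]
    if dropped:
        logger.warning("excluding zero-variance gene(s) from clustering: %s",
                       ", ".join(dropped))
    genes = [g for g, ok in zip(expr.genes, keep) if ok]
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    tree = linkage(pdist(z, metric="euclidean"), method="complete")
    labels = fcluster(tree, t=min(k, len(genes)), criterion="maxclust")
    return dict(zip(genes, (int(v) for v in labels)))


def compare_groupings(a: dict[str, object], b: dict[str, object]) -> float:
    """Adjusted Rand index between two labelings of the same genes."""
    if set(a) != set(b):
        raise ValueError("groupings cover different gene universes")
    genes = sorted(a)
    return float(adjusted_rand_score([str(a[g]) for g in genes],
                                     [str(b[g]) for g in genes]))


def heatmap_table(expr: ExpressionMatrix, eps: float = 1e-3,
                  cap_quantile: float = 0.99) -> pd.DataFrame:
    """log10(Q + eps) table capped at an upper quantile, for heat-map export."""
    vals = np.log10(expr.mean.to_numpy(dtype=float) + eps)
    cap = float(np.quantile(vals, cap_quantile))
    return pd.DataFrame(np.minimum(vals, cap), index=expr.mean.index,
                        columns=expr.mean.columns)
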