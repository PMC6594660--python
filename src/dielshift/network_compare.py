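"""Per-condition co-expression modules, module overlap, and interaction networks.

Co-expression follows the signed weighted-network recipe: biweight
midcorrelation, signed adjacency ``((1 + bicor)/2)**beta``, topological
overlap, average-linkage clustering with a fixed-height cut, minimum module
size, and merging of modules whose representative profiles (first principal
component) are nearly collinear.  The fixed-height cut plus merging is a
documented simplification of dynamic tree cutting: downstream module-overlap
statistics, not exact module boundaries, are the analytic output.

Interaction networks use a normalized mutual-information score (equal
frequency binning, ceil(sqrt(n)) bins, normalized by sqrt of the marginal
entropies so the score lies in [0, 1]) with data-processing-inequality
pruning of indirect edges.  This is a documented stand-in for
part-mutual-information estimators: it reproduces the condition-differencing
logic (activator/suppressor calls), not any particular program's edge scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact

from .core_io import ExpressionMatrix, logger


@dataclass(frozen=True)
class NetworkParams:
    """Signed co-expression network parameters (condition-specific defaults
    are beta 7 / merge height 0.01 for WW and beta 10 / 0.15 for DR)."""

    beta: float = 7.0
    min_module_size: int = 10
    cut_height: float = 0.6
    merge_height: float = 0.01

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 <= self.merge_height <= 1:
            raise ValueError("merge_height must be in [0, 1]")


def params_for(condition: str) -> NetworkParams:
    if condition == "WW":
        return NetworkParams(beta=7.0, merge_height=0.01)
    if condition == "DR":
        return NetworkParams(beta=10.0, merge_height=0.15)
    raise ValueError(f"unknown condition {condition!r}")


# -- correlation / adjacency / TOM ---------------------------------------


def bicor(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Biweight midcorrelation between rows of ``values``.

    Returns (correlation matrix, validity mask); rows whose median absolute
    deviation is zero have undefined bicor and are flagged invalid.
    """
    x = np.asarray(values, dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    valid = (mad[:, 0] > 0) & (x.std(axis=1) > 0)
    u = np.zeros_like(x)
    np.divide(x - med, 9.0 * mad, out=u, where=mad > 0)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    g = (x - med) * w
    norm = np.sqrt((g**2).sum(axis=1, keepdims=True))
    norm[norm == 0] = 1.0
    gn = g / norm
    corr = np.clip(gn @ gn.T, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr, valid


def signed_adjacency(corr: np.ndarray, beta: float) -> np.ndarray:
    return ((1.0 + corr) / 2.0) ** beta


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency (diagonal = 1).

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with the
    diagonal excluded from the shared-neighbour sum and from connectivity k.
    """
    a = np.array(adjacency, dtype=float)
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# -- module detection ----------------------------------------------------


def _representative_profile(values: np.ndarray) -> np.ndarray:
    """First principal component of standardized member profiles."""
    x = values - values.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    x = x / sd
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    pc = vt[0]
    if np.corrcoef(pc, x.mean(axis=0))[0, 1] < 0:
        pc = -pc
    return pc


def build_coexpression_modules(
    matrix: ExpressionMatrix | pd.DataFrame,
    params: NetworkParams = NetworkParams(),
) -> pd.Series:
    """Detect co-expression modules in one condition's (averaged) profiles.

    Returns a Series gene -> integer module label; 0 marks unassigned genes
    (constant profiles or modules below the minimum size).  Labels are
    contiguous, ordered by decreasing module size.
    """
    data = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    if data.shape[1] < 8:
        raise ValueError("need at least 8 samples to build a network")
    values = data.to_numpy(dtype=float)
    genes = list(data.index)

    corr, valid = bicor(values)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%d constant gene profiles assigned to module 0", n_bad)
    labels = np.zeros(len(genes), dtype=int)
    idx = np.flatnonzero(valid)
    if len(idx) >= 2:
        sub_corr = corr[np.ix_(idx, idx)]
        tom = topological_overlap(signed_adjacency(sub_corr, params.beta))
        dist = 1.0 - tom
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        raw = fcluster(z, t=params.cut_height, criterion="distance")

        # enforce minimum size
        sizes = pd.Series(raw).value_counts()
        keep = {int(c) for c, n in sizes.items() if n >= params.min_module_size}
        raw = np.array([c if c in keep else 0 for c in raw])

        raw = _merge_modules(values[idx], raw, params.merge_height)
        labels[idx] = raw

    # contiguous labels ordered by size
    out = pd.Series(labels, index=genes, name="module")
    sizes = out[out > 0].value_counts()
    remap = {old: new for new, old in enumerate(sizes.index, start=1)}
    out = out.map(lambda c: remap.get(c, 0)).astype(int)
    logger.info(
        "build_coexpression_modules: %d modules, %d unassigned genes",
        out.max(), int((out == 0).sum()),
    )
    return out


def _merge_modules(values: np.ndarray, labels: np.ndarray, merge_height: float) -> np.ndarray:
    """Merge modules whose representative profiles correlate above 1 - merge_height."""
    labels = labels.copy()
    while True:
        mods = sorted({c for c in labels if c > 0})
        if len(mods) < 2:
            return labels
        reps = {c: _representative_profile(values[labels == c]) for c in mods}
        best = None
        for i, a in enumerate(mods):
            for b in mods[i + 1 :]:
                r = float(np.corrcoef(reps[a], reps[b])[0, 1])
                if r > 1.0 - merge_height and (best is None or r > best[0]):
                    best = (r, a, b)
        if best is None:
            return labels
        _, a, b = best
        labels[labels == b] = a


# -- module overlap ------------------------------------------------------


def module_overlap_matrix(partition_ww: pd.Series, partition_dr: pd.Series) -> pd.DataFrame:
    """Cross-condition module overlap with one-sided Fisher exact p-values.

    Both partitions must cover the same gene universe.  Module 0
    (unassigned) is excluded.  Returns a long-form table: module pair,
    shared gene count, module sizes, percentage of the smaller module
    shared, and the enrichment p-value.
    """
    if set(partition_ww.index) != set(partition_dr.index):
        raise ValueError("partitions cover different gene universes")
    dr = partition_dr.loc[partition_ww.index]
    universe = len(partition_ww)
    rows = []
    for a in sorted(set(partition_ww) - {0}):
        in_a = partition_ww == a
        size_a = int(in_a.sum())
        for b in sorted(set(dr) - {0}):
            in_b = dr == b
            size_b = int(in_b.sum())
            shared = int((in_a & in_b).sum())
            table = [
                [shared, size_a - shared],
                [size_b - shared, universe - size_a - size_b + shared],
            ]
            _, p = fisher_exact(table, alternative="greater")
            rows.append(
                (a, b, shared, size_a, size_b, 100.0 * shared / min(size_a, size_b), float(p))
            )
    return pd.DataFrame(
        rows,
        columns=["module_ww", "module_dr", "shared", "size_ww", "size_dr", "pct_shared", "p_value"],
    )


# -- interaction network -------------------------------------------------


@dataclass
class InteractionNetwork:
    """Undirected weighted interaction network with its retention threshold."""

    graph: nx.Graph
    threshold: float

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene)) if gene in self.graph else set()

    def edges(self) -> pd.DataFrame:
        rows = [(u, v, d["score"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])

    def to_tsv(self, path) -> None:
        self.edges().to_csv(path, sep="\t", index=False)


def _equal_frequency_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    order = np.argsort(values, kind="stable", axis=1)
    n = values.shape[1]
    ranks = np.empty_like(order)
    rows = np.arange(values.shape[0])[:, None]
    ranks[rows, order] = np.arange(n)[None, :]
    return (ranks * n_bins) // n


def normalized_mutual_information(values: np.ndarray) -> np.ndarray:
    """Pairwise NMI between rows: MI / sqrt(H_i * H_j), equal-frequency bins."""
    x = np.asarray(values, dtype=float)
    n_genes, n = x.shape
    b = int(np.ceil(np.sqrt(n)))
    bins = _equal_frequency_bins(x, b)
    # marginal entropies
    ent = np.empty(n_genes)
    for i in range(n_genes):
        counts = np.bincount(bins[i], minlength=b)
        p = counts[counts > 0] / n
        ent[i] = -(p * np.log(p)).sum()
    nmi = np.eye(n_genes)
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            joint = np.bincount(bins[i] * b + bins[j], minlength=b * b) / n
            joint = joint[joint > 0]
            h_joint = -(joint * np.log(joint)).sum()
            mi = max(0.0, ent[i] + ent[j] - h_joint)
            denom = np.sqrt(ent[i] * ent[j])
            nmi[i, j] = nmi[j, i] = mi / denom if denom > 0 else 0.0
    return np.clip(nmi, 0.0, 1.0)


def infer_interaction_network(
    matrix: ExpressionMatrix | pd.DataFrame,
    threshold: float,
    dpi_tolerance: float = 0.1,
) -> InteractionNetwork:
    """Build an interaction network from per-sample profiles of one condition.

    Edges score >= ``threshold`` survive; an edge (i, j) is then removed by
    the data-processing-inequality step when some third gene k satisfies
    ``min(score(i,k), score(k,j)) > score(i,j) * (1 + dpi_tolerance)``.
    Constant genes are excluded with a warning.
    """
    data = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    if data.shape[1] < 10:
        raise ValueError("need at least 10 samples for interaction inference")
    values = data.to_numpy(dtype=float)
    genes = np.array(data.index)
    ok = values.std(axis=1) > 0
    if (~ok).any():
        logger.warning("%d constant genes excluded from interaction network", int((~ok).sum()))
    values, genes = values[ok], genes[ok]

    score = normalized_mutual_information(values)
    g = nx.Graph(threshold=threshold)
    g.add_nodes_from(genes)
    n = len(genes)
    candidate = [(i, j) for i in range(n) for j in range(i + 1, n) if score[i, j] >= threshold]
    for i, j in candidate:
        s_ij = score[i, j]
        indirect = False
        for k in range(n):
            if k in (i, j):
                continue
            if min(score[i, k], score[k, j]) > s_ij * (1.0 + dpi_tolerance):
                indirect = True
                break
        if not indirect:
            g.add_edge(genes[i], genes[j], score=float(s_ij))
    logger.info(
        "infer_interaction_network: %d nodes, %d edges at threshold %.2f",
        g.number_of_nodes(), g.number_of_edges(), threshold,
    )
    return InteractionNetwork(graph=g, threshold=threshold)


# -- condition differencing ----------------------------------------------


def classify_regulators(
    net_ww: InteractionNetwork,
    net_dr: InteractionNetwork,
    targets: Iterable[str],
) -> pd.DataFrame:
    """Per-target condition-specific interaction partners.

    Activators are neighbours present only in the drought (DR) network;
    suppressors are neighbours present only in the well-watered (WW)
    network; shared partners are reported separately.  Targets absent from
    both networks yield empty lists with a warning.
    """
    rows = []
    for t in targets:
        if t not in net_ww.graph and t not in net_dr.graph:
            logger.warning("target %s absent from both networks", t)
        nb_ww = net_ww.neighbors(t)
        nb_dr = net_dr.neighbors(t)
        activators = sorted(nb_dr - nb_ww)
        suppressors = sorted(nb_ww - nb_dr)
        shared = sorted(nb_ww & nb_dr)
        rows.append(
            (t, len(activators), len(suppressors), len(shared), activators, suppressors, shared)
        )
    return pd.DataFrame(
        rows,
        columns=["target", "n_activators", "n_suppressors", "n_shared",
                 "activators", "suppressors", "shared"],
    ).set_index("target")
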