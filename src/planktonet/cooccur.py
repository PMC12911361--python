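"""Sparse conditional co-occurrence networks on CLR-transformed compositions.

The estimator follows the SPIEC-EASI recipe with the Meinshausen–Bühlmann
neighborhood-selection variant: counts are centered-log-ratio transformed
(pseudocount 1), each ASV's CLR profile is L1-regressed on all others along a
geometric λ path, and the sparsity level is chosen by StARS — the least
regularization whose edge-selection instability over subsamples stays below a
bound β. Directed selections are combined into an undirected weighted graph
("or" rule, mean weights) whose out-degree view is retained for connectivity
ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from planktonet.data_model import AsvTable


@dataclass
class ClrMatrix:
    """Centered log-ratio transformed samples × ASVs matrix (rows sum to 0)."""

    data: pd.DataFrame
    pseudocount: float = 1.0

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def asv_ids(self) -> list:
        return list(self.data.columns)


@dataclass
class StarsResult:
    lambdas: np.ndarray
    instability: np.ndarray
    monotonized: np.ndarray
    lambda_star: float
    lambda_index: int
    bound_met: bool
    n_subsamples: int
    subsample_size: int
    seed: int


@dataclass
class SparseNetwork:
    """Weighted association graph over ASVs with its directed coefficient map."""

    graph: nx.Graph
    directed: pd.DataFrame
    lambda_star: float
    instability: float
    rule: str = "or"
    meta: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def out_degree(self) -> pd.Series:
        """Number of selected outgoing neighborhood-regression edges per node."""
        return (self.directed != 0).sum(axis=1)


def clr_transform(counts, pseudocount: float = 1.0) -> ClrMatrix:
    """CLR: x → log(x + pseudocount) − mean over the row of the same logs."""
    df = counts.data if isinstance(counts, AsvTable) else pd.DataFrame(counts)
    X = df.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    if (X.sum(axis=1) <= 0).any():
        raise ValueError("zero-total sample(s)")
    logs = np.log(X + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return ClrMatrix(pd.DataFrame(clr, index=df.index, columns=df.columns), pseudocount)


def merge_markers(table_16s: AsvTable, table_18s: AsvTable) -> AsvTable:
    """Concatenate 16S and 18S tables over shared samples (for one network).

    Samples present in only one marker are dropped with a warning.
    """
    shared = [s for s in table_16s.sample_ids if s in set(table_18s.sample_ids)]
    dropped = (set(table_16s.sample_ids) | set(table_18s.sample_ids)) - set(shared)
    if dropped:
        warnings.warn(f"merge_markers: dropped {len(dropped)} sample(s) missing a marker")
    merged = pd.concat(
        [table_16s.data.loc[shared], table_18s.data.loc[shared]], axis=1
    )
    return AsvTable(merged, marker="mixed")


# ---------------------------------------------------------------------------
# Neighborhood selection along a lambda path
# ---------------------------------------------------------------------------

def lambda_path(clr: ClrMatrix, n_lambdas: int = 20, min_ratio: float = 0.01) -> np.ndarray:
    """Geometric λ path from λ_max (the largest absolute pairwise correlation,
    at which every neighborhood regression is empty) down to min_ratio·λ_max."""
    Z = _standardize(clr.data.to_numpy(dtype=float))
    r = np.corrcoef(Z, rowvar=False)
    np.fill_diagonal(r, 0.0)
    lam_max = float(np.nanmax(np.abs(r)))
    if lam_max <= 0:
        raise ValueError("degenerate data: all pairwise correlations are zero")
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambdas)


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def neighborhood_lasso_path(clr_data, lambdas) -> np.ndarray:
    """Per-node lasso regressions along the λ path.

    Returns ``coefs`` with shape (n_lambdas, p, p): ``coefs[l, j, i]`` is the
    coefficient of ASV i in the L1 regression of ASV j on all other ASVs at
    ``lambdas[l]`` (a directed edge j→i when nonzero). Columns are
    standardized, so λ_max equals the largest absolute correlation.
    """
    X = clr_data.data.to_numpy(dtype=float) if isinstance(clr_data, ClrMatrix) else np.asarray(clr_data, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda path must be strictly decreasing")
    if (lambdas <= 0).any():
        raise ValueError("lambdas must be positive")
    n, p = X.shape
    if n < 10:
        warnings.warn("fewer than 10 samples; neighborhood selection is unstable")
    Z = _standardize(X)
    coefs = np.zeros((len(lambdas), p, p))
    others = np.arange(p)
    for j in range(p):
        mask = others != j
        _, path_coefs, _ = lasso_path(Z[:, mask], Z[:, j], alphas=lambdas)
        # lasso_path returns alphas in decreasing order = our order
        coefs[:, j, mask] = path_coefs.T
    return coefs


def edges_from_coefs(coefs_at_lambda: np.ndarray, rule: str = "or") -> np.ndarray:
    """Undirected boolean adjacency from one λ's directed coefficients."""
    sel = coefs_at_lambda != 0
    if rule == "or":
        und = sel | sel.T
    elif rule == "and":
        und = sel & sel.T
    else:
        raise ValueError(f"unknown rule {rule!r}")
    np.fill_diagonal(und, False)
    return und


# ---------------------------------------------------------------------------
# StARS
# ---------------------------------------------------------------------------

def default_subsample_size(n: int) -> int:
    """floor(10·√n) capped at n−1; floor(0.8·n) for small n (< 144)."""
    b = int(np.floor(10 * np.sqrt(n))) if n >= 144 else int(np.floor(0.8 * n))
    return min(b, n - 1)


def stars_select_lambda(
    clr: ClrMatrix,
    lambdas=None,
    n_subsamples: int = 50,
    subsample_size: int | None = None,
    beta: float = 0.05,
    seed: int = 0,
    rule: str = "or",
) -> StarsResult:
    """Stability selection of the penalty level.

    For each λ, the edge-selection frequency θₑ over random subsamples yields
    an instability D(λ) = mean over possible edges of 2θₑ(1−θₑ). D is
    monotonized from the sparse (large-λ) end and λ* is the smallest λ —
    the densest, least-regularized graph — whose monotonized instability is
    ≤ β. If no λ qualifies the sparsest λ is returned flagged.
    """
    if lambdas is None:
        lambdas = lambda_path(clr)
    lambdas = np.asarray(lambdas, dtype=float)
    if len(lambdas) < 2:
        raise ValueError("need >= 2 lambda values")
    n, p = clr.data.shape
    if subsample_size is None:
        subsample_size = default_subsample_size(n)
    if subsample_size < 10:
        raise ValueError("subsample size must be >= 10")
    rng = np.random.default_rng(seed)
    X = clr.data.to_numpy(dtype=float)
    freq = np.zeros((len(lambdas), p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=subsample_size, replace=False)
        coefs = neighborhood_lasso_path(X[idx], lambdas)
        for l in range(len(lambdas)):
            freq[l] += edges_from_coefs(coefs[l], rule=rule)
    freq /= n_subsamples
    iu = np.triu_indices(p, k=1)
    instability = np.array([(2 * freq[l] * (1 - freq[l]))[iu].mean() for l in range(len(lambdas))])
    monotonized = np.maximum.accumulate(instability)
    ok = np.where(monotonized <= beta)[0]
    if len(ok):
        idx_star = int(ok[-1])  # densest lambda still within the bound
        bound_met = True
    else:
        idx_star = 0
        bound_met = False
        warnings.warn(f"StARS: no lambda met instability bound {beta}; returning sparsest")
    return StarsResult(
        lambdas=lambdas,
        instability=instability,
        monotonized=monotonized,
        lambda_star=float(lambdas[idx_star]),
        lambda_index=idx_star,
        bound_met=bound_met,
        n_subsamples=n_subsamples,
        subsample_size=subsample_size,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Network assembly and summaries
# ---------------------------------------------------------------------------

def assemble_network(
    coefs_at_lambda: np.ndarray,
    asv_ids,
    domains: dict | pd.Series | None = None,
    lambda_star: float = np.nan,
    instability: float = np.nan,
    rule: str = "or",
    weight_rule: str = "mean",
) -> SparseNetwork:
    """Combine directed selections into an undirected weighted graph.

    An undirected edge (i, j) exists when i→j or j→i was selected ("or" rule;
    "and" requires both); its weight is the mean of the available directed
    coefficients ("mean") or the larger-magnitude one ("max"). All input nodes
    are retained, including isolated ones.
    """
    asv_ids = list(asv_ids)
    p = len(asv_ids)
    C = np.asarray(coefs_at_lambda, dtype=float)
    if C.shape != (p, p):
        raise ValueError("coefficient matrix shape must match asv_ids")
    und = edges_from_coefs(C, rule=rule)
    g = nx.Graph()
    dom = pd.Series(domains).reindex(asv_ids) if domains is not None else pd.Series("unknown", index=asv_ids)
    for a in asv_ids:
        g.add_node(a, domain=dom.get(a, "unknown"))
    for i, j in zip(*np.where(np.triu(und, k=1))):
        w_ij, w_ji = C[i, j], C[j, i]
        present = [w for w in (w_ij, w_ji) if w != 0]
        if rule == "and" or len(present) == 2:
            weight = float(np.mean([w_ij, w_ji])) if weight_rule == "mean" else float(
                max(w_ij, w_ji, key=abs))
        else:
            weight = float(present[0])
        g.add_edge(asv_ids[i], asv_ids[j], weight=weight)
    directed = pd.DataFrame(C, index=asv_ids, columns=asv_ids)
    return SparseNetwork(graph=g, directed=directed, lambda_star=float(lambda_star),
                         instability=float(instability), rule=rule)


def network_summary(net: SparseNetwork) -> dict:
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    weights = [d["weight"] for _, _, d in g.edges(data=True)]
    domains = pd.Series(nx.get_node_attributes(g, "domain"))
    return {
        "nodes": n,
        "edges": e,
        "mean_degree": (2 * e / n) if n else 0.0,
        "density": nx.density(g) if n > 1 else 0.0,
        "clustering": nx.average_clustering(g) if n else 0.0,
        "transitivity": nx.transitivity(g) if n else 0.0,
        "components": nx.number_connected_components(g) if n else 0,
        "nodes_per_domain": domains.value_counts().to_dict(),
        "weight_min": float(min(weights)) if weights else np.nan,
        "weight_max": float(max(weights)) if weights else np.nan,
        "weight_mean": float(np.mean(weights)) if weights else np.nan,
    }


def infer_network(
    counts: AsvTable,
    domains=None,
    lambdas=None,
    n_lambdas: int = 20,
    n_subsamples: int = 50,
    beta: float = 0.05,
    seed: int = 0,
    rule: str = "or",
    pseudocount: float = 1.0,
) -> tuple[SparseNetwork, StarsResult]:
    """End-to-end: CLR → λ path → StARS → final fit at λ* → assembled graph."""
    clr = clr_transform(counts, pseudocount=pseudocount)
    if lambdas is None:
        lambdas = lambda_path(clr, n_lambdas=n_lambdas)
    stars = stars_select_lambda(clr, lambdas, n_subsamples=n_subsamples, beta=beta,
                                seed=seed, rule=rule)
    coefs = neighborhood_lasso_path(clr, lambdas)
    net = assemble_network(
        coefs[stars.lambda_index],
        clr.asv_ids,
        domains=domains,
        lambda_star=stars.lambda_star,
        instability=float(stars.monotonized[stars.lambda_index]),
        rule=rule,
    )
    return net, stars


def correlation_baseline(clr: ClrMatrix, n_edges: int) -> set[frozenset]:
    """Edge set of the top-|correlation| pairs, matched for edge count — the
    marginal baseline that conditional-dependence estimation must beat."""
    Z = _standardize(clr.data.to_numpy(dtype=float))
    r = np.abs(np.corrcoef(Z, rowvar=False))
    iu = np.triu_indices(r.shape[0], k=1)
    order = np.argsort(r[iu])[::-1][:n_edges]
    ids = clr.asv_ids
    return {frozenset((ids[iu[0][k]], ids[iu[1][k]])) for k in order}


def edge_set(net: SparseNetwork) -> set[frozenset]:
    return {frozenset((u, v)) for u, v in net.graph.edges}


def precision_recall(predicted: set[frozenset], truth: set[frozenset]) -> tuple[float, float]:
    """Support-recovery precision and recall of an edge set against truth."""
    if not predicted:
        return 0.0, 0.0
    tp = len(predicted & truth)
    return tp / len(predicted), tp / len(truth) if truth else 0.0
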