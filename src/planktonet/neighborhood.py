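"""Microbial neighborhoods: joining modules with the co-occurrence network.

Candidate ASVs come from co-abundance modules that correlate positively and
significantly with a trait; their first-degree network neighbors are
extracted with weights and module labels, cross-tabulated by weight sign, and
the pipeline's internal positive control checks that a known association
(e.g. the *Braarudosphaera*–UCYN-A symbiosis) appears as an edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from planktonet.coabundance import UNASSIGNED, ModulePartition
from planktonet.cooccur import SparseNetwork
from planktonet.data_model import TaxonomyMap


@dataclass
class CandidateSet:
    """ASVs from trait-positive modules, with the qualifying records."""

    asv_ids: list[str]
    records: pd.DataFrame  # columns: module, trait, r, p

    def __len__(self) -> int:
        return len(self.asv_ids)


def select_candidate_modules(
    module_trait: pd.DataFrame,
    partition: ModulePartition,
    alpha: float = 0.05,
    correction: str | None = None,
) -> CandidateSet:
    """Members of modules with r > 0 and p < alpha for at least one trait.

    ``correction="bh"`` applies Benjamini–Hochberg across the table first;
    the default (no correction) mirrors reporting raw p-values directly.
    """
    mt = module_trait.dropna(subset=["r", "p"]).copy()
    if correction == "bh":
        mt["p"] = _benjamini_hochberg(mt["p"].to_numpy())
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    qualifying = mt[(mt["r"] > 0) & (mt["p"] < alpha)]
    modules = sorted(qualifying["module"].unique())
    if not modules:
        warnings.warn("no module passed the positive-correlation significance filter")
    asvs: list[str] = []
    for m in modules:
        asvs.extend(partition.members(m))
    return CandidateSet(asv_ids=sorted(set(asvs)), records=qualifying.reset_index(drop=True))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top
        running = min(running, p[idx] * m / k)
        adj[idx] = running
    return adj


def first_degree_neighbors(
    net: SparseNetwork,
    candidate: str,
    partition: ModulePartition | None = None,
) -> pd.DataFrame:
    """All network edges incident to a candidate, sorted by weight (descending,
    ties broken lexicographically by neighbor id).

    Columns: neighbor, weight (symmetrized), out_weight (candidate→neighbor
    directed coefficient), in_weight, module, domain.
    """
    if candidate not in net.graph:
        raise KeyError(f"candidate {candidate!r} not in network")
    rows = []
    for neighbor in net.graph.neighbors(candidate):
        data = net.graph.edges[candidate, neighbor]
        module = UNASSIGNED
        if partition is not None and neighbor in partition.labels.index:
            module = partition.labels[neighbor]
        rows.append({
            "candidate": candidate,
            "neighbor": neighbor,
            "weight": float(data["weight"]),
            "out_weight": float(net.directed.loc[candidate, neighbor]),
            "in_weight": float(net.directed.loc[neighbor, candidate]),
            "module": module,
            "domain": net.graph.nodes[neighbor].get("domain", "unknown"),
        })
    df = pd.DataFrame(rows, columns=["candidate", "neighbor", "weight", "out_weight",
                                     "in_weight", "module", "domain"])
    return df.sort_values(["weight", "neighbor"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)


def neighbor_module_crosstab(
    neighbors: pd.DataFrame,
    partition: ModulePartition,
    candidate_module: str | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Cross-tabulate neighbor module membership by edge-weight sign.

    Reports counts of (weight sign × neighbor module), plus a same-module
    enrichment odds ratio — the odds that a positive-edge neighbor shares the
    candidate's module versus a negative-edge neighbor — with a permutation
    p-value obtained by shuffling neighbor module labels. With zero negative
    (or positive) edges the odds ratio is undefined and reported as NaN.
    """
    df = neighbors.copy()
    labels = partition.labels
    df["module"] = [
        labels[n] if n in labels.index else "none" for n in df["neighbor"]
    ]
    if candidate_module is None and len(df):
        cands = df["candidate"].unique()
        candidate_module = labels.get(cands[0], "none")
    df["sign"] = np.where(df["weight"] > 0, "positive", "negative")
    table = pd.crosstab(df["sign"], df["module"]) if len(df) else pd.DataFrame()
    same = (df["module"] == candidate_module).to_numpy()
    pos = (df["sign"] == "positive").to_numpy()

    def odds_ratio(same_mask):
        a = (same_mask & pos).sum()       # positive, same module
        b = ((~same_mask) & pos).sum()    # positive, other
        c = (same_mask & ~pos).sum()      # negative, same
        d = ((~same_mask) & ~pos).sum()   # negative, other
        if min(a + b, c + d) == 0:
            return np.nan
        # Haldane correction keeps finite ratios with empty cells
        return (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))

    observed = odds_ratio(same)
    rng = np.random.default_rng(seed)
    p = np.nan
    if np.isfinite(observed):
        hits = 0
        for _ in range(n_permutations):
            hits += odds_ratio(rng.permutation(same)) >= observed
        p = (1 + hits) / (n_permutations + 1)
    return {
        "crosstab": table,
        "candidate_module": candidate_module,
        "odds_ratio": float(observed) if np.isfinite(observed) else np.nan,
        "p_value": float(p) if np.isfinite(p) else np.nan,
        "n_positive": int(pos.sum()),
        "n_negative": int((~pos).sum()),
    }


def check_known_association(
    net: SparseNetwork,
    taxonomy: TaxonomyMap,
    label_a: str,
    label_b: str,
) -> dict:
    """Check whether any network edge links two taxon labels (positive control).

    Labels match case-insensitively against any rank string of the lineage
    (e.g. ``"Braarudosphaera"`` and ``"UCYN-A"``). Returns the matched ASVs,
    edge presence, and the connecting edges with weights.
    """
    asvs_a = _resolve_label(net, taxonomy, label_a)
    asvs_b = _resolve_label(net, taxonomy, label_b)
    edges = []
    for a in asvs_a:
        for b in asvs_b:
            if net.graph.has_edge(a, b):
                edges.append({"a": a, "b": b,
                              "weight": float(net.graph.edges[a, b]["weight"])})
    return {
        "label_a": label_a,
        "label_b": label_b,
        "asvs_a": asvs_a,
        "asvs_b": asvs_b,
        "edge_present": bool(edges),
        "edges": edges,
    }


def _resolve_label(net: SparseNetwork, taxonomy: TaxonomyMap, label: str) -> list[str]:
    needle = label.lower()
    hits = [
        asv for asv in net.nodes
        if any(needle in rank.lower() for rank in taxonomy.lineage(asv))
    ]
    if not hits:
        raise KeyError(f"label {label!r} resolves to no ASV in the network")
    return hits
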