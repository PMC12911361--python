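"""Dissimilarity, ordination and permutation statistics.

Bray–Curtis dissimilarities, non-metric multidimensional scaling (Kruskal
stress-1, SMACOF majorization with a classical-scaling start), ANOSIM and
EnvFit permutation tests, and the subset-vs-whole comparison that quantifies
how closely persistent (or ephemeral) ASVs track the full community.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from planktonet.data_model import AsvTable, PersistenceLabel, relative_abundance


@dataclass
class DissimilarityMatrix:
    """Symmetric sample × sample dissimilarities in [0, 1], zero diagonal."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if len(self.sample_ids) != v.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-10:
            raise ValueError("diagonal must be zero")
        if v.min() < -1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("values must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class OrdinationResult:
    """NMDS configuration with its Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    n_restarts: int
    converged: bool


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    method: str
    extras: dict | None = None


def bray_curtis_matrix(abundances, sample_ids=None) -> DissimilarityMatrix:
    """Bray–Curtis dissimilarity d(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) between rows."""
    if isinstance(abundances, AsvTable):
        abundances = abundances.data
    if isinstance(abundances, pd.DataFrame):
        sample_ids = list(abundances.index) if sample_ids is None else sample_ids
        abundances = abundances.to_numpy(dtype=float)
    else:
        abundances = np.asarray(abundances, dtype=float)
        if sample_ids is None:
            sample_ids = list(range(abundances.shape[0]))
    if (abundances < 0).any():
        raise ValueError("abundances must be non-negative")
    if (abundances.sum(axis=1) <= 0).any():
        raise ValueError("all-zero row(s) present; Bray-Curtis undefined")
    d = squareform(pdist(abundances, metric="braycurtis"))
    return DissimilarityMatrix(sample_ids=sample_ids, values=d)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def classical_scaling(D: DissimilarityMatrix, k: int) -> np.ndarray:
    """Torgerson classical scaling (PCoA) coordinates, used to seed NMDS."""
    n = D.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D.values**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def kruskal_stress(D: DissimilarityMatrix, coords: np.ndarray) -> float:
    """Stress-1 of a configuration: monotone regression of fitted distances
    on observed dissimilarities, sqrt(Σ(d − d̂)² / Σd²)."""
    obs = D.condensed()
    fit = pdist(coords)
    dhat = IsotonicRegression().fit_transform(obs, fit)
    denom = (fit**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((fit - dhat) ** 2).sum() / denom))


def nmds_embed(
    D: DissimilarityMatrix,
    k: int = 2,
    n_restarts: int = 4,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    One restart is seeded from classical scaling of ``D``; the remaining
    restarts are random. The best (lowest-stress) configuration wins. Stress
    of every candidate is re-evaluated with the same isotonic-regression
    definition so restarts are comparable.
    """
    if k >= D.n:
        raise ValueError("embedding dimension must be < number of samples")
    rng = np.random.default_rng(seed)
    best_coords, best_stress, any_converged = None, np.inf, False
    inits = [classical_scaling(D, k)]
    scale = max(D.values.max(), 1e-12)
    for _ in range(max(n_restarts - 1, 0)):
        inits.append(rng.normal(scale=scale, size=(D.n, k)))
    for init in inits:
        try:
            mds = MDS(n_components=k, metric="precomputed", metric_mds=False,
                      n_init=1, max_iter=max_iter, eps=tol, normalized_stress=True)
        except TypeError:  # scikit-learn < 1.9 parameter names
            mds = MDS(n_components=k, metric=False, dissimilarity="precomputed",
                      n_init=1, max_iter=max_iter, eps=tol, normalized_stress=True)
        coords = mds.fit_transform(D.values, init=init)
        stress = kruskal_stress(D, coords)
        converged = mds.n_iter_ < max_iter
        any_converged = any_converged or converged
        if stress < best_stress:
            best_stress, best_coords = stress, coords
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(best_coords, index=D.sample_ids, columns=cols),
        stress=best_stress,
        n_restarts=len(inits),
        converged=any_converged,
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def anosim(
    D: DissimilarityMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Analysis of similarities.

    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2 condensed pairs ranked by midranks; the p-value counts
    permuted R values at least as large as the observed one.
    """
    grouping = np.asarray(pd.Series(grouping).reindex(D.sample_ids).to_numpy()
                          if isinstance(grouping, (pd.Series, dict)) else grouping)
    if len(grouping) != D.n:
        raise ValueError("grouping length must match number of samples")
    labels, counts = np.unique(grouping, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"group(s) of size 1 not allowed: {small}")
    ranks = rankdata(D.condensed())
    M = len(ranks)
    i_idx, j_idx = np.triu_indices(D.n, k=1)

    def r_stat(g):
        within = g[i_idx] == g[j_idx]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2)

    observed = r_stat(grouping)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        hits += r_stat(rng.permutation(grouping)) >= observed
    p = (1 + hits) / (n_permutations + 1)
    return PermutationTestResult(float(observed), float(p), n_permutations, seed, "anosim")


# ---------------------------------------------------------------------------
# EnvFit
# ---------------------------------------------------------------------------

def envfit(
    coordinates: pd.DataFrame | np.ndarray,
    variable,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Least-squares fit of an external variable onto ordination axes.

    r² = 1 − SSres/SStot from the regression of the (centered) variable on
    the axes; the arrow is the unit coefficient vector; the p-value permutes
    the variable across samples.
    """
    coords = coordinates.to_numpy() if isinstance(coordinates, pd.DataFrame) else np.asarray(coordinates)
    y = np.asarray(pd.Series(variable).reindex(coordinates.index).to_numpy()
                   if isinstance(coordinates, pd.DataFrame) and isinstance(variable, (pd.Series, dict))
                   else variable, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("variable must be finite")
    if np.ptp(y) == 0:
        raise ValueError("variable is constant")
    Xc = coords - coords.mean(axis=0)

    def fit_r2(yv):
        yc = yv - yv.mean()
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        ss_res = ((yc - Xc @ beta) ** 2).sum()
        return 1 - ss_res / (yc**2).sum(), beta

    r2, beta = fit_r2(y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        r2_perm, _ = fit_r2(rng.permutation(y))
        hits += r2_perm >= r2
    p = (1 + hits) / (n_permutations + 1)
    norm = np.linalg.norm(beta)
    arrow = beta / norm if norm > 0 else beta
    return PermutationTestResult(float(r2), float(p), n_permutations, seed, "envfit",
                                 extras={"arrow": arrow})


# ---------------------------------------------------------------------------
# Persistence subset vs whole community
# ---------------------------------------------------------------------------

def subset_vs_whole_dissimilarity(
    table: AsvTable,
    labels: PersistenceLabel,
    groups: pd.Series | None = None,
    unit: str = "per-sample-group",
) -> dict:
    """Bray–Curtis distance between a persistence class and the whole community.

    For each sample (× phytoplankton group when ``groups`` is given and
    ``unit="per-sample-group"``), the composition restricted to one persistence
    class, renormalized, is compared against the composition over all ASVs of
    that unit. Distances near 0 mean the class alone reproduces the community;
    a class holding share *s* of the unit's abundance sits at distance 1 − s
    when the two classes share no ASVs.

    Returns ``{"distances": DataFrame, "summary": DataFrame, "skipped": int}``.
    """
    if unit not in ("per-sample-group", "per-sample", "pooled"):
        raise ValueError(f"unknown aggregation unit {unit!r}")
    covered = set(labels.labels.index)
    missing = [a for a in table.asv_ids if a not in covered]
    if missing:
        raise ValueError(f"{len(missing)} ASV(s) lack persistence labels, e.g. {missing[:3]}")

    if unit == "per-sample-group" and groups is not None:
        grp = pd.Series(groups).reindex(table.asv_ids)
        units = [(name, list(members.index)) for name, members in grp.groupby(grp)]
        units = [(g, a) for g, a in units if len(a) > 0]
    else:
        units = [("all", table.asv_ids)]

    if unit == "pooled":
        data = pd.DataFrame(table.data.sum(axis=0)).T
        data.index = ["pooled"]
    else:
        data = table.data

    rows, skipped = [], 0
    for unit_name, asvs in units:
        sub = data[asvs].to_numpy(dtype=float)
        cls_masks = {
            cls: np.array([labels.labels[a] == cls for a in asvs])
            for cls in ("persistent", "ephemeral")
        }
        totals = sub.sum(axis=1)
        for i, sample in enumerate(data.index):
            if totals[i] <= 0:
                skipped += 1
                continue
            whole = sub[i] / totals[i]
            for cls, mask in cls_masks.items():
                cls_total = sub[i, mask].sum()
                if not mask.any() or cls_total <= 0:
                    skipped += 1
                    continue
                part = np.zeros_like(whole)
                part[mask] = sub[i, mask] / cls_total
                d = np.abs(part - whole).sum() / (part + whole).sum()
                rows.append({"sample": sample, "group": unit_name, "class": cls,
                             "distance": float(d)})
    distances = pd.DataFrame(rows, columns=["sample", "group", "class", "distance"])
    if len(distances):
        summary = distances.groupby("class")["distance"].agg(["mean", "median", "count"])
    else:
        summary = pd.DataFrame(columns=["mean", "median", "count"])
    return {"distances": distances, "summary": summary, "skipped": skipped}
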