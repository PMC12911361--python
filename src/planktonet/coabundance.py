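"""Weighted co-abundance modules and their correlation with traits.

A soft-thresholded correlation network is built over standardized relative
abundances of persistent phytoplankton ASVs (unsigned adjacency |r|^β by
default), converted to a topological overlap matrix (TOM), and cut into
modules by average-linkage clustering of 1 − TOM. Module eigengenes (first
principal components) summarize each module per sample and are correlated
against Box–Cox-transformed traits (NCP, POC, PON).

The branch cut is a fixed-height cut with eigengene-based merging rather than
the full dynamic hybrid tree cut: the cut height defaults to the largest gap
in the merge heights, and candidate modules must be tighter than the TOM
background, which recovers dynamic cutting's main effect (noise stays
unassigned) with far less machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import boxcox as _scipy_boxcox
from scipy.stats import pearsonr

#: WGCNA-style palette, assigned to modules in decreasing size order.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
)

UNASSIGNED = "grey"


@dataclass
class SoftThresholdReport:
    powers: list[int]
    fit_r2: list[float]
    mean_connectivity: list[float]
    chosen_power: int
    target_r2: float
    degenerate: bool = False


@dataclass
class ModulePartition:
    """ASV → module color plus per-module eigengene scores per sample."""

    labels: pd.Series
    eigengenes: pd.DataFrame
    cut_height: float

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]

    @property
    def n_unassigned(self) -> int:
        return int((self.labels == UNASSIGNED).sum())


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

def boxcox_transform(y, lmbda: float | None = None) -> tuple[np.ndarray, float, float]:
    """Box–Cox transform y(λ) = (y^λ − 1)/λ (log y at λ = 0).

    λ maximizes the profile log-likelihood when not given. Non-positive inputs
    are shifted to min + 1 first; the shift is returned so the transform is
    documented and invertible. Returns ``(transformed, lambda, shift)``.
    """
    y = np.asarray(y, dtype=float)
    y = y[np.isfinite(y)]
    if len(y) < 3:
        raise ValueError("need >= 3 finite values")
    if np.ptp(y) == 0:
        raise ValueError("constant input")
    shift = 0.0
    if y.min() <= 0:
        shift = 1.0 - y.min()
        y = y + shift
    if lmbda is None:
        transformed, lam = _scipy_boxcox(y)
    else:
        lam = float(lmbda)
        transformed = np.log(y) if lam == 0 else (y**lam - 1) / lam
    return np.asarray(transformed), float(lam), shift


# ---------------------------------------------------------------------------
# Adjacency / soft threshold / TOM
# ---------------------------------------------------------------------------

def log_abundance(rel: pd.DataFrame, pseudo: float | None = None) -> pd.DataFrame:
    """log₁₀ relative abundance with a small pseudo-fraction.

    Relative abundances are strongly right-skewed, which attenuates Pearson
    correlation; co-abundance networks are therefore built on the log scale.
    ``pseudo`` defaults to half the smallest nonzero proportion.
    """
    X = rel.to_numpy(dtype=float)
    if pseudo is None:
        positive = X[X > 0]
        pseudo = float(positive.min()) / 2 if positive.size else 1e-6
    return pd.DataFrame(np.log10(X + pseudo), index=rel.index, columns=rel.columns)


def adjacency_matrix(abundances: pd.DataFrame, power: float = 6, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded co-abundance adjacency between ASVs (columns).

    Unsigned: |cor|^β. Signed: ((1 + cor)/2)^β.
    """
    X = abundances.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = abundances.columns[sd == 0].tolist()
        raise ValueError(f"constant ASV profile(s): {bad[:5]}")
    r = np.corrcoef(X, rowvar=False)
    A = ((1 + r) / 2) ** power if signed else np.abs(r) ** power
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=abundances.columns, columns=abundances.columns)


def pick_soft_threshold(
    abundances: pd.DataFrame,
    powers=range(1, 21),
    target_r2: float = 0.8,
    n_bins: int = 10,
    signed: bool = False,
) -> SoftThresholdReport:
    """Scale-free topology criterion for the soft power β.

    For each β the connectivity distribution is binned and log₁₀ p(k) is
    regressed on log₁₀ k; the fit index is −sign(slope)·R². The chosen β is
    the smallest reaching ``target_r2``, else the argmax.
    """
    if abundances.shape[0] < 20:
        warnings.warn("fewer than 20 samples; soft-threshold fit is unreliable")
    powers = list(powers)
    r2s, conns = [], []
    degenerate = False
    for beta in powers:
        A = adjacency_matrix(abundances, power=beta, signed=signed).to_numpy()
        k = A.sum(axis=0) - 1.0
        conns.append(float(k.mean()))
        if np.ptp(k) < 1e-12:
            degenerate = True
            r2s.append(0.0)
            continue
        r2s.append(_scale_free_fit_index(k, n_bins))
    passing = [b for b, r2 in zip(powers, r2s) if r2 >= target_r2]
    chosen = passing[0] if passing else powers[int(np.argmax(r2s))]
    return SoftThresholdReport(powers, r2s, conns, chosen, target_r2, degenerate)


def _scale_free_fit_index(k: np.ndarray, n_bins: int) -> float:
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.digitize(k, edges) - 1
    ks, ps = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() > 0:
            ks.append(k[mask].mean())
            ps.append(mask.mean())
    ks, ps = np.array(ks), np.array(ps)
    ok = (ks > 0) & (ps > 0)
    if ok.sum() < 3:
        return 0.0
    x, yv = np.log10(ks[ok]), np.log10(ps[ok])
    slope, _ = np.polyfit(x, yv, 1)
    r = np.corrcoef(x, yv)[0, 1]
    return float(-np.sign(slope) * r**2)


def topological_overlap(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """TOMᵢⱼ = (Σᵤ AᵢᵤAᵤⱼ + Aᵢⱼ) / (min(kᵢ, kⱼ) + 1 − Aᵢⱼ), unit diagonal.

    ``A`` must be symmetric with entries in [0, 1] and unit diagonal; the sum
    over shared neighbors u excludes i and j themselves.
    """
    ids = adjacency.index if isinstance(adjacency, pd.DataFrame) else None
    A = adjacency.to_numpy(dtype=float) if ids is not None else np.asarray(adjacency, dtype=float)
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    k = A.sum(axis=0) - np.diag(A)
    # shared-neighbor sums excluding i and j: (A@A)ij − A_ii A_ij − A_ij A_jj
    L = A @ A - A * (np.diag(A)[:, None] + np.diag(A)[None, :])
    num = L + A
    den = np.minimum.outer(k, k) + 1.0 - A
    np.fill_diagonal(den, 1.0)  # diagonal is defined as 1 below
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2, 0.0, 1.0)
    return pd.DataFrame(tom, index=ids, columns=ids) if ids is not None else tom


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def module_eigengene(member_abundances: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal-component score of a module's standardized profiles.

    The sign is oriented so the mean correlation with member profiles is
    positive. Returns ``(scores per sample, fraction of variance explained)``.
    """
    if member_abundances.shape[1] < 2:
        raise ValueError("module must have >= 2 members")
    X = member_abundances.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant member profile(s)")
    Z = (X - X.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    score = U[:, 0] * S[0]
    explained = float(S[0] ** 2 / (S**2).sum())
    mean_cor = np.mean([np.corrcoef(score, Z[:, j])[0, 1] for j in range(Z.shape[1])])
    if mean_cor < 0:
        score = -score
    score = score / max(score.std(), 1e-12)
    return pd.Series(score, index=member_abundances.index), explained


def detect_modules(
    tom: pd.DataFrame,
    abundances: pd.DataFrame,
    min_module_size: int = 5,
    cut_height: float | None = None,
    merge_threshold: float = 0.25,
    tightness: float = 1.5,
    min_cor: float = 0.3,
    on_empty: str = "raise",
) -> ModulePartition:
    """Cut the 1 − TOM average-linkage dendrogram into co-abundance modules.

    ``cut_height=None`` evaluates cuts at the largest gaps between merge
    heights (upper half of the dendrogram, plus the everything-in-one-branch
    cut) and keeps the one maximizing weighted TOM modularity, which adapts
    the cut to the soft power in use. Branches smaller than
    ``min_module_size`` are left unassigned, as are loose branches: module
    quality is judged in correlation space (independent of the soft power),
    requiring mean intra-branch |cor| ≥ ``min_cor`` and ≥ ``tightness`` × the
    mean |cor| outside the branch. Modules whose eigengenes correlate above
    1 − ``merge_threshold`` are merged. Labels are colors ordered by size.
    """
    ids = list(tom.index)
    T = tom.to_numpy(dtype=float)
    dist = 1.0 - T
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    heights = Z[:, 2]
    n = T.shape[0]
    R = np.abs(np.corrcoef(abundances[ids].to_numpy(), rowvar=False))
    iu = np.triu_indices(n, k=1)
    total_sum = float(R[iu].sum())
    n_pairs = len(iu[0])

    def valid_clusters(cut):
        raw = fcluster(Z, t=cut, criterion="distance")
        out = []
        for c in np.unique(raw):
            members = np.where(raw == c)[0]
            if len(members) < min_module_size:
                continue
            m = len(members)
            intra = R[np.ix_(members, members)]
            intra_sum = float(intra[np.triu_indices(m, k=1)].sum())
            mean_intra = intra_sum / (m * (m - 1) / 2)
            if mean_intra < min_cor:
                continue
            outside_pairs = n_pairs - m * (m - 1) // 2
            if outside_pairs > 0:
                background = (total_sum - intra_sum) / outside_pairs
                if mean_intra < tightness * background:
                    continue
            out.append(members)
        return out

    if cut_height is None:
        cut_height, clusters = _best_gap_cut(heights, valid_clusters, T)
    else:
        clusters = valid_clusters(cut_height)
    labels = np.full(len(ids), UNASSIGNED, dtype=object)
    if not clusters:
        if on_empty == "raise":
            raise ValueError(
                "no module passed the size/tightness filters; consider lowering "
                "min_module_size or cut_height"
            )
        return ModulePartition(
            labels=pd.Series(labels, index=ids),
            eigengenes=pd.DataFrame(index=abundances.index),
            cut_height=float(cut_height),
        )
    clusters = _merge_by_eigengene(clusters, ids, abundances, merge_threshold)
    clusters.sort(key=len, reverse=True)
    eigengenes = {}
    for rank, members in enumerate(clusters):
        color = MODULE_COLORS[rank % len(MODULE_COLORS)]
        for m in members:
            labels[m] = color
        eg, _ = module_eigengene(abundances[[ids[m] for m in members]])
        eigengenes[color] = eg
    return ModulePartition(
        labels=pd.Series(labels, index=ids),
        eigengenes=pd.DataFrame(eigengenes),
        cut_height=float(cut_height),
    )


def _best_gap_cut(heights: np.ndarray, valid_clusters, T: np.ndarray,
                  n_candidates: int = 8):
    """Candidate cuts are midpoints of the largest gaps between consecutive
    merge heights (upper half of the dendrogram); the winner maximizes the
    weighted modularity of its valid modules on the TOM graph, which penalizes
    both over-splitting (lost within-module weight) and under-merging
    (included between-module weight)."""
    hs = np.sort(heights)
    if len(hs) == 1:
        cut = float(hs[0] + 1e-9)
        return cut, valid_clusters(cut)
    start = len(hs) // 2
    gaps = np.diff(hs)
    idx = np.arange(len(gaps))
    upper = idx[start:] if len(gaps) > start else idx
    ranked = upper[np.argsort(gaps[upper])[::-1][:n_candidates]]
    candidates = [float((hs[g] + hs[g + 1]) / 2) for g in ranked]
    candidates.append(float(hs[-1]) + 1e-9)  # everything-in-one-branch cut
    best = None
    for cut in candidates:
        clusters = valid_clusters(cut)
        score = (_tom_modularity(T, clusters), sum(len(c) for c in clusters))
        if best is None or score > best[0]:
            best = (score, cut, clusters)
    return best[1], best[2]


def _tom_modularity(T: np.ndarray, clusters) -> float:
    W = T.copy()
    np.fill_diagonal(W, 0.0)
    total = W.sum()  # 2 * sum of edge weights
    if total <= 0:
        return 0.0
    deg = W.sum(axis=0)
    q = 0.0
    for members in clusters:
        q += W[np.ix_(members, members)].sum() / total
        q -= (deg[members].sum() / total) ** 2
    return float(q)


def _merge_by_eigengene(clusters, ids, abundances, merge_threshold):
    merged = True
    clusters = [list(c) for c in clusters]
    while merged and len(clusters) > 1:
        merged = False
        egs = [module_eigengene(abundances[[ids[m] for m in c]])[0] for c in clusters]
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                r = float(np.corrcoef(egs[i], egs[j])[0, 1])
                if r > 1 - merge_threshold and (best is None or r > best[0]):
                    best = (r, i, j)
        if best is not None:
            _, i, j = best
            clusters[i] = clusters[i] + clusters[j]
            del clusters[j]
            merged = True
    return clusters


# ---------------------------------------------------------------------------
# Module-trait correlation and power stability
# ---------------------------------------------------------------------------

def module_trait_correlation(
    partition: ModulePartition,
    traits: pd.DataFrame,
    transform: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    Traits are Box–Cox transformed first (the stabilization applied before
    any trait correlation in this pipeline); missing trait values are dropped
    pairwise; cells with < 3 paired observations are NA.
    """
    rows = []
    for trait in traits.columns:
        t_raw = traits[trait]
        finite = t_raw.dropna()
        if transform and len(finite) >= 3 and np.ptp(finite.to_numpy()) > 0:
            tvals, lam, shift = boxcox_transform(finite.to_numpy())
            tseries = pd.Series(tvals, index=finite.index)
        else:
            tseries = finite.astype(float)
        for module in partition.eigengenes.columns:
            eg = partition.eigengenes[module]
            common = eg.index.intersection(tseries.index)
            if len(common) < 3:
                rows.append({"module": module, "trait": trait, "r": np.nan, "p": np.nan,
                             "n": len(common)})
                continue
            r, p = pearsonr(eg.loc[common], tseries.loc[common])
            rows.append({"module": module, "trait": trait, "r": float(r), "p": float(p),
                         "n": len(common)})
    return pd.DataFrame(rows)


def module_power_stability(
    abundances: pd.DataFrame,
    powers=range(1, 9),
    reference_power: int | None = None,
    signed: bool = False,
    **detect_kwargs,
) -> pd.DataFrame:
    """Jaccard stability of module memberships as the soft power varies.

    The partition at ``reference_power`` (default: the middle of ``powers``)
    anchors the comparison; for every other power each reference module is
    matched to its best-Jaccard counterpart. Rows: (power, module, jaccard).
    """
    powers = list(powers)
    if len(powers) < 2:
        raise ValueError("need >= 2 powers")
    if reference_power is None:
        reference_power = powers[len(powers) // 2]
    detect_kwargs.setdefault("on_empty", "keep")

    def partition_at(beta):
        A = adjacency_matrix(abundances, power=beta, signed=signed)
        return detect_modules(topological_overlap(A), abundances, **detect_kwargs)

    ref = partition_at(reference_power)
    ref_sets = {m: set(ref.members(m)) for m in ref.modules()}
    rows = []
    for beta in powers:
        part = ref if beta == reference_power else partition_at(beta)
        other_sets = [set(part.members(m)) for m in part.modules()]
        for module, members in ref_sets.items():
            if other_sets:
                jac = max(len(members & o) / len(members | o) for o in other_sets)
            else:
                jac = 0.0
            rows.append({"power": beta, "module": module, "jaccard": float(jac)})
    return pd.DataFrame(rows)
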