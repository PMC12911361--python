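"""Multi-kernel variance partitioning of biogeochemical traits.

Each phytoplankton group contributes a sample × sample *group kernel*: the
Gower-centered, PSD-projected similarity derived from Bray–Curtis
dissimilarities of the group-restricted community. A linear mixed model

    y = Xβ + Σ_g u_g + ε,   u_g ~ N(0, σ²_g K_g),   ε ~ N(0, σ²_e I)

is then fit by restricted maximum likelihood (average-information updates
with an EM fallback, non-negativity by projection), and the trait variance is
partitioned into per-group fractions f_g = σ²_g / (Σ_g σ²_g + σ²_e).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from planktonet.community import bray_curtis_matrix
from planktonet.data_model import AsvTable


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the optimization trajectory."""

    def __init__(self, message, trajectory):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class GroupKernel:
    """Trace-normalized PSD similarity kernel for one taxon group."""

    name: str
    K: np.ndarray
    sample_ids: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kernel must be symmetric")
        self.K = (K + K.T) / 2

    @property
    def n(self) -> int:
        return self.K.shape[0]


@dataclass
class VarianceDecomposition:
    """REML variance components, fractions, and fit diagnostics."""

    sigma2: dict[str, float]
    fractions: dict[str, float]
    loglik: float
    n: int
    rank_X: int
    aic: float
    bic: float
    converged: bool
    n_iter: int
    basis: str = "REML"
    aliased: list = field(default_factory=list)
    trajectory: list = field(default_factory=list)

    @property
    def k_params(self) -> int:
        return len(self.sigma2) + self.rank_X


def build_group_kernel(
    table: AsvTable,
    asv_ids,
    name: str = "group",
    zero_policy: str = "impute",
) -> GroupKernel:
    """Kernel from Bray–Curtis dissimilarities of one group's composition.

    D is Bray–Curtis on the group-restricted relative abundances; the kernel
    is the Gower transform S = −½·C(D∘D)C with C the centering projector,
    negative eigenvalues clipped to zero, and the result rescaled to trace n.

    Samples with zero group abundance are handled per ``zero_policy``:
    ``"impute"`` assigns them a uniform composition over the group's ASVs
    (maximally uninformative), ``"drop"`` removes them, ``"error"`` raises.
    """
    asv_ids = [a for a in asv_ids if a in table.data.columns]
    if len(asv_ids) < 2:
        raise ValueError(f"group {name!r} needs >= 2 ASVs present in the table")
    sub = table.data[asv_ids].to_numpy(dtype=float)
    sample_ids = list(table.data.index)
    totals = sub.sum(axis=1)
    zero = totals <= 0
    n_zero = int(zero.sum())
    if n_zero:
        if zero_policy == "error":
            raise ValueError(f"{n_zero} sample(s) have zero {name} abundance")
        if zero_policy == "drop":
            sub = sub[~zero]
            sample_ids = [s for s, z in zip(sample_ids, zero) if not z]
            totals = totals[~zero]
        elif zero_policy == "impute":
            sub[zero] = 1.0
            totals = sub.sum(axis=1)
            warnings.warn(f"build_group_kernel[{name}]: {n_zero} zero-abundance "
                          "sample(s) imputed as uniform composition")
        else:
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
    rel = sub / totals[:, None]
    D = bray_curtis_matrix(rel, sample_ids=sample_ids).values
    n = D.shape[0]
    C = np.eye(n) - np.ones((n, n)) / n
    S = -0.5 * C @ (D * D) @ C
    vals, vecs = np.linalg.eigh((S + S.T) / 2)
    min_eig = float(vals.min())  # Bray-Curtis is non-Euclidean: negatives expected
    vals = np.clip(vals, 0.0, None)
    K = (vecs * vals) @ vecs.T
    trace = float(np.trace(K))
    rank = int((vals > 1e-12 * max(vals.max(), 1.0)).sum())
    prov = {
        "dissimilarity": "bray-curtis",
        "n_asvs": len(asv_ids),
        "rank": rank,
        "min_eigenvalue_before_clip": min_eig,
        "n_zero_samples": n_zero,
        "zero_policy": zero_policy,
    }
    if trace <= 1e-12:
        warnings.warn(f"build_group_kernel[{name}]: degenerate kernel (all samples "
                      "identical); trace normalization skipped")
        prov["degenerate"] = True
        return GroupKernel(name, K, sample_ids, prov)
    K *= n / trace
    return GroupKernel(name, (K + K.T) / 2, sample_ids, prov)


# ---------------------------------------------------------------------------
# Fixed-effect design
# ---------------------------------------------------------------------------

def design_matrix(
    meta: pd.DataFrame,
    interaction: tuple = ("year", "month"),
    additive: tuple = ("size_fraction", "depth_bin"),
) -> pd.DataFrame:
    """Full-rank fixed-effect design: intercept + year×month + additive factors.

    Aliased (linearly dependent) dummy columns are dropped via a rank-revealing
    QR so the design is always full column rank.
    """
    parts = [pd.Series(1.0, index=meta.index, name="intercept")]
    if interaction and all(c in meta.columns for c in interaction):
        combo = meta[list(interaction)].astype(str).agg(":".join, axis=1)
        parts.append(pd.get_dummies(combo, prefix=":".join(interaction), drop_first=True, dtype=float))
    for col in additive:
        if col in meta.columns:
            parts.append(pd.get_dummies(meta[col].astype(str), prefix=col, drop_first=True, dtype=float))
    X = pd.concat(parts, axis=1)
    return drop_aliased_columns(X)


def drop_aliased_columns(X: pd.DataFrame, tol: float = 1e-8) -> pd.DataFrame:
    Q, R, piv = _qr_pivot(X.to_numpy(dtype=float))
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * max(diag.max(), 1.0)).sum())
    keep = sorted(piv[:rank])
    return X.iloc[:, keep]


def _qr_pivot(A):
    from scipy.linalg import qr

    Q, R, piv = qr(A, mode="economic", pivoting=True)
    return Q, R, piv


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _prepare(y, X, kernels):
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    elif isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    Ks = []
    names = []
    for i, k in enumerate(kernels):
        if isinstance(k, GroupKernel):
            Ks.append(k.K)
            names.append(k.name)
        else:
            Ks.append(np.asarray(k, dtype=float))
            names.append(f"kernel_{i}")
    for K in Ks:
        if K.shape != (n, n):
            raise ValueError("kernel shape must match len(y)")
    rank_X = np.linalg.matrix_rank(X)
    if n <= rank_X + 1:
        raise ValueError("need n > rank(X) + 1 observations")
    return y, X, Ks, names, n, rank_X


def reml_loglik(y, X, kernels, sigma2) -> float:
    """Restricted log-likelihood ℓ_R = −½[log|V| + log|XᵀV⁻¹X| + yᵀPy]
    at variance components ``sigma2`` (group components then residual)."""
    y, X, Ks, _, n, _ = _prepare(y, X, kernels)
    theta = np.asarray(sigma2, dtype=float)
    if len(theta) != len(Ks) + 1:
        raise ValueError("sigma2 must list one value per kernel plus the residual")
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], Ks):
        V += t * K
    return _loglik_from_V(y, X, V)[0]


def _loglik_from_V(y, X, V, ridge=1e-8):
    n = V.shape[0]
    try:
        c = cho_factor(V)
    except np.linalg.LinAlgError:
        warnings.warn("V singular; adding ridge 1e-8")
        c = cho_factor(V + ridge * np.trace(V) / n * np.eye(n))
    logdet_V = 2 * np.log(np.diag(c[0])).sum()
    Vi_X = cho_solve(c, X)
    Vi_y = cho_solve(c, y)
    XtViX = X.T @ Vi_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf, None, None
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    ll = -0.5 * (logdet_V + logdet_XtViX + float(y @ Py))
    P = cho_solve(c, np.eye(n)) - Vi_X @ np.linalg.solve(XtViX, Vi_X.T)
    return ll, P, Py


def fit_multikernel_reml(
    y,
    X,
    kernels,
    max_iter: int = 200,
    tol: float = 1e-6,
    verbose: bool = False,
) -> VarianceDecomposition:
    """REML estimation of (σ²_1…σ²_G, σ²_e) by average-information updates.

    Average-information steps are taken with step-halving so the restricted
    likelihood never decreases; when a step fails, an EM update is used
    instead. Components are kept non-negative by projection to a small floor.
    Non-convergence within ``max_iter`` raises :class:`ConvergenceError`
    carrying the trajectory.
    """
    y, Xm, Ks, names, n, rank_X = _prepare(y, X, kernels)
    aliased = _detect_aliasing(Ks, names, n)
    G = len(Ks)
    vy = float(np.var(y, ddof=1))
    if vy <= 0:
        raise ValueError("response is constant")
    floor = 1e-10 * vy
    theta = np.full(G + 1, vy / (G + 1))
    Ks_all = Ks + [np.eye(n)]
    trajectory = []
    ll, P, Py = _current(y, Xm, Ks_all, theta)
    converged = False
    for it in range(max_iter):
        trajectory.append((theta.copy(), ll))
        # score and average-information matrix
        KPy = [K @ Py for K in Ks_all]
        score = np.array([
            -0.5 * (np.einsum("ij,ji->", P, K) - float(Py @ K @ Py))
            for K in Ks_all
        ])
        PK = [P @ t for t in KPy]
        AI = 0.5 * np.array([[float(KPy[i] @ PK[j]) for j in range(G + 1)] for i in range(G + 1)])
        new_theta, new_ll, new_P, new_Py = _ai_step(y, Xm, Ks_all, theta, ll, score, AI, floor)
        if new_theta is None:
            # EM fallback: guaranteed-ascent fixed-point update
            nr = n - rank_X
            new_theta = np.clip(
                theta + theta**2 / nr * np.array(
                    [float(Py @ K @ Py) - np.einsum("ij,ji->", P, K) for K in Ks_all]
                ),
                floor,
                None,
            )
            new_ll, new_P, new_Py = _current(y, Xm, Ks_all, new_theta)
        delta = np.abs(new_theta - theta).max() / vy
        dll = new_ll - ll
        theta, ll, P, Py = new_theta, new_ll, new_P, new_Py
        if verbose:
            print(f"iter {it}: ll={ll:.6f} theta={theta}")
        # converged when parameters settle, or when the likelihood has
        # plateaued (boundary components can leave parameters creeping along
        # a flat ridge at negligible likelihood gain)
        if delta < tol or abs(dll) < 1e-8 * max(1.0, abs(ll)):
            converged = True
            break
    trajectory.append((theta.copy(), ll))
    if not converged:
        raise ConvergenceError(f"REML did not converge in {max_iter} iterations", trajectory)
    sigma2 = {name: float(t) for name, t in zip(names, theta[:-1])}
    sigma2["residual"] = float(theta[-1])
    total = sum(sigma2.values())
    fractions = {k: v / total for k, v in sigma2.items()}
    k_params = (G + 1) + rank_X
    aic, bic = information_criteria_from(ll, k_params, n)
    return VarianceDecomposition(
        sigma2=sigma2,
        fractions=fractions,
        loglik=float(ll),
        n=n,
        rank_X=int(rank_X),
        aic=aic,
        bic=bic,
        converged=converged,
        n_iter=len(trajectory) - 1,
        aliased=aliased,
        trajectory=trajectory,
    )


def _current(y, X, Ks_all, theta):
    V = sum(t * K for t, K in zip(theta, Ks_all))
    return _loglik_from_V(y, X, V)


def _ai_step(y, X, Ks_all, theta, ll, score, AI, floor, max_halvings=15):
    ridge = 1e-8 * max(np.abs(np.diag(AI)).max(), 1.0)
    try:
        direction = np.linalg.solve(AI + ridge * np.eye(len(theta)), score)
    except np.linalg.LinAlgError:
        return None, None, None, None
    step = 1.0
    for _ in range(max_halvings):
        cand = np.clip(theta + step * direction, floor, None)
        cand_ll, P, Py = _current(y, X, Ks_all, cand)
        if np.isfinite(cand_ll) and cand_ll >= ll - 1e-10:
            return cand, cand_ll, P, Py
        step /= 2
    return None, None, None, None


def _detect_aliasing(Ks, names, n, tol=1e-8):
    """Flag kernel pairs (including the implicit residual identity) that are
    numerically indistinguishable, making their components non-identifiable."""
    mats = Ks + [np.eye(n)]
    labels = names + ["residual"]
    aliased = []
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            if np.linalg.norm(mats[i] - mats[j]) / n < tol:
                aliased.append((labels[i], labels[j]))
    if aliased:
        warnings.warn(f"non-identifiable kernel pair(s): {aliased}")
    return aliased


def information_criteria_from(loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC = −2ℓ + 2k and BIC = −2ℓ + k·log n."""
    return float(-2 * loglik + 2 * k), float(-2 * loglik + k * np.log(n))


def information_criteria(decomp: VarianceDecomposition) -> tuple[float, float]:
    """(AIC, BIC) of a converged fit; the likelihood basis (REML) is recorded
    on the decomposition itself."""
    return information_criteria_from(decomp.loglik, decomp.k_params, decomp.n)


# ---------------------------------------------------------------------------
# Covariation direction
# ---------------------------------------------------------------------------

def covariation_direction(
    decomp: VarianceDecomposition,
    kernels,
    y,
    X=None,
    group_index: dict | None = None,
    min_fraction: float = 0.01,
    alpha: float = 0.05,
) -> dict[str, int | None]:
    """Sign of each group's covariation with the trait.

    The group's BLUP û_g = σ²_g K_g V⁻¹ (y − Xβ̂) is correlated against a
    per-sample group-abundance index (``group_index[name]``, e.g. total group
    relative abundance). Groups with a negligible variance fraction
    (< ``min_fraction``) or a non-significant correlation report ``None``.
    """
    from scipy.stats import pearsonr

    y, Xm, Ks, names, n, _ = _prepare(y, X, kernels)
    theta = np.array([decomp.sigma2[nm] for nm in names] + [decomp.sigma2["residual"]])
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], Ks):
        V += t * K
    c = cho_factor(V)
    Vi_y = cho_solve(c, y)
    Vi_X = cho_solve(c, Xm)
    beta = np.linalg.solve(Xm.T @ Vi_X, Xm.T @ Vi_y)
    resid_proj = cho_solve(c, y - Xm @ beta)
    signs: dict[str, int | None] = {}
    for nm, t, K in zip(names, theta[:-1], Ks):
        if decomp.fractions.get(nm, 0.0) < min_fraction:
            signs[nm] = None
            continue
        u = t * (K @ resid_proj)
        idx = np.asarray(group_index[nm], dtype=float) if group_index else u
        if np.ptp(idx) == 0 or np.ptp(u) == 0:
            signs[nm] = None
            continue
        r, p = pearsonr(u, idx)
        signs[nm] = (1 if r > 0 else -1) if p < alpha else None
    return signs
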