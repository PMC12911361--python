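"""Synthetic multi-year plankton surveys with planted truth.

The generator emulates the structure of a three-cruise latitudinal transect
crossing a salinity front and a chlorophyll front: six phytoplankton-containing
groups with Gaussian latitude niches, two size fractions with group-specific
enrichment, persistent and ephemeral ASVs, a planted sparse precision matrix
driving residual co-occurrence (logistic-normal-multinomial counts, so the
precision support is the literal truth for network recovery), planted
co-abundance modules driven by shared latent factors, and traits whose
variance decomposes over group kernels in specified fractions.

Every generated dataset carries a :class:`SyntheticTruth` sufficient to score
recovery of persistence classes, variance fractions, module labels and
precision support without regeneration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from planktonet.data_model import (
    AsvTable,
    TaxonomyMap,
    assign_groups,
    assign_region,
    depth_bin,
)
from planktonet.varpart import build_group_kernel

YEARS = (2016, 2017, 2019)
CRUISE_MONTHS = {2016: "June", 2017: "June", 2019: "May"}
SIZE_FRACTIONS = ("0.2", "3.0")

#: Group → (latitude optimum °N, niche width °) for the default transect.
DEFAULT_NICHES = {
    "Prochlorococcus": (26.0, 4.0),
    "Dinoflagellata": (27.5, 5.0),
    "Haptophyta": (31.0, 6.0),
    "Stramenopiles_photosynthetic": (36.0, 5.0),
    "Synechococcus": (37.0, 5.0),
    "Archaeplastida": (38.0, 4.0),
    "Other_16S": (32.0, 12.0),
    "Other_18S": (32.0, 12.0),
}

#: Log-scale enrichment of the small (0.2 µm) fraction relative to the large.
DEFAULT_SMALL_FRACTION_ENRICHMENT = {
    "Prochlorococcus": np.log(4.0),
    "Synechococcus": 0.0,
    "Archaeplastida": np.log(4.0),
    "Dinoflagellata": 0.0,
    "Haptophyta": np.log(2.5),
    "Stramenopiles_photosynthetic": np.log(3.0),
    "Other_16S": 0.0,
    "Other_18S": 0.0,
}

DEFAULT_ASVS_PER_GROUP = {
    "Prochlorococcus": 14,
    "Synechococcus": 14,
    "Archaeplastida": 26,
    "Dinoflagellata": 22,
    "Haptophyta": 18,
    "Stramenopiles_photosynthetic": 18,
    "Other_16S": 19,
    "Other_18S": 19,
}

GROUP_MARKER = {
    "Prochlorococcus": "16S",
    "Synechococcus": "16S",
    "Other_16S": "16S",
    "Archaeplastida": "18S",
    "Dinoflagellata": "18S",
    "Haptophyta": "18S",
    "Stramenopiles_photosynthetic": "18S",
    "Other_18S": "18S",
}

_GENERA = {
    "Prochlorococcus": ["Prochlorococcus"],
    "Synechococcus": ["Synechococcus"],
    "Archaeplastida": ["Bathycoccus", "Micromonas", "Ostreococcus", "Chloroparvula"],
    "Dinoflagellata": ["Gyrodinium", "Karlodinium", "Prorocentrum", "Heterocapsa"],
    "Haptophyta": ["Phaeocystis", "Chrysochromulina", "Emiliania", "Prymnesium"],
    "Stramenopiles_photosynthetic": ["Pelagomonas", "Triparma", "Thalassiosira", "Florenciella"],
    "Other_16S": ["Pelagibacter", "Polaribacter", "Sulfitobacter", "Marinobacter"],
    "Other_18S": ["Oikopleura", "Acanthocystis", "Telonema", "Cafeteria"],
}

_STRAM_CLASSES = ["Pelagophyceae", "Bolidophyceae", "Mediophyceae", "Dictyochophyceae"]


@dataclass
class SyntheticTruth:
    """Planted parameters against which recovery is scored."""

    group: dict[str, str]
    persistence: dict[str, str]
    ephemeral_years: dict[str, list]
    module: dict[str, str]
    module_factors: pd.DataFrame | None
    precision_support: list[tuple[str, str]]
    niche: dict[str, tuple[float, float]]
    trait_fractions: dict = field(default_factory=dict)
    seed: int = 0

    def module_labels(self) -> pd.Series:
        return pd.Series(self.module, dtype="object")

    def support_set(self) -> set[frozenset]:
        return {frozenset(e) for e in self.precision_support}

    def to_json(self, path) -> None:
        payload = {
            "group": self.group,
            "persistence": self.persistence,
            "ephemeral_years": {a: sorted(y) for a, y in self.ephemeral_years.items()},
            "module": self.module,
            "module_factors": (
                None if self.module_factors is None
                else {
                    "index": list(map(str, self.module_factors.index)),
                    "columns": list(map(str, self.module_factors.columns)),
                    "values": self.module_factors.to_numpy().tolist(),
                }
            ),
            "precision_support": [sorted(e) for e in self.precision_support],
            "niche": {a: list(v) for a, v in self.niche.items()},
            "trait_fractions": self.trait_fractions,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        mf = d.get("module_factors")
        factors = None
        if mf is not None:
            factors = pd.DataFrame(mf["values"], index=mf["index"], columns=mf["columns"])
        return cls(
            group=d["group"],
            persistence=d["persistence"],
            ephemeral_years={a: [int(y) for y in ys] for a, ys in d["ephemeral_years"].items()},
            module=d["module"],
            module_factors=factors,
            precision_support=[tuple(e) for e in d["precision_support"]],
            niche={a: tuple(v) for a, v in d["niche"].items()},
            trait_fractions=d.get("trait_fractions", {}),
            seed=d.get("seed", 0),
        )


@dataclass
class SyntheticDataset:
    """Generated survey: per-year marker tables, metadata, taxonomy, truth."""

    tables: dict[int, dict[str, AsvTable]]
    metadata: pd.DataFrame
    taxonomy: TaxonomyMap
    truth: SyntheticTruth
    traits: pd.DataFrame | None = None

    @property
    def years(self) -> list[int]:
        return sorted(self.tables)

    def tables_by_year(self, marker: str = "both") -> dict[int, AsvTable]:
        out = {}
        for year in self.years:
            out[year] = self._year_table(year, marker)
        return out

    def _year_table(self, year: int, marker: str) -> AsvTable:
        if marker in ("16S", "18S"):
            return self.tables[year][marker]
        frames = [self.tables[year][m].data for m in ("16S", "18S")
                  if m in self.tables[year]]
        joined = pd.concat(frames, axis=1)
        return AsvTable(joined, marker="mixed")

    def combined_table(self, marker: str = "both") -> AsvTable:
        """All samples across years stacked into one table."""
        frames = [self._year_table(y, marker).data for y in self.years]
        return AsvTable(pd.concat(frames, axis=0), marker="mixed" if marker == "both" else marker)


# ---------------------------------------------------------------------------
# Precision matrices
# ---------------------------------------------------------------------------

def make_precision_matrix(
    p: int,
    structure: str = "chain",
    strength: float | tuple[float, float] = 0.45,
    density: float = 0.05,
    seed: int = 0,
    extra_edges: list[tuple[int, int]] | None = None,
    min_eig: float = 0.05,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Sparse positive-definite precision matrix with known support.

    ``chain`` plants a tridiagonal band; ``random`` plants Bernoulli(density)
    edges with random signs; ``hub`` partitions nodes into star-shaped groups
    (hub size ≈ 8) whose leaves are conditionally independent given the hub —
    the structure where marginal correlation is most misleading. Off-diagonal entries are −``strength`` (a negative
    precision entry means a *positive* partial correlation). The matrix is
    shifted and rescaled to unit diagonal while preserving support; a
    non-positive-definite request raises.
    """
    rng = np.random.default_rng(seed)
    O = np.eye(p)
    edges: list[tuple[int, int]] = []

    def draw_strength():
        if np.isscalar(strength):
            return float(strength)
        lo, hi = strength
        return float(rng.uniform(lo, hi))

    if structure == "chain":
        for i in range(p - 1):
            O[i, i + 1] = O[i + 1, i] = -draw_strength()
            edges.append((i, i + 1))
    elif structure == "hub":
        hub_size = 8
        for start in range(0, p, hub_size):
            hub = start
            for leaf in range(start + 1, min(start + hub_size, p)):
                O[hub, leaf] = O[leaf, hub] = -draw_strength()
                edges.append((hub, leaf))
    elif structure == "random":
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < density:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    O[i, j] = O[j, i] = -sign * draw_strength()
                    edges.append((i, j))
    else:
        raise ValueError(f"unknown structure {structure!r}")
    for i, j in extra_edges or []:
        if O[i, j] == 0:
            edges.append((min(i, j), max(i, j)))
        O[i, j] = O[j, i] = -draw_strength()
    w = np.linalg.eigvalsh(O).min()
    if w < min_eig:
        O = O + (min_eig - w) * np.eye(p)
        d = np.sqrt(np.diag(O))
        O = O / d[:, None] / d[None, :]
    if np.linalg.eigvalsh(O).min() <= 0:
        raise ValueError("requested precision matrix is not positive definite")
    return O, edges


def sample_compositional_counts(
    omega: np.ndarray,
    n: int,
    asv_ids=None,
    mu: np.ndarray | None = None,
    depth_mean: float = 2e4,
    depth_sigma: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Logistic-normal-multinomial counts with precision ``omega``.

    Latent z ~ N(mu, Ω⁻¹) per sample; counts ~ Multinomial(N, softmax(z))
    with lognormal sequencing depth N.
    """
    rng = np.random.default_rng(seed)
    p = omega.shape[0]
    if asv_ids is None:
        asv_ids = [f"ASV{i + 1:04d}" for i in range(p)]
    sigma = np.linalg.inv(omega)
    L = np.linalg.cholesky((sigma + sigma.T) / 2)
    z = rng.standard_normal((n, p)) @ L.T
    if mu is not None:
        z = z + np.asarray(mu)
    probs = _softmax(z)
    depths = np.maximum(rng.lognormal(np.log(depth_mean), depth_sigma, size=n), 100).astype(int)
    counts = np.vstack([rng.multinomial(depths[i], probs[i]) for i in range(n)])
    return pd.DataFrame(counts, index=[f"S{i + 1:04d}" for i in range(n)], columns=asv_ids)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Community generation
# ---------------------------------------------------------------------------

def generate_community(
    n_stations: int = 10,
    years=YEARS,
    asvs_per_group: dict | None = None,
    lat_range: tuple[float, float] = (22.0, 42.0),
    niches: dict | None = None,
    niche_amplitude: float = 2.0,
    niche_jitter: float = 1.5,
    base_sd: float = 0.7,
    graph_spec: dict | None = None,
    noise_sd: float = 1.0,
    module_spec: dict | None = None,
    ephemeral_fraction: float = 0.3,
    fraction_enrichment: dict | None = None,
    depth_mean: float = 3e4,
    depth_sigma: float = 0.3,
    depths=(15.0,),
    include_known_pair: bool = True,
    ensure_detection: bool = True,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a three-year, two-size-fraction transect community.

    Latent log-abundance of ASV a in sample s is
    ``base_a + amplitude · exp(−(lat_s − opt_a)² / 2w_a²) + fraction offset +
    loading · module factor + MVN noise`` with the MVN precision given by
    ``graph_spec`` (default: a chain over a shuffled ASV order). Counts are
    multinomial draws per marker with lognormal depth. Ephemeral ASVs are
    zeroed outside their assigned years; with ``ensure_detection`` each ASV
    scheduled present in a year is guaranteed at least one read there, so
    persistence classes round-trip exactly.
    """
    rng = np.random.default_rng(seed)
    asvs_per_group = dict(asvs_per_group or DEFAULT_ASVS_PER_GROUP)
    niches = dict(niches or DEFAULT_NICHES)
    enrichment = dict(fraction_enrichment or DEFAULT_SMALL_FRACTION_ENRICHMENT)
    graph_spec = dict(graph_spec or {"structure": "chain", "strength": 0.35})
    module_spec = dict(module_spec) if module_spec is not None else {
        "n_modules": 4, "module_size": 12, "loading": 3.0}

    asv_ids, groups, taxonomy = _build_taxonomy(asvs_per_group, include_known_pair, rng)
    p = len(asv_ids)
    group_series = pd.Series(groups, index=asv_ids)

    # per-ASV niche parameters
    niche = {}
    base = {}
    for a in asv_ids:
        opt, width = niches[group_series[a]]
        niche[a] = (float(opt + rng.normal(0, niche_jitter)),
                    float(width * rng.lognormal(0, 0.15)))
        base[a] = float(rng.normal(0, base_sd))

    # planted precision graph over all ASVs
    order = rng.permutation(p)
    extra = []
    if include_known_pair:
        ia, ib = asv_ids.index("ASV_BRAARU"), asv_ids.index("ASV_UCYNA")
        extra.append((ia, ib))
    omega_base, edge_idx = make_precision_matrix(
        p,
        structure=graph_spec.get("structure", "chain"),
        strength=graph_spec.get("strength", 0.35),
        density=graph_spec.get("density", 0.05),
        seed=int(rng.integers(2**31)),
    )
    # permute the chain over a shuffled order so support is not index-adjacent
    perm = np.eye(p)[order]
    omega = perm.T @ omega_base @ perm
    support = [(asv_ids[order[i]], asv_ids[order[j]]) for i, j in edge_idx]
    if extra:
        ia, ib = extra[0]
        s = graph_spec.get("known_pair_strength", 0.45)
        omega[ia, ib] = omega[ib, ia] = -s
        w = np.linalg.eigvalsh(omega).min()
        if w < 0.05:
            omega += (0.05 - w) * np.eye(p)
            d = np.sqrt(np.diag(omega))
            omega = omega / d[:, None] / d[None, :]
        pair = (asv_ids[ia], asv_ids[ib])
        if frozenset(pair) not in {frozenset(e) for e in support}:
            support.append(pair)
    sigma = np.linalg.inv(omega)
    chol = np.linalg.cholesky((sigma + sigma.T) / 2)

    # persistence classes
    persistence, eph_years = _assign_persistence(asv_ids, ephemeral_fraction, years, rng)

    # module assignment among persistent phytoplankton ASVs
    module_labels, loadings = _assign_modules(
        asv_ids, group_series, persistence, module_spec, rng)

    # samples and metadata
    lats = np.linspace(*lat_range, n_stations)
    sample_rows, sample_ids_by_year = [], {}
    for year in years:
        ids = []
        for si, lat in enumerate(lats):
            for d in depths:
                for frac in SIZE_FRACTIONS:
                    sid = f"S{year}.{si + 1:02d}.{int(d)}m.{frac}"
                    ids.append(sid)
                    sal = 34.82 + 0.05 * (32.3 - lat) + rng.normal(0, 0.02)
                    chl = 0.05 + 0.28 / (1 + np.exp(-(lat - 34.3) / 0.8))
                    chl *= rng.lognormal(0, 0.1)
                    sample_rows.append({
                        "sample_id": sid, "year": year, "month": CRUISE_MONTHS.get(year, "June"),
                        "latitude": float(lat), "depth": float(d), "depth_bin": depth_bin(d),
                        "size_fraction": frac, "salinity": float(sal), "chlorophyll": float(chl),
                    })
        sample_ids_by_year[year] = ids
    meta = pd.DataFrame(sample_rows).set_index("sample_id")
    meta["region"] = assign_region(meta)

    # module factors per sample (shared across years; one factor per module)
    modules = sorted({m for m in module_labels.values() if m != "none"})
    all_samples = [s for year in years for s in sample_ids_by_year[year]]
    factors = None
    if modules:
        F = rng.standard_normal((len(all_samples), len(modules)))
        # orthogonalize so planted modules are exactly independent in-sample
        F = np.linalg.qr(F - F.mean(axis=0))[0]
        F = F / F.std(axis=0)
        factors = pd.DataFrame(F, index=all_samples, columns=modules)

    # latent abundances and counts per year
    opt = np.array([niche[a][0] for a in asv_ids])
    width = np.array([niche[a][1] for a in asv_ids])
    base_vec = np.array([base[a] for a in asv_ids])
    enrich_vec = np.array([enrichment.get(group_series[a], 0.0) for a in asv_ids])
    load_vec = np.array([loadings[a] for a in asv_ids])
    marker_cols = {m: [a for a in asv_ids if GROUP_MARKER[group_series[a]] == m]
                   for m in ("16S", "18S")}
    tables: dict[int, dict[str, AsvTable]] = {}
    for year in years:
        ids = sample_ids_by_year[year]
        lat_s = meta.loc[ids, "latitude"].to_numpy()
        small = (meta.loc[ids, "size_fraction"] == SIZE_FRACTIONS[0]).to_numpy()
        z = (
            base_vec[None, :]
            + niche_amplitude * np.exp(-((lat_s[:, None] - opt[None, :]) ** 2)
                                       / (2 * width[None, :] ** 2))
            + small[:, None] * enrich_vec[None, :]
            + noise_sd * (rng.standard_normal((len(ids), p)) @ chol.T)
        )
        if factors is not None:
            for mi, m in enumerate(modules):
                members = np.array([module_labels[a] == m for a in asv_ids])
                z[:, members] += (factors.loc[ids, m].to_numpy()[:, None]
                                  * load_vec[members][None, :])
        present = np.array([
            persistence[a] == "persistent" or year in eph_years.get(a, [])
            for a in asv_ids
        ])
        tables[year] = {}
        for marker in ("16S", "18S"):
            cols = marker_cols[marker]
            if not cols:
                continue
            cidx = [asv_ids.index(a) for a in cols]
            zm = z[:, cidx].copy()
            pm = present[cidx]
            zm[:, ~pm] = -np.inf
            probs = _softmax(zm)
            probs[:, ~pm] = 0.0
            probs /= probs.sum(axis=1, keepdims=True)
            depths_n = np.maximum(
                rng.lognormal(np.log(depth_mean), depth_sigma, size=len(ids)), 500
            ).astype(int)
            counts = np.vstack([rng.multinomial(depths_n[i], probs[i]) for i in range(len(ids))])
            if ensure_detection:
                absent = (counts.sum(axis=0) == 0) & pm
                for j in np.where(absent)[0]:
                    counts[int(np.argmax(probs[:, j])), j] += 1
            tables[year][marker] = AsvTable(
                pd.DataFrame(counts, index=ids, columns=cols), marker=marker
            )

    truth = SyntheticTruth(
        group={a: group_series[a] for a in asv_ids},
        persistence=persistence,
        ephemeral_years=eph_years,
        module=module_labels,
        module_factors=factors,
        precision_support=support,
        niche=niche,
        seed=seed,
    )
    return SyntheticDataset(tables=tables, metadata=meta, taxonomy=taxonomy, truth=truth)


def _build_taxonomy(asvs_per_group, include_known_pair, rng):
    asv_ids, groups = [], []
    ranks = {}
    counter = 1
    for group, n in asvs_per_group.items():
        for _ in range(n):
            asv = f"ASV{counter:04d}"
            counter += 1
            asv_ids.append(asv)
            groups.append(group)
            ranks[asv] = _lineage_for(group, rng)
    if include_known_pair:
        asv_ids.append("ASV_BRAARU")
        groups.append("Haptophyta")
        ranks["ASV_BRAARU"] = ["Eukaryota", "Haptophyta", "Prymnesiophyceae",
                               "Coccolithales", "Braarudosphaeraceae",
                               "Braarudosphaera", "Braarudosphaera bigelowii"]
        asv_ids.append("ASV_UCYNA")
        groups.append("Other_16S")
        ranks["ASV_UCYNA"] = ["Bacteria", "Cyanobacteria", "Cyanobacteriia",
                              "Phormidesmiales", "UCYN-A",
                              "Candidatus Atelocyanobacterium",
                              "Candidatus Atelocyanobacterium thalassa"]
    tax = TaxonomyMap(ranks=ranks)
    tax.group = assign_groups(tax)
    return asv_ids, groups, tax


def _lineage_for(group, rng):
    genus = _GENERA[group][int(rng.integers(len(_GENERA[group])))]
    if group == "Prochlorococcus":
        return ["Bacteria", "Cyanobacteria", "Cyanobacteriia", "Synechococcales",
                "Cyanobiaceae", "Prochlorococcus", "Prochlorococcus marinus"]
    if group == "Synechococcus":
        return ["Bacteria", "Cyanobacteria", "Cyanobacteriia", "Synechococcales",
                "Cyanobiaceae", "Synechococcus", "Synechococcus sp."]
    if group == "Other_16S":
        return ["Bacteria", "Proteobacteria", "Alphaproteobacteria", "Pelagibacterales",
                "Pelagibacteraceae", genus, f"{genus} sp."]
    if group == "Archaeplastida":
        return ["Eukaryota", "Archaeplastida", "Chlorophyta", "Mamiellophyceae",
                "Mamiellales", genus, f"{genus} sp."]
    if group == "Dinoflagellata":
        return ["Eukaryota", "Alveolata", "Dinoflagellata", "Dinophyceae",
                "Gymnodiniales", genus, f"{genus} sp."]
    if group == "Haptophyta":
        return ["Eukaryota", "Haptophyta", "Prymnesiophyceae", "Prymnesiales",
                "Chrysochromulinaceae", genus, f"{genus} sp."]
    if group == "Stramenopiles_photosynthetic":
        cls = _STRAM_CLASSES[int(rng.integers(len(_STRAM_CLASSES)))]
        return ["Eukaryota", "Stramenopiles", "Ochrophyta", cls, genus, f"{genus} sp."]
    return ["Eukaryota", "Opisthokonta", "Metazoa", "Appendicularia", genus, f"{genus} sp."]


def _assign_persistence(asv_ids, ephemeral_fraction, years, rng):
    persistence, eph_years = {}, {}
    n_eph = int(round(ephemeral_fraction * len(asv_ids)))
    eph = set(rng.choice(len(asv_ids), size=n_eph, replace=False).tolist())
    for i, a in enumerate(asv_ids):
        if a in ("ASV_BRAARU", "ASV_UCYNA"):
            persistence[a] = "persistent"
            continue
        if i in eph:
            persistence[a] = "ephemeral"
            k = int(rng.integers(1, 3))
            eph_years[a] = sorted(rng.choice(list(years), size=k, replace=False).tolist())
        else:
            persistence[a] = "persistent"
    return persistence, eph_years


def _assign_modules(asv_ids, group_series, persistence, module_spec, rng):
    labels = {a: "none" for a in asv_ids}
    loadings = {a: 0.0 for a in asv_ids}
    n_modules = module_spec.get("n_modules", 0)
    if not n_modules:
        return labels, loadings
    size = module_spec.get("module_size", 12)
    loading = module_spec.get("loading", 3.0)
    phyto = [a for a in asv_ids
             if group_series[a] not in ("Other_16S", "Other_18S")
             and persistence[a] == "persistent"]
    rng.shuffle(phyto)
    if size is None:
        # cover every persistent phytoplankton ASV, modules as even as possible
        bounds = np.linspace(0, len(phyto), n_modules + 1).astype(int)
        chunks = [phyto[bounds[m]:bounds[m + 1]] for m in range(n_modules)]
    else:
        if n_modules * size > len(phyto):
            size = len(phyto) // n_modules
        chunks = [phyto[m * size:(m + 1) * size] for m in range(n_modules)]
    for m, chunk in enumerate(chunks):
        for a in chunk:
            labels[a] = f"M{m + 1}"
            loadings[a] = loading * float(rng.lognormal(0, 0.1))
    return labels, loadings


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

#: response → (location, scale); NCP may go negative (net heterotrophy),
#: POC/PON are concentrations and get a trace-level floor after scaling.
TRAIT_SCALES = {"NCP": (12.0, 8.0), "POC": (5.0, 1.1), "PON": (0.8, 0.17)}


def generate_traits(
    dataset: SyntheticDataset,
    fractions: dict[str, float],
    residual_fraction: float,
    responses=("NCP", "POC", "PON"),
    fixed_effects: dict | None = None,
    exact: bool = True,
    seed: int = 0,
    samples=None,
) -> pd.DataFrame:
    """Traits whose variance decomposes over group kernels in set fractions.

    For each response, y = Σ_g u_g + ε with u_g drawn from N(0, K_g) (the
    Bray–Curtis Gower kernel of the group, built from the generated community)
    and ε white noise; with ``exact`` each component is rescaled so its
    empirical variance share hits the target exactly. ``fixed_effects``
    optionally adds per-year offsets before the random part. Each response is
    affinely mapped to a realistic location/scale (which leaves variance
    fractions invariant).
    """
    total = sum(fractions.values()) + residual_fraction
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"fractions plus residual must sum to 1, got {total}")
    if any(f < 0 for f in fractions.values()) or residual_fraction < 0:
        raise ValueError("fractions must be non-negative")
    rng = np.random.default_rng(seed)
    table = dataset.combined_table()
    if samples is not None:
        table = table.subset_samples(samples)
    sample_ids = table.sample_ids
    n = len(sample_ids)
    kernels = {}
    for group in fractions:
        asvs = [a for a, g in dataset.truth.group.items() if g == group]
        kernels[group] = build_group_kernel(table, asvs, name=group).K
    out = {}
    for resp in responses:
        parts = []
        for group, f in fractions.items():
            K = kernels[group]
            vals, vecs = np.linalg.eigh(K)
            vals = np.clip(vals, 0, None)
            u = vecs @ (np.sqrt(vals) * rng.standard_normal(n))
            parts.append((f, u))
        eps = rng.standard_normal(n)
        parts.append((residual_fraction, eps))
        y = np.zeros(n)
        for f, u in parts:
            if f == 0:
                continue
            sd = u.std(ddof=1)
            if exact and sd > 0:
                u = u / sd * np.sqrt(f)
            else:
                u = u * np.sqrt(f)
            y = y + u
        if fixed_effects:
            year = dataset.metadata.loc[sample_ids, "year"]
            offsets = year.map(fixed_effects.get("year", {})).fillna(0.0).to_numpy()
            y = y + offsets
        loc, scale = TRAIT_SCALES.get(resp, (0.0, 1.0))
        vals = loc + scale * y
        if resp in ("POC", "PON"):  # concentrations: floor at a trace level
            vals = np.maximum(vals, 0.01 * loc)
        out[resp] = vals
    traits = pd.DataFrame(out, index=sample_ids)
    dataset.truth.trait_fractions = {
        resp: {**fractions, "residual": residual_fraction} for resp in responses
    }
    dataset.traits = traits
    return traits


def generate_module_trait(
    dataset: SyntheticDataset,
    module: str,
    noise_sd: float = 0.5,
    name: str = "NCP",
    seed: int = 0,
) -> pd.Series:
    """A trait driven by one planted module's latent factor plus white noise
    (expected correlation with the module eigengene ≈ 1/√(1 + noise_sd²))."""
    factors = dataset.truth.module_factors
    if factors is None or module not in factors.columns:
        raise KeyError(f"no planted factor for module {module!r}")
    rng = np.random.default_rng(seed)
    f = factors[module]
    loc, scale = TRAIT_SCALES.get(name, (0.0, 1.0))
    return pd.Series(loc + scale * (f + noise_sd * rng.standard_normal(len(f))),
                     index=f.index, name=name)


# ---------------------------------------------------------------------------
# Fixture export / load
# ---------------------------------------------------------------------------

def export_fixture(dataset: SyntheticDataset, out_dir, force: bool = False) -> None:
    """Write the dataset as a canonical TSV/JSON fixture tree."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    for year, by_marker in dataset.tables.items():
        for marker, table in by_marker.items():
            table.data.to_csv(out / f"counts_{year}_{marker}.tsv", sep="\t")
    tax_rows = [
        {"Feature ID": a, "Taxon": ";".join(ranks)}
        for a, ranks in dataset.taxonomy.ranks.items()
    ]
    pd.DataFrame(tax_rows).to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    dataset.metadata.to_csv(out / "metadata.tsv", sep="\t")
    if dataset.traits is not None:
        dataset.traits.to_csv(out / "traits.tsv", sep="\t")
    dataset.truth.to_json(out / "truth.json")


def load_fixture(fixture_dir) -> SyntheticDataset:
    """Read back a fixture tree written by :func:`export_fixture`."""
    from planktonet.data_model import read_asv_table, read_metadata, read_taxonomy, read_traits

    d = Path(fixture_dir)
    tables: dict[int, dict[str, AsvTable]] = {}
    for f in sorted(d.glob("counts_*_*.tsv")):
        _, year, marker = f.stem.split("_")
        tables.setdefault(int(year), {})[marker] = read_asv_table(f, marker=marker)
    meta = read_metadata(d / "metadata.tsv")
    taxonomy = read_taxonomy(d / "taxonomy.tsv")
    truth = SyntheticTruth.from_json(d / "truth.json")
    traits = read_traits(d / "traits.tsv") if (d / "traits.tsv").exists() else None
    return SyntheticDataset(tables=tables, metadata=meta, taxonomy=taxonomy,
                            truth=truth, traits=traits)
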