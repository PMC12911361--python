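"""Core data types and ingest operations for ASV survey data.

The universal currency is the :class:`AsvTable`: a samples × ASVs matrix of
non-negative integer counts for one marker gene (16S or 18S). Everything
downstream — rarefaction, relative abundance, persistence classification,
taxon-group assignment and biogeographic region labels — operates on or
annotates these tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MARKERS = ("16S", "18S", "mixed")

#: The six phytoplankton-containing groups modeled throughout, plus background.
GROUPS = (
    "Prochlorococcus",
    "Synechococcus",
    "Archaeplastida",
    "Dinoflagellata",
    "Haptophyta",
    "Stramenopiles_photosynthetic",
    "Other",
)

#: Stramenopile classes retained as photosynthetic (diatoms and relatives).
PHOTOSYNTHETIC_STRAMENOPILE_CLASSES = frozenset(
    {
        "coscinodiscophyceae",
        "bacillariophyceae",
        "mediophyceae",
        "chrysophyceae",
        "bolidophyceae",
        "dictyochophyceae",
        "pelagophyceae",
        "pinguiophyceae",
    }
)

DEPTH_BINS = ((0.0, 15.0), (45.0, 75.0), (90.0, 125.0))
DEPTH_BIN_LABELS = ("0-15", "45-75", "90-125")

REGIONS = ("NPSG", "STZ", "NTZ", "unassigned")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AsvTable:
    """Samples × ASVs count matrix for one marker gene.

    Parameters
    ----------
    data
        DataFrame with sample ids as index, ASV ids as columns, and
        non-negative integer counts as values.
    marker
        ``"16S"``, ``"18S"`` or ``"mixed"`` (markers concatenated over shared
        samples, as used for co-occurrence networks).
    """

    data: pd.DataFrame
    marker: str = "mixed"

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValidationError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV id(s): {dupes}")
        if self.data.shape[0] == 0:
            raise ValidationError("no samples")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(self.data)
            raise ValidationError(f"non-numeric count at {bad}")
        if np.isnan(values.astype(float)).any():
            bad = _first_bad_cell(self.data, np.isnan(values.astype(float)))
            raise ValidationError(f"missing count at {bad}")
        if (values < 0).any():
            bad = _first_bad_cell(self.data, values < 0)
            raise ValidationError(f"negative count at {bad}")
        self.data = self.data.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def subset_asvs(self, asv_ids) -> "AsvTable":
        keep = [a for a in asv_ids if a in self.data.columns]
        return AsvTable(self.data[keep], marker=self.marker)

    def subset_samples(self, sample_ids) -> "AsvTable":
        keep = [s for s in sample_ids if s in self.data.index]
        return AsvTable(self.data.loc[keep], marker=self.marker)


def _first_bad_cell(df: pd.DataFrame, mask: np.ndarray) -> str:
    i, j = np.argwhere(mask)[0]
    return f"(sample {df.index[i]!r}, ASV {df.columns[j]!r})"


def _first_non_numeric(df: pd.DataFrame) -> str:
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            return f"(sample {df.index[bad.argmax()]!r}, ASV {col!r})"
    return "(unknown cell)"


def read_asv_table(path, marker: str = "mixed", orientation: str = "auto") -> AsvTable:
    """Read a delimited count table (TSV or CSV, sniffed from the header row).

    The canonical orientation is samples as rows. With ``orientation="auto"``
    a table whose row labels look like ASV ids while the column labels look
    like sample ids is transposed; ``"samples-rows"`` / ``"samples-columns"``
    force the layout.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError("no samples")
    if orientation == "samples-columns":
        df = df.T
    elif orientation == "auto" and _looks_like_asv_axis(df.index) and not _looks_like_asv_axis(df.columns):
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        raise ValidationError(f"non-numeric count at {_first_bad_cell(df, bad.to_numpy())}")
    return AsvTable(numeric.fillna(np.nan), marker=marker)


def _sniff_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _looks_like_asv_axis(labels) -> bool:
    lowered = [str(x).lower() for x in labels[: min(len(labels), 20)]]
    return sum(s.startswith(("asv", "otu", "sv", "feature")) for s in lowered) > len(lowered) / 2


def write_asv_table(table: AsvTable, path) -> None:
    table.data.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Rarefaction and relative abundance
# ---------------------------------------------------------------------------

def rarefy(table: AsvTable, depth: int | None = None, seed: int = 0) -> AsvTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (with a warning naming
    them). ``depth=None`` uses the minimum sample total, so no sample is
    dropped. The draw is multivariate hypergeometric, so an ASV absent from a
    sample can never appear after rarefaction.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    if (totals < depth).all():
        raise ValueError(f"depth {depth} exceeds every sample total (max {int(totals.max())})")
    dropped = totals.index[totals < depth].tolist()
    if dropped:
        warnings.warn(f"rarefy: dropped {len(dropped)} sample(s) below depth {depth}: {dropped}")
    kept = table.data.loc[totals >= depth]
    rng = np.random.default_rng(seed)
    out = np.empty(kept.shape, dtype=np.int64)
    for i, (_, row) in enumerate(kept.iterrows()):
        counts = row.to_numpy()
        if counts.sum() == depth:
            out[i] = counts
        else:
            out[i] = rng.multivariate_hypergeometric(counts, depth)
    return AsvTable(pd.DataFrame(out, index=kept.index, columns=kept.columns), marker=table.marker)


def relative_abundance(table: AsvTable | pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts to proportions (each row sums to 1)."""
    df = table.data if isinstance(table, AsvTable) else table
    totals = df.sum(axis=1)
    if (totals <= 0).any():
        zero = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero-total sample(s): {zero}")
    return df.div(totals, axis=0)


# ---------------------------------------------------------------------------
# Taxonomy and group assignment
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyMap:
    """ASV → ranked lineage plus derived phytoplankton group.

    ``ranks`` maps each ASV id to its ordered lineage strings (domain → species
    epithet where available). ``group`` is filled by :func:`assign_groups` and
    is a deterministic function of the ranks.
    """

    ranks: dict[str, list[str]]
    group: pd.Series | None = None

    def lineage(self, asv_id: str) -> list[str]:
        return self.ranks.get(asv_id, [])

    def group_of(self, asv_id: str) -> str:
        if self.group is None:
            raise ValueError("groups not assigned; call assign_groups first")
        return self.group.get(asv_id, "Other")

    def asvs_in_group(self, group: str) -> list[str]:
        if self.group is None:
            raise ValueError("groups not assigned; call assign_groups first")
        return list(self.group.index[self.group == group])


def read_taxonomy(path) -> TaxonomyMap:
    """Read a two-column taxonomy table (``Feature ID<TAB>Taxon``).

    The Taxon column holds semicolon-delimited ranks, optionally with
    rank-prefix decorations (``d__Bacteria`` style), which are stripped.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("taxonomy file needs >= 2 columns (id, lineage)")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise ValidationError(f"duplicate taxonomy id(s): {ids[ids.duplicated()].tolist()}")
    ranks = {}
    for asv, lineage in zip(ids, df.iloc[:, 1].astype(str)):
        parts = [p.strip() for p in lineage.split(";")]
        parts = [p.split("__", 1)[1] if "__" in p else p for p in parts]
        ranks[asv] = [p for p in parts if p]
    tax = TaxonomyMap(ranks=ranks)
    tax.group = assign_groups(tax)
    return tax


def assign_groups(taxonomy: TaxonomyMap) -> pd.Series:
    """Map each lineage to one of the six phytoplankton groups or ``Other``.

    Cyanobacterial genera (*Prochlorococcus*, *Synechococcus*) match at any
    rank of the 16S lineage; the eukaryotic divisions Archaeplastida,
    Dinoflagellata and Haptophyta match at division/phylum level; Stramenopiles
    are kept only when the class is one of the photosynthetic (diatom and
    related) classes. Everything else, including missing entries, is ``Other``.
    """
    labels = {}
    for asv, ranks in taxonomy.ranks.items():
        lowered = [r.lower() for r in ranks]
        labels[asv] = _group_from_ranks(lowered)
    return pd.Series(labels, name="group", dtype="object")


def _group_from_ranks(lowered: list[str]) -> str:
    joined = set(lowered)
    if any("prochlorococcus" in r for r in lowered):
        return "Prochlorococcus"
    if any("synechococcus" in r for r in lowered):
        return "Synechococcus"
    if "archaeplastida" in joined or "chlorophyta" in joined:
        return "Archaeplastida"
    if "dinoflagellata" in joined or "dinophyceae" in joined:
        return "Dinoflagellata"
    if "haptophyta" in joined:
        return "Haptophyta"
    if "stramenopiles" in joined or "ochrophyta" in joined:
        if joined & PHOTOSYNTHETIC_STRAMENOPILE_CLASSES:
            return "Stramenopiles_photosynthetic"
    return "Other"


# ---------------------------------------------------------------------------
# Persistence classification
# ---------------------------------------------------------------------------

@dataclass
class PersistenceLabel:
    """Per-ASV persistence call with the supporting years of detection.

    An ASV is *persistent* when detected (count > 0 in at least one sample) in
    all three survey years, *ephemeral* when detected in one or two.
    """

    labels: pd.Series
    years_detected: dict[str, frozenset] = field(default_factory=dict)

    def persistent_asvs(self) -> list[str]:
        return list(self.labels.index[self.labels == "persistent"])

    def ephemeral_asvs(self) -> list[str]:
        return list(self.labels.index[self.labels == "ephemeral"])

    def to_json(self, path) -> None:
        payload = {
            "labels": self.labels.to_dict(),
            "years_detected": {a: sorted(y) for a, y in self.years_detected.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def classify_persistence(tables_by_year: dict) -> PersistenceLabel:
    """Classify ASVs as persistent (all three years) or ephemeral (1–2 years).

    ASVs with zero counts everywhere are excluded from the labels with a
    warning — presence cannot be evaluated for them.
    """
    if len(tables_by_year) != 3:
        raise ValueError(f"need exactly three years, got {sorted(tables_by_year)}")
    detected: dict[str, set] = {}
    all_asvs: list[str] = []
    seen = set()
    for year, table in tables_by_year.items():
        present = table.data.columns[(table.data > 0).any(axis=0)]
        for asv in table.asv_ids:
            if asv not in seen:
                seen.add(asv)
                all_asvs.append(asv)
        for asv in present:
            detected.setdefault(asv, set()).add(year)
    never = [a for a in all_asvs if a not in detected]
    if never:
        warnings.warn(f"classify_persistence: {len(never)} ASV(s) absent in every year excluded")
    labels = {
        asv: ("persistent" if len(years) == 3 else "ephemeral")
        for asv, years in detected.items()
    }
    ordered = [a for a in all_asvs if a in labels]
    return PersistenceLabel(
        labels=pd.Series(labels, dtype="object").reindex(ordered),
        years_detected={a: frozenset(y) for a, y in detected.items()},
    )


# ---------------------------------------------------------------------------
# Sample metadata, traits, and region assignment
# ---------------------------------------------------------------------------

METADATA_COLUMNS = (
    "year",
    "month",
    "latitude",
    "depth",
    "depth_bin",
    "size_fraction",
    "salinity",
    "chlorophyll",
)


def depth_bin(depth: float) -> str:
    """Bin a depth (m) into the three sampled strata; nearest bin for gaps."""
    for (lo, hi), label in zip(DEPTH_BINS, DEPTH_BIN_LABELS):
        if lo <= depth <= hi:
            return label
    centers = [(lo + hi) / 2 for lo, hi in DEPTH_BINS]
    return DEPTH_BIN_LABELS[int(np.argmin([abs(depth - c) for c in centers]))]


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index = df.index.astype(str)
    if "depth_bin" not in df.columns and "depth" in df.columns:
        df["depth_bin"] = df["depth"].map(depth_bin)
    return df


def read_traits(path) -> pd.DataFrame:
    """Read sample → (NCP, POC, PON) trait table; missing values allowed."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index = df.index.astype(str)
    for col in ("POC", "PON"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValidationError(f"negative {col} value(s)")
    return df


def assign_region(
    meta: pd.DataFrame,
    salinity_cut: float = 34.82,
    chl_cut: float = 0.15,
    front_latitudes: dict | None = None,
) -> pd.Series:
    """Assign each sample to NPSG, STZ or NTZ from hydrography or front latitudes.

    NPSG lies south of the salinity front (salinity above ``salinity_cut``);
    within the transition zone, the chlorophyll front (``chl_cut``) separates
    the southern (STZ, below the cut) from the northern (NTZ, at or above)
    subregion. When per-sample salinity/chlorophyll are missing, interpolated
    front latitudes per cruise year (``front_latitudes[year] = (salinity_front,
    chlorophyll_front)``) are used instead; with neither available the sample
    is ``unassigned`` with a warning.
    """
    regions = {}
    n_missing = 0
    for sample, row in meta.iterrows():
        sal = row.get("salinity", np.nan)
        chl = row.get("chlorophyll", np.nan)
        if np.isfinite(sal) and np.isfinite(chl):
            regions[sample] = _region_from_hydrography(sal, chl, salinity_cut, chl_cut)
            continue
        year = row.get("year")
        lat = row.get("latitude", np.nan)
        if front_latitudes and year in front_latitudes and np.isfinite(lat):
            sal_front, chl_front = front_latitudes[year]
            if lat < sal_front:
                regions[sample] = "NPSG"
            elif lat < chl_front:
                regions[sample] = "STZ"
            else:
                regions[sample] = "NTZ"
        else:
            regions[sample] = "unassigned"
            n_missing += 1
    if n_missing:
        warnings.warn(f"assign_region: {n_missing} sample(s) unassigned (no hydrography or fronts)")
    return pd.Series(regions, name="region", dtype="object").reindex(meta.index)


def _region_from_hydrography(sal, chl, salinity_cut, chl_cut) -> str:
    if sal > salinity_cut:
        return "NPSG"
    return "NTZ" if chl >= chl_cut else "STZ"
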