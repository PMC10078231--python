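"""Community abundance tables, sample metadata, taxon filters and salinity bins.

The central container is :class:`CommunityMatrix`, a taxa x samples table of
per-sample relative abundances together with the derived presence-absence
view that every downstream stage (pairwise testing, confound filtering,
network construction, matrix randomization) consumes.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("cooxnet")

#: Environmental variables required for confound classification.
ENV_VARIABLES = ("salinity", "temperature", "ph", "dissolved_oxygen", "redox")

#: Columns a metadata table must provide.
METADATA_COLUMNS = ("sample_id", "lake_id", "date", "x", "y") + ENV_VARIABLES

#: Salinity-bin edges in percent mass: [0, 2.5) low, [2.5, 5) intermediate,
#: [5, inf) high.  The bins are half-open so that every non-negative salinity
#: maps to exactly one label.
SALINITY_BIN_EDGES = (2.5, 5.0)
SALINITY_BINS = ("low", "intermediate", "high")


class CommunityDataError(ValueError):
    """Raised for malformed abundance tables or metadata."""


@dataclass(frozen=True)
class SampleMetadata:
    """One sample's location, date and environmental measurements.

    Salinity is percent mass (0-40 over the gradient studied), temperature
    degrees C, dissolved oxygen mg/L, redox mV; pH is unitless.  Missing
    environmental values are allowed (NaN) — samples missing a variable are
    dropped from the tests that need it, not from the dataset.
    """

    sample_id: str
    lake_id: str
    date: _dt.date | None
    x: float
    y: float
    salinity: float
    temperature: float
    ph: float
    dissolved_oxygen: float
    redox: float

    def __post_init__(self) -> None:
        if np.isfinite(self.salinity) and self.salinity < 0:
            raise CommunityDataError(
                f"sample {self.sample_id!r}: salinity must be non-negative, "
                f"got {self.salinity}"
            )

    def env_value(self, variable: str) -> float:
        if variable not in ENV_VARIABLES:
            raise KeyError(variable)
        return getattr(self, variable)


@dataclass
class CommunityMatrix:
    """Taxa x samples relative abundances plus a presence-absence view.

    ``presence[i, s] == 1`` iff ``rel_abundance[i, s] > 0``; there is no
    separate detection cutoff.  Per-sample relative abundances sum to at
    most 1 (within tolerance); columns of an all-relative input are kept
    exactly as given.
    """

    taxa: list[str]
    samples: list[str]
    rel_abundance: np.ndarray

    def __post_init__(self) -> None:
        self.rel_abundance = np.asarray(self.rel_abundance, dtype=float)
        if self.rel_abundance.shape != (len(self.taxa), len(self.samples)):
            raise CommunityDataError(
                f"matrix shape {self.rel_abundance.shape} inconsistent with "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise CommunityDataError("duplicate taxon ids")
        if len(set(self.samples)) != len(self.samples):
            raise CommunityDataError("duplicate sample ids")
        if np.any(self.rel_abundance < 0):
            raise CommunityDataError("negative abundances")
        colsum = self.rel_abundance.sum(axis=0)
        if np.any(colsum > 1.0 + 1e-6):
            raise CommunityDataError(
                "per-sample relative abundances exceed 1; pass counts "
                "through read_abundance_table or normalize first"
            )

    @property
    def presence(self) -> np.ndarray:
        """Binary taxa x samples matrix (int8)."""
        return (self.rel_abundance > 0).astype(np.int8)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def occurrence_counts(self) -> np.ndarray:
        """Number of samples each taxon is present in."""
        return self.presence.sum(axis=1)

    def subset_samples(self, sample_ids: list[str]) -> "CommunityMatrix":
        """Restrict to the given samples (order preserved as given)."""
        idx = {s: k for k, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise CommunityDataError(f"unknown sample ids: {missing[:5]}")
        cols = [idx[s] for s in sample_ids]
        return CommunityMatrix(
            taxa=list(self.taxa),
            samples=list(sample_ids),
            rel_abundance=self.rel_abundance[:, cols].copy(),
        )

    def subset_taxa(self, taxon_ids: list[str]) -> "CommunityMatrix":
        idx = {t: k for k, t in enumerate(self.taxa)}
        rows = [idx[t] for t in taxon_ids]
        return CommunityMatrix(
            taxa=list(taxon_ids),
            samples=list(self.samples),
            rel_abundance=self.rel_abundance[rows, :].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rel_abundance, index=self.taxa, columns=self.samples)


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def _normalize_counts(values: np.ndarray, taxa: list[str], samples: list[str],
                      assume_counts: bool | None) -> np.ndarray:
    colsum = values.sum(axis=0)
    zero = np.where(colsum == 0)[0]
    if zero.size:
        raise CommunityDataError(
            f"sample with zero total: {samples[zero[0]]!r}"
        )
    if assume_counts is None:
        # Heuristic: any column summing past 1.5 cannot be relative abundances.
        assume_counts = bool(np.any(colsum > 1.5))
    if assume_counts:
        values = values / colsum
    return values


def read_abundance_table(path, *, taxa_as_rows: bool = True,
                         assume_counts: bool | None = None) -> CommunityMatrix:
    """Read a TSV abundance table into a :class:`CommunityMatrix`.

    The table has taxon rows and sample columns (set ``taxa_as_rows=False``
    for the transpose); ``#`` comment lines are skipped.  Counts are
    auto-detected (any column sum > 1.5) and converted to per-sample
    relative abundances; ``assume_counts`` overrides the heuristic.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if not taxa_as_rows:
        df = df.T
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise CommunityDataError(f"duplicate taxon id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise CommunityDataError(f"duplicate sample id {dup!r} in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for taxon, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise CommunityDataError(
                        f"non-numeric cell at taxon {taxon!r}, "
                        f"sample {sample!r}: {cell!r}"
                    ) from None
        raise
    taxa = [str(t) for t in df.index]
    samples = [str(s) for s in df.columns]
    values = _normalize_counts(values, taxa, samples, assume_counts)
    return CommunityMatrix(taxa=taxa, samples=samples, rel_abundance=values)


def write_abundance_table(m: CommunityMatrix, path) -> None:
    """Write relative abundances as TSV (taxon rows, sample columns)."""
    m.to_frame().to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path) -> list[SampleMetadata]:
    """Read a sample-metadata TSV into a list of :class:`SampleMetadata`.

    Requires the columns ``sample_id, lake_id, date, x, y, salinity,
    temperature, ph, dissolved_oxygen, redox``.  Dates must be ISO
    (YYYY-MM-DD); environmental cells may be empty (treated as missing).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str,
                                                         "lake_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise CommunityDataError(f"metadata missing required column(s): {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise CommunityDataError(f"duplicate sample_id {dup!r}")
    records = []
    for _, row in df.iterrows():
        raw_date = row["date"]
        if pd.isna(raw_date):
            date = None
        else:
            try:
                date = _dt.date.fromisoformat(str(raw_date))
            except ValueError:
                raise CommunityDataError(
                    f"sample {row['sample_id']!r}: unparseable date {raw_date!r}"
                ) from None
        records.append(SampleMetadata(
            sample_id=str(row["sample_id"]),
            lake_id=str(row["lake_id"]),
            date=date,
            x=float(row["x"]),
            y=float(row["y"]),
            salinity=float(row["salinity"]),
            temperature=float(row["temperature"]),
            ph=float(row["ph"]),
            dissolved_oxygen=float(row["dissolved_oxygen"]),
            redox=float(row["redox"]),
        ))
    return records


def write_metadata(meta: list[SampleMetadata], path) -> None:
    rows = []
    for s in meta:
        rows.append({
            "sample_id": s.sample_id, "lake_id": s.lake_id,
            "date": s.date.isoformat() if s.date else "",
            "x": s.x, "y": s.y, "salinity": s.salinity,
            "temperature": s.temperature, "ph": s.ph,
            "dissolved_oxygen": s.dissolved_oxygen, "redox": s.redox,
        })
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def read_taxonomy(path) -> dict[str, str]:
    """Read a 2-column taxon_id -> group_label TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", header=0)
    if df.shape[1] < 2:
        raise CommunityDataError("taxonomy table needs two columns")
    return {str(t): str(g) for t, g in zip(df.iloc[:, 0], df.iloc[:, 1])}


# --------------------------------------------------------------------------
# Filtering and binning
# --------------------------------------------------------------------------

def min_occurrence_count(n_samples: int, min_occ_frac: float) -> int:
    """Smallest integer occurrence count strictly greater than frac * n.

    An "occurrences > 5%" rule over 116 samples therefore requires presence
    in at least 6 samples.
    """
    return int(math.floor(min_occ_frac * n_samples + 1e-9)) + 1


def filter_taxa(m: CommunityMatrix, *, min_occ_frac: float = 0.05,
                min_max_abund: float = 0.001,
                apply_occurrence: bool = True) -> CommunityMatrix:
    """Drop rare taxa before pairwise testing.

    A taxon is kept iff its occurrence count meets the >``min_occ_frac``
    rule (skipped when ``apply_occurrence`` is false, as in the per-bin
    subnetwork analyses) and its maximum relative abundance over samples
    strictly exceeds ``min_max_abund``.
    """
    if not (0 <= min_occ_frac < 1 and 0 <= min_max_abund < 1):
        raise CommunityDataError("thresholds must lie in [0, 1)")
    max_abund = m.rel_abundance.max(axis=1) if m.n_samples else np.zeros(m.n_taxa)
    keep = max_abund > min_max_abund
    if apply_occurrence:
        required = min_occurrence_count(m.n_samples, min_occ_frac)
        keep &= m.occurrence_counts() >= required
    kept = [t for t, k in zip(m.taxa, keep) if k]
    if not kept:
        warnings.warn("all taxa removed by filters; returning empty matrix",
                      stacklevel=2)
        return CommunityMatrix(taxa=[], samples=list(m.samples),
                               rel_abundance=np.zeros((0, m.n_samples)))
    return m.subset_taxa(kept)


def assign_salinity_bin(salinity: float) -> str:
    """Map a salinity (percent mass) to ``low``/``intermediate``/``high``.

    Half-open intervals: [0, 2.5) low, [2.5, 5) intermediate, [5, inf) high.
    """
    if not np.isfinite(salinity) or salinity < 0:
        raise CommunityDataError(f"invalid salinity {salinity}")
    if salinity < 0.1:
        logger.warning("salinity %.4g below the gradient minimum 0.1; "
                       "assigned to 'low'", salinity)
    if salinity < SALINITY_BIN_EDGES[0]:
        return "low"
    if salinity < SALINITY_BIN_EDGES[1]:
        return "intermediate"
    return "high"


def split_by_salinity_bin(meta: list[SampleMetadata]) -> dict[str, list[str]]:
    """Sample ids per salinity bin, in input order."""
    out: dict[str, list[str]] = {b: [] for b in SALINITY_BINS}
    for s in meta:
        if np.isfinite(s.salinity):
            out[assign_salinity_bin(s.salinity)].append(s.sample_id)
    return out
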