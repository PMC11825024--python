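"""Domain containers, CSV I/O, validation, and covariate standardization.

The observed data unit is a *region*: one forest area with its own camera-trap
array. Within a region, ``y[i, j]`` counts the number of days species ``i`` was
detected at site ``j`` out of ``K[j]`` active camera-days. Region-level
covariates (human density, forest cover, patch gyration, NDVI, precipitation
CV, settlement distance, sampled area, continent) live in a
:class:`CovariateTable`; site-level covariates (settlement distance, camera
trigger class) live on each :class:`Site`.

CSV layout (UTF-8, header row, '.' decimal separator):

* ``detections.csv`` — region_id, site_id, species_id, days_detected,
  days_active; one row per region x site x species with >= 1 detection
  (absent rows imply y = 0).
* ``region_covariates.csv`` — region_id, continent, hden, settl_m, forest_ha,
  psize_m, ndvi, cvprec, area_km2, lat, lon.
* ``site_covariates.csv`` — region_id, site_id, settl_m, cam_trigger
  (fast|moderate), days_active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTINENTS",
    "CAM_TRIGGER_CLASSES",
    "FormatError",
    "ValidationError",
    "Site",
    "Region",
    "StudyDataset",
    "CovariateTable",
    "AugmentedRegion",
    "AugmentedDetectionArray",
    "StandardizationRecord",
    "read_study",
    "write_study",
    "augment",
    "standardize",
    "standardize_covariates",
    "standardize_site_settlement",
]

CONTINENTS = ("Afrotropics", "Neotropics", "IndoMalayan")
CAM_TRIGGER_CLASSES = ("fast", "moderate")

#: region covariate columns that are continuous and get z-scored
CONTINUOUS_COVARIATES = (
    "hden",
    "settl_m",
    "forest_ha",
    "psize_m",
    "ndvi",
    "cvprec",
    "area_km2",
)


class FormatError(ValueError):
    """A CSV is missing required columns or is otherwise malformed."""


class ValidationError(ValueError):
    """Input rows violate a dataset invariant; message names offenders."""


@dataclass(frozen=True)
class Site:
    site_id: str
    effort: int  # K_j, active camera-days
    settl_m: float  # distance to nearest settlement, metres
    cam_trigger: str  # "fast" (reference) or "moderate"

    def __post_init__(self) -> None:
        if self.cam_trigger not in CAM_TRIGGER_CLASSES:
            raise ValidationError(
                f"site {self.site_id!r}: unknown cam_trigger {self.cam_trigger!r}"
            )


@dataclass
class Region:
    """Detection data for one region: species x site day counts."""

    region_id: str
    continent: str
    sites: list[Site]
    species_ids: list[str]
    y: np.ndarray  # (n_species, n_sites) integer day counts

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def effort(self) -> np.ndarray:
        """K_j per site, camera-days."""
        return np.array([s.effort for s in self.sites], dtype=float)

    def validate(self) -> None:
        if self.continent not in CONTINENTS:
            raise ValidationError(
                f"region {self.region_id!r}: unknown continent {self.continent!r}"
            )
        if self.n_sites < 1:
            raise ValidationError(f"region {self.region_id!r}: no sites")
        y = np.asarray(self.y)
        if y.shape != (self.n_species, self.n_sites):
            raise ValidationError(
                f"region {self.region_id!r}: y shape {y.shape} != "
                f"({self.n_species}, {self.n_sites})"
            )
        if len(set(self.species_ids)) != self.n_species:
            raise ValidationError(f"region {self.region_id!r}: duplicate species ids")
        k = self.effort
        if np.any(k < 1):
            bad = [s.site_id for s, ki in zip(self.sites, k) if ki < 1]
            raise ValidationError(
                f"region {self.region_id!r}: sites with effort < 1 day: {bad}"
            )
        if np.any(y < 0):
            raise ValidationError(f"region {self.region_id!r}: negative day counts")
        over = np.argwhere(y > k[None, :])
        if over.size:
            cells = [
                (self.region_id, self.sites[j].site_id, self.species_ids[i])
                for i, j in over
            ]
            raise ValidationError(f"days_detected exceeds days_active at cells: {cells}")
        silent = [sid for sid, row in zip(self.species_ids, y) if row.sum() < 1]
        if silent:
            raise ValidationError(
                f"region {self.region_id!r}: species with all-zero histories "
                f"listed as detected: {silent}"
            )


@dataclass
class StudyDataset:
    """Validated multi-region detection data (the observed study)."""

    regions: list[Region]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate region ids")
        for r in self.regions:
            r.validate()

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    @property
    def n_detected(self) -> np.ndarray:
        """n_r: number of detected species per region."""
        return np.array([r.n_species for r in self.regions], dtype=int)

    def region(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)


@dataclass
class CovariateTable:
    """Region-level covariates as a DataFrame, one row per region.

    Columns: region_id, continent, hden, settl_m, forest_ha, psize_m, ndvi,
    cvprec, area_km2, and optionally lat/lon (used only for spatial checks).
    """

    df: pd.DataFrame

    REQUIRED = ("region_id", "continent") + CONTINUOUS_COVARIATES

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise FormatError(f"region covariates missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        bad = ~self.df["continent"].isin(CONTINENTS)
        if bad.any():
            raise ValidationError(
                f"unknown continent labels: {sorted(self.df.loc[bad, 'continent'])}"
            )
        vals = self.df[list(CONTINUOUS_COVARIATES)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite region covariate values")
        for col in ("hden", "forest_ha", "psize_m"):
            if (self.df[col] < 0).any():
                raise ValidationError(f"negative values in {col}")

    @property
    def region_ids(self) -> list[str]:
        return list(self.df["region_id"])

    def continent_dummies(self) -> pd.DataFrame:
        """0/1 columns neotropics, indo_malayan (Afrotropics = reference)."""
        d = pd.DataFrame(
            {
                "neotropics": (self.df["continent"] == "Neotropics").astype(float),
                "indo_malayan": (self.df["continent"] == "IndoMalayan").astype(float),
            }
        )
        assert (d.sum(axis=1) <= 1).all()
        return d

    def reindex(self, region_ids: Sequence[str]) -> "CovariateTable":
        df = self.df.set_index("region_id").loc[list(region_ids)].reset_index()
        return CovariateTable(df)


@dataclass(frozen=True)
class StandardizationRecord:
    """Constants of one covariate's z-scoring, for back-transformation."""

    name: str
    mean: float
    sd: float  # sample SD, n-1 denominator
    scope: str = "region"  # "region" or "site"

    def apply(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def invert(self, z) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


def standardize(
    values: Iterable[float], name: str = "x", scope: str = "region"
) -> tuple[np.ndarray, StandardizationRecord]:
    """Z-score ``values`` to mean 0, sample SD 1 (n-1 denominator)."""
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    if x.size < 2:
        raise ValidationError(f"{name}: need >= 2 values to standardize")
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValidationError(f"{name}: constant covariate, SD undefined")
    rec = StandardizationRecord(name=name, mean=mu, sd=sd, scope=scope)
    return rec.apply(x), rec


def standardize_covariates(
    table: CovariateTable, log_skewed: bool = False
) -> tuple[pd.DataFrame, dict[str, StandardizationRecord]]:
    """Standardize the continuous region covariates; pass dummies through.

    ``log_skewed=True`` log10-transforms the heavily right-skewed hden and
    forest_ha before z-scoring (opt-in; default standardizes raw values).
    Returns a DataFrame with region_id, the standardized continuous columns,
    and continent dummy columns, plus the per-covariate records.
    """
    out = {"region_id": table.df["region_id"]}
    records: dict[str, StandardizationRecord] = {}
    for col in CONTINUOUS_COVARIATES:
        x = table.df[col].to_numpy(dtype=float)
        if log_skewed and col in ("hden", "forest_ha"):
            x = np.log10(np.maximum(x, 1e-12))
        z, rec = standardize(x, name=col, scope="region")
        out[col] = z
        records[col] = rec
    dummies = table.continent_dummies()
    out["neotropics"] = dummies["neotropics"].to_numpy()
    out["indo_malayan"] = dummies["indo_malayan"].to_numpy()
    return pd.DataFrame(out), records


def standardize_site_settlement(
    data: StudyDataset,
) -> tuple[dict[str, np.ndarray], StandardizationRecord]:
    """Z-score site-level settlement distance pooled across all sites.

    The detection model uses settlement distance at the site scale; the
    occupancy/richness models use the region mean. Pooling across regions
    keeps one scale for the shared detection coefficient.
    """
    pooled = np.concatenate([[s.settl_m for s in r.sites] for r in data.regions])
    _, rec = standardize(pooled, name="settl_site", scope="site")
    per_region = {
        r.region_id: rec.apply([s.settl_m for s in r.sites]) for r in data.regions
    }
    return per_region, rec


# ---------------------------------------------------------------------------
# Data augmentation


@dataclass
class AugmentedRegion:
    region_id: str
    y: np.ndarray  # (M, n_sites); rows n_r.. are all zero
    effort: np.ndarray  # (n_sites,)
    n_detected: int
    species_ids: list[str]  # length n_detected

    @property
    def detected_mask(self) -> np.ndarray:
        m = np.zeros(self.y.shape[0], dtype=bool)
        m[: self.n_detected] = True
        return m


@dataclass
class AugmentedDetectionArray:
    """StudyDataset padded to M species rows per region (the superpopulation).

    Rows beyond the n_r detected species are all-zero encounter histories;
    whether each such row is a real community member is the latent quantity
    the model estimates.
    """

    M: int
    regions: list[AugmentedRegion]
    source: StudyDataset = field(repr=False)

    def to_study(self) -> StudyDataset:
        """Drop augmented rows; recovers the source dataset exactly."""
        out = []
        for src, aug in zip(self.source.regions, self.regions):
            out.append(
                Region(
                    region_id=src.region_id,
                    continent=src.continent,
                    sites=list(src.sites),
                    species_ids=list(aug.species_ids),
                    y=aug.y[: aug.n_detected].copy(),
                )
            )
        return StudyDataset(out)


def augment(data: StudyDataset, M: int) -> AugmentedDetectionArray:
    """Pad each region's detection matrix to ``M`` species rows.

    ``M`` is the assumed superpopulation size (default 55 in the fitting
    pipeline); it must be at least the richest region's detected count.
    """
    n_max = int(data.n_detected.max()) if data.regions else 0
    if M < n_max:
        raise ValueError(f"M={M} < max detected species {n_max}")
    regions = []
    for r in data.regions:
        y = np.zeros((M, r.n_sites), dtype=int)
        y[: r.n_species] = r.y
        regions.append(
            AugmentedRegion(
                region_id=r.region_id,
                y=y,
                effort=r.effort,
                n_detected=r.n_species,
                species_ids=list(r.species_ids),
            )
        )
    return AugmentedDetectionArray(M=M, regions=regions, source=data)


# ---------------------------------------------------------------------------
# CSV I/O

_DET_COLS = ["region_id", "site_id", "species_id", "days_detected", "days_active"]
_SITE_COLS = ["region_id", "site_id", "settl_m", "cam_trigger", "days_active"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing columns {missing}")


def read_study(
    detections_csv: str | Path,
    region_covariates_csv: str | Path,
    site_covariates_csv: str | Path,
) -> tuple[StudyDataset, CovariateTable]:
    """Read the three study CSVs into a validated dataset + covariate table.

    Site order within a region follows ``site_covariates.csv``; species order
    follows first appearance in ``detections.csv``. Sites with zero active
    days are dropped with a warning. Region order follows the covariate table.
    """
    det = pd.read_csv(detections_csv)
    sites = pd.read_csv(site_covariates_csv)
    covs = CovariateTable(pd.read_csv(region_covariates_csv))
    _require_columns(det, _DET_COLS, "detections.csv")
    _require_columns(sites, _SITE_COLS, "site_covariates.csv")

    dead = sites["days_active"] < 1
    if dead.any():
        dropped = sites.loc[dead, ["region_id", "site_id"]].to_records(index=False)
        warnings.warn(
            f"dropping {int(dead.sum())} site(s) with zero active days: "
            f"{list(map(tuple, dropped))}",
            stacklevel=2,
        )
        sites = sites.loc[~dead]

    regions: list[Region] = []
    for rid in covs.region_ids:
        srows = sites[sites["region_id"] == rid]
        if srows.empty:
            raise ValidationError(f"region {rid!r}: no sites in site_covariates.csv")
        site_objs = [
            Site(
                site_id=str(row.site_id),
                effort=int(row.days_active),
                settl_m=float(row.settl_m),
                cam_trigger=str(row.cam_trigger),
            )
            for row in srows.itertuples()
        ]
        site_index = {s.site_id: j for j, s in enumerate(site_objs)}
        drows = det[det["region_id"] == rid]
        species = list(dict.fromkeys(str(s) for s in drows["species_id"]))
        sp_index = {s: i for i, s in enumerate(species)}
        y = np.zeros((len(species), len(site_objs)), dtype=int)
        for row in drows.itertuples():
            sid = str(row.site_id)
            if sid not in site_index:
                raise ValidationError(
                    f"region {rid!r}: detection at unknown site {sid!r}"
                )
            j = site_index[sid]
            i = sp_index[str(row.species_id)]
            y[i, j] += int(row.days_detected)
            if int(row.days_active) != site_objs[j].effort:
                raise ValidationError(
                    f"region {rid!r} site {sid!r}: days_active mismatch between "
                    "detections.csv and site_covariates.csv"
                )
        continent = str(covs.df.set_index("region_id").loc[rid, "continent"])
        regions.append(
            Region(
                region_id=rid,
                continent=continent,
                sites=site_objs,
                species_ids=species,
                y=y,
            )
        )
    extra = set(det["region_id"].astype(str)) - set(map(str, covs.region_ids))
    if extra:
        raise ValidationError(f"detections reference unknown regions: {sorted(extra)}")
    return StudyDataset(regions), covs


def write_study(
    data: StudyDataset,
    covariates: CovariateTable,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write detections.csv, region_covariates.csv, site_covariates.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    det_rows = []
    site_rows = []
    for r in data.regions:
        for s in r.sites:
            site_rows.append((r.region_id, s.site_id, s.settl_m, s.cam_trigger, s.effort))
        # species-major order so first appearance preserves species order
        for i, sp in enumerate(r.species_ids):
            for j, s in enumerate(r.sites):
                if r.y[i, j] > 0:
                    det_rows.append((r.region_id, s.site_id, sp, int(r.y[i, j]), s.effort))
    paths = {
        "detections": out / "detections.csv",
        "region_covariates": out / "region_covariates.csv",
        "site_covariates": out / "site_covariates.csv",
    }
    pd.DataFrame(det_rows, columns=_DET_COLS).to_csv(paths["detections"], index=False)
    pd.DataFrame(site_rows, columns=_SITE_COLS).to_csv(
        paths["site_covariates"], index=False
    )
    covariates.df.to_csv(paths["region_covariates"], index=False)
    return paths
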