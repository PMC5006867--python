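"""Data model and I/O for constant-effort-site (CES) ringing data.

A CES dataset couples individual capture histories of adult birds with
site metadata (coordinates, operating years, visit effort) and per
site-year counts of juveniles.  Adult counts are always derived from the
histories themselves: one detected adult contributes exactly one to its
site-year-sex cell, however many times it was handled that season.  The
only piece of within-season information kept is whether an individual
was recaught at least once after its first capture of the first season,
which is what the transient-corrected survival model consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"
SEXES = (MALE, FEMALE)

#: Accepted spellings in input files (after lower-casing and stripping).
_SEX_ALIASES = {
    "m": MALE, "male": MALE, "1": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
    "u": UNKNOWN, "unknown": UNKNOWN, "unk": UNKNOWN, "na": UNKNOWN,
    "": UNKNOWN, "0": UNKNOWN,
}


class CesDataError(ValueError):
    """Raised for malformed or inconsistent CES input data."""


def normalize_sex(value: object) -> str:
    """Map a raw sex code to 'male' / 'female' / 'unknown'.

    Stray whitespace and case differences are tolerated; anything not in
    the documented alias table is an error.
    """
    key = str(value).strip().lower()
    if key in _SEX_ALIASES:
        return _SEX_ALIASES[key]
    raise CesDataError(f"unrecognized sex code {value!r}")


@dataclass(frozen=True)
class Site:
    site_id: str
    longitude: float
    latitude: float
    years_operated: tuple[int, ...]
    visits_per_year: Mapping[int, int]

    def __post_init__(self):
        yrs = tuple(sorted(set(int(y) for y in self.years_operated)))
        object.__setattr__(self, "years_operated", yrs)
        if not yrs:
            raise CesDataError(f"site {self.site_id}: no operating years")
        visits = {int(y): int(v) for y, v in dict(self.visits_per_year).items()}
        missing = [y for y in yrs if y not in visits]
        if missing:
            raise CesDataError(f"site {self.site_id}: no visit count for years {missing}")
        object.__setattr__(self, "visits_per_year", visits)


@dataclass(frozen=True)
class CaptureHistory:
    """Annual detections of one marked adult at one site.

    ``detection_years`` contains every year the bird was caught at least
    once; ``first_year`` is its minimum.  ``within_first_season_recapture``
    records whether the bird was handled a second time during the season
    of first capture — the residency evidence used by the transient model.
    """

    individual_id: str
    site_id: str
    sex: str
    first_year: int
    detection_years: frozenset[int]
    within_first_season_recapture: bool = False

    def __post_init__(self):
        object.__setattr__(self, "sex", normalize_sex(self.sex))
        yrs = frozenset(int(y) for y in self.detection_years)
        object.__setattr__(self, "detection_years", yrs)
        if not yrs or min(yrs) != self.first_year:
            raise CesDataError(
                f"individual {self.individual_id}: first_year {self.first_year} "
                f"must be the earliest detection year {sorted(yrs)}"
            )


@dataclass
class CesDataset:
    histories: list[CaptureHistory]
    sites: dict[str, Site]
    juvenile_counts: dict[tuple[str, int], int] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- consistency ---------------------------------------------------
    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for h in self.histories:
            if h.site_id not in self.sites:
                raise CesDataError(f"individual {h.individual_id}: unknown site {h.site_id!r}")
            site = self.sites[h.site_id]
            bad = sorted(set(h.detection_years) - set(site.years_operated))
            if bad:
                raise CesDataError(
                    f"individual {h.individual_id}: detections in years {bad} "
                    f"when site {h.site_id} did not operate"
                )
            key = (h.individual_id, h.site_id)
            if key in seen:
                raise CesDataError(f"duplicate history for individual {h.individual_id}")
            seen.add(key)
        for (s, y), c in self.juvenile_counts.items():
            if c < 0:
                raise CesDataError(f"negative juvenile count at ({s}, {y})")

    # -- derived tables ------------------------------------------------
    def adult_counts(self) -> pd.DataFrame:
        """Distinct adults caught per (site, year, sex), from the histories."""
        rows = []
        for h in self.histories:
            for y in sorted(h.detection_years):
                rows.append((h.site_id, y, h.sex))
        if not rows:
            return pd.DataFrame(columns=["site_id", "year", "sex", "count"])
        df = pd.DataFrame(rows, columns=["site_id", "year", "sex"])
        out = df.groupby(["site_id", "year", "sex"]).size().reset_index(name="count")
        return out

    def n_individuals(self) -> int:
        return len(self.histories)


# ---------------------------------------------------------------------
# CSV I/O
#
# Dialect: four UTF-8 CSVs with headers.
#   captures.csv        individual_id, site_id, sex, year, detected,
#                       within_first_season_recapture
#   sites.csv           site_id, longitude, latitude, years_operated
#                       (';'-separated), visits_per_year (';'-separated,
#                       aligned with years_operated)
#   juvenile_counts.csv site_id, year, count
#   adult_counts.csv    site_id, year, sex, count   (redundant; checked
#                       against the histories on read)
# ---------------------------------------------------------------------

CAPTURE_COLUMNS = ["individual_id", "site_id", "sex", "year", "detected",
                   "within_first_season_recapture"]


def write_dataset(dataset: CesDataset, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "captures": outdir / "captures.csv",
        "sites": outdir / "sites.csv",
        "juvenile_counts": outdir / "juvenile_counts.csv",
        "adult_counts": outdir / "adult_counts.csv",
    }

    cap_rows = []
    for h in dataset.histories:
        for y in sorted(h.detection_years):
            flag = int(h.within_first_season_recapture) if y == h.first_year else 0
            cap_rows.append((h.individual_id, h.site_id, h.sex, y, 1, flag))
    pd.DataFrame(cap_rows, columns=CAPTURE_COLUMNS).to_csv(paths["captures"], index=False)

    site_rows = []
    for s in dataset.sites.values():
        site_rows.append((
            s.site_id, s.longitude, s.latitude,
            ";".join(str(y) for y in s.years_operated),
            ";".join(str(s.visits_per_year[y]) for y in s.years_operated),
        ))
    pd.DataFrame(site_rows, columns=["site_id", "longitude", "latitude",
                                     "years_operated", "visits_per_year"]
                 ).to_csv(paths["sites"], index=False)

    juv = pd.DataFrame(
        [(s, y, c) for (s, y), c in sorted(dataset.juvenile_counts.items())],
        columns=["site_id", "year", "count"])
    juv.to_csv(paths["juvenile_counts"], index=False)

    dataset.adult_counts().to_csv(paths["adult_counts"], index=False)
    return paths


def read_dataset(indir: str | Path) -> CesDataset:
    """Read the CSV dialect written by :func:`write_dataset`.

    Malformed rows are rejected with their (1-based, header-exclusive)
    row number in the message.
    """
    indir = Path(indir)

    sites_df = pd.read_csv(indir / "sites.csv", dtype={"site_id": str},
                           float_precision="round_trip")
    _require(sites_df, ["site_id", "longitude", "latitude", "years_operated",
                        "visits_per_year"], "sites.csv")
    sites: dict[str, Site] = {}
    for i, row in sites_df.iterrows():
        years = tuple(int(y) for y in str(row["years_operated"]).split(";"))
        visits = [int(v) for v in str(row["visits_per_year"]).split(";")]
        if len(visits) != len(years):
            raise CesDataError(f"sites.csv row {i + 1}: visit list does not align with years")
        sites[row["site_id"]] = Site(row["site_id"], float(row["longitude"]),
                                     float(row["latitude"]), years,
                                     dict(zip(years, visits)))

    cap = pd.read_csv(indir / "captures.csv", dtype={"individual_id": str, "site_id": str})
    _require(cap, CAPTURE_COLUMNS, "captures.csv")
    histories: list[CaptureHistory] = []
    for (ind, site_id), grp in cap.groupby(["individual_id", "site_id"], sort=True):
        det_years: dict[int, int] = {}
        flag = False
        for i, row in grp.iterrows():
            year = int(row["year"])
            detected = int(row["detected"])
            if site_id not in sites:
                raise CesDataError(f"captures.csv row {i + 1}: unknown site {site_id!r}")
            if detected not in (0, 1):
                raise CesDataError(f"captures.csv row {i + 1}: detected must be 0/1")
            if detected and year not in sites[site_id].years_operated:
                raise CesDataError(
                    f"captures.csv row {i + 1}: individual {ind} detected in {year} "
                    f"but site {site_id} did not operate that year")
            if year in det_years and detected and det_years[year]:
                raise CesDataError(
                    f"captures.csv row {i + 1}: duplicate record for individual "
                    f"{ind} in {year}")
            det_years[year] = max(det_years.get(year, 0), detected)
            if detected and bool(int(row["within_first_season_recapture"])):
                flag = True
        years = frozenset(y for y, d in det_years.items() if d)
        if not years:
            continue
        sexes = {normalize_sex(s) for s in grp["sex"]}
        if len(sexes) > 1:
            raise CesDataError(f"individual {ind}: inconsistent sex codes {sorted(sexes)}")
        histories.append(CaptureHistory(ind, site_id, sexes.pop(), min(years), years, flag))

    juvenile_counts: dict[tuple[str, int], int] = {}
    juv_path = indir / "juvenile_counts.csv"
    if juv_path.exists():
        juv = pd.read_csv(juv_path, dtype={"site_id": str})
        _require(juv, ["site_id", "year", "count"], "juvenile_counts.csv")
        for i, row in juv.iterrows():
            c = int(row["count"])
            if c < 0:
                raise CesDataError(f"juvenile_counts.csv row {i + 1}: negative count")
            juvenile_counts[(row["site_id"], int(row["year"]))] = c

    ds = CesDataset(histories, sites, juvenile_counts)

    ac_path = indir / "adult_counts.csv"
    if ac_path.exists():
        stored = pd.read_csv(ac_path, dtype={"site_id": str})
        _require(stored, ["site_id", "year", "sex", "count"], "adult_counts.csv")
        stored = stored.assign(sex=stored["sex"].map(normalize_sex))
        derived = ds.adult_counts()
        key = ["site_id", "year", "sex"]
        merged = stored.merge(derived, on=key, how="outer", suffixes=("_stored", ""),
                              indicator=True)
        bad = merged[(merged["_merge"] != "both")
                     | (merged["count_stored"] != merged["count"])]
        if len(bad):
            raise CesDataError(
                "adult_counts.csv inconsistent with capture histories at "
                + ", ".join(f"({r.site_id}, {r.year}, {r.sex})" for r in bad.itertuples()))
    return ds


def _require(df: pd.DataFrame, columns: Iterable[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CesDataError(f"{name}: missing required columns {missing}")


# ---------------------------------------------------------------------
# Inclusion rules
# ---------------------------------------------------------------------

def filter_sites(dataset: CesDataset, min_years: int = 5, min_visits: int = 8,
                 min_captures_per_sex: int = 50,
                 visits_rule: str = "per_year") -> CesDataset:
    """Keep only sites meeting the CES inclusion rules.

    A site is retained when it (a) operated for at least ``min_years``
    seasons, (b) was visited at least ``min_visits`` times — in every
    operated season when ``visits_rule='per_year'`` (the default), or on
    average when ``visits_rule='mean'`` — and (c) accumulated at least
    ``min_captures_per_sex`` sexed capture events (distinct individual-
    year detections) of each sex across all years.
    """
    if min(min_years, min_visits, min_captures_per_sex) <= 0:
        raise ValueError("thresholds must be positive")
    if visits_rule not in ("per_year", "mean"):
        raise ValueError("visits_rule must be 'per_year' or 'mean'")

    captures = {(s, sex): 0 for s in dataset.sites for sex in SEXES}
    for h in dataset.histories:
        if h.sex in SEXES:
            captures[(h.site_id, h.sex)] += len(h.detection_years)

    keep: set[str] = set()
    for sid, site in dataset.sites.items():
        if len(site.years_operated) < min_years:
            continue
        visits = [site.visits_per_year[y] for y in site.years_operated]
        if visits_rule == "per_year":
            ok_visits = min(visits) >= min_visits
        else:
            ok_visits = float(np.mean(visits)) >= min_visits
        if not ok_visits:
            continue
        if any(captures[(sid, sex)] < min_captures_per_sex for sex in SEXES):
            continue
        keep.add(sid)

    if not keep:
        warnings.warn("no sites pass the inclusion rules", stacklevel=2)
    return CesDataset(
        [h for h in dataset.histories if h.site_id in keep],
        {sid: s for sid, s in dataset.sites.items() if sid in keep},
        {k: v for k, v in dataset.juvenile_counts.items() if k[0] in keep},
    )


def drop_unsexed(dataset: CesDataset) -> tuple[CesDataset, float]:
    """Remove histories with unknown sex; return (dataset, retained fraction)."""
    n = len(dataset.histories)
    kept = [h for h in dataset.histories if h.sex in SEXES]
    frac = len(kept) / n if n else float("nan")
    if n and not kept:
        warnings.warn("all individuals are unsexed; dataset is empty", stacklevel=2)
    return CesDataset(kept, dict(dataset.sites), dict(dataset.juvenile_counts)), frac
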