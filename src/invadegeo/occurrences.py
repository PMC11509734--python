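"""Occurrence-record ingestion and cleaning.

Parses Darwin-Core-style occurrence exports (GBIF downloads) and plain
specimen coordinate tables, applies taxon/geography/time filters,
collapses multiple reports of a single event (e.g. many specimens from
one nest) into one observation, and produces the two downstream inputs:
zero-filled annual count series and georeferenced point sets.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

VALID_BASES = ("specimen", "observation", "sighting", "unknown")

# Darwin Core header -> record field
_DWC_HEADERS = {
    "species": "taxon",
    "scientificname": "taxon",
    "taxon": "taxon",
    "infraspecificepithet": "subspecies",
    "subspecies": "subspecies",
    "decimallatitude": "latitude",
    "latitude": "latitude",
    "decimallongitude": "longitude",
    "longitude": "longitude",
    "year": "year",
    "eventdate": "date",
    "date": "date",
    "countrycode": "country",
    "country": "country",
    "basisofrecord": "basis",
    "basis": "basis",
    "id": "record_id",
    "gbifid": "record_id",
    "record_id": "record_id",
}

_BASIS_MAP = {
    "preserved_specimen": "specimen",
    "preservedspecimen": "specimen",
    "specimen": "specimen",
    "material_sample": "specimen",
    "materialsample": "specimen",
    "observation": "observation",
    "machine_observation": "observation",
    "machineobservation": "observation",
    "human_observation": "sighting",
    "humanobservation": "sighting",
    "sighting": "sighting",
    "occurrence": "unknown",
    "unknown": "unknown",
    "": "unknown",
}


class FormatError(ValueError):
    """The input file lacks a mandatory column or is structurally broken."""


class CoordinateBoundsError(ValueError):
    """A coordinate value lies outside [-90, 90] x [-180, 180]."""


@dataclass
class OccurrenceRecord:
    """One occurrence event: who, where, when.

    Coordinates may be absent (None); such records still count toward
    annual series but are never admitted into point sets.
    """

    record_id: str
    taxon: str
    year: Optional[int] = None
    subspecies: Optional[str] = None
    date: Optional[_dt.date] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    country: Optional[str] = None
    basis: str = "unknown"

    def __post_init__(self) -> None:
        if (self.latitude is None) != (self.longitude is None):
            raise ValueError(
                f"record {self.record_id}: latitude and longitude must both "
                "be present or both be absent"
            )
        if self.latitude is not None:
            _check_bounds(self.latitude, self.longitude, context=self.record_id)
        if self.year is not None and self.year <= 0:
            raise ValueError(f"record {self.record_id}: year must be positive")
        if self.basis not in VALID_BASES:
            raise ValueError(f"record {self.record_id}: unknown basis {self.basis!r}")

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None


@dataclass
class AnnualCountSeries:
    """Yearly observation counts over a closed analysis window.

    Years with no records carry an explicit zero: GBIF exports omit
    zero-count years, but the fit of a sparse invasion series depends on
    runs of zeros being present in the data.  Counts are normally
    integers; real-valued counts are allowed so that noise-free model
    expectations can flow through the same container.
    """

    window_start: int
    window_end: int
    counts: Sequence[float]

    def __post_init__(self) -> None:
        if self.window_start > self.window_end:
            raise ValueError("window_start must be <= window_end")
        expected = self.window_end - self.window_start + 1
        if len(self.counts) != expected:
            raise ValueError(
                f"counts has length {len(self.counts)}, window needs {expected}"
            )
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        self.counts = list(self.counts)

    @property
    def years(self) -> list[int]:
        return list(range(self.window_start, self.window_end + 1))

    def total(self) -> float:
        return sum(self.counts)

    def to_json(self) -> str:
        return json.dumps(
            {
                "window_start": self.window_start,
                "window_end": self.window_end,
                "counts": list(self.counts),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AnnualCountSeries":
        d = json.loads(text)
        return cls(d["window_start"], d["window_end"], d["counts"])


@dataclass
class TaxonPointSet:
    """Georeferenced points for one taxon, with a provenance note.

    Exact duplicate coordinate pairs are retained (they matter for
    subsampling) but counted in ``n_duplicates``; duplicates do not
    change the hull geometry.
    """

    taxon: str
    points: list[tuple[float, float]]  # (latitude, longitude)
    provenance: str = ""

    def __post_init__(self) -> None:
        for lat, lon in self.points:
            _check_bounds(lat, lon, context=self.taxon)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_duplicates(self) -> int:
        return len(self.points) - len(set(self.points))


def _check_bounds(lat: float, lon: float, context: str = "") -> None:
    if not (-90.0 <= lat <= 90.0):
        raise CoordinateBoundsError(f"{context}: latitude {lat} outside [-90, 90]")
    if not (-180.0 <= lon <= 180.0):
        raise CoordinateBoundsError(f"{context}: longitude {lon} outside [-180, 180]")


def _parse_date(text: str) -> Optional[_dt.date]:
    text = text.strip()
    if not text:
        return None
    # GBIF eventDate may be ISO date, datetime, or a range; take the first day
    head = text.split("/")[0].split("T")[0]
    try:
        return _dt.date.fromisoformat(head)
    except ValueError:
        return None


def parse_occurrences(path, dialect: Optional[str] = None) -> list[OccurrenceRecord]:
    """Parse a delimited occurrence file into records.

    Parameters
    ----------
    path
        Darwin-Core-style export (tab- or comma-separated) or a plain
        ``id,latitude,longitude,taxon`` specimen table.
    dialect
        ``"tab"`` or ``"comma"``; sniffed from the header line when None.

    Rows with blank or unparseable coordinates are retained with
    coordinates absent.  Rows with out-of-bounds coordinates raise
    :class:`CoordinateBoundsError` naming the offending row.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            warnings.warn(f"{path}: empty file, no records parsed")
            return []
        if dialect is None:
            dialect = "tab" if first.count("\t") >= first.count(",") and "\t" in first else "comma"
        sep = "\t" if dialect == "tab" else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=sep)
        header_map = {}
        for col in reader.fieldnames or []:
            key = col.strip().lower()
            if key in _DWC_HEADERS:
                header_map[col] = _DWC_HEADERS[key]
        fields = set(header_map.values())
        if "taxon" not in fields and not ({"latitude", "longitude"} <= fields or "year" in fields):
            raise FormatError(
                "missing mandatory columns: need a taxon column "
                "(species/scientificName) or coordinate/year columns; "
                f"found {reader.fieldnames}"
            )
        records: list[OccurrenceRecord] = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            vals = {header_map[k]: (v or "").strip() for k, v in row.items() if k in header_map}
            lat_s, lon_s = vals.get("latitude", ""), vals.get("longitude", "")
            lat = lon = None
            try:
                if lat_s and lon_s:
                    lat, lon = float(lat_s), float(lon_s)
            except ValueError:
                lat = lon = None  # unparseable -> absent, row retained
            if lat is not None:
                try:
                    _check_bounds(lat, lon, context=f"row {i}")
                except CoordinateBoundsError as err:
                    raise CoordinateBoundsError(
                        f"{path}: {err} (row {i} rejected)"
                    ) from None
            year = None
            if vals.get("year"):
                try:
                    year = int(float(vals["year"]))
                except ValueError:
                    year = None
            date = _parse_date(vals.get("date", ""))
            if year is None and date is not None:
                year = date.year
            basis = _BASIS_MAP.get(
                vals.get("basis", "").strip().lower().replace(" ", "_"), "unknown"
            )
            records.append(
                OccurrenceRecord(
                    record_id=vals.get("record_id") or f"row{i}",
                    taxon=vals.get("taxon", ""),
                    subspecies=vals.get("subspecies") or None,
                    year=year,
                    date=date,
                    latitude=lat,
                    longitude=lon,
                    country=(vals.get("country") or None),
                    basis=basis,
                )
            )
    if not records:
        warnings.warn(f"{path}: no data rows")
    return records


def write_records_csv(records: Iterable[OccurrenceRecord], path) -> None:
    """Write records to a canonical comma-separated file (round-trippable)."""
    cols = ["record_id", "taxon", "subspecies", "year", "date",
            "latitude", "longitude", "country", "basis"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for r in records:
            w.writerow([
                r.record_id, r.taxon, r.subspecies or "", r.year if r.year else "",
                r.date.isoformat() if r.date else "",
                "" if r.latitude is None else repr(r.latitude),
                "" if r.longitude is None else repr(r.longitude),
                r.country or "", r.basis,
            ])


def filter_records(
    records: Sequence[OccurrenceRecord],
    taxon: Optional[str] = None,
    subspecies: Optional[str] = None,
    countries: Optional[set[str]] = None,
    year_range: Optional[tuple[int, int]] = None,
    exclude_countries: Optional[set[str]] = None,
    drop_sightings: bool = False,
) -> list[OccurrenceRecord]:
    """Keep records satisfying the conjunction of all given predicates.

    Taxon and subspecies matches are case-insensitive; country codes are
    ISO alpha-2.  An unknown (non-2-letter) country code in a filter set
    triggers a warning and never matches.
    """
    if year_range is not None and year_range[0] > year_range[1]:
        raise ValueError("year_range start must be <= end")

    def norm_cc(cs: Optional[set[str]]) -> Optional[set[str]]:
        if cs is None:
            return None
        out = set()
        for c in cs:
            if len(c) != 2 or not c.isalpha():
                warnings.warn(f"unknown country code {c!r}; treated as non-matching")
                continue
            out.add(c.upper())
        return out

    countries = norm_cc(countries)
    exclude_countries = norm_cc(exclude_countries)
    out = []
    for r in records:
        if taxon is not None and r.taxon.lower() != taxon.lower():
            continue
        if subspecies is not None and (r.subspecies or "").lower() != subspecies.lower():
            continue
        if countries is not None and (r.country or "").upper() not in countries:
            continue
        if exclude_countries is not None and (r.country or "").upper() in exclude_countries:
            continue
        if year_range is not None and (r.year is None or not (year_range[0] <= r.year <= year_range[1])):
            continue
        if drop_sightings and r.basis == "sighting":
            continue
        out.append(r)
    return out


def deduplicate_events(
    records: Sequence[OccurrenceRecord],
    radius_deg: float = 0.001,
    same_day: bool = True,
) -> list[OccurrenceRecord]:
    """Collapse multiple reports of one event into a single observation.

    Records sharing the same year (and the same date, when ``same_day``
    and both dates are present) whose coordinates lie within
    ``radius_deg`` of each other (Chebyshev distance on raw degrees)
    form a cluster under transitive closure; each cluster keeps its
    first record by input order.  Records without coordinates never
    collapse.  The operation is idempotent.

    The default radius of 0.001 deg (~100 m) reproduces the rule that
    many specimens collected from a single nest count as one
    observation.
    """
    if radius_deg < 0:
        raise ValueError("radius_deg must be non-negative")
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # bucket by temporal key to avoid n^2 over unrelated years
    buckets: dict[object, list[int]] = {}
    for i, r in enumerate(records):
        if not r.has_coordinates:
            continue
        buckets.setdefault(r.year, []).append(i)
    for idxs in buckets.values():
        for a in range(len(idxs)):
            i = idxs[a]
            ri = records[i]
            for b in range(a + 1, len(idxs)):
                j = idxs[b]
                rj = records[j]
                if same_day and ri.date is not None and rj.date is not None and ri.date != rj.date:
                    continue
                cheb = max(abs(ri.latitude - rj.latitude), abs(ri.longitude - rj.longitude))
                # radius 0 still merges exact coordinate duplicates (cheb == 0)
                if cheb <= radius_deg:
                    union(i, j)
    seen: set[int] = set()
    out = []
    for i in range(n):
        root = find(i)
        if root in seen:
            continue
        seen.add(root)
        out.append(records[root])
    return out


def annual_counts(
    records: Sequence[OccurrenceRecord], window_start: int, window_end: int
) -> AnnualCountSeries:
    """Count records per calendar year over [window_start, window_end].

    Years absent from the records get an explicit zero.  Records outside
    the window (or without a year) are excluded with a debug log.
    """
    if window_start > window_end:
        raise ValueError("window_start must be <= window_end")
    counts = [0] * (window_end - window_start + 1)
    dropped = 0
    for r in records:
        if r.year is None or not (window_start <= r.year <= window_end):
            dropped += 1
            continue
        counts[r.year - window_start] += 1
    if dropped:
        logger.debug("annual_counts: %d records outside window [%d, %d]",
                     dropped, window_start, window_end)
    return AnnualCountSeries(window_start, window_end, counts)


def to_point_set(records: Sequence[OccurrenceRecord], taxon_label: str) -> TaxonPointSet:
    """Project records onto a point set; records lacking coordinates are
    skipped and counted in the provenance note."""
    pts = [(r.latitude, r.longitude) for r in records if r.has_coordinates]
    skipped = len(records) - len(pts)
    prov = f"{len(pts)} points from {len(records)} records; {skipped} skipped (no coordinates)"
    ps = TaxonPointSet(taxon=taxon_label, points=pts, provenance=prov)
    if ps.n_duplicates:
        ps.provenance += f"; {ps.n_duplicates} duplicate coordinate pairs retained"
    if not pts:
        warnings.warn(f"{taxon_label}: zero usable points")
    return ps


def read_specimen_table(path) -> list[tuple[str, float, float, str]]:
    """Read a plain ``id,latitude,longitude,taxon`` specimen table."""
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        need = {"id", "latitude", "longitude"}
        have = {c.strip().lower() for c in (reader.fieldnames or [])}
        if not need <= have:
            raise FormatError(f"specimen table missing columns {sorted(need - have)}")
        for row in reader:
            row = {k.strip().lower(): v for k, v in row.items()}
            lat, lon = float(row["latitude"]), float(row["longitude"])
            _check_bounds(lat, lon, context=row["id"])
            rows.append((row["id"].strip(), lat, lon, (row.get("taxon") or "").strip()))
    return rows
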