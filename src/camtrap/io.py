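"""Tabular IO and history-matrix construction.

File dialect: comma-separated UTF-8 with one header row. Spreadsheet (.xlsx)
input is supported read-only with the same column layout on the first sheet
(the assumed layout for deposited survey workbooks; minor case/spacing
variants in headers are tolerated).

Standard tables
---------------
stations.csv : station_id, site, x_km, y_km, dist_road_km, dist_river_km,
               dist_settlement_km, habitat, cam_spacing_m, active_from, active_to
photos.csv   : station_id, species, timestamp (ISO-8601), count
captures.csv : individual_id, station_id, day, site
masses.csv   : species, mass_kg

``active_from``/``active_to`` and capture ``day`` are 1-based survey days
(closed interval).
"""

from __future__ import annotations

import logging
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    CaptureMatrix,
    CaptureRecord,
    DetectionMatrix,
    PhotoEvent,
    RunConfig,
    SpeciesMass,
    Station,
    SurveyBundle,
    ValidationError,
)

log = logging.getLogger("camtrap")

STATION_COLUMNS = [
    "station_id", "site", "x_km", "y_km", "dist_road_km", "dist_river_km",
    "dist_settlement_km", "habitat", "cam_spacing_m", "active_from", "active_to",
]
PHOTO_COLUMNS = ["station_id", "species", "timestamp", "count"]
CAPTURE_COLUMNS = ["individual_id", "station_id", "day", "site"]
MASS_COLUMNS = ["species", "mass_kg"]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=0)
    else:
        df = pd.read_csv(path)
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    return df


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing columns {missing}")


def read_stations(path: str | Path, survey_days: int = 90) -> list[Station]:
    df = _read_table(path)
    _require(df, STATION_COLUMNS, "stations table")
    stations: list[Station] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        sid = str(row["station_id"])
        if sid in seen:
            raise ValidationError(f"stations row {i + 2}: duplicate station_id {sid!r}")
        seen.add(sid)
        a, b = int(row["active_from"]), int(row["active_to"])
        if not 1 <= a <= b <= survey_days:
            raise ValidationError(
                f"stations row {i + 2}: active window [{a}, {b}] outside 1..{survey_days}"
            )
        active = np.zeros(survey_days, dtype=bool)
        active[a - 1 : b] = True
        stations.append(
            Station(
                station_id=sid,
                site=str(row["site"]),
                x=float(row["x_km"]),
                y=float(row["y_km"]),
                dist_road=float(row["dist_road_km"]),
                dist_river=float(row["dist_river_km"]),
                dist_settlement=float(row["dist_settlement_km"]),
                habitat=int(row["habitat"]),
                cam_spacing=float(row["cam_spacing_m"]),
                active=active,
            )
        )
    return stations


def read_photos(path: str | Path) -> list[PhotoEvent]:
    df = _read_table(path)
    _require(df, PHOTO_COLUMNS, "photos table")
    events = []
    for i, row in df.iterrows():
        ts = pd.Timestamp(row["timestamp"]).to_pydatetime()
        events.append(
            PhotoEvent(
                station_id=str(row["station_id"]),
                species=str(row["species"]).strip().lower(),
                timestamp=ts,
                count=int(row["count"]),
            )
        )
    return events


def read_captures(path: str | Path) -> list[CaptureRecord]:
    df = _read_table(path)
    _require(df, CAPTURE_COLUMNS, "captures table")
    return [
        CaptureRecord(
            individual_id=str(r["individual_id"]),
            station_id=str(r["station_id"]),
            day=int(r["day"]),
            site=str(r["site"]),
        )
        for _, r in df.iterrows()
    ]


def read_masses(path: str | Path) -> list[SpeciesMass]:
    df = _read_table(path)
    _require(df, MASS_COLUMNS, "masses table")
    return [
        SpeciesMass(species=str(r["species"]).strip().lower(), mass=float(r["mass_kg"]))
        for _, r in df.iterrows()
    ]


def write_stations(stations: Sequence[Station], path: str | Path) -> None:
    rows = []
    for s in stations:
        days = np.flatnonzero(s.active) + 1
        rows.append(
            dict(
                station_id=s.station_id, site=s.site, x_km=s.x, y_km=s.y,
                dist_road_km=s.dist_road, dist_river_km=s.dist_river,
                dist_settlement_km=s.dist_settlement, habitat=s.habitat,
                cam_spacing_m=s.cam_spacing,
                active_from=int(days[0]) if days.size else 1,
                active_to=int(days[-1]) if days.size else 0,
            )
        )
    pd.DataFrame(rows, columns=STATION_COLUMNS).to_csv(path, index=False)


def write_photos(events: Sequence[PhotoEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(
                station_id=e.station_id, species=e.species,
                timestamp=e.timestamp.isoformat(timespec="minutes"), count=e.count,
            )
            for e in events
        ],
        columns=PHOTO_COLUMNS,
    ).to_csv(path, index=False)


def write_captures(records: Sequence[CaptureRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(individual_id=r.individual_id, station_id=r.station_id,
                 day=r.day, site=r.site)
            for r in records
        ],
        columns=CAPTURE_COLUMNS,
    ).to_csv(path, index=False)


def write_masses(masses: Sequence[SpeciesMass], path: str | Path) -> None:
    pd.DataFrame(
        [dict(species=m.species, mass_kg=m.mass) for m in masses],
        columns=MASS_COLUMNS,
    ).to_csv(path, index=False)


def event_day(event: PhotoEvent, survey_start: date) -> int:
    """1-based survey day of a photo event."""
    return (event.timestamp.date() - survey_start).days + 1


def read_survey(
    paths: Mapping[str, str | Path],
    config: RunConfig | None = None,
    survey_start: date | None = None,
) -> SurveyBundle:
    """Read and cross-validate the four standard tables.

    ``paths`` maps 'stations', 'photos', 'captures', 'masses' to files
    ('captures' and 'masses' optional). Photo/capture rows referencing
    unknown stations are rejected with their row number; photo timestamps
    outside a station's active window are rejected; non-monotone photo
    timestamps are allowed but flagged in the log.
    """
    config = config or RunConfig()
    stations = read_stations(paths["stations"], survey_days=config.survey_days)
    station_ids = {s.station_id: s for s in stations}
    photos = read_photos(paths["photos"]) if "photos" in paths else []
    if survey_start is None:
        survey_start = min((e.timestamp.date() for e in photos), default=None)
    for i, e in enumerate(photos):
        if e.station_id not in station_ids:
            raise ValidationError(
                f"photos row {i + 2}: unknown station {e.station_id!r}"
            )
        d = event_day(e, survey_start)
        st = station_ids[e.station_id]
        if not (1 <= d <= st.n_days) or not st.active[d - 1]:
            raise ValidationError(
                f"photos row {i + 2}: timestamp outside active window of "
                f"{e.station_id} (day {d})"
            )
    # flag (not reject) timestamps out of order within a station/species stream
    by_key: dict[tuple[str, str], datetime] = {}
    for e in photos:
        key = (e.station_id, e.species)
        if key in by_key and e.timestamp < by_key[key]:
            log.warning("non-monotone timestamps for %s/%s", *key)
        by_key[key] = max(e.timestamp, by_key.get(key, e.timestamp))

    captures = read_captures(paths["captures"]) if "captures" in paths else []
    for i, c in enumerate(captures):
        if c.station_id not in station_ids:
            raise ValidationError(
                f"captures row {i + 2}: unknown station {c.station_id!r}"
            )
        if not 1 <= c.day <= config.survey_days:
            raise ValidationError(
                f"captures row {i + 2}: day {c.day} outside survey window"
            )
    masses = read_masses(paths["masses"]) if "masses" in paths else []
    bundle = SurveyBundle(
        stations=stations, photos=photos, masses=masses, captures=captures,
        survey_start=survey_start, config=config,
    )
    log.info(
        "survey: %d stations, %d photo events, %d captures of %d individuals",
        len(stations), len(photos), bundle.n_captures, bundle.n_individuals,
    )
    return bundle


def _occasion_edges(survey_days: int, occasion_days: int) -> list[tuple[int, int]]:
    """Closed 1-based day intervals; a final short occasion is kept."""
    edges = []
    start = 1
    while start <= survey_days:
        end = min(start + occasion_days - 1, survey_days)
        edges.append((start, end))
        start = end + 1
    if survey_days % occasion_days:
        log.warning(
            "survey length %d not divisible by occasion length %d: final "
            "occasion spans %d day(s)", survey_days, occasion_days,
            edges[-1][1] - edges[-1][0] + 1,
        )
    return edges


def build_detection_matrix(
    events: Iterable[PhotoEvent],
    stations: Sequence[Station],
    species: str,
    occasion_days: int = 10,
    survey_start: date | None = None,
) -> DetectionMatrix:
    """Collapse photo events into a station x occasion detection history.

    y[s, o] = 1 iff at least one event of ``species`` fell at station s on an
    active day within occasion o; entries with zero effort are NaN. The result
    is independent of event order and idempotent.
    """
    species = species.strip().lower()
    n_days = stations[0].n_days
    edges = _occasion_edges(n_days, occasion_days)
    n_occ = len(edges)
    index = {s.station_id: i for i, s in enumerate(stations)}
    effort = np.zeros((len(stations), n_occ), dtype=int)
    for i, st in enumerate(stations):
        for o, (a, b) in enumerate(edges):
            effort[i, o] = int(st.active[a - 1 : b].sum())
    y = np.where(effort > 0, 0.0, np.nan)
    relevant = [e for e in events if e.species.strip().lower() == species]
    if not relevant:
        log.warning("species %r absent from all events: all-zero matrix", species)
    if survey_start is None:
        survey_start = min(
            (e.timestamp.date() for e in relevant), default=date(2000, 1, 1)
        )
    for e in relevant:
        if e.station_id not in index:
            raise ValidationError(f"photo references unknown station {e.station_id!r}")
        d = event_day(e, survey_start)
        if not 1 <= d <= n_days:
            raise ValidationError(
                f"photo at {e.station_id} on day {d} outside survey window"
            )
        o = next(k for k, (a, b) in enumerate(edges) if a <= d <= b)
        if effort[index[e.station_id], o] > 0:
            y[index[e.station_id], o] = 1.0
    return DetectionMatrix(
        species=species,
        stations=[s.station_id for s in stations],
        occasions=n_occ,
        y=y,
        effort=effort,
    )


def build_capture_matrix(
    records: Iterable[CaptureRecord],
    stations: Sequence[Station],
    occasion_days: int = 3,
    survey_days: int = 90,
) -> dict[str, CaptureMatrix]:
    """Per-site individual x occasion (and x station) capture matrices.

    Repeat captures within one occasion collapse to a single 1. An individual
    appearing at more than one site is an error: sites are analysed as
    independent closed populations.
    """
    records = list(records)
    site_of: dict[str, str] = {}
    for r in records:
        if r.individual_id in site_of and site_of[r.individual_id] != r.site:
            raise ValidationError(
                f"individual {r.individual_id!r} captured at two sites "
                f"({site_of[r.individual_id]!r}, {r.site!r})"
            )
        site_of[r.individual_id] = r.site
    edges = _occasion_edges(survey_days, occasion_days)
    n_occ = len(edges)
    out: dict[str, CaptureMatrix] = {}
    for site in dict.fromkeys(r.site for r in records):
        site_recs = [r for r in records if r.site == site]
        individuals = sorted({r.individual_id for r in site_recs})
        site_stations = [s for s in stations if s.site == site]
        st_index = {s.station_id: j for j, s in enumerate(site_stations)}
        X = np.zeros((len(individuals), n_occ), dtype=int)
        Y = np.zeros((len(individuals), len(site_stations)), dtype=int)
        ind_index = {ind: i for i, ind in enumerate(individuals)}
        seen_cells: set[tuple[str, str, int]] = set()
        for r in site_recs:
            if r.station_id not in st_index:
                raise ValidationError(
                    f"capture of {r.individual_id!r} at unknown station "
                    f"{r.station_id!r} for site {site!r}"
                )
            o = next(k for k, (a, b) in enumerate(edges) if a <= r.day <= b)
            X[ind_index[r.individual_id], o] = 1
            cell = (r.individual_id, r.station_id, o)
            if cell not in seen_cells:  # Bernoulli per trap-occasion
                Y[ind_index[r.individual_id], st_index[r.station_id]] += 1
                seen_cells.add(cell)
        out[site] = CaptureMatrix(
            site=site,
            individuals=individuals,
            stations=[s.station_id for s in site_stations],
            occasions=n_occ,
            X=X,
            Y=Y,
        )
    return out
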