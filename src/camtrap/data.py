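"""Domain types shared by every stage of the camera-trap pipeline.

Coordinates are planar projected kilometres (UTM-like); all distances are
Euclidean. Survey days are 1-based closed intervals: day 1 is the first
survey day. Photo timestamps have minute resolution; capture records have
day resolution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Sequence

import numpy as np

DEFAULT_SITES = ("Lorocachi", "Tiputini", "Keweriono", "Maxus Road")

#: Prey species roster with the ungulate / non-ungulate split used for the
#: biomass index classes.  Pumas are excluded from every biomass class.
UNGULATES = (
    "white-lipped peccary",
    "collared peccary",
    "amazonian tapir",
    "red brocket",
    "amazonian brown brocket",
)
NON_UNGULATES = ("paca", "black agouti", "armadillo")
BIOMASS_EXCLUDED = ("puma",)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class Station:
    """A paired-camera trap station and its accessibility covariates.

    ``habitat`` is a binary terrain class (0 = ridge, 1 = valley);
    ``cam_spacing`` is the distance in metres between the two cameras of the
    pair and acts as the detection covariate DC. ``active`` holds one boolean
    per survey day.
    """

    station_id: str
    site: str
    x: float
    y: float
    dist_road: float
    dist_river: float
    dist_settlement: float
    habitat: int
    cam_spacing: float
    active: np.ndarray

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError(f"station {self.station_id}: non-finite coordinates")
        for name in ("dist_road", "dist_river", "dist_settlement", "cam_spacing"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"station {self.station_id}: {name} must be >= 0")
        if self.habitat not in (0, 1):
            raise ValidationError(f"station {self.station_id}: habitat must be 0 or 1")

    @property
    def dist_rr(self) -> float:
        """Distance to the nearest road *or* river (covariate RR)."""
        return min(self.dist_road, self.dist_river)

    @property
    def n_days(self) -> int:
        return int(self.active.size)

    @property
    def days_active(self) -> int:
        return int(self.active.sum())


@dataclass(frozen=True)
class PhotoEvent:
    """One photographic record of a species at a station."""

    station_id: str
    species: str
    timestamp: datetime
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValidationError(
                f"photo at {self.station_id} {self.timestamp}: count must be >= 1"
            )


@dataclass(frozen=True)
class SpeciesMass:
    """Mean adult body mass (kg) for one species."""

    species: str
    mass: float

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValidationError(f"{self.species}: mass must be > 0")


@dataclass(frozen=True)
class CaptureRecord:
    """An identified capture of one predator individual."""

    individual_id: str
    station_id: str
    day: int  # 1-based survey day
    site: str


@dataclass
class DetectionMatrix:
    """Station x occasion detection histories for one species.

    ``y`` entries are 1 (detected), 0 (not detected) or NaN (no effort);
    ``effort`` counts active days per station-occasion. NaN appears exactly
    where effort is zero.
    """

    species: str
    stations: list[str]
    occasions: int
    y: np.ndarray
    effort: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.effort = np.asarray(self.effort, dtype=int)
        if self.y.shape != (len(self.stations), self.occasions):
            raise ValidationError("detection matrix dimensions inconsistent")
        if self.effort.shape != self.y.shape:
            raise ValidationError("effort dimensions inconsistent")
        missing = np.isnan(self.y)
        if not np.array_equal(missing, self.effort == 0):
            raise ValidationError("missing entries must coincide with zero effort")

    @property
    def n_detections(self) -> int:
        return int(np.nansum(self.y))


@dataclass
class CaptureMatrix:
    """Per-site individual capture histories for closed-population models.

    ``X``: individual x occasion binary (captured anywhere that occasion);
    ``Y``: individual x station counts of (station, occasion) detections —
    the spatial capture data consumed by the SECR sampler.
    """

    site: str
    individuals: list[str]
    stations: list[str]
    occasions: int
    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=int)
        self.Y = np.asarray(self.Y, dtype=int)
        if self.X.shape != (len(self.individuals), self.occasions):
            raise ValidationError("capture matrix X has wrong shape")
        if self.Y.shape != (len(self.individuals), len(self.stations)):
            raise ValidationError("capture matrix Y has wrong shape")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_captures(self) -> int:
        return int(self.Y.sum())


@dataclass
class RunConfig:
    """Run-wide knobs with the study-design defaults.

    Occupancy occasions are 10 days (9 per 90-day survey); capture-recapture
    occasions are 3 days (30 per survey). The SECR state space buffers the
    trap envelope by 15 km at 1 potential centre per km²; augmentation is
    30x the observed individuals (allowed 20-40x); MCMC discards the first
    50% and keeps every 10th draw.
    """

    survey_days: int = 90
    occ_occasion_days: int = 10
    cr_occasion_days: int = 3
    independence_window_h: float = 1.0
    buffer_km: float = 15.0
    center_density: float = 1.0
    aug_multiplier: int = 30
    mcmc_iters: int = 50_000
    mcmc_max_iters: int = 600_000
    burnin_frac: float = 0.5
    thin: int = 10
    boot_draws: int = 1000
    aicc_n: int | None = None  # effective sample size; None -> station count
    seed: int = 20180103

    def __post_init__(self) -> None:
        for name in (
            "survey_days", "occ_occasion_days", "cr_occasion_days",
            "independence_window_h", "buffer_km", "center_density",
            "aug_multiplier", "mcmc_iters", "thin", "boot_draws",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"config: {name} must be positive")
        if not 0 < self.burnin_frac < 1:
            raise ValidationError("config: burnin_frac must lie in (0, 1)")

    def rng_for(self, stage: str) -> np.random.Generator:
        """Independent reproducible substream for a named pipeline stage."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_stage_key(stage),))
        return np.random.default_rng(ss)


def _stage_key(stage: str) -> int:
    # stable small integer per stage name
    return sum(b * 31 ** i for i, b in enumerate(stage.encode())) % (2**31)


@dataclass
class SurveyBundle:
    """Validated collections for one survey run."""

    stations: list[Station]
    photos: list[PhotoEvent]
    masses: list[SpeciesMass]
    captures: list[CaptureRecord]
    survey_start: date | None = None
    config: RunConfig = field(default_factory=RunConfig)

    @property
    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.stations:
            seen.setdefault(s.site, None)
        return list(seen)

    @property
    def n_individuals(self) -> int:
        return len({c.individual_id for c in self.captures})

    @property
    def n_captures(self) -> int:
        return len(self.captures)

    def station(self, station_id: str) -> Station:
        for s in self.stations:
            if s.station_id == station_id:
                return s
        raise KeyError(station_id)

    def mass_of(self, species: str) -> float:
        for m in self.masses:
            if m.species == species:
                return m.mass
        raise KeyError(species)


def as_dict(obj) -> dict:
    """Shallow dict view of a domain dataclass (numpy arrays kept)."""
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}


def station_covariates(stations: Sequence[Station]) -> dict[str, np.ndarray]:
    """Covariate vectors (RR, ST, H in km/0-1; DC in m) in station order."""
    return {
        "RR": np.array([s.dist_rr for s in stations]),
        "ST": np.array([s.dist_settlement for s in stations]),
        "H": np.array([float(s.habitat) for s in stations]),
        "DC": np.array([s.cam_spacing for s in stations]),
    }
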