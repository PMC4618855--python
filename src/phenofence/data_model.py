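"""Domain types and I/O for phenological observation records.

A volunteered phenological record carries an ID, the calendar year, the
flowering-onset day of year (DOY), and the location (latitude, longitude,
elevation).  Status-monitoring programs additionally provide a dated series
of "Yes"/"No" reports per plant, from which onset DOYs, onset uncertainty
(days between the first "Yes" and the preceding "No") and multiple-onset
flags are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "StatusReport",
    "Observation",
    "RejectedRow",
    "ConflictingReportsError",
    "read_observations",
    "write_observations",
    "read_status_reports",
    "derive_onsets",
    "observations_from_status",
    "write_flagged",
    "VERDICTS",
]

VERDICTS = ("consistent", "inconsistent_early", "inconsistent_late", "unresolved")

#: canonical observation CSV columns
OBS_COLUMNS = [
    "obs_id",
    "year",
    "onset_doy",
    "latitude",
    "longitude",
    "elevation",
    "onset_uncertainty_days",
    "multiple_onset",
]


@dataclass(frozen=True)
class StatusReport:
    """One dated phenophase status report for an individual plant."""

    plant_id: str
    year: int
    doy: int
    status: str  # "yes" | "no"

    def __post_init__(self) -> None:
        if not 1 <= self.doy <= 366:
            raise ValueError(f"doy {self.doy} outside [1, 366]")
        if self.status not in ("yes", "no"):
            raise ValueError(f"status must be 'yes' or 'no', got {self.status!r}")


@dataclass(frozen=True)
class Observation:
    """A single flowering-onset record.

    ``onset_uncertainty_days`` is the gap between the first "Yes" report and
    the preceding "No" (None when no prior "No" exists or the record predates
    status monitoring).  ``location_id`` keys the daily-climate lookup and
    defaults to ``obs_id``.
    """

    obs_id: str
    year: int
    onset_doy: int
    latitude: float
    longitude: float
    elevation: float
    onset_uncertainty_days: int | None = None
    multiple_onset: bool = False
    location_id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.onset_doy <= 366:
            raise ValueError(f"onset_doy {self.onset_doy} outside [1, 366]")
        if self.onset_uncertainty_days is not None and self.onset_uncertainty_days < 1:
            raise ValueError("onset_uncertainty_days must be >= 1 when present")
        if not self.location_id:
            object.__setattr__(self, "location_id", self.obs_id)


@dataclass(frozen=True)
class RejectedRow:
    """A CSV row that failed validation, with the reason it was rejected."""

    row_number: int
    reason: str
    raw: Mapping


class ConflictingReportsError(ValueError):
    """Raised when a plant-year holds both "Yes" and "No" on the same day."""


_DEFAULT_DIALECT = {
    "id": "obs_id",
    "year": "year",
    "doy": "onset_doy",
    "lat": "latitude",
    "lon": "longitude",
    "elev": "elevation",
}


def read_observations(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> tuple[list[Observation], list[RejectedRow]]:
    """Read an observation CSV, validating every row.

    ``dialect`` maps canonical keys (id, year, doy, lat, lon, elev) to the
    column names used in the file; by default the canonical column names
    (obs_id, year, onset_doy, latitude, longitude, elevation) are expected.
    Invalid rows are returned as :class:`RejectedRow`, never silently dropped.
    A missing required column is a hard error naming the column.
    """
    colmap = dict(_DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for key in ("id", "year", "doy", "lat", "lon", "elev"):
        if colmap[key] not in df.columns:
            raise ValueError(f"missing required column {colmap[key]!r}")
    observations: list[Observation] = []
    rejects: list[RejectedRow] = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            unc_raw = row.get("onset_uncertainty_days", "")
            mult_raw = str(row.get("multiple_onset", "")).strip().lower()
            obs = Observation(
                obs_id=str(row[colmap["id"]]),
                year=int(row[colmap["year"]]),
                onset_doy=int(row[colmap["doy"]]),
                latitude=float(row[colmap["lat"]]),
                longitude=float(row[colmap["lon"]]),
                elevation=float(row[colmap["elev"]]),
                onset_uncertainty_days=int(unc_raw) if str(unc_raw).strip() else None,
                multiple_onset=mult_raw in ("true", "1", "yes"),
                location_id=str(row.get("location_id", "")).strip(),
            )
        except (ValueError, KeyError) as exc:
            reason = str(exc)
            if "outside [1, 366]" in reason:
                reason = "doy out of range"
            rejects.append(RejectedRow(row_number=i + 2, reason=reason, raw=row))
            continue
        observations.append(obs)
    return observations, rejects


def write_observations(observations: Sequence[Observation], path: str | Path) -> None:
    """Write observations to CSV in the canonical column order."""
    rows = []
    for o in observations:
        rows.append(
            {
                "obs_id": o.obs_id,
                "year": o.year,
                "onset_doy": o.onset_doy,
                "latitude": round(o.latitude, 6),
                "longitude": round(o.longitude, 6),
                "elevation": round(o.elevation, 6),
                "onset_uncertainty_days": (
                    "" if o.onset_uncertainty_days is None else o.onset_uncertainty_days
                ),
                "multiple_onset": o.multiple_onset,
            }
        )
    pd.DataFrame(rows, columns=OBS_COLUMNS).to_csv(path, index=False)


def read_status_reports(path: str | Path) -> dict[tuple[str, int], list[StatusReport]]:
    """Read a status-report CSV (plant_id, year, doy, status Y/N).

    Returns reports grouped by plant-year and sorted by DOY.  Runs never cross
    calendar years; the grouping enforces that.
    """
    df = pd.read_csv(path, dtype={"plant_id": str})
    groups: dict[tuple[str, int], list[StatusReport]] = {}
    for row in df.to_dict("records"):
        status = str(row["status"]).strip().lower()
        status = {"y": "yes", "n": "no"}.get(status, status)
        rep = StatusReport(
            plant_id=str(row["plant_id"]),
            year=int(row["year"]),
            doy=int(row["doy"]),
            status=status,
        )
        groups.setdefault((rep.plant_id, rep.year), []).append(rep)
    for key in groups:
        groups[key] = sorted(groups[key], key=lambda r: (r.doy, r.status))
    return groups


def derive_onsets(
    reports: Sequence[StatusReport],
) -> tuple[list[tuple[int, int | None]], bool]:
    """Derive onset DOYs and uncertainties from one plant-year of reports.

    An onset is the DOY of each "Yes" that begins a maximal run of "Yes"
    reports.  Its uncertainty is that DOY minus the DOY of the nearest
    preceding "No" (None when the series opens with "Yes").  ``multiple_onset``
    is True when a "Yes" run is followed by at least one "No" and a later
    "Yes" run; every run-initial "Yes" is then returned as an onset.

    Same-day conflicting reports ("Yes" and "No" on one DOY) raise
    :class:`ConflictingReportsError`: the plant-year cannot be interpreted.
    """
    if not reports:
        return [], False
    # de-duplicate identical (doy, status) pairs, then detect conflicts
    seen: dict[int, str] = {}
    for r in reports:
        if r.doy in seen and seen[r.doy] != r.status:
            raise ConflictingReportsError(
                f"plant {r.plant_id!r} year {r.year}: conflicting reports on doy {r.doy}"
            )
        seen[r.doy] = r.status
    days = sorted(seen)
    onsets: list[tuple[int, int | None]] = []
    last_no: int | None = None
    prev_status: str | None = None
    for d in days:
        status = seen[d]
        if status == "yes" and prev_status != "yes":
            onsets.append((d, None if last_no is None else d - last_no))
        if status == "no":
            last_no = d
        prev_status = status
    return onsets, len(onsets) > 1


def observations_from_status(
    groups: Mapping[tuple[str, int], Sequence[StatusReport]],
    locations: Mapping[str, tuple[float, float, float]],
    one_per_plant_year: bool = False,
) -> tuple[list[Observation], list[RejectedRow]]:
    """Build observations from status series plus a plant location table.

    ``locations`` maps plant_id to (latitude, longitude, elevation).  With
    ``one_per_plant_year`` only the first onset of a multiple-onset plant-year
    is kept; otherwise each onset becomes an independent observation carrying
    the multiple-onset flag (both conventions are supported downstream).
    Plant-years with same-day conflicting reports are rejected with a report.
    """
    observations: list[Observation] = []
    rejects: list[RejectedRow] = []
    for idx, ((plant_id, year), reports) in enumerate(sorted(groups.items())):
        try:
            onsets, multiple = derive_onsets(list(reports))
        except ConflictingReportsError as exc:
            rejects.append(RejectedRow(row_number=idx, reason=str(exc), raw={}))
            continue
        if not onsets:
            continue
        lat, lon, elev = locations[plant_id]
        kept = onsets[:1] if one_per_plant_year else onsets
        for j, (doy, unc) in enumerate(kept):
            suffix = f"-{j}" if len(kept) > 1 else ""
            observations.append(
                Observation(
                    obs_id=f"{plant_id}-{year}{suffix}",
                    year=year,
                    onset_doy=doy,
                    latitude=lat,
                    longitude=lon,
                    elevation=elev,
                    onset_uncertainty_days=unc,
                    multiple_onset=multiple,
                    location_id=plant_id,
                )
            )
    return observations, rejects


def write_flagged(observations: Sequence[Observation], flags, path: str | Path) -> None:
    """Write observations with their consistency verdicts to CSV.

    ``flags`` is a sequence of :class:`~phenofence.outlier_flag.ConsistencyFlag`
    aligned with ``observations`` (one per observation, same order).
    """
    if len(flags) != len(observations):
        raise ValueError(
            f"{len(observations)} observations but {len(flags)} flags"
        )
    rows = []
    for o, f in zip(observations, flags):
        if f.obs_id != o.obs_id:
            raise ValueError(f"flag/observation mismatch at obs_id {o.obs_id!r}")
        rows.append(
            {
                "obs_id": o.obs_id,
                "year": o.year,
                "onset_doy": o.onset_doy,
                "latitude": round(o.latitude, 6),
                "longitude": round(o.longitude, 6),
                "elevation": round(o.elevation, 6),
                "onset_uncertainty_days": (
                    "" if o.onset_uncertainty_days is None else o.onset_uncertainty_days
                ),
                "multiple_onset": o.multiple_onset,
                "cluster": f.cluster,
                "uncertainty": f.uncertainty,
                "flag": f.verdict,
            }
        )
    cols = OBS_COLUMNS + ["cluster", "uncertainty", "flag"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
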