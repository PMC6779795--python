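"""Domain types, long-format table I/O, and data-selection / QC rules.

The unit of analysis is an :class:`ActivityPanel`: the per-neuron,
per-scan-day activity (an immediate-early-gene fluorescence-intensity
proxy for firing) of one cortical location within one laminar
compartment (superficial layers II/III or deep layer V).  Panels are
read from tidy CSV/TSV tables, screened for eligibility (imaged down to
layer Vb on every scan day, not spanning a functional-area border), and
cleaned with the missing-detection policy: a neuron missed by the
detector on at most 3 scan days has each gap filled with that day's
cross-neuron median; a neuron missed on more than 3 days is dropped.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AREA_TYPES = frozenset({"VISp", "VISam", "SSp", "PTLp", "RSC", "Motor"})
HEMISPHERES = frozenset({"L", "R"})
COMPARTMENTS = ("II/III", "V")

#: Table of multimodal environments and the physical box each uses.
#: Context / Training / Retrieval of the same letter share one box; the
#: two stripe stimuli share the visual-stimulation setup.
ENVIRONMENT_BOX: Mapping[str, str] = {
    "H": "home",
    "CA": "A", "TA": "A", "RA": "A",
    "CB": "B", "TB": "B", "RB": "B",
    "TC": "C",
    "EE": "EE",
    "TU": "TU",
    "HS": "stim", "VS": "stim",
}

ENVIRONMENTS = frozenset(ENVIRONMENT_BOX)

# maximum number of scan days a neuron may be missed by the detector and
# still be retained (its gaps are median-imputed)
MAX_MISSED_DAYS = 3


@dataclass
class ActivityPanel:
    """Neurons x scan-days activity of one (location, compartment).

    Parameters
    ----------
    mouse_id, location_id
        Subject and imaging-position labels (e.g. ``"Ma"``, ``"A1"``).
    area_type, hemisphere, compartment
        Structural annotation: functional area type, hemisphere, and
        laminar compartment (``"II/III"`` or ``"V"``).
    neuron_ids
        Unique per-neuron labels; row order of ``activity``.
    scan_days
        Strictly increasing integer day offsets (Day 0 = first scan);
        column order of ``activity``.
    activity
        Dense ``(n_neurons, n_days)`` array of non-negative fluorescence
        intensities; entries under ``missing_mask`` are undefined.
    missing_mask
        Boolean array, same shape; True where the neuron was not
        detected on that day.
    """

    mouse_id: str
    location_id: str
    area_type: str
    hemisphere: str
    compartment: str
    neuron_ids: list[str]
    scan_days: np.ndarray
    activity: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scan_days = np.asarray(self.scan_days, dtype=int)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.activity.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.area_type not in AREA_TYPES:
            raise ValueError(f"unknown area type {self.area_type!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown laminar compartment {self.compartment!r}")
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise ValueError("neuron_ids must be unique")
        if self.activity.shape != (len(self.neuron_ids), len(self.scan_days)):
            raise ValueError(
                f"activity shape {self.activity.shape} does not match "
                f"{len(self.neuron_ids)} neurons x {len(self.scan_days)} days"
            )
        if self.missing_mask.shape != self.activity.shape:
            raise ValueError("missing_mask shape mismatch")
        if len(self.scan_days) > 1 and not np.all(np.diff(self.scan_days) > 0):
            raise ValueError("scan_days must be strictly increasing")
        if np.any(self.scan_days < 0):
            raise ValueError("scan_days must be non-negative day offsets")
        observed = ~self.missing_mask
        if not np.all(np.isfinite(self.activity[observed])):
            raise ValueError("observed activity must be finite")

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def n_days(self) -> int:
        return len(self.scan_days)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.mouse_id, self.location_id, self.compartment)

    def day_index(self, day: int) -> int:
        """Column index of a scan day; raises KeyError if not scanned."""
        idx = np.searchsorted(self.scan_days, day)
        if idx >= len(self.scan_days) or self.scan_days[idx] != day:
            raise KeyError(f"day {day} not in panel {self.key}")
        return int(idx)

    def subset_neurons(self, rows: Sequence[int]) -> "ActivityPanel":
        rows = np.asarray(rows, dtype=int)
        return dataclasses.replace(
            self,
            neuron_ids=[self.neuron_ids[i] for i in rows],
            activity=self.activity[rows].copy(),
            missing_mask=self.missing_mask[rows].copy(),
        )


@dataclass
class ScheduleEntry:
    scan_index: int
    day: int
    environment: str
    box_id: str


@dataclass
class EnvironmentSchedule:
    """Ordered scan days S_0..S_n with environment and box identity.

    Scan index k labels S_k; ``day`` is the calendar offset of that scan
    (Day 0 = first scan).  Each environment maps to exactly one physical
    box (Context/Training/Retrieval of the same letter share a box).
    """

    mouse_id: str
    entries: list[ScheduleEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("schedule has no entries")
        if self.entries[0].scan_index != 0:
            raise ValueError("first entry must be scan index 0 (S_0)")
        for prev, cur in zip(self.entries, self.entries[1:]):
            if cur.day <= prev.day:
                raise ValueError("schedule days must be strictly increasing")
            if cur.scan_index != prev.scan_index + 1:
                raise ValueError("scan indices must be consecutive from 0")
        for e in self.entries:
            if e.environment not in ENVIRONMENTS:
                raise ValueError(f"unknown environment {e.environment!r}")
            if e.box_id != ENVIRONMENT_BOX[e.environment]:
                raise ValueError(
                    f"environment {e.environment} must use box "
                    f"{ENVIRONMENT_BOX[e.environment]!r}, got {e.box_id!r}"
                )

    @property
    def days(self) -> np.ndarray:
        return np.array([e.day for e in self.entries], dtype=int)

    @property
    def environments(self) -> list[str]:
        return [e.environment for e in self.entries]

    def environment_on(self, day: int) -> str:
        for e in self.entries:
            if e.day == day:
                return e.environment
        raise KeyError(f"day {day} not in schedule for {self.mouse_id}")

    @classmethod
    def from_environments(
        cls, mouse_id: str, days: Sequence[int], environments: Sequence[str]
    ) -> "EnvironmentSchedule":
        """Build a schedule from day offsets and environment labels;
        box identities are filled in from the canonical mapping."""
        if len(days) != len(environments):
            raise ValueError("days and environments must have equal length")
        entries = [
            ScheduleEntry(k, int(d), env, ENVIRONMENT_BOX[env])
            for k, (d, env) in enumerate(zip(days, environments))
        ]
        return cls(mouse_id=mouse_id, entries=entries)


@dataclass
class LocationInfo:
    """Per-location eligibility metadata."""

    area_type: str
    hemisphere: str
    scanned_to_Vb_all_days: bool = True
    cross_functional: bool = False


@dataclass
class CohortMetadata:
    """Per-mouse summary: locations with eligibility flags plus scan counts."""

    mouse_id: str
    locations: dict[str, LocationInfo] = field(default_factory=dict)
    scanned_length_days: int = 0
    scanned_times: int = 0

    def __post_init__(self) -> None:
        if self.scanned_length_days < 0 or self.scanned_times < 0:
            raise ValueError("scan counts must be non-negative")


# ---------------------------------------------------------------------------
# table I/O

_ACTIVITY_COLUMNS = ["mouse", "location", "compartment", "neuron", "day", "value"]


def _read_table(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    # round_trip float parsing keeps reader∘writer lossless
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_panels(
    activity_table_path: Path | str, metadata_table_path: Path | str
) -> list[ActivityPanel]:
    """Read long-format activity and location-metadata tables into panels.

    The activity table needs columns (mouse, location, compartment,
    neuron, day, value); the metadata table is keyed by (mouse, location)
    with columns (area_type, hemisphere) and optional eligibility flags
    (scanned_to_Vb_all_days, cross_functional).  One panel is built per
    (mouse, location, compartment); a (neuron, day) cell absent from the
    table becomes a missing_mask entry.
    """
    act = _read_table(activity_table_path)
    missing_cols = [c for c in _ACTIVITY_COLUMNS if c not in act.columns]
    if missing_cols:
        raise ValueError(f"activity table lacks columns {missing_cols}")

    dup = act.duplicated(subset=["mouse", "location", "compartment", "neuron", "day"])
    if dup.any():
        rows = (act.index[dup] + 2).tolist()  # +2: header + 0-based index
        raise ValueError(f"duplicate (neuron, day) rows at file lines {rows}")

    bad_comp = sorted(set(act["compartment"]) - set(COMPARTMENTS))
    if bad_comp:
        raise ValueError(f"unknown compartment labels {bad_comp}")

    meta = _read_table(metadata_table_path).set_index(["mouse", "location"])
    bad_area = sorted(set(meta["area_type"]) - AREA_TYPES)
    if bad_area:
        raise ValueError(f"unknown area labels {bad_area}")

    panels: list[ActivityPanel] = []
    for (mouse, loc, comp), grp in act.groupby(
        ["mouse", "location", "compartment"], sort=True
    ):
        try:
            info = meta.loc[(mouse, loc)]
        except KeyError:
            raise ValueError(f"no metadata row for ({mouse}, {loc})") from None
        wide = grp.pivot(index="neuron", columns="day", values="value")
        wide = wide.sort_index(axis=1)
        mask = wide.isna().to_numpy()
        panels.append(
            ActivityPanel(
                mouse_id=str(mouse),
                location_id=str(loc),
                area_type=str(info["area_type"]),
                hemisphere=str(info["hemisphere"]),
                compartment=str(comp),
                neuron_ids=[str(n) for n in wide.index],
                scan_days=wide.columns.to_numpy(dtype=int),
                activity=np.nan_to_num(wide.to_numpy(dtype=float)),
                missing_mask=mask,
            )
        )
    return panels


def panels_to_frame(panels: Sequence[ActivityPanel]) -> pd.DataFrame:
    """Tidy long-format frame of all observed (non-missing) cells."""
    parts = []
    for p in panels:
        neu, day = np.nonzero(~p.missing_mask)
        parts.append(
            pd.DataFrame(
                {
                    "mouse": p.mouse_id,
                    "location": p.location_id,
                    "compartment": p.compartment,
                    "neuron": [p.neuron_ids[i] for i in neu],
                    "day": p.scan_days[day],
                    "value": p.activity[neu, day],
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_panels(
    panels: Sequence[ActivityPanel],
    activity_table_path: Path | str,
    metadata_table_path: Path | str,
) -> None:
    """Write panels as the long-format activity + metadata tables read
    by :func:`read_panels` (lossless round trip for observed cells)."""
    activity_table_path = Path(activity_table_path)
    sep = "\t" if activity_table_path.suffix.lower() in {".tsv", ".tab"} else ","
    # %.17g guarantees a lossless IEEE-754 double round trip
    panels_to_frame(panels).to_csv(
        activity_table_path, sep=sep, index=False, float_format="%.17g"
    )

    seen: dict[tuple[str, str], dict] = {}
    for p in panels:
        seen.setdefault(
            (p.mouse_id, p.location_id),
            {
                "mouse": p.mouse_id,
                "location": p.location_id,
                "area_type": p.area_type,
                "hemisphere": p.hemisphere,
                "scanned_to_Vb_all_days": True,
                "cross_functional": False,
            },
        )
    pd.DataFrame(list(seen.values())).to_csv(metadata_table_path, index=False)


def read_schedule(path: Path | str) -> EnvironmentSchedule:
    """Read a schedule CSV with columns (mouse, scan_index, day, environment, box)."""
    df = _read_table(path)
    mice = df["mouse"].unique()
    if len(mice) != 1:
        raise ValueError("schedule file must describe exactly one mouse")
    df = df.sort_values("scan_index")
    entries = [
        ScheduleEntry(int(r.scan_index), int(r.day), str(r.environment), str(r.box))
        for r in df.itertuples()
    ]
    return EnvironmentSchedule(mouse_id=str(mice[0]), entries=entries)


def write_schedule(schedule: EnvironmentSchedule, path: Path | str) -> None:
    pd.DataFrame(
        {
            "mouse": schedule.mouse_id,
            "scan_index": [e.scan_index for e in schedule.entries],
            "day": [e.day for e in schedule.entries],
            "environment": [e.environment for e in schedule.entries],
            "box": [e.box_id for e in schedule.entries],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QC rules


def apply_missing_policy(panel: ActivityPanel) -> ActivityPanel:
    """Impute short detection gaps, drop chronically missed neurons.

    Neurons missed on more than :data:`MAX_MISSED_DAYS` scan days are
    excluded; each remaining missing cell is filled with the median of
    all other (detected) neurons of the same panel on that day.
    Observed values are never altered.
    """
    missed_days = panel.missing_mask.sum(axis=1)
    keep = np.nonzero(missed_days <= MAX_MISSED_DAYS)[0]
    out = panel.subset_neurons(keep)

    activity = out.activity.copy()
    mask = out.missing_mask
    for j in range(out.n_days):
        col_missing = mask[:, j]
        if not col_missing.any():
            continue
        observed = panel.activity[~panel.missing_mask[:, j], j]
        if observed.size == 0:
            raise ValueError(
                f"day {panel.scan_days[j]} has no detected neurons; "
                "cross-neuron median undefined"
            )
        activity[col_missing, j] = np.median(observed)

    return dataclasses.replace(
        out, activity=activity, missing_mask=np.zeros_like(mask)
    )


def select_eligible_locations(
    panels: Sequence[ActivityPanel], cohort: CohortMetadata
) -> list[ActivityPanel]:
    """Keep only locations imaged to layer Vb on every scan day and not
    straddling a functional-region border (both compartments of an
    ineligible location are dropped)."""
    kept = []
    for p in panels:
        if p.mouse_id != cohort.mouse_id:
            continue
        info = cohort.locations.get(p.location_id)
        if info is None:
            continue
        if info.scanned_to_Vb_all_days and not info.cross_functional:
            kept.append(p)
    return kept
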