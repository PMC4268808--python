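"""Core domain types and tabular I/O for serial-CT implant geometry.

Coordinate convention (fixed package-wide, millimetres):

* ``x`` — left–right (L-R) axis, positive towards patient left;
* ``y`` — caudo-cranial (C-C) axis, positive towards caudal;
* ``z`` — dorso-ventral (D-V) axis, positive towards ventral.

Dwell positions are the discrete source stopping points inside each
implanted catheter (nominally 5 mm apart along the catheter) and serve as
a spatial proxy for the catheter.  Because the planning software defines
them identically on every scan, the pair ``(catheter_id, dwell_index)``
gives a one-to-one correspondence between scans of the same patient, which
every paired analysis in this package relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import math

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "SCAN_IDS",
    "MARKER_LABELS",
    "Point3",
    "DwellPosition",
    "MarkerSet",
    "ImplantSnapshot",
    "PatientSeries",
    "PairedDwells",
    "paired_dwells",
    "read_series",
    "write_series",
]

SCAN_IDS = ("CT1", "CT2", "CT3")
MARKER_LABELS = ("base_1", "base_2", "apex")

DWELL_COLUMNS = [
    "patient_id",
    "scan_id",
    "catheter_id",
    "dwell_index",
    "x_mm",
    "y_mm",
    "z_mm",
    "in_target",
]
MARKER_COLUMNS = ["patient_id", "scan_id", "marker_label", "x_mm", "y_mm", "z_mm"]
VOLUME_COLUMNS = ["patient_id", "scan_id", "volume_cm3"]

#: markers closer than this to a common line are treated as collinear
#: (cross-product area test); rotation about the marker axis would be
#: unidentifiable for the rigid fit.
COLLINEARITY_AREA_TOL_MM2 = 1e-6


class FormatError(ValueError):
    """An input table does not conform to the expected CSV dialect."""


class ValidationError(ValueError):
    """Input data violates a domain invariant."""


@dataclass(frozen=True)
class Point3:
    """A coordinate triple in the implant frame (mm): L-R, C-C, D-V."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValidationError(f"non-finite coordinate: {self!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(arr: Sequence[float]) -> "Point3":
        x, y, z = (float(v) for v in arr)
        return Point3(x, y, z)


@dataclass(frozen=True)
class DwellPosition:
    """One source stopping point inside a catheter.

    ``in_target`` flags dwells inside the prostate plus a 5 mm margin; only
    in-target dwells enter the paired analyses.  The flag is an input, not
    recomputed from a contour.
    """

    catheter_id: str
    dwell_index: int
    position: Point3
    in_target: bool

    def __post_init__(self) -> None:
        if self.dwell_index < 0:
            raise ValidationError(
                f"dwell_index must be non-negative, got {self.dwell_index}"
            )


@dataclass(frozen=True)
class MarkerSet:
    """Exactly three labelled fiducial markers: two base, one apex."""

    base_1: Point3
    base_2: Point3
    apex: Point3

    def __post_init__(self) -> None:
        a, b, c = (p.as_array() for p in (self.base_1, self.base_2, self.apex))
        area2 = np.linalg.norm(np.cross(b - a, c - a))
        if area2 <= COLLINEARITY_AREA_TOL_MM2:
            raise ValidationError(
                "markers are collinear (rotation about their axis is "
                "unidentifiable for rigid registration)"
            )

    def labelled(self) -> list[tuple[str, Point3]]:
        return list(zip(MARKER_LABELS, (self.base_1, self.base_2, self.apex)))

    def as_array(self) -> np.ndarray:
        """Marker coordinates as a (3, 3) array in label order."""
        return np.stack([p.as_array() for _, p in self.labelled()])

    @staticmethod
    def from_array(arr: np.ndarray) -> "MarkerSet":
        return MarkerSet(*(Point3.from_array(row) for row in np.asarray(arr, float)))


@dataclass(frozen=True)
class ImplantSnapshot:
    """One timepoint's dwell positions plus marker set.

    ``reference_volume_cm3`` optionally carries the delineated prostate
    volume, used only to convert relative volume changes to cm³.
    """

    scan_id: str
    dwells: tuple[DwellPosition, ...]
    markers: MarkerSet
    reference_volume_cm3: float | None = None

    def __post_init__(self) -> None:
        if self.scan_id not in SCAN_IDS:
            raise ValidationError(
                f"scan_id must be one of {SCAN_IDS}, got {self.scan_id!r}"
            )
        keys = [(d.catheter_id, d.dwell_index) for d in self.dwells]
        if len(keys) != len(set(keys)):
            raise ValidationError(
                f"duplicate (catheter_id, dwell_index) keys in scan {self.scan_id}"
            )
        catheters = {d.catheter_id for d in self.dwells}
        n_in = sum(d.in_target for d in self.dwells)
        if len(catheters) < 2 or n_in < 3:
            raise ValidationError(
                f"scan {self.scan_id}: need >= 2 catheters and >= 3 in-target "
                f"dwells (got {len(catheters)} catheters, {n_in} in-target)"
            )
        # canonical ordering so construction is row-order independent
        object.__setattr__(
            self,
            "dwells",
            tuple(sorted(self.dwells, key=lambda d: (d.catheter_id, d.dwell_index))),
        )

    @property
    def catheter_ids(self) -> frozenset[str]:
        return frozenset(d.catheter_id for d in self.dwells)

    def in_target_map(self) -> dict[tuple[str, int], np.ndarray]:
        """(catheter_id, dwell_index) -> coordinate array, in-target only."""
        return {
            (d.catheter_id, d.dwell_index): d.position.as_array()
            for d in self.dwells
            if d.in_target
        }

    def in_target_points(self) -> np.ndarray:
        """In-target dwell coordinates as an (n, 3) array, canonical order."""
        m = self.in_target_map()
        return np.stack([m[k] for k in sorted(m)])


@dataclass(frozen=True)
class PatientSeries:
    """2–3 correspondence-guaranteed snapshots for one patient."""

    patient_id: str
    snapshots: tuple[ImplantSnapshot, ...]

    def __post_init__(self) -> None:
        n = len(self.snapshots)
        if not 2 <= n <= 3:
            raise ValidationError(
                f"patient {self.patient_id}: need 2-3 snapshots, got {n}"
            )
        order = [SCAN_IDS.index(s.scan_id) for s in self.snapshots]
        object.__setattr__(
            self,
            "snapshots",
            tuple(s for _, s in sorted(zip(order, self.snapshots))),
        )
        ids = [s.scan_id for s in self.snapshots]
        if len(set(ids)) != len(ids):
            raise ValidationError(
                f"patient {self.patient_id}: duplicate scan ids {ids}"
            )
        cats = {s.scan_id: s.catheter_ids for s in self.snapshots}
        first = self.snapshots[0].catheter_ids
        for s in self.snapshots[1:]:
            if s.catheter_ids != first:
                raise ValidationError(
                    f"patient {self.patient_id}: catheter sets differ between "
                    f"scans {dict((k, sorted(v)) for k, v in cats.items())}"
                )

    @property
    def scan_ids(self) -> tuple[str, ...]:
        return tuple(s.scan_id for s in self.snapshots)

    def snapshot(self, scan_id: str) -> ImplantSnapshot:
        for s in self.snapshots:
            if s.scan_id == scan_id:
                return s
        raise KeyError(f"patient {self.patient_id} has no scan {scan_id}")

    def has_scan(self, scan_id: str) -> bool:
        return scan_id in self.scan_ids


@dataclass(frozen=True)
class PairedDwells:
    """Corresponding in-target dwell coordinates of two snapshots.

    One row per (catheter_id, dwell_index) key in-target in *both*
    snapshots, ordered by catheter_id then dwell_index.
    """

    keys: tuple[tuple[str, int], ...]
    points_a: np.ndarray  # (n, 3)
    points_b: np.ndarray  # (n, 3)

    def __len__(self) -> int:
        return len(self.keys)


def paired_dwells(snapshot_a: ImplantSnapshot, snapshot_b: ImplantSnapshot) -> PairedDwells:
    """Match in-target dwells of two snapshots by (catheter_id, dwell_index).

    Raises :class:`ValidationError` if the intersection is empty — such an
    implant pair is unusable for any paired analysis.
    """
    map_a = snapshot_a.in_target_map()
    map_b = snapshot_b.in_target_map()
    keys = sorted(set(map_a) & set(map_b))
    if not keys:
        raise ValidationError(
            f"no (catheter, dwell) key is in-target on both {snapshot_a.scan_id} "
            f"and {snapshot_b.scan_id}"
        )
    a = np.stack([map_a[k] for k in keys])
    b = np.stack([map_b[k] for k in keys])
    return PairedDwells(tuple(keys), a, b)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_series(
    dwell_table_path: str | Path,
    marker_table_path: str | Path,
    volume_table_path: str | Path | None = None,
) -> list[PatientSeries]:
    """Read patient series from the dwell/marker (and optional volume) CSVs.

    Row order in the input never affects the result: rows are canonically
    sorted during construction.
    """
    # round_trip parsing: the default float parser can be 1 ulp off, which
    # would break the write->read identity
    dwells = pd.read_csv(dwell_table_path, float_precision="round_trip")
    markers = pd.read_csv(marker_table_path, float_precision="round_trip")
    _require_columns(dwells, DWELL_COLUMNS, str(dwell_table_path))
    _require_columns(markers, MARKER_COLUMNS, str(marker_table_path))

    volumes: dict[tuple[str, str], float] = {}
    if volume_table_path is not None:
        vol = pd.read_csv(volume_table_path)
        _require_columns(vol, VOLUME_COLUMNS, str(volume_table_path))
        for row in vol.itertuples(index=False):
            volumes[(str(row.patient_id), str(row.scan_id))] = float(row.volume_cm3)

    dup = dwells.duplicated(
        subset=["patient_id", "scan_id", "catheter_id", "dwell_index"]
    )
    if dup.any():
        first = dwells[dup].iloc[0]
        raise ValidationError(
            "duplicate dwell key (patient={}, scan={}, catheter={}, index={})".format(
                first.patient_id, first.scan_id, first.catheter_id, first.dwell_index
            )
        )

    bad_scan = set(dwells["scan_id"].astype(str)) - set(SCAN_IDS)
    if bad_scan:
        raise ValidationError(f"unknown scan_id values {sorted(bad_scan)}")

    series: list[PatientSeries] = []
    marker_groups = {
        (str(p), str(s)): g
        for (p, s), g in markers.groupby(["patient_id", "scan_id"], sort=True)
    }
    for patient_id, pgroup in dwells.groupby("patient_id", sort=True):
        patient_id = str(patient_id)
        snapshots = []
        for scan_id, sgroup in pgroup.groupby("scan_id", sort=True):
            scan_id = str(scan_id)
            mk = marker_groups.get((patient_id, scan_id))
            if mk is None or len(mk) != 3 or set(mk["marker_label"]) != set(MARKER_LABELS):
                n = 0 if mk is None else len(mk)
                raise ValidationError(
                    f"patient {patient_id}, scan {scan_id}: expected exactly 3 "
                    f"markers labelled {MARKER_LABELS}, got {n}"
                )
            by_label = {
                str(r.marker_label): Point3(float(r.x_mm), float(r.y_mm), float(r.z_mm))
                for r in mk.itertuples(index=False)
            }
            dwell_objs = tuple(
                DwellPosition(
                    catheter_id=str(r.catheter_id),
                    dwell_index=int(r.dwell_index),
                    position=Point3(float(r.x_mm), float(r.y_mm), float(r.z_mm)),
                    in_target=bool(int(r.in_target)),
                )
                for r in sgroup.itertuples(index=False)
            )
            snapshots.append(
                ImplantSnapshot(
                    scan_id=scan_id,
                    dwells=dwell_objs,
                    markers=MarkerSet(
                        by_label["base_1"], by_label["base_2"], by_label["apex"]
                    ),
                    reference_volume_cm3=volumes.get((patient_id, scan_id)),
                )
            )
        series.append(PatientSeries(patient_id=patient_id, snapshots=tuple(snapshots)))
    return series


def write_series(
    series: Iterable[PatientSeries],
    dwell_table_path: str | Path,
    marker_table_path: str | Path,
    volume_table_path: str | Path | None = None,
) -> None:
    """Write series to the CSV dialects; inverse of :func:`read_series`.

    Coordinates are written with ``repr`` precision so a read-back
    reproduces every float bit-exactly.
    """
    dwell_rows, marker_rows, volume_rows = [], [], []
    for s in series:
        for snap in s.snapshots:
            for d in snap.dwells:
                dwell_rows.append(
                    (
                        s.patient_id,
                        snap.scan_id,
                        d.catheter_id,
                        d.dwell_index,
                        repr(d.position.x),
                        repr(d.position.y),
                        repr(d.position.z),
                        int(d.in_target),
                    )
                )
            for label, p in snap.markers.labelled():
                marker_rows.append(
                    (s.patient_id, snap.scan_id, label, repr(p.x), repr(p.y), repr(p.z))
                )
            if snap.reference_volume_cm3 is not None:
                volume_rows.append(
                    (s.patient_id, snap.scan_id, repr(snap.reference_volume_cm3))
                )
    pd.DataFrame(dwell_rows, columns=DWELL_COLUMNS).to_csv(dwell_table_path, index=False)
    pd.DataFrame(marker_rows, columns=MARKER_COLUMNS).to_csv(marker_table_path, index=False)
    if volume_table_path is not None:
        pd.DataFrame(volume_rows, columns=VOLUME_COLUMNS).to_csv(
            volume_table_path, index=False
        )
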