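"""Canonical 24-2 visual-field grid, test records, eye mirroring, and tabular I/O.

The 24-2 Humphrey grid samples 54 locations on a 6-degree lattice across the
central 24 degrees; two locations fall on the physiologic blind spot and carry
no usable total-deviation value (TDV), leaving the 52 locations every vector
in this package is built on.  All coordinates are kept in right-eye
convention: x positive toward the temporal side, y positive superior.

The canonical ordering is row-major, superior row first, x ascending within
each row.  It is frozen here because archetype vectors, CSV columns and every
downstream decomposition depend on a single immutable indexing.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("vfdecomp")

DAYS_PER_YEAR = 365.25

#: TDV validity range in dB; values outside are instrument-impossible.
TDV_MIN_DB = -50.0
TDV_MAX_DB = 20.0

# x offsets per |y| ring of the 24-2 lattice; the lone +27 column is the
# nasal-step extension present on one side only.
_ROW_X: dict[int, tuple[int, ...]] = {
    21: (-9, -3, 3, 9),
    15: (-15, -9, -3, 3, 9, 15),
    9: (-21, -15, -9, -3, 3, 9, 15, 21),
    3: (-21, -15, -9, -3, 3, 9, 15, 21, 27),
}

_BLIND_SPOTS = frozenset({(15, 3), (15, -3)})


@dataclass(frozen=True)
class GridLocation:
    """One test location of the 24-2 grid (right-eye convention)."""

    index: int
    x_deg: int
    y_deg: int
    blind_spot: bool


@dataclass(frozen=True)
class Vf242Grid:
    """The fixed 54-location 24-2 grid with its 52 active (non-blind-spot) points."""

    locations: tuple[GridLocation, ...]
    active_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.locations) != 54 or len(self.active_indices) != 52:
            raise ValueError("24-2 grid must have 54 locations, 52 active")

    @property
    def active_locations(self) -> tuple[GridLocation, ...]:
        return tuple(self.locations[i] for i in self.active_indices)

    def active_coords(self) -> np.ndarray:
        """(52, 2) array of (x_deg, y_deg) for the active locations."""
        return np.array([(l.x_deg, l.y_deg) for l in self.active_locations])

    def mirror_permutation(self) -> np.ndarray:
        """Permutation p over the 52 active positions mapping (x, y) -> (-x, y).

        Locations whose horizontal mirror is not an active grid point (the
        +27 nasal-step column and the active partners of the blind spot) map
        to themselves, making the permutation an involution on the full set.
        """
        coords = {(l.x_deg, l.y_deg): k for k, l in enumerate(self.active_locations)}
        perm = np.empty(52, dtype=np.intp)
        for k, loc in enumerate(self.active_locations):
            perm[k] = coords.get((-loc.x_deg, loc.y_deg), k)
        return perm


def canonical_grid() -> Vf242Grid:
    """Return the canonical 24-2 grid (pure constant, identical on every call)."""
    locations: list[GridLocation] = []
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        for x in _ROW_X[abs(y)]:
            locations.append(
                GridLocation(
                    index=len(locations),
                    x_deg=x,
                    y_deg=y,
                    blind_spot=(x, y) in _BLIND_SPOTS,
                )
            )
    active = tuple(l.index for l in locations if not l.blind_spot)
    return Vf242Grid(locations=tuple(locations), active_indices=active)


_GRID = canonical_grid()
_MIRROR_PERM = _GRID.mirror_permutation()


@dataclass(frozen=True)
class VisualFieldTest:
    """A single 24-2 exam: metadata, reliability indices and 52 TDVs.

    ``tdv`` is in canonical right-eye order regardless of the tested eye;
    for left eyes the positions carry anatomically mirrored meaning until
    :func:`mirror_to_right_eye` is applied.
    """

    patient_id: str
    eye: str  # "L" | "R"
    exam_date: _dt.date
    age_years: float
    fixation_loss_rate: float
    false_negative_rate: float
    false_positive_rate: float
    md_db: float
    psd_db: float
    vfi_pct: float
    tdv: np.ndarray  # 52 total-deviation values, dB

    def __post_init__(self) -> None:
        if self.eye not in ("L", "R"):
            raise ValueError(f"eye must be 'L' or 'R', got {self.eye!r}")
        tdv = np.asarray(self.tdv, dtype=float)
        object.__setattr__(self, "tdv", tdv)
        if tdv.shape != (52,):
            raise ValueError(f"tdv must have 52 entries, got shape {tdv.shape}")
        if not np.all(np.isfinite(tdv)):
            raise ValueError("tdv contains non-finite values")
        if tdv.min() < TDV_MIN_DB or tdv.max() > TDV_MAX_DB:
            raise ValueError(
                f"tdv outside [{TDV_MIN_DB}, {TDV_MAX_DB}] dB: "
                f"range [{tdv.min():.1f}, {tdv.max():.1f}]"
            )
        for name in ("fixation_loss_rate", "false_negative_rate", "false_positive_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name}={r} outside [0, 1]")
        if not 0.0 <= self.vfi_pct <= 100.0:
            raise ValueError(f"vfi_pct={self.vfi_pct} outside [0, 100]")


def mirror_to_right_eye(test: VisualFieldTest) -> VisualFieldTest:
    """Express a test in right-eye format.

    Right-eye tests are returned unchanged.  Left-eye tests have their TDV
    vector re-indexed by the grid's horizontal mirror map (x -> -x) and the
    eye label set to "R".  Idempotent: mirroring twice equals mirroring once.
    """
    if test.eye == "R":
        return test
    if test.eye != "L":
        raise ValueError(f"unknown eye label {test.eye!r}")
    mirrored = test.tdv[_MIRROR_PERM]
    return replace(test, eye="R", tdv=mirrored)


@dataclass(frozen=True)
class EyeSeries:
    """Time-ordered visits of one eye, with elapsed times in years from baseline."""

    patient_id: str
    eye: str
    visits: tuple[VisualFieldTest, ...]
    t_years: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        dates = [v.exam_date for v in self.visits]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("visit exam dates must be strictly increasing")
        if self.t_years is None and self.visits:
            t0 = dates[0]
            t = np.array([(d - t0).days / DAYS_PER_YEAR for d in dates])
            object.__setattr__(self, "t_years", t)
        elif self.t_years is None:
            object.__setattr__(self, "t_years", np.empty(0))
        else:
            t = np.asarray(self.t_years, dtype=float)
            object.__setattr__(self, "t_years", t)
            if len(t) != len(self.visits):
                raise ValueError("t_years length must match visits")
            if len(t) and t[0] != 0.0:
                raise ValueError("t_years must start at 0")

    def __len__(self) -> int:
        return len(self.visits)

    @property
    def followup_years(self) -> float:
        return float(self.t_years[-1]) if len(self) else 0.0

    def md_values(self) -> np.ndarray:
        return np.array([v.md_db for v in self.visits])

    def vfi_values(self) -> np.ndarray:
        return np.array([v.vfi_pct for v in self.visits])

    def tdv_matrix(self) -> np.ndarray:
        """(n_visits, 52) TDV matrix."""
        return np.vstack([v.tdv for v in self.visits]) if self.visits else np.empty((0, 52))


def group_into_series(tests: Iterable[VisualFieldTest]) -> list[EyeSeries]:
    """Group tests by (patient_id, eye) into chronologically sorted series."""
    by_eye: dict[tuple[str, str], list[VisualFieldTest]] = {}
    for t in tests:
        by_eye.setdefault((t.patient_id, t.eye), []).append(t)
    out = []
    for (pid, eye), visits in sorted(by_eye.items()):
        visits.sort(key=lambda v: v.exam_date)
        out.append(EyeSeries(patient_id=pid, eye=eye, visits=tuple(visits)))
    return out


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "patient_id", "eye", "exam_date", "age_years",
    "fl_rate", "fn_rate", "fp_rate", "md_db", "psd_db", "vfi_pct",
]
_TD_COLUMNS = [f"td_{i:02d}" for i in range(1, 55)]
_BLIND_TD_COLUMNS = [_TD_COLUMNS[i] for i in range(54) if _GRID.locations[i].blind_spot]
_ACTIVE_TD_COLUMNS = [_TD_COLUMNS[i] for i in _GRID.active_indices]


def read_vf_table(path, *, rates: str = "fraction") -> list[VisualFieldTest]:
    """Read visual-field test records from CSV.

    One row per exam; 54 ``td_XX`` columns in canonical grid order, the two
    blind-spot columns optional/ignored.  Rows violating record invariants
    are rejected with row-numbered log diagnostics; left eyes are NOT
    auto-mirrored.

    Parameters
    ----------
    rates
        "fraction" if reliability columns are in [0, 1], "percent" if in
        [0, 100]; internal representation is always fraction.
    """
    if rates not in ("fraction", "percent"):
        raise ValueError("rates must be 'fraction' or 'percent'")
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = _META_COLUMNS + _ACTIVE_TD_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    scale = 0.01 if rates == "percent" else 1.0
    tests: list[VisualFieldTest] = []
    for i, row in df.iterrows():
        try:
            exam_date = _dt.date.fromisoformat(str(row["exam_date"]))
            tdv = row[_ACTIVE_TD_COLUMNS].to_numpy(dtype=float)
            tests.append(
                VisualFieldTest(
                    patient_id=str(row["patient_id"]),
                    eye=str(row["eye"]),
                    exam_date=exam_date,
                    age_years=float(row["age_years"]),
                    fixation_loss_rate=float(row["fl_rate"]) * scale,
                    false_negative_rate=float(row["fn_rate"]) * scale,
                    false_positive_rate=float(row["fp_rate"]) * scale,
                    md_db=float(row["md_db"]),
                    psd_db=float(row["psd_db"]),
                    vfi_pct=float(row["vfi_pct"]),
                    tdv=tdv,
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning("row %d rejected: %s", i + 2, exc)  # +2: header + 1-based
    return tests


def write_vf_table(tests: Sequence[VisualFieldTest], path) -> None:
    """Write test records to the CSV schema read by :func:`read_vf_table`.

    Blind-spot td columns are emitted blank.  Round trip is lossless to
    1e-6 on all numeric fields.
    """
    rows = []
    for t in tests:
        row: dict[str, object] = {
            "patient_id": t.patient_id,
            "eye": t.eye,
            "exam_date": t.exam_date.isoformat(),
            "age_years": round(t.age_years, 6),
            "fl_rate": round(t.fixation_loss_rate, 6),
            "fn_rate": round(t.false_negative_rate, 6),
            "fp_rate": round(t.false_positive_rate, 6),
            "md_db": round(t.md_db, 6),
            "psd_db": round(t.psd_db, 6),
            "vfi_pct": round(t.vfi_pct, 6),
        }
        for col, v in zip(_ACTIVE_TD_COLUMNS, t.tdv):
            row[col] = round(float(v), 6)
        for col in _BLIND_TD_COLUMNS:
            row[col] = ""
        rows.append(row)
    df = pd.DataFrame(rows, columns=_META_COLUMNS + _TD_COLUMNS)
    df.to_csv(path, index=False)


def render_tdv(tdv: np.ndarray, *, width: int = 6) -> str:
    """ASCII rendering of a 52-TDV vector in right-eye format (blind spot '##')."""
    tdv = np.asarray(tdv, dtype=float)
    lines = []
    k = 0
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        xs = _ROW_X[abs(y)]
        pad = " " * (width * ((9 - len(xs)) // 2))
        cells = []
        for x in xs:
            if (x, y) in _BLIND_SPOTS:
                cells.append("##".rjust(width))
            else:
                cells.append(f"{tdv[k]:.0f}".rjust(width))
                k += 1
        lines.append(pad + "".join(cells))
    return "\n".join(lines)
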