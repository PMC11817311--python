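"""Pen-tablet recordings on disk: SVC-style text files and dataset manifests.

Recordings use the SVC dialect common to online-handwriting corpora:
a header line holding the sample count, then one whitespace-separated
line per sample with fields

    x  y  timestamp  pen_status  azimuth  altitude  pressure  [z]

``pen_status`` is 1 while the pen tip touches the surface and 0 while it
is lifted.  The optional eighth column carries pen height above the
surface; files written by this module always include it so that a
read-after-write round trip reproduces every channel exactly.  When the
column is absent, z is reconstructed as 0 on-surface with a
raised-cosine arc over each in-air run (the same lift model the
synthetic generator uses).

Timestamps are informational only: every recording is treated as lying
on a uniform grid with sampling interval 1/fs.  Parsing uses the C
locale unconditionally (decimal point, never comma).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sampling frequency of the target tablet, Hz.
DEFAULT_FS = 180.0

#: Peak height (device units) of the reconstructed z arc for in-air runs
#: of 7-column files.
DEFAULT_LIFT_HEIGHT = 60.0


class SVCFormatError(ValueError):
    """Raised for malformed or internally inconsistent SVC files."""


class Condition(str, enum.Enum):
    """Clinical group label of a subject."""

    PD = "PD"
    HC = "HC"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, value: "str | Condition") -> "Condition":
        if isinstance(value, Condition):
            return value
        v = str(value).strip()
        for member in cls:
            if v.lower() == member.value.lower():
                return member
        raise ValueError(f"unknown condition label: {value!r}")


@dataclass(eq=False)
class TabletRecording:
    """Six-channel pen-tablet recording of one subject.

    Channels (all of identical length n >= 2, uniform grid at ``fs`` Hz):

    x, y
        Pen position in tablet units; y increases upward, origin at the
        tablet's lower-left corner.
    z
        Pen height above the surface in tablet units; 0 on contact,
        positive only while the pen is lifted.
    azimuth, altitude
        Pen orientation in degrees: compass direction of the barrel in
        [0, 360) and elevation above the tablet plane in [0, 90].
    pressure
        Tip force in device units, >= 0; strictly positive exactly on
        pen-down samples.
    """

    subject_id: str
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    azimuth: np.ndarray
    altitude: np.ndarray
    pressure: np.ndarray
    fs: float = DEFAULT_FS
    condition: Condition = Condition.UNKNOWN

    def __post_init__(self) -> None:
        for name in ("x", "y", "z", "azimuth", "altitude", "pressure"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.condition = Condition.parse(self.condition)
        n = len(self.x)
        lengths = {name: len(getattr(self, name))
                   for name in ("x", "y", "z", "azimuth", "altitude", "pressure")}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        if n < 2:
            raise ValueError(f"recording needs at least 2 samples, got {n}")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if np.any(self.pressure < 0):
            raise ValueError("pressure must be non-negative")
        if np.any((self.azimuth < 0) | (self.azimuth >= 360)):
            raise ValueError("azimuth must lie in [0, 360)")
        if np.any((self.altitude < 0) | (self.altitude > 90)):
            raise ValueError("altitude must lie in [0, 90]")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Recording length in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def pen_down(self) -> np.ndarray:
        """Boolean mask of on-surface samples (pressure > 0)."""
        return self.pressure > 0

    def equals(self, other: "TabletRecording") -> bool:
        """Exact equality of metadata and every channel."""
        return (
            self.subject_id == other.subject_id
            and self.fs == other.fs
            and all(
                np.array_equal(getattr(self, c), getattr(other, c))
                for c in ("x", "y", "z", "azimuth", "altitude", "pressure")
            )
        )


def _in_air_runs(pen_down: np.ndarray) -> list[slice]:
    edges = np.flatnonzero(np.diff(pen_down.astype(int)))
    bounds = [0, *(int(e) + 1 for e in edges), len(pen_down)]
    return [
        slice(a, b)
        for a, b in zip(bounds[:-1], bounds[1:])
        if not pen_down[a]
    ]


def _reconstruct_z(pen_down: np.ndarray, height: float = DEFAULT_LIFT_HEIGHT) -> np.ndarray:
    """Raised-cosine lift arc per in-air run, zero on-surface."""
    z = np.zeros(len(pen_down))
    for run in _in_air_runs(pen_down):
        m = run.stop - run.start
        t = (np.arange(m) + 1) / (m + 1)
        z[run] = height * 0.5 * (1 - np.cos(2 * np.pi * t))
    return z


def read_svc(
    path: "str | Path",
    fs: float = DEFAULT_FS,
    subject_id: "str | None" = None,
    condition: "str | Condition" = Condition.UNKNOWN,
) -> TabletRecording:
    """Read an SVC-style recording.

    The declared sample count must match the number of data lines and
    each line must carry 7 or 8 fields; violations raise
    :class:`SVCFormatError` naming the offending line (1-based, counting
    the header as line 1).
    """
    path = Path(path)
    raw = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not raw:
        raise SVCFormatError(f"{path}: empty file")
    try:
        declared = int(raw[0].split()[0])
    except ValueError as exc:
        raise SVCFormatError(f"{path}: line 1: bad sample count {raw[0]!r}") from exc
    data_lines = raw[1:]
    if len(data_lines) != declared:
        raise SVCFormatError(
            f"{path}: declared {declared} samples but found {len(data_lines)} data lines"
        )

    cols: list[list[float]] = []
    ncols = None
    for i, line in enumerate(data_lines, start=2):
        fields = line.split()
        if len(fields) not in (7, 8):
            raise SVCFormatError(
                f"{path}: line {i}: expected 7 or 8 fields, got {len(fields)}"
            )
        if ncols is None:
            ncols = len(fields)
        elif len(fields) != ncols:
            raise SVCFormatError(
                f"{path}: line {i}: inconsistent field count ({len(fields)} vs {ncols})"
            )
        try:
            cols.append([float(f) for f in fields])
        except ValueError as exc:
            raise SVCFormatError(f"{path}: line {i}: non-numeric field in {line!r}") from exc

    arr = np.asarray(cols, dtype=float)
    x, y, _ts, pen_status, azimuth, altitude, pressure = arr[:, :7].T
    pen_down_flag = pen_status > 0.5
    if arr.shape[1] == 8:
        z = arr[:, 7]
    else:
        z = _reconstruct_z(pen_down_flag)
    return TabletRecording(
        subject_id=subject_id if subject_id is not None else path.stem,
        x=x,
        y=y,
        z=z,
        azimuth=azimuth,
        altitude=altitude,
        pressure=pressure,
        fs=fs,
        condition=condition,
    )


def write_svc(rec: TabletRecording, path: "str | Path") -> Path:
    """Write a recording as an 8-column SVC text file.

    Floating fields are serialized with shortest round-trip ``repr`` so
    ``read_svc(write_svc(rec))`` reproduces every channel bit for bit;
    timestamp (milliseconds on the uniform grid) and pen status are
    integers.
    """
    path = Path(path)
    pen_down = rec.pen_down
    lines = [str(rec.n)]
    for i in range(rec.n):
        ts = round(i * 1000.0 / rec.fs)
        lines.append(
            " ".join(
                (
                    repr(float(rec.x[i])),
                    repr(float(rec.y[i])),
                    str(ts),
                    str(int(pen_down[i])),
                    repr(float(rec.azimuth[i])),
                    repr(float(rec.altitude[i])),
                    repr(float(rec.pressure[i])),
                    repr(float(rec.z[i])),
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclass
class ManifestEntry:
    subject_id: str
    condition: Condition
    path: Path

    def load(self, fs: float = DEFAULT_FS) -> TabletRecording:
        return read_svc(self.path, fs=fs, subject_id=self.subject_id,
                        condition=self.condition)


@dataclass
class DatasetManifest:
    """Listing of a cohort: one recording file per subject with its label."""

    entries: list[ManifestEntry]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.subject_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_ids in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.condition.value] = out.get(e.condition.value, 0) + 1
        return out

    @property
    def subject_ids(self) -> list[str]:
        return [e.subject_id for e in self.entries]

    @property
    def conditions(self) -> list[Condition]:
        return [e.condition for e in self.entries]

    def load_recordings(self, fs: float = DEFAULT_FS) -> list[TabletRecording]:
        return [e.load(fs=fs) for e in self.entries]


def load_manifest(path: "str | Path") -> DatasetManifest:
    """Load a manifest CSV with columns ``subject_id,condition,path``.

    Relative recording paths are resolved against the manifest's own
    directory.  Duplicate subject ids and unresolvable paths are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"subject_id", "condition", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    base = path.parent
    entries = []
    for row in df.itertuples(index=False):
        rec_path = Path(row.path)
        if not rec_path.is_absolute():
            rec_path = base / rec_path
        if not rec_path.exists():
            raise FileNotFoundError(
                f"manifest entry {row.subject_id!r}: recording not found at {rec_path}"
            )
        entries.append(
            ManifestEntry(str(row.subject_id), Condition.parse(row.condition), rec_path)
        )
    manifest = DatasetManifest(entries)
    logger.info("loaded manifest %s: %s", path, manifest.counts())
    return manifest


def save_manifest(manifest: DatasetManifest, path: "str | Path") -> Path:
    """Write a manifest CSV; recording paths are stored relative when possible."""
    path = Path(path)
    rows = []
    for e in manifest.entries:
        p = e.path
        try:
            p = p.relative_to(path.parent)
        except ValueError:
            pass
        rows.append({"subject_id": e.subject_id, "condition": e.condition.value,
                     "path": str(p)})
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
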