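"""Segmentation and dynamic (time-series) features of tablet recordings.

A recording is split into on-surface movement (pen-down, the digit
strokes themselves) and in-air movement (pen lifts between digits).
On-surface is detected as ``pressure > 0``, the observable counterpart
of the pen touching the surface (z = 0 on contact).

Two feature families are computed per segment class:

Pressure (on-surface only)
    The raw pressure p, its changes Δp = p[n+1] − p[n], and the rate
    chain p' = Δp/Δt, p'' = Δ²p/Δt², p''' = Δ³p/Δt³ (Δt = 1/fs), plus
    the number of changes in pressure NCP (count of local extrema of
    Δp, p' and p'') with the duration-normalized RNCP = NCP / seconds.

Kinematic (on-surface and in-air)
    Base signals Δx, Δy, Δazimuth, Δaltitude, the pen trajectory
    r[n] = sqrt(x[n]² + y[n]²), the pen displacement
    Di[n] = sqrt((x[n+1] − x[n])² + (y[n+1] − y[n])²), and additionally
    Δz for the in-air class (z is informative only while the pen is
    lifted).  Each base signal is differentiated into velocity,
    acceleration and jerk tiers, and NCV / NCA count local extrema of
    its velocity / acceleration with RNCV / RNCA normalized by the
    segment-class duration.

All differences are taken within contiguous runs only -- never across a
pen lift -- and per-run vectors are concatenated.  Azimuth differences
are wrapped into (−180, 180] to avoid artificial 359→0 spikes.

After the four statistical functionals are applied downstream, the
cardinalities are 26 pressure features, 120 on-surface and 140 in-air
kinematic features (24 and 28 vector features times four functionals,
plus the same number of scalars).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from scribepd.io_formats import TabletRecording

logger = logging.getLogger(__name__)

ON_SURFACE = "on_surface"
IN_AIR = "in_air"

#: Canonical short set prefixes used in feature names.
SET_PREFIX = {"pressure": "pressure", ON_SURFACE: "kin_on", IN_AIR: "kin_air"}

TIERS = ("base", "vel", "acc", "jerk")


@dataclass
class SegmentMask:
    """On-surface/in-air partition of a recording into contiguous runs."""

    on_surface: np.ndarray          # boolean, length n
    runs_on: list[slice]
    runs_air: list[slice]

    @property
    def n_on(self) -> int:
        return int(self.on_surface.sum())

    @property
    def n_air(self) -> int:
        return int((~self.on_surface).sum())

    def runs(self, segment_class: str) -> list[slice]:
        if segment_class == ON_SURFACE:
            return self.runs_on
        if segment_class == IN_AIR:
            return self.runs_air
        raise ValueError(f"unknown segment class: {segment_class!r}")


@dataclass
class FeatureMatrix:
    """Named vector features (variable length) plus scalar features."""

    vectors: dict[str, np.ndarray]
    scalars: dict[str, float]
    segment_class: str

    def __post_init__(self) -> None:
        for name, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if v.size == 0:
                raise ValueError(f"vector feature {name!r} is empty")
            self.vectors[name] = v

    @property
    def n_vectors(self) -> int:
        return len(self.vectors)

    @property
    def n_scalars(self) -> int:
        return len(self.scalars)


def segment(rec: TabletRecording) -> SegmentMask:
    """Partition a recording into on-surface and in-air runs."""
    on = rec.pressure > 0
    edges = np.flatnonzero(np.diff(on.astype(int)))
    bounds = [0, *(int(e) + 1 for e in edges), len(on)]
    runs_on, runs_air = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        (runs_on if on[a] else runs_air).append(slice(a, b))
    if not runs_on:
        logger.warning("recording %s has no on-surface samples", rec.subject_id)
    logger.debug("segmented %s: %d on-surface runs, %d in-air runs",
                 rec.subject_id, len(runs_on), len(runs_air))
    return SegmentMask(on, runs_on, runs_air)


def count_local_extrema(signal: np.ndarray) -> int:
    """Strict local extrema: sign change of consecutive differences.

    An index i counts iff (s[i] − s[i−1]) · (s[i+1] − s[i]) < 0;
    plateaus do not count.
    """
    s = np.asarray(signal, dtype=float)
    if len(s) < 3:
        return 0
    d = np.diff(s)
    return int(np.sum(d[:-1] * d[1:] < 0))


def _diff_runs(runs: list[np.ndarray]) -> list[np.ndarray]:
    return [np.diff(r) for r in runs]


def _extrema_over_runs(runs: list[np.ndarray]) -> int:
    return sum(count_local_extrema(r) for r in runs)


def _concat(runs: list[np.ndarray]) -> np.ndarray:
    parts = [r for r in runs if r.size]
    return np.concatenate(parts) if parts else np.empty(0)


def _wrap_degrees(d: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (−180, 180]."""
    w = np.mod(d, 360.0)
    return np.where(w > 180.0, w - 360.0, w)


def pressure_features(rec: TabletRecording, mask: SegmentMask) -> FeatureMatrix:
    """Pressure feature set of the on-surface portion.

    Vectors: p, dp (= Δp), d1 (= p'), d2 (= p''), d3 (= p''').
    Scalars: NCP and RNCP for each of dp, d1, d2 (six in total).
    """
    runs = [rec.pressure[s] for s in mask.runs_on]
    n_on = sum(len(r) for r in runs)
    if n_on < 4 or max((len(r) for r in runs), default=0) < 4:
        raise ValueError(
            "pressure features need at least one on-surface run of >= 4 samples "
            "(pressure jerk is a third difference)")
    fs = rec.fs
    dp = _diff_runs(runs)
    d1 = [d * fs for d in dp]
    d2 = [np.diff(d) * fs for d in d1]
    d3 = [np.diff(d) * fs for d in d2]

    vectors = {
        "pressure.p": _concat(runs),
        "pressure.dp": _concat(dp),
        "pressure.d1": _concat(d1),
        "pressure.d2": _concat(d2),
        "pressure.d3": _concat(d3),
    }
    duration = n_on / fs
    scalars: dict[str, float] = {}
    for name, sig_runs in (("dp", dp), ("d1", d1), ("d2", d2)):
        ncp = _extrema_over_runs(sig_runs)
        scalars[f"pressure.ncp.{name}"] = float(ncp)
        scalars[f"pressure.rncp.{name}"] = ncp / duration
    return FeatureMatrix(vectors, scalars, "pressure")


def _base_signals(rec: TabletRecording, runs: list[slice],
                  include_z: bool) -> dict[str, list[np.ndarray]]:
    bases: dict[str, list[np.ndarray]] = {
        "dx": [], "dy": [], "daz": [], "dalt": [], "r": [], "di": [],
    }
    if include_z:
        bases["dz"] = []
    for s in runs:
        x, y = rec.x[s], rec.y[s]
        dx, dy = np.diff(x), np.diff(y)
        bases["dx"].append(dx)
        bases["dy"].append(dy)
        bases["daz"].append(_wrap_degrees(np.diff(rec.azimuth[s])))
        bases["dalt"].append(np.diff(rec.altitude[s]))
        bases["r"].append(np.hypot(x, y))
        bases["di"].append(np.hypot(dx, dy))
        if include_z:
            bases["dz"].append(np.diff(rec.z[s]))
    return bases


def kinematic_features(rec: TabletRecording, mask: SegmentMask,
                       segment_class: str) -> FeatureMatrix:
    """Kinematic feature set of one segment class.

    On-surface yields 6 base signals (dx, dy, daz, dalt, r, di), in-air
    adds dz; each base carries four tiers (base, vel, acc, jerk) and
    four scalars (NCV, RNCV, NCA, RNCA).
    """
    runs = mask.runs(segment_class)
    if not runs:
        raise ValueError(f"recording has no {segment_class} samples")
    n_seg = sum(s.stop - s.start for s in runs)
    if n_seg < 5:
        raise ValueError(
            f"{segment_class} portion has {n_seg} samples; at least 5 are "
            "required for the jerk tier")
    fs = rec.fs
    prefix = SET_PREFIX[segment_class]
    bases = _base_signals(rec, runs, include_z=(segment_class == IN_AIR))

    vectors: dict[str, np.ndarray] = {}
    scalars: dict[str, float] = {}
    duration = n_seg / fs
    for bname, base_runs in bases.items():
        tiers = {"base": base_runs}
        tiers["vel"] = [np.diff(r) * fs for r in base_runs]
        tiers["acc"] = [np.diff(r) * fs for r in tiers["vel"]]
        tiers["jerk"] = [np.diff(r) * fs for r in tiers["acc"]]
        for tname in TIERS:
            v = _concat(tiers[tname])
            if v.size == 0:
                raise ValueError(
                    f"{segment_class} runs are too short for tier {tname!r} "
                    f"of base signal {bname!r}")
            vectors[f"{prefix}.{bname}.{tname}"] = v
        ncv = _extrema_over_runs(tiers["vel"])
        nca = _extrema_over_runs(tiers["acc"])
        scalars[f"{prefix}.ncv.{bname}"] = float(ncv)
        scalars[f"{prefix}.rncv.{bname}"] = ncv / duration
        scalars[f"{prefix}.nca.{bname}"] = float(nca)
        scalars[f"{prefix}.rnca.{bname}"] = nca / duration
    return FeatureMatrix(vectors, scalars, segment_class)


def extract_all(rec: TabletRecording) -> dict[str, FeatureMatrix]:
    """Pressure plus both kinematic segment classes of one recording."""
    mask = segment(rec)
    return {
        "pressure": pressure_features(rec, mask),
        ON_SURFACE: kinematic_features(rec, mask, ON_SURFACE),
        IN_AIR: kinematic_features(rec, mask, IN_AIR),
    }
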