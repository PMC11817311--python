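"""Synthetic pen-tablet cohorts writing the digit sequence 0-9.

Real clinical handwriting corpora for Parkinson's disease (PD) are
rarely shareable, so this module generates six-channel tablet
recordings with controllable PD-like effects:

* micrographia -- writing size shrinks progressively along the
  sequence, reaching half size at the final digit when severity is 1;
* rest tremor -- a 4-6 Hz sinusoid added to pen position on-surface;
* hypotonic / irregular pressure -- the nominal pressure profile is
  scaled down and perturbed with multiplicative log-normal noise;
* bradykinesia -- the whole trajectory is slowed by a speed factor.

Digits come from a hand-authored glyph bank of single-stroke skeleton
polylines (each normalized to unit height), traversed at constant
nominal pen speed.  Pen-up transitions between digits are straight
lines in (x, y) with a raised-cosine lift arc in z and zero pressure,
so pen-down and pen-up samples partition every recording.

All randomness flows through per-subject seeds derived from a single
master seed, making cohorts bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from scribepd.io_formats import (
    Condition,
    DatasetManifest,
    ManifestEntry,
    TabletRecording,
    save_manifest,
    write_svc,
)

# ---------------------------------------------------------------------------
# Glyph bank
# ---------------------------------------------------------------------------

#: Layout constants, tablet units.
DIGIT_HEIGHT = 1000.0      # nominal glyph height
DIGIT_WIDTH = 700.0        # nominal glyph advance width
DIGIT_GAP = 250.0          # horizontal gap between digit boxes
BASELINE_Y = 1000.0        # y of the writing baseline
LIFT_HEIGHT = 60.0         # peak z of the in-air arc, device units
PEN_SPEED = 4500.0         # nominal pen speed, tablet units / s
TRANSITION_TIME = 0.25     # nominal in-air transition duration, s


@dataclass
class Stroke:
    """One continuous pen-down polyline with a nominal pressure profile."""

    points: np.ndarray      # (k, 2) control points
    pressure: np.ndarray    # (k,) nominal pressure in (0, 1]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("stroke points must have shape (k, 2)")
        if len(self.pressure) != len(self.points):
            raise ValueError("pressure profile must match point count")


@dataclass
class GlyphBank:
    """Skeleton strokes for the digits 0-9 in a unit box.

    Every digit has at least one stroke and all control points lie in
    [0, 1]^2 with the glyph's bounding box normalized to full unit
    height, so the micrographia size law acts identically on every
    digit.
    """

    glyphs: dict[int, list[Stroke]]

    def __post_init__(self) -> None:
        for d in range(10):
            if d not in self.glyphs or not self.glyphs[d]:
                raise ValueError(f"glyph bank is missing digit {d}")
        for d, strokes in self.glyphs.items():
            pts = np.vstack([s.points for s in strokes])
            if pts.min() < -1e-9 or pts.max() > 1 + 1e-9:
                raise ValueError(f"digit {d}: control points outside [0, 1]^2")

    def __getitem__(self, digit: int) -> list[Stroke]:
        return self.glyphs[digit]


def _arc(cx: float, cy: float, rx: float, ry: float,
         a0: float, a1: float, k: int = 36) -> np.ndarray:
    """Elliptic arc from angle a0 to a1 (degrees, CCW positive)."""
    t = np.radians(np.linspace(a0, a1, k))
    return np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])


def _nominal_pressure(k: int) -> np.ndarray:
    # gentle bell along the stroke; strictly positive at the endpoints
    s = np.linspace(0.0, 1.0, k)
    return 0.35 + 0.45 * np.sin(np.pi * s) ** 0.8


def _digit_paths() -> dict[int, list[np.ndarray]]:
    paths: dict[int, list[np.ndarray]] = {}
    paths[0] = [_arc(0.5, 0.5, 0.32, 0.46, 90, 450, 48)]
    paths[1] = [np.array([[0.32, 0.72], [0.52, 0.95], [0.52, 0.05]])]
    paths[2] = [np.vstack([
        _arc(0.5, 0.70, 0.26, 0.25, 160, -10, 20),
        np.array([[0.74, 0.62], [0.26, 0.05], [0.76, 0.05]]),
    ])]
    paths[3] = [np.vstack([
        _arc(0.47, 0.73, 0.25, 0.22, 150, -80, 20),
        _arc(0.47, 0.27, 0.28, 0.24, 80, -160, 22),
    ])]
    paths[4] = [np.array([
        [0.62, 0.95], [0.22, 0.38], [0.80, 0.38], [0.64, 0.60], [0.64, 0.05],
    ])]
    paths[5] = [np.vstack([
        np.array([[0.74, 0.95], [0.30, 0.95], [0.28, 0.55]]),
        _arc(0.48, 0.31, 0.27, 0.27, 120, -150, 24),
    ])]
    paths[6] = [np.vstack([
        np.array([[0.66, 0.93], [0.42, 0.62], [0.31, 0.38]]),
        _arc(0.50, 0.26, 0.21, 0.22, 160, -200, 28),
    ])]
    paths[7] = [np.array([[0.24, 0.95], [0.76, 0.95], [0.40, 0.05]])]
    paths[8] = [np.vstack([
        _arc(0.50, 0.71, 0.21, 0.22, -90, 270, 28),
        _arc(0.50, 0.27, 0.25, 0.24, 90, -270, 30),
    ])]
    paths[9] = [np.vstack([
        _arc(0.54, 0.70, 0.23, 0.23, 0, 360, 28),
        np.array([[0.77, 0.70], [0.70, 0.35], [0.58, 0.05]]),
    ])]
    return paths


def _normalize_unit_height(strokes: list[np.ndarray]) -> list[np.ndarray]:
    pts = np.vstack(strokes)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    h = hi[1] - lo[1]
    out = []
    for s in strokes:
        q = (s - lo) / h                      # full unit height
        q[:, 0] += 0.5 - (hi[0] - lo[0]) / h / 2
        out.append(np.clip(q, 0.0, 1.0))
    return out


def default_glyph_bank() -> GlyphBank:
    """Built-in single-stroke digit skeletons, each of unit height."""
    glyphs: dict[int, list[Stroke]] = {}
    for d, raw in _digit_paths().items():
        glyphs[d] = [
            Stroke(pts, _nominal_pressure(len(pts)))
            for pts in _normalize_unit_height(raw)
        ]
    return GlyphBank(glyphs)


# ---------------------------------------------------------------------------
# Subject profiles and cohort specs
# ---------------------------------------------------------------------------


@dataclass
class SubjectProfile:
    """Generative parameters of one simulated subject.

    micrographia_severity
        0 = constant size; 1 = the final digit is written at half its
        original size, with a linear shrink across the sequence.
    tremor_amplitude, tremor_freq
        Rest-tremor sinusoid added to on-surface x and y; amplitude in
        tablet units, frequency in the clinical 4-6 Hz band.
    pressure_scale, pressure_noise
        Multiplicative attenuation in (0, 1] and coefficient of
        variation of the multiplicative log-normal pressure noise.
    speed_factor
        Slow-down factor >= 1 applied to the whole trajectory.
    jitter_sigma
        Gaussian positional jitter (tablet units) on every sample.
    style_jitter
        Label-independent writer-style variability: fractional spread
        of per-digit and overall writing size (0.12 means roughly
        +/-12%).  Present in every group; it is nuisance variation,
        not a disease effect.
    """

    condition: Condition = Condition.HC
    micrographia_severity: float = 0.0
    tremor_amplitude: float = 0.0
    tremor_freq: float = 5.0
    pressure_scale: float = 1.0
    pressure_noise: float = 0.0
    speed_factor: float = 1.0
    jitter_sigma: float = 1.5
    style_jitter: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        self.condition = Condition.parse(self.condition)
        if not 0.0 <= self.micrographia_severity <= 1.0:
            raise ValueError("micrographia_severity must lie in [0, 1]")
        if self.tremor_amplitude < 0:
            raise ValueError("tremor_amplitude must be >= 0")
        if not 4.0 <= self.tremor_freq <= 6.0:
            raise ValueError("tremor_freq must lie in [4, 6] Hz")
        if not 0.0 < self.pressure_scale <= 1.0:
            raise ValueError("pressure_scale must lie in (0, 1]")
        if self.pressure_noise < 0:
            raise ValueError("pressure_noise must be >= 0")
        if self.speed_factor < 1.0:
            raise ValueError("speed_factor must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if not 0.0 <= self.style_jitter <= 0.5:
            raise ValueError("style_jitter must lie in [0, 0.5]")


#: Parameter ranges used to draw subject profiles, (low, high) per field.
#: These are the package's study conditions for a "typical" simulated
#: cohort; the null and pressure-dominant scenarios below reuse or
#: narrow them.
HC_PROFILE_RANGES: dict[str, tuple[float, float]] = {
    "micrographia_severity": (0.0, 0.0),
    "tremor_amplitude": (0.0, 0.0),
    "tremor_freq": (4.0, 6.0),
    "pressure_scale": (0.85, 1.0),
    "pressure_noise": (0.05, 0.10),
    "speed_factor": (1.0, 1.15),
    "jitter_sigma": (1.0, 2.0),
}

PD_PROFILE_RANGES: dict[str, tuple[float, float]] = {
    "micrographia_severity": (0.4, 0.8),
    "tremor_amplitude": (6.0, 14.0),
    "tremor_freq": (4.0, 6.0),
    "pressure_scale": (0.55, 0.80),
    "pressure_noise": (0.25, 0.45),
    "speed_factor": (1.2, 1.6),
    "jitter_sigma": (1.0, 2.0),
}

#: Strong pressure-channel group effect with only a mild shape effect:
#: the regime in which the dynamic branch should beat the image branch.
PD_PRESSURE_DOMINANT_RANGES: dict[str, tuple[float, float]] = {
    "micrographia_severity": (0.10, 0.25),
    "tremor_amplitude": (0.0, 3.0),
    "tremor_freq": (4.0, 6.0),
    "pressure_scale": (0.50, 0.70),
    "pressure_noise": (0.35, 0.55),
    "speed_factor": (1.0, 1.15),
    "jitter_sigma": (1.0, 2.0),
}


@dataclass
class CohortSpec:
    """Recipe for a simulated cohort.

    Profile fields are drawn uniformly from per-group (low, high)
    ranges; per-subject seeds are derived deterministically from the
    master seed.
    """

    n_pd: int
    n_hc: int
    master_seed: int = 0
    pd_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PD_PROFILE_RANGES))
    hc_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(HC_PROFILE_RANGES))

    def __post_init__(self) -> None:
        if self.n_pd < 0 or self.n_hc < 0:
            raise ValueError("subject counts must be >= 0")


def null_cohort_spec(n_pd: int, n_hc: int, master_seed: int = 0) -> CohortSpec:
    """Exchangeability null: both groups drawn from the HC ranges."""
    return CohortSpec(n_pd, n_hc, master_seed,
                      pd_ranges=dict(HC_PROFILE_RANGES),
                      hc_ranges=dict(HC_PROFILE_RANGES))


def pressure_dominant_cohort_spec(n_pd: int, n_hc: int,
                                  master_seed: int = 0) -> CohortSpec:
    """Strong pressure effect, mild shape effect (see module docstring)."""
    return CohortSpec(n_pd, n_hc, master_seed,
                      pd_ranges=dict(PD_PRESSURE_DOMINANT_RANGES),
                      hc_ranges=dict(HC_PROFILE_RANGES))


def subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def sample_profile(rng: np.random.Generator, condition: Condition,
                   ranges: dict[str, tuple[float, float]], seed: int) -> SubjectProfile:
    draws = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}
    return SubjectProfile(condition=condition, seed=seed, **draws)


# ---------------------------------------------------------------------------
# Stroke plans and recording synthesis
# ---------------------------------------------------------------------------


def micrographia_scale(digit: int, severity: float, onset: int = 0) -> float:
    """Per-digit size factor: linear shrink from ``onset`` to digit 9.

    At full severity the final digit is written at half size; at
    severity 0 the law degenerates to the identity.
    """
    if not 0 <= onset <= 5:
        raise ValueError("onset must lie in [0, 5]")
    if digit < onset:
        return 1.0
    frac = (digit - onset) / (9 - onset)
    return 1.0 - 0.5 * severity * frac


def plan_sequence(
    glyphs: GlyphBank,
    scales: np.ndarray,
    digit_scale_jitter: "np.ndarray | None" = None,
    baseline_offsets: "np.ndarray | None" = None,
) -> list[list[Stroke]]:
    """Lay out the digits 0-9 on a common baseline, in tablet units.

    ``scales[d]`` multiplies digit d's size about its baseline anchor;
    the optional jitter arrays add per-digit size and vertical baseline
    variation (used by the image pre-training corpus).
    """
    scales = np.asarray(scales, dtype=float)
    if scales.shape != (10,):
        raise ValueError("scales must have shape (10,)")
    sj = np.ones(10) if digit_scale_jitter is None else np.asarray(digit_scale_jitter)
    bo = np.zeros(10) if baseline_offsets is None else np.asarray(baseline_offsets)
    plan: list[list[Stroke]] = []
    x_cursor = 0.0
    for d in range(10):
        s = scales[d] * sj[d]
        digit_strokes = []
        for stroke in glyphs[d]:
            pts = stroke.points.copy()
            pts[:, 0] = x_cursor + pts[:, 0] * DIGIT_WIDTH * s
            pts[:, 1] = BASELINE_Y + bo[d] + pts[:, 1] * DIGIT_HEIGHT * s
            digit_strokes.append(Stroke(pts, stroke.pressure.copy()))
        plan.append(digit_strokes)
        x_cursor += DIGIT_WIDTH * s + DIGIT_GAP
    return plan


def _polyline_lengths(pts: np.ndarray) -> np.ndarray:
    return np.hypot(*np.diff(pts, axis=0).T)


def _resample_stroke(stroke: Stroke, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Resample a stroke to n samples uniform in arc length."""
    seg = _polyline_lengths(stroke.points)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        xy = np.repeat(stroke.points[:1], n, axis=0)
        return xy, np.full(n, stroke.pressure[0])
    s = np.linspace(0.0, total, n)
    x = np.interp(s, cum, stroke.points[:, 0])
    y = np.interp(s, cum, stroke.points[:, 1])
    u = cum / total
    p = np.interp(s / total, u, stroke.pressure)
    return np.column_stack([x, y]), p


def synthesize_recording(
    profile: SubjectProfile,
    glyphs: "GlyphBank | None" = None,
    fs: float = 180.0,
    subject_id: str = "synthetic",
) -> TabletRecording:
    """Generate one six-channel recording of the digit sequence 0-9.

    The recording alternates pen-down digit strokes with pen-up
    straight-line transitions; pressure is strictly positive exactly on
    pen-down samples and z is positive exactly on pen-up samples.
    Identical (profile, glyphs, fs) inputs give bit-identical output.
    """
    if not fs > 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if glyphs is None:
        glyphs = default_glyph_bank()
    rng = np.random.default_rng(profile.seed)

    # Writer-style size variability is drawn first so that toggling any
    # disease effect leaves the stroke plan's other draws unchanged.
    per_digit_style = 1.0 + profile.style_jitter * rng.uniform(-1, 1, size=10)
    overall_style = 1.0 + profile.style_jitter * rng.uniform(-1, 1)
    scales = np.array([
        micrographia_scale(d, profile.micrographia_severity) for d in range(10)
    ]) * per_digit_style * overall_style
    plan = plan_sequence(glyphs, scales)

    xy_parts: list[np.ndarray] = []
    p_nom_parts: list[np.ndarray] = []
    down_parts: list[np.ndarray] = []
    z_parts: list[np.ndarray] = []

    prev_end: "np.ndarray | None" = None
    for digit_strokes in plan:
        for stroke in digit_strokes:
            length = _polyline_lengths(stroke.points).sum()
            n_s = max(8, int(round(length / PEN_SPEED * profile.speed_factor * fs)))
            if prev_end is not None:
                n_t = max(4, int(round(TRANSITION_TIME * profile.speed_factor * fs)))
                t = (np.arange(n_t) + 1) / (n_t + 1)
                start = stroke.points[0]
                seg = prev_end[None, :] + t[:, None] * (start - prev_end)[None, :]
                xy_parts.append(seg)
                p_nom_parts.append(np.zeros(n_t))
                down_parts.append(np.zeros(n_t, dtype=bool))
                z_parts.append(LIFT_HEIGHT * 0.5 * (1 - np.cos(2 * np.pi * t)))
            xy, p_nom = _resample_stroke(stroke, n_s)
            xy_parts.append(xy)
            p_nom_parts.append(p_nom)
            down_parts.append(np.ones(n_s, dtype=bool))
            z_parts.append(np.zeros(n_s))
            prev_end = stroke.points[-1]

    xy = np.vstack(xy_parts)
    p_nom = np.concatenate(p_nom_parts)
    pen_down = np.concatenate(down_parts)
    z = np.concatenate(z_parts)
    n = len(xy)
    t_grid = np.arange(n) / fs

    # Randomness is drawn in a fixed order so that switching one effect
    # on or off leaves every other draw unchanged for the same seed.
    jitter = rng.normal(0.0, 1.0, size=(n, 2)) * profile.jitter_sigma
    tremor_phase = rng.uniform(0.0, 2 * np.pi)
    log_sigma = math.sqrt(math.log(1.0 + profile.pressure_noise ** 2))
    press_noise = rng.lognormal(mean=-0.5 * log_sigma ** 2, sigma=log_sigma, size=n)
    az_phase, al_phase = rng.uniform(0.0, 2 * np.pi, size=2)
    az_noise = rng.normal(0.0, 0.8, size=n)
    al_noise = rng.normal(0.0, 0.5, size=n)

    x = xy[:, 0] + jitter[:, 0]
    y = xy[:, 1] + jitter[:, 1]
    tremor = profile.tremor_amplitude * np.sin(
        2 * np.pi * profile.tremor_freq * t_grid + tremor_phase)
    x = np.where(pen_down, x + tremor, x)
    y = np.where(pen_down, y + tremor, y)

    pressure = np.where(pen_down,
                        np.maximum(p_nom * profile.pressure_scale * press_noise, 1e-3),
                        0.0)
    azimuth = np.mod(250.0 + 18.0 * np.sin(2 * np.pi * 0.35 * t_grid + az_phase)
                     + az_noise, 360.0)
    altitude = np.clip(60.0 + 8.0 * np.sin(2 * np.pi * 0.25 * t_grid + al_phase)
                       + al_noise, 0.0, 90.0)

    return TabletRecording(
        subject_id=subject_id,
        x=x, y=y, z=z,
        azimuth=azimuth, altitude=altitude, pressure=pressure,
        fs=fs, condition=profile.condition,
    )


def noiseless(profile: SubjectProfile) -> SubjectProfile:
    """Copy of a profile with every stochastic term switched off."""
    return replace(profile, tremor_amplitude=0.0, pressure_noise=0.0,
                   jitter_sigma=0.0, style_jitter=0.0)


def sample_cohort_profiles(spec: CohortSpec) -> list[SubjectProfile]:
    """Draw the subject profiles of a cohort (PD block first, then HC)."""
    profiles = []
    for i in range(spec.n_pd + spec.n_hc):
        cond = Condition.PD if i < spec.n_pd else Condition.HC
        ranges = spec.pd_ranges if cond is Condition.PD else spec.hc_ranges
        seed = subject_seed(spec.master_seed, i)
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(spec.master_seed), int(i), 0xC0FF]))
        profiles.append(sample_profile(rng, cond, ranges, seed))
    return profiles


def synthesize_cohort_recordings(
    spec: CohortSpec,
    glyphs: "GlyphBank | None" = None,
    fs: float = 180.0,
) -> list[TabletRecording]:
    """In-memory cohort generation (no files touched)."""
    if glyphs is None:
        glyphs = default_glyph_bank()
    recs = []
    n_pd_seen = 0
    n_hc_seen = 0
    for profile in sample_cohort_profiles(spec):
        if profile.condition is Condition.PD:
            n_pd_seen += 1
            sid = f"PD{n_pd_seen:03d}"
        else:
            n_hc_seen += 1
            sid = f"HC{n_hc_seen:03d}"
        recs.append(synthesize_recording(profile, glyphs, fs=fs, subject_id=sid))
    return recs


def synthesize_cohort(
    spec: CohortSpec,
    out_dir: "str | Path",
    glyphs: "GlyphBank | None" = None,
    fs: float = 180.0,
) -> DatasetManifest:
    """Write a cohort to disk (SVC files plus ``manifest.csv``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in synthesize_cohort_recordings(spec, glyphs, fs=fs):
        path = out_dir / f"{rec.subject_id}.svc"
        write_svc(rec, path)
        entries.append(ManifestEntry(rec.subject_id, rec.condition, path))
    manifest = DatasetManifest(entries, metadata={"master_seed": spec.master_seed})
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
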