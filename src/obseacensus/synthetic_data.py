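"""Ground-truthed synthetic inputs: underwater scenes, count-pair sets and
sensor streams.

No imagery or sensor data from the deployment is publicly available, so
every other module is exercised against generated inputs whose ground truth
is known by construction:

* scenes — a textured marine background with optional illumination drift and
  Gaussian noise, over which fusiform (elliptical) fish silhouettes are
  composited at a fixed contrast, either well separated or clustered into a
  school whose members may overlap and merge;
* count pairs — (manual, automatic) count sets that classify into a
  requested tally per error category, for evaluating the typology
  arithmetic;
* sample streams — diel + tidal sinusoids with noise and declared outage
  gaps, at CTD (10 s) or ADCP-product (10 min) cadence.

Every generator is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .census_evaluation import (
    LOW_THRESHOLD,
    SCHOOL_THRESHOLD,
    CountPair,
    ErrorCategory,
    ValidationError,
    classify_pair,
)
from .habitat_timeseries import SampleStream


class GenerationError(RuntimeError):
    """Raised when a scene cannot be generated (e.g. infeasible packing)."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic underwater scene.

    ``contrast`` is the absolute intensity offset of a fish silhouette from
    the background; fish are dark or light with equal probability.  In
    ``school`` mode the ``n_fish`` centres are drawn inside a disc whose
    radius scales with the square root of the total fish area, so members
    overlap and merge the way dense schools defeat per-individual counting.
    """

    seed: int
    width: int = 480
    height: int = 360
    n_fish: int = 0
    fish_area_range: tuple[int, int] = (60, 1500)
    school: bool = False
    contrast: float = 80.0
    illumination_drift: float = 0.0
    noise_sd: float = 0.0
    background_level: float = 120.0
    background_texture: str = "uniform"  # or "speckle"
    speckle_sd: float = 8.0
    school_radius_factor: float = 0.6
    min_gap: int = 6  # clearance between non-school fish outlines, px

    def __post_init__(self) -> None:
        if self.n_fish < 0:
            raise ValidationError("n_fish must be >= 0")
        if self.fish_area_range[0] <= 0 or self.fish_area_range[0] > self.fish_area_range[1]:
            raise ValidationError(f"bad fish_area_range {self.fish_area_range}")
        if self.background_texture not in ("uniform", "speckle"):
            raise ValidationError(f"unknown background_texture {self.background_texture!r}")


@dataclass(frozen=True)
class FishPlacement:
    area: int  # rendered pixel count
    centroid: tuple[float, float]  # (row, col)
    overlaps: bool


@dataclass(frozen=True)
class GroundTruth:
    true_count: int
    fish: tuple[FishPlacement, ...]

    @property
    def any_overlap(self) -> bool:
        return any(f.overlaps for f in self.fish)


def _background_base(spec: SceneSpec) -> np.ndarray:
    """Deterministic (seed-bound) background: texture + illumination drift.

    Shared by reference and scene so that subtraction cancels it exactly;
    only the per-exposure noise realisation differs between the two.
    """
    h, w = spec.height, spec.width
    base = np.full((h, w), spec.background_level, dtype=np.float64)
    if spec.background_texture == "speckle":
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
        base += rng.normal(0.0, spec.speckle_sd, size=(h, w))
    if spec.illumination_drift:
        base += spec.illumination_drift * np.linspace(-0.5, 0.5, w)[None, :]
    return base


def _finalize(base: np.ndarray, noise_rng: Optional[np.random.Generator], noise_sd: float) -> np.ndarray:
    img = base.copy()
    if noise_sd > 0 and noise_rng is not None:
        img += noise_rng.normal(0.0, noise_sd, size=base.shape)
    rgb = np.repeat(np.clip(np.rint(img), 0, 255).astype(np.uint8)[..., None], 3, axis=2)
    return rgb


def make_reference(spec: SceneSpec) -> np.ndarray:
    """Fish-free reference exposure of the scene's background."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    return _finalize(_background_base(spec), rng, spec.noise_sd)


def _fish_geometry(rng: np.random.Generator, area: float) -> tuple[float, float, float]:
    """Semi-axes and orientation of a fusiform ellipse of the given area."""
    aspect = rng.uniform(2.0, 4.0)
    a = math.sqrt(area * aspect / math.pi)  # semi-major
    b = a / aspect
    theta = rng.uniform(0.0, math.pi)
    return a, max(b, 1.0), theta


def render_scene(spec: SceneSpec, reference: np.ndarray) -> tuple[np.ndarray, GroundTruth]:
    """Composite ``n_fish`` elliptical silhouettes over the scene background.

    Non-school mode rejection-samples centres so outlines keep at least
    ``min_gap`` pixels of clearance (raises :class:`GenerationError` when the
    packing is infeasible).  School mode clusters centres inside a disc and
    records which fish ended up sharing pixels with a neighbour.
    """
    if reference.shape[:2] != (spec.height, spec.width):
        raise ValidationError(
            f"reference geometry {reference.shape[:2]} does not match spec "
            f"({spec.height}, {spec.width})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    h, w = spec.height, spec.width
    base = _background_base(spec)

    areas = rng.uniform(*spec.fish_area_range, size=spec.n_fish)
    geoms = [_fish_geometry(rng, a) for a in areas]
    radii = [g[0] for g in geoms]

    centers: list[tuple[float, float]] = []
    if spec.school and spec.n_fish:
        disc_r = spec.school_radius_factor * math.sqrt(float(np.sum(areas)))
        cr, cc = h / 2.0, w / 2.0
        for a in radii:
            ang = rng.uniform(0, 2 * math.pi)
            rad = disc_r * math.sqrt(rng.uniform())
            r = min(max(cr + rad * math.sin(ang), a + 2), h - a - 3)
            c = min(max(cc + rad * math.cos(ang), a + 2), w - a - 3)
            centers.append((r, c))
    else:
        # place the largest outlines first: greatly improves packability
        order = sorted(range(spec.n_fish), key=lambda i: -radii[i])
        placed: dict[int, tuple[float, float]] = {}
        for i in order:
            a = radii[i]
            if a + 4 >= min(h, w) / 2:
                raise GenerationError(f"fish {i} (radius {a:.1f}) cannot fit the frame")
            for _ in range(5000):
                r = rng.uniform(a + 4, h - a - 4)
                c = rng.uniform(a + 4, w - a - 4)
                if all(
                    math.hypot(r - rj, c - cj) > a + radii[j] + spec.min_gap
                    for j, (rj, cj) in placed.items()
                ):
                    placed[i] = (r, c)
                    break
            else:
                raise GenerationError(
                    f"could not place {spec.n_fish} non-overlapping fish "
                    f"(placed {len(placed)}) — packing infeasible"
                )
        centers = [placed[i] for i in range(spec.n_fish)]

    paint = np.zeros((h, w), dtype=np.int32)  # per-pixel fish multiplicity
    pixels: list[tuple[np.ndarray, np.ndarray]] = []
    signs = rng.choice([-1.0, 1.0], size=spec.n_fish)
    for (r, c), (a, b, theta) in zip(centers, geoms):
        rr, cc = draw_ellipse(r, c, a, b, shape=(h, w), rotation=theta)
        pixels.append((rr, cc))
        paint[rr, cc] += 1

    scene = base.copy()
    occupied = np.zeros((h, w), dtype=bool)
    fish: list[FishPlacement] = []
    for (rr, cc), sign in zip(pixels, signs):
        fresh = ~occupied[rr, cc]  # overlap pixels keep the first fish's shade
        scene[rr[fresh], cc[fresh]] = base[rr[fresh], cc[fresh]] + sign * spec.contrast
        occupied[rr, cc] = True
        fish.append(
            FishPlacement(
                area=int(len(rr)),
                centroid=(float(rr.mean()), float(cc.mean())) if len(rr) else (math.nan, math.nan),
                overlaps=bool((paint[rr, cc] > 1).any()),
            )
        )

    noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    frame = _finalize(scene, noise_rng, spec.noise_sd)
    return frame, GroundTruth(true_count=spec.n_fish, fish=tuple(fish))


# --------------------------------------------------------------------------
# count-pair simulation

_DEFAULT_MAX_COUNT = 60


def _draw_pair(
    rng: np.random.Generator,
    category: ErrorCategory,
    school: int,
    low: int,
    max_count: int,
) -> tuple[int, int]:
    """One (N, M) uniform draw from the category's feasible set."""
    if category is ErrorCategory.CORRECT0:
        return 0, 0
    if category is ErrorCategory.CORRECTN:
        n = int(rng.integers(1, max_count + 1))
        return n, n
    if category is ErrorCategory.IMG0_CLASSN:
        return 0, int(rng.integers(1, max_count + 1))
    if category is ErrorCategory.IMGN_CLASS0:
        # N > school with M = 0 is a school failure, so N is capped
        return int(rng.integers(1, school + 1)), 0
    if category is ErrorCategory.IMG_GT20_CLASS_LT10:
        return int(rng.integers(school + 1, max_count + 1)), int(rng.integers(0, low))
    if category is ErrorCategory.IMG_LT10_CLASS_GT20:
        return int(rng.integers(1, low)), int(rng.integers(school + 1, max_count + 1))
    # generic miscount: rejection-sample inside the residual feasible set
    for _ in range(10000):
        n = int(rng.integers(1, max_count + 1))
        m = int(rng.integers(1, max_count + 1))
        if n == m or (n > school and m < low) or (n < low and m > school):
            continue
        return n, m
    raise ValidationError(f"feasible set of {category} appears empty")  # pragma: no cover


def simulate_count_pairs(
    category_tallies: Mapping[ErrorCategory, int],
    seed: int,
    school_threshold: int = SCHOOL_THRESHOLD,
    low_threshold: int = LOW_THRESHOLD,
    max_count: int = _DEFAULT_MAX_COUNT,
) -> list[CountPair]:
    """Emit count pairs whose classification matches the requested tallies.

    N and M are drawn uniformly from each category's feasible set and the
    result is shuffled; classify-then-tally round-trips to the request
    exactly.
    """
    for cat, k in category_tallies.items():
        if k < 0:
            raise ValidationError(f"negative tally for {cat}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    raw: list[tuple[int, int]] = []
    for cat, k in category_tallies.items():
        for _ in range(k):
            n, m = _draw_pair(rng, cat, school_threshold, low_threshold, max_count)
            got = classify_pair(CountPair("x", n, m), school_threshold, low_threshold)
            if got is not cat:  # pragma: no cover - draw logic guarantees this
                raise ValidationError(f"drew ({n},{m}) for {cat} but it classifies as {got}")
            raw.append((n, m))
    rng.shuffle(raw)
    return [CountPair(f"img{i:05d}", n, m) for i, (n, m) in enumerate(raw)]


# --------------------------------------------------------------------------
# sensor-stream simulation

@dataclass(frozen=True)
class StreamSpec:
    """Parameters of one synthetic sensor stream.

    The signal is baseline + diel sinusoid (24 h period) + tidal sinusoid
    (principal lunar semidiurnal period 12.42 h by default) + Gaussian
    noise; samples inside declared gap windows are omitted, emulating sensor
    outages.
    """

    seed: int
    variable: str = "temperature"
    units: str = "degC"
    instrument: str = "CTD"
    start: str = "2009-06-01T00:00:00Z"
    span_hours: float = 72.0
    cadence: float = 10.0  # seconds between samples
    baseline: float = 18.0
    diel_amplitude: float = 1.0
    diel_phase_hours: float = 0.0
    tidal_amplitude: float = 0.3
    tidal_period_hours: float = 12.42
    noise_sd: float = 0.05
    gaps: tuple[tuple[float, float], ...] = ()  # (offset_hours, duration_hours)


def simulate_stream(spec: StreamSpec) -> SampleStream:
    """Generate a seed-reproducible raw sample stream per the spec."""
    start = pd.Timestamp(spec.start)
    if start.tz is None:
        start = start.tz_localize("UTC")
    n = int(spec.span_hours * 3600 / spec.cadence)
    t_s = np.arange(n) * spec.cadence
    t_h = t_s / 3600.0
    values = np.full(n, spec.baseline, dtype=np.float64)
    if spec.diel_amplitude:
        values += spec.diel_amplitude * np.sin(
            2 * math.pi * (t_h - spec.diel_phase_hours) / 24.0
        )
    if spec.tidal_amplitude:
        values += spec.tidal_amplitude * np.sin(2 * math.pi * t_h / spec.tidal_period_hours)
    if spec.noise_sd:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))
        values += rng.normal(0.0, spec.noise_sd, size=n)

    keep = np.ones(n, dtype=bool)
    for off_h, dur_h in spec.gaps:
        keep &= ~((t_h >= off_h) & (t_h < off_h + dur_h))

    index = start + pd.to_timedelta(t_s[keep], unit="s")
    return SampleStream(
        instrument=spec.instrument,
        variable=spec.variable,
        samples=pd.Series(values[keep], index=index),
        nominal_interval=spec.cadence,
        units=spec.units,
    )
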