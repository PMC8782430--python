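"""Digital brain phantom, time-activity curves and dynamic acquisition.

The phantom emulates a 2D axial brain slice: an elliptical head support
containing a gray-matter shell, a white-matter core and a small tumor disc
(radius 5 pixels by default) embedded in white matter.  Regional kinetics are
piecewise-linear time-activity curves (TACs, arbitrary activity-rate units):
the tumor curve rises fast and exceeds gray matter late in the study, white
matter rises slowly to a low plateau.  These curve shapes are an emulation of
typical FDG brain kinetics, not measured data.

A dynamic study renders 24 frames (4×20 s, 4×40 s, 4×60 s, 4×180 s, 8×300 s —
60 min total) whose pixel values are *expected emissions* (frame-mean activity
rate × frame duration), forward-projects them, calibrates the global scale so
the study's expected prompts total a configurable count level (default 3.0e7,
20% of it a spatially uniform random-plus-scatter background), and draws
independent Poisson realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomSpec",
    "FrameSchedule",
    "TimeActivityCurves",
    "DynamicSeries",
    "AcquisitionSettings",
    "AcquisitionResult",
    "build_phantom",
    "default_tacs",
    "render_dynamic_images",
    "simulate_acquisition",
    "rebin_composite_frames",
]

REGIONS = ("background", "gray_matter", "white_matter", "tumor")


@dataclass
class PhantomSpec:
    """Geometry of the brain-like phantom.

    Ellipse semi-axes are fractions of the grid size; the tumor is a
    rasterized disc (pixel centers with dx²+dy² ≤ r²) that must lie fully
    inside white matter.
    """

    grid_size: int = 217
    tumor_radius: int = 5
    tumor_center: tuple[int, int] | None = None  # (row, col); default offset into WM
    head_axes: tuple[float, float] = (0.45, 0.40)
    gm_outer_axes: tuple[float, float] = (0.42, 0.36)
    wm_axes: tuple[float, float] = (0.30, 0.24)

    def __post_init__(self):
        if self.grid_size < 32:
            raise ValueError("grid_size must be at least 32")
        if self.tumor_radius < 0:
            raise ValueError("tumor_radius must be nonnegative")


@dataclass
class FrameSchedule:
    """Ordered frame durations in seconds; start times are cumulative sums."""

    durations: np.ndarray

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        if self.durations.ndim != 1 or len(self.durations) == 0:
            raise ValueError("durations must be a nonempty 1D sequence")
        if np.any(self.durations <= 0):
            raise ValueError("all frame durations must be positive")

    @classmethod
    def default(cls) -> "FrameSchedule":
        """The 24-frame, 60-minute dynamic schedule."""
        return cls([20.0] * 4 + [40.0] * 4 + [60.0] * 4 + [180.0] * 4 + [300.0] * 8)

    @property
    def start_times(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.durations)[:-1]])

    @property
    def end_times(self) -> np.ndarray:
        return np.cumsum(self.durations)

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    def __len__(self) -> int:
        return len(self.durations)


@dataclass
class TimeActivityCurves:
    """Piecewise-linear activity-rate curves per region.

    ``curves`` maps region name → (n_points, 2) array of (time s, rate)
    control points; the curve is linearly interpolated between points and held
    constant beyond the last point.  Rates are in arbitrary activity units.
    """

    curves: dict[str, np.ndarray]

    def __post_init__(self):
        clean = {}
        for name, pts in self.curves.items():
            pts = np.asarray(pts, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2:
                raise ValueError(f"TAC for {name!r} must be (n, 2) control points")
            if np.any(np.diff(pts[:, 0]) <= 0):
                raise ValueError(f"TAC times for {name!r} must be strictly increasing")
            if np.any(pts[:, 1] < 0):
                raise ValueError(f"TAC for {name!r} has negative activity")
            clean[name] = pts
        self.curves = clean

    def rate(self, region: str, t: np.ndarray) -> np.ndarray:
        pts = self.curves[region]
        return np.interp(t, pts[:, 0], pts[:, 1])

    def frame_means(self, schedule: FrameSchedule) -> dict[str, np.ndarray]:
        """Exact time-average rate of each piecewise-linear curve over each
        frame interval (trapezoid rule on segment breakpoints is exact)."""
        out = {}
        for region, pts in self.curves.items():
            means = np.empty(len(schedule))
            for i, (t0, t1) in enumerate(zip(schedule.start_times, schedule.end_times)):
                knots = pts[:, 0]
                inner = knots[(knots > t0) & (knots < t1)]
                tgrid = np.concatenate([[t0], inner, [t1]])
                vals = self.rate(region, tgrid)
                means[i] = np.trapezoid(vals, tgrid) / (t1 - t0)
            out[region] = means
        return out


def default_tacs() -> TimeActivityCurves:
    """Default regional kinetics (emulated, arbitrary units).

    Tumor rises fast and keeps accumulating; gray matter peaks early then
    washes out slightly; white matter rises slowly to a low plateau; the
    extra-cerebral head background stays low.
    """
    return TimeActivityCurves(
        {
            "background": np.array([[0.0, 0.0], [300.0, 0.25], [3600.0, 0.15]]),
            "gray_matter": np.array([[0.0, 0.0], [240.0, 1.0], [900.0, 0.9], [3600.0, 0.75]]),
            "white_matter": np.array([[0.0, 0.0], [600.0, 0.30], [3600.0, 0.35]]),
            "tumor": np.array([[0.0, 0.0], [300.0, 1.1], [1200.0, 1.5], [3600.0, 1.9]]),
        }
    )


@dataclass
class DynamicSeries:
    """Ordered stack of 2D frames (images or sinograms) with its schedule."""

    schedule: FrameSchedule
    frames: np.ndarray  # (n_frames, H, W)
    kind: str  # "image" | "sinogram"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D stack (n_frames, H, W)")
        if self.frames.shape[0] != len(self.schedule):
            raise ValueError(
                f"{self.frames.shape[0]} frames but schedule has {len(self.schedule)}"
            )
        if self.kind not in ("image", "sinogram"):
            raise ValueError("kind must be 'image' or 'sinogram'")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise ValueError("frames must be finite and nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class AcquisitionSettings:
    total_expected_counts: float = 3.0e7
    background_fraction: float = 0.20
    realizations: int = 10
    rng_seed: int = 0

    def __post_init__(self):
        # tolerate YAML scalars like "3.0e6" that parse as strings
        self.total_expected_counts = float(self.total_expected_counts)
        self.background_fraction = float(self.background_fraction)
        self.realizations = int(self.realizations)
        self.rng_seed = int(self.rng_seed)
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must be in [0, 1)")
        if self.total_expected_counts <= 0:
            raise ValueError("total_expected_counts must be positive")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")


@dataclass
class AcquisitionResult:
    """Expected and sampled sinogram data from one simulated study."""

    trues: DynamicSeries  # expected true-coincidence sinograms
    background: DynamicSeries  # expected uniform background sinograms
    noisy: list[DynamicSeries] = field(default_factory=list)  # Poisson realizations
    scale: float = 1.0  # count calibration factor applied to projections

    @property
    def expected(self) -> np.ndarray:
        return self.trues.frames + self.background.frames


def _ellipse_mask(n: int, axes: tuple[float, float]) -> np.ndarray:
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    a = axes[0] * n
    b = axes[1] * n
    return ((xx - c) / a) ** 2 + ((yy - c) / b) ** 2 <= 1.0


def build_phantom(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Rasterize the phantom into disjoint labeled region masks.

    Returns a dict with the four region masks plus ``support`` (their union,
    the head outline).  Raises if the tumor disc is not fully inside white
    matter.
    """
    n = spec.grid_size
    head = _ellipse_mask(n, spec.head_axes)
    gm_outer = _ellipse_mask(n, spec.gm_outer_axes)
    wm = _ellipse_mask(n, spec.wm_axes)

    if spec.tumor_center is None:
        c = (n - 1) // 2
        center = (c - round(0.05 * n), c + round(0.10 * n))
    else:
        center = spec.tumor_center
    yy, xx = np.mgrid[0:n, 0:n]
    r2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    if spec.tumor_radius > 0:
        tumor = r2 <= spec.tumor_radius**2
    else:
        tumor = np.zeros((n, n), dtype=bool)  # degenerate disc is empty

    if np.any(tumor & ~wm):
        raise ValueError(
            f"tumor disc at {center} radius {spec.tumor_radius} is not fully "
            "inside white matter"
        )
    masks = {
        "background": head & ~gm_outer,
        "gray_matter": gm_outer & ~wm,
        "white_matter": wm & ~tumor,
        "tumor": tumor,
        "support": head,
    }
    return masks


def render_dynamic_images(
    masks: dict[str, np.ndarray],
    tacs: TimeActivityCurves,
    schedule: FrameSchedule,
) -> DynamicSeries:
    """Render per-frame expected-emission images.

    Each frame's pixel value is the region's frame-mean activity rate times
    the frame duration, so frames carry expected emissions rather than rates
    and Poisson sampling after projection needs no further time weighting.
    """
    regions = [k for k in masks if k != "support"]
    missing = [r for r in regions if r not in tacs.curves]
    if missing:
        raise ValueError(f"no time-activity curve for region(s): {', '.join(missing)}")
    means = tacs.frame_means(schedule)
    n = masks[regions[0]].shape[0]
    frames = np.zeros((len(schedule), n, n))
    for region in regions:
        m = masks[region]
        for i, dur in enumerate(schedule.durations):
            frames[i][m] = means[region][i] * dur
    return DynamicSeries(schedule=schedule, frames=frames, kind="image")


def simulate_acquisition(
    images: DynamicSeries,
    model,
    settings: AcquisitionSettings,
) -> AcquisitionResult:
    """Project a dynamic image series and draw Poisson count realizations.

    The noiseless projections are scaled so the study's total expected prompts
    (trues + background) equal ``total_expected_counts``; the background is a
    spatially uniform sinogram per frame whose study total is
    ``background_fraction`` of the prompts, apportioned across frames in
    proportion to each frame's trues.  One independent, seeded RNG sub-stream
    per realization.
    """
    if images.kind != "image":
        raise ValueError("simulate_acquisition expects an image-space series")
    raw = np.stack([model.forward_project(f) for f in images.frames])
    total_raw = raw.sum()
    if total_raw <= 0:
        raise ValueError("cannot calibrate counts: projections are all zero")

    total = settings.total_expected_counts
    bf = settings.background_fraction
    scale = total * (1.0 - bf) / total_raw
    trues = raw * scale

    frame_trues = trues.sum(axis=(1, 2))
    bg_totals = total * bf * frame_trues / frame_trues.sum()
    n_bins = trues.shape[1] * trues.shape[2]
    background = np.broadcast_to(
        (bg_totals / n_bins)[:, None, None], trues.shape
    ).copy()

    expected = trues + background
    seeds = np.random.SeedSequence(settings.rng_seed).spawn(settings.realizations)
    noisy = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        counts = rng.poisson(expected).astype(float)
        noisy.append(DynamicSeries(images.schedule, counts, "sinogram"))
    return AcquisitionResult(
        trues=DynamicSeries(images.schedule, trues, "sinogram"),
        background=DynamicSeries(images.schedule, background, "sinogram"),
        noisy=noisy,
        scale=scale,
    )


def rebin_composite_frames(series: DynamicSeries, n_composite: int = 3) -> DynamicSeries:
    """Sum consecutive frames into ``n_composite`` equal-duration composites.

    The study duration is divided into equal wall-clock intervals; every
    interval edge must coincide with a frame boundary (frames are Poisson
    observations and cannot be split).  Counts are conserved exactly.
    """
    total = series.schedule.total_duration
    edges = np.cumsum(series.schedule.durations)
    targets = total * np.arange(1, n_composite + 1) / n_composite
    idx = []
    for t in targets:
        hit = np.flatnonzero(np.isclose(edges, t, rtol=0, atol=1e-9))
        if len(hit) == 0:
            raise ValueError(
                f"composite interval edge at {t:g} s does not align with any "
                f"frame boundary (boundaries: {edges.tolist()})"
            )
        idx.append(hit[0] + 1)
    starts = [0] + idx[:-1]
    frames = np.stack(
        [series.frames[a:b].sum(axis=0) for a, b in zip(starts, idx)]
    )
    durations = [series.schedule.durations[a:b].sum() for a, b in zip(starts, idx)]
    return DynamicSeries(FrameSchedule(durations), frames, series.kind)
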