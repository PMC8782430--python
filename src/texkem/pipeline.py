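"""End-to-end experiment orchestration.

One configuration drives the whole study: simulate the dynamic phantom
acquisition, rebin the noisy sinograms into three equal-duration composite
frames, reconstruct each composite with 100 MLEM iterations to obtain prior
images, extract texture feature maps from the priors, build the per-method
kernels, reconstruct the requested frames with each method, and evaluate
SNR/NMSE/SSIM/SD/CRC against the known truth.

Kernel feature sets per method:

* ``mlem`` — no kernel (reference EM reconstruction);
* ``kem`` — prior intensities only;
* ``kem_glcm`` — prior intensities + GLCM correlation maps (comparator);
* ``kem_dual`` — prior intensities + IDM + LRLGE maps (the dual-texture
  method).

Everything is deterministic given the configured seed: the acquisition RNG is
the only stochastic component, and it spawns one sub-stream per noise
realization.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from . import metrics as tmetrics
from .kernel import KernelMatrix, build_kernel, feature_field_from_priors, knn_neighbors
from .phantom import (
    AcquisitionSettings,
    DynamicSeries,
    FrameSchedule,
    PhantomSpec,
    TimeActivityCurves,
    build_phantom,
    default_tacs,
    render_dynamic_images,
    rebin_composite_frames,
    simulate_acquisition,
)
from .projector import SystemModel, attenuation_from_mumap
from .recon import ReconSettings, mlem, reconstruct_dynamic

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "make_priors"]

log = logging.getLogger("texkem")

_METHOD_DESCRIPTORS = {
    "kem": ("intensity",),
    "kem_glcm": ("intensity", "glcm_correlation"),
    "kem_dual": ("intensity", "idm", "lrlge"),
}

WATER_MU_PER_MM = 0.0096  # 511 keV linear attenuation of water, per mm (≈ per pixel)


@dataclass
class KernelSettings:
    k: int = 50
    sigma: float = 1.0
    search_window: int = 9
    row_normalize: bool = True


@dataclass
class TextureSettings:
    n_gray: int = 8
    normalization: str = "global"  # quantization maxima: whole-prior or per-window


@dataclass
class ExperimentConfig:
    """Defaults reproduce the reference study conditions: 217×217 phantom,
    24-frame 60-min schedule, 3.0e7 expected counts with 20% background,
    10 realizations, k=50 neighbors, quantization to 8 levels, 100 EM
    iterations."""

    grid_size: int = 217
    tumor_radius: int = 5
    acquisition: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    texture: TextureSettings = field(default_factory=TextureSettings)
    kernel: KernelSettings = field(default_factory=KernelSettings)
    recon: ReconSettings = field(default_factory=ReconSettings)
    prior_iterations: int = 100
    n_composite: int = 3
    methods: tuple[str, ...] = ("mlem", "kem", "kem_glcm", "kem_dual")
    frames: tuple[int, ...] | None = None  # 1-based frame numbers; None = all
    attenuation_mu: float = WATER_MU_PER_MM
    seed: int = 0
    tac_curves: dict | None = None  # region -> [[t, rate], ...]; None = defaults
    frame_durations: tuple[float, ...] | None = None  # None = the 24-frame schedule

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kwargs = dict(raw)
        if "acquisition" in kwargs:
            kwargs["acquisition"] = AcquisitionSettings(**kwargs["acquisition"])
        if "texture" in kwargs:
            kwargs["texture"] = TextureSettings(**kwargs["texture"])
        if "kernel" in kwargs:
            kwargs["kernel"] = KernelSettings(**kwargs["kernel"])
        if "recon" in kwargs:
            kwargs["recon"] = ReconSettings(**kwargs["recon"])
        for key in ("methods", "frames", "frame_durations"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        d["frames"] = None if self.frames is None else list(self.frames)
        if self.frame_durations is not None:
            d["frame_durations"] = list(self.frame_durations)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    masks: dict
    truth: DynamicSeries  # count-calibrated true images
    rois: tmetrics.ROISet
    reconstructions: dict  # method -> list (per realization) of DynamicSeries
    metrics_rows: list  # dicts: realization, frame, method, snr, nmse, ssim, sd, crc


def make_priors(
    composites: DynamicSeries,
    model,
    r: DynamicSeries | None = None,
    iterations: int = 100,
) -> list[np.ndarray]:
    """MLEM prior images, one per composite frame (default 100 iterations)."""
    settings = ReconSettings(iterations=iterations)
    priors = []
    for i, y in enumerate(composites.frames):
        ri = None if r is None else r.frames[i]
        priors.append(mlem(y, model, r=ri, settings=settings).image)
    return priors


def _build_method_kernel(
    method: str,
    priors: list[np.ndarray],
    mask: np.ndarray,
    cfg: ExperimentConfig,
) -> KernelMatrix:
    field_ = feature_field_from_priors(
        priors,
        mask=mask,
        descriptors=_METHOD_DESCRIPTORS[method],
        n_gray=cfg.texture.n_gray,
        normalization=cfg.texture.normalization,
    )
    nbrs, dists = knn_neighbors(
        field_, k=cfg.kernel.k, search_window=cfg.kernel.search_window
    )
    return build_kernel(
        field_,
        nbrs,
        dists,
        sigma=cfg.kernel.sigma,
        row_normalize=cfg.kernel.row_normalize,
        search_window=cfg.kernel.search_window,
    )


def _select_frames(series: DynamicSeries, frames_1based) -> tuple[DynamicSeries, list[int]]:
    if frames_1based is None:
        return series, list(range(series.n_frames))
    idx = [f - 1 for f in frames_1based]
    sub = DynamicSeries(
        FrameSchedule(series.schedule.durations[idx]), series.frames[idx], series.kind
    )
    return sub, idx


def run_experiment(
    config: ExperimentConfig, outdir: str | Path | None = None
) -> ExperimentResult:
    """Run the full simulation → priors → kernel → reconstruction → metrics
    experiment; optionally persist all stage artifacts under ``outdir``."""
    t_start = time.time()
    stage_times: dict[str, float] = {}
    out = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        stage_times[name] = time.time()
        log.info("stage %s", name)

    _stage("phantom")
    spec = PhantomSpec(grid_size=config.grid_size, tumor_radius=config.tumor_radius)
    masks = build_phantom(spec)
    schedule = (
        FrameSchedule.default()
        if config.frame_durations is None
        else FrameSchedule(list(config.frame_durations))
    )
    tacs = (
        default_tacs()
        if config.tac_curves is None
        else TimeActivityCurves({k: np.asarray(v, float) for k, v in config.tac_curves.items()})
    )
    images = render_dynamic_images(masks, tacs, schedule)

    _stage("system_model")
    model = SystemModel.for_grid(config.grid_size)
    if config.attenuation_mu > 0:
        mu = np.where(masks["support"], config.attenuation_mu, 0.0)
        model.set_attenuation(attenuation_from_mumap(mu, model))

    _stage("acquisition")
    acq_settings = AcquisitionSettings(
        total_expected_counts=config.acquisition.total_expected_counts,
        background_fraction=config.acquisition.background_fraction,
        realizations=config.acquisition.realizations,
        rng_seed=config.seed,
    )
    acq = simulate_acquisition(images, model, acq_settings)
    truth = DynamicSeries(schedule, images.frames * acq.scale, "image")
    rois = tmetrics.rois_from_masks(masks)

    need_kernel = [m for m in config.methods if m != "mlem"]
    recons: dict[str, list[DynamicSeries]] = {m: [] for m in config.methods}
    rows: list[dict] = []
    for real_idx, noisy in enumerate(acq.noisy):
        _stage(f"realization_{real_idx}")
        kernels: dict[str, KernelMatrix] = {}
        if need_kernel:
            composites = rebin_composite_frames(noisy, config.n_composite)
            bg_composites = rebin_composite_frames(acq.background, config.n_composite)
            priors = make_priors(
                composites, model, r=bg_composites, iterations=config.prior_iterations
            )
            if out is not None:
                np.savez_compressed(
                    out / f"priors_r{real_idx}.npz", priors=np.stack(priors)
                )
            for m in need_kernel:
                kernels[m] = _build_method_kernel(m, priors, model.mask, config)

        sub, frame_idx = _select_frames(noisy, config.frames)
        r_frames = acq.background.frames[frame_idx]
        for method in config.methods:
            rec = reconstruct_dynamic(
                sub,
                model,
                method=method,
                K=kernels.get(method),
                r=r_frames,
                settings=config.recon,
            )
            recons[method].append(rec)
            for j, fi in enumerate(frame_idx):
                rep = tmetrics.evaluate(rec.frames[j], truth.frames[fi], rois)
                rows.append(
                    {
                        "realization": real_idx,
                        "frame": fi + 1,
                        "method": method,
                        "snr": rep.snr,
                        "nmse": rep.nmse,
                        "ssim": rep.ssim,
                        "sd": rep.sd,
                        "crc": rep.crc,
                    }
                )
            if out is not None:
                tio.save_series(out / f"recon_{method}_r{real_idx}.npz", rec)

    if out is not None:
        _stage("persist")
        tio.save_series(out / "truth.npz", truth)
        np.savez_compressed(
            out / "masks.npz", **{k: v for k, v in masks.items()}
        )
        with (out / "metrics.csv").open("w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["realization", "frame", "method", "snr", "nmse", "ssim", "sd", "crc"]
            )
            writer.writeheader()
            writer.writerows(rows)
        now = time.time()
        ordered = sorted(stage_times.items(), key=lambda kv: kv[1])
        durations = {
            name: (ordered[i + 1][1] if i + 1 < len(ordered) else now) - t0
            for i, (name, t0) in enumerate(ordered)
        }
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "versions": {"numpy": np.__version__, "texkem": _pkg_version()},
            "stage_seconds": {k: round(v, 3) for k, v in durations.items()},
            "total_seconds": round(now - t_start, 3),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return ExperimentResult(
        config=config,
        masks=masks,
        truth=truth,
        rois=rois,
        reconstructions=recons,
        metrics_rows=rows,
    )


def _pkg_version() -> str:
    try:
        from importlib.metadata import version

        return version("texkem")
    except Exception:
        return "unknown"
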