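"""NPZ / NIfTI serialization for dynamic series and kernel matrices.

NPZ is the canonical container: a dynamic series is stored as the frame stack
plus its schedule; a kernel matrix as a sparse COO triplet plus a JSON-encoded
metadata string.  Sinogram axis order is (radial, angle), with angle zero
meaning rays parallel to the image y-axis.  NIfTI export (frames as volumes,
schedule in a JSON sidecar) is provided for interoperability with imaging
tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .kernel import KernelMatrix
from .phantom import DynamicSeries, FrameSchedule

__all__ = [
    "save_series",
    "load_series",
    "save_kernel",
    "load_kernel",
    "export_nifti",
]


def save_series(path, series: DynamicSeries) -> None:
    np.savez_compressed(
        path,
        frames=series.frames,
        durations=series.schedule.durations,
        kind=np.array(series.kind),
    )


def load_series(path) -> DynamicSeries:
    with np.load(path) as data:
        return DynamicSeries(
            schedule=FrameSchedule(data["durations"]),
            frames=data["frames"],
            kind=str(data["kind"]),
        )


def save_kernel(path, km: KernelMatrix) -> None:
    coo = km.K.tocoo()
    meta = {
        "image_shape": list(km.image_shape),
        "sigma": km.sigma,
        "k": km.k,
        "search_window": km.search_window,
        "row_normalized": km.row_normalized,
    }
    np.savez_compressed(
        path,
        rows=coo.row,
        cols=coo.col,
        values=coo.data,
        meta=np.array(json.dumps(meta)),
    )


def load_kernel(path) -> KernelMatrix:
    with np.load(path) as data:
        meta = json.loads(str(data["meta"]))
        n = int(np.prod(meta["image_shape"]))
        K = sp.coo_matrix(
            (data["values"], (data["rows"], data["cols"])), shape=(n, n)
        ).tocsr()
    return KernelMatrix(
        K=K,
        image_shape=tuple(meta["image_shape"]),
        sigma=meta["sigma"],
        k=meta["k"],
        search_window=meta["search_window"],
        row_normalized=meta["row_normalized"],
    )


def export_nifti(path, series: DynamicSeries) -> None:
    """Write frames as a (H, W, 1, T) NIfTI volume with a schedule sidecar."""
    import nibabel as nib

    path = Path(path)
    vol = np.transpose(series.frames, (1, 2, 0))[:, :, None, :]
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
    sidecar = path.with_suffix("").with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"frame_durations_s": series.schedule.durations.tolist(), "kind": series.kind}
        )
    )
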