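"""Stack assembly and geometric preparation.

Serial FIB-SEM acquisitions are sometimes split across sessions and must be
concatenated; consecutive frames drift laterally and are re-registered by
maximizing mutual information under a small translation bound; and label
volumes are optionally downsampled before the (cubic-cost) geometry stage.

Registration is translation-only and integer-pixel: the mutual information
between a frame and its aligned predecessor is evaluated on a 64-bin joint
intensity histogram of the overlap region for every shift inside the bound,
and the argmax is applied.  Cumulative drift of the chain is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import StereogoldError
from .volumes import ImageStack, LabelVolume

__all__ = [
    "AlignmentResult",
    "concatenate_stacks",
    "align_stack_translation",
    "resize_volume",
    "crop_volume",
    "mutual_information",
]

_MI_BINS = 64


@dataclass
class AlignmentResult:
    """Per-frame integer shifts applied during alignment.

    ``offsets[k]`` is the ``(row, col)`` shift applied to frame ``k`` (frame 0
    is the fixed reference and has offset ``(0, 0)``).
    """

    offsets: np.ndarray  # (n_frames, 2) int
    max_translation_fraction: float


def concatenate_stacks(stacks: list[ImageStack]) -> ImageStack:
    """Concatenate acquisition sessions along Z, preserving frame order."""
    if not stacks:
        raise ValueError("need at least one stack")
    first = stacks[0]
    for s in stacks[1:]:
        if s.data.shape[1:] != first.data.shape[1:]:
            raise StereogoldError(
                f"XY dimension mismatch: {s.data.shape[1:]} vs {first.data.shape[1:]}"
            )
        if not np.allclose(s.voxel_size, first.voxel_size):
            raise StereogoldError(
                f"voxel size mismatch: {s.voxel_size} vs {first.voxel_size}"
            )
    data = np.concatenate([s.data for s in stacks], axis=0)
    return ImageStack(data=data, voxel_size=first.voxel_size.copy())


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = _MI_BINS) -> float:
    """Mutual information of two equally-shaped images, in nats."""
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _shift_frame(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer shift with zero fill outside the frame."""
    out = np.zeros_like(frame)
    h, w = frame.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    yo = slice(max(-dy, 0), min(h - dy, h))
    xo = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = frame[yo, xo]
    return out


def _overlap_mi(ref: np.ndarray, mov: np.ndarray, dy: int, dx: int) -> float:
    h, w = ref.shape
    ys_r = slice(max(dy, 0), min(h + dy, h))
    xs_r = slice(max(dx, 0), min(w + dx, w))
    ys_m = slice(max(-dy, 0), min(h - dy, h))
    xs_m = slice(max(-dx, 0), min(w - dx, w))
    a = ref[ys_r, xs_r]
    b = mov[ys_m, xs_m]
    if a.size == 0:
        return -np.inf
    return mutual_information(a, b)


def align_stack_translation(
    stack: ImageStack,
    max_translation_fraction: float = 0.005,
    reference: str = "previous_frame",
) -> tuple[ImageStack, AlignmentResult]:
    """Chain-align every frame to its (already aligned) predecessor.

    The search window per consecutive pair is ``±floor(f * dim)`` pixels in
    each axis, e.g. the "small" 0.5% bound gives ±3 px on a 600-px frame.
    Out-of-frame pixels are zero-filled.
    """
    if reference != "previous_frame":
        raise ValueError(f"unsupported reference {reference!r}")
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames to align")
    if not (0 < max_translation_fraction <= 1):
        raise ValueError("max_translation_fraction must be in (0, 1]")

    data = np.asarray(stack.data)
    h, w = data.shape[1:]
    ry = int(np.floor(max_translation_fraction * h))
    rx = int(np.floor(max_translation_fraction * w))
    aligned = np.empty_like(data)
    aligned[0] = data[0]
    offsets = np.zeros((stack.n_frames, 2), dtype=int)

    for k in range(1, stack.n_frames):
        ref = aligned[k - 1]
        mov = data[k]
        if ref.min() == ref.max() or mov.min() == mov.max():
            raise StereogoldError(
                f"frame {k - 1 if ref.min() == ref.max() else k} is constant: "
                "mutual-information histogram is degenerate"
            )
        best = (-np.inf, 0, 0)
        for dy in range(-ry, ry + 1):
            for dx in range(-rx, rx + 1):
                mi = _overlap_mi(ref, mov, dy, dx)
                if mi > best[0]:
                    best = (mi, dy, dx)
        _, dy, dx = best
        offsets[k] = (dy, dx)
        aligned[k] = _shift_frame(mov, dy, dx)

    return (
        ImageStack(data=aligned, voxel_size=stack.voxel_size.copy()),
        AlignmentResult(offsets=offsets, max_translation_fraction=max_translation_fraction),
    )


def _nn_indices(n_in: int, n_out: int) -> np.ndarray:
    # output voxel i samples the input voxel whose centre is nearest
    return np.minimum(((np.arange(n_out) + 0.5) * n_in / n_out).astype(int), n_in - 1)


def resize_volume(vol, factor: float, resize_z: bool = False):
    """Downsample a volume by ``factor`` in XY (and optionally Z).

    Label volumes are resampled nearest-neighbour so no new label can appear;
    image stacks are resampled with local averaging.  The physical voxel size
    is rescaled so the total physical extent is preserved.
    """
    if not (0 < factor <= 1):
        raise ValueError(f"resize factor must be in (0, 1], got {factor}")
    if factor == 1.0:
        return type(vol)(data=vol.data.copy(), voxel_size=vol.voxel_size.copy())

    nz, ny, nx = vol.data.shape
    out_shape = [
        max(1, round(nz * factor)) if resize_z else nz,
        max(1, round(ny * factor)),
        max(1, round(nx * factor)),
    ]
    scale = np.array(
        [nx / out_shape[2], ny / out_shape[1], nz / out_shape[0]]
    )  # (x, y, z) factors applied to the voxel size
    new_vs = vol.voxel_size * scale

    if isinstance(vol, LabelVolume):
        iz = _nn_indices(nz, out_shape[0])
        iy = _nn_indices(ny, out_shape[1])
        ix = _nn_indices(nx, out_shape[2])
        data = vol.data[np.ix_(iz, iy, ix)]
        return LabelVolume(data=data, voxel_size=new_vs)
    data = _sk_resize(
        vol.data.astype(float), out_shape, order=1, anti_aliasing=True, preserve_range=True
    )
    return ImageStack(data=np.clip(np.rint(data), 0, 255).astype(vol.data.dtype),
                      voxel_size=new_vs)


def crop_volume(vol, box):
    """Crop to an axis-aligned voxel box ``((z0, z1), (y0, y1), (x0, x1))``
    with half-open bounds; voxel size is unchanged."""
    (z0, z1), (y0, y1), (x0, x1) = box
    nz, ny, nx = vol.data.shape
    if not (0 <= z0 < z1 <= nz and 0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
        raise ValueError(f"crop box {box} empty or outside volume of shape {(nz, ny, nx)}")
    return type(vol)(data=vol.data[z0:z1, y0:y1, x0:x1].copy(),
                     voxel_size=vol.voxel_size.copy())
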