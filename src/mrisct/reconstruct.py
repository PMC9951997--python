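"""Inverse of the channel decomposition: scaled triplets back to HU volumes.

Generator outputs live in [-1, 1] per channel; each channel is rescaled to its
HU interval and the slice reassembled through the same tissue masks used for
segmentation.  Stacked slices are then resized (linear, per slice) onto the
original MRI in-plane grid — resizing happens after reassembly, mirroring the
forward pipeline's order.
"""

from __future__ import annotations

import numpy as np

from .preprocess import CHANNEL_NAMES, ChannelTriplet, resize_slice, scale_channels
from .volume import HU_MAX, HU_MIN, ImageVolume


def reassemble_slice(t: ChannelTriplet) -> np.ndarray:
    """Merge a scaled triplet into a single HU slice.

    Every body pixel takes the rescaled value of the channel that owns it;
    non-body pixels are -1000 HU.  Overlapping masks are rejected (a pixel
    with two owners has no well-defined HU).
    """
    overlap = sum(t.masks[n].astype(int) for n in CHANNEL_NAMES)
    if (overlap > 1).any():
        raise ValueError("overlapping channel masks")
    hu_t = scale_channels(t, "to_hu") if t.scaled else t
    out = np.full(t.shape, HU_MIN, dtype=np.float64)
    for n in CHANNEL_NAMES:
        m = t.masks[n]
        out[m] = hu_t.channels[n][m]
    return np.clip(out, HU_MIN, HU_MAX)


def stack_volume(
    slices: list[np.ndarray],
    target_grid: ImageVolume,
    background_masks: list[np.ndarray] | None = None,
) -> ImageVolume:
    """Stack HU slices and resize them onto ``target_grid``'s in-plane shape.

    ``background_masks`` (per-slice boolean, True = background at the slices'
    own resolution) are resized nearest-neighbour and force -1000 HU, keeping
    interpolation from bleeding tissue HU into the background.
    """
    nz, ny, nx = target_grid.shape
    if len(slices) != nz:
        raise ValueError(f"expected {nz} slices, got {len(slices)}")
    out = np.empty((nz, ny, nx), dtype=np.float64)
    bg_out = np.zeros((nz, ny, nx), dtype=bool)
    for k, sl in enumerate(slices):
        out[k] = resize_slice(np.asarray(sl, dtype=np.float64), (ny, nx))
        if background_masks is not None:
            bg = resize_slice(np.asarray(background_masks[k]), (ny, nx), is_mask=True)
            out[k][bg] = HU_MIN
            bg_out[k] = bg
    out = np.clip(out, HU_MIN, HU_MAX)
    return ImageVolume(
        out,
        target_grid.spacing,
        target_grid.origin,
        modality="CT",
        background_mask=bg_out if background_masks is not None else None,
    )
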