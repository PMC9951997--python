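"""Conditioning of CT/MRI pairs and the three-channel decomposition.

The translation network does not see raw volumes: CT is resampled to the MRI
grid and clipped to [-1000, +1047] HU, MRI goes through bias-field correction,
bilateral denoising, 99th-percentile clipping and histogram matching, and both
are decomposed per transversal slice into air / bone / soft-tissue channels by
HU range (air [-1000, -800), soft [-800, 150), bone [150, 1047]), each channel
linearly scaled to [-1, 1].  Training data is enlarged 8-fold by a fixed set of
geometric/noise transforms applied identically to the two modalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from skimage import transform as sktransform
from skimage.exposure import match_histograms
from skimage.restoration import denoise_bilateral

from .volume import HU_MAX, HU_MIN, ImageVolume

CHANNEL_NAMES = ("air", "bone", "soft")


@dataclass(frozen=True)
class ChannelRanges:
    """Half-open HU partition of the conditioned CT span.

    The printed clinical ranges share their endpoints; disjointness (required
    for mask-based reassembly) is restored by assigning each boundary to the
    upper class: -800 belongs to soft, 150 belongs to bone.
    """

    air: tuple[float, float] = (HU_MIN, -800.0)
    soft: tuple[float, float] = (-800.0, 150.0)
    bone: tuple[float, float] = (150.0, HU_MAX)

    def masks(self, hu: np.ndarray, body: np.ndarray) -> dict[str, np.ndarray]:
        return {
            "air": body & (hu < self.air[1]),
            "soft": body & (hu >= self.soft[0]) & (hu < self.soft[1]),
            "bone": body & (hu >= self.bone[0]),
        }

    def range_of(self, name: str) -> tuple[float, float]:
        return getattr(self, name)


@dataclass
class ChannelTriplet:
    """One transversal slice split into air/bone/soft channels.

    ``channels[name]`` holds the source intensities inside ``masks[name]``
    (or [-1, 1] values once ``scaled`` is True); ``ranges[name]`` is the
    affine scaling interval needed to invert the decomposition.
    """

    channels: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    ranges: dict[str, tuple[float, float]]
    scaled: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels["air"].shape

    @property
    def body_mask(self) -> np.ndarray:
        m = self.masks
        return m["air"] | m["bone"] | m["soft"]

    def stack(self) -> np.ndarray:
        """(3, H, W) array in the fixed channel order air, bone, soft."""
        return np.stack([self.channels[n] for n in CHANNEL_NAMES])

    def copy(self) -> "ChannelTriplet":
        return ChannelTriplet(
            {k: v.copy() for k, v in self.channels.items()},
            {k: v.copy() for k, v in self.masks.items()},
            dict(self.ranges),
            self.scaled,
        )


# ---------------------------------------------------------------------------
# SimpleITK bridges
# ---------------------------------------------------------------------------

def _to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.astype(np.float64)))
    dz, dy, dx = vol.spacing
    oz, oy, ox = vol.origin
    img.SetSpacing((dx, dy, dz))
    img.SetOrigin((ox, oy, oz))
    return img


def _grid_extent(vol: ImageVolume) -> tuple[np.ndarray, np.ndarray]:
    lo = np.asarray(vol.origin)
    hi = lo + np.asarray(vol.spacing) * np.asarray(vol.shape)
    return lo, hi


def prepare_ct(ct: ImageVolume, mri_grid: ImageVolume) -> ImageVolume:
    """Resample a CT onto the MRI voxel grid and condition the HU.

    Assumes the pair is already rigidly aligned.  Output values are clipped to
    [-1000, +1047] HU and background voxels forced to -1000 HU.
    """
    if ct.modality != "CT":
        raise ValueError("prepare_ct expects a CT volume")
    lo_a, hi_a = _grid_extent(ct)
    lo_b, hi_b = _grid_extent(mri_grid)
    if np.any(hi_a <= lo_b) or np.any(hi_b <= lo_a):
        raise ValueError("CT and MRI grids do not overlap")

    ref = _to_sitk(mri_grid)
    moving = _to_sitk(ct)
    res = sitk.Resample(moving, ref, sitk.Transform(), sitk.sitkLinear, float(HU_MIN))
    values = np.clip(sitk.GetArrayFromImage(res), HU_MIN, HU_MAX)

    background = None
    if ct.background_mask is not None:
        bg = _to_sitk(ct.copy_with(values=ct.background_mask.astype(np.float64)))
        bg_res = sitk.Resample(bg, ref, sitk.Transform(), sitk.sitkNearestNeighbor, 1.0)
        background = sitk.GetArrayFromImage(bg_res) > 0.5
        values[background] = HU_MIN
    return ImageVolume(
        values, mri_grid.spacing, mri_grid.origin, "CT", background_mask=background
    )


def correct_bias_field(mri: ImageVolume, shrink: int = 2,
                       iterations: tuple[int, ...] = (20, 10)) -> ImageVolume:
    """N4 multiplicative bias-field correction with a fixed iteration budget."""
    img = _to_sitk(mri)
    mask = sitk.GetImageFromArray(mri.body_mask.astype(np.uint8))
    mask.CopyInformation(img)
    small = sitk.Shrink(img, [shrink] * 3)
    small_mask = sitk.Shrink(mask, [shrink] * 3)
    n4 = sitk.N4BiasFieldCorrectionImageFilter()
    n4.SetMaximumNumberOfIterations(list(iterations))
    n4.Execute(small, small_mask)
    log_field = n4.GetLogBiasFieldAsImage(img)
    corrected = mri.values / np.exp(sitk.GetArrayFromImage(log_field))
    return mri.copy_with(values=corrected)


def prepare_mri(
    mri: ImageVolume,
    reference: ImageVolume | None = None,
    sigma_spatial_vox: float = 2.0,
    sigma_intensity_frac: float = 0.05,
) -> ImageVolume:
    """Condition an MRI volume for the network.

    Steps, in order: (i) N4-style bias-field correction, (ii) per-slice
    bilateral denoising, (iii) clipping at the 99th percentile of the in-body
    intensity, (iv) background set to zero, (v) monotone histogram matching of
    the in-body intensities to ``reference`` (skipped when None).
    """
    if mri.modality != "MRI":
        raise ValueError("prepare_mri expects an MRI volume")
    if not np.any(mri.values > 0):
        raise ValueError("all-zero MRI volume")

    vol = correct_bias_field(mri)
    body = vol.body_mask

    rng_ = float(vol.values.max() - vol.values.min())
    vals = np.empty_like(vol.values, dtype=np.float64)
    for k in range(vol.shape[0]):
        sl = vol.values[k].astype(np.float64)
        if rng_ > 0:
            vals[k] = denoise_bilateral(
                sl,
                sigma_color=sigma_intensity_frac * rng_,
                sigma_spatial=sigma_spatial_vox,
            )
        else:
            vals[k] = sl

    clip = float(np.percentile(vals[body], 99.0))
    vals = np.clip(vals, 0.0, clip)
    vals[~body] = 0.0

    if reference is not None:
        ref_body = reference.values[reference.body_mask]
        matched = match_histograms(vals[body], np.asarray(ref_body, dtype=np.float64))
        vals = vals.copy()
        vals[body] = matched
    return mri.copy_with(values=vals)


# ---------------------------------------------------------------------------
# channel decomposition
# ---------------------------------------------------------------------------

def segment_channels(
    vol: ImageVolume,
    masks: dict[str, np.ndarray] | None = None,
    ranges: ChannelRanges | None = None,
) -> list[ChannelTriplet]:
    """Split a volume into per-slice air/bone/soft channel triplets.

    Without external masks the volume must be a conditioned CT and the masks
    are derived from its own HU ranges.  With external masks (3D boolean grids,
    the MRI-only scenario) the masks must be disjoint and inside the body; the
    channels then carry the volume's own intensities.  For MRI volumes every
    channel shares the [0, in-body max] scaling interval.
    """
    ranges = ranges or ChannelRanges()
    body = vol.body_mask
    if masks is None:
        if vol.modality != "CT":
            raise ValueError("CT-range segmentation needs a CT volume")
        if vol.values.min() < HU_MIN - 1e-9 or vol.values.max() > HU_MAX + 1e-9:
            raise ValueError("CT must be conditioned (clipped) before segmentation")
        masks3d = ranges.masks(vol.values, body)
    else:
        masks3d = {n: np.asarray(masks[n], dtype=bool) for n in CHANNEL_NAMES}
        overlap = (
            masks3d["air"].astype(int) + masks3d["bone"].astype(int)
            + masks3d["soft"].astype(int)
        )
        if (overlap > 1).any():
            raise ValueError("channel masks must be disjoint")
        union = masks3d["air"] | masks3d["bone"] | masks3d["soft"]
        if (union & ~body).any():
            raise ValueError("channel mask voxel outside the body")

    if vol.modality == "MRI":
        vmax = float(vol.values[body].max()) if body.any() else 1.0
        chan_ranges = {n: (0.0, max(vmax, 1e-9)) for n in CHANNEL_NAMES}
    else:
        chan_ranges = {n: ranges.range_of(n) for n in CHANNEL_NAMES}

    triplets = []
    for k in range(vol.shape[0]):
        channels = {}
        slice_masks = {}
        for n in CHANNEL_NAMES:
            m = masks3d[n][k]
            ch = np.full(m.shape, chan_ranges[n][0], dtype=np.float64)
            ch[m] = vol.values[k][m]
            channels[n] = ch
            slice_masks[n] = m
        triplets.append(ChannelTriplet(channels, slice_masks, dict(chan_ranges), scaled=False))
    return triplets


def scale_channels(t: ChannelTriplet, direction: str) -> ChannelTriplet:
    """Affine per-channel scaling between source units and [-1, 1].

    ``to_unit`` maps each channel's [lo, hi] range onto [-1, 1] and fills
    out-of-mask pixels with -1 (the channel minimum); ``to_hu`` inverts it and
    fills out-of-mask pixels with the range minimum.  The two directions
    compose to the identity inside the masks.
    """
    if direction not in ("to_unit", "to_hu"):
        raise ValueError("direction must be 'to_unit' or 'to_hu'")
    out = t.copy()
    for n in CHANNEL_NAMES:
        lo, hi = t.ranges[n]
        if hi <= lo:
            raise ValueError(f"degenerate range for channel {n}: [{lo}, {hi}]")
        ch = t.channels[n]
        m = t.masks[n]
        if direction == "to_unit":
            if t.scaled:
                raise ValueError("triplet already scaled to [-1, 1]")
            scaled = 2.0 * (ch - lo) / (hi - lo) - 1.0
            scaled = np.where(m, np.clip(scaled, -1.0, 1.0), -1.0)
            out.channels[n] = scaled
        else:
            if not t.scaled:
                raise ValueError("triplet is not in [-1, 1] units")
            hu = (ch + 1.0) / 2.0 * (hi - lo) + lo
            hu = np.where(m, np.clip(hu, lo, hi), lo)
            out.channels[n] = hu
    out.scaled = direction == "to_unit"
    return out


# ---------------------------------------------------------------------------
# resizing
# ---------------------------------------------------------------------------

def resize_slice(arr: np.ndarray, shape: tuple[int, int], is_mask: bool = False) -> np.ndarray:
    """Anisotropic stretch to ``shape``: linear for intensities, nearest for masks."""
    if arr.shape == tuple(shape):
        return arr.copy()
    order = 0 if is_mask else 1
    out = sktransform.resize(
        arr.astype(np.float64), shape, order=order,
        anti_aliasing=False, preserve_range=True, mode="edge",
    )
    return out > 0.5 if is_mask else out


def resize_to_net(t: ChannelTriplet, size: int) -> ChannelTriplet:
    """Resize a triplet's channels (linear) and masks (nearest) to size x size."""
    shape = (size, size)
    channels = {n: resize_slice(t.channels[n], shape) for n in CHANNEL_NAMES}
    masks = {n: resize_slice(t.masks[n], shape, is_mask=True) for n in CHANNEL_NAMES}
    if t.scaled:
        channels = {n: np.clip(c, -1.0, 1.0) for n, c in channels.items()}
    return ChannelTriplet(channels, masks, dict(t.ranges), t.scaled)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationSpec:
    """The eight training-set transforms and their magnitudes.

    Geometric transforms are applied identically to the MRI and CT triplets of
    a pair; Gaussian noise is added to the MRI channels only.
    """

    rotation_deg: float = 10.0
    shear_deg: float = 8.0
    crop_fraction: float = 0.9
    noise_sd_fraction: float = 0.02  # of the [-1, 1] dynamic range (= 2)
    seed: int = 0
    transforms: tuple[str, ...] = (
        "hflip", "vflip", "noise", "shear", "rotation", "crop",
        "hflip+noise", "rotation+crop",
    )


def _affine_about_center(shape, rotation_deg=0.0, shear_deg=0.0):
    h, w = shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (
        sktransform.AffineTransform(translation=-center)
        + sktransform.AffineTransform(
            rotation=np.deg2rad(rotation_deg), shear=np.deg2rad(shear_deg)
        )
        + sktransform.AffineTransform(translation=center)
    )
    return tf


def _warp(arr: np.ndarray, tf, is_mask: bool, fill: float) -> np.ndarray:
    out = sktransform.warp(
        arr.astype(np.float64), tf.inverse, order=0 if is_mask else 1,
        cval=False if is_mask else fill, preserve_range=True, mode="constant",
    )
    return out > 0.5 if is_mask else out


def _apply_geometric(t: ChannelTriplet, name: str, spec: AugmentationSpec) -> ChannelTriplet:
    fill = -1.0 if t.scaled else min(lo for lo, _ in t.ranges.values())
    out = t.copy()
    if name == "hflip":
        for n in CHANNEL_NAMES:
            out.channels[n] = out.channels[n][:, ::-1].copy()
            out.masks[n] = out.masks[n][:, ::-1].copy()
    elif name == "vflip":
        for n in CHANNEL_NAMES:
            out.channels[n] = out.channels[n][::-1, :].copy()
            out.masks[n] = out.masks[n][::-1, :].copy()
    elif name in ("rotation", "shear"):
        tf = _affine_about_center(
            t.shape,
            rotation_deg=spec.rotation_deg if name == "rotation" else 0.0,
            shear_deg=spec.shear_deg if name == "shear" else 0.0,
        )
        for n in CHANNEL_NAMES:
            out.channels[n] = _warp(out.channels[n], tf, False, fill)
            out.masks[n] = _warp(out.masks[n], tf, True, fill)
    elif name == "crop":
        h, w = t.shape
        ch_, cw = int(round(h * spec.crop_fraction)), int(round(w * spec.crop_fraction))
        r0, c0 = (h - ch_) // 2, (w - cw) // 2
        for n in CHANNEL_NAMES:
            out.channels[n] = resize_slice(out.channels[n][r0:r0 + ch_, c0:c0 + cw], (h, w))
            out.masks[n] = resize_slice(out.masks[n][r0:r0 + ch_, c0:c0 + cw], (h, w), is_mask=True)
    else:
        raise ValueError(f"unknown geometric transform {name!r}")
    if out.scaled:
        for n in CHANNEL_NAMES:
            out.channels[n] = np.clip(out.channels[n], -1.0, 1.0)
    return out


def _add_noise(t: ChannelTriplet, spec: AugmentationSpec, rng: np.random.Generator) -> ChannelTriplet:
    out = t.copy()
    sd = spec.noise_sd_fraction * 2.0
    for n in CHANNEL_NAMES:
        noisy = out.channels[n] + rng.normal(0.0, sd, size=out.channels[n].shape)
        if out.scaled:
            noisy = np.clip(noisy, -1.0, 1.0)
            noisy[~out.masks[n]] = -1.0
        out.channels[n] = noisy
    return out


def augment_pair(
    pair: tuple[ChannelTriplet, ChannelTriplet], spec: AugmentationSpec
) -> list[tuple[ChannelTriplet, ChannelTriplet]]:
    """Produce the 8 transformed (MRI, CT) triplet pairs for one input pair."""
    mri_t, ct_t = pair
    rng = np.random.default_rng(spec.seed)
    out = []
    for name in spec.transforms:
        m, c = mri_t.copy(), ct_t.copy()
        for part in name.split("+"):
            if part == "noise":
                m = _add_noise(m, spec, rng)  # noise on the MRI channels only
            else:
                m = _apply_geometric(m, part, spec)
                c = _apply_geometric(c, part, spec)
        out.append((m, c))
    return out
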