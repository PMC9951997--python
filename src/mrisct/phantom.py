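"""Synthetic abdominal CT/MRI phantom, mismatch simulation and toy carbon-ion dose.

The phantom is a deliberately simple stand-in for an anthropomorphic digital
phantom: analytic ellipsoids/cylinders/spheres rasterized on the voxel grid
render both a CT (Hounsfield units) and an MRI (arbitrary intensities with a
multiplicative bias field) of identical geometry, so that the image-translation
and dosimetric-evaluation stages downstream can be exercised end to end with a
known, voxel-wise ground truth.

``toy_dose`` is an analytic depth-dose engine, not a clinical dose calculation:
HU are mapped to relative stopping power by a fixed piecewise-linear lookup,
water-equivalent depth is accumulated along the (axis-aligned) beam, and a
Bragg-like curve is placed so its peak sits at the nominal water-equivalent
range, broadened laterally by a Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import HU_MAX, HU_MIN, ImageVolume

# tissue classes and the HU intervals they must occupy (half-open at the top
# boundary for air/soft; see preprocess.ChannelRanges)
TISSUE_AIR = "air"
TISSUE_BONE = "bone"
TISSUE_SOFT = "soft"

_CLASS_BOUNDS = {
    TISSUE_AIR: (HU_MIN, -800.0),
    TISSUE_SOFT: (-800.0, 150.0),
    TISSUE_BONE: (150.0, HU_MAX),
}


@dataclass(frozen=True)
class Organ:
    """An analytic solid: ``ellipsoid`` (also spheres), or z-aligned ``cylinder``."""

    name: str
    shape: str  # "ellipsoid" | "cylinder"
    center: tuple[float, float, float]  # mm, (z, y, x); z ignored for cylinders
    semi_axes: tuple[float, float, float]  # mm, (z, y, x); z ignored for cylinders
    tissue: str  # TISSUE_AIR | TISSUE_BONE | TISSUE_SOFT
    label: int

    def contains(self, zz: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
        cz, cy, cx = self.center
        az, ay, ax = self.semi_axes
        if self.shape == "cylinder":
            return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        if self.shape == "ellipsoid":
            return (
                ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
                <= 1.0
            )
        raise ValueError(f"unknown organ shape {self.shape!r}")


def _default_organs() -> tuple[Organ, ...]:
    # grid default is 32 x 96 x 96 voxels at 3 x 2 x 2 mm -> 96 x 192 x 192 mm
    return (
        Organ("body", "cylinder", (48, 96, 96), (1e9, 72, 86), TISSUE_SOFT, 1),
        Organ("vertebra", "cylinder", (48, 140, 96), (1e9, 13, 13), TISSUE_BONE, 2),
        Organ("rib_l", "ellipsoid", (48, 60, 28), (8, 6, 9), TISSUE_BONE, 3),
        Organ("rib_r", "ellipsoid", (48, 60, 164), (8, 6, 9), TISSUE_BONE, 4),
        Organ("kidney_l", "ellipsoid", (48, 118, 52), (26, 17, 14), TISSUE_SOFT, 5),
        Organ("kidney_r", "ellipsoid", (48, 118, 140), (26, 17, 14), TISSUE_SOFT, 6),
        Organ("stomach_air", "ellipsoid", (60, 66, 70), (18, 15, 16), TISSUE_AIR, 7),
        Organ("colon_air", "ellipsoid", (27, 68, 128), (12, 11, 12), TISSUE_AIR, 8),
        Organ("tumor", "ellipsoid", (48, 90, 104), (10, 10, 10), TISSUE_SOFT, 9),
    )


def _default_hu_table() -> dict[str, tuple[float, float]]:
    # (mean HU, noise SD)
    return {
        "body": (40.0, 12.0),
        "vertebra": (700.0, 40.0),
        "rib_l": (600.0, 40.0),
        "rib_r": (600.0, 40.0),
        "kidney_l": (30.0, 10.0),
        "kidney_r": (30.0, 10.0),
        "stomach_air": (-950.0, 20.0),
        "colon_air": (-950.0, 20.0),
        "tumor": (60.0, 10.0),
    }


def _default_mri_table() -> dict[str, tuple[float, float]]:
    # (mean intensity, noise SD), arbitrary units
    return {
        "body": (400.0, 15.0),
        "vertebra": (120.0, 10.0),
        "rib_l": (130.0, 10.0),
        "rib_r": (130.0, 10.0),
        "kidney_l": (620.0, 15.0),
        "kidney_r": (620.0, 15.0),
        "stomach_air": (25.0, 5.0),
        "colon_air": (25.0, 5.0),
        "tumor": (720.0, 15.0),
    }


@dataclass
class PhantomSpec:
    """Geometry, intensity tables and noise model of one synthetic patient."""

    grid_shape: tuple[int, int, int] = (32, 96, 96)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (3.0, 2.0, 2.0)  # mm, (dz, dy, dx)
    organs: tuple[Organ, ...] = field(default_factory=_default_organs)
    hu_table: dict[str, tuple[float, float]] = field(default_factory=_default_hu_table)
    mri_table: dict[str, tuple[float, float]] = field(default_factory=_default_mri_table)
    bias_amplitude: float = 0.15  # multiplicative polynomial bias on MRI
    seed: int = 0

    def validate(self) -> None:
        if any(n < 32 for n in self.grid_shape):
            raise ValueError("grid_shape must be at least 32 voxels per axis")
        names = [o.name for o in self.organs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate organ names")
        if names[0] != "body":
            raise ValueError("first organ must be the body outline")
        for o in self.organs:
            lo, hi = _CLASS_BOUNDS[o.tissue]
            mean = self.hu_table[o.name][0]
            if not (lo <= mean < hi or (o.tissue == TISSUE_BONE and mean == hi)):
                raise ValueError(
                    f"organ {o.name}: HU mean {mean} outside its {o.tissue} range"
                )

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=int(seed))

    def jittered(self, seed: int, magnitude_mm: float = 6.0, max_tries: int = 20) -> "PhantomSpec":
        """Perturb organ centers (not the body) to emulate inter-patient variety.

        Draws are retried (deterministically) until no two organs claim the
        same voxel, so any jitter magnitude yields a valid phantom.
        """
        rng = np.random.default_rng(seed)
        for _ in range(max_tries):
            organs = [self.organs[0]]
            for o in self.organs[1:]:
                dz, dy, dx = rng.uniform(-magnitude_mm, magnitude_mm, size=3)
                organs.append(
                    replace(o, center=(o.center[0] + dz, o.center[1] + dy, o.center[2] + dx))
                )
            out = replace(self, organs=tuple(organs), seed=int(seed))
            try:
                rasterize_labels(out)
            except ValueError:
                continue
            return out
        raise ValueError("could not draw a non-overlapping jittered phantom")


def _coordinate_grids(spec: PhantomSpec):
    nz, ny, nx = spec.grid_shape
    dz, dy, dx = spec.spacing
    z = (np.arange(nz) + 0.5) * dz
    y = (np.arange(ny) + 0.5) * dy
    x = (np.arange(nx) + 0.5) * dx
    return np.meshgrid(z, y, x, indexing="ij")


def rasterize_labels(spec: PhantomSpec) -> np.ndarray:
    """Rasterize organs onto the voxel grid; 0 = background.

    Non-body organs must not overlap each other (a voxel with two tissue
    identities is ambiguous and the spec is rejected).
    """
    spec.validate()
    zz, yy, xx = _coordinate_grids(spec)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    body = spec.organs[0]
    body_mask = body.contains(zz, yy, xx)
    labels[body_mask] = body.label
    coverage = np.zeros(spec.grid_shape, dtype=np.int16)
    for o in spec.organs[1:]:
        m = o.contains(zz, yy, xx) & body_mask
        coverage += m
        labels[m] = o.label
    if (coverage > 1).any():
        raise ValueError("overlapping organ definitions: ambiguous voxel tissue")
    return labels


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field, 1 + a * (second-order polynomial in [-1,1]^3)."""
    nz, ny, nx = spec.grid_shape
    z = np.linspace(-1, 1, nz)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    x = np.linspace(-1, 1, nx)[None, None, :]
    c = rng.uniform(-1, 1, size=9)
    poly = (
        c[0] * z + c[1] * y + c[2] * x
        + c[3] * z * y + c[4] * y * x + c[5] * z * x
        + c[6] * z**2 + c[7] * y**2 + c[8] * x**2
    )
    poly = poly / max(np.abs(poly).max(), 1e-12)
    return 1.0 + spec.bias_amplitude * poly


def generate_pair(spec: PhantomSpec) -> tuple[ImageVolume, ImageVolume, ImageVolume]:
    """Render the co-registered (CT, MRI, label) triple for one phantom.

    The CT and MRI share the exact same rasterized geometry: with all noise
    SDs zero and bias amplitude zero they are deterministic functions of the
    intensity tables.
    """
    labels = rasterize_labels(spec)
    rng = np.random.default_rng(spec.seed)
    ct = np.full(spec.grid_shape, HU_MIN, dtype=np.float64)
    mri = np.zeros(spec.grid_shape, dtype=np.float64)
    for o in spec.organs:
        m = labels == o.label
        hu_mean, hu_sd = spec.hu_table[o.name]
        mri_mean, mri_sd = spec.mri_table[o.name]
        n = int(m.sum())
        ct[m] = hu_mean + (hu_sd * rng.standard_normal(n) if hu_sd > 0 else 0.0)
        mri[m] = mri_mean + (mri_sd * rng.standard_normal(n) if mri_sd > 0 else 0.0)
    ct = np.clip(ct, HU_MIN, HU_MAX)
    bias = _bias_field(spec, rng) if spec.bias_amplitude > 0 else 1.0
    mri = np.clip(mri * bias, 0.0, None)
    background = labels == 0
    mri[background] = 0.0
    dz_dy_dx = spec.spacing
    ct_vol = ImageVolume(ct, dz_dy_dx, modality="CT", background_mask=background)
    mri_vol = ImageVolume(mri, dz_dy_dx, modality="MRI", background_mask=background)
    label_vol = ImageVolume(labels, dz_dy_dx, modality="LABEL", background_mask=background)
    return ct_vol, mri_vol, label_vol


# ---------------------------------------------------------------------------
# inter-acquisition mismatch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MismatchSpec:
    """Rigid displacement and/or volume rescale of one structure.

    Emulates inter-acquisition anatomical change (chiefly mobile air fillings)
    between the CT and MRI scans of the same patient.  ``volume_scale`` is a
    volumetric factor (0 removes the pocket); ``applies_to`` records which
    member of the pair the change is meant for.
    """

    structure: str
    displacement_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (z, y, x)
    volume_scale: float = 1.0
    applies_to: str = "mri"

    @property
    def is_identity(self) -> bool:
        return self.volume_scale == 1.0 and all(d == 0.0 for d in self.displacement_mm)


def apply_mismatch(
    vol: ImageVolume,
    labels: ImageVolume,
    spec_or_organs: PhantomSpec | tuple[Organ, ...],
    m: MismatchSpec,
) -> tuple[ImageVolume, ImageVolume]:
    """Move/rescale one labelled structure inside the body.

    The vacated voxels take the representative (median) value of the body soft
    tissue; the relocated voxels take the structure's own representative value.
    Zero mismatch returns bit-exact copies.  A displacement that pushes the
    structure outside the body raises ``ValueError``.

    Returns the transformed volume and the updated label map.
    """
    organs = spec_or_organs.organs if isinstance(spec_or_organs, PhantomSpec) else spec_or_organs
    by_name = {o.name: o for o in organs}
    if m.structure not in by_name:
        raise ValueError(f"unknown structure {m.structure!r}")
    organ = by_name[m.structure]

    lab = labels.values.astype(np.int16)
    if m.is_identity:
        return (
            vol.copy_with(values=vol.values.copy()),
            labels.copy_with(values=lab.copy()),
        )

    mask = lab == organ.label
    if not mask.any():
        raise ValueError(f"structure {m.structure!r} not present in the label map")
    body = lab > 0

    values = vol.values.astype(np.float64).copy()
    struct_value = float(np.median(vol.values[mask]))
    body_soft = lab == by_name["body"].label
    fill_value = float(np.median(vol.values[body_soft]))

    # transformed mask: scale about the centroid, then translate (in voxels)
    new_mask = np.zeros_like(mask)
    if m.volume_scale > 0:
        lin = m.volume_scale ** (1.0 / 3.0)
        centroid = np.array(ndimage.center_of_mass(mask))
        shift_vox = np.array(m.displacement_mm) / np.array(vol.spacing)
        # affine_transform maps output coords -> input coords: x_in = A x_out + b
        a = np.diag([1.0 / lin] * 3)
        target_centroid = centroid + shift_vox
        offset = centroid - a @ target_centroid
        new_mask = ndimage.affine_transform(
            mask.astype(np.float64), a, offset=offset, order=1, mode="constant", cval=0.0
        ) > 0.5

    inside = np.clip(np.abs(np.array(m.displacement_mm)), 0, None)
    if np.any(inside / np.array(vol.spacing) >= np.array(vol.shape)):
        raise ValueError("displacement exceeds the grid")
    if new_mask.any() and not np.all(body[new_mask]):
        raise ValueError(
            f"mismatch pushes structure {m.structure!r} outside the body"
        )
    # clearing the old position must not delete other organs
    other = body & (lab != organ.label) & (lab != by_name["body"].label)
    if (new_mask & other).any():
        raise ValueError("mismatch makes the structure overlap another organ")

    values[mask] = fill_value
    values[new_mask] = struct_value
    new_lab = lab.copy()
    new_lab[mask] = by_name["body"].label
    new_lab[new_mask] = organ.label
    return (
        vol.copy_with(values=values),
        labels.copy_with(values=new_lab),
    )


# ---------------------------------------------------------------------------
# toy carbon-beam dose
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamSpec:
    """Axis-aligned pencil-like beam with a nominal water-equivalent range."""

    entry_mm: tuple[float, float, float]  # (z, y, x) on the entry face
    direction: tuple[float, float, float]  # unit vector, axis-aligned
    nominal_range_mm: float  # water-equivalent depth of the Bragg peak
    prescription_dose: float  # Gy(RBE) at the peak
    lateral_sigma_mm: float = 9.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if not math.isclose(float(np.linalg.norm(d)), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("beam direction must have unit norm")
        if np.count_nonzero(np.abs(d) > 1e-12) != 1:
            raise ValueError("only axis-aligned beam directions are supported")
        if self.nominal_range_mm <= 0 or self.prescription_dose <= 0:
            raise ValueError("nominal range and prescription dose must be positive")

    @property
    def axis(self) -> int:
        return int(np.argmax(np.abs(self.direction)))

    @property
    def forward(self) -> bool:
        return self.direction[self.axis] > 0


# HU -> relative stopping power, linear between anchors
_RSP_HU = np.array([-1000.0, 0.0, 1047.0])
_RSP = np.array([0.001, 1.0, 1.6])


def hu_to_rsp(hu: np.ndarray) -> np.ndarray:
    """Piecewise-linear HU to relative-stopping-power lookup."""
    return np.interp(np.asarray(hu, dtype=np.float64), _RSP_HU, _RSP)


def bragg_curve(wepl_mm: np.ndarray, range_mm: float,
                plateau: float = 0.3, sigma_prox: float = 7.0,
                sigma_dist: float = 1.5) -> np.ndarray:
    """Analytic Bragg-like depth-dose, peak value 1 at ``range_mm``.

    Proximal side: plateau rising as a broad Gaussian shoulder; distal side: a
    sharp Gaussian falloff.  The distal 80% point sits ~1 mm past the peak.
    """
    w = np.asarray(wepl_mm, dtype=np.float64)
    out = np.where(
        w <= range_mm,
        plateau + (1.0 - plateau) * np.exp(-((w - range_mm) ** 2) / (2 * sigma_prox**2)),
        np.exp(-((w - range_mm) ** 2) / (2 * sigma_dist**2)),
    )
    return np.where(w < 0, 0.0, out)


def toy_dose(ct: ImageVolume, beam: BeamSpec) -> ImageVolume:
    """Deterministic analytic dose from HU line integrals along the beam axis.

    The dose in each voxel is ``prescription x bragg(WEPL) x lateral Gaussian``
    where WEPL is the cumulative water-equivalent depth to the voxel center
    along its grid column.  HU perturbations upstream of a voxel therefore move
    the distal falloff by the change in water-equivalent path length.
    """
    axis = beam.axis
    vals = ct.values
    spacing = np.asarray(ct.spacing)

    # orient so the beam travels along increasing index of `axis`
    hu = vals if beam.forward else np.flip(vals, axis=axis)
    step = spacing[axis]
    rsp = hu_to_rsp(hu)
    cum = np.cumsum(rsp * step, axis=axis)
    wepl = cum - rsp * step * 0.5  # depth at voxel centers

    # lateral distance from the central axis (the two non-beam axes)
    lat_axes = [a for a in range(3) if a != axis]
    coords = []
    for a in lat_axes:
        c = (np.arange(ct.shape[a]) + 0.5) * spacing[a]
        coords.append(c - beam.entry_mm[a])
    r2 = np.zeros((1, 1, 1))
    for a, c in zip(lat_axes, coords):
        s = [1, 1, 1]
        s[a] = -1
        r2 = r2 + (c.reshape(s)) ** 2

    # require the central axis to hit the patient
    idx = [np.argmin(np.abs((np.arange(ct.shape[a]) + 0.5) * spacing[a] - beam.entry_mm[a]))
           for a in lat_axes]
    for a, i in zip(lat_axes, idx):
        if not (0 <= beam.entry_mm[a] <= ct.shape[a] * spacing[a]):
            raise ValueError("beam misses the volume")
    take = [slice(None)] * 3
    take[lat_axes[0]] = idx[0]
    take[lat_axes[1]] = idx[1]
    axis_column_bg = (
        ct.background_mask[tuple(take)] if ct.background_mask is not None else None
    )
    if axis_column_bg is not None and axis_column_bg.all():
        raise ValueError("beam does not intersect the body")

    depth_dose = bragg_curve(wepl, beam.nominal_range_mm)
    lateral = np.exp(-r2 / (2.0 * beam.lateral_sigma_mm**2))
    dose = beam.prescription_dose * depth_dose * lateral
    if not beam.forward:
        dose = np.flip(dose, axis=axis)
    return ct.copy_with(values=dose, modality="DOSE")
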