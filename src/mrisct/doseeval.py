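"""Dosimetric comparison of dose grids: DVH metrics, gamma analysis, range shift.

Gamma analysis is *global*: the dose tolerance is a percentage of the
prescription dose, voxels below a reference-dose threshold are excluded, and
the gamma value minimizes the combined dose/distance metric over a
neighbourhood (3x the distance-to-agreement) with configurable sub-voxel
interpolation.

Range shift follows the particle-therapy convention: the beam range R80 is the
depth of the *distal* crossing of 80% of each profile's peak dose, measured on
profiles parallel to the beam's central axis on a set of transversal slices;
RS = R80(evaluated) - R80(reference) and RRS = RS / R80(reference).  Shifts
beyond 5 mm are flagged as clinically unacceptable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import BeamSpec
from .volume import ImageVolume


@dataclass(frozen=True)
class DoseGrid:
    """A non-negative dose distribution with its prescription dose."""

    volume: ImageVolume
    prescription_dose: float  # Gy(RBE)

    def __post_init__(self):
        if self.prescription_dose <= 0:
            raise ValueError("prescription dose must be positive")
        if np.any(self.volume.values < -1e-9):
            raise ValueError("dose must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return self.volume.values

    @property
    def spacing(self):
        return self.volume.spacing


@dataclass(frozen=True)
class GammaCriteria:
    """Dose tolerance (% of prescription), DTA (mm), low-dose threshold (%)."""

    dose_tol_pct: float
    dta_mm: float
    threshold_pct: float = 10.0
    search_radius_factor: float = 3.0
    interp_fraction: float = 0.1  # search step = interp_fraction * DTA

    def __post_init__(self):
        if min(self.dose_tol_pct, self.dta_mm, self.threshold_pct) <= 0:
            raise ValueError("gamma criteria must all be positive")


@dataclass(frozen=True)
class RangeShiftRecord:
    slice_index: int
    r_ref80_mm: float
    r_eval80_mm: float
    rs_mm: float
    rrs: float
    flagged: bool  # |RS| above the 5 mm acceptability threshold
    valid: bool


RS_ACCEPTABILITY_MM = 5.0


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

def dvh(dose: DoseGrid, structure_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative DVH of a structure: (dose axis, fraction of volume >= dose).

    The curve starts at (0, 1) and is monotone non-increasing; at each voxel
    dose ``d_(i)`` (ascending) the fraction is ``(N - i) / N``.
    """
    mask = np.asarray(structure_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty structure mask")
    ds = np.sort(dose.values[mask].astype(np.float64))
    n = ds.size
    frac = (n - np.arange(n)) / n
    dose_axis = np.concatenate([[0.0], ds])
    volume_frac = np.concatenate([[1.0], frac])
    return dose_axis, volume_frac


def dvh_metric(curve: tuple[np.ndarray, np.ndarray], which: str) -> float:
    """D_x from a cumulative DVH: minimum dose to the hottest x% of the volume.

    ``which`` is e.g. ``"D95"`` or ``"D2"``.  Linear interpolation between the
    adjacent voxel-dose quantiles of the curve.
    """
    if not which.startswith("D"):
        raise ValueError(f"unknown DVH metric {which!r}")
    q = float(which[1:]) / 100.0
    if not 0 < q <= 1:
        raise ValueError(f"DVH percentage out of range in {which!r}")
    dose_axis, frac = curve
    # invert the non-increasing curve: interpolate dose as a function of fraction
    xp = frac[::-1]
    fp = dose_axis[::-1]
    # equal fractions (e.g. the (0, 1) start next to the minimum voxel dose)
    # must resolve to the larger dose: keep the first entry of each run
    keep = np.concatenate([[True], np.diff(xp) > 0])
    return float(np.interp(q, xp[keep], fp[keep]))


def dvh_d(dose: DoseGrid, structure_mask: np.ndarray, which: str) -> float:
    return dvh_metric(dvh(dose, structure_mask), which)


# ---------------------------------------------------------------------------
# dose difference
# ---------------------------------------------------------------------------

def dose_difference(ref: DoseGrid, eval_: DoseGrid) -> tuple[ImageVolume, dict]:
    """Signed ``eval - ref`` map and its median / IQR / max-|diff| summary."""
    if not ref.volume.same_grid(eval_.volume):
        raise ValueError("dose grids must share the same grid")
    diff = eval_.values.astype(np.float64) - ref.values.astype(np.float64)
    q25, q50, q75 = np.percentile(diff, [25, 50, 75])
    summary = {
        "median": float(q50),
        "iqr": float(q75 - q25),
        "max_abs": float(np.max(np.abs(diff))),
    }
    return ref.volume.copy_with(values=diff, modality="DOSE"), summary


# ---------------------------------------------------------------------------
# gamma analysis
# ---------------------------------------------------------------------------

def _offset_lattice(spacing, radius_mm, step_mm):
    """Displacement vectors (voxel units, mm norm) within the search sphere."""
    axes = []
    for sp in spacing:
        nmax = int(np.floor(radius_mm / step_mm))
        offs = np.arange(-nmax, nmax + 1) * step_mm
        axes.append(offs)
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    r2 = zz**2 + yy**2 + xx**2
    keep = r2 <= radius_mm**2 + 1e-12
    mm = np.stack([zz[keep], yy[keep], xx[keep]], axis=1)
    order = np.argsort(r2[keep], kind="stable")
    return mm[order]


def gamma_pass_rate(ref: DoseGrid, eval_: DoseGrid, criteria: GammaCriteria,
                    subvoxel: bool = True) -> float:
    """Percentage of evaluated voxels with gamma <= 1 (global normalization).

    Voxels whose *reference* dose is below ``threshold_pct`` of the
    prescription are excluded.  With ``subvoxel=True`` the minimization runs
    on a lattice of step ``interp_fraction * DTA`` with trilinear
    interpolation of the evaluated dose; with ``subvoxel=False`` only whole
    -voxel displacements are searched (the definition the brute-force oracle
    uses).
    """
    if not ref.volume.same_grid(eval_.volume):
        raise ValueError("dose grids must share the same grid")
    rx = ref.prescription_dose
    dd = criteria.dose_tol_pct / 100.0 * rx
    dta = criteria.dta_mm
    radius = criteria.search_radius_factor * dta
    spacing = np.asarray(ref.spacing, dtype=np.float64)

    mask = ref.values >= criteria.threshold_pct / 100.0 * rx
    if not mask.any():
        return float("nan")
    ref_vals = ref.values[mask].astype(np.float64)
    ev = eval_.values.astype(np.float64)

    if subvoxel:
        step = criteria.interp_fraction * dta
        offsets = _offset_lattice(spacing, radius, step)
    else:
        # whole-voxel lattice: per-axis steps equal to the voxel spacing
        axes = [np.arange(-int(np.floor(radius / sp)), int(np.floor(radius / sp)) + 1) * sp
                for sp in spacing]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        r2 = zz**2 + yy**2 + xx**2
        keep = r2 <= radius**2 + 1e-12
        offsets = np.stack([zz[keep], yy[keep], xx[keep]], axis=1)
        offsets = offsets[np.argsort(r2[keep], kind="stable")]

    gamma2 = np.full(ref_vals.shape, np.inf)
    for off_mm in offsets:
        dist2 = float(off_mm @ off_mm) / dta**2
        worst = gamma2.max()
        if dist2 >= worst:
            break
        off_vox = off_mm / spacing
        if np.allclose(off_vox, np.round(off_vox)):
            iv = np.round(off_vox).astype(int)
            shifted = _integer_shift(ev, iv)
        else:
            shifted = ndimage.shift(ev, -off_vox, order=1, mode="constant",
                                    cval=np.nan, prefilter=False)
        sv = shifted[mask]
        dose2 = (sv - ref_vals) ** 2 / dd**2
        cand = np.where(np.isnan(sv), np.inf, dose2 + dist2)
        np.minimum(gamma2, cand, out=gamma2)
    return float(100.0 * np.mean(gamma2 <= 1.0 + 1e-9))


def _integer_shift(arr: np.ndarray, shift_vox: np.ndarray) -> np.ndarray:
    """arr sampled at x + shift (voxels); out-of-range positions are NaN."""
    out = np.full(arr.shape, np.nan)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(shift_vox):
        n = arr.shape[ax]
        s = int(s)
        if abs(s) >= n:
            return out
        if s >= 0:
            dst[ax] = slice(0, n - s)
            src[ax] = slice(s, n)
        else:
            dst[ax] = slice(-s, n)
            src[ax] = slice(0, n + s)
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# range shift
# ---------------------------------------------------------------------------

def _distal_r80(profile: np.ndarray, depth: np.ndarray) -> float | None:
    """Depth of the distal 80%-of-peak crossing, linearly interpolated."""
    if profile.max() <= 0:
        return None
    ipk = int(np.argmax(profile))
    level = 0.8 * profile[ipk]
    for j in range(ipk + 1, profile.size):
        if profile[j] < level:
            p0, p1 = profile[j - 1], profile[j]
            frac = (p0 - level) / (p0 - p1)
            return float(depth[j - 1] + frac * (depth[j] - depth[j - 1]))
    return None


def range_shift(
    dose_ref: DoseGrid,
    dose_eval: DoseGrid,
    beam: BeamSpec,
    n_slices: int = 10,
    target_mask: np.ndarray | None = None,
) -> tuple[list[RangeShiftRecord], dict]:
    """RS/RRS on dose profiles parallel to the beam axis on transversal slices.

    ``n_slices`` transversal (z) slices are chosen evenly through the target's
    axial extent (``target_mask`` if given, else the region with reference dose
    >= 50% of prescription).  Each profile runs along the beam axis at the
    central-axis lateral position.  Profiles without a distal 80% crossing are
    flagged invalid and excluded from the median/IQR summary.
    """
    if not dose_ref.volume.same_grid(dose_eval.volume):
        raise ValueError("dose grids must share the same grid")
    axis = beam.axis
    if axis == 0:
        raise ValueError("beam must lie in the transversal plane (axis y or x)")
    vol = dose_ref.volume
    spacing = np.asarray(vol.spacing)

    if target_mask is None:
        target_mask = dose_ref.values >= 0.5 * dose_ref.prescription_dose
    zs = np.where(np.asarray(target_mask, dtype=bool).any(axis=(1, 2)))[0]
    if zs.size == 0:
        raise ValueError("target region is empty")
    z_sel = np.round(np.linspace(zs[0], zs[-1], n_slices)).astype(int)

    lat_axis = 3 - axis  # the other in-plane axis
    lat_idx = int(np.clip(
        np.floor(beam.entry_mm[lat_axis] / spacing[lat_axis]), 0,
        vol.shape[lat_axis] - 1,
    ))

    n = vol.shape[axis]
    pos = (np.arange(n) + 0.5) * spacing[axis]
    depth = pos - beam.entry_mm[axis] if beam.forward else beam.entry_mm[axis] - pos
    if not beam.forward:
        depth = depth[::-1]

    records = []
    for z in z_sel:
        sel = [slice(None)] * 3
        sel[0] = z
        sel[lat_axis] = lat_idx
        prof_ref = dose_ref.values[tuple(sel)].astype(np.float64)
        prof_eval = dose_eval.values[tuple(sel)].astype(np.float64)
        if not beam.forward:
            prof_ref, prof_eval = prof_ref[::-1], prof_eval[::-1]
        r_ref = _distal_r80(prof_ref, depth)
        r_eval = _distal_r80(prof_eval, depth)
        if r_ref is None or r_eval is None:
            records.append(RangeShiftRecord(int(z), np.nan, np.nan, np.nan,
                                            np.nan, False, False))
            continue
        rs = r_eval - r_ref
        rrs = rs / r_ref if r_ref > 0 else float("nan")
        records.append(RangeShiftRecord(
            int(z), r_ref, r_eval, float(rs), float(rrs),
            abs(rs) > RS_ACCEPTABILITY_MM, True,
        ))

    valid_rs = np.array([r.rs_mm for r in records if r.valid])
    if valid_rs.size:
        q25, q50, q75 = np.percentile(valid_rs, [25, 50, 75])
        summary = {
            "median_rs_mm": float(q50),
            "iqr_rs_mm": float(q75 - q25),
            "n_valid": int(valid_rs.size),
            "n_flagged": int(sum(r.flagged for r in records)),
            "n_invalid": int(sum(not r.valid for r in records)),
        }
    else:
        summary = {"median_rs_mm": float("nan"), "iqr_rs_mm": float("nan"),
                   "n_valid": 0, "n_flagged": 0,
                   "n_invalid": int(sum(not r.valid for r in records))}
    return records, summary
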