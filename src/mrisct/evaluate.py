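"""Image-quality and geometry metrics for sCT assessment, plus TOST-P.

All similarity metrics exclude the background: they are computed over
region masks (whole body or a tissue channel).  Geometry metrics compare
binary structure masks in physical millimetres.  ``tost_paired`` implements
the two one-sided equivalence test for paired samples used to compare DVH
metrics between original and recalculated plans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, stats

from .volume import ImageVolume

HU_DATA_RANGE = 2047.0  # span of the conditioned CT, [-1000, 1047]


@dataclass(frozen=True)
class RegionMetrics:
    mae: float
    rmse: float
    ncc: float
    ssim: float
    psnr: float


@dataclass(frozen=True)
class SimilarityReport:
    """Per-region similarity metrics; NaN marks an undefined (empty) region."""

    regions: dict[str, RegionMetrics]

    def __getitem__(self, region: str) -> RegionMetrics:
        return self.regions[region]


@dataclass(frozen=True)
class GeometryReport:
    dsc: float
    hd95_mm: float
    comd_mm: float


@dataclass(frozen=True)
class TostResult:
    equivalent: bool
    p_lower: float
    p_upper: float
    mean_diff: float
    margin: float
    n: int


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def _gaussian_kernel(win: int, sigma: float) -> np.ndarray:
    r = np.arange(win) - (win - 1) / 2.0
    g = np.exp(-(r**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def masked_ssim(
    a: np.ndarray,
    b: np.ndarray,
    mask: np.ndarray,
    data_range: float = HU_DATA_RANGE,
    win: int = 11,
    sigma: float = 1.5,
) -> float:
    """Volume SSIM with Gaussian windows whose centers lie in the mask.

    Computed per transversal slice over the mask's bounding box; windows must
    fit inside the box.  Slice values are averaged weighted by the number of
    valid window centers.  Returns NaN when no window center qualifies.
    """
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("shape mismatch")
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    kernel = _gaussian_kernel(win, sigma)
    half = win // 2
    total, weight = 0.0, 0
    for k in range(a.shape[0]):
        m = mask[k]
        if not m.any():
            continue
        rows = np.where(m.any(axis=1))[0]
        cols = np.where(m.any(axis=0))[0]
        r0, r1 = rows[0], rows[-1] + 1
        c0, cend = cols[0], cols[-1] + 1
        if r1 - r0 < win or cend - c0 < win:
            continue
        sa = a[k, r0:r1, c0:cend].astype(np.float64)
        sb = b[k, r0:r1, c0:cend].astype(np.float64)
        wa = sliding_window_view(sa, (win, win))
        wb = sliding_window_view(sb, (win, win))
        mu_a = np.tensordot(wa, kernel, axes=([2, 3], [0, 1]))
        mu_b = np.tensordot(wb, kernel, axes=([2, 3], [0, 1]))
        e_aa = np.tensordot(wa * wa, kernel, axes=([2, 3], [0, 1]))
        e_bb = np.tensordot(wb * wb, kernel, axes=([2, 3], [0, 1]))
        e_ab = np.tensordot(wa * wb, kernel, axes=([2, 3], [0, 1]))
        va = e_aa - mu_a**2
        vb = e_bb - mu_b**2
        vab = e_ab - mu_a * mu_b
        ssim_map = ((2 * mu_a * mu_b + c1) * (2 * vab + c2)) / (
            (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
        )
        centers = m[r0 + half : r1 - half, c0 + half : cend - half]
        n = int(centers.sum())
        if n:
            total += float(ssim_map[centers].sum())
            weight += n
    return total / weight if weight else float("nan")


def _region_metrics(av, bv, data_range: float) -> RegionMetrics:
    diff = av - bv
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff**2)))
    if av.size >= 2 and np.std(av) > 0 and np.std(bv) > 0:
        ncc = float(np.corrcoef(av, bv)[0, 1])
    elif np.array_equal(av, bv):
        ncc = 1.0
    else:
        ncc = float("nan")
    psnr = float("inf") if rmse == 0 else float(20.0 * np.log10(data_range / rmse))
    return mae, rmse, ncc, psnr


def similarity(
    a: ImageVolume,
    b: ImageVolume,
    region_masks: dict[str, np.ndarray],
    data_range: float = HU_DATA_RANGE,
) -> SimilarityReport:
    """MAE/RMSE/NCC/SSIM/PSNR per region, background excluded by the masks.

    NCC is the Pearson correlation of the masked voxels; SSIM restricts
    window centers to the mask; PSNR uses the conditioned-CT data range and is
    +inf for identical inputs.  An empty region yields NaN for every metric.
    """
    if not a.same_grid(b):
        raise ValueError("volumes must share the same grid")
    out = {}
    for name, mask in region_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            nanv = float("nan")
            out[name] = RegionMetrics(nanv, nanv, nanv, nanv, nanv)
            continue
        av = a.values[mask].astype(np.float64)
        bv = b.values[mask].astype(np.float64)
        mae, rmse, ncc, psnr = _region_metrics(av, bv, data_range)
        ssim = masked_ssim(a.values, b.values, mask, data_range=data_range)
        out[name] = RegionMetrics(mae, rmse, ncc, ssim, psnr)
    return SimilarityReport(out)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels under 6-connectivity (erosion with a cross kernel)."""
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


def _directed_hd95(surf_a, surf_b, spacing) -> float:
    dist_to_b = ndimage.distance_transform_edt(~surf_b, sampling=spacing)
    return float(np.percentile(dist_to_b[surf_a], 95.0))


def geometry(mask_a: np.ndarray, mask_b: np.ndarray,
             spacing: tuple[float, float, float]) -> GeometryReport:
    """Dice, symmetric 95th-percentile Hausdorff distance and centroid distance.

    HD95 takes the maximum of the two directed 95th percentiles of surface-to-
    surface distances (in mm); CoMD is the Euclidean distance between the
    binary centroids.  Empty masks are an error.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    if not a.any() or not b.any():
        raise ValueError("geometry metrics need non-empty masks")
    dsc = 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
    surf_a, surf_b = surface_voxels(a), surface_voxels(b)
    hd95 = max(
        _directed_hd95(surf_a, surf_b, spacing),
        _directed_hd95(surf_b, surf_a, spacing),
    )
    com_a = np.array(ndimage.center_of_mass(a)) * np.asarray(spacing)
    com_b = np.array(ndimage.center_of_mass(b)) * np.asarray(spacing)
    comd = float(np.linalg.norm(com_a - com_b))
    return GeometryReport(float(dsc), hd95, comd)


# ---------------------------------------------------------------------------
# equivalence testing
# ---------------------------------------------------------------------------

def tost_paired(x, y, margin: float, alpha: float = 0.05) -> TostResult:
    """Two one-sided paired t-tests of equivalence within ``+/- margin``.

    Equivalence is declared iff both one-sided tests reject at ``alpha``:
    H0a: mean(x - y) <= -margin and H0b: mean(x - y) >= +margin.  ``margin``
    is expressed in the units of the samples (e.g. Gy for DVH metrics, after
    converting the +/-0.5%-of-prescription interval).  Zero-variance
    differences degrade to an exact comparison of the mean against the margin.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D paired samples")
    n = x.size
    if n < 3:
        raise ValueError("TOST-P needs at least 3 pairs")
    if margin <= 0:
        raise ValueError("margin must be positive")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        inside = abs(mean) < margin
        p = 0.0 if inside else 1.0
        return TostResult(inside and p < alpha, p, p, mean, margin, n)
    se = sd / np.sqrt(n)
    df = n - 1
    t_lower = (mean + margin) / se
    t_upper = (mean - margin) / se
    p_lower = float(stats.t.sf(t_lower, df))
    p_upper = float(stats.t.cdf(t_upper, df))
    return TostResult(
        p_lower < alpha and p_upper < alpha, p_lower, p_upper, mean, margin, n
    )
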