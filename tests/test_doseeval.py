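import numpy as np
import pytest

from mrisct.doseeval import (
    DoseGrid, GammaCriteria, dose_difference, dvh, dvh_d, dvh_metric,
    gamma_pass_rate, range_shift,
)
from mrisct.phantom import BeamSpec, bragg_curve

from conftest import make_volume


def _grid(values, prescription=100.0, spacing=(1.0, 1.0, 1.0)):
    return DoseGrid(make_volume(values, spacing=spacing, modality="DOSE"),
                    prescription)


# ---------------------------------------------------------------------------
# brute-force gamma (whole-voxel search over all voxel pairs in the sphere)
# ---------------------------------------------------------------------------

def brute_gamma_pass_rate(ref, ev, criteria):
    rx = ref.prescription_dose
    dd = criteria.dose_tol_pct / 100.0 * rx
    dta = criteria.dta_mm
    radius = criteria.search_radius_factor * dta
    sp = np.asarray(ref.spacing)
    rv, evv = ref.values, ev.values
    mask = rv >= criteria.threshold_pct / 100.0 * rx
    if not mask.any():
        return float("nan")
    passed = 0
    total = 0
    coords = np.argwhere(np.ones_like(rv, dtype=bool))
    pos = coords * sp
    flat_ev = evv.reshape(-1)
    for idx in np.argwhere(mask):
        p = idx * sp
        d2 = ((pos - p) ** 2).sum(axis=1)
        keep = d2 <= radius**2 + 1e-12
        gam2 = d2[keep] / dta**2 + (flat_ev[keep] - rv[tuple(idx)]) ** 2 / dd**2
        total += 1
        if gam2.min() <= 1.0 + 1e-9:
            passed += 1
    return 100.0 * passed / total


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

def test_dvh_d2_on_1_to_100():
    """100 voxels with doses 1..100: D2 is exactly 99."""
    vals = np.arange(1.0, 101.0).reshape(1, 10, 10)
    g = _grid(vals)
    mask = np.ones(g.values.shape, dtype=bool)
    assert dvh_d(g, mask, "D2") == 99.0
    assert dvh_d(g, mask, "D95") == pytest.approx(6.0)
    assert dvh_d(g, mask, "D100") == pytest.approx(1.0)


def test_dvh_curve_sort_and_count_oracle():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 60, size=(4, 6, 6))
    mask = rng.random(vals.shape) < 0.5
    g = _grid(vals)
    dose_axis, frac = dvh(g, mask)
    # oracle: at every dose point, the fraction of voxels >= that dose
    sel = np.sort(vals[mask])
    for d, f in zip(dose_axis, frac):
        assert np.isclose(f, np.mean(sel >= d - 1e-12), atol=1e-12)
    assert dose_axis[0] == 0.0 and frac[0] == 1.0
    assert np.all(np.diff(frac) <= 1e-12)


def test_dvh_metric_validation():
    curve = (np.array([0.0, 1.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        dvh_metric(curve, "V20")
    with pytest.raises(ValueError):
        dvh_metric(curve, "D0")
    with pytest.raises(ValueError):
        dvh(_grid(np.ones((1, 2, 2))), np.zeros((1, 2, 2), dtype=bool))


def test_dose_grid_validation():
    with pytest.raises(ValueError):
        _grid(np.ones((1, 2, 2)), prescription=0.0)
    with pytest.raises(ValueError):
        _grid(-np.ones((1, 2, 2)))


def test_dose_difference_summary():
    a = _grid(np.zeros((2, 4, 4)))
    b = _grid(np.full((2, 4, 4), 3.0))
    diff, summary = dose_difference(a, b)
    assert np.all(diff.values == 3.0)
    assert summary == {"median": 3.0, "iqr": 0.0, "max_abs": 3.0}


# ---------------------------------------------------------------------------
# gamma
# ---------------------------------------------------------------------------

def test_gamma_identical_grids_pass():
    rng = np.random.default_rng(1)
    vals = rng.uniform(0, 100, size=(4, 8, 8))
    g = _grid(vals)
    for tol, dta in ((1.0, 1.0), (2.0, 2.0), (3.0, 3.0)):
        assert gamma_pass_rate(g, g, GammaCriteria(tol, dta)) == 100.0


def test_gamma_flat_field_threshold_behaviour():
    """Uniform dose offsets just inside/outside the dose tolerance."""
    base = np.full((4, 8, 8), 50.0)
    ref = _grid(base)
    crit = GammaCriteria(3.0, 3.0)  # 3% of 100 = 3.0 dose units
    ok = _grid(base + 0.99 * 3.0)
    bad = _grid(base + 1.01 * 3.0)
    assert gamma_pass_rate(ref, ok, crit) == 100.0
    # flat field: no gradient anywhere, DTA cannot rescue the dose failure
    assert gamma_pass_rate(ref, bad, crit) == 0.0


def test_gamma_whole_voxel_matches_brute(conditioned_pair):
    rng = np.random.default_rng(2)
    for _ in range(5):
        vals = rng.uniform(0, 100, size=(4, 6, 6))
        pert = np.clip(vals + rng.normal(0, 3.0, size=vals.shape), 0, None)
        ref = _grid(vals, spacing=(2.0, 1.5, 1.5))
        ev = _grid(pert, spacing=(2.0, 1.5, 1.5))
        crit = GammaCriteria(3.0, 3.0)
        fast = gamma_pass_rate(ref, ev, crit, subvoxel=False)
        brute = brute_gamma_pass_rate(ref, ev, crit)
        assert np.isclose(fast, brute, atol=1e-9)


def test_gamma_monotone_in_criteria():
    rng = np.random.default_rng(3)
    for _ in range(5):
        vals = rng.uniform(0, 100, size=(3, 8, 8))
        pert = np.clip(vals + rng.normal(0, 2.5, size=vals.shape), 0, None)
        ref, ev = _grid(vals), _grid(pert)
        rates = [gamma_pass_rate(ref, ev, GammaCriteria(t, t), subvoxel=False)
                 for t in (1.0, 2.0, 3.0)]
        assert rates[0] <= rates[1] + 1e-9 <= rates[2] + 2e-9


def test_gamma_threshold_excludes_low_dose():
    vals = np.zeros((1, 4, 4))
    vals[0, 0, 0] = 50.0
    ref = _grid(vals)
    ev = _grid(vals * 0.0 + 1e-6)  # everything fails where evaluated
    rate = gamma_pass_rate(ref, ev, GammaCriteria(3.0, 1.0, threshold_pct=10.0))
    assert rate == 0.0  # only the single above-threshold voxel is scored
    all_low = _grid(np.full((1, 4, 4), 1.0))
    assert np.isnan(gamma_pass_rate(all_low, all_low,
                                    GammaCriteria(3.0, 1.0, threshold_pct=10.0)))


def test_gamma_subvoxel_not_worse_than_whole_voxel():
    rng = np.random.default_rng(4)
    vals = rng.uniform(20, 100, size=(3, 8, 8))
    pert = np.clip(vals + rng.normal(0, 2.0, size=vals.shape), 0, None)
    ref, ev = _grid(vals, spacing=(2, 2, 2)), _grid(pert, spacing=(2, 2, 2))
    crit = GammaCriteria(2.0, 2.0)
    assert (gamma_pass_rate(ref, ev, crit, subvoxel=True)
            >= gamma_pass_rate(ref, ev, crit, subvoxel=False) - 1e-9)


def test_gamma_criteria_validation():
    with pytest.raises(ValueError):
        GammaCriteria(0.0, 3.0)
    with pytest.raises(ValueError):
        GammaCriteria(3.0, -1.0)


# ---------------------------------------------------------------------------
# range shift
# ---------------------------------------------------------------------------

def _bragg_grid(delta_mm=0.0, spacing_y=1.0, ny=140, range_mm=80.0):
    y = (np.arange(ny) + 0.5) * spacing_y
    prof = bragg_curve(y - delta_mm, range_mm) * 2.0
    vals = np.tile(prof.reshape(1, ny, 1), (8, 1, 8))
    return _grid(vals, prescription=2.0, spacing=(2.0, spacing_y, 2.0))


def test_range_shift_translated_profiles():
    beam = BeamSpec((8.0, 0.0, 8.0), (0.0, 1.0, 0.0), 80.0, 2.0)
    ref = _bragg_grid(0.0)
    for delta in (-5.0, -2.0, 0.0, 2.0, 5.0):
        ev = _bragg_grid(delta)
        _, summary = range_shift(ref, ev, beam, n_slices=5)
        assert abs(summary["median_rs_mm"] - delta) < 0.1
        assert summary["n_valid"] == 5 and summary["n_invalid"] == 0
        assert summary["n_flagged"] == 0  # |5.0| is not > 5 mm


def test_range_shift_antisymmetry_and_flagging():
    beam = BeamSpec((8.0, 0.0, 8.0), (0.0, 1.0, 0.0), 80.0, 2.0)
    a, b = _bragg_grid(0.0), _bragg_grid(6.0)
    _, fwd = range_shift(a, b, beam, n_slices=4)
    _, bwd = range_shift(b, a, beam, n_slices=4)
    assert abs(fwd["median_rs_mm"] + bwd["median_rs_mm"]) < 0.05
    assert fwd["n_flagged"] == 4  # 6 mm > 5 mm acceptability


def test_range_shift_rrs():
    beam = BeamSpec((8.0, 0.0, 8.0), (0.0, 1.0, 0.0), 80.0, 2.0)
    records, _ = range_shift(_bragg_grid(0.0), _bragg_grid(2.0), beam, n_slices=3)
    for r in records:
        assert r.valid
        assert np.isclose(r.rrs, r.rs_mm / r.r_ref80_mm, rtol=1e-12)


def test_range_shift_invalid_profiles_excluded():
    beam = BeamSpec((8.0, 0.0, 8.0), (0.0, 1.0, 0.0), 80.0, 2.0)
    ref = _bragg_grid(0.0)
    dead = _grid(np.zeros_like(ref.values), prescription=2.0,
                 spacing=ref.spacing)
    records, summary = range_shift(ref, dead, beam, n_slices=3,
                                   target_mask=ref.values > 1.0)
    assert summary["n_valid"] == 0 and summary["n_invalid"] == 3
    assert np.isnan(summary["median_rs_mm"])


def test_range_shift_rejects_axial_beam():
    beam = BeamSpec((8.0, 0.0, 8.0), (1.0, 0.0, 0.0), 80.0, 2.0)
    g = _bragg_grid(0.0)
    with pytest.raises(ValueError):
        range_shift(g, g, beam)


# ---------------------------------------------------------------------------
# additional documented properties
# ---------------------------------------------------------------------------

def test_dvh_uniform_dose():
    g = _grid(np.full((2, 4, 4), 7.5))
    mask = np.ones(g.values.shape, dtype=bool)
    assert dvh_d(g, mask, "D95") == 7.5
    assert dvh_d(g, mask, "D2") == 7.5


def test_dvh_d95_le_d2_property():
    rng = np.random.default_rng(9)
    for _ in range(20):
        g = _grid(rng.uniform(0, 60, size=(3, 6, 6)))
        mask = rng.random(g.values.shape) < 0.5
        if not mask.any():
            continue
        assert dvh_d(g, mask, "D95") <= dvh_d(g, mask, "D2") + 1e-12


def test_dose_difference_elementwise_oracle():
    rng = np.random.default_rng(10)
    a = rng.uniform(0, 50, size=(3, 5, 5))
    b = rng.uniform(0, 50, size=(3, 5, 5))
    diff, summary = dose_difference(_grid(a), _grid(b))
    assert np.allclose(diff.values, b - a, atol=1e-12)
    d = (b - a).ravel()
    assert np.isclose(summary["median"], np.median(d), atol=1e-12)
    assert np.isclose(summary["max_abs"], np.abs(d).max(), atol=1e-12)
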