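import numpy as np
import pytest

from mrisct import preprocess
from mrisct.preprocess import (
    CHANNEL_NAMES, AugmentationSpec, ChannelRanges, augment_pair, prepare_ct,
    prepare_mri, resize_slice, resize_to_net, scale_channels, segment_channels,
)
from mrisct.reconstruct import reassemble_slice

from conftest import make_volume


def test_channel_partition_covers_body():
    """The half-open HU partition tiles [-1000, 1047] without gaps or overlap."""
    r = ChannelRanges()
    hu = np.linspace(-1000.0, 1047.0, 3001).reshape(1, 1, -1)
    body = np.ones(hu.shape, dtype=bool)
    masks = r.masks(hu, body)
    total = sum(masks[n].astype(int) for n in CHANNEL_NAMES)
    assert np.all(total == 1)
    # boundary ownership: -800 is soft, 150 is bone
    b = np.array([[[-800.0, 150.0]]])
    m = r.masks(b, np.ones_like(b, dtype=bool))
    assert m["soft"][0, 0, 0] and not m["air"][0, 0, 0]
    assert m["bone"][0, 0, 1] and not m["soft"][0, 0, 1]


def test_prepare_ct_conditioning(phantom_pair):
    ct, mri, _ = phantom_pair
    out = prepare_ct(ct, mri)
    assert out.shape == mri.shape
    assert out.values.min() >= -1000.0 and out.values.max() <= 1047.0
    assert np.all(out.values[out.background_mask] == -1000.0)


def test_prepare_ct_rejects_non_ct(phantom_pair):
    _, mri, _ = phantom_pair
    with pytest.raises(ValueError):
        prepare_ct(mri, mri)


def test_prepare_mri_conditioning(phantom_pair):
    _, mri, _ = phantom_pair
    out = prepare_mri(mri)
    assert out.values.min() >= 0.0
    assert np.all(out.values[out.background_mask] == 0.0)
    # 99th-percentile clip: in-body max below the raw max for noisy input
    assert out.values.max() <= np.percentile(mri.values[mri.body_mask], 99.0) * 1.5


def test_prepare_mri_histogram_matching(phantom_pair, conditioned_pair):
    _, mri, _ = phantom_pair
    matched = prepare_mri(mri, reference=conditioned_pair[1])
    assert matched.shape == mri.shape
    assert matched.values.min() >= 0.0


def test_segment_reassemble_roundtrip(conditioned_pair):
    ct_c, _, _ = conditioned_pair
    trips = segment_channels(ct_c)
    assert len(trips) == ct_c.shape[0]
    for k, t in enumerate(trips):
        back = reassemble_slice(scale_channels(scale_channels(t, "to_unit"), "to_hu"))
        body = t.body_mask
        assert np.max(np.abs(back[body] - ct_c.values[k][body])) <= 1e-3
        assert np.all(back[~body] == -1000.0)


def test_segment_channels_requires_conditioned_ct():
    vol = make_volume(np.full((2, 8, 8), -2000.0))
    with pytest.raises(ValueError):
        segment_channels(vol)


def test_segment_channels_external_masks_validation(conditioned_pair):
    _, mri_c, _ = conditioned_pair
    shape = mri_c.shape
    ones = np.zeros(shape, dtype=bool)
    ones[:, 40:50, 40:50] = True
    overlapping = {"air": ones, "bone": ones, "soft": np.zeros(shape, dtype=bool)}
    with pytest.raises(ValueError):
        segment_channels(mri_c, masks=overlapping)
    outside = {"air": np.ones(shape, dtype=bool),
               "bone": np.zeros(shape, dtype=bool),
               "soft": np.zeros(shape, dtype=bool)}
    with pytest.raises(ValueError):
        segment_channels(mri_c, masks=outside)


def test_scale_channels_roundtrip_random():
    rng = np.random.default_rng(5)
    r = ChannelRanges()
    for _ in range(10):
        channels, masks = {}, {}
        for n in CHANNEL_NAMES:
            lo, hi = r.range_of(n)
            m = rng.random((16, 16)) < 0.4
            ch = np.full((16, 16), lo)
            ch[m] = rng.uniform(lo, hi, size=int(m.sum()))
            channels[n], masks[n] = ch, m
        t = preprocess.ChannelTriplet(channels, masks,
                                      {n: r.range_of(n) for n in CHANNEL_NAMES})
        back = scale_channels(scale_channels(t, "to_unit"), "to_hu")
        for n in CHANNEL_NAMES:
            assert np.max(np.abs(back.channels[n][masks[n]]
                                 - t.channels[n][masks[n]])) < 1e-9
        unit = scale_channels(t, "to_unit")
        for n in CHANNEL_NAMES:
            assert unit.channels[n].min() >= -1.0 and unit.channels[n].max() <= 1.0
            assert np.all(unit.channels[n][~masks[n]] == -1.0)


def test_scale_channels_direction_errors():
    r = ChannelRanges()
    t = preprocess.ChannelTriplet(
        {n: np.zeros((4, 4)) for n in CHANNEL_NAMES},
        {n: np.ones((4, 4), dtype=bool) for n in CHANNEL_NAMES},
        {n: r.range_of(n) for n in CHANNEL_NAMES})
    with pytest.raises(ValueError):
        scale_channels(t, "sideways")
    with pytest.raises(ValueError):
        scale_channels(t, "to_hu")  # not scaled yet
    u = scale_channels(t, "to_unit")
    with pytest.raises(ValueError):
        scale_channels(u, "to_unit")  # already scaled


def test_resize_slice_mask_is_binary():
    m = np.zeros((10, 10), dtype=bool)
    m[3:7, 3:7] = True
    out = resize_slice(m, (64, 64), is_mask=True)
    assert out.dtype == bool
    # nearest-neighbour keeps the area fraction roughly constant
    assert abs(out.mean() - m.mean()) < 0.05


def test_resize_to_net_shapes(conditioned_pair):
    ct_c, _, _ = conditioned_pair
    t = segment_channels(ct_c)[16]
    u = resize_to_net(scale_channels(t, "to_unit"), 64)
    assert u.shape == (64, 64)
    for n in CHANNEL_NAMES:
        assert u.channels[n].min() >= -1.0 and u.channels[n].max() <= 1.0


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _example_pair(conditioned):
    ct_c, mri_c, _ = conditioned
    r = ChannelRanges()
    masks3d = r.masks(ct_c.values, ct_c.body_mask)
    k = 16
    ct_t = segment_channels(ct_c)[k]
    mri_t = segment_channels(mri_c, masks=masks3d)[k]
    return (scale_channels(mri_t, "to_unit"), scale_channels(ct_t, "to_unit"))


def test_augment_count_is_eight(conditioned_pair):
    pair = _example_pair(conditioned_pair)
    out = augment_pair(pair, AugmentationSpec(seed=1))
    assert len(out) == 8


def test_augment_deterministic(conditioned_pair):
    pair = _example_pair(conditioned_pair)
    a = augment_pair(pair, AugmentationSpec(seed=1))
    b = augment_pair(pair, AugmentationSpec(seed=1))
    for (ma, ca), (mb, cb) in zip(a, b):
        for n in CHANNEL_NAMES:
            assert np.array_equal(ma.channels[n], mb.channels[n])
            assert np.array_equal(ca.channels[n], cb.channels[n])


def test_augment_geometry_identical_on_both(conditioned_pair):
    """Geometric transforms move MRI and CT masks identically."""
    pair = _example_pair(conditioned_pair)
    spec = AugmentationSpec(seed=1)
    out = augment_pair(pair, spec)
    by_name = dict(zip(spec.transforms, out))
    for name in ("hflip", "vflip", "shear", "rotation", "crop", "rotation+crop"):
        m, c = by_name[name]
        for n in CHANNEL_NAMES:
            assert np.array_equal(m.masks[n], c.masks[n])
    # hflip is an exact mirror
    m, c = by_name["hflip"]
    for n in CHANNEL_NAMES:
        assert np.array_equal(c.channels[n], pair[1].channels[n][:, ::-1])


def test_augment_noise_only_on_mri(conditioned_pair):
    pair = _example_pair(conditioned_pair)
    spec = AugmentationSpec(seed=1)
    by_name = dict(zip(spec.transforms, augment_pair(pair, spec)))
    m, c = by_name["noise"]
    for n in CHANNEL_NAMES:
        assert np.array_equal(c.channels[n], pair[1].channels[n])
        if pair[0].masks[n].any():
            assert not np.array_equal(m.channels[n], pair[0].channels[n])
        assert m.channels[n].min() >= -1.0 and m.channels[n].max() <= 1.0


# ---------------------------------------------------------------------------
# additional documented properties
# ---------------------------------------------------------------------------

def test_prepare_mri_near_idempotent(phantom_pair):
    """A second conditioning pass barely changes the volume.

    The bulk of the image is stable to well under 1 % of the dynamic range;
    only the re-applied 99th-percentile clip touches the brightest ~1 % of
    voxels, and even there the drift stays small.
    """
    _, mri, _ = phantom_pair
    m1 = prepare_mri(mri)
    m2 = prepare_mri(m1)
    dr = float(m1.values.max() - m1.values.min())
    d = np.abs(m2.values - m1.values) / dr
    assert d.mean() < 0.01
    assert (d < 0.01).mean() > 0.95
    assert np.percentile(d, 99.9) < 0.02


def test_bias_correction_reduces_cv():
    """On a noise-free biased phantom, N4 shrinks the in-organ CV."""
    from mrisct.phantom import PhantomSpec, generate_pair

    base = PhantomSpec()
    s0 = PhantomSpec(
        hu_table={k: (v[0], 0.0) for k, v in base.hu_table.items()},
        mri_table={k: (v[0], 0.0) for k, v in base.mri_table.items()},
        bias_amplitude=0.15, seed=3)
    _, mri, labels = generate_pair(s0)
    kidney = labels.values == next(o.label for o in s0.organs
                                   if o.name == "kidney_l")
    corrected = preprocess.correct_bias_field(mri)

    def cv(values):
        return values[kidney].std() / values[kidney].mean()

    assert cv(corrected.values) < 0.5 * cv(mri.values)


def test_resize_roundtrip_smooth_slice():
    """Down/up (and up/down) resizing of a smooth slice drifts < 1 % range."""
    yy, xx = np.mgrid[0:96, 0:96]
    sl = np.exp(-((yy - 48) ** 2 + (xx - 40) ** 2) / (2 * 15.0**2))
    dr = sl.max() - sl.min()
    down_up = resize_slice(resize_slice(sl, (64, 64)), (96, 96))
    up_down = resize_slice(resize_slice(sl, (128, 128)), (96, 96))
    assert np.abs(down_up - sl).max() < 0.01 * dr
    assert np.abs(up_down - sl).max() < 0.01 * dr


def test_rotation_centroid_analytic():
    """The rotation transform moves a blob's centroid to the analytic spot."""
    h = w = 96
    mask = np.zeros((h, w), dtype=bool)
    mask[30:42, 55:70] = True
    t = preprocess.ChannelTriplet(
        {n: np.where(mask, 0.5, -1.0) for n in CHANNEL_NAMES},
        {n: mask.copy() for n in CHANNEL_NAMES},
        {n: (-1.0, 1.0) for n in CHANNEL_NAMES}, scaled=True)
    spec = AugmentationSpec()
    out = preprocess._apply_geometric(t, "rotation", spec)
    c0 = np.argwhere(mask).mean(axis=0)  # (row, col)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    th = np.deg2rad(spec.rotation_deg)
    # the affine acts in (x=col, y=row) coordinates
    vx, vy = c0[1] - center[1], c0[0] - center[0]
    expected = np.array([center[0] + (np.sin(th) * vx + np.cos(th) * vy),
                         center[1] + (np.cos(th) * vx - np.sin(th) * vy)])
    got = np.argwhere(out.masks["air"]).mean(axis=0)
    assert np.abs(expected - got).max() < 0.5  # within half a voxel


def test_prepare_ct_cross_grid_preserves_uniform_region():
    """Resampling to a different grid keeps a uniform block's mean within 1 HU."""
    from mrisct.volume import ImageVolume

    ctv = np.full((32, 96, 96), -1000.0)
    ctv[:, 20:76, 20:76] = 50.0
    ct = ImageVolume(ctv, (3.0, 2.0, 2.0), (0.0, 0.0, 0.0), "CT",
                     background_mask=(ctv == -1000.0))
    mri_grid = ImageVolume(np.zeros((40, 80, 80)), (2.4, 2.4, 2.4),
                           (0.0, 0.0, 0.0), "MRI")
    out = prepare_ct(ct, mri_grid)
    assert out.shape == mri_grid.shape
    zz, yy, xx = np.meshgrid(np.arange(40) * 2.4 + 1.2,
                             np.arange(80) * 2.4 + 1.2,
                             np.arange(80) * 2.4 + 1.2, indexing="ij")
    interior = ((yy > 46) & (yy < 146) & (xx > 46) & (xx < 146)
                & (zz > 6) & (zz < 90))
    assert abs(out.values[interior].mean() - 50.0) < 1.0


def test_hflip_is_involution(conditioned_pair):
    pair = _example_pair(conditioned_pair)
    spec = AugmentationSpec()
    once = preprocess._apply_geometric(pair[1], "hflip", spec)
    twice = preprocess._apply_geometric(once, "hflip", spec)
    for n in CHANNEL_NAMES:
        assert np.array_equal(twice.channels[n], pair[1].channels[n])
        assert np.array_equal(twice.masks[n], pair[1].masks[n])


def test_noise_free_phantom_hu_masks_equal_label_masks():
    """On a noise-free phantom the HU-range masks equal the label-map classes."""
    from mrisct.phantom import PhantomSpec, generate_pair
    from mrisct.pipeline import masks_from_labels

    base = PhantomSpec()
    s0 = PhantomSpec(
        hu_table={k: (v[0], 0.0) for k, v in base.hu_table.items()},
        mri_table={k: (v[0], 0.0) for k, v in base.mri_table.items()},
        bias_amplitude=0.0, seed=3)
    ct, mri, labels = generate_pair(s0)
    ct_c = prepare_ct(ct, mri)
    hu_masks = ChannelRanges().masks(ct_c.values, ct_c.body_mask)
    label_masks = masks_from_labels(labels, s0.organs)
    for n in CHANNEL_NAMES:
        assert np.array_equal(hu_masks[n], label_masks[n])
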