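import numpy as np
import pytest

from canopycount import PointCloud, SceneSpec, TrayLayout, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_layout():
    return TrayLayout(n_trays=3)


@pytest.fixture(scope="session")
def small_scene(small_layout):
    """A 3-tray synthetic row with plants, reused across read-only tests."""
    spec = SceneSpec(layout=small_layout, rng_seed=11)
    return spec, *generate_scene(spec)


def late_germination_scene(seed=24):
    """A bowl-soil tray with one late-germinated plant low in the bowl.

    The soil comes from the synthetic generator (15 mm bowl, 1 mm noise, no
    plants, no clutter); a small plant is added by hand at the bowl center
    with leaf disks 14 and 18 mm above the local soil — above the reach of
    the k-NN neighborhoods, but below the soil level at the tray sides, so a
    fixed height cut cannot keep the plant without keeping soil.  A second,
    tall plant is added off-center.  Returns (frame-cleaned cloud, number of
    leading soil points); all plant points are appended after the soil.
    """
    from canopycount import remove_frame, split_trays
    from canopycount.synthetic import _soil_z

    layout = TrayLayout(n_trays=1)
    spec = SceneSpec(layout=layout, plants_per_tray=(0, 0), clutter_fraction=0.0,
                     rng_seed=seed)
    cloud, _ = generate_scene(spec)
    tray = split_trays(cloud, layout)[0]
    cleaned = remove_frame(tray, layout)
    n_soil = len(cleaned)
    inner = (20.0, 620.0, 20.0, 380.0)
    rng_ = np.random.default_rng(seed + 1)

    def disk(cx, cy, z, radius):
        xs = np.arange(cx - radius, cx + radius + 1e-9, spec.point_spacing_mm)
        ys = np.arange(cy - radius, cy + radius + 1e-9, spec.point_spacing_mm)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        pts += rng_.uniform(-1.0, 1.0, pts.shape)
        keep = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 <= radius ** 2
        return np.column_stack([pts[keep], np.full(keep.sum(), z)])

    def plant(cx, cy, heights, radius, stem=True):
        soil_here = float(_soil_z(spec, np.array([[cx, cy]]), inner)[0])
        disks = [disk(cx, cy, soil_here + h, radius) for h in heights]
        if stem:
            stem_z = np.arange(2.0, max(heights), 4.0)
            disks.insert(0, np.column_stack([
                np.full_like(stem_z, cx), np.full_like(stem_z, cy),
                soil_here + stem_z]))
        return np.vstack(disks)

    # a stemless seedling rosette low in the bowl: at scan resolution a
    # germinating plant is a pair of leaf disks just above the soil
    low = plant(320.0, 200.0, heights=(14.0, 18.0), radius=24.0, stem=False)
    tall = plant(480.0, 120.0, heights=(80.0, 110.0), radius=25.0)
    out = PointCloud(xyz=np.vstack([cleaned.xyz, low, tall]),
                     tray_rect_xy=cleaned.tray_rect_xy)
    return out, n_soil


def planar_cloud(n=400, z=7.0, side=100.0, seed=0, noise=0.0):
    """Jittered-grid sample of the horizontal plane z=const."""
    rng = np.random.default_rng(seed)
    m = int(np.sqrt(n))
    xs = np.linspace(0, side, m)
    gx, gy = np.meshgrid(xs, xs)
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    xy += rng.uniform(-0.2, 0.2, xy.shape) * side / m
    zz = np.full(len(xy), z) + (rng.normal(0, noise, len(xy)) if noise else 0.0)
    return PointCloud(xyz=np.column_stack([xy, zz]))
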