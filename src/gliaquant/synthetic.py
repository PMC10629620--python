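"""Ground-truthed synthetic inputs for every pipeline stage.

The scene generator emulates the features of the confocal data the pipeline
was designed for: bright quasi-spherical lipid droplets, elongated tubular
tracheal structures, a ring-shaped glia-membrane signal around the masked
region, a uniform background, and additive Gaussian noise clipped at zero.
Droplets are rasterized as solid balls by center-of-voxel inclusion; tubes as
a union of balls swept along a centerline. Every per-object integral is known
exactly on the noise-free render, so segmentation and extraction can be
checked against ground truth.

Non-imaging stages get generators too: per-fly injured/uninjured intensity
time courses with a known exponential decay, and qPCR Ct tables constructed
so that exact comparative-CT analysis recovers a chosen fold change.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString as _LineString

from .io_stack import ChannelSet, ImageStack, Polygon2D, polygon_pixel_mask

DROPLET = "droplet"
TUBE = "tube"


@dataclasses.dataclass(frozen=True)
class DropletSpec:
    """A solid ball: quasi-spherical lipid droplet."""

    center: tuple[float, float, float]  # (z, y, x)
    radius: float                       # voxels
    peak_intensity: float

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("droplet radius must be >= 1 voxel")
        if self.peak_intensity <= 0:
            raise ValueError("peak intensity must be positive")


@dataclasses.dataclass(frozen=True)
class TubeSpec:
    """A tube swept along a centerline: elongated tracheal structure."""

    centerline: tuple[tuple[float, float, float], ...]
    tube_radius: float
    peak_intensity: float

    def __post_init__(self) -> None:
        if len(self.centerline) < 2:
            raise ValueError("tube centerline needs >= 2 points")
        if self.tube_radius < 1:
            raise ValueError("tube radius must be >= 1 voxel")
        if self.peak_intensity <= 0:
            raise ValueError("peak intensity must be positive")


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    shape: tuple[int, int, int]
    droplets: tuple[DropletSpec, ...]
    tubes: tuple[TubeSpec, ...]
    glia_polygon: Polygon2D
    noise_sd: float = 0.0
    background_level: float = 10.0
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """What the pipeline should recover from a rendered scene."""

    label_map: np.ndarray               # 0 background, 1..N objects
    object_class: dict[int, str]        # label -> droplet | tube
    droplet_integral_in_mask: dict[int, float]  # noise-free, inside glia mask
    total_lipid_content: float          # sum of the above
    glia_mask_2d: np.ndarray            # (Y, X) pixel-center mask


def _ball_voxels(center: Sequence[float], radius: float,
                 shape: tuple[int, int, int]) -> np.ndarray:
    """Integer voxel coordinates whose centers lie within ``radius`` of ``center``."""
    cz, cy, cx = center
    lo = [max(0, int(np.floor(c - radius)) - 1) for c in (cz, cy, cx)]
    hi = [min(s - 1, int(np.ceil(c + radius)) + 1) for c, s in zip((cz, cy, cx), shape)]
    if any(l > h for l, h in zip(lo, hi)):
        return np.empty((0, 3), dtype=np.intp)
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0] + 1),
        np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
    keep = d2 <= radius**2
    return np.stack([zz[keep], yy[keep], xx[keep]], axis=1)


def _droplet_voxels(spec: DropletSpec, shape: tuple[int, int, int]) -> np.ndarray:
    cz, cy, cx = spec.center
    r = spec.radius
    for c, s in zip((cz, cy, cx), shape):
        if c - r < -0.5 or c + r > s - 0.5:
            raise ValueError(f"droplet at {spec.center} (r={r}) out of bounds {shape}")
    return _ball_voxels(spec.center, r, shape)


def _tube_voxels(spec: TubeSpec, shape: tuple[int, int, int]) -> np.ndarray:
    pts = np.asarray(spec.centerline, dtype=np.float64)
    r = spec.tube_radius
    if pts.min() - r < -0.5 or np.any(pts + r > np.asarray(shape) - 0.5):
        raise ValueError("tube out of bounds")
    # sweep: sample the centerline densely, union of balls
    samples = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        n = max(1, int(np.ceil(np.linalg.norm(seg) / 0.25)))
        for t in np.linspace(0, 1, n + 1)[1:]:
            samples.append(a + t * seg)
    vox: set[tuple[int, int, int]] = set()
    for p in samples:
        vox.update(map(tuple, _ball_voxels(p, r, shape)))
    return np.array(sorted(vox), dtype=np.intp)


def render_scene(spec: SceneSpec) -> tuple[ChannelSet, GroundTruth]:
    """Render a scene into lipid + glia channels with exact ground truth.

    The lipid channel is ``background + objects + N(0, noise_sd)`` clipped at
    zero; object interiors are flat at ``background + peak_intensity``. The
    glia channel carries a bright band along the glia polygon's boundary.
    Ground-truth per-droplet integrals are taken on the noise-free image
    inside the polygon's pixel-center mask (full depth). Identical specs give
    voxel-identical output.
    """
    nz, ny, nx = spec.shape
    clean = np.full(spec.shape, float(spec.background_level))
    label_map = np.zeros(spec.shape, dtype=np.int32)
    object_class: dict[int, str] = {}

    label = 0
    for kind, objs, getter in (
        (DROPLET, spec.droplets, _droplet_voxels),
        (TUBE, spec.tubes, _tube_voxels),
    ):
        for obj in objs:
            label += 1
            vox = getter(obj, spec.shape)
            if vox.size == 0:
                raise ValueError(f"{kind} rasterized to zero voxels: {obj}")
            zz, yy, xx = vox[:, 0], vox[:, 1], vox[:, 2]
            if not spec.allow_overlap and np.any(label_map[zz, yy, xx] != 0):
                raise ValueError(f"{kind} {obj} overlaps an earlier object")
            label_map[zz, yy, xx] = label
            clean[zz, yy, xx] = spec.background_level + obj.peak_intensity
            object_class[label] = kind

    mask2d = polygon_pixel_mask(spec.glia_polygon, (ny, nx))
    mask3d = np.broadcast_to(mask2d, spec.shape)
    droplet_integrals = {
        lab: float(clean[(label_map == lab) & mask3d].sum())
        for lab, cls in object_class.items()
        if cls == DROPLET
    }

    rng = np.random.default_rng(spec.seed)
    noisy = clean if spec.noise_sd == 0 else np.clip(
        clean + rng.normal(0.0, spec.noise_sd, size=spec.shape), 0.0, None
    )

    glia = np.zeros((ny, nx))
    boundary = _LineString(
        [(x, y) for y, x in spec.glia_polygon.vertices]
        + [(spec.glia_polygon.vertices[0][1], spec.glia_polygon.vertices[0][0])]
    )
    yy, xx = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float),
                         indexing="ij")
    pts = shapely.points(xx.ravel(), yy.ravel())
    dist = shapely.distance(pts, boundary).reshape(ny, nx)
    glia[dist <= 1.5] = 150.0  # membrane-reporter band ~3 px wide
    glia_vol = np.broadcast_to(glia, spec.shape).copy()
    if spec.noise_sd > 0:
        glia_vol = np.clip(
            glia_vol + rng.normal(0.0, spec.noise_sd, size=spec.shape), 0.0, None
        )

    channels = ChannelSet({
        "lipid": ImageStack(noisy, channel_name="lipid"),
        "glia": ImageStack(glia_vol, channel_name="glia"),
    })
    truth = GroundTruth(
        label_map=label_map,
        object_class=object_class,
        droplet_integral_in_mask=droplet_integrals,
        total_lipid_content=float(sum(droplet_integrals.values())),
        glia_mask_2d=mask2d,
    )
    return channels, truth


def random_scene(seed: int, shape: tuple[int, int, int] = (16, 96, 96),
                 n_droplets: int = 5, n_tubes: int = 3,
                 droplet_radius: tuple[float, float] = (3.0, 4.5),
                 peak_intensity: float = 100.0, noise_sd: float = 5.0,
                 background_level: float = 10.0) -> SceneSpec:
    """A randomized droplets-in-mask + tubes-outside scene.

    Droplets land inside a central rectangular glia polygon; tubes are
    axis-oblique segments of length ~40 voxels placed outside it. Placement
    retries until nothing overlaps. Defaults match the stress conditions the
    pipeline is validated under: 5 droplets, 3 tubes, noise at 5% of the
    droplet peak.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    # glia polygon: central rectangle occupying the middle of the field
    y0, y1 = ny // 4, 3 * ny // 4
    x0, x1 = nx // 4, 3 * nx // 4
    polygon = Polygon2D(((y0, x0), (y0, x1), (y1, x1), (y1, x0)))

    placed: list[set] = []
    # placement margin: reject candidates 26-adjacent to an existing object,
    # otherwise touching objects would merge into one connected component
    _nbhd = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]

    def overlaps(vox: np.ndarray) -> bool:
        dilated = {
            (z + dz, y + dy, x + dx)
            for z, y, x in map(tuple, vox)
            for dz, dy, dx in _nbhd
        }
        return any(dilated & p for p in placed)

    droplets = []
    for _ in range(n_droplets):
        for _attempt in range(200):
            r = rng.uniform(*droplet_radius)
            c = (
                rng.uniform(r + 0.5, nz - r - 1.5),
                rng.uniform(y0 + r + 1, y1 - r - 1),
                rng.uniform(x0 + r + 1, x1 - r - 1),
            )
            cand = DropletSpec(center=c, radius=r, peak_intensity=peak_intensity)
            vox = _droplet_voxels(cand, shape)
            if not overlaps(vox):
                placed.append({*map(tuple, vox)})
                droplets.append(cand)
                break
        else:
            raise RuntimeError("could not place droplet without overlap")

    tubes = []
    for _ in range(n_tubes):
        for _attempt in range(500):
            length, r = 40.0, 2.0
            zc = rng.uniform(r + 1, nz - r - 2)
            # start in the left or top margin, run roughly horizontally
            ystart = rng.uniform(r + 1, y0 - r - 2)
            xstart = rng.uniform(r + 1, nx - length - r - 2)
            angle = rng.uniform(-0.1, 0.1)
            p0 = (zc, ystart, xstart)
            p1 = (zc, ystart + length * np.sin(angle), xstart + length * np.cos(angle))
            if not (r + 0.5 < p1[1] < y0 - r - 1):
                continue
            cand = TubeSpec(centerline=(p0, p1), tube_radius=r,
                            peak_intensity=peak_intensity)
            try:
                vox = _tube_voxels(cand, shape)
            except ValueError:
                continue
            if not overlaps(vox):
                placed.append({*map(tuple, vox)})
                tubes.append(cand)
                break
        else:
            raise RuntimeError("could not place tube without overlap")

    return SceneSpec(
        shape=shape,
        droplets=tuple(droplets),
        tubes=tuple(tubes),
        glia_polygon=polygon,
        noise_sd=noise_sd,
        background_level=background_level,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# injury-clearance time courses
# ---------------------------------------------------------------------------

def generate_clearance_series(n_flies: int, days: int, decay_rate_injured: float,
                              baseline: float, noise_sd: float, seed: int,
                              diet_group: str = "ND") -> pd.DataFrame:
    """Per-fly injured/uninjured intensity pairs over post-injury days.

    The uninjured side holds at ``baseline``; the injured side decays as
    ``baseline * (1 - decay_rate_injured)**day`` (debris clearance), both plus
    Gaussian noise. Columns match the clearance-record schema.
    """
    if not (0.0 <= decay_rate_injured <= 1.0):
        raise ValueError("decay_rate_injured must be in [0, 1]")
    if days < 1:
        raise ValueError("days must be >= 1")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for fly in range(n_flies):
        for day in range(1, days + 1):
            uninjured = baseline + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            injured = baseline * (1.0 - decay_rate_injured) ** day + (
                rng.normal(0, noise_sd) if noise_sd else 0.0
            )
            rows.append({
                "fly_id": f"{diet_group}_fly{fly:03d}",
                "diet_group": diet_group,
                "day_post_injury": day,
                "injured_intensity": max(injured, 0.0),
                "uninjured_intensity": max(uninjured, 0.0),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def generate_ct_table(true_fold_changes: Mapping[str, float],
                      reference_gene: str = "alpha-tubulin",
                      n_replicates: int = 3, ct_noise_sd: float = 0.0,
                      seed: int = 0, control_group: str = "control",
                      treatment_group: str = "treatment",
                      reference_ct: float = 20.0,
                      target_delta_ct: float = 5.0) -> pd.DataFrame:
    """Construct a Ct table whose exact comparative-CT analysis gives the folds.

    The reference gene sits at ``reference_ct`` cycles in both groups; each
    target's control Ct is ``reference_ct + target_delta_ct`` and its
    treatment Ct is lowered by ``log2(fold)`` (one fewer cycle per doubling of
    transcript). Gaussian noise of ``ct_noise_sd`` cycles is added per
    replicate.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def add(gene: str, group: str, ct: float) -> None:
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0, ct_noise_sd) if ct_noise_sd else 0.0
            rows.append({"gene": gene, "group": group, "replicate": rep,
                         "ct": ct + noise})

    for group in (control_group, treatment_group):
        add(reference_gene, group, reference_ct)
    for gene, fold in true_fold_changes.items():
        if fold <= 0:
            raise ValueError(f"fold for {gene} must be positive, got {fold}")
        control_ct = reference_ct + target_delta_ct
        add(gene, control_group, control_ct)
        add(gene, treatment_group, control_ct - np.log2(fold))
    return pd.DataFrame(rows)
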