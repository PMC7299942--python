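"""Synthetic cell-folder generator.

Produces complete, pipeline-ready inputs — a tower label volume, a gold-bead
mask, the 4xN link table and its binary usage twin — for a stated bundle
geometry: near-cylindrical towers standing on a common base plane, arranged
as rows (1 kinocilium, 2 tall, 3 middle, 4 short, decreasing y) x columns
(along x), with a small seeded axis tilt so PCA never sees a perfectly
degenerate cylinder.  The validation bead pattern places exactly one bead
per stereocilium with a row-specific location (tall row: at the tip, on the
side away from the middle row; middle row: mid-shaft, away from the tall
row; short row: near the base, away from the middle row; none on the
kinocilium), so any orientation, row-assignment or association error shows
up as a bead outside its expected (segment, sector) cell.

Default dimensions correspond to P4 outer-hair-cell bundles: stereocilia
heights of ~2.4 / 2.0 / 1.2 um for the tall / middle / short rows (which is
what makes the ~200-nm segment rule yield 12 / 10 / 6 shaft segments),
~0.2 um stereocilia diameter, and a taller, slightly thicker kinocilium.
Voxels default to 10 x 10 x 15 nm — the working resolution the real data
reach after the pipeline's default 4x lateral downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import StereogoldError
from .geometry import rodrigues_rotate
from .io_formats import (LinkTable, TowerUsage, write_label_volume,
                         write_link_table, write_tower_usage)
from .quantification import segment_count
from .volumes import LabelVolume

__all__ = ["BundleSpec", "GroundTruth", "generate_bundle", "place_validation_beads",
           "write_cell_folder"]

DEFAULT_HEIGHTS = {1: 3.0, 2: 2.4, 3: 2.0, 4: 1.2}   # um
DEFAULT_RADII = {1: 0.12, 2: 0.10, 3: 0.10, 4: 0.10}  # um


@dataclass
class BundleSpec:
    n_columns: int = 5
    rows: tuple[int, ...] = (1, 2, 3, 4)
    heights: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_HEIGHTS))
    radii: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    column_spacing: float = 0.5      # um along x
    row_spacing: float = 0.45        # um along y
    base_z: float = 0.2              # um, base plane above the volume floor
    margin: float = 0.2              # um padding around the bundle
    voxel_size: tuple[float, float, float] = (10.0, 10.0, 15.0)  # nm (x, y, z)
    tilt_jitter_deg: float = 3.0     # per-tower axis tilt, seeded
    rotation_axis: tuple[float, float, float] | None = None  # optional global rotation
    rotation_angle: float = 0.0      # radians
    kino_column: int | None = None   # defaults to the middle column
    bead_radius: float = 0.02        # um
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_columns < 0:
            raise ValueError("n_columns must be >= 0")
        hs = [self.heights[r] for r in self.rows if r != 1]
        rows = [r for r in self.rows if r != 1]
        for a, b in zip(sorted(rows), sorted(rows)[1:]):
            if self.heights[a] < self.heights[b]:
                raise ValueError("stereocilia heights must decrease with row number")
        del hs


@dataclass
class GroundTruth:
    """What the generator actually rendered, for checking pipeline output."""

    towers: dict[int, dict]          # id -> row, column, base, axis, height, radius, north
    beads: list[dict] = field(default_factory=list)  # tower, position, segment, sector
    upward: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))


def _tower_layout(spec: BundleSpec) -> tuple[dict[int, dict], LinkTable, GroundTruth]:
    """Assign IDs, base points and axes; build the link table."""
    rows_sorted = sorted(spec.rows)
    kino_col = spec.kino_column if spec.kino_column is not None else spec.n_columns // 2
    rng = np.random.default_rng(spec.rng_seed)

    ids = np.zeros((4, spec.n_columns), dtype=int)
    towers: dict[int, dict] = {}
    next_id = 1
    # mechanotransduction direction: from the short-row end toward the kinocilium
    mech = np.array([0.0, 1.0, 0.0])
    north = -mech
    for row in rows_sorted:
        y = (4 - row) * spec.row_spacing + spec.margin
        for c in range(spec.n_columns):
            if row == 1 and c != kino_col:
                continue
            x = c * spec.column_spacing + spec.margin + spec.radii[row]
            base = np.array([x, y, spec.base_z])
            # small tilt about a random horizontal axis
            tilt = np.deg2rad(spec.tilt_jitter_deg) * rng.uniform(0.5, 1.0)
            phi = rng.uniform(0, 2 * np.pi)
            axis = np.array([np.cos(phi), np.sin(phi), 0.0])
            direction = rodrigues_rotate(np.array([[0.0, 0.0, 1.0]]), axis, tilt)[0]
            towers[next_id] = {
                "row": row, "column": c, "base": base, "axis": direction,
                "height": spec.heights[row], "radius": spec.radii[row], "north": north,
            }
            ids[row - 1, c] = next_id
            next_id += 1

    if spec.rotation_axis is not None and spec.rotation_angle:
        pts = np.array([t["base"] for t in towers.values()])
        center = pts.mean(axis=0)
        ax = np.asarray(spec.rotation_axis, float)
        for t in towers.values():
            t["base"] = rodrigues_rotate((t["base"] - center)[None], ax,
                                         spec.rotation_angle)[0] + center
            t["axis"] = rodrigues_rotate(t["axis"][None], ax, spec.rotation_angle)[0]
            t["north"] = rodrigues_rotate(t["north"][None], ax, spec.rotation_angle)[0]
        up = rodrigues_rotate(np.array([[0.0, 0.0, 1.0]]), ax, spec.rotation_angle)[0]
    else:
        up = np.array([0.0, 0.0, 1.0])

    link = LinkTable(ids) if ids.any() else None
    gt = GroundTruth(towers=towers, upward=up)
    return towers, link, gt


def _render_cylinders(towers: dict[int, dict], spec: BundleSpec,
                      shape: tuple[int, int, int]) -> np.ndarray:
    vs = np.asarray(spec.voxel_size, float)  # (x, y, z) nm
    data = np.zeros(shape, dtype=np.uint8)
    for tid, t in towers.items():
        base, d, h, r = t["base"], t["axis"], t["height"], t["radius"]
        # bounding box of the capped cylinder, in voxels
        lo_um = np.minimum(base, base + d * h) - r
        hi_um = np.maximum(base, base + d * h) + r
        lo = np.maximum(np.floor(lo_um * 1000.0 / vs).astype(int), 0)       # (x, y, z)
        hi = np.minimum(np.ceil(hi_um * 1000.0 / vs).astype(int) + 1,
                        np.array(shape)[::-1])
        if np.any(lo >= hi):
            raise StereogoldError(f"tower {tid} lies outside the rendered volume")
        zz, yy, xx = np.meshgrid(np.arange(lo[2], hi[2]), np.arange(lo[1], hi[1]),
                                 np.arange(lo[0], hi[0]), indexing="ij")
        centers = (np.stack([xx, yy, zz], axis=-1) + 0.5) * vs / 1000.0
        rel = centers - base
        axial = rel @ d
        radial = np.linalg.norm(rel - axial[..., None] * d, axis=-1)
        inside = (axial >= 0) & (axial <= h) & (radial <= r)
        sub = data[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]]
        if np.any(sub[inside] != 0):
            raise StereogoldError(f"tower {tid} overlaps an already-rendered tower")
        sub[inside] = tid
    return data


def generate_bundle(spec: BundleSpec) -> tuple[LabelVolume, LabelVolume, LinkTable,
                                               TowerUsage, GroundTruth]:
    """Voxelize the bundle; returns towers, (empty) gold volume, tables, truth."""
    if spec.n_columns == 0:
        vs = np.asarray(spec.voxel_size, float)
        empty = LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8), vs)
        ids = np.zeros((4, 0), dtype=int)
        # bypass LinkTable's "no towers" validation for the degenerate case
        link = LinkTable.__new__(LinkTable)
        link.ids = ids
        usage = TowerUsage(np.zeros((4, 0), dtype=int))
        return empty, LabelVolume(empty.data.copy(), vs), link, usage, GroundTruth({})

    towers, link, gt = _tower_layout(spec)
    vs = np.asarray(spec.voxel_size, float)
    pts = np.array([t["base"] for t in towers.values()])
    tips = np.array([t["base"] + t["axis"] * t["height"] for t in towers.values()])
    radii = np.array([t["radius"] for t in towers.values()])
    hi_um = np.maximum(pts.max(axis=0), tips.max(axis=0)) + radii.max() + spec.margin
    shape = tuple(int(np.ceil(h * 1000.0 / v)) for h, v in zip(hi_um[::-1], vs[::-1]))

    data = _render_cylinders(towers, spec, shape)
    tower_vol = LabelVolume(data, vs.copy())
    gold_vol = LabelVolume(np.zeros(shape, dtype=np.uint8), vs.copy())
    usage = TowerUsage((link.ids != 0).astype(int))
    return tower_vol, gold_vol, link, usage, gt


# row-specific validation bead placement: (side along +/-y, height fraction rule)
_ROW_SIDE = {2: +1.0, 3: -1.0, 4: -1.0}


def _bead_height_fraction(row: int, height: float) -> float:
    """Mid-segment height fractions: tall row at the tip segment, middle row
    mid-shaft, short row in the basal segment."""
    n_seg = segment_count(height)
    if row == 2:
        return 1.0 - 0.5 / n_seg
    if row == 3:
        k = (n_seg + 1) // 2  # mid-shaft segment
        return (k + 0.5) / n_seg
    return 0.5 / n_seg


def place_validation_beads(
    tower_vol: LabelVolume,
    gold_vol: LabelVolume,
    gt: GroundTruth,
    n_az_bins: int = 4,
    bead_radius: float = 0.02,
) -> tuple[LabelVolume, GroundTruth]:
    """Render exactly one bead per stereocilium in the row-specific pattern.

    The expected (segment, sector) of each bead under the default binning is
    recorded in the ground truth; kinocilia get no beads.
    """
    import warnings

    present_rows = {t["row"] for t in gt.towers.values()}
    for need in (2, 3, 4):
        if need not in present_rows:
            warnings.warn(f"row {need} absent; validation pattern incomplete", stacklevel=2)

    vs = gold_vol.voxel_size
    data = gold_vol.data.copy()
    beads: list[dict] = []
    for tid, t in sorted(gt.towers.items()):
        row = t["row"]
        if row == 1:
            continue  # no beads on the kinocilium
        side = _ROW_SIDE[row]
        frac = _bead_height_fraction(row, t["height"])
        # lateral direction: +/- y in the bundle's own frame, made orthogonal
        # to the (tilted, possibly rotated) tower axis
        lateral = side * t["north"] / np.linalg.norm(t["north"]) * -1.0  # north = -y side
        lateral = lateral - (lateral @ t["axis"]) * t["axis"]
        lateral = lateral / np.linalg.norm(lateral)
        center = t["base"] + t["axis"] * (frac * t["height"]) \
            + lateral * (t["radius"] + bead_radius)
        _render_ball(data, center, bead_radius, vs)

        n_seg = segment_count(t["height"])
        segment = min(n_seg, int(np.floor(frac * n_seg)) + 1)
        # sector under 'centered' binning, counted CCW from north
        sector = 1 if side < 0 else (n_az_bins // 2 + 1 if n_az_bins > 1 else 1)
        beads.append({"tower": tid, "position": center, "segment": segment,
                      "sector": sector, "row": row})
    gt.beads = beads
    return LabelVolume(data, vs.copy()), gt


def _render_ball(data: np.ndarray, center_um: np.ndarray, radius_um: float,
                 vs_nm: np.ndarray) -> None:
    lo = np.maximum(np.floor((center_um - radius_um) * 1000.0 / vs_nm).astype(int), 0)
    hi = np.minimum(np.ceil((center_um + radius_um) * 1000.0 / vs_nm).astype(int) + 1,
                    np.array(data.shape)[::-1])
    if np.any(lo >= hi):
        raise StereogoldError("bead lies outside the rendered volume")
    zz, yy, xx = np.meshgrid(np.arange(lo[2], hi[2]), np.arange(lo[1], hi[1]),
                             np.arange(lo[0], hi[0]), indexing="ij")
    centers = (np.stack([xx, yy, zz], axis=-1) + 0.5) * vs_nm / 1000.0
    inside = np.linalg.norm(centers - center_um, axis=-1) <= radius_um
    if not inside.any():  # radius below voxel size: mark the single nearest voxel
        vox = np.floor(center_um * 1000.0 / vs_nm).astype(int)[::-1]
        data[tuple(vox)] = 1
        return
    sub = data[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]]
    sub[inside] = 1


def write_cell_folder(spec: BundleSpec, out_dir, with_beads: bool = True,
                      n_az_bins: int = 4, format: str = "amira_rle") -> GroundTruth:
    """Write a complete synthetic cell folder: ``Towers.am``,
    ``GoldParticles.am``, ``LinkTable.csv``, ``TowerUsage.csv`` and
    ``ground_truth.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    towers, gold, link, usage, gt = generate_bundle(spec)
    if with_beads:
        gold, gt = place_validation_beads(towers, gold, gt,
                                          n_az_bins=n_az_bins,
                                          bead_radius=spec.bead_radius)
    write_label_volume(towers, out_dir / "Towers.am", format=format)
    write_label_volume(gold, out_dir / "GoldParticles.am", format=format)
    write_link_table(link, out_dir / "LinkTable.csv")
    write_tower_usage(usage, out_dir / "TowerUsage.csv")
    with open(out_dir / "ground_truth.csv", "w") as fh:
        fh.write("tower,row,x,y,z,segment,sector\n")
        for b in gt.beads:
            x, y, z = b["position"]
            fh.write(f"{b['tower']},{b['row']},{x:.9g},{y:.9g},{z:.9g},"
                     f"{b['segment']},{b['sector']}\n")
    return gt
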