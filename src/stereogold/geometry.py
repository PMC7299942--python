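"""Geometric core: tower orientation, registration and measurement.

Stereocilia and kinocilia are elongated, near-cylindrical "towers".  The
orientation stage estimates each tower's long axis by PCA of sampled border
voxels, randomly flips the (sign-ambiguous) axes so they form two antipodal
clusters on the unit sphere, finds the two cluster centres by spherical
mean shift, and picks the candidate that makes the tower bases most coplanar
("upward").  A single Rodrigues rotation then puts the whole scene upright
with the base plane at z = 0; per-column mechanotransduction directions from
the link table define a per-tower "north" that is rotated onto (0, 1, 0);
finally every tower is scaled to its row's average height/radius so beads
from different towers can be pooled on one template cylinder.

All rigid steps preserve pairwise distances; only the final per-row template
registration is (deliberately) non-rigid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .errors import StereogoldError, ValidationError
from .io_formats import LinkTable
from .volumes import LabelVolume, voxel_centers_um

__all__ = [
    "Tower",
    "BeadSet",
    "BundleFrame",
    "RowTemplate",
    "Hull",
    "sample_tower_borders",
    "extract_bead_centroids",
    "principal_direction",
    "random_sign_flip",
    "meanshift_sphere",
    "determine_upward",
    "rodrigues_rotate",
    "normalize_frame",
    "compute_column_azimuths",
    "azimuth_align_tower",
    "tower_height_radius",
    "register_tower_to_template",
    "convex_hull",
]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return np.asarray(v, float) / n


# ---------------------------------------------------------------------------
# domain records


@dataclass
class Tower:
    """One labelled tower, with geometry filled in as the pipeline advances."""

    id: int
    row: int = 0          # 1 kinocilium, 2 tall, 3 middle, 4 short
    column: int = -1
    border_points: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    principal_direction: np.ndarray | None = None
    centroid: np.ndarray | None = None
    height: float = 0.0
    radius: float = 0.0
    used: bool = True
    north: np.ndarray | None = None


@dataclass
class BeadSet:
    """Gold-bead centroids (um) with per-bead tower assignment state."""

    centroids: np.ndarray                      # (n, 3) xyz um
    assigned_tower: np.ndarray | None = None   # (n,) int, 0 = unassigned
    excluded: np.ndarray | None = None         # (n,) bool

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, float).reshape(-1, 3)
        n = len(self.centroids)
        if self.assigned_tower is None:
            self.assigned_tower = np.zeros(n, dtype=int)
        if self.excluded is None:
            self.excluded = np.zeros(n, dtype=bool)

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class BundleFrame:
    """The canonical frame after normalization: up = +z, norths in XY."""

    upward: np.ndarray
    per_tower_north: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class RowTemplate:
    """Average tower dimensions for one row, over used towers."""

    row: int
    avg_height: float
    avg_radius: float
    n_towers: int


@dataclass
class Hull:
    vertices: np.ndarray   # (v, 3)
    facets: np.ndarray     # (f, 3) indices into vertices
    planar: bool = False


# ---------------------------------------------------------------------------
# voxel-level extraction


def border_mask(labels: np.ndarray) -> np.ndarray:
    """Voxels with at least one 6-neighbour of a different label (the volume
    boundary counts as background)."""
    lab = np.asarray(labels)
    padded = np.pad(lab, 1, mode="constant", constant_values=0)
    border = np.zeros(lab.shape, dtype=bool)
    core = (slice(1, -1),) * 3
    for axis in range(3):
        for step in (-1, 1):
            sl = list(core)
            sl[axis] = slice(1 + step, lab.shape[axis] + 1 + step)
            border |= padded[tuple(sl)] != lab
    border &= lab != 0
    return border


def sample_tower_borders(
    vol: LabelVolume, factor: float = 0.1, seed: int = 0
) -> dict[int, np.ndarray]:
    """Random subset of each tower's border-voxel centres, in um.

    Per label, ``round(factor * n_border)`` voxels (at least 1) are drawn
    without replacement; the draw is reproducible under ``seed``.
    """
    if not (0 < factor <= 1):
        raise ValueError(f"border sampling factor must be in (0, 1], got {factor}")
    mask = border_mask(vol.data)
    coords = np.argwhere(mask)
    labels_at = vol.data[mask]
    rng = np.random.default_rng(seed)
    out: dict[int, np.ndarray] = {}
    for lab in vol.labels():
        sel = coords[labels_at == lab]
        n = len(sel)
        if n == 0:
            out[int(lab)] = np.zeros((0, 3))
            continue
        keep = max(1, _round_half_away(factor * n))
        if keep < n:
            sel = sel[np.sort(rng.choice(n, size=keep, replace=False))]
        out[int(lab)] = voxel_centers_um(sel, vol.voxel_size)
    return out


def extract_bead_centroids(gold: LabelVolume) -> BeadSet:
    """Centroid of every 26-connected component of the gold mask, in um."""
    binary = gold.data > 0
    structure = np.ones((3, 3, 3), dtype=bool)
    labeled, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return BeadSet(centroids=np.zeros((0, 3)))
    coms = ndimage.center_of_mass(binary, labeled, index=np.arange(1, n + 1))
    return BeadSet(centroids=voxel_centers_um(np.asarray(coms), gold.voxel_size))


# ---------------------------------------------------------------------------
# orientation


def principal_direction(points: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the point covariance (sign arbitrary)."""
    pts = np.asarray(points, float).reshape(-1, 3)
    if len(pts) < 3:
        raise StereogoldError(f"need >= 3 points for PCA, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    w, v = np.linalg.eigh(cov)
    if w[-1] <= 0:
        raise StereogoldError("degenerate covariance: all points coincident")
    return v[:, -1].copy()


def pca_condition(points: np.ndarray) -> float:
    """Ratio of the two largest covariance eigenvalues (1 = isotropic)."""
    pts = np.asarray(points, float).reshape(-1, 3)
    centered = pts - pts.mean(axis=0)
    w = np.linalg.eigvalsh(centered.T @ centered / len(pts))
    return float(w[-1] / w[-2]) if w[-2] > 0 else np.inf


def random_sign_flip(directions: np.ndarray, seed: int = 0) -> np.ndarray:
    """Independently flip each direction with probability 1/2.

    PCA axes are sign-ambiguous; forcing about half to point each way gives
    mean shift two balanced antipodal clusters to find.
    """
    dirs = np.asarray(directions, float).reshape(-1, 3)
    if len(dirs) == 0:
        return dirs.copy()
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=len(dirs))
    return dirs * signs[:, None]


def meanshift_sphere(
    directions: np.ndarray,
    bandwidth: float = 0.3,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> np.ndarray:
    """Mode-seeking on the unit sphere with a Gaussian angular kernel.

    Every input direction is iterated as a start point: the mode estimate is
    replaced by the kernel-weighted spherical mean of all directions until it
    moves less than ``tol`` radians.  Modes closer than ``bandwidth / 2`` are
    merged (largest basin wins).  Returns the distinct mode centres.
    """
    dirs = np.asarray(directions, float).reshape(-1, 3)
    if len(dirs) < 1:
        raise ValueError("need at least one direction")
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    modes = np.empty_like(dirs)
    for i, start in enumerate(dirs):
        m = start
        for _ in range(max_iter):
            ang = np.arccos(np.clip(dirs @ m, -1.0, 1.0))
            w = np.exp(-0.5 * (ang / bandwidth) ** 2)
            s = w @ dirs
            norm = np.linalg.norm(s)
            if norm < 1e-12:  # perfectly balanced antipodes; stay put
                break
            m_new = s / norm
            step = np.arccos(np.clip(m @ m_new, -1.0, 1.0))
            m = m_new
            if step < tol:
                break
        else:
            raise StereogoldError(f"spherical mean shift did not converge in {max_iter} iterations")
        modes[i] = m

    # merge modes within bandwidth/2, biggest basin first
    centers: list[np.ndarray] = []
    counts: list[int] = []
    for m in modes:
        for j, c in enumerate(centers):
            if np.arccos(np.clip(m @ c, -1.0, 1.0)) < bandwidth / 2:
                counts[j] += 1
                break
        else:
            centers.append(m)
            counts.append(1)
    order = np.argsort(counts)[::-1]
    return np.array([centers[j] for j in order])


def determine_upward(
    borders: dict[int, np.ndarray],
    candidates: np.ndarray,
    extremity: str = "min",
    tie_tol: float = 1e-9,
) -> np.ndarray:
    """Pick the candidate direction under which tower bases are coplanar.

    For each candidate ``u`` the minimum projection ``min_p <p, u>`` of every
    tower is taken; the candidate with the smallest standard deviation of
    these per-tower extremities across towers is "up" — tower *bases* sit on a
    common plate, tips do not.  ``extremity='max'`` scores per-tower maxima
    instead (the alternative reading of the rule).  Ties go to the candidate
    with the larger mean per-tower maximum projection (towers extend upward),
    then lexicographic order.
    """
    towers = [np.asarray(p, float).reshape(-1, 3) for p in borders.values() if len(p)]
    if len(towers) < 2:
        raise StereogoldError("need at least two towers to determine the upward direction")
    cands = np.asarray(candidates, float).reshape(-1, 3)

    def score(u: np.ndarray) -> tuple[float, float]:
        proj = [pts @ u for pts in towers]
        ext = [p.min() if extremity == "min" else p.max() for p in proj]
        return float(np.std(ext)), float(np.mean([p.max() for p in proj]))

    scored = [(*score(u), u) for u in cands]
    best_std = min(s[0] for s in scored)
    tied = [s for s in scored if s[0] <= best_std + tie_tol]
    if len(tied) > 1:
        best_reach = max(s[1] for s in tied)
        tied = [s for s in tied if s[1] >= best_reach - tie_tol]
        if len(tied) > 1:
            tied.sort(key=lambda s: tuple(s[2]), reverse=True)
    return _unit(tied[0][2])


def refine_upward(directions: np.ndarray, upward: np.ndarray) -> np.ndarray:
    """Spherical mean of all principal directions, sign-corrected to the
    selected upward's hemisphere.

    The mean-shift mode is a kernel mean over whichever axes the random sign
    flips put in its cluster, so it carries flip-subset noise; once the
    up/down choice is made, every tower's axis is evidence and the flip seed
    should not matter.  Averaging all n sign-corrected axes removes that
    noise and shrinks the tilt-jitter error by ~1/sqrt(n).
    """
    dirs = np.asarray(directions, float).reshape(-1, 3)
    if len(dirs) == 0:
        return _unit(upward)
    u = _unit(upward)
    corrected = dirs * np.sign(dirs @ u)[:, None]
    return _unit(corrected.sum(axis=0))


# ---------------------------------------------------------------------------
# rigid transforms


def rodrigues_rotate(points: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate points about a unit axis through the origin by ``angle``:
    ``v' = v cos(t) + (k x v) sin(t) + k <k, v> (1 - cos(t))``."""
    k = np.asarray(axis, float)
    if np.linalg.norm(k) < 1e-12:
        raise ValueError("rotation axis must be nonzero")
    k = k / np.linalg.norm(k)
    v = np.asarray(points, float).reshape(-1, 3)
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(k, v) * s + np.outer(v @ k, k) * (1.0 - c)


def _rotation_to_z(upward: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis/angle mapping ``upward`` onto +z (x-axis half-turn if antiparallel)."""
    u = _unit(upward)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(u, z)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        if u @ z > 0:
            return z, 0.0
        return np.array([1.0, 0.0, 0.0]), np.pi
    return axis / n, float(np.arctan2(n, u @ z))


def normalize_frame(
    borders: dict[int, np.ndarray],
    beads: BeadSet,
    upward: np.ndarray,
    used_ids: set[int] | None = None,
) -> tuple[dict[int, np.ndarray], BeadSet, BundleFrame]:
    """Rigidly move the scene so up = (0, 0, 1) and the base plane is z = 0.

    One rotation (about the pooled centre of mass of all tower border points)
    is applied to towers and beads alike, then a global translation puts the
    minimum z over *used* towers' points at exactly 0.
    """
    all_pts = np.vstack([p for p in borders.values() if len(p)])
    com = all_pts.mean(axis=0)
    axis, angle = _rotation_to_z(upward)

    def xform(pts: np.ndarray) -> np.ndarray:
        if len(pts) == 0:
            return pts.copy()
        return rodrigues_rotate(pts - com, axis, angle) + com

    new_borders = {tid: xform(p) for tid, p in borders.items()}
    new_centroids = xform(beads.centroids)

    if used_ids is None:
        used_ids = set(new_borders)
    z_floor = min(
        p[:, 2].min() for tid, p in new_borders.items() if tid in used_ids and len(p)
    )
    shift = np.array([0.0, 0.0, z_floor])
    new_borders = {tid: p - shift for tid, p in new_borders.items()}
    new_centroids = new_centroids - shift

    frame = BundleFrame(upward=np.array([0.0, 0.0, 1.0]))
    return new_borders, BeadSet(new_centroids, beads.assigned_tower.copy(),
                                beads.excluded.copy()), frame


# ---------------------------------------------------------------------------
# azimuths


def compute_column_azimuths(
    centroids: dict[int, np.ndarray], link: LinkTable
) -> dict[int, np.ndarray]:
    """Per-tower "north" vectors from the link table, in the upright frame.

    Each link-table column is a set of towers spanning the rows; a total-
    least-squares XY line through their centroids, oriented from the highest-
    row (shortest) end toward the lowest-row end, is the column's
    mechanotransduction direction.  North is its negation and is shared by
    every tower in the column.  Columns with fewer than two located towers
    get no azimuth (their towers are later dropped from pooling).
    """
    norths: dict[int, np.ndarray] = {}
    for c in range(link.n_columns):
        members = [(r + 1, int(tid)) for r, tid in enumerate(link.ids[:, c])
                   if tid != 0 and int(tid) in centroids]
        if len(members) < 2:
            continue
        xy = np.array([centroids[tid][:2] for _, tid in members])
        centered = xy - xy.mean(axis=0)
        cov = centered.T @ centered
        w, v = np.linalg.eigh(cov)
        if w[-1] < 1e-18:
            raise StereogoldError(
                f"link column {c}: tower centroids coincide in XY; azimuth undefined"
            )
        direction = v[:, -1]
        rows = np.array([r for r, _ in members])
        t = centered @ direction
        # orient from the highest-numbered (shortest) row toward row 1
        lo_end = t[np.argmin(rows)]   # row closest to the kinocilium side
        hi_end = t[np.argmax(rows)]
        if lo_end == hi_end:
            raise StereogoldError(f"link column {c}: degenerate row ordering along the fit line")
        if lo_end < hi_end:
            direction = -direction
        mech = np.array([direction[0], direction[1], 0.0])
        north = _unit(-mech)
        for _, tid in members:
            norths[tid] = north
    if not norths:
        raise ValidationError("no link column has two locatable towers; azimuths undefined")
    return norths


def azimuth_align_tower(
    points: np.ndarray, bead_points: np.ndarray, north: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate a tower (and its beads) about its own vertical axis so that its
    north maps to (0, 1, 0).  z coordinates are untouched."""
    n = np.asarray(north, float)
    if abs(n[2]) > 1e-9:
        raise ValueError("north must lie in the XY plane")
    nxy = _unit(n[:2])
    phi = np.arctan2(nxy[0], nxy[1])  # CCW rotation taking north to +y
    c, s = np.cos(phi), np.sin(phi)
    rot = np.array([[c, -s], [s, c]])
    pts = np.asarray(points, float).reshape(-1, 3)
    center = pts[:, :2].mean(axis=0)

    def apply(q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, float).reshape(-1, 3)
        out = q.copy()
        out[:, :2] = (q[:, :2] - center) @ rot.T + center
        return out

    return apply(pts), apply(bead_points)


# ---------------------------------------------------------------------------
# measurement and registration


def tower_height_radius(points: np.ndarray) -> tuple[float, float]:
    """Height = z extent of border points; radius = mean XY distance from the
    vertical axis through the XY centroid."""
    pts = np.asarray(points, float).reshape(-1, 3)
    if len(pts) < 3:
        raise StereogoldError(f"need >= 3 border points to estimate height/radius, got {len(pts)}")
    height = float(pts[:, 2].max() - pts[:, 2].min())
    center = pts[:, :2].mean(axis=0)
    radius = float(np.linalg.norm(pts[:, :2] - center, axis=1).mean())
    return height, radius


def register_tower_to_template(
    points: np.ndarray,
    bead_points: np.ndarray,
    template: RowTemplate,
    height: float | None = None,
    radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Affine-map a tower onto its row's template cylinder.

    The tower's base axis point (XY centroid at min z) goes to the origin,
    z is scaled by ``avg_height / height`` and XY radially by
    ``avg_radius / radius``; its beads get the same map.
    """
    pts = np.asarray(points, float).reshape(-1, 3)
    if height is None or radius is None:
        height, radius = tower_height_radius(pts)
    if height <= 0 or radius <= 0:
        raise StereogoldError(
            f"cannot register tower with height={height:.3g}, radius={radius:.3g}"
        )
    center = pts[:, :2].mean(axis=0)
    z0 = pts[:, 2].min()
    sz = template.avg_height / height
    sr = template.avg_radius / radius

    def apply(q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, float).reshape(-1, 3)
        out = np.empty_like(q)
        out[:, :2] = (q[:, :2] - center) * sr
        out[:, 2] = (q[:, 2] - z0) * sz
        return out

    return apply(pts), apply(bead_points)


def convex_hull(points: np.ndarray) -> Hull:
    """Convex hull with triangular facets; coplanar input falls back to a
    planar hull (fan-triangulated) with a warning."""
    pts = np.asarray(points, float).reshape(-1, 3)
    if len(pts) < 4:
        raise StereogoldError(f"need >= 4 points for a 3D hull, got {len(pts)}")
    try:
        hull = ConvexHull(pts)
    except QhullError:
        warnings.warn("input is (near-)coplanar; returning a planar hull", stacklevel=2)
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        plane2d = centered @ vt[:2].T
        h2 = ConvexHull(plane2d)
        verts = pts[h2.vertices]
        fan = np.array([[0, i, i + 1] for i in range(1, len(verts) - 1)], dtype=int)
        return Hull(vertices=verts, facets=fan, planar=True)
    vert_index = {v: i for i, v in enumerate(hull.vertices)}
    facets = np.array([[vert_index[s] for s in simplex] for simplex in hull.simplices])
    return Hull(vertices=pts[hull.vertices], facets=facets, planar=False)
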