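"""Per-cell analysis, result display and multi-cell aggregation.

``analyze_cell`` runs the full registration chain on one cell folder
(``Towers.am``, ``GoldParticles.am``, ``LinkTable.csv``, ``TowerUsage.csv``):

  load + resize -> border sampling + bead centroids -> PCA + random sign
  flips -> spherical mean shift -> upward selection -> bead association ->
  upright normalization -> column azimuths -> per-tower azimuth transforms
  (usage-aware) -> row averages -> template registration -> convex hulls

and writes a ``Tables`` folder (per-row bead coordinates, hull points, tower
heights/radii, row averages), a ``Figures`` folder, and a provenance record
(config, seed, input digests).  ``display_results`` regenerates figures from
``Tables`` alone; ``aggregate_results`` pools several analyzed cells.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry, quantification
from .association import Assignment, associate_dt, associate_nn
from .config import AnalysisConfig, PlotConfig
from .errors import StereogoldError
from .geometry import BeadSet, RowTemplate, Tower
from .io_formats import (read_label_volume, read_link_table,
                         read_results_tables, read_tower_usage,
                         write_results_tables)
from .preprocessing import resize_volume

__all__ = ["CellResults", "analyze_cell", "display_results", "aggregate_results"]

logger = logging.getLogger("stereogold")

INPUT_FILES = ("Towers.am", "GoldParticles.am", "LinkTable.csv", "TowerUsage.csv")


@dataclass
class CellResults:
    cell_dir: Path
    tables_dir: Path
    figures_dir: Path
    towers: dict[int, Tower]
    beads: BeadSet
    assignment: Assignment
    upward: np.ndarray
    templates: dict[int, RowTemplate]
    registered: dict[int, dict]          # row -> beads/hull/height_radius arrays
    provenance: dict = field(default_factory=dict)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze_cell(
    cell_dir,
    config: AnalysisConfig | None = None,
    plot: PlotConfig | None = None,
    voxel_size_nm=None,
    make_figures: bool = True,
) -> CellResults:
    """Run the full per-cell analysis; see the module docstring for steps."""
    config = config or AnalysisConfig()
    plot = plot or PlotConfig()
    cell_dir = Path(cell_dir)
    for name in INPUT_FILES:
        if not (cell_dir / name).exists():
            raise StereogoldError(f"missing input file {name!r} in {cell_dir}")

    # -- load + resize -----------------------------------------------------
    tower_vol = read_label_volume(cell_dir / "Towers.am", voxel_size_nm)
    gold_vol = read_label_volume(cell_dir / "GoldParticles.am", voxel_size_nm)
    link = read_link_table(cell_dir / "LinkTable.csv")
    usage = read_tower_usage(cell_dir / "TowerUsage.csv", link)
    link.validate_against(tower_vol)
    if not ((usage.flags == 1) & (link.ids != 0)).any():
        raise StereogoldError("no towers included: usage table excludes everything")
    if config.resize_factor < 1.0:
        tower_vol = resize_volume(tower_vol, config.resize_factor)
        gold_vol = resize_volume(gold_vol, config.resize_factor)

    used_ids = {int(t) for t in link.tower_ids() if usage.is_used(link, int(t))}

    # -- extraction --------------------------------------------------------
    borders = geometry.sample_tower_borders(
        tower_vol, config.border_sampling_factor, seed=config.rng_seed)
    beads = geometry.extract_bead_centroids(gold_vol)
    logger.info("cell %s: %d towers, %d beads", cell_dir.name, len(borders), len(beads))

    # -- orientation -------------------------------------------------------
    dir_ids = [tid for tid, p in borders.items() if len(p) >= 3]
    dirs = np.array([geometry.principal_direction(borders[tid]) for tid in dir_ids])
    flipped = geometry.random_sign_flip(dirs, seed=config.rng_seed + 1)
    centers = geometry.meanshift_sphere(flipped, config.meanshift_bandwidth_rad)
    candidates = centers[:2] if len(centers) >= 2 else np.array([centers[0], -centers[0]])
    upward = geometry.determine_upward(borders, candidates, extremity=config.extremity)
    upward = geometry.refine_upward(dirs, upward)

    # -- association (pre-normalization frame; distances are rigid anyway) --
    if config.association_method == "NN":
        assignment = associate_nn(beads, borders, k=config.n_nearest_neighbors,
                                  min_dist_thr_um=config.min_dist_thr_um)
    else:
        assignment = associate_dt(beads, tower_vol, min_dist_thr_um=config.min_dist_thr_um)
    beads = assignment.apply_to(beads)
    logger.info("associated %d/%d beads (%s)", assignment.n_assigned, len(beads),
                assignment.method)

    # -- upright normalization --------------------------------------------
    borders, beads, frame = geometry.normalize_frame(borders, beads, upward,
                                                     used_ids=used_ids)

    # -- azimuths ----------------------------------------------------------
    centroids = {tid: p.mean(axis=0) for tid, p in borders.items() if len(p)}
    norths = geometry.compute_column_azimuths(centroids, link)
    frame.per_tower_north = norths

    towers: dict[int, Tower] = {}
    aligned_borders: dict[int, np.ndarray] = {}
    aligned_beads: dict[int, np.ndarray] = {}
    for tid in sorted(borders):
        pts = borders[tid]
        in_link = tid in {int(t) for t in link.tower_ids()}
        t = Tower(id=tid,
                  row=link.row_of(tid) if in_link else 0,
                  column=link.column_of(tid) if in_link else -1,
                  border_points=pts,
                  used=tid in used_ids)
        if len(pts) >= 3:
            t.principal_direction = geometry.principal_direction(pts)
            t.centroid = pts.mean(axis=0)
        if tid in norths and len(pts) >= 3:
            t.north = norths[tid]
            bead_sel = beads.centroids[(beads.assigned_tower == tid) & ~beads.excluded]
            apts, abeads = geometry.azimuth_align_tower(pts, bead_sel, norths[tid])
            t.height, t.radius = geometry.tower_height_radius(apts)
            aligned_borders[tid] = apts
            aligned_beads[tid] = abeads
        else:
            t.used = False  # no azimuth: tower drops out of pooling
        towers[tid] = t

    # -- row averages + template registration ------------------------------
    templates: dict[int, RowTemplate] = {}
    for row in sorted({t.row for t in towers.values() if t.used and t.row > 0}):
        members = [t for t in towers.values() if t.used and t.row == row
                   and t.id in aligned_borders]
        if not members:
            continue
        templates[row] = RowTemplate(
            row=row,
            avg_height=float(np.mean([t.height for t in members])),
            avg_radius=float(np.mean([t.radius for t in members])),
            n_towers=len(members),
        )

    registered: dict[int, dict] = {}
    for row, template in templates.items():
        pooled_pts, pooled_beads, hr = [], [], []
        for t in sorted((t for t in towers.values() if t.used and t.row == row),
                        key=lambda t: t.id):
            rpts, rbeads = geometry.register_tower_to_template(
                aligned_borders[t.id], aligned_beads[t.id], template,
                height=t.height, radius=t.radius)
            pooled_pts.append(rpts)
            pooled_beads.append(rbeads)
            hr.append((t.id, t.height, t.radius))
        pts = np.vstack(pooled_pts)
        bd = np.vstack(pooled_beads) if pooled_beads else np.zeros((0, 3))
        hull = geometry.convex_hull(pts)
        registered[row] = {
            "beads": bd,
            "hull": hull.vertices,
            "height_radius": np.array(hr, float),
            "points": pts,
        }
        logger.info("row %d: %d towers, %d beads pooled", row, len(hr), len(bd))

    # -- outputs -----------------------------------------------------------
    tables_dir = cell_dir / "Tables"
    figures_dir = cell_dir / "Figures"
    write_results_tables(
        {r: {k: v for k, v in res.items() if k != "points"}
         for r, res in registered.items()},
        tables_dir,
    )
    provenance = {
        "config": config.to_dict(),
        "plot": {"n_az_bins": plot.n_az_bins, "n_ht_bins": plot.n_ht_bins},
        "inputs": {name: _digest(cell_dir / name) for name in INPUT_FILES},
        "upward": [float(v) for v in upward],
        "n_beads": int(len(beads)),
        "n_beads_assigned": int(assignment.n_assigned),
    }
    with open(tables_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)

    if make_figures:
        figures_dir.mkdir(exist_ok=True)
        from . import plotting

        rows_of = {t.id: t.row for t in towers.values()}
        gray = {t.id for t in towers.values() if not t.used}
        plotting.save_bundle_scene(borders, beads.centroids,
                                   figures_dir / "f01_borders_beads.png", plot,
                                   rows=rows_of, title="sampled borders + bead centroids")
        plotting.save_directions(flipped, centers,
                                 figures_dir / "f02_principal_directions.png", plot)
        plotting.save_bundle_scene(borders, beads.centroids[~beads.excluded],
                                   figures_dir / "f03_normalized.png", plot,
                                   rows=rows_of, gray_ids=gray,
                                   title="upright frame (used towers colored)")
        plotting.save_top_view(borders, norths, figures_dir / "f04_azimuths.png", plot)
        reg_borders = {row: res["points"] for row, res in registered.items()}
        reg_beads = (np.vstack([res["beads"] for res in registered.values()])
                     if registered else np.zeros((0, 3)))
        plotting.save_bundle_scene(reg_borders, reg_beads,
                                   figures_dir / "f05_registered_rows.png", plot,
                                   rows={r: r for r in registered},
                                   title="rows registered to templates")

    return CellResults(cell_dir=cell_dir, tables_dir=tables_dir,
                       figures_dir=figures_dir, towers=towers, beads=beads,
                       assignment=assignment, upward=upward, templates=templates,
                       registered=registered, provenance=provenance)


def display_results(cell_dir, plot: PlotConfig | None = None) -> list[Path]:
    """Regenerate per-cell figures from the ``Tables`` folder alone.

    Deterministic: two runs over the same tables produce byte-identical
    files.  Raises if the cell has not been analyzed.
    """
    plot = plot or PlotConfig()
    cell_dir = Path(cell_dir)
    results = read_results_tables(cell_dir / "Tables")
    figures_dir = cell_dir / "Figures"
    figures_dir.mkdir(exist_ok=True)
    from . import plotting

    written = []
    for row, res in sorted(results.items()):
        p = figures_dir / f"display_row{row}.png"
        plotting.save_bundle_scene({row: res["hull"]}, res["beads"], p, plot,
                                   rows={row: row},
                                   title=f"row {row}: registered beads on hull points")
        written.append(p)
    return written


def aggregate_results(
    parent_dir,
    config: AnalysisConfig | None = None,
    plot: PlotConfig | None = None,
    make_figures: bool = True,
) -> dict[int, quantification.AggregateRow]:
    """Pool every analyzed cell subfolder under ``parent_dir``.

    Outputs (combined tables, histograms, densities, figures) go to
    ``parent_dir / 'Aggregated'``.  Idempotent: re-running overwrites with
    identical content.
    """
    parent_dir = Path(parent_dir)
    cell_dirs = [d for d in sorted(parent_dir.iterdir())
                 if d.is_dir() and (d / "Tables").is_dir()]
    if not cell_dirs:
        raise StereogoldError(f"no analyzed cell subfolders under {parent_dir}")
    return quantification.aggregate_cells(
        cell_dirs, out_dir=parent_dir / "Aggregated", config=config, plot=plot,
        make_figures=make_figures)
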