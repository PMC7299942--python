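"""Bead-count histograms and surface-density maps on the template cylinder.

After registration every bead of a row lives on one template cylinder of the
row's average height H and radius r.  Beads are binned over height segments
and azimuth sectors; sector 1 is centred on "north" (0, 1, 0) and sectors
count counterclockwise as viewed from the top.  The last height bin always
collects beads above the tip (z > H); for density maps it is folded into the
top shaft segment, and counts are normalized by segment surface area
(pi * diameter * segment height / n_sectors) and by the number of cilia
pooled, giving beads per um^2 per cilium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import AnalysisConfig, PlotConfig
from .errors import StereogoldError
from .geometry import RowTemplate
from .io_formats import read_results_tables, write_results_tables

__all__ = [
    "CylinderHistogram",
    "DensityMap",
    "cylinder_histogram",
    "fold_above_tip",
    "segment_count",
    "labeling_density",
    "aggregate_cells",
    "AggregateRow",
]


@dataclass
class CylinderHistogram:
    """Bead counts over (height bin x azimuth sector).

    Unless folded, the last height bin is the above-tip bin; the sum of
    ``counts`` is always the number of beads binned.
    """

    counts: np.ndarray          # (n_ht_bins, n_az_bins) int
    row_id: int
    H: float                    # template height, um
    sector_edges_deg: np.ndarray
    has_above_tip: bool = True
    n_clamped: int = 0          # beads with z < 0, clamped into segment 1

    @property
    def n_ht_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_az_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class DensityMap:
    """Surface-normalized labeling density, beads per um^2 per cilium."""

    density: np.ndarray         # (n_segments, n_az_bins)
    segment_height: float       # um
    diameter: float             # um
    n_cilia: int
    row_id: int

    @property
    def segment_area(self) -> float:
        return float(np.pi * self.diameter * self.segment_height / self.density.shape[1])


def _sector_index(x: np.ndarray, y: np.ndarray, n_az: int, origin: str) -> np.ndarray:
    """0-based sector of each bead: angle from north (+y), counterclockwise
    viewed from the top.  On-axis beads go to sector 0 deterministically."""
    alpha = np.mod(np.arctan2(y, x) - np.pi / 2.0, 2.0 * np.pi)
    width = 2.0 * np.pi / n_az
    if origin == "centered":
        s = np.floor(np.mod(alpha + width / 2.0, 2.0 * np.pi) / width).astype(int)
    elif origin == "edge":
        s = np.floor(alpha / width).astype(int)
    else:
        raise ValueError(f"unknown sector origin {origin!r}")
    s = np.clip(s, 0, n_az - 1)
    s[(x == 0) & (y == 0)] = 0
    return s


def cylinder_histogram(
    bead_points: np.ndarray,
    H: float,
    n_ht_bins: int = 5,
    n_az_bins: int = 4,
    row_id: int = 0,
    sector_origin: str = "centered",
) -> CylinderHistogram:
    """Bin registered beads into (height segment, azimuth sector) cells.

    Bins 1..n_ht_bins-1 split [0, H] into equal segments; bin n_ht_bins takes
    z > H (above the tip).  Beads with z < 0 are clamped into segment 1 and
    counted in ``n_clamped``.
    """
    if n_ht_bins < 2:
        raise ValueError("n_ht_bins must be >= 2 (incl. the above-tip bin)")
    if n_az_bins < 1:
        raise ValueError("n_az_bins must be >= 1")
    if H <= 0:
        raise ValueError("template height must be positive")
    pts = np.asarray(bead_points, float).reshape(-1, 3)
    counts = np.zeros((n_ht_bins, n_az_bins), dtype=int)
    half = 180.0 / n_az_bins
    edges = (np.arange(n_az_bins + 1) * 2 * half - (half if sector_origin == "centered" else 0.0))
    if len(pts) == 0:
        return CylinderHistogram(counts, row_id, H, edges, True, 0)

    z = pts[:, 2]
    n_clamped = int((z < 0).sum())
    n_shaft = n_ht_bins - 1
    seg = np.floor(z / (H / n_shaft)).astype(int)
    seg = np.clip(seg, 0, n_shaft - 1)       # z == H stays in the top shaft bin
    seg[z > H] = n_ht_bins - 1               # strictly above the tip
    sec = _sector_index(pts[:, 0], pts[:, 1], n_az_bins, sector_origin)
    np.add.at(counts, (seg, sec), 1)
    return CylinderHistogram(counts, row_id, H, edges, True, n_clamped)


def fold_above_tip(hist: CylinderHistogram) -> CylinderHistogram:
    """Add the above-tip counts, sector-wise, into the top shaft segment."""
    if not hist.has_above_tip:
        raise ValueError("histogram is already folded")
    if hist.n_ht_bins < 2:
        raise ValueError("need at least two height bins to fold")
    counts = hist.counts[:-1].copy()
    counts[-1] += hist.counts[-1]
    return CylinderHistogram(counts, hist.row_id, hist.H, hist.sector_edges_deg.copy(),
                             has_above_tip=False, n_clamped=hist.n_clamped)


def segment_count(H: float, target_height_um: float = 0.2) -> int:
    """Number of ~200-nm shaft segments for a tower of height ``H`` —
    ``round(H / target)``, at least 1 (round half away from zero)."""
    if H <= 0:
        raise ValueError("height must be positive")
    return max(1, int(np.floor(H / target_height_um + 0.5)))


def labeling_density(hist: CylinderHistogram, template: RowTemplate) -> DensityMap:
    """Beads per um^2 per cilium from a folded histogram.

    Each cell's area is ``pi * diameter * (H / n_segments) / n_az_bins``;
    the count is divided by that area and by the number of cilia pooled.
    """
    if hist.has_above_tip:
        raise ValueError("fold the above-tip bin before computing densities")
    n_segments = hist.n_ht_bins
    diameter = 2.0 * template.avg_radius
    seg_h = hist.H / n_segments
    area = np.pi * diameter * seg_h / hist.n_az_bins
    if area <= 0:
        raise StereogoldError("zero segment area: template radius or height is zero")
    if template.n_towers < 1:
        raise StereogoldError("template has no towers")
    density = hist.counts / (area * template.n_towers)
    return DensityMap(density=density, segment_height=seg_h, diameter=diameter,
                      n_cilia=template.n_towers, row_id=hist.row_id)


# ---------------------------------------------------------------------------
# multi-cell aggregation


@dataclass
class AggregateRow:
    """Pooled per-row data across cells, plus its histograms."""

    row: int
    beads: np.ndarray
    hull_points: np.ndarray
    height_radius: np.ndarray     # (n_towers, 3): id, height, radius
    template: RowTemplate
    histogram: CylinderHistogram = None
    folded: CylinderHistogram = None
    density: DensityMap = None


def aggregate_cells(
    cell_dirs: list,
    out_dir=None,
    config: AnalysisConfig | None = None,
    plot: PlotConfig | None = None,
    make_figures: bool = True,
) -> dict[int, AggregateRow]:
    """Pool per-row tables of several analyzed cells and recompute histograms.

    Cells missing a ``Tables`` folder are skipped with a warning; with zero
    usable cells this is an error.  Cell order does not affect the result
    (directories are pooled in sorted order).
    """
    import warnings

    config = config or AnalysisConfig()
    plot = plot or PlotConfig()
    per_cell = []
    for d in sorted(Path(d) for d in cell_dirs):
        tables = d / "Tables"
        try:
            per_cell.append(read_results_tables(tables))
        except FileNotFoundError:
            warnings.warn(f"{d}: no Tables folder, skipping", stacklevel=2)
    if not per_cell:
        raise StereogoldError("no analyzed cells found to aggregate")

    rows = sorted({r for cell in per_cell for r in cell})
    out: dict[int, AggregateRow] = {}
    for row in rows:
        beads = np.vstack([c[row]["beads"] for c in per_cell if row in c])
        hull_points = np.vstack([c[row]["hull"] for c in per_cell if row in c])
        hr = np.vstack([c[row]["height_radius"] for c in per_cell if row in c])
        if hr.shape[0] == 0:
            continue
        template = RowTemplate(row=row, avg_height=float(hr[:, 1].mean()),
                               avg_radius=float(hr[:, 2].mean()), n_towers=hr.shape[0])
        n_seg = segment_count(template.avg_height, config.segment_height_um)
        hist = cylinder_histogram(
            beads, template.avg_height, n_ht_bins=n_seg + 1, n_az_bins=plot.n_az_bins,
            row_id=row, sector_origin=config.sector_origin,
        )
        folded = fold_above_tip(hist)
        density = labeling_density(folded, template)
        out[row] = AggregateRow(row, beads, hull_points, hr, template, hist, folded, density)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_results_tables(
            {r: {"beads": a.beads, "hull": a.hull_points, "height_radius": a.height_radius}
             for r, a in out.items()},
            out_dir,
        )
        for r, a in out.items():
            np.savetxt(out_dir / f"counts_row{r}.csv", a.histogram.counts,
                       fmt="%d", delimiter=",")
            np.savetxt(out_dir / f"counts_folded_row{r}.csv", a.folded.counts,
                       fmt="%d", delimiter=",")
            np.savetxt(out_dir / f"density_row{r}.csv", a.density.density,
                       fmt="%.9g", delimiter=",")
        if make_figures:
            from . import plotting

            plotting.save_aggregate_figures(out, out_dir, plot)
    return out
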