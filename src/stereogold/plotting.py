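"""Figure generation for the per-cell analysis and the aggregate maps.

Figures reproduce the *content* of the original workflow's plots — sampled
borders with bead centroids, orientation candidates, the normalized top
view, azimuth vectors, registered rows, and the side-view / top-view
bead-density heat maps — not their styling.  All figures are written
through the Agg backend with fixed metadata so repeated runs are
byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .config import PlotConfig  # noqa: E402

_ROW_COLORS = {1: "tab:purple", 2: "tab:blue", 3: "tab:green", 4: "tab:orange"}
_SAVEKW = dict(dpi=110, metadata={"Software": "stereogold"})


def _new3d(plot: PlotConfig):
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    ax.set_facecolor(plot.background_color)
    az, el = plot.view_direction
    ax.view_init(elev=el, azim=az)
    for lab, name in zip("xyz", ("x (um)", "y (um)", "z (um)")):
        getattr(ax, f"set_{lab}label")(name)
    return fig, ax


def save_bundle_scene(
    borders: dict[int, np.ndarray],
    beads: np.ndarray | None,
    path,
    plot: PlotConfig,
    rows: dict[int, int] | None = None,
    gray_ids: set[int] | None = None,
    title: str = "",
) -> None:
    """3D scatter of tower border samples (colored by row, excluded towers
    gray) with bead centroids overlaid."""
    gray_ids = gray_ids or set()
    fig, ax = _new3d(plot)
    for tid, pts in sorted(borders.items()):
        if not len(pts):
            continue
        color = "gray" if tid in gray_ids else _ROW_COLORS.get(
            (rows or {}).get(tid, 0), "lightsteelblue")
        ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], s=plot.tr_marker_size,
                   c=color, depthshade=False)
    if beads is not None and len(beads):
        beads = np.asarray(beads).reshape(-1, 3)
        ax.scatter(beads[:, 0], beads[:, 1], beads[:, 2], marker=plot.gp_marker,
                   s=10 * plot.gp_marker_size, c="yellow", depthshade=False)
    if title:
        ax.set_title(title)
    fig.savefig(path, **_SAVEKW)
    plt.close(fig)


def save_directions(directions: np.ndarray, centers: np.ndarray, path,
                    plot: PlotConfig) -> None:
    """Principal directions (after sign flips) on the unit sphere, with the
    mean-shift cluster centres marked."""
    fig, ax = _new3d(plot)
    d = np.asarray(directions).reshape(-1, 3)
    ax.scatter(d[:, 0], d[:, 1], d[:, 2], s=8, c="tab:red", depthshade=False)
    c = np.asarray(centers).reshape(-1, 3)
    ax.scatter(c[:, 0], c[:, 1], c[:, 2], s=60, marker="s", facecolors="none",
               edgecolors="white" if plot.background_color == "black" else "black")
    ax.set_title("principal directions and mode centres")
    fig.savefig(path, **_SAVEKW)
    plt.close(fig)


def save_top_view(borders: dict[int, np.ndarray], norths: dict[int, np.ndarray],
                  path, plot: PlotConfig) -> None:
    """Top (XY) view with tower IDs and their north vectors."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.set_facecolor(plot.background_color)
    for tid, pts in sorted(borders.items()):
        if not len(pts):
            continue
        ax.plot(pts[:, 0], pts[:, 1], ".", ms=1, color="lightsteelblue")
        cx, cy = pts[:, :2].mean(axis=0)
        ax.annotate(str(tid), (cx, cy), color="red", fontsize=7, ha="center")
        if tid in norths:
            n = norths[tid]
            ax.arrow(cx, cy, 0.25 * n[0], 0.25 * n[1], color="red",
                     head_width=0.03, length_includes_head=True)
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    fig.savefig(path, **_SAVEKW)
    plt.close(fig)


def _heatmap(ax, matrix: np.ndarray, title: str) -> None:
    im = ax.imshow(matrix, origin="lower", aspect="auto", cmap="inferno")
    ax.set_xlabel("sector (CCW from north)")
    ax.set_ylabel("segment (base to tip)")
    ax.set_xticks(range(matrix.shape[1]),
                  [["I", "II", "III", "IV"][i] if matrix.shape[1] == 4 else str(i + 1)
                   for i in range(matrix.shape[1])])
    ax.set_title(title)
    plt.colorbar(im, ax=ax, shrink=0.8)


def save_aggregate_figures(rows: dict, out_dir, plot: PlotConfig) -> list[Path]:
    """Heat maps (side view + polar top view) and the cumulative 3D map."""
    out_dir = Path(out_dir)
    written = []
    for r, agg in sorted(rows.items()):
        fig = plt.figure(figsize=(10, 4))
        ax0 = fig.add_subplot(1, 2, 1)
        _heatmap(ax0, agg.folded.counts, f"row {r}: folded bead counts")
        ax1 = fig.add_subplot(1, 2, 2, projection="polar")
        # concentric rings: outermost = most proximal segment
        n_seg, n_az = agg.folded.counts.shape
        theta = np.linspace(np.pi / 2 - np.pi / n_az, 2 * np.pi + np.pi / 2 - np.pi / n_az,
                            n_az + 1)
        vmax = max(1, agg.folded.counts.max())
        for s in range(n_seg):
            radii_in = n_seg - s - 1
            for a in range(n_az):
                ax1.bar((theta[a] + theta[a + 1]) / 2, 1, width=2 * np.pi / n_az,
                        bottom=radii_in,
                        color=plt.cm.inferno(agg.folded.counts[s, a] / vmax),
                        edgecolor="gray", linewidth=0.3)
        ax1.set_yticks([])
        ax1.set_xticks([])
        ax1.set_title("top view (outer ring = base)")
        p = out_dir / f"histogram_row{r}.png"
        fig.savefig(p, **_SAVEKW)
        plt.close(fig)
        written.append(p)

        fig, ax = _new3d_fig(plot)
        hp = agg.hull_points
        if len(hp):
            ax.scatter(hp[:, 0], hp[:, 1], hp[:, 2], s=plot.tr_marker_size, c="gray",
                       depthshade=False)
        if len(agg.beads):
            ax.scatter(agg.beads[:, 0], agg.beads[:, 1], agg.beads[:, 2],
                       marker=plot.gp_marker, s=10 * plot.gp_marker_size, c="yellow",
                       depthshade=False)
        ax.set_title(f"row {r}: cumulative bead map")
        p = out_dir / f"cumulative_row{r}.png"
        fig.savefig(p, **_SAVEKW)
        plt.close(fig)
        written.append(p)
    return written


def _new3d_fig(plot: PlotConfig):
    return _new3d(plot)
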