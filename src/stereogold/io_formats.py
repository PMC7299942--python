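"""File I/O for every format the pipeline touches.

A cell folder holds four inputs: a label field of segmented towers
(``Towers.am``), a mask of gold beads (``GoldParticles.am``), a 4xN table of
tower IDs by row (``LinkTable.csv``, row 1 = kinocilium, rows 2-4 = tall /
middle / short stereocilia) and its binary inclusion twin
(``TowerUsage.csv``).  Label fields may equivalently be multipage TIFF stacks.
Acquisition metadata (pixel size, milling step) comes from the microscope's
plain-text project log.

TIFF goes through :mod:`tifffile`, tables through :mod:`pandas`; the
AmiraMesh dialect is handled in :mod:`stereogold.amira`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import amira
from .errors import FormatError, ValidationError
from .volumes import ImageStack, LabelVolume

__all__ = [
    "LinkTable",
    "TowerUsage",
    "AcquisitionParams",
    "read_label_volume",
    "write_label_volume",
    "read_image_stack",
    "write_image_stack",
    "read_link_table",
    "read_tower_usage",
    "parse_acquisition_log",
    "write_results_tables",
    "read_results_tables",
]

N_ROWS = 4  # kinocilium + three stereocilia rows


# ---------------------------------------------------------------------------
# link / usage tables


@dataclass
class LinkTable:
    """4xN table of tower IDs; each column is one linked set of towers
    sharing a mechanotransduction direction.  Zeros are placeholders."""

    ids: np.ndarray  # (4, N) int

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        if self.ids.ndim != 2 or self.ids.shape[0] != N_ROWS:
            raise FormatError(f"link table must have exactly {N_ROWS} rows, got shape {self.ids.shape}")
        nz = self.ids[self.ids != 0]
        if nz.size == 0:
            raise ValidationError("no towers linked: link table is all zeros")
        vals, counts = np.unique(nz, return_counts=True)
        dup = vals[counts > 1]
        if dup.size:
            raise ValidationError(f"duplicate tower IDs in link table: {dup.tolist()}")

    @property
    def n_columns(self) -> int:
        return self.ids.shape[1]

    def row_of(self, tower_id: int) -> int:
        """1-based row of a tower ID."""
        r, _ = np.nonzero(self.ids == tower_id)
        if r.size == 0:
            raise KeyError(f"tower {tower_id} not in link table")
        return int(r[0]) + 1

    def column_of(self, tower_id: int) -> int:
        r, c = np.nonzero(self.ids == tower_id)
        if c.size == 0:
            raise KeyError(f"tower {tower_id} not in link table")
        return int(c[0])

    def tower_ids(self) -> np.ndarray:
        """All nonzero tower IDs, sorted."""
        return np.sort(self.ids[self.ids != 0])

    def validate_against(self, vol: LabelVolume) -> None:
        """Every nonzero ID must exist as a label in the tower volume."""
        present = set(int(v) for v in vol.labels())
        missing = [int(t) for t in self.tower_ids() if int(t) not in present]
        if missing:
            raise ValidationError(f"link table IDs absent from tower volume: {missing}")


@dataclass
class TowerUsage:
    """Binary inclusion table, same shape as the link table."""

    flags: np.ndarray  # (4, N) in {0, 1}

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=int)
        if self.flags.ndim != 2 or self.flags.shape[0] != N_ROWS:
            raise FormatError(f"usage table must have exactly {N_ROWS} rows, got shape {self.flags.shape}")
        if not np.isin(self.flags, (0, 1)).all():
            bad = np.unique(self.flags[~np.isin(self.flags, (0, 1))])
            raise ValidationError(f"usage table must be binary, found {bad.tolist()}")

    def is_used(self, link: LinkTable, tower_id: int) -> bool:
        r, c = np.nonzero(link.ids == tower_id)
        if r.size == 0:
            raise KeyError(f"tower {tower_id} not in link table")
        return bool(self.flags[r[0], c[0]])


def _read_headerless_csv(path) -> np.ndarray:
    try:
        df = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    arr = df.to_numpy()
    out = np.empty(arr.shape, dtype=int)
    for idx, cell in np.ndenumerate(arr):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            raise FormatError(f"{path}: empty cell at {idx}")
        try:
            v = float(str(cell).strip())
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell {cell!r} at {idx}") from exc
        if v != int(v):
            raise FormatError(f"{path}: non-integer cell {cell!r} at {idx}")
        out[idx] = int(v)
    return out


def read_link_table(path) -> LinkTable:
    """Read ``LinkTable.csv``: 4 headerless comma-separated integer rows."""
    return LinkTable(_read_headerless_csv(path))


def read_tower_usage(path, link: LinkTable) -> TowerUsage:
    """Read ``TowerUsage.csv`` and validate it against its link table."""
    flags = _read_headerless_csv(path)
    usage = TowerUsage(flags)
    if usage.flags.shape != link.ids.shape:
        raise ValidationError(
            f"usage table shape {usage.flags.shape} != link table shape {link.ids.shape}"
        )
    bad = (usage.flags == 1) & (link.ids == 0)
    if bad.any():
        cells = list(zip(*np.nonzero(bad)))
        raise ValidationError(f"usage flag 1 at placeholder (zero-ID) cells: {cells}")
    return usage


def write_link_table(link: LinkTable, path) -> None:
    np.savetxt(path, link.ids, fmt="%d", delimiter=",")


def write_tower_usage(usage: TowerUsage, path) -> None:
    np.savetxt(path, usage.flags, fmt="%d", delimiter=",")


# ---------------------------------------------------------------------------
# label volumes / image stacks


def read_label_volume(path, voxel_size_nm=None) -> LabelVolume:
    """Read a label field from AmiraMesh ``.am`` or a multipage TIFF.

    ``voxel_size_nm=None`` takes the calibration from the AmiraMesh header;
    TIFF stacks carry none, so they default to unit voxels unless given.
    """
    path = Path(path)
    if amira.is_amira_file(path):
        return amira.read_amira_label_field(path, voxel_size_nm)
    try:
        data = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"{path}: neither AmiraMesh nor readable TIFF ({exc})") from exc
    if data.ndim == 2:
        data = data[None]
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError(f"{path}: TIFF label stack must be integer, got {data.dtype}")
    vs = np.ones(3) if voxel_size_nm is None else np.asarray(voxel_size_nm, float)
    return LabelVolume(data=data.astype(np.int64), voxel_size=vs)


def write_label_volume(vol: LabelVolume, path, format: str = "amira_rle") -> None:
    """Write a label volume as ``amira_rle``, ``amira_raw`` or ``tiff``."""
    if format == "amira_rle":
        amira.write_amira_label_field(vol, path, compress=True)
    elif format == "amira_raw":
        amira.write_amira_label_field(vol, path, compress=False)
    elif format == "tiff":
        data = vol.data
        if data.size and data.max() <= 255:
            data = data.astype(np.uint8)
        else:
            data = data.astype(np.uint16)
        tifffile.imwrite(path, data, photometric="minisblack")
    else:
        raise ValueError(f"unknown format {format!r}; use 'amira_rle', 'amira_raw' or 'tiff'")


def read_image_stack(path, voxel_size_nm=(1.0, 1.0, 1.0)) -> ImageStack:
    """Read an 8-bit multipage TIFF EM stack."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data=data, voxel_size=np.asarray(voxel_size_nm, float))


def write_image_stack(stack: ImageStack, path) -> None:
    tifffile.imwrite(path, np.asarray(stack.data, dtype=np.uint8), photometric="minisblack")


# ---------------------------------------------------------------------------
# acquisition log


@dataclass(frozen=True)
class AcquisitionParams:
    """Voxel calibration extracted from a Slice&View project log.

    ``pixel_size_nm = 1000 * hfw_um / width_px`` — the horizontal field width
    divided by the image width in pixels gives the XY pixel, while the target
    milling thickness gives the Z step.
    """

    hfw_um: float | None
    width_px: int | None
    z_step_nm: float
    pixel_size_nm: float


_FLOAT = r"([0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)"


def _search_float(text: str, key: str) -> float | None:
    m = re.search(rf"{key}\s*[=:]\s*\"?{_FLOAT}", text, flags=re.IGNORECASE)
    return float(m.group(1)) if m else None


def parse_acquisition_log(text: str) -> AcquisitionParams:
    """Extract pixel size and Z step from Slice&View project-log text.

    Accepts ``HFW`` in metres or micrometres (values below 0.01 are taken as
    metres) together with an image width (``ResolutionX``/``Width``), or an
    explicit ``PixelSize`` in metres.  ``targetthickness`` is in metres.
    Pure function: same text always yields the same parameters.
    """
    tt = _search_float(text, "targetthickness")
    if tt is None:
        raise FormatError("acquisition log: missing 'targetthickness' entry")
    z_step_nm = tt * 1e9 if tt < 1e-3 else tt  # metres unless already nm-scale

    hfw = _search_float(text, "HFW")
    width = None
    for key in ("ResolutionX", "ImageWidth", "Width"):
        w = _search_float(text, key)
        if w is not None:
            width = int(w)
            break

    if hfw is not None and width is not None:
        hfw_um = hfw * 1e6 if hfw < 1e-2 else hfw
        pixel_size_nm = 1000.0 * hfw_um / width
        return AcquisitionParams(hfw_um=hfw_um, width_px=width, z_step_nm=z_step_nm,
                                 pixel_size_nm=pixel_size_nm)

    ps = _search_float(text, "PixelSize")
    if ps is not None:
        pixel_size_nm = ps * 1e9 if ps < 1e-3 else ps
        return AcquisitionParams(hfw_um=hfw, width_px=width, z_step_nm=z_step_nm,
                                 pixel_size_nm=pixel_size_nm)
    raise FormatError("acquisition log: need HFW + image width, or an explicit PixelSize")


# ---------------------------------------------------------------------------
# result tables

_FMT = "%.9g"  # fixed formatting keeps repeated runs byte-identical


def _savetxt(path, arr: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(arr), fmt=_FMT, delimiter=",")


def write_results_tables(results: dict[int, dict], out_dir) -> list[Path]:
    """Write per-row aggregate tables to ``out_dir``.

    ``results`` maps row number (1-4) to a dict with keys ``beads`` (n x 3
    bead coordinates), ``hull`` (m x 3 convex-hull vertices) and
    ``height_radius`` (t x 3 array of tower ID, height, radius).  Emits
    ``AgrGPRow{k}.csv``, ``AgrTwrRow{k}.csv``, ``HtRadRow{k}.csv`` per row
    plus one ``AvgHeightAndRadius.csv`` summary (CSV stand-in for the
    original spreadsheet output).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary_rows = []
    for row in sorted(results):
        res = results[row]
        p = out_dir / f"AgrGPRow{row}.csv"
        _savetxt(p, np.asarray(res["beads"], float).reshape(-1, 3))
        written.append(p)
        p = out_dir / f"AgrTwrRow{row}.csv"
        _savetxt(p, np.asarray(res["hull"], float).reshape(-1, 3))
        written.append(p)
        hr = np.asarray(res["height_radius"], float).reshape(-1, 3)
        p = out_dir / f"HtRadRow{row}.csv"
        _savetxt(p, hr)
        written.append(p)
        if hr.shape[0]:
            summary_rows.append((row, hr[:, 1].mean(), hr[:, 2].mean(), hr.shape[0]))
    summary = out_dir / "AvgHeightAndRadius.csv"
    with open(summary, "w") as fh:
        fh.write("row,avg_height_um,avg_radius_um,n_towers\n")
        for row, h, r, n in summary_rows:
            fh.write(f"{row},{h:.9g},{r:.9g},{n}\n")
    written.append(summary)
    return written


def _loadtxt3(path) -> np.ndarray:
    p = Path(path)
    if not p.exists() or p.stat().st_size == 0:
        return np.zeros((0, 3))
    return np.loadtxt(p, delimiter=",", ndmin=2).reshape(-1, 3)


def read_results_tables(tables_dir) -> dict[int, dict]:
    """Read back the tables written by :func:`write_results_tables`."""
    tables_dir = Path(tables_dir)
    if not tables_dir.is_dir():
        raise FileNotFoundError(f"no Tables directory at {tables_dir}")
    results: dict[int, dict] = {}
    for p in sorted(tables_dir.glob("AgrGPRow*.csv")):
        row = int(re.search(r"AgrGPRow(\d+)", p.name).group(1))
        entry: dict = {"beads": _loadtxt3(p)}
        entry["hull"] = _loadtxt3(tables_dir / f"AgrTwrRow{row}.csv")
        entry["height_radius"] = _loadtxt3(tables_dir / f"HtRadRow{row}.csv")
        results[row] = entry
    if not results:
        raise FileNotFoundError(f"no per-row tables under {tables_dir}")
    return results
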