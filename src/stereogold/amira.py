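"""Reader/writer for AmiraMesh label fields (the ``.am`` files Amira emits
when a segmentation LabelField is saved as "Amira RLE").

Only the dialect produced by that export path is supported: a uniform
``Lattice`` of ``byte`` labels with either a raw or ``HxByteRLE``-encoded data
section.  Anything else (multiple data sections, non-byte primitives,
rectilinear coordinates) is rejected loudly rather than half-read.

The byte-RLE scheme is the classic Amira one: each run starts with a control
byte ``c``.  If the high bit is set, the next ``c & 0x7f`` bytes are copied
literally; otherwise the single following byte is repeated ``c`` times.  Runs
never exceed 127 bytes.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .errors import FormatError
from .volumes import LabelVolume

__all__ = [
    "read_amira_label_field",
    "write_amira_label_field",
    "rle_encode",
    "rle_decode",
    "is_amira_file",
]

_MAGIC = b"# AmiraMesh"
_MAX_RUN = 127


def rle_encode(raw: bytes) -> bytes:
    """Encode ``raw`` with Amira byte-RLE."""
    data = np.frombuffer(raw, dtype=np.uint8)
    out = bytearray()
    n = len(data)
    i = 0
    while i < n:
        # length of the repeat run starting at i
        j = i
        while j < n and j - i < _MAX_RUN and data[j] == data[i]:
            j += 1
        run = j - i
        if run >= 3:
            out.append(run)
            out.append(int(data[i]))
            i = j
            continue
        # literal run: extend until the next >=3 repeat or the cap
        j = i
        while j < n and j - i < _MAX_RUN:
            if j + 2 < n and data[j] == data[j + 1] == data[j + 2]:
                break
            j += 1
        out.append(0x80 | (j - i))
        out.extend(data[i:j].tobytes())
        i = j
    return bytes(out)


def rle_decode(encoded: bytes, expected_size: int) -> bytes:
    """Decode Amira byte-RLE, checking the decoded length against the lattice."""
    out = bytearray()
    i = 0
    n = len(encoded)
    while i < n:
        c = encoded[i]
        i += 1
        if c == 0:
            raise FormatError("corrupt RLE stream: zero control byte")
        if c & 0x80:
            count = c & 0x7F
            if i + count > n:
                raise FormatError("corrupt RLE stream: literal run past end of data")
            out.extend(encoded[i : i + count])
            i += count
        else:
            if i >= n:
                raise FormatError("corrupt RLE stream: repeat run missing value byte")
            out.extend(bytes([encoded[i]]) * c)
            i += 1
        if len(out) > expected_size:
            raise FormatError(
                f"corrupt RLE stream: decoded {len(out)} bytes, lattice holds {expected_size}"
            )
    if len(out) != expected_size:
        raise FormatError(
            f"corrupt RLE stream: decoded {len(out)} bytes, lattice holds {expected_size}"
        )
    return bytes(out)


def is_amira_file(path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(len(_MAGIC)) == _MAGIC


def read_amira_label_field(path, voxel_size_nm=None) -> LabelVolume:
    """Read an AmiraMesh byte label field into a :class:`LabelVolume`.

    With ``voxel_size_nm=None`` the voxel size is derived from the header's
    ``BoundingBox`` (interpreted in um, Amira's convention for EM exports);
    pass an explicit ``(x, y, z)`` triple in nm to override — files exported
    from uncalibrated stacks often carry placeholder extents.
    """
    blob = Path(path).read_bytes()
    if not blob.startswith(_MAGIC):
        raise FormatError(f"{path}: not an AmiraMesh file (bad magic)")

    marker = b"\n@1"
    pos = blob.find(marker)
    if pos < 0:
        raise FormatError(f"{path}: no @1 data section")
    header = blob[:pos].decode("ascii", errors="replace")
    # data begins on the line after "@1"
    data_start = blob.index(b"\n", pos + 1) + 1
    body = blob[data_start:]

    m = re.search(r"define\s+Lattice\s+(\d+)\s+(\d+)\s+(\d+)", header)
    if m is None:
        raise FormatError(f"{path}: missing 'define Lattice' declaration")
    nx, ny, nz = (int(g) for g in m.groups())

    m = re.search(r"Lattice\s*\{\s*(\w+)\s+\w+\s*\}\s*@1(?:\(([^,)]+),(\d+)\))?", header)
    if m is None:
        raise FormatError(f"{path}: missing Lattice data declaration")
    primitive, codec, enc_len = m.group(1), m.group(2), m.group(3)
    if primitive.lower() != "byte":
        raise FormatError(f"{path}: only byte lattices are supported, got '{primitive}'")

    size = nx * ny * nz
    if codec is None:
        if len(body) < size:
            raise FormatError(f"{path}: raw data section too short ({len(body)} < {size})")
        raw = bytes(body[:size])
    elif codec == "HxByteRLE":
        enc_len = int(enc_len)
        if len(body) < enc_len:
            raise FormatError(f"{path}: RLE stream truncated ({len(body)} < {enc_len})")
        raw = rle_decode(bytes(body[:enc_len]), size)
    else:
        raise FormatError(f"{path}: unsupported data codec '{codec}'")

    if voxel_size_nm is None:
        mb = re.search(
            r"BoundingBox\s+" + r"\s+".join([r"([-\d.eE+]+)"] * 6), header
        )
        if mb is None:
            raise FormatError(
                f"{path}: no BoundingBox in header; pass voxel_size_nm explicitly"
            )
        x0, x1, y0, y1, z0, z1 = (float(g) for g in mb.groups())
        extent_um = np.array([x1 - x0, y1 - y0, z1 - z0])
        voxel_size_nm = extent_um * 1000.0 / np.array([nx, ny, nz])

    # x varies fastest in the AmiraMesh lattice stream
    data = np.frombuffer(raw, dtype=np.uint8).reshape((nz, ny, nx))
    return LabelVolume(data=data.copy(), voxel_size=np.asarray(voxel_size_nm, dtype=float))


def write_amira_label_field(vol: LabelVolume, path, compress: bool = True) -> None:
    """Write a :class:`LabelVolume` as an AmiraMesh byte label field.

    With ``compress=True`` the data section is HxByteRLE-encoded (Amira's
    "Amira RLE (.am)" flavour); otherwise it is written raw.
    """
    if vol.data.size and vol.data.max() > 255:
        raise ValueError(
            f"byte label field cannot hold label {int(vol.data.max())} (> 255); "
            "relabel or use the TIFF writer"
        )
    nz, ny, nx = vol.data.shape
    raw = np.ascontiguousarray(vol.data, dtype=np.uint8).tobytes()
    bx, by, bz = (np.array([nx, ny, nz]) * vol.voxel_size / 1000.0)

    if compress:
        payload = rle_encode(raw)
        decl = f"Lattice {{ byte Labels }} @1(HxByteRLE,{len(payload)})"
    else:
        payload = raw
        decl = "Lattice { byte Labels } @1"

    header = (
        "# AmiraMesh BINARY-LITTLE-ENDIAN 2.1\n"
        "\n"
        f"define Lattice {nx} {ny} {nz}\n"
        "\n"
        "Parameters {\n"
        f'    Content "{nx}x{ny}x{nz} byte, uniform coordinates",\n'
        f"    BoundingBox 0 {bx:.12g} 0 {by:.12g} 0 {bz:.12g},\n"
        '    CoordType "uniform"\n'
        "}\n"
        "\n"
        f"{decl}\n"
        "\n"
        "# Data section follows\n"
        "@1\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)
        fh.write(b"\n")
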