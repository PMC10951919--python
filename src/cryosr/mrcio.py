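"""Reading and writing movie stacks and micrographs in the MRC2014 container.

Movies are multi-section MRC/MRCS files (one section per dose-fractionated
frame, acquisition order preserved); micrographs are single-section MRC.
Only the fields the pipeline needs are interpreted: dimensions, data mode,
and the voxel (pixel) size derived from the cell dimensions.  The writer
always emits mode 2 (float32); the reader accepts modes 0/1/2/6 and promotes
to float.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["MovieStack", "read_movie", "write_movie", "read_image", "write_image"]

_HEADER_SIZE = 1024
_MAP_ID = b"MAP "

# MRC data modes -> numpy dtypes (little-endian assumed; machine stamp checked)
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


@dataclass
class MovieStack:
    """Ordered raw frames of a dose-fractionated exposure.

    Attributes
    ----------
    frames : (M, H, W) float ndarray
        Frame 0 is the first-exposed frame.
    pixel_size : float
        Pixel size in A/px (one value per stack).
    exposure_per_frame : float
        Electron exposure per frame in e-/A^2.
    """

    frames: np.ndarray
    pixel_size: float
    exposure_per_frame: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (M, H, W) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.exposure_per_frame < 0:
            raise ValueError("exposure_per_frame must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def cumulative_exposure(self) -> np.ndarray:
        """Exposure accumulated at the midpoint of each frame, e-/A^2."""
        m = self.n_frames
        return (np.arange(m) + 0.5) * self.exposure_per_frame

    def subset(self, start: int, stop: int) -> "MovieStack":
        """Frames [start, stop) with metadata propagated."""
        if stop - start < 2:
            raise ValueError("a movie subset needs at least 2 frames")
        return MovieStack(self.frames[start:stop].copy(), self.pixel_size,
                          self.exposure_per_frame)


def _read_header(fh) -> dict:
    raw = fh.read(_HEADER_SIZE)
    if len(raw) < _HEADER_SIZE:
        raise ValueError("truncated MRC header")
    # words 1-3: nx, ny, nz; word 4: mode; words 8-10: mx, my, mz;
    # words 11-13: cell dimensions in A; word 24: nsymbt
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    xlen, ylen, zlen = struct.unpack_from("<3f", raw, 40)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    if raw[208:212] not in (_MAP_ID, b"MAP\x00"):
        # tolerate pre-2014 files missing the MAP id but require sane dims
        if not (0 < nx < 1 << 20 and 0 < ny < 1 << 20 and 0 < nz < 1 << 20):
            raise ValueError("not an MRC file (missing MAP id)")
    return {"nx": nx, "ny": ny, "nz": nz, "mode": mode, "mx": mx,
            "xlen": xlen, "ylen": ylen, "my": my, "nsymbt": nsymbt}


def _pixel_size(hdr: dict) -> float:
    if hdr["mx"] <= 0 or hdr["my"] <= 0:
        raise ValueError("MRC header carries no sampling information")
    px_x = hdr["xlen"] / hdr["mx"]
    px_y = hdr["ylen"] / hdr["my"]
    if px_x <= 0 or px_y <= 0:
        raise ValueError("MRC header carries no pixel size (cell length zero)")
    if abs(px_x - px_y) > 1e-4 * px_x:
        raise ValueError("anisotropic pixel size not supported")
    return float(px_x)


def _read_data(path: Path) -> tuple[np.ndarray, float]:
    with open(path, "rb") as fh:
        hdr = _read_header(fh)
        if hdr["mode"] not in _MODE_DTYPES:
            raise ValueError(f"unsupported MRC mode {hdr['mode']}")
        fh.seek(_HEADER_SIZE + hdr["nsymbt"])
        dtype = np.dtype(_MODE_DTYPES[hdr["mode"]]).newbyteorder("<")
        count = hdr["nx"] * hdr["ny"] * hdr["nz"]
        data = np.fromfile(fh, dtype=dtype, count=count)
    if data.size != count:
        raise ValueError("MRC data block shorter than header promises")
    # sections are slowest axis; rows within a section follow the MRC
    # convention of y increasing with file offset, i.e. plain C order here
    data = data.reshape(hdr["nz"], hdr["ny"], hdr["nx"]).astype(np.float32)
    return data, _pixel_size(hdr)


def _write_mrc(path, data: np.ndarray, pixel_size: float) -> None:
    data = np.ascontiguousarray(data, dtype="<f4")
    if not np.all(np.isfinite(data)):
        raise ValueError("refusing to write non-finite values")
    nz, ny, nx = data.shape
    hdr = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", hdr, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", hdr, 28, nx, ny, nz)
    struct.pack_into("<3f", hdr, 40, nx * pixel_size, ny * pixel_size,
                     nz * pixel_size)
    struct.pack_into("<3f", hdr, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", hdr, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into("<3f", hdr, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    hdr[208:212] = _MAP_ID
    hdr[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", hdr, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        data.tofile(fh)


def read_movie(path, exposure_per_frame: float = 0.0) -> MovieStack:
    """Read a multi-section MRC/MRCS movie.

    Raises if the file holds a single section (a micrograph, not a movie)
    or if the header carries no usable pixel size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data, px = _read_data(path)
    if data.shape[0] < 2:
        raise ValueError(f"{path} is not a movie (single section)")
    return MovieStack(data, px, exposure_per_frame)


def write_movie(stack: MovieStack, path) -> None:
    """Write a MovieStack as a multi-section mode-2 MRC file."""
    _write_mrc(path, stack.frames, stack.pixel_size)


def read_image(path) -> tuple[np.ndarray, float]:
    """Read a single-section micrograph; returns (image, pixel_size)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data, px = _read_data(path)
    if data.shape[0] != 1:
        raise ValueError(f"{path} is not a single micrograph")
    return data[0], px


def write_image(image: np.ndarray, pixel_size: float, path) -> None:
    """Write a 2-D micrograph as a single-section mode-2 MRC file."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not pixel_size > 0:
        raise ValueError("pixel_size must be positive")
    _write_mrc(path, image[None, :, :], pixel_size)
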