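"""Spectrum and peak-list I/O and the spectral coordinate model.

A processed (frequency-domain) NMR spectrum is represented as a real-valued
intensity grid plus one :class:`AxisCalibration` per grid dimension.  All
internal computation is done in 0-based fractional grid points; chemical
shifts in ppm appear only at the I/O boundary (readers, peak-list writers).

Supported spectrum dialects:

``npy_container``
    A NumPy ``.npz`` archive holding the grid and the axis metadata as JSON.
    This is the canonical, reproducible interchange format of the package.
``nmrpipe``
    Single-file NMRPipe spectra (.ft2 / .ft3): a 512-float32 header followed
    by the real data plane(s).  Only real, frequency-domain data are handled.
``ucsf``
    UCSF-Sparky format: 180-byte global header, one 128-byte header per axis,
    tiled big-endian float32 data.

Peak lists can be written as Sparky ``.list``, XEASY ``.peaks`` or plain TSV
(the TSV dialect round-trips losslessly and is the canonical one).
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AxisCalibration",
    "Spectrum",
    "Peak",
    "PeakList",
    "FormatError",
    "CalibrationError",
    "read_spectrum",
    "write_spectrum",
    "read_peaklist",
    "write_peaklist",
]


class FormatError(ValueError):
    """File is not in the expected dialect."""


class CalibrationError(ValueError):
    """Axis metadata missing or inconsistent with the data grid."""


@dataclass(frozen=True)
class AxisCalibration:
    """Affine calibration of one spectral axis.

    The ppm scale decreases with increasing point index (index 0 is the
    downfield, highest-ppm edge), the usual storage order of processed
    spectra.  The carrier sits at the centre index ``(n_points - 1) / 2``,
    and the ppm step between adjacent points is
    ``spectral_width / n_points / spectrometer_freq``.

    Parameters
    ----------
    n_points : int
        Number of (real) points along the axis.
    spectral_width : float
        Sweep width in Hz.
    spectrometer_freq : float
        Larmor frequency of the axis nucleus in MHz (so Hz / MHz = ppm).
    carrier : float
        Chemical shift (ppm) at the centre of the axis.
    label : str
        Nucleus name, e.g. ``"1H"``, ``"15N"``, ``"13C"``.
    """

    n_points: int
    spectral_width: float
    spectrometer_freq: float
    carrier: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise CalibrationError(f"axis needs >= 2 points, got {self.n_points}")
        if not (self.spectral_width > 0 and self.spectrometer_freq > 0):
            raise CalibrationError("spectral_width and spectrometer_freq must be > 0")

    @property
    def ppm_per_point(self) -> float:
        return self.spectral_width / self.n_points / self.spectrometer_freq

    @property
    def center_index(self) -> float:
        return (self.n_points - 1) / 2.0

    def point_to_ppm(self, index: float) -> float:
        """Convert a fractional point index to ppm (affine, monotone)."""
        if not -1e-9 <= index <= self.n_points - 1 + 1e-9:
            raise ValueError(
                f"index {index} outside [0, {self.n_points - 1}] on axis {self.label!r}"
            )
        return self.carrier + (self.center_index - index) * self.ppm_per_point

    def ppm_to_point(self, ppm: float) -> float:
        """Inverse of :meth:`point_to_ppm`."""
        return self.center_index - (ppm - self.carrier) / self.ppm_per_point

    @property
    def ppm_limits(self) -> tuple[float, float]:
        """(highest, lowest) ppm of the axis, i.e. ppm at index 0 and n-1."""
        return self.point_to_ppm(0.0), self.point_to_ppm(self.n_points - 1.0)

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "spectral_width": self.spectral_width,
            "spectrometer_freq": self.spectrometer_freq,
            "carrier": self.carrier,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AxisCalibration":
        missing = {"n_points", "spectral_width", "spectrometer_freq", "carrier"} - set(d)
        if missing:
            raise CalibrationError(f"axis metadata missing fields {sorted(missing)}")
        return cls(
            n_points=int(d["n_points"]),
            spectral_width=float(d["spectral_width"]),
            spectrometer_freq=float(d["spectrometer_freq"]),
            carrier=float(d["carrier"]),
            label=str(d.get("label", "")),
        )


@dataclass
class Spectrum:
    """An N-dimensional real intensity grid with per-axis calibration.

    ``data`` is indexed slowest-varying axis first, matching on-disk storage.
    Raw (possibly negative) baseline values are preserved; clipping to the
    non-negative orthant is an explicit later step (`nmf.preprocess`).
    """

    data: np.ndarray
    axes: list[AxisCalibration]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != len(self.axes):
            raise CalibrationError(
                f"grid has {self.data.ndim} dimensions but {len(self.axes)} axes given"
            )
        for i, (n, ax) in enumerate(zip(self.data.shape, self.axes)):
            if n != ax.n_points:
                raise CalibrationError(
                    f"axis {i}: grid has {n} points but calibration says {ax.n_points}"
                )

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class Peak:
    """One picked resonance.

    positions_points / positions_ppm are per-axis, in the axis order of the
    source spectrum; linewidths are full widths at half maximum in points.
    """

    positions_points: tuple[float, ...]
    positions_ppm: tuple[float, ...]
    intensity: float
    linewidths: tuple[float, ...]
    component_id: int = -1
    assignment: str = "-"


@dataclass
class PeakList:
    peaks: list[Peak] = field(default_factory=list)
    source: str = ""
    axis_labels: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


# --------------------------------------------------------------------------
# npy_container dialect
# --------------------------------------------------------------------------

def _write_npz(spectrum: Spectrum, path: str) -> None:
    meta = json.dumps([ax.to_dict() for ax in spectrum.axes])
    np.savez(path, data=spectrum.data, axes_json=np.array(meta))


def _read_npz(path: str) -> Spectrum:
    with np.load(path, allow_pickle=False) as npz:
        if "data" not in npz or "axes_json" not in npz:
            raise FormatError(f"{path}: not an npy_container spectrum archive")
        data = npz["data"]
        axes = [AxisCalibration.from_dict(d) for d in json.loads(str(npz["axes_json"]))]
    return Spectrum(data=data, axes=axes)


# --------------------------------------------------------------------------
# NMRPipe dialect (single-file .ft2 / .ft3, real frequency-domain data)
# --------------------------------------------------------------------------
# Header word indices from the standard 512-float NMRPipe header layout.
_FD = {
    "FDMAGIC": 0, "FDFLTFORMAT": 1, "FDFLTORDER": 2, "FDDIMCOUNT": 9,
    "FDF3OBS": 10, "FDF3SW": 11, "FDF3ORIG": 12, "FDF3FTFLAG": 13,
    "FDF3SIZE": 15, "FDF2LABEL": 16, "FDF1LABEL": 18, "FDF3LABEL": 20,
    "FDDIMORDER1": 24, "FDDIMORDER2": 25, "FDDIMORDER3": 26, "FDDIMORDER4": 27,
    "FDF3QUADFLAG": 51, "FDF1QUADFLAG": 55, "FDF2QUADFLAG": 56, "FDPIPEFLAG": 57,
    "FDF2CAR": 66, "FDF1CAR": 67, "FDF3CAR": 68,
    "FDSIZE": 99, "FDF2SW": 100, "FDF2ORIG": 101, "FDQUADFLAG": 106,
    "FDF2OBS": 119, "FDF1OBS": 218, "FDSPECNUM": 219, "FDF2FTFLAG": 220,
    "FDTRANSPOSED": 221, "FDF1FTFLAG": 222, "FDF1SW": 229, "FDF1ORIG": 249,
    "FDFILECOUNT": 442,
}
_FLTORDER = 2.345  # byte-order sentinel stored in the header


def _pipe_axis_keys(dim: int) -> dict:
    # dim: 0 = fastest varying (F2/x), 1 = F1/y, 2 = F3/z
    return [
        {"sw": "FDF2SW", "obs": "FDF2OBS", "car": "FDF2CAR", "orig": "FDF2ORIG",
         "ft": "FDF2FTFLAG", "quad": "FDF2QUADFLAG", "label": "FDF2LABEL"},
        {"sw": "FDF1SW", "obs": "FDF1OBS", "car": "FDF1CAR", "orig": "FDF1ORIG",
         "ft": "FDF1FTFLAG", "quad": "FDF1QUADFLAG", "label": "FDF1LABEL"},
        {"sw": "FDF3SW", "obs": "FDF3OBS", "car": "FDF3CAR", "orig": "FDF3ORIG",
         "ft": "FDF3FTFLAG", "quad": "FDF3QUADFLAG", "label": "FDF3LABEL"},
    ][dim]


def _set_label(header: np.ndarray, word: int, label: str) -> None:
    raw = label.encode("ascii", "replace")[:8].ljust(8, b"\x00")
    header[word:word + 2] = np.frombuffer(raw, dtype=np.float32)


def _get_label(header: np.ndarray, word: int) -> str:
    raw = header[word:word + 2].tobytes()
    return raw.split(b"\x00", 1)[0].decode("ascii", "replace")


def _write_nmrpipe(spectrum: Spectrum, path: str) -> None:
    nd = spectrum.ndim
    if nd not in (2, 3):
        raise FormatError("nmrpipe writer handles 2D or 3D real spectra only")
    h = np.zeros(512, dtype=np.float32)
    h[_FD["FDFLTORDER"]] = _FLTORDER
    h[_FD["FDDIMCOUNT"]] = nd
    h[_FD["FDPIPEFLAG"]] = 0
    h[_FD["FDQUADFLAG"]] = 1  # real data
    h[_FD["FDFILECOUNT"]] = 1
    for k, order in zip(("FDDIMORDER1", "FDDIMORDER2", "FDDIMORDER3", "FDDIMORDER4"),
                        (2, 1, 3, 4)):
        h[_FD[k]] = order
    # storage axis nd-1 is the fastest varying -> NMRPipe F2
    for dim in range(nd):
        ax = spectrum.axes[nd - 1 - dim]
        keys = _pipe_axis_keys(dim)
        h[_FD[keys["sw"]]] = ax.spectral_width
        h[_FD[keys["obs"]]] = ax.spectrometer_freq
        h[_FD[keys["car"]]] = ax.carrier
        # ORIG = frequency (Hz) of the last point along the axis
        h[_FD[keys["orig"]]] = ax.point_to_ppm(ax.n_points - 1.0) * ax.spectrometer_freq
        h[_FD[keys["ft"]]] = 1
        h[_FD[keys["quad"]]] = 1
        _set_label(h, _FD[keys["label"]], ax.label)
    h[_FD["FDSIZE"]] = spectrum.shape[-1]
    h[_FD["FDSPECNUM"]] = spectrum.shape[-2] if nd >= 2 else 1
    if nd == 3:
        h[_FD["FDF3SIZE"]] = spectrum.shape[0]
    with open(path, "wb") as fh:
        fh.write(h.tobytes())
        fh.write(np.ascontiguousarray(spectrum.data, dtype=np.float32).tobytes())


def _read_nmrpipe(path: str) -> Spectrum:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 512 * 4:
        raise FormatError(f"{path}: too short for an NMRPipe header")
    h = np.frombuffer(raw[: 512 * 4], dtype=np.float32)
    if not math.isclose(float(h[_FD["FDFLTORDER"]]), _FLTORDER, rel_tol=1e-4):
        h = h.byteswap()
        if not math.isclose(float(h[_FD["FDFLTORDER"]]), _FLTORDER, rel_tol=1e-4):
            raise FormatError(f"{path}: NMRPipe byte-order sentinel not found")
        data_dtype = np.dtype(np.float32).newbyteorder()
    else:
        data_dtype = np.dtype(np.float32)
    nd = int(h[_FD["FDDIMCOUNT"]])
    if nd not in (2, 3):
        raise FormatError(f"{path}: unsupported dimension count {nd}")
    nx = int(h[_FD["FDSIZE"]])
    ny = int(h[_FD["FDSPECNUM"]])
    shape = (nx, ny) if nd == 2 else (nx, ny, int(h[_FD["FDF3SIZE"]]))
    axes: list[AxisCalibration] = []
    for dim in range(nd):  # dim 0 = fastest
        keys = _pipe_axis_keys(dim)
        sw = float(h[_FD[keys["sw"]]])
        obs = float(h[_FD[keys["obs"]]])
        if sw <= 0 or obs <= 0:
            raise CalibrationError(
                f"{path}: axis {nd - 1 - dim} missing sw/obs calibration"
            )
        axes.append(
            AxisCalibration(
                n_points=shape[dim],
                spectral_width=sw,
                spectrometer_freq=obs,
                carrier=float(h[_FD[keys["car"]]]),
                label=_get_label(h, _FD[keys["label"]]),
            )
        )
    grid = np.frombuffer(raw[512 * 4:], dtype=data_dtype)
    storage_shape = tuple(shape[::-1])  # slowest first
    if grid.size != int(np.prod(storage_shape)):
        raise CalibrationError(
            f"{path}: data size {grid.size} does not match header shape {storage_shape}"
        )
    return Spectrum(data=grid.reshape(storage_shape).astype(float),
                    axes=list(axes[::-1]))


# --------------------------------------------------------------------------
# UCSF-Sparky dialect
# --------------------------------------------------------------------------

def _write_ucsf(spectrum: Spectrum, path: str) -> None:
    nd = spectrum.ndim
    head = b"UCSF" + b"\x00" * 6 + bytes([nd, 1, 0, 2]) + b"\x00" * 166
    with open(path, "wb") as fh:
        fh.write(head)
        for ax in spectrum.axes:  # slowest axis first, matching data order
            hdr = bytearray(128)
            hdr[0:6] = ax.label.encode("ascii", "replace")[:6].ljust(6, b"\x00")
            struct.pack_into(">I", hdr, 8, ax.n_points)
            struct.pack_into(">I", hdr, 16, ax.n_points)  # one tile per axis
            struct.pack_into(">f", hdr, 20, ax.spectrometer_freq)
            struct.pack_into(">f", hdr, 24, ax.spectral_width)
            struct.pack_into(">f", hdr, 28, ax.carrier)
            fh.write(bytes(hdr))
        fh.write(np.ascontiguousarray(spectrum.data, dtype=">f4").tobytes())


def _read_ucsf(path: str) -> Spectrum:
    with open(path, "rb") as fh:
        head = fh.read(180)
        if len(head) < 180 or head[:4] != b"UCSF":
            raise FormatError(f"{path}: not a UCSF file")
        nd = head[10]
        if not 2 <= nd <= 3:
            raise FormatError(f"{path}: unsupported dimension count {nd}")
        axes, tiles = [], []
        for i in range(nd):
            hdr = fh.read(128)
            if len(hdr) < 128:
                raise CalibrationError(f"{path}: truncated header for axis {i}")
            npts = struct.unpack_from(">I", hdr, 8)[0]
            tile = struct.unpack_from(">I", hdr, 16)[0]
            freq = struct.unpack_from(">f", hdr, 20)[0]
            sw = struct.unpack_from(">f", hdr, 24)[0]
            center = struct.unpack_from(">f", hdr, 28)[0]
            if sw <= 0 or freq <= 0:
                raise CalibrationError(f"{path}: axis {i} missing sw/freq calibration")
            axes.append(AxisCalibration(npts, sw, freq, center,
                                        hdr[0:6].split(b"\x00")[0].decode("ascii", "replace")))
            tiles.append(tile or npts)
        flat = np.frombuffer(fh.read(), dtype=">f4")
    shape = tuple(ax.n_points for ax in axes)
    ntiles = [math.ceil(n / t) for n, t in zip(shape, tiles)]
    padded = [nt * t for nt, t in zip(ntiles, tiles)]
    if flat.size != int(np.prod(padded)):
        raise CalibrationError(
            f"{path}: data size {flat.size} does not match tiled shape {padded}"
        )
    # de-tile: file order is tile-by-tile (slowest tile index first), each tile
    # itself in C order
    tile_grid_shape = []
    for nt, t in zip(ntiles, tiles):
        tile_grid_shape.append(nt)
    arr = flat.reshape(tuple(tile_grid_shape) + tuple(tiles))
    order = [i for pair in enumerate(tiles) for i in (pair[0], pair[0] + nd)]
    # interleave (tile index, within-tile index) per axis, then crop padding
    arr = arr.transpose([order[2 * i] for i in range(nd)] +
                        [order[2 * i + 1] for i in range(nd)])
    arr = arr.transpose([i // 2 if i % 2 == 0 else nd + i // 2 for i in range(2 * nd)])
    arr = arr.reshape(padded)
    arr = arr[tuple(slice(0, n) for n in shape)]
    return Spectrum(data=arr.astype(float), axes=axes)


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------
_SPECTRUM_FORMATS = ("npy_container", "nmrpipe", "ucsf")


def _infer_spectrum_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".npz"):
        return "npy_container"
    if p.endswith((".ft2", ".ft3", ".ft", ".dat", ".pipe")):
        return "nmrpipe"
    if p.endswith(".ucsf"):
        return "ucsf"
    raise FormatError(f"cannot infer spectrum format from {path!r}; pass format=")


def read_spectrum(path, format: str | None = None) -> Spectrum:
    """Read a processed spectrum from disk.

    Axis order of the returned grid is storage order (slowest ... fastest
    varying).  Negative baseline values are preserved.
    """
    fmt = format or _infer_spectrum_format(path)
    if fmt == "npy_container":
        return _read_npz(path)
    if fmt == "nmrpipe":
        return _read_nmrpipe(path)
    if fmt == "ucsf":
        return _read_ucsf(path)
    raise FormatError(f"unknown spectrum format {fmt!r}; choose from {_SPECTRUM_FORMATS}")


def write_spectrum(spectrum: Spectrum, path, format: str | None = None) -> None:
    fmt = format or _infer_spectrum_format(path)
    if fmt == "npy_container":
        _write_npz(spectrum, path)
    elif fmt == "nmrpipe":
        _write_nmrpipe(spectrum, path)
    elif fmt == "ucsf":
        _write_ucsf(spectrum, path)
    else:
        raise FormatError(
            f"unknown spectrum format {fmt!r}; choose from {_SPECTRUM_FORMATS}"
        )


# --------------------------------------------------------------------------
# peak lists
# --------------------------------------------------------------------------

def write_peaklist(pl: PeakList, path, format: str = "tsv") -> None:
    """Write a peak list; ``tsv`` is lossless, sparky/xeasy follow convention.

    ppm columns are ordered per the source spectrum's axis order; intensities
    are printed in scientific notation with 4 significant digits.
    """
    ndim = len(pl.peaks[0].positions_ppm) if pl.peaks else len(pl.axis_labels) or 2
    labels = list(pl.axis_labels) or [f"w{i + 1}" for i in range(ndim)]
    lines: list[str] = []
    if format == "tsv":
        cols = [f"ppm_{l}" for l in labels]
        cols += ["intensity"]
        cols += [f"points_{l}" for l in labels] + [f"fwhm_{l}" for l in labels]
        cols += ["component", "assignment"]
        lines.append("\t".join(cols))
        for p in pl.peaks:
            row = [f"{v:.4f}" for v in p.positions_ppm]
            row.append(f"{p.intensity:.3e}")
            row += [f"{v:.4f}" for v in p.positions_points]
            row += [f"{v:.4f}" for v in p.linewidths]
            row += [str(p.component_id), p.assignment or "-"]
            lines.append("\t".join(row))
    elif format == "sparky":
        hdr = ["Assignment"] + [f"w{i + 1}" for i in range(ndim)] + ["Height"]
        lines.append("{:>12s}".format(hdr[0]) +
                     "".join(f"{c:>11s}" for c in hdr[1:]))
        for p in pl.peaks:
            asg = p.assignment if p.assignment not in ("", "-") else "?-" * (ndim - 1) + "?"
            lines.append(f"{asg:>12s}" +
                         "".join(f"{v:11.3f}" for v in p.positions_ppm) +
                         f"{p.intensity:>13.3e}")
    elif format == "xeasy":
        lines.append(f"# Number of dimensions {ndim}")
        for i, l in enumerate(labels, start=1):
            lines.append(f"#INAME {i} {l}")
        for i, p in enumerate(pl.peaks, start=1):
            lines.append(
                f"{i:4d} " + " ".join(f"{v:8.3f}" for v in p.positions_ppm) +
                f" 1 U {p.intensity:13.6e} 0.00e+00 e 0 0 0"
            )
    else:
        raise FormatError(f"unknown peak-list format {format!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_peaklist(path, format: str = "tsv") -> PeakList:
    """Read a peak list (tsv: lossless round trip; sparky: ppm + height)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    peaks: list[Peak] = []
    labels: tuple[str, ...] = ()
    if format == "tsv":
        if not lines:
            raise FormatError(f"{path}: empty peak-list file")
        header = lines[0].split("\t")
        labels = tuple(c[len("ppm_"):] for c in header if c.startswith("ppm_"))
        ndim = len(labels)
        for ln in lines[1:]:
            f = ln.split("\t")
            peaks.append(Peak(
                positions_ppm=tuple(float(x) for x in f[:ndim]),
                intensity=float(f[ndim]),
                positions_points=tuple(float(x) for x in f[ndim + 1:2 * ndim + 1]),
                linewidths=tuple(float(x) for x in f[2 * ndim + 1:3 * ndim + 1]),
                component_id=int(f[3 * ndim + 1]),
                assignment=f[3 * ndim + 2],
            ))
    elif format == "sparky":
        ndim_hint = None
        body = []
        for ln in lines:
            if ln.lstrip().startswith("Assignment"):
                ndim_hint = sum(1 for tok in ln.split() if tok.startswith("w"))
            else:
                body.append(ln)
        for ln in body:
            f = ln.split()
            if len(f) < 3:
                continue
            asg, rest = f[0], [float(x) for x in f[1:]]
            if ndim_hint:
                ndim = ndim_hint
            else:  # no header: assume a trailing height column unless plain 2D
                ndim = 2 if len(rest) == 2 else len(rest) - 1
            height = rest[ndim] if len(rest) > ndim else 0.0
            ppm = tuple(rest[:ndim])
            peaks.append(Peak(
                positions_ppm=ppm, intensity=height,
                positions_points=(float("nan"),) * ndim,
                linewidths=(float("nan"),) * ndim, assignment=asg,
            ))
    else:
        raise FormatError(f"unknown peak-list format {format!r}")
    return PeakList(peaks=peaks, source=str(path), axis_labels=labels)
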