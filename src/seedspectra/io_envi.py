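"""ENVI hypercube I/O, white-reference correction, band trimming and RGB rendering.

A hypercube is stored internally as a ``(row, col, band)`` float array with a
strictly increasing wavelength axis in nanometres; the ENVI interleave
(BSQ/BIL/BIP) is purely an on-disk concern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Hypercube",
    "RgbImage",
    "read_envi",
    "write_envi",
    "white_correct",
    "trim_bands",
    "render_rgb",
]

_DTYPE_CODES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_TO_CODE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}


@dataclass
class Hypercube:
    """Reflectance cube indexed ``(row, col, band)`` plus its wavelength axis (nm)."""

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("Hypercube data must be 3-D (row, col, band)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band dimension {self.data.shape[2]} does not match "
                f"{self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def pixels(self) -> np.ndarray:
        """Flattened (n_pixels, n_bands) view of the cube."""
        return self.data.reshape(-1, self.n_bands)

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose centre is nearest to ``wavelength_nm``.

        Raises ``ValueError`` if the request lies outside the cube's span.
        """
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= wavelength_nm <= hi):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside cube span [{lo}, {hi}] nm"
            )
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class RgbImage:
    """(row, col, 3) image with channels clipped to [0, 1]."""

    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.clip(np.asarray(self.data, dtype=np.float64), 0.0, 1.0)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("RgbImage data must be (row, col, 3)")


def _parse_header(header_path: Path) -> dict:
    text = header_path.read_text()
    # Collapse brace-delimited blocks (wavelength lists) onto single lines.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(header_path, raw_path) -> Hypercube:
    """Read an ENVI header/raw pair into a ``Hypercube``.

    BSQ, BIL and BIP interleaves are accepted and produce identical cubes.
    """
    header_path, raw_path = Path(header_path), Path(raw_path)
    fields = _parse_header(header_path)
    for key in ("samples", "lines", "bands"):
        if key not in fields:
            raise ValueError(f"ENVI header missing required key '{key}'")
    samples = int(fields["samples"])  # columns
    lines = int(fields["lines"])  # rows
    bands = int(fields["bands"])
    interleave = fields.get("interleave", "bsq").lower()
    dtype = _DTYPE_CODES.get(int(fields.get("data type", 4)))
    if dtype is None:
        raise ValueError(f"unsupported ENVI data type code {fields.get('data type')}")
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing required key 'wavelength'")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(x) for x in wl_text.split(",") if x.strip()])
    if wavelengths.size != bands:
        raise ValueError(
            f"header lists {wavelengths.size} wavelengths for {bands} bands"
        )

    raw = raw_path.read_bytes()
    expected = samples * lines * bands * np.dtype(dtype).itemsize
    if len(raw) != expected:
        raise ValueError(
            f"raw file size {len(raw)} bytes does not match header-declared "
            f"{expected} bytes ({lines}x{samples}x{bands} {np.dtype(dtype).name})"
        )
    flat = np.frombuffer(raw, dtype=dtype)
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave '{interleave}'")

    meta = {"interleave": interleave, "source": str(raw_path)}
    for extra in ("description", "view side", "accession", "mm per pixel"):
        if extra in fields:
            meta[extra] = fields[extra]
    return Hypercube(data=np.ascontiguousarray(data, dtype=np.float64),
                     wavelengths=wavelengths, meta=meta)


def write_envi(cube: Hypercube, header_path, raw_path, interleave: str = "bsq",
               dtype=np.float64) -> None:
    """Write a cube as an ENVI header/raw pair in the requested interleave."""
    header_path, raw_path = Path(header_path), Path(raw_path)
    interleave = interleave.lower()
    rows, cols, bands = cube.shape
    data = cube.data.astype(dtype)
    if interleave == "bsq":
        flat = data.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = data.transpose(0, 2, 1)
    elif interleave == "bip":
        flat = data
    else:
        raise ValueError(f"unknown interleave '{interleave}'")
    raw_path.write_bytes(flat.tobytes())

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_TO_CODE[np.dtype(dtype)]}",
        f"interleave = {interleave}",
        "byte order = 0",
        f"wavelength = {{ {wl} }}",
    ]
    for key in ("view side", "accession", "mm per pixel"):
        if key in cube.meta:
            lines.append(f"{key} = {cube.meta[key]}")
    header_path.write_text("\n".join(lines) + "\n")


def white_correct(raw: Hypercube, white_region: np.ndarray,
                  dark_level: float = 0.0) -> Hypercube:
    """Convert raw counts to reflectance against an in-scene white reference.

    Per band: ``R(b) = (raw(b) - dark) / (mean_white(b) - dark)``, so pixels of
    the white panel itself map to ~1. ``dark_level`` defaults to 0 (no dark
    frame).
    """
    white_region = np.asarray(white_region, dtype=bool)
    if white_region.shape != raw.shape[:2]:
        raise ValueError("white_region shape must match the cube's spatial shape")
    if not white_region.any():
        raise ValueError("white_region is empty")
    white_mean = raw.data[white_region].mean(axis=0)  # per band
    denom = white_mean - dark_level
    bad = np.where(denom <= 0)[0]
    if bad.size:
        raise ValueError(
            f"white reference invalid (mean white <= dark level) in bands {bad.tolist()}"
        )
    corrected = (raw.data - dark_level) / denom
    meta = dict(raw.meta)
    meta["white_corrected"] = True
    return Hypercube(data=corrected, wavelengths=raw.wavelengths.copy(), meta=meta)


def trim_bands(cube: Hypercube, fraction: float = 0.05, *,
               n_trim_start: int | None = None,
               n_trim_end: int | None = None) -> Hypercube:
    """Drop noisy band extremes.

    By default removes ``floor(fraction * n_bands)`` bands at each end.
    Explicit ``n_trim_start`` / ``n_trim_end`` counts override the fraction,
    e.g. (10, 11) retains 183 of 204 bands.
    """
    if not (0 <= fraction < 0.5):
        raise ValueError("fraction must be in [0, 0.5)")
    n = cube.n_bands
    lo = int(np.floor(fraction * n)) if n_trim_start is None else int(n_trim_start)
    hi = int(np.floor(fraction * n)) if n_trim_end is None else int(n_trim_end)
    if lo + hi >= n:
        raise ValueError("trim counts remove every band")
    stop = n - hi
    meta = dict(cube.meta)
    meta["trimmed_bands"] = (lo, hi)
    return Hypercube(data=cube.data[:, :, lo:stop].copy(),
                     wavelengths=cube.wavelengths[lo:stop].copy(), meta=meta)


def render_rgb(cube: Hypercube, r_nm: float = 640.0, g_nm: float = 550.0,
               b_nm: float = 460.0, *, stretch: tuple[float, float] = (1.0, 99.0)
               ) -> RgbImage:
    """Render a false-colour RGB preview from three nearest bands.

    Each channel is rescaled to [0, 1] by a single global percentile stretch
    shared across channels; the stretch limits are recorded in ``meta``.
    """
    idx = [cube.band_index(w) for w in (r_nm, g_nm, b_nm)]
    channels = cube.data[:, :, idx]
    lo, hi = np.percentile(channels, stretch)
    if hi <= lo:
        scaled = np.zeros_like(channels)
    else:
        scaled = (channels - lo) / (hi - lo)
    meta = {
        "bands_nm": [float(cube.wavelengths[i]) for i in idx],
        "stretch_percentiles": tuple(stretch),
        "stretch_limits": (float(lo), float(hi)),
    }
    return RgbImage(data=scaled, meta=meta)
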