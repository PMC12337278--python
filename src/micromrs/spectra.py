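"""Data model and minimal preprocessing for 1D 1H spectra and FIDs.

A :class:`Spectrum` is a chemical-shift axis (ppm, stored ascending) plus real
intensities and per-sample metadata; an :class:`FID` is the complex time-domain
signal it is Fourier-transformed from. Preprocessing is deliberately minimal:
Fourier transform with exponential apodization and zero filling, zero-order
phasing (or magnitude mode), rigid referencing to the unsuppressed water line,
and constant baseline subtraction estimated from a signal-free window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "FID",
    "Spectrum",
    "RegionSet",
    "DEFAULT_REGIONS",
    "fid_to_spectrum",
    "reference_to_water",
    "baseline_correct",
    "read_spectra",
    "write_spectra",
]

WATER_PPM = 4.70
#: default signal-free window used for baseline / noise estimation
NOISE_WINDOW = (9.0, 10.0)


class FormatError(ValueError):
    """Raised when a spectrum file violates the expected dialect."""


@dataclass
class FID:
    """Complex free-induction decay with acquisition bookkeeping.

    ``dwell_time`` is seconds per complex point, so the spectral width is
    ``1/dwell_time`` Hz; dividing by ``spectrometer_freq`` (the 1H Larmor
    frequency in MHz, ≈300 at 7 T) gives the width of the ppm axis.
    """

    samples: np.ndarray
    dwell_time: float
    spectrometer_freq: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1:
            raise ValueError("FID samples must be one-dimensional")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")
        if self.spectrometer_freq <= 0:
            raise ValueError("spectrometer_freq must be positive")

    @property
    def n_points(self) -> int:
        return self.samples.size

    @property
    def sweep_width_hz(self) -> float:
        return 1.0 / self.dwell_time


@dataclass
class Spectrum:
    """1D 1H spectrum: strictly ascending ppm axis + real intensities.

    NMR convention plots ppm descending; storage is ascending so that region
    slicing is plain interval arithmetic. ``referenced`` records whether the
    axis has been pinned to the water resonance.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)
    referenced: bool = False

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        d = np.diff(self.ppm)
        if self.ppm.size >= 2 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if self.ppm.size >= 2 and np.all(d < 0):  # normalize to ascending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()

    @property
    def bin_width(self) -> float:
        return float(np.median(np.diff(self.ppm)))

    def region_mask(self, lo: float, hi: float) -> np.ndarray:
        """Closed-interval membership of bin centers."""
        return (self.ppm >= lo) & (self.ppm <= hi)

    def copy(self, **changes) -> "Spectrum":
        out = replace(self, **changes)
        out.metadata = dict(changes.get("metadata", self.metadata))
        return out


class RegionSet(Mapping):
    """Named closed chemical-shift intervals [lo, hi] in ppm."""

    def __init__(self, regions: Mapping[str, tuple[float, float]]):
        self._regions = {}
        for name, (lo, hi) in regions.items():
            if not lo < hi:
                raise ValueError(f"region {name!r}: need lo < hi, got [{lo}, {hi}]")
            self._regions[name] = (float(lo), float(hi))

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self._regions[name]

    def __iter__(self):
        return iter(self._regions)

    def __len__(self) -> int:
        return len(self._regions)

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}=[{lo}, {hi}]" for k, (lo, hi) in self._regions.items())
        return f"RegionSet({inner})"


#: The six chemical-shift regions of the biomarker panel. PLC spans the whole
#: proton-lipid compartment; Saturate the bulk (CH2)n methylene envelope; S1 the
#: terminal methyl; S3 the alpha-carboxyl methylene; SaturateL/SaturateR split
#: the Saturate window at the methylene line (left = downfield in plotting
#: convention, i.e. the higher-ppm half).
DEFAULT_REGIONS = RegionSet(
    {
        "PLC": (0.83, 2.8),
        "Saturate": (1.1, 1.5),
        "S1": (0.83, 1.03),
        "S3": (2.23, 2.36),
        "SaturateL": (1.3, 1.5),
        "SaturateR": (1.1, 1.3),
    }
)


# ---------------------------------------------------------------------------
# FID -> spectrum


def _zero_order_phase(spec_complex: np.ndarray, ppm: np.ndarray,
                      region: tuple[float, float]) -> float:
    """Zero-order phase (rad) maximizing the real-part integral over a region."""
    mask = (ppm >= region[0]) & (ppm <= region[1])
    if not mask.any():
        mask = np.ones_like(ppm, dtype=bool)
    z = spec_complex[mask].sum()
    # real part of z*exp(-i*phi) is maximized at phi = angle(z)
    return float(np.angle(z))


def fid_to_spectrum(
    fid: FID,
    apodization_hz: float = 0.0,
    zero_fill_factor: int = 1,
    mode: str = "real",
    carrier_ppm: float | None = None,
    phase_region: tuple[float, float] = (0.83, 2.8),
) -> Spectrum:
    """Fourier transform an FID to a 1D spectrum on a ppm axis.

    Parameters
    ----------
    apodization_hz
        Exponential line broadening; multiplies the FID by ``exp(-pi*lb*t)``,
        adding ``lb`` Hz to every Lorentzian FWHM.
    zero_fill_factor
        1, 2 or 4; pads the FID to that multiple of its length before the FFT.
    mode
        ``"real"`` (zero-order phased real part, phase chosen to maximize the
        integral over ``phase_region``) or ``"magnitude"``.
    carrier_ppm
        Chemical shift of the zero-frequency channel; defaults to the FID's
        ``metadata["carrier_ppm"]`` or 5.0.
    """
    if apodization_hz < 0:
        raise ValueError("apodization_hz must be >= 0")
    if zero_fill_factor not in (1, 2, 4):
        raise ValueError("zero_fill_factor must be 1, 2 or 4")
    if mode not in ("real", "magnitude"):
        raise ValueError("mode must be 'real' or 'magnitude'")
    if not np.all(np.isfinite(fid.samples)):
        raise ValueError("FID contains non-finite samples")

    n = fid.n_points
    t = np.arange(n) * fid.dwell_time
    data = fid.samples * np.exp(-np.pi * apodization_hz * t)
    n_fft = n * zero_fill_factor
    spec_c = np.fft.fftshift(np.fft.fft(data, n=n_fft))
    freq_hz = np.fft.fftshift(np.fft.fftfreq(n_fft, d=fid.dwell_time))
    if carrier_ppm is None:
        carrier_ppm = float(fid.metadata.get("carrier_ppm", 5.0))
    ppm = freq_hz / fid.spectrometer_freq + carrier_ppm

    if mode == "magnitude":
        intensity = np.abs(spec_c)
    else:
        phi = _zero_order_phase(spec_c, ppm, phase_region)
        intensity = np.real(spec_c * np.exp(-1j * phi))
    if not np.all(np.isfinite(intensity)):
        raise ValueError("non-finite intensities after transform")
    meta = {k: v for k, v in fid.metadata.items() if k != "carrier_ppm"}
    return Spectrum(ppm=ppm, intensity=intensity, metadata=meta)


# ---------------------------------------------------------------------------
# referencing & baseline


def reference_to_water(spec: Spectrum, water_ppm: float = WATER_PPM) -> Spectrum:
    """Rigidly shift the ppm axis so the global maximum sits at ``water_ppm``.

    The unsuppressed water line dominates every spectrum here, so the global
    maximum is the water resonance. Ties are broken toward higher ppm with a
    warning. Exactly idempotent: after referencing, the argmax bin lies at
    ``water_ppm`` and a second call shifts by zero.
    """
    imax = np.flatnonzero(spec.intensity == spec.intensity.max())
    if imax.size == 0 or not np.isfinite(spec.intensity.max()):
        raise ValueError("spectrum has no finite global maximum")
    if imax.size > 1:
        warnings.warn(
            f"{imax.size} bins tie for the global maximum; using the highest-ppm one",
            stacklevel=2,
        )
    shift = water_ppm - spec.ppm[imax[-1]]
    out = spec.copy(ppm=spec.ppm + shift, referenced=True)
    out.metadata["reference_shift_ppm"] = float(shift)
    return out


def baseline_correct(
    spec: Spectrum, window: tuple[float, float] = NOISE_WINDOW
) -> Spectrum:
    """Subtract the median intensity of a signal-free window (constant offset)."""
    mask = spec.region_mask(*window)
    if not mask.any():
        raise ValueError(
            f"baseline window [{window[0]}, {window[1]}] ppm is outside the axis "
            f"[{spec.ppm[0]:.3g}, {spec.ppm[-1]:.3g}]"
        )
    offset = float(np.median(spec.intensity[mask]))
    out = spec.copy(intensity=spec.intensity - offset)
    out.metadata["baseline_offset"] = offset + spec.metadata.get("baseline_offset", 0.0)
    return out


# ---------------------------------------------------------------------------
# I/O — CSV dialect (`# key: value` header, then `ppm,intensity`) and JCAMP-DX

_META_SCALAR_KEYS = {
    "sample_id": str,
    "cohort_label": str,
    "sensor_id": str,
    "channel_index": int,
    "n_averages": int,
    "referenced": lambda s: s.lower() == "true",
    "repetition_time_s": float,
    "reference_shift_ppm": float,
    "baseline_offset": float,
}


def write_spectra(specs: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to a directory (one ``<sample_id>.csv`` each) or a single
    CSV file when given a ``.csv`` path and exactly one spectrum."""
    path = Path(path)
    specs = list(specs)
    if path.suffix == ".csv":
        if len(specs) != 1:
            raise ValueError("a .csv path holds exactly one spectrum; pass a directory")
        _write_one(specs[0], path)
        return
    path.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(specs):
        sid = str(s.metadata.get("sample_id", f"spectrum{i:04d}"))
        _write_one(s, path / f"{sid}.csv")


def _write_one(spec: Spectrum, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# referenced: {spec.referenced}\n")
        for k, v in sorted(spec.metadata.items()):
            if isinstance(v, (str, int, float, bool, np.integer, np.floating)):
                fh.write(f"# {k}: {v}\n")
        fh.write("ppm,intensity\n")
        for p, y in zip(spec.ppm, spec.intensity):
            fh.write(f"{float(p)!r},{float(y)!r}\n")


def read_spectra(path: str | Path, format: str | None = None) -> list[Spectrum]:
    """Read spectra from a CSV file/directory or a JCAMP-DX file (read-only)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise FormatError(f"no spectrum CSV files in {path}")
        return [s for f in files for s in read_spectra(f, format)]
    fmt = format
    if fmt is None:
        fmt = "jcamp" if path.suffix.lower() in (".jdx", ".dx", ".jcamp") else "csv"
    if fmt == "csv":
        return [_read_csv(path)]
    if fmt == "jcamp":
        return [_read_jcamp(path)]
    raise ValueError(f"unknown format {fmt!r}")


def _read_csv(path: Path) -> Spectrum:
    meta: dict = {}
    referenced = False
    ppm, inten = [], []
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise FormatError(f"{path}: empty spectrum file")
    data_started = False
    for ln, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if data_started:
                raise FormatError(f"{path}:{ln}: metadata after data rows")
            key, _, val = line.lstrip("# ").partition(":")
            key, val = key.strip(), val.strip()
            conv = _META_SCALAR_KEYS.get(key, str)
            try:
                parsed = conv(val)
            except ValueError:
                parsed = val
            if key == "referenced":
                referenced = bool(parsed)
            else:
                meta[key] = parsed
            continue
        if line.lower().startswith("ppm,"):
            data_started = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}:{ln}: expected 'ppm,intensity', got {line!r}")
        try:
            ppm.append(float(parts[0]))
            inten.append(float(parts[1]))
        except ValueError as e:
            raise FormatError(f"{path}:{ln}: {e}") from None
    if not ppm:
        raise FormatError(f"{path}: no data rows")
    arr = np.asarray(ppm)
    d = np.diff(arr)
    if arr.size >= 2 and not (np.all(d > 0) or np.all(d < 0)):
        bad = int(np.argmin(np.abs(d))) + 1
        raise FormatError(f"{path}: ppm axis not monotone near data row {bad}")
    return Spectrum(ppm=arr, intensity=np.asarray(inten), metadata=meta,
                    referenced=referenced)


def _read_jcamp(path: Path) -> Spectrum:
    """Minimal JCAMP-DX reader for (X++(Y..Y)) and (XY..XY) XYDATA tables."""
    header: dict[str, str] = {}
    ys: list[float] = []
    xs: list[float] = []
    mode = None
    firstx = lastx = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                val = val.strip()
                header[key] = val
                if key == "XYDATA":
                    mode = "xyy" if "X++" in val.upper() else "xyxy"
                elif key == "PEAKTABLE":
                    mode = "xyxy"
                elif key == "END":
                    break
                continue
            if mode is None:
                continue
            tokens = line.replace(",", " ").split()
            try:
                vals = [float(t) for t in tokens]
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-numeric token in XYDATA") from None
            if mode == "xyy":
                if len(vals) < 2:
                    raise FormatError(f"{path}:{ln}: X++(Y..Y) row needs >=2 values")
                ys.extend(vals[1:])
            else:
                if len(vals) % 2:
                    raise FormatError(f"{path}:{ln}: odd token count in XY..XY row")
                xs.extend(vals[0::2])
                ys.extend(vals[1::2])
    if mode is None or not ys:
        raise FormatError(f"{path}: no XYDATA table found")
    yfac = float(header.get("YFACTOR", 1.0))
    xfac = float(header.get("XFACTOR", 1.0))
    if mode == "xyy":
        firstx = float(header["FIRSTX"]) if "FIRSTX" in header else None
        lastx = float(header["LASTX"]) if "LASTX" in header else None
        if firstx is None or lastx is None:
            raise FormatError(f"{path}: X++(Y..Y) needs FIRSTX and LASTX")
        x = np.linspace(firstx, lastx, len(ys))
    else:
        x = np.asarray(xs) * xfac
    y = np.asarray(ys) * yfac
    meta = {"sample_id": header.get("TITLE", path.stem)}
    return Spectrum(ppm=x, intensity=y, metadata=meta)
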