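"""Leaf reflectance spectra: I/O, sensor splicing, resampling, and scalar traits.

A :class:`Spectrum` is a per-leaf reflectance curve on a strictly increasing
wavelength grid (nm). Field spectrometers stitch together two or three
detectors, which leaves small step discontinuities at the sensor overlap
wavelengths; :func:`splice_sensors` repairs these by linear interpolation over
a short window anchored on the lower-wavelength (reference) sensor. Scalar
traits are extracted either as single-band reflectances (:func:`band`) or as
normalized indices: the chlorophyll:carotenoid index

    CCI = (R531 - R645) / (R531 + R645)

and the water band index

    WBI = R970 / R900,

both unitless proxies for pigment balance and leaf water content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "read_spectra",
    "write_spectra",
    "splice_sensors",
    "resample",
    "to_transmittance",
    "band",
    "cci",
    "wbi",
    "qc_reflectance",
]


@dataclass
class Spectrum:
    """A single reflectance curve.

    Parameters
    ----------
    wavelengths : array of float
        Strictly increasing wavelength grid in nm.
    reflectance : array of float
        Reflectance fraction per wavelength; finite.
    meta : dict
        Optional individual metadata (id, garden, population, family, block).
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1 or self.reflectance.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D")
        if self.wavelengths.size != self.reflectance.size:
            raise ValueError("wavelengths and reflectance lengths differ")
        dif = np.diff(self.wavelengths)
        if np.any(dif == 0):
            bad = self.wavelengths[1:][dif == 0][0]
            raise ValueError(f"duplicate wavelength {bad:g} nm")
        if np.any(dif < 0):
            bad = self.wavelengths[1:][dif < 0][0]
            raise ValueError(f"non-monotone wavelengths at {bad:g} nm")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("non-finite reflectance values")

    @property
    def id(self) -> str | None:
        return self.meta.get("id")

    def copy(self, **updates) -> "Spectrum":
        new = Spectrum(
            self.wavelengths.copy(), self.reflectance.copy(), dict(self.meta)
        )
        for k, v in updates.items():
            setattr(new, k, v)
        return new


@dataclass
class SpectrumSet:
    """A collection of spectra on one shared wavelength grid."""

    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("empty SpectrumSet")
        g0 = self.spectra[0].wavelengths
        for s in self.spectra[1:]:
            if s.wavelengths.shape != g0.shape or not np.array_equal(
                s.wavelengths, g0
            ):
                raise ValueError("spectra do not share a common grid")
        ids = [s.id for s in self.spectra if s.id is not None]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate spectrum ids")

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    @property
    def ids(self) -> list[str | None]:
        return [s.id for s in self.spectra]

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, key):
        if isinstance(key, str):
            for s in self.spectra:
                if s.id == key:
                    return s
            raise KeyError(key)
        return self.spectra[key]

    def to_matrix(self) -> np.ndarray:
        """Samples x bands reflectance matrix (row order = spectra order)."""
        return np.vstack([s.reflectance for s in self.spectra])

    def map(self, fn) -> "SpectrumSet":
        return SpectrumSet([fn(s) for s in self.spectra])

    def to_frame(self) -> pd.DataFrame:
        """Wavelength-first wide table (wavelength column + one column per id)."""
        data = {"wavelength": self.grid}
        for i, s in enumerate(self.spectra):
            data[s.id if s.id is not None else f"s{i}"] = s.reflectance
        return pd.DataFrame(data)


def read_spectra(
    path: str | Path,
    format: str = "csv_matrix",
    metadata: str | Path | None = None,
) -> SpectrumSet:
    """Read a spectral matrix from disk.

    ``csv_matrix``: first column is wavelength (nm), one column per
    individual, header row carries individual ids. ``instrument_ascii``:
    whitespace-delimited two-column ASCII export (wavelength, reflectance)
    for a single spectrum, comment lines starting with ``#`` or ``/`` skipped.

    An optional metadata sidecar CSV keyed by ``id`` supplies garden,
    population, family and block per individual.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv_matrix":
        df = pd.read_csv(path)
        wl = _parse_wavelength_column(df)
        spectra = []
        for col in df.columns[1:]:
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy(float)
            if np.any(~np.isfinite(vals)):
                i = int(np.flatnonzero(~np.isfinite(vals))[0])
                raise ValueError(
                    f"non-numeric reflectance for id {col!r} at "
                    f"{wl[i]:g} nm"
                )
            spectra.append(Spectrum(wl, vals, {"id": str(col)}))
    elif format == "instrument_ascii":
        rows = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line[0] in "#/;":
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                continue
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                continue
        if not rows:
            raise ValueError(f"no spectral rows parsed from {path}")
        arr = np.array(rows)
        spectra = [Spectrum(arr[:, 0], arr[:, 1], {"id": path.stem})]
    else:
        raise ValueError(f"unknown format {format!r}")
    out = SpectrumSet(spectra)
    if metadata is not None:
        attach_metadata(out, pd.read_csv(metadata))
    return out


def _parse_wavelength_column(df: pd.DataFrame) -> np.ndarray:
    wl = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(wl)):
        i = int(np.flatnonzero(~np.isfinite(wl))[0])
        raise ValueError(f"non-numeric wavelength in row {i}")
    dif = np.diff(wl)
    if np.any(dif == 0):
        raise ValueError(
            f"duplicate wavelength {wl[1:][dif == 0][0]:g} nm in row "
            f"{int(np.flatnonzero(dif == 0)[0]) + 1}"
        )
    if np.any(dif < 0):
        raise ValueError(
            f"non-monotone wavelengths in row {int(np.flatnonzero(dif < 0)[0]) + 1}"
        )
    return wl


def attach_metadata(sset: SpectrumSet, meta: pd.DataFrame) -> SpectrumSet:
    """Attach garden/population/family/block from a sidecar table keyed by id."""
    meta = meta.set_index(meta["id"].astype(str))
    for s in sset:
        if s.id in meta.index:
            row = meta.loc[s.id]
            for key in ("garden", "population", "family", "block"):
                if key in row.index and pd.notna(row[key]):
                    s.meta[key] = str(row[key])
    return sset


def write_spectra(sset: SpectrumSet, path: str | Path) -> None:
    """Write a SpectrumSet as a wavelength-first CSV matrix."""
    sset.to_frame().to_csv(path, index=False, float_format="%.12g")


def qc_reflectance(sset: SpectrumSet, lo: float = 0.0, hi: float = 1.0):
    """Screen raw spectra for out-of-range reflectance.

    Instrument artifacts can push apparent reflectance slightly above 1 or
    below 0. Offending spectra are excluded (not clipped) and reported.

    Returns
    -------
    (clean, report) : (SpectrumSet | None, DataFrame)
        Spectra passing the screen, and a per-spectrum report with the
        number of out-of-range bands and the worst value.
    """
    rows, keep = [], []
    for s in sset:
        bad = (s.reflectance < lo) | (s.reflectance > hi)
        n_bad = int(bad.sum())
        worst = float(
            s.reflectance[bad][np.argmax(np.abs(s.reflectance[bad] - 0.5))]
        ) if n_bad else np.nan
        rows.append({"id": s.id, "n_out_of_range": n_bad, "worst_value": worst})
        if not n_bad:
            keep.append(s)
    report = pd.DataFrame(rows)
    clean = SpectrumSet(keep) if keep else None
    return clean, report


def splice_sensors(
    s: Spectrum,
    splice_points: Sequence[float],
    interp_widths: Sequence[float],
) -> Spectrum:
    """Repair sensor-overlap discontinuities by windowed linear interpolation.

    For each splice point ``p`` with width ``w``, reflectance inside the
    window ``[p, p + w]`` is replaced by the straight line between the
    values at the window endpoints; the lower-wavelength segment acts as the
    reference. The grid is unchanged.
    """
    splice_points = list(splice_points)
    interp_widths = list(interp_widths)
    if len(splice_points) != len(interp_widths):
        raise ValueError("splice_points and interp_widths lengths differ")
    if not splice_points:
        return s.copy()
    wl, refl = s.wavelengths, s.reflectance.copy()
    order = np.argsort(splice_points)
    pts = [splice_points[i] for i in order]
    wds = [interp_widths[i] for i in order]
    prev_end = -np.inf
    for p, w in zip(pts, wds):
        if w <= 0:
            raise ValueError(f"non-positive interpolation width {w:g}")
        if p < wl[0] or p + w > wl[-1]:
            raise ValueError(
                f"splice window [{p:g}, {p + w:g}] extends past grid "
                f"[{wl[0]:g}, {wl[-1]:g}]"
            )
        if p <= prev_end:
            raise ValueError("overlapping splice windows")
        prev_end = p + w
        # anchor on the nearest grid points just outside the window
        i_lo = int(np.searchsorted(wl, p, side="left")) - 1
        i_hi = int(np.searchsorted(wl, p + w, side="right"))
        if i_lo < 0 or i_hi >= wl.size:
            raise ValueError(
                f"splice window [{p:g}, {p + w:g}] has no anchor bands"
            )
        inside = slice(i_lo + 1, i_hi)
        x0, x1 = wl[i_lo], wl[i_hi]
        y0, y1 = refl[i_lo], refl[i_hi]
        refl[inside] = y0 + (wl[inside] - x0) * (y1 - y0) / (x1 - x0)
    return Spectrum(wl, refl, dict(s.meta))


def resample(s: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linearly interpolate reflectance onto a new grid (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D sequence")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] < s.wavelengths[0] or grid[-1] > s.wavelengths[-1]:
        raise ValueError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] outside source range "
            f"[{s.wavelengths[0]:g}, {s.wavelengths[-1]:g}]"
        )
    vals = np.interp(grid, s.wavelengths, s.reflectance)
    return Spectrum(grid, vals, dict(s.meta))


def to_transmittance(s: Spectrum) -> Spectrum:
    """T = 1 - R on the same grid; requires R in [0, 1]."""
    bad = (s.reflectance < 0) | (s.reflectance > 1)
    if np.any(bad):
        bands = ", ".join(f"{w:g}" for w in s.wavelengths[bad][:5])
        raise ValueError(f"reflectance outside [0, 1] at bands: {bands}")
    return Spectrum(s.wavelengths, 1.0 - s.reflectance, dict(s.meta))


def band(s: Spectrum, wavelength: float) -> float:
    """Reflectance at a wavelength; linear interpolation off-grid."""
    wl = s.wavelengths
    if wavelength < wl[0] or wavelength > wl[-1]:
        raise ValueError(
            f"wavelength {wavelength:g} nm outside grid "
            f"[{wl[0]:g}, {wl[-1]:g}]"
        )
    return float(np.interp(wavelength, wl, s.reflectance))


def cci(s: Spectrum) -> float:
    """Chlorophyll:carotenoid index (R531 - R645)/(R531 + R645)."""
    r531, r645 = band(s, 531.0), band(s, 645.0)
    denom = r531 + r645
    if denom == 0:
        raise ZeroDivisionError("R531 + R645 = 0")
    return (r531 - r645) / denom


def wbi(s: Spectrum) -> float:
    """Water band index R970 / R900."""
    r900 = band(s, 900.0)
    if r900 == 0:
        raise ZeroDivisionError("R900 = 0")
    return band(s, 970.0) / r900
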